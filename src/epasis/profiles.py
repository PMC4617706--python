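"""Elution-profile construction.

Raw replicate intensities become per-protein *cumulative relative
abundance* profiles: within each replicate the running intensity sum over
the ordered elution steps is divided by the replicate total, and the
per-replicate profiles are averaged.  Normalizing before averaging keeps
high-yield replicates from dominating the mean profile.

The presence filter reproduces the replication requirement of the study
design: a protein must be quantified in at least a given fraction of the
bait replicates (default 4/7) to enter the analysis at all.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .containers import ElutionProfileSet, IntensityMatrix

__all__ = [
    "presence_filter",
    "cumulative_profile",
    "average_replicates",
    "build_profiles",
]


def presence_filter(m: IntensityMatrix, min_fraction: float = 4 / 7) -> IntensityMatrix:
    """Keep proteins present in at least ``min_fraction`` of replicates.

    A protein is *present* in a replicate when it has at least one
    non-missing, positive intensity across that replicate's steps.  The
    replicate-count threshold is ``ceil(min_fraction * n_replicates)``,
    so 4/7 with seven replicates requires exactly four.

    Raises
    ------
    ValueError
        If the matrix is empty or ``min_fraction`` is outside (0, 1].
    """
    if len(m.proteins) == 0 or m.n_replicates == 0:
        raise ValueError("cannot filter an empty intensity matrix")
    if not 0 < min_fraction <= 1:
        raise ValueError(f"min_fraction must be in (0, 1], got {min_fraction}")
    # 1e-9 guard: 3/7*7 rounds up to 3.0000000000000004 in doubles
    required = math.ceil(min_fraction * m.n_replicates - 1e-9)
    counts = m.present_in().sum(axis=1)
    keep = [acc for acc in m.proteins if counts[acc] >= required]
    return m.subset(keep)


def cumulative_profile(intensities: np.ndarray) -> np.ndarray:
    """Cumulative relative abundance of one replicate's step intensities.

    Missing values are treated as zero.  The running sum is divided by
    the total so the profile is monotone non-decreasing and ends at
    exactly 1.

    Raises
    ------
    ValueError
        If the total intensity is zero — the replicate contributes no
        defined profile and must be excluded from averaging, never
        silently zeroed.
    """
    v = np.nan_to_num(np.asarray(intensities, dtype=float), nan=0.0)
    if (v < 0).any():
        raise ValueError("negative intensities")
    cs = np.cumsum(v)
    total = cs[-1]
    if total <= 0:
        raise ValueError("zero total intensity: profile undefined for this replicate")
    return cs / total


def average_replicates(replicate_profiles: list[np.ndarray]) -> np.ndarray:
    """Element-wise mean of the defined per-replicate profiles."""
    if len(replicate_profiles) == 0:
        raise ValueError(
            "no defined replicate profiles; protein should have been filtered"
        )
    stack = np.vstack(replicate_profiles)
    return stack.mean(axis=0)


def build_profiles(m: IntensityMatrix) -> ElutionProfileSet:
    """Averaged cumulative profiles for every protein in the matrix.

    Replicates in which a protein has zero total intensity are excluded
    from that protein's mean.  A protein with no defined replicate at all
    raises (run :func:`presence_filter` first).
    """
    arr = m.to_array()
    rows = []
    n_used = []
    for i, acc in enumerate(m.proteins):
        reps = []
        for r in range(m.n_replicates):
            v = np.nan_to_num(arr[i, r], nan=0.0)
            if v.sum() > 0:
                reps.append(cumulative_profile(v))
        if not reps:
            raise ValueError(f"protein {acc!r} has no replicate with nonzero intensity")
        rows.append(average_replicates(reps))
        n_used.append(len(reps))
    profiles = pd.DataFrame(np.vstack(rows), index=m.proteins, columns=m.steps)
    return ElutionProfileSet(
        profiles=profiles,
        steps=list(m.steps),
        n_replicates_used=pd.Series(n_used, index=m.proteins),
    )
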