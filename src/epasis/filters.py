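"""AP-MS evidence filters and the significance-A ratio-outlier statistic.

Two classic evidence rules for pull-down interactomes: a replication +
control rule (keep proteins seen in enough bait runs and absent from
control runs) and a two-unique-peptide identification rule.  For SILAC
experiments, significance A flags proteins whose log ratio is an outlier
of the ratio distribution, using percentile-based robust sigma estimates
and a normal tail probability.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import erfc
from statsmodels.stats.multitest import multipletests

__all__ = [
    "pulldown_filter",
    "two_peptide_rule",
    "significance_a",
]

#: Percentiles giving the normal-equivalent robust sigma: the 15.87th and
#: 84.13th percentiles of a normal distribution sit one sigma from the median.
_P_LOW, _P_MID, _P_HIGH = 15.87, 50.0, 84.13


def _check_evidence(e: pd.DataFrame) -> pd.DataFrame:
    required = {"accession", "run", "run_class", "unique_peptides"}
    missing = required - set(e.columns)
    if missing:
        raise ValueError(f"evidence table missing columns: {sorted(missing)}")
    bad = set(e["run_class"].unique()) - {"bait", "control"}
    if bad:
        raise ValueError(f"unknown run classes: {sorted(bad)}")
    e = e.copy()
    if "detected" not in e.columns:
        e["detected"] = e["unique_peptides"] >= 1
    if (e["detected"] & (e["unique_peptides"] < 1)).any():
        raise ValueError("detected flag requires unique_peptides >= 1")
    return e


def pulldown_filter(
    evidence: pd.DataFrame, min_bait_runs: int = 3, max_control_runs: int = 0
) -> list[str]:
    """Replication + control filter for pull-down evidence.

    Retains proteins detected in at least ``min_bait_runs`` bait runs
    *and* in at most ``max_control_runs`` control runs (defaults 3 and
    0: proteins seen in fewer than three of four bait experiments and/or
    in any control experiment are removed).  Output sorted by accession.
    """
    e = _check_evidence(evidence)
    bait_runs = e.loc[e["run_class"] == "bait", "run"].unique()
    if len(bait_runs) == 0:
        raise ValueError("no bait runs in evidence table")
    if min_bait_runs > len(bait_runs):
        raise ValueError(
            f"min_bait_runs={min_bait_runs} exceeds {len(bait_runs)} bait runs"
        )
    det = e[e["detected"]]
    counts = (
        det.groupby(["accession", "run_class"])["run"].nunique().unstack(fill_value=0)
    )
    for cls in ("bait", "control"):
        if cls not in counts.columns:
            counts[cls] = 0
    keep = counts[(counts["bait"] >= min_bait_runs) & (counts["control"] <= max_control_runs)]
    return sorted(keep.index)


def two_peptide_rule(
    evidence: pd.DataFrame, min_peptides: int = 2
) -> dict[str, list[str]]:
    """Per-run acceptance by unique-peptide count (default >= 2)."""
    if min_peptides < 1:
        raise ValueError("min_peptides must be >= 1")
    e = _check_evidence(evidence)
    ok = e[e["unique_peptides"] >= min_peptides]
    out: dict[str, list[str]] = {run: [] for run in e["run"].unique()}
    for run, grp in ok.groupby("run"):
        out[run] = sorted(grp["accession"].unique())
    return out


def significance_a(
    log_ratios: pd.Series | np.ndarray,
    *,
    benjamini_hochberg: bool = False,
) -> pd.Series:
    """Significance A: outlier p-values for a log-ratio distribution.

    The robust z-score of ratio r is ``(r - median) / (P84.13 - median)``
    above the median and ``(median - r) / (median - P15.87)`` below; for
    a normal distribution both denominators estimate sigma.  The p-value
    is the one-sided normal tail ``0.5 * erfc(z / sqrt(2))`` toward the
    protein's own side, so strong enrichment *or* depletion both yield
    small p.  With ``benjamini_hochberg=True`` the p-values are
    BH-adjusted.

    Raises
    ------
    ValueError
        Fewer than five finite ratios, or degenerate percentile spread.
    """
    if isinstance(log_ratios, pd.Series):
        index = log_ratios.index
        r = log_ratios.to_numpy(dtype=float)
    else:
        r = np.asarray(log_ratios, dtype=float)
        index = pd.RangeIndex(len(r))
    finite = np.isfinite(r)
    if finite.sum() < 5:
        raise ValueError("need at least 5 finite log ratios")
    p_low, med, p_high = np.percentile(r[finite], [_P_LOW, _P_MID, _P_HIGH])
    sigma_up = p_high - med
    sigma_down = med - p_low
    if sigma_up <= 0 or sigma_down <= 0:
        raise ValueError("degenerate ratio spread: percentile sigma is zero")
    z = np.where(r >= med, (r - med) / sigma_up, (med - r) / sigma_down)
    p = 0.5 * erfc(z / np.sqrt(2.0))
    p = np.clip(p, np.nextafter(0.0, 1.0), 1.0)
    p[~finite] = np.nan
    if benjamini_hochberg:
        adj = np.full_like(p, np.nan)
        adj[finite] = multipletests(p[finite], method="fdr_bh")[1]
        p = adj
    return pd.Series(p, index=index, name="significance_a")
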