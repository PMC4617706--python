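"""Core in-memory containers for stepwise-destabilization AP-MS data.

An experiment is a protein x replicate x elution-step block of label-free
intensities.  Missing cells (protein not quantified in a fraction) are NaN;
all stored intensities are nonnegative.  The elution axis is ordinal: steps
are ordered by elution sequence (increasing detergent, then the final
affinity-peptide elution), never re-sorted by nominal concentration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Default elution-step labels: four stepwise SDS concentrations (% w/v)
#: followed by the terminal FLAG-peptide elution.
DEFAULT_STEPS: tuple[str, ...] = (
    "SDS_0.001",
    "SDS_0.005",
    "SDS_0.01",
    "SDS_0.02",
    "FLAG",
)


@dataclass
class IntensityMatrix:
    """Nonnegative protein intensities over (replicate, elution step).

    Parameters
    ----------
    values
        DataFrame indexed by protein accession with a 2-level column
        MultiIndex ``(replicate, step)``.  NaN marks a missing cell.
    replicates
        Replicate identifiers in acquisition order.
    steps
        Elution-step labels in elution order.
    """

    values: pd.DataFrame
    replicates: list[str]
    steps: list[str]

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate protein accessions")
        if len(set(self.replicates)) != len(self.replicates):
            raise ValueError("duplicate replicate identifiers")
        if len(set(self.steps)) != len(self.steps):
            raise ValueError("duplicate step labels")
        expected = pd.MultiIndex.from_product(
            [self.replicates, self.steps], names=["replicate", "step"]
        )
        # reindex enforces the complete grid and canonical column order
        self.values = self.values.reindex(columns=expected)
        self.values.index.name = "accession"
        with np.errstate(invalid="ignore"):
            if (self.values.to_numpy() < 0).any():
                raise ValueError("negative intensities are not allowed")

    @property
    def proteins(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)

    @property
    def n_steps(self) -> int:
        return len(self.steps)

    def to_array(self) -> np.ndarray:
        """Return intensities as a (protein, replicate, step) float array."""
        return self.values.to_numpy(dtype=float).reshape(
            len(self.values), len(self.replicates), len(self.steps)
        )

    def present_in(self) -> pd.DataFrame:
        """Boolean protein x replicate table of the presence definition.

        A protein is present in a replicate when it has at least one
        non-missing, strictly positive intensity across that replicate's
        steps.
        """
        arr = self.to_array()
        with np.errstate(invalid="ignore"):
            present = np.nansum(arr > 0, axis=2) > 0
        return pd.DataFrame(present, index=self.values.index, columns=self.replicates)

    def subset(self, proteins: list[str]) -> "IntensityMatrix":
        return IntensityMatrix(
            self.values.loc[proteins].copy(), list(self.replicates), list(self.steps)
        )


@dataclass
class ElutionProfileSet:
    """Per-protein averaged cumulative relative-abundance profiles.

    ``profiles`` is a DataFrame (rows: accession, columns: ordered steps)
    of cumulative relative abundance in [0, 1]; every row is monotone
    non-decreasing and ends at 1.  ``n_replicates_used`` counts the
    replicates that contributed a defined (positive-total) profile.
    """

    profiles: pd.DataFrame
    steps: list[str]
    n_replicates_used: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.profiles = self.profiles.reindex(columns=self.steps)
        if self.n_replicates_used is None:
            self.n_replicates_used = pd.Series(1, index=self.profiles.index)

    @property
    def accessions(self) -> list[str]:
        return list(self.profiles.index)

    def __len__(self) -> int:
        return len(self.profiles)

    def vector(self, accession: str) -> np.ndarray:
        return self.profiles.loc[accession].to_numpy(dtype=float)
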