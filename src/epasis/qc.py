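"""Quality control: NMDS ordination and replicate reproducibility.

Ordination embeds the pairwise Euclidean distances between averaged
elution profiles in two dimensions by nonmetric multidimensional scaling
(NMDS); Kruskal stress-1 quantifies how faithfully the embedding
preserves the distance ranks.  Replicate QC computes Pearson correlation
(with Fisher-z 95% CI) and orthogonal (total-least-squares) regression
between replicate pairs on log2 intensities, plus a Spearman correlation
matrix across elution steps.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import isotonic_regression
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import MDS

from .containers import ElutionProfileSet, IntensityMatrix

__all__ = [
    "DistanceMatrix",
    "OrdinationResult",
    "ReplicateQC",
    "profile_distance_matrix",
    "kruskal_stress1",
    "nmds_ordination",
    "replicate_qc",
]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise profile-distance matrix (zero diagonal)."""

    labels: list[str]
    values: np.ndarray

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


@dataclass
class OrdinationResult:
    """Best-of-restarts NMDS embedding and its Kruskal stress-1."""

    coordinates: pd.DataFrame
    stress: float
    seed: int
    n_restarts: int


@dataclass
class ReplicateQC:
    """Replicate-pair and step-pair reproducibility statistics.

    ``replicate_pairs`` columns: rep_a, rep_b, n, pearson_r, ci_low,
    ci_high, slope, intercept (orthogonal regression on log2
    intensities).  ``step_spearman`` is the step x step Spearman rho
    matrix.  Pairs with fewer than three shared quantified cells are
    reported as NaN (undefined), not dropped.
    """

    replicate_pairs: pd.DataFrame
    step_spearman: pd.DataFrame


def profile_distance_matrix(
    profiles: ElutionProfileSet, *, normalized: bool = False
) -> DistanceMatrix:
    """All pairwise elution-profile distances (same metric as the EPD)."""
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    x = profiles.profiles.to_numpy(dtype=float)
    d = pdist(x, metric="euclidean")
    if normalized:
        d = d / np.sqrt(x.shape[1])
    return DistanceMatrix(labels=profiles.accessions, values=squareform(d))


def kruskal_stress1(dissimilarities: np.ndarray, distances: np.ndarray) -> float:
    """Kruskal stress-1 of an embedding.

    Disparities are the isotonic (primary-ties) regression of the
    embedded distances on the input dissimilarities; stress-1 is
    sqrt(sum((d - dhat)^2) / sum(d^2)) over all pairs.
    """
    diss = np.asarray(dissimilarities, float).ravel()
    dist = np.asarray(distances, float).ravel()
    # primary tie handling: within tied dissimilarities, order by distance
    order = np.lexsort((dist, diss))
    dhat = np.empty_like(dist)
    dhat[order] = isotonic_regression(dist[order]).x
    denom = float(np.sum(dist**2))
    if denom == 0:
        raise ValueError("degenerate embedding: all distances zero")
    return float(np.sqrt(np.sum((dist - dhat) ** 2) / denom))


def nmds_ordination(
    d: DistanceMatrix,
    dims: int = 2,
    seed: int = 0,
    n_restarts: int = 8,
) -> OrdinationResult:
    """Nonmetric MDS embedding of a profile-distance matrix.

    Runs ``n_restarts`` independent random starts (seeded
    deterministically from ``seed``) and keeps the configuration with
    the lowest Kruskal stress-1.  NMDS is non-convex, so restarts guard
    against poor local optima; fixed (seed, n_restarts) gives a
    deterministic result.
    """
    if dims < 1:
        raise ValueError("dims must be >= 1")
    diss = d.condensed()
    if np.all(diss == 0):
        raise ValueError("degenerate distance matrix: all distances zero")
    child_seeds = np.random.SeedSequence(seed).generate_state(n_restarts) % (2**31)
    best_stress = np.inf
    best_coords = None
    # first start from the classical-MDS solution (exact for Euclidean-
    # embeddable data), remaining restarts from random configurations
    inits = ["classical_mds"] + ["random"] * (n_restarts - 1)
    for s, init in zip(child_seeds, inits):
        mds = MDS(
            n_components=dims,
            metric_mds=False,
            metric="precomputed",
            init=init,
            n_init=1,
            random_state=int(s),
            normalized_stress=True,
            max_iter=3000,
            eps=1e-9,
        )
        coords = mds.fit_transform(d.values)
        stress = kruskal_stress1(diss, pdist(coords))
        if stress < best_stress:
            best_stress = stress
            best_coords = coords
    cols = [f"dim{i + 1}" for i in range(dims)]
    return OrdinationResult(
        coordinates=pd.DataFrame(best_coords, index=d.labels, columns=cols),
        stress=best_stress,
        seed=seed,
        n_restarts=n_restarts,
    )


def _tls_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Orthogonal (total-least-squares) regression slope and intercept."""
    sxx = np.var(x, ddof=1)
    syy = np.var(y, ddof=1)
    sxy = np.cov(x, y, ddof=1)[0, 1]
    if sxy == 0:
        slope = 0.0 if sxx >= syy else np.inf
    else:
        slope = (syy - sxx + np.sqrt((syy - sxx) ** 2 + 4 * sxy**2)) / (2 * sxy)
    intercept = float(np.mean(y) - slope * np.mean(x))
    return float(slope), intercept


def _fisher_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3)
    zc = stats.norm.ppf(0.5 + level / 2)
    return float(np.tanh(z - zc * se)), float(np.tanh(z + zc * se))


def replicate_qc(m: IntensityMatrix) -> ReplicateQC:
    """Reproducibility statistics on log2-transformed intensities.

    Replicate pairs use all (protein, step) cells strictly positive in
    both replicates; step pairs use all (protein, replicate) cells
    strictly positive in both steps.  Zero/missing cells are excluded
    pairwise (log2 is only taken of positive intensities).
    """
    if m.n_replicates < 2:
        raise ValueError("need at least two replicates")
    arr = m.to_array()  # (protein, replicate, step)
    with np.errstate(invalid="ignore"):
        pos = np.nan_to_num(arr, nan=0.0)

    rows = []
    for ia, ib in combinations(range(m.n_replicates), 2):
        a = pos[:, ia, :].ravel()
        b = pos[:, ib, :].ravel()
        ok = (a > 0) & (b > 0)
        n = int(ok.sum())
        if n < 3:
            rows.append(
                dict(rep_a=m.replicates[ia], rep_b=m.replicates[ib], n=n,
                     pearson_r=np.nan, ci_low=np.nan, ci_high=np.nan,
                     slope=np.nan, intercept=np.nan)
            )
            continue
        la, lb = np.log2(a[ok]), np.log2(b[ok])
        r = float(stats.pearsonr(la, lb).statistic)
        if abs(r) < 1.0 and n > 3:
            ci_low, ci_high = _fisher_ci(r, n)
        else:
            ci_low = ci_high = r
        slope, intercept = _tls_line(la, lb)
        rows.append(
            dict(rep_a=m.replicates[ia], rep_b=m.replicates[ib], n=n,
                 pearson_r=r, ci_low=ci_low, ci_high=ci_high,
                 slope=slope, intercept=intercept)
        )
    pair_df = pd.DataFrame(rows)

    rho = np.full((m.n_steps, m.n_steps), np.nan)
    for i in range(m.n_steps):
        rho[i, i] = 1.0
    for i, j in combinations(range(m.n_steps), 2):
        a = pos[:, :, i].ravel()
        b = pos[:, :, j].ravel()
        ok = (a > 0) & (b > 0)
        if ok.sum() < 3:
            continue
        res = stats.spearmanr(np.log2(a[ok]), np.log2(b[ok]))
        rho[i, j] = rho[j, i] = float(res.statistic)
    step_df = pd.DataFrame(rho, index=m.steps, columns=m.steps)
    return ReplicateQC(replicate_pairs=pair_df, step_spearman=step_df)
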