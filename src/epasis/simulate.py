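"""Synthetic stepwise-destabilization AP-MS experiments with known truth.

The generator emulates the study design the analysis assumes: a bait
purification destabilized by stepwise increasing SDS, measured over five
ordered elution fractions (0.001, 0.005, 0.01, 0.02 % SDS, then the
terminal FLAG elution) in seven biological replicates.  Proteins belong
to sub-complex modules with a shared *release curve* — a logistic CDF
over the ordinal step index, so an early midpoint models a loosely bound
module (eluting between 0.001 and 0.01 % SDS, like the dynein motor)
and a late midpoint a stable one (surviving to the FLAG elution, like
dynactin).  Background proteins draw independent Dirichlet step
fractions: maximally uninformative elution.

Per-protein total intensity is log-normal (LFQ-like dynamic range);
cells get multiplicative log-normal noise of scale ``noise_sd``, and a
protein drops out of an entire replicate with probability ``dropout``.
All randomness flows from one seed through per-protein child streams
(``SeedSequence.spawn``), so earlier proteins' draws are stable when a
config is extended with more proteins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import DEFAULT_STEPS, IntensityMatrix

__all__ = [
    "ModuleSpec",
    "SynthConfig",
    "SyntheticTruth",
    "module_release_curve",
    "generate_experiment",
    "corrupt_with_missingness",
    "study_like",
]

BACKGROUND = "background"


@dataclass(frozen=True)
class ModuleSpec:
    """One true sub-complex: size and logistic release-curve shape."""

    name: str
    n_members: int
    midpoint: float  # release midpoint on the ordinal step axis [0, n_steps-1]
    sharpness: float  # logistic steepness; larger = more step-like release


@dataclass
class SynthConfig:
    """Generator configuration (defaults follow the emulated study design)."""

    n_steps: int = 5
    step_labels: tuple[str, ...] = DEFAULT_STEPS
    modules: tuple[ModuleSpec, ...] = (
        ModuleSpec("DCTN", 10, midpoint=3.5, sharpness=4.0),
        ModuleSpec("DYN", 10, midpoint=1.0, sharpness=4.0),
    )
    n_background: int = 20
    n_replicates: int = 7
    total_log_mean: float = 16.0  # ln intensity; e^16 ~ 9e6, LFQ-like
    total_log_sd: float = 1.0
    noise_sd: float = 0.2  # multiplicative log-scale noise sigma
    dropout: float = 0.1  # P(protein absent from a whole replicate)
    seed: int = 0

    def validate(self) -> None:
        if self.n_steps < 2:
            raise ValueError("n_steps must be >= 2")
        if len(self.step_labels) != self.n_steps:
            raise ValueError("step_labels length must equal n_steps")
        if self.n_background < 0 or self.n_replicates < 1:
            raise ValueError("counts must be nonnegative (replicates >= 1)")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.noise_sd < 0 or self.total_log_sd < 0:
            raise ValueError("noise scales must be >= 0")
        for m in self.modules:
            if m.n_members < 0:
                raise ValueError(f"module {m.name}: negative member count")
            if m.sharpness <= 0:
                raise ValueError(f"module {m.name}: sharpness must be > 0")
        names = [m.name for m in self.modules]
        if len(set(names)) != len(names):
            raise ValueError("duplicate module names")
        if self.seed is None:
            raise ValueError("seed is mandatory for reproducibility")


@dataclass
class SyntheticTruth:
    """Ground-truth labels and release curves of a generated experiment."""

    labels: pd.Series  # accession -> module name or "background"
    release_curves: dict[str, np.ndarray] = field(default_factory=dict)

    def members(self) -> dict[str, list[str]]:
        """Curated member lists per true module (background excluded)."""
        out: dict[str, list[str]] = {}
        for acc, lab in self.labels.items():
            if lab != BACKGROUND:
                out.setdefault(lab, []).append(acc)
        return out


def module_release_curve(
    midpoint: float, sharpness: float, n_steps: int
) -> np.ndarray:
    """Per-step release fractions from a logistic CDF over step index.

    The logistic CDF ``1 / (1 + exp(-sharpness * (k - midpoint)))`` is
    evaluated at step indices k = 0..n_steps-1, rescaled to end at 1,
    and differenced; the fractions sum to 1.  High sharpness approaches
    a single-step release, sharpness near zero a uniform one.
    """
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    if sharpness <= 0:
        raise ValueError("sharpness must be > 0")
    k = np.arange(n_steps, dtype=float)
    cdf = 1.0 / (1.0 + np.exp(-sharpness * (k - midpoint)))
    cdf = cdf / cdf[-1]
    return np.diff(cdf, prepend=0.0)


def generate_experiment(cfg: SynthConfig) -> tuple[IntensityMatrix, SyntheticTruth]:
    """Draw one labeled synthetic experiment.

    Member cell intensities are ``total x release_fraction[step] x
    exp(N(0, noise_sd^2))``; background proteins use protein-specific
    symmetric Dirichlet(1) step fractions.  Dropout zeroes a protein in
    an entire replicate (cells become missing).  A fixed seed yields
    bit-identical output.
    """
    cfg.validate()
    plan: list[tuple[str, str]] = []  # (accession, label)
    for mod in cfg.modules:
        for i in range(mod.n_members):
            plan.append((f"{mod.name}_{i + 1:02d}", mod.name))
    for i in range(cfg.n_background):
        plan.append((f"BG_{i + 1:03d}", BACKGROUND))

    curves = {
        mod.name: module_release_curve(mod.midpoint, mod.sharpness, cfg.n_steps)
        for mod in cfg.modules
    }
    children = np.random.SeedSequence(cfg.seed).spawn(len(plan))
    n_rep, n_step = cfg.n_replicates, cfg.n_steps
    data = np.empty((len(plan), n_rep * n_step))
    for idx, ((acc, label), child) in enumerate(zip(plan, children)):
        rng = np.random.default_rng(child)
        total = np.exp(rng.normal(cfg.total_log_mean, cfg.total_log_sd))
        if label == BACKGROUND:
            frac = rng.dirichlet(np.ones(n_step))
            curves[acc] = frac
        else:
            frac = curves[label]
        noise = np.exp(rng.normal(0.0, cfg.noise_sd, size=(n_rep, n_step)))
        cells = total * frac[None, :] * noise
        drop = rng.random(n_rep) < cfg.dropout
        cells[drop, :] = np.nan
        data[idx] = cells.ravel()

    columns = pd.MultiIndex.from_product(
        [[f"R{r + 1}" for r in range(n_rep)], list(cfg.step_labels)],
        names=["replicate", "step"],
    )
    values = pd.DataFrame(data, index=[acc for acc, _ in plan], columns=columns)
    matrix = IntensityMatrix(
        values=values,
        replicates=[f"R{r + 1}" for r in range(n_rep)],
        steps=list(cfg.step_labels),
    )
    truth = SyntheticTruth(
        labels=pd.Series({acc: lab for acc, lab in plan}, name="true_module"),
        release_curves=curves,
    )
    return matrix, truth


def corrupt_with_missingness(
    m: IntensityMatrix, pattern: dict[str, int], seed: int
) -> IntensityMatrix:
    """Mask whole replicates per protein to exercise the presence filter.

    ``pattern`` maps accession -> number of replicates to drop for that
    protein; the replicates are chosen reproducibly from ``seed``.
    Everything not named in the pattern is untouched.
    """
    rng = np.random.default_rng(seed)
    values = m.values.copy()
    for acc, n_drop in pattern.items():
        if acc not in values.index:
            raise KeyError(f"unknown accession {acc!r}")
        if n_drop > m.n_replicates:
            raise ValueError(
                f"{acc!r}: cannot drop {n_drop} of {m.n_replicates} replicates"
            )
        which = rng.choice(m.n_replicates, size=n_drop, replace=False)
        for r in which:
            values.loc[acc, (m.replicates[r], slice(None))] = np.nan
    return IntensityMatrix(values, list(m.replicates), list(m.steps))


def study_like(seed: int = 0, **overrides) -> SynthConfig:
    """A config at the scale of the original interactome (~86 proteins).

    Two true modules sized like the curated dynactin and dynein groups
    plus enough background to reach 86 proteins total.
    """
    defaults = dict(
        modules=(
            ModuleSpec("DCTN", 9, midpoint=3.5, sharpness=4.0),
            ModuleSpec("DYN", 8, midpoint=1.0, sharpness=4.0),
        ),
        n_background=69,
        seed=seed,
    )
    defaults.update(overrides)
    return SynthConfig(**defaults)
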