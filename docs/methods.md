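# Methods

## Model and procedure

The analysis assumes an affinity-purified bait complex eluted in `S`
ordered fractions of stepwise increasing destabilization strength (by
default four SDS concentrations — 0.001, 0.005, 0.01, 0.02 % w/v — and a
terminal FLAG-peptide elution, `S = 5`), quantified label-free in `R`
bait replicates (default 7). The elution axis is treated as ordinal
(step index 0..S−1), not as the numeric SDS concentration: the steps are
a designed sequence, and the spacing of the nominal concentrations
carries no quantitative meaning for the profile geometry.

**Presence filter.** A protein is present in a replicate when it has at
least one positive, non-missing intensity in that replicate's fractions.
Proteins present in fewer than `ceil(min_fraction · R)` replicates are
removed (default `min_fraction = 4/7`, so 4 of 7). The ceiling is
computed with a 1e-9 guard because `3/7 · 7` rounds up in doubles.

**Profiles.** Within each replicate the protein's intensities are
converted to cumulative relative abundance (prefix sums divided by the
replicate total); replicates with zero total for the protein contribute
no profile and are excluded from the mean rather than entering as zeros.
Per-replicate normalization before averaging makes profiles invariant to
replicate yield; averaging raw intensities instead would let high-yield
replicates dominate. Every emitted profile is monotone non-decreasing
and ends at 1.

**Consensus and EPD.** A sub-complex consensus profile is the unweighted
mean of its curated members' profiles (the construction is not uniquely
determined by the reported group-average curves; the unweighted mean is
the simplest consistent choice). The elution-profile distance is the
plain Euclidean distance between profile vectors. Two documented
dialects exist behind flags because the published absolute EPD scale
cannot be pinned without the underlying raw data: `normalized=True`
divides by √S, and `leave_one_out=True` scores each member against a
consensus rebuilt without that member (the default includes it).

**Threshold calibration.** Candidate thresholds form an equally spaced
grid of `n_steps` points (default 1000) on [0, max observed EPD].
Positives are curated members scored by EPD to their own module;
negatives are curated members scored by EPD to the other module(s).
Unlabeled proteins are excluded from calibration — their membership is
the quantity being inferred. Sensitivity at t is the fraction of
positives with EPD ≤ t, specificity the fraction of negatives with
EPD > t; both are monotone in t by construction. The selected threshold
maximizes Youden's J (sensitivity + specificity − 1), the standard
operating-point rule when no cost ratio is specified; exact ties resolve
to the smallest threshold (the conservative choice: fewer candidates).

**Assignment.** Curated members within threshold of their own module
form the reference group and keep their curated label; a member that
drifts onto another module's consensus is *not* relabelled — it becomes
`unknown` if outside its own module's threshold, while its data-driven
nearest module remains visible in the output, so both readings of such
conflicts can be inspected. Non-members within threshold of their
nearest module (lexicographically smallest name on exact ties) become
`<module>_cand`; everything else is `unknown`. No statistical test for
splitting a module into further sub-modules is implemented; candidate
splits should be judged by ordination and replicate support.

**Ordination.** Nonmetric MDS (scikit-learn SMACOF, nonmetric mode) on
the pairwise profile-distance matrix, default 2 dimensions. Stress is
Kruskal stress-1, `sqrt(Σ(d−d̂)² / Σd²)`, with disparities `d̂` from
isotonic regression using primary tie handling (within tied
dissimilarities, target order breaks the tie). Because the objective is
non-convex, the embedding is the best of `n_restarts = 8` starts — one
from the classical-MDS solution (exact when the distances are Euclidean-
embeddable), the rest random — with restart seeds derived
deterministically from the user seed; fixed (seed, n_restarts) gives a
reproducible result. SMACOF runs with eps = 1e-9 and up to 3000
iterations so that exactly embeddable configurations reach stress below
1e-3.

**Replicate QC.** For each replicate pair, Pearson r (with Fisher-z 95%
CI) and orthogonal total-least-squares regression are computed on log2
intensities over all (protein, step) cells strictly positive in both
replicates; for each fraction pair, Spearman rho over all (protein,
replicate) cells positive in both fractions. Whether published replicate
scatter plots pool fractions is not stated anywhere; pooling uses all
quantitative evidence and is the choice made here. Pairs with fewer than
three shared cells are reported as undefined (NaN), not dropped. Zeros
and missing values are excluded pairwise since log2 requires positive
intensities.

**Evidence filters.** `pulldown_filter` keeps proteins detected in at
least `min_bait_runs` bait runs (default 3) and at most
`max_control_runs` control runs (default 0 — any control detection
removes the protein, the strict reading of "and/or in control
experiments"). `two_peptide_rule` accepts, per run, proteins with at
least `min_peptides` unique peptides (default 2).

**Significance A.** For log-ratio r with distribution median m, the
robust z-score is `(r − m)/(P84.13 − m)` above the median and
`(m − r)/(m − P15.87)` below; for a normal distribution both
denominators equal one standard deviation, which is why exactly these
percentiles are used. The p-value is the one-sided normal tail
`0.5·erfc(z/√2)` toward the protein's own side, so both strong
enrichment and strong depletion give small p; at the median p = 0.5
exactly. p-values are clipped into (0, 1]; fewer than five finite ratios
or a degenerate percentile spread raise an error. No multiple-testing
correction is applied by default; `benjamini_hochberg=True` adds BH
adjustment.

## Synthetic data: what it emulates and what it does not

The generator reproduces the statistical structure the analysis relies
on: (i) module co-elution — all members of a sub-complex share one
release curve, a logistic CDF over the ordinal step index whose
`midpoint` sets where the module lets go of the bait (≈1 for a weakly
bound, early-eluting motor module; ≈3.5 for a stable module surviving to
the FLAG elution) and whose `sharpness` (default 4) sets how step-like
the release is; (ii) uninformative background — symmetric Dirichlet(1)
step fractions per background protein; (iii) LFQ-like abundance spread —
per-protein totals are log-normal with ln-mean 16 (~10⁷ arbitrary units)
and ln-sd 1, a typical label-free dynamic range; (iv) multiplicative
measurement noise, log-normal per cell with σ = 0.2 by default; and (v)
replicate dropout — a protein vanishes from an entire replicate with
probability 0.1, mimicking run-to-run identification stochasticity.
Default scale is two modules × 10 members + 20 background over 7
replicates and 5 steps, matching the conditions under which recovery
properties are asserted; `study_like()` provides an 86-protein variant
at the scale of the motivating interactome.

Not emulated: peptide-level sampling, shared/razor peptide ambiguity,
intensity-dependent (left-censored) missingness within a replicate,
correlated noise across fractions, contaminants, or more than one bait.
A green synthetic test therefore establishes that the pipeline recovers
module structure *when the co-elution model holds*; it does not validate
peptide-to-protein inference or guard against structured missingness.

All randomness derives from one seed: each protein gets a child stream
via `SeedSequence.spawn` in a fixed order, so extending a config with
more proteins leaves earlier proteins' draws bit-identical.

## Numerical choices

- Profile terminal values equal 1 exactly (division by the last prefix
  sum); monotonicity tolerances in tests are 1e-12.
- With σ = 0 and no dropout, member EPDs to their own consensus are zero
  up to last-ulp rounding of the per-protein normalizations (observed
  ≲ 2e-16, asserted ≤ 1e-12).
- Nearest-module ties and threshold-grid ties are broken
  deterministically (lexicographic name, smaller threshold); output rows
  are ordered by accession, so every run is reproducible byte-for-byte.
- Intensity tables are read with correctly rounded float parsing
  (Python `float()` / pandas `round_trip`), making write→read an exact
  identity; the pipeline's provenance record (config hash, seed,
  versions, stage counts) pins the computation but not the output
  directory.

## Known limitations

- The assignment threshold is calibrated from curated members only; with
  very few curated proteins per module the sensitivity/specificity
  curves are coarse and the Youden optimum unstable.
- EPD treats all steps equally; a profile differing only in early steps
  is as distant as one differing late, although late steps may be more
  diagnostic of stable binding.
- NMDS stress values are comparable only within a dataset; the absolute
  stress of a published ordination cannot be reproduced without the
  underlying profiles.
- Control-experiment intensities do not enter profile averaging; they
  are used only by the evidence filters.
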