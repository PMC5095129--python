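# Methods

This note records the models, conventions and parameter choices behind
`samshape`, and what the synthetic-data tests do and do not demonstrate.

## Paraboloid model and estimators

The SAM is modelled as the solid of revolution of `z(x) = h (1 − x²/r²)`,
apex up, height `h` and basal radius `r` in μm. The eight estimators are
standard solid/surface-of-revolution results; with `b = h/r²` (the parabolic
coefficient) and `a = 2b`:

- volume `π r² h / 2`; cross-sectional area (parabola to base chord) `4hr/3`;
- arc length `r√(1 + a²r²) + asinh(ar)/a`;
- lateral surface `π/(6b²) · [(1 + 4b²r²)^{3/2} − 1]`, evaluated via
  `expm1(1.5·log1p(·))` so the flat-disk limit h → 0 (surface → πr²,
  arc → 2r) is numerically exact.

Surface area deliberately excludes a base cap — the meristem has no physical
base disk — and the flat-limit identities pin that convention. All four
non-trivial closed forms are validated against adaptive quadrature to 1e-6
relative over h, r ∈ {1, 10, 100, 500} μm in the test suite.

**Parabola fitting.** `fit_parabola` fits `y = apex_y + c (x − apex_x)²`
with `c < 0`: the apex abscissa starts at the contour's maximal-y point and
is refined by bounded 1-D minimisation of the residual sum of squares;
conditional on `apex_x` the model is linear and solved by OLS, keeping the
linear-model character of the fit. Reported radius is half the contour's
x-extent (the basal endpoints), height follows from `h = |c| r²`, and
`baseline_y` is the base level implied by the fit (`apex_y − h`), so
translation moves only `apex_x`/`baseline_y`. A fitted `c ≥ 0` returns a
fit-failure result rather than raising. Where "radius" sits on the organism
(base of dome vs primordium insertion) is a digitisation convention, not a
biological claim; this package defines it as half the basal width of the
trace.

## Contour pipeline

Contours are open polylines traced base → apex → base, y-up, μm; image-pixel
(y-down) files are flipped at read time. Orientation is explicit: the next
primordium to initiate (P0) defines left/right, and mirroring negates x
about the centroid and reverses point order. Resampling places `n` points at
equal arc length along the polyline (default 800), endpoints preserved
exactly.

Generalised Procrustes analysis uses landmark-index correspondence (valid
because all traces share the base→apex→base parameterisation; no sliding
landmarks), centring, optional scaling to unit centroid size, and optimal
*proper* rotations (SVD with determinant correction). Reflections are
forbidden because left/right asymmetry is a real signal handled by the
orientation step, not a nuisance. Convergence: mean-shape RMS change < 1e-8
or 100 iterations. Scaling is ON by default — the shape PCs are meant to
describe shape while size lives in the parabolic estimators — and can be
disabled (`with_scaling=False`) to retain size in the alignment, since
whether a given workflow's registration included scaling is a free choice;
original centroid sizes are always kept.

## DCT shape descriptors and PCA

Each aligned shape's x- and y-coordinate sequences are transformed
independently by the orthonormal DCT-II; harmonics k = 1..12 are retained
(k = 0 carries the mean, which centring makes ~0; keeping it is possible by
raising `n_harmonics` against an uncentred set, but dropping it is the
default convention). Twelve harmonics per axis suffice for smooth SAM-like
outlines: on a noiseless 800-landmark parabolic contour the 12-harmonic
reconstruction RMSE is < 1% of contour height. Orthonormal scaling makes
Parseval checks exact.

PCA is an eigen-decomposition (via SVD) of the covariance of the
column-centred coefficient matrix, *without* per-column standardisation —
the 24 coefficients share units, and standardising would erase the harmonic
energy ordering. PC signs are fixed deterministically (largest-|loading|
entry positive) so that regression tests and renderings are stable; any
correlation involving a PC is therefore sign-convention-dependent and only
its magnitude is meaningful. Reconstructions along a PC are inverse-DCTs of
`mean + m·sd·loading`.

## BC2S3 genetics

The cross is F1 → two backcrosses to the recurrent (maize) parent → three
selfings. The single-locus genotype prior follows from the design: after the
backcrosses P(het) = 1/4; each selfing halves heterozygosity, so
P(AB) = 1/4 · (1/2)³ = 1/32, the lost half splitting equally between
homozygotes, giving AA : AB : BB = 55/64 : 2/64 : 7/64.

Genotype probabilities at markers and pseudomarkers come from a three-state
HMM whose transition matrices are *exact* two-locus results: the joint
distribution over ordered diplotypes (4 two-locus haplotypes × 2) is
propagated generation by generation through the pedigree for each interval's
recombination fraction (inverse-Kosambi of the cM gap, `r = tanh(d/50)/2`),
then collapsed to genotype pairs and conditioned. Intervals are treated
independently (no crossover interference beyond the map function), which
keeps forward–backward exact under the model and matches the simulator's
generative process exactly — simulator and scanner share one model by
construction. Emissions use a genotyping-error rate ε = 0.002 (configurable);
missing genotypes and pseudomarkers are uninformative. The pseudomarker step
defaults to 1 cM; scanning on the marker grid only is a step-size choice.

**Scan.** Haley–Knott regression of phenotype on expected teosinte dosage
(E[allele count]/2 ∈ [0, 1]); LOD = (n/2)·log10(RSS₀/RSS₁) against the
intercept-only null, missing phenotypes dropped listwise, RSS₁ floored at
1e-12·RSS₀ to cap the LOD for perfect fits. Permutation thresholds shuffle
the phenotype against the fixed genotype matrix and take the type-7
empirical quantile of genome-wide maxima, so thresholds are reproducible
from a seed and monotone in α. Bayes credible intervals accumulate
10^LOD-normalised posterior mass over a chromosome's grid in decreasing
order until the target coverage, then expand outward to the nearest
genotyped flanking markers; a flat LOD yields the whole chromosome with a
warning.

**BLUP + coefficient.** Replicated measurements are summarised per line by
`y_ij = μ + rep_j + u_i + ε_ij` with replicate fixed (sum-to-zero coded, so
μ is the average-replicate intercept — the only structure under which a
per-line "BLUP + coefficient" value is well defined) and line random. REML
profiles the restricted likelihood in γ = σ²_u/σ²_e using Woodbury
identities for the line-indicator random effect and minimises the scalar
profile on log γ by bounded search (tolerance 1e-10); the reported value is
μ + û_i. Balanced designs admit the closed-form shrinkage
`û_i = (σ²_u / (σ²_u + σ²_e/m)) (ȳ_i − ȳ)`, used as the test oracle. Data
with no replicated line fall back to plain means with a warning (the
shrinkage ratio is unidentifiable).

## Comparative statistics

The "estimated shift between medians" quoted alongside a rank-sum test is
the Hodges–Lehmann estimate (median of all pairwise between-group
differences) — what R's `wilcox.test(conf.int = TRUE)` reports — not the
literal difference of group medians; both are emitted, HL primary. P-values
use exact enumeration when n₁n₂ ≤ 10,000 and the pooled sample is tie-free,
else the tie/continuity-corrected normal approximation. Correlations are
Pearson r with two-sided p from the Fisher transformation
`z = atanh(r)·√(n−3)`; the estimator × PC matrix applies no
multiple-testing correction (matching the descriptive use it serves) and
flags non-significant cells at α = 0.05. The clade comparison is a one-way
fixed-effects ANOVA on the supplied trait (parabolic coefficient in the
intended use); an optional second factor switches to an additive two-way
fit, since which second factor a crossed design should use is
context-dependent.

## Synthetic data: what it emulates, and what it does not

`simulate_cross` runs meiosis interval-by-interval with Bernoulli crossovers
at inverse-Kosambi fractions — deliberately the same no-interference model
the scanner's HMM assumes. Defaults: 400 lines, 5 chromosomes × 50 markers
× 100 cM, 2 replicates; baseline height 100 μm and radius 55 μm with
residual SDs of 8 and 5 μm and a 2 μm between-replicate offset — sizes and
noise levels realistic for two-week maize seedling SAM measurements while
keeping simulation-heavy tests in the minutes range. QTL effects are
additive on dosage (0, ½, 1), so `effect` is the full teosinte-homozygote
shift. `simulate_contour` draws `y = h (1 − (|x′|/r)^p)` with lean applied
as a shear `x = x′ − s·(y/h)·r` and iid Gaussian point noise; p = 2 is a
true parabola, p ≠ 2 produces the peaked/rounded axis, s ≠ 0 the
left/right-leaning axis. `simulate_taxa_panel` draws parabolic coefficients
uniformly over a range (default 0.005–0.08 μm⁻¹ at fixed 100 μm height,
spanning squat to very peaked apices).

Because simulator and scanner share the recombination model, QTL-scan tests
validate inference, not robustness to interference, segregation distortion
or genotyping artefacts. Likewise the contour generator produces exactly
parabola-family shapes plus white noise: pipeline tests show the DCT/PCA
machinery recovers known generative axes (elongation, lean, peakedness), not
that real SAMs have only those axes; primordium crowding, pinched bases and
correlated tracing error in real micrographs are outside the generative
model. All generators are byte-deterministic given the seed, with per-stage
substreams derived from one configured seed.

## Numerical choices and degenerate inputs

- LOD cap at RSS₁ ≥ 1e-12·RSS₀; monomorphic grid positions score LOD 0.
- Constant phenotypes scan to all-zero LOD with a warning.
- GPA requires ≥ 2 shapes with identical point counts; zero-size
  configurations are rejected.
- Reconstructed/degenerate contours (e.g. all-zero coefficients) bypass the
  distinct-consecutive-points invariant via `Contour(check=False)`.
- Quantile rule for thresholds fixed to type-7 (linear interpolation).
- Grid positions are rounded to 1e-9 cM before marker/pseudomarker merging.

## Problem sizes used in the shipped experiments

Calibration and recovery experiments run at desk scale: 200 null crosses ×
500 permutations for threshold calibration (the nominal level is recovered
within binomial error of the 95% target), 100 repeats for ±15 cM QTL
localisation at a 25%-of-variance QTL (n = 200 lines), 50 repeats for Bayes
interval coverage, 5000 lines for genotype-frequency goodness-of-fit, and
1e5 resamples for the permutation check of the Fisher-transformation
p-value. `scripts/acceptance.py` re-runs the threshold-calibration
experiment from scratch at exactly these sizes.

## Known limitations

- Single-QTL scans only: no multiple-QTL or composite interval mapping, no
  epistasis, no de novo map estimation (marker positions are inputs).
- Open outlines only; closed-outline (elliptic Fourier) analysis is out of
  scope.
- The HMM and simulator ignore crossover interference beyond what the
  Kosambi map function implies marginally.
- P0 orientation must be supplied; there is no automatic detection from
  image content.
- The exact DCT normalisation and PCA scaling conventions used by other
  morphometrics toolkits vary; this package's choices (orthonormal DCT-II,
  unscaled-coefficient PCA, k = 0 dropped) are recorded above and
  configurable where they are free parameters.
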