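# Methods

This note records the models, algorithmic choices and defaults behind
each pipeline stage, the assumptions they rest on, and what the
synthetic-data tests do and do not demonstrate about real data.

## ROI compression

The extractor reduces a centroided scan series to the mass traces that
plausibly belong to chromatographic peaks.  Three parameters control it
(`ROIParams`):

| parameter | default | meaning |
|---|---|---|
| `snr_fraction` | 0.001 | intensity threshold as a fraction of the run's maximum signal |
| `mz_tolerance` | 0.5 Da | assignment half-width around a trace's running mean m/z (unit-resolution triple-quadrupole accuracy) |
| `min_consecutive` | 25 scans | minimum consecutive supra-threshold scans for a retained trace |

Choices worth stating explicitly:

- The threshold is an **absolute intensity cutoff** computed per run from
  the maximum signal, not an estimate of the local noise floor.
- A candidate trace carries a **running unweighted mean m/z**, updated
  after each accepted centroid; the reported ROI m/z is the unweighted
  arithmetic mean of all member m/z values.  A supra-threshold centroid
  joins the *nearest* open candidate within tolerance; an exact distance
  tie goes to the lower mean m/z.  Processing centroids in ascending m/z
  order makes the result independent of within-scan peak ordering.
- Consecutiveness is counted in **scan indices**, not minutes, and a
  single sub-threshold (or empty) scan closes a candidate.  Two retained
  ROIs may therefore share a mean m/z if they were never simultaneously
  open (a trace interrupted mid-run).
- Positive- and negative-mode data are extracted separately; merging
  happens at the metabolite-matching stage.
- mzML input must be centroided; profile spectra are rejected.  The mzML
  reader/writer handles the minimal profile this pipeline needs (MS1,
  64-bit uncompressed arrays); a three-column CSV scan-list dialect is
  supported as a lightweight alternative.

On noise-free, well-separated traces the extractor provably coincides
with single-linkage m/z clustering of all supra-threshold points, which
the tests exploit as an independent oracle.  Overlapping traces closer
than the tolerance are merged — deconvolution is out of scope.

## Retention factors and matrix D

k = (t_R − t_0)/t_0, with t_R taken as the retention time of the
**global apex** of the matched ROI trace (the simplest deterministic
rule; shoulder peaks are not resolved).  The dead time is derived from
the column dead volume: t_0 = π(d/2)²·L·ε / F, with **total porosity ε
defaulting to 0.7** — a conventional value for packed columns, explicit
and configurable rather than hidden.  Early eluters (t_R < t_0) produce
a warning, not an error.

Targets are matched by expected m/z at a 0.5 Da tolerance (re-using the
ROI tolerance; nothing suggests a different value is warranted for a
unit-resolution analyser).  A target sought in both polarities keeps the
hit with the higher apex intensity.  Missing targets yield masked cells,
and downstream analyses run in strict mode (any mask is an error) unless
masked columns are explicitly dropped.

The packaged 54-compound target list stores each metabolite's molecular
formula (textbook values) and computes expected [M+H]+ / [M−H]− m/z with
pyteomics at load time; families follow the usual ionization practice
(amino acids, amines and nucleosides positive, sugars and organic acids
negative, nucleosides marked "either").

## Descriptor filtering and preprocessing

Descriptors arrive precomputed (structure → descriptor software is out
of scope).  Filtering removes first every descriptor missing for any
compound, then every descriptor whose coefficient of variation is below
20%.  The CV is **|sample sd / mean|**: sample (n−1) standard deviation
by chemometric convention, absolute value because descriptors may be
negative-valued.  A zero mean with variation gives CV = +∞ (kept); a
constant column is removed at any threshold.  The threshold is a strict
inequality (CV exactly 20% is kept).  Autoscaling (mean 0, sample sd 1)
precedes PCA and PLS; plain centering precedes ASCA.

## PCA and ASCA

PCA runs on autoscaled data (scikit-learn, full SVD) with a fixed sign
convention: each loading column's largest-magnitude entry is positive.

ASCA centers the data column-wise and assigns to each design term its
classical balanced-ANOVA estimate: level means of the centered data for
main effects, cell means minus parent main effects for pairwise
interactions; the three-way term is pooled into the residual.  Balance
is required (and checked) — on a balanced design the effect subspaces
are orthogonal, so the term sums of squares add up to the total, which
the tests verify to 1e−8 together with elementwise reconstruction to
1e−10 and equivalence with a brute-force two-way ANOVA oracle.

**Permutation testing.**  The test statistic is the tested term's SSQ.
Whole rows of the centered matrix are permuted — synchronized across
metabolites, preserving their correlation structure — and only the
tested term (plus, for interactions, its parent main effects) is
recomputed per permutation.  p = (1 + b)/(1 + N), so p is never zero and
the floor with N = 10,000 is 0.0001.  Two schemes are offered:

- `rows` (default): free permutation of all rows.  Exact when the tested
  factor is the only structure present, but *conservative* when other
  factors carry large effects, because scrambling rows leaks those
  effects into the permuted statistic.
- `within`: permutations restricted to the strata formed by the level
  combinations of the other design factors, the standard restricted-
  permutation remedy.  This keeps nuisance effects fixed and restores
  nominal type-I error when, e.g., a near-null ionic-strength factor is
  tested in the presence of dominant phase and pH effects.

The calibration tests measure both: empirical rejection at α = 0.05 over
200 synthetic null datasets lies within the binomial band [0.02, 0.09]
for `rows` on effect-free data and for `within` under active nuisance
factors.

Per-term structure ("scores at the mean level") is the SVD of the term's
level-mean matrix — one row per factor level — with the same sign
convention; loadings rank the metabolites driving the separation.

## PLS, cross-validation and VIP

PLS1 by NIPALS deflation: per latent variable, w = Xᵀy/‖Xᵀy‖, t = Xw,
p = Xᵀt/tᵀt, q = yᵀt/tᵀt, then X is deflated by t pᵀ (y-deflation is
unnecessary for a single response).  Both X and **y are autoscaled**
inside the fit (VIP is scale-dependent, so this is stated rather than
implied); the regression vector is b = W(PᵀW)⁻¹q and predictions invert
the scaling.  With as many latent variables as the rank of X the fit
coincides with least squares, and the implementation agrees with an
independently coded NIPALS (scikit-learn's) to 1e−8 on fixed toys.

The latent-variable count is chosen by leave-one-out cross-validation
with **rescaling recomputed inside every fold**; the minimiser of RMSECV
wins, ties going to fewer latent variables (parsimony).

VIP_j = sqrt( p · Σ_a SSY_a (w_ja/‖w_a‖)² / Σ_a SSY_a ), with
SSY_a = q_a² t_aᵀt_a; the mean squared VIP is 1 by construction and the
selection rule is strictly VIP > 1.  Top-k tables are sorted by
descending VIP with alphabetical tie-breaks.

Condition models: replicate injections at a (phase, pH) condition are
**averaged** into one retention factor per metabolite before fitting
(models describe conditions, not injections), and only low-ionic-
strength runs are used, since the ionic-strength factor is treated as
non-influential.  Overlap across conditions is reported as exhaustive
disjoint Venn-region counts (up to 6 sets); no figures are rendered.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *structure* the analysis assumes: a
balanced 4×3×2 factorial with duplicate injections (48 runs, replicates
innermost in row order); retention matrices as baseline + sum-to-zero
factor offsets + optional pairwise interactions + i.i.d. Gaussian
replicate noise, clipped at zero with the clip count logged (k is
physically nonnegative); chromatograms as Gaussian elution peaks at
fixed m/z over a uniform rt grid, with uniform baseline noise at decoy
m/z positions; and descriptor tables of i.i.d. standard normals with a
sparse linear response.

No effect magnitudes are published for the reference layout, so the
defaults in `study_effects()` are this package's own choices, stated in
code: baseline k = 2.0, phase offsets (−0.75, +0.30, +0.30, +0.15) with
BEH amide retaining least and amide/zwitterionic alike, pH offsets
(+0.2, 0, −0.2), near-null ionic strength (±0.02), a small phase×pH
interaction, replicate noise sd 0.1 and a metabolite-specific offset
spread of 0.15.  The spread perturbs each metabolite's level offset once
per seed (re-centered so per-metabolite offsets still sum to zero),
giving the between-metabolite contrast that makes ASCA loadings
non-degenerate.  `EffectSpec` itself defaults the spread to 0 so that
noise-free constructions are exactly reproducible.

Deliberately **not** emulated: isotope patterns, adducts, detector
saturation, pH-dependent ionization, retention drift between runs, and
correlated descriptor blocks.  Passing tests therefore demonstrate the
correctness of the algorithms under the stated additive-effects model,
not the chromatographic realism of any instrument; with real data the
ROI and matching stages additionally face centroiding quality, adduct
ambiguity and alignment issues that are out of scope here.

All stochastic generators require an explicit integer seed and are
bit-reproducible given one.

## Problem sizes and numerics

Tests and the acceptance script run at the reference scale where it is
cheap (48×54 matrices, 10,000 permutations — a fraction of a second) and
at reduced scale where repetition dominates: calibration uses 200
datasets at 1,000 permutations each; VIP recovery uses 50 seeds of a
54×20 descriptor problem with 5 active descriptors at noise sd 0.1;
per-condition PLS demonstrations use 40 synthetic descriptors with at
most 5 latent variables.  Tolerances: exact identities are asserted to
1e−8…1e−12; stochastic recoveries to 3–4 standard errors; calibration to
the binomial band above.  Degenerate inputs fail loudly (empty factor
levels, zero-variance response, constant columns under autoscaling,
unbalanced designs, profile spectra) rather than being silently coerced.

## Known limitations

- ROI merging is greedy single-pass; traces drifting more than the
  tolerance across a run can split, and co-eluting isobars merge.
- The apex rule picks one retention time per trace; double peaks
  (e.g., anomers) resolve to the taller apex.
- ASCA requires complete, balanced data; unbalanced variants
  (ASCA+/LiMM-PCA) are not implemented.
- PLS models here are exploratory; no external validation or
  applicability-domain machinery is provided.
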