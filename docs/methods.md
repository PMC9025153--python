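# Methods

This note documents the models, algorithms, parameters and design choices
behind `imsferm`, and what the synthetic study does and does not establish.

## Coordinate system and physics

A drift-tube IMS measures the arrival time t_D (s) of an ion packet over a
tube of length L (cm) at field strength E = U/L (V cm⁻¹), pressure p (hPa)
and temperature T (K). The reduced mobility

K₀ = L/(E·t_D) · (p/p₀) · (T₀/T),  p₀ = 1013.2 hPa, T₀ = 273.2 K,

normalizes arrival times to reference conditions. The stored inputs are
voltage and length (field strength is derived), temperatures are Kelvin
internally with the CLI converting °C by +273.15, and drift times are
seconds internally, milliseconds at I/O boundaries. The analysis itself
never needs absolute mobilities: all drift coordinates are expressed
relative to the reactant ion peak (RIP), t_D/t_RIP ("RIPrel"), which cancels
instrument geometry and drift-gas conditions. This is why a global rescale
of every raw drift axis leaves the preprocessed data unchanged (verified to
< 10⁻³ % on integrated peak volumes).

## Synthetic data generator

The generator emulates the study design the analysis assumes, not a
physical instrument simulation.

**Classes and panels.** Five classes: commercial yogurt, commercial kefir,
traditional mild kefir in two sub-varieties (LS, FN), traditional tangy
kefir; 16 samples per class by default, each measured in duplicate. All
classes share five milk-derived compounds at equal concentrations
(ethanol, acetone, 2-butanone, 2-heptanone, 2-nonanone). Yogurt adds the
bacterial-fermentation panel (diacetyl, 2,3-pentanedione, 2-pentanone,
acetoin, butyric and hexanoic acid). Commercial kefir is yogurt's panel
without 2,3-pentanedione and 2-pentanone, with acetoin ×3.5, diacetyl
×(1/2.3), plus acetic acid. Mild kefir drops 2-butanone, strongly elevates
ethanol, and adds the yeast panel (2-methyl-1-propanol, methyl-1-butanol,
ethyl acetate, ethyl hexanoate, 3-methylbutanal); hexanal appears in the FN
sub-variety only. Tangy kefir scales the mild panel (the two non-ethanol
alcohols ×1.6, ethyl acetate ×3.4, 3-methylbutanal ×4) and adds
3-methylbutyl acetate, 2-methylbutanal and 2-methylpropanal, without
hexanal. 2-methyl- and 3-methyl-1-butanol co-elute in practice and are
carried as one cumulated "methyl-1-butanol" entry.

**Positions.** Retention centers sit 8 s after the measured per-compound
retention *start* times of the compound table (the table records where a
peak begins, not its apex). Drift positions are synthetic fixture values —
only ethanol's 1.052 RIPrel monomer is a measured position — assigned once
and fixed, with the rule that compounds whose retention peaks can touch
(within ~54 s) are at least 0.072 RIPrel apart, so that pre-selected ±3σ
integration windows never overlap; this mirrors how an analyst picks peak
areas and keeps plateau estimates uncontaminated by neighbours.

**Peak shape.** Gaussian along drift (σ = 0.008 RIPrel); exponentially
modified Gaussian along retention (σ = 6 s) with a dimensionless tail
constant (τ/σ; 0 = symmetric) for chromatographic tailing. Peak scaling
preserves the analytic area: a symmetric peak of amplitude A integrates to
A·2π·σ_r·σ_d, the oracle used in the rendering and integration tests.

**Artifacts.**

- *RIP ridge*: Gaussian ridge at the RIP drift time (7.5 ms, σ 0.08 ms,
  amplitude 1200), locally depleted by `depletion_fraction` × (row analyte
  maximum / global analyte maximum) — a linear law, the simplest monotone
  choice for the charge competition that weakens the RIP where analytes
  ionize.
- *Ethanol saturation*: the analyte sum is clipped at a configurable
  ceiling (350 by default); together with ethanol's long tail (τ/σ = 8,
  amplitude 1200 in traditional kefir) this yields the characteristic
  saturated band more than 100 s long at 1.052 RIPrel. The artifact is
  qualitative only.
- *Baseline*: a smooth positive product of slow sinusoids (amplitude 15),
  with phases drawn per sample so duplicates share one baseline.
- *Noise and jitter*: i.i.d. Gaussian noise (σ = 2 intensity units, well
  below the 40–600-unit analyte amplitudes), a per-spectrum drift-axis
  shift (σ = 0.02 ms), and lognormal between-sample amplitude variation
  with 10% CV (mean-one). Duplicates share a sample's true amplitudes and
  differ only in noise and jitter; with both at zero they are bit-identical.
- Axes too coarse to resolve the narrowest peak (< 3 grid points per σ)
  are rejected at render time.

All randomness flows from one seeded generator; identical seeds give
bit-identical datasets. Ground truth records per-sample class, sub-variety
and true amplitudes, plus per-class presence vectors over the 11
kefir-associated qPCR taxa (commercial kefir: *Le. mesenteroides* and
*Lc. lactis* only; tangy adds *Kl. marxianus*; mild LS carries
*Kz. unispora* without *D. anomalus*; mild FN carries both; yogurt none of
the kefir panel).

## Preprocessing

Order: retention binning → RIP detection → RIPrel resampling → crop →
baseline correction → duplicate averaging → unfolding.

- **Binning**: arithmetic mean of every 5 consecutive retention rows; a
  trailing partial bin is kept and averaged over its actual rows. The
  averaging is interpreted as retention-direction data reduction (the
  direction in which consecutive IMS scans accumulate).
- **RIP detection**: argmax of the median drift profile over the 20% of
  retention rows with the lowest analyte signal (total intensity outside a
  small window around the provisional RIP column). Restricting to
  low-analyte rows makes the estimate robust to RIP depletion; a flat
  spectrum raises a detection error.
- **Resampling**: per retention row, a cubic spline over the RIPrel source
  axis evaluated on a uniform grid; no extrapolation (zeros outside the
  source range); the grid must not extend beyond the source range by more
  than one step. The default grid has 531 points across 1.03–2.0 RIPrel.
- **Crop**: 1.03–2.0 RIPrel × 150–600 s inclusive — the informative window
  past the RIP and the solvent front.
- **Baseline**: per drift row then per retention column, subtract a rolling
  minimum (window 10% of the axis length, minimum 3 points) smoothed by a
  moving average of the same width, then clip negatives to zero. The
  rolling minimum is parameter-light and cannot overshoot peaks whose
  width is below the window; the long saturated ethanol band exceeds the
  retention window and is partially flattened, which is why recovery
  references are built in this same space (below).
- **Unfolding**: row-wise (retention-major) reshape of the S × R × D cube
  into S × (R·D) with an explicit index bijection; refolding is bit-exact.
  Non-negativity holds end-to-end after clipping, as the factorization
  requires.

At the defaults the cube is 80 × 75 × 531 and the unfolded matrix
80 × 39 825.

## Decomposition

**PCA** is the standard mean-centered SVD (delegated to scikit-learn);
explained variance is reported in percent of total centered variance.

**NNMF** minimizes the RMS residual D = √mean((X − WH)²) subject to
W, H ≥ 0 by alternating non-negative least squares from seeded uniform
random initializations (5 restarts; the restart with the lowest residual
wins, ties to the earliest). Each half-step solves its subproblem exactly:
with k ≤ ~12 components, one small design matrix is shared by tens of
thousands of right-hand sides, so all 2^k − 1 active sets are enumerated,
the normal equations solved batched per support, each feasible candidate's
quadratic objective evaluated explicitly, and the best kept — with the
previous iterate seeding the incumbent, which makes the residual
structurally non-increasing (asserted every iteration, with a roundoff
floor of 10⁻¹² · rms(X) for exactly factorizable inputs). Iteration stops
when the relative residual change falls below 10⁻⁶ or at 500 iterations.
The component count k is an explicit parameter (no automatic rank
selection); k = 4 in the default study, matching the four merged classes.

NNMF components carry an arbitrary per-component scale and order, so all
component comparisons use cosine similarity and best one-to-one (Hungarian)
assignment, never fixed indices. Unseen samples are projected by per-row
NNLS against the fixed H; PCA projects linearly.

**Recovery references.** A recovered component is compared against the
noise-free class pattern *as the factorization sees it*: one clean spectrum
per class (no noise, jitter or amplitude variation) rendered and pushed
through the identical preprocessing chain, the two mild sub-varieties
averaged. Comparing against raw analyte renders instead would mix the
factorization's error with the preprocessing's reshaping of the saturated
ethanol band. On the default dataset the best-assignment cosines are
≈ 0.99 for all four classes.

## Classification

- **Split**: stratified 80:20; each class contributes round(0.8·n_c)
  training samples with half rounded up, members chosen by seeded shuffle.
  Applied to class sizes 18/16/20/22 this yields 61 training and 15 test
  samples.
- **Cross-validation**: seeded stratified fold assignment (per-class
  shuffle, round-robin deal); every sample is predicted exactly once, and
  the partition property is asserted at run time. Default 10 folds for the
  4-label problem, 8 for 5-label runs where the smallest class has 8
  training members; classes smaller than the fold count relax
  stratification with a logged warning.
- **Models**: LDA (pooled covariance); kNN with k = 5, Euclidean, majority
  vote, ties re-voted with k−1 until resolved (final fallback: nearest
  single neighbour), k clipped to the available training points; SVM with
  a linear kernel and cost 1 on unit-variance standardized features
  (standardization fitted on the training fold); PLS-DA as PLS regression
  on one-hot class indicators with class = argmax, run on the unfolded
  matrix directly with 4 components by default. LDA, SVM and the PLS core
  are scikit-learn; kNN and PLS-DA's class wrapper are implemented here to
  pin the tie-break and indicator conventions.
- **Reporting**: CV error as a one-decimal percent and test accuracy as an
  integer percent, both rounded half away from zero via exact decimal
  arithmetic; the report container asserts the rounding identities against
  its own counts. (With these conventions 2/61 → 3.3%, 13/15 → 87%,
  5/61 → 8.2%; note 3/61 rounds to 4.9%.)
- **HCA**: scipy Ward linkage on Euclidean distances; under scipy's
  convention two singletons merge at their plain Euclidean distance.
  Dendrograms export to Newick with branch lengths from merge heights.

## Quantification

"Plateau" integration is formalized as: grow the footprint from the apex by
an 8-connected flood fill that follows non-increasing intensity outward;
the first cells where intensity rises again, or cells at the floor, form
the boundary ring; the plateau is the **median** boundary intensity (robust
to single noisy cells); the raw volume is Σ(intensity − plateau) over
footprint cells above the plateau. Comparisons treat numerically equal
cells (within 10⁻⁹ of the apex intensity) as non-increasing so that
saturated flat tops and interpolation roundoff cannot flip the discrete
footprint. The measure is invariant to a constant pedestal (within 5% on
test oracles; the plateau absorbs it) and exactly linear in intensity
scale. Volumes are normalized by the cell count of a pre-selected
per-compound window (±3σ boxes from the compound library by default),
keeping windows of different size comparable.

Per-sample volumes search each library window for a local maximum
(hill-climb from the window argmax), integrate within the window, and
report 0 when no signal exceeds 2% of the spectrum maximum. Fold changes
are volume ratios between class-mean spectra; a zero numerator or
denominator is flagged as presence/absence rather than divided. Annotation
assigns library compounds to apexes one-to-one by increasing
tolerance-normalized distance (±5 s, ±0.01 RIPrel defaults). Component
heatmaps can be normalized per component (default) or per sample.

The microbe screen computes Pearson correlations between each compound's
per-sample volumes and each taxon's presence (0/1); pairs with |r| > 0.85
are flagged, and constant vectors are reported as missing rather than
flagged. On the default dataset hexanal correlates with *D. anomalus* at
r ≈ 0.99 and 3-methylbutyl acetate's top correlate is *Kl. marxianus*,
reproducing the intended microbe–compound associations by construction.

## Problem sizes and determinism

The default study — 160 raw spectra of 435 × 456 points, preprocessing to
80 × 39 825, NNMF with 5 restarts, 7 classifier reports, full
quantification — runs in well under a minute on one CPU; the test suite
regenerates everything programmatically (no stored data files). Every
random operation (generation, NNMF restarts, split, folds) references an
explicit seed, and reruns reproduce manifests bit-identically apart from
timings.

## Limitations

- The generator's peaks are separable Gaussian/EMG shapes with linear RIP
  depletion and a purely qualitative saturation artifact; real GC-IMS data
  show drift-time-dependent peak widths, monomer/dimer intensity coupling,
  retention drift between runs, and structured (non-i.i.d.) noise. Passing
  recovery tests here demonstrates the correctness of the chain's
  algorithms under the stated model, not instrument-grade robustness.
- Synthetic drift positions are fixtures, not measurements; only ethanol's
  RIPrel position is anchored to a measured value.
- Perfect classifier rows reflect the well-separated default panels; they
  are a correctness mirror, not a claim about noisy real-world separability.
- Microbial metadata is presence/absence; the correlation screen does not
  model abundance, and qPCR efficiency or cross-reaction are out of scope.
- Absolute concentration calibration is out of scope; volumes are
  arbitrary units, meaningful only relatively.
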