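# Methods

This note documents the models, conventions and design choices behind
`gspbench`, in the order data flows through the package.

## Synthetic cohort

The generator produces the statistical structure the comparative analysis
assumes, not a biophysical forward model (no hemodynamics, no
tractography).

**Structural backbone.** The group connectome is a weighted stochastic
block model: regions are split into contiguous communities
(`n_communities`, default 4), edges appear with probability 0.65 within and
0.15 between communities, and edge strengths are log-normal.  Draws are
rejected until the support is connected (at most 50 retries).  The
community structure makes the low-frequency harmonics contrast large,
spatially coherent blocks, analogous to the large-scale patterns
(hemispheres, anterior-posterior gradients) of real connectome harmonics.
All four edge properties are deterministic transforms of one latent
topology, so their supports coincide as they would when derived from a
single tractogram: NF is an integer fiber count (≥ 1 per edge), NFD
rescales NF by per-region log-normal size factors, MFL is a positive
continuous length-like field, MFA a logistic transform into (0, 1).

**Subject connectomes.** Each subject multiplies every existing edge by a
symmetric log-normal jitter (log-scale sd `subject_sc_jitter`, default
0.2), the same multiplicative field for all four properties of that
subject.  Support is exactly preserved; jitter 0 reproduces the group SC.

**BOLD-like signals.** No generative model for BOLD on a graph is implied
by the analysis itself, so the generator uses the simplest model consistent
with what GSP assumes about resting-state data: graph-smooth signals with
subject-specific spectral content,

    X = U_s diag(g ⊙ a_s) E + δ_day D_day + δ_phase D_phase + σ N + c·FD·m

with `U_s` the subject's unnormalized-Laplacian harmonics, low-pass
envelope `g_k = 1/(1+λ_k)`, per-subject log-normal spectral signature `a_s`
(log-scale sd `subject_signature_strength`, default 0.5; constant across
the subject's four scans — this is the trait-like fingerprint), white
driver `E` and white noise `N` (sd 0.5).  Two generator-internal choices
deserve a note:

* The Laplacian used for signal generation comes from the NFD connectome
  rescaled to unit mean degree.  Raw fiber-count-scale weights put all
  nonzero eigenvalues far above 1, collapsing `g` onto the constant mode
  and leaving nothing for z-scored analyses; unit mean degree places the
  spectrum in `g`'s useful range.  Eigenvectors are unaffected by the
  rescaling.
* Day and phase session effects are fixed random R×T fields shared across
  subjects (amplitudes `day_effect`, `phase_effect`, default 0.1 each).  A
  time-constant spatial map would be annihilated by temporal z-scoring,
  which would make the acquisition-settings criterion vacuously perfect for
  half the grid; a spatiotemporal field survives every preprocessing
  branch.

**Motion.** Per-scan mean framewise displacement is drawn by rejection
from a normal distribution truncated to hard bounds (defaults 0.13 ± 0.02
mm on [0.08, 0.18] mm, the regime of a low-motion cohort).  A smoothed
white-noise motion regressor, scaled by `motion_coupling · mean_fd`, is
added to all regions, producing a small, tunable FD-explained variance in
the features.

**Scan design.** Four scans per subject: 2 days × 2 phase-encoding
directions, LR acquired first on each day.  Session 1 (SES1) denotes the LR
scans, session 2 (SES2) the RL scans, on both days.

**Test mode.** `frozen_driver=True` reuses one white driver per subject,
so with noise, session effects and motion disabled the four scans are
bit-identical — the oracle condition for ICC = 1 and accuracy = 100%.

**Parcellation variants.** `S3` is the identity; `S3-` drops the last
`round(0.21·R)` regions (the proportion by which removing subcortex and
cerebellum shrinks a 274-region atlas to 216); `S1` merges regions pairwise
within communities, summing SC edge weights (self-loops discarded) and
averaging time courses, mirroring a coarser atlas scale.  The nearest-
integer drop count (rather than a ceiling) also reproduces the small-atlas
case 20 → 16.

**What the generator does not emulate.** Spatial autocorrelation of noise,
hemodynamic temporal autocorrelation, scanner drift, distance-dependent
connectome weights, heavy-tailed motion, and state-like day-to-day
reconfiguration.  Passing tests therefore show that the pipeline recovers
planted structure under its own assumptions — not that any particular
feature type will win on real data.

## Operators and harmonics

Connectomes are validated symmetric (tolerance 1e-10, then averaged with
their transpose), nonnegative, zero-diagonal.  Zero-degree regions are
handled through the Moore-Penrose inverse of the degree matrix.  The
modularity operator follows the `A − kkᵀ/(2M)` convention with `M = Σk`
by default; this differs by a factor 2 in the subtracted term from the
standard Newman matrix (`convention="newman"`), and the two are *not*
scalar multiples — row sums are `k/2` versus 0 — so both are exposed and
both conventions are asserted in tests.

`L_RW` is not symmetric; its harmonics are computed from the generalized
symmetric problem `L u = λ D u` restricted to nonzero-degree regions, which
is numerically stable, guarantees a real spectrum, and yields exactly the
`L_N` eigenvalues.  The degree vector is stored as the basis's inner-
product weight so the graph Fourier transform can use the correct adjoint
(`Uᵀ D X`), making analysis and synthesis a true inverse pair; a strict
mode applies the plain transpose for all kinds.  Eigenvalues are ascending
(stable order on ties); each eigenvector's largest-magnitude entry is made
positive, so features are reproducible across runs and platforms.

## Features

* **Temporal z-scoring** uses the population-sd convention (divide by T),
  the common fMRI practice; a flag selects the sample-sd convention.
  Constant rows are zeroed with a warning.
* **Spectral normalization** divides each time point's coefficient column
  by its L2 norm (zero columns untouched, with a warning), which makes the
  per-timepoint PSD sum exactly 1.
* **Energy** is `λ_k x̂_{t,k}` — the eigenvalue-weighted coefficient
  itself; the variance-like `λ_k x̂²` is available behind a flag.
* **Retained-harmonics grid**: 10 uniform percentages from 5% to 20% of R,
  rounded half-away-from-zero to counts.  Duplicate counts (inevitable at
  small R) are kept in the enumeration so the grid size stays 10, but
  identical combinations collapse to a single stored feature vector.
* **Cutoff schemes**: `f1 = ⌊R/2⌋`.  The equal-energy rule is "largest
  index with cumulative PSD ≤ 0.5": the strict-inequality formulation has
  no solution when the cumulative distribution ties at exactly 0.5, and the
  ≤ rule is its continuous limit.  `f2` applies it per time point (each
  column filtered with its own split before the temporal norms — the only
  reading consistent with one cutoff per time point), `f3` takes the mode
  of the `f2` values (smallest on ties), `f4` applies the rule to the
  time-averaged cumulative PSD.  On an exactly flat PSD all four schemes
  coincide at `⌊R/2⌋`.
* **SDI degenerate cases**: zero aligned norm with nonzero liberal norm
  gives +inf, 0/0 gives 0, each with a warning.
* The cutoff PSD is always computed from the same (optionally normalized)
  coefficients being analyzed, so the SDI of a combination is self-
  contained.

## Quality criteria

* **Session similarity**: same-day pairs are (LR, RL) within each day;
  different-day pairs are same-phase across days.  `ΔR = R̄= − R̄≠` per
  subject.  The penalty is `Ω = Σ_s max(0, −ΔR(s))`: a pure Heaviside count
  cannot grow with how strongly negative the gaps are, whereas the
  magnitude sum captures both the number and the severity of incongruent
  subjects; the count variant remains available.  Subjects with any
  constant feature vector are excluded from `ΔR` with a warning.
* **Motion sensitivity** is `100·r²` between each coefficient and per-scan
  mean FD across subjects, averaged over coefficients then over the four
  scans.  Under independence its expectation is `100/(S−1)`, which the
  tests verify by Monte Carlo.
* **ICC(A,1)** is computed from two-way ANOVA mean squares
  (`(MS_R − MS_E)/(MS_R + (k−1)MS_E + (k/n)(MS_C − MS_E))`), implemented
  directly and cross-checked in tests against both a naive sum-of-squares
  oracle and an independent statistics library.
* **Fingerprinting** maximizes total Pearson similarity with the Hungarian
  algorithm; accuracy is the percentage of correct assignments, averaged
  over the two same-phase day pairs for the full-feature criterion.  For
  single-coefficient feature vectors Pearson is undefined, so similarity
  degrades gracefully to the negative absolute coefficient difference
  (nearest-value matching) — without this, an all-zero similarity matrix
  would spuriously resolve to the identity assignment.
* **Subset selection** ranks coefficients by ICC computed on SES1 (LR)
  scans only (k = 2; undefined ICCs ranked last, ties by index) and
  evaluates accuracy on the SES2 (RL) day pair only, so selection and
  evaluation never share data.  The sweep includes every set size from 1 to
  R (configurable stride, R always included); the reported percentage of
  used coefficients is the smallest attaining the maximum.  The ICC
  criterion itself averages all-scan ICC over the selected subset.
* **Generalization** is the mean absolute change in full-set accuracy from
  S3 to S3− and from S3 to S1 (a signed-mean variant is exposed).
  Combinations are matched across variants by grid position, because the
  retained-harmonics counts depend on R.
* **Ranking**: min-max normalization over the concatenated cases per
  criterion, orientation flipped where lower is better, consensus = the
  unweighted mean of the six.  A criterion constant across cases carries no
  information and normalizes to 50 with a warning.

## Pattern embedding

Per subject and scan, cosine distances between the feature vectors of all
combinations enter the row-adaptive kernel `S(i,j) = exp(−d²_ij/σ²_i)` with
`σ_i` the mean distance from i to the rest; affinities are averaged over
scans then subjects.  The kernel is asymmetric, so by default the matrix is
symmetrized (`(S+Sᵀ)/2`) before eigendecomposition, keeping the spectrum
real; a raw mode decomposes the asymmetric matrix and takes real parts.
Coordinates are the second and third eigenvectors by descending eigenvalue.
Zero-norm feature vectors have undefined cosine distances; they are removed
from the `σ` estimate and their affinity row/column set to 0, with a
warning.

## Problem sizes

The analysis drivers use a 10-subject, 40-region, 150-timepoint cohort over
the full grid (2560 stored combinations after duplicate-`nH` collapse) and
all three parcellation variants; the fingerprinting-recovery analyses and
the acceptance script use the default 20-subject, 60-region, 200-timepoint
configuration.  These sizes keep the entire comparison reproducible on a
single CPU in minutes while leaving all planted effects recoverable.

## Known limitations

* The BOLD generative model is an assumption (see above); every strength in
  it is configurable, and the null configuration (no signature, no jitter)
  verifiably drives fingerprinting to chance.
* Whether the temporal L2 reduction should be scaled by `1/√T` is left
  unnormalized; it cancels in correlations and rankings.
* PSD feature vectors are used on their raw scale (no log transform).
* No time-resolved (dynamic) outputs, no voxel-level graphs, no Slepian
  localization, no mixed-effects factor modelling of feature values — the
  package scores pipelines, it does not decompose variance over factors.
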