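# gspbench

Comparative graph-signal-processing (GSP) pipelines for connectome-based
subject fingerprinting.

## The problem

In network neuroscience, GSP expresses regional BOLD activity in terms of
the structural connectome: a symmetric weight matrix `A ∈ R^{R×R}` defines a
graph shift operator, its eigenvectors (*connectome harmonics*) form a
basis, and the graph Fourier transform `x̂_t = Uᵀ x_t` re-describes each
functional frame as spectral coefficients.  Many choices hide inside that
pipeline — which edge property the connectome encodes, whether the
connectome is group-averaged or subject-specific, which operator variant is
used, whether time courses are z-scored and spectra normalized, how many
harmonics a filter retains — and many output features have been proposed.
`gspbench` implements the full comparison: five feature types over the
complete factor grid, scored by six quality criteria with subject
fingerprinting as the primary outcome, exercised end-to-end on a synthetic
multi-subject cohort so every stage is testable without any data download.
It is written for methods researchers who want to benchmark GSP pipeline
variants, or to reuse the individual building blocks (operators, harmonics,
graph filters, ICC, Hungarian fingerprinting, consensus ranking).

## The pipeline

**Operators** (from connectome `A`, degrees `k`, `D = diag(k)`,
`M = Σ_r k_r`):

| kind | definition |
|------|------------|
| `L_U`  | `D − A` (unnormalized Laplacian) |
| `L_N`  | `D^{+1/2} (D − A) D^{+1/2}` (normalized) |
| `L_RW` | `D^{+} (D − A)` (random walk; solved as `L u = λ D u`) |
| `L_Q`  | `A − kkᵀ/(2M)` (modularity; Newman's `kkᵀ/M` behind a flag) |

Eigenvalues are always sorted ascending; eigenvector signs are fixed
deterministically.

**Features** (each reduced to a length-R vector by the L2-norm over time):
PSD `P_{t,k} = x̂²_{t,k}`; energy `E_{t,k} = λ_k x̂_{t,k}`; alignment and
liberality, the low-/high-pass graph-filtered signals
`X_F = U H Uᵀ X` with `nH` retained harmonics swept from 5% to 20% of R in
10 steps; and the structural decoupling index `SDI = ‖X_L‖₂ / ‖X_A‖₂`
per region, with the low/high split chosen by one of four cutoff schemes
(half split; per-timepoint, modal, or time-averaged equal-energy splits of
the cumulative PSD).

**Quality criteria** per feature type × parameter combination: percentage
of subjects more similar across days than within a day (with the penalty
`Ω = Σ_s max(0, −ΔR(s))`), variance explained by mean framewise
displacement, ICC(A,1) of the selected coefficients, maximal Hungarian
fingerprinting accuracy under an ICC-ranked feature-subset sweep (selection
on the first-session scans, evaluation on the held-out second-session day
pair), parsimony of that subset, and accuracy change across parcellation
variants.  The six criteria are min-max normalized to [0, 100] and averaged
into a consensus ranking.

**Synthetic cohort**: a weighted stochastic-block-model backbone rendered
as four edge properties (NFD, NF, MFL, MFA) sharing one support;
subject-specific SCs via log-normal edge jitter; graph-smooth BOLD-like
signals `X = U_s diag(g ⊙ a_s) E + …` with a low-pass envelope
`g_k = 1/(1+λ_k)` and a per-subject spectral signature `a_s`; a
2-day × 2-phase-encoding scan design with additive session fields; and
per-scan mean FD from a truncated normal (0.13 ± 0.02 mm, bounded to
[0.08, 0.18] mm) coupled in through a smooth motion regressor.

## Worked example

```python
from gspbench import (CohortConfig, ParameterCombination, generate_cohort,
                      compute_single_combo, fingerprint_accuracy_pairs,
                      select_features_by_icc, session_similarity_stats)

cfg = CohortConfig(seed=7)          # 20 subjects, 60 regions, 200 frames
cohort = generate_cohort(cfg)

combo = ParameterCombination("NF", "individual", "L_U",
                             zscore=True, normalize=False, extra=12)
table = compute_single_combo(cohort, "liberality", combo)

acc = fingerprint_accuracy_pairs(table, "liberality", combo)
sim, omega, pct = session_similarity_stats(table, "liberality", combo)
acc_max, pct_used, sel, _ = select_features_by_icc(table, "liberality", combo)

print(f"full-set fingerprinting accuracy : {acc:.1f} %")
print(f"penalty Omega / incongruent      : {omega:.3f} / {pct:.1f} %")
print(f"max accuracy after ICC selection : {acc_max:.1f} % "
      f"using {pct_used:.1f} % of coefficients")
```

prints

```
full-set fingerprinting accuracy : 100.0 %
penalty Omega / incongruent      : 0.004 / 40.0 %
max accuracy after ICC selection : 100.0 % using 8.3 % of coefficients
```

Liberality features computed on subject-specific connectomes identify every
subject across days (100%); the near-zero penalty says same-day scans are
almost always more similar than cross-day scans; and an ICC-ranked subset of
5 of the 60 regional coefficients already suffices for perfect
identification on the held-out session pair.

## The full analysis

Numbered drivers under `analysis/` run the complete comparison on a
10-subject, 40-region cohort and write tables to `results/`:

```bash
python analysis/01_simulate_cohort.py     # cohort -> scratch/cohort.h5
python analysis/02_feature_grid.py        # 2560 combinations x 3 variants
python analysis/03_pattern_embedding.py   # results/embedding_<feature>.csv
python analysis/04_quality_criteria.py    # results/quality.csv
python analysis/05_rank_pipelines.py      # results/ranking.csv, top20.csv
```

On this cohort the operator choice is by far the strongest organizer of
feature-vector patterns (eta² ≥ 0.93 on the first embedding dimension for
every feature type), subject-specific connectomes dominate fingerprinting
(mean full-set accuracy 99.4% vs 83.9% for a group connectome), and the
spectral-domain features reach maximal accuracy with the fewest
coefficients while generalizing best across parcellation variants.

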