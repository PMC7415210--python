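# Methods

## Scope

`dynfc` implements a sliding-window dynamic functional-connectivity
(dFC) analysis for resting-state ROI time series: windowed Pearson
correlation, detection of recurring connectivity states by two-stage
k-means under the L1 distance, state temporal properties (dwell time,
transitions, transition frequencies), nodal temporal variability, and
a group-statistics layer (edgewise GLM with FDR, covariate-adjusted
rank tests, ROC on significant-edge strength, partial correlations
with clinical scores). A synthetic state-switching cohort generator
with full ground truth makes every stage testable without access to
clinical imaging data.

The package starts from extracted ROI time series. Image-space
processing (parcellation, nuisance regression, band-pass filtering,
motion handling) is upstream and out of scope.

## Windowed connectivity

Windows are rectangular, `window_length = 10` TRs advanced by
`step = 1` TR (30 s at TR = 3 s), indexed 0-based and half-open:
window *i* covers time points `[i, i+10)`. A T = 135 series yields
`(135 − 10)/1 + 1 = 126` windows. Each window's connectivity matrix is
the plain Pearson correlation of the segment — no Fisher z-transform
and no tapering anywhere; all downstream computation operates on raw
correlations. A zero-variance segment (a flat region within one
window) produces 0-valued correlations for that region plus an audit
flag, rather than NaN, so clustering stays total.

## State detection

**Exemplar subsampling.** For each participant, let `l_i` be the
L1-norm (sum of absolute values over the p(p−1)/2 unique edges) of
window *i*. Windows with `|l_i − m| > 1.5·SD(l)` are exemplars. The
reference `m` is the mean of the participant's window L1-norms
(`center="mean_norm"`); at 1.5 SD this selects the expected ~13%
high-deviation tail. The alternative reading — `m` as the L1-norm of
the across-window mean matrix — is available (`center="norm_of_mean"`)
but degenerate for noisy windowed FC: averaging cancels
sign-fluctuating noise on weak edges, so the mean matrix's norm falls
below every individual window's norm by roughly `0.8·σ` per weak edge
summed over thousands of edges, and the "tail" becomes the whole
sample. Deviation is two-sided; the SD is the participant's own
(ddof = 1).

**k-medians under L1.** "k-means with L1 distances" is realized with
element-wise-median centroid updates, the L1-consistent centroid:
assignment by cityblock distance (ties to the lowest centroid index),
update by the per-edge median, stopping when labels stabilize, the
cost decrease falls below `1e-8`, or 300 iterations pass. The cost
Σᵢ‖xᵢ − c(xᵢ)‖₁ is non-increasing by construction. An emptied cluster
is re-seeded at the vector farthest from its previous centroid and the
event is logged.

**Cluster number.** k is scanned over 2..9 with 100 replicate
initializations per k (k distinct exemplar vectors sampled without
replacement; all replicate seeds derive from one master seed). The
best-cost replicate per k is scored by the mean Silhouette coefficient
(cityblock metric) and the Calinski-Harabasz (CH) index. The chosen k
is the CH argmax; the Silhouette elbow (interior k maximizing
`2s_k − s_{k−1} − s_{k+1}`) is computed as a cross-check and any
disagreement is recorded, CH winning. A flat CH curve falls back to
the lowest k with a warning; maximum Silhouette below 0.25 raises a
"no cluster structure" warning.

**Final clustering.** All windows of all participants are clustered
once, deterministically, by k-medians initialized at the exemplar-stage
centroids. States are then renamed by ascending mean |centroid| so
that state 1 is always the weakest-connectivity "baseline" state; the
renaming is a pure permutation of labels.

## State metrics

Participant-specific state FC is the element-wise median over the
participant's windows in that state (absent states are marked, not
imputed). Dwell time is total occupancy — the number of windows
labeled with the state — not mean contiguous run length; the
occupancy convention keeps per-participant dwell times summing to the
window count (126 at defaults). A run-length variant sits behind
`contiguous=True`. Group dwell means average over all participants
(absent state = 0). The transition count is the number of label
changes; the transition-frequency matrix divides ordered
(source ≠ target) change counts by the total change count (all-zero
when no change occurs). The group transition-frequency distribution
averages participant matrices over participants with ≥ 1 transition.

## Temporal variability

For region k, its FC profile in window *i*, `F_{i,k}`, is row k of the
window-i correlation matrix with the self-entry removed (the diagonal
is the constant 1 and carries no information). Temporal variability is

    V_k = 1 − Σ_{i≠j} ρ(F_{i,k}, F_{j,k}) / (n (n − 1)),

the complement of the mean pairwise Pearson correlation over all
window pairs; V_k ∈ [0, 2]. Since ρ is symmetric the ordered-pair mean
equals the unordered-pair mean; the implementation standardizes the n
profiles and averages the off-diagonal of their Gram matrix, which is
algebraically identical to the printed double sum. An explicit
O(n²) pairwise-loop oracle ships in the package for validation, and
the two agree to 1e-10 on full-size inputs. Regions with any constant
window profile are flagged invalid (V = NaN) instead of silently
propagating NaN.

## Group statistics

- **Normality gate:** Lilliefors test (KS with estimated mean/SD,
  table-based p-values) at α = 0.05 routes continuous comparisons to
  parametric or rank tests. Constant input is non-normal with a
  warning.
- **Edgewise GLM:** per edge, `FC ~ group + age + sex` by OLS, with
  the group coefficient's t statistic and two-sided p. Age is
  centered and sex coded 0/1 for conditioning; participants lacking
  the state are excluded; a state with fewer than two participants in
  either group is skipped with a warning. Benjamini-Hochberg FDR is
  applied per state over its tested edges. FDR families follow the
  analysis block: per state for edges, per region set for
  variability, per the property set (k dwell + 1 transition count +
  k(k−1) frequencies) for temporal properties.
- **Covariate-adjusted rank test:** values are residualized on
  [1, age, sex] by pooled OLS (no group term), then a two-sided
  Mann-Whitney U runs on the residuals; with no covariates it is
  exactly the plain U test. U is reported in the min(U₁, U₂)
  convention. Residualization is the simplest faithful mechanism for
  "rank test with covariates controlled"; it is a documented choice,
  not the only one.
- **ROC:** per state and direction, each participant's score is the
  median of their state FC over that direction's significant edges;
  AUC uses the rank (Mann-Whitney) formulation with half-credit ties,
  reported with orientation so AUC ≥ 0.5. Edge selection and
  classification use the same sample — deliberately mirroring the
  published procedure; this is circular and the AUCs are optimistic
  as biomarker estimates.
- **Partial correlation:** Pearson correlation of the two OLS
  residual vectors on the covariates, p from t with n − 2 − #cov
  degrees of freedom, two-sided. Computed within the patient group
  between clinical scores (MMSE, NPI) and the dFC indicators.

## Synthetic cohort generator

The generator emulates the structure the analysis targets, not fMRI
physics: no hemodynamics, drift, or motion spikes.

- **States.** Each latent state is a correlation matrix from a
  seeded random 4-factor model (`C = corr(L Lᵀ + 0.6 I)` with L a
  60×4 standard-normal loading matrix, fixed per-state seeds), with
  off-diagonals scaled by (0.9, 1.0, 1.1) so the states are strength-
  ordered but separated chiefly by structure. The module-block builder
  (within/between levels over a region partition) is retained as an
  option; it is not the default because an equicorrelated block has a
  single dominant factor, and at 10-sample windows the correlated
  estimation error elongates each state's window cloud radially —
  model selection then merges weak states (k = 2) or splits the
  largest state (k = 4) for every block design we evaluated.
  Few-comparable-factor states have no dominant noise axis and are
  recovered cleanly.
- **Switching.** First-order Markov chains at time-point resolution;
  windows that straddle a switch are naturally mixed. Controls:
  self-transitions (0.985, 0.970, 0.975), stationary occupancy
  ≈ (0.54, 0.25, 0.21). Patients: (0.950, 0.980, 0.950), occupancy
  ≈ (0.19, 0.62, 0.19) — patients dwell in state 2, controls in
  state 1, patients switch more often (≈4.2 vs ≈2.8 expected
  transitions per series). Initial states draw from each chain's
  stationary distribution. The pooled window pool keeps no single
  state above half the mass, which the exemplar-based cluster-number
  selection needs.
- **Observations.** Given the state, draws are i.i.d. zero-mean
  multivariate normal with the state's (group-specific) correlation,
  plus white observation noise (SD 0.1; sampled correlations shrink
  by 1/(1+0.01), negligible). Zero means throughout because windowed
  Pearson correlation is mean-invariant; no autocorrelation model.
- **Planted group effects.** Patients carry Δr = ±0.4 on three
  state-2 edges with near-zero baseline. The perturbed matrix is
  projected back to the PSD cone by alternating projections that hold
  the planted entries fixed (a single eigenvalue-clip projection
  would erode the planted values by ~40%); the projection spreads a
  small remainder over other edges (collateral group differences up
  to ≈0.16 on a few edges, mean ≈0.009), so the significant edge set
  can legitimately exceed the three planted edges.
- **Demographics.** Age, MMSE and NPI are drawn per group from
  normal distributions with the means/SDs typical of an AD-vs-control
  resting-state cohort (e.g., MMSE 21.2 ± 3.2 vs 29.0 ± 1.3), clipped
  to instrument ranges; sex is Bernoulli(0.5).

What the generator does *not* emulate — autocorrelated BOLD noise,
inter-individual connectome differences within a group, scanner and
site effects, motion artifacts — bounds what passing tests show:
recovery under these conditions demonstrates the pipeline's
correctness and internal power, not expected sensitivity on real
fMRI.

## Problem sizes and numerical choices

- Default cohort: 20 participants/group, 60 regions, 135 time points;
  the acceptance script runs 26/group so the bookkeeping (52 × 126 =
  6552 windows, ~12% exemplars ≈ 770) matches the study geometry it
  emulates. Validation suites use scaled sizes chosen for the
  signal being tested: effect-recovery and null-level suites run 20
  replicates at 60/40 regions with the cluster count fixed at the
  (separately validated) k = 3; scalar-test levels use 500+ direct
  null simulations.
- PSD repair: eigenvalue clipping at 1e-8 with diagonal rescaling;
  with planted entries, alternating projections (≤ 500 iterations,
  feasibility tolerance 1e-6 with a final diagonal-shift touch-up).
- k-medians: tolerance 1e-8 on the cost decrease, max 300 iterations,
  assignment ties toward the lowest centroid index — all fixed for
  determinism. Every stochastic step derives its seed from one master
  seed via `numpy` SeedSequence spawning.
- Degenerate inputs: all-identical windows (no exemplars, clustering
  refuses k > distinct vectors), constant regions (flagged on load),
  constant profiles (invalid V_k), empty clusters (re-seeded, logged),
  states absent for a participant (excluded edge-wise), states too
  rare for inference (skipped with a warning).

## Known limitations

- The exemplar rule concentrates on strength outliers; states that
  differ only structurally at identical overall strength are
  under-sampled at the exemplar stage even when the final clustering
  would separate them.
- Occupancy-based dwell time conflates visit length with visit count;
  the run-length variant is provided but untested against group
  contrasts.
- The ROC analysis is circular by design (see above); a split-half
  mode would be the hygienic variant and is not implemented.
- With 10-sample windows, sampling noise per edge (σ ≈ 0.3) dominates
  single-window matrices; all inference relies on aggregation
  (medians over windows, group models), and per-window quantities
  should not be interpreted individually.
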