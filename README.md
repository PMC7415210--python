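# dynfc — dynamic functional-connectivity states from ROI time series

Resting-state functional connectivity (FC) is not static: over a scan,
whole-brain correlation structure moves through recurring
configurations ("FC states"), and both the states themselves and how a
brain moves between them differ between patients and controls — in
Alzheimer's disease, patients linger in an abnormal strongly-connected
state, switch more often, and show reduced region-level FC
variability. `dynfc` is an analysis pipeline for exactly this kind of
study: it takes per-participant ROI time-series tables plus a cohort
manifest and produces FC states, their temporal properties, nodal
temporal variability, and the full between-group statistics layer. A
synthetic cohort generator with planted ground truth makes the whole
pipeline verifiable end to end, which is how the test suite and the
reproduction script exercise it.

It is written for researchers running sliding-window dFC analyses who
want a tested, scriptable implementation rather than a GUI toolbox.

## The analysis

1. **Sliding-window FC.** Pearson correlation in windows of 10 TRs
   (30 s at TR = 3 s), stepped by 1 TR: a 135-time-point series gives
   n = 126 symmetric p × p matrices per participant. No Fisher
   z-transform, no tapering.
2. **State detection** (two-stage k-means under the L1 distance,
   i.e. k-medians). Per participant, *exemplar* windows whose
   edge-vector L1-norm deviates from the mean window L1-norm by more
   than 1.5 SD are pooled; k-medians with 100 replicate
   initializations is run for k = 2..9 and scored by the Silhouette
   coefficient (cityblock) and the Calinski-Harabasz index (CH peak
   decides, Silhouette elbow cross-checks). All windows are then
   clustered once, initialized at the exemplar centroids, and states
   are named by ascending overall connectivity strength (state 1 =
   baseline).
3. **Temporal properties.** Per participant: dwell time (windows
   spent in each state), number of state transitions, and the
   transition-frequency distribution over ordered source→target
   pairs.
4. **Temporal variability.** For region k with window-i FC profile
   F_{i,k} (row k of the window-i matrix, self-entry removed),

       V_k = 1 − Σ_{i≠j} ρ(F_{i,k}, F_{j,k}) / (n (n − 1)),

   one minus the mean pairwise Pearson correlation of the region's
   connectivity profile across all window pairs.
5. **Group statistics.** Lilliefors normality gate; edgewise GLM
   `FC ~ group + age + sex` with Benjamini-Hochberg FDR per state;
   covariate-adjusted Mann-Whitney tests (OLS residualization, then
   the rank test) with FDR over the temporal-property family;
   regionwise GLM + FDR for V_k; ROC/AUC on the per-participant
   median strength of each state's significant edges; partial
   correlations (age, sex controlled) between dFC indicators and
   clinical scores (MMSE, NPI) in the patient group.

`docs/methods.md` documents the model assumptions, parameter
defaults, numerical choices and limitations.

## Worked example

The `analysis/` scripts run the full study on the default synthetic
cohort (20 patients + 20 controls, 60 regions, 135 time points, three
planted states, patients sticky in state 2 with three planted ±0.4
edge effects):

```sh
python analysis/01_simulate_cohort.py   # writes results/cohort/
python analysis/02_detect_states.py     # windows, exemplars, k, labels
python analysis/03_temporal_properties.py
python analysis/04_group_statistics.py
```

Output of a run (seed 2026):

```
40 participants x 126 windows = 5040 correlation matrices
exemplars: 682 (13.5% of windows)
chosen k = 3 (CH peak; Silhouette elbow k = 3)
window-label ARI vs planted states (4087 pure windows): 1.000

group mean dwell times (windows):
  control: {1: 77.5, 2: 25.8, 3: 22.7}, transitions 2.30
  patient: {1: 24.5, 2: 75.2, 3: 26.4}, transitions 2.70
  control: mean V over regions 0.644
  patient: mean V over regions 0.593

state 2: 3 FDR-significant edges of 1770 tested
significant temporal properties: ['dwell_1', 'dwell_2', 'freq_2to3']
regions with significant variability difference: 8 of 60
ROC state2_patient>control: AUC 0.947 (2 edges, 35 participants)
ROC state2_patient<control: AUC 0.905 (1 edges, 35 participants)
```

Reading this: the pipeline recovered the three planted states
exactly (ARI 1.0 over windows that do not straddle a state switch),
found the planted dwell-time contrast (patients occupy state 2 for
~75 of 126 windows vs ~26 for controls), flagged exactly the three
planted ±0.4 edges, measured lower temporal variability in the
"rigid" patient group, and the median strength of the significant
edges separates the groups well (AUC ≈ 0.9–0.95) — with the caveat,
inherited from the published procedure, that edge selection and
classification share the same sample.

The same pipeline is scriptable via the CLI (`dynfc simulate`,
`dynfc run`, `dynfc summarize`) or the library API
(`dynfc.pipeline.run_pipeline`).

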