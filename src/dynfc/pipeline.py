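"""End-to-end orchestration: cohort -> windows -> states -> metrics ->
variability -> group statistics -> report.

The stage functions (`window_cohort`, `detect_states`,
`compute_temporal_properties`, `temporal_property_tests`,
`variability_statistics`, `roc_analysis`, `clinical_partial_correlations`)
are plain library calls over in-memory objects; `run_pipeline` wires
them together around disk I/O for a single reproducible run directory,
and `summarize_run` condenses a finished run. Every random draw flows
from the run's master seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering, metrics, stats, synthetic, variability as var_mod
from .windows import RoiTimeSeries, WindowParams, WindowedFCSeries, load_roi_timeseries, sliding_window_fc

__all__ = [
    "RunConfig",
    "run_pipeline",
    "summarize_run",
    "window_cohort",
    "detect_states",
    "state_label_frame",
    "compute_state_fc",
    "compute_temporal_properties",
    "temporal_property_tests",
    "variability_table",
    "variability_statistics",
    "roc_analysis",
    "clinical_partial_correlations",
]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    mode: str = "synthetic"  # "synthetic" | "directory"
    input_dir: str | None = None  # directory mode: cohort location
    generator: synthetic.GeneratorConfig | None = None
    window_length: int = 10
    step: int = 1
    tr: float = 3.0
    k_min: int = 2
    k_max: int = 9
    replicates: int = 100
    threshold_sd: float = 1.5
    fixed_k: int | None = None  # skip model selection when set
    alpha: float = 0.05
    q: float = 0.05
    seed: int = 0
    out_dir: str = "results/run"

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "directory"):
            raise ValueError("mode must be 'synthetic' or 'directory'")
        if self.mode == "directory" and not self.input_dir:
            raise ValueError("directory mode requires input_dir")
        if self.mode == "synthetic" and self.generator is None:
            self.generator = synthetic.default_config(seed=self.seed)


# ---------------------------------------------------------------- stages


def window_cohort(
    series: dict[str, np.ndarray],
    params: WindowParams,
    tr: float = 3.0,
) -> dict[str, WindowedFCSeries]:
    """Sliding-window FC for every participant (in-memory signals)."""
    out = {}
    for pid, x in series.items():
        labels = [f"R{i + 1:03d}" for i in range(x.shape[1])]
        out[pid] = sliding_window_fc(RoiTimeSeries(pid, x, labels, tr=tr), params)
    return out


def load_cohort(directory, params: WindowParams, tr: float = 3.0):
    """Directory mode: manifest + per-participant TSVs -> windowed FC."""
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv")
    windows = {}
    for pid in manifest["id"]:
        ts = load_roi_timeseries(directory / f"{pid}.tsv", participant_id=pid, tr=tr)
        windows[pid] = sliding_window_fc(ts, params)
    return windows, manifest


def detect_states(
    windows: dict[str, WindowedFCSeries],
    k_min: int = 2,
    k_max: int = 9,
    replicates: int = 100,
    threshold_sd: float = 1.5,
    seed: int = 0,
    fixed_k: int | None = None,
):
    """Two-stage state detection.

    Exemplar subsampling, then either a full model-selection scan
    (k_min..k_max, best-of-replicates) or, with ``fixed_k``, replicated
    k-medians at that k only; the winning exemplar centroids initialize
    the deterministic final clustering of all windows.
    """
    exemplars = clustering.select_exemplars(windows, threshold_sd=threshold_sd)
    selection = None
    if fixed_k is None:
        selection = clustering.evaluate_k_range(
            exemplars.vectors, k_min=k_min, k_max=k_max,
            replicates=replicates, seed=seed,
        )
        k = selection.chosen_k
        centroids = selection.best_centroids[k]
    else:
        k = fixed_k
        ss = np.random.SeedSequence(seed)
        best = None
        for child in ss.spawn(replicates):
            rng = np.random.default_rng(child)
            labels, cent, cost, _ = clustering.kmedians_l1(exemplars.vectors, k, rng=rng)
            if best is None or cost < best[1]:
                best = (cent, cost)
        centroids = best[0]
    model = clustering.final_clustering(windows, centroids)
    return exemplars, selection, model


def state_label_frame(model: clustering.StateModel) -> pd.DataFrame:
    rows = []
    for pid, lab in model.labels.items():
        for w, s in enumerate(lab):
            rows.append((pid, w, int(s)))
    return pd.DataFrame(rows, columns=["participant", "window_index", "state"])


def compute_state_fc(
    windows: dict[str, WindowedFCSeries], model: clustering.StateModel
) -> dict[str, metrics.ParticipantStateFC]:
    return {
        pid: metrics.participant_state_fc(windows[pid], model.labels[pid], model.k)
        for pid in windows
    }


def compute_temporal_properties(
    model: clustering.StateModel, manifest: pd.DataFrame
) -> pd.DataFrame:
    """Per-participant dwell times, transition count, and flattened
    transition frequencies, joined with group/covariates."""
    k = model.k
    rows = []
    man = manifest.set_index("id")
    for pid, lab in model.labels.items():
        tp = metrics.temporal_properties(pid, lab, k)
        row = {"id": pid, "group": man.loc[pid, "group"],
               "age": man.loc[pid, "age"], "sex": man.loc[pid, "sex"]}
        for s in range(1, k + 1):
            row[f"dwell_{s}"] = tp.dwell[s]
        row["transitions"] = tp.transitions
        for a in range(1, k + 1):
            for b in range(1, k + 1):
                if a != b:
                    row[f"freq_{a}to{b}"] = tp.frequencies[a - 1, b - 1]
        rows.append(row)
    return pd.DataFrame(rows)


def temporal_property_tests(
    props: pd.DataFrame, q: float = 0.05
) -> pd.DataFrame:
    """Covariate-adjusted Mann-Whitney per temporal property, FDR over
    the whole property family (dwell times + transition count +
    transition frequencies)."""
    cov = stats.encode_covariates(props)
    g = props["group"].to_numpy()
    names = [c for c in props.columns
             if c.startswith(("dwell_", "freq_")) or c == "transitions"]
    rows = []
    for name in names:
        u, p = stats.adjusted_rank_test(props[name].to_numpy(float), g, cov)
        pat = props.loc[props["group"] == "patient", name].mean()
        con = props.loc[props["group"] == "control", name].mean()
        rows.append({"property": name, "patient_mean": pat, "control_mean": con,
                     "U": u, "p": p})
    out = pd.DataFrame(rows)
    out["p_fdr"], out["significant"] = stats.bh_fdr(out["p"].to_numpy(), q=q)
    return out


def variability_table(
    windows: dict[str, WindowedFCSeries], manifest: pd.DataFrame
) -> tuple[pd.DataFrame, dict[str, list[bool]]]:
    """Per-participant V_k row per region + validity masks."""
    man = manifest.set_index("id")
    rows, masks = [], {}
    for pid, w in windows.items():
        prof = var_mod.temporal_variability(w)
        row = {"id": pid, "group": man.loc[pid, "group"],
               "age": man.loc[pid, "age"], "sex": man.loc[pid, "sex"]}
        for k, label in enumerate(w.region_labels):
            row[label] = prof.v[k]
        rows.append(row)
        masks[pid] = prof.valid.tolist()
    return pd.DataFrame(rows), masks


def variability_statistics(vtab: pd.DataFrame, q: float = 0.05) -> pd.DataFrame:
    """Regionwise GLM (V ~ group + age + sex), FDR over regions."""
    regions = [c for c in vtab.columns if c not in ("id", "group", "age", "sex")]
    cov = stats.encode_covariates(vtab)
    g = (vtab["group"] == "patient").to_numpy(float)
    Y = vtab[regions].to_numpy(float)
    ok = ~np.isnan(Y).any(axis=0)
    beta, t, p = stats._group_t_ols(Y[:, ok], g, cov)
    p_fdr, reject = stats.bh_fdr(p, q=q)
    out = pd.DataFrame({
        "region": np.asarray(regions)[ok],
        "beta": beta, "t": t, "p": p, "p_fdr": p_fdr, "significant": reject,
        "direction": np.where(beta > 0, "patient>control", "patient<control"),
    })
    return out


def roc_analysis(
    state_fc: dict[str, metrics.ParticipantStateFC],
    edge_tables: dict[int, pd.DataFrame | None],
    manifest: pd.DataFrame,
) -> tuple[dict, dict[int, dict[str, pd.Series]]]:
    """AUC per state x direction on the median strength of the state's
    significant edges; orientation chosen so AUC >= 0.5 and reported."""
    man = manifest.set_index("id")
    results: dict = {}
    scores: dict[int, dict[str, pd.Series]] = {}
    for state, tab in edge_tables.items():
        if tab is None:
            continue
        sig = tab[tab["significant"]]
        for direction, dtab in sig.groupby("direction"):
            edges = dtab[["i", "j"]].to_numpy()
            med = stats.median_significant_strength(state_fc, edges, state)
            labels = (man.loc[med.index, "group"] == "patient").to_numpy()
            if labels.all() or not labels.any():
                continue
            auc = stats.roc_auc(med.to_numpy(), labels)
            oriented = max(auc, 1 - auc)
            results[f"state{state}_{direction}"] = {
                "auc": oriented,
                "orientation": "patient_high" if auc >= 0.5 else "patient_low",
                "n_edges": int(len(dtab)),
                "n_participants": int(len(med)),
            }
            scores.setdefault(state, {})[direction] = med
    return results, scores


def clinical_partial_correlations(
    props: pd.DataFrame,
    vtab: pd.DataFrame,
    var_stats: pd.DataFrame,
    roc_scores: dict[int, dict[str, pd.Series]],
    manifest: pd.DataFrame,
    clinical: tuple[str, ...] = ("MMSE", "NPI"),
) -> pd.DataFrame:
    """Partial correlations (age, sex controlled) between clinical
    scores and dFC indicators, within the patient group."""
    man = manifest.set_index("id")
    patients = man[man["group"] == "patient"]
    indicators: dict[str, pd.Series] = {}
    for state, by_dir in roc_scores.items():
        for direction, med in by_dir.items():
            tag = "increased" if direction == "patient>control" else "decreased"
            indicators[f"median_strength_state{state}_{tag}"] = med
    p_idx = props.set_index("id")
    for c in p_idx.columns:
        if c.startswith(("dwell_", "freq_")) or c == "transitions":
            indicators[c] = p_idx[c]
    sig_regions = var_stats.loc[var_stats["significant"], "region"].tolist()
    v_idx = vtab.set_index("id")
    for r in sig_regions:
        indicators[f"V_{r}"] = v_idx[r]
    rows = []
    for name, series in indicators.items():
        common = series.index.intersection(patients.index)
        for score in clinical:
            sub = patients.loc[common]
            y = pd.to_numeric(sub[score], errors="coerce")
            keep = y.notna() & series.loc[common].notna()
            n = int(keep.sum())
            if n < 5:
                continue
            cov = stats.encode_covariates(sub[keep].reset_index())
            r, p = stats.partial_correlation(
                series.loc[common][keep].to_numpy(float), y[keep].to_numpy(float), cov
            )
            rows.append({"indicator": name, "clinical": score, "r": r, "p": p, "n": n})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------- driver


def _write_float_table(df: pd.DataFrame, path: Path, sep: str = "\t") -> None:
    df.to_csv(path, sep=sep, index=False, float_format="%.10g")


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full analysis and write the run directory.

    Identical config + seed produce identical numeric outputs. Any
    stage failure aborts with the stage named; earlier artifacts are
    retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    stage = "setup"
    warnings_seen: list[str] = []
    try:
        params = WindowParams(config.window_length, config.step)
        stage = "input"
        if config.mode == "synthetic":
            cohort_dir, _truth = synthetic.generate_cohort(config.generator, out / "cohort")
            windows, manifest = load_cohort(cohort_dir, params, tr=config.tr)
        else:
            windows, manifest = load_cohort(config.input_dir, params, tr=config.tr)
        logger.info("input: %d participants, %d windows each (%.1fs)",
                    len(windows), next(iter(windows.values())).n_windows, time.time() - t0)
        for w in windows.values():
            if w.zero_variance:
                warnings_seen.append(
                    f"{w.participant_id}: zero-variance segments {w.zero_variance[:5]}")

        stage = "state detection"
        exemplars, selection, model = detect_states(
            windows, config.k_min, config.k_max, config.replicates,
            config.threshold_sd, config.seed, config.fixed_k,
        )
        for s in range(model.k):
            np.savetxt(
                out / f"centroid_state{s + 1}.tsv",
                _devec(model.centroids[s]), delimiter="\t", fmt="%.10g",
            )
        _write_float_table(state_label_frame(model), out / "labels.csv", sep=",")
        sel_json = {
            "chosen_k": model.k,
            "n_exemplars": exemplars.n_exemplars,
            "threshold_sd": config.threshold_sd,
            "seed": config.seed,
        }
        if selection is not None:
            sel_json.update({
                "k_range": selection.k_range,
                "silhouette": selection.silhouette,
                "calinski_harabasz": selection.calinski_harabasz,
                "best_cost": selection.best_cost,
                "silhouette_elbow_k": selection.silhouette_elbow_k,
                "replicates": selection.replicates,
                "notes": selection.notes,
            })
            warnings_seen.extend(selection.notes)
        with open(out / "model_selection.json", "w") as fh:
            json.dump(sel_json, fh, indent=1, default=float)

        stage = "state metrics"
        state_fc = compute_state_fc(windows, model)
        absent = {pid: [s for s in range(1, model.k + 1)
                        if state_fc[pid].matrices[s] is None] for pid in state_fc}
        absent = {p: a for p, a in absent.items() if a}
        if absent:
            warnings_seen.append(f"absent states: {absent}")
        props = compute_temporal_properties(model, manifest)
        _write_float_table(props, out / "temporal_properties.csv", sep=",")

        stage = "temporal variability"
        vtab, masks = variability_table(windows, manifest)
        _write_float_table(vtab, out / "variability.csv", sep=",")
        with open(out / "variability_validity.json", "w") as fh:
            json.dump(masks, fh)

        stage = "group statistics"
        edge_tables: dict[int, pd.DataFrame | None] = {}
        for s in range(1, model.k + 1):
            tab = stats.edgewise_glm(state_fc, manifest, s, q=config.q)
            edge_tables[s] = tab
            if tab is not None:
                _write_float_table(tab, out / f"edges_state{s}.tsv")
            else:
                warnings_seen.append(f"state {s} skipped in edgewise GLM (too rare)")
        ttests = temporal_property_tests(props, q=config.q)
        _write_float_table(ttests, out / "temporal_stats.tsv")
        vstats = variability_statistics(vtab, q=config.q)
        _write_float_table(vstats, out / "variability_stats.tsv")
        roc, roc_scores = roc_analysis(state_fc, edge_tables, manifest)
        with open(out / "roc.json", "w") as fh:
            json.dump(roc, fh, indent=1, default=float)
        pcorr = clinical_partial_correlations(
            props, vtab, vstats, roc_scores, manifest)
        _write_float_table(pcorr, out / "partialcorr.tsv")
        demo = stats.demographics_table(manifest)
        _write_float_table(demo, out / "demographics.tsv")

        stage = "summary"
        summary = {
            "chosen_k": model.k,
            "n_participants": int(len(manifest)),
            "windows_per_participant": int(next(iter(windows.values())).n_windows),
            "total_windows": int(sum(w.n_windows for w in windows.values())),
            "n_exemplars": exemplars.n_exemplars,
            "final_cost": model.cost,
            "group_dwell_means": {
                g: {f"state{s}": float(props.loc[props["group"] == g, f"dwell_{s}"].mean())
                    for s in range(1, model.k + 1)}
                for g in ("control", "patient")
            },
            "group_transition_means": {
                g: float(props.loc[props["group"] == g, "transitions"].mean())
                for g in ("control", "patient")
            },
            "significant_edges": {
                f"state{s}": int(t["significant"].sum()) if t is not None else None
                for s, t in edge_tables.items()
            },
            "significant_temporal_properties":
                ttests.loc[ttests["significant"], "property"].tolist(),
            "significant_variability_regions": int(vstats["significant"].sum()),
            "roc": roc,
            "warnings": warnings_seen,
            "elapsed_seconds": round(time.time() - t0, 2),
        }
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=1, default=float)
        cfg_echo = {k: v for k, v in vars(config).items() if k != "generator"}
        if config.generator is not None:
            gen = {k: v for k, v in vars(config.generator).items()
                   if k not in ("module_partition", "transition_matrix")}
            cfg_echo["generator"] = gen
        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(cfg_echo, default=str)), fh)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc
    return out


def _devec(vector: np.ndarray) -> np.ndarray:
    from .windows import devectorize_upper

    return devectorize_upper(vector)


REQUIRED_ARTIFACTS = [
    "labels.csv", "model_selection.json", "temporal_properties.csv",
    "variability.csv", "temporal_stats.tsv", "variability_stats.tsv",
    "roc.json", "summary.json", "config.yaml",
]


def summarize_run(run_dir) -> dict:
    """Condense a finished run; lists missing artifacts if incomplete."""
    run_dir = Path(run_dir)
    missing = [f for f in REQUIRED_ARTIFACTS if not (run_dir / f).exists()]
    if missing:
        return {"complete": False, "missing": missing}
    with open(run_dir / "summary.json") as fh:
        summary = json.load(fh)
    summary["complete"] = True
    return summary
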