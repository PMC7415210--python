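"""Synthetic state-switching cohort generator.

Emulates a resting-state fMRI cohort at the ROI-time-series level: each
participant's signal is drawn from a small set of latent connectivity
states with distinct correlation structure (seeded low-rank factor
models by default, module-block designs optionally), switching
according to a first-order Markov chain at time-point resolution.
Patients and controls can differ in specific edges within a state, in
state stickiness (dwell/transition structure), and consequently in
nodal temporal variability. States differ by correlation structure
only — all means are zero — because windowed Pearson correlation is
mean-invariant. Observations are temporally independent given the
state.

Ground truth (state sequences, per-group state correlation matrices,
group labels) is returned alongside the written cohort so every
downstream stage can be validated without external data.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GeneratorConfig",
    "CohortTruth",
    "build_state_correlation",
    "build_factor_state_correlation",
    "nearest_psd_correlation",
    "sample_state_sequence",
    "generate_cohort",
    "generate_cohort_arrays",
    "default_config",
]

GROUPS = ("control", "patient")


def _default_partitions(n_regions: int, n_states: int, n_modules: int = 4) -> list[np.ndarray]:
    """Per-state module assignments: block partition rotated per state.

    Rotating the assignment shifts module boundaries so states differ in
    structure, not just in correlation level.
    """
    size = int(np.ceil(n_regions / n_modules))
    base = np.arange(n_regions) // size
    out = []
    for s in range(n_states):
        shift = s * max(1, size // 3)
        out.append(((np.arange(n_regions) + shift) // size) % n_modules)
    return out


@dataclass
class GeneratorConfig:
    """Cohort-generation parameters with ground-truth group effects.

    Defaults describe a well-separated three-state design at the scale
    of a typical single-site resting-state study: 20 participants per
    group, 60 regions, 135 time points (140 volumes with the first 5
    discarded, TR = 3 s). Each state's correlation matrix comes from a
    fixed-seed random 4-factor model; strength scales (0.9, 1.0, 1.1)
    order the states so state 1 is the weakest-connectivity "baseline"
    state while separation is carried by structure, not strength.
    Patients dwell longer in state 2, transition more often overall,
    and carry edge-level offsets (``patient_edge_effects``) in state 2
    — mirroring the patient-vs-control contrasts the analysis pipeline
    is meant to detect.
    """

    n_per_group: int = 20
    n_regions: int = 60
    n_timepoints: int = 135
    n_states: int = 3
    tr: float = 3.0
    # state construction: "factor" draws each state's correlation from a
    # fixed-seed random low-rank factor model (several loading directions,
    # no single dominant axis); "block" uses module_partition with
    # within_r/between_r levels
    state_style: str = "factor"
    n_factors: int = 4
    factor_idio: float = 0.15  # idiosyncratic variance share per factor
    state_scales: tuple[float, ...] = (0.9, 1.0, 1.1)  # overall-strength order
    state_seeds: tuple[int, ...] = (202, 303, 404)  # structure constants
    # block mode: one assignment array per state (or a single shared array)
    module_partition: list[np.ndarray] | None = None
    within_r: tuple[float, ...] = (0.15, 0.5, 0.75)
    between_r: tuple[float, ...] = (0.0, 0.1, 0.15)
    # row-stochastic (n_states x n_states) per group
    transition_matrix: dict[str, np.ndarray] | None = None
    # (region_i, region_j, state_label, delta_r) applied to the patient
    # group; None resolves to three +-0.4 effects on near-zero-baseline
    # state-2 edges (which survive PSD projection mostly intact), or to
    # no effects when the region count cannot accommodate them
    patient_edge_effects: list[tuple[int, int, int, float]] | None = None
    observation_noise_sd: float = 0.1
    # demographics: mean/sd per group, Table-style cohort description
    age_mean_sd: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"control": (75.7, 6.2), "patient": (74.6, 6.5)}
    )
    mmse_mean_sd: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"control": (29.04, 1.33), "patient": (21.18, 3.2)}
    )
    npi_mean_sd: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"control": (0.71, 1.31), "patient": (4.59, 3.92)}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.state_style not in ("factor", "block"):
            raise ValueError("state_style must be 'factor' or 'block'")
        if self.state_style == "factor":
            if len(self.state_scales) < self.n_states:
                raise ValueError("need one state_scales entry per state")
            if len(self.state_seeds) < self.n_states:
                self.state_seeds = tuple(
                    101 * (s + 2) for s in range(self.n_states)
                )
        if self.module_partition is None:
            self.module_partition = _default_partitions(self.n_regions, self.n_states)
        elif isinstance(self.module_partition, np.ndarray):
            self.module_partition = [self.module_partition] * self.n_states
        if self.state_style == "block":
            if len(self.within_r) != self.n_states or len(self.between_r) != self.n_states:
                raise ValueError("need one within_r/between_r level per state")
            for r in (*self.within_r, *self.between_r):
                if not -1 < r < 1:
                    raise ValueError(f"target correlation {r} outside (-1, 1)")
        if self.transition_matrix is None:
            if self.n_states == 3:
                self.transition_matrix = default_transition_matrices()
            else:
                self.transition_matrix = {
                    g: _generic_sticky_chain(self.n_states) for g in GROUPS
                }
        for g, P in self.transition_matrix.items():
            P = np.asarray(P, float)
            if P.shape != (self.n_states, self.n_states):
                raise ValueError(f"transition matrix for {g} has wrong shape")
            if np.max(np.abs(P.sum(axis=1) - 1)) > 1e-12:
                raise ValueError(f"transition matrix rows for {g} do not sum to 1")
            self.transition_matrix[g] = P
        if self.observation_noise_sd < 0:
            raise ValueError("observation_noise_sd must be nonnegative")
        if self.patient_edge_effects is None:
            if self.n_regions >= 58 and self.n_states >= 2:
                self.patient_edge_effects = [
                    (17, 42, 2, 0.4), (48, 57, 2, 0.4), (35, 36, 2, -0.4)
                ]
            else:
                self.patient_edge_effects = []
        for i, j, s, dr in self.patient_edge_effects:
            if not (0 <= i < self.n_regions and 0 <= j < self.n_regions and i != j):
                raise ValueError(f"edge effect references absent edge ({i},{j})")
            if not 1 <= s <= self.n_states:
                raise ValueError(f"edge effect references absent state {s}")


def _generic_sticky_chain(k: int, stay: float = 0.95) -> np.ndarray:
    P = np.full((k, k), (1 - stay) / (k - 1))
    np.fill_diagonal(P, stay)
    return P


def default_transition_matrices() -> dict[str, np.ndarray]:
    """Group Markov chains: controls dwell mostly in state 1, patients
    stick in state 2 and transition more often overall."""
    control = np.array(
        [
            [0.985, 0.010, 0.005],
            [0.020, 0.970, 0.010],
            [0.015, 0.010, 0.975],
        ]
    )
    patient = np.array(
        [
            [0.950, 0.040, 0.010],
            [0.008, 0.980, 0.012],
            [0.025, 0.025, 0.950],
        ]
    )
    return {"control": control, "patient": patient}


def default_config(**overrides) -> GeneratorConfig:
    return GeneratorConfig(**overrides)


@dataclass
class CohortTruth:
    """Planted ground truth for a generated cohort."""

    state_sequences: dict[str, np.ndarray]  # participant id -> (T,) labels in 1..k
    state_correlations: dict[str, list[np.ndarray]]  # group -> [k matrices]
    group: dict[str, str]  # participant id -> group
    config: GeneratorConfig


def nearest_psd_correlation(matrix: np.ndarray, eig_floor: float = 1e-8) -> np.ndarray:
    """Project to a nearby PSD correlation matrix.

    Eigenvalue clipping at ``eig_floor`` followed by diagonal rescaling
    to 1 — the standard nearest-correlation shortcut, adequate for block
    designs. Raises if the result is still indefinite.
    """
    m = (matrix + matrix.T) / 2
    w, v = np.linalg.eigh(m)
    if w.min() >= eig_floor:
        out = m
    else:
        w = np.clip(w, eig_floor, None)
        out = (v * w) @ v.T
        d = np.sqrt(np.diag(out))
        out = out / np.outer(d, d)
        out = (out + out.T) / 2
        np.fill_diagonal(out, 1.0)
    wmin = float(np.linalg.eigvalsh(out).min())
    if wmin < -1e-10:
        raise ValueError(
            f"correlation targets infeasible: smallest eigenvalue {wmin:.3e} "
            "after PSD projection"
        )
    return out


def build_state_correlation(
    module_partition: np.ndarray,
    within_r: float,
    between_r: float,
) -> np.ndarray:
    """Block correlation matrix: ``within_r`` inside a module,
    ``between_r`` across modules, unit diagonal, PSD-repaired."""
    for r in (within_r, between_r):
        if not -1 < r < 1:
            raise ValueError(f"target correlation {r} outside (-1, 1)")
    part = np.asarray(module_partition)
    same = part[:, None] == part[None, :]
    c = np.where(same, within_r, between_r).astype(float)
    np.fill_diagonal(c, 1.0)
    return nearest_psd_correlation(c)


def build_factor_state_correlation(
    n_regions: int,
    n_factors: int = 4,
    idio: float = 0.15,
    scale: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """State correlation from a seeded random low-rank factor model.

    C is the correlation of ``L z + e`` with L an (n_regions x
    n_factors) standard-normal loading matrix and idiosyncratic
    variance ``idio * n_factors`` per region, then off-diagonals scaled
    by ``scale`` (overall connectivity strength) and PSD-repaired.
    Several comparable loading directions avoid the single dominant
    axis of an equicorrelated block design, whose common-factor
    sampling error elongates short-window FC estimates along one
    direction.
    """
    rng = np.random.default_rng(seed)
    L = rng.standard_normal((n_regions, n_factors))
    C = L @ L.T + idio * n_factors * np.eye(n_regions)
    d = np.sqrt(np.diag(C))
    C = C / np.outer(d, d)
    C = C * scale
    np.fill_diagonal(C, 1.0)
    return nearest_psd_correlation(C)


def sample_state_sequence(
    transition_matrix: np.ndarray,
    n_timepoints: int,
    initial_distribution: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """First-order Markov chain sample; labels 1..k."""
    P = np.asarray(transition_matrix, float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("transition matrix must be square")
    if np.max(np.abs(P.sum(axis=1) - 1)) > 1e-12 or (P < 0).any():
        raise ValueError("transition matrix rows must be nonnegative and sum to 1")
    k = P.shape[0]
    if rng is None:
        rng = np.random.default_rng()
    if initial_distribution is None:
        pi = stationary_distribution(P)
    else:
        pi = np.asarray(initial_distribution, float)
        if abs(pi.sum() - 1) > 1e-12 or (pi < 0).any():
            raise ValueError("initial distribution must be a probability vector")
    seq = np.empty(n_timepoints, dtype=int)
    cum0 = np.cumsum(pi)
    cumP = np.cumsum(P, axis=1)
    u = rng.random(n_timepoints)
    seq[0] = np.searchsorted(cum0, u[0])
    for t in range(1, n_timepoints):
        seq[t] = np.searchsorted(cumP[seq[t - 1]], u[t])
    return seq + 1  # 1-based state labels


def stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (left Perron vector)."""
    w, v = np.linalg.eig(P.T)
    i = int(np.argmin(np.abs(w - 1)))
    pi = np.real(v[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def psd_with_fixed_entries(
    matrix: np.ndarray,
    fixed: list[tuple[int, int, float]],
    max_iter: int = 500,
    eig_floor: float = 1e-8,
) -> np.ndarray:
    """Nearest-ish PSD correlation matrix with prescribed entries.

    Alternating projections between the PSD cone (eigenvalue clipping)
    and the affine set {unit diagonal, fixed (i, j) entries}; keeps the
    planted values exact instead of letting a single global projection
    erode them. Raises if the constraints cannot be met.
    """
    M = (matrix + matrix.T) / 2
    for i, j, v in fixed:
        M[i, j] = M[j, i] = v
    for _ in range(max_iter):
        w, v_ = np.linalg.eigh(M)
        if w.min() >= -1e-12:
            break
        M = (v_ * np.clip(w, eig_floor, None)) @ v_.T
        np.fill_diagonal(M, 1.0)
        for i, j, val in fixed:
            M[i, j] = M[j, i] = val
        M = (M + M.T) / 2
    wmin = float(np.linalg.eigvalsh(M).min())
    if wmin < -1e-6:
        raise ValueError(
            f"planted entries infeasible: smallest eigenvalue {wmin:.3e} "
            "after alternating projections"
        )
    if wmin < eig_floor:  # final touch-up, preserving entries to ~1e-8
        M = M + (eig_floor - min(wmin, 0.0)) * np.eye(M.shape[0])
        d = np.sqrt(np.diag(M))
        M = M / np.outer(d, d)
        np.fill_diagonal(M, 1.0)
    return M


def _truth_matrices(config: GeneratorConfig) -> dict[str, list[np.ndarray]]:
    if config.state_style == "factor":
        base = [
            build_factor_state_correlation(
                config.n_regions,
                config.n_factors,
                config.factor_idio,
                config.state_scales[s],
                config.state_seeds[s],
            )
            for s in range(config.n_states)
        ]
    else:
        base = [
            build_state_correlation(
                config.module_partition[s], config.within_r[s], config.between_r[s]
            )
            for s in range(config.n_states)
        ]
    truth = {"control": base, "patient": [m.copy() for m in base]}
    by_state: dict[int, list[tuple[int, int, float]]] = {}
    for i, j, s, dr in config.patient_edge_effects:
        base_val = truth["patient"][s - 1][i, j]
        by_state.setdefault(s, []).append(
            (i, j, float(np.clip(base_val + dr, -0.99, 0.99)))
        )
    for s, fixed in by_state.items():
        truth["patient"][s - 1] = psd_with_fixed_entries(
            truth["patient"][s - 1], fixed
        )
    return truth


def _participant_ids(config: GeneratorConfig) -> list[tuple[str, str]]:
    ids = []
    for g, tag in (("control", "HC"), ("patient", "AD")):
        for i in range(config.n_per_group):
            ids.append((f"sub-{tag}{i + 1:03d}", g))
    return ids


def generate_cohort_arrays(
    config: GeneratorConfig,
) -> tuple[dict[str, np.ndarray], CohortTruth, pd.DataFrame]:
    """In-memory cohort: {participant id: (T, p) signal}, truth, manifest.

    Per participant: sample a state sequence from the group's chain,
    then at each time point draw from a zero-mean multivariate normal
    with the current state's (group-specific) correlation, plus white
    observation noise.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    truth_mats = _truth_matrices(config)
    chol = {
        g: [np.linalg.cholesky(m + 1e-10 * np.eye(config.n_regions)) for m in ms]
        for g, ms in truth_mats.items()
    }
    series: dict[str, np.ndarray] = {}
    sequences: dict[str, np.ndarray] = {}
    group_of: dict[str, str] = {}
    rows = []
    for pid, g in _participant_ids(config):
        seq = sample_state_sequence(
            config.transition_matrix[g], config.n_timepoints, rng=rng
        )
        eps = rng.standard_normal((config.n_timepoints, config.n_regions))
        x = np.empty_like(eps)
        for s in range(1, config.n_states + 1):
            idx = np.flatnonzero(seq == s)
            if idx.size:
                x[idx] = eps[idx] @ chol[g][s - 1].T
        if config.observation_noise_sd > 0:
            x = x + config.observation_noise_sd * rng.standard_normal(x.shape)
        series[pid] = x
        sequences[pid] = seq
        group_of[pid] = g
        age_m, age_s = config.age_mean_sd[g]
        mmse_m, mmse_s = config.mmse_mean_sd[g]
        npi_m, npi_s = config.npi_mean_sd[g]
        rows.append(
            {
                "id": pid,
                "group": g,
                "age": round(float(np.clip(rng.normal(age_m, age_s), 55, 95)), 1),
                "sex": "M" if rng.random() < 0.5 else "F",
                "MMSE": round(float(np.clip(rng.normal(mmse_m, mmse_s), 0, 30)), 0),
                "NPI": round(float(np.clip(rng.normal(npi_m, npi_s), 0, 30)), 1),
            }
        )
    manifest = pd.DataFrame(rows)
    truth = CohortTruth(sequences, truth_mats, group_of, config)
    return series, truth, manifest


def generate_cohort(config: GeneratorConfig, out_dir) -> tuple[Path, CohortTruth]:
    """Write a cohort to disk: one TSV per participant (time x regions,
    header R001..), manifest.csv, truth.json. Same seed, same bytes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    series, truth, manifest = generate_cohort_arrays(config)
    labels = [f"R{i + 1:03d}" for i in range(config.n_regions)]
    for pid, x in series.items():
        df = pd.DataFrame(x, columns=labels)
        df.to_csv(out / f"{pid}.tsv", sep="\t", index=False)
    manifest.to_csv(out / "manifest.csv", index=False)
    cfg = dataclasses.asdict(config)
    cfg["module_partition"] = [np.asarray(p).tolist() for p in config.module_partition]
    cfg["transition_matrix"] = {
        g: np.asarray(P).tolist() for g, P in config.transition_matrix.items()
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(
            {
                "config": cfg,
                "state_sequences": {
                    pid: seq.tolist() for pid, seq in truth.state_sequences.items()
                },
                "group": truth.group,
            },
            fh,
            indent=1,
        )
    return out, truth


def cohort_hash(directory) -> str:
    """SHA-256 over all cohort files, for determinism checks."""
    h = hashlib.sha256()
    for p in sorted(Path(directory).iterdir()):
        if p.is_file():
            h.update(p.name.encode())
            h.update(p.read_bytes())
    return h.hexdigest()


def load_truth(directory) -> tuple[dict[str, np.ndarray], dict[str, str]]:
    """Read back state sequences and group labels from truth.json."""
    with open(Path(directory) / "truth.json") as fh:
        d = json.load(fh)
    seqs = {pid: np.asarray(v, int) for pid, v in d["state_sequences"].items()}
    return seqs, d["group"]
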