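"""Detection of reoccurring FC states by two-stage L1 k-means.

Stage one subsamples "exemplar" windows — those whose edge-vector
L1-norm deviates from the L1-norm of the participant's mean matrix by
more than 1.5 SD of that participant's window L1-norms — and clusters
them repeatedly over a range of k to select the number of states
(Calinski-Harabasz peak, cross-checked by the Silhouette elbow). Stage
two clusters *all* windows once, initialized at the exemplar-stage
centroids.

"k-means with L1 distances" is realized as k-medians: assignment by
cityblock distance, centroid update by the element-wise median (the L1
centroid). States are relabeled by ascending mean absolute centroid
connectivity so that state 1 is always the weakest-connectivity
"baseline" state.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.metrics import calinski_harabasz_score, silhouette_score

from .windows import WindowedFCSeries

__all__ = [
    "ExemplarSet",
    "ModelSelection",
    "StateModel",
    "select_exemplars",
    "kmedians_l1",
    "evaluate_k_range",
    "choose_k",
    "final_clustering",
]

logger = logging.getLogger(__name__)


@dataclass
class ExemplarSet:
    participant_ids: list[str]
    indices: dict[str, np.ndarray]  # participant -> selected window indices
    vectors: np.ndarray  # stacked edge-vectors of selected windows
    threshold_sd: float = 1.5

    @property
    def n_exemplars(self) -> int:
        return self.vectors.shape[0]


@dataclass
class ModelSelection:
    k_range: list[int]
    silhouette: dict[int, float]
    calinski_harabasz: dict[int, float]
    best_cost: dict[int, float]
    best_centroids: dict[int, np.ndarray]
    chosen_k: int
    silhouette_elbow_k: int | None
    replicates: int
    seed: int
    notes: list[str] = field(default_factory=list)


@dataclass
class StateModel:
    centroids: np.ndarray  # (k, n_edges), state s -> row s-1
    labels: dict[str, np.ndarray]  # participant -> per-window labels in 1..k
    cost: float
    n_iter: int

    @property
    def k(self) -> int:
        return self.centroids.shape[0]

    def stacked_labels(self) -> np.ndarray:
        return np.concatenate([self.labels[p] for p in self.labels])


def select_exemplars(
    windows: dict[str, WindowedFCSeries],
    threshold_sd: float = 1.5,
    center: str = "mean_norm",
) -> ExemplarSet:
    """High-variance window subsampling, per participant.

    For participant windows with edge-vector L1-norms ``l_i``, select
    windows with ``|l_i - m| > threshold_sd * SD(l)``. Deviation is
    two-sided; SD is the participant's own (ddof=1). L1 norms are over
    unique off-diagonal edges.

    ``center`` picks the reference ``m``: ``"mean_norm"`` (default)
    uses the mean of the window L1-norms, which at 1.5 SD selects the
    expected ~13% tail of windows; ``"norm_of_mean"`` uses the L1-norm
    of the across-window mean matrix. The two differ because averaging
    cancels sign-fluctuating noise on weak edges, deflating the mean
    matrix's norm below every window's norm and making the selection
    degenerate (nearly all windows) for noisy data; the default keeps
    the rule a genuine high-variance tail filter.
    """
    if center not in ("mean_norm", "norm_of_mean"):
        raise ValueError("center must be 'mean_norm' or 'norm_of_mean'")
    ids, idx, vecs = [], {}, []
    for pid, w in windows.items():
        ev = w.edge_vectors()
        if ev.shape[0] < 2:
            raise ValueError(f"{pid}: need at least 2 windows for exemplar selection")
        l = np.abs(ev).sum(axis=1)
        if center == "mean_norm":
            m = float(l.mean())
        else:
            m = float(np.abs(ev.mean(axis=0)).sum())
        s = float(l.std(ddof=1))
        if s == 0:
            warnings.warn(f"{pid}: all windows identical, no exemplars selected")
            sel = np.array([], dtype=int)
        else:
            sel = np.flatnonzero(np.abs(l - m) > threshold_sd * s)
        ids.append(pid)
        idx[pid] = sel
        if sel.size:
            vecs.append(ev[sel])
    stacked = np.vstack(vecs) if vecs else np.empty((0, 0))
    return ExemplarSet(ids, idx, stacked, threshold_sd)


def kmedians_l1(
    vectors: np.ndarray,
    k: int,
    init_centroids: np.ndarray | None = None,
    max_iter: int = 300,
    tol: float = 1e-8,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, float, int]:
    """Lloyd-style k-medians under cityblock distance.

    Alternates assignment to the L1-nearest centroid (ties to the
    lowest centroid index) with element-wise-median centroid updates;
    stops when labels stabilize, the cost decrease falls below ``tol``,
    or ``max_iter`` is reached. The cost Σ_i L1(x_i, c_{label(i)}) is
    non-increasing across iterations. An emptied cluster is re-seeded
    at the vector farthest (L1) from its previous centroid.

    Returns (labels 0-based, centroids, cost, n_iter).
    """
    X = np.asarray(vectors, float)
    n = X.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds number of vectors {n}")
    if init_centroids is None:
        if rng is None:
            rng = np.random.default_rng()
        # sample k distinct rows; retry a few times if duplicates collapse
        uniq = np.unique(X, axis=0)
        if uniq.shape[0] < k:
            raise ValueError(f"k={k} exceeds number of distinct vectors {uniq.shape[0]}")
        centroids = uniq[rng.choice(uniq.shape[0], size=k, replace=False)].copy()
    else:
        centroids = np.array(init_centroids, float, copy=True)
        if centroids.shape[0] != k:
            raise ValueError("init_centroids row count must equal k")
    labels = np.full(n, -1)
    prev_cost = np.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        d = cdist(X, centroids, metric="cityblock")
        new_labels = d.argmin(axis=1)  # argmin takes the lowest index on ties
        for c in range(k):
            if not np.any(new_labels == c):
                far = int(d[:, c].argmax())
                logger.info("cluster %d emptied; re-seeded at farthest vector %d", c, far)
                centroids[c] = X[far]
                d[:, c] = cdist(X, centroids[c : c + 1], metric="cityblock")[:, 0]
                new_labels = d.argmin(axis=1)
        cost = float(d[np.arange(n), new_labels].sum())
        if (
            np.array_equal(new_labels, labels)
            or prev_cost - cost < tol
            or cost == 0.0
        ):
            labels = new_labels
            break
        labels = new_labels
        prev_cost = cost
        for c in range(k):
            centroids[c] = np.median(X[labels == c], axis=0)
    d = cdist(X, centroids, metric="cityblock")
    labels = d.argmin(axis=1)
    cost = float(d[np.arange(n), labels].sum())
    return labels, centroids, cost, n_iter


def evaluate_k_range(
    exemplar_vectors: np.ndarray,
    k_min: int = 2,
    k_max: int = 9,
    replicates: int = 100,
    seed: int = 0,
) -> ModelSelection:
    """Scan k, best-of-replicates by cost, scored by Silhouette
    (cityblock) and Calinski-Harabasz."""
    X = np.asarray(exemplar_vectors, float)
    n_distinct = np.unique(X, axis=0).shape[0]
    notes: list[str] = []
    if k_max > n_distinct:
        warnings.warn(
            f"k_max={k_max} exceeds {n_distinct} distinct exemplars; truncating"
        )
        notes.append(f"k range truncated to {n_distinct}")
        k_max = n_distinct
    ks = list(range(k_min, k_max + 1))
    ss = np.random.SeedSequence(seed)
    sil, ch, best_cost, best_cent = {}, {}, {}, {}
    for k in ks:
        child_rngs = [np.random.default_rng(s) for s in ss.spawn(replicates)]
        best = None
        for rng in child_rngs:
            labels, cent, cost, _ = kmedians_l1(X, k, rng=rng)
            if best is None or cost < best[2]:
                best = (labels, cent, cost)
        labels, cent, cost = best
        best_cost[k] = cost
        best_cent[k] = cent
        if len(np.unique(labels)) > 1:
            sil[k] = float(silhouette_score(X, labels, metric="cityblock"))
            ch[k] = float(calinski_harabasz_score(X, labels))
        else:  # degenerate: all points in one cluster
            sil[k] = 0.0
            ch[k] = 0.0
    if ks and max(sil.values()) < 0.25:
        warnings.warn("no cluster structure: Silhouette below 0.25 for every k")
        notes.append("no cluster structure")
    ms = ModelSelection(
        k_range=ks,
        silhouette=sil,
        calinski_harabasz=ch,
        best_cost=best_cost,
        best_centroids=best_cent,
        chosen_k=0,
        silhouette_elbow_k=None,
        replicates=replicates,
        seed=seed,
        notes=notes,
    )
    ms.chosen_k = choose_k(ms)
    return ms


def choose_k(selection: ModelSelection) -> int:
    """Calinski-Harabasz peak, cross-checked against the Silhouette elbow.

    The elbow is the interior k maximizing the negated discrete second
    difference 2 s_k - s_{k-1} - s_{k+1} (the sharpest downward bend of
    the Silhouette curve). On disagreement the CH peak wins and the
    disagreement is recorded; a flat CH curve falls back to the lowest
    k with a warning.
    """
    ks = selection.k_range
    ch = np.array([selection.calinski_harabasz[k] for k in ks])
    if np.allclose(ch, ch[0]):
        warnings.warn("flat Calinski-Harabasz curve; choosing the lowest k")
        selection.notes.append("flat CH curve")
        chosen = ks[0]
    else:
        chosen = ks[int(ch.argmax())]
    sil = np.array([selection.silhouette[k] for k in ks])
    if len(ks) >= 3:
        bend = 2 * sil[1:-1] - sil[:-2] - sil[2:]
        selection.silhouette_elbow_k = ks[1 + int(bend.argmax())]
        if selection.silhouette_elbow_k != chosen:
            selection.notes.append(
                f"Silhouette elbow k={selection.silhouette_elbow_k} "
                f"disagrees with CH peak k={chosen}"
            )
    return chosen


def final_clustering(
    windows: dict[str, WindowedFCSeries],
    exemplar_centroids: np.ndarray,
) -> StateModel:
    """Deterministic k-medians over all participants' windows,
    initialized at the exemplar-stage centroids; states renamed by
    ascending mean |centroid| (state 1 = weakest connectivity)."""
    pids = list(windows)
    stacks = [windows[p].edge_vectors() for p in pids]
    X = np.vstack(stacks)
    k = exemplar_centroids.shape[0]
    if np.unique(X, axis=0).shape[0] < k:
        raise ValueError(f"fewer than k={k} distinct window vectors")
    labels0, cent, cost, n_iter = kmedians_l1(X, k, init_centroids=exemplar_centroids)
    order = np.argsort(np.abs(cent).mean(axis=1), kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    labels1 = relabel[labels0]
    cent = cent[order]
    out: dict[str, np.ndarray] = {}
    start = 0
    for p, s in zip(pids, stacks):
        out[p] = labels1[start : start + s.shape[0]]
        start += s.shape[0]
    return StateModel(centroids=cent, labels=out, cost=cost, n_iter=n_iter)
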