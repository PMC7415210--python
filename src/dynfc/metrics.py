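"""Participant-specific state FC matrices and temporal properties.

Given per-window state labels, each participant gets (a) one median FC
matrix per state they visit (element-wise median over their windows in
that state) and (b) three temporal properties of the label sequence:
dwell time per state, transition count, and the transition-frequency
distribution over ordered (source, target) pairs.

Dwell time here is total occupancy — the number of windows spent in a
state — not mean contiguous run length; a run-length variant is
available behind ``contiguous=True``.
"""

from __future__ import annotations

import numpy as np

from .windows import WindowedFCSeries, devectorize_upper

__all__ = [
    "ParticipantStateFC",
    "TemporalProperties",
    "participant_state_fc",
    "dwell_times",
    "transition_count",
    "transition_frequencies",
    "temporal_properties",
]


class ParticipantStateFC:
    """Per-state median FC matrices for one participant.

    ``matrices[s]`` is the symmetric unit-diagonal median matrix for
    state ``s`` (1-based) or ``None`` when the participant never visits
    the state; ``window_counts[s]`` gives the member-window count.
    """

    def __init__(self, participant_id: str, k: int):
        self.participant_id = participant_id
        self.k = k
        self.matrices: dict[int, np.ndarray | None] = {s: None for s in range(1, k + 1)}
        self.window_counts: dict[int, int] = {s: 0 for s in range(1, k + 1)}

    def present_states(self) -> list[int]:
        return [s for s in self.matrices if self.matrices[s] is not None]


class TemporalProperties:
    def __init__(
        self,
        participant_id: str,
        dwell: dict[int, int],
        transitions: int,
        frequencies: np.ndarray,
    ):
        self.participant_id = participant_id
        self.dwell = dwell
        self.transitions = transitions
        self.frequencies = frequencies  # (k, k), zero diagonal


def participant_state_fc(
    windows: WindowedFCSeries,
    labels: np.ndarray,
    k: int,
) -> ParticipantStateFC:
    """Element-wise median over member windows, per state."""
    labels = np.asarray(labels, int)
    if labels.shape[0] != windows.n_windows:
        raise ValueError(
            f"{windows.participant_id}: {labels.shape[0]} labels for "
            f"{windows.n_windows} windows"
        )
    ev = windows.edge_vectors()
    out = ParticipantStateFC(windows.participant_id, k)
    for s in range(1, k + 1):
        members = labels == s
        out.window_counts[s] = int(members.sum())
        if out.window_counts[s]:
            out.matrices[s] = devectorize_upper(np.median(ev[members], axis=0))
    return out


def dwell_times(
    label_sequence: np.ndarray, k: int, contiguous: bool = False
) -> dict[int, float]:
    """Occupancy (window count) per state; counts sum to the sequence
    length. With ``contiguous=True``, mean contiguous run length
    instead (0 for unvisited states)."""
    seq = np.asarray(label_sequence, int)
    if seq.min(initial=k) < 1 or seq.max(initial=1) > k:
        raise ValueError("labels must lie in 1..k")
    if not contiguous:
        return {s: int((seq == s).sum()) for s in range(1, k + 1)}
    runs: dict[int, list[int]] = {s: [] for s in range(1, k + 1)}
    bounds = np.flatnonzero(np.diff(seq) != 0)
    starts = np.concatenate([[0], bounds + 1])
    ends = np.concatenate([bounds + 1, [len(seq)]])
    for a, b in zip(starts, ends):
        runs[int(seq[a])].append(b - a)
    return {s: (float(np.mean(r)) if r else 0.0) for s, r in runs.items()}


def transition_count(label_sequence: np.ndarray) -> int:
    """Number of indices where the label changes."""
    seq = np.asarray(label_sequence, int)
    if seq.size == 0:
        raise ValueError("empty label sequence")
    return int((np.diff(seq) != 0).sum())


def transition_frequencies(label_sequence: np.ndarray, k: int) -> np.ndarray:
    """Fraction of label changes per ordered (source, target) pair.

    Entry (a-1, b-1) = #(a->b changes) / #changes; diagonal 0; the
    all-zero matrix when the sequence never changes state.
    """
    seq = np.asarray(label_sequence, int)
    if seq.size == 0:
        raise ValueError("empty label sequence")
    freq = np.zeros((k, k))
    src, tgt = seq[:-1], seq[1:]
    change = src != tgt
    total = int(change.sum())
    if total == 0:
        return freq
    np.add.at(freq, (src[change] - 1, tgt[change] - 1), 1.0)
    return freq / total


def temporal_properties(
    participant_id: str, label_sequence: np.ndarray, k: int
) -> TemporalProperties:
    return TemporalProperties(
        participant_id,
        dwell_times(label_sequence, k),
        transition_count(label_sequence),
        transition_frequencies(label_sequence, k),
    )
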