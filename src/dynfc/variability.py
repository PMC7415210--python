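"""Nodal temporal variability of the functional-connectivity profile.

For region k, let F_{i,k} be its FC profile in window i — row k of the
window-i correlation matrix with the self-entry removed. Temporal
stability is the mean Pearson correlation between the profiles of all
window pairs, and temporal variability is one minus that:

    V_k = 1 - sum_{i != j} rho(F_{i,k}, F_{j,k}) / (n (n - 1)),

with n the number of windows. V_k lies in [0, 2]: 0 when the region's
FC fingerprint never changes, values above 1 when profiles
anti-correlate across time. Because rho is symmetric, the ordered-pair
mean equals the unordered-pair mean; the fast path computes it from
the Gram matrix of standardized profiles, and an explicit double-loop
oracle is provided for validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .windows import WindowedFCSeries

__all__ = ["VariabilityProfile", "temporal_variability", "variability_oracle"]


@dataclass
class VariabilityProfile:
    participant_id: str
    v: np.ndarray  # (p,) variability per region; NaN where invalid
    n_windows: int
    valid: np.ndarray  # (p,) bool; False if any window profile was constant


def _profiles(windows: WindowedFCSeries) -> np.ndarray:
    """(p, n, p-1): per region, per window, off-diagonal FC profile."""
    n, p = windows.n_windows, windows.n_regions
    if n < 2:
        raise ValueError("need at least 2 windows")
    if p < 3:
        raise ValueError("need at least 3 regions (profiles of length >= 2)")
    mask = ~np.eye(p, dtype=bool)
    out = np.empty((p, n, p - 1))
    for k in range(p):
        out[k] = windows.matrices[:, k, mask[k]]
    return out


def temporal_variability(windows: WindowedFCSeries) -> VariabilityProfile:
    """Vectorized V_k for every region.

    Standardizes each window profile and averages the off-diagonal of
    the resulting correlation Gram matrix. Regions with any constant
    window profile are flagged invalid (V set to NaN) rather than
    propagating NaN silently.
    """
    prof = _profiles(windows)
    p, n, m = prof.shape
    centered = prof - prof.mean(axis=2, keepdims=True)
    sd = centered.std(axis=2, ddof=1)
    valid = ~(sd == 0).any(axis=1)
    v = np.full(p, np.nan)
    for k in np.flatnonzero(valid):
        z = centered[k] / sd[k][:, None]
        gram = (z @ z.T) / (m - 1)  # (n, n) pairwise Pearson
        mean_rho = (gram.sum() - np.trace(gram)) / (n * (n - 1))
        v[k] = 1.0 - mean_rho
    return VariabilityProfile(windows.participant_id, v, n, valid)


def variability_oracle(windows: WindowedFCSeries) -> VariabilityProfile:
    """Reference V_k by an explicit double loop over window pairs.

    Iterates every unordered pair (i < j) and accumulates the Pearson
    correlation of the two profiles region by region; intended for
    validation, O(n^2) in the window count.
    """
    prof = _profiles(windows)
    p, n, m = prof.shape
    total = np.zeros(p)
    valid = np.ones(p, dtype=bool)
    for k in range(p):
        if any(np.ptp(prof[k, i]) == 0 for i in range(n)):
            valid[k] = False
    for i in range(n):
        for j in range(i + 1, n):
            a = prof[:, i, :]
            b = prof[:, j, :]
            ac = a - a.mean(axis=1, keepdims=True)
            bc = b - b.mean(axis=1, keepdims=True)
            denom = np.sqrt((ac * ac).sum(axis=1) * (bc * bc).sum(axis=1))
            with np.errstate(invalid="ignore", divide="ignore"):
                rho = (ac * bc).sum(axis=1) / denom
            total += np.where(valid, rho, 0.0)
    v = np.where(valid, 1.0 - 2.0 * total / (n * (n - 1)), np.nan)
    return VariabilityProfile(windows.participant_id, v, n, valid)
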