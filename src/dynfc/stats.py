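"""Between-group and brain-behavior statistics.

Implements the statistical layer of the dFC analysis: a Lilliefors
normality gate choosing between parametric and rank tests; edgewise
univariate GLMs (FC ~ group + age + sex) with Benjamini-Hochberg FDR
per state; covariate-adjusted Mann-Whitney tests for state temporal
properties (pooled OLS residualization on the covariates, then the
rank test on residuals); regionwise GLMs for temporal variability;
ROC/AUC on the per-participant median strength of significant edges;
and partial correlations between dFC indicators and clinical scores
with age and sex controlled.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.stats.multitest import multipletests

from .metrics import ParticipantStateFC

__all__ = [
    "normality_gate",
    "bh_fdr",
    "edgewise_glm",
    "adjusted_rank_test",
    "roc_auc",
    "median_significant_strength",
    "partial_correlation",
    "demographics_table",
    "encode_covariates",
]


def normality_gate(values, alpha: float = 0.05) -> str:
    """Lilliefors test (KS with estimated mean/SD) at ``alpha``.

    Returns "normal" or "non-normal"; constant input is non-normal
    with a warning.
    """
    x = np.asarray(values, float)
    if x.size < 5:
        raise ValueError("need at least 5 observations")
    if np.ptp(x) == 0:
        warnings.warn("constant input; treating as non-normal")
        return "non-normal"
    _, p = lilliefors(x, dist="norm", pvalmethod="table")
    return "normal" if p >= alpha else "non-normal"


def bh_fdr(pvalues, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (adjusted p, rejection mask)."""
    p = np.asarray(pvalues, float)
    if not np.all(np.isfinite(p)):
        raise ValueError("non-finite p-values")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


def encode_covariates(manifest: pd.DataFrame) -> np.ndarray:
    """Age (centered) and sex (0/1) columns from a cohort manifest."""
    age = manifest["age"].to_numpy(float)
    sex = (manifest["sex"].astype(str).str.upper() == "M").to_numpy(float)
    return np.column_stack([age - age.mean(), sex])


def _group_t_ols(Y: np.ndarray, group: np.ndarray, covariates: np.ndarray | None):
    """Vectorized OLS of each column of Y on [1, group, covariates];
    returns (beta_group, t_group, p_group)."""
    n = Y.shape[0]
    cols = [np.ones(n), np.asarray(group, float)]
    if covariates is not None and covariates.size:
        C = np.atleast_2d(np.asarray(covariates, float))
        if C.shape[0] != n:
            C = C.T
        cols.extend(C.T)
    X = np.column_stack(cols)
    q = X.shape[1]
    if n <= q:
        raise ValueError("more model parameters than observations")
    XtX_inv = np.linalg.pinv(X.T @ X)
    if np.linalg.matrix_rank(X) < q:
        raise ValueError("singular design matrix")
    beta = XtX_inv @ X.T @ Y
    resid = Y - X @ beta
    dof = n - q
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(np.maximum(sigma2 * XtX_inv[1, 1], 1e-300))
    t = beta[1] / se
    p = 2 * sps.t.sf(np.abs(t), dof)
    return beta[1], t, p


def edgewise_glm(
    state_fc: dict[str, ParticipantStateFC],
    manifest: pd.DataFrame,
    state: int,
    q: float = 0.05,
) -> pd.DataFrame | None:
    """Univariate GLM per edge: FC ~ group + age + sex, FDR over the
    state's edges.

    Participants lacking the state are excluded. Returns a DataFrame
    with columns (i, j, beta, t, p, p_fdr, direction, state), or None
    (with a warning) when fewer than 2 participants per group visited
    the state.
    """
    man = manifest.set_index("id")
    pids = [
        pid
        for pid, fc in state_fc.items()
        if fc.matrices.get(state) is not None and pid in man.index
    ]
    groups = man.loc[pids, "group"].to_numpy()
    n_pat = int((groups == "patient").sum())
    n_con = int((groups == "control").sum())
    if n_pat < 2 or n_con < 2:
        warnings.warn(
            f"state {state}: fewer than 2 participants per group "
            f"({n_pat} patient, {n_con} control); skipped"
        )
        return None
    if n_pat + n_con <= 5:  # intercept + group + age + sex need n > 4
        warnings.warn(
            f"state {state}: only {n_pat + n_con} participants present, "
            "too few for the covariate model; skipped"
        )
        return None
    sub = man.loc[pids].reset_index()
    cov = encode_covariates(sub)
    g = (groups == "patient").astype(float)
    p_regions = state_fc[pids[0]].matrices[state].shape[0]
    iu = np.triu_indices(p_regions, k=1)
    Y = np.stack([state_fc[pid].matrices[state][iu] for pid in pids])
    beta, t, p = _group_t_ols(Y, g, cov)
    p_fdr, reject = bh_fdr(p, q=q)
    return pd.DataFrame(
        {
            "i": iu[0],
            "j": iu[1],
            "beta": beta,
            "t": t,
            "p": p,
            "p_fdr": p_fdr,
            "significant": reject,
            "direction": np.where(beta > 0, "patient>control", "patient<control"),
            "state": state,
        }
    )


def adjusted_rank_test(
    values,
    group_labels,
    covariates: np.ndarray | None = None,
) -> tuple[float, float]:
    """Mann-Whitney U after pooled OLS residualization on covariates.

    Values are regressed on [1, covariates] with both groups pooled
    and no group term; the two-sided U test runs on the residuals. With
    no covariates this is the plain Mann-Whitney U test. U is reported
    in the min(U1, U2) convention.
    """
    y = np.asarray(values, float)
    g = np.asarray(group_labels)
    if covariates is not None and np.size(covariates):
        C = np.atleast_2d(np.asarray(covariates, float))
        if C.shape[0] != y.shape[0]:
            C = C.T
        X = np.column_stack([np.ones(y.shape[0]), C])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("singular covariate design")
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        y = y - X @ beta
    names = np.unique(g)
    if names.size != 2:
        raise ValueError("need exactly 2 groups")
    a, b = y[g == names[0]], y[g == names[1]]
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per group")
    res = sps.mannwhitneyu(a, b, alternative="two-sided")
    u = min(res.statistic, a.size * b.size - res.statistic)
    return float(u), float(res.pvalue)


def roc_auc(scores, labels) -> float:
    """AUC by the rank (Mann-Whitney) formulation, 0.5 credit for ties.

    ``labels`` is boolean/0-1 with 1 = positive class (patient).
    """
    s = np.asarray(scores, float)
    y = np.asarray(labels).astype(bool)
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    r = sps.rankdata(s)
    return float((r[y].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def median_significant_strength(
    state_fc: dict[str, ParticipantStateFC],
    significant_edges: np.ndarray,
    state: int,
) -> pd.Series:
    """Per participant, median FC over the significant edge set in one
    state; participants lacking the state are excluded.

    ``significant_edges`` is an (m, 2) array of (i, j) region pairs.
    """
    edges = np.atleast_2d(np.asarray(significant_edges, int))
    if edges.size == 0:
        raise ValueError(f"empty significant edge set for state {state}")
    out = {}
    for pid, fc in state_fc.items():
        m = fc.matrices.get(state)
        if m is None:
            continue
        out[pid] = float(np.median(m[edges[:, 0], edges[:, 1]]))
    return pd.Series(out, name=f"median_strength_state{state}")


def partial_correlation(
    x, y, covariates: np.ndarray | None = None
) -> tuple[float, float]:
    """Pearson correlation of OLS residuals of x and y on covariates.

    p-value from the t distribution with n - 2 - n_cov degrees of
    freedom, two-sided. With no covariates this is the plain Pearson
    correlation.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    ncov = 0
    if covariates is not None and np.size(covariates):
        C = np.atleast_2d(np.asarray(covariates, float))
        if C.shape[0] != n:
            C = C.T
        ncov = C.shape[1]
        if n < ncov + 3:
            raise ValueError("too few complete cases for partial correlation")
        X = np.column_stack([np.ones(n), C])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("singular covariate design")
        x = x - X @ np.linalg.lstsq(X, x, rcond=None)[0]
        y = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    r = float(np.corrcoef(x, y)[0, 1])
    dof = n - 2 - ncov
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt(dof / (1 - r * r))
    return r, float(2 * sps.t.sf(abs(t), dof))


def demographics_table(manifest: pd.DataFrame) -> pd.DataFrame:
    """Group summaries and tests: pooled t for age/MMSE, Mann-Whitney U
    for NPI, chi-square for sex; missing counts reported per variable."""
    for g in ("patient", "control"):
        if not (manifest["group"] == g).any():
            raise ValueError(f"group '{g}' is empty")
    pat = manifest[manifest["group"] == "patient"]
    con = manifest[manifest["group"] == "control"]
    rows = []

    def summarize(name, test, stat, p):
        a, b = pat[name].dropna(), con[name].dropna()
        rows.append(
            {
                "variable": name,
                "patient_mean": a.mean() if name != "sex" else np.nan,
                "patient_sd": a.std(ddof=1) if name != "sex" else np.nan,
                "control_mean": b.mean() if name != "sex" else np.nan,
                "control_sd": b.std(ddof=1) if name != "sex" else np.nan,
                "n_missing": int(manifest[name].isna().sum()),
                "test": test,
                "statistic": stat,
                "p": p,
            }
        )

    for name in ("age", "MMSE"):
        a, b = pat[name].dropna(), con[name].dropna()
        t, p = sps.ttest_ind(a, b, equal_var=True)
        summarize(name, "t", float(t), float(p))
    a, b = pat["NPI"].dropna(), con["NPI"].dropna()
    res = sps.mannwhitneyu(a, b, alternative="two-sided")
    summarize("NPI", "mannwhitney", float(res.statistic), float(res.pvalue))
    tab = pd.crosstab(manifest["group"], manifest["sex"])
    if np.ptp(tab.to_numpy(), axis=None) == 0 or tab.shape[1] < 2:
        chi2, p = 0.0, 1.0
    else:
        chi2, p, _, _ = sps.chi2_contingency(tab, correction=False)
    summarize("sex", "chi2", float(chi2), float(p))
    return pd.DataFrame(rows)
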