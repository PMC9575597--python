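"""Per-site mass-univariate GLM.

At every vertex and measure, an ordinary least-squares model is fit within
one site:

    y_v = b0 + b_g * group + b' covariates + e,   e ~ N(0, s_v^2)

with age, sex, and intracranial volume as default covariates.  The group
contrast is summarized as the coefficient (beta, measure units), its t
statistic, a Cohen's d derived from t, and a percent change of the
measure.  Conventions:

* d = t * sqrt(1/n1 + 1/n0) — the covariate-adjusted two-group conversion
  used in consortium-style meta-analyses of effect sizes;
* thickness percent change = 100 * beta / adjusted control mean (control
  mean with covariates held at the whole-sample mean);
* log-Jacobian percent change = 100 * (exp(beta) - 1), the percent area
  change implied by a log-scale shift.

Residual degrees of freedom are n - rank(design), counting the intercept.
Constant (rank-deficient) covariate columns — e.g. sex at a single-sex
site — are dropped with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SiteStats",
    "fit_site_glm",
    "mass_ols",
    "cohens_d_from_t",
    "percent_change",
    "d_sampling_variance",
]

DEFAULT_COVARIATES = ("age", "sex", "icv")


@dataclass
class SiteStats:
    """Vertex-wise group-contrast statistics for one site and measure."""

    site: str
    measure: str
    beta: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    df: int
    d: np.ndarray
    pct: np.ndarray
    n1: int
    n0: int
    control_mean: np.ndarray     # covariate-adjusted control mean (thickness pct denominator)
    extra_beta: dict | None = None   # moderator/interaction terms: name -> (beta, se, df)

    @property
    def d_variance(self) -> np.ndarray:
        return d_sampling_variance(self.d, self.n1, self.n0)


def cohens_d_from_t(t, n1: int, n0: int):
    """Cohen's d from the covariate-adjusted t: d = t * sqrt(1/n1 + 1/n0)."""
    if n1 < 1 or n0 < 1:
        raise ValueError("both groups must be nonempty")
    return np.asarray(t) * np.sqrt(1.0 / n1 + 1.0 / n0)


def d_sampling_variance(d, n1: int, n0: int):
    """Large-sample variance of Cohen's d for a two-group comparison."""
    n = n1 + n0
    return n / (n1 * n0) + np.asarray(d) ** 2 / (2.0 * n)


def percent_change(beta, measure: str, control_adjusted_mean=None):
    """Group difference as percent of the control-group measure level."""
    beta = np.asarray(beta, dtype=float)
    if measure == "logj":
        return 100.0 * np.expm1(beta)
    if measure == "thickness":
        cm = np.asarray(control_adjusted_mean, dtype=float)
        if np.any(cm <= 0.0):
            raise ValueError("control adjusted mean thickness must be positive")
        return 100.0 * beta / cm
    raise ValueError(f"unknown measure {measure!r}")


def mass_ols(X: np.ndarray, Y: np.ndarray):
    """OLS of every column of Y on the design X.

    Returns ``(beta, se, df)`` with beta and se of shape (p, V).  The
    design must have full column rank.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    # column scaling for numerical stability (covariates span ~7 decades)
    scale = np.linalg.norm(X, axis=0)
    Xs = X / scale
    xtx_inv = np.linalg.inv(Xs.T @ Xs)
    beta_s = xtx_inv @ Xs.T @ Y
    resid = Y - Xs @ beta_s
    df = n - p
    if df <= 0:
        raise ValueError(f"no residual degrees of freedom (n={n}, p={p})")
    sigma2 = np.einsum("nv,nv->v", resid, resid) / df
    beta = beta_s / scale[:, None]
    se = np.sqrt(np.outer(np.diag(xtx_inv) / scale**2, sigma2))
    return beta, se, df


def _drop_constant_columns(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str]]:
    keep = [0]   # intercept
    kept_names = [names[0]]
    for j in range(1, X.shape[1]):
        if np.ptp(X[:, j]) == 0.0:
            warnings.warn(f"dropping constant design column {names[j]!r}", RuntimeWarning)
        else:
            keep.append(j)
            kept_names.append(names[j])
    return X[:, keep], kept_names


def fit_site_glm(
    Y: np.ndarray,
    cohort: pd.DataFrame,
    contrast: str | np.ndarray,
    measure: str,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    moderators: tuple[str, ...] = (),
    site: str = "",
) -> SiteStats:
    """Vertex-wise GLM for one site's subjects.

    ``Y`` is (n_subjects, V) for this site, ``cohort`` the matching subject
    rows.  ``contrast`` is either a column name (0/1 group indicator or a
    continuous clinical variable) or an explicit vector.  Rows with missing
    values in the contrast or covariates must be dropped by the caller.
    ``moderators`` name additional columns of interest (e.g. interaction
    terms already present in ``cohort``); their beta and SE are reported in
    ``extra_beta`` for beta-scale pooling.
    """
    cohort = cohort.reset_index(drop=True)
    g = cohort[contrast].to_numpy(dtype=float) if isinstance(contrast, str) else np.asarray(contrast, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if len(g) != len(Y):
        raise ValueError("contrast length does not match data rows")

    names = ["intercept", "group", *covariates, *moderators]
    cols = [np.ones(len(g)), g]
    cols += [cohort[c].to_numpy(dtype=float) for c in covariates]
    cols += [cohort[m].to_numpy(dtype=float) for m in moderators]
    X = np.column_stack(cols)
    if np.isnan(X).any():
        raise ValueError("missing values in design; apply listwise deletion first")
    X, names = _drop_constant_columns(X, names)
    if "group" not in names:
        raise ValueError("group contrast is constant within this site")

    beta, se, df = mass_ols(X, Y)
    j = names.index("group")
    t = beta[j] / se[j]
    p = 2.0 * stats.t.sf(np.abs(t), df)

    binary = set(np.unique(g)) <= {0.0, 1.0}
    if binary:
        n1, n0 = int((g == 1).sum()), int((g == 0).sum())
        if n1 == 0 or n0 == 0:
            raise ValueError("both contrast groups must be nonempty")
        d = cohens_d_from_t(t, n1, n0)
    else:   # continuous regressor: no two-group d scale
        n1 = n0 = 0
        d = np.full_like(t, np.nan)

    # adjusted control mean: controls' average y with covariates at the
    # whole-sample mean (standard covariate-adjusted group mean)
    if binary:
        ctrl = g == 0
        cov_idx = [k for k, nm in enumerate(names) if nm not in ("intercept", "group")]
        adj = Y[ctrl].mean(axis=0)
        if cov_idx:
            xbar_all = X[:, cov_idx].mean(axis=0)
            xbar_ctrl = X[ctrl][:, cov_idx].mean(axis=0)
            adj = adj + (xbar_all - xbar_ctrl) @ beta[cov_idx]
    else:
        adj = Y.mean(axis=0)

    if measure == "thickness" and binary:
        pct = percent_change(beta[j], "thickness", adj)
    elif measure == "logj" and binary:
        pct = percent_change(beta[j], "logj")
    else:
        pct = np.full_like(t, np.nan)

    extra = None
    if moderators:
        extra = {
            m: (beta[names.index(m)], se[names.index(m)], df)
            for m in moderators
            if m in names
        }
    return SiteStats(
        site=site,
        measure=measure,
        beta=beta[j],
        se=se[j],
        t=t,
        p=p,
        df=df,
        d=d,
        pct=pct,
        n1=n1,
        n0=n0,
        control_mean=adj,
        extra_beta=extra,
    )
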