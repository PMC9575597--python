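"""Random-effects meta-analysis of per-site vertex-wise effects.

Per-site effect estimates (Cohen's d for group contrasts, regression
coefficients for clinical and interaction analyses) are pooled at every
vertex with the DerSimonian-Laird moment estimator of the between-site
variance tau^2:

    w_i  = 1 / v_i
    Q    = sum w_i (y_i - ybar_w)^2
    tau2 = max(0, (Q - (k - 1)) / (sum w_i - sum w_i^2 / sum w_i))

followed by inverse-variance pooling with weights 1 / (v_i + tau2).  The
sampling variance of d uses the common large-sample formula
v = (n1 + n0)/(n1 n0) + d^2 / (2 (n1 + n0)); no small-sample (Hedges g)
correction is applied.  Single-site vertices pool to the site value with
tau2 = 0 by convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .glm import SiteStats

__all__ = ["MetaStats", "dl_tau2", "pool_random_effects", "pool_effects", "meta_map"]


@dataclass
class MetaStats:
    """Pooled vertex-wise statistics for one measure and contrast."""

    measure: str
    d: np.ndarray            # pooled Cohen's d (NaN for beta-scale analyses)
    d_se: np.ndarray
    beta: np.ndarray         # pooled coefficient (measure units)
    beta_se: np.ndarray
    tau2: np.ndarray
    Q: np.ndarray
    k: np.ndarray            # contributing sites per vertex
    z: np.ndarray
    p: np.ndarray
    control_mean: np.ndarray | None = None   # pooled adjusted control mean
    n1: int = 0
    n0: int = 0


def _as_2d(effects, variances):
    y = np.asarray(effects, dtype=float)
    v = np.asarray(variances, dtype=float)
    if y.ndim == 1:          # k sites at a single vertex
        y = y[:, None]
    if v.ndim == 1:
        v = v[:, None]
    if y.shape != v.shape:
        raise ValueError("effects and variances must have the same shape")
    if np.any(v[np.isfinite(y)] <= 0.0):
        raise ValueError("sampling variances must be positive")
    return y, v


def dl_tau2(effects, variances):
    """DerSimonian-Laird between-site variance, vectorized over columns.

    ``effects``/``variances`` are (k,) or (k, V); NaN effects mark sites
    missing at a vertex.  Vertices with a single contributing site get
    tau2 = 0 by convention.
    """
    y, v = _as_2d(effects, variances)
    scalar = np.asarray(effects).ndim == 1
    valid = np.isfinite(y)
    w = np.where(valid, 1.0 / v, 0.0)
    k = valid.sum(axis=0)
    sw = w.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ybar = np.where(sw > 0, (w * np.where(valid, y, 0.0)).sum(axis=0) / sw, np.nan)
        Q = (w * np.where(valid, (y - ybar) ** 2, 0.0)).sum(axis=0)
        C = sw - (w**2).sum(axis=0) / np.where(sw > 0, sw, 1.0)
        tau2 = np.where((k >= 2) & (C > 0), (Q - (k - 1)) / np.where(C > 0, C, 1.0), 0.0)
    tau2 = np.maximum(tau2, 0.0)
    tau2 = np.where(k >= 1, tau2, np.nan)
    if scalar:
        return float(tau2[0]) if tau2.size == 1 else tau2
    return tau2


def pool_effects(effects, variances):
    """Random-effects pooling; returns a dict of vectorized statistics.

    Keys: est, se, tau2, Q, k, z, p.  Vertices with zero contributing
    sites give NaN estimates and k = 0.
    """
    y, v = _as_2d(effects, variances)
    valid = np.isfinite(y)
    k = valid.sum(axis=0)
    tau2 = np.atleast_1d(dl_tau2(y, v))
    with np.errstate(invalid="ignore", divide="ignore"):
        wstar = np.where(valid, 1.0 / (v + tau2[None, :]), 0.0)
        sw = wstar.sum(axis=0)
        est = np.where(k > 0, (wstar * np.where(valid, y, 0.0)).sum(axis=0) / np.where(sw > 0, sw, 1.0), np.nan)
        se = np.where(k > 0, 1.0 / np.sqrt(np.where(sw > 0, sw, 1.0)), np.nan)
        w = np.where(valid, 1.0 / v, 0.0)
        swf = w.sum(axis=0)
        ybar = np.where(k > 0, (w * np.where(valid, y, 0.0)).sum(axis=0) / np.where(swf > 0, swf, 1.0), np.nan)
        Q = (w * np.where(valid, (y - ybar) ** 2, 0.0)).sum(axis=0)
        z = est / se
    p = np.clip(2.0 * stats.norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0)
    return {"est": est, "se": se, "tau2": tau2, "Q": Q, "k": k, "z": z, "p": p}


def pool_random_effects(effects, variances):
    """Scalar-vertex convenience wrapper: (pooled effect, SE, tau2, z, p)."""
    y = np.asarray(effects, dtype=float)
    if y.size == 0:
        raise ValueError("no effects to pool")
    r = pool_effects(y[:, None], np.asarray(variances, dtype=float)[:, None])
    return (
        float(r["est"][0]),
        float(r["se"][0]),
        float(r["tau2"][0]),
        float(r["z"][0]),
        float(r["p"][0]),
    )


def meta_map(site_stats: list[SiteStats], scale: str = "d") -> MetaStats:
    """Pool a list of per-site vertex maps into one MetaStats.

    ``scale`` selects the pooled quantity: "d" (Cohen's d with its
    large-sample variance; group contrasts) or "beta" (the raw coefficient
    with its OLS variance; clinical regressions and interaction terms).
    Sites excluded upstream are simply absent from the list.
    """
    if not site_stats:
        raise ValueError("no contributing sites")
    measure = site_stats[0].measure
    if scale == "d":
        eff = np.vstack([s.d for s in site_stats])
        var = np.vstack([s.d_variance for s in site_stats])
    elif scale == "beta":
        eff = np.vstack([s.beta for s in site_stats])
        var = np.vstack([s.se**2 for s in site_stats])
    else:
        raise ValueError(f"unknown pooling scale {scale!r}")
    pooled = pool_effects(eff, var)

    betas = np.vstack([s.beta for s in site_stats])
    bvars = np.vstack([s.se**2 for s in site_stats])
    bpool = pool_effects(betas, bvars)

    # precision-weighted adjusted control mean across sites (for thickness pct)
    cms = np.vstack([s.control_mean for s in site_stats])
    wts = np.where(np.isfinite(betas), 1.0 / bvars, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cm = (wts * cms).sum(axis=0) / wts.sum(axis=0)

    return MetaStats(
        measure=measure,
        d=pooled["est"] if scale == "d" else np.full_like(pooled["est"], np.nan),
        d_se=pooled["se"] if scale == "d" else np.full_like(pooled["se"], np.nan),
        beta=bpool["est"],
        beta_se=bpool["se"],
        tau2=pooled["tau2"],
        Q=pooled["Q"],
        k=pooled["k"],
        z=pooled["z"],
        p=pooled["p"],
        control_mean=cm,
        n1=sum(s.n1 for s in site_stats),
        n0=sum(s.n0 for s in site_stats),
    )
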