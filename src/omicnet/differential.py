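"""Two-group differential abundance with plain and moderated t-statistics.

Fold changes are case-minus-control differences of log2 means (positive =
higher in the case strain).  The metabolomic convention is a Welch unequal
variance t-test per feature; the proteomic convention is an empirical-Bayes
moderated t in which per-feature pooled variances are shrunk toward a common
prior estimated from the whole ensemble:

    s_tilde^2 = (d0 * s0^2 + d * s^2) / (d0 + d)

with the prior (d0, s0^2) fitted by the method of moments to the observed
variance distribution (the per-feature variances are modelled as scaled
F-variates s^2/s0^2 ~ F(d, d0)).  The moderated t uses s_tilde and d0 + d
degrees of freedom, which stabilizes inference at small n.

Multiple testing is controlled by Benjamini-Hochberg step-up FDR, and the
volcano-style caller labels features up/down when both the fold-change and
FDR gates pass.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .containers import OmicsMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "fold_change",
    "welch_t",
    "moderated_t",
    "bh_adjust",
    "call_significant",
    "differential_table",
]

CASE, CONTROL = "case", "control"


def _split_groups(m: OmicsMatrix, groups) -> tuple:
    groups = pd.Series(groups)
    bad = sorted(set(groups.unique()) - {CASE, CONTROL})
    if bad:
        raise ValueError(f"unknown group labels {bad}; expected {CASE!r}/{CONTROL!r}")
    case = [s for s in m.samples if groups.get(s) == CASE]
    ctrl = [s for s in m.samples if groups.get(s) == CONTROL]
    if len(case) < 2 or len(ctrl) < 2:
        raise ValueError("each group needs >= 2 samples")
    return m.values[case], m.values[ctrl]


def fold_change(m: OmicsMatrix, groups) -> pd.Series:
    """Per-feature log2 fold change: mean(case) - mean(control) on log2 scale.

    Features with fewer than 2 observed values in either group are skipped
    (NaN) with a logged warning.
    """
    m.require_scale("log2", "quantile", "unit-variance")
    a, b = _split_groups(m, groups)
    ok = (a.notna().sum(axis=1) >= 2) & (b.notna().sum(axis=1) >= 2)
    lfc = a.mean(axis=1) - b.mean(axis=1)
    lfc[~ok] = np.nan
    n_skip = int((~ok).sum())
    if n_skip:
        logger.warning("fold_change: skipped %d features with <2 observations per group",
                       n_skip)
    return lfc.rename("log2FC")


def _welch_arrays(a: np.ndarray, b: np.ndarray) -> tuple:
    """Vectorized Welch t over feature rows, with zero-variance conventions."""
    n1 = np.sum(~np.isnan(a), axis=1)
    n2 = np.sum(~np.isnan(b), axis=1)
    m1, m2 = np.nanmean(a, axis=1), np.nanmean(b, axis=1)
    v1 = np.nanvar(a, axis=1, ddof=1)
    v2 = np.nanvar(b, axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        se2 = v1 / n1 + v2 / n2
        t = (m1 - m2) / np.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        p = 2 * stats.t.sf(np.abs(t), df)
    # degenerate: both variances zero
    degen = se2 == 0
    if np.any(degen):
        logger.warning("welch_t: %d features with zero variance in both groups",
                       int(degen.sum()))
        eq = degen & (m1 == m2)
        ne = degen & (m1 != m2)
        t[eq], p[eq] = 0.0, 1.0
        t[ne] = np.sign(m1[ne] - m2[ne]) * np.inf
        p[ne] = 0.0
    return t, p


def welch_t(m: OmicsMatrix, groups) -> pd.DataFrame:
    """Welch unequal-variance t with Satterthwaite df; two-sided p per feature."""
    m.require_scale("log2", "quantile", "unit-variance")
    a, b = _split_groups(m, groups)
    t, p = _welch_arrays(a.to_numpy(float), b.to_numpy(float))
    return pd.DataFrame({"t": t, "p": p}, index=m.features)


def moments_prior(s2: np.ndarray, d: float) -> tuple:
    """Method-of-moments fit of the variance prior (d0, s0^2).

    Under the hierarchical model s^2 / s0^2 ~ F(d, d0):
        E[s^2]   = s0^2 * d0 / (d0 - 2)
        Var[s^2] = s0^4 * 2 d0^2 (d + d0 - 2) / (d (d0-2)^2 (d0-4))
    Solving the two moment equations for d0 gives
        c  = Var/Mean^2 * d / 2,   d0 = (d + 4c - 2) / (c - 1)
    with d0 = +inf (no excess dispersion, s0^2 = mean) when c <= 1.
    """
    s2 = np.asarray(s2, float)
    s2 = s2[np.isfinite(s2)]
    mean = s2.mean()
    var = s2.var(ddof=1) if s2.size > 1 else 0.0
    if mean <= 0:
        return np.inf, float(mean)
    c = var / mean**2 * d / 2.0
    if c <= 1.0:
        return np.inf, float(mean)
    d0 = (d + 4.0 * c - 2.0) / (c - 1.0)
    s02 = mean * (d0 - 2.0) / d0
    return float(d0), float(s02)


def moderated_t(m: OmicsMatrix, groups, prior: tuple | None = None) -> pd.DataFrame:
    """Empirical-Bayes moderated t per feature.

    ``prior`` optionally fixes (d0, s0^2); otherwise it is estimated from
    the per-feature pooled variances by the method of moments.  Falls back
    to :func:`welch_t` (with a warning) when fewer than 2 features are
    available, since shrinkage needs an ensemble.
    """
    m.require_scale("log2", "quantile", "unit-variance")
    if m.n_features < 2:
        logger.warning("moderated_t: <2 features; falling back to welch_t")
        return welch_t(m, groups)
    a, b = _split_groups(m, groups)
    A, B = a.to_numpy(float), b.to_numpy(float)
    n1 = np.sum(~np.isnan(A), axis=1)
    n2 = np.sum(~np.isnan(B), axis=1)
    m1, m2 = np.nanmean(A, axis=1), np.nanmean(B, axis=1)
    v1 = np.nanvar(A, axis=1, ddof=1)
    v2 = np.nanvar(B, axis=1, ddof=1)
    d = n1 + n2 - 2
    s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / d
    if prior is None:
        d0, s02 = moments_prior(s2, float(np.median(d)))
    else:
        d0, s02 = prior
    if np.isinf(d0):
        s2_tilde = np.full_like(s2, s02)
        df = np.full_like(s2, np.inf)
    else:
        s2_tilde = (d0 * s02 + d * s2) / (d0 + d)
        df = d0 + d
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(s2_tilde * (1.0 / n1 + 1.0 / n2))
    finite_df = np.where(np.isinf(df), 1e12, df)
    p = 2 * stats.t.sf(np.abs(t), finite_df)
    out = pd.DataFrame({"t": t, "p": p}, index=m.features)
    out.attrs["d0"] = d0
    out.attrs["s0_squared"] = s02
    return out


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), original order.

    q_(i) = min_{j >= i} m * p_(j) / j, clipped to 1.
    """
    p = np.asarray(p, float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m_ = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m_ / np.arange(1, m_ + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m_)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def call_significant(
    results: pd.DataFrame,
    fc_threshold: float = 1.5,
    fdr_threshold: float = 0.05,
) -> pd.Series:
    """Volcano-style call: 'up'/'down' when |fold| > fc_threshold (raw fold
    scale, i.e. |log2FC| > log2 fc_threshold) and q < fdr_threshold, else 'ns'."""
    if fc_threshold < 1:
        raise ValueError("fc_threshold is on the raw fold scale; must be >= 1")
    cut = np.log2(fc_threshold)
    lfc, q = results["log2FC"], results["q"]
    call = np.where(
        (lfc > cut) & (q < fdr_threshold),
        "up",
        np.where((lfc < -cut) & (q < fdr_threshold), "down", "ns"),
    )
    call = np.where(lfc.isna() | q.isna(), "ns", call)
    return pd.Series(call, index=results.index, name="call")


def signed_fold(log2fc) -> pd.Series:
    """Signed raw fold: 2^log2FC for increases, -2^(-log2FC) for decreases."""
    lfc = pd.Series(log2fc)
    return pd.Series(
        np.where(lfc >= 0, 2.0**lfc, -(2.0 ** (-lfc))), index=lfc.index, name="fold"
    )


def differential_table(
    m: OmicsMatrix,
    groups,
    method: str = "welch",
    fc_threshold: float = 1.5,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Full per-feature differential summary for one layer.

    Columns: feature, layer, log2FC, fold (signed raw fold), t, p, q, call.
    ``method`` is ``"welch"`` or ``"moderated"``.
    """
    lfc = fold_change(m, groups)
    if method == "welch":
        tp = welch_t(m, groups)
    elif method == "moderated":
        tp = moderated_t(m, groups)
    else:
        raise ValueError(f"unknown method {method!r}")
    out = pd.DataFrame(
        {
            "feature": m.features,
            "layer": m.layers.values,
            "log2FC": lfc.values,
            "fold": signed_fold(lfc).values,
            "t": tp["t"].values,
            "p": tp["p"].values,
        }
    ).set_index("feature")
    ok = out["p"].notna()
    q = np.full(len(out), np.nan)
    if ok.any():
        q[ok.to_numpy()] = bh_adjust(out.loc[ok, "p"].to_numpy())
    out["q"] = q
    out["call"] = call_significant(out, fc_threshold, fdr_threshold)
    return out
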