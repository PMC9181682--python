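"""Per-layer normalization and multi-layer integration.

The normalization chain is log2 -> quantile -> unit-variance within each
layer, after which layers are stacked into a single feature-by-sample matrix
whose rows are comparable across omics (every row mean 0, sd 1).  Quantile
normalization is toggleable per layer; outlier detection is report-only (it
returns flags and never mutates the data).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import OmicsMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "log_transform",
    "quantile_normalize",
    "unit_variance_scale",
    "drop_high_missing",
    "detect_outliers",
    "concatenate_layers",
    "normalize_layer",
]


def log_transform(m: OmicsMatrix, offset: float = 0.0) -> OmicsMatrix:
    """log2(v + offset) for every present value; missing stays missing.

    Raises a ``ValueError`` naming the offending cell if any present value
    plus ``offset`` is not strictly positive.
    """
    m.require_scale("raw")
    if offset < 0:
        raise ValueError("offset must be non-negative")
    shifted = m.values + offset
    bad = shifted <= 0
    if bad.any().any():
        rows, cols = np.nonzero(bad.to_numpy())
        feat = m.values.index[rows[0]]
        samp = m.values.columns[cols[0]]
        raise ValueError(
            f"non-positive value at feature {feat!r}, sample {samp!r}: "
            f"{m.values.iat[rows[0], cols[0]]} + offset {offset} <= 0"
        )
    return m.with_values(np.log2(shifted), scale="log2")


def _quantile_normalize_complete(X: np.ndarray) -> np.ndarray:
    """Exact quantile normalization for a complete matrix.

    Reference distribution = row means of the column-sorted matrix; ties
    within a column receive the mean of the reference values at their tied
    ranks.
    """
    n_feat, n_samp = X.shape
    ref = np.sort(X, axis=0).mean(axis=1)
    csum = np.concatenate([[0.0], np.cumsum(ref)])
    out = np.empty_like(X)
    for j in range(n_samp):
        s = pd.Series(X[:, j])
        rmin = s.rank(method="min").to_numpy(int)
        rmax = s.rank(method="max").to_numpy(int)
        out[:, j] = (csum[rmax] - csum[rmin - 1]) / (rmax - rmin + 1)
    return out


def quantile_normalize(m: OmicsMatrix) -> OmicsMatrix:
    """Force every sample column onto a common reference distribution.

    For complete data the reference is the vector of row means of the
    column-sorted matrix, and after normalization the sorted values of every
    column are identical.  Columns containing missing values keep them
    missing; their observed values are mapped through the reference by
    fractional rank interpolation (the reference is then built from
    per-column quantile grids so that unequal observed counts are handled).
    """
    m.require_scale("log2")
    if m.n_samples < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    X = m.values.to_numpy(float)
    if not np.isnan(X).any():
        out = _quantile_normalize_complete(X)
    else:
        n_feat, n_samp = X.shape
        grid = np.linspace(0.0, 1.0, n_feat)
        # per-column empirical quantiles on a common grid, averaged
        ref = np.nanquantile(X, grid, axis=0).mean(axis=1)
        out = np.full_like(X, np.nan)
        for j in range(n_samp):
            col = X[:, j]
            obs = ~np.isnan(col)
            n_obs = obs.sum()
            if n_obs == 0:
                continue
            ranks = pd.Series(col[obs]).rank(method="average").to_numpy()
            frac = (ranks - 1) / max(n_obs - 1, 1)
            out[obs, j] = np.interp(frac, grid, ref)
    return m.with_values(
        pd.DataFrame(out, index=m.values.index, columns=m.values.columns),
        scale="quantile",
    )


def unit_variance_scale(m: OmicsMatrix) -> OmicsMatrix:
    """Center each feature row and divide by its sample standard deviation
    (n-1 denominator).  Rows with fewer than 2 observed values or zero
    variance are dropped with a logged warning.
    """
    m.require_scale("log2", "quantile")
    X = m.values
    n_obs = X.notna().sum(axis=1)
    sd = X.std(axis=1, ddof=1)
    keep = (n_obs >= 2) & (sd > 0)
    dropped = X.index[~keep].tolist()
    if dropped:
        logger.warning(
            "unit_variance_scale: dropping %d constant/under-observed features: %s",
            len(dropped),
            dropped[:10],
        )
    X = X.loc[keep]
    scaled = X.sub(X.mean(axis=1), axis=0).div(sd[keep], axis=0)
    return m.with_values(scaled, scale="unit-variance")


def drop_high_missing(m: OmicsMatrix, max_missing: float = 0.3) -> OmicsMatrix:
    """Drop features with more than ``max_missing`` fraction missing values."""
    frac = m.values.isna().mean(axis=1)
    keep = frac <= max_missing
    n_drop = int((~keep).sum())
    if n_drop:
        logger.warning("drop_high_missing: removing %d features (> %.0f%% missing)",
                       n_drop, 100 * max_missing)
    return m.with_values(m.values.loc[keep])


def detect_outliers(m: OmicsMatrix, k_sd: float = 3.0) -> pd.Series:
    """Flag outlier samples in the space of the first two principal components.

    Samples are points; the score space is spanned by the two leading PCs of
    the feature-centered matrix.  A sample is flagged when its Euclidean
    distance from the score-space centroid exceeds ``k_sd`` times the
    standard deviation of those distances.  Returns a boolean Series indexed
    by sample; never mutates the matrix.
    """
    if m.n_samples < 4:
        raise ValueError("outlier detection needs >= 4 samples")
    if k_sd <= 0:
        raise ValueError("k_sd must be positive")
    X = m.values.to_numpy(float).T  # samples x features
    X = np.nan_to_num(X - np.nanmean(X, axis=0, keepdims=True))
    X = X - X.mean(axis=0, keepdims=True)
    # scores on the two leading PCs
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    k = min(2, s.size)
    scores = u[:, :k] * s[:k]
    centroid = scores.mean(axis=0)
    dist = np.linalg.norm(scores - centroid, axis=1)
    sd = dist.std(ddof=1)
    if sd == 0 or not np.isfinite(k_sd):
        flags = np.zeros(m.n_samples, dtype=bool)
    else:
        flags = dist > k_sd * sd
    return pd.Series(flags, index=m.samples, name="outlier")


def concatenate_layers(layers: list) -> OmicsMatrix:
    """Stack unit-variance-scaled layers into one matrix.

    All layers must share the same sample ID set; sample order is harmonized
    to the first layer's order.  Feature IDs colliding across layers are
    prefixed with their layer tag.
    """
    if not layers:
        raise ValueError("no layers to concatenate")
    for lay in layers:
        lay.require_scale("unit-variance")
    first = layers[0]
    ref_samples = list(first.samples)
    for lay in layers[1:]:
        a, b = set(ref_samples), set(lay.samples)
        if a != b:
            raise ValueError(
                f"sample ID mismatch between layers: only in first={sorted(a - b)}, "
                f"only in other={sorted(b - a)}"
            )
    seen: set = set()
    frames, tag_frames = [], []
    for lay in layers:
        vals = lay.values.loc[:, ref_samples]
        rename = {f: f"{lay.layers[f]}:{f}" for f in vals.index if f in seen}
        if rename:
            logger.warning("concatenate_layers: prefixing %d colliding feature IDs",
                           len(rename))
            vals = vals.rename(index=rename)
        tags = lay.layers.rename(index=rename)
        seen.update(vals.index)
        frames.append(vals)
        tag_frames.append(tags)
    return OmicsMatrix(
        values=pd.concat(frames, axis=0),
        layers=pd.concat(tag_frames),
        scale="unit-variance",
    )


def normalize_layer(
    m: OmicsMatrix,
    log_offset: float = 0.0,
    quantile: bool = True,
    max_missing: float = 0.3,
) -> OmicsMatrix:
    """Full per-layer chain: drop high-missing features, log2, optional
    quantile normalization, unit-variance scaling."""
    m = drop_high_missing(m, max_missing=max_missing)
    m = log_transform(m, offset=log_offset)
    if quantile:
        m = quantile_normalize(m)
    return unit_variance_scale(m)
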