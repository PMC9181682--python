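"""Correlation network construction and module detection.

The network is built over the concatenated, unit-variance-scaled multi-omic
matrix: nodes are features, edge weights are Pearson correlations of feature
profiles across samples (pairwise-complete when values are missing).  The
adjacency is |r|^beta (unsigned, the default) or ((1+r)/2)^beta (signed).
Modules are found by average-linkage hierarchical clustering of the
dissimilarity d = 1 - |r|, cutting the tree at a quantile of its merge
heights; clusters below the minimum size are pooled into the reserved
"grey" (unassigned) label and the rest are named from a fixed color list in
decreasing size order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .containers import OmicsMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationNetwork",
    "ModulePartition",
    "correlation_matrix",
    "adjacency",
    "cluster_modules",
    "module_eigengene",
    "eigengene_set",
    "intramodular_connectivity",
    "GREY",
    "MODULE_COLORS",
]

GREY = "grey"

#: Fixed color vocabulary for module labels, assigned in decreasing module
#: size order; "grey" is reserved for unassigned features.
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta",
)


@dataclass
class CorrelationNetwork:
    """Pairwise feature correlations and the derived adjacency."""

    features: pd.Index
    r: pd.DataFrame                      # symmetric, unit diagonal; NaN = unestimable pair
    counts: pd.DataFrame | None = None   # per-pair complete-observation counts
    a: pd.DataFrame | None = None        # adjacency, zero diagonal
    beta: float | None = None
    signed: bool | None = None


@dataclass
class ModulePartition:
    """Feature -> color-label assignment plus the dendrogram that produced it."""

    assignments: pd.Series               # feature -> color, "grey" = unassigned
    linkage: np.ndarray | None = None    # scipy linkage matrix
    cut_height: float | None = None
    params: dict = field(default_factory=dict)

    def modules(self, include_grey: bool = False) -> list:
        sizes = self.assignments.value_counts()
        out = [c for c in sizes.index if c != GREY]
        out.sort(key=lambda c: (-sizes[c], c))
        if include_grey and GREY in sizes.index:
            out.append(GREY)
        return out

    def members(self, module: str) -> list:
        return sorted(self.assignments.index[self.assignments == module])


def correlation_matrix(m: OmicsMatrix, min_pairs: int = 4) -> CorrelationNetwork:
    """Pearson correlation over pairwise-complete samples for every feature pair.

    Pairs with fewer than ``min_pairs`` complete observations get r recorded
    as missing (their adjacency will be 0).  Requires >= 4 samples.
    """
    if m.n_samples < 4:
        raise ValueError("correlation network needs >= 4 samples")
    X = m.values.to_numpy(float)
    obs = ~np.isnan(X)
    counts = obs.astype(np.int64) @ obs.T.astype(np.int64)
    if not np.isnan(X).any():
        with np.errstate(invalid="ignore"):
            r = np.corrcoef(X)
    else:
        r = m.values.T.corr(min_periods=min_pairs).to_numpy()
    r[counts < min_pairs] = np.nan
    n_low = int((counts < min_pairs).sum() - np.sum(np.diag(counts) < min_pairs))
    if n_low:
        logger.warning("correlation_matrix: %d pairs below %d complete observations",
                       n_low // 2, min_pairs)
    r = (r + r.T) / 2.0  # enforce exact symmetry
    np.fill_diagonal(r, 1.0)
    idx = m.features
    return CorrelationNetwork(
        features=idx,
        r=pd.DataFrame(r, index=idx, columns=idx),
        counts=pd.DataFrame(counts, index=idx, columns=idx),
    )


def adjacency(net: CorrelationNetwork, beta: float = 1.0, signed: bool = False) -> CorrelationNetwork:
    """Fill the adjacency: |r|^beta (unsigned) or ((1+r)/2)^beta (signed).

    Unestimable correlations contribute adjacency 0; the diagonal is 0 so
    self-edges never enter connectivity sums.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    r = net.r.to_numpy(float)
    if signed:
        a = ((1.0 + r) / 2.0) ** beta
    else:
        a = np.abs(r) ** beta
    a = np.nan_to_num(a, nan=0.0)
    np.fill_diagonal(a, 0.0)
    net.a = pd.DataFrame(a, index=net.features, columns=net.features)
    net.beta = beta
    net.signed = signed
    return net


def _eigvec(X: np.ndarray, idx) -> np.ndarray:
    """Leading right-singular vector of the row-centered submatrix, unit sd."""
    M = X[list(idx)]
    M = np.nan_to_num(M - np.nanmean(M, axis=1, keepdims=True))
    if len(idx) == 1:
        e = M[0].copy()
    else:
        _, _, vt = np.linalg.svd(M, full_matrices=False)
        e = vt[0]
    sd = e.std(ddof=1)
    return e / sd if sd > 0 else e


def _merge_correlated_clusters(absr: np.ndarray, mods: dict, ratio_min: float) -> dict:
    """Iteratively merge the cluster pair with the highest between/within
    mean-|r| ratio until no pair reaches ``ratio_min``.

    Normalizing the between-cluster mean |r| by the geometric mean of the
    within-cluster means makes the criterion insensitive to the overall
    strength of a module's shared signal, so fragments of one weakly
    realized module still reunite while distinct modules stay apart.
    """

    def within(idx) -> float:
        k = len(idx)
        if k < 2:
            return np.nan
        sub = absr[np.ix_(idx, idx)]
        return (sub.sum() - k) / (k * k - k)

    while len(mods) > 1:
        labs = sorted(mods)
        best = (0.0, None, None)
        for i in range(len(labs)):
            for j in range(i + 1, len(labs)):
                a, b = mods[labs[i]], mods[labs[j]]
                denom = np.sqrt(max(within(a), 1e-9) * max(within(b), 1e-9))
                ratio = absr[np.ix_(a, b)].mean() / denom
                if ratio > best[0]:
                    best = (ratio, labs[i], labs[j])
        if best[0] < ratio_min:
            break
        mods[best[1]] = mods[best[1]] + mods[best[2]]
        del mods[best[2]]
    return mods


def _kme_reassign(X: np.ndarray, mods: dict, kme_min: float, core_size: int) -> dict:
    """Reassign every feature to the module whose eigengene it correlates
    with most strongly (|kME|), dropping features below ``kme_min`` to grey
    and modules falling below ``core_size``."""
    labs = sorted(mods)
    E = np.array([_eigvec(X, mods[l]) for l in labs])
    Xc = np.nan_to_num(X - np.nanmean(X, axis=1, keepdims=True))
    norms = np.linalg.norm(Xc, axis=1, keepdims=True)
    Xn = np.divide(Xc, norms, out=np.zeros_like(Xc), where=norms > 0)
    Ec = E - E.mean(axis=1, keepdims=True)
    Ec = Ec / np.linalg.norm(Ec, axis=1, keepdims=True)
    kme = np.abs(Xn @ Ec.T)  # features x modules
    best = kme.argmax(axis=1)
    best_r = kme.max(axis=1)
    out: dict = {l: [] for l in labs}
    for i, (b, r) in enumerate(zip(best, best_r)):
        if r >= kme_min:
            out[labs[b]].append(i)
    return {l: idx for l, idx in out.items() if len(idx) >= core_size}


def cluster_modules(
    net: CorrelationNetwork,
    m: OmicsMatrix | None = None,
    min_size: int = 10,
    cut_height_quantile: float = 0.85,
    merge_ratio_min: float = 0.7,
    kme_min: float = 0.8,
    core_size: int = 5,
    refine_cycles: int = 2,
) -> ModulePartition:
    """Partition the network into color-labeled modules.

    Average-linkage hierarchical clustering of the dissimilarity
    d = 1 - |r| (unestimable pairs get d = 1) is cut at the given quantile
    of its merge heights, yielding candidate cluster cores (clusters of at
    least ``core_size`` members).  When the data matrix ``m`` is supplied
    the cores are then refined, which is strongly recommended at small
    sample sizes where module fragments and chance correlations are common:

    1. cores whose between/within mean-|r| ratio exceeds
       ``merge_ratio_min`` are merged (fragments of one underlying module
       reunite regardless of how strongly its factor was realized);
    2. every feature is reassigned to the module whose eigengene it
       correlates with best, kept only when that |kME| reaches
       ``kme_min``;
    steps 1-2 are repeated ``refine_cycles`` times.

    Clusters smaller than ``min_size`` end up "grey" (unassigned), and the
    survivors are named from :data:`MODULE_COLORS` in decreasing size
    order, ties broken by the lexicographically smallest member ID.  With
    ``m=None`` (or ``refine_cycles=0``) the partition is the plain static
    tree cut.
    """
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    if not 0 < cut_height_quantile <= 1:
        raise ValueError("cut_height_quantile must lie in (0, 1]")
    absr = np.abs(net.r.to_numpy(float))
    absr = np.nan_to_num(absr, nan=0.0)
    np.fill_diagonal(absr, 1.0)
    d = np.clip(1.0 - absr, 0.0, None)
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    Z = hierarchy.linkage(squareform(d, checks=False), method="average")
    cut = float(np.quantile(Z[:, 2], cut_height_quantile))
    raw = hierarchy.fcluster(Z, t=cut, criterion="distance")
    mods = {
        lab: list(np.nonzero(raw == lab)[0])
        for lab in np.unique(raw)
        if (raw == lab).sum() >= core_size
    }
    if m is not None and refine_cycles > 0:
        X = m.values.reindex(net.features).to_numpy(float)
        for _ in range(refine_cycles):
            if not mods:
                break
            mods = _merge_correlated_clusters(absr, mods, merge_ratio_min)
            mods = _kme_reassign(X, mods, kme_min, core_size)
    feats = net.features
    assignments = pd.Series(GREY, index=feats, dtype=object)
    clusters = []
    for lab, idx in mods.items():
        members = feats[idx]
        if len(members) >= min_size:
            clusters.append((len(members), min(members), members))
    clusters.sort(key=lambda t: (-t[0], t[1]))
    for i, (_, _, members) in enumerate(clusters):
        color = MODULE_COLORS[i] if i < len(MODULE_COLORS) else f"module{i + 1}"
        assignments.loc[members] = color
    return ModulePartition(
        assignments=assignments,
        linkage=Z,
        cut_height=cut,
        params={
            "min_size": min_size,
            "cut_height_quantile": cut_height_quantile,
            "merge_ratio_min": merge_ratio_min,
            "kme_min": kme_min,
            "core_size": core_size,
            "refine_cycles": refine_cycles if m is not None else 0,
        },
    )


def module_eigengene(m: OmicsMatrix, members) -> pd.Series:
    """First principal component of a module's feature-by-sample submatrix.

    Returns a per-sample profile (the leading right-singular vector), scaled
    to unit standard deviation across samples and sign-oriented so that the
    mean correlation with the member profiles is non-negative.
    """
    members = list(members)
    if len(members) < 2:
        raise ValueError("module eigengene needs >= 2 members")
    missing = [f for f in members if f not in m.features]
    if missing:
        raise KeyError(f"members absent from matrix: {missing}")
    X = m.values.loc[members].to_numpy(float)
    X = np.nan_to_num(X - np.nanmean(X, axis=1, keepdims=True))
    _, _, vt = np.linalg.svd(X, full_matrices=False)
    e = vt[0]
    sd = e.std(ddof=1)
    if sd > 0:
        e = (e - e.mean()) / sd
    with np.errstate(invalid="ignore"):
        cors = [np.corrcoef(row, e)[0, 1] for row in X]
    if np.nanmean(cors) < 0:
        e = -e
    return pd.Series(e, index=m.samples, name="eigengene")


def eigengene_set(m: OmicsMatrix, partition: ModulePartition) -> pd.DataFrame:
    """Eigengenes of every non-grey module: modules as rows, samples as columns."""
    rows = {}
    for mod in partition.modules():
        rows[mod] = module_eigengene(m, partition.members(mod))
    return pd.DataFrame(rows).T.reindex(columns=m.samples)


def export_edges(net: CorrelationNetwork, path, min_abs_r: float = 0.5) -> pd.DataFrame:
    """Write the network as an edge list TSV (feature_i, feature_j, r, a),
    keeping edges with |r| >= ``min_abs_r``.  Returns the exported frame."""
    if net.a is None:
        raise ValueError("adjacency not computed; call adjacency() first")
    r = net.r.to_numpy(float)
    iu = np.triu_indices_from(r, k=1)
    keep = np.abs(r[iu]) >= min_abs_r
    edges = pd.DataFrame(
        {
            "feature_i": net.features[iu[0][keep]],
            "feature_j": net.features[iu[1][keep]],
            "r": r[iu][keep],
            "a": net.a.to_numpy()[iu][keep],
        }
    )
    edges.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return edges


def intramodular_connectivity(net: CorrelationNetwork, partition: ModulePartition) -> pd.Series:
    """kWithin(i): sum of adjacency from feature i to its module co-members.

    Grey features get their within-grey sums too, but are never hub
    candidates downstream.
    """
    if net.a is None:
        raise ValueError("adjacency not computed; call adjacency() first")
    labels = partition.assignments.reindex(net.features)
    a = net.a.to_numpy(float)
    k = np.zeros(len(net.features))
    codes, uniq = pd.factorize(labels)
    for gi in range(len(uniq)):
        idx = np.nonzero(codes == gi)[0]
        sub = a[np.ix_(idx, idx)]
        k[idx] = sub.sum(axis=1)
    return pd.Series(k, index=net.features, name="kWithin")
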