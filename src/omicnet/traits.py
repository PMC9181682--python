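"""Module-trait correlation and hub identification.

Every module eigengene is correlated (Pearson) against every phenotype
trait; the 0/1 strain indicator makes that a point-biserial correlation.
Significance uses the Student-t transform t = r sqrt(n-2) / sqrt(1-r^2)
with n-2 degrees of freedom, two-sided — the standard analytic p for a
correlation coefficient.  A permutation p-value is available as a
cross-check mode.

The hub of a module is the member that is simultaneously most connected
(largest kWithin) and most significantly correlated with the module
eigengene (smallest kME p).  The two criteria are combined by rank sum;
ties fall back to the smaller kME p, then the lexicographically smallest
feature ID.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .containers import OmicsMatrix
from .network import CorrelationNetwork, ModulePartition

logger = logging.getLogger(__name__)

__all__ = [
    "pearson_with_p",
    "permutation_p",
    "module_trait_matrix",
    "find_hub",
]


def pearson_with_p(x, y) -> tuple:
    """Pearson r and two-sided analytic p over complete pairs.

    Requires >= 4 complete pairs.  A constant vector makes r undefined:
    (nan, nan) is returned.  |r| = 1 is reported with p = 0.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = x.size
    if n < 4:
        raise ValueError(f"need >= 4 complete pairs, got {n}")
    if x.std() == 0 or y.std() == 0:
        return np.nan, np.nan
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if 1.0 - abs(r) < 1e-12:  # numerically perfect correlation
        return float(np.sign(r)), 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return r, float(p)


def permutation_p(x, y, n_perm: int = 10000, seed: int = 0) -> float:
    """Two-sided permutation p for the Pearson correlation (cross-check mode)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    r_obs = abs(np.corrcoef(x, y)[0, 1])
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        r = np.corrcoef(x, rng.permutation(y))[0, 1]
        if abs(r) >= r_obs - 1e-12:
            hits += 1
    return (1 + hits) / (n_perm + 1)


def module_trait_matrix(eigengenes: pd.DataFrame, traits: pd.DataFrame) -> pd.DataFrame:
    """Full (module x trait) grid of Pearson r and analytic p.

    ``eigengenes``: modules as rows, samples as columns.  ``traits``:
    samples as rows, traits as columns.  Only shared samples are used
    (>= 4 required).  Returns a long-format frame (module, trait, r, p, n).
    """
    shared = [s for s in eigengenes.columns if s in traits.index]
    if len(shared) < 4:
        raise ValueError(
            f"need >= 4 shared samples between eigengenes and traits, got {len(shared)}"
        )
    rows = []
    for mod in eigengenes.index:
        e = eigengenes.loc[mod, shared].to_numpy(float)
        for tr in traits.columns:
            y = traits.loc[shared, tr].to_numpy(float)
            ok = ~(np.isnan(e) | np.isnan(y))
            if ok.sum() < 4:
                r, p = np.nan, np.nan
            else:
                r, p = pearson_with_p(e[ok], y[ok])
            rows.append({"module": mod, "trait": tr, "r": r, "p": p, "n": int(ok.sum())})
    return pd.DataFrame(rows)


def module_trait_grid(long: pd.DataFrame, value: str = "r") -> pd.DataFrame:
    """Pivot the long-format module-trait table to a modules x traits grid."""
    return long.pivot(index="module", columns="trait", values=value)


def find_hub(
    net: CorrelationNetwork,
    partition: ModulePartition,
    eigengenes: pd.DataFrame,
    m: OmicsMatrix,
) -> pd.DataFrame:
    """Identify each non-grey module's central regulatory hub.

    Members are ranked by kWithin (descending) and by kME p (ascending);
    the hub minimizes the rank sum, ties resolved by smaller kME p, then by
    lexicographically smallest feature ID.  Modules of size < 3 are reported
    with ``low_confidence=True``.
    """
    from .network import intramodular_connectivity

    mods = partition.modules()
    if not mods:
        raise ValueError("no non-grey modules in partition")
    kwithin = intramodular_connectivity(net, partition)
    rows = []
    for mod in mods:
        members = partition.members(mod)
        e = eigengenes.loc[mod]
        stats_rows = []
        for f in members:
            x = m.values.loc[f].to_numpy(float)
            y = e.reindex(m.samples).to_numpy(float)
            ok = ~(np.isnan(x) | np.isnan(y))
            if ok.sum() >= 4:
                kme, kme_p = pearson_with_p(x[ok], y[ok])
            else:
                kme, kme_p = np.nan, np.nan
            stats_rows.append((f, kwithin[f], kme, kme_p))
        df = pd.DataFrame(stats_rows, columns=["feature", "kWithin", "kME", "kME_p"])
        df["rank_k"] = df["kWithin"].rank(ascending=False, method="average")
        df["rank_p"] = df["kME_p"].rank(ascending=True, method="average", na_option="bottom")
        df["rank_sum"] = df["rank_k"] + df["rank_p"]
        df = df.sort_values(
            ["rank_sum", "kME_p", "feature"], na_position="last", kind="stable"
        )
        best = df.iloc[0]
        rows.append(
            {
                "module": mod,
                "hub": best["feature"],
                "kWithin": best["kWithin"],
                "kME": best["kME"],
                "kME_p": best["kME_p"],
                "rank_sum": best["rank_sum"],
                "module_size": len(members),
                "low_confidence": len(members) < 3,
            }
        )
    return pd.DataFrame(rows).set_index("module")
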