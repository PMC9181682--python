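"""Pathway annotation of modules and quantitative pathway-level testing.

Two complementary analyses over user-supplied GMT pathway sets (which may
mix proteins and metabolites in one set, enabling a joint multi-omic query):

* over-representation (ORA): hypergeometric upper-tail test of the overlap
  between a query feature set (e.g. one module's members) and each pathway
  set, within an explicit universe, BH-corrected across sets;
* a down-weighted quantitative score in the PADOG style: features occurring
  in many sets are down-weighted (w = 1 + sqrt((f_max - f)/(f_max - f_min))),
  each set is scored by the weighted mean absolute moderated t of its
  members, and significance comes from a group-label permutation null with
  per-permutation re-scoring and across-set standardization;
* a direction-of-change summary: the unweighted mean member log2
  fold-change, positive = pathway up in the case group.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import OmicsMatrix
from .differential import bh_adjust, moderated_t
from .overlap import overlap_log10_p

logger = logging.getLogger(__name__)

__all__ = [
    "ora_hypergeometric",
    "padog_weights",
    "padog_like_score",
    "pathway_direction",
]


def ora_hypergeometric(query, db: dict, universe) -> pd.DataFrame:
    """Over-representation of ``query`` in each pathway set, within ``universe``.

    Sets are intersected with the universe first; sets retaining < 2 universe
    members are skipped.  Returns a frame indexed by set name with columns
    overlap, set_size, expected, p, neg_log10_p, q — sorted by p then name.
    """
    query = set(query)
    universe = set(universe)
    stray = sorted(query - universe)
    if stray:
        raise ValueError(f"query features outside the universe: {stray[:10]}")
    N, n = len(universe), len(query)
    rows = []
    for name in sorted(db):
        members = set(db[name]) & universe
        K = len(members)
        if K < 2:
            logger.warning("ora: skipping set %r (<2 universe members)", name)
            continue
        k = len(members & query)
        l10 = overlap_log10_p(k, n, K, N)
        rows.append(
            {
                "set": name,
                "overlap": k,
                "set_size": K,
                "expected": n * K / N,
                "p": min(10.0**l10, 1.0),
                "neg_log10_p": -l10,
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["overlap", "set_size", "expected", "p", "neg_log10_p", "q"]
        )
    out = pd.DataFrame(rows).set_index("set")
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out.sort_values(["p", "set"], kind="stable")


def padog_weights(db: dict) -> pd.Series:
    """Down-weighting by set-occurrence frequency.

    f_g = number of sets containing feature g; w_g = 1 + sqrt((f_max - f_g)
    / (f_max - f_min)).  When every feature occurs in the same number of
    sets, all weights are 1.
    """
    freq: dict = {}
    for members in db.values():
        for g in set(members):
            freq[g] = freq.get(g, 0) + 1
    f = pd.Series(freq, dtype=float)
    fmax, fmin = f.max(), f.min()
    if fmax == fmin:
        return pd.Series(1.0, index=f.index)
    return 1.0 + np.sqrt((fmax - f) / (fmax - fmin))


def _set_scores(abs_t: pd.Series, w: pd.Series, sets: dict) -> np.ndarray:
    wt = (w * abs_t).dropna()
    return np.array([wt.reindex(members).mean() for members in sets.values()])


def padog_like_score(
    m: OmicsMatrix,
    groups,
    db: dict,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Down-weighted quantitative pathway scores with a permutation null.

    Per set: score = mean over quantified members of w_g * |moderated t_g|.
    Group labels are permuted ``n_perm`` times with full re-scoring; scores
    are standardized across sets within each permutation (skipped if only
    one set survives) and the per-set p is
    (1 + #{permuted >= observed}) / (n_perm + 1).  Deterministic for a
    fixed seed.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    groups = pd.Series(groups).reindex(m.samples)
    quantified = set(m.features)
    sets = {}
    for name in sorted(db):
        members = sorted(set(db[name]) & quantified)
        if members:
            sets[name] = members
        else:
            logger.warning("padog: skipping set %r (no quantified members)", name)
    if not sets:
        raise ValueError("no pathway set has quantified members")
    w = padog_weights(db)

    def score_for(labels: pd.Series) -> np.ndarray:
        tp = moderated_t(m, labels)
        return _set_scores(tp["t"].abs(), w, sets)

    obs = score_for(groups)
    rng = np.random.default_rng(seed)
    label_values = groups.to_numpy()
    perm = np.empty((n_perm, len(sets)))
    for i in range(n_perm):
        shuffled = pd.Series(rng.permutation(label_values), index=m.samples)
        perm[i] = score_for(shuffled)

    def standardize(row: np.ndarray) -> np.ndarray:
        if row.size < 2:
            return row
        sd = row.std(ddof=1)
        return (row - row.mean()) / sd if sd > 0 else row - row.mean()

    obs_z = standardize(obs)
    perm_z = np.apply_along_axis(standardize, 1, perm)
    hits = (perm_z >= obs_z[None, :] - 1e-12).sum(axis=0)
    p = (1 + hits) / (n_perm + 1)
    out = pd.DataFrame(
        {
            "score": obs,
            "z": obs_z,
            "p": p,
            "n_members": [len(v) for v in sets.values()],
        },
        index=pd.Index(sets.keys(), name="set"),
    )
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out.sort_values(["p", "set"], kind="stable")


def pathway_direction(diff: pd.DataFrame, db: dict) -> pd.Series:
    """Unweighted mean member log2FC per pathway set.

    ``diff`` must carry a ``log2FC`` column indexed by feature.  Sets with
    no quantified member are reported missing (NaN).
    """
    lfc = diff["log2FC"]
    out = {}
    for name in sorted(db):
        members = [g for g in set(db[name]) if g in lfc.index]
        out[name] = float(lfc.loc[members].mean()) if members else np.nan
    return pd.Series(out, name="mean_log2FC")
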