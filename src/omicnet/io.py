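"""Plain-text readers and writers for every pipeline artifact.

Formats: feature-by-sample matrices and trait tables as TSV, pathway sets
as GMT (set name, description, tab-separated members), ground truth and run
manifests as JSON.  Empty TSV cells are missing values, never zeros.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import OmicsMatrix, make_matrix, validate_traits

logger = logging.getLogger(__name__)

__all__ = [
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_traits_tsv",
    "write_traits_tsv",
    "read_gmt",
    "write_gmt",
]

FLOAT_FORMAT = "%.10g"


class ParseError(ValueError):
    """Malformed input file; message carries the offending line number."""


def read_matrix_tsv(path, layer: str, scale: str = "raw") -> OmicsMatrix:
    """Read a feature-by-sample TSV (first column = feature ID, header row =
    sample IDs; empty cells = missing) into a single-layer matrix."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        n_cols = len(header)
        samples = header[1:]
        feats, rows = [], []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != n_cols:
                raise ParseError(
                    f"{path}:{lineno}: expected {n_cols} fields, got {len(parts)}"
                )
            feats.append(parts[0])
            vals = []
            for j, cell in enumerate(parts[1:], start=2):
                if cell == "":
                    vals.append(np.nan)
                else:
                    try:
                        vals.append(float(cell))
                    except ValueError:
                        raise ParseError(
                            f"{path}:{lineno}: non-numeric cell {cell!r} in column {j}"
                        ) from None
            rows.append(vals)
    idx = pd.Index(feats, name="feature")
    if idx.has_duplicates:
        dup = idx[idx.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate feature IDs: {dup}")
    values = pd.DataFrame(rows, index=idx, columns=samples)
    return make_matrix(values, layer=layer, scale=scale)


def write_matrix_tsv(m: OmicsMatrix, path) -> None:
    out = m.values.copy()
    out.index.name = "feature"
    out.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, na_rep="")


def read_traits_tsv(path) -> pd.DataFrame:
    """Trait table TSV: samples as rows (first column = sample ID)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return validate_traits(df)


def write_traits_tsv(traits: pd.DataFrame, path) -> None:
    out = traits.copy()
    out.index.name = "sample"
    out.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_gmt(path) -> dict:
    """Parse a GMT file into {set name: member list}.

    Duplicate members within a set are deduplicated with a warning;
    duplicate set names or lines with fewer than 3 tab-separated fields are
    errors carrying the line number.
    """
    db: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields"
                )
            name, _desc, *members = parts
            members = [g for g in members if g]
            if name in db:
                raise ParseError(f"{path}:{lineno}: duplicate set name {name!r}")
            deduped = list(dict.fromkeys(members))
            if len(deduped) != len(members):
                logger.warning("read_gmt: %s:%d: duplicate members in set %r deduplicated",
                               path, lineno, name)
            db[name] = deduped
    return db


def write_gmt(db: dict, path, descriptions: dict | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name in db:
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *db[name]]) + "\n")
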