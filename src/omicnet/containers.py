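"""Core in-memory containers shared by every pipeline stage.

An :class:`OmicsMatrix` is a feature-by-sample abundance table (proteins or
metabolite peaks, or both after concatenation) together with a per-feature
layer tag and a scale tag recording how far along the normalization chain
(raw -> log2 -> quantile -> unit-variance) the values are.  Values are floats
with NaN for missing observations (mass-spec dropouts).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

PROTEIN = "protein"
METABOLITE = "metabolite"
LAYERS = (PROTEIN, METABOLITE)

#: Allowed scale tags, in the only order transitions may occur.
SCALE_ORDER = ("raw", "log2", "quantile", "unit-variance")


@dataclass
class OmicsMatrix:
    """Feature-by-sample abundance matrix with layer and scale metadata.

    Parameters
    ----------
    values
        DataFrame with unique feature IDs as index and unique sample IDs as
        columns; entries are floats, NaN = missing.
    layers
        Per-feature layer tag, aligned with ``values.index``; each entry is
        ``"protein"`` or ``"metabolite"``.
    scale
        One of :data:`SCALE_ORDER`.
    """

    values: pd.DataFrame
    layers: pd.Series
    scale: str = "raw"

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            dup = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature IDs: {dup}")
        if not self.values.columns.is_unique:
            dup = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs: {dup}")
        if self.scale not in SCALE_ORDER:
            raise ValueError(f"unknown scale tag {self.scale!r}; expected one of {SCALE_ORDER}")
        self.layers = pd.Series(self.layers).reindex(self.values.index)
        if self.layers.isna().any():
            missing = self.layers.index[self.layers.isna()].tolist()
            raise ValueError(f"features without a layer tag: {missing}")
        bad = sorted(set(self.layers.unique()) - set(LAYERS))
        if bad:
            raise ValueError(f"unknown layer tags {bad}; expected {LAYERS}")
        self.values = self.values.astype(float)

    # -- convenience -------------------------------------------------------

    @property
    def features(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: pd.DataFrame, scale: str | None = None) -> "OmicsMatrix":
        """Return a copy holding ``values`` (features may be a subset)."""
        return OmicsMatrix(
            values=values,
            layers=self.layers.reindex(values.index),
            scale=self.scale if scale is None else scale,
        )

    def subset_samples(self, samples) -> "OmicsMatrix":
        return self.with_values(self.values.loc[:, list(samples)])

    def require_scale(self, *allowed: str) -> None:
        if self.scale not in allowed:
            raise ValueError(
                f"operation requires scale in {allowed}, got {self.scale!r}"
            )


def make_matrix(values: pd.DataFrame, layer: str, scale: str = "raw") -> OmicsMatrix:
    """Build a single-layer :class:`OmicsMatrix` tagging every feature ``layer``."""
    layers = pd.Series(layer, index=values.index)
    return OmicsMatrix(values=values, layers=layers, scale=scale)


#: Canonical trait columns emulating the study design: a 0/1 strain
#: indicator, two seizure traits (zero in controls by construction) and two
#: behavioral read-outs.
TRAIT_COLUMNS = (
    "strain",
    "seizure_count",
    "mean_seizure_duration",
    "time_in_center",
    "sucrose_preference",
)


def validate_traits(traits: pd.DataFrame) -> pd.DataFrame:
    """Check a trait table: unique sample index, all-numeric, finite strain 0/1."""
    if not traits.index.is_unique:
        raise ValueError("duplicate sample IDs in trait table")
    out = traits.astype(float)
    if "strain" in out.columns:
        vals = set(out["strain"].dropna().unique().tolist())
        if not vals <= {0.0, 1.0}:
            raise ValueError(f"strain column must be 0/1-valued, got {sorted(vals)}")
    return out
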