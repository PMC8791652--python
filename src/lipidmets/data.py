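"""Core in-memory container for abundance data.

An :class:`AbundanceMatrix` is a features x samples concentration table
with per-sample binary group labels (MetS / no-MetS) and a ``scale`` tag
recording where the matrix sits in the preprocessing chain
(``raw`` -> ``median_centered`` -> ``log``).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = ["AbundanceMatrix"]

_SCALES = ("raw", "median_centered", "log")


@dataclass
class AbundanceMatrix:
    """Features x samples concentration table with group labels.

    Attributes
    ----------
    values:
        DataFrame, index = feature ids, columns = sample ids.
    group:
        Per-sample binary labels aligned with ``values.columns``;
        1 = MetS, 0 = no-MetS.
    scale:
        One of ``"raw"``, ``"median_centered"``, ``"log"``.
    """

    values: pd.DataFrame
    group: pd.Series
    scale: str = "raw"

    def __post_init__(self) -> None:
        if self.scale not in _SCALES:
            raise ValueError(f"scale must be one of {_SCALES}, got {self.scale!r}")
        if not self.values.index.is_unique:
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate feature ids: {dupes[:5]}")
        self.group = pd.Series(self.group).reindex(self.values.columns)
        if self.group.isna().any():
            missing = self.group.index[self.group.isna()].tolist()
            raise ValueError(f"group label missing for samples: {missing[:5]}")
        self.group = self.group.astype(int)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: pd.DataFrame, scale: str | None = None) -> "AbundanceMatrix":
        return replace(self, values=values, scale=scale or self.scale)

    def subset_features(self, keep) -> "AbundanceMatrix":
        return self.with_values(self.values.loc[list(keep)])

    def to_csv(self, path, sep: str = "\t") -> None:
        """Write features-in-rows table, first column = feature id."""
        self.values.rename_axis("feature_id").to_csv(path, sep=sep)

    @classmethod
    def from_csv(cls, path, group: pd.Series, scale: str = "raw", sep: str = "\t") -> "AbundanceMatrix":
        values = pd.read_csv(path, sep=sep, index_col=0)
        return cls(values=values, group=group, scale=scale)

    def concat(self, other: "AbundanceMatrix") -> "AbundanceMatrix":
        """Stack two matrices over the same samples (e.g. lipids + metabolites)."""
        if list(other.values.columns) != list(self.values.columns):
            raise ValueError("sample ids differ between matrices")
        if self.scale != other.scale:
            raise ValueError(f"scale mismatch: {self.scale} vs {other.scale}")
        vals = pd.concat([self.values, other.values], axis=0)
        return AbundanceMatrix(values=vals, group=self.group, scale=self.scale)

    def zscores(self) -> pd.DataFrame:
        """Per-feature z-scored values (ddof=1); constant features give 0."""
        v = self.values
        sd = v.std(axis=1, ddof=1).replace(0.0, np.nan)
        z = v.sub(v.mean(axis=1), axis=0).div(sd, axis=0)
        return z.fillna(0.0)
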