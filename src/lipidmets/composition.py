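"""Structural composition maps of the group effect.

Organizes per-species differential statistics into per-class matrices
indexed by lipid size (total acyl carbons) and saturation (total double
bonds), the layout used for structural heatmaps: each (class, carbons,
double-bonds) cell aggregates the species mapping there — mean log-scale
effect, minimum FDR-adjusted q, and a significance flag at a configurable
cut (default FDR < 0.01).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .nomenclature import LipidSpecies

__all__ = ["CompositionMap", "composition_map", "class_trend_summary"]


@dataclass
class CompositionMap:
    """Long-format cell table: class, carbons, double_bonds, effect, q,
    significant, n_species."""

    cells: pd.DataFrame
    q_cut: float

    def for_class(self, lipid_class: str) -> pd.DataFrame:
        """Wide effect matrix (carbons x double bonds) for one class."""
        sub = self.cells[self.cells["class"] == lipid_class]
        return sub.pivot(index="carbons", columns="double_bonds", values="effect")

    def to_tsv(self, path) -> None:
        self.cells.to_csv(path, sep="\t", index=False)


def composition_map(
    stats: pd.DataFrame, species: list[LipidSpecies], q_cut: float = 0.01
) -> CompositionMap:
    """Aggregate per-species moderated statistics into (class, C, DB) cells.

    ``stats`` must be indexed by feature name with columns ``beta`` and
    ``q``; every species must be present. Cell effect is the mean beta of
    member species; cell q is the minimum member q (a cell is significant
    when its best species passes the cut).
    """
    missing = [sp.name for sp in species if sp.name not in stats.index]
    if missing:
        raise ValueError(f"species absent from stats: {missing[:5]}")
    rows = []
    for sp in species:
        rows.append(
            {
                "class": sp.lipid_class,
                "carbons": sp.total_carbons,
                "double_bonds": sp.total_double_bonds,
                "beta": float(stats.loc[sp.name, "beta"]),
                "q": float(stats.loc[sp.name, "q"]),
            }
        )
    df = pd.DataFrame(rows)
    cells = (
        df.groupby(["class", "carbons", "double_bonds"], as_index=False)
        .agg(effect=("beta", "mean"), q=("q", "min"), n_species=("q", "size"))
    )
    cells["significant"] = cells["q"] < q_cut
    return CompositionMap(cells=cells, q_cut=q_cut)


def class_trend_summary(cmap: CompositionMap) -> pd.DataFrame:
    """Per-class direction of the significant cells.

    Classes without significant cells are omitted. Direction is
    ``increase``/``decrease`` when at least two-thirds of significant cells
    share the sign, else ``mixed``.
    """
    rows = []
    for cls, sub in cmap.cells.groupby("class"):
        sig = sub[sub["significant"]]
        if sig.empty:
            continue
        pos = (sig["effect"] > 0).mean()
        neg = (sig["effect"] < 0).mean()
        if pos >= 2 / 3:
            direction = "increase"
        elif neg >= 2 / 3:
            direction = "decrease"
        else:
            direction = "mixed"
        rows.append(
            {
                "class": cls,
                "direction": direction,
                "fraction_significant": len(sig) / len(sub),
                "n_significant_cells": len(sig),
            }
        )
    return pd.DataFrame(rows, columns=["class", "direction", "fraction_significant",
                                       "n_significant_cells"])
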