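"""Parsing of complex-lipid-panel shorthand names.

Commercial lipid panels report species in a compact shorthand such as
``TAG(52:2)-FA(16:0)``, ``DAG(16:0/18:1)``, ``SM(d18:1/16:0)`` or
``CE(18:2)``.  The name encodes the lipid class, the total number of acyl
carbons, the total number of carbon-carbon double bonds and, for some
classes, individually annotated fatty-acyl chains.  This module turns such
names into structured :class:`LipidSpecies` records and rolls classes up
into the four biochemical categories (glycerolipids, glycerophospholipids,
sphingolipids, steroids) used throughout the analysis.

Three syntactic forms are recognised:

``CLS(c:d)``
    acyl-sum form: *c* total carbons, *d* total double bonds.
``CLS(a:x/b:y[/...])``
    enumerated acyls: totals are the sums over chains.  A leading ``d`` (or
    ``t``) on the first chain marks a sphingoid long-chain base; the prefix
    is stripped and the base is summed like any other chain.
``TAG(c:d)-FA(f:g)``
    neutral-loss form: totals come from the parent ion, the single annotated
    fatty acid ``(f, g)`` from the neutral loss.

Unknown class prefixes degrade to ``lipid_class="other"`` /
``category="other"`` so that panels with extra classes still parse.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "LipidSpecies",
    "LipidParseError",
    "DEFAULT_CLASS_CATEGORIES",
    "parse_lipid_name",
    "summarize_categories",
    "write_feature_metadata",
]


class LipidParseError(ValueError):
    """Raised when a lipid name has no parsable ``(c:d)`` motif."""

    def __init__(self, name: str, reason: str = "no parsable '(c:d)' motif"):
        self.name = name
        super().__init__(f"cannot parse lipid name {name!r}: {reason}")


#: Default mapping of shorthand class prefix -> biochemical category.
#: Extensible: pass an augmented copy as ``class_categories`` to the parser.
DEFAULT_CLASS_CATEGORIES: Mapping[str, str] = {
    "TAG": "glycerolipid",
    "DAG": "glycerolipid",
    "MAG": "glycerolipid",
    "PC": "glycerophospholipid",
    "PE": "glycerophospholipid",
    "PI": "glycerophospholipid",
    "LPC": "glycerophospholipid",
    "LPE": "glycerophospholipid",
    "CER": "sphingolipid",
    "DCER": "sphingolipid",
    "HCER": "sphingolipid",
    "LCER": "sphingolipid",
    "SM": "sphingolipid",
    "CE": "steroid",
    "FFA": "other",
}


@dataclass(frozen=True)
class LipidSpecies:
    """Structured identity of one lipid species.

    Attributes
    ----------
    name:
        The verbatim input name.
    lipid_class:
        Shorthand class prefix (``TAG``, ``SM``, ...) or ``"other"``.
    category:
        Biochemical category implied by the class.
    total_carbons, total_double_bonds:
        Summed acyl-chain carbons / double bonds.
    annotated_fas:
        Individually annotated fatty acids as ``(carbons, double_bonds)``
        pairs; empty for acyl-sum names.
    """

    name: str
    lipid_class: str
    category: str
    total_carbons: int
    total_double_bonds: int
    annotated_fas: tuple[tuple[int, int], ...] = field(default_factory=tuple)


_CHAIN = re.compile(r"^[dtme]?(\d+):(\d+)(?:\([^)]*\))?$")
_NAME = re.compile(r"^([A-Za-z0-9]+)\(([^)]+)\)(?:-FA\((\d+):(\d+)\))?$")


def _parse_chain(token: str, name: str) -> tuple[int, int]:
    m = _CHAIN.match(token.strip())
    if m is None:
        raise LipidParseError(name, f"unparsable chain token {token!r}")
    return int(m.group(1)), int(m.group(2))


def parse_lipid_name(
    name: str,
    class_categories: Mapping[str, str] = DEFAULT_CLASS_CATEGORIES,
) -> LipidSpecies:
    """Parse one shorthand lipid name into a :class:`LipidSpecies`.

    Parameters
    ----------
    name:
        Shorthand name, e.g. ``"TAG(52:2)-FA(16:0)"``.
    class_categories:
        Class-prefix -> category table; unknown prefixes map to ``"other"``.

    Raises
    ------
    LipidParseError
        If no ``(c:d)`` motif can be extracted.
    """
    if not name or not name.strip():
        raise LipidParseError(name, "empty name")
    m = _NAME.match(name.strip())
    if m is None:
        raise LipidParseError(name)
    prefix, inner, fa_c, fa_db = m.groups()
    cls = prefix.upper()
    if cls not in class_categories:
        cls_out, category = "other", "other"
    else:
        cls_out, category = cls, class_categories[cls]

    chains = [_parse_chain(tok, name) for tok in inner.split("/")]
    if fa_c is not None:
        # neutral-loss form: totals from the parent, one annotated acyl
        if len(chains) != 1:
            raise LipidParseError(name, "neutral-loss form with enumerated acyls")
        total_c, total_db = chains[0]
        fas = ((int(fa_c), int(fa_db)),)
        if fas[0][0] > total_c or fas[0][1] > total_db:
            raise LipidParseError(name, "annotated FA exceeds parent totals")
    elif len(chains) == 1:
        total_c, total_db = chains[0]
        fas = ()
    else:
        total_c = sum(c for c, _ in chains)
        total_db = sum(d for _, d in chains)
        fas = tuple(chains)
    return LipidSpecies(
        name=name,
        lipid_class=cls_out,
        category=category,
        total_carbons=total_c,
        total_double_bonds=total_db,
        annotated_fas=fas,
    )


def summarize_categories(
    names: Iterable[str],
    class_categories: Mapping[str, str] = DEFAULT_CLASS_CATEGORIES,
) -> dict[str, int]:
    """Count parsed lipid names per biochemical category.

    Propagates parse failures with the position of the offending name.
    """
    counts: Counter[str] = Counter()
    for i, name in enumerate(names):
        try:
            sp = parse_lipid_name(name, class_categories)
        except LipidParseError as exc:
            raise LipidParseError(name, f"at index {i}: {exc}") from exc
        counts[sp.category] += 1
    return dict(counts)


def write_feature_metadata(names: Sequence[str], path) -> None:
    """Write a feature-metadata TSV: name, class, category, carbons, double bonds."""
    import pandas as pd

    rows = []
    for n in names:
        sp = parse_lipid_name(n)
        rows.append(
            {
                "name": sp.name,
                "class": sp.lipid_class,
                "category": sp.category,
                "total_carbons": sp.total_carbons,
                "total_double_bonds": sp.total_double_bonds,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
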