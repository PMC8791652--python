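"""Synthetic cohort generator.

Emulates a two-group (MetS vs no-MetS, 100 + 100 samples) plasma lipidome
of 917 species — 602 glycerolipids, 228 glycerophospholipids, 61
sphingolipids, 26 steroids — plus an 11-metabolite panel and a 13-variable
clinical table, with known ground truth:

* concentrations are multiplicative log-normal; the group effect is an
  additive shift on the log2 scale applied to a planted subset of DAG/TAG
  species (mirroring the up-shift of glycerolipids under MetS);
* a Gaussian-copula block ties the planted lipids to a glutamate-pathway-like
  metabolite sub-block, and a second all-lipid block provides a further
  network community;
* below-limit-of-detection missingness is MNAR at the low end: the smallest
  draws of a feature are zeroed;
* the clinical table reproduces the marginal composition of the cohort
  (90% male, mean age ~54.5, VAT/SAT shifted upward under MetS, ART-class
  exposure rates per group).

Everything is a pure function of ``(CohortConfig, seed)``.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import AbundanceMatrix
from .nomenclature import parse_lipid_name

__all__ = ["CohortConfig", "SyntheticCohort", "generate_lipid_names", "generate_cohort"]

DEFAULT_CATEGORY_COUNTS = {
    "glycerolipid": 602,
    "glycerophospholipid": 228,
    "sphingolipid": 61,
    "steroid": 26,
}

#: The 11-metabolite panel taken as given input (key metabolites of the
#: matched metabolomics analysis). The first six form the correlated
#: glutamate-pathway-like sub-block.
METABOLITE_NAMES = [
    "glutamate",
    "4-hydroxyglutamate",
    "alpha-ketoglutarate",
    "gamma-glutamylglutamate",
    "glycerate",
    "isoleucine",
    "1-carboxyethylisoleucine",
    "4-cholesten-3-one",
    "carotene diol (2)",
    "PC/3-MAPC",
    "PSP",
]


@dataclass(frozen=True)
class CohortConfig:
    """Generator configuration; defaults define the emulated study conditions."""

    n_per_group: int = 100
    category_counts: dict = field(default_factory=lambda: dict(DEFAULT_CATEGORY_COUNTS))
    n_metabolites: int = 11
    effect_fraction: float = 0.05  # fraction of DAG/TAG species planted
    effect_log2fc: float = 1.0  # planted log2 fold change (MetS - no-MetS)
    noise_sd: float = 0.5  # residual sd on the log2 scale
    block_correlation: float = 0.5  # within-block pairwise correlation
    missing_rate: float = 0.02  # expected below-LOD zero fraction
    seed: int = 0

    def __post_init__(self):
        for name in ("effect_fraction", "block_correlation", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0 + (name == "effect_fraction") * 1e-12:
                raise ValueError(f"{name} must lie in [0, 1): got {v}")
        if self.n_per_group <= 0 or self.n_metabolites <= 0:
            raise ValueError("counts must be positive")
        if any(c <= 0 for c in self.category_counts.values()):
            raise ValueError("category counts must be positive")


@dataclass
class SyntheticCohort:
    """Generated cohort: abundance matrices, clinical table and ground truth."""

    lipids: AbundanceMatrix
    metabolites: AbundanceMatrix
    clinical: pd.DataFrame  # samples x 13 variables
    truth: set  # planted differential feature names
    config: CohortConfig

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.lipids.to_csv(outdir / "lipids.tsv")
        self.metabolites.to_csv(outdir / "metabolites.tsv")
        self.clinical.rename_axis("sample_id").to_csv(outdir / "clinical.tsv", sep="\t")
        (outdir / "truth.json").write_text(json.dumps(sorted(self.truth), indent=1))


# ---------------------------------------------------------------------------
# name generation

_COMMON_FA = [(14, 0), (16, 0), (16, 1), (18, 0), (18, 1), (18, 2), (18, 3),
              (20, 2), (20, 3), (20, 4), (22, 5), (22, 6)]


def _tag_candidates():
    for c in range(40, 61):
        for d in range(0, 9):
            for fc, fd in _COMMON_FA:
                if fc <= c - 28 and fd <= d:
                    yield f"TAG({c}:{d})-FA({fc}:{fd})"


def _pair_candidates(cls):
    # sn-position ordered, so a/b and b/a are distinct species
    for (a, x), (b, y) in itertools.product(_COMMON_FA, _COMMON_FA):
        yield f"{cls}({a}:{x}/{b}:{y})"


def _single_candidates(cls, crange, drange):
    for c in crange:
        for d in drange:
            yield f"{cls}({c}:{d})"


def _sphingo_candidates(cls):
    for c, d in _COMMON_FA:
        yield f"{cls}(d18:1/{c}:{d})"
    for c, d in _COMMON_FA:
        yield f"{cls}(d18:2/{c}:{d})"
    for c, d in _COMMON_FA:
        yield f"{cls}(d16:1/{c}:{d})"


# per-category class inventory: (class generator, share of the category)
_CATEGORY_INVENTORY = {
    "glycerolipid": [
        (lambda: _tag_candidates(), 0.85),
        (lambda: _pair_candidates("DAG"), 0.12),
        (lambda: _single_candidates("MAG", range(14, 25), range(0, 5)), 0.03),
    ],
    "glycerophospholipid": [
        (lambda: _pair_candidates("PC"), 0.40),
        (lambda: _pair_candidates("PE"), 0.26),
        (lambda: _pair_candidates("PI"), 0.10),
        (lambda: _single_candidates("LPC", range(14, 25), range(0, 7)), 0.13),
        (lambda: _single_candidates("LPE", range(14, 25), range(0, 7)), 0.11),
    ],
    "sphingolipid": [
        (lambda: _sphingo_candidates("SM"), 0.40),
        (lambda: _sphingo_candidates("CER"), 0.26),
        (lambda: _sphingo_candidates("DCER"), 0.14),
        (lambda: _sphingo_candidates("HCER"), 0.10),
        (lambda: _sphingo_candidates("LCER"), 0.10),
    ],
    "steroid": [
        (lambda: _single_candidates("CE", range(14, 25), range(0, 7)), 1.0),
    ],
}


def generate_lipid_names(config: CohortConfig) -> list[str]:
    """Deterministically generate unique, parseable lipid names with exactly
    the requested per-category composition."""
    rng = np.random.default_rng(config.seed)
    names: list[str] = []
    for category, total in config.category_counts.items():
        if category not in _CATEGORY_INVENTORY:
            raise ValueError(f"unknown lipid category {category!r}")
        inventory = _CATEGORY_INVENTORY[category]
        # integer split of `total` over classes, largest share absorbs rounding
        counts = [int(round(share * total)) for _, share in inventory]
        counts[0] += total - sum(counts)
        for (gen, _), k in zip(inventory, counts):
            pool = sorted(set(gen()))
            if k > len(pool):
                raise ValueError(
                    f"requested {k} names for {category} class pool of {len(pool)}"
                )
            picked = rng.choice(len(pool), size=k, replace=False)
            names.extend(pool[i] for i in sorted(picked))
    assert len(names) == len(set(names)) == sum(config.category_counts.values())
    return names


# ---------------------------------------------------------------------------
# cohort generation

#: per-group Bernoulli rates of the binary clinical variables
#: (no-MetS rate, MetS rate), matching the cohort's marginal composition.
_CLINICAL_RATES = {
    "sex_male": (0.90, 0.90),
    "immunodeficiency": (0.14, 0.13),
    "early_generation_art": (0.34, 0.46),
    "art_nrti": (0.95, 0.96),
    "art_nnrti": (0.54, 0.45),
    "art_pi": (0.37, 0.47),
    "art_insti": (0.16, 0.21),
    "art_other": (0.00, 0.03),
}
_ETHNICITIES = ["Caucasian", "Asian", "Black", "Other"]
_ETHNICITY_P = [0.87, 0.025, 0.05, 0.055]


def _clinical_table(rng: np.random.Generator, sample_ids, group: np.ndarray) -> pd.DataFrame:
    n = len(group)
    tbl = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
    tbl["mets"] = group
    for var, (p0, p1) in _CLINICAL_RATES.items():
        p = np.where(group == 1, p1, p0)
        tbl[var] = (rng.random(n) < p).astype(int)
    tbl["age"] = np.round(rng.normal(54.5, 9.0, n), 1)
    tbl["ethnicity"] = rng.choice(_ETHNICITIES, size=n, p=_ETHNICITY_P)
    # adipose tissue areas (cm^2), up-shifted under MetS; truncated at 0
    vat = rng.normal(np.where(group == 1, 149.4, 76.1), np.where(group == 1, 71.0, 53.6))
    sat = rng.normal(np.where(group == 1, 150.6, 111.1), np.where(group == 1, 77.1, 71.1))
    tbl["vat"] = np.round(np.clip(vat, 1.0, None), 1)
    tbl["sat"] = np.round(np.clip(sat, 1.0, None), 1)
    cols = ["mets", "sex_male", "age", "ethnicity", "immunodeficiency",
            "early_generation_art", "vat", "sat", "art_nrti", "art_nnrti",
            "art_pi", "art_insti", "art_other"]
    return tbl[cols]


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate the full synthetic cohort (lipids, metabolites, clinical, truth).

    Raises
    ------
    ValueError
        If ``effect_fraction > 0`` but the name inventory contains no DAG/TAG
        species to plant effects on.
    """
    rng = np.random.default_rng(config.seed)
    names = generate_lipid_names(config)
    species = [parse_lipid_name(n) for n in names]
    n_feat, n = len(names), 2 * config.n_per_group
    sample_ids = [f"S{i+1:03d}" for i in range(n)]
    group = np.repeat([0, 1], config.n_per_group)

    dagtag = [i for i, sp in enumerate(species) if sp.lipid_class in ("TAG", "DAG")]
    n_plant = int(round(config.effect_fraction * len(dagtag)))
    if config.effect_fraction > 0 and not dagtag:
        raise ValueError("effect_fraction > 0 but no DAG/TAG features to plant on")
    planted_idx = sorted(rng.choice(dagtag, size=n_plant, replace=False)) if n_plant else []
    planted = {names[i] for i in planted_idx}

    # second correlated lipid block among non-planted DAG/TAG, for a second
    # network community; no group effect
    rest = [i for i in dagtag if i not in set(planted_idx)]
    n_block2 = min(len(rest), max(n_plant, 10))
    block2_idx = sorted(rng.choice(rest, size=n_block2, replace=False)) if n_block2 else []

    # metabolites: first 6 form the block correlated with planted lipids and
    # carry the group effect ("key metabolite" behaviour)
    met_names = METABOLITE_NAMES[: config.n_metabolites]
    if config.n_metabolites > len(METABOLITE_NAMES):
        met_names = met_names + [
            f"metabolite_{i}" for i in range(len(METABOLITE_NAMES), config.n_metabolites)
        ]
    n_met_block = min(6, len(met_names))

    rho = config.block_correlation
    f1 = rng.standard_normal(n)  # block factor: planted lipids + metabolite block
    f2 = rng.standard_normal(n)  # block factor: second lipid community

    def _draw(n_rows: int, factor: np.ndarray | None, in_block: np.ndarray) -> np.ndarray:
        """log2-scale residuals with within-block correlation rho."""
        e = rng.standard_normal((n_rows, n))
        if factor is None or rho == 0:
            return e
        mix = np.sqrt(rho) * factor[None, :] + np.sqrt(1 - rho) * e
        return np.where(in_block[:, None], mix, e)

    in_b1 = np.zeros(n_feat, bool)
    in_b1[list(planted_idx)] = True
    in_b2 = np.zeros(n_feat, bool)
    in_b2[list(block2_idx)] = True
    eps = rng.standard_normal((n_feat, n))
    if rho > 0:
        eps[in_b1] = np.sqrt(rho) * f1[None, :] + np.sqrt(1 - rho) * eps[in_b1]
        eps[in_b2] = np.sqrt(rho) * f2[None, :] + np.sqrt(1 - rho) * eps[in_b2]

    base = rng.normal(0.0, 1.5, n_feat)  # per-feature log2 baseline abundance
    beta = np.zeros(n_feat)
    beta[list(planted_idx)] = config.effect_log2fc
    log2x = base[:, None] + beta[:, None] * group[None, :] + config.noise_sd * eps
    lipid_vals = np.exp2(log2x)

    # MNAR below-LOD zeros: zero out the smallest draws per feature
    if config.missing_rate > 0:
        k = rng.binomial(n, config.missing_rate, size=n_feat)
        for i in range(n_feat):
            if k[i]:
                order = np.argsort(lipid_vals[i])[: k[i]]
                lipid_vals[i, order] = 0.0

    met_eps = rng.standard_normal((len(met_names), n))
    if rho > 0 and n_met_block:
        met_eps[:n_met_block] = (
            np.sqrt(rho) * f1[None, :] + np.sqrt(1 - rho) * met_eps[:n_met_block]
        )
    met_beta = np.zeros(len(met_names))
    met_beta[:n_met_block] = config.effect_log2fc
    met_base = rng.normal(0.0, 1.0, len(met_names))
    met_vals = np.exp2(
        met_base[:, None] + met_beta[:, None] * group[None, :] + config.noise_sd * met_eps
    )
    truth = set(planted)
    if config.effect_log2fc != 0:
        truth |= set(met_names[:n_met_block])

    grp = pd.Series(group, index=sample_ids)
    lipids = AbundanceMatrix(
        pd.DataFrame(lipid_vals, index=names, columns=sample_ids), grp, "raw"
    )
    mets = AbundanceMatrix(
        pd.DataFrame(met_vals, index=met_names, columns=sample_ids), grp, "raw"
    )
    clinical = _clinical_table(rng, sample_ids, group)
    return SyntheticCohort(lipids, mets, clinical, truth, config)
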