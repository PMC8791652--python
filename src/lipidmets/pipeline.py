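"""End-to-end orchestration of the consensus lipidomics analysis.

Stages, in fixed order: preprocess (impute -> median-center -> near-zero-
variance filter) -> four differential-abundance arms (Mann-Whitney,
moderated t, PLS-DA VIP, rdCV random forest) -> four-way consensus ->
structural composition map -> lipid-metabolite network integration
(Spearman network, ER null, Leiden communities, clinical association) ->
cohort characteristics table. Every threshold applied is recorded in the
run manifest together with the feature-universe size at each stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import CohortComparison, cohort_table
from .composition import CompositionMap, class_trend_summary, composition_map
from .data import AbundanceMatrix
from .diffabund import DifferentialResult, fit_moderated, mann_whitney_all
from .network import (
    BiomolecularNetwork,
    CommunityPartition,
    centrality_rank,
    community_clinical_assoc,
    detect_communities,
    er_null_compare,
    spearman_network,
)
from .nomenclature import LipidParseError, parse_lipid_name
from .preprocess import filter_near_zero_variance, impute_and_center, log_transform
from .select import consensus_features, fit_plsda, q2y, rdcv_rf_select
from .synthetic import CohortConfig, SyntheticCohort, generate_cohort

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline", "default_config"]


def default_config() -> dict:
    """Full default configuration, one block per stage."""
    return {
        "seed": 0,
        "synthetic": {},  # CohortConfig overrides
        "preprocess": {"freq_ratio_cut": 19.0, "unique_cut_pct": 10.0,
                       "zeros_as_missing": True},
        "differential": {"fdr_cut": 0.001},
        "plsda": {"n_components": 2, "vip_cut": 1.0, "k_folds": 7},
        # lighter resampling schedule than the selector's own defaults so a
        # full-cohort orchestrated run stays interactive; raise for final runs
        "rf": {"n_rep": 2, "n_outer": 5, "var_ratio": 0.6,
               "tolerance": 0.05, "n_estimators": 50},
        "composition": {"q_cut": 0.01},
        "network": {"fdr_cut": 1e-07, "rho_cut": 0.38, "resolution": 1.0,
                    "leiden_seed": 1, "null_draws": 50,
                    "community_score": "mean_z", "community_q_cut": 0.12,
                    "feature_q_cut": 0.01, "top_fraction": 0.1},
    }


class PipelineConfig(dict):
    """Dict-backed config merged over :func:`default_config`."""

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        return cls.merged(user)

    @classmethod
    def merged(cls, user: dict | None) -> "PipelineConfig":
        cfg = default_config()
        for key, val in (user or {}).items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
        return cls(cfg)


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


@dataclass
class PipelineReport:
    """Everything a pipeline run produced, plus the run manifest."""

    cohort: SyntheticCohort | None
    lipids_centered: AbundanceMatrix
    lipids_log: AbundanceMatrix
    removed_features: list
    mw: DifferentialResult
    moderated: DifferentialResult
    plsda: object
    plsda_q2y: float
    rf: object
    consensus: object
    composition: CompositionMap
    class_trends: pd.DataFrame
    network: BiomolecularNetwork
    null_comparison: object
    partition: CommunityPartition
    hubs: list
    community_assoc: pd.DataFrame
    cohort_comparison: CohortComparison
    manifest: dict = dc_field(default_factory=dict)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.mw.to_tsv(out / "diff_mann_whitney.tsv")
        self.moderated.to_tsv(out / "diff_moderated_t.tsv")
        self.plsda.vip.rename_axis("feature_id").to_csv(out / "plsda_vip.tsv", sep="\t")
        self.rf.validation_curve.to_csv(out / "rf_validation_curve.tsv", sep="\t",
                                        index=False)
        pd.Series(self.rf.auroc).rename_axis("model").rename("auroc").to_csv(
            out / "rf_auroc.tsv", sep="\t")
        self.consensus.to_tsv(out / "consensus_upset.tsv")
        self.composition.to_tsv(out / "composition_map.tsv")
        self.class_trends.to_csv(out / "class_trends.tsv", sep="\t", index=False)
        self.network.write_graphml(out / "network.graphml")
        self.network.write_edgelist(out / "network_edges.tsv")
        self.partition.to_tsv(out / "communities.tsv")
        self.partition.summary.to_csv(out / "community_summary.tsv", sep="\t",
                                      index=False)
        self.community_assoc.to_csv(out / "community_clinical.tsv", sep="\t",
                                    index=False)
        self.cohort_comparison.to_tsv(out / "cohort_table.tsv")
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=1,
                                                      sort_keys=True))


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:
                raise PipelineStageError(name, exc) from exc
        return wrapped
    return deco


def run_pipeline(
    config: dict | None = None,
    lipids: AbundanceMatrix | None = None,
    metabolites: AbundanceMatrix | None = None,
    clinical: pd.DataFrame | None = None,
    out_dir=None,
) -> PipelineReport:
    """Run the full analysis on supplied matrices or a synthetic cohort.

    When ``lipids`` is None a synthetic cohort is generated from
    ``config['synthetic']`` with ``config['seed']``. Any stage failure
    aborts with the stage name and underlying error.
    """
    cfg = PipelineConfig.merged(config)
    seed = int(cfg["seed"])
    manifest: dict = {
        "package_version": __version__,
        "seed": seed,
        "thresholds": {
            "differential_fdr": cfg["differential"]["fdr_cut"],
            "vip_cut": cfg["plsda"]["vip_cut"],
            "network_fdr": cfg["network"]["fdr_cut"],
            "network_rho": cfg["network"]["rho_cut"],
            "community_clinical_fdr": cfg["network"]["community_q_cut"],
            "feature_clinical_fdr": cfg["network"]["feature_q_cut"],
            "composition_fdr": cfg["composition"]["q_cut"],
        },
        "stages": {},
    }

    cohort = None
    if lipids is None:
        syn_cfg = CohortConfig(**{**cfg["synthetic"], "seed": seed})
        cohort = _stage("synthetic")(generate_cohort)(syn_cfg)
        lipids, metabolites, clinical = cohort.lipids, cohort.metabolites, cohort.clinical
    manifest["stages"]["input_features"] = lipids.n_features
    manifest["stages"]["samples"] = lipids.n_samples

    pp = cfg["preprocess"]

    @_stage("preprocess")
    def _preprocess():
        centered = impute_and_center(lipids, zeros_as_missing=pp["zeros_as_missing"])
        filtered, removed = filter_near_zero_variance(
            centered, pp["freq_ratio_cut"], pp["unique_cut_pct"])
        return filtered, removed, log_transform(filtered)

    centered, removed, logged = _preprocess()
    log.info("%d of %d features survive the near-zero-variance filter",
             centered.n_features, lipids.n_features)
    manifest["stages"]["after_nzv_filter"] = centered.n_features

    fdr = cfg["differential"]["fdr_cut"]
    mw = _stage("mann_whitney")(mann_whitney_all)(centered, fdr_cut=fdr)
    moderated_model = _stage("moderated_t")(fit_moderated)(logged)
    moderated = moderated_model.result(fdr_cut=fdr)

    Xlog = logged.values.T  # samples x features
    y = logged.group.to_numpy()

    @_stage("plsda")
    def _plsda():
        model = fit_plsda(Xlog, y, n_components=cfg["plsda"]["n_components"])
        model.q2y = q2y(Xlog, y, n_components=cfg["plsda"]["n_components"],
                        k_folds=cfg["plsda"]["k_folds"], seed=seed)
        return model

    pls = _plsda()
    rf = _stage("rdcv_rf")(rdcv_rf_select)(
        Xlog, y, seed=seed,
        n_rep=cfg["rf"]["n_rep"], n_outer=cfg["rf"]["n_outer"],
        var_ratio=cfg["rf"]["var_ratio"], tolerance=cfg["rf"]["tolerance"],
        n_estimators=cfg["rf"]["n_estimators"])

    consensus = _stage("consensus")(consensus_features)(
        {
            "mann_whitney": mw.selected,
            "moderated_t": moderated.selected,
            "plsda_vip": pls.selected(cfg["plsda"]["vip_cut"]),
            "rf_rdcv": rf.max_set,
        },
        universe=centered.feature_ids,
    )
    manifest["stages"]["selected_per_method"] = {
        k: len(v) for k, v in consensus.method_sets.items()}
    manifest["stages"]["consensus_size"] = len(consensus.intersection)

    @_stage("composition")
    def _composition():
        species = []
        for name in logged.feature_ids:
            try:
                species.append(parse_lipid_name(name))
            except LipidParseError:
                pass
        cmap = composition_map(moderated_model.table, species,
                               q_cut=cfg["composition"]["q_cut"])
        return cmap, class_trend_summary(cmap)

    cmap, trends = _composition()

    ncfg = cfg["network"]

    @_stage("network")
    def _network():
        combined = logged
        node_types = {f: "lipid" for f in logged.feature_ids}
        if metabolites is not None:
            met_log = log_transform(impute_and_center(metabolites))
            combined = logged.concat(met_log)
            node_types.update({f: "metabolite" for f in met_log.feature_ids})
        net = spearman_network(combined, fdr_cut=ncfg["fdr_cut"],
                               rho_cut=ncfg["rho_cut"], node_types=node_types)
        null = er_null_compare(net, n_draws=ncfg["null_draws"], seed=seed) \
            if net.n_edges else None
        part = detect_communities(net, resolution=ncfg["resolution"],
                                  seed=ncfg["leiden_seed"]) if net.n_edges else None
        hubs = centrality_rank(net, ncfg["top_fraction"]) if net.n_edges else []
        assoc = (community_clinical_assoc(part, combined, clinical,
                                          ncfg["community_score"])
                 if part is not None and clinical is not None else pd.DataFrame())
        return net, null, part, hubs, assoc

    net, null_cmp, part, hubs, assoc = _network()
    manifest["stages"]["network_nodes"] = net.n_nodes
    manifest["stages"]["network_edges"] = net.n_edges
    if part is not None:
        manifest["stages"]["n_communities"] = part.n_communities
    manifest["leiden_seed"] = ncfg["leiden_seed"]

    comparison = _stage("cohort_table")(cohort_table)(clinical) \
        if clinical is not None else CohortComparison(pd.DataFrame())

    report = PipelineReport(
        cohort=cohort, lipids_centered=centered, lipids_log=logged,
        removed_features=removed, mw=mw, moderated=moderated, plsda=pls,
        plsda_q2y=pls.q2y, rf=rf, consensus=consensus, composition=cmap,
        class_trends=trends, network=net, null_comparison=null_cmp,
        partition=part, hubs=hubs, community_assoc=assoc,
        cohort_comparison=comparison, manifest=manifest,
    )
    if out_dir is not None:
        report.write(out_dir)
    return report
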