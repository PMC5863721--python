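"""End-to-end orchestration: QC chain, distances, and all analyses.

Stage order is fixed: occupancy filter -> contamination subtraction ->
discordant-replicate drop -> rarefaction -> distance matrices ->
{variance partitioning, NMDS + community assignment, time-step series,
association tests, constrained CCA}. Every random draw is routed through a
seed substream derived from the run seed and the stage name, so any stage
can be re-run reproducibly on its own.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import AssociationReport, community_association_report
from .distances import bray_curtis, jaccard
from .io_core import Dataset, ValidationError, read_metadata, read_otu_table, \
    validate_dataset, write_otu_table
from .ordination import CCAResult, CommunityAssignment, NMDSResult, \
    assign_communities, cca_constrained, high_leverage_otus, nmds
from .quality_control import QCReport, build_detection_histories, \
    control_profile, drop_discordant, fit_dissimilarity_threshold, \
    fit_occupancy_all, occupancy_filter, rarefy, replicate_dissimilarities, \
    subtract_contamination
from .synthetic_data import SimConfig, SyntheticTruth, generate_dataset
from .temporal import TimestepSeries, dissimilarity_model, kruskal_steps, \
    timestep_series
from .variance_partitioning import PER_SITE_TERMS, WHOLE_DATASET_TERMS, \
    PermanovaResult, permanova

__all__ = ["PipelineConfig", "PipelineError", "PipelineResult", "run_pipeline",
           "stage_seed"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage = stage
        self.code = code


@dataclass(frozen=True)
class PipelineConfig:
    """All knobs of one run; defaults are the study's stated values."""

    otu_table: str | None = None
    metadata: str | None = None
    simulate: SimConfig | None = None
    occupancy_threshold: float = 0.80
    replicate_threshold_mode: str = "fixed"  # "fixed" or "fit"
    replicate_threshold: float = 0.49
    rarefaction_depth: int = 18_500
    metric: str = "braycurtis"
    terms: tuple[str, ...] = tuple(WHOLE_DATASET_TERMS)
    n_perm: int = 999
    nmds_starts: int = 20
    cca_score_min: float = 0.7
    cca_count_min: int = 1000
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.occupancy_threshold <= 1.0:
            raise PipelineError("config", "bad_threshold",
                                f"occupancy threshold {self.occupancy_threshold}")
        if self.replicate_threshold_mode not in ("fixed", "fit"):
            raise PipelineError("config", "bad_mode",
                                f"mode {self.replicate_threshold_mode!r}")
        if not 0.0 < self.replicate_threshold <= 1.0:
            raise PipelineError("config", "bad_threshold",
                                f"replicate threshold {self.replicate_threshold}")
        if self.rarefaction_depth < 1:
            raise PipelineError("config", "bad_depth",
                                f"depth {self.rarefaction_depth}")
        if self.metric not in ("braycurtis", "jaccard"):
            raise PipelineError("config", "bad_metric", self.metric)
        if self.simulate is None and not (self.otu_table and self.metadata):
            raise PipelineError("config", "no_input",
                                "need otu_table+metadata paths or a simulate block")

    @staticmethod
    def from_yaml(path: str | Path) -> "PipelineConfig":
        with Path(path).open("r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        sim = doc.pop("simulate", None)
        if sim is not None:
            for key in ("salinity_means", "temperature_means"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            sim = SimConfig(**sim)
        if "terms" in doc:
            doc["terms"] = tuple(doc["terms"])
        return PipelineConfig(simulate=sim, **doc)


@dataclass
class PipelineResult:
    config: PipelineConfig
    qc_report: QCReport
    dataset: Dataset  # post-QC, rarefied
    truth: SyntheticTruth | None
    distance: Any  # skbio DistanceMatrix
    permanova_all: PermanovaResult
    permanova_by_site: dict[str, PermanovaResult]
    nmds: NMDSResult
    communities: CommunityAssignment
    cca: CCAResult
    high_leverage: pd.Series
    timesteps: dict[str, dict]
    association: AssociationReport | None
    manifest: dict


def stage_seed(base_seed: int, stage: str) -> int:
    """Stage-name-derived substream seed (stable, < 2**31)."""
    return int(np.random.SeedSequence(
        [int(base_seed), zlib.crc32(stage.encode())]
    ).generate_state(1)[0] % (2 ** 31))


def _run_stage(stage: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except PipelineError:
        raise
    except Exception as exc:
        code = type(exc).__name__
        raise PipelineError(stage, code, str(exc)) from exc


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None
                 ) -> PipelineResult:
    """Execute the full analysis; optionally write all artifacts to
    ``out_dir`` (created if needed)."""
    config.validate()

    truth = None
    if config.simulate is not None:
        sim = dataclasses.replace(
            config.simulate, seed=stage_seed(config.seed, "simulate"))
        dataset, truth = _run_stage("simulate", generate_dataset, sim)
    else:
        table = _run_stage("load", read_otu_table, config.otu_table)
        metadata = _run_stage("load", read_metadata, config.metadata)
        dataset = _run_stage("load", validate_dataset, table, metadata)

    report = QCReport()

    # 1. occupancy filter
    histories = _run_stage("occupancy", build_detection_histories, dataset)
    estimates = _run_stage("occupancy", fit_occupancy_all, histories)
    dataset, rec = _run_stage("occupancy", occupancy_filter, dataset,
                              estimates, config.occupancy_threshold)
    report.add(rec)

    # 2. contamination subtraction
    if dataset.metadata.control_replicates():
        profile = _run_stage("decontam", control_profile, dataset)
        dataset, rec = _run_stage("decontam", subtract_contamination,
                                  dataset, profile)
        report.add(rec)
    else:
        warnings.warn("no positive controls; skipping contamination "
                      "subtraction", stacklevel=2)

    # 3. discordant replicates
    pairs = _run_stage("replicates", replicate_dissimilarities, dataset)
    if config.replicate_threshold_mode == "fit":
        _, _, threshold = _run_stage(
            "replicates", fit_dissimilarity_threshold,
            [v for _, _, v in pairs])
    else:
        threshold = config.replicate_threshold
    dataset, rec = _run_stage("replicates", drop_discordant, dataset, threshold)
    report.add(rec)

    # 4. rarefaction
    dataset, rec = _run_stage(
        "rarefy", rarefy, dataset, config.rarefaction_depth,
        stage_seed(config.seed, "rarefy"))
    report.add(rec)

    # 5. distances
    metric_fn = bray_curtis if config.metric == "braycurtis" else jaccard
    dist = _run_stage("distances", metric_fn, dataset.table)

    # 6. variance partitioning
    perm_all = _run_stage(
        "permanova", permanova, dist, dataset.metadata, list(config.terms),
        config.n_perm, stage_seed(config.seed, "permanova"))
    perm_by_site: dict[str, PermanovaResult] = {}
    meta = dataset.metadata.records
    for site in sorted(meta.loc[meta["role"] == "field", "site_id"].unique()):
        reps = [r for r in dist.ids if meta.loc[r, "site_id"] == site]
        if len(reps) < 4:
            continue
        sub = dist.filter(reps)
        try:
            perm_by_site[site] = permanova(
                sub, dataset.metadata, PER_SITE_TERMS, config.n_perm,
                stage_seed(config.seed, f"permanova.{site}"))
        except ValidationError as exc:
            warnings.warn(f"per-site PERMANOVA skipped for {site}: {exc}",
                          stacklevel=2)

    # 7. ordination / communities / CCA
    nmds_res = _run_stage("nmds", nmds, dist, 2, config.nmds_starts,
                          500, 1e-7, stage_seed(config.seed, "nmds"))
    communities = _run_stage("communities", assign_communities, dist, 2,
                             dataset.metadata)
    cca = _run_stage("cca", cca_constrained, dataset.table, communities)
    leverage = _run_stage("cca", high_leverage_otus, cca, dataset.table,
                          config.cca_score_min, config.cca_count_min)

    # 8. temporal series
    timesteps: dict[str, dict] = {}
    for site in sorted(meta.loc[meta["role"] == "field", "site_id"].unique()):
        try:
            series = timestep_series(dist, dataset.metadata, site)
            timesteps[site] = {
                "series": series,
                "kruskal": kruskal_steps(series),
                "model": dissimilarity_model(series),
            }
        except ValidationError as exc:
            warnings.warn(f"time-step series skipped for {site}: {exc}",
                          stacklevel=2)

    # 9. association tests
    association = None
    try:
        association = _run_stage("associate", community_association_report,
                                 communities, dataset.metadata)
    except PipelineError as exc:
        warnings.warn(f"association tests skipped: {exc}", stacklevel=2)

    manifest = _build_manifest(config, report)
    result = PipelineResult(
        config=config, qc_report=report, dataset=dataset, truth=truth,
        distance=dist, permanova_all=perm_all, permanova_by_site=perm_by_site,
        nmds=nmds_res, communities=communities, cca=cca,
        high_leverage=leverage, timesteps=timesteps, association=association,
        manifest=manifest,
    )
    if out_dir is not None:
        write_artifacts(result, out_dir)
    return result


def _build_manifest(config: PipelineConfig, report: QCReport) -> dict:
    cfg = dataclasses.asdict(config)
    if cfg.get("simulate") is not None:
        for key in ("salinity_means", "temperature_means"):
            cfg["simulate"][key] = list(cfg["simulate"][key])
        cfg["simulate"]["community_overrides"] = {
            f"{s}:{e}": v
            for (s, e), v in cfg["simulate"]["community_overrides"].items()
        }
    cfg["terms"] = list(cfg["terms"])
    return {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": {
            s: stage_seed(config.seed, s)
            for s in ("simulate", "rarefy", "permanova", "nmds")
        },
        "config": cfg,
        "qc": report.to_json_dict(),
        "retained_read_percentage": report.retained_read_percentage(),
    }


def write_artifacts(result: PipelineResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def dump(name: str, obj) -> None:
        with (out / name).open("w", encoding="utf-8") as fh:
            json.dump(obj, fh, indent=1, sort_keys=True, default=_jsonify)

    write_otu_table(result.dataset.table, out / "otu_table_rarefied.tsv")
    result.distance.to_data_frame().to_csv(out / "distance_matrix.tsv", sep="\t")
    dump("qc_report.json", result.qc_report.to_json_dict())
    dump("permanova.json", {
        "whole_dataset": result.permanova_all.to_json_dict(),
        "by_site": {s: r.to_json_dict()
                    for s, r in result.permanova_by_site.items()},
    })
    dump("nmds.json", {
        "stress": result.nmds.stress,
        "converged": result.nmds.converged,
        "coordinates": result.nmds.coordinates.round(6).to_dict(orient="index"),
    })
    dump("communities.json", result.communities.to_json_dict())
    dump("cca.json", {
        "constrained_inertia_fraction": result.cca.constrained_inertia_fraction,
        "total_inertia": result.cca.total_inertia,
        "otu_scores": result.cca.otu_scores.round(6).to_dict(),
        "high_leverage": result.high_leverage.round(6).to_dict(),
    })
    dump("timesteps.json", {
        site: {
            "series": d["series"].to_json_dict(),
            "kruskal": d["kruskal"],
            "model": d["model"].to_dict(orient="index"),
        }
        for site, d in result.timesteps.items()
    })
    dump("association.json",
         None if result.association is None
         else result.association.to_json_dict())
    dump("manifest.json", result.manifest)


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, pd.Timestamp):
        return obj.isoformat()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
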