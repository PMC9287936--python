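"""End-to-end per-trait pipeline: projection -> meta-analysis -> anchoring ->
candidate genes -> enrichment/expression -> report.

The pipeline is driven by a config (YAML/JSON or dict) naming the input
files and thresholds.  Stages execute in order, in memory, and each writes
its artifacts to the output directory; a run log records every dropped
marker and QTL with its reason, and ``report.json`` summarises the funnel
(initial -> projected -> meta-QTLs -> filtered meta-QTLs -> genes).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .anchoring import mqtl_physical_interval, overlap_domains
from .ci import apply_lod_defaults
from .consensus import ConsensusMap, map_density, merge_maps
from .core import GenomicInterval, QTLRecord, Trait
from .genes import (
    GO_P_THRESHOLD,
    EXPRESSED_MIN_FPKM,
    HIGH_WINDOW_MEAN,
    GeneAnnotation,
    classify_expression_window,
    genes_in_interval,
    go_enrichment,
    profiles_from_matrix,
)
from .meta import MQTL, analyze_group, filter_mqtls
from .projection import (
    DEFAULT_EXTRAPOLATION_CAP,
    ProjectedQTL,
    Provenance,
    project_qtls,
)

logger = logging.getLogger(__name__)

STAGES = ("project", "meta", "anchor", "genes", "enrich", "report")


@dataclass
class PipelineConfig:
    """Input paths and tunables for one trait's run."""

    trait: Trait
    reference_map: Path
    experiments: Path
    qtl_table: Path
    out_dir: Path
    study_maps: dict[str, Path] = field(default_factory=dict)  # experiment_id -> map
    annotation: Optional[Path] = None
    expression: Optional[Path] = None
    go_table: Optional[Path] = None
    k_max: int = 10
    min_experiments: int = 2
    extrapolation_cap: float = DEFAULT_EXTRAPOLATION_CAP
    go_threshold: float = GO_P_THRESHOLD
    expressed_min_fpkm: float = EXPRESSED_MIN_FPKM
    high_window_mean: float = HIGH_WINDOW_MEAN

    def __post_init__(self) -> None:
        self.trait = Trait(self.trait)
        for name in ("reference_map", "experiments", "qtl_table"):
            path = Path(getattr(self, name))
            setattr(self, name, path)
            if not path.exists():
                raise FileNotFoundError(f"{name}: {path}")
        self.out_dir = Path(self.out_dir)
        self.study_maps = {k: Path(v) for k, v in self.study_maps.items()}
        for name in ("annotation", "expression", "go_table"):
            value = getattr(self, name)
            if value is not None:
                setattr(self, name, Path(value))

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw.update(overrides)
        base = path.parent

        def resolve(p):
            p = Path(p)
            return p if p.is_absolute() else base / p

        for key in ("reference_map", "experiments", "qtl_table", "annotation",
                    "expression", "go_table"):
            if raw.get(key):
                raw[key] = resolve(raw[key])
        if raw.get("study_maps"):
            raw["study_maps"] = {k: resolve(v) for k, v in raw["study_maps"].items()}
        return cls(**raw)


@dataclass
class PipelineResult:
    config: PipelineConfig
    consensus: ConsensusMap
    projected: list[ProjectedQTL]
    mqtls_all: list[MQTL]
    mqtls: list[MQTL]  # experiment-support filtered
    summary: dict


def run_pipeline(
    config: PipelineConfig | str | Path, stages: tuple[str, ...] = STAGES
) -> PipelineResult:
    """Run the pipeline through the requested (prefix of) stages."""
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_file(config)
    for stage in stages:
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}")
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    trait = config.trait
    summary: dict = {"trait": trait.value}

    # ------------------------------------------------------------- project
    reference = mio.read_genetic_map(config.reference_map, "reference")
    study_maps = {}
    experiment_to_map = {}
    for exp_id, path in config.study_maps.items():
        map_id = path.stem
        study_maps[map_id] = mio.read_genetic_map(path, map_id)
        experiment_to_map[exp_id] = map_id
    experiments = mio.read_experiment_table(config.experiments)
    consensus = merge_maps(reference, list(study_maps.values()))
    consensus.write(out / "consensus_map.tsv")
    density, per_group = map_density(consensus)
    summary["n_consensus_markers"] = consensus.n_markers
    summary["consensus_density_markers_per_cM"] = round(density, 4)

    accepted, rejected = mio.read_qtl_table(config.qtl_table, experiments)
    accepted = [q for q in accepted if q.trait is trait]
    rejected = [(q, reason) for q, reason in rejected if q.trait is trait]
    accepted = apply_lod_defaults(accepted)
    projected, discarded = project_qtls(
        accepted,
        study_maps,
        consensus,
        experiments,
        experiment_to_map,
        extrapolation_cap=config.extrapolation_cap,
    )
    _write_projected(projected, out / "projected_qtls.tsv")
    pd.DataFrame(
        [{"qtl_id": q.qtl_id, "reason": r} for q, r in rejected]
        + [{"qtl_id": d.qtl_id, "reason": d.reason} for d in discarded],
        columns=["qtl_id", "reason"],
    ).to_csv(out / "discarded_qtls.tsv", sep="\t", index=False)
    summary["n_input_qtls"] = len(accepted) + len(rejected)
    summary["n_rejected_records"] = len(rejected)
    summary["n_projected"] = len(projected)
    summary["n_discarded_in_projection"] = len(discarded)
    widths = [q.ci_end - q.ci_start for q in projected]
    summary["mean_initial_ci_cM"] = round(float(np.mean(widths)), 4) if widths else None
    logger.info(
        "%s: %d QTLs in, %d projected, %d discarded",
        trait.value,
        summary["n_input_qtls"],
        len(projected),
        len(discarded) + len(rejected),
    )
    result = PipelineResult(config, consensus, projected, [], [], summary)
    if "meta" not in stages:
        return _finish(result, out, stages)

    # ---------------------------------------------------------------- meta
    by_group: dict[str, list[ProjectedQTL]] = {}
    for q in projected:
        by_group.setdefault(q.linkage_group, []).append(q)
    mqtls_all: list[MQTL] = []
    profiles = []
    for group in sorted(by_group, key=_group_key):
        members = by_group[group]
        group_mqtls, fit = analyze_group(members, trait, group, k_max=config.k_max)
        mqtls_all.extend(group_mqtls)
        prof = fit.aic_profile.copy()
        prof.insert(0, "linkage_group", group)
        prof["selected"] = prof["k"] == fit.k
        profiles.append(prof)
    pd.concat(profiles, ignore_index=True).to_csv(
        out / "aic_profiles.tsv", sep="\t", index=False
    )
    mqtls = filter_mqtls(mqtls_all, config.min_experiments)
    mio.write_mqtl_table(mqtls_all, out / "mqtls_all.tsv")
    mio.write_mqtl_table(mqtls, out / "mqtls_filtered.tsv")
    summary["n_mqtls_all"] = len(mqtls_all)
    summary["n_mqtls_filtered"] = len(mqtls)
    if mqtls:
        mean_ci = float(np.mean([m.ci_width for m in mqtls]))
        summary["mean_mqtl_ci_cM"] = round(mean_ci, 4)
        if summary["mean_initial_ci_cM"]:
            summary["ci_fold_reduction"] = round(
                1 - mean_ci / summary["mean_initial_ci_cM"], 4
            )
    logger.info(
        "%s: %d MQTLs, %d supported by >= %d experiments",
        trait.value,
        len(mqtls_all),
        len(mqtls),
        config.min_experiments,
    )
    result.mqtls_all = mqtls_all
    result.mqtls = mqtls
    if "anchor" not in stages:
        return _finish(result, out, stages)

    # -------------------------------------------------------------- anchor
    for m in mqtls:
        m.physical = mqtl_physical_interval(m, consensus)
    anchored = [m for m in mqtls if m.physical is not None]
    mio.write_bed(
        [m.physical for m in anchored],
        out / "mqtls.bed",
        names=[m.name for m in anchored],
    )
    mio.write_mqtl_table(mqtls, out / "mqtls_filtered.tsv")
    summary["n_mqtls_anchored"] = len(anchored)
    if "genes" not in stages or config.annotation is None:
        return _finish(result, out, stages)

    # --------------------------------------------------------------- genes
    annotation = GeneAnnotation.from_gff3(config.annotation)
    gene_rows = []
    for m in anchored:
        m.genes = genes_in_interval(annotation, m.physical)
        for g in m.genes:
            gene_rows.append(
                {
                    "mqtl": m.name,
                    "gene_id": g.gene_id,
                    "chromosome": g.interval.chromosome,
                    "start": g.interval.start,
                    "end": g.interval.end,
                    "strand": g.strand,
                }
            )
    pd.DataFrame(
        gene_rows,
        columns=["mqtl", "gene_id", "chromosome", "start", "end", "strand"],
    ).to_csv(out / "candidate_genes.tsv", sep="\t", index=False)
    mio.write_mqtl_table(mqtls, out / "mqtls_filtered.tsv")
    candidate_ids = sorted({row["gene_id"] for row in gene_rows})
    summary["n_candidate_genes"] = len(candidate_ids)
    logger.info("%s: %d candidate genes", trait.value, len(candidate_ids))
    if "enrich" not in stages:
        return _finish(result, out, stages)

    # -------------------------------------------------------------- enrich
    if config.go_table is not None:
        go_map = mio.read_go_table(config.go_table)
        population = annotation.all_gene_ids()
        results = go_enrichment(
            candidate_ids, population, go_map, threshold=config.go_threshold
        )
        pd.DataFrame(
            [
                {
                    "term_id": r.term_id,
                    "study_count": r.study_count,
                    "study_size": r.study_size,
                    "population_count": r.population_count,
                    "population_size": r.population_size,
                    "p_value": r.p_value,
                    "enriched": r.enriched,
                }
                for r in results
            ]
        ).to_csv(out / "go_enrichment.tsv", sep="\t", index=False)
        summary["n_enriched_terms"] = sum(r.enriched for r in results)
    if config.expression is not None:
        fpkm = mio.read_expression_matrix(config.expression)
        subset = fpkm.loc[fpkm.index.intersection(candidate_ids)]
        classes = []
        for profile in profiles_from_matrix(subset):
            window = classify_expression_window(
                profile,
                high_mean=config.high_window_mean,
                min_fpkm=config.expressed_min_fpkm,
            )
            classes.append(
                {
                    "gene_id": profile.gene_id,
                    "expressed": profile.expressed,
                    "window": window.value,
                }
            )
        class_df = pd.DataFrame(classes, columns=["gene_id", "expressed", "window"])
        class_df.to_csv(out / "expression_classes.tsv", sep="\t", index=False)
        summary["expression_class_counts"] = (
            class_df["window"].value_counts().to_dict()
        )
    return _finish(result, out, stages)


def _finish(result: PipelineResult, out: Path, stages) -> PipelineResult:
    with open(out / "report.json", "w") as fh:
        json.dump(result.summary, fh, indent=2)
    return result


def _group_key(group: str):
    return (0, int(group)) if group.isdigit() else (1, group)


def _write_projected(projected: list[ProjectedQTL], path: Path) -> None:
    rows = [
        {
            "qtl_id": q.qtl_id,
            "trait": q.source.trait.value,
            "experiment_id": q.experiment_id,
            "linkage_group": q.linkage_group,
            "peak_cM": round(q.peak_pos, 6),
            "ci_start_cM": round(q.ci_start, 6),
            "ci_end_cM": round(q.ci_end, 6),
            "sigma_cM": round(q.sigma, 6),
            "provenance": q.provenance.value,
            "extrapolated": q.extrapolated,
            "lod": q.source.lod,
            "r_squared": q.source.r_squared,
        }
        for q in projected
    ]
    pd.DataFrame(
        rows,
        columns=[
            "qtl_id",
            "trait",
            "experiment_id",
            "linkage_group",
            "peak_cM",
            "ci_start_cM",
            "ci_end_cM",
            "sigma_cM",
            "provenance",
            "extrapolated",
            "lod",
            "r_squared",
        ],
    ).to_csv(path, sep="\t", index=False)


def compute_overlap(
    mqtls_a: list[MQTL], mqtls_b: list[MQTL]
) -> list:
    """Overlap domains between two traits' anchored meta-QTLs."""
    set_a = [(m.name, m.physical) for m in mqtls_a if m.physical is not None]
    set_b = [(m.name, m.physical) for m in mqtls_b if m.physical is not None]
    return overlap_domains(set_a, set_b)


def write_overlap(domains, out_path: str | Path) -> Path:
    out_path = Path(out_path)
    rows = []
    for d in domains:
        rows.append(
            {
                "chromosome": d.interval.chromosome,
                "start": d.interval.start,
                "end": d.interval.end,
                "mqtls_a": ",".join(d.names_a),
                "mqtls_b": ",".join(d.names_b),
            }
        )
    pd.DataFrame(
        rows, columns=["chromosome", "start", "end", "mqtls_a", "mqtls_b"]
    ).to_csv(out_path, sep="\t", index=False)
    bed = out_path.with_suffix(".bed")
    mio.write_bed(
        [d.interval for d in domains],
        bed,
        names=["|".join(d.names_a + d.names_b) for d in domains],
    )
    return out_path
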