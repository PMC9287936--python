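"""Synthetic maize meta-QTL study generator with known ground truth.

The generator emulates the statistical structure of the published GDR/GWC
meta-analysis inputs: a 10-linkage-group reference map with physical
anchors, 25 mapping experiments of mixed population types (14 of which
publish their own distorted linkage maps, two of which are SNP-based and
report only physical coordinates), and 282 initial QTLs (87 GDR, 195 GWC)
scattered around planted true meta-QTL positions, with R² spanning 1-90%,
CI widths spanning roughly 0.7-476 cM, and a share of records missing their
CI or LOD so the imputation formulas are exercised.  A truth table records
every QTL's generating locus, so K-selection rate, position error, CI
coverage and gene recovery are all measurable downstream.

All randomness flows from ``scenario.seed`` through one named generator.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .anchoring import anchor_pairs_from_loci, genetic_to_physical
from .core import (
    CoordSystem,
    ExperimentMeta,
    GeneRecord,
    GeneticMap,
    GenomicInterval,
    MappingMethod,
    MarkerLocus,
    PopulationType,
    QTLRecord,
    Trait,
)
from . import io as mio

logger = logging.getLogger(__name__)

_DAP_TIMEPOINTS = np.arange(0.0, 39.0, 2.0)  # 0-38 DAP, 2-day sampling


@dataclass
class SimulationScenario:
    """Configuration of one synthetic meta-QTL study.

    Defaults mirror the published study's scale: 10 linkage groups, 25
    experiments, 87 GDR + 195 GWC QTLs around 21 + 47 planted true loci,
    R² in 1-90%, QTL position s.d. spanning 0.19-120 cM (95% CI widths of
    about 0.7-470 cM).
    """

    seed: int = 0
    n_chromosomes: int = 10
    ref_markers_per_group: int = 200
    group_length: float = 800.0  # cM; reference scale is recombination-dense
    chromosome_bp: float = 2.2e8
    anchor_fraction: float = 0.5  # share of reference markers with bp positions
    n_experiments: int = 25
    n_mapped_experiments: int = 14  # experiments that publish a linkage map
    n_snp_experiments: int = 2  # experiments reporting physical coordinates
    n_gdr_qtls: int = 87
    n_gwc_qtls: int = 195
    n_gdr_loci: int = 21
    n_gwc_loci: int = 47
    gdr_groups: tuple[str, ...] = ("2", "3", "4", "6")
    gwc_groups: tuple[str, ...] = ("2", "3", "4", "5", "6", "7", "8", "9", "10")
    qtl_sigma_range: tuple[float, float] = (0.19, 120.0)  # cM, log-uniform
    r2_range: tuple[float, float] = (0.01, 0.90)  # log-uniform
    popsize_range: tuple[int, int] = (84, 400)
    shared_marker_fraction: float = 0.5
    study_only_markers_per_group: int = 10
    map_distortion: float = 0.1  # multiplicative warp amplitude
    missing_ci_fraction: float = 0.3
    missing_lod_fraction: float = 0.3
    one_flank_fraction: float = 0.15  # of flank-based QTLs, right flank unmappable
    genes_per_chromosome: int = 250
    true_mqtls: Optional[dict] = None  # {trait: {group: [(pos, n_qtls), ...]}}

    def __post_init__(self) -> None:
        for lo, hi in (self.qtl_sigma_range, self.r2_range, self.popsize_range):
            if lo > hi:
                raise ValueError("scenario ranges must be ordered (lo <= hi)")
        for frac in (
            self.anchor_fraction,
            self.shared_marker_fraction,
            self.missing_ci_fraction,
            self.missing_lod_fraction,
            self.one_flank_fraction,
        ):
            if not 0 <= frac <= 1:
                raise ValueError("scenario fractions must lie in [0, 1]")
        if self.ref_markers_per_group < 2:
            raise ValueError("need at least two reference markers per group")

    @property
    def groups(self) -> list[str]:
        return [str(i + 1) for i in range(self.n_chromosomes)]


@dataclass
class SimulatedData:
    """Everything one scenario run produces, plus the ground truth."""

    scenario: SimulationScenario
    reference: GeneticMap
    study_maps: dict[str, GeneticMap]
    experiments: dict[str, ExperimentMeta]
    experiment_to_map: dict[str, str]
    qtls: list[QTLRecord]
    truth: pd.DataFrame  # qtl_id, trait, linkage_group, mqtl_id, true_pos, sigma
    plan: pd.DataFrame  # mqtl_id, trait, group, position, n_qtls
    genes: list[GeneRecord]
    fpkm: pd.DataFrame
    go_table: dict[str, set[str]]
    gene_labels: pd.DataFrame


def _loguniform(rng: np.random.Generator, lo: float, hi: float, size=None):
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=size))


def simulate_reference_map(
    scenario: SimulationScenario, rng: Optional[np.random.Generator] = None
) -> GeneticMap:
    """Reference map: jittered uniform marker spacing, monotone-cubic cM->bp.

    A seeded ``anchor_fraction`` of markers carries a physical position
    sampled from a smooth monotone cM->bp curve per chromosome, so the
    genetic-to-physical transfer is invertible by construction.
    """
    if scenario.ref_markers_per_group < 1:
        raise ValueError("zero markers requested")
    rng = rng or np.random.default_rng(scenario.seed)
    groups: dict[str, list[MarkerLocus]] = {}
    n = scenario.ref_markers_per_group
    length = scenario.group_length
    for group in scenario.groups:
        spacing = length / max(n - 1, 1)
        pos = np.linspace(0, length, n) + rng.normal(0, 0.2 * spacing, size=n)
        pos = np.sort(np.clip(pos, 0, length))
        # monotone cubic cM -> bp through jittered control points
        ctrl_g = np.linspace(0, length, 6)
        increments = rng.uniform(0.5, 1.5, size=5)
        ctrl_p = np.concatenate(
            [[1.0], 1.0 + np.cumsum(increments) / increments.sum() * (scenario.chromosome_bp - 1)]
        )
        to_bp = PchipInterpolator(ctrl_g, ctrl_p)
        anchored = rng.random(n) < scenario.anchor_fraction
        anchored[0] = anchored[-1] = True  # span the group for interpolation
        loci = []
        for i in range(n):
            bp = int(round(float(to_bp(pos[i])))) if anchored[i] else None
            loci.append(
                MarkerLocus(
                    name=f"m{group}_{i:04d}",
                    linkage_group=group,
                    genetic_pos=float(pos[i]),
                    physical_pos=max(bp, 1) if bp is not None else None,
                )
            )
        groups[group] = loci
    return GeneticMap(map_id="reference", groups=groups)


def plan_true_mqtls(
    scenario: SimulationScenario, rng: Optional[np.random.Generator] = None
) -> pd.DataFrame:
    """Plant true meta-QTL loci and allot member-QTL counts per locus.

    Loci are spread over each trait's linkage groups with at least 5 cM
    separation; member counts are drawn so every locus has >= 1 QTL and the
    trait totals match the scenario.
    """
    if scenario.true_mqtls is not None:
        rows = []
        for trait, by_group in scenario.true_mqtls.items():
            trait = Trait(trait)
            i = 0
            for group, entries in by_group.items():
                for pos, n_members in entries:
                    if not 0 <= pos <= scenario.group_length:
                        raise ValueError(
                            f"true MQTL position {pos} outside group span "
                            f"[0, {scenario.group_length}]"
                        )
                    i += 1
                    rows.append(
                        {
                            "mqtl_id": f"true_{trait.value}_{i}",
                            "trait": trait.value,
                            "group": str(group),
                            "position": float(pos),
                            "n_qtls": int(n_members),
                        }
                    )
        return pd.DataFrame(rows)

    rng = rng or np.random.default_rng(scenario.seed)
    rows = []
    specs = [
        (Trait.GDR, scenario.n_gdr_loci, scenario.n_gdr_qtls, scenario.gdr_groups),
        (Trait.GWC, scenario.n_gwc_loci, scenario.n_gwc_qtls, scenario.gwc_groups),
    ]
    margin = 0.05 * scenario.group_length
    for trait, n_loci, n_qtls, group_pool in specs:
        # member counts: one QTL guaranteed per locus, the rest multinomial
        extra = rng.multinomial(n_qtls - n_loci, np.full(n_loci, 1.0 / n_loci))
        counts = extra + 1
        groups = rng.choice(list(group_pool), size=n_loci)
        positions: dict[str, list[float]] = {}
        for i in range(n_loci):
            group = str(groups[i])
            taken = positions.setdefault(group, [])
            for _ in range(200):
                pos = rng.uniform(margin, scenario.group_length - margin)
                if all(abs(pos - t) >= 5.0 for t in taken):
                    break
            taken.append(pos)
            rows.append(
                {
                    "mqtl_id": f"true_{trait.value}_{i + 1}",
                    "trait": trait.value,
                    "group": group,
                    "position": float(pos),
                    "n_qtls": int(counts[i]),
                }
            )
    return pd.DataFrame(rows)


_POPULATION_CYCLE = [
    PopulationType.RIL,
    PopulationType.F2_3,
    PopulationType.RIL,
    PopulationType.TC,
    PopulationType.F3_4,
    PopulationType.BC,
    PopulationType.RIL,
    PopulationType.F2,
    PopulationType.DH,
    PopulationType.RIL,
]


def _monotone_warp(
    rng: np.random.Generator, length: float, amplitude: float
) -> PchipInterpolator:
    """A smooth strictly increasing cM->cM distortion of a study map scale."""
    ctrl = np.linspace(0, length, 6)
    warped = ctrl * np.exp(rng.uniform(-amplitude, amplitude, size=6))
    warped[0] = 0.0
    warped = np.maximum.accumulate(warped)
    warped += np.arange(6) * 1e-9  # strictness under accumulate ties
    return PchipInterpolator(ctrl, warped)


def simulate_experiments(
    scenario: SimulationScenario,
    reference: GeneticMap,
    rng: Optional[np.random.Generator] = None,
    plan: Optional[pd.DataFrame] = None,
) -> tuple[
    dict[str, GeneticMap],
    dict[str, ExperimentMeta],
    dict[str, str],
    list[QTLRecord],
    pd.DataFrame,
]:
    """Study maps, experiment metadata, QTL records and the truth table.

    Mapped experiments get a warped subset of the reference markers plus a
    few private markers and express their QTLs in study-map coordinates;
    map-less experiments report flanking reference-marker names; SNP
    experiments report physical coordinates.  Per the missing-data
    fractions, CIs and LODs are blanked (R² and N stay available so the CI
    formulas apply).
    """
    rng = rng or np.random.default_rng(scenario.seed)
    if plan is None:
        plan = plan_true_mqtls(scenario, rng)

    n_exp = scenario.n_experiments
    n_gdr_exp = max(1, round(n_exp * scenario.n_gdr_qtls / (scenario.n_gdr_qtls + scenario.n_gwc_qtls)))
    experiments: dict[str, ExperimentMeta] = {}
    experiment_trait: dict[str, Trait] = {}
    experiment_to_map: dict[str, str] = {}
    study_maps: dict[str, GeneticMap] = {}
    snp_ids: set[str] = set()

    for i in range(n_exp):
        exp_id = f"exp{i + 1:02d}"
        pop_type = _POPULATION_CYCLE[i % len(_POPULATION_CYCLE)]
        experiments[exp_id] = ExperimentMeta(
            experiment_id=exp_id,
            parents=f"P{2 * i + 1}xP{2 * i + 2}",
            population_type=pop_type,
            population_size=int(rng.integers(scenario.popsize_range[0], scenario.popsize_range[1] + 1)),
            n_environments=int(rng.integers(1, 9)),
            mapping_method=MappingMethod.CIM if i % 3 else MappingMethod.IM,
        )
        experiment_trait[exp_id] = Trait.GDR if i < n_gdr_exp else Trait.GWC
    exp_ids = list(experiments)
    # last experiments are SNP-based; the first n_mapped publish maps
    for exp_id in exp_ids[n_exp - scenario.n_snp_experiments:]:
        snp_ids.add(exp_id)
    mapped_ids = [e for e in exp_ids[: scenario.n_mapped_experiments] if e not in snp_ids]

    warps: dict[tuple[str, str], PchipInterpolator] = {}
    for exp_id in mapped_ids:
        map_id = f"map_{exp_id}"
        experiment_to_map[exp_id] = map_id
        groups: dict[str, list[MarkerLocus]] = {}
        for group, ref_loci in reference.groups.items():
            warp = _monotone_warp(rng, scenario.group_length, scenario.map_distortion)
            warps[(exp_id, group)] = warp
            keep = rng.random(len(ref_loci)) < scenario.shared_marker_fraction
            keep[0] = keep[-1] = True
            loci = [
                MarkerLocus(
                    name=ref_loci[i].name,
                    linkage_group=group,
                    genetic_pos=float(max(warp(ref_loci[i].genetic_pos), 0.0)),
                )
                for i in range(len(ref_loci))
                if keep[i]
            ]
            for j in range(scenario.study_only_markers_per_group):
                g = rng.uniform(0, scenario.group_length)
                loci.append(
                    MarkerLocus(
                        name=f"s_{exp_id}_{group}_{j:02d}",
                        linkage_group=group,
                        genetic_pos=float(max(warp(g), 0.0)),
                    )
                )
            groups[group] = loci
        study_maps[map_id] = GeneticMap(map_id=map_id, groups=groups)

    # ---------------------------------------------------------------- QTLs
    qtls: list[QTLRecord] = []
    truth_rows = []
    counter = 0
    anchor_cache = {
        group: anchor_pairs_from_loci(reference.groups[group])
        for group in reference.groups
    }
    for _, locus in plan.iterrows():
        trait = Trait(locus["trait"])
        group = str(locus["group"])
        pool = [e for e in exp_ids if experiment_trait[e] is trait]
        for _ in range(int(locus["n_qtls"])):
            counter += 1
            qtl_id = f"q{trait.value}{counter:03d}"
            exp_id = str(rng.choice(pool))
            meta = experiments[exp_id]
            sigma = float(_loguniform(rng, *scenario.qtl_sigma_range))
            peak_ref = float(
                np.clip(
                    rng.normal(locus["position"], sigma), 0.0, scenario.group_length
                )
            )
            r2 = float(_loguniform(rng, *scenario.r2_range))
            lod = None if rng.random() < scenario.missing_lod_fraction else float(
                rng.uniform(2.5, 12.0)
            )
            ci_lo = max(peak_ref - 1.96 * sigma, 0.0)
            ci_hi = min(peak_ref + 1.96 * sigma, scenario.group_length)
            record: Optional[QTLRecord] = None
            if exp_id in snp_ids:
                pairs = anchor_cache[group]
                bp_lo, _ = genetic_to_physical(ci_lo, pairs)
                bp_hi, _ = genetic_to_physical(ci_hi, pairs)
                bp_peak, _ = genetic_to_physical(peak_ref, pairs)
                record = QTLRecord(
                    qtl_id=qtl_id,
                    trait=trait,
                    experiment_id=exp_id,
                    linkage_group=group,
                    peak_pos=float(min(max(bp_lo, bp_peak), bp_hi)),
                    ci_start=float(min(bp_lo, bp_hi)),
                    ci_end=float(max(bp_lo, bp_hi)),
                    lod=lod,
                    r_squared=r2,
                    coord_system=CoordSystem.PHYSICAL,
                )
            elif exp_id in experiment_to_map:
                warp = warps[(exp_id, group)]
                blank_ci = rng.random() < scenario.missing_ci_fraction
                record = QTLRecord(
                    qtl_id=qtl_id,
                    trait=trait,
                    experiment_id=exp_id,
                    linkage_group=group,
                    peak_pos=float(warp(peak_ref)),
                    ci_start=None if blank_ci else float(warp(ci_lo)),
                    ci_end=None if blank_ci else float(warp(ci_hi)),
                    lod=lod,
                    r_squared=r2,
                    coord_system=CoordSystem.GENETIC,
                )
            else:
                # map-less experiment: report flanking reference markers
                loci = reference.groups[group]
                positions = np.array([m.genetic_pos for m in loci])
                left_idx = int(np.searchsorted(positions, ci_lo, side="right")) - 1
                right_idx = int(np.searchsorted(positions, ci_hi, side="left"))
                left_idx = max(left_idx, 0)
                right_idx = min(right_idx, len(loci) - 1)
                if right_idx <= left_idx:
                    right_idx = min(left_idx + 1, len(loci) - 1)
                flank_right = loci[right_idx].name
                if rng.random() < scenario.one_flank_fraction:
                    flank_right = f"unplaced_{qtl_id}"
                record = QTLRecord(
                    qtl_id=qtl_id,
                    trait=trait,
                    experiment_id=exp_id,
                    linkage_group=group,
                    flank_left=loci[left_idx].name,
                    flank_right=flank_right,
                    lod=lod,
                    r_squared=r2,
                    coord_system=CoordSystem.GENETIC,
                )
            qtls.append(record)
            truth_rows.append(
                {
                    "qtl_id": qtl_id,
                    "trait": trait.value,
                    "linkage_group": group,
                    "experiment_id": exp_id,
                    "mqtl_id": locus["mqtl_id"],
                    "true_pos": float(locus["position"]),
                    "sigma": sigma,
                }
            )
    return study_maps, experiments, experiment_to_map, qtls, pd.DataFrame(truth_rows)


_PROFILE_TEMPLATES = ("early", "mid", "late", "early_and_late")


def _template_profile(
    rng: np.random.Generator, label: str, t: np.ndarray
) -> np.ndarray:
    peak = float(_loguniform(rng, 5.0, 80.0))

    def bump(center: float, width: float) -> np.ndarray:
        return np.exp(-0.5 * ((t - center) / width) ** 2)

    if label == "early":
        shape = bump(4.0, 3.0)
    elif label == "mid":
        shape = bump(20.0, 5.0)
    elif label == "late":
        shape = bump(34.0, 3.0)
    else:  # early_and_late
        shape = np.maximum(bump(4.0, 3.0), bump(34.0, 3.0))
    noise = rng.uniform(0.0, 0.05, size=t.size)
    return peak * np.clip(shape + noise, 0.0, None)


def simulate_annotation_and_expression(
    scenario: SimulationScenario,
    reference: GeneticMap,
    plan: Optional[pd.DataFrame] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[GeneRecord], pd.DataFrame, dict[str, set[str]], pd.DataFrame]:
    """Gene models tiling each chromosome, FPKM time courses, GO terms.

    Genes falling inside a true-MQTL physical window (true position +/- 5 cM
    through the reference anchors) are labelled ``in_mqtl`` and enriched for
    the planted GO term; expression profiles are drawn from labelled
    early/mid/late/bimodal templates, with a seeded share left unexpressed.
    """
    rng = rng or np.random.default_rng(scenario.seed)
    if plan is None:
        plan = plan_true_mqtls(scenario, rng)
    t = _DAP_TIMEPOINTS
    genes: list[GeneRecord] = []
    rows_fpkm = {}
    labels = []
    go_table: dict[str, set[str]] = {}
    background_terms = [f"GO:{i:07d}" for i in range(1, 16)]
    planted_term = "GO:1111111"

    # physical windows of the true loci
    windows: dict[str, list[tuple[int, int]]] = {}
    for _, locus in plan.iterrows():
        group = str(locus["group"])
        pairs = anchor_pairs_from_loci(reference.groups[group])
        lo, _ = genetic_to_physical(
            max(locus["position"] - 5.0, 0.0), pairs
        )
        hi, _ = genetic_to_physical(
            min(locus["position"] + 5.0, scenario.group_length), pairs
        )
        windows.setdefault(group, []).append((min(lo, hi), max(lo, hi)))

    for group in scenario.groups:
        n_genes = scenario.genes_per_chromosome
        starts = np.linspace(1, scenario.chromosome_bp - 5000, n_genes).astype(int)
        for j, start in enumerate(starts):
            gene_id = f"gene{group}_{j:04d}"
            end = int(start + rng.integers(1500, 5000))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GeneRecord(
                    gene_id=gene_id,
                    interval=GenomicInterval(group, int(start), end),
                    strand=strand,
                )
            )
            in_mqtl = any(
                start <= w_hi and end >= w_lo for w_lo, w_hi in windows.get(group, [])
            )
            label = (
                "not_expressed"
                if rng.random() < 0.2
                else str(rng.choice(_PROFILE_TEMPLATES))
            )
            if label == "not_expressed":
                values = rng.uniform(0.0, 0.5, size=t.size)
            else:
                values = _template_profile(rng, label, t)
            rows_fpkm[gene_id] = values
            terms = {
                term for term in background_terms if rng.random() < 0.05
            }
            p_planted = 0.5 if in_mqtl else 0.05
            if rng.random() < p_planted:
                terms.add(planted_term)
            if terms:
                go_table[gene_id] = terms
            labels.append(
                {
                    "gene_id": gene_id,
                    "window_label": label,
                    "in_mqtl": in_mqtl,
                    "has_planted_term": planted_term in terms,
                }
            )
    fpkm = pd.DataFrame.from_dict(rows_fpkm, orient="index", columns=t)
    fpkm.index.name = "gene_id"
    return genes, fpkm, go_table, pd.DataFrame(labels)


def simulate(scenario: SimulationScenario) -> SimulatedData:
    """Run the full generator: maps, experiments, QTLs, annotation, truth."""
    streams = [
        np.random.default_rng(s)
        for s in np.random.SeedSequence(scenario.seed).generate_state(4)
    ]
    reference = simulate_reference_map(scenario, streams[0])
    plan = plan_true_mqtls(scenario, streams[1])
    study_maps, experiments, exp_to_map, qtls, truth = simulate_experiments(
        scenario, reference, streams[2], plan
    )
    genes, fpkm, go_table, labels = simulate_annotation_and_expression(
        scenario, reference, plan, streams[3]
    )
    return SimulatedData(
        scenario=scenario,
        reference=reference,
        study_maps=study_maps,
        experiments=experiments,
        experiment_to_map=exp_to_map,
        qtls=qtls,
        truth=truth,
        plan=plan,
        genes=genes,
        fpkm=fpkm,
        go_table=go_table,
        gene_labels=labels,
    )


def write_gff3(genes: list[GeneRecord], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                "\t".join(
                    [
                        g.interval.chromosome,
                        "mqtlmap_sim",
                        "gene",
                        str(g.interval.start),
                        str(g.interval.end),
                        ".",
                        g.strand,
                        ".",
                        f"ID={g.gene_id}",
                    ]
                )
                + "\n"
            )
    return path


def write_bundle(data: SimulatedData, outdir: str | Path) -> Path:
    """Write the full fixture bundle as the pipeline's canonical input files."""
    outdir = Path(outdir)
    (outdir / "maps").mkdir(parents=True, exist_ok=True)
    mio.write_genetic_map(data.reference, outdir / "maps" / "reference.tsv")
    for map_id, gmap in data.study_maps.items():
        mio.write_genetic_map(gmap, outdir / "maps" / f"{map_id}.tsv")
    mio.write_experiment_table(data.experiments.values(), outdir / "experiments.tsv")
    mio.write_qtl_table(data.qtls, outdir / "qtls.tsv")
    data.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    data.plan.to_csv(outdir / "true_mqtls.tsv", sep="\t", index=False)
    write_gff3(data.genes, outdir / "annotation.gff3")
    fpkm = data.fpkm.copy()
    fpkm.columns = [f"{c:g}" for c in fpkm.columns]
    fpkm.to_csv(outdir / "fpkm.tsv", sep="\t")
    go_rows = [
        {"gene_id": gene, "go_term": term}
        for gene in sorted(data.go_table)
        for term in sorted(data.go_table[gene])
    ]
    pd.DataFrame(go_rows, columns=["gene_id", "go_term"]).to_csv(
        outdir / "go_terms.tsv", sep="\t", index=False
    )
    data.gene_labels.to_csv(outdir / "gene_labels.tsv", sep="\t", index=False)
    manifest = {
        "scenario": asdict(data.scenario),
        "reference_map": "maps/reference.tsv",
        "study_maps": {
            exp_id: f"maps/{map_id}.tsv"
            for exp_id, map_id in data.experiment_to_map.items()
        },
        "experiments": "experiments.tsv",
        "qtl_table": "qtls.tsv",
        "annotation": "annotation.gff3",
        "expression": "fpkm.tsv",
        "go_table": "go_terms.tsv",
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=list)
    return outdir
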