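"""Readers and writers for the pipeline's tabular formats.

The canonical on-disk dialect is tab-separated text with a header row.
Genetic maps use columns ``marker, linkage_group, cM_position`` and an
optional ``bp_position``; QTL tables use the field names of
:class:`~mqtlmap.core.QTLRecord`.  Physical intervals are written 1-based
inclusive in report tables and 0-based half-open in BED files.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .core import (
    CoordSystem,
    ExperimentMeta,
    GeneticMap,
    GenomicInterval,
    MarkerLocus,
    ParseError,
    QTLRecord,
    Trait,
    ValidationError,
)

logger = logging.getLogger(__name__)

_MAP_COLUMNS = ["marker", "linkage_group", "cM_position"]
_QTL_COLUMNS = [
    "qtl_id",
    "trait",
    "experiment_id",
    "linkage_group",
    "peak_pos",
    "ci_start",
    "ci_end",
    "flank_left",
    "flank_right",
    "lod",
    "r_squared",
    "coord_system",
]
_EXPERIMENT_COLUMNS = [
    "experiment_id",
    "parents",
    "population_type",
    "population_size",
    "n_environments",
    "mapping_method",
]


def _opt_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str) and not value.strip():
        return None
    return float(value)


def _opt_str(value) -> Optional[str]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip()
    return s or None


def read_genetic_map(path: str | Path, map_id: str) -> GeneticMap:
    """Read a tab-separated linkage map into a :class:`GeneticMap`.

    Markers are sorted by genetic position within each linkage group;
    duplicate marker names raise :class:`ValidationError`.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            dtype={"marker": str, "linkage_group": str},
            float_precision="round_trip",
        )
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"{path}: cannot parse map file: {exc}") from exc
    missing = [c for c in _MAP_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    has_bp = "bp_position" in df.columns

    groups: dict[str, list[MarkerLocus]] = {}
    for idx, row in df.iterrows():
        line_no = idx + 2  # 1-based, after the header line
        try:
            cm = float(row["cM_position"])
        except (TypeError, ValueError) as exc:
            raise ParseError(
                f"{path}:{line_no}: malformed cM_position {row['cM_position']!r}"
            ) from exc
        bp = None
        if has_bp:
            bp_raw = _opt_float(row["bp_position"])
            bp = int(bp_raw) if bp_raw is not None else None
        try:
            locus = MarkerLocus(
                name=str(row["marker"]),
                linkage_group=str(row["linkage_group"]),
                genetic_pos=cm,
                physical_pos=bp,
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}:{line_no}: {exc}") from exc
        groups.setdefault(locus.linkage_group, []).append(locus)
    return GeneticMap(map_id=map_id, groups=groups)


def write_genetic_map(gmap: GeneticMap, path: str | Path) -> Path:
    path = Path(path)
    rows = []
    for group, loci in gmap.groups.items():
        for m in loci:
            rows.append(
                {
                    "marker": m.name,
                    "linkage_group": group,
                    "cM_position": m.genetic_pos,
                    "bp_position": "" if m.physical_pos is None else m.physical_pos,
                }
            )
    pd.DataFrame(rows, columns=_MAP_COLUMNS + ["bp_position"]).to_csv(
        path, sep="\t", index=False
    )
    return path


def read_experiment_table(path: str | Path) -> dict[str, ExperimentMeta]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"experiment_id": str})
    missing = [c for c in _EXPERIMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    experiments: dict[str, ExperimentMeta] = {}
    for idx, row in df.iterrows():
        meta = ExperimentMeta(
            experiment_id=str(row["experiment_id"]),
            parents=str(row["parents"]),
            population_type=str(row["population_type"]),
            population_size=int(row["population_size"]),
            n_environments=int(row["n_environments"]),
            mapping_method=str(row["mapping_method"]),
        )
        if meta.experiment_id in experiments:
            raise ValidationError(
                f"{path}:{idx + 2}: duplicate experiment_id {meta.experiment_id!r}"
            )
        experiments[meta.experiment_id] = meta
    return experiments


def write_experiment_table(
    experiments: Iterable[ExperimentMeta], path: str | Path
) -> Path:
    path = Path(path)
    rows = [
        {
            "experiment_id": e.experiment_id,
            "parents": e.parents,
            "population_type": e.population_type.value,
            "population_size": e.population_size,
            "n_environments": e.n_environments,
            "mapping_method": e.mapping_method.value,
        }
        for e in experiments
    ]
    pd.DataFrame(rows, columns=_EXPERIMENT_COLUMNS).to_csv(path, sep="\t", index=False)
    return path


def read_qtl_table(
    path: str | Path, experiments: dict[str, ExperimentMeta]
) -> tuple[list[QTLRecord], list[tuple[QTLRecord, str]]]:
    """Read a QTL table, splitting records into accepted and rejected lists.

    Rejected entries are ``(record, reason)`` pairs for records that carry
    neither a CI, nor flanking markers, nor the R-squared needed to impute a
    CI.  Hard schema violations (unknown experiment, inverted CI) raise.
    """
    path = Path(path)
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={
            "qtl_id": str,
            "experiment_id": str,
            "linkage_group": str,
            "flank_left": str,
            "flank_right": str,
        },
        float_precision="round_trip",
    )
    missing = [c for c in _QTL_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")

    accepted: list[QTLRecord] = []
    rejected: list[tuple[QTLRecord, str]] = []
    for idx, row in df.iterrows():
        line_no = idx + 2
        exp_id = str(row["experiment_id"])
        if exp_id not in experiments:
            raise ValidationError(
                f"{path}:{line_no}: unknown experiment_id {exp_id!r}"
            )
        try:
            record = QTLRecord(
                qtl_id=str(row["qtl_id"]),
                trait=Trait(str(row["trait"])),
                experiment_id=exp_id,
                linkage_group=str(row["linkage_group"]),
                peak_pos=_opt_float(row["peak_pos"]),
                ci_start=_opt_float(row["ci_start"]),
                ci_end=_opt_float(row["ci_end"]),
                flank_left=_opt_str(row["flank_left"]),
                flank_right=_opt_str(row["flank_right"]),
                lod=_opt_float(row["lod"]),
                r_squared=_opt_float(row["r_squared"]),
                coord_system=CoordSystem(str(row["coord_system"])),
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}:{line_no}: {exc}") from exc
        if not record.is_informative():
            rejected.append((record, "insufficient information"))
            continue
        accepted.append(record)
    if rejected:
        logger.info(
            "%s: rejected %d of %d QTL records for insufficient information",
            path.name,
            len(rejected),
            len(df),
        )
    return accepted, rejected


def write_qtl_table(records: Iterable[QTLRecord], path: str | Path) -> Path:
    path = Path(path)
    fmt = lambda v: "" if v is None else v  # noqa: E731
    rows = [
        {
            "qtl_id": r.qtl_id,
            "trait": r.trait.value,
            "experiment_id": r.experiment_id,
            "linkage_group": r.linkage_group,
            "peak_pos": fmt(r.peak_pos),
            "ci_start": fmt(r.ci_start),
            "ci_end": fmt(r.ci_end),
            "flank_left": fmt(r.flank_left),
            "flank_right": fmt(r.flank_right),
            "lod": fmt(r.lod),
            "r_squared": fmt(r.r_squared),
            "coord_system": r.coord_system.value,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_QTL_COLUMNS).to_csv(path, sep="\t", index=False)
    return path


_MQTL_COLUMNS = [
    "mqtl",
    "trait",
    "chromosome",
    "position_cM",
    "pve_percent",
    "ci_start_cM",
    "ci_end_cM",
    "ci_width_cM",
    "left_bp",
    "right_bp",
    "n_qtls",
    "n_genes",
    "n_experiments",
]


def write_mqtl_table(mqtls: Sequence, path: str | Path) -> Path:
    """Write the consensus-locus report (one row per meta-QTL).

    Unresolved physical intervals and gene counts are written as empty
    fields, never as zeros.
    """
    path = Path(path)
    rows = []
    for m in mqtls:
        rows.append(
            {
                "mqtl": m.name,
                "trait": m.trait.value,
                "chromosome": m.linkage_group,
                "position_cM": round(m.position, 4),
                "pve_percent": round(m.pve_percent, 4),
                "ci_start_cM": round(m.ci_start, 4),
                "ci_end_cM": round(m.ci_end, 4),
                "ci_width_cM": round(m.ci_end - m.ci_start, 4),
                "left_bp": "" if m.physical is None else m.physical.start,
                "right_bp": "" if m.physical is None else m.physical.end,
                "n_qtls": len(m.members),
                "n_genes": "" if m.genes is None else len(m.genes),
                "n_experiments": m.n_experiments,
            }
        )
    pd.DataFrame(rows, columns=_MQTL_COLUMNS).to_csv(path, sep="\t", index=False)
    return path


def write_bed(
    intervals: Iterable[GenomicInterval],
    path: str | Path,
    names: Optional[Sequence[str]] = None,
) -> Path:
    """Write intervals as BED (0-based half-open): start-1, end."""
    path = Path(path)
    intervals = list(intervals)
    if names is not None and len(names) != len(intervals):
        raise ValueError("names must match intervals in length")
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            fields = [iv.chromosome, str(iv.start - 1), str(iv.end)]
            if names is not None:
                fields.append(names[i])
            fh.write("\t".join(fields) + "\n")
    return path


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Read a gene x timepoint FPKM matrix; columns are DAP values."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.columns = [float(c) for c in df.columns]
    return df


def read_go_table(path: str | Path) -> dict[str, set[str]]:
    """Read a two-column gene_id / go_term table into a gene -> terms map."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene_id", "go_term"} <= set(df.columns):
        raise ParseError(f"{path}: need columns gene_id, go_term")
    table: dict[str, set[str]] = {}
    for gene, term in zip(df["gene_id"], df["go_term"]):
        table.setdefault(gene, set()).add(term)
    return table
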