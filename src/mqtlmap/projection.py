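"""Projection of literature QTLs onto the consensus map.

Every initial QTL must be re-expressed on the consensus cM scale before
meta-analysis.  Four routes exist, recorded as the projected QTL's
provenance:

* ``both_flanks`` — peak and CI endpoints transferred homothetically through
  the order-consistent shared markers of the source and consensus maps (or
  both flanking markers located directly on the consensus map when the study
  published no map);
* ``one_flank_plus_formula`` — only one flanking marker is placeable; the CI
  width is imputed from population size and R² and laid out from the known
  flank, the peak at the CI midpoint;
* ``physical_converted`` — SNP-based studies report bp coordinates, which
  are converted to cM through the consensus map's physical anchors;
* ``formula_only`` — peak projected, CI entirely imputed.

QTLs that cannot be placed (no shared markers, flanks absent from the
consensus, extrapolation beyond the configured cap) are discarded with a
recorded reason.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from .anchoring import anchor_pairs_from_loci, physical_to_genetic
from .ci import CI_TO_SIGMA_DIVISOR, impute_ci, NoFormulaError
from .consensus import ConsensusMap, shared_marker_frame
from .core import CoordSystem, ExperimentMeta, GeneticMap, QTLRecord
from .interpolate import piecewise_transfer

logger = logging.getLogger(__name__)

#: Maximum allowed extrapolation beyond the terminal shared markers,
#: as a fraction of the consensus group length.
DEFAULT_EXTRAPOLATION_CAP = 0.2


class Provenance(str, Enum):
    BOTH_FLANKS = "both_flanks"
    ONE_FLANK_PLUS_FORMULA = "one_flank_plus_formula"
    PHYSICAL_CONVERTED = "physical_converted"
    FORMULA_ONLY = "formula_only"


class ProjectionError(ValueError):
    """A QTL cannot be projected; the message is the discard reason."""


@dataclass
class ProjectedQTL:
    """A QTL re-expressed on the consensus map, with its position s.d."""

    source: QTLRecord
    linkage_group: str
    peak_pos: float
    ci_start: float
    ci_end: float
    provenance: Provenance
    extrapolated: bool = False
    sigma: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.ci_start <= self.peak_pos <= self.ci_end:
            raise ProjectionError(
                f"QTL {self.source.qtl_id!r}: peak {self.peak_pos} outside CI "
                f"[{self.ci_start}, {self.ci_end}]"
            )
        width = self.ci_end - self.ci_start
        if width <= 0:
            raise ProjectionError(
                f"QTL {self.source.qtl_id!r}: non-positive projected CI width"
            )
        self.sigma = width / CI_TO_SIGMA_DIVISOR

    @property
    def qtl_id(self) -> str:
        return self.source.qtl_id

    @property
    def experiment_id(self) -> str:
        return self.source.experiment_id


@dataclass(frozen=True)
class DiscardedQTL:
    qtl_id: str
    reason: str


def project_position(
    pos: float, xs: list[float], ys: list[float]
) -> tuple[float, bool]:
    """Transfer one source-map position to the consensus through shared markers.

    ``xs``/``ys`` are the source/consensus coordinates of the
    order-consistent shared markers (strictly increasing in x).  Positions
    outside the shared span use the nearest interval's ratio and are flagged
    extrapolated.
    """
    return piecewise_transfer(pos, xs, ys)


def _imputed_width(qtl: QTLRecord, experiment: ExperimentMeta) -> float:
    if qtl.r_squared is None:
        raise ProjectionError(
            f"QTL {qtl.qtl_id!r}: no CI, no flanks and no R² to impute from"
        )
    try:
        return impute_ci(
            experiment.population_size, qtl.r_squared, experiment.population_type
        )
    except NoFormulaError as exc:
        raise ProjectionError(f"QTL {qtl.qtl_id!r}: {exc}") from exc


def _check_extrapolation(
    values: list[float],
    span: tuple[float, float],
    group_length: float,
    cap: float,
    qtl_id: str,
) -> bool:
    """True if any value extrapolates; raise when beyond the cap."""
    lo, hi = span
    allowance = cap * group_length
    extrapolated = False
    for v in values:
        if v < lo or v > hi:
            extrapolated = True
        if v < lo - allowance or v > hi + allowance:
            raise ProjectionError(
                f"QTL {qtl_id!r}: position {v:.2f} cM extrapolates beyond "
                f"{cap:.0%} of the group length outside the shared span"
            )
    return extrapolated


def _finalize(
    qtl: QTLRecord,
    group: str,
    peak: float,
    ci_start: float,
    ci_end: float,
    provenance: Provenance,
    extrapolated: bool,
) -> ProjectedQTL:
    if ci_start > ci_end:
        ci_start, ci_end = ci_end, ci_start
    ci_start = max(ci_start, 0.0)
    if ci_end <= ci_start:
        raise ProjectionError(
            f"QTL {qtl.qtl_id!r}: degenerate projected CI at {ci_start:.2f} cM"
        )
    if not ci_start <= peak <= ci_end:
        logger.info(
            "QTL %s: projected peak %.2f clipped into CI [%.2f, %.2f]",
            qtl.qtl_id,
            peak,
            ci_start,
            ci_end,
        )
        peak = min(max(peak, ci_start), ci_end)
    return ProjectedQTL(
        source=qtl,
        linkage_group=group,
        peak_pos=peak,
        ci_start=ci_start,
        ci_end=ci_end,
        provenance=provenance,
        extrapolated=extrapolated,
    )


def project_qtl(
    qtl: QTLRecord,
    source_map: Optional[GeneticMap],
    consensus: ConsensusMap,
    experiment: ExperimentMeta,
    extrapolation_cap: float = DEFAULT_EXTRAPOLATION_CAP,
) -> ProjectedQTL:
    """Project one QTL onto the consensus map (raises ProjectionError if not).

    ``source_map`` is None for studies that published no linkage map; their
    QTLs are placed through flanking-marker names found directly on the
    consensus map, or through physical coordinates via the anchors.
    """
    group = qtl.linkage_group
    cons_loci = consensus.groups.get(group)
    if not cons_loci:
        raise ProjectionError(
            f"QTL {qtl.qtl_id!r}: linkage group {group!r} absent from consensus"
        )
    group_span = (cons_loci[0].genetic_pos, cons_loci[-1].genetic_pos)
    group_length = group_span[1] - group_span[0]

    if qtl.coord_system is CoordSystem.PHYSICAL:
        return _project_physical(
            qtl, consensus, experiment, group_span, group_length, extrapolation_cap
        )
    if source_map is not None and group in source_map.groups:
        return _project_through_map(
            qtl,
            source_map,
            consensus,
            experiment,
            group_span,
            group_length,
            extrapolation_cap,
        )
    return _project_by_flanks(
        qtl, consensus, experiment, group_span, group_length, extrapolation_cap
    )


def _project_physical(
    qtl, consensus, experiment, group_span, group_length, cap
) -> ProjectedQTL:
    pairs = anchor_pairs_from_loci(consensus.groups[qtl.linkage_group])
    if len(pairs) < 2:
        raise ProjectionError(
            f"QTL {qtl.qtl_id!r}: no physical anchors on group "
            f"{qtl.linkage_group!r} to convert bp coordinates"
        )
    extrapolated = False
    if qtl.has_ci:
        g_start, e1 = physical_to_genetic(qtl.ci_start, pairs)
        g_end, e2 = physical_to_genetic(qtl.ci_end, pairs)
        extrapolated = e1 or e2
        if qtl.peak_pos is not None:
            g_peak, e3 = physical_to_genetic(qtl.peak_pos, pairs)
            extrapolated = extrapolated or e3
        else:
            g_peak = (g_start + g_end) / 2
    elif qtl.peak_pos is not None:
        g_peak, extrapolated = physical_to_genetic(qtl.peak_pos, pairs)
        width = _imputed_width(qtl, experiment)
        g_start, g_end = g_peak - width / 2, g_peak + width / 2
    else:
        raise ProjectionError(
            f"QTL {qtl.qtl_id!r}: physical record carries neither CI nor peak"
        )
    extrapolated |= _check_extrapolation(
        [g_peak], group_span, group_length, cap, qtl.qtl_id
    )
    return _finalize(
        qtl,
        qtl.linkage_group,
        g_peak,
        g_start,
        g_end,
        Provenance.PHYSICAL_CONVERTED,
        extrapolated,
    )


def _project_through_map(
    qtl, source_map, consensus, experiment, group_span, group_length, cap
) -> ProjectedQTL:
    group = qtl.linkage_group
    xs, ys = shared_marker_frame(source_map, consensus, group)
    if len(xs) < 2:
        raise ProjectionError(
            f"QTL {qtl.qtl_id!r}: fewer than two order-consistent shared "
            f"markers between map {source_map.map_id!r} and the consensus on "
            f"group {group!r}"
        )
    src_pos = source_map.positions(group)
    peak = qtl.peak_pos
    # resolve source-scale CI, imputing the width if necessary
    if qtl.has_ci:
        s_start, s_end = qtl.ci_start, qtl.ci_end
        provenance = Provenance.BOTH_FLANKS
    elif qtl.has_flanks and qtl.flank_left in src_pos and qtl.flank_right in src_pos:
        s_start = src_pos[qtl.flank_left]
        s_end = src_pos[qtl.flank_right]
        if s_start > s_end:
            s_start, s_end = s_end, s_start
        provenance = Provenance.BOTH_FLANKS
    else:
        width = _imputed_width(qtl, experiment)
        if peak is None:
            raise ProjectionError(
                f"QTL {qtl.qtl_id!r}: no CI, no resolvable flanks and no peak"
            )
        s_start, s_end = peak - width / 2, peak + width / 2
        provenance = Provenance.FORMULA_ONLY
    if peak is None:
        peak = (s_start + s_end) / 2
    # each position projects through its own flanking shared interval
    p_peak, e1 = piecewise_transfer(peak, xs, ys)
    p_start, e2 = piecewise_transfer(s_start, xs, ys)
    p_end, e3 = piecewise_transfer(s_end, xs, ys)
    extrapolated = e1 or e2 or e3
    extrapolated |= _check_extrapolation(
        [p_peak, p_start, p_end], group_span, group_length, cap, qtl.qtl_id
    )
    return _finalize(qtl, group, p_peak, p_start, p_end, provenance, extrapolated)


def _project_by_flanks(
    qtl, consensus, experiment, group_span, group_length, cap
) -> ProjectedQTL:
    group = qtl.linkage_group
    cons_pos = consensus.positions(group)
    left = cons_pos.get(qtl.flank_left) if qtl.flank_left else None
    right = cons_pos.get(qtl.flank_right) if qtl.flank_right else None
    if left is not None and right is not None:
        s, e = sorted((left, right))
        peak = (s + e) / 2
        return _finalize(qtl, group, peak, s, e, Provenance.BOTH_FLANKS, False)
    if left is None and right is None:
        raise ProjectionError(
            f"QTL {qtl.qtl_id!r}: neither flanking marker found on the "
            "consensus map"
        )
    # one flank known: lay the imputed CI out from it; peak at the midpoint
    known = left if left is not None else right
    width = _imputed_width(qtl, experiment)
    if left is not None:
        s, e = known, known + width
    else:
        s, e = known - width, known
    peak = (s + e) / 2
    _check_extrapolation([peak], group_span, group_length, cap, qtl.qtl_id)
    return _finalize(
        qtl, group, peak, s, e, Provenance.ONE_FLANK_PLUS_FORMULA, False
    )


def project_qtls(
    qtls: list[QTLRecord],
    source_maps: dict[str, GeneticMap],
    consensus: ConsensusMap,
    experiments: dict[str, ExperimentMeta],
    experiment_to_map: Optional[dict[str, str]] = None,
    extrapolation_cap: float = DEFAULT_EXTRAPOLATION_CAP,
) -> tuple[list[ProjectedQTL], list[DiscardedQTL]]:
    """Project a QTL collection; every input ends up projected or discarded.

    ``experiment_to_map`` links experiment_ids to source map_ids; experiments
    without an entry are projected by flank lookup on the consensus map.
    """
    experiment_to_map = experiment_to_map or {}
    projected: list[ProjectedQTL] = []
    discarded: list[DiscardedQTL] = []
    for qtl in qtls:
        experiment = experiments.get(qtl.experiment_id)
        if experiment is None:
            discarded.append(
                DiscardedQTL(qtl.qtl_id, f"unknown experiment {qtl.experiment_id!r}")
            )
            continue
        map_id = experiment_to_map.get(qtl.experiment_id)
        source_map = source_maps.get(map_id) if map_id else None
        try:
            projected.append(
                project_qtl(qtl, source_map, consensus, experiment, extrapolation_cap)
            )
        except ProjectionError as exc:
            logger.info("discarded %s: %s", qtl.qtl_id, exc)
            discarded.append(DiscardedQTL(qtl.qtl_id, str(exc)))
    return projected, discarded
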