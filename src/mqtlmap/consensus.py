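"""Integration of study linkage maps with a reference map.

The reference cM scale (in the maize study, IBM2 2008 Neighbors) is
authoritative: reference markers keep their positions exactly.  Each study
map is merged against the reference independently (star topology).  Shared
markers whose order disagrees between the two maps are resolved by keeping
the largest order-consistent subset — a longest increasing subsequence of
the study's markers indexed by reference rank — and study-only markers are
then placed by homothetic interpolation between their nearest retained
shared markers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .core import GeneticMap, MarkerLocus
from .interpolate import piecewise_transfer, strictly_increasing_pairs

logger = logging.getLogger(__name__)


def lis_indices(seq: list) -> list[int]:
    """Indices of a longest strictly increasing subsequence of ``seq``.

    Among all maximum-length increasing subsequences, returns the one whose
    *value* sequence is lexicographically smallest (deterministic tie-break;
    remaining value ties broken toward the earliest index).
    """
    n = len(seq)
    if n == 0:
        return []
    # g[i] = length of the longest increasing subsequence starting at i
    g = [1] * n
    for i in range(n - 2, -1, -1):
        for j in range(i + 1, n):
            if seq[j] > seq[i] and g[j] + 1 > g[i]:
                g[i] = g[j] + 1
    length = max(g)
    result: list[int] = []
    last_idx = -1
    last_val = float("-inf")
    for remaining in range(length, 0, -1):
        best = None
        for i in range(last_idx + 1, n):
            if seq[i] > last_val and g[i] >= remaining:
                if best is None or seq[i] < seq[best]:
                    best = i
        result.append(best)
        last_idx = best
        last_val = seq[best]
    return result


def resolve_marker_conflicts(
    ref_order: list[str], study_order: list[str]
) -> list[str]:
    """Largest subset of shared markers whose relative order agrees in both maps.

    Returns marker names in reference order.  An empty shared set returns an
    empty list (the group cannot be merged).
    """
    shared = set(ref_order) & set(study_order)
    if not shared:
        logger.warning("no shared markers between maps; group cannot be merged")
        return []
    rank = {name: i for i, name in enumerate(ref_order) if name in shared}
    shared_in_study = [name for name in study_order if name in shared]
    seq = [rank[name] for name in shared_in_study]
    retained = [shared_in_study[i] for i in lis_indices(seq)]
    # the retained subset is increasing in reference rank, so it is already
    # in reference order
    return retained


@dataclass
class ConsensusMap(GeneticMap):
    """A reference-scaled merged map with per-marker provenance.

    ``provenance`` maps marker name to the set of source map_ids it was
    observed in; ``flags`` records placement caveats (e.g. "extrapolated").
    """

    provenance: dict[str, set[str]] = field(default_factory=dict)
    flags: dict[str, set[str]] = field(default_factory=dict)

    def anchors(self, group: str) -> list[MarkerLocus]:
        """Markers of a group that carry a physical position, in cM order."""
        return [m for m in self.groups.get(group, []) if m.is_anchor]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for group, loci in self.groups.items():
            for m in loci:
                rows.append(
                    {
                        "marker": m.name,
                        "linkage_group": group,
                        "cM_position": m.genetic_pos,
                        "bp_position": m.physical_pos,
                        "anchor": m.is_anchor,
                        "provenance": ",".join(sorted(self.provenance.get(m.name, set()))),
                        "flags": ",".join(sorted(self.flags.get(m.name, set()))),
                    }
                )
        return pd.DataFrame(rows)

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def shared_marker_frame(
    source: GeneticMap, consensus: GeneticMap, group: str
) -> tuple[list[float], list[float]]:
    """Order-consistent shared-marker coordinates (source cM, consensus cM).

    The conflict-resolved subset is used, so the returned x/y lists are both
    increasing; collided x positions are deduplicated.
    """
    src_loci = source.groups.get(group, [])
    cons_pos = consensus.positions(group)
    ref_order = [m.name for m in consensus.groups.get(group, [])]
    study_order = [m.name for m in src_loci]
    retained = resolve_marker_conflicts(ref_order, study_order)
    src_pos = source.positions(group)
    xs = [src_pos[name] for name in retained]
    ys = [cons_pos[name] for name in retained]
    pairs = sorted(zip(xs, ys))
    xs, ys = strictly_increasing_pairs([p[0] for p in pairs], [p[1] for p in pairs])
    return xs, ys


def merge_maps(reference: GeneticMap, studies: list[GeneticMap]) -> ConsensusMap:
    """Merge study maps into the reference scale.

    Reference markers keep their positions; retained shared markers gain the
    study's provenance; study-only markers are interpolated (extrapolation
    beyond terminal shared markers is flagged).  A study group sharing fewer
    than two markers with the reference contributes nothing (warning).
    """
    groups: dict[str, list[MarkerLocus]] = {
        g: list(loci) for g, loci in reference.groups.items()
    }
    provenance: dict[str, set[str]] = {
        m.name: {reference.map_id} for loci in groups.values() for m in loci
    }
    flags: dict[str, set[str]] = {}
    ref_names = set(provenance)

    for study in studies:
        for group, study_loci in study.groups.items():
            if group not in reference.groups:
                logger.warning(
                    "map %s: linkage group %s absent from reference; skipped",
                    study.map_id,
                    group,
                )
                continue
            ref_order = [m.name for m in reference.groups[group]]
            study_order = [m.name for m in study_loci]
            retained = resolve_marker_conflicts(ref_order, study_order)
            dropped = [n for n in study_order if n in set(ref_order) and n not in set(retained)]
            if dropped:
                logger.info(
                    "map %s group %s: %d order-conflicting marker(s) discarded: %s",
                    study.map_id,
                    group,
                    len(dropped),
                    ", ".join(dropped[:10]),
                )
            if len(retained) < 2:
                logger.warning(
                    "map %s group %s: <2 order-consistent shared markers; "
                    "group contributes no markers",
                    study.map_id,
                    group,
                )
                continue
            ref_pos = reference.positions(group)
            study_pos = study.positions(group)
            xs = [study_pos[n] for n in retained]
            ys = [ref_pos[n] for n in retained]
            pairs = sorted(zip(xs, ys))
            xs, ys = strictly_increasing_pairs(
                [p[0] for p in pairs], [p[1] for p in pairs]
            )
            for name in retained:
                provenance.setdefault(name, set()).add(study.map_id)
            if len(xs) < 2:
                continue
            for locus in study_loci:
                if locus.name in ref_names:
                    continue
                if locus.name in provenance:
                    # already placed by an earlier study; keep first placement
                    provenance[locus.name].add(study.map_id)
                    continue
                value, extrapolated = piecewise_transfer(locus.genetic_pos, xs, ys)
                value = max(value, 0.0)
                groups[group].append(
                    MarkerLocus(
                        name=locus.name,
                        linkage_group=group,
                        genetic_pos=value,
                        physical_pos=locus.physical_pos,
                    )
                )
                provenance[locus.name] = {study.map_id}
                if extrapolated:
                    flags.setdefault(locus.name, set()).add("extrapolated")

    return ConsensusMap(
        map_id=f"consensus({reference.map_id})",
        groups=groups,
        provenance=provenance,
        flags=flags,
    )


def map_density(gmap: GeneticMap) -> tuple[float, dict[str, float]]:
    """Markers per cM, overall and per linkage group.

    Overall density is total marker count over total map length (sum of
    per-group spans).  Zero-length groups are excluded from per-group
    densities and contribute no length (warning).
    """
    per_group: dict[str, float] = {}
    total_markers = 0
    total_length = 0.0
    for group, loci in gmap.groups.items():
        if not loci:
            continue
        length = loci[-1].genetic_pos - loci[0].genetic_pos
        total_markers += len(loci)
        if length <= 0:
            logger.warning("group %s has zero genetic length; density undefined", group)
            continue
        per_group[group] = len(loci) / length
        total_length += length
    if total_length <= 0:
        raise ValueError("map has no positive-length linkage group")
    return total_markers / total_length, per_group


def density_from_counts(n_markers: int, total_length_cm: float) -> float:
    """Marker density (markers/cM) from summary counts."""
    if total_length_cm <= 0:
        raise ValueError("total map length must be positive")
    return n_markers / total_length_cm


def ci_fold_reduction(initial_mean_ci: float, mqtl_mean_ci: float) -> float:
    """Fractional CI reduction achieved by meta-analysis: (initial - final)/initial."""
    if initial_mean_ci <= 0:
        raise ValueError("initial mean CI must be positive")
    return (initial_mean_ci - mqtl_mean_ci) / initial_mean_ci
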