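"""Genetic <-> physical coordinate conversion and trait-pair overlap domains.

Markers that carry both a cM and a bp position ("anchors") define a
piecewise-linear transfer between the consensus genetic map and the genome
assembly:

    p = p1 + (p2 - p1) * (g - g1) / (g2 - g1)

with (g1, p1), (g2, p2) the flanking anchors of the query.  Anchor sets can
contain bp-inversions relative to the assembly; the minimal set of inverted
anchors is dropped (longest-increasing-subsequence rule) so the transfer is
monotone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

from intervaltree import IntervalTree

from .core import GenomicInterval, MarkerLocus
from .consensus import lis_indices
from .interpolate import piecewise_transfer, strictly_increasing_pairs

logger = logging.getLogger(__name__)

AnchorPair = tuple[float, float]  # (cM, bp)


def monotone_anchor_pairs(pairs: Sequence[AnchorPair]) -> tuple[list[float], list[float]]:
    """Sort anchors by cM and drop the minimal bp-inverted subset.

    Returns (gs, bps), both strictly increasing in g and non-decreasing in bp.
    """
    pairs = sorted(pairs)
    gs, bps = strictly_increasing_pairs(
        [p[0] for p in pairs], [p[1] for p in pairs]
    )
    keep = lis_indices(bps)
    if len(keep) < len(bps):
        logger.warning(
            "%d of %d anchors dropped as bp-inverted", len(bps) - len(keep), len(bps)
        )
    return [gs[i] for i in keep], [bps[i] for i in keep]


def anchor_pairs_from_loci(loci: Sequence[MarkerLocus]) -> list[AnchorPair]:
    return [
        (m.genetic_pos, float(m.physical_pos))
        for m in loci
        if m.physical_pos is not None
    ]


def genetic_to_physical(
    g: float, anchors: Sequence[AnchorPair], precise: bool = False
) -> tuple[int | float, bool]:
    """Interpolate a genetic position (cM) to a physical one (bp).

    Returns ``(bp, extrapolated)``; bp is rounded to the nearest integer and
    floored at 1 unless ``precise`` (the unrounded float, for exact inverse
    transforms).
    """
    gs, bps = monotone_anchor_pairs(anchors)
    if len(gs) < 2:
        raise ValueError("need at least two usable anchors")
    value, extrapolated = piecewise_transfer(g, gs, bps)
    if precise:
        return value, extrapolated
    return max(1, int(round(value))), extrapolated


def physical_to_genetic(
    p: float, anchors: Sequence[AnchorPair]
) -> tuple[float, bool]:
    """Inverse transfer: physical position (bp) to genetic position (cM)."""
    gs, bps = monotone_anchor_pairs(anchors)
    bps, gs = strictly_increasing_pairs(bps, gs)
    if len(bps) < 2:
        raise ValueError("need at least two usable anchors")
    return piecewise_transfer(p, bps, gs)


def mqtl_physical_interval(mqtl, consensus) -> Optional[GenomicInterval]:
    """Physical interval spanned by an MQTL's genetic CI, via group anchors.

    Returns None (and logs) when the linkage group carries fewer than two
    usable anchors.  Endpoints are swapped if the anchor orientation inverts
    them, so start <= end always holds.
    """
    pairs = anchor_pairs_from_loci(consensus.groups.get(mqtl.linkage_group, []))
    if len(pairs) < 2:
        logger.warning(
            "MQTL %s: no usable anchors on group %s; physical interval absent",
            mqtl.name,
            mqtl.linkage_group,
        )
        return None
    left, _ = genetic_to_physical(mqtl.ci_start, pairs)
    right, _ = genetic_to_physical(mqtl.ci_end, pairs)
    if left > right:
        left, right = right, left
    return GenomicInterval(mqtl.linkage_group, left, right)


@dataclass(frozen=True)
class OverlapDomain:
    """A genomic region where intervals from the two trait sets intersect."""

    interval: GenomicInterval
    names_a: tuple[str, ...]
    names_b: tuple[str, ...]


def overlap_domains(
    set_a: Sequence[tuple[str, GenomicInterval]],
    set_b: Sequence[tuple[str, GenomicInterval]],
) -> list[OverlapDomain]:
    """Regions where any interval of ``set_a`` intersects any of ``set_b``.

    Pairwise intersections of >= 1 bp are computed per chromosome and merged
    where they themselves overlap; each domain lists the contributing
    interval names from both sets.  Symmetric in its arguments.
    """
    trees: dict[str, IntervalTree] = {}
    for name, iv in set_b:
        trees.setdefault(iv.chromosome, IntervalTree()).addi(
            iv.start, iv.end + 1, name
        )
    # raw pairwise intersections, then a sweep to merge overlapping ones
    raw: dict[str, list[tuple[int, int, str, str]]] = {}
    for name_a, iv in set_a:
        tree = trees.get(iv.chromosome)
        if tree is None:
            continue
        for hit in tree.overlap(iv.start, iv.end + 1):
            start = max(iv.start, hit.begin)
            end = min(iv.end, hit.end - 1)
            raw.setdefault(iv.chromosome, []).append((start, end, name_a, hit.data))
    domains: list[OverlapDomain] = []
    for chrom in sorted(raw):
        pieces = sorted(raw[chrom])
        cur_start, cur_end, a, b = pieces[0][0], pieces[0][1], {pieces[0][2]}, {pieces[0][3]}
        for start, end, name_a, name_b in pieces[1:]:
            if start <= cur_end:  # genuine overlap, not mere adjacency
                cur_end = max(cur_end, end)
                a.add(name_a)
                b.add(name_b)
            else:
                domains.append(
                    OverlapDomain(
                        GenomicInterval(chrom, cur_start, cur_end),
                        tuple(sorted(a)),
                        tuple(sorted(b)),
                    )
                )
                cur_start, cur_end, a, b = start, end, {name_a}, {name_b}
        domains.append(
            OverlapDomain(
                GenomicInterval(chrom, cur_start, cur_end),
                tuple(sorted(a)),
                tuple(sorted(b)),
            )
        )
    return domains
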