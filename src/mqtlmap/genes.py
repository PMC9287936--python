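"""Candidate-gene extraction, GO enrichment and expression-window classification.

Genes overlapping a meta-QTL's physical interval by at least one base pair
are its candidate genes.  Enrichment of a GO term in a candidate list is the
one-sided hypergeometric upper tail against the annotated genome, with a raw
P < 0.01 call (no multiple-testing correction by default, with an optional
Benjamini-Hochberg switch).  Grain expression profiles (FPKM over days after
pollination) are normalised per gene by their maximum and classified by
which developmental windows — before 10 DAP, 10-30 DAP, after 30 DAP — show
high normalised expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import hypergeom

from .core import GeneRecord, GenomicInterval

logger = logging.getLogger(__name__)

GO_P_THRESHOLD = 0.01
EXPRESSED_MIN_FPKM = 1.0
HIGH_WINDOW_MEAN = 0.5
DAP_RANGE = (0.0, 38.0)
DEFAULT_WINDOW_BOUNDARIES = (10.0, 30.0)


class GeneAnnotation:
    """An interval-indexed gene set, typically loaded from GFF3."""

    def __init__(self, genes: Iterable[GeneRecord]):
        self._by_chrom: dict[str, list[GeneRecord]] = {}
        self._trees: dict[str, IntervalTree] = {}
        for g in genes:
            chrom = g.interval.chromosome
            self._by_chrom.setdefault(chrom, []).append(g)
        for chrom, recs in self._by_chrom.items():
            recs.sort(key=lambda g: (g.interval.start, g.interval.end))
            tree = IntervalTree()
            for g in recs:
                tree.addi(g.interval.start, g.interval.end + 1, g)
            self._trees[chrom] = tree

    @classmethod
    def from_gff3(cls, path: str | Path, featuretype: str = "gene") -> "GeneAnnotation":
        import gffutils

        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
        genes = []
        for feat in db.features_of_type(featuretype):
            genes.append(
                GeneRecord(
                    gene_id=feat.id,
                    interval=GenomicInterval(feat.seqid, feat.start, feat.end),
                    strand=feat.strand if feat.strand in {"+", "-"} else ".",
                )
            )
        return cls(genes)

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._by_chrom)

    def all_gene_ids(self) -> list[str]:
        return [g.gene_id for c in sorted(self._by_chrom) for g in self._by_chrom[c]]

    def genes_on(self, chromosome: str) -> list[GeneRecord]:
        return list(self._by_chrom.get(chromosome, []))

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_chrom.values())


def genes_in_interval(
    annotation: GeneAnnotation, interval: GenomicInterval
) -> list[GeneRecord]:
    """Genes whose span overlaps the interval by >= 1 bp, in coordinate order."""
    tree = annotation._trees.get(interval.chromosome)
    if tree is None:
        logger.warning(
            "chromosome %r absent from annotation; no genes returned",
            interval.chromosome,
        )
        return []
    hits = [h.data for h in tree.overlap(interval.start, interval.end + 1)]
    hits.sort(key=lambda g: (g.interval.start, g.interval.end))
    return hits


def intersect_gene_lists(a: Sequence[str], b: Iterable[str]) -> list[str]:
    """Set intersection, preserving the order of ``a``."""
    b_set = set(b)
    seen: set[str] = set()
    out = []
    for g in a:
        if g in b_set and g not in seen:
            out.append(g)
            seen.add(g)
    return out


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    study_count: int
    study_size: int
    population_count: int
    population_size: int
    p_value: float
    enriched: bool


def go_enrichment(
    study: Sequence[str],
    population: Sequence[str],
    annotation: Mapping[str, set[str]],
    threshold: float = GO_P_THRESHOLD,
    fdr: bool = False,
) -> list[EnrichmentResult]:
    """Hypergeometric GO-term over-representation of ``study`` in ``population``.

    Per term, P = P(X >= study_count) for X ~ Hypergeom(population_size,
    population_count, study_size); a term is enriched when P < threshold
    (raw P by default; set ``fdr=True`` for Benjamini-Hochberg adjusted P).
    Genes missing from ``annotation`` count as term-free.
    """
    study_set = set(study)
    pop_set = set(population)
    if not study_set <= pop_set:
        raise ValueError("study gene list must be a subset of the population")
    n_pop = len(pop_set)
    n_study = len(study_set)
    term_pop: dict[str, int] = {}
    term_study: dict[str, int] = {}
    for gene in pop_set:
        for term in annotation.get(gene, ()):
            term_pop[term] = term_pop.get(term, 0) + 1
            if gene in study_set:
                term_study[term] = term_study.get(term, 0) + 1
    results = []
    for term in sorted(term_pop):
        k = term_study.get(term, 0)
        m = term_pop[term]
        # upper tail P(X >= k); sf(k-1) handles k = 0 -> P = 1 exactly
        p = float(hypergeom.sf(k - 1, n_pop, m, n_study))
        results.append((term, k, m, min(p, 1.0)))
    p_values = np.array([r[3] for r in results]) if results else np.array([])
    if fdr and len(p_values):
        order = np.argsort(p_values)
        ranked = p_values[order] * len(p_values) / (np.arange(len(p_values)) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        adjusted = np.empty_like(p_values)
        adjusted[order] = np.clip(ranked, 0, 1)
        p_values = adjusted
    out = []
    for (term, k, m, _), p in zip(results, p_values):
        out.append(
            EnrichmentResult(
                term_id=term,
                study_count=k,
                study_size=n_study,
                population_count=m,
                population_size=n_pop,
                p_value=float(p),
                enriched=bool(p < threshold),
            )
        )
    out.sort(key=lambda r: (r.p_value, r.term_id))
    return out


class ExpressionWindow(str, Enum):
    EARLY = "early"              # high before 10 DAP
    MID = "mid"                  # high between 10 and 30 DAP
    LATE = "late"                # high after 30 DAP
    EARLY_AND_LATE = "early_and_late"
    MID_OTHER = "mid_other"      # any other combination of high windows
    NOT_EXPRESSED = "not_expressed"


@dataclass
class ExpressionProfile:
    """A gene's FPKM time course over grain development (DAP)."""

    gene_id: str
    timepoints: np.ndarray
    values: np.ndarray
    normalized: np.ndarray = field(init=False)
    expressed: bool = field(init=False)

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.timepoints.shape != self.values.shape:
            raise ValueError("timepoints and values must align")
        if np.any(self.values < 0):
            raise ValueError(f"gene {self.gene_id!r}: negative FPKM")
        if np.any(
            (self.timepoints < DAP_RANGE[0]) | (self.timepoints > DAP_RANGE[1])
        ):
            logger.warning(
                "gene %s: timepoints outside %g-%g DAP", self.gene_id, *DAP_RANGE
            )
        peak = self.values.max() if self.values.size else 0.0
        self.expressed = bool(peak >= EXPRESSED_MIN_FPKM)
        if peak > 0:
            self.normalized = self.values / peak
        else:
            # all-zero profile: flagged not expressed, left unnormalised
            self.normalized = self.values.copy()


def classify_expression_window(
    profile: ExpressionProfile,
    boundaries: tuple[float, float] = DEFAULT_WINDOW_BOUNDARIES,
    high_mean: float = HIGH_WINDOW_MEAN,
    min_fpkm: float = EXPRESSED_MIN_FPKM,
) -> ExpressionWindow:
    """Classify a profile by which developmental windows show high expression.

    A window (before ``boundaries[0]``, between the boundaries inclusive,
    after ``boundaries[1]``) is "high" when the mean normalised value within
    it is >= ``high_mean``.  Profiles whose maximum FPKM is below
    ``min_fpkm`` are not expressed in grain.
    """
    if profile.values.max(initial=0.0) < min_fpkm:
        return ExpressionWindow.NOT_EXPRESSED
    t = profile.timepoints
    lo, hi = boundaries
    windows = {
        "early": t < lo,
        "mid": (t >= lo) & (t <= hi),
        "late": t > hi,
    }
    high = {
        name
        for name, mask in windows.items()
        if mask.any() and profile.normalized[mask].mean() >= high_mean
    }
    if high == {"early"}:
        return ExpressionWindow.EARLY
    if high == {"mid"}:
        return ExpressionWindow.MID
    if high == {"late"}:
        return ExpressionWindow.LATE
    if high == {"early", "late"}:
        return ExpressionWindow.EARLY_AND_LATE
    return ExpressionWindow.MID_OTHER


def profiles_from_matrix(fpkm: pd.DataFrame) -> list[ExpressionProfile]:
    """One profile per row of a gene x DAP FPKM matrix."""
    t = np.array([float(c) for c in fpkm.columns])
    return [
        ExpressionProfile(gene_id=str(g), timepoints=t, values=row.to_numpy(float))
        for g, row in fpkm.iterrows()
    ]
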