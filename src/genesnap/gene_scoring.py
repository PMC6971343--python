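"""Pilot-cycle gene prioritization.

Genes are ranked by a weighted composite of annotation richness and usage:

    totalScore = GO score + evidence score + page views / 10
                 + number of publications + 20·[human ortholog]
                 + 50·[ortholog has an OMIM record]

where the GO score gives one point per GO term (half a point for an
uninformative aspect-root term) and the evidence score awards 200/100/50
points for having at least one Biological Process / Molecular Function /
Cellular Component annotation respectively.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .config import GeneScoreWeights
from .corpus import Gene

__all__ = ["GeneScoreBreakdown", "go_score", "evidence_score", "total_score",
           "rank_genes", "score_table"]


@dataclass(frozen=True)
class GeneScoreBreakdown:
    """Per-component decomposition of one gene's priority score."""

    gene_id: str
    go_score: float
    evidence_score: float
    page_view_term: float
    publication_term: float
    ortholog_term: float
    omim_term: float

    @property
    def total(self) -> float:
        return (self.go_score + self.evidence_score + self.page_view_term
                + self.publication_term + self.ortholog_term + self.omim_term)


def go_score(gene: Gene, weights: GeneScoreWeights | None = None) -> float:
    """Sum over GO annotations: 1 point per term, 0.5 for an aspect root."""
    w = weights or GeneScoreWeights()
    return sum(
        w.root_term_points if a.is_root else w.term_points
        for a in gene.go_annotations
    )


def evidence_score(gene: Gene, weights: GeneScoreWeights | None = None) -> float:
    """200/100/50 points for having ≥1 BP / MF / CC annotation respectively.

    Any evidence class counts; the award is per aspect present, not per term.
    """
    w = weights or GeneScoreWeights()
    aspects = {a.aspect for a in gene.go_annotations}
    return (
        (w.bp_points if "BP" in aspects else 0.0)
        + (w.mf_points if "MF" in aspects else 0.0)
        + (w.cc_points if "CC" in aspects else 0.0)
    )


def total_score(gene: Gene, weights: GeneScoreWeights | None = None) -> GeneScoreBreakdown:
    """Full weighted totalScore with its per-component breakdown."""
    w = weights or GeneScoreWeights()
    return GeneScoreBreakdown(
        gene_id=gene.gene_id,
        go_score=go_score(gene, w),
        evidence_score=evidence_score(gene, w),
        page_view_term=gene.page_views / w.page_view_divisor,
        publication_term=float(gene.n_publications),
        ortholog_term=w.ortholog_weight if gene.has_human_ortholog else 0.0,
        omim_term=w.omim_weight if gene.ortholog_in_omim else 0.0,
    )


def rank_genes(
    genes: Iterable[Gene],
    top_n: int,
    weights: GeneScoreWeights | None = None,
) -> list[GeneScoreBreakdown]:
    """Top *top_n* genes by totalScore, descending; ties broken by gene_id."""
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    scored = [total_score(g, weights) for g in genes]
    scored.sort(key=lambda b: (-b.total, b.gene_id))
    return scored[:top_n]


def score_table(breakdowns: Sequence[GeneScoreBreakdown]) -> pd.DataFrame:
    """Tabulate breakdowns for TSV export (one row per gene, full breakdown)."""
    return pd.DataFrame(
        [
            {
                "gene_id": b.gene_id,
                "go_score": b.go_score,
                "evidence_score": b.evidence_score,
                "page_view_term": b.page_view_term,
                "publication_term": b.publication_term,
                "ortholog_term": b.ortholog_term,
                "omim_term": b.omim_term,
                "total": b.total,
            }
            for b in breakdowns
        ]
    )
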