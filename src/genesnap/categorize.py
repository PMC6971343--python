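"""Gene stratification by annotation evidence.

Later solicitation cycles replaced the pilot's single composite score with
explicit filters on the *kind* of annotation a gene carries:

* cycle 2 dropped unnamed genes lacking classical alleles with phenotypes;
* cycle 3 stratified all protein-coding genes on three axes — GO status
  (experimental / non-experimental / none), presence of alleles with
  phenotype data, and orthology to humans or other non-arthropod metazoa —
  and declared a gene to merit a snapshot when it has experimental GO data
  AND alleles with phenotypes (the top two of the twelve strata).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .corpus import Gene

__all__ = ["GeneCategory", "CATEGORY_ORDER", "go_status", "categorize",
           "merits_snapshot", "cycle2_eligible", "stratify"]

GO_STATUSES = ("exp", "non_exp", "none")


@dataclass(frozen=True, order=True)
class GeneCategory:
    """One of the 12 strata: GO status × phenotype alleles × orthology."""

    go_status: str  # exp | non_exp | none
    has_pheno_alleles: bool
    has_ortholog: bool

    def __post_init__(self) -> None:
        if self.go_status not in GO_STATUSES:
            raise ValueError(f"go_status must be one of {GO_STATUSES}")


# Presentation order: strongest evidence first, within a GO status
# alleles-yes before alleles-no, ortholog-yes before ortholog-no.
CATEGORY_ORDER: tuple[GeneCategory, ...] = tuple(
    GeneCategory(s, p, o)
    for s in GO_STATUSES
    for p in (True, False)
    for o in (True, False)
)


def go_status(gene: Gene) -> str:
    """``exp`` if any experimental GO annotation, else ``non_exp`` if any
    annotation at all, else ``none``."""
    if any(a.evidence_class == "experimental" for a in gene.go_annotations):
        return "exp"
    if gene.go_annotations:
        return "non_exp"
    return "none"


def categorize(gene: Gene) -> GeneCategory:
    """Place a gene in exactly one of the 12 strata.

    The allele axis asks for alleles *with phenotype data*, not any allele;
    the orthology axis is satisfied by a human ortholog or any other
    non-arthropod metazoan ortholog.
    """
    return GeneCategory(
        go_status=go_status(gene),
        has_pheno_alleles=any(a.has_phenotype for a in gene.alleles),
        has_ortholog=gene.has_human_ortholog or gene.has_nonarthropod_metazoan_ortholog,
    )


def merits_snapshot(gene: Gene) -> bool:
    """Well-characterized enough for a summary: experimental GO data AND
    alleles with phenotypes (orthology does not enter the rule)."""
    cat = categorize(gene)
    return cat.go_status == "exp" and cat.has_pheno_alleles


def cycle2_eligible(gene: Gene) -> bool:
    """Cycle-2 filter: exclude unnamed genes that have no classical allele
    with phenotypic effects; every named gene stays eligible."""
    if gene.is_named:
        return True
    return any(a.is_classical and a.has_phenotype for a in gene.alleles)


def stratify(genes: Iterable[Gene]) -> pd.DataFrame:
    """Count genes per stratum; always returns all 12 rows in display order.

    Columns: go_status, has_pheno_alleles, has_ortholog, n_genes,
    merits_snapshot.  Row counts sum to the number of genes supplied.
    """
    counts = {cat: 0 for cat in CATEGORY_ORDER}
    for gene in genes:
        counts[categorize(gene)] += 1
    return pd.DataFrame(
        [
            {
                "go_status": cat.go_status,
                "has_pheno_alleles": cat.has_pheno_alleles,
                "has_ortholog": cat.has_ortholog,
                "n_genes": counts[cat],
                "merits_snapshot": cat.go_status == "exp" and cat.has_pheno_alleles,
            }
            for cat in CATEGORY_ORDER
        ]
    )
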