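"""Expert-author ranking and gene assignment.

For every (author, gene) pair the module counts seven features over the
author's publications linked to the gene — recency, reagent generation,
non-high-throughput papers, classical-allele phenotypes, experimental GO
annotation, expression/antibody data and gene-source papers — and combines
them into a single expert score:

    score = (recent/10 + reagent/5)
            × (papers<500genes/5 + 3·classical + 10·expGO + 10·expr+AB + 10·source)

The first factor favors authors still active on the gene or who built
genetic tools for it; the second weighs how gene-specific and functional
their publications are.  Authors who were never last author on a paper
about the gene are excluded, as are manually listed authors (retired,
deceased, ...).  Zero-score authors are dropped: they carry no solicitable
expertise.  Scores are displayed rounded to the nearest integer (half away
from zero); ranking uses the raw value.

``assign_genes`` turns per-gene rankings into a gene→author assignment,
optionally enforcing a load cap: an author asked for more than *cap* genes
keeps their *cap* highest-scoring ones and the rest move to the next-ranked
author.  This replaces ad hoc manual reassignment with a deterministic rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .config import ExpertScoreWeights
from .corpus import Corpus, ReferentialError

__all__ = ["AuthorGeneFeatures", "ExpertScore", "Assignment", "compute_features",
           "expert_score", "rank_authors", "assign_genes", "escalate",
           "NO_EXPERT_REMAINING"]

NO_EXPERT_REMAINING = "no-expert-remaining"


@dataclass(frozen=True)
class AuthorGeneFeatures:
    """The seven per-(author, gene) publication counts plus seniority flag."""

    ten_year_recent: int = 0
    mutagen_or_nature_of_lesion: int = 0
    gene_counts_500_limit: int = 0
    classical_alleles_with_pheno: int = 0
    exp_go: int = 0
    expression_plus_antibody: int = 0
    gene_source: int = 0
    ever_last_author: bool = False

    def __post_init__(self) -> None:
        for name in ("ten_year_recent", "mutagen_or_nature_of_lesion",
                     "gene_counts_500_limit", "classical_alleles_with_pheno",
                     "exp_go", "expression_plus_antibody", "gene_source"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class ExpertScore:
    raw: float
    display: int  # raw rounded to the nearest integer, half away from zero


@dataclass
class Assignment:
    """The escalation ladder of one gene: its ranked experts and which rank
    is currently being asked."""

    gene_id: str
    ranked_authors: list[tuple[str, ExpertScore]]
    current_index: int = 0
    status: str = "assigned"  # assigned | unassignable | no-expert-remaining
    history: list[str] = field(default_factory=list)

    @property
    def current_author(self) -> Optional[str]:
        if self.status == "unassignable" or self.current_index >= len(self.ranked_authors):
            return None
        return self.ranked_authors[self.current_index][0]

    @property
    def current_score(self) -> Optional[ExpertScore]:
        if self.current_author is None:
            return None
        return self.ranked_authors[self.current_index][1]


def compute_features(
    author_id: str,
    gene_id: str,
    corpus: Corpus,
    reference_year: int,
    weights: ExpertScoreWeights | None = None,
) -> AuthorGeneFeatures:
    """Count the seven features over the author's publications on the gene.

    Counts run over all authorship positions; the last-author condition is
    only the separate eligibility flag.  Recency means publication year
    strictly within the last ``recent_window_years`` (default 10) before
    *reference_year*; the high-throughput cutoff drops papers linked to
    ``high_throughput_gene_count`` (default 500) or more genes.
    """
    w = weights or ExpertScoreWeights()
    if author_id not in corpus.authors:
        raise ReferentialError(f"unknown author {author_id!r}")
    pubs = [p for p in corpus.publications_for_gene(gene_id)
            if author_id in p.author_ids]
    recent_floor = reference_year - w.recent_window_years
    counts = dict(ten_year_recent=0, mutagen_or_nature_of_lesion=0,
                  gene_counts_500_limit=0, classical_alleles_with_pheno=0,
                  exp_go=0, expression_plus_antibody=0, gene_source=0)
    ever_last = False
    for pub in pubs:
        flags = pub.per_gene_flags[gene_id]
        if pub.year > recent_floor:
            counts["ten_year_recent"] += 1
        if flags.mutagen_or_nature_of_lesion:
            counts["mutagen_or_nature_of_lesion"] += 1
        if pub.n_linked_genes < w.high_throughput_gene_count:
            counts["gene_counts_500_limit"] += 1
        if flags.classical_allele_with_pheno:
            counts["classical_alleles_with_pheno"] += 1
        if flags.exp_go_bp_mf:
            counts["exp_go"] += 1
        if flags.expression_or_antibody:
            counts["expression_plus_antibody"] += 1
        if flags.gene_source:
            counts["gene_source"] += 1
        if pub.last_author == author_id:
            ever_last = True
    return AuthorGeneFeatures(ever_last_author=ever_last, **counts)


def expert_score(
    features: AuthorGeneFeatures,
    weights: ExpertScoreWeights | None = None,
) -> ExpertScore:
    """Combine the feature counts into the multiplicative expert score.

    Either factor being zero zeroes the score; because the first factor is a
    *sum*, an author with no recent papers can still score if they described
    genetic reagents (and vice versa).
    """
    w = weights or ExpertScoreWeights()
    activity = (features.ten_year_recent / w.recent_divisor
                + features.mutagen_or_nature_of_lesion / w.mutagen_divisor)
    specificity = (features.gene_counts_500_limit / w.g500_divisor
                   + w.classical_weight * features.classical_alleles_with_pheno
                   + w.expgo_weight * features.exp_go
                   + w.expab_weight * features.expression_plus_antibody
                   + w.source_weight * features.gene_source)
    raw = activity * specificity
    return ExpertScore(raw=raw, display=int(math.floor(raw + 0.5)))


def rank_authors(
    gene_id: str,
    corpus: Corpus,
    exclusions: Iterable[str] = (),
    reference_year: int = 2016,
    weights: ExpertScoreWeights | None = None,
) -> list[tuple[str, ExpertScore]]:
    """Ranked (author, score) list for one gene.

    Keeps only authors who were last author on ≥1 linked publication, are
    not excluded (in *exclusions* or flagged in the corpus), and have a
    strictly positive raw score.  Sorted by raw score descending, author_id
    ascending on ties.
    """
    excluded = set(exclusions)
    ranked: list[tuple[str, ExpertScore]] = []
    for author_id in corpus.authors_for_gene(gene_id):
        if author_id in excluded or corpus.authors[author_id].excluded:
            continue
        feats = compute_features(author_id, gene_id, corpus, reference_year, weights)
        if not feats.ever_last_author:
            continue
        score = expert_score(feats, weights)
        if score.raw > 0:
            ranked.append((author_id, score))
    ranked.sort(key=lambda pair: (-pair[1].raw, pair[0]))
    return ranked


def assign_genes(
    gene_ids: Sequence[str],
    corpus: Corpus,
    exclusions: Iterable[str] = (),
    reference_year: int = 2016,
    load_cap: Optional[int] = None,
    weights: ExpertScoreWeights | None = None,
) -> dict[str, Assignment]:
    """Assign each gene to its top-ranked expert, then enforce the load cap.

    With a cap *k*, any author currently asked for more than *k* genes keeps
    their *k* highest raw-scoring genes (ties broken by gene_id ascending)
    and the remainder escalate to their next-ranked author; this repeats
    until no author is over cap.  Genes whose ranking is empty (or becomes
    exhausted) are marked ``unassignable`` / ``no-expert-remaining``.
    """
    if load_cap is not None and load_cap < 1:
        raise ValueError("load_cap must be >= 1")
    exclusions = list(exclusions)
    assignments: dict[str, Assignment] = {}
    for gid in gene_ids:
        ranked = rank_authors(gid, corpus, exclusions, reference_year, weights)
        assignments[gid] = Assignment(
            gene_id=gid, ranked_authors=ranked,
            status="assigned" if ranked else "unassignable",
        )
    if load_cap is None:
        return assignments

    while True:
        load: dict[str, list[Assignment]] = {}
        for a in assignments.values():
            if a.current_author is not None:
                load.setdefault(a.current_author, []).append(a)
        over = sorted(aid for aid, held in load.items() if len(held) > load_cap)
        if not over:
            break
        for author_id in over:
            held = sorted(load[author_id],
                          key=lambda a: (-a.current_score.raw, a.gene_id))
            for a in held[load_cap:]:
                escalate(a, reason=f"load cap {load_cap} at {author_id}")
    return assignments


def save_assignments(assignments: Mapping[str, Assignment], path) -> None:
    """Persist assignments (incl. full ranked lists) as TSV."""
    import pandas as pd

    rows = []
    for gid in sorted(assignments):
        a = assignments[gid]
        rows.append({
            "gene_id": gid,
            "current_index": a.current_index,
            "status": a.status,
            "current_author": a.current_author or "",
            "ranked_authors": ";".join(
                f"{aid}:{s.raw!r}:{s.display}" for aid, s in a.ranked_authors
            ),
        })
    pd.DataFrame(rows, columns=["gene_id", "current_index", "status",
                                "current_author", "ranked_authors"]).to_csv(
        path, sep="\t", index=False, lineterminator="\n")


def load_assignments(path) -> dict[str, Assignment]:
    """Inverse of :func:`save_assignments`."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out: dict[str, Assignment] = {}
    for row in df.itertuples(index=False):
        ranked = []
        for item in row.ranked_authors.split(";"):
            if not item:
                continue
            aid, raw, display = item.rsplit(":", 2)
            ranked.append((aid, ExpertScore(raw=float(raw), display=int(display))))
        out[row.gene_id] = Assignment(
            gene_id=row.gene_id, ranked_authors=ranked,
            current_index=int(row.current_index), status=row.status,
        )
    return out


def escalate(assignment: Assignment, reason: str = "") -> Assignment:
    """Advance to the next-ranked author, recording the one passed over."""
    prior = assignment.current_author
    if prior is None:
        raise ValueError(f"{assignment.gene_id}: no author currently assigned")
    note = f"escalated past {prior}" + (f" ({reason})" if reason else "")
    assignment.history.append(note)
    assignment.current_index += 1
    if assignment.current_index >= len(assignment.ranked_authors):
        assignment.status = NO_EXPERT_REMAINING
    return assignment
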