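import datetime as dt
from pathlib import Path

import pytest

from genesnap.corpus import (Allele, Author, Corpus, Gene, GOAnnotation,
                             PubGeneFlags, Publication)

FIXTURE_DIR = Path(__file__).parent / "data" / "corpus3"

# Worked ranking example: feature counts and printed display scores for ten
# authors of one well-characterized gene.  Column order: papers-under-500-
# gene-limit, 10-year-recent, classical-alleles-with-pheno, expGO,
# expression+antibody, mutagen-or-nature-of-lesion, gene-source → score.
RANKING_EXAMPLE = [
    (24, 8, 12, 1, 0, 5, 0, 91),
    (9, 5, 7, 3, 0, 5, 0, 79),
    (12, 4, 7, 3, 0, 5, 0, 75),
    (28, 6, 9, 0, 0, 7, 0, 65),
    (14, 0, 10, 1, 0, 7, 0, 60),
    (17, 2, 6, 2, 0, 5, 0, 50),
    (15, 5, 7, 3, 0, 1, 0, 38),
    (28, 10, 4, 0, 0, 4, 0, 32),
    (12, 7, 3, 1, 0, 3, 0, 28),
    (14, 1, 2, 0, 3, 3, 0, 27),
]


@pytest.fixture
def fixture_corpus_dir() -> Path:
    return FIXTURE_DIR


def make_gene(gene_id="gX", n_exp=0, n_nonexp=0, n_root=0, aspects=("BP",),
              pheno_alleles=0, plain_alleles=0, classical=True,
              human_ortholog=False, omim=False, metazoan_ortholog=False,
              page_views=0, n_publications=0, is_named=True) -> Gene:
    """Construct a gene with the requested annotation profile."""
    annotations = []
    for i in range(n_exp):
        annotations.append(GOAnnotation(f"GO:{i:07d}", aspects[i % len(aspects)],
                                        False, "experimental"))
    for i in range(n_nonexp):
        annotations.append(GOAnnotation(f"GO:1{i:06d}", aspects[i % len(aspects)],
                                        False, "non_experimental"))
    for i in range(n_root):
        annotations.append(GOAnnotation(f"GO:2{i:06d}", aspects[i % len(aspects)],
                                        True, "non_experimental"))
    alleles = []
    for i in range(pheno_alleles):
        alleles.append(Allele(f"{gene_id}[{i}]", classical, True, ""))
    for i in range(plain_alleles):
        alleles.append(Allele(f"{gene_id}[p{i}]", classical, False, ""))
    return Gene(
        gene_id=gene_id, symbol=gene_id, name=gene_id, is_named=is_named,
        page_views=page_views, n_publications=n_publications,
        go_annotations=annotations, alleles=alleles,
        has_human_ortholog=human_ortholog, ortholog_in_omim=omim,
        has_nonarthropod_metazoan_ortholog=metazoan_ortholog,
    )


def ranking_example_corpus(reference_year: int = 2016) -> tuple[Corpus, str]:
    """A single-gene corpus whose per-author feature counts reproduce the
    ten-author worked ranking example; returns (corpus, gene_id).

    For each author we mint the exact number of publications needed: the
    first `g500` papers are small (linked to <500 genes) and any surplus
    recent papers are modelled as high-throughput ones so every count lands
    exactly.  Each author signs last on all of their papers.
    """
    gene_id = "gene1"
    authors = {}
    pubs = {}
    gene = make_gene(gene_id, n_exp=2, pheno_alleles=2)
    counter = 0
    for idx, (g500, recent, clas, expgo, expab, mut, src, _) in enumerate(RANKING_EXAMPLE):
        aid = f"auth{idx + 1:02d}"
        authors[aid] = Author(aid, f"Surname{idx + 1}")
        n_papers = max(g500, recent)
        for j in range(n_papers):
            pid = f"p{counter:04d}"
            counter += 1
            year = reference_year - 2 if j < recent else reference_year - 12
            flags = PubGeneFlags(
                mutagen_or_nature_of_lesion=j < mut,
                classical_allele_with_pheno=j < clas,
                exp_go_bp_mf=j < expgo,
                expression_or_antibody=j < expab,
                gene_source=j < src,
            )
            pubs[pid] = Publication(
                pub_id=pid, year=year, author_ids=[aid],
                n_linked_genes=10 if j < g500 else 600,
                per_gene_flags={gene_id: flags},
            )
    return Corpus(genes={gene_id: gene}, publications=pubs, authors=authors), gene_id


@pytest.fixture
def table_example_corpus() -> tuple[Corpus, str]:
    return ranking_example_corpus()


@pytest.fixture
def request_factory():
    def factory(n: int, deadline_days: int = 7, sent=dt.date(2016, 5, 1)):
        from genesnap.campaign import SolicitationRequest

        return [
            SolicitationRequest(
                gene_id=f"g{i:04d}", author_id=f"a{i:04d}",
                batch_kind="individual" if deadline_days == 7 else "spreadsheet",
                sent_date=sent, deadline_days=deadline_days,
            )
            for i in range(n)
        ]

    return factory
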