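"""Data model for a curation-database extract, plus TSV readers/writers.

The corpus is the in-memory image of a tabular extract from a genetic
database such as FlyBase: genes with their Gene Ontology (GO) annotations,
alleles, orthology calls and usage statistics; publications with ordered
author lists and per-gene curated data-type flags; and the authors
themselves.  All cross-references are checked on construction so that
downstream scoring and ranking code can assume referential integrity.

Interchange format
------------------
Six UTF-8 TSV tables with fixed headers (booleans serialized as ``0``/``1``,
missing optional strings as empty fields):

=====================  ==========================================================
file                   columns
=====================  ==========================================================
genes.tsv              gene_id, symbol, name, is_named, is_protein_coding,
                       page_views, n_publications, has_human_ortholog,
                       ortholog_in_omim, has_nonarthropod_metazoan_ortholog,
                       gene_group_summary, interactive_fly_summary
go_annotations.tsv     gene_id, term_id, aspect, is_root, evidence_class
alleles.tsv            gene_id, allele_id, is_classical, has_phenotype, source_pub
publications.tsv       pub_id, year, n_linked_genes, author_ids  (";"-joined,
                       order preserved; the last element is the last author)
pub_gene_flags.tsv     pub_id, gene_id, mutagen_or_nature_of_lesion,
                       classical_allele_with_pheno, exp_go_bp_mf,
                       expression_or_antibody, gene_source
authors.tsv            author_id, surname, known_email, excluded, exclusion_reason
=====================  ==========================================================

Snapshot flat file
------------------
Submitted gene summaries are persisted in a proforma-like line-oriented
format: one record per gene with ``KEY: value`` lines, the free text after
a ``TEXT:`` line, records separated by a line containing only ``//``.
Text lines that would collide with the record grammar (lines starting with
``//`` or ``\\``) are escaped with a leading backslash on write and
unescaped on read, so round-trips are exact.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "GOAnnotation",
    "Allele",
    "Gene",
    "PubGeneFlags",
    "Publication",
    "Author",
    "Snapshot",
    "Corpus",
    "SchemaError",
    "ReferentialError",
    "read_corpus",
    "write_corpus",
    "read_snapshots",
    "write_snapshots",
    "looks_like_annotation_symbol",
]

GO_ASPECTS = ("BP", "MF", "CC")
EVIDENCE_CLASSES = ("experimental", "non_experimental")


class SchemaError(ValueError):
    """A table is missing a required column or carries an invalid value."""


class ReferentialError(ValueError):
    """An identifier referenced somewhere does not resolve."""


@dataclass(frozen=True)
class GOAnnotation:
    term_id: str
    aspect: str  # one of BP / MF / CC
    is_root: bool = False
    evidence_class: str = "non_experimental"

    def __post_init__(self) -> None:
        if self.aspect not in GO_ASPECTS:
            raise SchemaError(f"GO aspect must be one of {GO_ASPECTS}, got {self.aspect!r}")
        if self.evidence_class not in EVIDENCE_CLASSES:
            raise SchemaError(
                f"evidence_class must be one of {EVIDENCE_CLASSES}, got {self.evidence_class!r}"
            )


@dataclass(frozen=True)
class Allele:
    allele_id: str
    is_classical: bool = False
    has_phenotype: bool = False
    source_pub: str = ""

    def __post_init__(self) -> None:
        if not self.allele_id:
            raise SchemaError("allele_id must be non-empty")


@dataclass
class Gene:
    """One gene with the annotation summary the pipeline scores and filters on."""

    gene_id: str
    symbol: str = ""
    name: str = ""
    is_named: bool = True
    is_protein_coding: bool = True
    page_views: int = 0
    n_publications: int = 0
    go_annotations: list[GOAnnotation] = field(default_factory=list)
    alleles: list[Allele] = field(default_factory=list)
    has_human_ortholog: bool = False
    ortholog_in_omim: bool = False
    has_nonarthropod_metazoan_ortholog: bool = False
    gene_group_summary: Optional[str] = None
    interactive_fly_summary: Optional[str] = None

    def __post_init__(self) -> None:
        if self.page_views < 0 or self.n_publications < 0:
            raise SchemaError(f"{self.gene_id}: page_views/n_publications must be >= 0")
        if self.ortholog_in_omim and not self.has_human_ortholog:
            raise SchemaError(
                f"{self.gene_id}: an OMIM record implies a human ortholog"
            )


@dataclass(frozen=True)
class PubGeneFlags:
    """Curated data-type flags for one (publication, gene) pair."""

    mutagen_or_nature_of_lesion: bool = False
    classical_allele_with_pheno: bool = False
    exp_go_bp_mf: bool = False
    expression_or_antibody: bool = False
    gene_source: bool = False


@dataclass
class Publication:
    pub_id: str
    year: int
    author_ids: list[str]  # ordered; last element = last author
    n_linked_genes: int = 1
    per_gene_flags: dict[str, PubGeneFlags] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.author_ids:
            raise SchemaError(f"{self.pub_id}: author list must be non-empty")
        if self.year <= 1900:
            raise SchemaError(f"{self.pub_id}: implausible year {self.year}")
        if self.n_linked_genes < 1:
            raise SchemaError(f"{self.pub_id}: n_linked_genes must be positive")

    @property
    def last_author(self) -> str:
        return self.author_ids[-1]


@dataclass
class Author:
    author_id: str
    surname: str
    known_email: Optional[str] = None
    excluded: bool = False
    exclusion_reason: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.surname:
            raise SchemaError(f"{self.author_id}: surname must be non-empty")
        if self.excluded and not self.exclusion_reason:
            raise SchemaError(f"{self.author_id}: excluded authors need an exclusion_reason")


@dataclass(frozen=True)
class Snapshot:
    """A submitted gene summary with contributor and date stamp."""

    gene_id: str
    text: str
    contributor: str
    date_stamp: str  # ISO-8601

    def __post_init__(self) -> None:
        if not self.text:
            raise SchemaError(f"{self.gene_id}: snapshot text must be non-empty")
        _dt.date.fromisoformat(self.date_stamp)  # raises ValueError if unparseable


@dataclass
class Corpus:
    """All genes, publications and authors of one extract, cross-linked."""

    genes: dict[str, Gene] = field(default_factory=dict)
    publications: dict[str, Publication] = field(default_factory=dict)
    authors: dict[str, Author] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._gene_pubs: dict[str, list[str]] = {}
        self.validate()

    # -- integrity ---------------------------------------------------------

    def validate(self) -> None:
        """Check every cross-reference; raise ReferentialError on a dangling id."""
        gene_pubs: dict[str, list[str]] = {g: [] for g in self.genes}
        for pub in self.publications.values():
            for aid in pub.author_ids:
                if aid not in self.authors:
                    raise ReferentialError(
                        f"publication {pub.pub_id} references unknown author {aid!r}"
                    )
            for gid in pub.per_gene_flags:
                if gid not in self.genes:
                    raise ReferentialError(
                        f"publication {pub.pub_id} references unknown gene {gid!r}"
                    )
                gene_pubs[gid].append(pub.pub_id)
        for gene in self.genes.values():
            for allele in gene.alleles:
                if allele.source_pub and allele.source_pub not in self.publications:
                    raise ReferentialError(
                        f"allele {allele.allele_id} of {gene.gene_id} references "
                        f"unknown publication {allele.source_pub!r}"
                    )
        if self.publications:
            for gid, pubs in gene_pubs.items():
                self.genes[gid].n_publications = len(pubs)
        self._gene_pubs = gene_pubs

    # -- lookups -----------------------------------------------------------

    def publications_for_gene(self, gene_id: str) -> list[Publication]:
        if gene_id not in self.genes:
            raise ReferentialError(f"unknown gene {gene_id!r}")
        return [self.publications[pid] for pid in self._gene_pubs.get(gene_id, [])]

    def authors_for_gene(self, gene_id: str) -> list[str]:
        """All authors appearing on at least one publication linked to the gene."""
        seen: dict[str, None] = {}
        for pub in self.publications_for_gene(gene_id):
            for aid in pub.author_ids:
                seen.setdefault(aid)
        return list(seen)


# ---------------------------------------------------------------------------
# TSV interchange
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = {
    "genes": [
        "gene_id", "symbol", "name", "is_named", "is_protein_coding",
        "page_views", "n_publications", "has_human_ortholog", "ortholog_in_omim",
        "has_nonarthropod_metazoan_ortholog", "gene_group_summary",
        "interactive_fly_summary",
    ],
    "go_annotations": ["gene_id", "term_id", "aspect", "is_root", "evidence_class"],
    "alleles": ["gene_id", "allele_id", "is_classical", "has_phenotype", "source_pub"],
    "publications": ["pub_id", "year", "n_linked_genes", "author_ids"],
    "pub_gene_flags": [
        "pub_id", "gene_id", "mutagen_or_nature_of_lesion",
        "classical_allele_with_pheno", "exp_go_bp_mf", "expression_or_antibody",
        "gene_source",
    ],
    "authors": ["author_id", "surname", "known_email", "excluded", "exclusion_reason"],
}

_BOOL_COLUMNS = {
    "is_named", "is_protein_coding", "has_human_ortholog", "ortholog_in_omim",
    "has_nonarthropod_metazoan_ortholog", "is_root", "is_classical",
    "has_phenotype", "excluded", "mutagen_or_nature_of_lesion",
    "classical_allele_with_pheno", "exp_go_bp_mf", "expression_or_antibody",
    "gene_source",
}


def _read_table(path: Path, table: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _TABLE_COLUMNS[table] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing column(s) {', '.join(missing)}")
    for col in df.columns:
        if col in _BOOL_COLUMNS:
            df[col] = df[col].map({"0": False, "1": True})
            if df[col].isna().any():
                raise SchemaError(f"{path.name}: column {col} must contain only 0/1")
    return df


def _opt(value: str) -> Optional[str]:
    return value if value else None


def read_corpus(directory: str | Path) -> Corpus:
    """Load the six interchange tables from *directory* into a checked Corpus."""
    d = Path(directory)
    genes_df = _read_table(d / "genes.tsv", "genes")
    go_df = _read_table(d / "go_annotations.tsv", "go_annotations")
    alleles_df = _read_table(d / "alleles.tsv", "alleles")
    pubs_df = _read_table(d / "publications.tsv", "publications")
    flags_df = _read_table(d / "pub_gene_flags.tsv", "pub_gene_flags")
    authors_df = _read_table(d / "authors.tsv", "authors")

    go_by_gene: dict[str, list[GOAnnotation]] = {}
    for row in go_df.itertuples(index=False):
        go_by_gene.setdefault(row.gene_id, []).append(
            GOAnnotation(row.term_id, row.aspect, row.is_root, row.evidence_class)
        )
    alleles_by_gene: dict[str, list[Allele]] = {}
    for row in alleles_df.itertuples(index=False):
        alleles_by_gene.setdefault(row.gene_id, []).append(
            Allele(row.allele_id, row.is_classical, row.has_phenotype, row.source_pub)
        )

    genes: dict[str, Gene] = {}
    for row in genes_df.itertuples(index=False):
        genes[row.gene_id] = Gene(
            gene_id=row.gene_id,
            symbol=row.symbol,
            name=row.name,
            is_named=row.is_named,
            is_protein_coding=row.is_protein_coding,
            page_views=int(row.page_views),
            n_publications=int(row.n_publications) if row.n_publications else 0,
            go_annotations=go_by_gene.get(row.gene_id, []),
            alleles=alleles_by_gene.get(row.gene_id, []),
            has_human_ortholog=row.has_human_ortholog,
            ortholog_in_omim=row.ortholog_in_omim,
            has_nonarthropod_metazoan_ortholog=row.has_nonarthropod_metazoan_ortholog,
            gene_group_summary=_opt(row.gene_group_summary),
            interactive_fly_summary=_opt(row.interactive_fly_summary),
        )
    for gid in go_by_gene.keys() | alleles_by_gene.keys():
        if gid not in genes:
            raise ReferentialError(f"annotation table references unknown gene {gid!r}")

    flags_by_pub: dict[str, dict[str, PubGeneFlags]] = {}
    for row in flags_df.itertuples(index=False):
        flags_by_pub.setdefault(row.pub_id, {})[row.gene_id] = PubGeneFlags(
            row.mutagen_or_nature_of_lesion, row.classical_allele_with_pheno,
            row.exp_go_bp_mf, row.expression_or_antibody, row.gene_source,
        )
    publications: dict[str, Publication] = {}
    for row in pubs_df.itertuples(index=False):
        publications[row.pub_id] = Publication(
            pub_id=row.pub_id,
            year=int(row.year),
            author_ids=row.author_ids.split(";"),
            n_linked_genes=int(row.n_linked_genes),
            per_gene_flags=flags_by_pub.get(row.pub_id, {}),
        )
    for pid in flags_by_pub:
        if pid not in publications:
            raise ReferentialError(f"flag table references unknown publication {pid!r}")

    authors: dict[str, Author] = {}
    for row in authors_df.itertuples(index=False):
        authors[row.author_id] = Author(
            author_id=row.author_id,
            surname=row.surname,
            known_email=_opt(row.known_email),
            excluded=row.excluded,
            exclusion_reason=_opt(row.exclusion_reason),
        )

    return Corpus(genes=genes, publications=publications, authors=authors)


def _b(value: bool) -> str:
    return "1" if value else "0"


def write_corpus(corpus: Corpus, directory: str | Path) -> None:
    """Write *corpus* as the six interchange tables (deterministic row order)."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)

    gene_rows, go_rows, allele_rows = [], [], []
    for gid in sorted(corpus.genes):
        g = corpus.genes[gid]
        gene_rows.append([
            g.gene_id, g.symbol, g.name, _b(g.is_named), _b(g.is_protein_coding),
            str(g.page_views), str(g.n_publications), _b(g.has_human_ortholog),
            _b(g.ortholog_in_omim), _b(g.has_nonarthropod_metazoan_ortholog),
            g.gene_group_summary or "", g.interactive_fly_summary or "",
        ])
        for a in g.go_annotations:
            go_rows.append([gid, a.term_id, a.aspect, _b(a.is_root), a.evidence_class])
        for al in g.alleles:
            allele_rows.append(
                [gid, al.allele_id, _b(al.is_classical), _b(al.has_phenotype), al.source_pub]
            )

    pub_rows, flag_rows = [], []
    for pid in sorted(corpus.publications):
        p = corpus.publications[pid]
        pub_rows.append([pid, str(p.year), str(p.n_linked_genes), ";".join(p.author_ids)])
        for gid in sorted(p.per_gene_flags):
            f = p.per_gene_flags[gid]
            flag_rows.append([
                pid, gid, _b(f.mutagen_or_nature_of_lesion),
                _b(f.classical_allele_with_pheno), _b(f.exp_go_bp_mf),
                _b(f.expression_or_antibody), _b(f.gene_source),
            ])

    author_rows = []
    for aid in sorted(corpus.authors):
        a = corpus.authors[aid]
        author_rows.append(
            [aid, a.surname, a.known_email or "", _b(a.excluded), a.exclusion_reason or ""]
        )

    tables = {
        "genes": gene_rows, "go_annotations": go_rows, "alleles": allele_rows,
        "publications": pub_rows, "pub_gene_flags": flag_rows, "authors": author_rows,
    }
    for name, rows in tables.items():
        df = pd.DataFrame(rows, columns=_TABLE_COLUMNS[name])
        df.to_csv(d / f"{name}.tsv", sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Snapshot flat file
# ---------------------------------------------------------------------------

_SNAPSHOT_HEADER = "# genesnap snapshot records v1"
_RECORD_SEP = "//"
_REVIEW_TEXT = "reviewed, insufficient information"
_REVIEW_CONTRIBUTOR = "curator-review"


def _escape_text_line(line: str) -> str:
    if line.startswith(_RECORD_SEP) or line.startswith("\\"):
        return "\\" + line
    return line


def _unescape_text_line(line: str) -> str:
    return line[1:] if line.startswith("\\") else line


def write_snapshots(
    snapshots: Sequence[Snapshot],
    path: str | Path,
    reviewed_insufficient: Iterable[tuple[str, str]] = (),
) -> None:
    """Write snapshots to the flat record file at *path*.

    *reviewed_insufficient* is an optional iterable of ``(gene_id, iso_date)``
    pairs for genes that were reviewed but hold too little information for a
    summary; they are written as date-stamped placeholder records.
    """
    lines = [_SNAPSHOT_HEADER]
    records = list(snapshots) + [
        Snapshot(gid, _REVIEW_TEXT, _REVIEW_CONTRIBUTOR, date)
        for gid, date in reviewed_insufficient
    ]
    for snap in records:
        lines.append(f"GENE: {snap.gene_id}")
        lines.append(f"CONTRIBUTOR: {snap.contributor}")
        lines.append(f"DATE: {snap.date_stamp}")
        lines.append("TEXT:")
        lines.extend(_escape_text_line(l) for l in snap.text.split("\n"))
        lines.append(_RECORD_SEP)
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_snapshots(path: str | Path) -> list[Snapshot]:
    """Read back a snapshot flat file; inverse of :func:`write_snapshots`."""
    raw = Path(path).read_text(encoding="utf-8").split("\n")
    if not raw or raw[0] != _SNAPSHOT_HEADER:
        raise SchemaError(f"{path}: missing snapshot header line")
    out: list[Snapshot] = []
    fields: dict[str, str] = {}
    text_lines: Optional[list[str]] = None
    for line in raw[1:]:
        if text_lines is None:
            if not line.strip():
                continue
            if line == "TEXT:":
                text_lines = []
            elif ": " in line or line.endswith(":"):
                key, _, value = line.partition(": ")
                fields[key] = value
            else:
                raise SchemaError(f"{path}: unexpected line {line!r}")
        elif line == _RECORD_SEP:
            out.append(Snapshot(
                gene_id=fields["GENE"],
                text="\n".join(_unescape_text_line(l) for l in text_lines),
                contributor=fields.get("CONTRIBUTOR", ""),
                date_stamp=fields["DATE"],
            ))
            fields, text_lines = {}, None
        else:
            text_lines.append(line)
    if text_lines is not None:
        raise SchemaError(f"{path}: unterminated record (missing '//')")
    return out


def looks_like_annotation_symbol(symbol: str) -> bool:
    """Heuristic helper: does *symbol* look like a database-assigned placeholder
    (a "CG number") rather than a community name?  The ``is_named`` column is
    authoritative; this exists only for building test data or sanity checks.
    """
    import re

    return bool(re.fullmatch(r"CG\d+", symbol))
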