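"""Seeded synthetic corpora and a simulated author-response model.

No external database extract is required anywhere in the package: this
module fabricates genes, authors, publications, annotations and response
behavior with the statistical shape the pipeline logic exercises —

* the 12-stratum category mix defaults to the proportions observed across
  the ~14k Drosophila protein-coding genes (dominated by well-studied genes
  with experimental GO + phenotype alleles on one end and uncharacterized
  orphans on the other);
* per-gene publication counts follow a truncated power law (literature
  links are heavy-tailed);
* each gene has a small recurring "lab" of authors so that last-authorship
  and per-author feature counts are informative;
* stage-wise response probabilities default to the observed second-cycle
  rates (29% initial, 32% first reminder, 11% second reminder, 30% for the
  second-ranked author).

Everything is driven by one :class:`numpy.random.Generator` seeded from the
config; identical config + seed reproduce byte-identical TSV output.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np

from .campaign import (Action, CampaignPolicy, Response, SolicitationRequest,
                       apply_action, next_action, record_response)
from .corpus import (Allele, Author, Corpus, Gene, GOAnnotation, PubGeneFlags,
                     Publication, Snapshot)

__all__ = ["SynthConfig", "DEFAULT_CATEGORY_MIX", "generate_corpus",
           "generate_publication_texts", "SimulationResult", "simulate_responses"]

# Stratum proportions of a full protein-coding gene complement, in the
# display order of categorize.CATEGORY_ORDER (exp/non-exp/no GO × pheno
# alleles × orthology).  Counts: 3214, 813, 1573, 601, 758, 196, 2544, 923,
# 155, 272, 517, 2341 of 13907.
DEFAULT_CATEGORY_MIX = tuple(
    n / 13907
    for n in (3214, 813, 1573, 601, 758, 196, 2544, 923, 155, 272, 517, 2341)
)

DEFAULT_STAGE_PROBABILITIES = (0.29, 0.32, 0.11, 0.30)

_SYLLABLES = ("an", "ber", "chi", "dor", "el", "fan", "gar", "hov", "is",
              "jun", "kov", "lin", "mar", "nov", "ol", "per", "qui", "ros",
              "sta", "tur", "ul", "var", "wen", "yam", "zel")


@dataclass(frozen=True)
class SynthConfig:
    """Knobs of the corpus generator; defaults are the study conditions."""

    n_genes: int = 300
    n_authors: int = 150
    pubs_per_gene: tuple[str, dict] = ("zipf", {"a": 1.6, "max": 40})
    authors_per_pub: tuple[int, int] = (2, 8)
    flag_probabilities: dict = field(default_factory=lambda: {
        "mutagen_or_nature_of_lesion": 0.30,
        "classical_allele_with_pheno": 0.35,
        "exp_go_bp_mf": 0.25,
        "expression_or_antibody": 0.30,
        "gene_source": 0.05,
    })
    category_mix: Optional[tuple[float, ...]] = DEFAULT_CATEGORY_MIX
    response_probabilities: tuple[float, ...] = DEFAULT_STAGE_PROBABILITIES
    year_range: tuple[int, int] = (1990, 2016)
    p_named: float = 0.45
    p_zero_pubs: float = 0.08
    p_extra_gene_link: float = 0.20
    p_high_throughput: float = 0.01
    high_throughput_links: int = 550
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.authors_per_pub
        if not (1 <= lo <= hi):
            raise ValueError("authors_per_pub must be a 1-based (lo, hi) range")
        if lo > self.n_authors:
            raise ValueError("authors_per_pub lower bound exceeds n_authors")
        for name, p in self.flag_probabilities.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"flag probability {name} outside [0, 1]")
        if any(not 0.0 <= p <= 1.0 for p in self.response_probabilities):
            raise ValueError("response probabilities must lie in [0, 1]")
        if self.category_mix is not None:
            if len(self.category_mix) != 12:
                raise ValueError("category_mix must have 12 entries")
            if abs(sum(self.category_mix) - 1.0) > 1e-9:
                raise ValueError("category_mix must sum to 1")


def _surname(rng: np.random.Generator) -> str:
    n = int(rng.integers(2, 4))
    return "".join(rng.choice(_SYLLABLES) for _ in range(n)).capitalize()


def _word(rng: np.random.Generator) -> str:
    return "".join(rng.choice(_SYLLABLES) for _ in range(2))


def _n_pubs(rng: np.random.Generator, family: str, params: dict) -> int:
    if family == "zipf":
        return int(min(rng.zipf(params.get("a", 1.6)), params.get("max", 40)))
    if family == "poisson":
        return int(rng.poisson(params.get("lam", 3.0)))
    if family == "constant":
        return int(params.get("value", 3))
    raise ValueError(f"unknown pubs_per_gene family {family!r}")


def generate_corpus(config: SynthConfig) -> Corpus:
    """Generate a referentially intact corpus from *config* (deterministic)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    y_lo, y_hi = config.year_range

    author_ids = [f"A{i:04d}" for i in range(config.n_authors)]
    authors = {
        aid: Author(
            author_id=aid,
            surname=_surname(rng),
            known_email=(f"{aid.lower()}@inst{int(rng.integers(1, 40))}.example.edu"
                         if rng.random() < 0.5 else None),
        )
        for aid in author_ids
    }

    gene_ids = [f"G{i:05d}" for i in range(config.n_genes)]
    if config.category_mix is not None and config.n_genes > 0:
        cat_idx = rng.choice(12, size=config.n_genes, p=np.asarray(config.category_mix))
    else:
        cat_idx = rng.integers(0, 12, size=config.n_genes)
    # decode index per categorize.CATEGORY_ORDER: status-major, then pheno, then ortholog
    statuses = ("exp", "non_exp", "none")

    publications: dict[str, Publication] = {}
    genes: dict[str, Gene] = {}
    pub_counter = 0
    gene_pub_ids: dict[str, list[str]] = {}

    for gid, ci in zip(gene_ids, cat_idx):
        status = statuses[ci // 4]
        wants_pheno = (ci % 4) < 2
        wants_ortholog = (ci % 2) == 0

        # publications of this gene, authored by a recurring lab
        if rng.random() < config.p_zero_pubs and not wants_pheno:
            n_pubs = 0
        else:
            n_pubs = max(1, _n_pubs(rng, *config.pubs_per_gene))
        lab_size = int(rng.integers(2, 6))
        lab = list(rng.choice(author_ids, size=lab_size, replace=False))
        pi = lab[0]  # the lab head usually signs last
        pub_ids: list[str] = []
        for _ in range(n_pubs):
            pid = f"P{pub_counter:06d}"
            pub_counter += 1
            lo, hi = config.authors_per_pub
            n_auth = int(rng.integers(lo, hi + 1))
            members = [a for a in lab if rng.random() < 0.7] or [pi]
            extras_needed = max(0, n_auth - len(members))
            if extras_needed:
                pool = [a for a in author_ids if a not in members]
                members += list(rng.choice(pool, size=min(extras_needed, len(pool)),
                                           replace=False))
            rng.shuffle(members)
            last = pi if rng.random() < 0.8 else members[-1]
            members = [a for a in members if a != last] + [last]
            year = int(rng.integers(y_lo, y_hi + 1))
            flags = {gid: _draw_flags(rng, config.flag_probabilities)}
            if rng.random() < config.p_extra_gene_link and config.n_genes > 1:
                for extra in rng.choice(config.n_genes,
                                        size=int(rng.integers(1, 3)), replace=False):
                    egid = gene_ids[int(extra)]
                    if egid != gid:
                        flags.setdefault(egid, _draw_flags(rng, config.flag_probabilities))
            publications[pid] = Publication(
                pub_id=pid, year=year, author_ids=members,
                n_linked_genes=len(flags), per_gene_flags=flags,
            )
            pub_ids.append(pid)
        gene_pub_ids[gid] = pub_ids

        annotations = _draw_annotations(rng, status)
        alleles = _draw_alleles(rng, gid, wants_pheno, pub_ids)
        has_human = wants_ortholog and rng.random() < 0.75
        genes[gid] = Gene(
            gene_id=gid,
            symbol=(_word(rng) if rng.random() < config.p_named
                    else f"CG{10000 + int(rng.integers(0, 80000))}"),
            name=f"{_word(rng)} {_word(rng)}",
            is_named=rng.random() < config.p_named,
            is_protein_coding=True,
            page_views=int(rng.pareto(1.2) * 50),
            go_annotations=annotations,
            alleles=alleles,
            has_human_ortholog=has_human,
            ortholog_in_omim=has_human and rng.random() < 0.5,
            has_nonarthropod_metazoan_ortholog=wants_ortholog and not has_human,
            gene_group_summary=(f"Member of the {_word(rng)} group."
                                if rng.random() < 0.3 else None),
            interactive_fly_summary=(f"Acts in {_word(rng)} development."
                                     if rng.random() < 0.3 else None),
        )

    # occasional high-throughput papers linking very many genes
    if config.n_genes >= 2 and publications:
        for pid in sorted(publications):
            if rng.random() < config.p_high_throughput:
                pub = publications[pid]
                n_links = min(config.high_throughput_links, config.n_genes)
                linked = rng.choice(config.n_genes, size=n_links, replace=False)
                for gi in linked:
                    pub.per_gene_flags.setdefault(gene_ids[int(gi)], PubGeneFlags())
                pub.n_linked_genes = len(pub.per_gene_flags)

    return Corpus(genes=genes, publications=publications, authors=authors)


def _draw_flags(rng: np.random.Generator, probs: dict) -> PubGeneFlags:
    return PubGeneFlags(**{name: bool(rng.random() < p) for name, p in probs.items()})


def _draw_annotations(rng: np.random.Generator, status: str) -> list[GOAnnotation]:
    if status == "none":
        return []
    aspects = ("BP", "MF", "CC")
    out: list[GOAnnotation] = []
    n_exp = 1 + int(rng.poisson(2)) if status == "exp" else 0
    n_non = (int(rng.poisson(3)) if status == "exp" else 1 + int(rng.poisson(2)))
    for i in range(n_exp + n_non):
        out.append(GOAnnotation(
            term_id=f"GO:{int(rng.integers(1, 2_000_000)):07d}",
            aspect=str(rng.choice(aspects)),
            is_root=bool(rng.random() < 0.05),
            evidence_class="experimental" if i < n_exp else "non_experimental",
        ))
    return out


def _draw_alleles(rng: np.random.Generator, gid: str, wants_pheno: bool,
                  pub_ids: list[str]) -> list[Allele]:
    out: list[Allele] = []
    n_pheno = (1 + int(rng.poisson(1.5))) if wants_pheno else 0
    n_plain = int(rng.poisson(0.5))
    for i in range(n_pheno + n_plain):
        source = str(rng.choice(pub_ids)) if pub_ids else ""
        out.append(Allele(
            allele_id=f"{gid}[{i + 1}]",
            is_classical=bool(rng.random() < 0.8),
            has_phenotype=i < n_pheno,
            source_pub=source,
        ))
    return out


def generate_publication_texts(corpus: Corpus, seed: int = 0) -> dict[str, str]:
    """Plain-text blobs per publication, with the last author's contact
    address embedded the way journals print correspondence lines."""
    rng = np.random.default_rng(seed)
    texts: dict[str, str] = {}
    for pid in sorted(corpus.publications):
        pub = corpus.publications[pid]
        last = corpus.authors[pub.last_author]
        address = f"{last.surname.lower()}.{pub.last_author.lower()}@uni{int(rng.integers(1, 99))}.example.edu"
        other = f"office@journal{int(rng.integers(1, 20))}.example.org"
        texts[pid] = (
            f"Study of gene function ({pub.year}).\n"
            f"Authors: {', '.join(pub.author_ids)}.\n"
            f"Correspondence: {address}. Editorial contact: {other}.\n"
        )
    return texts


# ---------------------------------------------------------------------------
# Simulated author-response model
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    """Everything a simulated campaign produced."""

    requests: list[SolicitationRequest]  # originals plus escalated successors
    responses: list[Response]
    snapshots: list[Snapshot]
    last_day: int  # days from send-out to the final event


def simulate_responses(
    requests: Sequence[SolicitationRequest],
    response_probabilities: Sequence[float] = DEFAULT_STAGE_PROBABILITIES,
    seed: int = 0,
    policy: CampaignPolicy | None = None,
    next_author: Optional[Callable[[SolicitationRequest], Optional[str]]] = None,
) -> SimulationResult:
    """Drive *requests* through the campaign state machine with Bernoulli
    responders at each stage.

    At every stage (initial contact, each reminder, then the escalated ask
    of the next-ranked author) each still-active request independently
    submits a snapshot with that stage's probability.  ``next_author`` maps
    an exhausted request to the gene's next expert; the default invents a
    deterministic successor id, and escalated successors are asked once
    (no further reminders), mirroring a single second-author stage.
    """
    pol = policy or CampaignPolicy()
    probs = list(response_probabilities)
    if len(probs) < pol.max_reminders + 2:
        raise ValueError("need a probability for each stage incl. escalation")
    rng = np.random.default_rng(seed)
    if next_author is None:
        next_author = lambda r: f"{r.author_id}.r{r.author_rank + 2}"

    all_requests = list(requests)
    responses: list[Response] = []
    snapshots: list[Snapshot] = []
    last_day = 0

    def submit(req: SolicitationRequest, day0: _dt.date, offset: int) -> None:
        nonlocal last_day
        date = day0 + _dt.timedelta(days=offset)
        resp = Response(req.gene_id, req.author_id, "snapshot", date,
                        text=f"Synthetic snapshot for {req.gene_id}.")
        snap = record_response(req, resp)
        responses.append(resp)
        if snap is not None:
            snapshots.append(snap)
        last_day = max(last_day, (date - req.sent_date).days)

    # first-ranked author: initial + reminders per policy
    n_stages = 1 + pol.max_reminders
    for req in requests:
        day = req.sent_date
        for stage_idx in range(n_stages):
            if rng.random() < probs[stage_idx]:
                submit(req, day, offset=1)
                break
            # deadline lapses: one full period after last contact
            day = req.last_contact + req.period + _dt.timedelta(days=1)
            action = next_action(req, day, pol)
            apply_action(req, action, day)
            last_day = max(last_day, (day - req.sent_date).days)
            if action is Action.ESCALATE:
                break
        else:
            day = req.last_contact + req.period + _dt.timedelta(days=1)
            apply_action(req, next_action(req, day, pol), day)
            last_day = max(last_day, (day - req.sent_date).days)

        if req.status != "escalated":
            continue
        successor_id = next_author(req)
        if successor_id is None or not pol.escalate_after_exhaustion:
            continue
        succ = SolicitationRequest(
            gene_id=req.gene_id, author_id=successor_id,
            batch_kind="individual", sent_date=day,
            deadline_days=pol.individual_deadline_days,
            author_rank=req.author_rank + 1,
        )
        all_requests.append(succ)
        if rng.random() < probs[n_stages]:
            submit(succ, day, offset=1)
        else:
            close_day = succ.last_contact + succ.period + _dt.timedelta(days=1)
            succ.status = "closed"
            succ.log(close_day, "closed")
            last_day = max(last_day, (close_day - req.sent_date).days)

    return SimulationResult(all_requests, responses, snapshots, last_day)
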