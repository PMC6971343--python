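# Methods

This note documents the models, rules and numerical choices behind
`genesnap`, in the order the pipeline runs them.

## Problem setting

A model-organism database wants short, manually written summaries ("gene
snapshots") of each well-characterized gene's function. Writing thousands
of summaries in-house is infeasible, so the pipeline solicits them from the
researchers who generated the underlying data: it decides *which genes*
merit a summary, *which author* to ask for each gene, *where to reach
them*, and *how to follow up* when they do not respond.

## Gene prioritization (pilot score)

Each gene receives

```
totalScore = GO score + evidence score + page_views / 10
             + n_publications + 20·[human ortholog] + 50·[ortholog in OMIM]
```

- **GO score** — 1 point per GO annotation, 0.5 for an aspect-root term
  (root terms carry almost no information), 0 with no annotation.
- **evidence score** — 200 / 100 / 50 points for having at least one
  Biological Process / Molecular Function / Cellular Component term.
  The award is per aspect *present*, regardless of evidence class: the
  score measures annotation breadth, not quality (quality enters later via
  the categorizer).
- Page views are divided by 10 to put typical view counts on the same
  scale as publication counts; orthology and OMIM presence are 0/1
  indicators.

All weights live in `PipelineConfig.gene_score` so a sensitivity
experiment is a YAML edit. Ranking ties are broken by gene id ascending —
a deterministic rule chosen here because none is published.

Root-term flags (`is_root`) are taken from the input tables as given; the
package deliberately does not bundle an ontology to re-derive them.

## Gene categorization

Later cycles replace the composite score with explicit evidence filters.

- `go_status(gene)` — `exp` if any annotation carries experimental
  evidence, else `non_exp` if any annotation exists, else `none`.
- `categorize(gene)` — the 3 × 2 × 2 stratification: GO status ×
  has-alleles-with-phenotype × has-ortholog (human or other non-arthropod
  metazoan). The twelve strata partition any gene set; this is property-
  tested on random corpora.
- `merits_snapshot(gene)` — experimental GO data AND alleles with
  phenotype. Orthology does not enter the rule, and the alleles need not
  be classical.
- `cycle2_eligible(gene)` — drops unnamed genes lacking a *classical*
  allele with phenotypic effects; named genes always pass. Note the
  asymmetry with `merits_snapshot`: the eligibility filter demands
  classical alleles, the merit rule does not — the two rules are stated
  independently and implemented literally.

Published stratum totals place 4 027 genes in the two meriting strata
while ~4 981 genes are described as meriting a summary; the discrepancy is
in the source material and is not reconciled here — the package implements
the stated rule only.

## Expert scoring and ranking

For one author and one gene, seven counts are taken over the author's
publications linked to the gene (any authorship position):

| feature | condition on the publication |
|---|---|
| `ten_year_recent` | year within the last 10 years of the reference year |
| `mutagen_or_nature_of_lesion` | describes new genetic reagents |
| `gene_counts_500_limit` | linked to < 500 genes (excludes high-throughput papers) |
| `classical_alleles_with_pheno` | describes classical-allele phenotypes |
| `exp_go` | contributes experimental-evidence GO (BP/MF) |
| `expression_plus_antibody` | expression data and/or an antibody |
| `gene_source` | first characterization ("gene source") |

The score is

```
(ten_year_recent/10 + mutagen/5)
  × (g500/5 + 3·classical + 10·expGO + 10·expr+AB + 10·gene_source)
```

The first factor is an *activity* gate (recent work or reagent
generation), the second a *specificity* weight favoring functional,
gene-focused work. Because the first factor is a sum, an author with no
recent papers but reagent papers still scores — the worked ten-author
example confirms this (its rank-5 author has zero recent papers and score
60), even though the accompanying prose describes the gate as requiring
both. The formula, which the printed scores follow, is what is
implemented.

Display scores are rounded to the nearest integer, half away from zero;
all ten printed example scores reproduce exactly (golden-tested). Ranking
uses the raw value. Eligibility: the author must have been last author on
at least one linked publication (a seniority proxy), must not be on the
exclusion list (retired, deceased, opted out — maintained as a one-id-per-
line file), and must have a strictly positive score.

`reference_year` is an explicit parameter everywhere; nothing reads the
wall clock.

### Assignment and load capping

Uncapped, each gene goes to its top-ranked author (verified equal to a
brute-force per-gene argmax). With a load cap *k* — replacing the original
ad hoc manual reassignment with a deterministic rule — any author holding
more than *k* genes keeps their *k* highest raw-scoring ones (ties by gene
id) and the rest escalate to their next-ranked author, iterating to a
fixed point. The iteration terminates because rank indices only ever
increase. Genes with an empty or exhausted ranking are reported
`unassignable` / `no-expert-remaining` rather than silently dropped.

## E-mail address extraction

Addresses are captured from plain publication text with a conservative
pattern (`[A-Za-z0-9._%+-]+@` dotted-domain, TLD ≥ 2 letters), lowercased
and deduplicated. Obfuscated forms ("name at domain dot com") are
deliberately out of pattern. For a given author, only publications from
the last 5 years on which the author appears are searched — older
addresses are too likely stale — and a candidate must contain the author's
surname after normalization (casefold, strip diacritics, drop
hyphens/apostrophes/spaces; so "García-López" matches `garcialopez@…`).
The surname is matched against the whole address, not just the local part.
Ties prefer the most recent publication, then the lexicographically
smallest address. No match ⇒ the author is flagged `needs_review` for a
manual lookup; the package never guesses.

## Campaign state machine

Authors asked for ≤ 5 genes get one individual e-mail per gene with a
7-day reply deadline; authors asked for ≥ 6 genes get a single e-mail
covering all of them plus a CSV manifest (gene id, symbol, name, blank
snapshot column) with a 28-day deadline. Messages are rendered from a
`{placeholder}` template (gene name, symbol, author surname, personalized
form link, optional gene-group and Interactive Fly summaries — absent
summaries render as an explicit omission line). Message *delivery* is out
of scope: the CLI writes `.eml`-style text files to an outbox.

A reminder becomes due one full deadline period after the previous
contact ("period = deadline" is the one published timing rule; the first
day strictly after the period triggers it). The default policy sends up to
two reminders then escalates to the next-ranked author; a one-reminder
policy (adopted after the second reminder's yield proved low) skips
straight to escalation. Individual requests may carry a per-request
deadline override for authors who negotiated their own timeline. Bounces
escalate immediately. Responses map: snapshot → `submitted` (a Snapshot
record with contributor and date stamp is emitted), decline / not-my-gene /
too-busy → `declined`, bounce → `bounced`. Terminal statuses only accept
history appends; duplicate submissions are kept and deduplicated per gene
afterwards (earliest kept).

`summarize_campaign` reports, per stage (initial, first reminder, second
reminder, second-ranked author), how many requests were contacted at that
stage and how many snapshots that stage yielded, with whole-percent
rounding. Denominators are defined as "requests actually contacted at the
stage"; bookkeeping in the original campaign involved manual removals
between stages, so externally published denominators can differ from this
definition.

## Synthetic corpus and responder

The generator fabricates a corpus whose statistical shape exercises every
pipeline branch, with all randomness from one seeded
`numpy.random.Generator`:

- **Category mix** — each gene's stratum is drawn from a 12-vector of
  proportions; the default is the observed stratum distribution of a full
  ~13.9k-gene protein-coding complement (≈23% experimental GO + phenotype
  alleles + ortholog, …, ≈17% entirely uncharacterized). Annotations,
  alleles and orthology flags are then drawn to realize the stratum.
- **Publications** — per-gene counts follow a truncated power law
  (`zipf(a=1.6)` capped at 40 by default; the family is configurable since
  no distribution is published). Each gene has a small recurring "lab"
  whose head usually signs last, making last-authorship and per-author
  counts informative. A small fraction of papers (1%) are high-throughput,
  linking ~550 genes, to exercise the 500-gene cutoff.
- **Flags** — per-(publication, gene) data-type flags are independent
  Bernoulli draws with configurable probabilities.
- **Responder** — at each stage (initial, each reminder, escalated ask)
  every active request independently submits with that stage's
  probability; defaults are the observed second-cycle stage rates
  (0.29, 0.32, 0.11, 0.30). Escalated successor requests are asked once.

What the generator does **not** emulate: real author-name ambiguity,
correlation between a paper's flags and the gene's annotation state,
non-stationary response behavior, and bounce timing. Passing tests
therefore demonstrate the pipeline's logic and arithmetic, not field
response rates.

## Problem sizes and tolerances

Statistical tests run at sizes chosen to keep binomial error interpretable:
the category-mix check uses 5 000 genes against 3 standard errors; the
partition property uses 100 corpora of 40 genes; the campaign-rate check
pools 20 seeded runs of 1 690 requests per stage and compares the pooled
rate to the configured probability within 4 standard errors; assignment-
oracle comparisons use corpora of ≤ 50 genes. Percent reporting rounds
half up; score display rounds half away from zero (no printed value sits
on a half).

## Known limitations

- The TSV schemas are this package's interchange invention; the original
  internal database schemas are not public.
- `n_linked_genes` on a hand-built publication may exceed the number of
  per-gene flag rows supplied (a partial extract); the synthetic generator
  always keeps the two consistent.
- The PDF→text step is not included; extraction operates on plain text.
- Whether "presence of ortholog" in the pilot score meant specifically a
  human ortholog is ambiguous in the source; it is implemented as the
  human-ortholog flag (the OMIM term already implies human).
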