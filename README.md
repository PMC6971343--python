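# genesnap

A pipeline for soliciting short, expert-written gene summaries ("gene
snapshots") from a research community, driven entirely by the curated data
already inside a model-organism database. It is written for biocurators
running a community-curation campaign: given a tabular extract of genes
(GO annotations, alleles, orthology, page views), publications (ordered
author lists, per-gene data-type flags) and authors, it

1. **scores and stratifies genes** to decide which merit a summary,
2. **ranks authors per gene** by an expert score computed from their
   publication record on that gene,
3. **extracts contact addresses** from publication text by regular
   expression with surname anchoring and a 5-year recency filter, and
4. **plans and tracks the e-mail campaign** — individual vs spreadsheet
   batching, 1-week/4-week deadlines, reminders, escalation to the
   next-ranked expert, and stage-wise response-rate reporting.

A seeded synthetic-corpus generator and a simulated responder let the
entire pipeline run end-to-end with no external data.

## The two scores

Pilot-cycle gene prioritization:

```
totalScore = GO score + evidence score + pageViews/10 + nPubs
             + 20·[human ortholog] + 50·[ortholog in OMIM]
```

with 1 point per GO term (0.5 for aspect roots) and 200/100/50 points for
having ≥1 BP/MF/CC term.

Per-(author, gene) expert score, over the author's publications linked to
the gene:

```
score = (recent₁₀/10 + reagent/5)
        × (papers₍<500 genes₎/5 + 3·classicalPheno + 10·expGO
           + 10·expr+AB + 10·geneSource)
```

Authors never last author on the gene, manually excluded authors and
zero scores are dropped; display scores are rounded to the nearest
integer. Later cycles filter genes by evidence instead of score: a gene
*merits a snapshot* iff it has experimental GO data and alleles with
phenotypes.

## Worked example

The expert score for an author with 8 recent papers, 5 reagent papers,
24 papers under the 500-gene limit, 12 classical-allele-phenotype papers
and 1 experimental-GO paper on the gene:

```python
>>> from genesnap.expert_rank import AuthorGeneFeatures, expert_score
>>> f = AuthorGeneFeatures(ten_year_recent=8, mutagen_or_nature_of_lesion=5,
...                        gene_counts_500_limit=24,
...                        classical_alleles_with_pheno=12, exp_go=1)
>>> s = expert_score(f)
>>> print(f"raw={s.raw}  display={s.display}")
raw=91.44  display=91
```

(8/10 + 5/5) = 1.8 activity × (24/5 + 36 + 10) = 50.8 specificity →
91.44, displayed as 91: this author is the gene's top-ranked expert and
would be e-mailed first.

End-to-end on a synthetic corpus:

```sh
$ genesnap simulate --out corpus/ --seed 7 --n-genes 200 --n-authors 120
wrote corpus with 200 genes, 1420 publications to corpus/
$ genesnap categorize --corpus corpus/ --summary --out strata.tsv
wrote 12 rows to strata.tsv
```

`strata.tsv` then holds the 12-way stratification (GO status × phenotype
alleles × orthology); with seed 7 its first rows are

```
go_status  has_pheno_alleles  has_ortholog  n_genes  merits_snapshot
exp        True               True          38       True
exp        True               False         11       True
exp        False              True          22       False
...
```

so 49 of the 200 synthetic genes (the two `merits_snapshot` strata) would
be targeted for solicitation. From there, `genesnap assign --cap N` picks
and load-caps experts, `plan-campaign` writes the request ledger, message
files and spreadsheet manifests, `tick --today DATE` advances reminders
and escalations, `ingest-responses` records submissions as date-stamped
snapshot records, and `report` prints the stage-wise response table.

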