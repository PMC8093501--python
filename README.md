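# genespectrum

Curating the disease spectrum of breast cancer susceptibility genes (BCSGs)
from heterogeneous evidence.

## The problem

Pathogenic germline variants in the established breast cancer susceptibility
genes (*ATM, BARD1, BRCA1, BRCA2, CDH1, CHEK2, NF1, PALB2, PTEN, RECQL,
STK11, TP53*) raise the risk of diseases well beyond breast cancer, but the
resources clinicians consult — ClinGen gene-disease validity and
actionability reports, the NCCN testing guidelines, OMIM, Genetics Home
Reference (GHR/MedlinePlus Genetics), GeneCards, and Gene-NCBI — disagree,
lag, or are silent about many gene-disease pairs.  `genespectrum` implements
a reproducible procedure for consolidating them: code each resource's
content for each candidate pair, push the coded evidence through a fixed
decision tree, and resolve what remains uncertain with a semiautomated
literature review plus a quantitative penetrance rule.

It is a library for biostatisticians and clinical-genetics curators who want
the rule engine, not a web scraper: resource content arrives pre-extracted
(categories and flags), and literature retrieval is represented by offline
query strings and a pluggable study provider.

## The method

**Evidence coding.** Each (gene, disease, resource) observation becomes a
four-valued code: `1` (SUPPORTED — the association is definitive in that
resource), `9` (POSSIBLE), `0` (REFUTED — a report exists and disputes the
association or finds no evidence), or blank (NOT_LISTED — no record).
ClinGen validity categories map Definitive/Strong/Moderate → `1`, Limited →
`9`, Refuted/Disputed/No Reported Evidence → `0`; actionability and NCCN
entries are coded from report flags; the four minor resources are coded by
presence.

**Verification tree.** For each pair, evaluated in fixed order:

1. combined ClinGen `1` or NCCN `1` → **verified** (major route);
2. combined ClinGen `0` → **no association**, directly;
3. ≥ 3 of the 4 minor resources `1` → **verified** (minor route);
4. otherwise **uncertain** → literature stage.

**Literature stage.** A boolean query `(gene terms) AND (disease terms)` is
built per uncertain pair; abstracts are classified by a one-vs-rest linear
SVM over tf-idf unigram/bigram features into PENETRANCE / PREVALENCE / BOTH
/ NEITHER, and the relevant subset feeds adjudication.

**Adjudication.** An uncertain association is verified when at least one
high-quality penetrance study (allowed design, adequate carrier count)
reports an effect estimate `≥ 2.0` (OR/RR/HR/SIR) that is statistically
significant — 95% CI lower bound `> 1`, or `p < 0.05` when no CI is given.
An empty literature result means no association; anything else stays
uncertain pending an explicit consensus override.

## Worked example

```python
from genespectrum import (VerificationRoute, load_fixture, summarize,
                          resource_support_counts, table1_to_evidence_rows)

outcomes = summarize(load_fixture("table2_spectrum"))
print(outcomes.total_verified)                                        # 86
print(outcomes.by_route[VerificationRoute.MAJOR_CLINGEN_NCCN])        # 78
print(outcomes.route_percent(VerificationRoute.MAJOR_CLINGEN_NCCN))   # 90

rows = table1_to_evidence_rows(load_fixture("table1_breast"))
print(resource_support_counts(rows, "breast cancer")["ATM"])          # 6
```

The packaged spectrum fixture holds 86 verified gene-disease pairs: 78
established by ClinGen and/or NCCN (90%), 4 rescued by the ≥3-of-4
minor-resource rule, and 4 verified by the NLP-aided literature review
alone (*ATM*-gastric, *CHEK2*-gastric, *CHEK2*-kidney, *CHEK2*-thyroid).
The support counts reconstruct the per-gene "number of resources" column
for the anchor breast-cancer association (6,6,6,6,6,6,4,4,4,3,1,1).

Longer narrative walkthroughs live in `examples/` — one script per
capability (classification, full pipeline on a synthetic matrix, triage,
adjudication, spectrum reporting); each prints the numbers it computes.

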