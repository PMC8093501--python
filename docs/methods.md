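# Methods

## Evidence model

Each gene-disease pair carries seven per-resource codes: ClinGen validity,
ClinGen actionability, NCCN, OMIM, GHR, GeneCards, and Gene-NCBI.  The code
alphabet is `SUPPORTED` ('1'), `POSSIBLE` ('9'), `REFUTED` ('0') and
`NOT_LISTED` (blank).  Distinguishing `NOT_LISTED` from `REFUTED` is a
deliberate modelling choice: published coded matrices of this kind often
collapse "absent" and "refuted" into '0', but the two states behave
differently downstream — only an explicit refutation short-circuits the
evaluation, while mere absence leaves a pair rescuable by the minor-resource
rule or the literature.  This is the only reading under which associations
absent from both major resources can still be verified by three minor
resources, as the procedure requires.  Accordingly, ClinGen's "No Reported
Evidence" category (a report exists, and it found nothing) codes as
`REFUTED`, whereas a missing ClinGen record is `NOT_LISTED`.

The two ClinGen sub-codes are merged for the decision tree with the
precedence *support > validity refutation > possible > not listed*.  The
merge order is a package decision (the sources that motivate the pipeline
track two ClinGen report types but evaluate a single ClinGen status);
actionability reports cannot refute by construction, so only the validity
sub-code can drive the no-association branch.

Disease names are normalized by case-folding, punctuation stripping
(hyphens kept), and whitespace collapsing; an optional synonym table maps
variants onto canonical labels.  Trailing "cancer"/"carcinoma" is never
stripped implicitly — benign "thyroid" and malignant "thyroid cancer" must
remain distinct — only a synonym entry can merge such labels.  Uniqueness of
diseases is computed on normalized names.  Gene symbols are opaque uppercase
identifiers; no registry lookup is attempted.

## Verification tree

Rows are evaluated in a fixed order: (1) combined ClinGen or NCCN supported
→ verified via the major route; (2) combined ClinGen refuted → no
association; (3) at least `minor_resource_threshold` of the four minor
resources supported → verified via the minor route; (4) otherwise uncertain.

Two genuinely open points were resolved as follows:

* **Threshold wording.** The narrative sources describing this procedure
  state the minor-resource rule variously as "more than three" and "three or
  more"; only ≥ 3 is consistent with the complementary "fewer than three"
  wording of the uncertain branch and with the four minor-route associations
  actually reported.  The default is therefore ≥ 3, configurable through
  `EngineConfig.minor_resource_threshold` (valid range 1..4).
* **Precedence of refutation.** Verification is checked before refutation,
  so NCCN support survives a ClinGen refutation; "no association directly"
  is read as short-circuiting only the minor-resource and literature steps.
  The engine's full 4^7 truth table is pinned against an independently
  written rule table in the tests, along with the partition property and
  evidence monotonicity (promoting any single code to supported never
  demotes a verified pair).

`POSSIBLE` codes never count toward the minor-resource threshold by default
(`count_possible_as_support=False`): the rule counts definitive listings.
The group consensus meeting that reviewed every association is represented
by an explicit override map applied after the literature stage; overridden
verifications carry the `MANUAL_CONSENSUS` route so they remain auditable.

## Literature triage

The abstract classifier is a one-vs-rest linear SVM (squared-hinge, L2,
C = 1.0) over tf-idf features (sublinear tf, unigrams + bigrams) of the
concatenated title and abstract, with a deterministic tokenizer (lowercase,
split on non-alphanumerics, drop single-character tokens, no stemming).
The four-class scheme — penetrance, prevalence, both, neither — follows the
semiautomated procedure the pipeline emulates; the original classifier and
its labelled corpus are not publicly available, so this is a re-implementation
of the described algorithm family, not a replica, and its accuracy figures
characterize the synthetic corpus only.  An abstract whose tokens are all
out of vocabulary produces a zero feature vector and defaults to NEITHER.
Abstracts labelled penetrance, prevalence or both are forwarded to
adjudication (the inclusive reading; the relevant label set is an argument).
Query strings are emitted offline in the form
`(gene terms) AND (disease terms)`; no retrieval is performed.

## Adjudication

A study is **high quality** when its design is whitelisted (case-control,
cohort, family-based, GWAS — not "other") and any reported carrier count is
at least `min_carriers`.  A study is **significant** when its 95% CI lower
bound strictly exceeds 1, or, lacking a CI, when p < alpha; the CI takes
precedence when both are present and disagree.  A study **meets the risk
rule** when its point estimate is at least `fold_threshold` (inclusive,
default 2.0) and it is significant.  An association **adjudicates** to
verified when at least `min_passing_studies` (default 1) studies pass both
screens; an empty study list adjudicates to no association (the literature
search found nothing relevant); otherwise the pair stays uncertain.

Defaults and their standing: `fold_threshold = 2.0` and the "at least
two-fold, statistically significant" shape are the method's stated rule;
`alpha = 0.05`, the strict CI convention, `min_carriers = 10` and the design
whitelist are package conventions standing in for the consensus group's
unstated judgment, and all are configurable.  Protective effects never
satisfy the rule; cumulative-risk-only studies carry no ratio estimate, are
not adjudicable, and must be handled through the override hook.

## Synthetic data

The three generators emulate the study conditions so that every stage is
testable without network access or the undeposited source data.

* **Evidence matrix** — default 12 genes × 66 candidate diseases, 160
  candidate pairs with planted routes in proportions 78:4:4:74
  (major : minor : literature : none), matching the accounting of the
  curation exercise the package reproduces.  Route planting is constructive
  (major rows get a supported major resource; minor rows get 3-4 supported
  minors and silent majors; literature rows carry no support; none rows are
  ClinGen-refuted), and `possible_code_rate` injects '9' noise into blank
  cells, which cannot change a planted route because possible codes never
  count as support.  Route counts are apportioned by largest remainder
  (ties to the earlier-declared route).  `refuted_none_fraction` (default
  1.0) controls whether non-associations are planted as explicit refutations
  or as sparse rows; only the refuted form is distinguishable from a
  literature-route row before the literature stage, which is why it is the
  default.
* **Abstract corpus** — four balanced classes with class-specific token
  pools (the penetrance pool is seeded with terms like "penetrance",
  "cumulative", "hazard"; the prevalence pool with "prevalence",
  "frequency", "unselected"; BOTH pools both), plus a shared background
  pool.  `vocab_overlap` is the per-token probability of drawing from the
  shared pool: 0 gives linear separability, 1 removes all signal and
  held-out accuracy falls to chance (0.25).  Defaults: 200 documents per
  class, overlap 0.1, 40 tokens per class pool, 60 tokens per document.
  What the corpus does *not* emulate: real abstract length variation,
  correlated topical vocabulary, class imbalance, and annotation noise —
  passing triage tests therefore demonstrate the training/evaluation
  machinery and the generator's contract, not expected performance on
  PubMed text.
* **Penetrance studies** — per-study log effect drawn Normal(true log
  ratio, se) with se uniform in `se_range` (default 0.1-0.5, spanning
  well-powered cohorts to small series), 95% Wald interval and two-sided
  Wald p-value derived from the same draw, carrier counts uniform in
  `carrier_range` (default 20-200, above the quality screen so the
  simulations exercise the risk rule, not the screen).  The generative
  model is a package choice: a normal-on-log-scale effect with Wald
  uncertainty is the standard approximation for ratio estimates.

All generators are pure functions of their config including the seed.

## Numerical and formatting conventions

* Integer percentages are computed by truncation, matching how the headline
  share (78/86 → 90%) is conventionally printed; `integer_percent` documents
  this and the exact fraction is always available from the counts.
* Spectrum output is sorted gene → category (malignant, benign, borderline)
  → disease, making serialized tables diff-stable.
* The CI-bracketing invariant (`ci_low ≤ point ≤ ci_high`) and the
  positivity of ratio estimates are enforced at construction; violations
  raise rather than propagate.
* Simulation sizes in the shipped tests and acceptance script (1,000
  replicates of 5-study sets; 800-document corpora) were chosen as the
  smallest sizes at which the Monte-Carlo noise is far from the asserted
  margins.

## Known limitations

* Resource content must arrive pre-extracted; the package contains no
  clients for the six resources, so coding fidelity depends on the upstream
  extraction.
* The unique-disease count depends on the normalization and synonym table;
  the packaged spectrum yields 47 unique names under the default
  normalization, and no external value is asserted for it (the fixture
  README documents the ambiguity in the source material).
* The triage model is a re-implementation trained on synthetic text; its
  published-validation sensitivity/specificity do not transfer.
* Adjudication is per-study by design — no meta-analytic pooling — so a set
  of individually sub-threshold but consistent studies will not verify a
  pair without a manual override.
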