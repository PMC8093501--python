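"""Train and evaluate the abstract-triage classifier on a synthetic corpus.

Generates a balanced four-class corpus (penetrance / prevalence / both /
neither) with 10% shared vocabulary, trains the linear SVM on half, and
prints held-out metrics.  Also shows the offline boolean query builder.
"""

from genespectrum import (
    CorpusSimConfig,
    QuerySpec,
    build_query,
    evaluate_triage,
    generate_abstract_corpus,
    train_triage,
    triage_abstracts,
)

query = build_query(
    QuerySpec(["CHEK2", "RAD53"], ["gastric cancer", "stomach neoplasm"])
)
print("literature query:", query)

corpus = generate_abstract_corpus(
    CorpusSimConfig(n_per_class=200, vocab_overlap=0.1, seed=0)
)
train, heldout = corpus[::2], corpus[1::2]
model = train_triage(train, seed=0)
metrics = evaluate_triage(model, heldout)

print(f"\nheld-out accuracy: {metrics.accuracy:.3f} on {len(heldout)} abstracts")
print("per-class sensitivity / specificity:")
for label in metrics.sensitivity:
    print(f"  {label.value:<11} {metrics.sensitivity[label]:.3f} / "
          f"{metrics.specificity[label]:.3f}")

labels, relevant = triage_abstracts(model, heldout)
print(f"\nabstracts triaged as relevant (penetrance/prevalence/both): "
      f"{len(relevant)} of {len(heldout)}")

# The relevant subset is what proceeds to full-text review and the two-fold
# adjudication rule; NEITHER-class abstracts are discarded at this stage.
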