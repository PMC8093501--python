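"""Boolean query building and SVM abstract triage."""

import re

import pytest

from genespectrum import (
    AbstractRecord,
    CorpusSimConfig,
    QuerySpec,
    TriageLabel,
    build_query,
    evaluate_triage,
    generate_abstract_corpus,
    read_abstracts_jsonl,
    tokenize,
    train_triage,
    triage_abstracts,
    write_abstracts_jsonl,
)


def parse_query(query: str) -> tuple[list[str], list[str]]:
    """Independent parser for the emitted boolean template (test oracle)."""
    match = re.fullmatch(r"\((?P<genes>.+)\) AND \((?P<diseases>.+)\)", query)
    assert match, query

    def split(group: str) -> list[str]:
        return [term.strip('"') for term in group.split(" OR ")]

    return split(match.group("genes")), split(match.group("diseases"))


class TestQueryBuilder:
    @pytest.mark.parametrize(
        "genes, diseases, expected",
        [
            (["CHEK2"], ["gastric cancer"], '(CHEK2) AND ("gastric cancer")'),
            (
                ["ATM"],
                ["gastric cancer", "stomach neoplasm"],
                '(ATM) AND ("gastric cancer" OR "stomach neoplasm")',
            ),
            (["BRCA1", "BRCC1"], ["melanoma"], "(BRCA1 OR BRCC1) AND (melanoma)"),
        ],
    )
    def test_template_substitution(self, genes, diseases, expected):
        assert build_query(QuerySpec(genes, diseases)) == expected

    @pytest.mark.parametrize(
        "genes, diseases",
        [
            (["CHEK2", "RAD53"], ["kidney cancer", "renal cell carcinoma", "hypernephroma"]),
            (["NF1"], ["pulmonary stenosis"]),
        ],
    )
    def test_round_trip_recovers_term_lists(self, genes, diseases):
        query = build_query(QuerySpec(genes, diseases))
        assert parse_query(query) == (genes, diseases)

    def test_empty_term_lists_rejected(self):
        with pytest.raises(ValueError):
            QuerySpec([], ["breast cancer"])
        with pytest.raises(ValueError):
            QuerySpec(["ATM"], [])


class TestTokenizer:
    def test_lowercase_split_and_length_filter(self):
        assert tokenize("CHEK2 1100delC: a 2-fold risk!") == [
            "chek2",
            "1100delc",
            "fold",
            "risk",
        ]


def toy_corpus(n_per_class=20):
    """Two classes with disjoint vocabularies: linearly separable."""
    records = []
    for i in range(n_per_class):
        records.append(
            AbstractRecord(
                id=f"pen{i}",
                title="penetrance study",
                text="cumulative risk penetrance carriers lifetime",
                label=TriageLabel.PENETRANCE,
            )
        )
        records.append(
            AbstractRecord(
                id=f"nei{i}",
                title="expression analysis",
                text="pathway signaling transcription proliferation",
                label=TriageLabel.NEITHER,
            )
        )
    return records


class TestTraining:
    def test_separable_corpus_reaches_perfect_training_accuracy(self):
        corpus = toy_corpus()
        model = train_triage(corpus, seed=0)
        assert model.predict(corpus) == [r.label for r in corpus]

    def test_same_seed_gives_identical_predictions(self):
        corpus = generate_abstract_corpus(CorpusSimConfig(n_per_class=30, seed=3))
        probe = generate_abstract_corpus(CorpusSimConfig(n_per_class=10, seed=4))
        first = train_triage(corpus, seed=11).predict(probe)
        second = train_triage(corpus, seed=11).predict(probe)
        assert first == second

    def test_single_class_corpus_rejected(self):
        corpus = [r for r in toy_corpus() if r.label is TriageLabel.PENETRANCE]
        with pytest.raises(ValueError, match="two classes"):
            train_triage(corpus)

    def test_unlabelled_records_rejected(self):
        corpus = toy_corpus() + [AbstractRecord(id="x", title="t", text="u")]
        with pytest.raises(ValueError, match="unlabelled"):
            train_triage(corpus)

    def test_vocabulary_nonempty_after_training(self):
        model = train_triage(toy_corpus(), seed=0)
        assert len(model.vocabulary) > 0
        assert model.weights.shape[1] == len(model.vocabulary)


class TestPrediction:
    def test_out_of_vocabulary_text_defaults_to_neither(self):
        model = train_triage(toy_corpus(), seed=0)
        oov = AbstractRecord(id="oov", title="zzzz", text="qqqq wwww")
        assert model.predict([oov]) == [TriageLabel.NEITHER]

    def test_planted_penetrance_abstract_recovered(self):
        corpus = generate_abstract_corpus(
            CorpusSimConfig(n_per_class=100, vocab_overlap=0.1, seed=5)
        )
        model = train_triage(corpus[::2], seed=0)
        planted = [r for r in corpus[1::2] if r.label is TriageLabel.PENETRANCE][0]
        assert model.predict([planted]) == [TriageLabel.PENETRANCE]

    def test_relevant_subset_is_order_preserving(self):
        model = train_triage(toy_corpus(), seed=0)
        records = toy_corpus(5)
        labels, subset = triage_abstracts(model, records)
        assert len(labels) == len(records)
        assert set(labels) <= set(TriageLabel)
        relevant_ids = [r.id for r in subset]
        assert relevant_ids == [
            r.id
            for r, lab in zip(records, labels)
            if lab in {TriageLabel.PENETRANCE, TriageLabel.PREVALENCE, TriageLabel.BOTH}
        ]

    def test_empty_record_list(self):
        model = train_triage(toy_corpus(), seed=0)
        labels, subset = triage_abstracts(model, [])
        assert labels == [] and subset == []

    def test_strict_relevance_excludes_prevalence(self):
        model = train_triage(toy_corpus(), seed=0)
        records = toy_corpus(3)
        _, subset = triage_abstracts(
            model, records, relevant=(TriageLabel.PENETRANCE, TriageLabel.BOTH)
        )
        assert all(r.label is TriageLabel.PENETRANCE for r in subset)


class _StubModel:
    def __init__(self, labels):
        self._labels = list(labels)

    def predict(self, records):
        return self._labels[: len(records)]


class TestEvaluation:
    def test_perfect_predictions_score_one_everywhere(self):
        corpus = toy_corpus(10)
        model = train_triage(corpus, seed=0)
        metrics = evaluate_triage(model, corpus)
        present = {TriageLabel.PENETRANCE, TriageLabel.NEITHER}
        for label in present:
            assert metrics.sensitivity[label] == 1.0
            assert metrics.specificity[label] == 1.0
        assert metrics.accuracy == 1.0

    def test_absent_class_metrics_are_undefined_not_zero(self):
        corpus = toy_corpus(10)
        metrics = evaluate_triage(train_triage(corpus, seed=0), corpus)
        assert metrics.sensitivity[TriageLabel.BOTH] is None
        assert metrics.specificity[TriageLabel.BOTH] is not None

    def test_degenerate_all_neither_predictor(self):
        heldout = [
            AbstractRecord(f"r{i}", title="t", text="x", label=label)
            for i, label in enumerate(list(TriageLabel) * 3)
        ]
        stub = _StubModel([TriageLabel.NEITHER] * len(heldout))
        metrics = evaluate_triage(stub, heldout)
        assert metrics.sensitivity[TriageLabel.NEITHER] == 1.0
        for label in (TriageLabel.PENETRANCE, TriageLabel.PREVALENCE, TriageLabel.BOTH):
            assert metrics.sensitivity[label] == 0.0

    def test_metrics_match_hand_computed_confusion_matrix(self):
        # 12 records; predictions fixed by a stub; counts done by hand:
        # truth PEN x4 -> predicted PEN, PEN, PREV, NEITHER
        # truth PREV x4 -> predicted PREV, PREV, PREV, PEN
        # truth NEITHER x4 -> predicted NEITHER x4
        truth = (
            [TriageLabel.PENETRANCE] * 4
            + [TriageLabel.PREVALENCE] * 4
            + [TriageLabel.NEITHER] * 4
        )
        predicted = [
            TriageLabel.PENETRANCE,
            TriageLabel.PENETRANCE,
            TriageLabel.PREVALENCE,
            TriageLabel.NEITHER,
            TriageLabel.PREVALENCE,
            TriageLabel.PREVALENCE,
            TriageLabel.PREVALENCE,
            TriageLabel.PENETRANCE,
            TriageLabel.NEITHER,
            TriageLabel.NEITHER,
            TriageLabel.NEITHER,
            TriageLabel.NEITHER,
        ]
        heldout = [
            AbstractRecord(f"h{i}", title="t", text="x", label=lab)
            for i, lab in enumerate(truth)
        ]
        metrics = evaluate_triage(_StubModel(predicted), heldout)
        # sensitivity: PEN 2/4, PREV 3/4, NEITHER 4/4
        assert metrics.sensitivity[TriageLabel.PENETRANCE] == pytest.approx(0.5)
        assert metrics.sensitivity[TriageLabel.PREVALENCE] == pytest.approx(0.75)
        assert metrics.sensitivity[TriageLabel.NEITHER] == 1.0
        # specificity: PEN TN=7 FP=1, PREV TN=7 FP=1, NEITHER TN=7 FP=1
        assert metrics.specificity[TriageLabel.PENETRANCE] == pytest.approx(7 / 8)
        assert metrics.specificity[TriageLabel.PREVALENCE] == pytest.approx(7 / 8)
        assert metrics.specificity[TriageLabel.NEITHER] == pytest.approx(7 / 8)
        assert metrics.accuracy == pytest.approx(9 / 12)
        assert int(metrics.confusion.to_numpy().sum()) == 12

    def test_empty_heldout_rejected(self):
        with pytest.raises(ValueError):
            evaluate_triage(_StubModel([]), [])


class TestCorpusIO:
    def test_jsonl_round_trip(self, tmp_path):
        records = toy_corpus(3) + [AbstractRecord(id="u1", title="t", text="x")]
        path = tmp_path / "corpus.jsonl"
        write_abstracts_jsonl(records, path)
        back = read_abstracts_jsonl(path)
        assert back == records

    def test_duplicate_ids_rejected(self, tmp_path):
        path = tmp_path / "dup.jsonl"
        write_abstracts_jsonl([toy_corpus(1)[0]] * 2, path)
        with pytest.raises(ValueError, match="duplicate"):
            read_abstracts_jsonl(path)
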