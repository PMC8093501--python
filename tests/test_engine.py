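"""Decision-tree engine: branch order, truth table, pipeline orchestration."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genespectrum import (
    AdjudicationCriteria,
    DiseaseRecord,
    EngineConfig,
    EvidenceCode,
    EvidenceRow,
    GeneRecord,
    VerificationRoute,
    VerificationStatus,
    classify_association,
    classify_matrix,
    load_fixture,
    run_pipeline,
    table1_to_evidence_rows,
    truth_table,
)
from genespectrum.evidence import CODE_FIELDS


def row(**codes) -> EvidenceRow:
    return EvidenceRow(GeneRecord("GENE"), DiseaseRecord("some disease"), **codes)


S, P, R, N = (
    EvidenceCode.SUPPORTED,
    EvidenceCode.POSSIBLE,
    EvidenceCode.REFUTED,
    EvidenceCode.NOT_LISTED,
)


class TestClassifyAssociation:
    def test_all_six_resources_supported_is_major(self):
        outcome = classify_association(
            row(clingen_validity=S, nccn=S, omim=S, ghr=S, genecards=S, gene_ncbi=S)
        )
        assert outcome.status is VerificationStatus.VERIFIED
        assert outcome.route is VerificationRoute.MAJOR_CLINGEN_NCCN

    def test_actionability_support_alone_is_major(self):
        outcome = classify_association(row(clingen_actionability=S))
        assert outcome.route is VerificationRoute.MAJOR_CLINGEN_NCCN

    def test_three_minor_resources_rescue_an_absent_pair(self):
        outcome = classify_association(row(omim=S, ghr=S, genecards=S))
        assert outcome.status is VerificationStatus.VERIFIED
        assert outcome.route is VerificationRoute.MINOR_THREE_OF_FOUR

    def test_two_minor_resources_are_not_enough(self):
        outcome = classify_association(row(omim=S, ghr=S))
        assert outcome.status is VerificationStatus.UNCERTAIN

    def test_no_evidence_anywhere_is_uncertain(self):
        outcome = classify_association(row())
        assert outcome.status is VerificationStatus.UNCERTAIN
        assert outcome.route is VerificationRoute.NONE

    def test_clingen_refutation_blocks_minor_rescue(self):
        outcome = classify_association(
            row(clingen_validity=R, omim=S, ghr=S, genecards=S, gene_ncbi=S)
        )
        assert outcome.status is VerificationStatus.NO_ASSOCIATION

    def test_verification_precedes_refutation(self):
        # NCCN support wins even against an explicit ClinGen refutation
        outcome = classify_association(row(clingen_validity=R, nccn=S))
        assert outcome.status is VerificationStatus.VERIFIED
        assert outcome.route is VerificationRoute.MAJOR_CLINGEN_NCCN

    def test_possible_codes_do_not_count_by_default(self):
        outcome = classify_association(row(omim=P, ghr=P, genecards=P, gene_ncbi=P))
        assert outcome.status is VerificationStatus.UNCERTAIN

    def test_possible_codes_count_when_enabled(self):
        config = EngineConfig(count_possible_as_support=True)
        outcome = classify_association(row(omim=P, ghr=P, genecards=P), config)
        assert outcome.route is VerificationRoute.MINOR_THREE_OF_FOUR

    def test_raising_threshold_disables_three_of_four_rescue(self):
        config = EngineConfig(minor_resource_threshold=4)
        outcome = classify_association(row(omim=S, ghr=S, genecards=S), config)
        assert outcome.status is VerificationStatus.UNCERTAIN

    def test_threshold_must_fit_resource_count(self):
        with pytest.raises(ValueError):
            EngineConfig(minor_resource_threshold=5)
        with pytest.raises(ValueError):
            EngineConfig(minor_resource_threshold=0)


class TestClassifyMatrix:
    def test_empty_matrix(self):
        assert classify_matrix([]) == []

    def test_table1_genes_all_verify_via_major_resources(self, table1_rows):
        rows = table1_to_evidence_rows(table1_rows)
        outcomes = classify_matrix(rows)
        assert len(outcomes) == 12
        assert all(o.route is VerificationRoute.MAJOR_CLINGEN_NCCN for o in outcomes)

    def test_order_equivariance(self):
        rows = [
            EvidenceRow(GeneRecord(f"G{i}"), DiseaseRecord("d"), omim=S)
            for i in range(5)
        ]
        forward = classify_matrix(rows)
        backward = classify_matrix(rows[::-1])
        assert forward == backward[::-1]

    def test_duplicate_pairs_listed_in_error(self):
        duplicated = [row(), row()]
        with pytest.raises(ValueError, match="GENE"):
            classify_matrix(duplicated)


class TestTruthTable:
    def test_enumerates_all_code_combinations(self):
        table = truth_table()
        assert len(table) == 4 ** len(CODE_FIELDS)
        assert table[CODE_FIELDS[0]].nunique() == 4

    def test_status_route_coupling_partitions_outcomes(self):
        table = truth_table()
        verified = table["status"] == VerificationStatus.VERIFIED.value
        assert (table.loc[verified, "route"] != VerificationRoute.NONE.value).all()
        assert (table.loc[~verified, "route"] == VerificationRoute.NONE.value).all()
        assert set(table["status"].unique()) == {
            s.value for s in VerificationStatus
        }


@st.composite
def evidence_rows(draw):
    codes = {
        name: draw(st.sampled_from(list(EvidenceCode))) for name in CODE_FIELDS
    }
    return row(**codes)


class TestEngineProperties:
    @given(evidence_rows())
    @settings(max_examples=300, deadline=None)
    def test_every_row_gets_exactly_one_status(self, r):
        outcome = classify_association(r)
        assert outcome.status in VerificationStatus

    @given(evidence_rows(), st.sampled_from(CODE_FIELDS))
    @settings(max_examples=300, deadline=None)
    def test_promoting_a_field_to_supported_never_demotes_verified(self, r, name):
        before = classify_association(r)
        promoted = EvidenceRow(
            r.gene,
            r.disease,
            **{
                f: (S if f == name else getattr(r, f))
                for f in CODE_FIELDS
            },
        )
        after = classify_association(promoted)
        if before.status is VerificationStatus.VERIFIED:
            assert after.status is VerificationStatus.VERIFIED


class TestRunPipeline:
    def _uncertain_row(self, gene="CHEK2", disease="gastric cancer"):
        return EvidenceRow(GeneRecord(gene), DiseaseRecord(disease))

    def test_literature_verifies_uncertain_pair(self, studies_by_id):
        studies = [
            studies_by_id["chek2_gastric_cc"],
            studies_by_id["chek2_gastric_cohort"],
        ]
        outcomes = run_pipeline(
            [self._uncertain_row()],
            triage_provider=lambda gene, disease: studies,
        )
        assert outcomes[0].status is VerificationStatus.VERIFIED
        assert outcomes[0].route is VerificationRoute.LITERATURE_NLP

    def test_empty_literature_means_no_association(self):
        outcomes = run_pipeline(
            [self._uncertain_row()], triage_provider=lambda gene, disease: []
        )
        assert outcomes[0].status is VerificationStatus.NO_ASSOCIATION

    def test_absent_provider_behaves_as_empty_search(self):
        outcomes = run_pipeline([self._uncertain_row()])
        assert outcomes[0].status is VerificationStatus.NO_ASSOCIATION

    def test_sub_threshold_studies_leave_pair_uncertain(self, studies_by_id):
        outcomes = run_pipeline(
            [self._uncertain_row()],
            triage_provider=lambda g, d: [studies_by_id["chek2_gastric_cc"]],
        )
        assert outcomes[0].status is VerificationStatus.UNCERTAIN

    def test_override_applies_last_with_consensus_route(self):
        outcomes = run_pipeline(
            [self._uncertain_row()],
            overrides={("CHEK2", "gastric cancer"): VerificationStatus.VERIFIED},
        )
        assert outcomes[0].status is VerificationStatus.VERIFIED
        assert outcomes[0].route is VerificationRoute.MANUAL_CONSENSUS

    def test_override_for_unknown_pair_is_rejected(self):
        with pytest.raises(ValueError, match="unknown pairs"):
            run_pipeline(
                [self._uncertain_row()],
                overrides={("BRCA1", "lung cancer"): VerificationStatus.VERIFIED},
            )

    def test_verified_rows_bypass_literature(self):
        calls = []

        def provider(gene, disease):
            calls.append(gene.symbol)
            return []

        run_pipeline(
            [EvidenceRow(GeneRecord("ATM"), DiseaseRecord("breast cancer"), nccn=S)],
            triage_provider=provider,
        )
        assert calls == []
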