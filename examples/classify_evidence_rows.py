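"""Classify individual coded evidence rows through the decision tree.

Builds a handful of evidence rows by hand — one per branch of the tree —
and prints the verdict and route for each.
"""

from genespectrum import (
    DiseaseRecord,
    EvidenceCode,
    EvidenceRow,
    GeneRecord,
    classify_association,
)

S, R = EvidenceCode.SUPPORTED, EvidenceCode.REFUTED

rows = {
    "major (ClinGen + NCCN support)": EvidenceRow(
        GeneRecord("ATM"), DiseaseRecord("breast cancer"),
        clingen_validity=S, nccn=S, omim=S, ghr=S, genecards=S, gene_ncbi=S,
    ),
    "minor (3 of 4 minor resources)": EvidenceRow(
        GeneRecord("CDH1"), DiseaseRecord("bcd syndrome"),
        omim=S, ghr=S, genecards=S,
    ),
    "uncertain (no resource lists it)": EvidenceRow(
        GeneRecord("CHEK2"), DiseaseRecord("gastric cancer"),
    ),
    "refuted by ClinGen": EvidenceRow(
        GeneRecord("G1"), DiseaseRecord("some disease"),
        clingen_validity=R, omim=S, ghr=S, genecards=S, gene_ncbi=S,
    ),
}

for description, row in rows.items():
    outcome = classify_association(row)
    print(f"{description:<34} -> {outcome.status.value} ({outcome.route.value})")

# Note the last row: an explicit ClinGen refutation blocks the minor-resource
# rescue even though all four minor resources list the association, while a
# pair that is merely absent everywhere stays uncertain and proceeds to the
# literature stage.
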