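"""Decision-tree verification engine for coded gene-disease associations.

The tree evaluates each evidence row in a fixed order:

1. **Major-resource rule** — verified if the (combined) ClinGen status or the
   NCCN status is SUPPORTED.
2. **Refutation rule** — no association, directly, if the combined ClinGen
   status is REFUTED.  Refutation short-circuits the remaining steps only;
   it never overrides support found in step 1.
3. **Minor-resource rule** — verified if at least ``minor_resource_threshold``
   (default 3) of the four minor resources (OMIM, GHR, GeneCards, Gene-NCBI)
   are SUPPORTED.  POSSIBLE codes do not count unless explicitly enabled.
4. Otherwise the pair is UNCERTAIN and proceeds to the literature stage.

``run_pipeline`` orchestrates the full procedure: uncertain pairs are handed
to a triage provider (abstract classification + study extraction), their
study sets adjudicated by the two-fold risk rule, and finally an explicit
override map — standing in for the group consensus meeting — is applied.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

from .adjudication import AdjudicationCriteria, PenetranceStudy, adjudicate
from .evidence import (
    CODE_FIELDS,
    MINOR_RESOURCES,
    DiseaseRecord,
    EvidenceCode,
    EvidenceRow,
    GeneRecord,
    combine_clingen,
)
from .outcomes import ClassificationOutcome, VerificationRoute, VerificationStatus

__all__ = [
    "EngineConfig",
    "classify_association",
    "classify_matrix",
    "run_pipeline",
    "truth_table",
    "TriageProvider",
]

#: Callable that supplies, for an uncertain pair, the penetrance studies that
#: survived abstract triage (possibly none).
TriageProvider = Callable[[GeneRecord, DiseaseRecord], Sequence[PenetranceStudy]]


@dataclass(frozen=True)
class EngineConfig:
    minor_resource_threshold: int = 3
    minor_resources: tuple[str, ...] = MINOR_RESOURCES
    count_possible_as_support: bool = False

    def __post_init__(self) -> None:
        if not self.minor_resources:
            raise ValueError("minor_resources must be non-empty")
        unknown = set(self.minor_resources) - set(CODE_FIELDS)
        if unknown:
            raise ValueError(f"unknown resource fields: {sorted(unknown)}")
        if not 1 <= self.minor_resource_threshold <= len(self.minor_resources):
            raise ValueError(
                "minor_resource_threshold must lie between 1 and the number of "
                f"minor resources ({len(self.minor_resources)})"
            )
        object.__setattr__(self, "minor_resources", tuple(self.minor_resources))


def classify_association(
    row: EvidenceRow, config: EngineConfig = EngineConfig()
) -> ClassificationOutcome:
    """Classify one gene-disease pair through the decision tree.

    Total and deterministic: every row maps to exactly one of
    VERIFIED (with its route), NO_ASSOCIATION, or UNCERTAIN.
    """
    clingen = combine_clingen(row.clingen_validity, row.clingen_actionability)

    if clingen is EvidenceCode.SUPPORTED or row.nccn is EvidenceCode.SUPPORTED:
        return ClassificationOutcome(
            row.gene, row.disease, VerificationStatus.VERIFIED,
            VerificationRoute.MAJOR_CLINGEN_NCCN,
        )
    if clingen is EvidenceCode.REFUTED:
        return ClassificationOutcome(
            row.gene, row.disease, VerificationStatus.NO_ASSOCIATION,
            VerificationRoute.NONE,
        )

    counted = {EvidenceCode.SUPPORTED}
    if config.count_possible_as_support:
        counted.add(EvidenceCode.POSSIBLE)
    support = sum(1 for name in config.minor_resources if getattr(row, name) in counted)
    if support >= config.minor_resource_threshold:
        return ClassificationOutcome(
            row.gene, row.disease, VerificationStatus.VERIFIED,
            VerificationRoute.MINOR_THREE_OF_FOUR,
        )
    return ClassificationOutcome(
        row.gene, row.disease, VerificationStatus.UNCERTAIN, VerificationRoute.NONE
    )


def classify_matrix(
    rows: Sequence[EvidenceRow], config: EngineConfig = EngineConfig()
) -> list[ClassificationOutcome]:
    """Classify a whole matrix, order-preserving; rows must be unique pairs."""
    seen: set[tuple[str, str]] = set()
    dups: list[tuple[str, str]] = []
    for row in rows:
        if row.key in seen:
            dups.append(row.key)
        seen.add(row.key)
    if dups:
        raise ValueError(f"duplicate (gene, disease) pairs: {sorted(set(dups))}")
    return [classify_association(row, config) for row in rows]


def run_pipeline(
    rows: Sequence[EvidenceRow],
    config: EngineConfig = EngineConfig(),
    triage_provider: TriageProvider | None = None,
    adjudication_criteria: AdjudicationCriteria = AdjudicationCriteria(),
    overrides: Mapping[tuple[str, str], VerificationStatus] | None = None,
) -> list[ClassificationOutcome]:
    """Run the full evaluation: decision tree, literature stage, overrides.

    Uncertain pairs are resolved by adjudicating the studies the triage
    provider returns (an absent provider behaves as an empty literature
    search, so uncertain pairs become NO_ASSOCIATION).  Pairs verified at
    this stage carry route LITERATURE_NLP.  Overrides — a
    ``(gene symbol, disease name) -> VerificationStatus`` map representing
    the consensus meeting — are applied last; an override to VERIFIED gets
    route MANUAL_CONSENSUS.
    """
    outcomes = classify_matrix(rows, config)
    row_by_key = {row.key: row for row in rows}

    resolved: list[ClassificationOutcome] = []
    for outcome in outcomes:
        if outcome.status is VerificationStatus.UNCERTAIN:
            studies = (
                list(triage_provider(outcome.gene, outcome.disease))
                if triage_provider is not None
                else []
            )
            verdict = adjudicate(studies, adjudication_criteria)
            route = (
                VerificationRoute.LITERATURE_NLP
                if verdict is VerificationStatus.VERIFIED
                else VerificationRoute.NONE
            )
            outcome = ClassificationOutcome(outcome.gene, outcome.disease, verdict, route)
        resolved.append(outcome)

    if overrides:
        normalized = {
            (GeneRecord(g).symbol, DiseaseRecord(d).name): status
            for (g, d), status in overrides.items()
        }
        unknown = set(normalized) - set(row_by_key)
        if unknown:
            raise ValueError(f"overrides reference unknown pairs: {sorted(unknown)}")
        final: list[ClassificationOutcome] = []
        for outcome in resolved:
            if outcome.key in normalized:
                status = normalized[outcome.key]
                route = (
                    VerificationRoute.MANUAL_CONSENSUS
                    if status is VerificationStatus.VERIFIED
                    else VerificationRoute.NONE
                )
                outcome = ClassificationOutcome(outcome.gene, outcome.disease, status, route)
            final.append(outcome)
        resolved = final
    return resolved


def truth_table(config: EngineConfig = EngineConfig()) -> pd.DataFrame:
    """Enumerate the engine over all 4^7 code combinations.

    Returns a DataFrame with one row per combination of the seven code
    fields plus the resulting ``status`` and ``route``.  Used as a testing
    surface: an independently written rule table can be compared against the
    full enumeration.
    """
    gene = GeneRecord("GENE")
    disease = DiseaseRecord("disease")
    records = []
    for combo in itertools.product(list(EvidenceCode), repeat=len(CODE_FIELDS)):
        row = EvidenceRow(gene, disease, **dict(zip(CODE_FIELDS, combo)))
        outcome = classify_association(row, config)
        records.append(
            {
                **{name: code.name for name, code in zip(CODE_FIELDS, combo)},
                "status": outcome.status.value,
                "route": outcome.route.value,
            }
        )
    return pd.DataFrame.from_records(records)
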