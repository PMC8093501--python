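"""Shared outcome vocabulary for the verification pipeline."""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .evidence import DiseaseRecord, GeneRecord

__all__ = ["VerificationStatus", "VerificationRoute", "ClassificationOutcome"]


class VerificationStatus(enum.Enum):
    VERIFIED = "VERIFIED"
    NO_ASSOCIATION = "NO_ASSOCIATION"
    UNCERTAIN = "UNCERTAIN"


class VerificationRoute(enum.Enum):
    """Which branch of the decision tree established (or failed) a pair."""

    MAJOR_CLINGEN_NCCN = "MAJOR_CLINGEN_NCCN"
    MINOR_THREE_OF_FOUR = "MINOR_THREE_OF_FOUR"
    LITERATURE_NLP = "LITERATURE_NLP"
    MANUAL_CONSENSUS = "MANUAL_CONSENSUS"
    NONE = "NONE"


_VERIFIED_ROUTES = frozenset(
    {
        VerificationRoute.MAJOR_CLINGEN_NCCN,
        VerificationRoute.MINOR_THREE_OF_FOUR,
        VerificationRoute.LITERATURE_NLP,
        VerificationRoute.MANUAL_CONSENSUS,
    }
)


@dataclass(frozen=True)
class ClassificationOutcome:
    """Verdict for one gene-disease pair plus the route that produced it.

    A VERIFIED outcome always carries one of the four verification routes;
    NO_ASSOCIATION and UNCERTAIN always carry route NONE.
    """

    gene: GeneRecord
    disease: DiseaseRecord
    status: VerificationStatus
    route: VerificationRoute

    def __post_init__(self) -> None:
        verified = self.status is VerificationStatus.VERIFIED
        routed = self.route in _VERIFIED_ROUTES
        if verified != routed:
            raise ValueError(
                f"inconsistent outcome for {self.gene.symbol}/{self.disease.name}: "
                f"status={self.status.value} with route={self.route.value}"
            )

    @property
    def key(self) -> tuple[str, str]:
        return (self.gene.symbol, self.disease.name)
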