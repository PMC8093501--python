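"""Penetrance-study adjudication: the two-fold, statistically-significant rule.

Uncertain gene-disease associations are resolved from the literature.  Each
candidate penetrance study carries a ratio-scale effect estimate (OR, RR, HR
or SIR) with a confidence interval and/or a p-value, plus quality metadata
(design, carrier count, ascertainment).  An association is accepted when at
least one high-quality study reports at least a two-fold increased risk that
is statistically significant.

Significance convention: when a confidence interval is reported, it decides —
the lower bound must exceed 1 (strictly); a p-value below alpha is used only
when no interval is available.  Protective effects (point estimate < 1) never
satisfy the rule.  Cumulative-risk-only studies carry no ratio estimate and
are not adjudicable; they are routed to the manual-override hook instead.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .evidence import normalize_disease_name
from .outcomes import VerificationStatus

__all__ = [
    "EffectType",
    "StudyDesign",
    "PenetranceStudy",
    "AdjudicationCriteria",
    "is_high_quality",
    "is_significant",
    "meets_risk_rule",
    "adjudicate",
    "read_studies_json",
    "read_studies_csv",
]


class EffectType(enum.Enum):
    OR = "OR"
    RR = "RR"
    HR = "HR"
    SIR = "SIR"


class StudyDesign(enum.Enum):
    CASE_CONTROL = "CASE_CONTROL"
    COHORT = "COHORT"
    FAMILY_BASED = "FAMILY_BASED"
    GWAS = "GWAS"
    OTHER = "OTHER"


@dataclass(frozen=True)
class PenetranceStudy:
    """One literature effect estimate for a gene-disease pair."""

    study_id: str
    gene: str
    disease: str
    effect_type: EffectType
    point_estimate: float
    ci_low: float | None = None
    ci_high: float | None = None
    p_value: float | None = None
    n_carriers: int | None = None
    design: StudyDesign = StudyDesign.OTHER
    ascertainment_note: str = ""

    def __post_init__(self) -> None:
        if not self.study_id:
            raise ValueError("study_id must be non-empty")
        if self.point_estimate <= 0:
            raise ValueError(
                f"{self.study_id}: ratio-scale point estimate must be positive"
            )
        if (self.ci_low is None) != (self.ci_high is None):
            raise ValueError(f"{self.study_id}: confidence interval must have both bounds")
        if self.ci_low is not None:
            if self.ci_low <= 0:
                raise ValueError(f"{self.study_id}: CI bounds must be positive")
            if not (self.ci_low <= self.point_estimate <= self.ci_high):
                raise ValueError(
                    f"{self.study_id}: CI ({self.ci_low}, {self.ci_high}) does not "
                    f"bracket the point estimate {self.point_estimate}"
                )
        if self.p_value is not None and not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"{self.study_id}: p-value must lie in [0, 1]")
        if self.n_carriers is not None and self.n_carriers < 0:
            raise ValueError(f"{self.study_id}: carrier count must be non-negative")
        object.__setattr__(self, "gene", self.gene.strip().upper())
        object.__setattr__(self, "disease", normalize_disease_name(self.disease))

    @property
    def has_ci(self) -> bool:
        return self.ci_low is not None

    @property
    def is_adjudicable(self) -> bool:
        """A study is adjudicable when it carries a CI or a p-value."""
        return self.has_ci or self.p_value is not None


@dataclass(frozen=True)
class AdjudicationCriteria:
    """Thresholds for quality screening and the risk rule.

    ``fold_threshold`` and ``alpha`` encode the "at least two-fold increased
    risk that was statistically significant" rule; the quality thresholds
    (design whitelist, minimum carrier count, number of passing studies
    required) parameterize the consensus group's study screening.
    """

    fold_threshold: float = 2.0
    alpha: float = 0.05
    min_carriers: int = 10
    allowed_designs: frozenset[StudyDesign] = frozenset(
        {
            StudyDesign.CASE_CONTROL,
            StudyDesign.COHORT,
            StudyDesign.FAMILY_BASED,
            StudyDesign.GWAS,
        }
    )
    min_passing_studies: int = 1

    def __post_init__(self) -> None:
        if self.fold_threshold <= 1:
            raise ValueError("fold_threshold must exceed 1")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie strictly between 0 and 1")
        if self.min_carriers < 0:
            raise ValueError("min_carriers must be non-negative")
        if self.min_passing_studies < 1:
            raise ValueError("min_passing_studies must be at least 1")
        object.__setattr__(self, "allowed_designs", frozenset(self.allowed_designs))


def is_high_quality(
    study: PenetranceStudy, criteria: AdjudicationCriteria = AdjudicationCriteria()
) -> bool:
    """Quality screen: allowed design and, when reported, enough carriers.

    A missing carrier count does not fail the screen — many otherwise sound
    studies do not report it — but a reported count below ``min_carriers``
    does.
    """
    if study.design not in criteria.allowed_designs:
        return False
    if study.n_carriers is not None and study.n_carriers < criteria.min_carriers:
        return False
    return True


def is_significant(study: PenetranceStudy, alpha: float = 0.05) -> bool:
    """Statistical significance of an increased risk.

    CI takes precedence: significant iff the lower bound strictly exceeds 1.
    Without a CI, significant iff p < alpha.  A study with neither is not
    adjudicable.
    """
    if study.has_ci:
        return study.ci_low > 1.0
    if study.p_value is not None:
        return study.p_value < alpha
    raise ValueError(
        f"{study.study_id}: not adjudicable — neither a confidence interval "
        "nor a p-value is reported"
    )


def meets_risk_rule(
    study: PenetranceStudy, criteria: AdjudicationCriteria = AdjudicationCriteria()
) -> bool:
    """True iff the study reports at least a ``fold_threshold``-fold increased
    risk that is statistically significant."""
    return study.point_estimate >= criteria.fold_threshold and is_significant(
        study, criteria.alpha
    )


def adjudicate(
    studies: Sequence[PenetranceStudy],
    criteria: AdjudicationCriteria = AdjudicationCriteria(),
) -> VerificationStatus:
    """Resolve one uncertain association from its triaged study set.

    No studies at all means the literature search came up empty: the
    association is designated NO_ASSOCIATION.  If at least
    ``min_passing_studies`` studies are high-quality and meet the risk rule,
    the association is VERIFIED.  Otherwise (studies exist but none passes)
    it remains UNCERTAIN, awaiting consensus/override.
    """
    if not studies:
        return VerificationStatus.NO_ASSOCIATION
    pairs = {(s.gene, s.disease) for s in studies}
    if len(pairs) > 1:
        raise ValueError(
            f"adjudicate expects studies for a single gene-disease pair, got {sorted(pairs)}"
        )
    passing = sum(
        1
        for s in studies
        if s.is_adjudicable and is_high_quality(s, criteria) and meets_risk_rule(s, criteria)
    )
    if passing >= criteria.min_passing_studies:
        return VerificationStatus.VERIFIED
    return VerificationStatus.UNCERTAIN


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_FIELDS = (
    "study_id",
    "gene",
    "disease",
    "effect_type",
    "point_estimate",
    "ci_low",
    "ci_high",
    "p_value",
    "n_carriers",
    "design",
    "ascertainment_note",
)


def _study_from_mapping(record: dict) -> PenetranceStudy:
    def opt_float(x):
        return None if x is None or x == "" or pd.isna(x) else float(x)

    def opt_int(x):
        return None if x is None or x == "" or pd.isna(x) else int(x)

    return PenetranceStudy(
        study_id=str(record["study_id"]),
        gene=str(record["gene"]),
        disease=str(record["disease"]),
        effect_type=EffectType(str(record["effect_type"]).upper()),
        point_estimate=float(record["point_estimate"]),
        ci_low=opt_float(record.get("ci_low")),
        ci_high=opt_float(record.get("ci_high")),
        p_value=opt_float(record.get("p_value")),
        n_carriers=opt_int(record.get("n_carriers")),
        design=StudyDesign(str(record.get("design", "OTHER")).upper()),
        ascertainment_note=str(record.get("ascertainment_note", "") or ""),
    )


def read_studies_json(path: str | Path) -> list[PenetranceStudy]:
    """Read penetrance studies from a JSON list of objects."""
    with open(path, encoding="utf-8") as handle:
        data = json.load(handle)
    return [_study_from_mapping(record) for record in data]


def read_studies_csv(path: str | Path) -> list[PenetranceStudy]:
    """Read penetrance studies from CSV with the standard columns."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = {"study_id", "gene", "disease", "effect_type", "point_estimate"} - set(
        frame.columns
    )
    if missing:
        raise ValueError(f"study table {path} missing columns: {sorted(missing)}")
    return [_study_from_mapping(dict(row)) for _, row in frame.iterrows()]
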