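"""Summary artifacts: disease spectra, resource-support counts, accounting.

Aggregates classification outcomes into the study's summary shapes — a
per-gene disease-spectrum table (three category columns: malignant, benign,
borderline), per-gene counts of supporting resources for a chosen disease,
and the route accounting (how many associations each verification route
established).  Also loads the packaged fixtures transcribing the published
tables and provides the gene-selection rule that defines the 12-gene panel.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .adjudication import PenetranceStudy, read_studies_json
from .evidence import (
    ClinGenValidityCategory,
    DiseaseCategory,
    DiseaseRecord,
    EvidenceCode,
    EvidenceRow,
    GeneRecord,
    NCCNCategory,
    code_clingen_validity,
    combine_clingen,
    normalize_disease_name,
)
from .outcomes import ClassificationOutcome, VerificationRoute, VerificationStatus

__all__ = [
    "SpectrumTable",
    "SummaryCounts",
    "Table1Row",
    "build_spectrum",
    "summarize",
    "integer_percent",
    "resource_support_counts",
    "select_bcsg",
    "table1_to_evidence_rows",
    "FixtureName",
    "load_fixture",
]


def integer_percent(numerator: int, denominator: int) -> int:
    """Integer percent by truncation: 78/86 -> 90.

    Truncation (not rounding) matches how the study's headline shares are
    printed.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return (100 * numerator) // denominator


_CATEGORY_ORDER = (
    DiseaseCategory.MALIGNANT,
    DiseaseCategory.BENIGN,
    DiseaseCategory.BORDERLINE,
)


@dataclass(frozen=True)
class SpectrumTable:
    """Per-gene disease lists by category, each entry with its route.

    ``entries`` maps gene symbol -> category -> alphabetically sorted list
    of (normalized disease name, verification route).
    """

    entries: Mapping[str, Mapping[DiseaseCategory, tuple[tuple[str, VerificationRoute], ...]]]

    @property
    def genes(self) -> list[str]:
        return sorted(self.entries)

    def pairs(self) -> list[tuple[str, str]]:
        return [
            (gene, name)
            for gene in self.genes
            for category in _CATEGORY_ORDER
            for name, _ in self.entries[gene].get(category, ())
        ]

    def to_frame(self) -> pd.DataFrame:
        """Flat frame with columns gene, disease, category, route, in the
        diff-stable sort order (gene, category, disease)."""
        records = [
            {
                "gene": gene,
                "disease": name,
                "category": category.value,
                "route": route.value,
            }
            for gene in self.genes
            for category in _CATEGORY_ORDER
            for name, route in self.entries[gene].get(category, ())
        ]
        return pd.DataFrame.from_records(
            records, columns=["gene", "disease", "category", "route"]
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            gene: {
                category.value: [[name, route.value] for name, route in items]
                for category, items in by_cat.items()
            }
            for gene, by_cat in self.entries.items()
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "SpectrumTable":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        entries = {
            gene: {
                DiseaseCategory(category): tuple(
                    (name, VerificationRoute(route)) for name, route in items
                )
                for category, items in by_cat.items()
            }
            for gene, by_cat in payload.items()
        }
        return cls(entries)


def build_spectrum(
    outcomes: Sequence[ClassificationOutcome],
    categories: Mapping[str, DiseaseCategory] | None = None,
) -> SpectrumTable:
    """Build the per-gene disease spectrum from VERIFIED outcomes only.

    Categories come from each outcome's disease record unless an explicit
    ``categories`` map (normalized disease name -> category) is given, in
    which case every verified disease must be covered by it.
    """
    normalized_categories = (
        {normalize_disease_name(k): v for k, v in categories.items()}
        if categories is not None
        else None
    )
    grouped: dict[str, dict[DiseaseCategory, list[tuple[str, VerificationRoute]]]] = {}
    seen: set[tuple[str, str]] = set()
    for outcome in outcomes:
        if outcome.status is not VerificationStatus.VERIFIED:
            continue
        if outcome.key in seen:
            raise ValueError(f"duplicate verified pair {outcome.key}")
        seen.add(outcome.key)
        if normalized_categories is not None:
            try:
                category = normalized_categories[outcome.disease.name]
            except KeyError:
                raise ValueError(
                    f"verified disease {outcome.disease.name!r} has no category"
                ) from None
        else:
            category = outcome.disease.category
        grouped.setdefault(outcome.gene.symbol, {}).setdefault(category, []).append(
            (outcome.disease.name, outcome.route)
        )
    entries = {
        gene: {
            category: tuple(sorted(items))
            for category, items in by_cat.items()
        }
        for gene, by_cat in grouped.items()
    }
    return SpectrumTable(entries)


@dataclass(frozen=True)
class SummaryCounts:
    """Route accounting over a set of classification outcomes."""

    total_verified: int
    by_route: Mapping[VerificationRoute, int]
    unique_diseases: int
    per_gene_counts: Mapping[str, int]

    def __post_init__(self) -> None:
        if sum(self.by_route.values()) != self.total_verified:
            raise ValueError("by_route must sum to total_verified")
        if sum(self.per_gene_counts.values()) != self.total_verified:
            raise ValueError("per_gene_counts must sum to total_verified")

    def route_percent(self, route: VerificationRoute) -> int:
        """Share of verified associations on a route, as integer percent."""
        return integer_percent(self.by_route.get(route, 0), self.total_verified)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "total_verified": self.total_verified,
            "by_route": {r.value: n for r, n in self.by_route.items()},
            "unique_diseases": self.unique_diseases,
            "per_gene_counts": dict(sorted(self.per_gene_counts.items())),
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "SummaryCounts":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            total_verified=payload["total_verified"],
            by_route={VerificationRoute(r): n for r, n in payload["by_route"].items()},
            unique_diseases=payload["unique_diseases"],
            per_gene_counts=payload["per_gene_counts"],
        )


def summarize(outcomes: Sequence[ClassificationOutcome]) -> SummaryCounts:
    """Count verified associations by route, gene, and unique disease name."""
    by_route: dict[VerificationRoute, int] = {}
    per_gene: dict[str, int] = {}
    diseases: set[str] = set()
    total = 0
    for outcome in outcomes:
        if outcome.status is not VerificationStatus.VERIFIED:
            continue
        total += 1
        by_route[outcome.route] = by_route.get(outcome.route, 0) + 1
        per_gene[outcome.gene.symbol] = per_gene.get(outcome.gene.symbol, 0) + 1
        diseases.add(outcome.disease.name)
    return SummaryCounts(
        total_verified=total,
        by_route=by_route,
        unique_diseases=len(diseases),
        per_gene_counts=per_gene,
    )


def resource_support_counts(
    matrix: Sequence[EvidenceRow], disease: str
) -> dict[str, int]:
    """Per-gene count of supporting resources (out of six) for one disease.

    The two ClinGen sub-codes are combined into a single ClinGen resource;
    the six counted resources are ClinGen, NCCN, OMIM, GHR, GeneCards and
    Gene-NCBI.
    """
    name = normalize_disease_name(disease)
    rows = [row for row in matrix if row.disease.name == name]
    if not rows:
        raise ValueError(f"disease {disease!r} not present in the matrix")
    counts: dict[str, int] = {}
    for row in rows:
        n = 0
        if combine_clingen(row.clingen_validity, row.clingen_actionability) is EvidenceCode.SUPPORTED:
            n += 1
        for resource in ("nccn", "omim", "ghr", "genecards", "gene_ncbi"):
            if getattr(row, resource) is EvidenceCode.SUPPORTED:
                n += 1
        counts[row.gene.symbol] = n
    return counts


@dataclass(frozen=True)
class Table1Row:
    """One gene's breast-cancer evidence across the six resources."""

    gene: str
    clingen_category: ClinGenValidityCategory | None
    nccn_category: NCCNCategory | None
    omim: bool
    ghr: bool
    genecards: bool
    gene_ncbi: bool


_BCSG_CLINGEN = {
    ClinGenValidityCategory.DEFINITIVE,
    ClinGenValidityCategory.STRONG,
    ClinGenValidityCategory.MODERATE,
}
_BCSG_NCCN = {NCCNCategory.VERY_STRONG, NCCNCategory.STRONG}


def select_bcsg(rows: Sequence[Table1Row]) -> list[str]:
    """Gene-panel inclusion rule: ClinGen Definitive/Strong/Moderate for
    breast cancer, or NCCN Very strong/Strong."""
    return [
        row.gene
        for row in rows
        if (row.clingen_category in _BCSG_CLINGEN)
        or (row.nccn_category in _BCSG_NCCN)
    ]


def table1_to_evidence_rows(
    rows: Sequence[Table1Row], disease: str = "Breast Cancer"
) -> list[EvidenceRow]:
    """Convert per-gene resource evidence into coded evidence rows.

    ClinGen categories pass through the validity coding rule; NCCN Very
    strong/Strong code as SUPPORTED and Limited as POSSIBLE; minor resources
    code by presence.
    """
    nccn_map = {
        NCCNCategory.VERY_STRONG: EvidenceCode.SUPPORTED,
        NCCNCategory.STRONG: EvidenceCode.SUPPORTED,
        NCCNCategory.LIMITED: EvidenceCode.POSSIBLE,
        None: EvidenceCode.NOT_LISTED,
    }
    record = DiseaseRecord(disease, DiseaseCategory.MALIGNANT)
    out = []
    for row in rows:
        out.append(
            EvidenceRow(
                gene=GeneRecord(row.gene),
                disease=record,
                clingen_validity=(
                    code_clingen_validity(row.clingen_category)
                    if row.clingen_category is not None
                    else EvidenceCode.NOT_LISTED
                ),
                clingen_actionability=EvidenceCode.NOT_LISTED,
                nccn=nccn_map[row.nccn_category],
                omim=EvidenceCode.SUPPORTED if row.omim else EvidenceCode.NOT_LISTED,
                ghr=EvidenceCode.SUPPORTED if row.ghr else EvidenceCode.NOT_LISTED,
                genecards=EvidenceCode.SUPPORTED if row.genecards else EvidenceCode.NOT_LISTED,
                gene_ncbi=EvidenceCode.SUPPORTED if row.gene_ncbi else EvidenceCode.NOT_LISTED,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------

class FixtureName(enum.Enum):
    TABLE1_BREAST = "table1_breast"
    TABLE2_SPECTRUM = "table2_spectrum"
    ADJUDICATION_EXAMPLES = "adjudication_examples"


def _fixture_path(filename: str) -> Path:
    return Path(resources.files("genespectrum.fixtures") / filename)


def load_fixture(
    name: FixtureName | str,
) -> list[Table1Row] | list[ClassificationOutcome] | list[PenetranceStudy]:
    """Load and validate a packaged fixture.

    * ``table1_breast`` -> list of :class:`Table1Row` (12 genes);
    * ``table2_spectrum`` -> list of VERIFIED :class:`ClassificationOutcome`
      (86 route-annotated pairs);
    * ``adjudication_examples`` -> list of :class:`PenetranceStudy`.
    """
    name = FixtureName(name) if not isinstance(name, FixtureName) else name

    if name is FixtureName.TABLE1_BREAST:
        frame = pd.read_csv(
            _fixture_path("table1_breast.tsv"), sep="\t", dtype=str, keep_default_na=False
        )
        rows = [
            Table1Row(
                gene=rec.gene,
                clingen_category=(
                    ClinGenValidityCategory.parse(rec.clingen_category)
                    if rec.clingen_category
                    else None
                ),
                nccn_category=(
                    NCCNCategory.parse(rec.nccn_category) if rec.nccn_category else None
                ),
                omim=rec.omim == "1",
                ghr=rec.ghr == "1",
                genecards=rec.genecards == "1",
                gene_ncbi=rec.gene_ncbi == "1",
            )
            for rec in frame.itertuples(index=False)
        ]
        symbols = [r.gene for r in rows]
        if len(set(symbols)) != len(symbols):
            raise ValueError("table1_breast fixture has duplicate genes")
        return rows

    if name is FixtureName.TABLE2_SPECTRUM:
        frame = pd.read_csv(
            _fixture_path("table2_spectrum.tsv"), sep="\t", dtype=str, keep_default_na=False
        )
        outcomes = [
            ClassificationOutcome(
                gene=GeneRecord(rec.gene),
                disease=DiseaseRecord(rec.disease, DiseaseCategory.parse(rec.category)),
                status=VerificationStatus.VERIFIED,
                route=VerificationRoute(rec.route),
            )
            for rec in frame.itertuples(index=False)
        ]
        keys = [o.key for o in outcomes]
        if len(set(keys)) != len(keys):
            raise ValueError("table2_spectrum fixture has duplicate pairs")
        return outcomes

    if name is FixtureName.ADJUDICATION_EXAMPLES:
        return read_studies_json(_fixture_path("adjudication_examples.json"))

    raise ValueError(f"unknown fixture {name!r}")  # pragma: no cover
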