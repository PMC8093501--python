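"""Evidence model: genes, diseases, and per-resource evidence codes.

Gene-disease associations are curated across six genetic resources — ClinGen
(gene-disease validity and actionability, treated as two sub-codes of one
major resource), the NCCN guidelines, and four "minor" resources (OMIM,
Genetics Home Reference, GeneCards, Gene-NCBI).  Each resource's content is
reduced to a four-valued evidence code:

* ``SUPPORTED`` — the resource reports the association as definitive ('1'),
* ``POSSIBLE`` — the resource suggests a possible relationship ('9'),
* ``REFUTED`` — a report exists and refutes/disputes the association or
  finds no evidence for it ('0'),
* ``NOT_LISTED`` — the resource has no record at all (blank cell).

``NOT_LISTED`` and ``REFUTED`` are deliberately distinct states: only an
explicit refutation short-circuits downstream evaluation, whereas mere
absence leaves an association rescuable by other resources or by the
literature.

The module also provides the per-resource coding rules that turn extracted
resource content (ClinGen validity categories, actionability/NCCN report
flags, simple presence) into codes, disease-name normalization, and TSV I/O
for the coded evidence matrix.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "EvidenceCode",
    "ClinGenValidityCategory",
    "NCCNCategory",
    "DiseaseCategory",
    "GeneRecord",
    "DiseaseRecord",
    "EvidenceRow",
    "CODE_FIELDS",
    "MINOR_RESOURCES",
    "code_clingen_validity",
    "code_clingen_actionability",
    "code_nccn",
    "code_presence",
    "combine_clingen",
    "normalize_disease_name",
    "read_synonym_table",
    "read_evidence_matrix",
    "write_evidence_matrix",
    "MATRIX_COLUMNS",
]


class EvidenceCode(enum.Enum):
    """Four-valued evidence code; serializes to '1' / '9' / '0' / blank."""

    SUPPORTED = "1"
    POSSIBLE = "9"
    REFUTED = "0"
    NOT_LISTED = ""

    @classmethod
    def from_cell(cls, cell: str) -> "EvidenceCode":
        """Parse a matrix cell; whitespace-only cells mean NOT_LISTED."""
        cell = (cell or "").strip()
        try:
            return cls(cell)
        except ValueError:
            raise ValueError(
                f"invalid evidence code cell {cell!r}: expected '1', '9', '0' or blank"
            ) from None

    def to_cell(self) -> str:
        return self.value


class ClinGenValidityCategory(enum.Enum):
    """ClinGen gene-disease validity strength categories (closed set)."""

    DEFINITIVE = "Definitive"
    STRONG = "Strong"
    MODERATE = "Moderate"
    LIMITED = "Limited"
    REFUTED = "Refuted"
    DISPUTED = "Disputed"
    NO_REPORTED_EVIDENCE = "No Reported Evidence"

    @classmethod
    def parse(cls, label: str) -> "ClinGenValidityCategory":
        normalized = " ".join(str(label).split()).casefold()
        for member in cls:
            if member.value.casefold() == normalized:
                return member
        raise ValueError(
            f"unknown ClinGen validity category {label!r}; expected one of "
            f"{[m.value for m in cls]}"
        )


class NCCNCategory(enum.Enum):
    """NCCN breast-cancer risk strength categories used for gene selection."""

    VERY_STRONG = "Very strong"
    STRONG = "Strong"
    LIMITED = "Limited"

    @classmethod
    def parse(cls, label: str) -> "NCCNCategory":
        normalized = " ".join(str(label).split()).casefold()
        for member in cls:
            if member.value.casefold() == normalized:
                return member
        raise ValueError(
            f"unknown NCCN category {label!r}; expected one of {[m.value for m in cls]}"
        )


class DiseaseCategory(enum.Enum):
    """Tumor/condition category used to lay out the disease spectrum."""

    MALIGNANT = "MALIGNANT"
    BENIGN = "BENIGN"
    BORDERLINE = "BORDERLINE"

    @classmethod
    def parse(cls, label: str) -> "DiseaseCategory":
        try:
            return cls(str(label).strip().upper())
        except ValueError:
            raise ValueError(
                f"unknown disease category {label!r}; expected MALIGNANT, BENIGN or BORDERLINE"
            ) from None


# keep hyphens (cafe-au-lait) and alphanumerics; everything else becomes a space
_PUNCT_RE = re.compile(r"[^0-9a-z\- ]+")


def normalize_disease_name(
    name: str, synonyms: Mapping[str, str] | None = None
) -> str:
    """Normalize a disease label: case-fold, strip punctuation, collapse
    whitespace, then apply an optional synonym table.

    Synonym keys and values are themselves normalized before lookup, so the
    operation is idempotent.  Trailing "cancer"/"carcinoma" is stripped only
    when the synonym table maps the full label (the bare normalization never
    drops it, keeping e.g. benign "thyroid" distinct from "thyroid cancer").
    """

    def base(s: str) -> str:
        s = s.casefold().strip()
        s = _PUNCT_RE.sub(" ", s)
        s = re.sub(r"-{2,}", "-", s)
        return " ".join(s.split())

    out = base(name)
    if synonyms:
        table = {base(k): base(v) for k, v in synonyms.items()}
        seen = {out}
        while out in table:  # follow chains, but never loop
            out = table[out]
            if out in seen:
                break
            seen.add(out)
    return out


def read_synonym_table(path: str | Path) -> dict[str, str]:
    """Read a ``term,canonical`` CSV into a synonym mapping."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = {"term", "canonical"} - set(frame.columns)
    if missing:
        raise ValueError(f"synonym table {path} missing columns: {sorted(missing)}")
    return dict(zip(frame["term"], frame["canonical"]))


@dataclass(frozen=True)
class GeneRecord:
    """A gene identified by its (uppercase, HGNC-style) symbol."""

    symbol: str
    synonyms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        symbol = self.symbol.strip().upper()
        if not symbol:
            raise ValueError("gene symbol must be non-empty")
        object.__setattr__(self, "symbol", symbol)
        object.__setattr__(self, "synonyms", tuple(self.synonyms))


@dataclass(frozen=True)
class DiseaseRecord:
    """A disease with a normalized name and a spectrum category."""

    name: str
    category: DiseaseCategory = DiseaseCategory.MALIGNANT
    synonyms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        normalized = normalize_disease_name(self.name)
        if not normalized:
            raise ValueError(f"disease name {self.name!r} normalizes to empty")
        object.__setattr__(self, "name", normalized)
        object.__setattr__(self, "synonyms", tuple(self.synonyms))


#: EvidenceRow attribute names of the seven per-resource code fields, in
#: matrix column order.
CODE_FIELDS: tuple[str, ...] = (
    "clingen_validity",
    "clingen_actionability",
    "nccn",
    "omim",
    "ghr",
    "genecards",
    "gene_ncbi",
)

#: The four resources eligible for the >=3-of-4 rescue rule.
MINOR_RESOURCES: tuple[str, ...] = ("omim", "ghr", "genecards", "gene_ncbi")


@dataclass(frozen=True)
class EvidenceRow:
    """One gene-disease pair with its seven per-resource evidence codes.

    Every code field is always populated; ``NOT_LISTED`` is the default and
    stands for "no record exists in that resource".
    """

    gene: GeneRecord
    disease: DiseaseRecord
    clingen_validity: EvidenceCode = EvidenceCode.NOT_LISTED
    clingen_actionability: EvidenceCode = EvidenceCode.NOT_LISTED
    nccn: EvidenceCode = EvidenceCode.NOT_LISTED
    omim: EvidenceCode = EvidenceCode.NOT_LISTED
    ghr: EvidenceCode = EvidenceCode.NOT_LISTED
    genecards: EvidenceCode = EvidenceCode.NOT_LISTED
    gene_ncbi: EvidenceCode = EvidenceCode.NOT_LISTED

    def __post_init__(self) -> None:
        for name in CODE_FIELDS:
            if not isinstance(getattr(self, name), EvidenceCode):
                raise TypeError(f"{name} must be an EvidenceCode")

    @property
    def key(self) -> tuple[str, str]:
        return (self.gene.symbol, self.disease.name)

    def codes(self) -> tuple[EvidenceCode, ...]:
        return tuple(getattr(self, name) for name in CODE_FIELDS)


# ---------------------------------------------------------------------------
# Per-resource coding rules
# ---------------------------------------------------------------------------

_VALIDITY_CODE = {
    ClinGenValidityCategory.DEFINITIVE: EvidenceCode.SUPPORTED,
    ClinGenValidityCategory.STRONG: EvidenceCode.SUPPORTED,
    ClinGenValidityCategory.MODERATE: EvidenceCode.SUPPORTED,
    ClinGenValidityCategory.LIMITED: EvidenceCode.POSSIBLE,
    ClinGenValidityCategory.REFUTED: EvidenceCode.REFUTED,
    ClinGenValidityCategory.DISPUTED: EvidenceCode.REFUTED,
    ClinGenValidityCategory.NO_REPORTED_EVIDENCE: EvidenceCode.REFUTED,
}


def code_clingen_validity(
    category: ClinGenValidityCategory | str,
) -> EvidenceCode:
    """Code a ClinGen gene-disease validity category.

    Definitive/Strong/Moderate -> SUPPORTED; Limited -> POSSIBLE;
    Refuted/Disputed/No Reported Evidence -> REFUTED.  A gene-disease pair
    with no ClinGen validity record at all is NOT_LISTED and never passes
    through this function.
    """
    if isinstance(category, str):
        category = ClinGenValidityCategory.parse(category)
    return _VALIDITY_CODE[category]


def code_clingen_actionability(
    is_manifestation: bool,
    management_recommended: bool,
    in_penetrance_section: bool,
    possible_relationship: bool,
) -> EvidenceCode:
    """Code a ClinGen actionability report.

    SUPPORTED if the disease is a manifestation of the disorder, if its
    management (screening/prevention) is recommended, or if it is verified in
    the report's penetrance section; POSSIBLE if the report only suggests a
    possible relationship; otherwise NOT_LISTED.
    """
    if is_manifestation or management_recommended or in_penetrance_section:
        return EvidenceCode.SUPPORTED
    if possible_relationship:
        return EvidenceCode.POSSIBLE
    return EvidenceCode.NOT_LISTED


def code_nccn(
    testing_criterion: bool,
    management_recommended: bool,
    possible_relationship: bool,
) -> EvidenceCode:
    """Code an NCCN guideline entry.

    SUPPORTED if the disease is a genetic-testing criterion or its management
    is recommended for carriers; POSSIBLE for a suggested relationship;
    otherwise NOT_LISTED.
    """
    if testing_criterion or management_recommended:
        return EvidenceCode.SUPPORTED
    if possible_relationship:
        return EvidenceCode.POSSIBLE
    return EvidenceCode.NOT_LISTED


def code_presence(present: bool) -> EvidenceCode:
    """Code a minor resource (OMIM/GHR/GeneCards/Gene-NCBI) by presence."""
    return EvidenceCode.SUPPORTED if present else EvidenceCode.NOT_LISTED


def combine_clingen(
    validity: EvidenceCode, actionability: EvidenceCode
) -> EvidenceCode:
    """Merge the two ClinGen sub-codes into a single ClinGen status.

    Precedence: support from either sub-code wins; otherwise an explicit
    validity refutation wins; otherwise a possible relationship from either;
    otherwise not listed.  Actionability reports never refute (the
    actionability coding rule cannot produce REFUTED), so only the validity
    sub-code can drive the no-association branch.
    """
    if EvidenceCode.SUPPORTED in (validity, actionability):
        return EvidenceCode.SUPPORTED
    if validity is EvidenceCode.REFUTED:
        return EvidenceCode.REFUTED
    if EvidenceCode.POSSIBLE in (validity, actionability):
        return EvidenceCode.POSSIBLE
    return EvidenceCode.NOT_LISTED


# ---------------------------------------------------------------------------
# Matrix I/O
# ---------------------------------------------------------------------------

MATRIX_COLUMNS: tuple[str, ...] = (
    "gene",
    "disease",
    "category",
    "clingen_validity",
    "clingen_actionability",
    "nccn",
    "omim",
    "ghr",
    "genecards",
    "gene_ncbi",
)


def _check_unique(rows: Sequence[EvidenceRow]) -> None:
    seen: dict[tuple[str, str], int] = {}
    dups: list[tuple[str, str]] = []
    for row in rows:
        if row.key in seen:
            dups.append(row.key)
        seen[row.key] = seen.get(row.key, 0) + 1
    if dups:
        raise ValueError(f"duplicate (gene, disease) pairs in matrix: {sorted(set(dups))}")


def read_evidence_matrix(path: str | Path) -> list[EvidenceRow]:
    """Read a coded evidence matrix from tab-delimited text.

    The expected header is ``gene  disease  category  clingen_validity
    clingen_actionability  nccn  omim  ghr  genecards  gene_ncbi``; code
    cells hold '1', '9', '0' or are empty.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(MATRIX_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"evidence matrix {path} missing columns: {sorted(missing)}")
    rows: list[EvidenceRow] = []
    for record in frame.itertuples(index=False):
        rows.append(
            EvidenceRow(
                gene=GeneRecord(record.gene),
                disease=DiseaseRecord(
                    record.disease, DiseaseCategory.parse(record.category)
                ),
                **{
                    name: EvidenceCode.from_cell(getattr(record, name))
                    for name in CODE_FIELDS
                },
            )
        )
    _check_unique(rows)
    return rows


def write_evidence_matrix(rows: Iterable[EvidenceRow], path: str | Path) -> None:
    """Write rows back to the canonical tab-delimited layout (UTF-8, LF)."""
    records = [
        {
            "gene": row.gene.symbol,
            "disease": row.disease.name,
            "category": row.disease.category.value,
            **{name: getattr(row, name).to_cell() for name in CODE_FIELDS},
        }
        for row in rows
    ]
    frame = pd.DataFrame.from_records(records, columns=list(MATRIX_COLUMNS))
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n")
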