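"""Synthetic inputs with planted ground truth for every pipeline stage.

The study's real inputs — the coded evidence matrix extracted from six
genetic resources, the labelled abstract corpus behind the triage
classifier, and the penetrance studies screened at consensus — are not
publicly deposited.  These generators emulate all three so each stage is
testable end to end:

* :func:`generate_evidence_matrix` plants verification routes (major /
  minor / literature / none) in a coded matrix shaped like the study's
  candidate set (12 genes, ~66 candidate diseases, 160 pairs by default,
  of which 78 / 4 / 4 are planted on the three verification routes and the
  remaining 74 are non-associations).
* :func:`generate_abstract_corpus` draws four balanced classes of abstracts
  with class-specific token pools and a tunable shared-vocabulary fraction.
* :func:`generate_penetrance_studies` draws effect estimates around a known
  true log-ratio with Wald intervals and p-values.

All generators are pure functions of their config (seed included):
re-running with the same config is bit-identical.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .adjudication import EffectType, PenetranceStudy, StudyDesign
from .evidence import (
    CODE_FIELDS,
    MINOR_RESOURCES,
    DiseaseCategory,
    DiseaseRecord,
    EvidenceCode,
    EvidenceRow,
    GeneRecord,
)
from .triage import AbstractRecord, TriageLabel

__all__ = [
    "PlantedRoute",
    "MatrixSimConfig",
    "CorpusSimConfig",
    "StudySimConfig",
    "generate_evidence_matrix",
    "generate_abstract_corpus",
    "generate_penetrance_studies",
]


class PlantedRoute(enum.Enum):
    """Ground-truth route planted for a generated evidence row."""

    MAJOR = "MAJOR"
    MINOR = "MINOR"
    LITERATURE = "LITERATURE"
    NONE = "NONE"


@dataclass(frozen=True)
class MatrixSimConfig:
    """Configuration for the planted-route evidence-matrix generator.

    Defaults mirror the study's printed accounting: 160 candidate pairs over
    12 genes and 66 candidate diseases, with 78 major-route, 4 minor-route,
    4 literature-route and 74 non-associations (proportions 78:4:4:74).

    ``refuted_none_fraction`` controls how non-associations are planted: a
    fraction carries an explicit ClinGen refutation (classified
    NO_ASSOCIATION by the tree alone); the remainder are merely sparse
    (<3 minor resources), which present as UNCERTAIN until the literature
    stage returns nothing.  The default 1.0 makes the pre-literature
    UNCERTAIN set coincide exactly with the planted literature rows.
    """

    n_genes: int = 12
    n_diseases: int = 66
    n_pairs: int = 160
    route_mix: Mapping[PlantedRoute, float] = field(
        default_factory=lambda: {
            PlantedRoute.MAJOR: 78 / 160,
            PlantedRoute.MINOR: 4 / 160,
            PlantedRoute.LITERATURE: 4 / 160,
            PlantedRoute.NONE: 74 / 160,
        }
    )
    possible_code_rate: float = 0.05
    refuted_none_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_diseases < 1 or self.n_pairs < 1:
            raise ValueError("counts must be positive")
        if self.n_pairs > self.n_genes * self.n_diseases:
            raise ValueError("n_pairs exceeds the gene x disease grid")
        mix = dict(self.route_mix)
        if set(mix) != set(PlantedRoute):
            raise ValueError("route_mix must cover exactly the four planted routes")
        if any(not 0 <= p <= 1 for p in mix.values()):
            raise ValueError("route_mix proportions must lie in [0, 1]")
        if abs(sum(mix.values()) - 1.0) > 1e-9:
            raise ValueError("route_mix proportions must sum to 1")
        if not 0 <= self.possible_code_rate <= 1:
            raise ValueError("possible_code_rate must lie in [0, 1]")
        if not 0 <= self.refuted_none_fraction <= 1:
            raise ValueError("refuted_none_fraction must lie in [0, 1]")
        object.__setattr__(self, "route_mix", mix)


def _largest_remainder(mix: Mapping[PlantedRoute, float], total: int) -> dict[PlantedRoute, int]:
    """Apportion ``total`` rows to routes by largest remainder."""
    quotas = {route: mix[route] * total for route in PlantedRoute}
    counts = {route: math.floor(q) for route, q in quotas.items()}
    short = total - sum(counts.values())
    order = list(PlantedRoute)  # ties go to the earlier-declared route
    by_remainder = sorted(
        order, key=lambda r: (-(quotas[r] - counts[r]), order.index(r))
    )
    for route in by_remainder[:short]:
        counts[route] += 1
    return counts


def generate_evidence_matrix(
    config: MatrixSimConfig = MatrixSimConfig(),
) -> tuple[list[EvidenceRow], list[PlantedRoute]]:
    """Generate a coded evidence matrix with planted verification routes.

    Planting rules:

    * MAJOR — one of {ClinGen validity, ClinGen actionability, NCCN} is
      SUPPORTED; minor resources are free (each supported with prob. 1/2).
    * MINOR — ClinGen and NCCN are NOT_LISTED; 3 or 4 minors SUPPORTED.
    * LITERATURE — no SUPPORTED code anywhere (the pair is UNCERTAIN until
      the literature stage verifies it).
    * NONE — ClinGen validity REFUTED (for ``refuted_none_fraction`` of the
      rows), else all-NOT_LISTED with at most 2 minors supported.

    '9' (POSSIBLE) noise is then injected into NOT_LISTED cells at
    ``possible_code_rate``; POSSIBLE never counts as support, so the noise
    cannot alter a planted route.
    """
    rng = np.random.default_rng(config.seed)
    genes = [GeneRecord(f"G{i + 1:02d}") for i in range(config.n_genes)]
    diseases = [
        DiseaseRecord(f"synthetic disease {j + 1:02d}", DiseaseCategory.MALIGNANT)
        for j in range(config.n_diseases)
    ]
    grid = [(i, j) for i in range(config.n_genes) for j in range(config.n_diseases)]
    picked = [grid[k] for k in rng.choice(len(grid), size=config.n_pairs, replace=False)]

    counts = _largest_remainder(config.route_mix, config.n_pairs)
    routes: list[PlantedRoute] = [
        route for route in PlantedRoute for _ in range(counts[route])
    ]
    rng.shuffle(routes)  # type: ignore[arg-type]

    rows: list[EvidenceRow] = []
    for (gi, dj), route in zip(picked, routes):
        codes = {name: EvidenceCode.NOT_LISTED for name in CODE_FIELDS}
        if route is PlantedRoute.MAJOR:
            anchor = rng.choice(["clingen_validity", "clingen_actionability", "nccn"])
            codes[anchor] = EvidenceCode.SUPPORTED
            for name in MINOR_RESOURCES:
                if rng.random() < 0.5:
                    codes[name] = EvidenceCode.SUPPORTED
        elif route is PlantedRoute.MINOR:
            k = int(rng.integers(3, len(MINOR_RESOURCES) + 1))
            chosen = rng.choice(len(MINOR_RESOURCES), size=k, replace=False)
            for idx in chosen:
                codes[MINOR_RESOURCES[idx]] = EvidenceCode.SUPPORTED
        elif route is PlantedRoute.NONE:
            if rng.random() < config.refuted_none_fraction:
                codes["clingen_validity"] = EvidenceCode.REFUTED
            k = int(rng.integers(0, 3))  # sub-threshold minor support
            chosen = rng.choice(len(MINOR_RESOURCES), size=k, replace=False)
            for idx in chosen:
                codes[MINOR_RESOURCES[idx]] = EvidenceCode.SUPPORTED
        # LITERATURE: leave everything NOT_LISTED

        for name in CODE_FIELDS:
            if (
                codes[name] is EvidenceCode.NOT_LISTED
                and rng.random() < config.possible_code_rate
            ):
                codes[name] = EvidenceCode.POSSIBLE
        rows.append(EvidenceRow(genes[gi], diseases[dj], **codes))
    return rows, routes


# ---------------------------------------------------------------------------
# Abstract corpus
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorpusSimConfig:
    """Configuration for the labelled synthetic abstract corpus.

    ``vocab_overlap`` is the per-token probability of drawing from a shared
    background pool instead of the class pool: 0 gives linearly separable
    classes, 1 removes all class signal (held-out accuracy falls to chance).
    """

    n_per_class: int = 200
    vocab_overlap: float = 0.1
    class_vocab_size: int = 40
    doc_length: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be at least 1")
        if self.doc_length < 5:
            raise ValueError("doc_length must be at least 5")
        if not 0 <= self.vocab_overlap <= 1:
            raise ValueError("vocab_overlap must lie in [0, 1]")
        if self.class_vocab_size < 5:
            raise ValueError("class_vocab_size must be at least 5")


_PENETRANCE_SEED = (
    "penetrance cumulative risk hazard ratio carriers lifetime incidence "
    "age-specific absolute".split()
)
_PREVALENCE_SEED = (
    "prevalence frequency pathogenic variant unselected population carrier "
    "proportion screening detection".split()
)
_NEITHER_SEED = (
    "expression pathway signaling apoptosis methylation transcription cell "
    "line proliferation assay".split()
)


def _class_pools(size: int) -> dict[TriageLabel, list[str]]:
    def pad(seed_words: list[str], prefix: str) -> list[str]:
        pool = list(seed_words)
        i = 0
        while len(pool) < size:
            pool.append(f"{prefix}{i:03d}")
            i += 1
        return pool[:size]

    pen = pad(_PENETRANCE_SEED, "penet")
    prev = pad(_PREVALENCE_SEED, "preval")
    neither = pad(_NEITHER_SEED, "biol")
    return {
        TriageLabel.PENETRANCE: pen,
        TriageLabel.PREVALENCE: prev,
        TriageLabel.BOTH: pen + prev,
        TriageLabel.NEITHER: neither,
    }


def generate_abstract_corpus(
    config: CorpusSimConfig = CorpusSimConfig(),
) -> list[AbstractRecord]:
    """Generate a balanced, labelled four-class abstract corpus.

    Each document of ``doc_length`` tokens draws, per token, from a shared
    background pool with probability ``vocab_overlap`` and from its class
    pool otherwise.  The BOTH class pools penetrance and prevalence
    vocabulary.  Titles are the first five tokens of the body, so they carry
    no extra signal.
    """
    rng = np.random.default_rng(config.seed)
    pools = _class_pools(config.class_vocab_size)
    shared = [f"common{i:03d}" for i in range(4 * config.class_vocab_size)]

    records: list[AbstractRecord] = []
    counter = 0
    for label in TriageLabel:
        pool = pools[label]
        for _ in range(config.n_per_class):
            counter += 1
            tokens = [
                shared[rng.integers(len(shared))]
                if rng.random() < config.vocab_overlap
                else pool[rng.integers(len(pool))]
                for _ in range(config.doc_length)
            ]
            records.append(
                AbstractRecord(
                    id=f"SYN{counter:05d}",
                    title=" ".join(tokens[:5]),
                    text=" ".join(tokens[5:]),
                    label=label,
                )
            )
    return records


# ---------------------------------------------------------------------------
# Penetrance studies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StudySimConfig:
    """Configuration for the penetrance-study generator.

    Per-study log effects are Normal(true_log_ratio, se) with the standard
    error uniform in ``se_range``; 95% Wald intervals and two-sided Wald
    p-values are derived from the same draw, and carrier counts are uniform
    integers in ``carrier_range``.
    """

    true_log_ratio: float = 0.0
    n_studies: int = 5
    se_range: tuple[float, float] = (0.1, 0.5)
    carrier_range: tuple[int, int] = (20, 200)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_studies < 0:
            raise ValueError("n_studies must be non-negative")
        lo, hi = self.se_range
        if not (0 < lo <= hi):
            raise ValueError("se_range must be ordered and positive")
        clo, chi = self.carrier_range
        if not (0 <= clo <= chi):
            raise ValueError("carrier_range must be ordered and non-negative")


_EFFECT_CYCLE = (EffectType.OR, EffectType.RR, EffectType.HR, EffectType.SIR)
_DESIGN_CYCLE = (
    StudyDesign.CASE_CONTROL,
    StudyDesign.COHORT,
    StudyDesign.FAMILY_BASED,
    StudyDesign.GWAS,
)


def generate_penetrance_studies(
    config: StudySimConfig = StudySimConfig(),
    gene: str = "GENE",
    disease: str = "synthetic disease",
) -> list[PenetranceStudy]:
    """Draw ``n_studies`` effect estimates around the true log-ratio."""
    rng = np.random.default_rng(config.seed)
    studies: list[PenetranceStudy] = []
    for i in range(config.n_studies):
        se = float(rng.uniform(*config.se_range))
        log_ratio = float(rng.normal(config.true_log_ratio, se))
        point = math.exp(log_ratio)
        ci_low = math.exp(log_ratio - 1.96 * se)
        ci_high = math.exp(log_ratio + 1.96 * se)
        p_value = float(2.0 * stats.norm.sf(abs(log_ratio) / se))
        carriers = int(rng.integers(config.carrier_range[0], config.carrier_range[1] + 1))
        studies.append(
            PenetranceStudy(
                study_id=f"SIM{i + 1:03d}",
                gene=gene,
                disease=disease,
                effect_type=_EFFECT_CYCLE[i % len(_EFFECT_CYCLE)],
                point_estimate=point,
                ci_low=ci_low,
                ci_high=ci_high,
                p_value=p_value,
                n_carriers=carriers,
                design=_DESIGN_CYCLE[i % len(_DESIGN_CYCLE)],
                ascertainment_note="simulated",
            )
        )
    return studies
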