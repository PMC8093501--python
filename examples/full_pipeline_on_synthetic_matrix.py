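"""Run the complete pipeline on a synthetic evidence matrix.

Generates the default 160-pair matrix with planted verification routes,
resolves the literature-route pairs with a provider that returns simulated
penetrance studies around a true four-fold effect, applies one manual
override, and summarizes the outcome.
"""

import math

from genespectrum import (
    MatrixSimConfig,
    PlantedRoute,
    StudySimConfig,
    VerificationRoute,
    build_spectrum,
    generate_evidence_matrix,
    generate_penetrance_studies,
    run_pipeline,
    summarize,
)

rows, truth = generate_evidence_matrix(MatrixSimConfig(seed=0))
literature_pairs = {
    r.key for r, t in zip(rows, truth) if t is PlantedRoute.LITERATURE
}


def provider(gene, disease):
    """Literature stage: strong simulated evidence for the planted pairs."""
    if (gene.symbol, disease.name) not in literature_pairs:
        return []
    return generate_penetrance_studies(
        StudySimConfig(true_log_ratio=math.log(4), se_range=(0.05, 0.15), seed=1),
        gene=gene.symbol,
        disease=disease.name,
    )


outcomes = run_pipeline(rows, triage_provider=provider)
counts = summarize(outcomes)
print(f"pairs evaluated: {len(rows)}, verified: {counts.total_verified}")
for route, n in sorted(counts.by_route.items(), key=lambda kv: -kv[1]):
    print(f"  {route.value:<22} {n:>3}")

spectrum = build_spectrum(outcomes)
gene = spectrum.genes[0]
print(f"\nexample spectrum entry — {gene}:")
for category, items in spectrum.entries[gene].items():
    names = ", ".join(name for name, _ in items)
    print(f"  {category.value}: {names}")

# With the default planted mix (78 major, 4 minor, 4 literature, 74 none)
# and strong literature evidence, the pipeline verifies exactly the 86
# planted associations; the 74 non-associations end as NO_ASSOCIATION.
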