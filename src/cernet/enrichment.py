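"""Hypergeometric over-representation analysis of gene sets.

Plain upper-tail hypergeometric per term against a term -> gene map; no
length-bias correction.  GO-style filtering uses the BH-adjusted column,
KEGG-style filtering uses the raw p-value, both strictly below 0.05.
"""

from __future__ import annotations

from typing import Iterable, Sequence

from .models import EnrichmentResult, TermMap
from .stats import bh_adjust, hypergeom_upper_tail

DEFAULT_ENRICHMENT_THRESHOLD = 0.05


def enrich(
    study_genes: Iterable[str],
    population_genes: Iterable[str],
    term_map: Sequence[TermMap],
) -> list[EnrichmentResult]:
    """Per-term upper-tail hypergeometric enrichment of the study set.

    N = |population|, K = |term ∩ population|, n = |study|,
    k = |term ∩ study|.  Study genes must be a subset of the population.
    Results are sorted by p ascending, ties broken by term id.
    """
    study = set(study_genes)
    population = set(population_genes)
    offenders = sorted(study - population)
    if offenders:
        raise ValueError(f"study genes absent from population: {offenders}")
    N, n = len(population), len(study)

    terms = sorted(term_map, key=lambda t: t.term_id)
    raw: list[tuple[TermMap, int, int, float]] = []
    for term in terms:
        members = term.genes & population
        K = len(members)
        k = len(members & study)
        p = hypergeom_upper_tail(k, N, K, n)
        raw.append((term, k, K, p))

    adjusted = bh_adjust([r[3] for r in raw]) if raw else []
    results = [
        EnrichmentResult(
            term_id=term.term_id,
            name=term.name,
            k_study=k,
            n_study=n,
            K_pop=K,
            N_pop=N,
            p_value=float(p),
            adjusted_p=float(q),
        )
        for (term, k, K, p), q in zip(raw, adjusted)
    ]
    results.sort(key=lambda r: (r.p_value, r.term_id))
    return results


def filter_enrichment(
    results: Sequence[EnrichmentResult],
    mode: str,
    threshold: float = DEFAULT_ENRICHMENT_THRESHOLD,
) -> list[EnrichmentResult]:
    """'go' keeps adjusted_p < threshold; 'kegg' keeps raw p < threshold."""
    if mode == "go":
        return [r for r in results if r.adjusted_p < threshold]
    if mode == "kegg":
        return [r for r in results if r.p_value < threshold]
    raise ValueError(f"unknown mode {mode!r}: expected 'go' or 'kegg'")
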