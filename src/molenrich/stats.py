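"""Plain (unweighted) over-representation statistics.

One binomial tail test per ontology class: a trial checks whether a queried
molecule belongs to the class; the success probability is the class's share
of the background population.  Raw p-values are corrected with the
Benjamini-Hochberg step-up procedure over the family of tested classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as _sps

from .ontology import AnnotationIndex, ConfigurationError

MODE_ENTITIES = "entities"
MODE_CLASSES = "classes"


class InputError(ValueError):
    """Raised for unusable sample input."""


@dataclass
class EnrichmentRow:
    """Per-class enrichment statistics.

    ``fold`` is ``None`` when undefined (class absent from the population).
    """

    class_id: str
    name: str
    k: int
    n: int
    K: int
    N: int
    p_success: float
    p_raw: float
    p_adj: float = 1.0
    fold: float | None = None
    sample_pct: float = 0.0


def binomial_tail(k: int, n: int, p: float) -> float:
    """Upper tail P[X >= k] for X ~ Binomial(n, p)."""
    if not 0 <= k <= n:
        raise ValueError(f"require 0 <= k <= n, got k={k}, n={n}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"success probability outside [0, 1]: {p}")
    return float(_sps.binom.sf(k - 1, n, p))


def class_success_probability(K: int, index: AnnotationIndex, mode: str = MODE_ENTITIES) -> float:
    """Per-trial success probability for a class annotating K molecules.

    ``entities`` divides by the molecule population N_e; ``classes`` divides
    by the number of ontology classes N_c.
    """
    if K < 0:
        raise ValueError("K must be non-negative")
    denom = population_size(index, mode)
    if denom <= 0:
        raise ConfigurationError(f"population size is zero in mode {mode!r}")
    return K / denom


def population_size(index: AnnotationIndex, mode: str) -> int:
    if mode == MODE_ENTITIES:
        return index.population_size_entities
    if mode == MODE_CLASSES:
        return index.population_size_classes
    raise ConfigurationError(f"unknown population mode {mode!r}")


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    adjusted_(i) = min(1, min_{j >= rank(i)} p_(j) * m / j)
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m, dtype=float)
    out[order] = adjusted
    return out.tolist()


def fold_enrichment(k: int, n: int, K: int, N: int) -> float | None:
    """(k/n) / (K/N); ``None`` when K == 0 (undefined)."""
    if n <= 0 or N <= 0:
        raise ValueError("n and N must be positive")
    if K == 0:
        return None
    return (k / n) / (K / N)


def _sorted_rows(rows: list[EnrichmentRow]) -> list[EnrichmentRow]:
    return sorted(rows, key=lambda r: (r.p_adj, r.p_raw, r.class_id))


def plain_enrichment(
    index: AnnotationIndex,
    sample: Iterable[str],
    mode: str = MODE_ENTITIES,
) -> list[EnrichmentRow]:
    """Binomial over-representation test for every class hit by the sample.

    Only classes with at least one sample member are tested (and enter the
    BH family).  Unknown ids are dropped; an empty recognised sample is an
    error listing them.
    """
    requested = set(sample)
    recognised = requested & index.molecule_ids
    if not recognised:
        raise InputError(
            "no sample id matches a molecule in the ontology; unrecognised: "
            + ", ".join(sorted(requested))
        )
    n = len(recognised)
    N = population_size(index, mode)
    rows: list[EnrichmentRow] = []
    for class_id in sorted(index.class_to_molecules):
        members = index.class_to_molecules[class_id]
        k = len(members & recognised)
        if k == 0:
            continue
        K = len(members)
        p_s = class_success_probability(K, index, mode)
        rows.append(
            EnrichmentRow(
                class_id=class_id,
                name=index.names.get(class_id, ""),
                k=k,
                n=n,
                K=K,
                N=N,
                p_success=p_s,
                p_raw=binomial_tail(k, n, min(p_s, 1.0)),
                fold=fold_enrichment(k, n, K, N),
                sample_pct=100.0 * k / n,
            )
        )
    for row, adj in zip(rows, bh_adjust([r.p_raw for r in rows])):
        row.p_adj = adj
    return _sorted_rows(rows)
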