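"""Weighted enrichment via a saddlepoint tail approximation.

Significance of the weight sum S accumulated by the m sample members of a
class, against the null that the m weights are drawn iid from the empirical
distribution of the complete submitted weight list.  The tail probability
P[sum >= S] is approximated with the Lugannani-Rice formula on the empirical
cumulant generating function; m = 1 uses the exact empirical tail count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import norm as _norm

from .ontology import AnnotationIndex
from .stats import (
    MODE_ENTITIES,
    EnrichmentRow,
    InputError,
    bh_adjust,
    fold_enrichment,
    plain_enrichment,
    population_size,
    _sorted_rows,
)

#: |t_hat| below this uses the normal (t -> 0 continuity) fallback.
T_ZERO_THRESHOLD = 1e-8

#: Convergence requirement for the saddlepoint equation residual.
RESIDUAL_TOL = 1e-10


class DegenerateWeightsWarning(UserWarning):
    """All submitted weights are (effectively) identical."""


@dataclass
class WeightedSample:
    """User sample: molecule ids with optional weights in [0, 1]."""

    entries: list[tuple[str, float | None]]
    n_duplicates: int = 0

    def __post_init__(self) -> None:
        seen = set()
        for mol_id, w in self.entries:
            if mol_id in seen:
                raise ValueError(f"duplicate sample id {mol_id!r}")
            seen.add(mol_id)
            if w is not None and not 0.0 <= w <= 1.0:
                raise ValueError(f"weight for {mol_id!r} outside [0, 1]: {w}")

    @property
    def is_weighted(self) -> bool:
        return bool(self.entries) and self.entries[0][1] is not None

    def ids(self) -> list[str]:
        return [mol_id for mol_id, _ in self.entries]

    def weight_map(self) -> dict[str, float]:
        return {mol_id: w for mol_id, w in self.entries if w is not None}


def empirical_cgf(weights: Sequence[float], t: float) -> tuple[float, float, float]:
    """Empirical CGF K(t) = log mean(exp(t*w_i)) and its first two derivatives.

    Stabilised by shifting out the maximum exponent, so large |t| stays
    finite for weights on a bounded support.
    """
    w = np.asarray(weights, dtype=float)
    if w.size == 0:
        raise ValueError("weights must be non-empty")
    a = t * w
    shift = a.max()
    e = np.exp(a - shift)
    se = e.sum()
    value = shift + np.log(se / w.size)
    d1 = float((w * e).sum() / se)
    d2 = float((w * w * e).sum() / se) - d1 * d1
    if not np.isfinite(value) or not np.isfinite(d1):
        raise FloatingPointError(f"CGF overflow at t={t}")
    return float(value), d1, max(d2, 0.0)


@dataclass
class SaddleContext:
    """State for one tail evaluation: background, class size m, observed S."""

    background_weights: np.ndarray
    m: int
    S: float
    t_hat: float | None = field(default=None)

    def cgf(self, t: float) -> float:
        return empirical_cgf(self.background_weights, t)[0]

    def cgf_d1(self, t: float) -> float:
        return empirical_cgf(self.background_weights, t)[1]

    def cgf_d2(self, t: float) -> float:
        return empirical_cgf(self.background_weights, t)[2]


def solve_saddlepoint(ctx: SaddleContext) -> float:
    """Root t_hat of m * K'(t) = S: Newton iteration with bisection safeguard.

    Requires S strictly inside (m*min(w), m*max(w)); K' is monotone
    increasing, so a doubling search always brackets the root.
    """
    w = ctx.background_weights
    target = ctx.S / ctx.m
    tol = RESIDUAL_TOL * max(1.0, abs(ctx.S))
    if not (w.min() < target < w.max()):
        raise ValueError("S must be strictly interior to the weight-sum support")

    lo, hi = -1.0, 1.0
    while empirical_cgf(w, lo)[1] > target:
        lo *= 2.0
        if lo < -1e9:  # pragma: no cover - bounded weights make this unreachable
            raise FloatingPointError("failed to bracket saddlepoint")
    while empirical_cgf(w, hi)[1] < target:
        hi *= 2.0
        if hi > 1e9:  # pragma: no cover
            raise FloatingPointError("failed to bracket saddlepoint")

    t = 0.5 * (lo + hi)
    for _ in range(200):
        _, d1, d2 = empirical_cgf(w, t)
        resid = ctx.m * d1 - ctx.S
        if abs(resid) <= tol:
            ctx.t_hat = t
            return t
        if d1 < target:
            lo = t
        else:
            hi = t
        if d2 > 0:
            t_new = t - (d1 - target) / d2
        else:
            t_new = 0.5 * (lo + hi)
        if not lo < t_new < hi:
            t_new = 0.5 * (lo + hi)
        t = t_new
    ctx.t_hat = t
    if abs(ctx.m * empirical_cgf(w, t)[1] - ctx.S) > tol:
        raise FloatingPointError("saddlepoint iteration did not converge")
    return t


def saddlesum_pvalue(background: Sequence[float], m: int, S: float) -> float:
    """Approximate P[W_1 + ... + W_m >= S], W_j iid from ``background``.

    Lugannani-Rice tail on the empirical CGF; exact empirical counts for
    m = 1 and m = 2 (the expansion is unreliable there on lattice-like
    data); degenerate/boundary cases return the exact 0/1 answer.  Result
    is clamped to [0, 1].
    """
    w = np.asarray(background, dtype=float)
    if w.size == 0:
        raise ValueError("background weight list must be non-empty")
    if m < 1:
        raise ValueError("m must be >= 1")
    wmin, wmax = float(w.min()), float(w.max())
    eps = 1e-12 * max(1.0, abs(S))
    if S <= m * wmin + eps:
        return 1.0
    if S > m * wmax + eps:
        return 0.0
    if m == 1:
        return float(np.count_nonzero(w >= S - eps)) / w.size
    if m == 2:
        # exact pair convolution; the approximation is unreliable at m = 2
        ws = np.sort(w)
        lo = np.searchsorted(ws, S - ws - eps, side="left")
        return float((w.size - lo).sum()) / (w.size * w.size)
    if wmax - wmin < 1e-15:
        return 1.0  # degenerate support, S <= m*wmax handled above
    if S >= m * wmax - eps:
        # saddlepoint diverges at the support edge; P[all draws at the max]
        return float((np.count_nonzero(w >= wmax - eps) / w.size) ** m)

    ctx = SaddleContext(background_weights=w, m=m, S=S)
    t_hat = solve_saddlepoint(ctx)
    if abs(t_hat) < T_ZERO_THRESHOLD:
        mean = float(w.mean())
        var = float(w.var())
        z = (S - m * mean) / np.sqrt(m * var)
        return float(np.clip(_norm.sf(z), 0.0, 1.0))
    K, _, K2 = empirical_cgf(w, t_hat)
    arg = 2.0 * (t_hat * S - m * K)
    w_hat = float(np.sign(t_hat) * np.sqrt(max(arg, 0.0)))
    u_hat = float(t_hat * np.sqrt(m * K2))
    if w_hat == 0.0 or u_hat == 0.0:
        mean = float(w.mean())
        z = (S - m * mean) / np.sqrt(m * float(w.var()))
        return float(np.clip(_norm.sf(z), 0.0, 1.0))
    p = _norm.sf(w_hat) + _norm.pdf(w_hat) * (1.0 / u_hat - 1.0 / w_hat)
    return float(np.clip(p, 0.0, 1.0))


def weighted_enrichment(
    index: AnnotationIndex,
    sample: WeightedSample,
    mode: str = MODE_ENTITIES,
) -> list[EnrichmentRow]:
    """SaddleSum-style weighted enrichment over every class hit by the sample.

    The background distribution is the complete submitted weight list.  With
    fewer than two distinct weights the weighted model is degenerate and the
    analysis falls back (with a warning) to the plain binomial test on the
    id set.
    """
    if not sample.is_weighted:
        raise InputError("weighted analysis requires weights on every sample row")
    weight_map = sample.weight_map()
    recognised = {mid: w for mid, w in weight_map.items() if mid in index.molecule_ids}
    if not recognised:
        raise InputError(
            "no sample id matches a molecule in the ontology; unrecognised: "
            + ", ".join(sorted(weight_map))
        )
    background = np.asarray(sorted(recognised.values()), dtype=float)
    if np.unique(background).size < 2:
        warnings.warn(
            "all weights identical; falling back to plain analysis on the id set",
            DegenerateWeightsWarning,
            stacklevel=2,
        )
        return plain_enrichment(index, recognised.keys(), mode)

    n = len(recognised)
    N = population_size(index, mode)
    rows: list[EnrichmentRow] = []
    for class_id in sorted(index.class_to_molecules):
        members = index.class_to_molecules[class_id]
        hit = [mid for mid in members if mid in recognised]
        m = len(hit)
        if m == 0:
            continue
        S = float(sum(recognised[mid] for mid in hit))
        K = len(members)
        rows.append(
            EnrichmentRow(
                class_id=class_id,
                name=index.names.get(class_id, ""),
                k=m,
                n=n,
                K=K,
                N=N,
                p_success=K / N if N else 0.0,
                p_raw=saddlesum_pvalue(background, m, S),
                fold=fold_enrichment(m, n, K, N),
                sample_pct=100.0 * m / n,
            )
        )
    for row, adj in zip(rows, bh_adjust([r.p_raw for r in rows])):
        row.p_adj = adj
    return _sorted_rows(rows)
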