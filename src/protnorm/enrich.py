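"""Local over-representation analysis (ORA).

Hypergeometric upper-tail test per gene set against a quantified-proteome
universe, with Benjamini-Hochberg FDR control. The defensible background
for a selection drawn from a quantified proteome is the set of proteins
quantified at the active evidence filter, not the whole annotation space;
gene-set members are intersected with the universe before the set size K
is computed.

Sets whose overlap with the selection is below ``min_overlap`` are
excluded *before* correction, so the BH ``m`` equals the number of sets
actually tested.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .errors import ContainmentError, CountError
from .io import GeneSetCollection

__all__ = [
    "EnrichmentResult",
    "hypergeom_upper",
    "bh_adjust",
    "ora",
    "results_to_frame",
]


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    N: universe size, K: set size in the universe, n: selection size,
    k: observed overlap. Computed through log-factorial machinery (exact to
    ~1e-12 relative against rational-arithmetic enumeration).
    """
    for name, v in (("k", k), ("K", K), ("n", n), ("N", N)):
        if v < 0:
            raise CountError(f"{name} must be >= 0, got {v}")
    if K > N or n > N:
        raise CountError(f"K={K} and n={n} must not exceed N={N}")
    if k > min(K, n):
        raise CountError(f"overlap k={k} exceeds min(K={K}, n={n})")
    if k == 0:
        return 1.0
    p = float(hypergeom.sf(k - 1, N, K, n))
    return min(max(p, 0.0), 1.0)


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Step-up Benjamini-Hochberg q-values, aligned to the input order.

    q_(i) = min_{j >= i} (m * p_(j) / j), clipped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q.tolist()


@dataclass(frozen=True)
class EnrichmentResult:
    set_id: str
    name: str
    universe_size: int
    set_size: int
    selected_size: int
    overlap: int
    p_value: float
    q_value: float
    overlap_members: tuple[str, ...]


def ora(
    selected: Iterable[str],
    universe: Iterable[str],
    sets: GeneSetCollection,
    min_overlap: int = 2,
) -> list[EnrichmentResult]:
    """Over-representation of ``selected`` within each gene set.

    Results are ordered by ascending p-value, ties broken by set id. An
    empty selection yields an empty result list.
    """
    selected_set = set(selected)
    universe_set = set(universe)
    if not universe_set:
        raise ContainmentError("universe is empty")
    offenders = sorted(selected_set - universe_set)
    if offenders:
        raise ContainmentError(
            f"selected identifiers outside the universe: {offenders}"
        )
    if not selected_set:
        return []
    N = len(universe_set)
    n = len(selected_set)

    tested: list[EnrichmentResult] = []
    for set_id in sorted(sets.sets):
        gene_set = sets[set_id]
        members_in_universe = gene_set.members & universe_set
        K = len(members_in_universe)
        overlap_members = tuple(sorted(members_in_universe & selected_set))
        k = len(overlap_members)
        if k < min_overlap:
            continue
        p = hypergeom_upper(k, K, n, N)
        tested.append(
            EnrichmentResult(
                set_id=set_id,
                name=gene_set.name,
                universe_size=N,
                set_size=K,
                selected_size=n,
                overlap=k,
                p_value=p,
                q_value=1.0,  # placeholder until BH below
                overlap_members=overlap_members,
            )
        )
    if not tested:
        return []
    q_values = bh_adjust([r.p_value for r in tested])
    adjusted = [
        EnrichmentResult(
            set_id=r.set_id,
            name=r.name,
            universe_size=r.universe_size,
            set_size=r.set_size,
            selected_size=r.selected_size,
            overlap=r.overlap,
            p_value=r.p_value,
            q_value=q,
            overlap_members=r.overlap_members,
        )
        for r, q in zip(tested, q_values)
    ]
    return sorted(adjusted, key=lambda r: (r.p_value, r.set_id))


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    rows = [
        {
            "set_id": r.set_id,
            "name": r.name,
            "N": r.universe_size,
            "K": r.set_size,
            "n": r.selected_size,
            "k": r.overlap,
            "p_value": r.p_value,
            "q_value": r.q_value,
            "overlap_members": ";".join(r.overlap_members),
        }
        for r in results
    ]
    columns = [
        "set_id", "name", "N", "K", "n", "k",
        "p_value", "q_value", "overlap_members",
    ]
    return pd.DataFrame(rows, columns=columns)
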