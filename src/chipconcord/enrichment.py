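"""Gene-set enrichment of bound-gene lists.

Each gene set is tested for over-representation among the bound genes with
a one-sided Fisher's exact test: with N genes in the universe, n bound,
K in the set and k bound-and-in-set, the p-value is the upper tail of the
hypergeometric distribution,

    p = sum_{j=k}^{min(n,K)} C(K,j) C(N-K, n-j) / C(N,n).

Raw p-values across sets are converted to q-values with the
Benjamini–Hochberg step-up procedure.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from scipy.stats import hypergeom

from .model import EnrichmentResult, GeneSet, ValidationError

__all__ = ["fisher_enrichment", "bh_adjust"]


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjustment.

    On the sorted p-values, q_(i) = min_{j >= i} p_(j)·m/j, clipped at 1,
    mapped back to the input order. Idempotent and permutation-equivariant.
    """
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q.tolist()


def fisher_enrichment(
    bound: set[str],
    universe: set[str],
    sets: Iterable[GeneSet],
    alternative: str = "greater",
) -> list[EnrichmentResult]:
    """One-sided Fisher's exact enrichment of gene sets in a bound-gene list.

    Set members are intersected with the universe before testing; the bound
    list must be a subset of the universe. Results are sorted by p-value,
    then set name, and carry BH-adjusted q-values computed across all
    tested sets.
    """
    if alternative != "greater":
        raise ValidationError("only the one-sided enrichment alternative is supported")
    if not universe:
        raise ValidationError("empty gene universe")
    if not bound <= universe:
        extra = sorted(bound - universe)[:5]
        raise ValidationError(f"bound genes outside the universe, e.g. {extra}")

    N = len(universe)
    n = len(bound)
    rows: list[tuple[str, int, int, float]] = []
    for s in sets:
        members = s.members & universe
        K = len(members)
        k = len(bound & members)
        # upper-tail hypergeometric P(X >= k)
        p = float(hypergeom.sf(k - 1, N, K, n))
        p = min(1.0, max(0.0, p))
        rows.append((s.name, k, K, p))

    qs = bh_adjust([r[3] for r in rows])
    results = [
        EnrichmentResult(name, k, n, K, N, p, max(q, p))
        for (name, k, K, p), q in zip(rows, qs)
    ]
    results.sort(key=lambda r: (r.p_value, r.set_name))
    return results
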