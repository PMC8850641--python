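"""Shared statistical kernels.

The upper-tail hypergeometric probability lives here and nowhere else: the
sponge test and the term-enrichment test both call :func:`hypergeom_upper_tail`.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as _st
from statsmodels.stats.multitest import multipletests


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    N is the population size, K the number of marked items, n the draw
    size, and k the observed overlap.  ``k = 0`` returns exactly 1.0.
    """
    if min(k, N, K, n) < 0:
        raise ValueError("all hypergeometric arguments must be non-negative")
    if max(K, n) > N:
        raise ValueError(f"margins (K={K}, n={n}) exceed universe N={N}")
    if k > min(K, n):
        raise ValueError(f"overlap k={k} exceeds min(K={K}, n={n})")
    if k == 0:
        return 1.0
    return float(_st.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_(i) = p_(i) * m / i on the ascending sort, made monotone from the
    largest rank down, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
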