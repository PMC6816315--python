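"""Set-overlap statistics.

The quantitative core of the package: the Jaccard/Tanimoto coefficient
``T = Nc / (Na + Nb - Nc)``, its exact one-sided significance under a
central-hypergeometric null (both set sizes and the annotation universe
fixed), Benjamini-Hochberg step-up FDR adjustment, and a Mann-Whitney
rank-sum contrast between similarity distributions.

The null model for :func:`jaccard_exact_p`: sets A and B are uniformly
random subsets of fixed sizes ``na`` and ``nb`` drawn independently from a
universe of ``n_universe`` annotatable elements.  The intersection size K
then follows a hypergeometric law, and the reported p-value is the
upper tail ``P(K >= nc)`` — similarity at least as large as observed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats as _st

__all__ = [
    "UndefinedSimilarityError",
    "SetComparison",
    "jaccard",
    "jaccard_exact_p",
    "compare_sets",
    "bh_fdr",
    "rank_sum_compare",
]


class UndefinedSimilarityError(ValueError):
    """Raised when similarity of two empty sets is requested."""


@dataclass(frozen=True)
class SetComparison:
    """One pairwise set comparison: counts, coefficient and significance.

    Attributes
    ----------
    na, nb : int
        Sizes of the two compared sets.
    nc : int
        Size of their intersection.
    n_universe : int
        Size of the annotation universe the sets were drawn from.
    T : float
        Jaccard/Tanimoto coefficient ``nc / (na + nb - nc)``.
    p : float
        One-sided exact p-value, ``P(K >= nc)`` under the hypergeometric null.
    q : float or None
        BH-adjusted value; filled in once the comparison joins a family.
    """

    na: int
    nb: int
    nc: int
    n_universe: int
    T: float
    p: float
    q: Optional[float] = None

    def with_q(self, q: float) -> "SetComparison":
        return replace(self, q=float(q))


def jaccard(a: Iterable, b: Iterable) -> float:
    """Jaccard/Tanimoto coefficient |A∩B| / |A∪B| of two finite sets.

    Equals 1 when the sets coincide (and are nonempty), 0 when they are
    disjoint.  Two empty sets have no defined similarity: the caller must
    decide whether to exclude such a pair, so an
    :class:`UndefinedSimilarityError` is raised.
    """
    sa, sb = set(a), set(b)
    union = len(sa | sb)
    if union == 0:
        raise UndefinedSimilarityError(
            "Jaccard similarity of two empty sets is undefined"
        )
    return len(sa & sb) / union


def _check_counts(na: int, nb: int, nc: int, n_universe: int) -> None:
    if min(na, nb, nc, n_universe) < 0:
        raise ValueError("counts must be non-negative")
    if nc > min(na, nb):
        raise ValueError(f"infeasible counts: nc={nc} > min(na={na}, nb={nb})")
    if max(na, nb) > n_universe:
        raise ValueError(
            f"infeasible counts: set sizes ({na}, {nb}) exceed universe {n_universe}"
        )
    if nc < na + nb - n_universe:
        raise ValueError(
            f"infeasible counts: nc={nc} < na+nb-N = {na + nb - n_universe}"
        )


def jaccard_exact_p(na: int, nb: int, nc: int, n_universe: int) -> float:
    """Exact one-sided p-value for an observed intersection of size ``nc``.

    Under the null, K = |A∩B| for independent uniform subsets of sizes
    ``na`` and ``nb`` of an ``n_universe``-element universe is
    hypergeometric; the returned value is the upper tail P(K >= nc).
    ``nc = 0`` (the smallest possible overlap) always yields p = 1.
    """
    _check_counts(na, nb, nc, n_universe)
    if nc == 0:
        return 1.0
    # K ~ Hypergeometric(N=n_universe, K=na, n=nb)
    return float(_st.hypergeom.sf(nc - 1, n_universe, na, nb))


def compare_sets(a: Iterable, b: Iterable, n_universe: int) -> SetComparison:
    """Build a :class:`SetComparison` for two concrete sets.

    ``n_universe`` is supplied by the caller: the number of distinct
    annotated terms (term level), of selected top-level categories
    (category level), or of corpus genes (gene-set level).
    """
    sa, sb = set(a), set(b)
    na, nb, nc = len(sa), len(sb), len(sa & sb)
    t = jaccard(sa, sb)
    p = jaccard_exact_p(na, nb, nc, n_universe)
    return SetComparison(na=na, nb=nb, nc=nc, n_universe=n_universe, T=t, p=p)


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in input order.

    q_(i) = min_{j >= i} ( m * p_(j) / j ), clipped at 1.  Ties in the
    ranking are broken by stable input order, which does not affect the
    adjusted values.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest rank down
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m, dtype=float)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def rank_sum_compare(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Mann-Whitney U contrast of two similarity distributions.

    Returns ``(U, p)`` with U counted for ``x`` and a two-sided p-value:
    exact by enumeration of labelings when ``len(x)+len(y) <= 12`` and the
    pooled sample is tie-free, otherwise the normal approximation with tie
    and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size + y.size <= 12 and tie_free) else "asymptotic"
    res = _st.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.statistic), float(res.pvalue)
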