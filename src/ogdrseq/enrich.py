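"""Hypergeometric over-representation analysis of a DEG list.

For a universe of ``N`` genes of which ``M`` are annotated to a term, and a
DEG list of ``n`` universe genes of which ``m`` hit the term, the
enrichment p-value is the upper hypergeometric tail ``P(X >= m)``. Both a
Bonferroni column and a Benjamini-Hochberg column are reported; the
significance gate is BH <= alpha (0.05 by default). The universe convention
is decided by the caller; the pipeline uses genes that are both quantified
(testable in the comparison) and annotated to at least one term of the
namespace, the GO::TermFinder convention. Gene sets are taken as given —
no ontology-graph ancestor propagation is performed.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd

from .deg import bh_adjust
from .io import GeneSetCollection, ValidationError

#: fixed column order of the enrichment report table
ENRICHMENT_COLUMNS = (
    "term_id", "description", "namespace", "N", "M", "n", "m",
    "p_raw", "p_bonferroni", "p_fdr", "significant",
)


def hypergeom_upper_tail(N: int, M: int, n: int, m: int) -> float:
    """Exact ``P(X >= m)`` for ``X ~ Hypergeometric(N, M, n)``.

    Computed with exact integer arithmetic (the tail sum of binomial
    products over ``C(N, n)``) and rounded once to float, so the result is
    correct to full double precision for any practical universe size.
    """
    if not (0 <= M <= N and 0 <= n <= N and 0 <= m):
        raise ValidationError(f"invalid hypergeometric bounds N={N} M={M} n={n} m={m}")
    if m > min(M, n):
        raise ValidationError(f"m={m} exceeds min(M={M}, n={n})")
    lo = max(m, n - (N - M))
    total = sum(comb(M, k) * comb(N - M, n - k) for k in range(lo, min(M, n) + 1))
    return float(Fraction(total, comb(N, n)))


def enrich(
    deg_genes: frozenset[str] | set[str],
    universe: frozenset[str] | set[str],
    sets: GeneSetCollection,
    namespace: str | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Test every term of ``namespace`` for over-representation of DEGs.

    ``deg_genes`` and each term's members are intersected with ``universe``
    before counting. Terms with no DEG overlap (``m = 0``) are still tested
    (p = 1) and counted in the correction denominator. Results are sorted by
    raw p-value ascending, ties broken by term id, with the
    :data:`ENRICHMENT_COLUMNS` columns; ``significant`` is the
    ``p_fdr <= alpha`` gate.
    """
    universe = frozenset(universe)
    if not universe:
        raise ValidationError("empty universe")
    terms = sets.in_namespace(namespace)
    if not terms:
        raise ValidationError(f"no terms in namespace {namespace!r}")

    degs_u = frozenset(deg_genes) & universe
    N, n = len(universe), len(degs_u)

    rows = []
    for tid in sorted(terms):
        desc, ns, members = terms[tid]
        members_u = members & universe
        M = len(members_u)
        m = len(members_u & degs_u)
        p = hypergeom_upper_tail(N, M, n, m)
        rows.append((tid, desc, ns, N, M, n, m, p))

    T = len(rows)
    df = pd.DataFrame(rows, columns=["term_id", "description", "namespace",
                                     "N", "M", "n", "m", "p_raw"])
    df["p_bonferroni"] = np.minimum(1.0, df["p_raw"] * T)
    df["p_fdr"] = bh_adjust(df["p_raw"].to_numpy())
    df["significant"] = df["p_fdr"] <= alpha
    df = df.sort_values(["p_raw", "term_id"], kind="mergesort").reset_index(drop=True)
    return df


def significant_terms(enrichment: pd.DataFrame) -> frozenset[str]:
    """Term ids passing the significance gate of an enrichment table."""
    return frozenset(enrichment.loc[enrichment["significant"], "term_id"])


def genes_in_significant_terms(enrichment: pd.DataFrame, sets: GeneSetCollection) -> frozenset[str]:
    """Union of member genes over the significant terms of a table."""
    out: set[str] = set()
    for tid in significant_terms(enrichment):
        out |= sets.members(tid)
    return frozenset(out)
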