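"""Gene co-expression network with degree-centrality and k-core analysis.

Nodes are genes; an edge joins every pair whose expression profiles across
all samples are significantly correlated (|Pearson r| at or above a floor
and correlation-test p at or below a cap). Profiles are ``log2(RPKM + 1)``.
Degree centrality is the number of incident edges; a node's core number is
the largest k such that it survives in the k-core, the maximal subgraph
whose nodes all have at least k neighbours inside it. Negative correlations
form edges too — the sign is kept as an edge attribute.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

from .deg import ExpressionMatrix
from .io import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class CoexpressionNetwork:
    graph: nx.Graph
    degree: dict[str, int] = field(default_factory=dict)
    core_number: dict[str, int] = field(default_factory=dict)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return sorted((min(a, b), max(a, b)) for a, b in self.graph.edges)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def pearson_with_p(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with its two-sided p-value.

    The p-value comes from ``t = r * sqrt((L-2) / (1-r^2))`` against a
    Student-t law with L-2 degrees of freedom; ``|r| = 1`` maps to p = 0.
    Raises :class:`ValidationError` for profiles shorter than 3 or with zero
    variance (the caller skips such pairs).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValidationError("profiles must be equal-length 1-d arrays with >= 3 samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("zero-variance profile: correlation undefined")
    r, p = stats.pearsonr(x, y)
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        return r, 0.0
    return r, float(p)


def build_network(
    em: ExpressionMatrix,
    genes,
    r_min: float = 0.9,
    p_max: float = 0.05,
) -> CoexpressionNetwork:
    """Build the co-expression network over ``genes``.

    Every unordered pair with ``|r| >= r_min`` and ``p <= p_max`` becomes an
    edge with attributes ``r`` and ``p``. Genes with constant profiles (no
    variance) cannot form edges but are retained as isolated nodes, as are
    genes that simply fail the thresholds. The edge set is independent of
    the input order of ``genes``.
    """
    genes = sorted(set(genes))
    missing = [g for g in genes if g not in em.rpkm.index]
    if missing:
        raise ValidationError(f"gene {missing[0]!r} not in expression matrix")
    n_samples = em.rpkm.shape[1]
    if n_samples < 3:
        raise ValidationError("correlation p-value undefined with fewer than 3 samples")

    profiles = np.log2(em.rpkm.loc[genes].to_numpy(dtype=np.float64) + 1.0)
    sd = profiles.std(axis=1)
    variable = sd > 0
    n_const = int((~variable).sum())
    if n_const:
        logger.info("%d constant-profile genes kept as isolated nodes", n_const)

    g = nx.Graph()
    g.add_nodes_from(genes)

    idx = np.nonzero(variable)[0]
    if idx.size >= 2:
        r = np.corrcoef(profiles[idx])
        r = np.clip(r, -1.0, 1.0)
        dof = n_samples - 2
        with np.errstate(divide="ignore"):
            t = np.abs(r) * np.sqrt(dof / (1.0 - r**2))
        p = 2.0 * stats.t.sf(t, dof)
        p[np.abs(r) == 1.0] = 0.0
        iu, ju = np.triu_indices(len(idx), k=1)
        keep = (np.abs(r[iu, ju]) >= r_min) & (p[iu, ju] <= p_max)
        for i, j in zip(iu[keep], ju[keep]):
            a, b = genes[idx[i]], genes[idx[j]]
            g.add_edge(a, b, r=float(r[i, j]), p=float(p[i, j]))

    net = CoexpressionNetwork(graph=g)
    net.degree = {v: int(d) for v, d in g.degree()}
    net.core_number = kcore_decompose(net)
    return net


def kcore_decompose(net: CoexpressionNetwork) -> dict[str, int]:
    """Core number of every node (largest k whose k-core contains it).

    Uses the standard peeling decomposition; core numbers are a property of
    the graph, independent of peeling order.
    """
    return {v: int(k) for v, k in nx.core_number(net.graph).items()}


def rank_core_genes(net: CoexpressionNetwork, top: int) -> list[str]:
    """Top genes by (core number desc, degree desc, gene id asc)."""
    if top < 1:
        raise ValidationError("top must be >= 1")
    order = sorted(
        net.graph.nodes,
        key=lambda v: (-net.core_number.get(v, 0), -net.degree.get(v, 0), v),
    )
    return order[:top]
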