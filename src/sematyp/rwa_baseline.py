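"""Random-walk baseline scorer.

A uniform random walk on the knowledge graph moves from a node to each of
its neighbors with probability 1/deg.  The transition matrix is M = D A,
with A the (simple, undirected) adjacency matrix and D = diag(1/deg); the
t-step occupancy is P_t = (M^T)^t P_0.  A candidate drug is scored for a
disease by making the disease absorbing and reading off the probability
of having reached it within t steps when starting at the drug.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .semkg import KnowledgeGraph

__all__ = [
    "TransitionMatrix",
    "WalkDistribution",
    "transition_matrix",
    "walk_distribution",
    "rwa_score",
    "make_rwa_scorer",
]

logger = logging.getLogger(__name__)


@dataclass
class TransitionMatrix:
    """Row-stochastic transition matrix plus the node index map."""

    matrix: np.ndarray
    nodes: tuple[str, ...]
    index: dict[str, int]
    absorbing: str | None = None


@dataclass
class WalkDistribution:
    """Occupancy probabilities over nodes after t steps."""

    probabilities: np.ndarray
    nodes: tuple[str, ...]
    step: int

    def probability_of(self, node: str) -> float:
        return float(self.probabilities[self.nodes.index(node)])


def transition_matrix(
    graph: KnowledgeGraph,
    absorbing: str | None = None,
    weighted: bool = False,
) -> TransitionMatrix:
    """Uniform-over-neighbors transitions on the simple undirected graph.

    Multi-edges are collapsed: p_ij = 1/deg(i) if i and j share any
    relation, 0 otherwise; isolated nodes keep zero rows (walk mass is
    lost there).  With ``weighted=True`` transitions are proportional to
    the pair's total predication count instead.  If ``absorbing`` is
    given, its row is replaced by a unit self-loop so occupancy at that
    node accumulates, turning the t-step occupancy into the probability
    of having reached the node within t steps.
    """
    nodes = tuple(sorted(graph.entities))
    if not nodes:
        raise ValueError("graph is empty")
    index = {n: i for i, n in enumerate(nodes)}
    if absorbing is not None and absorbing not in index:
        raise KeyError(f"absorbing node {absorbing!r} not in graph")
    n = len(nodes)
    mat = np.zeros((n, n))
    for node in nodes:
        i = index[node]
        neighbors = sorted(graph.neighbors(node))
        if not neighbors:
            continue
        if weighted:
            weights = np.array(
                [graph.edge_weight(node, other) for other in neighbors], float
            )
            row = weights / weights.sum()
        else:
            row = np.full(len(neighbors), 1.0 / len(neighbors))
        for other, p in zip(neighbors, row):
            mat[i, index[other]] = p
    if absorbing is not None:
        i = index[absorbing]
        mat[i, :] = 0.0
        mat[i, i] = 1.0
    return TransitionMatrix(matrix=mat, nodes=nodes, index=index, absorbing=absorbing)


def walk_distribution(tm: TransitionMatrix, start: str, t: int) -> WalkDistribution:
    """P_t = (M^T)^t P_0 with P_0 the unit mass at ``start``."""
    if t < 0:
        raise ValueError("t must be >= 0")
    if start not in tm.index:
        raise KeyError(f"start node {start!r} not in transition matrix")
    p = np.zeros(len(tm.nodes))
    p[tm.index[start]] = 1.0
    mt = tm.matrix.T
    for _ in range(t):
        p = mt @ p
    return WalkDistribution(probabilities=p, nodes=tm.nodes, step=t)


def rwa_score(
    graph: KnowledgeGraph,
    drug: str,
    disease: str,
    t: int,
    absorbing: bool = True,
) -> float:
    """Probability that a walk started at the drug reaches the disease
    within t steps (absorbing reading, default) or occupies it at exactly
    step t (``absorbing=False``); 0 when either node is missing."""
    if t < 1:
        raise ValueError("t must be >= 1")
    if drug not in graph or disease not in graph:
        logger.warning("rwa_score: %r or %r not in graph; score 0", drug, disease)
        return 0.0
    tm = transition_matrix(graph, absorbing=disease if absorbing else None)
    dist = walk_distribution(tm, drug, t)
    return dist.probability_of(disease)


def make_rwa_scorer(t: int, absorbing: bool = True):
    """Scorer factory for the rediscovery protocol.

    Returns a callable (graph, drug, disease, target_pool) -> score that
    caches the t-step matrix power per disease, so sweeping 100 candidate
    drugs per disease costs one matrix power instead of 100.
    """
    cache: dict[tuple[int, str], tuple[TransitionMatrix, np.ndarray]] = {}

    def scorer(graph, drug, disease, target_pool=None):
        if drug not in graph or disease not in graph:
            return 0.0
        key = (id(graph), disease)
        if key not in cache:
            tm = transition_matrix(graph, absorbing=disease if absorbing else None)
            cache[key] = (tm, np.linalg.matrix_power(tm.matrix, t))
        tm, power = cache[key]
        return float(power[tm.index[drug], tm.index[disease]])

    return scorer
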