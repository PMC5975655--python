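"""Enumeration of drug -> target -> disease paths in the knowledge graph.

A candidate therapy (drug, target, disease) is supported by the simple
paths from the drug to the disease that pass through the target, with
lengths from 2 (the direct drug-target-disease route) up to a maximum
``max_len``.  Shorter paths are later padded to ``max_len`` by repeating
the target node so that all feature vectors share one dimension.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator, Sequence

from .semkg import KnowledgeGraph

__all__ = [
    "Path",
    "PathSet",
    "enumerate_constrained_paths",
    "enumerate_paths",
    "extend_path",
    "MIN_PATH_LENGTH",
    "DEFAULT_MAX_PATHS",
]

MIN_PATH_LENGTH = 2
DEFAULT_MAX_PATHS = 10_000


@dataclass(frozen=True)
class Path:
    """A node sequence drug ... disease constrained through a target node.

    ``target_position`` indexes the (first) occurrence of the target.
    Before extension all nodes are distinct; after extension only the
    target repeats, in consecutive positions.
    """

    nodes: tuple[str, ...]
    target_position: int

    @property
    def length(self) -> int:
        """Number of edges."""
        return len(self.nodes) - 1

    @property
    def drug(self) -> str:
        return self.nodes[0]

    @property
    def disease(self) -> str:
        return self.nodes[-1]

    @property
    def target(self) -> str:
        return self.nodes[self.target_position]


@dataclass(frozen=True)
class PathSet:
    """Deduplicated collection of constrained paths, all lengths in 2..max_len."""

    paths: tuple[Path, ...]

    def __len__(self) -> int:
        return len(self.paths)

    def __iter__(self) -> Iterator[Path]:
        return iter(self.paths)

    def by_length(self, length: int) -> tuple[Path, ...]:
        return tuple(p for p in self.paths if p.length == length)


def _distances_within(
    graph: KnowledgeGraph, source: str, limit: int, directed: bool
) -> dict[str, int]:
    """BFS hop counts from ``source`` up to ``limit`` (undirected uses the
    symmetric adjacency; directed walks edges in reverse so the result is
    the distance *to* source along stored subject->object direction)."""
    if not directed:
        from scipy.sparse.csgraph import dijkstra

        mat, nodes, index = graph.csr_adjacency()
        if source not in index:
            return {}
        dist = dijkstra(
            mat, directed=False, unweighted=True,
            indices=index[source], limit=float(limit),
        )
        return {
            nodes[i]: int(d) for i, d in enumerate(dist) if d <= limit
        }
    if directed:
        # reverse adjacency for distance-to-source pruning
        radj: dict[str, set[str]] = {n: set() for n in graph.adjacency}
        for a, outs in graph.directed_adjacency.items():
            for b in outs:
                radj[b].add(a)
        neigh = radj.__getitem__
    else:
        neigh = lambda n: graph.adjacency.get(n, set())  # noqa: E731
    dist = {source: 0}
    frontier = [source]
    d = 0
    while frontier and d < limit:
        d += 1
        nxt = []
        for node in frontier:
            for other in neigh(node):
                if other not in dist:
                    dist[other] = d
                    nxt.append(other)
        frontier = nxt
    return dist


def enumerate_paths(
    graph: KnowledgeGraph,
    drug: str,
    disease: str,
    max_len: int,
    directed: bool = False,
    max_paths: int | None = DEFAULT_MAX_PATHS,
) -> list[tuple[str, ...]]:
    """All simple node sequences from drug to disease with 2..max_len edges,
    in lexicographic node-sequence order (no via-node constraint).

    The search is a depth-first traversal over sorted neighbor lists,
    pruned by breadth-first distance-to-disease, so enumeration order is
    deterministic and independent of insertion order.
    """
    if max_len < MIN_PATH_LENGTH:
        raise ValueError(f"max_len must be >= {MIN_PATH_LENGTH}, got {max_len}")
    if drug == disease:
        raise ValueError("drug and disease must differ")
    if drug not in graph or disease not in graph:
        return []
    dist_to_disease = _distances_within(graph, disease, max_len, directed)
    if drug not in dist_to_disease:
        return []
    results: list[tuple[str, ...]] = []
    stack: list[str] = [drug]
    on_path = {drug}

    def dfs() -> bool:
        """Return False when the path cap has been reached."""
        node = stack[-1]
        depth = len(stack) - 1
        neighbors = graph.neighbors(node, directed=directed)
        for nxt in sorted(neighbors):
            if nxt in on_path:
                continue
            remaining = max_len - depth - 1
            if nxt == disease:
                if depth + 1 >= MIN_PATH_LENGTH:
                    results.append(tuple(stack) + (disease,))
                    if max_paths is not None and len(results) >= max_paths:
                        return False
                continue
            if remaining < 1:
                continue
            if dist_to_disease.get(nxt, max_len + 1) > remaining:
                continue
            stack.append(nxt)
            on_path.add(nxt)
            ok = dfs()
            on_path.discard(nxt)
            stack.pop()
            if not ok:
                return False
        return True

    dfs()
    return results


def enumerate_constrained_paths(
    graph: KnowledgeGraph,
    drug: str,
    disease: str,
    target: str,
    max_len: int,
    directed: bool = False,
    max_paths: int | None = DEFAULT_MAX_PATHS,
    _dist_to_target: dict[str, int] | None = None,
    _dist_to_disease: dict[str, int] | None = None,
) -> PathSet:
    """All simple paths of length 2..max_len from drug to disease whose
    interior contains the target node, in lexicographic node order.

    Returns an empty PathSet when any of the three nodes is absent or when
    the target coincides with an endpoint (the target must be interior).
    The search prunes on breadth-first distances to the target and to the
    disease, so infeasible triples are rejected without exploring the
    neighborhood; callers sweeping many triples may pass precomputed
    distance maps.
    """
    if max_len < MIN_PATH_LENGTH:
        raise ValueError(f"max_len must be >= {MIN_PATH_LENGTH}, got {max_len}")
    if drug == disease:
        raise ValueError("drug and disease must differ")
    if target not in graph or target in (drug, disease):
        return PathSet(())
    if drug not in graph or disease not in graph:
        return PathSet(())
    dist_t = (
        _dist_to_target
        if _dist_to_target is not None
        else _distances_within(graph, target, max_len, directed)
    )
    dist_s = (
        _dist_to_disease
        if _dist_to_disease is not None
        else _distances_within(graph, disease, max_len, directed)
    )
    tail = dist_s.get(target, max_len + 1)  # target -> disease budget
    if dist_t.get(drug, max_len + 1) + tail > max_len:
        return PathSet(())

    results: list[Path] = []
    stack: list[str] = [drug]
    on_path = {drug}

    def dfs(target_pos: int | None) -> bool:
        node = stack[-1]
        depth = len(stack) - 1
        for nxt in sorted(graph.neighbors(node, directed=directed)):
            if nxt in on_path:
                continue
            used = depth + 1
            remaining = max_len - used
            if nxt == disease:
                if target_pos is not None and used >= MIN_PATH_LENGTH:
                    results.append(
                        Path(nodes=tuple(stack) + (disease,), target_position=target_pos)
                    )
                    if max_paths is not None and len(results) >= max_paths:
                        return False
                continue
            if remaining < 1:
                continue
            if target_pos is None:
                # must still pass through the target, then reach the disease
                to_target = 0 if nxt == target else dist_t.get(nxt, max_len + 1)
                bound = to_target + tail
            else:
                bound = dist_s.get(nxt, max_len + 1)
            if bound > remaining:
                continue
            stack.append(nxt)
            on_path.add(nxt)
            ok = dfs(used if nxt == target else target_pos)
            on_path.discard(nxt)
            stack.pop()
            if not ok:
                return False
        return True

    dfs(None)
    return PathSet(tuple(results))


def extend_path(path: Path, max_len: int) -> Path:
    """Pad a path to ``max_len`` edges by reduplicating the target node.

    The copies are inserted immediately after the original target position
    so the repeated targets are consecutive:
    (drug, target, disease) at max_len 4 becomes
    (drug, target, target, target, disease).  Featurization treats each
    inserted relation slot as a copy of the relation slot immediately
    preceding the original target.
    """
    if path.length > max_len:
        raise ValueError(
            f"path length {path.length} exceeds max_len {max_len}"
        )
    if path.length == max_len:
        return path
    n_copies = max_len - path.length
    pos = path.target_position
    nodes = (
        path.nodes[: pos + 1] + (path.target,) * n_copies + path.nodes[pos + 1 :]
    )
    return replace(path, nodes=nodes)


def paths_to_tsv(paths: Sequence[Path]) -> str:
    """Export paths as TSV: drug, disease, target, length, pipe-joined nodes."""
    lines = ["drug\tdisease\ttarget\tlength\tnodes"]
    for p in paths:
        lines.append(
            f"{p.drug}\t{p.disease}\t{p.target}\t{p.length}\t{'|'.join(p.nodes)}"
        )
    return "\n".join(lines) + "\n"
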