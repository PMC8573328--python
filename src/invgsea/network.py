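"""Interaction-network construction and MCODE core-module detection.

Networks come from STRING-style three-column edge lists (node, node,
combined score); only edges with combined score strictly above the
confidence threshold (default 0.4) are retained.  Core modules are found
with a from-scratch MCODE implementation: vertices are weighted by the
highest k-core of their closed neighborhood times that core's density,
complexes are grown greedily outward from high-weight seeds admitting
neighbors within a score window of the seed, and post-processing keeps
complexes containing a k-core and (with haircut on) trims members of
induced degree < 2.  A module's score is its induced density times its node
count.  Edge scores are used only for thresholding; the detection itself is
purely topological.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "InteractionNetwork",
    "McodeParams",
    "ModuleResult",
    "load_string_edges",
    "mcode_vertex_weight",
    "mcode_find_complexes",
    "module_report",
    "check_module_validity",
]

SCORE_THRESHOLD = 0.4


@dataclass
class InteractionNetwork:
    """Simple undirected graph with combined-score-weighted edges."""

    graph: nx.Graph
    score_threshold: float = SCORE_THRESHOLD

    def __post_init__(self) -> None:
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            raise ValueError(f"self-loops not allowed: {loops[:3]}")
        for u, v, s in self.graph.edges(data="combined_score", default=1.0):
            if not s > self.score_threshold:
                raise ValueError(
                    f"edge ({u}, {v}) score {s} not above {self.score_threshold}"
                )

    @classmethod
    def from_edges(
        cls,
        edges: list[tuple[str, str, float]],
        score_threshold: float = SCORE_THRESHOLD,
    ) -> "InteractionNetwork":
        g = nx.Graph()
        for u, v, s in sorted(edges):
            if u == v:
                continue
            if s > score_threshold:
                prev = g.edges[u, v]["combined_score"] if g.has_edge(u, v) else -1.0
                g.add_edge(u, v, combined_score=max(float(s), prev))
        return cls(g, score_threshold)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass(frozen=True)
class McodeParams:
    """The MCODE parameter panel (degree cutoff, node score cutoff, haircut,
    fluff, K-core, max depth); defaults are the conventional 2 / 0.2 / on /
    off / 2 / 100."""

    degree_cutoff: int = 2
    node_score_cutoff: float = 0.2
    haircut: bool = True
    fluff: bool = False
    k_core: int = 2
    max_depth: int = 100

    def __post_init__(self) -> None:
        if self.degree_cutoff < 1:
            raise ValueError("degree_cutoff must be >= 1")
        if not 0.0 <= self.node_score_cutoff <= 1.0:
            raise ValueError("node_score_cutoff must lie in [0, 1]")
        if self.k_core < 1:
            raise ValueError("k_core must be >= 1")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")


@dataclass
class ModuleResult:
    rank: int
    members: frozenset[str]
    n_nodes: int
    n_edges: int
    score: float
    seed_node: str


def load_string_edges(
    path: str | Path, score_threshold: float = SCORE_THRESHOLD
) -> InteractionNetwork:
    """Read a STRING-style edge list and apply the combined-score threshold.

    Accepts both score dialects: reals in [0, 1] and STRING's 0-1000
    integers (auto-detected — any score above 1 rescales the whole file by
    1/1000).  Reciprocal duplicate rows are collapsed (highest score wins),
    self-loops dropped, and only edges with score strictly above the
    threshold are retained.  An optional header row is tolerated.
    """
    path = Path(path)
    edges: list[tuple[str, str, float]] = []
    n_loops = 0
    lines = path.read_text().splitlines()
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(
                f"{path}:{lineno}: expected 3 tab-separated columns, got {len(parts)}"
            )
        u, v, raw = parts[0].strip().upper(), parts[1].strip().upper(), parts[2]
        try:
            s = float(raw)
        except ValueError:
            if lineno == 1:  # header row
                continue
            raise ValueError(
                f"{path}:{lineno}: non-numeric combined score {raw!r}"
            ) from None
        if not np.isfinite(s) or s < 0:
            raise ValueError(f"{path}:{lineno}: invalid combined score {s}")
        if u == v:
            n_loops += 1
            continue
        edges.append((u, v, s))

    if not edges:
        log.warning("%s: no edges parsed; returning an empty network", path)
        return InteractionNetwork(nx.Graph(), score_threshold)
    if n_loops:
        log.info("%s: dropped %d self-loop rows", path, n_loops)
    if max(s for _, _, s in edges) > 1.0:  # STRING 0-1000 integer dialect
        edges = [(u, v, s / 1000.0) for u, v, s in edges]
    edges = [(min(u, v), max(u, v), s) for u, v, s in edges]
    return InteractionNetwork.from_edges(edges, score_threshold)


def mcode_vertex_weight(
    net: InteractionNetwork | nx.Graph, params: McodeParams = McodeParams()
) -> dict[str, float]:
    """MCODE vertex weights: k_max of the closed neighborhood times the
    density of that highest k-core; nodes under the degree cutoff weigh 0."""
    g = net.graph if isinstance(net, InteractionNetwork) else net
    weights: dict[str, float] = {}
    for v in g.nodes:
        if g.degree(v) < params.degree_cutoff:
            weights[v] = 0.0
            continue
        nbhd = g.subgraph([v, *g.neighbors(v)])
        core_num = nx.core_number(nbhd)
        k_max = max(core_num.values())
        if k_max == 0:
            weights[v] = 0.0
            continue
        core = nbhd.subgraph([u for u, k in core_num.items() if k >= k_max])
        weights[v] = k_max * nx.density(core)
    return weights


def _grow_complex(
    g: nx.Graph,
    seed: str,
    weights: dict[str, float],
    assigned: set[str],
    params: McodeParams,
) -> set[str]:
    """Greedy outward growth: admit unassigned neighbors whose weight exceeds
    seed_weight * (1 - node_score_cutoff), up to max_depth from the seed."""
    threshold = weights[seed] * (1.0 - params.node_score_cutoff)
    members = {seed}
    queue = deque([(seed, 0)])
    examined = {seed}
    while queue:
        node, depth = queue.popleft()
        if depth >= params.max_depth:
            continue
        for nb in sorted(g.neighbors(node)):
            if nb in examined or nb in assigned:
                continue
            examined.add(nb)
            if weights[nb] > threshold:
                members.add(nb)
                queue.append((nb, depth + 1))
    return members


def mcode_find_complexes(
    net: InteractionNetwork | nx.Graph, params: McodeParams = McodeParams()
) -> list[ModuleResult]:
    """Detect core modules; deterministic, node-disjoint, sorted by score.

    Seeds are taken in descending weight (ties by node id).  Post-processing
    drops complexes lacking a ``k_core``-core; haircut reduces a complex to
    its 2-core; if post-processing disconnects a complex, the component
    containing the seed (else the largest, ties by smallest member id) is
    kept.  Score = induced density x node count.  The fluff option of the
    original algorithm is deliberately not implemented.
    """
    if params.fluff:
        raise NotImplementedError("fluff post-processing is not provided")
    g = net.graph if isinstance(net, InteractionNetwork) else net
    weights = mcode_vertex_weight(g, params)
    order = sorted(g.nodes, key=lambda v: (-weights[v], v))
    assigned: set[str] = set()
    raw: list[tuple[str, set[str]]] = []
    for seed in order:
        if seed in assigned or weights[seed] <= 0.0:
            continue
        members = _grow_complex(g, seed, weights, assigned, params)
        assigned |= members
        raw.append((seed, members))

    modules: list[ModuleResult] = []
    for seed, members in raw:
        sub = g.subgraph(members)
        if nx.k_core(sub, params.k_core).number_of_nodes() == 0:
            continue
        if params.haircut:
            sub = nx.k_core(sub, 2)
            if sub.number_of_nodes() == 0:
                continue
        if not nx.is_connected(sub):
            comps = sorted(
                nx.connected_components(sub), key=lambda c: (-len(c), min(c))
            )
            keep = next((c for c in comps if seed in c), comps[0])
            sub = sub.subgraph(keep)
        n, e = sub.number_of_nodes(), sub.number_of_edges()
        score = 0.0 if n < 2 else n * (2.0 * e / (n * (n - 1)))
        modules.append(
            ModuleResult(
                rank=0,
                members=frozenset(sub.nodes),
                n_nodes=n,
                n_edges=e,
                score=score,
                seed_node=seed,
            )
        )

    modules.sort(key=lambda m: (-m.score, -m.n_nodes, m.seed_node))
    for i, m in enumerate(modules, start=1):
        m.rank = i
    return modules


def check_module_validity(
    net: InteractionNetwork | nx.Graph, module: ModuleResult, params: McodeParams
) -> list[str]:
    """Independent post-hoc checker; returns a list of violations (empty = ok).

    Verifies edge-count consistency with the induced subgraph, connectivity,
    presence of a ``k_core``-core, the haircut degree bound, and the score
    formula.
    """
    g = net.graph if isinstance(net, InteractionNetwork) else net
    problems = []
    sub = g.subgraph(module.members)
    if sub.number_of_nodes() != module.n_nodes:
        problems.append("node count inconsistent with members")
    if sub.number_of_edges() != module.n_edges:
        problems.append("edge count inconsistent with induced subgraph")
    if module.n_nodes > 1 and not nx.is_connected(sub):
        problems.append("module not connected")
    if nx.k_core(sub, params.k_core).number_of_nodes() == 0:
        problems.append(f"module lacks a {params.k_core}-core")
    if params.haircut and any(d < 2 for _, d in sub.degree):
        problems.append("haircut violated: member with induced degree < 2")
    n, e = module.n_nodes, module.n_edges
    expect = 0.0 if n < 2 else n * (2.0 * e / (n * (n - 1)))
    if abs(expect - module.score) > 1e-9:
        problems.append("score is not density x node count")
    return problems


def module_report(
    modules: list[ModuleResult],
    top_k: int | None = None,
    loops_inclusive_density: bool = False,
) -> pd.DataFrame:
    """Tabular module summary: rank, score, n_nodes, n_edges, members.

    ``loops_inclusive_density`` reports the alternative score n*2E/(n(n+1))
    (the density variant that counts self-loop capacity) alongside.
    """
    if top_k is not None and top_k < 1:
        raise ValueError("top_k must be >= 1")
    rows = []
    for m in modules[: top_k if top_k is not None else len(modules)]:
        row = {
            "rank": m.rank,
            "score": round(m.score, 6),
            "n_nodes": m.n_nodes,
            "n_edges": m.n_edges,
            "members": ",".join(sorted(g.upper() for g in m.members)),
        }
        if loops_inclusive_density:
            row["score_loops_inclusive"] = round(
                m.n_nodes * 2.0 * m.n_edges / (m.n_nodes * (m.n_nodes + 1)), 6
            )
        rows.append(row)
    cols = ["rank", "score", "n_nodes", "n_edges", "members"]
    if loops_inclusive_density:
        cols.insert(4, "score_loops_inclusive")
    return pd.DataFrame(rows, columns=cols)
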