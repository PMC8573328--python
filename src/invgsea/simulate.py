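"""Synthetic two-contrast RNA-seq data with known ground truth.

The generator emulates the structure of a spiral-ganglion-neuron degeneration
study: contrast A (degeneration vs. control in wild-type animals) and
contrast B (double-knockout vs. wild-type, both under degeneration) share a
gene universe and a core of differentially expressed genes whose direction of
regulation is partially inverted between the two contrasts.  Counts are drawn
from a negative-binomial model with log-normally distributed gene-wise
baseline means.  Everything planted — the differential genes of each
contrast, the inverted core, dense interaction modules — is recorded in a
:class:`SimTruth` object so every downstream stage can be validated offline.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .genesets import GeneSet, GeneSetCollection

__all__ = [
    "SimDesign",
    "SimTruth",
    "simulate_two_contrast_counts",
    "simulate_gene_sets",
    "simulate_planted_module_graph",
    "write_counts_tsv",
    "write_group_map_tsv",
    "write_network_tsv",
]

# sigma of the log-normal spread of gene-wise baseline means (natural-log
# scale); one unit gives roughly a 10-fold interquartile spread, typical of
# bulk RNA-seq abundance distributions
_BASELINE_SIGMA = 1.0


@dataclass(frozen=True)
class SimDesign:
    """Parameters of a two-contrast count simulation.

    Defaults are the package's standard desk-scale study conditions: 2000
    genes, 200 truly differential genes at |log2FC| = 1, negative-binomial
    dispersion 0.1 (biological CV ~0.32, typical of inbred-mouse replicates),
    six biological replicates per group, and half of the contrast-A effects
    inverted in contrast B.
    """

    n_genes: int = 2000
    n_samples_per_group: int = 6
    n_de: int = 200
    lfc_magnitude: float = 1.0
    dispersion: float = 0.1
    baseline_mean: float = 200.0
    inversion_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_samples_per_group < 1:
            raise ValueError("n_genes and n_samples_per_group must be positive")
        if not 0 <= self.n_de <= self.n_genes:
            raise ValueError(f"n_de must lie in [0, n_genes], got {self.n_de}")
        for name in ("lfc_magnitude", "dispersion", "baseline_mean"):
            v = float(getattr(self, name))
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative, got {v}")
        if not 0.0 <= self.inversion_fraction <= 1.0:
            raise ValueError(
                f"inversion_fraction must lie in [0, 1], got {self.inversion_fraction}"
            )


@dataclass
class SimTruth:
    """Planted structure of a simulation run.

    ``de_genes_A`` / ``de_genes_B`` map gene id -> direction (+1 up, -1 down)
    in the respective contrast; ``inverted_genes`` are the genes whose
    direction differs between the two maps; ``planted_modules`` lists the
    member sets of dense subgraphs planted into an interaction network.
    """

    de_genes_A: dict[str, int] = field(default_factory=dict)
    de_genes_B: dict[str, int] = field(default_factory=dict)
    inverted_genes: list[str] = field(default_factory=list)
    planted_modules: list[list[str]] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        return cls(**json.loads(Path(path).read_text()))


def _gene_ids(n: int) -> np.ndarray:
    width = max(5, len(str(n)))
    return np.array([f"G{i:0{width}d}" for i in range(1, n + 1)])


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draws parameterised by mean and dispersion alpha.

    var = mu + alpha * mu^2; alpha -> 0 degenerates to Poisson.
    """
    if dispersion == 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_two_contrast_counts(
    design: SimDesign,
) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Simulate count matrices for both contrasts plus the planted truth.

    Returns ``(counts_A, counts_B, truth)`` where each counts frame is genes
    x samples with sample columns named ``{A,B}_{ctrl,trt}_{i}``.  Contrast A
    plants ``n_de`` effects of +/- ``lfc_magnitude`` on the log2 scale in its
    treated group; contrast B reuses the same genes and baseline means but
    flips the direction of ``round(inversion_fraction * n_de)`` of them (a
    deterministic prefix of the planted gene list, so designs differing only
    in the inversion fraction are nested).
    """
    rng = np.random.default_rng(design.seed)
    genes = _gene_ids(design.n_genes)
    n = design.n_samples_per_group

    base = design.baseline_mean * rng.lognormal(
        -0.5 * _BASELINE_SIGMA**2, _BASELINE_SIGMA, design.n_genes
    )

    de_idx = rng.choice(design.n_genes, size=design.n_de, replace=False)
    signs_a = rng.choice([1, -1], size=design.n_de)
    n_inv = int(round(design.inversion_fraction * design.n_de))
    signs_b = signs_a.copy()
    signs_b[:n_inv] *= -1

    fc_a = np.ones(design.n_genes)
    fc_b = np.ones(design.n_genes)
    fc_a[de_idx] = 2.0 ** (signs_a * design.lfc_magnitude)
    fc_b[de_idx] = 2.0 ** (signs_b * design.lfc_magnitude)

    def matrix(prefix: str, fc: np.ndarray) -> pd.DataFrame:
        mean_ctrl = np.repeat(base[:, None], n, axis=1)
        mean_trt = np.repeat((base * fc)[:, None], n, axis=1)
        ctrl = _nb_counts(rng, mean_ctrl, design.dispersion)
        trt = _nb_counts(rng, mean_trt, design.dispersion)
        cols = [f"{prefix}_ctrl_{i}" for i in range(1, n + 1)] + [
            f"{prefix}_trt_{i}" for i in range(1, n + 1)
        ]
        return pd.DataFrame(np.hstack([ctrl, trt]), index=genes, columns=cols)

    counts_a = matrix("A", fc_a)
    counts_b = matrix("B", fc_b)

    order = np.argsort(de_idx, kind="stable")  # report truth in gene order
    truth = SimTruth(
        de_genes_A={genes[de_idx[i]]: int(signs_a[i]) for i in order},
        de_genes_B={genes[de_idx[i]]: int(signs_b[i]) for i in order},
        inverted_genes=sorted(genes[de_idx[:n_inv]]),
    )
    return counts_a, counts_b, truth


def simulate_gene_sets(
    universe: list[str] | np.ndarray,
    n_sets: int,
    set_size_range: tuple[int, int] = (15, 200),
    spike_set: GeneSet | None = None,
    seed: int = 0,
) -> GeneSetCollection:
    """Random gene-set collection over ``universe`` (GO/KEGG-like sizes).

    Sets are sampled without replacement; ``spike_set`` (if given) is included
    verbatim under its own name, ahead of the random sets.
    """
    universe = list(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    lo, hi = set_size_range
    if not 1 <= lo <= hi:
        raise ValueError(f"invalid set_size_range {set_size_range}")
    if hi > len(universe):
        raise ValueError("set sizes cannot exceed the universe size")
    rng = np.random.default_rng(seed)
    sets: list[GeneSet] = []
    if spike_set is not None:
        sets.append(spike_set)
    width = max(4, len(str(n_sets)))
    for i in range(1, n_sets + 1):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(universe), size=size, replace=False)
        sets.append(
            GeneSet(
                name=f"RANDOM_SET_{i:0{width}d}",
                members=frozenset(universe[j] for j in members),
                description="synthetic random set",
            )
        )
    return GeneSetCollection(sets)


def simulate_planted_module_graph(
    n_nodes: int,
    background_edge_prob: float,
    modules: list[tuple[int, float]],
    seed: int = 0,
    nodes: list[str] | None = None,
) -> tuple[nx.Graph, list[list[str]]]:
    """Erdős–Rényi background with planted dense subgraphs.

    Each ``(size, within_density)`` module occupies a disjoint block of
    nodes; inside a block every pair is connected independently with
    probability ``within_density`` (background edges inside the block are
    discarded first, so the internal edge probability is exactly the
    requested density).  Edge ``combined_score`` attributes are drawn uniform
    in (0.4, 1] so the whole graph survives the STRING-style score threshold.

    Returns the graph and the list of planted member lists.
    """
    if not 0.0 <= background_edge_prob <= 1.0:
        raise ValueError("background_edge_prob must lie in [0, 1]")
    for size, dens in modules:
        if size > n_nodes:
            raise ValueError(f"module size {size} exceeds n_nodes {n_nodes}")
        if not background_edge_prob < dens <= 1.0:
            raise ValueError(
                "within_density must exceed background_edge_prob and be <= 1"
            )
    if sum(size for size, _ in modules) > n_nodes:
        raise ValueError("planted modules exceed the node budget")
    if nodes is None:
        width = max(4, len(str(n_nodes)))
        nodes = [f"N{i:0{width}d}" for i in range(1, n_nodes + 1)]
    elif len(nodes) < n_nodes:
        raise ValueError("not enough node names supplied")
    nodes = [str(v).upper() for v in nodes[:n_nodes]]

    rng = np.random.default_rng(seed)
    g = nx.Graph()
    g.add_nodes_from(nodes)
    bg = nx.gnp_random_graph(
        n_nodes, background_edge_prob, seed=int(rng.integers(2**31))
    )
    g.add_edges_from((nodes[u], nodes[v]) for u, v in bg.edges)

    planted: list[list[str]] = []
    offset = 0
    for size, dens in modules:
        block = nodes[offset : offset + size]
        offset += size
        g.remove_edges_from(
            [(u, v) for u, v in g.edges(block) if u in block and v in block]
        )
        for i in range(size):
            for j in range(i + 1, size):
                if rng.random() < dens:
                    g.add_edge(block[i], block[j])
        planted.append(list(block))

    for u, v in g.edges:
        # strictly above the 0.4 threshold
        g.edges[u, v]["combined_score"] = float(0.4 + 0.6 * (1.0 - rng.random()))
    return g, planted


# ---------------------------------------------------------------------------
# plain-text writers (TSV / STRING-style exports)

def write_counts_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    """Genes-in-rows TSV with a leading ``gene`` column."""
    out = counts.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


def write_group_map_tsv(group_map: dict[str, str], path: str | Path) -> None:
    df = pd.DataFrame(
        {"sample": list(group_map), "group": [group_map[s] for s in group_map]}
    )
    df.to_csv(path, sep="\t", index=False)


def write_network_tsv(graph: nx.Graph, path: str | Path) -> None:
    """Three-column STRING-export-style edge list (node1, node2, combined_score)."""
    rows = sorted(
        (min(u, v), max(u, v), graph.edges[u, v].get("combined_score", 1.0))
        for u, v in graph.edges
    )
    with open(path, "w") as fh:
        fh.write("node1\tnode2\tcombined_score\n")
        for u, v, s in rows:
            fh.write(f"{u}\t{v}\t{s:.6f}\n")
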