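"""Weighted running-sum gene-set enrichment with permutation nulls.

The enrichment score (ES) of a gene set S against a ranked list L of N genes
is the signed maximum deviation between two cumulative distributions walked
along L: the hit distribution P_hit, which accumulates |r_j|^w over members
of S (normalized by the total over all members), and the miss distribution
P_miss, which accumulates 1/(N - N_h) over non-members.  Positive ES means S
concentrates at the top of the list, negative at the bottom; |ES| equals the
maximum of |P_hit - P_miss|, and at w = 0 it reduces to the classical
two-sample Kolmogorov-Smirnov statistic between hit and miss ranks.

Significance is assessed by permutation: *phenotype* permutations shuffle the
sample-to-group labels and recompute the ranking (preserving inter-gene
correlation), *gene-set* permutations rescore random sets of the same size on
the fixed ranking.  The p-value is the add-one estimator over permutations
whose ES sign matches the observed sign, and NES is the observed ES divided
by the mean |ES*| of those same-sign permutations.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .dge import RankedList, rank_genes
from .expression import ExpressionMatrix
from .genesets import GeneSet, GeneSetCollection

log = logging.getLogger(__name__)

__all__ = [
    "EnrichmentProfile",
    "EnrichmentResult",
    "compute_es",
    "leading_edge",
    "permutation_test",
    "enrich_collection",
    "write_enrichment_tsv",
    "write_running_score_tsv",
]

#: sentinel reported when fewer than 2 same-sign permutations exist
NES_UNDEFINED = float("nan")

PERMUTATION_MODES = ("phenotype", "gene_set")


@dataclass
class EnrichmentProfile:
    """Running score of one gene set along one ranked list."""

    running_score: np.ndarray  # length N, value of P_hit - P_miss after rank i
    es: float
    es_position: int  # 1-based rank position attaining the extreme
    weight_exponent: float
    set_name: str = ""

    @property
    def n(self) -> int:
        return len(self.running_score)


@dataclass
class EnrichmentResult:
    set_name: str
    es: float
    nes: float
    p_value: float
    fdr_q: float = float("nan")
    leading_edge: frozenset[str] = field(default_factory=frozenset)
    n_permutations: int = 0
    permutation_mode: str = "phenotype"
    n_hits: int = 0


def _hit_mask(ranked: RankedList, members: frozenset[str]) -> np.ndarray:
    return np.fromiter((g in members for g in ranked.genes), dtype=bool, count=ranked.N)


def _es_core(
    scores: np.ndarray, hits: np.ndarray, w: float
) -> tuple[np.ndarray, float, int]:
    """Running score, signed ES, and 1-based extreme position.

    ``scores`` are the ranking metric in list order; ``hits`` the membership
    mask.  Raises if the set covers nothing or everything, or if all hit
    weights are zero with w > 0.
    """
    n = scores.size
    n_h = int(hits.sum())
    if n_h == 0:
        raise ValueError("gene set has no members in the ranked list")
    if n_h == n:
        raise ValueError("gene set covers the whole ranked list (N - N_h = 0)")
    if w == 0:
        weights = hits.astype(float)
    else:
        weights = np.where(hits, np.abs(scores) ** w, 0.0)
    total = weights.sum()
    if total <= 0:
        raise ValueError(
            "degenerate normalizer: all |r|^w are zero over the gene set"
        )
    p_hit = np.cumsum(weights) / total
    p_miss = np.cumsum(~hits) / (n - n_h)
    running = p_hit - p_miss
    pos = int(np.argmax(np.abs(running)))  # first extreme -> deterministic
    return running, float(running[pos]), pos + 1


def compute_es(
    ranked: RankedList, gene_set: GeneSet, w: float = 1.0
) -> EnrichmentProfile:
    """Enrichment profile of ``gene_set`` against ``ranked`` with weight ``w``."""
    if w < 0:
        raise ValueError("weight exponent w must be >= 0")
    members = (
        gene_set.members if isinstance(gene_set, GeneSet) else frozenset(gene_set)
    )
    running, es, pos = _es_core(ranked.scores, _hit_mask(ranked, members), w)
    assert abs(running[-1]) < 1e-9, "running score must terminate at 0"
    return EnrichmentProfile(
        running_score=running,
        es=es,
        es_position=pos,
        weight_exponent=w,
        set_name=getattr(gene_set, "name", ""),
    )


def leading_edge(
    profile: EnrichmentProfile, ranked: RankedList, gene_set: GeneSet
) -> frozenset[str]:
    """Set members at or before the extreme (after it, for negative ES)."""
    members = (
        gene_set.members if isinstance(gene_set, GeneSet) else frozenset(gene_set)
    )
    if profile.es == 0:
        return frozenset()
    if profile.es > 0:
        genes = ranked.genes[: profile.es_position]
    else:
        genes = ranked.genes[profile.es_position - 1 :]
    return frozenset(g for g in genes if g in members)


def _p_and_nes(es: float, perm_es: np.ndarray) -> tuple[float, float, int]:
    """Add-one permutation p-value and mean-|ES*| normalization, sign-matched."""
    if es == 0:
        return 1.0, 0.0, 0
    same = perm_es[np.sign(perm_es) == np.sign(es)]
    n_same = same.size
    p = (1.0 + float((np.abs(same) >= abs(es)).sum())) / (1.0 + n_same)
    if n_same < 2:
        warnings.warn(
            "fewer than 2 same-sign permutations: NES undefined", RuntimeWarning
        )
        return p, NES_UNDEFINED, n_same
    return p, float(es / np.abs(same).mean()), n_same


def _phenotype_rankings(
    expr: ExpressionMatrix,
    treated: str,
    reference: str,
    n_permutations: int,
    seed: int,
    metric: str,
) -> list[RankedList]:
    """Ranked lists under random reassignments of the group labels."""
    rng = np.random.default_rng(seed)
    st = expr.group_samples(treated)
    sr = expr.group_samples(reference)
    cols = st + sr
    sub = expr.values[cols]
    n_t = len(st)
    out = []
    for _ in range(n_permutations):
        perm = rng.permutation(len(cols))
        gm = {
            cols[j]: (treated if i < n_t else reference)
            for i, j in enumerate(perm)
        }
        out.append(
            rank_genes(ExpressionMatrix(sub, gm), treated, reference, metric=metric)
        )
    return out


def _gene_set_null(
    ranked: RankedList, n_h: int, w: float, n_permutations: int, seed: int
) -> tuple[np.ndarray, bool]:
    """Null ES values for random same-size sets on a fixed ranking.

    Enumerates *all* size-n_h subsets when there are no more of them than the
    requested number of permutations (the estimator is then exact); otherwise
    draws random subsets.  Returns (es values, exact flag).
    """
    n = ranked.N
    n_subsets = math.comb(n, n_h)
    if n_subsets <= n_permutations:
        es = np.empty(n_subsets)
        for i, idx in enumerate(combinations(range(n), n_h)):
            hits = np.zeros(n, dtype=bool)
            hits[list(idx)] = True
            es[i] = _es_core(ranked.scores, hits, w)[1]
        return es, True
    rng = np.random.default_rng(seed)
    es = np.empty(n_permutations)
    hits = np.zeros(n, dtype=bool)
    for i in range(n_permutations):
        idx = rng.choice(n, size=n_h, replace=False)
        hits[:] = False
        hits[idx] = True
        es[i] = _es_core(ranked.scores, hits, w)[1]
    return es, False


def permutation_test(
    gene_set: GeneSet,
    *,
    ranked: RankedList | None = None,
    expr: ExpressionMatrix | None = None,
    treated: str | None = None,
    reference: str | None = None,
    n_permutations: int = 1000,
    mode: str = "phenotype",
    seed: int | None = None,
    w: float = 1.0,
    metric: str = "signal_to_noise",
) -> EnrichmentResult:
    """ES, permutation p-value, NES and leading edge for one gene set.

    Phenotype mode needs ``expr`` with the two group labels (the observed
    ranking is derived from them if ``ranked`` is not given); gene-set mode
    needs only ``ranked``.
    """
    if mode not in PERMUTATION_MODES:
        raise ValueError(f"unknown mode {mode!r}; valid: {PERMUTATION_MODES}")
    if n_permutations < 10:
        raise ValueError("n_permutations must be >= 10")
    if seed is None:
        raise ValueError("a seed is required for permutation testing")
    if mode == "phenotype" and expr is None:
        raise ValueError("phenotype mode requires an expression matrix")
    if ranked is None:
        if expr is None:
            raise ValueError("either ranked or expr must be provided")
        ranked = rank_genes(expr, treated, reference, metric=metric)

    profile = compute_es(ranked, gene_set, w=w)
    n_h = int(_hit_mask(ranked, gene_set.members).sum())

    if mode == "phenotype":
        perm_es = np.array(
            [
                compute_es(rk, gene_set, w=w).es
                for rk in _phenotype_rankings(
                    expr, treated, reference, n_permutations, seed, metric
                )
            ]
        )
        n_perm_done = n_permutations
    else:
        perm_es, exact = _gene_set_null(ranked, n_h, w, n_permutations, seed)
        n_perm_done = perm_es.size
        if exact:
            # exhaustive null: the observed set is itself one of the subsets,
            # so the plain proportion is already a valid (exact) p-value
            same = perm_es[np.sign(perm_es) == np.sign(profile.es)]
            p = float((np.abs(same) >= abs(profile.es)).sum()) / max(1, same.size)
            nes = (
                float(profile.es / np.abs(same).mean())
                if same.size >= 2
                else NES_UNDEFINED
            )
            return EnrichmentResult(
                set_name=gene_set.name,
                es=profile.es,
                nes=nes,
                p_value=p if profile.es != 0 else 1.0,
                leading_edge=leading_edge(profile, ranked, gene_set),
                n_permutations=n_perm_done,
                permutation_mode=mode,
                n_hits=n_h,
            )

    p, nes, _ = _p_and_nes(profile.es, perm_es)
    return EnrichmentResult(
        set_name=gene_set.name,
        es=profile.es,
        nes=nes,
        p_value=p,
        leading_edge=leading_edge(profile, ranked, gene_set),
        n_permutations=n_perm_done,
        permutation_mode=mode,
        n_hits=n_h,
    )


def enrich_collection(
    collection: GeneSetCollection,
    *,
    ranked: RankedList | None = None,
    expr: ExpressionMatrix | None = None,
    treated: str | None = None,
    reference: str | None = None,
    n_permutations: int = 1000,
    mode: str = "phenotype",
    seed: int | None = None,
    w: float = 1.0,
    metric: str = "signal_to_noise",
    min_size: int = 5,
    max_size: int = 500,
) -> list[EnrichmentResult]:
    """Enrichment of every retained set in a collection, with BH FDR.

    Sets are first filtered by their overlap with the ranked universe
    (``min_size`` <= N_h <= ``max_size``).  In phenotype mode the permuted
    rankings are computed once and shared by all sets.  Results are sorted by
    NES, descending.
    """
    if mode not in PERMUTATION_MODES:
        raise ValueError(f"unknown mode {mode!r}; valid: {PERMUTATION_MODES}")
    if n_permutations < 10:
        raise ValueError("n_permutations must be >= 10")
    if seed is None:
        raise ValueError("a seed is required for permutation testing")
    if ranked is None:
        if expr is None:
            raise ValueError("either ranked or expr must be provided")
        ranked = rank_genes(expr, treated, reference, metric=metric)

    universe = set(ranked.genes)
    retained = collection.filter_by_size(universe, min_size, max_size)
    if len(retained) == 0:
        raise ValueError(
            f"no gene sets left after the size filter [{min_size}, {max_size}]"
        )
    log.info("testing %d of %d gene sets", len(retained), len(collection))

    results: list[EnrichmentResult] = []
    if mode == "phenotype":
        if expr is None:
            raise ValueError("phenotype mode requires an expression matrix")
        perm_ranked = _phenotype_rankings(
            expr, treated, reference, n_permutations, seed, metric
        )
        # shared positional encoding: gene -> universal id, then per permuted
        # ranking the rank position of every universal id
        gene_ids = {g: i for i, g in enumerate(ranked.genes)}
        n = ranked.N
        perm_pos = np.empty((len(perm_ranked), n), dtype=np.intp)
        for k, rk in enumerate(perm_ranked):
            for j, g in enumerate(rk.genes):
                perm_pos[k, gene_ids[g]] = j
        for gs in retained:
            profile = compute_es(ranked, gs, w=w)
            member_ids = np.array(
                [gene_ids[g] for g in gs.members if g in gene_ids], dtype=np.intp
            )
            perm_es = np.empty(len(perm_ranked))
            hits = np.zeros(n, dtype=bool)
            for k, rk in enumerate(perm_ranked):
                hits[:] = False
                hits[perm_pos[k, member_ids]] = True
                perm_es[k] = _es_core(rk.scores, hits, w)[1]
            p, nes, _ = _p_and_nes(profile.es, perm_es)
            results.append(
                EnrichmentResult(
                    set_name=gs.name,
                    es=profile.es,
                    nes=nes,
                    p_value=p,
                    leading_edge=leading_edge(profile, ranked, gs),
                    n_permutations=n_permutations,
                    permutation_mode=mode,
                    n_hits=len(gs.members & universe),
                )
            )
    else:
        rng = np.random.default_rng(seed)
        for gs in retained:
            results.append(
                permutation_test(
                    gs,
                    ranked=ranked,
                    n_permutations=n_permutations,
                    mode="gene_set",
                    seed=int(rng.integers(2**31)),
                    w=w,
                )
            )

    from statsmodels.stats.multitest import multipletests

    q = multipletests([r.p_value for r in results], method="fdr_bh")[1]
    for r, qv in zip(results, q):
        r.fdr_q = float(qv)
    results.sort(key=lambda r: (-(r.nes if np.isfinite(r.nes) else -np.inf), r.set_name))
    return results


# ---------------------------------------------------------------------------
# I/O

def write_enrichment_tsv(results: list[EnrichmentResult], path: str | Path) -> None:
    rows = [
        {
            "set": r.set_name,
            "size": r.n_hits,
            "es": r.es,
            "nes": r.nes,
            "p": r.p_value,
            "fdr": r.fdr_q,
            "leading_edge": ";".join(sorted(r.leading_edge)),
        }
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_running_score_tsv(profile: EnrichmentProfile, path: str | Path) -> None:
    """Plain (rank, running score) pairs for curve plotting elsewhere."""
    pd.DataFrame(
        {"rank": np.arange(1, profile.n + 1), "running_score": profile.running_score}
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")
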