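"""Cross-contrast inverted enrichment.

Contrast A (degeneration vs. control) defines the degeneration-specific
(PAND) gene set: its up- and down-regulated genes at the differential-call
thresholds.  That set is then scored, direction-aware, against contrast B's
ranked list (knockout vs. wild type under degeneration): each A-up gene keeps
its contrast-B ranking metric, each A-down gene contributes the negated
metric, the modified list is re-ranked and the weighted running-sum ES of the
combined set is computed.  Concordant regulation therefore accumulates the
set at the top of the list (positive ES/NES); systematically reversed
regulation drives it to the bottom (negative ES/NES) — the "inverted
enrichment" signature.  Exact set arithmetic over the shared gene universe
additionally counts the genes whose up/down call flips between contrasts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dge import DgeResult, RankedList
from .enrichment import (
    NES_UNDEFINED,
    _es_core,
    _p_and_nes,
    _phenotype_rankings,
)
from .expression import ExpressionMatrix
from .genesets import GeneSet, SignedGeneSet

log = logging.getLogger(__name__)

__all__ = [
    "ContrastPair",
    "InversionReport",
    "build_pand_gene_set",
    "inverted_enrichment",
    "inversion_table",
    "write_inversion_table",
]


@dataclass
class ContrastPair:
    """The two contrasts entering the inversion analysis.

    ``expr_B`` plus its group labels are optional; when present they enable
    phenotype permutations for the inverted-enrichment p-value, otherwise
    gene-set permutations on ``ranked_B`` are used.
    """

    dge_A: DgeResult
    dge_B: DgeResult
    ranked_B: RankedList
    expr_B: ExpressionMatrix | None = None
    treated_B: str | None = None
    reference_B: str | None = None

    @property
    def shared_universe(self) -> frozenset[str]:
        return frozenset(self.dge_A.genes) & frozenset(self.ranked_B.genes) & frozenset(
            self.dge_B.genes
        )


@dataclass
class InversionReport:
    n_up_A: int
    n_up_A_down_B: int
    n_down_A: int
    n_down_A_up_B: int
    es: float
    nes: float
    p_value: float
    table: pd.DataFrame  # gene, call_A, call_B, inverted
    n_permutations: int = 0
    permutation_mode: str = "phenotype"
    unsigned_nes: float = field(default=float("nan"))

    @property
    def n_inverted(self) -> int:
        return self.n_up_A_down_B + self.n_down_A_up_B


def build_pand_gene_set(
    dge_A: DgeResult,
) -> tuple[GeneSet, GeneSet, SignedGeneSet]:
    """Degeneration-specific gene sets from contrast A's differential calls.

    Returns (up_set, down_set, signed_set); the signed set records the
    per-gene direction for direction-aware scoring.
    """
    up = dge_A.genes_called("up")
    down = dge_A.genes_called("down")
    if not up and not down:
        raise ValueError(
            "contrast A has no differential genes; review the p-value and "
            "fold-change thresholds before building the degeneration set"
        )
    directions = {g: 1 for g in up} | {g: -1 for g in down}
    return (
        GeneSet("PAND_UP", frozenset(up), "contrast-A upregulated genes"),
        GeneSet("PAND_DOWN", frozenset(down), "contrast-A downregulated genes"),
        SignedGeneSet("PAND_SIGNED", directions, "direction-aware contrast-A set"),
    )


def _signed_ranking(
    ranked: RankedList, down_genes: frozenset[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Re-rank after negating the metric of the down-direction genes.

    Returns (scores in new order, hit positions bool mask placeholder) — the
    caller supplies the membership mask against the new order.
    """
    scores = np.where(
        np.fromiter((g in down_genes for g in ranked.genes), bool, ranked.N),
        -ranked.scores,
        ranked.scores,
    )
    order = np.lexsort((ranked.genes.astype(str), -scores))
    return ranked.genes[order], scores[order]


def _directional_es(
    ranked: RankedList, signed_set: SignedGeneSet, w: float
) -> tuple[float, int]:
    """Signed-set ES against a ranked list; returns (es, N_h)."""
    down = frozenset(g for g, d in signed_set.directions.items() if d < 0)
    genes, scores = _signed_ranking(ranked, down)
    members = signed_set.members
    hits = np.fromiter((g in members for g in genes), bool, len(genes))
    running, es, _ = _es_core(scores, hits, w)
    return es, int(hits.sum())


def inverted_enrichment(
    pair: ContrastPair,
    n_permutations: int = 1000,
    seed: int | None = None,
    w: float = 1.0,
    mode: str | None = None,
) -> InversionReport:
    """Direction-aware enrichment of contrast A's DEG set in contrast B.

    ``mode`` defaults to phenotype permutations when ``pair.expr_B`` is
    available, else gene-set permutations.  Also reports the unsigned variant
    (the A-up set alone against ranked_B) and the exact cross-contrast
    direction-flip counts.
    """
    if seed is None:
        raise ValueError("a seed is required for permutation testing")
    if n_permutations < 10:
        raise ValueError("n_permutations must be >= 10")
    universe = pair.shared_universe
    if not universe:
        raise ValueError("empty shared gene universe between the two contrasts")

    up_set, down_set, signed_set = build_pand_gene_set(pair.dge_A)
    pand = signed_set.members
    coverage = len(pand & universe) / len(pand)
    if coverage < 0.9:
        warnings.warn(
            f"shared universe covers only {coverage:.0%} of the degeneration set",
            RuntimeWarning,
        )
    dropped = len(pand) - len(pand & universe)
    if dropped:
        log.info("dropped %d degeneration-set genes absent from contrast B", dropped)

    # restrict the ranked list to the shared universe
    keep = np.fromiter((g in universe for g in pair.ranked_B.genes), bool,
                       pair.ranked_B.N)
    ranked_b = RankedList(
        pair.ranked_B.genes[keep], pair.ranked_B.scores[keep],
        metric=pair.ranked_B.metric,
    )
    signed_shared = SignedGeneSet(
        signed_set.name,
        {g: d for g, d in signed_set.directions.items() if g in universe},
    )

    if mode is None:
        mode = "phenotype" if pair.expr_B is not None else "gene_set"
    if mode == "phenotype" and pair.expr_B is None:
        raise ValueError("phenotype mode requires expr_B on the contrast pair")

    es, n_h = _directional_es(ranked_b, signed_shared, w)

    if mode == "phenotype":
        perm_rankings = _phenotype_rankings(
            pair.expr_B, pair.treated_B, pair.reference_B,
            n_permutations, seed, ranked_b.metric
            if ranked_b.metric in ("signal_to_noise", "log2fc")
            else "signal_to_noise",
        )
        perm_es = np.empty(n_permutations)
        for k, rk in enumerate(perm_rankings):
            keep_k = np.fromiter((g in universe for g in rk.genes), bool, rk.N)
            rk_shared = RankedList(rk.genes[keep_k], rk.scores[keep_k])
            perm_es[k] = _directional_es(rk_shared, signed_shared, w)[0]
    else:
        # random signed sets: the observed direction multiset assigned to
        # random genes of the shared universe
        rng = np.random.default_rng(seed)
        dirs = np.array(sorted(signed_shared.directions.values()))
        genes_arr = np.array(sorted(universe), dtype=object)
        perm_es = np.empty(n_permutations)
        for k in range(n_permutations):
            pick = rng.choice(genes_arr.size, size=dirs.size, replace=False)
            rng.shuffle(dirs)
            rand_set = SignedGeneSet(
                "null", dict(zip(genes_arr[pick], (int(d) for d in dirs)))
            )
            perm_es[k] = _directional_es(ranked_b, rand_set, w)[0]

    p, nes, _ = _p_and_nes(es, perm_es)

    # unsigned comparison variant: A-up set alone against ranked_B
    unsigned_nes = NES_UNDEFINED
    up_shared = up_set.members & universe
    if 0 < len(up_shared) < ranked_b.N:
        hits = np.fromiter((g in up_shared for g in ranked_b.genes), bool, ranked_b.N)
        es_u = _es_core(ranked_b.scores, hits, w)[1]
        _, unsigned_nes, _ = _p_and_nes(
            es_u,
            np.array(
                [
                    _es_core(ranked_b.scores, _random_mask(ranked_b.N, hits.sum(), i),
                             w)[1]
                    for i in np.random.default_rng(seed).integers(2**31, size=100)
                ]
            ),
        )

    table, counts = _inversion_counts(pair, universe)
    return InversionReport(
        n_up_A=counts["n_up_A"],
        n_up_A_down_B=counts["n_up_A_down_B"],
        n_down_A=counts["n_down_A"],
        n_down_A_up_B=counts["n_down_A_up_B"],
        es=es,
        nes=nes,
        p_value=p,
        table=table,
        n_permutations=n_permutations,
        permutation_mode=mode,
        unsigned_nes=unsigned_nes,
    )


def _random_mask(n: int, n_h: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(int(seed))
    mask = np.zeros(n, dtype=bool)
    mask[rng.choice(n, size=int(n_h), replace=False)] = True
    return mask


def _inversion_counts(
    pair: ContrastPair, universe: frozenset[str]
) -> tuple[pd.DataFrame, dict[str, int]]:
    genes = sorted(universe)
    call_a = pair.dge_A.table.loc[genes, "call"]
    call_b = pair.dge_B.table.loc[genes, "call"]
    inverted = ((call_a == "up") & (call_b == "down")) | (
        (call_a == "down") & (call_b == "up")
    )
    table = pd.DataFrame(
        {
            "gene": genes,
            "call_A": call_a.to_numpy(),
            "call_B": call_b.to_numpy(),
            "inverted": inverted.to_numpy(),
        }
    )
    counts = {
        "n_up_A": int((call_a == "up").sum()),
        "n_up_A_down_B": int(((call_a == "up") & (call_b == "down")).sum()),
        "n_down_A": int((call_a == "down").sum()),
        "n_down_A_up_B": int(((call_a == "down") & (call_b == "up")).sum()),
    }
    return table, counts


def inversion_table(pair: ContrastPair) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-gene cross-contrast call table over the shared universe."""
    universe = pair.shared_universe
    if not universe:
        raise ValueError("empty shared gene universe between the two contrasts")
    return _inversion_counts(pair, universe)


def write_inversion_table(
    table: pd.DataFrame, counts: dict[str, int], path
) -> None:
    """Fixed-column TSV (gene, call_A, call_B, inverted) + summary footer."""
    with open(path, "w") as fh:
        table.to_csv(fh, sep="\t", index=False, columns=["gene", "call_A", "call_B",
                                                         "inverted"])
        for key in ("n_up_A", "n_up_A_down_B", "n_down_A", "n_down_A_up_B"):
            fh.write(f"# {key}\t{counts[key]}\n")
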