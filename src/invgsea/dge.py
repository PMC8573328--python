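"""Two-group differential expression and gene ranking.

Per-gene p-values come from a two-sided location test on log2(x+1)
transformed expression: either Welch's t-test or an empirical-Bayes
moderated t-test that shrinks the per-gene pooled variance towards a common
prior (the standard remedy for the low power of per-gene variance estimates
at small replicate numbers).  Differential calls follow the study criteria
of raw P < 0.01 and |log2 fold change| > 0.2; Benjamini-Hochberg adjusted
p-values are reported alongside but do not drive the calls unless requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special, stats

from .expression import ExpressionMatrix

__all__ = [
    "DgeResult",
    "RankedList",
    "differential_expression",
    "rank_genes",
    "classify_calls",
    "write_dge_table",
    "write_rnk",
    "read_rnk",
]

P_THRESHOLD = 0.01
LFC_THRESHOLD = 0.2

RANK_METRICS = ("signal_to_noise", "log2fc")
DE_TESTS = ("moderated", "welch")


@dataclass
class DgeResult:
    """Per-gene fold change, p-value and up/down/ns call for one contrast."""

    table: pd.DataFrame  # index gene; columns log2fc, p, padj, call
    treated: str
    reference: str
    p_threshold: float = P_THRESHOLD
    lfc_threshold: float = LFC_THRESHOLD
    test: str = "moderated"

    @property
    def genes(self) -> np.ndarray:
        return self.table.index.to_numpy()

    @property
    def calls(self) -> pd.Series:
        return self.table["call"]

    def genes_called(self, call: str) -> frozenset[str]:
        return frozenset(self.table.index[self.table["call"] == call])

    @property
    def n_up(self) -> int:
        return int((self.table["call"] == "up").sum())

    @property
    def n_down(self) -> int:
        return int((self.table["call"] == "down").sum())

    @property
    def n_ns(self) -> int:
        return int((self.table["call"] == "ns").sum())


@dataclass
class RankedList:
    """Genes ordered by a ranking metric, descending (pre-ranked list).

    Ties in the metric are broken by gene id, ascending lexicographic order,
    so the ranking is total and reproducible.
    """

    genes: np.ndarray  # ordered, descending metric
    scores: np.ndarray  # metric value aligned with genes
    metric: str = "signal_to_noise"
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.genes = np.array(
            [str(g).strip().upper() for g in self.genes], dtype=object
        )
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.genes) != len(self.scores):
            raise ValueError("genes and scores length mismatch")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in ranked list")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("ranking metric must be finite")
        self._index = {g: i for i, g in enumerate(self.genes)}

    @property
    def N(self) -> int:
        return len(self.genes)

    def position(self, gene: str) -> int:
        """0-based rank of ``gene``."""
        return self._index[gene]

    def as_series(self) -> pd.Series:
        return pd.Series(self.scores, index=self.genes, name=self.metric)

    @classmethod
    def from_scores(cls, genes, scores, metric: str = "custom") -> "RankedList":
        genes = np.array([str(g).strip().upper() for g in genes], dtype=object)
        scores = np.asarray(scores, dtype=float)
        order = np.lexsort((genes.astype(str), -scores))
        return cls(genes[order], scores[order], metric=metric)


def classify_calls(
    log2fc: np.ndarray,
    p: np.ndarray,
    p_threshold: float = P_THRESHOLD,
    lfc_threshold: float = LFC_THRESHOLD,
) -> np.ndarray:
    """Apply the differential-call rule: significant and beyond the fold bound."""
    log2fc = np.asarray(log2fc, dtype=float)
    p = np.asarray(p, dtype=float)
    call = np.full(log2fc.shape, "ns", dtype=object)
    sig = p < p_threshold
    call[sig & (log2fc > lfc_threshold)] = "up"
    call[sig & (log2fc < -lfc_threshold)] = "down"
    return call


def _group_arrays(
    expr: ExpressionMatrix, treated: str, reference: str
) -> tuple[np.ndarray, np.ndarray]:
    st = expr.group_samples(treated)
    sr = expr.group_samples(reference)
    if len(st) < 2 or len(sr) < 2:
        raise ValueError("each group needs >= 2 samples for testing")
    return (
        expr.values[st].to_numpy(dtype=float),
        expr.values[sr].to_numpy(dtype=float),
    )


def _welch(xt: np.ndarray, xr: np.ndarray) -> np.ndarray:
    res = stats.ttest_ind(xt, xr, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    # zero variance in both groups: equal means -> p = 1, unequal -> p = 0
    degenerate = np.isnan(p)
    if degenerate.any():
        diff = xt.mean(axis=1) - xr.mean(axis=1)
        p[degenerate & (diff == 0)] = 1.0
        p[degenerate & (diff != 0)] = 0.0
    return p


def _trigamma_inv(y: np.ndarray) -> np.ndarray:
    """Newton inversion of the trigamma function (positive branch)."""
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        x = x + tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = np.clip(x, 1e-8, 1e8)
    return x


def _moderated_t(xt: np.ndarray, xr: np.ndarray) -> np.ndarray:
    """Empirical-Bayes moderated t: pooled variances shrunk to a common prior.

    The prior degrees of freedom d0 and scale s0^2 are estimated by matching
    the moments of log pooled variances to a scaled inverse-chi-square model;
    the posterior variance (d0*s0^2 + d*s^2)/(d0+d) enters an ordinary
    two-sample t statistic with d0+d degrees of freedom.
    """
    n1, n2 = xt.shape[1], xr.shape[1]
    d = n1 + n2 - 2
    s2 = (xt.var(axis=1, ddof=1) * (n1 - 1) + xr.var(axis=1, ddof=1) * (n2 - 1)) / d
    diff = xt.mean(axis=1) - xr.mean(axis=1)

    positive = s2 > 0
    if positive.sum() < 2:  # degenerate matrix: fall back to Welch behaviour
        return _welch(xt, xr)
    z = np.log(s2[positive])
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    var_e = float(np.var(e, ddof=1))
    rhs = var_e - special.polygamma(1, d / 2.0)
    if rhs > 1e-10:
        d0 = 2.0 * float(_trigamma_inv(np.array([rhs]))[0])
        s0_2 = float(np.exp(np.mean(e) + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
        s2_post = (d0 * s0_2 + d * s2) / (d0 + d)
        df = d0 + d
    else:  # observed variances indistinguishable from a single value
        s2_post = np.full_like(s2, float(np.exp(np.mean(e))))
        df = 1e6
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p[np.isnan(p) & (diff == 0)] = 1.0
    p[np.isnan(p)] = 0.0
    return p


def differential_expression(
    expr: ExpressionMatrix,
    treated: str,
    reference: str,
    p_threshold: float = P_THRESHOLD,
    lfc_threshold: float = LFC_THRESHOLD,
    test: str = "moderated",
) -> DgeResult:
    """Per-gene two-group differential expression for one contrast.

    Fold change is the log2 ratio of pseudocounted group means of the raw
    values; the p-value comes from ``test`` (``moderated`` or ``welch``)
    applied to log2(x+1) transformed values.
    """
    if test not in DE_TESTS:
        raise ValueError(f"unknown test {test!r}; valid: {DE_TESTS}")
    raw_t, raw_r = _group_arrays(expr, treated, reference)
    log2fc = np.log2(raw_t.mean(axis=1) + 1.0) - np.log2(raw_r.mean(axis=1) + 1.0)
    xt, xr = np.log2(raw_t + 1.0), np.log2(raw_r + 1.0)
    p = _moderated_t(xt, xr) if test == "moderated" else _welch(xt, xr)
    padj = _benjamini_hochberg(p)
    call = classify_calls(log2fc, p, p_threshold, lfc_threshold)
    table = pd.DataFrame(
        {"log2fc": log2fc, "p": p, "padj": padj, "call": call}, index=expr.genes
    )
    return DgeResult(table, treated, reference, p_threshold, lfc_threshold, test)


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


def rank_genes(
    expr: ExpressionMatrix,
    treated: str,
    reference: str,
    metric: str = "signal_to_noise",
) -> RankedList:
    """Rank all genes for enrichment, descending in the chosen metric.

    ``signal_to_noise``: difference of group means over the sum of group
    standard deviations on log2(x+1) values, with the conventional floor
    sigma_used = max(sigma, 0.2*|mu|, 0.2) guarding near-constant genes.
    ``log2fc``: signed log2 ratio of pseudocounted group means.
    """
    if metric not in RANK_METRICS:
        raise ValueError(f"unknown metric {metric!r}; valid: {RANK_METRICS}")
    raw_t, raw_r = _group_arrays(expr, treated, reference)
    if metric == "log2fc":
        scores = np.log2(raw_t.mean(axis=1) + 1.0) - np.log2(raw_r.mean(axis=1) + 1.0)
    else:
        xt, xr = np.log2(raw_t + 1.0), np.log2(raw_r + 1.0)
        scores = _signal_to_noise(
            xt.mean(axis=1), xr.mean(axis=1),
            xt.std(axis=1, ddof=1), xr.std(axis=1, ddof=1),
        )
    return RankedList.from_scores(expr.genes, scores, metric=metric)


def _signal_to_noise(
    mu_t: np.ndarray, mu_r: np.ndarray, sd_t: np.ndarray, sd_r: np.ndarray
) -> np.ndarray:
    sd_t = np.maximum.reduce([sd_t, 0.2 * np.abs(mu_t), np.full_like(sd_t, 0.2)])
    sd_r = np.maximum.reduce([sd_r, 0.2 * np.abs(mu_r), np.full_like(sd_r, 0.2)])
    return (mu_t - mu_r) / (sd_t + sd_r)


# ---------------------------------------------------------------------------
# I/O

def write_dge_table(result: DgeResult, path: str | Path) -> None:
    out = result.table.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t", float_format="%.6g")


def write_rnk(ranked: RankedList, path: str | Path) -> None:
    """Standard two-column pre-ranked file, descending metric."""
    with open(path, "w") as fh:
        for g, s in zip(ranked.genes, ranked.scores):
            fh.write(f"{g}\t{s:.6g}\n")


def read_rnk(path: str | Path) -> RankedList:
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "score"])
    if df["score"].isna().any():
        line = int(df["score"].isna().idxmax()) + 1
        raise ValueError(f"{path}: non-numeric ranking metric at line {line}")
    genes = df["gene"].astype(str).str.strip().str.upper().to_numpy()
    return RankedList.from_scores(genes, df["score"].to_numpy(), metric="preranked")
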