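"""End-to-end pipeline runs, configuration and manifests.

A run chains five stages over two contrasts: differential expression of
contrast A, differential expression plus ranking of contrast B, gene-set
enrichment against a GMT collection, the cross-contrast inverted-enrichment
analysis, and interaction-network core-module detection.  Every stage writes
its table to the output directory and the run ends with a manifest recording
input hashes, parameters, package version and stage status — sufficient to
re-run the bundle byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import __version__
from .dge import differential_expression, rank_genes, write_dge_table, write_rnk
from .enrichment import enrich_collection, write_enrichment_tsv
from .expression import read_expression
from .genesets import read_gmt, write_gmt
from .inversion import ContrastPair, inverted_enrichment, write_inversion_table
from .network import McodeParams, load_string_edges, mcode_find_complexes, module_report
from .simulate import (
    SimDesign,
    simulate_gene_sets,
    simulate_planted_module_graph,
    simulate_two_contrast_counts,
    write_counts_tsv,
    write_group_map_tsv,
    write_network_tsv,
)

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "StageError", "cmd_simulate", "cmd_run_all"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class ContrastDef:
    counts: str
    groups: str
    treated: str
    reference: str


@dataclass
class PipelineConfig:
    contrast_A: ContrastDef
    contrast_B: ContrastDef
    gene_sets: str
    network: str
    out_dir: str
    seed: int
    p_threshold: float = 0.01
    lfc_threshold: float = 0.2
    de_test: str = "moderated"
    rank_metric: str = "signal_to_noise"
    weight_exponent: float = 1.0
    n_permutations: int = 1000
    permutation_mode: str = "phenotype"
    min_set_size: int = 5
    max_set_size: int = 500
    score_threshold: float = 0.4
    mcode: McodeParams = field(default_factory=McodeParams)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        raw["contrast_A"] = ContrastDef(**raw["contrast_A"])
        raw["contrast_B"] = ContrastDef(**raw["contrast_B"])
        if "mcode" in raw:
            raw["mcode"] = McodeParams(**raw["mcode"])
        return cls(**raw)

    def validate(self) -> None:
        for label, p in [
            ("contrast_A.counts", self.contrast_A.counts),
            ("contrast_A.groups", self.contrast_A.groups),
            ("contrast_B.counts", self.contrast_B.counts),
            ("contrast_B.groups", self.contrast_B.groups),
            ("gene_sets", self.gene_sets),
            ("network", self.network),
        ]:
            if not Path(p).is_file():
                raise FileNotFoundError(f"{label}: no such file: {p}")
        if self.n_permutations >= 10 and self.seed is None:
            raise ValueError("a seed is required when permutations are requested")


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def cmd_simulate(
    design: SimDesign,
    out_dir: str | Path,
    n_sets: int = 50,
    set_size_range: tuple[int, int] = (15, 200),
    n_network_nodes: int = 200,
    background_edge_prob: float = 0.01,
    planted_modules: list[tuple[int, float]] = ((10, 0.9),),
) -> dict[str, Path]:
    """Write a complete synthetic fixture bundle (six files).

    counts for both contrasts, one combined sample->group map, a GMT
    collection over the gene universe, a STRING-style network with planted
    dense modules among the contrast-A differential genes, and the ground
    truth as JSON.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts_a, counts_b, truth = simulate_two_contrast_counts(design)

    gm = {c: ("A_trt" if "trt" in c else "A_ctrl") for c in counts_a.columns}
    gm |= {c: ("B_trt" if "trt" in c else "B_ctrl") for c in counts_b.columns}

    universe = list(counts_a.index)
    collection = simulate_gene_sets(
        universe, n_sets, set_size_range, seed=design.seed + 1
    )

    # plant interaction modules among the contrast-A differential genes so the
    # network stage has signal linked to the planted biology
    de = list(truth.de_genes_A)
    rest = [g for g in universe if g not in set(de)]
    graph, planted = simulate_planted_module_graph(
        n_network_nodes,
        background_edge_prob,
        list(planted_modules),
        seed=design.seed + 2,
        nodes=(de + rest)[:n_network_nodes],
    )
    truth.planted_modules = planted

    paths = {
        "counts_A": out / "counts_A.tsv",
        "counts_B": out / "counts_B.tsv",
        "groups": out / "groups.tsv",
        "gene_sets": out / "gene_sets.gmt",
        "network": out / "network.tsv",
        "truth": out / "truth.json",
    }
    write_counts_tsv(counts_a, paths["counts_A"])
    write_counts_tsv(counts_b, paths["counts_B"])
    write_group_map_tsv(gm, paths["groups"])
    write_gmt(collection, paths["gene_sets"])
    write_network_tsv(graph, paths["network"])
    truth.to_json(paths["truth"])
    log.info("wrote %d fixture files to %s", len(paths), out)
    return paths


def cmd_run_all(config: PipelineConfig) -> dict:
    """Run the five-stage pipeline and return the manifest dictionary."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "inputs": {
            "counts_A": _sha256(config.contrast_A.counts),
            "counts_B": _sha256(config.contrast_B.counts),
            "groups_A": _sha256(config.contrast_A.groups),
            "groups_B": _sha256(config.contrast_B.groups),
            "gene_sets": _sha256(config.gene_sets),
            "network": _sha256(config.network),
        },
        "params": {
            k: v
            for k, v in asdict(config).items()
            if k not in ("contrast_A", "contrast_B")
        },
        "stages": {},
    }

    def stage(name: str, fn):
        try:
            result = fn()
        except Exception as exc:
            manifest["stages"][name] = {"status": "failed", "error": str(exc)}
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
            raise StageError(f"stage {name!r} failed: {exc}") from exc
        manifest["stages"][name] = {"status": "ok", **result}
        return result

    # stage 1: contrast A differential expression
    def run_dge_a():
        expr = read_expression(config.contrast_A.counts, config.contrast_A.groups, allow_extra=True)
        expr = expr.subset([config.contrast_A.treated, config.contrast_A.reference])
        dge = differential_expression(
            expr, config.contrast_A.treated, config.contrast_A.reference,
            config.p_threshold, config.lfc_threshold, config.de_test,
        )
        write_dge_table(dge, out / "dge_A.tsv")
        self_state["expr_A"], self_state["dge_A"] = expr, dge
        return {"n_genes": len(dge.genes), "n_up": dge.n_up, "n_down": dge.n_down}

    # stage 2: contrast B differential expression + ranking
    def run_dge_b():
        expr = read_expression(config.contrast_B.counts, config.contrast_B.groups, allow_extra=True)
        expr = expr.subset([config.contrast_B.treated, config.contrast_B.reference])
        dge = differential_expression(
            expr, config.contrast_B.treated, config.contrast_B.reference,
            config.p_threshold, config.lfc_threshold, config.de_test,
        )
        ranked = rank_genes(
            expr, config.contrast_B.treated, config.contrast_B.reference,
            config.rank_metric,
        )
        write_dge_table(dge, out / "dge_B.tsv")
        write_rnk(ranked, out / "ranked_B.rnk")
        self_state.update(expr_B=expr, dge_B=dge, ranked_B=ranked)
        return {"n_genes": len(dge.genes), "n_up": dge.n_up, "n_down": dge.n_down}

    # stage 3: gene-set enrichment on contrast B
    def run_enrich():
        collection = read_gmt(config.gene_sets)
        results = enrich_collection(
            collection,
            ranked=self_state["ranked_B"],
            expr=self_state["expr_B"],
            treated=config.contrast_B.treated,
            reference=config.contrast_B.reference,
            n_permutations=config.n_permutations,
            mode=config.permutation_mode,
            seed=config.seed,
            w=config.weight_exponent,
            metric=config.rank_metric,
            min_size=config.min_set_size,
            max_size=config.max_set_size,
        )
        write_enrichment_tsv(results, out / "enrichment_B.tsv")
        return {"n_sets_tested": len(results)}

    # stage 4: cross-contrast inverted enrichment
    def run_invert():
        pair = ContrastPair(
            dge_A=self_state["dge_A"],
            dge_B=self_state["dge_B"],
            ranked_B=self_state["ranked_B"],
            expr_B=self_state["expr_B"],
            treated_B=config.contrast_B.treated,
            reference_B=config.contrast_B.reference,
        )
        report = inverted_enrichment(
            pair,
            n_permutations=config.n_permutations,
            seed=config.seed,
            w=config.weight_exponent,
            mode=config.permutation_mode,
        )
        write_inversion_table(
            report.table,
            {
                "n_up_A": report.n_up_A,
                "n_up_A_down_B": report.n_up_A_down_B,
                "n_down_A": report.n_down_A,
                "n_down_A_up_B": report.n_down_A_up_B,
            },
            out / "inversion.tsv",
        )
        return {
            "nes": report.nes,
            "p_value": report.p_value,
            "n_inverted": report.n_inverted,
        }

    # stage 5: network core modules
    def run_modules():
        net = load_string_edges(config.network, config.score_threshold)
        modules = mcode_find_complexes(net, config.mcode)
        module_report(modules).to_csv(out / "modules.tsv", sep="\t", index=False)
        return {"n_modules": len(modules)}

    self_state: dict = {}
    stage("dge_A", run_dge_a)
    stage("dge_B", run_dge_b)
    stage("enrichment", run_enrich)
    stage("inversion", run_invert)
    stage("modules", run_modules)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
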