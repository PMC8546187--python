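"""End-to-end orchestration: DE sets -> target network -> GWAS enrichment.

The pipeline consumes plain TSV/BED inputs named in a YAML config, runs
every stage with the configured thresholds, and writes plain-text outputs
plus a JSON run report with per-stage survivor counts, a config echo and
file checksums. Re-running with an identical config reproduces
byte-identical tabular outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import de as de_mod
from . import enrichment as enr
from . import io as mio
from . import network as net
from . import simulate as sim
from .intervals import GenomicInterval

__all__ = ["PipelineConfig", "run_full_pipeline", "make_demo"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    # input paths
    de_table_a: str = ""
    de_table_b: str = ""
    mirna_expression: str = ""
    gene_expression: str = ""
    predicted_pairs: str = ""
    gwas_summary: str = ""
    precursors_bed: str = ""
    genes_bed: str = ""
    de_genes: str = ""
    # thresholds
    lfc_threshold: float = 0.8
    p_threshold: float = 0.05
    min_score: float = 50.0
    max_energy: float = -20.0
    corr_p_threshold: float = 0.05
    # enrichment
    precursor_flank: int = 50_000
    target_flank: int = 5_000
    nperm: int = 10_000
    seed: int = 0
    tie: str = "strict"
    null_mode: str = "circular"
    exclusion: dict | None = None  # {chrom, start, end, margin}
    # clustering
    k_range: list[int] = field(default_factory=lambda: list(range(1, 10)))
    # output
    outdir: str = "pipeline_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def validate(self) -> None:
        for name in (
            "de_table_a",
            "de_table_b",
            "mirna_expression",
            "gene_expression",
            "predicted_pairs",
            "gwas_summary",
            "precursors_bed",
            "genes_bed",
            "de_genes",
        ):
            p = getattr(self, name)
            if not p or not Path(p).exists():
                raise PipelineError("validate", f"missing input file for {name!r}: {p!r}")
        if not (0 < self.p_threshold <= 1 and 0 < self.corr_p_threshold <= 1):
            raise PipelineError("validate", "p-value thresholds must lie in (0, 1]")
        if self.lfc_threshold < 0 or self.nperm < 1:
            raise PipelineError("validate", "lfc_threshold >= 0 and nperm >= 1 required")

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _write_table(table: pd.DataFrame, path: Path, stage: str, confhash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# stage={stage} config={confhash}\n")
        table.to_csv(fh, sep="\t", index=False)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _group_means(expr: pd.DataFrame) -> pd.DataFrame | None:
    """Mean expression per sample group (sample name minus trailing digits)."""
    groups = expr.index.str.replace(r"\d+$", "", regex=True)
    if groups.nunique() < 2:
        return None
    return expr.groupby(groups).mean().T  # features x groups


def run_full_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the run report (also written to outdir)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    confhash = config.config_hash()
    counts: dict[str, int] = {}
    outputs: dict[str, str] = {}

    def emit(name: str, table: pd.DataFrame, stage: str) -> None:
        path = outdir / name
        _write_table(table, path, stage, confhash)
        outputs[name] = str(path)

    # ---- DE stage -------------------------------------------------------
    try:
        de_a_raw = mio.read_de_table(config.de_table_a)
        de_b_raw = mio.read_de_table(config.de_table_b)
        de_a = de_mod.filter_de(de_a_raw, config.lfc_threshold, config.p_threshold)
        de_b = de_mod.filter_de(de_b_raw, config.lfc_threshold, config.p_threshold)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("de", str(exc)) from exc
    comparison = de_mod.compare_de_sets(de_a["mirna_id"], de_b["mirna_id"])
    emit("de_a_filtered.tsv", de_a, "de")
    emit("de_b_filtered.tsv", de_b, "de")
    venn_path = outdir / "venn.json"
    with open(venn_path, "w") as fh:
        json.dump(comparison.to_dict(), fh, indent=2, sort_keys=True)
    outputs["venn.json"] = str(venn_path)
    counts.update(
        de_a_input=len(de_a_raw),
        de_a=len(de_a),
        de_a_up=int((de_a["direction"] == "up").sum()),
        de_a_down=int((de_a["direction"] == "down").sum()),
        de_b_input=len(de_b_raw),
        de_b=len(de_b),
        de_b_up=int((de_b["direction"] == "up").sum()),
        de_b_down=int((de_b["direction"] == "down").sum()),
        de_common=len(comparison.common_ids),
        de_union=comparison.union_size,
    )
    de_union = sorted(comparison.set_a_ids | comparison.set_b_ids)

    # ---- expression + clustering ---------------------------------------
    try:
        mirna_expr = mio.read_expression(config.mirna_expression)
        gene_expr = mio.read_expression(config.gene_expression)
    except Exception as exc:
        raise PipelineError("expression", str(exc)) from exc
    de_in_expr = [m for m in de_union if m in mirna_expr.columns]
    gm = _group_means(mirna_expr[de_in_expr]) if de_in_expr else None
    if gm is not None and len(gm) >= 2:
        k_max = min(max(config.k_range), len(gm))
        ks = [k for k in config.k_range if k <= k_max]
        labels, chosen_k = de_mod.cluster_patterns(gm, ks, seed=config.seed)
        clusters = pd.DataFrame({"mirna_id": gm.index, "cluster": labels})
        emit("clusters.tsv", clusters, "cluster")
        counts["cluster_k"] = int(chosen_k)

    # ---- target network --------------------------------------------------
    try:
        predicted = pd.read_csv(config.predicted_pairs, sep="\t", comment="#")
        filtered = net.filter_predictions(predicted, config.min_score, config.max_energy)
        correlated = net.correlate_targets(
            mirna_expr, gene_expr, filtered, p_threshold=config.corr_p_threshold
        )
        de_genes = [
            line.strip()
            for line in Path(config.de_genes).read_text().splitlines()
            if line.strip()
        ]
        edges = net.select_de_de_edges(correlated, de_union, de_genes)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("network", str(exc)) from exc
    emit("correlated_pairs.tsv", correlated, "correlate")
    emit("edges.tsv", edges, "network")
    net.write_edge_list(edges, outdir / "edges_export.tsv", outdir / "nodes.tsv")
    outputs["edges_export.tsv"] = str(outdir / "edges_export.tsv")
    outputs["nodes.tsv"] = str(outdir / "nodes.tsv")
    counts.update(
        predicted_pairs=len(predicted),
        predictions_passing=len(filtered),
        correlated_pairs=len(correlated),
        **{f"network_{k}": v for k, v in net.network_summary(edges).items()},
    )

    # ---- GWAS enrichment -------------------------------------------------
    try:
        snps = mio.read_gwas_summary(config.gwas_summary)
        precursors = mio.read_intervals(config.precursors_bed, format="bed")
        genes = mio.read_intervals(config.genes_bed, format="bed")
    except Exception as exc:
        raise PipelineError("enrichment-io", str(exc)) from exc

    exclusion = None
    margin = 0
    if config.exclusion:
        exclusion = GenomicInterval(
            chrom=str(config.exclusion["chrom"]),
            start=int(config.exclusion["start"]),
            end=int(config.exclusion["end"]),
            feature_id=str(config.exclusion.get("feature_id", "exclusion")),
        )
        margin = int(config.exclusion.get("margin", 1_000_000))

    prec_ids = set(precursors.ids())
    gene_ids = set(genes.ids())
    candidate_sets = {}
    for label, table in (("HP_vs_LP", de_a), ("HD_vs_LD", de_b)):
        ids = [m for m in table["mirna_id"] if m in prec_ids]
        if ids:
            candidate_sets[f"precursors_{label}"] = precursors.subset(ids)
    try:
        results = []
        if candidate_sets:
            results.append(
                enr.run_enrichment(
                    snps,
                    candidate_sets,
                    background=precursors,
                    flank=config.precursor_flank,
                    nperm=config.nperm,
                    seed=config.seed,
                    exclusion=exclusion,
                    exclusion_margin=margin,
                    tie=config.tie,
                    null_mode=config.null_mode,
                )
            )
        target_ids = [g for g in edges["gene_id"].unique() if g in gene_ids]
        if target_ids:
            results.append(
                enr.run_enrichment(
                    snps,
                    {"targets_DE_network": genes.subset(target_ids)},
                    background=genes,
                    flank=config.target_flank,
                    nperm=config.nperm,
                    seed=config.seed,
                    exclusion=exclusion,
                    exclusion_margin=margin,
                    tie=config.tie,
                    null_mode=config.null_mode,
                )
            )
        enrichment = (
            pd.concat(results, ignore_index=True)
            if results
            else pd.DataFrame(columns=["feature_set", "m", "tsum", "n_over", "pvalue", "fdr"])
        )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("enrichment", str(exc)) from exc
    emit("enrichment.tsv", enrichment, "enrich")
    counts["enrichment_sets_tested"] = int(enrichment["pvalue"].notna().sum())

    # ---- report ----------------------------------------------------------
    report = {
        "config": dataclasses.asdict(config),
        "config_hash": confhash,
        "seed": config.seed,
        "counts": counts,
        "outputs": {k: _sha256(Path(v)) for k, v in outputs.items()},
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    logger.info("pipeline complete: %s", counts)
    return report


def make_demo(outdir: str | Path, seed: int = 0) -> PipelineConfig:
    """Write a self-contained synthetic dataset plus a config exercising
    every stage; returns the config (also saved as config.yaml)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    n_true = 15
    flank = 20_000
    config = sim.SimulationConfig(
        n_chromosomes=2,
        chrom_length=5_000_000,
        n_snps=20_000,
        n_genes=80,
        n_precursors=60,
        sigma0=0.01,
        inflation_lambda=3.0,
        enriched_feature_ids=tuple(f"mir_{i + 1}" for i in range(5)),
        n_samples=12,
        n_true_pairs=n_true,
        pair_r=-0.9,
        seed=seed,
    )
    files = sim.write_dataset(config, outdir, flank=flank, de_counts=(11, 17, 20),
                              de_counts_b=(22, 30, 8))

    rng = np.random.default_rng(np.random.SeedSequence([seed, 99]))
    # predictions: every planted pair passes; decoys straddle the thresholds
    rows = [
        (f"mir_{k + 1}", f"gene_{k + 1}", float(rng.uniform(55, 160)), float(rng.uniform(-35, -21)))
        for k in range(n_true)
    ]
    for _ in range(300):
        m = int(rng.integers(1, config.n_precursors + 1))
        g = int(rng.integers(1, config.n_genes + 1))
        rows.append(
            (f"mir_{m}", f"gene_{g}", float(rng.uniform(20, 160)), float(rng.uniform(-35, -5)))
        )
    predicted = pd.DataFrame(rows, columns=["mirna_id", "gene_id", "score", "energy"])
    predicted.to_csv(outdir / "predicted_pairs.tsv", sep="\t", index=False)

    de_genes = [f"gene_{k + 1}" for k in range(n_true)] + [
        f"gene_{g}" for g in rng.choice(range(n_true + 1, config.n_genes + 1), 10, replace=False)
    ]
    (outdir / "de_genes.txt").write_text("\n".join(de_genes) + "\n")

    pconf = PipelineConfig(
        de_table_a=files["de_table_a_tsv"],
        de_table_b=files["de_table_b_tsv"],
        mirna_expression=files["mirna_expression_tsv"],
        gene_expression=files["gene_expression_tsv"],
        predicted_pairs=str(outdir / "predicted_pairs.tsv"),
        gwas_summary=files["gwas_tsv"],
        precursors_bed=files["precursors_bed"],
        genes_bed=files["genes_bed"],
        de_genes=str(outdir / "de_genes.txt"),
        precursor_flank=flank,
        target_flank=5_000,
        nperm=200,
        seed=seed,
        outdir=str(outdir / "results"),
    )
    pconf.to_yaml(outdir / "config.yaml")
    return pconf
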