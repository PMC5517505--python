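"""End-to-end orchestration: quantify -> DEG -> enrich -> network -> screen.

Every stage reads and writes only the documented text formats, so stages can
be re-run independently from on-disk intermediates. A JSON run manifest
records the package version, all thresholds, the seed and per-stage record
counts; given identical inputs and configuration the whole run is
byte-identical (no timestamps are written anywhere).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import __version__
from .deg import call_degs, compute_rpkm, differential_stats, DEG_COLUMNS
from .enrich import enrich, genes_in_significant_terms
from .io import (
    CountMatrix,
    MechanismGeneList,
    ValidationError,
    read_counts,
    read_gene_list,
    read_gmt,
    write_network,
    write_table,
)
from .network import build_network
from .screen import screen_key_genes
from .simulate import OGDR_COMPARISONS

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths, comparisons and thresholds of one pipeline run.

    ``comparisons`` lists (treatment, reference) sample-id pairs; the default
    mirrors the five-condition OGD/R design (acute OGD vs control, then each
    reperfusion time point vs OGD).
    """

    counts_path: str = "counts.tsv"
    totals_path: str = "totals.tsv"
    gmt_path: str = "gene_sets.gmt"
    mechanism_path: str | None = "mechanism_genes.txt"
    out_dir: str = "results"
    comparisons: list[tuple[str, str]] = field(
        default_factory=lambda: [list(c) for c in OGDR_COMPARISONS]
    )
    fc_threshold: float = 2.0
    fdr_threshold: float = 0.001
    enrichment_alpha: float = 0.05
    r_min: float = 0.9
    p_max: float = 0.05
    log2_ratio_gate: float = 1.5
    screen_mode: str = "strict"
    seed: int = 0

    def validate(self, cm: CountMatrix) -> None:
        if not self.comparisons:
            raise ValidationError("no comparisons configured")
        for trt, ref in self.comparisons:
            for s in (trt, ref):
                if s not in cm.sample_ids:
                    raise ValidationError(f"comparison sample {s!r} not in counts header")
            if trt == ref:
                raise ValidationError(f"comparison {trt!r} vs itself")
        for name, value, lo, hi in [
            ("fc_threshold", self.fc_threshold, 1.0, float("inf")),
            ("fdr_threshold", self.fdr_threshold, 0.0, 1.0),
            ("enrichment_alpha", self.enrichment_alpha, 0.0, 1.0),
            ("r_min", self.r_min, 0.0, 1.0),
            ("p_max", self.p_max, 0.0, 1.0),
            ("log2_ratio_gate", self.log2_ratio_gate, 0.0, float("inf")),
        ]:
            if not lo <= value <= hi:
                raise ValidationError(f"{name}={value} outside [{lo}, {hi}]")
        if self.screen_mode not in ("strict", "any_two"):
            raise ValidationError("screen_mode must be 'strict' or 'any_two'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True), encoding="utf-8")


def _comparison_tag(treatment: str, reference: str) -> str:
    return f"{treatment}_vs_{reference}"


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage for every configured comparison; return the manifest."""
    cm = read_counts(config.counts_path, config.totals_path)
    config.validate(cm)
    sets = read_gmt(config.gmt_path)
    mech: MechanismGeneList | None = None
    if config.mechanism_path:
        mech = read_gene_list(config.mechanism_path)
        if len(mech) == 0:
            mech = None

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    em = compute_rpkm(cm)
    rpkm_table = em.rpkm.reset_index()
    write_table(rpkm_table, out / "rpkm.tsv")

    manifest: dict = {
        "tool": "ogdrseq",
        "version": __version__,
        "parameters": asdict(config),
        "n_genes": cm.shape[0],
        "n_samples": cm.shape[1],
        "comparisons": {},
        "outputs": ["rpkm.tsv"],
    }

    for trt, ref in config.comparisons:
        tag = _comparison_tag(trt, ref)
        logger.info("comparison %s", tag)
        stats_table = differential_stats(em, cm, trt, ref)
        degs = call_degs(em, cm, trt, ref, config.fc_threshold, config.fdr_threshold)
        deg_path = out / f"deg_{tag}.tsv"
        write_table(degs[list(DEG_COLUMNS)], deg_path)

        deg_genes = frozenset(degs["gene_id"])
        tested_genes = frozenset(stats_table.loc[stats_table["tested"], "gene_id"])

        enrich_tables = {}
        for ns in sets.namespaces():
            universe = tested_genes & sets.annotated_genes(ns)
            table = enrich(deg_genes, universe, sets, namespace=ns, alpha=config.enrichment_alpha)
            enrich_tables[ns] = table
            write_table(table, out / f"enrichment_{ns}_{tag}.tsv")

        # network over DEGs restricted to members of significant terms (all
        # namespaces); falls back to all DEGs when nothing is significant
        sig_genes: set[str] = set()
        for table in enrich_tables.values():
            sig_genes |= genes_in_significant_terms(table, sets)
        net_genes = deg_genes & sig_genes if sig_genes else deg_genes
        l2r = dict(zip(degs["gene_id"], degs["log2_ratio"]))
        net = build_network(em, net_genes, r_min=config.r_min, p_max=config.p_max)
        for gene in net.graph.nodes:
            net.graph.nodes[gene]["log2_ratio"] = float(l2r[gene])
        write_network(net, out / f"network_{tag}.graphml", out / f"network_{tag}.edges.tsv")

        report = screen_key_genes(
            degs, list(enrich_tables.values()), sets, mech, net,
            mode=config.screen_mode, log2_ratio_gate=config.log2_ratio_gate,
        )
        write_table(report, out / f"keygenes_{tag}.tsv")

        manifest["comparisons"][tag] = {
            "treatment": trt,
            "reference": ref,
            "genes_tested": int(stats_table["tested"].sum()),
            "degs": len(degs),
            "degs_up": int((degs["direction"] == "up").sum()),
            "degs_down": int((degs["direction"] == "down").sum()),
            "significant_terms": {
                ns: int(t["significant"].sum()) for ns, t in enrich_tables.items()
            },
            "network_nodes": net.graph.number_of_nodes(),
            "network_edges": net.n_edges,
            "key_genes_selected": int(report["selected"].sum()) if len(report) else 0,
        }
        manifest["outputs"].extend([
            deg_path.name,
            *[f"enrichment_{ns}_{tag}.tsv" for ns in enrich_tables],
            f"network_{tag}.graphml",
            f"network_{tag}.edges.tsv",
            f"keygenes_{tag}.tsv",
        ])

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True), encoding="utf-8")
    return manifest
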