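"""Planted-truth recovery experiments on synthetic data.

Each experiment generates a dataset with known planted structure, runs the
relevant pipeline stage(s), and scores the result against the truth object.
They are the package's standing evidence that the statistical machinery
recovers what it is supposed to recover under the reference study
conditions, and are reused by both the test suite and the acceptance
script.

The DEG and enrichment experiments plant no co-expression modules: module
latent profiles are genuine condition-dependence that would be
indistinguishable from differential expression, so benchmarks that score
DE recovery isolate them. Symmetrically, the network experiment plants no
DE genes and uses extended profiles (20 conditions) so pairwise
correlations are estimable with useful power.
"""

from __future__ import annotations

import dataclasses

from .deg import call_degs, compute_rpkm, differential_stats
from .enrich import enrich, significant_terms
from .network import build_network
from .simulate import SimulationConfig, generate_counts, generate_gene_sets

#: reference DEG-recovery scenario: 2000 genes, one library of ~5M mapped
#: reads per condition, NB dispersion 0.05, 100 planted DE genes at 4-16x
DEG_RECOVERY_CONFIG = SimulationConfig(n_modules=0)

#: reference network-recovery scenario: extended 20-condition profiles,
#: three 30-gene modules at target correlation 0.95, no planted DE
NETWORK_RECOVERY_CONFIG = SimulationConfig(
    n_genes=300, n_conditions=20, n_de_genes=0,
    n_modules=3, module_size=30, module_correlation=0.95,
    n_enriched_sets=0,
)


def deg_recovery(seed: int = 0) -> dict:
    """Sensitivity and false positives of the DEG caller on planted DE.

    Returns planted/called gene counts, sensitivity against truth, and the
    number of null genes incorrectly called.
    """
    cfg = dataclasses.replace(DEG_RECOVERY_CONFIG, seed=seed)
    cm, truth = generate_counts(cfg)
    em = compute_rpkm(cm)
    treatment = cfg.condition_names()[cfg.de_condition]
    reference = cfg.condition_names()[0]
    degs = call_degs(em, cm, treatment, reference)
    planted = truth.de_set(treatment, reference)
    called = frozenset(degs["gene_id"])
    return {
        "n_genes": cfg.n_genes,
        "n_planted": len(planted),
        "n_called": len(called),
        "sensitivity": len(called & planted) / len(planted) if planted else float("nan"),
        "false_positives": len(called - planted),
        "n_null": cfg.n_genes - len(planted),
    }


def enrichment_recovery(seed: int = 0) -> dict:
    """Recovery of planted-enriched terms from the realized DEG list.

    The universe is genes that are both testable in the comparison and
    annotated to at least one term. Scores how many planted terms are
    BH-significant and how many non-planted terms come out significant.
    """
    cfg = dataclasses.replace(DEG_RECOVERY_CONFIG, seed=seed)
    cm, truth = generate_counts(cfg)
    sets = generate_gene_sets(cfg, truth)
    em = compute_rpkm(cm)
    treatment = cfg.condition_names()[cfg.de_condition]
    reference = cfg.condition_names()[0]
    stats = differential_stats(em, cm, treatment, reference)
    degs = call_degs(em, cm, treatment, reference)
    tested = frozenset(stats.loc[stats["tested"], "gene_id"])
    universe = tested & sets.annotated_genes()
    table = enrich(frozenset(degs["gene_id"]), universe, sets)
    sig = significant_terms(table)
    planted = truth.enriched_terms
    return {
        "n_terms": len(sets),
        "n_planted_terms": len(planted),
        "planted_significant": len(sig & planted),
        "spurious_significant": len(sig - planted),
        "all_planted_recovered": sig >= planted,
    }


def network_recovery(seed: int = 0) -> dict:
    """Modularity of the co-expression network on planted modules.

    Builds the network over all genes of an extended-profile dataset and
    reports the fraction of edges joining two genes of the same module.
    """
    cfg = dataclasses.replace(NETWORK_RECOVERY_CONFIG, seed=seed)
    cm, truth = generate_counts(cfg)
    em = compute_rpkm(cm)
    net = build_network(em, cm.gene_ids)
    modules = truth.module_assignments
    intra = sum(
        1 for a, b in net.graph.edges
        if a in modules and b in modules and modules[a] == modules[b]
    )
    n_edges = net.n_edges
    return {
        "n_edges": n_edges,
        "intra_module_edges": intra,
        "intra_module_fraction": intra / n_edges if n_edges else float("nan"),
    }


def average_null_deg_rate(n_seeds: int = 20, base_seed: int = 0) -> float:
    """Average DEG calls per gene on data with nothing planted (null control).

    Uses the Poisson limit (dispersion 0), the regime in which the exact
    test's calibration claim applies; see the methods note for why a
    replicate-free design cannot distinguish per-library overdispersion
    from signal.
    """
    calls = 0
    genes = 0
    for k in range(n_seeds):
        cfg = dataclasses.replace(
            DEG_RECOVERY_CONFIG, n_de_genes=0, dispersion=0.0, seed=base_seed + k
        )
        cm, _ = generate_counts(cfg)
        em = compute_rpkm(cm)
        degs = call_degs(em, cm, cfg.condition_names()[1], cfg.condition_names()[0])
        calls += len(degs)
        genes += cfg.n_genes
    return calls / genes
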