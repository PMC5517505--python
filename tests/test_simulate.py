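"""Synthetic-data generator: determinism, planted structure, fidelity."""

import dataclasses

import numpy as np
import pytest

from ogdrseq import (
    SimulationConfig,
    SyntheticTruth,
    ValidationError,
    call_degs,
    compute_rpkm,
    generate_counts,
    generate_gene_sets,
    generate_mechanism_list,
)

SMALL = SimulationConfig(n_genes=300, n_de_genes=20, n_modules=2, module_size=10,
                         n_gene_sets=12, n_enriched_sets=2,
                         gene_set_size_range=(8, 15), seed=7)


class TestDeterminism:
    def test_identical_config_bit_identical_outputs(self):
        cm1, t1 = generate_counts(SMALL)
        cm2, t2 = generate_counts(SMALL)
        assert cm1.counts.equals(cm2.counts)
        assert cm1.lengths.equals(cm2.lengths)
        assert cm1.totals.equals(cm2.totals)
        assert t1.de_genes == t2.de_genes
        s1 = generate_gene_sets(SMALL, t1)
        s2 = generate_gene_sets(SMALL, t2)
        assert s1.terms == s2.terms
        assert t1.enriched_terms == t2.enriched_terms

    def test_different_seed_differs(self):
        cm1, _ = generate_counts(SMALL)
        cm2, _ = generate_counts(dataclasses.replace(SMALL, seed=8))
        assert not cm1.counts.equals(cm2.counts)

    def test_truth_json_round_trip(self, tmp_path):
        cm, truth = generate_counts(SMALL)
        generate_gene_sets(SMALL, truth)
        truth.to_json(tmp_path / "truth.json")
        back = SyntheticTruth.from_json(tmp_path / "truth.json")
        assert back.de_genes == truth.de_genes
        assert back.module_assignments == truth.module_assignments
        assert back.enriched_terms == truth.enriched_terms


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"n_de_genes": 301},
        {"n_modules": 40, "module_size": 10},
        {"de_log2fc_range": (3.0, 2.0)},
        {"gene_set_size_range": (0, 5)},
        {"module_correlation": 1.0},
        {"dispersion": -0.1},
        {"enriched_set_de_fraction": 0.0},
        {"de_condition": 0},
    ])
    def test_inconsistent_config_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            generate_counts(dataclasses.replace(SMALL, **kwargs))


class TestPlantedStructure:
    def test_nothing_planted_when_zero_de(self):
        cfg = dataclasses.replace(SMALL, n_de_genes=0, dispersion=0.0,
                                  n_enriched_sets=0)
        cm, truth = generate_counts(cfg)
        assert truth.de_genes == {}
        sets = generate_gene_sets(cfg, truth)
        assert truth.enriched_terms == set()
        assert len(sets) == cfg.n_gene_sets

    def test_all_planted_genes_exist_in_matrix(self):
        cm, truth = generate_counts(SMALL)
        genes = set(cm.gene_ids)
        for pair, d in truth.de_genes.items():
            assert set(d) <= genes
        assert set(truth.module_assignments) <= genes

    def test_de_and_module_genes_disjoint(self):
        _, truth = generate_counts(SMALL)
        assert not truth.all_de_genes() & set(truth.module_assignments)

    def test_reversed_pair_has_negated_fold_changes(self):
        _, truth = generate_counts(SMALL)
        fwd = truth.de_genes[("OGD45_R0h", "OGD0_R0h")]
        rev = truth.de_genes[("OGD0_R0h", "OGD45_R0h")]
        assert {g: -v for g, v in fwd.items()} == rev

    def test_full_de_fraction_sets_are_subsets_of_planted(self):
        cfg = dataclasses.replace(SMALL, enriched_set_de_fraction=1.0,
                                  gene_set_size_range=(10, 10))
        cm, truth = generate_counts(cfg)
        sets = generate_gene_sets(cfg, truth)
        de = truth.all_de_genes()
        for tid in truth.enriched_terms:
            assert sets.members(tid) <= de
        assert len(truth.enriched_terms) == cfg.n_enriched_sets

    def test_enriched_sets_need_enough_de_genes(self):
        cfg = dataclasses.replace(SMALL, n_de_genes=5, enriched_set_de_fraction=1.0,
                                  gene_set_size_range=(10, 10))
        _, truth = generate_counts(cfg)
        with pytest.raises(ValidationError):
            generate_gene_sets(cfg, truth)

    def test_mechanism_list_mixes_de_and_background(self):
        cm, truth = generate_counts(SMALL)
        mech = generate_mechanism_list(SMALL, truth, n_de_members=10, n_background=5)
        de = truth.all_de_genes()
        assert len(mech & de) == 10
        assert len(mech - de) == 5


class TestFidelity:
    def test_mean_fidelity_poisson_deep_library(self):
        """With no overdispersion and a deep library, every realized log2 RPKM
        ratio sits within 0.25 of its planted value."""
        cfg = SimulationConfig(
            n_genes=200, n_de_genes=20, de_log2fc_range=(1.0, 2.0),
            mean_library_size=10**8, dispersion=0.0,
            gene_length_log_mean=7.6, gene_length_log_sd=0.3,
            baseline_expression_log_mean=4.0, baseline_expression_log_sd=0.3,
            n_modules=0, seed=11,
        )
        cm, truth = generate_counts(cfg)
        em = compute_rpkm(cm)
        planted = truth.de_genes[("OGD45_R0h", "OGD0_R0h")]
        ratio = np.log2(em.rpkm["OGD45_R0h"] / em.rpkm["OGD0_R0h"])
        for gene, lfc in planted.items():
            assert ratio[gene] == pytest.approx(lfc, abs=0.25)

    def test_module_correlation_fidelity_extended_profiles(self):
        """Average intra-module Pearson correlation of log2(RPKM+1) over 24
        conditions lands within 0.15 of the configured target."""
        for rho in (0.6, 0.95):
            cfg = SimulationConfig(
                n_genes=150, n_conditions=24, n_de_genes=0, n_modules=3,
                module_size=15, module_correlation=rho,
                mean_library_size=10**7, n_enriched_sets=0, seed=13,
            )
            cm, truth = generate_counts(cfg)
            em = compute_rpkm(cm)
            log_expr = np.log2(em.rpkm + 1.0)
            means = []
            for mod in sorted(set(truth.module_assignments.values())):
                members = [g for g, m in truth.module_assignments.items() if m == mod]
                c = np.corrcoef(log_expr.loc[members].to_numpy())
                iu = np.triu_indices(len(members), k=1)
                means.append(c[iu].mean())
            assert np.mean(means) == pytest.approx(rho, abs=0.15)

    def test_marginal_counts_track_expected_depth(self):
        cfg = dataclasses.replace(SMALL, n_de_genes=0, n_modules=0, dispersion=0.0)
        cm, _ = generate_counts(cfg)
        # realized library sums should be within a few percent of each other
        # times the ratio implied by RPKM scaling (same expected composition)
        sums = cm.counts.sum(axis=0).to_numpy(dtype=float)
        assert sums.std() / sums.mean() < 0.05


class TestRecovery:
    def test_deg_caller_recovers_planted_de(self):
        """Reference scenario: >= 90% sensitivity for planted 4-16x changes."""
        cfg = SimulationConfig(n_modules=0, seed=5)
        cm, truth = generate_counts(cfg)
        em = compute_rpkm(cm)
        degs = call_degs(em, cm, "OGD45_R0h", "OGD0_R0h")
        planted = truth.de_set("OGD45_R0h", "OGD0_R0h")
        called = set(degs["gene_id"])
        assert len(called & planted) / len(planted) >= 0.9
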