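import numpy as np
import pandas as pd
import pytest

from mirweave import (
    SimulationConfig,
    TargetCompendium,
    classify_de_genes,
    compute_log2cpm,
    cross_tissue_mirna_correlation,
    cross_tissue_target_overlap,
    enrich_mirna_targets,
    fit_de,
    list_overlap,
    run_all_modes,
    screen_de_mirnas,
    simulate_blood_mirnas,
    simulate_paired_counts,
    simulate_study,
    make_ground_truth,
)
from _oracles import hypergeom_upper_tail_exact


def _de_table(up=(), down=(), ns=()):
    rows = []
    for ids, direction in ((up, "up"), (down, "down"), (ns, "ns")):
        for f in ids:
            rows.append(dict(feature_id=f, log2fc={"up": 1.0, "down": -1.0, "ns": 0.0}[direction],
                             pvalue=0.01, qvalue=0.01, direction=direction))
    return pd.DataFrame(rows)


class TestEnrichMirnaTargets:
    def test_pvalue_matches_enumeration(self):
        genes = [f"g{i}" for i in range(100)]
        targets = frozenset(genes[:10])
        down = genes[:8] + genes[50:62]  # 8 of the 10 targets among 20 down genes
        comp = TargetCompendium({"m1": targets, "m2": frozenset(genes)})
        cand = _de_table(up=["m1"])
        gene_de = _de_table(down=down, ns=[g for g in genes if g not in down])
        net = enrich_mirna_targets(cand, gene_de, comp, "canonical_up_down")
        row = net.regulators.iloc[0]
        assert (row["N"], row["K"], row["n"], row["k"]) == (100, 10, 20, 8)
        expected = float(hypergeom_upper_tail_exact(100, 10, 20, 8))
        assert row["pvalue"] == pytest.approx(expected, rel=1e-9)

    def test_no_overlap_gives_p_one_and_no_edges(self):
        genes = [f"g{i}" for i in range(50)]
        comp = TargetCompendium({"m1": frozenset(genes[:5]), "m2": frozenset(genes)})
        gene_de = _de_table(down=genes[10:20], ns=genes[:10] + genes[20:])
        net = enrich_mirna_targets(_de_table(up=["m1"]), gene_de, comp, "canonical_up_down")
        assert net.regulators.iloc[0]["pvalue"] == 1.0
        assert net.edges == set()

    def test_mirna_without_universe_targets_skipped(self):
        comp = TargetCompendium({"m1": frozenset(["other"]), "m2": frozenset(["g0", "g1"])})
        gene_de = _de_table(down=["g0"], ns=["g1"])
        net = enrich_mirna_targets(_de_table(up=["m1", "m2"]), gene_de, comp, "canonical_up_down")
        assert list(net.regulators["mirna_id"]) == ["m2"]

    def test_empty_universe_raises(self):
        comp = TargetCompendium({"m1": frozenset(["x"])})
        gene_de = _de_table(down=["g0"])
        with pytest.raises(ValueError):
            enrich_mirna_targets(_de_table(up=["m1"]), gene_de, comp, "canonical_up_down")

    def test_unknown_mode_raises(self):
        comp = TargetCompendium({"m1": frozenset(["g0"])})
        with pytest.raises(ValueError):
            enrich_mirna_targets(_de_table(), _de_table(ns=["g0"]), comp, "sideways")

    def test_edges_are_bipartite_and_constrained(self, default_study):
        de = classify_de_genes(fit_de(default_study.gene_counts, default_study.metadata))
        mi = screen_de_mirnas(fit_de(default_study.mirna_counts, default_study.metadata))
        net = enrich_mirna_targets(mi, de, default_study.compendium, "canonical_up_down")
        down = set(de.loc[de["direction"] == "down", "feature_id"])
        sig = set(net.significant_regulators)
        for mirna, gene in net.edges:
            assert mirna in sig
            assert gene in down
            assert gene in default_study.compendium.targets[mirna]

    def test_significant_regulators_are_enriched_not_depleted(self, default_study):
        de = classify_de_genes(fit_de(default_study.gene_counts, default_study.metadata))
        mi = screen_de_mirnas(fit_de(default_study.mirna_counts, default_study.metadata))
        net = enrich_mirna_targets(mi, de, default_study.compendium, "canonical_up_down")
        sig = net.regulators[net.regulators["qvalue"] < 0.05]
        assert len(sig) > 0
        assert (sig["k"] / sig["n"] > sig["K"] / sig["N"]).all()


class TestRunAllModes:
    def test_planted_structure_fills_only_canonical_mode(self, default_study):
        de = classify_de_genes(fit_de(default_study.gene_counts, default_study.metadata))
        mi = screen_de_mirnas(fit_de(default_study.mirna_counts, default_study.metadata))
        nets = run_all_modes(mi, de, default_study.compendium)
        assert len(nets) == 4
        assert len(nets["canonical_up_down"].significant_regulators) > 0
        assert len(nets["noncanonical_up_up"].significant_regulators) == 0
        assert len(nets["canonical_down_up"].significant_regulators) == 0

    def test_no_candidates_gives_empty_networks(self):
        comp = TargetCompendium({"m1": frozenset(["g0"])})
        gene_de = _de_table(down=["g0"], ns=["g1"])
        nets = run_all_modes(_de_table(ns=["m1"]), gene_de, comp)
        assert all(len(n.regulators) == 0 for n in nets.values())

    def test_mode_gene_lists_partition_directions(self):
        # up and down gene lists are disjoint by construction
        genes = [f"g{i}" for i in range(30)]
        comp = TargetCompendium({"m1": frozenset(genes)})
        gene_de = _de_table(up=genes[:10], down=genes[10:25], ns=genes[25:])
        nets = run_all_modes(_de_table(up=["m1"]), gene_de, comp)
        n_up = nets["noncanonical_up_up"].regulators.iloc[0]["n"]
        n_down = nets["canonical_up_down"].regulators.iloc[0]["n"]
        assert (n_up, n_down) == (10, 15)


class TestDecoyCalibration:
    def test_decoy_only_compendium_false_positive_rate(self):
        # no planted regulators: every tested miRNA is a null
        sig_counts, tested = [], []
        for seed in range(1, 16):
            cfg = SimulationConfig.null(
                n_genes=500, n_mirnas=20, n_true_regulators=0,
                targets_per_mirna=25, seed=seed,
            )
            truth = make_ground_truth(cfg)
            genes, mirnas, meta = simulate_paired_counts(cfg, truth)
            comp = __import__("mirweave").generate_target_compendium(cfg, truth)
            de = classify_de_genes(fit_de(genes, meta))
            mi = screen_de_mirnas(fit_de(mirnas, meta))
            for mode in ("canonical_up_down", "canonical_down_up"):
                net = enrich_mirna_targets(mi, de, comp, mode)
                sig_counts.append(len(net.significant_regulators))
                tested.append(len(net.regulators))
        assert np.mean(sig_counts) <= 0.05 * max(np.mean(tested), 1.0)


class TestListOverlap:
    def test_expected_overlap_arithmetic(self):
        universe = [f"g{i}" for i in range(347)]
        a, b = universe[:107], universe[50:211]
        res = list_overlap(a, b, universe)
        assert res.expected_overlap == pytest.approx(107 * 161 / 347)
        assert res.overlap == len(set(a) & set(b))

    def test_disjoint_lists(self):
        universe = [f"g{i}" for i in range(100)]
        res = list_overlap(universe[:20], universe[50:70], universe)
        assert res.overlap == 0
        assert res.pvalue > 0.95

    def test_identical_lists_minimal_p(self):
        universe = [f"g{i}" for i in range(100)]
        res = list_overlap(universe[:10], universe[:10], universe)
        assert res.overlap == 10
        expected = float(hypergeom_upper_tail_exact(100, 10, 10, 10))
        assert res.pvalue == pytest.approx(expected, rel=1e-9)

    def test_list_outside_universe_raises(self):
        with pytest.raises(ValueError):
            list_overlap(["a"], ["b"], ["b", "c"])

    def test_network_target_overlap(self, default_study):
        de = classify_de_genes(fit_de(default_study.gene_counts, default_study.metadata))
        mi = screen_de_mirnas(fit_de(default_study.mirna_counts, default_study.metadata))
        net = enrich_mirna_targets(mi, de, default_study.compendium, "canonical_up_down")
        universe = set(de["feature_id"]) & set(default_study.compendium.universe)
        res = cross_tissue_target_overlap(net, net, universe)
        assert res.overlap == len(net.target_genes)


class TestCrossTissueCorrelation:
    def test_identical_matrices_give_unit_correlation(self):
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(rng.normal(size=(5, 10)),
                            index=[f"m{i}" for i in range(5)],
                            columns=[f"s{i}" for i in range(10)])
        tab = cross_tissue_mirna_correlation(expr, expr)
        assert np.allclose(tab["r"], 1.0)

    def test_null_calibration_on_independent_tissues(self):
        rng = np.random.default_rng(1)
        a = pd.DataFrame(rng.normal(size=(200, 26)), index=[f"m{i}" for i in range(200)],
                         columns=[f"s{i}" for i in range(26)])
        b = pd.DataFrame(rng.normal(size=(200, 26)), index=a.index, columns=a.columns)
        tab = cross_tissue_mirna_correlation(a, b)
        assert 0.005 <= tab["significant"].mean() <= 0.12

    def test_planted_donor_latent_recovered(self):
        cfg = SimulationConfig(
            nb_dispersion=0.01, donor_latent_sd=1.0,
            cross_tissue_loading=1.0, cross_tissue_noise_sd=0.2,
            covariate_effects={}, module_factor_sd=0.0, seed=9,
        )
        truth = make_ground_truth(cfg)
        _, brain, _ = simulate_paired_counts(cfg, truth)
        blood = simulate_blood_mirnas(cfg, truth)
        tab = cross_tissue_mirna_correlation(compute_log2cpm(brain), compute_log2cpm(blood))
        assert tab["r"].median() >= 0.8

    def test_too_few_shared_donors_raise(self):
        expr = pd.DataFrame(np.ones((2, 2)), index=["m1", "m2"], columns=["s1", "s2"])
        with pytest.raises(ValueError):
            cross_tissue_mirna_correlation(expr, expr)

    def test_constant_mirnas_skipped(self):
        rng = np.random.default_rng(2)
        a = pd.DataFrame(rng.normal(size=(3, 8)), index=["m1", "m2", "m3"],
                         columns=[f"s{i}" for i in range(8)])
        b = a.copy()
        b.loc["m2"] = 1.0
        tab = cross_tissue_mirna_correlation(a, b)
        assert set(tab["mirna_id"]) == {"m1", "m3"}
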