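import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from mirweave import (
    compute_adjacency,
    compute_eigengenes,
    compute_tom,
    deconvolve_fractions,
    detect_modules,
    module_trait_association,
    pick_soft_threshold,
    simulate_coexpression_blocks,
)
from _oracles import tom_brute_force


def _frame(arr, prefix="g"):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(
        arr, index=[f"{prefix}{i}" for i in range(arr.shape[0])],
        columns=[f"s{i}" for i in range(arr.shape[1])],
    )


class TestAdjacency:
    def test_perfectly_correlated_pair(self):
        expr = _frame([[1, 2, 3, 4], [2, 4, 6, 8]])
        adj = compute_adjacency(expr, power=1)
        assert adj.iloc[0, 1] == pytest.approx(1.0)

    def test_contract_symmetric_unit_interval_zero_diag(self):
        rng = np.random.default_rng(0)
        adj = compute_adjacency(_frame(rng.normal(size=(15, 30))), power=6).to_numpy()
        assert np.allclose(adj, adj.T)
        assert adj.min() >= 0 and adj.max() <= 1
        assert np.all(np.diag(adj) == 0)

    def test_higher_power_never_increases_adjacency(self):
        rng = np.random.default_rng(1)
        expr = _frame(rng.normal(size=(10, 25)))
        a2 = compute_adjacency(expr, 2).to_numpy()
        a6 = compute_adjacency(expr, 6).to_numpy()
        assert np.all(a6 <= a2 + 1e-12)

    def test_constant_gene_rejected(self):
        expr = _frame([[1, 1, 1, 1], [1, 2, 3, 4]])
        with pytest.raises(ValueError):
            compute_adjacency(expr, 2)


class TestSoftThreshold:
    def test_single_candidate_returned(self):
        rng = np.random.default_rng(2)
        expr = _frame(rng.normal(size=(10, 20)))
        assert pick_soft_threshold(expr, candidate_powers=[7]) == 7

    def test_empty_candidates_raise(self):
        rng = np.random.default_rng(2)
        with pytest.raises(ValueError):
            pick_soft_threshold(_frame(rng.normal(size=(6, 10))), candidate_powers=[])

    def test_block_structure_reaches_good_fit(self):
        from mirweave.coexpression import compute_adjacency as adj, scale_free_fit

        expr, _ = simulate_coexpression_blocks([7, 11, 18, 20, 36], 60, 0.8, 26, seed=5)
        power = pick_soft_threshold(expr)
        assert scale_free_fit(adj(expr, power)) >= 0.8


class TestTom:
    def test_hand_computed_three_gene_example(self):
        a = pd.DataFrame(0.5 * (1 - np.eye(3)), index=list("abc"), columns=list("abc"))
        tom = compute_tom(a)
        # (0.25 + 0.5) / (1 + 1 - 0.5) = 0.5
        off = tom.to_numpy()[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 0.5)
        assert np.allclose(np.diag(tom), 1.0)

    def test_zero_adjacency_gives_zero_overlap(self):
        a = pd.DataFrame(np.zeros((4, 4)), index=list("abcd"), columns=list("abcd"))
        tom = compute_tom(a).to_numpy()
        assert np.allclose(tom[~np.eye(4, dtype=bool)], 0.0)

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            raw = rng.uniform(0, 1, size=(20, 20))
            a = (raw + raw.T) / 2
            np.fill_diagonal(a, 0.0)
            frame = pd.DataFrame(a, index=[f"g{i}" for i in range(20)],
                                 columns=[f"g{i}" for i in range(20)])
            assert np.max(np.abs(compute_tom(frame).to_numpy() - tom_brute_force(a))) < 1e-10

    def test_asymmetric_input_raises(self):
        a = pd.DataFrame([[0, 0.2], [0.4, 0]], index=list("ab"), columns=list("ab"))
        with pytest.raises(ValueError):
            compute_tom(a)


class TestDetectModules:
    def _assign(self, sizes, n_noise, seed, n_samples=60, within=0.8):
        expr, labels = simulate_coexpression_blocks(sizes, n_samples, within, n_noise, seed)
        power = pick_soft_threshold(expr)
        tom = compute_tom(compute_adjacency(expr, power))
        return detect_modules(tom), labels

    def test_cluster_below_minimum_size_goes_grey(self):
        assign, _ = self._assign([4], n_noise=10, seed=1)
        assert (assign == "grey").all()

    def test_planted_blocks_recovered(self):
        assign, labels = self._assign([7, 11, 18, 20, 36], n_noise=26, seed=2)
        ari = adjusted_rand_score([labels[g] for g in assign.index], list(assign))
        assert ari >= 0.8
        assert all(assign[g] == "grey" for g in assign.index if labels[g] == "grey")
        sizes = assign.value_counts()
        assert all(s >= 5 for m, s in sizes.items() if m != "grey")

    def test_partition_covers_every_gene_once(self):
        assign, labels = self._assign([10, 10], n_noise=5, seed=3)
        assert len(assign) == len(labels)
        assert assign.index.is_unique

    def test_independent_genes_mostly_all_grey(self):
        all_grey = 0
        n_seeds = 20
        for seed in range(n_seeds):
            assign, _ = self._assign([], n_noise=40, seed=seed)
            all_grey += int((assign == "grey").all())
        assert all_grey >= 0.9 * n_seeds

    def test_min_module_size_validation(self):
        tom = pd.DataFrame(np.eye(3), index=list("abc"), columns=list("abc"))
        with pytest.raises(ValueError):
            detect_modules(tom, min_module_size=1)


class TestEigengenes:
    def test_identical_members_reproduce_profile(self):
        rng = np.random.default_rng(4)
        profile = rng.normal(size=30)
        expr = _frame(np.tile(profile, (6, 1)) + rng.normal(0, 1e-8, size=(6, 30)))
        assign = pd.Series(["turquoise"] * 6, index=expr.index)
        eig, varex = compute_eigengenes(expr, assign)
        r = np.corrcoef(eig.loc["turquoise"], profile)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-6)
        assert varex["turquoise"] == pytest.approx(1.0, abs=1e-6)

    def test_sign_orientation_invariant_to_member_flip(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=(8, 40))
        factor = rng.normal(size=40)
        expr = _frame(factor + 0.2 * base)
        assign = pd.Series(["blue"] * 8, index=expr.index)
        eig1, _ = compute_eigengenes(expr, assign)
        eig2, _ = compute_eigengenes(-expr, assign)
        r = np.corrcoef(eig1.loc["blue"], eig2.loc["blue"])[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-9)
        for e in (eig1, eig2):
            mean_r = np.mean(
                [np.corrcoef(e.loc["blue"], expr.loc[g] * s)[0, 1]
                 for g, s in zip(expr.index, [1] * 8)]
            )
        assert eig1.loc["blue"].std(ddof=1) == pytest.approx(1.0)

    def test_variance_explained_at_least_reciprocal_size(self):
        rng = np.random.default_rng(6)
        expr = _frame(rng.normal(size=(9, 25)))
        assign = pd.Series(["brown"] * 9, index=expr.index)
        _, varex = compute_eigengenes(expr, assign)
        assert varex["brown"] >= 1 / 9


class TestDeconvolution:
    def _signature(self, n_markers=30, n_types=3, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            rng.uniform(1, 10, size=(n_markers, n_types)),
            index=[f"g{i}" for i in range(n_markers)],
            columns=[f"type{t}" for t in range(n_types)],
        )

    def test_pure_type_recovered(self):
        S = self._signature()
        bulk = pd.DataFrame({"s1": S["type1"]}, index=S.index)
        frac = deconvolve_fractions(bulk, S)
        assert frac.loc["s1", "type1"] == pytest.approx(1.0, abs=1e-9)

    def test_noiseless_mixture_exact(self):
        S = self._signature()
        mix = np.array([[0.3, 0.7, 0.0], [0.2, 0.3, 0.5]])
        bulk = pd.DataFrame((S.to_numpy() @ mix.T), index=S.index, columns=["s1", "s2"])
        frac = deconvolve_fractions(bulk, S)
        assert np.abs(frac.to_numpy() - mix).max() < 1e-6

    def test_noisy_mixture_within_tolerance(self):
        rng = np.random.default_rng(7)
        S = self._signature(n_markers=60)
        mix = rng.dirichlet([2, 2, 2], size=20)
        clean = S.to_numpy() @ mix.T
        noisy = clean * (1 + rng.normal(0, 0.05, size=clean.shape))
        bulk = pd.DataFrame(noisy, index=S.index, columns=[f"s{i}" for i in range(20)])
        frac = deconvolve_fractions(bulk, S)
        assert np.abs(frac.to_numpy() - mix).max() <= 0.05

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(8)
        S = self._signature()
        bulk = pd.DataFrame(rng.uniform(0, 20, size=(30, 7)), index=S.index,
                            columns=[f"s{i}" for i in range(7)])
        frac = deconvolve_fractions(bulk, S)
        assert np.allclose(frac.sum(axis=1), 1.0, atol=1e-9)
        assert frac.to_numpy().min() >= 0

    def test_rank_deficient_signature_raises(self):
        S = self._signature(n_types=2)
        S["type1"] = S["type0"]
        bulk = pd.DataFrame({"s1": S["type0"]}, index=S.index)
        with pytest.raises(ValueError):
            deconvolve_fractions(bulk, S)


class TestTraitAssociation:
    def test_eigengene_equal_to_trait(self):
        rng = np.random.default_rng(9)
        e = rng.normal(size=20)
        eig = pd.DataFrame([e], index=["turquoise"], columns=[f"s{i}" for i in range(20)])
        traits = pd.DataFrame({"status": e, "noise": rng.normal(size=20)}, index=eig.columns)
        tab = module_trait_association(eig, traits).set_index("trait")
        assert tab.loc["status", "r"] == pytest.approx(1.0)
        assert bool(tab.loc["status", "significant"])

    def test_permutation_destroys_association(self):
        rng = np.random.default_rng(10)
        e = rng.normal(size=30)
        eig = pd.DataFrame([e], index=["blue"], columns=[f"s{i}" for i in range(30)])
        pvals = []
        for _ in range(20):
            perm = rng.permutation(e)
            traits = pd.DataFrame({"status": perm}, index=eig.columns)
            pvals.append(module_trait_association(eig, traits)["pvalue"].iloc[0])
        assert np.median(pvals) > 0.05

    def test_constant_trait_skipped(self):
        rng = np.random.default_rng(11)
        eig = pd.DataFrame([rng.normal(size=10)], index=["m"],
                           columns=[f"s{i}" for i in range(10)])
        traits = pd.DataFrame({"flat": np.ones(10), "ok": rng.normal(size=10)},
                              index=eig.columns)
        tab = module_trait_association(eig, traits)
        assert set(tab["trait"]) == {"ok"}
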