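import numpy as np
import pytest

from grasstraits.pgls import profile_lambda
from grasstraits.synthetic import (
    SimConfig,
    assign_groups,
    simulate_study,
    simulate_traits,
    simulate_yule_tree,
)
from grasstraits.treeio import phylo_covariance, write_newick


class TestYuleTree:
    def test_tip_count_and_binary_topology(self):
        tree = simulate_yule_tree(42, seed=1)
        assert tree.n_tips == 42
        internal = sum(1 for n in tree._dtree.preorder_node_iter() if not n.is_leaf())
        assert internal == 41

    def test_ultrametric_with_unit_depth(self):
        tree = simulate_yule_tree(30, seed=2)
        depths = np.array(list(tree.depths().values()))
        np.testing.assert_allclose(depths, 1.0, atol=1e-9)

    def test_deterministic_given_seed(self):
        assert write_newick(simulate_yule_tree(20, seed=5)) == write_newick(
            simulate_yule_tree(20, seed=5)
        )
        assert write_newick(simulate_yule_tree(20, seed=5)) != write_newick(
            simulate_yule_tree(20, seed=6)
        )

    def test_too_few_tips(self):
        with pytest.raises(ValueError):
            simulate_yule_tree(1, seed=0)


def mean_pairwise_cov(C, idx):
    sub = C[np.ix_(idx, idx)]
    return (sub.sum() - np.trace(sub)) / (len(idx) * (len(idx) - 1))


class TestAssignGroups:
    def test_default_cell_counts_match_study(self, study):
        _, groups, _ = study
        cells = groups.groupby(["PT", "AP"]).size()
        assert cells[("C3", "annual")] == 4
        assert cells[("C3", "perennial")] == 6
        assert cells[("C4", "annual")] == 13
        assert cells[("C4", "perennial")] == 19

    def test_deterministic_given_seed(self):
        tree = simulate_yule_tree(42, seed=3)
        a = assign_groups(tree, SimConfig(seed=3))
        b = assign_groups(tree, SimConfig(seed=3))
        assert a.equals(b)

    def test_pt_is_phylogenetically_clustered_by_default(self):
        """C3 tips share more history than random tip sets when the latent
        character is strongly clustered, and do not when clustering is 0."""
        tree = simulate_yule_tree(42, seed=11)
        C = phylo_covariance(tree).C
        rng = np.random.default_rng(0)
        stats = {0.0: [], 0.95: []}
        for strength in stats:
            for seed in range(100):
                cfg = SimConfig(seed=seed, pt_clustering=strength)
                g = assign_groups(tree, cfg)
                idx = np.flatnonzero((g["PT"] == "C3").to_numpy())
                stats[strength].append(mean_pairwise_cov(C, idx))
        perm = [
            mean_pairwise_cov(C, rng.choice(42, size=10, replace=False))
            for _ in range(400)
        ]
        null_mean = np.mean(perm)
        se0 = np.sqrt(np.var(stats[0.0]) / 100 + np.var(perm) / 400)
        se1 = np.sqrt(np.var(stats[0.95]) / 100 + np.var(perm) / 400)
        # strength 0: mean statistic consistent with random tip draws
        assert abs(np.mean(stats[0.0]) - null_mean) < 4 * se0
        # default strength: clearly elevated shared history among C3 tips
        assert np.mean(stats[0.95]) - null_mean > 4 * se1

    def test_infeasible_counts_error(self):
        tree = simulate_yule_tree(10, seed=1)
        with pytest.raises(ValueError):
            assign_groups(tree, SimConfig(n_tips=10, seed=1,
                                          cells={"C3-annual": 4, "C3-perennial": 6,
                                                 "C4-annual": 13, "C4-perennial": 19}))


class TestSimulateTraits:
    def test_zero_variance_is_exact_mean(self, three_tip):
        _, cov = three_tip
        X = np.column_stack([np.ones(3), [0, 1, 2]])
        y = simulate_traits(cov, X, [1.0, 2.0], 0.0, 1.0, seed=0)
        np.testing.assert_allclose(y, X @ [1.0, 2.0], atol=1e-12)

    def test_empirical_covariance_matches_tree(self, three_tip):
        _, cov = three_tip
        reps = simulate_traits(cov, np.ones((3, 1)), [0.0], 1.0, 1.0, seed=1, n_reps=20_000)
        emp = np.cov(reps, rowvar=False)
        np.testing.assert_allclose(emp, cov.C, rtol=0.05, atol=0.05)

    def test_lambda_zero_removes_shared_covariance(self, three_tip):
        _, cov = three_tip
        reps = simulate_traits(cov, np.ones((3, 1)), [0.0], 1.0, 0.0, seed=2, n_reps=5000)
        emp = np.cov(reps, rowvar=False)
        off = emp[~np.eye(3, dtype=bool)]
        assert np.abs(off).max() < 0.05 * emp.diagonal().mean() + 0.05

    @pytest.mark.parametrize("lam", [0.0, 0.5, 1.0])
    def test_profile_lambda_recovers_generating_value(self, lam):
        """Generative/inferential consistency at n=200 tips."""
        tree = simulate_yule_tree(200, seed=31)
        C = phylo_covariance(tree)
        X = np.ones((200, 1))
        est = np.array([
            profile_lambda(simulate_traits(C, X, [0.0], 1.0, lam, seed=70_000 + r), X, C).lambda_hat
            for r in range(20)
        ])
        se = max(est.std(ddof=1) / np.sqrt(20), 0.01)
        assert abs(est.mean() - lam) < 4 * se + 0.02


class TestSimulateStudy:
    def test_bundle_shape_matches_study(self, bundle):
        assert bundle.traits.shape == (42, 26)
        assert bundle.niche.shape == (42, 6)
        assert bundle.niche.dropna(how="any").shape[0] == 34
        assert set(bundle.trait_meta["class"]) == {"structural", "physiological"}
        assert (bundle.trait_meta["class"] == "structural").sum() == 15
        assert (bundle.trait_meta["class"] == "physiological").sum() == 11

    def test_negative_traits_are_negative_on_natural_scale(self, bundle):
        for trait in ("Psi_tlp", "Psi_pre", "Psi_mid", "d13C"):
            assert (bundle.traits[trait] < 0).all()

    def test_byte_identical_given_config(self, tmp_path):
        a = simulate_study(SimConfig(seed=8))
        b = simulate_study(SimConfig(seed=8))
        a.write(tmp_path / "a")
        b.write(tmp_path / "b")
        for name in ("tree.nwk", "groups.tsv", "traits.tsv", "niche.tsv", "truth.json"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_truth_record_lists_generating_models(self, bundle):
        assert bundle.truth["traits"]["K_leaf"]["model"] == "AP×PT"
        assert set(bundle.truth["niche"]) == set(bundle.niche.columns)
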