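import subprocess
import sys

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

from grasstraits.pgls import aicc, build_design, gls_fit, profile_lambda
from grasstraits.synthetic import simulate_traits, simulate_yule_tree
from grasstraits.treeio import lambda_transform, parse_newick, phylo_covariance, write_newick


def balanced_tree_newick(depth: int, edge: float = 1.0) -> str:
    """Balanced binary tree with unit edges (deep shared history)."""

    def rec(d, prefix):
        if d == 0:
            return f"{prefix}:{edge}"
        return f"({rec(d - 1, prefix + 'L')},{rec(d - 1, prefix + 'R')}):{edge}"

    return f"({rec(depth - 1, 'L')},{rec(depth - 1, 'R')});"


class TestBuildDesign:
    @staticmethod
    def groups(ap, pt):
        return pd.DataFrame({"AP": ap, "PT": pt})

    def test_saturated_interaction_design(self):
        g = self.groups(
            ["annual", "annual", "perennial", "perennial"], ["C3", "C4", "C3", "C4"]
        )
        d = build_design(g, "AP×PT")
        assert d.X.shape == (4, 4)
        assert np.linalg.matrix_rank(d.X) == 4
        assert d.column_names == ["intercept", "AP[perennial]", "PT[C4]", "AP:PT"]

    def test_single_level_factor_is_rank_error(self):
        g = self.groups(["annual"] * 4, ["C3", "C4", "C3", "C4"])
        with pytest.raises(ValueError, match="AP"):
            build_design(g, "AP")

    def test_study_shaped_additive_design(self, study):
        _, groups, _ = study
        d = build_design(groups, "AP+PT")
        assert d.X.shape == (42, 3)
        assert np.linalg.matrix_rank(d.X) == 3
        # reference levels annual/C3: indicator sums equal perennial/C4 counts
        assert d.X[:, 1].sum() == (groups["AP"] == "perennial").sum() == 25
        assert d.X[:, 2].sum() == (groups["PT"] == "C4").sum() == 32


class TestGlsFit:
    def test_identity_covariance_reduces_to_mean(self):
        beta, sigma2, _ = gls_fit([1, 2, 3], np.ones((3, 1)), np.eye(3))
        assert beta[0] == pytest.approx(2.0)
        assert sigma2 == pytest.approx(2 / 3)

    def test_diagonal_weights_hand_computed(self):
        # weighted mean (1 + 2 + 3/4) / (1 + 1 + 1/4) = 5/3
        beta, _, _ = gls_fit([1, 2, 3], np.ones((3, 1)), np.diag([1.0, 1.0, 4.0]))
        assert beta[0] == pytest.approx(5 / 3)

    @pytest.mark.parametrize("seed", range(5))
    def test_loglik_matches_mvn_density_oracle(self, seed):
        """logL equals the multivariate-normal density at (X beta, sigma2 V)."""
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 9)
        tree = simulate_yule_tree(int(n), seed=seed + 100)
        V = lambda_transform(phylo_covariance(tree), 0.7).C
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = rng.standard_normal(n) * 2 + 1
        beta, sigma2, logL = gls_fit(y, X, V)
        oracle = multivariate_normal(mean=X @ beta, cov=sigma2 * V).logpdf(y)
        assert logL == pytest.approx(oracle, abs=1e-8)

    def test_lambda_zero_equals_ols(self, study):
        """With lambda=0 the GLS fit must reduce to OLS on (y, X)."""
        sm = pytest.importorskip("statsmodels.api")
        _, groups, C = study
        X = build_design(groups, "AP+PT").X
        rng = np.random.default_rng(0)
        y = X @ np.array([1.0, 0.5, -0.5]) + rng.standard_normal(42)
        V0 = lambda_transform(C, 0.0).C
        beta, sigma2, logL = gls_fit(y, X, V0)
        ols = sm.OLS(y, X).fit()
        np.testing.assert_allclose(beta, ols.params, atol=1e-8)
        oracle = multivariate_normal(mean=X @ beta, cov=sigma2 * V0).logpdf(y)
        assert logL == pytest.approx(oracle, abs=1e-8)

    def test_degenerate_perfect_fit_is_error(self, three_tip):
        _, cov = three_tip
        X = np.column_stack([np.ones(3), [0.0, 1.0, 2.0]])
        with pytest.raises(FloatingPointError):
            gls_fit(X @ np.array([1.0, 2.0]), X, cov.C)


class TestAicc:
    def test_hand_arithmetic(self):
        assert aicc(0.0, 2, 42) == pytest.approx(4 + 12 / 39)

    def test_converges_to_aic_for_large_n(self):
        assert aicc(0.0, 3, 10**6) - 6.0 < 1e-4

    def test_small_sample_error(self):
        with pytest.raises(ValueError):
            aicc(0.0, 9, 10)


class TestProfileLambda:
    def test_star_tree_lambda_unidentifiable_returns_zero(self):
        nwk = "(" + ",".join(f"t{i}:1" for i in range(12)) + ");"
        C = phylo_covariance(parse_newick(nwk))
        rng = np.random.default_rng(1)
        fit = profile_lambda(rng.standard_normal(12), np.ones((12, 1)), C)
        assert fit.lambda_hat == 0.0

    def test_brownian_traits_recover_high_lambda(self):
        """Traits simulated with lambda=1 on a 100-tip tree: median estimate > 0.7."""
        tree = simulate_yule_tree(100, seed=11)
        C = phylo_covariance(tree)
        X = np.ones((100, 1))
        est = [
            profile_lambda(
                simulate_traits(C, X, [0.0], 1.0, 1.0, seed=40_000 + r), X, C
            ).lambda_hat
            for r in range(50)
        ]
        assert np.median(est) > 0.7

    def test_independent_noise_recovers_low_lambda(self):
        """iid noise on a deep balanced tree: lambda < 0.2 in >= 90% of replicates."""
        tree = parse_newick(balanced_tree_newick(6))
        C = phylo_covariance(tree)
        n = len(C.taxa)
        X = np.ones((n, 1))
        rng = np.random.default_rng(5)
        est = [profile_lambda(rng.standard_normal(n), X, C).lambda_hat for _ in range(50)]
        assert np.mean(np.asarray(est) < 0.2) >= 0.9

    def test_scaling_response_shifts_all_loglik_equally(self, study):
        """y -> c y shifts every model's logL by the same constant, so all
        AICc differences are invariant (this is why the log base is inert)."""
        _, groups, C = study
        rng = np.random.default_rng(8)
        y = rng.standard_normal(42) + 3.0
        fits, fits_scaled = {}, {}
        for m in ("AP", "PT", "AP+PT"):
            X = build_design(groups, m)
            fits[m] = profile_lambda(y, X, C)
            fits_scaled[m] = profile_lambda(7.5 * y, X, C)
        shifts = [fits_scaled[m].logL - fits[m].logL for m in fits]
        assert max(shifts) - min(shifts) == pytest.approx(0.0, abs=1e-10)
        d0 = fits["AP"].aicc - fits["PT"].aicc
        d1 = fits_scaled["AP"].aicc - fits_scaled["PT"].aicc
        assert d0 == pytest.approx(d1, abs=1e-10)

    def test_k_counts_lambda_by_default_and_is_configurable(self, study):
        _, groups, C = study
        rng = np.random.default_rng(2)
        y = rng.standard_normal(42)
        X = build_design(groups, "AP")
        assert profile_lambda(y, X, C).k == 4
        assert profile_lambda(y, X, C, count_lambda_in_k=False).k == 3

    def test_agrees_with_phytools_phylosig(self, tmp_path):
        """Independent R oracle: phytools::phylosig ML lambda and logL."""
        tree = simulate_yule_tree(40, seed=21)
        C = phylo_covariance(tree)
        X = np.ones((40, 1))
        y = simulate_traits(C, X, [0.0], 1.0, 0.6, seed=99)
        fit = profile_lambda(y, X, C)
        (tmp_path / "tree.nwk").write_text(write_newick(tree) + "\n")
        (tmp_path / "y.csv").write_text(
            "\n".join(f"{t},{float(v)!r}" for t, v in zip(C.taxa, y)) + "\n"
        )
        rscript = tmp_path / "check.R"
        rscript.write_text(
            'suppressMessages(library(phytools))\n'
            f'tr <- read.tree("{tmp_path}/tree.nwk")\n'
            f'd <- read.csv("{tmp_path}/y.csv", header=FALSE)\n'
            'y <- setNames(d$V2, d$V1)\n'
            'res <- phylosig(tr, y, method="lambda")\n'
            'cat(sprintf("%.8f %.8f\\n", res$lambda, res$logL))\n'
        )
        out = subprocess.run(
            ["Rscript", str(rscript)], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        r_lambda, r_logL = map(float, out.stdout.split())
        assert fit.lambda_hat == pytest.approx(r_lambda, abs=2e-3)
        assert fit.logL == pytest.approx(r_logL, abs=1e-4)
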