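"""AICc model ranking, Tukey contrasts, PERMANOVA, and PCA."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from symbiotherm.stats import (
    CandidateModel,
    aicc,
    compact_letter_display,
    fit_candidates,
    pca,
    permanova,
    rank_by_aicc,
    tukey_contrasts,
    tukey_contrasts_oneway,
)


class TestAicc:
    def test_formula_oracle(self):
        for ll, k, n in [(-10.0, 2, 20), (-123.4, 5, 37), (0.0, 1, 4)]:
            expected = -2 * ll + 2 * k + 2 * k * (k + 1) / (n - k - 1)
            assert aicc(ll, k, n) == pytest.approx(expected, abs=0)

    def test_approaches_aic_for_large_n(self):
        ll, k, n = -500.0, 3, 10**6
        assert abs(aicc(ll, k, n) - (-2 * ll + 2 * k)) < 1e-3

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            aicc(-1.0, 5, 6)


class TestFitCandidates:
    def test_intercept_only_matches_closed_form(self):
        rng = np.random.default_rng(0)
        y = rng.normal(2.0, 1.0, 50)
        data = pd.DataFrame({"y": y})
        fits = fit_candidates(data, [CandidateModel("y ~ 1")])
        sigma2 = np.mean((y - y.mean()) ** 2)  # MLE variance
        ll = -0.5 * len(y) * (np.log(2 * np.pi * sigma2) + 1)
        assert fits[0].log_lik == pytest.approx(ll, rel=1e-10)
        assert fits[0].k == 2  # mean + variance

    def test_nested_model_loglik_ordering(self):
        rng = np.random.default_rng(1)
        data = pd.DataFrame({"y": rng.normal(size=40), "x": rng.normal(size=40)})
        fits = fit_candidates(
            data, [CandidateModel("y ~ 1"), CandidateModel("y ~ x")]
        )
        assert fits[1].log_lik >= fits[0].log_lik

    def test_random_intercept_recovered_when_present(self):
        """With real container variance the mixed candidate should win most
        of the time under AICc."""
        wins = 0
        runs = 60
        for seed in range(runs):
            rng = np.random.default_rng(seed)
            containers = np.repeat(np.arange(12), 5)
            cont_eff = rng.normal(0, 1.0, 12)[containers]
            y = 1.0 + cont_eff + rng.normal(0, 0.7, containers.size)
            data = pd.DataFrame({"y": y, "container": containers.astype(str)})
            fits = fit_candidates(
                data,
                [
                    CandidateModel("y ~ 1", name="plain"),
                    CandidateModel("y ~ 1", kind="mixed", groups="container",
                                   name="random-intercept"),
                ],
            )
            best, _ = rank_by_aicc(fits)
            wins += best.candidate.name == "random-intercept"
        assert wins / runs >= 0.8

    def test_noise_covariate_worsens_aicc_on_average(self):
        deltas = []
        for seed in range(40):
            rng = np.random.default_rng(seed)
            data = pd.DataFrame(
                {"y": rng.normal(size=30), "junk": rng.normal(size=30)}
            )
            fits = fit_candidates(
                data, [CandidateModel("y ~ 1"), CandidateModel("y ~ junk")]
            )
            deltas.append(fits[1].aicc - fits[0].aicc)
        assert np.mean(deltas) > 0


class TestRanking:
    def test_ascending_order_and_tie_break(self):
        from symbiotherm.stats import ModelFit

        a = ModelFit(CandidateModel("y ~ x", name="big"), -10.0, 4, 30,
                     aicc(-10.0, 4, 30))
        b = ModelFit(CandidateModel("y ~ 1", name="small"), -12.3, 2, 30,
                     aicc(-12.3, 2, 30))
        tie = ModelFit(CandidateModel("y ~ z", name="tied"), None, 3, 30, b.aicc)
        best, table = rank_by_aicc([a, b, tie])
        assert table.aicc.is_monotonic_increasing
        assert best.candidate.name == "small"  # tie broken by fewer parameters


class TestTukey:
    def test_two_groups_equal_t_test(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 8), rng.normal(0.7, 1, 11)
        tab = tukey_contrasts_oneway(
            np.concatenate([a, b]), np.array(["a"] * 8 + ["b"] * 11)
        )
        t = sps.ttest_ind(a, b)
        assert tab.p_adj[0] == pytest.approx(t.pvalue, abs=1e-6)

    def test_identical_groups_single_letter(self):
        vals = np.tile([1.0, 1.1, 0.9, 1.0, 1.05], 4)
        labels = np.repeat(list("abcd"), 5)
        data = pd.DataFrame({"y": vals, "g": labels})
        ct = tukey_contrasts(data, "y", "g")
        assert (ct.table.p_adj > 0.9).all()
        assert len(set(ct.letters.values())) == 1

    def test_familywise_error_rate_null(self):
        hits = 0
        runs = 600
        for seed in range(runs):
            rng = np.random.default_rng(seed)
            vals = rng.normal(size=32)
            labels = np.repeat(list("abcd"), 8)
            tab = tukey_contrasts_oneway(vals, labels)
            hits += bool((tab.p_adj < 0.05).any())
        assert 0.03 < hits / runs < 0.07

    def test_one_level_factor_rejected(self):
        with pytest.raises(ValueError):
            tukey_contrasts_oneway(np.arange(4.0), np.array(["a"] * 4))

    def test_letters_respect_significance(self):
        rng = np.random.default_rng(9)
        data = pd.DataFrame(
            {
                "y": np.concatenate(
                    [rng.normal(0, 0.2, 10), rng.normal(0.1, 0.2, 10),
                     rng.normal(5.0, 0.2, 10)]
                ),
                "g": np.repeat(["a", "b", "c"], 10),
            }
        )
        ct = tukey_contrasts(data, "y", "g")
        # a and b overlap; c stands alone
        assert set(ct.letters["a"]) & set(ct.letters["b"])
        assert not (set(ct.letters["c"]) & set(ct.letters["a"]))


class TestPermanova:
    def test_exhaustive_enumeration_n6(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(6, 3))
        X[:3] += 1.5
        groups = np.array(["a"] * 3 + ["b"] * 3)
        res = permanova(X, groups, n_perm=999, seed=1)

        # oracle: every assignment of 3 labels out of 6
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        d2 = ((Z[:, None, :] - Z[None, :, :]) ** 2).sum(-1)

        def pseudo_f(idx_a):
            idx_a = np.asarray(idx_a)
            idx_b = np.setdiff1d(np.arange(6), idx_a)
            ss_t = d2.sum() / 12.0
            ss_w = d2[np.ix_(idx_a, idx_a)].sum() / 6.0 + d2[np.ix_(idx_b, idx_b)].sum() / 6.0
            return (ss_t - ss_w) / 1.0 / (ss_w / 4.0)

        f_obs = pseudo_f([0, 1, 2])
        assert res.pseudo_f == pytest.approx(f_obs, rel=1e-10)
        fs = [pseudo_f(c) for c in itertools.combinations(range(6), 3)]
        p_exact = np.mean([f >= f_obs - 1e-12 for f in fs])
        assert abs(res.p_perm - p_exact) < 3 * np.sqrt(p_exact * (1 - p_exact) / 999)

    def test_null_rejection_rate(self):
        rej = 0
        runs = 300
        for seed in range(runs):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(10, 3))
            res = permanova(X, ["a"] * 5 + ["b"] * 5, n_perm=199, seed=seed + 10000)
            rej += res.p_perm <= 0.05
        assert 0.02 < rej / runs < 0.08

    def test_separated_clusters_minimal_p(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(24, 3))
        X[:12] += 50.0
        res = permanova(X, ["a"] * 12 + ["b"] * 12, n_perm=199, seed=1)
        assert res.p_perm == pytest.approx(1 / 200)
        assert res.r_squared > 0.9

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(12, 4))
        g = ["a"] * 6 + ["b"] * 6
        assert permanova(X, g, seed=3).p_perm == permanova(X, g, seed=3).p_perm

    def test_matches_skbio_pseudo_f(self):
        """Independent cross-check of the pseudo-F statistic."""
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import permanova as sk_permanova

        rng = np.random.default_rng(12)
        X = rng.normal(size=(12, 3))
        X[:6] += 1.0
        g = ["a"] * 6 + ["b"] * 6
        res = permanova(X, g, n_perm=99, seed=0, standardize=False)
        d = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
        sk = sk_permanova(DistanceMatrix(d), grouping=g, permutations=99)
        assert res.pseudo_f == pytest.approx(float(sk["test statistic"]), rel=1e-10)

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError):
            permanova(np.eye(4), ["a"] * 4)


class TestPca:
    def test_perfect_correlation_one_component(self):
        x = np.linspace(0, 1, 20)
        res = pca(np.column_stack([x, 3 * x + 1]))
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_reconstruction(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(15, 4))
        res = pca(X, scale=True)
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        assert np.allclose(res.scores @ res.loadings.T, Z, atol=1e-10)

    def test_loadings_orthonormal_and_fractions_sum_to_one(self):
        rng = np.random.default_rng(1)
        res = pca(rng.normal(size=(30, 5)))
        assert np.allclose(res.loadings.T @ res.loadings, np.eye(5), atol=1e-10)
        assert res.explained_variance_ratio.sum() == pytest.approx(1.0)

    def test_rotation_invariant_spectrum(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(25, 4)) @ np.diag([3.0, 2.0, 1.0, 0.5])
        Q, _ = np.linalg.qr(rng.normal(size=(4, 4)))
        a = pca(X, scale=False).explained_variance_ratio
        b = pca(X @ Q, scale=False).explained_variance_ratio
        assert np.allclose(a, b, atol=1e-10)


def test_compact_letter_display_cliques():
    contrasts = pd.DataFrame(
        {"pair": ["a-b", "a-c", "b-c"], "p_adj": [0.5, 0.01, 0.3]}
    )
    letters = compact_letter_display(contrasts, {"a": 3.0, "b": 2.0, "c": 1.0})
    assert set(letters["a"]) & set(letters["b"])
    assert set(letters["b"]) & set(letters["c"])
    assert not set(letters["a"]) & set(letters["c"])
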