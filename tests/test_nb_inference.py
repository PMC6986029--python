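import math

import mpmath as mp
import numpy as np
import pytest
import scipy.stats

from normbench.nb_inference import (
    DispersionEstimates,
    bh_adjust,
    estimate_dispersions,
    exact_test,
    fit_nb_glm,
    moderated_t,
    nb_logpmf,
    ql_ftest,
    squeeze_variances,
    trigamma_inverse,
    wald_test,
)
from normbench.normalization import normalize, normalize_uq, normalize_uq_pgq2

from conftest import make_cm


def known_disp(cm, phi):
    return DispersionEstimates(phi, {g: phi for g in cm.gene_ids}, float("inf"))


# ---------------------------------------------------------------------------
# high-precision exact-test oracle (mpmath, 50 digits)
# ---------------------------------------------------------------------------

def _mp_nb_logpmf_vector(y_s, n_mean, phi_over_n):
    """mpmath pmf vector P(Y = a), a = 0..y_s, for NB(n*u, phi/n)."""
    mp.mp.dps = 50
    out = []
    for a in range(y_s + 1):
        a = mp.mpf(a)
        if phi_over_n == 0:
            out.append(a * mp.log(n_mean) - n_mean - mp.loggamma(a + 1))
        else:
            r = 1 / mp.mpf(phi_over_n)
            out.append(
                mp.loggamma(a + r)
                - mp.loggamma(r)
                - mp.loggamma(a + 1)
                + r * mp.log(r / (r + n_mean))
                + a * mp.log(n_mean / (r + n_mean))
            )
    return out


def exact_oracle(y_a, y_b, n_a, n_b, phi):
    """Arbitrary-precision direct enumeration of the conditional p-value."""
    y_s = y_a + y_b
    if y_s == 0:
        return 1.0
    u_hat = mp.mpf(y_s) / (n_a + n_b)
    la = _mp_nb_logpmf_vector(y_s, n_a * u_hat, phi / n_a if phi else 0)
    lb = _mp_nb_logpmf_vector(y_s, n_b * u_hat, phi / n_b if phi else 0)
    joint = [mp.e**(la[a] + lb[y_s - a]) for a in range(y_s + 1)]
    obs = joint[y_a]
    p1 = mp.fsum(p for p in joint if p <= obs * (1 + mp.mpf("1e-12")))
    p2 = mp.fsum(joint)
    return float(p1 / p2)


class TestNbLogpmf:
    def test_poisson_limit(self, rng):
        y = rng.integers(0, 50, 20)
        mean = rng.uniform(0.5, 30, 20)
        got = nb_logpmf(y, mean, 1e-12)
        want = scipy.stats.poisson.logpmf(y, mean)
        np.testing.assert_allclose(got, want, atol=1e-6)

    def test_zero_count_closed_form(self):
        mean, phi = 7.3, 0.4
        assert nb_logpmf(0, mean, phi) == pytest.approx(
            math.log((1 + phi * mean) ** (-1 / phi)), rel=1e-12
        )

    def test_pmf_sums_to_one(self):
        y = np.arange(0, 5001)
        total = np.exp(nb_logpmf(y, 5.0, 0.3)).sum()
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_matches_scipy_nbinom(self, rng):
        y = rng.integers(0, 100, 30)
        mean, phi = 12.0, 0.25
        r = 1 / phi
        want = scipy.stats.nbinom.logpmf(y, r, r / (r + mean))
        np.testing.assert_allclose(nb_logpmf(y, mean, phi), want, rtol=1e-10)


class TestExactTest:
    def test_symmetric_observation_gives_p_one(self):
        cm = make_cm([[5, 5, 5, 5]], groups=["A", "A", "B", "B"])
        tt = exact_test(cm, ["A", "A", "B", "B"], known_disp(cm, 0.1))
        assert tt["pvalue"].iloc[0] == pytest.approx(1.0)

    def test_group_relabel_symmetry(self, nb_null_counts):
        groups = [nb_null_counts.groups[s] for s in nb_null_counts.sample_ids]
        flipped = ["B" if g == "A" else "A" for g in groups]
        disp = known_disp(nb_null_counts, 0.15)
        t1 = exact_test(nb_null_counts, groups, disp)
        t2 = exact_test(nb_null_counts, flipped, disp)
        np.testing.assert_allclose(t1["pvalue"], t2["pvalue"], rtol=1e-12)
        np.testing.assert_allclose(t1["log2fc"], -t2["log2fc"], rtol=1e-12)

    def test_specific_case_against_oracle(self):
        # n_A = n_B = 2, y_A = 10, y_B = 2, phi = 0.1
        cm = make_cm([[6, 4, 1, 1]], groups=["A", "A", "B", "B"])
        tt = exact_test(cm, ["A", "A", "B", "B"], known_disp(cm, 0.1))
        want = exact_oracle(10, 2, 2, 2, 0.1)
        assert tt["pvalue"].iloc[0] == pytest.approx(want, abs=1e-12)

    def test_zero_total_flagged_p_one(self):
        cm = make_cm([[0, 0, 0, 0], [1, 2, 3, 4]], groups=["A", "A", "B", "B"])
        tt = exact_test(cm, ["A", "A", "B", "B"], known_disp(cm, 0.1))
        assert tt["pvalue"].iloc[0] == 1.0
        assert tt["flag"].iloc[0] == "zero-total"

    @pytest.mark.parametrize("phi", [0.0, 0.1, 1.0])
    @pytest.mark.parametrize("n_a,n_b", [(1, 1), (1, 3), (2, 2), (3, 2)])
    def test_oracle_spot_grid(self, phi, n_a, n_b):
        """Enumeration oracle agreement on a small spot grid (the full
        exhaustive grid runs in the acceptance suite)."""
        from normbench.nb_inference import _exact_pvalue_one

        for y_a, y_b in [(0, 0), (0, 5), (3, 3), (10, 2), (7, 20)]:
            got = _exact_pvalue_one(y_a, y_a + y_b, n_a, n_b, phi, exact_limit=10**6)
            want = exact_oracle(y_a, y_b, n_a, n_b, phi)
            assert got == pytest.approx(want, abs=1e-10)

    def test_beta_approximation_continuity(self):
        """Exact and large-count branches agree to a few percent at the
        crossover total."""
        from normbench.nb_inference import _exact_pvalue_one

        for y_a in (2400, 2500, 2600, 2750):
            y_s = 5000
            exact = _exact_pvalue_one(y_a, y_s, 5, 5, 0.2, exact_limit=10**6)
            approx = _exact_pvalue_one(y_a, y_s, 5, 5, 0.2, exact_limit=10)
            assert approx == pytest.approx(exact, rel=0.05, abs=5e-4)


class TestGlmAndWald:
    def test_coefficient_equals_log_mean_ratio(self, rng):
        y = rng.poisson([5] * 4 + [20] * 4)
        y[0] += 1  # ensure positive group means
        fit = fit_nb_glm(y, ["A"] * 4 + ["B"] * 4, dispersion=0.2)
        expected = math.log(y[4:].mean() / y[:4].mean())
        assert fit.coefficients[1] == pytest.approx(expected, abs=1e-8)
        assert fit.residual_df == 6

    def test_identical_groups_beta1_zero(self):
        y = [7, 9, 8, 7, 9, 8]
        fit = fit_nb_glm(y, ["A"] * 3 + ["B"] * 3, dispersion=0.1)
        assert fit.coefficients[1] == pytest.approx(0.0, abs=1e-10)

    def test_se_matches_numeric_hessian(self, rng):
        y = rng.negative_binomial(5, 0.3, size=8)
        y = np.maximum(y, 1)
        groups = ["A"] * 4 + ["B"] * 4
        phi = 0.2
        fit = fit_nb_glm(y, groups, dispersion=phi)
        b0, b1 = fit.coefficients

        def loglik(b0_, b1_):
            mu = np.exp(b0_ + b1_ * np.array([0, 0, 0, 0, 1, 1, 1, 1.0]))
            return nb_logpmf(np.asarray(y, float), mu, phi).sum()

        h = 1e-5
        H = np.empty((2, 2))
        for i in range(2):
            for j in range(2):
                pp = [b0, b1]; pm = [b0, b1]; mp_ = [b0, b1]; mm = [b0, b1]
                pp[i] += h; pp[j] += h
                pm[i] += h; pm[j] -= h
                mp_[i] -= h; mp_[j] += h
                mm[i] -= h; mm[j] -= h
                H[i, j] = (loglik(*pp) - loglik(*pm) - loglik(*mp_) + loglik(*mm)) / (4 * h * h)
        se_num = math.sqrt(np.linalg.inv(-H)[1, 1])
        assert fit.standard_error_b1 == pytest.approx(se_num, rel=1e-4)

    def test_all_zero_group_clamped(self):
        fit = fit_nb_glm([0, 0, 0, 5, 6, 7], ["A"] * 3 + ["B"] * 3, dispersion=0.1)
        assert abs(fit.coefficients[1]) == pytest.approx(math.log(1e8))
        assert fit.flag == "lfc-clamped"

    def test_wald_identical_groups(self):
        cm = make_cm(np.tile([[8], [30]], (1, 6)), groups=["A"] * 3 + ["B"] * 3)
        tt = wald_test(cm, ["A"] * 3 + ["B"] * 3, known_disp(cm, 0.1))
        np.testing.assert_allclose(tt["stat"], 0.0)
        np.testing.assert_allclose(tt["pvalue"], 1.0)

    def test_wald_relabel_negates_z(self, nb_null_counts):
        groups = [nb_null_counts.groups[s] for s in nb_null_counts.sample_ids]
        flipped = ["B" if g == "A" else "A" for g in groups]
        disp = known_disp(nb_null_counts, 0.15)
        t1 = wald_test(nb_null_counts, groups, disp)
        t2 = wald_test(nb_null_counts, flipped, disp)
        np.testing.assert_allclose(t1["stat"], -t2["stat"], atol=1e-12)
        np.testing.assert_allclose(t1["pvalue"], t2["pvalue"], atol=1e-12)

    def test_wald_agrees_with_exact_at_large_n(self, rng):
        # asymptotic agreement on a null with n = 50 per group
        G, n, phi = 300, 50, 0.1
        mu = rng.lognormal(np.log(10), 0.8, G)
        r = 1 / phi
        y = rng.negative_binomial(r, r / (r + mu[:, None]), size=(G, 2 * n))
        cm = make_cm(y)
        groups = ["A"] * n + ["B"] * n
        disp = known_disp(cm, phi)
        pe = exact_test(cm, groups, disp, exact_limit=10**6)["pvalue"]
        pw = wald_test(cm, groups, disp)["pvalue"]
        rho = scipy.stats.spearmanr(pe, pw).statistic
        assert rho >= 0.95


class TestQlFtest:
    def test_identical_groups(self):
        cm = make_cm(np.tile([[8], [30]], (1, 8)), groups=["A"] * 4 + ["B"] * 4)
        tt = ql_ftest(cm, ["A"] * 4 + ["B"] * 4, known_disp(cm, 0.1))
        np.testing.assert_allclose(tt["stat"], 0.0)
        np.testing.assert_allclose(tt["pvalue"], 1.0)

    def test_reduces_to_chi2_of_wald(self, nb_null_counts):
        groups = [nb_null_counts.groups[s] for s in nb_null_counts.sample_ids]
        disp = known_disp(nb_null_counts, 0.15)
        tq = ql_ftest(nb_null_counts, groups, disp,
                      d0_override=float("inf"), s0_sq_override=1.0)
        tw = wald_test(nb_null_counts, groups, disp)
        want = scipy.stats.chi2.sf(tw["stat"] ** 2, 1)
        np.testing.assert_allclose(tq["pvalue"], want, atol=1e-9)

    def test_degenerate_spread_gives_infinite_prior(self):
        s2 = np.full(50, 2.5)
        d0, s0, s2_post = squeeze_variances(s2, 8)
        assert math.isinf(d0)
        np.testing.assert_allclose(s2_post, s2_post[0])

    def test_trigamma_inverse_roundtrip(self):
        for x in (0.05, 0.7, 3.0, 40.0):
            y = float(scipy.special.polygamma(1, x))
            assert trigamma_inverse(y) == pytest.approx(x, rel=1e-8)


class TestModeratedT:
    def test_identical_groups(self):
        cm = make_cm(np.tile([[8], [30], [4], [100]], (1, 8)))
        nm = normalize(cm, "uq")
        tt = moderated_t(nm, ["A"] * 4 + ["B"] * 4)
        np.testing.assert_allclose(tt["stat"], 0.0)
        np.testing.assert_allclose(tt["pvalue"], 1.0)

    def test_uq_and_uq_pgq2_identical_pvalues(self, rng):
        cm = make_cm(rng.integers(0, 400, size=(300, 10)))
        groups = ["A"] * 5 + ["B"] * 5
        _, uq = normalize_uq(cm)
        _, pg = normalize_uq_pgq2(cm)
        p1 = moderated_t(uq, groups)["pvalue"].to_numpy()
        p2 = moderated_t(pg, groups)["pvalue"].to_numpy()
        assert np.array_equal(p1, p2)  # bit identical

    def test_unsqueezed_matches_textbook_t(self, rng):
        cm = make_cm(rng.integers(1, 300, size=(50, 8)))
        groups = ["A"] * 4 + ["B"] * 4
        nm = normalize(cm, "uq")
        tt = moderated_t(nm, groups, d0_override=0)
        logv = np.log2(nm.values + 0.5)
        want = scipy.stats.ttest_ind(logv[:, 4:], logv[:, :4], axis=1).pvalue
        np.testing.assert_allclose(tt["pvalue"], want, atol=1e-10)


class TestDispersionEstimation:
    def test_needs_two_replicates_per_group(self, rng):
        cm = make_cm(rng.integers(1, 50, size=(20, 3)))
        with pytest.raises(ValueError, match="replicates"):
            estimate_dispersions(cm, ["A", "B", "B"])

    def test_infinite_prior_weight_collapses_to_common(self, nb_null_counts):
        groups = [nb_null_counts.groups[s] for s in nb_null_counts.sample_ids]
        est = estimate_dispersions(nb_null_counts, groups, prior_weight=float("inf"))
        assert set(est.tagwise.values()) == {est.common}

    def test_constant_genes_estimate_at_floor(self):
        # every gene constant within both groups -> no overdispersion signal
        cm = make_cm(np.tile([[8], [30], [4], [100], [55]], (1, 8)))
        groups = ["A"] * 4 + ["B"] * 4
        est = estimate_dispersions(cm, groups)
        assert est.common == pytest.approx(est.floor, rel=1e-2)
        assert min(est.tagwise.values()) >= est.floor

    def test_recovers_true_dispersion_and_matches_grid_oracle(self, rng):
        G, n, phi = 2000, 10, 0.2
        mu = rng.lognormal(np.log(40), 1.2, G)
        r = 1 / phi
        y = rng.negative_binomial(r, r / (r + mu[:, None]), size=(G, 2 * n))
        cm = make_cm(y)
        groups = ["A"] * n + ["B"] * n
        est = estimate_dispersions(cm, groups)
        assert abs(est.common - phi) <= 0.05
        # exhaustive grid maximization of the same objective
        from normbench.nb_inference import _apl_all_genes

        mask = np.array([True] * n + [False] * n)
        grid = np.arange(0.001, 1.0, 0.001)
        totals = [ _apl_all_genes(cm.counts, mask, ~mask, p).sum() for p in grid ]
        oracle = grid[int(np.argmax(totals))]
        assert abs(est.common - oracle) <= 1e-3


class TestBhAdjust:
    def test_single_and_constant_vectors(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), 0.2)

    def test_matches_naive_oracle(self, rng):
        def naive_bh(p):
            m = len(p)
            order = np.argsort(p)
            adj = np.empty(m)
            prev = 1.0
            for rank_from_top in range(m, 0, -1):
                i = order[rank_from_top - 1]
                val = min(prev, p[i] * m / rank_from_top)
                adj[i] = val
                prev = val
            return adj

        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 400))
            np.testing.assert_array_equal(bh_adjust(p), naive_bh(p))

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=500)
        want = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(bh_adjust(p), want, atol=1e-14)

    def test_nan_passthrough(self):
        out = bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(out[1])
        np.testing.assert_allclose(out[[0, 2]], [0.02, 0.04])

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])
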