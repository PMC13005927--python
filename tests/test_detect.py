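import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from codeharmony.detect import (SiteDataHolder, bonferroni_adjust,
                                burden_test, chisq_mixture_sf,
                                code_level_test, federated_fit_null,
                                federated_group_tests, fit_null_model,
                                liu_sf, pooled_group_tests, skat_test,
                                smoothed_frequency_ratio, weighted_rate_tests)
from codeharmony.store import CodeMatrix, CovariateTable, patient_code_matrix
from conftest import pooled_design


class TestFrequencyRatio:
    def test_zero_count_site_with_calibrated_person_time(self):
        # 70 vs 0 endorsements; person-time ratio PT_B/PT_A = 0.93895
        r = smoothed_frequency_ratio(70, 0, pt_a=1.0, pt_b=0.93895)
        assert r.ratio == pytest.approx(7.51, abs=0.005)

    def test_equal_zero_counts_give_unit_ratio(self):
        assert smoothed_frequency_ratio(0, 0, 3.0, 3.0).ratio == pytest.approx(1.0)

    def test_ninety_vs_zero_equal_person_time(self):
        assert smoothed_frequency_ratio(90, 0, 2.0, 2.0).ratio == pytest.approx(10.0)

    @given(
        f_a=st.integers(0, 10_000),
        f_b=st.integers(0, 10_000),
        pt_a=st.floats(0.1, 100),
        pt_b=st.floats(0.1, 100),
    )
    def test_site_swap_inverts_ratio(self, f_a, f_b, pt_a, pt_b):
        fwd = smoothed_frequency_ratio(f_a, f_b, pt_a, pt_b).ratio
        rev = smoothed_frequency_ratio(f_b, f_a, pt_b, pt_a).ratio
        assert fwd * rev == pytest.approx(1.0)

    def test_nonpositive_person_time_rejected(self):
        with pytest.raises(ValueError):
            smoothed_frequency_ratio(1, 1, 0.0, 1.0)


class TestWeightedRateTest:
    def test_matches_hand_rolled_wls_on_toy_table(self):
        # independent oracle: weighted normal equations + HC1 sandwich
        rng = np.random.default_rng(3)
        n = 8
        site = np.array([1, 1, 1, 1, 0, 0, 0, 0], dtype=float)
        Z = rng.normal(size=(n, 2))
        w = rng.uniform(0.5, 2.0, n)
        y = rng.normal(size=n)
        X = np.column_stack([np.ones(n), site, Z])
        XtWX = X.T @ (X * w[:, None])
        beta = np.linalg.solve(XtWX, X.T @ (w * y))
        e = y - X @ beta
        A = np.linalg.inv(XtWX)
        meat = (X * (w * e) [:, None]).T @ (X * (w * e)[:, None])
        cov = A @ meat @ A * (n / (n - 4))
        res = weighted_rate_tests(y[:, None], site, Z, w)
        assert res["coef"].iloc[0] == pytest.approx(beta[1], abs=1e-10)
        assert res["se"].iloc[0] == pytest.approx(np.sqrt(cov[1, 1]), abs=1e-10)

    def test_null_p_values_uniform_under_label_permutation(self):
        """With site labels assigned at random the p-value distribution
        should be uniform (KS check over replicates)."""
        rng = np.random.default_rng(0)
        n = 400
        pvals = []
        for _ in range(200):
            y = rng.gamma(2.0, 1.0, n)
            site = rng.permutation(np.r_[np.ones(n // 2), np.zeros(n // 2)])
            Z = rng.normal(size=(n, 2))
            w = rng.uniform(0.5, 2.0, n)
            pvals.append(float(weighted_rate_tests(y[:, None], site, Z, w)["p"].iloc[0]))
        assert stats.kstest(pvals, "uniform").pvalue > 1e-3

    def test_identical_rates_give_unit_p(self):
        import pandas as pd

        rng = np.random.default_rng(9)
        n = 12
        frame = pd.DataFrame(
            {
                "person_time": rng.uniform(0.5, 3.0, n),
                "age": rng.normal(63, 10, n),
                "sex": (rng.random(n) < 0.5).astype(float),
                "insulin_use": (rng.random(n) < 0.3).astype(float),
                "elixhauser": rng.poisson(3, n).astype(float),
            },
            index=pd.Index([f"p{i}" for i in range(n)], name="patient_id"),
        )
        covars = CovariateTable(frame=frame)
        site = np.r_[np.ones(6), np.zeros(6)]
        res = code_level_test(np.full(n, 2.5), site, covars)
        assert res.statistic == 0.0
        assert res.p == 1.0

    def test_collinear_covariates_name_the_column(self):
        n = 20
        site = np.r_[np.ones(10), np.zeros(10)]
        Z = np.column_stack([np.arange(n, dtype=float), np.arange(n, dtype=float)])
        with pytest.raises(ValueError, match="z1"):
            weighted_rate_tests(np.zeros((n, 1)), site, Z, np.ones(n))


class TestNullModel:
    def test_intercept_only_closed_form(self):
        site = np.r_[np.ones(30), np.zeros(20)]
        null = fit_null_model(np.empty((50, 0)), site)
        assert null.beta[0] == pytest.approx(np.log(30 / 20), abs=1e-10)

    def test_matches_statsmodels_logit(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(1)
        n = 200
        Z = rng.normal(size=(n, 3))
        site = (rng.random(n) < 1 / (1 + np.exp(-(0.3 + Z @ [0.5, -0.4, 0.2])))).astype(float)
        ours = fit_null_model(Z, site)
        X = sm.add_constant(Z)
        theirs = sm.Logit(site, X).fit(disp=0, tol=1e-12)
        assert np.allclose(ours.beta, theirs.params, atol=1e-8)

    def test_complete_separation_raises(self):
        from codeharmony.detect import SeparationError

        z = np.r_[np.ones(10), np.zeros(10)][:, None]
        site = np.r_[np.ones(10), np.zeros(10)]
        with pytest.raises(SeparationError):
            fit_null_model(z, site)


@pytest.fixture(scope="module")
def toy_null():
    rng = np.random.default_rng(5)
    n = 120
    Z = rng.normal(size=(n, 2))
    site = (rng.random(n) < 0.5).astype(float)
    G = rng.poisson(1.5, size=(n, 4)).astype(float)
    return fit_null_model(Z, site), G


class TestGroupScoreTests:
    def test_burden_matches_direct_matrix_assembly(self, toy_null):
        null, G = toy_null
        w = np.ones(G.shape[1])
        # independent assembly straight from the definition
        r = null.y - null.mu
        d = null.mu * (1 - null.mu)
        b = G @ w
        X = null.X
        S = r @ b
        XtDX = X.T @ (X * d[:, None])
        v = b @ (d * b) - (b * d) @ X @ np.linalg.solve(XtDX, X.T @ (d * b))
        res = burden_test(null, G, w)
        assert res.statistic == pytest.approx(S**2 / v, rel=1e-10)

    def test_single_code_group_burden_equals_skat(self, toy_null):
        null, G = toy_null
        single = G[:, :1]
        b = burden_test(null, single)
        s = skat_test(null, single)
        # Q = S^2 and the 1-term mixture is v * chi^2_1, so p-values coincide
        assert s.statistic == pytest.approx(b.statistic * _burden_v(null, single), rel=1e-8)
        assert s.p == pytest.approx(b.p, rel=1e-6)

    def test_skat_invariant_to_member_order(self, toy_null):
        null, G = toy_null
        p1 = skat_test(null, G).p
        p2 = skat_test(null, G[:, ::-1]).p
        assert p1 == pytest.approx(p2, rel=1e-10)

    def test_degenerate_burden_warns_and_returns_unit_p(self, toy_null):
        null, _ = toy_null
        zero = np.zeros((len(null.y), 2))
        with pytest.warns(UserWarning, match="degenerate"):
            res = burden_test(null, zero, group_id="empty")
        assert res.p == 1.0

    def test_all_zero_group_skat_warns(self, toy_null):
        from codeharmony.detect import skat_test

        null, _ = toy_null
        with pytest.warns(UserWarning, match="all-zero"):
            res = skat_test(null, np.zeros((len(null.y), 3)))
        assert res.p == 1.0


def _burden_v(null, single):
    """Variance factor linking the 1-df burden statistic S^2/v to SKAT's
    Q = S^2 (flat weights)."""
    r = null.y - null.mu
    d = null.mu * (1 - null.mu)
    b = single[:, 0]
    X = null.X
    XtDX = X.T @ (X * d[:, None])
    return b @ (d * b) - (b * d) @ X @ np.linalg.solve(XtDX, X.T @ (d * b))


class TestMixtureTail:
    def test_davies_and_liu_agree_on_random_eigenvalue_sets(self):
        """Inversion and moment matching agree within 10% relative error in
        the moderate tail (p >= 1e-3), and within a factor of two at 1e-6
        where fourth-moment matching degrades; Liu only ever substitutes
        for the inversion below its resolution limit."""
        rng = np.random.default_rng(7)
        for _ in range(30):
            lam = rng.uniform(0.2, 3.0, size=rng.integers(2, 9))
            for target in (0.5, 0.05, 1e-3):
                q = _mixture_quantile(lam, target)
                p_inv = chisq_mixture_sf(q, lam)[0]
                p_liu = liu_sf(q, lam)
                assert p_liu == pytest.approx(p_inv, rel=0.10), (lam, target)
            q = _mixture_quantile(lam, 1e-6)
            p_inv = chisq_mixture_sf(q, lam)[0]
            assert 1 / 3 < liu_sf(q, lam) / p_inv < 3.0, lam

    def test_single_weight_reduces_to_scaled_chi_square(self):
        p, method = chisq_mixture_sf(5.0, np.array([2.0]))
        assert method == "exact"
        assert p == pytest.approx(stats.chi2.sf(2.5, df=1))

    def test_nonpositive_q_gives_unit_p(self):
        assert chisq_mixture_sf(0.0, np.array([1.0, 1.0]))[0] == 1.0


def _mixture_quantile(lam, p_target):
    """Bisection on the Liu approximation to land near a target tail mass
    (only used to position test points)."""
    lo, hi = 0.0, 1000 * lam.sum()
    for _ in range(200):
        mid = (lo + hi) / 2
        if liu_sf(mid, lam) > p_target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


class TestBonferroni:
    def test_examples(self):
        assert np.allclose(bonferroni_adjust([0.01, 0.5]), [0.02, 1.0])
        assert np.allclose(bonferroni_adjust([0.2]), [0.2])
        assert np.allclose(bonferroni_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_order_preserving_and_bounded(self, pvals):
        adj = bonferroni_adjust(pvals)
        assert (adj <= 1).all() and (adj >= np.asarray(pvals)).all()
        order = np.argsort(pvals, kind="stable")
        assert (np.diff(adj[order]) >= -1e-15).all()


class TestFederated:
    def test_two_holders_match_pooled_fit(self):
        rng = np.random.default_rng(2)
        n = 150
        Z = rng.normal(size=(n, 3))
        site = (rng.random(n) < 0.5).astype(float)
        pooled = fit_null_model(Z, site)
        holders = [
            SiteDataHolder("A", site[:70], Z[:70]),
            SiteDataHolder("B", site[70:], Z[70:]),
        ]
        fed = federated_fit_null(holders)
        assert np.allclose(fed.beta, pooled.beta, atol=1e-8)

    def test_single_holder_degenerate_federation(self):
        rng = np.random.default_rng(4)
        n = 80
        Z = rng.normal(size=(n, 2))
        site = (rng.random(n) < 0.4).astype(float)
        fed = federated_fit_null([SiteDataHolder("solo", site, Z)])
        assert np.allclose(fed.beta, fit_null_model(Z, site).beta, atol=1e-10)

    def test_audit_log_contains_only_aggregate_payloads(self):
        rng = np.random.default_rng(6)
        n, k = 90, 3
        Z = rng.normal(size=(n, k))
        site = (rng.random(n) < 0.5).astype(float)
        holder = SiteDataHolder("A", site, Z)
        federated_fit_null([holder])
        for entry in holder.audit_log:
            for shape in entry["shapes"]:
                assert np.prod(shape) <= (1 + k) ** 2

    def test_group_tests_match_pooled_on_substitution_cohort(
        self, substitution_cohort
    ):
        config, ev_a, cov_a, ev_b, cov_b, _ = substitution_cohort
        vocab = sorted(set(ev_a.codes.unique()) | set(ev_b.codes.unique()))
        Xa = patient_code_matrix(ev_a, cov_a, vocab, "count")
        Xb = patient_code_matrix(ev_b, cov_b, vocab, "count")
        Z, site, _ = pooled_design(cov_a, cov_b)
        counts = np.vstack([Xa.values, Xb.values])
        pooled_null = fit_null_model(Z, site)
        G = CodeMatrix(counts, list(Xa.patients) + list(Xb.patients), vocab, "count")
        pooled = pooled_group_tests(pooled_null, G, config.group_catalog())
        nA = len(Xa.patients)
        holders = [
            SiteDataHolder("A", site[:nA], Z[:nA], Xa.values, vocab),
            SiteDataHolder("B", site[nA:], Z[nA:], Xb.values, vocab),
        ]
        fed_null = federated_fit_null(holders)
        aggs = [h.aggregates(fed_null.beta) for h in holders]
        federated = federated_group_tests(aggs, config.group_catalog())
        assert len(pooled) == len(federated)
        for p_res, f_res in zip(pooled, federated):
            assert p_res.unit == f_res.unit and p_res.kind == f_res.kind
            scale = max(1.0, abs(p_res.statistic))
            assert abs(p_res.statistic - f_res.statistic) / scale < 1e-8
            assert p_res.p == pytest.approx(f_res.p, abs=1e-8)

    def test_dimension_mismatch_between_sites_raises(self):
        rng = np.random.default_rng(8)

        def holder(name, m):
            n = 40
            Z = rng.normal(size=(n, 2))
            site = (rng.random(n) < 0.5).astype(float)
            return SiteDataHolder(name, site, Z, rng.poisson(1, (n, m)).astype(float),
                                  [f"c{j}" for j in range(m)])

        h1, h2 = holder("A", 3), holder("B", 4)
        beta = np.zeros(3)
        from codeharmony.store import GroupCatalog

        with pytest.raises(ValueError, match="mismatch"):
            federated_group_tests(
                [h1.aggregates(beta), h2.aggregates(beta)],
                GroupCatalog({"c0": "g"}),
            )
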