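import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from pseudonet import CountTable, InputError, SparccConfig, sparcc
from pseudonet.sparcc import (
    BasisVariances,
    LogRatioVariances,
    estimate_correlations,
    logratio_variance,
    solve_basis_variances,
    to_fractions,
)


class TestToFractions:
    @pytest.mark.parametrize(
        "row, pseudocount, expected",
        [
            ([1, 1], 1, [0.5, 0.5]),
            ([0, 0, 0], 1, [1 / 3, 1 / 3, 1 / 3]),
            ([3, 1], 1, [4 / 6, 2 / 6]),
        ],
    )
    def test_known_rows(self, row, pseudocount, expected):
        out = to_fractions(np.array([row]), pseudocount)
        np.testing.assert_allclose(out[0], expected)

    def test_rows_are_stochastic_and_positive(self, rng):
        counts = rng.poisson(5, size=(20, 8))
        out = to_fractions(counts, 1.0)
        np.testing.assert_allclose(out.sum(axis=1), 1.0)
        assert np.all(out > 0)

    def test_negative_counts_rejected(self):
        with pytest.raises(InputError):
            to_fractions(np.array([[1, -1, 2]]))


class TestLogratioVariance:
    def test_constant_ratio_gives_zero(self):
        u = np.tile([0.2, 0.2, 0.6], (5, 1))
        lrv = logratio_variance(u)
        assert lrv.T[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_two_level_ratio_closed_form(self):
        # u_j/u_k alternates between e and 1/e over 4 samples:
        # log-ratios are (+1, -1, +1, -1), unbiased variance 4/3
        e = np.e
        u = np.array(
            [[e, 1.0, 1.0], [1.0, e, 1.0], [e, 1.0, 1.0], [1.0, e, 1.0]]
        )
        u = u / u.sum(axis=1, keepdims=True)
        lrv = logratio_variance(u)
        assert lrv.T[0, 1] == pytest.approx(4 / 3)

    def test_matches_bruteforce_double_loop(self, rng):
        u = rng.dirichlet(np.ones(4), size=10)
        lrv = logratio_variance(u)
        for j in range(4):
            for k in range(4):
                expected = np.var(np.log(u[:, j] / u[:, k]), ddof=1)
                assert lrv.T[j, k] == pytest.approx(expected, abs=1e-10)

    def test_too_few_samples_rejected(self):
        with pytest.raises(InputError):
            logratio_variance(np.full((2, 3), 1 / 3))


def _forward_T(sigma2: np.ndarray, rho: np.ndarray | None = None) -> np.ndarray:
    """Construct a log-ratio variance matrix from known basis parameters."""
    p = len(sigma2)
    rho = np.zeros((p, p)) if rho is None else rho
    s = np.sqrt(sigma2)
    T = sigma2[:, None] + sigma2[None, :] - 2 * rho * np.outer(s, s)
    np.fill_diagonal(T, 0.0)
    return T


class TestBasisVariances:
    def test_symmetric_closed_form(self):
        s = 1.7
        T = _forward_T(np.full(3, s))
        out = solve_basis_variances(LogRatioVariances(T=T, t_row=T.sum(1)))
        np.testing.assert_allclose(out.sigma2, s)

    def test_recovers_heterogeneous_variances(self):
        sigma2 = np.array([1.0, 2.0, 3.0, 4.0])
        T = _forward_T(sigma2)
        out = solve_basis_variances(LogRatioVariances(T=T, t_row=T.sum(1)))
        np.testing.assert_allclose(out.sigma2, sigma2, atol=1e-10)

    def test_exclusion_keeps_consistent_system(self):
        sigma2 = np.array([1.0, 2.0, 3.0, 4.0])
        T = _forward_T(sigma2)
        out = solve_basis_variances(
            LogRatioVariances(T=T, t_row=T.sum(1)), excluded_pairs={(1, 2)}
        )
        np.testing.assert_allclose(out.sigma2, sigma2, atol=1e-10)

    def test_over_exclusion_raises(self):
        T = _forward_T(np.ones(3))
        with pytest.raises(Exception, match="partner"):
            solve_basis_variances(
                LogRatioVariances(T=T, t_row=T.sum(1)),
                excluded_pairs={(0, 1), (0, 2)},
            )


class TestEstimateCorrelations:
    @pytest.mark.parametrize("target_rho", [0.0, 1.0, -1.0])
    def test_algebraic_identities(self, target_rho):
        # t_jk = sigma_j^2 + sigma_k^2 - 2 rho sigma_j sigma_k inverts exactly
        sigma2 = np.array([1.0, 4.0, 9.0])
        rho = np.full((3, 3), target_rho)
        np.fill_diagonal(rho, 1.0)
        T = _forward_T(sigma2, rho)
        out = estimate_correlations(
            LogRatioVariances(T=T, t_row=T.sum(1)), BasisVariances(sigma2=sigma2)
        )
        off = out.rho[np.triu_indices(3, 1)]
        np.testing.assert_allclose(off, target_rho, atol=1e-12)

    def test_zero_basis_variance_rejected(self):
        T = _forward_T(np.ones(3))
        with pytest.raises(Exception, match="basis variance"):
            estimate_correlations(
                LogRatioVariances(T=T, t_row=T.sum(1)),
                BasisVariances(sigma2=np.array([1.0, 0.0, 1.0])),
            )


def _lognormal_composition(rng, cov: np.ndarray, n: int) -> CountTable:
    """Multinomial reads from a log-normal basis with known covariance."""
    p = cov.shape[0]
    log_abund = rng.multivariate_normal(np.zeros(p), cov, size=n)
    abund = np.exp(log_abund)
    frac = abund / abund.sum(axis=1, keepdims=True)
    counts = np.vstack([rng.multinomial(100000, f) for f in frac])
    return CountTable(counts)


class TestSparccPipeline:
    def test_output_is_valid_association_matrix(self, rng):
        counts = CountTable(rng.poisson(30, size=(25, 7)))
        out = sparcc(counts)
        np.testing.assert_allclose(out.rho, out.rho.T)
        np.testing.assert_allclose(np.diag(out.rho), 1.0)
        assert np.all(np.abs(out.rho) <= 1.0 + 1e-12)

    def test_taxon_permutation_equivariance(self, rng):
        counts = rng.poisson(30, size=(20, 6))
        perm = rng.permutation(6)
        a = sparcc(CountTable(counts)).rho
        b = sparcc(CountTable(counts[:, perm])).rho
        np.testing.assert_allclose(b, a[np.ix_(perm, perm)], atol=1e-10)

    def test_compositional_invariance_without_pseudocount(self, rng):
        counts = rng.poisson(40, size=(15, 5)) + 1
        scaled = counts * np.array([1, 7, 2, 9, 3, 1, 4, 1, 1, 5, 2, 8, 1, 1, 6])[:, None]
        cfg = SparccConfig(pseudocount=0.0, max_exclusion_iters=2)
        a = sparcc(CountTable(counts), cfg).rho
        b = sparcc(CountTable(scaled), cfg).rho
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_recovers_null_correlation_at_large_n(self, rng):
        cov = np.diag(rng.uniform(0.5, 1.5, size=6))
        counts = _lognormal_composition(rng, cov, n=2000)
        out = sparcc(counts)
        off = out.rho[np.triu_indices(6, 1)]
        assert np.max(np.abs(off)) < 0.1

    def test_recovers_single_strong_pair(self, rng):
        cov = np.eye(6)
        cov[0, 1] = cov[1, 0] = 0.8
        counts = _lognormal_composition(rng, cov, n=2000)
        cfg = SparccConfig()
        out_once = sparcc(counts, SparccConfig(max_exclusion_iters=0))
        a = np.abs(out_once.rho).copy()
        np.fill_diagonal(a, 0)
        assert {*np.unravel_index(np.argmax(a), a.shape)} == {0, 1}
        # the full estimate still reports the pair as the strongest
        out = sparcc(counts, cfg)
        a = np.abs(out.rho).copy()
        np.fill_diagonal(a, 0)
        assert {*np.unravel_index(np.argmax(a), a.shape)} == {0, 1}
        assert out.rho[0, 1] > 0.5

    def test_parameter_recovery_known_basis_correlation(self, rng):
        # sparse known correlation (the estimator's working assumption),
        # p <= 10, n = 2000: max abs error <= 0.1
        p = 8
        rho_true = np.eye(p)
        rho_true[0, 1] = rho_true[1, 0] = 0.6
        rho_true[2, 3] = rho_true[3, 2] = -0.4
        sd = rng.uniform(0.8, 1.2, p)
        cov = rho_true * np.outer(sd, sd)
        counts = _lognormal_composition(rng, cov, n=2000)
        out = sparcc(counts)
        assert np.max(np.abs(out.rho - rho_true)) <= 0.1

    def test_zero_exclusion_iters_is_single_solve(self, rng):
        counts = CountTable(rng.poisson(30, size=(20, 6)))
        cfg = SparccConfig(max_exclusion_iters=0)
        out = sparcc(counts, cfg)
        frac = to_fractions(counts.counts, cfg.pseudocount)
        lrv = logratio_variance(frac)
        basis = solve_basis_variances(lrv, set())
        expected = estimate_correlations(lrv, basis)
        np.testing.assert_allclose(out.rho, expected.rho)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    arrays(
        np.int64,
        (8, 5),
        elements=st.integers(min_value=0, max_value=500),
    )
)
def test_sparcc_output_bounds_property(counts):
    from pseudonet import EstimationError

    try:
        out = sparcc(CountTable(counts))
    except EstimationError:
        # degenerate tables (e.g. proportional rows) legitimately over-exclude;
        # the contract is that any *returned* estimate satisfies the bounds
        return
    assert np.all(np.abs(out.rho) <= 1.0 + 1e-12)
    np.testing.assert_allclose(out.rho, out.rho.T)
    np.testing.assert_allclose(np.diag(out.rho), 1.0)
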