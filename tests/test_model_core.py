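"""CAR precision/density, logistic processes, mixture, joint posterior."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import multivariate_normal, norm, beta as beta_dist, invgamma

from pojsdm import (
    MISSING,
    ModelData,
    ModelParams,
    Priors,
    build_grid_lattice,
    adjacency_from_lattice,
    car_precision,
    car_logpdf,
    process_probability,
    mixture_probability,
    joint_log_posterior,
)


def grid_adjacency(nx, ny, rule="rook"):
    return adjacency_from_lattice(
        build_grid_lattice((0, 0, nx, ny), 1.0), rule)


class TestCarPrecision:
    def test_three_cell_path_hand_computation(self):
        adj = grid_adjacency(3, 1)
        Q = car_precision(adj, 0.5, 1.0).toarray()
        expected = np.array([[1.0, -0.5, 0.0],
                             [-0.5, 2.0, -0.5],
                             [0.0, -0.5, 1.0]])
        np.testing.assert_allclose(Q, expected)
        assert np.all(np.linalg.eigvalsh(expected) > 0)

    def test_lambda_to_zero_limit_is_degree_diagonal(self):
        adj = grid_adjacency(3, 3)
        Q = car_precision(adj, 1e-12, 2.0).toarray()
        np.testing.assert_allclose(np.diag(Q), 2.0 * adj.degrees)
        off = Q - np.diag(np.diag(Q))
        assert np.abs(off).max() < 1e-10

    def test_invalid_lambda_rejected(self):
        adj = grid_adjacency(2, 2)
        for lam in (0.0, 1.0, -0.2, 1.5):
            with pytest.raises(ValueError):
                car_precision(adj, lam, 1.0)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(nx=st.integers(2, 8), ny=st.integers(2, 8),
           lam=st.floats(0.01, 0.99), tau=st.floats(0.05, 20.0),
           rule=st.sampled_from(["rook", "queen"]))
    def test_positive_definite_for_all_valid_parameters(self, nx, ny, lam,
                                                        tau, rule):
        Q = car_precision(grid_adjacency(nx, ny, rule), lam, tau).toarray()
        np.testing.assert_allclose(Q, Q.T)
        assert np.all(np.diag(Q) > 0)
        np.linalg.cholesky(Q)  # raises if not PD


class TestCarLogpdf:
    def test_zero_field_value(self):
        adj = grid_adjacency(3, 2)
        n = 6
        lam, tau = 0.7, 2.0
        Q = car_precision(adj, lam, tau).toarray()
        expected = -0.5 * n * np.log(2 * np.pi) \
            + 0.5 * np.linalg.slogdet(Q)[1]
        assert car_logpdf(np.zeros(n), adj, lam, tau) == \
            pytest.approx(expected, abs=1e-10)

    def test_matches_dense_mvn_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            nx = int(rng.integers(2, 11))
            ny = int(rng.integers(2, 100 // nx + 1))
            adj = grid_adjacency(nx, ny, rng.choice(["rook", "queen"]))
            lam = float(rng.uniform(0.01, 0.99))
            tau = float(rng.uniform(0.05, 10.0))
            g = rng.normal(scale=2.0, size=adj.n_cells)
            Q = car_precision(adj, lam, tau).toarray()
            dense = multivariate_normal(
                mean=np.zeros(adj.n_cells),
                cov=np.linalg.inv(Q)).logpdf(g)
            assert car_logpdf(g, adj, lam, tau) == \
                pytest.approx(dense, abs=1e-8)

    def test_tau_scaling_against_oracle(self):
        adj = grid_adjacency(5, 2)
        rng = np.random.default_rng(1)
        g = rng.normal(size=10)
        lam, tau = 0.4, 1.3
        base = car_logpdf(g, adj, lam, tau)
        quad = float(g @ (car_precision(adj, lam, 1.0) @ g))
        # scaling tau -> 4 tau adds (n/2) log 4 and -(3/2) tau quad
        expected = base + 0.5 * 10 * np.log(4.0) - 1.5 * tau * quad
        assert car_logpdf(g, adj, lam, 4 * tau) == \
            pytest.approx(expected, abs=1e-9)


class TestProcesses:
    def test_logistic_values(self):
        assert process_probability([1.0, 0.5], [0.0, 0.0], 0.0) == 0.5
        assert process_probability([1.0, 0.5], [1.0, 2.0], -2.0) == 0.5
        assert process_probability([1.0], [40.0], 0.0) == \
            pytest.approx(1.0, abs=1e-12)
        with pytest.raises(ValueError):
            process_probability([1.0, 2.0], [1.0], 0.0)

    def test_mixture_arithmetic_and_limits(self):
        assert mixture_probability(0.2, 0.6, 0.5) == pytest.approx(0.4)
        assert mixture_probability(0.3, 0.9, 1.0) == 0.3
        assert mixture_probability(0.3, 0.9, 0.0) == 0.9

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(p=st.floats(0, 1), s=st.floats(0, 1), a=st.floats(0, 1))
    def test_mixture_convexity(self, p, s, a):
        q = mixture_probability(p, s, a)
        assert min(p, s) - 1e-12 <= q <= max(p, s) + 1e-12


def tiny_data(rng, n_taxa=1, nx=2, ny=2, miss=False):
    adj = grid_adjacency(nx, ny)
    n = adj.n_cells
    y = rng.integers(0, 2, size=(n_taxa, n)).astype(np.int8)
    y_c = rng.integers(0, 2, size=n).astype(np.int8)
    if miss:
        y[0, 0] = MISSING
        y_c[1] = MISSING
    d_e = np.column_stack([np.ones(n), rng.normal(size=n)])
    d_a = np.column_stack([np.ones(n), rng.normal(size=n)])
    return ModelData(y=y, y_c=y_c, design_eco=d_e, design_samp=d_a,
                     adjacency=adj)


def oracle_log_posterior(params, data, priors):
    """Independent term-by-term sum (plain loops, scipy densities)."""
    total = 0.0
    s = np.array([process_probability(data.design_samp[k], params.beta_s,
                                      params.g[k])
                  for k in range(data.n_cells)])
    for k in range(data.n_cells):
        if data.y_c[k] != MISSING:
            total += np.log(s[k] if data.y_c[k] == 1 else 1 - s[k])
    for i in range(data.n_taxa):
        for k in range(data.n_cells):
            if data.y[i, k] == MISSING:
                continue
            p = process_probability(data.design_eco_for(i)[k],
                                    params.beta_p[i], params.g[k])
            q = params.alpha[i] * p + (1 - params.alpha[i]) * s[k]
            total += np.log(q if data.y[i, k] == 1 else 1 - q)
    Q = car_precision(data.adjacency, params.lambda_g, params.tau).toarray()
    total += multivariate_normal(mean=np.zeros(data.n_cells),
                                 cov=np.linalg.inv(Q)).logpdf(params.g)
    sd = np.sqrt(priors.beta_scale)
    total += norm.logpdf(params.beta_p, 0, sd).sum()
    total += norm.logpdf(params.beta_s, 0, sd).sum()
    total += beta_dist.logpdf(params.alpha, priors.alpha_a,
                              priors.alpha_b).sum()
    total += beta_dist.logpdf(params.lambda_g, priors.lambda_a,
                              priors.lambda_b)
    total += invgamma.logpdf(params.tau, priors.tau_shape,
                             scale=priors.tau_scale)
    return total


class TestJointLogPosterior:
    def test_matches_term_by_term_oracle(self):
        rng = np.random.default_rng(7)
        for trial in range(5):
            data = tiny_data(rng, n_taxa=2, miss=(trial % 2 == 0))
            params = ModelParams(
                beta_p=rng.normal(size=(2, 2)),
                beta_s=rng.normal(size=2),
                alpha=rng.uniform(0.1, 0.9, size=2),
                lambda_g=float(rng.uniform(0.1, 0.9)),
                tau=float(rng.uniform(0.2, 3.0)),
                g=rng.normal(size=data.n_cells),
            )
            priors = Priors()
            assert joint_log_posterior(params, data, priors) == \
                pytest.approx(oracle_log_posterior(params, data, priors),
                              abs=1e-10)

    def test_single_observation_term_additivity(self):
        rng = np.random.default_rng(3)
        data = tiny_data(rng, n_taxa=1)
        params = ModelParams(beta_p=[[0.3, -0.2]], beta_s=[0.1, 0.4],
                             alpha=[0.6], lambda_g=0.5, tau=1.0,
                             g=rng.normal(size=4))
        base = joint_log_posterior(params, data, Priors())
        # masking one observed cell removes exactly its Bernoulli term
        y2 = data.y.copy()
        cell = 2
        y2[0, cell] = MISSING
        data2 = ModelData(y=y2, y_c=data.y_c, design_eco=data.design_eco,
                          design_samp=data.design_samp,
                          adjacency=data.adjacency)
        p = process_probability(data.design_eco[cell], params.beta_p[0],
                                params.g[cell])
        s = process_probability(data.design_samp[cell], params.beta_s,
                                params.g[cell])
        q = mixture_probability(p, s, params.alpha[0])
        term = np.log(q) if data.y[0, cell] == 1 else np.log(1 - q)
        assert joint_log_posterior(params, data2, Priors()) == \
            pytest.approx(base - term, abs=1e-10)

    def test_conflicting_degenerate_probability_is_minus_inf(self):
        rng = np.random.default_rng(0)
        data = tiny_data(rng, n_taxa=1)
        data.y[0, :] = 1
        # logit(-800) underflows to a probability of exactly zero
        params = ModelParams(beta_p=[[-800.0, 0.0]], beta_s=[-800.0, 0.0],
                             alpha=[1.0], lambda_g=0.5, tau=1.0,
                             g=np.zeros(4))
        priors = Priors(alpha_a=1.0, alpha_b=1.0)  # uniform: allows alpha=1
        assert joint_log_posterior(params, data, priors) == -np.inf

    def test_invariant_under_consistent_cell_permutation(self):
        rng = np.random.default_rng(9)
        data = tiny_data(rng, n_taxa=2, nx=3, ny=3, miss=True)
        params = ModelParams(beta_p=rng.normal(size=(2, 2)),
                             beta_s=rng.normal(size=2),
                             alpha=[0.4, 0.7], lambda_g=0.6, tau=0.8,
                             g=rng.normal(size=9))
        perm = rng.permutation(9)
        from pojsdm.lattice import Adjacency
        W = data.adjacency.matrix.toarray()[np.ix_(perm, perm)]
        import scipy.sparse as sp
        adj_p = Adjacency(matrix=sp.csr_matrix(W), degrees=W.sum(axis=1))
        data_p = ModelData(y=data.y[:, perm], y_c=data.y_c[perm],
                           design_eco=data.design_eco[perm],
                           design_samp=data.design_samp[perm],
                           adjacency=adj_p)
        params_p = ModelParams(beta_p=params.beta_p, beta_s=params.beta_s,
                               alpha=params.alpha, lambda_g=params.lambda_g,
                               tau=params.tau, g=params.g[perm])
        assert joint_log_posterior(params, data, Priors()) == \
            pytest.approx(joint_log_posterior(params_p, data_p, Priors()),
                          abs=1e-9)


def test_standardize_centers_and_scales_non_intercept_columns():
    rng = np.random.default_rng(2)
    data = tiny_data(rng, nx=4, ny=4)
    data.design_eco[:, 1] = 5.0 + 3.0 * rng.normal(size=16)
    z = data.standardize()
    np.testing.assert_allclose(z.design_eco[:, 0], 1.0)  # intercept kept
    assert abs(z.design_eco[:, 1].mean()) < 1e-12
    assert z.design_eco[:, 1].std() == pytest.approx(1.0)
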