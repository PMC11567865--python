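import numpy as np
import pandas as pd
import pytest

from peptinet.core import NodeMeta, validate_network
from peptinet.ggm import (
    GlassoError,
    ebic,
    estimate_network,
    glasso,
    n_edges,
    select_model,
    to_partial_correlations,
)

from _oracles import sklearn_glasso


def random_spd_corr(rng, p, n=None):
    n = n or 10 * p
    X = rng.standard_normal((n, p))
    return np.corrcoef(X.T)


class TestGlasso:
    def test_zero_penalty_is_matrix_inverse_2x2(self):
        R = np.array([[1.0, 0.5], [0.5, 1.0]])
        Theta = glasso(R, 0.0)
        assert np.allclose(Theta, [[4 / 3, -2 / 3], [-2 / 3, 4 / 3]], atol=1e-10)

    def test_full_shrinkage_gives_diagonal_precision(self, rng):
        R = random_spd_corr(rng, 5)
        lam_max = np.max(np.abs(R - np.eye(5)))
        Theta = glasso(R, lam_max * 1.0001)
        off = Theta[~np.eye(5, dtype=bool)]
        assert np.all(off == 0)

    def test_matches_coordinate_descent_oracle(self, rng):
        for _ in range(3):
            R = random_spd_corr(rng, 5)
            Theta = glasso(R, 0.1, tol=1e-9)
            K = sklearn_glasso(R, 0.1)
            assert np.max(np.abs(Theta - K)) < 1e-5

    def test_solution_is_spd(self, rng):
        R = random_spd_corr(rng, 6)
        Theta = glasso(R, 0.05)
        assert np.linalg.eigvalsh(Theta).min() > 0

    def test_non_psd_input_rejected(self):
        R = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues -1, 3
        with pytest.raises(GlassoError, match="positive semidefinite"):
            glasso(R, 0.1)

    def test_negative_lambda_rejected(self, rng):
        with pytest.raises(ValueError):
            glasso(np.eye(3), -0.1)


class TestEbic:
    def test_identity_closed_form(self):
        # L = (100/2)(0 - 2) = -100, no edges: EBIC = 200
        assert ebic(np.eye(2), np.eye(2), n=100, gamma=0.5) == pytest.approx(200.0)

    def test_gamma_zero_is_bic(self, rng):
        R = random_spd_corr(rng, 4)
        Theta = glasso(R, 0.05)
        E = n_edges(Theta)
        sign, logdet = np.linalg.slogdet(Theta)
        L = 50 * (logdet - np.sum(R * Theta))
        assert ebic(Theta, R, 100, gamma=0.0) == pytest.approx(-2 * L + E * np.log(100))

    def test_extra_edge_costs_logn_plus_4gamma_logp(self):
        # same likelihood, one more nonzero entry
        Theta0 = np.eye(3)
        Theta1 = Theta0.copy()
        Theta1[0, 1] = Theta1[1, 0] = 1e-9  # negligible for the likelihood
        n, p, gamma = 200, 3, 0.5
        delta = ebic(Theta1, np.eye(3), n, gamma) - ebic(Theta0, np.eye(3), n, gamma)
        assert delta == pytest.approx(np.log(n) + 4 * gamma * np.log(p), rel=1e-6)

    def test_singular_theta_rejected(self):
        with pytest.raises(GlassoError):
            ebic(np.zeros((2, 2)), np.eye(2), 100)


class TestSelectModel:
    def test_identity_correlation_selects_empty_graph(self):
        fit = select_model(np.eye(5), n=200, n_lambda=20)
        assert n_edges(fit.selected_precision) == 0

    def test_selected_index_is_argmin(self, rng):
        fit = select_model(random_spd_corr(rng, 6), n=100, n_lambda=15)
        assert fit.selected_index == int(np.argmin(fit.ebic_values))
        assert np.all(np.isfinite(fit.ebic_values))

    def test_edge_count_monotone_along_path(self, rng):
        fit = select_model(random_spd_corr(rng, 8, n=60), n=60, n_lambda=25)
        counts = fit.path_summary()["n_edges"].to_numpy()
        assert np.all(np.diff(counts) >= 0)  # grid runs from large to small lambda

    def test_heavier_ebic_penalty_selects_sparser_model(self, rng):
        R = random_spd_corr(rng, 8, n=50)
        e_heavy = n_edges(select_model(R, 50, gamma=0.5, n_lambda=25).selected_precision)
        e_light = n_edges(select_model(R, 50, gamma=0.0, n_lambda=25).selected_precision)
        assert e_heavy <= e_light


class TestPartialCorrelations:
    def test_two_by_two_closed_form(self):
        W = to_partial_correlations(np.array([[2.0, -1.0], [-1.0, 2.0]]))
        assert W[0, 1] == pytest.approx(0.5)
        assert W[0, 0] == 0

    def test_diagonal_precision_gives_empty_network(self):
        assert np.all(to_partial_correlations(np.diag([1.0, 2.0, 3.0])) == 0)

    def test_magnitudes_below_one_for_spd(self, rng):
        for _ in range(5):
            R = random_spd_corr(rng, 6)
            W = to_partial_correlations(np.linalg.inv(R))
            assert np.max(np.abs(W)) < 1

    def test_sign_pattern_negates_precision(self, rng):
        Theta = glasso(random_spd_corr(rng, 5, n=30), 0.05)
        W = to_partial_correlations(Theta)
        off = ~np.eye(5, dtype=bool)
        assert np.all(np.sign(W[off]) == -np.sign(Theta[off]))

    def test_nonpositive_diagonal_rejected(self):
        with pytest.raises(ValueError):
            to_partial_correlations(np.array([[0.0, 1.0], [1.0, 1.0]]))


class TestEstimateNetwork:
    def _data(self, rng, n=150):
        Theta = np.array([
            [1.5, -0.4, 0.0, 0.0],
            [-0.4, 1.5, -0.4, 0.0],
            [0.0, -0.4, 1.5, 0.0],
            [0.0, 0.0, 0.0, 1.0],
        ])
        L = np.linalg.cholesky(np.linalg.inv(Theta))
        X = rng.standard_normal((n, 4)) @ L.T
        cols = [f"v{i}" for i in range(4)]
        meta = [NodeMeta(c, c, "synaptic_peptide") for c in cols]
        return pd.DataFrame(X, columns=cols), meta

    def test_row_permutation_invariance(self, rng):
        X, meta = self._data(rng)
        net1, _ = estimate_network(X, meta, n_lambda=15, compute_layout=False)
        perm = rng.permutation(len(X))
        net2, _ = estimate_network(X.iloc[perm].reset_index(drop=True), meta,
                                   n_lambda=15, compute_layout=False)
        assert np.allclose(net1.network.W, net2.network.W)

    def test_estimate_is_valid_signed_network(self, rng):
        X, meta = self._data(rng)
        net, fit = estimate_network(X, meta, n_lambda=15, compute_layout=False)
        assert validate_network(net.network) == []
        assert net.network.n_samples == fit.n_effective == len(X)

    def test_layout_is_seeded_and_stored(self, rng):
        X, meta = self._data(rng, n=80)
        net1, _ = estimate_network(X, meta, n_lambda=10, layout_seed=7)
        net2, _ = estimate_network(X, meta, n_lambda=10, layout_seed=7)
        assert net1.network.layout == net2.network.layout

    def test_column_mismatch_rejected(self, rng):
        X, meta = self._data(rng, n=50)
        with pytest.raises(ValueError, match="match node metadata"):
            estimate_network(X, list(reversed(meta)), n_lambda=5)


def test_partial_correlation_error_shrinks_with_n(rng):
    """Estimated partial correlations approach the truth as n grows."""
    Theta = np.eye(6)
    for i, j, v in [(0, 1, -0.35), (1, 2, -0.3), (3, 4, 0.3), (4, 5, -0.25)]:
        Theta[i, j] = Theta[j, i] = v
    Theta += np.eye(6) * 0.3
    W_true = to_partial_correlations(Theta)
    L = np.linalg.cholesky(np.linalg.inv(Theta))
    errs = []
    for n in (200, 440, 2000):
        devs = []
        for rep in range(5):
            X = rng.standard_normal((n, 6)) @ L.T
            R = np.corrcoef(X.T)
            fit = select_model(R, n, n_lambda=30)
            W = to_partial_correlations(fit.selected_precision)
            devs.append(np.max(np.abs(W - W_true)))
        errs.append(np.median(devs))
    assert errs[0] > errs[2]
    assert errs[2] < 0.1
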