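"""Coupling-model inference, direct distributions and rankings."""

import numpy as np
import pytest
from scipy.optimize import root

from tcsdca.dca import (
    CouplingModel,
    DirectCouplingAnalysis,
    average_coupling_matrix,
    direct_information,
    direct_pair_distribution,
    fit_model,
    model_pair_marginals,
    random_gauge_shift,
    rank_direct_couplings,
    select_columns,
    zero_sum_gauge,
)
from tcsdca.frequencies import FrequencyCounts
from tcsdca.synthetic import default_planted_model, sample_pairs


def _counts_from_fij(f_ij, f_i, q):
    return FrequencyCounts(
        f_i=f_i, f_ij=f_ij, pseudocount=0.0, m_eff=1.0, q=q, boundary=1
    )


def _ips_oracle(target_fij, n, q, sweeps=5000):
    """Iterative proportional scaling on the fully enumerated joint tensor.

    Independent oracle for the maximum-entropy distribution matching all
    pair marginals: start uniform, cyclically rescale by each pair's
    target/current marginal ratio.
    """
    p = np.ones((q,) * n)
    p /= p.sum()
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    for _ in range(sweeps):
        for i, j in pairs:
            axes = tuple(k for k in range(n) if k not in (i, j))
            cur = p.sum(axis=axes)
            ratio = target_fij[i, j] / np.maximum(cur, 1e-300)
            shape = [1] * n
            shape[i] = q
            shape[j] = q
            # ratio currently indexed (i, j); expand to the joint shape
            p = p * ratio.reshape(shape)
        p /= p.sum()
    return p


class TestColumnSelection:
    def test_dominant_pair_selected_first(self):
        mi = np.zeros((6, 6))
        mi[1, 4] = mi[4, 1] = 5.0
        mi[0, 5] = mi[5, 0] = 1.0
        cols = select_columns(mi, boundary=3, n_max=2)
        assert list(cols) == [1, 4]

    def test_n_max_total_takes_all_touched_columns(self, rng):
        mi = np.abs(rng.normal(size=(8, 8)))
        mi = mi + mi.T
        cols = select_columns(mi, boundary=4, n_max=8)
        assert list(cols) == list(range(8))

    def test_planted_columns_fill_first_slots(self, fitted, planted_model):
        planted_cols = sorted({c for p in planted_model.planted_pairs for c in p})
        assert set(planted_cols) <= set(fitted.columns_.tolist())

    def test_n_max_below_two_rejected(self):
        with pytest.raises(ValueError):
            select_columns(np.zeros((4, 4)), boundary=2, n_max=1)


class TestExactFit:
    def test_two_column_q3_reproduces_pair_marginal_to_machine_precision(self, rng):
        # for 2 columns the max-ent model matching f_12 IS f_12 itself
        q = 3
        f12 = rng.dirichlet(np.ones(q * q)).reshape(q, q)
        f_i = np.stack([f12.sum(axis=1), f12.sum(axis=0)])
        f_ij = np.empty((2, 2, q, q))
        f_ij[0, 1] = f12
        f_ij[1, 0] = f12.T
        f_ij[0, 0] = np.diag(f_i[0])
        f_ij[1, 1] = np.diag(f_i[1])
        counts = _counts_from_fij(f_ij, f_i, q)
        model = fit_model(counts, [0, 1], method="exact", boundary=1)
        _, m2 = model_pair_marginals(model.e, model.h, q)
        np.testing.assert_allclose(m2[0, 1], f12, atol=1e-8)

    def test_three_column_fit_matches_ips_enumeration_oracle(self, rng):
        n, q = 3, 3
        # consistent targets: draw a random joint distribution, use its
        # pair marginals
        joint = rng.dirichlet(np.ones(q**n)).reshape((q,) * n)
        f_ij = np.empty((n, n, q, q))
        f_i = np.empty((n, q))
        for i in range(n):
            axes = tuple(k for k in range(n) if k != i)
            f_i[i] = joint.sum(axis=axes)
            f_ij[i, i] = np.diag(f_i[i])
        for i in range(n):
            for j in range(n):
                if i != j:
                    axes = tuple(k for k in range(n) if k not in (i, j))
                    m = joint.sum(axis=axes)
                    f_ij[i, j] = m if i < j else m.T
        counts = _counts_from_fij(f_ij, f_i, q)
        model = fit_model(counts, [0, 1, 2], method="exact", boundary=1)
        _, fitted_m2 = model_pair_marginals(model.e, model.h, q)
        oracle = _ips_oracle(f_ij, n, q)
        oracle_01 = oracle.sum(axis=2)
        np.testing.assert_allclose(fitted_m2[0, 1], f_ij[0, 1], atol=1e-8)
        np.testing.assert_allclose(fitted_m2[0, 1], oracle_01, atol=1e-7)

    def test_product_counts_give_zero_couplings(self, rng):
        q = 4
        f_i = np.stack([rng.dirichlet(np.ones(q)) for _ in range(2)])
        f_ij = np.empty((2, 2, q, q))
        f_ij[0, 1] = np.outer(f_i[0], f_i[1])
        f_ij[1, 0] = f_ij[0, 1].T
        f_ij[0, 0] = np.diag(f_i[0])
        f_ij[1, 1] = np.diag(f_i[1])
        counts = _counts_from_fij(f_ij, f_i, q)
        model = fit_model(counts, [0, 1], method="exact", boundary=1)
        np.testing.assert_allclose(model.e[0, 1], 0.0, atol=1e-4)
        # fields reproduce ln f_i up to the zero-sum gauge constant
        expected = np.log(f_i) - np.log(f_i).mean(axis=1, keepdims=True)
        np.testing.assert_allclose(model.h, expected, atol=1e-4)


class TestGauge:
    def test_zero_sum_constraints_hold_exactly(self, fitted):
        e, h = fitted.e_, fitted.h_
        np.testing.assert_allclose(e.sum(axis=2), 0.0, atol=1e-10)
        np.testing.assert_allclose(e.sum(axis=3), 0.0, atol=1e-10)
        np.testing.assert_allclose(h.sum(axis=1), 0.0, atol=1e-10)

    def test_gauge_transform_preserves_distribution(self, rng):
        n, q = 3, 3
        e = rng.normal(size=(n, n, q, q))
        e = 0.5 * (e + e.transpose(1, 0, 3, 2))
        for i in range(n):
            e[i, i] = 0
        h = rng.normal(size=(n, q))
        e2, h2 = zero_sum_gauge(e, h)
        p1 = model_pair_marginals(e, h, q)[1]
        p2 = model_pair_marginals(e2, h2, q)[1]
        np.testing.assert_allclose(p1, p2, atol=1e-12)

    def test_random_gauge_shift_preserves_distribution(self, rng):
        n, q = 3, 4
        e = rng.normal(size=(n, n, q, q))
        e = 0.5 * (e + e.transpose(1, 0, 3, 2))
        for i in range(n):
            e[i, i] = 0
        h = rng.normal(size=(n, q))
        e2, h2 = random_gauge_shift(e, h, rng)
        p1 = model_pair_marginals(e, h, q)[1]
        p2 = model_pair_marginals(e2, h2, q)[1]
        np.testing.assert_allclose(p1, p2, atol=1e-12)


class TestDirectPairDistribution:
    def test_zero_coupling_gives_outer_product(self, rng):
        f_i = rng.dirichlet(np.ones(21))
        f_j = rng.dirichlet(np.ones(21))
        p, _, _, resid = direct_pair_distribution(np.zeros((21, 21)), f_i, f_j)
        np.testing.assert_allclose(p, np.outer(f_i, f_j), atol=1e-12)
        assert resid < 1e-12

    def test_marginals_match_within_tolerance(self, rng):
        e = rng.normal(size=(21, 21))
        f_i = rng.dirichlet(np.ones(21) * 3)
        f_j = rng.dirichlet(np.ones(21) * 3)
        p, _, _, _ = direct_pair_distribution(e, f_i, f_j, tol=1e-12)
        np.testing.assert_allclose(p.sum(axis=1), f_i, atol=1e-8)
        np.testing.assert_allclose(p.sum(axis=0), f_j, atol=1e-8)
        assert np.all(p > 0)

    def test_matches_independent_root_solver(self, rng):
        # brute-force oracle: solve for the compensating fields with a
        # generic nonlinear root finder instead of IPF
        q = 4
        e = rng.normal(size=(q, q))
        f_i = np.full(q, 1.0 / q)
        f_j = np.full(q, 1.0 / q)

        def equations(x):
            a, b = x[:q], x[q:]
            p = np.exp(e + a[:, None] + b[None, :])
            p /= p.sum()
            return np.concatenate(
                [p.sum(axis=1) - f_i, (p.sum(axis=0) - f_j)[:-1]]
            )[: 2 * q]

        sol = root(lambda x: equations(np.append(x, 0.0)), np.zeros(2 * q - 1))
        assert sol.success
        a, b = np.append(sol.x, 0.0)[:q], np.append(sol.x, 0.0)[q:]
        oracle = np.exp(e + a[:, None] + b[None, :])
        oracle /= oracle.sum()
        p, _, _, _ = direct_pair_distribution(e, f_i, f_j, tol=1e-13)
        np.testing.assert_allclose(p, oracle, atol=1e-6)


class TestRanking:
    def test_uncoupled_model_has_zero_strengths(self):
        q = 5
        f = np.full((2, q), 1.0 / q)
        model = CouplingModel(
            columns=np.array([0, 1]),
            e=np.zeros((2, 2, q, q)),
            h=np.zeros((2, q)),
            f_i=f,
            boundary=1,
            q=q,
        )
        ranked = rank_direct_couplings(model)
        assert all(abs(s) < 1e-12 for _, _, s in ranked)

    def test_planted_pairs_fill_top_ranks(self, fitted, planted_model):
        ranked = rank_direct_couplings(fitted.model_)
        top = {(i, j) for i, j, _ in ranked[:6]}
        assert top == set(map(tuple, planted_model.planted_pairs))

    def test_strength_is_gauge_invariant(self, rng):
        q = 4
        e_block = rng.normal(size=(q, q))
        f = np.stack([rng.dirichlet(np.ones(q) * 5) for _ in range(2)])

        def di_of(block):
            p, _, _, _ = direct_pair_distribution(block, f[0], f[1], tol=1e-13)
            return direct_information(p)

        base = di_of(e_block)
        shifted = e_block + rng.normal(size=q)[:, None] + rng.normal(size=q)[None, :]
        assert di_of(shifted) == pytest.approx(base, abs=1e-9)


class TestAverageMatrix:
    def test_top_k_one_returns_that_matrix(self, fitted):
        ranked = rank_direct_couplings(fitted.model_)
        i, j, _ = ranked[0]
        cidx = {int(c): k for k, c in enumerate(fitted.columns_)}
        avg = average_coupling_matrix(fitted.model_, top_k=1)
        np.testing.assert_allclose(avg, fitted.e_[cidx[i], cidx[j]])

    def test_symmetric_construction_gives_symmetric_average(self, planted_model):
        # charge-complementary planted couplings are symmetric matrices, so
        # the average over planted truth is symmetric
        model = planted_model.to_coupling_model()
        avg = average_coupling_matrix(model, top_k=6)
        assert np.linalg.norm(avg - avg.T) / np.linalg.norm(avg) < 1e-10

    def test_fitted_average_much_more_symmetric_than_noise(self, fitted):
        # the planted rule is symmetric; the fitted average's asymmetric
        # part is pure sampling noise, so it must sit well below the ~1.0
        # ratio of an uncorrelated matrix (it decays ~ n^{-1/2})
        avg = average_coupling_matrix(fitted.model_, top_k=6)
        assert np.linalg.norm(avg - avg.T) / np.linalg.norm(avg) < 0.5

    def test_charge_blocks_positive_on_opposite_charges(self, planted_model):
        from tcsdca.alphabet import DEFAULT_ALPHABET
        from tcsdca.modes import NEGATIVE, POSITIVE

        avg = average_coupling_matrix(planted_model.to_coupling_model(), top_k=6)
        pos = [DEFAULT_ALPHABET.index_of[a] for a in POSITIVE]
        neg = [DEFAULT_ALPHABET.index_of[a] for a in NEGATIVE]
        assert np.all(avg[np.ix_(pos, neg)] > 0.5)
        assert np.all(avg[np.ix_(neg, pos)] > 0.5)
        assert np.all(avg[np.ix_(pos, pos)] < -0.5)

    def test_too_few_pairs_is_error(self, planted_model):
        model = planted_model.to_coupling_model()
        with pytest.raises(ValueError, match="need"):
            average_coupling_matrix(model, top_k=1000)


class TestParameterRecovery:
    def test_planted_coupling_recovery_at_large_n(self):
        # recovery experiment at n = 10^4 samples of the default model
        model = default_planted_model(seed=0)
        corpus = sample_pairs(model, n=10_000, seed=6, burn_in=300)
        est = DirectCouplingAnalysis(method="plm").fit(corpus.msa)
        ez, _ = zero_sum_gauge(model.e, model.h)
        cidx = {int(c): k for k, c in enumerate(est.columns_)}
        a, b = [], []
        for i, j in model.planted_pairs:
            a.append(ez[i, j].ravel())
            b.append(est.e_[cidx[i], cidx[j]].ravel())
        r = np.corrcoef(np.concatenate(a), np.concatenate(b))[0, 1]
        assert r > 0.9
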