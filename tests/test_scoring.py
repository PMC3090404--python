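"""Null model, interaction score and the two baseline scorers."""

import numpy as np
import pytest

from tcsdca.dca import CouplingModel, random_gauge_shift
from tcsdca.frequencies import FrequencyCounts
from tcsdca.scoring import (
    DcaScorer,
    MutualInformationScorer,
    NearestNeighborScorer,
    null_logprob,
    score_matrix,
)
from tcsdca.synthetic import sample_pairs


def _uncoupled_model(q=5, n_sk=2, n_rr=2, f=None, rng=None):
    n = n_sk + n_rr
    f_i = (
        np.stack([rng.dirichlet(np.ones(q) * 5) for _ in range(n)])
        if rng is not None
        else np.full((n, q), 1.0 / q)
    )
    if f is not None:
        f_i = f
    return CouplingModel(
        columns=np.arange(n),
        e=np.zeros((n, n, q, q)),
        h=np.zeros((n, q)),
        f_i=f_i,
        boundary=n_sk,
        q=q,
    )


class TestNullModel:
    def test_point_mass_match_gives_zero(self):
        f = np.zeros((2, 4))
        f[0, 1] = 1.0
        f[1, 2] = 1.0
        model = _uncoupled_model(q=4, n_sk=1, n_rr=1, f=f)
        assert null_logprob(np.array([1, 2]), model) == 0.0

    def test_uniform_frequencies_give_l_log_q(self):
        model = _uncoupled_model(q=5, n_sk=2, n_rr=2)
        seq = np.array([0, 1, 2, 3])
        assert null_logprob(seq, model) == pytest.approx(4 * np.log(1 / 5))

    def test_hand_summed_toy(self, rng):
        model = _uncoupled_model(q=5, n_sk=1, n_rr=2, rng=rng)
        seq = np.array([3, 0, 4])
        expected = (
            np.log(model.f_i[0, 3])
            + np.log(model.f_i[1, 0])
            + np.log(model.f_i[2, 4])
        )
        assert null_logprob(seq, model) == pytest.approx(expected)


class TestDcaScore:
    def test_uncoupled_model_scores_exactly_zero(self, rng):
        model = _uncoupled_model(rng=rng)
        scorer = DcaScorer(model)
        for _ in range(5):
            sk = rng.integers(0, 5, 2)
            res = scorer.score_pair(sk, rng.integers(0, 5, 2))
            assert res.score == pytest.approx(0.0, abs=1e-12)

    def test_contributions_sum_to_total_and_are_additive(self, fitted, corpus):
        scorer = DcaScorer(fitted.model_)
        sk = corpus.sk_codes[0]
        rr = corpus.rr_codes[0]
        res = scorer.score_pair(sk, rr)
        assert res.score == pytest.approx(
            sum(c for _, _, c in res.contributions), abs=1e-10
        )
        # removing one pair changes the score by exactly its contribution
        i, j, c0 = res.contributions[0]
        partial = sum(
            c for a, b, c in res.contributions if (a, b) != (i, j)
        )
        assert res.score - partial == pytest.approx(c0, abs=1e-12)

    def test_cognates_outscore_shuffles_on_planted_corpus(
        self, planted_model, small_corpus
    ):
        scorer = DcaScorer(planted_model.to_coupling_model())
        cog = scorer.score_rows(small_corpus.sk_codes, small_corpus.rr_codes)
        non = scorer.score_rows(
            small_corpus.sk_codes[[a for a, _ in small_corpus.noncognate_rows]],
            small_corpus.rr_codes[[b for _, b in small_corpus.noncognate_rows]],
        )
        assert cog.mean() > 0
        assert cog.mean() > non.mean()

    def test_score_is_gauge_invariant(self, planted_model, small_corpus, rng):
        model = planted_model.to_coupling_model()
        e2, h2 = random_gauge_shift(model.e, model.h, rng)
        shifted = CouplingModel(
            columns=model.columns,
            e=e2,
            h=h2,
            f_i=model.f_i,
            boundary=model.boundary,
            q=model.q,
        )
        s1 = DcaScorer(model, ipf_tol=1e-14).score_rows(
            small_corpus.sk_codes[:20], small_corpus.rr_codes[:20]
        )
        s2 = DcaScorer(shifted, ipf_tol=1e-14).score_rows(
            small_corpus.sk_codes[:20], small_corpus.rr_codes[:20]
        )
        np.testing.assert_allclose(s1, s2, atol=1e-10)

    def test_score_rows_matches_score_pair(self, fitted, corpus):
        scorer = DcaScorer(fitted.model_)
        rows = scorer.score_rows(corpus.sk_codes[:5], corpus.rr_codes[:5])
        singles = [
            scorer.score_pair(corpus.sk_codes[k], corpus.rr_codes[k]).score
            for k in range(5)
        ]
        np.testing.assert_allclose(rows, singles, atol=1e-12)

    def test_gap_policy_skip_zeroes_gapped_pairs(self, planted_model, rng):
        model = planted_model.to_coupling_model()
        sk = rng.integers(0, 20, planted_model.l_sk)
        rr = rng.integers(0, 20, planted_model.l_rr)
        sk_gapped = sk.copy()
        sk_gapped[[i for i, _ in planted_model.planted_pairs]] = 20
        res = DcaScorer(model, gap_policy="skip").score_pair(sk_gapped, rr)
        assert res.score == 0.0
        assert res.contributions == []


class TestScoreMatrix:
    def test_one_by_one_matrix_equals_single_score(self, fitted, corpus):
        scorer = DcaScorer(fitted.model_)
        sm = score_matrix(
            corpus.sk_codes[:1], corpus.rr_codes[:1], fitted.model_, scorer=scorer
        )
        single = scorer.score_pair(corpus.sk_codes[0], corpus.rr_codes[0])
        assert sm.scores[0, 0] == pytest.approx(single.score, abs=1e-12)

    def test_cognate_diagonal_beats_off_diagonal(self, planted_model, small_corpus):
        c = small_corpus
        ids_sk = [r[0] for r in c.msa.row_ids][:30]
        ids_rr = [r[1] for r in c.msa.row_ids][:30]
        sm = score_matrix(
            c.sk_codes[:30],
            c.rr_codes[:30],
            planted_model.to_coupling_model(),
            sk_ids=ids_sk,
            rr_ids=ids_rr,
            cognate_pairs=set(zip(ids_sk, ids_rr)),
        )
        diag = sm.scores[sm.cognate_mask].mean()
        off = sm.scores[~sm.cognate_mask].mean()
        assert diag > off

    def test_within_genome_flag_masks_cross_genome(self, planted_model, small_corpus):
        c = small_corpus
        sm = score_matrix(
            c.sk_codes[:12],
            c.rr_codes[:12],
            planted_model.to_coupling_model(),
            sk_genomes=[r[2] for r in c.msa.row_ids][:12],
            rr_genomes=[r[2] for r in c.msa.row_ids][:12],
            within_genome=True,
        )
        assert np.isnan(sm.scores[0, -1])
        assert np.isfinite(sm.scores[0, 0])


class TestMiBaseline:
    def test_independent_counts_score_zero(self, rng):
        q = 4
        f_i = np.stack([rng.dirichlet(np.ones(q)) for _ in range(3)])
        f_ij = np.empty((3, 3, q, q))
        for i in range(3):
            for j in range(3):
                f_ij[i, j] = (
                    np.outer(f_i[i], f_i[j]) if i != j else np.diag(f_i[i])
                )
        counts = FrequencyCounts(
            f_i=f_i, f_ij=f_ij, pseudocount=0.0, m_eff=1.0, q=q, boundary=1
        )
        model = _uncoupled_model(q=q, n_sk=1, n_rr=2, f=f_i)
        scorer = MutualInformationScorer(counts, model)
        assert scorer.score_pair(np.array([2, 0, 1]), np.array([0, 3, 1])) == (
            pytest.approx(0.0, abs=1e-12)
        )

    def test_hand_computed_toy_counts(self):
        q = 2
        f_i = np.array([[0.5, 0.5], [0.25, 0.75]])
        f12 = np.array([[0.2, 0.3], [0.05, 0.45]])
        f_ij = np.empty((2, 2, q, q))
        f_ij[0, 1] = f12
        f_ij[1, 0] = f12.T
        f_ij[0, 0] = np.diag(f_i[0])
        f_ij[1, 1] = np.diag(f_i[1])
        counts = FrequencyCounts(
            f_i=f_i, f_ij=f_ij, pseudocount=0.0, m_eff=1.0, q=q, boundary=1
        )
        model = _uncoupled_model(q=q, n_sk=1, n_rr=1, f=f_i)
        scorer = MutualInformationScorer(counts, model)
        expected = np.log(0.45 / (0.5 * 0.75))
        assert scorer.score_pair(np.array([1]), np.array([1])) == pytest.approx(
            expected
        )


class TestKnnBaseline:
    @pytest.fixture()
    def train(self, planted_model):
        return sample_pairs(planted_model, n=12, seed=9, burn_in=100).msa

    def test_training_member_query_scores_100_at_k1(self, train):
        scorer = NearestNeighborScorer(train, k=1)
        b = train.boundary
        s = scorer.score_pair(train.codes[0, :b], train.codes[0, b:])
        assert s == pytest.approx(100.0)

    def test_k_equal_m_averages_over_all(self, train):
        scorer = NearestNeighborScorer(train, k=train.n_seqs)
        b = train.boundary
        sk, rr = train.codes[0, :b], train.codes[0, b:]
        rr_ids = (train.codes[:, b:] == rr).mean(axis=1) * 100
        sk_ids = (train.codes[:, :b] == sk).mean(axis=1) * 100
        expected = 0.5 * (rr_ids.mean() + sk_ids.mean())
        assert scorer.score_pair(sk, rr) == pytest.approx(expected)

    def test_k_above_training_size_rejected(self, train):
        with pytest.raises(ValueError, match="exceeds"):
            NearestNeighborScorer(train, k=train.n_seqs + 1)
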