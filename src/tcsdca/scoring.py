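"""Interaction scoring of SK/RR sequence pairs.

The null model keeps each retained column's empirical residue statistics
but destroys all inter-column correlation (independent per-column
permutation of the training alignment), i.e. a factorized distribution
``P0(A) = prod_i f_i(A_i)``.  The interaction score of a candidate SK/RR
pair is the log-likelihood ratio of the coupled model against that null,
restricted to inter-protein column pairs:

    S(sk, rr) = sum_{i in SK, j in RR} ln[ P^dir_ij(A_i, B_j)
                                           / (f_i(A_i) f_j(B_j)) ]

Intra-protein terms are deliberately excluded: they measure whether each
sequence looks like its own family, not whether the two interact.  A large
positive score means the residue combinations across the interface are the
ones enriched among known interacting (cognate) pairs.

Two simpler reference scorers are provided for benchmarking: the same sum
using raw pair frequencies (which over-counts couplings transmitted
indirectly through chains of positions), and a k-nearest-neighbor score
based purely on sequence identity to the training pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .dca import CouplingModel, direct_pair_distribution
from .frequencies import FrequencyCounts
from .msa_io import JointMSA


@dataclass
class InteractionScore:
    sk_id: str
    rr_id: str
    score: float
    contributions: list[tuple[int, int, float]]  # (sk_col, rr_col, term)


@dataclass
class ScoreMatrix:
    """All-vs-all interaction scores with cognate labels."""

    sk_ids: list[str]
    rr_ids: list[str]
    scores: np.ndarray  # (n_sk, n_rr)
    cognate_mask: np.ndarray  # bool, same shape
    sk_genomes: list[str] | None = None
    rr_genomes: list[str] | None = None

    def intra_genome_mask(self) -> np.ndarray:
        if self.sk_genomes is None or self.rr_genomes is None:
            return np.ones_like(self.cognate_mask)
        sk = np.asarray(self.sk_genomes)
        rr = np.asarray(self.rr_genomes)
        return sk[:, None] == rr[None, :]


class DcaScorer(BaseEstimator):
    """Log-likelihood interaction scorer backed by a fitted coupling model.

    Precomputes, for every retained inter-protein column pair, the matrix
    of per-residue-combination log contributions
    ``ln[P^dir_ij(A,B) / (f_i(A) f_j(B))]``, so scoring a pair is a table
    lookup summed over pairs.
    """

    def __init__(
        self,
        model: CouplingModel,
        gap_policy: str = "state",
        ipf_tol: float = 1e-10,
    ):
        if gap_policy not in ("state", "skip"):
            raise ValueError("gap_policy must be 'state' or 'skip'")
        self.model = model
        self.gap_policy = gap_policy
        self.ipf_tol = ipf_tol
        self._build()

    def _build(self) -> None:
        m = self.model
        self.pairs_ = m.inter_pairs()
        self.tables_ = {}
        for i, j in self.pairs_:
            p_dir, _, _, _ = direct_pair_distribution(
                m.e[i, j], m.f_i[i], m.f_i[j], tol=self.ipf_tol
            )
            self.tables_[(i, j)] = np.log(p_dir) - np.log(
                np.outer(m.f_i[i], m.f_i[j])
            )
        self.sk_local_ = np.where(m.sk_mask)[0]
        self.rr_local_ = np.where(~m.sk_mask)[0]
        self.sk_cols_ = m.columns[self.sk_local_]
        self.rr_cols_ = m.columns[self.rr_local_] - m.boundary

    def score_pair(
        self, sk_seq: np.ndarray, rr_seq: np.ndarray, sk_id="sk", rr_id="rr"
    ) -> InteractionScore:
        """Score one encoded SK sequence against one encoded RR sequence."""
        m = self.model
        sk_seq = np.asarray(sk_seq)
        rr_seq = np.asarray(rr_seq)
        if len(sk_seq) < m.boundary:
            raise ValueError("SK sequence shorter than the model's SK segment")
        gap = m.q - 1
        contribs = []
        total = 0.0
        for i, j in self.pairs_:
            a = int(sk_seq[m.columns[i]])
            b = int(rr_seq[m.columns[j] - m.boundary])
            if self.gap_policy == "skip" and (a == gap or b == gap):
                continue
            term = float(self.tables_[(i, j)][a, b])
            contribs.append((int(m.columns[i]), int(m.columns[j]), term))
            total += term
        return InteractionScore(sk_id, rr_id, total, contribs)

    def score_rows(
        self, sk_codes: np.ndarray, rr_codes: np.ndarray
    ) -> np.ndarray:
        """Scores of row-aligned (SK, RR) pairs: (n,) vector."""
        m = self.model
        sk_sub = np.asarray(sk_codes)[:, self.sk_cols_]
        rr_sub = np.asarray(rr_codes)[:, self.rr_cols_]
        out = np.zeros(sk_sub.shape[0])
        gap = m.q - 1
        for k, (i, j) in enumerate(self.pairs_):
            a = sk_sub[:, np.searchsorted(self.sk_local_, i)]
            b = rr_sub[:, np.searchsorted(self.rr_local_, j)]
            term = self.tables_[(i, j)][a, b]
            if self.gap_policy == "skip":
                term = np.where((a == gap) | (b == gap), 0.0, term)
            out += term
        return out

    def score_many(
        self, sk_codes: np.ndarray, rr_codes: np.ndarray
    ) -> np.ndarray:
        """Vectorized all-vs-all scores: (n_sk, n_rr) matrix.

        With the default gap policy (gap as a bona fide 21st state) every
        pair table is a dense lookup, so the sum over column pairs is a
        tensor contraction over precomputed tables.
        """
        m = self.model
        sk_sub = np.asarray(sk_codes)[:, self.sk_cols_]
        rr_sub = np.asarray(rr_codes)[:, self.rr_cols_]
        n_sk, n_rr = sk_sub.shape[0], rr_sub.shape[0]
        out = np.zeros((n_sk, n_rr))
        gap = m.q - 1
        for (i, j), table in self.tables_.items():
            ii = np.where(self.sk_local_ == i)[0][0]
            jj = np.where(self.rr_local_ == j)[0][0]
            a = sk_sub[:, ii]
            b = rr_sub[:, jj]
            term = table[a[:, None], b[None, :]]
            if self.gap_policy == "skip":
                mask = (a[:, None] == gap) | (b[None, :] == gap)
                term = np.where(mask, 0.0, term)
            out += term
        return out


def null_logprob(
    seq: np.ndarray, model: CouplingModel
) -> float:
    """Log-probability of a joint sequence under the factorized null.

    Sums ``ln f_i(A_i)`` over the model's retained columns only.
    """
    seq = np.asarray(seq)
    return float(
        np.log(model.f_i[np.arange(model.n_columns), seq[model.columns]]).sum()
    )


def interaction_score(
    sk_seq: np.ndarray,
    rr_seq: np.ndarray,
    model: CouplingModel,
    gap_policy: str = "state",
) -> InteractionScore:
    """Functional one-shot scoring (see :class:`DcaScorer`)."""
    return DcaScorer(model, gap_policy=gap_policy).score_pair(sk_seq, rr_seq)


def score_matrix(
    sk_codes: np.ndarray,
    rr_codes: np.ndarray,
    model: CouplingModel,
    sk_ids: list[str] | None = None,
    rr_ids: list[str] | None = None,
    cognate_pairs: set[tuple[str, str]] | None = None,
    sk_genomes: list[str] | None = None,
    rr_genomes: list[str] | None = None,
    within_genome: bool = False,
    scorer: DcaScorer | None = None,
) -> ScoreMatrix:
    """All-vs-all DCA scores for an SK set against an RR set.

    ``within_genome=True`` masks (NaN) pairings across different genomes,
    mirroring intra-species analyses.
    """
    sk_ids = sk_ids or [f"sk{k}" for k in range(len(sk_codes))]
    rr_ids = rr_ids or [f"rr{k}" for k in range(len(rr_codes))]
    scorer = scorer or DcaScorer(model)
    scores = scorer.score_many(sk_codes, rr_codes)
    mask = np.zeros(scores.shape, dtype=bool)
    if cognate_pairs:
        for a, s in enumerate(sk_ids):
            for b, r in enumerate(rr_ids):
                if (s, r) in cognate_pairs:
                    mask[a, b] = True
    sm = ScoreMatrix(sk_ids, rr_ids, scores, mask, sk_genomes, rr_genomes)
    if within_genome:
        sm.scores = np.where(sm.intra_genome_mask(), sm.scores, np.nan)
    return sm


class MutualInformationScorer(BaseEstimator):
    """Local-covariance baseline: raw pair-frequency log-ratios.

    Uses ``ln[f_ij(A,B) / (f_i(A) f_j(B))]`` summed over the same
    inter-protein column pairs as the DCA score.  Because raw pair
    frequencies mix direct and indirect correlations, chains of couplings
    are over-counted — which is exactly why this is a baseline.
    """

    def __init__(self, counts: FrequencyCounts, model: CouplingModel):
        self.counts = counts
        self.model = model

    def score_pair(self, sk_seq: np.ndarray, rr_seq: np.ndarray) -> float:
        m = self.model
        total = 0.0
        for i, j in m.inter_pairs():
            ci, cj = int(m.columns[i]), int(m.columns[j])
            a = int(np.asarray(sk_seq)[ci])
            b = int(np.asarray(rr_seq)[cj - m.boundary])
            f_ij = self.counts.f_ij[ci, cj, a, b]
            total += float(
                np.log(f_ij)
                - np.log(self.counts.f_i[ci, a])
                - np.log(self.counts.f_i[cj, b])
            )
        return total

    def score_rows(self, sk_codes, rr_codes) -> np.ndarray:
        """Scores of row-aligned (SK, RR) pairs: (n,) vector."""
        m = self.model
        out = np.zeros(len(sk_codes))
        for i, j in m.inter_pairs():
            ci, cj = int(m.columns[i]), int(m.columns[j])
            table = np.log(self.counts.f_ij[ci, cj]) - np.log(
                np.outer(self.counts.f_i[ci], self.counts.f_i[cj])
            )
            a = np.asarray(sk_codes)[:, ci]
            b = np.asarray(rr_codes)[:, cj - m.boundary]
            out += table[a, b]
        return out

    def score_many(self, sk_codes, rr_codes) -> np.ndarray:
        m = self.model
        out = np.zeros((len(sk_codes), len(rr_codes)))
        for i, j in m.inter_pairs():
            ci, cj = int(m.columns[i]), int(m.columns[j])
            table = np.log(self.counts.f_ij[ci, cj]) - np.log(
                np.outer(self.counts.f_i[ci], self.counts.f_i[cj])
            )
            a = np.asarray(sk_codes)[:, ci]
            b = np.asarray(rr_codes)[:, cj - m.boundary]
            out += table[a[:, None], b[None, :]]
        return out


class NearestNeighborScorer(BaseEstimator):
    """Sequence-identity baseline (kNN, default k = 2).

    For a query (SK, RR): find the k training cognate pairs whose SK is
    most similar to the query SK and average the %identity of the query RR
    to those pairs' RRs; symmetrize by also matching on RR and averaging
    the SK identities; the score is the mean of the two directions, in
    percent.  Ties in neighbor selection are broken by training row order.
    """

    def __init__(self, train: JointMSA, k: int = 2):
        if k < 1:
            raise ValueError("k must be >= 1")
        if k > train.n_seqs:
            raise ValueError(f"k={k} exceeds training size {train.n_seqs}")
        self.train = train
        self.k = k

    @staticmethod
    def _identity(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        return (a[None, :] == b).mean(axis=1) * 100.0

    def score_pair(self, sk_seq: np.ndarray, rr_seq: np.ndarray) -> float:
        b = self.train.boundary
        sk_train = self.train.codes[:, :b]
        rr_train = self.train.codes[:, b:]
        sk_id_frac = self._identity(np.asarray(sk_seq)[:b], sk_train)
        rr_id_frac = self._identity(np.asarray(rr_seq)[: rr_train.shape[1]], rr_train)
        nn_by_sk = np.argsort(-sk_id_frac, kind="stable")[: self.k]
        nn_by_rr = np.argsort(-rr_id_frac, kind="stable")[: self.k]
        return float(
            0.5 * (rr_id_frac[nn_by_sk].mean() + sk_id_frac[nn_by_rr].mean())
        )

    def score_rows(self, sk_codes, rr_codes) -> np.ndarray:
        """Scores of row-aligned (SK, RR) pairs: (n,) vector."""
        b = self.train.boundary
        return np.array(
            [self.score_pair(sk[:b], rr) for sk, rr in zip(sk_codes, rr_codes)]
        )

    def score_many(self, sk_codes, rr_codes) -> np.ndarray:
        out = np.empty((len(sk_codes), len(rr_codes)))
        b = self.train.boundary
        for a_idx, sk in enumerate(sk_codes):
            for b_idx, rr in enumerate(rr_codes):
                out[a_idx, b_idx] = self.score_pair(sk[:b], rr)
        return out


def mi_baseline_score(
    sk_seq: np.ndarray,
    rr_seq: np.ndarray,
    counts: FrequencyCounts,
    model: CouplingModel,
) -> float:
    return MutualInformationScorer(counts, model).score_pair(sk_seq, rr_seq)


def knn_identity_score(
    sk_seq: np.ndarray, rr_seq: np.ndarray, train: JointMSA, k: int = 2
) -> float:
    return NearestNeighborScorer(train, k=k).score_pair(sk_seq, rr_seq)
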