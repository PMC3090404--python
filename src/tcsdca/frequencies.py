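"""Reweighted, pseudocount-regularized frequency counts and mutual information.

Rows of the joint MSA are down-weighted by the number of neighbors sharing
more than an identity threshold (default 80%) of aligned positions, so that
clusters of near-identical sequences — multiple strains of one species,
tight phylogenetic clades — count roughly once.  With per-row multiplicity
``m_a`` (the row itself included), row ``a`` carries weight ``1/m_a`` and the
effective sample size is ``M_eff = sum_a 1/m_a``.

Single-column and column-pair frequencies add a uniform pseudocount
``lambda`` spread over the q (resp. q^2) cells:

    f_i(A)    = (lambda/q   + sum_a delta(A, x_i^a)/m_a) / (lambda + M_eff)
    f_ij(A,B) = (lambda/q^2 + sum_a delta(A, x_i^a) delta(B, x_j^a)/m_a)
                / (lambda + M_eff)

These satisfy exactly: normalization, marginal consistency
``sum_B f_ij(A,B) = f_i(A)`` and symmetry ``f_ij(A,B) = f_ji(B,A)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .msa_io import JointMSA


@dataclass
class SequenceWeights:
    """Phylogenetic reweighting of MSA rows."""

    m_a: np.ndarray  # per-row neighbor multiplicities, int >= 1
    identity_threshold: float = 0.80

    @property
    def weights(self) -> np.ndarray:
        return 1.0 / self.m_a

    @property
    def m_eff(self) -> float:
        return float(np.sum(1.0 / self.m_a))


@dataclass
class FrequencyCounts:
    """Reweighted single and pair frequencies on the full joint alignment.

    The pair tensor is dense (L, L, q, q); for the alignment lengths this
    package targets (joint length of a few hundred) that is well within
    memory, and diagonal blocks follow the convention
    ``f_ii(A,B) = f_i(A) delta(A,B)``.
    """

    f_i: np.ndarray  # (L, q)
    f_ij: np.ndarray  # (L, L, q, q)
    pseudocount: float
    m_eff: float
    q: int = 21
    boundary: int | None = None
    weights: SequenceWeights | None = field(default=None, repr=False)

    @property
    def length(self) -> int:
        return self.f_i.shape[0]


def _one_hot(codes: np.ndarray, q: int) -> np.ndarray:
    """(M, L) int codes -> (M, L*q) float one-hot."""
    m, length = codes.shape
    out = np.zeros((m, length * q))
    idx = np.arange(length) * q + codes
    out[np.arange(m)[:, None], idx] = 1.0
    return out


def compute_weights(
    msa: JointMSA | np.ndarray, threshold: float = 0.80
) -> SequenceWeights:
    """Count, per row, the rows sharing > threshold fraction of positions.

    Identity is computed over all joint columns; a gap aligned to a gap
    counts as identical.  ``m_a`` includes the row itself, so it is always
    at least 1 and equals M when all rows coincide.
    """
    codes = msa.codes if isinstance(msa, JointMSA) else np.asarray(msa)
    m, length = codes.shape
    if m == 0:
        raise ValueError("empty alignment")
    cutoff = threshold * length
    m_a = np.zeros(m, dtype=np.int64)
    block = max(1, int(2e7 // (m * length)) or 1)
    for lo in range(0, m, block):
        hi = min(m, lo + block)
        ident = (codes[lo:hi, None, :] == codes[None, :, :]).sum(axis=2)
        m_a[lo:hi] = (ident > cutoff).sum(axis=1)
    return SequenceWeights(m_a=m_a, identity_threshold=threshold)


def single_counts(
    msa: JointMSA | np.ndarray,
    weights: SequenceWeights,
    pseudocount: float,
    q: int = 21,
) -> np.ndarray:
    """Reweighted single-column frequencies f_i(A), shape (L, q)."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    codes = msa.codes if isinstance(msa, JointMSA) else np.asarray(msa)
    m, length = codes.shape
    w = weights.weights
    counts = np.zeros((length, q))
    for a in range(q):
        counts[:, a] = ((codes == a) * w[:, None]).sum(axis=0)
    return (pseudocount / q + counts) / (pseudocount + weights.m_eff)


def pair_counts(
    msa: JointMSA | np.ndarray,
    weights: SequenceWeights,
    pseudocount: float,
    q: int = 21,
) -> np.ndarray:
    """Reweighted pair frequencies f_ij(A,B), shape (L, L, q, q).

    Computed as a single weighted one-hot cross-product; the diagonal
    i == j is overwritten with ``f_i(A) delta(A,B)``.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    codes = msa.codes if isinstance(msa, JointMSA) else np.asarray(msa)
    m, length = codes.shape
    one_hot = _one_hot(codes, q)
    weighted = one_hot * weights.weights[:, None]
    cross = one_hot.T @ weighted  # (L q, L q)
    f_ij = (
        cross.reshape(length, q, length, q).transpose(0, 2, 1, 3)
        + pseudocount / q**2
    ) / (pseudocount + weights.m_eff)
    f_i = single_counts(codes, weights, pseudocount, q)
    for i in range(length):
        f_ij[i, i] = np.diag(f_i[i])
    return f_ij


def compute_counts(
    msa: JointMSA | np.ndarray,
    threshold: float = 0.80,
    pseudocount: float | None = None,
    q: int = 21,
    weights: SequenceWeights | None = None,
) -> FrequencyCounts:
    """Full frequency pipeline: weights, then f_i and f_ij.

    ``pseudocount=None`` uses lambda = M_eff (equal total weight to the
    data and the uniform prior), the convention adopted throughout this
    package.
    """
    codes = msa.codes if isinstance(msa, JointMSA) else np.asarray(msa)
    boundary = msa.boundary if isinstance(msa, JointMSA) else None
    if weights is None:
        weights = compute_weights(codes, threshold)
    lam = weights.m_eff if pseudocount is None else pseudocount
    return FrequencyCounts(
        f_i=single_counts(codes, weights, lam, q),
        f_ij=pair_counts(codes, weights, lam, q),
        pseudocount=lam,
        m_eff=weights.m_eff,
        q=q,
        boundary=boundary,
        weights=weights,
    )


def mutual_information(counts: FrequencyCounts) -> np.ndarray:
    """Column-pair mutual information (nats), shape (L, L), zero diagonal.

    MI_ij = sum_{A,B} f_ij(A,B) ln[f_ij(A,B) / (f_i(A) f_j(B))]; with a
    positive pseudocount every term is finite.  Zero-probability cells (only
    possible at pseudocount 0) contribute zero.
    """
    f_i, f_ij = counts.f_i, counts.f_ij
    prod = f_i[:, None, :, None] * f_i[None, :, None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = f_ij * np.log(np.where(f_ij > 0, f_ij / prod, 1.0))
    mi = terms.sum(axis=(2, 3))
    np.fill_diagonal(mi, 0.0)
    return 0.5 * (mi + mi.T)
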