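"""Physical interpretation of averaged coupling matrices.

The averaged top-coupling matrix is projected onto simple physico-chemical
interaction modes.  Each mode is a per-amino-acid feature vector xi and a
sign prefactor: -1 for electrostatics (opposite charges attract, so a
*negative* product xi(A) xi(B) marks an attractive combination) and +1 for
hydrophilic/hydrophobic (like attracts like).  The overlap

    q = prefactor * sum_{A,B} E(A,B) xi(A) xi(B)

is compared against a null obtained by randomly permuting the 20
amino-acid labels of xi (the gap never participates), yielding an
empirical p-value (add-one smoothed) and a Gaussian tail p-value from the
null's Z-score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .alphabet import AMINO_ACIDS, DEFAULT_ALPHABET

POSITIVE = "HKR"
NEGATIVE = "DE"
HYDROPHILIC = "DEHKNQRST"  # roughly the Wimley–White interface scale
HYDROPHOBIC = "ACFILMVWY"


@dataclass(frozen=True)
class FeatureVector:
    """Per-amino-acid mode values (gap entry fixed at 0) plus sign."""

    mode: str
    xi: np.ndarray  # length q; last entry (gap) = 0
    prefactor: int  # +1 or -1

    def __post_init__(self) -> None:
        if self.prefactor not in (+1, -1):
            raise ValueError("prefactor must be +1 or -1")
        if self.xi[-1] != 0:
            raise ValueError("gap feature value must be 0")


def _vector(assign: dict[str, float]) -> np.ndarray:
    xi = np.zeros(DEFAULT_ALPHABET.q)
    for aa, v in assign.items():
        xi[DEFAULT_ALPHABET.index_of[aa]] = v
    return xi


def feature_vector(mode: str, custom_xi: np.ndarray | None = None) -> FeatureVector:
    """Build one of the standard interaction-mode vectors (or a custom one)."""
    if mode == "electrostatic":
        xi = _vector({**{a: 1.0 for a in POSITIVE}, **{a: -1.0 for a in NEGATIVE}})
        return FeatureVector(mode, xi, -1)
    if mode == "hydrophilic":
        return FeatureVector(mode, _vector({a: 1.0 for a in HYDROPHILIC}), +1)
    if mode == "hydrophobic":
        return FeatureVector(mode, _vector({a: 1.0 for a in HYDROPHOBIC}), +1)
    if mode == "custom":
        if custom_xi is None:
            raise ValueError("custom mode needs custom_xi")
        xi = np.asarray(custom_xi, dtype=float)
        if len(xi) == len(AMINO_ACIDS):
            xi = np.concatenate([xi, [0.0]])
        return FeatureVector(mode, xi, +1)
    raise ValueError(f"unknown mode {mode!r}")


@dataclass
class OverlapResult:
    mode: str
    overlap_q: float
    null_mean: float
    null_sd: float
    z_score: float
    p_empirical: float
    p_gaussian: float
    n_permutations: int
    seed: int | None


def gaussian_tail(z: float) -> float:
    """Upper-tail standard-normal probability P(Z >= z)."""
    return float(norm.sf(z))


def overlap(avg_matrix: np.ndarray, fv: FeatureVector) -> float:
    """Signed projection of the averaged coupling matrix onto a mode."""
    return float(fv.prefactor * fv.xi @ avg_matrix[: len(fv.xi), : len(fv.xi)] @ fv.xi)


def permutation_test(
    avg_matrix: np.ndarray,
    fv: FeatureVector,
    n_perm: int = 1_000_000,
    seed: int | None = None,
) -> OverlapResult:
    """Amino-acid-label permutation null for the overlap statistic.

    Each permutation relabels the 20 amino acids of xi uniformly at random
    (gap fixed) and recomputes the overlap.  The empirical p-value is
    add-one smoothed, ``(1 + #{q_rand >= q_obs}) / (1 + n_perm)``; the
    Gaussian p-value is the standard-normal upper tail at the Z-score.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    q_obs = overlap(avg_matrix, fv)
    n_aa = len(AMINO_ACIDS)
    e20 = avg_matrix[:n_aa, :n_aa]
    xi20 = fv.xi[:n_aa]
    # batch the permutations; each null draw is xi[perm]^T E xi[perm]
    null = np.empty(n_perm)
    batch = 20_000
    for lo in range(0, n_perm, batch):
        hi = min(n_perm, lo + batch)
        perms = np.argsort(rng.random((hi - lo, n_aa)), axis=1)
        v = xi20[perms]  # (b, 20)
        null[lo:hi] = fv.prefactor * np.einsum("bi,ij,bj->b", v, e20, v)
    sd = float(null.std(ddof=0))
    if sd == 0:
        raise ValueError("degenerate permutation null (sd = 0)")
    mean = float(null.mean())
    z = (q_obs - mean) / sd
    return OverlapResult(
        mode=fv.mode,
        overlap_q=q_obs,
        null_mean=mean,
        null_sd=sd,
        z_score=z,
        p_empirical=float((1 + np.sum(null >= q_obs)) / (1 + n_perm)),
        p_gaussian=float(norm.sf(z)),
        n_permutations=n_perm,
        seed=seed,
    )


def extreme_pairings(
    matrices: list[tuple[tuple[int, int], np.ndarray]],
    hi: float = 1.0,
    lo: float = -0.6,
) -> list[tuple[str, str, float, tuple[int, int]]]:
    """List favorable / unfavorable residue combinations.

    Scans the supplied (position-pair, coupling-matrix) list — typically
    the top-10 strongest inter-protein couplings in zero-sum gauge — for
    entries above ``hi`` (favorable) or below ``lo`` (unfavorable).
    Returns (SK residue, RR residue, value, source pair) sorted by value,
    descending.  Gap rows/columns are skipped.
    """
    n_aa = len(AMINO_ACIDS)
    out = []
    for pair, mat in matrices:
        core = mat[:n_aa, :n_aa]
        rows, cols = np.where((core > hi) | (core < lo))
        for a, b in zip(rows, cols):
            out.append(
                (AMINO_ACIDS[a], AMINO_ACIDS[b], float(core[a, b]), pair)
            )
    out.sort(key=lambda t: (-t[2], t[0], t[1]))
    return out
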