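"""Corpus-level applications of the interaction score.

Given an all-vs-all score matrix with cognate labels: compare cognate and
non-cognate score distributions, count potential crosstalk partners above
score thresholds, group two-component systems of one genome by
hierarchical clustering of mutual scores, and rank candidate partners for
orphan kinases and regulators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from sklearn.metrics import roc_curve, auc as _auc

from .scoring import ScoreMatrix


def score_histograms(
    matrix: ScoreMatrix, bins: int | np.ndarray = 50
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cognate and non-cognate score histograms over shared bins.

    Only intra-genome pairings enter (genome labels permitting).  Returns
    (bin_edges, cognate_counts, noncognate_counts).
    """
    intra = matrix.intra_genome_mask()
    valid = intra & np.isfinite(matrix.scores)
    cog = matrix.scores[valid & matrix.cognate_mask]
    non = matrix.scores[valid & ~matrix.cognate_mask]
    all_scores = np.concatenate([cog, non])
    edges = np.histogram_bin_edges(all_scores, bins=bins)
    c_counts, _ = np.histogram(cog, bins=edges)
    n_counts, _ = np.histogram(non, bins=edges)
    return edges, c_counts, n_counts


@dataclass
class CrosstalkReport:
    thresholds: list[float]
    cognate_above: list[int]
    noncognate_above: list[int]
    sk_fraction_with_crosstalk: list[float]
    candidates: list[tuple[str, str, str, float]]  # (genome, sk, rr, score)


def crosstalk_report(
    matrix: ScoreMatrix,
    thresholds: tuple[float, ...] = (20.0, 30.0, 60.0),
    top_n_candidates: int = 50,
) -> CrosstalkReport:
    """Count intra-genome pairs scoring above each threshold.

    The SK fraction is, per threshold, the fraction of SKs with at least
    one *non-cognate* intra-genome partner above it.  The candidate list
    collects the highest-scoring non-cognate pairs.
    """
    thresholds = sorted(thresholds)
    intra = matrix.intra_genome_mask()
    valid = intra & np.isfinite(matrix.scores)
    cog = matrix.scores[valid & matrix.cognate_mask]
    non_mask = valid & ~matrix.cognate_mask
    non = matrix.scores[non_mask]
    cog_counts = [int((cog > t).sum()) for t in thresholds]
    non_counts = [int((non > t).sum()) for t in thresholds]
    n_sk = matrix.scores.shape[0]
    fractions = [
        float(((np.where(non_mask, matrix.scores, -np.inf) > t).any(axis=1)).sum() / n_sk)
        if n_sk
        else 0.0
        for t in thresholds
    ]
    sk_g = matrix.sk_genomes or [""] * n_sk
    cand_idx = np.argwhere(non_mask)
    cand = sorted(
        (
            (
                sk_g[a],
                matrix.sk_ids[a],
                matrix.rr_ids[b],
                float(matrix.scores[a, b]),
            )
            for a, b in cand_idx
        ),
        key=lambda t: -t[3],
    )[:top_n_candidates]
    return CrosstalkReport(
        thresholds=list(thresholds),
        cognate_above=cog_counts,
        noncognate_above=non_counts,
        sk_fraction_with_crosstalk=fractions,
        candidates=cand,
    )


def cluster_tcs(
    matrix: ScoreMatrix,
    linkage: str = "average",
    dissimilarity: str = "max-score",
) -> tuple[np.ndarray, list[int], str]:
    """Hierarchically cluster the cognate systems of one genome.

    The score matrix must be square and system-aligned: row k and column k
    are the SK and RR of cognate system k.  Dissimilarity between systems
    a and b (``max-score`` default):

        D(a, b) = S_max - max( S(SK_a, RR_b), S(SK_b, RR_a) )

    with S_max the matrix maximum, so mutually high-scoring (potentially
    cross-talking) systems are close.  ``score-diff`` instead uses the
    cognate-vs-crossed score gap
    ``0.5 * [S(a,a) - S(a,b) + S(b,b) - S(b,a)]`` clipped at 0.

    Returns (scipy linkage matrix, leaf order, Newick string).
    """
    s = matrix.scores
    if s.shape[0] != s.shape[1] or s.shape[0] < 2:
        raise ValueError("need a square system-by-system matrix with >= 2 systems")
    n = s.shape[0]
    if dissimilarity == "max-score":
        cross = np.maximum(s, s.T)
        d = s.max() - cross
    elif dissimilarity == "score-diff":
        diag = np.diag(s)
        d = 0.5 * (diag[:, None] - s + diag[None, :] - s.T)
        d = np.clip(d, 0.0, None)
    else:
        raise ValueError(f"unknown dissimilarity {dissimilarity!r}")
    d = 0.5 * (d + d.T)
    np.fill_diagonal(d, 0.0)
    from scipy.spatial.distance import squareform

    z = hierarchy.linkage(squareform(d, checks=False), method=linkage)
    order = list(hierarchy.leaves_list(z))
    labels = [f"{matrix.sk_ids[k]}/{matrix.rr_ids[k]}" for k in range(n)]
    newick = _linkage_to_newick(z, labels)
    return z, order, newick


def _linkage_to_newick(z: np.ndarray, labels: list[str]) -> str:
    tree = hierarchy.to_tree(z)

    def walk(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        left, right = walk(node.left), walk(node.right)
        dl = node.dist - node.left.dist
        dr = node.dist - node.right.dist
        return f"({left}:{dl:.6g},{right}:{dr:.6g})"

    return walk(tree) + ";"


@dataclass
class OrphanRanking:
    """Per orphan SK, the top-scoring orphan RR candidates."""

    rankings: dict[str, list[tuple[str, float]]]
    full_matrix: ScoreMatrix


def rank_orphans(
    matrix: ScoreMatrix, top_n: int = 5
) -> OrphanRanking:
    """Rank orphan RRs for each orphan SK by descending score.

    Ties are broken by RR id; lists are truncated to ``top_n`` entries.
    """
    rankings: dict[str, list[tuple[str, float]]] = {}
    for a, sk in enumerate(matrix.sk_ids):
        row = [
            (rr, float(matrix.scores[a, b]))
            for b, rr in enumerate(matrix.rr_ids)
            if np.isfinite(matrix.scores[a, b])
        ]
        row.sort(key=lambda t: (-t[1], t[0]))
        rankings[sk] = row[:top_n]
    return OrphanRanking(rankings, matrix)


def roc(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC curve and trapezoidal AUC for score-based discrimination.

    ``labels`` are 1 for true (cognate / interacting) pairs and 0
    otherwise; equal scores are grouped by the threshold sweep.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC needs both positive and negative labels")
    fpr, tpr, _ = roc_curve(labels, np.asarray(scores))
    return fpr, tpr, float(_auc(fpr, tpr))
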