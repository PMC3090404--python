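"""Global Potts-model inference on a joint SK/RR alignment.

The model assigns each joint sequence ``(A_1..A_L)`` the probability

    P(A) = exp( sum_{i<j} e_ij(A_i, A_j) + sum_i h_i(A_i) ) / Z

with pairwise couplings ``e_ij`` and single-site fields ``h_i`` chosen so
the model's two-site marginals reproduce the reweighted empirical pair
frequencies.  Inference runs on a subset of the most correlated columns
(selected by inter-protein mutual information) and is pluggable:

``plm``
    Symmetric pseudo-likelihood maximization with L2 regularization
    (default; accurate and robust for realistic sample sizes).
``mf``
    Naive mean-field: couplings from the inverse connected-correlation
    matrix (fast; used for large scans).
``exact``
    Gradient fitting of the fully enumerated distribution; only feasible
    for tiny systems (q^n states) and used as a test oracle backend.

From the couplings, the *direct pair distribution* of a column pair is the
two-site model ``P^dir_ij(A,B) ∝ exp(e_ij(A,B) + h~_i(A) + h~_j(B))`` with
compensating fields fitted (iterative proportional fitting) so that both
its marginals equal the empirical single-column frequencies.  Its mutual
information — the direct information — is the gauge-invariant coupling
strength used for ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

from .frequencies import FrequencyCounts, compute_counts, mutual_information
from .msa_io import JointMSA

GAUGE_ZERO_SUM = "zero-sum"


# ---------------------------------------------------------------------------
# gauge


def zero_sum_gauge(
    e: np.ndarray, h: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Shift (e, h) into the zero-sum gauge without changing the model.

    In the zero-sum gauge every coupling matrix has zero row and column
    sums and every field sums to zero, which makes the sign of an entry
    directly interpretable as favorable (+) or unfavorable (−).

    Parameters: ``e`` of shape (n, n, q, q) with ``e[i, j] = e[j, i].T``,
    ``h`` of shape (n, q).
    """
    n, q = h.shape
    row = e.mean(axis=3, keepdims=True)  # mean over B
    col = e.mean(axis=2, keepdims=True)  # mean over A
    tot = e.mean(axis=(2, 3), keepdims=True)
    e_zs = e - row - col + tot
    h_zs = h.copy()
    # absorb removed parts into the fields: for pair (i,j), site i gains
    # mean_B e_ij(A, .) - mean_AB e_ij
    gain = (row - tot).squeeze(axis=3).sum(axis=1)  # (n, q)
    idx = np.arange(n)
    gain -= (row - tot)[idx, idx].squeeze(axis=2)  # drop self term
    h_zs += gain
    h_zs -= h_zs.mean(axis=1, keepdims=True)
    return e_zs, h_zs


def random_gauge_shift(
    e: np.ndarray, h: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Apply a random model-preserving reparameterization (for tests)."""
    n, q = h.shape
    e2, h2 = e.copy(), h.copy()
    for i in range(n):
        for j in range(i + 1, n):
            a = rng.normal(size=q)  # absorbed into h_i
            b = rng.normal(size=q)  # absorbed into h_j
            e2[i, j] += a[:, None] + b[None, :]
            e2[j, i] = e2[i, j].T
            h2[i] -= a
            h2[j] -= b
    return e2, h2


# ---------------------------------------------------------------------------
# column selection


def select_columns(
    mi: np.ndarray, boundary: int, n_max: int = 70
) -> np.ndarray:
    """Pick the columns involved in the strongest inter-protein MI pairs.

    Pairs (i, j) with i < boundary <= j are visited in decreasing MI order
    (ties broken lexicographically); both members join the set until it
    would exceed ``n_max`` columns.  Returns the sorted column indices.
    """
    if n_max < 2:
        raise ValueError("n_max must be at least 2")
    length = mi.shape[0]
    ii, jj = np.meshgrid(
        np.arange(boundary), np.arange(boundary, length), indexing="ij"
    )
    ii, jj = ii.ravel(), jj.ravel()
    vals = mi[ii, jj]
    order = np.lexsort((jj, ii, -vals))
    chosen: list[int] = []
    in_set = set()
    for k in order:
        i, j = int(ii[k]), int(jj[k])
        new = [c for c in (i, j) if c not in in_set]
        if len(in_set) + len(new) > n_max:
            continue
        for c in new:
            in_set.add(c)
            chosen.append(c)
        if len(in_set) >= n_max:
            break
    return np.array(sorted(in_set), dtype=int)


# ---------------------------------------------------------------------------
# model container


@dataclass
class CouplingModel:
    """Fitted couplings and fields on a column subset of the joint MSA."""

    columns: np.ndarray  # indices into the joint MSA
    e: np.ndarray  # (n, n, q, q), e[i,j] = e[j,i].T, zero diagonal
    h: np.ndarray  # (n, q)
    f_i: np.ndarray  # (n, q) empirical single frequencies on columns
    boundary: int  # joint-MSA boundary (first RR column)
    gauge: str = GAUGE_ZERO_SUM
    q: int = 21
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    @property
    def sk_mask(self) -> np.ndarray:
        return self.columns < self.boundary

    def inter_pairs(self) -> list[tuple[int, int]]:
        """Local index pairs (i, j) with column i in SK and j in RR."""
        sk = np.where(self.sk_mask)[0]
        rr = np.where(~self.sk_mask)[0]
        return [(int(i), int(j)) for i in sk for j in rr]

    def save(self, path) -> None:
        np.savez(
            path,
            schema_version=1,
            columns=self.columns,
            e=self.e,
            h=self.h,
            f_i=self.f_i,
            boundary=self.boundary,
            gauge=self.gauge,
            q=self.q,
        )

    @classmethod
    def load(cls, path) -> "CouplingModel":
        z = np.load(path, allow_pickle=False)
        return cls(
            columns=z["columns"],
            e=z["e"],
            h=z["h"],
            f_i=z["f_i"],
            boundary=int(z["boundary"]),
            gauge=str(z["gauge"]),
            q=int(z["q"]),
        )


# ---------------------------------------------------------------------------
# inference backends


def _fit_plm(
    codes: np.ndarray,
    w: np.ndarray,
    q: int,
    reg_coupling: float = 0.01,
    reg_field: float = 0.01,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Symmetric pseudo-likelihood maximization via L-BFGS.

    Minimizes the weighted negative log-pseudo-likelihood (mean of the per
    site conditional likelihoods) plus L2 penalties on couplings and
    fields.  One-hot algebra keeps the per-iteration cost at two dense
    matrix products.
    """
    from scipy.optimize import minimize

    m, n = codes.shape
    nq = n * q
    one_hot = np.zeros((m, nq))
    one_hot[np.arange(m)[:, None], np.arange(n) * q + codes] = 1.0
    w = w / w.sum()
    iu = np.triu_indices(n, k=1)
    n_pairs = len(iu[0])

    def unpack(x):
        h = x[: n * q].reshape(n, q)
        jt = x[n * q :].reshape(n_pairs, q, q)
        jmat = np.zeros((n, n, q, q))
        jmat[iu] = jt
        jmat = jmat + jmat.transpose(1, 0, 3, 2)
        return h, jmat

    def objective(x):
        h, jmat = unpack(x)
        jfull = jmat.transpose(0, 2, 1, 3).reshape(nq, nq)
        logits = one_hot @ jfull + h.reshape(-1)[None, :]
        lse = logsumexp(logits.reshape(m, n, q), axis=2)
        picked = (logits * one_hot).reshape(m, n, q).sum(axis=2)
        nll = -(w * (picked - lse).sum(axis=1)).sum()
        probs = np.exp(logits.reshape(m, n, q) - lse[:, :, None]).reshape(m, nq)
        resid = (probs - one_hot) * w[:, None]
        grad_full = one_hot.T @ resid
        grad_full = grad_full + grad_full.T
        grad_j4 = grad_full.reshape(n, q, n, q).transpose(0, 2, 1, 3)
        grad_h = resid.reshape(m, n, q).sum(axis=0)
        nll += reg_field * (h**2).sum() + reg_coupling * (jmat[iu] ** 2).sum()
        grad_h += 2 * reg_field * h
        grad_j = grad_j4[iu] + 2 * reg_coupling * jmat[iu]
        return nll, np.concatenate([grad_h.ravel(), grad_j.ravel()])

    x0 = np.zeros(n * q + n_pairs * q * q)
    res = minimize(
        objective,
        x0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": tol},
    )
    h, jmat = unpack(res.x)
    grad_norm = float(np.max(np.abs(res.jac)))
    # hitting the iteration cap with a small residual gradient still counts
    converged = bool(res.success) or grad_norm < 1e-2
    diag = {
        "iterations": int(res.nit),
        "converged": converged,
        "objective": float(res.fun),
        "grad_norm": grad_norm,
    }
    return jmat, h, diag


def _fit_mf(
    counts_f_i: np.ndarray,
    counts_f_ij: np.ndarray,
    q: int,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Naive mean-field: e = -C^{-1} on the (q-1)-state reduced alphabet.

    The connected correlation matrix C is built excluding the last state
    (the gap) as reference; the resulting couplings carry the last-state
    gauge and are re-gauged by the caller.  Fields follow the mean-field
    self-consistency relation.
    """
    n = counts_f_i.shape[0]
    r = q - 1
    c = np.empty((n * r, n * r))
    for i in range(n):
        for j in range(n):
            block = counts_f_ij[i, j, :r, :r] - np.outer(
                counts_f_i[i, :r], counts_f_i[j, :r]
            )
            c[i * r : (i + 1) * r, j * r : (j + 1) * r] = block
    e_red = -np.linalg.inv(c)
    e = np.zeros((n, n, q, q))
    for i in range(n):
        for j in range(n):
            if i != j:
                e[i, j, :r, :r] = e_red[i * r : (i + 1) * r, j * r : (j + 1) * r]
    e = 0.5 * (e + e.transpose(1, 0, 3, 2))
    for i in range(n):
        e[i, i] = 0.0
    with np.errstate(divide="ignore"):
        h = np.log(counts_f_i / counts_f_i[:, -1][:, None])
    h -= np.einsum("ijab,jb->ia", e, counts_f_i)
    return e, h, {"converged": True, "iterations": 0}


def _enumerate_states(n: int, q: int) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(q)] * n, indexing="ij")
    return np.stack([g.ravel() for g in grids], axis=1)


def model_pair_marginals(
    e: np.ndarray, h: np.ndarray, q: int
) -> tuple[np.ndarray, np.ndarray]:
    """Exact single and pair marginals of the Potts model by enumeration.

    Only feasible for q**n up to a few hundred thousand states; intended
    for test oracles and the ``exact`` backend.
    """
    n = h.shape[0]
    states = _enumerate_states(n, q)
    logp = h[np.arange(n), states].sum(axis=1)
    for i in range(n):
        for j in range(i + 1, n):
            logp += e[i, j][states[:, i], states[:, j]]
    logp -= logsumexp(logp)
    p = np.exp(logp)
    f1 = np.zeros((n, q))
    np.add.at(f1.reshape(-1), (np.arange(n) * q + states).ravel(), np.repeat(p, n))
    f2 = np.zeros((n, n, q, q))
    for i in range(n):
        for j in range(n):
            np.add.at(f2[i, j], (states[:, i], states[:, j]), p)
    return f1, f2


def _fit_exact(
    counts_f_i: np.ndarray,
    counts_f_ij: np.ndarray,
    q: int,
    tol: float = 1e-10,
    max_iter: int = 2000,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Maximum-likelihood fit on the fully enumerated state space.

    Minimizes the convex dual log Z − <params, empirical moments> with
    L-BFGS; at the optimum the model marginals equal the empirical ones.
    """
    from scipy.optimize import minimize

    n = counts_f_i.shape[0]
    if q**n > 500_000:
        raise ValueError("exact backend infeasible: state space too large")
    states = _enumerate_states(n, q)
    iu = np.triu_indices(n, k=1)
    n_pairs = len(iu[0])
    target_h = counts_f_i
    target_e = np.stack([counts_f_ij[i, j] for i, j in zip(*iu)])

    def unpack(x):
        h = x[: n * q].reshape(n, q)
        et = x[n * q :].reshape(n_pairs, q, q)
        return h, et

    def objective(x):
        h, et = unpack(x)
        logp = h[np.arange(n), states].sum(axis=1)
        for k, (i, j) in enumerate(zip(*iu)):
            logp += et[k][states[:, i], states[:, j]]
        logz = logsumexp(logp)
        p = np.exp(logp - logz)
        f1 = np.zeros((n, q))
        for i in range(n):
            np.add.at(f1[i], states[:, i], p)
        grad_h = f1 - target_h
        grad_e = np.zeros_like(et)
        for k, (i, j) in enumerate(zip(*iu)):
            np.add.at(grad_e[k], (states[:, i], states[:, j]), p)
        grad_e -= target_e
        obj = logz - (h * target_h).sum() - (et * target_e).sum()
        return obj, np.concatenate([grad_h.ravel(), grad_e.ravel()])

    x0 = np.zeros(n * q + n_pairs * q * q)
    res = minimize(
        objective,
        x0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "gtol": tol, "ftol": 0},
    )
    h, et = unpack(res.x)
    e = np.zeros((n, n, q, q))
    e[iu] = et
    e = e + e.transpose(1, 0, 3, 2)
    resid = float(np.max(np.abs(res.jac)))
    diag = {
        "converged": resid < 100 * tol or bool(res.success),
        "iterations": int(res.nit),
        "max_marginal_residual": resid,
    }
    return e, h, diag


# ---------------------------------------------------------------------------
# direct pair distributions


def direct_pair_distribution(
    e_ij: np.ndarray,
    f_i: np.ndarray,
    f_j: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Two-site distribution with coupling e_ij and empirical marginals.

    Iterative proportional fitting finds compensating fields (row/column
    scalings of exp(e_ij)) such that the distribution's marginals equal
    f_i and f_j.  Returns (P_dir, h_i_hat, h_j_hat, residual).
    """
    if np.any(f_i <= 0) or np.any(f_j <= 0):
        raise ValueError("marginals must be strictly positive")
    w = np.exp(e_ij - e_ij.max())
    r = np.ones(len(f_i))
    s = np.ones(len(f_j))
    resid = np.inf
    for _ in range(max_iter):
        p = r[:, None] * w * s[None, :]
        r *= f_i / p.sum(axis=1)
        p = r[:, None] * w * s[None, :]
        s *= f_j / p.sum(axis=0)
        p = r[:, None] * w * s[None, :]
        resid = max(
            np.abs(p.sum(axis=1) - f_i).max(), np.abs(p.sum(axis=0) - f_j).max()
        )
        if resid < tol:
            break
    else:
        raise RuntimeError(
            f"IPF did not converge in {max_iter} sweeps (residual {resid:.2e})"
        )
    return p, np.log(r), np.log(s), resid


def direct_information(p_dir: np.ndarray) -> float:
    """Mutual information of a direct pair distribution (nats)."""
    fi = p_dir.sum(axis=1)
    fj = p_dir.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = p_dir * np.log(np.where(p_dir > 0, p_dir / np.outer(fi, fj), 1.0))
    return float(t.sum())


def rank_direct_couplings(
    model: CouplingModel,
    strength: str = "di",
) -> list[tuple[int, int, float]]:
    """Rank inter-protein column pairs by coupling strength.

    ``strength='di'`` uses direct information (gauge-invariant, default);
    ``'frobenius'`` uses the Frobenius norm of the zero-sum-gauged
    coupling matrix.  Returns (sk_column, rr_column, strength) in joint-MSA
    coordinates, descending, ties broken by (i, j).
    """
    out = []
    for i, j in model.inter_pairs():
        if strength == "di":
            p, _, _, _ = direct_pair_distribution(
                model.e[i, j], model.f_i[i], model.f_i[j]
            )
            s = direct_information(p)
        elif strength == "frobenius":
            block = model.e[i, j]
            block = block - block.mean(0) - block.mean(1)[:, None] + block.mean()
            s = float(np.linalg.norm(block))
        else:
            raise ValueError(f"unknown strength measure {strength!r}")
        out.append((int(model.columns[i]), int(model.columns[j]), s))
    out.sort(key=lambda t: (-t[2], t[0], t[1]))
    return out


def average_coupling_matrix(
    model: CouplingModel, top_k: int = 10, strength: str = "di"
) -> np.ndarray:
    """Entrywise mean of e_ij over the top_k strongest inter-protein pairs.

    Rows index the SK-side amino acid, columns the RR-side one, in the
    model's gauge (zero-sum by default, so signs read as favorable /
    unfavorable).
    """
    ranked = rank_direct_couplings(model, strength=strength)
    if len(ranked) < top_k:
        raise ValueError(f"only {len(ranked)} inter-protein pairs; need {top_k}")
    col_index = {int(c): k for k, c in enumerate(model.columns)}
    mats = [
        model.e[col_index[i], col_index[j]] for i, j, _ in ranked[:top_k]
    ]
    return np.mean(mats, axis=0)


# ---------------------------------------------------------------------------
# estimator


class DirectCouplingAnalysis(BaseEstimator):
    """Direct-coupling analysis of a joint two-domain alignment.

    Fits the pairwise maximum-entropy model on the most-correlated column
    subset of a joint MSA of interacting sequence pairs and exposes the
    couplings, direct pair distributions and derived rankings.

    Parameters
    ----------
    n_columns : int
        Maximum number of joint-MSA columns entering the model (the most
        correlated inter-protein pairs drive the selection).
    identity_threshold : float
        Reweighting threshold; rows with more than this fraction of
        identical positions share statistical weight.
    pseudocount : float or None
        Frequency regularizer lambda; ``None`` uses lambda = M_eff.
    method : {"plm", "mf", "exact"}
        Inference backend.
    reg_coupling, reg_field : float
        L2 regularization strengths (``plm`` only).
    max_iter : int
        Optimizer iteration cap.

    Attributes (after :meth:`fit`)
    ------------------------------
    columns_ : selected joint-MSA column indices
    e_ : couplings (n, n, q, q) in zero-sum gauge
    h_ : fields (n, q) in zero-sum gauge
    counts_ : :class:`FrequencyCounts` on the full alignment
    model_ : :class:`CouplingModel`
    m_eff_ : effective sequence count
    """

    def __init__(
        self,
        n_columns: int = 70,
        identity_threshold: float = 0.80,
        pseudocount: float | None = None,
        method: str = "plm",
        reg_coupling: float = 0.01,
        reg_field: float = 0.01,
        max_iter: int = 200,
        tol: float = 1e-8,
    ):
        self.n_columns = n_columns
        self.identity_threshold = identity_threshold
        self.pseudocount = pseudocount
        self.method = method
        self.reg_coupling = reg_coupling
        self.reg_field = reg_field
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X: JointMSA, y=None, counts: FrequencyCounts | None = None):
        """Fit the coupling model to a joint MSA of cognate pairs."""
        if not isinstance(X, JointMSA):
            raise TypeError("X must be a JointMSA")
        if X.n_seqs == 0:
            raise ValueError("cannot fit on an empty alignment")
        q = X.alphabet.q
        if counts is None:
            counts = compute_counts(
                X,
                threshold=self.identity_threshold,
                pseudocount=self.pseudocount,
                q=q,
            )
        self.counts_ = counts
        self.mi_ = mutual_information(counts)
        self.columns_ = select_columns(self.mi_, X.boundary, self.n_columns)
        cols = self.columns_
        f_i = counts.f_i[cols]
        f_ij = counts.f_ij[np.ix_(cols, cols)]
        if self.method == "plm":
            sub = X.codes[:, cols].astype(np.int64)
            w = counts.weights.weights if counts.weights is not None else np.ones(X.n_seqs)
            e, h, diag = _fit_plm(
                sub,
                w,
                q,
                reg_coupling=self.reg_coupling,
                reg_field=self.reg_field,
                max_iter=self.max_iter,
            )
        elif self.method == "mf":
            e, h, diag = _fit_mf(f_i, f_ij, q)
        elif self.method == "exact":
            e, h, diag = _fit_exact(f_i, f_ij, q, tol=self.tol, max_iter=self.max_iter)
        else:
            raise ValueError(f"unknown method {self.method!r}")
        e, h = zero_sum_gauge(e, h)
        self.e_, self.h_ = e, h
        self.m_eff_ = counts.m_eff
        self.diagnostics_ = diag
        self.model_ = CouplingModel(
            columns=cols,
            e=e,
            h=h,
            f_i=f_i,
            boundary=X.boundary,
            gauge=GAUGE_ZERO_SUM,
            q=q,
            diagnostics=diag,
        )
        return self

    def rank_couplings(self, strength: str = "di"):
        self._check_fitted()
        return rank_direct_couplings(self.model_, strength=strength)

    def average_coupling_matrix(self, top_k: int = 10):
        self._check_fitted()
        return average_coupling_matrix(self.model_, top_k=top_k)

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted")


def fit_model(
    counts: FrequencyCounts,
    columns: np.ndarray,
    method: str = "plm",
    tol: float = 1e-8,
    codes: np.ndarray | None = None,
    boundary: int | None = None,
    **kwargs,
) -> CouplingModel:
    """Functional fitting interface over precomputed counts.

    ``codes`` (the raw column-restricted alignment) is required for the
    ``plm`` backend; count-based backends (``mf``, ``exact``) ignore it.
    """
    q = counts.q
    cols = np.asarray(columns, dtype=int)
    f_i = counts.f_i[cols]
    f_ij = counts.f_ij[np.ix_(cols, cols)]
    if method == "plm":
        if codes is None:
            raise ValueError("plm backend needs the encoded alignment")
        w = counts.weights.weights if counts.weights is not None else np.ones(codes.shape[0])
        e, h, diag = _fit_plm(codes[:, cols].astype(np.int64), w, q, **kwargs)
    elif method == "mf":
        e, h, diag = _fit_mf(f_i, f_ij, q)
    elif method == "exact":
        e, h, diag = _fit_exact(f_i, f_ij, q, tol=tol, **kwargs)
    else:
        raise ValueError(f"unknown method {method!r}")
    if not diag.get("converged", True):
        raise RuntimeError(f"fit did not converge: {diag}")
    e, h = zero_sum_gauge(e, h)
    return CouplingModel(
        columns=cols,
        e=e,
        h=h,
        f_i=f_i,
        boundary=int(boundary if boundary is not None else counts.boundary),
        gauge=GAUGE_ZERO_SUM,
        q=q,
        diagnostics=diag,
    )
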