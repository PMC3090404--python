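"""Synthetic data with the statistical structure the method assumes.

Everything the pipeline consumes can be generated here: a *planted*
pairwise model over a joint SK+RR alignment with a known set of coupled
inter-protein column pairs (ground truth for recovery experiments),
Gibbs-sampled sequence pairs grouped into pseudo-genomes, within-genome
shuffles providing labeled non-interacting pairs, near-duplicate rows
emulating phylogenetic redundancy, toy gene/domain tables exercising the
operon extraction rules, and two-model mutation-scan fixtures.

The default planted model is deliberately smaller than the real SK/RR
domains (20+25 columns instead of 87+117) so that end-to-end fits run in
seconds to minutes; couplings follow a charge-complementarity rule
(opposite charges attract) of magnitude ~1 in zero-sum gauge on six
disjoint inter-protein column pairs.

All generators are pure functions of their arguments and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import softmax

from .alphabet import DEFAULT_ALPHABET
from .dca import GAUGE_ZERO_SUM, CouplingModel
from .genome_pairing import DomainHit, GeneRecord
from .modes import NEGATIVE, POSITIVE
from .msa_io import JointMSA, PairingTable

CHARGED = POSITIVE + NEGATIVE


@dataclass
class PlantedModel:
    """Ground-truth pairwise model over a joint SK+RR alignment."""

    l_sk: int
    l_rr: int
    q: int
    e: np.ndarray  # (L, L, q, q), zero except at planted pairs
    h: np.ndarray  # (L, q)
    planted_pairs: list[tuple[int, int]]  # joint coordinates, i < boundary <= j
    rule: str = "charge-complementary"

    @property
    def length(self) -> int:
        return self.l_sk + self.l_rr

    @property
    def boundary(self) -> int:
        return self.l_sk

    def pair_distribution(self, i: int, j: int) -> np.ndarray:
        """Exact two-site distribution of a planted (disjoint) pair."""
        logits = self.h[i][:, None] + self.h[j][None, :] + self.e[i, j]
        return softmax(logits)

    def site_marginal(self, i: int) -> np.ndarray:
        """Exact marginal of site i (valid for disjoint planted pairs)."""
        for a, b in self.planted_pairs:
            if i == a:
                return self.pair_distribution(a, b).sum(axis=1)
            if i == b:
                return self.pair_distribution(a, b).sum(axis=0)
        return softmax(self.h[i])

    def to_coupling_model(self, columns=None) -> CouplingModel:
        """Expose the ground truth in the fitted-model container.

        Default columns: the planted ones.  Marginals are the exact ones,
        so scorers built on this model are exact planted-truth scorers.
        """
        if columns is None:
            columns = sorted({c for p in self.planted_pairs for c in p})
        columns = np.asarray(columns, dtype=int)
        idx = {int(c): k for k, c in enumerate(columns)}
        n = len(columns)
        e = np.zeros((n, n, self.q, self.q))
        for a, b in self.planted_pairs:
            if a in idx and b in idx:
                e[idx[a], idx[b]] = self.e[a, b]
                e[idx[b], idx[a]] = self.e[a, b].T
        f_i = np.stack([self.site_marginal(int(c)) for c in columns])
        return CouplingModel(
            columns=columns,
            e=e,
            h=self.h[columns],
            f_i=f_i,
            boundary=self.boundary,
            gauge=GAUGE_ZERO_SUM,
            q=self.q,
            diagnostics={"planted": True},
        )


def _charge_block_matrix(q: int, coupling: float) -> np.ndarray:
    """Charge-complementary coupling block, zero-sum gauged."""
    alpha = DEFAULT_ALPHABET
    sign = np.zeros(q)
    for a in POSITIVE:
        sign[alpha.index_of[a]] = 1.0
    for a in NEGATIVE:
        sign[alpha.index_of[a]] = -1.0
    block = -coupling * np.outer(sign, sign)  # opposite charges attract
    block -= block.mean(axis=0)
    block -= block.mean(axis=1)[:, None]
    return block


def default_planted_model(
    l_sk: int = 20,
    l_rr: int = 25,
    q: int = 21,
    n_pairs: int = 6,
    coupling: float = 1.0,
    charged_field: float = 1.5,
    field_sd: float = 0.3,
    seed: int = 0,
) -> PlantedModel:
    """Standard planted benchmark model.

    Six disjoint inter-protein pairs carry the charge-complementary
    coupling; their columns get a field bonus on charged residues (so the
    interacting states are actually populated), and every column gets mild
    random fields for realistic non-uniform composition.
    """
    rng = np.random.default_rng(seed)
    length = l_sk + l_rr
    if n_pairs > min(l_sk, l_rr):
        raise ValueError("more planted pairs than available columns")
    sk_sites = np.linspace(0, l_sk - 1, n_pairs).astype(int)
    rr_sites = l_sk + np.linspace(0, l_rr - 1, n_pairs).astype(int)
    pairs = list(zip(sk_sites.tolist(), rr_sites.tolist()))
    e = np.zeros((length, length, q, q))
    block = _charge_block_matrix(q, coupling)
    for i, j in pairs:
        e[i, j] = block
        e[j, i] = block.T
    h = rng.normal(0.0, field_sd, size=(length, q))
    h[:, -1] -= 2.0  # keep gaps rare
    charged_idx = [DEFAULT_ALPHABET.index_of[a] for a in CHARGED]
    for i, j in pairs:
        h[i, charged_idx] += charged_field
        h[j, charged_idx] += charged_field
    h -= h.mean(axis=1, keepdims=True)
    return PlantedModel(l_sk, l_rr, q, e, h, pairs)


@dataclass
class SyntheticCorpus:
    """Sampled cognate pairs with genome grouping and ground truth."""

    msa: JointMSA
    model: PlantedModel
    seed: int
    pairs_per_genome: int = 10
    noncognate_rows: list[tuple[int, int]] = field(default_factory=list)

    @property
    def sk_codes(self) -> np.ndarray:
        return self.msa.codes[:, : self.msa.boundary]

    @property
    def rr_codes(self) -> np.ndarray:
        return self.msa.codes[:, self.msa.boundary :]

    def pairing_table(self) -> PairingTable:
        return PairingTable(list(self.msa.row_ids))


def sample_pairs(
    model: PlantedModel,
    n: int,
    seed: int = 0,
    burn_in: int = 1000,
    thin: int = 10,
    pairs_per_genome: int = 10,
) -> SyntheticCorpus:
    """Draw n joint sequences from the planted model by Gibbs sampling.

    One independent chain per output sequence is run for ``burn_in``
    single-site heat-bath sweeps (so samples are independent across rows;
    ``thin`` only applies to the single-chain mode used when memory is
    tight).  Rows are grouped into pseudo-genomes of ``pairs_per_genome``
    cognate pairs each.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    length, q = model.length, model.q
    probs0 = softmax(model.h, axis=1)
    codes = np.empty((n, length), dtype=np.int8)
    for i in range(length):
        codes[:, i] = _sample_categorical(np.tile(probs0[i], (n, 1)), rng)
    neighbors: dict[int, list[int]] = {i: [] for i in range(length)}
    for a, b in model.planted_pairs:
        neighbors[a].append(b)
        neighbors[b].append(a)
    coupled_sites = [i for i in range(length) if neighbors[i]]
    for _ in range(burn_in):
        for i in coupled_sites:
            logits = np.tile(model.h[i], (n, 1))
            for j in neighbors[i]:
                logits += model.e[i, j][:, codes[:, j].astype(int)].T
            codes[:, i] = _sample_categorical(softmax(logits, axis=1), rng)
    row_ids = [
        (f"sk{k:05d}", f"rr{k:05d}", f"g{k // pairs_per_genome:04d}")
        for k in range(n)
    ]
    msa = JointMSA(codes=codes, boundary=model.boundary, row_ids=row_ids)
    return SyntheticCorpus(msa=msa, model=model, seed=seed, pairs_per_genome=pairs_per_genome)


def _sample_categorical(p: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Row-wise categorical draw from an (n, q) probability matrix."""
    cdf = np.cumsum(p, axis=1)
    u = rng.random(p.shape[0])[:, None] * cdf[:, -1:]
    return (u >= cdf).sum(axis=1).astype(np.int8)


def make_noncognates(
    corpus: SyntheticCorpus, seed: int = 0
) -> list[tuple[int, int]]:
    """Within-genome shuffled (SK row, RR row) pairings, derangement-safe.

    Each genome group of size >= 2 contributes one full derangement (a
    random cyclic rotation), so no shuffled pair coincides with a cognate
    one; singleton groups are skipped.
    """
    rng = np.random.default_rng(seed)
    out: list[tuple[int, int]] = []
    for rows in corpus.msa.genome_groups().values():
        g = len(rows)
        if g < 2:
            continue
        order = rng.permutation(rows)
        for t in range(g):
            out.append((int(order[t]), int(order[(t + 1) % g])))
    corpus.noncognate_rows = out
    return out


def add_redundancy(
    corpus: SyntheticCorpus,
    dup_fraction: float = 0.2,
    mutation_rate: float = 0.05,
    seed: int = 0,
) -> SyntheticCorpus:
    """Append near-duplicate rows emulating phylogenetic redundancy.

    A fraction of rows is copied with iid per-site substitution to a
    uniformly random different state at ``mutation_rate``; expected
    pairwise identity of a duplicate to its source is 1 - mutation_rate
    (within binomial error).
    """
    if not 0 <= dup_fraction <= 1 or not 0 <= mutation_rate <= 1:
        raise ValueError("rates must be in [0, 1]")
    rng = np.random.default_rng(seed)
    m = corpus.msa.n_seqs
    n_dup = int(round(dup_fraction * m))
    if n_dup == 0:
        return corpus
    picks = rng.choice(m, size=n_dup, replace=False)
    q = corpus.model.q
    new_rows, new_ids = [], []
    for t, k in enumerate(picks):
        row = corpus.msa.codes[k].copy()
        hit = rng.random(len(row)) < mutation_rate
        if hit.any():
            shift = rng.integers(1, q, size=hit.sum())
            row[hit] = (row[hit] + shift) % q
        new_rows.append(row)
        sk, rr, g = corpus.msa.row_ids[k]
        new_ids.append((f"{sk}.d{t}", f"{rr}.d{t}", g))
    msa = JointMSA(
        codes=np.vstack([corpus.msa.codes, np.array(new_rows)]),
        boundary=corpus.msa.boundary,
        row_ids=list(corpus.msa.row_ids) + new_ids,
    )
    return SyntheticCorpus(
        msa=msa,
        model=corpus.model,
        seed=corpus.seed,
        pairs_per_genome=corpus.pairs_per_genome,
    )


# ---------------------------------------------------------------------------
# toy genomes for the operon/domain extraction rules

#: motifs available to make_toy_genome
TOY_MOTIFS = (
    "cognate",  # [SK, RR] same strand, small gap -> 1 cognate pair
    "gap200",  # [SK, RR] gap exactly 200 -> still cognate (boundary inclusive)
    "gap264",  # [SK, RR] gap 264 -> separate operons -> orphan SK + orphan RR
    "hybrid_rr",  # [hybrid, RR] -> no pair
    "multi_rr",  # [SK, RR, RR] -> excluded entirely
    "orphan_sk",  # lone SK
    "orphan_rr",  # lone RR
    "alt_kinase_rr",  # [HisKA_3 kinase, RR] -> RR not orphan, no pair
    "hpt_rr",  # [Hpt, RR] -> RR not orphan
    "opposite_strand",  # [SK+, RR-] adjacent -> two operons -> orphans
)


def make_toy_genome(
    motifs: list[str], seed: int = 0
) -> tuple[list[GeneRecord], list[DomainHit], PairingTable, set[str]]:
    """Build gene and domain-hit tables realizing the requested motifs.

    Each motif is placed on its own replicon so motifs cannot interact.
    Returns (genes, hits, expected pairing table, expected excluded ids).
    """
    genes: list[GeneRecord] = []
    hits: list[DomainHit] = []
    cognates: list[tuple[str, str, str]] = []
    orphan_sk: list[str] = []
    orphan_rr: list[str] = []
    excluded: set[str] = set()

    def add_gene(gid, rep, strand, start, length=900):
        genes.append(GeneRecord(gid, rep, strand, start, start + length))

    def sk_hits(gid, domain="HisKA"):
        hits.append(DomainHit(gid, domain, 1e-20))
        hits.append(DomainHit(gid, "HATPase_c", 1e-10))

    def rr_hits(gid):
        hits.append(DomainHit(gid, "Response_reg", 1e-15))

    for t, motif in enumerate(motifs):
        rep = f"rep{t:02d}"
        p = f"{motif}{t}"
        if motif in ("cognate", "gap200", "gap264"):
            gap = {"cognate": 50, "gap200": 200, "gap264": 264}[motif]
            add_gene(f"{p}_sk", rep, "+", 1000)
            add_gene(f"{p}_rr", rep, "+", 1900 + gap)
            sk_hits(f"{p}_sk")
            rr_hits(f"{p}_rr")
            if motif == "gap264":
                orphan_sk.append(f"{p}_sk")
                orphan_rr.append(f"{p}_rr")
            else:
                cognates.append((f"{p}_sk", f"{p}_rr", "genome"))
        elif motif == "hybrid_rr":
            add_gene(f"{p}_hy", rep, "+", 1000)
            add_gene(f"{p}_rr", rep, "+", 1950)
            sk_hits(f"{p}_hy")
            rr_hits(f"{p}_hy")
            rr_hits(f"{p}_rr")
            excluded.add(f"{p}_hy")
            orphan_rr.append(f"{p}_rr")
        elif motif == "multi_rr":
            add_gene(f"{p}_sk", rep, "+", 1000)
            add_gene(f"{p}_rr1", rep, "+", 1950)
            add_gene(f"{p}_rr2", rep, "+", 2900)
            sk_hits(f"{p}_sk")
            rr_hits(f"{p}_rr1")
            rr_hits(f"{p}_rr2")
            excluded.update({f"{p}_sk", f"{p}_rr1", f"{p}_rr2"})
        elif motif == "orphan_sk":
            add_gene(f"{p}_sk", rep, "+", 1000)
            sk_hits(f"{p}_sk")
            orphan_sk.append(f"{p}_sk")
        elif motif == "orphan_rr":
            add_gene(f"{p}_rr", rep, "+", 1000)
            rr_hits(f"{p}_rr")
            orphan_rr.append(f"{p}_rr")
        elif motif == "alt_kinase_rr":
            add_gene(f"{p}_k3", rep, "+", 1000)
            add_gene(f"{p}_rr", rep, "+", 1950)
            sk_hits(f"{p}_k3", domain="HisKA_3")
            rr_hits(f"{p}_rr")
        elif motif == "hpt_rr":
            add_gene(f"{p}_hpt", rep, "+", 1000)
            add_gene(f"{p}_rr", rep, "+", 1950)
            hits.append(DomainHit(f"{p}_hpt", "Hpt", 1e-8))
            rr_hits(f"{p}_rr")
        elif motif == "opposite_strand":
            add_gene(f"{p}_sk", rep, "+", 1000)
            add_gene(f"{p}_rr", rep, "-", 1950)
            sk_hits(f"{p}_sk")
            rr_hits(f"{p}_rr")
            orphan_sk.append(f"{p}_sk")
            orphan_rr.append(f"{p}_rr")
        else:
            raise ValueError(f"unknown motif {motif!r}")
    truth = PairingTable(cognates, sorted(orphan_sk), sorted(orphan_rr))
    return genes, hits, truth, excluded


# ---------------------------------------------------------------------------
# mutation scans


def score_table(model: PlantedModel, pair: tuple[int, int]) -> np.ndarray:
    """Planted-truth per-pair score table ln[P(A,B)/(f_i(A) f_j(B))]."""
    p = model.pair_distribution(*pair)
    fi, fj = p.sum(axis=1), p.sum(axis=0)
    return np.log(p) - np.log(np.outer(fi, fj))


def preferred_partner_state(model: PlantedModel, pair: tuple[int, int], a: int) -> int:
    """Most favorable RR-side state given SK-side state ``a``."""
    return int(np.argmax(score_table(model, pair)[a]))


def mutation_scan_fixture(
    model_a: PlantedModel,
    model_b: PlantedModel,
    base_sk: np.ndarray,
    base_rr: np.ndarray,
    mutation_sets: list[list[tuple[int, int]]],
) -> pd.DataFrame:
    """Ground-truth score deltas for SK mutations under two models.

    Each mutation set is a list of (joint SK column, new state) applied
    together to the base SK sequence; every mutated column must be a
    planted SK column in both models.  Returns a table with the exact
    delta (mutant minus base score, from the planted tables) under each
    model; sign(delta) is the ground truth a fitted scorer should match.
    """
    for model in (model_a, model_b):
        planted_sk = {i for i, _ in model.planted_pairs}
        for ms in mutation_sets:
            off = [i for i, _ in ms if i not in planted_sk]
            if off:
                raise ValueError(f"substitutions off planted columns: {off}")
    rows = []
    for k, ms in enumerate(mutation_sets):
        rec = {"mutation_set": k, "n_subs": len(ms)}
        for name, model in (("model_a", model_a), ("model_b", model_b)):
            delta = 0.0
            for i, new_state in ms:
                j = dict(model.planted_pairs)[i]
                t = score_table(model, (i, j))
                b = int(base_rr[j - model.boundary])
                delta += float(t[new_state, b] - t[int(base_sk[i]), b])
            rec[f"delta_{name}"] = delta
            rec[f"sign_{name}"] = int(np.sign(delta))
        rows.append(rec)
    return pd.DataFrame(rows)
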