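"""Run configuration and stage orchestration.

A :class:`RunConfig` gathers every tunable with its default; a manifest
records the configuration, input hashes and seeds next to each output so
runs are reproducible.  The synthetic end-to-end pipeline (simulate ->
weights/counts -> fit -> score) is wired here for the CLI.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .dca import DirectCouplingAnalysis
from .scoring import DcaScorer, score_matrix
from .synthetic import default_planted_model, make_noncognates, sample_pairs


@dataclass
class RunConfig:
    """All pipeline tunables with their defaults."""

    pseudocount: float | None = None  # None -> lambda = M_eff
    identity_threshold: float = 0.80
    max_gap_bp: int = 200
    n_columns: int = 70
    top_k: int = 10
    thresholds: tuple[float, ...] = (20.0, 30.0, 60.0)
    n_permutations: int = 1_000_000
    backend: str = "plm"
    seed: int = 0
    n_train: int = 2000

    def manifest(self, **extra) -> dict:
        cfg = asdict(self)
        blob = json.dumps(cfg, sort_keys=True, default=str).encode()
        return {
            "config": cfg,
            "config_hash": hashlib.sha256(blob).hexdigest()[:16],
            "version": __version__,
            **extra,
        }


@dataclass
class PipelineResult:
    config: RunConfig
    corpus: object
    estimator: DirectCouplingAnalysis
    scorer: DcaScorer
    scores: object
    manifest: dict = field(default_factory=dict)


def run_synthetic_pipeline(config: RunConfig) -> PipelineResult:
    """Simulate a corpus, fit the model, score cognates vs shuffles."""
    model = default_planted_model(seed=config.seed)
    corpus = sample_pairs(model, n=config.n_train, seed=config.seed + 1)
    make_noncognates(corpus, seed=config.seed + 2)
    est = DirectCouplingAnalysis(
        n_columns=config.n_columns,
        identity_threshold=config.identity_threshold,
        pseudocount=config.pseudocount,
        method=config.backend,
    ).fit(corpus.msa)
    scorer = DcaScorer(est.model_)
    sm = score_matrix(
        corpus.sk_codes,
        corpus.rr_codes,
        est.model_,
        sk_ids=[r[0] for r in corpus.msa.row_ids],
        rr_ids=[r[1] for r in corpus.msa.row_ids],
        cognate_pairs={(r[0], r[1]) for r in corpus.msa.row_ids},
        sk_genomes=[r[2] for r in corpus.msa.row_ids],
        rr_genomes=[r[2] for r in corpus.msa.row_ids],
        scorer=scorer,
    )
    manifest = config.manifest(
        m_eff=est.m_eff_,
        n_selected_columns=int(len(est.columns_)),
        fit_diagnostics=est.diagnostics_,
    )
    return PipelineResult(config, corpus, est, scorer, sm, manifest)


def specificity_benchmark(
    corpus,
    estimator: DirectCouplingAnalysis,
    knn_k: int = 2,
    seed: int = 0,
) -> dict:
    """Cognate-vs-shuffled discrimination AUCs for the three scorers.

    Positives are the corpus's cognate rows; negatives are within-genome
    derangements.  Returns AUCs for the DCA score, the raw pair-frequency
    (local covariance) baseline and the kNN sequence-identity baseline.
    """
    from .network import roc
    from .scoring import MutualInformationScorer, NearestNeighborScorer
    from .synthetic import make_noncognates

    non = corpus.noncognate_rows or make_noncognates(corpus, seed=seed)
    sk_rows = np.array([a for a, _ in non])
    rr_rows = np.array([b for _, b in non])
    sk_all = np.vstack([corpus.sk_codes, corpus.sk_codes[sk_rows]])
    rr_all = np.vstack([corpus.rr_codes, corpus.rr_codes[rr_rows]])
    labels = np.concatenate(
        [np.ones(corpus.msa.n_seqs), np.zeros(len(non))]
    )
    model = estimator.model_
    scorers = {
        "dca": DcaScorer(model),
        "mi": MutualInformationScorer(estimator.counts_, model),
        "knn": NearestNeighborScorer(corpus.msa, k=knn_k),
    }
    out = {}
    for name, scorer in scorers.items():
        scores = scorer.score_rows(sk_all, rr_all)
        out[f"auc_{name}"] = roc(scores, labels)[2]
    return out


def write_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_jsonable(manifest), indent=2))


def _jsonable(x):
    if isinstance(x, dict):
        return {k: _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    return x
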