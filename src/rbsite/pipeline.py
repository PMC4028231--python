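"""End-to-end orchestration: from query + database + PSSM to final scores.

The prediction path mirrors the published workflow: homology transfer where
usable homologs exist, the PSSM-window SVM everywhere, and the logistic
stacker on the 2-D score vector (missing homology scores imputed), so every
residue of every query receives a final probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .combiner import CombinerModel, combine, fit_combiner
from .database import HomologDatabase
from .homology import HomologyResult, predict_query
from .ic_model import ICModel, ZoneThresholds
from .svm_window import ChainSample, SVMModelSpec, TrainedSVM, sequence_based_cv, train_svm, window_matrix


@dataclass
class QueryPrediction:
    """All per-residue scores for one query."""

    query_id: str
    sequence: str
    homology: HomologyResult
    svm_scores: np.ndarray
    combined: np.ndarray

    @property
    def calls(self) -> np.ndarray:
        return (self.combined >= 0.5).astype(int)


def predict_one(
    query_id: str,
    sequence: str,
    db: HomologDatabase,
    svm_model: TrainedSVM,
    pssm,
    combiner: CombinerModel,
    ic_model: ICModel | None = None,
    thresholds: ZoneThresholds | None = None,
    similarity_exclusion: float = 0.95,
    vote_threshold: float = 0.5,
) -> QueryPrediction:
    """Predict all residues of one query through both stages and the stack."""
    hits = db.hits_for(query_id, ic_model, thresholds)
    hom = predict_query(
        query_id, len(sequence), hits,
        similarity_exclusion=similarity_exclusion, vote_threshold=vote_threshold,
    )
    X = window_matrix(pssm, svm_model.spec.window_size)
    svm_scores = svm_model.probabilities(X)
    combined = combine(hom.scores, svm_scores, combiner)
    return QueryPrediction(query_id, sequence, hom, svm_scores, combined)


def out_of_fold_svm_scores(
    chains: Sequence[ChainSample],
    spec: SVMModelSpec | None = None,
    k: int = 5,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Out-of-fold SVM probabilities per chain (sequence-based k-fold), used
    to train the stacker without within-chain leakage."""
    spec = spec or SVMModelSpec()
    ids = [c.chain_id for c in chains]
    folds = sequence_based_cv(ids, k, seed)
    by_id = {c.chain_id: c for c in chains}
    out: dict[str, np.ndarray] = {}
    for fold in folds:
        held = set(fold)
        train = [c for c in chains if c.chain_id not in held]
        X = np.vstack([window_matrix(c.pssm, spec.window_size) for c in train])
        y = np.concatenate([c.labels for c in train])
        model = train_svm(X, y, spec)
        for cid in fold:
            c = by_id[cid]
            out[cid] = model.probabilities(window_matrix(c.pssm, spec.window_size))
    return out


def collect_stacking_rows(
    chains: Sequence[ChainSample],
    homology_scores: dict[str, np.ndarray],
    svm_scores: dict[str, np.ndarray],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Assemble (homology_score, svm_score, label) training rows for the
    combiner; chains missing from ``homology_scores`` contribute NaN."""
    h_all, s_all, y_all = [], [], []
    for c in chains:
        n = len(c.labels)
        h = homology_scores.get(c.chain_id)
        h_all.append(np.full(n, np.nan) if h is None else np.asarray(h, dtype=float))
        s_all.append(np.asarray(svm_scores[c.chain_id], dtype=float))
        y_all.append(c.labels)
    return np.concatenate(h_all), np.concatenate(s_all), np.concatenate(y_all)


def train_stack(
    chains: Sequence[ChainSample],
    db: HomologDatabase,
    spec: SVMModelSpec | None = None,
    ic_model: ICModel | None = None,
    thresholds: ZoneThresholds | None = None,
    ridge: float = 1e-8,
    k: int = 5,
    seed: int = 0,
):
    """Train SVM + combiner on labeled chains with out-of-fold base scores.

    Returns (trained_svm, combiner_results).  The final SVM is refitted on
    all chains; the combiner sees only out-of-fold SVM scores and the
    homology scores the database yields for each chain.
    """
    spec = spec or SVMModelSpec()
    oof = out_of_fold_svm_scores(chains, spec, k=k, seed=seed)
    hom_scores: dict[str, np.ndarray] = {}
    for c in chains:
        hits = db.hits_for(c.chain_id, ic_model, thresholds)
        res = predict_query(c.chain_id, len(c.labels), hits)
        hom_scores[c.chain_id] = res.scores
    h, s, y = collect_stacking_rows(chains, hom_scores, oof)
    comb = fit_combiner(h, s, y, ridge=ridge)
    X = np.vstack([window_matrix(c.pssm, spec.window_size) for c in chains])
    yy = np.concatenate([c.labels for c in chains])
    final_svm = train_svm(X, yy, spec)
    return final_svm, comb
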