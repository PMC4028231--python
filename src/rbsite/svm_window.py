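"""PSSM sliding-window SVM for per-residue interface prediction.

Each residue is encoded by the rows of a position-specific scoring matrix
(PSSM) in a window centered on it (default width 21, the tuned value on the
training benchmark), flattened to a window_size × 20 feature vector with
zero-vector padding beyond the sequence ends.  An RBF-kernel SVM with
inverse-frequency class weighting separates interface from non-interface
residues; its margin is mapped to [0, 1] by a Platt-style logistic
calibration fitted on the training margins.

Hyper-parameters (C, γ, window size) are tuned by a three-dimensional grid
search under the published protocol: chains are split into six parts, one
held out as a final test set; on the rest, each candidate is scored by
sequence-based 5-fold cross-validation (folds partition whole chains, never
residues, so no within-chain leakage is possible), and the winner is
retrained on all training + validation chains.

PSSMs are read from the PSI-BLAST ``-out_ascii_pssm`` dialect.  The protocol
that produces real PSSMs (PSI-BLAST, 3 iterations, inclusion E-value 0.001,
against nr) is external; synthetic PSSMs serve for testing.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from scipy.optimize import minimize
from scipy.special import expit
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

#: PSI-BLAST column ordering of the 20 amino acids.
PSSM_ALPHABET = "ARNDCQEGHILKMFPSTWYV"

DEFAULT_WINDOW = 21
#: Documented grid spans: powers of two for C and gamma, odd windows 15–27.
DEFAULT_C_GRID = tuple(2.0 ** k for k in range(-5, 16, 4))
DEFAULT_GAMMA_GRID = tuple(2.0 ** k for k in range(-15, 4, 4))
DEFAULT_WINDOW_GRID = tuple(range(15, 28, 2))


@dataclass
class PSSM:
    """Per-residue log-odds matrix (L × 20) for one protein."""

    protein_id: str
    matrix: np.ndarray
    sequence: str | None = None
    column_order: str = PSSM_ALPHABET

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 20:
            raise ValueError("PSSM matrix must be (L, 20)")
        if self.sequence is not None and len(self.sequence) != len(self.matrix):
            raise ValueError("sequence length must equal matrix length")

    def __len__(self) -> int:
        return len(self.matrix)


def read_ascii_pssm(path: str | Path, protein_id: str | None = None) -> PSSM:
    """Read a PSI-BLAST ASCII PSSM (header, 20 log-odds columns)."""
    rows: list[list[float]] = []
    seq: list[str] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            # data rows: index, residue, >= 20 numeric columns
            if len(parts) >= 22 and parts[0].isdigit() and len(parts[1]) == 1:
                rows.append([float(v) for v in parts[2:22]])
                seq.append(parts[1])
    if not rows:
        raise ValueError(f"no PSSM rows found in {path}")
    return PSSM(
        protein_id or Path(path).stem,
        np.array(rows),
        sequence="".join(seq),
    )


def write_ascii_pssm(pssm: PSSM, path: str | Path) -> None:
    """Write a PSSM in the ``-out_ascii_pssm`` dialect (log-odds block only,
    weighted-percentage block zero-filled)."""
    seq = pssm.sequence or "X" * len(pssm)
    with open(path, "w") as fh:
        fh.write("\n")
        fh.write("Last position-specific scoring matrix computed, weighted, and scaled\n")
        header = "            " + "  ".join(pssm.column_order) + "   " + "  ".join(pssm.column_order)
        fh.write(header + "\n")
        for i, (aa, row) in enumerate(zip(seq, pssm.matrix), start=1):
            scores = " ".join(f"{v:3.0f}" if v == int(v) else f"{v:6.2f}" for v in row)
            pct = " ".join("  0" for _ in range(20))
            fh.write(f"{i:5d} {aa}  {scores}  {pct}  0.00 0.00\n")
        fh.write("\n")


# ---------------------------------------------------------------------------
# Window features
# ---------------------------------------------------------------------------

@dataclass
class WindowFeature:
    """Flattened PSSM window centered on one residue."""

    center_position: int
    vector: np.ndarray
    window_size: int


def window_matrix(pssm: PSSM, window_size: int = DEFAULT_WINDOW) -> np.ndarray:
    """(L, window_size·20) feature matrix with zero padding at the ends."""
    if window_size < 1 or window_size % 2 == 0:
        raise ValueError("window_size must be odd and >= 1")
    half = window_size // 2
    padded = np.vstack(
        [np.zeros((half, 20)), pssm.matrix, np.zeros((half, 20))]
    )
    L = len(pssm)
    return np.stack(
        [padded[i : i + window_size].reshape(-1) for i in range(L)]
    )


def windows_from_pssm(pssm: PSSM, window_size: int = DEFAULT_WINDOW) -> list[WindowFeature]:
    """One :class:`WindowFeature` per residue (1-based centers)."""
    mat = window_matrix(pssm, window_size)
    return [
        WindowFeature(i + 1, mat[i], window_size) for i in range(len(pssm))
    ]


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class SVMModelSpec:
    """RBF-SVM hyper-parameters plus feature handling.

    ``C`` is a total cost budget: the per-sample cost used at fit time is
    C / n_train, which makes the solution invariant to duplicating the
    training set.
    """

    C: float = 100.0
    gamma: float = 1.0 / (DEFAULT_WINDOW * 20)
    window_size: int = DEFAULT_WINDOW
    scale_features: bool = True

    def __post_init__(self) -> None:
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError("C and gamma must be positive")
        if self.window_size % 2 == 0 or self.window_size < 1:
            raise ValueError("window_size must be odd and >= 1")


def _fit_platt(margins: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Logistic map margin → probability, fitted on mean log loss (+ tiny
    ridge), so the calibration is invariant to duplicating the data."""
    y = labels.astype(float)

    def nll(theta):
        z = theta[0] + theta[1] * margins
        return float(
            np.mean(np.logaddexp(0.0, z) - y * z) + 1e-8 * (theta[0] ** 2 + theta[1] ** 2)
        )

    res = minimize(nll, x0=np.array([0.0, 1.0]), method="BFGS")
    return float(res.x[0]), float(res.x[1])


class TrainedSVM:
    """A fitted PSSM-window SVM exposing margins, probabilities and calls."""

    def __init__(self, spec: SVMModelSpec, scaler: StandardScaler | None, svc: SVC,
                 platt: tuple[float, float]) -> None:
        self.spec = spec
        self.scaler = scaler
        self.svc = svc
        self.platt = platt

    def _transform(self, X: np.ndarray) -> np.ndarray:
        return self.scaler.transform(X) if self.scaler is not None else np.asarray(X)

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        """Raw SVM margins."""
        return self.svc.decision_function(self._transform(X))

    def probabilities(self, X: np.ndarray) -> np.ndarray:
        """Calibrated interface probabilities in (0, 1)."""
        a, b = self.platt
        return expit(a + b * self.decision_scores(X))

    def predict(self, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        return (self.probabilities(X) >= threshold).astype(int)

    def save(self, path: str | Path) -> None:
        joblib.dump(
            {"format_version": 1, "spec": self.spec, "scaler": self.scaler,
             "svc": self.svc, "platt": self.platt},
            path,
        )

    @classmethod
    def load(cls, path: str | Path) -> "TrainedSVM":
        blob = joblib.load(path)
        return cls(blob["spec"], blob["scaler"], blob["svc"], blob["platt"])


def train_svm(
    features: np.ndarray,
    labels: np.ndarray,
    spec: SVMModelSpec | None = None,
    class_weighting: str = "balanced",
) -> TrainedSVM:
    """Train the RBF SVM with inverse-frequency class weights.

    Raises ``ValueError`` on a single-class training set.
    """
    spec = spec or SVMModelSpec()
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single class")
    scaler = None
    if spec.scale_features:
        scaler = StandardScaler().fit(X)
        X = scaler.transform(X)
    svc = SVC(
        C=spec.C / len(y),
        gamma=spec.gamma,
        kernel="rbf",
        class_weight=None if class_weighting == "none" else class_weighting,
        tol=1e-7,
    )
    svc.fit(X, y)
    margins = svc.decision_function(X)
    return TrainedSVM(spec, scaler, svc, _fit_platt(margins, y))


# ---------------------------------------------------------------------------
# Sequence-based cross-validation and the grid search
# ---------------------------------------------------------------------------

@dataclass
class ChainSample:
    """One chain of a residue-labeled PSSM dataset."""

    chain_id: str
    pssm: PSSM
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.pssm):
            raise ValueError("labels length must equal PSSM length")


def sequence_based_cv(chain_ids: Sequence[str], k: int, seed: int = 0) -> list[list[str]]:
    """Partition whole chains into k seeded folds (every residue of a chain
    shares its chain's fold)."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(chain_ids) < k:
        raise ValueError("need at least k chains")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(chain_ids))
    return [
        [chain_ids[i] for i in part] for part in np.array_split(order, k)
    ]


def _assert_no_leakage(folds: Sequence[Sequence[str]]) -> None:
    seen: set[str] = set()
    for fold in folds:
        overlap = seen & set(fold)
        if overlap:
            raise ValueError(f"chain leakage between folds: {sorted(overlap)}")
        seen |= set(fold)


def _stack(chains: Sequence[ChainSample], window_size: int) -> tuple[np.ndarray, np.ndarray]:
    X = np.vstack([window_matrix(c.pssm, window_size) for c in chains])
    y = np.concatenate([c.labels for c in chains])
    return X, y


def _mcc(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    from .evaluation import confusion, metrics

    return metrics(confusion(y_pred, y_true)).mcc


@dataclass
class GridSearchResult:
    best_spec: SVMModelSpec
    model: TrainedSVM
    history: list[dict]
    trainval_ids: list[str]
    test_ids: list[str]


def grid_search(
    chains: Sequence[ChainSample],
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
    window_grid: Sequence[int] = DEFAULT_WINDOW_GRID,
    k: int = 5,
    seed: int = 0,
    base_spec: SVMModelSpec | None = None,
) -> GridSearchResult:
    """Three-dimensional grid search over (C, γ, window).

    Chains are split into six seeded parts; one part is held out as the test
    set and never touched during selection.  Each candidate is scored by the
    mean validation MCC over sequence-based k-fold CV on the remaining
    chains; the winner (first encountered on ties) is retrained on all
    training + validation chains.
    """
    if not (C_grid and gamma_grid and window_grid):
        raise ValueError("grids must be non-empty")
    if len(chains) < 6:
        raise ValueError("need at least 6 chains for the 6-way split protocol")
    base_spec = base_spec or SVMModelSpec()
    ids = [c.chain_id for c in chains]
    parts = sequence_based_cv(ids, 6, seed)
    _assert_no_leakage(parts)
    test_ids = parts[-1]
    trainval_ids = [cid for part in parts[:-1] for cid in part]
    by_id = {c.chain_id: c for c in chains}
    trainval = [by_id[cid] for cid in trainval_ids]

    folds = sequence_based_cv(trainval_ids, k, seed + 1)
    _assert_no_leakage(folds)
    if set(trainval_ids) & set(test_ids):
        raise ValueError("protocol violation: test chains overlap training chains")

    history: list[dict] = []
    best: tuple[float, SVMModelSpec] | None = None
    for window in window_grid:
        for C in C_grid:
            for gamma in gamma_grid:
                spec = replace(base_spec, C=C, gamma=gamma, window_size=window)
                scores = []
                for j in range(k):
                    val_ids = set(folds[j])
                    tr = [c for c in trainval if c.chain_id not in val_ids]
                    va = [c for c in trainval if c.chain_id in val_ids]
                    Xtr, ytr = _stack(tr, window)
                    Xva, yva = _stack(va, window)
                    model = train_svm(Xtr, ytr, spec)
                    scores.append(_mcc(yva, model.predict(Xva)))
                mean_mcc = float(np.mean(scores))
                history.append(
                    {"C": C, "gamma": gamma, "window_size": window, "cv_mcc": mean_mcc}
                )
                if best is None or mean_mcc > best[0]:
                    best = (mean_mcc, spec)

    assert best is not None
    best_spec = best[1]
    Xtv, ytv = _stack(trainval, best_spec.window_size)
    final = train_svm(Xtv, ytv, best_spec)
    return GridSearchResult(best_spec, final, history, trainval_ids, test_ids)
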