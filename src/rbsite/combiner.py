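"""Second-stage logistic regression combining the two base predictors.

The hybrid predictor stacks the homology-transfer score and the SVM score
with a ridge-penalized logistic regression over the 2-D score vector.  The
homology score is undefined ('?') wherever no usable homolog covers a
residue; missing values are imputed with the training-set mean of the
non-missing homology scores (the imputation value is stored in the fitted
model so prediction is self-contained).  Because the SVM score always
exists, the hybrid emits a probability for every residue — 100% coverage —
which is the point of the stacking stage.

The fit is Newton/IRLS on the penalized log-likelihood with the bias
unpenalized (default ridge 1e-8, effectively maximum likelihood); standard
errors come from the unpenalized Fisher information at the estimate, in the
statsmodels fit()→results idiom.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import expit

logger = logging.getLogger(__name__)

MISSING = float("nan")


@dataclass
class CombinerModel:
    """Fitted stacking model: two weights, a bias, and the imputation value."""

    weight_homology: float
    weight_svm: float
    bias: float
    ridge: float = 1e-8
    imputation_value: float = 0.5

    def __post_init__(self) -> None:
        if self.ridge < 0:
            raise ValueError("ridge must be non-negative")
        if not np.isfinite(self.imputation_value):
            raise ValueError("imputation value must be finite")

    def to_config(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name in ("weight_homology", "weight_svm", "bias", "ridge", "imputation_value"):
                fh.write(f"{name} = {getattr(self, name)!r}\n")

    @classmethod
    def from_config(cls, path: str | Path) -> "CombinerModel":
        kwargs = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            kwargs[key.strip()] = float(value)
        return cls(**kwargs)


class CombinerResults:
    """Fit diagnostics for the stacking logistic regression."""

    def __init__(self, model: CombinerModel, params: np.ndarray, bse: np.ndarray,
                 n_obs: int, n_imputed: int, svm_only: bool) -> None:
        self.model = model
        self.params = params            # (bias, w_homology, w_svm)
        self.bse = bse
        self.n_obs = n_obs
        self.n_imputed = n_imputed
        self.svm_only = svm_only

    def summary(self) -> str:
        names = ("bias", "homology_score", "svm_score")
        rows = [f"{'term':<16}{'estimate':>12}{'std err':>12}"]
        for name, p, se in zip(names, self.params, self.bse):
            rows.append(f"{name:<16}{p:>12.4f}{se:>12.4f}")
        rows.append(
            f"n = {self.n_obs}, imputed homology scores = {self.n_imputed}"
            + (", SVM-only (all homology scores missing)" if self.svm_only else "")
        )
        return "\n".join(rows)


def _irls(X: np.ndarray, y: np.ndarray, ridge: float, penalize: np.ndarray,
          max_iter: int = 100, tol: float = 1e-10) -> tuple[np.ndarray, np.ndarray]:
    """Newton iterations on the ridge-penalized log-likelihood.

    ``penalize`` masks which coefficients the ridge applies to (bias is
    exempt).  Returns (beta, standard errors from the unpenalized observed
    information).
    """
    n, p = X.shape
    beta = np.zeros(p)
    R = 2.0 * ridge * np.diag(penalize.astype(float))
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        W = mu * (1 - mu)
        grad = X.T @ (y - mu) - R @ beta
        H = X.T @ (X * W[:, None]) + R
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # dampen huge steps on (quasi-)separated data
        norm = np.linalg.norm(step)
        if norm > 20.0:
            step *= 20.0 / norm
        beta = beta + step
        if np.linalg.norm(step) < tol:
            break
    mu = expit(X @ beta)
    W = np.clip(mu * (1 - mu), 1e-12, None)
    info = X.T @ (X * W[:, None])
    try:
        cov = np.linalg.inv(info)
        bse = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        bse = np.full(p, np.nan)
    return beta, bse


def fit_combiner(
    homology_scores,
    svm_scores,
    labels,
    ridge: float = 1e-8,
) -> CombinerResults:
    """Fit the stacking logistic regression.

    ``homology_scores`` may contain NaN (MISSING); they are imputed with the
    training mean of the non-missing scores.  When *all* homology scores are
    missing the model degenerates, with a warning, to an SVM-only logistic
    fit (homology weight 0, imputation value 0.5 so prediction-time inputs
    are well defined).
    """
    h = np.asarray(homology_scores, dtype=float)
    s = np.asarray(svm_scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if not (len(h) == len(s) == len(y)):
        raise ValueError("input lengths differ")
    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single class")
    if np.any(np.isnan(s)):
        raise ValueError("svm scores cannot be missing")

    missing = np.isnan(h)
    svm_only = bool(missing.all())
    if svm_only:
        warnings.warn(
            "all homology scores missing; fitting SVM-only combiner", stacklevel=2
        )
        X = np.column_stack([np.ones(len(y)), s])
        beta, bse2 = _irls(X, y.astype(float), ridge, np.array([False, True]))
        params = np.array([beta[0], 0.0, beta[1]])
        bse = np.array([bse2[0], np.nan, bse2[1]])
        model = CombinerModel(0.0, float(beta[1]), float(beta[0]), ridge, 0.5)
        return CombinerResults(model, params, bse, len(y), 0, True)

    imputation = float(np.mean(h[~missing]))
    h_filled = np.where(missing, imputation, h)
    X = np.column_stack([np.ones(len(y)), h_filled, s])
    beta, bse = _irls(X, y.astype(float), ridge, np.array([False, True, True]))
    model = CombinerModel(
        weight_homology=float(beta[1]),
        weight_svm=float(beta[2]),
        bias=float(beta[0]),
        ridge=ridge,
        imputation_value=imputation,
    )
    return CombinerResults(model, beta, bse, len(y), int(missing.sum()), False)


def combine(homology_score, svm_score, model: CombinerModel) -> np.ndarray:
    """Combined interface probability, elementwise; MISSING homology scores
    are imputed with the model's stored training mean."""
    h = np.atleast_1d(np.asarray(homology_score, dtype=float))
    s = np.atleast_1d(np.asarray(svm_score, dtype=float))
    h = np.where(np.isnan(h), model.imputation_value, h)
    p = expit(model.bias + model.weight_homology * h + model.weight_svm * s)
    # keep probabilities strictly inside (0, 1) even when the logit saturates
    return np.clip(p, 1e-12, 1.0 - 1e-12)


def write_final_table(
    sequence: str,
    homology_scores: np.ndarray,
    svm_scores: np.ndarray,
    combined: np.ndarray,
    path: str | Path,
    threshold: float = 0.5,
) -> None:
    """Final prediction TSV with the three score columns and the hybrid call."""
    with open(path, "w") as fh:
        fh.write(
            "position\tamino_acid\thomology_score\tsvm_score\tcombined_score\tcombined_call\n"
        )
        for i, aa in enumerate(sequence):
            hval = homology_scores[i]
            fh.write(
                f"{i + 1}\t{aa}\t"
                f"{'NA' if np.isnan(hval) else f'{hval:.6f}'}\t"
                f"{svm_scores[i]:.6f}\t{combined[i]:.6f}\t"
                f"{int(combined[i] >= threshold)}\n"
            )
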