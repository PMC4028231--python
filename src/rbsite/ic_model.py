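"""Linear prediction of interface conservation and homology-zone assignment.

When a query's interface is unknown, its IC score with respect to a homolog
cannot be computed directly; it is instead predicted by a linear model on four
alignment statistics:

    ic_hat = b0 + b1·(−log10 E) + b2·log10(L) + b3·PS + b4·(L / min(LQ, LH))

The shipped default coefficients are the published estimates
(b0 = −0.532, b1 = 0.001, b2 = 0.005, b3 = 0.600, b4 = 0.089).  Predicted IC
stratifies homologs into reliability tiers (zones): Safe (≥ 0.70),
Twilight (≥ 0.20), Dark (≥ 0.15); hits below the Dark cutoff are discarded.
Predicted values are deliberately NOT clamped to [−1, 1] — clamping would
silently move hits across zone boundaries.

``ICRegression`` refits the model to (statistics, observed IC) pairs by
ordinary least squares, in the statsmodels Model→fit()→Results idiom, with
per-coefficient standard errors, adjusted R² and Type II sums of squares.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Sequence

import numpy as np

from .alignment import AlignmentStatistics

PREDICTOR_NAMES = ("neg_log_e", "log_l", "positive_score", "length_fraction")


@dataclass
class ICModel:
    """Intercept and four coefficients of the IC predictor."""

    intercept: float = -0.532
    coef_neg_log_e: float = 0.001
    coef_log_l: float = 0.005
    coef_positive_score: float = 0.600
    coef_length_fraction: float = 0.089
    log_base: float = 10.0

    def __post_init__(self) -> None:
        vals = [getattr(self, f.name) for f in fields(self)]
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("all model parameters must be finite")

    @property
    def coefficients(self) -> np.ndarray:
        return np.array(
            [
                self.coef_neg_log_e,
                self.coef_log_l,
                self.coef_positive_score,
                self.coef_length_fraction,
            ]
        )

    def to_config(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for f in fields(self):
                fh.write(f"{f.name} = {getattr(self, f.name)!r}\n")

    @classmethod
    def from_config(cls, path: str | Path) -> "ICModel":
        kwargs = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            kwargs[key.strip()] = float(value)
        return cls(**kwargs)


def predictor_vector(stats: AlignmentStatistics) -> np.ndarray:
    """The four predictors in model order."""
    return np.array(
        [stats.neg_log_e, stats.log_l, stats.positive_score, stats.length_fraction]
    )


def predict_ic(stats: AlignmentStatistics, model: ICModel | None = None) -> float:
    """Predicted IC score of a query/homolog pair (unclamped)."""
    model = model or ICModel()
    return float(model.intercept + model.coefficients @ predictor_vector(stats))


# ---------------------------------------------------------------------------
# Refitting
# ---------------------------------------------------------------------------

class ICRegression:
    """OLS model for interface conservation on alignment statistics.

    Parameters
    ----------
    stats
        Alignment statistics per pair, or an (n, 4) predictor array in the
        order (−log E, log L, PS, length fraction).
    observed_ic
        The IC score computed from known interfaces for each pair.
    """

    def __init__(self, stats: Sequence[AlignmentStatistics] | np.ndarray, observed_ic) -> None:
        y = np.asarray(observed_ic, dtype=float)
        if isinstance(stats, np.ndarray):
            X = np.asarray(stats, dtype=float)
        else:
            X = np.array([predictor_vector(s) for s in stats])
        if X.ndim != 2 or X.shape[1] != len(PREDICTOR_NAMES):
            raise ValueError(f"predictor matrix must be (n, {len(PREDICTOR_NAMES)})")
        if X.shape[0] != y.shape[0]:
            raise ValueError("stats and observed_ic lengths differ")
        if X.shape[0] < 10:
            raise ValueError("need at least 10 pairs to fit")
        self.exog = X
        self.endog = y
        self._check_rank()

    def _check_rank(self) -> None:
        design = np.column_stack([np.ones(len(self.endog)), self.exog])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            centered = self.exog - self.exog.mean(axis=0)
            norms = np.linalg.norm(centered, axis=0)
            degenerate = [
                PREDICTOR_NAMES[j] for j in range(len(norms)) if norms[j] < 1e-12
            ]
            if not degenerate:
                corr = np.corrcoef(self.exog, rowvar=False)
                degenerate = sorted(
                    {
                        PREDICTOR_NAMES[k]
                        for i in range(corr.shape[0])
                        for j in range(i + 1, corr.shape[1])
                        if abs(corr[i, j]) > 1 - 1e-10
                        for k in (i, j)
                    }
                )
            raise ValueError(
                "rank-deficient design; collinear predictors: "
                + (", ".join(degenerate) if degenerate else "undetermined")
            )

    def fit(self) -> "ICRegressionResults":
        import statsmodels.api as sm

        design = sm.add_constant(self.exog, has_constant="add")
        res = sm.OLS(self.endog, design).fit()
        # Type II SS: with no interaction terms, the drop in SSE from removing
        # one predictor equals t_j^2 * MSE.
        mse = res.mse_resid
        type2 = {
            name: float(res.tvalues[j + 1] ** 2 * mse)
            for j, name in enumerate(PREDICTOR_NAMES)
        }
        model = ICModel(
            intercept=float(res.params[0]),
            coef_neg_log_e=float(res.params[1]),
            coef_log_l=float(res.params[2]),
            coef_positive_score=float(res.params[3]),
            coef_length_fraction=float(res.params[4]),
        )
        return ICRegressionResults(self, model, res, type2)


class ICRegressionResults:
    """Fitted IC regression: coefficient table, diagnostics, summary()."""

    def __init__(self, model_obj: ICRegression, model: ICModel, sm_results, type2_ss: dict) -> None:
        self.model_obj = model_obj
        self.model = model
        self._sm = sm_results
        self.type2_ss = type2_ss

    @property
    def params(self) -> np.ndarray:
        return np.asarray(self._sm.params)

    @property
    def bse(self) -> np.ndarray:
        return np.asarray(self._sm.bse)

    @property
    def pvalues(self) -> np.ndarray:
        return np.asarray(self._sm.pvalues)

    @property
    def rsquared_adj(self) -> float:
        return float(self._sm.rsquared_adj)

    @property
    def fittedvalues(self) -> np.ndarray:
        return np.asarray(self._sm.fittedvalues)

    def summary(self) -> str:
        rows = [
            f"{'variable':<18}{'estimate':>12}{'std err':>12}{'type II SS':>14}"
        ]
        rows.append(
            f"{'intercept':<18}{self.params[0]:>12.4f}{self.bse[0]:>12.4f}{'':>14}"
        )
        for j, name in enumerate(PREDICTOR_NAMES):
            rows.append(
                f"{name:<18}{self.params[j + 1]:>12.4f}{self.bse[j + 1]:>12.4f}"
                f"{self.type2_ss[name]:>14.4f}"
            )
        rows.append(f"adjusted R^2: {self.rsquared_adj:.4f}  n = {len(self.model_obj.endog)}")
        return "\n".join(rows)


# ---------------------------------------------------------------------------
# Homology zones
# ---------------------------------------------------------------------------

class Zone(enum.IntEnum):
    """Reliability tiers for homology transfer, ordered worst → best."""

    NONE = 0
    DARK = 1
    TWILIGHT = 2
    SAFE = 3


@dataclass
class ZoneThresholds:
    """Predicted-IC cutoffs; each zone is closed below (ic >= cutoff)."""

    safe: float = 0.70
    twilight: float = 0.20
    dark: float = 0.15

    def __post_init__(self) -> None:
        if not (self.safe > self.twilight > self.dark >= -1.0):
            raise ValueError("need safe > twilight > dark >= -1")

    def to_config(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for f in fields(self):
                fh.write(f"{f.name} = {getattr(self, f.name)!r}\n")

    @classmethod
    def from_config(cls, path: str | Path) -> "ZoneThresholds":
        kwargs = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            kwargs[key.strip()] = float(value)
        return cls(**kwargs)


def assign_zone(predicted_ic: float, thresholds: ZoneThresholds | None = None) -> Zone:
    """Zone of a hit from its predicted IC; NONE means the hit is discarded."""
    t = thresholds or ZoneThresholds()
    if predicted_ic >= t.safe:
        return Zone.SAFE
    if predicted_ic >= t.twilight:
        return Zone.TWILIGHT
    if predicted_ic >= t.dark:
        return Zone.DARK
    return Zone.NONE
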