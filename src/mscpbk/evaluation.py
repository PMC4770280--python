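"""Model evaluation against observed data: bias, precision and fit quality.

Bias is the mean (signed) prediction error and precision the mean absolute
prediction error, both as percentages relative to the observed values
(the standard Sheiner-Beal forms)::

    MPE  = 100/N * sum((M_pred - M_obs) / M_obs)
    MAPE = 100/N * sum(|M_pred - M_obs| / M_obs)

95% confidence intervals are t-intervals over the per-pair (absolute)
relative errors. Amounts are compared on a cells-per-kg-of-organ scale so
that datasets from different species and organ sizes are commensurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .calibration import goodness_of_fit

__all__ = ["PredictionComparison", "normalize_to_cells_per_kg", "prediction_errors"]


def normalize_to_cells_per_kg(amount: float, organ_mass: float) -> float:
    """Convert a cell amount to cells per kg of organ.

    ``organ_mass`` is in kg; with tissue density 1 kg/L it equals the organ
    volume in litres.
    """
    if not organ_mass > 0:
        raise ValueError(f"organ mass must be > 0 kg, got {organ_mass!r}")
    return amount / organ_mass


@dataclass
class PredictionComparison:
    """Paired prediction/observation summary: bias, precision and R^2."""

    n: int
    mpe: float
    mpe_ci: tuple[float, float]
    mape: float
    mape_ci: tuple[float, float]
    r2: float | None

    def __post_init__(self) -> None:
        if self.mape < abs(self.mpe) - 1e-9:
            raise ValueError("MAPE cannot be smaller than |MPE|")


def _t_interval(values: np.ndarray, confidence: float = 0.95) -> tuple[float, float]:
    mean = float(np.mean(values))
    if len(values) < 2:
        return (mean, mean)
    se = float(np.std(values, ddof=1) / np.sqrt(len(values)))
    half = float(stats.t.ppf(0.5 + confidence / 2, df=len(values) - 1)) * se
    return (mean - half, mean + half)


def prediction_errors(pred, obs, confidence: float = 0.95) -> PredictionComparison:
    """Bias (MPE) and precision (MAPE) with t-distribution CIs.

    Requires paired series of equal length N >= 2 with strictly positive
    observed values (they are the denominators). R^2 is reported when at
    least 3 pairs with observed variance are available, else ``None``.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape or pred.ndim != 1:
        raise ValueError("pred and obs must be 1-D series of equal length")
    if len(pred) < 2:
        raise ValueError("need at least 2 pairs")
    if np.any(obs <= 0):
        raise ValueError("observed values must be strictly positive")
    rel = 100.0 * (pred - obs) / obs
    r2 = None
    if len(pred) >= 3 and np.ptp(np.log10(obs + 1.0)) > 0:
        r2 = goodness_of_fit(pred, obs)
    return PredictionComparison(
        n=len(pred),
        mpe=float(np.mean(rel)),
        mpe_ci=_t_interval(rel, confidence),
        mape=float(np.mean(np.abs(rel))),
        mape_ci=_t_interval(np.abs(rel), confidence),
        r2=r2,
    )
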