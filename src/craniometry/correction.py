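"""Quadratic bias correction of photographic cranial measurements.

Measurements taken off a 2-D top-view photograph carry a systematic error
relative to the clinical caliper values (projection, cap thickness, lens
geometry).  Each of the five parameters gets its own quadratic map

    Y = beta0 + beta1 * X + beta2 * X**2

from the raw photographic value X (cm) to the corrected estimate Y (cm),
fitted by ordinary least squares against reference measurements.  The
package bundles published coefficient sets for height (anteroposterior
length), width, perimeter, and the left/right transcranial diagonals.

Residual diagnostics report MAE, RMSE (or plain mean-square by flag),
a Shapiro-Wilk normality p-value, and a normal-theory 95 % confidence
interval for the mean residual.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import stats

#: Raw-measurement plausibility windows (cm): clinical ranges widened 20 %.
_CLINICAL = {
    "height": (12.0, 17.0),
    "width": (11.3, 14.5),
    "perimeter": (39.2, 51.0),
    "left_diagonal": (12.1, 15.9),
    "right_diagonal": (11.7, 16.9),
}
PARAMETERS = tuple(_CLINICAL)

#: Correction-parameter name -> morphometry measurement field (configurable;
#: "height" is the anteroposterior length and the left/right diagonals map to
#: diagonals A/B).
MEASUREMENT_FIELDS = {
    "height": "length_cm",
    "width": "width_cm",
    "perimeter": "perimeter_cm",
    "left_diagonal": "diag_a_cm",
    "right_diagonal": "diag_b_cm",
}


def plausibility_window(parameter: str, widen: float = 0.2) -> tuple[float, float]:
    lo, hi = _CLINICAL[parameter]
    span = hi - lo
    return lo - widen * span, hi + widen * span


@dataclass(frozen=True)
class CorrectionModel:
    """One parameter's quadratic raw -> corrected mapping."""

    parameter: str
    beta0: float
    beta1: float
    beta2: float
    diagnostics: Optional[dict] = field(default=None, compare=False)

    def __call__(self, x: float) -> float:
        return self.beta0 + self.beta1 * x + self.beta2 * x * x

    def to_dict(self) -> dict:
        return {
            "parameter": self.parameter,
            "beta0": self.beta0,
            "beta1": self.beta1,
            "beta2": self.beta2,
        }


def identity_model(parameter: str) -> CorrectionModel:
    return CorrectionModel(parameter, 0.0, 1.0, 0.0)


def default_models() -> dict[str, CorrectionModel]:
    """The coefficient sets bundled with the package, keyed by parameter."""
    raw = json.loads(
        resources.files("craniometry").joinpath("data/correction_defaults.json").read_text()
    )
    return {
        name: CorrectionModel(name, c["beta0"], c["beta1"], c["beta2"])
        for name, c in raw.items()
    }


def load_models(path: str | Path) -> dict[str, CorrectionModel]:
    raw = json.loads(Path(path).read_text())
    return {
        name: CorrectionModel(name, c["beta0"], c["beta1"], c["beta2"])
        for name, c in raw.items()
    }


def save_models(models: dict[str, CorrectionModel], path: str | Path) -> None:
    payload = {
        name: {"beta0": m.beta0, "beta1": m.beta1, "beta2": m.beta2}
        for name, m in models.items()
    }
    Path(path).write_text(json.dumps(payload, indent=2))


@dataclass(frozen=True)
class CorrectedValue:
    raw: float
    corrected: float
    extrapolated: bool


def apply_correction(
    model: CorrectionModel,
    x: float,
    window: Optional[tuple[float, float]] = None,
) -> CorrectedValue:
    """Evaluate the quadratic at ``x`` (cm).

    ``x`` outside the plausibility window marks the result as extrapolated
    (a warning flag, not a failure): the quadratic was fitted on clinical
    heads and bends over outside their range.
    """
    if window is None and model.parameter in _CLINICAL:
        window = plausibility_window(model.parameter)
    extrapolated = bool(window is not None and not (window[0] <= x <= window[1]))
    return CorrectedValue(raw=float(x), corrected=float(model(x)), extrapolated=extrapolated)


def fit_correction(
    x: Sequence[float], y: Sequence[float], parameter: str = "height"
) -> CorrectionModel:
    """Ordinary least-squares quadratic fit of corrected vs raw values."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    if np.unique(x).size < 3:
        raise ValueError("need at least 3 distinct x values for a quadratic fit")
    # Vandermonde least squares on centred x for conditioning
    xm = x.mean()
    design = np.column_stack([np.ones_like(x), x - xm, (x - xm) ** 2])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    c0, c1, c2 = coef
    beta2 = c2
    beta1 = c1 - 2.0 * c2 * xm
    beta0 = c0 - c1 * xm + c2 * xm * xm
    return CorrectionModel(parameter, float(beta0), float(beta1), float(beta2))


def residual_report(
    model: CorrectionModel,
    x: Sequence[float],
    y: Sequence[float],
    squared_error: str = "rmse",
    confidence: float = 0.95,
) -> dict:
    """Residual diagnostics for a fitted correction.

    Residuals are ``r = y - model(x)``.  ``squared_error`` selects between
    root-mean-square error in cm (default, comparable to the MAE) and the
    plain mean of squares (``"mse"``).  The normality p-value comes from the
    Shapiro-Wilk test; the confidence interval is the normal-theory interval
    for the mean residual.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    r = y - (model.beta0 + model.beta1 * x + model.beta2 * x * x)
    mae = float(np.mean(np.abs(r)))
    msq = float(np.mean(r * r))
    if squared_error == "rmse":
        mse_value = math.sqrt(msq)
    elif squared_error == "mse":
        mse_value = msq
    else:
        raise ValueError("squared_error must be 'rmse' or 'mse'")
    # Shapiro-Wilk is defined for 3 <= n <= 5000; subsample deterministically
    sample = r if n <= 5000 else r[:: max(1, n // 5000)][:5000]
    shapiro_p = float(stats.shapiro(sample).pvalue)
    sem = float(r.std(ddof=1) / math.sqrt(n))
    tcrit = float(stats.t.ppf(0.5 + confidence / 2.0, df=n - 1))
    mean_r = float(r.mean())
    return {
        "n": int(n),
        "mae": mae,
        "mse": float(mse_value),
        "shapiro_p": shapiro_p,
        "mean_residual": mean_r,
        "ci_low": mean_r - tcrit * sem,
        "ci_high": mean_r + tcrit * sem,
        "confidence": confidence,
    }
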