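"""Energy-expenditure prediction equations for wrist accelerometry.

Five published regression models are implemented, each with its floor and
ceiling bounds:

* ``hildebrand_linear`` / ``hildebrand_nonlinear`` — VO2 (ml/kg/min) from
  1-s ENMO; piecewise-linear and power-law forms, bounded to [3, 70].
* ``hibbing_2rm`` — two-regression MET models for the left and right
  wrist.  A sedentary cut-point on ENMO, then a CV cut-point separating
  continuous walking/running (log model) from intermittent activity
  (cubic), bounded to [1.25, 20] METs.
* ``staudenmayer_linear`` — METs from 15-s SD of vector magnitude and
  mean inclination angle, bounded to [1, 20].

A common conversion chain turns predictions into kcal/min: METs -> VO2 at
3.5 ml/kg/min per MET, VO2 -> kcal at 4.862 kcal per litre of O2 (Lusk
table at a respiratory quotient of 0.85), scaled by body weight.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .accel_features import EpochSeries

MODEL_IDS = (
    "hildebrand_linear",
    "hildebrand_nonlinear",
    "hibbing_left",
    "hibbing_right",
    "staudenmayer_linear",
)

ML_O2_PER_KG_PER_MET = 3.5
KCAL_PER_L_O2 = 4.862  # RQ 0.85

HILDEBRAND_BOUNDS = (3.0, 70.0)  # ml/kg/min
HIBBING_BOUNDS = (1.25, 20.0)  # METs
STAUDENMAYER_BOUNDS = (1.0, 20.0)  # METs

# Two-regression model constants, keyed by wrist side:
# sedentary ENMO cut (milli-g), CV cut (%), CWR log-model (intercept, slope on
# ln ENMO), IA cubic (c0..c3 on ENMO).
_HIBBING = {
    "left": {
        "enmo_cut": 45.6,
        "cv_cut": 19.4,
        "cwr": (-12.13, 3.1381),
        "ia": (0.81, 0.03033, -0.00005, 0.00000002),
    },
    "right": {
        "enmo_cut": 60.2,
        "cv_cut": 21.2,
        "cwr": (-8.86, 2.6564),
        "ia": (0.82, 0.03423, -0.00004, 0.00000004),
    },
}


def _check_nonneg(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr, dtype=float)
    if np.any(arr < 0) or not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite and non-negative")
    return arr


def hildebrand_linear(enmo: np.ndarray | float) -> np.ndarray:
    """Piecewise-linear VO2 (ml/kg/min) from 1-s ENMO (milli-g).

    3.0 below the 44.8 milli-g sedentary cut; 7.28 + 0.032*ENMO above,
    clamped to [3.0, 70.0].  The jump at the cut-point is a property of
    the published piecewise form, not an artefact.
    """
    enmo = _check_nonneg(enmo, "enmo")
    active = 7.28 + 0.032 * enmo
    out = np.where(enmo <= 44.8, 3.0, np.clip(active, *HILDEBRAND_BOUNDS))
    return out


def hildebrand_nonlinear(enmo: np.ndarray | float) -> np.ndarray:
    """Power-law VO2 (ml/kg/min) from 1-s ENMO: 0.901 * ENMO^0.534.

    The model has no intercept, so a floor of 3.0 ml/kg/min is applied
    (ENMO = 0 maps to the floor); ceiling 70.0.
    """
    enmo = _check_nonneg(enmo, "enmo")
    return np.clip(0.901 * np.power(enmo, 0.534), *HILDEBRAND_BOUNDS)


def hibbing_2rm(
    enmo: np.ndarray | float, cv: np.ndarray | float, side: str = "left"
) -> np.ndarray:
    """Two-regression MET prediction from 1-s ENMO and sliding-window CV.

    Seconds at or below the sedentary ENMO cut-point get a static 1.25
    METs.  Above it, low-CV seconds (continuous walking and running) use
    an ``a + b*ln(ENMO)`` model and high-CV seconds (intermittent
    activity) a cubic in ENMO.  Output clamped to [1.25, 20] METs.
    """
    if side not in _HIBBING:
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    c = _HIBBING[side]
    enmo = _check_nonneg(enmo, "enmo")
    cv = _check_nonneg(cv, "cv")
    enmo, cv = np.broadcast_arrays(enmo, cv)

    sedentary = enmo <= c["enmo_cut"]
    # natural log; guard the sedentary lane where ENMO may be 0
    with np.errstate(divide="ignore"):
        cwr = c["cwr"][0] + c["cwr"][1] * np.log(np.where(sedentary, 1.0, enmo))
    c0, c1, c2, c3 = c["ia"]
    ia = c0 + c1 * enmo + c2 * enmo**2 + c3 * enmo**3

    mets = np.where(sedentary, 1.25, np.where(cv <= c["cv_cut"], cwr, ia))
    return np.clip(mets, *HIBBING_BOUNDS)


def staudenmayer_linear(
    sd_vm: np.ndarray | float, mean_angle: np.ndarray | float
) -> np.ndarray:
    """Linear MET model on 15-s windows: SD of vector magnitude (g) and
    mean inclination angle (degrees), truncated to [1, 20] METs."""
    sd_vm = _check_nonneg(sd_vm, "sd_vm")
    mean_angle = np.asarray(mean_angle, dtype=float)
    mets = 1.89378 + 5.50821 * sd_vm - 0.02705 * mean_angle
    return np.clip(mets, *STAUDENMAYER_BOUNDS)


def mets_to_vo2(mets: np.ndarray | float) -> np.ndarray:
    """METs -> VO2 (ml/kg/min) at 1 MET = 3.5 ml/kg/min."""
    return np.asarray(mets, dtype=float) * ML_O2_PER_KG_PER_MET


def vo2_to_kcal_per_min(vo2: np.ndarray | float, weight_kg: float) -> np.ndarray:
    """VO2 (ml/kg/min) -> kcal/min for a given body weight.

    ``vo2 * weight / 1000`` litres O2 per minute, at 4.862 kcal/L
    (respiratory quotient 0.85).
    """
    if not np.isfinite(weight_kg) or weight_kg <= 0:
        raise ValueError(f"weight must be positive, got {weight_kg!r}")
    return np.asarray(vo2, dtype=float) * weight_kg / 1000.0 * KCAL_PER_L_O2


@dataclasses.dataclass
class MinuteEE:
    """Minute-level EE (kcal/min), one column per prediction model."""

    frame: pd.DataFrame  # index: minute_start; columns: model ids

    def __post_init__(self) -> None:
        if (self.frame.to_numpy() < 0).any():
            raise ValueError("kcal/min must be non-negative")


def minute_smooth(
    predictions: EpochSeries, weight_kg: float, units: str = "ml/kg/min"
) -> pd.Series:
    """Smooth per-epoch predictions to minute level and convert to kcal/min.

    Epoch predictions (1-s for the ENMO models, 15-s for the window model)
    are averaged over each whole minute, then converted METs -> VO2 ->
    kcal/min.  Trailing partial minutes are dropped.
    """
    if units not in ("ml/kg/min", "METs"):
        raise ValueError(f"unknown prediction units {units!r}")
    per_min = 60.0 / predictions.epoch_length
    if per_min != int(per_min):
        raise ValueError("epoch length must divide 60 s")
    per_min = int(per_min)
    vals = predictions.values
    n_min = len(vals) // per_min
    if n_min == 0:
        return pd.Series(
            np.empty(0), index=pd.DatetimeIndex([]), name="kcal_per_min", dtype=float
        )
    minute_mean = vals[: n_min * per_min].reshape(n_min, per_min).mean(axis=1)
    vo2 = mets_to_vo2(minute_mean) if units == "METs" else minute_mean
    kcal = vo2_to_kcal_per_min(vo2, weight_kg)
    idx = pd.DatetimeIndex(
        predictions.start + pd.to_timedelta(np.arange(n_min), unit="min")
    )
    return pd.Series(kcal, index=idx, name="kcal_per_min")


def predict_minute_ee(
    enmo_1s: EpochSeries,
    cv_1s: EpochSeries,
    window_feats,
    weight_kg: float,
    models: tuple[str, ...] = MODEL_IDS,
) -> MinuteEE:
    """Run every requested model and assemble a minute-level kcal/min table."""
    cols = {}
    for model in models:
        if model == "hildebrand_linear":
            pred = EpochSeries(enmo_1s.start, 1.0, hildebrand_linear(enmo_1s.values),
                               model, "ml/kg/min")
            cols[model] = minute_smooth(pred, weight_kg, "ml/kg/min")
        elif model == "hildebrand_nonlinear":
            pred = EpochSeries(enmo_1s.start, 1.0, hildebrand_nonlinear(enmo_1s.values),
                               model, "ml/kg/min")
            cols[model] = minute_smooth(pred, weight_kg, "ml/kg/min")
        elif model in ("hibbing_left", "hibbing_right"):
            side = model.split("_")[1]
            mets = hibbing_2rm(enmo_1s.values, cv_1s.values, side)
            pred = EpochSeries(enmo_1s.start, 1.0, mets, model, "METs")
            cols[model] = minute_smooth(pred, weight_kg, "METs")
        elif model == "staudenmayer_linear":
            mets = staudenmayer_linear(window_feats.sd_vm, window_feats.mean_angle)
            pred = EpochSeries(window_feats.start, window_feats.window_length,
                               mets, model, "METs")
            cols[model] = minute_smooth(pred, weight_kg, "METs")
        else:
            raise ValueError(f"unknown model id {model!r}")
    frame = pd.DataFrame(cols)
    frame.index.name = "minute_start"
    return MinuteEE(frame)
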