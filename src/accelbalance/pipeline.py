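"""High-level glue: raw trace -> features -> minute EE -> daily EE -> EI.

These helpers chain the stage modules for one participant-period and are
what the command-line interface (and the simulation smoke paths) call.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import accel_features as af
from . import ee_models as ee
from . import wear_screening as ws
from .intake_balance import BodyCompPair, EIEstimate, delta_es, estimate_ei
from .io import RunConfig

logger = logging.getLogger(__name__)


def extract_features(
    trace: af.RawTrace, config: RunConfig | None = None
) -> tuple[af.EpochSeries, af.EpochSeries, af.WindowFeatures]:
    """1-s ENMO, sliding-window CV and 15-s window features for a trace."""
    config = config or RunConfig()
    enmo = af.compute_enmo(trace)
    enmo_1s = af.aggregate_epochs(
        enmo, trace.sample_rate, config.epoch_length, start=trace.start
    )
    cv_1s = af.sliding_cv(enmo_1s, window=config.cv_window)
    feats = af.staudenmayer_features(
        trace, window=config.staudenmayer_window, reference_axis=config.reference_axis
    )
    return enmo_1s, cv_1s, feats


def minute_enmo(enmo_1s: af.EpochSeries) -> pd.Series:
    """Minute-level mean ENMO (for non-wear screening)."""
    per_min = int(round(60.0 / enmo_1s.epoch_length))
    n_min = len(enmo_1s) // per_min
    vals = enmo_1s.values[: n_min * per_min].reshape(n_min, per_min).mean(axis=1)
    idx = pd.DatetimeIndex(enmo_1s.start + pd.to_timedelta(np.arange(n_min), unit="min"))
    return pd.Series(vals, index=idx, name="enmo")


def screen_wear(
    enmo_min: pd.Series,
    sleep_mask: pd.Series | None = None,
    config: RunConfig | None = None,
) -> pd.Series:
    """Minute mask from non-wear detection plus a sleep source.

    ``sleep_mask`` is an externally supplied per-minute state series (only
    its sleep minutes are used).  Without one, the fixed-window fallback
    from the config applies.
    """
    config = config or RunConfig()
    params = ws.ChoiParams(
        min_period=config.choi_min_period, zero_threshold=config.choi_zero_threshold
    )
    nonwear = ws.choi_nonwear(enmo_min, params)
    if sleep_mask is not None:
        sleep = (
            sleep_mask.reindex(enmo_min.index, fill_value=ws.STATE_AWAKE)
            == ws.STATE_SLEEP
        ).to_numpy()
    else:
        sleep = ws.fixed_sleep_window(
            pd.DatetimeIndex(enmo_min.index), *config.sleep_window
        )
    return ws.build_minute_mask(pd.DatetimeIndex(enmo_min.index), nonwear, sleep)


def participant_period_ei(
    minute_ee: ee.MinuteEE,
    mask: pd.Series,
    participant: ws.Participant,
    pair: BodyCompPair,
    period: str = "1",
    config: RunConfig | None = None,
) -> tuple[pd.DataFrame, list[EIEstimate], bool]:
    """Daily totals, per-model EI estimates and the valid-participant flag."""
    config = config or RunConfig()
    bmr = ws.schofield_bmr(participant)
    daily = ws.impute_and_total(
        minute_ee, mask, bmr, valid_day_minutes=config.valid_day_minutes
    )
    _, participant_valid = ws.screen_valid(
        mask, config.valid_day_minutes, config.min_valid_days
    )
    if not participant_valid:
        logger.warning(
            "participant %s period %s has < %d valid days",
            participant.id, period, config.min_valid_days,
        )
        return daily, [], False
    mean_ee = ws.period_mean_ee(daily, config.models)
    des = delta_es(pair)
    estimates = [
        estimate_ei(mean_ee[m], des, participant.id, period, m)
        for m in config.models if m in mean_ee.index
    ]
    return daily, estimates, True
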