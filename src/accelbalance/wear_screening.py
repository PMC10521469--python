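"""Wear-time screening, valid-day rules and basal-EE imputation.

Every minute of a recording is classified as awake wear, sleep or
non-wear.  Non-wear is detected from minute-level activity with the
consecutive-zero-run rule of the standard 90-minute algorithm; sleep is
taken from an external minute mask (or a fixed-window fallback for
simulations).  A day is *valid* with >= 10 h (600 min) of awake wear, and
a participant is retained with >= 4 valid days.  On valid days, sleep and
non-wear minutes are imputed at the basal rate (sex/age/weight/height
BMR / 1440) and daily totals, then period means, are produced per model.
"""

from __future__ import annotations

import dataclasses
import functools
import importlib.resources
import logging

import numpy as np
import pandas as pd
import yaml

from .ee_models import MODEL_IDS, MinuteEE

logger = logging.getLogger(__name__)

KCAL_PER_MJ = 239.006
VALID_DAY_MINUTES = 600  # >= 10 h awake wear
MIN_VALID_DAYS = 4

STATE_AWAKE = "awake_wear"
STATE_SLEEP = "sleep"
STATE_NONWEAR = "non_wear"
STATES = (STATE_AWAKE, STATE_SLEEP, STATE_NONWEAR)


@dataclasses.dataclass
class Participant:
    id: str
    sex: str  # 'female' | 'male'
    age: float  # years
    weight: float  # kg
    height: float  # cm

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise ValueError(f"sex must be 'female' or 'male', got {self.sex!r}")
        if min(self.age, self.weight, self.height) <= 0:
            raise ValueError("age, weight and height must be positive")


@dataclasses.dataclass
class ChoiParams:
    """Parameters of the consecutive-zero-run non-wear rule."""

    min_period: int = 90  # minimum non-wear window, minutes
    spike_tolerance: int = 2  # max length of one interruption, minutes
    max_interrupt_minutes: int = 2  # max total interruption minutes per window
    flank: int = 30  # required zero minutes either side of an interruption
    zero_threshold: float = 1.0  # minute ENMO below this counts as zero activity


def _runs(mask: np.ndarray) -> list[tuple[int, int, bool]]:
    """Run-length encode a boolean array as (start, length, value)."""
    out = []
    n = len(mask)
    i = 0
    while i < n:
        j = i
        while j < n and mask[j] == mask[i]:
            j += 1
        out.append((i, j - i, bool(mask[i])))
        i = j
    return out


def choi_nonwear(
    minute_values: pd.Series | np.ndarray, params: ChoiParams | None = None
) -> np.ndarray:
    """Flag non-wear minutes from a contiguous minute-level activity series.

    A minute is non-wear iff it lies in a window of at least
    ``min_period`` consecutive zero-activity minutes, where up to
    ``max_interrupt_minutes`` interrupting nonzero minutes are tolerated
    provided each interruption is at most ``spike_tolerance`` minutes long
    and is flanked by at least ``flank`` zero minutes on both sides.
    Tolerated interruption minutes inside a qualifying window are
    themselves flagged.

    Returns a boolean array aligned with the input.
    """
    params = params or ChoiParams()
    if isinstance(minute_values, pd.Series):
        if len(minute_values) > 1:
            deltas = np.diff(minute_values.index.values).astype("timedelta64[s]")
            gaps = np.flatnonzero(deltas != np.timedelta64(60, "s"))
            if gaps.size:
                missing = [str(minute_values.index[g]) for g in gaps[:5]]
                raise ValueError(f"minute series has gaps after: {missing}")
        values = minute_values.to_numpy(dtype=float)
    else:
        values = np.asarray(minute_values, dtype=float)

    n = len(values)
    nonwear = np.zeros(n, dtype=bool)
    if n == 0:
        return nonwear
    zero = values < params.zero_threshold

    runs = _runs(zero)
    zero_runs = [(s, l) for s, l, v in runs if v]
    if not zero_runs:
        return nonwear

    # interruption between consecutive zero runs is tolerated if short and
    # flanked by long-enough zero runs on both sides
    def tolerated(k: int) -> bool:
        s0, l0 = zero_runs[k]
        s1, l1 = zero_runs[k + 1]
        gap = s1 - (s0 + l0)
        return gap <= params.spike_tolerance and l0 >= params.flank and l1 >= params.flank

    # two-pointer over chains of zero runs linked by tolerated interruptions,
    # keeping total interruption minutes within the allowance
    k = len(zero_runs)
    a = 0
    while a < k:
        b = a
        interrupt = 0
        while True:
            span_start = zero_runs[a][0]
            span_end = zero_runs[b][0] + zero_runs[b][1]
            if span_end - span_start >= params.min_period:
                nonwear[span_start:span_end] = True
            if b + 1 < k and tolerated(b):
                gap = zero_runs[b + 1][0] - span_end
                if interrupt + gap <= params.max_interrupt_minutes:
                    interrupt += gap
                    b += 1
                    continue
            break
        a += 1
    return nonwear


def fixed_sleep_window(
    minutes: pd.DatetimeIndex, start: str = "23:00", end: str = "07:00"
) -> np.ndarray:
    """Fallback sleep mask: True inside a fixed clock window (may wrap
    midnight).  Used for simulations when no external sleep mask exists."""
    t0 = pd.Timestamp(f"2000-01-01 {start}").time()
    t1 = pd.Timestamp(f"2000-01-01 {end}").time()
    tod = minutes.time
    if t0 <= t1:
        return np.array([(t0 <= t) & (t < t1) for t in tod])
    return np.array([(t >= t0) | (t < t1) for t in tod])


def build_minute_mask(
    minutes: pd.DatetimeIndex,
    nonwear: np.ndarray | set,
    sleep: np.ndarray | set,
) -> pd.Series:
    """Combine non-wear and sleep flags into a per-minute state series.

    Precedence: non_wear > sleep > awake_wear.  Overlaps are resolved by
    that order and logged.
    """

    def to_bool(flags) -> np.ndarray:
        if isinstance(flags, (set, frozenset)):
            return np.array([m in flags for m in minutes])
        arr = np.asarray(flags, dtype=bool)
        if len(arr) != len(minutes):
            raise ValueError("flag array length does not match minute index")
        return arr

    nw = to_bool(nonwear)
    sl = to_bool(sleep)
    overlap = int((nw & sl).sum())
    if overlap:
        logger.info("%d minutes flagged both non-wear and sleep; kept non-wear", overlap)
    state = np.where(nw, STATE_NONWEAR, np.where(sl, STATE_SLEEP, STATE_AWAKE))
    return pd.Series(state, index=minutes, name="state")


def screen_valid(
    mask: pd.Series,
    valid_day_minutes: int = VALID_DAY_MINUTES,
    min_valid_days: int = MIN_VALID_DAYS,
) -> tuple[pd.DataFrame, bool]:
    """Apply the valid-day and valid-participant rules to a minute mask.

    Returns a per-day frame (awake/sleep/non-wear minute counts, valid
    flag) and the participant-level flag (>= ``min_valid_days`` valid
    days).  First and last partial days participate under the same rule.
    """
    df = pd.DataFrame({"state": mask, "date": mask.index.normalize()})
    counts = (
        df.groupby(["date", "state"], observed=False).size().unstack(fill_value=0)
    )
    for s in STATES:
        if s not in counts:
            counts[s] = 0
    daily = counts[list(STATES)].copy()
    daily.columns = [f"{s}_minutes" for s in STATES]
    daily["valid"] = daily["awake_wear_minutes"] >= valid_day_minutes
    participant_valid = bool(daily["valid"].sum() >= min_valid_days)
    return daily, participant_valid


@functools.cache
def _schofield_table() -> tuple[dict, ...]:
    text = (
        importlib.resources.files("accelbalance").joinpath("schofield.yaml").read_text()
    )
    return tuple(yaml.safe_load(text))


def schofield_bmr(p: Participant) -> float:
    """Basal metabolic rate (kcal/day) from the sex- and age-specific
    weight+height coefficient table.

    Coefficients are in MJ/day with height in metres; the result is
    converted at 239.006 kcal/MJ.
    """
    for row in _schofield_table():
        if row["sex"] == p.sex and row["age_low"] <= p.age < row["age_high"]:
            mj = (
                row["weight_coef"] * p.weight
                + row["height_coef"] * (p.height / 100.0)
                + row["intercept"]
            )
            return mj * KCAL_PER_MJ
    raise ValueError(f"no BMR coefficient band for sex={p.sex}, age={p.age}")


def impute_and_total(
    minute_ee: MinuteEE,
    mask: pd.Series,
    bmr: float,
    valid_day_minutes: int = VALID_DAY_MINUTES,
) -> pd.DataFrame:
    """Daily EE totals (kcal) per model on valid days.

    Awake-wear minutes contribute their predicted kcal/min; sleep and
    non-wear minutes are imputed at ``bmr / 1440`` kcal/min.  Days that
    fail the awake-wear rule are excluded entirely.

    Returns a frame indexed by date with one total column per model plus
    ``awake_wear_minutes``, ``imputed_minutes`` and ``valid``.
    """
    ee = minute_ee.frame
    awake_idx = mask.index[mask == STATE_AWAKE]
    missing = awake_idx.difference(ee.index)
    if len(missing):
        raise ValueError(
            f"{len(missing)} awake-wear minutes lack EE predictions, "
            f"first at {missing[0]}"
        )
    basal_per_min = bmr / 1440.0

    df = pd.DataFrame(index=mask.index)
    df["date"] = df.index.normalize()
    df["awake"] = (mask == STATE_AWAKE).to_numpy()
    for model in ee.columns:
        kcal = ee[model].reindex(mask.index)
        df[model] = np.where(df["awake"], kcal, basal_per_min)

    models = list(ee.columns)
    daily = df.groupby("date").agg(
        awake_wear_minutes=("awake", "sum"), **{m: (m, "sum") for m in models}
    )
    n_minutes = df.groupby("date").size()
    daily["imputed_minutes"] = n_minutes - daily["awake_wear_minutes"]
    daily["valid"] = daily["awake_wear_minutes"] >= valid_day_minutes
    return daily[daily["valid"]].copy()


def period_mean_ee(daily: pd.DataFrame, models: tuple[str, ...] = MODEL_IDS) -> pd.Series:
    """Mean daily EE (kcal/day) per model across valid days."""
    present = [m for m in models if m in daily.columns]
    if daily.empty:
        raise ValueError("no valid days; participant should be excluded upstream")
    return daily[present].mean(axis=0)
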