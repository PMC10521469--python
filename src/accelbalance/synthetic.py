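"""Synthetic study-data generation with known ground truth.

Everything the pipeline consumes can be simulated: multi-day minute
schedules over six behavioural states (sleep, non-wear, sedentary,
walking, running, intermittent activity), raw tri-axial traces rendered
from those schedules, body-composition pairs constructed to hit a target
daily change in energy storage, and cohorts of paired predicted/criterion
energy-intake occasions with a specified mixed bias structure.

Locomotion is rendered as gravity plus a sinusoid whose amplitude is
calibrated (closed-form phase average plus a root solve) so the 1-s ENMO
of each state lands on its target, which is enough to drive every branch
of the prediction equations and the CV classifier; biomechanical realism
is a non-goal.  Non-wear blocks are rendered as an exactly still device,
giving exact-zero ENMO minutes for the non-wear detector.  All generators
are deterministic given (configuration, seed).
"""

from __future__ import annotations

import dataclasses
import functools

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .accel_features import RawTrace, aggregate_epochs, compute_enmo
from .ee_models import KCAL_PER_L_O2, ML_O2_PER_KG_PER_MET
from .intake_balance import KCAL_PER_KG_FFM, KCAL_PER_KG_FM, BodyCompPair, delta_es
from .wear_screening import STATE_AWAKE, STATE_NONWEAR, STATE_SLEEP, Participant

SIM_STATES = ("sleep", "non_wear", "sedentary", "walk", "run", "intermittent")

LOCOMOTION_HZ = 2.0  # dominant arm-swing frequency for rendered gait


@dataclasses.dataclass
class StateParams:
    """Rendering and truth parameters for one behavioural state."""

    true_mets: float  # >= 1
    target_enmo: float = 0.0  # milli-g, 1-s mean for rendered signal
    noise_sd: float = 0.0  # g, per-axis Gaussian noise
    enmo_lo: float | None = None  # intermittent: alternating second targets
    enmo_hi: float | None = None


#: Defaults chosen so each state triggers the regime it names: sedentary and
#: sleep sit below every sedentary cut-point (44.8 / 45.6 / 60.2 milli-g),
#: walking and running exceed them with steady signal (low CV -> the
#: continuous walking/running branch), and intermittent activity alternates
#: second-level intensity for a high CV (> 21.2 %).
DEFAULT_STATE_PARAMS: dict[str, StateParams] = {
    "sleep": StateParams(true_mets=1.0, noise_sd=0.010),
    "non_wear": StateParams(true_mets=1.0),
    "sedentary": StateParams(true_mets=1.3, noise_sd=0.015),
    "walk": StateParams(true_mets=3.5, target_enmo=200.0, noise_sd=0.003),
    "run": StateParams(true_mets=8.0, target_enmo=700.0, noise_sd=0.003),
    "intermittent": StateParams(
        true_mets=4.0, noise_sd=0.003, enmo_lo=80.0, enmo_hi=470.0
    ),
}


@dataclasses.dataclass
class ScheduleProfile:
    """Daily behaviour mix for the schedule generator.

    Defaults emulate the free-living cohort the pipeline targets: about
    8.6 h/day of sleep, occasional non-wear blocks long enough to be
    detectable (>= 90 min, averaging a few tenths of an hour per day),
    and a handful of activity bouts on a sedentary background.
    """

    sleep_onset_minute: int = 1380  # 23:00
    sleep_duration_mean_h: float = 8.6
    sleep_duration_sd_h: float = 0.25
    nonwear_prob_per_day: float = 0.15
    nonwear_len_range: tuple[int, int] = (90, 180)
    walk_bouts: int = 2
    walk_bout_min: int = 30
    run_bouts: int = 1
    run_bout_min: int = 20
    intermittent_bouts: int = 2
    intermittent_bout_min: int = 20


@dataclasses.dataclass
class ActivitySchedule:
    """A per-minute behavioural state sequence with truth parameters."""

    start: pd.Timestamp
    states: np.ndarray  # len = days * 1440, values in SIM_STATES
    state_params: dict[str, StateParams]

    def __post_init__(self) -> None:
        self.start = pd.Timestamp(self.start)
        bad = set(np.unique(self.states)) - set(SIM_STATES)
        if bad:
            raise ValueError(f"unknown states {bad}")
        if any(p.true_mets < 1 for p in self.state_params.values()):
            raise ValueError("true METs must be >= 1")

    @property
    def n_days(self) -> int:
        return len(self.states) // 1440

    def minutes(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(
            self.start + pd.to_timedelta(np.arange(len(self.states)), unit="min")
        )

    def wear_states(self) -> pd.Series:
        """Collapse to the three wear states the screening module uses."""
        out = np.where(
            self.states == "non_wear",
            STATE_NONWEAR,
            np.where(self.states == "sleep", STATE_SLEEP, STATE_AWAKE),
        )
        return pd.Series(out, index=self.minutes(), name="state")


def gen_schedule(
    days: int,
    profile: ScheduleProfile | None = None,
    seed: int = 0,
    start: str | pd.Timestamp = "2024-01-01",
    state_params: dict[str, StateParams] | None = None,
) -> ActivitySchedule:
    """Generate a reproducible minute-state schedule for ``days`` days."""
    if days < 1:
        raise ValueError("days must be >= 1")
    profile = profile or ScheduleProfile()
    params = state_params or DEFAULT_STATE_PARAMS
    rng = np.random.default_rng(seed)

    bout_budget = (
        profile.walk_bouts * profile.walk_bout_min
        + profile.run_bouts * profile.run_bout_min
        + profile.intermittent_bouts * profile.intermittent_bout_min
    )
    if bout_budget + profile.sleep_duration_mean_h * 60 > 1440:
        raise ValueError("daily state proportions exceed 1440 minutes")

    states = np.full(days * 1440, "sedentary", dtype=object)
    evening = 1440 - profile.sleep_onset_minute
    for d in range(days):
        base = d * 1440
        dur = rng.normal(profile.sleep_duration_mean_h, profile.sleep_duration_sd_h)
        dur_min = int(round(np.clip(dur, 6.0, 11.0) * 60))
        wake = max(dur_min - evening, 0)
        states[base : base + wake] = "sleep"
        states[base + profile.sleep_onset_minute : base + 1440] = "sleep"

        day_free = (wake + 30, profile.sleep_onset_minute - 30)

        if rng.random() < profile.nonwear_prob_per_day:
            length = int(rng.integers(*profile.nonwear_len_range, endpoint=True))
            lo, hi = day_free[0], day_free[1] - length
            if hi > lo:
                s = int(rng.integers(lo, hi))
                states[base + s : base + s + length] = "non_wear"

        bouts = (
            [("walk", profile.walk_bout_min)] * profile.walk_bouts
            + [("run", profile.run_bout_min)] * profile.run_bouts
            + [("intermittent", profile.intermittent_bout_min)] * profile.intermittent_bouts
        )
        for name, length in bouts:
            for _ in range(20):  # rejection sampling onto sedentary background
                lo, hi = day_free[0], day_free[1] - length
                if hi <= lo:
                    break
                s = int(rng.integers(lo, hi))
                if np.all(states[base + s : base + s + length] == "sedentary"):
                    states[base + s : base + s + length] = name
                    break

    return ActivitySchedule(start=pd.Timestamp(start), states=states, state_params=params)


@functools.lru_cache(maxsize=None)
def amplitude_for_enmo(target_mg: float) -> float:
    """Sinusoid amplitude (g) whose gravity-superposed phase-average ENMO
    equals ``target_mg`` milli-g.  Solved numerically; the phase average is
    the closed-form limit of the per-second ENMO mean."""
    if target_mg <= 0:
        return 0.0
    phases = np.linspace(0.0, 2.0 * np.pi, 720, endpoint=False)
    sin2 = np.sin(phases) ** 2

    def mean_enmo(a: float) -> float:
        return float((np.sqrt(1.0 + a * a * sin2) - 1.0).mean() * 1000.0)

    return brentq(lambda a: mean_enmo(a) - target_mg, 0.0, 50.0, xtol=1e-12)


def _per_second_targets(
    schedule: ActivitySchedule, minute_lo: int, minute_hi: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-second (target ENMO, noise sd) arrays for a minute range."""
    states = schedule.states[minute_lo:minute_hi]
    n_sec = len(states) * 60
    target = np.zeros(n_sec)
    noise = np.zeros(n_sec)
    sec_state = np.repeat(states, 60)
    abs_sec = minute_lo * 60 + np.arange(n_sec)
    for name, p in schedule.state_params.items():
        m = sec_state == name
        if not m.any():
            continue
        noise[m] = p.noise_sd
        if p.enmo_lo is not None:  # intermittent: alternate by absolute second
            target[m] = np.where(abs_sec[m] % 2 == 0, p.enmo_lo, p.enmo_hi)
        else:
            target[m] = p.target_enmo
    return target, noise


def render_trace(
    schedule: ActivitySchedule,
    sample_rate: int = 30,
    seed: int = 0,
    minute_range: tuple[int, int] | None = None,
) -> RawTrace:
    """Render a raw tri-axial trace for (a slice of) a schedule.

    Still states are gravity on the z axis plus per-axis Gaussian noise;
    locomotion adds a calibrated sinusoid on the x axis at ~2 Hz; non-wear
    is an exactly still device (zero ENMO).  The noise stream is seeded by
    ``(seed, minute_range start)`` so day-by-day chunked rendering is
    itself deterministic.
    """
    lo, hi = minute_range if minute_range is not None else (0, len(schedule.states))
    if not (0 <= lo < hi <= len(schedule.states)):
        raise ValueError(f"minute_range {minute_range} out of bounds")
    target, noise_sd = _per_second_targets(schedule, lo, hi)
    n_sec = len(target)
    n = n_sec * sample_rate

    amp_sec = np.array([amplitude_for_enmo(t) for t in np.unique(target)])
    amp_map = dict(zip(np.unique(target), amp_sec))
    amp = np.vectorize(amp_map.get)(target).astype(float)

    t = np.arange(n) / sample_rate
    amp_samples = np.repeat(amp, sample_rate)
    sd_samples = np.repeat(noise_sd, sample_rate)

    rng = np.random.default_rng([seed, lo])
    x = amp_samples * np.sin(2.0 * np.pi * LOCOMOTION_HZ * t)
    y = np.zeros(n)
    z = np.ones(n)
    active = sd_samples > 0
    x[active] += rng.standard_normal(active.sum()) * sd_samples[active]
    y[active] += rng.standard_normal(active.sum()) * sd_samples[active]
    z[active] += rng.standard_normal(active.sum()) * sd_samples[active]

    start = schedule.start + pd.Timedelta(minutes=lo)
    return RawTrace(start=start, sample_rate=sample_rate, x=x, y=y, z=z)


def simulate_minute_enmo(
    schedule: ActivitySchedule, sample_rate: int = 20, seed: int = 0
) -> pd.Series:
    """Minute-level mean ENMO for a whole schedule, rendered day by day.

    Chunked rendering keeps memory flat for multi-week schedules; the
    result is what the non-wear detector screens.
    """
    chunks = []
    for d in range(schedule.n_days):
        trace = render_trace(
            schedule, sample_rate=sample_rate, seed=seed,
            minute_range=(d * 1440, (d + 1) * 1440),
        )
        enmo = compute_enmo(trace)
        ep = aggregate_epochs(enmo, sample_rate, 60.0, start=trace.start)
        chunks.append(pd.Series(ep.values, index=ep.epoch_starts()))
    out = pd.concat(chunks)
    out.name = "enmo"
    return out


def true_minute_kcal(schedule: ActivitySchedule, participant: Participant) -> pd.Series:
    """Ground-truth kcal/min for every minute, from the schedule's METs."""
    mets = np.array(
        [schedule.state_params[s].true_mets for s in schedule.states], dtype=float
    )
    kcal = mets * ML_O2_PER_KG_PER_MET * participant.weight / 1000.0 * KCAL_PER_L_O2
    return pd.Series(kcal, index=schedule.minutes(), name="kcal_per_min")


@dataclasses.dataclass
class SimTruth:
    """Ground truth for one simulated participant-period."""

    daily_ee: pd.Series  # kcal per calendar day (basal-imputed sleep/non-wear)
    mean_ee: float  # kcal/day over all days
    delta_es: float  # kcal/day
    ei: float  # kcal/day; always mean_ee + delta_es
    body_comp: BodyCompPair


def summarize_truth(
    schedule: ActivitySchedule,
    participant: Participant,
    bmr: float,
    target_delta_es: float = -117.0,
    ffm_fraction: float = 0.3,
    ffm_start: float = 52.5,
    fm_start: float = 21.4,
) -> SimTruth:
    """True daily EE, ΔES and EI for a simulated participant-period.

    True daily EE counts awake minutes at the schedule's METs and sleep /
    non-wear minutes at the basal rate (bmr / 1440) — the same accounting
    the pipeline applies — so that a pipeline run with truth substituted
    for the EE model conserves energy exactly.  The body-composition pair
    is built by inverting the storage equation at ``target_delta_es``.
    """
    kcal = true_minute_kcal(schedule, participant)
    awake = schedule.wear_states() == STATE_AWAKE
    per_min = np.where(awake.to_numpy(), kcal.to_numpy(), bmr / 1440.0)
    daily = pd.Series(per_min, index=kcal.index).groupby(kcal.index.normalize()).sum()

    d_ffm, d_fm = invert_delta_es(target_delta_es, schedule.n_days, ffm_fraction)
    pair = BodyCompPair(
        ffm_start=ffm_start, ffm_end=ffm_start + d_ffm,
        fm_start=fm_start, fm_end=fm_start + d_fm,
        elapsed_days=float(schedule.n_days),
    )
    mean_ee = float(daily.mean())
    des = delta_es(pair)
    return SimTruth(
        daily_ee=daily, mean_ee=mean_ee, delta_es=des, ei=mean_ee + des,
        body_comp=pair,
    )


def invert_delta_es(
    target: float, days: float, ffm_fraction: float
) -> tuple[float, float]:
    """Split a target ΔES (kcal/day) into (ΔFFM, ΔFM) in kg.

    ``ffm_fraction`` of the stored energy goes to fat-free mass; the
    storage equation applied to the result returns ``target`` exactly.
    """
    if not 0.0 <= ffm_fraction <= 1.0:
        raise ValueError("ffm_fraction must lie in [0, 1]")
    energy = target * days
    d_ffm = ffm_fraction * energy / KCAL_PER_KG_FFM
    d_fm = (1.0 - ffm_fraction) * energy / KCAL_PER_KG_FM
    return d_ffm, d_fm


def gen_validity_cohort(
    n_participants: int,
    occasions: int = 2,
    bias_mean: float = 0.0,
    sd_between: float = 300.0,
    sd_resid: float = 200.0,
    slope: float = 0.0,
    seed: int = 0,
    criterion_center: float = 2382.0,
    criterion_sd_between: float = 400.0,
    criterion_sd_within: float = 300.0,
) -> pd.DataFrame:
    """Paired predicted/criterion EI occasions with a known bias structure.

    Criterion EI is drawn around ``criterion_center`` (default the
    criterion cohort mean of 2382 kcal/day) with between-participant and
    within-participant components.  The predicted value is the criterion
    plus ``bias_mean + slope * (criterion − center) + b_i + e_ij`` with
    ``b_i ~ N(0, sd_between²)`` and ``e_ij ~ N(0, sd_resid²)``.
    """
    if n_participants < 2:
        raise ValueError("need at least 2 participants")
    if min(sd_between, sd_resid, criterion_sd_between, criterion_sd_within) < 0:
        raise ValueError("SDs must be non-negative")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_participants):
        pid = f"P{i:03d}"
        crit_i = criterion_center + rng.normal(0.0, criterion_sd_between)
        b_i = rng.normal(0.0, sd_between)
        for j in range(occasions):
            crit = crit_i + rng.normal(0.0, criterion_sd_within)
            bias = (
                bias_mean
                + slope * (crit - criterion_center)
                + b_i
                + rng.normal(0.0, sd_resid)
            )
            rows.append(
                {
                    "participant": pid,
                    "occasion": j,
                    "criterion_ei": crit,
                    "predicted_ei": crit + bias,
                }
            )
    return pd.DataFrame(rows)
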