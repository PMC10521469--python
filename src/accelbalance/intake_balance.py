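"""Intake-balance energy-intake estimation.

The energy-balance identity ``ΔES = EI − EE`` lets energy intake be
back-calculated from measured expenditure and the concurrent change in
energy storage: ``EI = EE + ΔES``.  ΔES is computed from two-timepoint
body composition at fixed tissue energy densities — 1020 kcal per kg of
fat-free mass and 9500 kcal per kg of fat mass — scaled by the length of
the measurement period in days.
"""

from __future__ import annotations

import dataclasses

KCAL_PER_KG_FFM = 1020.0
KCAL_PER_KG_FM = 9500.0


@dataclasses.dataclass
class BodyCompPair:
    """Fat-free and fat mass (kg) at the start and end of a period."""

    ffm_start: float
    ffm_end: float
    fm_start: float
    fm_end: float
    elapsed_days: float

    def __post_init__(self) -> None:
        if min(self.ffm_start, self.ffm_end, self.fm_start, self.fm_end) <= 0:
            raise ValueError("all masses must be positive")
        if self.elapsed_days <= 0:
            raise ValueError(f"elapsed_days must be positive, got {self.elapsed_days}")

    @property
    def delta_ffm(self) -> float:
        return self.ffm_end - self.ffm_start

    @property
    def delta_fm(self) -> float:
        return self.fm_end - self.fm_start


@dataclasses.dataclass
class EIEstimate:
    """An energy-intake estimate for one participant-period-model cell."""

    participant: str
    period: str
    model_id: str
    mean_ee: float  # kcal/day
    delta_es: float  # kcal/day
    ei: float  # kcal/day


def delta_es(pair: BodyCompPair) -> float:
    """Daily change in energy storage (kcal/day) from a body-comp pair.

    ``(1020 * ΔFFM + 9500 * ΔFM) / elapsed_days``.  The denominator is
    the actual period length in days (possibly fractional); the canonical
    protocol length is 14 days.
    """
    return (
        KCAL_PER_KG_FFM * pair.delta_ffm + KCAL_PER_KG_FM * pair.delta_fm
    ) / pair.elapsed_days


def estimate_ei(
    mean_ee: float,
    des: float,
    participant: str = "",
    period: str = "",
    model_id: str = "",
) -> EIEstimate:
    """Energy intake (kcal/day) as ``EE + ΔES``."""
    for name, v in (("mean_ee", mean_ee), ("delta_es", des)):
        if not (v == v and abs(v) != float("inf")):
            raise ValueError(f"{name} must be finite, got {v!r}")
    return EIEstimate(
        participant=participant,
        period=period,
        model_id=model_id,
        mean_ee=float(mean_ee),
        delta_es=float(des),
        ei=float(mean_ee) + float(des),
    )
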