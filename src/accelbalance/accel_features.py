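"""Epoch-level signal features from raw wrist acceleration.

The energy-expenditure models downstream consume three features derived
from a raw tri-axial trace:

* **ENMO** (Euclidean Norm Minus One): the vector magnitude of the three
  acceleration axes minus 1 g, negatives truncated to zero, expressed in
  milli-g.  Truncation happens per sample, *before* epoch averaging.
* **CV**: a per-second coefficient of variation of 1-s ENMO, computed by a
  minimum-over-sliding-windows rule — for each second, the CV of every
  contiguous window of ``window`` seconds that contains it is computed and
  the smallest value kept.  This separates continuous walking/running
  (steady signal, low CV) from intermittent activity (bursty, high CV).
* **Window features** for the wrist linear-regression model: per 15-s
  window, the sample SD of the signal vector magnitude and the mean
  inclination angle of a reference axis.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

logger = logging.getLogger(__name__)

MIN_SAMPLE_RATE = 20  # Hz


@dataclasses.dataclass
class RawTrace:
    """A uniformly sampled tri-axial acceleration recording.

    Parameters
    ----------
    start : pandas.Timestamp
        Wall-clock time of the first sample (device clock, naive).
    sample_rate : int
        Sampling frequency in Hz; must be >= 20.
    x, y, z : numpy.ndarray
        Per-axis acceleration in gravitational units (g).
    """

    start: pd.Timestamp
    sample_rate: int
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray

    def __post_init__(self) -> None:
        self.start = pd.Timestamp(self.start)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if not (len(self.x) == len(self.y) == len(self.z)):
            raise ValueError("axis series must have equal length")
        if int(self.sample_rate) != self.sample_rate or self.sample_rate < MIN_SAMPLE_RATE:
            raise ValueError(
                f"sample_rate must be an integer >= {MIN_SAMPLE_RATE} Hz, "
                f"got {self.sample_rate!r}"
            )
        self.sample_rate = int(self.sample_rate)
        for name, axis in (("x", self.x), ("y", self.y), ("z", self.z)):
            bad = np.flatnonzero(~np.isfinite(axis))
            if bad.size:
                raise ValueError(
                    f"non-finite sample in axis {name} at index {bad[0]}"
                )

    @property
    def n_samples(self) -> int:
        return len(self.x)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate

    def timestamps(self) -> pd.DatetimeIndex:
        """Per-sample wall-clock timestamps derived from start + rate."""
        step = pd.to_timedelta(np.arange(self.n_samples) / self.sample_rate, unit="s")
        return pd.DatetimeIndex(self.start + step)

    def vector_magnitude(self) -> np.ndarray:
        """Root sum of squares across the three axes (g)."""
        return np.sqrt(self.x**2 + self.y**2 + self.z**2)


@dataclasses.dataclass
class EpochSeries:
    """A contiguous, non-overlapping epoch-level feature series."""

    start: pd.Timestamp
    epoch_length: float  # seconds
    values: np.ndarray
    feature_name: str
    units: str

    def __post_init__(self) -> None:
        self.start = pd.Timestamp(self.start)
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.values)

    def epoch_starts(self) -> pd.DatetimeIndex:
        step = pd.to_timedelta(np.arange(len(self)) * self.epoch_length, unit="s")
        return pd.DatetimeIndex(self.start + step)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"epoch_start": self.epoch_starts(), self.feature_name: self.values}
        )


@dataclasses.dataclass
class WindowFeatures:
    """Per-window SD of vector magnitude and mean inclination angle."""

    start: pd.Timestamp
    window_length: float  # seconds
    sd_vm: np.ndarray  # g
    mean_angle: np.ndarray  # degrees, in [-90, 90]

    def __post_init__(self) -> None:
        self.start = pd.Timestamp(self.start)
        self.sd_vm = np.asarray(self.sd_vm, dtype=float)
        self.mean_angle = np.asarray(self.mean_angle, dtype=float)

    def __len__(self) -> int:
        return len(self.sd_vm)

    def window_starts(self) -> pd.DatetimeIndex:
        step = pd.to_timedelta(np.arange(len(self)) * self.window_length, unit="s")
        return pd.DatetimeIndex(self.start + step)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "window_start": self.window_starts(),
                "sd_vm": self.sd_vm,
                "mean_angle": self.mean_angle,
            }
        )


def compute_enmo(trace: RawTrace) -> np.ndarray:
    """Per-sample ENMO in milli-g: ``max(0, (|a| - 1) * 1000)``.

    Negative values (vector magnitude below 1 g, e.g. during free fall or
    from sensor noise) are truncated to zero sample-by-sample.
    """
    return np.maximum(0.0, (trace.vector_magnitude() - 1.0) * 1000.0)


def aggregate_epochs(
    values: np.ndarray,
    sample_rate: int,
    epoch_length: float = 1.0,
    start: pd.Timestamp | None = None,
    feature_name: str = "enmo",
    units: str = "milli-g",
) -> EpochSeries:
    """Average a per-sample series into fixed-length epochs.

    Epochs are aligned to the series start; a trailing partial epoch is
    dropped.  ``sample_rate * epoch_length`` must be a whole number of
    samples.
    """
    values = np.asarray(values, dtype=float)
    per_epoch = sample_rate * epoch_length
    if per_epoch != int(per_epoch) or per_epoch < 1:
        raise ValueError(
            f"epoch_length {epoch_length}s is not a whole number of samples "
            f"at {sample_rate} Hz"
        )
    per_epoch = int(per_epoch)
    n_epochs = len(values) // per_epoch
    trimmed = values[: n_epochs * per_epoch].reshape(n_epochs, per_epoch)
    means = trimmed.mean(axis=1) if n_epochs else np.empty(0)
    return EpochSeries(
        start=pd.Timestamp(start) if start is not None else pd.Timestamp(0),
        epoch_length=float(epoch_length),
        values=means,
        feature_name=feature_name,
        units=units,
    )


def _clipped_window_cv(x: np.ndarray, window: int) -> np.ndarray:
    """CV (%) of every nominal window of ``window`` elements, clipped to the
    series bounds.  Window ``j`` starts at ``j - window + 1`` so that the
    windows containing index ``i`` are exactly ``j = i .. i + window - 1``.
    Windows with fewer than 2 elements after clipping are returned as +inf
    (excluded from any minimum); windows with zero mean return 0.
    """
    n = len(x)
    cv = np.full(n + window - 1, np.inf)

    def one(seg: np.ndarray) -> float:
        if len(seg) < 2:
            return np.inf
        m = seg.mean()
        if m <= 0:
            return 0.0
        return float(seg.std(ddof=1) / m * 100.0)

    # interior (full-length) windows, vectorized over a strided view;
    # numpy's two-pass std keeps the variance exact to round-off
    if n >= window:
        wins = sliding_window_view(x, window)
        means = wins.mean(axis=1)
        sds = wins.std(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            full = np.where(means > 0, sds / np.where(means > 0, means, 1.0) * 100.0, 0.0)
        cv[window - 1 : n] = full
    # windows clipped at the left boundary (nominal start < 0)
    for j, s in enumerate(range(-(window - 1), 0)):
        cv[j] = one(x[0 : min(n, s + window)])
    # windows clipped at the right boundary
    for s in range(max(0, n - window + 1), n):
        cv[s + window - 1] = one(x[s:n])
    return cv


def sliding_cv(enmo_1s: EpochSeries | np.ndarray, window: int = 10) -> EpochSeries:
    """Minimum-over-containing-windows CV (%) of 1-s ENMO.

    For each second ``i``, every contiguous window of ``window`` seconds
    containing ``i`` is considered (windows truncated at the series
    boundaries count if they retain at least 2 elements) and the smallest
    SD/mean x 100 is kept.  Zero-mean windows contribute CV = 0 by
    convention — such epochs sit below every sedentary cut-point, so the
    choice cannot affect activity classification.
    """
    if isinstance(enmo_1s, EpochSeries):
        x = enmo_1s.values
        start = enmo_1s.start
        if enmo_1s.epoch_length != 1.0:
            raise ValueError("sliding_cv expects 1-s epochs")
    else:
        x = np.asarray(enmo_1s, dtype=float)
        start = pd.Timestamp(0)
    if window < 2:
        raise ValueError("window must span at least 2 seconds")
    n = len(x)
    if n < 2:
        out = np.zeros(n)
    else:
        cv = _clipped_window_cv(x, window)
        # min over the `window` nominal windows containing each index
        out = sliding_window_view(cv, window).min(axis=1)
    return EpochSeries(
        start=start, epoch_length=1.0, values=out, feature_name="cv", units="%"
    )


def staudenmayer_features(
    trace: RawTrace, window: float = 15.0, reference_axis: str = "x"
) -> WindowFeatures:
    """Per-window SD of vector magnitude (g) and mean inclination angle (deg).

    The inclination angle of each sample is ``degrees(arcsin(a / |v|))``
    for the designated reference axis ``a`` (default the first axis, which
    is forearm-aligned for wrist wear); the ratio is clamped to [-1, 1]
    before the arcsine.  Samples with zero vector magnitude contribute an
    angle of 0 and are logged.  A trailing partial window is dropped.
    """
    if reference_axis not in ("x", "y", "z"):
        raise ValueError(f"unknown reference axis {reference_axis!r}")
    per_win = trace.sample_rate * window
    if per_win != int(per_win) or per_win < 2:
        raise ValueError(
            f"window {window}s is not a whole number (>= 2) of samples "
            f"at {trace.sample_rate} Hz"
        )
    per_win = int(per_win)
    vm = trace.vector_magnitude()
    axis = getattr(trace, reference_axis)
    n_win = len(vm) // per_win
    vm_w = vm[: n_win * per_win].reshape(n_win, per_win)
    ax_w = axis[: n_win * per_win].reshape(n_win, per_win)

    sd_vm = vm_w.std(axis=1, ddof=1) if n_win else np.empty(0)

    zero_vm = vm_w == 0
    if zero_vm.any():
        logger.warning(
            "%d zero-magnitude samples; their angle contribution set to 0",
            int(zero_vm.sum()),
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(zero_vm, 0.0, ax_w / np.where(zero_vm, 1.0, vm_w))
    angles = np.degrees(np.arcsin(np.clip(ratio, -1.0, 1.0)))
    mean_angle = angles.mean(axis=1) if n_win else np.empty(0)

    return WindowFeatures(
        start=trace.start, window_length=float(window), sd_vm=sd_vm, mean_angle=mean_angle
    )
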