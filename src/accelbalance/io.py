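"""CSV/JSON readers and writers for every pipeline artifact.

All timestamps are serialized as ISO-8601 with millisecond precision in
device-local naive time; numeric output is written at 6 significant
digits so re-runs with the same configuration and seed are
byte-identical.  Every writer here has a paired reader that accepts its
output.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .accel_features import EpochSeries, RawTrace, WindowFeatures
from .ee_models import MODEL_IDS, MinuteEE
from .intake_balance import BodyCompPair, EIEstimate
from .wear_screening import STATES, Participant

SCHEMA_VERSION = 1
TIME_FORMAT = "%Y-%m-%dT%H:%M:%S.%f"
FLOAT_FORMAT = "%.6g"


def _fmt_times(idx) -> pd.Index:
    # ISO-8601 at millisecond precision, vectorized via datetime64[ms]
    vals = pd.DatetimeIndex(idx).values.astype("datetime64[ms]").astype(str)
    return pd.Index(vals)


# ---------------------------------------------------------------- raw traces

def write_raw_csv(trace: RawTrace, path: str | Path, header_lines: list[str] | None = None) -> None:
    """Write a raw trace as ``timestamp,x,y,z`` with optional device header."""
    path = Path(path)
    ts = trace.start.value // 10**6  # ms since epoch; vectorized formatting
    ms = ts + (np.arange(trace.n_samples) * 1000) // trace.sample_rate
    times = ms.astype("datetime64[ms]").astype(str)
    df = pd.DataFrame({"timestamp": times, "x": trace.x, "y": trace.y, "z": trace.z})
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(line.rstrip("\n") + "\n")
        df.to_csv(fh, index=False, float_format="%.4f")


def read_raw_csv(
    path: str | Path,
    skip_header_lines: int = 0,
    sample_rate: int | None = None,
    rate_tolerance: float = 0.01,
) -> RawTrace:
    """Read a raw trace CSV, validating spacing against the sample rate.

    ``sample_rate`` may be declared (then the file's median timestamp
    spacing must agree within ``rate_tolerance``) or omitted (then it is
    inferred from the median spacing).
    """
    path = Path(path)
    df = pd.read_csv(path, skiprows=skip_header_lines, dtype=str)
    expected = ["timestamp", "x", "y", "z"]
    if list(df.columns[:4]) != expected:
        raise ValueError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    axes = {}
    for col in ("x", "y", "z"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(vals.isna().to_numpy())
        if bad.size:
            # +2: one for the header row, one for 1-based line numbers
            line = bad[0] + 2 + skip_header_lines
            raise ValueError(f"{path}: non-numeric {col!r} value at line {line}")
        axes[col] = vals.to_numpy()
    times = pd.to_datetime(df["timestamp"], format="ISO8601")
    if len(times) < 2:
        raise ValueError(f"{path}: need at least 2 samples")
    if not times.is_monotonic_increasing:
        raise ValueError(f"{path}: timestamps are not monotone increasing")
    deltas = np.diff(times.to_numpy()).astype("timedelta64[us]").astype(float) / 1e6
    median_spacing = float(np.median(deltas))
    if sample_rate is None:
        # overall span is robust to the millisecond quantization of stamps
        span = (times.iloc[-1] - times.iloc[0]).total_seconds()
        sample_rate = int(round((len(times) - 1) / span))
    expected = 1.0 / sample_rate
    # 1.5 ms floor: serialized stamps are quantized to whole milliseconds
    if abs(median_spacing - expected) > max(rate_tolerance * expected, 1.5e-3):
        raise ValueError(
            f"{path}: declared {sample_rate} Hz but median spacing is "
            f"{median_spacing * 1e3:.2f} ms"
        )
    return RawTrace(start=times.iloc[0], sample_rate=sample_rate, **axes)


# ----------------------------------------------------------- epoch features

def write_epoch_csv(series_list: list[EpochSeries], path: str | Path) -> None:
    """Write aligned epoch series (same start/length) as one CSV with a
    units comment line."""
    first = series_list[0]
    for s in series_list[1:]:
        if len(s) != len(first) or s.epoch_length != first.epoch_length:
            raise ValueError("epoch series are not aligned")
    df = pd.DataFrame({"epoch_start": _fmt_times(first.epoch_starts())})
    units = []
    for s in series_list:
        df[s.feature_name] = s.values
        units.append(f"{s.feature_name}: {s.units}")
    with open(path, "w") as fh:
        fh.write(f"# epoch_length_s: {first.epoch_length}; " + "; ".join(units) + "\n")
        df.to_csv(fh, index=False, float_format=FLOAT_FORMAT)


def read_epoch_csv(path: str | Path) -> pd.DataFrame:
    """Read an epoch feature CSV into a frame indexed by epoch_start."""
    df = pd.read_csv(path, comment="#", parse_dates=["epoch_start"])
    return df.set_index("epoch_start")


def write_window_csv(feats: WindowFeatures, path: str | Path) -> None:
    df = feats.to_frame()
    df["window_start"] = _fmt_times(df["window_start"])
    with open(path, "w") as fh:
        fh.write(f"# window_length_s: {feats.window_length}; sd_vm: g; mean_angle: degrees\n")
        df.to_csv(fh, index=False, float_format=FLOAT_FORMAT)


def read_window_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", parse_dates=["window_start"])
    return df.set_index("window_start")


# ------------------------------------------------------------ minute tables

def write_minute_ee_csv(minute_ee: MinuteEE, path: str | Path) -> None:
    df = minute_ee.frame.copy()
    df.index = _fmt_times(df.index)
    df.index.name = "minute_start"
    df.to_csv(path, float_format=FLOAT_FORMAT)


def read_minute_ee_csv(path: str | Path) -> MinuteEE:
    df = pd.read_csv(path, parse_dates=["minute_start"]).set_index("minute_start")
    unknown = set(df.columns) - set(MODEL_IDS)
    if unknown:
        raise ValueError(f"{path}: unknown model columns {sorted(unknown)}")
    return MinuteEE(df)


def write_mask_csv(mask: pd.Series, path: str | Path) -> None:
    df = pd.DataFrame({"minute_start": _fmt_times(mask.index), "state": mask.values})
    df.to_csv(path, index=False)


def read_mask_csv(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, parse_dates=["minute_start"])
    bad = set(df["state"].unique()) - set(STATES)
    if bad:
        raise ValueError(f"{path}: unknown states {sorted(bad)}")
    return pd.Series(df["state"].to_numpy(), index=pd.DatetimeIndex(df["minute_start"]),
                     name="state")


# ------------------------------------------------------ participants & body

def write_participants_csv(participants: list[Participant], path: str | Path) -> None:
    pd.DataFrame([dataclasses.asdict(p) for p in participants]).to_csv(path, index=False)


def read_participants_csv(path: str | Path) -> dict[str, Participant]:
    df = pd.read_csv(path, dtype={"id": str})
    return {
        row["id"]: Participant(
            id=row["id"], sex=row["sex"], age=float(row["age"]),
            weight=float(row["weight"]), height=float(row["height"]),
        )
        for _, row in df.iterrows()
    }


def write_body_comp_csv(rows: pd.DataFrame, path: str | Path) -> None:
    """``rows``: participant, period, timepoint (start|end), ffm_kg, fm_kg,
    scan_date columns."""
    rows.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_body_comp_csv(path: str | Path) -> dict[tuple[str, str], BodyCompPair]:
    """Assemble BodyCompPairs keyed by (participant, period)."""
    df = pd.read_csv(path, dtype={"participant": str, "period": str},
                     parse_dates=["scan_date"])
    out: dict[tuple[str, str], BodyCompPair] = {}
    for (pid, period), grp in df.groupby(["participant", "period"]):
        grp = grp.set_index("timepoint")
        if not {"start", "end"} <= set(grp.index):
            raise ValueError(f"{path}: participant {pid} period {period} "
                             "needs both start and end timepoints")
        s, e = grp.loc["start"], grp.loc["end"]
        elapsed = (e["scan_date"] - s["scan_date"]).total_seconds() / 86400.0
        out[(pid, period)] = BodyCompPair(
            ffm_start=float(s["ffm_kg"]), ffm_end=float(e["ffm_kg"]),
            fm_start=float(s["fm_kg"]), fm_end=float(e["fm_kg"]),
            elapsed_days=elapsed,
        )
    return out


# ------------------------------------------------------------------ results

def write_ei_estimates_csv(estimates: list[EIEstimate], path: str | Path) -> None:
    pd.DataFrame([dataclasses.asdict(e) for e in estimates]).to_csv(
        path, index=False, float_format=FLOAT_FORMAT
    )


def read_ei_estimates_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"participant": str, "period": str})


def write_validity_report(
    summaries: pd.DataFrame, fits: pd.DataFrame, out_dir: str | Path
) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summaries.to_csv(out_dir / "validity_summaries.csv", index=False,
                     float_format=FLOAT_FORMAT)
    fits.to_csv(out_dir / "mixed_fits.csv", index=False, float_format=FLOAT_FORMAT)
    report = {
        "schema_version": SCHEMA_VERSION,
        "summaries": json.loads(summaries.to_json(orient="records")),
        "mixed_fits": json.loads(fits.to_json(orient="records")),
    }
    (out_dir / "validity_report.json").write_text(json.dumps(report, indent=2))


# ------------------------------------------------------------------- config

@dataclasses.dataclass
class RunConfig:
    """Pipeline run configuration; YAML keys are overridden by CLI flags."""

    models: tuple[str, ...] = MODEL_IDS
    epoch_length: float = 1.0
    cv_window: int = 10
    staudenmayer_window: float = 15.0
    reference_axis: str = "x"
    choi_zero_threshold: float = 1.0
    choi_min_period: int = 90
    sleep_source: str = "mask"  # 'mask' | 'fixed_window'
    sleep_window: tuple[str, str] = ("23:00", "07:00")
    valid_day_minutes: int = 600
    min_valid_days: int = 4
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        if "models" in data:
            data["models"] = tuple(data["models"])
        if "sleep_window" in data:
            data["sleep_window"] = tuple(data["sleep_window"])
        return cls(**data)
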