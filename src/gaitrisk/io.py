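"""Reading and writing participant IMU recordings, manifests, and frames.

File conventions
----------------
Participant file: plain CSV with columns ``t,a_ml,a_v,a_ap,w_ml,w_v,w_ap``.
Lines starting with ``#`` are comments; the first comment line may declare
``unit_accel=g|ms2`` and ``rate_hz=<float>``. Accelerations declared in [g]
(the sensor's native unit) are converted to m/s^2 on load, so everything
downstream works in the units the variability tables use.

Cohort manifest: CSV with columns ``participant_id,tug_s,faller,imu_path``;
``imu_path`` is resolved relative to the manifest's directory.
"""

from __future__ import annotations

import io as _io
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    ACCEL_CHANNELS,
    CHANNELS,
    G_TO_MS2,
    Frame,
    FormatError,
    ImuTimeSeries,
    ParticipantRecord,
    SamplingError,
)

__all__ = [
    "read_imu_csv",
    "write_imu_csv",
    "split_frames",
    "read_manifest",
    "write_manifest",
    "load_cohort",
    "save_cohort",
]

_COLUMNS = ("t",) + CHANNELS


def _parse_header_directives(path: Path) -> dict:
    """Extract ``key=value`` directives from leading comment lines."""
    directives: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            for token in line[1:].split():
                if "=" in token:
                    key, _, value = token.partition("=")
                    directives[key.strip()] = value.strip()
    return directives


def read_imu_csv(
    path, sampling_rate: float | None = None, nan_policy: str = "reject"
) -> ImuTimeSeries:
    """Load one participant recording.

    Parameters
    ----------
    path : path-like
        CSV file with a header row naming the 7 columns.
    sampling_rate : float, optional
        Expected rate in Hz; overrides any ``rate_hz`` file directive.
        Defaults to the directive, or 100 Hz if absent.
    nan_policy : {"reject", "interpolate"}
        ``reject`` (default) raises on any missing value, naming the first
        offending row. ``interpolate`` linearly fills interior gaps of at
        most 5 consecutive samples (50 ms at 100 Hz) and rejects longer ones.

    Raises
    ------
    FormatError
        Missing or misnamed columns.
    SamplingError
        Timestamps inconsistent with the sampling rate.
    """
    path = Path(path)
    directives = _parse_header_directives(path)
    df = pd.read_csv(path, comment="#")
    for col in _COLUMNS:
        if col not in df.columns:
            raise FormatError(f"column {col!r} missing from {path.name}")
    df = df[list(_COLUMNS)]
    if sampling_rate is None:
        sampling_rate = float(directives.get("rate_hz", 100.0))

    if df.isna().any().any():
        bad_rows = np.nonzero(df.isna().any(axis=1).to_numpy())[0]
        if nan_policy == "reject":
            raise ValueError(
                f"missing values in {path.name}, first at data row {bad_rows[0]}"
            )
        elif nan_policy == "interpolate":
            runs = np.diff(np.concatenate([[-2], bad_rows]))
            run_lengths = []
            count = 1
            for gap in runs[1:]:
                if gap == 1:
                    count += 1
                else:
                    run_lengths.append(count)
                    count = 1
            run_lengths.append(count)
            if max(run_lengths) > 5:
                raise ValueError(
                    f"gap of {max(run_lengths)} consecutive missing samples in "
                    f"{path.name} exceeds the 5-sample interpolation limit"
                )
            if df.iloc[0].isna().any() or df.iloc[-1].isna().any():
                raise ValueError(f"missing values at the edges of {path.name}")
            df = df.interpolate(method="linear", limit_area="inside")
        else:
            raise ValueError(f"unknown nan_policy {nan_policy!r}")

    data = {c: df[c].to_numpy(dtype=float) for c in CHANNELS}
    if directives.get("unit_accel", "ms2") == "g":
        for c in ACCEL_CHANNELS:
            data[c] = data[c] * G_TO_MS2
    return ImuTimeSeries(t=df["t"].to_numpy(dtype=float), sampling_rate=sampling_rate, **data)


def write_imu_csv(series: ImuTimeSeries, path) -> None:
    """Write a recording; output is re-readable losslessly to 1e-9.

    The file declares ``unit_accel=ms2`` and the sampling rate in a leading
    comment line and stores 12 significant digits per value.
    """
    path = Path(path)
    buf = _io.StringIO()
    buf.write(f"# unit_accel=ms2 rate_hz={series.sampling_rate:g}\n")
    df = pd.DataFrame({"t": series.t, **{c: series.channel(c) for c in CHANNELS}})
    df.to_csv(buf, index=False, float_format="%.12g")
    path.write_text(buf.getvalue())


def split_frames(
    series: ImuTimeSeries,
    window_s: float,
    step_s: float,
    participant_id: str = "",
    label: int = 0,
) -> list[Frame]:
    """Cut a recording into fixed-duration windows.

    Frames start at 0, ``step_s``, ``2*step_s``, ...; any window extending
    past the end of the recording is dropped (no padding), so the count is
    ``floor((duration - window) / step) + 1`` whenever the recording is at
    least one window long.
    """
    if step_s <= 0:
        raise ValueError("step_s must be positive")
    n = len(series)
    win = int(round(window_s * series.sampling_rate))
    step = int(round(step_s * series.sampling_rate))
    if win > n:
        warnings.warn(
            f"window of {window_s} s exceeds the {series.duration:.1f} s recording; "
            "no frames produced",
            stacklevel=2,
        )
        return []
    arr = series.as_array()
    frames = []
    for start in range(0, n - win + 1, step):
        frames.append(
            Frame(
                participant_id=participant_id,
                start_time=start / series.sampling_rate,
                duration=window_s,
                data=arr[:, start : start + win],
                label=label,
            )
        )
    return frames


def read_manifest(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("participant_id", "tug_s", "faller"):
        if col not in df.columns:
            raise FormatError(f"manifest column {col!r} missing from {path.name}")
    return df


def write_manifest(df: pd.DataFrame, path) -> None:
    pd.DataFrame(df).to_csv(path, index=False)


def load_cohort(manifest_path, nan_policy: str = "reject") -> list[ParticipantRecord]:
    """Read a manifest and every recording it points to."""
    manifest_path = Path(manifest_path)
    df = read_manifest(manifest_path)
    if "imu_path" not in df.columns:
        raise FormatError("manifest lacks an 'imu_path' column")
    records = []
    for row in df.itertuples(index=False):
        imu_path = Path(row.imu_path)
        if not imu_path.is_absolute():
            imu_path = manifest_path.parent / imu_path
        series = read_imu_csv(imu_path, nan_policy=nan_policy)
        records.append(
            ParticipantRecord(
                participant_id=str(row.participant_id),
                tug_time=float(row.tug_s),
                series=series,
                faller=int(row.faller),
            )
        )
    return records


def save_cohort(records: list[ParticipantRecord], out_dir) -> Path:
    """Write per-participant CSVs plus a manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        fname = f"{rec.participant_id}.csv"
        write_imu_csv(rec.series, out_dir / fname)
        rows.append(
            {
                "participant_id": rec.participant_id,
                "tug_s": rec.tug_time,
                "faller": rec.faller,
                "imu_path": fname,
            }
        )
    manifest_path = out_dir / "manifest.csv"
    write_manifest(pd.DataFrame(rows), manifest_path)
    return manifest_path
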