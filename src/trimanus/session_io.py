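"""Session file I/O: TSV sample tables, JSON sidecars, events tables.

Layout (names follow neuroimaging-style conventions)::

    out/
      sub-01/
        sub-01_task-trimanual_run-01_eeg.tsv      (t, uv)
        sub-01_task-trimanual_run-01_eeg.json
        sub-01_task-trimanual_run-01_gaze.tsv     (t, x_deg, y_deg, valid)
        sub-01_task-trimanual_run-01_gaze.json
        sub-01_task-trimanual_run-01_pose.tsv     (t, hand, x, y, z)
        sub-01_task-trimanual_run-01_pose.json
        sub-01_task-trimanual_run-01_events.tsv   (onset, duration, event_type, value, detail)
      session_config.json

Floats are written with 17 significant digits so that write -> read
round-trips float64 values exactly and identical configs produce
byte-identical files.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SessionConfig
from .streams import Episode, GroundTruth, SampleStream

FLOAT_FMT = "%.17g"
TASK = "trimanual"


class SessionFormatError(ValueError):
    """Raised when session files are missing or malformed."""


def _prefix(subject: int, run: int) -> str:
    return f"sub-{subject:02d}_task-{TASK}_run-{run:02d}"


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def _sidecar(stream: SampleStream) -> dict:
    return {
        "SamplingFrequency": stream.rate,
        "StartTime": stream.t0,
        "Units": stream.units,
        "Columns": list(stream.columns or ()),
    }


def write_session(streams: dict[str, SampleStream], ground_truth: GroundTruth,
                  config: SessionConfig, out_dir, subject: int = 1, run: int = 1,
                  overwrite: bool = False) -> list[Path]:
    """Write one run's streams + events under ``out_dir``; returns paths."""
    out_dir = Path(out_dir)
    sub_dir = out_dir / f"sub-{subject:02d}"
    if sub_dir.exists() and any(sub_dir.iterdir()) and not overwrite:
        existing = sub_dir / f"{_prefix(subject, run)}_eeg.tsv"
        if existing.exists():
            raise FileExistsError(
                f"{sub_dir} already contains run {run}; pass overwrite=True"
            )
    sub_dir.mkdir(parents=True, exist_ok=True)
    prefix = _prefix(subject, run)
    written: list[Path] = []

    tables = {
        "eeg": pd.DataFrame({"t": streams["eeg"].times, "uv": streams["eeg"].values}),
        "gaze": pd.DataFrame({
            "t": streams["gaze"].times,
            "x_deg": streams["gaze"].values[:, 0],
            "y_deg": streams["gaze"].values[:, 1],
            "valid": (streams["gaze"].valid
                      if streams["gaze"].valid is not None
                      else np.ones(streams["gaze"].n, bool)).astype(int),
        }),
    }
    pose = streams["pose"]
    pose_rows = []
    for hand, sl in (("left", slice(0, 3)), ("right", slice(3, 6))):
        block = pd.DataFrame(pose.values[:, sl], columns=["x", "y", "z"])
        block.insert(0, "hand", hand)
        block.insert(0, "t", pose.times)
        pose_rows.append(block)
    tables["pose"] = pd.concat(pose_rows, ignore_index=True)

    for kind, df in tables.items():
        path = sub_dir / f"{prefix}_{kind}.tsv"
        _write_tsv(df, path)
        written.append(path)
        side = sub_dir / f"{prefix}_{kind}.json"
        side.write_text(json.dumps(_sidecar(streams[kind]), indent=1, sort_keys=True))
        written.append(side)

    events = pd.DataFrame(
        [{
            "onset": e.onset,
            "duration": e.duration,
            "event_type": e.kind,
            "value": e.value,
            "detail": json.dumps(e.detail, sort_keys=True) if e.detail else "",
        } for e in ground_truth.all_events()],
        columns=["onset", "duration", "event_type", "value", "detail"],
    )
    events_path = sub_dir / f"{prefix}_events.tsv"
    _write_tsv(events, events_path)
    written.append(events_path)

    cfg_path = out_dir / "session_config.json"
    cfg_path.write_text(json.dumps(config.to_dict(), indent=1, sort_keys=True))
    written.append(cfg_path)
    return written


def _load_sidecar(path: Path) -> dict:
    if not path.exists():
        raise SessionFormatError(f"missing sidecar {path.name}")
    return json.loads(path.read_text())


def _require_columns(df: pd.DataFrame, cols, path: Path) -> None:
    for col in cols:
        if col not in df.columns:
            raise SessionFormatError(f"{path.name}: missing column '{col}'")


def read_session(in_dir, subject: int = 1, run: int = 1,
                 ) -> tuple[dict[str, SampleStream], GroundTruth, SessionConfig]:
    """Read a run written by :func:`write_session`."""
    in_dir = Path(in_dir)
    sub_dir = in_dir / f"sub-{subject:02d}"
    prefix = _prefix(subject, run)
    streams: dict[str, SampleStream] = {}

    for kind in ("eeg", "gaze", "pose"):
        tsv = sub_dir / f"{prefix}_{kind}.tsv"
        if not tsv.exists():
            raise SessionFormatError(f"missing stream table {tsv.name}")
        meta = _load_sidecar(sub_dir / f"{prefix}_{kind}.json")
        df = pd.read_csv(tsv, sep="\t", float_precision="round_trip")
        rate, t0, units = meta["SamplingFrequency"], meta["StartTime"], meta["Units"]
        if kind == "eeg":
            _require_columns(df, ("t", "uv"), tsv)
            streams[kind] = SampleStream("eeg", rate, t0, df["uv"].to_numpy(),
                                         units, columns=("uv",))
        elif kind == "gaze":
            _require_columns(df, ("t", "x_deg", "y_deg", "valid"), tsv)
            streams[kind] = SampleStream(
                "gaze", rate, t0, df[["x_deg", "y_deg"]].to_numpy(), units,
                columns=("x_deg", "y_deg"), valid=df["valid"].to_numpy(bool))
        else:
            _require_columns(df, ("t", "hand", "x", "y", "z"), tsv)
            left = df[df["hand"] == "left"][["x", "y", "z"]].to_numpy()
            right = df[df["hand"] == "right"][["x", "y", "z"]].to_numpy()
            if len(left) != len(right):
                raise SessionFormatError(f"{tsv.name}: unbalanced hand rows")
            streams[kind] = SampleStream(
                "pose", rate, t0, np.hstack([left, right]), units,
                columns=("lx", "ly", "lz", "rx", "ry", "rz"))

    events_path = sub_dir / f"{prefix}_events.tsv"
    if not events_path.exists():
        raise SessionFormatError(f"missing events table {events_path.name}")
    edf = pd.read_csv(events_path, sep="\t", keep_default_na=False,
                      float_precision="round_trip")
    _require_columns(edf, ("onset", "duration", "event_type", "value"), events_path)
    gt = GroundTruth()
    buckets = {"attention": gt.attention, "blink": gt.artifacts,
               "muscle": gt.artifacts, "fixation": gt.fixations, "reach": gt.reaches}
    for _, row in edf.iterrows():
        detail = json.loads(row["detail"]) if row.get("detail", "") else {}
        value = row["value"]
        try:
            value = float(value)
        except (TypeError, ValueError):
            pass
        ep = Episode(row["event_type"], float(row["onset"]), float(row["duration"]),
                     value, detail)
        buckets.get(ep.kind, gt.artifacts).append(ep)

    cfg_path = in_dir / "session_config.json"
    if not cfg_path.exists():
        raise SessionFormatError("missing session_config.json")
    config = SessionConfig.from_dict(json.loads(cfg_path.read_text()))
    return streams, gt, config


def list_runs(in_dir, subject: int = 1) -> list[int]:
    sub_dir = Path(in_dir) / f"sub-{subject:02d}"
    runs = []
    if sub_dir.exists():
        for name in os.listdir(sub_dir):
            if name.endswith("_eeg.tsv"):
                runs.append(int(name.split("_run-")[1].split("_")[0]))
    return sorted(runs)


def write_features(df: pd.DataFrame, path) -> None:
    _write_tsv(df, Path(path))


def read_features(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SessionFormatError(f"missing features table {path}")
    return pd.read_csv(path, sep="\t", float_precision="round_trip")
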