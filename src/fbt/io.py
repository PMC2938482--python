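"""Readers and writers for the pipeline's on-disk formats.

Recordings and impulse responses travel as stereo float WAV files (sample
rate preserved exactly in the header, IEEE float64 frames so round-trips
are lossless) with a JSON sidecar holding the source angle and microphone
site. Tabular data (ECAP frames, growth functions, impedance logs,
trajectories, cue curves) travel as CSV with documented column names;
results as JSON.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .acoustics import CueCurve, ImpulseResponsePair, MicSite
from .ecap import EcapFrameSet, GrowthFunction
from .impedance import LOG_COLUMNS, validate_log
from .orienting import Trajectory


class SchemaError(ValueError):
    """A table is missing required columns or is otherwise malformed."""


def read_table(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    """Read a CSV and verify the required columns are present."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"missing input file: {path}")
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# WAV + sidecar
# ---------------------------------------------------------------------------


def write_ir_pair(ir: ImpulseResponsePair, path: str | Path) -> Path:
    """Stereo float64 WAV (left, right) plus a ``.json`` metadata sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.column_stack([ir.left_ir, ir.right_ir])
    wavfile.write(path, int(round(ir.fs)), data)
    sidecar = {
        "source_angle_deg": ir.source_angle,
        "mic_site": ir.mic_site.value,
        "fs_hz": ir.fs,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, sort_keys=True, indent=1))
    return path


def read_ir_pair(path: str | Path) -> ImpulseResponsePair:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"missing input file: {path}")
    fs, data = wavfile.read(path)
    if data.ndim != 2 or data.shape[1] != 2:
        raise ValueError(f"{path}: expected a stereo WAV")
    sidecar_path = path.with_suffix(".json")
    angle, site = 0.0, MicSite.EAR_CANAL
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
        angle = float(meta.get("source_angle_deg", 0.0))
        site = MicSite(meta.get("mic_site", "ear_canal"))
        fs = float(meta.get("fs_hz", fs))
    return ImpulseResponsePair(
        left_ir=data[:, 0].astype(float),
        right_ir=data[:, 1].astype(float),
        fs=float(fs),
        source_angle=angle,
        mic_site=site,
    )


# ---------------------------------------------------------------------------
# ECAP tables
# ---------------------------------------------------------------------------

_FRAME_NAMES = ("probe_alone", "masker_probe", "masker_alone", "no_stimulus")
FRAME_COLUMNS = ("level", "t_ms", "frame", "uv")


def frame_sets_to_table(frame_sets: Sequence[EcapFrameSet]) -> pd.DataFrame:
    """Long-format table: one row per (level, frame, sample)."""
    rows = []
    for fr in frame_sets:
        t_ms = np.arange(fr.probe_alone.size) / fr.fs * 1e3
        for name in _FRAME_NAMES:
            for t, v in zip(t_ms, getattr(fr, name)):
                rows.append((fr.stimulus_level, t, name, v))
    return pd.DataFrame(rows, columns=list(FRAME_COLUMNS))


def frame_sets_from_table(df: pd.DataFrame, fs: float) -> list[EcapFrameSet]:
    missing = [c for c in FRAME_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"frame table missing column(s): {', '.join(missing)}")
    frame_sets = []
    for level, group in df.groupby("level", sort=True):
        traces = {}
        for name in _FRAME_NAMES:
            sub = group[group["frame"] == name].sort_values("t_ms")
            if sub.empty:
                raise SchemaError(f"level {level}: missing frame '{name}'")
            traces[name] = sub["uv"].to_numpy(dtype=float)
        frame_sets.append(
            EcapFrameSet(fs=fs, stimulus_level=float(level), **traces)
        )
    return frame_sets


def growth_to_table(gf: GrowthFunction) -> pd.DataFrame:
    return pd.DataFrame(gf.points, columns=["level", "p1n1_uv"])


def growth_from_table(df: pd.DataFrame) -> GrowthFunction:
    missing = [c for c in ("level", "p1n1_uv") if c not in df.columns]
    if missing:
        raise SchemaError(f"growth table missing column(s): {', '.join(missing)}")
    return GrowthFunction(points=list(zip(df["level"].astype(float), df["p1n1_uv"].astype(float))))


# ---------------------------------------------------------------------------
# cue curves
# ---------------------------------------------------------------------------


def _band_column(band: tuple[float, float]) -> str:
    return f"ild_db_{int(band[0])}_{int(band[1])}"


def cue_curve_to_table(curve: CueCurve) -> pd.DataFrame:
    data = {"angle_deg": curve.angles, "itd_us": curve.itd_us}
    for band, vals in curve.ild_db.items():
        data[_band_column(band)] = vals
    return pd.DataFrame(data)


def cue_curve_from_table(df: pd.DataFrame) -> CueCurve:
    missing = [c for c in ("angle_deg", "itd_us") if c not in df.columns]
    if missing:
        raise SchemaError(f"cue table missing column(s): {', '.join(missing)}")
    ild = {}
    for col in df.columns:
        if col.startswith("ild_db_"):
            lo, hi = col[len("ild_db_") :].split("_")
            ild[(float(lo), float(hi))] = df[col].to_numpy(dtype=float)
    return CueCurve(
        angles=df["angle_deg"].to_numpy(dtype=float),
        itd_us=df["itd_us"].to_numpy(dtype=float),
        ild_db=ild,
    )


# ---------------------------------------------------------------------------
# impedance logs, trajectories
# ---------------------------------------------------------------------------


def read_impedance_log(path: str | Path) -> pd.DataFrame:
    return validate_log(read_table(path, LOG_COLUMNS))


TRAJECTORY_COLUMNS = ("frame", "t_s", "x", "y")


def trajectory_to_table(traj: Trajectory) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "frame": np.arange(traj.n_frames),
            "t_s": traj.t_s,
            "x": traj.x,
            "y": traj.y,
        }
    )


def read_trajectory(path: str | Path, onset_index: int, fps: float = 60.0) -> Trajectory:
    df = read_table(path, TRAJECTORY_COLUMNS)
    return Trajectory(
        t_s=df["t_s"].to_numpy(dtype=float),
        x=df["x"].to_numpy(dtype=float),
        y=df["y"].to_numpy(dtype=float),
        onset_index=onset_index,
        fps=fps,
    )


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_json(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, sort_keys=True, indent=1, default=float) + "\n")
    return path
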