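"""CSV and TIFF dialects shared by all pipeline stages.

All CSVs are comma-separated UTF-8 with a header row and ``.`` decimal;
positions are always µm and frame indices 0-based.  Movies are
multi-page 16-bit unsigned TIFF.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .localize import SpotDetection
from .msd import MotionFit, MSDCurve
from .simulate import Trajectory

TRAJ_COLUMNS = ["traj_id", "frame", "x_um", "y_um", "true_mode", "true_D"]
DET_COLUMNS = ["frame", "x_um", "y_um", "intensity", "width_um", "quality"]
FIT_COLUMNS = ["traj_id", "D_um2_s", "alpha", "mode", "r2", "n_frames"]
MSD_COLUMNS = ["traj_id", "lag_s", "msd_um2", "n_pairs"]


def trajectories_to_df(trajectories: list[Trajectory]) -> pd.DataFrame:
    rows = []
    for t in trajectories:
        for k in range(len(t)):
            rows.append((t.traj_id, int(t.frames[k]), t.x[k], t.y[k],
                         t.true_mode if t.true_mode is not None else "",
                         t.true_D if t.true_D is not None else np.nan))
    return pd.DataFrame(rows, columns=TRAJ_COLUMNS)


def df_to_trajectories(df: pd.DataFrame, source: str = "<dataframe>") -> list[Trajectory]:
    missing = [c for c in ("traj_id", "frame", "x_um", "y_um") if c not in df.columns]
    if missing:
        raise ValueError(f"{source}: missing trajectory columns {missing}")
    if len(df) == 0:
        raise ValueError(f"{source}: empty trajectory table")
    out = []
    for tid, g in df.groupby("traj_id", sort=True):
        g = g.sort_values("frame")
        mode = None
        true_D = None
        if "true_mode" in g.columns:
            m = g["true_mode"].iloc[0]
            mode = m if isinstance(m, str) and m else None
        if "true_D" in g.columns and np.isfinite(g["true_D"].iloc[0]):
            true_D = float(g["true_D"].iloc[0])
        out.append(Trajectory(traj_id=tid, frames=g["frame"].to_numpy(),
                              x=g["x_um"].to_numpy(), y=g["y_um"].to_numpy(),
                              true_mode=mode, true_D=true_D))
    return out


def write_trajectories(trajectories: list[Trajectory], path: str | Path) -> None:
    trajectories_to_df(trajectories).to_csv(path, index=False)


def read_trajectories(path: str | Path) -> list[Trajectory]:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as e:
        raise ValueError(f"{path}: empty or malformed CSV ({e})") from e
    return df_to_trajectories(df, source=str(path))


def detections_to_df(detections_by_frame: dict[int, list[SpotDetection]]) -> pd.DataFrame:
    rows = [
        (d.frame, d.x, d.y, d.intensity, d.width, d.quality)
        for f in sorted(detections_by_frame)
        for d in detections_by_frame[f]
    ]
    return pd.DataFrame(rows, columns=DET_COLUMNS)


def df_to_detections(df: pd.DataFrame, source: str = "<dataframe>") -> dict[int, list[SpotDetection]]:
    missing = [c for c in ("frame", "x_um", "y_um") if c not in df.columns]
    if missing:
        raise ValueError(f"{source}: missing detection columns {missing}")
    out: dict[int, list[SpotDetection]] = {}
    for row in df.itertuples(index=False):
        d = SpotDetection(
            frame=int(row.frame), x=float(row.x_um), y=float(row.y_um),
            intensity=float(getattr(row, "intensity", np.nan)),
            width=float(getattr(row, "width_um", np.nan)),
            quality=float(getattr(row, "quality", np.nan)),
        )
        out.setdefault(d.frame, []).append(d)
    return out


def write_detections(detections_by_frame, path: str | Path) -> None:
    detections_to_df(detections_by_frame).to_csv(path, index=False)


def read_detections(path: str | Path) -> dict[int, list[SpotDetection]]:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as e:
        raise ValueError(f"{path}: empty or malformed CSV ({e})") from e
    return df_to_detections(df, source=str(path))


def fits_to_df(fits: list[MotionFit]) -> pd.DataFrame:
    rows = [
        (f.traj_id, f.D, f.alpha, f.mode if f.mode is not None else "",
         f.r2_loglog, f.n_frames)
        for f in fits
    ]
    return pd.DataFrame(rows, columns=FIT_COLUMNS)


def write_fits(fits: list[MotionFit], path: str | Path) -> None:
    fits_to_df(fits).to_csv(path, index=False)


def read_fits(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as e:
        raise ValueError(f"{path}: empty or malformed CSV ({e})") from e
    missing = [c for c in FIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing fit columns {missing}")
    return df


def msd_curves_to_df(curves: list[MSDCurve]) -> pd.DataFrame:
    rows = [
        (c.traj_id, c.lags[i], c.values[i], int(c.n_pairs[i]))
        for c in curves
        for i in range(len(c.lags))
    ]
    return pd.DataFrame(rows, columns=MSD_COLUMNS)


def write_movie(stack: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(path, np.asarray(stack, dtype=np.uint16),
                     photometric="minisblack")


def read_movie(path: str | Path) -> np.ndarray:
    path = Path(path)
    try:
        stack = tifffile.imread(path)
    except (tifffile.TiffFileError, ValueError) as e:
        raise ValueError(f"{path}: cannot read TIFF ({e})") from e
    if stack.ndim == 2:
        stack = stack[None, :, :]
    if stack.ndim != 3:
        raise ValueError(f"{path}: expected a 2-D or 3-D stack, got ndim={stack.ndim}")
    return stack
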