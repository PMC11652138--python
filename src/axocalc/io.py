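"""File I/O: multi-page TIFF stacks, label images, trace and trajectory
tables (CSV), and structured key-value configuration files (YAML)."""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .datatypes import MitoTrajectory, RatioTrace, RatiometricStack, TransportEvent

__all__ = [
    "read_stack",
    "write_stack",
    "read_ratiometric",
    "write_ratiometric",
    "read_label_image",
    "write_label_image",
    "write_traces_csv",
    "read_traces_csv",
    "write_trajectories_csv",
    "read_trajectories_csv",
    "write_events_csv",
    "load_config",
    "dump_config",
    "file_checksum",
]


def read_stack(path: str | Path) -> np.ndarray:
    """Read a (T, H, W) stack from a multi-page TIFF."""
    arr = tifffile.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = arr[None]
    return arr.astype(float)


def write_stack(path: str | Path, stack: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32))


def read_ratiometric(
    path_340: str | Path,
    path_380: str | Path,
    frame_interval: float,
    pixel_size: float = 1.0,
) -> RatiometricStack:
    return RatiometricStack(
        f340=read_stack(path_340),
        f380=read_stack(path_380),
        frame_interval=frame_interval,
        pixel_size=pixel_size,
    )


def write_ratiometric(
    dir_path: str | Path, stack: RatiometricStack, prefix: str = "stack"
) -> tuple[Path, Path]:
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    p340 = dir_path / f"{prefix}_340.tif"
    p380 = dir_path / f"{prefix}_380.tif"
    write_stack(p340, stack.f340)
    write_stack(p380, stack.f380)
    return p340, p380


def read_label_image(path: str | Path) -> np.ndarray:
    return np.asarray(tifffile.imread(path)).astype(np.int32)


def write_label_image(path: str | Path, labels: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(labels, dtype=np.int32))


def write_traces_csv(path: str | Path, traces: dict[str, RatioTrace]) -> None:
    rows = []
    for name, tr in traces.items():
        for i in range(len(tr.time)):
            rows.append(
                (name, tr.time[i], tr.f340[i], tr.f380[i], tr.ratio[i],
                 bool(tr.valid[i]))
            )
    pd.DataFrame(
        rows, columns=["compartment", "t", "F340", "F380", "R", "valid"]
    ).to_csv(path, index=False)


def read_traces_csv(path: str | Path) -> dict[str, RatioTrace]:
    df = pd.read_csv(path)
    out = {}
    for name, g in df.groupby("compartment", sort=False):
        out[str(name)] = RatioTrace(
            time=g["t"].to_numpy(), f340=g["F340"].to_numpy(),
            f380=g["F380"].to_numpy(), ratio=g["R"].to_numpy(),
            valid=g["valid"].to_numpy(bool), compartment=str(name),
        )
    return out


def write_trajectories_csv(
    path: str | Path, trajs: list[MitoTrajectory]
) -> None:
    rows = []
    for tr in trajs:
        for t, x in zip(tr.time, tr.position):
            rows.append((tr.id, tr.segment, t, x))
    pd.DataFrame(
        rows, columns=["id", "segment", "t", "position_um"]
    ).to_csv(path, index=False)


def read_trajectories_csv(path: str | Path) -> list[MitoTrajectory]:
    df = pd.read_csv(path)
    out = []
    for (mid, seg), g in df.groupby(["id", "segment"], sort=True):
        out.append(
            MitoTrajectory(
                id=int(mid), segment=int(seg),
                time=g["t"].to_numpy(), position=g["position_um"].to_numpy(),
            )
        )
    return out


def write_events_csv(path: str | Path, trajs: list[MitoTrajectory]) -> None:
    rows = []
    for tr in trajs:
        for ev in tr.events:
            rows.append(
                (tr.id, tr.segment, ev.type, ev.start, ev.end,
                 ev.displacement, ev.velocity)
            )
    pd.DataFrame(
        rows,
        columns=["id", "segment", "type", "start", "end", "displacement_um",
                 "velocity_um_s"],
    ).to_csv(path, index=False)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def dump_config(path: str | Path, config: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
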