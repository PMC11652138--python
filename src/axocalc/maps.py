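"""Pixel-resolution calcium maps: per-pixel calibration, baseline and
peak-amplitude maps, repeat-stimulation reproducibility, and geodesic
(quasi-Euclidean) distance-to-soma maps with correlation analyses.

The distance metric is the 8-connected chamfer metric: shortest path on
the pixel graph with axial steps of length 1 and diagonal steps of
length sqrt(2), with paths constrained to the segmented mask — so a
dendritic pixel's distance is measured along the dendrite, not across
background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.stats import pearsonr

from .calib import CalibrationParams, ratio_to_concentration
from .datatypes import CompartmentROIs, NeuronMask, PixelMap, RatiometricStack

__all__ = [
    "ConcentrationStack",
    "pixel_concentration_stack",
    "baseline_map",
    "peak_amplitude_map",
    "stimulation_window",
    "DistanceMap",
    "geodesic_distance_map",
    "MapCorrelation",
    "map_correlation",
]

SQRT2 = float(np.sqrt(2.0))


@dataclass
class ConcentrationStack:
    """Per-frame concentration maps (nM), (T, H, W) with validity."""

    data: np.ndarray
    valid: np.ndarray
    frame_interval: float

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def frame(self, t: int) -> PixelMap:
        return PixelMap(
            data=self.data[t], semantics="concentration-nM", valid=self.valid[t]
        )


def pixel_concentration_stack(
    stack: RatiometricStack,
    mask: NeuronMask,
    calib: CalibrationParams,
    rois: CompartmentROIs | None = None,
    autofluorescence: dict[str, tuple[float, float]] | None = None,
) -> ConcentrationStack:
    """Calibrate every masked pixel trace to absolute concentration.

    The same calculation as the ROI pipeline, performed per pixel. If a
    compartment annotation and autofluorescence table are given, the
    compartment-specific contribution is subtracted per pixel before the
    ratio is formed. Pixels outside the mask, frames with non-positive
    corrected F380, and out-of-range ratios are invalid.
    """
    if not mask.mask.any():
        raise ValueError("mask is empty")
    m = mask.mask
    f340 = stack.f340.astype(float).copy()
    f380 = stack.f380.astype(float).copy()
    if autofluorescence and rois is not None:
        for name, (a3, a8) in autofluorescence.items():
            sel = rois.roi(name)
            f340[:, sel] -= a3
            f380[:, sel] -= a8
    ok = m[None] & (f380 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(ok, f340 / np.where(ok, f380, 1.0), np.nan)
    conc, flags = ratio_to_concentration(ratio, calib, return_flags=True)
    valid = ok & ~flags
    conc = np.where(valid, conc, np.nan)
    return ConcentrationStack(
        data=conc, valid=valid, frame_interval=stack.frame_interval
    )


def baseline_map(cstack: ConcentrationStack, n_frames: int = 30) -> PixelMap:
    """Per-pixel mean concentration over the first ``n_frames`` frames
    (the pre-stimulation resting level; 30 frames = 7.5 s at 4 Hz)."""
    if n_frames < 1 or n_frames > cstack.n_frames:
        raise ValueError(
            f"n_frames={n_frames} outside recording of {cstack.n_frames} frames"
        )
    return _window_mean(cstack, 0, n_frames)


def stimulation_window(
    onset: float, frame_interval: float, n_frames: int = 8
) -> tuple[int, int]:
    """(start_frame, n_frames) covering the stimulation period, located
    from the protocol onset and the frame interval (8 frames = 2 s at
    4 Hz), not from signal detection."""
    start = int(round(onset / frame_interval))
    return start, n_frames


def peak_amplitude_map(
    cstack: ConcentrationStack,
    start_frame: int,
    n_frames: int = 8,
) -> PixelMap:
    """Per-pixel mean concentration over the stimulation window."""
    if start_frame < 0 or start_frame + n_frames > cstack.n_frames:
        raise ValueError("stimulation window outside the recording")
    return _window_mean(cstack, start_frame, start_frame + n_frames)


def _window_mean(cstack: ConcentrationStack, t0: int, t1: int) -> PixelMap:
    window = cstack.data[t0:t1]
    wvalid = cstack.valid[t0:t1]
    count = wvalid.sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.nansum(np.where(wvalid, window, 0.0), axis=0) / np.maximum(
            count, 1
        )
    valid = count == (t1 - t0)
    return PixelMap(
        data=np.where(count > 0, mean, np.nan),
        semantics="concentration-nM",
        valid=valid,
    )


@dataclass
class DistanceMap:
    """Quasi-Euclidean distance (in pixels) to the soma centre within a mask."""

    map: PixelMap
    soma_center: tuple[int, int]
    metric: str = "quasi-euclidean"


def geodesic_distance_map(
    mask: NeuronMask | np.ndarray, soma_center: tuple[int, int]
) -> DistanceMap:
    """Shortest-path distance from every mask pixel to the soma centre.

    8-connected pixel graph with edge weights 1 (axial) and sqrt(2)
    (diagonal), restricted to mask pixels. Pixels not connected to the
    soma centre are invalid and carry +inf.
    """
    m = mask.mask if isinstance(mask, NeuronMask) else np.asarray(mask, bool)
    r0, c0 = soma_center
    h, w = m.shape
    if not (0 <= r0 < h and 0 <= c0 < w) or not m[r0, c0]:
        raise ValueError("soma_center must lie inside the mask")

    idx = -np.ones(m.shape, dtype=np.int64)
    pix = np.argwhere(m)
    idx[m] = np.arange(len(pix))
    rows, cols, weights = [], [], []
    for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
        wgt = 1.0 if dr * dc == 0 else SQRT2
        src_r = slice(max(0, -dr), h - max(0, dr))
        src_c = slice(max(0, -dc), w - max(0, dc))
        dst_r = slice(max(0, dr), h - max(0, -dr))
        dst_c = slice(max(0, dc), w - max(0, -dc))
        both = m[src_r, src_c] & m[dst_r, dst_c]
        a = idx[src_r, src_c][both]
        b = idx[dst_r, dst_c][both]
        rows.append(a)
        cols.append(b)
        weights.append(np.full(len(a), wgt))
    if rows:
        graph = coo_matrix(
            (np.concatenate(weights), (np.concatenate(rows), np.concatenate(cols))),
            shape=(len(pix), len(pix)),
        )
    else:
        graph = coo_matrix((len(pix), len(pix)))
    dist = dijkstra(graph.tocsr(), directed=False, indices=idx[r0, c0])

    out = np.full(m.shape, np.inf)
    out[m] = dist
    valid = m & np.isfinite(out)
    pm = PixelMap(data=out, semantics="distance-px", valid=valid)
    return DistanceMap(map=pm, soma_center=(int(r0), int(c0)))


@dataclass
class MapCorrelation:
    """Pearson correlation between two pixel maps over shared valid pixels."""

    r: float
    p: float
    n: int
    per_compartment: dict[str, tuple[float, int]] | None = None


def map_correlation(
    map_a: PixelMap,
    map_b: PixelMap,
    rois: CompartmentROIs | None = None,
) -> MapCorrelation:
    """Correlate two maps pixel-wise (e.g. peak amplitude vs baseline, or
    amplitude vs distance from the soma), optionally per compartment."""
    if map_a.data.shape != map_b.data.shape:
        raise ValueError("maps must share shape")
    shared = (
        map_a.valid & map_b.valid
        & np.isfinite(map_a.data) & np.isfinite(map_b.data)
    )
    n = int(shared.sum())
    if n < 3:
        raise ValueError(f"only {n} shared valid pixels (< 3)")
    r, p = pearsonr(map_a.data[shared], map_b.data[shared])
    per = None
    if rois is not None:
        per = {}
        for name in rois.names:
            sel = shared & rois.roi(name)
            k = int(sel.sum())
            if k >= 3:
                rr, _ = pearsonr(map_a.data[sel], map_b.data[sel])
                per[name] = (float(rr), k)
            else:
                per[name] = (float("nan"), k)
    return MapCorrelation(r=float(r), p=float(p), n=n, per_compartment=per)
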