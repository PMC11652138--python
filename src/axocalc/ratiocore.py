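"""Preprocessing and inverse-correlation segmentation of dual-wavelength stacks.

The segmentation principle: at a pixel reporting genuine ratiometric signal,
the 340 nm trace rises when Ca2+ rises while the 380 nm trace falls, so the
two channel traces are negatively correlated over the recording. Pixels
dominated by bleaching, movement or debris move both channels together and
correlate neutrally or positively. Thresholding the pixel-wise Pearson
correlation map (default threshold -0.3) therefore isolates the responding
neuronal silhouette and rejects contamination that intensity thresholding
cannot.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage
from skimage.morphology import remove_small_objects
from skimage.registration import phase_cross_correlation

from .datatypes import (
    COMPARTMENTS,
    CompartmentROIs,
    NeuronMask,
    PixelMap,
    RatiometricStack,
    RatioTrace,
)

__all__ = [
    "register_stacks",
    "subtract_background",
    "correlation_map",
    "segment_by_correlation",
    "segment_by_intensity",
    "define_compartment_rois",
    "extract_roi_traces",
    "RegistrationError",
    "InsufficientFramesError",
    "EmptyROIError",
]


class RegistrationError(RuntimeError):
    pass


class InsufficientFramesError(ValueError):
    pass


class EmptyROIError(ValueError):
    pass


def _integer_shift(frame: np.ndarray, shift: tuple[int, int]) -> np.ndarray:
    """Translate a frame by whole pixels, zero-filling the exposed border."""
    out = np.zeros_like(frame)
    dr, dc = shift
    h, w = frame.shape
    src_r = slice(max(0, -dr), min(h, h - dr))
    src_c = slice(max(0, -dc), min(w, w - dc))
    dst_r = slice(max(0, dr), min(h, h + dr))
    dst_c = slice(max(0, dc), min(w, w + dc))
    out[dst_r, dst_c] = frame[src_r, src_c]
    return out


def register_stacks(
    stack: RatiometricStack, max_shift: float = 10.0
) -> tuple[RatiometricStack, np.ndarray]:
    """Align the 380 nm channel onto the 340 nm channel frame by frame.

    Per-frame integer-pixel translation estimated by cross-correlation.
    Constant (blank) frames are assigned shift (0, 0) by convention.

    Returns the aligned stack and the (T, 2) array of detected (row, col)
    displacements of the 380 frame relative to the 340 frame (the applied
    correction is their negation). A frame whose estimated shift exceeds
    ``max_shift`` raises :class:`RegistrationError` naming the frame.
    """
    if max_shift < 0:
        raise ValueError("max_shift must be non-negative")
    f380 = stack.f380.copy()
    shifts = np.zeros((stack.n_frames, 2), dtype=int)
    for t in range(stack.n_frames):
        ref, mov = stack.f340[t], stack.f380[t]
        if np.ptp(ref) == 0 or np.ptp(mov) == 0:
            continue  # blank frame: (0, 0) by convention
        corr_shift, _, _ = phase_cross_correlation(ref, mov, upsample_factor=1)
        corr_shift = np.round(corr_shift).astype(int)
        disp = -corr_shift  # displacement of the 380 frame relative to 340
        if np.any(np.abs(disp) > max_shift):
            raise RegistrationError(
                f"frame {t}: estimated shift {tuple(disp)} exceeds "
                f"max_shift={max_shift}"
            )
        shifts[t] = disp
        if np.any(corr_shift):
            f380[t] = _integer_shift(mov, (int(corr_shift[0]), int(corr_shift[1])))
    aligned = RatiometricStack(
        f340=stack.f340.copy(),
        f380=f380,
        frame_interval=stack.frame_interval,
        pixel_size=stack.pixel_size,
    )
    return aligned, shifts


def subtract_background(
    stack: RatiometricStack,
    blank: RatiometricStack,
    floor: float = 0.0,
) -> RatiometricStack:
    """Subtract the time-averaged blank recording per channel per pixel.

    The blank is an identically acquired recording of an identical sample
    preparation containing imaging medium but no cells; its time average
    estimates camera offset plus medium fluorescence. Results are clipped
    at ``floor`` (default 0).
    """
    if blank.f340.shape[1:] != stack.f340.shape[1:]:
        raise ValueError(
            f"blank frame shape {blank.f340.shape[1:]} does not match "
            f"stack frame shape {stack.f340.shape[1:]}"
        )
    b340 = blank.f340.mean(axis=0)
    b380 = blank.f380.mean(axis=0)
    return RatiometricStack(
        f340=np.maximum(stack.f340 - b340, floor),
        f380=np.maximum(stack.f380 - b380, floor),
        frame_interval=stack.frame_interval,
        pixel_size=stack.pixel_size,
    )


def correlation_map(stack: RatiometricStack) -> PixelMap:
    """Pixel-wise Pearson correlation of the 340 and 380 nm traces.

    Computed over the full recording (one map per recording). Pixels with
    zero variance in either channel carry no usable temporal signal; they
    are marked invalid and assigned 0.
    """
    if stack.n_frames < 3:
        raise InsufficientFramesError(
            f"correlation map needs >= 3 frames, got {stack.n_frames}"
        )
    a = stack.f340 - stack.f340.mean(axis=0)
    b = stack.f380 - stack.f380.mean(axis=0)
    sa = np.sqrt((a * a).sum(axis=0))
    sb = np.sqrt((b * b).sum(axis=0))
    valid = (sa > 0) & (sb > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (a * b).sum(axis=0) / (sa * sb)
    r = np.where(valid, np.clip(r, -1.0, 1.0), 0.0)
    return PixelMap(data=r, semantics="correlation", valid=valid)


def segment_by_correlation(
    corr: PixelMap,
    threshold: float = -0.3,
    min_component_px: int = 10,
) -> NeuronMask:
    """Threshold the correlation map to segment the responding silhouette.

    A pixel belongs to the mask when it is valid and r <= threshold;
    8-connected components smaller than ``min_component_px`` are removed.
    """
    if corr.semantics != "correlation":
        raise ValueError("segment_by_correlation requires a correlation map")
    if not (-1.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [-1, 1]")
    raw = corr.valid & (corr.data <= threshold)
    if min_component_px > 1:
        # drop components strictly smaller than min_component_px
        cleaned = remove_small_objects(
            raw, max_size=min_component_px - 1, connectivity=2
        )
    else:
        cleaned = raw
    return NeuronMask(mask=cleaned, provenance="correlation", threshold=threshold)


def segment_by_intensity(
    stack: RatiometricStack,
    threshold_340: float,
    threshold_380: float,
) -> NeuronMask:
    """Conventional intensity segmentation baseline.

    Each channel's median projection is thresholded and the two per-channel
    masks are combined by intersection.
    """
    if threshold_340 < 0 or threshold_380 < 0:
        raise ValueError("intensity thresholds must be non-negative")
    med340 = np.median(stack.f340, axis=0)
    med380 = np.median(stack.f380, axis=0)
    mask = (med340 >= threshold_340) & (med380 >= threshold_380)
    return NeuronMask(
        mask=mask, provenance="intensity", threshold=(threshold_340, threshold_380)
    )


def define_compartment_rois(
    mask: NeuronMask,
    annotation: np.ndarray,
    names: dict[str, int],
) -> CompartmentROIs:
    """Restrict a user-supplied compartment annotation to the segmented mask.

    ``annotation`` is a label image whose codes are described by ``names``
    (compartment name -> code). Each ROI is annotation == code intersected
    with the mask; empty intersections are reported as warnings.
    """
    annotation = np.asarray(annotation)
    if annotation.shape != mask.mask.shape:
        raise ValueError("annotation shape does not match mask")
    unknown = set(names) - set(COMPARTMENTS)
    if unknown:
        raise ValueError(f"unknown compartment labels: {sorted(unknown)}")
    present = set(np.unique(annotation)) - {0}
    undeclared = present - set(names.values())
    if undeclared:
        raise ValueError(
            f"annotation contains undeclared label codes: {sorted(undeclared)}"
        )
    out = np.where(mask.mask, annotation, 0)
    for name, code in names.items():
        if np.any(annotation == code) and not np.any(out == code):
            warnings.warn(
                f"compartment '{name}' has no pixels inside the mask",
                stacklevel=2,
            )
    return CompartmentROIs(labels=out, names=dict(names))


def extract_roi_traces(
    stack: RatiometricStack,
    rois: CompartmentROIs,
    autofluorescence: dict[str, tuple[float, float]] | None = None,
) -> dict[str, RatioTrace]:
    """Mean ROI intensity traces, autofluorescence-corrected, with R = F340/F380.

    ``autofluorescence`` maps compartment name to the (340 nm, 380 nm)
    contribution measured in unloaded neurons; it is subtracted from the
    ROI-mean signal before the ratio is formed. Frames where the corrected
    F380 is <= 0 are flagged invalid (ratio undefined there).
    """
    autofluorescence = autofluorescence or {}
    times = stack.times
    traces: dict[str, RatioTrace] = {}
    for name in rois.names:
        roi = rois.roi(name)
        if not roi.any():
            raise EmptyROIError(f"ROI '{name}' is empty")
        af340, af380 = autofluorescence.get(name, (0.0, 0.0))
        if af340 < 0 or af380 < 0:
            raise ValueError("autofluorescence values must be non-negative")
        f340 = stack.f340[:, roi].mean(axis=1) - af340
        f380 = stack.f380[:, roi].mean(axis=1) - af380
        valid = f380 > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(valid, f340 / np.where(valid, f380, 1.0), np.nan)
        traces[name] = RatioTrace(
            time=times, f340=f340, f380=f380, ratio=ratio, valid=valid,
            compartment=name,
        )
    return traces
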