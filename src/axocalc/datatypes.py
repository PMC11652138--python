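"""Shared container types for ratiometric calcium and transport analysis.

These are thin, validated dataclasses; all heavy lifting lives in the
operation modules (:mod:`axocalc.ratiocore`, :mod:`axocalc.calib`,
:mod:`axocalc.maps`, :mod:`axocalc.transport`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "StimulationProtocol",
    "RatiometricStack",
    "PixelMap",
    "NeuronMask",
    "CompartmentROIs",
    "RatioTrace",
    "CalciumTrace",
    "AxonPath",
    "Kymograph",
    "TransportEvent",
    "MitoTrajectory",
    "TransportSummary",
    "ComparisonResult",
    "COMPARTMENTS",
]

#: Canonical compartment labels used throughout the pipeline.
COMPARTMENTS = ("axon", "dendrites", "soma", "nucleus", "cytosol")


@dataclass(frozen=True)
class StimulationProtocol:
    """An electrical field stimulation paradigm: a train of action potentials.

    Parameters
    ----------
    frequency : float
        Pulse frequency in Hz.
    duration : float
        Train duration in seconds.
    onset : float
        Time of the first pulse within the recording, in seconds.
    """

    frequency: float
    duration: float
    onset: float = 0.0

    def __post_init__(self) -> None:
        if self.frequency < 0 or self.duration < 0 or self.onset < 0:
            raise ValueError(
                "frequency, duration and onset must all be non-negative"
            )

    @property
    def offset(self) -> float:
        """Time of the end of the train, seconds."""
        return self.onset + self.duration

    def ap_count(self) -> int:
        """Number of action potentials evoked: round(frequency x duration)."""
        return int(round(self.frequency * self.duration))

    def pulse_times(self) -> np.ndarray:
        """Times of the individual pulses, seconds; first pulse at onset."""
        n = self.ap_count()
        if n == 0:
            return np.empty(0)
        return self.onset + np.arange(n) / self.frequency


def ap_count(protocol: StimulationProtocol) -> int:
    """Action-potential count of a stimulation protocol (module-level alias)."""
    return protocol.ap_count()


@dataclass
class RatiometricStack:
    """Paired 340/380 nm excitation time-lapse stacks.

    ``f340`` and ``f380`` are (T, H, W) arrays in arbitrary camera units.
    """

    f340: np.ndarray
    f380: np.ndarray
    frame_interval: float  # seconds
    pixel_size: float = 1.0  # micrometres per pixel

    def __post_init__(self) -> None:
        self.f340 = np.asarray(self.f340, dtype=float)
        self.f380 = np.asarray(self.f380, dtype=float)
        if self.f340.shape != self.f380.shape:
            raise ValueError(
                f"channel shapes differ: {self.f340.shape} vs {self.f380.shape}"
            )
        if self.f340.ndim != 3:
            raise ValueError("stacks must be 3-D (T, H, W)")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.f340.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.f340.shape

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


MapSemantics = Literal["correlation", "concentration-nM", "distance-px", "intensity"]


@dataclass
class PixelMap:
    """An (H, W) scalar image with value semantics and a validity mask."""

    data: np.ndarray
    semantics: MapSemantics
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("PixelMap data must be 2-D")
        if self.valid is None:
            self.valid = np.ones(self.data.shape, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.data.shape:
                raise ValueError("validity mask shape mismatch")
        if self.semantics == "correlation":
            v = self.data[self.valid]
            if v.size and (np.nanmin(v) < -1 - 1e-9 or np.nanmax(v) > 1 + 1e-9):
                raise ValueError("correlation map values outside [-1, 1]")


@dataclass
class NeuronMask:
    """Binary neuronal silhouette with segmentation provenance."""

    mask: np.ndarray
    provenance: Literal["correlation", "intensity", "ground-truth"]
    threshold: float | tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass
class CompartmentROIs:
    """Compartment label image; labels are names mapping to integer codes."""

    labels: np.ndarray  # (H, W) int, 0 = unlabeled
    names: dict[str, int]  # compartment name -> code (>0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        unknown = set(self.names) - set(COMPARTMENTS)
        if unknown:
            raise ValueError(f"unknown compartment labels: {sorted(unknown)}")

    def roi(self, name: str) -> np.ndarray:
        """Boolean ROI for one compartment."""
        return self.labels == self.names[name]

    def pixel_counts(self) -> dict[str, int]:
        return {name: int((self.labels == code).sum()) for name, code in self.names.items()}


@dataclass
class RatioTrace:
    """Background- and autofluorescence-corrected ROI trace with R = F340/F380."""

    time: np.ndarray  # seconds
    f340: np.ndarray
    f380: np.ndarray
    ratio: np.ndarray
    valid: np.ndarray
    compartment: str | None = None

    def __post_init__(self) -> None:
        n = len(self.time)
        for name in ("f340", "f380", "ratio", "valid"):
            if len(getattr(self, name)) != n:
                raise ValueError("trace arrays must share length")


@dataclass
class CalciumTrace:
    """Absolute calcium concentration over time for one compartment, nM."""

    time: np.ndarray
    concentration: np.ndarray  # nM
    valid: np.ndarray
    compartment: str | None = None

    @property
    def peak(self) -> float:
        c = self.concentration[self.valid]
        return float(np.max(c)) if c.size else float("nan")


@dataclass
class AxonPath:
    """Ordered polyline along an axon; positions in pixel coordinates (row, col).

    ``width`` is the perpendicular averaging band (pixels) used when reading
    intensity along the path. The soma end is the first vertex; anterograde
    means increasing arc length.
    """

    vertices: np.ndarray  # (N, 2) float pixel coordinates (row, col)
    pixel_size: float = 1.0  # micrometres per pixel
    width: int = 3

    def __post_init__(self) -> None:
        self.vertices = np.atleast_2d(np.asarray(self.vertices, dtype=float))
        if self.vertices.shape[0] < 2 or self.vertices.shape[1] != 2:
            raise ValueError("path needs at least two (row, col) vertices")
        if self.width < 1:
            raise ValueError("width must be >= 1 pixel")
        seg = np.linalg.norm(np.diff(self.vertices, axis=0), axis=1)
        if np.any(seg <= 0):
            raise ValueError("arc length must be strictly increasing")
        self._cumlen_px = np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def length_px(self) -> float:
        return float(self._cumlen_px[-1])

    @property
    def length_um(self) -> float:
        return self.length_px * self.pixel_size

    def sample(self, arclen_px: np.ndarray) -> np.ndarray:
        """Interpolate (row, col) coordinates at the given arc lengths (px)."""
        arclen_px = np.asarray(arclen_px, dtype=float)
        r = np.interp(arclen_px, self._cumlen_px, self.vertices[:, 0])
        c = np.interp(arclen_px, self._cumlen_px, self.vertices[:, 1])
        return np.stack([r, c], axis=-1)


@dataclass
class Kymograph:
    """Time (rows) x position-along-path (columns) intensity image."""

    data: np.ndarray  # (T, L)
    frame_interval: float  # seconds
    pixel_size: float  # micrometres per column

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("kymograph must be 2-D (time x position)")


EventType = Literal["run-antero", "run-retro", "pause"]


@dataclass
class TransportEvent:
    """One motility event: a processive run or a pause."""

    type: EventType
    start: float  # seconds
    end: float  # seconds
    displacement: float  # micrometres, signed (anterograde positive)

    @property
    def duration(self) -> float:
        return self.end - self.start

    @property
    def velocity(self) -> float:
        """Mean velocity over the event, um/s (signed)."""
        return self.displacement / self.duration if self.duration > 0 else 0.0


@dataclass
class MitoTrajectory:
    """Per-mitochondrion position along the axon over time.

    Positions are micrometres from the somatic end of the traced segment.
    """

    id: int
    time: np.ndarray  # seconds
    position: np.ndarray  # micrometres
    events: list[TransportEvent] = field(default_factory=list)
    segment: int = 0

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.position = np.asarray(self.position, dtype=float)
        if self.time.shape != self.position.shape:
            raise ValueError("time and position must share shape")
        if self.time.size >= 2 and np.any(np.diff(self.time) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def span(self) -> tuple[float, float]:
        return float(self.time[0]), float(self.time[-1])


@dataclass
class TransportSummary:
    """Ensemble transport metrics over a set of trajectories."""

    n_mito: int
    total_distance: np.ndarray  # per mito, um (sum of |event displacements|)
    antero_distance: np.ndarray
    retro_distance: np.ndarray
    net_displacement: np.ndarray
    mobile: np.ndarray  # per mito bool
    mean_moving_velocity: np.ndarray  # per mito, um/s, NaN if never moving
    pause_count: np.ndarray
    time_mobile_fraction: np.ndarray  # per mito fraction of time in run state
    bin_edges: np.ndarray  # seconds, len B+1
    bin_distance: np.ndarray  # (n_mito, B) distance per mito per bin, um
    bin_mean: np.ndarray  # (B,) mean over mitochondria
    bin_sem: np.ndarray  # (B,)
    mobility_min_distance: float
    bin_width: float

    @property
    def mobile_fraction(self) -> float:
        return float(self.mobile.mean()) if self.n_mito else float("nan")


@dataclass
class ComparisonResult:
    """Two-group comparison following the normality-gated test choice."""

    n_a: int
    n_b: int
    test: Literal["t", "mannwhitneyu"]
    statistic: float
    p_value: float
    mean_a: float
    mean_b: float
    std_a: float
    std_b: float
    normal_a: bool
    normal_b: bool
    stars: str = "ns"

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")
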