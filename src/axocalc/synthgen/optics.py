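"""Forward optical model: from ground-truth concentration fields to raw
camera stacks.

The dual-excitation channels are rendered so that the dye-derived signal
splits a total brightness S(x) between them according to the ratio R that
the calibration maps the local concentration to:

    F340_dye = S * R / (1 + R),   F380_dye = S / (1 + R)

so F340_dye + F380_dye = S and F340_dye / F380_dye = R exactly. A rising
concentration therefore moves the two channels in opposite directions —
the anti-correlation the segmentation exploits — while bleaching (a
common multiplicative decay of S) and moving debris (added identically up
to a fixed split in both channels) correlate the channels positively.
Camera offset/medium background and compartment-specific autofluorescence
are added on top; shot noise is approximated as Gaussian with variance
equal to the expected count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..calib import CalibrationParams, concentration_to_ratio
from ..datatypes import AxonPath, RatiometricStack
from .calcium import CalciumField
from .phantom import NeuronPhantom

__all__ = [
    "FuraOpticsParams",
    "RenderInfo",
    "render_fura_stack",
    "MitoOpticsParams",
    "render_mito_movie",
]


def _default_autofluorescence() -> dict[str, tuple[float, float]]:
    # counts per channel (340, 380) measured in unloaded neurons
    return {
        "axon": (10.0, 15.0),
        "dendrites": (10.0, 15.0),
        "soma": (20.0, 30.0),
        "nucleus": (15.0, 20.0),
        "cytosol": (20.0, 30.0),
    }


@dataclass(frozen=True)
class FuraOpticsParams:
    """Rendering parameters for the dual-wavelength stacks.

    Default counts emulate a 12-bit widefield camera: ~2000-count dye
    signal over a 100-count background with ~6-count read noise.
    """

    brightness: float = 2000.0  # total dye counts S per neuron pixel
    brightness_cv: float = 0.1  # static per-pixel dye-loading variation
    background: float = 100.0  # camera offset + medium, counts
    autofluorescence: dict[str, tuple[float, float]] = field(
        default_factory=_default_autofluorescence
    )
    bleach_rate: float = 0.002  # 1/s, common-mode on the dye signal
    read_noise: float = 6.0  # counts RMS, Gaussian
    photon_noise: bool = True
    n_debris: int = 3
    debris_brightness: float = 1500.0
    debris_radius: tuple[float, float] = (2.0, 5.0)
    debris_speed: float = 0.15  # px per frame drift
    debris_bleach_rate: float = 0.03  # 1/s, much faster than the dye
    debris_split: float = 0.45  # fraction of debris light in the 340 channel
    n_fibers: int = 0  # bright non-responsive fibers crossing the field
    fiber_brightness: float = 1800.0
    fiber_ratio: float = 1.0  # fixed 340/380 ratio of the fiber signal
    brightness_scale: np.ndarray | None = None  # optional (H, W) multiplier

    def noiseless(self) -> "FuraOpticsParams":
        """No noise, bleaching, debris or fibers: exact round-trips."""
        return FuraOpticsParams(
            brightness=self.brightness,
            brightness_cv=0.0,
            background=self.background,
            autofluorescence=dict(self.autofluorescence),
            bleach_rate=0.0,
            read_noise=0.0,
            photon_noise=False,
            n_debris=0,
            n_fibers=0,
            brightness_scale=self.brightness_scale,
        )


@dataclass
class RenderInfo:
    """Side products of rendering used as test oracles."""

    debris_mask: np.ndarray  # pixels ever covered by a debris object
    fiber_mask: np.ndarray
    debris_tracks: list[np.ndarray]  # per object (T, 2) centre coordinates
    autofluorescence: dict[str, tuple[float, float]]


def _gaussian_blob(
    h: int, w: int, center: tuple[float, float], sigma_r: float, sigma_c: float
) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    return np.exp(
        -((yy - center[0]) ** 2) / (2 * sigma_r**2)
        - ((xx - center[1]) ** 2) / (2 * sigma_c**2)
    )


def render_fura_stack(
    field: CalciumField,
    phantom: NeuronPhantom,
    calib: CalibrationParams,
    optics: FuraOpticsParams = FuraOpticsParams(),
    seed: int = 0,
) -> tuple[RatiometricStack, RatiometricStack, RenderInfo]:
    """Render (stack, blank, info) from a ground-truth concentration field.

    The blank is an identically sized recording of background only
    (imaging medium, no cells), as used for background correction. In the
    noiseless configuration, background + autofluorescence subtraction
    followed by the 340/380 ratio recovers ``concentration_to_ratio`` of
    the true field exactly on every neuron pixel.
    """
    if calib.r_min >= calib.r_max:
        raise ValueError("invalid calibration: R_min >= R_max")
    rng = np.random.default_rng(seed)
    conc = field.concentration
    T, h, w = conc.shape
    labels = phantom.labels
    neuron = labels > 0
    t = field.time

    ratio = np.empty_like(conc)
    ratio[:] = np.nan
    ratio[:, neuron] = concentration_to_ratio(conc[:, neuron], calib)

    s_map = np.where(neuron, optics.brightness, 0.0)
    if optics.brightness_cv > 0:
        s_map = s_map * np.maximum(
            rng.normal(1.0, optics.brightness_cv, (h, w)), 0.05
        )
    if optics.brightness_scale is not None:
        s_map = s_map * np.asarray(optics.brightness_scale, dtype=float)

    af340 = np.zeros((h, w))
    af380 = np.zeros((h, w))
    for name, (a3, a8) in optics.autofluorescence.items():
        sel = labels == phantom.names[name]
        af340[sel] = a3
        af380[sel] = a8

    bleach = np.exp(-optics.bleach_rate * t)[:, None, None]
    frac340 = np.zeros_like(ratio)
    frac340[:, neuron] = ratio[:, neuron] / (1.0 + ratio[:, neuron])
    frac380 = np.zeros_like(ratio)
    frac380[:, neuron] = 1.0 / (1.0 + ratio[:, neuron])
    s_t = s_map[None] * bleach
    f340 = optics.background + af340[None] + s_t * frac340
    f380 = optics.background + af380[None] + s_t * frac380

    debris_mask = np.zeros((h, w), dtype=bool)
    tracks: list[np.ndarray] = []
    if optics.n_debris > 0:
        dec = np.exp(-optics.debris_bleach_rate * t)
        for _ in range(optics.n_debris):
            c0 = rng.uniform([2, 2], [h - 3, w - 3])
            ang = rng.uniform(0, 2 * np.pi)
            vel = optics.debris_speed * np.array([np.sin(ang), np.cos(ang)])
            sr = rng.uniform(*optics.debris_radius)
            sc = rng.uniform(*optics.debris_radius)
            track = np.clip(
                c0[None] + vel[None] * np.arange(T)[:, None], 2, [h - 3, w - 3]
            )
            tracks.append(track)
            for i in range(T):
                blob = _gaussian_blob(h, w, tuple(track[i]), sr, sc)
                amp = optics.debris_brightness * dec[i]
                f340[i] += optics.debris_split * amp * blob
                f380[i] += (1 - optics.debris_split) * amp * blob
                debris_mask |= blob > 0.2

    fiber_mask = np.zeros((h, w), dtype=bool)
    if optics.n_fibers > 0:
        dec = np.exp(-optics.debris_bleach_rate * t)
        rfix = optics.fiber_ratio
        for _ in range(optics.n_fibers):
            edge = rng.integers(0, 2)
            if edge == 0:
                r0, r1 = 0.0, float(h - 1)
                c0, c1 = rng.uniform(0, w - 1, 2)
            else:
                c0, c1 = 0.0, float(w - 1)
                r0, r1 = rng.uniform(0, h - 1, 2)
            n = int(2 * max(h, w))
            rr = np.clip(np.round(np.linspace(r0, r1, n)).astype(int), 0, h - 1)
            cc = np.clip(np.round(np.linspace(c0, c1, n)).astype(int), 0, w - 1)
            fm = np.zeros((h, w), dtype=bool)
            fm[rr, cc] = True
            fm |= np.roll(fm, 1, axis=0)
            fiber_mask |= fm
        amp_t = optics.fiber_brightness * dec
        add = fiber_mask[None] * amp_t[:, None, None]
        f340 = f340 + add * (rfix / (1 + rfix))
        f380 = f380 + add * (1 / (1 + rfix))

    blank340 = np.full((T, h, w), optics.background)
    blank380 = np.full((T, h, w), optics.background)

    def corrupt(img: np.ndarray) -> np.ndarray:
        out = img
        if optics.photon_noise:
            out = out + rng.normal(0.0, 1.0, img.shape) * np.sqrt(
                np.maximum(img, 0.0)
            )
        if optics.read_noise > 0:
            out = out + rng.normal(0.0, optics.read_noise, img.shape)
        return np.maximum(out, 0.0) if out is not img else img

    stack = RatiometricStack(
        f340=corrupt(f340),
        f380=corrupt(f380),
        frame_interval=field.frame_interval,
        pixel_size=phantom.pixel_size,
    )
    blank = RatiometricStack(
        f340=corrupt(blank340),
        f380=corrupt(blank380),
        frame_interval=field.frame_interval,
        pixel_size=phantom.pixel_size,
    )
    info = RenderInfo(
        debris_mask=debris_mask,
        fiber_mask=fiber_mask,
        debris_tracks=tracks,
        autofluorescence=dict(optics.autofluorescence),
    )
    return stack, blank, info


@dataclass(frozen=True)
class MitoOpticsParams:
    """Rendering parameters for single-channel mitochondria movies."""

    spot_amplitude: float = 400.0  # counts above background per mitochondrion
    spot_sigma: float = 1.3  # px
    background: float = 50.0
    read_noise: float = 5.0
    photon_noise: bool = True

    def noiseless(self) -> "MitoOpticsParams":
        return MitoOpticsParams(
            spot_amplitude=self.spot_amplitude,
            spot_sigma=self.spot_sigma,
            background=self.background,
            read_noise=0.0,
            photon_noise=False,
        )


def render_mito_movie(
    trajectories,
    path: AxonPath,
    shape: tuple[int, int],
    optics: MitoOpticsParams = MitoOpticsParams(),
    frame_times: np.ndarray | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Render mitochondria as Gaussian spots moving along an axon path.

    ``trajectories`` supply position along the path in micrometres; the
    path converts micrometres to pixel coordinates. Returns a (T, H, W)
    float array. Trajectories exceeding the path length raise a bounds
    error.
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    if frame_times is None:
        if not trajectories:
            raise ValueError("frame_times required when no trajectories given")
        frame_times = np.asarray(trajectories[0].time, dtype=float)
    T = len(frame_times)
    movie = np.full((T, h, w), optics.background, dtype=float)

    rad = int(np.ceil(4 * optics.spot_sigma))
    dy, dx = np.mgrid[-rad : rad + 1, -rad : rad + 1]
    for traj in trajectories:
        if np.max(traj.position) > path.length_um + 1e-6 or np.min(traj.position) < -1e-6:
            raise ValueError(
                f"trajectory {traj.id} leaves the path "
                f"(length {path.length_um:.1f} um)"
            )
        pos = np.interp(frame_times, traj.time, traj.position)
        coords = path.sample(pos / path.pixel_size)
        for i in range(T):
            r0, c0 = coords[i]
            ri, ci = int(round(r0)), int(round(c0))
            yy = ri + dy
            xx = ci + dx
            ok = (yy >= 0) & (yy < h) & (xx >= 0) & (xx < w)
            g = optics.spot_amplitude * np.exp(
                -((yy - r0) ** 2 + (xx - c0) ** 2) / (2 * optics.spot_sigma**2)
            )
            movie[i][yy[ok], xx[ok]] += g[ok]

    if optics.photon_noise:
        movie = movie + rng.normal(0.0, 1.0, movie.shape) * np.sqrt(
            np.maximum(movie, 0.0)
        )
    if optics.read_noise > 0:
        movie = movie + rng.normal(0.0, optics.read_noise, movie.shape)
    return np.maximum(movie, 0.0)
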