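"""Compartmentalised neuron phantom: soma, nucleus, cytosol ring, dendritic
tree and a single axon, rendered as a label image plus vector paths.

The soma is modelled as three concentric zones (nucleus, somatic-cytosol
ring, remaining soma annulus) so that the five analysis compartments —
axon, dendrites, soma, nucleus, cytosol — partition the silhouette with
pairwise-disjoint labels. Neurites are jittered random walks rasterised
with a small structuring disk.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..datatypes import COMPARTMENTS, AxonPath

__all__ = ["GeometryParams", "NeuronPhantom", "build_neuron_phantom"]

#: Label codes for the phantom / annotation images (0 = background).
LABEL_CODES = {name: i + 1 for i, name in enumerate(COMPARTMENTS)}


@dataclass(frozen=True)
class GeometryParams:
    """Geometry of the synthetic neuron.

    Pixel size defaults to 0.32 um/px (20x objective, 6.45 um camera
    pixels), so the default 160 px field spans ~51 um.
    """

    shape: tuple[int, int] = (160, 160)
    soma_radius: float = 8.0  # px
    nucleus_radius_frac: float = 0.55  # nucleus radius / soma radius
    cytosol_outer_frac: float = 0.8  # outer radius of the cytosol ring / soma
    n_dendrites: int = 5
    dendrite_length: tuple[float, float] = (40.0, 65.0)  # px
    dendrite_radius: float = 1.0  # rasterisation half-width, px
    axon_length: float = 60.0  # px
    axon_radius: float = 1.0
    step: float = 4.0  # random-walk segment length, px
    angle_jitter: float = 0.18  # radians per step
    pixel_size: float = 0.32  # um / px

    def __post_init__(self) -> None:
        h, w = self.shape
        if min(h, w) < 2 * self.soma_radius + 6:
            raise ValueError("image too small to contain the soma")
        if not (0 < self.nucleus_radius_frac < self.cytosol_outer_frac <= 1):
            raise ValueError(
                "require 0 < nucleus_radius_frac < cytosol_outer_frac <= 1"
            )
        if self.n_dendrites < 0 or self.axon_length <= 0:
            raise ValueError("invalid neurite parameters")


@dataclass
class NeuronPhantom:
    """Ground-truth neuron geometry.

    ``labels`` holds the compartment codes of :data:`LABEL_CODES`;
    ``branch_labels`` identifies individual dendritic branches (0 = not a
    dendrite, k = k-th branch) for per-branch amplitude assignment.
    """

    labels: np.ndarray
    names: dict[str, int]
    soma_center: tuple[int, int]
    axon_path: AxonPath
    dendrite_paths: list[np.ndarray] = field(default_factory=list)
    branch_labels: np.ndarray | None = None
    pixel_size: float = 0.32

    @property
    def silhouette(self) -> np.ndarray:
        """Boolean union of all compartments."""
        return self.labels > 0

    def compartment(self, name: str) -> np.ndarray:
        return self.labels == self.names[name]


def _walk(
    start: np.ndarray,
    direction: float,
    length: float,
    step: float,
    jitter: float,
    shape: tuple[int, int],
    rng: np.random.Generator,
    margin: float = 2.0,
) -> np.ndarray:
    """Jittered random walk polyline kept inside the image with reflection."""
    h, w = shape
    pts = [start.astype(float)]
    pos = start.astype(float).copy()
    theta = direction
    travelled = 0.0
    while travelled < length:
        d = min(step, length - travelled)
        theta += rng.normal(0.0, jitter)
        nxt = pos + d * np.array([np.sin(theta), np.cos(theta)])
        # reflect off borders to stay in frame
        if not (margin <= nxt[0] <= h - 1 - margin):
            theta = -theta
            nxt = pos + d * np.array([np.sin(theta), np.cos(theta)])
        if not (margin <= nxt[1] <= w - 1 - margin):
            theta = np.pi - theta
            nxt = pos + d * np.array([np.sin(theta), np.cos(theta)])
        nxt[0] = np.clip(nxt[0], margin, h - 1 - margin)
        nxt[1] = np.clip(nxt[1], margin, w - 1 - margin)
        travelled += np.linalg.norm(nxt - pos)
        if np.linalg.norm(nxt - pos) < 1e-6:
            break
        pos = nxt
        pts.append(pos.copy())
    return np.array(pts)


def _paint_path(
    canvas: np.ndarray, path: np.ndarray, radius: float, value: int
) -> None:
    """Rasterise a polyline onto a label canvas with a disk brush."""
    h, w = canvas.shape
    seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
    total = seg.sum()
    n = max(2, int(np.ceil(total / 0.5)) + 1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    s = np.linspace(0, total, n)
    rr = np.interp(s, cum, path[:, 0])
    cc = np.interp(s, cum, path[:, 1])
    rad = int(np.ceil(radius))
    dy, dx = np.mgrid[-rad : rad + 1, -rad : rad + 1]
    brush = (dy**2 + dx**2) <= radius**2 + 0.25
    by, bx = np.nonzero(brush)
    for r0, c0 in zip(np.round(rr).astype(int), np.round(cc).astype(int)):
        ys = np.clip(r0 + by - rad, 0, h - 1)
        xs = np.clip(c0 + bx - rad, 0, w - 1)
        canvas[ys, xs] = value


def build_neuron_phantom(
    params: GeometryParams = GeometryParams(), seed: int = 0
) -> NeuronPhantom:
    """Construct a reproducible neuron phantom from (params, seed).

    Neurites radiate from the soma boundary: the axon in one randomly
    chosen direction, dendrites spread over the remaining directions.
    The soma (with its nucleus and cytosol ring) is painted last so that
    it takes precedence where neurites originate.
    """
    rng = np.random.default_rng(seed)
    h, w = params.shape
    center = np.array([h / 2.0, w / 2.0])

    labels = np.zeros((h, w), dtype=np.int32)
    branch_labels = np.zeros((h, w), dtype=np.int32)

    axon_dir = rng.uniform(0, 2 * np.pi)
    axon_start = center + params.soma_radius * np.array(
        [np.sin(axon_dir), np.cos(axon_dir)]
    )
    axon_pts = _walk(
        axon_start, axon_dir, params.axon_length, params.step,
        params.angle_jitter, (h, w), rng,
    )

    dendrite_pts: list[np.ndarray] = []
    if params.n_dendrites > 0:
        spread = np.linspace(0, 2 * np.pi, params.n_dendrites, endpoint=False)
        offsets = rng.uniform(-0.25, 0.25, size=params.n_dendrites)
        for k in range(params.n_dendrites):
            ang = axon_dir + np.pi / 2 + spread[k] * 0.75 + offsets[k]
            start = center + params.soma_radius * np.array(
                [np.sin(ang), np.cos(ang)]
            )
            length = rng.uniform(*params.dendrite_length)
            dendrite_pts.append(
                _walk(start, ang, length, params.step, params.angle_jitter,
                      (h, w), rng)
            )

    # paint order: dendrites, axon, then the soma zones take precedence
    for k, pts in enumerate(dendrite_pts, start=1):
        _paint_path(labels, pts, params.dendrite_radius, LABEL_CODES["dendrites"])
        _paint_path(branch_labels, pts, params.dendrite_radius, k)
    _paint_path(labels, axon_pts, params.axon_radius, LABEL_CODES["axon"])

    yy, xx = np.mgrid[0:h, 0:w]
    rad2 = (yy - center[0]) ** 2 + (xx - center[1]) ** 2
    r_soma = params.soma_radius
    r_nuc = params.nucleus_radius_frac * r_soma
    r_cyt = params.cytosol_outer_frac * r_soma
    soma_disk = rad2 <= r_soma**2
    labels[soma_disk] = LABEL_CODES["soma"]
    labels[rad2 <= r_cyt**2] = LABEL_CODES["cytosol"]
    labels[rad2 <= r_nuc**2] = LABEL_CODES["nucleus"]
    branch_labels[soma_disk] = 0

    soma_center = tuple(int(round(v)) for v in center)
    return NeuronPhantom(
        labels=labels,
        names=dict(LABEL_CODES),
        soma_center=soma_center,  # type: ignore[arg-type]
        axon_path=AxonPath(vertices=axon_pts, pixel_size=params.pixel_size),
        dendrite_paths=dendrite_pts,
        branch_labels=branch_labels,
        pixel_size=params.pixel_size,
    )
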