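"""Pre-assembled synthetic experiments bundling phantom, dynamics, optics
and rendered stacks with their full ground truth."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..calib import CalibrationParams
from ..datatypes import RatiometricStack, StimulationProtocol
from .calcium import CalciumField, DynamicsParams, simulate_calcium_dynamics
from .optics import FuraOpticsParams, RenderInfo, render_fura_stack
from .phantom import GeometryParams, NeuronPhantom, build_neuron_phantom

__all__ = ["GroundTruth", "fura_scene", "contaminated_scene"]


def _child_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-stage sub-seeds (< 2**31) derived from one seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


@dataclass
class GroundTruth:
    """Everything needed to score an analysis of a rendered experiment."""

    phantom: NeuronPhantom
    field: CalciumField
    stack: RatiometricStack
    blank: RatiometricStack
    info: RenderInfo
    calib: CalibrationParams
    dynamics: DynamicsParams
    optics: FuraOpticsParams
    seed: int


def fura_scene(
    protocol: StimulationProtocol | list[StimulationProtocol],
    geometry: GeometryParams = GeometryParams(),
    dynamics: DynamicsParams = DynamicsParams(),
    optics: FuraOpticsParams = FuraOpticsParams(),
    calib: CalibrationParams = CalibrationParams(),
    seed: int = 0,
    noiseless: bool = False,
    duration: float | None = None,
    frame_interval: float | None = None,
) -> GroundTruth:
    """Simulate and render one ratiometric recording with ground truth.

    ``noiseless=True`` switches both the dynamics (no cell-level
    amplitude jitter, homogeneous branches) and the optics (no noise,
    bleaching or contamination) to their exact-round-trip variants.
    """
    if noiseless:
        dynamics = dynamics.noiseless()
        optics = optics.noiseless()
    s_ph, s_dy, s_re = _child_seeds(seed, 3)
    phantom = build_neuron_phantom(geometry, seed=s_ph)
    cal_field = simulate_calcium_dynamics(
        phantom, protocol, dynamics, seed=s_dy,
        duration=duration, frame_interval=frame_interval,
    )
    stack, blank, info = render_fura_stack(
        cal_field, phantom, calib, optics, seed=s_re
    )
    return GroundTruth(
        phantom=phantom, field=cal_field, stack=stack, blank=blank,
        info=info, calib=calib, dynamics=dynamics, optics=optics, seed=seed,
    )


def contaminated_scene(
    protocol: StimulationProtocol | None = None,
    seed: int = 0,
    dim_axon_scale: float = 0.12,
) -> GroundTruth:
    """A deliberately hard segmentation scene: moving bleaching debris, a
    bright non-responsive fiber crossing the field, and a responsive but
    dim axon (brightness scaled down to ``dim_axon_scale``).

    Intensity thresholding picks up the bright contamination and loses
    the dim responsive fiber; inverse-correlation segmentation does the
    opposite.
    """
    if protocol is None:
        protocol = StimulationProtocol(frequency=20.0, duration=2.0, onset=10.0)
    geometry = GeometryParams()
    s_ph, _ = _child_seeds(seed, 2)
    phantom = build_neuron_phantom(geometry, seed=s_ph)
    scale = np.ones(phantom.labels.shape)
    scale[phantom.compartment("axon")] = dim_axon_scale
    optics = FuraOpticsParams(
        n_debris=3, n_fibers=1, brightness_scale=scale
    )
    return fura_scene(
        protocol, geometry=geometry, optics=optics, seed=seed
    )
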