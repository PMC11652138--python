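"""Inverse-correlation segmentation and absolute compartment traces.

Simulates a 100 Hz 2 s stimulation recording, segments the responding
neuron by thresholding the pixel-wise 340/380 correlation map at -0.3,
and recovers absolute calcium traces per compartment.
"""

import numpy as np

from axocalc import (
    calibrate_trace,
    correlation_map,
    define_compartment_rois,
    extract_roi_traces,
    register_stacks,
    segment_by_correlation,
    subtract_background,
    StimulationProtocol,
)
from axocalc.synthgen import fura_scene

scene = fura_scene(StimulationProtocol(100.0, 2.0, onset=10.0), seed=2)

registered, shifts = register_stacks(scene.stack)
corrected = subtract_background(registered, scene.blank)
corr = correlation_map(corrected)
mask = segment_by_correlation(corr, threshold=-0.3)

sil = scene.phantom.silhouette
jac = (mask.mask & sil).sum() / (mask.mask | sil).sum()
print(f"correlation mask: {mask.n_pixels} px, Jaccard vs ground truth "
      f"{jac:.3f}")
# negative correlation isolates responding pixels; debris is excluded

rois = define_compartment_rois(mask, scene.phantom.labels,
                               scene.phantom.names)
traces = extract_roi_traces(corrected, rois, scene.info.autofluorescence)
for name, tr in traces.items():
    ct = calibrate_trace(tr, scene.calib)
    base = np.median(ct.concentration[ct.valid][:30])
    print(f"{name:10s} baseline {base:6.1f} nM   peak {ct.peak:6.1f} nM")
# axonal peak lies near the 713 nM amplitude configured for 100 Hz bursts
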