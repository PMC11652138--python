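"""Registration, background subtraction, pixel-wise correlation maps and
inverse-correlation segmentation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from axocalc import (
    PixelMap,
    RatiometricStack,
    correlation_map,
    define_compartment_rois,
    extract_roi_traces,
    register_stacks,
    segment_by_correlation,
    segment_by_intensity,
    subtract_background,
)
from axocalc.datatypes import NeuronMask
from axocalc.ratiocore import (
    EmptyROIError,
    InsufficientFramesError,
    RegistrationError,
)
from tests.conftest import jaccard


def _stack(f340, f380, dt=0.25):
    return RatiometricStack(f340=f340, f380=f380, frame_interval=dt)


class TestRegistration:
    def test_identical_channels_zero_shift(self, noisy_scene):
        st_ = _stack(noisy_scene.stack.f340, noisy_scene.stack.f340)
        reg, shifts = register_stacks(st_)
        assert np.all(shifts == 0)
        assert np.array_equal(reg.f380, st_.f380)

    def test_synthetic_shift_recovered(self, noisy_scene):
        f380 = np.roll(noisy_scene.stack.f380, (2, -1), axis=(1, 2))
        st_ = _stack(noisy_scene.stack.f340, f380)
        _, shifts = register_stacks(st_)
        assert np.all(shifts == np.array([2, -1]))

    def test_blank_frames_zero_by_convention(self):
        st_ = _stack(np.ones((5, 16, 16)), np.ones((5, 16, 16)))
        _, shifts = register_stacks(st_)
        assert np.all(shifts == 0)

    def test_excessive_shift_names_frame(self, noisy_scene):
        f380 = np.roll(noisy_scene.stack.f380, (6, 0), axis=(1, 2))
        st_ = _stack(noisy_scene.stack.f340, f380)
        with pytest.raises(RegistrationError, match="frame 0"):
            register_stacks(st_, max_shift=3)


class TestBackgroundSubtraction:
    def test_blank_equal_to_stack_zeroes(self):
        arr = np.random.default_rng(0).uniform(10, 20, (4, 8, 8))
        st_ = _stack(arr, arr)
        out = subtract_background(st_, st_)
        # time-averaged blank: residual is deviation from the mean, >= 0 clip
        assert np.allclose(out.f340, np.maximum(arr - arr.mean(0), 0))

    def test_zero_blank_is_identity(self):
        arr = np.random.default_rng(1).uniform(10, 20, (4, 8, 8))
        st_ = _stack(arr, arr)
        zero = _stack(np.zeros((2, 8, 8)), np.zeros((2, 8, 8)))
        out = subtract_background(st_, zero)
        assert np.array_equal(out.f340, arr)

    def test_known_background_removed(self):
        # noisy but debris-free scene, unclipped subtraction: background
        # residual mean indistinguishable from zero
        from axocalc.synthgen import (
            FuraOpticsParams, GeometryParams, fura_scene,
        )
        from axocalc import StimulationProtocol

        scene = fura_scene(
            StimulationProtocol(20.0, 2.0, 10.0),
            geometry=GeometryParams(shape=(64, 64), soma_radius=5.0,
                                    n_dendrites=2, axon_length=25.0),
            optics=FuraOpticsParams(n_debris=0),
            seed=8,
        )
        out = subtract_background(scene.stack, scene.blank, floor=-np.inf)
        bg_px = ~scene.phantom.silhouette
        resid = out.f340[:, bg_px]
        sem = resid.std() / np.sqrt(resid.size)
        # per-pixel blank-average error also contributes ~sigma/sqrt(T)
        assert abs(resid.mean()) < 5 * sem + 0.1

    def test_shape_mismatch(self):
        st_ = _stack(np.zeros((3, 8, 8)), np.zeros((3, 8, 8)))
        blank = _stack(np.zeros((3, 9, 9)), np.zeros((3, 9, 9)))
        with pytest.raises(ValueError):
            subtract_background(st_, blank)


class TestCorrelationMap:
    def test_perfect_anticorrelation(self):
        y = np.linspace(1, 2, 10)[:, None, None] * np.ones((10, 4, 4))
        st_ = _stack(y, 3.0 - y)
        cm = correlation_map(st_)
        assert np.allclose(cm.data, -1.0)

    def test_common_bleaching_positive(self):
        y = np.exp(-np.linspace(0, 1, 20))[:, None, None] * np.ones((20, 4, 4))
        cm = correlation_map(_stack(y, 2 * y))
        assert np.allclose(cm.data, 1.0)

    def test_zero_variance_invalid(self):
        f340 = np.ones((10, 4, 4))
        f380 = np.random.default_rng(0).normal(5, 1, (10, 4, 4))
        cm = correlation_map(_stack(f340, f380))
        assert not cm.valid.any()
        assert np.all(cm.data == 0.0)

    def test_too_few_frames(self):
        with pytest.raises(InsufficientFramesError):
            correlation_map(_stack(np.zeros((2, 4, 4)), np.zeros((2, 4, 4))))

    @given(
        gain=st.floats(min_value=0.1, max_value=50.0),
        offset=st.floats(min_value=-10.0, max_value=10.0),
    )
    def test_invariant_under_positive_affine_rescaling(self, gain, offset):
        rng = np.random.default_rng(42)
        f340 = rng.normal(100, 10, (12, 3, 3))
        f380 = rng.normal(80, 10, (12, 3, 3))
        base = correlation_map(_stack(f340, f380)).data
        scaled = correlation_map(_stack(gain * f340 + offset, f380)).data
        assert np.allclose(base, scaled, atol=1e-9)

    def test_generator_labels_separate_signs(self, hard_scene):
        corrected = subtract_background(hard_scene.stack, hard_scene.blank)
        cm = correlation_map(corrected)
        neuron = hard_scene.phantom.silhouette
        debris_only = hard_scene.info.debris_mask & ~neuron
        assert np.median(cm.data[neuron]) < -0.3
        assert np.median(cm.data[debris_only]) >= 0.0


class TestSegmentation:
    def test_all_positive_correlation_gives_empty_mask(self):
        cm = PixelMap(data=np.ones((8, 8)), semantics="correlation")
        mask = segment_by_correlation(cm)
        assert mask.n_pixels == 0

    def test_threshold_out_of_range(self):
        cm = PixelMap(data=np.zeros((8, 8)), semantics="correlation")
        with pytest.raises(ValueError):
            segment_by_correlation(cm, threshold=-1.5)

    @given(st.floats(min_value=-0.9, max_value=0.0))
    def test_monotone_in_threshold(self, thr):
        rng = np.random.default_rng(0)
        cm = PixelMap(
            data=rng.uniform(-1, 1, (16, 16)), semantics="correlation"
        )
        loose = segment_by_correlation(cm, threshold=thr, min_component_px=1)
        tight = segment_by_correlation(
            cm, threshold=thr - 0.1, min_component_px=1
        )
        assert np.all(loose.mask | ~tight.mask)  # tight subset of loose

    def test_default_snr_jaccard(self, noisy_scene, noisy_analysis):
        _, _, mask, _ = noisy_analysis
        assert jaccard(mask.mask, noisy_scene.phantom.silhouette) >= 0.9

    def test_intensity_thresholds(self, noisy_scene):
        full = segment_by_intensity(noisy_scene.stack, 0.0, 0.0)
        assert full.mask.all()
        too_high = segment_by_intensity(noisy_scene.stack, 1e9, 1e9)
        assert not too_high.mask.any()

    def test_correlation_beats_intensity_on_hard_scene(self, hard_scene):
        corrected = subtract_background(hard_scene.stack, hard_scene.blank)
        cmask = segment_by_correlation(correlation_map(corrected))
        imask = segment_by_intensity(corrected, 300.0, 300.0)
        sil = hard_scene.phantom.silhouette
        assert jaccard(cmask.mask, sil) > jaccard(imask.mask, sil)
        # the bright non-responsive fiber fools intensity, not correlation
        fiber = hard_scene.info.fiber_mask & ~sil
        assert (imask.mask & fiber).sum() > 0
        assert (cmask.mask & fiber).sum() == 0


class TestROIs:
    def test_annotation_equal_to_mask_single_label(self):
        m = np.zeros((8, 8), bool)
        m[2:6, 2:6] = True
        mask = NeuronMask(mask=m, provenance="correlation")
        rois = define_compartment_rois(mask, m.astype(int), {"axon": 1})
        assert np.array_equal(rois.roi("axon"), m)

    def test_annotation_outside_mask_excluded(self):
        m = np.zeros((8, 8), bool)
        m[2:6, 2:6] = True
        ann = np.zeros((8, 8), int)
        ann[0, 0] = 1
        ann[3, 3] = 1
        mask = NeuronMask(mask=m, provenance="correlation")
        rois = define_compartment_rois(mask, ann, {"axon": 1})
        assert rois.roi("axon").sum() == 1

    def test_unknown_label_rejected(self):
        m = np.ones((4, 4), bool)
        mask = NeuronMask(mask=m, provenance="correlation")
        with pytest.raises(ValueError):
            define_compartment_rois(mask, m.astype(int), {"mitochondria": 1})

    def test_phantom_roi_counts(self, noisy_scene, noisy_analysis):
        _, _, mask, rois = noisy_analysis
        ph = noisy_scene.phantom
        for name in rois.names:
            expect = (ph.compartment(name) & mask.mask).sum()
            assert rois.roi(name).sum() == expect


class TestTraceExtraction:
    def test_uniform_roi_ratio(self):
        f340 = np.full((5, 4, 4), 8.0)
        f380 = np.full((5, 4, 4), 2.0)
        m = np.ones((4, 4), bool)
        mask = NeuronMask(mask=m, provenance="correlation")
        rois = define_compartment_rois(mask, m.astype(int), {"axon": 1})
        traces = extract_roi_traces(_stack(f340, f380), rois)
        assert np.allclose(traces["axon"].ratio, 4.0)

    def test_autofluorescence_swallowing_signal_flags_frames(self):
        f340 = np.full((5, 4, 4), 8.0)
        f380 = np.full((5, 4, 4), 2.0)
        m = np.ones((4, 4), bool)
        mask = NeuronMask(mask=m, provenance="correlation")
        rois = define_compartment_rois(mask, m.astype(int), {"axon": 1})
        traces = extract_roi_traces(
            _stack(f340, f380), rois, {"axon": (0.0, 2.0)}
        )
        assert not traces["axon"].valid.any()

    def test_empty_roi_raises(self):
        m = np.zeros((4, 4), bool)
        m[0, 0] = True
        mask = NeuronMask(mask=m, provenance="correlation")
        ann = np.zeros((4, 4), int)
        ann[1, 1] = 1  # outside mask -> empty intersection
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rois = define_compartment_rois(mask, ann, {"axon": 1})
        with pytest.raises(EmptyROIError):
            extract_roi_traces(_stack(np.ones((5, 4, 4)), np.ones((5, 4, 4))),
                               rois)

    def test_noiseless_round_trip(self, noiseless_scene, calib):
        from axocalc import calibrate_trace

        scene = noiseless_scene
        corrected = subtract_background(scene.stack, scene.blank)
        mask = segment_by_correlation(correlation_map(corrected))
        rois = define_compartment_rois(
            mask, scene.phantom.labels, scene.phantom.names
        )
        traces = extract_roi_traces(
            corrected, rois, scene.info.autofluorescence
        )
        for name, tr in traces.items():
            ct = calibrate_trace(tr, calib)
            assert np.allclose(
                ct.concentration, scene.field.traces[name], atol=1e-6
            )
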