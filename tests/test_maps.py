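"""Pixel-resolution maps: per-pixel calibration, baseline/peak maps,
geodesic distance and map correlations."""

import networkx as nx
import numpy as np
import pytest

from axocalc import (
    CalibrationParams,
    PixelMap,
    RatiometricStack,
    baseline_map,
    concentration_to_ratio,
    geodesic_distance_map,
    map_correlation,
    peak_amplitude_map,
    pixel_concentration_stack,
    stimulation_window,
    subtract_background,
)
from axocalc.datatypes import NeuronMask
from axocalc.maps import SQRT2, ConcentrationStack


def uniform_stack(conc, calib, shape=(6, 6), frames=40):
    r = concentration_to_ratio(conc, calib)
    f380 = np.full((frames,) + shape, 100.0)
    f340 = f380 * r
    return RatiometricStack(f340=f340, f380=f380, frame_interval=0.25)


def brute_force_distance(mask, center):
    """Independent oracle: explicit pixel graph + networkx Dijkstra."""
    G = nx.Graph()
    pts = [tuple(p) for p in np.argwhere(mask)]
    G.add_nodes_from(pts)
    for r, c in pts:
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if (dr, dc) != (0, 0) and (r + dr, c + dc) in G:
                    G.add_edge(
                        (r, c), (r + dr, c + dc),
                        weight=1.0 if dr * dc == 0 else SQRT2,
                    )
    lengths = nx.single_source_dijkstra_path_length(G, tuple(center))
    out = np.full(mask.shape, np.inf)
    for k, v in lengths.items():
        out[k] = v
    return out


class TestPixelConcentration:
    def test_uniform_stack_gives_uniform_maps(self, calib):
        cs = pixel_concentration_stack(
            uniform_stack(200.0, calib),
            NeuronMask(np.ones((6, 6), bool), "ground-truth"),
            calib,
        )
        assert np.allclose(cs.data, 200.0)
        assert cs.valid.all()

    def test_pixel_outside_mask_invalid(self, calib):
        m = np.zeros((6, 6), bool)
        m[2, 2] = True
        cs = pixel_concentration_stack(
            uniform_stack(100.0, calib), NeuronMask(m, "ground-truth"), calib
        )
        assert not cs.valid[:, 0, 0].any()
        assert cs.valid[:, 2, 2].all()
        assert np.isnan(cs.data[:, 0, 0]).all()

    def test_empty_mask_rejected(self, calib):
        with pytest.raises(ValueError):
            pixel_concentration_stack(
                uniform_stack(100.0, calib),
                NeuronMask(np.zeros((6, 6), bool), "ground-truth"),
                calib,
            )

    def test_noiseless_field_recovered_per_pixel(self, noiseless_scene):
        scene = noiseless_scene
        corrected = subtract_background(scene.stack, scene.blank)
        from tests.conftest import analyze_scene

        _, _, mask, rois = analyze_scene(scene)
        cs = pixel_concentration_stack(
            corrected, mask, scene.calib, rois, scene.info.autofluorescence
        )
        sel = mask.mask
        assert np.allclose(
            cs.data[:, sel], scene.field.concentration[:, sel], atol=1e-6
        )


class TestWindows:
    def test_constant_field_baseline(self, calib):
        cs = pixel_concentration_stack(
            uniform_stack(50.0, calib),
            NeuronMask(np.ones((6, 6), bool), "ground-truth"),
            calib,
        )
        bm = baseline_map(cs, n_frames=30)
        assert np.allclose(bm.data, 50.0)

    def test_full_length_baseline_is_whole_trace_mean(self, calib):
        cs = pixel_concentration_stack(
            uniform_stack(80.0, calib, frames=35),
            NeuronMask(np.ones((6, 6), bool), "ground-truth"),
            calib,
        )
        bm = baseline_map(cs, n_frames=35)
        assert np.allclose(bm.data, 80.0)

    def test_flat_trace_peak_equals_baseline(self, calib):
        cs = pixel_concentration_stack(
            uniform_stack(120.0, calib),
            NeuronMask(np.ones((6, 6), bool), "ground-truth"),
            calib,
        )
        bm = baseline_map(cs, n_frames=30)
        pm = peak_amplitude_map(cs, 20, 8)
        assert np.allclose(pm.data, bm.data)

    def test_window_bounds_checked(self, calib):
        cs = pixel_concentration_stack(
            uniform_stack(50.0, calib, frames=10),
            NeuronMask(np.ones((6, 6), bool), "ground-truth"),
            calib,
        )
        with pytest.raises(ValueError):
            baseline_map(cs, n_frames=11)
        with pytest.raises(ValueError):
            peak_amplitude_map(cs, 5, 8)

    def test_window_located_from_protocol(self):
        assert stimulation_window(10.0, 0.25) == (40, 8)
        assert stimulation_window(15.0, 0.25, 8) == (60, 8)

    def test_maps_linear_in_field(self):
        rng = np.random.default_rng(0)
        data = rng.uniform(40, 400, (40, 6, 6))
        valid = np.ones(data.shape, bool)
        a = ConcentrationStack(data, valid, 0.25)
        b = ConcentrationStack(3.0 * data, valid, 0.25)
        assert np.allclose(
            3.0 * baseline_map(a, 30).data, baseline_map(b, 30).data
        )
        assert np.allclose(
            3.0 * peak_amplitude_map(a, 30, 8).data,
            peak_amplitude_map(b, 30, 8).data,
        )

    def test_baseline_cytosol_above_nucleus(self, repeat_scene, repeat_analysis):
        corrected, _, mask, rois = repeat_analysis
        cs = pixel_concentration_stack(
            corrected, mask, repeat_scene.calib, rois,
            repeat_scene.info.autofluorescence,
        )
        bm = baseline_map(cs)
        nuc = bm.data[rois.roi("nucleus") & bm.valid].mean()
        cyt = bm.data[rois.roi("cytosol") & bm.valid].mean()
        assert cyt > nuc


class TestGeodesicDistance:
    def test_straight_corridor(self):
        m = np.zeros((3, 12), bool)
        m[1, :] = True
        dm = geodesic_distance_map(m, (1, 0))
        assert np.allclose(dm.map.data[1, :], np.arange(12))

    def test_single_diagonal_step(self):
        m = np.zeros((3, 3), bool)
        m[0, 0] = m[1, 1] = True
        dm = geodesic_distance_map(m, (0, 0))
        assert dm.map.data[1, 1] == pytest.approx(SQRT2)

    def test_l_shaped_corridor_matches_brute_force(self):
        m = np.zeros((10, 10), bool)
        m[1, 1:9] = True
        m[1:9, 8] = True
        dm = geodesic_distance_map(m, (1, 1))
        ref = brute_force_distance(m, (1, 1))
        assert np.allclose(dm.map.data[m], ref[m])

    def test_random_masks_match_brute_force(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            h, w = rng.integers(5, 25, 2)
            m = rng.random((h, w)) < 0.6
            pts = np.argwhere(m)
            if len(pts) == 0:
                continue
            c = tuple(pts[rng.integers(len(pts))])
            dm = geodesic_distance_map(m, c)
            ref = brute_force_distance(m, c)
            assert np.allclose(dm.map.data[m], ref[m])

    def test_lower_bounded_by_euclidean(self):
        rng = np.random.default_rng(2)
        m = rng.random((20, 20)) < 0.7
        m[10, 10] = True
        dm = geodesic_distance_map(m, (10, 10))
        yy, xx = np.mgrid[0:20, 0:20]
        eu = np.hypot(yy - 10, xx - 10)
        sel = dm.map.valid
        assert np.all(dm.map.data[sel] >= eu[sel] - 1e-9)

    def test_neighbor_difference_bounded(self):
        rng = np.random.default_rng(3)
        m = rng.random((20, 20)) < 0.7
        m[5, 5] = True
        dm = geodesic_distance_map(m, (5, 5))
        d = dm.map.data
        valid = dm.map.valid
        h, w = d.shape
        for r, c in np.argwhere(valid):
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr, cc = r + dr, c + dc
                    if (dr, dc) != (0, 0) and 0 <= rr < h and 0 <= cc < w \
                            and valid[rr, cc]:
                        assert abs(d[r, c] - d[rr, cc]) <= SQRT2 + 1e-9

    def test_center_outside_mask_rejected(self):
        m = np.zeros((5, 5), bool)
        m[2, 2] = True
        with pytest.raises(ValueError):
            geodesic_distance_map(m, (0, 0))

    def test_unreachable_pixels_flagged_infinite(self):
        m = np.zeros((5, 5), bool)
        m[0, 0] = True
        m[4, 4] = True
        dm = geodesic_distance_map(m, (0, 0))
        assert np.isinf(dm.map.data[4, 4])
        assert not dm.map.valid[4, 4]


class TestMapCorrelation:
    def _pm(self, data, valid=None):
        return PixelMap(data=data, semantics="intensity", valid=valid)

    def test_proportional_maps_r_one(self):
        a = np.random.default_rng(0).uniform(0, 1, (8, 8))
        res = map_correlation(self._pm(a), self._pm(2 * a))
        assert res.r == pytest.approx(1.0)

    def test_antiproportional_maps_r_minus_one(self):
        a = np.random.default_rng(1).uniform(0, 1, (8, 8))
        res = map_correlation(self._pm(a), self._pm(3.0 - a))
        assert res.r == pytest.approx(-1.0)

    def test_too_few_shared_pixels(self):
        a = np.ones((4, 4))
        v = np.zeros((4, 4), bool)
        v[0, :2] = True
        with pytest.raises(ValueError):
            map_correlation(self._pm(a, v), self._pm(a, v))

    def test_repeat_stimulation_maps_reproduce(self, repeat_scene,
                                               repeat_analysis):
        corrected, _, mask, rois = repeat_analysis
        scene = repeat_scene
        cs = pixel_concentration_stack(
            corrected, mask, scene.calib, rois, scene.info.autofluorescence
        )
        pmaps = [
            peak_amplitude_map(
                cs, *stimulation_window(p.onset, scene.stack.frame_interval)
            )
            for p in scene.field.protocols
        ]
        assert map_correlation(pmaps[0], pmaps[1]).r > 0.9
        assert map_correlation(pmaps[1], pmaps[2]).r > 0.9
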