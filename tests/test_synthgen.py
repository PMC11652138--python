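"""Generator properties: phantom construction, calcium dynamics, forward
rendering and the run/pause transport process."""

import numpy as np
import pytest

from axocalc import (
    StimulationProtocol,
    concentration_to_ratio,
    ratio_to_concentration,
)
from axocalc.synthgen import (
    DynamicsParams,
    FuraOpticsParams,
    GeometryParams,
    MotilityParams,
    build_neuron_phantom,
    expected_moved_fraction,
    frequency_to_amplitude,
    fura_scene,
    render_fura_stack,
    simulate_calcium_dynamics,
    simulate_mito_transport,
    stationary_run_fraction,
)
from axocalc.transport import summarize_transport

SMALL_GEOM = GeometryParams(
    shape=(64, 64), soma_radius=5.0, n_dendrites=0, axon_length=30.0
)


class TestPhantom:
    def test_minimal_phantom_has_soma_and_axon(self):
        ph = build_neuron_phantom(SMALL_GEOM, seed=1)
        from scipy import ndimage

        soma_zone = (
            ph.compartment("soma") | ph.compartment("nucleus")
            | ph.compartment("cytosol")
        )
        _, n_soma = ndimage.label(soma_zone)
        assert n_soma == 1
        assert ph.compartment("axon").any()
        assert not ph.compartment("dendrites").any()

    def test_determinism(self):
        a = build_neuron_phantom(seed=7)
        b = build_neuron_phantom(seed=7)
        assert np.array_equal(a.labels, b.labels)
        assert np.array_equal(a.axon_path.vertices, b.axon_path.vertices)

    def test_seeds_differ_but_share_label_set(self):
        a = build_neuron_phantom(seed=1)
        b = build_neuron_phantom(seed=2)
        assert not np.array_equal(a.labels, b.labels)
        assert set(np.unique(a.labels)) == set(np.unique(b.labels))

    def test_nucleus_inside_soma_footprint(self):
        ph = build_neuron_phantom(seed=3)
        h, w = ph.labels.shape
        yy, xx = np.mgrid[0:h, 0:w]
        rad2 = (yy - ph.soma_center[0]) ** 2 + (xx - ph.soma_center[1]) ** 2
        soma_disk = rad2 <= GeometryParams().soma_radius**2 + 2
        assert np.all(soma_disk[ph.compartment("nucleus")])

    def test_labels_partition_silhouette(self):
        ph = build_neuron_phantom(seed=4)
        assert set(np.unique(ph.labels)) <= set(range(6))

    def test_image_too_small_for_soma(self):
        with pytest.raises(ValueError):
            GeometryParams(shape=(12, 12), soma_radius=8.0)


class TestCalciumDynamics:
    def test_zero_frequency_is_flat_baseline(self):
        ph = build_neuron_phantom(SMALL_GEOM, seed=1)
        f = simulate_calcium_dynamics(
            ph, StimulationProtocol(0.0, 2.0, 10.0), seed=1
        )
        for name, trace in f.traces.items():
            if np.isnan(trace).all():
                continue
            assert np.ptp(trace) == 0.0

    def test_noiseless_axonal_peak_hits_configured_amplitude(self):
        # 100 Hz 2 s paradigm: 713 nM absolute axonal peak
        ph = build_neuron_phantom(SMALL_GEOM, seed=1)
        f = simulate_calcium_dynamics(
            ph, StimulationProtocol(100.0, 2.0, 10.0),
            DynamicsParams().noiseless(), seed=1,
        )
        assert f.traces["axon"].max() == pytest.approx(713.0, abs=1e-9)

    @pytest.mark.parametrize(
        "freq,peak", [(2.0, 182.0), (20.0, 419.0), (100.0, 713.0)]
    )
    def test_frequency_amplitude_anchors(self, freq, peak):
        mean, sd = frequency_to_amplitude(freq)
        assert mean == peak and sd > 0

    def test_monte_carlo_peak_converges_to_anchor(self):
        # ensemble mean over 100 seeded axon traces within 2 SEM of 713 nM
        proto = StimulationProtocol(100.0, 2.0, 10.0)
        peaks = []
        for s in range(100):
            ph = build_neuron_phantom(SMALL_GEOM, seed=s)
            f = simulate_calcium_dynamics(ph, proto, seed=s)
            peaks.append(f.traces["axon"].max())
        peaks = np.asarray(peaks)
        sem = peaks.std(ddof=1) / np.sqrt(len(peaks))
        assert abs(peaks.mean() - 713.0) < 2 * sem

    def test_repeated_stimulation_reproduces_branch_pattern(self):
        # per-branch amplitude map correlates r > 0.9 across repeats
        protos = [StimulationProtocol(20.0, 2.0, o) for o in (15.0, 45.0)]
        ph = build_neuron_phantom(seed=5)
        f = simulate_calcium_dynamics(ph, protos, seed=5)
        dend = ph.compartment("dendrites")
        i1 = int(round(15.0 / f.frame_interval)) + 4
        i2 = int(round(45.0 / f.frame_interval)) + 4
        m1 = f.concentration[i1][dend]
        m2 = f.concentration[i2][dend]
        r = np.corrcoef(m1, m2)[0, 1]
        assert r > 0.9

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError):
            DynamicsParams(baselines={"axon": 0.0, "dendrites": 50.0,
                                      "soma": 50.0, "nucleus": 50.0,
                                      "cytosol": 50.0})

    def test_determinism(self):
        ph = build_neuron_phantom(SMALL_GEOM, seed=2)
        proto = StimulationProtocol(20.0, 2.0, 10.0)
        a = simulate_calcium_dynamics(ph, proto, seed=3)
        b = simulate_calcium_dynamics(ph, proto, seed=3)
        assert np.array_equal(
            a.concentration, b.concentration, equal_nan=True
        )


class TestRenderFura:
    def test_noiseless_ratio_round_trips_to_true_field(self, calib):
        ph = build_neuron_phantom(SMALL_GEOM, seed=1)
        f = simulate_calcium_dynamics(
            ph, StimulationProtocol(100.0, 2.0, 10.0),
            DynamicsParams().noiseless(), seed=1,
        )
        stack, blank, _ = render_fura_stack(
            f, ph, calib, FuraOpticsParams().noiseless(), seed=1
        )
        neuron = ph.silhouette
        af = FuraOpticsParams().autofluorescence
        af340 = np.zeros(neuron.shape)
        af380 = np.zeros(neuron.shape)
        for name, (a3, a8) in af.items():
            sel = ph.compartment(name)
            af340[sel], af380[sel] = a3, a8
        f340 = stack.f340 - blank.f340.mean(axis=0) - af340[None]
        f380 = stack.f380 - blank.f380.mean(axis=0) - af380[None]
        ratio = f340[:, neuron] / f380[:, neuron]
        recovered = ratio_to_concentration(ratio, calib)
        assert np.allclose(recovered, f.concentration[:, neuron], atol=1e-6)

    def test_responding_pixels_anticorrelated(self, noisy_scene):
        ph = noisy_scene.phantom
        axon = ph.compartment("axon")
        f340 = noisy_scene.stack.f340[:, axon]
        f380 = noisy_scene.stack.f380[:, axon]
        rs = [
            np.corrcoef(f340[:, i], f380[:, i])[0, 1]
            for i in range(f340.shape[1])
        ]
        assert np.median(rs) < -0.3

    def test_debris_only_pixels_positively_correlated(self, hard_scene):
        sel = hard_scene.info.debris_mask & ~hard_scene.phantom.silhouette
        f340 = hard_scene.stack.f340[:, sel]
        f380 = hard_scene.stack.f380[:, sel]
        rs = [
            np.corrcoef(f340[:, i], f380[:, i])[0, 1]
            for i in range(f340.shape[1])
        ]
        assert np.median(rs) > 0.0

    def test_invalid_calibration_rejected(self):
        from axocalc.calib import CalibrationError

        with pytest.raises(CalibrationError):
            fura_scene(
                StimulationProtocol(20.0, 2.0, 10.0),
                calib=__import__("axocalc").CalibrationParams(
                    r_min=3.0, r_max=2.0
                ),
            )


class TestMitoSimulator:
    def test_infinite_pause_rate_freezes_everything(self):
        trajs = simulate_mito_transport(
            motility=MotilityParams(pause_rate=np.inf),
            n_mito=20, duration=60.0, seed=1,
        )
        s = summarize_transport(trajs)
        assert s.mobile_fraction == 0.0
        assert np.all(s.total_distance == 0.0)

    def test_pure_run_is_constant_velocity_ramp_until_boundary(self):
        mp = MotilityParams(
            speed_mean=0.5, speed_sd=0.0, switch_prob=0.0,
            pause_rate=0.0, resume_rate=1.0, antero_bias=1.0,
        )
        trajs = simulate_mito_transport(
            axon_length_um=1000.0, motility=mp, n_mito=5,
            duration=60.0, seed=2,
        )
        for tr in trajs:
            v = np.diff(tr.position) / np.diff(tr.time)
            assert np.allclose(np.abs(v), 0.5, atol=1e-9)

    def test_positions_confined_to_segment(self):
        trajs = simulate_mito_transport(
            axon_length_um=20.0, n_mito=50, duration=300.0, seed=3
        )
        for tr in trajs:
            assert tr.position.min() >= -1e-9
            assert tr.position.max() <= 20.0 + 1e-9

    def test_events_tile_time_span(self):
        trajs = simulate_mito_transport(n_mito=10, duration=120.0, seed=4)
        for tr in trajs:
            assert tr.events[0].start == 0.0
            assert tr.events[-1].end == pytest.approx(120.0)
            for a, b in zip(tr.events, tr.events[1:]):
                assert a.end == pytest.approx(b.start)
                assert a.type != b.type or True

    def test_stationary_time_fraction_matches_chain(self):
        mp = MotilityParams()
        trajs = simulate_mito_transport(
            motility=mp, n_mito=500, duration=300.0, seed=5
        )
        tmf = summarize_transport(trajs).time_mobile_fraction
        sem = tmf.std(ddof=1) / np.sqrt(len(tmf))
        assert abs(tmf.mean() - stationary_run_fraction(mp)) < 3 * sem

    def test_moved_fraction_matches_analytic(self):
        # short recording so a paused mitochondrion can stay paused
        mp = MotilityParams(resume_rate=1.0 / 60.0)
        trajs = simulate_mito_transport(
            motility=mp, n_mito=2000, duration=30.0, seed=6
        )
        s = summarize_transport(trajs, mobility_min_distance=0.0)
        moved = (s.total_distance > 0).mean()
        expect = expected_moved_fraction(mp, 30.0)
        sem = np.sqrt(expect * (1 - expect) / 2000)
        assert abs(moved - expect) < 4 * sem

    def test_parameter_errors(self):
        with pytest.raises(ValueError):
            simulate_mito_transport(frame_interval=0.0)
        with pytest.raises(ValueError):
            simulate_mito_transport(n_mito=-1)

    def test_determinism(self):
        a = simulate_mito_transport(n_mito=5, duration=60.0, seed=9)
        b = simulate_mito_transport(n_mito=5, duration=60.0, seed=9)
        for x, y in zip(a, b):
            assert np.array_equal(x.position, y.position)
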