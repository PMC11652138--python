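"""End-to-end orchestration: validated run configurations, deterministic
per-stage seeding, file contracts between stages, and provenance.

A single run seed expands into per-stage sub-seeds through
``numpy.random.SeedSequence(seed).generate_state``, indexed by fixed
stage order (simulate_fura, analyze_fura, simulate_mito, analyze_mito),
so each stage is independently reproducible from the config alone.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as axio
from .calib import CalibrationParams, calibrate_trace
from .datatypes import AxonPath, StimulationProtocol, ap_count
from .maps import (
    baseline_map,
    geodesic_distance_map,
    map_correlation,
    peak_amplitude_map,
    pixel_concentration_stack,
    stimulation_window,
)
from .ratiocore import (
    correlation_map,
    define_compartment_rois,
    extract_roi_traces,
    register_stacks,
    segment_by_correlation,
    subtract_background,
)
from .stats import compare_groups
from .synthgen import (
    DynamicsParams,
    FuraOpticsParams,
    GeometryParams,
    HaltingParams,
    MitoOpticsParams,
    MotilityParams,
    fura_scene,
    render_mito_movie,
    simulate_mito_transport,
)
from .transport import (
    build_kymograph,
    segment_events,
    summarize_transport,
    track_kymograph,
)

__all__ = ["run_pipeline", "validate_config", "stage_seeds", "ap_count"]

STAGES = ("simulate_fura", "analyze_fura", "simulate_mito", "analyze_mito")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "stages": list(STAGES),
    "fura": {
        "protocol": {"frequency": 100.0, "duration": 2.0, "onset": 10.0},
        "noiseless": False,
        "corr_threshold": -0.3,
        "min_component_px": 10,
        "max_shift": 10,
        "baseline_frames": 30,
        "peak_frames": 8,
        "calibration": {
            "k_d": 228.0, "r_min": 0.5, "r_max": 6.0, "alpha": 1.0,
            "ceiling": 10000.0,
        },
        "inputs": None,  # optional dict of file paths for standalone analyze
    },
    "mito": {
        "protocol": {"frequency": 100.0, "duration": 2.0, "onset": 120.0},
        "connecting": True,
        "n_mito": 20,
        "axon_length_um": 100.0,
        "duration": 300.0,
        "frame_interval": 1.0,
        "bin_width": 30.0,
        "mobility_min_distance": 2.0,
        "pause_speed_threshold": 0.05,
        "min_event_duration": 2.0,
        "inputs": None,
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            out[k] = _merge(base[k], v)
        else:
            out[k] = v
    return out


def validate_config(config: dict | None) -> dict:
    """Merge with defaults and fail early with descriptive errors."""
    cfg = _merge(DEFAULT_CONFIG, config or {})
    unknown = set(cfg["stages"]) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)} (choose from {STAGES})")
    if not isinstance(cfg["seed"], int) or cfg["seed"] < 0:
        raise ValueError("config field 'seed' must be a non-negative integer")
    for key in ("fura", "mito"):
        proto = cfg[key].get("protocol")
        if proto is not None:
            missing = {"frequency", "duration", "onset"} - set(proto)
            if missing:
                raise ValueError(
                    f"config field '{key}.protocol' missing {sorted(missing)}"
                )
    calib = cfg["fura"].get("calibration")
    if calib is None:
        raise ValueError(
            "config field 'fura.calibration' is required for the calibrate step"
        )
    if "analyze_fura" in cfg["stages"] and "simulate_fura" not in cfg["stages"]:
        if not cfg["fura"].get("inputs"):
            raise ValueError(
                "config field 'fura.inputs' (stack_340, stack_380, blank_340, "
                "blank_380, annotation) is required when analyze_fura runs "
                "without simulate_fura"
            )
    if "analyze_mito" in cfg["stages"] and "simulate_mito" not in cfg["stages"]:
        if not cfg["mito"].get("inputs"):
            raise ValueError(
                "config field 'mito.inputs' (movie, path) is required when "
                "analyze_mito runs without simulate_mito"
            )
    return cfg


def stage_seeds(seed: int) -> dict[str, int]:
    """Per-stage sub-seeds (< 2**31) in fixed stage order."""
    state = np.random.SeedSequence(seed).generate_state(len(STAGES))
    return {name: int(s) % (2**31) for name, s in zip(STAGES, state)}


def _protocol(d: dict) -> StimulationProtocol:
    return StimulationProtocol(
        frequency=float(d["frequency"]), duration=float(d["duration"]),
        onset=float(d["onset"]),
    )


def run_pipeline(config: dict | None, out_dir: str | Path) -> Path:
    """Run the configured stages, writing all artefacts under ``out_dir``.

    Deterministic given (config, seed): reruns produce byte-identical CSV
    outputs. A provenance file records parameters, sub-seeds, the package
    version and checksums of every file read.
    """
    cfg = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(cfg["seed"])
    checksums: dict[str, str] = {}
    read_files: list[Path] = []

    fura_paths: dict[str, Path] = {}
    mito_paths: dict[str, Path] = {}

    if "simulate_fura" in cfg["stages"]:
        fc = cfg["fura"]
        calib = CalibrationParams(**fc["calibration"])
        scene = fura_scene(
            _protocol(fc["protocol"]), calib=calib,
            seed=seeds["simulate_fura"], noiseless=bool(fc["noiseless"]),
        )
        p340, p380 = axio.write_ratiometric(out, scene.stack, "fura")
        b340, b380 = axio.write_ratiometric(out, scene.blank, "blank")
        ann = out / "annotation.tif"
        axio.write_label_image(ann, scene.phantom.labels)
        gt = out / "ground_truth_traces.csv"
        rows = [
            (name, t, c)
            for name, trace in scene.field.traces.items()
            for t, c in zip(scene.field.time, trace)
        ]
        pd.DataFrame(rows, columns=["compartment", "t", "nM"]).to_csv(
            gt, index=False
        )
        af = out / "autofluorescence.csv"
        pd.DataFrame(
            [(k, v[0], v[1]) for k, v in scene.info.autofluorescence.items()],
            columns=["compartment", "af340", "af380"],
        ).to_csv(af, index=False)
        fura_paths = {
            "stack_340": p340, "stack_380": p380,
            "blank_340": b340, "blank_380": b380,
            "annotation": ann, "autofluorescence": af,
            "frame_interval": scene.stack.frame_interval,
            "pixel_size": scene.stack.pixel_size,
        }
        axio.dump_config(out / "fura_simulation.yaml", {
            "seed": seeds["simulate_fura"], "protocol": fc["protocol"],
            "noiseless": bool(fc["noiseless"]),
        })

    if "analyze_fura" in cfg["stages"]:
        fc = cfg["fura"]
        calib = CalibrationParams(**fc["calibration"])
        if not fura_paths:
            inp = fc["inputs"]
            fura_paths = {k: Path(v) for k, v in inp.items()
                          if k not in ("frame_interval", "pixel_size")}
            fura_paths["frame_interval"] = float(inp.get("frame_interval", 0.25))
            fura_paths["pixel_size"] = float(inp.get("pixel_size", 0.32))
        stack = axio.read_ratiometric(
            fura_paths["stack_340"], fura_paths["stack_380"],
            frame_interval=fura_paths["frame_interval"],
            pixel_size=fura_paths["pixel_size"],
        )
        blank = axio.read_ratiometric(
            fura_paths["blank_340"], fura_paths["blank_380"],
            frame_interval=fura_paths["frame_interval"],
        )
        annotation = axio.read_label_image(fura_paths["annotation"])
        read_files += [fura_paths[k] for k in
                       ("stack_340", "stack_380", "blank_340", "blank_380",
                        "annotation")]
        af = {}
        if fura_paths.get("autofluorescence"):
            df = pd.read_csv(fura_paths["autofluorescence"])
            af = {
                str(r.compartment): (float(r.af340), float(r.af380))
                for r in df.itertuples()
            }
            read_files.append(fura_paths["autofluorescence"])

        registered, shifts = register_stacks(stack, max_shift=fc["max_shift"])
        corrected = subtract_background(registered, blank)
        corr = correlation_map(corrected)
        axio.write_stack(out / "correlation_map.tif", corr.data[None])
        mask = segment_by_correlation(
            corr, threshold=fc["corr_threshold"],
            min_component_px=fc["min_component_px"],
        )
        axio.write_label_image(out / "mask.tif", mask.mask.astype(np.int32))
        names = {
            name: code for name, code in
            zip(("axon", "dendrites", "soma", "nucleus", "cytosol"),
                range(1, 6))
            if np.any(annotation == code)
        }
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rois = define_compartment_rois(mask, annotation, names)
        traces = extract_roi_traces(corrected, rois, af)
        axio.write_traces_csv(out / "roi_traces.csv", traces)
        cal_rows = []
        for name, tr in traces.items():
            ct = calibrate_trace(tr, calib)
            for t, c, v in zip(ct.time, ct.concentration, ct.valid):
                cal_rows.append((name, t, c, bool(v)))
        pd.DataFrame(
            cal_rows, columns=["compartment", "t", "nM", "valid"]
        ).to_csv(out / "calcium_traces.csv", index=False)

        cstack = pixel_concentration_stack(
            stack=corrected, mask=mask, calib=calib, rois=rois,
            autofluorescence=af,
        )
        n_base = min(fc["baseline_frames"], cstack.n_frames)
        bmap = baseline_map(cstack, n_frames=n_base)
        axio.write_stack(out / "baseline_map.tif", bmap.data[None])
        proto = _protocol(fc["protocol"])
        start, n_peak = stimulation_window(
            proto.onset, stack.frame_interval, fc["peak_frames"]
        )
        summary: dict = {"registration_max_shift_px": int(np.abs(shifts).max())}
        if start + n_peak <= cstack.n_frames:
            pmap = peak_amplitude_map(cstack, start, n_peak)
            axio.write_stack(out / "peak_map.tif", pmap.data[None])
            if rois.roi("soma").any():
                soma_px = np.argwhere(rois.roi("soma"))
                centroid = soma_px.mean(axis=0)
                k = np.argmin(((soma_px - centroid) ** 2).sum(axis=1))
                center = tuple(int(v) for v in soma_px[k])
                dmap = geodesic_distance_map(mask, center)
                axio.write_stack(
                    out / "distance_map.tif",
                    np.where(np.isfinite(dmap.map.data), dmap.map.data, -1)[None],
                )
                mc = map_correlation(pmap, dmap.map)
                summary["amplitude_vs_distance_r"] = mc.r
                summary["amplitude_vs_distance_n"] = mc.n
            mb = map_correlation(pmap, bmap)
            summary["amplitude_vs_baseline_r"] = mb.r
        with open(out / "fura_summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)

    if "simulate_mito" in cfg["stages"]:
        mc = cfg["mito"]
        proto = _protocol(mc["protocol"]) if mc["protocol"] else None
        trajs = simulate_mito_transport(
            axon_length_um=mc["axon_length_um"],
            protocol=proto, connecting=bool(mc["connecting"]),
            n_mito=int(mc["n_mito"]), duration=float(mc["duration"]),
            frame_interval=float(mc["frame_interval"]),
            seed=seeds["simulate_mito"],
        )
        pixel_size = 0.32
        n_px = int(mc["axon_length_um"] / pixel_size) + 8
        pathv = np.stack(
            [np.full(n_px, 10.0), 4.0 + np.arange(n_px, dtype=float)], axis=1
        )
        path = AxonPath(vertices=pathv, pixel_size=pixel_size)
        movie = render_mito_movie(
            trajs, path, shape=(21, n_px + 8),
            frame_times=trajs[0].time if trajs else
            np.arange(0, mc["duration"], mc["frame_interval"]),
            seed=seeds["simulate_mito"],
        )
        mv = out / "mito_movie.tif"
        axio.write_stack(mv, movie)
        tj = out / "mito_ground_truth.csv"
        axio.write_trajectories_csv(tj, trajs)
        axio.write_events_csv(out / "mito_ground_truth_events.csv", trajs)
        pcsv = out / "axon_path.csv"
        pd.DataFrame(pathv, columns=["row", "col"]).to_csv(pcsv, index=False)
        mito_paths = {
            "movie": mv, "path": pcsv,
            "frame_interval": float(mc["frame_interval"]),
            "pixel_size": pixel_size,
        }

    if "analyze_mito" in cfg["stages"]:
        mc = cfg["mito"]
        if not mito_paths:
            inp = mc["inputs"]
            mito_paths = {
                "movie": Path(inp["movie"]), "path": Path(inp["path"]),
                "frame_interval": float(inp.get("frame_interval",
                                                mc["frame_interval"])),
                "pixel_size": float(inp.get("pixel_size", 0.32)),
            }
        movie = axio.read_stack(mito_paths["movie"])
        pv = pd.read_csv(mito_paths["path"])[["row", "col"]].to_numpy()
        read_files += [mito_paths["movie"], mito_paths["path"]]
        path = AxonPath(vertices=pv, pixel_size=mito_paths["pixel_size"])
        kymo = build_kymograph(
            movie, path, frame_interval=mito_paths["frame_interval"]
        )
        axio.write_stack(out / "kymograph.tif", kymo.data[None])
        tracked = [
            segment_events(
                tr, pause_speed_threshold=mc["pause_speed_threshold"],
                min_event_duration=mc["min_event_duration"],
            )
            for tr in track_kymograph(kymo)
        ]
        axio.write_trajectories_csv(out / "tracked_trajectories.csv", tracked)
        axio.write_events_csv(out / "tracked_events.csv", tracked)
        summ = summarize_transport(
            tracked, bin_width=float(mc["bin_width"]),
            mobility_min_distance=float(mc["mobility_min_distance"]),
        )
        pd.DataFrame({
            "bin_start_s": summ.bin_edges[:-1],
            "mean_distance_um": summ.bin_mean,
            "sem_um": summ.bin_sem,
        }).to_csv(out / "binned_distance.csv", index=False)
        report: dict = {
            "n_mito": summ.n_mito,
            "mobile_fraction": summ.mobile_fraction,
            "mobility_min_distance_um": summ.mobility_min_distance,
        }
        proto = _protocol(mc["protocol"]) if mc["protocol"] else None
        if proto is not None and summ.n_mito >= 3:
            half = proto.onset
            edges = summ.bin_edges
            pre = edges[1:] <= half
            post = edges[:-1] >= half
            a = summ.bin_distance[:, pre].sum(axis=1)
            b = summ.bin_distance[:, post].sum(axis=1)
            dur_pre = float(edges[1:][pre].max() - edges[:-1][pre].min())
            dur_post = float(edges[1:][post].max() - edges[:-1][post].min())
            res = compare_groups(a / dur_pre * 60.0, b / dur_post * 60.0)
            report["baseline_vs_post"] = {
                "test": res.test, "p": res.p_value, "stars": res.stars,
                "mean_baseline_um_per_min": res.mean_a,
                "mean_post_um_per_min": res.mean_b,
                "n": [res.n_a, res.n_b],
            }
        with open(out / "transport_report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)

    for p in read_files:
        checksums[str(p)] = axio.file_checksum(p)
    provenance = {
        "version": __version__,
        "config": cfg,
        "stage_seeds": seeds,
        "input_checksums": checksums,
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True, default=str)
    return out
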