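"""The end-to-end motion-correction workflow.

simulate (optional) -> extract trace -> respiratory triggers -> gate
(respiratory and random) -> gating+ -> CMI -> metrics.  Artifacts (NIfTI
volumes, CSV tables, JSON reports and a run manifest) are written to an
output directory; identical config + seed reproduce identical outputs.

Motion significance at the single-scan level is judged against repeated
random gatings of the same stream: the scan's respiratory-gated maximum
COM displacement is compared with the mean + 2 SD of the max COM
displacements of ``n_random_repeats`` independent random gatings — the
per-scan analogue of the population count-vs-displacement envelope.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np

from . import gating, gatingplus, io, metrics, respsignal, simdata
from .config import PipelineConfig
from .errors import PetgateError, StageError
from .geometry import ScannerGeometry


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except PetgateError:
        raise
    except Exception as exc:  # surface the failing stage with a hint
        raise StageError(name, f"{type(exc).__name__}: {exc}") from exc


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    manifest: dict = {"config": config.to_dict(), "stages": {}}
    t_all = time.perf_counter()

    def tick(name, fn, *args, **kwargs):
        t0 = time.perf_counter()
        res = _stage(name, fn, *args, **kwargs)
        manifest["stages"][name] = {"seconds": round(time.perf_counter() - t0, 3)}
        return res

    # --- input stream -----------------------------------------------------
    if config.input_rglm is not None:
        stream = tick("load", io.read_rglm, config.input_rglm)
    else:
        sim = config.simulate

        def simulate():
            geom = ScannerGeometry.small()
            waveform = simdata.make_waveform(
                sim["mean_period_s"], sim["jitter_sd_s"], sim["duration_s"],
                seed=rng,
            )
            phantom = simdata.make_rat_phantom(
                geom, motion_amplitude_mm=sim.get("motion_amplitude_mm", 3.0)
            )
            return simdata.sample_events(
                phantom, waveform, sim["total_expected_counts"],
                sim["duration_s"], seed=rng, geometry=geom,
            )

        stream = tick("simulate", simulate)
    manifest["n_events"] = int(stream.n_events)

    # --- trace extraction --------------------------------------------------
    def extract():
        ids, traces, _ = respsignal.region_traces_from_stream(
            stream, config.bin_ms, config.region_block
        )
        return respsignal.build_global_trace(
            (ids, traces),
            bin_ms=config.bin_ms,
            window_hz=config.pass_window_hz,
            block=config.region_block,
            n_segments=config.n_segments,
            top_fraction=config.top_fraction,
            detrend_window_s=config.detrend_window_s,
        )

    trace = tick("extract-trace", extract)
    trace.to_frame().to_csv(out / "global_trace.csv", index=False)
    manifest["n_regions_used"] = int(trace.n_regions_used)

    # --- triggers & gating -------------------------------------------------
    triggers = tick("trigger", gating.detect_triggers, trace)
    triggers.to_frame().to_csv(out / "triggers.csv", index=False)
    stream = gating.insert_triggers(stream, triggers)
    rnd = tick("random-trigger", gating.random_triggers, stream, triggers, rng)
    rnd.to_frame().to_csv(out / "random_triggers.csv", index=False)

    gated = tick("gate", gating.bin_gates, stream, triggers,
                 config.n_gates, config.smoothing_fwhm_mm)
    random_gated = tick("gate-random", gating.bin_gates, stream, rnd,
                        config.n_gates, config.smoothing_fwhm_mm)
    io.write_nifti(gated.data, gated.voxel_size, out / "gated.nii")
    (out / "gating_report.json").write_text(json.dumps(gated.report(), indent=1))

    # --- gating+ and CMI ---------------------------------------------------
    result = tick("plus", gatingplus.apply_filter, gated, random_gated,
                  config.threshold_factor)
    io.write_nifti(result.filtered, gated.voxel_size, out / "gating_plus.nii")
    io.write_nifti(result.motion_map.cutoff.astype(np.float32),
                   gated.voxel_size, out / "motion_map.nii")
    cmi = tick("cmi", gatingplus.cmi_frames, result, config.n_cmi_frames)
    io.write_nifti(cmi, gated.voxel_size, out / "cmi.nii")

    # --- metrics -----------------------------------------------------------
    def measure():
        com_gated = metrics.max_com_displacement(gated)
        com_plus = metrics.max_com_displacement(
            result.filtered, gated.voxel_size
        )
        com_random = []
        for _ in range(config.n_random_repeats):
            r_i = gating.random_triggers(stream, triggers, rng)
            g_i = gating.bin_gates(stream, r_i, config.n_gates)
            com_random.append(metrics.max_com_displacement(g_i))
        com_random = np.asarray(com_random)
        threshold = float(com_random.mean() + 2 * com_random.std(ddof=1))
        return {
            "max_com_displacement_mm": {
                "gated": com_gated,
                "gating_plus": com_plus,
                "random_gated": com_random.tolist(),
            },
            "random_envelope_threshold_mm": threshold,
            "motion_significant": bool(com_gated > threshold),
            "most_represented_period_s": triggers.most_represented_period_s,
            "median_period_s": triggers.median_period_s,
            "gating_plus_diagnostics": result.diagnostics,
            "motion_map_histogram": result.motion_map.histogram(),
        }

    summary = tick("metrics", measure)
    (out / "metrics.json").write_text(json.dumps(summary, indent=1))

    manifest["elapsed_seconds"] = round(time.perf_counter() - t_all, 3)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return {
        "stream": stream,
        "trace": trace,
        "triggers": triggers,
        "random_triggers": rnd,
        "gated": gated,
        "random_gated": random_gated,
        "gating_plus": result,
        "cmi": cmi,
        "summary": summary,
        "manifest": manifest,
    }
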