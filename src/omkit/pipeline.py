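"""End-to-end pipeline: simulate -> condition -> analyze -> report.

Each stage is a pure function over explicit inputs; ``run_pipeline`` wires
them together, writes every artifact (movie, conditioned bundle, maps,
JSON summary) under one output directory and returns a run report.  A
single global seed fans out to per-stage seeds through a documented counter
scheme, so identical configurations reproduce bit-identical summaries.
"""
from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import mapping as map_mod
from .conditioning import (
    BeatWindows,
    ConditionedBeat,
    PixelMask,
    SNRMap,
    build_mask,
    compute_snr,
    ensemble_average,
    extract_beat_stack,
    normalize_invert,
    segment_beats,
    spatial_gaussian_filter,
)
from .io import Recording, write_recording
from .mapping import (
    ActivationMap,
    APDMap,
    VelocityField,
    compute_apd80,
    detect_activation,
    estimate_resting_level,
    exclude_outliers_iqr,
    extract_axis_cv,
    fit_cv_bayly,
)
from .synth import GroundTruth, Scenario, load_scenario

_SEED_MULTIPLIER = 100_003  # stage seed = (seed * multiplier + stage) mod 2^31


def stage_seed(seed: int, stage: int) -> int:
    """Deterministic per-stage seed fan-out from one global seed."""
    return (seed * _SEED_MULTIPLIER + stage) % (2**31 - 1)


@dataclass(frozen=True)
class ConditioningParams:
    """Parameters of the conditioning chain (defaults follow the packaged
    rodent scenarios: 5x5 spatial gaussian, 2 s ensemble window, diastolic
    noise window = last 20% of each cycle)."""

    pcl: float
    spatial_window: int = 5
    spatial_sigma: float | None = None
    ensemble_window_ms: float = 2000.0
    diastolic_fraction: float = 0.2
    snr_cutoff: float = 2.0
    intensity_cutoff: float = 0.0

    def __post_init__(self) -> None:
        if self.spatial_window < 1 or self.spatial_window % 2 == 0:
            raise ValueError(f"spatial_window must be odd, got {self.spatial_window}")
        if not 0 < self.diastolic_fraction < 1:
            raise ValueError("diastolic_fraction must be in (0, 1)")


@dataclass(frozen=True)
class MappingParams:
    """Parameters of the map-making stage."""

    axis_angle_deg: float = 0.0
    axis_tolerance_deg: float = 15.0
    cv_window: int = 7
    cv_order: int = 2
    cv_residual_ms_max: float = 2.0
    activation_smooth_ms: float = 2.0


@dataclass
class ConditioningResult:
    """Everything the conditioning chain produces for one recording."""

    beat: ConditionedBeat  # normalized, upstroke-positive traces
    resting_level: np.ndarray
    amplitude: np.ndarray
    snr_raw: SNRMap
    snr_conditioned: SNRMap
    intensity: np.ndarray
    mask: PixelMask
    windows: BeatWindows
    dead: np.ndarray
    params: ConditioningParams
    frame_rate: float
    pixel_size: float
    bits_per_sample: int


def condition_recording(
    recording: Recording, params: ConditioningParams
) -> ConditioningResult:
    """Run the full conditioning chain on one movie recording.

    Spatial gaussian binning -> beat segmentation on the global signal ->
    ensemble averaging of all complete beats in the window -> raw and
    conditioned SNR maps -> resting-level estimation -> polarity-corrected
    normalization -> SNR/intensity validity mask.
    """
    h = recording.header
    raw = recording.frames
    filtered = spatial_gaussian_filter(raw, params.spatial_window, params.spatial_sigma)
    windows = segment_beats(
        filtered, params.pcl, h.frame_rate,
        window_ms=params.ensemble_window_ms,
        diastolic_fraction=params.diastolic_fraction,
    )
    stack = extract_beat_stack(filtered, windows)
    avg = ensemble_average(stack, h.frame_rate, params.pcl)
    del stack

    snr_raw = SNRMap(compute_snr(raw, windows), definition="raw")
    snr_cond = SNRMap(
        compute_snr(avg.traces, diastolic_fraction=params.diastolic_fraction),
        definition="conditioned",
    )
    rest = estimate_resting_level(avg.traces, h.frame_rate)
    normalized, dead = normalize_invert(avg.traces, rest, polarity="inverted")
    amplitude = (rest - avg.traces.min(axis=0))  # counts, inverted polarity
    intensity = raw.mean(axis=0, dtype=np.float64)
    mask = build_mask(
        snr_cond, intensity, params.snr_cutoff, params.intensity_cutoff,
        bits_per_sample=h.bits_per_sample,
    )
    mask.keep &= ~dead
    beat = ConditionedBeat(
        traces=normalized, n_beats_averaged=avg.n_beats_averaged,
        frame_rate=h.frame_rate, pcl=params.pcl,
    )
    return ConditioningResult(
        beat=beat, resting_level=rest, amplitude=amplitude,
        snr_raw=snr_raw, snr_conditioned=snr_cond, intensity=intensity,
        mask=mask, windows=windows, dead=dead, params=params,
        frame_rate=h.frame_rate, pixel_size=h.pixel_size,
        bits_per_sample=h.bits_per_sample,
    )


@dataclass
class AnalysisResult:
    """Maps plus the scalar summary of one conditioned recording."""

    activation: ActivationMap
    apd: APDMap
    velocity: VelocityField
    summary: dict


def analyze_conditioned(
    cond: ConditioningResult,
    mapping: MappingParams,
    ground_truth: GroundTruth | None = None,
) -> AnalysisResult:
    """Compute activation, APD80 and CV maps and the scalar summary.

    If a simulator ground truth is supplied, recovery errors (activation
    MAE, APD80 error, per-axis CV errors) are added to the summary.
    """
    fr = cond.frame_rate
    beat = cond.beat.traces
    act, act_valid = detect_activation(beat, fr, smooth_ms=mapping.activation_smooth_ms)
    m = cond.mask.keep & act_valid

    rest_norm = estimate_resting_level(beat, fr)
    apd_values = compute_apd80(beat, act, rest_norm, fr)
    masked_apd = apd_values[m]
    retained, bounds = exclude_outliers_iqr(masked_apd)
    apd_mask = m & np.isfinite(apd_values)
    if bounds is not None:
        apd_mask &= (apd_values >= bounds[0]) & (apd_values <= bounds[1])

    velocity = fit_cv_bayly(
        act, cond.pixel_size, mask=m,
        window=mapping.cv_window, order=mapping.cv_order,
        residual_ms_max=mapping.cv_residual_ms_max,
    )
    cv_long, cv_trans = extract_axis_cv(
        velocity, mapping.axis_angle_deg, mapping.axis_tolerance_deg
    )

    summary = {
        "pcl": cond.params.pcl,
        "n_beats_averaged": cond.beat.n_beats_averaged,
        "n_masked_pixels": int(m.sum()),
        "snr_raw_mean": cond.snr_raw.masked_mean(m),
        "snr_conditioned_mean": cond.snr_conditioned.masked_mean(m),
        "apd80_mean": float(np.mean(retained)) if retained.size else float("nan"),
        "apd80_sd": float(np.std(retained)) if retained.size else float("nan"),
        "apd80_n": int(retained.size),
        "apd80_outlier_bounds": list(bounds) if bounds is not None else None,
        "cv_long_cm_s": cv_long,
        "cv_trans_cm_s": cv_trans,
        "axis_angle_deg": mapping.axis_angle_deg,
        "n_velocity_vectors": int(velocity.valid.sum()),
    }
    if ground_truth is not None:
        summary["truth"] = {
            "apd80": float(np.mean(ground_truth.apd_field[m])),
            "v_long_cm_s": 100.0 * ground_truth.v_long,
            "v_trans_cm_s": 100.0 * ground_truth.v_trans,
        }
        summary["errors"] = {
            "activation_mae_ms": map_mod.activation_map_error(
                act, ground_truth.activation_field, m
            ),
            "apd80_error_ms": summary["apd80_mean"] - summary["truth"]["apd80"],
            "cv_long_error_cm_s": cv_long - summary["truth"]["v_long_cm_s"],
            "cv_trans_error_cm_s": cv_trans - summary["truth"]["v_trans_cm_s"],
        }
    return AnalysisResult(
        activation=ActivationMap(values=np.where(m, act, np.nan), mask=m, frame_rate=fr),
        apd=APDMap(values=np.where(apd_mask, apd_values, np.nan), mask=apd_mask,
                   outlier_bounds=bounds),
        velocity=velocity,
        summary=summary,
    )


def analyze_scenario(
    scenario: Scenario, mapping: MappingParams | None = None
) -> tuple[ConditioningResult, AnalysisResult, GroundTruth]:
    """Simulate a scenario, condition it and analyze it in one call."""
    recording, truth = scenario.simulate()
    params = ConditioningParams(
        pcl=scenario.wave.pcl,
        spatial_window=scenario.spatial_window,
        spatial_sigma=scenario.spatial_sigma,
        ensemble_window_ms=scenario.ensemble_window_ms,
        diastolic_fraction=scenario.diastolic_fraction,
        snr_cutoff=scenario.snr_cutoff,
        intensity_cutoff=scenario.intensity_cutoff,
    )
    cond = condition_recording(recording, params)
    if mapping is None:
        mapping = MappingParams(axis_angle_deg=scenario.wave.long_axis_angle)
    analysis = analyze_conditioned(cond, mapping, ground_truth=truth)
    return cond, analysis, truth


# ---------------------------------------------------------------------------
# bundle + artifact I/O


def save_bundle(path: str | Path, cond: ConditioningResult) -> None:
    """Save a conditioned bundle (.npz container with a JSON metadata blob)."""
    meta = {
        "params": dataclasses.asdict(cond.params),
        "frame_rate": cond.frame_rate,
        "pixel_size": cond.pixel_size,
        "bits_per_sample": cond.bits_per_sample,
        "n_beats_averaged": cond.beat.n_beats_averaged,
        "pcl": cond.beat.pcl,
        "windows": {
            "starts": cond.windows.starts.tolist(),
            "frames_per_beat": cond.windows.frames_per_beat,
            "pre_frames": cond.windows.pre_frames,
            "diastolic_fraction": cond.windows.diastolic_fraction,
        },
        "mask_provenance": cond.mask.provenance,
    }
    np.savez_compressed(
        path,
        beat=cond.beat.traces.astype(np.float32),
        resting_level=cond.resting_level,
        amplitude=cond.amplitude,
        snr_raw=cond.snr_raw.values,
        snr_conditioned=cond.snr_conditioned.values,
        intensity=cond.intensity,
        mask=cond.mask.keep,
        dead=cond.dead,
        meta=np.frombuffer(json.dumps(meta, sort_keys=True).encode(), dtype=np.uint8),
    )


def load_bundle(path: str | Path) -> ConditioningResult:
    """Load a conditioned bundle written by :func:`save_bundle`."""
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta"].tobytes()).decode())
        params = ConditioningParams(**meta["params"])
        w = meta["windows"]
        windows = BeatWindows(
            starts=np.asarray(w["starts"], dtype=np.int64),
            frames_per_beat=int(w["frames_per_beat"]),
            pre_frames=int(w["pre_frames"]),
            frame_rate=float(meta["frame_rate"]),
            pcl=float(meta["pcl"]),
            diastolic_fraction=float(w["diastolic_fraction"]),
        )
        beat = ConditionedBeat(
            traces=z["beat"].astype(np.float64),
            n_beats_averaged=int(meta["n_beats_averaged"]),
            frame_rate=float(meta["frame_rate"]),
            pcl=float(meta["pcl"]),
        )
        return ConditioningResult(
            beat=beat,
            resting_level=z["resting_level"],
            amplitude=z["amplitude"],
            snr_raw=SNRMap(z["snr_raw"], "raw"),
            snr_conditioned=SNRMap(z["snr_conditioned"], "conditioned"),
            intensity=z["intensity"],
            mask=PixelMask(keep=z["mask"], provenance=meta["mask_provenance"]),
            windows=windows,
            dead=z["dead"],
            params=params,
            frame_rate=float(meta["frame_rate"]),
            pixel_size=float(meta["pixel_size"]),
            bits_per_sample=int(meta["bits_per_sample"]),
        )


def save_map_csv(path: str | Path, values: np.ndarray) -> None:
    np.savetxt(path, values, delimiter=",", fmt="%.6g")


def save_map_png(
    path: str | Path, values: np.ndarray, title: str, units: str = "",
    cmap: str = "viridis",
) -> None:
    """Render a scalar per-pixel map to PNG (NaN shown transparent)."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(values, origin="upper", cmap=cmap, interpolation="nearest")
    ax.set_title(title)
    cbar = fig.colorbar(im, ax=ax)
    if units:
        cbar.set_label(units)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


# ---------------------------------------------------------------------------
# full pipeline


@dataclass(frozen=True)
class PipelineConfig:
    """One reproducible simulate -> condition -> analyze run."""

    scenario: str = "mouse_control"
    seed: int = 0
    pcl: float | None = None
    duration_ms: float | None = None
    shape: tuple[int, int] | None = None
    out_dir: str | Path = "omkit_run"
    write_pngs: bool = True


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages, write every artifact and return the run report.

    Outputs under ``out_dir``: ``movie.omr1``, ``ground_truth.json`` (+
    activation/APD truth fields as CSV), ``conditioned.npz``, map CSVs and
    PNGs, ``summary.json`` (deterministic for a given config+seed) and
    ``report.json`` (adds stage timings).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    outputs: list[str] = []

    t0 = time.perf_counter()
    scenario = load_scenario(
        config.scenario, pcl=config.pcl, seed=stage_seed(config.seed, 0),
        duration_ms=config.duration_ms, shape=config.shape,
    )
    recording, truth = scenario.simulate()
    write_recording(recording, out / "movie.omr1")
    outputs.append("movie.omr1")
    truth_scalars = {
        "scenario": scenario.name,
        "seed": config.seed,
        "pcl": scenario.wave.pcl,
        "apd80": scenario.true_apd80(),
        "v_long_m_s": scenario.wave.v_long,
        "v_trans_m_s": scenario.wave.v_trans,
        "long_axis_angle_deg": scenario.wave.long_axis_angle,
        "stimulus_times_ms": truth.stimulus_times,
        "noise_sd": scenario.noise.noise_sd,
        "n_clipped": truth.n_clipped,
    }
    (out / "ground_truth.json").write_text(json.dumps(truth_scalars, indent=2))
    save_map_csv(out / "truth_activation_ms.csv", truth.activation_field)
    save_map_csv(out / "truth_apd80_ms.csv", truth.apd_field)
    outputs += ["ground_truth.json", "truth_activation_ms.csv", "truth_apd80_ms.csv"]
    timings["simulate"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    params = ConditioningParams(
        pcl=scenario.wave.pcl,
        spatial_window=scenario.spatial_window,
        spatial_sigma=scenario.spatial_sigma,
        ensemble_window_ms=scenario.ensemble_window_ms,
        diastolic_fraction=scenario.diastolic_fraction,
        snr_cutoff=scenario.snr_cutoff,
        intensity_cutoff=scenario.intensity_cutoff,
    )
    cond = condition_recording(recording, params)
    save_bundle(out / "conditioned.npz", cond)
    outputs.append("conditioned.npz")
    if config.write_pngs:
        save_map_png(out / "snr_conditioned.png", cond.snr_conditioned.values,
                     "Conditioned SNR")
        save_map_png(out / "snr_raw.png", cond.snr_raw.values, "Raw SNR")
        save_map_png(out / "intensity.png", cond.intensity,
                     "Mean intensity", "counts", cmap="gray")
        outputs += ["snr_conditioned.png", "snr_raw.png", "intensity.png"]
    timings["condition"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    mapping = MappingParams(axis_angle_deg=scenario.wave.long_axis_angle)
    analysis = analyze_conditioned(cond, mapping, ground_truth=truth)
    save_map_csv(out / "activation_ms.csv", analysis.activation.values)
    save_map_csv(out / "apd80_ms.csv", analysis.apd.values)
    save_map_csv(out / "cv_speed_cm_s.csv", analysis.velocity.speed)
    outputs += ["activation_ms.csv", "apd80_ms.csv", "cv_speed_cm_s.csv"]
    if config.write_pngs:
        save_map_png(out / "activation.png", analysis.activation.values,
                     "Activation time", "ms")
        save_map_png(out / "apd80.png", analysis.apd.values, "APD80", "ms")
        save_map_png(out / "cv_speed.png", analysis.velocity.speed,
                     "Conduction speed", "cm/s")
        outputs += ["activation.png", "apd80.png", "cv_speed.png"]
    summary = dict(analysis.summary)
    summary["scenario"] = scenario.name
    summary["seed"] = config.seed
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    outputs.append("summary.json")
    timings["analyze"] = time.perf_counter() - t0

    report = {
        "config": {**dataclasses.asdict(config), "out_dir": str(config.out_dir)},
        "scenario_params": {
            "wave": dataclasses.asdict(scenario.wave),
            "template": dataclasses.asdict(scenario.template),
            "noise": dataclasses.asdict(scenario.noise),
            "conditioning": dataclasses.asdict(params),
        },
        "stage_timings_s": timings,
        "outputs": outputs,
        "summary": summary,
    }
    (out / "report.json").write_text(json.dumps(report, indent=2))
    missing = [name for name in outputs if not (out / name).exists()]
    if missing:
        raise RuntimeError(f"declared outputs missing: {missing}")
    return report
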