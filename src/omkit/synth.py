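"""Synthetic paced-heart optical-mapping movies with known ground truth.

The simulator emulates a voltage-dye fluorescence recording of a rodent
heart paced from a point electrode:

* an elliptical activation wave expanding anisotropically from the pacing
  site (longitudinal / transversal conduction velocities, fiber axis angle),
* a stereotyped action-potential waveform per pixel (smoothstep upstroke,
  exponential repolarization tuned so the 80%-repolarization duration is
  exact), with APD restitution and an optional drug mode that prolongs APD,
* inverted-polarity fluorescence (depolarization darkens the dye emission)
  riding on a vignetted baseline with linear drift and additive white
  gaussian noise whose amplitude is solved in closed form from a target raw
  signal-to-noise ratio.

Every recording is returned together with the analytic ground truth
(activation field, APD field, axis velocities), so the downstream
conditioning and mapping stages can be validated as parameter-recovery
experiments.
"""
from __future__ import annotations

import math
import tomllib
import warnings
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

import numpy as np

from .io import Recording, RecordingHeader

#: reference pacing cycle length (ms) at which APTemplate.apd80 is stated
PCL_REF = 150.0

#: first stimulus time (ms); guarantees a diastolic window before beat 1
STIMULUS_START_MS = 10.0

_LN5 = math.log(5.0)
_CHUNK_FRAMES = 256


class ClippingWarning(UserWarning):
    """Synthetic samples exceeded the bit range and were clipped."""


@dataclass(frozen=True)
class WaveModel:
    """Anisotropic elliptical wavefront expanding from a point pacing site.

    Velocities are in m/s (numerically equal to mm/ms); ``long_axis_angle``
    is the fiber long-axis direction in degrees from the +x (column) axis,
    measured toward +y (rows, image-down).
    """

    pacing_site: tuple[int, int]  # (row, col)
    v_long: float = 0.51
    v_trans: float = 0.29
    long_axis_angle: float = 0.0
    pcl: float = 150.0

    def validate(self) -> None:
        if not (self.v_long >= self.v_trans > 0):
            raise ValueError(
                f"need v_long >= v_trans > 0, got {self.v_long}, {self.v_trans}"
            )
        if not self.pcl > 0:
            raise ValueError(f"pcl must be > 0, got {self.pcl}")


@dataclass(frozen=True)
class APTemplate:
    """Stereotyped normalized action-potential waveform.

    ``apd80`` is the action-potential duration at 80% repolarization at the
    reference pacing cycle length (``PCL_REF`` = 150 ms); at other cycle
    lengths it shortens linearly with slope ``restitution_slope`` (ms APD
    per ms PCL).  ``drug_apd_increment`` models a potassium-current blocker
    as a fixed APD prolongation.
    """

    apd80: float = 40.0
    upstroke_duration: float = 2.0
    amplitude_fraction: float = 0.05
    restitution_slope: float = 19.0 / 70.0
    drug_apd_increment: float = 19.0

    def validate(self) -> None:
        if not (self.apd80 > self.upstroke_duration > 0):
            raise ValueError(
                f"need apd80 > upstroke_duration > 0, got "
                f"{self.apd80}, {self.upstroke_duration}"
            )
        if not 0 < self.amplitude_fraction < 1:
            raise ValueError(
                f"amplitude_fraction must be in (0, 1), got {self.amplitude_fraction}"
            )

    def apd80_at(self, pcl: float, drug: bool = False) -> float:
        """APD80 (ms) at a given pacing cycle length, optionally with drug."""
        apd = self.apd80 - self.restitution_slope * (PCL_REF - pcl)
        if drug:
            apd += self.drug_apd_increment
        return apd

    def repolarization_tau(self, pcl: float, drug: bool = False) -> float:
        """Exponential decay constant (ms) so that the 20%-of-amplitude
        crossing falls exactly ``apd80_at(pcl)`` after the activation time
        (maximum upstroke derivative, at mid-upstroke)."""
        apd = self.apd80_at(pcl, drug)
        return (apd - 0.5 * self.upstroke_duration) / _LN5


@dataclass(frozen=True)
class NoiseModel:
    """Baseline, shading and noise of the synthetic camera image."""

    baseline_intensity: float = 600.0
    vignette_strength: float = 0.3
    noise_sd: float = 0.0
    drift_per_second: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if not 0 <= self.vignette_strength < 1:
            raise ValueError(
                f"vignette_strength must be in [0, 1), got {self.vignette_strength}"
            )


@dataclass
class GroundTruth:
    """Analytic truth attached to a simulated recording.

    ``activation_field`` is relative to the stimulus (zero at the pacing
    site); ``apd_field`` holds the true per-pixel APD80 in ms.
    """

    activation_field: np.ndarray
    apd_field: np.ndarray
    v_long: float
    v_trans: float
    long_axis_angle: float
    stimulus_times: list[float]
    pcl: float
    n_clipped: int = 0


def compute_activation_field(
    model: WaveModel, shape: tuple[int, int], pixel_size: float
) -> np.ndarray:
    """Per-pixel activation time (ms) of the elliptical paced wave.

    T(x, y) = sqrt((u / v_long)^2 + (w / v_trans)^2) where (u, w) are the mm
    offsets from the pacing site rotated into the fiber frame.  Zero at the
    pacing site.
    """
    model.validate()
    rows, cols = shape
    r0, c0 = model.pacing_site
    if not (0 <= r0 < rows and 0 <= c0 < cols):
        raise ValueError(f"pacing site {model.pacing_site} outside {shape} frame")
    y = (np.arange(rows)[:, None] - r0) * pixel_size
    x = (np.arange(cols)[None, :] - c0) * pixel_size
    theta = math.radians(model.long_axis_angle)
    u = x * math.cos(theta) + y * math.sin(theta)
    w = -x * math.sin(theta) + y * math.cos(theta)
    return np.sqrt((u / model.v_long) ** 2 + (w / model.v_trans) ** 2)


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def ap_train_value(
    t_ms: np.ndarray,
    template: APTemplate,
    pcl: float,
    drug: bool = False,
) -> np.ndarray:
    """Normalized AP train value at arbitrary times (stimulus at t = 0).

    Periodic with period ``pcl``; every beat is identical (the residual
    repolarization tail at wrap-around is below ~1e-3 of the peak for the
    packaged scenarios).  Zero before the first stimulus; peak value 1.
    """
    template.validate()
    apd = template.apd80_at(pcl, drug)
    if apd <= template.upstroke_duration:
        raise ValueError(
            f"APD80 at PCL {pcl} ms is {apd:.2f} ms, not above the "
            f"{template.upstroke_duration} ms upstroke"
        )
    if pcl <= apd:
        raise ValueError(f"PCL {pcl} ms must exceed APD80 {apd:.2f} ms")
    t = np.asarray(t_ms, dtype=np.float64)
    phase = np.mod(t, pcl)
    up = template.upstroke_duration
    tau = template.repolarization_tau(pcl, drug)
    v = np.where(
        phase < up,
        _smoothstep(phase / up),
        np.exp(-(phase - up) / tau),
    )
    return np.where(t < 0, 0.0, v)


def make_ap_trace(
    template: APTemplate,
    pcl: float,
    frame_rate: float,
    n_beats: int,
    drug: bool = False,
) -> np.ndarray:
    """Normalized AP trace sampled at the camera frame rate.

    Covers ``n_beats`` pacing cycles with the first stimulus at t = 0;
    values in [0, 1], resting level 0, upstroke positive-going.
    """
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    n_frames = int(round(n_beats * pcl * frame_rate / 1000.0))
    t = np.arange(n_frames) * (1000.0 / frame_rate)
    return ap_train_value(t, template, pcl, drug)


def vignette_map(shape: tuple[int, int], strength: float) -> np.ndarray:
    """Radial cosine illumination falloff, 1 at the center.

    f(r) = 1 - strength * (1 - cos(pi r / 2R)) with R = half the smaller
    frame dimension; clipped so the factor never goes below 1 - 2*strength.
    """
    rows, cols = shape
    r0, c0 = (rows - 1) / 2.0, (cols - 1) / 2.0
    rr = np.hypot(
        (np.arange(rows)[:, None] - r0), (np.arange(cols)[None, :] - c0)
    )
    radius = min(rows, cols) / 2.0
    f = 1.0 - strength * (1.0 - np.cos(np.clip(np.pi * rr / (2 * radius), 0, np.pi)))
    return f


def ap_rms_amplitude(
    template: APTemplate, pcl: float, frame_rate: float, drug: bool = False
) -> float:
    """RMS of the normalized AP train over one full pacing cycle."""
    v = make_ap_trace(template, pcl, frame_rate, n_beats=1, drug=drug)
    return float(np.sqrt(np.mean(v**2)))


def solve_noise_sd(
    target_raw_snr: float,
    baseline_map: np.ndarray,
    mask: np.ndarray,
    amplitude_fraction: float,
    v_rms: float,
) -> float:
    """Noise SD (counts) so the masked-mean raw SNR equals the target.

    Raw SNR is defined as (per-pixel RMS signal amplitude) / (RMS diastolic
    noise); with signal amplitude B(x,y) * amplitude_fraction * v_rms and a
    spatially uniform noise SD sigma, the masked mean is
    mean(B[mask]) * amplitude_fraction * v_rms / sigma, which this inverts.
    """
    if not target_raw_snr > 0:
        raise ValueError("target_raw_snr must be > 0")
    mean_b = float(np.mean(baseline_map[mask]))
    return mean_b * amplitude_fraction * v_rms / target_raw_snr


def simulate_recording(
    wave: WaveModel,
    template: APTemplate,
    noise: NoiseModel,
    header: RecordingHeader,
    drug: bool = False,
) -> tuple[Recording, GroundTruth]:
    """Render the synthetic fluorescence movie and its ground truth.

    F(x,y,t) = B(x,y) * (1 - a * V(x,y,t)) + drift * t + N(0, sd), where
    V is the normalized AP train delayed by the activation field and B the
    vignetted baseline.  Polarity is inverted: depolarization darkens.
    Samples are rounded to integers; clipping raises a warning and is
    counted in the ground truth.
    """
    wave.validate()
    template.validate()
    noise.validate()
    header.validate()
    shape = (header.height, header.width)
    T = compute_activation_field(wave, shape, header.pixel_size)
    duration = header.duration_ms
    if duration < STIMULUS_START_MS + wave.pcl:
        raise ValueError(
            f"{duration:.0f} ms recording does not cover one full beat "
            f"(stimulus at {STIMULUS_START_MS} ms + PCL {wave.pcl} ms)"
        )
    baseline = noise.baseline_intensity * vignette_map(shape, noise.vignette_strength)
    rng = np.random.default_rng(noise.seed)
    t_frames = np.arange(header.n_frames) * (1000.0 / header.frame_rate)

    frames = np.empty(header.shape, dtype=np.uint16)
    max_sample = header.max_sample
    n_clipped = 0
    alpha = template.amplitude_fraction
    delay = STIMULUS_START_MS + T  # (H, W)
    for start in range(0, header.n_frames, _CHUNK_FRAMES):
        stop = min(start + _CHUNK_FRAMES, header.n_frames)
        tt = t_frames[start:stop, None, None] - delay[None, :, :]
        v = ap_train_value(tt, template, wave.pcl, drug)
        f = baseline[None, :, :] * (1.0 - alpha * v)
        f += noise.drift_per_second * (t_frames[start:stop, None, None] / 1000.0)
        if noise.noise_sd > 0:
            f += rng.normal(0.0, noise.noise_sd, size=f.shape)
        np.rint(f, out=f)
        n_clipped += int(np.count_nonzero((f < 0) | (f > max_sample)))
        np.clip(f, 0, max_sample, out=f)
        frames[start:stop] = f.astype(np.uint16)
    if n_clipped:
        warnings.warn(
            f"{n_clipped} samples clipped to the {header.bits_per_sample}-bit range",
            ClippingWarning,
        )
    stimulus_times = [
        STIMULUS_START_MS + k * wave.pcl
        for k in range(int((duration - STIMULUS_START_MS) // wave.pcl) + 1)
        if STIMULUS_START_MS + k * wave.pcl < duration
    ]
    truth = GroundTruth(
        activation_field=T,
        apd_field=np.full(shape, template.apd80_at(wave.pcl, drug)),
        v_long=wave.v_long,
        v_trans=wave.v_trans,
        long_axis_angle=wave.long_axis_angle,
        stimulus_times=stimulus_times,
        pcl=wave.pcl,
        n_clipped=n_clipped,
    )
    recording = Recording(header=header, frames=frames)
    return recording, truth


# ---------------------------------------------------------------------------
# scenario presets


@dataclass
class Scenario:
    """A fully specified simulation scenario plus its conditioning defaults."""

    name: str
    wave: WaveModel
    template: APTemplate
    noise: NoiseModel
    header: RecordingHeader
    drug: bool = False
    target_raw_snr: float | None = None
    spatial_window: int = 5
    spatial_sigma: float | None = None
    ensemble_window_ms: float = 2000.0
    diastolic_fraction: float = 0.2
    snr_cutoff: float = 2.0
    intensity_cutoff: float = 0.0

    def true_apd80(self) -> float:
        return self.template.apd80_at(self.wave.pcl, self.drug)

    def simulate(self) -> tuple[Recording, GroundTruth]:
        return simulate_recording(
            self.wave, self.template, self.noise, self.header, drug=self.drug
        )


def available_scenarios() -> list[str]:
    root = resources.files("omkit") / "presets"
    return sorted(p.name.removesuffix(".toml") for p in root.iterdir()
                  if p.name.endswith(".toml"))


def load_scenario(
    name: str,
    *,
    pcl: float | None = None,
    seed: int | None = None,
    duration_ms: float | None = None,
    shape: tuple[int, int] | None = None,
) -> Scenario:
    """Load a packaged scenario preset, optionally overriding PCL, seed,
    duration or frame shape, and solve the noise SD from the preset's raw-SNR
    calibration target."""
    if Path(name).suffix == ".toml" and Path(name).exists():
        raw = Path(name).read_bytes()
        name = Path(name).stem
    else:
        try:
            raw = (resources.files("omkit") / "presets" / f"{name}.toml").read_bytes()
        except FileNotFoundError:
            raise ValueError(
                f"unknown scenario {name!r}; available: {available_scenarios()}"
            ) from None
    cfg = tomllib.loads(raw.decode())

    cam = cfg["camera"]
    if shape is not None:
        cam["height"], cam["width"] = shape
    if duration_ms is None:
        duration_ms = cam.pop("duration_ms")
    else:
        cam.pop("duration_ms", None)
    n_frames = int(round(duration_ms * cam["frame_rate"] / 1000.0))
    header = RecordingHeader(
        width=int(cam["width"]),
        height=int(cam["height"]),
        frame_rate=float(cam["frame_rate"]),
        bits_per_sample=int(cam["bits_per_sample"]),
        n_frames=n_frames,
        pixel_size=float(cam["pixel_size"]),
    )

    w = cfg["wave"]
    site = w.get("pacing_site", "center")
    if site == "center":
        site = (header.height // 2, header.width // 2)
    pcl_val = float(pcl if pcl is not None else w["pcl"])
    # CV restitution: velocities shorten linearly with PCL below the
    # reference cycle length (anchored slopes live in the preset).
    slope_l = float(w.get("cv_slope_long_per_ms", 0.0))
    slope_t = float(w.get("cv_slope_trans_per_ms", 0.0))
    wave = WaveModel(
        pacing_site=tuple(site),
        v_long=float(w["v_long"]) - slope_l * (PCL_REF - pcl_val),
        v_trans=float(w["v_trans"]) - slope_t * (PCL_REF - pcl_val),
        long_axis_angle=float(w.get("long_axis_angle", 0.0)),
        pcl=pcl_val,
    )

    a = cfg["ap"]
    template = APTemplate(
        apd80=float(a["apd80"]),
        upstroke_duration=float(a.get("upstroke_duration", 2.0)),
        amplitude_fraction=float(a.get("amplitude_fraction", 0.05)),
        restitution_slope=float(a.get("restitution_slope", 19.0 / 70.0)),
        drug_apd_increment=float(a.get("drug_apd_increment", 19.0)),
    )
    drug = bool(a.get("drug", False))

    n = cfg["noise"]
    cond = cfg.get("conditioning", {})
    intensity_cutoff = float(cond.get("intensity_cutoff", 0.0))
    noise = NoiseModel(
        baseline_intensity=float(n["baseline_intensity"]),
        vignette_strength=float(n.get("vignette_strength", 0.3)),
        noise_sd=float(n.get("noise_sd", 0.0)),
        drift_per_second=float(n.get("drift_per_second", 0.0)),
        seed=int(seed if seed is not None else n.get("seed", 0)),
    )
    target = n.get("target_raw_snr")
    if target is not None:
        baseline = noise.baseline_intensity * vignette_map(
            (header.height, header.width), noise.vignette_strength
        )
        mask = baseline >= intensity_cutoff
        v_rms = ap_rms_amplitude(template, wave.pcl, header.frame_rate, drug)
        sd = solve_noise_sd(
            float(target), baseline, mask, template.amplitude_fraction, v_rms
        )
        noise = replace(noise, noise_sd=sd)

    return Scenario(
        name=name,
        wave=wave,
        template=template,
        noise=noise,
        header=header,
        drug=drug,
        target_raw_snr=None if target is None else float(target),
        spatial_window=int(cond.get("spatial_window", 5)),
        spatial_sigma=cond.get("spatial_sigma"),
        ensemble_window_ms=float(cond.get("ensemble_window_ms", 2000.0)),
        diastolic_fraction=float(cond.get("diastolic_fraction", 0.2)),
        snr_cutoff=float(cond.get("snr_cutoff", 2.0)),
        intensity_cutoff=intensity_cutoff,
    )
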