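"""Signal conditioning for noisy voltage-dye movies.

The chain mirrors standard optical-mapping practice for paced rhythms:
spatial gaussian binning of each frame, stimulus-aligned beat segmentation
from the global (frame-mean) signal, ensemble averaging of all complete
beats in the analysis window, polarity correction / per-pixel normalization,
SNR mapping (RMS signal amplitude over RMS diastolic noise), and validity
masking by SNR and intensity cutoffs.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


class SegmentationError(ValueError):
    """Beats could not be located (recording too short or flat signal)."""


class SNRComputationError(ValueError):
    """SNR undefined (no usable diastolic samples)."""


# ---------------------------------------------------------------------------
# spatial binning


def spatial_gaussian_filter(
    movie: np.ndarray, window: int = 5, sigma: float | None = None
) -> np.ndarray:
    """Convolve each frame with a normalized truncated 2-D gaussian.

    ``window`` must be odd; the kernel is exactly ``window x window``
    (truncation radius (window-1)/2) with weights summing to 1; boundaries
    are reflect-padded.  ``sigma`` defaults to (window - 1) / 4 so the
    truncation occurs at 2 sigma.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    movie = np.asarray(movie)
    spatial_shape = movie.shape[-2:]
    if window > min(spatial_shape):
        raise ValueError(f"window {window} exceeds frame size {spatial_shape}")
    if window == 1:
        return movie.astype(np.float32, copy=True)
    if sigma is None:
        sigma = (window - 1) / 4.0
    radius = (window - 1) // 2
    out = np.empty(movie.shape, dtype=np.float32)
    sigmas = (0.0,) * (movie.ndim - 2) + (sigma, sigma)
    ndimage.gaussian_filter(
        movie.astype(np.float32, copy=False), sigma=sigmas, mode="reflect",
        truncate=radius / sigma, output=out,
    )
    return out


# ---------------------------------------------------------------------------
# beat segmentation


@dataclass(frozen=True)
class BeatWindows:
    """Stimulus-aligned complete beat windows of one recording.

    Each beat occupies ``frames_per_beat`` frames starting at
    ``starts[k]`` = refined onset k minus ``pre_frames`` (a small diastolic
    lead-in).  The diastolic (noise) window of each beat is its last
    ``diastolic_fraction`` portion.
    """

    starts: np.ndarray
    frames_per_beat: int
    pre_frames: int
    frame_rate: float
    pcl: float
    diastolic_fraction: float = 0.2

    @property
    def n_beats(self) -> int:
        return len(self.starts)

    @property
    def diastolic_frames(self) -> int:
        return max(3, int(round(self.diastolic_fraction * self.frames_per_beat)))

    def slices(self) -> list[slice]:
        return [slice(int(s), int(s) + self.frames_per_beat) for s in self.starts]

    def diastolic_slices(self) -> list[slice]:
        n = self.diastolic_frames
        return [
            slice(int(s) + self.frames_per_beat - n, int(s) + self.frames_per_beat)
            for s in self.starts
        ]


def segment_beats(
    movie_or_trace: np.ndarray,
    pcl: float,
    frame_rate: float,
    *,
    window_ms: float | None = None,
    diastolic_fraction: float = 0.2,
    pre_fraction: float = 0.05,
) -> BeatWindows:
    """Locate stimulus-aligned complete beats from the global signal.

    The global signal is the spatial mean (for a movie) or the trace itself.
    The largest-magnitude first derivative fixes the upstroke phase; beat
    onsets then follow at strides of one PCL, each refined within +/- 2
    frames by the local derivative extremum.  Only beats whose full window
    lies inside the recording (and inside ``window_ms`` if given) are
    returned.
    """
    x = np.asarray(movie_or_trace, dtype=np.float64)
    g = x.mean(axis=(1, 2)) if x.ndim == 3 else x
    n = g.size
    stride = pcl * frame_rate / 1000.0
    if n < stride:
        raise SegmentationError(
            f"recording of {n} frames shorter than one {pcl} ms PCL "
            f"({stride:.1f} frames)"
        )
    if np.ptp(g) == 0:
        raise SegmentationError("flat global signal: no detectable upstroke")
    # light temporal smoothing (sigma = 1 ms) stabilizes the derivative
    g_s = ndimage.gaussian_filter1d(g, sigma=max(frame_rate / 1000.0, 1.0),
                                    mode="reflect")
    d = np.diff(g_s)
    if np.max(np.abs(d)) <= 0:
        raise SegmentationError("flat global signal: no detectable upstroke")
    i_star = int(np.argmax(np.abs(d)))
    sign = 1.0 if d[i_star] >= 0 else -1.0
    onset0 = i_star - stride * np.floor(i_star / stride)

    frames_per_beat = int(round(stride))
    # The global derivative peaks at the *mean* activation time, but pixels
    # near the pacing site fire earlier; each window must open before the
    # earliest upstroke or those pixels lose their activation.  Measure the
    # lead of the global upstroke's left edge (10% of the peak derivative)
    # and add a small fractional margin.
    j = int(round(onset0)) if onset0 >= 1 else i_star
    threshold = 0.1 * sign * d[min(j, len(d) - 1)]
    lead_limit = max(1, int(round(0.25 * stride)))
    lead = 0
    while (lead < lead_limit and j - lead - 1 >= 0
           and sign * d[j - lead - 1] >= threshold):
        lead += 1
    pre = lead + int(round(pre_fraction * stride))
    limit = n if window_ms is None else min(n, int(round(window_ms * frame_rate / 1000.0)))

    starts = []
    k = 0
    while True:
        cand = onset0 + k * stride
        j = int(round(cand))
        if j - pre < 0:
            k += 1
            continue
        if j - pre + frames_per_beat > limit:
            break
        lo, hi = max(j - 2, 0), min(j + 3, len(d))
        refined = lo + int(np.argmax(sign * d[lo:hi]))
        start = refined - pre
        if start < 0 or start + frames_per_beat > limit:
            if start + frames_per_beat > limit:
                break
            k += 1
            continue
        starts.append(start)
        k += 1
    if not starts:
        raise SegmentationError("no complete beat fits the analysis window")
    return BeatWindows(
        starts=np.asarray(starts, dtype=np.int64),
        frames_per_beat=frames_per_beat,
        pre_frames=pre,
        frame_rate=frame_rate,
        pcl=pcl,
        diastolic_fraction=diastolic_fraction,
    )


def extract_beat_stack(movie: np.ndarray, windows: BeatWindows) -> np.ndarray:
    """Gather the aligned beat windows into a (n_beats, L, ...) stack."""
    return np.stack([movie[s] for s in windows.slices()], axis=0)


# ---------------------------------------------------------------------------
# ensemble averaging


@dataclass
class ConditionedBeat:
    """Per-pixel ensemble-averaged beat (frames_per_beat x rows x cols)."""

    traces: np.ndarray
    n_beats_averaged: int
    frame_rate: float
    pcl: float

    @property
    def frames_per_beat(self) -> int:
        return self.traces.shape[0]

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.frames_per_beat) * (1000.0 / self.frame_rate)


def ensemble_average(
    beats: np.ndarray | list[np.ndarray], frame_rate: float, pcl: float
) -> ConditionedBeat:
    """Average aligned beats; uncorrelated noise shrinks by ~sqrt(n)."""
    if isinstance(beats, (list, tuple)):
        lengths = {np.asarray(b).shape[0] for b in beats}
        if len(lengths) > 1:
            raise ValueError(f"ragged beat lengths {sorted(lengths)}")
        beats = np.stack([np.asarray(b) for b in beats], axis=0)
    beats = np.asarray(beats)
    if beats.ndim < 2 or beats.shape[0] < 1:
        raise ValueError("need a (n_beats, frames, ...) stack with >= 1 beat")
    return ConditionedBeat(
        traces=beats.mean(axis=0, dtype=np.float64),
        n_beats_averaged=beats.shape[0],
        frame_rate=frame_rate,
        pcl=pcl,
    )


# ---------------------------------------------------------------------------
# polarity / normalization


def normalize_invert(
    traces: np.ndarray,
    resting_level: np.ndarray | float,
    polarity: str = "inverted",
    dead_range: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray]:
    """Flip dye polarity and rescale each pixel to resting 0 / peak 1.

    ``traces`` is a (frames, ...) array; ``polarity`` is "inverted"
    (depolarization darkens, the voltage-dye case), "upright", or "auto"
    (chooses the orientation with the larger pooled excursion from rest).
    Returns (normalized, dead) where ``dead`` flags zero-range pixels that
    cannot be normalized (their output is 0, no exception raised).
    """
    traces = np.asarray(traces, dtype=np.float64)
    rest = np.broadcast_to(np.asarray(resting_level, dtype=np.float64),
                           traces.shape[1:])
    dev = traces - rest[None]
    if polarity == "auto":
        polarity = "inverted" if -dev.min() >= dev.max() else "upright"
    if polarity == "inverted":
        dev = -dev
    elif polarity != "upright":
        raise ValueError(f"polarity must be inverted/upright/auto, got {polarity!r}")
    amplitude = dev.max(axis=0)
    dead = (np.ptp(traces, axis=0) <= dead_range) | (amplitude <= dead_range)
    safe = np.where(dead, 1.0, amplitude)
    out = dev / safe[None]
    out[:, dead] = 0.0
    return out, dead


# ---------------------------------------------------------------------------
# SNR


def compute_snr(
    traces: np.ndarray,
    windows: BeatWindows | None = None,
    resting_level: np.ndarray | float | None = None,
    *,
    diastolic_fraction: float | None = None,
    correct_noise_bias: bool = True,
) -> np.ndarray:
    """Per-pixel SNR: RMS signal amplitude over RMS diastolic noise.

    The noise RMS is evaluated at resting potential — over the pooled
    diastolic windows (the last ``diastolic_fraction`` of each beat).  With
    ``correct_noise_bias`` (default) the signal amplitude is estimated as
    sqrt(max(P_beat - P_noise, 0)) where P are mean squared deviations from
    the resting level over the beat and diastolic windows respectively: on a
    noise-dominated raw trace the beat-window RMS contains the noise power
    itself, and subtracting it makes SNR values below 1 measurable.  With
    ``correct_noise_bias=False`` the plain ratio RMS_beat / RMS_noise is
    returned.

    ``resting_level`` defaults to per-beat diastolic means (robust to slow
    drift).  A noise-free pixel returns ``inf``.
    """
    traces = np.asarray(traces)
    if windows is None:
        # single-beat input (e.g. an ensemble-averaged beat)
        L = traces.shape[0]
        frac = 0.2 if diastolic_fraction is None else diastolic_fraction
        windows = BeatWindows(
            starts=np.asarray([0]), frames_per_beat=L, pre_frames=0,
            frame_rate=1000.0, pcl=L, diastolic_fraction=frac,
        )
    elif diastolic_fraction is not None:
        windows = BeatWindows(
            starts=windows.starts, frames_per_beat=windows.frames_per_beat,
            pre_frames=windows.pre_frames, frame_rate=windows.frame_rate,
            pcl=windows.pcl, diastolic_fraction=diastolic_fraction,
        )
    n_dia = windows.diastolic_frames
    if n_dia < 3:
        raise SNRComputationError("need >= 3 diastolic samples per beat")
    shape = traces.shape[1:]
    p_beat = np.zeros(shape)
    ss_noise = np.zeros(shape)
    n_beat_samples = 0
    n_noise_samples = 0
    n_windows = 0
    rest_estimated = resting_level is None
    for beat_sl, dia_sl in zip(windows.slices(), windows.diastolic_slices()):
        if dia_sl.stop > traces.shape[0]:
            raise SNRComputationError("diastolic window outside the recording")
        dia = traces[dia_sl].astype(np.float64, copy=False)
        rest = (dia.mean(axis=0) if rest_estimated
                else np.broadcast_to(np.asarray(resting_level, dtype=np.float64), shape))
        dev_beat = traces[beat_sl].astype(np.float64, copy=False) - rest[None]
        dev_dia = dia - rest[None]
        p_beat += (dev_beat**2).sum(axis=0)
        ss_noise += (dev_dia**2).sum(axis=0)
        n_beat_samples += dev_beat.shape[0]
        n_noise_samples += dev_dia.shape[0]
        n_windows += 1
    p_beat /= n_beat_samples
    # unbiased noise power: each window's diastolic mean consumed one dof
    noise_dof = n_noise_samples - (n_windows if rest_estimated else 0)
    p_noise = ss_noise / max(noise_dof, 1)
    if correct_noise_bias:
        # The beat-window mean square contains the noise power itself plus
        # the variance of the estimated resting level; subtract both so the
        # signal amplitude stays unbiased even when noise dominates.
        n_d = n_noise_samples / n_windows
        n_b = n_beat_samples / n_windows
        excess = 1.0 + (1.0 / n_d - 2.0 / n_b if rest_estimated else 0.0)
        amp = np.sqrt(np.maximum(p_beat - excess * p_noise, 0.0))
    else:
        amp = np.sqrt(p_beat)
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = amp / np.sqrt(p_noise)
    snr = np.where(p_noise == 0, np.inf, snr)
    return snr if snr.shape else float(snr)


@dataclass
class SNRMap:
    """Per-pixel SNR with a tag recording which trace it was computed on."""

    values: np.ndarray
    definition: str  # "raw" | "conditioned"

    def masked_mean(self, mask: np.ndarray) -> float:
        v = self.values[mask]
        v = v[np.isfinite(v)]
        return float(v.mean()) if v.size else float("nan")


# ---------------------------------------------------------------------------
# masking


@dataclass
class PixelMask:
    """Boolean validity mask plus the cutoffs that produced it."""

    keep: np.ndarray
    provenance: dict = field(default_factory=dict)

    @property
    def n_kept(self) -> int:
        return int(self.keep.sum())


def build_mask(
    snr_map: SNRMap | np.ndarray,
    intensity_map: np.ndarray,
    snr_cutoff: float,
    intensity_cutoff: float,
    bits_per_sample: int = 10,
    saturation_guard: float = 0.01,
) -> PixelMask:
    """Keep pixels with SNR >= cutoff and intensity inside the valid band.

    The saturation bound excludes the top ``saturation_guard`` fraction of
    the sample range (oversaturated areas).  An empty mask is allowed but
    warned about.
    """
    snr = snr_map.values if isinstance(snr_map, SNRMap) else np.asarray(snr_map)
    intensity = np.asarray(intensity_map)
    if snr.shape != intensity.shape:
        raise ValueError(f"shape mismatch {snr.shape} vs {intensity.shape}")
    saturation_bound = (2**bits_per_sample - 1) * (1.0 - saturation_guard)
    keep = (
        (snr >= snr_cutoff)
        & (intensity >= intensity_cutoff)
        & (intensity <= saturation_bound)
    )
    if not keep.any():
        warnings.warn("mask is empty: every pixel excluded by the cutoffs")
    return PixelMask(
        keep=keep,
        provenance={
            "snr_cutoff": snr_cutoff,
            "intensity_cutoff": intensity_cutoff,
            "saturation_bound": saturation_bound,
            "definition": getattr(snr_map, "definition", "unknown"),
        },
    )
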