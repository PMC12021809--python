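"""Classifier inputs and ground-truth labels from voltage recordings.

From a pre-ablation AF episode this module extracts, per atrium:

* a dominant-frequency (DF) map — the frequency of the largest spectral peak
  of each node's detrended, Hann-windowed voltage signal, capped at 20 Hz
  (quiescent nodes get 0);
* a phase-singularity-density (PSD) map — phase via the analytic signal
  (Hilbert transform) of the mean-removed voltage, singularities by the
  winding number of phase around each 2x2 plaquette, counted over all frames
  and Gaussian-smoothed;

and combines them with the two ablation masks and the fibrosis map into the
five-channel :class:`FeatureStack` each Siamese head consumes.

From the post-ablation episodes it derives the termination labels: per node,
the time of the last action-potential peak as a fraction of the recording
(0 for silent nodes), averaged over all conducting nodes of both atria;
the episode counts as terminated when that average is <= 0.6 (the 0-60%
band is read as inclusive).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .ep import ACTIVATION_THRESHOLD_MV, SimulationResult
from .remodeling import STRATEGY_ORDER, AblationStrategy

DEFAULT_F_MAX_HZ = 20.0
#: Channel order of one head's input stack.
CHANNEL_NAMES = ("pvi_mask", "pvi_fibrosis_mask", "psd", "df", "fibrosis")
#: Minimum peak separation for the last-peak rule (refractory guard).
PEAK_REFRACTORY_MS = 50.0
TERMINATION_FRACTION = 0.6


@dataclass
class FeatureStack:
    """Five aligned channels for one atrium, plus normalization metadata.

    ``channels`` has shape (5, H, W) in the order of :data:`CHANNEL_NAMES`,
    already normalized for the classifier: masks binary {0,1}, DF divided by
    f_max, PSD by its own maximum (0 map if empty), fibrosis IIR by 2.
    """

    channels: np.ndarray
    atrium: str
    norm: dict

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=np.float64)
        if self.channels.ndim != 3 or self.channels.shape[0] != 5:
            raise ValueError("feature stack must have exactly 5 channels")
        if np.any(self.channels[2:4] < 0):
            raise ValueError("PSD/DF channels must be non-negative")


@dataclass
class OutcomeLabel:
    """Per-strategy termination outcome with its underlying statistic."""

    terminated: bool
    mean_last_peak_fraction: float

    def __post_init__(self) -> None:
        if self.terminated != (self.mean_last_peak_fraction <= TERMINATION_FRACTION):
            raise ValueError("terminated flag inconsistent with the last-peak rule")


def _downsample_to(arr: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Block-mean downsampling when shapes divide; zoom otherwise."""
    if arr.shape == tuple(shape):
        return arr
    fy, fx = arr.shape[0] / shape[0], arr.shape[1] / shape[1]
    if fy.is_integer() and fx.is_integer():
        fy, fx = int(fy), int(fx)
        return arr.reshape(shape[0], fy, shape[1], fx).mean(axis=(1, 3))
    return ndimage.zoom(arr, (shape[0] / arr.shape[0], shape[1] / arr.shape[1]),
                        order=1)


def dominant_frequency_map(
    result: SimulationResult,
    sheet: int = 0,
    f_max_hz: float = DEFAULT_F_MAX_HZ,
    out_shape: tuple[int, int] | None = None,
) -> np.ndarray:
    """Per-node dominant frequency (Hz) of one sheet's voltage traces."""
    volts = result.voltages[sheet]
    n_frames = volts.shape[0]
    fs = 1000.0 / result.downsample_ms  # Hz
    if n_frames * result.downsample_ms < 1000.0:
        raise ValueError("traces shorter than 1 s: spectrum unresolved")
    traces = volts.reshape(n_frames, -1).astype(np.float64)
    freqs, psd = signal.periodogram(traces, fs=fs, window="hann", axis=0,
                                    detrend="constant")
    band = (freqs > 0) & (freqs <= f_max_hz)
    df = freqs[band][np.argmax(psd[band], axis=0)]
    # quiescent nodes: never crossed the activation threshold
    active = (volts.max(axis=0) >= ACTIVATION_THRESHOLD_MV).ravel()
    df = np.where(active, df, 0.0).reshape(volts.shape[1:])
    return _downsample_to(df, out_shape) if out_shape else df


def phase_map(volts: np.ndarray) -> np.ndarray:
    """Instantaneous phase in (-pi, pi] via the analytic signal per node."""
    centered = volts - volts.mean(axis=0, keepdims=True)
    return np.angle(signal.hilbert(centered, axis=0))


def _wrap(x: np.ndarray) -> np.ndarray:
    return (x + math.pi) % (2 * math.pi) - math.pi


def find_phase_singularities(phase: np.ndarray) -> list[tuple[int, int, int]]:
    """Phase singularities of one frame as (row, col, charge).

    The winding number is the sum of wrapped phase differences around each
    2x2 plaquette; +-2pi marks a singularity of charge +-1.  The reported
    (row, col) is the plaquette's top-left corner.
    """
    d1 = _wrap(phase[:-1, 1:] - phase[:-1, :-1])
    d2 = _wrap(phase[1:, 1:] - phase[:-1, 1:])
    d3 = _wrap(phase[1:, :-1] - phase[1:, 1:])
    d4 = _wrap(phase[:-1, :-1] - phase[1:, :-1])
    winding = (d1 + d2 + d3 + d4) / (2 * math.pi)
    out = []
    for r, c in zip(*np.nonzero(np.round(winding).astype(int))):
        out.append((int(r), int(c), int(round(winding[r, c]))))
    return out


def phase_and_singularities(
    result: SimulationResult,
    frame: int,
    sheet: int = 0,
) -> tuple[np.ndarray, list[tuple[int, int, int]]]:
    """Phase map of one frame plus detected singularities (x=col, y=row swapped
    to (row, col, charge) tuples)."""
    volts = result.voltages[sheet]
    if not 0 <= frame < volts.shape[0]:
        raise IndexError(f"frame {frame} out of range [0, {volts.shape[0]})")
    ph = phase_map(volts)
    return ph[frame], find_phase_singularities(ph[frame])


def psd_map(
    result: SimulationResult,
    sheet: int = 0,
    smoothing_sigma: float = 2.0,
    out_shape: tuple[int, int] | None = None,
) -> np.ndarray:
    """Phase-singularity occurrence counts over all frames, smoothed."""
    volts = result.voltages[sheet]
    if volts.shape[0] < 10:
        raise ValueError("need at least 10 frames for PS counting")
    ph = phase_map(volts)
    counts = np.zeros(volts.shape[1:], dtype=np.float64)
    for f in range(ph.shape[0]):
        for r, c, _q in find_phase_singularities(ph[f]):
            counts[r, c] += 1
    if smoothing_sigma > 0:
        counts = ndimage.gaussian_filter(counts, smoothing_sigma, mode="reflect")
    return _downsample_to(counts, out_shape) if out_shape else counts


def last_peak_fractions(result: SimulationResult) -> list[np.ndarray]:
    """Per sheet: time of each node's last action-potential peak as a
    fraction of duration (0 where no peak; non-conducting nodes NaN)."""
    refr = max(1, int(round(PEAK_REFRACTORY_MS / result.downsample_ms)))
    out = []
    for volts, cond in zip(result.voltages, result.conducting):
        n_frames = volts.shape[0]
        v = volts.reshape(n_frames, -1)
        above = v >= ACTIVATION_THRESHOLD_MV
        # local maxima above threshold, scanning from the last frame back
        interior = np.zeros_like(above)
        interior[1:-1] = above[1:-1] & (v[1:-1] >= v[:-2]) & (v[1:-1] >= v[2:])
        # refractory separation: a peak only counts if no peak within refr
        # after it -- for the *last* peak, later peaks dominate anyway, so the
        # last local maximum is the last peak.
        has_peak = interior.any(axis=0)
        last_idx = n_frames - 1 - np.argmax(interior[::-1], axis=0)
        frac = np.where(has_peak,
                        last_idx * result.downsample_ms / result.duration_ms, 0.0)
        frac = frac.reshape(volts.shape[1:])
        frac = np.where(cond, frac, np.nan)
        out.append(frac)
    return out


def ground_truth_label(
    results_per_strategy: dict[AblationStrategy, SimulationResult],
) -> dict[AblationStrategy, OutcomeLabel]:
    """Termination labels for the four strategies from post-ablation runs."""
    missing = [s for s in STRATEGY_ORDER if s not in results_per_strategy]
    if missing:
        raise KeyError(f"missing post-ablation results for {missing}")
    labels = {}
    for strat in STRATEGY_ORDER:
        res = results_per_strategy[strat]
        fracs = np.concatenate([f[np.isfinite(f)].ravel()
                                for f in last_peak_fractions(res)])
        mean_frac = float(fracs.mean()) if fracs.size else 0.0
        labels[strat] = OutcomeLabel(mean_frac <= TERMINATION_FRACTION, mean_frac)
    return labels


def build_feature_stack(
    fibrosis_map: np.ndarray,
    pvi_mask: np.ndarray,
    pvi_fibrosis_mask: np.ndarray,
    psd: np.ndarray,
    df: np.ndarray,
    atrium: str,
    f_max_hz: float = DEFAULT_F_MAX_HZ,
) -> FeatureStack:
    """Assemble and normalize the 5-channel input of one Siamese head."""
    shape = np.asarray(fibrosis_map).shape
    psd = _downsample_to(np.asarray(psd, float), shape)
    df = _downsample_to(np.asarray(df, float), shape)
    psd_max = float(psd.max())
    channels = np.stack([
        np.asarray(pvi_mask, float),
        np.asarray(pvi_fibrosis_mask, float),
        psd / psd_max if psd_max > 0 else np.zeros(shape),
        df / f_max_hz,
        np.asarray(fibrosis_map, float) / 2.0,
    ])
    return FeatureStack(channels, atrium,
                        {"psd_max": psd_max, "f_max_hz": f_max_hz,
                         "iir_scale": 2.0})
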