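"""Threshold spike detection and snippet extraction.

Candidate spikes are samples crossing ``multiplier`` times the per-channel
standard deviation — the classic 5-sigma rule.  The default polarity is
negative-only: somatic extracellular spikes are negative-dominant, and
absolute-value thresholding re-triggers on the positive after-wave of
large spikes; ``polarity="both"`` and ``"pos"`` remain available.  Events detected on several channels within a
refractory window are merged, keeping the largest-amplitude one, and
snippets are cut from the peak channel aligned on the extreme sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from .io_formats import Recording, WaveformSet

DEFAULT_MULTIPLIER = 5.0
DEFAULT_REFRACTORY_S = 1e-3
DEFAULT_WINDOW_MS = (0.8, 1.9)  # pre, post — about 64 samples at 24 kHz


@dataclass
class DetectionResult:
    """Detected events with their provenance.

    ``event_times`` are seconds (sorted), ``peak_channels`` the channel of
    each event's extreme sample, ``amplitudes`` the signed value there.
    """

    event_times: np.ndarray
    peak_channels: np.ndarray
    amplitudes: np.ndarray
    thresholds: np.ndarray
    multiplier: float = DEFAULT_MULTIPLIER
    degenerate_channels: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        self.event_times = np.asarray(self.event_times, dtype=float)
        self.peak_channels = np.asarray(self.peak_channels, dtype=int)
        if np.any(np.diff(self.event_times) < 0):
            raise ValueError("event_times must be sorted")
        if len(self.thresholds) and np.any(np.asarray(self.thresholds) < 0):
            raise ValueError("thresholds must be nonnegative")

    @property
    def n_events(self) -> int:
        return self.event_times.shape[0]


def estimate_thresholds(rec: Recording, multiplier: float = DEFAULT_MULTIPLIER,
                        robust: bool = False) -> np.ndarray:
    """Per-channel detection thresholds, ``multiplier * sigma``.

    ``sigma`` is the plain standard deviation of each channel by default;
    with ``robust=True`` the MAD-based estimate ``median(|x|)/0.6745`` is
    used instead.  Channels with zero variance get threshold 0 and a
    degenerate-channel warning.
    """
    if not multiplier > 0:
        raise ValueError("multiplier must be positive")
    if robust:
        sigma = np.median(np.abs(rec.samples - np.median(rec.samples, axis=1, keepdims=True)), axis=1) / 0.6745
    else:
        sigma = rec.samples.std(axis=1)
    if np.any(sigma == 0):
        warnings.warn(
            f"degenerate (zero-variance) channels: {np.flatnonzero(sigma == 0).tolist()}",
            RuntimeWarning,
        )
    return multiplier * sigma


def detect_spikes(rec: Recording, thresholds: Optional[np.ndarray] = None,
                  refractory: float = DEFAULT_REFRACTORY_S,
                  polarity: str = "neg",
                  multiplier: float = DEFAULT_MULTIPLIER,
                  merge_radius: Optional[float] = 100.0) -> DetectionResult:
    """Find one event per supra-threshold excursion, deduplicated across channels.

    Within each contiguous run of samples beyond threshold the extreme
    sample marks the event.  Events closer in time than ``refractory``
    collapse to the single largest-|amplitude| event; when the recording
    carries channel positions, only events within ``merge_radius`` µm of
    each other are merged (simultaneous spikes on distant channels are
    distinct neurons, not duplicates).  Without positions, or with
    ``merge_radius=None``, the merge spans all channels.
    """
    if refractory < 0:
        raise ValueError("refractory must be nonnegative")
    if refractory > rec.duration:
        raise ValueError("refractory longer than the recording")
    if thresholds is None:
        thresholds = estimate_thresholds(rec, multiplier)
    thresholds = np.asarray(thresholds, dtype=float)
    degenerate = np.flatnonzero(thresholds == 0)

    idx_all, chan_all, amp_all = [], [], []
    for c in range(rec.n_channels):
        x = rec.samples[c]
        if polarity == "both":
            mask = np.abs(x) > thresholds[c]
        elif polarity == "neg":
            mask = x < -thresholds[c]
        elif polarity == "pos":
            mask = x > thresholds[c]
        else:
            raise ValueError(f"unknown polarity {polarity!r}")
        if thresholds[c] == 0:
            continue  # degenerate channel: skip rather than flag every sample
        for start, stop in _runs(mask):
            seg = x[start:stop]
            rel = int(np.argmax(np.abs(seg)))
            idx_all.append(start + rel)
            chan_all.append(c)
            amp_all.append(seg[rel])

    if not idx_all:
        return DetectionResult(
            np.array([]), np.array([], dtype=int), np.array([]),
            thresholds, multiplier, degenerate,
        )

    idx = np.array(idx_all)
    chan = np.array(chan_all)
    amp = np.array(amp_all)
    order = np.argsort(idx, kind="stable")
    idx, chan, amp = idx[order], chan[order], amp[order]

    # cross-channel dedup: sweep in time, merge events within the refractory
    # window (and, when positions are known, within merge_radius) keeping
    # the larger |amplitude|
    ref_samples = refractory * rec.sampling_rate
    pos = rec.channel_positions if merge_radius is not None else None
    keep_idx, keep_chan, keep_amp = [], [], []
    for i in range(len(idx)):
        merged = False
        for k in range(len(keep_idx) - 1, -1, -1):
            if idx[i] - keep_idx[k] >= ref_samples:
                break
            if pos is not None and np.linalg.norm(
                    pos[chan[i]] - pos[keep_chan[k]]) > merge_radius:
                continue
            if np.abs(amp[i]) > np.abs(keep_amp[k]):
                keep_idx[k], keep_chan[k], keep_amp[k] = idx[i], chan[i], amp[i]
                # keep the sweep sorted after replacing an older event
                while (k + 1 < len(keep_idx)
                       and keep_idx[k] > keep_idx[k + 1]):
                    keep_idx[k], keep_idx[k + 1] = keep_idx[k + 1], keep_idx[k]
                    keep_chan[k], keep_chan[k + 1] = keep_chan[k + 1], keep_chan[k]
                    keep_amp[k], keep_amp[k + 1] = keep_amp[k + 1], keep_amp[k]
                    k += 1
            merged = True
            break
        if not merged:
            keep_idx.append(idx[i])
            keep_chan.append(chan[i])
            keep_amp.append(amp[i])

    order = np.argsort(keep_idx, kind="stable")
    keep_idx = [keep_idx[i] for i in order]
    keep_chan = [keep_chan[i] for i in order]
    keep_amp = [keep_amp[i] for i in order]

    return DetectionResult(
        np.array(keep_idx) / rec.sampling_rate,
        np.array(keep_chan), np.array(keep_amp),
        thresholds, multiplier, degenerate,
    )


def _runs(mask: np.ndarray):
    """Yield (start, stop) for each contiguous True run."""
    diff = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(diff == 1) + 1
    stops = np.flatnonzero(diff == -1) + 1
    if mask[0]:
        starts = np.r_[0, starts]
    if mask[-1]:
        stops = np.r_[stops, len(mask)]
    yield from zip(starts, stops)


def extract_waveforms(rec: Recording, det: DetectionResult,
                      window: Optional[Tuple[int, int]] = None,
                      align: str = "interpolated") -> WaveformSet:
    """Cut peak-channel snippets around each event.

    ``window`` is ``(pre_samples, post_samples)``; the extreme sits at
    index ``pre_samples`` of every snippet.  With ``align="interpolated"``
    (default) the extremum position is refined to sub-sample precision by
    parabolic interpolation and the snippet is resampled there with a cubic
    spline — without this, flat-troughed spikes split into distinct
    one-sample-phase clusters downstream.  ``align="sample"`` keeps the raw
    sample grid.  Events whose window clips a recording edge are dropped;
    the count is stored on the result as ``n_dropped``.
    """
    if align not in ("interpolated", "sample"):
        raise ValueError("align must be 'interpolated' or 'sample'")
    if window is None:
        pre = int(round(DEFAULT_WINDOW_MS[0] * 1e-3 * rec.sampling_rate))
        post = int(round(DEFAULT_WINDOW_MS[1] * 1e-3 * rec.sampling_rate))
    else:
        pre, post = window
    n = pre + post + 1
    snippets, times, dropped = [], [], 0
    for t, c in zip(det.event_times, det.peak_channels):
        center = int(round(t * rec.sampling_rate))
        if center - pre < 0 or center + post + 1 > rec.n_samples:
            dropped += 1
            continue
        trace = rec.samples[c]
        if align == "interpolated" and 3 <= center < rec.n_samples - 3:
            snippets.append(_aligned_snippet(trace, center, pre, post))
        else:
            snippets.append(trace[center - pre:center + post + 1])
        times.append(t)
    wave = np.array(snippets) if snippets else np.empty((0, n))
    ws = WaveformSet(wave, np.array(times), rec.sampling_rate)
    ws.n_dropped = dropped
    ws.pre_samples = pre
    return ws


def _aligned_snippet(trace: np.ndarray, center: int, pre: int, post: int
                     ) -> np.ndarray:
    """Resample a snippet on a grid centered at the interpolated extremum.

    The sub-sample offset comes from a least-squares parabola over the 7
    samples around the extreme — a 3-point parabola is too noise-sensitive
    on flat troughs and leaves one-sample phase jitter in place.
    """
    from scipy.interpolate import CubicSpline

    xs = np.arange(-3, 4)
    a, b, _ = np.polyfit(xs, trace[center - 3:center + 4], 2)
    delta = -b / (2 * a) if a != 0 else 0.0
    delta = float(np.clip(delta, -0.5, 0.5))
    lo = max(center - pre - 4, 0)
    hi = min(center + post + 5, len(trace))
    spline = CubicSpline(np.arange(lo, hi), trace[lo:hi])
    grid = center + delta + np.arange(-pre, post + 1)
    return spline(np.clip(grid, lo, hi - 1))
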