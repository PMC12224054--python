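"""Ground-truth synthetic spike data for offline testing of the whole pipeline.

Three regimes are emulated:

* single-channel waveform sets with background noise built from superposed
  faint spike shapes (noise std 0.05-0.4 of the unit peak, 24 kHz) and
  flagged overlapping collisions;
* the same with an added multiunit background — a pooled 5 Hz process of 20
  faint shapes firing at 0.25 Hz each;
* continuous multichannel recordings on a 24-channel high-density probe
  (32 kHz, 1 µV Gaussian noise, unit amplitudes 100-500 µV, rates 5-15 Hz,
  units at least 20 µm apart) with per-channel amplitude decaying
  exponentially, exp(-d/lambda), from each unit's location.

Templates are parametric two-lobe shapes (a negative trough plus a delayed
positive after-wave), peak-normalized to 1 — an emulation of averaged real
extracellular shapes, not a biophysical reproduction.  Everything is a pure
function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from .io_formats import GroundTruth, Recording, WaveformSet

DEFAULT_FS_WAVEFORMS = 24000.0
DEFAULT_FS_RECORDING = 32000.0
DEFAULT_N_SAMPLES = 64
SPATIAL_LAMBDA_UM = 30.0


@dataclass
class ProbeGeometry:
    """Channel coordinates of a high-density probe (µm)."""

    positions: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if len(np.unique(self.positions, axis=0)) != len(self.positions):
            raise ValueError("channel positions must be distinct")

    @property
    def n_channels(self) -> int:
        return self.positions.shape[0]

    @classmethod
    def dense_probe(cls, n_channels: int = 24, pitch: float = 20.0,
                    n_columns: int = 2) -> "ProbeGeometry":
        """Two-column dense layout, ``pitch`` µm between neighboring sites."""
        rows = -(-n_channels // n_columns)
        pos = [(c * pitch, r * pitch)
               for r in range(rows) for c in range(n_columns)]
        return cls(np.array(pos[:n_channels]))


@dataclass
class TemplateBank:
    """Peak-normalized spike shapes, one row per unit."""

    templates: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        t = np.asarray(self.templates, dtype=float)
        peaks = np.max(np.abs(t), axis=1)
        if not np.allclose(peaks, 1.0):
            raise ValueError("templates must be peak-normalized to 1")
        self.templates = t

    @property
    def n_units(self) -> int:
        return self.templates.shape[0]

    @property
    def n_samples(self) -> int:
        return self.templates.shape[1]

    def max_cross_correlation(self) -> float:
        """Largest pairwise normalized cross-correlation over all lags."""
        return float(max(
            _max_xcorr(self.templates[i], self.templates[j])
            for i in range(self.n_units) for j in range(i + 1, self.n_units)
        )) if self.n_units > 1 else 0.0


@dataclass
class SimConfig:
    """Conditions of a synthetic run.

    ``noise_level`` is the background std relative to the (unit) spike peak
    for waveform sets, or absolute µV for recordings.  ``rates=None`` draws
    per-unit rates uniformly from ``rate_range``.
    """

    n_units: int = 3
    duration: float = 60.0
    fs: float = DEFAULT_FS_WAVEFORMS
    n_samples: int = DEFAULT_N_SAMPLES
    rates: Optional[np.ndarray] = None
    rate_range: Tuple[float, float] = (5.0, 15.0)
    noise_level: float = 0.1
    overlap_fraction: float = 0.0  # extra forced collisions on top of natural ones
    multiunit_rate: float = 0.0
    multiunit_n_shapes: int = 20
    multiunit_amplitude: float = 0.5
    probe: Optional[ProbeGeometry] = None
    amp_range: Tuple[float, float] = (100.0, 500.0)
    min_unit_distance: float = 20.0
    refractory: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")
        if not self.duration > 0:
            raise ValueError("duration must be positive")
        if self.noise_level < 0:
            raise ValueError("noise_level must be >= 0")
        if self.rates is not None:
            self.rates = np.asarray(self.rates, dtype=float)
            if np.any(self.rates <= 0):
                raise ValueError("rates must be positive")


# ---------------------------------------------------------------------------
# templates
# ---------------------------------------------------------------------------

def _spike_shape(t_ms: np.ndarray, trough_ms: float, w_main: float,
                 ratio: float, delay: float, w_ahp: float,
                 pre_ratio: float, pre_delay: float, pre_w: float) -> np.ndarray:
    """Negative Gaussian trough, delayed positive after-wave, optional
    positive pre-deflection — the classic tri-phasic extracellular shape."""
    main = -np.exp(-0.5 * ((t_ms - trough_ms) / w_main) ** 2)
    ahp = ratio * np.exp(-0.5 * ((t_ms - trough_ms - delay) / w_ahp) ** 2)
    pre = pre_ratio * np.exp(-0.5 * ((t_ms - trough_ms + pre_delay) / pre_w) ** 2)
    return main + ahp + pre


def _max_xcorr(a: np.ndarray, b: np.ndarray) -> float:
    corr = np.correlate(a - a.mean(), b - b.mean(), mode="full")
    denom = np.std(a) * np.std(b) * len(a)
    return float(np.max(np.abs(corr)) / denom) if denom else 1.0


def make_templates(n_units: int, n_samples: int = DEFAULT_N_SAMPLES,
                   seed: int = 0, fs: float = DEFAULT_FS_WAVEFORMS,
                   max_xcorr: float = 0.999, max_draws: int = 100
                   ) -> TemplateBank:
    """Draw a bank of distinct parametric spike shapes.

    Each template is a negative trough (width 0.06-0.45 ms, position varying
    over 22-42% of the window) with a positive after-wave (relative height
    0.1-0.55, delay 0.2-1.2 ms, width 0.2-1.0 ms) and an optional positive
    pre-deflection (0-0.3), peak-normalized — secondary lobes stay well below
    the trough, as in averaged extracellular shapes.  The wide ranges give
    morphologically diverse banks, like shapes from different cell
    classes; templates whose max pairwise normalized cross-correlation
    reaches ``max_xcorr`` are redrawn, unit by unit.
    """
    rng = np.random.default_rng(seed)
    t_ms = np.arange(n_samples) / fs * 1e3
    window_ms = n_samples / fs * 1e3

    def draw() -> np.ndarray:
        w = _spike_shape(
            t_ms,
            trough_ms=rng.uniform(0.22, 0.42) * window_ms,
            w_main=rng.uniform(0.06, 0.45),
            ratio=rng.uniform(0.1, 0.55),
            delay=rng.uniform(0.2, 1.2),
            w_ahp=rng.uniform(0.2, 1.0),
            pre_ratio=rng.uniform(0.0, 0.3),
            pre_delay=rng.uniform(0.2, 0.6),
            pre_w=rng.uniform(0.1, 0.4),
        )
        return w / np.max(np.abs(w))

    bank = [draw()]
    for _ in range(1, n_units):
        for attempt in range(max_draws):
            cand = draw()
            if all(_max_xcorr(cand, t) < max_xcorr for t in bank):
                bank.append(cand)
                break
        else:
            raise RuntimeError(
                f"could not draw a distinct template in {max_draws} attempts"
            )
    return TemplateBank(np.array(bank), fs)


# ---------------------------------------------------------------------------
# spike trains
# ---------------------------------------------------------------------------

def _poisson_times(rate: float, duration: float, rng: np.random.Generator,
                   refractory: float = 0.0) -> np.ndarray:
    n = rng.poisson(rate * duration)
    times = np.sort(rng.uniform(0, duration, size=n))
    if refractory > 0 and len(times) > 1:
        keep = [0]
        for i in range(1, len(times)):
            if times[i] - times[keep[-1]] >= refractory:
                keep.append(i)
        times = times[keep]
    return times


# ---------------------------------------------------------------------------
# waveform-set simulation (single-channel regimes)
# ---------------------------------------------------------------------------

def simulate_waveform_set(cfg: SimConfig,
                          bank: Optional[TemplateBank] = None
                          ) -> Tuple[WaveformSet, GroundTruth]:
    """Simulate labeled spike snippets with structured background noise.

    Per-unit Poisson spike trains are pooled and each spike becomes a
    snippet: its unit's template plus background noise made of many faint,
    randomly shifted templates scaled so the snippet-noise std equals
    ``cfg.noise_level``.  Overlaps arise physically: whenever another
    spike's time falls inside a snippet's window, that unit's template is
    superposed at the true lag and the snippet is flagged.  A further
    ``cfg.overlap_fraction`` of snippets can receive forced collisions at a
    random lag (off by default; useful for targeted fixtures).
    ``cfg.multiunit_rate > 0`` superposes a pooled multiunit background of
    faint extra shapes.
    """
    rng = np.random.default_rng(cfg.seed)
    if bank is None:
        bank = make_templates(cfg.n_units, cfg.n_samples,
                              seed=rng.integers(2 ** 31), fs=cfg.fs)
    n_samples = bank.n_samples
    if cfg.rates is not None:
        rates = cfg.rates
    else:
        rates = rng.uniform(*cfg.rate_range, size=cfg.n_units)

    times_list, units_list = [], []
    for u in range(cfg.n_units):
        t = _poisson_times(rates[u], cfg.duration, rng, cfg.refractory)
        times_list.append(t)
        units_list.append(np.full(len(t), u))
    times = np.concatenate(times_list)
    units = np.concatenate(units_list)
    order = np.argsort(times, kind="stable")
    times, units = times[order], units[order]
    n_spikes = len(times)

    mu_bank = None
    if cfg.multiunit_rate > 0:
        mu_bank = make_templates(cfg.multiunit_n_shapes, n_samples,
                                 seed=rng.integers(2 ** 31), fs=cfg.fs)

    window_s = n_samples / cfg.fs
    waves = np.empty((n_spikes, n_samples))
    overlap = np.zeros(n_spikes, dtype=bool)
    for i in range(n_spikes):
        snippet = bank.templates[units[i]].copy()
        noise = _spike_background(bank, n_samples, rng)
        if cfg.noise_level > 0:
            noise *= cfg.noise_level / max(noise.std(), 1e-12)
            snippet = snippet + noise
        # natural collisions: any other spike inside this snippet's window
        j = i - 1
        while j >= 0 and times[i] - times[j] < window_s:
            snippet += _shifted(bank.templates[units[j]],
                                -int(round((times[i] - times[j]) * cfg.fs)))
            overlap[i] = True
            j -= 1
        j = i + 1
        while j < n_spikes and times[j] - times[i] < window_s:
            snippet += _shifted(bank.templates[units[j]],
                                int(round((times[j] - times[i]) * cfg.fs)))
            overlap[i] = True
            j += 1
        if rng.uniform() < cfg.overlap_fraction and cfg.n_units > 1:
            other = int(rng.choice([u for u in range(cfg.n_units) if u != units[i]]))
            # any lag that leaves part of the second spike inside the window
            lag = int(rng.integers(-(n_samples - 1), n_samples))
            snippet += _shifted(bank.templates[other], lag)
            overlap[i] = True
        if mu_bank is not None:
            n_mu = rng.poisson(cfg.multiunit_rate * window_s)
            for _ in range(n_mu):
                shape = mu_bank.templates[rng.integers(mu_bank.n_units)]
                lag = int(rng.integers(-n_samples // 2, n_samples // 2 + 1))
                snippet += cfg.multiunit_amplitude * _shifted(shape, lag)
        waves[i] = snippet

    ws = WaveformSet(waves, times, cfg.fs, labels=units, overlap_flags=overlap)
    truth = GroundTruth(units, times, overlap_flags=overlap)
    return ws, truth


def _spike_background(bank: TemplateBank, n_samples: int,
                      rng: np.random.Generator, n_events: int = 20) -> np.ndarray:
    """Superposition of faint randomly shifted templates (unit-std shape)."""
    noise = np.zeros(n_samples)
    for _ in range(n_events):
        shape = bank.templates[rng.integers(bank.n_units)]
        lag = int(rng.integers(-n_samples, n_samples + 1))
        noise += rng.normal() * _shifted(shape, lag)
    return noise


def _shifted(w: np.ndarray, lag: int) -> np.ndarray:
    """Shift with zero padding (positive lag delays the shape)."""
    out = np.zeros_like(w)
    if lag >= 0:
        out[lag:] = w[:len(w) - lag] if lag < len(w) else 0.0
    else:
        out[:lag] = w[-lag:]
    return out


# ---------------------------------------------------------------------------
# multichannel recording simulation
# ---------------------------------------------------------------------------

def simulate_recording(cfg: SimConfig,
                       bank: Optional[TemplateBank] = None
                       ) -> Tuple[Recording, GroundTruth]:
    """Simulate a continuous multichannel recording with ground truth.

    Units are placed near the probe at least ``cfg.min_unit_distance`` µm
    apart; each fires a Poisson train with its rate drawn from
    ``cfg.rate_range`` and a peak amplitude drawn from ``cfg.amp_range``
    (realized exactly on its nearest channel; other channels decay
    exponentially with distance, exp(-d/lambda), lambda = 30 µm, so a
    unit's footprint spans only a handful of nearby sites).  Gaussian noise
    of ``cfg.noise_level`` µV (interpreted absolutely here) is added to
    every channel.
    """
    rng = np.random.default_rng(cfg.seed)
    probe = cfg.probe or ProbeGeometry.dense_probe()
    fs = cfg.fs if cfg.fs != DEFAULT_FS_WAVEFORMS else DEFAULT_FS_RECORDING
    n_samples_rec = int(round(cfg.duration * fs))
    n_wave = cfg.n_samples
    if bank is None:
        bank = make_templates(cfg.n_units, n_wave,
                              seed=rng.integers(2 ** 31), fs=fs)

    unit_pos = _place_units(probe, cfg.n_units, cfg.min_unit_distance, rng)
    amps = rng.uniform(*cfg.amp_range, size=cfg.n_units)
    rates = (cfg.rates if cfg.rates is not None
             else rng.uniform(*cfg.rate_range, size=cfg.n_units))

    # per-unit channel gains, normalized to 1 on the nearest channel
    dists = np.linalg.norm(
        probe.positions[None, :, :] - unit_pos[:, None, :], axis=2)
    gains = np.exp(-dists / SPATIAL_LAMBDA_UM)
    gains /= gains.max(axis=1, keepdims=True)

    # ground-truth times mark each template's extreme sample
    trough_idx_per_unit = np.argmax(np.abs(bank.templates), axis=1)
    samples = np.zeros((probe.n_channels, n_samples_rec))
    all_times, all_units = [], []
    margin = n_wave / fs
    for u in range(cfg.n_units):
        trough_idx = int(trough_idx_per_unit[u])
        times = _poisson_times(rates[u], cfg.duration - 2 * margin, rng,
                               cfg.refractory) + margin
        for t in times:
            start = int(round(t * fs)) - trough_idx
            seg = amps[u] * bank.templates[u]
            samples[:, start:start + n_wave] += gains[u][:, None] * seg[None, :]
        all_times.append(times)
        all_units.append(np.full(len(times), u))

    if cfg.noise_level > 0:
        samples += rng.normal(0.0, cfg.noise_level, size=samples.shape)

    times = np.concatenate(all_times)
    units = np.concatenate(all_units)
    order = np.argsort(times, kind="stable")
    rec = Recording(samples, fs, channel_positions=probe.positions)
    rec.unit_positions = unit_pos
    rec.unit_amplitudes = amps
    truth = GroundTruth(units[order], times[order])
    return rec, truth


def _place_units(probe: ProbeGeometry, n_units: int, min_dist: float,
                 rng: np.random.Generator, margin: float = 10.0,
                 max_tries: int = 1000) -> np.ndarray:
    lo = probe.positions.min(axis=0) - margin
    hi = probe.positions.max(axis=0) + margin
    placed: list = []
    for _ in range(n_units):
        for _ in range(max_tries):
            p = rng.uniform(lo, hi)
            if all(np.linalg.norm(p - q) >= min_dist for q in placed):
                placed.append(p)
                break
        else:
            raise RuntimeError(
                f"could not place {n_units} units {min_dist} µm apart"
            )
    return np.array(placed)
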