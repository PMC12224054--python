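"""n-th order temporal gradients of spike waveforms.

The building block is the first-order central difference
``f'(x_i) ~ (f(x_{i+1}) - f(x_{i-1})) / 2h`` with O(h^2) truncation error;
the n-th gradient is n repeated applications.  The operator is linear and
shift-equivariant, exact for polynomials of degree <= 2 on interior points.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io_formats import WaveformSet

_BOUNDARIES = ("one_sided", "replicate", "trim")


@dataclass(frozen=True)
class GradientConfig:
    """Order, step and boundary policy for the gradient operator.

    ``order`` 0 means "leave the waveform untouched".  ``step`` is in
    samples; rescaling it multiplies every feature by a constant, so it is
    held at 1 to keep distance-based embeddings comparable across runs.
    ``boundary`` controls the two edge samples: first-order one-sided
    differences (length-preserving, the default), replication of the nearest
    interior value, or trimming (each application shortens by 2).
    """

    order: int = 0
    step: float = 1.0
    boundary: str = "one_sided"

    def __post_init__(self) -> None:
        if self.order < 0:
            raise ValueError("order must be >= 0")
        if not self.step > 0:
            raise ValueError("step must be positive")
        if self.boundary not in _BOUNDARIES:
            raise ValueError(f"boundary must be one of {_BOUNDARIES}")


def central_difference(w: np.ndarray, h: float = 1.0,
                       boundary: str = "one_sided") -> np.ndarray:
    """First-order central difference along the last axis.

    Interior points get ``(w[i+1] - w[i-1]) / (2h)``; the two edge samples
    follow the boundary policy.  Accepts a single waveform vector or a
    (n_spikes, n_samples) matrix.
    """
    w = np.asarray(w, dtype=float)
    if w.shape[-1] < 3:
        raise ValueError("waveform must have at least 3 samples")
    if boundary not in _BOUNDARIES:
        raise ValueError(f"boundary must be one of {_BOUNDARIES}")
    interior = (w[..., 2:] - w[..., :-2]) / (2.0 * h)
    if boundary == "trim":
        return interior
    out = np.empty_like(w)
    out[..., 1:-1] = interior
    if boundary == "one_sided":
        out[..., 0] = (w[..., 1] - w[..., 0]) / h
        out[..., -1] = (w[..., -1] - w[..., -2]) / h
    else:  # replicate
        out[..., 0] = interior[..., 0]
        out[..., -1] = interior[..., -1]
    return out


def nth_gradient(ws: WaveformSet, cfg: GradientConfig) -> WaveformSet:
    """Apply the central-difference operator ``cfg.order`` times row-wise.

    Order 0 returns an identical copy.  Spike times, labels and overlap
    flags pass through unchanged.
    """
    if cfg.order == 0:
        return replace(ws, waveforms=ws.waveforms.copy())
    if cfg.boundary == "trim":
        remaining = ws.n_samples - 2 * cfg.order
        if remaining < 2:
            max_n = (ws.n_samples - 2) // 2
            raise ValueError(
                f"order {cfg.order} trims below 2 samples; max feasible order "
                f"is {max_n} for {ws.n_samples}-sample waveforms"
            )
    w = ws.waveforms
    for _ in range(cfg.order):
        w = central_difference(w, cfg.step, cfg.boundary)
    return replace(ws, waveforms=w)


def gradient_kernel(order: int, h: float = 1.0) -> np.ndarray:
    """The n-fold self-convolution of the central-difference kernel.

    Convolving a waveform with this kernel ('valid' mode) reproduces the
    interior points of ``order`` repeated central differences — used as an
    equivalence oracle in tests.
    """
    base = np.array([1.0, 0.0, -1.0]) / (2.0 * h)  # np.convolve flips
    k = np.array([1.0])
    for _ in range(order):
        k = np.convolve(k, base)
    return k
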