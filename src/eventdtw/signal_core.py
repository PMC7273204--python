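"""Signal container, validation, and amplitude preprocessing.

Every alignment experiment in this package operates on plain one-dimensional
signals: ordered ``(timestamp, amplitude)`` pairs, possibly unevenly sampled.
A *uniform* signal is one whose timestamps are the observation indices
``0, 1, ..., L-1`` — the convention for evenly sampled reference signals,
where one time unit separates adjacent observations.

Preprocessing before alignment is Gaussian smoothing followed by amplitude
standardization (z-scoring), so that amplitude distances are comparable
across signals recorded in arbitrary units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "Signal",
    "SignalError",
    "ParameterError",
    "make_uniform_signal",
    "gaussian_smooth",
    "standardize",
]


class SignalError(ValueError):
    """Raised for structurally invalid or degenerate signals."""


class ParameterError(ValueError):
    """Raised for out-of-range algorithm parameters."""


@dataclass(frozen=True)
class Signal:
    """An ordered sequence of (timestamp, amplitude) observations.

    Parameters
    ----------
    timestamps : array-like of float
        Strictly increasing sample times, in seconds or index units.
    values : array-like of float
        Amplitudes, one per timestamp, in arbitrary units.
    uniform : bool
        If True, timestamps are asserted to be exactly ``0..L-1``
        (the evenly-sampled index-time convention).
    """

    timestamps: np.ndarray
    values: np.ndarray
    uniform: bool = field(default=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.timestamps, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "timestamps", t)
        object.__setattr__(self, "values", v)
        if t.ndim != 1 or v.ndim != 1:
            raise SignalError("timestamps and values must be one-dimensional")
        if len(t) != len(v):
            raise SignalError(
                f"length mismatch: {len(t)} timestamps vs {len(v)} values"
            )
        if len(t) < 2:
            raise SignalError("a signal needs at least 2 observations")
        if not (np.isfinite(t).all() and np.isfinite(v).all()):
            raise SignalError("timestamps and values must be finite")
        if not (np.diff(t) > 0).all():
            bad = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 1
            raise SignalError(f"timestamps not strictly increasing at index {bad}")
        if self.uniform and not np.array_equal(t, np.arange(len(t), dtype=float)):
            raise SignalError("uniform signal must have timestamps 0..L-1")

    def __len__(self) -> int:
        return len(self.values)

    def with_values(self, values: np.ndarray, *, uniform: bool | None = None) -> "Signal":
        """Return a copy of this signal with new amplitudes on the same time base."""
        return Signal(
            self.timestamps.copy(),
            np.asarray(values, dtype=float),
            uniform=self.uniform if uniform is None else uniform,
        )


def make_uniform_signal(values) -> Signal:
    """Build an evenly sampled signal with index timestamps ``0..L-1``.

    This is the canonical representation of a reference signal whose
    observations are one time unit apart.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) < 2:
        raise SignalError("need a one-dimensional sequence of at least 2 values")
    return Signal(np.arange(len(v), dtype=float), v, uniform=True)


def gaussian_smooth(signal: Signal, sigma: float = 1.0, *, truncate: float = 4.0) -> Signal:
    """Smooth amplitudes with a truncated Gaussian kernel.

    The kernel is applied in index space (sample order), with reflect
    padding at the boundaries, and is normalized so constants pass
    through unchanged.  Timestamps are untouched; for unevenly sampled
    signals this is an index-space convolution, not a time-domain one —
    a documented limitation for strongly irregular sampling.

    Parameters
    ----------
    sigma : float
        Kernel standard deviation in index units.  Must be positive.
    truncate : float
        Kernel support radius in multiples of sigma (default 4).
    """
    if sigma <= 0:
        raise ParameterError(f"sigma must be positive, got {sigma}")
    smoothed = gaussian_filter1d(signal.values, sigma=sigma, mode="reflect", truncate=truncate)
    return signal.with_values(smoothed)


def standardize(signal: Signal) -> Signal:
    """Z-score the amplitudes: zero mean, unit population standard deviation.

    Raises
    ------
    SignalError
        If the signal has (numerically) zero amplitude variance.
    """
    v = signal.values
    sd = float(np.std(v))
    if sd < 1e-12 * max(1.0, float(np.max(np.abs(v)))) or sd == 0.0:
        raise SignalError("cannot standardize a constant signal (zero variance)")
    return signal.with_values((v - np.mean(v)) / sd)


def preprocess(signal: Signal, *, smooth_sigma: float = 1.0, truncate: float = 4.0) -> Signal:
    """Standard preprocessing: Gaussian smoothing, then z-scoring."""
    return standardize(gaussian_smooth(signal, smooth_sigma, truncate=truncate))
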