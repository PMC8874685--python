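"""Signal conditioning applied before template matching.

Walking signals from a shoe-mounted IMU arrive with arbitrary offsets
(gravity, sensor bias) and amplitudes that vary with subject and speed.
Elastic template matching is only meaningful after the query and the
template are brought onto a common scale, so every channel is
z-normalized to zero mean and unit (unbiased) standard deviation before
descriptors are extracted.  Accelerometer channels additionally carry
high-frequency "burrs" from ground impacts; a short centered moving
average removes them without destroying the heel-strike spike that the
event detectors rely on.  Multi-axis schemes are fused to a single
signal by the per-sample Euclidean modulus, and a loosely worn sensor
may invert the signal orientation, which the sign-flip handles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError, ParameterError

__all__ = ["ChannelScheme", "znormalize", "mean_filter", "fuse_axes", "flip"]

_AXIS_INDEX = {"X": 0, "Y": 1, "Z": 2}


@dataclass(frozen=True)
class ChannelScheme:
    """Which sensor and axes feed the matcher.

    Parameters
    ----------
    sensor : {"acc", "gyro"}
        Source triad.
    axes : tuple of {"X", "Y", "Z"}
        Axes used.  X points forward, Y upward, Z to the left.
    fused : bool
        If true, the selected axes are combined into one signal by the
        per-sample 2-norm before descriptor extraction; otherwise each
        axis is described separately and descriptor distances are summed.
    """

    sensor: str
    axes: tuple[str, ...] = ("Z",)
    fused: bool = field(default=False)

    def __post_init__(self) -> None:
        if self.sensor not in ("acc", "gyro"):
            raise ParameterError(f"sensor must be 'acc' or 'gyro', got {self.sensor!r}")
        axes = tuple(self.axes)
        if not axes or len(set(axes)) != len(axes):
            raise ParameterError(f"axes must be a nonempty set of unique axes, got {axes!r}")
        for a in axes:
            if a not in _AXIS_INDEX:
                raise ParameterError(f"unknown axis {a!r}; allowed: X, Y, Z")
        object.__setattr__(self, "axes", axes)
        if self.fused and len(axes) < 2:
            raise ParameterError("fused schemes need at least two axes")

    @property
    def axis_indices(self) -> tuple[int, ...]:
        return tuple(_AXIS_INDEX[a] for a in self.axes)

    @classmethod
    def parse(cls, sensor: str, axes: str, fused: bool | None = None) -> "ChannelScheme":
        """Build a scheme from CLI-style strings, e.g. ``("gyro", "XZ")``.

        Multi-axis strings default to fused (modulus) combination.
        """
        ax = tuple(axes.upper())
        if fused is None:
            fused = len(ax) > 1
        return cls(sensor=sensor, axes=ax, fused=fused)

    def __str__(self) -> str:
        tag = "+".join(self.axes) if not self.fused else "|" + "".join(self.axes) + "|"
        return f"{self.sensor}:{tag}"


def znormalize(series: np.ndarray) -> np.ndarray:
    """Shift/scale a series to mean 0 and unbiased standard deviation 1.

    The scale is the unbiased estimator (divisor n-1).  A constant series
    has no meaningful shape and raises :class:`DegenerateInputError`.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ParameterError("znormalize expects a 1-D series")
    n = x.size
    if n < 2:
        raise DegenerateInputError("need at least 2 samples to normalize")
    mean = x.mean()
    s = x.std(ddof=1)
    if s == 0.0 or not np.isfinite(s):
        raise DegenerateInputError("constant (or non-finite) series cannot be z-normalized")
    return (x - mean) / s


def mean_filter(series: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with shrinking windows at the edges.

    ``window`` must be odd so the filter is symmetric (zero phase shift),
    which keeps event timing unbiased.  Output length equals input length.
    """
    if window % 2 == 0 or window < 1:
        raise ParameterError(f"window must be odd and >= 1, got {window}")
    x = np.asarray(series, dtype=float)
    if window > x.size:
        raise ParameterError(f"window {window} exceeds series length {x.size}")
    if window == 1:
        return x.copy()
    half = window // 2
    csum = np.concatenate(([0.0], np.cumsum(x)))
    idx = np.arange(x.size)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, x.size - 1)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def fuse_axes(vectors: np.ndarray) -> np.ndarray:
    """Per-sample Euclidean norm of 2 or 3 axis columns (m x d -> m)."""
    v = np.asarray(vectors, dtype=float)
    if v.ndim != 2 or v.shape[1] not in (2, 3):
        raise ParameterError(f"expected an m x d array with d in {{2,3}}, got shape {v.shape}")
    return np.linalg.norm(v, axis=1)


def flip(series: np.ndarray) -> np.ndarray:
    """Sign-inverted copy of the series (orientation correction)."""
    return -np.asarray(series, dtype=float)
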