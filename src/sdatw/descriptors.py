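"""Local shape descriptors and descriptor-space distances.

Pointwise DTW compares raw sample values, which makes the accumulated
distance curve of a periodic walking signal bumpy and its stride-boundary
valleys ambiguous.  Describing each sample by a feature vector of its
local neighborhood instead — the shapeDTW idea — smooths the cost
surface and sharpens the valleys, which is what lets the matcher run
without any distance threshold.

Two descriptor families are provided.  Magnitude-aware descriptors (RAW,
PAA, DWT) summarize the amplitude distribution of the neighborhood;
fluctuation-capturing descriptors (SLOPE, DERIVATIVE, HOG1D) record only
direction and size of local changes and are therefore exactly invariant
to additive offsets.  A compound descriptor concatenates one of each,
block-normalized so neither family dominates the distance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pywt
from scipy.spatial.distance import cdist

from .errors import ParameterError
from .preprocess import ChannelScheme

__all__ = [
    "DescriptorConfig",
    "DescriptorSequence",
    "extract_subsequence",
    "describe",
    "describe_window",
    "descriptor_distance",
    "distance_matrix",
]

BASIC_KINDS = ("raw", "paa", "dwt", "slope", "derivative", "hog1d")


@dataclass(frozen=True)
class DescriptorConfig:
    """Configuration of one shape-descriptor mapping.

    Parameters
    ----------
    kind : str
        One of ``raw, paa, dwt, slope, derivative, hog1d`` or ``compound``.
    l : int
        Neighborhood size in samples (odd, >= 3).  310 ms at 100 Hz by
        default, enough to span the within-stride features being matched.
    intervals : int
        Number of equal-length intervals for PAA and SLOPE.
    dwt_levels : int
        Haar decomposition depth for DWT.
    hog_bins, hog_intervals, hog_scale :
        Orientation bins, intervals and gradient scaling for HOG1D.
    components : pair of DescriptorConfig, for ``compound`` only.
    weights : per-block weights for ``compound``.
    """

    kind: str = "raw"
    l: int = 31
    intervals: int = 5
    dwt_levels: int = 3
    hog_bins: int = 8
    hog_intervals: int = 2
    hog_scale: float = 0.1
    components: Optional[tuple["DescriptorConfig", "DescriptorConfig"]] = None
    weights: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        if self.kind not in BASIC_KINDS + ("compound",):
            raise ParameterError(f"unknown descriptor kind {self.kind!r}")
        if self.l % 2 == 0 or self.l < 1:
            raise ParameterError(f"neighborhood l must be odd and >= 1, got {self.l}")
        if self.kind != "raw" and self.l < 3:
            raise ParameterError("only RAW admits a single-sample neighborhood (l = 1)")
        if self.kind in ("paa", "slope") and not (1 <= self.intervals <= self.l):
            raise ParameterError("intervals must be in [1, l]")
        if self.dwt_levels < 1:
            raise ParameterError("dwt_levels must be >= 1")
        if self.kind == "compound":
            if self.components is None or len(self.components) != 2:
                raise ParameterError("compound descriptor needs exactly two components")
            if any(w <= 0 for w in self.weights):
                raise ParameterError("compound weights must be positive")

    @classmethod
    def from_name(cls, name: str, **kwargs) -> "DescriptorConfig":
        """Parse names like ``"paa"`` or ``"hog1d+raw"`` (compound)."""
        name = name.lower()
        if "+" in name:
            a, b = name.split("+", 1)
            return cls(
                kind="compound",
                components=(cls.from_name(a, **kwargs), cls.from_name(b, **kwargs)),
                **kwargs,
            )
        return cls(kind=name, **kwargs)

    @property
    def name(self) -> str:
        if self.kind == "compound":
            return "+".join(c.name for c in self.components)
        return self.kind

    def to_json(self) -> str:
        def enc(cfg: "DescriptorConfig") -> dict:
            d = {
                "kind": cfg.kind,
                "l": cfg.l,
                "intervals": cfg.intervals,
                "dwt_levels": cfg.dwt_levels,
                "hog_bins": cfg.hog_bins,
                "hog_intervals": cfg.hog_intervals,
                "hog_scale": cfg.hog_scale,
            }
            if cfg.kind == "compound":
                d["components"] = [enc(c) for c in cfg.components]
                d["weights"] = list(cfg.weights)
            return d

        return json.dumps(enc(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "DescriptorConfig":
        def dec(d: dict) -> "DescriptorConfig":
            comps = d.pop("components", None)
            weights = tuple(d.pop("weights", (1.0, 1.0)))
            if comps is not None:
                return cls(components=(dec(comps[0]), dec(comps[1])), weights=weights, **d)
            return cls(**d)

        return dec(json.loads(text))


@dataclass
class DescriptorSequence:
    """One descriptor vector per sample of a signal (m x d matrix)."""

    vectors: np.ndarray
    config: DescriptorConfig
    source_channel: Optional[ChannelScheme] = field(default=None)

    def __len__(self) -> int:
        return len(self.vectors)

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]


def extract_subsequence(series: np.ndarray, center: int, l: int) -> np.ndarray:
    """Window of odd length ``l`` centered on ``center``, edges replicated."""
    x = np.asarray(series, dtype=float)
    half = l // 2
    idx = np.clip(np.arange(center - half, center + half + 1), 0, x.size - 1)
    return x[idx]


def _windows(series: np.ndarray, l: int, pad: str = "edge") -> np.ndarray:
    """All centered windows as an (m, l) matrix.

    ``pad="edge"`` replicates the boundary samples (default, for
    streams); ``pad="wrap"`` continues the series periodically, which is
    the right context for a stride template — the samples before a
    stride boundary are the tail of the previous, near-identical cycle,
    not a frozen copy of the boundary value.
    """
    x = np.asarray(series, dtype=float)
    half = l // 2
    padded = np.pad(x, half, mode=pad)
    return np.lib.stride_tricks.sliding_window_view(padded, l)


def _interval_bounds(l: int, k: int) -> np.ndarray:
    """k near-equal interval boundaries over [0, l] (sizes differ by <= 1)."""
    return np.round(np.linspace(0, l, k + 1)).astype(int)


def _paa(windows: np.ndarray, k: int) -> np.ndarray:
    b = _interval_bounds(windows.shape[1], k)
    return np.stack(
        [windows[:, b[i] : b[i + 1]].mean(axis=1) for i in range(k)], axis=1
    )


def _slope(windows: np.ndarray, k: int) -> np.ndarray:
    """Least-squares line slope per interval (offset-invariant)."""
    b = _interval_bounds(windows.shape[1], k)
    out = np.empty((windows.shape[0], k))
    for i in range(k):
        seg = windows[:, b[i] : b[i + 1]]
        t = np.arange(seg.shape[1], dtype=float)
        t = t - t.mean()
        denom = float(np.sum(t * t))
        if denom == 0.0:  # single-sample interval
            out[:, i] = 0.0
        else:
            out[:, i] = (seg - seg.mean(axis=1, keepdims=True)) @ t / denom
    return out


def _dwt(windows: np.ndarray, levels: int) -> np.ndarray:
    coeffs = pywt.wavedec(windows, "haar", level=levels, axis=1)
    return np.concatenate(coeffs, axis=1)


def _hog1d(windows: np.ndarray, bins: int, k: int, scale: float) -> np.ndarray:
    """Histogram of oriented gradients per interval, concatenated.

    Gradients are central differences; each sample votes its gradient
    magnitude sqrt(1 + (scale*g)^2) into the orientation bin of
    arctan(scale*g), with ``bins`` uniform bins over (-pi/2, pi/2).
    """
    g = np.gradient(windows, axis=1) * scale
    theta = np.arctan(g)
    weight = np.sqrt(1.0 + g * g)
    bin_idx = np.clip(((theta + np.pi / 2) / np.pi * bins).astype(int), 0, bins - 1)
    m, l = windows.shape
    b = _interval_bounds(l, k)
    out = np.zeros((m, k * bins))
    rows = np.arange(m)
    for i in range(k):
        for j in range(b[i], b[i + 1]):
            np.add.at(out, (rows, i * bins + bin_idx[:, j]), weight[:, j])
    return out


def _scale_block(block: np.ndarray) -> np.ndarray:
    """L2-normalize each descriptor vector of a compound block.

    Projecting both blocks onto the unit sphere keeps either family —
    whose raw distance scales differ by an order of magnitude — from
    dominating the concatenated distance.  The cost is that per-sample
    amplitude information survives only through the window's *shape*,
    which makes compound descriptors more sensitive to additive noise
    than their magnitude-aware component alone (see the methods note).
    """
    norms = np.linalg.norm(block, axis=-1, keepdims=True)
    return block / np.where(norms == 0.0, 1.0, norms)


def describe(
    series: np.ndarray,
    config: DescriptorConfig,
    source_channel: Optional[ChannelScheme] = None,
    pad: str = "edge",
) -> DescriptorSequence:
    """Map a signal to its per-sample shape-descriptor sequence.

    Use ``pad="wrap"`` for periodic signals such as a stride template,
    where the window context across the boundary is the opposite end of
    the cycle.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ParameterError("describe expects a 1-D series of length >= 2")
    vectors = _describe_matrix(x, config, pad)
    return DescriptorSequence(vectors=vectors, config=config, source_channel=source_channel)


def _describe_matrix(x: np.ndarray, config: DescriptorConfig, pad: str = "edge") -> np.ndarray:
    if config.kind == "compound":
        blocks = []
        for comp, w in zip(config.components, config.weights):
            block = _scale_block(_describe_matrix(x, comp, pad))
            blocks.append(w * block)
        return np.concatenate(blocks, axis=1)
    w = _windows(x, config.l, pad)
    if config.kind == "raw":
        return w.copy()
    if config.kind == "paa":
        return _paa(w, config.intervals)
    if config.kind == "dwt":
        return _dwt(w, config.dwt_levels)
    if config.kind == "slope":
        return _slope(w, config.intervals)
    if config.kind == "derivative":
        return np.gradient(w, axis=1)
    if config.kind == "hog1d":
        return _hog1d(w, config.hog_bins, config.hog_intervals, config.hog_scale)
    raise ParameterError(f"unknown descriptor kind {config.kind!r}")


def describe_window(window: np.ndarray, config: DescriptorConfig) -> np.ndarray:
    """Apply the descriptor mapping to one explicit subsequence.

    Unlike :func:`describe`, no centered-window extraction happens: the
    given samples *are* the neighborhood.
    """
    w = np.atleast_2d(np.asarray(window, dtype=float))
    if config.kind == "compound":
        blocks = []
        for comp, weight in zip(config.components, config.weights):
            block = _scale_block(np.atleast_2d(describe_window(window, comp)))
            blocks.append(weight * block)
        return np.concatenate(blocks, axis=1)[0]
    if config.kind == "raw":
        return w[0].copy()
    if config.kind == "paa":
        return _paa(w, config.intervals)[0]
    if config.kind == "dwt":
        return _dwt(w, config.dwt_levels)[0]
    if config.kind == "slope":
        return _slope(w, config.intervals)[0]
    if config.kind == "derivative":
        return np.gradient(w, axis=1)[0]
    if config.kind == "hog1d":
        return _hog1d(w, config.hog_bins, config.hog_intervals, config.hog_scale)[0]
    raise ParameterError(f"unknown descriptor kind {config.kind!r}")


def descriptor_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean distance between two descriptor vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ParameterError(f"descriptor dimension mismatch: {a.shape} vs {b.shape}")
    return float(np.linalg.norm(a - b))


def distance_matrix(
    q: DescriptorSequence | list[DescriptorSequence],
    t: DescriptorSequence | list[DescriptorSequence],
) -> np.ndarray:
    """m x n matrix of descriptor distances between query and template.

    When lists are given (one DescriptorSequence per channel), per-channel
    Euclidean distances are summed elementwise.
    """
    qs = q if isinstance(q, list) else [q]
    ts = t if isinstance(t, list) else [t]
    if len(qs) != len(ts):
        raise ParameterError("query and template must have the same number of channels")
    total = None
    for qi, ti in zip(qs, ts):
        if qi.config != ti.config:
            raise ParameterError("query and template descriptor configs differ")
        d = cdist(qi.vectors, ti.vectors, metric="euclidean")
        total = d if total is None else total + d
    return total
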