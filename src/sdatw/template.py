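"""Average stride template construction.

A stride template is a fixed-length (200-sample) six-channel reference
waveform — accelerometer X/Y/Z and gyroscope X/Y/Z — obtained by
resampling labeled stride segments to a common length and averaging them
sample by sample.  Averaging strides drawn evenly across height groups
and walking speeds produces a compromise waveform that matches a wide
range of subjects, which is exactly what a threshold-free matcher
needs: one template, no per-subject tuning.

Stride segments must run from stance end to stance end, since that is
the stride-boundary convention used throughout the package.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, ParameterError

__all__ = ["StrideTemplate", "resample_stride", "build_template", "save_template", "load_template"]

TEMPLATE_LENGTH = 200
CHANNEL_NAMES = ("acc_x", "acc_y", "acc_z", "gyro_x", "gyro_y", "gyro_z")


@dataclass
class StrideTemplate:
    """An n x 6 averaged reference stride (default n = 200)."""

    B: np.ndarray
    source_count: int = 1
    height_groups: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        self.B = np.asarray(self.B, dtype=float)
        if self.B.ndim != 2 or self.B.shape[1] != len(CHANNEL_NAMES):
            raise ParameterError(f"template must be n x 6, got shape {self.B.shape}")
        if not np.all(np.isfinite(self.B)):
            raise ParameterError("template contains non-finite values")

    def __len__(self) -> int:
        return len(self.B)

    def channel(self, sensor: str, axis_index: int) -> np.ndarray:
        col = {"acc": 0, "gyro": 3}[sensor] + axis_index
        return self.B[:, col]


def resample_stride(segment: np.ndarray, n: int = TEMPLATE_LENGTH) -> np.ndarray:
    """Linearly interpolate a k x c stride segment onto n equally spaced points.

    Endpoints are preserved exactly; each channel is interpolated
    independently on the normalized span [0, 1].
    """
    seg = np.asarray(segment, dtype=float)
    if seg.ndim == 1:
        seg = seg[:, None]
    k = seg.shape[0]
    if k < 2:
        raise DegenerateInputError("stride segment needs at least 2 samples to resample")
    src = np.linspace(0.0, 1.0, k)
    dst = np.linspace(0.0, 1.0, n)
    out = np.empty((n, seg.shape[1]))
    for c in range(seg.shape[1]):
        out[:, c] = np.interp(dst, src, seg[:, c])
    return out


def _even_indices(count: int, fraction: float) -> np.ndarray:
    """ceil(fraction*count) evenly spaced indices into range(count)."""
    k = max(1, math.ceil(fraction * count))
    return np.unique(np.round(np.linspace(0, count - 1, k)).astype(int))


def build_template(
    strides: list[np.ndarray],
    fraction: float = 0.30,
    groups: list[str] | None = None,
    n: int = TEMPLATE_LENGTH,
    seed: int | None = None,
) -> StrideTemplate:
    """Average an evenly selected fraction of strides into one template.

    Selection is stratified per height group: within each group the
    strides are taken in their given (time) order and ceil(fraction *
    group size) of them are picked at evenly spaced positions, or
    uniformly at random when ``seed`` is given.  Selected segments are
    resampled to ``n`` samples and averaged sample by sample.
    """
    if not strides:
        raise ParameterError("need at least one stride to build a template")
    if not (0.0 < fraction <= 1.0):
        raise ParameterError("fraction must be in (0, 1]")
    if groups is None:
        groups = ["all"] * len(strides)
    if len(groups) != len(strides):
        raise ParameterError("groups must have one label per stride")

    rng = np.random.default_rng(seed) if seed is not None else None
    selected: list[np.ndarray] = []
    used_groups: list[str] = []
    for group in dict.fromkeys(groups):  # preserves first-seen order
        members = [s for s, g in zip(strides, groups) if g == group]
        if rng is not None:
            k = max(1, math.ceil(fraction * len(members)))
            idx = np.sort(rng.choice(len(members), size=k, replace=False))
        else:
            idx = _even_indices(len(members), fraction)
        selected.extend(members[i] for i in idx)
        used_groups.append(group)

    resampled = np.stack([resample_stride(s, n) for s in selected])
    return StrideTemplate(
        B=resampled.mean(axis=0),
        source_count=len(selected),
        height_groups=tuple(used_groups),
    )


def save_template(template: StrideTemplate, path: str | Path) -> None:
    """Write the template as CSV plus a JSON provenance sidecar."""
    path = Path(path)
    pd.DataFrame(template.B, columns=list(CHANNEL_NAMES)).to_csv(
        path, index=False, float_format="%.17g"
    )
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "source_count": template.source_count,
                "height_groups": list(template.height_groups),
                "length": len(template),
            },
            indent=2,
        )
    )


def load_template(path: str | Path) -> StrideTemplate:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in CHANNEL_NAMES if c not in df.columns]
    if missing:
        raise ParameterError(f"template CSV missing column(s): {', '.join(missing)}")
    meta = {}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return StrideTemplate(
        B=df[list(CHANNEL_NAMES)].to_numpy(float),
        source_count=int(meta.get("source_count", 1)),
        height_groups=tuple(meta.get("height_groups", ())),
    )
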