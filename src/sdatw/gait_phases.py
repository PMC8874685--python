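"""Gait-event detection and four-phase division inside detected strides.

Three events split a stride (bounded at stance end) into its four
phases.  Toe-off (TO) is the zero crossing of the coronal-axis
gyroscope as the ankle passes from plantar flexion to dorsiflexion;
heel-touch (HT) is the sharp impact transient visible simultaneously on
the coronal gyro and the sagittal (forward) accelerometer; heel-off
(HO) breaks the quiet stance and is found as the point where a short
sliding-window variance first exceeds a threshold.  The heelstrike
phase ends when the signal settles back below that same variance
threshold ("settling"), which marks full foot contact and the start of
stance.

The detectors operate on sign changes, high-pass residuals and local
variance, so they are invariant to constant offsets on the channels.
Axis mapping (coronal = gyro Z, sagittal = acc X in the forward/up/left
frame) is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .engine import DetectedStride
from .errors import DetectionError
from .imu_io import ImuRecording
from .preprocess import mean_filter

__all__ = [
    "PhaseConfig",
    "GaitEvent",
    "StrideEvents",
    "GaitPhaseSegment",
    "detect_toe_off",
    "detect_heel_touch",
    "detect_heel_off",
    "detect_settling",
    "detect_events",
    "phase_segment",
    "phases_for_strides",
]


@dataclass(frozen=True)
class PhaseConfig:
    """Channel mapping and detector parameters.

    theta_var is the stance-break variance threshold in (rad/s)^2 over a
    var_window-sample (50 ms) window.  The default 0.2 sits well above
    stance-phase noise variance (~0.11 (rad/s)^2 even at power SNR 10)
    yet below the sliding variance that a push-off onset of ~2 rad/s
    reaches within its first few samples; a much larger threshold would
    be blind to the gentler push-offs of slow walking.
    """

    coronal_gyro_axis: int = 2  # rotation about the left-pointing axis
    sagittal_acc_axis: int = 0  # forward
    smooth_window: int = 5
    theta_var: float = 0.2
    var_window: int = 5
    direction: float = 1.0  # template polarity of the dorsiflexion swing
    spike_z_floor: float = 3.0


@dataclass(frozen=True)
class GaitEvent:
    kind: str  # TO | HT | HO
    time: int  # sample index
    stride_ref: DetectedStride


@dataclass
class StrideEvents:
    """All events of one stride, with flags for degraded detections."""

    to: Optional[GaitEvent]
    ht: Optional[GaitEvent]
    settling: Optional[int]
    ho: Optional[GaitEvent] = None
    flags: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class GaitPhaseSegment:
    label: str
    start: int
    end: int
    stride_ref: DetectedStride

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


def _sliding_var(x: np.ndarray, window: int) -> np.ndarray:
    """Centered sliding sample variance with shrinking edge windows."""
    m1 = mean_filter(x, window)
    m2 = mean_filter(x * x, window)
    return np.maximum(m2 - m1 * m1, 0.0)


def detect_toe_off(
    gyro_coronal: np.ndarray,
    stride: DetectedStride,
    config: PhaseConfig = PhaseConfig(),
) -> Optional[GaitEvent]:
    """Zero crossing of the coronal gyro into the dorsiflexion swing lobe.

    Robust form of "first crossing after stride start": locate the
    dominant positive swing peak of the smoothed signal, then walk back
    to the last non-positive sample; the crossing is one sample later.
    Returns None (event missing) if the signal never goes non-positive
    before the peak or never goes positive at all.
    """
    seg = config.direction * np.asarray(gyro_coronal[stride.start : stride.end], dtype=float)
    if seg.size < config.smooth_window:
        return None
    smooth = mean_filter(seg, config.smooth_window)
    peak = int(np.argmax(smooth))
    if smooth[peak] <= 0:
        return None  # no dorsiflexion lobe
    nonpos = np.nonzero(smooth[: peak + 1] <= 0)[0]
    if nonpos.size == 0:
        return None  # all positive before the peak: no crossing
    return GaitEvent(kind="TO", time=stride.start + int(nonpos[-1]) + 1, stride_ref=stride)


def detect_heel_touch(
    gyro_coronal: np.ndarray,
    acc_sagittal: np.ndarray,
    stride: DetectedStride,
    to: GaitEvent,
    config: PhaseConfig = PhaseConfig(),
) -> Optional[GaitEvent]:
    """Impact transient after toe-off, scored jointly on both channels.

    The spike is the largest standardized high-pass residual (signal
    minus its short moving average), summed over the coronal gyro and
    the sagittal accelerometer.  Spikes before TO are outside the search
    window; a maximum below the noise floor returns None.
    """
    lo, hi = to.time + 1, stride.end
    if hi - lo < config.smooth_window:
        return None
    score = np.zeros(hi - lo)
    for channel in (gyro_coronal, acc_sagittal):
        seg = np.asarray(channel[lo:hi], dtype=float)
        resid = seg - mean_filter(seg, config.smooth_window)
        mad = 1.4826 * np.median(np.abs(resid - np.median(resid)))
        scale = max(mad, 1e-12)
        score += np.abs(resid) / scale
    peak = int(np.argmax(score))
    if score[peak] < 2 * config.spike_z_floor:  # z-floor per channel
        return None
    return GaitEvent(kind="HT", time=lo + peak, stride_ref=stride)


def detect_settling(
    gyro_coronal: np.ndarray,
    stride: DetectedStride,
    ht: GaitEvent,
    config: PhaseConfig = PhaseConfig(),
) -> tuple[int, bool]:
    """First sample after HT where the sliding variance drops below
    theta_var: the foot is flat, stance begins.  Falls back to a fixed
    100 ms offset (flagged False) if the signal never quiets down."""
    lo, hi = ht.time + 1, stride.end
    seg = np.asarray(gyro_coronal[lo:hi], dtype=float)
    if seg.size < config.var_window:
        return min(ht.time + 10, stride.end - 1), False
    var = _sliding_var(seg, config.var_window)
    quiet = np.nonzero(var < config.theta_var)[0]
    if quiet.size == 0:
        return min(ht.time + 10, stride.end - 1), False
    return lo + int(quiet[0]), True


def detect_heel_off(
    gyro_coronal: np.ndarray,
    stride: DetectedStride,
    next_boundary: int,
    config: PhaseConfig = PhaseConfig(),
    settled_from: Optional[int] = None,
) -> GaitEvent:
    """Break of the static phase: first sample after stance onset whose
    sliding-window variance exceeds theta_var.

    With the stride boundary at stance end, HO nominally coincides with
    the boundary; detecting it validates the start of the next cycle.
    If the variance never exceeds the threshold the event is placed at
    the boundary (callers may treat that as flagged).
    """
    lo = stride.start if settled_from is None else settled_from
    hi = min(next_boundary, gyro_coronal.shape[0])
    seg = np.asarray(gyro_coronal[lo:hi], dtype=float)
    if seg.size >= config.var_window:
        var = _sliding_var(seg, config.var_window)
        loud = np.nonzero(var > config.theta_var)[0]
        if loud.size:
            return GaitEvent(kind="HO", time=lo + int(loud[0]), stride_ref=stride)
    return GaitEvent(kind="HO", time=hi, stride_ref=stride)


def detect_events(
    rec: ImuRecording,
    stride: DetectedStride,
    next_boundary: Optional[int] = None,
    config: PhaseConfig = PhaseConfig(),
) -> StrideEvents:
    """Run all three detectors for one stride and collect flags."""
    gyro = rec.channel("gyro", config.coronal_gyro_axis)
    acc = rec.channel("acc", config.sagittal_acc_axis)
    flags: list[str] = []
    to = detect_toe_off(gyro, stride, config)
    if to is None:
        flags.append("to_missing")
    ht = detect_heel_touch(gyro, acc, stride, to, config) if to is not None else None
    if to is not None and ht is None:
        flags.append("ht_missing")
    settling = None
    if ht is not None:
        settling, ok = detect_settling(gyro, stride, ht, config)
        if not ok:
            flags.append("settling_fallback")
    ho = None
    if next_boundary is not None and settling is not None:
        ho = detect_heel_off(gyro, stride, next_boundary, config, settled_from=settling)
        if ho.time >= next_boundary:
            flags.append("ho_at_boundary")
    return StrideEvents(to=to, ht=ht, settling=settling, ho=ho, flags=flags)


def phase_segment(events: StrideEvents, stride: DetectedStride) -> list[GaitPhaseSegment]:
    """Tile the stride into pushoff | swing | heelstrike | stance.

    TO and HT are mandatory; the heelstrike/stance boundary is the
    settling point, clamped so every phase is non-empty.  Raises
    DetectionError when a mandatory event is missing or out of order, so
    callers can exclude (and count) the stride.
    """
    if events.to is None or events.ht is None:
        raise DetectionError("stride lacks a mandatory gait event (TO or HT)")
    to, ht = events.to.time, events.ht.time
    if not (stride.start < to < ht < stride.end - 1):
        raise DetectionError("gait events out of order within the stride")
    settling = events.settling if events.settling is not None else ht + 1
    settling = int(np.clip(settling, ht + 1, stride.end - 1))
    tiles = [
        GaitPhaseSegment("pushoff", stride.start, to, stride),
        GaitPhaseSegment("swing", to, ht, stride),
        GaitPhaseSegment("heelstrike", ht, settling, stride),
        GaitPhaseSegment("stance", settling, stride.end, stride),
    ]
    return tiles


def phases_for_strides(
    rec: ImuRecording,
    strides: list[DetectedStride],
    config: PhaseConfig = PhaseConfig(),
) -> tuple[list[GaitPhaseSegment], int]:
    """Phase segments for every stride; returns (segments, excluded count)."""
    segments: list[GaitPhaseSegment] = []
    excluded = 0
    for i, stride in enumerate(strides):
        nxt = strides[i + 1].start if i + 1 < len(strides) else None
        events = detect_events(rec, stride, next_boundary=nxt, config=config)
        try:
            segments.extend(phase_segment(events, stride))
        except DetectionError:
            excluded += 1
    return segments, excluded
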