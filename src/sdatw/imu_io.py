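"""Reading, writing and aligning foot-mounted IMU recordings and gait labels.

The on-disk formats are deliberately plain: an 11-column CSV for the
sensor stream (two tick counters plus three 3-axis triads at 100 Hz,
one tick = 0.01 s) and a minimal ELAN-compatible XML dialect for the
gait-phase annotations (a time-slot table in milliseconds plus one tier
of alignable annotations).  Because the IMU has no acquisition trigger,
each trial is book-ended by deliberate foot stomps — sharp vertical
accelerations clearly larger than anything produced by walking — and the
label track is aligned to the sensor clock by matching stomp times.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import (
    DetectionError,
    FormatError,
    IntegrityError,
    SynchronizationError,
    ValidationError,
)

__all__ = [
    "PHASE_LABELS",
    "ImuRecording",
    "GaitLabelTrack",
    "read_imu_csv",
    "write_imu_csv",
    "read_labels",
    "write_labels",
    "detect_stomps",
    "walking_region",
    "synchronize",
]

#: The four gait phases, in within-stride order (stride bounded at stance end).
PHASE_LABELS = ("pushoff", "swing", "heelstrike", "stance")

TICK_SECONDS = 0.01

IMU_COLUMNS = (
    "time_stamp_0",
    "time_stamp_1",
    "acc_x",
    "acc_y",
    "acc_z",
    "turnrate_x",
    "turnrate_y",
    "turnrate_z",
    "magnetometer_x",
    "magnetometer_y",
    "magnetometer_z",
)


@dataclass
class ImuRecording:
    """A synchronized 6(+3)-axis sensor stream with a sample clock.

    Axis convention: X forward, Y upward, Z to the left.  ``acc`` is in
    m/s^2, ``gyro`` in rad/s, ``mag`` normalized field strength.
    """

    acc: np.ndarray
    gyro: np.ndarray
    mag: np.ndarray
    sample_rate: float = 100.0
    start_tick: int = 0

    def __post_init__(self) -> None:
        self.acc = np.atleast_2d(np.asarray(self.acc, dtype=float))
        self.gyro = np.atleast_2d(np.asarray(self.gyro, dtype=float))
        self.mag = np.atleast_2d(np.asarray(self.mag, dtype=float))
        n = len(self.acc)
        if len(self.gyro) != n or len(self.mag) != n:
            raise IntegrityError("acc, gyro and mag must have equal length")
        if self.sample_rate <= 0:
            raise IntegrityError("sample_rate must be positive")

    def __len__(self) -> int:
        return len(self.acc)

    @property
    def time(self) -> np.ndarray:
        """Per-sample time in seconds."""
        return (self.start_tick + np.arange(len(self))) / self.sample_rate

    def channel(self, sensor: str, axis_index: int) -> np.ndarray:
        arr = {"acc": self.acc, "gyro": self.gyro, "mag": self.mag}[sensor]
        return arr[:, axis_index]


@dataclass
class GaitLabelTrack:
    """Time-ordered, non-overlapping (label, start, end) phase intervals.

    Times are seconds on the sensor clock once ``offset_applied`` has been
    added (zero for a freshly read, unsynchronized track).
    """

    entries: list[tuple[str, float, float]]
    offset_applied: float = 0.0
    stomp_times: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        entries = sorted(self.entries, key=lambda e: e[1])
        prev_end = -np.inf
        for label, start, end in entries:
            if label not in PHASE_LABELS:
                raise ValidationError(
                    f"unknown label {label!r}; allowed labels: {', '.join(PHASE_LABELS)}"
                )
            if end <= start:
                raise IntegrityError(f"interval ({label}, {start}, {end}) has end <= start")
            if start < prev_end - 1e-9:
                raise IntegrityError(f"interval starting at {start} overlaps the previous one")
            prev_end = end
        self.entries = entries

    def __len__(self) -> int:
        return len(self.entries)

    def shifted(self, offset: float) -> "GaitLabelTrack":
        return replace(
            self,
            entries=[(lab, s + offset, e + offset) for lab, s, e in self.entries],
            offset_applied=self.offset_applied + offset,
            stomp_times=[t + offset for t in self.stomp_times],
        )

    def stride_intervals(self) -> list[tuple[float, float]]:
        """Stride intervals implied by the phase track (stance-end to stance-end)."""
        strides = []
        current_start = None
        for label, start, end in self.entries:
            if label == "pushoff":
                current_start = start
            elif label == "stance" and current_start is not None:
                strides.append((current_start, end))
                current_start = None
        return strides


def read_imu_csv(path: str | Path) -> ImuRecording:
    """Read an 11-column IMU CSV; tick counters are converted at 0.01 s/tick."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in IMU_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"IMU CSV {path} is missing column(s): {', '.join(missing)}")
    ticks = df["time_stamp_0"].to_numpy()
    if len(ticks) > 1 and np.any(np.diff(ticks) <= 0):
        raise IntegrityError(f"IMU CSV {path} has non-monotone timestamps")
    return ImuRecording(
        acc=df[["acc_x", "acc_y", "acc_z"]].to_numpy(float),
        gyro=df[["turnrate_x", "turnrate_y", "turnrate_z"]].to_numpy(float),
        mag=df[["magnetometer_x", "magnetometer_y", "magnetometer_z"]].to_numpy(float),
        sample_rate=1.0 / TICK_SECONDS,
        start_tick=int(ticks[0]) if len(ticks) else 0,
    )


def write_imu_csv(rec: ImuRecording, path: str | Path) -> None:
    ticks = rec.start_tick + np.arange(len(rec))
    df = pd.DataFrame(
        {
            "time_stamp_0": ticks,
            "time_stamp_1": ticks,
            "acc_x": rec.acc[:, 0],
            "acc_y": rec.acc[:, 1],
            "acc_z": rec.acc[:, 2],
            "turnrate_x": rec.gyro[:, 0],
            "turnrate_y": rec.gyro[:, 1],
            "turnrate_z": rec.gyro[:, 2],
            "magnetometer_x": rec.mag[:, 0],
            "magnetometer_y": rec.mag[:, 1],
            "magnetometer_z": rec.mag[:, 2],
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


def _annotation_root(track: GaitLabelTrack) -> ET.Element:
    root = ET.Element("ANNOTATION_DOCUMENT", {"FORMAT": "2.8", "AUTHOR": "sdatw"})
    order = ET.SubElement(root, "TIME_ORDER")
    slot_ids: dict[int, str] = {}

    def slot(t_s: float) -> str:
        ms = int(round(t_s * 1000.0))
        if ms not in slot_ids:
            sid = f"ts{len(slot_ids) + 1}"
            slot_ids[ms] = sid
            ET.SubElement(order, "TIME_SLOT", {"TIME_SLOT_ID": sid, "TIME_VALUE": str(ms)})
        return slot_ids[ms]

    tier = ET.SubElement(root, "TIER", {"TIER_ID": "gait", "LINGUISTIC_TYPE_REF": "phase"})
    for i, (label, start, end) in enumerate(track.entries):
        ann = ET.SubElement(tier, "ANNOTATION")
        al = ET.SubElement(
            ann,
            "ALIGNABLE_ANNOTATION",
            {
                "ANNOTATION_ID": f"a{i + 1}",
                "TIME_SLOT_REF1": slot(start),
                "TIME_SLOT_REF2": slot(end),
            },
        )
        ET.SubElement(al, "ANNOTATION_VALUE").text = label
    return root


def write_labels(track: GaitLabelTrack, path: str | Path) -> None:
    """Write the track as a minimal ELAN-style XML file (times in ms)."""
    tree = ET.ElementTree(_annotation_root(track))
    ET.indent(tree)
    tree.write(path, encoding="unicode", xml_declaration=True)


def read_labels(path: str | Path) -> GaitLabelTrack:
    """Read (label, start, end) intervals from the ELAN-style XML dialect."""
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise FormatError(f"cannot parse annotation XML {path}: {exc}") from exc
    slots: dict[str, float] = {}
    for ts in root.iter("TIME_SLOT"):
        slots[ts.attrib["TIME_SLOT_ID"]] = float(ts.attrib["TIME_VALUE"]) / 1000.0
    entries = []
    for al in root.iter("ALIGNABLE_ANNOTATION"):
        value = al.find("ANNOTATION_VALUE")
        label = (value.text or "").strip() if value is not None else ""
        try:
            start = slots[al.attrib["TIME_SLOT_REF1"]]
            end = slots[al.attrib["TIME_SLOT_REF2"]]
        except KeyError as exc:
            raise FormatError(f"annotation references unknown time slot {exc}") from exc
        entries.append((label, start, end))
    return GaitLabelTrack(entries=entries)


def detect_stomps(
    rec: ImuRecording, k_sigma: float = 6.0, refractory_s: float = 0.3
) -> list[int]:
    """Find stomp peaks in the acceleration-magnitude signal.

    The per-axis median (gravity plus bias) is removed first, so the
    detector is invariant to constant offsets.  Peaks must exceed
    ``median + k_sigma * robust scale`` of the magnitude and be separated
    by at least ``refractory_s`` seconds.
    """
    if k_sigma <= 0:
        raise ValueError("k_sigma must be positive")
    centered = rec.acc - np.median(rec.acc, axis=0)
    mag = np.linalg.norm(centered, axis=1)
    med = np.median(mag)
    # quantile-range scale: tracks the walking-signal envelope while the
    # stomps themselves (rare, extreme) cannot inflate it; a plain MAD
    # collapses to the noise floor on mostly-quiet trials and would flag
    # ordinary heel-strike transients as stomps
    scale = float(np.quantile(mag, 0.95) - med)
    threshold = med + k_sigma * scale
    distance = max(1, int(round(refractory_s * rec.sample_rate)))
    peaks, _ = find_peaks(mag, height=threshold, distance=distance)
    if len(peaks) == 0:
        raise DetectionError("no stomp peak found above the robust threshold")
    return [int(p) for p in peaks]


def walking_region(
    rec: ImuRecording,
    k_sigma: float = 6.0,
    margin_s: float = 0.3,
) -> tuple[float, float]:
    """The time span between the head and tail stomp groups, in seconds.

    Trials are book-ended by synchronization stomps; only the stretch
    between the last head stomp and the first tail stomp contains
    walking, so detections outside it have no ground truth to be scored
    against.  Stomps are split into head/tail groups at the largest
    inter-stomp gap; ``margin_s`` of settling time is trimmed from both
    sides.  With fewer than two stomps the whole recording is returned.
    """
    try:
        stomps = detect_stomps(rec, k_sigma=k_sigma)
    except DetectionError:
        return (0.0, len(rec) / rec.sample_rate)
    times = rec.time[np.asarray(stomps)]
    if len(times) < 2:
        return (0.0, len(rec) / rec.sample_rate)
    gaps = np.diff(times)
    split = int(np.argmax(gaps))
    return (float(times[split]) + margin_s, float(times[split + 1]) - margin_s)


def synchronize(
    rec: ImuRecording,
    labels: GaitLabelTrack,
    video_stomp_times: list[float],
    k_sigma: float = 6.0,
) -> GaitLabelTrack:
    """Shift the label track onto the sensor clock using paired stomps.

    Stomps are paired by order of occurrence; the applied shift is the
    mean of (IMU stomp time - video stomp time) over all pairs, i.e. the
    lag of the label clock behind the sensor clock.  Counts must agree.
    """
    imu_stomps = detect_stomps(rec, k_sigma=k_sigma)
    if len(imu_stomps) != len(video_stomp_times):
        raise SynchronizationError(
            f"stomp count mismatch: {len(imu_stomps)} in IMU stream "
            f"vs {len(video_stomp_times)} provided"
        )
    imu_times = rec.time[np.asarray(imu_stomps)]
    offsets = imu_times - np.asarray(video_stomp_times, dtype=float)
    shift = float(np.mean(offsets))
    out = labels.shifted(shift)
    out.stomp_times = [t + shift for t in video_stomp_times]
    return out
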