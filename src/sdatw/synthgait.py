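"""Synthetic 100 Hz foot-mounted IMU walking data with exact ground truth.

The generator emulates the structure of a recorded walking trial: a
quiet lead-in with sharp synchronization stomps, a run of strides, and a
quiet tail with closing stomps.  Each stride is a four-phase cycle —
pushoff, swing, heelstrike, stance — with the stride boundary at stance
end, matching the segmentation convention of the rest of the package.

The waveforms are sums of raised sinusoid lobes, damped oscillations and
Gaussian spikes.  They are not a biomechanical simulation; they encode
only the qualitative facts the detectors rely on:

* the coronal-axis gyroscope swings negative during pushoff (plantar
  flexion), crosses zero exactly at toe-off, rises through a smooth
  positive swing lobe, drops in a sharp spike at heel-touch followed by
  a damped settling oscillation, and is quiet during stance;
* forward/vertical acceleration shows a pushoff burst, mild swing
  oscillation, a heel-touch spike sharing the gyro's timing, and
  gravity-only stance (9.81 m/s^2 on the upward axis);
* stomps are isolated high-magnitude acceleration spikes, far larger
  than anything produced by walking.

Every event time, phase interval, stride boundary and stomp position is
recorded exactly as the signal is laid down, so recovered quantities can
be scored against construction-time truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import ParameterError
from .imu_io import GaitLabelTrack, ImuRecording, write_imu_csv, write_labels

__all__ = ["WalkSpec", "GroundTruth", "simulate_walk", "simulate_dataset", "noise_sd_for_snr"]

SAMPLE_RATE = 100.0
SPEED_MEAN_DURATION = {"fast": 0.9, "mid": 1.1, "slow": 1.4}
GRAVITY = 9.81

# waveform amplitudes (gyro rad/s, acc m/s^2)
GYRO_PUSHOFF_AMP = 2.0
GYRO_SWING_AMP = 3.5
GYRO_HT_AMP = 6.0
HT_OSC_HZ = 15.0
ACC_PUSHOFF_AMP = 3.0
ACC_SWING_AMP = 1.0
ACC_HT_AMP = 8.0
STANCE_ROCK_GYRO = 0.4
STANCE_ROCK_ACC = 0.4
STOMP_AMP = 60.0


@dataclass(frozen=True)
class WalkSpec:
    """Conditions of one synthetic walking trial.

    Stride durations are drawn per stride from a normal distribution
    with speed-dependent mean (0.9 / 1.1 / 1.4 s for fast / mid / slow)
    and 10% relative standard deviation, clipped to the physiological
    0.25–2.0 s range.  Phase fractions default to (0.15, 0.35, 0.10,
    0.40) — stance occupying about 40% of the cycle.  ``noise_sd`` is
    additive white Gaussian noise, one value per sensor in that sensor's
    units.
    """

    n_strides: int = 60
    speed: str = "mid"
    phase_fractions: tuple[float, float, float, float] = (0.15, 0.35, 0.10, 0.40)
    noise_sd: dict = field(default_factory=dict)  # keys: acc, gyro, mag
    subject_scale: float = 1.0
    seed: int = 0
    stomps: int = 3
    duration_sd_frac: float = 0.10
    flipped: bool = False
    gender: str = "unspecified"
    height_group: str = "170-175"

    def __post_init__(self) -> None:
        if self.speed not in SPEED_MEAN_DURATION:
            raise ParameterError(f"speed must be one of {sorted(SPEED_MEAN_DURATION)}")
        f = self.phase_fractions
        if len(f) != 4 or any(x <= 0 for x in f) or abs(sum(f) - 1.0) > 1e-9:
            raise ParameterError("phase_fractions must be 4 positive values summing to 1")
        if self.n_strides < 1:
            raise ParameterError("need at least one stride")
        mean_d = SPEED_MEAN_DURATION[self.speed]
        if not (0.25 <= mean_d <= 2.0):
            raise ParameterError("mean stride duration outside the 0.25-2.0 s envelope")


@dataclass
class GroundTruth:
    """Construction-time truth for one simulated trial (sample indices)."""

    stride_intervals: list[tuple[int, int]]
    phase_intervals: list[tuple[str, int, int]]
    event_times: dict  # kind -> list of sample indices (TO, HT, HO)
    stomp_times: list[int]
    sample_rate: float = SAMPLE_RATE

    def to_label_track(self) -> GaitLabelTrack:
        fs = self.sample_rate
        return GaitLabelTrack(
            entries=[(lab, s / fs, e / fs) for lab, s, e in self.phase_intervals]
        )

    def stride_intervals_s(self) -> list[tuple[float, float]]:
        fs = self.sample_rate
        return [(s / fs, e / fs) for s, e in self.stride_intervals]


def stride_waveform(
    k: int, phase_fractions: tuple[float, float, float, float], subject_scale: float = 1.0
) -> tuple[np.ndarray, dict]:
    """Clean k x 6 stride matrix (acc XYZ, gyro XYZ) and its event offsets.

    Events (sample offsets from stride start): ``to`` at pushoff end,
    ``ht`` at swing end, ``stance`` at heelstrike end; heel-off
    coincides with the stride boundary at k.
    """
    if k < 8:
        raise ParameterError("stride too short to carve four phases")
    f_po, f_sw, f_hs, _ = phase_fractions
    a = max(2, int(round(k * f_po)))  # toe-off
    b = max(a + 2, int(round(k * (f_po + f_sw))))  # heel-touch
    c = max(b + 2, int(round(k * (f_po + f_sw + f_hs))))  # stance start
    if c >= k - 1:
        raise ParameterError("phase fractions leave no room for stance")

    sig = np.zeros((k, 6))
    acc = sig[:, 0:3]
    gyro = sig[:, 3:6]
    fs = SAMPLE_RATE

    i_po = np.arange(a)
    i_sw = np.arange(a, b)
    i_hs = np.arange(b, c)
    i_st = np.arange(c, k)
    lobe_po = np.sin(np.pi * i_po / a)
    lobe_sw = np.sin(np.pi * (i_sw - a) / (b - a))
    tau = (i_hs - b) / (c - b)
    osc = (1.0 - tau) * np.cos(2 * np.pi * HT_OSC_HZ * (i_hs - b) / fs)

    # coronal gyro (Z): plantar-flexion lobe, dorsiflexion swing lobe,
    # heel-touch spike + damped settling, quiet stance
    gyro[i_po, 2] = -GYRO_PUSHOFF_AMP * lobe_po
    gyro[i_sw, 2] = GYRO_SWING_AMP * lobe_sw
    gyro[i_hs, 2] = -GYRO_HT_AMP * osc
    # minor rotation on the other gyro axes
    gyro[i_sw, 0] = 0.4 * GYRO_SWING_AMP * np.sin(2 * np.pi * (i_sw - a) / (b - a))
    gyro[i_hs, 0] = -0.3 * GYRO_HT_AMP * osc
    gyro[:, 1] = 0.25 * gyro[:, 0]

    # forward (sagittal) acceleration: pushoff burst, swing sway, HT spike
    acc[i_po, 0] = ACC_PUSHOFF_AMP * lobe_po
    acc[i_sw, 0] = ACC_SWING_AMP * np.sin(2 * np.pi * (i_sw - a) / (b - a))
    acc[i_hs, 0] = -ACC_HT_AMP * osc
    # vertical acceleration: pushoff lift and impact transient (gravity
    # is added once for the whole trial, not per stride)
    acc[i_po, 1] = 0.7 * ACC_PUSHOFF_AMP * lobe_po
    acc[i_hs, 1] = ACC_HT_AMP * osc
    # lateral sway
    acc[i_sw, 2] = 0.3 * np.sin(np.pi * (i_sw - a) / (b - a))

    # stance: the foot is only *relatively* stationary — weight transfer
    # rocks the instep-mounted sensor through one slow, low-amplitude
    # cycle.  This matters: a literally motionless stance would make the
    # stance-end stride boundary unidentifiable in principle, for any
    # matcher, because the signal would carry no positional information
    # there.  The amplitude stays far below the stance-break variance
    # threshold of the heel-off detector.
    tau_st = (i_st - c) / (k - c)
    rock = np.sin(2 * np.pi * tau_st)
    gyro[i_st, 2] = STANCE_ROCK_GYRO * rock
    acc[i_st, 0] = STANCE_ROCK_ACC * rock
    acc[i_st, 1] = 0.3 * STANCE_ROCK_ACC * np.sin(np.pi * tau_st)

    sig *= subject_scale
    return sig, {"to": a, "ht": b, "stance": c}


def _stomp_spike(length: int, center: int, fs: float) -> np.ndarray:
    """Gaussian acceleration spike (sigma 10 ms) peaking exactly at center."""
    t = np.arange(length)
    return STOMP_AMP * np.exp(-0.5 * ((t - center) / (0.01 * fs)) ** 2)


def simulate_walk(spec: WalkSpec) -> tuple[ImuRecording, GroundTruth]:
    """Generate one trial: stomps, strides, stomps — with exact truth."""
    rng = np.random.default_rng(spec.seed)
    fs = SAMPLE_RATE
    mean_d = SPEED_MEAN_DURATION[spec.speed]
    durations = rng.normal(mean_d, spec.duration_sd_frac * mean_d, spec.n_strides)
    durations = np.clip(durations, 0.25, 2.0)
    stride_lengths = np.round(durations * fs).astype(int)

    quiet = int(0.8 * fs)
    stomp_gap = int(0.5 * fs)
    head_len = quiet + spec.stomps * stomp_gap + quiet
    tail_len = quiet + spec.stomps * stomp_gap + quiet
    total = head_len + int(stride_lengths.sum()) + tail_len

    sig = np.zeros((total, 6))
    stomp_times: list[int] = []
    for i in range(spec.stomps):
        stomp_times.append(quiet + i * stomp_gap + stomp_gap // 2)
    for i in range(spec.stomps):
        stomp_times.append(
            head_len + int(stride_lengths.sum()) + quiet + i * stomp_gap + stomp_gap // 2
        )
    for t0 in stomp_times:
        sig[:, 1] += _stomp_spike(total, t0, fs)

    stride_intervals: list[tuple[int, int]] = []
    phase_intervals: list[tuple[str, int, int]] = []
    events: dict = {"TO": [], "HT": [], "HO": []}
    cursor = head_len
    for k in stride_lengths:
        wave, ev = stride_waveform(int(k), spec.phase_fractions, spec.subject_scale)
        sig[cursor : cursor + k] += wave
        a, b, c = ev["to"], ev["ht"], ev["stance"]
        stride_intervals.append((cursor, cursor + int(k)))
        phase_intervals.extend(
            [
                ("pushoff", cursor, cursor + a),
                ("swing", cursor + a, cursor + b),
                ("heelstrike", cursor + b, cursor + c),
                ("stance", cursor + c, cursor + int(k)),
            ]
        )
        events["TO"].append(cursor + a)
        events["HT"].append(cursor + b)
        events["HO"].append(cursor + int(k))
        cursor += int(k)

    acc = sig[:, 0:3].copy()
    gyro = sig[:, 3:6].copy()
    acc[:, 1] += GRAVITY
    mag = np.tile(np.array([0.42, 0.12, 0.21]), (total, 1))

    acc += rng.normal(0.0, spec.noise_sd.get("acc", 0.0), acc.shape)
    gyro += rng.normal(0.0, spec.noise_sd.get("gyro", 0.0), gyro.shape)
    mag += rng.normal(0.0, spec.noise_sd.get("mag", 0.0), mag.shape)

    if spec.flipped:
        acc = -acc
        gyro = -gyro

    rec = ImuRecording(acc=acc, gyro=gyro, mag=mag, sample_rate=fs)
    truth = GroundTruth(
        stride_intervals=stride_intervals,
        phase_intervals=phase_intervals,
        event_times=events,
        stomp_times=stomp_times,
        sample_rate=fs,
    )
    return rec, truth


def noise_sd_for_snr(spec: WalkSpec, snr: float) -> dict:
    """Per-sensor noise levels giving the requested power signal-to-noise
    ratio against this spec's clean (zero-noise) walking signal.

    The signal power is measured on the mean-removed clean channels over
    the stride region, averaged within each sensor triad.
    """
    clean_spec = replace(spec, noise_sd={})
    rec, truth = simulate_walk(clean_spec)
    lo = truth.stride_intervals[0][0]
    hi = truth.stride_intervals[-1][1]
    out = {}
    for name, arr in (("acc", rec.acc), ("gyro", rec.gyro)):
        seg = arr[lo:hi] - arr[lo:hi].mean(axis=0)
        rms = float(np.sqrt((seg**2).mean()))
        out[name] = rms / np.sqrt(snr)
    return out


def simulate_dataset(specs: list[WalkSpec], out_dir: str | Path) -> list[dict]:
    """Write one CSV + annotation XML + metadata file per spec, plus a
    manifest holding the exact ground truth.  Returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = []
    for i, spec in enumerate(specs):
        rec, truth = simulate_walk(spec)
        stem = f"trial_{i:03d}"
        write_imu_csv(rec, out / f"{stem}.csv")
        write_labels(truth.to_label_track(), out / f"{stem}.xml")
        meta_lines = [
            f"gender = {spec.gender}",
            f"height_group = {spec.height_group}",
            f"speed = {spec.speed}",
            f"seed = {spec.seed}",
        ]
        (out / f"{stem}.meta").write_text("\n".join(meta_lines) + "\n")
        manifest.append(
            {
                "trial": stem,
                "speed": spec.speed,
                "seed": spec.seed,
                "n_strides": spec.n_strides,
                "stride_intervals": truth.stride_intervals,
                "event_times": truth.event_times,
                "stomp_times": truth.stomp_times,
            }
        )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def read_metadata(path: str | Path) -> dict:
    """Parse the flat ``key = value`` metadata file."""
    meta = {}
    for line in Path(path).read_text().splitlines():
        if "=" in line:
            key, _, value = line.partition("=")
            meta[key.strip()] = value.strip()
    return meta
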