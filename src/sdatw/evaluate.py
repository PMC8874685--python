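"""Matching detections to labels and precision / recall / F-measure.

Detected stride (or phase) intervals are paired one-to-one with labeled
intervals greedily by descending Jaccard overlap; a pair counts as a
true positive when its Jaccard ratio reaches ``min_overlap`` (default
0.5).  Unmatched detections are false positives, unmatched labels false
negatives.  A boundary-distance mode (both endpoints within a time
tolerance) is available as an alternative matching rule.

    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F         = 2 * precision * recall / (precision + recall)

`sweep` runs segmentation + matching + metrics over a grid of
descriptor configurations and channel schemes across many recordings,
aggregating mean +- standard deviation per speed group, mirroring how
benchmark tables for this kind of method are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .descriptors import DescriptorConfig
from .engine import segment
from .errors import ParameterError
from .preprocess import ChannelScheme
from .template import StrideTemplate

__all__ = [
    "EvalResult",
    "MatchResult",
    "match_intervals",
    "metrics",
    "restrict_to_span",
    "sweep",
    "format_markdown",
]

Interval = tuple[float, float]


@dataclass(frozen=True)
class MatchResult:
    tp: int
    fp: int
    fn: int
    pairs: tuple[tuple[int, int], ...] = ()  # (detected index, labeled index)


@dataclass(frozen=True)
class EvalResult:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f_measure: float
    precision_defined: bool = True
    recall_defined: bool = True
    stratum: tuple = field(default=())


def _jaccard(a: Interval, b: Interval) -> float:
    inter = max(0.0, min(a[1], b[1]) - max(a[0], b[0]))
    union = (a[1] - a[0]) + (b[1] - b[0]) - inter
    return inter / union if union > 0 else 0.0


def match_intervals(
    detected: list[Interval],
    labeled: list[Interval],
    min_overlap: float = 0.5,
    mode: str = "jaccard",
    boundary_tol: float = 0.15,
) -> MatchResult:
    """One-to-one greedy pairing of detections with labels.

    ``mode="jaccard"`` pairs by descending Jaccard ratio and accepts a
    pair when the ratio reaches ``min_overlap``; ``mode="boundary"``
    accepts when both interval endpoints agree within ``boundary_tol``
    (same units as the intervals), preferring the smallest summed
    boundary error.
    """
    if not (0.0 < min_overlap <= 1.0):
        raise ParameterError("min_overlap must be in (0, 1]")
    if mode not in ("jaccard", "boundary"):
        raise ParameterError(f"unknown matching mode {mode!r}")

    candidates = []
    for i, d in enumerate(detected):
        for j, lab in enumerate(labeled):
            if mode == "jaccard":
                score = _jaccard(d, lab)
                if score >= min_overlap:
                    candidates.append((score, i, j))
            else:
                err = max(abs(d[0] - lab[0]), abs(d[1] - lab[1]))
                if err <= boundary_tol:
                    candidates.append((-err, i, j))
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))

    used_d: set[int] = set()
    used_l: set[int] = set()
    pairs = []
    for _, i, j in candidates:
        if i in used_d or j in used_l:
            continue
        used_d.add(i)
        used_l.add(j)
        pairs.append((i, j))
    tp = len(pairs)
    return MatchResult(tp=tp, fp=len(detected) - tp, fn=len(labeled) - tp, pairs=tuple(pairs))


def restrict_to_span(
    detected: list[Interval], labeled: list[Interval]
) -> list[Interval]:
    """Keep only detections whose midpoint falls inside the annotated span.

    Ground truth exists only between the first and last label; a
    detection outside that span (the quiet lead-in/tail of a trial)
    can be neither confirmed nor refuted, so it is excluded from
    scoring rather than counted as a false positive.
    """
    if not labeled:
        return list(detected)
    lo = min(a for a, _ in labeled)
    hi = max(b for _, b in labeled)
    return [d for d in detected if lo <= (d[0] + d[1]) / 2.0 <= hi]


def metrics(tp: int, fp: int, fn: int, stratum: tuple = ()) -> EvalResult:
    """Precision, recall and F-measure from raw counts.

    Undefined ratios (zero denominator) are reported as 0 with the
    corresponding ``*_defined`` flag cleared, so sweeps aggregate
    without NaNs.
    """
    if min(tp, fp, fn) < 0:
        raise ParameterError("counts must be nonnegative")
    p_def = (tp + fp) > 0
    r_def = (tp + fn) > 0
    precision = tp / (tp + fp) if p_def else 0.0
    recall = tp / (tp + fn) if r_def else 0.0
    f = 2 * precision * recall / (precision + recall) if (precision + recall) > 0 else 0.0
    return EvalResult(
        tp=tp,
        fp=fp,
        fn=fn,
        precision=precision,
        recall=recall,
        f_measure=f,
        precision_defined=p_def,
        recall_defined=r_def,
        stratum=stratum,
    )


def sweep(
    trials: list[dict],
    grid: list[tuple[DescriptorConfig, ChannelScheme]],
    template: StrideTemplate,
    min_overlap: float = 0.5,
    smooth_window: int = 5,
) -> pd.DataFrame:
    """Evaluate every (descriptor, scheme) cell on every trial.

    Each trial is a dict with keys ``rec`` (ImuRecording), ``labels``
    (list of labeled stride intervals in seconds) and ``speed``.
    Returns a tidy frame: one row per (speed stratum x grid cell) plus
    an ``all`` stratum, with mean and standard deviation of F across
    recordings.  Cells that fail on a trial record the error and keep
    going.
    """
    rows = []
    for config, scheme in grid:
        per_trial = []
        for trial in trials:
            try:
                detected = segment(
                    trial["rec"], template, config, scheme, smooth_window=smooth_window
                )
                fs = trial["rec"].sample_rate
                det_s = restrict_to_span(
                    [(s.start / fs, s.end / fs) for s in detected], trial["labels"]
                )
                m = match_intervals(det_s, trial["labels"], min_overlap=min_overlap)
                res = metrics(m.tp, m.fp, m.fn)
                per_trial.append(
                    {
                        "speed": trial.get("speed", "all"),
                        "precision": res.precision,
                        "recall": res.recall,
                        "f": res.f_measure,
                        "error": "",
                    }
                )
            except Exception as exc:  # noqa: BLE001 - failed cells are data
                per_trial.append(
                    {"speed": trial.get("speed", "all"), "precision": np.nan,
                     "recall": np.nan, "f": np.nan, "error": str(exc)}
                )
        df = pd.DataFrame(per_trial)
        strata = [("all", df)] + [(sp, g) for sp, g in df.groupby("speed")]
        for speed, group in strata:
            ok = group[group["error"] == ""]
            rows.append(
                {
                    "descriptor": config.name,
                    "sensor": scheme.sensor,
                    "axes": "".join(scheme.axes),
                    "fused": scheme.fused,
                    "speed": speed,
                    "n_trials": len(group),
                    "n_failed": int((group["error"] != "").sum()),
                    "precision_mean": ok["precision"].mean() if len(ok) else np.nan,
                    "recall_mean": ok["recall"].mean() if len(ok) else np.nan,
                    "f_mean": ok["f"].mean() if len(ok) else np.nan,
                    "f_std": ok["f"].std(ddof=0) if len(ok) else np.nan,
                }
            )
    return pd.DataFrame(rows)


def format_markdown(table: pd.DataFrame) -> str:
    """Render a sweep result as a Markdown grid: descriptor/scheme rows,
    speed columns, cells formatted as ``F +- sd``."""
    table = table.copy()
    table["row"] = table["descriptor"] + " " + table["sensor"] + ":" + table["axes"]
    speeds = list(dict.fromkeys(table["speed"]))
    lines = ["| scheme | " + " | ".join(speeds) + " |",
             "|" + "---|" * (len(speeds) + 1)]
    for row_name, group in table.groupby("row", sort=False):
        cells = []
        for speed in speeds:
            sel = group[group["speed"] == speed]
            if len(sel) and np.isfinite(sel["f_mean"].iloc[0]):
                cells.append(f"{sel['f_mean'].iloc[0]:.3f} ± {sel['f_std'].iloc[0]:.3f}")
            else:
                cells.append("—")
        lines.append(f"| {row_name} | " + " | ".join(cells) + " |")
    return "\n".join(lines)
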