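"""Validation machinery: detection scores, event errors, agreement, sweeps.

Detection scoring follows the event-counting convention in which true
negatives are zero (the detectors only ever claim that an event happened):

    accuracy    = (TP + TN) / total,  total = TP + FP + FN,  TN = 0
    sensitivity = TP / (TP + FN)
    precision   = TP / (TP + FP)

Event timing errors are signed (detected − true, negative = early) and are
summarized as mean ± sample standard deviation in ms. Phase-duration errors
are absolute (ms) and relative (% of the true duration). Bland–Altman
agreement gives the bias and the 95% limits of agreement. The threshold
sweep re-runs an analysis closure with every threshold perturbed by ±10%
(or any fraction) and tabulates the outcome changes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, fields
from typing import Callable

import numpy as np
import pandas as pd

from .errors import InvalidInputError, InvalidParameterError
from .thresholds import ThresholdSet

__all__ = [
    "DetectionScore",
    "ErrorStats",
    "match_events",
    "detection_scores",
    "event_error_stats",
    "phase_duration_error",
    "phase_duration_errors",
    "bland_altman",
    "threshold_sensitivity",
]


@dataclass(frozen=True)
class DetectionScore:
    tp: int
    fp: int
    fn: int
    tn: int = 0

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise InvalidInputError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def sensitivity(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else 1.0

    @property
    def precision(self) -> float:
        d = self.tp + self.fp
        # undefined when nothing is detected; 0 unless vacuously perfect
        if d == 0:
            return 1.0 if self.fn == 0 else 0.0
        return self.tp / d

    @property
    def accuracy(self) -> float:
        if self.total == 0:
            return 1.0
        return (self.tp + self.tn) / self.total

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
            "total": self.total, "sensitivity": self.sensitivity,
            "precision": self.precision, "accuracy": self.accuracy,
        }


@dataclass(frozen=True)
class ErrorStats:
    """Mean and sample standard deviation of signed event errors (ms)."""

    mean_ms: float
    sd_ms: float
    n: int

    def __post_init__(self):
        if self.n < 1:
            raise InvalidInputError("error statistics need at least one pair")
        if self.sd_ms < 0:
            raise InvalidInputError("standard deviation must be nonnegative")


def match_events(
    detected: list[float], truth: list[float], tolerance: float
) -> tuple[list[tuple[float, float]], list[float], list[float]]:
    """Greedy one-to-one matching in time order within ``tolerance``.

    Returns (matched pairs as (detected, true), unmatched detected,
    unmatched truth).
    """
    if tolerance <= 0:
        raise InvalidParameterError("tolerance must be positive")
    det = sorted(detected)
    tru = sorted(truth)
    pairs: list[tuple[float, float]] = []
    used = [False] * len(det)
    for t in tru:
        best, best_d = None, tolerance
        for i, d in enumerate(det):
            if used[i]:
                continue
            dd = abs(d - t)
            if dd <= best_d:
                best, best_d = i, dd
            if d - t > tolerance:
                break
        if best is not None:
            used[best] = True
            pairs.append((det[best], t))
    fp = [d for d, u in zip(det, used) if not u]
    fn = [t for t in tru if t not in [p[1] for p in pairs]]
    return pairs, fp, fn


def detection_scores(
    detected: list[float], truth: list[float], tolerance: float = 0.3
) -> DetectionScore:
    """Score detected event times against true times within ``tolerance`` s."""
    pairs, fp, fn = match_events(detected, truth, tolerance)
    return DetectionScore(tp=len(pairs), fp=len(fp), fn=len(fn))


def event_error_stats(pairs: list[tuple[float, float]]) -> ErrorStats:
    """Signed errors (detected − true) of matched pairs, in ms."""
    if not pairs:
        raise InvalidInputError("no matched pairs")
    e = np.array([(d - t) * 1000.0 for d, t in pairs])
    sd = float(np.std(e, ddof=1)) if e.size > 1 else 0.0
    return ErrorStats(mean_ms=float(np.mean(e)), sd_ms=sd, n=e.size)


def phase_duration_error(d_imu_ms: float, d_true_ms: float) -> tuple[float, float]:
    """(absolute error in ms, relative error in %) of one phase duration."""
    err = d_imu_ms - d_true_ms
    if d_true_ms == 0:
        raise InvalidInputError("relative error undefined: true duration is zero")
    return err, err / d_true_ms * 100.0


def phase_duration_errors(
    durations_imu_ms: dict[str, float], durations_true_ms: dict[str, float]
) -> dict[str, tuple[float, float]]:
    """Per-phase (error ms, relative %) for matching phase names."""
    out = {}
    for name, d_true in durations_true_ms.items():
        if name not in durations_imu_ms:
            continue
        out[name] = phase_duration_error(durations_imu_ms[name], d_true)
    return out


def bland_altman(a: list[float], b: list[float]) -> tuple[float, float, float]:
    """(bias, lower LoA, upper LoA): bias ± 1.96 × sd of the differences."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise InvalidInputError("paired series must have equal length")
    if a.size < 2:
        raise InvalidInputError("agreement needs at least 2 pairs")
    d = a - b
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def threshold_sensitivity(
    pipeline: Callable[[ThresholdSet], dict[str, float]],
    th: ThresholdSet | None = None,
    pct: float = 0.1,
    names: list[str] | None = None,
) -> pd.DataFrame:
    """Rerun ``pipeline`` with every threshold perturbed by ±``pct``.

    ``pipeline`` maps a ThresholdSet to a flat dict of numeric outcomes.
    The table has one row per (threshold, direction) with the perturbed
    value, a status, the maximal absolute outcome change and per-outcome
    deltas. A pipeline failure under a perturbation is recorded in the row,
    not raised.
    """
    if not 0 < pct < 1:
        raise InvalidParameterError("pct must lie in (0, 1)")
    th = th or ThresholdSet()
    if names is None:
        names = [f.name for f in fields(ThresholdSet)
                 if isinstance(getattr(th, f.name), float)]
    baseline = pipeline(th)
    rows = []
    for name in names:
        value = getattr(th, name)
        for direction, factor in (("-", 1 - pct), ("+", 1 + pct)):
            perturbed = dataclasses.replace(th, **{name: value * factor})
            row = {"threshold": name, "direction": direction,
                   "value": value * factor, "status": "ok",
                   "max_abs_delta": 0.0}
            try:
                result = pipeline(perturbed)
            except Exception as exc:  # noqa: BLE001 — recorded, not raised
                row["status"] = f"error: {type(exc).__name__}"
                row["max_abs_delta"] = float("nan")
                rows.append(row)
                continue
            deltas = {k: result.get(k, float("nan")) - baseline[k]
                      for k in baseline}
            row["max_abs_delta"] = float(np.nanmax(
                [abs(v) for v in deltas.values()] or [0.0]
            ))
            for k, v in deltas.items():
                row[f"delta_{k}"] = v
            rows.append(row)
    return pd.DataFrame(rows)
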