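"""Macro-level analysis: swimming bouts, laps (approximate turns), technique.

Bout boundaries are posture changes between upright rest and horizontal
swimming, visible as sustained level shifts of the longitudinal acceleration;
laps are separated by the turn, whose rapid dynamics produce the largest
acceleration peaks of the bout; the swimming technique is identified from a
short window of upper-limb cycles using principal axes of rotation (pitching
vs rolling), the gravity sign on the anterior-posterior axis (supine
backstroke), spectral amplitude (butterfly vs breaststroke) and wrist
|Acc| statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError, InvalidParameterError
from .primitives import (
    TimeSeries,
    amplitude_spectrum,
    detect_extrema,
    detect_sharp_change,
    envelope,
    lowpass,
    moving_average,
    principal_components,
)
from .session import SensorLocation, SessionRecording, Technique, TurnType
from .thresholds import ThresholdSet

__all__ = [
    "BoutInterval",
    "LapContext",
    "detect_bouts",
    "detect_approximate_turn",
    "identify_technique",
    "make_laps",
    "default_turn_type",
]

MACRO_LOCATIONS = (SensorLocation.SA, SensorLocation.HE,
                   SensorLocation.RS, SensorLocation.RW)


@dataclass(frozen=True)
class BoutInterval:
    """Approximate start/end of one swimming bout."""

    approx_start: float
    approx_end: float
    source_location: SensorLocation

    def __post_init__(self):
        if not self.approx_start < self.approx_end:
            raise InvalidInputError("bout start must precede end")

    @property
    def duration(self) -> float:
        return self.approx_end - self.approx_start


@dataclass
class LapContext:
    """One lap inside a bout: anchors, index, and (optional) labels."""

    bout: BoutInterval
    lap_index: int
    start_anchor: float          # bout start or the preceding approximate turn
    end_anchor: float            # this lap's approximate turn, or bout end
    is_final: bool               # last lap of the bout (ends at the wall)
    technique: Technique | None = None
    turn_type: TurnType | None = None

    @property
    def approximate_turn(self) -> float | None:
        return None if self.is_final else self.end_anchor

    @property
    def span(self) -> tuple[float, float]:
        return (self.start_anchor, self.end_anchor)


def default_turn_type(technique: Technique) -> TurnType:
    if technique in (Technique.FRONT_CRAWL, Technique.BACKSTROKE):
        return TurnType.TUMBLE
    return TurnType.SIMPLE


def _require_macro_location(location: SensorLocation) -> SensorLocation:
    location = SensorLocation(location)
    if location not in MACRO_LOCATIONS:
        raise InvalidParameterError(
            f"macro analysis supports {[l.value for l in MACRO_LOCATIONS]}, "
            f"not {location.value}"
        )
    return location


# ---------------------------------------------------------------------------
# swimming bout detection
# ---------------------------------------------------------------------------


def detect_bouts(
    session: SessionRecording,
    location: SensorLocation,
    th: ThresholdSet | None = None,
    method: str | None = None,
) -> list[BoutInterval]:
    """Detect swimming bouts at one sensor location.

    SA/HE/RS: sharp-change detection on the longitudinal acceleration — the
    posture transition produces a derivative trough at the approximate start
    and a derivative peak at the approximate end; falls and rises are paired
    in temporal order. RW: intervals where the |Acc| envelope exceeds the
    wrist bout threshold (cycling of the upper limbs), with nearby
    sub-intervals merged across the mid-bout turn.

    ``method`` overrides the per-location default (``"posture"`` or
    ``"envelope"``): wrist phase detection needs posture-anchored bouts
    because the envelope interval only starts with the first arm cycles.
    """
    th = th or ThresholdSet()
    location = _require_macro_location(location)
    session.require_anatomical()
    rec = session[location]
    if method is None:
        method = "envelope" if location == SensorLocation.RW else "posture"
    if method not in ("posture", "envelope"):
        raise InvalidParameterError("method must be 'posture' or 'envelope'")

    if method == "envelope":
        env = envelope(rec.norm("acc"), th.bout_envelope_window)
        above = env.values > th.TH_BW
        edges = np.flatnonzero(np.diff(above.astype(int)))
        starts = list(edges[~above[edges]] + 1)
        ends = list(edges[above[edges]] + 1)
        if above[0]:
            starts.insert(0, 0)
        if above[-1]:
            ends.append(len(env) - 1)
        intervals = [(env.time_of(a), env.time_of(b))
                     for a, b in zip(starts, ends)]
        merged: list[list[float]] = []
        for a, b in intervals:
            if merged and a - merged[-1][1] <= th.bout_merge_gap:
                merged[-1][1] = b
            else:
                merged.append([a, b])
        return [
            BoutInterval(a, b, location)
            for a, b in merged
            if b - a >= th.min_bout_duration
        ]

    events = detect_sharp_change(
        rec.channel("acc_y"), th.fraction_B, fc=th.bout_fc, order=th.filter_order
    )
    # a genuine bout edge separates a sustained upright level (Acc_y ≈ 1 g)
    # from a sustained horizontal level (≈ 0 g); derivative blips from swim
    # dynamics fail this check and are discarded
    lp = lowpass(rec.channel("acc_y"), th.bout_fc, th.filter_order)

    def _level_near(t0: float, after: bool) -> float:
        lo, hi = (t0 + 1.0, t0 + 4.0) if after else (t0 - 4.0, t0 - 1.0)
        lo = max(lo, lp.t0)
        hi = min(hi, lp.t_end)
        if hi <= lo:
            return float(lp.values[lp.index_of(t0)])
        return float(np.mean(lp.crop(lo, hi).values))

    mid = 0.5  # g, halfway between upright and horizontal
    events = [
        e for e in events
        if (e.polarity == "fall"
            and _level_near(e.time, False) > mid > _level_near(e.time, True))
        or (e.polarity == "rise"
            and _level_near(e.time, False) < mid < _level_near(e.time, True))
    ]
    # residue can still split one edge into nearby same-polarity events;
    # keep the strongest within 5 s
    merged: list = []
    for e in events:
        if (merged and e.polarity == merged[-1].polarity
                and e.time - merged[-1].time < 5.0):
            if abs(e.amplitude) > abs(merged[-1].amplitude):
                merged[-1] = e
        else:
            merged.append(e)
    events = merged
    bouts: list[BoutInterval] = []
    open_start: float | None = None
    for e in events:
        if e.polarity == "fall" and open_start is None:
            open_start = e.time
        elif e.polarity == "rise" and open_start is not None:
            if e.time - open_start >= th.min_bout_duration:
                bouts.append(BoutInterval(open_start, e.time, location))
            open_start = None
    return bouts


# ---------------------------------------------------------------------------
# lap detection (approximate turns)
# ---------------------------------------------------------------------------


def _cluster_candidates(
    cands: list[tuple[float, float]], merge_window: float, min_separation: float,
    keep: str = "strongest",
) -> list[float]:
    """Merge candidate (time, score) pairs, then enforce a minimal separation."""
    if not cands:
        return []
    cands = sorted(cands)
    clusters: list[list[tuple[float, float]]] = [[cands[0]]]
    for c in cands[1:]:
        if c[0] - clusters[-1][-1][0] <= merge_window:
            clusters[-1].append(c)
        else:
            clusters.append([c])
    if keep == "earliest":
        picks = [cl[0] for cl in clusters]
    else:
        picks = [max(cl, key=lambda c: c[1]) for cl in clusters]
    result: list[tuple[float, float]] = []
    for t, s in picks:
        if result and t - result[-1][0] < min_separation:
            if s > result[-1][1]:
                result[-1] = (t, s)
        else:
            result.append((t, s))
    return [t for t, _ in result]


def detect_approximate_turn(
    session: SessionRecording,
    bout: BoutInterval,
    location: SensorLocation,
    th: ThresholdSet | None = None,
) -> list[float]:
    """Approximate turn times inside one bout (empty if the bout is one lap).

    SA/HE: the turn carries the highest peaks of the bout on the forward
    acceleration and on |Acc_y,z|; accepted peaks exceed a fraction of the
    bout maximum and are separated by at least the minimal lap time.
    RS: threshold peaks on Acc_z or Gyr_z against the highest peak of a 2-s
    reference window during swimming (the earlier channel wins). RW: the
    wrist rotation rate drops below TH_LW during the turn; the midpoint of
    each drop is reported.
    """
    th = th or ThresholdSet()
    location = _require_macro_location(location)
    session.require_anatomical()
    if bout.duration < th.min_lap_time:
        return []
    rec = session[location]
    # a turn separates two laps, so it cannot sit within half a lap time of
    # either bout edge; this also excludes the final wall-touch transient
    margin = th.min_lap_time / 2
    lo, hi = bout.approx_start + margin, bout.approx_end - margin
    if hi <= lo:
        return []

    if location in (SensorLocation.SA, SensorLocation.HE):
        cands: list[tuple[float, float]] = []
        for series in (rec.channel("acc_x"), rec.norm("acc", "yz")):
            s = lowpass(series, th.filter_fc, th.filter_order).crop(lo, hi)
            med = float(np.median(s.values))
            mx = float(np.max(s.values)) - med
            # the 60%-of-maximum rule is relative; the absolute floor keeps
            # it from firing on ordinary swim dynamics in turn-less bouts
            level = med + max(th.turn_peak_fraction * mx, th.turn_min_amp)
            if mx <= 0:
                continue
            for e in detect_extrema(s, level, "peak"):
                cands.append((e.time, (e.amplitude - med) / mx))
        return _cluster_candidates(cands, 2.0, th.min_lap_time)

    if location == SensorLocation.RS:
        gyr_norm = lowpass(rec.norm("gyr"), th.filter_fc, th.filter_order).crop(
            bout.approx_start, bout.approx_end
        )
        # 2-s reference window of maximal |Gyr| RMS, taken as swimming phase;
        # spiky windows (turn/push transients) are excluded by a crest-factor
        # gate so the reference reflects sustained kicking
        w = max(2, int(round(th.rs_turn_ref_window * gyr_norm.fs)))
        stride = max(1, w // 8)
        best, best_rms = None, -1.0
        for i in range(0, len(gyr_norm) - w, stride):
            seg = gyr_norm.values[i : i + w]
            rms = float(np.sqrt(np.mean(seg**2)))
            if rms <= 0 or float(np.max(seg)) / rms > 2.0:
                continue
            if rms > best_rms:
                best, best_rms = i, rms
        j = best if best is not None else int(
            np.argmax(np.convolve(gyr_norm.values**2, np.ones(w) / w, "valid"))
        )
        ref_lo, ref_hi = gyr_norm.time_of(j), gyr_norm.time_of(j + w - 1)
        cands = []
        floors = {"gyr_z": 100.0, "acc_z": 0.5}
        for name, floor in floors.items():
            full = lowpass(rec.channel(name), th.filter_fc,
                           th.filter_order).crop(bout.approx_start,
                                                 bout.approx_end)
            th_ls = float(np.max(full.crop(ref_lo, ref_hi).values))
            bout_max = float(np.max(full.values))
            level = max(1.2 * th_ls, 0.6 * bout_max, floor)
            s = full.crop(lo, hi)
            for e in detect_extrema(s, level, "peak"):
                cands.append((e.time, e.amplitude / max(bout_max, 1e-9)))
        return _cluster_candidates(cands, 2.0, th.min_lap_time, keep="earliest")

    # RW: rotation-rate drop during the turn
    g = lowpass(rec.norm("gyr"), th.filter_fc, th.filter_order).crop(
        bout.approx_start, bout.approx_end
    )
    below = g.values < th.TH_LW
    edges = np.flatnonzero(np.diff(below.astype(int)))
    starts = edges[~below[edges]] + 1
    ends = edges[below[edges]] + 1
    # drops touching the bout boundaries (start-up, final stop at the wall)
    # are not turns; only fully interior drops count
    turns = []
    for a in starts:
        later = ends[ends > a]
        if later.size == 0:
            continue
        b = int(later[0])
        dur = (b - a) / g.fs
        if th.rw_turn_min_drop <= dur <= th.rw_turn_max_drop:
            turns.append(g.time_of((int(a) + b) // 2))
    return turns


def make_laps(
    bout: BoutInterval,
    turns: list[float],
    technique: Technique | None = None,
    turn_type: TurnType | None = None,
) -> list[LapContext]:
    """Split a bout into lap contexts at its approximate turns."""
    bounds = [bout.approx_start, *sorted(turns), bout.approx_end]
    laps = []
    for i, (a, b) in enumerate(zip(bounds, bounds[1:])):
        laps.append(
            LapContext(
                bout=bout, lap_index=i, start_anchor=a, end_anchor=b,
                is_final=(i == len(bounds) - 2),
                technique=technique, turn_type=turn_type,
            )
        )
    return laps


# ---------------------------------------------------------------------------
# swimming technique identification
# ---------------------------------------------------------------------------


def _technique_window(
    session: SessionRecording,
    lap: LapContext,
    location: SensorLocation,
    th: ThresholdSet,
) -> tuple[float, float]:
    """Window of upper-limb cycles inside the swimming phase of the lap.

    The swimming phase occupies the later part of a lap (after push-off,
    glide and strokes preparation), so the window sits at 65% of the lap
    span for trunk/head/shank. For the wrist, the |Acc| envelope localizes
    the cycling directly and the window is centered on it.
    """
    a, b = lap.span
    span = b - a
    if span < th.technique_window:
        raise InvalidInputError(
            f"lap span {span:.1f} s shorter than the {th.technique_window} s "
            "technique window"
        )
    if location == SensorLocation.RW:
        rec = session[location]
        env = envelope(rec.norm("acc"), th.bout_envelope_window).crop(a, b)
        above = np.flatnonzero(env.values > th.TH_BW)
        if above.size:
            center = env.time_of(int(np.median(above)))
        else:
            center = a + 0.65 * span
    else:
        center = a + 0.65 * span
    half = th.technique_window / 2
    center = min(max(center, a + half), b - half)
    return center - half, center + half


def identify_technique(
    session: SessionRecording,
    lap: LapContext,
    location: SensorLocation,
    th: ThresholdSet | None = None,
) -> Technique:
    """Identify the lap's swimming technique at one sensor location."""
    th = th or ThresholdSet()
    location = _require_macro_location(location)
    session.require_anatomical()
    rec = session[location]
    lo, hi = _technique_window(session, lap, location, th)

    def chan(name: str) -> TimeSeries:
        return lowpass(rec.channel(name), th.filter_fc, th.filter_order).crop(lo, hi)

    if location in (SensorLocation.SA, SensorLocation.HE):
        gyr = np.column_stack([chan(f"gyr_{ax}").values for ax in "xyz"])
        pc1 = principal_components(gyr)[0][0]
        rolling = abs(pc1[1]) > abs(pc1[2])  # roll (y) vs pitch (z) dominance
        if rolling:
            mean_fwd = float(np.mean(chan("acc_x").values))
            return Technique.BACKSTROKE if mean_fwd > 0 else Technique.FRONT_CRAWL
        if location == SensorLocation.SA:
            spec_sig = chan("acc_x")
            style_th = th.TH_StyleSA
        else:
            spec_sig = lowpass(rec.norm("acc", "xy"), th.filter_fc,
                               th.filter_order).crop(lo, hi)
            style_th = th.TH_StyleHE
        freqs, amp = amplitude_spectrum(spec_sig)
        band = (freqs >= th.style_fmin) & (freqs <= th.style_fmax)
        peak = float(np.max(amp[band]))
        return Technique.BUTTERFLY if peak >= style_th else Technique.BREASTSTROKE

    if location == SensorLocation.RS:
        if float(np.mean(chan("acc_x").values)) > 0:
            return Technique.BACKSTROKE
        gyr = np.column_stack([chan(f"gyr_{ax}").values for ax in "xyz"])
        pc1 = principal_components(gyr)[0][0]
        if int(np.argmax(np.abs(pc1))) == 0:  # mediolateral screw-kick axis
            return Technique.BREASTSTROKE
        roll = float(np.var(chan("gyr_y").values))
        pitch = float(np.var(chan("gyr_z").values))
        ratio = roll / max(pitch, 1e-12)
        return (Technique.FRONT_CRAWL if ratio >= th.rs_roll_ratio
                else Technique.BUTTERFLY)

    # RW
    acc = np.column_stack([chan(f"acc_{ax}").values for ax in "xyz"])
    pc1 = principal_components(acc)[0][0]
    if int(np.argmax(np.abs(pc1))) == 0:  # anterior-posterior dominance, supine
        return Technique.BACKSTROKE
    norm = rec.norm("acc").crop(lo, hi)
    if float(np.mean(norm.values)) > th.TH_StyleWmean:
        return Technique.BUTTERFLY
    smooth = moving_average(norm, th.rw_var_smooth)
    if float(np.var(smooth.values)) < th.TH_StyleWvar:
        return Technique.FRONT_CRAWL
    return Technique.BREASTSTROKE
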