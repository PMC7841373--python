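"""Micro-level analysis: the five phase-begin events of each lap.

Each lap is segmented into wall push-off, glide, strokes preparation,
swimming and turn. The detectors are anchored on the macro outputs
(approximate start, approximate turn, approximate end) and chain forward:
Push_B is searched near the lap's start anchor, Glid_B after Push_B, and so
on. Rules are specific to sensor location and, where the motion differs, to
technique and turn type.

All detected events are times in seconds from the start of the recording.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DetectionError, OrderingError
from .macro import LapContext, default_turn_type, identify_technique
from .primitives import (
    TimeSeries,
    derivative,
    detect_extrema,
    emd,
    instantaneous_energy,
    lowpass,
)
from .session import SensorLocation, SessionRecording, Technique, TurnType
from .thresholds import ThresholdSet

__all__ = [
    "PhaseEvents",
    "LapSegmentation",
    "detect_push_begin",
    "detect_glide_begin",
    "detect_stroke_prep_begin",
    "detect_swim_begin",
    "detect_turn_begin",
    "segment_lap",
]

MICRO_LOCATIONS = (SensorLocation.SA, SensorLocation.HE,
                   SensorLocation.RS, SensorLocation.RW)

_EVENT_NAMES = ("Push_B", "Glid_B", "StPr_B", "Swim_B", "Turn_B")


@dataclass(frozen=True)
class PhaseEvents:
    """The five phase-begin times of one lap (strictly increasing)."""

    push_b: float
    glid_b: float
    stpr_b: float
    swim_b: float
    turn_b: float
    location: SensorLocation
    technique: Technique
    turn_type: TurnType

    def __post_init__(self):
        times = (self.push_b, self.glid_b, self.stpr_b, self.swim_b, self.turn_b)
        for a, b, na, nb in zip(times, times[1:], _EVENT_NAMES, _EVENT_NAMES[1:]):
            if not a < b:
                raise OrderingError(
                    f"{na} ({a:.3f} s) must precede {nb} ({b:.3f} s) "
                    f"[{self.location.value}]"
                )

    def times(self) -> tuple[float, float, float, float, float]:
        return (self.push_b, self.glid_b, self.stpr_b, self.swim_b, self.turn_b)


@dataclass(frozen=True)
class LapSegmentation:
    """Phase events plus the derived phase durations in ms.

    ΔPush = Glid_B − Push_B and so on; ΔTurn ends at the next lap's Push_B,
    or at the approximate end of the bout for the last lap.
    """

    events: PhaseEvents
    d_push_ms: float
    d_glid_ms: float
    d_stpr_ms: float
    d_swim_ms: float
    d_turn_ms: float

    def durations_ms(self) -> dict[str, float]:
        return {
            "push": self.d_push_ms,
            "glid": self.d_glid_ms,
            "stpr": self.d_stpr_ms,
            "swim": self.d_swim_ms,
            "turn": self.d_turn_ms,
        }


# ---------------------------------------------------------------------------
# channel helpers
# ---------------------------------------------------------------------------


def _lp(session: SessionRecording, loc: SensorLocation, name: str,
        th: ThresholdSet) -> TimeSeries:
    return lowpass(session[loc].channel(name), th.filter_fc, th.filter_order)


def _lp_emd(session: SessionRecording, loc: SensorLocation, name: str,
            th: ThresholdSet) -> TimeSeries:
    """Stronger low-pass ahead of EMD: keeps the kick mode as the first
    intrinsic mode and the stroke-rate undulation as the second."""
    return lowpass(session[loc].channel(name), th.emd_fc, th.filter_order)


def _lp_norm(session: SessionRecording, loc: SensorLocation, kind: str,
             axes: str, th: ThresholdSet) -> TimeSeries:
    return lowpass(session[loc].norm(kind, axes), th.filter_fc, th.filter_order)


def _detrended(session: SessionRecording, loc: SensorLocation, name: str,
               th: ThresholdSet) -> TimeSeries:
    """Band signal with the slow posture component removed.

    Near a bout boundary the upright gravity level (≈1 g) would otherwise
    dwarf the push-off complex on the longitudinal axis. The trend filter is
    fast enough (~0.5 Hz) to follow the posture change closely, so its
    residual around the transition stays well below the push-off amplitude.
    """
    fast = _lp(session, loc, name, th)
    slow = lowpass(session[loc].channel(name), th.push_detrend_fc,
                   th.filter_order)
    return fast.map(fast.values - slow.values)


def _crop(ts: TimeSeries, lo: float, hi: float) -> TimeSeries:
    return ts.crop(max(lo, ts.t0), min(hi, ts.t_end))


def _fail(event: str, loc: SensorLocation, why: str) -> DetectionError:
    return DetectionError(f"{event} not found on {loc.value}: {why}",
                          event=event, location=loc.value)


def _first_peak(ts: TimeSeries, level: float, event: str,
                loc: SensorLocation):
    ev = detect_extrema(ts, level, "peak")
    if not ev:
        raise _fail(event, loc, f"no peak above {level:.3g} in window "
                                f"[{ts.t0:.2f}, {ts.t_end:.2f}] s")
    return ev[0]


def _largest_peak(ts: TimeSeries, level: float, event: str,
                  loc: SensorLocation):
    ev = detect_extrema(ts, level, "peak")
    if not ev:
        raise _fail(event, loc, f"no peak above {level:.3g} in window "
                                f"[{ts.t0:.2f}, {ts.t_end:.2f}] s")
    return max(ev, key=lambda e: e.amplitude)


def _last_local_min_before(ts: TimeSeries, t_peak: float) -> float:
    """Time of the last local minimum strictly before ``t_peak``."""
    i = ts.index_of(t_peak)
    v = ts.values[: i + 1]
    mins = np.flatnonzero((v[1:-1] < v[:-2]) & (v[1:-1] < v[2:])) + 1
    if mins.size == 0:
        return ts.t0
    return ts.time_of(int(mins[-1]))


def _second_imf(sig: TimeSeries, event: str, loc: SensorLocation) -> TimeSeries:
    """Second intrinsic mode: the slow (stroke-rate) component below the kicks."""
    imfs, _ = emd(sig, max_imfs=5)
    if len(imfs) < 2:
        raise _fail(event, loc, "decomposition yielded fewer than 2 intrinsic modes")
    return imfs[1]


def _energy_cross(sig: TimeSeries, level: float, direction: str,
                  event: str, loc: SensorLocation, guard: float = 0.1) -> float:
    """First instantaneous-energy crossing of ``level`` (up or down)."""
    en = instantaneous_energy(sig)
    i0 = en.index_of(en.t0 + guard)  # skip analytic-signal edge effects
    i1 = max(i0 + 2, en.index_of(en.t_end - guard))
    v = en.values[:i1]
    if direction == "up":
        idx = np.flatnonzero((v[i0 + 1 :] >= level) & (v[i0:-1] < level))
    else:
        peak = i0 + int(np.argmax(v[i0:]))
        if v[peak] < level:
            raise _fail(event, loc, "energy never exceeded the drop threshold")
        seg = v[peak:]
        idx = np.flatnonzero((seg[1:] < level) & (seg[:-1] >= level))
        if idx.size:
            return en.time_of(peak + int(idx[0]) + 1)
        raise _fail(event, loc, "energy never dropped below the threshold")
    if idx.size == 0:
        raise _fail(event, loc, f"energy never crossed {level:.3g}")
    return en.time_of(i0 + int(idx[0]) + 1)


# ---------------------------------------------------------------------------
# detectors
# ---------------------------------------------------------------------------


def _push_window(lap: LapContext, th: ThresholdSet) -> tuple[float, float]:
    a = lap.start_anchor
    if lap.lap_index == 0:
        return a - th.push_search_pre, a + th.push_search_post
    # anchored at a turn: the turn spike itself sits at the anchor and is
    # excluded by starting the window shortly after it
    return a + 0.3, a + th.push_search_post


def detect_push_begin(
    session: SessionRecording,
    lap: LapContext,
    location: SensorLocation,
    th: ThresholdSet | None = None,
) -> float:
    """Beginning of wall push-off: forward acceleration onset near the anchor."""
    th = th or ThresholdSet()
    location = SensorLocation(location)
    session.require_anatomical()
    lo, hi = _push_window(lap, th)
    tech = lap.technique

    if location == SensorLocation.SA:
        sig = _crop(_detrended(session, location, "acc_y", th), lo, hi)
        peak = _largest_peak(sig, th.push_min_peak, "Push_B", location)
        if tech == Technique.BACKSTROKE:
            return peak.time
        # concavity change: last second-derivative zero crossing before the
        # peak; the signal is smoothed further so second differencing does
        # not amplify sample noise into spurious sign flips
        smooth = lowpass(sig, min(4.0, th.filter_fc), th.filter_order)
        d2 = derivative(derivative(smooth))
        i = sig.index_of(peak.time)
        sign = np.sign(d2.values[:i])
        flips = np.flatnonzero(np.diff(sign) != 0)
        if flips.size == 0:
            raise _fail("Push_B", location, "no concavity change before the push peak")
        return sig.time_of(int(flips[-1]) + 1)

    if location == SensorLocation.HE:
        if tech == Technique.BACKSTROKE:
            sig = _crop(_detrended(session, location, "acc_y", th), lo, hi)
            return _largest_peak(sig, th.push_min_peak, "Push_B", location).time
        sig = _crop(_lp_norm(session, location, "acc", "xyz", th), lo, hi)
        return _largest_peak(sig, 1.0 + th.push_min_peak, "Push_B", location).time

    if location == SensorLocation.RW:
        sig = _crop(_detrended(session, location, "acc_y", th), lo, hi)
        ev = detect_extrema(sig, -th.push_min_peak, "trough")
        if not ev:
            raise _fail("Push_B", location, "no downward-hand trough in window")
        return min(ev, key=lambda e: e.amplitude).time

    if location == SensorLocation.RS:
        sig = _crop(_lp_norm(session, location, "gyr", "xyz", th), lo, hi)
        level = max(th.push_rs_gyr, 0.5 * float(np.max(sig.values)))
        return _first_peak(sig, level, "Push_B", location).time

    raise _fail("Push_B", location, "unsupported location")


def detect_glide_begin(
    session: SessionRecording,
    lap: LapContext,
    location: SensorLocation,
    th: ThresholdSet | None = None,
    push_b: float | None = None,
) -> float:
    """Beginning of glide: the body settles, no propulsion."""
    th = th or ThresholdSet()
    location = SensorLocation(location)
    if push_b is None:
        push_b = detect_push_begin(session, lap, location, th)
    lo, hi = push_b + th.glide_min_after_push, push_b + th.glide_search

    if location in (SensorLocation.SA, SensorLocation.HE):
        sig = _crop(_lp(session, location, "acc_y", th), lo, hi)
        ev = detect_extrema(sig, th.glide_trough_th, "trough")
        if not ev:
            raise _fail("Glid_B", location, "no post-push trough on Acc_y")
        return ev[0].time

    if location == SensorLocation.RS:
        sig = _crop(_lp_norm(session, location, "gyr", "xyz", th), lo, hi)
        return _first_peak(sig, th.glide_rs_gyr, "Glid_B", location).time

    if location == SensorLocation.RW:
        sig = _crop(_detrended(session, location, "acc_y", th), lo, hi)
        ev = detect_extrema(sig, th.glide_rw_peak, "peak",
                            min_prominence=th.glide_rw_prom)
        if not ev:
            raise _fail("Glid_B", location, "no prominent Acc_y peak after push")
        return ev[0].time

    raise _fail("Glid_B", location, "unsupported location")


def detect_stroke_prep_begin(
    session: SessionRecording,
    lap: LapContext,
    location: SensorLocation,
    th: ThresholdSet | None = None,
    glid_b: float | None = None,
) -> float:
    """Beginning of strokes preparation: first underwater lower-limb action."""
    th = th or ThresholdSet()
    location = SensorLocation(location)
    if glid_b is None:
        glid_b = detect_glide_begin(session, lap, location, th)
    lo, hi = glid_b + 0.1, glid_b + th.stpr_search
    tech = lap.technique

    if location == SensorLocation.SA:
        ax = _crop(_lp(session, location, "acc_x", th), lo, hi)
        mag = ax.map(np.abs(ax.values))
        half = max(1, int(round(th.spsa_var_window * ax.fs / 2)))
        for e in detect_extrema(mag, th.TH_SPSA, "peak"):
            i = ax.index_of(e.time)
            seg = ax.values[max(0, i - half) : i + half]
            if float(np.var(seg)) >= th.TH_SPSAvar:
                return e.time
        raise _fail("StPr_B", location,
                    f"no |Acc_x| peak above {th.TH_SPSA} g with variance gate")

    if location == SensorLocation.HE:
        sig = _crop(_lp(session, location, "acc_y", th), lo, hi)
        ev = detect_extrema(sig, th.TH_SPHE, "trough",
                            min_prominence=th.TH_SPHEprom)
        if not ev:
            raise _fail("StPr_B", location,
                        f"no Acc_y trough below {th.TH_SPHE} g")
        return ev[0].time

    if location == SensorLocation.RW:
        norm = _crop(_lp_norm(session, location, "acc", "xyz", th), lo, hi)
        offset = norm.map(norm.values - 1.0)  # trough criterion about 1 g
        ev = detect_extrema(offset, th.TH_SPRW, "trough")
        if not ev:
            raise _fail("StPr_B", location,
                        f"|Acc| never dropped to {1.0 + th.TH_SPRW:.2f} g")
        return ev[0].time

    if location == SensorLocation.RS:
        if tech == Technique.BACKSTROKE:
            sig = _crop(_lp(session, location, "acc_y", th), lo, hi)
            return _first_peak(sig, th.stpr_bas_rs, "StPr_B", location).time
        ax = _crop(_lp(session, location, "acc_x", th), lo, hi)
        mag = ax.map(np.abs(ax.values))
        peak = _first_peak(mag, th.TH_SPRS, "StPr_B", location)
        norm = _crop(_lp_norm(session, location, "acc", "xyz", th), lo, hi)
        i = norm.index_of(peak.time)
        v = norm.values
        crossings = np.flatnonzero(
            np.sign(v[i + 1 :] - 1.0) != np.sign(v[i:-1] - 1.0)
        )
        if crossings.size == 0:
            raise _fail("StPr_B", location, "|Acc| never crossed 1 g after the kick")
        return norm.time_of(i + int(crossings[0]) + 1)

    raise _fail("StPr_B", location, "unsupported location")


def _wrist_cycle_start(sig: TimeSeries, th: ThresholdSet, event: str,
                       loc: SensorLocation) -> float:
    """Trough immediately before the first cycle peak.

    The window median (gravity offset on the chosen axis) is removed first so
    the fraction-of-maximum peak criterion applies to the cycle dynamics.
    """
    sig = sig.map(sig.values - float(np.median(sig.values)))
    m = float(np.max(sig.values))
    peak = _first_peak(sig, th.swim_wrist_peak_fraction * m, event, loc)
    return _last_local_min_before(sig, peak.time)


def detect_swim_begin(
    session: SessionRecording,
    lap: LapContext,
    location: SensorLocation,
    th: ThresholdSet | None = None,
    stpr_b: float | None = None,
) -> float:
    """Beginning of swimming: onset of upper-limb cycles (roll/pitch onset)."""
    th = th or ThresholdSet()
    location = SensorLocation(location)
    if stpr_b is None:
        stpr_b = detect_stroke_prep_begin(session, lap, location, th)
    lo, hi = stpr_b + 0.05, stpr_b + th.swim_search
    tech = lap.technique
    if tech is None:
        raise _fail("Swim_B", location, "technique must be known")

    if location == SensorLocation.SA:
        if tech in (Technique.FRONT_CRAWL, Technique.BACKSTROKE):
            gy = _crop(_lp(session, location, "gyr_y", th), lo, hi)
            mag = gy.map(np.abs(gy.values))
            return _first_peak(mag, th.TH_SSA_FCBaS, "Swim_B", location).time
        if tech == Technique.BREASTSTROKE:
            gz = _crop(_lp_emd(session, location, "gyr_z", th), lo, hi)
            imf2 = _second_imf(gz, "Swim_B", location)
            return _energy_cross(imf2, th.TH_SSA_BrS, "up", "Swim_B", location)
        ay = _crop(_lp_emd(session, location, "acc_y", th), lo, hi)
        imf2 = _second_imf(ay, "Swim_B", location)
        return _first_peak(imf2, th.TH_SSA_BF, "Swim_B", location).time

    if location == SensorLocation.HE:
        if tech == Technique.FRONT_CRAWL:
            sig = _crop(_lp(session, location, "gyr_y", th), lo, hi)
            return _energy_cross(sig, th.TH_SHE_FC, "up", "Swim_B", location)
        sig = _crop(_lp(session, location, "gyr_z", th), lo, hi)
        if tech == Technique.BACKSTROKE:
            return _energy_cross(sig, th.TH_SHE_BaS, "down", "Swim_B", location)
        return _energy_cross(sig, th.TH_SHE_BFBrS, "up", "Swim_B", location)

    if location == SensorLocation.RW:
        chan = {Technique.FRONT_CRAWL: "acc_y", Technique.BUTTERFLY: "acc_y",
                Technique.BACKSTROKE: "acc_x", Technique.BREASTSTROKE: "gyr_y"}[tech]
        wrists = [w for w in (SensorLocation.RW, SensorLocation.LW)
                  if w in session]
        starts = []
        for w in wrists:
            try:
                sig = _crop(_lp(session, w, chan, th), lo, hi)
                starts.append(_wrist_cycle_start(sig, th, "Swim_B", w))
            except DetectionError:
                continue
        if not starts:
            raise _fail("Swim_B", location, "no wrist showed a cycle start")
        return min(starts)

    if location == SensorLocation.RS:
        chan = "acc_y" if tech == Technique.BREASTSTROKE else "acc_x"
        sig = _crop(_lp_emd(session, location, chan, th), lo, hi)
        imf2 = _second_imf(sig, "Swim_B", location)
        peak = _first_peak(imf2, th.TH_T_RS, "Swim_B", location)
        return _last_local_min_before(imf2, peak.time)

    raise _fail("Swim_B", location, "unsupported location")


def detect_turn_begin(
    session: SessionRecording,
    lap: LapContext,
    location: SensorLocation,
    th: ThresholdSet | None = None,
    turn_type: TurnType | None = None,
) -> float:
    """Beginning of turn, anchored at the approximate turn (or bout end)."""
    th = th or ThresholdSet()
    location = SensorLocation(location)
    session.require_anatomical()
    tech = lap.technique
    turn_type = turn_type or lap.turn_type or (
        default_turn_type(tech) if tech else TurnType.TUMBLE
    )
    approx = lap.end_anchor
    lo, hi = approx - th.turn_search_pre, approx + th.turn_search_post

    # during backstroke the approximate turn itself is the best estimate;
    # the final lap ends at the wall and uses the location rules instead
    if tech == Technique.BACKSTROKE and not lap.is_final:
        return approx

    if location == SensorLocation.SA:
        sig = _crop(_lp(session, location, "acc_x", th), lo, hi)
        peak = _largest_peak(sig, float(np.min(sig.values)), "Turn_B", location)
        # first prominent trough before the large turn peak (noise dimples
        # between the true trough and the peak are rejected by prominence)
        pre = _crop(sig, sig.t0, peak.time)
        troughs = detect_extrema(pre, float(np.max(pre.values)), "trough",
                                 min_prominence=0.2)
        if troughs:
            return troughs[-1].time
        return _last_local_min_before(sig, peak.time)

    def _before_approx(sig: TimeSeries, pick: str) -> float:
        m = float(np.max(sig.values))
        ev = [e for e in detect_extrema(sig, th.turn_min_peak_fraction * m, "peak")
              if e.time < approx - 0.1]
        if not ev:
            raise _fail("Turn_B", location, "no qualifying peak before the "
                                            "approximate turn")
        if pick == "largest":
            return max(ev, key=lambda e: e.amplitude).time
        return ev[-1].time

    if location == SensorLocation.HE:
        if turn_type == TurnType.TUMBLE:
            sig = _crop(_lp_norm(session, location, "acc", "xyz", th), lo, hi)
        else:
            sig = _crop(_lp(session, location, "gyr_x", th), lo, hi)
        return _before_approx(sig, "largest")

    if location == SensorLocation.RW:
        sig = _crop(_lp(session, location, "acc_y", th), lo, hi)
        return _before_approx(sig, "last")

    if location == SensorLocation.RS:
        chan = "gyr_z" if turn_type == TurnType.TUMBLE else "acc_z"
        sig = _crop(_lp(session, location, chan, th), lo, hi)
        m = float(np.max(sig.values))
        ev = detect_extrema(sig, th.turn_min_peak_fraction * m, "peak")
        if not ev:
            raise _fail("Turn_B", location, "no shank turn peak in window")
        return ev[-1].time  # the latest: the turn follows the last kicks

    raise _fail("Turn_B", location, "unsupported location")


# ---------------------------------------------------------------------------
# lap segmentation
# ---------------------------------------------------------------------------


def segment_lap(
    session: SessionRecording,
    lap: LapContext,
    location: SensorLocation,
    th: ThresholdSet | None = None,
) -> LapSegmentation:
    """Chain the five detectors and derive phase durations for one lap."""
    th = th or ThresholdSet()
    location = SensorLocation(location)
    if lap.technique is None:
        lap.technique = identify_technique(session, lap, location, th)
    if lap.turn_type is None:
        lap.turn_type = default_turn_type(lap.technique)

    push_b = detect_push_begin(session, lap, location, th)
    glid_b = detect_glide_begin(session, lap, location, th, push_b=push_b)
    stpr_b = detect_stroke_prep_begin(session, lap, location, th, glid_b=glid_b)
    swim_b = detect_swim_begin(session, lap, location, th, stpr_b=stpr_b)
    turn_b = detect_turn_begin(session, lap, location, th)

    events = PhaseEvents(push_b, glid_b, stpr_b, swim_b, turn_b,
                         location, lap.technique, lap.turn_type)

    if lap.is_final:
        turn_end = lap.bout.approx_end
    else:
        next_lap = LapContext(
            bout=lap.bout, lap_index=lap.lap_index + 1,
            start_anchor=lap.end_anchor, end_anchor=lap.bout.approx_end,
            is_final=True, technique=lap.technique, turn_type=lap.turn_type,
        )
        turn_end = detect_push_begin(session, next_lap, location, th)
    if turn_end <= turn_b:
        raise OrderingError(
            f"Turn_B ({turn_b:.3f} s) must precede the next Push_B/bout end "
            f"({turn_end:.3f} s) [{location.value}]"
        )

    ms = 1000.0
    return LapSegmentation(
        events=events,
        d_push_ms=(glid_b - push_b) * ms,
        d_glid_ms=(stpr_b - glid_b) * ms,
        d_stpr_ms=(swim_b - stpr_b) * ms,
        d_swim_ms=(turn_b - swim_b) * ms,
        d_turn_ms=(turn_end - turn_b) * ms,
    )
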