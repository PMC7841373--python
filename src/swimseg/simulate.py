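"""Synthetic training-session generator with exact ground truth.

The generator emits piecewise-smooth template signals (raised-cosine pulses,
amplitude-modulated oscillations, posture level shifts), not a biomechanical
simulation: the macro/micro detectors are rule-based on exactly these
signatures, so a session whose every trigger is stamped into the ground truth
makes each detector testable end to end without any recorded data.

Session structure: rest → bout (laps separated by turns) → rest → … Each lap
contains the five phases wall push-off, glide, strokes preparation, swimming
and turn; phase durations are drawn from truncated normal distributions whose
defaults are the validation-data statistics (ΔPush 218±29 ms, ΔGlid 880±476,
ΔStPr 2673±1268, ΔSwim 12423±1905, ΔTurn 1223±166).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidParameterError
from .session import (
    GroundTruth,
    ImuRecording,
    LapTruth,
    SensorLocation,
    SessionRecording,
    Technique,
    TurnType,
)

__all__ = ["SimulationConfig", "default_paper_config", "simulate_session"]

# timeline shape constants (s)
POSTURE_STEP = 0.6          # width of the upright <-> horizontal posture transition
PUSH_AFTER_START = 0.5      # Push_B relative to the bout-start posture center
TURN_SPIKE_OFFSET = 0.35    # approximate-turn spike after Turn_B (prone techniques)
TURN_SPIKE_OFFSET_BAS = 0.10  # backstroke: turn visible almost immediately
FINAL_STAND_AFTER_TURN = 1.0  # bout-end posture center after the last Turn_B
LEFT_WRIST_DELAY = 0.25     # left wrist starts its cycles after the right
LEFT_SHANK_DELAY = 0.2      # alternate-leg kick offset


@dataclass(frozen=True)
class DurationModel:
    """Truncated-normal phase duration in ms (±3 sd, floored)."""

    mean_ms: float
    sd_ms: float
    floor_ms: float = 50.0

    def sample(self, rng: np.random.Generator) -> float:
        """One duration in seconds."""
        for _ in range(100):
            d = rng.normal(self.mean_ms, self.sd_ms)
            if abs(d - self.mean_ms) <= 3 * self.sd_ms and d >= self.floor_ms:
                return d / 1000.0
        return max(self.mean_ms, self.floor_ms) / 1000.0


@dataclass(frozen=True)
class SimulationConfig:
    n_bouts: int = 4
    laps_per_bout: int = 2
    techniques: tuple[Technique, ...] = (
        Technique.FRONT_CRAWL,
        Technique.BREASTSTROKE,
        Technique.BUTTERFLY,
        Technique.BACKSTROKE,
    )
    turn_types: tuple[TurnType, ...] | None = None  # default by technique
    fs: float = 500.0
    push: DurationModel = DurationModel(218, 29, 80)
    glide: DurationModel = DurationModel(880, 476, 300)
    stpr: DurationModel = DurationModel(2673, 1268, 800)
    swim: DurationModel = DurationModel(12423, 1905, 3000)
    turn: DurationModel = DurationModel(1223, 166, 700)
    stroke_freq: float = 0.6    # Hz, upper-limb cycles
    kick_freq: float = 2.5      # Hz, lower-limb actions
    rest_duration: float = 20.0  # s between bouts (and before the first)
    noise_sd_acc: float = 0.05  # g
    noise_sd_gyr: float = 5.0   # °/s
    seed: int = 0

    def __post_init__(self):
        if self.n_bouts < 1 or self.laps_per_bout < 1:
            raise InvalidParameterError("need at least one bout and one lap")
        if len(self.techniques) != self.n_bouts:
            raise InvalidParameterError("one technique per bout required")
        if self.turn_types is not None and len(self.turn_types) != self.n_bouts:
            raise InvalidParameterError("one turn type per bout required")
        if self.fs <= 0:
            raise InvalidParameterError("fs must be positive")
        shortest = min(m.floor_ms for m in
                       (self.push, self.glide, self.stpr, self.swim, self.turn))
        if shortest / 1000.0 < 2.0 / self.fs:
            raise InvalidParameterError("phase durations incompatible with fs")


def default_turn_type(technique: Technique) -> TurnType:
    """Competition convention: flip turns for crawl/backstroke, open turns else."""
    if technique in (Technique.FRONT_CRAWL, Technique.BACKSTROKE):
        return TurnType.TUMBLE
    return TurnType.SIMPLE


def default_paper_config(**overrides) -> SimulationConfig:
    """Four 2-lap bouts, one per technique, validation-data phase durations."""
    return replace(SimulationConfig(), **overrides) if overrides else SimulationConfig()


# ---------------------------------------------------------------------------
# timeline
# ---------------------------------------------------------------------------


@dataclass
class _BoutPlan:
    start: float                  # posture-transition center into the bout
    end: float                    # posture-transition center out of the bout
    technique: Technique
    turn_type: TurnType
    laps: list[LapTruth]


def _build_timeline(cfg: SimulationConfig,
                    rng: np.random.Generator) -> list[_BoutPlan]:
    bouts: list[_BoutPlan] = []
    t = cfg.rest_duration
    for b in range(cfg.n_bouts):
        tech = Technique(cfg.techniques[b])
        tt = (TurnType(cfg.turn_types[b]) if cfg.turn_types is not None
              else default_turn_type(tech))
        start = t
        push_b = start + PUSH_AFTER_START
        laps: list[LapTruth] = []
        for lap in range(cfg.laps_per_bout):
            glid_b = push_b + cfg.push.sample(rng)
            stpr_b = glid_b + cfg.glide.sample(rng)
            swim_b = stpr_b + cfg.stpr.sample(rng)
            turn_b = swim_b + cfg.swim.sample(rng)
            laps.append(LapTruth(bout_index=b, technique=tech, turn_type=tt,
                                 push_b=push_b, glid_b=glid_b, stpr_b=stpr_b,
                                 swim_b=swim_b, turn_b=turn_b))
            d_turn = cfg.turn.sample(rng)
            push_b = turn_b + d_turn
        # last lap: the sampled "turn" span ends standing at the wall
        end = laps[-1].turn_b + FINAL_STAND_AFTER_TURN
        bouts.append(_BoutPlan(start, end, tech, tt, laps))
        t = end + cfg.rest_duration
    return bouts


# ---------------------------------------------------------------------------
# waveform building blocks
# ---------------------------------------------------------------------------


def _pulse(t: np.ndarray, center: float, width: float, amp: float) -> np.ndarray:
    """Raised-cosine pulse of full support ``width`` centered at ``center``."""
    x = (t - center) / width
    out = np.zeros_like(t)
    m = np.abs(x) < 0.5
    out[m] = amp * 0.5 * (1.0 + np.cos(2 * np.pi * x[m]))
    return out


def _step(t: np.ndarray, center: float, width: float = POSTURE_STEP) -> np.ndarray:
    """Smooth 0→1 step (raised cosine) centered at ``center``."""
    x = (t - center) / width
    out = np.where(x >= 0.5, 1.0, 0.0)
    m = np.abs(x) < 0.5
    out[m] = 0.5 * (1.0 + np.sin(np.pi * x[m]))
    return out


def _burst_env(t: np.ndarray, on: float, off: float, tau: float) -> np.ndarray:
    """Unit envelope over [on, off] with raised-cosine ramps of length tau."""
    return _step(t, on + tau / 2, tau) * (1.0 - _step(t, off + tau / 2, tau))


def _osc(
    t: np.ndarray,
    on: float,
    off: float,
    freq: float,
    amp: float,
    tau: float = 0.15,
    first_peak: float | None = None,
    first_trough: float | None = None,
    snap_cycles: bool = False,
) -> np.ndarray:
    """Amplitude-modulated sinusoid starting at ``on``.

    The phase is set so the first extremum lands at ``on + first_peak`` (or
    ``first_trough``); default puts the first peak a quarter period in.
    With ``snap_cycles`` the burst starts and ends at zero phase (an integer
    number of half cycles), so switching it on/off leaves no step transient.
    """
    if snap_cycles:
        period = 1.0 / freq
        off = on + max(1, int((off - on) / period)) * period
        phi = 0.0
    elif first_peak is not None:
        phi = np.pi / 2 - 2 * np.pi * freq * first_peak
    elif first_trough is not None:
        phi = -np.pi / 2 - 2 * np.pi * freq * first_trough
    else:
        phi = 0.0
    return amp * _burst_env(t, on, off, tau) * np.sin(
        2 * np.pi * freq * (t - on) + phi
    )


def _pulse_train(
    t: np.ndarray,
    on: float,
    off: float,
    rate: float,
    amp: float,
    width: float,
    first_offset: float,
) -> np.ndarray:
    """Train of raised-cosine pulses at ``rate`` Hz over [on, off]."""
    out = np.zeros_like(t)
    c = on + first_offset
    while c < off:
        out += _pulse(t, c, width, amp)
        c += 1.0 / rate
    return out


def _level(t: np.ndarray, nodes: list[tuple[float, float]],
           ramp: float = 0.3) -> np.ndarray:
    """Piecewise-constant level with smooth transitions at the node times."""
    out = np.full_like(t, nodes[0][1])
    for (t0, v0), (t1, v1) in zip(nodes, nodes[1:]):
        out += (v1 - v0) * _step(t, t1, ramp)
    return out


# ---------------------------------------------------------------------------
# per-location synthesis
# ---------------------------------------------------------------------------


def _prone_sign(tech: Technique) -> float:
    return 1.0 if tech == Technique.BACKSTROKE else -1.0


def _posture(t: np.ndarray, bouts: list[_BoutPlan]) -> tuple[np.ndarray, np.ndarray]:
    """(Acc_y, Acc_x) gravity baselines: upright 1/0, in-bout 0/±1."""
    acc_y = np.ones_like(t)
    acc_x = np.zeros_like(t)
    for b in bouts:
        inside = _step(t, b.start) - _step(t, b.end)
        acc_y -= inside
        acc_x += _prone_sign(b.technique) * inside
    return acc_y, acc_x


def _turn_offset(tech: Technique) -> float:
    return TURN_SPIKE_OFFSET_BAS if tech == Technique.BACKSTROKE else TURN_SPIKE_OFFSET


def _synth_sacrum(t, bouts, cfg) -> tuple[np.ndarray, np.ndarray]:
    acc = np.zeros((t.size, 3))
    gyr = np.zeros((t.size, 3))
    acc[:, 1], acc[:, 0] = _posture(t, bouts)
    fs_, fk = cfg.stroke_freq, cfg.kick_freq
    for b in bouts:
        tech, ps, toff = b.technique, _prone_sign(b.technique), _turn_offset(b.technique)
        for i, lap in enumerate(b.laps):
            pb, gb, sb, sw, tb = lap.events()
            final = i == len(b.laps) - 1
            # push-off complex on Acc_y, scaled to this lap's push duration so
            # the propulsion peak stays inside [Push_B, Glid_B]
            d_push = gb - pb
            if tech == Technique.BACKSTROKE:
                acc[:, 1] += _pulse(t, pb, 0.3, 0.9)
            else:
                acc[:, 1] += _pulse(t, pb - 0.15, 0.24, -0.8)
                acc[:, 1] += _pulse(t, pb + 0.5 * d_push,
                                    min(0.3, max(0.14, 0.8 * d_push)), 0.8)
            acc[:, 1] += _pulse(t, gb + 0.05, 0.2, -0.45)   # glide settle trough
            # kick bursts on Acc_x (StPr trigger: |Acc_x| peaks + local variance)
            acc[:, 0] += _osc(t, sb, tb, fk, 0.55 * ps, tau=0.1, first_peak=0.08)
            # swimming-phase oscillations
            swim_amp_x = {Technique.FRONT_CRAWL: 0.08, Technique.BACKSTROKE: 0.08,
                          Technique.BREASTSTROKE: 0.05, Technique.BUTTERFLY: 0.45}[tech]
            acc[:, 0] += _osc(t, sw, tb, fs_, swim_amp_x * ps, tau=0.2)
            if tech == Technique.BUTTERFLY:
                acc[:, 1] += _osc(t, sw, tb, fs_, 0.28, tau=0.2, first_peak=0.2)
                acc[:, 1] += _osc(t, sw, tb, 3.0, 0.35, tau=0.2, snap_cycles=True)
            else:
                acc[:, 1] += _osc(t, sw, tb, fs_, 0.06, tau=0.2)
            if tech in (Technique.FRONT_CRAWL, Technique.BACKSTROKE):
                gyr[:, 1] += _osc(t, sw, tb, fs_, 260, tau=0.2, first_peak=0.3)
                gyr[:, 2] += _osc(t, sw, tb, fs_, 10, tau=0.2)
            elif tech == Technique.BREASTSTROKE:
                gyr[:, 1] += _osc(t, sw, tb, fs_, 8, tau=0.2)
                gyr[:, 2] += _osc(t, sw, tb, fs_, 45, tau=0.2)
                gyr[:, 2] += _osc(t, sw, tb, 3.0, 30, tau=0.2, snap_cycles=True)
            else:  # butterfly
                gyr[:, 1] += _osc(t, sw, tb, fs_, 8, tau=0.2)
                gyr[:, 2] += _osc(t, sw, tb, fs_, 130, tau=0.2)
                gyr[:, 2] += _osc(t, sw, tb, 3.0, 9, tau=0.2)
            gyr[:, 0] += _osc(t, sw, tb, fs_, 5, tau=0.2)
            # turn: Acc_x trough at Turn_B then the large spike used as the
            # approximate turn; the final wall gets a smaller touch spike
            if final:
                spike = 1.0 if tech == Technique.BACKSTROKE else 1.6
            else:
                spike = 3.0
            acc[:, 0] += _pulse(t, tb, 0.3, -0.6 * 1.0)
            acc[:, 0] += _pulse(t, tb + toff, 0.3, spike)
            acc[:, 2] += _pulse(t, tb + toff, 0.3, 0.8 if final else 2.5)
    return acc, gyr


def _synth_head(t, bouts, cfg) -> tuple[np.ndarray, np.ndarray]:
    acc = np.zeros((t.size, 3))
    gyr = np.zeros((t.size, 3))
    acc[:, 1], acc[:, 0] = _posture(t, bouts)
    fs_, fk = cfg.stroke_freq, cfg.kick_freq
    for b in bouts:
        tech, ps, toff = b.technique, _prone_sign(b.technique), _turn_offset(b.technique)
        for i, lap in enumerate(b.laps):
            pb, gb, sb, sw, tb = lap.events()
            final = i == len(b.laps) - 1
            acc[:, 1] += _pulse(t, pb, 0.3, 1.2)            # push |Acc| / Acc_y peak
            acc[:, 1] += _pulse(t, gb, 0.24, -0.3)          # glide trough
            acc[:, 1] += _pulse(t, sb + 0.05, 0.3, -0.7)    # StPr head dip
            swim_amp_x = {Technique.FRONT_CRAWL: 0.1, Technique.BACKSTROKE: 0.1,
                          Technique.BREASTSTROKE: 0.08, Technique.BUTTERFLY: 0.5}[tech]
            acc[:, 0] += _osc(t, sw, tb, fs_, swim_amp_x * ps, tau=0.2)
            if tech == Technique.FRONT_CRAWL:
                gyr[:, 1] += _osc(t, sw, tb, fs_, 130, tau=0.1, first_peak=0.3)
                gyr[:, 2] += _osc(t, sw, tb, fs_, 8, tau=0.2)
            elif tech == Technique.BACKSTROKE:
                gyr[:, 1] += _osc(t, sw, tb, fs_, 160, tau=0.1, first_peak=0.3)
                # kick-driven head pitch that stops when the arm cycles start
                gyr[:, 2] += _osc(t, sb, sw, fk, 65, tau=0.15)
            else:  # breaststroke / butterfly
                gyr[:, 1] += _osc(t, sw, tb, fs_, 8, tau=0.2)
                gyr[:, 2] += _osc(t, sw, tb, fs_, 190, tau=0.1, first_peak=0.3)
            # turn: event pulse at Turn_B, large spike at the approximate turn
            if b.turn_type == TurnType.TUMBLE:
                acc[:, 2] += _pulse(t, tb, 0.25, 1.4)
            else:
                gyr[:, 0] += _pulse(t, tb, 0.25, 220)
            acc[:, 0] += _pulse(t, tb + toff, 0.3, (1.2 if final else 3.0))
            acc[:, 2] += _pulse(t, tb + toff, 0.3, 0.8 if final else 2.6)
    return acc, gyr


def _wrist_swim_acc(t, lap: LapTruth, tech: Technique, cfg,
                    delay: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(Acc_x, Acc_y, Acc_z) swim-phase components for one wrist and lap."""
    fs_ = cfg.stroke_freq
    sw, tb = lap.swim_b + delay, lap.turn_b
    ax = np.zeros_like(t)
    ay = np.zeros_like(t)
    az = np.zeros_like(t)
    rate = 2 * fs_                       # two load peaks per arm cycle
    width = 0.3 / rate
    if tech == Technique.FRONT_CRAWL:
        ay += _pulse_train(t, sw, tb, rate, 2.3, width, 0.12)
    elif tech == Technique.BUTTERFLY:
        ay += _pulse_train(t, sw, tb, rate, 2.3, width, 0.12)
        az += 1.6 * _burst_env(t, sw, tb, 0.3)   # sustained both-arm load
    elif tech == Technique.BREASTSTROKE:
        # |Acc| modulated at the stroke frequency: pull then in-cycle glide;
        # carried on the mediolateral axis so the longitudinal posture
        # channel keeps its level structure
        env = _burst_env(t, sw, tb, 0.2)
        target = 1.0 + 0.47 * env + env * 0.45 * np.sin(
            2 * np.pi * fs_ * (t - sw))
        az += np.sqrt(np.maximum(target**2 - 1.0, 0.0))
    else:  # backstroke: dominant anterior-posterior oscillation
        ax += _osc(t, sw, tb, fs_, 1.05, tau=0.08, first_trough=0.08)
    return ax, ay, az


def _synth_wrist(t, bouts, cfg, delay: float) -> tuple[np.ndarray, np.ndarray]:
    acc = np.zeros((t.size, 3))
    gyr = np.zeros((t.size, 3))
    acc[:, 1], acc[:, 0] = _posture(t, bouts)
    fs_ = cfg.stroke_freq
    for b in bouts:
        tech, ps = b.technique, _prone_sign(b.technique)
        # |Gyr| level: sustained rotation while swimming, drop during turns
        nodes = [(0.0, 0.0), (b.start, 250.0)]
        for i, lap in enumerate(b.laps):
            nodes.append((lap.swim_b, 330.0))
            nodes.append((lap.turn_b, 60.0))
            if i < len(b.laps) - 1:
                nodes.append((b.laps[i + 1].push_b, 250.0))
        nodes.append((b.end, 0.0))
        level = _level(t, nodes, ramp=0.25)
        phase = 2 * np.pi * fs_ * t
        gyr[:, 0] += level * np.cos(phase)
        gyr[:, 2] += level * np.sin(phase)
        for i, lap in enumerate(b.laps):
            pb, gb, sb, sw, tb = lap.events()
            acc[:, 1] += _pulse(t, pb, 0.25, -0.9)          # push-off hand drop
            acc[:, 1] += _pulse(t, gb, 0.25, 0.35)          # glide-entry peak
            # StPr: near free-fall |Acc| dip (trough on |Acc| − 1 g)
            acc[:, 0] += _pulse(t, sb + 0.05, 0.35, -0.998 * ps)
            ax, ay, az = _wrist_swim_acc(t, lap, tech, cfg, delay)
            acc[:, 0] += ax
            acc[:, 1] += ay
            acc[:, 2] += az
            if tech == Technique.BREASTSTROKE:
                gyr[:, 1] += _osc(t, sw + delay, tb, fs_, 260, tau=0.08,
                                  first_trough=0.08)
            acc[:, 1] += _pulse(t, tb, 0.25, 1.3)           # turn hand swing
    return acc, gyr


def _synth_shank(t, bouts, cfg, delay: float) -> tuple[np.ndarray, np.ndarray]:
    acc = np.zeros((t.size, 3))
    gyr = np.zeros((t.size, 3))
    acc[:, 1], acc[:, 0] = _posture(t, bouts)
    fs_, fk = cfg.stroke_freq, cfg.kick_freq
    for b in bouts:
        tech, ps, toff = b.technique, _prone_sign(b.technique), _turn_offset(b.technique)
        for i, lap in enumerate(b.laps):
            pb, gb, sb, sw, tb = lap.events()
            sbd = sb + delay
            final = i == len(b.laps) - 1
            kick_end = tb - 0.3  # legs reach for the wall before the turn
            gyr[:, 1] += _pulse(t, pb, 0.2, 520)            # push-off knee extension
            gyr[:, 1] += _pulse(t, gb, 0.16, 160)           # legs settle into glide
            # kicks: angular velocity + spiky |Acc_x| train with an offset base
            if tech == Technique.BREASTSTROKE:
                gyr[:, 0] += _osc(t, sbd, kick_end, fs_, 300, tau=0.15)
                gyr[:, 2] += _osc(t, sbd, kick_end, fs_, 40, tau=0.15)
            elif tech == Technique.BUTTERFLY:
                gyr[:, 2] += _osc(t, sbd, kick_end, fk, 400, tau=0.15)
            elif tech == Technique.FRONT_CRAWL:
                gyr[:, 2] += _osc(t, sbd, kick_end, fk, 350, tau=0.15)
                gyr[:, 1] += _osc(t, sw, kick_end, fs_, 150, tau=0.2)
            else:  # backstroke
                gyr[:, 2] += _osc(t, sbd, kick_end, fk, 350, tau=0.15)
            kick_base = -0.2 * ps
            acc[:, 0] += kick_base * _burst_env(t, sbd, kick_end, 0.2)
            acc[:, 0] += _pulse_train(t, sbd, kick_end, fk, 1.1 * ps, 0.16, 0.0)
            # sustained kick oscillation: keeps the kick-rate mode separable
            # from the slow undulation in the decomposition
            acc[:, 0] += _osc(t, sbd, kick_end, fk, 1.6, tau=0.15,
                              snap_cycles=True)
            if tech == Technique.BACKSTROKE:
                acc[:, 1] += _pulse_train(t, sbd, kick_end, fk, 0.5, 0.2, 0.05)
            elif tech == Technique.BREASTSTROKE:
                # kick vibration on the longitudinal axis: the fast mode above
                # the slow swimming undulation
                acc[:, 1] += _osc(t, sbd, kick_end, fk, 1.6, tau=0.15,
                                  snap_cycles=True)
            # swimming: strong slow undulation component (2nd intrinsic mode)
            chan = 1 if tech == Technique.BREASTSTROKE else 0
            acc[:, chan] += _osc(t, sw, tb, fs_, 3.0, tau=0.2, snap_cycles=True)
            # turn spikes (the final wall touch is gentler)
            if b.turn_type == TurnType.TUMBLE:
                gyr[:, 2] += _pulse(t, tb + 0.1, 0.25, 300 if final else 750)
            else:
                acc[:, 2] += _pulse(t, tb + 0.1, 0.25, 0.6 if final else 1.6)
    return acc, gyr


def simulate_session(
    cfg: SimulationConfig,
) -> tuple[SessionRecording, GroundTruth]:
    """Generate a session and its ground truth; identical seeds are bit-identical."""
    rng = np.random.default_rng(cfg.seed)
    bouts = _build_timeline(cfg, rng)
    total = bouts[-1].end + cfg.rest_duration
    n = int(round(total * cfg.fs)) + 1
    t = np.arange(n) / cfg.fs

    synth = {
        SensorLocation.SA: _synth_sacrum(t, bouts, cfg),
        SensorLocation.HE: _synth_head(t, bouts, cfg),
        SensorLocation.RW: _synth_wrist(t, bouts, cfg, 0.0),
        SensorLocation.LW: _synth_wrist(t, bouts, cfg, LEFT_WRIST_DELAY),
        SensorLocation.RS: _synth_shank(t, bouts, cfg, 0.0),
        SensorLocation.LS: _synth_shank(t, bouts, cfg, LEFT_SHANK_DELAY),
    }
    recordings = {}
    for loc, (acc, gyr) in synth.items():
        acc = acc + rng.normal(0.0, cfg.noise_sd_acc, acc.shape)
        gyr = gyr + rng.normal(0.0, cfg.noise_sd_gyr, gyr.shape)
        recordings[loc] = ImuRecording(acc=acc, gyr=gyr, fs=cfg.fs,
                                       location=loc, frame="anatomical")

    gt = GroundTruth(
        bouts=[(b.start, b.end) for b in bouts],
        turns=[(lap.turn_b, b.turn_type)
               for b in bouts for lap in b.laps[:-1]],
        laps=[lap for b in bouts for lap in b.laps],
    )
    return SessionRecording(recordings, swimmer_id=f"sim-{cfg.seed}"), gt
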