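"""Session data model, file I/O and simplified functional calibration.

A training session is a set of synchronized six-location IMU recordings
(3-D accelerometer in g, 3-D gyroscope in °/s, one sampling rate). Data are
expressed either in the sensor frame or, after functional calibration, in the
per-segment anatomical frame: y along the longitudinal axis pointing up,
x anterior–posterior pointing forward, z mediolateral pointing right. All
detectors consume anatomical-frame data only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import h5py
import numpy as np

from .errors import (
    CalibrationError,
    FormatError,
    FrameError,
    InvalidInputError,
    InvalidParameterError,
    ValidationError,
)
from .primitives import TimeSeries, principal_components

G = 9.81  # m/s² per g
RAD2DEG = 180.0 / np.pi

ANNOTATION_SCHEMA = "swimseg-gt-1"

__all__ = [
    "SensorLocation",
    "Technique",
    "TurnType",
    "ImuRecording",
    "SessionRecording",
    "CalibrationTransform",
    "LapTruth",
    "GroundTruth",
    "read_session",
    "write_session",
    "read_annotations",
    "write_annotations",
    "estimate_calibration",
    "apply_calibration",
]


class SensorLocation(str, Enum):
    SA = "SA"  # sacrum
    HE = "HE"  # head
    RW = "RW"  # right wrist
    LW = "LW"  # left wrist
    RS = "RS"  # right shank
    LS = "LS"  # left shank


class Technique(str, Enum):
    FRONT_CRAWL = "front_crawl"
    BREASTSTROKE = "breaststroke"
    BUTTERFLY = "butterfly"
    BACKSTROKE = "backstroke"


class TurnType(str, Enum):
    SIMPLE = "simple"
    TUMBLE = "tumble"


_AXES = {"x": 0, "y": 1, "z": 2}


@dataclass
class ImuRecording:
    """One sensor's channels: acc (N×3, g) and gyr (N×3, °/s)."""

    acc: np.ndarray
    gyr: np.ndarray
    fs: float
    location: SensorLocation
    frame: str = "anatomical"  # or "sensor"

    def __post_init__(self):
        self.acc = np.asarray(self.acc, dtype=float)
        self.gyr = np.asarray(self.gyr, dtype=float)
        if self.acc.ndim != 2 or self.acc.shape[1] != 3:
            raise InvalidInputError("acc must be N×3")
        if self.gyr.shape != self.acc.shape:
            raise InvalidInputError("acc and gyr must have equal shape")
        if self.fs <= 0:
            raise InvalidParameterError("fs must be positive")
        if self.frame not in ("sensor", "anatomical"):
            raise InvalidParameterError("frame must be 'sensor' or 'anatomical'")
        self.location = SensorLocation(self.location)

    def __len__(self) -> int:
        return self.acc.shape[0]

    def channel(self, name: str) -> TimeSeries:
        """Single axis as a TimeSeries, e.g. 'acc_y' or 'gyr_z'."""
        kind, _, axis = name.partition("_")
        data = {"acc": self.acc, "gyr": self.gyr}[kind]
        return TimeSeries(data[:, _AXES[axis]], self.fs)

    def norm(self, kind: str = "acc", axes: str = "xyz") -> TimeSeries:
        """Norm over the given axes, e.g. |Acc| or |Acc_{y,z}|."""
        data = {"acc": self.acc, "gyr": self.gyr}[kind]
        cols = [_AXES[a] for a in axes]
        return TimeSeries(np.linalg.norm(data[:, cols], axis=1), self.fs)


@dataclass
class SessionRecording:
    """All-location IMU channels for one training session."""

    recordings: dict[SensorLocation, ImuRecording]
    pool_length: float = 25.0
    swimmer_id: str = ""

    def __post_init__(self):
        self.recordings = {
            SensorLocation(k): v for k, v in self.recordings.items()
        }
        if not self.recordings:
            raise InvalidInputError("session has no recordings")
        lengths = {len(r) for r in self.recordings.values()}
        rates = {r.fs for r in self.recordings.values()}
        if len(lengths) != 1 or len(rates) != 1:
            raise InvalidInputError("all recordings must share fs and length")
        required = {SensorLocation.SA, SensorLocation.HE, SensorLocation.RW,
                    SensorLocation.RS}
        if not required & set(self.recordings):
            raise InvalidInputError(
                "session needs at least one of SA, HE, RW, RS"
            )

    @property
    def fs(self) -> float:
        return next(iter(self.recordings.values())).fs

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.recordings.values())))

    @property
    def duration(self) -> float:
        return (self.n_samples - 1) / self.fs

    @property
    def frame(self) -> str:
        frames = {r.frame for r in self.recordings.values()}
        return frames.pop() if len(frames) == 1 else "mixed"

    def __getitem__(self, loc: SensorLocation | str) -> ImuRecording:
        return self.recordings[SensorLocation(loc)]

    def __contains__(self, loc: SensorLocation | str) -> bool:
        try:
            return SensorLocation(loc) in self.recordings
        except ValueError:
            return False

    def require_anatomical(self) -> None:
        if self.frame != "anatomical":
            raise FrameError(
                "detectors require anatomical-frame data; apply calibration first"
            )


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------


@dataclass
class LapTruth:
    """True phase-begin times and labels for one lap."""

    bout_index: int
    technique: Technique
    turn_type: TurnType
    push_b: float
    glid_b: float
    stpr_b: float
    swim_b: float
    turn_b: float

    def events(self) -> tuple[float, float, float, float, float]:
        return (self.push_b, self.glid_b, self.stpr_b, self.swim_b, self.turn_b)


@dataclass
class GroundTruth:
    """Simulator- or annotator-provided true events for a session."""

    bouts: list[tuple[float, float]] = field(default_factory=list)
    turns: list[tuple[float, TurnType]] = field(default_factory=list)
    laps: list[LapTruth] = field(default_factory=list)

    def __post_init__(self):
        self.validate()

    def validate(self) -> "GroundTruth":
        for i, (s, e) in enumerate(self.bouts):
            if not s < e:
                raise ValidationError(f"bout {i}: start must precede end")
        names = ("Push_B", "Glid_B", "StPr_B", "Swim_B", "Turn_B")
        for k, lap in enumerate(self.laps):
            ev = lap.events()
            for a, b, na, nb in zip(ev, ev[1:], names, names[1:]):
                if not a < b:
                    raise ValidationError(
                        f"lap {k}: {na} ({a:.3f}s) must precede {nb} ({b:.3f}s)"
                    )
            if lap.bout_index < len(self.bouts):
                s, e = self.bouts[lap.bout_index]
                if not (s - 2.0 <= ev[0] and ev[-1] <= e + 2.0):
                    raise ValidationError(f"lap {k}: events outside bout {lap.bout_index}")
        return self

    @property
    def techniques(self) -> list[Technique]:
        return [lap.technique for lap in self.laps]

    def laps_of_bout(self, bout_index: int) -> list[LapTruth]:
        return [l for l in self.laps if l.bout_index == bout_index]


def write_annotations(gt: GroundTruth, path: str | Path) -> None:
    """Write ground truth as versioned JSON (schema ``swimseg-gt-1``)."""
    doc = {
        "schema": ANNOTATION_SCHEMA,
        "bouts": [{"start": s, "end": e} for s, e in gt.bouts],
        "turns": [{"time": t, "turn_type": tt.value} for t, tt in gt.turns],
        "laps": [
            {
                "bout_index": lap.bout_index,
                "technique": lap.technique.value,
                "turn_type": lap.turn_type.value,
                "push_b": lap.push_b,
                "glid_b": lap.glid_b,
                "stpr_b": lap.stpr_b,
                "swim_b": lap.swim_b,
                "turn_b": lap.turn_b,
            }
            for lap in gt.laps
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def read_annotations(path: str | Path) -> GroundTruth:
    """Read a ground-truth annotation file; ordering is re-validated."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"annotation file is not valid JSON: {exc}") from exc
    if doc.get("schema") != ANNOTATION_SCHEMA:
        raise FormatError(
            f"unsupported annotation schema {doc.get('schema')!r}", field="schema"
        )
    try:
        return GroundTruth(
            bouts=[(b["start"], b["end"]) for b in doc.get("bouts", [])],
            turns=[(t["time"], TurnType(t["turn_type"])) for t in doc.get("turns", [])],
            laps=[
                LapTruth(
                    bout_index=l["bout_index"],
                    technique=Technique(l["technique"]),
                    turn_type=TurnType(l["turn_type"]),
                    push_b=l["push_b"],
                    glid_b=l["glid_b"],
                    stpr_b=l["stpr_b"],
                    swim_b=l["swim_b"],
                    turn_b=l["turn_b"],
                )
                for l in doc.get("laps", [])
            ],
        )
    except KeyError as exc:
        raise FormatError(f"annotation file misses field {exc}", field=str(exc)) from exc


# ---------------------------------------------------------------------------
# Session file I/O
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ("t", "acc_x", "acc_y", "acc_z", "gyr_x", "gyr_y", "gyr_z")


def _convert_units(acc: np.ndarray, gyr: np.ndarray, units_acc: str,
                   units_gyr: str) -> tuple[np.ndarray, np.ndarray]:
    if units_acc == "m/s2":
        acc = acc / G
    elif units_acc != "g":
        raise FormatError(f"unknown acceleration unit {units_acc!r}", field="units_acc")
    if units_gyr == "rad/s":
        gyr = gyr * RAD2DEG
    elif units_gyr != "dps":
        raise FormatError(f"unknown angular-velocity unit {units_gyr!r}",
                          field="units_gyr")
    return acc, gyr


def write_session(session: SessionRecording, path: str | Path) -> None:
    """Write a session to HDF5 (one group per location)."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["pool_length"] = session.pool_length
        f.attrs["swimmer_id"] = session.swimmer_id
        for loc, rec in session.recordings.items():
            g = f.create_group(loc.value)
            g.create_dataset("acc", data=rec.acc)
            g.create_dataset("gyr", data=rec.gyr)
            g.attrs["fs"] = rec.fs
            g.attrs["units_acc"] = "g"
            g.attrs["units_gyr"] = "dps"
            g.attrs["frame"] = rec.frame


def _read_session_h5(path: Path) -> SessionRecording:
    recordings = {}
    with h5py.File(path, "r") as f:
        pool_length = float(f.attrs.get("pool_length", 25.0))
        swimmer_id = str(f.attrs.get("swimmer_id", ""))
        for name, g in f.items():
            try:
                loc = SensorLocation(name)
            except ValueError as exc:
                raise FormatError(f"unknown location group {name!r}",
                                  field=name) from exc
            for ds in ("acc", "gyr"):
                if ds not in g:
                    raise FormatError(f"group {name} misses dataset {ds!r}", field=ds)
            acc = np.asarray(g["acc"], dtype=float)
            gyr = np.asarray(g["gyr"], dtype=float)
            acc, gyr = _convert_units(
                acc, gyr,
                str(g.attrs.get("units_acc", "g")),
                str(g.attrs.get("units_gyr", "dps")),
            )
            recordings[loc] = ImuRecording(
                acc=acc, gyr=gyr,
                fs=float(g.attrs.get("fs", 500.0)),
                location=loc,
                frame=str(g.attrs.get("frame", "anatomical")),
            )
    return SessionRecording(recordings, pool_length=pool_length,
                            swimmer_id=swimmer_id)


def _read_location_csv(path: Path, loc: SensorLocation) -> ImuRecording:
    meta = {"fs": "500", "units_acc": "g", "units_gyr": "dps",
            "frame": "anatomical"}
    header = None
    rows = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, value = line.lstrip("#").strip().partition("=")
            meta[key.strip()] = value.strip()
            continue
        parts = [p.strip() for p in line.split(",")]
        if header is None:
            header = parts
            continue
        rows.append(parts)
    if header is None or tuple(header) != _CSV_COLUMNS:
        missing = set(_CSV_COLUMNS) - set(header or ())
        raise FormatError(
            f"{path.name}: expected columns {_CSV_COLUMNS}, missing {sorted(missing)}",
            field=",".join(sorted(missing)) or "header",
        )
    try:
        data = np.array(rows, dtype=float)
    except ValueError as exc:
        raise FormatError(f"{path.name}: non-numeric sample: {exc}") from exc
    if data.ndim != 2 or data.shape[1] != 7:
        raise FormatError(f"{path.name}: malformed rows")
    acc, gyr = _convert_units(
        data[:, 1:4], data[:, 4:7], meta["units_acc"], meta["units_gyr"]
    )
    return ImuRecording(acc=acc, gyr=gyr, fs=float(meta["fs"]),
                        location=loc, frame=meta["frame"])


def write_session_csv(session: SessionRecording, directory: str | Path) -> None:
    """Write a session as one CSV file per location into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for loc, rec in session.recordings.items():
        t = np.arange(len(rec)) / rec.fs
        lines = [
            f"# fs={rec.fs:g}",
            "# units_acc=g",
            "# units_gyr=dps",
            f"# frame={rec.frame}",
            ",".join(_CSV_COLUMNS),
        ]
        for i in range(len(rec)):
            vals = [t[i], *rec.acc[i], *rec.gyr[i]]
            lines.append(",".join(f"{v:.9g}" for v in vals))
        (directory / f"{loc.value}.csv").write_text("\n".join(lines) + "\n")


def read_session(path: str | Path) -> SessionRecording:
    """Read a session from an HDF5 file or a directory of per-location CSVs."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such session path: {path}")
    if path.is_dir():
        recordings = {}
        for loc in SensorLocation:
            f = path / f"{loc.value}.csv"
            if f.exists():
                recordings[loc] = _read_location_csv(f, loc)
        if not recordings:
            raise FormatError(f"no per-location CSV files found in {path}")
        return SessionRecording(recordings)
    return _read_session_h5(path)


# ---------------------------------------------------------------------------
# Simplified functional calibration
# ---------------------------------------------------------------------------


@dataclass
class CalibrationTransform:
    """Per-location rotation matrices mapping sensor frame to anatomical frame."""

    rotations: dict[SensorLocation, np.ndarray]

    def __post_init__(self):
        self.rotations = {
            SensorLocation(k): np.asarray(v, dtype=float)
            for k, v in self.rotations.items()
        }
        for loc, r in self.rotations.items():
            if r.shape != (3, 3):
                raise InvalidParameterError(f"{loc}: rotation must be 3×3")
            if not np.allclose(r @ r.T, np.eye(3), atol=1e-6):
                raise InvalidParameterError(f"{loc}: rotation must be orthonormal")
            if not np.isclose(np.linalg.det(r), 1.0, atol=1e-6):
                raise InvalidParameterError(f"{loc}: rotation must have det +1")


def estimate_calibration(
    standing: ImuRecording,
    squat: ImuRecording | None = None,
    arm_rotation: ImuRecording | None = None,
    static_tolerance: float = 0.05,
) -> np.ndarray:
    """Estimate one location's sensor→anatomical rotation from calibration moves.

    The anatomical y axis is the mean gravity (reaction) direction during quiet
    upright standing; z is the dominant rotation axis during squatting (trunk,
    head, shank) or arm rotation (wrist), orthogonalized against y; x = y × z.
    The sign of z is taken from the dominant rotation direction.

    Returns the 3×3 rotation R with v_anatomical = R @ v_sensor.
    """
    if len(standing) < 2 * standing.fs:
        raise CalibrationError("standing segment must last at least 2 s")
    norm = np.linalg.norm(standing.acc, axis=1)
    if float(np.std(norm)) > static_tolerance:
        raise CalibrationError(
            f"standing segment is not static (|Acc| sd {np.std(norm):.3f} g "
            f"> {static_tolerance} g)"
        )
    y = standing.acc.mean(axis=0)
    y = y / np.linalg.norm(y)

    rot_seg = arm_rotation if standing.location in (
        SensorLocation.RW, SensorLocation.LW) else squat
    if rot_seg is None:
        raise CalibrationError(
            f"no rotation segment supplied for location {standing.location.value}"
        )
    comps, ratios = principal_components(rot_seg.gyr)
    u = comps[0]
    # dominant rotation direction fixes the sign of the axis
    proj = rot_seg.gyr @ u
    s = np.sign(np.sum(proj**3))
    if s == 0:
        s = 1.0
    z = s * u
    z = z - (z @ y) * y
    nz = np.linalg.norm(z)
    if nz < 1e-6:
        raise CalibrationError("rotation axis is parallel to gravity")
    z = z / nz
    x = np.cross(y, z)
    return np.vstack([x, y, z])


def apply_calibration(
    session: SessionRecording, cal: CalibrationTransform
) -> SessionRecording:
    """Rotate every sample of every present location into the anatomical frame."""
    if session.frame != "sensor":
        raise FrameError("apply_calibration expects a sensor-frame session")
    recordings = {}
    for loc, rec in session.recordings.items():
        if loc not in cal.rotations:
            raise CalibrationError(f"no calibration for present location {loc.value}")
        r = cal.rotations[loc]
        recordings[loc] = ImuRecording(
            acc=rec.acc @ r.T, gyr=rec.gyr @ r.T, fs=rec.fs,
            location=loc, frame="anatomical",
        )
    return SessionRecording(recordings, pool_length=session.pool_length,
                            swimmer_id=session.swimmer_id)
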