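"""Session model, file round-trips, units, and functional calibration."""

import numpy as np
import pytest

from swimseg.errors import (
    CalibrationError,
    FormatError,
    FrameError,
    ValidationError,
)
from swimseg.session import (
    CalibrationTransform,
    GroundTruth,
    ImuRecording,
    LapTruth,
    SensorLocation,
    SessionRecording,
    Technique,
    TurnType,
    apply_calibration,
    estimate_calibration,
    read_annotations,
    read_session,
    write_annotations,
    write_session,
    write_session_csv,
)

G = 9.81


def small_session(frame="anatomical", seed=0):
    rng = np.random.default_rng(seed)
    recordings = {}
    for loc in (SensorLocation.SA, SensorLocation.RW):
        recordings[loc] = ImuRecording(
            acc=rng.normal(0, 1, (100, 3)),
            gyr=rng.normal(0, 50, (100, 3)),
            fs=500.0, location=loc, frame=frame,
        )
    return SessionRecording(recordings, swimmer_id="t01")


class TestSessionIO:
    def test_hdf5_round_trip_bit_exact(self, tmp_path):
        s = small_session()
        p = tmp_path / "s.h5"
        write_session(s, p)
        back = read_session(p)
        for loc in s.recordings:
            assert np.array_equal(back[loc].acc, s[loc].acc)
            assert np.array_equal(back[loc].gyr, s[loc].gyr)
        assert back.swimmer_id == "t01"

    def test_csv_round_trip_and_si_unit_conversion(self, tmp_path):
        s = small_session()
        d = tmp_path / "csvdir"
        write_session_csv(s, d)
        back = read_session(d)
        assert np.allclose(back["SA"].acc, s["SA"].acc, atol=1e-7)

        # hand-convert three samples written in SI units
        f = d / "SA.csv"
        text = f.read_text().replace("# units_acc=g", "# units_acc=m/s2")
        text = text.replace("# units_gyr=dps", "# units_gyr=rad/s")
        f.write_text(text)
        si = read_session(d)
        assert np.allclose(si["SA"].acc[:3], s["SA"].acc[:3] / G, atol=1e-7)
        assert np.allclose(si["SA"].gyr[:3], s["SA"].gyr[:3] * 180 / np.pi,
                           rtol=1e-6)

    def test_missing_columns_raise_format_error(self, tmp_path):
        d = tmp_path / "bad"
        d.mkdir()
        (d / "SA.csv").write_text(
            "# fs=500\nt,acc_x,acc_y,acc_z\n0,0,1,0\n"
        )
        with pytest.raises(FormatError, match="gyr"):
            read_session(d)

    def test_missing_path_raises(self, tmp_path):
        with pytest.raises(FormatError):
            read_session(tmp_path / "nope.h5")


def make_truth():
    return GroundTruth(
        bouts=[(10.0, 40.0)],
        turns=[(25.0, TurnType.TUMBLE)],
        laps=[LapTruth(0, Technique.FRONT_CRAWL, TurnType.TUMBLE,
                       10.5, 10.7, 11.6, 14.0, 25.0)],
    )


class TestAnnotations:
    def test_round_trip_identity(self, tmp_path):
        gt = make_truth()
        p = tmp_path / "gt.json"
        write_annotations(gt, p)
        back = read_annotations(p)
        assert back.bouts == gt.bouts
        assert back.turns == gt.turns
        assert back.laps == gt.laps

    def test_event_order_violation_rejected(self, tmp_path):
        gt = make_truth()
        p = tmp_path / "gt.json"
        write_annotations(gt, p)
        doc = p.read_text().replace('"push_b": 10.5', '"push_b": 12.5')
        p.write_text(doc)
        with pytest.raises(ValidationError, match="lap 0"):
            read_annotations(p)

    def test_empty_session_is_valid(self, tmp_path):
        p = tmp_path / "gt.json"
        write_annotations(GroundTruth(), p)
        back = read_annotations(p)
        assert back.bouts == [] and back.laps == []


def calibration_segments(rotation, loc=SensorLocation.SA, fs=500.0):
    """Ideal standing + squat segments, pre-rotated into a sensor frame."""
    rng = np.random.default_rng(5)
    n = int(3 * fs)
    t = np.arange(n) / fs
    acc_stand = np.zeros((n, 3))
    acc_stand[:, 1] = 1.0
    gyr_squat = np.zeros((n, 3))
    # squat: biased rotation about the anatomical mediolateral axis
    gyr_squat[:, 2] = 60.0 * np.sin(2 * np.pi * 0.5 * t) ** 2
    # measured signals live in the sensor frame: v_S = Rᵀ v_A
    standing = ImuRecording(acc=acc_stand @ rotation + rng.normal(0, 0.005, (n, 3)),
                            gyr=rng.normal(0, 0.5, (n, 3)),
                            fs=fs, location=loc, frame="sensor")
    squat = ImuRecording(acc=acc_stand @ rotation, gyr=gyr_squat @ rotation,
                         fs=fs, location=loc, frame="sensor")
    return standing, squat


def rotation_about(axis, deg):
    axis = np.asarray(axis, float) / np.linalg.norm(axis)
    a = np.deg2rad(deg)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(a) * k + (1 - np.cos(a)) * (k @ k)


class TestCalibration:
    def test_aligned_sensor_gives_identity(self):
        standing, squat = calibration_segments(np.eye(3))
        r = estimate_calibration(standing, squat=squat)
        assert np.allclose(r, np.eye(3), atol=1e-2)

    @pytest.mark.parametrize("axis,deg", [([0, 0, 1], 20), ([1, 1, 0], 35),
                                          ([1, 2, 3], 50)])
    def test_recovers_known_misalignment_within_2_degrees(self, axis, deg):
        true_r = rotation_about(axis, deg)
        standing, squat = calibration_segments(true_r)
        est = estimate_calibration(standing, squat=squat)
        # residual rotation angle between estimate and truth
        resid = est @ true_r.T
        angle = np.rad2deg(np.arccos(np.clip((np.trace(resid) - 1) / 2, -1, 1)))
        assert angle < 2.0

    def test_output_is_proper_rotation(self):
        standing, squat = calibration_segments(rotation_about([1, 0, 1], 30))
        r = estimate_calibration(standing, squat=squat)
        assert np.allclose(r @ r.T, np.eye(3), atol=1e-9)
        assert np.linalg.det(r) == pytest.approx(1.0, abs=1e-9)

    def test_non_static_standing_rejected(self):
        standing, squat = calibration_segments(np.eye(3))
        shaken = ImuRecording(
            acc=standing.acc + np.sin(np.arange(len(standing)))[:, None],
            gyr=standing.gyr, fs=standing.fs,
            location=standing.location, frame="sensor",
        )
        with pytest.raises(CalibrationError, match="static"):
            estimate_calibration(shaken, squat=squat)


class TestApplyCalibration:
    def test_identity_transform_keeps_data(self):
        s = small_session(frame="sensor")
        cal = CalibrationTransform({loc: np.eye(3) for loc in s.recordings})
        out = apply_calibration(s, cal)
        assert out.frame == "anatomical"
        for loc in s.recordings:
            assert np.allclose(out[loc].acc, s[loc].acc)

    def test_norms_preserved_and_inverse_restores(self):
        s = small_session(frame="sensor")
        r = rotation_about([1, 2, 0], 40)
        cal = CalibrationTransform({loc: r for loc in s.recordings})
        out = apply_calibration(s, cal)
        for loc in s.recordings:
            assert np.allclose(np.linalg.norm(out[loc].acc, axis=1),
                               np.linalg.norm(s[loc].acc, axis=1), atol=1e-9)
        inv = CalibrationTransform({loc: r.T for loc in s.recordings})
        back = apply_calibration(
            SessionRecording({loc: ImuRecording(out[loc].acc, out[loc].gyr,
                                                out[loc].fs, loc, "sensor")
                              for loc in out.recordings}), inv)
        for loc in s.recordings:
            assert np.allclose(back[loc].acc, s[loc].acc, atol=1e-9)

    def test_detectors_refuse_sensor_frame(self):
        from swimseg.macro import detect_bouts

        s = small_session(frame="sensor")
        with pytest.raises(FrameError):
            detect_bouts(s, SensorLocation.SA)
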