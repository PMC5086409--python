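"""File format: filenames, round trips, validation, anonymization."""

import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fallsig import (
    FallReport,
    FilenameFields,
    SensorMeta,
    SensorRecording,
    SubjectRecord,
    anonymize,
    format_filename,
    parse_filename,
    read_recording,
    read_signal_file,
    validate_dataset,
    write_recording,
    write_signal_file,
)
from fallsig.signal_io import GRAVITY
from fallsig.timebase import CalendarDateTime

from conftest import constant_recording


# -- filenames ---------------------------------------------------------------


def test_filename_round_trip():
    fields = parse_filename("8f2k1-02-2014-03-09-16-45-12.mat")
    assert fields.random_id == "8f2k1"
    assert fields.fall_number == 2
    assert fields.timestamp == CalendarDateTime(2014, 3, 9, 16, 45, 12)
    assert format_filename(fields) == "8f2k1-02-2014-03-09-16-45-12.mat"


def test_filename_formatting_pads_fall_number():
    fields = FilenameFields("a1", 1, CalendarDateTime(2013, 1, 2, 3, 4, 5))
    assert format_filename(fields) == "a1-01-2013-01-02-03-04-05.mat"
    assert parse_filename(format_filename(fields)) == fields


@pytest.mark.parametrize(
    "bad",
    ["a1-01-2013-01-02-03-04-05",        # no extension
     "a1-2013-01-02-03-04-05.mat",       # missing fall number
     "a1-01-2013-01-02-03-04-xx.mat"],   # non-numeric seconds
)
def test_filename_rejections(bad):
    with pytest.raises(ValueError):
        parse_filename(bad)


# -- fall-file round trips ---------------------------------------------------


def _make_recording(rng, n, fs, with_gyro, with_mag):
    cols = [rng.normal(0.0, 3.0, size=(n, 3)) + [0.0, 0.0, GRAVITY]]
    types = ["accelerometer"]
    if with_gyro:
        cols.append(rng.normal(0.0, 30.0, size=(n, 3)))
        types.append("gyroscope")
    else:
        cols.append(np.full((n, 3), np.nan))
    if with_mag:
        cols.append(rng.normal(20.0, 5.0, size=(n, 3)))
        types.append("magnetometer")
    meta = SensorMeta("testdev", tuple(types), fs, {"accelerometer": 16 * GRAVITY}, "L5")
    return SensorRecording(
        CalendarDateTime(2014, 3, 9, 16, 40, 0),
        np.hstack(cols), meta, frame="uniform",
    )


@settings(max_examples=12, deadline=None, derandomize=True)
@given(
    fs=st.sampled_from([20.0, 100.0]),
    with_gyro=st.booleans(),
    with_mag=st.booleans(),
    fmt=st.sampled_from(["mat", "csv"]),
    seed=st.integers(0, 2**16),
)
def test_write_read_round_trip_bit_exact(tmp_path_factory, fs, with_gyro, with_mag, fmt, seed):
    """Any channel layout, both sample rates, both containers: exact recovery."""
    rng = np.random.default_rng(seed)
    rec = _make_recording(rng, n=200, fs=fs, with_gyro=with_gyro, with_mag=with_mag)
    dest = tmp_path_factory.mktemp("io")
    path = write_signal_file(rec, (57, 4), dest, random_id="rt", fmt=fmt)
    back = read_signal_file(path)
    expect = np.column_stack([
        np.arange(200) / fs,
        rec.start_days() + (np.arange(200) / fs) / 86400.0,
        rec.channels,
        np.eye(1, 200, 57).ravel() * 4,
    ])
    assert np.array_equal(back.matrix, expect, equal_nan=True)
    assert back.indicator == (57, 4)
    assert back.meta is not None and back.meta.sample_rate == fs
    # absent channels come back as NaN sentinels
    if not with_gyro:
        assert np.isnan(back.matrix[:, 5:8]).all()


def test_written_file_layout(tmp_path):
    """Acc-only file: 12 columns, gyro/mag sentinel-filled, one indicator."""
    rng = np.random.default_rng(0)
    rec = _make_recording(rng, n=500, fs=100.0, with_gyro=False, with_mag=False)
    path = write_signal_file(rec, (123, 4), tmp_path, random_id="solo")
    back = read_signal_file(path)
    assert back.matrix.shape[1] == 12
    assert np.isnan(back.matrix[:, 5:11]).all()
    ind = back.matrix[:, 11]
    assert np.count_nonzero(ind) == 1 and ind[123] == 4.0
    # relative and absolute time columns stay consistent (float64 day-number
    # quantum at modern dates is ~1e-5 s)
    drift = (back.matrix[:, 1] - back.matrix[0, 1]) * 86400.0 - back.matrix[:, 0]
    assert np.abs(drift).max() < 1e-4


def test_writer_rejects_raw_frame_and_bad_indicator(tmp_path):
    rng = np.random.default_rng(1)
    rec = _make_recording(rng, 50, 100.0, False, False)
    raw = SensorRecording(rec.start, rec.channels, rec.meta, frame="raw")
    with pytest.raises(ValueError, match="uniform"):
        write_signal_file(raw, (5, 4), tmp_path, "x")
    with pytest.raises(ValueError, match="indicator"):
        write_signal_file(rec, (5, 7), tmp_path, "x")
    with pytest.raises(ValueError, match="outside"):
        write_signal_file(rec, (500, 4), tmp_path, "x")


def test_reader_rejects_wrong_column_count(tmp_path):
    path = tmp_path / "bad-01-2014-03-09-10-00-00.csv"
    header = ",".join(f"c{i}" for i in range(11))
    rows = "\n".join(",".join("1.0" for _ in range(11)) for _ in range(5))
    path.write_text(header + "\n" + rows + "\n")
    with pytest.raises(ValueError, match="column"):
        read_signal_file(path)


def test_reader_rejects_malformed_filename(tmp_path):
    path = tmp_path / "not_a_fall_file.mat"
    path.write_text("x")
    with pytest.raises(ValueError, match="filename"):
        read_signal_file(path)


def test_intermediate_recording_round_trip(tmp_path):
    rng = np.random.default_rng(3)
    rec = _make_recording(rng, 100, 20.0, True, True)
    path = write_recording(rec, tmp_path / "rec.csv")
    back = read_recording(path)
    assert np.array_equal(back.channels, rec.channels, equal_nan=True)
    assert back.frame == "uniform"
    assert back.start == rec.start
    assert back.meta.sample_rate == 20.0


# -- validation --------------------------------------------------------------


def _triple():
    rec = constant_recording([GRAVITY, 0.0, 0.0], n=3000, fs=100.0)
    rec.meta.sensor_range = {"accelerometer": 16 * GRAVITY}
    report = FallReport(fall_date=dt.date(2014, 3, 9), reported_time=dt.time(12, 0))
    subject = SubjectRecord("abc123", sex="female", age_years=76)
    return rec, report, subject


def test_validate_consistent_triple_is_clean():
    assert validate_dataset(*_triple()) == []


def test_validate_flags_uncovered_fall_date():
    rec, report, subject = _triple()
    report = FallReport(fall_date=dt.date(2014, 3, 11))
    issues = validate_dataset(rec, report, subject)
    assert any("fall_date" in i.field and "not covered" in i.rule for i in issues)


def test_validate_flags_untruncated_age():
    rec, report, subject = _triple()
    subject.age_years = 76.9
    issues = validate_dataset(rec, report, subject)
    assert any("age not truncated" in i.rule for i in issues)


def test_validate_flags_range_clipping():
    rec, report, subject = _triple()
    rec.meta.sensor_range = {"accelerometer": 5.0}
    issues = validate_dataset(rec, report, subject)
    assert any("sensor_range" in i.rule for i in issues)


def test_report_time_forms_are_exclusive():
    with pytest.raises(ValueError, match="mutually exclusive"):
        FallReport(fall_date=dt.date(2014, 3, 9),
                   reported_time=dt.time(9, 0), time_of_day="morning")


# -- anonymization -----------------------------------------------------------


def test_anonymize_truncates_age_and_is_deterministic():
    _, report, subject = _triple()
    subject.age_years = 76.9
    subject.source_id = "hospital-0042"
    a1, _ = anonymize(subject, report, seed=5)
    a2, _ = anonymize(subject, report, seed=5)
    a3, _ = anonymize(subject, report, seed=6)
    assert a1.age_years == 76
    assert a1.random_id == a2.random_id != a3.random_id
    assert a1.source_id is None
    assert "hospital-0042" not in a1.to_dict().values()


def test_anonymize_redacts_free_text():
    _, report, subject = _triple()
    report = FallReport(fall_date=dt.date(2014, 3, 9),
                        pre_fall_activity="walking with Mrs Smith",
                        environment="Smith residence hallway")
    _, rep = anonymize(subject, report, seed=0, redactions=["Smith"])
    assert "Smith" not in rep.pre_fall_activity
    assert "Smith" not in rep.environment
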