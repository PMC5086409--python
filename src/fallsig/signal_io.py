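"""Read, write, validate and anonymize harmonized fall-signal files.

The on-disk exchange unit is a samples x 12 numeric matrix:

    1  relative time [s]            7  gyroscope y [deg/s]
    2  absolute time [serial days]  8  gyroscope z [deg/s]
    3  acceleration x [m/s^2]       9  magnetometer x [uT]
    4  acceleration y [m/s^2]      10  magnetometer y [uT]
    5  acceleration z [m/s^2]      11  magnetometer z [uT]
    6  gyroscope x [deg/s]         12  fall indicator value

Column 12 is zero everywhere except at the impact-start sample, which carries
the verification-certainty score (1-4).  Missing gyroscope/magnetometer
channels are stored as NaN sentinel columns so the 12-column layout is fixed
for every consumer.  Two container dialects are supported and auto-detected:
a MAT v5 file holding the matrix plus a metadata struct, and a plain CSV file
with a header row and a YAML metadata sidecar.  File names follow

    <random id>-<fall number>-YYYY-MM-DD-HH-MM-SS.(mat|csv)

with the timestamp taken at the impact-start sample.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import hashlib
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml
from scipy.io import loadmat, savemat

from .timebase import DAY_SECONDS, CalendarDateTime, from_absolute_days, to_absolute_days

__all__ = [
    "GRAVITY",
    "CHANNEL_NAMES",
    "COLUMN_NAMES",
    "TIME_OF_DAY_CATEGORIES",
    "SensorMeta",
    "SubjectRecord",
    "FallReport",
    "SensorRecording",
    "FilenameFields",
    "FallSignalFile",
    "Issue",
    "format_filename",
    "parse_filename",
    "write_signal_file",
    "write_fall_file",
    "read_signal_file",
    "write_recording",
    "read_recording",
    "validate_dataset",
    "anonymize",
]

GRAVITY = 9.81  # m/s^2

CHANNEL_NAMES = (
    "acc_x", "acc_y", "acc_z",
    "gyro_x", "gyro_y", "gyro_z",
    "mag_x", "mag_y", "mag_z",
)

COLUMN_NAMES = (
    "relative_time_s",
    "absolute_time_days",
    "acc_x_ms2", "acc_y_ms2", "acc_z_ms2",
    "gyro_x_degs", "gyro_y_degs", "gyro_z_degs",
    "mag_x_uT", "mag_y_uT", "mag_z_uT",
    "fall_indicator",
)

TIME_OF_DAY_CATEGORIES = ("morning", "noon", "afternoon", "evening", "night")

PLACEMENTS = ("L5", "thigh")
SENSOR_TYPES = ("accelerometer", "gyroscope", "magnetometer")


# ---------------------------------------------------------------------------
# metadata records
# ---------------------------------------------------------------------------


@dataclass
class SensorMeta:
    """Technical description of one sensor recording.

    ``sensor_range`` maps a sensor type to its full-scale value in the unit of
    the stored channel (m/s^2, deg/s, uT).
    """

    device_type: str
    sensor_types: tuple[str, ...] = ("accelerometer",)
    sample_rate: float = 100.0
    sensor_range: dict[str, float] = field(default_factory=dict)
    placement: str = "L5"

    def to_dict(self) -> dict:
        return {
            "device_type": self.device_type,
            "sensor_types": list(self.sensor_types),
            "sample_rate": float(self.sample_rate),
            "sensor_range": {k: float(v) for k, v in self.sensor_range.items()},
            "placement": self.placement,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SensorMeta":
        return cls(
            device_type=str(d["device_type"]),
            sensor_types=tuple(d.get("sensor_types", ("accelerometer",))),
            sample_rate=float(d["sample_rate"]),
            sensor_range=dict(d.get("sensor_range", {})),
            placement=str(d.get("placement", "L5")),
        )


@dataclass
class SubjectRecord:
    """Minimal clinical description of a faller.

    ``random_id`` is an opaque pseudonym; ``icf_codes`` are WHO ICF
    classification codes kept as opaque strings.  ``age_years`` should be a
    whole number of years (aggregation for anonymity); validation flags
    fractional ages.
    """

    random_id: str
    sex: str = "unknown"
    age_years: float = 0
    icf_codes: list[str] = field(default_factory=list)
    source_id: str | None = None

    def to_dict(self) -> dict:
        d = {
            "random_id": self.random_id,
            "sex": self.sex,
            "age_years": self.age_years,
            "icf_codes": list(self.icf_codes),
        }
        if self.source_id is not None:
            d["source_id"] = self.source_id
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SubjectRecord":
        return cls(
            random_id=str(d["random_id"]),
            sex=str(d.get("sex", "unknown")),
            age_years=d.get("age_years", 0),
            icf_codes=list(d.get("icf_codes", [])),
            source_id=d.get("source_id"),
        )


@dataclass
class FallReport:
    """Standardised fall report, to be completed within a day of the fall.

    Exactly one timing form is carried besides the date: an exact clock time
    (``reported_time``), a time-of-day category (``time_of_day``), or neither
    (date-only report).
    """

    fall_date: _dt.date
    reported_time: _dt.time | None = None
    time_of_day: str | None = None
    pre_fall_activity: str = ""
    fall_direction: str = ""
    environment: str = ""
    report_latency_days: float = 0.0

    def __post_init__(self) -> None:
        if self.reported_time is not None and self.time_of_day is not None:
            raise ValueError(
                "reported_time and time_of_day are mutually exclusive"
            )
        if self.time_of_day is not None and self.time_of_day not in TIME_OF_DAY_CATEGORIES:
            raise ValueError(
                f"unknown time-of-day category {self.time_of_day!r}; "
                f"expected one of {TIME_OF_DAY_CATEGORIES}"
            )

    def to_dict(self) -> dict:
        return {
            "fall_date": self.fall_date.isoformat(),
            "reported_time": (
                None if self.reported_time is None
                else self.reported_time.isoformat()
            ),
            "time_of_day": self.time_of_day,
            "pre_fall_activity": self.pre_fall_activity,
            "fall_direction": self.fall_direction,
            "environment": self.environment,
            "report_latency_days": float(self.report_latency_days),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FallReport":
        date = d["fall_date"]
        if isinstance(date, str):
            date = _dt.date.fromisoformat(date)
        t = d.get("reported_time")
        if isinstance(t, str):
            t = _dt.time.fromisoformat(t)
        return cls(
            fall_date=date,
            reported_time=t,
            time_of_day=d.get("time_of_day"),
            pre_fall_activity=str(d.get("pre_fall_activity", "")),
            fall_direction=str(d.get("fall_direction", "")),
            environment=str(d.get("environment", "")),
            report_latency_days=float(d.get("report_latency_days", 0.0)),
        )


# ---------------------------------------------------------------------------
# recordings
# ---------------------------------------------------------------------------


class SensorRecording:
    """A uniformly sampled tri-axial recording with metadata.

    ``channels`` is a samples x 9 float matrix ordered acc x/y/z (m/s^2),
    gyro x/y/z (deg/s), mag x/y/z (uT); channels that were not recorded are
    all-NaN columns.  ``frame`` is ``"raw"`` (device axes) or ``"uniform"``
    (anatomical axes: x vertical, y medio-lateral, z anterior-posterior).
    """

    def __init__(
        self,
        start: CalendarDateTime,
        channels: np.ndarray,
        meta: SensorMeta,
        frame: str = "raw",
    ) -> None:
        channels = np.asarray(channels, dtype=float)
        if channels.ndim != 2 or channels.shape[1] not in (3, 6, 9):
            raise ValueError("channels must be samples x {3,6,9}")
        if channels.shape[1] < 9:
            pad = np.full((channels.shape[0], 9 - channels.shape[1]), np.nan)
            channels = np.hstack([channels, pad])
        if channels.shape[0] < 1:
            raise ValueError("recording must contain at least one sample")
        if frame not in ("raw", "uniform"):
            raise ValueError(f"frame must be 'raw' or 'uniform', got {frame!r}")
        if not np.isfinite(channels[:, :3]).all():
            raise ValueError("accelerometer channels must be present and finite")
        self.start = start
        self.channels = channels
        self.meta = meta
        self.frame = frame

    # -- basic geometry ------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.channels.shape[0]

    @property
    def sample_rate(self) -> float:
        return float(self.meta.sample_rate)

    @property
    def duration_s(self) -> float:
        return (self.n_samples - 1) / self.sample_rate

    @property
    def acc(self) -> np.ndarray:
        return self.channels[:, 0:3]

    @property
    def gyro(self) -> np.ndarray | None:
        block = self.channels[:, 3:6]
        return None if np.isnan(block).all() else block

    @property
    def mag(self) -> np.ndarray | None:
        block = self.channels[:, 6:9]
        return None if np.isnan(block).all() else block

    def times_s(self) -> np.ndarray:
        """Seconds of each sample relative to the first sample."""
        return np.arange(self.n_samples) / self.sample_rate

    def start_days(self) -> float:
        return to_absolute_days(self.start)

    def absolute_days(self) -> np.ndarray:
        """Serial day number of every sample."""
        return self.start_days() + self.times_s() / DAY_SECONDS

    def index_at(self, seconds: float) -> int:
        i = int(round(seconds * self.sample_rate))
        if not (0 <= i < self.n_samples):
            raise ValueError(f"time {seconds} s outside recording")
        return i

    def slice(self, i0: int, i1: int) -> "SensorRecording":
        """Contiguous sub-recording over samples [i0, i1)."""
        if not (0 <= i0 < i1 <= self.n_samples):
            raise ValueError("slice outside recording")
        start = self.start.add_seconds(i0 / self.sample_rate)
        return SensorRecording(start, self.channels[i0:i1].copy(), self.meta, self.frame)

    def with_channels(self, channels: np.ndarray, frame: str | None = None) -> "SensorRecording":
        return SensorRecording(self.start, channels, self.meta, frame or self.frame)


# ---------------------------------------------------------------------------
# filename convention
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FilenameFields:
    random_id: str
    fall_number: int
    timestamp: CalendarDateTime


_FILENAME_RE = re.compile(
    r"^(?P<id>[A-Za-z0-9_]+)-(?P<fall>\d+)-(?P<y>\d{4})-(?P<mo>\d{2})-(?P<d>\d{2})"
    r"-(?P<h>\d{2})-(?P<mi>\d{2})-(?P<s>\d{2})\.(?P<ext>mat|csv)$"
)


def format_filename(fields: FilenameFields, ext: str = "mat") -> str:
    """Build ``<id>-<fall#>-Y-M-D-H-M-S.<ext>`` (fall number zero-padded to 2)."""
    t = fields.timestamp
    return (
        f"{fields.random_id}-{fields.fall_number:02d}-"
        f"{t.year:04d}-{t.month:02d}-{t.day:02d}-"
        f"{t.hour:02d}-{t.minute:02d}-{t.second:02d}.{ext}"
    )


def parse_filename(name: str) -> FilenameFields:
    m = _FILENAME_RE.match(name)
    if m is None:
        raise ValueError(
            f"filename {name!r} does not match "
            "'<id>-<fall number>-YYYY-MM-DD-HH-MM-SS.(mat|csv)'"
        )
    ts = CalendarDateTime(
        int(m["y"]), int(m["mo"]), int(m["d"]),
        int(m["h"]), int(m["mi"]), int(m["s"]),
    )
    return FilenameFields(m["id"], int(m["fall"]), ts)


# ---------------------------------------------------------------------------
# fall signal files
# ---------------------------------------------------------------------------


@dataclass
class FallSignalFile:
    """In-memory image of one standard fall-signal file."""

    matrix: np.ndarray
    filename_fields: FilenameFields
    meta: SensorMeta | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 12:
            raise ValueError(
                f"fall signal matrix must have 12 columns, got shape {m.shape}"
            )
        ind = m[:, 11]
        nz = np.nonzero(ind)[0]
        if nz.size != 1:
            raise ValueError(
                f"fall indicator column must have exactly one nonzero sample, got {nz.size}"
            )
        if ind[nz[0]] not in (1, 2, 3, 4):
            raise ValueError(f"fall indicator value must be in 1..4, got {ind[nz[0]]}")
        if np.any(np.diff(m[:, 0]) < 0):
            raise ValueError("relative-time column must be nondecreasing")
        self.matrix = m

    @property
    def indicator(self) -> tuple[int, int]:
        """(sample index, certainty value) of the impact-start mark."""
        i = int(np.nonzero(self.matrix[:, 11])[0][0])
        return i, int(self.matrix[i, 11])

    def to_recording(self) -> SensorRecording:
        start = from_absolute_days(float(self.matrix[0, 1]))
        meta = self.meta or SensorMeta(device_type="unknown", sample_rate=_infer_rate(self.matrix[:, 0]))
        return SensorRecording(start, self.matrix[:, 2:11], meta, frame="uniform")


def _infer_rate(rel: np.ndarray) -> float:
    if rel.size < 2:
        return 100.0
    return 1.0 / float(np.median(np.diff(rel)))


def build_fall_matrix(recording: SensorRecording, indicator: tuple[int, int]) -> np.ndarray:
    idx, value = indicator
    if not (0 <= idx < recording.n_samples):
        raise ValueError(f"indicator sample {idx} outside recording")
    if value not in (1, 2, 3, 4):
        raise ValueError(f"indicator value must be in 1..4, got {value}")
    rel = recording.times_s()
    absd = recording.start_days() + rel / DAY_SECONDS
    ind = np.zeros(recording.n_samples)
    ind[idx] = value
    return np.column_stack([rel, absd, recording.channels, ind])


def write_signal_file(
    recording: SensorRecording,
    indicator: tuple[int, int],
    dest: str | Path,
    random_id: str,
    fall_number: int = 1,
    fmt: str = "mat",
) -> Path:
    """Write a uniform-frame recording as a standard 12-column fall file.

    The file name is timestamped at the *indicator* (impact-start) sample.
    """
    if recording.frame != "uniform":
        raise ValueError("only uniform-frame recordings may be written as fall files")
    matrix = build_fall_matrix(recording, indicator)
    ts = recording.start.add_seconds(indicator[0] / recording.sample_rate)
    fields = FilenameFields(random_id, fall_number, ts)
    fsf = FallSignalFile(matrix, fields, recording.meta)
    return write_fall_file(fsf, dest, fmt=fmt)


def write_fall_file(fsf: FallSignalFile, dest: str | Path, fmt: str = "mat") -> Path:
    if fmt not in ("mat", "csv"):
        raise ValueError(f"unknown container format {fmt!r}")
    dest = Path(dest)
    dest.mkdir(parents=True, exist_ok=True)
    path = dest / format_filename(fsf.filename_fields, ext=fmt)
    if fmt == "mat":
        payload: dict = {"data": fsf.matrix}
        if fsf.meta is not None:
            payload["meta"] = fsf.meta.to_dict()
        savemat(path, payload, format="5")
    else:
        _write_csv_matrix(path, fsf.matrix, COLUMN_NAMES)
        if fsf.meta is not None:
            path.with_suffix(".yaml").write_text(
                yaml.safe_dump(fsf.meta.to_dict(), sort_keys=False)
            )
    return path


def read_signal_file(path: str | Path) -> FallSignalFile:
    """Read a standard fall-signal file (MAT or CSV, auto-detected)."""
    path = Path(path)
    fields = parse_filename(path.name)
    if path.suffix == ".mat":
        raw = loadmat(path, simplify_cells=True)
        if "data" not in raw:
            raise ValueError(f"{path.name}: MAT container lacks the 'data' matrix")
        matrix = np.atleast_2d(np.asarray(raw["data"], dtype=float))
        meta = SensorMeta.from_dict(raw["meta"]) if "meta" in raw else None
    else:
        matrix = _read_csv_matrix(path, expected_cols=12)
        sidecar = path.with_suffix(".yaml")
        meta = (
            SensorMeta.from_dict(yaml.safe_load(sidecar.read_text()))
            if sidecar.exists()
            else None
        )
    if matrix.shape[1] != 12:
        raise ValueError(
            f"{path.name}: expected 12 columns, found {matrix.shape[1]}"
        )
    if np.any(np.diff(matrix[:, 0]) < 0):
        raise ValueError(f"{path.name}: relative-time column is not monotone")
    return FallSignalFile(matrix, fields, meta)


# ---------------------------------------------------------------------------
# intermediate (pre-verification) recordings
# ---------------------------------------------------------------------------


def write_recording(recording: SensorRecording, path: str | Path) -> Path:
    """Write a recording in the vendor-neutral intermediate form.

    CSV with relative time, absolute day number and the nine channels, plus a
    YAML sidecar holding the sensor metadata, the start time and the frame.
    """
    path = Path(path)
    rel = recording.times_s()
    absd = recording.start_days() + rel / DAY_SECONDS
    matrix = np.column_stack([rel, absd, recording.channels])
    _write_csv_matrix(path, matrix, COLUMN_NAMES[:11])
    sidecar = {
        "meta": recording.meta.to_dict(),
        "frame": recording.frame,
        "start": recording.start.to_datetime().isoformat(timespec="milliseconds"),
    }
    path.with_suffix(".yaml").write_text(yaml.safe_dump(sidecar, sort_keys=False))
    return path


def read_recording(path: str | Path) -> SensorRecording:
    path = Path(path)
    matrix = _read_csv_matrix(path, expected_cols=11)
    sidecar = yaml.safe_load(path.with_suffix(".yaml").read_text())
    meta = SensorMeta.from_dict(sidecar["meta"])
    start = CalendarDateTime.from_datetime(
        _dt.datetime.fromisoformat(sidecar["start"])
    )
    return SensorRecording(start, matrix[:, 2:11], meta, frame=sidecar.get("frame", "raw"))


def _write_csv_matrix(path: Path, matrix: np.ndarray, names: Sequence[str]) -> None:
    # %.17g round-trips IEEE doubles exactly, keeping CSV round trips bit-identical
    np.savetxt(path, matrix, fmt="%.17g", delimiter=",",
               header=",".join(names), comments="")


def _read_csv_matrix(path: Path, expected_cols: int) -> np.ndarray:
    matrix = np.atleast_2d(np.loadtxt(path, delimiter=",", skiprows=1, dtype=float))
    if matrix.shape[1] != expected_cols:
        raise ValueError(
            f"{path.name}: expected {expected_cols} columns, found {matrix.shape[1]}"
        )
    return matrix


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Issue:
    """One data-check finding: which record, which field, which rule."""

    record: str
    field: str
    rule: str

    def __str__(self) -> str:
        return f"{self.record}.{self.field}: {self.rule}"


def validate_dataset(
    recording: SensorRecording | None,
    report: FallReport | None,
    subject: SubjectRecord | None,
) -> list[Issue]:
    """Check the sensor/report/clinical triple for missing values and coding.

    Returns an empty list iff every record invariant holds and the reported
    fall date is covered by the recording.  Issues are data, not exceptions.
    """
    issues: list[Issue] = []
    if recording is not None:
        m = recording.meta
        if "accelerometer" not in m.sensor_types:
            issues.append(Issue("sensor", "sensor_types", "accelerometer missing"))
        if not m.sample_rate > 0:
            issues.append(Issue("sensor", "sample_rate", "must be positive"))
        if m.placement not in PLACEMENTS:
            issues.append(Issue("sensor", "placement",
                                f"unknown placement {m.placement!r}; expected L5 or thigh"))
        for st in m.sensor_types:
            if st not in SENSOR_TYPES:
                issues.append(Issue("sensor", "sensor_types", f"unknown sensor type {st!r}"))
        if not np.isfinite(recording.acc).all():
            issues.append(Issue("signal", "acc", "non-finite accelerometer samples"))
        rng = m.sensor_range.get("accelerometer")
        if rng is not None and np.nanmax(np.abs(recording.acc)) > rng:
            issues.append(Issue("signal", "acc", "samples exceed sensor_range (clipping?)"))
    if subject is not None:
        if not subject.random_id:
            issues.append(Issue("subject", "random_id", "missing"))
        if subject.sex not in ("female", "male", "unknown"):
            issues.append(Issue("subject", "sex", f"uncoded value {subject.sex!r}"))
        if float(subject.age_years) != math.trunc(float(subject.age_years)):
            issues.append(Issue("subject", "age_years", "age not truncated to full years"))
    if report is not None:
        if report.time_of_day is not None and report.time_of_day not in TIME_OF_DAY_CATEGORIES:
            issues.append(Issue("report", "time_of_day", "unknown category"))
        if recording is not None:
            first = recording.start.date
            last = recording.start.add_seconds(recording.duration_s).date
            if not (first <= report.fall_date <= last):
                issues.append(Issue("report", "fall_date",
                                    "fall_date not covered by the recording span"))
    return issues


# ---------------------------------------------------------------------------
# anonymization
# ---------------------------------------------------------------------------

DEFAULT_REDACTIONS: tuple[str, ...] = ()


def _pseudonym(source: str, seed: int) -> str:
    digest = hashlib.sha256(f"{seed}:{source}".encode()).hexdigest()
    return digest[:10]


def anonymize(
    subject: SubjectRecord,
    report: FallReport,
    seed: int = 0,
    redactions: Iterable[str] = DEFAULT_REDACTIONS,
) -> tuple[SubjectRecord, FallReport]:
    """Aggregate and pseudonymize a subject/report pair.

    Any source identifier is replaced by a pseudonym drawn deterministically
    from ``seed`` (stable: same subject and seed give the same pseudonym);
    age is truncated toward zero to whole years; free-text fields are passed
    through the configured redaction list.
    """
    source = subject.source_id or subject.random_id
    new_id = _pseudonym(source, seed)
    subj = dataclasses.replace(
        subject,
        random_id=new_id,
        age_years=math.trunc(float(subject.age_years)),
        source_id=None,
    )
    terms = [t for t in redactions if t]

    def redact(text: str) -> str:
        for term in terms:
            text = re.sub(re.escape(term), "[redacted]", text, flags=re.IGNORECASE)
        return text

    rep = dataclasses.replace(
        report,
        pre_fall_activity=redact(report.pre_fall_activity),
        environment=redact(report.environment),
    )
    return subj, rep
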