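"""Printable per-fall documentation sheets.

One paginated PDF per processed fall: faller summary, fall-report fields,
sensor configuration, and a time-series panel for every available sensor
with the indicator (impact-start) sample marked.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402

from .signal_io import (
    FallReport,
    FallSignalFile,
    SensorMeta,
    SubjectRecord,
    format_filename,
    read_signal_file,
)

__all__ = ["render_documentation"]

_PANELS = (
    ("Acceleration [m/s²]", slice(2, 5)),
    ("Angular rate [°/s]", slice(5, 8)),
    ("Magnetic field [µT]", slice(8, 11)),
)
_AXIS_LABELS = ("vertical", "medio-lateral", "anterior-posterior")
_AXIS_COLORS = ("tab:blue", "tab:green", "tab:red")


def render_documentation(
    fall_file: FallSignalFile | str | Path,
    report: FallReport | None = None,
    subject: SubjectRecord | None = None,
    meta: SensorMeta | None = None,
    out: str | Path | None = None,
) -> Path:
    """Render the documentation sheet for one fall file; returns the PDF path."""
    if not isinstance(fall_file, FallSignalFile):
        fall_file = read_signal_file(fall_file)
    meta = meta or fall_file.meta
    m = fall_file.matrix
    idx, value = fall_file.indicator
    t = m[:, 0]

    import numpy as np

    panels = [
        (title, cols) for title, cols in _PANELS
        if not np.isnan(m[:, cols]).all()
    ]
    fig, axes = plt.subplots(
        len(panels) + 1, 1,
        figsize=(8.27, 11.69),  # A4 portrait
        gridspec_kw={"height_ratios": [1.1] + [2] * len(panels)},
    )
    axes = np.atleast_1d(axes)

    header = axes[0]
    header.axis("off")
    lines = [f"Fall documentation — {format_filename(fall_file.filename_fields)}"]
    if subject is not None:
        lines.append(
            f"Subject {subject.random_id}: {subject.sex}, {subject.age_years} y; "
            f"ICF: {', '.join(subject.icf_codes) or '—'}"
        )
    if report is not None:
        when = (
            report.reported_time.isoformat() if report.reported_time
            else (report.time_of_day or "date only")
        )
        lines.append(
            f"Reported: {report.fall_date.isoformat()} {when}; "
            f"pre-fall activity: {report.pre_fall_activity or '—'}; "
            f"direction: {report.fall_direction or '—'}"
        )
    if meta is not None:
        lines.append(
            f"Sensor: {meta.device_type}, {'+'.join(meta.sensor_types)}, "
            f"{meta.sample_rate:g} Hz, placement {meta.placement}"
        )
    lines.append(f"Verification certainty: {value} (marked at t = {t[idx]:.2f} s)")
    header.text(0.0, 0.95, "\n".join(lines), va="top", ha="left", fontsize=9,
                family="monospace", transform=header.transAxes)

    for ax, (title, cols) in zip(axes[1:], panels):
        block = m[:, cols]
        for j in range(3):
            ax.plot(t, block[:, j], lw=0.6, color=_AXIS_COLORS[j], label=_AXIS_LABELS[j])
        ax.axvline(t[idx], color="k", ls="--", lw=0.8, label=f"indicator = {value}")
        ax.set_ylabel(title, fontsize=8)
        ax.tick_params(labelsize=7)
        ax.legend(fontsize=6, ncol=4, loc="upper right")
    axes[-1].set_xlabel("time since file start [s]", fontsize=8)

    if out is None:
        out = Path(format_filename(fall_file.filename_fields)).with_suffix(".pdf")
    out = Path(out)
    fig.savefig(out, format="pdf")
    plt.close(fig)
    return out
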