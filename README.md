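# fallsig

Tools for harmonizing, verifying and exchanging **real-world fall signals**
recorded by body-worn inertial sensors (accelerometer, optionally gyroscope
and magnetometer) worn at the lower back (L5) or thigh by older adults.

Real-world falls are rare — capturing a hundred of them takes on the order of
300 person-years of continuous recording — so the signals that do exist come
from many studies, devices, sample rates (20 or 100 Hz) and axis conventions,
and the reported time of a fall can be off by hours. `fallsig` implements the
standard operating procedure that turns such heterogeneous material into a
uniform, verified, anonymized archive:

* **Signal file format** — every fall is stored as a samples × 12 matrix:
  relative time [s], absolute time as a serial day number (days since
  January 1st, year 0 = day 1; the fractional part is the fraction of the day,
  so noon ≡ .5), acceleration x/y/z [m/s²], gyroscope x/y/z [°/s],
  magnetometer x/y/z [µT], and a fall-indicator column that is zero except at
  the impact-start sample. Containers: MAT v5 or CSV + YAML sidecar, named
  `RandomID-FallNumber-Year-Month-Day-Hour-Minute-Seconds.{mat,csv}`.
* **Uniform orientation** — raw device axes are rotated by a declared signed
  permutation (optionally refined from quiet-stance gravity) into a common
  anatomical frame: x vertical (upright standing reads ≈ +g ≈ 10 m/s²),
  y medio-lateral, z anterior-posterior (a supine lier reads ≈ +g on z).
* **Fall-event identification** — the impact-phase start is the local minimum
  of the vertical acceleration (the free-fall dip) followed by a rapid rise
  (≥ 1 g within 0.4 s; total magnitude ≥ 2 g), with a sustained
  posture-change fallback when no impact is visible.
* **Verification certainty** — each identified fall is scored 1–4 (or *not
  verifiable*) from the lag between reported and identified time and the
  correspondence of the described pre-fall activity and orientation:
  ±60 min + matching description → 4; matching time-of-day category +
  description → 3; date + description, or ±60 min without description → 2;
  date only → 1; wrong date or multiple same-date candidates → not
  verifiable. Two blinded raters identify independently; disagreement goes
  to an expert panel. The certainty value becomes the fall indicator.
* **Window extraction** — 10 minutes of signal before the impact and at least
  10 minutes after it (extended to cover a later recovery movement).
* **Anonymization** — seeded pseudonyms, ages truncated to whole years,
  configurable free-text redaction.
* **Simulator** — a seeded generator of ADL (standing/walking/sitting/lying)
  recordings with embedded falls following the canonical phase sequence
  (pre-fall activity → falling/free-fall dip → impact → resting → recovery),
  plus fall reports with configurable timing/description corruption. It
  supplies the ground truth that makes the whole procedure testable without
  access to restricted clinical data.

## Worked example

```python
import numpy as np
from fallsig import (FallSpec, ReportErrorModel, SimulationConfig,
                     make_fall_report, simulate_recording, write_fall_file)
from fallsig.workflow import run_sop

cfg = SimulationConfig(
    duration_s=1800.0, sample_rate=100.0, seed=7,
    falls=[FallSpec(time_s=900.0, direction="backward", peak_g=3.0, recovery_s=180.0)],
)
recording, truth = simulate_recording(cfg)
rng = np.random.default_rng(7)
report, _ = make_fall_report(truth.falls[0], ReportErrorModel(lag_sd_min=10.0), rng)
result = run_sop(recording, report, description_corresponds=True, random_id="8f2k1")

print("reported:", report.fall_date, report.reported_time)
print("identified impact:", f"{result.event.time_s:.2f} s",
      f"(truth {truth.falls[0].impact_time_s:.2f} s)")
print("certainty:", result.outcome.certainty, "| status:", result.outcome.status.value)
print("wrote:", write_fall_file(result.fall_file, "falls", fmt="csv"))
```

prints

```
reported: 2014-03-09 08:15:00
identified impact: 899.91 s (truth 900.00 s)
certainty: 4 | status: finally verified
wrote: falls/8f2k1-01-2014-03-09-08-14-59.csv
```

The simulated fall happened at 900 s (08:15:00 clock time); the faller's
report, drawn with a 10-minute-s.d. timing error, still lands within ±60 min
and the description matches, so the fall is finally verified with certainty 4
— the value written into column 12 of the extracted file, which contains
exactly 10 min of pre-fall and 10 min of post-fall signal (the simulated
recovery at +3 min lies inside the 10-minute floor).

The same chain is available from the shell:

```bash
fallsig --seed 11 simulate --out study --subjects 1 --duration 1800 --rate 100
fallsig extract study/sim000-recording.csv \
        --report study/sim000-fall01-report.yaml --out falls --fmt mat
fallsig report falls/anon-01-*.mat --out fall.pdf   # printable documentation sheet
```

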