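# Methods

## Time representation

Absolute time is a *serial day number*: a float counting days since the
reference date January 1st of year 0, which itself carries day number 1 (the
convention of MATLAB's `datenum`, chosen so files interoperate with tools
reading that format). The fractional part is the fraction of the day elapsed
since midnight — noon ≡ .5. Proleptic Gregorian leap rules are applied
uniformly, also before 1582, matching the same convention; the epoch offset
(Python ordinal + 366) is verified in the tests against a brute-force
calendar walk that sums days year by year. Times are opaque local clock
times: fall reports carry no timezone, so none is modelled, and leap seconds
are ignored. Sub-second precision is kept to 1 ms, ten times finer than the
fastest (100 Hz) sample period handled.

A consequence of the serial-day representation worth knowing: at
modern dates (~7.4 × 10⁵ days) an IEEE double resolves about 1 × 10⁻⁵ s, so
the absolute-time column of a written file reproduces the exact relative-time
column only to that quantum. The relative-time column (column 1) is therefore
always computed exactly from the sample index and the sample rate, and the
consistency property between the two columns is asserted at 10⁻⁴ s.

## File format and containers

The exchange matrix has exactly 12 columns (relative seconds; absolute day
number; acc x/y/z in m/s²; gyro x/y/z in °/s; mag x/y/z in µT; fall
indicator). Channels that a device did not record are stored as all-NaN
sentinel columns — the fixed-width layout keeps every consumer trivial, and
NaN cannot be confused with a physical reading. Two containers are
supported and auto-detected by extension: MAT v5 (matrix + metadata struct,
via `scipy.io`) and CSV with a header row plus a YAML metadata sidecar. CSV
floats are printed with `%.17g`, which round-trips IEEE doubles bit-exactly.
Fall numbers in file names are zero-padded to two digits so lexicographic
and chronological order coincide.

## Uniform orientation

The anatomical frame is x = vertical (positive up; upright stance reads
≈ +9.81 m/s² on x), y = medio-lateral, z = anterior-posterior (positive
anterior; supine reads ≈ +9.81 m/s² on z). The mapping from device axes is a
declared signed permutation per placement — the contributing studies perform
no calibration, so nothing finer is assumed. An optional *gravity
refinement* estimates the vertical from the quietest ≥ 2 s window (standard
deviation of the acceleration magnitude below 0.6 m/s²) and applies one
additional static rotation; if no quiet window exists the declared mapping
is kept. Per-sample attitude estimation (sensor fusion) is deliberately out
of scope. Gravity/posture separation uses a 4th-order zero-phase Butterworth
low-pass at 0.25 Hz, which sits well below gait frequencies (~2 Hz) at both
20 and 100 Hz; the tilt angle is measured between the filtered acceleration
vector and the vertical axis.

## Fall-event identification

The impact-phase start is anchored at a local minimum of the vertical
acceleration (median-filtered over 3 samples to kill single-sample noise)
that is followed by a rapid rise. "Rapid" is policy, not physics, and is
configurable; the defaults are: rise ≥ 9.81 m/s² (1 g) within 0.4 s of the
minimum, total-acceleration peak ≥ 2 g within 1 s. At 20 Hz the rise window
widens to 0.5 s because the impact is spread over fewer samples. Candidates
closer than a 5 s refractory period are merged — one fall strikes ground
several times (body, then head or arms) — keeping the candidate with the
largest peak magnitude (earliest on ties). The fast vectorized scan is
checked against a literal per-sample brute-force scan in the tests.

When no impact is visible (soft fall, low sample rate) the event is anchored
at the first sustained posture change: the tilt leaving the upright band
(< 30°), reaching the lying band (> 60°) for at least 5 s, with a total
change ≥ 45°. Ordinary sit-stand transfers (~15° here) stay far below the
threshold.

Report-guided selection searches the reported calendar date, impact
candidates first and posture changes only when no impact exists. Reported
time-of-day categories map to clock intervals morning 06–11, noon 11–14,
afternoon 14–18, evening 18–23, night 23–06 (these are needed to score
category-3 correspondence and for nearest-candidate selection; they are a
package convention). Category reports resolve to the interval midpoint and
date-only reports to noon for nearest-candidate selection.

## Verification certainty

The four category rules overlap as written (a ≤ 60 min lag with a matching
description satisfies both the "4" and the "date + description" part of the
"2" row). The implementation resolves this by precedence 4 → 3 → 2 → 1:
the highest attainable certainty wins, consistent with the table's ordering.
The *not verifiable* guard (wrong date, or > 1 candidate on the same date)
applies before any row. Two deliberate readings of ambiguous corners, both
asserted in tests: an exact reported time within 60 min of the identified
time across midnight counts as a date match (the lag is the stronger
evidence), and a date-only report with a non-corresponding description is
category 1, not *not verifiable* (the date does correspond). The
description-correspondence judgment is an explicit input — in the real
procedure it belongs to human raters; the simulator provides an oracle
stand-in by comparing reported and true pre-fall activity and direction.

Rater agreement tolerance is 5 s between identified impact starts (the
procedure's source is silent; 5 s is far below any plausible inter-fall gap
and far above the inter-rater jitter of a deterministic detector). The
expert-panel verdict is an input and is rejected unless the raters actually
disagree.

## Window extraction

Pre-fall window: 10 min before the impact-start sample. Post-fall: at least
10 min, extended to the recovery movement when that is later ("at least" is
read as a floor, never shortened). Recovery is the earlier of: tilt < 30°
sustained ≥ 10 s, or rolling 2 s variance of the 0.5–3 Hz band-passed
acceleration magnitude exceeding 0.5 (m/s²)² — walking reappearing. The
first 10 s after the impact are excluded so the impact transient itself
cannot count as recovery. Boundaries snap to whole samples toward the
outside; truncation at either end of the source recording is allowed and
logged as a warning. The extracted matrix is a contiguous slice of the
source — no resampling.

## Simulator

The generator produces what the identification/verification/extraction rules
need to be exercised, and no more. Kinematics are piecewise phase templates:
a unit gravity-direction trajectory with raised-cosine (slerp) transitions
between postures, a magnitude envelope for the free-fall dip, and a
half-sine impact spike along a mostly-vertical shock axis. Defaults: g =
9.81 m/s² (plots that say "10 m/s²" show the rounded value); accelerometer
noise 0.2 m/s² per axis; walking as a 2 m/s² vertical oscillation at a
per-recording cadence drawn from 1.5–2.5 Hz; free-fall dip to 2 m/s² total
magnitude over 0.35 s; impact peak 3 g; sitting as a 15° trunk tilt. Falls
specify direction (backward/forward/lateral → end orientation on +z/−z/y),
rest duration, and an optional recovery time; `soft=True` scripts a slow
collapse with no dip or spike, leaving only the posture change. The
gyroscope is the finite-difference angular rate of the orientation
trajectory; the magnetometer is a fixed Earth-field vector (44, 0, 20 µT
when upright) rotated by the same trajectory. All randomness flows from one
seed.

Report corruption models what degrades real fall reports: Gaussian timing
lag (default s.d. 10 min), date errors (±1 day), misdescription of activity
and direction, and degradation of an exact time to a time-of-day category or
to date-only. Setting these probabilities steers reports into every
certainty category, which the tests exploit.

What the simulator does **not** emulate: realistic gait spectra, soft-tissue
and mounting resonances, device clipping/saturation, baseline drift,
disease-specific movement, or multiple wearers' variability. Passing the
seed-pinned recovery bound (≥ 95 % of category-4 truth falls within ±1 s on
a 200-fall study, half at 20 Hz and half at 100 Hz, peaks 3–6 g, 10-minute
single-fall recordings) therefore demonstrates the correctness and
stability of the processing chain under the stated signal model — not field
performance on clinical data.

## Numerical and design notes

* Detection is fully deterministic: identical input and policy give an
  identical candidate list; the blinded "second rater" in the automated
  chain is a re-run and always agrees.
* The local-minimum test is `v[i] <= v[i-1] and v[i] < v[i+1]` (first sample
  of a flat trough wins); forward-window maxima include sample *i*, which is
  provably equivalent at a local minimum and keeps the scan vectorizable.
* Degenerate inputs: recordings shorter than the posture-filter warm-up
  (~25 samples) are rejected; an all-quiet window with zero mean
  acceleration cannot define a vertical and reports refinement unavailable;
  empty candidate lists propagate as "no event" rather than errors.
* Problem sizes in the tests (10-minute recordings for the 200-fall study,
  one 24 h ADL day for the false-positive bound, ≤ 10 000 samples for
  brute-force equivalence) were chosen as the smallest scales at which each
  property is meaningfully exercised.
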