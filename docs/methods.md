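# Methods

## Scope and model

`somnogram` segments an epoch-wise sleep-stage sequence (hypnogram) into
NREM periods (NREMPs) and REM periods (REMPs) with an explicit rule set,
and computes a per-epoch multitaper power spectrum of the accompanying EEG
so that the spectrogram and the hypnogram share one time axis.  There is
no statistical inference anywhere in the core: the segmentation is a
deterministic function of the stage sequence and a small set of duration
thresholds.  The package does not perform automatic sleep staging — stage
annotations are a required input for period detection — and it does not
define explicit "sleep cycle" objects: NREMPs and REMPs are first-class on
their own, because disrupted nights routinely contain consecutive periods
of the same kind that do not pair into cycles.  The rules target children
and adults; newborn sleep has a different architecture and is out of
scope.

## Period rules and their epoch arithmetic

All thresholds are configured in minutes (`DetectionConfig`) and converted
to epoch counts with two fixed conventions: a run of `k` epochs satisfies
an "at least m minutes" rule iff `k·epoch_len ≥ 60m`, and an "exceeding m
minutes" rule iff `k·epoch_len > 60m`.  At the default 30-s epoch this
gives 10 epochs for the 5-min wake-break and stage-transition rules, 3
epochs for the >1-min arousal trigger and 7 for the >3-min lightening
trigger.  The "at least 5 min" transition phrasing and the "longer than
5 min" REMP-minimum phrasing are harmonized to `≥ 300 s`: at 30-s epochs
both bracket the same 10-epoch count, and a single convention keeps every
boundary case exact.

The scan walks maximal same-family runs (families: W; R; N = {N1,N2,N3}).
Design choices where the rules leave room:

* **Onset.** Scanning starts at the first N1/N2 epoch.  A leading N3 run
  with no prior N1/N2 also opens an NREMP but is logged as atypical, since
  period onset is defined via N1/N2.
* **First-R rule.** "The first NREMP ends upon encountering an R stage" is
  applied to *every* NREMP that precedes the first REMP — wake breaks can
  create several of them — so the first R epoch of the night always opens
  the first REMP.
* **Wake breaks.** A qualifying W run closes the current period at its
  last non-wake epoch (boundary epochs are therefore never W) and the next
  period opens at the next non-wake epoch, typed by that epoch's family
  (R → REMP, otherwise NREMP).
* **Merging.** Under-minimum periods are absorbed into the immediately
  preceding period when no qualifying wake run intervenes, else into the
  following one, else dropped (logged); after each absorption, abutting
  same-kind periods coalesce; the process iterates to a fixpoint (bounded
  by the raw period count, since every step removes a period).  The
  "first REMP" exemption is re-resolved each iteration as the REMP with
  the lowest start epoch.
* **Cuts.** Candidates are enumerated for every NREMP whose wake-excluded
  duration exceeds the maximum: arousal cuts at the first epoch of each N3
  run whose immediately preceding W run exceeds 1 min, and lightening cuts
  at the first epoch of each N1 run exceeding 3 min that runs directly
  into N3.  A candidate that would leave either fragment under the 15-min
  NREMP minimum is suppressed, so applying a cut can never re-violate the
  minimum.  The cut lands at the N3 start (arousal) or the N1-run start
  (lightening); when several candidates exist the caller chooses (the CLI
  `--cut` flag replays fixed choices; the default takes the first).  REMPs
  have no maximum duration and are never split.  An over-long NREMP with
  no admissible candidate is kept whole and logged.
* **Duration.** Period duration always excludes internal W epochs.  Short
  internal R epochs inside an NREMP (and N epochs inside a REMP) count
  toward its duration — only wake is excluded.

Two properties worth stating precisely because they are *conditional*:

* Raising the wake-break threshold never increases the number of periods
  the **raw scan** produces (fewer W runs qualify, and every break only
  adds boundaries).  After the merge stage the statement can fail: a large
  threshold can keep one 28-min NREMP intact where a small threshold
  produces two 14-min fragments that are both isolated by wake breaks and
  therefore dropped — 1 period versus 0.  The property test targets the
  scan accordingly.
* Re-running detection on the sequence with leading/trailing/inter-period
  wake removed preserves period kinds and epoch lengths on alternating
  nights; when two same-kind periods flank a removed wake gap they would
  legitimately coalesce into one, so the idempotence test uses alternating
  templates.

## Input handling

Text annotations are two columns (epoch number, stage label), whitespace-
or comma-delimited (auto-detected), `#` comments allowed, any line order;
epoch numbers must be unique and consecutive.  A `StageLabelMap` makes the
vendor vocabulary total: every label maps to one of the five stages or to
`EXCLUDE`; unmapped labels abort a text parse with the complete offender
list.  Excluded epochs behave exactly like unannotated ones — they are
dropped from both the stage and the signal streams before detection, which
means the surviving epochs become adjacent (a deliberate reading of the
"unwanted annotations" filter, e.g. bathroom breaks).

EDF/EDF+ files are read through `mne`; channels are matched tolerantly
against the conventional `EEG <name>` labels, missing requested channels
are reported and the run continues with the intersection (default montage
F3, F4, C3, C4, O1, O2, M1, M2).  Channels with differing sampling rates
are brought to the highest rate on load.  Annotation onsets are snapped to
the epoch grid when within 0.5 s of a grid line; larger offsets raise an
alignment error, since silent shifting would desynchronize the hypnogram
and the spectrogram.  Annotation descriptions not present in the label map
are ignored for EDF input (PSG files carry many non-stage events); a file
with no recognizable stage annotations yields spectrogram-only mode.  A
trailing partial signal epoch is discarded; epochs present in only one
stream are dropped from both.

## Spectral estimation

Per epoch and channel the power spectral density is the plain average of
periodograms computed with orthonormal DPSS (Slepian) tapers —
time-bandwidth product 4, 7 tapers (= 2·TW − 1), giving a half-bandwidth
of ≈ 0.27 Hz over a 30-s window.  Windows coincide with scoring epochs
with no overlap, which is what keeps the spectrogram column-aligned with
the hypnogram; sub-epoch time resolution is deliberately out of scope.
The one-sided density (DC and Nyquist not doubled) is evaluated at the
exact grid frequencies 0, 0.05, …, 45 Hz (901 inclusive points) by padding
the transform to the smallest length whose native bin spacing divides
0.05 Hz; this requires the sampling rate to be commensurate with the grid
step (any integer rate is).  Display conversion is dB re 1 µV²/Hz with a
−60 dB floor (applied to zero power and anything below the floor); floor
and reference are configurable constants.  The optional filters are
zero-phase: an IIR notch (60 Hz, Q 30) and an 8th-order Butterworth
bandpass (0.3–45 Hz), whose forward-backward application gives > 20 dB
attenuation one grid step (5 Hz) past the band edge.  Epoch screening
flags an epoch when any channel exceeds 500 µV in absolute value, when any
channel's standard deviation falls below 0.1 µV (flat/disconnected), or
when its annotation is on the exclusion list; flagged epochs are removed
from both streams before detection and spectral analysis, when filtering
is enabled.

## Synthetic data

The generator exists so the whole pipeline is testable without clinical
recordings; its defaults describe a plausible, unambiguous night rather
than pathology.  A `PeriodTemplate` concatenates NREMP/REMP/wake-gap
blocks with explicit (stage, count) recipes and returns the exact period
intervals detection must recover; validation rejects any template the
rules could segment differently (duration minima and maxima, internal
run-length bounds, no R before the first REMP, unambiguous opening runs
at direct block transitions, wake gaps meeting the break rule).
`random_template` draws valid nights of 1–5 sleep blocks from a seeded
generator.  Synthetic EEG is, per epoch, a sum of stage-keyed sinusoids
plus Gaussian white noise (default σ = 5 µV): alpha-dominant wake
(10 Hz, 20 µV), theta N1 (6 Hz, 15 µV), spindle-band plus slow activity
for N2 (13 and 2.5 Hz, 15 µV), delta-dominant N3 (2 Hz, 30 µV) and
theta-range REM (6.5 Hz, 12 µV) — enough for band power to track stage.
It is explicitly not physiological: no 1/f background, no spindle or
K-complex morphology, no inter-channel covariance.  Passing tests
therefore demonstrate the correctness of the rule arithmetic, alignment
and spectral machinery, not staging performance on real EEG.

The EDF+ writer is a purpose-built serializer (16-bit samples over a
configurable ±1000 µV physical range, one data record per scoring epoch,
stage events as `Sleep stage X` timed-annotation lists).  Values outside
the physical range are clipped; quantization bounds the round-trip error
by one LSB ≈ 0.031 µV, which the round-trip tests assert.

## Problem sizes and numerical choices

The test-suite and acceptance runs use synthetic nights of roughly 90–300
epochs, 1–2 channels at 100–200 Hz, 10⁴ random stage sequences of ≤ 200
epochs for the oracle-equivalence suite and 200 random templates for
recovery — sizes chosen so the full suite completes in well under a
minute while still exercising every rule interaction the generator can
produce.  Duration comparisons carry a 10⁻⁹ tolerance purely to guard
float minute↔second conversions; all interval arithmetic is integer.
Epoch indexing is 0-based with half-open `[start, end)` intervals
throughout.  Degenerate inputs are defined, not special-cased: an all-wake
or empty-after-trim hypnogram yields an empty period list; an empty
candidate list leaves an over-long NREMP whole.

## Known limitations

* Period detection requires stage annotations; no staging from raw EEG.
* Only standard EDF/EDF+ annotations are parsed; vendor-specific dialects
  need a user-supplied text annotation file.
* The multitaper window length, overlap and taper count are declared
  defaults (one epoch, none, 7), not values the method itself pins down;
  they are configurable.
* The rules are inappropriate for newborns.
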