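# somnogram

Rule-based segmentation of overnight sleep recordings into NREM and REM
sleep periods, with a time-matched multitaper EEG spectrogram.

An overnight polysomnography (PSG) study is scored in fixed 30-s epochs,
each annotated with one of five stages — wake (W), N1, N2, N3 or REM (R).
Sleep clinicians and researchers reason about the night in coarser units:
**NREM periods (NREMPs)** and **REM periods (REMPs)**, whose alternation
(the ultradian rhythm) carries diagnostic information about sleep
architecture.  `somnogram` takes the epoch-wise stage sequence (from a
plain-text file or embedded in an EDF/EDF+ recording), applies an explicit
rule set to delimit the NREMPs and REMPs, and — when EEG signals are
available — renders a hypnogram with shaded periods above a spectrogram
that shares its epoch axis, plus text listings and an exportable power
matrix.  It is aimed at sleep researchers who want reproducible,
scriptable period identification without a GUI.

## The rule set

Scanning runs from the first N1/N2 epoch (leading wake/REM is ignored, as
is trailing wake):

* The NREMP(s) before the first REMP end at the **first R epoch**.  After
  that, an NREMP ends at the start of the first REM run of ≥ 5 min, and a
  REMP ends at the start of the first NREM run of ≥ 5 min; shorter foreign
  runs stay inside the period.
* A wake run of ≥ 5 min (**10 epochs** at 30 s) always closes the current
  period, is excised, and a new period opens at the next non-wake epoch.
* An NREMP must last 15–120 min and a REMP ≥ 5 min (no minimum for the
  first REMP), durations always excluding internal wake; under-minimum
  periods merge into an adjacent period or are dropped when isolated by
  wake breaks.
* An NREMP longer than 120 min is split at a user-chosen cut point: an
  *arousal* (first epoch of N3 preceded by > 1 min of wake) or a
  *lightening of sleep* (first epoch of an N1 run > 3 min that runs into
  N3).  REMPs are never split.

The spectrogram is a per-epoch multitaper estimate (7 orthonormal Slepian
tapers, time-bandwidth 4, one 30-s window per scoring epoch, no overlap)
evaluated on a fixed 901-point grid from 0 to 45 Hz in 0.05 Hz steps, in
µV²/Hz (dB re 1 µV²/Hz for display).

## Worked example

Generate a synthetic night with known ground truth, then analyse it:

```sh
$ somnogram simulate --outdir fixture --seed 4
wrote fixture/synthetic.edf (118 epochs, 2 channels, seed 4)

$ somnogram run fixture/synthetic.edf --channels C3 --channels C4 --outdir results
stages  results/stages.tsv
periods results/periods.tsv
log     results/run_log.txt
matrix  results/spectrogram.npz
figure  results/figure.jpg

$ cat results/periods.tsv
ordinal code  kind  start_epoch end_epoch duration_min  start_time  end_time
1 NC1 NREMP 12  52  20.00 22:06:00  22:26:00
2 RC1 REMP  52  64  6.00  22:26:00  22:32:00
3 NC2 NREMP 64  104 20.00 22:32:00  22:52:00
4 RC2 REMP  104 118 7.00  22:52:00  22:59:00
```

The night opens with 12 epochs (6 min) of wake, which the scan ignores, so
the first NREM period `NC1` starts at epoch 12 and lasts 20 min of sleep;
the 12-epoch REM run that follows becomes `RC1`, and so on — exactly the
period structure the simulator embedded.  `stages.tsv` lists every epoch
with its stage and its period assignment (`leading_wake` for the opening
wake epochs), and `spectrogram.npz` holds the power matrix, here shaped
`(118, 901, 2)` — epochs × frequency bins × channels.  The figure stacks
the hypnogram (periods shaded and labelled NC1, RC1, …) over the
spectrogram heatmap on one shared epoch axis.

The same pipeline is available as a library:

```python
from somnogram import DetectionConfig, detect_periods, parse_annotation_text

hypnogram = parse_annotation_text(open("stages.txt"))
result = detect_periods(hypnogram.drop_unscored()[0], DetectionConfig())
for p in result.periods:
    print(p.kind.value, p.start_epoch, p.end_epoch, round(p.duration_min, 1))
```

For a recording whose first NREMP exceeds 120 min, `somnogram cutpoints`
lists the admissible split epochs and `somnogram run --cut K` applies the
K-th candidate non-interactively.

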