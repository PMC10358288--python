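"""Reading sleep-stage annotations and EEG signals, and aligning them into epochs.

Polysomnography scoring divides a night into fixed-length epochs (30 s by
convention) and assigns each epoch one of five stages: wake (W), the three
NREM stages (N1, N2, N3) and REM (R).  This module provides the containers
for that data — :class:`Hypnogram` for the stage sequence and
:class:`SignalRecord` for the multichannel EEG — and the loaders that build
them from a plain-text annotation file or an EDF/EDF+ recording.  Epochs
that carry no usable stage (unannotated, or mapped to ``EXCLUDE`` by the
label map) are dropped from *both* the stage sequence and the signal blocks
so that downstream period detection and spectral analysis stay aligned.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from datetime import datetime
from enum import Enum
from typing import IO, Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger("somnogram")

#: Maximum distance (seconds) between an EDF annotation onset and the epoch
#: grid before the annotation is considered misaligned.  Vendor files jitter
#: by a few samples; a hard tolerance keeps behaviour reproducible.
ANNOTATION_SNAP_TOL_S = 0.5

#: Default EEG montage used when the caller selects no channels.
DEFAULT_CHANNELS = ("F3", "F4", "C3", "C4", "O1", "O2", "M1", "M2")


class SleepStage(str, Enum):
    """The five canonical AASM sleep stages."""

    W = "W"
    N1 = "N1"
    N2 = "N2"
    N3 = "N3"
    R = "R"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Marker a :class:`StageLabelMap` can map a vendor label to in order to
#: exclude the epoch (e.g. "Movement", "Lights on", bathroom breaks).
EXCLUDE = "EXCLUDE"

#: NREM family, used throughout the rule engine.
NREM_STAGES = frozenset({SleepStage.N1, SleepStage.N2, SleepStage.N3})


class StageIOError(ValueError):
    """Raised for malformed annotation or signal inputs."""


def _canonical_default_map() -> dict[str, object]:
    out: dict[str, object] = {}
    for stage in SleepStage:
        out[stage.value] = stage
        out[f"Sleep stage {stage.value}"] = stage
    # common vendor spellings
    out.update(
        {
            "Wake": SleepStage.W,
            "REM": SleepStage.R,
            "Sleep stage 1": SleepStage.N1,
            "Sleep stage 2": SleepStage.N2,
            "Sleep stage 3": SleepStage.N3,
            "Sleep stage 4": SleepStage.N3,
        }
    )
    return out


@dataclass
class StageLabelMap:
    """Total mapping from vendor stage labels to canonical stages.

    A label may map to a :class:`SleepStage` or to :data:`EXCLUDE`; any label
    present in the input but absent from the map is an error, reported with
    the full list of unmapped labels so a user can fix the map in one pass.
    """

    mapping: dict[str, object] = field(default_factory=_canonical_default_map)

    @classmethod
    def from_dict(cls, user: Mapping[str, str], *, extend_default: bool = True) -> "StageLabelMap":
        base = _canonical_default_map() if extend_default else {}
        for label, target in user.items():
            if target == EXCLUDE:
                base[label] = EXCLUDE
            else:
                try:
                    base[label] = SleepStage(target)
                except ValueError as exc:
                    raise StageIOError(
                        f"label map target {target!r} is not one of "
                        f"{[s.value for s in SleepStage]} or {EXCLUDE!r}"
                    ) from exc
        return cls(base)

    def check_total(self, labels: Iterable[str]) -> None:
        unmapped = sorted({lab for lab in labels if lab not in self.mapping})
        if unmapped:
            raise StageIOError(f"unmapped stage labels: {unmapped}")

    def __getitem__(self, label: str) -> object:
        return self.mapping[label]


@dataclass
class Hypnogram:
    """An ordered sequence of per-epoch sleep stages.

    ``stages[i]`` is the stage of 0-based epoch ``i``; ``None`` marks an
    epoch that was unannotated or excluded and must be dropped (together
    with its signal block) before period detection.
    """

    stages: list[SleepStage | None]
    epoch_len_s: float = 30.0
    origin_time: datetime | None = None

    def __post_init__(self) -> None:
        if self.epoch_len_s <= 0:
            raise StageIOError("epoch_len_s must be positive")

    def __len__(self) -> int:
        return len(self.stages)

    @property
    def is_fully_scored(self) -> bool:
        return all(s is not None for s in self.stages)

    def drop_unscored(self) -> tuple["Hypnogram", list[tuple[int, str]]]:
        """Remove ``None`` epochs, reindexing the survivors consecutively.

        Returns the compacted hypnogram and ``(original_index, reason)``
        pairs for every dropped epoch.
        """
        kept = [s for s in self.stages if s is not None]
        dropped = [(i, "unannotated") for i, s in enumerate(self.stages) if s is None]
        return Hypnogram(kept, self.epoch_len_s, self.origin_time), dropped

    def clock_time(self, epoch: int) -> datetime | None:
        if self.origin_time is None:
            return None
        from datetime import timedelta

        return self.origin_time + timedelta(seconds=epoch * self.epoch_len_s)


@dataclass
class SignalRecord:
    """Multichannel EEG voltages in microvolts at one sampling rate."""

    channel_names: list[str]
    fs: float
    samples: np.ndarray  # (n_channels, n_samples), µV

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[0] != len(self.channel_names):
            raise StageIOError(
                f"samples must be (n_channels={len(self.channel_names)}, n_samples), "
                f"got {self.samples.shape}"
            )
        if self.fs <= 0:
            raise StageIOError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    @property
    def duration_s(self) -> float:
        return self.samples.shape[1] / self.fs


@dataclass
class EpochedRecording:
    """Signal blocks and hypnogram cut into the same retained epochs.

    ``epochs`` has shape (n_epochs, n_channels, samples_per_epoch); its i-th
    block corresponds to ``hypnogram.stages[i]``.  ``source_epochs[i]`` is
    the epoch's index in the original (pre-drop) numbering and
    ``dropped_epochs`` records every discarded epoch with its reason.
    """

    hypnogram: Hypnogram
    epochs: np.ndarray
    channel_names: list[str]
    fs: float
    source_epochs: list[int] = field(default_factory=list)
    dropped_epochs: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.epochs.shape[0] != len(self.hypnogram):
            raise StageIOError(
                f"{self.epochs.shape[0]} signal epochs vs "
                f"{len(self.hypnogram)} hypnogram epochs"
            )
        if not self.source_epochs:
            self.source_epochs = list(range(self.epochs.shape[0]))

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    def drop(self, indices: Sequence[int], reasons: Mapping[int, str]) -> "EpochedRecording":
        """Return a copy with the given (current-index) epochs removed from both streams."""
        bad = set(indices)
        keep = [i for i in range(self.n_epochs) if i not in bad]
        dropped = list(self.dropped_epochs)
        for i in sorted(bad):
            dropped.append((self.source_epochs[i], reasons.get(i, "filtered")))
        hyp = Hypnogram(
            [self.hypnogram.stages[i] for i in keep],
            self.hypnogram.epoch_len_s,
            self.hypnogram.origin_time,
        )
        return EpochedRecording(
            hypnogram=hyp,
            epochs=self.epochs[keep],
            channel_names=self.channel_names,
            fs=self.fs,
            source_epochs=[self.source_epochs[i] for i in keep],
            dropped_epochs=dropped,
        )


# ---------------------------------------------------------------------------
# Text annotation parsing
# ---------------------------------------------------------------------------

def parse_annotation_text(
    source: IO[str] | str | Sequence[str],
    label_map: StageLabelMap | None = None,
    epoch_len_s: float = 30.0,
) -> Hypnogram:
    """Parse a two-column (epoch number, stage label) annotation file.

    The delimiter (whitespace or comma) is auto-detected from the first data
    line; ``#``-prefixed lines are comments.  Lines may appear in any order —
    epochs are sorted by number — but the numbers must be unique and
    consecutive from the minimum.  Labels mapped to :data:`EXCLUDE` yield
    ``None`` entries (dropped epochs); unmapped labels abort the parse with
    the complete list of offenders.
    """
    label_map = label_map or StageLabelMap()
    if isinstance(source, str):
        lines = source.splitlines()
    elif hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        lines = list(source)

    rows: list[tuple[int, str, int]] = []  # (epoch, label, line number)
    delimiter: str | None = None
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if delimiter is None:
            delimiter = "," if "," in line else None  # None → any whitespace
        parts = [p.strip() for p in line.split(delimiter)]
        parts = [p for p in parts if p]
        if len(parts) != 2:
            raise StageIOError(f"line {lineno}: expected two columns, got {parts!r}")
        try:
            epoch = int(parts[0])
        except ValueError as exc:
            raise StageIOError(f"line {lineno}: epoch number {parts[0]!r} is not an integer") from exc
        rows.append((epoch, parts[1], lineno))

    if not rows:
        raise StageIOError("annotation file contains no data lines")

    label_map.check_total(lab for _, lab, _ in rows)

    seen: dict[int, int] = {}
    for epoch, _, lineno in rows:
        if epoch in seen:
            raise StageIOError(
                f"duplicate epoch number {epoch} (lines {seen[epoch]} and {lineno})"
            )
        seen[epoch] = lineno

    rows.sort(key=lambda r: r[0])
    first, last = rows[0][0], rows[-1][0]
    if last - first + 1 != len(rows):
        missing = sorted(set(range(first, last + 1)) - set(seen))
        raise StageIOError(f"non-contiguous epoch numbers; missing {missing[:10]}")

    stages: list[SleepStage | None] = []
    n_excluded = 0
    for _, label, _ in rows:
        target = label_map[label]
        if target == EXCLUDE:
            stages.append(None)
            n_excluded += 1
        else:
            stages.append(target)  # type: ignore[arg-type]
    if n_excluded:
        logger.info("parse_annotation_text: %d epochs mapped to EXCLUDE", n_excluded)
    return Hypnogram(stages, epoch_len_s)


# ---------------------------------------------------------------------------
# EDF loading
# ---------------------------------------------------------------------------

def load_recording(
    path,
    channels: Sequence[str] | None = None,
    label_map: StageLabelMap | None = None,
    epoch_len_s: float = 30.0,
) -> tuple[SignalRecord, Hypnogram | None]:
    """Load an EDF/EDF+ file into a :class:`SignalRecord` and, when stage
    annotations are embedded, a :class:`Hypnogram`.

    ``channels`` restricts the record to a montage (default
    :data:`DEFAULT_CHANNELS`); requested channels missing from the file are
    reported and the run continues with the intersection.  Channels sampled
    at different rates are resampled to the highest rate among the selected
    ones.  Returns ``(record, None)`` for a file without stage annotations
    (spectrogram-only mode).
    """
    import mne

    label_map = label_map or StageLabelMap()
    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except FileNotFoundError:
        raise
    except Exception as exc:  # mne raises assorted types for bad files
        raise StageIOError(f"could not read EDF file {path}: {exc}") from exc

    wanted = list(channels) if channels else list(DEFAULT_CHANNELS)
    # EDF labels conventionally carry a signal-type prefix ("EEG C3");
    # match requested names against both the raw and the stripped label.
    lookup: dict[str, str] = {}
    for name in raw.ch_names:
        lookup.setdefault(name.upper(), name)
        stripped = name.upper().removeprefix("EEG ").strip()
        lookup.setdefault(stripped, name)
    present = [lookup[ch.upper()] for ch in wanted if ch.upper() in lookup]
    missing = [ch for ch in wanted if ch.upper() not in lookup]
    if missing:
        logger.warning("channels not in file, continuing without them: %s", missing)
    if not present:
        raise StageIOError(
            f"none of the requested channels {wanted} found; file has {raw.ch_names}"
        )
    raw.pick(present)
    present = [ch.removeprefix("EEG ").strip() for ch in present]
    fs = float(raw.info["sfreq"])  # mne resamples to a common rate on load
    data_uv = raw.get_data() * 1e6  # mne returns volts for EEG channels

    origin = None
    meas_date = raw.info.get("meas_date")
    if meas_date is not None:
        origin = meas_date.replace(tzinfo=None) if hasattr(meas_date, "replace") else None
    record = SignalRecord(channel_names=present, fs=fs, samples=data_uv)

    hypnogram = _hypnogram_from_annotations(raw, label_map, epoch_len_s, origin)
    if hypnogram is not None:
        hypnogram.origin_time = origin
    return record, hypnogram


def _hypnogram_from_annotations(raw, label_map, epoch_len_s, origin) -> Hypnogram | None:
    """Build a hypnogram from mne's annotation list, snapping onsets to the
    epoch grid (tolerance :data:`ANNOTATION_SNAP_TOL_S`)."""
    ann = raw.annotations
    mapped = [
        (float(on), float(dur), label_map[desc])
        for on, dur, desc in zip(ann.onset, ann.duration, ann.description)
        if desc in label_map.mapping
    ]
    if not mapped:
        return None

    n_epochs = int(math.floor(raw.times[-1] / epoch_len_s)) + 1 if len(raw.times) else 0
    stages: list[SleepStage | None] = [None] * n_epochs
    for onset, duration, target in mapped:
        grid = round(onset / epoch_len_s) * epoch_len_s
        if abs(onset - grid) > ANNOTATION_SNAP_TOL_S:
            raise StageIOError(
                f"annotation onset {onset:.2f}s is {abs(onset - grid):.2f}s away from the "
                f"{epoch_len_s}s epoch grid (tolerance {ANNOTATION_SNAP_TOL_S}s)"
            )
        start_epoch = int(round(grid / epoch_len_s))
        span = max(1, int(round(duration / epoch_len_s)))
        for k in range(start_epoch, min(start_epoch + span, n_epochs)):
            stages[k] = None if target == EXCLUDE else target  # type: ignore[assignment]
    return Hypnogram(stages, epoch_len_s, origin)


# ---------------------------------------------------------------------------
# Epoching and alignment
# ---------------------------------------------------------------------------

def epoch_and_align(record: SignalRecord, hypnogram: Hypnogram) -> EpochedRecording:
    """Cut the signal into hypnogram-aligned epochs, dropping unusable ones.

    A trailing partial signal epoch is discarded; epochs present in only one
    stream are dropped from both with reasons ``"no signal"`` or
    ``"no annotation"``; ``None`` stages drop as ``"unannotated"``.
    """
    spe_f = hypnogram.epoch_len_s * record.fs
    spe = int(round(spe_f))
    if abs(spe - spe_f) > 1e-9:
        raise StageIOError(
            f"epoch length {hypnogram.epoch_len_s}s × fs {record.fs}Hz is not an "
            "integer number of samples"
        )
    n_samples = record.samples.shape[1]
    if n_samples < spe:
        raise StageIOError(
            f"signal has {n_samples} samples, less than one {hypnogram.epoch_len_s}s epoch"
        )
    n_sig = n_samples // spe
    leftover = n_samples - n_sig * spe
    if leftover:
        logger.info("discarding trailing partial epoch (%.1f s)", leftover / record.fs)

    n_hyp = len(hypnogram)
    n_common = min(n_sig, n_hyp)
    if n_common == 0:
        raise StageIOError("signal and hypnogram share no epochs")

    dropped: list[tuple[int, str]] = []
    for i in range(n_common, n_hyp):
        dropped.append((i, "no signal"))
    if n_sig > n_hyp:
        logger.info("discarding %d signal epochs beyond the hypnogram", n_sig - n_hyp)

    keep = [i for i in range(n_common) if hypnogram.stages[i] is not None]
    dropped.extend((i, "unannotated") for i in range(n_common) if hypnogram.stages[i] is None)
    if not keep:
        raise StageIOError("no annotated epochs overlap the signal")
    dropped.sort()

    blocks = record.samples[:, : n_common * spe].reshape(record.n_channels, n_common, spe)
    blocks = np.transpose(blocks, (1, 0, 2))  # (epoch, channel, sample)
    hyp = Hypnogram(
        [hypnogram.stages[i] for i in keep], hypnogram.epoch_len_s, hypnogram.origin_time
    )
    return EpochedRecording(
        hypnogram=hyp,
        epochs=blocks[keep],
        channel_names=list(record.channel_names),
        fs=record.fs,
        source_epochs=keep,
        dropped_epochs=dropped,
    )
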