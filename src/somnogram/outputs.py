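"""Figure rendering, text listings, matrix export, and the full pipeline.

A complete run produces up to four artifacts in the output directory:
``figure.<fmt>`` (hypnogram with shaded NC/RC periods over a time-matched
spectrogram heatmap), ``stages.tsv`` (one row per retained epoch),
``periods.tsv`` (one row per detected period), and ``spectrogram.npz``
(the epochs × 901 × channels power matrix with its axes).  Inputs missing
one side degrade gracefully: annotations alone give a hypnogram-only
figure and the two listings; signals without annotations give a
spectrogram-only figure and the matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .period_engine import (
    CutSelector,
    DetectionConfig,
    DetectionResult,
    PeriodKind,
    detect_periods,
    first_candidate_selector,
    find_cut_candidates,
    indexed_selector,
    period_duration,
)
from .spectral import (
    EpochQualityConfig,
    FilterConfig,
    SpectralConfig,
    Spectrogram,
    aggregate_display,
    apply_frequency_filters,
    export_spectrogram,
    flag_bad_epochs,
    multitaper_spectrogram,
)
from .stage_io import (
    DEFAULT_CHANNELS,
    EpochedRecording,
    Hypnogram,
    SleepStage,
    StageLabelMap,
    epoch_and_align,
    load_recording,
    parse_annotation_text,
)

logger = logging.getLogger("somnogram")

# vertical hypnogram ordering, top to bottom: W > R > N1 > N2 > N3
_STAGE_Y = {
    SleepStage.W: 4,
    SleepStage.R: 3,
    SleepStage.N1: 2,
    SleepStage.N2: 1,
    SleepStage.N3: 0,
}
_PERIOD_FACE = {PeriodKind.NREMP: "#9ecae1", PeriodKind.REMP: "#fdae6b"}


@dataclass
class RunConfig:
    """Everything one pipeline invocation needs."""

    edf_path: Path | None = None
    annotation_path: Path | None = None
    outdir: Path = Path(".")
    channels: Sequence[str] = DEFAULT_CHANNELS
    label_map: StageLabelMap = field(default_factory=StageLabelMap)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    filters: FilterConfig = field(default_factory=FilterConfig)
    quality: EpochQualityConfig = field(default_factory=EpochQualityConfig)
    spectral: SpectralConfig = field(default_factory=SpectralConfig)
    cut_indices: Sequence[int] | None = None
    figure_format: str = "jpeg"
    display_method: str = "mean"

    def __post_init__(self) -> None:
        if self.edf_path is None and self.annotation_path is None:
            raise ValueError("need an EDF file, a text annotation file, or both")


def render_figure(
    result: DetectionResult | None,
    display: np.ndarray | None,
    path,
    spectral: SpectralConfig | None = None,
    fmt: str | None = None,
) -> Path:
    """Draw the hypnogram-with-periods and/or spectrogram panels.

    Panels share the epoch axis.  Period intervals are shaded and labelled
    NC1, NC2, … (NREM) and RC1, … (REM).  Format is taken from the file
    suffix unless ``fmt`` is given (jpeg default, png/svg supported).
    """
    if result is None and display is None:
        raise ValueError("nothing to render: no detection result and no spectrogram")
    if result is not None and display is not None:
        if display.shape[0] != len(result.hypnogram):
            raise ValueError(
                f"spectrogram epochs ({display.shape[0]}) do not match the "
                f"hypnogram ({len(result.hypnogram)})"
            )
    spectral = spectral or SpectralConfig()
    n_panels = (result is not None) + (display is not None)
    fig, axes = plt.subplots(
        n_panels, 1, figsize=(12, 3.2 * n_panels), sharex=True, squeeze=False
    )
    axes = axes[:, 0]
    panel = 0

    if result is not None:
        ax = axes[panel]
        panel += 1
        y = [_STAGE_Y[s] for s in result.hypnogram.stages]
        ax.step(np.arange(len(y)), y, where="post", color="black", linewidth=0.8)
        ax.set_yticks(sorted(_STAGE_Y.values()))
        ax.set_yticklabels(
            [s.value for s in sorted(_STAGE_Y, key=_STAGE_Y.get)]
        )
        ax.set_ylabel("stage")
        codes = result.labels_by_kind()
        for p in result.periods:
            ax.axvspan(
                p.start_epoch, p.end_epoch, color=_PERIOD_FACE[p.kind], alpha=0.45
            )
            ax.text(
                (p.start_epoch + p.end_epoch) / 2,
                4.45,
                codes[p.ordinal],
                ha="center",
                va="bottom",
                fontsize=9,
            )
        ax.set_ylim(-0.5, 5.0)
        ax.set_title("Hypnogram with detected sleep periods")

    if display is not None:
        ax = axes[panel]
        ax.imshow(
            display.T,
            origin="lower",
            aspect="auto",
            extent=(0, display.shape[0], spectral.freq_min_hz, spectral.freq_max_hz),
            cmap="magma",
            vmin=spectral.db_floor,
        )
        ax.set_ylabel("frequency (Hz)")
        ax.set_title("Multitaper spectrogram (dB)")

    axes[-1].set_xlabel("epoch")
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".") or "jpeg").lower()
    if fmt == "jpg":
        fmt = "jpeg"
    if fmt not in {"jpeg", "png", "svg"}:
        raise ValueError(f"unsupported figure format {fmt!r}")
    fig.savefig(path, format=fmt, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path


def write_stage_listing(result: DetectionResult, path) -> Path:
    path = Path(path)
    codes = result.labels_by_kind()
    with open(path, "w") as fh:
        fh.write("epoch\tstage\tperiod\n")
        for i, (stage, label) in enumerate(
            zip(result.hypnogram.stages, result.per_epoch_label)
        ):
            fh.write(f"{i}\t{stage.value}\t{label}\n")
    return path


def write_period_listing(result: DetectionResult, path) -> Path:
    path = Path(path)
    codes = result.labels_by_kind()
    has_clock = result.hypnogram.origin_time is not None
    with open(path, "w") as fh:
        header = "ordinal\tcode\tkind\tstart_epoch\tend_epoch\tduration_min"
        if has_clock:
            header += "\tstart_time\tend_time"
        fh.write(header + "\n")
        for p in result.periods:
            row = (
                f"{p.ordinal}\t{codes[p.ordinal]}\t{p.kind.value}\t"
                f"{p.start_epoch}\t{p.end_epoch}\t{p.duration_min:.2f}"
            )
            if has_clock:
                row += (
                    f"\t{result.hypnogram.clock_time(p.start_epoch):%H:%M:%S}"
                    f"\t{result.hypnogram.clock_time(p.end_epoch):%H:%M:%S}"
                )
            fh.write(row + "\n")
    return path


def write_log(result: DetectionResult, dropped: list[tuple[int, str]], path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for idx, reason in dropped:
            fh.write(f"epoch{idx}: dropped ({reason})\n")
        for line in result.log:
            fh.write(line + "\n")
    return path


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute load → filter → detect → spectrogram → write artifacts.

    Returns the artifact paths that were written.  Raises on any component
    error; the CLI converts exceptions into a nonzero exit status.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    record = None
    hypnogram: Hypnogram | None = None
    if config.edf_path is not None:
        record, hypnogram = load_recording(
            config.edf_path,
            channels=config.channels,
            label_map=config.label_map,
            epoch_len_s=config.detection.epoch_len_s,
        )
    if config.annotation_path is not None:
        with open(config.annotation_path) as fh:
            hypnogram = parse_annotation_text(
                fh, config.label_map, config.detection.epoch_len_s
            )

    dropped: list[tuple[int, str]] = []
    result: DetectionResult | None = None
    display = None
    spec: Spectrogram | None = None

    if record is not None:
        if config.filters.apply:
            record = apply_frequency_filters(record, config.filters)
        if hypnogram is None:
            # spectrogram-only mode: every signal epoch is usable
            spe = int(round(config.detection.epoch_len_s * record.fs))
            n = record.samples.shape[1] // spe
            hyp_stub = Hypnogram([SleepStage.W] * n, config.detection.epoch_len_s)
            epoched = epoch_and_align(record, hyp_stub)
            if config.filters.apply:
                mask, reasons = flag_bad_epochs(epoched, config.quality)
                epoched = epoched.drop(np.flatnonzero(mask), reasons)
            spec = multitaper_spectrogram(epoched, config.spectral)
            dropped = epoched.dropped_epochs
        else:
            epoched = epoch_and_align(record, hypnogram)
            if config.filters.apply:
                mask, reasons = flag_bad_epochs(epoched, config.quality)
                epoched = epoched.drop(np.flatnonzero(mask), reasons)
            dropped = epoched.dropped_epochs
            spec = multitaper_spectrogram(epoched, config.spectral)
            hypnogram = epoched.hypnogram
    elif hypnogram is not None:
        hypnogram, dropped = hypnogram.drop_unscored()

    if hypnogram is not None:
        selector: CutSelector = (
            indexed_selector(config.cut_indices)
            if config.cut_indices is not None
            else first_candidate_selector
        )
        result = detect_periods(hypnogram, config.detection, selector)
        artifacts["stages"] = write_stage_listing(result, outdir / "stages.tsv")
        artifacts["periods"] = write_period_listing(result, outdir / "periods.tsv")
        artifacts["log"] = write_log(result, dropped, outdir / "run_log.txt")

    if spec is not None:
        display = aggregate_display(spec, config.display_method, config=config.spectral)
        export_spectrogram(spec, outdir / "spectrogram.npz")
        artifacts["matrix"] = outdir / "spectrogram.npz"

    suffix = "jpg" if config.figure_format == "jpeg" else config.figure_format
    artifacts["figure"] = render_figure(
        result,
        display,
        outdir / f"figure.{suffix}",
        config.spectral,
        fmt=config.figure_format,
    )
    logger.info("pipeline wrote %s", {k: str(v) for k, v in artifacts.items()})
    return artifacts


def list_cut_candidates(config: RunConfig):
    """Detection up to the cut stage: over-long NREMPs and their candidates."""
    from .period_engine import merge_and_coalesce, scan_periods

    if config.annotation_path is not None:
        with open(config.annotation_path) as fh:
            hypnogram = parse_annotation_text(
                fh, config.label_map, config.detection.epoch_len_s
            )
    elif config.edf_path is not None:
        _, hypnogram = load_recording(
            config.edf_path,
            channels=config.channels,
            label_map=config.label_map,
            epoch_len_s=config.detection.epoch_len_s,
        )
        if hypnogram is None:
            raise ValueError("EDF file has no stage annotations")
    else:  # pragma: no cover - RunConfig guards this
        raise ValueError("no input")
    hypnogram, _ = hypnogram.drop_unscored()
    periods = merge_and_coalesce(
        scan_periods(hypnogram, config.detection), hypnogram, config.detection
    )
    out = []
    for p in periods:
        if p.kind is PeriodKind.NREMP and period_duration(p, hypnogram) > config.detection.max_nremp_min:
            out.append((p, find_cut_candidates(p, hypnogram, config.detection)))
    return out
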