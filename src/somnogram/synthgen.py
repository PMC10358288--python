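"""Synthetic hypnograms and EEG with known ground truth.

Real overnight recordings are private clinical data, so every end-to-end
test here runs on synthetic material: a :class:`PeriodTemplate` spells out
a night as ordered NREMP / REMP / wake-gap blocks with explicit stage
recipes, and the generator returns both the concatenated hypnogram and the
exact period intervals the rule engine must recover.  Template validation
enforces the same duration and run-length rules the engine applies, so a
valid template is by construction unambiguous.

EEG is emulated per epoch as a sum of stage-dependent sinusoids (band
centre, amplitude in µV) plus seeded Gaussian white noise — enough
structure for spectral peaks to track stages, with no pretence of
physiological realism (no 1/f background, no spindle morphology).

:func:`write_recording` serialises a record and its stage annotations to
EDF+ (16-bit, one data record per epoch, TAL annotation channel), and the
result round-trips through :func:`somnogram.stage_io.load_recording`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime

import numpy as np

from .period_engine import DetectionConfig, PeriodKind, SleepPeriod
from .stage_io import Hypnogram, NREM_STAGES, SignalRecord, SleepStage

WAKE_GAP = "WAKE_GAP"


class TemplateError(ValueError):
    pass


@dataclass(frozen=True)
class Block:
    """One template block: a period (or wake gap) as (stage, epoch count) runs."""

    kind: str  # "NREMP" | "REMP" | "WAKE_GAP"
    recipe: tuple[tuple[SleepStage, int], ...]

    @property
    def n_epochs(self) -> int:
        return sum(n for _, n in self.recipe)

    def stages(self) -> list[SleepStage]:
        out: list[SleepStage] = []
        for stage, n in self.recipe:
            out.extend([stage] * n)
        return out


def block(kind: str, *recipe: tuple[str | SleepStage, int]) -> Block:
    """Convenience constructor: ``block("NREMP", ("N2", 40), ("W", 3))``."""
    return Block(kind, tuple((SleepStage(s), int(n)) for s, n in recipe))


@dataclass
class PeriodTemplate:
    blocks: list[Block]
    epoch_len_s: float = 30.0
    config: DetectionConfig = field(default_factory=DetectionConfig)

    def __post_init__(self) -> None:
        if abs(self.config.epoch_len_s - self.epoch_len_s) > 1e-9:
            self.config = DetectionConfig(
                **{**self.config.__dict__, "epoch_len_s": self.epoch_len_s}
            )
        _validate_template(self)


def _runs(stages: list[SleepStage]) -> list[tuple[SleepStage, int, int]]:
    out = []
    i = 0
    while i < len(stages):
        j = i
        while j < len(stages) and stages[j] is stages[i]:
            j += 1
        out.append((stages[i], i, j - i))
        i = j
    return out


def _validate_template(template: PeriodTemplate) -> None:
    """Reject any template the rule engine could segment differently."""
    cfg = template.config
    eps = template.epoch_len_s
    seen_remp = False
    prev_sleep_kind: str | None = None
    prev_was_gap = True  # template start behaves like a boundary
    for bi, blk in enumerate(template.blocks):
        name = f"block {bi} ({blk.kind})"
        if blk.n_epochs == 0:
            raise TemplateError(f"{name}: empty block")
        stages = blk.stages()
        if blk.kind == WAKE_GAP:
            if any(s is not SleepStage.W for s in stages):
                raise TemplateError(f"{name}: wake gap must be all W")
            if blk.n_epochs < cfg.wake_break_epochs:
                raise TemplateError(
                    f"{name}: wake gap of {blk.n_epochs} epochs is below the "
                    f"{cfg.wake_break_epochs}-epoch break threshold"
                )
            prev_was_gap = True
            continue
        if blk.kind not in (PeriodKind.NREMP.value, PeriodKind.REMP.value):
            raise TemplateError(f"{name}: unknown block kind")

        dur_s = sum(1 for s in stages if s is not SleepStage.W) * eps
        if stages[0] is SleepStage.W or stages[-1] is SleepStage.W:
            raise TemplateError(f"{name}: period blocks must start and end non-W")

        if blk.kind == PeriodKind.NREMP.value:
            own, foreign = NREM_STAGES, SleepStage.R
            if stages[0] not in {SleepStage.N1, SleepStage.N2}:
                raise TemplateError(f"{name}: an NREMP must open with N1 or N2")
            if not (cfg.min_nremp_min * 60 <= dur_s <= cfg.max_nremp_min * 60):
                raise TemplateError(
                    f"{name}: wake-excluded duration {dur_s / 60:.1f} min outside "
                    f"[{cfg.min_nremp_min}, {cfg.max_nremp_min}] min"
                )
            if not seen_remp and any(s is SleepStage.R for s in stages):
                raise TemplateError(
                    f"{name}: R epochs are not allowed before the first REMP "
                    "(the first R epoch would end the NREMP)"
                )
        else:
            own, foreign = frozenset({SleepStage.R}), None
            if stages[0] is not SleepStage.R:
                raise TemplateError(f"{name}: a REMP must open with R")
            if seen_remp and dur_s < cfg.min_remp_min * 60:
                raise TemplateError(
                    f"{name}: non-first REMP of {dur_s / 60:.1f} min is below the "
                    f"{cfg.min_remp_min}-min minimum"
                )

        # internal runs must stay below the thresholds that would split/end it
        for stage, start, length in _runs(stages):
            if stage is SleepStage.W:
                if length >= cfg.wake_break_epochs:
                    raise TemplateError(
                        f"{name}: internal W run of {length} epochs reaches the break rule"
                    )
            elif stage not in own:
                if length >= cfg.transition_epochs:
                    raise TemplateError(
                        f"{name}: foreign run of {length} {stage} epochs reaches the "
                        "transition rule"
                    )
        # the engine works on stage *families*, so also bound maximal
        # foreign-family runs (e.g. N1+N3 inside a REMP count as one run)
        fams = ["W" if s is SleepStage.W else ("R" if s is SleepStage.R else "N") for s in stages]
        own_fam = "N" if blk.kind == PeriodKind.NREMP.value else "R"
        i = 0
        while i < len(fams):
            j = i
            while j < len(fams) and fams[j] == fams[i]:
                j += 1
            if fams[i] not in ("W", own_fam) and j - i >= cfg.transition_epochs:
                raise TemplateError(
                    f"{name}: foreign family run of {j - i} epochs reaches the transition rule"
                )
            i = j

        # an unambiguous transition needs a long-enough opening run when two
        # sleep blocks abut directly
        if not prev_was_gap and prev_sleep_kind is not None:
            lead_fam = fams[0]
            lead_len = next(i for i in range(len(fams) + 1) if i == len(fams) or fams[i] != lead_fam)
            if prev_sleep_kind == blk.kind:
                raise TemplateError(
                    f"{name}: two adjacent {blk.kind} blocks without a wake gap are one period"
                )
            first_r_transition = blk.kind == PeriodKind.REMP.value and not seen_remp
            if not first_r_transition and lead_len < cfg.transition_epochs:
                raise TemplateError(
                    f"{name}: opening run of {lead_len} epochs cannot trigger the "
                    f"{cfg.transition_epochs}-epoch transition rule"
                )
        if blk.kind == PeriodKind.REMP.value:
            seen_remp = True
        prev_sleep_kind = blk.kind
        prev_was_gap = False

    if prev_sleep_kind is None:
        raise TemplateError("template contains no sleep blocks")
    first_sleep = next(b for b in template.blocks if b.kind != WAKE_GAP)
    if first_sleep.kind != PeriodKind.NREMP.value:
        raise TemplateError("the first sleep block must be an NREMP (leading R is ignored)")


def generate_hypnogram(template: PeriodTemplate) -> tuple[Hypnogram, list[SleepPeriod]]:
    """Concatenate a template into a hypnogram plus its ground-truth periods."""
    stages: list[SleepStage] = []
    truth: list[SleepPeriod] = []
    for blk in template.blocks:
        start = len(stages)
        stages.extend(blk.stages())
        if blk.kind != WAKE_GAP:
            truth.append(SleepPeriod(PeriodKind(blk.kind), start, len(stages)))
    hyp = Hypnogram(stages, template.epoch_len_s)
    for ordinal, p in enumerate(truth, start=1):
        p.ordinal = ordinal
        p.duration_min = (
            sum(1 for s in stages[p.start_epoch : p.end_epoch] if s is not SleepStage.W)
            * template.epoch_len_s
            / 60.0
        )
    return hyp, truth


def random_template(
    seed: int | np.random.Generator,
    n_sleep_blocks: int | None = None,
    config: DetectionConfig | None = None,
    epoch_len_s: float = 30.0,
    alternate_only: bool = False,
) -> PeriodTemplate:
    """Draw a random valid template (recoverable night) from a seeded RNG.

    Every sleep block opens with a pure own-stage run long enough to trigger
    the transition rule, carries short internal decorations (wake, and for
    NREMPs after the first REMP, REM), and respects all duration minima, so
    the rule engine must reproduce the block boundaries exactly.
    ``alternate_only`` restricts the draw to strictly alternating
    NREMP/REMP nights with no same-kind neighbours.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cfg = config or DetectionConfig(epoch_len_s=epoch_len_s)
    n_blocks = n_sleep_blocks or int(rng.integers(1, 6))
    min_nremp_ep = int(math.ceil(cfg.min_nremp_min * 60 / epoch_len_s))
    min_remp_ep = int(math.ceil(cfg.min_remp_min * 60 / epoch_len_s))
    max_nremp_ep = int(cfg.max_nremp_min * 60 // epoch_len_s)

    def decorations(own_pool, allow_r):
        pool = list(own_pool)
        if allow_r:
            pool = pool + [SleepStage.R]
        stage = pool[int(rng.integers(len(pool)))]
        length = int(rng.integers(1, cfg.wake_break_epochs if stage is SleepStage.W
                                  else cfg.transition_epochs))
        return stage, length

    blocks: list[Block] = []
    seen_remp = False
    prev_kind: str | None = None
    if rng.random() < 0.5:
        blocks.append(Block(WAKE_GAP, ((SleepStage.W, int(rng.integers(cfg.wake_break_epochs, 30))),)))
    for b in range(n_blocks):
        if prev_kind is None:
            kind = PeriodKind.NREMP.value  # nights must start with NREM sleep
        elif alternate_only:
            kind = (
                PeriodKind.REMP.value
                if prev_kind == PeriodKind.NREMP.value
                else PeriodKind.NREMP.value
            )
        else:
            kind = PeriodKind.REMP.value if rng.random() < 0.4 else PeriodKind.NREMP.value
        if kind == prev_kind or rng.random() < 0.3:
            blocks.append(
                Block(WAKE_GAP, ((SleepStage.W, int(rng.integers(cfg.wake_break_epochs, 25))),))
            )
        recipe: list[tuple[SleepStage, int]] = []
        if kind == PeriodKind.NREMP.value:
            opener = SleepStage.N2 if rng.random() < 0.8 else SleepStage.N1
            recipe.append((opener, int(rng.integers(cfg.transition_epochs, 2 * min_nremp_ep))))
            for _ in range(int(rng.integers(0, 4))):
                recipe.append(decorations([SleepStage.W, SleepStage.N1, SleepStage.N3], seen_remp))
                recipe.append((SleepStage.N2, int(rng.integers(2, min_nremp_ep))))
            own = sum(n for s, n in recipe if s is not SleepStage.W and s is not SleepStage.R)
            if own < min_nremp_ep:
                recipe.append((SleepStage.N2, min_nremp_ep - own + 1))
            while sum(n for s, n in recipe if s not in (SleepStage.W, SleepStage.R)) > max_nremp_ep:
                recipe.pop()  # pragma: no cover - draw bounds keep this rare
        else:
            recipe.append((SleepStage.R, int(rng.integers(cfg.transition_epochs, 3 * min_remp_ep))))
            for _ in range(int(rng.integers(0, 3))):
                recipe.append(decorations([SleepStage.W, SleepStage.N1, SleepStage.N2], False))
                recipe.append((SleepStage.R, int(rng.integers(2, 2 * min_remp_ep))))
            seen_remp = True
        blocks.append(Block(kind, tuple(recipe)))
        prev_kind = kind
    if rng.random() < 0.5:
        blocks.append(Block(WAKE_GAP, ((SleepStage.W, int(rng.integers(cfg.wake_break_epochs, 30))),)))
    return PeriodTemplate(blocks=blocks, epoch_len_s=epoch_len_s, config=cfg)


# ---------------------------------------------------------------------------
# Synthetic EEG
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StageBandProfile:
    """Per-stage oscillation recipe: (band centre Hz, amplitude µV) pairs."""

    bands: dict[SleepStage, tuple[tuple[float, float], ...]]
    noise_sigma_uv: float = 5.0

    def max_freq(self) -> float:
        centres = [f for pairs in self.bands.values() for f, _ in pairs]
        return max(centres) if centres else 0.0


def default_profile() -> StageBandProfile:
    """Textbook band structure: alpha-dominant wake, theta N1/REM,
    spindle-band N2, delta-dominant N3."""
    return StageBandProfile(
        bands={
            SleepStage.W: ((10.0, 20.0), (22.0, 5.0)),
            SleepStage.N1: ((6.0, 15.0),),
            SleepStage.N2: ((13.0, 15.0), (2.5, 15.0)),
            SleepStage.N3: ((2.0, 30.0),),
            SleepStage.R: ((6.5, 12.0), (4.0, 8.0)),
        },
        noise_sigma_uv=5.0,
    )


def generate_eeg(
    hypnogram: Hypnogram,
    profile: StageBandProfile | None = None,
    fs: float = 200.0,
    n_channels: int = 2,
    seed: int = 0,
) -> SignalRecord:
    """Stage-locked sinusoids plus Gaussian noise; deterministic per seed."""
    profile = profile or default_profile()
    if fs < 2 * profile.max_freq():
        raise TemplateError(
            f"fs {fs} Hz aliases a band centre at {profile.max_freq()} Hz"
        )
    rng = np.random.default_rng(seed)
    spe = int(round(hypnogram.epoch_len_s * fs))
    t = np.arange(spe) / fs
    n_epochs = len(hypnogram)
    out = np.empty((n_channels, n_epochs * spe))
    for i, stage in enumerate(hypnogram.stages):
        if stage is None:
            raise TemplateError("cannot synthesise EEG for unscored epochs")
        seg = rng.normal(0.0, profile.noise_sigma_uv, size=(n_channels, spe))
        for freq, amp in profile.bands.get(stage, ()):
            phases = rng.uniform(0, 2 * np.pi, size=n_channels)
            seg += amp * np.sin(2 * np.pi * freq * t[np.newaxis, :] + phases[:, np.newaxis])
        out[:, i * spe : (i + 1) * spe] = seg
    names = [f"C{k + 3}" if k < 2 else f"EEG{k + 1}" for k in range(n_channels)]
    return SignalRecord(channel_names=names, fs=fs, samples=out)


# ---------------------------------------------------------------------------
# EDF+ writer
# ---------------------------------------------------------------------------

#: Default physical range of the 16-bit EDF signals, µV.
EDF_PHYS_RANGE_UV = 1000.0
_ANNOT_SAMPLES_PER_RECORD = 64  # 128 bytes of TAL space per data record


def _ascii(value, width: int) -> bytes:
    s = f"{value}"
    if len(s) > width:
        raise TemplateError(f"EDF header field {s!r} exceeds {width} bytes")
    return s.ljust(width).encode("ascii")


def _num(value: float, width: int) -> bytes:
    s = f"{value:g}"
    if len(s) > width:
        s = f"{value:.{max(0, width - 8)}e}"
    return _ascii(s, width)


def write_recording(
    record: SignalRecord,
    hypnogram: Hypnogram,
    path,
    phys_range_uv: float = EDF_PHYS_RANGE_UV,
) -> None:
    """Write an EDF+C file with the signals and per-epoch stage annotations.

    One data record per scoring epoch; 16-bit samples over
    ``±phys_range_uv`` µV (values outside are clipped); stages written as
    ``Sleep stage <X>`` timed-annotation events.  The file loads back with
    :func:`somnogram.stage_io.load_recording`.
    """
    if len(hypnogram) == 0:
        raise TemplateError("refusing to write an EDF with an empty hypnogram")
    if not hypnogram.is_fully_scored:
        raise TemplateError("hypnogram must be fully scored to be written")
    spe = int(round(hypnogram.epoch_len_s * record.fs))
    n_records = len(hypnogram)
    if record.samples.shape[1] != n_records * spe:
        raise TemplateError(
            f"signal length {record.samples.shape[1]} does not equal "
            f"{n_records} epochs × {spe} samples"
        )
    if hypnogram.epoch_len_s != int(hypnogram.epoch_len_s):
        raise TemplateError("EDF writer requires an integer epoch length in seconds")

    n_sig = record.n_channels + 1  # + annotations channel
    start = hypnogram.origin_time or datetime(2026, 1, 1, 22, 0, 0)

    header = b"".join(
        [
            _ascii("0", 8),
            _ascii("X X X X", 80),
            _ascii(f"Startdate {start.strftime('%d-%b-%Y').upper()} X X X", 80),
            _ascii(start.strftime("%d.%m.%y"), 8),
            _ascii(start.strftime("%H.%M.%S"), 8),
            _ascii(str(256 * (1 + n_sig)), 8),
            _ascii("EDF+C", 44),
            _ascii(str(n_records), 8),
            _num(hypnogram.epoch_len_s, 8),
            _ascii(str(n_sig), 4),
        ]
    )

    labels = [f"EEG {name}"[:16] for name in record.channel_names] + ["EDF Annotations"]
    transducers = ["AgAgCl electrode"] * record.n_channels + [""]
    dims = ["uV"] * record.n_channels + [""]
    phys_min = [-phys_range_uv] * record.n_channels + [-32768]
    phys_max = [phys_range_uv] * record.n_channels + [32767]
    dig_min = [-32768] * n_sig
    dig_max = [32767] * n_sig
    prefilter = [""] * n_sig
    spr = [spe] * record.n_channels + [_ANNOT_SAMPLES_PER_RECORD]

    def sig_field(values, width, fmt=_ascii):
        return b"".join(fmt(v, width) for v in values)

    header += sig_field(labels, 16)
    header += sig_field(transducers, 80)
    header += sig_field(dims, 8)
    header += sig_field(phys_min, 8, _num)
    header += sig_field(phys_max, 8, _num)
    header += sig_field(dig_min, 8, _num)
    header += sig_field(dig_max, 8, _num)
    header += sig_field(prefilter, 80)
    header += sig_field(spr, 8)
    header += sig_field([""] * n_sig, 32)

    scale = 65535.0 / (2 * phys_range_uv)
    clipped = np.clip(record.samples, -phys_range_uv, phys_range_uv)
    digital = np.round((clipped + phys_range_uv) * scale - 32768.0).astype("<i2")

    eps = hypnogram.epoch_len_s
    with open(path, "wb") as fh:
        fh.write(header)
        for rec in range(n_records):
            for ch in range(record.n_channels):
                fh.write(digital[ch, rec * spe : (rec + 1) * spe].tobytes())
            onset = rec * eps
            tal = f"+{onset:g}\x14\x14\x00".encode("ascii")
            stage = hypnogram.stages[rec]
            tal += (
                f"+{onset:g}\x15{eps:g}\x14Sleep stage {stage.value}\x14\x00".encode("ascii")
            )
            slot = _ANNOT_SAMPLES_PER_RECORD * 2
            if len(tal) > slot:
                raise TemplateError("annotation TAL overflows its record slot")
            fh.write(tal.ljust(slot, b"\x00"))
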