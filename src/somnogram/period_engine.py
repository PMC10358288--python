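"""Rule-based segmentation of a hypnogram into NREM and REM sleep periods.

A night of scored sleep decomposes into alternating NREM periods (NREMPs)
and REM periods (REMPs).  The segmentation here follows an explicit rule
set rather than a statistical model:

* Scanning starts at the first N1/N2 epoch; wake and REM epochs before it
  are ignored, as is wake after the last period.
* The NREMP(s) before the first REMP end at the first R epoch.  Afterwards
  an NREMP ends at the start of the first REM run of at least 5 min, and a
  REMP ends at the start of the first NREM run of at least 5 min; shorter
  foreign runs stay inside the period.
* A wake run of at least 5 min always closes the current period (at its
  last non-wake epoch), is excised, and a new period opens at the next
  non-wake epoch with the type of that epoch's stage.
* An NREMP shorter than 15 min, or a REMP other than the first shorter
  than 5 min, is merged into an adjacent period (preceding first) or
  dropped when wake breaks isolate it; period duration always excludes
  internal wake.
* An NREMP longer than 120 min is split at a user-chosen cut point: either
  an "arousal" (first epoch of an N3 stage preceded by a wake run longer
  than 1 min) or a "lightening of sleep" (first epoch of an N1 run longer
  than 3 min that runs into N3).  REMPs are never split.

All thresholds live in :class:`DetectionConfig` in minutes and convert to
epoch counts via the conventions ``k·epoch_len ≥ m·60`` for "at least m
minutes" and ``k·epoch_len > m·60`` for "exceeding m minutes".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Callable, Sequence

from .stage_io import Hypnogram, NREM_STAGES, SleepStage

__all__ = [
    "PeriodKind",
    "DetectionConfig",
    "SleepPeriod",
    "CutCandidate",
    "DetectionResult",
    "scan_periods",
    "merge_and_coalesce",
    "find_cut_candidates",
    "apply_cut",
    "detect_periods",
    "period_duration",
    "epochs_at_least",
    "epochs_exceeding",
]


class PeriodKind(str, Enum):
    NREMP = "NREMP"
    REMP = "REMP"

    @property
    def code(self) -> str:
        """Figure label prefix: NC for NREM periods, RC for REM periods."""
        return "NC" if self is PeriodKind.NREMP else "RC"


def epochs_at_least(minutes: float, epoch_len_s: float) -> int:
    """Smallest run length (epochs) satisfying an "at least m minutes" rule."""
    return int(math.ceil(minutes * 60.0 / epoch_len_s - 1e-9))


def epochs_exceeding(minutes: float, epoch_len_s: float) -> int:
    """Smallest run length (epochs) satisfying an "exceeding m minutes" rule."""
    return int(math.floor(minutes * 60.0 / epoch_len_s + 1e-9)) + 1


@dataclass(frozen=True)
class DetectionConfig:
    """Every threshold the period rules use, in minutes.

    Defaults: NREMP duration bounds 15–120 min, REMP minimum 5 min (waived
    for the first REMP), wake-break and stage-transition thresholds 5 min,
    arousal cut trigger >1 min of wake, lightening cut trigger >3 min of N1.
    """

    min_nremp_min: float = 15.0
    max_nremp_min: float = 120.0
    min_remp_min: float = 5.0
    wake_break_min: float = 5.0
    transition_run_min: float = 5.0
    arousal_cut_min: float = 1.0
    lightening_cut_min: float = 3.0
    epoch_len_s: float = 30.0

    def __post_init__(self) -> None:
        for name in (
            "min_nremp_min",
            "max_nremp_min",
            "min_remp_min",
            "wake_break_min",
            "transition_run_min",
            "arousal_cut_min",
            "lightening_cut_min",
            "epoch_len_s",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.max_nremp_min <= self.min_nremp_min:
            raise ValueError("max_nremp_min must exceed min_nremp_min")

    # epoch-count views of the thresholds -----------------------------------
    @property
    def wake_break_epochs(self) -> int:
        return epochs_at_least(self.wake_break_min, self.epoch_len_s)

    @property
    def transition_epochs(self) -> int:
        return epochs_at_least(self.transition_run_min, self.epoch_len_s)

    @property
    def arousal_cut_epochs(self) -> int:
        return epochs_exceeding(self.arousal_cut_min, self.epoch_len_s)

    @property
    def lightening_cut_epochs(self) -> int:
        return epochs_exceeding(self.lightening_cut_min, self.epoch_len_s)


@dataclass
class SleepPeriod:
    """A typed, half-open epoch interval ``[start_epoch, end_epoch)``.

    ``duration_min`` excludes internal wake epochs; boundary epochs are
    always non-wake.  ``ordinal`` is the 1-based position in the final
    result (0 before ordinals are assigned).
    """

    kind: PeriodKind
    start_epoch: int
    end_epoch: int
    ordinal: int = 0
    duration_min: float = 0.0

    def __post_init__(self) -> None:
        if self.start_epoch >= self.end_epoch:
            raise ValueError(
                f"empty period interval [{self.start_epoch}, {self.end_epoch})"
            )

    @property
    def n_epochs(self) -> int:
        return self.end_epoch - self.start_epoch


@dataclass(frozen=True)
class CutCandidate:
    """A legal split point inside an over-long NREMP."""

    cut_epoch: int
    kind: str  # "arousal" | "lightening"
    context: tuple[int, int]  # (triggering run start, run length in epochs)


@dataclass
class DetectionResult:
    """Final periods plus a per-epoch account of every input epoch."""

    periods: list[SleepPeriod]
    per_epoch_label: list[str]
    log: list[str]
    hypnogram: Hypnogram

    def labels_by_kind(self) -> dict[int, str]:
        """Map period ordinal → NC1/NC2/…/RC1/… display code."""
        counters = {PeriodKind.NREMP: 0, PeriodKind.REMP: 0}
        out = {}
        for p in self.periods:
            counters[p.kind] += 1
            out[p.ordinal] = f"{p.kind.code}{counters[p.kind]}"
        return out


def period_duration(period: SleepPeriod, hypnogram: Hypnogram) -> float:
    """Wake-excluded duration of ``period`` in minutes."""
    if period.start_epoch < 0 or period.end_epoch > len(hypnogram):
        raise ValueError(
            f"period [{period.start_epoch}, {period.end_epoch}) outside "
            f"hypnogram of {len(hypnogram)} epochs"
        )
    n = sum(
        1
        for s in hypnogram.stages[period.start_epoch : period.end_epoch]
        if s is not SleepStage.W
    )
    return n * hypnogram.epoch_len_s / 60.0


# ---------------------------------------------------------------------------
# Stage-family runs
# ---------------------------------------------------------------------------

_W, _R, _N = "W", "R", "N"


def _family(stage: SleepStage) -> str:
    if stage is SleepStage.W:
        return _W
    if stage is SleepStage.R:
        return _R
    return _N


def _family_runs(stages: Sequence[SleepStage]) -> list[tuple[str, int, int]]:
    """Maximal same-family runs as (family, start, length)."""
    runs: list[tuple[str, int, int]] = []
    i = 0
    n = len(stages)
    while i < n:
        fam = _family(stages[i])
        j = i
        while j < n and _family(stages[j]) == fam:
            j += 1
        runs.append((fam, i, j - i))
        i = j
    return runs


# ---------------------------------------------------------------------------
# Scan
# ---------------------------------------------------------------------------

def scan_periods(
    hypnogram: Hypnogram,
    config: DetectionConfig | None = None,
    log: list[str] | None = None,
) -> list[SleepPeriod]:
    """Scan epochs low→high into raw (pre-merge) periods.

    Returns ordered, disjoint periods whose boundary epochs are non-wake;
    an all-wake or empty hypnogram yields an empty list.
    """
    config = config or DetectionConfig(epoch_len_s=hypnogram.epoch_len_s)
    if log is None:
        log = []
    stages = hypnogram.stages
    if not hypnogram.is_fully_scored:
        raise ValueError("hypnogram has unscored epochs; drop them before detection")

    runs = _family_runs(stages)  # type: ignore[arg-type]
    # onset: first NREM run (leading W/R ignored; an N3 onset is atypical)
    start_run = next((k for k, (fam, _, _) in enumerate(runs) if fam == _N), None)
    if start_run is None:
        return []
    onset = runs[start_run][1]
    if stages[onset] is SleepStage.N3:
        log.append(f"epoch{onset}: scan onset at N3 without preceding N1/N2 (atypical)")

    wake_break = config.wake_break_epochs
    transition = config.transition_epochs

    periods: list[SleepPeriod] = []
    kind = PeriodKind.NREMP
    cur_start = onset
    cur_end = onset  # end of the last non-W run included so far
    seen_remp = False
    open_period = True

    def close() -> None:
        nonlocal open_period
        if open_period and cur_end > cur_start:
            periods.append(SleepPeriod(kind, cur_start, cur_end))
        open_period = False

    for fam, s, length in runs[start_run:]:
        end = s + length
        if not open_period:
            # waiting for the next non-W run after a wake break
            if fam == _W:
                continue
            kind = PeriodKind.REMP if fam == _R else PeriodKind.NREMP
            if kind is PeriodKind.REMP and not seen_remp:
                seen_remp = True
            cur_start, cur_end = s, end
            open_period = True
            log.append(f"epoch{s}: new {kind.value} opened after wake break")
            continue

        if fam == _W:
            if length >= wake_break:
                log.append(
                    f"epoch{s}: wake run of {length} epochs ≥ {wake_break} closes {kind.value}"
                )
                close()
            # shorter W runs are internal and excluded from cur_end
            continue

        if fam == _R:
            if kind is PeriodKind.REMP:
                cur_end = end
            elif not seen_remp:
                log.append(f"epoch{s}: first R epoch ends the NREMP before the first REMP")
                close()
                kind = PeriodKind.REMP
                cur_start, cur_end = s, end
                open_period = True
                seen_remp = True
            elif length >= transition:
                log.append(
                    f"epoch{s}: REM run of {length} epochs ≥ {transition} ends the NREMP"
                )
                close()
                kind = PeriodKind.REMP
                cur_start, cur_end = s, end
                open_period = True
            else:
                cur_end = end  # short internal REM inside an NREMP
        else:  # NREM family
            if kind is PeriodKind.NREMP:
                cur_end = end
            elif length >= transition:
                log.append(
                    f"epoch{s}: NREM run of {length} epochs ≥ {transition} ends the REMP"
                )
                close()
                kind = PeriodKind.NREMP
                cur_start, cur_end = s, end
                open_period = True
            else:
                cur_end = end  # short internal NREM inside a REMP

    close()
    for p in periods:
        p.duration_min = period_duration(p, hypnogram)
    return periods


# ---------------------------------------------------------------------------
# Merge
# ---------------------------------------------------------------------------

def _gap_epochs(a: SleepPeriod, b: SleepPeriod) -> int:
    return b.start_epoch - a.end_epoch


def merge_and_coalesce(
    raw: list[SleepPeriod],
    hypnogram: Hypnogram,
    config: DetectionConfig | None = None,
    log: list[str] | None = None,
) -> list[SleepPeriod]:
    """Absorb under-minimum periods into adjacent ones, to fixpoint.

    An NREMP below the 15-min minimum, or a REMP other than the earliest
    one below the 5-min minimum, merges into the immediately preceding
    period when no wake break intervenes, else into the following one, else
    is dropped.  After each absorption, truly adjacent same-kind periods
    coalesce.  Ordinals are assigned at the end.
    """
    config = config or DetectionConfig(epoch_len_s=hypnogram.epoch_len_s)
    if log is None:
        log = []
    periods = [replace(p) for p in raw]
    wake_break = config.wake_break_epochs
    eps = hypnogram.epoch_len_s

    def dur_s(p: SleepPeriod) -> float:
        return period_duration(p, hypnogram) * 60.0

    def violates(i: int) -> bool:
        p = periods[i]
        if p.kind is PeriodKind.NREMP:
            return dur_s(p) < config.min_nremp_min * 60.0 - 1e-9
        first_remp = min(
            (q.start_epoch for q in periods if q.kind is PeriodKind.REMP), default=None
        )
        if p.start_epoch == first_remp:
            return False  # no minimum for the first REMP
        return dur_s(p) < config.min_remp_min * 60.0 - 1e-9

    def coalesce() -> None:
        i = 0
        while i + 1 < len(periods):
            a, b = periods[i], periods[i + 1]
            if a.kind is b.kind and _gap_epochs(a, b) < wake_break:
                log.append(
                    f"epoch{a.start_epoch}: coalesced adjacent {a.kind.value}s "
                    f"[{a.start_epoch},{a.end_epoch}) + [{b.start_epoch},{b.end_epoch})"
                )
                a.end_epoch = b.end_epoch
                del periods[i + 1]
            else:
                i += 1

    for _ in range(max(1, len(raw))):
        idx = next((i for i in range(len(periods)) if violates(i)), None)
        if idx is None:
            break
        p = periods[idx]
        prev_adj = idx > 0 and _gap_epochs(periods[idx - 1], p) < wake_break
        next_adj = idx + 1 < len(periods) and _gap_epochs(p, periods[idx + 1]) < wake_break
        if prev_adj:
            log.append(
                f"epoch{p.start_epoch}: short {p.kind.value} "
                f"({period_duration(p, hypnogram):.1f} min) absorbed into preceding period"
            )
            periods[idx - 1].end_epoch = p.end_epoch
            del periods[idx]
        elif next_adj:
            log.append(
                f"epoch{p.start_epoch}: short {p.kind.value} "
                f"({period_duration(p, hypnogram):.1f} min) absorbed into following period"
            )
            periods[idx + 1].start_epoch = p.start_epoch
            del periods[idx]
        else:
            log.append(
                f"epoch{p.start_epoch}: short {p.kind.value} "
                f"({period_duration(p, hypnogram):.1f} min) isolated by wake breaks; dropped"
            )
            del periods[idx]
        coalesce()

    for ordinal, p in enumerate(periods, start=1):
        p.ordinal = ordinal
        p.duration_min = period_duration(p, hypnogram)
    return periods


# ---------------------------------------------------------------------------
# Cuts
# ---------------------------------------------------------------------------

def find_cut_candidates(
    period: SleepPeriod,
    hypnogram: Hypnogram,
    config: DetectionConfig | None = None,
    log: list[str] | None = None,
) -> list[CutCandidate]:
    """Enumerate legal split points for an over-long NREMP, in epoch order.

    An *arousal* candidate cuts at the first epoch of an N3 stage whose
    immediately preceding wake run exceeds 1 min; a *lightening* candidate
    cuts at the first epoch of an N1 run that exceeds 3 min and runs
    directly into N3.  Candidates that would leave either fragment under
    the 15-min NREMP minimum are suppressed.
    """
    config = config or DetectionConfig(epoch_len_s=hypnogram.epoch_len_s)
    if log is None:
        log = []
    if period.kind is not PeriodKind.NREMP:
        raise ValueError("cut candidates exist only for NREMPs")
    if period_duration(period, hypnogram) <= config.max_nremp_min + 1e-9:
        return []

    stages = hypnogram.stages
    s0, s1 = period.start_epoch, period.end_epoch
    arousal_n = config.arousal_cut_epochs
    lightening_n = config.lightening_cut_epochs
    eps = hypnogram.epoch_len_s
    min_frag_s = config.min_nremp_min * 60.0

    candidates: list[CutCandidate] = []
    i = s0
    while i < s1:
        stage = stages[i]
        j = i
        while j < s1 and stages[j] is stage:
            j += 1
        run_len = j - i
        if stage is SleepStage.N3 and i > s0:
            # length of the W run ending right before this N3
            k = i
            while k > s0 and stages[k - 1] is SleepStage.W:
                k -= 1
            if i - k >= arousal_n:
                candidates.append(CutCandidate(i, "arousal", (k, i - k)))
        if (
            stage is SleepStage.N1
            and run_len >= lightening_n
            and j < s1
            and stages[j] is SleepStage.N3
            and i > s0
        ):
            candidates.append(CutCandidate(i, "lightening", (i, run_len)))
        i = j

    kept: list[CutCandidate] = []
    for cand in candidates:
        left = sum(
            1 for s in stages[s0 : cand.cut_epoch] if s is not SleepStage.W
        ) * eps
        right = sum(
            1 for s in stages[cand.cut_epoch : s1] if s is not SleepStage.W
        ) * eps
        if left < min_frag_s - 1e-9 or right < min_frag_s - 1e-9:
            log.append(
                f"epoch{cand.cut_epoch}: {cand.kind} cut suppressed "
                "(fragment below the NREMP minimum)"
            )
        else:
            kept.append(cand)
    return kept


def apply_cut(
    periods: list[SleepPeriod],
    parent: SleepPeriod,
    candidate: CutCandidate,
    hypnogram: Hypnogram,
    config: DetectionConfig | None = None,
    log: list[str] | None = None,
) -> list[SleepPeriod]:
    """Replace ``parent`` by the two NREMP fragments around ``candidate``.

    Trailing wake is trimmed from the left fragment and leading wake from
    the right one; ordinals are reassigned.  ``candidate`` must be one the
    parent actually admits (contract enforced by re-derivation).
    """
    config = config or DetectionConfig(epoch_len_s=hypnogram.epoch_len_s)
    if log is None:
        log = []
    legal = find_cut_candidates(parent, hypnogram, config)
    if candidate not in legal:
        raise ValueError(
            f"cut candidate {candidate} was not generated for period "
            f"[{parent.start_epoch},{parent.end_epoch})"
        )
    stages = hypnogram.stages
    cut = candidate.cut_epoch
    left_end = cut
    while left_end > parent.start_epoch and stages[left_end - 1] is SleepStage.W:
        left_end -= 1
    right_start = cut
    while right_start < parent.end_epoch and stages[right_start] is SleepStage.W:
        right_start += 1
    log.append(
        f"epoch{cut}: {candidate.kind} cut applied; "
        f"[{parent.start_epoch},{left_end}) + [{right_start},{parent.end_epoch})"
    )
    fragments = [
        SleepPeriod(PeriodKind.NREMP, parent.start_epoch, left_end),
        SleepPeriod(PeriodKind.NREMP, right_start, parent.end_epoch),
    ]
    out: list[SleepPeriod] = []
    replaced = False
    for p in periods:
        if p.start_epoch == parent.start_epoch and p.end_epoch == parent.end_epoch:
            out.extend(fragments)
            replaced = True
        else:
            out.append(replace(p))
    if not replaced:
        raise ValueError("parent period not present in the period list")
    out.sort(key=lambda p: p.start_epoch)
    for ordinal, p in enumerate(out, start=1):
        p.ordinal = ordinal
        p.duration_min = period_duration(p, hypnogram)
    return out


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

#: A cut selector maps (period, candidates) → the chosen candidate.
CutSelector = Callable[[SleepPeriod, list[CutCandidate]], CutCandidate]


def first_candidate_selector(period: SleepPeriod, candidates: list[CutCandidate]) -> CutCandidate:
    return candidates[0]


def indexed_selector(indices: Sequence[int]) -> CutSelector:
    """Selector replaying a fixed list of candidate indices (CLI --cut)."""
    queue = list(indices)

    def select(period: SleepPeriod, candidates: list[CutCandidate]) -> CutCandidate:
        idx = queue.pop(0) if queue else 0
        if not 0 <= idx < len(candidates):
            raise ValueError(
                f"cut index {idx} out of range; period "
                f"[{period.start_epoch},{period.end_epoch}) has {len(candidates)} candidates"
            )
        return candidates[idx]

    return select


def detect_periods(
    hypnogram: Hypnogram,
    config: DetectionConfig | None = None,
    cut_selector: CutSelector = first_candidate_selector,
) -> DetectionResult:
    """Run the full rule set: scan → merge → split over-long NREMPs.

    Deterministic for a fixed selector.  The result carries every input
    epoch's assignment: its period, or one of ``leading_wake``,
    ``trailing_wake``, ``inter_period_wake``, ``unassigned``.
    """
    config = config or DetectionConfig(epoch_len_s=hypnogram.epoch_len_s)
    log: list[str] = []
    raw = scan_periods(hypnogram, config, log)
    periods = merge_and_coalesce(raw, hypnogram, config, log)

    guard = 0
    while True:
        overlong = next(
            (
                p
                for p in periods
                if p.kind is PeriodKind.NREMP
                and period_duration(p, hypnogram) > config.max_nremp_min + 1e-9
                and find_cut_candidates(p, hypnogram, config)
            ),
            None,
        )
        if overlong is None:
            break
        candidates = find_cut_candidates(overlong, hypnogram, config, log)
        chosen = cut_selector(overlong, candidates)
        periods = apply_cut(periods, overlong, chosen, hypnogram, config, log)
        guard += 1
        if guard > len(hypnogram):  # pragma: no cover - defensive
            raise RuntimeError("cut loop failed to terminate")
    for p in periods:
        if (
            p.kind is PeriodKind.NREMP
            and period_duration(p, hypnogram) > config.max_nremp_min + 1e-9
        ):
            log.append(
                f"epoch{p.start_epoch}: NREMP of {period_duration(p, hypnogram):.1f} min "
                "exceeds the maximum but admits no cut point"
            )

    labels = _per_epoch_labels(hypnogram, periods)
    return DetectionResult(periods=periods, per_epoch_label=labels, log=log, hypnogram=hypnogram)


def _per_epoch_labels(hypnogram: Hypnogram, periods: list[SleepPeriod]) -> list[str]:
    n = len(hypnogram)
    labels = ["unassigned"] * n
    if not periods:
        for i, s in enumerate(hypnogram.stages):
            if s is SleepStage.W:
                labels[i] = "leading_wake"
        return labels
    display: dict[int, str] = {}
    counters = {PeriodKind.NREMP: 0, PeriodKind.REMP: 0}
    for p in periods:
        counters[p.kind] += 1
        code = f"{p.kind.code}{counters[p.kind]}"
        for i in range(p.start_epoch, p.end_epoch):
            labels[i] = code
    first, last = periods[0].start_epoch, periods[-1].end_epoch
    for i, s in enumerate(hypnogram.stages):
        if labels[i] != "unassigned":
            continue
        if s is SleepStage.W:
            if i < first:
                labels[i] = "leading_wake"
            elif i >= last:
                labels[i] = "trailing_wake"
            else:
                labels[i] = "inter_period_wake"
    return labels
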