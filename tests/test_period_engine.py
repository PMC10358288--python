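"""Rule-engine behaviour: scanning, merging, cutting, and their invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import hyp, random_stage_sequence
from reference_engine import reference_detect
from somnogram import (
    CutCandidate,
    DetectionConfig,
    Hypnogram,
    PeriodKind,
    SleepPeriod,
    SleepStage,
    apply_cut,
    detect_periods,
    epochs_at_least,
    epochs_exceeding,
    find_cut_candidates,
    indexed_selector,
    merge_and_coalesce,
    period_duration,
    scan_periods,
)
from somnogram.stage_io import NREM_STAGES


def intervals(periods):
    return [(p.kind.value, p.start_epoch, p.end_epoch) for p in periods]


def assert_period_invariants(periods, hypnogram, config):
    """Every final period: non-W boundaries, no internal qualifying wake run,
    ordered disjoint intervals, and no R before the first REMP."""
    stages = hypnogram.stages
    prev_end = -1
    first_remp = min(
        (p.start_epoch for p in periods if p.kind is PeriodKind.REMP), default=None
    )
    for p in periods:
        assert p.start_epoch < p.end_epoch
        assert p.start_epoch > prev_end or prev_end == -1 or p.start_epoch >= prev_end
        prev_end = p.end_epoch
        assert stages[p.start_epoch] is not SleepStage.W
        assert stages[p.end_epoch - 1] is not SleepStage.W
        run = 0
        for s in stages[p.start_epoch : p.end_epoch]:
            run = run + 1 if s is SleepStage.W else 0
            assert run < config.wake_break_epochs
        if first_remp is not None and p.kind is PeriodKind.NREMP and p.end_epoch <= first_remp:
            assert all(
                s is not SleepStage.R for s in stages[p.start_epoch : p.end_epoch]
            )


# ---------------------------------------------------------------------------
# threshold conversion
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "minutes, epoch_len, at_least, exceeding",
    [
        (5.0, 30.0, 10, 11),
        (1.0, 30.0, 2, 3),
        (3.0, 30.0, 6, 7),
        (5.0, 20.0, 15, 16),
        (0.5, 30.0, 1, 2),
    ],
)
def test_minute_rules_convert_to_epoch_counts(minutes, epoch_len, at_least, exceeding):
    assert epochs_at_least(minutes, epoch_len) == at_least
    assert epochs_exceeding(minutes, epoch_len) == exceeding


def test_config_rejects_inverted_duration_bounds():
    with pytest.raises(ValueError):
        DetectionConfig(min_nremp_min=120, max_nremp_min=15)


# ---------------------------------------------------------------------------
# scan
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "runs, expected",
    [
        # leading wake ignored; first R ends the first NREMP; long NREM run
        # ends the REMP; trailing wake ignored
        (
            (("W", 10), ("N2", 40), ("R", 12), ("N2", 40), ("W", 5)),
            [("NREMP", 10, 50), ("REMP", 50, 62), ("NREMP", 62, 102)],
        ),
        # a ≥10-epoch wake run splits the NREMP and is excised
        (
            (("N2", 30), ("W", 12), ("N2", 34)),
            [("NREMP", 0, 30), ("NREMP", 42, 76)],
        ),
        # all wake → no sleep periods
        ((("W", 100),), []),
        # wake run just under the threshold stays inside the period
        (
            (("N2", 30), ("W", 9), ("N2", 34)),
            [("NREMP", 0, 73)],
        ),
        # short REM run inside an NREMP after the first REMP is absorbed
        (
            (("N2", 40), ("R", 12), ("N2", 40), ("R", 4), ("N2", 20)),
            [("NREMP", 0, 40), ("REMP", 40, 52), ("NREMP", 52, 116)],
        ),
        # wake break followed by REM opens a REM period
        (
            (("N2", 40), ("W", 10), ("R", 20), ("N2", 40)),
            [("NREMP", 0, 40), ("REMP", 50, 70), ("NREMP", 70, 110)],
        ),
    ],
)
def test_scan_traces(runs, expected):
    assert intervals(scan_periods(hyp(*runs), DetectionConfig())) == expected


def test_scan_requires_fully_scored_hypnogram():
    h = Hypnogram([SleepStage.N2, None, SleepStage.N2])
    with pytest.raises(ValueError, match="unscored"):
        scan_periods(h)


def test_scan_onset_at_leading_n3_is_logged_as_atypical():
    log = []
    periods = scan_periods(hyp(("W", 4), ("N3", 10), ("N2", 30)), DetectionConfig(), log)
    assert intervals(periods) == [("NREMP", 4, 44)]
    assert any("atypical" in line for line in log)


# ---------------------------------------------------------------------------
# merge
# ---------------------------------------------------------------------------

def test_merge_absorbs_short_nremp_and_coalesces_flanking_remps(config):
    h = hyp(("N2", 40), ("R", 12), ("N2", 18), ("R", 12), ("N2", 40))
    raw = [
        SleepPeriod(PeriodKind.NREMP, 0, 40),
        SleepPeriod(PeriodKind.REMP, 40, 52),
        SleepPeriod(PeriodKind.NREMP, 52, 70),  # 9 min, below the 15-min minimum
        SleepPeriod(PeriodKind.REMP, 70, 82),
        SleepPeriod(PeriodKind.NREMP, 82, 122),
    ]
    merged = merge_and_coalesce(raw, h, config)
    assert intervals(merged) == [
        ("NREMP", 0, 40),
        ("REMP", 40, 82),
        ("NREMP", 82, 122),
    ]
    assert [p.ordinal for p in merged] == [1, 2, 3]


def test_first_remp_is_exempt_from_the_minimum(config):
    # a 1-min first REMP survives; the rules put no minimum on it
    h = hyp(("N2", 40), ("R", 2), ("N2", 40))
    result = detect_periods(h, config)
    assert intervals(result.periods) == [
        ("NREMP", 0, 40),
        ("REMP", 40, 42),
        ("NREMP", 42, 82),
    ]


def test_merge_returns_compliant_input_unchanged(config):
    h = hyp(("N2", 40), ("R", 12), ("N2", 40))
    raw = scan_periods(h, config)
    assert intervals(merge_and_coalesce(raw, h, config)) == intervals(raw)


def test_merge_drops_period_isolated_by_wake_breaks(config):
    # 10-min NREMP fenced by wake breaks on both sides cannot merge anywhere
    h = hyp(("N2", 40), ("W", 12), ("N2", 20), ("W", 12), ("N2", 40))
    log = []
    merged = merge_and_coalesce(scan_periods(h, config), h, config, log)
    assert intervals(merged) == [("NREMP", 0, 40), ("NREMP", 84, 124)]
    assert any("dropped" in line for line in log)


def test_short_non_first_remp_is_absorbed(config):
    h = hyp(("N2", 40), ("R", 12), ("N2", 40), ("R", 4), ("N2", 40), ("R", 12))
    result = detect_periods(h, config)
    # the 2-min second REM run sits inside an NREMP; only 2 REMPs survive
    kinds = [p.kind.value for p in result.periods]
    assert kinds == ["NREMP", "REMP", "NREMP", "REMP"]


# ---------------------------------------------------------------------------
# duration
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "runs, interval, expected_min",
    [
        (((("N2", 20), ("W", 4), ("N2", 20))), (0, 44), 20.0),  # W excluded
        ((("W", 10),), (0, 10), 0.0),
        ((("R", 10),), (0, 10), 5.0),
    ],
)
def test_period_duration_excludes_wake(runs, interval, expected_min):
    h = hyp(*runs)
    p = SleepPeriod(PeriodKind.NREMP, *interval)
    assert period_duration(p, h) == pytest.approx(expected_min)


def test_period_duration_rejects_out_of_range_interval():
    with pytest.raises(ValueError):
        period_duration(SleepPeriod(PeriodKind.NREMP, 0, 99), hyp(("N2", 10)))


# ---------------------------------------------------------------------------
# cuts
# ---------------------------------------------------------------------------

def _overlong_with_arousal():
    # 250 epochs (>120 min) of N2 with a 4-epoch wake run then N3
    stages = [SleepStage.N2] * 250
    stages[100:104] = [SleepStage.W] * 4
    stages[104:111] = [SleepStage.N3] * 7
    h = Hypnogram(stages)
    return h, SleepPeriod(PeriodKind.NREMP, 0, 250)


def test_arousal_candidate_found_at_n3_after_long_wake(config):
    h, p = _overlong_with_arousal()
    cands = find_cut_candidates(p, h, config)
    assert cands == [CutCandidate(104, "arousal", (100, 4))]


def test_lightening_candidate_found_at_n1_run_start(config):
    stages = [SleepStage.N2] * 250
    stages[120:127] = [SleepStage.N1] * 7  # 3.5 min of N1, exceeding 3 min
    stages[127:134] = [SleepStage.N3] * 7
    h = Hypnogram(stages)
    cands = find_cut_candidates(SleepPeriod(PeriodKind.NREMP, 0, 250), h, config)
    assert cands == [CutCandidate(120, "lightening", (120, 7))]


def test_no_candidates_below_the_maximum_duration(config):
    h = hyp(("N2", 200))  # 100 min
    assert find_cut_candidates(SleepPeriod(PeriodKind.NREMP, 0, 200), h, config) == []


def test_no_candidates_without_a_trigger(config):
    h = hyp(("N2", 250))
    assert find_cut_candidates(SleepPeriod(PeriodKind.NREMP, 0, 250), h, config) == []


def test_candidate_creating_short_fragment_is_suppressed(config):
    stages = [SleepStage.N2] * 250
    stages[10:14] = [SleepStage.W] * 4  # would leave a 5-min left fragment
    stages[14:21] = [SleepStage.N3] * 7
    h = Hypnogram(stages)
    log = []
    assert find_cut_candidates(SleepPeriod(PeriodKind.NREMP, 0, 250), h, config, log) == []
    assert any("suppressed" in line for line in log)


def test_apply_cut_trims_wake_and_reassigns_ordinals(config):
    h, p = _overlong_with_arousal()
    cand = find_cut_candidates(p, h, config)[0]
    out = apply_cut([p], p, cand, h, config)
    assert intervals(out) == [("NREMP", 0, 100), ("NREMP", 104, 250)]
    assert [q.ordinal for q in out] == [1, 2]
    for q in out:
        assert find_cut_candidates(q, h, config) == []


def test_apply_cut_rejects_foreign_candidate(config):
    h, p = _overlong_with_arousal()
    with pytest.raises(ValueError, match="not generated"):
        apply_cut([p], p, CutCandidate(50, "arousal", (46, 4)), h, config)


def test_detect_splits_overlong_nremp_end_to_end(config):
    h, _ = _overlong_with_arousal()
    result = detect_periods(h, config)
    assert intervals(result.periods) == [("NREMP", 0, 100), ("NREMP", 104, 250)]
    assert [lab for lab in result.per_epoch_label[100:104]] == ["inter_period_wake"] * 4


def test_indexed_selector_picks_requested_candidates(config):
    stages = [SleepStage.N2] * 260
    stages[100:104] = [SleepStage.W] * 4
    stages[104:111] = [SleepStage.N3] * 7
    stages[150:154] = [SleepStage.W] * 4
    stages[154:161] = [SleepStage.N3] * 7
    h = Hypnogram(stages)
    first = detect_periods(h, config, indexed_selector([0]))
    second = detect_periods(h, config, indexed_selector([1]))
    assert intervals(first.periods)[0] == ("NREMP", 0, 100)
    assert intervals(second.periods)[0] == ("NREMP", 0, 150)


def test_unsplittable_overlong_nremp_is_kept_and_logged(config):
    h = hyp(("N2", 250))
    result = detect_periods(h, config)
    assert intervals(result.periods) == [("NREMP", 0, 250)]
    assert any("no cut point" in line for line in result.log)


# ---------------------------------------------------------------------------
# orchestration and labels
# ---------------------------------------------------------------------------

def test_detect_simple_alternation(config):
    result = detect_periods(hyp(("N2", 40), ("R", 12), ("N2", 40)), config)
    assert intervals(result.periods) == [
        ("NREMP", 0, 40),
        ("REMP", 40, 52),
        ("NREMP", 52, 92),
    ]
    assert result.labels_by_kind() == {1: "NC1", 2: "RC1", 3: "NC2"}


def test_detect_all_wake_yields_empty_result(config):
    result = detect_periods(hyp(("W", 50)), config)
    assert result.periods == []
    assert set(result.per_epoch_label) == {"leading_wake"}


def test_per_epoch_labels_partition_every_epoch(config):
    h = hyp(("W", 10), ("N2", 40), ("W", 12), ("R", 20), ("W", 7))
    result = detect_periods(h, config)
    assert len(result.per_epoch_label) == len(h)
    assert result.per_epoch_label[0] == "leading_wake"
    assert result.per_epoch_label[55] == "inter_period_wake"
    assert result.per_epoch_label[-1] == "trailing_wake"
    for p in result.periods:
        code = result.labels_by_kind()[p.ordinal]
        assert all(
            lab == code for lab in result.per_epoch_label[p.start_epoch : p.end_epoch]
        )


# ---------------------------------------------------------------------------
# properties
# ---------------------------------------------------------------------------

@settings(max_examples=300, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10**9))
def test_engine_matches_brute_force_reference(seed):
    """scan+merge agrees with the windowed literal transcription of the rules."""
    cfg = DetectionConfig()
    rng = np.random.default_rng(seed)
    stages = random_stage_sequence(rng)
    h = Hypnogram([SleepStage(s) for s in stages])
    ours = merge_and_coalesce(scan_periods(h, cfg), h, cfg)
    theirs = reference_detect(stages)
    assert intervals(ours) == [(k, a, b) for k, a, b in theirs]


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10**9))
def test_final_periods_satisfy_all_invariants(seed):
    cfg = DetectionConfig()
    rng = np.random.default_rng(seed)
    h = Hypnogram([SleepStage(s) for s in random_stage_sequence(rng)])
    result = detect_periods(h, cfg)
    assert_period_invariants(result.periods, h, cfg)
    # duration bounds, except over-long periods the log declares unsplittable
    for p in result.periods:
        d = period_duration(p, h)
        if p.kind is PeriodKind.NREMP:
            assert d >= cfg.min_nremp_min - 1e-9
            if d > cfg.max_nremp_min + 1e-9:
                assert any("no cut point" in line for line in result.log)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10**9))
def test_more_wake_tolerance_never_adds_raw_periods(seed):
    """Raising wake_break_min can only remove break points from the scan."""
    rng = np.random.default_rng(seed)
    h = Hypnogram([SleepStage(s) for s in random_stage_sequence(rng)])
    counts = [
        len(scan_periods(h, DetectionConfig(wake_break_min=m))) for m in (5.0, 7.5, 10.0)
    ]
    assert counts[0] >= counts[1] >= counts[2]


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10**9))
def test_detection_is_stable_after_removing_unassigned_wake(seed):
    """On alternating-template nights, stripping leading/trailing/inter-period
    wake shifts the periods but keeps their kinds and epoch lengths."""
    from somnogram.synthgen import generate_hypnogram, random_template

    cfg = DetectionConfig()
    template = random_template(seed, alternate_only=True)
    h, _ = generate_hypnogram(template)
    first = detect_periods(h, cfg)
    keep = [
        s
        for s, lab in zip(h.stages, first.per_epoch_label)
        if lab not in ("leading_wake", "trailing_wake", "inter_period_wake")
    ]
    if not keep:
        return
    second = detect_periods(Hypnogram(keep, h.epoch_len_s), cfg)
    assert [(p.kind, p.n_epochs) for p in second.periods] == [
        (p.kind, p.n_epochs) for p in first.periods
    ]
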