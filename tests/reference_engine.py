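"""Independent brute-force reference for the period rules.

This is a deliberately naive transcription of the segmentation rules,
kept structurally different from the shipped engine: it works on plain
stage strings, re-checks fixed-size windows at every epoch instead of
walking run-length encodings, and re-derives everything from scratch at
each step.  It exists so the production engine can be checked against an
implementation that shares none of its machinery.
"""

from __future__ import annotations


def _fam(stage: str) -> str:
    if stage == "W":
        return "W"
    if stage == "R":
        return "R"
    return "N"


def reference_scan(stages: list[str], wake_break: int, transition: int):
    """Raw periods as (kind, start, end) triples, half-open intervals."""
    n = len(stages)

    def window_all(i: int, k: int, fam: str) -> bool:
        return i + k <= n and all(_fam(stages[j]) == fam for j in range(i, i + k))

    # onset: first NREM epoch; everything before it is ignored
    i = 0
    while i < n and _fam(stages[i]) != "N":
        i += 1
    if i == n:
        return []

    periods = []
    seen_remp = False
    while i < n:
        kind = "REMP" if _fam(stages[i]) == "R" else "NREMP"
        if kind == "REMP":
            seen_remp = True
        start = i
        j = i
        while j < n:
            f = _fam(stages[j])
            if f == "W" and window_all(j, wake_break, "W"):
                break
            if kind == "NREMP" and f == "R":
                if not seen_remp or window_all(j, transition, "R"):
                    break
            if kind == "REMP" and f == "N" and window_all(j, transition, "N"):
                break
            j += 1
        end = j
        while end > start and _fam(stages[end - 1]) == "W":
            end -= 1
        if end > start:
            periods.append((kind, start, end))
        i = j
        while i < n and _fam(stages[i]) == "W":
            i += 1
    return periods


def reference_merge(
    periods,
    stages: list[str],
    min_nremp_epochs: int,
    min_remp_epochs: int,
    wake_break: int,
):
    """Absorb/drop under-minimum periods, coalescing as the rules demand."""
    ps = [list(p) for p in periods]

    def sleep_epochs(p) -> int:
        return sum(1 for s in stages[p[1] : p[2]] if s != "W")

    def too_short(p) -> bool:
        if p[0] == "NREMP":
            return sleep_epochs(p) < min_nremp_epochs
        starts = [q[1] for q in ps if q[0] == "REMP"]
        if starts and p[1] == min(starts):
            return False  # the earliest REMP has no minimum
        return sleep_epochs(p) < min_remp_epochs

    def adjacent(a, b) -> bool:
        return b[1] - a[2] < wake_break

    changed = True
    while changed:
        changed = False
        for k, p in enumerate(ps):
            if not too_short(p):
                continue
            if k > 0 and adjacent(ps[k - 1], p):
                ps[k - 1][2] = p[2]
                del ps[k]
            elif k + 1 < len(ps) and adjacent(p, ps[k + 1]):
                ps[k + 1][1] = p[1]
                del ps[k]
            else:
                del ps[k]
            # coalesce neighbours of the same kind wherever they now touch
            m = 0
            while m + 1 < len(ps):
                if ps[m][0] == ps[m + 1][0] and adjacent(ps[m], ps[m + 1]):
                    ps[m][2] = ps[m + 1][2]
                    del ps[m + 1]
                else:
                    m += 1
            changed = True
            break
    return [tuple(p) for p in ps]


def reference_detect(
    stages: list[str],
    wake_break: int = 10,
    transition: int = 10,
    min_nremp_epochs: int = 30,
    min_remp_epochs: int = 10,
):
    raw = reference_scan(stages, wake_break, transition)
    return reference_merge(raw, stages, min_nremp_epochs, min_remp_epochs, wake_break)
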