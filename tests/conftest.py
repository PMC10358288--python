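import numpy as np
import pytest

from somnogram import DetectionConfig, Hypnogram, SleepStage

STAGE_NAMES = ["W", "N1", "N2", "N3", "R"]


def hyp(*runs, epoch_len_s: float = 30.0) -> Hypnogram:
    """Build a hypnogram from (stage, count) runs: hyp(("W", 10), ("N2", 40))."""
    stages = []
    for stage, n in runs:
        stages.extend([SleepStage(stage)] * n)
    return Hypnogram(stages, epoch_len_s)


def random_stage_sequence(rng: np.random.Generator, max_len: int = 200) -> list[str]:
    """Random stage string; half the draws are run-structured so that long
    wake/REM runs (the interesting rule triggers) actually occur."""
    n = int(rng.integers(1, max_len + 1))
    if rng.random() < 0.5:
        return [STAGE_NAMES[k] for k in rng.integers(0, 5, size=n)]
    out: list[str] = []
    while len(out) < n:
        stage = STAGE_NAMES[int(rng.integers(0, 5))]
        out.extend([stage] * int(rng.integers(1, 16)))
    return out[:n]


@pytest.fixture
def config() -> DetectionConfig:
    return DetectionConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20261001)
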