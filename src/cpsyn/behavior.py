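"""Visual water task thresholds and the looming response fraction.

In the visual water task (VWT), a swimming mouse chooses between two
monitors in a two-alternative forced choice; the rewarded stimulus marks
a hidden escape platform. Training runs at an easy discrimination until
90% block accuracy; testing then makes the discrimination progressively
harder — higher spatial frequency for acuity (starting at 0.086
cycles/degree), smaller orientation difference in 5 degree steps for
orientation discrimination — and the threshold is the extreme level at
which 70% accuracy is still achieved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ThresholdNotReached

logger = logging.getLogger(__name__)

__all__ = [
    "TrialLog",
    "blocks_to_learn",
    "acuity_threshold",
    "orientation_threshold",
    "looming_response_fraction",
]

LEARN_CRITERION = 0.9
THRESHOLD_CRITERION = 0.7
ORIENTATION_STEP_DEG = 5.0


@dataclass
class TrialLog:
    """Per-trial VWT log.

    ``trials`` columns: ``phase`` ('train' or 'test'), ``block_id``,
    ``level`` (cycles/degree for acuity, degrees of orientation
    difference for orientation) and ``correct`` (boolean).
    """

    task: str  # 'acuity' | 'orientation'
    trials: pd.DataFrame

    def __post_init__(self) -> None:
        if self.task not in ("acuity", "orientation"):
            raise ValueError("task must be 'acuity' or 'orientation'")
        required = {"phase", "block_id", "level", "correct"}
        missing = required - set(self.trials.columns)
        if missing:
            raise ValueError(f"trial log missing columns: {sorted(missing)}")

    def phase_trials(self, phase: str) -> pd.DataFrame:
        return self.trials[self.trials["phase"] == phase]


def blocks_to_learn(log: TrialLog, criterion: float = LEARN_CRITERION) -> int | None:
    """1-based index of the first training block with accuracy >= criterion.

    Returns None when the criterion is never reached (not-learned).
    """
    train = log.phase_trials("train")
    if len(train) == 0:
        raise ValueError("no training trials in the log")
    acc = train.groupby("block_id", sort=True)["correct"].mean()
    for i, (_, a) in enumerate(acc.items(), start=1):
        if a >= criterion:
            return i
    return None


def _level_accuracy(log: TrialLog, pool: str) -> pd.Series:
    test = log.phase_trials("test")
    if len(test) == 0:
        raise ValueError("no test trials in the log")
    if pool == "all":
        return test.groupby("level")["correct"].mean()
    if pool == "last-block":
        last = test.groupby("level")["block_id"].transform("max")
        return test[test["block_id"] == last].groupby("level")["correct"].mean()
    raise ValueError("pool must be 'all' or 'last-block'")


def _check_monotone(passing: np.ndarray, levels: np.ndarray, task: str) -> None:
    # a pass-fail-pass sequence along the difficulty axis is worth flagging
    idx = np.argsort(levels)
    seq = passing[idx]
    if np.any(np.diff(np.where(seq)[0]) > 1):
        logger.warning(
            "%s: non-monotone performance across levels; reporting the extreme "
            "passing level per the threshold definition",
            task,
        )


def acuity_threshold(log: TrialLog, criterion: float = THRESHOLD_CRITERION,
                     pool: str = "all") -> float:
    """Highest spatial frequency (cycles/degree) with accuracy >= criterion."""
    acc = _level_accuracy(log, pool)
    levels = acc.index.to_numpy(float)
    passing = acc.to_numpy(float) >= criterion
    if not passing.any():
        raise ThresholdNotReached("no spatial frequency reached the criterion")
    _check_monotone(passing, levels, "acuity")
    return float(levels[passing].max())


def orientation_threshold(log: TrialLog, criterion: float = THRESHOLD_CRITERION,
                          pool: str = "all") -> float:
    """Smallest orientation difference (degrees) with accuracy >= criterion."""
    acc = _level_accuracy(log, pool)
    levels = acc.index.to_numpy(float)
    passing = acc.to_numpy(float) >= criterion
    if not passing.any():
        raise ThresholdNotReached("no orientation difference reached the criterion")
    _check_monotone(passing, levels, "orientation")
    return float(levels[passing].min())


def looming_response_fraction(trials, max_trials: int = 3) -> float:
    """Fraction of looming presentations eliciting a defensive response."""
    responses = [bool(t) for t in trials]
    if not 1 <= len(responses) <= max_trials:
        raise ValueError(f"expected between 1 and {max_trials} trials")
    return sum(responses) / len(responses)
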