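"""Bernoulli psychometric observer for the visual water task.

Accuracy follows a logistic psychometric function bounded between the
two-alternative guess rate (0.5) and 1 - lapse_rate, centred on the true
threshold. For acuity, higher spatial frequencies are harder; for
orientation discrimination, smaller angular differences are harder.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from ..behavior import TrialLog

__all__ = ["PsychometricObserver", "VWTProtocol", "simulate_vwt_session",
           "default_acuity_levels", "default_orientation_levels"]


def default_acuity_levels() -> np.ndarray:
    """Tested spatial frequencies: the 0.086 c/deg training stimulus,
    then 0.05 c/deg increments."""
    return np.round(np.concatenate([[0.086], np.arange(0.136, 0.787, 0.05)]), 3)


def default_orientation_levels() -> np.ndarray:
    """Angular differences from 90 degrees down in 5 degree steps."""
    return np.arange(90.0, 4.9, -5.0)


@dataclass(frozen=True)
class PsychometricObserver:
    """Stationary observer with a logistic psychometric function.

    ``slope`` has units of 1/level; large values approach a step
    function at the threshold, where accuracy crosses the midpoint
    between 1 - lapse_rate and the guess rate.
    """

    task: str  # 'acuity' | 'orientation'
    true_threshold: float
    slope: float = 60.0
    lapse_rate: float = 0.02
    guess_rate: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.task not in ("acuity", "orientation"):
            raise ValueError("task must be 'acuity' or 'orientation'")
        if self.slope <= 0:
            raise ValueError("slope must be positive")
        if not 0.0 <= self.lapse_rate < 0.5:
            raise ValueError("lapse_rate must lie in [0, 0.5)")

    def accuracy(self, level) -> np.ndarray:
        level = np.asarray(level, dtype=float)
        signed = (
            self.true_threshold - level
            if self.task == "acuity"
            else level - self.true_threshold
        )
        return self.guess_rate + (1.0 - self.guess_rate - self.lapse_rate) * expit(
            self.slope * signed
        )


@dataclass(frozen=True)
class VWTProtocol:
    """Session structure for threshold testing.

    ``levels`` are visited in order (increasing frequency for acuity,
    decreasing angle for orientation); each level is tested with
    ``blocks_per_level`` blocks of ``trials_per_block`` trials,
    emulating the repeated testing a mouse receives at each step before
    the difficulty advances. Testing stops after the first level whose
    pooled accuracy falls below ``stop_criterion`` (the rig advances the
    difficulty only while the animal still performs). Training blocks at
    ``levels[0]`` run until 90% block accuracy, up to
    ``max_training_blocks``.
    """

    levels: tuple[float, ...]
    trials_per_block: int = 10
    blocks_per_level: int = 3
    stop_criterion: float = 0.7
    learn_criterion: float = 0.9
    max_training_blocks: int = 40

    def __post_init__(self) -> None:
        if len(self.levels) == 0:
            raise ValueError("protocol needs at least one level")
        if self.trials_per_block < 1 or self.blocks_per_level < 1:
            raise ValueError("block sizes must be positive")
        if not 0.5 <= self.stop_criterion <= 1.0:
            raise ValueError("stop_criterion must lie in [0.5, 1]")

    @classmethod
    def acuity(cls, **kwargs) -> "VWTProtocol":
        return cls(levels=tuple(default_acuity_levels()), **kwargs)

    @classmethod
    def orientation(cls, **kwargs) -> "VWTProtocol":
        return cls(levels=tuple(default_orientation_levels()), **kwargs)


def simulate_vwt_session(
    observer: PsychometricObserver,
    protocol: VWTProtocol,
    rng: np.random.Generator | None = None,
) -> TrialLog:
    """One training + threshold-testing session as a trial log."""
    rng = rng if rng is not None else np.random.default_rng(observer.seed)
    rows = []
    block = 0
    # training at the easiest level until the learning criterion
    p_train = float(observer.accuracy(protocol.levels[0]))
    for _ in range(protocol.max_training_blocks):
        block += 1
        correct = rng.random(protocol.trials_per_block) < p_train
        rows += [
            {"phase": "train", "block_id": block, "level": protocol.levels[0],
             "correct": bool(c)}
            for c in correct
        ]
        if correct.mean() >= protocol.learn_criterion:
            break
    # threshold testing
    for level in protocol.levels:
        p = float(observer.accuracy(level))
        hits = 0
        for _ in range(protocol.blocks_per_level):
            block += 1
            correct = rng.random(protocol.trials_per_block) < p
            hits += int(correct.sum())
            rows += [
                {"phase": "test", "block_id": block, "level": level,
                 "correct": bool(c)}
                for c in correct
            ]
        pooled = hits / (protocol.blocks_per_level * protocol.trials_per_block)
        if pooled < protocol.stop_criterion:
            break
    return TrialLog(task=observer.task, trials=pd.DataFrame(rows))
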