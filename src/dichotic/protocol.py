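"""3AFC screening protocol: block assembly, scoring, and pass/fail rules.

A screening block is six trials drawn without replacement from a test's
12-trial pool.  A subject's block score is the number of trials on which
their response (interval 1, 2 or 3) matched the target position; chance
performance is 6 * 1/3 = 2 correct.  Pass thresholds of 3-6 correct out of
6 are the operating points swept by the downstream ROC analysis, with 6/6
the recommended screening criterion.  A "Both" rule accepts a subject only
if they pass two tests (e.g. HP and AP) at the same threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .stimuli import TrialPool, TrialSpec

__all__ = [
    "BlockResult",
    "ScreeningOutcome",
    "PASS_THRESHOLDS",
    "sample_block",
    "score_block",
    "classify_pass",
    "combine_both",
    "latin_square_order",
    "block_results_frame",
]

#: Above-chance pass thresholds considered by the evaluation (correct out of 6).
PASS_THRESHOLDS = (6, 5, 4, 3)

#: Trials per screening block.
BLOCK_SIZE = 6


@dataclass(frozen=True)
class BlockResult:
    """Scored responses for one six-trial block."""

    test_kind: str
    trial_indices: tuple[int, ...]
    responses: tuple[int, ...]
    correct: tuple[bool, ...]
    n_correct: int

    def __post_init__(self) -> None:
        if self.n_correct != sum(self.correct):
            raise ValueError("n_correct must equal the number of correct responses")
        if not 0 <= self.n_correct <= len(self.responses):
            raise ValueError("n_correct out of range")


@dataclass(frozen=True)
class ScreeningOutcome:
    """Pass/fail decision for one subject at one threshold.

    ``excluded_on_example`` flags a subject who failed to hear the target in
    the practice example; this is recorded, not enforced interactively.
    """

    passes: Mapping[str, bool]
    threshold: int
    combined_pass: bool = field(default=False)
    excluded_on_example: bool = False

    def __post_init__(self) -> None:
        if self.combined_pass and not all(self.passes.values()):
            raise ValueError("combined pass requires every component pass")


def sample_block(pool: TrialPool, n: int = BLOCK_SIZE, seed=None) -> list[TrialSpec]:
    """Draw ``n`` distinct trials from the pool, in randomised order.

    Deterministic given ``seed`` (int, SeedSequence or Generator).
    """
    if n > len(pool):
        raise ValueError(f"cannot draw {n} trials from a pool of {len(pool)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pool))[:n]
    return [pool[int(i)] for i in order]


def _target_position(trial) -> int:
    return trial.target_position if isinstance(trial, TrialSpec) else int(trial)


def score_block(trials: Sequence, responses: Sequence[int],
                test_kind: str | None = None) -> BlockResult:
    """Score one block: a response is correct iff it equals the target position.

    ``trials`` may be TrialSpecs or bare target positions (1-based).
    """
    if len(trials) != len(responses):
        raise ValueError("one response is required per trial")
    targets = [_target_position(t) for t in trials]
    resp = [int(r) for r in responses]
    if any(r not in (1, 2, 3) for r in resp):
        raise ValueError("responses must be interval indices 1, 2 or 3")
    correct = tuple(r == t for r, t in zip(resp, targets))
    if test_kind is None:
        test_kind = trials[0].test_kind if isinstance(trials[0], TrialSpec) else "HP"
    indices = tuple(
        t.metadata.get("seed_scheme", {}).get("trial_index", i)
        if isinstance(t, TrialSpec) and isinstance(t.metadata, dict) else i
        for i, t in enumerate(trials)
    )
    return BlockResult(test_kind=test_kind, trial_indices=indices,
                       responses=tuple(resp), correct=correct,
                       n_correct=sum(correct))


def classify_pass(n_correct: int, threshold: int) -> bool:
    """A subject passes a test iff n_correct >= threshold (6/6 recommended)."""
    if not 0 <= n_correct <= 6:
        raise ValueError("n_correct must lie in 0..6")
    if not 0 <= threshold <= 6:
        raise ValueError("threshold must lie in 0..6")
    return n_correct >= threshold


def combine_both(pass_a: bool, pass_b: bool) -> bool:
    """The "Both" rule: accept only subjects who pass both component tests."""
    return bool(pass_a) and bool(pass_b)


def latin_square_order(participant_index: int, n_blocks: int = 4) -> list[int]:
    """Block ordering for one participant under a cyclic Latin-square design.

    Row ``participant_index mod n_blocks`` of the cyclic square: across any
    ``n_blocks`` consecutive participants every block occupies every serial
    position exactly once.
    """
    if participant_index < 0:
        raise ValueError("participant_index must be non-negative")
    row = participant_index % n_blocks
    return [(row + j) % n_blocks for j in range(n_blocks)]


def block_results_frame(subject_id: str, equipment_label: str,
                        result: BlockResult,
                        trials: Sequence | None = None) -> pd.DataFrame:
    """Long-format results table for one scored block.

    Columns: subject_id, test, equipment_label, trial_index, target_position,
    response, correct, n_correct, pass_at_6 .. pass_at_3.
    """
    targets = ([_target_position(t) for t in trials] if trials is not None
               else [np.nan] * len(result.responses))
    rows = pd.DataFrame({
        "subject_id": subject_id,
        "test": result.test_kind,
        "equipment_label": equipment_label,
        "trial_index": list(result.trial_indices),
        "target_position": targets,
        "response": list(result.responses),
        "correct": list(result.correct),
        "n_correct": result.n_correct,
    })
    for t in PASS_THRESHOLDS:
        rows[f"pass_at_{t}"] = classify_pass(result.n_correct, t)
    return rows
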