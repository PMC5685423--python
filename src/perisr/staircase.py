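"""3-down-1-up adaptive staircase controlling Landolt-gap size.

The gap starts at 17.8 arcmin with a 4.5-arcmin step.  Every error
increases the gap by the current step; every third consecutive correct
response decreases it.  A change in the direction of movement is a
reversal; on each size-increasing reversal the step is halved, the
halved step governing all subsequent moves.  A run
terminates after eight reversals or 50 trials, whichever comes first.
This rule converges near the 79.4%-correct point of the psychometric
function (p = 0.5^(1/3)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError, UsageError

INITIAL_GAP = 17.8  # arcmin
INITIAL_STEP = 4.5  # arcmin
MAX_REVERSALS = 8
MAX_TRIALS = 50
GAP_FLOOR = 1.05  # arcmin: one display pixel, the rasterization limit
N_DOWN = 3

#: Accuracy tracked by an n-down-1-up rule: p = 0.5**(1/n).
TRACKED_P = 0.5 ** (1.0 / N_DOWN)

CSV_COLUMNS = ["subject_id", "condition", "density", "run", "trial",
               "gap_arcmin", "orientation", "response", "correct", "seed"]


@dataclass
class TrialRecord:
    """One trial of an adaptive run."""

    gap: float
    correct: bool
    condition: str = ""
    density: float = float("nan")
    run: int = 0
    subject_id: str = ""
    trial: int = 0
    seed: int = 0
    orientation: str = ""
    response: str = ""

    def __post_init__(self) -> None:
        if self.gap <= 0:
            raise ParameterError("gap must be positive")


@dataclass
class StaircaseState:
    """Mutable state of one adaptive track."""

    current_gap: float = INITIAL_GAP
    step: float = INITIAL_STEP
    consecutive_correct: int = 0
    n_trials: int = 0
    n_reversals: int = 0
    last_direction: str = "none"  # none | decreasing | increasing
    terminated: bool = False
    history: list = field(default_factory=list)
    reversal_gaps: list = field(default_factory=list)
    max_trials: int = MAX_TRIALS
    max_reversals: int = MAX_REVERSALS
    gap_floor: float = GAP_FLOOR


def init_staircase(max_trials: int = MAX_TRIALS,
                   max_reversals: int = MAX_REVERSALS) -> StaircaseState:
    """Fresh track: gap 17.8 arcmin, step 4.5 arcmin, counters zeroed."""
    return StaircaseState(max_trials=max_trials, max_reversals=max_reversals)


def update(state: StaircaseState, correct: bool) -> StaircaseState:
    """Advance the track by one response; returns the (mutated) state."""
    if state.terminated:
        raise UsageError("staircase already terminated")
    state.n_trials += 1
    move = 0
    if correct:
        state.consecutive_correct += 1
        if state.consecutive_correct >= N_DOWN:
            move = -1
            state.consecutive_correct = 0
    else:
        state.consecutive_correct = 0
        move = +1
    if move != 0:
        direction = "decreasing" if move < 0 else "increasing"
        reversal = (state.last_direction != "none"
                    and direction != state.last_direction)
        if reversal:
            state.n_reversals += 1
            state.reversal_gaps.append(state.current_gap)
        state.current_gap = max(state.gap_floor,
                                state.current_gap + move * state.step)
        if reversal and direction == "increasing":
            # halve on every size-increasing reversal; the halved step
            # governs subsequent moves
            state.step /= 2.0
        state.last_direction = direction
    if state.n_reversals >= state.max_reversals or state.n_trials >= state.max_trials:
        state.terminated = True
    return state


def run_staircase(
    responder,
    cond,
    seed,
    subject_id: str = "s1",
    run: int = 0,
    max_trials: int = MAX_TRIALS,
    max_reversals: int = MAX_REVERSALS,
) -> list[TrialRecord]:
    """Run one adaptive track against a responder.

    ``responder`` must expose ``respond(cond, gap_size, orientation, seed)
    -> bool``; ``cond`` is a :class:`~perisr.stimulus.ConditionSpec` (or
    any label object with ``label``/``density`` attributes for
    image-free responders).  The gap orientation is drawn uniformly from
    the four obliques on every trial.
    """
    rng = np.random.default_rng(seed)
    from .stimulus import ORIENTATIONS

    names = list(ORIENTATIONS)
    state = init_staircase(max_trials=max_trials, max_reversals=max_reversals)
    records: list[TrialRecord] = []
    label = getattr(cond, "label", str(cond))
    density = getattr(cond, "density", float("nan"))
    while not state.terminated:
        orientation = names[rng.integers(4)]
        trial_seed = int(rng.integers(2**31))
        gap = state.current_gap
        correct = bool(responder.respond(cond, gap, orientation, trial_seed))
        rec = TrialRecord(gap=gap, correct=correct, condition=label,
                          density=density, run=run, subject_id=subject_id,
                          trial=state.n_trials, seed=trial_seed,
                          orientation=orientation,
                          response=orientation if correct else "other")
        records.append(rec)
        state.history.append(rec)
        update(state, correct)
    return records


def records_to_frame(records) -> pd.DataFrame:
    """Trial records as a DataFrame with the canonical CSV columns."""
    rows = [
        {
            "subject_id": r.subject_id,
            "condition": r.condition,
            "density": r.density,
            "run": r.run,
            "trial": r.trial,
            "gap_arcmin": r.gap,
            "orientation": r.orientation,
            "response": r.response,
            "correct": bool(r.correct),
            "seed": r.seed,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def write_records_csv(records, path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_records_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise UsageError(f"trial CSV missing columns: {sorted(missing)}")
    return df


def tracked_gap(mu: float, sigma: float) -> float:
    """Gap at which the logistic psychometric function hits the tracked
    accuracy p = 0.5^(1/3) (approximately mu + 0.97 sigma)."""
    p = TRACKED_P
    return mu - sigma * np.log(0.75 / (p - 0.25) - 1.0)
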