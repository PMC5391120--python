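"""Speller grid and constrained stimulus-sequence generation.

The visual speller uses a 6×7 grid: 32 selectable symbols (A–Z plus
"⎵" "." "," "!" "?" "←") and 10 "#" visual blanks that equalize stimulus
brightness but can never be attended or selected. Two kinds of stimulus
blocks create the two label-proportion groups the LLP decoder needs:

* sequence 1 — 8 events of 12 symbols each; every selectable symbol is
  highlighted exactly 3 times, blanks never. Whatever symbol the user
  attends, the block contains 3 targets and 5 non-targets.
* sequence 2 — 18 events of 12 symbols; every selectable symbol exactly
  twice, the remaining slots filled with blanks: 2 targets, 16 non-targets.

A trial (one character selection) interleaves 4 sequence-1 blocks with 2
sequence-2 blocks → 68 events, 16 targets and 52 non-targets for any
attended symbol, with fixed group-wise proportions (3/8, 5/8) and
(2/18, 16/18).

Double-flash avoidance: no *selectable* symbol appears in two consecutive
events (enforced within blocks and across block boundaries). Blanks are
exempt — a sequence-2 block needs 152 blank slots shared by 10 blanks in
18 events, so consecutive blank repeats are unavoidable by counting; since
blanks are never attended, a repeated blank cannot cause the perceptual
double-flash error the rule exists to prevent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from ._utils import as_rng
from .epochs import NONTARGET, TARGET
from .meanmap import MixingMatrix

__all__ = [
    "SpellerGrid",
    "StimulusEvent",
    "StimulusSchedule",
    "ScheduleGenerationError",
    "make_default_grid",
    "generate_block",
    "generate_trial",
    "label_events",
    "mixing_from_schedule",
    "trial_timing",
    "write_schedules",
    "read_schedules",
    "SYMBOLS_PER_EVENT",
    "SEQ1_LENGTH",
    "SEQ2_LENGTH",
    "STUDY_SENTENCE",
]

SYMBOLS_PER_EVENT = 12
SEQ1_LENGTH = 8        # events per sequence-1 block; each selectable 3x
SEQ1_REPEATS = 3
SEQ2_LENGTH = 18       # events per sequence-2 block; each selectable 2x
SEQ2_REPEATS = 2
MAX_RESTARTS = 10_000  # cap on randomized constructive restarts per block

# 62 characters; the trailing "." pads the study preset to the 63 trials
# spelled per sentence repetition.
STUDY_SENTENCE = "FRANZY⎵JAGT⎵IM⎵KOMPLETT⎵VERWAHRLOSTEN⎵TAXI⎵QUER⎵DURCH⎵FREIBURG."


class ScheduleGenerationError(RuntimeError):
    """Raised when the constrained generator exhausts its restart budget."""


@dataclass(frozen=True)
class SpellerGrid:
    """Row-major symbol grid with blank flags (0-based symbol indices)."""

    rows: int
    cols: int
    symbols: tuple[str, ...]
    blank_flags: tuple[bool, ...]

    def __post_init__(self) -> None:
        if self.rows * self.cols != len(self.symbols):
            raise ValueError("rows * cols must equal the number of symbols")
        if len(self.blank_flags) != len(self.symbols):
            raise ValueError("need one blank flag per symbol")

    @property
    def selectable_indices(self) -> np.ndarray:
        return np.flatnonzero(~np.asarray(self.blank_flags))

    @property
    def blank_indices(self) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.blank_flags))

    @property
    def n_selectable(self) -> int:
        return len(self.selectable_indices)

    def index_of(self, symbol: str) -> int:
        return self.symbols.index(symbol)


@dataclass(frozen=True)
class StimulusEvent:
    """One highlighting event: 12 symbol indices, a group tag, a block id."""

    highlighted: frozenset[int]
    group: int
    block: int


@dataclass
class StimulusSchedule:
    """Ordered stimulus events of one trial (one character selection)."""

    events: list[StimulusEvent]
    trial_id: int = 0

    def __len__(self) -> int:
        return len(self.events)

    def groups(self) -> np.ndarray:
        return np.asarray([e.group for e in self.events])

    def highlighted(self) -> list[frozenset[int]]:
        return [e.highlighted for e in self.events]


def make_default_grid() -> SpellerGrid:
    """The 6×7 study grid: 26 letters + ⎵ . , ! ? ← + 10 blanks (last)."""
    letters = tuple("ABCDEFGHIJKLMNOPQRSTUVWXYZ")
    extras = ("⎵", ".", ",", "!", "?", "←")
    blanks = ("#",) * 10
    symbols = letters + extras + blanks
    flags = (False,) * 32 + (True,) * 10
    return SpellerGrid(rows=6, cols=7, symbols=symbols, blank_flags=flags)


def _assign_selectable(
    selectable: np.ndarray,
    n_events: int,
    repeats: int,
    per_event: Sequence[int],
    rng: np.random.Generator,
    forbid_first: frozenset[int],
    conflict: Callable[[int, int], bool] | None,
) -> list[list[int]] | None:
    """One randomized constructive pass; None on dead end.

    Greedy urgency heuristic: each event takes the required number of
    symbols among those with remaining quota that were not shown in the
    previous event, preferring symbols with the highest remaining quota
    (random tie-break). This keeps quotas balanced so late events rarely
    run out of admissible symbols.
    """
    remaining = {int(s): repeats for s in selectable}
    events: list[list[int]] = []
    prev: frozenset[int] = forbid_first
    for e in range(n_events):
        need = per_event[e]
        pool = [s for s, r in remaining.items() if r > 0 and s not in prev]
        if conflict is not None:
            pool = [s for s in pool if not any(conflict(s, p) for p in prev)]
        if len(pool) < need:
            return None
        urgency = np.array([remaining[s] for s in pool], dtype=float)
        urgency += rng.random(len(pool))  # random tie-break
        chosen = [pool[i] for i in np.argsort(-urgency)[:need]]
        for s in chosen:
            remaining[s] -= 1
        events.append(sorted(chosen))
        prev = frozenset(chosen)
    if any(r != 0 for r in remaining.values()):
        return None
    return events


def generate_block(
    grid: SpellerGrid,
    sequence_id: int,
    rng: np.random.Generator | int | None = None,
    forbid_first: frozenset[int] = frozenset(),
    conflict: Callable[[int, int], bool] | None = None,
) -> list[frozenset[int]]:
    """Generate one constrained stimulus block as a list of highlight sets.

    ``forbid_first`` lists selectable symbols banned from the first event
    (used to enforce double-flash avoidance across block boundaries);
    ``conflict`` is an optional pairwise predicate (a, b) -> bool marking
    additional symbol pairs that may not appear in consecutive events
    (hook for spatial-adjacency rules).
    """
    rng = as_rng(rng)
    if sequence_id == 1:
        n_events, repeats = SEQ1_LENGTH, SEQ1_REPEATS
        per_event = [SYMBOLS_PER_EVENT] * n_events
    elif sequence_id == 2:
        n_events, repeats = SEQ2_LENGTH, SEQ2_REPEATS
        total = grid.n_selectable * repeats
        base, extra = divmod(total, n_events)
        per_event = [base + 1] * extra + [base] * (n_events - extra)
        rng.shuffle(per_event)
    else:
        raise ValueError("sequence_id must be 1 or 2")

    selectable = grid.selectable_indices
    for _ in range(MAX_RESTARTS):
        assignment = _assign_selectable(
            selectable, n_events, repeats, per_event, rng, forbid_first, conflict
        )
        if assignment is not None:
            break
    else:
        raise ScheduleGenerationError(
            f"could not satisfy sequence-{sequence_id} constraints "
            f"(12 symbols/event, {repeats} repeats/symbol, no double flash) "
            f"within {MAX_RESTARTS} restarts"
        )

    if sequence_id == 1:
        return [frozenset(ev) for ev in assignment]

    # sequence 2: fill each event to 12 symbols with blanks, spreading the
    # blank quota as evenly as possible (blanks may repeat consecutively)
    blanks = [int(b) for b in grid.blank_indices]
    slots = sum(SYMBOLS_PER_EVENT - len(ev) for ev in assignment)
    base, extra = divmod(slots, len(blanks))
    order = list(blanks)
    rng.shuffle(order)
    quota = {b: base + (1 if i < extra else 0) for i, b in enumerate(order)}
    events = []
    for ev in assignment:
        need = SYMBOLS_PER_EVENT - len(ev)
        ranked = sorted(blanks, key=lambda b: (-quota[b], rng.random()))
        fill = ranked[:need]
        for b in fill:
            quota[b] -= 1
        events.append(frozenset(ev) | frozenset(fill))
    return events


def generate_trial(
    grid: SpellerGrid,
    rng: np.random.Generator | int | None = None,
    trial_id: int = 0,
    n_seq1: int = 4,
    n_seq2: int = 2,
    interleave: str = "block",
    conflict: Callable[[int, int], bool] | None = None,
) -> StimulusSchedule:
    """Generate one trial: 4 sequence-1 + 2 sequence-2 blocks, interleaved.

    ``interleave='block'`` (default) randomly orders whole blocks, keeping
    the within-block count guarantees intact; ``'event'`` additionally
    shuffles events across block boundaries under the same double-flash
    constraint.
    """
    rng = as_rng(rng)
    order = [1] * n_seq1 + [2] * n_seq2
    rng.shuffle(order)
    selectable = set(int(s) for s in grid.selectable_indices)

    events: list[StimulusEvent] = []
    prev_selectable: frozenset[int] = frozenset()
    for block_id, seq in enumerate(order):
        block = generate_block(
            grid, seq, rng, forbid_first=prev_selectable, conflict=conflict
        )
        events.extend(StimulusEvent(ev, seq, block_id) for ev in block)
        prev_selectable = frozenset(events[-1].highlighted & selectable)

    if interleave == "event":
        events = _interleave_events(events, selectable, rng)
    elif interleave != "block":
        raise ValueError("interleave must be 'block' or 'event'")
    return StimulusSchedule(events=events, trial_id=trial_id)


def _interleave_events(
    events: list[StimulusEvent], selectable: set[int], rng: np.random.Generator
) -> list[StimulusEvent]:
    """Randomized merge of the block streams under double-flash avoidance.

    Within-block event order is preserved (it already satisfies the
    constraint); at each step a random block whose next event does not
    clash with the previous emitted event continues. Two sequence-1 events
    from different blocks almost surely share a symbol, so genuinely
    uniform event shuffles are infeasible — the merge weaves blocks at the
    points where the constraint permits, restarting on dead ends.
    """
    streams: dict[int, list[StimulusEvent]] = {}
    for event in events:
        streams.setdefault(event.block, []).append(event)
    for _ in range(MAX_RESTARTS):
        position = {b: 0 for b in streams}
        merged: list[StimulusEvent] = []
        prev: frozenset[int] = frozenset()
        while len(merged) < len(events):
            candidates = [
                b
                for b, p in position.items()
                if p < len(streams[b])
                and not (streams[b][p].highlighted & prev & selectable)
            ]
            if not candidates:
                break
            b = candidates[rng.integers(len(candidates))]
            event = streams[b][position[b]]
            position[b] += 1
            merged.append(event)
            prev = event.highlighted
        if len(merged) == len(events):
            return merged
    raise ScheduleGenerationError(
        "event-level interleaving could not satisfy double-flash avoidance"
    )


def label_events(schedule: StimulusSchedule, attended: int, grid: SpellerGrid) -> np.ndarray:
    """±1 labels: an event is a target iff it highlights the attended symbol."""
    if bool(grid.blank_flags[attended]):
        raise ValueError("the attended symbol must be selectable, not a blank")
    return np.asarray(
        [TARGET if attended in e.highlighted else NONTARGET for e in schedule.events]
    )


def mixing_from_schedule(
    schedule: StimulusSchedule, grid: SpellerGrid
) -> MixingMatrix:
    """Count per-group target proportions; identical for every attended symbol.

    By the paradigm's counting guarantees every selectable symbol sees the
    same per-group target/non-target split, so the mixing matrix can be
    read off the schedule by counting. A schedule violating this (after
    manual perturbation) raises.
    """
    groups = sorted(set(e.group for e in schedule.events))
    if len(groups) < 2:
        raise ValueError("schedule has a single proportion group: rank-1 mixing")
    rows = None
    for symbol in grid.selectable_indices:
        symbol = int(symbol)
        row = []
        for g in groups:
            in_group = [e for e in schedule.events if e.group == g]
            hits = sum(symbol in e.highlighted for e in in_group)
            row.append(hits / len(in_group))
        row = np.asarray(row)
        if rows is None:
            rows = row
        elif not np.allclose(row, rows, atol=1e-12):
            raise ValueError(
                "target proportions differ across attended symbols: "
                "the schedule violates the label-proportion paradigm"
            )
    proportions = np.column_stack([rows, 1.0 - rows])
    return MixingMatrix(proportions, group_names=tuple(groups))


def trial_timing(
    n_events: int = 68,
    soa_s: float = 0.25,
    cue_s: float = 4.0,
    feedback_s: float = 4.0,
) -> tuple[float, float]:
    """(seconds per character, max characters per minute).

    Study defaults: 68 events at 250 ms SOA = 17 s of highlighting, plus
    4 s cue and 4 s feedback → 25 s per character, 2.4 characters/minute.
    """
    seconds = n_events * soa_s + cue_s + feedback_s
    return seconds, 60.0 / seconds


# -- JSONL schedule round trip ---------------------------------------------


def write_schedules(path: str | Path, schedules: Sequence[StimulusSchedule]) -> None:
    """One event per line: trial_id, group, block, highlighted indices."""
    with Path(path).open("w") as fh:
        for schedule in schedules:
            for event in schedule.events:
                fh.write(
                    json.dumps(
                        {
                            "trial_id": schedule.trial_id,
                            "group": event.group,
                            "block": event.block,
                            "highlighted": sorted(event.highlighted),
                        }
                    )
                    + "\n"
                )


def read_schedules(path: str | Path) -> list[StimulusSchedule]:
    by_trial: dict[int, list[StimulusEvent]] = {}
    with Path(path).open() as fh:
        for line in fh:
            rec = json.loads(line)
            by_trial.setdefault(rec["trial_id"], []).append(
                StimulusEvent(frozenset(rec["highlighted"]), rec["group"], rec["block"])
            )
    return [
        StimulusSchedule(events=events, trial_id=tid)
        for tid, events in sorted(by_trial.items())
    ]
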