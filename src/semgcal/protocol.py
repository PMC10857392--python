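"""Cross-session evaluation protocol: dataset variants and training grids.

Sessions are split into fixed roles: early sessions train the model, one
session validates the classifier choice, and each remaining session is
tested after optionally donating its first few trials as calibration data.
Four training-set compositions are compared on an identical test set:

* baseline   — all trials of the train + validation sessions;
* calibrated — only the first ``n_calib`` trials of the test session;
* updated    — baseline plus the test session's calibration trials;
* cumulative — baseline plus the calibration trials of every test-role
  session up to and including the current one.

"First/final trials" are counted per gesture in acquisition order.  The
presets mirror the two study layouts: ``study`` (7 sessions, train 1-2,
validate 3, calibrate/test 4-7, final 15 of 20 trials tested) and
``db6like`` (10 sessions, train 1-3, validate 4, calibrate/test 5-10,
final 7 of 12 trials tested).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import List, Optional, Sequence, Tuple

__all__ = ["ProtocolSpec", "DatasetAssembly", "make_protocol", "assemble_dataset",
           "training_grid", "GridCell", "VARIANTS"]

VARIANTS = ("baseline", "calibrated", "updated", "cumulative")

Triple = Tuple[int, int, int]  # (session, gesture, trial)


@dataclass(frozen=True)
class ProtocolSpec:
    train_sessions: Tuple[int, ...]
    val_session: int
    calib_sessions: Tuple[int, ...]
    max_calib_trials: int
    test_trials_per_session: int
    trials_per_session: int

    def __post_init__(self) -> None:
        roles = list(self.train_sessions) + [self.val_session] + list(self.calib_sessions)
        if len(set(roles)) != len(roles):
            raise ValueError("train, validation and calibration/test sessions must be disjoint")
        if self.max_calib_trials + self.test_trials_per_session > self.trials_per_session:
            raise ValueError(
                "max_calib_trials + test_trials_per_session must not exceed trials_per_session"
            )
        if min(self.max_calib_trials, self.test_trials_per_session, self.trials_per_session) < 1:
            raise ValueError("trial counts must be >= 1")

    @property
    def baseline_sessions(self) -> Tuple[int, ...]:
        return tuple(self.train_sessions) + (self.val_session,)

    @property
    def test_trials(self) -> Tuple[int, ...]:
        first = self.trials_per_session - self.test_trials_per_session + 1
        return tuple(range(first, self.trials_per_session + 1))


_PRESETS = {
    "study": dict(train_sessions=(1, 2), val_session=3, calib_sessions=(4, 5, 6, 7),
                  max_calib_trials=5, test_trials_per_session=15, trials_per_session=20),
    "db6like": dict(train_sessions=(1, 2, 3), val_session=4,
                    calib_sessions=(5, 6, 7, 8, 9, 10),
                    max_calib_trials=5, test_trials_per_session=7, trials_per_session=12),
}


def make_protocol(preset: Optional[str] = None, **fields) -> ProtocolSpec:
    """Build a validated ProtocolSpec from a preset name and/or explicit fields."""
    if preset is not None:
        if preset not in _PRESETS:
            raise ValueError(f"unknown preset {preset!r}; choose from {sorted(_PRESETS)}")
        merged = dict(_PRESETS[preset])
        merged.update(fields)
        fields = merged
    fields["train_sessions"] = tuple(fields["train_sessions"])
    fields["calib_sessions"] = tuple(fields["calib_sessions"])
    return ProtocolSpec(**fields)


@dataclass(frozen=True)
class DatasetAssembly:
    """A dataset variant resolved to explicit (session, gesture, trial) members."""

    variant: str
    test_session: int
    n_calib: int
    train: Tuple[Triple, ...]
    test: Tuple[Triple, ...]

    def __post_init__(self) -> None:
        if set(self.train) & set(self.test):
            raise ValueError("train and test memberships overlap")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)


def _all_trials(sessions: Sequence[int], gestures: Sequence[int],
                trials: Sequence[int]) -> List[Triple]:
    return [(s, g, t) for s in sessions for g in gestures for t in trials]


def assemble_dataset(
    spec: ProtocolSpec,
    variant: str,
    test_session: int,
    n_calib: int,
    gestures: Sequence[int],
) -> DatasetAssembly:
    """Resolve one (variant, test session, n_calib) cell to trial memberships.

    The test membership — the final ``test_trials_per_session`` trials of
    the test session — is identical for all four variants.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    if test_session not in spec.calib_sessions:
        raise ValueError(f"session {test_session} is not a calibration/test session")
    if not 1 <= n_calib <= spec.max_calib_trials:
        raise ValueError(f"n_calib must be in 1..{spec.max_calib_trials}")

    all_trials = range(1, spec.trials_per_session + 1)
    calib_trials = range(1, n_calib + 1)
    baseline = _all_trials(spec.baseline_sessions, gestures, all_trials)

    if variant == "baseline":
        train = baseline
    elif variant == "calibrated":
        train = _all_trials([test_session], gestures, calib_trials)
    elif variant == "updated":
        train = baseline + _all_trials([test_session], gestures, calib_trials)
    else:  # cumulative
        upto = [s for s in spec.calib_sessions if s <= test_session]
        train = baseline + _all_trials(upto, gestures, calib_trials)

    test = _all_trials([test_session], gestures, spec.test_trials)
    return DatasetAssembly(variant=variant, test_session=test_session,
                           n_calib=n_calib, train=tuple(train), test=tuple(test))


@dataclass(frozen=True)
class GridCell:
    n_sessions: int
    n_trials: int
    train: Tuple[Triple, ...]


def training_grid(
    spec: ProtocolSpec,
    sessions_range: Sequence[int],
    trials_range: Sequence[int],
    gestures: Sequence[int],
    test_session: Optional[int] = None,
) -> Tuple[List[GridCell], Tuple[Triple, ...]]:
    """Training-amount grid: one training set per (n_sessions, n_trials).

    Cell (S, T) contains the first S sessions and, per gesture, the first T
    trials of each.  Evaluation uses all trials of ``test_session`` (by
    default the last session), which must lie outside every cell.
    """
    max_session = max(spec.calib_sessions)
    if test_session is None:
        test_session = max_session
    if max(sessions_range) >= test_session:
        raise ValueError("training grid must not touch the test session")
    if max(trials_range) > spec.trials_per_session:
        raise ValueError("trials_range exceeds trials_per_session")
    cells = []
    for n_sessions in sessions_range:
        for n_trials in trials_range:
            train = _all_trials(range(1, n_sessions + 1), gestures, range(1, n_trials + 1))
            cells.append(GridCell(n_sessions=n_sessions, n_trials=n_trials, train=tuple(train)))
    test = tuple(_all_trials([test_session], gestures, range(1, spec.trials_per_session + 1)))
    return cells, test
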