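"""Core data model for foraging experiments.

A foraging trial is an ordered sequence of target selections from a
*stimulus*: a set of targets of two classes (``a`` and ``b``), each with an
optional spatial position. This module holds the containers (:class:`Target`,
:class:`Stimulus`, :class:`Trial`, :class:`Dataset`), the classical run
statistics (:func:`run_summary`), inter-target step distances, and tabular
I/O in a simple CSV dialect.

CSV dialect
-----------
UTF-8, header row, one row per selection, columns
``participant,condition,trial,order,class,x,y`` with ``class`` in ``{a, b}``
and ``x,y`` optional floats (normalized stimulus-width units: x in [0, 1]).
``order`` is 1-based in files and 0-based internally. Optional columns
``n_a,n_b`` give the initial stimulus composition for non-exhaustive trials;
without them the stimulus is taken to be exactly the selected targets.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TargetClass",
    "Target",
    "Stimulus",
    "Trial",
    "Dataset",
    "RunSummary",
    "run_summary",
    "intertarget_distances",
    "read_trials",
    "write_trials",
]


class MalformedDataError(ValueError):
    """Raised when an input file violates the trial-CSV dialect."""


class TargetClass(str, enum.Enum):
    """Binary target category with a fixed signed coding (a = +1, b = -1)."""

    A = "a"
    B = "b"

    @property
    def code(self) -> int:
        return 1 if self is TargetClass.A else -1

    @property
    def other(self) -> "TargetClass":
        return TargetClass.B if self is TargetClass.A else TargetClass.A

    @classmethod
    def from_label(cls, label: str) -> "TargetClass":
        try:
            return cls(str(label))
        except ValueError:
            raise MalformedDataError(
                f"unknown target class {label!r}; expected 'a' or 'b'"
            ) from None


@dataclass(frozen=True)
class Target:
    """A single selectable target.

    Positions are in normalized stimulus-width units: x in [0, 1], y in
    [0, h] where h is the stimulus height/width ratio.
    """

    id: int
    cls: TargetClass
    pos: tuple[float, float] | None = None


@dataclass(frozen=True)
class Stimulus:
    """A set of binary-class targets, optionally with positions.

    Either every target has a position (spatial stimulus) or none does.
    """

    targets: tuple[Target, ...]
    height: float = 1.0

    def __post_init__(self):
        ids = [t.id for t in self.targets]
        if len(set(ids)) != len(ids):
            raise ValueError("target ids must be unique within a stimulus")
        has_pos = [t.pos is not None for t in self.targets]
        if any(has_pos) and not all(has_pos):
            raise ValueError("either all targets have positions or none do")
        for t in self.targets:
            if t.pos is not None:
                x, y = t.pos
                if not (-1e-9 <= x <= 1 + 1e-9 and -1e-9 <= y <= self.height + 1e-9):
                    raise ValueError(
                        f"target {t.id} position {t.pos} outside [0,1]x[0,{self.height}]"
                    )

    @classmethod
    def from_classes(cls, classes: Iterable[TargetClass | str],
                     positions: Sequence[tuple[float, float]] | None = None,
                     height: float = 1.0) -> "Stimulus":
        labels = [TargetClass.from_label(c) if not isinstance(c, TargetClass) else c
                  for c in classes]
        if positions is None:
            targets = tuple(Target(i, c) for i, c in enumerate(labels))
        else:
            targets = tuple(Target(i, c, tuple(p)) for i, (c, p) in
                            enumerate(zip(labels, positions, strict=True)))
        return cls(targets, height=height)

    @classmethod
    def from_counts(cls, n_a: int, n_b: int) -> "Stimulus":
        """Non-spatial stimulus with the given class composition."""
        return cls.from_classes([TargetClass.A] * n_a + [TargetClass.B] * n_b)

    @property
    def n_a(self) -> int:
        return sum(t.cls is TargetClass.A for t in self.targets)

    @property
    def n_b(self) -> int:
        return sum(t.cls is TargetClass.B for t in self.targets)

    @property
    def n_T(self) -> int:
        return len(self.targets)

    @property
    def is_spatial(self) -> bool:
        return len(self.targets) > 0 and self.targets[0].pos is not None

    def target(self, tid: int) -> Target:
        return self._by_id[tid]

    @property
    def _by_id(self) -> dict[int, Target]:
        return {t.id: t for t in self.targets}

    def positions(self) -> np.ndarray:
        """(n_T, 2) array of positions, ordered as ``self.targets``."""
        if not self.is_spatial:
            raise ValueError("stimulus has no positions")
        return np.array([t.pos for t in self.targets], dtype=float)

    def codes(self) -> np.ndarray:
        """(n_T,) array of signed class codes (+1 = a, -1 = b)."""
        return np.array([t.cls.code for t in self.targets], dtype=float)


@dataclass(frozen=True)
class Trial:
    """An ordered selection sequence over a stimulus."""

    stimulus: Stimulus
    selections: tuple[int, ...]
    participant: str = "p1"
    condition: str = "c1"
    trial_id: str = "t1"

    def __post_init__(self):
        if len(set(self.selections)) != len(self.selections):
            raise ValueError("selections must be distinct target ids")
        if len(self.selections) > self.stimulus.n_T:
            raise ValueError("more selections than targets")
        known = {t.id for t in self.stimulus.targets}
        missing = set(self.selections) - known
        if missing:
            raise ValueError(f"selected ids not in stimulus: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.selections)

    @property
    def class_sequence(self) -> list[TargetClass]:
        by_id = self.stimulus._by_id
        return [by_id[i].cls for i in self.selections]

    @property
    def class_labels(self) -> str:
        return "".join(c.value for c in self.class_sequence)

    def selected_positions(self) -> np.ndarray:
        if not self.stimulus.is_spatial:
            raise ValueError("trial is not spatial")
        by_id = self.stimulus._by_id
        return np.array([by_id[i].pos for i in self.selections], dtype=float)


@dataclass(frozen=True)
class RunSummary:
    """Run statistics of a class sequence.

    A *run* is a maximal block of consecutive selections of the same class.
    ``switch_rate`` is switches / (length - 1), defined as 0 for length-1
    sequences.
    """

    n_runs: int
    max_run: int
    length: int

    @property
    def switch_rate(self) -> float:
        if self.length <= 1:
            return 0.0
        return (self.n_runs - 1) / (self.length - 1)


def run_summary(sequence: Sequence) -> RunSummary:
    """Count maximal constant blocks ('runs') in a class sequence.

    Accepts any sequence of hashable labels (e.g. a string ``"aabba"``, a
    list of :class:`TargetClass`, or a :class:`Trial` whose class sequence
    is used).
    """
    if isinstance(sequence, Trial):
        sequence = sequence.class_sequence
    seq = list(sequence)
    if not seq:
        raise ValueError("empty sequence has no run statistics")
    n_runs = 1
    max_run = cur = 1
    for prev, nxt in zip(seq, seq[1:]):
        if nxt == prev:
            cur += 1
            max_run = max(max_run, cur)
        else:
            n_runs += 1
            cur = 1
    return RunSummary(n_runs=n_runs, max_run=max_run, length=len(seq))


def intertarget_distances(trial: Trial) -> np.ndarray:
    """Euclidean step distances between consecutive selections.

    Returns an array of length ``len(trial) - 1`` in normalized width units;
    empty for a single selection.
    """
    pos = trial.selected_positions()
    if len(pos) < 2:
        return np.empty(0)
    return np.linalg.norm(np.diff(pos, axis=0), axis=1)


class Dataset:
    """A collection of trials grouped by participant and condition."""

    def __init__(self, trials: Iterable[Trial]):
        self.trials: list[Trial] = list(trials)

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self) -> Iterator[Trial]:
        return iter(self.trials)

    @property
    def participants(self) -> list[str]:
        return sorted({t.participant for t in self.trials})

    @property
    def conditions(self) -> list[str]:
        return sorted({t.condition for t in self.trials})

    @property
    def is_spatial(self) -> bool:
        return bool(self.trials) and self.trials[0].stimulus.is_spatial

    def by_condition(self, condition: str) -> "Dataset":
        return Dataset(t for t in self.trials if t.condition == condition)

    def by_participant(self, participant: str) -> "Dataset":
        return Dataset(t for t in self.trials if t.participant == participant)

    def run_summaries(self) -> pd.DataFrame:
        rows = []
        for t in self.trials:
            rs = run_summary(t)
            rows.append({
                "participant": t.participant, "condition": t.condition,
                "trial": t.trial_id, "n_runs": rs.n_runs, "max_run": rs.max_run,
                "length": rs.length, "switch_rate": rs.switch_rate,
            })
        return pd.DataFrame(rows)

    def to_frame(self) -> pd.DataFrame:
        """Selections table in the CSV dialect (1-based order)."""
        rows = []
        for t in self.trials:
            by_id = t.stimulus._by_id
            nonexhaustive = len(t) < t.stimulus.n_T
            for k, tid in enumerate(t.selections):
                row = {
                    "participant": t.participant, "condition": t.condition,
                    "trial": t.trial_id, "order": k + 1,
                    "class": by_id[tid].cls.value,
                }
                if t.stimulus.is_spatial:
                    row["x"], row["y"] = by_id[tid].pos
                if nonexhaustive:
                    row["n_a"], row["n_b"] = t.stimulus.n_a, t.stimulus.n_b
                rows.append(row)
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Dataset":
        required = {"participant", "condition", "trial", "order", "class"}
        missing = required - set(df.columns)
        if missing:
            raise MalformedDataError(f"missing columns: {sorted(missing)}")
        spatial = {"x", "y"} <= set(df.columns) and df["x"].notna().all()
        has_counts = {"n_a", "n_b"} <= set(df.columns)
        trials = []
        for (part, cond, tid), g in df.groupby(
                ["participant", "condition", "trial"], sort=True):
            orders = g["order"].to_numpy()
            if len(set(orders)) != len(orders):
                raise MalformedDataError(
                    f"duplicate selection order in trial {tid!r} "
                    f"(participant {part!r}, condition {cond!r})"
                )
            g = g.sort_values("order")
            classes = [TargetClass.from_label(c) for c in g["class"]]
            positions = None
            if spatial:
                positions = list(zip(g["x"].astype(float), g["y"].astype(float)))
            if has_counts:
                n_a = int(g["n_a"].iloc[0])
                n_b = int(g["n_b"].iloc[0])
                sel_a = sum(c is TargetClass.A for c in classes)
                sel_b = len(classes) - sel_a
                if n_a < sel_a or n_b < sel_b:
                    raise MalformedDataError(
                        f"trial {tid!r}: stated counts smaller than selections"
                    )
                extra = ([TargetClass.A] * (n_a - sel_a)
                         + [TargetClass.B] * (n_b - sel_b))
                if positions is not None and extra:
                    raise MalformedDataError(
                        "non-exhaustive spatial trials need unselected "
                        "positions, which the CSV dialect does not carry"
                    )
                classes = classes + extra
            stim = Stimulus.from_classes(classes, positions)
            trials.append(Trial(
                stimulus=stim,
                selections=tuple(range(len(g))),
                participant=str(part), condition=str(cond), trial_id=str(tid),
            ))
        return cls(trials)


def read_trials(path, schema: dict[str, str] | None = None) -> Dataset:
    """Read a trial CSV into a :class:`Dataset`.

    ``schema`` optionally maps dialect column names to the file's column
    names, e.g. ``{"participant": "subj"}``.
    """
    df = pd.read_csv(path)
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    return Dataset.from_frame(df)


def write_trials(dataset: Dataset, path) -> None:
    """Write a dataset in the trial-CSV dialect."""
    dataset.to_frame().to_csv(path, index=False)
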