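"""Domain types for two-alternative forced-choice (2AFC) lateralization data.

Every behavioral trial presents a binaural cue pair: an interaural time
difference (ITD, µs) and an interaural level difference (ILD, dB).  The sign
convention throughout the package is *negative = left*: a negative ITD means
the left ear leads, a negative ILD means the left ear is louder.

Trials fall into two classes:

* **honesty trials** — the two cues agree (same sign, or one cue is zero), so
  a correct side exists; the animal is rewarded only for responding on that
  side.  Honesty trials anchor session quality control.
* **probe trials** — the cues point in opposite directions; there is no
  correct side, the animal is always rewarded, and its choice reveals the
  relative perceptual weighting of the two cues.

The condition (0 µs, 0 dB) carries no lateral information and is never
presented; encountering it anywhere is an error, never a silent drop.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    InvalidConditionError,
    QCWarning,
    UndefinedSideError,
)

#: Default stimulus grids: ITD in µs, ILD in dB.  With the (0, 0) cell
#: excluded this is a 24-condition design: 16 honesty + 8 probe conditions.
DEFAULT_ITD_GRID: tuple[float, ...] = (-80.0, -60.0, 0.0, 60.0, 80.0)
DEFAULT_ILD_GRID: tuple[float, ...] = (-4.0, -1.0, 0.0, 1.0, 4.0)

#: Electrical stimulation rate label attached to trials (pulses per second).
DEFAULT_PULSE_RATE_PPS: int = 900


class TrialClass(str, enum.Enum):
    HONESTY = "honesty"
    PROBE = "probe"


class Side(str, enum.Enum):
    LEFT = "left"
    RIGHT = "right"


@dataclass(frozen=True)
class StimulusCondition:
    """One (ITD, ILD) cue pair; negative values point to the left ear."""

    itd_us: float
    ild_db: float
    pulse_rate_pps: int = DEFAULT_PULSE_RATE_PPS

    def __post_init__(self) -> None:
        if not (math.isfinite(self.itd_us) and math.isfinite(self.ild_db)):
            raise InvalidConditionError(
                f"non-finite stimulus condition ({self.itd_us}, {self.ild_db})"
            )
        if self.pulse_rate_pps <= 0:
            raise InvalidConditionError(
                f"pulse rate must be positive, got {self.pulse_rate_pps}"
            )

    @property
    def cell(self) -> tuple[float, float]:
        """The (itd_us, ild_db) key used by response tables."""
        return (self.itd_us, self.ild_db)


def classify_trial(condition: StimulusCondition) -> TrialClass:
    """Classify a condition as an honesty or a probe trial.

    Probe trials are exactly the strict sign conflicts
    (``sign(itd) * sign(ild) < 0``); everything else — congruent signs or a
    single zero cue — is an honesty trial.  (0, 0) is invalid.
    """
    itd, ild = condition.itd_us, condition.ild_db
    if itd == 0 and ild == 0:
        raise InvalidConditionError(
            "(0 µs, 0 dB) is never presented and cannot be classified"
        )
    if itd * ild < 0:
        return TrialClass.PROBE
    return TrialClass.HONESTY


def correct_side(condition: StimulusCondition) -> Side:
    """Return the rewarded side of an honesty condition.

    The nonzero cue(s) define the side: negative cues point left, positive
    cues point right.  Probe conditions have no correct side and raise
    :class:`UndefinedSideError`.
    """
    if classify_trial(condition) is TrialClass.PROBE:
        raise UndefinedSideError(
            f"probe condition ({condition.itd_us} µs, {condition.ild_db} dB) "
            "has no correct side"
        )
    # Honesty: signs agree or one cue is zero, so itd + ild has the cue sign.
    return Side.LEFT if condition.itd_us + condition.ild_db < 0 else Side.RIGHT


@dataclass(frozen=True)
class Trial:
    """A single 2AFC response.

    Construction enforces the task's reward contract: probe trials are always
    rewarded, honesty trials are rewarded iff the response side matches
    :func:`correct_side`, and the declared trial class must match
    :func:`classify_trial`.
    """

    animal_id: str
    session_id: str
    trial_index: int
    condition: StimulusCondition
    trial_class: TrialClass
    response: Side
    rewarded: bool

    def __post_init__(self) -> None:
        expected = classify_trial(self.condition)
        if self.trial_class is not expected:
            raise ValueError(
                f"trial_class {self.trial_class.value!r} contradicts the cue "
                f"signs of ({self.condition.itd_us}, {self.condition.ild_db}); "
                f"expected {expected.value!r}"
            )
        if self.trial_class is TrialClass.PROBE:
            if not self.rewarded:
                raise ValueError("probe trials are always rewarded")
        else:
            should_reward = self.response is correct_side(self.condition)
            if self.rewarded is not should_reward:
                raise ValueError(
                    "honesty trial reward flag inconsistent with response side"
                )

    @property
    def correct(self) -> bool | None:
        """True/False for honesty trials, None for probes (no correct side)."""
        if self.trial_class is TrialClass.PROBE:
            return None
        return self.response is correct_side(self.condition)


@dataclass
class Session:
    """An ordered collection of trials from one animal on one session."""

    session_id: str
    animal_id: str
    trials: list[Trial] = field(default_factory=list)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_honesty(self) -> int:
        return sum(1 for t in self.trials if t.trial_class is TrialClass.HONESTY)

    @property
    def honesty_accuracy(self) -> float | None:
        """Fraction correct on honesty trials only; None if the session has none.

        Probe trials are excluded: they are rewarded unconditionally and would
        inflate the metric.
        """
        honest = [t for t in self.trials if t.trial_class is TrialClass.HONESTY]
        if not honest:
            return None
        return sum(t.correct for t in honest) / len(honest)


@dataclass
class QCResult:
    """Partition of sessions by the honesty-accuracy reliability criterion."""

    included: list[Session]
    excluded: list[Session]
    table: pd.DataFrame  # one row per session: accuracy, counts, included flag

    def __iter__(self):
        return iter((self.included, self.excluded))


def filter_sessions(
    sessions: Sequence[Session],
    threshold: float = 0.75,
    *,
    inclusive: bool = True,
) -> QCResult:
    """Apply the session reliability criterion on honesty-trial accuracy.

    A session is included when its honesty accuracy meets the threshold
    (``>=`` by default; set ``inclusive=False`` for a strict ``>``).  Sessions
    with zero honesty trials have undefined accuracy and are excluded with a
    :class:`QCWarning`.

    Returns a :class:`QCResult` whose ``table`` reports per-session accuracy
    for all input sessions (the session-performance series).
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    included: list[Session] = []
    excluded: list[Session] = []
    rows = []
    for s in sessions:
        acc = s.honesty_accuracy
        if acc is None:
            warnings.warn(
                f"session {s.session_id!r} of animal {s.animal_id!r} has no "
                "honesty trials; accuracy undefined, session excluded",
                QCWarning,
                stacklevel=2,
            )
            ok = False
        else:
            ok = acc >= threshold if inclusive else acc > threshold
        (included if ok else excluded).append(s)
        rows.append(
            {
                "animal_id": s.animal_id,
                "session_id": s.session_id,
                "n_trials": s.n_trials,
                "n_honesty": s.n_honesty,
                "honesty_accuracy": float("nan") if acc is None else acc,
                "included": ok,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "animal_id",
            "session_id",
            "n_trials",
            "n_honesty",
            "honesty_accuracy",
            "included",
        ],
    )
    return QCResult(included=included, excluded=excluded, table=table)


@dataclass
class ResponseTable:
    """Per-condition response counts, the sufficient statistics for fitting.

    ``counts`` maps a grid cell ``(itd_us, ild_db)`` to ``(n_right, n_total)``.
    Cells never presented are absent from the mapping (unknown, not
    zero-probability).  The excluded (0, 0) cell never appears.
    """

    animal_id: str
    itd_grid: tuple[float, ...] = DEFAULT_ITD_GRID
    ild_grid: tuple[float, ...] = DEFAULT_ILD_GRID
    counts: dict[tuple[float, float], tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (itd, ild), (k, n) in self.counts.items():
            if itd == 0 and ild == 0:
                raise InvalidConditionError("(0, 0) cell in response table")
            if itd not in self.itd_grid or ild not in self.ild_grid:
                raise ValueError(f"cell ({itd}, {ild}) is off the stimulus grid")
            if not 0 <= k <= n:
                raise ValueError(
                    f"cell ({itd}, {ild}): n_right={k} outside [0, n_total={n}]"
                )

    @property
    def n_trials(self) -> int:
        return sum(n for _, n in self.counts.values())

    def presented_cells(self) -> list[tuple[float, float]]:
        """Cells with at least one presented trial, in grid order."""
        return [
            (itd, ild)
            for ild in self.ild_grid
            for itd in self.itd_grid
            if self.counts.get((itd, ild), (0, 0))[1] > 0
        ]

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(itd, ild, n_right, n_total) arrays over presented cells."""
        cells = self.presented_cells()
        itd = np.array([c[0] for c in cells], dtype=float)
        ild = np.array([c[1] for c in cells], dtype=float)
        k = np.array([self.counts[c][0] for c in cells], dtype=float)
        n = np.array([self.counts[c][1] for c in cells], dtype=float)
        return itd, ild, k, n

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format table with one row per grid cell (absent cells NaN)."""
        rows = []
        for ild in self.ild_grid:
            for itd in self.itd_grid:
                if itd == 0 and ild == 0:
                    continue
                k, n = self.counts.get((itd, ild), (0, 0))
                rows.append(
                    {
                        "animal_id": self.animal_id,
                        "itd_us": itd,
                        "ild_db": ild,
                        "n_right": k,
                        "n_total": n,
                        "p_right": k / n if n else float("nan"),
                    }
                )
        return pd.DataFrame(rows)

    def to_matrix(self) -> pd.DataFrame:
        """Right-response fraction matrix: rows ILD descending, columns ITD ascending."""
        ilds = sorted(self.ild_grid, reverse=True)
        itds = sorted(self.itd_grid)
        data = []
        for ild in ilds:
            row = []
            for itd in itds:
                k, n = self.counts.get((itd, ild), (0, 0))
                row.append(k / n if n else float("nan"))
            data.append(row)
        return pd.DataFrame(data, index=ilds, columns=itds)


def build_response_table(
    sessions: Iterable[Session],
    animal_id: str | None = None,
    itd_grid: Sequence[float] = DEFAULT_ITD_GRID,
    ild_grid: Sequence[float] = DEFAULT_ILD_GRID,
) -> ResponseTable:
    """Tally right responses per grid cell over (QC-filtered) sessions.

    Both honesty and probe trials are counted — conflicting-cue cells are what
    make cue trading measurable.  All trials must come from one animal; pass
    ``animal_id`` explicitly to assert which one (required when ``sessions``
    may be empty).
    """
    trials = [t for s in sessions for t in s.trials]
    animals = {t.animal_id for t in trials}
    if animal_id is None:
        if len(animals) != 1:
            raise ValueError(
                f"expected trials from exactly one animal, found {sorted(animals)}"
            )
        animal_id = next(iter(animals))
    elif animals - {animal_id}:
        raise ValueError(
            f"trials from animals {sorted(animals - {animal_id})} mixed into "
            f"table for {animal_id!r}"
        )
    counts: dict[tuple[float, float], list[int]] = {}
    for t in trials:
        cell = t.condition.cell
        if cell[0] not in itd_grid or cell[1] not in ild_grid:
            raise ValueError(f"trial condition {cell} is off the stimulus grid")
        c = counts.setdefault(cell, [0, 0])
        c[0] += t.response is Side.RIGHT
        c[1] += 1
    return ResponseTable(
        animal_id=animal_id,
        itd_grid=tuple(itd_grid),
        ild_grid=tuple(ild_grid),
        counts={cell: (k, n) for cell, (k, n) in counts.items()},
    )


def grid_conditions(
    itd_grid: Sequence[float] = DEFAULT_ITD_GRID,
    ild_grid: Sequence[float] = DEFAULT_ILD_GRID,
    pulse_rate_pps: int = DEFAULT_PULSE_RATE_PPS,
) -> tuple[list[StimulusCondition], list[StimulusCondition]]:
    """All presentable grid conditions split into (honesty, probe) lists."""
    honesty, probe = [], []
    for itd in itd_grid:
        for ild in ild_grid:
            if itd == 0 and ild == 0:
                continue
            cond = StimulusCondition(itd, ild, pulse_rate_pps)
            (probe if classify_trial(cond) is TrialClass.PROBE else honesty).append(
                cond
            )
    return honesty, probe
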