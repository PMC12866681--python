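"""Trial-log reading and writing.

The trial log is the single interchange format between all modules and the
command line: UTF-8, comma-delimited, dot decimal separator, mandatory header,
booleans serialized as ``true``/``false``.  Columns::

    animal_id, session_id, trial_index, itd_us, ild_db,
    trial_class, response, rewarded, pulse_rate_pps

Writing is deterministic (fixed column order and number formatting), so
identical session collections produce byte-identical files.
"""

from __future__ import annotations

import csv
import warnings
from pathlib import Path
from typing import Iterable

from .errors import (
    InvalidConditionError,
    TrialClassMismatchWarning,
    TrialLogError,
)
from .schema import (
    Session,
    Side,
    StimulusCondition,
    Trial,
    TrialClass,
    classify_trial,
)

COLUMNS = (
    "animal_id",
    "session_id",
    "trial_index",
    "itd_us",
    "ild_db",
    "trial_class",
    "response",
    "rewarded",
    "pulse_rate_pps",
)

_REQUIRED = COLUMNS[:-1]  # pulse_rate_pps is optional on read


def _fmt(value: float) -> str:
    return format(value, ".10g")


def write_trial_log(sessions: Iterable[Session], path: str | Path) -> None:
    """Serialize sessions to a trial-log CSV (deterministic byte layout)."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(COLUMNS)
        for session in sessions:
            for t in sorted(session.trials, key=lambda t: t.trial_index):
                if t.condition.itd_us == 0 and t.condition.ild_db == 0:
                    raise InvalidConditionError(
                        f"refusing to serialize (0, 0) trial in session "
                        f"{session.session_id!r}"
                    )
                writer.writerow(
                    [
                        t.animal_id,
                        t.session_id,
                        t.trial_index,
                        _fmt(t.condition.itd_us),
                        _fmt(t.condition.ild_db),
                        t.trial_class.value,
                        t.response.value,
                        "true" if t.rewarded else "false",
                        t.condition.pulse_rate_pps,
                    ]
                )


def read_trial_log(path: str | Path) -> list[Session]:
    """Parse a trial log into sessions grouped by (animal_id, session_id).

    Trials are ordered by ``trial_index`` within each session.  The declared
    ``trial_class`` of every row is cross-checked against the cue signs; rows
    that disagree are re-classified and reported once via
    :class:`TrialClassMismatchWarning`.  Structural problems (missing columns,
    unparsable numbers, out-of-vocabulary responses, duplicate trial indices,
    the forbidden (0, 0) condition, reward-rule violations) raise
    :class:`TrialLogError` naming the offending row.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise TrialLogError(f"{path}: empty file, no header")
        missing = [c for c in _REQUIRED if c not in reader.fieldnames]
        if missing:
            raise TrialLogError(f"{path}: missing required column(s) {missing}")
        groups: dict[tuple[str, str], list[Trial]] = {}
        seen: set[tuple[str, str, int]] = set()
        mismatches: list[str] = []
        for lineno, row in enumerate(reader, start=2):
            trial = _parse_row(path, lineno, row, mismatches)
            key = (trial.animal_id, trial.session_id)
            dup = (trial.animal_id, trial.session_id, trial.trial_index)
            if dup in seen:
                raise TrialLogError(
                    f"{path}: row {lineno}: duplicate trial_index "
                    f"{trial.trial_index} in session {trial.session_id!r}"
                )
            seen.add(dup)
            groups.setdefault(key, []).append(trial)
    if mismatches:
        warnings.warn(
            f"{path}: {len(mismatches)} trial(s) re-classified from the cue "
            "signs: " + "; ".join(mismatches),
            TrialClassMismatchWarning,
            stacklevel=2,
        )
    return [
        Session(
            session_id=session_id,
            animal_id=animal_id,
            trials=sorted(trials, key=lambda t: t.trial_index),
        )
        for (animal_id, session_id), trials in groups.items()
    ]


def _parse_row(
    path: Path, lineno: int, row: dict[str, str], mismatches: list[str]
) -> Trial:
    def fail(msg: str) -> TrialLogError:
        return TrialLogError(f"{path}: row {lineno}: {msg}")

    try:
        itd = float(row["itd_us"])
        ild = float(row["ild_db"])
        trial_index = int(row["trial_index"])
        rate_raw = row.get("pulse_rate_pps")
        rate = int(rate_raw) if rate_raw not in (None, "") else 900
    except (ValueError, TypeError) as exc:
        raise fail(f"unparsable numeric field ({exc})") from exc

    resp_raw = (row["response"] or "").strip().lower()
    try:
        response = Side(resp_raw)
    except ValueError:
        raise fail(
            f"response {row['response']!r} not in {{'left', 'right'}}"
        ) from None

    rew_raw = (row["rewarded"] or "").strip().lower()
    if rew_raw not in ("true", "false"):
        raise fail(f"rewarded {row['rewarded']!r} not in {{'true', 'false'}}")
    rewarded = rew_raw == "true"

    cls_raw = (row["trial_class"] or "").strip().lower()
    try:
        declared = TrialClass(cls_raw)
    except ValueError:
        raise fail(
            f"trial_class {row['trial_class']!r} not in {{'honesty', 'probe'}}"
        ) from None

    try:
        condition = StimulusCondition(itd, ild, rate)
        expected = classify_trial(condition)
    except InvalidConditionError as exc:
        raise fail(str(exc)) from exc

    if declared is not expected:
        mismatches.append(
            f"row {lineno} ({itd:g} µs, {ild:g} dB) declared "
            f"{declared.value}, is {expected.value}"
        )
    try:
        return Trial(
            animal_id=row["animal_id"],
            session_id=row["session_id"],
            trial_index=trial_index,
            condition=condition,
            trial_class=expected,
            response=response,
            rewarded=rewarded,
        )
    except ValueError as exc:
        raise fail(str(exc)) from exc
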