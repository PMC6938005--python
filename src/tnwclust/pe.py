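"""Prefix-encoded (PE) temporal event sequences.

A PE sequence describes one subject's event history as alternating
inter-event durations and state symbols, e.g. ``"0.A,5.B,2.Z"``: the
subject entered state ``A`` at time 0, switched to ``B`` five time units
later, and was censored (symbol ``Z``) two units after that.  The leading
duration is always 0.  Durations are kept in whatever unit the source data
uses; no rescaling is applied.

This module builds PE sequences from panel-format longitudinal records
(one row per visit), parses and serializes the text encoding, and reads
and writes one-sequence-per-line files.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Reserved censoring symbol: marks that the final state's outcome is
#: unobserved (e.g. an ongoing therapy at the end of follow-up).
CENSOR_SYMBOL = "Z"


class PEParseError(ValueError):
    """Raised when a PE-format string violates the grammar."""


@dataclass(frozen=True)
class Event:
    """One state in a trajectory.

    Parameters
    ----------
    symbol : str
        State label drawn from a finite alphabet.  Must be non-empty and
        contain neither ``","`` nor ``"."`` (both are grammar delimiters).
    preceding_duration : float
        Time elapsed since the previous event; 0 for the first event.
    """

    symbol: str
    preceding_duration: float

    def __post_init__(self) -> None:
        if not self.symbol or "," in self.symbol or "." in self.symbol:
            raise ValueError(f"invalid event symbol {self.symbol!r}")
        if self.preceding_duration < 0:
            raise ValueError(
                f"negative duration {self.preceding_duration!r} before {self.symbol!r}"
            )


@dataclass(frozen=True)
class PESequence:
    """An ordered, prefix-encoded event sequence for one subject."""

    patient_id: str
    events: tuple[Event, ...]

    def __post_init__(self) -> None:
        if len(self.events) < 1:
            raise ValueError("a PE sequence needs at least one event")
        if self.events[0].preceding_duration != 0:
            raise ValueError("first event must have preceding_duration 0")
        for pos, ev in enumerate(self.events[:-1]):
            if ev.symbol == CENSOR_SYMBOL:
                raise ValueError(
                    f"censoring symbol {CENSOR_SYMBOL!r} at non-final position {pos}"
                )

    def __len__(self) -> int:
        return len(self.events)

    @property
    def symbols(self) -> tuple[str, ...]:
        return tuple(ev.symbol for ev in self.events)

    @property
    def durations(self) -> tuple[float, ...]:
        return tuple(ev.preceding_duration for ev in self.events)

    @property
    def censored(self) -> bool:
        return self.events[-1].symbol == CENSOR_SYMBOL


def _format_duration(t: float) -> str:
    """Render a duration as positional decimal text: integers without a
    decimal point, otherwise the shortest digits that round-trip the
    float exactly (never exponent notation)."""
    if t == int(t):
        return str(int(t))
    return np.format_float_positional(t, unique=True, trim="-")


def parse_pe(text: str, patient_id: str = "") -> PESequence:
    """Parse a PE-format string like ``"0.A,5.B,2.Z"``.

    The grammar is ``duration "." symbol ("," duration "." symbol)*`` with
    a mandatory leading duration of 0.  Durations may carry a fractional
    part, so the *last* ``.`` of each token separates duration from symbol
    (symbols cannot contain ``.``).

    Raises
    ------
    PEParseError
        On malformed tokens, a negative duration, a non-zero first
        duration, or a censoring symbol in non-final position; the message
        names the offending token position.
    """
    tokens = text.strip().split(",")
    if tokens == [""]:
        raise PEParseError("empty PE string")
    events = []
    for pos, tok in enumerate(tokens):
        dur_s, sep, sym = tok.rpartition(".")
        if not sep or not sym or not dur_s:
            raise PEParseError(f"malformed token {tok!r} at position {pos}")
        try:
            dur = float(dur_s)
        except ValueError:
            raise PEParseError(
                f"unreadable duration {dur_s!r} at position {pos}"
            ) from None
        if dur < 0:
            raise PEParseError(f"negative duration {dur!r} at position {pos}")
        if pos == 0 and dur != 0:
            raise PEParseError(f"first duration must be 0, got {dur!r}")
        if sym == CENSOR_SYMBOL and pos != len(tokens) - 1:
            raise PEParseError(
                f"censoring symbol {CENSOR_SYMBOL!r} at non-final position {pos}"
            )
        try:
            events.append(Event(sym, dur))
        except ValueError as exc:
            raise PEParseError(f"{exc} (token position {pos})") from None
    return PESequence(patient_id, tuple(events))


def format_pe(seq: PESequence) -> str:
    """Serialize a PESequence; inverse of :func:`parse_pe`."""
    return ",".join(
        f"{_format_duration(ev.preceding_duration)}.{ev.symbol}" for ev in seq.events
    )


# ---------------------------------------------------------------------------
# panel data -> PE sequences


def _to_days(value, date_format: str | None):
    """Parse one time value as a date and return an ordinal day count."""
    if isinstance(value, (_dt.datetime, _dt.date, pd.Timestamp)):
        ts = pd.Timestamp(value)
    elif date_format is not None:
        ts = pd.to_datetime(value, format=date_format)
    else:
        ts = pd.to_datetime(value)  # ISO-8601 and friends
    return ts.normalize().value / 86_400_000_000_000  # ns -> days


def panel_to_pe(
    records: pd.DataFrame,
    *,
    time_mode: str = "numeric",
    id_col: str = "patient_id",
    event_col: str = "event",
    time_col: str = "time",
    date_format: str | None = None,
    collapse_repeats: bool = True,
    censor: bool = False,
) -> list[PESequence]:
    """Convert panel-format longitudinal records into PE sequences.

    Each row of ``records`` is one visit: a subject identifier, an event
    symbol, and a time stamp.  Two time representations are supported:
    ``time_mode="dates"`` turns calendar dates into day differences
    between consecutive visits, while ``time_mode="numeric"`` differences
    the raw numbers in whatever unit they are.  Rows are sorted by time
    within each subject, so input row order is irrelevant.

    Consecutive visits with the same symbol describe an ongoing state, not
    a switch; with ``collapse_repeats`` (the default) they are merged into
    a single event whose next transition spans all merged visits.  With
    ``censor=True``, a trajectory whose last state has no recorded end is
    closed with the censoring symbol, carrying the time from the start of
    that state to the last observed visit.

    Returns one PESequence per distinct subject, in order of first
    appearance.  Raises ``ValueError`` when a subject mixes the two time
    representations or has two different symbols at the same time.
    """
    if time_mode not in ("dates", "numeric"):
        raise ValueError(f"time_mode must be 'dates' or 'numeric', got {time_mode!r}")
    missing = {id_col, event_col, time_col} - set(records.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")

    sequences: list[PESequence] = []
    conflicts: list[str] = []
    for pid, grp in records.groupby(id_col, sort=False):
        if time_mode == "dates":
            try:
                times = [_to_days(v, date_format) for v in grp[time_col]]
            except (ValueError, TypeError):
                conflicts.append(str(pid))
                continue
        else:
            times = []
            ok = True
            for v in grp[time_col]:
                try:
                    times.append(float(v))
                except (ValueError, TypeError):
                    ok = False
                    break
            if not ok:
                conflicts.append(str(pid))
                continue
        rows = sorted(zip(times, grp[event_col].astype(str)), key=lambda r: r[0])

        # deduplicate exact ties; conflicting symbols at one time are an error
        visits: list[tuple[float, str]] = []
        bad = False
        for t, sym in rows:
            if visits and visits[-1][0] == t:
                if visits[-1][1] != sym:
                    bad = True
                    break
                continue
            visits.append((t, sym))
        if bad:
            conflicts.append(str(pid))
            continue

        if collapse_repeats:
            collapsed = [visits[0]]
            for t, sym in visits[1:]:
                if sym != collapsed[-1][1]:
                    collapsed.append((t, sym))
            states = collapsed
        else:
            states = visits

        events = [Event(states[0][1], 0.0)]
        for (t_prev, _), (t, sym) in zip(states, states[1:]):
            events.append(Event(sym, t - t_prev))
        if censor and events[-1].symbol != CENSOR_SYMBOL:
            last_state_start = states[-1][0]
            last_observed = visits[-1][0]
            events.append(Event(CENSOR_SYMBOL, last_observed - last_state_start))
        sequences.append(PESequence(str(pid), tuple(events)))

    if conflicts:
        raise ValueError(
            "conflicting or mixed time/event records for patients: "
            + ", ".join(conflicts)
        )
    return sequences


def read_panel(
    path,
    *,
    sep: str = ",",
    **kwargs,
) -> list[PESequence]:
    """Read a CSV/TSV panel file and convert it with :func:`panel_to_pe`."""
    return panel_to_pe(pd.read_csv(path, sep=sep), **kwargs)


def write_pe_file(sequences: Iterable[PESequence], path) -> None:
    """Write ``patient_id<TAB>pe_string`` lines."""
    with open(path, "w") as fh:
        for seq in sequences:
            fh.write(f"{seq.patient_id}\t{format_pe(seq)}\n")


def read_pe_file(path) -> list[PESequence]:
    """Read a file written by :func:`write_pe_file`."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            pid, _, text = line.partition("\t")
            out.append(parse_pe(text, pid))
    return out
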