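"""Footfall data model and delimited-text readers/writers.

The pipeline's raw input is a table of stance intervals: for every paw
contact of every limb we record the limb identity, the stance onset and
offset times (seconds), and the contact position on the runway (cm).
Contacts are grouped into locomotor *bouts* (one uninterrupted pass of the
animal along the runway); all downstream quantities -- step cycles, phase
differences, gaits -- are computed per bout.

The on-disk format is a plain CSV with the header
``bout_id,animal_id,condition,limb,onset_s,offset_s,x_cm,y_cm``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "Limb",
    "CONDITIONS",
    "StanceInterval",
    "Bout",
    "BoutParseError",
    "BoutValidationError",
    "normalize_condition",
    "read_bouts",
    "write_bouts",
]

log = logging.getLogger(__name__)

BOUT_COLUMNS = (
    "bout_id",
    "animal_id",
    "condition",
    "limb",
    "onset_s",
    "offset_s",
    "x_cm",
    "y_cm",
)

#: Recognized injury conditions; anything else is normalized to "other".
CONDITIONS = ("intact", "hemisection", "contusion", "other")


class Limb(str, Enum):
    """One of the four limbs of a quadruped."""

    LH = "LH"  #: left hindlimb (default reference limb)
    RH = "RH"  #: right hindlimb
    LF = "LF"  #: left forelimb
    RF = "RF"  #: right forelimb

    @property
    def is_hind(self) -> bool:
        return self in (Limb.LH, Limb.RH)

    @property
    def is_fore(self) -> bool:
        return not self.is_hind

    @property
    def is_left(self) -> bool:
        return self in (Limb.LH, Limb.LF)

    @property
    def is_right(self) -> bool:
        return not self.is_left

    @property
    def mirrored(self) -> "Limb":
        """The contralateral limb (left-right swap)."""
        return _MIRROR[self]


_MIRROR = {Limb.LH: Limb.RH, Limb.RH: Limb.LH, Limb.LF: Limb.RF, Limb.RF: Limb.LF}


class BoutParseError(ValueError):
    """A row of a bout file could not be parsed."""


class BoutValidationError(ValueError):
    """Parsed data violates a structural invariant (ordering, overlap...)."""


@dataclass(frozen=True)
class StanceInterval:
    """A single paw contact: one stance phase of one limb."""

    limb: Limb
    onset_s: float
    offset_s: float
    contact_x_cm: float
    contact_y_cm: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.onset_s, self.offset_s, self.contact_x_cm, self.contact_y_cm)
        if not all(math.isfinite(v) for v in vals):
            raise BoutValidationError(f"non-finite value in stance interval: {self}")
        if not self.onset_s < self.offset_s:
            raise BoutValidationError(
                f"stance onset must precede offset (limb {self.limb.value}: "
                f"onset {self.onset_s} >= offset {self.offset_s})"
            )

    @property
    def midstance_s(self) -> float:
        """Halfway point between stance onset and offset."""
        return 0.5 * (self.onset_s + self.offset_s)

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


def normalize_condition(text: str) -> str:
    """Map free-text condition labels onto the canonical enumeration."""
    cond = str(text).strip().lower()
    if cond in CONDITIONS:
        return cond
    log.warning("unknown condition %r mapped to 'other'", text)
    return "other"


@dataclass(frozen=True)
class Bout:
    """All stance intervals of one locomotor bout of one animal.

    On construction the intervals are sorted by (limb, onset) and validated:
    within each limb stances must not overlap (each offset strictly before
    the next onset).
    """

    bout_id: str
    animal_id: str
    condition: str
    intervals: tuple[StanceInterval, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "condition", normalize_condition(self.condition))
        ordered = tuple(
            sorted(self.intervals, key=lambda s: (s.limb.value, s.onset_s))
        )
        object.__setattr__(self, "intervals", ordered)
        for prev, cur in zip(ordered, ordered[1:]):
            if prev.limb is cur.limb and not prev.offset_s < cur.onset_s:
                raise BoutValidationError(
                    f"overlapping stances for limb {cur.limb.value} in bout "
                    f"{self.bout_id!r} (offset {prev.offset_s} >= onset {cur.onset_s})"
                )

    def intervals_for(self, limb: Limb) -> tuple[StanceInterval, ...]:
        return tuple(s for s in self.intervals if s.limb is limb)

    @property
    def analyzable(self) -> bool:
        """True when every limb contributed at least one stance."""
        present = {s.limb for s in self.intervals}
        return present == set(Limb)


def _parse_float(value: str, column: str, lineno: int) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        raise BoutParseError(
            f"line {lineno}: column {column!r} is not a number: {value!r}"
        ) from None


def read_bouts(path: str | Path) -> list[Bout]:
    """Read a bout CSV, returning validated :class:`Bout` objects.

    Bouts are returned grouped by ``bout_id`` in order of first appearance.
    Malformed rows raise :class:`BoutParseError` naming the offending line;
    invariant violations raise :class:`BoutValidationError`.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in BOUT_COLUMNS if c not in frame.columns]
    if missing:
        raise BoutParseError(f"{path}: missing column(s) {missing}")

    rows: dict[str, dict] = {}
    for i, rec in enumerate(frame.itertuples(index=False)):
        lineno = i + 2  # header is line 1
        try:
            limb = Limb(rec.limb)
        except ValueError:
            raise BoutParseError(
                f"line {lineno}: unknown limb code {rec.limb!r} "
                f"(expected one of {[l.value for l in Limb]})"
            ) from None
        interval = StanceInterval(
            limb=limb,
            onset_s=_parse_float(rec.onset_s, "onset_s", lineno),
            offset_s=_parse_float(rec.offset_s, "offset_s", lineno),
            contact_x_cm=_parse_float(rec.x_cm, "x_cm", lineno),
            contact_y_cm=_parse_float(rec.y_cm, "y_cm", lineno),
        )
        entry = rows.setdefault(
            rec.bout_id,
            {"animal_id": rec.animal_id, "condition": rec.condition, "intervals": []},
        )
        entry["intervals"].append(interval)

    return [
        Bout(
            bout_id=bout_id,
            animal_id=entry["animal_id"],
            condition=entry["condition"],
            intervals=tuple(entry["intervals"]),
        )
        for bout_id, entry in rows.items()
    ]


def write_bouts(bouts: Iterable[Bout], path: str | Path) -> None:
    """Write bouts to the CSV format read back by :func:`read_bouts`."""
    records = [
        {
            "bout_id": b.bout_id,
            "animal_id": b.animal_id,
            "condition": b.condition,
            "limb": s.limb.value,
            "onset_s": s.onset_s,
            "offset_s": s.offset_s,
            "x_cm": s.contact_x_cm,
            "y_cm": s.contact_y_cm,
        }
        for b in bouts
        for s in b.intervals
    ]
    frame = pd.DataFrame.from_records(records, columns=list(BOUT_COLUMNS))
    frame.to_csv(path, index=False)
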