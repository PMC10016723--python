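"""Domain types, validation and I/O for developmental event-coding tables.

The raw input of the analysis is a long-format table with one row per
(specimen, skeletal element, developmental event), holding the specimen's
standard length (SL, mm) and a binary state: 1 if the element has attained
the event's developmental state (present / cartilaginous / ossified /
segmented / bifurcated), 0 if not, missing if unobservable (staining or
preservation).  Serial elements are proximal radials (PR), distal radials
(DR) and lepidotrichia (L), numbered 1..n from the anterior to the
posterior of the fin.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

FINS = ("dorsal", "anal")
SERIES = ("PR", "DR", "L")

#: The eleven skeletogenic events of median fin formation, in ontogenetic
#: order of the fin as a whole.  Codes are fixed; names are descriptive.
EVENT_NAMES: Mapping[int, str] = {
    1: "actinotrichia_apparition",
    2: "proximal_radial_apparition",
    3: "proximal_radial_chondrification",
    4: "lepidotrichium_apparition",
    5: "distal_radial_apparition",
    6: "distal_radial_chondrification",
    7: "lepidotrichium_segmentation",
    8: "lepidotrichium_ossification",
    9: "lepidotrichium_bifurcation",
    10: "proximal_radial_ossification",
    11: "distal_radial_ossification",
}

#: Series each event applies to.
EVENT_SERIES: Mapping[int, str] = {
    2: "PR", 3: "PR", 4: "L", 5: "DR", 6: "DR",
    7: "L", 8: "L", 9: "L", 10: "PR", 11: "DR",
}

STATUSES = (
    "estimated", "nonsignificant", "always_present", "never_reached",
    "inestimable",
)

_COLUMNS = ["specimen_id", "SL_mm", "fin", "event", "series", "position",
            "state"]


class CodingError(ValueError):
    """Raised on invalid coding-table content."""


@dataclass(frozen=True, order=True)
class ElementId:
    """A serial skeletal element of a median fin.

    Ordering of elements within a series is by anterior-to-posterior
    position (1-based, matching the anatomical labels PR1, L01, ...).
    """
    fin: str
    series: str
    position: int

    def __post_init__(self):
        if self.fin not in FINS:
            raise CodingError(f"unknown fin {self.fin!r}")
        if self.series not in SERIES:
            raise CodingError(f"unknown series {self.series!r}")
        if self.position < 1:
            raise CodingError("element position must be >= 1")

    @property
    def label(self) -> str:
        width = 2 if self.series == "L" else 1
        return f"{self.series}{self.position:0{width}d}"

    def __str__(self):  # pragma: no cover - cosmetic
        return f"{self.fin}:{self.label}"


@dataclass(frozen=True)
class EventId:
    code: int
    name: str = ""

    def __post_init__(self):
        if self.code not in EVENT_NAMES:
            raise CodingError(f"unknown event code {self.code}")
        expected = EVENT_NAMES[self.code]
        if self.name and self.name != expected:
            raise CodingError(
                f"event {self.code} is {expected!r}, not {self.name!r}")
        object.__setattr__(self, "name", expected)


@dataclass(frozen=True)
class SpecimenRecord:
    """A cleared-and-stained specimen; ``age`` (days post hatching) is
    metadata only — standard length drives every analysis."""
    specimen_id: str
    standard_length: float
    age: float | None = None

    def __post_init__(self):
        if not self.standard_length > 0:
            raise CodingError(
                f"specimen {self.specimen_id!r}: non-positive SL "
                f"{self.standard_length}")


class EventCodingTable:
    """Validated long-format table of binary attainment states.

    Wraps a tidy :class:`pandas.DataFrame` with columns
    ``specimen_id, SL_mm, fin, event, series, position, state`` where
    ``state`` is 0.0, 1.0 or NaN (unobservable).
    """

    def __init__(self, frame: pd.DataFrame):
        self._frame = _validate_frame(frame)

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame.copy()

    @property
    def specimens(self) -> list[SpecimenRecord]:
        sub = self._frame.drop_duplicates("specimen_id")
        return [SpecimenRecord(r.specimen_id, r.SL_mm)
                for r in sub.itertuples()]

    def elements(self, fin: str, event: int) -> list[ElementId]:
        sub = self._frame[(self._frame.fin == fin)
                          & (self._frame.event == event)]
        out = {ElementId(fin, r.series, int(r.position))
               for r in sub.itertuples()}
        return sorted(out, key=lambda e: (e.series, e.position))

    def observations(self, element: ElementId, event: int
                     ) -> tuple[np.ndarray, np.ndarray]:
        """Complete-case (size, state) arrays for one element and event."""
        f = self._frame
        sub = f[(f.fin == element.fin) & (f.event == event)
                & (f.series == element.series)
                & (f.position == element.position)].dropna(subset=["state"])
        return sub.SL_mm.to_numpy(float), sub.state.to_numpy(float)

    def __len__(self):
        return len(self._frame)

    def __eq__(self, other):
        if not isinstance(other, EventCodingTable):
            return NotImplemented
        a = self._frame.sort_values(_COLUMNS[:6]).reset_index(drop=True)
        b = other._frame.sort_values(_COLUMNS[:6]).reset_index(drop=True)
        return a.equals(b)

    def write_csv(self, path) -> None:
        self._frame.to_csv(path, index=False)


def _validate_frame(frame: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _COLUMNS if c not in frame.columns]
    if missing:
        raise CodingError(f"missing columns: {missing}")
    f = frame[_COLUMNS].copy()
    f["state"] = pd.to_numeric(f["state"], errors="coerce")
    bad = f.state.dropna()[~f.state.dropna().isin([0.0, 1.0])]
    if len(bad):
        raise CodingError(
            f"states must be 0, 1 or missing; found {bad.iloc[0]!r} "
            f"at row {bad.index[0]}")
    f["SL_mm"] = pd.to_numeric(f["SL_mm"])
    if (f.SL_mm <= 0).any():
        row = f[f.SL_mm <= 0].iloc[0]
        raise CodingError(
            f"non-positive SL {row.SL_mm} for specimen {row.specimen_id!r}")
    if not f.fin.isin(FINS).all():
        raise CodingError("fin must be 'dorsal' or 'anal'")
    if not f.series.isin(SERIES).all():
        raise CodingError("series must be PR, DR or L")
    f["event"] = f.event.astype(int)
    if not f.event.isin(EVENT_NAMES).all():
        raise CodingError("event codes must be 1-11")
    f["position"] = f.position.astype(int)
    if (f.position < 1).any():
        raise CodingError("positions must be >= 1")
    key = ["specimen_id", "fin", "event", "series", "position"]
    dup = f.duplicated(key)
    if dup.any():
        r = f[dup].iloc[0]
        raise CodingError(
            "duplicate row for specimen "
            f"{r.specimen_id!r}, element {r.series}{r.position} "
            f"({r.fin}), event {r.event}")
    # one SL per specimen
    per = f.groupby("specimen_id").SL_mm.nunique()
    if (per > 1).any():
        raise CodingError(
            f"specimen {per[per > 1].index[0]!r} has conflicting SL values")
    return f.reset_index(drop=True)


def read_coding_table(path) -> EventCodingTable:
    """Read and validate a long-format coding CSV.

    Expected header: ``specimen_id, SL_mm, fin, event, series, position,
    state`` with state in {0, 1, empty/NA}.
    """
    return EventCodingTable(pd.read_csv(path,
                                        float_precision="round_trip"))


# ---------------------------------------------------------------------------
# SL50 profile containers


@dataclass(frozen=True)
class SL50Entry:
    """Per-element outcome of the logistic size-at-50%-attainment analysis.

    ``status`` is one of: estimated (significant fit), nonsignificant
    (fitted but failing the Bonferroni-corrected likelihood-ratio gate),
    always_present (attained in every specimen, no model possible),
    never_reached (attained in none), inestimable (no usable fit).
    ``span`` lists the lepidotrichium positions covered by a radial that
    articulates with more than one fin ray (stored once, never duplicated).
    """
    element: ElementId
    sl50: float | None
    status: str
    span: tuple[int, int] | None = None
    p_value: float | None = None
    n_obs: int | None = None
    fit_status: str | None = None

    def __post_init__(self):
        if self.status not in STATUSES:
            raise CodingError(f"unknown status {self.status!r}")
        has = self.sl50 is not None
        if has != (self.status in ("estimated", "nonsignificant")):
            raise CodingError(
                f"{self.element.label}: sl50 present iff status is "
                f"estimated/nonsignificant (got {self.status})")

    @property
    def rankable(self) -> bool:
        return self.status in ("estimated", "nonsignificant")


@dataclass(frozen=True)
class SL50Profile:
    """Anterior-to-posterior SL50 entries for one fin and event."""
    fin: str
    event: int
    entries: tuple[SL50Entry, ...]
    n_elements_tested: int = field(default=0)

    def __post_init__(self):
        pos = [e.element.position for e in self.entries]
        if pos != sorted(pos):
            raise CodingError("entries must be ordered by position")
        if len(set(pos)) != len(pos):
            raise CodingError("duplicate element positions in profile")

    def entry(self, position: int) -> SL50Entry | None:
        for e in self.entries:
            if e.element.position == position:
                return e
        return None

    def with_status(self, *statuses: str) -> list[SL50Entry]:
        return [e for e in self.entries if e.status in statuses]


# ---------------------------------------------------------------------------
# Packaged fixture: the published trout SL50 table


def load_published_sl50_table() -> dict[tuple[str, int], SL50Profile]:
    """Published per-element SL50 values for the rainbow trout dorsal and
    anal fins (events 2-10), with non-significance flags, always-present
    and inestimable statuses as printed.

    Returns a mapping (fin, event) -> :class:`SL50Profile` covering all
    18 profiles.  Multi-lepidotrichium radials carry a ``span`` annotation.
    """
    doc = _load_fixture_json()
    out: dict[tuple[str, int], SL50Profile] = {}
    for prof in doc["profiles"]:
        fin, event = prof["fin"], int(prof["event"])
        entries = []
        for e in prof["entries"]:
            entries.append(SL50Entry(
                element=ElementId(fin, e["series"], int(e["position"])),
                sl50=e.get("sl50"),
                status=e["status"],
                span=tuple(e["span"]) if "span" in e else None,
            ))
        tested = sum(1 for e in entries if e.rankable)
        out[(fin, event)] = SL50Profile(fin, event, tuple(entries), tested)
    return out


def smallest_specimen_sl(fin: str) -> float:
    """SL (mm) of the smallest specimen surveyed for a fin; used as the
    proxy size when ranking always-present elements first."""
    return float(_load_fixture_json()["smallest_specimen_sl_mm"][fin])


def _load_fixture_json() -> dict:
    ref = resources.files("finseq.data").joinpath("trout_sl50.json")
    with ref.open("r", encoding="utf-8") as fh:
        return json.load(fh)


def coding_table_from_rows(rows: Iterable[tuple]) -> EventCodingTable:
    """Build a table from (specimen_id, SL_mm, fin, event, series,
    position, state) tuples; state may be None for unobservable."""
    f = pd.DataFrame(list(rows), columns=_COLUMNS)
    return EventCodingTable(f)
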