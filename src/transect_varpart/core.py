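"""Data model for time-stamped video-transect detections.

A survey consists of fixed transects, each covered repeatedly by several
observers filming while snorkelling.  Every fish identification carries a
time stamp; because observers keep a constant swimming speed, a time stamp
maps linearly to a position along the transect, which lets a 50 m recording
be re-analysed as if the transect had been 10, 20, 30 or 40 m long by
keeping only detections inside a central distance window.

Two counting metrics are supported:

* ``MaxCount`` — total number of individuals of a species over the whole
  pass (sums all detection events);
* ``MinCount`` (a.k.a. MaxN) — the maximum number of individuals of a
  species visible simultaneously in one frame, which avoids double counting
  when the same fish re-enters the field of view.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, IntegrityError

#: Central distance windows (m) used to emulate shorter transects on a 50 m
#: recording: effective lengths 50, 40, 30, 20 and 10 m.
DISTANCE_WINDOWS: tuple[tuple[float, float], ...] = (
    (0.0, 50.0),
    (5.0, 45.0),
    (10.0, 40.0),
    (15.0, 35.0),
    (20.0, 30.0),
)

TRANSFORMS = ("none", "fourth_root", "log1p", "presence_absence")
METRICS = ("MaxCount", "MinCount", "PresenceAbsence")

REQUIRED_COLUMNS = (
    "island",
    "location",
    "transect",
    "observer",
    "repeat_index",
    "order_index",
    "direction",
    "duration_s",
    "turbidity_grade",
    "species",
    "t_start",
    "t_end",
    "n_individuals",
)


@dataclass(frozen=True)
class DetectionEvent:
    """One fish identification: a species on screen during [t_start, t_end]."""

    species_id: str
    t_start: float
    t_end: float
    n_individuals: int = 1

    def __post_init__(self) -> None:
        if self.t_start < 0:
            raise ValueError(f"t_start must be >= 0, got {self.t_start}")
        if self.t_end < self.t_start:
            raise ValueError("t_end must be >= t_start")
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")


@dataclass
class ObservationRecord:
    """One covered transect pass by one observer.

    ``order_index`` is the global temporal order (1..18) of the pass within
    its transect; ``repeat_index`` is the repeat (1..6) within the observer.
    """

    island: str
    location: str
    transect: str
    observer: str
    repeat_index: int
    order_index: int
    direction: str = "forward"
    duration_s: float = 276.0
    turbidity_grade: int = 1
    events: list[DetectionEvent] = field(default_factory=list)
    window_m: tuple[float, float] | None = None

    @property
    def key(self) -> tuple[str, str, str, str, int]:
        return (self.island, self.location, self.transect, self.observer, self.repeat_index)

    @property
    def transect_key(self) -> tuple[str, str, str]:
        return (self.island, self.location, self.transect)


@dataclass(frozen=True)
class StudyDesign:
    """Balanced hierarchical design: islands / locations / transects, with
    every transect covered ``repeats_per_observer`` times by each observer."""

    n_islands: int = 2
    locations_per_island: int = 5
    transects_per_location: int = 3
    n_observers: int = 3
    repeats_per_observer: int = 6
    transect_length_m: float = 50.0
    half_width_m: float = 2.5

    def __post_init__(self) -> None:
        for name in (
            "n_islands",
            "locations_per_island",
            "transects_per_location",
            "n_observers",
            "repeats_per_observer",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")

    @property
    def n_transects(self) -> int:
        return self.n_islands * self.locations_per_island * self.transects_per_location

    @property
    def passes_per_transect(self) -> int:
        return self.n_observers * self.repeats_per_observer

    @property
    def n_observations(self) -> int:
        return self.n_transects * self.passes_per_transect


@dataclass
class CommunityMatrix:
    """Observations x species count matrix with its provenance.

    ``counts`` has one row per observation (pass) and one column per
    species; ``row_meta`` carries the factor labels in the same row order.
    """

    counts: pd.DataFrame
    row_meta: pd.DataFrame
    metric: str = "MaxCount"
    window_m: tuple[float, float] | None = None
    transform: str = "none"

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("community matrix entries must be non-negative")
        if len(self.counts) != len(self.row_meta):
            raise ValueError("counts and row_meta must have the same number of rows")

    @property
    def species(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def values(self) -> np.ndarray:
        return self.counts.to_numpy(dtype=float)

    def to_wide_csv(self, path) -> None:
        pd.concat(
            [self.row_meta.reset_index(drop=True), self.counts.reset_index(drop=True)], axis=1
        ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# long-format I/O
# ---------------------------------------------------------------------------

def write_observations(records: Iterable[ObservationRecord], path) -> None:
    """Write records to long-format CSV, one detection event per row.

    An observation without any detection is written as a single row with an
    empty species field, so the pass itself is not lost on re-reading.
    """
    rows = []
    for rec in records:
        base = dict(
            island=rec.island,
            location=rec.location,
            transect=rec.transect,
            observer=rec.observer,
            repeat_index=rec.repeat_index,
            order_index=rec.order_index,
            direction=rec.direction,
            duration_s=rec.duration_s,
            turbidity_grade=rec.turbidity_grade,
        )
        if not rec.events:
            rows.append({**base, "species": "", "t_start": "", "t_end": "", "n_individuals": ""})
        for ev in rec.events:
            rows.append(
                {
                    **base,
                    "species": ev.species_id,
                    "t_start": ev.t_start,
                    "t_end": ev.t_end,
                    "n_individuals": ev.n_individuals,
                }
            )
    pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS)).to_csv(path, index=False)


def read_observations(path) -> list[ObservationRecord]:
    """Read long-format CSV into observation records.

    Records are grouped by (island, location, transect, observer, repeat)
    and ordered by ``order_index``.  A duplicated (transect, order_index)
    pair — two passes of the same transect claiming the same temporal slot —
    raises :class:`IntegrityError`.
    """
    df = pd.read_csv(path, dtype={"island": str, "location": str, "transect": str,
                                  "observer": str, "species": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required columns: {missing}")

    records: dict[tuple, ObservationRecord] = {}
    for _, row in df.iterrows():
        key = (
            str(row["island"]),
            str(row["location"]),
            str(row["transect"]),
            str(row["observer"]),
            int(row["repeat_index"]),
        )
        if key not in records:
            records[key] = ObservationRecord(
                island=key[0],
                location=key[1],
                transect=key[2],
                observer=key[3],
                repeat_index=key[4],
                order_index=int(row["order_index"]),
                direction=str(row["direction"]),
                duration_s=float(row["duration_s"]),
                turbidity_grade=int(row["turbidity_grade"]),
            )
        elif records[key].order_index != int(row["order_index"]):
            raise IntegrityError(f"inconsistent order_index within pass {key}")
        sp = row["species"]
        if isinstance(sp, str) and sp != "":
            records[key].events.append(
                DetectionEvent(
                    species_id=sp,
                    t_start=float(row["t_start"]),
                    t_end=float(row["t_end"]),
                    n_individuals=int(row["n_individuals"]),
                )
            )

    seen: dict[tuple, set[int]] = {}
    for rec in records.values():
        orders = seen.setdefault(rec.transect_key, set())
        if rec.order_index in orders:
            raise IntegrityError(
                f"duplicated order_index {rec.order_index} within transect {rec.transect_key}"
            )
        orders.add(rec.order_index)

    out = list(records.values())
    out.sort(key=lambda r: (r.island, r.location, r.transect, r.order_index))
    return out


# ---------------------------------------------------------------------------
# distance-window splitting
# ---------------------------------------------------------------------------

def split_distance_window(
    record: ObservationRecord,
    window: tuple[float, float],
    length_m: float = 50.0,
) -> ObservationRecord:
    """Keep only events whose mapped distance lies in the closed ``window``.

    Assuming constant swimming speed, the distance of an event from the
    transect start is ``d = (t_start / duration_s) * length_m``.  Events are
    windowed by their start time.
    """
    lo, hi = window
    if not (0 <= lo < hi <= length_m):
        raise ValueError(f"window must satisfy 0 <= lo < hi <= length, got {window}")
    if record.duration_s <= 0:
        raise ValueError("record duration must be positive")
    kept = [
        ev
        for ev in record.events
        if lo <= (ev.t_start / record.duration_s) * length_m <= hi
    ]
    return replace(record, events=list(kept), window_m=(lo, hi))


# ---------------------------------------------------------------------------
# counting metrics
# ---------------------------------------------------------------------------

def max_count(record: ObservationRecord, species: Sequence[str] | None = None) -> pd.Series:
    """Total individuals per species over all detection events of a pass."""
    if species is None:
        species = sorted({ev.species_id for ev in record.events})
    out = pd.Series(0, index=list(species), dtype=int)
    for ev in record.events:
        if ev.species_id in out.index:
            out[ev.species_id] += ev.n_individuals
    return out


def min_count(record: ObservationRecord, species: Sequence[str] | None = None) -> pd.Series:
    """Maximum simultaneously visible individuals per species (MaxN).

    Each event occupies the closed interval [t_start, t_end]; the MinCount
    of a species is the interval-stabbing maximum of the summed
    ``n_individuals``.  With closed intervals the maximum is attained at
    some event start, so scanning event starts is exact.
    """
    if species is None:
        species = sorted({ev.species_id for ev in record.events})
    out = pd.Series(0, index=list(species), dtype=int)
    by_species: dict[str, list[DetectionEvent]] = {}
    for ev in record.events:
        by_species.setdefault(ev.species_id, []).append(ev)
    for sp, evs in by_species.items():
        if sp not in out.index:
            continue
        best = 0
        for anchor in evs:
            t = anchor.t_start
            simultaneous = sum(e.n_individuals for e in evs if e.t_start <= t <= e.t_end)
            best = max(best, simultaneous)
        out[sp] = best
    return out


def presence_absence_count(record: ObservationRecord, species: Sequence[str] | None = None) -> pd.Series:
    return (max_count(record, species) > 0).astype(int)


_METRIC_FUNCS = {
    "MaxCount": max_count,
    "MinCount": min_count,
    "PresenceAbsence": presence_absence_count,
}


# ---------------------------------------------------------------------------
# transforms and community matrices
# ---------------------------------------------------------------------------

def _apply_transform(x: np.ndarray, transform: str) -> np.ndarray:
    if transform == "none":
        return x.astype(float)
    if transform == "fourth_root":
        return np.power(x.astype(float), 0.25)
    if transform == "log1p":
        return np.log1p(x.astype(float))
    if transform == "presence_absence":
        return (x > 0).astype(float)
    raise ValueError(f"unknown transform {transform!r}; choose from {TRANSFORMS}")


def transform_counts(matrix: CommunityMatrix, transform: str) -> CommunityMatrix:
    """Return a new community matrix with the elementwise transform applied.

    Counts contain zeros, so the logarithm is taken as log(1+y).
    """
    values = _apply_transform(matrix.counts.to_numpy(), transform)
    counts = pd.DataFrame(values, columns=matrix.counts.columns, index=matrix.counts.index)
    return CommunityMatrix(
        counts=counts,
        row_meta=matrix.row_meta,
        metric=matrix.metric,
        window_m=matrix.window_m,
        transform=transform,
    )


def build_community_matrix(
    records: Sequence[ObservationRecord],
    metric: str = "MaxCount",
    window: tuple[float, float] | None = None,
    length_m: float = 50.0,
    transform: str = "none",
    species: Sequence[str] | None = None,
) -> CommunityMatrix:
    """Assemble the observations x species matrix for one (metric, window).

    The species column order is the sorted global species list, so matrices
    derived from the same records under different metrics/windows are
    column-aligned.
    """
    if metric not in _METRIC_FUNCS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    if species is None:
        species = sorted({ev.species_id for rec in records for ev in rec.events})
    if window is not None:
        records = [split_distance_window(r, window, length_m) for r in records]
    func = _METRIC_FUNCS[metric]
    rows = [func(rec, species).to_numpy() for rec in records]
    counts = pd.DataFrame(np.asarray(rows, dtype=float), columns=list(species))
    meta = pd.DataFrame(
        {
            "island": [r.island for r in records],
            "location": [r.location for r in records],
            "transect": [r.transect for r in records],
            "observer": [r.observer for r in records],
            "repeat_index": [r.repeat_index for r in records],
            "order_index": [r.order_index for r in records],
            "turbidity_grade": [r.turbidity_grade for r in records],
        }
    )
    cm = CommunityMatrix(counts=counts, row_meta=meta, metric=metric, window_m=window,
                         transform="none")
    if transform != "none":
        cm = transform_counts(cm, transform)
    return cm


# ---------------------------------------------------------------------------
# univariate summaries
# ---------------------------------------------------------------------------

def species_density(counts: Sequence[float]) -> int:
    """Number of species with a positive count in one observation."""
    arr = np.asarray(counts, dtype=float)
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    return int((arr > 0).sum())


def shannon_diversity(counts: Sequence[float], base: float | None = None) -> float:
    """Shannon diversity H = -sum p log p of one observation row.

    Natural log by default (``base`` switches it).  An all-zero or
    single-species row has H = 0.
    """
    arr = np.asarray(counts, dtype=float)
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    total = arr.sum()
    if total <= 0:
        return 0.0
    p = arr[arr > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h
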