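"""Time-course container and its CSV dialect.

One :class:`TimeCourse` holds a strictly increasing time grid (minutes) and
one or more named series defined on that grid, each with a *kind*
(``species`` | ``observable`` | ``flux``), units, and a normalization tag
(``raw`` | ``max`` | ``fraction_of_basal``).

The on-disk dialect is a plain CSV with columns
``time_min, series, value, units, normalization`` (UTF-8, ``.`` decimal),
written with deterministic row order and 12-significant-digit floats so
identical time courses produce byte-identical files.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = ["SeriesMeta", "TimeCourse", "TimeCourseError",
           "read_timecourse", "write_timecourse"]

CSV_HEADER = ["time_min", "series", "value", "units", "normalization"]


class TimeCourseError(ValueError):
    """Malformed time-course data or file."""


@dataclass(frozen=True)
class SeriesMeta:
    kind: str = "species"          # species | observable | flux
    units: str = "M"
    normalization: str = "raw"     # raw | max | fraction_of_basal


@dataclass
class TimeCourse:
    """Time grid in minutes plus named series of equal length."""

    t_min: np.ndarray
    series: dict[str, np.ndarray]
    meta: dict[str, SeriesMeta] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t_min = np.asarray(self.t_min, dtype=float)
        if self.t_min.ndim != 1:
            raise TimeCourseError("time grid must be one-dimensional")
        if self.t_min.size and np.any(np.diff(self.t_min) <= 0):
            raise TimeCourseError("time grid must be strictly increasing")
        self.series = {k: np.asarray(v, dtype=float) for k, v in self.series.items()}
        for name, values in self.series.items():
            if values.shape != self.t_min.shape:
                raise TimeCourseError(
                    f"series {name!r}: length {values.size} != grid "
                    f"length {self.t_min.size}"
                )
            if not np.all(np.isfinite(values)):
                raise TimeCourseError(f"series {name!r} contains non-finite values")
        for name in self.series:
            self.meta.setdefault(name, SeriesMeta())

    def __getitem__(self, name: str) -> np.ndarray:
        return self.series[name]

    def names(self) -> list[str]:
        return sorted(self.series)

    def subset(self, names) -> "TimeCourse":
        return TimeCourse(
            self.t_min.copy(),
            {n: self.series[n].copy() for n in names},
            {n: self.meta[n] for n in names},
        )

    def equals(self, other: "TimeCourse", rtol: float = 0.0, atol: float = 0.0) -> bool:
        """Equality of grid, values and persisted metadata.

        The CSV dialect stores units and normalization but not the series
        kind, so ``kind`` is not compared.
        """
        if set(self.series) != set(other.series):
            return False
        if not np.allclose(self.t_min, other.t_min, rtol=rtol, atol=atol):
            return False
        return all(
            np.allclose(self.series[n], other.series[n], rtol=rtol, atol=atol)
            and (self.meta[n].units, self.meta[n].normalization)
            == (other.meta[n].units, other.meta[n].normalization)
            for n in self.series
        )


def _format(x: float) -> str:
    return f"{x:.12g}"


def write_timecourse(tc: TimeCourse, path) -> None:
    """Write *tc* in the CSV dialect (deterministic order; 12 sig. digits)."""
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(CSV_HEADER)
    for name in sorted(tc.series):
        m = tc.meta[name]
        for t, v in zip(tc.t_min, tc.series[name]):
            writer.writerow([_format(t), name, _format(v), m.units, m.normalization])
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(buf.getvalue())


def read_timecourse(path) -> TimeCourse:
    """Read a time course, validating header, rows and grid monotonicity.

    Rows may appear in any order; they are canonically sorted by series
    name and time.  Errors name the offending line number.
    """
    rows: dict[str, list[tuple[float, float]]] = {}
    meta: dict[str, SeriesMeta] = {}
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise TimeCourseError(f"{path}: empty file") from None
        if header != CSV_HEADER:
            raise TimeCourseError(
                f"{path}: line 1: expected header {','.join(CSV_HEADER)}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 5:
                raise TimeCourseError(f"{path}: line {lineno}: expected 5 columns")
            t_raw, name, v_raw, units, norm = row
            try:
                t, v = float(t_raw), float(v_raw)
            except ValueError:
                raise TimeCourseError(
                    f"{path}: line {lineno}: non-numeric value"
                ) from None
            if t < 0:
                raise TimeCourseError(f"{path}: line {lineno}: negative time {t}")
            m = SeriesMeta(meta.get(name, SeriesMeta()).kind, units, norm)
            prior = meta.setdefault(name, m)
            if (prior.units, prior.normalization) != (units, norm):
                raise TimeCourseError(
                    f"{path}: line {lineno}: inconsistent metadata for {name!r}"
                )
            rows.setdefault(name, []).append((t, v))

    if not rows:
        return TimeCourse(np.array([]), {})

    grids = {}
    series = {}
    for name, pairs in rows.items():
        pairs.sort()
        ts = np.array([p[0] for p in pairs])
        if np.any(np.diff(ts) <= 0):
            raise TimeCourseError(
                f"{path}: series {name!r}: duplicate or non-increasing times"
            )
        grids[name] = ts
        series[name] = np.array([p[1] for p in pairs])
    ref = next(iter(grids.values()))
    for name, ts in grids.items():
        if ts.shape != ref.shape or not np.array_equal(ts, ref):
            raise TimeCourseError(f"{path}: series {name!r} on a different grid")
    return TimeCourse(ref, series, meta)


def replicate_mean(replicates: Mapping[int, TimeCourse]) -> TimeCourse:
    """Pointwise mean across replicate time courses (shared grid)."""
    reps = list(replicates.values())
    first = reps[0]
    out = {}
    for name in first.series:
        out[name] = np.mean([r.series[name] for r in reps], axis=0)
    return TimeCourse(first.t_min.copy(), out, dict(first.meta))
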