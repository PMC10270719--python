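"""Readers and writers for every on-disk artifact, with a fixed dialect.

All tabular files are comma-separated UTF-8 with a mandatory header row and
``.`` decimal separator.  Floats are serialized with ``repr``-style shortest
round-trip formatting so identical inputs always produce byte-identical
files.  Vertices are 0-based indices into a :class:`RegionLabelSet`
internally; every user-facing file speaks region names.

Essential (infinite) bars serialize with empty ``death`` and ``longitude``
fields and ``essential=true``, mirroring the unbounded H0 lines of a
barcode plot.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np

from .tda_core import Bar, Simplex

if TYPE_CHECKING:  # pragma: no cover - import cycle guard
    from .features import SubjectFeature

__all__ = [
    "FormatError",
    "TimeCourseMatrix",
    "RegionLabelSet",
    "default_atlas",
    "read_time_courses",
    "write_time_courses",
    "read_distance_matrix",
    "write_distance_matrix",
    "write_barcodes",
    "read_barcodes",
    "write_cycles",
    "read_cycles",
]


class FormatError(ValueError):
    """Raised when an on-disk artifact violates the documented dialect."""


def _fmt(x: float) -> str:
    """Shortest decimal string that round-trips to the same float."""
    return repr(float(x))


@dataclass
class TimeCourseMatrix:
    """Labeled regional time courses: one BOLD-like signal per region.

    ``values`` has shape (n_regions, n_timepoints); row order matches
    ``region_labels``.  At least 3 regions (a 1-hole needs ≥ 3 boundary
    vertices) and 3 time points (a correlation needs variance) are
    required.
    """

    region_labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise FormatError(f"time courses must be 2-D, got {self.values.ndim}-D")
        n_regions, n_timepoints = self.values.shape
        if len(self.region_labels) != n_regions:
            raise FormatError(
                f"{len(self.region_labels)} labels for {n_regions} rows")
        if n_regions < 3:
            raise FormatError("need at least 3 regions")
        if n_timepoints < 3:
            raise FormatError("need at least 3 time points")
        if any(not lbl for lbl in self.region_labels):
            raise FormatError("empty region label")
        dupes = _duplicates(self.region_labels)
        if dupes:
            raise FormatError(f"duplicate region labels: {sorted(dupes)}")
        if np.isnan(self.values).any():
            bad = [self.region_labels[i]
                   for i in np.unique(np.nonzero(np.isnan(self.values))[0])]
            raise FormatError(f"missing values in rows: {bad}")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class RegionLabelSet:
    """Ordered region names; list position is the canonical vertex index."""

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        dupes = _duplicates(self.names)
        if dupes:
            raise FormatError(f"duplicate region names: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)


def _duplicates(items: Iterable[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for x in items:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup


def default_atlas() -> RegionLabelSet:
    """The 68 Desikan–Killiany cortical labels shipped with the package."""
    text = (resources.files("connectoloop") / "data" /
            "desikan_killiany_cortical.txt").read_text(encoding="utf-8")
    return RegionLabelSet(tuple(line for line in text.splitlines() if line))


# --------------------------------------------------------------------------
# time courses: CSV `region,t0,t1,...`, one row per region
# --------------------------------------------------------------------------

def read_time_courses(path: str | Path) -> TimeCourseMatrix:
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file") from None
        if not header or header[0] != "region":
            raise FormatError(f"{path}: header must start with 'region'")
        width = len(header)
        labels: list[str] = []
        rows: list[list[float]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != width:
                raise FormatError(
                    f"{path}: ragged row for region {row[0]!r} (line {lineno})")
            labels.append(row[0])
            try:
                rows.append([float(x) for x in row[1:]])
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric cell in region {row[0]!r} "
                    f"(line {lineno})") from None
    if not rows:
        raise FormatError(f"{path}: no data rows")
    return TimeCourseMatrix(region_labels=labels, values=np.array(rows))


def write_time_courses(tc: TimeCourseMatrix, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["region"] + [f"t{i}" for i in range(tc.n_timepoints)])
        for label, row in zip(tc.region_labels, tc.values):
            writer.writerow([label] + [_fmt(x) for x in row])


# --------------------------------------------------------------------------
# distance matrices: square CSV with labels on header row and first column
# --------------------------------------------------------------------------

def read_distance_matrix(path: str | Path) -> tuple[list[str], np.ndarray]:
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file") from None
        if not header or header[0] != "region":
            raise FormatError(f"{path}: header must start with 'region'")
        labels = header[1:]
        rows = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(labels) + 1:
                raise FormatError(f"{path}: ragged row (line {lineno})")
            if row[0] != labels[len(rows)]:
                raise FormatError(
                    f"{path}: row label {row[0]!r} does not match header order")
            try:
                rows.append([float(x) for x in row[1:]])
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric cell (line {lineno})") from None
    d = np.array(rows)
    if d.shape[0] != d.shape[1]:
        raise FormatError(f"{path}: matrix is {d.shape}, not square")
    return labels, d


def write_distance_matrix(labels: Sequence[str], d: np.ndarray,
                          path: str | Path) -> None:
    d = np.asarray(d, dtype=float)
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["region"] + list(labels))
        for label, row in zip(labels, d):
            writer.writerow([label] + [_fmt(x) for x in row])


# --------------------------------------------------------------------------
# barcodes: CSV `subject_id,dim,birth,death,longitude,essential`
# --------------------------------------------------------------------------

_BARCODE_HEADER = ["subject_id", "dim", "birth", "death", "longitude",
                   "essential"]


def write_barcodes(bars: Sequence[Bar], subject_id: str,
                   path: str | Path) -> None:
    """Write one subject's bars, sorted by (dim, birth, death)."""
    path = Path(path)
    ordered = sorted(bars, key=lambda b: (b.dim, b.birth, b.death))
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(_BARCODE_HEADER)
        for b in ordered:
            if b.essential:
                writer.writerow([subject_id, b.dim, _fmt(b.birth), "", "",
                                 "true"])
            else:
                writer.writerow([subject_id, b.dim, _fmt(b.birth),
                                 _fmt(b.death), _fmt(b.longitude), "false"])


def read_barcodes(path: str | Path) -> list[tuple[str, Bar]]:
    """Read a barcode CSV back into (subject_id, Bar) pairs.

    Simplex references are not stored on disk; returned bars carry a
    placeholder birth simplex of the right dimension.
    """
    path = Path(path)
    out: list[tuple[str, Bar]] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != _BARCODE_HEADER:
            raise FormatError(f"{path}: unexpected barcode header {header}")
        for row in reader:
            if not row:
                continue
            subject_id, dim_s, birth_s, death_s, _longitude_s, ess_s = row
            dim = int(dim_s)
            birth = float(birth_s)
            essential = ess_s == "true"
            death = math.inf if essential else float(death_s)
            placeholder = Simplex(tuple(range(dim + 1)), birth)
            out.append((subject_id,
                        Bar(dim=dim, birth=birth, death=death,
                            birth_simplex=placeholder)))
    return out


# --------------------------------------------------------------------------
# cycles: JSON array of per-subject longest-loop records
# --------------------------------------------------------------------------

def write_cycles(records: Sequence["SubjectFeature"], path: str | Path) -> None:
    """Serialize per-subject loop records as a JSON array.

    A subject without any positive-persistence H1 bar is recorded with
    ``regions: []`` and null birth/death/longitude rather than omitted, so
    cohort denominators stay visible.
    """
    payload = []
    for rec in records:
        if rec.bar is None:
            payload.append({"subject_id": rec.subject_id, "birth": None,
                            "death": None, "longitude": None, "regions": []})
        else:
            payload.append({
                "subject_id": rec.subject_id,
                "birth": rec.bar.birth,
                "death": rec.bar.death,
                "longitude": rec.bar.longitude,
                "regions": list(rec.regions),
            })
    Path(path).write_text(json.dumps(payload, indent=2) + "\n",
                          encoding="utf-8")


def read_cycles(path: str | Path) -> list[dict]:
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    if not isinstance(data, list):
        raise FormatError(f"{path}: expected a JSON array")
    return data
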