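"""Cohort-level aggregation of per-subject loop features.

Three summaries mirror the population-level figures of a connectome-loop
study: the distribution of longest-loop persistences, an enhanced
persistence diagram (one point per subject, annotated with the loop's
region count), and a region-occurrence frequency table counting in how
many subjects each brain region sits on the longest loop's boundary.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .features import SubjectFeature

__all__ = ["CohortSummary", "aggregate", "frequency_report",
           "write_cohort_summary"]

DEFAULT_BIN_WIDTH = 0.025


@dataclass
class CohortSummary:
    """Aggregated loop statistics for one cohort.

    ``length_histogram`` bins longest-loop longitudes with fixed-width
    bins on [0, 1]; the counts sum to the number of subjects with a
    present bar.  ``region_frequency`` counts subjects (once per subject,
    regardless of how often a region could appear) whose longest-loop
    representative contains each region.
    """

    features: list[SubjectFeature]
    bin_edges: np.ndarray
    counts: np.ndarray
    diagram_points: pd.DataFrame  # subject_id, birth, death, longitude, n_regions
    region_frequency: dict[str, int]

    @property
    def n_subjects(self) -> int:
        return len(self.features)

    @property
    def n_present(self) -> int:
        return int(self.counts.sum())


def aggregate(features: Sequence[SubjectFeature],
              bin_width: float = DEFAULT_BIN_WIDTH,
              label_set: Sequence[str] | None = None) -> CohortSummary:
    """Summarize a cohort of per-subject longest-loop records.

    The output is invariant to the order of ``features``: the histogram
    and frequency table are order-free, and diagram points are sorted by
    subject id.  If ``label_set`` is given, every region mentioned by any
    feature must belong to it (guards against mixing cohorts parcellated
    with different atlases).
    """
    if bin_width <= 0 or bin_width > 1:
        raise ValueError("bin_width must be in (0, 1]")
    if label_set is not None:
        known = set(label_set)
        for f in features:
            stray = set(f.regions) - known
            if stray:
                raise ValueError(
                    f"subject {f.subject_id!r} uses regions outside the "
                    f"cohort label set: {sorted(stray)}")
    n_bins = int(np.ceil(1.0 / bin_width))
    # round to 10 decimals so e.g. 6 * 0.05 lands on the decimal grid point
    edges = np.minimum(np.round(np.arange(n_bins + 1) * bin_width, 10), 1.0)

    present = [f for f in features if f.bar is not None]
    longitudes = np.array([f.bar.longitude for f in present])
    counts, _ = np.histogram(longitudes, bins=edges)

    rows = [{
        "subject_id": f.subject_id,
        "birth": f.bar.birth,
        "death": f.bar.death,
        "longitude": f.bar.longitude,
        "n_regions": f.n_regions,
    } for f in present]
    diagram = pd.DataFrame(rows, columns=["subject_id", "birth", "death",
                                          "longitude", "n_regions"])
    diagram = diagram.sort_values("subject_id", kind="stable",
                                  ignore_index=True)

    freq: dict[str, int] = {}
    for f in present:
        for region in set(f.regions):
            freq[region] = freq.get(region, 0) + 1

    return CohortSummary(features=list(features), bin_edges=edges,
                         counts=counts.astype(int), diagram_points=diagram,
                         region_frequency=freq)


def frequency_report(summary: CohortSummary,
                     ascending: bool = False) -> pd.DataFrame:
    """Region occurrence table: (region, count, fraction of all subjects).

    The fraction denominator is the full cohort — subjects without any
    loop included — matching how population percentages are usually
    quoted.  Sorted by count (descending by default), ties by name.
    """
    n = summary.n_subjects
    rows = [{"region": region, "count": count,
             "fraction": count / n if n else 0.0}
            for region, count in summary.region_frequency.items()]
    sign = 1 if ascending else -1
    rows.sort(key=lambda r: (sign * r["count"], r["region"]))
    return pd.DataFrame(rows, columns=["region", "count", "fraction"])


def _fmt(x: float) -> str:
    return repr(float(x))


def write_cohort_summary(summary: CohortSummary, out_dir: str | Path,
                         ascending: bool = False) -> None:
    """Write lengths.csv, diagram_points.csv, region_frequency.csv and
    projection.csv (a plain region→value table for external brain-surface
    viewers) into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    with (out / "lengths.csv").open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["bin_left", "bin_right", "count"])
        for left, right, c in zip(summary.bin_edges[:-1],
                                  summary.bin_edges[1:], summary.counts):
            w.writerow([_fmt(left), _fmt(right), int(c)])

    with (out / "diagram_points.csv").open("w", newline="",
                                           encoding="utf-8") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["subject_id", "birth", "death", "longitude", "n_regions"])
        for row in summary.diagram_points.itertuples(index=False):
            w.writerow([row.subject_id, _fmt(row.birth), _fmt(row.death),
                        _fmt(row.longitude), int(row.n_regions)])

    report = frequency_report(summary, ascending=ascending)
    with (out / "region_frequency.csv").open("w", newline="",
                                             encoding="utf-8") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["region", "count", "fraction"])
        for row in report.itertuples(index=False):
            w.writerow([row.region, int(row.count), _fmt(row.fraction)])

    with (out / "projection.csv").open("w", newline="",
                                       encoding="utf-8") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["region", "value"])
        for region in sorted(summary.region_frequency):
            w.writerow([region, int(summary.region_frequency[region])])
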