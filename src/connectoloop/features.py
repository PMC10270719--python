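"""Per-subject selection of the most persistent loop and its regions.

The subject-level result of the whole analysis is a single record: the
H1 bar with the largest longitude (persistence) and the brain regions on
the boundary of the cycle that witnesses it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .distance import DegenerateRegionError, correlation_distance
from .io_formats import TimeCourseMatrix
from .tda_core import (Bar, build_filtration, reduce_filtration,
                       representative_cycle, tighten_cycle)

__all__ = ["SubjectFeature", "longest_h1", "subject_pipeline"]


@dataclass
class SubjectFeature:
    """One subject's most persistent loop, or its recorded absence.

    ``regions`` lists the representative-cycle vertices mapped to region
    names, in canonical label order; it is empty exactly when ``bar`` is
    None (no positive-persistence H1 bar existed — counted in cohort
    denominators, not an error).
    """

    subject_id: str
    bar: Bar | None
    regions: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.bar is None) != (len(self.regions) == 0):
            raise ValueError("regions must be nonempty iff a bar is present")
        if self.bar is not None and len(self.regions) < 3:
            raise ValueError("a 1-cycle needs at least 3 boundary regions")

    @property
    def n_regions(self) -> int:
        return len(self.regions)


def longest_h1(bars: list[Bar]) -> Bar | None:
    """The finite dimension-1 bar with the largest longitude.

    Ties (measure zero on real data, but possible on constructed inputs)
    break deterministically: earliest birth first, then lexicographically
    smallest representative vertex tuple.  Returns None when no
    positive-longitude H1 bar exists.
    """
    candidates = [b for b in bars
                  if b.dim == 1 and not b.essential and b.longitude > 0.0]
    if not candidates:
        return None
    return min(candidates,
               key=lambda b: (-b.longitude, b.birth,
                              b.representative
                              if b.representative is not None
                              else b.birth_simplex.vertices))


def subject_pipeline(
    tc: TimeCourseMatrix,
    subject_id: str,
    *,
    form: str = "sqrt-half",
    eps_max: float = math.inf,
    keep_zero_bars: bool = False,
    tighten: bool = False,
) -> SubjectFeature:
    """Distance → filtration → reduction → longest loop, for one subject.

    Deterministic given the input and options.  ``tighten`` applies the
    greedy cycle-shortening pass to the winning bar's representative; off
    by default because the plain death-column cycle is the documented
    convention.
    """
    feature, _ = subject_pipeline_full(
        tc, subject_id, form=form, eps_max=eps_max,
        keep_zero_bars=keep_zero_bars, tighten=tighten)
    return feature


def subject_pipeline_full(
    tc: TimeCourseMatrix,
    subject_id: str,
    *,
    form: str = "sqrt-half",
    eps_max: float = math.inf,
    keep_zero_bars: bool = False,
    tighten: bool = False,
) -> tuple[SubjectFeature, list[Bar]]:
    """Like :func:`subject_pipeline` but also returns the full barcode."""
    try:
        d = correlation_distance(tc, form=form)
    except DegenerateRegionError as err:
        raise DegenerateRegionError(f"subject {subject_id!r}: {err}") from err
    filtration = build_filtration(d, max_dim=2, eps_max=eps_max)
    bars, state = reduce_filtration(filtration, keep_zero_bars=keep_zero_bars)
    bar = longest_h1(bars)
    if bar is None:
        return SubjectFeature(subject_id=subject_id, bar=bar), bars
    vertex_set = representative_cycle(bar, state)
    if tighten:
        edges = tighten_cycle(bar, d, state)
        bar.representative_edges = edges
        bar.representative = tuple(sorted({v for e in edges for v in e}))
        vertex_set = bar.representative
    if any(v >= tc.n_regions for v in vertex_set):
        raise RuntimeError("representative vertex outside the label set")
    regions = [tc.region_labels[v] for v in vertex_set]
    return SubjectFeature(subject_id=subject_id, bar=bar,
                          regions=regions), bars
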