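"""Correlation distance between regional time courses.

The point-cloud metric of the analysis: Pearson correlation r between two
regional signals is mapped to d = sqrt((1 − r) / 2), which sends perfectly
synchronized pairs (r = 1) to 0 and perfectly anti-synchronized pairs
(r = −1) to 1.  The sqrt form is a true metric — it equals the Euclidean
distance between the z-scored signals rescaled by 1/sqrt(2n) — so the
Vietoris–Rips construction downstream operates on a genuine metric space.
The plain (1 − r)/2 variant is available as ``form="half"`` for
sensitivity checks.

Because r is invariant to affine rescaling of either signal, to adding a
constant to every sample, and to applying one shared permutation of time
points to all signals, the distance matrix inherits all three invariances.
"""

from __future__ import annotations

import numpy as np

from .io_formats import FormatError, TimeCourseMatrix

__all__ = ["DegenerateRegionError", "pearson_r", "correlation_distance",
           "DISTANCE_FORMS"]

DISTANCE_FORMS = ("sqrt-half", "half")


class DegenerateRegionError(ValueError):
    """A region's time course has zero variance, so r is undefined."""


def pearson_r(x: np.ndarray, y: np.ndarray,
              names: tuple[str, str] = ("x", "y")) -> float:
    """Product-moment correlation, clamped to [−1, 1] against round-off."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be 1-D arrays of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(xc @ xc)
    sy = np.sqrt(yc @ yc)
    if sx == 0.0:
        raise DegenerateRegionError(f"region {names[0]!r} has zero variance")
    if sy == 0.0:
        raise DegenerateRegionError(f"region {names[1]!r} has zero variance")
    r = float((xc @ yc) / (sx * sy))
    return min(1.0, max(-1.0, r))


def correlation_distance(tc: TimeCourseMatrix,
                         form: str = "sqrt-half") -> np.ndarray:
    """Pairwise correlation distance of all regions of one subject.

    Returns an exactly symmetric (n, n) matrix with zero diagonal and
    entries in [0, 1].  Zero-variance rows raise
    :class:`DegenerateRegionError` naming the region; duplicated signals
    are legal and simply sit at distance 0.
    """
    if form not in DISTANCE_FORMS:
        raise ValueError(f"unknown distance form {form!r}; "
                         f"expected one of {DISTANCE_FORMS}")
    values = tc.values
    if np.isnan(values).any():
        raise FormatError("time courses contain NaN")
    stds = values.std(axis=1)
    flat = [tc.region_labels[i] for i in np.nonzero(stds == 0.0)[0]]
    if flat:
        raise DegenerateRegionError(
            f"zero-variance region(s): {flat}")

    r = np.corrcoef(values)
    r = np.clip(r, -1.0, 1.0)
    if form == "sqrt-half":
        d = np.sqrt((1.0 - r) / 2.0)
    else:
        d = (1.0 - r) / 2.0
    # enforce exact symmetry and a clean diagonal against round-off
    d = np.triu(d, k=1)
    d = d + d.T
    return d
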