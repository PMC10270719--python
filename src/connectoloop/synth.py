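"""Synthetic cohorts with a planted synchronization loop.

Each synthetic subject is a region × time matrix shaped like a
resting-state acquisition (defaults: 64 cortical regions, 255 time
points).  A chosen subset of K regions carries phase-shifted cosines on a
circle,

    x_k(t) = cos(2π · c · t/T + 2πk/K) + σ · ε_kt,

with an integer number of cycles c in the window so that, at σ = 0,
pairwise correlations are exactly cos(2πΔk/K) and correlation distances
are exactly |sin(πΔk/K)| — a planted 1-hole whose Vietoris–Rips
persistence is solvable in closed form.  The remaining "background"
regions share a weak common signal (so the null is not trivially distant
from the loop) plus independent noise:

    b_r(t) = sqrt(ρ) · g(t) + sqrt(1 − ρ) · η_rt.

All randomness flows through one root seed; subject s uses the NumPy
``SeedSequence([root_seed, s])`` stream, so any subject of a cohort can be
regenerated in isolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_formats import RegionLabelSet, TimeCourseMatrix, default_atlas

__all__ = ["SynthConfig", "region_labels_for", "generate_subject",
           "generate_cohort", "write_manifest"]


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; defaults emulate a resting-state cohort shape.

    ``cycles_in_window`` is the integer number of full oscillator periods
    across the acquisition (frequency = cycles_in_window / n_timepoints
    per sample); keeping it integral makes the σ = 0 correlations exact.
    """

    n_regions: int = 64
    n_timepoints: int = 255
    loop_size: int = 12
    loop_members: tuple[int, ...] | None = None  # default: first loop_size
    noise_sigma: float = 0.2
    cycles_in_window: int = 8
    background_corr: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.loop_size < 4:
            raise ValueError("loop_size must be at least 4")
        if self.loop_size > self.n_regions:
            raise ValueError("loop_size cannot exceed n_regions")
        if self.n_regions < 3 or self.n_timepoints < 3:
            raise ValueError("need at least 3 regions and 3 time points")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        if not (0 <= self.background_corr < 1):
            raise ValueError("background_corr must be in [0, 1)")
        if self.cycles_in_window < 1:
            raise ValueError("cycles_in_window must be a positive integer")
        members = self.members()
        if len(set(members)) != self.loop_size:
            raise ValueError("loop_members must be loop_size distinct indices")
        if any(m < 0 or m >= self.n_regions for m in members):
            raise ValueError("loop member index out of range")

    def members(self) -> tuple[int, ...]:
        if self.loop_members is None:
            return tuple(range(self.loop_size))
        return tuple(self.loop_members)


def region_labels_for(n_regions: int) -> list[str]:
    """Region names for a synthetic subject.

    The shipped Desikan–Killiany cortical labels are used as long as they
    suffice; beyond 68 regions, generated ``region-NNN`` names take over.
    """
    atlas = default_atlas()
    if n_regions <= len(atlas):
        return list(atlas.names[:n_regions])
    extra = [f"region-{i:03d}" for i in range(len(atlas), n_regions)]
    return list(atlas.names) + extra


def generate_subject(cfg: SynthConfig, subject_seed: int,
                     plant_loop: bool = True) -> TimeCourseMatrix:
    """One synthetic subject; deterministic given (cfg.seed, subject_seed).

    With ``plant_loop=False`` every region is background — the null model
    for false-positive characterization.
    """
    rng = np.random.default_rng(np.random.SeedSequence(
        [int(cfg.seed), int(subject_seed)]))
    n, T = cfg.n_regions, cfg.n_timepoints
    t = np.arange(T)
    values = np.empty((n, T))

    members = set(cfg.members()) if plant_loop else set()
    K = cfg.loop_size
    g = rng.standard_normal(T)  # weak signal shared by background regions
    rho = cfg.background_corr
    for r in range(n):
        if r in members:
            k = sorted(members).index(r)
            phase = 2.0 * np.pi * k / K
            signal = np.cos(2.0 * np.pi * cfg.cycles_in_window * t / T + phase)
            values[r] = signal + cfg.noise_sigma * rng.standard_normal(T)
        else:
            values[r] = (np.sqrt(rho) * g
                         + np.sqrt(1.0 - rho) * rng.standard_normal(T))

    return TimeCourseMatrix(region_labels=region_labels_for(n), values=values)


def generate_cohort(
    cfg: SynthConfig,
    n_subjects: int,
    fraction_with_loop: float = 1.0,
    member_pool: Sequence[int] | None = None,
    anchor_members: Sequence[int] | None = None,
) -> tuple[list[tuple[str, TimeCourseMatrix]], list[dict]]:
    """A cohort of subjects plus a ground-truth manifest.

    The first ``round(fraction_with_loop * n_subjects)`` subjects carry a
    planted loop.  When ``member_pool`` is given, each planted subject
    draws its loop members from the pool (``anchor_members``, a subset of
    the pool, are always included; the rest are sampled without
    replacement) so that cohort-level region-frequency structure emerges.
    Without a pool every planted subject uses ``cfg`` members.

    The manifest records per subject: id, whether a loop was planted, and
    the planted member names — the ground truth for recovery scoring.
    """
    if not (0.0 <= fraction_with_loop <= 1.0):
        raise ValueError("fraction_with_loop must be in [0, 1]")
    anchors = tuple(anchor_members or ())
    if member_pool is not None:
        pool = tuple(member_pool)
        if any(a not in pool for a in anchors):
            raise ValueError("anchor_members must be a subset of member_pool")
        if len(pool) < cfg.loop_size:
            raise ValueError("member_pool smaller than loop_size")
    labels = region_labels_for(cfg.n_regions)

    n_planted = round(fraction_with_loop * n_subjects)
    subjects: list[tuple[str, TimeCourseMatrix]] = []
    manifest: list[dict] = []
    width = max(3, len(str(max(n_subjects - 1, 0))))
    for s in range(n_subjects):
        subject_id = f"sub-{s:0{width}d}"
        plant = s < n_planted
        subj_cfg = cfg
        if plant and member_pool is not None:
            rng = np.random.default_rng(np.random.SeedSequence(
                [int(cfg.seed), int(s), 1]))
            free = [p for p in pool if p not in anchors]
            picked = rng.choice(len(free), size=cfg.loop_size - len(anchors),
                                replace=False)
            members = tuple(sorted(set(anchors) | {free[i] for i in picked}))
            subj_cfg = replace(cfg, loop_members=members)
        tc = generate_subject(subj_cfg, subject_seed=s, plant_loop=plant)
        subjects.append((subject_id, tc))
        manifest.append({
            "subject_id": subject_id,
            "has_loop": plant,
            "members": [labels[m] for m in subj_cfg.members()] if plant else [],
        })
    return subjects, manifest


def write_manifest(manifest: list[dict], path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n",
                          encoding="utf-8")
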