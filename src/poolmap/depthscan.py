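"""Pool-contrast per-base read-depth analysis.

A large insertion present in one pool but absent from the mapping reference
leaves a localized collapse of mapped depth in that pool: reads spanning the
insertion breakpoints fail to map across a halo around the insertion point.
This module simulates such profiles and flags candidate insertion sites as
contiguous runs where one pool's smoothed depth falls below a ratio
threshold relative to the other pool.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DepthProfile",
    "DipCall",
    "simulate_depth_profiles",
    "detect_depth_dips",
]


@dataclass
class DepthProfile:
    """Per-base depth of two pools over one contiguous region.

    ``positions`` are 1-based; both depth arrays cover the same range.
    """

    chromosome: str
    start: int
    depths: dict[str, np.ndarray]

    def __post_init__(self):
        lens = {len(v) for v in self.depths.values()}
        if len(lens) != 1:
            raise ValueError("pool depth arrays must have equal length")
        for label, arr in self.depths.items():
            if (np.asarray(arr) < 0).any():
                raise ValueError(f"negative depth in pool {label!r}")

    @property
    def length(self) -> int:
        return len(next(iter(self.depths.values())))

    @property
    def positions(self) -> np.ndarray:
        return np.arange(self.start, self.start + self.length)


@dataclass(frozen=True)
class DipCall:
    chromosome: str
    start: int
    end: int
    ratio_inside: float
    ratio_flanking: float
    affected_pool: str

    def __post_init__(self):
        if self.end < self.start:
            raise ValueError("end < start")


def simulate_depth_profiles(
    region_length: int,
    base_depth: int = 30,
    insertion_pos: int | None = None,
    insertion_halo: int = 100,
    dip_factor: float = 1.0,
    seed: int | None = None,
    affected_pool: str = "high",
    chromosome: str = "A07",
    start: int = 1,
) -> DepthProfile:
    """Poisson per-base depth for two pools with an optional planted dip.

    Both pools draw depth Poisson(``base_depth``) at every base; within
    ``insertion_pos ± insertion_halo`` the affected pool's rate is
    multiplied by ``dip_factor`` (0 = full collapse, 1 = no signal).
    """
    if not 0 <= dip_factor <= 1:
        raise ValueError("dip_factor must lie in [0, 1]")
    if insertion_pos is not None and not (
        start <= insertion_pos < start + region_length
    ):
        raise ValueError("insertion_pos outside the simulated region")
    rng = np.random.default_rng(seed)
    rate = {p: np.full(region_length, float(base_depth)) for p in ("high", "low")}
    if insertion_pos is not None:
        lo = max(insertion_pos - insertion_halo, start) - start
        hi = min(insertion_pos + insertion_halo, start + region_length - 1) - start
        rate[affected_pool][lo : hi + 1] *= dip_factor
    depths = {p: rng.poisson(rate[p]) for p in ("high", "low")}
    return DepthProfile(chromosome, start, depths)


def _smooth(arr: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with shrinking edges (cumulative-sum based)."""
    n = len(arr)
    half = window // 2
    cum = np.concatenate([[0.0], np.cumsum(arr, dtype=float)])
    i = np.arange(n)
    lo = np.maximum(i - half, 0)
    hi = np.minimum(i + half, n - 1)
    return (cum[hi + 1] - cum[lo]) / (hi - lo + 1)


def detect_depth_dips(
    profile: DepthProfile,
    smooth_window: int = 50,
    ratio_threshold: float = 0.5,
    min_length: int = 50,
    pseudocount: float = 1.0,
    median_normalize: bool = False,
) -> list[DipCall]:
    """Flag candidate insertion halos as one-sided depth collapses.

    For each pool taken as the affected pool, the smoothed depth ratio
    ``r = (d_affected + pseudocount) / (d_other + pseudocount)`` is scanned
    for maximal runs with ``r < ratio_threshold`` of length at least
    ``min_length``.  ``median_normalize`` rescales each pool by its region
    median first, compensating unequal total sequencing yield.
    """
    if smooth_window < 1:
        raise ValueError("smooth_window must be >= 1")
    labels = sorted(profile.depths)
    arrays = {}
    for label in labels:
        arr = np.asarray(profile.depths[label], dtype=float)
        if median_normalize:
            med = np.median(arr)
            if med > 0:
                arr = arr / med * np.mean(
                    [np.median(np.asarray(v, dtype=float)) for v in profile.depths.values()]
                )
        if not arr.any():
            warnings.warn(f"pool {label!r} has zero depth everywhere")
        arrays[label] = _smooth(arr, smooth_window)

    calls: list[DipCall] = []
    for affected in labels:
        other = [l for l in labels if l != affected][0]
        r = (arrays[affected] + pseudocount) / (arrays[other] + pseudocount)
        below = r < ratio_threshold
        if not below.any():
            continue
        edges = np.diff(below.astype(int))
        starts = list(np.flatnonzero(edges == 1) + 1)
        ends = list(np.flatnonzero(edges == -1))
        if below[0]:
            starts.insert(0, 0)
        if below[-1]:
            ends.append(len(below) - 1)
        for s, e in zip(starts, ends):
            if e - s + 1 < min_length:
                continue
            flank_idx = np.concatenate(
                [np.arange(max(s - smooth_window, 0), s), np.arange(e + 1, min(e + 1 + smooth_window, len(r)))]
            )
            calls.append(
                DipCall(
                    chromosome=profile.chromosome,
                    start=int(profile.start + s),
                    end=int(profile.start + e),
                    ratio_inside=float(r[s : e + 1].mean()),
                    ratio_flanking=float(r[flank_idx].mean()) if len(flank_idx) else float("nan"),
                    affected_pool=affected,
                )
            )
    calls.sort(key=lambda c: (c.chromosome, c.start, c.affected_pool))
    return calls
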