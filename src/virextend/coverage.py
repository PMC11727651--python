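"""Depth-of-coverage audit: segment a contig into suspicious and
non-suspicious regions by the percentile uniformity rule.

A base is *normal* when its depth lies within the inclusive
[lower_pct, upper_pct] nearest-rank percentile bounds of the contig's depth
distribution **and** is covered by at least one read. Zero-depth bases are
always suspicious: a position with no read support cannot be validated by
the data, however large the fraction of such positions. Maximal runs of
suspicious bases strictly longer than ``min_suspicious_len`` are the true
suspicious regions; everything else is non-suspicious.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import Contig, Region


@dataclass(frozen=True)
class AuditParams:
    lower_pct: float = 15.0
    upper_pct: float = 85.0
    min_suspicious_len: int = 1000

    def __post_init__(self) -> None:
        if not (0 <= self.lower_pct < self.upper_pct <= 100):
            raise ValueError("need 0 <= lower_pct < upper_pct <= 100")
        if self.min_suspicious_len < 1:
            raise ValueError("min_suspicious_len must be >= 1")


@dataclass
class CoverageProfile:
    contig_id: str
    depth: np.ndarray  # int per-base depth
    lower_bound: float
    upper_bound: float

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ValueError("lower_bound > upper_bound")


def nearest_rank(values: np.ndarray, pct: float) -> float:
    """Nearest-rank percentile: the ceil(pct/100 * n)-th smallest value."""
    n = len(values)
    if n == 0:
        raise ValueError("empty value vector")
    rank = max(1, math.ceil(pct / 100.0 * n))
    return float(np.partition(values, rank - 1)[rank - 1])


def compute_depth(
    contig: Contig,
    placements: Sequence[tuple[int, int]],
    params: AuditParams | None = None,
) -> CoverageProfile:
    """Per-base depth from (start, end) placement intervals.

    depth[i] = number of intervals covering position i. Percentile bounds
    are taken from the resulting depth vector with ``params``.
    """
    params = params or AuditParams()
    n = len(contig)
    delta = np.zeros(n + 1, dtype=np.int64)
    for start, end in placements:
        if not (0 <= start <= end <= n):
            raise ValueError(f"placement [{start}, {end}) outside contig of length {n}")
        delta[start] += 1
        delta[end] -= 1
    depth = np.cumsum(delta[:-1])
    return CoverageProfile(
        contig.id,
        depth,
        lower_bound=nearest_rank(depth, params.lower_pct),
        upper_bound=nearest_rank(depth, params.upper_pct),
    )


def suspicious_mask(profile: CoverageProfile) -> np.ndarray:
    """Boolean per-base mask of suspicious positions (before run-length filter)."""
    d = profile.depth
    return (d < profile.lower_bound) | (d > profile.upper_bound) | (d == 0)


def flag_suspicious(
    profile: CoverageProfile, params: AuditParams | None = None
) -> list[Region]:
    """Maximal suspicious runs strictly longer than ``min_suspicious_len``."""
    params = params or AuditParams()
    mask = suspicious_mask(profile)
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(padded[1:] != padded[:-1])
    starts, ends = edges[::2], edges[1::2]
    return [
        Region(profile.contig_id, int(s), int(e), "suspicious")
        for s, e in zip(starts, ends)
        if e - s > params.min_suspicious_len
    ]


class WholeContigSuspiciousError(ValueError):
    """The entire contig is flagged suspicious; nothing left to extend."""


def longest_non_suspicious(
    profile: CoverageProfile, suspicious: Sequence[Region]
) -> Region:
    """Longest gap between/around suspicious regions; ties -> leftmost."""
    n = len(profile.depth)
    best = None
    prev = 0
    bounds = sorted((r.start, r.end) for r in suspicious)
    for s, e in bounds + [(n, n)]:
        if s > prev and (best is None or s - prev > len(best)):
            best = Region(profile.contig_id, prev, s, "non_suspicious")
        prev = max(prev, e)
    if best is None:
        raise WholeContigSuspiciousError(
            f"{profile.contig_id}: whole contig flagged suspicious"
        )
    return best


def depth_table(profile: CoverageProfile) -> str:
    """Depth vector as TSV text (pos, depth), 0-based positions."""
    lines = ["pos\tdepth"]
    lines += [f"{i}\t{int(d)}" for i, d in enumerate(profile.depth)]
    return "\n".join(lines) + "\n"
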