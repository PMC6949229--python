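"""Effective whole-genome coverage (EWC) masks.

The EWC region is the set of autosomal positions where *every* sample in the
study has reliable sequence: high-mapping-quality depth between 50% and 300%
of that sample's coverage peak, and at least 80% of reads at the position
carrying high mapping quality.  Its total size is the denominator of every
mutation rate, so the mask must be computed identically for all samples and
then intersected.

Coordinates are 0-based half-open (BED convention) throughout this module.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EwcParams",
    "EwcMask",
    "peak_coverage",
    "depth_histogram",
    "sample_mask",
    "intersect_masks",
    "bool_to_intervals",
]


@dataclass(frozen=True)
class EwcParams:
    """Thresholds defining per-sample callable positions.

    lower_frac, upper_frac
        Bounds on high-MQ depth as fractions of the sample's peak coverage
        (defaults 0.5 and 3.0, i.e. 50%-300% of the peak).
    min_mq_ratio
        Minimum fraction of reads at a position with high mapping quality
        (default 0.8).
    """

    lower_frac: float = 0.5
    upper_frac: float = 3.0
    min_mq_ratio: float = 0.8

    def __post_init__(self) -> None:
        if not (0 < self.lower_frac < self.upper_frac):
            raise ValueError("require 0 < lower_frac < upper_frac")
        if not (0 < self.min_mq_ratio <= 1):
            raise ValueError("require 0 < min_mq_ratio <= 1")


def _check_intervals(iv: np.ndarray) -> np.ndarray:
    iv = np.asarray(iv, dtype=np.int64).reshape(-1, 2)
    if iv.size:
        if np.any(iv[:, 0] >= iv[:, 1]):
            raise ValueError("empty or inverted interval")
        if np.any(iv[1:, 0] < iv[:-1, 1]):
            raise ValueError("intervals must be sorted and disjoint")
    return iv


@dataclass(frozen=True)
class EwcMask:
    """Per-chromosome sorted, disjoint, half-open intervals of callable sequence."""

    intervals: dict[str, np.ndarray]
    sample_set: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "intervals",
            {c: _check_intervals(iv) for c, iv in self.intervals.items()},
        )

    @property
    def total_bp(self) -> int:
        return int(
            sum((iv[:, 1] - iv[:, 0]).sum() for iv in self.intervals.values() if iv.size)
        )

    def contains(self, chrom: str, pos: int) -> bool:
        """Membership of a single 0-based position."""
        iv = self.intervals.get(chrom)
        if iv is None or not iv.size:
            return False
        i = np.searchsorted(iv[:, 0], pos, side="right") - 1
        return i >= 0 and pos < iv[i, 1]

    def contains_vcf_pos(self, chrom: str, pos_1based: int) -> bool:
        """Membership of a 1-based (VCF) position."""
        return self.contains(chrom, pos_1based - 1)

    def to_bool(self, chrom: str, length: int) -> np.ndarray:
        """Expand one chromosome to a boolean per-position vector."""
        out = np.zeros(length, dtype=bool)
        for s, e in self.intervals.get(chrom, np.empty((0, 2), dtype=np.int64)):
            out[s:e] = True
        return out

    @classmethod
    def from_bool(
        cls, flags: Mapping[str, np.ndarray], sample_set: Iterable[str] = ()
    ) -> "EwcMask":
        return cls(
            intervals={c: bool_to_intervals(b) for c, b in flags.items()},
            sample_set=frozenset(sample_set),
        )


def bool_to_intervals(flags: np.ndarray) -> np.ndarray:
    """Merge adjacent True positions into half-open intervals."""
    flags = np.asarray(flags, dtype=bool)
    if not flags.size:
        return np.empty((0, 2), dtype=np.int64)
    edges = np.flatnonzero(np.diff(np.concatenate(([False], flags, [False])).astype(np.int8)))
    return edges.reshape(-1, 2).astype(np.int64)


def depth_histogram(track: Mapping[str, np.ndarray]) -> np.ndarray:
    """Pool a per-chromosome depth track into an integer depth histogram."""
    hists = [np.bincount(np.asarray(d, dtype=np.int64)) for d in track.values()]
    n = max((h.size for h in hists), default=0)
    out = np.zeros(n, dtype=np.int64)
    for h in hists:
        out[: h.size] += h
    return out


def peak_coverage(histogram) -> int:
    """Modal depth of a depth histogram over depths >= 1.

    The peak defines the reference point for the 50%/300% coverage bounds.
    Depth 0 is excluded (uncovered sites carry no signal about the coverage
    distribution); ties are broken toward the lower depth so the result is
    deterministic.
    """
    if isinstance(histogram, Mapping):
        n = max(histogram, default=-1) + 1
        counts = np.zeros(max(n, 0), dtype=np.int64)
        for depth, c in histogram.items():
            if depth < 0:
                raise ValueError("negative depth in histogram")
            counts[depth] = c
    else:
        counts = np.asarray(histogram, dtype=np.int64)
    if counts.size <= 1 or counts[1:].sum() <= 0:
        raise ValueError("no covered positions")
    counts = counts.copy()
    counts[0] = 0
    return int(np.argmax(counts))  # argmax returns the first (lowest) mode


def sample_mask(
    hq_track: Mapping[str, np.ndarray],
    total_track: Mapping[str, np.ndarray],
    params: EwcParams = EwcParams(),
    sample: str | None = None,
) -> EwcMask:
    """Callable mask for one sample from its high-MQ and total depth tracks.

    A position qualifies iff
    ``lower_frac*peak <= hq <= upper_frac*peak`` and ``hq/total >= min_mq_ratio``;
    positions with zero total depth are excluded before the ratio test.
    """
    if set(hq_track) != set(total_track):
        raise ValueError("tracks cover different chromosomes")
    peak = peak_coverage(depth_histogram(hq_track))
    lo = params.lower_frac * peak
    hi = params.upper_frac * peak
    flags: dict[str, np.ndarray] = {}
    for chrom, hq in hq_track.items():
        hq = np.asarray(hq, dtype=np.int64)
        total = np.asarray(total_track[chrom], dtype=np.int64)
        if hq.shape != total.shape:
            raise ValueError(f"track length mismatch on {chrom}")
        ok = (hq >= lo) & (hq <= hi) & (total > 0)
        # hq/total >= r without division (total > 0 already enforced)
        ok &= hq >= params.min_mq_ratio * total
        flags[chrom] = ok
    return EwcMask.from_bool(flags, sample_set=() if sample is None else (sample,))


def _intersect_pair(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Intersection of two sorted disjoint interval lists (two-pointer sweep)."""
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i, 0], b[j, 0])
        e = min(a[i, 1], b[j, 1])
        if s < e:
            out.append((s, e))
        if a[i, 1] <= b[j, 1]:
            i += 1
        else:
            j += 1
    return np.array(out, dtype=np.int64).reshape(-1, 2)


def intersect_masks(masks: Sequence[EwcMask]) -> EwcMask:
    """Positions callable in every input mask (the shared EWC region)."""
    if not masks:
        raise ValueError("need at least one mask")
    chroms = set(masks[0].intervals)
    for m in masks[1:]:
        chroms &= set(m.intervals)
    intervals: dict[str, np.ndarray] = {}
    for c in sorted(chroms):
        iv = masks[0].intervals[c]
        for m in masks[1:]:
            iv = _intersect_pair(iv, m.intervals[c])
            if not iv.size:
                break
        intervals[c] = iv
    samples: set[str] = set()
    for m in masks:
        samples |= m.sample_set
    return EwcMask(intervals=intervals, sample_set=frozenset(samples))
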