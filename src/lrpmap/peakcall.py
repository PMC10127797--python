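"""Peak calling on knockout-subtracted occupancy and cross-condition consensus.

A peak is a maximal run of bins at or above a robust-z threshold on the
scar-subtracted track, with short sub-threshold gaps bridged and very narrow
runs discarded. Consensus sites are the merged union of peaks over all
samples/conditions — a site counts once however many conditions hit it — and
carry the per-sample mean occupancy over the merged interval, forming the
rows of the sites x samples matrix used for clustering and correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .tracks import OccupancyTrack, SampleMeta

#: default calling threshold, in robust-z units of scar-subtracted occupancy
DEFAULT_THRESHOLD = 4.0
#: defaults in bins: minimum peak width and largest bridged gap
DEFAULT_MIN_WIDTH_BINS = 2
DEFAULT_MERGE_GAP_BINS = 4


@dataclass(frozen=True)
class PeakCall:
    """One called peak: 0-based half-open interval in bases on a replicon."""

    replicon: str
    start: int
    end: int
    summit: int          # bin index of the maximum
    score: float         # maximum scar-subtracted occupancy within the peak
    meta: SampleMeta | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("peak end must exceed start")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclass
class ConsensusSite:
    """Merged interval significant in at least one sample, with the mean
    occupancy of every sample over the merged footprint."""

    replicon: str
    start: int
    end: int
    occupancy: dict[str, float] = field(default_factory=dict)
    membership: dict[str, bool] = field(default_factory=dict)

    @property
    def site_id(self) -> str:
        return f"{self.replicon}:{self.start}-{self.end}"


def call_peaks(
    track: OccupancyTrack,
    threshold: float = DEFAULT_THRESHOLD,
    min_width: int | None = None,
    merge_gap: int | None = None,
) -> list[PeakCall]:
    """Call peaks on a scar-subtracted track.

    Parameters are in bases; ``min_width`` defaults to 2 bins and
    ``merge_gap`` to 4 bins of the track's resolution. A non-positive
    threshold is permitted but almost certainly not what you want, so it is
    flagged with a warning. The run search is linear along the binned track;
    the synthetic generator keeps planted sites away from the origin of the
    circular replicon.
    """
    if track.stage != "scar_subtracted":
        raise ValueError("call_peaks expects a scar_subtracted track")
    if threshold <= 0:
        import warnings

        warnings.warn(
            f"peak-calling threshold {threshold} is <= 0; every bin at background "
            "level will satisfy it",
            stacklevel=2,
        )
    bs = track.bin_size
    min_width_bins = DEFAULT_MIN_WIDTH_BINS if min_width is None else max(1, int(np.ceil(min_width / bs)))
    merge_gap_bins = DEFAULT_MERGE_GAP_BINS if merge_gap is None else int(merge_gap // bs)

    above = track.values >= threshold
    if not above.any():
        return []
    # run-length extraction on the boolean mask
    padded = np.concatenate([[False], above, [False]])
    step = np.diff(padded.astype(np.int8))
    run_starts = np.flatnonzero(step == 1)
    run_ends = np.flatnonzero(step == -1)

    # bridge sub-threshold gaps of at most merge_gap_bins
    merged: list[list[int]] = []
    for s, e in zip(run_starts, run_ends):
        if merged and s - merged[-1][1] <= merge_gap_bins:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    peaks: list[PeakCall] = []
    for s, e in merged:
        if e - s < min_width_bins:
            continue
        summit = s + int(np.argmax(track.values[s:e]))
        score = float(track.values[summit])
        peaks.append(
            PeakCall(track.replicon, s * bs, e * bs, summit, score, track.meta)
        )
    return peaks


def _merge_intervals(intervals: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or touching (gap 0) intervals."""
    if not intervals:
        return []
    ordered = sorted(intervals)
    out = [list(ordered[0])]
    for s, e in ordered[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(x) for x in out]


def consensus_union(
    peak_sets: Mapping[str, Sequence[PeakCall]],
    tracks: Mapping[str, OccupancyTrack] | None = None,
) -> tuple[list[ConsensusSite], pd.DataFrame]:
    """Union of peak intervals across samples, merged at gap 0.

    ``peak_sets`` maps a sample label to its peak list. If ``tracks`` gives a
    scar-subtracted track per label, the matrix entry is the mean occupancy
    of that sample over the merged interval; otherwise entries are the mean
    only over samples whose peaks contributed (NaN elsewhere).

    Returns the consensus sites (pairwise disjoint, coordinate-sorted) and
    the sites x samples occupancy matrix.
    """
    replicons = {p.replicon for peaks in peak_sets.values() for p in peaks}
    if len(replicons) > 1:
        raise ValueError(f"peaks span multiple replicons: {sorted(replicons)}")
    replicon = replicons.pop() if replicons else "NA"

    intervals = [(p.start, p.end) for peaks in peak_sets.values() for p in peaks]
    merged = _merge_intervals(intervals)
    sites: list[ConsensusSite] = []
    for s, e in merged:
        site = ConsensusSite(replicon, s, e)
        for label, peaks in peak_sets.items():
            hits = [p for p in peaks if p.start < e and p.end > s]
            site.membership[label] = bool(hits)
            if tracks is not None and label in tracks:
                t = tracks[label]
                b0, b1 = s // t.bin_size, max(s // t.bin_size + 1, -(-e // t.bin_size))
                site.occupancy[label] = float(np.mean(t.values[b0:b1]))
            elif hits:
                site.occupancy[label] = float(np.mean([p.score for p in hits]))
            else:
                site.occupancy[label] = float("nan")
        sites.append(site)

    matrix = pd.DataFrame(
        {label: [s.occupancy[label] for s in sites] for label in peak_sets},
        index=[s.site_id for s in sites],
    )
    return sites, matrix


def _reciprocal_overlap(a: PeakCall, b: PeakCall) -> float:
    ov = min(a.end, b.end) - max(a.start, b.start)
    if ov <= 0:
        return 0.0
    return min(ov / a.width, ov / b.width)


def novel_peaks(
    set_a: Sequence[PeakCall],
    set_b: Sequence[PeakCall],
    min_overlap: float = 0.25,
) -> list[PeakCall]:
    """Peaks of ``set_a`` with less than ``min_overlap`` reciprocal overlap
    with every peak of ``set_b`` — e.g. mutant binding sites absent from the
    wild-type peak set."""
    if not 0 < min_overlap <= 1:
        raise ValueError("min_overlap must be in (0, 1]")
    out = []
    for a in set_a:
        if all(_reciprocal_overlap(a, b) < min_overlap for b in set_b):
            out.append(a)
    return out


def poisson_rate_test(n1: int, n2: int) -> float:
    """Two-sided exact test that two Poisson counts share one rate.

    Conditional on the total, ``n1`` is Binomial(n1 + n2, 1/2) under equal
    rates and equal exposure; this is the classical exact Poisson rate
    comparison (as in R's ``poisson.test`` with two counts).
    """
    if n1 < 0 or n2 < 0:
        raise ValueError("counts must be non-negative")
    if n1 + n2 == 0:
        return 1.0
    return float(stats.binomtest(n1, n1 + n2, 0.5, alternative="two-sided").pvalue)


def proportion_test(x1: int, n1: int, x2: int, n2: int) -> float:
    """Two-sample test for equality of proportions.

    Chi-square on the 2x2 table with Yates continuity correction, matching
    R's ``prop.test``. Returns p = 1 for exactly equal proportions.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group sizes must be positive")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("successes must lie within group sizes")
    if x1 * n2 == x2 * n1:
        return 1.0
    table = np.array([[x1, n1 - x1], [x2, n2 - x2]], dtype=float)
    if np.any(table.sum(axis=0) == 0):
        return 1.0
    res = stats.chi2_contingency(table, correction=True)
    return float(res.pvalue)
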