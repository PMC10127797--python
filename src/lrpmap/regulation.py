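"""Binding-to-transcription analysis.

Connects regulator peaks to transcription: which promoters (TSSs) are bound,
whether that binding is enriched over chance, how RNA-polymerase occupancy
over each transcription-unit (TU) body shifts relative to the knockout, which
TUs are direct targets, how the effector (leucine) modulates each effect, and
the six-mode classification of regulation:

    {independent, concerted, reciprocal} x {activating, repressing}

with *reciprocal* meaning the effector weakens/removes the regulator's
effect, *concerted* meaning it strengthens it, and *independent* meaning the
effect persists unchanged while the regulator stays bound in both media.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage

from .peakcall import PeakCall
from .tracks import OccupancyTrack

MODES = (
    "independent_activating",
    "independent_repressing",
    "concerted_activating",
    "concerted_repressing",
    "reciprocal_activating",
    "reciprocal_repressing",
    "unclassified",
)


@dataclass(frozen=True)
class TSSAnnotation:
    """Annotated transcription start site, 0-based position on the replicon."""

    position: int
    strand: str
    tu_id: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True)
class TranscriptionUnit:
    tu_id: str
    start: int
    end: int
    strand: str
    genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("TU end must exceed start")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def tss_position(self) -> int:
        """Strand-appropriate 5' end (0-based)."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class RNAPChange:
    """Per-TU RNA-polymerase occupancy change vs the knockout, log2 units."""

    tu_id: str
    condition: tuple[str, str]
    log2fc: float
    se: float
    q: float = float("nan")


@dataclass
class RegulationCall:
    tu_id: str
    bound_min: bool
    bound_liv: bool
    mode: str

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")


# ---------------------------------------------------------------------------
# TSS overlap and enrichment

def overlap_tss(
    peaks: Sequence[PeakCall],
    tss_set: Sequence[TSSAnnotation],
) -> tuple[dict[int, list[TSSAnnotation]], float]:
    """Map each peak to the TSSs inside it (half-open: position in [start, end)).

    Returns ``(mapping, fraction)`` where ``mapping[i]`` lists the TSSs
    overlapped by ``peaks[i]`` and ``fraction`` is the share of peaks with at
    least one TSS.
    """
    mapping: dict[int, list[TSSAnnotation]] = {}
    for i, p in enumerate(peaks):
        hits = [t for t in tss_set if p.start <= t.position < p.end]
        if hits:
            mapping[i] = hits
    fraction = len(mapping) / len(peaks) if peaks else 0.0
    return mapping, fraction


def tss_enrichment(
    peaks: Sequence[PeakCall],
    tss_set: Sequence[TSSAnnotation],
    replicon_length: int,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, np.ndarray, float]:
    """Permutation test for promoter enrichment of peaks.

    Null: each peak is re-placed uniformly at random on the circular
    replicon, preserving its width; the TSS-overlap fraction is recomputed
    per permutation. p = (1 + #{null >= observed}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not peaks:
        raise ValueError("no peaks given")
    _, observed = overlap_tss(peaks, tss_set)
    if not tss_set:
        return 0.0, np.zeros(n_perm), 1.0

    tss_pos = np.sort(np.array([t.position for t in tss_set]))
    widths = np.array([p.width for p in peaks])
    rng = np.random.default_rng(seed)
    L = replicon_length
    # starts: (n_perm, n_peaks); count TSSs in [s, s+w) with circular wrap
    starts = rng.integers(0, L, size=(n_perm, len(peaks)))
    ends = starts + widths[None, :]
    n_in = np.searchsorted(tss_pos, np.minimum(ends, L)) - np.searchsorted(tss_pos, starts)
    wrap = np.maximum(ends - L, 0)
    n_in = n_in + np.searchsorted(tss_pos, wrap)
    null = (n_in > 0).mean(axis=1)
    p = (1 + int(np.sum(null >= observed - 1e-12))) / (1 + n_perm)
    return observed, null, float(p)


# ---------------------------------------------------------------------------
# RNAP occupancy changes at TU bodies

def _tu_bins(tu: TranscriptionUnit, bin_size: int, n_bins: int) -> slice:
    b0 = tu.start // bin_size
    b1 = max(b0 + 1, -(-tu.end // bin_size))
    return slice(b0, min(b1, n_bins))


def tu_replicate_matrix(
    tracks: Sequence[OccupancyTrack],
    tus: Sequence[TranscriptionUnit],
) -> np.ndarray:
    """Per-replicate mean occupancy statistic over each TU body.

    Rows are replicate tracks (log-ratio stage or later), columns TUs.
    """
    out = np.empty((len(tracks), len(tus)))
    for i, t in enumerate(tracks):
        for j, tu in enumerate(tus):
            out[i, j] = float(np.mean(t.values[_tu_bins(tu, t.bin_size, t.n_bins)]))
    return out


def tu_log2fc(
    genotype_tracks: Sequence[OccupancyTrack],
    scar_tracks: Sequence[OccupancyTrack],
    tu: TranscriptionUnit,
) -> RNAPChange:
    """Log2 fold change in knockout-subtracted RNAP occupancy over a TU body.

    Both inputs are per-replicate log2(chip/input) tracks. The statistic is
    mean(genotype TU means) - mean(scar TU means); the standard error
    combines the replicate scatter of both groups.
    """
    if not genotype_tracks or not scar_tracks:
        raise ValueError("need at least one replicate per group")
    g = tu_replicate_matrix(genotype_tracks, [tu])[:, 0]
    s = tu_replicate_matrix(scar_tracks, [tu])[:, 0]
    log2fc = float(g.mean() - s.mean())
    var = 0.0
    if g.size > 1:
        var += g.var(ddof=1) / g.size
    if s.size > 1:
        var += s.var(ddof=1) / s.size
    cond = genotype_tracks[0].meta.condition
    return RNAPChange(tu.tu_id, cond, log2fc, float(np.sqrt(var)))


def diff_significance(
    genotype_stats: np.ndarray,
    scar_stats: np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Permutation p and Benjamini-Hochberg q per TU for a genotype-vs-scar
    difference of mean TU statistics.

    ``genotype_stats`` and ``scar_stats`` are replicate x TU matrices. Group
    labels are reshuffled ``n_perm`` times; the two-sided p-value counts
    permuted mean differences at least as extreme as the observed one, with
    the +1 correction that keeps the test valid at any n_perm.
    """
    g = np.atleast_2d(np.asarray(genotype_stats, dtype=float))
    s = np.atleast_2d(np.asarray(scar_stats, dtype=float))
    if g.shape[1] != s.shape[1]:
        raise ValueError("replicate matrices must agree on the number of TUs")
    n_g = g.shape[0]
    pooled = np.vstack([g, s])
    n = pooled.shape[0]
    obs = np.abs(g.mean(axis=0) - s.mean(axis=0))
    rng = np.random.default_rng(seed)
    exceed = np.zeros(pooled.shape[1])
    for _ in range(n_perm):
        idx = rng.permutation(n)
        diff = pooled[idx[:n_g]].mean(axis=0) - pooled[idx[n_g:]].mean(axis=0)
        exceed += np.abs(diff) >= obs - 1e-12
    p = (1 + exceed) / (1 + n_perm)
    q = stats.false_discovery_control(p, method="bh")
    return p, q


def call_direct_targets(
    bound_tus: Iterable[str],
    changes: Sequence[RNAPChange],
    q_cut: float = 0.05,
) -> set[str]:
    """TUs that are bound at the TSS *and* show a significant regulator-
    dependent RNAP change (q <= q_cut) under at least one condition."""
    bound = set(bound_tus)
    significant = {c.tu_id for c in changes if c.q <= q_cut}
    return bound & significant


def leucine_modulation_score(change_min: float, change_liv: float) -> float:
    """Effector-modulation score: (LIV effect - Min effect) x sign(Min effect).

    Positive: the effector strengthens the regulator's effect; negative: it
    weakens it. Zero when the effect is unchanged (or absent in Min).
    """
    return (change_liv - change_min) * float(np.sign(change_min))


def classify_mode(
    tu_id: str,
    bound_min: bool,
    bound_liv: bool,
    fc_min: float,
    se_min: float,
    sig_min: bool,
    fc_liv: float,
    se_liv: float,
    sig_liv: bool,
    z: float = 1.96,
) -> RegulationCall:
    """Assign one of the six regulation modes (or unclassified).

    A TU qualifies only if it is a direct target: bound under at least one
    condition with a significant effect under at least one condition. The
    activation/repression axis comes from the sign of the Min effect (LIV if
    Min is not significant). The effector axis compares effect magnitudes
    between media using +/- z*se intervals on |log2FC|:

    - effect absent or binding lost in LIV        -> reciprocal
    - effect only appears in LIV                  -> concerted
    - |LIV| interval entirely below |Min| interval -> reciprocal
    - |LIV| interval entirely above |Min| interval -> concerted
    - overlapping intervals, bound in both        -> independent
    """
    direct = (bound_min or bound_liv) and (sig_min or sig_liv)
    if not direct:
        return RegulationCall(tu_id, bound_min, bound_liv, "unclassified")

    base_fc = fc_min if sig_min else fc_liv
    direction = "activating" if base_fc > 0 else "repressing"

    if not (sig_liv and bound_liv):
        axis = "reciprocal"
    elif not sig_min:
        axis = "concerted"
    else:
        a_lo, a_hi = abs(fc_min) - z * se_min, abs(fc_min) + z * se_min
        b_lo, b_hi = abs(fc_liv) - z * se_liv, abs(fc_liv) + z * se_liv
        if b_hi < a_lo:
            axis = "reciprocal"
        elif b_lo > a_hi:
            axis = "concerted"
        else:
            axis = "independent"
    return RegulationCall(tu_id, bound_min, bound_liv, f"{axis}_{direction}")


# ---------------------------------------------------------------------------
# Pileups and clustering

def tss_pileup(
    track: OccupancyTrack,
    tss_set: Sequence[TSSAnnotation],
    half_width: int = 1000,
) -> np.ndarray:
    """TSS-centred occupancy matrix, one row per TSS.

    Columns span ``[-half_width, +half_width]`` at bin resolution; rows for
    minus-strand TSSs are reversed so transcription always proceeds toward
    increasing column index. Windows wrap around the circular replicon.
    """
    k = half_width // track.bin_size
    rows = []
    for t in tss_set:
        c = t.position // track.bin_size
        idx = np.arange(c - k, c + k + 1)
        row = track.values.take(idx, mode="wrap")
        if t.strand == "-":
            row = row[::-1]
        rows.append(row)
    return np.array(rows) if rows else np.empty((0, 2 * k + 1))


def cluster_order(
    matrix: np.ndarray | pd.DataFrame,
    axis: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Agglomerative clustering of matrix rows (axis=0) or columns (axis=1),
    Euclidean metric, average linkage. Returns (leaf order, linkage tree)."""
    x = np.asarray(matrix, dtype=float)
    if axis == 1:
        x = x.T
    if x.shape[0] < 2:
        return np.arange(x.shape[0]), np.empty((0, 4))
    Z = linkage(x, method="average", metric="euclidean")
    return np.asarray(leaves_list(Z)), Z
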