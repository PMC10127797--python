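"""Occupancy-track primitives.

The central statistic of the pipeline is the knockout-subtracted robust
z-scored log-ratio ("rz-log ratio") of ChIP coverage over matched input:

    lr  = log2((chip + c) / (input + c))          per bin, pseudocount c
    rz  = (lr - median(lr)) / (1.4826 * MAD(lr))
    occ = rz_sample - rz_knockout                 matched medium and phase

where the knockout is the regulator-deletion ("scar") strain grown under the
same condition, so that any apparent enrichment shared with a strain carrying
no regulator is removed before peaks are called.

Tracks move through the stages raw -> log_ratio -> rz -> scar_subtracted and
the stage transitions are enforced: each operation accepts only the stage it
is defined on.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

GENOTYPES = ("WT", "D114E", "L136R", "dC11", "scar")
MEDIA = ("Min", "LIV")
PHASES = ("Log", "Stat")
ASSAYS = ("Lrp", "RNAP")
STAGES = ("raw", "log_ratio", "rz", "scar_subtracted")

#: normal-consistency constant: 1/Phi^-1(3/4), the standard robust-z scaling
MAD_SCALE = 1.4826


@dataclass(frozen=True)
class SampleMeta:
    """Sample axes: genotype x medium x growth phase x lineage x biorep x assay.

    A *lineage* is an independently constructed strain carrying the same
    intended genotype; a *biorep* is an independent culture of one lineage.
    """

    genotype: str
    medium: str
    phase: str
    lineage: int = 1
    biorep: int = 1
    assay: str = "Lrp"

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}; expected one of {GENOTYPES}")
        if self.medium not in MEDIA:
            raise ValueError(f"unknown medium {self.medium!r}; expected one of {MEDIA}")
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}; expected one of {PHASES}")
        if self.assay not in ASSAYS:
            raise ValueError(f"unknown assay {self.assay!r}; expected one of {ASSAYS}")

    @property
    def condition(self) -> tuple[str, str]:
        """(medium, phase) — the axes a scar control must match."""
        return (self.medium, self.phase)

    def label(self) -> str:
        return f"{self.genotype}_{self.medium}_{self.phase}_L{self.lineage}_R{self.biorep}_{self.assay}"


@dataclass
class OccupancyTrack:
    """Binned, genome-indexed signal for one sample and assay.

    ``values[i]`` covers bases ``[i * bin_size, (i+1) * bin_size)`` of a
    single (circular) replicon, 0-based half-open.
    """

    replicon: str
    bin_size: int
    values: np.ndarray
    meta: SampleMeta
    stage: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("track values must be one-dimensional")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")

    @property
    def n_bins(self) -> int:
        return self.values.size

    @property
    def length(self) -> int:
        """Replicon length in bases spanned by the binned values."""
        return self.n_bins * self.bin_size

    def with_values(self, values: np.ndarray, stage: str) -> "OccupancyTrack":
        new = STAGES.index(stage)
        old = STAGES.index(self.stage)
        if new < old:
            raise ValueError(f"stage may only advance ({self.stage} -> {stage} is backwards)")
        return OccupancyTrack(self.replicon, self.bin_size, values, self.meta, stage)


def _check_compatible(a: OccupancyTrack, b: OccupancyTrack) -> None:
    if a.replicon != b.replicon:
        raise ValueError(f"replicon mismatch: {a.replicon!r} vs {b.replicon!r}")
    if a.bin_size != b.bin_size:
        raise ValueError(f"bin_size mismatch: {a.bin_size} vs {b.bin_size}")
    if a.n_bins != b.n_bins:
        raise ValueError(f"track length mismatch: {a.n_bins} vs {b.n_bins} bins")


def log_ratio(
    chip: OccupancyTrack,
    input_: OccupancyTrack,
    pseudocount: float = 1.0,
    depth_normalize: bool = True,
) -> OccupancyTrack:
    """Per-bin log2 ratio of ChIP over input.

    With ``depth_normalize`` (default) the input track is rescaled to the
    total signal of the ChIP track before the ratio, so that an overall
    sequencing-depth difference between the libraries does not shift the
    whole log-ratio track. The pseudocount stabilises empty bins.
    """
    _check_compatible(chip, input_)
    if chip.stage != "raw" or input_.stage != "raw":
        raise ValueError("log_ratio expects raw coverage tracks")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    c = chip.values
    i = input_.values
    if np.any(c < 0) or np.any(i < 0):
        raise ValueError("coverage tracks must be non-negative")
    if depth_normalize and i.sum() > 0 and c.sum() > 0:
        i = i * (c.sum() / i.sum())
    values = np.log2((c + pseudocount) / (i + pseudocount))
    return chip.with_values(values, "log_ratio")


def robust_z(track: OccupancyTrack) -> OccupancyTrack:
    """Robust z-score: median-centred, scaled by 1.4826 x MAD."""
    if track.stage != "log_ratio":
        raise ValueError("robust_z expects a log_ratio track")
    x = track.values
    med = np.median(x)
    mad = stats.median_abs_deviation(x)
    if mad == 0:
        raise ValueError(
            "robust z-score undefined: MAD of the track is 0 "
            "(more than half of the bins carry an identical value)"
        )
    values = (x - med) / (MAD_SCALE * mad)
    return track.with_values(values, "rz")


def subtract_scar(
    sample_rz: OccupancyTrack,
    scar_rz: OccupancyTrack,
    force: bool = False,
) -> OccupancyTrack:
    """Knockout subtraction: sample rz minus the scar-control rz.

    The scar track must come from the same medium and growth phase unless
    ``force`` is set (an override for deliberately mismatched comparisons).
    """
    _check_compatible(sample_rz, scar_rz)
    if sample_rz.stage != "rz" or scar_rz.stage != "rz":
        raise ValueError("subtract_scar expects rz-stage tracks")
    if not force and sample_rz.meta.condition != scar_rz.meta.condition:
        raise ValueError(
            f"condition mismatch: sample {sample_rz.meta.condition} vs scar "
            f"{scar_rz.meta.condition}; pass force=True to override"
        )
    values = sample_rz.values - scar_rz.values
    return sample_rz.with_values(values, "scar_subtracted")


def score_track(
    chip: OccupancyTrack,
    input_: OccupancyTrack,
    pseudocount: float = 1.0,
    depth_normalize: bool = True,
) -> OccupancyTrack:
    """Convenience: raw chip+input -> rz log-ratio in one step."""
    return robust_z(log_ratio(chip, input_, pseudocount, depth_normalize))


def average_replicates(
    tracks: Sequence[OccupancyTrack],
    group_by: Sequence[str] = ("genotype", "medium", "phase", "lineage", "assay"),
) -> dict[tuple, OccupancyTrack]:
    """Per-bin arithmetic mean of tracks within each metadata group.

    Lineages are kept separate by default; pass a ``group_by`` without
    ``"lineage"`` to pool them. Raises on an empty input.
    """
    if not tracks:
        raise ValueError("no tracks to average")
    groups: dict[tuple, list[OccupancyTrack]] = {}
    for t in tracks:
        key = tuple(getattr(t.meta, k) for k in group_by)
        groups.setdefault(key, []).append(t)
    out: dict[tuple, OccupancyTrack] = {}
    for key, members in groups.items():
        first = members[0]
        for m in members[1:]:
            _check_compatible(first, m)
            if m.stage != first.stage:
                raise ValueError("cannot average tracks at different stages")
        mean = np.mean([m.values for m in members], axis=0)
        meta = dataclasses.replace(first.meta, biorep=0)
        out[key] = OccupancyTrack(first.replicon, first.bin_size, mean, meta, first.stage)
    return out


def row_normalize(matrix: np.ndarray | pd.DataFrame) -> tuple[np.ndarray | pd.DataFrame, np.ndarray]:
    """Divide every row of a sites x samples matrix by its maximum.

    Rows whose maximum is <= 0 carry no positive occupancy anywhere; dividing
    by a non-positive maximum would flip signs, so those rows are zeroed and
    flagged. Returns ``(normalized, flagged)`` where ``flagged`` is a boolean
    vector marking the zeroed rows.
    """
    is_frame = isinstance(matrix, pd.DataFrame)
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a 2-D sites x samples matrix")
    rowmax = x.max(axis=1)
    flagged = rowmax <= 0
    safe = np.where(flagged, 1.0, rowmax)
    out = x / safe[:, None]
    out[flagged] = 0.0
    if is_frame:
        out = pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return out, flagged


def condition_correlation(matrix: np.ndarray | pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman correlation between the sample columns of a
    sites x samples occupancy matrix. Symmetric with a unit diagonal."""
    if isinstance(matrix, pd.DataFrame):
        cols = list(matrix.columns)
        x = matrix.to_numpy(dtype=float)
    else:
        x = np.asarray(matrix, dtype=float)
        cols = list(range(x.shape[1]))
    if x.shape[0] < 2:
        raise ValueError("need at least two sites to correlate samples")
    rho = stats.spearmanr(x, axis=0).statistic
    rho = np.atleast_2d(rho)
    if rho.shape == (1, 1):  # spearmanr collapses the 2-column case
        r = float(rho[0, 0])
        rho = np.array([[1.0, r], [r, 1.0]])
    return pd.DataFrame(rho, index=cols, columns=cols)


def paired_occupancy_test(occ_a: np.ndarray, occ_b: np.ndarray) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value for per-site occupancy.

    Exact null distribution for n <= 25 informative pairs, normal
    approximation with continuity correction above that. Identical vectors
    (no informative pairs) give p = 1.
    """
    a = np.asarray(occ_a, dtype=float)
    b = np.asarray(occ_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired test needs two equal-length 1-D vectors")
    d = a - b
    n_informative = int(np.count_nonzero(d))
    if n_informative == 0:
        return 1.0
    method = "exact" if n_informative <= 25 else "approx"
    res = stats.wilcoxon(a, b, alternative="two-sided", method=method, correction=True)
    return float(res.pvalue)
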