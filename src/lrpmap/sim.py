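"""Synthetic-data generator with known ground truth.

Every downstream stage of the pipeline is exercised on data from this
module: a single circular replicon carrying non-overlapping transcription
units, planted primary regulator-binding sites (a configurable fraction at
TSSs), satellite secondary sites offset by 1.2-2.0 kb (the spacing band the
bridging statistics must detect), genotype- and medium-specific binding
scales, regulator-coupled RNAP occupancy shifts at target TUs, and
log-normal-noise quantification tables (blot densitometry and qPCR Cq).

The genotype behaviours emulated by the default parameters:

- WT: full binding in minimal medium; with exogenous leucine (LIV) binding
  is abrogated at one class of sites and reduced at the other.
- L136R: leucine-insensitive; binds slightly more strongly than WT and
  keeps binding in LIV.
- D114E: leucine-sensitive like WT, but in minimal medium it decorates
  primary sites with extra satellite peaks (the bridging-prone mutant).
- dC11: a dimer-only variant that cannot bind DNA at all.
- scar: the regulator-deletion control; all binding scales are zero.

Track noise is per-bin gamma noise on the expected coverage — the
continuous mixing backbone of a gamma-Poisson (negative-binomial) count
model — with coefficient of variation ``noise_sd``, so that ``noise_sd=0``
returns the expected coverage exactly (which the noiseless-limit contracts
rely on). All randomness is driven by ``numpy.random.SeedSequence`` keyed on
the config seed plus the sample coordinates, so identical configs give
byte-identical outputs regardless of generation order.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .regulation import TSSAnnotation, TranscriptionUnit
from .tracks import GENOTYPES, MEDIA, OccupancyTrack, PHASES, SampleMeta

REPLICON = "simrep"


@dataclass(frozen=True)
class GenotypeParams:
    """Binding behaviour of one genotype.

    ``min_binding_scale`` and ``liv_binding_scale`` multiply the planted
    enrichment in minimal and LIV medium; ``extra_secondary_rate`` is the
    expected number of additional genotype-private satellite sites per
    primary site (the D114E behaviour); ``leucine_sensitive`` controls
    whether the abrogated site class loses binding entirely in LIV.
    """

    min_binding_scale: float
    liv_binding_scale: float
    extra_secondary_rate: float = 0.0
    leucine_sensitive: bool = True

    def __post_init__(self) -> None:
        if self.min_binding_scale < 0 or self.liv_binding_scale < 0:
            raise ValueError("binding scales must be >= 0")
        if self.extra_secondary_rate < 0:
            raise ValueError("extra_secondary_rate must be >= 0")


DEFAULT_GENOTYPE_PARAMS: dict[str, GenotypeParams] = {
    "WT": GenotypeParams(1.0, 0.35, 0.0, True),
    "D114E": GenotypeParams(1.0, 0.30, 1.5, True),
    "L136R": GenotypeParams(1.2, 1.05, 0.0, False),
    "dC11": GenotypeParams(0.0, 0.0, 0.0, True),
    "scar": GenotypeParams(0.0, 0.0, 0.0, True),
}


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters of the generator.

    Defaults are a desk-scale rendition of the study design: a 500 kb
    circular replicon (vs the ~4.6 Mb chromosome), 25 bp bins, 40 primary
    sites, satellites at 1.2-2.0 kb, signal-to-background 5, two lineages
    with two biological replicates each.
    """

    genome_length: int = 500_000
    n_tus: int = 60
    bin_size: int = 25
    n_primary_sites: int = 40
    secondary_site_rate: float = 0.5
    secondary_spacing: tuple[int, int] = (1200, 2000)
    peak_width: int = 400
    snr: float = 5.0
    genotype_params: Mapping[str, GenotypeParams] = field(
        default_factory=lambda: dict(DEFAULT_GENOTYPE_PARAMS)
    )
    fraction_abrogated: float = 0.5
    satellite_scale: float = 0.6
    frac_sites_at_tss: float = 0.5
    rnap_effect_size: float = 1.0
    rnap_base_enrichment: float = 3.0
    background_mean: float = 50.0
    noise_sd: float = 0.2
    lineage_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length < 10 * self.n_primary_sites * self.peak_width:
            raise ValueError(
                "genome_length must be at least 10 x n_primary_sites x peak_width "
                f"({10 * self.n_primary_sites * self.peak_width}); got {self.genome_length}"
            )
        lo, hi = self.secondary_spacing
        if not lo < hi:
            raise ValueError("secondary_spacing low must be < high")
        if self.noise_sd < 0 or self.lineage_sd < 0 or self.snr < 0:
            raise ValueError("noise/snr scales must be >= 0")
        if not 0 <= self.fraction_abrogated <= 1:
            raise ValueError("fraction_abrogated must be a probability")
        if self.genome_length % self.bin_size:
            raise ValueError("genome_length must be a multiple of bin_size")
        for g, p in self.genotype_params.items():
            if g not in GENOTYPES:
                raise ValueError(f"unknown genotype {g!r} in genotype_params")
        if "scar" in self.genotype_params:
            p = self.genotype_params["scar"]
            if p.min_binding_scale != 0 or p.liv_binding_scale != 0:
                raise ValueError("scar genotype must have all binding scales = 0")


@dataclass(frozen=True)
class PlantedSite:
    """One planted binding site with its per-(genotype, medium) occupancy scale."""

    center: int
    width: int
    role: str                      # "primary" | "secondary"
    primary_index: int
    response: str                  # "abrogated" | "reduced"
    scales: Mapping[tuple[str, str], float]
    tu_id: str | None = None       # set when the site sits on a TSS

    @property
    def start(self) -> int:
        return self.center - self.width // 2

    @property
    def end(self) -> int:
        return self.center + self.width // 2


@dataclass
class SimTruth:
    """Ground truth for parameter-recovery tests."""

    planted_sites: list[PlantedSite]
    tu_effects: dict[tuple[str, str, str], float]   # (tu_id, genotype, medium) -> log2FC
    western_truth: dict[tuple[str, str, str], float]  # (strain, medium, phase) -> level
    qpcr_truth: dict[tuple[str, str], float]          # (strain, amplicon) -> linear enrichment

    def sites_for(self, genotype: str, medium: str, min_scale: float = 0.0) -> list[PlantedSite]:
        return [s for s in self.planted_sites if s.scales.get((genotype, medium), 0.0) > min_scale]


def _rng(config_seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((config_seed, *key)))


# ---------------------------------------------------------------------------
# Annotation

def simulate_annotation(config: SimConfig) -> tuple[list[TSSAnnotation], list[TranscriptionUnit]]:
    """Non-overlapping TUs with one strand-appropriate TSS each.

    TUs are placed one per equal-width slot of the replicon with random
    length (0.8-3 kb) and jitter, which guarantees disjointness by
    construction; the guarantee is still brute-force checked in the tests.
    """
    if config.n_tus == 0:
        return [], []
    rng = _rng(config.seed, 1)
    slot = config.genome_length // config.n_tus
    if slot < 1200:
        raise ValueError(
            f"genome too small: {config.n_tus} TUs leave {slot} bp per slot; "
            "need >= 1200 bp each"
        )
    tus: list[TranscriptionUnit] = []
    tss: list[TSSAnnotation] = []
    for i in range(config.n_tus):
        max_len = min(3000, slot - 200)
        length = int(rng.integers(800, max_len + 1))
        start = slot * i + int(rng.integers(100, slot - length - 99))
        strand = "+" if rng.random() < 0.5 else "-"
        tu = TranscriptionUnit(f"TU{i:04d}", start, start + length, strand)
        tus.append(tu)
        tss.append(TSSAnnotation(tu.tss_position, strand, tu.tu_id))
    return tss, tus


# ---------------------------------------------------------------------------
# Ground truth

def _site_scales(
    config: SimConfig,
    response: str,
    role_scale: float,
    only_genotype: str | None = None,
) -> dict[tuple[str, str], float]:
    scales: dict[tuple[str, str], float] = {}
    for g, p in config.genotype_params.items():
        for medium in MEDIA:
            if only_genotype is not None and g != only_genotype:
                scales[(g, medium)] = 0.0
                continue
            if medium == "Min":
                s = p.min_binding_scale
            elif response == "abrogated" and p.leucine_sensitive:
                s = 0.0
            else:
                s = p.liv_binding_scale
            scales[(g, medium)] = s * role_scale
    return scales


def build_truth(
    config: SimConfig,
    tss_set: Sequence[TSSAnnotation],
    tus: Sequence[TranscriptionUnit],
) -> SimTruth:
    """Plant sites, wire TU effects to the sites at their TSSs, and set the
    quantification ground truths.

    Primary sites sit on a jittered grid (separation >> satellite spacing);
    ``frac_sites_at_tss`` of them are instead snapped onto TSSs of
    well-separated TUs, and those TUs receive a regulator-dependent RNAP
    log2 effect whose per-(genotype, medium) value follows the site's
    binding scale relative to WT in minimal medium — so a medium that
    removes binding also removes the expression effect.
    """
    rng = _rng(config.seed, 2)
    L = config.genome_length
    n = config.n_primary_sites
    spacing = L / max(n, 1)
    min_sep = 2 * config.secondary_spacing[1] + 2 * config.peak_width

    # TSS-linked primaries: greedily pick TUs with pairwise-separated TSSs
    n_at_tss = int(round(config.frac_sites_at_tss * n))
    chosen: list[TSSAnnotation] = []
    for t in rng.permutation(np.array(tss_set, dtype=object)):
        if len(chosen) == n_at_tss:
            break
        if t.position < min_sep or t.position > L - min_sep:
            continue
        if all(min(abs(t.position - c.position), L - abs(t.position - c.position)) >= min_sep
               for c in chosen):
            chosen.append(t)

    centers: list[tuple[int, str | None]] = [(t.position, t.tu_id) for t in chosen]
    # remaining primaries on grid positions away from everything placed so far
    i = 0
    while len(centers) < n and i < 4 * n:
        c = int((i % n) * spacing + spacing / 2 + rng.integers(-int(spacing / 8), int(spacing / 8) + 1))
        c %= L
        i += 1
        if c < config.peak_width or c > L - config.peak_width:
            continue
        if all(min(abs(c - c0), L - abs(c - c0)) >= min_sep for c0, _ in centers):
            centers.append((c, None))

    sites: list[PlantedSite] = []
    lo, hi = config.secondary_spacing

    def draw_offset(taken: list[int]) -> int | None:
        """Satellite offset that keeps distinct sites spatially distinct."""
        for _ in range(20):
            off = int(rng.integers(lo, hi + 1)) * (1 if rng.random() < 0.5 else -1)
            if all(abs(off - t) >= 1.5 * config.peak_width for t in taken):
                return off
        return None

    for pi, (center, tu_id) in enumerate(centers):
        response = "abrogated" if rng.random() < config.fraction_abrogated else "reduced"
        sites.append(
            PlantedSite(
                center, config.peak_width, "primary", pi, response,
                _site_scales(config, response, 1.0), tu_id,
            )
        )
        taken: list[int] = [0]
        if rng.random() < config.secondary_site_rate:
            offset = draw_offset(taken)
            if offset is not None:
                taken.append(offset)
                sites.append(
                    PlantedSite(
                        (center + offset) % L, config.peak_width, "secondary", pi,
                        response, _site_scales(config, response, config.satellite_scale),
                    )
                )
        for g, p in config.genotype_params.items():
            if p.extra_secondary_rate <= 0:
                continue
            for _ in range(rng.poisson(p.extra_secondary_rate)):
                offset = draw_offset(taken)
                if offset is None:
                    continue
                taken.append(offset)
                extra_scales = _site_scales(
                    config, "abrogated", config.satellite_scale, only_genotype=g
                )
                sites.append(
                    PlantedSite(
                        (center + offset) % L, config.peak_width, "secondary", pi,
                        "abrogated", extra_scales,
                    )
                )

    # TU effects, coupled to binding
    tu_effects: dict[tuple[str, str, str], float] = {}
    wt_min = config.genotype_params.get("WT", GenotypeParams(1.0, 0.0)).min_binding_scale
    for s in sites:
        if s.tu_id is None:
            continue
        base = config.rnap_effect_size * float(rng.uniform(0.75, 1.5))
        if rng.random() < 0.5:
            base = -base
        for g in config.genotype_params:
            for medium in MEDIA:
                rel = s.scales[(g, medium)] / max(wt_min, 1e-12)
                tu_effects[(s.tu_id, g, medium)] = base * rel

    western_truth = {}
    for medium in MEDIA:
        for phase in PHASES:
            western_truth[("WT", medium, phase)] = 1.0
            western_truth[("D114E", medium, phase)] = 1.25
            western_truth[("L136R", medium, phase)] = 0.75
            western_truth[("dC11", medium, phase)] = 0.85 if phase == "Log" else 0.40

    qpcr_truth = {
        ("WT", "Peak1"): 4.0, ("WT", "Peak2"): 3.0,
        ("WT", "Peak3"): 16.0, ("WT", "Peak4"): 5.0,
        ("Lrp5-scr", "Peak1"): 3.2, ("Lrp5-scr", "Peak2"): 2.4,
        ("Lrp5-scr", "Peak3"): 6.0, ("Lrp5-scr", "Peak4"): 4.0,
        ("Peak3-scr", "Peak1"): 2.0, ("Peak3-scr", "Peak2"): 1.6,
        ("Peak3-scr", "Peak3"): 1.0, ("Peak3-scr", "Peak4"): 2.2,
        ("Secondary-scr", "Peak1"): 1.0, ("Secondary-scr", "Peak2"): 1.0,
        ("Secondary-scr", "Peak3"): 10.0, ("Secondary-scr", "Peak4"): 1.0,
    }
    return SimTruth(sites, tu_effects, western_truth, qpcr_truth)


def simulate_experiment(config: SimConfig) -> tuple[list[TSSAnnotation], list[TranscriptionUnit], SimTruth]:
    """Annotation plus matching ground truth in one call."""
    tss, tus = simulate_annotation(config)
    return tss, tus, build_truth(config, tss, tus)


# ---------------------------------------------------------------------------
# Tracks

def _gamma_noise(mu: np.ndarray, cv: float, rng: np.random.Generator) -> np.ndarray:
    """Multiplicative gamma noise with mean mu and coefficient of variation cv."""
    if cv == 0:
        return mu.copy()
    shape = 1.0 / cv**2
    return rng.gamma(shape, mu / shape)


def _lineage_factor(config: SimConfig, lineage: int) -> float:
    r = _rng(config.seed, 9, lineage)
    return float(np.exp(config.lineage_sd * r.standard_normal()))


def _enrichment_profile(
    config: SimConfig,
    truth: SimTruth,
    genotype: str,
    medium: str,
) -> np.ndarray:
    """Sum of Gaussian peak enrichments over the binned replicon, in units of
    the background (1.0 = one background's worth of extra signal)."""
    n_bins = config.genome_length // config.bin_size
    profile = np.zeros(n_bins)
    x = (np.arange(n_bins) + 0.5) * config.bin_size
    sd = config.peak_width / 4.0
    halo = int(np.ceil(4 * sd / config.bin_size))
    for site in truth.planted_sites:
        scale = site.scales.get((genotype, medium), 0.0)
        if scale <= 0:
            continue
        c_bin = site.center // config.bin_size
        idx = np.arange(c_bin - halo, c_bin + halo + 1) % n_bins
        d = np.abs(x[idx] - site.center)
        d = np.minimum(d, config.genome_length - d)
        profile[idx] += config.snr * scale * np.exp(-0.5 * (d / sd) ** 2)
    return profile


def simulate_chip_tracks(
    config: SimConfig,
    truth: SimTruth,
    sample: SampleMeta,
) -> tuple[OccupancyTrack, OccupancyTrack]:
    """Regulator ChIP and matched input coverage for one sample.

    input = background noise; chip = background x (1 + planted enrichment),
    both under gamma noise and a shared lineage factor. For the scar and
    dC11 genotypes the expected chip - input difference at planted sites
    is zero.
    """
    if sample.genotype not in config.genotype_params:
        raise ValueError(f"genotype {sample.genotype!r} not present in config.genotype_params")
    key = (
        3, GENOTYPES.index(sample.genotype), MEDIA.index(sample.medium),
        PHASES.index(sample.phase), sample.lineage, sample.biorep, 0,
    )
    rng = _rng(config.seed, *key)
    lf = _lineage_factor(config, sample.lineage)
    profile = _enrichment_profile(config, truth, sample.genotype, sample.medium)
    mu_chip = config.background_mean * lf * (1.0 + profile)
    mu_input = np.full_like(mu_chip, config.background_mean * lf)
    chip = _gamma_noise(mu_chip, config.noise_sd, rng)
    inp = _gamma_noise(mu_input, config.noise_sd, rng)
    meta = dataclasses.replace(sample, assay="Lrp")
    return (
        OccupancyTrack(REPLICON, config.bin_size, chip, meta, "raw"),
        OccupancyTrack(REPLICON, config.bin_size, inp, meta, "raw"),
    )


def simulate_rnap_tracks(
    config: SimConfig,
    truth: SimTruth,
    sample: SampleMeta,
    tus: Sequence[TranscriptionUnit],
) -> tuple[OccupancyTrack, OccupancyTrack]:
    """RNA-polymerase ChIP and matched input for one sample.

    Every TU body carries a uniform RNAP enrichment of
    ``rnap_base_enrichment x 2**effect`` over background, where the effect is
    the truth's regulator-dependent log2 shift for (tu, genotype, medium) —
    zero for the scar control, so genotype-minus-scar log-ratios recover the
    planted effect exactly in the noiseless limit.
    """
    if sample.genotype not in config.genotype_params:
        raise ValueError(f"genotype {sample.genotype!r} not present in config.genotype_params")
    key = (
        4, GENOTYPES.index(sample.genotype), MEDIA.index(sample.medium),
        PHASES.index(sample.phase), sample.lineage, sample.biorep, 1,
    )
    rng = _rng(config.seed, *key)
    lf = _lineage_factor(config, sample.lineage)
    n_bins = config.genome_length // config.bin_size
    factor = np.ones(n_bins)
    for tu in tus:
        eff = truth.tu_effects.get((tu.tu_id, sample.genotype, sample.medium), 0.0)
        b0, b1 = tu.start // config.bin_size, max(tu.start // config.bin_size + 1, -(-tu.end // config.bin_size))
        factor[b0:b1] = config.rnap_base_enrichment * 2.0**eff
    mu_chip = config.background_mean * lf * factor
    mu_input = np.full(n_bins, config.background_mean * lf)
    chip = _gamma_noise(mu_chip, config.noise_sd, rng)
    inp = _gamma_noise(mu_input, config.noise_sd, rng)
    meta = dataclasses.replace(sample, assay="RNAP")
    return (
        OccupancyTrack(REPLICON, config.bin_size, chip, meta, "raw"),
        OccupancyTrack(REPLICON, config.bin_size, inp, meta, "raw"),
    )


def simulate_condition_tracks(
    config: SimConfig,
    truth: SimTruth,
    genotypes: Sequence[str],
    media: Sequence[str] = MEDIA,
    phases: Sequence[str] = ("Log",),
    lineages: Sequence[int] = (1, 2),
    bioreps: Sequence[int] = (1, 2),
    assay: str = "Lrp",
    tus: Sequence[TranscriptionUnit] | None = None,
) -> dict[SampleMeta, tuple[OccupancyTrack, OccupancyTrack]]:
    """Bulk generation over a sample grid; keys are the SampleMeta."""
    out: dict[SampleMeta, tuple[OccupancyTrack, OccupancyTrack]] = {}
    for g in genotypes:
        for m in media:
            for ph in phases:
                for li in lineages:
                    for r in bioreps:
                        sm = SampleMeta(g, m, ph, li, r, assay)
                        if assay == "Lrp":
                            out[sm] = simulate_chip_tracks(config, truth, sm)
                        else:
                            if tus is None:
                                raise ValueError("RNAP simulation needs the TU annotation")
                            out[sm] = simulate_rnap_tracks(config, truth, sm, tus)
    return out


# ---------------------------------------------------------------------------
# Quantification tables

def simulate_western(
    truth: SimTruth,
    n_bioreps: int = 2,
    n_lineages: int = 2,
    seed: int = 0,
    noise_sd: float = 0.15,
) -> pd.DataFrame:
    """Blot densitometry table: one row per strain x condition x lineage x
    biorep with ``lrp_density`` and ``total_density`` columns.

    Multiplicative log-normal noise throughout; lineages share a smaller
    common factor (half the replicate noise scale). The scar strain carries
    no band and is omitted, matching the modelling convention downstream.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 21)))
    total0 = 1000.0
    rows = []
    strains = sorted({k[0] for k in truth.western_truth} - {"scar"})
    conditions = sorted({(k[1], k[2]) for k in truth.western_truth})
    for strain in strains:
        for medium, phase in conditions:
            level = truth.western_truth[(strain, medium, phase)]
            for lineage in range(1, n_lineages + 1):
                lf = float(np.exp(0.5 * noise_sd * rng.standard_normal()))
                for biorep in range(1, n_bioreps + 1):
                    lrp = level * total0 * lf * float(np.exp(noise_sd * rng.standard_normal()))
                    tot = total0 * float(np.exp(noise_sd * rng.standard_normal()))
                    rows.append(
                        dict(
                            strain=strain, medium=medium, phase=phase,
                            lineage=lineage, biorep=biorep,
                            lrp_density=lrp, total_density=tot,
                        )
                    )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class QPCRDesign:
    """Layout of a ChIP-qPCR run: which strains and amplicons, how many
    replicates, and the two never-bound control amplicons."""

    strains: tuple[str, ...] = ("WT", "Lrp5-scr", "Peak3-scr", "Secondary-scr")
    targets: tuple[str, ...] = ("Peak1", "Peak2", "Peak3", "Peak4")
    controls: tuple[str, ...] = ("ctrlA", "ctrlB")
    n_reps: int = 3
    base_cq: float = 18.0
    ip_efficiency: float = 1.0


def simulate_qpcr(
    truth: SimTruth,
    design: QPCRDesign | None = None,
    seed: int = 0,
    noise_sd: float = 0.1,
) -> pd.DataFrame:
    """ChIP-qPCR Cq table: Cq = base - log2(abundance) + noise.

    Input-fraction abundance is 1 for every amplicon; IP-fraction abundance
    is the truth's planted enrichment (1 at the control amplicons) times a
    global IP efficiency that cancels in the control subtraction.
    """
    design = design or QPCRDesign()
    rng = np.random.default_rng(np.random.SeedSequence((seed, 22)))
    rows = []
    for strain in design.strains:
        for amplicon in design.targets + design.controls:
            enrich = 1.0 if amplicon in design.controls else truth.qpcr_truth[(strain, amplicon)]
            for rep in range(1, design.n_reps + 1):
                cq_in = design.base_cq + noise_sd * rng.standard_normal()
                cq_ip = (
                    design.base_cq
                    - np.log2(enrich * design.ip_efficiency)
                    + noise_sd * rng.standard_normal()
                )
                rows.append(dict(strain=strain, amplicon=amplicon, fraction="input", rep=rep, cq=cq_in))
                rows.append(dict(strain=strain, amplicon=amplicon, fraction="IP", rep=rep, cq=cq_ip))
    return pd.DataFrame(rows)


def simulate_qrt_table(
    effects: Mapping[tuple[str, str], float],
    reference_transcripts: Sequence[str] = ("refA", "refB"),
    strains: Sequence[str] = ("WT",),
    n_reps: int = 4,
    base_cq: float = 20.0,
    seed: int = 0,
    noise_sd: float = 0.15,
) -> pd.DataFrame:
    """qRT-PCR Cq table for the ddCq model.

    ``effects[(gene, strain)]`` is the true log2 expression change of the
    gene in that strain relative to WT (positive = higher in the strain);
    reference transcripts are unchanged everywhere. Genes are taken from the
    effect keys; WT rows are always emitted.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 23)))
    genes = sorted({g for g, _ in effects})
    all_strains = sorted(set(strains) | {s for _, s in effects} | {"WT"})
    rows = []
    for strain in all_strains:
        for rep in range(1, n_reps + 1):
            for ref in reference_transcripts:
                rows.append(dict(gene=ref, strain=strain, rep=rep,
                                 cq=base_cq + noise_sd * rng.standard_normal()))
            for gene in genes:
                eff = effects.get((gene, strain), 0.0) if strain != "WT" else 0.0
                rows.append(dict(gene=gene, strain=strain, rep=rep,
                                 cq=base_cq - eff + noise_sd * rng.standard_normal()))
    return pd.DataFrame(rows)
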