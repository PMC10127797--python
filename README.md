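# lrpmap

Analysis pipeline for genome-wide binding and regulatory output of a
leucine-responsive global transcription regulator (Lrp-family / feast-famine
response proteins), built around paired regulator + RNA-polymerase ChIP on a
bacterial chromosome with a regulator-deletion (`lrp::scar`) control.

The package answers four questions a regulator-ChIP study asks:

1. **Where does the regulator bind, beyond what a knockout shows?**
   Occupancy is the *rz-log ratio* — the robust z-scored log2 ratio of ChIP
   over input — with the knockout's rz track subtracted under the matched
   medium and growth phase:

       lr  = log2((chip + c) / (input + c))
       rz  = (lr − median(lr)) / (1.4826 · MAD(lr))
       occ = rz_sample − rz_knockout

   Peaks are maximal runs of bins with `occ ≥ 4` (gaps ≤ 4 bins bridged,
   runs < 2 bins dropped); consensus sites are the merged union over all
   strains and conditions, giving the sites × samples occupancy matrix used
   for row-normalised heat maps, Euclidean/average-linkage clustering, and
   pairwise Spearman condition correlations.

2. **What does binding do to transcription?** RNAP occupancy per
   transcription-unit body, expressed as a log2 fold change versus the
   knockout, with label-permutation significance and Benjamini–Hochberg
   correction. A TU is a *direct target* when a peak overlaps its TSS *and*
   the RNAP change is significant. Direct targets are classified into the
   six regulation modes — {independent, concerted, reciprocal} ×
   {activating, repressing} — and the effector's influence is summarised by
   the leucine-modulation score `(ΔLIV − ΔMin) · sign(ΔMin)`.

3. **Does the regulator bridge DNA?** Higher-order oligomers show up as
   clustered peaks: local peak counts within a 2 kb radius (permutation test
   between genotypes), and the interpeak-distance distribution against a
   null built from 200 random re-placements of the peaks within their local
   regions, summarised as Gaussian-KDE densities with a pointwise 95% band.

4. **How much protein / binding / expression, with what certainty?**
   Bayesian normal models on log-scale responses (ensemble MCMC): Western
   densitometry with a lineage random intercept reporting `P_diff` (the
   posterior probability of a difference vs wild type in the observed
   direction), ChIP-qPCR log2 enrichment vs two control amplicons with
   Savage–Dickey log10 Bayes factors (tiers `*` 0.5–1, `**` 1–2, `***` >2),
   and ΔΔCq expression effects vs reference transcripts.

A synthetic-data generator (`lrpmap.sim`) emulates the study's signal
structure — planted primary sites, satellite peaks at 1.2–2.0 kb spacing,
genotype-specific leucine responses, regulator-coupled RNAP shifts, and
log-normal quantification noise — with full ground truth, so every stage is
testable end to end without external data.

## Worked example

```python
from lrpmap import sim, tracks, peakcall, bridging

config = sim.SimConfig(seed=1)           # 500 kb circular replicon, SNR 5
tss_set, tus, truth = sim.simulate_experiment(config)

def averaged_rz(genotype, medium):
    rzs = []
    for lineage in (1, 2):
        for biorep in (1, 2):
            meta = tracks.SampleMeta(genotype, medium, "Log", lineage, biorep)
            chip, inp = sim.simulate_chip_tracks(config, truth, meta)
            rzs.append(tracks.score_track(chip, inp))
    (avg,) = tracks.average_replicates(rzs, group_by=("genotype",)).values()
    return avg

occ = {}
for genotype in ("WT", "D114E"):
    for medium in ("Min", "LIV"):
        occ[(genotype, medium)] = tracks.subtract_scar(
            averaged_rz(genotype, medium), averaged_rz("scar", medium)
        )

peaks = {key: peakcall.call_peaks(track) for key, track in occ.items()}
for (genotype, medium), p in peaks.items():
    print(f"{genotype:6s} {medium}: {len(p):3d} peaks")

sites, matrix = peakcall.consensus_union(
    {f"{g}_{m}": p for (g, m), p in peaks.items()},
    {f"{g}_{m}": t for (g, m), t in occ.items()},
)
print(f"consensus sites: {len(sites)}")

L = config.genome_length
wt = bridging.local_peak_counts(peaks[("WT", "Min")], radius=2000, genome_length=L)
d1 = bridging.local_peak_counts(peaks[("D114E", "Min")], radius=2000, genome_length=L)
p = bridging.local_count_permutation(d1.local_counts, wt.local_counts,
                                     n_perm=999, seed=1)
print(f"mean local peak count: WT {wt.mean_local_count:.2f}, "
      f"D114E {d1.mean_local_count:.2f} (permutation p = {p:.3f})")
```

prints

```
WT     Min:  59 peaks
WT     LIV:   4 peaks
D114E  Min: 106 peaks
D114E  LIV:   3 peaks
consensus sites: 107
mean local peak count: WT 1.64, D114E 2.38 (permutation p = 0.001)
```

Reading the output: the wild-type regulator binds broadly in minimal medium
and loses nearly all binding when leucine is added; the
oligomerisation-biased D114E variant decorates primary sites with extra
satellite peaks in minimal medium (106 vs 59 peaks; a higher mean local peak
count, significant at the permutation floor), the signature of DNA bridging
by higher-order oligomers. The 107 consensus sites are the union of
everything bound in at least one sample, each carrying the per-sample mean
occupancy for downstream clustering.

A `lrpmap` CLI wraps the same stages for file-based use
(`simulate`, `score`, `callpeaks`, `regulation`, `bridging`, `bayes`,
`all`); every subcommand consumes and emits plain files (bedGraph, BED6,
GFF3, TSV, JSON) and logs each default parameter it used.

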