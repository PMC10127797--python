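# Methods

## Occupancy statistic

All binding analysis runs on binned coverage (default 25 bp bins, 0-based
half-open, one circular replicon). The occupancy statistic is computed in
three enforced stages:

1. **log-ratio** `log2((chip + c)/(input + c))` per bin. The input track is
   first rescaled to the ChIP track's total signal ("depth normalisation"),
   so library-size differences do not shift the whole track; the pseudocount
   `c` (default 1) stabilises empty bins. Both choices are configurable.
2. **robust z** `(x − median)/(1.4826·MAD)`. The constant 1.4826 makes the
   scale estimate consistent with a normal standard deviation — the standard
   robust-z convention. A track whose MAD is zero (more than half the bins
   identical) is rejected rather than silently passed through.
3. **knockout subtraction**: the rz track of the regulator-deletion (scar)
   strain grown in the same medium and phase is subtracted bin-wise. This
   removes apparent enrichment present without any regulator (copy-number
   waves, sticky regions). Mismatched conditions are rejected unless an
   override flag is set.

Replicate averaging is a plain per-bin mean within metadata groups; lineage
replicates (independently constructed strains of the same genotype) are kept
separate by default and pooled only on request.

## Peak calling and consensus sites

A peak is a maximal run of bins at or above a threshold of 4 robust-z units
on the scar-subtracted track, with sub-threshold gaps of at most 4 bins
bridged and runs narrower than 2 bins discarded. The threshold and both
width parameters are exposed and logged on every run; 4 rz units sits well
above the scar-vs-scar noise floor at the generator's default noise level
while keeping satellite peaks (60% of primary amplitude) detectable on
replicate-averaged tracks.

The run search is linear along the binned track: a run crossing the origin
of the circular replicon would be split in two. The synthetic generator
never plants sites within one peak width of the origin, and all downstream
distance statistics are fully circular; for external data with a hot origin
the track should be rotated first. This is a known limitation, not a
configuration option.

Consensus sites are the union of peak intervals over all samples merged at
gap zero. A site counts once however many samples hit it, which is why
per-genotype "total" counts are not row sums. The sites × samples matrix
holds each sample's mean scar-subtracted occupancy over the merged interval;
row normalisation divides by the row maximum, zeroing and flagging rows
whose maximum is non-positive (dividing by a negative maximum would flip
signs). Heat-map ordering uses agglomerative clustering with Euclidean
distance and average linkage.

Count comparisons between genotypes/conditions use the exact conditional
Poisson rate test (binomial on `n1` of `n1+n2` at p = 1/2) and the
two-proportion chi-square with Yates continuity correction — the same tests
R's `poisson.test` and `prop.test` perform.

## Binding-to-transcription

TSS overlap is containment of the TSS position in the half-open peak
interval. Promoter enrichment is an approximate permutation test: each peak
is re-placed uniformly at random on the circular replicon (width preserved)
and the overlap fraction recomputed; the p-value carries the +1 correction,
`p = (1 + #{null ≥ obs})/(1 + n_perm)`, which keeps it valid (super-uniform
under the null) at any permutation count.

The RNAP effect for a TU is the mean log-ratio over TU-body bins, genotype
minus knockout, averaged over replicates; its standard error combines both
groups' replicate scatter. Significance is by label permutation between the
genotype and knockout replicate groups with Benjamini–Hochberg adjustment
across TUs. With 4-vs-4 replicates the permutation p-value has a discrete
floor of 2/70 ≈ 0.029, so q < 0.05 calls require a well-populated
alternative — which a global regulator provides; the floor is stated here
because it surprises users expecting arbitrarily small single-TU q-values.

A direct target is a TU whose TSS is overlapped by a peak *and* whose RNAP
change is significant (q ≤ 0.05 by default) in at least one condition.

### Six-mode classification

The activation/repression axis is the sign of the minimal-medium effect
(the effector-supplemented effect if minimal medium shows none). The
effector axis compares effect magnitudes between media using ±1.96·se
intervals on |log2FC|:

- effect absent or binding lost with the effector → **reciprocal**;
- effect present only with the effector → **concerted**;
- |effect| intervals disjoint, effector side smaller → **reciprocal**;
  larger → **concerted**;
- overlapping intervals while bound in both media → **independent**.

"Bound" is binary at the peak-call level; partial reduction of binding still
counts as bound, with magnitude handled by the interval comparison and by
the leucine-modulation score `(ΔLIV − ΔMin)·sign(ΔMin)` (positive = the
effector strengthens the regulator's effect). The interval-overlap rule is a
design choice: no published boundary exists for "augmented / inhibited /
unchanged", so the package uses replicate-based intervals at the 0.05 level
and exposes `z`.

## Bridging statistics

Local peak counts: for each peak, the number of peaks whose edge-to-edge
(circular) distance is within a 2 kb radius, the focal peak included — so an
isolated peak scores 1 and a mean of ~2 reads as "self plus one neighbour".
Inclusion is a flag (`include_self`) because either convention is coherent;
only the baseline shifts by exactly 1. Genotype comparisons use a two-sided
permutation test on the pooled counts, switching to full label enumeration
when the number of distinct reassignments is ≤ 20 000 (groups up to ~8 per
side), and Monte Carlo with the +1 correction otherwise.

Interpeak distances are center-to-center between consecutive peaks (circular
for genome-wide sets, linear within regions). The null distribution
re-places every peak uniformly at random *within its region* — regions
default to fixed-span (10 kb) windows around observed peak clusters and are
serialized with results — preserving peak count and widths per region
(asserted on every shuffle) and enforcing non-overlap by rejection sampling
with a retry cap. Two hundred shuffles give a pointwise mean and central 95%
band over a distance grid; densities are Gaussian KDEs with Scott's-rule
bandwidth. An observed density above the upper band near 1.2–2.0 kb is the
bridging signature the generator plants.

## Bayesian quantification models

All three models use a normal likelihood on log-scale responses with weakly
informative priors — cell means `Normal(data mean, (2.5·data SD)²)`, scales
half-normal — recorded on every summary. Sampling is ensemble MCMC (emcee)
with differential-evolution moves, 48 walkers, 3000 steps with 1000 burn-in
by default, walkers initialised at the per-cell means with residual-scale
dispersion. Convergence is flagged (`converged=False`) when a split-Rhat
over walker groups exceeds 1.01; walkers are pooled into four pseudo-chains
for this diagnostic because individual ensemble walkers are autocorrelated
by construction. Summaries are deterministic given the seed.

- **Densitometry (Western) model**: response `log(band/total)`, one mean per
  strain × medium × phase plus a lineage random intercept, which is
  integrated out analytically (per-lineage block covariance
  `σ²I + τ²J`, inverted by Sherman–Morrison). Marginalisation removes the
  location ridge and the τ funnel that otherwise slow ensemble samplers
  several-fold. Reported per cell: posterior mean, 95% credible interval,
  and `P_diff` — `max(P(Δ>0), P(Δ<0))` against the wild-type cell of the
  same medium and phase, with the direction. The knockout strain has no band
  and is rejected if present.
- **ChIP-qPCR model**: per replicate, `ΔCq = Cq(IP) − Cq(input)`; the log2
  enrichment of a target is the mean control ΔCq minus the target ΔCq (two
  control amplicons required). Cell means share a residual scale; the
  enrichment prior `Normal(0, 4)` (log2 units) also anchors the
  Savage–Dickey Bayes factor: `log10 BF = log10(prior(0)/posterior(0))`,
  posterior density at zero by Gaussian KDE over the draws, floored at
  1e−12 so the BF stays finite. Evidence tiers 0.5–1 / 1–2 / >2 map to
  * / ** / ***. The KDE density is only trustworthy where the posterior has
  mass; beyond ~3 posterior SDs from zero the BF is a saturating lower-bound
  statement, which is all the tier labels require.
- **ΔΔCq model**: `ΔCq` against the mean of a reference-transcript set, one
  mean per strain per gene with a shared residual; the reported effect is
  `m(WT) − m(mutant)`, so positive = higher expression in the mutant, and
  its prior for the Bayes factor is the analytic difference prior
  `Normal(0, 2·(2.5·SD)²)`.

## Synthetic-data generator

The generator defines the study conditions; its defaults are fixed, not
tuning knobs. One circular 500 kb replicon (a desk-scale stand-in for a
~4.6 Mb chromosome) carries 60 non-overlapping TUs (0.8–3 kb, one per
genome slot, strand random, TSS at the strand-appropriate end) and 40
primary binding sites, half snapped onto TSSs of well-separated TUs, the
rest on a jittered grid with ≥ 2×(max spacing)+2×(peak width) separation.
Half the primary sites are "abrogated" (binding lost with the effector),
half "reduced". With probability 0.5 a primary carries one satellite site at
1.2–2.0 kb offset (random sign) at 60% amplitude; satellite offsets around
one primary are kept ≥ 1.5 peak widths apart so distinct sites stay
spatially distinct.

Genotype behaviour is a per-genotype (Min scale, LIV scale, extra-satellite
rate, leucine-sensitive) tuple: wild type (1.0, 0.35, 0, sensitive);
a leucine-insensitive variant (1.2, 1.05, 0, insensitive — binds slightly
stronger and keeps binding); a bridging-prone variant (1.0, 0.30,
Poisson(1.5) private satellites per primary in minimal medium, sensitive);
a non-binding dimer-only variant and the knockout (all zero). These values
express the qualitative contrasts the pipeline must resolve (binding
abrogated vs reduced vs insensitive; satellite formation) at the default
SNR of 5; they were chosen once as the generator's study conditions.

Tracks: enrichment is a Gaussian bump (SD = peak width/4) scaled by
SNR × site scale on a flat background of 50 counts/bin. Noise is per-bin
gamma noise with coefficient of variation `noise_sd` (default 0.2) — the
continuous mixing backbone of a gamma-Poisson (negative-binomial) count
model. The continuous form was chosen so that `noise_sd = 0` returns the
expected coverage exactly, which the noiseless-limit contracts (exact
log2FC recovery) rely on; the background model of real tracks is not
specified anywhere, so this is a stand-in and parameter-recovery results
should be read as properties of this noise family. Lineages share a small
multiplicative factor (`lineage_sd = 0.05`) mirroring the
lineage-vs-biological-replicate hierarchy.

RNAP tracks put a uniform 3× enrichment over every TU body, multiplied by
`2^effect` where the planted effect for (TU, genotype, medium) follows the
TSS site's binding scale relative to wild type in minimal medium — a medium
that removes binding removes the expression effect, which is what makes the
"effector only weakens binding ⇒ only reciprocal modes" property hold by
construction. Western truth plants the dimer-only variant low (0.85× in log
phase, 0.40× stationary), the bridging variant high (1.25×), the insensitive
variant low (0.75×); qPCR truth plants 4/3/16/5-fold enrichment at four
linked peaks with scrambling-derived reductions (key-site scramble: primary
peak 16→6; whole-peak scramble: 16→1 with linked peaks reduced). Replicate
tables use multiplicative log-normal noise; all tables and tracks are
byte-reproducible from the config seed via `SeedSequence` keyed on the
sample coordinates.

What the generator does **not** emulate: read-level sampling and mapping
artefacts, sequence-dependent background, motif content, growth-curve
dynamics, and condition-dependent library composition. Passing tests
therefore demonstrate the pipeline's statistical machinery — calibration,
recovery, classification — under a controlled noise family, not performance
on any particular real data set.

## Problem sizes and numerical choices

Test and acceptance runs use the 500 kb/40-site genome, 100 TUs for effect
recovery, 999 permutations for single tests, 99 for the 500-trial
calibration studies, 200 shuffles for the interpeak null, and 50 seeded
replicates for credible-interval coverage — sizes at which every acceptance
property is stable across seeds. Permutation p-values always carry the +1
correction; BH is scipy's `false_discovery_control`; the Wilcoxon test is
exact for ≤ 25 informative pairs and normal-approximated with continuity
correction above; identical paired vectors return p = 1 by convention.
Degenerate KDE inputs (fewer than two distances, zero spread) fall back to a
narrow Gaussian so density plots remain defined.
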