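# Methods

## Experimental model

Three TMT 10-plex multiplexes, one per myogenic stage — myoblast (M, day 0),
early myotube (EM, day 5), late myotube (LM, day 9). Each multiplex carries
nine sample channels, {untreated, vehicle (EtOH), TMX+vehicle} × 3 biological
replicates, plus a tenth channel containing an identical pooled *bridge*
sample (one designated replicate of every condition × timepoint, pooled on the
linear scale). Input to the pipeline is protein-level reporter intensity — no
peptide/PSM processing is modelled. Intensities are nonnegative; zero means
"not quantified" and is treated as missing, because a log2 abundance is
undefined there and absence of reporter signal carries no quantitative
information.

## Normalization

Two layers, in order:

1. **Sample loading.** Each channel's intensities are multiplied by
   (grand mean of all 30 channel totals) / (that channel's total), computed on
   the protein intersection of the three multiplexes. This equalizes all
   channel totals and removes per-channel loading/labeling factors under the
   usual compositional assumption that total protein per channel is equal by
   design. The assumption has a measurable cost: if regulated proteins move
   the *linear* channel total by a factor r, every log2 ratio against that
   channel is shifted by −log2 r. At the emulated prevalence (~10 % regulated,
   both directions) the shift is ≈ 0.02 log2 units — negligible against the
   |log2FC| ≥ 1 call threshold — but validation scenarios that plant many
   same-direction effects must balance their linear totals (the recovery tests
   plant a 1:4 up:down mix at ±2 precisely so the totals cancel).
2. **Bridge correction.** Per protein p and multiplex m, the offset
   log2 bridge(p, ref) − log2 bridge(p, m) is added to every log2 value of p
   in m (reference: the M multiplex). Because the bridge sample is identical
   in every multiplex, its expectation differs across multiplexes only by the
   multiplex batch term, which the offset therefore cancels — exactly, in the
   noiseless limit (verified to 1e−9). Proteins with a missing bridge in any
   multiplex cannot be aligned; they are dropped and listed. The two layers
   commute with the downstream ratio analysis only when the loading layer is
   composition-free, which is why the exact batch-cancellation property is
   stated (and tested) on the bridge layer alone.

Open interpretation, recorded here deliberately: "normalize to the average
channel intensity" is implemented as total-sum (equivalently mean) scaling on
the linear scale before log transformation; median-based scaling would differ
only by a per-channel constant with no effect on any downstream call.

## Longitudinal (MR) analysis

Per condition and protein: log2FC = mean(log2 later stage) − mean(log2 M)
over replicates (not log of ratio of means — consistent with channel-level
log transformation); two-tailed two-sample pooled-variance Student t test,
df = n1+n2−2; BH step-up per condition × comparison family over all proteins
with ≥ 2 quantified replicates in both groups. MR iff both EM/M and LM/M have
adjusted p ≤ 0.05 **and** either |log2FC| ≥ 1. Both thresholds are
configuration, not constants.

Degenerate rows (pooled variance exactly zero, which the noiseless simulation
produces legitimately): p = 1 when the means are equal, p = 0 otherwise, and
the row is flagged. Welch's unequal-variance test is available via
`equal_var=False` on every testing entry point; the pooled Student form is
the default (it is the literal reading of "Student's t test").
`pooled_ttest_rows` is the single shared implementation, cross-checked
against `scipy.stats.ttest_ind` in both modes.

A consequence worth knowing: with n = 3 (df = 4), a |log2FC| = 1 effect at
log2 noise SD 0.25 has a raw-p floor near 2×10⁻³, which proteome-wide BH at
10⁴ tests converts to adjusted p ≈ 0.1 unless many proteins share the effect.
Recovery is therefore excellent for |log2FC| = 2 (sensitivity ≈ 0.98 in the
acceptance run) but deliberately modest for threshold-sized effects; the
emulation's MR counts at default noise are correspondingly smaller than the
planted archetype counts. This is a property of the published design's
statistics at the simulator's noise policy, not of the implementation.

## Trajectory clustering

Vector per protein: (log2 mean M abundance, log2FC EM/M, log2FC LM/M), each
column standardized over the clustered set to median 0 and population SD 1.
k-means: Lloyd with k-means++ seeding, k = 5 (fixed by the model of five
canonical trends; a knob, with no automatic selection), best of 50 restarts
by within-cluster sum of squares, deterministic under the documented seed.
Cross-condition cluster correspondence is a minimum-cost one-to-one
assignment on centroid Euclidean distances (Hungarian algorithm; equals the
brute-force minimum over all 5! permutations in tests), with per-pair
overlap/only-A/only-B counts over shared proteins.

Degenerate input (a component column whose spread is at floating round-off
level, ≤ 1e−12 relative) is rejected rather than standardized into noise.

## Vehicle-corrected stagewise DE

Within each multiplex, corrected(channel) = log2(channel) − mean(log2
untreated replicates of that protein, same multiplex), applied to vehicle and
TMX channels. The correction expresses both treated groups relative to the
untreated baseline; any solvent (EtOH) effect loads on both and cancels in
the TMX-vs-vehicle contrast, whose group-mean difference is numerically
identical before and after correction — the correction buys interpretability
and baseline-referenced per-replicate values, not a different estimate. DE
per stage: pooled t test, BH over all proteins tested at that stage, call iff
|log2FC| ≥ 1 and adjusted p **strictly** < 0.05 (the −log10 ≥ 1.3
convention); the MR rule's ≤ is kept distinct on purpose, mirroring the two
rules' sources.

## Set logic

Seven-region Venn partition of the three MR sets. The TMX clustering input
removes regulation that requires the vehicle without the untreated condition:
kept = all-three ∪ TMX-only ∪ untreated∩TMX. The "DE as a result of
treatment" total is the union over stages (a protein DE twice counts once).
Highly regulated: DE at ≥ 2 stages, sorted by stage count then ID. External
overlap takes a caller-supplied homolog identifier list and reports
|intersection| and its percentage of the reference (nearest integer); no
ortholog database is consulted.

## Synthetic data generator

What it emulates: the 3 × 10-channel layout; five archetype trajectory
shapes as (M, EM, LM) log2 offsets — defaults (0,−1,−2), (0,−1,+0.5),
(0,+1,0), (0,+0.7,+1.4), (0,+2,+2), of which only the last's quadrupling
between M and EM is anchored to the biology, the rest encode the qualitative
trends and are configurable; archetype prevalences 306/346/182/166/62 per
10,000; baseline abundance N(14, 2) on log2 (configurable to a shared
per-archetype baseline, making the M-abundance trajectory component
class-informative as it is for real co-regulated families); multiplex batch
offsets (0, +0.3, −0.2) log2 and per-channel loading N(0, 0.15) drawn once
per run; multiplicative log-normal measurement noise (additive Gaussian on
log2, SD 0.25 by default — TMT reporter CVs are approximately constant on the
log scale); planted treatment effects as (condition, stage(s), log2 effect,
fraction) entries, where vehicle effects load on vehicle *and* TMX channels
(the drug is dissolved in the solvent) and comma-joined stages put one effect
in one protein subset at several stages. Default grid: vehicle +1.5 at EM,LM
on 1.5 % (vehicle-dependent regulation for the exclusion step); TMX −1.5 at
M/EM/LM on 1.35 %/0.04 %/0.53 %, at M,LM on 0.09 %, +1.5 at all three stages
on 0.01 % (multi-stage regulation with a single three-stage protein in
expectation).

The bridge channel is the linear-scale mean of the designated replicate's
noise-free program over all nine condition × timepoint pools, times the
multiplex's batch/loading/noise factors — identical in expectation across
multiplexes, which is the property bridge correction exploits. Randomness:
one seed; the ground truth, the loading draw and per-protein noise substreams
are derived from it deterministically (spawned sequences), so any protein
subset is reproducible independent of the rest and byte-identical reruns are
guaranteed.

What it does **not** emulate, hence what passing tests cannot show about real
data: peptide/PSM-level effects (co-isolation interference, isotopic
impurity, ratio compression), missingness that correlates with abundance,
heavier-tailed replicate noise, and correlated protein families beyond the
shared archetype means.

## Numerical and design choices

- BH adjustment delegates to the standard step-up implementation and is
  checked against a literal brute-force evaluation of the definition on 1,000
  random families.
- k-means and the assignment problem use the standard library
  implementations (scikit-learn, SciPy); the t test is implemented here
  because the degenerate zero-variance policy is part of the contract.
- TSV is the only on-disk format; floats round-trip at full precision.
  A JSON manifest records config, seed, thresholds and per-stage counts, and
  contains no timestamps so reruns are byte-identical.
- Default problem sizes in tests and the acceptance script (600–10,000
  proteins, 1,000 BH families, 3 seeds for stochastic claims) were chosen as
  the smallest sizes at which the quantities of interest are stable.

## Known limitations

- The loading-normalization compositional bias described above is inherent to
  total-sum scaling; strongly one-sided proteome remodelling would need a
  reference-set normalization instead.
- With three replicates, threshold-sized effects (|log2FC| ≈ 1) are
  underpowered at proteome-wide FDR control; the pipeline reports them
  faithfully rather than moderating variances (no empirical-Bayes shrinkage,
  by design — plain Student t is the contract).
- Cluster matching assumes the same k on both sides and one-to-one
  correspondence; genuinely merged/split trends across conditions will be
  forced into the nearest permutation.
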