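# Methods

`medipdiff` re-implements, as a reusable and fully testable pipeline, the
analysis layer of a MeDIP promoter tiling-array study of differential DNA
methylation: per-probe enrichment scoring and sliding-window peak calling,
the M′ differential statistic with a two-criterion filter for differential
enrichment peaks (DEPs), CpG-density promoter classification, gene
annotation with gene-set over-representation, and the validation-layer
statistics (bisulfite clone ratios, 2^−ΔΔCt expression, OGTT AUC, HOMA-IR).
Every stage can be driven by a synthetic-data generator that plants known
signal, so the whole pipeline is exercised without any external download.

## Array data model

Probe-level signal is the per-sample log2(MeDIP/Input) ratio on a promoter
tiling array. All intervals are 0-based half-open; probe tables are kept
sorted by (chromosome, start). The design contrasts exactly two groups
(default labels `HF-inulin` vs `HF`) with at least two — by default three —
replicates each. Missing per-sample values are dropped from probe means and
CVs; a probe with fewer than two non-missing replicates in either group is
excluded from peak membership.

## Normalization

The protocol this pipeline follows starts "from the normalized log2 ratio
data" without specifying the normalization; `normalize_log2_ratios` applies
per-sample median centering. It is robust, preserves scale (the downstream
0.3-log2 filter threshold stays meaningful) and is idempotent.

## Probe scoring

The vendor software the protocol names scores probes with a windowed test
against the array-wide distribution but does not document the statistic.
`score_probes` uses a windowed one-sided Mann–Whitney U test: for each
probe, the across-sample averages of the probes within a centred 750 bp
window are compared against the rest of the array, alternative "greater",
and the probe score is −log10 p. Windows holding fewer than 4 probes score
0. Because window ∪ rest is exactly the whole array, the rank sum of the
window is obtained from a single global ranking with per-chromosome prefix
sums; the tie-corrected normal approximation with continuity correction is
then evaluated in closed form. This is numerically identical to
`scipy.stats.mannwhitneyu(window, rest, alternative="greater",
method="asymptotic")` (asserted in the tests) but runs in O(n log n) for
the whole array instead of one scipy call per probe. Window width and the
minimum occupancy are parameters of `PeakCallParams`.

## Peak calling

A peak is a maximal run of probes scoring at least the −log10 p cutoff
(default 2) in which consecutive member midpoints are at most 500 bp apart
(defaults from the emulated protocol: at least two probes above a −log10 p
cutoff of 2 with maximum 500 bp spacing). Ties at the cutoff count as
above; a below-cutoff probe between two members does not break a run (the
gap rule is evaluated between member midpoints). The peak interval spans
the first member's start to the last member's end and the peak score is the
median member score. `find_peaks` is checked against a brute-force
maximal-run oracle on thousands of random tracks.

## Differential analysis: M′ and the DEP filter

Per probe, `M′ = mean(log2 MeDIP/Input over treatment replicates) − mean
over control replicates`, so swapping the group labels negates the track
exactly. DEPs are called by running the windowed scorer and peak finder on
M′ (hypermethylated) and on −M′ (hypomethylated) and filtering:

1. at least one group has a median — over member probes — within-group mean
   log2 ratio ≥ 0.3, **and** the median M′ over member probes is positive
   in the peak's own direction. The source protocol states "a median M′ >
   0" without a sign convention; applied literally it would forbid
   hypomethylated DEPs entirely, so the criterion is evaluated on the
   direction-signed M′ (−M′ for hypo peaks), the only reading under which
   both directions can exist.
2. in both groups, at least half of the member probes have CV ≤ 0.8 across
   replicates, with CV = SD/mean computed on the linear-scale ratio
   2^(log2 ratio) (the CV of a signed log quantity is ill-defined).

Both criteria and all their summary quantities are recorded on each
returned `DifferentialPeak`, so a verdict is always reproducible from the
stored summaries. Tightening any threshold can only remove DEPs, and the
hyper/hypo call sets exchange exactly under label swap (both are property
tests).

### Operating characteristics

Sliding-window scores are spatially correlated: with 100 bp probe spacing
inside a 750 bp window, neighbouring probes share about six of seven window
members, so their scores are nearly identical and null exceedances of the
1%-level cutoff arrive in runs rather than singly. Consequently the
"at least two probes above the cutoff" rule does not square the per-probe
false-positive rate the way it would for independent scores. Under the
default synthetic conditions (500 promoters, 9000 probes, 3 replicates per
group, noise SD 0.3) the acceptance script measures, per null array, a few
dozen raw false peaks of which the DEP filter removes those on
unmethylated baseline — leaving on the order of 5–12 false DEPs per run
(about 1–2 per 100 promoters) — and, at a planted effect of 1.0 log2
units, sensitivity ≈ 1.0 with precision ≈ 0.8–0.93. This is an intrinsic
property of windowed peak calling at a fixed per-probe cutoff, not a
tuning artifact: decorrelating the scores would require abandoning the
windowed statistic, and tightening the cutoff would depart from the
protocol's stated −log10 p = 2. Real studies using this protocol should
therefore expect the DEP list to contain a non-trivial false-positive
fraction; orthogonal validation (e.g. bisulfite sequencing of candidate
loci, as in the study this pipeline emulates) remains essential.

## CpG-density promoter classification

Each promoter sequence is scanned with 500 bp windows every 5 bp. Per
window: GC fraction and the CpG observed/expected ratio
(#CpG × L)/(#C × #G), defined as 0 when the denominator vanishes. A
promoter is **HCP** if any window has ratio > 0.75 and GC > 0.55, **LCP**
if no window has ratio > 0.48, **ICP** otherwise. The thresholds follow
the published three-way classification scheme the protocol cites (it does
not restate them) and are exposed in `CpgClassThresholds`. Classification
applies to the host promoter, and inserting CpGs can never demote a
promoter toward LCP (property test).

## Annotation and over-representation

DEPs map to promoters by ≥ 1 bp interval overlap; a DEP spanning two
promoters (divergent genes) is assigned both. The study list is the
deduplicated mapped-gene set — which is why region counts exceed gene
counts. Over-representation uses the upper-tail hypergeometric test per
gene set with the array's gene list as universe (the standard background
for array designs), Benjamini–Hochberg adjusted across all tested sets;
significance is flagged at adjusted P < 0.01 (GO-style) and < 0.05
(KEGG-style). `bh_adjust` is the classic step-up
(q_i = min_{j≥i} p_(j)·m/j, capped at 1) and is verified against
statsmodels on random vectors; the hypergeometric tail is verified against
exact enumeration. The pipeline deliberately uses the plain hypergeometric
test rather than the EASE-modified Fisher score of DAVID-style web tools,
so enrichment results on real data are structurally, not numerically,
comparable to those tools.

## Bisulfite clone statistics

Clone matrices are binary (clone × CpG site) methylation calls per animal
per amplicon; missing calls are excluded from numerator and denominator.
The per-animal overall ratio — not the clone — is the unit of analysis, to
avoid pseudoreplication from many clones per mouse. Groups are compared per
amplicon with one-way ANOVA and Tukey's HSD (statsmodels); the ANOVA p is
cross-checked against a permutation test in the suite.

## Phenotype endpoints

* **OGTT AUC**: trapezoidal integral over the measured span (glucose at 0,
  15, 30, 60 and 120 min; mmol/L·min). Total area is the primary output;
  the incremental area above the fasting baseline is emitted alongside
  since conventions differ.
* **HOMA-IR** = fasting insulin × fasting glucose / 22.5, units taken as
  given.
* **Relative expression**: 2^−ΔΔCt with ΔCt = Ct_target − Ct_reference
  (reference Gapdh) and ΔΔCt relative to the mean ΔCt of the control
  group; amplification efficiency assumed 100%.
* **Group statistics**: Student's t-test for two groups; one-way ANOVA with
  Tukey's HSD for three; summaries as mean ± SEM.

## Synthetic data

The generators define the study conditions:

* **Array** (`simulate_probe_array`): 500 promoters (a desk-scale stand-in
  for a 22,327-promoter commercial design) on 19 chromosomes, TSS 100 kb
  apart, probes of 60 bp every 100 bp across a [−1300, +500) window — 18
  probes per promoter. 20% of promoters carry a methylated baseline
  (log2 ratio 1.0) and the rest 0.0; values are baseline + group effect +
  i.i.d. Gaussian noise (SD 0.3). Planted DMRs are centred 8-probe blocks:
  20 hypermethylated (on unmethylated promoters — a gain needs headroom)
  and 20 hypomethylated (on methylated promoters — a loss needs something
  to lose; the DEP filter's 0.3-median criterion could never retain a loss
  from a zero baseline). Truth intervals and directions are emitted as BED.
* **Promoter sequences** (`simulate_promoter_sequences`): class truth comes
  from construction rules, never from the classifier: HCP embeds a 500 bp
  alternating-CG block (ratio 2.0, GC 1.0); LCP is CpG-free A/T sequence;
  ICP tiles a 15-mer with one CpG, five Cs and five Gs, holding every
  window's ratio near 0.6 — between the 0.48 and 0.75 bounds.
* **Clones** (`simulate_clone_matrices`): Bernoulli calls, 10 animals × 10
  clones per group, amplicon CpG counts 6/22/9/31 matching the four
  validated loci, group probabilities echoing their published direction of
  change; optional Beta-distributed animal-level overdispersion.
* **Phenotypes** (`simulate_phenotypes`): group means echo the published
  contrasts (high-fat/control body-weight ratio 1.225, OGTT-AUC ratio
  1.497, intervention group intermediate) with 10% multiplicative
  measurement noise and 0.15-cycle Ct noise, n = 10 per group.

Everything is a pure function of (configuration, seed); noise-free settings
reproduce the configured effects exactly. The simulators deliberately omit
dye bias, spatial artifacts, sequence-dependent MeDIP affinity, bisulfite
conversion failure and qPCR efficiency drift — so green tests demonstrate
the correctness of the computations under the stated noise model, not
robustness to those real-data pathologies.

## Problem sizes and determinism

Default runs use 500 promoters (9000 probes), chosen so a full pipeline run
completes in a few seconds and the entire suite (including a 10-seed null
calibration and a 1000-track peak-caller oracle comparison) in well under a
minute of compute. All randomness in a pipeline run flows from one seed;
reports are byte-identical across repeated runs.

## Known limitations

* The probe p-value is this package's definition, not the vendor's
  undocumented one; published call sets from the original instrument
  software are not expected to be reproduced region-for-region.
* The false-DEP rate discussed above under "Operating characteristics".
* Enrichment uses plain hypergeometric ORA against user-supplied GMT sets;
  no term databases ship with the package.
* HOMA-IR and ΔΔCt take their inputs' units and efficiencies at face
  value.
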