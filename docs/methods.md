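# Methods

This note documents the models behind `sedacomp`, the defaults and why they
were chosen, what the synthetic-data generator does and does not emulate,
and the numerical choices that affect results.

## The taphonomic model

Environmental DNA deposited in sediment is assumed to degrade by two
age-dependent processes:

**Fragmentation.** Fragment lengths follow a geometric distribution
(discrete analogue of the exponential, the standard single-parameter
ancient-DNA fragmentation model) with mean

    λ(age) = max(λ_floor, λ0 · exp(−δ · age/1000)),

default λ0 = 110 bp at age 0, decay δ = 0.14 per kyr and a 35 bp floor.
These values put the mean mapped fragment length below 100 bp over most of
an 8,000-year marine record while leaving a small tail of amplifiable
molecules even in the oldest samples — the regime in which the
metabarcoding/metagenomics contrast is interesting. The fraction of
template spanning an amplicon of length ℓ is P(L ≥ ℓ) = (1 − 1/λ)^(ℓ−1).

**Deamination.** The true damage amplitude grows with age as a saturating
exponential, A(age) = A_max (1 − exp(−k · age/1000)), default A_max = 0.30
and k = 0.35 per kyr, reaching ~0.1 by 400 yr and ~0.28 by 8 kyr. No
published quantitative form exists for amplitude accumulation in marine
sediment; the saturating exponential is a deliberate stand-in that is (a)
zero at age 0, (b) monotone, and (c) bounded, which is all the downstream
authentication logic relies on. Modern contaminants carry amplitude 0 at
every age. Per-read C→T probability at 5′ position x is
A(1 − q)^(x−1) + c with per-position decay q = 0.35 and background
c = 0.01, typical of published damage profiles. 3′ G→A offsets are
generated symmetrically and recorded but not modelled.

## The synthetic record

The default record mirrors the study design the pipeline targets: 11
samples, five younger than 2,000 cal BP and six between 4,200 and 8,200 cal
BP; eight independent PCR replicates per sample plus extraction, PCR and
library negative controls; a variable-length 90–130 bp amplicon. The
community is 28 genera (marine metazoans, marine protists, terrestrial
plants, the marine eelgrass *Zostera*, and modern contaminants), each with
two species under a small NCBI-style taxonomy. Every genus has a Gaussian
abundance optimum along the age axis on top of a constant baseline, so
**true richness is constant while composition turns over smoothly** — the
ground truth against which methodological artifacts are measured.

Detection in a PCR replicate is occupancy-style,
p = 1 − exp(−γ · abundance · amplifiable fraction) with γ = 60, rather than
an explicit PCR-cycle simulation: the quantity the pipeline analyses is
replicate-level presence, and the occupancy form reproduces its stochastic
dropout with one interpretable parameter. Detected taxa receive lognormal
read counts (median 8,000 per detection, σ = 0.7), sized so that young
samples comfortably clear the 20,000-read rarefaction depth while the
oldest samples lose some replicates — the behaviour real records show.
Metagenomic read recovery scales linearly from 0.6× (youngest) to 1.5×
(oldest sample), emulating a short-fragment-optimised extraction that
under-samples the longer template of recent sediments; this is the
mechanism that makes metagenomic genus richness *rise* with age through the
100-read observation threshold.

What the generator does **not** emulate: real sequence content (ASVs are
random nucleotide strings; only length and orientation matter downstream),
sequencing error beyond an identity band, chimeras, primer-template
mismatch bias, reference-database incompleteness, and tag jumping. Passing
tests therefore demonstrate that the pipeline's logic is correct and that
the taphonomic mechanisms are sufficient to produce the documented
artifacts — not that real data are free of additional biases.

## Filter cascade conventions

Stage order is fixed: singleton removal → negative floor → length window →
(rarefaction | CSS). Two readings of the negative-control rule were
possible; this package computes the floor **per ASV** (not a global
maximum), pools all three control types, and compares **strictly** (counts
equal to the floor survive). A config option excludes designated outlier
control replicates (e.g. one grossly contaminated negative) from the floor.
Rarefaction is a seeded multivariate hypergeometric draw (without
replacement); replicates below depth are dropped, and replicates emptied by
the earlier filters are dropped before normalisation. CSS follows the
cumulative-sum-scaling definition: s_j = sum of counts ≤ the chosen
quantile of the replicate's positive counts, normalised value =
count/s_j · median(s); the adaptive mode scans a 0.05-grid for the smallest
quantile at which the median scaling factor becomes unstable (relative
change > 0.1) and falls back to the fixed median otherwise.

ASV taxonomic assignment passes all hits within 1 percentage point of the
best identity to the LCA; this top-band width is a documented convention
(common LCA practice), configurable. The quality screen (best identity
> 0.99 and coverage > 0.95) only flags ASVs, it does not drop them.

## Damage fitting and authentication

The binomial likelihood is maximised by L-BFGS-B from four starts under
bounds A, c ∈ [0, 1], q ∈ [0, 0.99]. The opportunity denominator n_x counts
reads of length ≥ x rather than reference cytosines, because the pipeline
carries no reference sequences; the generator emits offsets under the same
convention, so estimator and generator agree by construction (a documented
divergence from reference-conditioned damage tools). se(A) comes from the
observed information (central-difference Hessian, step 1e−5, inverted);
when A sits on the zero boundary and the Hessian is singular, a binomial
standard error on the position-1 frequency is used instead. z = A/se(A) is
a Wald statistic — the simplest estimator consistent with a "significance
z" reading; at n = 5,000 opportunities per position its spurious-
significance rate under A = 0 measures ≈ 4%, acceptably anti-conservative.

The envelope uses **running-minimum interpolation** over qualifying plant
calibration points (≥ 500 reads, z ≥ 2, both inclusive): conservative, and
monotone by construction even when the underlying plant amplitudes are
noisy. A per-age-bin-minimum variant (`mode="bin_min"`, 1 kyr bins) is
provided because "minimum damage per age" admits both readings. Ages
younger than the earliest calibration point are *unassessable* — with no
young calibration there is no defensible floor, and labelling such
detections not-damaged would conflate "no evidence" with "evidence of
absence". Authentication comparisons are inclusive (≥), so boundary
observations are kept. Non-aquatic taxa (default: *Homo*) are removed
after classification via a config list, not hard-coded.

## Statistics

Permutation p-values use the add-one estimator (1 + #extreme)/(1 + n_perm),
except when n! ≤ n_perm, in which case all permutations are enumerated and
the p-value is exact (the identity permutation keeps it positive). Mantel
vectorises the off-diagonal upper triangle and permutes rows and columns of
the second matrix simultaneously; protest centres and scales both
configurations, rotates by SVD, and counts permutations with m12² ≤
observed. NMDS is SMACOF with monotone (pool-adjacent-violators)
regression, 20 seeded random restarts plus one start at the
principal-coordinates solution, convergence at stress change < 1e−6 or 300
iterations; reported stress is Kruskal stress-1 for both NMDS and the
metric embedding so the two are comparable. Ordination dimensionality
defaults to 2. The metabarcoding abundance convention for dissimilarities
is positive-replicate counts, the metagenomic convention read counts, both
standardised to relative frequencies.

## Problem sizes

Default runs use 20,000 metagenomic reads per sample (scaled by the
recovery gradient) — enough that abundant genera clear the 500-read
calibration floor and rare genera straddle the 100-read observation
threshold, at a few seconds per record. The test suite's calibration study
uses 500 null datasets at 99 permutations per test (the add-one estimator
makes the nominal 0.05 level exact at 99 permutations), and the recovery
study 50 replicate fits per amplitude at 5,000 opportunities per position.

## Known limitations

* The age–amplitude law is a stand-in; absolute authenticated fractions on
  synthetic records should not be read as field predictions.
* The Wald z is anti-conservative near the A = 0 boundary; a spuriously
  significant young plant fit can extend the envelope to younger ages than
  a likelihood-ratio test would.
* Damage is fitted on 5′ C→T only; the mirrored 3′ G→A channel is emitted
  but unused.
* With few qualifying plant observations the envelope degrades exactly as
  it would on real offshore or high-latitude records — this is reported
  (warning + unassessable statuses), not repaired.
* `run_pipeline` orchestrates the synthetic comparison; user-supplied data
  enter through the per-stage CLI subcommands and library functions.
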