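# sedacomp

Comparison pipeline for the two dominant ways of reading biodiversity out of
**sedimentary ancient DNA (sedaDNA)**: metabarcoding (PCR amplification of a
short taxonomic marker across the community) and shotgun metagenomics
(untargeted sequencing of the total DNA pool, classified against reference
taxa). The two methods sit on opposite sides of a taphonomic trade-off: PCR
needs intact template spanning the whole amplicon, so detection decays as
DNA fragments with age, while short-read classification keeps working on the
heavily fragmented molecules that dominate old sediments. `sedacomp`
implements both analysis arms, a damage-based authentication model, the
statistics used to compare the arms, and a ground-truthed synthetic record
generator so that every stage is testable end to end without external
databases or sequencing data.

It is aimed at researchers analysing marine or lacustrine sediment-core eDNA
who want a tested, scriptable version of the standard processing cascade —
and at methodologists who want to study how taphonomic bias distorts
diversity metrics under known ground truth.

## What it computes

**Metabarcoding arm** (`sedacomp.mbfilter`). From ASV-by-PCR-replicate count
tables: orientation merging (reverse-complement and sum identical
sequences), removal of single-read observations, a per-ASV negative-control
floor (the maximum count of that ASV across extraction/PCR/library
negatives; experimental observations strictly below it are zeroed), an
amplicon length window (75–150 bp by default), then rarefaction to a fixed
depth (20,000) and/or cumulative sum scaling. ASVs are assigned taxa by
lowest common ancestor (LCA) over near-best reference hits, and per-sample
detections are summarised as the number of positive PCR replicates out of 8.

**Metagenomic arm** (`sedacomp.mgprofile`). From per-read hit tables:
similarity-band filtering (identity 0.95–1.00), per-read LCA classification,
genus-level roll-up with a 100-read observation threshold, and per-genus
tallies of C→T mismatches by 5′ read position.

**Damage authentication** (`sedacomp.damage`). Post-mortem cytosine
deamination is read as C→T substitutions concentrated at fragment ends.
Per (genus, sample) observation the position-x mismatch count is modelled as

    k_x ~ Binomial(n_x, A (1 − q)^(x−1) + c)

with amplitude `A`, per-position decay `q` and background `c`, fitted by
maximum likelihood; `z = A / se(A)` is a Wald significance statistic.
Terrestrial plant taxa (Viridiplantae, excluding the marine eelgrass
*Zostera*) with ≥ 500 reads and z ≥ 2 calibrate a **minimum expected
amplitude per age** (a running-minimum envelope); an observation is
authenticated *ancient* when its amplitude is significant and reaches the
envelope at its sample's age.

**Comparison statistics** (`sedacomp.diversity`). Richness series and their
least-squares regression, Bray–Curtis and Jaccard dissimilarities on
relative frequencies, metric and non-metric multidimensional scaling,
Procrustes superimposition with permutation significance (protest), and the
Mantel test (10,000 permutations by default).

## Worked example

```python
from sedacomp import PipelineConfig, run_pipeline

result = run_pipeline(PipelineConfig(), seed=1)

reg = result.statistics["richness_regression"]
print(f"metabarcoding richness vs age: slope {reg['metabarcoding_vs_age']['slope']:.4f} ASVs/yr "
      f"(r = {reg['metabarcoding_vs_age']['r']:.2f}, p = {reg['metabarcoding_vs_age']['p']:.2g})")
print(f"metagenomics richness vs age:  slope {reg['metagenomics_vs_age']['slope']:.4f} genera/yr "
      f"(r = {reg['metagenomics_vs_age']['r']:.2f}, p = {reg['metagenomics_vs_age']['p']:.2g})")
m = result.statistics["mantel_full"]
print(f"Mantel (all taxa):             r = {m['r']:.2f}, p = {m['p']:.2g}")
cl = result.classifications
print(f"authenticated ancient:         {(cl['status'] == 'ancient').sum()} of {len(cl)} observations")
```

prints

```
metabarcoding richness vs age: slope -0.0012 ASVs/yr (r = -0.87, p = 0.00042)
metagenomics richness vs age:  slope 0.0007 genera/yr (r = 0.88, p = 0.00039)
Mantel (all taxa):             r = 0.43, p = 0.0001
authenticated ancient:         195 of 210 observations
```

The simulated record holds **true richness constant** across all 11 samples
— every genus is present in every sample — yet the metabarcoding arm loses
about 1.2 ASVs per thousand years of sample age (old DNA is too fragmented
to amplify), while the metagenomic arm gains genera with age (the
ancient-DNA-optimised extraction recovers more short template). The two
richness series are strongly *negatively* related even though nothing
biological changed: a purely methodological artifact. Beta diversity is more
robust: the Mantel correlation between the arms' Bray–Curtis matrices stays
significantly positive because both arms track the same underlying community
turnover. Most metagenomic observations authenticate as ancient; the
youngest samples fail authentication because damage has not yet accumulated
there.

The same run is available from the shell:

```bash
sedacomp run --seed 1 --outdir report/
```

which writes all intermediate tables (TSV), the age–damage envelope (JSON),
the Figure-style detection matrix, the statistics bundle and a per-stage
audit log. Subcommands `simulate`, `filter-mb`, `profile-mg`, `damage` and
`diversity` expose each stage individually for user-supplied files.

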