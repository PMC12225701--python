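"""Synthetic sedimentary-ancient-DNA record generator.

Generates complete, ground-truthed sedaDNA datasets for both sequencing arms:

* a *true record* — per-sample community composition along an age gradient,
  per-sample fragment-length and deamination-damage parameters;
* a *metabarcoding* emission — ASV-by-PCR-replicate count tables (in two read
  orientations) with negative controls, contaminants and injected singletons;
* a *metagenomic* emission — a per-read hit table with identities, fragment
  lengths and C->T / G->A mismatch offsets.

The taphonomic model: DNA fragments to a geometric length distribution whose
mean shrinks with sediment age, so the fraction of template molecules longer
than the amplicon declines with age and PCR detection becomes patchy in old
samples, while short-read metagenomic classification is unaffected.
Cytosine deamination accumulates with age, giving authentic taxa an excess
C->T frequency at fragment ends that decays geometrically along the read;
modern contaminants carry only the background mismatch rate.

Defaults describe an 11-sample marine record spanning roughly 8000 calibrated
years BP (5 samples younger than 2000 BP, 6 between 4000 and 8500 BP), eight
independent PCR replicates per sample, and a 90-130 bp variable-length
eukaryotic amplicon.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .mbfilter import ReplicateTable
from .taxonomy import Taxon, TaxonomyTree

__all__ = [
    "TaxonSpec",
    "SimulationConfig",
    "TrueRecord",
    "MetabarcodingSim",
    "default_taxonomy",
    "default_community",
    "simulate_record",
    "emit_metabarcoding",
    "emit_metagenomics",
    "amplifiable_fraction",
    "detection_probability",
]

SOURCES = ("marine_insitu", "terrestrial_plant", "modern_contaminant")

#: Default sample ages (calibrated years BP): five younger than 2000 BP
#: (industrialisation window) and six between 4000 and 8500 BP (agricultural
#: transition window).
DEFAULT_AGES: tuple[float, ...] = (
    0.0, 400.0, 900.0, 1400.0, 1900.0,
    4200.0, 5000.0, 5800.0, 6600.0, 7400.0, 8200.0,
)


@dataclass
class TaxonSpec:
    """One simulated genus: identity, mean abundance and provenance.

    ``niche_age`` places a Gaussian abundance optimum on the age axis so the
    community turns over smoothly through the record (shared by both arms);
    ``None`` makes the taxon flat across time.
    """

    taxon_id: int
    mean_abundance: float
    source: str
    niche_age: float | None = None
    niche_width: float = 2500.0

    def __post_init__(self):
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}")
        if self.mean_abundance <= 0:
            raise ValueError("mean_abundance must be positive")


@dataclass
class SimulationConfig:
    """All knobs of the synthetic record; defaults are the study conditions.

    Fragment length is geometric with mean lambda(age) = max(lambda_floor,
    lambda0 * exp(-lambda_decay * age_kyr)).  Damage amplitude grows as
    A(age) = a_max * (1 - exp(-k_age * age_kyr)) for in-situ and plant taxa
    and is zero for modern contaminants; per-read C->T probability at 5'
    position x is A * (1-q)**(x-1) + c.
    """

    seed: int = 0
    ages: Sequence[float] = DEFAULT_AGES
    taxa: list[TaxonSpec] | None = None

    # fragmentation
    lambda0: float = 110.0          # mean fragment length (bp) at age 0
    lambda_decay: float = 0.14      # per kyr
    lambda_floor: float = 35.0      # bp

    # deamination
    a_max: float = 0.30
    k_age: float = 0.35             # per kyr
    q: float = 0.35                 # per-position decay of the damage signal
    c: float = 0.01                 # background mismatch rate

    # metabarcoding arm
    amplicon_min: int = 90          # bp, without primers
    amplicon_max: int = 130
    n_pcr_replicates: int = 8
    gamma: float = 60.0             # occupancy scale of PCR detection
    mb_reads_mean: float = 8000.0   # lognormal read count per detection
    mb_reads_sigma: float = 0.7
    singleton_rate: float = 0.01    # spurious count-1 observations per cell
    contamination_rate: float = 0.6  # detection prob of contaminants in negatives
    neg_contam_scale: float = 80.0  # mean contaminant reads in negatives
    include_negative_controls: bool = True

    # metagenomic arm
    mg_reads_per_sample: int = 20000
    mg_recovery_range: tuple[float, float] = (0.6, 1.5)  # young -> old multiplier
    identity_range: tuple[float, float] = (0.90, 1.0)
    ambiguous_hit_fraction: float = 0.2
    max_damage_pos: int = 15
    min_read_length: int = 30       # mapper floor
    decouple_metazoans: bool = False

    def __post_init__(self):
        ages = np.asarray(self.ages, dtype=float)
        if ages.ndim != 1 or len(ages) < 2:
            raise ValueError("need at least two sample ages")
        if not np.all(np.diff(ages) > 0):
            raise ValueError("ages must be strictly increasing")
        for name in ("q", "c", "a_max", "singleton_rate", "ambiguous_hit_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.a_max + self.c > 1:
            raise ValueError("a_max + c must not exceed 1")
        if self.lambda0 <= 0 or self.lambda_floor <= 0:
            raise ValueError("fragment-length means must be positive")
        if not 30 <= self.amplicon_min <= self.amplicon_max:
            raise ValueError("invalid amplicon length bounds")

    @property
    def n_samples(self) -> int:
        return len(self.ages)


# -- default synthetic taxonomy & community --------------------------------

_CLADES = [
    # (taxid, parent, rank, name)
    (1, 1, "no rank", "root"),
    (2, 1, "superkingdom", "Eukaryota"),
    (3, 1, "superkingdom", "Bacteria"),
    (10, 2, "kingdom", "Metazoa"),
    (11, 2, "kingdom", "Viridiplantae"),
    (12, 2, "clade", "Sar"),
    (13, 10, "phylum", "Chordata"),
    (14, 10, "phylum", "Mollusca"),
    (15, 10, "phylum", "Arthropoda"),
    (16, 11, "phylum", "Streptophyta"),
    (17, 12, "phylum", "Bacillariophyta"),
    (18, 12, "phylum", "Dinoflagellata"),
    (19, 3, "phylum", "Pseudomonadota"),
    (20, 13, "no rank", "Tunicata"),
]

# genus name -> (genus taxid, parent clade taxid, source, mean abundance, niche age)
_GENERA: list[tuple[str, int, int, str, float, float | None]] = [
    # marine metazoans (Figure-2-style overlap taxa first)
    ("Oikopleura", 100, 20, "marine_insitu", 0.020, 6000.0),
    ("Gadus", 110, 13, "marine_insitu", 0.018, 2000.0),
    ("Clupea", 120, 13, "marine_insitu", 0.022, 4500.0),
    ("Pleuronectes", 130, 13, "marine_insitu", 0.004, 1000.0),
    ("Limanda", 140, 13, "marine_insitu", 0.004, 7500.0),
    ("Mytilus", 150, 14, "marine_insitu", 0.012, 3000.0),
    ("Ostrea", 160, 14, "marine_insitu", 0.005, 6500.0),
    ("Calanus", 170, 15, "marine_insitu", 0.025, 5000.0),
    # marine protists (bulk of the eukaryotic community)
    ("Thalassiosira", 200, 17, "marine_insitu", 0.090, 1500.0),
    ("Chaetoceros", 210, 17, "marine_insitu", 0.080, 3500.0),
    ("Skeletonema", 220, 17, "marine_insitu", 0.070, 5500.0),
    ("Pseudonitzschia", 230, 17, "marine_insitu", 0.050, 7000.0),
    ("Fragilariopsis", 240, 17, "marine_insitu", 0.0045, 8000.0),
    ("Alexandrium", 250, 18, "marine_insitu", 0.060, 800.0),
    ("Dinophysis", 260, 18, "marine_insitu", 0.055, 2500.0),
    ("Tripos", 270, 18, "marine_insitu", 0.045, 4000.0),
    ("Gyrodinium", 280, 18, "marine_insitu", 0.0050, 300.0),
    ("Protoperidinium", 290, 18, "marine_insitu", 0.0040, 6200.0),
    # terrestrial plants (damage-calibration clade)
    ("Quercus", 300, 16, "terrestrial_plant", 0.060, 2000.0),
    ("Betula", 310, 16, "terrestrial_plant", 0.065, 7000.0),
    ("Pinus", 320, 16, "terrestrial_plant", 0.070, 4500.0),
    ("Alnus", 330, 16, "terrestrial_plant", 0.055, 5500.0),
    ("Corylus", 340, 16, "terrestrial_plant", 0.050, 6500.0),
    ("Salix", 350, 16, "terrestrial_plant", 0.045, 1000.0),
    # marine eelgrass: a plant, but excluded from damage calibration
    ("Zostera", 360, 16, "marine_insitu", 0.030, 3000.0),
    # modern contaminants
    ("Homo", 400, 13, "modern_contaminant", 0.002, None),
    ("Mesorhizobium", 410, 19, "modern_contaminant", 0.002, None),
    ("Bradyrhizobium", 420, 19, "modern_contaminant", 0.002, None),
]


def default_taxonomy() -> TaxonomyTree:
    """The synthetic taxonomy backing the default community: a small tree
    with real genus names, two species per genus, and a few unranked
    intermediate nodes (as NCBI trees have)."""
    taxa = [Taxon(*row) for row in _CLADES]
    for name, taxid, parent, _src, _ab, _niche in _GENERA:
        taxa.append(Taxon(taxid, parent, "genus", name))
        for k in (1, 2):
            taxa.append(Taxon(taxid + k, taxid, "species", f"{name} sp{k}"))
    return TaxonomyTree(taxa)


def default_community() -> list[TaxonSpec]:
    return [
        TaxonSpec(taxid, abundance, source, niche)
        for _name, taxid, _parent, source, abundance, niche in _GENERA
    ]


# -- ground truth ----------------------------------------------------------


@dataclass
class TrueRecord:
    """Ground truth for one simulated record.

    ``composition``: samples x genera relative abundances (rows sum to 1).
    ``a_true``: samples x genera true damage amplitude.
    ``lam``: per-sample mean fragment length (bp).
    ``taxa``: per-genus metadata (source, amplicon length, clade flags).
    """

    sample_ids: list[str]
    ages: np.ndarray
    composition: pd.DataFrame
    a_true: pd.DataFrame
    lam: pd.Series
    taxa: pd.DataFrame
    config: SimulationConfig

    def to_json(self) -> dict:
        return {
            "sample_ids": self.sample_ids,
            "ages": self.ages.tolist(),
            "composition": self.composition.to_dict(),
            "a_true": self.a_true.to_dict(),
            "lam": self.lam.to_dict(),
            "taxa": self.taxa.to_dict(),
        }


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # independent deterministic streams per emitter
    return np.random.default_rng(np.random.SeedSequence((config.seed, stream)))


def mean_fragment_length(config: SimulationConfig, age: float) -> float:
    return max(config.lambda_floor,
               config.lambda0 * np.exp(-config.lambda_decay * age / 1000.0))


def true_amplitude(config: SimulationConfig, age: float, source: str) -> float:
    if source == "modern_contaminant":
        return 0.0
    return config.a_max * (1.0 - np.exp(-config.k_age * age / 1000.0))


def amplifiable_fraction(lam: float, amplicon_length: int) -> float:
    """P(fragment length >= amplicon length) under a geometric length
    distribution (support 1, 2, ...) with mean ``lam``."""
    p = 1.0 / lam
    return (1.0 - p) ** (amplicon_length - 1)


def detection_probability(gamma: float, abundance: float, amp_frac: float) -> float:
    """Per-PCR-replicate occupancy probability 1 - exp(-gamma * x * f)."""
    return 1.0 - np.exp(-gamma * abundance * amp_frac)


def simulate_record(config: SimulationConfig,
                    tree: TaxonomyTree | None = None) -> TrueRecord:
    """Draw the ground truth: compositions along the age gradient, per-sample
    fragmentation, per-taxon damage amplitudes and amplicon lengths."""
    tree = tree or default_taxonomy()
    taxa = config.taxa if config.taxa is not None else default_community()
    rng = _rng(config, 0)
    ages = np.asarray(config.ages, dtype=float)
    sample_ids = [f"S{i + 1:02d}" for i in range(len(ages))]
    taxon_ids = [t.taxon_id for t in taxa]

    weights = np.empty((len(ages), len(taxa)))
    for j, t in enumerate(taxa):
        if t.niche_age is None:
            weights[:, j] = t.mean_abundance
        else:
            niche = np.exp(-0.5 * ((ages - t.niche_age) / t.niche_width) ** 2)
            # baseline keeps every taxon present in every sample: constant
            # true richness, varying relative abundance (turnover)
            weights[:, j] = t.mean_abundance * (0.30 + niche)
    composition = pd.DataFrame(
        weights / weights.sum(axis=1, keepdims=True),
        index=sample_ids, columns=taxon_ids,
    )

    a_true = pd.DataFrame(
        [[true_amplitude(config, a, t.source) for t in taxa] for a in ages],
        index=sample_ids, columns=taxon_ids,
    )
    lam = pd.Series([mean_fragment_length(config, a) for a in ages],
                    index=sample_ids, name="lam")

    metazoa = tree.find("Metazoa")
    plants = tree.find("Viridiplantae")
    taxa_meta = pd.DataFrame(
        {
            "source": [t.source for t in taxa],
            "mean_abundance": [t.mean_abundance for t in taxa],
            "amplicon_len": rng.integers(config.amplicon_min,
                                         config.amplicon_max + 1, len(taxa)),
            "is_metazoan": [tree.descends_from(i, metazoa) for i in taxon_ids],
            "is_plant": [tree.descends_from(i, plants) for i in taxon_ids],
            "name": [tree.name(i) for i in taxon_ids],
        },
        index=taxon_ids,
    )
    return TrueRecord(sample_ids, ages, composition, a_true, lam, taxa_meta, config)


# -- metabarcoding emission -------------------------------------------------


@dataclass
class MetabarcodingSim:
    """Raw metabarcoding output in two read orientations, plus the ASV
    candidate hits used for taxonomic assignment and the true ASV->genus map."""

    forward: ReplicateTable
    reverse: ReplicateTable
    asv_hits: pd.DataFrame   # asv_id, taxon_id (species), identity, coverage
    asv_truth: pd.DataFrame  # asv_id -> genus taxon_id, source


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def emit_metabarcoding(record: TrueRecord,
                       config: SimulationConfig | None = None) -> MetabarcodingSim:
    """Emit ASV-by-replicate count tables with negative controls.

    Per taxon and sample, the amplifiable fraction is P(fragment >= amplicon)
    under the sample's geometric length distribution; each PCR replicate then
    detects the taxon with occupancy probability
    1 - exp(-gamma * abundance * amplifiable); detections receive lognormal
    read counts.  Negative controls carry sparse contaminant counts.  Every
    third taxon is emitted in both read orientations (counts split
    binomially) to exercise orientation merging, and spurious count-1
    observations are injected at ``singleton_rate``.
    """
    config = config or record.config
    rng = _rng(config, 1)
    taxon_ids = list(record.composition.columns)
    n_taxa = len(taxon_ids)

    # ASV sequences: random nucleotides at the taxon's amplicon length
    seqs = {}
    asv_ids = {}
    for j, tid in enumerate(taxon_ids):
        length = int(record.taxa.loc[tid, "amplicon_len"])
        seqs[tid] = "".join(rng.choice(list("ACGT"), size=length))
        asv_ids[tid] = f"ASV{j + 1:04d}"

    sample_reps = [(f"{s}.r{k + 1}", s, "sample")
                   for s in record.sample_ids
                   for k in range(config.n_pcr_replicates)]
    neg_reps = (
        [(f"NEGE.r{k + 1}", "NEGE", "extraction_negative")
         for k in range(config.n_pcr_replicates)]
        + [("NEGP.r1", "NEGP", "pcr_negative"), ("NEGP.r2", "NEGP", "pcr_negative")]
        + [("NEGL.r1", "NEGL", "library_negative")]
    ) if config.include_negative_controls else []
    all_reps = sample_reps + neg_reps
    rep_ids = [r[0] for r in all_reps]
    replicates = pd.DataFrame(
        {"sample": [r[1] for r in all_reps], "role": [r[2] for r in all_reps]},
        index=pd.Index(rep_ids, name="replicate"),
    )

    counts = np.zeros((n_taxa, len(rep_ids)), dtype=np.int64)
    contaminant = record.taxa["source"].values == "modern_contaminant"

    col = 0
    for s in record.sample_ids:
        lam = record.lam[s]
        comp = record.composition.loc[s].values
        amp = np.array([
            amplifiable_fraction(lam, int(record.taxa.loc[t, "amplicon_len"]))
            for t in taxon_ids
        ])
        p_det = 1.0 - np.exp(-config.gamma * comp * amp)
        for _k in range(config.n_pcr_replicates):
            detected = rng.random(n_taxa) < p_det
            n_det = int(detected.sum())
            if n_det:
                reads = rng.lognormal(np.log(config.mb_reads_mean),
                                      config.mb_reads_sigma, n_det)
                counts[detected, col] = np.maximum(2, np.round(reads)).astype(np.int64)
            col += 1

    # negative controls: contaminants only (sparse)
    for j in range(len(neg_reps)):
        hit = contaminant & (rng.random(n_taxa) < config.contamination_rate)
        counts[hit, col + j] = rng.poisson(config.neg_contam_scale, int(hit.sum())) + 1
    # contaminants also leak weakly into experimental replicates, below the
    # negative floor most of the time
    leak = contaminant[:, None] & (rng.random((n_taxa, col)) < 0.3)
    counts[:, :col][leak] = rng.poisson(config.neg_contam_scale * 0.3, int(leak.sum())) + 1

    # spurious singletons
    zeros = counts == 0
    counts[zeros & (rng.random(counts.shape) < config.singleton_rate)] = 1

    # orientation split: every third taxon appears in both orientations
    both = np.zeros(n_taxa, dtype=bool)
    both[::3] = True
    fwd_counts = counts.copy()
    rev_counts = np.zeros_like(counts)
    split = rng.binomial(counts[both], 0.5)
    fwd_counts[both] = split
    rev_counts[both] = counts[both] - split

    asv_index = pd.Index([asv_ids[t] for t in taxon_ids], name="asv")
    forward = ReplicateTable(
        counts=pd.DataFrame(fwd_counts, index=asv_index, columns=rep_ids),
        replicates=replicates,
        sequences=pd.Series({asv_ids[t]: seqs[t] for t in taxon_ids}, name="sequence"),
    )
    rev_index = pd.Index([asv_ids[t] + ".rev" for t in np.array(taxon_ids)[both]],
                         name="asv")
    reverse = ReplicateTable(
        counts=pd.DataFrame(rev_counts[both], index=rev_index, columns=rep_ids),
        replicates=replicates.copy(),
        sequences=pd.Series(
            {asv_ids[t] + ".rev": _revcomp(seqs[t])
             for t in np.array(taxon_ids)[both]},
            name="sequence",
        ),
    )

    # candidate reference hits per ASV: one or both species of the true genus
    hit_rows = []
    for tid in taxon_ids:
        ident = rng.uniform(0.995, 1.0)
        cover = rng.uniform(0.96, 1.0)
        ambiguous = rng.random() < config.ambiguous_hit_fraction
        species = [tid + 1, tid + 2] if ambiguous else [tid + int(rng.integers(1, 3))]
        for sp in species:
            hit_rows.append((asv_ids[tid], sp, ident, cover))
    asv_hits = pd.DataFrame(hit_rows, columns=["asv", "taxon_id", "identity", "coverage"])

    asv_truth = pd.DataFrame(
        {
            "taxon_id": taxon_ids,
            "source": record.taxa["source"].values,
            "is_metazoan": record.taxa["is_metazoan"].values,
        },
        index=asv_index,
    )
    return MetabarcodingSim(forward, reverse, asv_hits, asv_truth)


# -- metagenomic emission ----------------------------------------------------


def emit_metagenomics(record: TrueRecord,
                      config: SimulationConfig | None = None) -> pd.DataFrame:
    """Emit the per-read hit table for the shotgun arm.

    Reads are multinomially assigned to genera by (possibly decoupled)
    composition; each read draws a geometric fragment length (floored at the
    mapper minimum), an identity in the configured band, and C->T / G->A
    mismatch offsets at position x with probability A_true*(1-q)**(x-1) + c.
    A configurable fraction of reads hits both species of its genus
    (exercising per-read LCA); the rest hit a single species.

    Read recovery scales linearly with age (``mg_recovery_range``): the
    ancient-DNA-optimised extraction enriches short fragments, so older
    samples yield more classifiable template.
    """
    config = config or record.config
    rng = _rng(config, 2)
    taxon_ids = np.array(record.composition.columns)
    ages = record.ages
    comp = record.composition.copy()

    if config.decouple_metazoans:
        # break the age alignment of the metazoan sub-community in this arm
        metazoan = record.taxa["is_metazoan"].values.astype(bool)
        perm = rng.permutation(len(comp))
        shuffled = comp.values.copy()
        shuffled[:, metazoan] = comp.values[perm][:, metazoan]
        comp = pd.DataFrame(shuffled / shuffled.sum(axis=1, keepdims=True),
                            index=comp.index, columns=comp.columns)

    lo, hi = config.mg_recovery_range
    span = ages.max() - ages.min()
    recovery = lo + (hi - lo) * (ages - ages.min()) / span

    q, c = config.q, config.c
    max_pos = config.max_damage_pos
    pos = np.arange(1, max_pos + 1)

    frames = []
    for i, s in enumerate(record.sample_ids):
        n_reads = int(round(config.mg_reads_per_sample * recovery[i]))
        n_per_taxon = rng.multinomial(n_reads, comp.loc[s].values)
        lam = record.lam[s]
        for tid, n_t in zip(taxon_ids, n_per_taxon):
            if n_t == 0:
                continue
            a = record.a_true.loc[s, tid]
            lengths = np.maximum(config.min_read_length,
                                 rng.geometric(1.0 / lam, n_t))
            ident = rng.uniform(*config.identity_range, n_t)
            p_x = a * (1.0 - q) ** (pos - 1) + c
            ct = rng.random((n_t, max_pos)) < p_x
            ga = rng.random((n_t, max_pos)) < p_x
            within = pos[None, :] <= lengths[:, None]
            ct &= within
            ga &= within
            ct_str = [",".join(map(str, pos[row])) for row in ct]
            ga_str = [",".join(map(str, pos[row])) for row in ga]
            ambiguous = rng.random(n_t) < config.ambiguous_hit_fraction
            species = tid + rng.integers(1, 3, n_t)
            frames.append(pd.DataFrame({
                "read_id": [f"{s}:{tid}:{k}" for k in range(n_t)],
                "sample": s,
                "taxon_id": species,
                "identity": ident,
                "read_length": lengths,
                "ct_offsets": ct_str,
                "ga_offsets": ga_str,
                "_ambiguous": ambiguous,
                "_sister": np.where(species == tid + 1, tid + 2, tid + 1),
            }))
    hits = pd.concat(frames, ignore_index=True)
    extra = hits[hits["_ambiguous"]].copy()
    extra["taxon_id"] = extra["_sister"]
    hits = pd.concat([hits, extra], ignore_index=True)
    hits = hits.drop(columns=["_ambiguous", "_sister"])
    hits = hits.sort_values(["sample", "read_id", "taxon_id"],
                            kind="mergesort").reset_index(drop=True)
    return hits


def write_hit_table(hits: pd.DataFrame, path) -> None:
    hits.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_hit_table(path) -> pd.DataFrame:
    hits = pd.read_csv(path, sep="\t", dtype={"ct_offsets": str, "ga_offsets": str})
    hits["ct_offsets"] = hits["ct_offsets"].fillna("")
    hits["ga_offsets"] = hits["ga_offsets"].fillna("")
    return hits
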