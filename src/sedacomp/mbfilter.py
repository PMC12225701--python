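"""Metabarcoding post-denoising filter cascade.

Starting from raw ASV-by-PCR-replicate count tables (one per read
orientation), the cascade is, in order:

1. ``merge_orientations`` — reverse-complement one orientation and sum ASVs
   with identical sequence;
2. ``remove_singletons`` — any single-read observation (one read of an ASV in
   one replicate) is set to zero;
3. ``negative_floor_filter`` — for each ASV, the maximum count observed in
   any negative-control replicate (extraction, PCR or library negative) is a
   conservative false-positive floor; experimental observations strictly
   below it are zeroed;
4. ``length_filter`` — ASVs outside the marker's plausible length window are
   non-target amplification and are dropped;
5. either ``rarefy`` (subsample replicates without replacement to a fixed
   depth, dropping shallower replicates) or ``css_normalize`` (cumulative sum
   scaling) for cross-replicate comparability.

``assign_asvs`` gives each ASV a taxon by lowest-common-ancestor over its
near-best reference hits, and ``positive_replicates`` collapses replicate
detections into the per-sample occupancy counts used as the metabarcoding
abundance proxy downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .taxonomy import TaxonomyTree

__all__ = [
    "ReplicateTable",
    "CssResult",
    "merge_orientations",
    "remove_singletons",
    "negative_floor_filter",
    "length_filter",
    "rarefy",
    "css_normalize",
    "assign_asvs",
    "positive_replicates",
]

ROLES = ("sample", "extraction_negative", "pcr_negative", "library_negative")
NEGATIVE_ROLES = ROLES[1:]


@dataclass
class ReplicateTable:
    """ASV x replicate counts with replicate roles and ASV sequences.

    ``counts``: integer DataFrame, rows = ASV ids, columns = replicate ids.
    ``replicates``: DataFrame indexed by replicate id with columns ``sample``
    and ``role`` (one of sample / extraction_negative / pcr_negative /
    library_negative).
    ``sequences``: ASV id -> nucleotide sequence (lengths drive the length
    filter).
    """

    counts: pd.DataFrame
    replicates: pd.DataFrame
    sequences: pd.Series

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.replicates.index)
        if missing:
            raise ValueError(f"replicates without metadata: {sorted(missing)}")
        bad = set(self.replicates["role"]) - set(ROLES)
        if bad:
            raise ValueError(f"unknown replicate roles: {sorted(bad)}")
        no_seq = set(self.counts.index) - set(self.sequences.index)
        if no_seq:
            raise ValueError(f"ASVs without sequence: {sorted(no_seq)[:5]}")

    @property
    def lengths(self) -> pd.Series:
        return self.sequences.loc[self.counts.index].str.len()

    def total(self) -> int:
        return int(self.counts.values.sum())

    def sample_columns(self) -> list[str]:
        roles = self.replicates.loc[self.counts.columns, "role"]
        return [c for c in self.counts.columns if roles[c] == "sample"]

    def negative_columns(self) -> list[str]:
        roles = self.replicates.loc[self.counts.columns, "role"]
        return [c for c in self.counts.columns if roles[c] != "sample"]

    # -- IO (plain TSV / FASTA) ---------------------------------------

    def write(self, outdir: str | Path, prefix: str = "replicate_table") -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.counts.to_csv(outdir / f"{prefix}.tsv", sep="\t")
        self.replicates.to_csv(outdir / f"{prefix}.replicates.tsv", sep="\t")
        with open(outdir / f"{prefix}.fasta", "w") as fh:
            for asv in self.counts.index:
                fh.write(f">{asv}\n{self.sequences[asv]}\n")

    @classmethod
    def read(cls, outdir: str | Path, prefix: str = "replicate_table") -> "ReplicateTable":
        from Bio import SeqIO

        outdir = Path(outdir)
        counts = pd.read_csv(outdir / f"{prefix}.tsv", sep="\t", index_col=0)
        reps = pd.read_csv(outdir / f"{prefix}.replicates.tsv", sep="\t", index_col=0)
        seqs = pd.Series(
            {rec.id: str(rec.seq)
             for rec in SeqIO.parse(outdir / f"{prefix}.fasta", "fasta")},
            name="sequence",
        )
        return cls(counts, reps, seqs)


def merge_orientations(forward: ReplicateTable,
                       reverse: ReplicateTable) -> ReplicateTable:
    """Merge the two read orientations of one library.

    Reverse-orientation sequences are reverse-complemented; ASVs whose
    sequences then match at 100% identity are summed cell-wise, all others
    concatenated.  Total counts are conserved.
    """
    from Bio.Seq import Seq

    if list(forward.counts.columns) != list(reverse.counts.columns):
        if set(forward.counts.columns) != set(reverse.counts.columns):
            raise ValueError("orientation tables have different replicate sets")
        reverse = replace(reverse,
                          counts=reverse.counts[forward.counts.columns])

    rc = reverse.sequences.map(lambda s: str(Seq(s).reverse_complement()))
    seq_to_id = {forward.sequences[a]: a for a in forward.counts.index}

    counts = forward.counts.copy()
    sequences = forward.sequences.copy()
    for asv in reverse.counts.index:
        seq = rc[asv]
        target = seq_to_id.get(seq)
        if target is None:
            seq_to_id[seq] = asv
            counts.loc[asv] = reverse.counts.loc[asv]
            sequences[asv] = seq
        else:
            counts.loc[target] += reverse.counts.loc[asv]
    return ReplicateTable(counts.astype(np.int64), forward.replicates,
                          sequences.loc[counts.index])


def remove_singletons(table: ReplicateTable) -> ReplicateTable:
    """Zero every single-read observation (cell equal to 1)."""
    counts = table.counts.where(table.counts != 1, 0)
    return replace(table, counts=counts)


def negative_floor_filter(table: ReplicateTable,
                          exclude_replicates: list[str] | None = None
                          ) -> ReplicateTable:
    """Apply the per-ASV negative-control floor and drop control columns.

    For each ASV, the threshold is the maximum count across all
    negative-control replicates (all three control types pooled);
    experimental cells strictly below it are zeroed, cells equal to it kept.
    ``exclude_replicates`` removes designated outlier controls (e.g. a
    grossly contaminated negative) from the floor computation.
    """
    neg_cols = [c for c in table.negative_columns()
                if not exclude_replicates or c not in exclude_replicates]
    sample_cols = table.sample_columns()
    if neg_cols:
        floor = table.counts[neg_cols].max(axis=1)
    else:
        floor = pd.Series(0, index=table.counts.index)
    counts = table.counts[sample_cols]
    counts = counts.where(counts.ge(floor, axis=0), 0)
    return ReplicateTable(counts, table.replicates.loc[sample_cols],
                          table.sequences.loc[counts.index])


def length_filter(table: ReplicateTable, min_bp: int = 75,
                  max_bp: int = 150) -> ReplicateTable:
    """Drop ASVs shorter than ``min_bp`` or longer than ``max_bp`` entirely
    (bounds inclusive; the defaults are the 18S marker window)."""
    lengths = table.lengths
    keep = (lengths >= min_bp) & (lengths <= max_bp)
    counts = table.counts.loc[keep.values]
    return replace(table, counts=counts, sequences=table.sequences.loc[counts.index])


def rarefy(table: ReplicateTable, depth: int = 20000,
           seed: int | np.random.Generator = 0) -> ReplicateTable:
    """Subsample every replicate without replacement to exactly ``depth``
    reads; replicates with fewer total reads are dropped."""
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    totals = table.counts.sum(axis=0)
    keep = [c for c in table.counts.columns if totals[c] >= depth]
    out = {}
    for c in keep:
        col = table.counts[c].to_numpy(dtype=np.int64)
        out[c] = rng.multivariate_hypergeometric(col, depth, method="count")
    counts = pd.DataFrame(out, index=table.counts.index, columns=keep)
    return replace(table, counts=counts,
                   replicates=table.replicates.loc[keep])


@dataclass
class CssResult:
    """Cumulative-sum-scaled table: real-valued normalized counts, the
    quantile used, and the per-replicate scaling factors."""

    values: pd.DataFrame
    quantile: float
    scaling: pd.Series


def _css_factor(col: np.ndarray, p: float) -> float:
    positive = col[col > 0]
    if positive.size == 0:
        raise ValueError("replicate with no positive counts")
    threshold = np.quantile(positive, p)
    return float(col[col <= threshold].sum())


def css_normalize(table: ReplicateTable, quantile: str | float = "adaptive",
                  instability_threshold: float = 0.1) -> CssResult:
    """Cumulative sum scaling of a count table.

    Per replicate j the scaling factor s_j is the sum of counts less than or
    equal to the chosen quantile of that replicate's positive counts
    (interpolated); normalized value = count / s_j * median(s).  In adaptive
    mode the quantile is the smallest p on a 0.05 grid at which the relative
    change of the median scaling factor exceeds ``instability_threshold``
    (the point where the cumulative sums stop being stable across
    replicates); if the criterion never triggers, the fixed median (p = 0.5)
    is used.
    """
    cols = {c: table.counts[c].to_numpy(dtype=float) for c in table.counts.columns}
    if quantile == "adaptive":
        grid = np.arange(0.05, 1.0, 0.05)
        med = np.array([np.median([_css_factor(v, p) for v in cols.values()])
                        for p in grid])
        p_used = 0.5
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.abs(np.diff(med)) / np.where(med[:-1] > 0, med[:-1], np.nan)
        unstable = np.nonzero(rel > instability_threshold)[0]
        if unstable.size:
            p_used = float(grid[unstable[0]])
    else:
        p_used = float(quantile)
    s = pd.Series({c: _css_factor(v, p_used) for c, v in cols.items()})
    med_s = float(np.median(s))
    values = table.counts.div(s, axis=1) * med_s
    return CssResult(values, p_used, s)


def assign_asvs(asv_hits: pd.DataFrame, tree: TaxonomyTree,
                band: float = 0.01, min_identity: float = 0.99,
                min_coverage: float = 0.95) -> pd.DataFrame:
    """Assign each ASV the LCA of its near-best reference hits.

    ``asv_hits`` columns: asv, taxon_id, identity, coverage.  Hits with
    identity within ``band`` of the ASV's best hit enter the LCA.  ASVs whose
    best hit fails the quality screen (identity > ``min_identity`` and
    coverage > ``min_coverage``) are flagged low-quality.  Returns a
    DataFrame indexed by ASV with columns taxon_id, best_identity,
    best_coverage, high_quality.
    """
    rows = {}
    for asv, grp in asv_hits.groupby("asv", sort=True):
        best = grp["identity"].max()
        kept = grp[grp["identity"] >= best - band]
        taxon = tree.lca(kept["taxon_id"].tolist())
        rows[asv] = {
            "taxon_id": taxon,
            "best_identity": best,
            "best_coverage": grp["coverage"].max(),
            "high_quality": bool(best > min_identity
                                 and grp["coverage"].max() > min_coverage),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "asv"
    return out


def positive_replicates(table: ReplicateTable) -> pd.DataFrame:
    """Per-sample occupancy: number of that sample's PCR replicates in which
    each ASV has a positive count.  Rows = samples, columns = ASVs."""
    sample_of = table.replicates.loc[table.counts.columns, "sample"]
    positive = (table.counts > 0).T  # replicate x ASV
    out = positive.groupby(sample_of.values).sum()
    out.index.name = "sample"
    return out.astype(np.int64)
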