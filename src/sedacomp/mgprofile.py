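"""Metagenomic read classification and genus-level profiling.

The shotgun arm starts from a per-read hit table (one row per candidate
reference taxon per read, with alignment identity and the 5' C->T / 3' G->A
mismatch offsets).  Processing is:

1. ``filter_hits`` — keep hits inside the similarity band (default
   0.95-1.00, inclusive);
2. ``classify_reads`` — assign each read the lowest common ancestor of its
   surviving hits;
3. ``genus_table`` — roll genus-or-finer assignments up to genus and drop
   (genus, sample) observations below a read-count threshold (default 100,
   below which false-positive rates climb);
4. ``damage_counts`` — per (genus, sample) group, tally C->T mismatches per
   5' position (k_x) against the number of reads long enough to show one
   (n_x), the input of the damage model.

The opportunity denominator n_x counts reads of length >= x rather than
reference cytosines: the pipeline carries no reference sequences, and the
simulator emits offsets under the same per-read convention, keeping
estimator and generator consistent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .taxonomy import TaxonomyTree

__all__ = [
    "filter_hits",
    "classify_reads",
    "genus_table",
    "damage_counts",
    "damage_count_table",
    "GenusProfile",
]


def filter_hits(hits: pd.DataFrame, min_sim: float = 0.95,
                max_sim: float = 1.00) -> pd.DataFrame:
    """Keep hit rows with identity in [min_sim, max_sim] (inclusive band)."""
    if min_sim > max_sim:
        raise ValueError("min_sim must not exceed max_sim")
    keep = (hits["identity"] >= min_sim) & (hits["identity"] <= max_sim)
    return hits[keep].reset_index(drop=True)


def classify_reads(hits: pd.DataFrame, tree: TaxonomyTree) -> pd.DataFrame:
    """Per-read LCA over all surviving hits.

    Returns one row per read: read_id, sample, taxon_id.  Reads whose id
    appears under more than one sample are invalid input.  Reads with no
    surviving hits simply do not appear (they were removed upstream by the
    similarity filter).
    """
    if hits.empty:
        return pd.DataFrame(columns=["read_id", "sample", "taxon_id"])
    samples_per_read = hits.groupby("read_id")["sample"].nunique()
    if (samples_per_read > 1).any():
        bad = samples_per_read[samples_per_read > 1].index[0]
        raise ValueError(f"read id {bad!r} appears in more than one sample")

    # LCA per unique candidate-taxon set, cached: ambiguous reads share a
    # small number of distinct sets
    grouped = hits.groupby("read_id", sort=True).agg(
        sample=("sample", "first"),
        taxa=("taxon_id", lambda t: tuple(sorted(set(t)))),
    )
    cache: dict[tuple, int] = {}
    assigned = [cache.setdefault(key, tree.lca(key)) if key not in cache
                else cache[key]
                for key in grouped["taxa"]]
    out = pd.DataFrame({
        "read_id": grouped.index,
        "sample": grouped["sample"].values,
        "taxon_id": assigned,
    })
    return out.reset_index(drop=True)


@dataclass
class GenusProfile:
    """Genus x sample read counts plus the genus-resolved read assignments
    they were built from (used downstream for damage counting)."""

    counts: pd.DataFrame          # index genus taxon_id, columns sample
    assignments: pd.DataFrame     # read_id, sample, taxon_id, genus
    n_above_genus: int            # reads assigned above genus (discarded)


def genus_table(assignments: pd.DataFrame, tree: TaxonomyTree,
                min_reads: int = 100) -> GenusProfile:
    """Roll read assignments up to genus and threshold observations.

    Reads assigned at genus rank or below contribute to their genus; reads
    assigned above genus are discarded (counted in ``n_above_genus``).
    (genus, sample) cells with fewer than ``min_reads`` reads are removed.
    """
    genus_of: dict[int, int | None] = {}
    for tid in assignments["taxon_id"].unique():
        genus_of[tid] = tree.rank_ancestor(int(tid), "genus")
    asg = assignments.copy()
    asg["genus"] = asg["taxon_id"].map(genus_of)
    n_above = int(asg["genus"].isna().sum())
    asg = asg.dropna(subset=["genus"])
    asg["genus"] = asg["genus"].astype(np.int64)

    counts = (asg.groupby(["genus", "sample"]).size()
              .unstack(fill_value=0))
    counts = counts.where(counts >= min_reads, 0)
    # drop cells below threshold from the read-level view as well
    key = asg.set_index(["genus", "sample"]).index
    kept_cells = counts.stack()
    kept_cells = set(kept_cells[kept_cells > 0].index)
    asg = asg[[k in kept_cells for k in key]]
    counts = counts.loc[(counts.sum(axis=1) > 0)]
    return GenusProfile(counts.astype(np.int64), asg.reset_index(drop=True), n_above)


def _read_level(hits: pd.DataFrame) -> pd.DataFrame:
    """One row per read with its length and offsets (identical across a
    read's hit rows; the first is taken)."""
    return (hits.drop_duplicates("read_id")
            [["read_id", "read_length", "ct_offsets", "ga_offsets"]]
            .set_index("read_id"))


def damage_counts(hits: pd.DataFrame, assignments: pd.DataFrame,
                  genus: int, sample: str,
                  max_pos: int = 15) -> tuple[np.ndarray, np.ndarray]:
    """C->T mismatch tallies for one (genus, sample) group.

    Returns (k, n) arrays over 5' positions x = 1..max_pos where n_x is the
    number of group reads with length >= x and k_x the number carrying a
    C->T offset at x.
    """
    if "genus" not in assignments.columns:
        raise ValueError("assignments must carry a 'genus' column (see genus_table)")
    group = assignments[(assignments["genus"] == genus)
                        & (assignments["sample"] == sample)]
    if group.empty:
        raise ValueError(f"no reads for genus {genus} in sample {sample!r}")
    reads = _read_level(hits).loc[group["read_id"]]
    return _tally(reads, max_pos)


def _tally(reads: pd.DataFrame, max_pos: int) -> tuple[np.ndarray, np.ndarray]:
    lengths = reads["read_length"].to_numpy()
    n = (lengths[:, None] >= np.arange(1, max_pos + 1)[None, :]).sum(axis=0)
    k = np.zeros(max_pos, dtype=np.int64)
    for offsets in reads["ct_offsets"]:
        if not offsets:
            continue
        for x in str(offsets).split(","):
            x = int(x)
            if 1 <= x <= max_pos:
                k[x - 1] += 1
    return k, n


def damage_count_table(hits: pd.DataFrame, profile: GenusProfile,
                       max_pos: int = 15) -> pd.DataFrame:
    """Damage tallies for every (genus, sample) observation of a profile.

    Returns a long DataFrame with columns genus, sample, position, k, n.
    """
    reads = _read_level(hits)
    rows = []
    for (genus, sample), grp in profile.assignments.groupby(["genus", "sample"]):
        k, n = _tally(reads.loc[grp["read_id"]], max_pos)
        for x in range(max_pos):
            rows.append((genus, sample, x + 1, int(k[x]), int(n[x])))
    return pd.DataFrame(rows, columns=["genus", "sample", "position", "k", "n"])
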