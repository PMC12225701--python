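"""Shared fixtures: random taxonomy trees with an independent LCA oracle,
and session-scoped pipeline runs reused across tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from sedacomp import mbfilter as mb
from sedacomp.pipeline import PipelineConfig, run_pipeline
from sedacomp.simulate import SimulationConfig, default_taxonomy
from sedacomp.taxonomy import RANKS, Taxon, TaxonomyTree


def random_tree(rng: np.random.Generator, n_nodes: int) -> TaxonomyTree:
    """Random rooted tree with ids 1..n; parent of node i drawn from 1..i-1."""
    taxa = [Taxon(1, 1, "no rank", "root")]
    for i in range(2, n_nodes + 1):
        parent = int(rng.integers(1, i))
        rank = str(rng.choice(list(RANKS) + ["no rank"]))
        taxa.append(Taxon(i, parent, rank, f"node{i}"))
    return TaxonomyTree(taxa)


def lca_bruteforce(tree: TaxonomyTree, ids) -> int:
    """Independent oracle: intersect root-paths, take the last shared node."""
    paths = [tree.lineage(i) for i in ids]
    shortest = min(len(p) for p in paths)
    last = None
    for depth in range(shortest):
        nodes = {p[depth] for p in paths}
        if len(nodes) == 1:
            last = nodes.pop()
        else:
            break
    return last


def random_replicate_table(rng: np.random.Generator, n_asvs: int = 8,
                           n_samples: int = 3, n_reps: int = 4,
                           n_neg: int = 3, max_count: int = 50,
                           seq_len: int = 100) -> mb.ReplicateTable:
    reps = [(f"S{s}.r{r}", f"S{s}", "sample")
            for s in range(n_samples) for r in range(n_reps)]
    reps += [(f"NEG.r{r}", "NEG", "extraction_negative") for r in range(n_neg)]
    rep_ids = [r[0] for r in reps]
    counts = pd.DataFrame(
        rng.integers(0, max_count, (n_asvs, len(rep_ids))),
        index=pd.Index([f"A{i}" for i in range(n_asvs)], name="asv"),
        columns=rep_ids,
    )
    replicates = pd.DataFrame({"sample": [r[1] for r in reps],
                               "role": [r[2] for r in reps]},
                              index=pd.Index(rep_ids, name="replicate"))
    seqs = pd.Series({f"A{i}": "".join(rng.choice(list("ACGT"), seq_len))
                      for i in range(n_asvs)}, name="sequence")
    return mb.ReplicateTable(counts, replicates, seqs)


@pytest.fixture(scope="session")
def tree_default():
    return default_taxonomy()


@pytest.fixture(scope="session")
def pipeline_default():
    """Full pipeline on the default synthetic record (shared gradients)."""
    cfg = PipelineConfig(sim=SimulationConfig(seed=1),
                         n_perm_mantel=999, n_perm_procrustes=199)
    return run_pipeline(cfg)


@pytest.fixture(scope="session")
def pipeline_decoupled():
    """Same record but with the metazoan sub-community decoupled between
    arms in the metagenomic emission."""
    cfg = PipelineConfig(sim=SimulationConfig(seed=1, decouple_metazoans=True),
                         n_perm_mantel=999, n_perm_procrustes=199)
    return run_pipeline(cfg)
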