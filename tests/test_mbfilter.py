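"""Metabarcoding filter cascade: exact rules, conservation laws and
idempotence."""

import numpy as np
import pandas as pd
import pytest

from conftest import random_replicate_table
from sedacomp import mbfilter as mb


def tiny_table(counts: dict, roles: dict, seqs: dict) -> mb.ReplicateTable:
    rep_ids = list(roles)
    counts_df = pd.DataFrame(counts, index=rep_ids).T
    counts_df.index.name = "asv"
    replicates = pd.DataFrame(
        {"sample": [r.split(".")[0] for r in rep_ids],
         "role": [roles[r] for r in rep_ids]},
        index=pd.Index(rep_ids, name="replicate"))
    return mb.ReplicateTable(counts_df, replicates, pd.Series(seqs, name="sequence"))


class TestMergeOrientations:
    def test_revcomp_pair_is_summed(self):
        f = tiny_table({"X": {"S.r1": 5}}, {"S.r1": "sample"}, {"X": "AAGG"})
        r = tiny_table({"Y": {"S.r1": 3}}, {"S.r1": "sample"}, {"Y": "CCTT"})
        merged = mb.merge_orientations(f, r)
        assert list(merged.counts.index) == ["X"]
        assert merged.counts.loc["X", "S.r1"] == 8

    def test_empty_reverse_is_identity(self):
        f = tiny_table({"X": {"S.r1": 5}}, {"S.r1": "sample"}, {"X": "AAGG"})
        r = tiny_table({}, {"S.r1": "sample"}, {})
        merged = mb.merge_orientations(f, r)
        pd.testing.assert_frame_equal(merged.counts, f.counts)

    def test_distinct_sequences_concatenated(self):
        f = tiny_table({"X": {"S.r1": 5}}, {"S.r1": "sample"}, {"X": "AAGG"})
        r = tiny_table({"Y": {"S.r1": 3}}, {"S.r1": "sample"}, {"Y": "GGGG"})
        merged = mb.merge_orientations(f, r)
        assert merged.counts.values.sum() == 8
        assert len(merged.counts) == 2
        assert merged.sequences["Y"] == "CCCC"  # stored reverse-complemented

    def test_total_counts_conserved_on_random_tables(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            f = random_replicate_table(rng)
            r = random_replicate_table(rng)
            merged = mb.merge_orientations(
                f, mb.ReplicateTable(r.counts.rename(index=lambda a: a + "r"),
                                     r.replicates,
                                     r.sequences.rename(index=lambda a: a + "r")))
            assert merged.total() == f.total() + r.total()

    def test_mismatched_replicates_rejected(self):
        f = tiny_table({"X": {"S.r1": 5}}, {"S.r1": "sample"}, {"X": "AAGG"})
        r = tiny_table({"Y": {"S.r2": 3}}, {"S.r2": "sample"}, {"Y": "CCTT"})
        with pytest.raises(ValueError, match="replicate"):
            mb.merge_orientations(f, r)


def test_remove_singletons_rule():
    t = tiny_table({"X": {"S.r1": 1, "S.r2": 2, "S.r3": 0}},
                   {"S.r1": "sample", "S.r2": "sample", "S.r3": "sample"},
                   {"X": "ACGT"})
    out = mb.remove_singletons(t)
    assert list(out.counts.loc["X"]) == [0, 2, 0]
    # idempotent
    pd.testing.assert_frame_equal(mb.remove_singletons(out).counts, out.counts)


class TestNegativeFloor:
    def test_strict_threshold_per_asv(self):
        roles = {"S.r1": "sample", "S.r2": "sample", "S.r3": "sample",
                 "N.r1": "extraction_negative", "N.r2": "pcr_negative",
                 "N.r3": "library_negative"}
        t = tiny_table({"X": {"S.r1": 2, "S.r2": 3, "S.r3": 10,
                              "N.r1": 0, "N.r2": 3, "N.r3": 1}},
                       roles, {"X": "ACGT"})
        out = mb.negative_floor_filter(t)
        assert list(out.counts.loc["X"]) == [0, 3, 10]  # < 3 zeroed, == 3 kept
        assert out.negative_columns() == []

    def test_no_negatives_passes_through(self):
        t = tiny_table({"X": {"S.r1": 2}}, {"S.r1": "sample"}, {"X": "ACGT"})
        out = mb.negative_floor_filter(t)
        pd.testing.assert_frame_equal(out.counts, t.counts)

    def test_excluded_outlier_control_ignored(self):
        roles = {"S.r1": "sample", "N.r1": "extraction_negative",
                 "N.r2": "extraction_negative"}
        t = tiny_table({"X": {"S.r1": 50, "N.r1": 2, "N.r2": 100000}},
                       roles, {"X": "ACGT"})
        assert mb.negative_floor_filter(t).counts.loc["X", "S.r1"] == 0
        out = mb.negative_floor_filter(t, exclude_replicates=["N.r2"])
        assert out.counts.loc["X", "S.r1"] == 50

    def test_matches_cellwise_oracle_and_commutes_with_reordering(self):
        rng = np.random.default_rng(8)
        t = random_replicate_table(rng, max_count=6)
        out = mb.negative_floor_filter(t)
        neg = t.negative_columns()
        for asv in t.counts.index:
            floor = t.counts.loc[asv, neg].max()
            for rep in t.sample_columns():
                v = t.counts.loc[asv, rep]
                assert out.counts.loc[asv, rep] == (v if v >= floor else 0)
        # permuted rows/columns give the same cell values
        perm = t.counts.sample(frac=1, axis=0, random_state=1).sample(
            frac=1, axis=1, random_state=2)
        t2 = mb.ReplicateTable(perm, t.replicates, t.sequences)
        out2 = mb.negative_floor_filter(t2)
        assert (out2.counts.loc[out.counts.index, out.counts.columns]
                == out.counts).all().all()
        # idempotent
        pd.testing.assert_frame_equal(mb.negative_floor_filter(out).counts,
                                      out.counts)


def test_length_filter_boundaries():
    seqs = {"A74": "A" * 74, "A75": "A" * 75, "A150": "A" * 150, "A151": "A" * 151}
    t = tiny_table({a: {"S.r1": 5} for a in seqs}, {"S.r1": "sample"}, seqs)
    out = mb.length_filter(t, 75, 150)
    assert set(out.counts.index) == {"A75", "A150"}
    pd.testing.assert_frame_equal(mb.length_filter(out, 75, 150).counts, out.counts)


class TestRarefy:
    def test_shallow_replicates_dropped_and_survivors_exact(self):
        t = tiny_table({"X": {"S.r1": 19_999, "S.r2": 15_000},
                        "Y": {"S.r1": 0, "S.r2": 10_000}},
                       {"S.r1": "sample", "S.r2": "sample"},
                       {"X": "ACGT", "Y": "ACGA"})
        out = mb.rarefy(t, depth=20_000, seed=0)
        assert list(out.counts.columns) == ["S.r2"]
        assert out.counts["S.r2"].sum() == 20_000

    def test_single_asv_forced_outcome(self):
        t = tiny_table({"X": {"S.r1": 30_000}}, {"S.r1": "sample"}, {"X": "ACGT"})
        out = mb.rarefy(t, depth=20_000, seed=0)
        assert out.counts.loc["X", "S.r1"] == 20_000

    def test_expected_proportions_within_3se(self):
        counts = np.array([5000, 3000, 2000])
        t = tiny_table({"A": {"S.r1": 5000}, "B": {"S.r1": 3000}, "C": {"S.r1": 2000}},
                       {"S.r1": "sample"},
                       {"A": "AC", "B": "AG", "C": "AT"})
        depth = 1000
        draws = np.array([
            mb.rarefy(t, depth, seed=s).counts["S.r1"].to_numpy()
            for s in range(200)
        ])
        p = counts / counts.sum()
        expect = depth * p
        se = np.sqrt(depth * p * (1 - p) / 200)  # SE of the mean over 200 seeds
        assert (np.abs(draws.mean(axis=0) - expect) < 3.5 * se).all()

    def test_invalid_depth(self):
        t = tiny_table({"X": {"S.r1": 5}}, {"S.r1": "sample"}, {"X": "AC"})
        with pytest.raises(ValueError):
            mb.rarefy(t, depth=0)


class TestCssNormalize:
    def test_hand_computed_scaling_factor(self):
        """Counts [1,2,3,4], p=0.5: interpolated median of positives is 2.5,
        so s = 1 + 2 = 3."""
        t = tiny_table({"A": {"S.r1": 1}, "B": {"S.r1": 2},
                        "C": {"S.r1": 3}, "D": {"S.r1": 4}},
                       {"S.r1": "sample"},
                       {a: "AC" for a in "ABCD"})
        res = mb.css_normalize(t, quantile=0.5)
        assert res.scaling["S.r1"] == 3.0

    def test_identical_replicates_share_scaling(self):
        t = tiny_table({"A": {"S.r1": 2, "S.r2": 2}, "B": {"S.r1": 6, "S.r2": 6}},
                       {"S.r1": "sample", "S.r2": "sample"},
                       {"A": "AC", "B": "AG"})
        res = mb.css_normalize(t, quantile=0.5)
        assert res.scaling["S.r1"] == res.scaling["S.r2"]
        ratio = res.values / t.counts
        assert np.allclose(ratio.values, ratio.values[0, 0])

    def test_scale_invariance_of_doubled_replicate(self):
        rng = np.random.default_rng(4)
        t = random_replicate_table(rng, n_asvs=10, n_samples=2, n_reps=3, n_neg=0,
                                   max_count=30)
        t = mb.ReplicateTable(t.counts + 1, t.replicates, t.sequences)
        doubled = t.counts.copy()
        doubled.iloc[:, 0] *= 2
        t2 = mb.ReplicateTable(doubled, t.replicates, t.sequences)
        r1 = mb.css_normalize(t, quantile=0.5)
        r2 = mb.css_normalize(t2, quantile=0.5)
        col = t.counts.columns[0]
        np.testing.assert_allclose(r1.values[col], r2.values[col])

    def test_all_zero_replicate_rejected(self):
        t = tiny_table({"A": {"S.r1": 0, "S.r2": 3}},
                       {"S.r1": "sample", "S.r2": "sample"},
                       {"A": "AC"})
        with pytest.raises(ValueError, match="positive"):
            mb.css_normalize(t, quantile=0.5)

    def test_adaptive_mode_returns_quantile(self):
        rng = np.random.default_rng(6)
        t = random_replicate_table(rng, n_asvs=40, max_count=200)
        t = mb.ReplicateTable(t.counts + 1, t.replicates, t.sequences)
        res = mb.css_normalize(t, quantile="adaptive")
        assert 0 < res.quantile < 1


class TestAssignAsvs:
    def test_single_hit_and_congeneric_lca(self, tree_default):
        gadus = tree_default.find("Gadus")
        hits = pd.DataFrame({
            "asv": ["X", "Y", "Y"],
            "taxon_id": [gadus + 1, gadus + 1, gadus + 2],
            "identity": [1.0, 0.998, 0.998],
            "coverage": [1.0, 0.99, 0.99],
        })
        out = mb.assign_asvs(hits, tree_default)
        assert out.loc["X", "taxon_id"] == gadus + 1
        assert out.loc["Y", "taxon_id"] == gadus
        assert out.loc["X", "high_quality"]

    def test_low_quality_flagged(self, tree_default):
        gadus = tree_default.find("Gadus")
        hits = pd.DataFrame({"asv": ["X"], "taxon_id": [gadus + 1],
                             "identity": [0.96], "coverage": [0.80]})
        assert not mb.assign_asvs(hits, tree_default).loc["X", "high_quality"]

    def test_matches_bruteforce_band_then_lca(self, tree_default):
        from conftest import lca_bruteforce
        rng = np.random.default_rng(12)
        species = [t for t in tree_default if tree_default.rank(t) == "species"]
        rows = []
        for i in range(30):
            for _ in range(int(rng.integers(1, 5))):
                rows.append((f"A{i}", int(rng.choice(species)),
                             float(rng.uniform(0.95, 1.0)),
                             float(rng.uniform(0.9, 1.0))))
        hits = pd.DataFrame(rows, columns=["asv", "taxon_id", "identity", "coverage"])
        out = mb.assign_asvs(hits, tree_default, band=0.01)
        for asv, grp in hits.groupby("asv"):
            best = grp["identity"].max()
            kept = grp.loc[grp["identity"] >= best - 0.01, "taxon_id"]
            assert out.loc[asv, "taxon_id"] == lca_bruteforce(tree_default, list(kept))


def test_positive_replicates_counts_and_oracle():
    roles = {f"S1.r{i}": "sample" for i in range(1, 9)}
    counts = {"X": dict(zip(roles, [0, 5, 2, 0, 0, 0, 0, 0])),
              "Y": dict(zip(roles, [0] * 8))}
    t = tiny_table(counts, roles, {"X": "AC", "Y": "AG"})
    out = mb.positive_replicates(t)
    assert out.loc["S1", "X"] == 2
    assert out.loc["S1", "Y"] == 0

    rng = np.random.default_rng(9)
    t = random_replicate_table(rng, n_neg=0)
    out = mb.positive_replicates(t)
    for s in out.index:
        reps = [r for r in t.counts.columns if t.replicates.loc[r, "sample"] == s]
        for asv in t.counts.index:
            assert out.loc[s, asv] == int((t.counts.loc[asv, reps] > 0).sum())
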