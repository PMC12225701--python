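"""End-to-end orchestration: simulate -> filter -> profile -> damage ->
diversity, with per-stage audit logging and a reproducible report bundle.

``run_pipeline`` drives a complete synthetic comparison: it generates a
ground-truthed sedaDNA record, pushes the metabarcoding arm through the
filter cascade and the metagenomic arm through classification, damage
fitting and authentication, then computes the cross-method comparison
statistics (richness regression, ordinations, Procrustes and Mantel tests)
and the Figure-2-style detection matrix.  All outputs are plain TSV/JSON,
byte-reproducible from config + seed.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import damage as dmg
from . import diversity as div
from . import mbfilter as mb
from . import mgprofile as mg
from . import simulate as sim
from .taxonomy import TaxonomyTree

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
    "interpolate_age",
    "detection_matrix",
]


def interpolate_age(age_depth: pd.DataFrame, depth: float) -> float:
    """Piecewise-linear age lookup from an age-depth table.

    ``age_depth`` has columns ``depth`` (cm) and ``age`` (cal BP), both
    strictly increasing; ``depth`` must be within the table's range.
    """
    d = np.asarray(age_depth["depth"], dtype=float)
    a = np.asarray(age_depth["age"], dtype=float)
    if len(d) < 2:
        raise ValueError("age-depth table needs at least 2 points")
    if not (np.all(np.diff(d) > 0) and np.all(np.diff(a) > 0)):
        raise ValueError("age-depth table must be strictly increasing")
    if not d[0] <= depth <= d[-1]:
        raise ValueError(f"depth {depth} outside table range [{d[0]}, {d[-1]}]")
    return float(np.interp(depth, d, a))


@dataclass
class PipelineConfig:
    """Full pipeline configuration; defaults mirror the study parameters
    (8 PCR replicates, 20,000-read rarefaction, 75-150 bp ASV window,
    0.95-1.00 similarity band, 100-read genus threshold, 500-read / z >= 2
    damage calibration, 10,000 Mantel permutations)."""

    sim: sim.SimulationConfig = field(default_factory=sim.SimulationConfig)

    # metabarcoding filters
    min_len: int = 75
    max_len: int = 150
    rarefy_depth: int = 20000
    exclude_negative_replicates: tuple[str, ...] = ()

    # metagenomic profiling
    min_sim: float = 0.95
    max_sim: float = 1.00
    min_reads_genus: int = 100
    max_damage_pos: int = 15

    # damage authentication
    min_reads_damage: int = 500
    min_z: float = 2.0
    envelope_mode: str = "running_min"
    plant_clade: str = "Viridiplantae"
    plant_exclusions: tuple[str, ...] = ("Zostera",)
    post_exclusions: tuple[str, ...] = ("Homo",)  # non-aquatic taxa, dropped after classification

    # statistics
    metric: str = "braycurtis"
    ordination_method: str = "nmds"
    n_perm_mantel: int = 10000
    n_perm_procrustes: int = 999

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_cfg = raw.pop("sim", {})
        taxa = sim_cfg.pop("taxa", None)
        if taxa is not None:
            sim_cfg["taxa"] = [sim.TaxonSpec(**t) for t in taxa]
        for key in ("mg_recovery_range", "identity_range"):
            if key in sim_cfg:
                sim_cfg[key] = tuple(sim_cfg[key])
        for key in ("plant_exclusions", "post_exclusions",
                    "exclude_negative_replicates"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(sim=sim.SimulationConfig(**sim_cfg), **raw)


@dataclass
class PipelineResult:
    config: PipelineConfig
    record: sim.TrueRecord
    tree: TaxonomyTree
    mb_table: mb.ReplicateTable            # rarefied, filtered
    mb_css: mb.CssResult
    mb_positive: pd.DataFrame              # sample x ASV occupancy
    asv_assignments: pd.DataFrame
    genus_profile: mg.GenusProfile
    damage_fits: pd.DataFrame
    envelope: dmg.AgeDamageEnvelope | None
    classifications: pd.DataFrame
    detections: pd.DataFrame
    richness: pd.DataFrame
    statistics: dict
    audit: list[dict]


def detection_matrix(mb_positive: pd.DataFrame, asv_assignments: pd.DataFrame,
                     classifications: pd.DataFrame, tree: TaxonomyTree,
                     sample_ages: pd.Series) -> pd.DataFrame:
    """Figure-2-style detection records: one row per (genus, sample, method)
    with the method's evidence (positive PCR replicates, or mapped reads)
    and the damage status (metagenomics only).  Genera detected by both
    methods anywhere in the record are flagged ``shared``."""
    records = []
    genus_of_asv = {}
    for asv, row in asv_assignments.iterrows():
        genus_of_asv[asv] = tree.rank_ancestor(int(row["taxon_id"]), "genus")
    for sample_id in mb_positive.index:
        row = mb_positive.loc[sample_id]
        per_genus: dict[int, int] = {}
        for asv, n_pos in row[row > 0].items():
            genus = genus_of_asv.get(asv)
            if genus is not None:
                per_genus[genus] = max(per_genus.get(genus, 0), int(n_pos))
        for genus, n_pos in per_genus.items():
            records.append({
                "taxon_id": genus, "taxon": tree.name(genus),
                "sample": sample_id, "age": float(sample_ages[sample_id]),
                "method": "metabarcoding", "evidence": n_pos,
                "damage_status": "not_applicable",
            })
    for row in classifications.itertuples():
        records.append({
            "taxon_id": int(row.genus), "taxon": tree.name(int(row.genus)),
            "sample": row.sample, "age": float(sample_ages[row.sample]),
            "method": "metagenomics", "evidence": int(row.n_reads),
            "damage_status": row.status,
        })
    out = pd.DataFrame(records)
    if out.empty:
        out["shared"] = []
        return out
    by_method = out.groupby("taxon_id")["method"].nunique()
    out["shared"] = out["taxon_id"].map(by_method) == 2
    return out.sort_values(["taxon_id", "sample", "method"]).reset_index(drop=True)


def _metazoan_features(tree: TaxonomyTree, taxon_ids) -> list:
    metazoa = tree.find("Metazoa")
    return [t for t in taxon_ids if tree.descends_from(int(t), metazoa)]


def run_pipeline(config: PipelineConfig | None = None,
                 seed: int | None = None,
                 outdir: str | Path | None = None) -> PipelineResult:
    """Run the full synthetic comparison; optionally write the report bundle.

    ``seed`` overrides the simulation seed in ``config``.  Everything
    downstream of the generator is deterministic given config + seed.
    """
    config = config or PipelineConfig()
    if seed is not None:
        config = dataclasses.replace(
            config, sim=dataclasses.replace(config.sim, seed=seed))
    audit: list[dict] = []

    def log(stage: str, **info):
        audit.append({"stage": stage, **info})

    tree = sim.default_taxonomy()
    record = sim.simulate_record(config.sim, tree)
    ages = pd.Series(record.ages, index=record.sample_ids, name="age")
    log("simulate", n_samples=len(record.sample_ids),
        n_taxa=record.composition.shape[1], seed=config.sim.seed)

    # -- metabarcoding arm --------------------------------------------
    mbsim = sim.emit_metabarcoding(record, config.sim)
    table = mb.merge_orientations(mbsim.forward, mbsim.reverse)
    log("merge_orientations", n_asvs=len(table.counts), total=table.total())
    table = mb.remove_singletons(table)
    log("remove_singletons", total=table.total())
    table = mb.negative_floor_filter(
        table, exclude_replicates=list(config.exclude_negative_replicates))
    if not mbsim.forward.negative_columns():
        warnings.warn("no negative-control replicates: floor thresholds are 0")
    log("negative_floor", total=table.total())
    table = mb.length_filter(table, config.min_len, config.max_len)
    log("length_filter", n_asvs=len(table.counts), total=table.total())
    # replicates emptied by the filters carry no information for either
    # normalisation branch
    nonempty = [c for c in table.counts.columns if table.counts[c].sum() > 0]
    if len(nonempty) < table.counts.shape[1]:
        log("drop_empty_replicates",
            n_dropped=table.counts.shape[1] - len(nonempty))
        table = mb.ReplicateTable(table.counts[nonempty],
                                  table.replicates.loc[nonempty],
                                  table.sequences)
    css = mb.css_normalize(table)
    rarefied = mb.rarefy(table, config.rarefy_depth, seed=config.sim.seed)
    log("rarefy", depth=config.rarefy_depth,
        n_replicates=rarefied.counts.shape[1], total=rarefied.total())
    positive = mb.positive_replicates(rarefied)
    assignments = mb.assign_asvs(mbsim.asv_hits, tree)
    log("assign_asvs", n_assigned=len(assignments))

    # -- metagenomic arm ----------------------------------------------
    hits = sim.emit_metagenomics(record, config.sim)
    n_raw = hits["read_id"].nunique()
    hits_f = mg.filter_hits(hits, config.min_sim, config.max_sim)
    log("filter_hits", reads_in=n_raw, reads_out=hits_f["read_id"].nunique())
    reads = mg.classify_reads(hits_f, tree)
    profile = mg.genus_table(reads, tree, config.min_reads_genus)
    log("genus_table", n_genera=len(profile.counts),
        n_above_genus=profile.n_above_genus)
    damage_table = mg.damage_count_table(hits_f, profile, config.max_damage_pos)
    fits = dmg.fit_damage_table(damage_table)
    log("fit_damage", n_fits=len(fits))

    plant_root = tree.find(config.plant_clade)
    exclusions = tuple(tree.find(n) for n in config.plant_exclusions)
    envelope = dmg.build_envelope(
        fits, tree, plant_root, ages, exclusions,
        min_reads=config.min_reads_damage, min_z=config.min_z,
        mode=config.envelope_mode)
    classifications = dmg.classify_table(fits, envelope, ages, config.min_z)
    # drop designated non-aquatic taxa after classification
    post_excl = {tree.find(n) for n in config.post_exclusions}
    classifications = classifications[
        ~classifications["genus"].isin(post_excl)].reset_index(drop=True)
    log("classify_ancient",
        n_ancient=int((classifications["status"] == dmg.ANCIENT).sum()),
        n_observations=len(classifications))

    detections = detection_matrix(positive, assignments, classifications,
                                  tree, ages)

    # -- diversity comparison -----------------------------------------
    genus_counts = profile.counts.drop(index=post_excl, errors="ignore")
    mg_community = genus_counts.T  # samples x genera
    mb_community = positive
    shared = [s for s in record.sample_ids
              if s in mb_community.index and s in mg_community.index]
    mb_comm = mb_community.loc[shared]
    mg_comm = mg_community.loc[shared]
    mb_rich = div.richness(mb_comm)
    mg_rich = div.richness(mg_comm)
    richness = pd.DataFrame({
        "age": ages[shared], "metabarcoding": mb_rich, "metagenomics": mg_rich,
    })
    reg_arms = div.compare_richness(mb_rich, mg_rich)
    reg_mb_age = div.compare_richness(ages[shared], mb_rich)
    reg_mg_age = div.compare_richness(ages[shared], mg_rich)

    metric_fn = div.bray_curtis if config.metric == "braycurtis" else div.jaccard
    nonzero = [s for s in shared
               if mb_comm.loc[s].sum() > 0 and mg_comm.loc[s].sum() > 0]
    d_mb = metric_fn(div.standardize_relfreq(mb_comm.loc[nonzero]))
    d_mg = metric_fn(div.standardize_relfreq(mg_comm.loc[nonzero]))
    mantel_full = div.mantel_test(d_mb, d_mg, config.n_perm_mantel,
                                  seed=config.sim.seed)
    ord_mb = div.ordinate(d_mb, method=config.ordination_method,
                          seed=config.sim.seed)
    ord_mg = div.ordinate(d_mg, method=config.ordination_method,
                          seed=config.sim.seed)
    protest_full = div.procrustes_test(ord_mb, ord_mg,
                                       config.n_perm_procrustes,
                                       seed=config.sim.seed)

    # metazoan subsets
    mb_metaz_asvs = [a for a, row in assignments.iterrows()
                     if tree.descends_from(int(row["taxon_id"]),
                                           tree.find("Metazoa"))
                     and a in mb_comm.columns]
    mg_metaz = _metazoan_features(tree, mg_comm.columns)
    statistics = {
        "richness_regression": {
            "arms": dataclasses.asdict(reg_arms),
            "metabarcoding_vs_age": dataclasses.asdict(reg_mb_age),
            "metagenomics_vs_age": dataclasses.asdict(reg_mg_age),
        },
        "mantel_full": dataclasses.asdict(mantel_full),
        "procrustes_full": dataclasses.asdict(protest_full),
        "nmds_stress": {"metabarcoding": ord_mb.stress,
                        "metagenomics": ord_mg.stress},
    }
    mb_metaz = mb_comm[mb_metaz_asvs]
    mg_metaz_comm = mg_comm[mg_metaz]
    ok = [s for s in nonzero
          if mb_metaz.loc[s].sum() > 0 and mg_metaz_comm.loc[s].sum() > 0]
    if len(ok) >= 4 and len(mb_metaz.columns) >= 2 and len(mg_metaz) >= 2:
        d_mb_m = metric_fn(div.standardize_relfreq(mb_metaz.loc[ok]))
        d_mg_m = metric_fn(div.standardize_relfreq(mg_metaz_comm.loc[ok]))
        mantel_metaz = div.mantel_test(d_mb_m, d_mg_m, config.n_perm_mantel,
                                       seed=config.sim.seed)
        statistics["mantel_metazoa"] = dataclasses.asdict(mantel_metaz)
    else:
        statistics["mantel_metazoa"] = None
    log("statistics", mantel_full_r=mantel_full.r, mantel_full_p=mantel_full.p)

    result = PipelineResult(
        config=config, record=record, tree=tree, mb_table=rarefied,
        mb_css=css, mb_positive=positive, asv_assignments=assignments,
        genus_profile=profile, damage_fits=fits, envelope=envelope,
        classifications=classifications, detections=detections,
        richness=richness, statistics=statistics, audit=audit,
    )
    if outdir is not None:
        write_report(result, outdir)
    return result


def write_report(result: PipelineResult, outdir: str | Path) -> None:
    """Write the full report bundle (TSV tables + JSON manifest), with
    stable formatting so identical runs are byte-identical."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ff = "%.10g"

    result.mb_table.write(outdir, "mb_rarefied")
    result.mb_css.values.to_csv(outdir / "mb_css.tsv", sep="\t", float_format=ff)
    result.mb_positive.to_csv(outdir / "mb_positive_replicates.tsv", sep="\t")
    result.asv_assignments.to_csv(outdir / "asv_assignments.tsv", sep="\t",
                                  float_format=ff)
    result.genus_profile.counts.to_csv(outdir / "mg_genus_counts.tsv", sep="\t")
    result.damage_fits.to_csv(outdir / "mg_damage_fits.tsv", sep="\t",
                              index=False, float_format=ff)
    if result.envelope is not None:
        (outdir / "envelope.json").write_text(result.envelope.to_json())
    result.classifications.to_csv(outdir / "classifications.tsv", sep="\t",
                                  index=False, float_format=ff)
    result.detections.to_csv(outdir / "detections.tsv", sep="\t",
                             index=False, float_format=ff)
    result.richness.to_csv(outdir / "richness.tsv", sep="\t", float_format=ff)
    (outdir / "statistics.json").write_text(
        json.dumps(result.statistics, indent=2, sort_keys=True))
    (outdir / "truth.json").write_text(
        json.dumps(result.record.to_json(), sort_keys=True))
    with open(outdir / "audit.log", "w") as fh:
        for entry in result.audit:
            fh.write(json.dumps(entry, sort_keys=True) + "\n")
    manifest = {
        "files": sorted(p.name for p in outdir.iterdir()
                        if p.name != "manifest.json"),
        "seed": result.config.sim.seed,
        "n_samples": len(result.record.sample_ids),
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))
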