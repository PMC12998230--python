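"""End-to-end orchestration: simulate/load -> gate -> clean -> distances ->
clusters -> ordination/tests -> assembly -> traits -> report.

Every stage is a pure file-to-file function over a run directory, so the
CLI subcommands compose to exactly the monolithic :func:`run` result, and a
rerun with the same configuration is bit-identical.  The single global seed
fans out to per-stage seeds through a fixed counter scheme recorded in the
report.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ._errors import InvalidConfigError, TreeError
from . import assembly as asm
from . import diversity as dv
from . import features as ft
from . import flow as fc
from . import phylo as ph
from . import simulate as sim
from . import structure as st
from . import traits as tr

__all__ = ["PipelineConfig", "run", "stage_seed"]

FLOAT_FMT = "%.10g"


def stage_seed(seed: int, stage: int) -> int:
    """Counter-based per-stage seed; stable under stage reordering."""
    return (int(seed) * 100_003 + 7919 * stage) % (2**31)


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "run_out"
    input_dir: str = None  # dataset directory (write_dataset layout) or None
    simulate: dict = field(default_factory=dict)  # SimulationConfig overrides
    unifrac_alpha: float = 0.5
    unifrac_mode: str = "absolute"
    k_all: int = 3
    k_surface: int = 4
    n_null: int = 1000
    bin_size_limit: int = 24
    ds: float = 0.5
    confidence: float = 0.975
    rc_threshold: float = 0.95
    n_perm: int = 999
    prune_height: float = 2.0
    rare_threshold: float = 1e-4

    def null_config(self) -> asm.NullModelConfig:
        return asm.NullModelConfig(
            n_null=self.n_null, confidence=self.confidence,
            rc_threshold=self.rc_threshold, bin_size_limit=self.bin_size_limit,
            ds=self.ds, seed=stage_seed(self.seed, 6),
        )

    def analysis_params(self) -> dict:
        """Config without filesystem locations: what defines the analysis."""
        d = asdict(self)
        d.pop("out_dir", None)
        d.pop("input_dir", None)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.analysis_params(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_distance(d: dv.DistanceMatrix, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# metric={d.metric} alpha={d.alpha} mode={d.mode}\n")
        d.values_df.to_csv(fh, float_format=FLOAT_FMT)


def _read_distance(path: Path) -> dv.DistanceMatrix:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().strip().lstrip("# ")
        meta = dict(kv.split("=", 1) for kv in header.split())
        df = pd.read_csv(fh, index_col=0)
    alpha = None if meta.get("alpha") == "None" else float(meta["alpha"])
    return dv.DistanceMatrix(df, metric=meta.get("metric", ""), alpha=alpha,
                             mode=meta.get("mode", "relative"))


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(config: PipelineConfig, out: Path) -> sim.SyntheticDataset:
    sim_cfg = sim.SimulationConfig(
        seed=stage_seed(config.seed, 1), **config.simulate
    )
    ds = sim.simulate_dataset(sim_cfg)
    sim.write_dataset(ds, out / "dataset")
    return ds

def stage_gate(dataset_dir: Path, out_csv: Path) -> pd.Series:
    """Flow events -> per-sample cell concentrations (mean over stain reps)."""
    ds = sim.read_dataset(dataset_dir)
    gate = fc.default_gate()
    rows = []
    for s in sorted(ds.flow_events):
        reps = [
            fc.concentration(et, gate)
            for et in ds.flow_events[s]
        ]
        agg = fc.aggregate_replicates(reps)
        rows.append(
            dict(sample_id=s, cells_per_ml=agg.cells_per_ml,
                 n_gated_events=agg.n_gated_events,
                 replicate_cv=agg.replicate_cv)
        )
    df = pd.DataFrame(rows).set_index("sample_id")
    df.to_csv(out_csv, float_format=FLOAT_FMT)
    return df["cells_per_ml"]


def stage_clean(dataset_dir: Path, conc_csv: Path, out: Path,
                prune_height: float = 2.0) -> dict:
    """Filters, replicate merge, abundance transforms and tree preparation."""
    ds = sim.read_dataset(dataset_dir)
    conc = pd.read_csv(conc_csv, index_col=0)["cells_per_ml"]
    tallies = {"input_taxa": len(ds.counts.taxon_ids),
               "input_columns": len(ds.counts.sample_ids)}

    counts = ft.remove_organelles(ds.counts, ds.taxonomy)
    tallies["organelle_taxa_removed"] = tallies["input_taxa"] - len(counts.taxon_ids)
    counts, contam = ft.remove_contaminants(counts)
    tallies["contaminant_taxa_removed"] = len(contam)
    pd.Series(contam, name="taxon_id", dtype=object).to_csv(
        out / "removed_contaminants.csv", index=False
    )
    counts = counts.drop_controls()
    merged = ft.merge_replicates(
        counts, {c: ds.metadata.loc[c, "merged_id"] for c in counts.sample_ids},
        metadata=ds.metadata,
    )
    tallies["merged_samples"] = len(merged.sample_ids)
    rel = ft.to_relative(merged)
    absolute = ft.to_absolute(rel, conc)

    # tree: root at the archaeal MRCA, then drop anomalous long tips
    archaea = list(
        ds.taxonomy.ranks_df.index[ds.taxonomy.ranks_df["Domain"] == "Archaea"]
    )
    archaea = [t for t in archaea if t in set(merged.taxon_ids)]
    if not archaea:
        raise TreeError("no archaeal taxa available to root the tree")
    tree = ph.root_at_mrca(ds.tree, archaea)
    tree, long_tips = ph.prune_long_tips(tree, max_height=prune_height)
    tallies["long_branch_tips_removed"] = len(long_tips)
    keep = [t for t in merged.taxon_ids if t in {x.name for x in tree.tips()}]
    tallies["analysis_taxa"] = len(keep)
    merged = merged.subset_taxa(keep)
    rel = ft.AbundanceMatrix(rel.values_df.loc[keep], "relative")
    absolute = ft.AbundanceMatrix(absolute.values_df.loc[keep], "absolute")

    merged.values_df.to_csv(out / "merged_counts.tsv", sep="\t")
    rel.values_df.to_csv(out / "relative.tsv", sep="\t", float_format=FLOAT_FMT)
    absolute.values_df.to_csv(out / "absolute.tsv", sep="\t", float_format=FLOAT_FMT)
    ph.write_newick(tree, out / "tree_pruned.nwk")
    return tallies


def stage_dist(out: Path, alpha: float = 0.5, mode: str = "absolute") -> dv.DistanceMatrix:
    table = "absolute.tsv" if mode == "absolute" else "relative.tsv"
    values = pd.read_csv(out / table, sep="\t", index_col=0)
    tree = ph.read_newick(out / "tree_pruned.nwk")
    branches = ph.branch_abundances(
        tree, ft.AbundanceMatrix(values, mode)
    )
    d = dv.unifrac(branches, mode="generalized", alpha=alpha)
    _write_distance(d, out / "distance.csv")
    return d


def stage_cluster(out: Path, k: int, subset=None, tag: str = "all") -> st.GroupAssignment:
    d = _read_distance(out / "distance.csv")
    if subset is not None:
        d = d.subset([s for s in d.sample_ids if s in set(subset)])
    dend = st.upgma(d)
    groups = st.cut_tree(dend, k)
    (out / f"dendrogram_{tag}.nwk").write_text(dend.to_newick(), encoding="utf-8")
    groups.labels.rename("group").to_csv(out / f"groups_{tag}.csv")
    return groups


def stage_assembly(out: Path, cfg: asm.NullModelConfig) -> pd.DataFrame:
    counts = pd.read_csv(out / "merged_counts.tsv", sep="\t", index_col=0)
    tree = ph.read_newick(out / "tree_pruned.nwk")
    pair_df = asm.analyze_pairs(tree, counts, cfg)
    pair_df.to_csv(out / "assembly_pairs.csv", index=False, float_format=FLOAT_FMT)
    groups = pd.read_csv(out / "groups_all.csv", index_col=0)["group"]
    agg = asm.aggregate_groups(pair_df, groups)
    agg.to_csv(out / "assembly_aggregate.csv", float_format=FLOAT_FMT)
    return pair_df


def stage_traits(out: Path, dataset_dir: Path) -> tr.TraitAbundance:
    values = pd.read_csv(out / "absolute.tsv", sep="\t", index_col=0)
    taxonomy = ft.TaxonomyTable(
        pd.read_csv(dataset_dir / "taxonomy.tsv", sep="\t", index_col=0,
                    keep_default_na=False)
    )
    db = tr.parse_trait_db(dataset_dir / "trait_db.txt")
    ta = tr.trait_abundance(
        db, taxonomy, ft.AbundanceMatrix(values, "absolute")
    )
    ta.values_df.to_csv(out / "traits.csv", float_format=FLOAT_FMT)
    return ta


# ---------------------------------------------------------------------------
# monolithic run
# ---------------------------------------------------------------------------

def run(config: PipelineConfig) -> dict:
    """Execute every stage in order and write a deterministic RunReport."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = {
        "config": config.analysis_params(),
        "config_hash": config.config_hash(),
        "stage_seeds": {f"stage_{k}": stage_seed(config.seed, k) for k in range(1, 9)},
    }

    if config.input_dir is not None:
        dataset_dir = Path(config.input_dir)
        if not dataset_dir.exists():
            raise InvalidConfigError(f"input_dir {dataset_dir} does not exist")
    else:
        stage_simulate(config, out)
        dataset_dir = out / "dataset"

    conc = stage_gate(dataset_dir, out / "concentrations.csv")
    report["n_flow_samples"] = int(len(conc))

    tallies = stage_clean(dataset_dir, out / "concentrations.csv", out,
                          prune_height=config.prune_height)
    report["filters"] = tallies

    stage_dist(out, alpha=config.unifrac_alpha, mode=config.unifrac_mode)
    d = _read_distance(out / "distance.csv")

    groups = stage_cluster(out, config.k_all, tag="all")
    meta = pd.read_csv(dataset_dir / "metadata.csv", index_col=0)
    merged_meta = meta[~meta["is_negative_control"]].drop_duplicates("merged_id").set_index("merged_id")
    for month in sorted(merged_meta["month"].dropna().unique()):
        surf = merged_meta.index[
            (merged_meta["month"] == month) & (merged_meta["depth_class"] == "E")
        ]
        surf = [s for s in surf if s in d.sample_ids]
        if len(surf) >= config.k_surface:
            stage_cluster(out, config.k_surface, subset=surf, tag=f"surface_{month}")

    f_stat, r2, p = st.permanova(d, groups, n_perm=config.n_perm,
                                 seed=stage_seed(config.seed, 4))
    disp_f, disp_p, disp = st.dispersion_test(
        d, groups, n_perm=config.n_perm, seed=stage_seed(config.seed, 5)
    )
    report["permanova"] = {"F": f_stat, "R2": r2, "p": p, "n_perm": config.n_perm}
    report["dispersion"] = {"F": disp_f, "p": disp_p,
                            "per_group": {k: float(v) for k, v in disp.items()}}

    simmat = dv.similarity(d)
    decay = {}
    for month in sorted(merged_meta["month"].dropna().unique()):
        ids = [s for s in d.sample_ids if merged_meta.loc[s, "month"] == month]
        if len(ids) < 4:
            continue
        sub = simmat.loc[ids, ids]
        geo = st.haversine_km(merged_meta.loc[ids, "lat"], merged_meta.loc[ids, "lon"])
        depth = merged_meta.loc[ids, "depth_m"].to_numpy(dtype=float)
        ddep = pd.DataFrame(np.abs(depth[:, None] - depth[None, :]), index=ids, columns=ids)
        rho_g, p_g = st.decay_correlation(sub, geo, n_perm=config.n_perm,
                                          seed=stage_seed(config.seed, 7))
        rho_d, p_d = st.decay_correlation(sub, ddep, n_perm=config.n_perm,
                                          seed=stage_seed(config.seed, 8))
        decay[month] = {"distance_rho": rho_g, "distance_p": p_g,
                        "depth_rho": rho_d, "depth_p": p_d}
    report["decay"] = decay

    pair_df = stage_assembly(out, config.null_config())
    agg = pd.read_csv(out / "assembly_aggregate.csv", index_col=0)
    report["assembly_strata"] = {
        s: {p_: float(agg.loc[s, p_]) for p_ in asm.PROCESSES}
        for s in agg.index
    }
    report["assembly_pairs"] = int(pair_df[["sample_a", "sample_b"]].drop_duplicates().shape[0]) if not pair_df.empty else 0

    counts = pd.read_csv(out / "merged_counts.tsv", sep="\t", index_col=0)
    hill_rows = []
    for s in counts.columns:
        prof = dv.hill_profile(counts[s].to_numpy(), sample_id=s)
        for q, v in zip(prof.orders, prof.values):
            hill_rows.append({"sample_id": s, "q": q, "hill": v})
    pd.DataFrame(hill_rows).to_csv(out / "hill.csv", index=False,
                                   float_format=FLOAT_FMT)

    ta = stage_traits(out, dataset_dir)
    report["trait_coverage"] = ta.coverage

    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
    return report
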