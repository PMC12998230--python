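"""Seeded synthetic datasets with the statistical structure of a stratified
great-lake microbial survey.

The generator emulates, at desk scale, the features the downstream analysis
assumes: three depth-month community groups (Shallow May, Shallow September,
Deep — the deep pool shared across months) over a shared cosmopolitan core;
wind-driven upwelling that mixes hypolimnion taxa into September surface
samples and plants novel rare taxa (< 0.01 % relative abundance) carrying
traits absent elsewhere; cell concentrations positively coupled to
temperature; duplicate biological replicates differing only by multinomial
resampling plus a small lognormal taxon-level jitter; negative-control
columns carrying contaminant taxa; and flow-cytometry event clouds whose
gated counts analytically reproduce each sample's true cell concentration.

Everything is driven by a single integer seed; identical configurations
produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from ._errors import InvalidConfigError
from .features import CountMatrix, TaxonomyTable, RANKS
from .flow import EventTable
from . import phylo as _phylo

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "simulate_tree",
    "simulate_dataset",
    "simulate_flow_sample",
    "simulate_assembly_scenario",
    "write_dataset",
    "read_dataset",
    "FIXTURE_TRAIT_DB",
]

GROUPS = ("Shallow May", "Shallow September", "Deep")

# clade identity cycle: (Class, Phylum, Domain, home-group bias)
_CLADE_CYCLE = [
    ("Actinobacteria", "Actinobacteriota", "Bacteria", None),
    ("Alphaproteobacteria", "Proteobacteria", "Bacteria", None),
    ("Bacteroidia", "Bacteroidota", "Bacteria", "Shallow May"),
    ("Cyanobacteriia", "Cyanobacteria", "Bacteria", "Shallow September"),
    ("Anaerolineae", "Chloroflexi", "Bacteria", "Deep"),
    ("Nitrososphaeria", "Crenarchaeota", "Archaea", "Deep"),
]

FIXTURE_TRAIT_DB = """\
# Curated fixture trait database (synthetic; four focal traits plus one
# add_group example). Patterns are anchored globs over the semicolon-joined
# lineage Domain;Phylum;Class;Order;Family;Genus;Species.
photoautotrophy\telements:C
*;Cyanobacteriia;*
aerobic_ammonia_oxidation\telements:N
*;Nitrososphaeria;*
*Nitrosomonadaceae*
sulfate_respiration\telements:S
*Desulfuromonas*
methanotrophy\telements:C,H
*Methylomonadaceae*
methylotrophy\telements:C
*Methylophilaceae*
add_group:methanotrophy
"""


@dataclass
class SimulationConfig:
    seed: int = 0
    n_taxa: int = 300
    n_stations: int = 8
    depth_classes: tuple = ("E", "M", "B")
    months: tuple = ("May", "September")
    group_effect: float = 2.0
    drift_concentration: float = 200.0
    dispersal_block_size: int = 20
    upwelling_stations: tuple = ("ST02",)
    upwelling_mix: float = 0.5
    rare_novel_taxa: int = 8
    temp_cell_slope: float = 1.5e5  # cells/ml per deg C
    replicate_noise_cv: float = 0.05
    contaminant_taxa: int = 6
    # secondary knobs (defaults are the study conditions; see docs/methods.md)
    cell_intercept: float = 5e5
    conc_noise_cv: float = 0.05
    read_depth_range: tuple = (8000, 80000)
    core_fraction: float = 0.3
    organelle_taxa: int = 4
    n_controls: int = 2
    n_replicates: int = 2
    flow_volume_ul: float = 42.5
    flow_dilution: float = 20.0
    flow_stain_replicates: int = 3

    def __post_init__(self):
        if self.n_taxa < 4:
            raise InvalidConfigError("n_taxa must be >= 4")
        if not 0.0 <= self.upwelling_mix <= 1.0:
            raise InvalidConfigError("upwelling_mix must be in [0, 1]")
        if self.group_effect < 0 or self.drift_concentration <= 0:
            raise InvalidConfigError("group_effect >= 0 and drift_concentration > 0")
        if self.replicate_noise_cv < 0:
            raise InvalidConfigError("replicate_noise_cv must be >= 0")
        if self.dispersal_block_size < 0 or self.rare_novel_taxa < 0:
            raise InvalidConfigError("dispersal_block_size and rare_novel_taxa must be >= 0")

    def station_ids(self):
        return [f"ST{i + 1:02d}" for i in range(self.n_stations)]


@dataclass
class SyntheticDataset:
    tree: TreeNode
    counts: CountMatrix  # replicate columns + negative controls
    taxonomy: TaxonomyTable
    metadata: pd.DataFrame  # indexed by column id of counts
    flow_events: dict  # merged sample id -> list[EventTable]
    trait_db: str  # FAPROTAX-dialect text
    sample_truth: pd.DataFrame  # merged sample id -> group/upwelling/temp/cells
    taxon_truth: pd.DataFrame  # taxon -> pool/clade/class
    config: SimulationConfig = None

    @property
    def replicate_map(self) -> dict:
        """counts column id -> merged biological sample id."""
        out = {}
        for col in self.counts.sample_ids:
            out[col] = self.metadata.loc[col, "merged_id"]
        return out


def _rng(config, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) % (2**31), stage])


def _random_binary_tree(rng, labels, blen_lo, blen_hi):
    nodes = [TreeNode(name=l, length=float(rng.uniform(blen_lo, blen_hi))) for l in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = TreeNode(length=float(rng.uniform(blen_lo, blen_hi)))
        parent.extend([a, b])
        nodes.append(parent)
    return nodes[0]


def _clade_sizes(config):
    n_clades = max(2, config.n_taxa // 50)
    base = config.n_taxa // n_clades
    sizes = [base] * n_clades
    for i in range(config.n_taxa - base * n_clades):
        sizes[i] += 1
    return sizes


def simulate_tree(config: SimulationConfig) -> TreeNode:
    """Rooted binary tree with tight clades joined by a long backbone.

    Each clade is rescaled so its maximum tip-to-tip distance falls in
    [0.25, 0.40] — below the default binning distance of 0.5 — while
    backbone branches (>= 0.5) keep clades mutually distant, so the default
    binning parameters are exercisable whenever clades hold enough tips.
    """
    rng = _rng(config, 1)
    sizes = _clade_sizes(config)
    labels = [f"ASV{i + 1:04d}" for i in range(config.n_taxa)]
    clades = []
    start = 0
    for size in sizes:
        clade = _random_binary_tree(rng, labels[start : start + size], 0.005, 0.03)
        start += size
        if size > 1:
            diam = max(
                clade.tip_tip_distances().data.max(), 1e-9
            )
            target = float(rng.uniform(0.25, 0.40))
            scale = target / diam
            for node in clade.traverse(include_self=False):
                node.length *= scale
        # clade stems >= 0.3 keep any two clades > 0.6 apart (above the 0.5
        # binning distance) while root-to-tip heights stay well below the
        # long-branch pruning threshold of 2
        clade.length = float(rng.uniform(0.3, 0.45))
        clades.append(clade)
    backbone = clades
    while len(backbone) > 1:
        i, j = sorted(rng.choice(len(backbone), size=2, replace=False))
        b = backbone.pop(j)
        a = backbone.pop(i)
        parent = TreeNode(length=float(rng.uniform(0.1, 0.25)))
        parent.extend([a, b])
        backbone.append(parent)
    root = backbone[0]
    root.length = None
    return root


def _assign_taxonomy(rng, config, clade_of, n_clades):
    """Rank table per taxon, driven by clade identity."""
    rows = {}
    clade_ident = [_CLADE_CYCLE[c % len(_CLADE_CYCLE)] for c in range(n_clades)]
    if not any(ident[2] == "Archaea" for ident in clade_ident):
        # the tree must always be rootable at an archaeal MRCA
        clade_ident[-1] = next(c for c in _CLADE_CYCLE if c[2] == "Archaea")
    for taxon, clade in clade_of.items():
        cls, phylum, domain, _bias = clade_ident[clade]
        order = f"{cls[:6]}ales_{clade + 1}"
        family = f"{cls[:6]}aceae_{clade + 1}"
        genus = f"{cls[:4]}_g{int(rng.integers(1, 9))}"
        rows[taxon] = [domain, phylum, cls, order, family, genus, ""]
    return rows, clade_ident


def simulate_flow_sample(
    true_cells_per_ml: float,
    rng,
    sample_id: str = "",
    volume_ul: float = 42.5,
    dilution: float = 20.0,
    n_stain_replicates: int = 3,
    debris_fraction: float = 0.4,
):
    """Event tables whose expected gated count matches the true concentration.

    Stained cells form a bivariate lognormal cluster inside the packaged
    default gate; debris sits at low scatter/fluorescence outside it.  The
    stained event count per stain replicate is Poisson with mean
    ``conc * volume_ul * 1e-3 / dilution``, the analytic inverse of the
    concentration formula.
    """
    target = true_cells_per_ml * volume_ul * 1e-3 / dilution
    tables = []
    for rep in range(1, n_stain_replicates + 1):
        n_cells = int(rng.poisson(target))
        n_debris = int(rng.poisson(debris_fraction * max(target, 1.0)))
        fsc_c = 10 ** rng.normal(3.6, 0.15, size=n_cells)
        fl1_c = 10 ** rng.normal(3.9, 0.15, size=n_cells)
        fsc_d = 10 ** rng.normal(1.6, 0.25, size=n_debris)
        fl1_d = 10 ** rng.normal(2.2, 0.25, size=n_debris)
        df = pd.DataFrame(
            {
                "fsc_h": np.concatenate([fsc_c, fsc_d]),
                "fl1_h": np.concatenate([fl1_c, fl1_d]),
            }
        )
        df = df.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(
            drop=True
        )
        tables.append(EventTable(df, sample_id=sample_id, stain_replicate=rep))
    return tables


def _temperature(rng, depth_class, month, upwelled):
    if depth_class == "E":
        if upwelled:
            return float(rng.normal(9.0, 0.8))
        return float(rng.normal(10.0, 1.5) if month == "May" else rng.normal(20.5, 1.0))
    if depth_class == "M":
        # May mid samples sit at the thermocline; September mid samples at
        # average station depth lie below it and are nearly as cold as bottom
        return float(rng.normal(8.0, 1.0) if month == "May" else rng.normal(6.0, 1.0))
    return float(rng.normal(4.2, 0.4))


def _pool_group(depth_class, month):
    """Which community pool a depth-month stratum draws from."""
    if depth_class == "B":
        return "Deep"
    if depth_class == "M":
        return "Shallow May" if month == "May" else "Deep"
    return f"Shallow {month}"


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Full dataset: tree, counts, taxonomy, metadata, flow, traits, truth."""
    stations = config.station_ids()
    unknown = [s for s in config.upwelling_stations if s not in stations]
    if unknown:
        raise InvalidConfigError(f"upwelling stations not in metadata: {unknown}")

    tree = simulate_tree(config)
    taxa = sorted(t.name for t in tree.tips())
    n = len(taxa)
    sizes = _clade_sizes(config)
    clade_of = {}
    start = 0
    for c, size in enumerate(sizes):
        for t in [f"ASV{i + 1:04d}" for i in range(start, start + size)]:
            clade_of[t] = c
        start += size

    rng = _rng(config, 2)

    # ---- special taxa: novel (upwelling-only), contaminants, organelles ----
    upw_samples = [
        (st, "E", "September")
        for st in stations
        if st in config.upwelling_stations and "September" in config.months
        and "E" in config.depth_classes
    ]
    n_novel = config.rare_novel_taxa * len(upw_samples)
    n_special = n_novel + config.contaminant_taxa + config.organelle_taxa
    if n_special > n // 2:
        raise InvalidConfigError(
            f"{n_special} special taxa exceed half of n_taxa={n}"
        )
    special = rng.choice(n, size=n_special, replace=False)
    novel_ids = [taxa[i] for i in special[:n_novel]]
    contam_ids = [taxa[i] for i in special[n_novel : n_novel + config.contaminant_taxa]]
    organelle_ids = [taxa[i] for i in special[n_novel + config.contaminant_taxa :]]
    novel_of_sample = {
        f"{st}_{dc}_{mo}": novel_ids[k * config.rare_novel_taxa : (k + 1) * config.rare_novel_taxa]
        for k, (st, dc, mo) in enumerate(upw_samples)
    }

    # ---- taxonomy ----
    tax_rows, clade_ident = _assign_taxonomy(rng, config, clade_of, len(sizes))
    for i, t in enumerate(novel_ids):
        if i % 2 == 0:
            tax_rows[t] = ["Bacteria", "Desulfobacterota", "Desulfuromonadia",
                           "Desulfuromonadales", "Desulfuromonadaceae",
                           "Desulfuromonas", f"Desulfuromonas_sp{i + 1}"]
        else:
            tax_rows[t] = ["Bacteria", "Proteobacteria", "Gammaproteobacteria",
                           "Methylococcales", "Methylomonadaceae",
                           f"Methylomonas_n{i + 1}", ""]
    for i, t in enumerate(organelle_ids):
        if i % 2 == 0:
            tax_rows[t] = ["Bacteria", "Cyanobacteria", "Cyanobacteriia",
                           "Chloroplast", "", "", ""]
        else:
            tax_rows[t] = ["Bacteria", "Proteobacteria", "Alphaproteobacteria",
                           "Rickettsiales", "Mitochondria", "", ""]
    taxonomy = TaxonomyTable(
        pd.DataFrame.from_dict(tax_rows, orient="index", columns=RANKS).loc[taxa]
    )

    # ---- group pools ----
    base = np.exp(rng.normal(0.0, 1.2, size=n))
    pool_label = pd.Series("", index=taxa, dtype=object)
    idx_of = {t: i for i, t in enumerate(taxa)}
    regular = [t for t in taxa if t not in set(novel_ids) | set(contam_ids) | set(organelle_ids)]
    n_core = int(round(config.core_fraction * len(regular)))
    core_ids = list(rng.choice(regular, size=n_core, replace=False))
    pool_label[core_ids] = "core"
    home = {}
    for t in regular:
        if t in set(core_ids):
            continue
        bias = clade_ident[clade_of[t]][3]
        if bias is not None and rng.random() < 0.75:
            home[t] = bias
        else:
            home[t] = GROUPS[int(rng.integers(len(GROUPS)))]
        pool_label[t] = {"Shallow May": "shallow_may",
                         "Shallow September": "shallow_september",
                         "Deep": "deep"}[home[t]]
    pool_label[novel_ids] = "novel"
    pool_label[contam_ids] = "contaminant"
    pool_label[organelle_ids] = "organelle"

    pools = {}
    for g in GROUPS:
        w = np.zeros(n)
        for t in regular:
            i = idx_of[t]
            if t in set(core_ids):
                w[i] = base[i]
            else:
                w[i] = base[i] * np.exp(config.group_effect if home[t] == g else 0.0)
        for t in organelle_ids:
            w[idx_of[t]] = 0.3 * base[idx_of[t]]
        pools[g] = w / w.sum()

    # ---- dispersal blocks (Deep samples only) ----
    # dispersal_block_size taxa per station-restricted block; up to
    # n_stations//2 blocks, so the knob is monotone: 0 disables blocking,
    # larger values restrict more hypolimnion taxa to station subsets.
    deep_taxa = list(rng.permutation(
        [t for t in regular if t not in set(core_ids) and home[t] == "Deep"]
    ))
    block_allowed = {}  # taxon -> set of stations where it may occur (Deep)
    bs = int(config.dispersal_block_size)
    if bs > 0:
        n_blocks = max(2, len(stations) // 2)
        blocked = deep_taxa[: min(len(deep_taxa), bs * n_blocks)]
        for b0 in range(0, len(blocked), bs):
            block = blocked[b0 : b0 + bs]
            n_allowed = max(1, len(stations) // 2)
            allowed = set(rng.choice(stations, size=n_allowed, replace=False))
            for t in block:
                block_allowed[t] = allowed

    # ---- samples ----
    meta_rows, truth_rows = [], []
    count_cols = {}
    station_depth = {st: float(rng.uniform(40, 200)) for st in stations}
    lat = {st: float(rng.uniform(43.2, 44.0)) for st in stations}
    lon = {st: float(rng.uniform(-79.8, -76.4)) for st in stations}
    lo, hi = config.read_depth_range

    for month in config.months:
        for st in stations:
            for dc in config.depth_classes:
                merged = f"{st}_{dc}_{month}"
                upwelled = (
                    dc == "E" and month == "September" and st in config.upwelling_stations
                )
                group = _pool_group(dc, month)
                temp = _temperature(rng, dc, month, upwelled)
                p = pools[group].copy()
                if group == "Deep" and block_allowed:
                    for t, allowed in block_allowed.items():
                        if st not in allowed:
                            p[idx_of[t]] = 0.0
                    p = p / p.sum()
                if upwelled:
                    p = config.upwelling_mix * pools["Deep"] + (1 - config.upwelling_mix) * p
                # within-group compositional drift
                alpha = config.drift_concentration * p
                gam = np.where(alpha > 0, rng.gamma(np.maximum(alpha, 1e-12)), 0.0)
                pi = gam / gam.sum() if gam.sum() > 0 else p
                if upwelled:
                    # proportions sized so realized relative abundance stays
                    # below the 1e-4 rare threshold at the default read depths
                    eps = rng.uniform(1e-5, 4e-5, size=len(novel_of_sample[merged]))
                    pi = pi * (1.0 - eps.sum())
                    for t, e in zip(novel_of_sample[merged], eps):
                        pi[idx_of[t]] = e
                conc = config.cell_intercept + config.temp_cell_slope * temp
                conc = conc + rng.normal(0.0, config.conc_noise_cv * conc)
                conc = float(max(conc, 1e4))
                depth_m = {"E": 5.0, "M": 15.0 if month == "May" else 25.0,
                           "B": station_depth[st] - 2.0}[dc]
                for r in range(1, config.n_replicates + 1):
                    col = f"{merged}_R{r}"
                    jitter = np.exp(rng.normal(0.0, config.replicate_noise_cv, size=n)) \
                        if config.replicate_noise_cv > 0 else np.ones(n)
                    q = pi * jitter
                    q = q / q.sum()
                    reads = int(np.exp(rng.uniform(np.log(lo), np.log(hi))))
                    count_cols[col] = rng.multinomial(reads, q)
                    meta_rows.append(
                        dict(sample_id=col, merged_id=merged, station_id=st,
                             lat=lat[st], lon=lon[st], depth_m=depth_m,
                             depth_class=dc, month=month,
                             temperature_C=round(temp, 3),
                             is_negative_control=False, replicate_id=f"R{r}")
                    )
                truth_rows.append(
                    dict(sample_id=merged, group=group, upwelling=upwelled,
                         station_id=st, month=month, depth_class=dc,
                         temperature_C=round(temp, 3), cells_per_ml=conc)
                )

    # ---- negative controls: contaminant taxa only ----
    for c in range(1, config.n_controls + 1):
        col = f"NEG{c}"
        w = np.zeros(n)
        if contam_ids:
            w[[idx_of[t] for t in contam_ids]] = rng.dirichlet(
                np.full(len(contam_ids), 5.0)
            )
            reads = int(rng.integers(1000, 5000))
            count_cols[col] = rng.multinomial(reads, w)
        else:
            count_cols[col] = np.zeros(n, dtype=int)
        meta_rows.append(
            dict(sample_id=col, merged_id=col, station_id="CTRL", lat=np.nan,
                 lon=np.nan, depth_m=np.nan, depth_class="", month="",
                 temperature_C=np.nan, is_negative_control=True,
                 replicate_id="R1")
        )

    metadata = pd.DataFrame(meta_rows).set_index("sample_id")
    counts_df = pd.DataFrame(count_cols, index=taxa).astype(int)
    counts = CountMatrix(counts_df, metadata["is_negative_control"])
    sample_truth = pd.DataFrame(truth_rows).set_index("sample_id")

    # ---- flow cytometry events per merged water sample ----
    flow_rng = _rng(config, 3)
    flow_events = {
        s: simulate_flow_sample(
            row["cells_per_ml"], flow_rng, sample_id=s,
            volume_ul=config.flow_volume_ul, dilution=config.flow_dilution,
            n_stain_replicates=config.flow_stain_replicates,
        )
        for s, row in sample_truth.iterrows()
    }

    taxon_truth = pd.DataFrame(
        {
            "pool": pool_label,
            "clade": pd.Series({t: clade_of[t] for t in taxa}),
            "class": taxonomy.ranks_df["Class"],
        }
    )
    return SyntheticDataset(
        tree=tree, counts=counts, taxonomy=taxonomy, metadata=metadata,
        flow_events=flow_events, trait_db=FIXTURE_TRAIT_DB,
        sample_truth=sample_truth, taxon_truth=taxon_truth, config=config,
    )


# ---------------------------------------------------------------------------
# assembly-process scenario generators (parameter-recovery checks)
# ---------------------------------------------------------------------------

def simulate_assembly_scenario(
    kind: str,
    seed: int,
    n_samples: int = 6,
    bin_size: int = 30,
    n_bins: int = 2,
    read_depth: int = 3000,
    block_strength: float = 1.0,
):
    """Tree + counts engineered so one assembly process dominates.

    kind='homogenizing_selection': every sample concentrates abundance on
    the same phylogenetically tight subclade within each bin, so observed
    betaMPD sits far below the label-shuffle null.
    kind='dispersal_limitation': samples belong to two sites whose taxa
    pools are phylogenetically random, (nearly) disjoint blocks within each
    bin; ``block_strength`` in [0, 1] scales how exclusive the blocks are.
    kind='drift': every sample is an independent Dirichlet-multinomial draw
    from one shared pool.

    Returns ``(tree, counts_df, site_of_sample)``.
    """
    if kind not in ("homogenizing_selection", "dispersal_limitation", "drift"):
        raise InvalidConfigError(f"unknown scenario {kind!r}")
    cfg = SimulationConfig(seed=seed, n_taxa=bin_size * n_bins)
    rng = np.random.default_rng([int(seed) % (2**31), 17])
    tree = simulate_tree(cfg)
    taxa = sorted(t.name for t in tree.tips())
    n = len(taxa)
    samples = [f"S{i + 1:02d}" for i in range(n_samples)]
    sizes = _clade_sizes(cfg)
    clade_of = np.zeros(n, dtype=int)
    start = 0
    for c, size in enumerate(sizes):
        clade_of[start : start + size] = c
        start += size
    dist = _phylo.cophenetic(tree).loc[taxa, taxa].to_numpy()

    site_of = {s: i % 2 for i, s in enumerate(samples)}
    cols = {}
    if kind == "homogenizing_selection":
        w = np.full(n, 0.02)
        for c in range(len(sizes)):
            members = np.flatnonzero(clade_of == c)
            # tight focal subset: the closest neighbours of a focal tip
            focal = members[0]
            order = members[np.argsort(dist[focal, members])]
            w[order[: max(3, len(members) // 6)]] = 1.0
        p = w / w.sum()
        for s in samples:
            gam = rng.gamma(50.0 * p)
            cols[s] = rng.multinomial(read_depth, gam / gam.sum())
    elif kind == "dispersal_limitation":
        block_of = np.zeros(n, dtype=int)
        for c in range(len(sizes)):
            members = np.flatnonzero(clade_of == c)
            shuffled = rng.permutation(members)  # phylogenetically random split
            block_of[shuffled[: len(members) // 2]] = 1
        base = np.exp(rng.normal(0, 0.5, size=n))
        for s in samples:
            # multinomial sampling (null-like) modulated only by the blocks,
            # so block_strength = 0 degenerates to neutral drift
            w = base * np.where(
                block_of == site_of[s], 1.0, 1.0 - block_strength
            )
            p = w / w.sum()
            cols[s] = rng.multinomial(read_depth, p)
    else:  # drift: independent multinomial sampling from one shared pool
        base = np.exp(rng.normal(0, 1.0, size=n))
        p = base / base.sum()
        for s in samples:
            cols[s] = rng.multinomial(read_depth, p)
    counts = pd.DataFrame(cols, index=taxa)
    return tree, counts, site_of


# ---------------------------------------------------------------------------
# on-disk round trip
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_dataset(ds: SyntheticDataset, directory) -> dict:
    """Write every dataset component to ``directory``; return the manifest.

    Layout: tree.nwk, counts.tsv, taxonomy.tsv, metadata.csv,
    flow/<sample>_r<k>.csv, trait_db.txt, truth_samples.csv,
    truth_taxa.csv, manifest.json (relative paths + sha256 checksums).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    (directory / "flow").mkdir(exist_ok=True)
    _phylo.write_newick(ds.tree, directory / "tree.nwk")
    ds.counts.values_df.to_csv(directory / "counts.tsv", sep="\t")
    ds.taxonomy.ranks_df.to_csv(directory / "taxonomy.tsv", sep="\t")
    ds.metadata.to_csv(directory / "metadata.csv")
    for s, tables in ds.flow_events.items():
        for et in tables:
            et.events.to_csv(
                directory / "flow" / f"{s}_r{et.stain_replicate}.csv", index=False
            )
    (directory / "trait_db.txt").write_text(ds.trait_db, encoding="utf-8")
    ds.sample_truth.to_csv(directory / "truth_samples.csv")
    ds.taxon_truth.to_csv(directory / "truth_taxa.csv")
    files = sorted(
        str(p.relative_to(directory))
        for p in directory.rglob("*")
        if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "config": {k: list(v) if isinstance(v, tuple) else v
                   for k, v in asdict(ds.config).items()} if ds.config else {},
        "files": {f: _sha256(directory / f) for f in files},
    }
    with open(directory / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def read_dataset(directory) -> SyntheticDataset:
    """Load a dataset written by :func:`write_dataset`."""
    directory = Path(directory)
    for required in ("tree.nwk", "counts.tsv", "taxonomy.tsv", "metadata.csv",
                     "trait_db.txt", "truth_samples.csv", "truth_taxa.csv"):
        if not (directory / required).exists():
            raise FileNotFoundError(f"missing dataset file: {required}")
    tree = _phylo.read_newick(directory / "tree.nwk")
    counts_df = pd.read_csv(directory / "counts.tsv", sep="\t", index_col=0)
    metadata = pd.read_csv(directory / "metadata.csv", index_col=0,
                           keep_default_na=True)
    metadata["depth_class"] = metadata["depth_class"].fillna("")
    metadata["month"] = metadata["month"].fillna("")
    counts = CountMatrix(counts_df, metadata["is_negative_control"])
    taxonomy = TaxonomyTable(
        pd.read_csv(directory / "taxonomy.tsv", sep="\t", index_col=0,
                    keep_default_na=False)
    )
    sample_truth = pd.read_csv(directory / "truth_samples.csv", index_col=0)
    taxon_truth = pd.read_csv(directory / "truth_taxa.csv", index_col=0)
    flow_events = {}
    for s in sample_truth.index:
        tables = []
        rep = 1
        while (directory / "flow" / f"{s}_r{rep}.csv").exists():
            df = pd.read_csv(directory / "flow" / f"{s}_r{rep}.csv")
            tables.append(EventTable(df, sample_id=s, stain_replicate=rep))
            rep += 1
        if not tables:
            raise FileNotFoundError(f"missing flow event files for sample {s}")
        flow_events[s] = tables
    trait_db = (directory / "trait_db.txt").read_text(encoding="utf-8")
    return SyntheticDataset(
        tree=tree, counts=counts, taxonomy=taxonomy, metadata=metadata,
        flow_events=flow_events, trait_db=trait_db,
        sample_truth=sample_truth, taxon_truth=taxon_truth, config=None,
    )
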