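"""Phylogenetic-bin null-model inference of community assembly processes.

Taxa are partitioned into monophyletic bins of closely related tips.  For
every sample pair and every bin present in both samples, two standardized
metrics are computed against randomized null distributions:

* betaNRI — the standardized effect size of the abundance-weighted
  beta-mean-pairwise-distance (betaMPD), with nulls built by shuffling
  taxon labels across the bin's tips.  |betaNRI| beyond the confidence
  quantile indicates selection (negative: homogenizing; positive:
  heterogeneous).
* RC_Bray — Raup-Crick-standardized Bray-Curtis dissimilarity in [-1, 1],
  with null communities that preserve each sample's within-bin richness
  and read total while drawing taxa by occurrence frequency and allocating
  reads by mean relative abundance.  Extreme values indicate less/more
  exchange than expected (dispersal limitation / homogenizing dispersal).

Pairs are then classified into five processes (heterogeneous selection,
homogenizing selection, dispersal limitation, homogenizing dispersal,
drift), weighted by bin relative abundance, and aggregated within and
between sample groups.  One randomization per null iteration serves every
sample pair, as in standard implementations of the framework.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._errors import InvalidConfigError
from .phylo import cophenetic

__all__ = [
    "NullModelConfig",
    "PhyloBin",
    "bin_phylogeny",
    "beta_mpd",
    "beta_nri",
    "rc_bray",
    "classify_process",
    "process_fractions",
    "analyze_pairs",
    "aggregate_groups",
    "bin_abundance_cv",
    "PROCESSES",
]

PROCESSES = [
    "heterogeneous_selection",
    "homogenizing_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "drift",
]


@dataclass
class NullModelConfig:
    n_null: int = 1000
    confidence: float = 0.975
    rc_threshold: float = 0.95
    bin_size_limit: int = 24
    ds: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not 0.5 < self.confidence < 1.0:
            raise InvalidConfigError("confidence must be in (0.5, 1)")
        if self.n_null < 100:
            raise InvalidConfigError("n_null must be >= 100")
        if self.bin_size_limit < 1 or self.ds <= 0:
            raise InvalidConfigError("bin_size_limit >= 1 and ds > 0 required")

    @property
    def z_star(self) -> float:
        return float(norm.ppf(self.confidence))


@dataclass
class PhyloBin:
    bin_id: str
    members: list
    max_within_distance: float


def bin_phylogeny(tree, cfg: NullModelConfig, dist: pd.DataFrame = None):
    """Partition the tree's tips into phylogenetic bins.

    Seed bins are the maximal monophyletic clades whose within-clade maximum
    cophenetic distance is <= ``cfg.ds``; bins smaller than
    ``cfg.bin_size_limit`` are then merged, smallest first, into the bin at
    smallest mean inter-bin cophenetic distance (the final merges may exceed
    ``ds``).  Deterministic given the tree.
    """
    if dist is None:
        dist = cophenetic(tree)
    tips = list(dist.index)
    if len(tips) < cfg.bin_size_limit:
        warnings.warn(
            f"{len(tips)} tips < bin_size_limit={cfg.bin_size_limit}; single bin"
        )
        return [PhyloBin("bin01", sorted(tips), float(dist.values.max(initial=0.0)))]
    d = dist.to_numpy(dtype=float)
    idx_of = {t: i for i, t in enumerate(tips)}

    def clade_diameter(names):
        rows = [idx_of[n] for n in names]
        if len(rows) < 2:
            return 0.0
        sub = d[np.ix_(rows, rows)]
        return float(sub.max())

    seeds = []

    def descend(node):
        names = [t.name for t in node.tips()] if not node.is_tip() else [node.name]
        if clade_diameter(names) <= cfg.ds:
            seeds.append(sorted(names))
            return
        for child in node.children:
            descend(child)

    descend(tree)

    bins = [set(s) for s in seeds]
    while len(bins) > 1:
        small = [b for b in bins if len(b) < cfg.bin_size_limit]
        if not small:
            break
        # smallest bin first; ties broken by lexicographically first member
        small.sort(key=lambda b: (len(b), min(b)))
        b = small[0]
        rows_b = [idx_of[t] for t in b]
        best, best_key = None, None
        for other in bins:
            if other is b:
                continue
            rows_o = [idx_of[t] for t in other]
            mean_d = float(d[np.ix_(rows_b, rows_o)].mean())
            key = (mean_d, min(other))
            if best_key is None or key < best_key:
                best, best_key = other, key
        bins.remove(b)
        bins.remove(best)
        bins.append(b | best)
    bins.sort(key=lambda b: min(b))
    return [
        PhyloBin(f"bin{i + 1:02d}", sorted(b), clade_diameter(b))
        for i, b in enumerate(bins)
    ]


def beta_mpd(f_a, f_b, dist_sub) -> float:
    """Abundance-weighted mean pairwise phylogenetic distance between samples.

    ``f_a``/``f_b`` are abundances over the bin's members (renormalized to
    proportions internally); ``dist_sub`` is the matching cophenetic
    submatrix.  Includes i == j terms (distance 0).
    """
    a = np.asarray(f_a, dtype=float)
    b = np.asarray(f_b, dtype=float)
    if a.sum() <= 0 or b.sum() <= 0:
        raise InvalidConfigError("bin absent from one of the samples")
    a, b = a / a.sum(), b / b.sum()
    return float(a @ np.asarray(dist_sub, dtype=float) @ b)


def _null_beta_mpd(a, b, d, perms):
    """betaMPD under label shuffles: vectorized over permutations."""
    ap = a[perms]  # (n_null, m)
    bp = b[perms]
    return np.einsum("km,mn,kn->k", ap, d, bp, optimize=True)


def beta_nri(f_a, f_b, dist_sub, cfg: NullModelConfig, rng=None):
    """Standardized effect size of betaMPD against a within-bin label shuffle.

    Returns ``(beta_nri, degenerate)``; a zero-variance null yields 0 with
    the degenerate flag set.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    a = np.asarray(f_a, dtype=float)
    b = np.asarray(f_b, dtype=float)
    if a.sum() <= 0 or b.sum() <= 0:
        raise InvalidConfigError("bin absent from one of the samples")
    a, b = a / a.sum(), b / b.sum()
    d = np.asarray(dist_sub, dtype=float)
    obs = float(a @ d @ b)
    m = len(a)
    perms = np.argsort(rng.random((cfg.n_null, m)), axis=1)
    nulls = _null_beta_mpd(a, b, d, perms)
    sd = nulls.std(ddof=0)
    if sd == 0:
        return 0.0, True
    return float((obs - nulls.mean()) / sd), False


def _bray_curtis(a, b):
    tot = a.sum() + b.sum()
    if tot == 0:
        return 0.0
    return float(np.abs(a - b).sum() / tot)


def _draw_null_counts(rng, n_null, m, richness, total, occ_w, abund_w):
    """Null count matrix (n_null x m) preserving richness and read total.

    Taxa are selected without replacement with probability proportional to
    occurrence frequency (Gumbel top-k trick); reads are allocated by a
    multinomial with probabilities proportional to mean relative abundance
    over the selected taxa.
    """
    richness = min(max(int(richness), 1), m)
    logw = np.log(np.maximum(occ_w, 1e-12))
    keys = logw[None, :] + rng.gumbel(size=(n_null, m))
    sel = np.argpartition(-keys, richness - 1, axis=1)[:, :richness]
    out = np.zeros((n_null, m), dtype=np.int64)
    for k in range(n_null):
        p = np.maximum(abund_w[sel[k]], 1e-12)
        out[k, sel[k]] = rng.multinomial(int(total), p / p.sum())
    return out


def rc_bray(counts_a, counts_b, occ_freq, mean_rel, cfg: NullModelConfig, rng=None):
    """Raup-Crick-standardized Bray-Curtis for one pair within one bin.

    RC = 2 * [(#{null BC < obs} + 0.5 * #{null BC = obs}) / n_null] - 1.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.sum() <= 0 or b.sum() <= 0:
        raise InvalidConfigError("bin absent from one of the samples")
    obs = _bray_curtis(a, b)
    m = len(a)
    occ = np.asarray(occ_freq, dtype=float)
    mra = np.asarray(mean_rel, dtype=float)
    na = _draw_null_counts(rng, cfg.n_null, m, (a > 0).sum(), a.sum(), occ, mra)
    nb = _draw_null_counts(rng, cfg.n_null, m, (b > 0).sum(), b.sum(), occ, mra)
    tot = na.sum(axis=1) + nb.sum(axis=1)
    with np.errstate(invalid="ignore"):
        bc = np.abs(na - nb).sum(axis=1) / np.where(tot == 0, 1, tot)
    below = (bc < obs - 1e-12).sum()
    equal = (np.abs(bc - obs) <= 1e-12).sum()
    return float(2.0 * ((below + 0.5 * equal) / cfg.n_null) - 1.0)


def classify_process(beta_nri_value: float, rc: float, cfg: NullModelConfig) -> str:
    """Map (betaNRI, RC_Bray) to one of the five assembly processes."""
    z = cfg.z_star
    if beta_nri_value > z:
        return "heterogeneous_selection"
    if beta_nri_value < -z:
        return "homogenizing_selection"
    if rc > cfg.rc_threshold:
        return "dispersal_limitation"
    if rc < -cfg.rc_threshold:
        return "homogenizing_dispersal"
    return "drift"


def analyze_pairs(
    tree,
    counts_df: pd.DataFrame,
    cfg: NullModelConfig,
    bins=None,
    dist: pd.DataFrame = None,
    pairs=None,
) -> pd.DataFrame:
    """betaNRI, RC_Bray and process labels for sample pairs, per bin.

    ``counts_df`` is taxa x samples integer-like reads (post-merge).  One
    randomization per null iteration serves all pairs.  Returns a
    long-format DataFrame (sample_a, sample_b, bin_id, beta_nri, rc_bray,
    process, weight) where weight is the pair-mean bin relative abundance
    renormalized over the bins present in both samples.
    """
    if dist is None:
        dist = cophenetic(tree)
    if bins is None:
        bins = bin_phylogeny(tree, cfg, dist=dist)
    samples = list(counts_df.columns)
    if pairs is None:
        pairs = [
            (samples[i], samples[j])
            for i in range(len(samples))
            for j in range(i + 1, len(samples))
        ]
    col_tot = counts_df.sum(axis=0).astype(float)
    rel = counts_df.div(col_tot.replace(0, np.nan), axis=1).fillna(0.0)

    rows = []
    for b_idx, pb in enumerate(bins):
        members = [t for t in pb.members if t in counts_df.index]
        if len(members) == 0:
            continue
        rng = np.random.default_rng([int(cfg.seed) % (2**31), b_idx])
        sub_counts = counts_df.loc[members].to_numpy(dtype=float)
        sub_rel = rel.loc[members]
        d = dist.loc[members, members].to_numpy(dtype=float)
        m = len(members)
        col = {s: k for k, s in enumerate(samples)}
        bin_tot = sub_counts.sum(axis=0)
        present = bin_tot > 0
        occ = (sub_counts > 0).mean(axis=1)
        mean_rel = sub_rel.mean(axis=1).to_numpy()

        # betaMPD nulls: one tip-label shuffle per iteration, all pairs
        f = sub_counts / np.where(bin_tot == 0, 1, bin_tot)
        perms = np.argsort(rng.random((cfg.n_null, m)), axis=1)
        obs_mpd = f.T @ d @ f
        null_sum = np.zeros_like(obs_mpd)
        null_sq = np.zeros_like(obs_mpd)
        for k in range(cfg.n_null):
            fp = f[perms[k]]
            nm = fp.T @ d @ fp
            null_sum += nm
            null_sq += nm**2
        null_mean = null_sum / cfg.n_null
        null_sd = np.sqrt(np.maximum(null_sq / cfg.n_null - null_mean**2, 0.0))

        # RC nulls: one null community per sample per iteration
        null_counts = {}
        for s in samples:
            k = col[s]
            if not present[k]:
                continue
            null_counts[s] = _draw_null_counts(
                rng, cfg.n_null, m, (sub_counts[:, k] > 0).sum(),
                bin_tot[k], occ, mean_rel,
            )

        bin_rel_abund = sub_rel.sum(axis=0)  # bin share of each sample
        for sa, sb in pairs:
            ia, ib = col[sa], col[sb]
            if not (present[ia] and present[ib]):
                continue
            sd = null_sd[ia, ib]
            if sd == 0:
                bnri, degen = 0.0, True
            else:
                bnri = (obs_mpd[ia, ib] - null_mean[ia, ib]) / sd
                degen = False
            obs_bc = _bray_curtis(sub_counts[:, ia], sub_counts[:, ib])
            na, nb = null_counts[sa], null_counts[sb]
            tot = na.sum(axis=1) + nb.sum(axis=1)
            bc = np.abs(na - nb).sum(axis=1) / np.where(tot == 0, 1, tot)
            below = (bc < obs_bc - 1e-12).sum()
            equal = (np.abs(bc - obs_bc) <= 1e-12).sum()
            rc = 2.0 * ((below + 0.5 * equal) / cfg.n_null) - 1.0
            rows.append(
                {
                    "sample_a": sa,
                    "sample_b": sb,
                    "bin_id": pb.bin_id,
                    "beta_nri": float(bnri),
                    "rc_bray": float(rc),
                    "process": classify_process(bnri, rc, cfg),
                    "weight": float(
                        (bin_rel_abund[sa] + bin_rel_abund[sb]) / 2.0
                    ),
                    "degenerate_null": degen,
                }
            )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    # renormalize weights over the bins present for each pair
    df["weight"] = df["weight"] / df.groupby(["sample_a", "sample_b"])["weight"].transform("sum")
    return df


def process_fractions(pair_df: pd.DataFrame) -> pd.DataFrame:
    """Per-pair process fractions (sum to 1) from a long-format result."""
    if pair_df.empty:
        warnings.warn("no shared bins; attributing the pair entirely to drift")
        return pd.DataFrame(columns=PROCESSES)
    out = (
        pair_df.pivot_table(
            index=["sample_a", "sample_b"],
            columns="process",
            values="weight",
            aggfunc="sum",
            fill_value=0.0,
        )
        .reindex(columns=PROCESSES, fill_value=0.0)
    )
    return out


def aggregate_groups(pair_df: pd.DataFrame, group_labels: pd.Series) -> pd.DataFrame:
    """Mean process fractions per within-group and between-group stratum.

    Strata are each group (pairs inside it) and each unordered group pair.
    Returns a DataFrame indexed by stratum with one column per process plus
    the pair count ``n_pairs``; empty strata are omitted.
    """
    fr = process_fractions(pair_df)
    if fr.empty:
        return pd.DataFrame(columns=PROCESSES + ["n_pairs"])
    rows = {}
    for (sa, sb), frac in fr.iterrows():
        ga, gb = group_labels.get(sa), group_labels.get(sb)
        if ga is None or gb is None:
            continue
        stratum = f"within:{ga}" if ga == gb else "between:" + "|".join(sorted([str(ga), str(gb)]))
        rows.setdefault(stratum, []).append(frac)
    agg = {
        s: pd.concat(v, axis=1).T.mean().to_dict() | {"n_pairs": len(v)}
        for s, v in rows.items()
    }
    return pd.DataFrame(agg).T[PROCESSES + ["n_pairs"]].sort_index()


def bin_abundance_cv(bins, abund) -> pd.DataFrame:
    """Per-bin mean abundance and coefficient of variation across samples.

    Bin abundance in a sample is the sum over member taxa (cells/ml for an
    absolute matrix); CV = sd/mean with sd over samples (ddof=1).  A
    zero-mean bin gets CV = NaN with the ``undefined`` flag set.
    """
    values = getattr(abund, "values_df", abund)
    rows = []
    for pb in bins:
        members = [t for t in pb.members if t in values.index]
        per_sample = values.loc[members].sum(axis=0)
        mean = float(per_sample.mean())
        sd = float(per_sample.std(ddof=1)) if len(per_sample) > 1 else 0.0
        rows.append(
            {
                "bin_id": pb.bin_id,
                "mean_abundance": mean,
                "cv": sd / mean if mean > 0 else np.nan,
                "undefined": mean <= 0,
            }
        )
    return pd.DataFrame(rows).set_index("bin_id")
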