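"""Count-matrix hygiene and abundance transforms.

A :class:`CountMatrix` holds integer read counts (taxa x samples) together
with a per-sample negative-control mask.  Cleaning proceeds: organelle
removal -> negative-control contaminant removal -> replicate merging ->
relative abundance -> absolute abundance (cells/ml) via per-sample cell
concentrations from flow cytometry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._errors import InvalidConfigError, MismatchError

__all__ = [
    "CountMatrix",
    "TaxonomyTable",
    "AbundanceMatrix",
    "remove_organelles",
    "remove_contaminants",
    "merge_replicates",
    "to_relative",
    "to_absolute",
    "flag_rare_taxa",
    "unique_taxa",
]

ORGANELLE_TOKENS = frozenset({"mitochondria", "chloroplast"})
RANKS = ["Domain", "Phylum", "Class", "Order", "Family", "Genus", "Species"]


@dataclass
class CountMatrix:
    """Taxa x samples integer read counts with a negative-control mask."""

    values_df: pd.DataFrame
    control_mask: pd.Series = None  # bool per sample; default all False

    def __post_init__(self):
        if self.values_df.index.duplicated().any():
            raise MismatchError("duplicate taxon ids in count matrix")
        if self.values_df.columns.duplicated().any():
            raise MismatchError("duplicate sample ids in count matrix")
        if (self.values_df.to_numpy() < 0).any():
            raise InvalidConfigError("negative counts")
        if self.control_mask is None:
            self.control_mask = pd.Series(False, index=self.values_df.columns)
        self.control_mask = self.control_mask.reindex(
            self.values_df.columns, fill_value=False
        ).astype(bool)

    @property
    def taxon_ids(self):
        return list(self.values_df.index)

    @property
    def sample_ids(self):
        return list(self.values_df.columns)

    def subset_taxa(self, taxa) -> "CountMatrix":
        return CountMatrix(self.values_df.loc[list(taxa)], self.control_mask)

    def drop_controls(self) -> "CountMatrix":
        keep = self.control_mask.index[~self.control_mask]
        return CountMatrix(self.values_df[keep], self.control_mask[keep])


@dataclass
class TaxonomyTable:
    """taxon_id -> ordered ranks Domain..Species (lower ranks may be empty)."""

    ranks_df: pd.DataFrame  # index taxon_id, columns RANKS (strings, '' ok)

    def __post_init__(self):
        missing = [c for c in RANKS if c not in self.ranks_df.columns]
        for c in missing:
            self.ranks_df[c] = ""
        self.ranks_df = self.ranks_df[RANKS].fillna("").astype(str)

    def lineage(self, taxon_id) -> str:
        """Semicolon-joined lineage string with no rank prefixes."""
        return ";".join(self.ranks_df.loc[taxon_id])

    def lineages(self) -> pd.Series:
        return self.ranks_df.apply(lambda r: ";".join(r), axis=1)

    def covers(self, taxa) -> bool:
        return set(taxa) <= set(self.ranks_df.index)


@dataclass
class AbundanceMatrix:
    """Taxa x samples abundances: proportions ('relative') or cells/ml ('absolute')."""

    values_df: pd.DataFrame
    mode: str = "relative"

    def __post_init__(self):
        if self.mode not in ("relative", "absolute"):
            raise InvalidConfigError(f"unknown abundance mode {self.mode!r}")

    @property
    def sample_ids(self):
        return list(self.values_df.columns)

    @property
    def taxon_ids(self):
        return list(self.values_df.index)


def remove_organelles(counts: CountMatrix, tax: TaxonomyTable) -> CountMatrix:
    """Drop taxa classified as mitochondria or chloroplasts at any rank.

    Matching is case-insensitive on the whole rank token; empty taxonomy
    strings never match (absence of evidence retains the taxon).
    """
    if not tax.covers(counts.taxon_ids):
        missing = sorted(set(counts.taxon_ids) - set(tax.ranks_df.index))
        raise MismatchError(f"taxonomy missing for taxa: {missing[:10]}")
    sub = tax.ranks_df.loc[counts.taxon_ids]
    is_organelle = sub.apply(
        lambda row: any(v.strip().lower() in ORGANELLE_TOKENS for v in row), axis=1
    )
    keep = sub.index[~is_organelle]
    return counts.subset_taxa(keep)


def _column_relative(values: pd.DataFrame) -> pd.DataFrame:
    sums = values.sum(axis=0)
    sums = sums.replace(0, np.nan)
    return values.div(sums, axis=1).fillna(0.0)


def remove_contaminants(counts: CountMatrix):
    """Remove taxa whose relative abundance peaks in a negative control.

    A taxon is a contaminant iff its maximum per-column relative abundance
    over control samples strictly exceeds its maximum over true samples.
    Relative abundance is computed within each raw (pre-merge) column.
    Returns ``(filtered_counts, removed_taxon_ids)``.
    """
    if not counts.control_mask.any():
        warnings.warn("no negative controls flagged; contaminant filter is a no-op")
        return counts, []
    rel = _column_relative(counts.values_df)
    ctrl_cols = counts.control_mask.index[counts.control_mask]
    true_cols = counts.control_mask.index[~counts.control_mask]
    max_ctrl = rel[ctrl_cols].max(axis=1)
    max_true = rel[true_cols].max(axis=1) if len(true_cols) else 0.0
    removed = sorted(rel.index[max_ctrl > max_true])
    keep = [t for t in counts.taxon_ids if t not in set(removed)]
    return counts.subset_taxa(keep), removed


def merge_replicates(counts: CountMatrix, replicate_map, metadata=None) -> CountMatrix:
    """Sum replicate columns into one column per biological sample.

    ``replicate_map`` maps each column id to its merged sample id.  If
    ``metadata`` (indexed by column id, with station_id/depth_class/month
    columns) is given, replicate groups spanning different
    station/depth/month combinations raise :class:`MismatchError`.
    """
    replicate_map = dict(replicate_map)
    missing = [c for c in counts.sample_ids if c not in replicate_map]
    if missing:
        raise MismatchError(f"columns without a merged id: {missing[:10]}")
    if metadata is not None:
        keys = ["station_id", "depth_class", "month"]
        present = [k for k in keys if k in metadata.columns]
        groups: dict[str, set] = {}
        for col in counts.sample_ids:
            if col not in metadata.index:
                continue
            sig = tuple(metadata.loc[col, k] for k in present)
            groups.setdefault(replicate_map[col], set()).add(sig)
        bad = {g: s for g, s in groups.items() if len(s) > 1}
        if bad:
            raise MismatchError(
                f"replicate groups span different stations/depths/months: {sorted(bad)[:5]}"
            )
    merged = counts.values_df.T.groupby(
        [replicate_map[c] for c in counts.sample_ids]
    ).sum().T
    ctrl = counts.control_mask.groupby(
        [replicate_map[c] for c in counts.sample_ids]
    ).any()
    return CountMatrix(merged, ctrl.reindex(merged.columns))


def to_relative(counts: CountMatrix) -> AbundanceMatrix:
    """Per-column proportions; columns must have positive totals."""
    sums = counts.values_df.sum(axis=0)
    zero = list(sums.index[sums == 0])
    if zero:
        raise InvalidConfigError(f"samples with zero total reads: {zero[:10]}")
    return AbundanceMatrix(counts.values_df.div(sums, axis=1), mode="relative")


def to_absolute(rel: AbundanceMatrix, cells_per_ml) -> AbundanceMatrix:
    """Scale relative abundances by each sample's cell concentration.

    ``cells_per_ml`` is a mapping/Series from sample id to cells/ml; every
    sample of ``rel`` must be present.
    """
    if rel.mode != "relative":
        raise InvalidConfigError("to_absolute expects a relative-mode matrix")
    conc = pd.Series(cells_per_ml)
    missing = [s for s in rel.sample_ids if s not in conc.index]
    if missing:
        raise MismatchError(f"missing cell concentration for sample(s): {missing}")
    scaled = rel.values_df.mul(conc[rel.sample_ids], axis=1)
    return AbundanceMatrix(scaled, mode="absolute")


def flag_rare_taxa(rel: AbundanceMatrix, threshold: float = 1e-4):
    """Per-sample sets of taxa present below ``threshold`` relative abundance.

    A taxon is rare in sample s iff 0 < rel(t, s) < threshold (strict on
    both sides: absent taxa are not rare; the boundary value is not rare).
    """
    if rel.mode != "relative":
        raise InvalidConfigError("flag_rare_taxa expects a relative-mode matrix")
    if not (0.0 < threshold < 1.0):
        raise InvalidConfigError(f"threshold must be in (0, 1), got {threshold}")
    v = rel.values_df
    return {
        s: set(v.index[(v[s] > 0) & (v[s] < threshold)]) for s in rel.sample_ids
    }


def unique_taxa(rel: AbundanceMatrix, focal_samples) -> set:
    """Taxa present in >= 1 focal sample and absent from all other samples."""
    focal = set(focal_samples)
    all_samples = set(rel.sample_ids)
    if not focal or not focal < all_samples:
        raise InvalidConfigError(
            "focal_samples must be a non-empty proper subset of the samples"
        )
    v = rel.values_df
    fcols = sorted(focal)
    ocols = sorted(all_samples - focal)
    present_focal = (v[fcols] > 0).any(axis=1)
    absent_other = (v[ocols] == 0).all(axis=1)
    return set(v.index[present_focal & absent_other])
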