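"""Alpha and beta diversity: Hill numbers, analytic rarefaction, and the
UniFrac family including the absolute-abundance generalization GU^A_alpha.

The generalized UniFrac dissimilarity between samples r and s, with
per-branch masses A_i, B_i and branch lengths b_i, is

    d = sum_i b_i (A_i + B_i)^alpha |A_i - B_i| / (A_i + B_i)
        -------------------------------------------------------
        sum_i b_i (A_i + B_i)^alpha

Branches with A_i + B_i = 0 contribute to neither sum.  In *relative* mode
the masses are per-branch proportions; in *absolute* mode they are cells/ml,
so two samples with identical composition but different total biomass are
at nonzero distance — the whole point of coupling 16S profiles to
flow-cytometry cell counts.  The ratio form stays within [0, 1] and reduces
to the relative statistic whenever sample totals are equal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from ._errors import InvalidConfigError, UndefinedDiversityError
from .phylo import BranchTable

__all__ = [
    "DistanceMatrix",
    "HillProfile",
    "hill_number",
    "hill_profile",
    "rarefaction_curve",
    "unifrac",
    "similarity",
]


@dataclass
class DistanceMatrix:
    """Sample x sample dissimilarities with metric metadata."""

    values_df: pd.DataFrame
    metric: str = ""
    alpha: float = None
    mode: str = "relative"

    def __post_init__(self):
        v = self.values_df.to_numpy()
        if not np.allclose(v, v.T, atol=1e-12):
            raise InvalidConfigError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise InvalidConfigError("distance matrix diagonal is not zero")

    @property
    def sample_ids(self):
        return list(self.values_df.columns)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in scipy condensed order."""
        v = self.values_df.to_numpy()
        iu = np.triu_indices(len(v), k=1)
        return v[iu]

    def subset(self, samples) -> "DistanceMatrix":
        samples = list(samples)
        return DistanceMatrix(
            self.values_df.loc[samples, samples], self.metric, self.alpha, self.mode
        )


def hill_number(abund_column, q: float) -> float:
    """Hill number ^qD of one community (any non-negative abundances).

    ^qD = (sum p_i^q)^(1/(1-q)) for q != 1 and exp(-sum p_i ln p_i) at
    q = 1; zeros are excluded and the column is renormalized internally.
    q = 0 gives observed richness, q = 2 the inverse Simpson index.
    """
    if q < 0:
        raise InvalidConfigError("diversity order q must be >= 0")
    x = np.asarray(abund_column, dtype=float)
    x = x[x > 0]
    if x.size == 0:
        raise UndefinedDiversityError("all-zero abundance column")
    p = x / x.sum()
    if abs(q - 1.0) < 1e-9:
        return float(np.exp(-np.sum(p * np.log(p))))
    return float(np.sum(p**q) ** (1.0 / (1.0 - q)))


@dataclass
class HillProfile:
    sample_id: str
    orders: list
    values: list
    rarefaction: list = field(default_factory=list)  # [(depth, expected_richness)]


def hill_profile(abund_column, sample_id="", orders=(0, 1, 2)) -> HillProfile:
    return HillProfile(
        sample_id=sample_id,
        orders=list(orders),
        values=[hill_number(abund_column, q) for q in orders],
    )


def rarefaction_curve(counts_column, depths) -> list:
    """Expected richness at sub-sampling depths, analytically.

    E[S_m] = sum_i (1 - C(N - N_i, m) / C(N, m)) under hypergeometric
    subsampling without replacement; evaluated in log space for stability.
    Returns [(depth, expected_richness), ...]; non-decreasing in depth.
    """
    n = np.asarray(counts_column, dtype=float)
    if np.any(n < 0) or not np.allclose(n, np.round(n)):
        raise InvalidConfigError("rarefaction needs non-negative integer counts")
    n = n[n > 0]
    total = n.sum()
    out = []
    for m in depths:
        if m < 0 or m > total:
            raise InvalidConfigError(f"depth {m} exceeds total reads {int(total)}")
        # log C(N - N_i, m) - log C(N, m); term is 0 when N - N_i < m
        feasible = (total - n) >= m
        log_p = np.full(n.shape, -np.inf)
        if feasible.any():
            nf = total - n[feasible]
            log_p[feasible] = (
                gammaln(nf + 1)
                - gammaln(m + 1)
                - gammaln(nf - m + 1)
                - (gammaln(total + 1) - gammaln(m + 1) - gammaln(total - m + 1))
            )
        out.append((m, float(np.sum(1.0 - np.exp(log_p)))))
    return out


def _pair_generalized(bl, a, b, alpha):
    tot = a + b
    use = tot > 0
    if not use.any():
        return 0.0
    bl, a, b, tot = bl[use], a[use], b[use], tot[use]
    w = bl * tot**alpha
    denom = w.sum()
    if denom == 0:
        return 0.0
    return float((w * np.abs(a - b) / tot).sum() / denom)


def _pair_unweighted(bl, a, b):
    pa, pb = a > 0, b > 0
    denom = (bl * (pa | pb)).sum()
    if denom == 0:
        return 0.0
    return float((bl * (pa ^ pb)).sum() / denom)


def unifrac(
    branches: BranchTable,
    mode: str = "generalized",
    alpha: float = 0.5,
    abundance: str = None,
) -> DistanceMatrix:
    """Pairwise UniFrac distances from a :class:`BranchTable`.

    mode: 'unweighted' (presence/absence), 'weighted' (generalized with
    alpha = 1), or 'generalized'.  ``abundance`` records whether the branch
    masses are proportions or cells/ml; it defaults to the table's own mode.
    """
    if mode not in ("unweighted", "weighted", "generalized"):
        raise InvalidConfigError(f"unknown unifrac mode {mode!r}")
    if mode == "weighted":
        alpha = 1.0
    if not 0.0 <= alpha <= 1.0:
        raise InvalidConfigError(f"alpha must be in [0, 1], got {alpha}")
    abundance = abundance or branches.mode
    bl = branches.lengths
    A = branches.abundances
    ids = branches.sample_ids
    n = len(ids)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if mode == "unweighted":
                d = _pair_unweighted(bl, A[:, i], A[:, j])
            else:
                d = _pair_generalized(bl, A[:, i], A[:, j], alpha)
            out[i, j] = out[j, i] = d
    metric = {
        "unweighted": "unweighted_unifrac",
        "weighted": "weighted_unifrac",
        "generalized": "generalized_unifrac",
    }[mode]
    return DistanceMatrix(
        pd.DataFrame(out, index=ids, columns=ids),
        metric=metric,
        alpha=None if mode == "unweighted" else alpha,
        mode=abundance,
    )


def similarity(d: DistanceMatrix) -> pd.DataFrame:
    """Community similarity, 1 - dissimilarity, entrywise."""
    return 1.0 - d.values_df
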