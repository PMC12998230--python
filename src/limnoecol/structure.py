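"""Sample-level community structure from distance matrices.

UPGMA clustering with a deterministic lexicographic tie-break, dendrogram
cutting, principal coordinates analysis, one-factor PERMANOVA, a
PERMDISP-style dispersion test, and Mantel-type decay correlations against
geographic or depth separation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from ._errors import InvalidConfigError, MismatchError
from .diversity import DistanceMatrix

__all__ = [
    "Dendrogram",
    "GroupAssignment",
    "upgma",
    "cut_tree",
    "pcoa",
    "permanova",
    "dispersion_test",
    "decay_correlation",
    "haversine_km",
]

EARTH_RADIUS_KM = 6371.0088  # WGS84 mean radius


@dataclass
class Dendrogram:
    """UPGMA merge history: ``merges[t] = (left_members, right_members, height)``.

    Members are sorted tuples of leaf ids; heights are non-decreasing.
    """

    leaves: list
    merges: list

    def to_newick(self) -> str:
        rep = {(leaf,): leaf for leaf in self.leaves}
        height = {(leaf,): 0.0 for leaf in self.leaves}
        key = None
        for left, right, h in self.merges:
            lstr, rstr = rep.pop(tuple(left)), rep.pop(tuple(right))
            bl = h - height[tuple(left)]
            br = h - height[tuple(right)]
            key = tuple(sorted(left + right))
            rep[key] = f"({lstr}:{bl:.10g},{rstr}:{br:.10g})"
            height[key] = h
        if len(rep) != 1:
            # forest (shouldn't happen for a complete merge history)
            return "(" + ",".join(rep.values()) + ");"
        return next(iter(rep.values())) + ";"


@dataclass
class GroupAssignment:
    labels: pd.Series  # sample_id -> group label
    k: int

    def __post_init__(self):
        if self.labels.nunique() != self.k:
            raise InvalidConfigError(
                f"expected {self.k} non-empty groups, found {self.labels.nunique()}"
            )

    def groups(self):
        return {g: list(idx) for g, idx in self.labels.groupby(self.labels).groups.items()}


def upgma(d: DistanceMatrix) -> Dendrogram:
    """Average-linkage agglomeration with a deterministic tie-break.

    Cluster-cluster distance is the unweighted mean over cross pairs.  When
    several pairs tie at the minimum, the pair whose (smallest-leaf,
    smallest-leaf) ids sort first lexicographically is merged, making the
    result invariant under input sample order.
    """
    v = d.values_df.to_numpy(dtype=float)
    if np.isnan(v).any():
        raise InvalidConfigError("distance matrix contains NaN")
    ids = list(d.values_df.columns)
    n = len(ids)
    if n < 2:
        raise InvalidConfigError("need >= 2 samples to cluster")
    members = {i: (ids[i],) for i in range(n)}
    size = {i: 1 for i in range(n)}
    dist = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = v[i, j]
    active = set(range(n))
    merges = []
    next_id = n
    while len(active) > 1:
        best = None
        for (i, j), dij in dist.items():
            tie_key = tuple(sorted((min(members[i]), min(members[j]))))
            cand = (dij, tie_key, (i, j))
            if best is None or cand[:2] < best[:2]:
                best = cand
        dij, _, (i, j) = best
        left, right = sorted((members[i], members[j]), key=lambda m: min(m))
        merges.append((left, right, dij))
        new_members = tuple(sorted(left + right))
        for k in list(active):
            if k in (i, j):
                continue
            dik = dist.pop((min(i, k), max(i, k)))
            djk = dist.pop((min(j, k), max(j, k)))
            dist[(min(next_id, k), max(next_id, k))] = (
                size[i] * dik + size[j] * djk
            ) / (size[i] + size[j])
        del dist[(i, j)]
        active -= {i, j}
        active.add(next_id)
        members[next_id] = new_members
        size[next_id] = size[i] + size[j]
        next_id += 1
    return Dendrogram(leaves=sorted(ids), merges=merges)


def cut_tree(dend: Dendrogram, k: int) -> GroupAssignment:
    """Groups obtained by undoing the k-1 last (highest) merges."""
    n = len(dend.leaves)
    if not 1 <= k <= n:
        raise InvalidConfigError(f"k must be in [1, {n}], got {k}")
    parent = {leaf: leaf for leaf in dend.leaves}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for left, right, _ in dend.merges[: n - k]:
        a, b = find(left[0]), find(right[0])
        if a != b:
            parent[max(a, b)] = min(a, b)
    roots = sorted({find(leaf) for leaf in dend.leaves})
    label_of_root = {r: f"G{i + 1}" for i, r in enumerate(roots)}
    labels = pd.Series({leaf: label_of_root[find(leaf)] for leaf in dend.leaves})
    return GroupAssignment(labels=labels, k=k)


@dataclass
class PCoAResult:
    coordinates: pd.DataFrame  # samples x positive axes
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives reported)
    imaginary: pd.DataFrame  # samples x |negative| axes, scaled by sqrt(-lambda)


def pcoa(d: DistanceMatrix, eps: float = 1e-10) -> PCoAResult:
    """Classical MDS (Gower double centering) of a distance matrix.

    Axes with positive eigenvalues form the returned coordinates; negative
    eigenvalues are reported and their axes kept separately (needed for the
    PERMDISP imaginary-part correction) but excluded from the ordination.
    """
    v = d.values_df.to_numpy(dtype=float)
    n = len(v)
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (v**2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = eps * max(1.0, np.abs(evals).max())
    pos = evals > tol
    neg = evals < -tol
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    imag = evecs[:, neg] * np.sqrt(-evals[neg])
    ids = d.sample_ids
    return PCoAResult(
        coordinates=pd.DataFrame(
            coords, index=ids, columns=[f"PC{i + 1}" for i in range(coords.shape[1])]
        ),
        eigenvalues=evals,
        imaginary=pd.DataFrame(
            imag, index=ids, columns=[f"NC{i + 1}" for i in range(imag.shape[1])]
        ),
    )


def _ss_within(d2: np.ndarray, codes: np.ndarray, k: int) -> float:
    ss = 0.0
    for g in range(k):
        idx = np.flatnonzero(codes == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    return ss


def permanova(d: DistanceMatrix, groups: GroupAssignment, n_perm: int = 999, seed=0):
    """One-factor PERMANOVA: pseudo-F, R^2 and a permutation p-value.

    SS_total = sum of squared distances over all pairs / n; SS_within is the
    analogous per-group sum; R^2 = 1 - SS_within/SS_total; the p-value uses
    the (1 + #{F_perm >= F_obs}) / (1 + n_perm) estimator under random
    relabeling of samples.
    """
    labels = groups.labels.reindex(d.sample_ids)
    if labels.isna().any():
        raise MismatchError("group assignment does not cover all samples")
    counts = labels.value_counts()
    if len(counts) < 2:
        raise InvalidConfigError("need >= 2 groups")
    if (counts < 2).any():
        raise InvalidConfigError("every group needs >= 2 samples")
    codes, _ = pd.factorize(labels)
    k = len(counts)
    n = len(codes)
    d2 = d.values_df.to_numpy(dtype=float) ** 2
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n

    def f_stat(c):
        ss_w = _ss_within(d2, c, k)
        ss_b = ss_total - ss_w
        return (ss_b / (k - 1)) / (ss_w / (n - k)), ss_w

    f_obs, ss_w = f_stat(codes)
    r2 = 1.0 - ss_w / ss_total
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        f_p, _ = f_stat(rng.permutation(codes))
        if f_p >= f_obs:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return float(f_obs), float(r2), float(p)


def dispersion_test(d: DistanceMatrix, groups: GroupAssignment, n_perm: int = 999, seed=0):
    """PERMDISP-style homogeneity-of-dispersions test.

    Each sample's distance to its own group centroid is computed in full
    PCoA space; squared contributions of negative-eigenvalue axes are
    subtracted and the result floored at zero before the square root.  The
    F statistic is a one-way ANOVA on those distances; the p-value permutes
    the distances across groups.  Returns (F, p, per-group mean dispersion).
    """
    labels = groups.labels.reindex(d.sample_ids)
    if labels.isna().any():
        raise MismatchError("group assignment does not cover all samples")
    counts = labels.value_counts()
    if len(counts) < 2 or (counts < 2).any():
        raise InvalidConfigError("need >= 2 groups with >= 2 samples each")
    res = pcoa(d)
    real = res.coordinates.to_numpy()
    imag = res.imaginary.to_numpy()
    z = np.empty(len(labels))
    for g, idx in labels.groupby(labels).groups.items():
        rows = [d.sample_ids.index(s) for s in idx]
        cr = real[rows].mean(axis=0)
        ci = imag[rows].mean(axis=0) if imag.size else np.zeros(0)
        for r in rows:
            z2 = ((real[r] - cr) ** 2).sum()
            if imag.size:
                z2 -= ((imag[r] - ci) ** 2).sum()
            z[r] = np.sqrt(max(z2, 0.0))
    codes, uniq = pd.factorize(labels)
    k, n = len(uniq), len(codes)

    def anova_f(zv, c):
        grand = zv.mean()
        ssb = sum(
            (c == g).sum() * (zv[c == g].mean() - grand) ** 2 for g in range(k)
        )
        ssw = sum(((zv[c == g] - zv[c == g].mean()) ** 2).sum() for g in range(k))
        if ssw == 0:
            return np.inf if ssb > 0 else 0.0
        return (ssb / (k - 1)) / (ssw / (n - k))

    f_obs = anova_f(z, codes)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if anova_f(z[rng.permutation(n)], codes) >= f_obs:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    disp = pd.Series(z, index=labels.index).groupby(labels).mean()
    return float(f_obs), float(p), disp


def _spearman_condensed(x_rank: np.ndarray, y: np.ndarray) -> float:
    y_rank = rankdata(y)
    xm, ym = x_rank - x_rank.mean(), y_rank - y_rank.mean()
    denom = np.sqrt((xm**2).sum() * (ym**2).sum())
    if denom == 0:
        raise InvalidConfigError("constant covariate: Spearman rho undefined")
    return float((xm * ym).sum() / denom)


def decay_correlation(sim: pd.DataFrame, covariate: pd.DataFrame, n_perm: int = 999, seed=0):
    """Mantel test (Spearman) between a similarity matrix and a covariate.

    ``sim`` and ``covariate`` are symmetric sample x sample DataFrames over
    the same ids.  rho is computed over upper-triangle pairs; the p-value
    (two-sided) permutes rows/columns of the covariate jointly.
    """
    if list(sim.columns) != list(covariate.columns):
        covariate = covariate.loc[sim.columns, sim.columns]
    s = sim.to_numpy(dtype=float)
    c = covariate.to_numpy(dtype=float)
    n = len(s)
    iu = np.triu_indices(n, k=1)
    s_rank = rankdata(s[iu])
    rho = _spearman_condensed(s_rank, c[iu])
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        cp = c[np.ix_(perm, perm)]
        if abs(_spearman_condensed(s_rank, cp[iu])) >= abs(rho) - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return float(rho), float(p)


def haversine_km(lat, lon) -> pd.DataFrame:
    """Pairwise great-circle distances (km) from latitude/longitude Series."""
    lat = pd.Series(lat)
    lon = pd.Series(lon).reindex(lat.index)
    phi = np.radians(lat.to_numpy(dtype=float))
    lam = np.radians(lon.to_numpy(dtype=float))
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    a = np.sin(dphi / 2) ** 2 + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlam / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=lat.index, columns=lat.index)
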