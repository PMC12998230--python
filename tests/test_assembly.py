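"""Phylogenetic binning, betaMPD/betaNRI, RC_Bray, process classification."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from limnoecol._errors import InvalidConfigError
from limnoecol.assembly import (
    NullModelConfig,
    PhyloBin,
    aggregate_groups,
    analyze_pairs,
    beta_mpd,
    beta_nri,
    bin_abundance_cv,
    bin_phylogeny,
    classify_process,
    process_fractions,
    rc_bray,
)
from limnoecol.phylo import cophenetic, parse_newick
from limnoecol.simulate import SimulationConfig, simulate_tree

from conftest import random_tree


@pytest.fixture
def cfg200():
    return NullModelConfig(n_null=200, seed=0)


def _two_clade_tree(n_per_clade=30, inner=0.005, stem=0.5):
    """Two tight clades (diameter << 0.5) separated by long stems."""
    from skbio import TreeNode

    def clade(prefix):
        tips = [TreeNode(name=f"{prefix}{i}", length=inner) for i in range(n_per_clade)]
        while len(tips) > 1:
            a, b = tips.pop(0), tips.pop(0)
            p = TreeNode(length=inner)
            p.extend([a, b])
            tips.append(p)
        tips[0].length = stem
        return tips[0]

    root = TreeNode()
    root.extend([clade("A"), clade("B")])
    return root


class TestConfig:
    def test_z_star_from_confidence(self):
        assert NullModelConfig().z_star == pytest.approx(1.959964, abs=1e-6)

    @pytest.mark.parametrize("kw", [dict(confidence=0.4), dict(confidence=1.0),
                                    dict(n_null=10), dict(bin_size_limit=0)])
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(InvalidConfigError):
            NullModelConfig(**kw)


class TestBinPhylogeny:
    def test_two_clades_give_two_bins(self):
        tree = _two_clade_tree(30)
        bins = bin_phylogeny(tree, NullModelConfig(bin_size_limit=24, ds=0.5))
        assert len(bins) == 2
        assert sorted(len(b.members) for b in bins) == [30, 30]
        assert all(b.max_within_distance <= 0.5 for b in bins)

    def test_star_tree_single_bin(self):
        tree = parse_newick("(" + ",".join(f"t{i}:0.2" for i in range(30)) + ");")
        bins = bin_phylogeny(tree, NullModelConfig(bin_size_limit=24, ds=0.5))
        assert len(bins) == 1 and len(bins[0].members) == 30

    def test_too_few_tips_single_bin_with_warning(self):
        rng = np.random.default_rng(1)
        tree = random_tree(rng, 10)
        with pytest.warns(UserWarning):
            bins = bin_phylogeny(tree, NullModelConfig(bin_size_limit=24))
        assert len(bins) == 1

    def test_partition_covers_all_taxa_once(self):
        tree = simulate_tree(SimulationConfig(seed=2, n_taxa=200))
        bins = bin_phylogeny(tree, NullModelConfig())
        members = [t for b in bins for t in b.members]
        assert len(members) == 200 and len(set(members)) == 200
        assert all(len(b.members) >= 24 for b in bins)
        assert len(bins) >= 2


class TestBetaMpd:
    def test_identical_single_taxon_zero(self):
        assert beta_mpd([1.0], [1.0], [[0.0]]) == 0.0

    def test_two_taxa_full_turnover(self):
        d = [[0.0, 2.0], [2.0, 0.0]]
        assert beta_mpd([1.0, 0.0], [0.0, 1.0], d) == pytest.approx(2.0)

    def test_uniform_weights_give_mean_distance(self):
        rng = np.random.default_rng(2)
        m = 8
        d = rng.uniform(0, 3, (m, m))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        u = np.ones(m)
        # brute-force double loop oracle
        oracle = sum(d[i, j] for i in range(m) for j in range(m)) / m**2
        assert beta_mpd(u, u, d) == pytest.approx(oracle, rel=1e-12)


class TestBetaNri:
    def test_degenerate_null_flagged(self, cfg200):
        v, degen = beta_nri([1.0], [1.0], [[0.0]], cfg200)
        assert v == 0.0 and degen

    def test_label_shuffled_data_is_standard_normal(self):
        rng = np.random.default_rng(3)
        tree = simulate_tree(SimulationConfig(seed=5, n_taxa=100))
        d = cophenetic(tree)
        taxa = list(d.index)[:30]
        dsub = d.loc[taxa, taxa].to_numpy()
        cfg = NullModelConfig(n_null=200, seed=0)
        fa0 = rng.dirichlet(np.ones(30) * 0.5)
        fb0 = rng.dirichlet(np.ones(30) * 0.5)
        vals = [
            beta_nri(fa0[rng.permutation(30)], fb0[rng.permutation(30)],
                     dsub, cfg, rng=np.random.default_rng([5, i]))[0]
            for i in range(150)
        ]
        vals = np.array(vals)
        assert abs(vals.mean()) < 0.2
        assert 0.85 < vals.std(ddof=1) < 1.15


class TestRcBray:
    def test_identical_compositions_near_minus_one(self, cfg200):
        c = np.array([50, 30, 20, 10, 5])
        occ = np.full(5, 0.8)
        mra = c / c.sum()
        rc = rc_bray(c, c, occ, mra, cfg200, rng=np.random.default_rng(0))
        assert rc < -0.9

    def test_disjoint_taxa_near_plus_one(self, cfg200):
        # 8 taxa, richness 4 vs 4: a disjoint null pair arises with
        # probability 1/C(8,4), so the observed BC = 1 tops the null
        a = np.array([50, 50, 50, 50, 0, 0, 0, 0])
        b = np.array([0, 0, 0, 0, 50, 50, 50, 50])
        occ = np.full(8, 0.5)
        mra = np.full(8, 0.125)
        rc = rc_bray(a, b, occ, mra, cfg200, rng=np.random.default_rng(1))
        assert rc > 0.9

    def test_bounded_for_random_inputs(self, cfg200):
        rng = np.random.default_rng(2)
        for _ in range(10):
            m = int(rng.integers(3, 10))
            a = rng.integers(0, 50, m)
            b = rng.integers(0, 50, m)
            if a.sum() == 0 or b.sum() == 0:
                continue
            occ = rng.uniform(0.1, 1, m)
            mra = rng.dirichlet(np.ones(m))
            rc = rc_bray(a, b, occ, mra, cfg200, rng=rng)
            assert -1.0 <= rc <= 1.0


class TestClassifyProcess:
    @pytest.mark.parametrize("bnri,rc,expected", [
        (-3.0, 0.99, "homogenizing_selection"),
        (3.0, -0.99, "heterogeneous_selection"),
        (0.0, 0.99, "dispersal_limitation"),
        (0.0, -0.99, "homogenizing_dispersal"),
        (0.0, 0.0, "drift"),
        (1.9, 0.0, "drift"),
    ])
    def test_rule_table(self, bnri, rc, expected):
        assert classify_process(bnri, rc, NullModelConfig()) == expected


class TestFractionsAndAggregation:
    def _pair_df(self, rows):
        return pd.DataFrame(rows)

    def test_single_bin_drift_gives_unit_fraction(self):
        df = self._pair_df([dict(sample_a="a", sample_b="b", bin_id="bin01",
                                 beta_nri=0.0, rc_bray=0.0, process="drift",
                                 weight=1.0, degenerate_null=False)])
        fr = process_fractions(df)
        assert fr.loc[("a", "b"), "drift"] == pytest.approx(1.0)

    def test_two_equal_bins_split_half_half(self):
        df = self._pair_df([
            dict(sample_a="a", sample_b="b", bin_id="bin01", beta_nri=-3.0,
                 rc_bray=0.0, process="homogenizing_selection", weight=0.5,
                 degenerate_null=False),
            dict(sample_a="a", sample_b="b", bin_id="bin02", beta_nri=0.0,
                 rc_bray=0.0, process="drift", weight=0.5,
                 degenerate_null=False),
        ])
        fr = process_fractions(df)
        assert fr.loc[("a", "b"), "homogenizing_selection"] == pytest.approx(0.5)
        assert fr.loc[("a", "b"), "drift"] == pytest.approx(0.5)

    def test_fractions_sum_to_one_on_synthetic_pairs(self):
        tree = simulate_tree(SimulationConfig(seed=7, n_taxa=96))
        rng = np.random.default_rng(7)
        taxa = sorted(t.name for t in tree.tips())
        counts = pd.DataFrame(
            rng.integers(0, 60, size=(len(taxa), 8)), index=taxa,
            columns=[f"s{i}" for i in range(8)],
        )
        df = analyze_pairs(tree, counts, NullModelConfig(n_null=100, seed=1))
        fr = process_fractions(df)
        assert np.allclose(fr.sum(axis=1), 1.0, atol=1e-9)

    def test_aggregation_strata_and_counts(self):
        rows = []
        samples = ["a1", "a2", "a3", "b1", "b2"]
        for i in range(len(samples)):
            for j in range(i + 1, len(samples)):
                rows.append(dict(sample_a=samples[i], sample_b=samples[j],
                                 bin_id="bin01", beta_nri=0.0, rc_bray=0.0,
                                 process="drift", weight=1.0,
                                 degenerate_null=False))
        labels = pd.Series({"a1": "A", "a2": "A", "a3": "A", "b1": "B", "b2": "B"})
        agg = aggregate_groups(pd.DataFrame(rows), labels)
        assert agg.loc["within:A", "n_pairs"] == 3  # C(3,2)
        assert agg.loc["within:B", "n_pairs"] == 1  # C(2,2)
        assert agg.loc["between:A|B", "n_pairs"] == 6  # 3*2
        assert agg.loc["within:A", "drift"] == pytest.approx(1.0)


class TestBinAbundanceCv:
    def test_constant_bin_zero_cv(self):
        bins = [PhyloBin("bin01", ["a", "b"], 0.1)]
        abund = pd.DataFrame({"s1": [1.0, 2.0], "s2": [2.0, 1.0]}, index=["a", "b"])
        out = bin_abundance_cv(bins, abund)
        assert out.loc["bin01", "cv"] == pytest.approx(0.0)

    def test_hand_cv(self):
        bins = [PhyloBin("bin01", ["a"], 0.0)]
        abund = pd.DataFrame({"s1": [50.0], "s2": [150.0]}, index=["a"])
        out = bin_abundance_cv(bins, abund)
        assert out.loc["bin01", "mean_abundance"] == pytest.approx(100.0)
        assert out.loc["bin01", "cv"] == pytest.approx(0.70710678, rel=1e-6)

    def test_mean_cv_negatively_associated_for_lognormal_pools(self):
        # common-pool lognormal abundances with proportional sampling noise:
        # high-mean bins fluctuate relatively less across samples
        rng = np.random.default_rng(9)
        n_bins, n_samples = 30, 40
        means = np.exp(rng.normal(4, 1.5, n_bins))
        abund = means[:, None] * np.exp(rng.normal(0, 0.3, (n_bins, n_samples))) \
            + rng.exponential(30.0, (n_bins, n_samples))
        df = pd.DataFrame(abund, index=[f"t{i}" for i in range(n_bins)],
                          columns=[f"s{j}" for j in range(n_samples)])
        bins = [PhyloBin(f"bin{i:02d}", [f"t{i}"], 0.0) for i in range(n_bins)]
        out = bin_abundance_cv(bins, df)
        rho, _ = spearmanr(out["mean_abundance"], out["cv"])
        assert rho < -0.4
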