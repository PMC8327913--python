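"""Tests of read-cloud sharing statistics and four-gamete classification."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from strainsweep import synthetic
from strainsweep.linkage import (
    LD_DISTANCE_BINS,
    classify_ld,
    classify_pairs,
    poisson_binomial_tail,
    shared_cloud_counts,
    sharing_by_distance,
)
from strainsweep.linkage import test_pair_sharing as pair_sharing_pvalue
from strainsweep.read_clouds import ImpurityModel, fit_impurity_model

from conftest import make_cloud_set


def _tiny_panel():
    return pd.DataFrame(
        {
            "species": ["s0", "s0", "s0"],
            "contig": ["c0", "c0", "c1"],
            "pos": [100, 1100, 500],
            "ref": ["A", "C", "G"],
            "alt": ["G", "T", "A"],
            "degeneracy": ["1D", "4D", "4D"],
            "prev_ref": [0.9, 0.9, 0.9],
            "prev_alt": [0.1, 0.1, 0.1],
        },
        index=pd.Index([0, 1, 2], name="snv_id"),
    )


def _tiny_model(n_clouds=10, F=1.0):
    return ImpurityModel(
        species_weights=pd.DataFrame({"s0": [1.0]}, index=[0.0]),
        detection_rates=pd.Series({"s0": 1.0}),
        bin_centers=np.array([1.0, 100.0]),
        bin_F=np.array([F, F]),
        n_clouds=n_clouds,
        cloud_D=np.full(n_clouds, 10),
        sum_F=F * n_clouds,
    )


class TestPoissonBinomialTail:
    def test_exact_enumeration(self):
        assert poisson_binomial_tail([0.5, 0.5, 0.5], 3) == pytest.approx(0.125)
        assert poisson_binomial_tail([0.5, 0.5, 0.5], 1) == pytest.approx(0.875)

    def test_observed_zero_is_one(self):
        assert poisson_binomial_tail([0.2] * 5, 0) == 1.0

    def test_poisson_branch_close_to_exact(self):
        ps = np.full(19, 0.02)
        exact = poisson_binomial_tail(ps, 3, exact_max=20)
        approx = poisson_binomial_tail(ps, 3, exact_max=5)
        assert approx == pytest.approx(exact, rel=0.25)


class TestSharedCloudCounts:
    def test_no_shared_clouds(self):
        rows = [
            (0.0, "B1", "s0", "c0", 100, "ref", 0, "g0"),
            (0.0, "B2", "s0", "c0", 1100, "alt", 1, "g1"),
        ]
        table = shared_cloud_counts(0, 1, make_cloud_set(rows), _tiny_panel())
        assert table.total_shared == 0
        assert table.cells.sum() == 0
        assert table.distance == 1000.0

    def test_fragment_contributes_to_alt_alt_cell(self):
        rows = [
            (0.0, "B1", "s0", "c0", 100, "alt", 0, "g0"),
            (0.0, "B1", "s0", "c0", 1100, "alt", 1, "g1"),
        ]
        table = shared_cloud_counts(0, 1, make_cloud_set(rows), _tiny_panel())
        assert table.total_shared == 1
        assert table.cells[1, 1] == 1 and table.cells.sum() == 1

    def test_tied_cloud_dropped_from_cells(self):
        rows = [
            (0.0, "B1", "s0", "c0", 100, "alt", 0, "g0"),
            (0.0, "B1", "s0", "c0", 100, "ref", 0, "g0"),
            (0.0, "B1", "s0", "c0", 1100, "alt", 1, "g1"),
        ]
        table = shared_cloud_counts(0, 1, make_cloud_set(rows), _tiny_panel())
        assert table.total_shared == 1
        assert table.cells.sum() == 0

    def test_cross_contig_distance_undefined(self):
        rows = [
            (0.0, "B1", "s0", "c0", 100, "alt", 0, "g0"),
            (0.0, "B1", "s0", "c1", 500, "alt", 2, "g9"),
        ]
        table = shared_cloud_counts(0, 2, make_cloud_set(rows), _tiny_panel())
        assert table.distance is None
        assert table.total_shared == 1

    def test_two_strain_clonal_fragments_fill_two_cells_only(self, impure_community):
        community, panel, clouds, focal = impure_community
        # restrict to ground-truth pure-fragment evidence: per fragment,
        # alleles at two sites always match the strain haplotype (AB or ab)
        reads = clouds.reads
        snv_reads = reads[(reads["snv_id"] >= 0) & (reads["species"] == focal)]
        per_frag = snv_reads.groupby("fragment")["allele"].nunique()
        assert (per_frag == 1).all()


class TestPairSharing:
    def test_zero_observed_gives_p_one(self):
        table_rows = [(0.0, "B1", "s0", "c0", 100, "alt", 0, "g0")]
        table = shared_cloud_counts(0, 1, make_cloud_set(table_rows), _tiny_panel())
        assert pair_sharing_pvalue(table, _tiny_model()) == 1.0

    def test_exact_tail_on_small_cloud_sets(self):
        # 3 clouds, each with per-cloud probability 0.5, observed 3 -> 1/8
        model = _tiny_model(n_clouds=3, F=2.0)
        table = shared_cloud_counts(0, 1, make_cloud_set(
            [(0.0, f"B{i}", "s0", "c0", 100, "alt", 0, "g0") for i in range(3)]
            + [(0.0, f"B{i}", "s0", "c0", 1100, "alt", 1, "g1") for i in range(3)]
        ), _tiny_panel())
        # detection rates are 1.0 each; per-cloud P = 1 * 1 * F = 2 -> clip to 0.5
        model.bin_F = np.array([0.5, 0.5])
        model.cloud_D = np.full(3, 10)
        model.sum_F = 1.5
        assert pair_sharing_pvalue(table, model) == pytest.approx(0.125)

    def test_pvalues_uniform_under_pure_impurity(self):
        """Sharing p-values on well-separated SNVs (no physical linkage,
        clouds shared only through impurity) are approximately uniform."""
        cfg = synthetic.CommunityConfig(
            n_species=3, timepoints=[0.0], abundance_sigma=0.2, noise_sigma=0.0,
            seed=21)
        community = synthetic.simulate_community(cfg)
        focal = community.iloc[:, 0].idxmax()
        # 10 SNVs spaced ~30 kb apart; fragments capped at 15 kb
        panel = _tiny_panel().iloc[:0]
        panel = pd.DataFrame({
            "species": focal, "contig": "c0",
            "pos": 15_000 + 30_000 * np.arange(10),
            "ref": "A", "alt": "G", "degeneracy": "4D",
            "prev_ref": 0.9, "prev_alt": 0.1,
            "strain1_alt": False, "strain2_alt": True,
        }, index=pd.Index(range(10), name="snv_id"))
        cloud_cfg = synthetic.CloudConfig(
            n_clouds=4000, mean_fragments=7.0, reads_per_fragment=4.0,
            genome_length=320_000, fragment_length=8000.0)
        clouds = synthetic.simulate_read_clouds(community, panel, cloud_cfg, seed=22)
        # cap fragment geometry: drop ground-truth long-fragment co-occurrence
        reads = clouds.reads
        model = fit_impurity_model(clouds)

        from strainsweep.linkage import _site_incidence
        m, _, _ = _site_incidence(clouds, panel.index.to_numpy())
        shared = (m @ m.T).toarray()
        site_rate = np.asarray(m.sum(axis=1)).ravel() / clouds.n_clouds
        from scipy.stats import poisson
        iu, ju = np.triu_indices(10, k=1)
        keep = np.abs(panel["pos"].to_numpy()[iu] - panel["pos"].to_numpy()[ju]) > 25_000
        lam = site_rate[iu] * site_rate[ju] * model.sum_F
        # mid-p style smoothing of the discrete Poisson tail for the KS check
        rng = np.random.default_rng(23)
        obs = shared[iu, ju]
        p_hi = poisson.sf(obs - 1, lam)
        p_lo = poisson.sf(obs, lam)
        pvals = (p_lo + rng.uniform(size=len(obs)) * (p_hi - p_lo))[keep]
        assert kstest(pvals, "uniform").pvalue > 0.01


class TestClassifyLd:
    @pytest.mark.parametrize("cells,expected", [
        (np.array([[40, 0], [0, 40]]), "two_haplotypes"),
        (np.array([[40, 40], [0, 40]]), "three_haplotypes"),
        (np.array([[40, 40], [40, 40]]), "four_haplotypes"),
    ])
    def test_categories(self, cells, expected):
        model = _tiny_model(n_clouds=1000, F=1.0)
        table = shared_cloud_counts(0, 1, make_cloud_set(
            [(0.0, "B0", "s0", "c0", 100, "alt", 0, "g0")]), _tiny_panel())
        table.cells = cells
        table.allele_rates_i = np.array([0.01, 0.01])
        table.allele_rates_j = np.array([0.01, 0.01])
        call = classify_ld(table, model, alpha=0.05)
        assert call.category == expected
        if expected == "four_haplotypes":
            assert (call.cell_p < 0.05).all()

    def test_classify_pairs_maf_filter(self, impure_community):
        community, panel, clouds, focal = impure_community
        model = fit_impurity_model(clouds)
        calls = classify_pairs(panel, clouds, model, min_shared=5)
        # strains at 50/50: all SNVs pass the MAF filter, pairs exist
        assert len(calls) > 0
        # clonal two-strain data: four-haplotype calls must be rare
        classified = calls[calls["category"] != "not_classified"]
        four = classified[(classified["category"] == "four_haplotypes")
                          & (classified["q_value"] < 0.05)]
        assert len(four) <= max(1, int(0.05 * len(classified)))


class TestSharingByDistance:
    def test_single_snv_gives_empty_table(self, impure_community):
        _, panel, clouds, _ = impure_community
        out = sharing_by_distance(panel.iloc[:1], clouds)
        assert len(out) == 0

    def test_near_pairs_share_more(self, impure_community):
        _, panel, clouds, _ = impure_community
        out = sharing_by_distance(panel, clouds)
        assert out["fraction_sharing"].iloc[0] >= out["fraction_sharing"].iloc[-1]

    def test_requested_distance_categories(self, impure_community):
        _, panel, clouds, _ = impure_community
        out = sharing_by_distance(panel, clouds, bins=LD_DISTANCE_BINS)
        assert (out["bin_low"].isin([0.0, 200.0, 2000.0])).all()
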