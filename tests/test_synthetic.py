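"""Tests of the synthetic community / trajectory / read-cloud generators."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit
from scipy.stats import binom, chisquare

from strainsweep import synthetic
from strainsweep.synthetic import (
    CloudConfig,
    CommunityConfig,
    WrightFisherParams,
    simulate_allele_counts,
    simulate_community,
    simulate_read_clouds,
    simulate_strain_panel,
    simulate_strain_trajectory,
)


class TestCommunity:
    def test_single_species_is_all_the_community(self):
        cfg = CommunityConfig(n_species=1, timepoints=[0.0, 1.0, 2.0], seed=0)
        table = simulate_community(cfg)
        assert np.allclose(table.to_numpy(), 1.0)

    def test_columns_sum_to_one(self):
        cfg = CommunityConfig(n_species=50, timepoints=[0.0, 7.0, 14.0], seed=3)
        table = simulate_community(cfg)
        assert np.allclose(table.sum(axis=0), 1.0)
        assert (table.to_numpy() >= 0).all()

    def test_perturbation_log_fold_effect_at_zero_noise(self):
        cfg = CommunityConfig(
            n_species=50, timepoints=[0.0, 10.0, 20.0, 60.0],
            perturbation_window=(5.0, 15.0), perturbation_effects={4: -2.0},
            noise_sigma=0.0, seed=11,
        )
        raw = simulate_community(cfg, normalize=False)
        in_window = raw.iloc[4][10.0] / raw.iloc[4][0.0]
        assert in_window == pytest.approx(1e-2, rel=1e-9)
        # relaxation back toward baseline afterwards
        assert raw.iloc[4][60.0] > raw.iloc[4][10.0]

    def test_fixed_seed_reproducible(self):
        cfg = CommunityConfig(n_species=12, timepoints=[0.0, 5.0], seed=9)
        a = simulate_community(cfg)
        b = simulate_community(cfg)
        pd.testing.assert_frame_equal(a, b)

    @pytest.mark.parametrize("kwargs", [
        {"n_species": 0, "timepoints": [0.0]},
        {"n_species": 5, "timepoints": []},
        {"n_species": 5, "timepoints": [0.0, 5.0], "perturbation_window": (-1.0, 2.0)},
    ])
    def test_invalid_configuration_raises(self, kwargs):
        with pytest.raises(ValueError):
            simulate_community(CommunityConfig(**kwargs))


class TestStrainTrajectory:
    def test_no_dynamics_without_selection_or_drift(self):
        params = WrightFisherParams(f0=0.3)
        f = simulate_strain_trajectory(params, [0.0, 1.0, 5.0], seed=0)
        assert np.allclose(f, 0.3)

    def test_logistic_closed_form(self):
        # s = 1/day, f0 = 0.1, t = 2 d: logit f(2) = logit(0.1) + 2
        params = WrightFisherParams(f0=0.1, s_schedule=((0.0, 1.0),), dt_sim=1e-3)
        f = simulate_strain_trajectory(params, [0.0, 2.0], seed=0)
        expected = expit(logit(0.1) + 2.0)
        assert f[1] == pytest.approx(expected, abs=1e-6)
        assert f[1] == pytest.approx(0.451, abs=1e-3)

    def test_neutral_drift_is_a_martingale(self):
        params = WrightFisherParams(
            f0=0.4, ne_schedule=((0.0, 300.0),), dt_sim=0.5)
        f = simulate_strain_trajectory(params, [0.0, 7.0, 14.0, 21.0], seed=123,
                                       n_reps=2000)
        # mean final frequency stays near f0; MC error ~ sd/sqrt(n)
        sd = f[:, -1].std()
        assert abs(f[:, -1].mean() - 0.4) < 4 * sd / np.sqrt(2000)

    def test_dt_larger_than_gap_rejected(self):
        params = WrightFisherParams(f0=0.5, dt_sim=5.0)
        with pytest.raises(ValueError):
            simulate_strain_trajectory(params, [0.0, 1.0], seed=0)

    def test_absorbing_boundaries(self):
        params = WrightFisherParams(f0=0.0, s_schedule=((0.0, 5.0),))
        f = simulate_strain_trajectory(params, [0.0, 10.0], seed=0)
        assert f[1] == 0.0


class TestAlleleCounts:
    def test_degenerate_frequencies(self):
        D = np.full(5, 30)
        assert (simulate_allele_counts(np.zeros(5), D, seed=0) == 0).all()
        assert (simulate_allele_counts(np.ones(5), D, seed=0) == D).all()

    def test_binomial_moments(self, rng):
        A = simulate_allele_counts(np.full(10_000, 0.5), np.full(10_000, 100), seed=rng)
        assert A.mean() == pytest.approx(50.0, abs=0.5)
        assert A.var() == pytest.approx(25.0, rel=0.1)

    def test_binomial_goodness_of_fit(self, rng):
        D, f = 20, 0.3
        draws = simulate_allele_counts(np.full(10_000, f), np.full(10_000, D), seed=rng)
        ks = np.arange(D + 1)
        expected = binom.pmf(ks, D, f) * 10_000
        # pool tail bins so expected counts stay above ~5
        keep = expected >= 5
        obs = np.array([np.sum(draws == k) for k in ks])
        obs_p = np.concatenate([obs[keep], [obs[~keep].sum()]])
        exp_p = np.concatenate([expected[keep], [expected[~keep].sum()]])
        stat, p = chisquare(obs_p, exp_p * obs_p.sum() / exp_p.sum())
        assert p > 0.01

    def test_out_of_range_frequency_rejected(self):
        with pytest.raises(ValueError):
            simulate_allele_counts([1.2], [10], seed=0)


class TestStrainPanel:
    def test_private_markers_have_zero_prevalence(self):
        cfg = synthetic.StrainPanelConfig(n_snvs=40, private_marker_count=5)
        panel = simulate_strain_panel(cfg, seed=2)
        prev = panel[["prev_ref", "prev_alt"]].to_numpy()
        private = (prev == 0).any(axis=1)
        assert private.sum() == 10  # 5 per strain
        # strain 1 markers: reference allele unseen in the cohort
        assert (panel["prev_ref"].iloc[:5] == 0).all()
        assert (panel["prev_alt"].iloc[5:10] == 0).all()

    def test_shared_snvs_on_both_strains(self):
        cfg = synthetic.StrainPanelConfig(n_snvs=10, n_shared_between_strains=4)
        panel = simulate_strain_panel(cfg, seed=2)
        shared = panel[panel["strain1_alt"] & panel["strain2_alt"]]
        assert len(shared) == 4


class TestReadClouds:
    def test_single_fragment_clouds_are_pure(self, impure_community):
        community, panel, _, _ = impure_community
        cfg = CloudConfig(n_clouds=200, mean_fragments=1.0, reads_per_fragment=4.0)
        clouds = simulate_read_clouds(community, panel, cfg, seed=1)
        spc = clouds.species_per_cloud()
        assert (spc.groupby("cloud").size() == 1).all()

    def test_impure_clouds_detect_multiple_species(self):
        cfg = CommunityConfig(n_species=50, timepoints=[0.0], abundance_sigma=0.5,
                              seed=4)
        community = simulate_community(cfg)
        panel = simulate_strain_panel(
            synthetic.StrainPanelConfig(n_snvs=5), seed=0,
            species=community.index[0])
        clouds = simulate_read_clouds(
            community, panel, CloudConfig(n_clouds=400, mean_fragments=7.0), seed=2)
        k = clouds.species_per_cloud().groupby("cloud").size()
        assert k.median() > 1

    def test_fragment_cooccurrence_and_distance_decay(self, impure_community):
        community, panel, clouds, focal = impure_community
        reads = clouds.reads
        snv_reads = reads[reads["snv_id"] >= 0]
        # two SNVs on one simulated fragment always co-occur in its cloud
        per_frag = snv_reads.groupby("fragment")["snv_id"].nunique()
        multi = per_frag[per_frag >= 2].index[:5]
        for frag in multi:
            sub = reads[reads["fragment"] == frag]
            assert sub["barcode"].nunique() == 1

        # sharing decays with distance: ~1 kb pairs share more than ~50 kb
        from strainsweep.linkage import _site_incidence
        ids = panel.index.to_numpy()
        m, _, _ = _site_incidence(clouds, ids)
        shared = (m @ m.T).toarray()
        pos = panel["pos"].to_numpy()
        dist = np.abs(pos[:, None] - pos[None, :])
        iu = np.triu_indices(len(ids), k=1)
        near = shared[iu][dist[iu] < 2000]
        far = shared[iu][dist[iu] > 15_000]
        assert near.mean() > far.mean()

    def test_invalid_fragment_length(self, impure_community):
        community, panel, _, _ = impure_community
        with pytest.raises(ValueError):
            simulate_read_clouds(community, panel,
                                 CloudConfig(fragment_length=-1.0), seed=0)

    def test_fixed_seed_reproducible(self, impure_community):
        community, panel, _, _ = impure_community
        cfg = CloudConfig(n_clouds=100)
        a = simulate_read_clouds(community, panel, cfg, seed=42)
        b = simulate_read_clouds(community, panel, cfg, seed=42)
        pd.testing.assert_frame_equal(a.reads, b.reads)
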