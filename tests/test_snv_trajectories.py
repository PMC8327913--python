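"""Tests of frequency estimation, polarization, sweep detection, backbone
confirmation and diversity summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strainsweep.snv_trajectories import (
    AlleleCountTable,
    apply_inclusion_rule,
    confirm_backbone,
    detect_snv_differences,
    estimate_frequencies,
    flip_snvs,
    intermediate_diversity,
    jensen_shannon_distance,
    polarize_by_cohort,
)

from conftest import make_cloud_set


def make_table(A, D, times=None, prev_alt=None, species="s0"):
    A = np.atleast_2d(np.asarray(A))
    D = np.atleast_2d(np.asarray(D))
    n, T = A.shape
    times = list(map(float, times if times is not None else range(T)))
    idx = pd.Index(range(n), name="snv_id")
    panel = pd.DataFrame(
        {
            "species": species, "contig": "c0", "pos": 100 * (np.arange(n) + 1),
            "ref": "A", "alt": "G", "degeneracy": "4D",
            "prev_ref": 1.0 - (prev_alt if prev_alt is not None else np.full(n, 0.1)),
            "prev_alt": prev_alt if prev_alt is not None else np.full(n, 0.1),
        },
        index=idx,
    )
    return AlleleCountTable(panel, pd.DataFrame(A, index=idx, columns=times),
                            pd.DataFrame(D, index=idx, columns=times))


class TestFrequencies:
    def test_plugin_estimator(self):
        t = make_table([[0, 5, 3]], [[10, 10, 3]])
        f = estimate_frequencies(t, min_depth=10)
        assert f.iloc[0, 0] == 0.0
        assert f.iloc[0, 1] == 0.5
        assert np.isnan(f.iloc[0, 2])  # depth below threshold -> missing

    def test_table_invariants(self):
        with pytest.raises(ValueError):
            make_table([[5]], [[3]])  # A > D
        with pytest.raises(ValueError):
            make_table([[1, 1]], [[2, 2]], times=[3.0, 1.0])  # non-increasing


class TestPolarization:
    def test_majority_alt_is_flipped(self):
        t = make_table([[8, 2]], [[10, 10]], prev_alt=np.array([0.9]))
        out, record = polarize_by_cohort(t)
        assert record["flipped"].iloc[0]
        assert out.A.iloc[0, 0] == 2  # A <- D - A
        assert out.panel["prev_alt"].iloc[0] == pytest.approx(0.1)

    def test_minority_alt_unchanged(self):
        t = make_table([[8, 2]], [[10, 10]], prev_alt=np.array([0.1]))
        out, record = polarize_by_cohort(t)
        assert not record["flipped"].iloc[0]
        assert out.A.iloc[0, 0] == 8

    def test_tie_recorded_and_unchanged(self):
        t = make_table([[8]], [[10]], prev_alt=np.array([0.5]))
        out, record = polarize_by_cohort(t)
        assert record["tie"].iloc[0] and not record["flipped"].iloc[0]
        assert out.A.iloc[0, 0] == 8

    def test_missing_prevalence_flagged(self):
        t = make_table([[8]], [[10]], prev_alt=np.array([np.nan]))
        out, record = polarize_by_cohort(t)
        assert record["missing_prevalence"].iloc[0]

    def test_polarization_idempotent(self):
        t = make_table([[8, 2], [1, 9]], [[10, 10], [10, 10]],
                       prev_alt=np.array([0.9, 0.2]))
        once, _ = polarize_by_cohort(t)
        twice, rec = polarize_by_cohort(once)
        assert not rec["flipped"].any()
        pd.testing.assert_frame_equal(once.A, twice.A)

    @given(st.lists(st.tuples(st.integers(0, 20), st.integers(0, 20)),
                    min_size=1, max_size=8))
    @settings(deadline=None, max_examples=50)
    def test_flip_is_an_involution(self, pairs):
        A = np.array([[min(a, d)] for a, d in pairs])
        D = np.array([[d] for _, d in pairs])
        t = make_table(A, D)
        mask = pd.Series([i % 2 == 0 for i in range(len(pairs))], index=t.panel.index)
        back = flip_snvs(flip_snvs(t, mask), mask)
        pd.testing.assert_frame_equal(back.A, t.A)
        pd.testing.assert_frame_equal(back.panel, t.panel)

    def test_inclusion_rule(self):
        t = make_table([[0, 1], [3, 3]], [[20, 20], [20, 20]])
        kept = apply_inclusion_rule(t, min_freq=0.1, min_depth=10)
        assert list(kept.panel.index) == [1]


class TestDiversity:
    def test_all_zero(self):
        f = pd.DataFrame(np.zeros((5, 3)), columns=[0.0, 1.0, 2.0])
        assert (intermediate_diversity(f, 100) == 0).all()

    def test_fraction_and_strict_boundaries(self):
        f = pd.DataFrame(np.array([[0.5], [0.5], [0.5], [0.2], [0.8]]),
                         columns=[0.0])
        div = intermediate_diversity(f, 1000)
        assert div.iloc[0] == pytest.approx(0.003)  # boundary values excluded


class TestDetectSnvDifferences:
    def test_clear_sweep_flagged_with_tiny_null(self):
        t = make_table([[5, 95]], [[100, 100]], times=[0.0, 7.0])
        res = detect_snv_differences(t, 0.0, 7.0)
        assert res.observed == 1
        # conservative null (maximized over f0, both directions) is still
        # astronomically small for a 0.05 -> 0.95 shift at depth 100
        assert res.flagged["null_probability"].iloc[0] < 1e-12
        assert res.declared

    def test_constant_intermediate_frequency_not_candidate(self):
        t = make_table([[50, 50]], [[100, 100]], times=[0.0, 7.0])
        res = detect_snv_differences(t, 0.0, 7.0)
        assert res.observed == 0 and not res.declared

    def test_falling_reference_allele_flagged(self):
        # alt falls 0.95 -> 0.05, i.e. the reference allele sweeps up
        t = make_table([[95, 5]], [[100, 100]], times=[0.0, 7.0])
        res = detect_snv_differences(t, 0.0, 7.0)
        assert res.observed == 1
        assert res.flagged["rising_allele"].iloc[0] == "ref"

    def test_monotone_in_effect_size(self):
        flags = []
        for a2 in (71, 80, 95, 100):
            t = make_table([[10, a2]], [[100, 100]], times=[0.0, 7.0])
            flags.append(detect_snv_differences(t, 0.0, 7.0).observed)
        assert flags == sorted(flags)
        assert flags[0] == 1

    def test_ordered_timepoints_required(self):
        t = make_table([[5, 95]], [[100, 100]], times=[0.0, 7.0])
        with pytest.raises(ValueError):
            detect_snv_differences(t, 7.0, 0.0)

    def test_null_rarely_declared(self, rng):
        """FDR contract: on fully null panels the declaration fires rarely."""
        declared = 0
        for _ in range(20):
            A = rng.binomial(20, 0.15, size=(200, 2))
            t = make_table(A, np.full((200, 2), 20), times=[0.0, 7.0])
            declared += detect_snv_differences(t, 0.0, 7.0).declared
        assert declared <= 2


class TestBackboneConfirmation:
    def _clouds(self, other_fraction):
        # 12 clouds; each carries the SNV (alternating alleles) plus reads
        # from one core gene, so each gene accumulates >= 3 distinct clouds
        # per allele ("frequently shared")
        rows = []
        n_other = int(12 * other_fraction)
        for i in range(12):
            bc = f"B{i}"
            allele = "alt" if i % 2 else "ref"
            rows.append((0.0, bc, "s0", "c0", 100, allele, 0, "s0|g0"))
            sp = "s1" if i < n_other else "s0"
            rows.append((0.0, bc, sp, "c0", 1000 + i, "", -1, f"{sp}|g1"))
        return make_cloud_set(rows)

    def _core_genes(self):
        return pd.DataFrame(
            [{"gene": f"s0|g{i}", "species": "s0"} for i in range(6)]
            + [{"gene": f"s1|g{i}", "species": "s1"} for i in range(6)]
        )

    def _panel(self):
        return pd.DataFrame({"species": ["s0"], "contig": ["c0"], "pos": [100],
                             "ref": ["A"], "alt": ["G"], "degeneracy": ["4D"],
                             "prev_ref": [0.9], "prev_alt": [0.1]},
                            index=pd.Index([0], name="snv_id"))

    def test_all_own_species_positive(self):
        out = confirm_backbone(0, self._clouds(0.0), self._core_genes(), self._panel())
        assert out == "positive"

    def test_half_foreign_genes_negative(self):
        out = confirm_backbone(0, self._clouds(0.6), self._core_genes(), self._panel())
        assert out == "negative"

    def test_no_shared_genes_unconfirmed(self):
        rows = [(0.0, "B1", "s0", "c0", 100, "alt", 0, "s0|g0"),
                (0.0, "B2", "s0", "c0", 100, "ref", 0, "s0|g0")]
        out = confirm_backbone(0, make_cloud_set(rows), self._core_genes(),
                               self._panel())
        assert out == "unconfirmed"


class TestJensenShannon:
    def test_identical_vectors(self):
        assert jensen_shannon_distance([0.3, 0.7], [0.3, 0.7]) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_support_is_one(self):
        assert jensen_shannon_distance([1, 0], [0, 1]) == pytest.approx(1.0)

    def test_direct_evaluation(self):
        assert jensen_shannon_distance([1, 0], [0.5, 0.5]) == pytest.approx(0.5579, abs=2e-4)

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError):
            jensen_shannon_distance([1, 0], [1, 0, 0])


class TestIO:
    def test_tsv_round_trip(self, tmp_path):
        t = make_table([[5, 95], [10, 20]], [[100, 100], [50, 50]], times=[0.0, 7.0])
        path = tmp_path / "counts.tsv"
        t.to_tsv(path)
        back = AlleleCountTable.from_tsv(path)
        pd.testing.assert_frame_equal(back.A, t.A, check_column_type=False)
        pd.testing.assert_frame_equal(back.D, t.D, check_column_type=False)

    def test_vcf_export(self, tmp_path):
        t = make_table([[5, 95]], [[100, 100]], times=[0.0, 7.0])
        path = tmp_path / "panel.vcf"
        t.to_vcf(path)
        lines = path.read_text().splitlines()
        assert lines[0].startswith("##fileformat=VCF")
        body = [l for l in lines if not l.startswith("#")]
        assert len(body) == 1
        assert body[0].split("\t")[9] == "95,5"  # AD at t=0: ref,alt
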