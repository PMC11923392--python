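"""Genotype QC stages: masking, site filters, HDplot, thinning, panels."""

import numpy as np
import pytest

from rohscan.core import MISSING, from_calls
from rohscan import qc, sim


class TestQualityMasking:
    def _gm(self, gq, depth):
        calls = np.array([[1]], dtype=np.int8)
        return from_calls(
            calls,
            gq=np.array([[gq]], dtype=np.int16),
            depth=np.array([[depth]], dtype=np.int32),
        )

    @pytest.mark.parametrize(
        "gq,depth,expect_missing",
        [
            (29, 10, True),  # GQ below 30 -> masked
            (30, 6, False),  # both at the boundary -> retained (strict cuts)
            (99, 5, True),  # depth below 6 -> masked
            (30, 7, False),
        ],
    )
    def test_strict_thresholds(self, gq, depth, expect_missing):
        out = qc.mask_low_quality_genotypes(self._gm(gq, depth))
        assert (out.calls[0, 0] == MISSING) == expect_missing

    def test_no_layers_is_noop_with_warning(self, tiny_gm):
        with pytest.warns(UserWarning, match="skipped"):
            out = qc.mask_low_quality_genotypes(tiny_gm)
        assert np.array_equal(out.calls, tiny_gm.calls)


class TestSiteFilters:
    def test_mac_call_rate_and_het_pathologies(self):
        # columns: MAC 2 | 69% called | all-het | no-het polymorphic | good
        calls = np.full((100, 5), 0, dtype=np.int8)
        calls[:2, 0] = 1  # MAC 2
        calls[:31, 1] = MISSING  # 69/100 called
        calls[31:41, 1] = 1
        calls[:, 2] = 1  # only heterozygotes
        calls[:50, 3] = 2  # polymorphic but zero hets
        calls[:30, 4] = 1  # well-behaved site
        gm = from_calls(calls)
        kept = qc.filter_sites(gm)
        assert kept.sites["pos"].tolist() == [5000]  # only the good site

    def test_call_rate_boundary_70pct_kept(self):
        calls = np.zeros((10, 1), dtype=np.int8)
        calls[:3, 0] = MISSING  # exactly 70% called
        calls[3:7, 0] = 1
        gm = from_calls(calls)
        assert qc.filter_sites(gm, min_mac=1).n_sites == 1

    def test_idempotent(self, hwe_gm):
        once = qc.filter_sites(hwe_gm)
        twice = qc.filter_sites(once)
        assert np.array_equal(once.calls, twice.calls)


class TestHDplot:
    def _gm_with_ad(self, ref, alt):
        """One site, het calls with given pooled read splits."""
        n = len(ref)
        calls = np.ones((n, 1), dtype=np.int8)
        ad = np.zeros((n, 1, 2), dtype=np.int32)
        ad[:, 0, 0] = ref
        ad[:, 0, 1] = alt
        return from_calls(calls, allele_depth=ad)

    def test_balanced_reads_give_zero(self):
        gm = self._gm_with_ad([25, 25], [25, 25])  # a = b = 50
        assert qc.hdplot(gm)["D"].iloc[0] == pytest.approx(0.0)

    def test_hand_computed_deviation(self):
        gm = self._gm_with_ad([30, 30], [20, 20])  # a=60, b=40 -> 20/10
        table = qc.hdplot(gm)
        assert table["D"].iloc[0] == pytest.approx(2.0)
        kept, _ = qc.hdplot_screen(gm, d_max=5)
        assert kept.n_sites == 1

    def test_no_het_site_retained_and_flagged(self):
        calls = np.zeros((4, 1), dtype=np.int8)
        ad = np.zeros((4, 1, 2), dtype=np.int32)
        ad[:, 0, 0] = 30
        gm = from_calls(calls, allele_depth=ad)
        kept, table = qc.hdplot_screen(gm)
        assert kept.n_sites == 1
        assert bool(table["d_undefined"].iloc[0])

    def test_requires_allele_depth(self, tiny_gm):
        with pytest.raises(ValueError, match="allele_depth"):
            qc.hdplot(tiny_gm)

    def test_merged_paralog_het_ratio_and_flagging(self):
        """A ref-fixed duplicate shifts het allele ratios toward 3:1 and
        drives |D| far past the threshold."""
        rng = np.random.default_rng(0)
        calls = rng.binomial(2, 0.5, size=(60, 50)).astype(np.int8)
        gm = from_calls(calls)
        true_het = gm.calls == 1
        gm, truth = sim.simulate_read_layers(
            gm, mean_depth=50, paralog_fraction=1.0, seed=1
        )
        # a genuine het merged with a ref-fixed copy pools d/2 + d ref
        # reads against d/2 alt reads: a 3:1 expected ratio
        ref = gm.allele_depth[..., 0][true_het].sum()
        alt = gm.allele_depth[..., 1][true_het].sum()
        assert ref / (ref + alt) == pytest.approx(0.75, abs=0.03)
        table = qc.hdplot(gm)
        assert (np.abs(table["D"]) > 5).all()


class TestThinning:
    def test_same_bin_keeps_one(self):
        calls = np.array([[0, 0], [1, MISSING]], dtype=np.int8)
        gm = from_calls(calls, positions=[100, 900])
        out = qc.thin_one_per_kb(gm)
        # higher call rate wins: position 100 (fully called)
        assert out.sites["pos"].tolist() == [100]

    def test_adjacent_bins_keep_both(self):
        gm = from_calls(np.zeros((2, 2), dtype=np.int8), positions=[100, 1100])
        assert qc.thin_one_per_kb(gm).n_sites == 2

    def test_bin_boundary_1000_vs_1001(self):
        gm = from_calls(np.zeros((1, 2), dtype=np.int8), positions=[1000, 1001])
        assert qc.thin_one_per_kb(gm).n_sites == 2  # bins [1,1000], [1001,2000]

    def test_tie_breaks_to_lowest_position(self):
        gm = from_calls(np.zeros((2, 2), dtype=np.int8), positions=[300, 700])
        assert qc.thin_one_per_kb(gm).sites["pos"].tolist() == [300]

    def test_idempotent(self, hwe_gm):
        once = qc.thin_one_per_kb(hwe_gm)
        assert np.array_equal(once.calls, qc.thin_one_per_kb(once).calls)


class TestMafAndIndividualFilters:
    def test_maf_boundary(self):
        # 1000 alleles: 49 alt -> MAF 0.049 removed; 50 alt -> kept
        calls = np.zeros((500, 2), dtype=np.int8)
        calls[:49, 0] = 1
        calls[:50, 1] = 1
        gm = from_calls(calls)
        out = qc.filter_maf(gm, 0.05)
        assert out.sites["pos"].tolist() == [2000]

    def test_maf_zero_removes_nothing(self, hwe_gm):
        assert qc.filter_maf(hwe_gm, 0.0).n_sites == hwe_gm.n_sites

    def test_individual_missingness_inclusive(self):
        calls = np.zeros((3, 10), dtype=np.int8)
        calls[0, :2] = MISSING  # exactly 20% -> removed
        calls[1, :1] = MISSING  # 10% -> kept
        gm = from_calls(calls)
        out = qc.filter_individuals(gm, 0.20)
        assert out.individual_ids == ["ind1", "ind2"]

    def test_all_removed_is_hard_error(self):
        calls = np.full((2, 4), MISSING, dtype=np.int8)
        with pytest.raises(ValueError, match="every individual"):
            qc.filter_individuals(from_calls(calls), 0.20)


class TestBuildPanels:
    def test_report_reconciles_and_panels_differ_by_maf(self):
        rng = np.random.default_rng(11)
        p = np.concatenate(
            [rng.uniform(0.02, 0.04, 300), rng.uniform(0.1, 0.9, 700)]
        )
        calls = rng.binomial(2, p, size=(80, 1000)).astype(np.int8)
        pos = np.arange(1, 1001) * 1500  # already 1 per kb
        gm = from_calls(calls, positions=pos, populations=["A"] * 40 + ["B"] * 40)
        inbreeding, scan, report = qc.build_panels(gm)
        report.check()
        frame = report.to_frame()
        assert (frame["sites_in"] - frame["sites_removed"] == frame["sites_out"]).all()
        # permissive-MAF panel retains at least as many sites
        assert inbreeding.n_sites >= scan.n_sites
        assert scan.n_sites > 0

    def test_scan_population_restriction(self):
        rng = np.random.default_rng(2)
        calls = rng.binomial(2, 0.4, size=(30, 200)).astype(np.int8)
        gm = from_calls(
            calls,
            positions=np.arange(1, 201) * 2000,
            populations=["A"] * 10 + ["B"] * 10 + ["C"] * 10,
        )
        _, scan, _ = qc.build_panels(gm, scan_populations=["A", "B"])
        assert set(scan.populations) == {"A", "B"}
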