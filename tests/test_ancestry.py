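"""Consensus dosages, ancestry windows and nonnative masking."""

import numpy as np
import pandas as pd
import pytest

from rohscan import ancestry, diversity, sim
from rohscan.ancestry import NO_CALL, AncestryWindow
from rohscan.core import MISSING, from_calls


class TestConsensus:
    def test_agreement_passes_through(self):
        tracks = np.array([[1, 0, 2], [1, 0, 2], [1, 0, 2]])
        assert ancestry.consensus_dosage(tracks).tolist() == [1, 0, 2]

    def test_disagreement_is_no_call(self):
        tracks = np.array([[1.0], [1.0], [2.0]])
        assert ancestry.consensus_dosage(tracks).tolist() == [NO_CALL]

    def test_raw_dosages_round_to_consensus(self):
        tracks = np.array([[0.96], [1.02], [1.04]])
        assert ancestry.consensus_dosage(tracks).tolist() == [1]

    def test_far_from_integer_is_replicate_no_call(self):
        assert ancestry.discretize_dosage(np.array([2.7])).tolist() == [NO_CALL]
        assert ancestry.discretize_dosage(np.array([-0.7])).tolist() == [NO_CALL]
        assert ancestry.discretize_dosage(np.array([1.4])).tolist() == [1]

    def test_requires_three_replicates(self):
        with pytest.raises(ValueError, match="3 replicate"):
            ancestry.consensus_dosage(np.array([[1, 1], [1, 1]]))


class TestWindows:
    def _windows(self, positions, consensus, **kw):
        chroms = np.array(["chr1"] * len(positions))
        return ancestry.build_windows(
            "s1", chroms, np.asarray(positions), np.asarray(consensus), **kw
        )

    def test_short_window_dropped_exact_boundary(self):
        # run spanning 999 bp (positions 1..999) dropped; 1000 bp kept
        w = self._windows([1, 999], [1, 1])
        assert w == []
        w = self._windows([1, 1000], [1, 1])
        assert len(w) == 1 and w[0].length == 1000

    def test_uniform_consensus_single_window(self):
        pos = np.arange(1, 51) * 1000
        w = self._windows(pos, np.zeros(50))
        assert len(w) == 1
        assert (w[0].start, w[0].end) == (1000, 50_000)

    def test_no_call_breaks_runs(self):
        pos = [1000, 2000, 3000, 4000, 5000]
        w = self._windows(pos, [1, 1, NO_CALL, 1, 1])
        assert [(x.start, x.end) for x in w] == [(1000, 2000), (4000, 5000)]

    def test_dosage_change_starts_new_window(self):
        pos = [1000, 3000, 5000, 7000]
        w = self._windows(pos, [0, 0, 2, 2])
        assert [(x.start, x.end, x.dosage) for x in w] == [
            (1000, 3000, 0),
            (5000, 7000, 2),
        ]


class TestMasking:
    def _gm(self):
        calls = np.array([[0, 1, 2, 0], [2, 2, 0, 1]], dtype=np.int8)
        return from_calls(
            calls,
            positions=[1000, 2000, 3000, 4000],
            individual_ids=["s1", "s2"],
        )

    def test_nonnative_window_masks_only_its_individual(self):
        gm = self._gm()
        w = AncestryWindow("s1", "chr1", 1500, 3500, dosage=2)
        out = ancestry.mask_nonnative(gm, [w])
        assert out.calls[0].tolist() == [0, MISSING, MISSING, 0]
        assert out.calls[1].tolist() == gm.calls[1].tolist()

    def test_native_window_is_noop(self):
        gm = self._gm()
        w = AncestryWindow("s1", "chr1", 1, 4000, dosage=0)
        out = ancestry.mask_nonnative(gm, [w])
        assert np.array_equal(out.calls, gm.calls)

    def test_masking_never_alters_retained_values(self):
        gm = self._gm()
        w = AncestryWindow("s2", "chr1", 1000, 2000, dosage=1)
        out = ancestry.mask_nonnative(gm, [w])
        changed = out.calls != gm.calls
        assert (out.calls[changed] == MISSING).all()

    def test_zero_admixture_pipeline_is_noop(self):
        rng = np.random.default_rng(4)
        calls = rng.binomial(2, 0.4, size=(4, 100)).astype(np.int8)
        gm = from_calls(calls, positions=np.arange(1, 101) * 2000)
        truth = sim.SimTruth()
        tracks = sim.dosage_tracks_from_truth(gm, truth)
        windows = ancestry.consensus_windows_from_tracks(gm, tracks)
        out = ancestry.mask_nonnative(gm, windows)
        assert np.array_equal(out.calls, gm.calls)


class TestTruthTractRecovery:
    def test_noise_free_tracks_mask_nearly_all_tract_genotypes(self):
        """With exact dosage tracks, >=95% of calls inside true tracts
        are masked."""
        scenario = sim.recent_bottleneck(n_pops=1)
        scenario.target_snps = 4000
        gm, truth = sim.simulate_populations(scenario, 12, seed=9)
        gm, truth = sim.inject_nonnative_tracts(
            gm, truth, fraction_admixed=0.5, seed=10
        )
        tracks = sim.dosage_tracks_from_truth(gm, truth)
        windows = ancestry.consensus_windows_from_tracks(gm, tracks)
        masked = ancestry.mask_nonnative(gm, windows)
        chrom = gm.sites["chrom"].to_numpy()
        pos = gm.sites["pos"].to_numpy()
        inside = masked_inside = 0
        for i, ind in enumerate(gm.individual_ids):
            for cname, start, end, _, _ in truth.tracts.get(ind, []):
                sel = (chrom == cname) & (pos >= start) & (pos <= end)
                called = gm.calls[i, sel] != MISSING
                inside += called.sum()
                masked_inside += (masked.calls[i, sel][called] == MISSING).sum()
        assert inside > 0
        assert masked_inside / inside >= 0.95

    def test_tract_fraction_bookkeeping(self):
        calls = np.zeros((1, 20), dtype=np.int8)
        gm = from_calls(calls, positions=np.arange(1, 21) * 1_000_000)
        truth = sim.SimTruth(
            tracts={"ind0": [("chr1", 1, 2_000_000, "nonnative", 0)]}
        )
        # one 2-Mb tract on one haplotype of a 20-Mb chromosome
        assert truth.tract_fraction("ind0", 20_000_000) == pytest.approx(0.05)

    def test_injection_conserves_genotypes_outside_tracts(self):
        scenario = sim.recent_bottleneck(n_pops=1)
        scenario.target_snps = 2000
        gm, truth = sim.simulate_populations(scenario, 8, seed=2)
        gm2, truth2 = sim.inject_nonnative_tracts(
            gm, truth, fraction_admixed=0.5, seed=3
        )
        chrom = gm.sites["chrom"].to_numpy()
        pos = gm.sites["pos"].to_numpy()
        outside = np.ones((gm.n_individuals, gm.n_sites), dtype=bool)
        for i, ind in enumerate(gm.individual_ids):
            for cname, start, end, _, _ in truth2.tracts.get(ind, []):
                outside[i, (chrom == cname) & (pos >= start) & (pos <= end)] = False
        assert np.array_equal(gm.calls[outside], gm2.calls[outside])

    def test_fraction_zero_is_identity(self):
        rng = np.random.default_rng(1)
        calls = rng.binomial(2, 0.3, size=(5, 50)).astype(np.int8)
        gm = from_calls(calls, positions=np.arange(1, 51) * 10_000)
        out, _ = sim.inject_nonnative_tracts(
            gm, sim.SimTruth(), fraction_admixed=0.0, seed=0
        )
        assert np.array_equal(out.calls, gm.calls)

    def test_fixed_donor_on_fixed_ref_recipient(self):
        calls = np.zeros((2, 60), dtype=np.int8)
        gm = from_calls(calls, positions=np.arange(1, 61) * 100_000)
        donor = np.ones(60)  # donor fixed for the alternate allele
        out, truth = sim.inject_nonnative_tracts(
            gm,
            sim.SimTruth(),
            donor_divergence=donor * 0.99,
            fraction_admixed=1.0,
            admixed_genome_fraction=0.3,
            mean_tract_bp=3_000_000,
            seed=5,
        )
        chrom = gm.sites["chrom"].to_numpy()
        pos = gm.sites["pos"].to_numpy()
        touched = 0
        for i, ind in enumerate(gm.individual_ids):
            for cname, start, end, _, _ in truth.tracts.get(ind, []):
                sel = (chrom == cname) & (pos >= start) & (pos <= end)
                vals = out.calls[i, sel]
                touched += vals.size
                assert np.isin(vals, [1, 2]).all()  # het or hom-alt
        assert touched > 0


def test_heterozygosity_repair_over_seeds():
    """Masking moves per-population H_e back toward the no-admixture
    truth when a divergent donor inflates it."""
    from rohscan.experiments import masking_repair

    res = masking_repair(seeds=(0, 1, 2), n_per_pop=10, n_snps=3000)
    assert res["n_improved"] == 3
    assert res["mean_he_error_post"] < res["mean_he_error_pre"]
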