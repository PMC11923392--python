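"""Covariance model, XtX, POD calibration and Bayes factors."""

import numpy as np
import pandas as pd
import pytest

from rohscan import scan, sim
from rohscan.core import from_calls
from rohscan.scan import OmegaModel, PODCalibration


def _identity_model(j=10, n=1e9):
    omega = np.eye(j)
    return OmegaModel(
        omega=omega,
        precision=np.linalg.inv(omega),
        pi=np.array([0.5]),
        kept=np.array([0]),
        beta_a=1.0,
        beta_b=1.0,
        populations=[f"p{k}" for k in range(j)],
        harmonic_n=np.full(j, n),
    )


class TestXtX:
    def test_zero_residual_gives_zero(self):
        model = _identity_model()
        r = np.zeros((10, 1))
        assert scan.xtx_stats(r, model)[0] == 0.0

    def test_identity_omega_vector_of_ones(self):
        model = _identity_model()
        r = np.ones((10, 1))
        assert scan.xtx_stats(r, model)[0] == pytest.approx(10.0)

    def test_allele_label_swap_invariance(self):
        model = _identity_model()
        rng = np.random.default_rng(0)
        r = rng.standard_normal((10, 5))
        assert np.allclose(
            scan.xtx_stats(r, model), scan.xtx_stats(-r, model)
        )

    def test_null_mean_matches_chi_square_expectation(self):
        """With small sampling noise the null mean approaches the
        chi-square expectation of about one per population (binomial
        sampling noise inflates it away from this limit, which is why
        thresholds are POD-calibrated rather than taken from the
        chi-square)."""
        j = 20
        alt, tot, _, _ = sim.simulate_drift_panel(
            n_pops=j, n_snps=20_000, n_alleles=500, seed=1
        )
        model = scan.estimate_omega((alt, tot))
        r, _, _, _ = scan.standardized_residuals(alt, tot)
        x = scan.xtx_stats(r, model)
        assert x.mean() == pytest.approx(j, rel=0.05)


class TestOmega:
    def test_independent_drift_gives_near_diagonal(self):
        alt, tot, _, _ = sim.simulate_drift_panel(n_pops=8, n_snps=20_000, seed=2)
        model = scan.estimate_omega((alt, tot))
        off = model.omega[~np.eye(8, dtype=bool)]
        # centering by the per-SNP mean induces a small uniform negative
        # off-diagonal; entries stay within +/-0.05 of zero
        assert np.abs(off).max() < 0.05

    def test_duplicated_population_fully_correlated(self):
        rng = np.random.default_rng(4)
        calls_one = rng.binomial(2, rng.uniform(0.1, 0.9, 3000), size=(15, 3000))
        calls = np.vstack([calls_one, calls_one, rng.binomial(2, 0.5, (15, 3000))])
        gm = from_calls(
            calls.astype(np.int8),
            positions=np.arange(1, 3001) * 1000,
            populations=["A"] * 15 + ["B"] * 15 + ["C"] * 15,
        )
        model = scan.estimate_omega(gm)
        i, j = 0, 1  # A and B are byte-identical
        assert model.omega[i, j] == pytest.approx(
            model.omega[i, i], rel=0.05
        )

    def test_shared_history_raises_off_diagonal(self):
        """Populations cloned from a common bottlenecked ancestor show a
        larger covariance than unrelated pairs."""
        related, unrelated = [], []
        for seed in range(3):
            sc = sim.DemographyScenario(
                "hier",
                4,
                [(6, 40)],
                shared_epochs=[(12, 25)],
                groups=[[0, 1]],
                target_snps=4000,
            )
            gm, _ = sim.simulate_populations(sc, 15, seed=seed)
            model = scan.estimate_omega(gm)
            related.append(model.omega[0, 1])
            unrelated.append(max(model.omega[0, 2], model.omega[0, 3],
                                 model.omega[1, 2], model.omega[2, 3]))
        assert np.mean(related) > np.mean(unrelated)

    def test_too_few_populations_rejected(self):
        with pytest.raises(ValueError, match="2 populations"):
            scan.estimate_omega((np.ones((1, 10)), np.full((1, 10), 20)))


class TestPOD:
    def test_threshold_is_its_own_quantile(self):
        alt, tot, _, _ = sim.simulate_drift_panel(n_pops=6, n_snps=5000, seed=3)
        model = scan.estimate_omega((alt, tot))
        calib = scan.pod_calibrate(model, 20_000, seed=9)
        frac = (calib.xtx >= calib.threshold_1pct).mean()
        assert frac == pytest.approx(0.01, abs=0.002)
        assert calib.threshold_001pct >= calib.threshold_1pct

    def test_same_seed_same_thresholds(self):
        alt, tot, _, _ = sim.simulate_drift_panel(n_pops=6, n_snps=5000, seed=3)
        model = scan.estimate_omega((alt, tot))
        a = scan.pod_calibrate(model, 15_000, seed=7)
        b = scan.pod_calibrate(model, 15_000, seed=7)
        assert a.threshold_1pct == b.threshold_1pct

    def test_small_pod_warns(self):
        alt, tot, _, _ = sim.simulate_drift_panel(n_pops=6, n_snps=2000, seed=3)
        model = scan.estimate_omega((alt, tot))
        with pytest.warns(UserWarning, match="unstable"):
            scan.pod_calibrate(model, 5000, seed=1)


class TestBayesFactor:
    def test_trait_affine_rescaling_invariance(self):
        alt, tot, z, _ = sim.simulate_drift_panel(n_pops=10, n_snps=2000, seed=5)
        model = scan.estimate_omega((alt, tot))
        r, _, _, _ = scan.standardized_residuals(alt, tot)
        raw = 100 + 37 * z
        db1, _ = scan.bayes_factor(r, scan.standardize_trait(z), model)
        db2, _ = scan.bayes_factor(r, scan.standardize_trait(raw), model)
        assert np.allclose(db1, db2, atol=1e-9)

    def test_constant_trait_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            scan.standardize_trait(np.full(10, 3.0))

    def test_strong_cline_is_decisive_null_is_not(self):
        alt, tot, z, idx = sim.simulate_drift_panel(
            n_pops=10, n_snps=2000, seed=6, causal_site=-1
        )
        model = scan.estimate_omega((alt, tot))
        r, _, _, kept = scan.standardized_residuals(alt, tot)
        db, beta = scan.bayes_factor(r, z, model)
        ci = int(np.flatnonzero(kept == idx)[0])
        assert db[ci] >= 20.0
        assert np.median(db) < 0.0  # typical null SNP carries no evidence
        assert abs(beta[ci]) > abs(np.median(beta))


class TestTraitCorrelation:
    def test_closed_form_fixture(self):
        freqs = np.array([[0.1], [0.2], [0.3], [0.4]])
        traits = np.array([1.0, 2.0, 3.0, 5.0])
        # textbook Pearson r for (0.1,0.2,0.3,0.4) vs (1,2,3,5)
        x = freqs[:, 0]
        expected = (
            np.sum((x - x.mean()) * (traits - traits.mean()))
            / np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((traits - traits.mean()) ** 2))
        )
        r = scan.trait_correlation(freqs, traits)[0]
        assert r == pytest.approx(expected, abs=1e-12)
        assert r == pytest.approx(0.9827076298239908, abs=1e-12)

    def test_affine_frequencies_give_unit_correlation(self):
        traits = np.array([1.0, 2.0, 3.0, 4.0])
        freqs = (0.05 + 0.1 * traits)[:, None]
        assert scan.trait_correlation(freqs, traits)[0] == pytest.approx(1.0)

    def test_sign_antisymmetry(self):
        rng = np.random.default_rng(1)
        freqs = rng.uniform(0.1, 0.9, (6, 4))
        traits = rng.normal(size=6)
        r1 = scan.trait_correlation(freqs, traits)
        r2 = scan.trait_correlation(freqs, -traits)
        assert np.allclose(r1, -r2)

    def test_zero_variance_flagged_nan(self):
        freqs = np.full((5, 1), 0.3)
        traits = np.arange(5.0)
        assert np.isnan(scan.trait_correlation(freqs, traits)[0])

    def test_requires_three_populations(self):
        with pytest.raises(ValueError, match="3 populations"):
            scan.trait_correlation(np.ones((2, 1)), np.array([1.0, 2.0]))


class TestRunScanAndCandidates:
    def _scan(self, causal=True):
        alt, tot, z, idx = sim.simulate_drift_panel(
            n_pops=10, n_snps=3000, seed=8, causal_site=-1 if causal else None
        )
        traits = pd.DataFrame(
            {"length": 100 + 30 * z, "growth": np.linspace(30, 60, 10)},
            index=pd.Index([f"pop{k}" for k in range(10)], name="population"),
        )
        table, model, calib = scan.run_scan(
            (alt, tot),
            traits,
            populations=[f"pop{k}" for k in range(10)],
            n_pod_snps=20_000,
            seed=12,
        )
        return table, model, calib, idx

    def test_candidate_requires_both_thresholds(self):
        table, _, calib, _ = self._scan()
        assert (table["candidate"] <= table["xtx_significant"]).all()
        assert (table["candidate"] <= table["bf_decisive"]).all()
        near_miss = table["xtx_significant"] & ~table["bf_decisive"]
        assert not table.loc[near_miss, "candidate"].any()

    def test_causal_locus_flagged(self):
        table, _, _, idx = self._scan()
        row = table[table["site"] == idx]
        assert bool(row["candidate"].iloc[0])

    def test_bookkeeping_conservation(self):
        table, _, calib, _ = self._scan()
        summary = scan.classify_candidates(table, calib)
        assert summary["n_associations"] == sum(
            summary["per_trait_associations"].values()
        )
        assert summary["n_candidate_snps"] <= summary["n_associations"] + 1
        assert len(summary["candidate_index"]) == summary["n_candidate_snps"]

    def test_empty_record_list(self):
        table = pd.DataFrame(
            {
                "xtx": [],
                "bf_db_length": [],
                "xtx_significant": pd.Series([], dtype=bool),
                "xtx_stringent": pd.Series([], dtype=bool),
            }
        )
        summary = scan.classify_candidates(table)
        assert summary["n_candidate_snps"] == 0

    def test_missing_trait_population_errors(self):
        alt, tot, z, _ = sim.simulate_drift_panel(n_pops=4, n_snps=500, seed=2)
        traits = pd.DataFrame({"t": [1.0, 2.0]}, index=["pop0", "pop1"])
        with pytest.raises(ValueError, match="lacks populations"):
            scan.run_scan((alt, tot), traits, populations=[f"pop{k}" for k in range(4)])
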