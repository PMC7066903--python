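"""Synthetic-cohort generator: band purity, coupling calibration,
cohort structure and the summary-level generator."""

import numpy as np
import pytest

from dmnaec.bands import ALPHA, CANONICAL_BANDS, DELTA, GAMMA1, BandSpec
from dmnaec.cohort import (HC, SCD, CohortConfig, CouplingSpec,
                           SummaryCohortConfig, expected_envelope_correlation,
                           make_narrowband_noise, simulate_cohort,
                           simulate_strength_summaries, simulate_subject)
from dmnaec.connectivity import node_strength, aec_matrix
from dmnaec.spectral import band_power, welch_psd

from conftest import narrowband_pair, pair_aec


class TestNarrowbandNoise:
    def test_unit_variance_and_zero_mean(self):
        x = make_narrowband_noise(1000, 60, DELTA, seed=5)
        assert abs(x.mean()) < 1e-12
        assert x.var() == pytest.approx(1.0, rel=0.02)

    def test_seeded_determinism(self):
        a = make_narrowband_noise(500, 30, ALPHA, seed=9)
        b = make_narrowband_noise(500, 30, ALPHA, seed=9)
        assert np.array_equal(a, b)

    @pytest.mark.parametrize("band", CANONICAL_BANDS, ids=lambda b: b.name)
    def test_band_purity(self, band):
        # >=95% of spectral mass inside the band; a 10-s window keeps the
        # check from being limited by Welch smearing rather than the filter
        fs = 1000.0
        x = make_narrowband_noise(fs, 60, band, seed=1)
        psd = welch_psd(x, fs, window_s=10.0)
        inside = band_power(psd, band.f_lo, band.f_hi)[0]
        total = band_power(psd, 0.5, fs / 2 - 1)[0]
        assert inside / total >= 0.95

    def test_alpha_relative_power_example(self):
        # (1000 Hz, 60 s, alpha, seed 1): alpha fraction of total >= 0.95
        x = make_narrowband_noise(1000, 60, ALPHA, seed=1)
        psd = welch_psd(x, 1000, window_s=10.0)
        frac = band_power(psd, 8, 12)[0] / band_power(psd, 2, 90)[0]
        assert frac >= 0.95

    def test_band_beyond_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            make_narrowband_noise(100, 10, BandSpec("hi", 40, 60), seed=0)


class TestCouplingCalibration:
    def test_uncoupled_pair_aec_near_zero(self):
        # Monte-Carlo mean over seeds compared to 0 within 3 SE
        vals = [pair_aec(*narrowband_pair(0.0, seed=s), fs=200.0)
                for s in range(20)]
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals)) < max(3 * se, 0.05)

    def test_full_coupling_gives_aec_one(self):
        x1, x2 = narrowband_pair(1.0, seed=3)
        assert pair_aec(x1, x2, fs=200.0) == pytest.approx(1.0, abs=1e-12)

    def test_r07_matches_long_duration_oracle(self):
        # brute-force oracle: one 10x-duration run; short runs agree
        oracle = pair_aec(*narrowband_pair(0.7, duration=3000, seed=99), fs=200.0)
        vals = [pair_aec(*narrowband_pair(0.7, seed=s), fs=200.0)
                for s in range(12)]
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert np.mean(vals) == pytest.approx(oracle, abs=max(3 * se, 0.02))
        assert np.mean(vals) == pytest.approx(0.49, abs=0.05)

    def test_closed_form_matches_simulation(self):
        # analytic Rayleigh-envelope correlation vs a long simulation
        r = 0.5
        sim = pair_aec(*narrowband_pair(r, duration=2000, seed=7), fs=200.0)
        assert sim == pytest.approx(expected_envelope_correlation(r), abs=0.03)

    def test_expected_envelope_correlation_limits(self):
        assert expected_envelope_correlation(0.0) == 0.0
        assert expected_envelope_correlation(1.0) == pytest.approx(1.0)
        rs = np.linspace(0, 1, 11)
        vals = [expected_envelope_correlation(r) for r in rs]
        assert np.all(np.diff(vals) > 0)
        assert np.allclose(vals, rs**2, atol=0.05)


class TestSubjectAndCohort:
    def test_overloaded_coupling_rejected(self):
        cfg = CohortConfig(
            n_hc=2, n_scd=2, fs=250, duration=30,
            baseline_coupling=(CouplingSpec(ALPHA, (("PCC_L", "PCC_R", 0.6),
                                                    ("PCC_L", "PCu_L", 0.6))),),
            scd_extra_coupling=())
        with pytest.raises(ValueError, match="imaginary"):
            simulate_subject(cfg, HC, 0)

    def test_invalid_r_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            CouplingSpec(ALPHA, (("PCC_L", "PCC_R", 1.2),))

    def test_cohort_structure(self, small_cohort_config):
        records = simulate_cohort(small_cohort_config)
        assert len(records) == 8
        assert sum(r.group == HC for r in records) == 4
        assert all(r.roi_ts.shape == (12, 15000) for r in records)
        assert all(r.complaint_count is None for r in records if r.group == HC)
        assert all(1 <= r.complaint_count <= 12
                   for r in records if r.group == SCD)

    def test_cohort_bit_identical_for_same_seed(self, small_cohort_config):
        a = simulate_cohort(small_cohort_config)
        b = simulate_cohort(small_cohort_config)
        assert all(np.array_equal(x.roi_ts, y.roi_ts) for x, y in zip(a, b))
        assert [x.complaint_count for x in a] == [y.complaint_count for y in b]

    def test_default_counts_are_26_and_27(self):
        cfg = CohortConfig()
        assert (cfg.n_hc, cfg.n_scd, cfg.fs, cfg.duration) == (26, 27, 1000.0, 300.0)

    def test_scd_delta_pcc_strength_elevated(self):
        # group-mean SCD delta PCC strength exceeds HC in every one of a
        # few scaled-down replicates (full power check in acceptance)
        wins = 0
        for rep in range(5):
            cfg = CohortConfig(n_hc=4, n_scd=4, fs=250, duration=60,
                               seed=400 + rep)
            recs = simulate_cohort(cfg)
            means = {HC: [], SCD: []}
            k = cfg.roi_names.index("PCC_R")
            for r in recs:
                s = node_strength(aec_matrix(r.roi_ts, DELTA, cfg.fs,
                                             cfg.roi_names))
                means[r.group].append(s[k])
            wins += np.mean(means[SCD]) > np.mean(means[HC])
        assert wins >= 4

    def test_null_cohort_groups_indistinguishable(self):
        from dmnaec.cohort import null_config
        from scipy import stats as sps

        cfg = null_config(CohortConfig(n_hc=5, n_scd=5, fs=250, duration=60,
                                       seed=77))
        recs = simulate_cohort(cfg)
        k = cfg.roi_names.index("PCC_R")
        s = {HC: [], SCD: []}
        for r in recs:
            s[r.group].append(node_strength(
                aec_matrix(r.roi_ts, DELTA, cfg.fs, cfg.roi_names))[k])
        assert sps.ttest_ind(s[HC], s[SCD]).pvalue > 0.05


class TestSummaryCohorts:
    def test_moments_converge_to_printed_values(self):
        cfg = SummaryCohortConfig(n_hc=100_000, n_scd=100_000, seed=1)
        table = simulate_strength_summaries(cfg)
        cell = table.query("group == 'HC' and roi == 'PCC_L' and band == 'delta'")
        assert cell["strength"].mean() == pytest.approx(3.1, rel=0.01)
        cell = table.query("group == 'SCD' and roi == 'PCC_L' and band == 'delta'")
        assert cell["strength"].mean() == pytest.approx(4.4, rel=0.01)

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            SummaryCohortConfig(cells={(HC, "PCC_L", "delta"): (3.1, 0.0)})

    def test_fixed_seed_reproducible(self):
        cfg = SummaryCohortConfig(seed=5)
        assert simulate_strength_summaries(cfg).equals(
            simulate_strength_summaries(cfg))
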