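import dataclasses

import numpy as np
import pytest

from lipidqy import (
    SessionConfig,
    StrainProfile,
    default_campaign_configs,
    emission_area,
    generate_campaign,
    generate_session,
    generate_spectrum,
)
from lipidqy.errors import ConfigurationError, DomainError
from lipidqy.pipeline import load_campaign, session_parameter_table
from lipidqy.synthdata import DEFAULT_LAMP_DECAY_RATE, write_campaign


class TestGenerateSpectrum:
    def test_noise_free_area_equals_true_area(self, profile):
        rng = np.random.default_rng(0)
        spec = generate_spectrum(profile, 1000.0, 1.0, 0.0, rng)
        assert emission_area(spec) == pytest.approx(1000.0, rel=1e-4)

    def test_lamp_factor_scales_area_linearly(self, profile):
        rng = np.random.default_rng(0)
        spec = generate_spectrum(profile, 1000.0, 0.5, 0.0, rng)
        assert emission_area(spec) == pytest.approx(500.0, rel=1e-4)

    def test_negative_true_area_rejected(self, profile):
        with pytest.raises(DomainError):
            generate_spectrum(profile, -1.0, 1.0, 0.0, np.random.default_rng(0))

    def test_invalid_lamp_factor_rejected(self, profile):
        rng = np.random.default_rng(0)
        with pytest.raises(DomainError):
            generate_spectrum(profile, 10.0, 0.0, 0.0, rng)
        with pytest.raises(DomainError):
            generate_spectrum(profile, 10.0, 1.5, 0.0, rng)

    def test_monte_carlo_area_cv_matches_noise_model(self, profile):
        # stated noise model: multiplicative log-normal, CV 0.05
        rng = np.random.default_rng(7)
        areas = [emission_area(generate_spectrum(profile, 1000.0, 1.0, 0.05, rng))
                 for _ in range(500)]
        cv = np.std(areas, ddof=1) / np.mean(areas)
        assert 0.04 <= cv <= 0.06


class TestSessionConfig:
    def test_lamp_factor_in_unit_interval(self):
        cfg = SessionConfig(lamp_hours=490.0)
        assert 0.0 < cfg.lamp_factor <= 1.0

    def test_default_decay_gives_30pct_loss_over_420_hours(self):
        assert np.exp(-DEFAULT_LAMP_DECAY_RATE * 420.0) == pytest.approx(0.7, rel=1e-12)

    @pytest.mark.parametrize("kwargs", [
        {"dilution_ods": ()},
        {"dilution_ods": (0.2, -0.4)},
        {"noise_cv": -0.1},
        {"lamp_hours": -1.0},
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            SessionConfig(**kwargs)


class TestGenerateCampaign:
    def test_structural_contract(self, noisy_campaign):
        assert len(noisy_campaign.sessions) == 2
        assert len(noisy_campaign.readings) == 10  # 5 dilutions x 2 sessions
        assert len(noisy_campaign.standard_readings) == 2
        for session in noisy_campaign.sessions:
            profile = session.config.strain_profile
            truths = np.asarray(session.truths)
            dils = np.asarray(session.config.dilution_ods)
            np.testing.assert_allclose(truths, dils * profile.lipid_at_od1, rtol=1e-12)

    def test_same_seed_is_bit_identical(self):
        m1, m7 = default_campaign_configs(seed=3)
        a = generate_campaign(m1, m7)
        b = generate_campaign(m1, m7)
        for ra, rb in zip(a.readings, b.readings):
            np.testing.assert_array_equal(ra.spectrum.intensities, rb.spectrum.intensities)
            assert ra.i_e == rb.i_e and ra.a_e == rb.a_e

    def test_noiseless_equal_lamp_sessions_identical(self):
        m1, m7 = default_campaign_configs(seed=3, noise_cv=0.0, lamp_decay_rate=0.0)
        campaign = generate_campaign(m1, m7)
        s1, s7 = campaign.sessions
        for r1, r7 in zip(s1.readings, s7.readings):
            np.testing.assert_array_equal(r1.spectrum.intensities, r7.spectrum.intensities)

    def test_noiseless_lamp_drift_scales_ie_but_not_phi(self):
        m1, m7 = default_campaign_configs(seed=3, noise_cv=0.0)
        campaign = generate_campaign(m1, m7)
        s1, s7 = campaign.sessions
        lamp_ratio = s7.lamp_factor / s1.lamp_factor
        assert lamp_ratio == pytest.approx(0.7, rel=1e-12)
        t1 = session_parameter_table(s1)
        t7 = session_parameter_table(s7)
        np.testing.assert_allclose(t7["I_E"], lamp_ratio * t1["I_E"], rtol=1e-12)
        np.testing.assert_allclose(t7["A_E"], lamp_ratio * t1["A_E"], rtol=1e-12)
        np.testing.assert_allclose(t7["PHI_FL"], t1["PHI_FL"], rtol=1e-12)

    def test_mismatched_profiles_rejected(self):
        m1, m7 = default_campaign_configs(seed=0)
        other = dataclasses.replace(m7, strain_profile=StrainProfile(name="other"))
        with pytest.raises(ConfigurationError):
            generate_campaign(m1, other)

    def test_later_session_needs_more_lamp_hours(self):
        m1, m7 = default_campaign_configs(seed=0)
        with pytest.raises(ConfigurationError):
            generate_campaign(m7, m1)


class TestStrainProfile:
    def test_peak_must_sit_in_scan_range(self):
        with pytest.raises(ConfigurationError):
            StrainProfile(peak_center=900.0)

    def test_positive_fields_enforced(self):
        with pytest.raises(ConfigurationError):
            StrainProfile(lipid_at_od1=0.0)


class TestCampaignWriter:
    def test_written_campaign_reloads_to_same_parameters(self, tmp_path, noisy_campaign):
        outdir = write_campaign(noisy_campaign, tmp_path / "camp")
        assert (outdir / "manifest.csv").exists()
        assert (outdir / "truths.csv").exists()
        assert (outdir / "standards.csv").exists()
        table = load_campaign(outdir)
        assert len(table) == 10
        in_memory = []
        for session in noisy_campaign.sessions:
            in_memory.append(session_parameter_table(session))
        import pandas as pd
        mem = pd.concat(in_memory, ignore_index=True)
        for col in ("I_E", "A_E", "PHI_FL", "lipid_true"):
            np.testing.assert_allclose(
                np.sort(table[col].to_numpy()), np.sort(mem[col].to_numpy()),
                rtol=1e-8, err_msg=col)

    def test_session_generation_is_deterministic_per_seed(self):
        cfg = SessionConfig(seed=99)
        a = generate_session(cfg)
        b = generate_session(cfg)
        assert a.standard.a_e_s == b.standard.a_e_s
        np.testing.assert_array_equal(a.readings[0].spectrum.intensities,
                                      b.readings[0].spectrum.intensities)
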