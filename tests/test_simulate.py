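"""Synthetic RR/ECG generator: IPFM behavior, presets, ground-truth ECG."""

import numpy as np
import pytest

from mousehrv import (
    EcgTemplate,
    EcgWave,
    ModulationSpec,
    RRSeries,
    band_powers,
    berger_resample,
    generate_ecg,
    generate_rr_series,
    group_preset,
    welch_psd,
)


class TestIpfmGenerator:
    def test_unmodulated_ipfm_is_metronomic(self):
        spec = ModulationSpec(mean_rr=200.0)
        rr = generate_rr_series(spec, duration=60.0, seed=0)
        assert len(rr) == 300
        np.testing.assert_allclose(rr.intervals, 200.0, rtol=1e-9)

    def test_kx_preset_mean_hr_matches_group_level(self):
        preset = group_preset("KX")
        rr = generate_rr_series(preset.modulation, duration=300.0, seed=42)
        hr = 60000.0 / np.mean(rr.intervals)
        assert abs(hr - 253.81) / 253.81 < 0.02

    def test_requested_sd_is_reached(self):
        spec = ModulationSpec(mean_rr=180.0, frac_vlf=0.3, frac_lf=0.3,
                              frac_hf=0.2, total_sd=5.0)
        rr = generate_rr_series(spec, duration=300.0, seed=5)
        assert np.std(rr.intervals, ddof=1) == pytest.approx(5.0, rel=0.15)

    def test_hf_dominant_spec_yields_hf_dominant_spectrum(self):
        spec = ModulationSpec(mean_rr=150.0, frac_hf=0.9, total_sd=3.0)
        rr = generate_rr_series(spec, duration=240.0, seed=3)
        bp = band_powers(welch_psd(berger_resample(rr)))
        assert bp.hf_rel >= 80.0

    @pytest.mark.parametrize("band,frac_kw", [
        ("vlf_rel", "frac_vlf"), ("lf_rel", "frac_lf"), ("hf_rel", "frac_hf"),
    ])
    def test_single_band_specs_put_dominant_power_in_requested_band(self, band, frac_kw):
        for seed in (1, 2, 3):
            spec = ModulationSpec(mean_rr=150.0, total_sd=3.0, **{frac_kw: 0.9})
            rr = generate_rr_series(spec, duration=240.0, seed=seed)
            bp = band_powers(welch_psd(berger_resample(rr)))
            rels = {"vlf_rel": bp.vlf_rel, "lf_rel": bp.lf_rel, "hf_rel": bp.hf_rel}
            assert max(rels, key=rels.get) == band

    def test_determinism_bit_identical(self):
        spec = group_preset("P").modulation
        a = generate_rr_series(spec, duration=60.0, seed=9)
        b = generate_rr_series(spec, duration=60.0, seed=9)
        np.testing.assert_array_equal(a.intervals, b.intervals)
        c = generate_rr_series(spec, duration=60.0, seed=10)
        assert not np.array_equal(a.intervals, c.intervals)

    @pytest.mark.parametrize("total_sd", [0.0, 2.0])
    def test_rate_conservation(self, total_sd):
        # zero-band spec: all requested power (if any) in the fractal remainder
        spec = ModulationSpec(mean_rr=200.0, total_sd=total_sd)
        rr = generate_rr_series(spec, duration=120.0, seed=1)
        expected = 120.0 / 0.2
        tol = 2 + 3 * total_sd / 200.0 * np.sqrt(len(rr))
        assert abs(len(rr) - expected) <= tol

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            ModulationSpec(mean_rr=-5.0)
        with pytest.raises(ValueError):
            ModulationSpec(mean_rr=200.0, frac_vlf=0.7, frac_hf=0.7)
        with pytest.raises(ValueError):
            ModulationSpec(mean_rr=200.0, f_hf=6.0)
        with pytest.raises(ValueError, match="duration"):
            generate_rr_series(ModulationSpec(mean_rr=200.0), duration=10.0, seed=0)

    def test_excessive_amplitude_rejected(self):
        spec = ModulationSpec(mean_rr=200.0, frac_hf=1.0, total_sd=160.0)
        with pytest.raises(ValueError, match="zero or below"):
            generate_rr_series(spec, duration=60.0, seed=0)


class TestGroupPresets:
    def test_preset_mean_rr_levels(self):
        assert group_preset("KX").modulation.mean_rr == pytest.approx(236.4, abs=0.05)
        assert group_preset("PF").modulation.mean_rr == pytest.approx(158.7, abs=0.05)

    def test_variability_ordering(self):
        sds = [group_preset(g).modulation.total_sd for g in ("KX", "P", "PF")]
        assert sds[0] > sds[1] > sds[2]

    def test_unknown_preset_lists_valid_names(self):
        with pytest.raises(ValueError, match="KX.*P.*PF"):
            group_preset("xx")


class TestEcgSynthesis:
    def test_constant_rr_gives_exact_peak_count_and_argmax(self):
        rr = RRSeries(np.full(300, 200.0))
        tmpl = EcgTemplate(baseline_wander_amp=0.0, noise_sd=0.0)
        ecg, truth = generate_ecg(rr, fs=4000.0, template=tmpl, seed=0)
        assert truth.size == 300
        # argmax inside each beat window sits exactly on the ground-truth time
        for bt in truth[::25]:
            lo = int((bt - 0.05) * 4000)
            hi = int((bt + 0.05) * 4000)
            i = lo + np.argmax(ecg.samples[lo:hi])
            assert i / 4000.0 == pytest.approx(bt, abs=1e-9)

    def test_zero_amplitude_template_is_noise_only(self):
        rr = RRSeries(np.full(150, 200.0))
        z = EcgWave(0.0, 0.0, 1.0)
        tmpl = EcgTemplate(p=z, q=z, r=z, s=z, t=EcgWave(0.0, 22.0, 9.0),
                           baseline_wander_amp=0.0, noise_sd=0.02)
        ecg, _ = generate_ecg(rr, fs=1000.0, template=tmpl, seed=1)
        assert np.abs(ecg.samples).max() < 0.2
        assert np.std(ecg.samples) == pytest.approx(0.02, rel=0.1)

    def test_template_invariants(self):
        with pytest.raises(ValueError, match="R amplitude"):
            EcgTemplate(r=EcgWave(0.1, 0.0, 2.0))
        with pytest.raises(ValueError, match="width"):
            EcgWave(1.0, 0.0, -1.0)

    def test_too_close_beats_rejected(self):
        rr = RRSeries(np.full(100, 40.0))
        with pytest.raises(ValueError, match="footprint"):
            generate_ecg(rr, fs=4000.0, seed=0)
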