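"""Spectral estimation, band separation, and per-cycle AC/DC extraction."""

import numpy as np
import pytest
from dataclasses import replace

import venoxim as vx
from venoxim.decompose import CyclePair, design_component_bands
from venoxim.errors import (
    InsufficientDataError,
    InvalidInputError,
    ResampleRequiredError,
    SeparationInfeasibleError,
)


def two_tone_ppg(f1=1.2, f2=4.0, a1=0.004, a2=0.008, offset=0.5, fs=100.0, dur=60.0):
    """Clean two-tone fixture on a positive baseline, both channels identical."""
    t = np.arange(int(dur * fs)) / fs
    x = offset + a1 * np.sin(2 * np.pi * f1 * t) + a2 * np.sin(2 * np.pi * f2 * t)
    return vx.DualWavelengthPPG(time=t, i_red=x.copy(), i_ir=x.copy())


class TestPowerSpectrum:
    def test_pure_tone_peak_within_one_bin(self):
        fs, dur, f0 = 100.0, 30.0, 2.3
        t = np.arange(int(dur * fs)) / fs
        x = 1.0 + 0.01 * np.sin(2 * np.pi * f0 * t)
        ppg = vx.DualWavelengthPPG(time=t, i_red=x, i_ir=x)
        spec = vx.compute_power_spectrum(ppg)
        peak = spec.frequency[np.argmax(spec.power_ir)]
        assert abs(peak - f0) <= spec.resolution

    def test_constant_signal_has_no_off_dc_power(self):
        t = np.arange(1000) / 100.0
        x = np.full_like(t, 0.7)
        spec = vx.compute_power_spectrum(vx.DualWavelengthPPG(time=t, i_red=x, i_ir=x))
        assert np.all(spec.power_red[spec.frequency > 0.5] < 1e-20)

    def test_simulated_ppg_shows_both_peaks(self, clean_ppg):
        spec = vx.compute_power_spectrum(clean_ppg)
        for f0 in (1.2, 4.0):
            band = (spec.frequency > f0 - 0.5) & (spec.frequency < f0 + 0.5)
            peak = spec.frequency[band][np.argmax(spec.total[band])]
            assert abs(peak - f0) <= spec.resolution

    def test_nonuniform_time_base_rejected(self):
        t = np.array([0.0, 0.01, 0.03, 0.035, 0.05])
        x = np.ones_like(t)
        with pytest.raises(ResampleRequiredError):
            vx.compute_power_spectrum(vx.DualWavelengthPPG(time=t, i_red=x, i_ir=x))


class TestPeakLocation:
    def test_two_tone_frequencies_recovered(self):
        spec = vx.compute_power_spectrum(two_tone_ppg())
        loc = vx.locate_component_peaks(
            spec, vx.BandSpec(1.5, 1.0), vx.BandSpec(6.0, 3.4)
        )
        assert abs(loc.pulse_freq - 1.2) <= spec.resolution
        assert abs(loc.stim_freq - 4.0) <= spec.resolution
        assert loc.separated

    def test_absent_stimulation_not_prominent(self, noisy_config):
        cfg = replace(noisy_config, venous_stim_amp=0.0)
        spec = vx.compute_power_spectrum(vx.simulate_ppg(cfg))
        loc = vx.locate_component_peaks(
            spec, vx.BandSpec(1.5, 1.0), vx.BandSpec(6.0, 3.4)
        )
        assert loc.pulse_prominent
        assert not loc.stim_prominent
        assert not loc.separated

    def test_overlapping_search_bands_rejected(self, clean_ppg):
        spec = vx.compute_power_spectrum(clean_ppg)
        with pytest.raises(InvalidInputError):
            vx.locate_component_peaks(spec, vx.BandSpec(2.0, 1.0), vx.BandSpec(3.0, 1.0))


class TestBandDesign:
    def test_bands_avoid_pulse_harmonics(self):
        pulse_band, stim_band = design_component_bands(1.2, 4.0)
        # 3.6 and 4.8 Hz are pulse harmonics; the stim band must exclude them
        assert not stim_band.contains(3.6)
        assert not stim_band.contains(4.8)
        assert not pulse_band.overlaps(stim_band)

    def test_collision_is_infeasible(self):
        with pytest.raises(SeparationInfeasibleError):
            design_component_bands(1.2, 1.2)

    def test_harmonic_collision_is_infeasible(self):
        with pytest.raises(SeparationInfeasibleError):
            design_component_bands(1.2, 2.4)

    def test_both_orderings_supported(self):
        # stimulation below the pulse rate must also yield valid bands
        pulse_band, stim_band = design_component_bands(1.5, 0.6)
        assert stim_band.center == 0.6
        assert not pulse_band.overlaps(stim_band)


class TestSeparation:
    def test_two_tone_recovery_and_leakage(self):
        f1, f2, a1, a2 = 1.2, 4.0, 0.004, 0.008
        ppg = two_tone_ppg(f1, f2, a1, a2)
        comps = vx.separate_components(ppg, f1, f2)
        g = comps.edge_guard
        sl = slice(g, len(ppg) - g)
        t = ppg.time[sl]
        tone1 = a1 * np.sin(2 * np.pi * f1 * t)
        tone2 = a2 * np.sin(2 * np.pi * f2 * t)

        def rel_rms(err, ref):
            return np.sqrt(np.mean(err**2)) / np.sqrt(np.mean(ref**2))

        # each component recovers its own tone...
        assert rel_rms(comps.pulse_ir[sl] - tone1, tone1) < 0.01
        assert rel_rms(comps.stim_ir[sl] - tone2, tone2) < 0.01
        # ...and carries <1 % RMS of the other (cross-band leakage)
        assert rel_rms(comps.pulse_ir[sl] - tone1, tone2) < 0.01
        assert rel_rms(comps.stim_ir[sl] - tone2, tone1) < 0.01

    def test_filter_linearity(self):
        ppg = two_tone_ppg()
        scaled = vx.DualWavelengthPPG(
            time=ppg.time, i_red=3.0 * ppg.i_red, i_ir=3.0 * ppg.i_ir
        )
        c1 = vx.separate_components(ppg, 1.2, 4.0)
        c3 = vx.separate_components(scaled, 1.2, 4.0)
        assert np.allclose(c3.pulse_ir, 3.0 * c1.pulse_ir, atol=1e-12)
        assert np.allclose(c3.stim_red, 3.0 * c1.stim_red, atol=1e-12)

    def test_absent_stimulation_component_is_negligible(self, clean_config):
        # stim-band content with the cuff off is <1 % (RMS) of the cuff-on signal
        def stim_rms(amp):
            ppg = vx.simulate_ppg(replace(clean_config, venous_stim_amp=amp))
            comps = vx.separate_components(ppg, 1.2, 4.0)
            g = comps.edge_guard
            return np.sqrt(np.mean(comps.stim_ir[g:-g] ** 2))

        assert stim_rms(0.0) < 0.01 * stim_rms(clean_config.venous_stim_amp)

    def test_determinism_on_seeded_noise(self, noisy_config):
        a = vx.separate_components(vx.simulate_ppg(noisy_config), 1.2, 4.0)
        b = vx.separate_components(vx.simulate_ppg(noisy_config), 1.2, 4.0)
        assert np.array_equal(a.stim_red, b.stim_red)
        assert np.array_equal(a.dc_ir, b.dc_ir)

    def test_overlapping_bands_rejected(self):
        ppg = two_tone_ppg()
        with pytest.raises(SeparationInfeasibleError):
            vx.separate_components(
                ppg, 1.2, 4.0,
                pulse_band=vx.BandSpec(2.0, 1.5), stim_band=vx.BandSpec(3.0, 1.0),
            )

    def test_group_delay_compensation_keeps_peaks_aligned(self):
        # zero-lag filtering: component extrema within one sample of the raw tone's
        fs, f0 = 100.0, 1.2
        t = np.arange(3000) / fs
        x = 0.5 + 0.01 * np.sin(2 * np.pi * f0 * t)
        ppg = vx.DualWavelengthPPG(time=t, i_red=x, i_ir=x)
        comps = vx.separate_components(ppg, f0, 4.0)
        g = comps.edge_guard
        pairs = vx.detect_cycle_extrema(comps.pulse_ir[g:-g], f0, fs)
        raw = x[g:-g]
        for p in pairs[1:-1]:
            w = slice(max(p.peak - 20, 0), p.peak + 21)
            raw_peak = w.start + np.argmax(raw[w])
            assert abs(raw_peak - p.peak) <= 1


class TestCycleExtrema:
    def test_clean_sinusoid_pair_count(self):
        fs, f0, n_cycles = 100.0, 2.0, 8
        t = np.arange(int(n_cycles * fs / f0)) / fs
        x = np.sin(2 * np.pi * f0 * t)
        pairs = vx.detect_stimulation_peaks(x, f0, fs)
        assert len(pairs) == n_cycles
        idx = [i for p in pairs for i in (p.peak, p.trough)]
        assert idx == sorted(idx)  # peak precedes its trough, pairs in order

    def test_amplitude_modulated_extrema_match_exhaustive_scan(self):
        fs, f0 = 100.0, 2.0
        t = np.arange(800) / fs
        x = (1.0 + 0.5 * np.sin(2 * np.pi * 0.2 * t)) * np.sin(2 * np.pi * f0 * t)
        pairs = vx.detect_stimulation_peaks(x, f0, fs)
        # exhaustive local-extremum scan as the oracle
        local_max = {i for i in range(1, len(x) - 1) if x[i - 1] < x[i] > x[i + 1]}
        local_min = {i for i in range(1, len(x) - 1) if x[i - 1] > x[i] < x[i + 1]}
        for p in pairs:
            assert p.peak in local_max
            assert p.trough in local_min

    def test_flat_trace_is_insufficient(self):
        with pytest.raises(InsufficientDataError):
            vx.detect_stimulation_peaks(np.zeros(500), 2.0, 100.0)

    def test_single_cycle_is_insufficient(self):
        fs, f0 = 100.0, 1.0
        t = np.arange(int(1.2 * fs)) / fs
        with pytest.raises(InsufficientDataError):
            vx.detect_stimulation_peaks(np.sin(2 * np.pi * f0 * t), f0, fs)


class TestAcDcExtraction:
    def test_sinusoid_analytic_values(self):
        fs, f0, a, b = 100.0, 2.0, 0.03, 0.8
        t = np.arange(600) / fs
        comp = a * np.sin(2 * np.pi * f0 * t)
        dc = np.full_like(comp, b)
        pairs = vx.detect_stimulation_peaks(comp, f0, fs)
        ac, dcv = vx.extract_ac_dc(comp, dc, pairs)
        # sampling can miss the true extremum by half a sample: ~0.2 % low bias
        assert np.allclose(ac, 2 * a, rtol=5e-3)
        assert np.allclose(dcv, b)

    def test_zero_amplitude_component_gives_zero_ac(self):
        comp = np.zeros(100)
        dc = np.ones(100)
        pairs = [CyclePair(10, 20), CyclePair(40, 50)]
        ac, _ = vx.extract_ac_dc(comp, dc, pairs)
        assert np.all(ac == 0.0)

    def test_nonpositive_dc_rejected(self):
        comp = np.sin(np.linspace(0, 4 * np.pi, 100))
        dc = np.zeros(100)
        with pytest.raises(InvalidInputError):
            vx.extract_ac_dc(comp, dc, [CyclePair(12, 37)])

    def test_forward_model_acdc_matches_relative_modulation(self, clean_ppg, clean_config):
        # noiseless stim-band AC/DC ratio equals the forward model's ΔI/I
        comps = vx.separate_components(clean_ppg, 1.2, 4.0)
        g = comps.edge_guard
        fs = clean_config.sampling_rate
        pairs = vx.detect_stimulation_peaks(comps.stim_ir[g:-g], 4.0, fs)
        ac, dcv = vx.extract_ac_dc(comps.stim_ir[g:-g], comps.dc_ir[g:-g], pairs)
        # forward model: stimulation-band log-intensity swing at 940 nm
        cfg, coefs = clean_config, clean_config.coefficients
        mu_mix = (
            coefs.effective(cfg.svo2, "ir")
            + cfg.arterial_stim_coupling * coefs.effective(cfg.sao2, "ir")
        )
        full_swing = mu_mix * cfg.venous_stim_amp
        med = np.median(ac / dcv)
        # the band-pass keeps only the cuff fundamental, whose peak-to-trough is
        # 2·|c1|·full_swing with c1 the first Fourier coefficient of the drive
        phase = np.arange(4096) / 4096
        w = vx.simulate.cuff_waveform(phase)
        c1 = np.abs(2.0 * np.mean(w * np.exp(-2j * np.pi * phase)))
        assert med == pytest.approx(2.0 * c1 * full_swing, rel=0.03)
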