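"""Modulation-index PAC: extraction, MI, comodulograms, surrogates."""

import numpy as np
import pytest
from scipy.stats import chisquare, spearmanr

from gammasurge._dsp import analytic, band_limited_noise
from gammasurge.core import Recording
from gammasurge.pac import (
    PACParams,
    band_pac_matrix,
    comodulogram,
    extract_amplitude,
    extract_phase,
    modulation_index,
    pac_surrogate_threshold,
)
from gammasurge.synth import PACLink, SessionSpec, StageSpec, gen_pac_signal, gen_session

FS = 512.0


def brute_force_mi(phase, amp, n_bins):
    """Literal histogram evaluation of the MI formula, loop by loop."""
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    means = []
    for j in range(n_bins):
        sel = (phase > edges[j]) & (phase <= edges[j + 1])
        means.append(amp[sel].mean() if sel.any() else 0.0)
    p = np.array(means) / np.sum(means)
    h = -sum(pj * np.log(pj) for pj in p if pj > 0)
    return (np.log(n_bins) - h) / np.log(n_bins)


class TestExtraction:
    def test_phase_advances_linearly(self):
        f = 10.0
        t = np.arange(int(20 * FS)) / FS
        x = np.sin(2 * np.pi * f * t)
        phase = extract_phase(x, FS, (8, 12))[1024:-1024]
        slope = np.polyfit(np.arange(len(phase)) / FS, np.unwrap(phase), 1)[0]
        assert slope == pytest.approx(2 * np.pi * f, rel=1e-3)

    def test_noisy_phase_tracks_truth(self, rng):
        f = 10.0
        t = np.arange(int(20 * FS)) / FS
        true_phase = np.angle(np.exp(1j * (2 * np.pi * f * t - np.pi / 2)))
        x = np.sin(2 * np.pi * f * t) + 0.1 * rng.standard_normal(len(t))
        est = extract_phase(x, FS, (8, 12))[1024:-1024]
        r = np.abs(np.mean(np.exp(1j * (est - true_phase[1024:-1024]))))
        assert r > 0.99  # circular correlation with the true phase

    def test_offband_phase_uniform(self, rng):
        # a band that excludes the tone sees only noise: phase ~ uniform
        t = np.arange(int(60 * FS)) / FS
        x = np.sin(2 * np.pi * 10 * t) + rng.standard_normal(len(t))
        phase = extract_phase(x, FS, (30, 40))[1024:-1024]
        sub = phase[:: int(FS // 4)]  # decorrelate before chi-square
        counts, _ = np.histogram(sub, bins=8, range=(-np.pi, np.pi))
        assert chisquare(counts).pvalue > 0.01

    def test_constant_amplitude_flat_envelope(self):
        t = np.arange(int(10 * FS)) / FS
        x = 3.0 * np.sin(2 * np.pi * 40 * t)
        env = extract_amplitude(x, FS, (30, 50))[1024:-1024]
        assert np.abs(env - 3.0).max() < 0.05

    def test_am_envelope_recovered(self):
        t = np.arange(int(20 * FS)) / FS
        true_env = 1.0 + 0.3 * np.sin(2 * np.pi * 2 * t)
        x = true_env * np.sin(2 * np.pi * 40 * t)
        env = extract_amplitude(x, FS, (30, 50))[1024:-1024]
        rms_err = np.sqrt(np.mean((env - true_env[1024:-1024]) ** 2))
        assert rms_err / np.sqrt(np.mean(true_env**2)) < 0.02

    def test_zero_signal_zero_envelope(self):
        env = extract_amplitude(np.zeros(int(10 * FS)), FS, (30, 50))
        assert np.abs(env).max() < 1e-10


class TestModulationIndex:
    def test_constant_envelope_zero(self, rng):
        phase = rng.uniform(-np.pi, np.pi, 20000)
        assert modulation_index(phase, np.ones(20000)) == 0.0

    def test_single_bin_envelope_one(self, rng):
        phase = rng.uniform(-np.pi, np.pi, 20000)
        amp = np.where((phase > 0) & (phase < 2 * np.pi / 18), 1.0, 0.0)
        mi = modulation_index(phase, amp, 18)
        assert mi == pytest.approx(1.0, abs=1e-12)

    def test_matches_bruteforce_histogram(self):
        phase = np.linspace(-np.pi + 1e-9, np.pi, 100000)
        amp = 1.0 + 0.5 * np.cos(phase)
        mi = modulation_index(phase, amp, 18)
        assert mi == pytest.approx(brute_force_mi(phase, amp, 18), abs=1e-12)

    def test_invariances(self, rng):
        phase = rng.uniform(-np.pi, np.pi, 50000)
        amp = 1.0 + 0.5 * np.cos(phase) + 0.05 * rng.standard_normal(50000)
        amp = np.abs(amp)
        base = modulation_index(phase, amp)
        assert modulation_index(phase, 17.3 * amp) == pytest.approx(base, abs=1e-15)
        shifted = np.angle(np.exp(1j * (phase + 2 * np.pi / 18)))  # whole bin
        assert modulation_index(shifted, amp) == pytest.approx(base, abs=1e-3)

    def test_all_zero_amplitude_rejected(self, rng):
        with pytest.raises(ValueError):
            modulation_index(rng.uniform(-np.pi, np.pi, 100), np.zeros(100))


class TestComodulogram:
    def test_argmax_at_injected_cell(self):
        x = gen_pac_signal(FS, 60, 10, 80, 0.9, seed=1)
        rec = Recording(x[None, :], FS, ["C4"])
        cm = comodulogram(
            rec, "C4", "C4", np.arange(4, 21, 2.0), np.arange(40, 121, 10.0)
        )
        assert cm.argmax_cell() == (10.0, 80.0)

    def test_masked_cells_are_nan_not_zero(self):
        x = gen_pac_signal(FS, 20, 10, 80, 0.5, seed=2)
        rec = Recording(x[None, :], FS, ["C4"])
        cm = comodulogram(rec, "C4", "C4", np.array([20.0]), np.array([10.0, 80.0]))
        assert np.isnan(cm.mi[0, 0])  # amp 10 Hz below phase 20 Hz: masked
        assert np.isfinite(cm.mi[0, 1])

    def test_too_short_record_rejected(self):
        rec = Recording(np.zeros((1, int(1.0 * FS))), FS, ["C4"])
        with pytest.raises(ValueError, match="cycles"):
            comodulogram(rec, "C4", "C4", np.array([2.0]), np.array([40.0]))


def _coupled_aperiodic(rng, dur=40.0, chi=0.9):
    """Noise-carrier PAC whose alignment circular shifts can destroy."""
    n = int(dur * FS)
    slow = band_limited_noise(rng, n, FS, 8, 12, 1.0)
    phase = np.angle(analytic(slow))
    carrier = band_limited_noise(rng, n, FS, 70, 90, 1.0)
    x = slow + (1 + chi * np.cos(phase)) * carrier + 0.1 * rng.standard_normal(n)
    ph = extract_phase(x, FS, (8, 12))[512:-512]
    am = extract_amplitude(x, FS, (65, 95))[512:-512]
    return ph, am


class TestSurrogates:
    def test_strong_coupling_high_z(self, rng):
        ph, am = _coupled_aperiodic(rng)
        _, z = pac_surrogate_threshold(
            ph, am, FS, PACParams(n_surrogates=100, seed=0)
        )
        assert z >= 5.0

    def test_alpha_one_gives_min_surrogate(self, rng):
        ph, am = _coupled_aperiodic(rng, dur=10.0, chi=0.0)
        params = PACParams(n_surrogates=100, alpha=1.0, seed=0)
        thr, _ = pac_surrogate_threshold(ph, am, FS, params)
        sur_rng = np.random.default_rng(0)
        shifts = sur_rng.integers(int(FS), len(ph) - int(FS), size=100)
        sur = [modulation_index(ph, np.roll(am, s)) for s in shifts]
        assert thr == pytest.approx(min(sur), abs=1e-15)

    def test_too_few_surrogates_rejected(self, rng):
        ph, am = _coupled_aperiodic(rng, dur=10.0)
        with pytest.raises(ValueError, match="n_surrogates"):
            pac_surrogate_threshold(ph, am, FS, PACParams(n_surrogates=10))

    def test_short_record_rejected(self, rng):
        with pytest.raises(ValueError, match="short"):
            pac_surrogate_threshold(
                rng.uniform(-np.pi, np.pi, 256), np.ones(256), FS,
                PACParams(n_surrogates=100),
            )


def _pac_session(seed, phase_ch, amp_ch):
    stage = StageSpec(
        label="S1",
        duration=40.0,
        band_amp={ch: {"gamma2": 0.5, "beta": 1.0} for ch in
                  ("F8", "C3", "C4", "O1")},
        pac_links=[PACLink(phase_ch, amp_ch, "beta", "gamma2", 0.9,
                           slow_uv=8.0, fast_uv=4.0)],
    )
    return gen_session(SessionSpec(stages=[stage], seed=seed))


class TestBandPACMatrix:
    def test_local_argmax_at_injected_channel(self):
        rec, stages, _ = _pac_session(3, "C4", "C4")
        mat = band_pac_matrix(rec, "beta", "gamma2", mode="local",
                              params=PACParams(seed=0))
        diag = np.diag(mat.values.to_numpy())
        order = np.argsort(diag)
        assert mat.values.index[order[-1]] == "C4"
        assert diag[order[-1]] >= 3 * diag[order[-2]]

    def test_cross_argmax_at_injected_pair(self):
        rec, stages, _ = _pac_session(4, "F8", "C4")
        mat = band_pac_matrix(rec, "beta", "gamma2", mode="cross",
                              params=PACParams(seed=0))
        v = mat.values.to_numpy()
        i, j = np.unravel_index(np.nanargmax(v), v.shape)
        assert (mat.values.index[i], mat.values.columns[j]) == ("F8", "C4")

    def test_local_and_cross_agree_on_same_channel(self):
        # a cross-mode cell with phase channel == amp channel must equal the
        # local value: same signals, same estimator path
        rec, stages, _ = _pac_session(5, "C4", "C4")
        params = PACParams(seed=0)
        local = band_pac_matrix(rec, "beta", "gamma2", "local", params)
        from gammasurge.pac import _windowed_mi

        cross_same = _windowed_mi(
            rec.get("C4"), rec.get("C4"), rec.fs,
            local.phase_band, local.amp_band, params,
        )
        assert cross_same == pytest.approx(local.values.loc["C4", "C4"], abs=1e-12)

    def test_non_gamma_amplitude_rejected(self, short_recording):
        with pytest.raises(ValueError, match="gamma"):
            band_pac_matrix(short_recording, "delta", "alpha", mode="local")


def test_mi_monotone_in_coupling_strength():
    chis = np.arange(0, 1.0, 0.1)
    mis = []
    for chi in chis:
        x = gen_pac_signal(FS, 30, 10, 80, chi, seed=7)
        ph = extract_phase(x, FS, (9, 11))[512:-512]
        am = extract_amplitude(x, FS, (69, 91))[512:-512]
        mis.append(modulation_index(ph, am))
    assert spearmanr(chis, mis).statistic >= 0.95
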