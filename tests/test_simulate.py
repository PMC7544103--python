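"""Simulator contracts: determinism, coupling law, artifacts, respiration."""
import numpy as np
import pytest
from conftest import quiet_sim_config

from pttrack.config import ConfigurationError, SimulationConfig
from pttrack.simulate import simulate_cohort, simulate_subject


def test_same_seed_and_index_reproduce_bit_identical_records():
    cfg = quiet_sim_config(
        sbp_noise_sd=2.0, ecg_noise_sd=0.02, p_missing_beat=0.05, seed=9
    )
    rec1, tr1 = simulate_subject(cfg, 3)
    rec2, tr2 = simulate_subject(cfg, 3)
    for name in rec1.channels:
        assert np.array_equal(rec1.channels[name], rec2.channels[name])
    assert np.array_equal(tr1.true_ptt, tr2.true_ptt)
    assert np.array_equal(tr1.injected_flags, tr2.injected_flags)


def test_constant_sbp_yields_exact_peaks_and_ptt_from_inverse_law():
    # slope -1.0, intercept 470 -> SBP 130 corresponds to PTT 340 ms
    cfg = quiet_sim_config(
        sbp_baseline=130.0,
        sbp_nadir=100.0,
        true_slope_mean=-1.0,
        true_slope_sd=0.0,
        ptt_at_baseline=340.0,
        resp_bp_amp=0.0,
        rsa_depth=0.0,
    )
    rec, truth = simulate_subject(cfg, 0)
    assert truth.true_intercept == pytest.approx(470.0)
    pre = truth.beat_times < cfg.ramp_onset
    assert pre.sum() > 50
    assert np.allclose(truth.true_sbp[pre], 130.0)
    assert np.allclose(truth.true_ptt[pre], 340.0)
    # rendered ABP local maximum equals that beat's SBP exactly
    abp = rec.channel("abp")
    fs = rec.fs
    for t, ptt in zip(truth.beat_times[pre], truth.true_ptt[pre]):
        peak = int(round(t * fs)) + int(round(ptt * fs / 1000.0))
        assert abp[peak] == pytest.approx(130.0, abs=1e-9)
        assert abp[peak] >= abp[peak - 1] and abp[peak] >= abp[peak + 1]


def test_rendered_abp_peak_times_match_true_ptt_within_one_sample(quiet_subject):
    rec, truth = quiet_subject
    abp = rec.channel("abp")
    fs = rec.fs
    for t, ptt in zip(truth.beat_times, truth.true_ptt):
        r = int(round(t * fs))
        lo, hi = r + int(0.05 * fs), r + int(0.6 * fs)
        peak = lo + int(np.argmax(abp[lo:hi]))
        assert abs((peak - r) / fs * 1000.0 - ptt) <= 1000.0 / fs


def test_missing_beat_fraction_matches_injection_probability():
    cfg = quiet_sim_config(p_missing_beat=0.5, record_duration=220.0,
                           ramp_onset=30.0, ramp_duration=100.0,
                           nadir_hold=20.0, recovery_duration=40.0, seed=21)
    _, truth = simulate_subject(cfg, 0)
    assert truth.n_beats >= 200
    frac = np.mean(truth.injected_flags == "missing")
    assert abs(frac - 0.5) < 0.1


def test_qrs_count_equals_beat_count(quiet_subject):
    rec, truth = quiet_subject
    ecg = rec.channel("ecg")
    # zero noise: every QRS is an isolated run of samples above half the R amp
    above = ecg > 0.5
    n_qrs = int(np.sum(above[1:] & ~above[:-1]) + above[0])
    assert n_qrs == truth.n_beats


def test_beat_wise_sbp_spectrum_peaks_at_respiratory_rate():
    cfg = quiet_sim_config(
        rsa_depth=0.0, record_duration=430.0, ramp_onset=320.0,
        ramp_duration=60.0, nadir_hold=5.0, recovery_duration=10.0,
    )
    _, truth = simulate_subject(cfg, 0)
    pre = truth.beat_times < cfg.ramp_onset
    x = truth.true_sbp[pre] - np.mean(truth.true_sbp[pre])
    spec = np.abs(np.fft.rfft(x))
    spec[0] = 0.0
    beat_rate = cfg.mean_hr / 60.0
    freqs = np.fft.rfftfreq(len(x), d=1.0 / beat_rate)
    f_dominant = freqs[np.argmax(spec)]
    assert f_dominant == pytest.approx(cfg.resp_rate / 60.0, rel=0.05)


def test_independent_hr_coupling_leaves_hr_uncorrelated_with_sbp():
    cfg = quiet_sim_config(
        record_duration=700.0, ramp_onset=150.0, ramp_duration=200.0,
        nadir_hold=60.0, recovery_duration=120.0, sbp_noise_sd=2.0, seed=4,
    )
    _, truth = simulate_subject(cfg, 0)
    assert truth.n_beats >= 500
    r = np.corrcoef(truth.true_hr, truth.true_sbp)[0, 1]
    assert abs(r) < 0.1


def test_baroreflex_coupling_raises_hr_as_sbp_falls():
    cfg = quiet_sim_config(hr_coupling="baroreflex", sbp_noise_sd=0.0)
    _, truth = simulate_subject(cfg, 0)
    r = np.corrcoef(truth.true_hr, truth.true_sbp)[0, 1]
    assert r < -0.5


def test_truth_obeys_linear_law_up_to_injected_ptt_noise():
    cfg = quiet_sim_config(sbp_noise_sd=2.0, ptt_noise_sd=3.0, seed=8)
    _, truth = simulate_subject(cfg, 0)
    resid = truth.true_sbp - (
        truth.true_slope * truth.true_ptt + truth.true_intercept
    )
    assert np.max(np.abs(resid)) < 6 * abs(truth.true_slope) * 3.0


def test_cohort_slope_draws():
    cfg = quiet_sim_config(n_subjects=5, true_slope_sd=0.0)
    cohort = simulate_cohort(cfg)
    slopes = [t.true_slope for _, t in cohort]
    assert np.allclose(slopes, cfg.true_slope_mean)
    # different cohort seeds must differ once sd > 0
    a = simulate_cohort(quiet_sim_config(n_subjects=2, true_slope_sd=0.4, seed=1))
    b = simulate_cohort(quiet_sim_config(n_subjects=2, true_slope_sd=0.4, seed=2))
    assert a[0][1].true_slope != b[0][1].true_slope


def test_cohort_slope_sample_mean_near_population_mean():
    # CLT: sd 0.4 / sqrt(500) ~ 0.018, so +-0.06 is a >3-sigma band
    from pttrack.simulate import draw_subject_slope

    cfg = quiet_sim_config(true_slope_sd=0.4, seed=13)
    draws = [draw_subject_slope(cfg, i) for i in range(500)]
    assert abs(np.mean(draws) - (-1.23)) < 0.06


@pytest.mark.parametrize(
    "kw",
    [
        dict(fs=0.0),
        dict(p_missing_beat=1.5),
        dict(sbp_baseline=80.0, sbp_nadir=90.0),
        dict(ramp_duration=1000.0),
        dict(ramp_onset=350.0),  # ramp does not fit in the record
        dict(hr_coupling="magic"),
    ],
)
def test_invalid_configurations_are_rejected(kw):
    with pytest.raises(ConfigurationError):
        quiet_sim_config(**kw).validate()
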