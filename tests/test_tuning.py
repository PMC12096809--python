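"""FRA metrics: BF/CF tie-breaks, Q10dB, latency/duration, recovery."""

import numpy as np
import pytest

import batvoc as bv
from batvoc.psth import NonResponsiveError
from batvoc.tuning import FRA, best_frequency, characteristic_frequency, q10db
from batvoc.units import default_tone_freqs_khz


def _fra(freqs, levels, response, criterion=1.0):
    return FRA(
        freqs_khz=np.asarray(freqs, float),
        levels_db=np.asarray(levels, float),
        response=np.asarray(response, float),
        spontaneous_rate=0.1,
        criterion=criterion,
    )


class TestBestFrequency:
    def test_single_peak(self):
        freqs, levels = [20.0, 30.0, 40.0], [40.0, 50.0, 60.0]
        resp = np.zeros((3, 3))
        resp[2, 2] = 5.0  # (60 dB, 40 kHz)
        assert best_frequency(_fra(freqs, levels, resp)) == (40.0, 60.0)

    def test_tie_breaks_low_freq_then_high_level(self):
        freqs, levels = [20.0, 30.0, 40.0], [40.0, 50.0]
        resp = np.zeros((2, 3))
        resp[0, 0] = resp[1, 0] = resp[1, 2] = 5.0
        # ties at 20 kHz (both levels) and 40 kHz: lowest freq wins, then highest level
        assert best_frequency(_fra(freqs, levels, resp)) == (20.0, 50.0)

    def test_non_responsive_raises(self):
        with pytest.raises(NonResponsiveError):
            best_frequency(_fra([20.0], [40.0], [[0.0]]))


class TestCharacteristicFrequency:
    def test_v_shape_tip(self):
        freqs = [20.0, 25.0, 30.0, 35.0, 40.0]
        levels = [25.0, 35.0, 45.0]
        resp = np.zeros((3, 5))
        resp[0, 2] = 2.0            # tip at (30 kHz, 25 dB)
        resp[1, 1:4] = 3.0
        resp[2, :] = 4.0
        assert characteristic_frequency(_fra(freqs, levels, resp)) == (30.0, 25.0)

    def test_flat_threshold_row_tie_goes_to_bf(self):
        freqs = [20.0, 30.0, 40.0]
        levels = [25.0, 45.0]
        resp = np.array([[2.0, 2.0, 2.0], [2.0, 9.0, 2.0]])  # BF at 30 kHz
        assert characteristic_frequency(_fra(freqs, levels, resp)) == (30.0, 25.0)


class TestQ10:
    def test_band_25_to_35_gives_3(self):
        # responsive run 25..35 kHz at cf_threshold + 10; edge responses barely
        # above criterion so the interpolated edges sit at the edge cells
        freqs = [20.0, 25.0, 30.0, 35.0, 40.0]
        levels = [25.0, 35.0]
        eps = 1e-6
        resp = np.array([
            [0.0, 0.0, 2.0, 0.0, 0.0],
            [0.0, 1.0 + eps, 9.0, 1.0 + eps, 0.0],
        ])
        q, censored = q10db(_fra(freqs, levels, resp), cf_khz=30.0, cf_threshold_db=25.0)
        assert not censored
        assert q == pytest.approx(30.0 / 10.0, abs=1e-3)

    def test_band_28_to_32_gives_7_5(self):
        freqs = [24.0, 28.0, 30.0, 32.0, 36.0]
        levels = [25.0, 35.0]
        eps = 1e-6
        resp = np.array([
            [0.0, 0.0, 2.0, 0.0, 0.0],
            [0.0, 1.0 + eps, 9.0, 1.0 + eps, 0.0],
        ])
        q, censored = q10db(_fra(freqs, levels, resp), 30.0, 25.0)
        assert not censored
        assert q == pytest.approx(30.0 / 4.0, abs=2e-2)

    def test_edge_touching_band_is_censored(self):
        freqs = [20.0, 30.0, 40.0]
        levels = [25.0, 35.0]
        resp = np.array([[0.0, 2.0, 0.0], [5.0, 5.0, 5.0]])
        _, censored = q10db(_fra(freqs, levels, resp), 30.0, 25.0)
        assert censored

    def test_invariant_to_uniform_scaling(self):
        freqs = [20.0, 25.0, 30.0, 35.0, 40.0]
        levels = [25.0, 35.0]
        resp = np.array([[0, 0, 2.0, 0, 0], [0, 1.5, 9.0, 1.5, 0.0]], float)
        fra1 = _fra(freqs, levels, resp, criterion=1.0)
        fra2 = _fra(freqs, levels, 10 * resp, criterion=10.0)
        q1, _ = q10db(fra1, 30.0, 25.0)
        q2, _ = q10db(fra2, 30.0, 25.0)
        assert q1 == pytest.approx(q2)

    def test_q10_recovery_simulated(self):
        """Programmed Q10dB of 4 recovered within +-1 (CF on the grid)."""
        grid_freqs = default_tone_freqs_khz()
        cf = float(grid_freqs[np.argmin(np.abs(grid_freqs - 30.0))])
        vals = []
        for seed in range(6):
            prof = bv.UnitProfile(
                unit_id=f"q{seed}", latency_ms=10.0, response_kernel="tonic",
                response_duration_ms=60.0, baseline_rate_hz=5.0,
                driven_gain_hz=150.0, jitter_ms=1.0, cf_khz=cf, q10=4.0,
                threshold_db=40.0,
            )
            grid = bv.simulate_tone_grid(prof, protocol=bv.TrialProtocol(50, 300, 10, seed=seed))
            vals.append(bv.summarize_unit(grid).q10)
        assert abs(np.nanmedian(vals) - 4.0) < 1.0


class TestLatencyDuration:
    def test_hand_built_psth(self):
        # 1-ms bins over [0, 200): baseline 1 count, evoked burst 10 counts
        counts = np.ones(200)
        counts[80:140] = 10.0
        psth = bv.PSTH(1.0, 0.0, counts, n_trials=20)
        lat, dur = bv.latency_and_duration(psth, pre_ms=50.0)
        assert lat == pytest.approx(30.0)
        assert dur == pytest.approx(60.0)

    def test_flat_psth_non_responsive(self):
        psth = bv.PSTH(1.0, 0.0, np.ones(200), n_trials=20)
        with pytest.raises(NonResponsiveError):
            bv.latency_and_duration(psth)

    def test_latency_recovery_dac_like(self):
        """Programmed 6-ms latency recovered within 2 ms (median over seeds)."""
        errs = []
        for seed in range(6):
            prof = bv.UnitProfile(
                unit_id=f"l{seed}", latency_ms=6.0, response_kernel="tonic",
                response_duration_ms=48.0, baseline_rate_hz=5.0,
                driven_gain_hz=200.0, jitter_ms=0.5, cf_khz=30.0, q10=4.0,
                threshold_db=40.0,
            )
            grid = bv.simulate_tone_grid(prof, protocol=bv.TrialProtocol(50, 300, 10, seed=seed))
            ts = bv.summarize_unit(grid)
            errs.append(abs(ts.latency_ms - 6.0))
        assert np.median(errs) <= 2.0


def test_fra_median_robust_to_outlier_trial(library):
    """Inflating the strongest trial per cell cannot change the median FRA
    (a mean-based response would shift by the injected burst size)."""
    prof = bv.UnitProfile(
        unit_id="u", cf_khz=30.0, q10=4.0, threshold_db=40.0, latency_ms=8.0,
        response_kernel="tonic", response_duration_ms=60.0,
        baseline_rate_hz=4.0, driven_gain_hz=200.0, jitter_ms=0.5,
    )
    proto = bv.TrialProtocol(50.0, 300.0, n_trials=11, seed=5)
    grid = bv.simulate_tone_grid(prof, [20.0, 30.0], [40.0, 60.0], protocol=proto)
    fra1 = bv.compute_fra(grid)
    for sts in grid.values():
        counts = sts.spike_count(50.0, 150.0)
        k = int(np.argmax(counts))
        sts.trials[k] = np.sort(np.concatenate([sts.trials[k], np.linspace(60, 140, 40)]))
    fra2 = bv.compute_fra(grid)
    assert np.allclose(fra1.response, fra2.response, atol=1e-9)


def test_faf_like_anchor_recovery(library):
    """FAF-like units: ~35 ms latency, ~95 ms tonic duration recovered."""
    prof = bv.UnitProfile(
        unit_id="faf", area="FAF", latency_ms=35.0, response_kernel="tonic",
        response_duration_ms=95.0, baseline_rate_hz=8.0, driven_gain_hz=150.0,
        jitter_ms=2.0, cf_khz=56.0, q10=4.4, threshold_db=45.0,
    )
    grid = bv.simulate_tone_grid(prof, protocol=bv.TrialProtocol(50, 300, 10, seed=9))
    ts = bv.summarize_unit(grid)
    assert ts.responsive
    assert abs(ts.latency_ms - 35.0) <= 4.0
    assert abs(ts.response_duration_ms - 95.0) / 95.0 <= 0.2
    assert abs(np.log2(ts.cf_khz / 56.0)) <= 2 / 8  # within two grid steps
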