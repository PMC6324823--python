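"""Event detection, cumulative binning, PPR, MK-801 decay, Sr2+ quanta."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cpsyn.events import (
    EventSeries,
    Recording,
    bin_cumulative,
    detect_events,
    mk801_decay,
    ppr,
    rank_bin_means,
    sr_quantal_analysis,
)
from cpsyn.exceptions import UnreliableMeasurement
from cpsyn.synth import (
    SynapseModel,
    simulate_mepsc,
    simulate_mk801,
    simulate_ppr_pair,
    simulate_sr_release,
)


def _match(det_times, true_times, tol_s=5e-3):
    used = np.zeros(det_times.size, dtype=bool)
    matched = 0
    for t in true_times:
        if det_times.size == 0:
            break
        i = int(np.argmin(np.abs(det_times - t)))
        if abs(det_times[i] - t) < tol_s and not used[i]:
            used[i] = True
            matched += 1
    return matched


class TestDetection:
    def test_flat_recording_yields_empty_series(self):
        rec = Recording(np.zeros(10_000), 10_000.0)
        assert len(detect_events(rec)) == 0

    def test_noiseless_count_and_constant_latency(self):
        """Noiseless, well-separated events: every event is found, all at
        the same kernel-peak latency after the true onset."""
        rec, truth = simulate_mepsc(2.0, duration_s=30.0, noise_sd_pA=0.0,
                                    seed=4)
        tt = truth["time_s"].to_numpy()
        assert np.min(np.diff(tt)) > 0.02  # no overlapping events this seed
        ev = detect_events(rec)
        assert len(ev) == len(truth)
        latency = ev.times_s - tt
        # constant detection latency, to within one sample
        assert np.ptp(latency) <= 1.0 / rec.sample_rate_hz + 1e-12

    def test_sensitivity_and_precision_at_snr5(self):
        rec, truth = simulate_mepsc(5.0, amp_mean_pA=10.0, duration_s=60.0,
                                    noise_sd_pA=2.0, seed=0)
        ev = detect_events(rec)
        matched = _match(ev.times_s, truth["time_s"].to_numpy())
        assert matched / len(truth) >= 0.95  # sensitivity
        assert matched / len(ev) >= 0.95  # precision

    def test_rejects_too_short_recording(self):
        with pytest.raises(ValueError):
            detect_events(Recording(np.zeros(10), 10_000.0))


class TestBinning:
    def test_bin_means_of_1_to_400(self):
        """Values 1..400 in 20 rank bins of 20: means 10.5, 30.5, ... 390.5."""
        cell = EventSeries("c", np.arange(400) * 0.1 + 0.1,
                           np.random.default_rng(0).permutation(400) + 1.0,
                           duration_s=60.0)
        binned = bin_cumulative([cell], "amplitude")
        np.testing.assert_allclose(binned.bin_values,
                                   np.arange(10.5, 400, 20.0))

    def test_identical_cells_average_to_single_cell(self, rng):
        amps = rng.gamma(10, 1.2, 400)
        cells = [
            EventSeries(f"c{i}", np.arange(400) * 0.2 + 0.1, amps, 90.0)
            for i in range(5)
        ]
        binned = bin_cumulative(cells, "amplitude")
        np.testing.assert_allclose(binned.bin_values, binned.per_cell_bins[0])

    def test_nondecreasing_and_mean_conservation(self, rng):
        cells = [
            EventSeries(
                f"c{i}",
                np.cumsum(rng.exponential(0.2, 400)),
                rng.gamma(11.1, 12 / 11.1, 400),
                120.0,
            )
            for i in range(6)
        ]
        binned = bin_cumulative(cells, "amplitude")
        assert np.all(np.diff(binned.bin_values) >= 0)
        # grand mean of bin means equals the grand per-cell mean
        assert binned.bin_values.mean() == pytest.approx(
            binned.per_cell_means["mean"].mean(), abs=1e-12
        )

    def test_short_cells_excluded_with_log(self, rng):
        short = EventSeries("short", np.arange(100) * 0.1 + 0.1,
                            np.ones(100), 20.0)
        full = EventSeries(
            "full", np.cumsum(rng.exponential(0.2, 400)),
            rng.gamma(10, 1.0, 400), 90.0
        )
        binned = bin_cumulative([short, full], "amplitude")
        assert binned.n_cells == 1
        assert binned.excluded[0][0] == "short"

    def test_iei_binning_uses_intervals(self, rng):
        t = np.cumsum(rng.exponential(0.2, 400))
        cell = EventSeries("c", t, np.ones(400), 120.0)
        binned = bin_cumulative([cell], "iei")
        assert np.all(np.diff(binned.bin_values) >= 0)
        assert binned.per_cell_means["mean"].iloc[0] == pytest.approx(
            np.diff(t).mean() * 1e3
        )


class TestPPR:
    def test_identical_nonoverlapping_responses_give_unity(self):
        trace = simulate_ppr_pair(80.0, 0.0, 200.0, tau_decay_ms=3.0)
        m = ppr(trace, 10_000.0, 20.0, 200.0)
        assert m.ratio == pytest.approx(1.0, abs=1e-3)

    @pytest.mark.parametrize("interval_ms", [50.0, 100.0, 200.0])
    def test_depletion_recovered_through_tail_subtraction(self, interval_ms):
        d = 0.25
        trace = simulate_ppr_pair(80.0, d, interval_ms)
        m = ppr(trace, 10_000.0, 20.0, interval_ms)
        assert m.ratio == pytest.approx(1.0 - d, rel=0.01)

    def test_gain_invariance(self):
        trace = simulate_ppr_pair(80.0, 0.3, 50.0)
        r1 = ppr(trace, 10_000.0, 20.0, 50.0).ratio
        r2 = ppr(trace * 7.5, 10_000.0, 20.0, 50.0).ratio
        assert r1 == pytest.approx(r2, rel=1e-6)

    def test_absent_first_response_signalled(self):
        trace = np.zeros(4000)
        with pytest.raises(UnreliableMeasurement):
            ppr(trace, 10_000.0, 20.0, 50.0)


class TestMK801Fit:
    def test_survival_recovers_release_probability(self):
        p = 0.3
        m = SynapseModel(n_synapses=100, silent_fraction=0.0, release_prob=p,
                         noise_sd_pA=0.0, seed=31)
        rng = np.random.default_rng(31)
        peaks = np.vstack(
            [simulate_mk801(m, 50, rng=rng)["peak_pA"].to_numpy()
             for _ in range(40)]
        )
        decay = mk801_decay(peaks)
        assert decay.survival == pytest.approx(1.0 - p, abs=0.03)
        assert not decay.degenerate

    def test_survival_monotone_in_release_probability(self):
        """Fitted survival decreases with p with perfect rank order."""
        rng = np.random.default_rng(5)
        survivals = []
        for p in np.arange(0.1, 0.95, 0.1):
            m = SynapseModel(n_synapses=100, silent_fraction=0.0,
                             release_prob=float(p), noise_sd_pA=0.0, seed=1)
            peaks = np.vstack(
                [simulate_mk801(m, 30, rng=rng)["peak_pA"].to_numpy()
                 for _ in range(20)]
            )
            survivals.append(mk801_decay(peaks).survival)
        rho = stats.spearmanr(np.arange(len(survivals)), survivals).statistic
        assert rho == pytest.approx(-1.0)

    def test_flat_series_flagged_degenerate(self):
        decay = mk801_decay(np.ones(30))
        assert decay.degenerate
        assert decay.survival > 0.99

    def test_nonpositive_first_peak_rejected(self):
        with pytest.raises(ValueError):
            mk801_decay(np.concatenate([[0.0], np.ones(29)]))


class TestSrQuantal:
    def test_deterministic_quanta_recovered_exactly(self):
        m = SynapseModel(quantal_cv=0.0, noise_sd_pA=0.0, seed=3)
        ev = simulate_sr_release(m, 400.0, 80)
        res = sr_quantal_analysis(ev, 400.0)
        assert res.mean_amplitude_pA == pytest.approx(m.quantal_mean_ampa_pA)

    def test_evoked_and_spontaneous_quanta_agree(self):
        """Sr2+-evoked quantal size matches the spontaneous (mEPSC-style)
        amplitude distribution when the generator parameters coincide."""
        m = SynapseModel(n_synapses=5, silent_fraction=0.0, release_prob=0.4,
                         quantal_mean_ampa_pA=12.0, quantal_cv=0.3,
                         noise_sd_pA=0.0, seed=8)
        ev = simulate_sr_release(m, 400.0, 1500)
        res = sr_quantal_analysis(ev, 400.0)
        _, truth = simulate_mepsc(5.0, amp_mean_pA=12.0, amp_cv=0.3,
                                  duration_s=120.0, noise_sd_pA=0.0, seed=9)
        t = stats.ttest_ind(res.amplitudes_pA, truth["amplitude_pA"])
        assert t.pvalue > 0.01

    def test_doubling_rate_halves_mean_iei(self):
        means = []
        for i, p in enumerate((0.15, 0.3)):
            m = SynapseModel(n_synapses=100, silent_fraction=0.0,
                             release_prob=p, noise_sd_pA=0.0, seed=2)
            ev = simulate_sr_release(m, 400.0, 800,
                                     rng=np.random.default_rng(100 + i))
            means.append(sr_quantal_analysis(ev, 400.0).mean_iei_ms)
        # twice the per-synapse release probability => twice the event
        # density in the window => mean IEI halves (Poisson-like thinning)
        assert means[0] / means[1] == pytest.approx(2.0, rel=0.1)

    def test_empty_window_rejected(self):
        ev = pd.DataFrame({"stimulus": [0], "time_ms": [500.0],
                           "amplitude_pA": [10.0]})
        with pytest.raises(ValueError):
            sr_quantal_analysis(ev, 400.0)


class TestRankBins:
    def test_requires_enough_values(self):
        with pytest.raises(ValueError):
            rank_bin_means(np.arange(10), 20)

    def test_output_sorted_for_any_input(self, rng):
        v = rng.normal(size=403)
        out = rank_bin_means(v)
        assert np.all(np.diff(out) >= 0)
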