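"""Minimal-stimulation analysis: QC, classification, the silent-synapse
estimator, potency and NMDA potency."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cpsyn.exceptions import EstimatorUndefined, UnreliableMeasurement
from cpsyn.minstim import (
    VH_AMPA,
    VH_COMPOSITE,
    MinStimDataset,
    TraceSpec,
    ampa_nmda_ratio,
    analyze_cell,
    classify_trials,
    nmda_potency,
    qc_filter,
    silent_fraction,
)
from cpsyn.synth import SynapseModel, simulate_minstim, simulate_minstim_cohort
from cpsyn._util import double_exp_kernel


def _cell(cell_id, rs, drift):
    trials = pd.DataFrame(
        {"vh_mv": [VH_AMPA, VH_COMPOSITE], "peak_pA": [10.0, 10.0],
         "baseline_rms_pA": [1.0, 1.0]}
    )
    qc = {}
    if rs is not None:
        qc["series_resistance_mohm"] = rs
    if drift is not None:
        qc["resistance_drift_fraction"] = drift
    return MinStimDataset(cell_id=cell_id, trials=trials, qc=qc)


class TestQC:
    @pytest.mark.parametrize(
        "rs,drift,kept",
        [
            (29.0, 0.10, True),   # inside both limits
            (30.0, 0.10, False),  # series resistance bound is strict
            (15.0, 0.25, False),  # drift bound is strict
            (15.0, 0.20, False),  # drift exactly at the bound
            (29.999, 0.199, True),
        ],
    )
    def test_retention_rules(self, rs, drift, kept):
        retained, excluded = qc_filter([_cell("c", rs, drift)])
        assert (len(retained) == 1) is kept
        if not kept:
            assert excluded[0][0] == "c"

    def test_missing_qc_fields_excluded_with_reason(self):
        _, excluded = qc_filter([_cell("c", None, 0.1)])
        assert excluded == [("c", "missing qc fields")]


class TestEstimator:
    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        p=st.floats(0.05, 0.95),
        n=st.integers(2, 10),
        n_silent=st.integers(0, 9),
    )
    def test_identity_on_exact_binomial_rates(self, p, n, n_silent):
        """1 - ln((1-p)^Na)/ln((1-p)^N) = 1 - Na/N for every p."""
        n_silent = min(n_silent, n - 1)
        n_active = n - n_silent
        f60 = (1.0 - p) ** n_active
        f40 = (1.0 - p) ** n
        est = silent_fraction(f60, f40)
        assert abs(est - n_silent / n) < 1e-12

    def test_equal_rates_give_zero(self):
        assert silent_fraction(0.3, 0.3) == pytest.approx(0.0, abs=1e-15)

    def test_negative_values_returned_unclipped(self):
        val = silent_fraction(0.25, 0.35)
        assert val == pytest.approx(1 - math.log(0.25) / math.log(0.35))
        assert val < 0

    @pytest.mark.parametrize("f60,f40", [(0.0, 0.5), (0.5, 0.0), (0.5, 1.0)])
    def test_degenerate_rates_signalled_explicitly(self, f60, f40):
        with pytest.raises(EstimatorUndefined):
            silent_fraction(f60, f40)

    def test_out_of_range_rates_rejected(self):
        with pytest.raises(ValueError):
            silent_fraction(1.5, 0.5)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        f40=st.floats(0.05, 0.95),
        f60a=st.floats(0.05, 0.95),
        f60b=st.floats(0.05, 0.95),
    )
    def test_strictly_monotone_in_f60(self, f40, f60a, f60b):
        """More failures at -60 mV (F+40 fixed) means more silent synapses:
        the estimator is strictly increasing in F-60."""
        if f60a == f60b:
            return
        lo, hi = sorted((f60a, f60b))
        assert silent_fraction(lo, f40) < silent_fraction(hi, f40)


class TestClassification:
    def test_matches_ground_truth_at_high_snr(self):
        m = SynapseModel(noise_sd_pA=0.5, seed=17)
        ds = simulate_minstim(m, 2000)
        success = classify_trials(ds)
        match = (success == ~ds.trials["is_failure_true"]).mean()
        assert match >= 0.99

    def test_trace_classification_matches_ground_truth(self, trace_spec):
        m = SynapseModel(noise_sd_pA=0.3, seed=18)
        ds = simulate_minstim(m, 100, spec=trace_spec, render_traces=True)
        success = classify_trials(ds)
        match = (success == ~ds.trials["is_failure_true"]).mean()
        assert match >= 0.99

    def test_noiseless_flat_trace_is_failure(self, trace_spec):
        m = SynapseModel(silent_fraction=0.4, noise_sd_pA=0.0, seed=19)
        ds = simulate_minstim(m, 200, spec=trace_spec, render_traces=True)
        success = classify_trials(ds)
        assert (success == ~ds.trials["is_failure_true"]).all()


class TestAnalyzeCell:
    def test_all_success_potency_and_success_rate(self):
        trials = pd.DataFrame(
            {
                "vh_mv": [VH_AMPA] * 4 + [VH_COMPOSITE] * 4,
                "peak_pA": [20.0] * 4 + [15.0, 15.0, 0.0, 0.0],
                "baseline_rms_pA": 1.0,
            }
        )
        res = analyze_cell(MinStimDataset("c", trials))
        assert res.potency_pA == pytest.approx(20.0)
        assert res.success_rate == pytest.approx(1.0)
        assert res.f_plus40 == pytest.approx(0.5)
        assert not res.estimator_defined  # F-60 = 0 has no estimator value

    def test_no_success_cell_flagged_undefined(self):
        trials = pd.DataFrame(
            {
                "vh_mv": [VH_AMPA] * 4 + [VH_COMPOSITE] * 4,
                "peak_pA": [0.0] * 4 + [15.0, 15.0, 15.0, 0.0],
                "baseline_rms_pA": 1.0,
            }
        )
        res = analyze_cell(MinStimDataset("c", trials))
        assert res.f_minus60 == 1.0
        assert not res.estimator_defined
        assert res.silent_fraction is None
        assert res.potency_pA is None

    def test_invariant_under_trial_permutation(self, default_model):
        ds = simulate_minstim(default_model, 200)
        shuffled = MinStimDataset(
            ds.cell_id,
            ds.trials.sample(frac=1.0, random_state=0).reset_index(drop=True),
            qc=ds.qc,
        )
        a, b = analyze_cell(ds), analyze_cell(shuffled)
        assert a.f_minus60 == b.f_minus60
        assert a.f_plus40 == b.f_plus40
        assert a.silent_fraction == pytest.approx(b.silent_fraction)
        assert a.potency_pA == pytest.approx(b.potency_pA)

    def test_cohort_recovery_across_silent_fractions(self):
        """Mean estimate within 2 points of the realized silent fraction."""
        for s in (0.0, 0.25, 0.5, 0.8):
            model = SynapseModel(
                n_synapses=5, silent_fraction=s, release_prob=0.3,
                noise_sd_pA=1.0, seed=100 + int(s * 100),
            )
            cells = simulate_minstim_cohort(model, 200, 200)
            res = [analyze_cell(c) for c in cells]
            est = np.array(
                [r.silent_fraction for r in res if r.estimator_defined]
            )
            assert est.size > 150
            assert abs(est.mean() - model.realized_silent_fraction) < 0.02


class TestTraceMeasures:
    def _traces(self, spec, ampa_pA, nmda_pA):
        t_ms = np.arange(spec.n_samples) / spec.sample_rate_hz * 1e3 - spec.baseline_ms
        k_a = double_exp_kernel(t_ms, spec.tau_rise_ampa_ms, spec.tau_decay_ampa_ms)
        k_n = double_exp_kernel(t_ms, spec.tau_rise_nmda_ms, spec.tau_decay_nmda_ms)
        trace60 = -ampa_pA * k_a
        trace40 = ampa_pA * k_a + nmda_pA * k_n
        return trace60, trace40

    def test_ratio_is_direct_quotient_on_simple_traces(self, trace_spec):
        t60, t40 = self._traces(trace_spec, 100.0, 80.0)
        # oracle: read the +40 trace 50 ms after its own argmax
        spec = trace_spec
        j0, j1 = spec.window_indices(VH_COMPOSITE)
        pk = int(np.argmax(t40[j0:j1])) + j0
        lag = int(round(0.050 * spec.sample_rate_hz))
        i0, i1 = spec.window_indices(VH_AMPA)
        expected = np.max(-t60[i0:i1]) / t40[pk + lag]
        assert ampa_nmda_ratio(t60, t40, spec) == pytest.approx(expected)

    def test_pure_nmda_cell_signalled_or_tiny(self, trace_spec):
        t60, t40 = self._traces(trace_spec, 0.0, 80.0)
        ratio = ampa_nmda_ratio(t60, t40, trace_spec)
        assert ratio == pytest.approx(0.0, abs=1e-9)

    def test_ratio_monotone_in_active_fraction(self, trace_spec):
        ratios = []
        for active_frac in (0.2, 0.4, 0.6, 0.8, 1.0):
            t60, t40 = self._traces(trace_spec, 100.0 * active_frac, 80.0)
            ratios.append(ampa_nmda_ratio(t60, t40, trace_spec))
        assert np.all(np.diff(ratios) > 0)

    def test_denominator_below_noise_floor_signalled(self, trace_spec):
        t60, t40 = self._traces(trace_spec, 100.0, 1.0)
        with pytest.raises(UnreliableMeasurement):
            ampa_nmda_ratio(t60, t40, trace_spec, noise_floor_pA=5.0)

    def test_nmda_potency_zero_failures_equals_success_peak(self, trace_spec):
        m = SynapseModel(n_synapses=5, silent_fraction=0.0, release_prob=1.0,
                         quantal_cv=0.0, noise_sd_pA=0.0, seed=1)
        ds = simulate_minstim(m, 20, spec=trace_spec, render_traces=True)
        res = nmda_potency(ds)
        assert res.no_failures
        assert res.potency_pA == pytest.approx(5 * m.quantal_mean_nmda_pA, rel=1e-6)

    def test_nmda_potency_matches_conditional_expectation(self, trace_spec):
        """Noiseless single-quantum potency = E[quanta | success] * q."""
        n, p, q = 5, 0.3, 10.0
        m = SynapseModel(n_synapses=n, silent_fraction=0.0, release_prob=p,
                         quantal_mean_nmda_pA=q, quantal_cv=0.0,
                         noise_sd_pA=0.0, seed=23)
        ds = simulate_minstim(m, 3000, spec=trace_spec, render_traces=True)
        res = nmda_potency(ds)
        # oracle: enumerate the binomial release configurations
        from math import comb

        probs = np.array([comb(n, k) * p**k * (1 - p) ** (n - k)
                          for k in range(n + 1)])
        expect = sum(k * probs[k] for k in range(1, n + 1)) / (1 - probs[0]) * q
        assert res.n_failure > 0
        assert res.potency_pA == pytest.approx(expect, rel=0.05)


class TestTraceSpecValidation:
    def test_window_outside_trace_rejected(self):
        with pytest.raises(ValueError):
            TraceSpec(duration_ms=40.0, window_plus40_ms=(5.0, 60.0))

    def test_inverted_kinetics_rejected(self):
        with pytest.raises(ValueError):
            TraceSpec(tau_rise_ampa_ms=5.0, tau_decay_ampa_ms=1.0)
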