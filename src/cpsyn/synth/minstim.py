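"""Simulated minimal-stimulation, MK-801, Sr2+ and paired-pulse data.

Each generator draws per-synapse vesicle release as independent
Bernoulli(p) events and per-release quantal amplitudes from a gamma
distribution, then either tabulates trial peaks (fast, the default) or
renders full stimulus-aligned traces with difference-of-exponential
kinetics on a Gaussian-noise baseline. Ground-truth labels (releases per
trial, failure flags) are always attached so every analysis stage has a
recoverable target.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .._util import double_exp_kernel, gamma_amplitudes, gamma_sum
from ..minstim import VH_AMPA, VH_COMPOSITE, MinStimDataset, TraceSpec
from .models import SynapseModel

__all__ = [
    "simulate_minstim",
    "simulate_minstim_cohort",
    "simulate_mk801",
    "simulate_sr_release",
    "simulate_ppr_pair",
]


def _render_traces(
    amps: np.ndarray, vh: float, spec: TraceSpec, noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Stimulus-aligned traces: noise + sign * amp * kernel(t - t_stim)."""
    n = amps.size
    t_ms = (np.arange(spec.n_samples) / spec.sample_rate_hz) * 1e3 - spec.baseline_ms
    if vh < 0:
        kernel = double_exp_kernel(t_ms, spec.tau_rise_ampa_ms, spec.tau_decay_ampa_ms)
    else:
        kernel = double_exp_kernel(t_ms, spec.tau_rise_nmda_ms, spec.tau_decay_nmda_ms)
    sign = -1.0 if vh < 0 else 1.0
    traces = sign * amps[:, None] * kernel[None, :]
    if noise_sd > 0:
        traces = traces + rng.normal(0.0, noise_sd, traces.shape)
    return traces


def simulate_minstim(
    model: SynapseModel,
    n_trials_per_vh: int = 50,
    spec: TraceSpec | None = None,
    render_traces: bool = False,
    cell_id: str = "sim",
    rng: np.random.Generator | None = None,
) -> MinStimDataset:
    """One simulated minimal-stimulation cell.

    At -60 mV each AMPA-active synapse releases independently with
    probability p and contributes a gamma quantal amplitude; at +40 mV
    all synapses (silent included) contribute NMDA-mediated amplitude.
    The tabulated ``peak_pA`` is the summed quantal amplitude plus one
    Gaussian noise draw (a peak-picked measurement); ground-truth
    columns ``n_released`` and ``is_failure_true`` record the release
    configuration, a failure being a trial on which zero synapses
    released. With ``render_traces`` full traces are attached and
    classification can run on them instead.
    """
    if n_trials_per_vh < 1:
        raise ValueError("n_trials_per_vh must be >= 1")
    spec = spec or TraceSpec()
    rng = rng if rng is not None else model.rng()
    frames = []
    traces: dict[float, np.ndarray] = {}
    for vh, n_syn, qmean in (
        (VH_AMPA, model.n_active, model.quantal_mean_ampa_pA),
        (VH_COMPOSITE, model.n_synapses, model.quantal_mean_nmda_pA),
    ):
        released = (
            rng.binomial(n_syn, model.release_prob, n_trials_per_vh)
            if n_syn > 0
            else np.zeros(n_trials_per_vh, dtype=int)
        )
        amps = gamma_sum(released, qmean, model.quantal_cv, rng)
        meas = np.abs(amps + rng.normal(0.0, model.noise_sd_pA, n_trials_per_vh)) \
            if model.noise_sd_pA > 0 else amps.copy()
        frames.append(
            pd.DataFrame(
                {
                    "vh_mv": vh,
                    "peak_pA": meas,
                    "baseline_rms_pA": model.noise_sd_pA,
                    "n_released": released,
                    "is_failure_true": released == 0,
                }
            )
        )
        if render_traces:
            traces[vh] = _render_traces(amps, vh, spec, model.noise_sd_pA, rng)
    trials = pd.concat(frames, ignore_index=True)
    return MinStimDataset(
        cell_id=cell_id,
        trials=trials,
        qc={"series_resistance_mohm": 15.0, "resistance_drift_fraction": 0.05},
        traces=traces if render_traces else None,
        trace_spec=spec if render_traces else None,
    )


def simulate_minstim_cohort(
    model: SynapseModel,
    n_cells: int,
    n_trials_per_vh: int = 200,
    seed: int | None = None,
    **kwargs,
) -> list[MinStimDataset]:
    """Independent cells sharing one generative model (one RNG stream)."""
    rng = np.random.default_rng(model.seed if seed is None else seed)
    return [
        simulate_minstim(
            model, n_trials_per_vh, cell_id=f"cell{i:04d}", rng=rng, **kwargs
        )
        for i in range(n_cells)
    ]


def simulate_mk801(
    model: SynapseModel,
    n_stimuli: int = 50,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-sweep NMDA-EPSC peaks under open-channel (MK-801) block.

    A synapse that releases on a sweep while unblocked contributes its
    NMDA quantal amplitude and is then permanently blocked (the open
    channel is required for block). With blocking certainty the expected
    normalized peak after k sweeps is (1-p)^(k-1). Returns columns
    ``sweep`` (1-based), ``peak_pA`` (with measurement noise) and the
    ground-truth ``n_unblocked_released``.
    """
    if n_stimuli < 1:
        raise ValueError("n_stimuli must be >= 1")
    rng = rng if rng is not None else model.rng()
    unblocked = np.ones(model.n_synapses, dtype=bool)
    rows = []
    for sweep in range(1, n_stimuli + 1):
        release = rng.random(model.n_synapses) < model.release_prob
        contributing = release & unblocked
        k = int(contributing.sum())
        amp = float(
            gamma_amplitudes(
                model.quantal_mean_nmda_pA, model.quantal_cv, k, rng
            ).sum()
        )
        if model.noise_sd_pA > 0:
            amp += float(rng.normal(0.0, model.noise_sd_pA))
        unblocked &= ~release
        rows.append(
            {"sweep": sweep, "peak_pA": amp, "n_unblocked_released": k}
        )
    return pd.DataFrame(rows)


def simulate_sr_release(
    model: SynapseModel,
    window_ms: float = 400.0,
    n_stimuli: int = 100,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Sr2+-desynchronized evoked quantal events.

    Replacing Ca2+ with Sr2+ desynchronizes vesicle release: each
    AMPA-active synapse that releases emits its quantum at a random
    latency within the post-stimulus window, so individual quantal
    amplitudes are resolvable. Returns one row per event with columns
    ``stimulus``, ``time_ms`` and ``amplitude_pA``.
    """
    if window_ms <= 0:
        raise ValueError("window_ms must be positive")
    if n_stimuli < 1:
        raise ValueError("n_stimuli must be >= 1")
    rng = rng if rng is not None else model.rng()
    rows = []
    for stim in range(n_stimuli):
        release = rng.random(model.n_active) < model.release_prob
        k = int(release.sum())
        if k == 0:
            continue
        t = np.sort(rng.uniform(0.0, window_ms, k))
        a = gamma_amplitudes(model.quantal_mean_ampa_pA, model.quantal_cv, k, rng)
        if model.noise_sd_pA > 0:
            a = np.abs(a + rng.normal(0.0, model.noise_sd_pA, k))
        for ti, ai in zip(t, a):
            rows.append({"stimulus": stim, "time_ms": ti, "amplitude_pA": ai})
    return pd.DataFrame(rows, columns=["stimulus", "time_ms", "amplitude_pA"])


def simulate_ppr_pair(
    amp1_pA: float,
    depletion: float,
    interval_ms: float,
    sample_rate_hz: float = 10_000.0,
    stim1_ms: float = 20.0,
    tail_ms: float = 100.0,
    tau_rise_ms: float = 0.5,
    tau_decay_ms: float = 8.0,
    noise_sd_pA: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Paired-pulse trace: second response scaled by (1 - depletion).

    Renders two inward (negative) responses with identical kinetics at
    ``stim1_ms`` and ``stim1_ms + interval_ms``; the overlapping decay
    tail of response 1 is exactly the kernel's, so tail-subtraction
    recovery can be checked against a closed form.
    """
    if not 0.0 <= depletion <= 1.0:
        raise ValueError("depletion must lie in [0, 1]")
    fs = sample_rate_hz
    n = int(round((stim1_ms + interval_ms + tail_ms) * 1e-3 * fs))
    t_ms = np.arange(n) / fs * 1e3
    k1 = double_exp_kernel(t_ms - stim1_ms, tau_rise_ms, tau_decay_ms)
    k2 = double_exp_kernel(t_ms - stim1_ms - interval_ms, tau_rise_ms, tau_decay_ms)
    trace = -(amp1_pA * k1 + amp1_pA * (1.0 - depletion) * k2)
    if noise_sd_pA > 0:
        trace = trace + np.random.default_rng(seed).normal(0.0, noise_sd_pA, n)
    return trace
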