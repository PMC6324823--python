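"""Continuous mEPSC recording synthesis.

Event times are homogeneous Poisson; amplitudes i.i.d. gamma; each event
is rendered as an inward (negative) difference-of-exponentials transient
on a Gaussian-noise baseline.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .._util import double_exp_kernel, gamma_amplitudes
from ..events import Recording

__all__ = ["simulate_mepsc"]


def simulate_mepsc(
    rate_hz: float,
    amp_mean_pA: float = 12.0,
    amp_cv: float = 0.3,
    duration_s: float = 120.0,
    noise_sd_pA: float = 1.5,
    seed: int = 0,
    sample_rate_hz: float = 10_000.0,
    tau_rise_ms: float = 0.5,
    tau_decay_ms: float = 4.0,
    cell_id: str = "sim",
) -> tuple[Recording, pd.DataFrame]:
    """Poisson train of quantal events on a noisy baseline.

    Returns the continuous recording (inward events, polarity -1) and a
    ground-truth table with columns ``time_s`` and ``amplitude_pA``.
    Defaults emulate a cortical mEPSC recording in TTX: ~12 pA quanta,
    amplitude CV 0.3, 1.5 pA baseline noise at 10 kHz.
    """
    if rate_hz <= 0 or duration_s <= 0:
        raise ValueError("rate_hz and duration_s must be positive")
    rng = np.random.default_rng(seed)
    n_samples = int(round(duration_s * sample_rate_hz))
    # Poisson times via exponential gaps, clipped to the recording
    expected = rate_hz * duration_s
    gaps = rng.exponential(1.0 / rate_hz, size=int(expected + 6 * np.sqrt(expected) + 10))
    times = np.cumsum(gaps)
    while times.size and times[-1] < duration_s:
        extra = rng.exponential(1.0 / rate_hz, size=100)
        times = np.concatenate([times, times[-1] + np.cumsum(extra)])
    times = times[times < duration_s]
    amps = gamma_amplitudes(amp_mean_pA, amp_cv, times.size, rng)

    signal = np.zeros(n_samples)
    idx = np.minimum((times * sample_rate_hz).round().astype(int), n_samples - 1)
    np.add.at(signal, idx, amps)
    t_ms = np.arange(int(8 * tau_decay_ms * 1e-3 * sample_rate_hz)) / sample_rate_hz * 1e3
    kernel = double_exp_kernel(t_ms, tau_rise_ms, tau_decay_ms)
    signal = fftconvolve(signal, kernel)[:n_samples]
    signal = -signal  # inward currents
    if noise_sd_pA > 0:
        signal = signal + rng.normal(0.0, noise_sd_pA, n_samples)
    rec = Recording(
        signal=signal, sample_rate_hz=sample_rate_hz, polarity=-1, cell_id=cell_id
    )
    truth = pd.DataFrame({"time_s": times, "amplitude_pA": amps})
    return rec, truth
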