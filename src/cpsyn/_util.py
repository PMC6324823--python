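"""Shared numerical helpers: seeding, kernels, circular statistics."""

from __future__ import annotations

import zlib

import numpy as np

__all__ = [
    "derive_rng",
    "derive_seed",
    "gamma_amplitudes",
    "gamma_sum",
    "double_exp_kernel",
    "wrap_2pi",
    "circular_difference",
    "boxcar_smooth",
]


def derive_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from one master seed.

    Uses a CRC32 of the stage name so stages can be rerun independently
    without sharing streams. Result is always < 2**31.
    """
    ss = np.random.SeedSequence([int(master_seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


def derive_rng(master_seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(derive_seed(master_seed, stage))


def gamma_amplitudes(
    mean: float, cv: float, size, rng: np.random.Generator
) -> np.ndarray:
    """Positive amplitudes with given mean and coefficient of variation.

    Gamma-distributed (shape k = 1/cv^2, scale = mean*cv^2); cv = 0 yields
    the constant mean.
    """
    if mean < 0 or cv < 0:
        raise ValueError("mean and cv must be non-negative")
    if cv == 0 or mean == 0:
        return np.full(size, float(mean))
    shape = 1.0 / cv**2
    return rng.gamma(shape, mean / shape, size)


def gamma_sum(
    k: np.ndarray, mean: float, cv: float, rng: np.random.Generator
) -> np.ndarray:
    """Sum of ``k`` i.i.d. gamma amplitudes per entry, drawn in one shot.

    Exploits gamma additivity: a sum of k draws with shape a is one draw
    with shape k*a. Entries with k = 0 are exactly zero.
    """
    k = np.asarray(k)
    out = np.zeros(k.shape, dtype=float)
    pos = k > 0
    if not np.any(pos):
        return out
    if cv == 0 or mean == 0:
        out[pos] = k[pos] * mean
        return out
    shape = 1.0 / cv**2
    out[pos] = rng.gamma(k[pos] * shape, mean / shape)
    return out


def double_exp_kernel(
    t_ms: np.ndarray, tau_rise_ms: float, tau_decay_ms: float
) -> np.ndarray:
    """Unit-peak difference-of-exponentials synaptic kernel.

    k(t) = exp(-t/tau_d) - exp(-t/tau_r), normalised so its maximum is 1;
    zero for t < 0. Requires tau_rise < tau_decay.
    """
    if not 0 < tau_rise_ms < tau_decay_ms:
        raise ValueError("need 0 < tau_rise_ms < tau_decay_ms")
    t = np.asarray(t_ms, dtype=float)
    k = np.where(t >= 0, np.exp(-t / tau_decay_ms) - np.exp(-t / tau_rise_ms), 0.0)
    # analytic peak time of the difference of exponentials
    t_peak = (
        tau_rise_ms
        * tau_decay_ms
        / (tau_decay_ms - tau_rise_ms)
        * np.log(tau_decay_ms / tau_rise_ms)
    )
    peak = np.exp(-t_peak / tau_decay_ms) - np.exp(-t_peak / tau_rise_ms)
    return k / peak


def wrap_2pi(phi: np.ndarray) -> np.ndarray:
    """Wrap angles into [0, 2*pi)."""
    return np.mod(phi, 2.0 * np.pi)


def circular_difference(a, b) -> np.ndarray:
    """Absolute circular difference in [0, pi]."""
    d = np.mod(np.asarray(a) - np.asarray(b) + np.pi, 2.0 * np.pi) - np.pi
    return np.abs(d)


def boxcar_smooth(x: np.ndarray, width_samples: int) -> np.ndarray:
    """Centred moving average with edge-shrinking normalisation."""
    if width_samples <= 1:
        return np.asarray(x, dtype=float)
    kernel = np.ones(int(width_samples))
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x, dtype=float), kernel, mode="same")
    return num / den
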