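"""Periodic-stimulus response movie synthesis.

Each pixel oscillates at the stimulus frequency with a programmed
amplitude (per eye) and a retinotopic phase; Gaussian frame noise and an
optional pink (1/f) temporal component are added on top. Amplitudes are
in the convention of intrinsic-signal imaging: fractional reflectance
change x 1e-4.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .._util import wrap_2pi
from ..fourier_maps import ResponseMovie

__all__ = ["ImagingGroundTruth", "simulate_movie", "linear_phase_field"]


def linear_phase_field(shape: tuple[int, int], axis: int = 1) -> np.ndarray:
    """Retinotopic phase ramp spanning one full cycle across the map."""
    h, w = shape
    n = shape[axis]
    ramp = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return np.broadcast_to(ramp if axis == 1 else ramp[:, None], (h, w)).copy()


@dataclass
class ImagingGroundTruth:
    """Programmed per-pixel response fields for one imaging experiment."""

    amplitude_contra: np.ndarray
    amplitude_ipsi: np.ndarray
    phase: np.ndarray
    stim_freq_hz: float = 0.125
    frame_rate_hz: float = 7.5
    n_frames: int = 600
    noise_sd: float = 0.0
    pink_amp: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.amplitude_contra = np.asarray(self.amplitude_contra, dtype=float)
        self.amplitude_ipsi = np.asarray(self.amplitude_ipsi, dtype=float)
        self.phase = wrap_2pi(np.asarray(self.phase, dtype=float))
        shapes = {
            self.amplitude_contra.shape,
            self.amplitude_ipsi.shape,
            self.phase.shape,
        }
        if len(shapes) != 1:
            raise ValueError("ground-truth fields must share one shape")
        if np.any(self.amplitude_contra < 0) or np.any(self.amplitude_ipsi < 0):
            raise ValueError("amplitude fields must be non-negative")
        cycles = self.n_frames * self.stim_freq_hz / self.frame_rate_hz
        if cycles < 5:
            raise ValueError(
                f"n_frames must span at least 5 stimulus cycles (got {cycles:.2f})"
            )

    def amplitude(self, eye: str) -> np.ndarray:
        if eye == "contra":
            return self.amplitude_contra
        if eye == "ipsi":
            return self.amplitude_ipsi
        raise ValueError("eye must be 'contra' or 'ipsi'")


def _pink_noise(t: int, hw: tuple[int, int], amp: float,
                rng: np.random.Generator) -> np.ndarray:
    """Temporal 1/f noise per pixel via spectral shaping."""
    freqs = np.fft.rfftfreq(t)
    scale = np.zeros_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    white = rng.normal(size=(t,) + hw)
    spec = np.fft.rfft(white, axis=0) * scale[:, None, None]
    pink = np.fft.irfft(spec, n=t, axis=0)
    pink /= pink.std(axis=0, keepdims=True).clip(min=1e-12)
    return amp * pink


def simulate_movie(
    gt: ImagingGroundTruth,
    eye: str = "contra",
    run_id: str | None = None,
    rng: np.random.Generator | None = None,
) -> ResponseMovie:
    """Render one run: A(eye) * cos(2*pi*f*t - phase) + noise.

    Raises if ``n_frames`` does not span one full stimulus cycle (the
    ground-truth container already requires five).
    """
    cycles = gt.n_frames * gt.stim_freq_hz / gt.frame_rate_hz
    if cycles < 1:
        raise ValueError("movie must span at least one full stimulus cycle")
    rng = rng if rng is not None else np.random.default_rng(gt.seed)
    t = np.arange(gt.n_frames) / gt.frame_rate_hz
    amp = gt.amplitude(eye)
    frames = amp[None, :, :] * np.cos(
        2.0 * np.pi * gt.stim_freq_hz * t[:, None, None] - gt.phase[None, :, :]
    )
    if gt.noise_sd > 0:
        frames = frames + rng.normal(0.0, gt.noise_sd, frames.shape)
    if gt.pink_amp > 0:
        frames = frames + _pink_noise(gt.n_frames, amp.shape, gt.pink_amp, rng)
    return ResponseMovie(
        frames=frames,
        frame_rate_hz=gt.frame_rate_hz,
        stim_freq_hz=gt.stim_freq_hz,
        eye=eye,
        run_id=run_id,
    )
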