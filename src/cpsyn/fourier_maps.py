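"""Fourier analysis of periodic-stimulus intrinsic-signal movies.

A temporally periodic visual stimulus drives cortical reflectance at the
stimulus frequency; per-pixel projection onto that frequency yields an
amplitude map (response magnitude, conventionally expressed as fractional
reflectance change x 1e-4) and a phase map encoding retinotopic position.
Contra/ipsi amplitude maps combine into per-pixel ocular-dominance scores
(C-I)/(C+I) and their mean over responsive pixels, the ODI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._util import circular_difference, wrap_2pi

logger = logging.getLogger(__name__)

__all__ = [
    "ResponseMovie",
    "RetinoMaps",
    "ODMap",
    "BlockODIResult",
    "temporal_bin",
    "fourier_extract",
    "od_analysis",
    "odi_blocks",
    "map_scatter",
]


@dataclass
class ResponseMovie:
    """Frame stack with stimulus metadata. Frames are (T, H, W)."""

    frames: np.ndarray
    frame_rate_hz: float
    stim_freq_hz: float
    eye: str = "contra"
    run_id: str | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) array")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frames contain non-finite values")
        if self.frame_rate_hz <= 0 or self.stim_freq_hz <= 0:
            raise ValueError("frame_rate_hz and stim_freq_hz must be positive")
        if self.eye not in ("contra", "ipsi"):
            raise ValueError("eye must be 'contra' or 'ipsi'")

    @property
    def n_cycles(self) -> float:
        return self.frames.shape[0] * self.stim_freq_hz / self.frame_rate_hz


@dataclass
class RetinoMaps:
    """Amplitude (>= 0) and phase (wrapped to [0, 2*pi)) maps."""

    amplitude: np.ndarray
    phase: np.ndarray

    def __post_init__(self) -> None:
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        self.phase = np.asarray(self.phase, dtype=float)
        if self.amplitude.shape != self.phase.shape:
            raise ValueError("amplitude and phase must share a shape")
        if np.any(self.amplitude < 0):
            raise ValueError("amplitude map must be non-negative")
        self.phase = wrap_2pi(self.phase)


@dataclass
class ODMap:
    """Per-pixel OD score map, responsive mask, and their mean (ODI)."""

    od_score: np.ndarray  # NaN outside the responsive mask
    responsive_mask: np.ndarray
    odi: float


@dataclass
class BlockODIResult:
    block_odis: np.ndarray
    animal_odi: float | None
    excluded: bool
    n_dropped_runs: int
    reason: str | None = None


# ---------------------------------------------------------------------------


def temporal_bin(frames: np.ndarray, factor: int = 4) -> np.ndarray:
    """Non-overlapping temporal averaging (30 Hz -> 7.5 Hz with factor 4).

    A trailing remainder of fewer than ``factor`` frames is dropped and
    logged.
    """
    frames = np.asarray(frames, dtype=float)
    if factor < 1:
        raise ValueError("factor must be >= 1")
    t = frames.shape[0]
    if t < factor:
        raise ValueError(f"need at least {factor} frames, got {t}")
    n_out = t // factor
    dropped = t - n_out * factor
    if dropped:
        logger.info("temporal_bin: dropping %d trailing frame(s)", dropped)
    return frames[: n_out * factor].reshape((n_out, factor) + frames.shape[1:]).mean(axis=1)


def fourier_extract(movie: ResponseMovie, detrend: str | None = "linear") -> RetinoMaps:
    """Per-pixel projection onto the stimulus frequency.

    Each pixel's time series (optionally detrended to remove slow
    hemodynamic drift) is projected onto cos/sin at ``stim_freq_hz``;
    amplitude is 2/T times the modulus, so a pure cosine of amplitude A
    is recovered as A, and phase is the cosine phase offset wrapped to
    [0, 2*pi).
    """
    fr, f = movie.frame_rate_hz, movie.stim_freq_hz
    if f >= fr / 2:
        raise ValueError("stim_freq_hz must be below the Nyquist frequency")
    t_frames = movie.frames.shape[0]
    min_t = int(np.ceil(fr / f))
    if t_frames < min_t:
        raise ValueError(
            f"stimulus frequency not resolvable: need at least {min_t} frames "
            f"(one full cycle), got {t_frames}"
        )
    x = movie.frames
    t = np.arange(t_frames) / fr
    if detrend == "linear":
        # least-squares line per pixel, removed before projection
        design = np.vstack([np.ones_like(t), t]).T
        coef, *_ = np.linalg.lstsq(design, x.reshape(t_frames, -1), rcond=None)
        x = x - (design @ coef).reshape(x.shape)
    elif detrend == "mean":
        x = x - x.mean(axis=0, keepdims=True)
    elif detrend is not None:
        raise ValueError("detrend must be 'linear', 'mean' or None")
    basis = np.exp(-2j * np.pi * f * t)
    proj = np.tensordot(basis, x, axes=(0, 0)) * (2.0 / t_frames)
    amplitude = np.abs(proj)
    # x ~ A cos(2*pi*f*t - phi) projects to A exp(-i*phi)
    phase = wrap_2pi(-np.angle(proj))
    return RetinoMaps(amplitude=amplitude, phase=phase)


def responsive_mask(
    contra: RetinoMaps,
    ipsi: RetinoMaps,
    rule: str = "contra-p99",
    frac: float = 0.30,
) -> np.ndarray:
    """Default responsive-pixel rule for OD analysis.

    ``contra-p99``: a pixel is responsive when its contra or ipsi
    amplitude exceeds ``frac`` of the 99th percentile of the contra
    amplitude map (scale-free and robust to hot pixels). ``either-p99``
    references the 99th percentile of the pixelwise max of both maps
    instead, making the rule symmetric under eye swap.
    """
    c, i = contra.amplitude, ipsi.amplitude
    if rule == "contra-p99":
        thr = frac * np.percentile(c, 99)
    elif rule == "either-p99":
        thr = frac * np.percentile(np.maximum(c, i), 99)
    else:
        raise ValueError(f"unknown responsive rule {rule!r}")
    return (c > thr) | (i > thr)


def od_analysis(
    contra: RetinoMaps,
    ipsi: RetinoMaps,
    rule: str = "contra-p99",
    frac: float = 0.30,
    mask: np.ndarray | None = None,
) -> ODMap:
    """Ocular-dominance score map and index.

    Per responsive pixel, od_score = (C - I)/(C + I) with C and I the
    raw response magnitudes to contra- and ipsilateral-eye stimulation;
    the ODI is the mean score over responsive pixels and ranges from -1
    (fully ipsilateral) to +1 (fully contralateral). Pixels with
    C + I = 0 are removed from the mask. An explicit boolean ``mask``
    overrides the built-in responsive rule.
    """
    c, i = contra.amplitude, ipsi.amplitude
    if c.shape != i.shape:
        raise ValueError("contra and ipsi maps must be co-registered (same shape)")
    if mask is None:
        mask = responsive_mask(contra, ipsi, rule=rule, frac=frac)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != c.shape:
            raise ValueError("mask shape mismatch")
    mask = mask & ((c + i) > 0)
    score = np.full(c.shape, np.nan)
    score[mask] = (c[mask] - i[mask]) / (c[mask] + i[mask])
    if not mask.any():
        raise ValueError("no responsive pixels")
    return ODMap(od_score=score, responsive_mask=mask, odi=float(score[mask].mean()))


def odi_blocks(
    run_odis, block_size: int = 4, min_blocks: int = 3
) -> BlockODIResult:
    """Block-averaged animal ODI with the exclusion rule.

    Consecutive runs are grouped into blocks of ``block_size`` (trailing
    remainder dropped and logged); one ODI per block is the mean of its
    run ODIs. Animals providing fewer than ``min_blocks`` block ODIs are
    excluded — an outcome, not an error. The animal value is the mean of
    its block ODIs.
    """
    runs = np.asarray(list(run_odis), dtype=float)
    n_blocks = runs.size // block_size
    dropped = runs.size - n_blocks * block_size
    if dropped:
        logger.info("odi_blocks: dropping %d trailing run(s)", dropped)
    blocks = runs[: n_blocks * block_size].reshape(n_blocks, block_size).mean(axis=1)
    if n_blocks < min_blocks:
        return BlockODIResult(
            block_odis=blocks,
            animal_odi=None,
            excluded=True,
            n_dropped_runs=dropped,
            reason=f"only {n_blocks} block ODIs (< {min_blocks})",
        )
    return BlockODIResult(
        block_odis=blocks,
        animal_odi=float(blocks.mean()),
        excluded=False,
        n_dropped_runs=dropped,
    )


def map_scatter(
    maps: RetinoMaps, mask: np.ndarray | None = None, neighborhood: int = 5
) -> float:
    """Local retinotopic scatter of a phase map (radians; lower = smoother).

    For every masked pixel, the circular mean direction of the
    surrounding ``neighborhood`` x ``neighborhood`` masked pixels
    (centre excluded) is computed, and the absolute circular difference
    between the pixel's phase and that local mean is averaged over the
    mask. A locally planar phase ramp scores near 0; i.i.d. uniform
    phases score near pi/2. This is a stated surrogate for the
    map-quality metric of the underlying imaging literature, which is
    not given in closed form.
    """
    from scipy.signal import convolve2d

    phase = maps.phase
    if neighborhood < 2:
        raise ValueError("neighborhood must be >= 2")
    if neighborhood > min(phase.shape):
        raise ValueError("neighborhood larger than the map")
    if mask is None:
        mask = np.ones(phase.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    z = np.exp(1j * phase) * mask
    kernel = np.ones((neighborhood, neighborhood))
    zsum = convolve2d(z, kernel, mode="same") - z
    count = convolve2d(mask.astype(float), kernel, mode="same") - mask
    valid = mask & (count > 0) & (np.abs(zsum) > 0)
    local_mean = np.angle(zsum[valid])
    return float(np.mean(circular_difference(phase[valid], local_mean)))
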