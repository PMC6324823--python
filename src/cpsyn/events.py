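"""Event-based synaptic analyses.

Covers quantal-event detection from continuous recordings (mEPSCs in TTX,
or Sr2+-desynchronized evoked quanta), the per-cell 400-event / 20-bin
cumulative-distribution machinery, paired-pulse ratio with tail
subtraction, and the use-dependent NMDA-receptor (MK-801) decay fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, signal

from ._util import boxcar_smooth
from .exceptions import UnreliableMeasurement

logger = logging.getLogger(__name__)

__all__ = [
    "Recording",
    "EventSeries",
    "BinnedCumulative",
    "PPRMeasure",
    "MK801Decay",
    "SrQuantalResult",
    "detect_events",
    "bin_cumulative",
    "rank_bin_means",
    "plot_cumulative",
    "ppr",
    "mk801_decay",
    "sr_quantal_analysis",
]

#: events per cell entering the cumulative-distribution analysis
EVENTS_PER_CELL = 400
#: number of rank bins
N_BINS = 20


@dataclass
class Recording:
    """Continuous single-channel current recording.

    ``polarity`` is the sign of a synaptic deflection in the raw signal:
    -1 for inward currents at negative holding potentials (the usual
    mEPSC convention), +1 for outward.
    """

    signal: np.ndarray
    sample_rate_hz: float
    polarity: int = -1
    cell_id: str = "cell"

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 1:
            raise ValueError("signal must be 1-D")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if self.polarity not in (-1, 1):
            raise ValueError("polarity must be -1 or +1")

    @property
    def duration_s(self) -> float:
        return self.signal.size / self.sample_rate_hz


@dataclass
class EventSeries:
    """Detected quantal events of one cell."""

    cell_id: str
    times_s: np.ndarray
    amplitudes_pA: np.ndarray
    duration_s: float

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.amplitudes_pA = np.asarray(self.amplitudes_pA, dtype=float)
        if self.times_s.shape != self.amplitudes_pA.shape:
            raise ValueError("times and amplitudes must align")
        if self.times_s.size and np.any(np.diff(self.times_s) <= 0):
            raise ValueError("event times must be strictly increasing")
        if np.any(self.amplitudes_pA <= 0):
            raise ValueError("amplitudes must be positive")

    def __len__(self) -> int:
        return self.times_s.size

    @property
    def iei_s(self) -> np.ndarray:
        return np.diff(self.times_s)


@dataclass
class BinnedCumulative:
    """Cross-cell average of per-cell rank-bin means."""

    bin_values: np.ndarray  # (N_BINS,) averaged across cells
    per_cell_bins: np.ndarray  # (n_cells, N_BINS)
    per_cell_means: pd.DataFrame  # cell_id, mean
    variable: str
    excluded: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_cells(self) -> int:
        return self.per_cell_bins.shape[0]


@dataclass
class PPRMeasure:
    interval_ms: float
    amp1_pA: float
    amp2_pA: float

    @property
    def ratio(self) -> float:
        return self.amp2_pA / self.amp1_pA


@dataclass
class MK801Decay:
    normalized: np.ndarray  # mean normalized peak per sweep
    survival: float  # fitted per-sweep survival fraction
    degenerate: bool  # True when no decrement was detectable


@dataclass
class SrQuantalResult:
    amplitudes_pA: np.ndarray
    mean_amplitude_pA: float
    iei_ms: np.ndarray
    mean_iei_ms: float
    bin_values: np.ndarray


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------


def detect_events(
    rec: Recording,
    threshold_sd: float = 3.5,
    refractory_ms: float = 5.0,
    detect_smooth_ms: float = 5.0,
    measure_smooth_ms: float = 1.0,
) -> EventSeries:
    """Threshold-crossing quantal event detection.

    The signal is flipped to positive-going deflections, median-baseline
    subtracted, and heavily smoothed for detection; the noise scale is
    estimated robustly (MAD) on the smoothed trace so sparse events do
    not inflate it. Peaks exceeding ``threshold_sd`` x noise and
    separated by at least ``refractory_ms`` are kept (closer candidates
    are merged onto the larger peak). Amplitudes are then read
    baseline-to-peak from a lightly smoothed copy at the local maximum
    around each detection, so heavy detection smoothing does not bias
    the measured quantal size.

    The detector is a documented surrogate for rig-side scoring; both
    the threshold and the smoothing windows are configurable. A flat
    recording yields an empty series.
    """
    fs = rec.sample_rate_hz
    refractory = max(1, int(round(refractory_ms * 1e-3 * fs)))
    if rec.signal.size <= refractory:
        raise ValueError("recording shorter than the refractory period")
    x = rec.polarity * rec.signal
    x = x - np.median(x)
    w_det = max(1, int(round(detect_smooth_ms * 1e-3 * fs)))
    w_meas = max(1, int(round(measure_smooth_ms * 1e-3 * fs)))
    x_det = boxcar_smooth(x, w_det)
    x_meas = boxcar_smooth(x, w_meas)
    noise = 1.4826 * np.median(np.abs(x_det - np.median(x_det)))
    # floor guards a noiseless recording against numerical ripple peaks
    height = max(threshold_sd * noise, 1e-9 * np.abs(x_det).max(initial=0.0))
    if height == 0.0:
        return EventSeries(rec.cell_id, np.array([]), np.array([]), rec.duration_s)
    # prominence on par with the height threshold rejects noise ripples
    # riding on the decay tail of a large event
    peaks, _ = signal.find_peaks(
        x_det, height=height, prominence=height, distance=refractory
    )
    if peaks.size == 0:
        return EventSeries(rec.cell_id, np.array([]), np.array([]), rec.duration_s)
    # refine peak position and amplitude on the lightly smoothed trace
    half = max(w_det // 2, 1)
    times = np.empty(peaks.size)
    amps = np.empty(peaks.size)
    for k, p in enumerate(peaks):
        lo, hi = max(0, p - half), min(x_meas.size, p + half + 1)
        j = lo + int(np.argmax(x_meas[lo:hi]))
        times[k] = j / fs
        amps[k] = x_meas[j]
    keep = amps > 0
    order = np.argsort(times[keep])
    times, amps = times[keep][order], amps[keep][order]
    # merging in find_peaks is index-based; enforce strict monotonicity
    uniq = np.concatenate(([True], np.diff(times) > 0))
    return EventSeries(rec.cell_id, times[uniq], amps[uniq], rec.duration_s)


# ---------------------------------------------------------------------------
# cumulative distributions
# ---------------------------------------------------------------------------


def rank_bin_means(values: np.ndarray, n_bins: int = N_BINS) -> np.ndarray:
    """Sort values and average them within ``n_bins`` rank (quantile) bins.

    With 400 values and 20 bins each bin holds exactly 20 events; other
    counts are split as evenly as possible. Output is non-decreasing by
    construction.
    """
    v = np.sort(np.asarray(values, dtype=float))
    if v.size < n_bins:
        raise ValueError(f"need at least {n_bins} values, got {v.size}")
    return np.array([chunk.mean() for chunk in np.array_split(v, n_bins)])


def bin_cumulative(
    cells: list[EventSeries],
    variable: str = "amplitude",
    n_events: int = EVENTS_PER_CELL,
    n_bins: int = N_BINS,
) -> BinnedCumulative:
    """The 400-event / 20-bin cumulative-distribution procedure.

    Per cell, exactly the first ``n_events`` events in recording order
    are used (cells with fewer are excluded and logged); the chosen
    variable (amplitude, or inter-event interval) is sorted and averaged
    in ``n_bins`` rank bins, and bin k is then averaged across cells.
    Per-cell overall means are returned for the inset-style bar
    summaries.
    """
    if variable not in ("amplitude", "iei"):
        raise ValueError("variable must be 'amplitude' or 'iei'")
    rows, bins, excluded = [], [], []
    for cell in cells:
        if len(cell) < n_events:
            reason = f"only {len(cell)} events (< {n_events})"
            excluded.append((cell.cell_id, reason))
            logger.info("bin_cumulative excluded %s: %s", cell.cell_id, reason)
            continue
        if variable == "amplitude":
            values = cell.amplitudes_pA[:n_events]
        else:
            values = np.diff(cell.times_s[:n_events]) * 1e3  # ms
        bins.append(rank_bin_means(values, n_bins))
        rows.append({"cell_id": cell.cell_id, "mean": float(np.mean(values))})
    if not bins:
        raise ValueError("no cell reached the event-count requirement")
    per_cell = np.vstack(bins)
    return BinnedCumulative(
        bin_values=per_cell.mean(axis=0),
        per_cell_bins=per_cell,
        per_cell_means=pd.DataFrame(rows),
        variable=variable,
        excluded=excluded,
    )


def plot_cumulative(binned: BinnedCumulative, ax=None):
    """Cumulative-probability plot of cross-cell bin averages.

    Bin k carries cumulative probability (k+1)/n_bins; per-cell curves
    are drawn faintly behind the average. Presentation only.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    n_bins = binned.bin_values.size
    cum = np.arange(1, n_bins + 1) / n_bins
    for row in binned.per_cell_bins:
        ax.plot(row, cum, color="0.8", lw=0.8)
    ax.plot(binned.bin_values, cum, color="k", lw=2.0)
    ax.set_xlabel(
        "amplitude (pA)" if binned.variable == "amplitude"
        else "inter-event interval (ms)"
    )
    ax.set_ylabel("cumulative probability")
    ax.set_ylim(0, 1.02)
    return ax


# ---------------------------------------------------------------------------
# paired-pulse ratio
# ---------------------------------------------------------------------------


def _double_exp_decay(t, a1, tau1, a2, tau2):
    return a1 * np.exp(-t / tau1) + a2 * np.exp(-t / tau2)


def ppr(
    trace: np.ndarray,
    sample_rate_hz: float,
    stim1_ms: float,
    interval_ms: float,
    response_window_ms: tuple[float, float] = (0.5, 20.0),
    polarity: int = -1,
    noise_floor_pA: float = 0.0,
) -> PPRMeasure:
    """Paired-pulse ratio with decay-tail subtraction.

    The first response amplitude is the peak after stimulus 1. Its decay
    between that peak and stimulus 2 is fitted with a double exponential
    and extrapolated under the second response; the second amplitude is
    the peak of the residual. The ratio amp2/amp1 is invariant to any
    uniform gain applied to the trace.
    """
    x = polarity * np.asarray(trace, dtype=float)
    fs = sample_rate_hz
    i_stim1 = int(round(stim1_ms * 1e-3 * fs))
    i_stim2 = int(round((stim1_ms + interval_ms) * 1e-3 * fs))
    w0, w1 = (int(round(w * 1e-3 * fs)) for w in response_window_ms)
    base = x[:i_stim1].mean() if i_stim1 > 0 else 0.0
    x = x - base

    seg1 = x[i_stim1 + w0 : min(i_stim1 + w1, i_stim2)]
    if seg1.size == 0:
        raise ValueError("first response window is empty")
    p1 = int(np.argmax(seg1)) + i_stim1 + w0
    amp1 = float(x[p1])
    if amp1 <= noise_floor_pA:
        raise UnreliableMeasurement(
            f"first-pulse amplitude {amp1:g} pA at or below noise floor"
        )

    # fit the tail between the first peak and the second stimulus
    tail = x[p1:i_stim2]
    t = np.arange(tail.size) / fs * 1e3  # ms
    if tail.size >= 8:
        guess_tau = max(interval_ms / 3.0, 1.0)
        try:
            popt, _ = optimize.curve_fit(
                _double_exp_decay,
                t,
                tail,
                p0=(amp1, guess_tau, 0.0, guess_tau / 5.0),
                bounds=(
                    [-5 * abs(amp1), 1e-3, -5 * abs(amp1), 1e-3],
                    [5 * abs(amp1), 50 * interval_ms, 5 * abs(amp1), 50 * interval_ms],
                ),
                maxfev=20000,
            )
        except RuntimeError:
            logger.warning("ppr: tail fit failed, extrapolating a single exponential")
            k = np.polyfit(t, np.log(np.clip(tail, 1e-12 * amp1, None)), 1)
            popt = (np.exp(k[1]), -1.0 / min(k[0], -1e-9), 0.0, 1.0)
    else:
        popt = (0.0, 1.0, 0.0, 1.0)

    t2 = (np.arange(i_stim2 + w0, i_stim2 + w1) - p1) / fs * 1e3
    extrap = _double_exp_decay(t2, *popt)
    resid = x[i_stim2 + w0 : i_stim2 + w1] - extrap
    if resid.size == 0:
        raise ValueError("second response window is empty")
    amp2 = float(np.max(resid))
    return PPRMeasure(interval_ms=interval_ms, amp1_pA=amp1, amp2_pA=amp2)


# ---------------------------------------------------------------------------
# MK-801 decay
# ---------------------------------------------------------------------------


def mk801_decay(peaks: np.ndarray, degenerate_survival: float = 0.995) -> MK801Decay:
    """Use-dependent NMDA-receptor block: fit the per-sweep survival.

    ``peaks`` is a 1-D per-sweep NMDA-EPSC peak series or a 2-D
    (cells x sweeps) array. Each series is normalised to its first
    sweep; series are averaged and the geometric decay
    ``a * r**(sweep-1)`` is fitted by least squares. The free amplitude
    ``a`` absorbs the small upward bias that dividing by a stochastic
    first sweep introduces, so the decay rate is not distorted by it.
    Because MK-801 blocks an NMDA receptor the first time it opens
    after release, ``r`` estimates the per-sweep probability that a
    synapse has not yet released, i.e. ``1 - p``. A flat series (fitted
    survival above ``degenerate_survival``) is flagged as degenerate
    rather than interpreted.
    """
    arr = np.atleast_2d(np.asarray(peaks, dtype=float))
    if arr.shape[1] < 10:
        raise ValueError("need at least 10 sweeps")
    first = arr[:, 0]
    if np.any(first <= 0):
        raise ValueError("first-sweep peak must be positive in every series")
    norm = (arr.T / first).T.mean(axis=0)
    k = np.arange(norm.size)

    def sse(r: float) -> float:
        basis = r**k
        a = float(basis @ norm) / float(basis @ basis)  # optimal amplitude
        return float(np.sum((norm - a * basis) ** 2))

    res = optimize.minimize_scalar(sse, bounds=(1e-6, 1.0), method="bounded")
    r = float(res.x)
    return MK801Decay(normalized=norm, survival=r, degenerate=r > degenerate_survival)


# ---------------------------------------------------------------------------
# Sr2+ quantal analysis
# ---------------------------------------------------------------------------


def sr_quantal_analysis(
    events: pd.DataFrame, window_ms: float, n_bins: int = N_BINS
) -> SrQuantalResult:
    """Quantal-size analysis of Sr2+-desynchronized evoked events.

    ``events`` needs columns ``stimulus``, ``time_ms`` (latency within
    the post-stimulus window) and ``amplitude_pA``. Events outside the
    asynchronous window are discarded; amplitudes are summarised with
    the same rank-binning machinery as spontaneous mEPSCs, and
    inter-event intervals are computed within each stimulus window and
    pooled.
    """
    if window_ms <= 0:
        raise ValueError("window_ms must be positive")
    sel = events[events["time_ms"] <= window_ms]
    if len(sel) == 0:
        raise ValueError("no events inside the asynchronous window")
    amps = sel["amplitude_pA"].to_numpy(float)
    ieis = []
    for _, grp in sel.groupby("stimulus"):
        t = np.sort(grp["time_ms"].to_numpy(float))
        if t.size > 1:
            ieis.append(np.diff(t))
    iei = np.concatenate(ieis) if ieis else np.array([])
    bins = (
        rank_bin_means(amps, n_bins)
        if amps.size >= n_bins
        else np.sort(amps)
    )
    return SrQuantalResult(
        amplitudes_pA=amps,
        mean_amplitude_pA=float(amps.mean()),
        iei_ms=iei,
        mean_iei_ms=float(iei.mean()) if iei.size else float("nan"),
        bin_values=bins,
    )
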