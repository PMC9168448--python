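"""Narrowband phase-synchrony metrics on epoched source data.

Implements the 39-41 Hz analysis chain: zero-phase FIR band-pass plus
analytic-signal phase, inter-trial phase consistency (ITPC), seed-based
phase-locking value (PLV) and corrected imaginary PLV (ciPLV), baseline
z-scoring against the -500 to -200 ms pre-stimulus window, and averaging
over the 300-700 ms steady-state window — yielding one cortical map per
recording.

Conventions fixed here: metrics are computed across trials at each time
sample; the z-score uses the sample standard deviation (ddof=1); the
seed average is over the moduli of the per-seed-vertex metrics with the
self-pair (seed vertex with itself) excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import filtfilt, firwin, hilbert

from .synthetic_data import TriMesh, TrialSet

__all__ = [
    "BandSpec",
    "AnalysisWindows",
    "SyncMap",
    "narrowband_phase",
    "itpc",
    "plv_pair",
    "ciplv_pair",
    "seed_connectivity_map",
    "baseline_zscore",
    "steady_state_average",
    "itpc_map",
    "seed_sync_map",
]


@dataclass(frozen=True)
class BandSpec:
    """Narrowband FIR filter specification.

    ``n_taps=None`` picks an odd length of about 0.4 s of samples — long
    enough for a steep 39-41 Hz band, short enough that the (zero-phase)
    transient around the stimulus onset discontinuity stays out of the
    baseline and steady-state windows of a 3 s epoch.
    """

    low_hz: float = 39.0
    high_hz: float = 41.0
    n_taps: int | None = None
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.low_hz < self.high_hz):
            raise ValueError("need 0 < low_hz < high_hz")

    def taps_for(self, fs: float) -> int:
        if self.high_hz >= fs / 2:
            raise ValueError(f"band edge {self.high_hz} Hz >= Nyquist {fs / 2} Hz")
        n = self.n_taps if self.n_taps is not None else int(round(0.4 * fs)) | 1
        return n | 1  # force odd (type I linear phase)


@dataclass(frozen=True)
class AnalysisWindows:
    """Baseline (z-score reference) and steady-state averaging windows, s."""

    baseline_s: tuple[float, float] = (-0.5, -0.2)
    steady_s: tuple[float, float] = (0.3, 0.7)

    def __post_init__(self) -> None:
        b0, b1 = self.baseline_s
        s0, s1 = self.steady_s
        if not (b0 < b1 and s0 < s1):
            raise ValueError("windows must be non-empty intervals")
        if b1 > s0:
            raise ValueError("baseline and steady-state windows must be disjoint")

    def baseline_mask(self, times: np.ndarray) -> np.ndarray:
        return (times >= self.baseline_s[0]) & (times <= self.baseline_s[1])

    def steady_mask(self, times: np.ndarray) -> np.ndarray:
        return (times >= self.steady_s[0]) & (times <= self.steady_s[1])


@dataclass
class SyncMap:
    """Per-vertex scalar synchrony map tied to a mesh.

    ``kind`` is "raw" (metric in [0, 1]) or "zscore" (unbounded).
    """

    values: np.ndarray
    metric: str                      # "ITPC" | "PLV" | "ciPLV"
    kind: str = "zscore"
    window_s: tuple[float, float] = (0.3, 0.7)
    seed_roi: str | None = None
    mesh: TriMesh | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.metric not in ("ITPC", "PLV", "ciPLV"):
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.kind not in ("raw", "zscore"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.kind == "raw" and self.values.size and (
                self.values.min() < -1e-9 or self.values.max() > 1 + 1e-9):
            raise ValueError("raw synchrony values must lie in [0, 1]")
        if self.mesh is not None and self.values.shape != (self.mesh.n_vertices,):
            raise ValueError("map length does not match mesh vertex count")


# --------------------------------------------------------------------------
# phase extraction
# --------------------------------------------------------------------------

def narrowband_phase(trialset: TrialSet, band: BandSpec = BandSpec()) -> np.ndarray:
    """Instantaneous narrowband phase per trial/vertex/sample, in (-pi, pi].

    Zero-phase (forward-backward) Hamming-window FIR band-pass followed by
    the analytic-signal (Hilbert) phase.
    """
    fs = trialset.sample_rate_hz
    n_taps = band.taps_for(fs)
    n_samples = trialset.data.shape[-1]
    if n_taps >= n_samples:
        raise ValueError(
            f"filter length {n_taps} exceeds epoch length {n_samples} samples")
    b = firwin(n_taps, [band.low_hz, band.high_hz], pass_zero=False,
               fs=fs, window="hamming")
    if band.zero_phase:
        padlen = min(3 * n_taps, n_samples - 1)
        filtered = filtfilt(b, [1.0], trialset.data, axis=-1, padlen=padlen)
    else:
        filtered = np.apply_along_axis(np.convolve, -1, trialset.data, b, mode="same")
    return np.angle(hilbert(filtered, axis=-1))


# --------------------------------------------------------------------------
# trial-wise phase metrics
# --------------------------------------------------------------------------

def itpc(phases: np.ndarray) -> np.ndarray:
    """Inter-trial phase consistency: mean resultant length across trials.

    ``phases`` has trials on the first axis; the result drops that axis.
    ITPC = | (1/N) sum_n exp(i phi_n) |, in [0, 1].
    """
    phases = np.asarray(phases)
    if phases.shape[0] < 2:
        raise ValueError("ITPC needs at least 2 trials")
    return np.abs(np.mean(np.exp(1j * phases), axis=0))


def _complex_plv(phases1: np.ndarray, phases2: np.ndarray) -> np.ndarray:
    phases1, phases2 = np.asarray(phases1), np.asarray(phases2)
    if phases1.shape[0] != phases2.shape[0]:
        raise ValueError("phase arrays must have matching trial counts")
    try:
        dphi = phases1 - phases2  # remaining axes broadcast (e.g. 1 vs V)
    except ValueError as exc:
        raise ValueError(f"phase arrays not broadcastable: "
                         f"{phases1.shape} vs {phases2.shape}") from exc
    return np.mean(np.exp(1j * dphi), axis=0)


def plv_pair(phases1: np.ndarray, phases2: np.ndarray) -> np.ndarray:
    """Phase-locking value between two signals: |mean exp(i*dphi)|."""
    return np.abs(_complex_plv(phases1, phases2))


def ciplv_pair(phases1: np.ndarray, phases2: np.ndarray) -> np.ndarray:
    """Corrected imaginary PLV: |Im C| / sqrt(1 - Re(C)^2).

    Insensitive to zero-lag coupling (volume conduction / leakage).  At
    pure zero lag Re C = +/-1 and the statistic is defined as 0 (warned).
    """
    c = _complex_plv(phases1, phases2)
    re2 = np.minimum(c.real ** 2, 1.0)
    denom = np.sqrt(1.0 - re2)
    degenerate = denom < 1e-12
    if np.any(degenerate):
        warnings.warn("ciPLV undefined at pure zero lag (|Re C| = 1); set to 0")
    out = np.zeros_like(denom)
    ok = ~degenerate
    out[ok] = np.abs(c.imag[ok]) / denom[ok]
    return np.minimum(out, 1.0)


_PAIR_METRICS = {"PLV": plv_pair, "ciPLV": ciplv_pair}


def seed_connectivity_map(trialset: TrialSet, band: BandSpec, seed_roi: str,
                          metric: str = "PLV", *,
                          phases: np.ndarray | None = None,
                          average: str = "modulus") -> np.ndarray:
    """Time-resolved seed-to-cortex connectivity map, (V, T).

    For every cortical vertex w, the metric between each seed vertex s and
    w is computed across trials per time sample and then averaged over the
    seed vertices (``average="modulus"``, the default, averages the metric
    values; ``"complex"`` averages the complex mean vectors first and takes
    the metric of the average).  The self-pair s = w is excluded from the
    average so seed vertices are not inflated by their identically-1 PLV.
    """
    if metric not in _PAIR_METRICS:
        raise ValueError(f"metric must be one of {sorted(_PAIR_METRICS)}")
    if trialset.mesh is None:
        raise ValueError("trialset has no mesh reference")
    seed = trialset.mesh.roi_labels.get(seed_roi)
    if seed is None or seed.size == 0:
        raise ValueError(f"seed ROI {seed_roi!r} missing or empty on mesh")
    if phases is None:
        phases = narrowband_phase(trialset, band)

    n_v, n_t = phases.shape[1], phases.shape[2]
    acc = np.zeros((n_v, n_t))
    count = np.full((n_v, 1), float(seed.size))
    if average == "complex":
        acc_c = np.zeros((n_v, n_t), dtype=np.complex128)
    for s in seed:
        c = _complex_plv(phases[:, [s], :], phases)  # (V, T)
        if average == "complex":
            acc_c += c
            acc_c[s] -= c[s]
        else:
            if metric == "PLV":
                val = np.abs(c)
            else:
                re2 = np.minimum(c.real ** 2, 1.0)
                denom = np.sqrt(1.0 - re2)
                val = np.where(denom < 1e-12, 0.0,
                               np.abs(c.imag) / np.maximum(denom, 1e-12))
            acc += val
            acc[s] -= val[s]  # drop the self-pair (PLV(s,s) = 1)
        count[s, 0] = seed.size - 1
    count[count == 0] = 1.0  # single-vertex seed: its own row is undefined -> 0
    if average == "complex":
        c_bar = acc_c / count
        if metric == "PLV":
            return np.abs(c_bar)
        re2 = np.minimum(c_bar.real ** 2, 1.0)
        denom = np.sqrt(1.0 - re2)
        return np.where(denom < 1e-12, 0.0, np.abs(c_bar.imag) / np.maximum(denom, 1e-12))
    return acc / count


# --------------------------------------------------------------------------
# z-scoring & time averaging
# --------------------------------------------------------------------------

def baseline_zscore(metric_ts: np.ndarray, times: np.ndarray,
                    windows: AnalysisWindows = AnalysisWindows()) -> np.ndarray:
    """z-score a time-resolved metric against its pre-stimulus baseline.

    z(v, t) = (M(v, t) - mean_b(v)) / sd_b(v), with mean/sd taken over the
    baseline time samples (sample sd, ddof=1).  Vertices with zero baseline
    variance get z = 0 with a warning rather than an error, so a constant
    vertex cannot abort a cohort run.
    """
    metric_ts = np.asarray(metric_ts, dtype=np.float64)
    mask = windows.baseline_mask(np.asarray(times))
    if mask.sum() < 2:
        raise ValueError("baseline window contains fewer than 2 samples")
    base = metric_ts[..., mask]
    mu = base.mean(axis=-1, keepdims=True)
    sd = base.std(axis=-1, ddof=1, keepdims=True)
    degenerate = sd[..., 0] == 0
    if np.any(degenerate):
        warnings.warn(
            f"{int(np.sum(degenerate))} vertex/vertices with zero baseline "
            "variance; z set to 0 there")
    sd = np.where(sd == 0, 1.0, sd)
    z = (metric_ts - mu) / sd
    z[degenerate, :] = 0.0
    return z


def steady_state_average(z_ts: np.ndarray, times: np.ndarray,
                         windows: AnalysisWindows = AnalysisWindows()) -> np.ndarray:
    """Mean over the steady-state window samples -> one scalar per vertex."""
    mask = windows.steady_mask(np.asarray(times))
    if not mask.any():
        raise ValueError("steady-state window contains no samples")
    return np.asarray(z_ts, dtype=np.float64)[..., mask].mean(axis=-1)


# --------------------------------------------------------------------------
# per-recording map pipelines
# --------------------------------------------------------------------------

def itpc_map(trialset: TrialSet, band: BandSpec = BandSpec(),
             windows: AnalysisWindows = AnalysisWindows(), *,
             zscored: bool = True, window: str = "steady") -> SyncMap:
    """Full ITPC chain for one recording: phase -> ITPC -> (z) -> average.

    ``window="steady"`` averages over the steady-state window;
    ``"baseline"`` averages the raw metric over the Silence window (the
    resting control maps).
    """
    phases = narrowband_phase(trialset, band)
    m = itpc(phases)
    return _finalize_map(m, trialset.times, windows, "ITPC", None,
                         trialset.mesh, zscored, window)


def seed_sync_map(trialset: TrialSet, band: BandSpec, seed_roi: str,
                  metric: str = "PLV",
                  windows: AnalysisWindows = AnalysisWindows(), *,
                  zscored: bool = True, window: str = "steady",
                  phases: np.ndarray | None = None) -> SyncMap:
    """Seed-based PLV/ciPLV chain, z-scored and averaged like ITPC."""
    m = seed_connectivity_map(trialset, band, seed_roi, metric, phases=phases)
    return _finalize_map(m, trialset.times, windows, metric, seed_roi,
                         trialset.mesh, zscored, window)


def _finalize_map(metric_ts, times, windows, metric, seed_roi, mesh,
                  zscored, window) -> SyncMap:
    if window == "steady":
        win, mask = windows.steady_s, None
    elif window == "baseline":
        win = windows.baseline_s
        mask = windows.baseline_mask(times)
    else:
        raise ValueError("window must be 'steady' or 'baseline'")
    if zscored:
        ts = baseline_zscore(metric_ts, times, windows)
        kind = "zscore"
    else:
        ts, kind = metric_ts, "raw"
    if window == "steady":
        values = steady_state_average(ts, times, windows)
    else:
        values = ts[..., mask].mean(axis=-1)
    return SyncMap(values, metric, kind=kind, window_s=win,
                   seed_roi=seed_roi, mesh=mesh)
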