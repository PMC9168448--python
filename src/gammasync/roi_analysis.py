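"""ROI-level statistics: inter-A1 connectivity contrast and thalamic
volume-synchrony correlations.

The inter-hemispheric auditory connectivity analysis computes PLV/ciPLV
between every (left-A1, right-A1) vertex pair, averages over pairs, and
contrasts the raw steady-state (stimulus) value against the raw baseline
(Silence) value across recordings with a Wilcoxon signed-rank test.  The
thalamic analysis correlates TIV-normalized nucleus volumes with a
subject-level synchrony summary, with family-wise correction by a
max-|rho| permutation across nuclei.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .surface_stats import spearman_rho_rows, _rho_to_t
from .sync_metrics import AnalysisWindows, BandSpec, _PAIR_METRICS, \
    _complex_plv, narrowband_phase
from .synthetic_data import TrialSet

__all__ = [
    "PairedSamples",
    "WilcoxonResult",
    "a1_to_a1_connectivity",
    "paired_signed_rank_test",
    "thalamic_correlation",
    "normalize_thalamic_table",
]


@dataclass
class PairedSamples:
    """Per-recording paired condition values (A = stimulus, B = Silence)."""

    condition_a: np.ndarray
    condition_b: np.ndarray
    metric: str = ""

    def __post_init__(self) -> None:
        self.condition_a = np.asarray(self.condition_a, dtype=np.float64)
        self.condition_b = np.asarray(self.condition_b, dtype=np.float64)
        if self.condition_a.shape != self.condition_b.shape:
            raise ValueError("paired samples must have equal length")
        if self.condition_a.ndim != 1:
            raise ValueError("paired samples must be 1-D")

    @property
    def n(self) -> int:
        return self.condition_a.size

    @property
    def differences(self) -> np.ndarray:
        return self.condition_a - self.condition_b


@dataclass
class WilcoxonResult:
    z: float
    p: float                 # normal-approximation two-sided p
    w_plus: float            # sum of ranks of positive differences
    n_effective: int         # pairs after dropping zero differences
    p_exact: float | None    # exact two-sided p (n_effective <= exact cutoff)
    p_exact_one_sided: float | None


def a1_to_a1_connectivity(trialset: TrialSet, band: BandSpec = BandSpec(),
                          metric: str = "PLV",
                          windows: AnalysisWindows = AnalysisWindows(),
                          ) -> tuple[float, float]:
    """Raw inter-A1 connectivity during stimulation and Silence.

    The metric is computed across trials per time sample for every
    (left-A1 vertex, right-A1 vertex) pair, averaged over pairs
    (modulus-then-average), then time-averaged over the steady-state
    window (stimulus value) and the baseline window (Silence value).
    Returns ``(stim, silence)``.
    """
    if metric not in _PAIR_METRICS:
        raise ValueError(f"metric must be one of {sorted(_PAIR_METRICS)}")
    mesh = trialset.mesh
    if mesh is None:
        raise ValueError("trialset has no mesh reference")
    left = mesh.roi_labels.get("A1-left")
    right = mesh.roi_labels.get("A1-right")
    if left is None or right is None or left.size == 0 or right.size == 0:
        raise ValueError("mesh must label both 'A1-left' and 'A1-right'")

    phases = narrowband_phase(trialset, band)
    pair_metric = _PAIR_METRICS[metric]
    acc = 0.0
    for s in left:
        acc = acc + pair_metric(phases[:, [s], :], phases[:, right, :])
    mean_ts = (acc / left.size).mean(axis=0)  # (T,)

    times = trialset.times
    stim = float(mean_ts[windows.steady_mask(times)].mean())
    silence = float(mean_ts[windows.baseline_mask(times)].mean())
    return stim, silence


# --------------------------------------------------------------------------
# Wilcoxon signed-rank
# --------------------------------------------------------------------------

def _signed_ranks(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Drop zeros, average-rank |d|; return (ranks, signs)."""
    d = d[d != 0]
    from scipy.stats import rankdata
    r = rankdata(np.abs(d), method="average")
    return r, np.sign(d)


def _exact_wplus_tail(ranks: np.ndarray, w_obs: float) -> tuple[float, float]:
    """Exact P(W+ >= w_obs) and P(W+ <= w_obs) under random sign flips.

    Dynamic programming over the distribution of W+ with ranks doubled to
    integers (average ranks with ties are multiples of 1/2), so ties are
    handled exactly.
    """
    r2 = np.round(2.0 * ranks).astype(np.int64)
    total = int(r2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = 0.5 * (dist + shifted)
    w2 = 2.0 * w_obs
    support = np.arange(total + 1)
    # half-ulp slack so float w_obs hits its exact lattice point
    p_ge = float(dist[support >= w2 - 1e-9].sum())
    p_le = float(dist[support <= w2 + 1e-9].sum())
    return p_ge, p_le


def paired_signed_rank_test(samples: PairedSamples, *,
                            exact_cutoff: int = 20) -> WilcoxonResult:
    """Wilcoxon signed-rank test on paired recordings.

    Zero differences are dropped; tied |d| get average ranks.  Z uses the
    normal approximation with tie-corrected variance and is signed toward
    condition A (positive Z means A > B).  For n_effective <=
    ``exact_cutoff`` the exact sign-flip p-values are also computed (DP
    over the signed-rank distribution, exact with ties).
    """
    if samples.n < 5:
        raise ValueError("need at least 5 pairs")
    d = samples.differences
    if np.all(d == 0):
        raise ValueError("all paired differences are zero")
    ranks, signs = _signed_ranks(d)
    n = ranks.size
    w_plus = float(ranks[signs > 0].sum())

    mu = n * (n + 1) / 4.0
    # tie correction: subtract sum(t^3 - t)/48 over tied groups of |d|
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(counts.astype(np.float64) ** 3 - counts)) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    from scipy.stats import norm
    z = (w_plus - mu) / np.sqrt(var)
    p = 2.0 * norm.sf(abs(z))

    p_exact = p_exact_one = None
    if n <= exact_cutoff:
        p_ge, p_le = _exact_wplus_tail(ranks, w_plus)
        p_exact_one = p_ge
        p_exact = min(1.0, 2.0 * min(p_ge, p_le))
    return WilcoxonResult(float(z), float(p), w_plus, n, p_exact, p_exact_one)


# --------------------------------------------------------------------------
# thalamic volumes
# --------------------------------------------------------------------------

def normalize_thalamic_table(table: pd.DataFrame) -> pd.DataFrame:
    """Add TIV-normalized volumes to a long-format thalamic table.

    Expects columns ``subject, nucleus, volume_mm3, tiv_mm3``; adds
    ``volume_norm = volume_mm3 / tiv_mm3``.
    """
    required = {"subject", "nucleus", "volume_mm3", "tiv_mm3"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"thalamic table missing columns: {sorted(missing)}")
    if (table["volume_mm3"] <= 0).any() or (table["tiv_mm3"] <= 0).any():
        raise ValueError("volumes and TIV must be positive")
    out = table.copy()
    out["volume_norm"] = out["volume_mm3"] / out["tiv_mm3"]
    if (out["volume_norm"] >= 1).any():
        raise ValueError("normalized volume >= 1; check units")
    return out


def thalamic_correlation(table: pd.DataFrame, sync_summary: dict[str, float] |
                         pd.Series, *, n_perm: int = 5000,
                         rng_seed: int = 0) -> pd.DataFrame:
    """Per-nucleus Spearman correlation between TIV-normalized volume and
    a subject-level synchrony summary, max-|rho| permutation corrected.

    ``sync_summary`` maps subject id to a scalar (e.g. whole-cortex mean
    steady-state ITPC z).  The family-wise correction shuffles subject
    labels of the summary and refers each nucleus's |rho| to the null of
    the maximum |rho| across nuclei (5000 shuffles by default).  Returns
    a DataFrame with columns ``nucleus, rho, t, p_uncorrected, p_maxstat``.
    """
    table = normalize_thalamic_table(table)
    sync = pd.Series(sync_summary, dtype=float)
    wide = table.pivot_table(index="subject", columns="nucleus",
                             values="volume_norm")
    common = wide.index.intersection(sync.index)
    if len(common) < 8:
        raise ValueError(f"need >= 8 subjects with both volumes and synchrony, "
                         f"got {len(common)}")
    wide = wide.loc[common]
    if wide.isna().any().any():
        raise ValueError("missing nucleus volumes for some subjects")
    if (wide.nunique() <= 1).any():
        raise ValueError("constant nucleus volumes across subjects")
    y = sync.loc[common].to_numpy()
    x = wide.to_numpy().T  # (n_nuclei, n_subjects)
    n = y.size

    y_rows = np.broadcast_to(y, x.shape)
    rho, _ = spearman_rho_rows(x, y_rows)
    t = _rho_to_t(rho, n)
    from scipy.stats import t as t_dist
    p_unc = 2.0 * t_dist.sf(np.abs(t), n - 2)

    rng = np.random.default_rng(rng_seed)
    null_max = np.empty(n_perm)
    for p in range(n_perm):
        yp = np.broadcast_to(y[rng.permutation(n)], x.shape)
        rho_p, _ = spearman_rho_rows(x, yp)
        null_max[p] = np.abs(rho_p).max()
    p_max = (1.0 + (null_max[:, None] >= np.abs(rho)[None, :]).sum(axis=0)) \
        / (1.0 + n_perm)

    return pd.DataFrame({
        "nucleus": wide.columns,
        "rho": rho,
        "t": t,
        "p_uncorrected": p_unc,
        "p_maxstat": p_max,
    }).sort_values("p_maxstat", ignore_index=True)
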