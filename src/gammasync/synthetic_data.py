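"""Synthetic source-space cohorts with known ground truth.

This module generates everything the downstream pipeline consumes —
triangulated two-hemisphere cortical meshes, spatially smooth cortical
thickness maps, and epoched per-trial source time series with 40 Hz
phase locking — together with a sidecar ground-truth record (per-vertex
von Mises concentration, planted effect ROI and slope, inter-regional
coupling lag) so every stage has a parameter-recovery test.

The signal model is deliberately minimal: trial-wise phase locking is
modeled at the level of the 40 Hz onset phase, drawn from a von Mises
distribution with vertex-specific concentration kappa.  The synchrony
metrics downstream only ever see phase distributions, so a biophysical
oscillator model would add nothing they could detect.  During the
baseline (Silence) the 40 Hz phase is uniform; during the stimulus the
phase concentrates around zero with strength kappa, and kappa increases
with cortical thickness inside the planted effect ROI.  Coupled target
vertices replay the seed's trial phase shifted by a fixed lag, which
gives the seed-based connectivity metrics a known positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
from scipy.spatial import ConvexHull
from scipy.sparse.csgraph import connected_components, dijkstra

__all__ = [
    "TriMesh",
    "CohortSpec",
    "TrialSet",
    "SubjectRecord",
    "Cohort",
    "GroundTruth",
    "make_mesh",
    "sample_thickness",
    "simulate_trialset",
    "simulate_cohort",
    "calibrate_effect_slope",
    "THALAMIC_NUCLEI_MM3",
]

# Nominal thalamic nucleus volumes (mm^3), one set per side, loosely
# anthropometric; used as lognormal medians by the cohort generator.
THALAMIC_NUCLEI_MM3: dict[str, float] = {
    "anteroventral": 120.0,
    "mediodorsal": 700.0,
    "pulvinar": 1200.0,
    "ventral-posterolateral": 350.0,
    "ventral-lateral": 600.0,
    "lateral-geniculate": 115.0,
    "medial-geniculate": 65.0,
}


# --------------------------------------------------------------------------
# mesh
# --------------------------------------------------------------------------

@dataclass
class TriMesh:
    """Triangulated two-hemisphere cortical surface.

    Attributes
    ----------
    coords : (V, 3) float array, mm
    faces : (F, 3) int array of vertex index triples
    hemisphere : (V,) int8 array, 0 = left, 1 = right
    roi_labels : dict mapping ROI name to sorted vertex-index array;
        must contain ``"A1-left"`` and ``"A1-right"``.
    """

    coords: np.ndarray
    faces: np.ndarray
    hemisphere: np.ndarray
    roi_labels: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int32)
        self.hemisphere = np.asarray(self.hemisphere, dtype=np.int8)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (V, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (F, 3)")
        v = self.n_vertices
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= v):
            raise ValueError("face indices out of range")
        if self.hemisphere.shape != (v,):
            raise ValueError("hemisphere labels must be per-vertex")
        # no face may straddle hemispheres
        h = self.hemisphere[self.faces]
        if np.any(h.min(axis=1) != h.max(axis=1)):
            raise ValueError("a triangle spans both hemispheres")
        self.roi_labels = {
            k: np.asarray(idx, dtype=np.intp) for k, idx in self.roi_labels.items()
        }
        self._adjacency: sp.csr_matrix | None = None

    @property
    def n_vertices(self) -> int:
        return self.coords.shape[0]

    @property
    def n_faces(self) -> int:
        return self.faces.shape[0]

    def adjacency(self) -> sp.csr_matrix:
        """Symmetric vertex adjacency (shared triangle edges), cached."""
        if self._adjacency is None:
            i = np.concatenate([self.faces[:, 0], self.faces[:, 1], self.faces[:, 2]])
            j = np.concatenate([self.faces[:, 1], self.faces[:, 2], self.faces[:, 0]])
            v = self.n_vertices
            a = sp.coo_matrix((np.ones_like(i, dtype=np.int8), (i, j)), shape=(v, v))
            a = ((a + a.T) > 0).tocsr()
            a.setdiag(0)
            a.eliminate_zeros()
            self._adjacency = a.astype(np.int8)
        return self._adjacency

    def edge_lengths(self) -> np.ndarray:
        """Lengths (mm) of the unique mesh edges."""
        a = sp.triu(self.adjacency(), k=1).tocoo()
        return np.linalg.norm(self.coords[a.row] - self.coords[a.col], axis=1)

    def weighted_graph(self) -> sp.csr_matrix:
        """Adjacency weighted by Euclidean edge length, for geodesics."""
        a = self.adjacency().tocoo()
        w = np.linalg.norm(self.coords[a.row] - self.coords[a.col], axis=1)
        return sp.csr_matrix((w, (a.row, a.col)), shape=a.shape)

    def geodesic_distances(self, sources: np.ndarray) -> np.ndarray:
        """Graph-geodesic distance (mm) from ``sources`` to every vertex."""
        d = dijkstra(self.weighted_graph(), directed=False, indices=np.asarray(sources))
        return d if d.ndim == 1 else d.min(axis=0)

    def validate(self) -> None:
        """Check hemisphere edge-connectivity (O(V+E), not run in __init__)."""
        adj = self.adjacency()
        for side in (0, 1):
            mask = self.hemisphere == side
            if not mask.any():
                continue
            sub = adj[mask][:, mask]
            n_comp, _ = connected_components(sub, directed=False)
            if n_comp != 1:
                raise ValueError(f"hemisphere {side} is not edge-connected")


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n points quasi-uniform on the unit sphere (golden-spiral lattice)."""
    k = np.arange(n, dtype=np.float64)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * k
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _orient_outward(points: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Flip triangles so all normals point away from the centroid."""
    c = points.mean(axis=0)
    p = points[faces]
    n = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    flip = np.einsum("ij,ij->i", n, p.mean(axis=1) - c) < 0
    faces = faces.copy()
    faces[flip] = faces[flip][:, [0, 2, 1]]
    return faces


def _sphere_hemi(n: int, rng: np.random.Generator, radius: float, jitter: float):
    """Closed, jittered sphere with exactly n vertices via convex hull."""
    pts = _fibonacci_sphere(n)
    hull = ConvexHull(pts)
    if len(np.unique(hull.simplices)) != n:  # pragma: no cover - hull always tight
        raise RuntimeError("hull triangulation dropped vertices")
    faces = _orient_outward(pts, hull.simplices.astype(np.int32))
    # radial + tangential jitter applied after triangulation keeps topology
    radial = 1.0 + jitter * rng.standard_normal(n)
    coords = pts * radial[:, None] * radius
    coords += jitter * radius * 0.3 * rng.standard_normal((n, 3))
    return coords, faces


def _grow_patch(adj: sp.csr_matrix, seed_vertex: int, size: int,
                allowed: np.ndarray) -> np.ndarray:
    """Breadth-first contiguous patch of ``size`` vertices from a seed."""
    indptr, indices = adj.indptr, adj.indices
    picked: list[int] = [seed_vertex]
    in_patch = {seed_vertex}
    frontier = [seed_vertex]
    allowed_set = set(int(a) for a in allowed)
    while len(picked) < size and frontier:
        nxt: list[int] = []
        for u in frontier:
            for w in indices[indptr[u]:indptr[u + 1]]:
                w = int(w)
                if w not in in_patch and w in allowed_set:
                    in_patch.add(w)
                    picked.append(w)
                    nxt.append(w)
                    if len(picked) >= size:
                        break
            if len(picked) >= size:
                break
        frontier = nxt
    return np.array(sorted(picked), dtype=np.intp)


def make_mesh(n_vertices_per_hemi: int, rng_seed: int = 0, *,
              radius_mm: float = 50.0, jitter: float = 0.02) -> TriMesh:
    """Build a two-hemisphere closed test surface with labeled ROIs.

    Each hemisphere is a jittered icosphere-like triangulation with exactly
    ``n_vertices_per_hemi`` vertices (golden-spiral points + convex hull),
    shifted apart along x.  Contiguous geodesic patches are labeled:
    ``A1-left`` / ``A1-right`` placed laterally (the vertex most distant
    from the midline), plus ``effect-ROI-1`` (superior left hemisphere) and
    ``coupled-ROI-1`` (superior right hemisphere) for planting effects.
    """
    if n_vertices_per_hemi < 12:
        raise ValueError("need at least 12 vertices per hemisphere")
    rng = np.random.default_rng(rng_seed)
    n = n_vertices_per_hemi
    offset = 1.5 * radius_mm

    cl, fl = _sphere_hemi(n, rng, radius_mm, jitter)
    cr, fr = _sphere_hemi(n, rng, radius_mm, jitter)
    cl = cl + np.array([-offset, 0.0, 0.0])
    cr = cr + np.array([offset, 0.0, 0.0])

    coords = np.vstack([cl, cr])
    faces = np.vstack([fl, fr + n])
    hemi = np.repeat(np.array([0, 1], dtype=np.int8), n)
    mesh = TriMesh(coords, faces, hemi)

    adj = mesh.adjacency()
    left = np.arange(n)
    right = np.arange(n, 2 * n)
    a1_size = max(3, n // 15)
    eff_size = max(5, n // 8)

    a1_left = _grow_patch(adj, int(left[np.argmin(coords[left, 0])]), a1_size, left)
    a1_right = _grow_patch(adj, int(right[np.argmax(coords[right, 0])]), a1_size, right)
    left_free = np.setdiff1d(left, a1_left)
    right_free = np.setdiff1d(right, a1_right)
    eff_seed = int(left_free[np.argmax(coords[left_free, 2])])
    cpl_seed = int(right_free[np.argmax(coords[right_free, 2])])
    effect = _grow_patch(adj, eff_seed, eff_size, left_free)
    coupled = _grow_patch(adj, cpl_seed, max(3, n // 15), right_free)

    mesh.roi_labels = {
        "A1-left": a1_left,
        "A1-right": a1_right,
        "effect-ROI-1": effect,
        "coupled-ROI-1": coupled,
    }
    return mesh


# --------------------------------------------------------------------------
# thickness
# --------------------------------------------------------------------------

def sample_thickness(mesh: TriMesh, mean_mm: float = 2.5, sd_mm: float = 0.3,
                     smoothness_mm: float = 15.0, rng_seed: int = 0) -> np.ndarray:
    """Sample a spatially smooth, positive per-vertex thickness map (mm).

    A white Gaussian field on the vertices is diffused to a geodesic
    Gaussian scale of ``smoothness_mm`` (the kernel sigma), rescaled to the
    requested spatial mean and sd, and floored at 0.5 mm.
    """
    if sd_mm <= 0:
        raise ValueError("sd_mm must be positive")
    if mean_mm <= 0:
        raise ValueError("mean_mm must be positive")
    from .surface_stats import SmoothSpec, smooth_surface

    rng = np.random.default_rng(rng_seed)
    field_ = rng.standard_normal(mesh.n_vertices)
    if smoothness_mm > 0:
        field_ = smooth_surface(field_, mesh, SmoothSpec(fwhm_mm=2.3548 * smoothness_mm))
    sd = field_.std()
    if sd > 0:
        field_ = (field_ - field_.mean()) / sd
    else:  # degenerate constant field
        field_ = np.zeros_like(field_)
    return np.maximum(mean_mm + sd_mm * field_, 0.5)


# --------------------------------------------------------------------------
# cohort spec & containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Study-design parameters of a simulated cohort.

    Defaults mirror the recording design the pipeline targets: 180 trials
    per recording, 600 Hz sampling, 3 s epochs from -1.5 to +1.5 s around
    sound onset with the stimulus in 0-1 s, and a -0.5 to -0.2 s baseline.
    """

    n_subjects: int = 72
    n_trials: int = 180
    sample_rate_hz: float = 600.0
    epoch_window_s: tuple[float, float] = (-1.5, 1.5)
    stim_window_s: tuple[float, float] = (0.0, 1.0)
    kappa_base: float = 2.0
    effect_slope: float = 0.0      # d(kappa)/d(thickness), 1/mm, in effect ROI
    effect_roi: str = "effect-ROI-1"
    thickness_mean_mm: float = 2.5
    thickness_sd_mm: float = 0.3
    thickness_smoothness_mm: float = 15.0
    coupling_lag_rad: float = np.pi / 2
    coupled_roi: str | None = "A1-right"  # lag-coupled target of the seed ROI
    seed_roi: str = "A1-left"
    noise_snr: float = 1.0
    rng_seed: int = 0
    repeated_fraction: float = 0.0  # fraction of subjects scanned twice

    def __post_init__(self) -> None:
        if self.n_trials < 2:
            raise ValueError("n_trials must be >= 2")
        t0, t1 = self.epoch_window_s
        s0, s1 = self.stim_window_s
        if not (t0 <= s0 < s1 <= t1):
            raise ValueError("stimulus window must lie inside the epoch")
        if not (t0 <= -0.5 and -0.2 <= t1):
            raise ValueError("epoch must contain the (-0.5, -0.2) baseline window")
        if self.kappa_base < 0:
            raise ValueError("kappa_base must be >= 0")
        if self.thickness_sd_mm <= 0:
            raise ValueError("thickness_sd_mm must be > 0")
        if not (0.0 <= self.repeated_fraction <= 1.0):
            raise ValueError("repeated_fraction must be in [0, 1]")


@dataclass
class TrialSet:
    """Epoched per-trial, per-vertex source time series.

    ``data`` has shape (n_trials, n_vertices, n_samples); ``times`` is the
    common time axis in seconds relative to stimulus onset.
    """

    data: np.ndarray
    sample_rate_hz: float
    times: np.ndarray
    mesh: TriMesh | None = None
    subject_id: str = ""
    scan_id: int = 1

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_trials, n_vertices, n_samples)")
        if self.times.shape != (self.data.shape[2],):
            raise ValueError("time axis length mismatch")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("time axis must be strictly increasing")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_vertices(self) -> int:
        return self.data.shape[1]


@dataclass
class SubjectRecord:
    subject_id: str
    scan_id: int
    thickness: np.ndarray
    trialset: TrialSet | None = None
    sync_maps: dict[str, np.ndarray] = field(default_factory=dict)
    thalamic_volumes: dict[str, float] = field(default_factory=dict)
    tiv: float = float("nan")

    @property
    def recording_id(self) -> str:
        return f"{self.subject_id}_scan{self.scan_id}"


@dataclass
class Cohort:
    subjects: list[SubjectRecord]
    mesh: TriMesh

    def __len__(self) -> int:
        return len(self.subjects)

    def thickness_matrix(self) -> np.ndarray:
        """(n_recordings, V) stacked thickness maps."""
        return np.stack([s.thickness for s in self.subjects])

    def sync_matrix(self, key: str) -> np.ndarray:
        """(n_recordings, V) stacked synchrony maps for ``key``."""
        return np.stack([s.sync_maps[key] for s in self.subjects])

    def unique_subjects(self) -> "Cohort":
        """Keep the first scan of each subject (repeated-scan sensitivity)."""
        seen: set[str] = set()
        kept = []
        for s in self.subjects:
            if s.subject_id not in seen:
                seen.add(s.subject_id)
                kept.append(s)
        return Cohort(kept, self.mesh)


@dataclass
class GroundTruth:
    """Sidecar record of the generative parameters, for recovery tests.

    Kept out of the data containers on purpose: pipeline code can never
    see it.
    """

    effect_roi: np.ndarray
    effect_slope: float
    kappa_base: float
    coupling_lag_rad: float
    coupled_roi: np.ndarray
    seed_roi: np.ndarray
    kappa_per_subject: np.ndarray  # (n_recordings, V)


def _kappa_map(mesh: TriMesh, spec: CohortSpec, thickness: np.ndarray) -> np.ndarray:
    kappa = np.full(mesh.n_vertices, spec.kappa_base, dtype=np.float64)
    roi = mesh.roi_labels.get(spec.effect_roi)
    if roi is not None and spec.effect_slope != 0.0:
        kappa[roi] += spec.effect_slope * (thickness[roi] - spec.thickness_mean_mm)
    return np.maximum(kappa, 0.0)


def _one_over_f_noise(rng: np.random.Generator, shape: tuple[int, ...],
                      fs: float) -> np.ndarray:
    """Gaussian noise with ~1/f power spectrum, unit RMS, last axis = time."""
    n = shape[-1]
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** -0.5  # power ~ 1/f
    spec = amp * (rng.standard_normal(shape[:-1] + (freqs.size,))
                  + 1j * rng.standard_normal(shape[:-1] + (freqs.size,)))
    x = np.fft.irfft(spec, n=n, axis=-1)
    rms = np.sqrt(np.mean(x ** 2, axis=-1, keepdims=True))
    rms[rms == 0] = 1.0
    return x / rms


def _vonmises(rng: np.random.Generator, kappa: np.ndarray,
              size: tuple[int, ...]) -> np.ndarray:
    """von Mises draws, tolerant of kappa=0 (uniform) and huge kappa."""
    kappa = np.broadcast_to(np.asarray(kappa, dtype=np.float64), size)
    out = rng.vonmises(0.0, np.maximum(kappa, 1e-12), size=size)
    # numpy's sampler degrades for extreme kappa; use wrapped normal there
    big = kappa > 1e5
    if np.any(big):
        z = rng.standard_normal(size)
        wrapped = np.angle(np.exp(1j * z / np.sqrt(np.maximum(kappa, 1.0))))
        out = np.where(big, wrapped, out)
    return out


def simulate_trialset(mesh: TriMesh, spec: CohortSpec, thickness: np.ndarray,
                      rng_seed: int = 0, subject_id: str = "sim",
                      scan_id: int = 1) -> TrialSet:
    """Simulate epoched source time series for one recording.

    Per trial and vertex: outside the stimulus window the signal is a 40 Hz
    sinusoid with uniformly random phase plus 1/f background noise (the
    Silence model); inside the stimulus window the 40 Hz phase at onset is
    drawn von Mises(0, kappa_v).  Vertices of the coupled target ROI replay
    the seed ROI's trial phase shifted by ``coupling_lag_rad``.
    """
    if thickness.shape != (mesh.n_vertices,):
        raise ValueError("thickness map does not match mesh")
    rng = np.random.default_rng(rng_seed)
    fs = spec.sample_rate_hz
    t0, t1 = spec.epoch_window_s
    times = t0 + np.arange(int(round((t1 - t0) * fs))) / fs
    n_t, n_v, n_s = spec.n_trials, mesh.n_vertices, times.size
    f0 = 40.0

    kappa = _kappa_map(mesh, spec, thickness)
    stim_phase = _vonmises(rng, kappa[None, :], (n_t, n_v))

    seed = mesh.roi_labels.get(spec.seed_roi)
    coupled = mesh.roi_labels.get(spec.coupled_roi) if spec.coupled_roi else None
    if seed is not None and seed.size:
        # one coherent ensemble phase per trial for the seed ROI
        kappa_seed = float(kappa[seed].mean())
        theta = _vonmises(rng, np.full((n_t, 1), kappa_seed), (n_t, 1))
        stim_phase[:, seed] = theta
        if coupled is not None and coupled.size:
            stim_phase[:, coupled] = theta + spec.coupling_lag_rad

    base_phase = rng.uniform(-np.pi, np.pi, size=(n_t, n_v))

    stim_mask = (times >= spec.stim_window_s[0]) & (times < spec.stim_window_s[1])
    carrier = 2 * np.pi * f0 * times
    sig = np.cos(carrier[None, None, :] + base_phase[:, :, None])
    # stimulus segment: phase referenced to onset so the drawn angle is the
    # instantaneous 40 Hz phase at t = 0
    sig[:, :, stim_mask] = np.cos(
        2 * np.pi * f0 * (times[stim_mask] - spec.stim_window_s[0])[None, None, :]
        + stim_phase[:, :, None]
    )

    if np.isfinite(spec.noise_snr) and spec.noise_snr > 0:
        sig = sig + _one_over_f_noise(rng, (n_t, n_v, n_s), fs) / spec.noise_snr
    return TrialSet(sig, fs, times, mesh=mesh, subject_id=subject_id, scan_id=scan_id)


def _resultant_length(phases: np.ndarray, axis: int = 0) -> np.ndarray:
    return np.abs(np.mean(np.exp(1j * phases), axis=axis))


def _subject_maps(mesh: TriMesh, spec: CohortSpec, thickness: np.ndarray,
                  rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Phase-level shortcut: stimulus/Silence ITPC maps without waveforms.

    The full signal path (simulate_trialset -> narrowband filter -> analytic
    phase -> ITPC) reduces, for noiseless phase-locked sinusoids, to the
    resultant length of the onset phases; this generates the per-recording
    steady-state maps directly from the same von Mises phase model, which
    keeps large cohort simulations tractable.
    """
    kappa = _kappa_map(mesh, spec, thickness)
    stim = _vonmises(rng, kappa[None, :], (spec.n_trials, mesh.n_vertices))
    sil = rng.uniform(-np.pi, np.pi, size=(spec.n_trials, mesh.n_vertices))
    return {
        "itpc_stim": _resultant_length(stim),
        "itpc_silence": _resultant_length(sil),
    }


def simulate_cohort(spec: CohortSpec, mesh: TriMesh, *,
                    mode: str = "maps") -> tuple[Cohort, GroundTruth]:
    """Simulate a cohort of recordings with a planted structure-function effect.

    mode="maps" attaches per-recording raw steady-state ITPC maps computed
    directly from the phase model (fast; the default for statistical
    experiments); mode="trials" attaches full TrialSets so the complete
    signal pipeline can run.  Thalamic nucleus volumes (7 per side) and TIV
    are drawn lognormally and are independent of synchrony.  A fraction of
    subjects can be scanned twice (fresh trial noise, same anatomy).
    """
    if mode not in ("maps", "trials"):
        raise ValueError("mode must be 'maps' or 'trials'")
    master = np.random.default_rng(spec.rng_seed)
    subjects: list[SubjectRecord] = []
    kappas: list[np.ndarray] = []

    n_repeat = int(round(spec.repeated_fraction * spec.n_subjects))
    for i in range(spec.n_subjects):
        sid = f"sub-{i + 1:03d}"
        th_seed = int(master.integers(2 ** 31))
        thickness = sample_thickness(
            mesh, spec.thickness_mean_mm, spec.thickness_sd_mm,
            spec.thickness_smoothness_mm, rng_seed=th_seed)
        n_scans = 2 if i < n_repeat else 1
        for scan in range(1, n_scans + 1):
            rec_rng = np.random.default_rng(int(master.integers(2 ** 31)))
            vols = {
                f"{nuc}-{side}": float(med * np.exp(0.10 * rec_rng.standard_normal()))
                for nuc, med in THALAMIC_NUCLEI_MM3.items()
                for side in ("lh", "rh")
            }
            tiv = float(1.5e6 * np.exp(0.08 * rec_rng.standard_normal()))
            rec = SubjectRecord(sid, scan, thickness, thalamic_volumes=vols, tiv=tiv)
            if mode == "maps":
                rec.sync_maps = _subject_maps(mesh, spec, thickness, rec_rng)
            else:
                rec.trialset = simulate_trialset(
                    mesh, spec, thickness,
                    rng_seed=int(rec_rng.integers(2 ** 31)),
                    subject_id=sid, scan_id=scan)
            subjects.append(rec)
            kappas.append(_kappa_map(mesh, spec, thickness))

    truth = GroundTruth(
        effect_roi=mesh.roi_labels.get(spec.effect_roi, np.array([], dtype=np.intp)),
        effect_slope=spec.effect_slope,
        kappa_base=spec.kappa_base,
        coupling_lag_rad=spec.coupling_lag_rad,
        coupled_roi=mesh.roi_labels.get(spec.coupled_roi or "", np.array([], dtype=np.intp)),
        seed_roi=mesh.roi_labels.get(spec.seed_roi, np.array([], dtype=np.intp)),
        kappa_per_subject=np.stack(kappas),
    )
    return Cohort(subjects, mesh), truth


def calibrate_effect_slope(mesh: TriMesh, spec: CohortSpec, *,
                           target_rho: float = 0.5, n_pilot: int = 12,
                           rng_seed: int = 0, tol: float = 0.02,
                           max_iter: int = 20) -> float:
    """Find the effect slope at which the planted across-subject Spearman
    correlation between thickness and stimulus ITPC reaches ``target_rho``.

    Pilot Monte-Carlo: for a candidate slope, simulate ``n_pilot`` cohorts
    (maps mode, effect-ROI vertices only) and take the median per-vertex
    Spearman rho over ROI vertices and pilots; bisect the slope.  The
    relation is monotone in the slope, so bisection converges.
    """
    from .surface_stats import spearman_rho_rows

    roi = mesh.roi_labels[spec.effect_roi]
    rng = np.random.default_rng(rng_seed)
    pilot_seeds = rng.integers(2 ** 31, size=n_pilot)

    def median_rho(slope: float) -> float:
        rhos = []
        for s in pilot_seeds:
            sub_rng = np.random.default_rng(int(s))
            th = np.empty((spec.n_subjects, roi.size))
            it = np.empty((spec.n_subjects, roi.size))
            for i in range(spec.n_subjects):
                thickness = sample_thickness(
                    mesh, spec.thickness_mean_mm, spec.thickness_sd_mm,
                    spec.thickness_smoothness_mm,
                    rng_seed=int(sub_rng.integers(2 ** 31)))
                kappa = np.maximum(
                    spec.kappa_base
                    + slope * (thickness[roi] - spec.thickness_mean_mm), 0.0)
                ph = _vonmises(sub_rng, kappa[None, :], (spec.n_trials, roi.size))
                th[i] = thickness[roi]
                it[i] = _resultant_length(ph)
            rhos.append(np.median(spearman_rho_rows(th.T, it.T)[0]))
        return float(np.median(rhos))

    lo, hi = 0.0, 2.0
    while median_rho(hi) < target_rho:
        hi *= 2.0
        if hi > 1e3:
            raise RuntimeError("calibration failed: target rho unreachable")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        r = median_rho(mid)
        if abs(r - target_rho) < tol:
            return mid
        if r < target_rho:
            lo = mid
        else:
            hi = mid
    warnings.warn("effect-slope calibration hit max_iter; returning midpoint")
    return 0.5 * (lo + hi)


def cohort_with_effect(spec: CohortSpec, mesh: TriMesh, *,
                       target_rho: float = 0.5, mode: str = "maps",
                       calibration_seed: int | None = None,
                       effect_slope: float | None = None,
                       ) -> tuple[Cohort, GroundTruth, float]:
    """Convenience: calibrate the slope to ``target_rho`` then simulate.

    Pass ``effect_slope`` to reuse a previously calibrated value.
    """
    if effect_slope is None:
        seed = spec.rng_seed if calibration_seed is None else calibration_seed
        effect_slope = calibrate_effect_slope(
            mesh, spec, target_rho=target_rho, rng_seed=seed)
    spec = replace(spec, effect_slope=effect_slope)
    cohort, truth = simulate_cohort(spec, mesh, mode=mode)
    return cohort, truth, effect_slope
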