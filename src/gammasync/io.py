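"""Standard-format IO, configuration and the end-to-end pipeline driver.

Surfaces and scalar maps round-trip through GIFTI (preferred on write)
and FreeSurfer binary geometry / "curv" morph files via nibabel; trial
tensors go to HDF5 (trials x vertices x samples are too large for text
formats); cohort tables to CSV.  ``run_pipeline`` ties simulation ->
smoothing -> synchrony metrics -> cluster statistics -> ROI statistics
into one seeded, cached, logged run that emits a JSON + Markdown report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .roi_analysis import (PairedSamples, a1_to_a1_connectivity,
                           paired_signed_rank_test, thalamic_correlation)
from .surface_stats import (ClusterResult, PermSpec, SmoothSpec,
                            cluster_permutation_correlation, silence_control,
                            smooth_surface)
from .sync_metrics import AnalysisWindows, BandSpec, itpc_map, seed_sync_map
from .synthetic_data import (Cohort, CohortSpec, TriMesh, TrialSet,
                             make_mesh, simulate_cohort)

logger = logging.getLogger("gammasync")

__all__ = [
    "read_surface", "write_surface", "read_morph", "write_morph",
    "save_trialset", "load_trialset", "save_thalamic_table",
    "load_thalamic_table", "PipelineConfig", "run_pipeline",
    "validate_report", "config_hash",
]


# --------------------------------------------------------------------------
# surfaces
# --------------------------------------------------------------------------

def write_surface(mesh: TriMesh, path: str | Path) -> Path:
    """Write a mesh as a GIFTI surface (.gii) or FreeSurfer geometry.

    Hemisphere and ROI labels travel in a JSON sidecar ``<path>.labels.json``
    (neither container has a native slot for named vertex sets).
    """
    path = Path(path)
    if path.suffix == ".gii":
        img = nib.gifti.GiftiImage(darrays=[
            nib.gifti.GiftiDataArray(mesh.coords.astype(np.float32),
                                     intent="NIFTI_INTENT_POINTSET"),
            nib.gifti.GiftiDataArray(mesh.faces.astype(np.int32),
                                     intent="NIFTI_INTENT_TRIANGLE"),
        ])
        nib.save(img, path)
    else:
        nib.freesurfer.write_geometry(str(path), mesh.coords, mesh.faces)
    sidecar = {
        "hemisphere": mesh.hemisphere.tolist(),
        "roi_labels": {k: v.tolist() for k, v in mesh.roi_labels.items()},
    }
    path.with_suffix(path.suffix + ".labels.json").write_text(
        json.dumps(sidecar))
    return path


def read_surface(path: str | Path) -> TriMesh:
    """Read a GIFTI or FreeSurfer binary surface back into a TriMesh."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        if path.suffix == ".gii":
            img = nib.load(path)
            coords = faces = None
            for da in img.darrays:
                if da.intent == nib.nifti1.intent_codes["NIFTI_INTENT_POINTSET"]:
                    coords = np.asarray(da.data, dtype=np.float64)
                elif da.intent == nib.nifti1.intent_codes["NIFTI_INTENT_TRIANGLE"]:
                    faces = np.asarray(da.data, dtype=np.int32)
            if coords is None or faces is None:
                raise ValueError(
                    f"{path}: GIFTI surface lacks a pointset or triangle array")
        else:
            coords, faces = nib.freesurfer.read_geometry(str(path))
            coords = np.asarray(coords, dtype=np.float64)
            faces = np.asarray(faces, dtype=np.int32)
    except ValueError:
        raise
    except Exception as exc:
        raise ValueError(f"{path}: malformed surface file ({exc})") from exc

    sidecar_path = path.with_suffix(path.suffix + ".labels.json")
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        hemi = np.asarray(sidecar["hemisphere"], dtype=np.int8)
        rois = {k: np.asarray(v, dtype=np.intp)
                for k, v in sidecar["roi_labels"].items()}
    else:
        # without a sidecar assume a single-hemisphere file (the FreeSurfer
        # convention) and no ROI labels
        hemi = np.zeros(coords.shape[0], dtype=np.int8)
        rois = {}
        warnings.warn(f"{path}: no label sidecar; treating surface as one "
                      "hemisphere with no ROI labels")
    return TriMesh(coords, faces, hemi, rois)


# --------------------------------------------------------------------------
# scalar maps
# --------------------------------------------------------------------------

def write_morph(values: np.ndarray, path: str | Path) -> Path:
    """Write a per-vertex scalar map (GIFTI .gii or FreeSurfer curv)."""
    path = Path(path)
    values = np.asarray(values, dtype=np.float32)
    if path.suffix == ".gii":
        img = nib.gifti.GiftiImage(darrays=[
            nib.gifti.GiftiDataArray(values, intent="NIFTI_INTENT_SHAPE")])
        nib.save(img, path)
    else:
        nib.freesurfer.write_morph_data(str(path), values)
    return path


def read_morph(path: str | Path, mesh: TriMesh | None = None) -> np.ndarray:
    """Read a per-vertex scalar map; optionally validate against a mesh."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        if path.suffix == ".gii":
            img = nib.load(path)
            values = np.asarray(img.darrays[0].data, dtype=np.float64)
        else:
            values = np.asarray(nib.freesurfer.read_morph_data(str(path)),
                                dtype=np.float64)
    except Exception as exc:
        raise ValueError(f"{path}: malformed scalar map ({exc})") from exc
    if mesh is not None and values.shape[0] != mesh.n_vertices:
        raise ValueError(
            f"{path}: map has {values.shape[0]} values but mesh has "
            f"{mesh.n_vertices} vertices")
    return values


# --------------------------------------------------------------------------
# trial tensors
# --------------------------------------------------------------------------

def save_trialset(trialset: TrialSet, path: str | Path, *,
                  seed: int | None = None) -> Path:
    """Store a TrialSet in HDF5 (/data, /time, /sample_rate + attrs)."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=trialset.data, compression="gzip",
                         compression_opts=1)
        f.create_dataset("time", data=trialset.times)
        f.create_dataset("sample_rate", data=trialset.sample_rate_hz)
        f.attrs["subject"] = trialset.subject_id
        f.attrs["scan"] = trialset.scan_id
        if seed is not None:
            f.attrs["seed"] = seed
    return path


def load_trialset(path: str | Path, mesh: TriMesh | None = None) -> TrialSet:
    path = Path(path)
    with h5py.File(path, "r") as f:
        return TrialSet(
            data=f["data"][()],
            sample_rate_hz=float(f["sample_rate"][()]),
            times=f["time"][()],
            mesh=mesh,
            subject_id=str(f.attrs.get("subject", "")),
            scan_id=int(f.attrs.get("scan", 1)),
        )


def save_thalamic_table(cohort: Cohort, path: str | Path) -> Path:
    """Long-format CSV: subject, scan, nucleus, volume_mm3, tiv_mm3."""
    rows = [
        {"subject": s.subject_id, "scan": s.scan_id, "nucleus": nuc,
         "volume_mm3": vol, "tiv_mm3": s.tiv}
        for s in cohort.subjects for nuc, vol in s.thalamic_volumes.items()
    ]
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def load_thalamic_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path))


# --------------------------------------------------------------------------
# configuration & report
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end run configuration; one master seed feeds every stage."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    mesh_vertices_per_hemi: int = 200
    band: BandSpec = field(default_factory=BandSpec)
    windows: AnalysisWindows = field(default_factory=AnalysisWindows)
    smooth_fwhm_mm: float = 5.0
    perm: PermSpec = field(default_factory=PermSpec)
    master_seed: int = 0
    unique_subjects: bool = False
    cohort_mode: str = "maps"         # "maps" | "trials"
    out_dir: str = "gammasync_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "cohort" in kwargs:
            kwargs["cohort"] = CohortSpec(**kwargs["cohort"])
        if "band" in kwargs:
            kwargs["band"] = BandSpec(**kwargs["band"])
        if "windows" in kwargs:
            w = kwargs["windows"]
            kwargs["windows"] = AnalysisWindows(
                tuple(w["baseline_s"]), tuple(w["steady_s"]))
        if "perm" in kwargs:
            kwargs["perm"] = PermSpec(**kwargs["perm"])
        return cls(**kwargs)


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


def config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(_to_jsonable(config), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def validate_report(report: dict) -> None:
    """Check a pipeline report against the shipped JSON schema.

    Minimal structural validation (required keys and value types) against
    ``report_schema.json``.
    """
    schema = json.loads(
        (Path(__file__).parent / "report_schema.json").read_text())
    _check_schema(report, schema, "report")


_TYPES = {"object": dict, "array": list, "string": str,
          "number": (int, float), "integer": int, "boolean": bool}


def _check_schema(value, schema: dict, where: str) -> None:
    expected = schema.get("type")
    if expected and not isinstance(value, _TYPES[expected]):
        raise ValueError(f"{where}: expected {expected}, got {type(value).__name__}")
    if expected == "object":
        for key in schema.get("required", []):
            if key not in value:
                raise ValueError(f"{where}: missing required key {key!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in value:
                _check_schema(value[key], sub, f"{where}.{key}")
    elif expected == "array" and "items" in schema:
        for i, item in enumerate(value):
            _check_schema(item, schema["items"], f"{where}[{i}]")


def _cluster_summary(result: ClusterResult) -> dict:
    return {
        "n_clusters": len(result.clusters),
        "n_significant": len(result.significant_clusters),
        "clusters": [
            {"n_vertices": int(c.vertices.size), "mass": float(c.mass),
             "p_mc": float(c.p_mc), "significant": bool(c.significant)}
            for c in result.clusters
        ],
        "max_abs_rho": float(np.max(np.abs(result.rho))) if result.rho.size else 0.0,
    }


# --------------------------------------------------------------------------
# pipeline driver
# --------------------------------------------------------------------------

def _stage(name: str, report: dict):
    class _Timer:
        def __enter__(self):
            logger.info("stage %s: start", name)
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc_type is not None:
                logger.error("stage %s: FAILED after %.2fs (%s)", name, dt, exc)
                report.setdefault("failed_stage", name)
                return False
            logger.info("stage %s: done in %.2fs", name, dt)
            report.setdefault("timing_s", {})[name] = round(dt, 3)
            return False
    return _Timer()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run simulate -> smooth -> metrics -> correlate -> roi-stats.

    All randomness derives from ``config.master_seed``.  Stage outputs are
    cached in ``out_dir`` keyed by the config hash; re-running with the
    same config reuses the cached cohort.  Returns the report dict (also
    written as report.json and report.md, each with a provenance block).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    master = np.random.default_rng(config.master_seed)
    seeds = {k: int(master.integers(2 ** 31))
             for k in ("mesh", "cohort", "perm", "thalamus")}

    report: dict = {
        "provenance": {
            "package": "gammasync", "version": __version__,
            "config_hash": chash, "master_seed": config.master_seed,
            "stage_seeds": seeds, "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        },
        "config": _to_jsonable(config),
    }

    cache = out / f"cohort_{chash}.npz"
    with _stage("simulate", report):
        mesh = make_mesh(config.mesh_vertices_per_hemi, rng_seed=seeds["mesh"])
        spec = dataclasses.replace(config.cohort, rng_seed=seeds["cohort"])
        if cache.exists():
            logger.info("reusing cached cohort %s", cache.name)
            npz = np.load(cache, allow_pickle=True)
            thickness = npz["thickness"]
            stim = npz["stim"]
            silence = npz["silence"]
            subject_ids = list(npz["subject_ids"])
            scan_ids = list(npz["scan_ids"])
            thal = pd.read_csv(out / f"thalamus_{chash}.csv")
        else:
            cohort, _truth = simulate_cohort(spec, mesh, mode=config.cohort_mode)
            if config.cohort_mode == "trials":
                for s in cohort.subjects:
                    m = itpc_map(s.trialset, config.band, config.windows)
                    s.sync_maps["itpc_stim"] = m.values
                    raw_sil = itpc_map(s.trialset, config.band, config.windows,
                                       zscored=False, window="baseline")
                    s.sync_maps["itpc_silence"] = raw_sil.values
                    s.trialset = None  # free memory once maps exist
            thickness = cohort.thickness_matrix()
            stim = cohort.sync_matrix("itpc_stim")
            silence = cohort.sync_matrix("itpc_silence")
            subject_ids = [s.subject_id for s in cohort.subjects]
            scan_ids = [s.scan_id for s in cohort.subjects]
            save_thalamic_table(cohort, out / f"thalamus_{chash}.csv")
            thal = pd.read_csv(out / f"thalamus_{chash}.csv")
            np.savez_compressed(cache, thickness=thickness, stim=stim,
                                silence=silence, subject_ids=subject_ids,
                                scan_ids=scan_ids)
        if config.unique_subjects:
            keep, seen = [], set()
            for i, sid in enumerate(subject_ids):
                if sid not in seen:
                    seen.add(sid)
                    keep.append(i)
            thickness, stim, silence = thickness[keep], stim[keep], silence[keep]
            subject_ids = [subject_ids[i] for i in keep]
        report["n_recordings"] = len(subject_ids)
        report["n_unique_subjects"] = len(set(subject_ids))
        report["n_vertices"] = mesh.n_vertices
    if "failed_stage" in report:
        raise RuntimeError(f"pipeline aborted at stage {report['failed_stage']}")

    with _stage("smooth", report):
        sm = SmoothSpec(config.smooth_fwhm_mm)
        thickness_s = smooth_surface(thickness, mesh, sm)
        stim_s = smooth_surface(stim, mesh, sm)
        silence_s = smooth_surface(silence, mesh, sm)

    with _stage("correlate", report):
        perm = dataclasses.replace(config.perm, rng_seed=seeds["perm"])
        res_stim = cluster_permutation_correlation(thickness_s, stim_s, mesh, perm)
        res_sil = silence_control(thickness_s, silence_s, mesh, perm)
        report["correlation_stimulus"] = _cluster_summary(res_stim)
        report["correlation_silence"] = _cluster_summary(res_sil)
        write_morph(res_stim.rho, out / "rho_stimulus.gii")
        write_morph(res_stim.t, out / "t_stimulus.gii")
        pd.DataFrame({"max_abs_mass": res_stim.null_max_mass}).to_csv(
            out / "null_distribution.csv", index=False)

    with _stage("roi_stats", report):
        summary = {sid: float(stim_s[i].mean())
                   for i, sid in enumerate(subject_ids)}
        # one scalar per unique subject (first scan) for the thalamic table
        first = {}
        for sid, val in summary.items():
            first.setdefault(sid, val)
        thal_res = thalamic_correlation(
            thal.drop_duplicates(subset=["subject", "nucleus"]),
            first, n_perm=min(config.perm.n_perm, 2000),
            rng_seed=seeds["thalamus"])
        report["thalamic"] = {
            "n_nuclei": int(len(thal_res)),
            "n_significant": int((thal_res["p_maxstat"] < config.perm.alpha).sum()),
            "min_p_maxstat": float(thal_res["p_maxstat"].min()),
        }
        # paired stimulus-vs-Silence contrast of the subject-mean raw ITPC
        pairs = PairedSamples(stim.mean(axis=1), silence.mean(axis=1),
                              metric="ITPC")
        wr = paired_signed_rank_test(pairs)
        report["stim_vs_silence"] = {
            "metric": "ITPC", "z": wr.z, "p": wr.p, "n": wr.n_effective,
        }

    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=2))
    _write_markdown_report(report, out / "report.md")
    validate_report(report)
    for fname in ("rho_stimulus.gii", "t_stimulus.gii"):
        sidecar = {"config_hash": chash, "version": __version__}
        (out / (fname + ".json")).write_text(json.dumps(sidecar))
    logger.info("report written to %s", report_path)
    return report


def _write_markdown_report(report: dict, path: Path) -> None:
    lines = ["# gammasync pipeline report", ""]
    prov = report["provenance"]
    lines += [f"- version: {prov['version']}  ",
              f"- config hash: `{prov['config_hash']}`  ",
              f"- master seed: {prov['master_seed']}", ""]
    lines += [f"Recordings: {report['n_recordings']} "
              f"({report['n_unique_subjects']} unique subjects), "
              f"{report['n_vertices']} vertices", ""]
    for key, title in (("correlation_stimulus", "Thickness vs stimulus ITPC"),
                       ("correlation_silence", "Thickness vs Silence ITPC")):
        c = report[key]
        lines += [f"## {title}", "",
                  f"{c['n_significant']} significant of {c['n_clusters']} "
                  f"clusters (max |rho| = {c['max_abs_rho']:.3f})", ""]
        if c["clusters"]:
            lines += ["| vertices | mass | p |", "|---|---|---|"]
            lines += [f"| {cl['n_vertices']} | {cl['mass']:.1f} | "
                      f"{cl['p_mc']:.4f} |" for cl in c["clusters"][:10]]
            lines.append("")
    th = report["thalamic"]
    lines += ["## Thalamic volumes", "",
              f"{th['n_significant']} of {th['n_nuclei']} nuclei significant "
              f"after max-stat correction (min p = {th['min_p_maxstat']:.3f})", ""]
    sv = report["stim_vs_silence"]
    lines += ["## Stimulus vs Silence", "",
              f"{sv['metric']}: Z = {sv['z']:.3f}, p = {sv['p']:.3g} "
              f"(n = {sv['n']})", ""]
    path.write_text("\n".join(lines))
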