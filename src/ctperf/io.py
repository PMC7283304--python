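"""NIfTI and tabular I/O.

Subjects, truth maps and parametric maps travel as NIfTI (via nibabel)
with a diagonal affine built from the voxel size; cohort-level results
are CSV.  Gzip members are written with a zeroed mtime so identical runs
serialise byte-identically.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from ctperf.phantom import CTPStudy, SubjectTruth

__all__ = [
    "save_volume", "load_volume", "save_subject", "load_subject",
    "save_map_set", "load_map_set",
]


def _affine(voxel_size) -> np.ndarray:
    return np.diag(list(voxel_size) + [1.0])


def save_volume(data: np.ndarray, voxel_size, path: str | Path) -> Path:
    """Write a 3D/4D array as NIfTI; boolean arrays are stored as uint8."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if data.dtype == bool:
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(np.asarray(data), _affine(voxel_size))
    if str(path).endswith(".gz"):
        # deterministic gzip payload regardless of wall clock
        with open(path, "wb") as raw:
            import gzip

            with gzip.GzipFile(fileobj=raw, mode="wb", mtime=0) as f:
                f.write(img.to_bytes())
    else:
        nib.save(img, str(path))
    return path


def load_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Return (data, affine)."""
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine


def save_subject(out_dir: str | Path, study: CTPStudy,
                 truth: SubjectTruth | None = None,
                 aif_curve: np.ndarray | None = None) -> Path:
    """Write one subject: 4D study, coverage mask, optional truth + AIF."""
    out_dir = Path(out_dir)
    sid = study.subject_id
    save_volume(study.data, study.voxel_size, out_dir / f"{sid}_ctp.nii.gz")
    save_volume(study.coverage_mask, study.voxel_size,
                out_dir / f"{sid}_coverage.nii.gz")
    meta = {"subject_id": sid, "group": study.group, "dt": study.dt,
            "voxel_size": list(study.voxel_size)}
    if aif_curve is not None:
        meta["aif_curve"] = [float(v) for v in aif_curve]
    (out_dir / f"{sid}_meta.json").write_text(json.dumps(meta, indent=1))
    if truth is not None:
        save_volume(truth.fiv_mask_true, study.voxel_size,
                    out_dir / f"{sid}_fiv.nii.gz")
        save_volume(truth.region_label_map.astype(np.uint8), study.voxel_size,
                    out_dir / f"{sid}_regions.nii.gz")
        for name in ("cbf", "cbv", "mtt", "delay"):
            save_volume(getattr(truth, f"{name}_true"), study.voxel_size,
                        out_dir / f"{sid}_true_{name}.nii.gz")
    return out_dir


def load_subject(out_dir: str | Path, subject_id: str
                 ) -> tuple[CTPStudy, np.ndarray | None, np.ndarray | None]:
    """Load a subject written by :func:`save_subject`.

    Returns (study, fiv_mask or None, aif_curve or None).
    """
    out_dir = Path(out_dir)
    meta = json.loads((out_dir / f"{subject_id}_meta.json").read_text())
    data, _ = load_volume(out_dir / f"{subject_id}_ctp.nii.gz")
    coverage, _ = load_volume(out_dir / f"{subject_id}_coverage.nii.gz")
    study = CTPStudy(
        data=np.asarray(data, dtype=float),
        dt=float(meta["dt"]),
        voxel_size=tuple(meta["voxel_size"]),
        coverage_mask=np.asarray(coverage).astype(bool),
        subject_id=meta["subject_id"],
        group=meta["group"],
    )
    fiv_path = out_dir / f"{subject_id}_fiv.nii.gz"
    fiv = None
    if fiv_path.exists():
        fiv = np.asarray(load_volume(fiv_path)[0]).astype(bool)
    aif = meta.get("aif_curve")
    return study, fiv, np.asarray(aif, dtype=float) if aif is not None else None


def save_map_set(out_dir: str | Path, subject_id: str, map_set,
                 voxel_size) -> None:
    """Write each parametric map (and validity masks) as 3D NIfTI."""
    algo = map_set.algorithm.upper()
    out_dir = Path(out_dir)
    for name in map_set.parameter_names(relative=True):
        save_volume(np.nan_to_num(map_set[name], nan=0.0), voxel_size,
                    out_dir / f"{subject_id}_{algo}_{name}.nii.gz")
    save_volume(map_set.valid_mask, voxel_size,
                out_dir / f"{subject_id}_{algo}_valid.nii.gz")
    for name, mask in map_set.rel_valid.items():
        save_volume(mask, voxel_size,
                    out_dir / f"{subject_id}_{algo}_{name}_valid.nii.gz")


def load_map_set(out_dir: str | Path, subject_id: str, algorithm: str):
    """Reconstruct a ParametricMapSet written by :func:`save_map_set`.

    Stored maps replace NaN with 0; invalidity is restored from the
    saved validity masks.
    """
    from ctperf.perfusion import ParametricMapSet

    out_dir = Path(out_dir)
    algo = algorithm.upper()

    def vol(name):
        return np.asarray(load_volume(out_dir / f"{subject_id}_{algo}_{name}.nii.gz")[0],
                          dtype=float)

    valid = vol("valid").astype(bool)
    time_param = "ttp" if algorithm.lower() == "ats" else "tmax"

    def masked(name, mask):
        v = vol(name)
        v[~mask] = np.nan
        return v

    ms = ParametricMapSet(
        algorithm=algorithm.lower(),
        cbf=masked("cbf", valid),
        cbv=masked("cbv", valid),
        mtt=masked("mtt", valid),
        time_map=masked(time_param, valid),
        valid_mask=valid,
    )
    for base in ("cbf", "cbv", "mtt", time_param):
        name = f"{base}_rel"
        rel_valid = vol(f"{name}_valid").astype(bool)
        ms.rel[name] = masked(name, rel_valid)
        ms.rel_valid[name] = rel_valid
    return ms
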