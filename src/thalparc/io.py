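"""NIfTI and table I/O with provenance.

Volumes are NIfTI-1 via nibabel; the SH coefficient axis is the 4th
dimension; label/mask volumes are integer 3D volumes.  Voxel indices are
0-based; world coordinates (RAS) enter only through the affine at this
boundary.  Tables are TSV (UTF-8, header row); nested results are JSON with
a provenance block (package version, seed, config hash).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from . import __version__
from .phantom import Cohort
from .shmath import FODImage, sh_basis_size


def default_affine(voxel_size=(1.25, 1.25, 1.25)) -> np.ndarray:
    aff = np.diag(list(voxel_size) + [1.0])
    return aff


def write_volume(path, data: np.ndarray, voxel_size=(1.25, 1.25, 1.25), affine=None):
    affine = default_affine(voxel_size) if affine is None else affine
    img = nib.Nifti1Image(np.asarray(data), affine)
    img.to_filename(str(path))


def read_volume(path) -> tuple[np.ndarray, np.ndarray]:
    """Load a NIfTI volume; returns (data, affine)."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"no such volume: {p}")
    img = nib.load(str(p))
    return np.asarray(img.get_fdata()), img.affine


def read_fod(path, lmax: int | None = None, mask: np.ndarray | None = None) -> FODImage:
    """Load a 4D SH coefficient volume, validating the coefficient axis."""
    data, affine = read_volume(path)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D SH volume, got shape {data.shape}")
    if lmax is not None and data.shape[-1] != sh_basis_size(lmax):
        raise ValueError(
            f"{path}: coefficient axis {data.shape[-1]} != sh_basis_size({lmax}) = {sh_basis_size(lmax)}"
        )
    voxel_size = tuple(np.abs(np.diag(affine)[:3]))
    return FODImage(data, voxel_size=voxel_size, mask=mask)


def check_grid(shape_a, shape_b, what="volumes"):
    if tuple(shape_a) != tuple(shape_b):
        raise ValueError(f"misaligned {what}: grid {tuple(shape_a)} vs {tuple(shape_b)}")


def write_cohort(cohort: Cohort, outdir) -> Path:
    """Write a cohort as a directory tree of NIfTI volumes + TSV metadata + manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    vs = cohort.config.voxel_size
    write_volume(out / "mask.nii.gz", cohort.mask.astype(np.uint8), vs)
    write_volume(out / "truth_labels.nii.gz", cohort.labels.astype(np.int16), vs)
    write_volume(out / "pathways.nii.gz", cohort.pathways.astype(np.int16), vs)
    for s in cohort.subjects:
        sid = s.record["id"]
        sub = out / sid
        sub.mkdir(exist_ok=True)
        write_volume(sub / "fod.nii.gz", s.fod.coeffs.astype(np.float32), vs)
        write_volume(sub / "warp.nii.gz", s.warp_field.astype(np.float32), vs)
        write_volume(sub / "tensor_eigs.nii.gz", s.tensor_eigs.astype(np.float32), vs)
    cohort.metadata.to_csv(out / "metadata.tsv", sep="\t", index=False)
    (out / "manifest.json").write_text(json.dumps(cohort.manifest, indent=2, sort_keys=True))
    return out


def config_hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:12]


def save_summary(summary: dict, path, seed: int | None = None) -> None:
    payload = {
        "provenance": {
            "tool": "thalparc",
            "version": __version__,
            "seed": seed,
            "config_hash": config_hash(summary.get("config", {})),
        },
        **summary,
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def write_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=True)
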