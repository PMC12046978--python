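"""NIfTI / TSV / YAML input-output for cohorts and results."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .volume import METRIC_UNITS, METRICS, MaskSet, SubjectRecord, VolumeMap

__all__ = [
    "save_volume",
    "load_volume",
    "save_cohort",
    "load_cohort",
    "load_yaml_config",
    "write_manifest",
]

MASK_NAMES = ("wm", "wmh", "lacunes", "brain")


def _affine(voxel_size_mm) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size_mm
    return aff


def save_volume(vm: VolumeMap, path, dtype=None) -> None:
    data = vm.values if dtype is None else np.asarray(vm.values, dtype=dtype)
    img = nib.Nifti1Image(np.asarray(data), _affine(vm.voxel_size_mm))
    img.header.set_zooms(vm.voxel_size_mm)
    nib.save(img, str(path))


def load_volume(path, units: str = "") -> VolumeMap:
    img = nib.load(str(path))
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VolumeMap(np.asarray(img.dataobj), zooms, units=units)


def save_cohort(subjects: list[SubjectRecord], outdir, table: pd.DataFrame | None = None) -> None:
    """Write per-subject NIfTI volumes and the cohort TSV under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for s in subjects:
        sdir = outdir / s.id
        sdir.mkdir(exist_ok=True)
        for name, vm in s.maps.items():
            save_volume(vm, sdir / f"{name}.nii.gz", dtype=np.float32)
        sp = s.masks.voxel_size_mm
        for mname in MASK_NAMES:
            arr = getattr(s.masks, mname)
            if arr is None:
                continue
            save_volume(VolumeMap(arr.astype(np.uint8), sp), sdir / f"{mname}.nii.gz")
    if table is None:
        from .simulate import cohort_table

        table = cohort_table(subjects)
    table.to_csv(outdir / "cohort.tsv", sep="\t", index=False)


def load_cohort(indir) -> list[SubjectRecord]:
    """Load a cohort written by :func:`save_cohort` (or arranged the same way)."""
    indir = Path(indir)
    table = pd.read_csv(indir / "cohort.tsv", sep="\t")
    subjects = []
    for _, row in table.iterrows():
        sdir = indir / str(row["id"])
        maps = {}
        for name in METRICS:
            p = sdir / f"{name}.nii.gz"
            if p.exists():
                maps[name] = load_volume(p, units=METRIC_UNITS.get(name, ""))
        if not maps:
            raise FileNotFoundError(f"no metric maps found under {sdir}")
        sp = next(iter(maps.values())).voxel_size_mm

        def _mask(name, required=True):
            p = sdir / f"{name}.nii.gz"
            if not p.exists():
                if required:
                    raise FileNotFoundError(f"missing mask {name!r} for subject {row['id']}")
                return None
            return np.asarray(load_volume(p).values) > 0

        masks = MaskSet(
            wm=_mask("wm"),
            wmh=_mask("wmh"),
            lacunes=_mask("lacunes"),
            voxel_size_mm=sp,
            brain=_mask("brain", required=False),
        )
        subjects.append(
            SubjectRecord(
                id=str(row["id"]),
                group=str(row["group"]),
                age=float(row["age"]),
                sex=int(row["sex"]),
                education=float(row["education"]),
                maps=maps,
                masks=masks,
                cognition=float(row.get("cognition", np.nan)),
            )
        )
    return subjects


def load_yaml_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def write_manifest(path, payload: dict) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, tuple):
            return list(o)
        return str(o)

    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_default)
        fh.write("\n")
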