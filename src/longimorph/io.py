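"""CSV and NIfTI-1 input/output for cohorts, volume tables and map stacks.

CSV dialect: UTF-8, comma separated, header row, ``.`` decimal point.
Voxel coordinates in cluster tables are 0-based.
"""
from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .cohort import Cohort
from .tbm import TBMStack

__all__ = [
    "SchemaError",
    "read_table",
    "write_table",
    "read_cohort",
    "write_cohort",
    "read_nifti",
    "write_nifti",
    "read_mask",
    "write_tbm_stack",
    "read_tbm_stack",
]

PARTICIPANT_COLUMNS = ["participant_id", "group", "diabetes", "sex", "baseline_age", "etiv"]
VISIT_COLUMNS = [
    "participant_id", "session", "age_at_scan", "time_from_baseline", "time_to_midpoint",
]
VOLUME_COLUMNS = ["participant_id", "session", "region", "time_from_baseline", "volume", "etiv"]
MANIFEST_COLUMNS = ["participant_id", "session", "variant", "time", "filename"]


class SchemaError(ValueError):
    """A required column is missing from an input table."""


def _check_columns(df: pd.DataFrame, required: list, what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing column(s) {missing}")


def read_table(path, required: list | None = None, what: str = "table") -> pd.DataFrame:
    df = pd.read_csv(path)
    if required:
        _check_columns(df, required, what)
    return df


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def write_cohort(cohort: Cohort, out_dir) -> dict:
    out = Path(out_dir)
    return {
        "participants": write_table(cohort.participants, out / "participants.csv"),
        "visits": write_table(cohort.visits, out / "visits.csv"),
    }


def read_cohort(out_dir) -> Cohort:
    out = Path(out_dir)
    parts = read_table(out / "participants.csv", PARTICIPANT_COLUMNS, "participants")
    visits = read_table(out / "visits.csv", VISIT_COLUMNS, "visits")
    return Cohort(participants=parts, visits=visits)


# --------------------------------------------------------------------------

def write_nifti(data: np.ndarray, path, affine: np.ndarray | None = None,
                grid_spacing: float = 2.0) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if affine is None:
        affine = np.diag([grid_spacing, grid_spacing, grid_spacing, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine), str(path))
    return path


def read_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=np.float64), img.affine


def read_mask(path) -> np.ndarray:
    data, _ = read_nifti(path)
    vals = np.unique(data)
    if not np.all(np.isin(vals, (0.0, 1.0))):
        raise ValueError(f"mask must be binary; found values {vals[:5]}")
    return data.astype(bool)


def write_tbm_stack(stack: TBMStack, out_dir) -> Path:
    """One NIfTI per map plus manifest.csv and mask.nii.gz."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for _, r in stack.meta.iterrows():
        fname = f"map_{int(r['index']):05d}_{r.participant_id}_s{int(r.session)}_{r.variant}.nii.gz"
        write_nifti(stack.maps[int(r["index"])], out / fname, grid_spacing=stack.grid_spacing)
        rows.append((r.participant_id, int(r.session), r.variant, float(r.time), fname))
    write_nifti(stack.mask.astype(float), out / "mask.nii.gz", grid_spacing=stack.grid_spacing)
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    write_table(manifest, out / "manifest.csv")
    return out


def read_tbm_stack(out_dir) -> TBMStack:
    out = Path(out_dir)
    manifest = read_table(out / "manifest.csv", MANIFEST_COLUMNS, "manifest")
    mask = read_mask(out / "mask.nii.gz")
    maps = []
    for _, r in manifest.iterrows():
        data, _ = read_nifti(out / r.filename)
        if data.shape != mask.shape:
            raise ValueError(
                f"{r.filename}: shape {data.shape} does not match mask {mask.shape}"
            )
        maps.append(data)
    meta = manifest.drop(columns=["filename"]).copy()
    meta.insert(0, "index", np.arange(len(meta)))
    img = nib.load(str(out / "mask.nii.gz"))
    spacing = float(img.affine[0, 0])
    return TBMStack(maps=np.stack(maps), mask=mask, meta=meta, grid_spacing=spacing)
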