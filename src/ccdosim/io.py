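"""File I/O: label volumes (HDF5 / NIfTI), field solutions (HDF5),
impedance curves and dose tables (delimited text / JSON)."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .contact import ImpedanceCurve

__all__ = [
    "write_label_volume", "read_label_volume",
    "write_field_solution", "read_impedance_curve", "write_impedance_curve",
    "doses_to_frame", "write_dose_reports",
]


def write_label_volume(phantom, path: str | Path) -> None:
    """Write the phantom's label grid; format chosen by extension
    (.h5/.hdf5 or .nii/.nii.gz)."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            ds = f.create_dataset("labels", data=phantom.labels, compression="gzip")
            ds.attrs["spacing_mm"] = phantom.spacing
            ds.attrs["origin_mm"] = phantom.origin
            ds.attrs["tissue_map"] = json.dumps(
                {str(k): v for k, v in phantom.tissue_map.items()})
            ds.attrs["heart_axes_mm"] = phantom.heart_axes.reshape(-1)
    elif path.name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        affine = np.diag(list(phantom.spacing) + [1.0])
        affine[:3, 3] = phantom.origin
        img = nib.Nifti1Image(phantom.labels.astype(np.uint8), affine)
        img.header.set_zooms(tuple(phantom.spacing))
        nib.save(img, str(path))
    else:
        raise ValueError(f"unsupported label-volume extension: {path.name}")


def read_label_volume(path: str | Path):
    """Read (labels, spacing_mm, origin_mm, heart_axes or None)."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            ds = f["labels"]
            labels = ds[...]
            spacing = np.asarray(ds.attrs.get("spacing_mm", [1.0, 1.0, 1.0]), float)
            origin = np.asarray(ds.attrs.get("origin_mm", [0.0, 0.0, 0.0]), float)
            axes = ds.attrs.get("heart_axes_mm")
            heart_axes = np.asarray(axes, float).reshape(3, 2, 3) if axes is not None else None
        return labels, spacing, origin, heart_axes
    if path.name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(str(path))
        labels = np.asarray(img.dataobj).astype(np.int64)
        spacing = np.asarray(img.header.get_zooms()[:3], float)
        origin = np.asarray(img.affine[:3, 3], float)
        return labels, spacing, origin, None
    raise ValueError(f"unsupported label-volume extension: {path.name}")


def write_field_solution(solution, path: str | Path) -> None:
    """Serialize a field solution (phi, E, J complex grids) to HDF5."""
    with h5py.File(path, "w") as f:
        f.create_dataset("phi", data=solution.potential, compression="gzip")
        if solution.e_field is not None:
            f.create_dataset("E", data=solution.e_field, compression="gzip")
        if solution.j_field is not None:
            f.create_dataset("J", data=solution.j_field, compression="gzip")
        f.attrs["frequency_hz"] = solution.frequency
        f.attrs["residual"] = solution.residual
        scen = solution.scenario
        f.attrs["scenario"] = json.dumps({
            "path": scen.path.label,
            "frequency_hz": scen.frequency,
            "touch_voltage_v": scen.touch_voltage,
            "mode": scen.mode.value,
        })


def read_impedance_curve(path: str | Path, contact: str = "") -> ImpedanceCurve:
    """Read a reference impedance curve from delimited text with header
    columns (frequency_hz, touch_voltage_v, z_ohm)."""
    df = pd.read_csv(path)
    required = {"frequency_hz", "touch_voltage_v", "z_ohm"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"{path}: expected columns {sorted(required)}, got {list(df.columns)}")
    points = tuple(
        (float(r.frequency_hz), float(r.touch_voltage_v), float(r.z_ohm))
        for r in df.itertuples())
    return ImpedanceCurve(points=points, contact=contact)


def write_impedance_curve(curve: ImpedanceCurve, path: str | Path) -> None:
    pd.DataFrame(curve.points,
                 columns=["frequency_hz", "touch_voltage_v", "z_ohm"]).to_csv(
        path, index=False)


def doses_to_frame(doses) -> pd.DataFrame:
    """One row per (path, frequency): currents, impedances, heart fields, HCFs."""
    rows = []
    for d in doses:
        rows.append({
            "path": d.path_label,
            "frequency_hz": d.frequency,
            "touch_voltage_v": d.touch_voltage,
            "mode": d.mode,
            "i_body_a": abs(d.i_body),
            "i_phase_rad": float(np.angle(d.i_body)),
            "z_total_ohm": abs(d.z_total),
            "e99_heart_v_per_m": d.e99_heart,
            "e_sam_v_per_m": d.e_sam,
            "f99_num": d.f99_num,
            "f_sam_num": d.f_sam_num,
            "plane_spread": d.plane_spread,
            "residual": d.residual,
        })
    return pd.DataFrame(rows).sort_values(["path", "frequency_hz"]).reset_index(drop=True)


def write_dose_reports(doses, path: str | Path) -> None:
    doses_to_frame(doses).to_csv(path, index=False)
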