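"""File I/O: HDF5 subject containers, NIfTI volumes, and report tables."""

from __future__ import annotations

from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

from .containers import GroundTruth, LeadField, SensorRecording, SourceGrid, VolumeSeries

__all__ = [
    "save_subject_container",
    "load_subject_container",
    "save_volume_nifti",
    "load_volume_nifti",
    "save_map_nifti",
    "load_map_nifti",
    "write_table",
]


def save_subject_container(
    path,
    rec: SensorRecording,
    grid: SourceGrid,
    leadfield: LeadField,
    truth: GroundTruth | None = None,
    template: np.ndarray | None = None,
) -> None:
    """Write one subject's EEG + forward model (+ ground truth) to HDF5."""
    with h5py.File(path, "w") as fh:
        g = fh.create_group("eeg")
        g.create_dataset("data", data=rec.data, compression="gzip")
        g.attrs["fs"] = rec.fs
        g.create_dataset("labels", data=np.array(rec.labels, dtype="S"))
        g.create_dataset("positions", data=rec.positions)
        g.create_dataset("tr_markers", data=rec.tr_markers)
        g.create_dataset("cardiac_markers", data=rec.cardiac_markers)
        g.create_dataset("bad_flags", data=rec.bad_flags)

        g = fh.create_group("grid")
        g.create_dataset("coords", data=grid.coords)
        g.attrs["spacing"] = grid.spacing
        g.attrs["shape"] = grid.shape
        g.create_dataset("gm_mask", data=grid.gm_mask)

        g = fh.create_group("leadfield")
        g.create_dataset("matrix", data=leadfield.matrix)
        g.create_dataset("sensor_positions", data=leadfield.sensor_positions)
        g.attrs["reference"] = leadfield.reference

        if truth is not None:
            g = fh.create_group("truth")
            g.create_dataset("network_maps", data=truth.network_maps)
            g.create_dataset("envelopes", data=truth.envelopes)
            g.create_dataset("carrier_bands",
                             data=np.array(list(truth.carrier_bands), dtype="S"))
        if template is not None:
            fh.create_dataset("template", data=np.asarray(template))


def load_subject_container(path):
    """Inverse of :func:`save_subject_container`.

    Returns ``(rec, grid, leadfield, truth, template)``; truth/template are
    None when absent.
    """
    with h5py.File(path, "r") as fh:
        g = fh["eeg"]
        rec = SensorRecording(
            data=g["data"][()],
            fs=float(g.attrs["fs"]),
            labels=[s.decode() for s in g["labels"][()]],
            positions=g["positions"][()],
            tr_markers=g["tr_markers"][()],
            cardiac_markers=g["cardiac_markers"][()],
            bad_flags=g["bad_flags"][()],
        )
        g = fh["grid"]
        grid = SourceGrid(
            coords=g["coords"][()],
            spacing=float(g.attrs["spacing"]),
            gm_mask=g["gm_mask"][()],
            shape=tuple(int(s) for s in g.attrs["shape"]),
        )
        g = fh["leadfield"]
        leadfield = LeadField(
            matrix=g["matrix"][()],
            sensor_positions=g["sensor_positions"][()],
            reference=str(g.attrs["reference"]),
        )
        truth = None
        if "truth" in fh:
            g = fh["truth"]
            truth = GroundTruth(
                network_maps=g["network_maps"][()],
                envelopes=g["envelopes"][()],
                carrier_bands=[s.decode() for s in g["carrier_bands"][()]],
            )
        template = fh["template"][()] if "template" in fh else None
    return rec, grid, leadfield, truth, template


def save_volume_nifti(path, vol: VolumeSeries, grid: SourceGrid) -> None:
    """Write a voxel × volume series as a 4-D NIfTI-1 on the grid's affine."""
    data = grid.volume(vol.values).astype(np.float32)
    img = nib.Nifti1Image(data, grid.affine())
    img.header.set_zooms(tuple([grid.spacing] * 3) + (vol.tr,))
    nib.save(img, str(path))


def load_volume_nifti(path, grid: SourceGrid) -> VolumeSeries:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 1.0
    return VolumeSeries(values=data.reshape(grid.n_voxels, -1), tr=tr)


def save_map_nifti(path, values: np.ndarray, grid: SourceGrid) -> None:
    """Write a flat per-voxel map as a 3-D NIfTI-1 on the grid."""
    img = nib.Nifti1Image(grid.volume(np.asarray(values, dtype=np.float32)),
                          grid.affine())
    nib.save(img, str(path))


def load_map_nifti(path, grid: SourceGrid) -> np.ndarray:
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=np.float64).reshape(grid.n_voxels)


def write_table(path, table: pd.DataFrame) -> None:
    """Write a report table as tab-delimited text."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", float_format="%.4f")
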