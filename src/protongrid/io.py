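"""File I/O: delimited-text dose planes, MHD volumes, STL meshes, DICOM-RT dose.

Planar doses travel as plain text with a two-line header carrying the
origin and spacing (mm); volumes as MetaImage (.mhd/.raw via SimpleITK);
meshes as STL (binary by default).  A minimal DICOM-RT Dose writer/reader
is provided for interoperability with planning systems.
"""

from __future__ import annotations

import datetime
from pathlib import Path

import numpy as np
import pandas as pd
import SimpleITK as sitk
import trimesh

from .grids import DoseGrid, DosePlane

__all__ = [
    "write_plane_txt", "read_plane_txt", "write_volume_mhd", "read_volume_mhd",
    "write_stl", "read_stl", "write_layout_csv", "write_dicom_dose",
    "read_dicom_dose",
]


def write_plane_txt(plane: DosePlane, path) -> None:
    """Write a 2D plane as whitespace-delimited text.

    Header: two comment lines with origin (x, y[, depth]) and spacing in mm;
    body: one row per x index, one column per y index.
    """
    path = Path(path)
    depth = "" if plane.depth is None else f" depth_mm: {plane.depth:.6g}"
    header = (f"origin_mm: {plane.origin[0]:.6g} {plane.origin[1]:.6g}{depth}\n"
              f"spacing_mm: {plane.spacing[0]:.6g} {plane.spacing[1]:.6g}")
    np.savetxt(path, plane.values, header=header, fmt="%.8g")


def read_plane_txt(path) -> DosePlane:
    path = Path(path)
    origin, spacing, depth = None, None, None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            tokens = line.lstrip("# ").split()
            if tokens and tokens[0] == "origin_mm:":
                origin = [float(tokens[1]), float(tokens[2])]
                if "depth_mm:" in tokens:
                    depth = float(tokens[tokens.index("depth_mm:") + 1])
            elif tokens and tokens[0] == "spacing_mm:":
                spacing = [float(tokens[1]), float(tokens[2])]
    if origin is None or spacing is None:
        raise ValueError(f"{path} lacks the origin/spacing header")
    values = np.loadtxt(path, ndmin=2)
    return DosePlane(origin=np.array(origin), spacing=np.array(spacing),
                     values=values, depth=depth)


def _grid_to_sitk(grid: DoseGrid) -> sitk.Image:
    # SimpleITK arrays are indexed [z, y, x]
    img = sitk.GetImageFromArray(np.ascontiguousarray(grid.values.T))
    img.SetSpacing(tuple(float(s) for s in grid.spacing))
    img.SetOrigin(tuple(float(o) for o in grid.origin))
    return img


def write_volume_mhd(grid: DoseGrid, path) -> None:
    """Write a dose volume as MetaImage (.mhd header + .raw payload)."""
    sitk.WriteImage(_grid_to_sitk(grid), str(path))


def read_volume_mhd(path) -> DoseGrid:
    img = sitk.ReadImage(str(path))
    values = sitk.GetArrayFromImage(img).T  # back to [x, y, z]
    return DoseGrid(origin=np.array(img.GetOrigin()),
                    spacing=np.array(img.GetSpacing()),
                    values=np.asarray(values, dtype=float))


def write_stl(mesh: trimesh.Trimesh, path, ascii: bool = False) -> None:
    """Export a mesh as STL, units mm (binary unless ``ascii``)."""
    path = Path(path)
    mesh.export(path, file_type="stl_ascii" if ascii else "stl")


def read_stl(path) -> trimesh.Trimesh:
    """Load an STL and rebuild per-cell connectivity.

    STL stores an unindexed triangle soup, so vertices are first merged to
    recover shared edges and the mesh is then split into face-adjacency
    components (the per-aperture cells, which touch only at corner points)
    so each component is closed again.
    """
    m = trimesh.load_mesh(str(path))
    parts = m.split(only_watertight=False)
    if len(parts) <= 1:
        return m
    return trimesh.util.concatenate(list(parts))


def write_layout_csv(holes, path) -> None:
    """Aperture layout table: row, col, x, y, tilt_x, tilt_y (mm / degrees)."""
    df = pd.DataFrame([{
        "row": h.row_index, "col": h.col_index,
        "x_mm": h.center[0], "y_mm": h.center[1],
        "tilt_x_deg": h.tilt_x, "tilt_y_deg": h.tilt_y,
    } for h in holes])
    df.to_csv(path, index=False)


def write_dicom_dose(grid: DoseGrid, path, dose_scaling: float | None = None) -> None:
    """Write a minimal DICOM-RT Dose object (GRIDS of physical dose, Gy).

    Dose is stored as 32-bit integers with a DoseGridScaling chosen to span
    the grid's range unless given explicitly.
    """
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import generate_uid, ExplicitVRLittleEndian

    if dose_scaling is None:
        mx = float(grid.values.max())
        dose_scaling = (mx / (2 ** 31 - 1)) if mx > 0 else 1.0
    pixel = np.round(grid.values.T / dose_scaling).astype(np.uint32)  # [z, y, x]

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.RTDoseStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    now = datetime.datetime.now()
    ds.ContentDate = now.strftime("%Y%m%d")
    ds.ContentTime = now.strftime("%H%M%S")
    ds.Modality = "RTDOSE"
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    ds.PatientName = "protongrid^phantom"
    ds.PatientID = "protongrid"
    ds.StudyInstanceUID = generate_uid()
    ds.SeriesInstanceUID = generate_uid()
    ds.FrameOfReferenceUID = generate_uid()
    nz = grid.values.shape[2]
    ds.NumberOfFrames = nz
    ds.Rows = grid.values.shape[1]
    ds.Columns = grid.values.shape[0]
    ds.PixelSpacing = [float(grid.spacing[1]), float(grid.spacing[0])]
    ds.ImagePositionPatient = [float(grid.origin[0]), float(grid.origin[1]),
                               float(grid.origin[2])]
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.GridFrameOffsetVector = [float(k * grid.spacing[2]) for k in range(nz)]
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    ds.DoseGridScaling = float(dose_scaling)
    ds.PixelData = pixel.tobytes()
    pydicom.dcmwrite(str(path), ds, enforce_file_format=True)


def read_dicom_dose(path) -> DoseGrid:
    import pydicom

    ds = pydicom.dcmread(str(path))
    if getattr(ds, "Modality", "") != "RTDOSE":
        raise ValueError("not an RT Dose object")
    scaling = float(getattr(ds, "DoseGridScaling", 1.0))
    arr = ds.pixel_array.astype(float) * scaling   # [frames, rows, cols]
    if arr.ndim == 2:
        arr = arr[None]
    values = arr.T  # -> [x, y, z]
    offsets = np.asarray([float(v) for v in ds.GridFrameOffsetVector]) \
        if "GridFrameOffsetVector" in ds else np.array([0.0])
    dz = float(offsets[1] - offsets[0]) if len(offsets) > 1 else 1.0
    origin = np.array([float(ds.ImagePositionPatient[0]),
                       float(ds.ImagePositionPatient[1]),
                       float(ds.ImagePositionPatient[2])])
    spacing = np.array([float(ds.PixelSpacing[1]), float(ds.PixelSpacing[0]), dz])
    return DoseGrid(origin=origin, spacing=spacing, values=values)
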