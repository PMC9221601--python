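"""Optional DICOM-RT adapter: RT-DOSE grids and RT-STRUCT contour masks.

Isolated so the core package never depends on DICOM input; everything here
converts to the plain :class:`~dvhlasso.dvh.DoseGrid` /
:class:`~dvhlasso.dvh.StructureMask` containers.
"""

from __future__ import annotations

import numpy as np

from .dvh import DoseGrid, StructureMask

__all__ = ["read_rt_dose", "read_rt_struct", "rasterize_contours"]


def read_rt_dose(path) -> DoseGrid:
    """Read an RT-DOSE file into a DoseGrid (dose in Gy).

    Applies DoseGridScaling to the stored pixel array; spacing comes from
    PixelSpacing and the GridFrameOffsetVector (assumed uniform).
    """
    import pydicom

    ds = pydicom.dcmread(path)
    if getattr(ds, "Modality", "") != "RTDOSE":
        raise ValueError(f"{path}: not an RT-DOSE file")
    values = ds.pixel_array.astype(float) * float(ds.DoseGridScaling)
    if values.ndim == 2:
        values = values[None]
    offsets = np.asarray(ds.GridFrameOffsetVector, dtype=float)
    dz = float(abs(offsets[1] - offsets[0])) if offsets.size > 1 else 1.0
    dy, dx = (float(v) for v in ds.PixelSpacing)
    return DoseGrid(values, (dz, dy, dx))


def rasterize_contours(contours, shape, origin, spacing) -> StructureMask:
    """Rasterize planar contours to a voxel mask by even-odd polygon fill.

    ``contours`` is an iterable of (N, 3) arrays of (x, y, z) points in mm,
    each lying on one axial slice; overlapping polygons on a slice toggle
    membership (XOR), which realises the even-odd rule for holes.
    ``origin`` is the (z, y, x) position in mm of voxel (0, 0, 0) and
    ``spacing`` the (dz, dy, dx) voxel size in mm.
    """
    from matplotlib.path import Path as MplPath

    nz, ny, nx = shape
    oz, oy, ox = origin
    dz, dy, dx = spacing
    mask = np.zeros(shape, dtype=bool)
    ys = oy + dy * np.arange(ny)
    xs = ox + dx * np.arange(nx)
    xx, yy = np.meshgrid(xs, ys)
    points = np.column_stack([xx.ravel(), yy.ravel()])
    for contour in contours:
        pts = np.asarray(contour, dtype=float).reshape(-1, 3)
        k = int(round((pts[0, 2] - oz) / dz))
        if not 0 <= k < nz:
            continue
        inside = MplPath(pts[:, :2]).contains_points(points).reshape(ny, nx)
        mask[k] ^= inside
    if not mask.any():
        raise ValueError("contours rasterized to an empty mask")
    return StructureMask(mask)


def read_rt_struct(path, roi_name: str, grid_shape, origin, spacing
                   ) -> StructureMask:
    """Read one named ROI from an RT-STRUCT file onto the given dose lattice."""
    import pydicom

    ds = pydicom.dcmread(path)
    if getattr(ds, "Modality", "") != "RTSTRUCT":
        raise ValueError(f"{path}: not an RT-STRUCT file")
    numbers = {roi.ROIName: roi.ROINumber for roi in ds.StructureSetROISequence}
    if roi_name not in numbers:
        raise ValueError(f"ROI {roi_name!r} not found; available: {sorted(numbers)}")
    target = numbers[roi_name]
    contours = []
    for roi_contour in ds.ROIContourSequence:
        if roi_contour.ReferencedROINumber != target:
            continue
        for c in getattr(roi_contour, "ContourSequence", []):
            contours.append(np.asarray(c.ContourData, dtype=float).reshape(-1, 3))
    if not contours:
        raise ValueError(f"ROI {roi_name!r} has no contour data")
    return rasterize_contours(contours, grid_shape, origin, spacing)
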