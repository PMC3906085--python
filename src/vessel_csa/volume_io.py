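"""Volumetric image and mesh I/O with the coordinate conventions used package-wide.

Conventions
-----------
* Intensities are Hounsfield Units (HU): water ~ 0, air ~ -1000.
* ``Volume.data`` is indexed ``[i, j, k]`` along world x, y, z.
* The world coordinate of voxel index ``i`` is ``origin + i * spacing``
  (voxel-center convention, right-handed axes, all geometry in mm).
* Raw volumes require an explicit JSON sidecar header; nothing is guessed.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import trimesh

__all__ = [
    "Volume",
    "LabelMask",
    "read_volume",
    "write_volume",
    "write_mesh",
    "read_mesh",
]

LABEL_BACKGROUND = 0
LABEL_LUMEN = 1
LABEL_CALCIFIC = 2


@dataclass
class Volume:
    """A 3D scalar grid in HU with anisotropic spacing and a world origin."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_order: str = "xyz"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3D, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 strictly positive values, got {self.spacing}")
        if self.axis_order != "xyz":
            raise ValueError("only 'xyz' axis order is supported")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def world_coordinates(self, indices: np.ndarray) -> np.ndarray:
        """Map (possibly fractional) voxel indices to world mm coordinates."""
        return np.asarray(self.origin) + np.asarray(indices, dtype=float) * np.asarray(self.spacing)

    def index_coordinates(self, points: np.ndarray) -> np.ndarray:
        """Map world mm coordinates to fractional voxel indices."""
        return (np.asarray(points, dtype=float) - np.asarray(self.origin)) / np.asarray(self.spacing)

    def copy_with(self, data: np.ndarray) -> "Volume":
        if data.shape != self.data.shape:
            raise ValueError("replacement data must match grid shape")
        return Volume(data, self.spacing, self.origin)


@dataclass
class LabelMask:
    """Integer label grid aligned with a parent :class:`Volume`.

    Codes: 0 background, 1 lumen, 2 calcific.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    allowed_labels: frozenset = field(default_factory=lambda: frozenset({0, 1, 2}))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("LabelMask data must be 3D")
        if not np.issubdtype(self.data.dtype, np.integer):
            if np.issubdtype(self.data.dtype, np.bool_):
                self.data = self.data.astype(np.uint8)
            else:
                raise ValueError("LabelMask data must be integer or boolean")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        present = set(np.unique(self.data).tolist())
        if not present <= set(self.allowed_labels):
            raise ValueError(f"labels {present - set(self.allowed_labels)} outside allowed set")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def same_grid(self, other) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    @property
    def lumen(self) -> np.ndarray:
        return self.data == LABEL_LUMEN

    @property
    def calcific(self) -> np.ndarray:
        return self.data == LABEL_CALCIFIC


# ---------------------------------------------------------------------------
# volume reading


def _detect_format(path: str) -> str:
    if os.path.isdir(path):
        return "dicom-series"
    lower = path.lower()
    if lower.endswith((".nii", ".nii.gz")):
        return "nifti"
    if lower.endswith(".raw"):
        return "raw"
    raise ValueError(
        f"cannot infer format of {path!r}; supported: dicom-series (directory), "
        "nifti (.nii/.nii.gz), raw (.raw + .json sidecar)"
    )


def read_volume(path: str, format: str | None = None) -> Volume:
    """Read a volumetric image as HU.

    Supports a DICOM series directory, a NIfTI-1 file, or a raw binary file
    with a mandatory JSON sidecar (``<path>.json`` holding shape, dtype,
    spacing, optional origin).
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    fmt = format or _detect_format(path)
    if fmt == "nifti":
        return _read_nifti(path)
    if fmt == "dicom-series":
        return _read_dicom_series(path)
    if fmt == "raw":
        return _read_raw(path)
    raise ValueError(f"unsupported format {fmt!r}; supported: dicom-series, nifti, raw")


def _read_nifti(path: str) -> Volume:
    img = nib.load(path)
    data = np.asanyarray(img.dataobj).astype(np.float32)
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise ValueError(f"missing or non-positive voxel spacing in {path}: {zooms}")
    origin = tuple(float(x) for x in img.affine[:3, 3])
    return Volume(data, tuple(float(z) for z in zooms), origin)


def _read_dicom_series(path: str) -> Volume:
    import pydicom

    files = sorted(
        os.path.join(path, f)
        for f in os.listdir(path)
        if not f.startswith(".") and os.path.isfile(os.path.join(path, f))
    )
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(f)
        except Exception:
            continue
        if hasattr(ds, "PixelData"):
            slices.append(ds)
    if not slices:
        raise ValueError(f"no DICOM image slices found in {path}")
    uids = {getattr(s, "SeriesInstanceUID", None) for s in slices}
    if len(uids) > 1:
        raise ValueError(f"directory {path} mixes {len(uids)} DICOM series; expected one")

    first = slices[0]
    try:
        px = [float(x) for x in first.PixelSpacing]
    except Exception as exc:
        raise ValueError(f"missing PixelSpacing in DICOM series {path}") from exc
    for s in slices[1:]:
        if not np.allclose([float(x) for x in s.PixelSpacing], px):
            raise ValueError("non-uniform in-plane PixelSpacing across series")

    # slice order from ImagePositionPatient projected on the slice normal,
    # never from InstanceNumber
    orient = np.array([float(x) for x in first.ImageOrientationPatient], dtype=float)
    row, col = orient[:3], orient[3:]
    normal = np.cross(row, col)
    positions = np.array(
        [[float(x) for x in s.ImagePositionPatient] for s in slices], dtype=float
    )
    proj = positions @ normal
    order = np.argsort(proj, kind="stable")
    slices = [slices[i] for i in order]
    proj = proj[order]

    if len(slices) > 1:
        gaps = np.diff(proj)
        if np.any(gaps <= 0):
            raise ValueError("duplicate slice positions in DICOM series")
        if (gaps.max() - gaps.min()) > 0.01 * gaps.mean():
            bad = int(np.argmax(np.abs(gaps - gaps.mean())))
            raise ValueError(
                f"non-uniform slice gap between slices {bad} and {bad + 1}: "
                f"{gaps[bad]:.4f} mm vs mean {gaps.mean():.4f} mm"
            )
        dz = float(gaps.mean())
    else:
        dz = float(getattr(first, "SliceThickness", 0) or 0)
        if dz <= 0:
            raise ValueError("single-slice series without SliceThickness: spacing ambiguous")

    planes = []
    for s in slices:
        arr = s.pixel_array.astype(np.float32)
        slope = float(getattr(s, "RescaleSlope", 1.0))
        intercept = float(getattr(s, "RescaleIntercept", 0.0))
        planes.append(arr * slope + intercept)
    # pixel_array is rows(y) x cols(x); transpose to (x, y) then stack along z
    data = np.stack([p.T for p in planes], axis=-1)
    origin = tuple(float(x) for x in slices[0].ImagePositionPatient)
    # PixelSpacing is (row spacing, col spacing) = (dy, dx)
    return Volume(data, (px[1], px[0], dz), origin)


def _read_raw(path: str) -> Volume:
    sidecar = path + ".json"
    if not os.path.exists(sidecar):
        raise ValueError(
            f"raw volume {path} requires an explicit sidecar header {sidecar} "
            "(keys: shape, dtype, spacing, optional origin); refusing to guess"
        )
    with open(sidecar) as fh:
        hdr = json.load(fh)
    for key in ("shape", "dtype", "spacing"):
        if key not in hdr:
            raise ValueError(f"sidecar {sidecar} missing required key {key!r}")
    shape = tuple(int(n) for n in hdr["shape"])
    data = np.fromfile(path, dtype=np.dtype(hdr["dtype"])).reshape(shape)
    return Volume(
        data.astype(np.float32),
        tuple(hdr["spacing"]),
        tuple(hdr.get("origin", (0.0, 0.0, 0.0))),
    )


# ---------------------------------------------------------------------------
# volume writing


def write_volume(v: Volume, path: str, format: str | None = None) -> str:
    """Write ``v`` so that :func:`read_volume` reproduces data, spacing, origin."""
    fmt = format
    if fmt is None:
        lower = path.lower()
        if lower.endswith((".nii", ".nii.gz")):
            fmt = "nifti"
        elif lower.endswith(".raw"):
            fmt = "raw"
        else:
            raise ValueError(
                f"cannot infer output format of {path!r}; supported: nifti, raw"
            )
    if fmt == "nifti":
        affine = np.diag(list(v.spacing) + [1.0])
        affine[:3, 3] = v.origin
        img = nib.Nifti1Image(np.asarray(v.data, dtype=np.float32), affine)
        img.header.set_zooms(v.spacing)
        nib.save(img, path)
    elif fmt == "raw":
        arr = np.ascontiguousarray(v.data, dtype=np.float32)
        arr.tofile(path)
        with open(path + ".json", "w") as fh:
            json.dump(
                {
                    "shape": list(arr.shape),
                    "dtype": str(arr.dtype),
                    "spacing": list(v.spacing),
                    "origin": list(v.origin),
                },
                fh,
                indent=1,
            )
    else:
        raise ValueError(f"unsupported volume format {fmt!r}; supported: nifti, raw")
    return path


def write_mask(mask: LabelMask, path: str) -> str:
    """Write a label mask as a NIfTI label volume (uint8)."""
    affine = np.diag(list(mask.spacing) + [1.0])
    affine[:3, 3] = mask.origin
    img = nib.Nifti1Image(mask.data.astype(np.uint8), affine)
    img.header.set_zooms(mask.spacing)
    nib.save(img, path)
    return path


def read_mask(path: str) -> LabelMask:
    img = nib.load(path)
    data = np.rint(np.asanyarray(img.dataobj)).astype(np.uint8)
    zooms = img.header.get_zooms()[:3]
    origin = tuple(float(x) for x in img.affine[:3, 3])
    return LabelMask(data, tuple(float(z) for z in zooms), origin)


# ---------------------------------------------------------------------------
# mesh I/O

_MESH_FORMATS = ("obj", "stl", "ply")


def write_mesh(m: trimesh.Trimesh, path: str, format: str | None = None) -> str:
    """Write a surface mesh with vertices in world mm units."""
    if m.faces.shape[0] < 1:
        raise ValueError("refusing to write an empty mesh (no faces)")
    fmt = format or os.path.splitext(path)[1].lstrip(".").lower()
    if fmt not in _MESH_FORMATS:
        raise ValueError(f"unsupported mesh format {fmt!r}; supported: {_MESH_FORMATS}")
    m.export(path, file_type=fmt)
    return path


def read_mesh(path: str) -> trimesh.Trimesh:
    loaded = trimesh.load_mesh(path)
    if isinstance(loaded, trimesh.Scene):
        geoms = list(loaded.geometry.values())
        if len(geoms) != 1:
            warnings.warn(f"{path} holds {len(geoms)} geometries; concatenating")
        loaded = trimesh.util.concatenate(geoms)
    return loaded
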