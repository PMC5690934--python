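"""Reading and writing volumes, displacement fields, and label masks.

Supported containers: NIfTI (``.nii``, ``.nii.gz``) via nibabel and
MetaImage (``.mha``, ``.mhd``) via SimpleITK.  Displacement fields are
stored as 3-component voxel data with an explicit header tag recording the
direction convention (``target_to_source``: the field lives on the SOT grid
and maps SOT world points into EOT space).  Fields declared in the opposite
convention are inverted at load time.

Masks travel as a single integer label volume (0 = background) with a
sidecar JSON name-to-label map.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import SimpleITK as sitk

from .grid import ImageGrid, ROIMask, ScalarVolume, VectorField, invert_field

__all__ = [
    "save_volume",
    "load_volume",
    "save_field",
    "load_field",
    "save_masks",
    "load_masks",
    "FIELD_CONVENTION",
]

#: Header value marking the package-native field direction.
FIELD_CONVENTION = "target_to_source"

_NIFTI_EXT = (".nii", ".nii.gz")
_META_EXT = (".mha", ".mhd")


def _is_nifti(path: Path) -> bool:
    return path.name.endswith(_NIFTI_EXT)


def _is_meta(path: Path) -> bool:
    return path.suffix in _META_EXT


def _affine(grid: ImageGrid) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(grid.spacing)
    aff[:3, 3] = grid.origin
    return aff


def _grid_from_affine(aff: np.ndarray, shape) -> ImageGrid:
    if not np.allclose(aff[:3, :3], np.diag(np.diag(aff[:3, :3]))):
        raise ValueError("only axis-aligned grids are supported")
    return ImageGrid(
        shape=tuple(shape[:3]),
        spacing=tuple(np.diag(aff[:3, :3])),
        origin=tuple(aff[:3, 3]),
    )


def _to_sitk(arr: np.ndarray, grid: ImageGrid, vector: bool = False) -> sitk.Image:
    # SimpleITK array layout is (z, y, x); our arrays are (x, y, z[, c]).
    if vector:
        img = sitk.GetImageFromArray(np.transpose(arr, (2, 1, 0, 3)), isVector=True)
    else:
        img = sitk.GetImageFromArray(np.transpose(arr, (2, 1, 0)))
    img.SetSpacing(grid.spacing)
    img.SetOrigin(grid.origin)
    return img


def _from_sitk(img: sitk.Image) -> tuple[np.ndarray, ImageGrid]:
    arr = sitk.GetArrayFromImage(img)
    if arr.ndim == 4:
        arr = np.transpose(arr, (2, 1, 0, 3))
    else:
        arr = np.transpose(arr, (2, 1, 0))
    direction = np.asarray(img.GetDirection()).reshape(3, 3)
    if not np.allclose(direction, np.eye(3)):
        raise ValueError("non-identity direction cosines are not supported")
    grid = ImageGrid(
        shape=arr.shape[:3],
        spacing=tuple(img.GetSpacing()),
        origin=tuple(img.GetOrigin()),
    )
    return arr, grid


# ---------------------------------------------------------------------------
# scalar volumes


def save_volume(volume: ScalarVolume, path: str | Path) -> None:
    path = Path(path)
    if _is_nifti(path):
        nib.save(nib.Nifti1Image(volume.values, _affine(volume.grid)), str(path))
    elif _is_meta(path):
        sitk.WriteImage(_to_sitk(volume.values, volume.grid), str(path))
    else:
        raise ValueError(f"unsupported volume format: {path.name}")


def load_volume(path: str | Path) -> ScalarVolume:
    path = Path(path)
    if _is_nifti(path):
        img = nib.load(str(path))
        arr = np.asarray(img.dataobj, dtype=float)
        grid = _grid_from_affine(img.affine, arr.shape)
    elif _is_meta(path):
        arr, grid = _from_sitk(sitk.ReadImage(str(path)))
    else:
        raise ValueError(f"unsupported volume format: {path.name}")
    if arr.ndim != 3:
        raise ValueError(f"{path.name} is not a scalar volume")
    return ScalarVolume(grid, arr)


# ---------------------------------------------------------------------------
# vector fields


def save_field(
    field: VectorField, path: str | Path, convention: str = FIELD_CONVENTION
) -> None:
    path = Path(path)
    if _is_nifti(path):
        img = nib.Nifti1Image(field.displacements, _affine(field.grid))
        img.header["descrip"] = f"dvf_convention={convention}".encode()
        nib.save(img, str(path))
    elif _is_meta(path):
        img = _to_sitk(field.displacements, field.grid, vector=True)
        img.SetMetaData("dvf_convention", convention)
        sitk.WriteImage(img, str(path))
    else:
        raise ValueError(f"unsupported field format: {path.name}")


def load_field(path: str | Path, assume_convention: str | None = None) -> VectorField:
    """Load a displacement field, honoring its declared direction convention.

    A field tagged ``source_to_target`` is inverted on load so that every
    in-memory field obeys the package convention.  ``assume_convention``
    overrides a missing header tag.
    """
    path = Path(path)
    convention = None
    if _is_nifti(path):
        img = nib.load(str(path))
        arr = np.asarray(img.dataobj, dtype=float)
        if arr.ndim == 5:  # NIfTI vector convention (x, y, z, 1, 3)
            arr = arr[:, :, :, 0, :]
        grid = _grid_from_affine(img.affine, arr.shape)
        descrip = img.header["descrip"].tobytes().rstrip(b"\x00").decode(errors="ignore")
        if "dvf_convention=" in descrip:
            convention = descrip.split("dvf_convention=")[1].split()[0]
    elif _is_meta(path):
        img = sitk.ReadImage(str(path))
        arr, grid = _from_sitk(img)
        if img.HasMetaDataKey("dvf_convention"):
            convention = img.GetMetaData("dvf_convention")
    else:
        raise ValueError(f"unsupported field format: {path.name}")
    if arr.ndim != 4 or arr.shape[-1] != 3:
        raise ValueError(f"{path.name} is not a 3-component vector field")
    convention = convention or assume_convention or FIELD_CONVENTION
    field = VectorField(grid, arr)
    if convention == FIELD_CONVENTION:
        return field
    if convention == "source_to_target":
        return invert_field(field)
    raise ValueError(f"unknown field convention {convention!r} in {path.name}")


# ---------------------------------------------------------------------------
# masks


def save_masks(masks: dict[str, ROIMask], path: str | Path) -> None:
    """Write masks as one integer label volume plus a JSON name-label map."""
    path = Path(path)
    names = sorted(masks)
    grid = masks[names[0]].grid
    # "external" encloses the organs; write it first so organ labels win.
    order = sorted(names, key=lambda n: (n != "external", n))
    labels = np.zeros(grid.shape, dtype=float)
    label_map = {}
    for i, name in enumerate(order, start=1):
        if masks[name].grid != grid:
            raise ValueError("all masks must share one grid")
        labels[masks[name].membership] = i
        label_map[name] = i
    save_volume(ScalarVolume(grid, labels), path)
    sidecar = path.with_name(path.name.split(".")[0] + "_labels.json")
    sidecar.write_text(json.dumps(label_map, indent=2, sort_keys=True))


def load_masks(path: str | Path) -> dict[str, ROIMask]:
    """Load a label volume written by :func:`save_masks`.

    Any organ painted over the external label is restored as a subset of
    external, mirroring containment in the originals.
    """
    path = Path(path)
    vol = load_volume(path)
    sidecar = path.with_name(path.name.split(".")[0] + "_labels.json")
    label_map = json.loads(sidecar.read_text())
    labels = np.rint(vol.values).astype(int)
    masks = {}
    for name, label in label_map.items():
        member = labels == label
        if name == "external":
            member = labels > 0
        masks[name] = ROIMask(vol.grid, name, member)
    return masks
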