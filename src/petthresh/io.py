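"""Image and model file I/O.

Images and masks travel as NIfTI (spacing from the header) or as
whitespace/comma-delimited numeric text grids with a ``<path>.spacing``
sidecar declaring the pixel size:

    dx = 4.0
    dy = 4.0

Text grids without a sidecar require explicit ``dx``/``dy`` arguments —
spacing is never guessed, because every physical measurement (areas, major
axes) depends on it.  All grids are 0-based and row-major.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import GeometryError
from .imaging import ImageSlice2D, RegionMask
from .models import ThresholdFunctionModel, model_from_config, model_to_config, predefined_model

__all__ = [
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "read_model",
    "write_model",
    "resolve_model",
]

_NIFTI_SUFFIXES = (".nii", ".nii.gz")


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return any(name.endswith(s) for s in _NIFTI_SUFFIXES)


def _read_text_grid(path: Path) -> np.ndarray:
    text = path.read_text()
    delimiter = "," if "," in text.splitlines()[0] else None
    return np.atleast_2d(np.loadtxt(path, delimiter=delimiter))


def _read_sidecar(path: Path) -> tuple[float, float] | None:
    sidecar = path.with_name(path.name + ".spacing")
    if not sidecar.exists():
        return None
    fields: dict[str, float] = {}
    for line in sidecar.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or "=" not in line:
            continue
        key, _, value = line.partition("=")
        fields[key.strip()] = float(value)
    try:
        return fields["dx"], fields["dy"]
    except KeyError as exc:
        raise GeometryError(f"sidecar {sidecar} must declare dx and dy") from exc


def _load_grid(
    path: str | Path,
    dx: float | None,
    dy: float | None,
    slice_index: int | None,
) -> tuple[np.ndarray, float, float]:
    path = Path(path)
    if _is_nifti(path):
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        zooms = img.header.get_zooms()
        if data.ndim == 3:
            if slice_index is None:
                if data.shape[2] != 1:
                    raise GeometryError(
                        f"{path} is a volume with {data.shape[2]} slices; "
                        "pass slice_index"
                    )
                slice_index = 0
            data = data[:, :, int(slice_index)]
        elif data.ndim != 2:
            raise GeometryError(f"{path}: expected a 2D slice or 3D volume")
        return np.asarray(data, dtype=float), float(zooms[0]), float(zooms[1])
    data = _read_text_grid(path)
    if dx is None or dy is None:
        spacing = _read_sidecar(path)
        if spacing is None:
            raise GeometryError(
                f"{path}: text grids carry no spacing; provide dx/dy or a "
                f"'{path.name}.spacing' sidecar"
            )
        dx, dy = spacing
    return data, float(dx), float(dy)


def read_image(
    path: str | Path,
    dx: float | None = None,
    dy: float | None = None,
    slice_index: int | None = None,
) -> ImageSlice2D:
    """Read a PET/CT slice from NIfTI or a delimited text grid."""
    data, dx, dy = _load_grid(path, dx, dy, slice_index)
    return ImageSlice2D(data, dx=dx, dy=dy)


def read_mask(
    path: str | Path,
    slice_index: int | None = None,
) -> RegionMask:
    """Read a 0/1 mask from NIfTI or a delimited text grid."""
    path = Path(path)
    if _is_nifti(path):
        data, _, _ = _load_grid(path, None, None, slice_index)
    else:
        data = _read_text_grid(path)
    return RegionMask(data > 0.5)


def write_image(path: str | Path, image: ImageSlice2D) -> None:
    """Write a slice as NIfTI (or text grid + spacing sidecar)."""
    path = Path(path)
    if _is_nifti(path):
        affine = np.diag([image.dx, image.dy, 1.0, 1.0])
        nib.save(nib.Nifti1Image(np.asarray(image.values), affine), str(path))
        return
    np.savetxt(path, image.values, fmt="%.6g")
    path.with_name(path.name + ".spacing").write_text(
        f"dx = {image.dx}\ndy = {image.dy}\n"
    )


def write_mask(path: str | Path, mask: RegionMask, dx: float = 1.0, dy: float = 1.0) -> None:
    """Write a mask as 0/1 NIfTI (or text grid)."""
    path = Path(path)
    data = mask.array.astype(np.uint8)
    if _is_nifti(path):
        affine = np.diag([dx, dy, 1.0, 1.0])
        nib.save(nib.Nifti1Image(data, affine), str(path))
        return
    np.savetxt(path, data, fmt="%d")


def read_model(path: str | Path) -> ThresholdFunctionModel:
    return model_from_config(Path(path).read_text())


def write_model(path: str | Path, model: ThresholdFunctionModel) -> None:
    Path(path).write_text(model_to_config(model))


def resolve_model(selector: str) -> ThresholdFunctionModel:
    """Resolve ``predefined:<id>`` or a model-config path to a model."""
    if selector.startswith("predefined:"):
        return predefined_model(int(selector.split(":", 1)[1]))
    return read_model(selector)
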