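"""Image and label I/O: NIfTI, PNG and raw volumes with a JSON sidecar.

The clustering code itself never touches files; everything enters as a
:class:`~wmtfcm.types.TaskData` built here.  Raw binary volumes (the
format real simulated T1 volumes ship in) need a ``<file>.json`` sidecar
declaring ``shape`` and ``dtype``; 3-D volumes are reduced to an axial
slice by index.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .types import Phantom, TaskData

_NIFTI_SUFFIXES = (".nii", ".nii.gz")


def _is_nifti(path: Path) -> bool:
    return path.name.endswith(_NIFTI_SUFFIXES)


def _load_array(path: Path) -> np.ndarray:
    if not path.exists():
        raise IOError(f"no such image file: {path}")
    if _is_nifti(path):
        import nibabel as nib

        return np.asarray(nib.load(str(path)).dataobj, dtype=float)
    if path.suffix.lower() == ".png":
        import imageio.v3 as iio

        return np.asarray(iio.imread(path), dtype=float)
    if path.suffix.lower() == ".raw":
        sidecar = Path(str(path) + ".json")
        if not sidecar.exists():
            raise IOError(f"raw volume {path} needs a sidecar {sidecar}")
        meta = json.loads(sidecar.read_text())
        shape = tuple(meta["shape"])
        data = np.fromfile(path, dtype=np.dtype(meta.get("dtype", "uint8")))
        if data.size != int(np.prod(shape)):
            raise IOError(
                f"raw volume {path}: {data.size} values do not fill shape {shape}"
            )
        return data.reshape(shape).astype(float)
    raise IOError(f"unsupported image format: {path}")


def read_image(
    path: str | Path, slice_index: int | None = None, task_id: str | None = None
) -> TaskData:
    """Read an intensity image (or one axial slice of a volume) as a task.

    ``slice_index`` selects ``volume[:, :, k]`` from a 3-D input; a 2-D
    input is used as-is.
    """
    path = Path(path)
    arr = _load_array(path)
    if arr.ndim == 3:
        if slice_index is None:
            raise IOError(f"{path} is 3-D; pass a slice index")
        arr = arr[:, :, int(slice_index)]
    elif arr.ndim != 2:
        raise IOError(f"{path}: expected a 2-D image or 3-D volume")
    return TaskData.from_image(arr, task_id=task_id or path.stem)


def read_labels(path: str | Path, slice_index: int | None = None) -> np.ndarray:
    """Read an integer label map (same formats as :func:`read_image`)."""
    arr = read_image(path, slice_index=slice_index).to_image()
    labels = np.rint(arr).astype(np.int64)
    return labels


def write_image(path: str | Path, array: np.ndarray) -> None:
    """Write a 2-D array as NIfTI (float32) or 16-bit PNG (rounded)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    array = np.asarray(array)
    if _is_nifti(path):
        import nibabel as nib

        nib.save(nib.Nifti1Image(array.astype(np.float32), affine=np.eye(4)), str(path))
        return
    if path.suffix.lower() == ".png":
        import imageio.v3 as iio

        scaled = np.rint(array)
        if scaled.min() < 0 or scaled.max() > np.iinfo(np.uint16).max:
            raise IOError("PNG output requires values in [0, 65535]")
        iio.imwrite(path, scaled.astype(np.uint16))
        return
    raise IOError(f"unsupported output format: {path}")


def write_labels(path: str | Path, labels: np.ndarray) -> None:
    write_image(path, np.asarray(labels, dtype=np.int64))


def write_phantom(basepath: str | Path, phantom: Phantom, fmt: str = "png") -> dict:
    """Write image + truth + JSON parameter sidecar; returns the paths used.

    PNG intensity output is rounded to integers, so exact round-trips
    need integer class means (the defaults are integers).
    """
    base = Path(basepath)
    ext = ".nii" if fmt == "nii" else ".png"
    paths = {
        "image": base.with_name(base.name + "_image" + ext),
        "truth": base.with_name(base.name + "_truth" + ext),
        "params": base.with_name(base.name + "_params.json"),
    }
    write_image(paths["image"], phantom.image)
    write_labels(paths["truth"], phantom.truth)
    paths["params"].parent.mkdir(parents=True, exist_ok=True)
    paths["params"].write_text(json.dumps(phantom.params, indent=2))
    return {k: str(v) for k, v in paths.items()}
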