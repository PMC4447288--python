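"""SUV volume and normal-model I/O.

The in-memory currency of the pipeline is :class:`SuvVolume`: a 3D grid of
standardized uptake values (SUV, dimensionless) with voxel spacing in mm.

Internal axis convention (fixed throughout the package):

* axis 0 = x, patient left -> right   ("sagittal" planes are fixed-x slices)
* axis 1 = y, anterior -> posterior   ("coronal"  planes are fixed-y slices)
* axis 2 = z, inferior -> superior    ("axial"    planes are fixed-z slices)

All indices are 0-based; a detected "plane" is a voxel index on its axis.

Volumes are persisted as NIfTI (via nibabel) with an affine that encodes the
convention above, so files written here reload identically and files from
other tools are reoriented on read. Normal models are persisted as a single
versioned ZIP archive holding two NIfTI grids (mean, SD) plus a JSON metadata
sidecar; serialization is deterministic so identical models produce
byte-identical archives.
"""

from __future__ import annotations

import io as _stdio
import json
import zipfile
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import TYPE_CHECKING

import nibabel as nib
import numpy as np

from .errors import ModelFormatError, ValidationError, VolumeFormatError

if TYPE_CHECKING:  # pragma: no cover - import cycle guard
    from .model import NormalUptakeResults

AXES_TAG = "RPS"  # x: ->right, y: ->posterior, z: ->superior

MODEL_FORMAT = "torsonorm-normal-model"
MODEL_VERSION = 1


@dataclass
class SuvVolume:
    """A 3D SUV grid with voxel spacing in mm.

    Parameters
    ----------
    data : ndarray
        3D array of SUV values; stored as float32. All values must be finite
        and non-negative.
    spacing : tuple of float
        Per-axis voxel size in mm, strictly positive.
    sex : {"male", "female", "unknown"}
        Sex tag of the scanned subject; standardization refuses to mix sexes.
    id : str
        Scan identifier.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    sex: str = "unknown"
    id: str = ""
    axes: str = AXES_TAG
    suv_normalization: str = "body_weight"

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise VolumeFormatError(f"volume must be 3D, got {arr.ndim}D")
        if any(s < 2 for s in arr.shape):
            raise ValidationError(f"grid needs >= 2 voxels per axis, got {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValidationError("volume contains non-finite values")
        n_neg = int(np.count_nonzero(arr < 0))
        if n_neg:
            raise ValidationError(f"volume contains {n_neg} negative voxels")
        self.data = np.ascontiguousarray(arr, dtype=np.float32)
        sp = tuple(float(s) for s in self.spacing)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise ValidationError(f"spacing must be 3 positive values, got {self.spacing}")
        self.spacing = sp
        if self.sex not in ("male", "female", "unknown"):
            raise ValidationError(f"sex must be male/female/unknown, got {self.sex!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def with_data(self, data: np.ndarray) -> "SuvVolume":
        return replace(self, data=data)


def _internal_affine(spacing: tuple[float, float, float]) -> np.ndarray:
    # axis0 -> +R, axis1 -> -A (i.e. anterior->posterior), axis2 -> +S
    sx, sy, sz = spacing
    return np.diag([sx, -sy, sz, 1.0])


def write_volume(volume: SuvVolume, path: str | Path) -> None:
    """Write a volume as NIfTI (.nii or .nii.gz)."""
    img = nib.Nifti1Image(volume.data.astype(np.float32), _internal_affine(volume.spacing))
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def read_volume(path: str | Path, sex: str = "unknown", id: str | None = None) -> SuvVolume:
    """Read a NIfTI volume and reorient it to the internal axis convention.

    Raises
    ------
    FileNotFoundError
        If the path does not exist.
    VolumeFormatError
        If the image is not 3D.
    ValidationError
        If voxels are negative or non-finite (the count is reported).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    img = nib.load(str(path))
    shape = img.header.get_data_shape()
    if len(shape) == 4 and shape[3] == 1:
        pass  # tolerated: squeezed below
    elif len(shape) != 3:
        raise VolumeFormatError(f"expected a 3D image, got shape {shape}")
    canonical = nib.as_closest_canonical(img)  # RAS+
    data = np.asanyarray(canonical.dataobj, dtype=np.float32)
    data = np.squeeze(data)
    if data.ndim != 3:
        raise VolumeFormatError(f"expected a 3D image, got shape {data.shape}")
    # RAS -> internal RPS: flip axis 1 (posterior->anterior becomes anterior->posterior)
    data = data[:, ::-1, :]
    zooms = canonical.header.get_zooms()[:3]
    return SuvVolume(
        data=data,
        spacing=tuple(float(z) for z in zooms),
        sex=sex,
        id=id if id is not None else path.name,
    )


def suv_convert(
    activity: np.ndarray,
    injected_dose: float,
    body_mass: float,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    sex: str = "unknown",
    id: str = "",
) -> SuvVolume:
    """Convert a raw activity-concentration grid to body-weight SUV.

    SUV = activity [kBq/mL] * body mass [g] / injected dose [kBq], i.e. the
    tissue concentration normalized by the average whole-body concentration.
    With ``injected_dose`` in MBq and ``body_mass`` in kg the two factors of
    1000 cancel, giving ``activity * body_mass / injected_dose``.
    """
    if injected_dose <= 0:
        raise ValidationError(f"injected_dose must be > 0, got {injected_dose}")
    if body_mass <= 0:
        raise ValidationError(f"body_mass must be > 0, got {body_mass}")
    suv = np.asarray(activity, dtype=np.float64) * (body_mass / injected_dose)
    return SuvVolume(data=suv, spacing=spacing, sex=sex, id=id,
                     suv_normalization="body_weight")


# ---------------------------------------------------------------------------
# Normal-model archive

def _nifti_bytes(arr: np.ndarray, spacing: tuple[float, float, float]) -> bytes:
    img = nib.Nifti1Image(np.ascontiguousarray(arr, dtype=np.float32),
                          _internal_affine(spacing))
    img.header.set_zooms(spacing)
    return img.to_bytes()


def _nifti_from_bytes(raw: bytes) -> np.ndarray:
    img = nib.Nifti1Image.from_bytes(raw)
    canonical = nib.as_closest_canonical(img)
    data = np.asanyarray(canonical.dataobj, dtype=np.float32)
    return data[:, ::-1, :]


def save_model(model: "NormalUptakeResults", path: str | Path) -> None:
    """Persist a fitted normal model as a deterministic versioned archive.

    The archive contains ``mean.nii``, ``sd.nii``, ``valid.nii`` and
    ``meta.json``; entries are written in a fixed order with fixed timestamps
    so two saves of the same model are byte-identical.
    """
    meta = {
        "format": MODEL_FORMAT,
        "version": MODEL_VERSION,
        "n": int(model.n),
        "sex": model.sex,
        "spacing": list(model.spacing),
        "grid_shape": list(model.mean.shape),
        "standard": model.standard_meta,
        "software": "torsonorm 0.1.0",
    }
    entries = [
        ("meta.json", json.dumps(meta, sort_keys=True, indent=1).encode()),
        ("mean.nii", _nifti_bytes(model.mean, model.spacing)),
        ("sd.nii", _nifti_bytes(model.sd, model.spacing)),
        ("valid.nii", _nifti_bytes(model.valid.astype(np.float32), model.spacing)),
    ]
    with zipfile.ZipFile(str(path), "w", compression=zipfile.ZIP_DEFLATED) as zf:
        for name, payload in entries:
            info = zipfile.ZipInfo(name, date_time=(1980, 1, 1, 0, 0, 0))
            info.compress_type = zipfile.ZIP_DEFLATED
            info.external_attr = 0o644 << 16
            zf.writestr(info, payload)


def load_model(path: str | Path) -> "NormalUptakeResults":
    """Load a normal model saved by :func:`save_model`.

    Raises :class:`ModelFormatError` on truncation or version mismatch; never
    returns a partial model.
    """
    from .model import NormalUptakeResults

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such model archive: {path}")
    try:
        with zipfile.ZipFile(str(path)) as zf:
            meta = json.loads(zf.read("meta.json"))
            if meta.get("format") != MODEL_FORMAT:
                raise ModelFormatError(f"not a normal-model archive: {path}")
            if meta.get("version") != MODEL_VERSION:
                raise ModelFormatError(
                    f"model version {meta.get('version')} incompatible with "
                    f"reader version {MODEL_VERSION}")
            mean = _nifti_from_bytes(zf.read("mean.nii"))
            sd = _nifti_from_bytes(zf.read("sd.nii"))
            valid = _nifti_from_bytes(zf.read("valid.nii")) > 0.5
    except (zipfile.BadZipFile, KeyError, json.JSONDecodeError) as exc:
        raise ModelFormatError(f"corrupt model archive {path}: {exc}") from exc
    return NormalUptakeResults(
        mean=mean, sd=sd, valid=valid, n=int(meta["n"]), sex=meta["sex"],
        spacing=tuple(meta["spacing"]), standard_meta=meta.get("standard"),
    )
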