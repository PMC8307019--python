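"""Core data model for magnitude MR images and multi-echo series.

Everything downstream works on 2-D magnitude images: a :class:`ImageFrame`
bundles one pixel matrix with the acquisition metadata that the biomarker
arms need (echo time, field strength, sequence role), and an
:class:`EchoSeries` is an ordered multi-echo stack of frames sharing
geometry.  I/O covers DICOM series directories (via pydicom) and NIfTI
volumes with a JSON sidecar carrying echo times (via nibabel).

Coordinates are 0-based ``(row, col)``, row-major, throughout the package.
Complex or phase data are never represented.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path

import numpy as np
import nibabel as nib
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .config import BASE_ECHO_SPACING_MS, SUPPORTED_FIELDS_T, TE_TOLERANCE_MS

__all__ = [
    "Role",
    "ImageFrame",
    "EchoSeries",
    "classify_phase",
    "read_series",
    "write_series",
    "read_frame",
    "write_frame",
]


class Role(str, Enum):
    """Sequence role of a magnitude image."""

    T1_MAP = "T1_MAP"
    IN_PHASE = "IN_PHASE"
    OPPOSED_PHASE = "OPPOSED_PHASE"
    FAT_ONLY = "FAT_ONLY"
    WATER_ONLY = "WATER_ONLY"


class MetadataError(ValueError):
    """Required acquisition metadata is missing or inconsistent."""


def classify_phase(te_ms: float, field_t: float) -> Role:
    """Classify an echo time as in-phase or opposed-phase.

    Water and fat magnetisation realign every other echo of the base
    spacing (2.4 ms at 1.5 T, 1.2 ms at 3 T): odd multiples of the base
    spacing are opposed-phase, even multiples in-phase.

    Parameters
    ----------
    te_ms : float
        Echo time in milliseconds.
    field_t : float
        Main field strength in tesla (1.5 or 3.0).

    Raises
    ------
    ValueError
        If the field is unsupported or ``te_ms`` is not within
        ±0.1 ms of a positive integer multiple of the base spacing.
    """
    if field_t not in BASE_ECHO_SPACING_MS:
        raise ValueError(f"unsupported field strength: {field_t} T")
    base = BASE_ECHO_SPACING_MS[field_t]
    k = round(te_ms / base)
    if k < 1 or abs(te_ms - k * base) > TE_TOLERANCE_MS:
        raise ValueError(
            f"TE={te_ms} ms is not a multiple of the {base} ms base echo "
            f"spacing at {field_t} T (tolerance {TE_TOLERANCE_MS} ms)"
        )
    return Role.OPPOSED_PHASE if k % 2 == 1 else Role.IN_PHASE


@dataclass
class ImageFrame:
    """One 2-D magnitude MR image plus acquisition metadata.

    Attributes
    ----------
    pixels : ndarray
        2-D non-negative matrix in arbitrary units.
    te_ms : float or None
        Echo time in ms; ``None`` for parameter maps (T1 maps).
    field_t : float
        Main field strength in tesla (1.5 or 3.0).
    role : Role
        Sequence role of the frame.
    pixel_spacing_mm : tuple of float
        (row, col) spacing in millimetres.
    """

    pixels: np.ndarray
    field_t: float
    role: Role
    te_ms: float | None = None
    pixel_spacing_mm: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D matrix")
        if np.any(self.pixels < 0):
            raise ValueError("magnitude images cannot contain negative pixels")
        self.role = Role(self.role)
        if self.field_t not in SUPPORTED_FIELDS_T:
            raise ValueError(f"field_t must be one of {SUPPORTED_FIELDS_T}")
        if self.role in (Role.IN_PHASE, Role.OPPOSED_PHASE):
            if self.te_ms is None or self.te_ms <= 0:
                raise ValueError(f"{self.role.value} frames require te_ms > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class EchoSeries:
    """Ordered multi-echo collection of frames sharing geometry.

    Frames are kept sorted by strictly increasing echo time; all frames
    must share matrix dimensions and field strength.
    """

    frames: list[ImageFrame]
    field_t: float
    echo_spacing_ms: float | None = None

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("EchoSeries requires at least one frame")
        shapes = {f.shape for f in self.frames}
        if len(shapes) != 1:
            raise MetadataError(f"mixed matrix sizes in series: {sorted(shapes)}")
        tes = [f.te_ms for f in self.frames]
        if any(t is None for t in tes):
            raise MetadataError("every frame in an EchoSeries needs an echo time")
        if any(b <= a for a, b in zip(tes, tes[1:])):
            raise ValueError("echo times must be strictly increasing")
        if any(f.field_t != self.field_t for f in self.frames):
            raise ValueError("all frames must share the series field strength")
        if self.echo_spacing_ms is None and len(tes) >= 2:
            self.echo_spacing_ms = float(tes[1] - tes[0])

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def te_ms(self) -> np.ndarray:
        return np.array([f.te_ms for f in self.frames], dtype=float)

    @property
    def roles(self) -> list[Role]:
        return [f.role for f in self.frames]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames[0].shape


# ---------------------------------------------------------------------------
# NIfTI I/O: a .nii/.nii.gz volume (rows x cols x echoes) plus a JSON
# sidecar {"te_ms": [...], "field_t": x, "roles": [...]}.
# ---------------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    raise ValueError(f"not a NIfTI path: {path}")


def write_series(series: EchoSeries, path: str | Path) -> Path:
    """Write a series as a NIfTI volume with a JSON metadata sidecar.

    Pixel data are stored as float64, so a read-back reproduces the
    series bit-exactly.  Returns the NIfTI path.
    """
    path = Path(path)
    vol = np.stack([f.pixels for f in series.frames], axis=-1)
    sp = series.frames[0].pixel_spacing_mm
    affine = np.diag([sp[0], sp[1], 1.0, 1.0])
    nib.save(nib.Nifti1Image(vol, affine), str(path))
    meta = {
        "te_ms": [f.te_ms for f in series.frames],
        "field_t": series.field_t,
        "roles": [f.role.value for f in series.frames],
        "pixel_spacing_mm": list(sp),
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def _read_nifti_series(path: Path) -> EchoSeries:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise MetadataError(
            f"missing JSON sidecar with echo times for {path} (expected {sidecar})"
        )
    meta = json.loads(sidecar.read_text())
    if "te_ms" not in meta:
        raise MetadataError(f"sidecar {sidecar} lacks the te_ms list")
    vol = np.asarray(nib.load(str(path)).dataobj, dtype=float)
    if vol.ndim == 2:
        vol = vol[:, :, None]
    if vol.ndim != 3:
        raise MetadataError(f"{path}: expected a 2-D or 3-D volume, got {vol.ndim}-D")
    tes = [float(t) for t in meta["te_ms"]]
    if len(tes) != vol.shape[2]:
        raise MetadataError(
            f"{path}: {vol.shape[2]} echoes in volume but {len(tes)} TEs in sidecar"
        )
    field = float(meta["field_t"])
    roles = meta.get("roles")
    spacing = tuple(meta.get("pixel_spacing_mm", (1.0, 1.0)))
    frames = []
    for i, te in enumerate(tes):
        role = Role(roles[i]) if roles else classify_phase(te, field)
        frames.append(
            ImageFrame(vol[:, :, i], field_t=field, role=role, te_ms=te,
                       pixel_spacing_mm=spacing)
        )
    frames.sort(key=lambda f: f.te_ms)
    return EchoSeries(frames, field_t=field)


# ---------------------------------------------------------------------------
# DICOM I/O: one file per echo.  Pixels are written as 32-bit float
# FloatPixelData; readers fall back to classic integer PixelData with
# RescaleSlope/Intercept for third-party files.
# ---------------------------------------------------------------------------

_MR_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.4"


def _frame_to_dataset(frame: ImageFrame, instance: int, series_uid: str) -> Dataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = _MR_SOP_CLASS
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = _MR_SOP_CLASS
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.SeriesInstanceUID = series_uid
    ds.Modality = "MR"
    ds.SeriesDescription = frame.role.value
    ds.InstanceNumber = instance
    ds.MagneticFieldStrength = frame.field_t
    if frame.te_ms is not None:
        ds.EchoTime = frame.te_ms
    ds.Rows, ds.Columns = frame.shape
    ds.PixelSpacing = [frame.pixel_spacing_mm[0], frame.pixel_spacing_mm[1]]
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 32
    ds.FloatPixelData = frame.pixels.astype("<f4").tobytes()
    return ds


def _dataset_pixels(ds: Dataset, path: Path) -> np.ndarray:
    if "FloatPixelData" in ds:
        arr = np.frombuffer(ds.FloatPixelData, dtype="<f4").astype(float)
        return arr.reshape(int(ds.Rows), int(ds.Columns))
    arr = ds.pixel_array.astype(float)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    return arr * slope + intercept


def _dataset_to_frame(ds: Dataset, path: Path) -> ImageFrame:
    if "EchoTime" not in ds:
        raise MetadataError(f"{path}: DICOM file lacks EchoTime (0018,0081)")
    if "MagneticFieldStrength" not in ds:
        raise MetadataError(f"{path}: DICOM file lacks MagneticFieldStrength (0018,0087)")
    te = float(ds.EchoTime)
    field = float(ds.MagneticFieldStrength)
    desc = str(getattr(ds, "SeriesDescription", ""))
    try:
        role = Role(desc)
    except ValueError:
        role = classify_phase(te, field)
    spacing = tuple(float(s) for s in getattr(ds, "PixelSpacing", (1.0, 1.0)))
    return ImageFrame(np.clip(_dataset_pixels(ds, path), 0, None), field_t=field,
                      role=role, te_ms=te, pixel_spacing_mm=spacing)


def _read_dicom_series(path: Path) -> EchoSeries:
    files = sorted(p for p in path.iterdir() if p.is_file() and p.suffix != ".json")
    if not files:
        raise FileNotFoundError(f"no DICOM files in {path}")
    frames = []
    for p in files:
        ds = pydicom.dcmread(str(p))
        frames.append(_dataset_to_frame(ds, p))
    frames.sort(key=lambda f: f.te_ms)
    return EchoSeries(frames, field_t=frames[0].field_t)


def write_series_dicom(series: EchoSeries, directory: str | Path) -> Path:
    """Write each echo of a series as one DICOM file in ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid()
    for i, frame in enumerate(series.frames, start=1):
        ds = _frame_to_dataset(frame, i, series_uid)
        ds.save_as(str(directory / f"echo_{i:03d}.dcm"), enforce_file_format=True)
    return directory


def read_series(path: str | Path) -> EchoSeries:
    """Read a multi-echo series from a DICOM directory or a NIfTI file.

    A directory is treated as a DICOM series (one file per echo); a
    ``.nii``/``.nii.gz`` file requires a JSON sidecar listing the echo
    times and field strength.  Frames come back sorted by ascending TE
    with pixel data unmodified.
    """
    path = Path(path)
    if path.is_dir():
        return _read_dicom_series(path)
    if path.name.endswith((".nii", ".nii.gz")):
        return _read_nifti_series(path)
    raise ValueError(f"cannot infer series format from {path}")


def write_frame(frame: ImageFrame, path: str | Path) -> Path:
    """Write a single frame as NIfTI + sidecar (TE omitted for maps)."""
    path = Path(path)
    sp = frame.pixel_spacing_mm
    nib.save(nib.Nifti1Image(frame.pixels[:, :, None],
                             np.diag([sp[0], sp[1], 1.0, 1.0])), str(path))
    meta = {
        "field_t": frame.field_t,
        "roles": [frame.role.value],
        "pixel_spacing_mm": list(sp),
    }
    if frame.te_ms is not None:
        meta["te_ms"] = [frame.te_ms]
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_frame(path: str | Path, role: Role | None = None) -> ImageFrame:
    """Read a single 2-D frame from NIfTI (+ sidecar) or a DICOM file.

    ``role`` overrides the stored role; parameter maps (no TE) require
    either a stored role or an explicit one.
    """
    path = Path(path)
    if path.name.endswith((".nii", ".nii.gz")):
        sidecar = _sidecar_path(path)
        meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        vol = np.asarray(nib.load(str(path)).dataobj, dtype=float)
        if vol.ndim == 3:
            if vol.shape[2] != 1:
                raise ValueError(f"{path} holds {vol.shape[2]} frames; use read_series")
            vol = vol[:, :, 0]
        field = float(meta.get("field_t", 3.0))
        tes = meta.get("te_ms")
        te = float(tes[0]) if tes else None
        stored = meta.get("roles")
        frame_role = role or (Role(stored[0]) if stored else None)
        if frame_role is None:
            raise MetadataError(f"{path}: no role stored; pass role= explicitly")
        return ImageFrame(vol, field_t=field, role=frame_role, te_ms=te,
                          pixel_spacing_mm=tuple(meta.get("pixel_spacing_mm", (1.0, 1.0))))
    ds = pydicom.dcmread(str(path))
    frame = _dataset_to_frame(ds, path)
    return replace(frame, role=role) if role is not None else frame
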