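"""Measurement input/output.

Reads phantom CT volumes (DICOM series or plain arrays) or pre-extracted
tabular per-foam CT numbers, extracts ROI statistics, applies an
air-truncation correction, and emits :class:`RawMeasurement` records.

Conventions: all voxel indices are 0-based in ``(z, y, x)`` order; an
ROI is the closed cube ``center ± half_width`` per axis (default
half-width 2, i.e. the conventional 5x5x5 voxel block at the center of
each foam).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid
from scipy import optimize, stats

from .phantom import ALIAS_BY_MATERIAL, MATERIAL_ALIASES, PhantomDefinition

__all__ = [
    "RECON_LABELS",
    "ScanProtocol",
    "RoiSpec",
    "RawMeasurement",
    "extract_roi_means",
    "correct_truncation",
    "read_measurement_table",
    "write_measurement_table",
    "read_dicom_series",
    "write_dicom_series",
    "DICOM_HU_QUANTUM",
]

RECON_LABELS = ("fbp_standard", "fbp_sharp", "ir_40", "ir_100")

#: HU resolution of the DICOM writer (RescaleSlope).  1/16 is an exact
#: binary fraction, so any HU value on this grid survives the integer
#: pixel encoding bit-exactly.
DICOM_HU_QUANTUM = 1.0 / 16.0


@dataclass(frozen=True)
class ScanProtocol:
    """Acquisition metadata for one phantom scan."""

    scanner_id: str
    vendor: str = ""
    kvp: float = 120.0
    ctdi: float = 3.0
    recon: str = "fbp_standard"
    slice_thickness: float | None = None

    def __post_init__(self) -> None:
        if self.kvp <= 0:
            raise ValueError(f"kvp must be positive, got {self.kvp}")
        if self.ctdi <= 0:
            raise ValueError(f"ctdi must be positive, got {self.ctdi}")
        if self.recon not in RECON_LABELS:
            raise ValueError(
                f"unknown reconstruction label {self.recon!r}; expected one of {RECON_LABELS}"
            )


@dataclass(frozen=True)
class RoiSpec:
    """Cubic ROI: closed cube of side ``2*half_width + 1`` around ``center``."""

    material_name: str
    center: tuple[int, int, int]
    half_width: int = 2

    def __post_init__(self) -> None:
        if self.half_width < 0:
            raise ValueError("half_width must be >= 0")

    def slices(self, shape: tuple[int, ...]) -> tuple[slice, slice, slice]:
        out = []
        for axis, (c, n) in enumerate(zip(self.center, shape)):
            lo, hi = c - self.half_width, c + self.half_width + 1
            if lo < 0 or hi > n:
                raise ValueError(
                    f"ROI for {self.material_name!r} out of bounds on axis {axis}: "
                    f"[{lo}, {hi}) vs size {n}"
                )
            out.append(slice(lo, hi))
        return tuple(out)

    @property
    def n_voxels(self) -> int:
        return (2 * self.half_width + 1) ** 3


@dataclass
class RawMeasurement:
    """Per-scan, per-material measured mean CT numbers plus protocol."""

    protocol: ScanProtocol
    values: dict[str, float]
    roi_sd: dict[str, float] = field(default_factory=dict)
    n_voxels: int | None = None
    truncation_flag: bool = False

    def validate(self, phantom: PhantomDefinition) -> None:
        missing = [n for n in phantom.required_names() if n not in self.values]
        if missing:
            raise ValueError(f"measurement missing required materials: {missing}")
        for name, hu in self.values.items():
            if not math.isfinite(hu) or hu < -1100:
                raise ValueError(f"implausible CT number for {name!r}: {hu}")


# ---------------------------------------------------------------------------
# ROI extraction

def extract_roi_means(
    volume: np.ndarray, rois: list[RoiSpec]
) -> dict[str, tuple[float, float, int]]:
    """Mean/SD/count over each cubic ROI.

    SD uses the n-1 (sample) denominator; an ROI of a single voxel
    reports SD 0.  Raises if any ROI leaves the volume or touches
    non-finite voxels.
    """
    volume = np.asarray(volume, dtype=float)
    if volume.ndim != 3:
        raise ValueError(f"expected a 3-D volume, got shape {volume.shape}")
    out: dict[str, tuple[float, float, int]] = {}
    for roi in rois:
        cube = volume[roi.slices(volume.shape)]
        if not np.all(np.isfinite(cube)):
            raise ValueError(f"non-finite voxels in ROI for {roi.material_name!r}")
        n = cube.size
        sd = float(cube.std(ddof=1)) if n > 1 else 0.0
        out[roi.material_name] = (float(cube.mean()), sd, n)
    return out


# ---------------------------------------------------------------------------
# Truncation correction

def _censored_normal_mean(values: np.ndarray, floor: float) -> float:
    """MLE of the mean of a normal left-censored at ``floor``.

    Voxels at the floor are treated as censored (true value <= floor);
    the rest follow the upper part of the same Gaussian.
    """
    clipped = values <= floor
    free = values[~clipped]
    n_c = int(clipped.sum())
    if free.size == 0:
        return float(floor)
    mu0 = float(np.median(values))
    sd0 = float(free.std(ddof=1)) if free.size > 1 else 1.0
    sd0 = max(sd0, 0.5)

    def nll(theta: np.ndarray) -> float:
        mu, log_sd = theta
        sd = math.exp(log_sd)
        ll = stats.norm.logpdf(free, mu, sd).sum()
        if n_c:
            ll += n_c * stats.norm.logcdf(floor, mu, sd)
        return -ll

    res = optimize.minimize(
        nll, x0=np.array([mu0, math.log(sd0)]), method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000},
    )
    return float(res.x[0])


def correct_truncation(
    volume: np.ndarray,
    clip_floor: float,
    air_roi: RoiSpec,
    fraction_threshold: float = 0.05,
) -> tuple[float, bool]:
    """Air mean corrected for vendor low-HU truncation filters.

    Some vendors clip CT numbers below a floor (−1000 or −1024 HU
    dialects), which biases the measured air mean upward.  Clipping is
    detected as the fraction of air-ROI voxels at ``clip_floor``
    exceeding ``fraction_threshold``; the mean is then re-estimated by a
    censored-Gaussian fit to the unclipped voxels.  When no clipping is
    detected the plain ROI mean is returned with ``flag=False``.
    """
    if clip_floor > -900:
        raise ValueError(f"clip_floor must be <= -900 HU, got {clip_floor}")
    if not 0 <= fraction_threshold <= 1:
        raise ValueError("fraction_threshold must lie in [0, 1]")
    volume = np.asarray(volume, dtype=float)
    cube = volume[air_roi.slices(volume.shape)].ravel()
    if cube.size == 0:
        raise ValueError("empty air ROI")
    frac = float(np.mean(cube <= clip_floor))
    if frac > fraction_threshold:
        return _censored_normal_mean(cube, clip_floor), True
    return float(cube.mean()), False


# ---------------------------------------------------------------------------
# Tabular interface

_META_COLS = ("scanner", "vendor", "kvp", "ctdi_mgy", "recon")
_REQUIRED_MATERIAL_COLS = ("air", "ref1", "ref2", "ref3", "lung")
_OPTIONAL_MATERIAL_COLS = ("water", "acrylic")


def read_measurement_table(path) -> list[RawMeasurement]:
    """Read per-scan foam CT numbers from a CSV file.

    Expected header: ``scanner,vendor,kvp,ctdi_mgy,recon`` plus one
    column per material (``air,ref1,ref2,ref3,lung`` required;
    ``water,acrylic`` optional).  Tabular inputs are assumed to be
    truncation-corrected already.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return []
    if df.empty and len(df.columns) == 0:
        return []
    for col in _META_COLS:
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r}")
    for col in _REQUIRED_MATERIAL_COLS:
        if col not in df.columns:
            raise ValueError(f"missing required material column {col!r}")
    material_cols = [
        c for c in (*_REQUIRED_MATERIAL_COLS, *_OPTIONAL_MATERIAL_COLS) if c in df.columns
    ]
    out = []
    for i, row in df.iterrows():
        values = {}
        for col in material_cols:
            raw = row[col]
            try:
                hu = float(raw)
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-numeric CT number {raw!r} in column {col!r}, row {i}"
                ) from None
            if not math.isfinite(hu):
                raise ValueError(f"non-finite CT number in column {col!r}, row {i}")
            values[MATERIAL_ALIASES[col]] = hu
        protocol = ScanProtocol(
            scanner_id=str(row["scanner"]),
            vendor=str(row["vendor"]),
            kvp=float(row["kvp"]),
            ctdi=float(row["ctdi_mgy"]),
            recon=str(row["recon"]),
        )
        out.append(RawMeasurement(protocol=protocol, values=values))
    return out


def write_measurement_table(measurements: list[RawMeasurement], path) -> None:
    """Write measurements to the CSV schema consumed by :func:`read_measurement_table`."""
    rows = []
    for m in measurements:
        row = {
            "scanner": m.protocol.scanner_id,
            "vendor": m.protocol.vendor,
            "kvp": m.protocol.kvp,
            "ctdi_mgy": m.protocol.ctdi,
            "recon": m.protocol.recon,
        }
        for name, hu in m.values.items():
            row[ALIAS_BY_MATERIAL.get(name, name)] = hu
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# DICOM series

def write_dicom_series(
    volume: np.ndarray,
    directory,
    kvp: float = 120.0,
    vendor: str = "lungct-synthetic",
    slice_thickness: float = 1.0,
    pixel_spacing: float = 0.5,
    intercept: float = -1024.0,
    slope: float = DICOM_HU_QUANTUM,
) -> None:
    """Write a volume as one CT Image Storage series (one file per slice).

    Pixel data is signed 16-bit; HU values are quantized to the nearest
    multiple of ``slope`` (default 1/16 HU), so any volume already on
    that grid round-trips exactly.
    """
    volume = np.asarray(volume, dtype=float)
    if volume.ndim != 3:
        raise ValueError("expected a 3-D volume")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    raw = np.round((volume - intercept) / slope)
    if raw.min() < np.iinfo(np.int16).min or raw.max() > np.iinfo(np.int16).max:
        raise ValueError("HU range not representable with the chosen slope/intercept")
    raw = raw.astype(np.int16)
    series_uid = generate_uid()
    study_uid = generate_uid()
    frame_uid = generate_uid()
    for k in range(volume.shape[0]):
        ds = Dataset()
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = generate_uid()
        ds.Modality = "CT"
        ds.Manufacturer = vendor
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.FrameOfReferenceUID = frame_uid
        ds.InstanceNumber = k + 1
        ds.ImagePositionPatient = [0.0, 0.0, k * slice_thickness]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.PixelSpacing = [pixel_spacing, pixel_spacing]
        ds.SliceThickness = slice_thickness
        ds.KVP = kvp
        ds.Rows, ds.Columns = volume.shape[1:]
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleIntercept = intercept
        ds.RescaleSlope = slope
        ds.PixelData = raw[k].tobytes()
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = CTImageStorage
        meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.file_meta = meta
        pydicom.dcmwrite(
            directory / f"slice_{k:04d}.dcm", ds, enforce_file_format=True
        )


def read_dicom_series(
    directory,
    scanner_id: str | None = None,
    ctdi: float | None = None,
    recon: str | None = None,
) -> tuple[np.ndarray, ScanProtocol]:
    """Assemble one DICOM series into an HU volume plus protocol metadata.

    Slices are ordered by z position (ImagePositionPatient), not by file
    name; pixel values are mapped to HU via the stored rescale
    slope/intercept.  CTDI and reconstruction label are vendor-dependent
    header fields and may be supplied as arguments when absent.
    """
    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.suffix.lower() == ".dcm")
    if not files:
        raise ValueError(f"no DICOM files in {directory}")
    datasets = [pydicom.dcmread(p) for p in files]
    series = {ds.SeriesInstanceUID for ds in datasets}
    if len(series) != 1:
        raise ValueError(f"directory mixes {len(series)} series")
    shapes = {(int(ds.Rows), int(ds.Columns)) for ds in datasets}
    if len(shapes) != 1:
        raise ValueError("inconsistent slice shapes within series")

    def z_of(ds: Dataset) -> float:
        if "ImagePositionPatient" in ds:
            return float(ds.ImagePositionPatient[2])
        return float(ds.InstanceNumber)

    datasets.sort(key=z_of)
    slices = []
    for ds in datasets:
        if "RescaleSlope" not in ds or "RescaleIntercept" not in ds:
            raise ValueError("missing rescale slope/intercept tags")
        arr = ds.pixel_array.astype(float)
        slices.append(arr * float(ds.RescaleSlope) + float(ds.RescaleIntercept))
    volume = np.stack(slices, axis=0)
    first = datasets[0]
    protocol = ScanProtocol(
        scanner_id=scanner_id or str(getattr(first, "StationName", "unknown")),
        vendor=str(getattr(first, "Manufacturer", "")),
        kvp=float(getattr(first, "KVP", 120.0)),
        ctdi=float(ctdi) if ctdi is not None else float(
            getattr(first, "CTDIvol", 3.0)
        ),
        recon=recon or "fbp_standard",
        slice_thickness=float(getattr(first, "SliceThickness", 1.0)),
    )
    return volume, protocol
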