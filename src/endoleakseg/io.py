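"""Readers and writers: DICOM series in, NIfTI label volumes in, HDF5 cohort store.

The internal store is one HDF5 group per case:

* ``pixels``   — (n_slices, H, W) attenuation values, native dtype (int16 canonical)
* ``labels``   — (n_slices, H, W) uint8 bitmask: bit0 sac, bit1 lumen, bit2 endoleak
* ``present``  — (n_slices, 3) bool, whether each mask is present (distinguishes an
  absent mask from an empty one)
* ``slice_indices`` — (n_slices,) int32
* attrs ``case_id``, ``label``, ``pixel_spacing``

Writes go to a temporary file renamed into place on success, so a failed write
never leaves a partial store behind.
"""

from __future__ import annotations

import os
import warnings
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np

from .types import CONTROL, POSITIVE, CaseRecord, CTSlice, MaskAlignmentError, MaskSet

_MASK_NAMES = ("aneurysm_sac", "stent_lumen", "endoleak")


class DicomFormatError(ValueError):
    pass


class DicomSeriesAmbiguityError(ValueError):
    pass


# ---------------------------------------------------------------------------
# DICOM
# ---------------------------------------------------------------------------

def read_dicom_case(directory: str | Path, label: str | None = None) -> CaseRecord:
    """Read one DICOM series (one directory per case) into a CaseRecord.

    Slices are sorted by anatomical position (ImagePositionPatient z) when
    available, falling back to file order with a warning.  Stored values are
    rescaled to HU with RescaleSlope/RescaleIntercept.  The case label comes
    from a sidecar ``label.txt`` (containing ``positive`` or ``control``) or
    the ``label`` argument; it defaults to control.
    """
    import pydicom

    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.suffix.lower() == ".dcm")
    if not files:
        raise DicomFormatError(f"no DICOM files found in {directory}")
    try:
        datasets = [pydicom.dcmread(str(f)) for f in files]
    except Exception as exc:  # pragma: no cover - corrupt-file path
        raise DicomFormatError(f"failed to read DICOM series in {directory}: {exc}")

    uids = {getattr(ds, "SeriesInstanceUID", None) for ds in datasets}
    if len(uids) > 1:
        raise DicomSeriesAmbiguityError(
            f"directory {directory} mixes {len(uids)} series UIDs")

    def _zpos(ds):
        ipp = getattr(ds, "ImagePositionPatient", None)
        return float(ipp[2]) if ipp is not None else None

    zs = [_zpos(ds) for ds in datasets]
    if all(z is not None for z in zs):
        order = np.argsort(zs, kind="stable")
    else:
        warnings.warn("no anatomical position in series; using file order")
        order = np.arange(len(datasets))

    if label is None:
        sidecar = directory / "label.txt"
        label = sidecar.read_text().strip() if sidecar.exists() else CONTROL
    case_id = directory.name

    slices, masks = [], []
    for rank, i in enumerate(order):
        ds = datasets[i]
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        hu = ds.pixel_array.astype(np.float64) * slope + intercept
        if np.allclose(hu, np.round(hu)):
            hu = np.round(hu).astype(np.int16)
        spacing = getattr(ds, "PixelSpacing", [1.0, 1.0])
        slices.append(CTSlice(pixels=hu, case_id=case_id, slice_index=rank,
                              pixel_spacing=(float(spacing[0]), float(spacing[1]))))
        masks.append(MaskSet())
    return CaseRecord(case_id=case_id, slices=slices, masks=masks, label=label)


def write_dicom_case(case: CaseRecord, directory: str | Path,
                     slope: float = 1.0, intercept: float = -1024.0) -> None:
    """Write a CaseRecord as a minimal DICOM series (fixture/round-trip helper).

    Pixel data are stored as ``(HU - intercept) / slope`` in uint16.
    """
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid()
    for sl in case.slices:
        stored = np.round((np.asarray(sl.pixels, dtype=np.float64) - intercept) / slope)
        if stored.min() < 0 or stored.max() > 65535:
            raise ValueError("pixels out of range for uint16 storage with given rescale")
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.Modality = "CT"
        ds.PatientID = case.case_id
        ds.InstanceNumber = sl.slice_index + 1
        ds.ImagePositionPatient = [0.0, 0.0, float(sl.slice_index)]
        ds.PixelSpacing = [float(sl.pixel_spacing[0]), float(sl.pixel_spacing[1])]
        ds.RescaleSlope = slope
        ds.RescaleIntercept = intercept
        ds.Rows, ds.Columns = stored.shape
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.PixelData = stored.astype(np.uint16).tobytes()
        ds.save_as(str(directory / f"slice_{sl.slice_index:04d}.dcm"),
                   enforce_file_format=True)
    (directory / "label.txt").write_text(case.label + "\n")


# ---------------------------------------------------------------------------
# NIfTI label volumes
# ---------------------------------------------------------------------------

def read_mask_volume(path: str | Path, slice_shape: tuple[int, int]) -> list[MaskSet]:
    """Read a NIfTI integer label volume into per-slice MaskSets.

    Labels: 0 background, 1 aneurysm sac, 2 stent lumen, 3 endoleak.  The
    annotation convention is hierarchical: lumen and endoleak voxels are carved
    out of the sac region, so the derived sac mask is ``label >= 1``.  A slice
    carrying lumen or endoleak voxels with no sac voxel at all is rejected as
    misaligned (a lumen cannot exist without a surrounding sac).
    """
    import nibabel as nib

    vol = np.asanyarray(nib.load(str(path)).dataobj)
    if vol.ndim != 3:
        raise ValueError(f"expected a 3-D label volume, got shape {vol.shape}")
    # NIfTI axis order is (x, y, z); slices are along the last axis.
    if vol.shape[:2] != tuple(slice_shape):
        raise MaskAlignmentError(
            f"label volume in-plane shape {vol.shape[:2]} != CT slice shape {slice_shape}")
    bad = np.setdiff1d(np.unique(vol), [0, 1, 2, 3])
    if bad.size:
        raise ValueError(f"unknown label values {bad.tolist()} in {path}")

    out = []
    for k in range(vol.shape[2]):
        sl = vol[:, :, k]
        if np.any(sl == 2) and not np.any(sl == 1):
            raise MaskAlignmentError(
                f"slice {k}: stent lumen labeled outside any aneurysm sac")
        out.append(MaskSet(aneurysm_sac=(sl >= 1).astype(np.uint8),
                           stent_lumen=(sl == 2).astype(np.uint8),
                           endoleak=(sl == 3).astype(np.uint8)))
    return out


# ---------------------------------------------------------------------------
# HDF5 cohort store
# ---------------------------------------------------------------------------

def _encode_masks(case: CaseRecord) -> tuple[np.ndarray, np.ndarray]:
    h, w = case.slices[0].shape
    labels = np.zeros((case.n_slices, h, w), dtype=np.uint8)
    present = np.zeros((case.n_slices, 3), dtype=bool)
    for i, ms in enumerate(case.masks):
        for bit, name in enumerate(_MASK_NAMES):
            m = getattr(ms, name)
            if m is not None:
                present[i, bit] = True
                labels[i] |= (m.astype(np.uint8) << bit)
    return labels, present


def _decode_masks(labels: np.ndarray, present: np.ndarray) -> list[MaskSet]:
    out = []
    for i in range(labels.shape[0]):
        kwargs = {}
        for bit, name in enumerate(_MASK_NAMES):
            if present[i, bit]:
                kwargs[name] = ((labels[i] >> bit) & 1).astype(np.uint8)
        out.append(MaskSet(**kwargs))
    return out


def store_cohort(cases: Sequence[CaseRecord], store_path: str | Path) -> Path:
    """Write a cohort to HDF5.  Atomic: a partial write leaves no store behind."""
    store_path = Path(store_path)
    tmp = store_path.with_name(store_path.name + ".tmp")
    try:
        with h5py.File(tmp, "w") as f:
            f.attrs["n_cases"] = len(cases)
            for case in cases:
                g = f.create_group(f"case/{case.case_id}")
                g.create_dataset(
                    "pixels", data=np.stack([s.pixels for s in case.slices]))
                labels, present = _encode_masks(case)
                g.create_dataset("labels", data=labels)
                g.create_dataset("present", data=present)
                g.create_dataset(
                    "slice_indices",
                    data=np.array([s.slice_index for s in case.slices], dtype=np.int32))
                g.attrs["case_id"] = case.case_id
                g.attrs["label"] = case.label
                g.attrs["pixel_spacing"] = np.asarray(
                    case.slices[0].pixel_spacing, dtype=float)
        os.replace(tmp, store_path)
    except BaseException:
        tmp.unlink(missing_ok=True)
        raise
    return store_path


def load_cohort(store_path: str | Path) -> list[CaseRecord]:
    """Load a cohort written by :func:`store_cohort`; round-trip is bit-exact."""
    cases = []
    with h5py.File(store_path, "r") as f:
        if "case" not in f:
            return []
        for cid in sorted(f["case"]):
            g = f[f"case/{cid}"]
            pixels = g["pixels"][...]
            labels = g["labels"][...]
            present = g["present"][...]
            idx = g["slice_indices"][...]
            spacing = tuple(float(v) for v in g.attrs["pixel_spacing"])
            slices = [CTSlice(pixels=pixels[i], case_id=cid, slice_index=int(idx[i]),
                              pixel_spacing=spacing)
                      for i in range(pixels.shape[0])]
            cases.append(CaseRecord(case_id=cid, slices=slices,
                                    masks=_decode_masks(labels, present),
                                    label=str(g.attrs["label"])))
    return cases


def read_manifest(path: str | Path):
    """Read a cohort manifest CSV with columns case_id, path, label."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"case_id", "path", "label"}
    if not required.issubset(df.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    bad = set(df["label"]) - {POSITIVE, CONTROL}
    if bad:
        raise ValueError(f"unknown labels in manifest: {sorted(bad)}")
    return df
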