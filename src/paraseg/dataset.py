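"""CT slice IO, HU-filtered ground truth and patient-level data splitting.

The network never sees raw HU: inputs are normalized by a fixed linear map
from HU in [-1024, +1024] to [0, 1] (clipped outside), which is
dataset-independent and keeps the muscle window's contrast. Ground truth is
the manual ROI restricted to the skeletal-muscle HU window [-29, +150]
(both bounds inclusive, the standard body-composition convention).
Train/validation/test splits are drawn per patient in a 6:2:2 ratio so
that no patient contributes slices to two partitions.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .phantoms import HU_MIN, HU_MAX, MUSCLE_HU_WINDOW

__all__ = [
    "HUImage",
    "GroundTruthMask",
    "DatasetSplit",
    "read_slice",
    "read_mask",
    "load_manifest",
    "apply_hu_filter",
    "split_by_patient",
    "normalize_hu",
    "write_dicom_slice",
    "write_png16_slice",
    "write_mask_png",
]

NORM_HU_LO, NORM_HU_HI = -1024.0, 1024.0


@dataclass
class HUImage:
    """One axial slice in Hounsfield units with its identity."""

    pixels: np.ndarray  # int16 (H, W)
    patient_id: str = ""
    slice_index: int = 0

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] != px.shape[1]:
            raise ValueError(f"slice must be square 2-D, got shape {px.shape}")
        if px.min() < HU_MIN or px.max() > HU_MAX:
            raise ValueError(
                f"HU values outside [{HU_MIN}, {HU_MAX}]: "
                f"range [{px.min()}, {px.max()}]"
            )
        self.pixels = px.astype(np.int16)

    @property
    def shape(self):
        return self.pixels.shape


@dataclass
class GroundTruthMask:
    """ROI restricted to the muscle HU window; records the window used."""

    pixels: np.ndarray  # uint8 {0,1}
    hu_window: tuple[float, float] = MUSCLE_HU_WINDOW


@dataclass(frozen=True)
class DatasetSplit:
    """Patient-disjoint train/val/test partition."""

    train_ids: frozenset
    val_ids: frozenset
    test_ids: frozenset
    ratios: tuple[float, float, float] = (0.6, 0.2, 0.2)
    seed: int = 0

    def __post_init__(self):
        parts = (self.train_ids, self.val_ids, self.test_ids)
        total = sum(len(p) for p in parts)
        union = self.train_ids | self.val_ids | self.test_ids
        if len(union) != total:
            raise ValueError("split partitions are not pairwise disjoint")

    def partition_of(self, patient_id) -> str:
        if patient_id in self.train_ids:
            return "train"
        if patient_id in self.val_ids:
            return "val"
        if patient_id in self.test_ids:
            return "test"
        raise KeyError(patient_id)


def _check_binary(mask: np.ndarray, name: str = "mask") -> np.ndarray:
    m = np.asarray(mask)
    vals = np.unique(m)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError(f"{name} must be binary over {{0,1}}, found values {vals}")
    return m.astype(np.uint8)


def apply_hu_filter(img, roi, hu_lo: float = MUSCLE_HU_WINDOW[0],
                    hu_hi: float = MUSCLE_HU_WINDOW[1]) -> GroundTruthMask:
    """Ground truth = ROI AND (hu_lo <= HU <= hu_hi), bounds inclusive."""
    if hu_lo > hu_hi:
        raise ValueError(f"hu_lo={hu_lo} exceeds hu_hi={hu_hi}")
    px = img.pixels if isinstance(img, HUImage) else np.asarray(img)
    m = _check_binary(roi, "roi")
    if px.shape != m.shape:
        raise ValueError(f"image shape {px.shape} != roi shape {m.shape}")
    keep = (px >= hu_lo) & (px <= hu_hi)
    return GroundTruthMask((m.astype(bool) & keep).astype(np.uint8), (hu_lo, hu_hi))


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def split_by_patient(ids, ratios=(0.6, 0.2, 0.2), seed: int = 0) -> DatasetSplit:
    """Seeded random patient-level partition.

    Train and validation sizes are rounded half-up from their ratios; the
    remainder forms the test set (256 patients -> 154/51/51).
    """
    ids = sorted(ids)
    if len(ids) < 3:
        raise ValueError("need at least 3 patients to split")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios {ratios} do not sum to 1")
    n = len(ids)
    n_train = _round_half_up(ratios[0] * n)
    n_val = _round_half_up(ratios[1] * n)
    # tiny cohorts: rounding may consume everything; keep the test set
    # non-empty by shrinking the larger of train/val
    while n_train + n_val >= n:
        if n_train >= n_val and n_train > 1:
            n_train -= 1
        elif n_val > 1:
            n_val -= 1
        else:
            raise ValueError("too few patients to form three partitions")
    order = np.random.default_rng(seed).permutation(n)
    shuffled = [ids[i] for i in order]
    return DatasetSplit(
        train_ids=frozenset(shuffled[:n_train]),
        val_ids=frozenset(shuffled[n_train:n_train + n_val]),
        test_ids=frozenset(shuffled[n_train + n_val:]),
        ratios=tuple(ratios),
        seed=seed,
    )


def write_split_tsv(split: DatasetSplit, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["patient_id", "partition"])
        for part, ids in (("train", split.train_ids), ("val", split.val_ids),
                          ("test", split.test_ids)):
            for pid in sorted(ids):
                w.writerow([pid, part])


def read_split_tsv(path) -> DatasetSplit:
    parts = {"train": set(), "val": set(), "test": set()}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            parts[row["partition"]].add(row["patient_id"])
    return DatasetSplit(frozenset(parts["train"]), frozenset(parts["val"]),
                        frozenset(parts["test"]))


def normalize_hu(img) -> np.ndarray:
    """Fixed linear map HU in [-1024, +1024] -> [0, 1], clipping outside."""
    px = img.pixels if isinstance(img, HUImage) else np.asarray(img)
    px = np.clip(px.astype(np.float32), NORM_HU_LO, NORM_HU_HI)
    return (px - NORM_HU_LO) / (NORM_HU_HI - NORM_HU_LO)


# ---------------------------------------------------------------------------
# slice / mask IO


def write_dicom_slice(pixels: np.ndarray, path, patient_id: str = "",
                      slice_index: int = 0) -> None:
    """Write one HU slice as a DICOM secondary capture storing HU directly
    (RescaleSlope=1, RescaleIntercept=0, signed 16-bit)."""
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = pydicom.uid.generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = SecondaryCaptureImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "CT"
    ds.PatientID = patient_id
    ds.InstanceNumber = slice_index + 1
    ds.Rows, ds.Columns = pixels.shape
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 1  # signed
    ds.RescaleSlope = 1.0
    ds.RescaleIntercept = 0.0
    ds.PixelData = np.ascontiguousarray(pixels.astype(np.int16)).tobytes()
    ds.save_as(str(path), enforce_file_format=True)


def write_png16_slice(pixels: np.ndarray, path) -> tuple[float, float]:
    """Write one HU slice as 16-bit grayscale PNG.

    PNG stores unsigned values, so HU are shifted by +1024; the returned
    (slope, intercept) = (1, -1024) must be recorded in the manifest to
    recover HU on read.
    """
    from PIL import Image

    intercept = -1024.0
    stored = (pixels.astype(np.int32) - int(intercept)).astype(np.uint16)
    Image.fromarray(stored).save(str(path))
    return 1.0, intercept


def write_mask_png(mask: np.ndarray, path) -> None:
    from PIL import Image

    Image.fromarray(_check_binary(mask), mode="L").save(str(path))


def read_slice(path, fmt: str | None = None, slope: float | None = None,
               intercept: float | None = None, patient_id: str = "",
               slice_index: int = 0) -> HUImage:
    """Read one CT slice and convert to HU.

    DICOM slices use the file's RescaleSlope/RescaleIntercept (their absence
    is an error — identity is never silently assumed). 16-bit PNG slices
    require the calibration (slope, intercept) from the manifest.
    """
    path = Path(path)
    if fmt is None:
        fmt = "dicom" if path.suffix.lower() in (".dcm", ".dicom") else "png16"
    if fmt == "dicom":
        import pydicom

        ds = pydicom.dcmread(str(path))
        if "RescaleSlope" not in ds or "RescaleIntercept" not in ds:
            raise ValueError(f"{path}: DICOM lacks RescaleSlope/RescaleIntercept")
        hu = ds.pixel_array.astype(np.float64) * float(ds.RescaleSlope) \
            + float(ds.RescaleIntercept)
    elif fmt == "png16":
        if slope is None or intercept is None:
            raise ValueError(
                f"{path}: PNG slice needs HU calibration (slope, intercept) "
                "from the manifest"
            )
        from PIL import Image

        stored = np.asarray(Image.open(str(path)), dtype=np.float64)
        hu = stored * float(slope) + float(intercept)
    else:
        raise ValueError(f"unknown slice format {fmt!r}")
    return HUImage(np.rint(hu).astype(np.int16), patient_id, slice_index)


def read_mask(path) -> np.ndarray:
    """Read a binary mask from PNG or NIfTI; values must be {0,1}."""
    path = Path(path)
    if path.suffix in (".nii", ".gz") or path.name.endswith(".nii.gz"):
        import nibabel as nib

        arr = np.asarray(nib.load(str(path)).dataobj)
        arr = np.squeeze(arr)
    else:
        from PIL import Image

        arr = np.asarray(Image.open(str(path)))
    return _check_binary(arr)


def load_manifest(manifest_path):
    """Load a cohort manifest written by ``phantoms.write_cohort``.

    Returns a list of PatientRecord with slices read back into HU.
    """
    from .phantoms import PatientRecord

    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    records: dict[str, PatientRecord] = {}
    with open(manifest_path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            pid = row["patient_id"]
            fmt = row["format"]
            img = read_slice(
                root / row["path"],
                fmt="dicom" if fmt == "dicom" else "png16",
                slope=float(row["slope"]),
                intercept=float(row["intercept"]),
                patient_id=pid,
                slice_index=int(row["slice_index"]),
            )
            mask = read_mask(root / row["mask_path"])
            rec = records.setdefault(pid, PatientRecord(patient_id=pid))
            rec.slices.append((img.pixels, mask))
    return list(records.values())
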