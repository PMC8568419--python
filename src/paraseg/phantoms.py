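"""Synthetic abdominal CT phantoms with labeled paravertebral muscles.

Each phantom is an axial cross-section built from simple geometric
primitives: an elliptical body filled with fat-range tissue, a vertebral
body plus spinous process in bone-range HU, and six muscle compartments —
bilateral psoas (ellipses flanking the vertebra), bilateral quadratus
lumborum (small lateral ellipses) and bilateral paraspinal muscle
(posterior crescents formed as ellipse differences). Muscle HU are drawn
so that nearly all muscle pixels fall inside the skeletal-muscle window
[-29, +150] HU; everything outside the body is air near -1000 HU.

A cohort draws one geometry jitter per patient (shared by all of that
patient's slices, default 4) so that patient-level data splits are
meaningful; per-slice variation is acquisition noise only.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

HU_MIN, HU_MAX = -1024, 3071
MUSCLE_HU_WINDOW = (-29, 150)

__all__ = [
    "PhantomSpec",
    "PhantomConfigError",
    "generate_phantom",
    "generate_cohort",
    "write_cohort",
]


class PhantomConfigError(ValueError):
    """A PhantomSpec field violates one of its invariants."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic CT slice generator.

    All HU parameters are in Hounsfield units. ``body_axes`` are the body
    ellipse semi-axes in pixels (default 0.40/0.30 of the image side).
    ``muscle_scale`` scales all muscle compartment axes (0 gives an empty
    foreground). ``per_patient_jitter`` is the half-width of the uniform
    relative jitter applied to compartment centers and axes per patient.
    """

    image_size: int = 512
    body_axes: tuple[float, float] | None = None
    muscle_hu_mean: float = 50.0
    muscle_hu_sd: float = 15.0
    fat_hu_mean: float = -100.0
    fat_hu_sd: float = 20.0
    bone_hu_mean: float = 700.0
    bone_hu_sd: float = 150.0
    air_hu: float = -1000.0
    noise_sd: float = 10.0
    muscle_scale: float = 1.0
    per_patient_jitter: float = 0.10
    seed: int = 0

    def __post_init__(self):
        lo, hi = MUSCLE_HU_WINDOW
        if not (lo <= self.muscle_hu_mean <= hi):
            raise PhantomConfigError(
                f"muscle_hu_mean={self.muscle_hu_mean} must lie in [{lo}, {hi}]"
            )
        if not self.fat_hu_mean < lo:
            raise PhantomConfigError(f"fat_hu_mean={self.fat_hu_mean} must be < {lo}")
        if not self.bone_hu_mean > hi:
            raise PhantomConfigError(f"bone_hu_mean={self.bone_hu_mean} must be > {hi}")
        if not self.air_hu <= -900:
            raise PhantomConfigError(f"air_hu={self.air_hu} must be <= -900")
        if self.image_size < 32 or self.image_size % 2:
            raise PhantomConfigError(
                f"image_size={self.image_size} must be even and >= 32"
            )
        if self.muscle_scale < 0:
            raise PhantomConfigError("muscle_scale must be >= 0")
        for name in ("noise_sd", "muscle_hu_sd", "fat_hu_sd", "bone_hu_sd"):
            if getattr(self, name) < 0:
                raise PhantomConfigError(f"{name} must be >= 0")


@dataclass
class PatientRecord:
    """All slices of one synthetic patient: (HU image, ROI mask) pairs."""

    patient_id: str
    slices: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.slices)


def _ellipse(shape, center, axes, angle_deg=0.0):
    """Boolean mask of an axis-aligned (or rotated) filled ellipse."""
    ay, ax = axes
    if ay <= 0 or ax <= 0:
        return np.zeros(shape, dtype=bool)
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    y = yy - center[0]
    x = xx - center[1]
    if angle_deg:
        t = np.deg2rad(angle_deg)
        y, x = y * np.cos(t) - x * np.sin(t), y * np.sin(t) + x * np.cos(t)
    return (y / ay) ** 2 + (x / ax) ** 2 <= 1.0


def _geometry(spec: PhantomSpec, jitter: np.ndarray | None):
    """Compartment masks for one patient geometry.

    ``jitter`` is a vector of multiplicative factors around 1 (one per
    geometric degree of freedom), or None for the nominal geometry.
    Returns (body, bone, muscle_union) boolean masks.
    """
    n = spec.image_size
    shape = (n, n)
    j = np.ones(40) if jitter is None else jitter
    # pixel-grid center, so the nominal anatomy is mirror-symmetric about
    # the vertebral column under a horizontal flip
    cy, cx = (n - 1) * 0.5, (n - 1) * 0.5
    if spec.body_axes is not None:
        bay, bax = spec.body_axes[1], spec.body_axes[0]
    else:
        bay, bax = 0.30 * n, 0.40 * n
    body = _ellipse(shape, (cy, cx), (bay * j[0], bax * j[1]))

    # vertebral body + spinous process (posterior = larger row index)
    vert_c = (cy + 0.06 * n * j[2], cx)
    bone = _ellipse(shape, vert_c, (0.055 * n * j[3], 0.07 * n * j[4]))
    bone |= _ellipse(shape, (cy + 0.145 * n * j[5], cx), (0.05 * n * j[6], 0.018 * n * j[7]))

    ms = spec.muscle_scale
    muscle = np.zeros(shape, dtype=bool)
    for side, base in ((-1, 8), (+1, 16)):
        # psoas: anterolateral ellipse beside the vertebral body
        muscle |= _ellipse(
            shape,
            (cy + 0.035 * n * j[base], cx + side * 0.115 * n * j[base + 1]),
            (0.062 * n * ms * j[base + 2], 0.046 * n * ms * j[base + 3]),
            angle_deg=side * 15.0,
        )
        # quadratus lumborum: small lateral ellipse, posterior to psoas
        muscle |= _ellipse(
            shape,
            (cy + 0.10 * n * j[base + 4], cx + side * 0.175 * n * j[base + 5]),
            (0.042 * n * ms * j[base + 6], 0.036 * n * ms * j[base + 7]),
        )
    for side, base in ((-1, 24), (+1, 28)):
        # paraspinal muscle: posterior crescent = outer minus inner ellipse
        outer = _ellipse(
            shape,
            (cy + 0.165 * n * j[base], cx + side * 0.075 * n * j[base + 1]),
            (0.062 * n * ms * j[base + 2], 0.068 * n * ms * j[base + 3]),
        )
        inner = _ellipse(
            shape,
            (cy + 0.115 * n, cx + side * 0.045 * n),
            (0.045 * n * ms, 0.05 * n * ms),
        )
        muscle |= outer & ~inner
    muscle &= ~bone
    muscle &= body
    return body, bone, muscle


def _render(spec: PhantomSpec, body, bone, muscle, rng: np.random.Generator):
    """Sample HU for one slice given compartment masks."""
    n = spec.image_size
    hu = np.full((n, n), spec.air_hu, dtype=np.float64)
    fat = body & ~bone & ~muscle
    hu[fat] = rng.normal(spec.fat_hu_mean, spec.fat_hu_sd, int(fat.sum()))
    hu[bone] = rng.normal(spec.bone_hu_mean, spec.bone_hu_sd, int(bone.sum()))
    hu[muscle] = rng.normal(spec.muscle_hu_mean, spec.muscle_hu_sd, int(muscle.sum()))
    if spec.noise_sd > 0:
        hu += rng.normal(0.0, spec.noise_sd, hu.shape)
    img = np.clip(np.rint(hu), HU_MIN, HU_MAX).astype(np.int16)
    return img, muscle.astype(np.uint8)


def generate_phantom(spec: PhantomSpec, rng: np.random.Generator | int | None = None):
    """Generate one (HU image, ROI mask) pair with the nominal geometry.

    The mask is 1 exactly on the union of the six muscle compartments.
    Deterministic given (spec, rng state).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(spec.seed if rng is None else rng)
    body, bone, muscle = _geometry(spec, None)
    return _render(spec, body, bone, muscle, rng)


def generate_cohort(
    n_patients: int,
    slices_per_patient: int = 4,
    spec: PhantomSpec | None = None,
    seed: int | None = None,
) -> list[PatientRecord]:
    """Generate a synthetic cohort: one jittered geometry per patient,
    ``slices_per_patient`` noisy slices sharing it."""
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    if slices_per_patient < 1:
        raise ValueError("slices_per_patient must be >= 1")
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    jw = spec.per_patient_jitter
    cohort = []
    for p in range(n_patients):
        jitter = rng.uniform(1.0 - jw, 1.0 + jw, size=40)
        body, bone, muscle = _geometry(spec, jitter)
        rec = PatientRecord(patient_id=f"P{p:04d}")
        for _ in range(slices_per_patient):
            rec.slices.append(_render(spec, body, bone, muscle, rng))
        cohort.append(rec)
    return cohort


def write_cohort(cohort, out_dir, image_format: str = "dicom") -> Path:
    """Write a cohort to disk as paired slices + masks and a TSV manifest.

    Images go out as DICOM secondary captures (RescaleSlope=1,
    RescaleIntercept=0, signed 16-bit HU) or 16-bit PNG with the HU
    calibration recorded in the manifest; masks as 8-bit {0,1} PNG.
    Returns the manifest path.
    """
    from .dataset import write_dicom_slice, write_png16_slice, write_mask_png

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.tsv"
    with open(manifest, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["path", "mask_path", "patient_id", "slice_index",
                    "format", "slope", "intercept"])
        for rec in cohort:
            for k, (img, mask) in enumerate(rec.slices):
                stem = f"{rec.patient_id}_s{k}"
                mask_path = out_dir / f"{stem}_mask.png"
                write_mask_png(mask, mask_path)
                if image_format == "dicom":
                    img_path = out_dir / f"{stem}.dcm"
                    write_dicom_slice(img, img_path, rec.patient_id, k)
                    slope, intercept = 1.0, 0.0
                elif image_format == "png16":
                    img_path = out_dir / f"{stem}.png"
                    slope, intercept = write_png16_slice(img, img_path)
                else:
                    raise ValueError(f"unknown image format {image_format!r}")
                w.writerow([img_path.name, mask_path.name, rec.patient_id, k,
                            image_format, slope, intercept])
    return manifest


def nominal_spec_for_size(size: int, **overrides) -> PhantomSpec:
    """Convenience: the default spec at a given image side."""
    return replace(PhantomSpec(image_size=size), **overrides)
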