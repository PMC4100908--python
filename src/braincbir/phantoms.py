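"""Synthetic tumor-slice phantoms with class-specific spatial layout.

Clinical T1-weighted contrast-enhanced MR datasets of brain tumors are not
publicly shareable, so the pipeline is exercised on 2-D phantoms that mimic the
*spatial* signatures radiology reports describe for the three common tumor
types:

* ``meningioma`` — a homogeneous bright lesion touching a bright rim arc
  (dural/skull attachment);
* ``glioma`` — a textured lesion with a darker necrotic core, surrounded by an
  intermediate-intensity halo (edema);
* ``pituitary`` — a homogeneous lesion adjacent to a separate small bright
  landmark (sphenoidal sinus / vascular structure).

Each synthetic patient owns one lesion geometry (a smooth polar blob); its
slices share that geometry up to small shifts, scalings and rotations.  Images
carry additive Gaussian noise and a smooth multiplicative bias field standing
in for MR coil inhomogeneity.  Everything is driven by one seeded generator so
output is bit-identical across runs.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

from .errors import ConfigurationError

CLASS_LABELS = ("meningioma", "glioma", "pituitary")

#: fixed scale mapping phantom intensities to 16-bit PNG samples (lossless to
#: ~2.5e-5, well below the phantom noise floor)
PNG_SCALE = 40000.0


@dataclass(frozen=True)
class PhantomConfig:
    """Generation parameters for one phantom dataset."""

    n_patients_per_class: int = 10
    slices_per_patient: int = 3
    image_size: tuple[int, int] = (64, 64)
    noise_sd: float = 0.02
    bias_amplitude: float = 0.10
    roi_margin_range: tuple[int, int] = (2, 5)
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients_per_class < 1 or self.slices_per_patient < 1:
            raise ConfigurationError("patient and slice counts must be positive")
        if self.noise_sd < 0 or self.bias_amplitude < 0:
            raise ConfigurationError("noise_sd and bias_amplitude must be >= 0")
        lo, hi = self.roi_margin_range
        if lo < 0 or hi < lo:
            raise ConfigurationError("roi_margin_range must satisfy 0 <= min <= max")
        if min(self.image_size) < 16:
            raise ConfigurationError("image too small to contain motif and margin")


@dataclass
class ImageRecord:
    """One 2-D slice: pixel data, ROI bounding box, label and patient id.

    ``roi`` is ``(row0, col0, height, width)``, 0-based and half-open.
    """

    image: np.ndarray
    roi: tuple[int, int, int, int]
    label: str
    patient_id: str
    slice_index: int = 0
    path: str | None = None

    def roi_view(self) -> np.ndarray:
        r0, c0, h, w = self.roi
        return self.image[r0 : r0 + h, c0 : c0 + w]


def _radius_profile(phi, r0, a2, psi2, a3, psi3):
    """Smooth polar blob boundary radius R(phi)."""
    return r0 * (1.0 + a2 * np.cos(2 * phi + psi2) + a3 * np.cos(3 * phi + psi3))


def _soft_disc(r, radius, edge):
    """Sigmoid edge profile: ~1 inside ``radius``, ~0 outside, soft over ``edge`` px."""
    return 1.0 / (1.0 + np.exp((r - radius) / edge))


def _wrap_angle(a):
    return (a + np.pi) % (2 * np.pi) - np.pi


def _draw_patient(rng: np.random.Generator, label: str) -> dict:
    p = {
        "r0": rng.uniform(8.0, 11.0),
        "a2": rng.uniform(0.02, 0.08),
        "psi2": rng.uniform(0, 2 * np.pi),
        "a3": rng.uniform(0.02, 0.06),
        "psi3": rng.uniform(0, 2 * np.pi),
        "rot": rng.uniform(0, 2 * np.pi),
    }
    if label == "meningioma":
        p["arc_dir"] = rng.uniform(0, 2 * np.pi)
        p["arc_halfwidth"] = rng.uniform(0.7, 1.1)  # radians
        p["rim_gap"] = rng.uniform(0.5, 1.5)
        p["rim_sigma"] = rng.uniform(1.0, 1.6)
    elif label == "glioma":
        p["core_frac"] = rng.uniform(0.45, 0.6)
        p["halo_frac"] = rng.uniform(1.35, 1.55)
        p["tex_seed"] = int(rng.integers(0, 2**31 - 1))
    else:  # pituitary
        p["lm_dir"] = rng.uniform(0, 2 * np.pi)
        p["lm_dist_extra"] = rng.uniform(5.0, 7.0)
        p["lm_radius"] = rng.uniform(2.0, 3.0)
    return p


def _patient_extent(label: str, p: dict) -> float:
    """Half-size of the square guaranteed to contain the full motif."""
    rmax = p["r0"] * (1.0 + p["a2"] + p["a3"])
    if label == "meningioma":
        return rmax + p["rim_gap"] + 3.5 * p["rim_sigma"]
    if label == "glioma":
        return p["halo_frac"] * rmax + 3.0
    return rmax + p["lm_dist_extra"] + p["lm_radius"] + 2.0


def _render_slice(shape, label, p, cy, cx, scale, drot, rng) -> np.ndarray:
    rows, cols = shape
    yy, xx = np.mgrid[0:rows, 0:cols].astype(float)
    dy, dx = yy - cy, xx - cx
    r = np.hypot(dy, dx) / scale
    phi = np.arctan2(dy, dx) - p["rot"] - drot

    img = np.full(shape, 0.08)
    R = _radius_profile(phi, p["r0"], p["a2"], p["psi2"], p["a3"], p["psi3"])
    if label == "meningioma":
        img = np.maximum(img, 0.75 * _soft_disc(r, R, 0.8))
        ang = _wrap_angle(phi + p["rot"] + drot - p["arc_dir"])
        window = np.exp(-((ang / p["arc_halfwidth"]) ** 2))
        rim = 0.95 * np.exp(-((r - (R + p["rim_gap"])) ** 2) / (2 * p["rim_sigma"] ** 2))
        img = np.maximum(img, rim * window)
    elif label == "glioma":
        tex_rng = np.random.default_rng(p["tex_seed"])
        tex = gaussian_filter(tex_rng.normal(size=shape), 1.5)
        tex *= 0.15 / (tex.std() + 1e-12)
        halo = 0.5 * _soft_disc(r, p["halo_frac"] * R, 1.2)
        body = _soft_disc(r, R, 0.8)
        core = _soft_disc(r, p["core_frac"] * R, 0.8)
        interior = np.clip(0.72 + tex - 0.35 * core, 0.0, 1.0)
        img = np.maximum(img, np.maximum(halo, body * interior))
    else:  # pituitary
        img = np.maximum(img, 0.78 * _soft_disc(r, R, 0.8))
        lm_d = (p["r0"] + p["lm_dist_extra"]) * scale
        a = p["lm_dir"] + drot
        lmy, lmx = cy + lm_d * math.sin(a), cx + lm_d * math.cos(a)
        r2 = np.hypot(yy - lmy, xx - lmx)
        img = np.maximum(img, 0.95 * _soft_disc(r2, p["lm_radius"] * scale, 0.6))
    return np.clip(img, 0.0, 1.0)


def _bias_field(shape, amplitude, rng) -> np.ndarray:
    # low-order multiplicative polynomial, normalized to peak |amplitude|
    rows, cols = shape
    y = np.linspace(-1, 1, rows)[:, None]
    x = np.linspace(-1, 1, cols)[None, :]
    c = rng.uniform(-1, 1, size=5)
    poly = c[0] * x + c[1] * y + c[2] * x * y + c[3] * x**2 + c[4] * y**2
    peak = np.abs(poly).max()
    if peak < 1e-12 or amplitude == 0:
        return np.ones(shape)
    return 1.0 + amplitude * poly / peak


def generate_phantoms(config: PhantomConfig) -> list[ImageRecord]:
    """Generate the full labeled phantom dataset described by ``config``.

    Returns ``3 * n_patients_per_class * slices_per_patient`` records; each
    patient's slices share one class label and one base geometry.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    rows, cols = config.image_size
    m_lo, m_hi = config.roi_margin_range
    records: list[ImageRecord] = []
    pid = 0
    for label in CLASS_LABELS:
        for _ in range(config.n_patients_per_class):
            p = _draw_patient(rng, label)
            ext = _patient_extent(label, p)
            pad = ext + m_hi + 2.5  # slice jitter stays within 2 px
            if pad >= rows / 2 or pad >= cols / 2:
                raise ConfigurationError(
                    f"image {config.image_size} too small for motif extent "
                    f"{ext:.1f} plus margin"
                )
            cy0 = rng.uniform(pad, rows - pad)
            cx0 = rng.uniform(pad, cols - pad)
            patient_id = f"P{pid:04d}"
            for s in range(config.slices_per_patient):
                cy = cy0 + rng.uniform(-1.5, 1.5)
                cx = cx0 + rng.uniform(-1.5, 1.5)
                scale = rng.uniform(0.95, 1.05)
                drot = rng.uniform(-0.15, 0.15)
                img = _render_slice(
                    config.image_size, label, p, cy, cx, scale, drot, rng
                )
                img *= _bias_field(config.image_size, config.bias_amplitude, rng)
                if config.noise_sd > 0:
                    img = img + rng.normal(0.0, config.noise_sd, size=img.shape)
                img = np.clip(img, 0.0, None)
                margin = int(rng.integers(m_lo, m_hi + 1))
                half = ext + margin
                r0 = max(0, int(round(cy - half)))
                c0 = max(0, int(round(cx - half)))
                r1 = min(rows, int(round(cy + half)))
                c1 = min(cols, int(round(cx + half)))
                records.append(
                    ImageRecord(
                        image=img,
                        roi=(r0, c0, r1 - r0, c1 - c0),
                        label=label,
                        patient_id=patient_id,
                        slice_index=s,
                    )
                )
            pid += 1
    return records


# ---------------------------------------------------------------------------
# plain-text-friendly persistence: 16-bit PNG slices + one CSV metadata table

META_COLUMNS = (
    "image_path",
    "patient_id",
    "label",
    "roi_row0",
    "roi_col0",
    "roi_height",
    "roi_width",
)


def save_phantoms(records: list[ImageRecord], out_dir: str | Path) -> Path:
    """Write slices as 16-bit grayscale PNGs plus ``metadata.csv``; returns the CSV path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta_path = out / "metadata.csv"
    with open(meta_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(META_COLUMNS)
        for i, rec in enumerate(records):
            name = f"{rec.patient_id}_s{rec.slice_index}_{i:05d}.png"
            arr = np.clip(np.round(rec.image * PNG_SCALE), 0, 65535).astype(np.uint16)
            Image.fromarray(arr).save(out / name)
            writer.writerow((name, rec.patient_id, rec.label) + rec.roi)
    return meta_path


def load_records(meta_csv: str | Path) -> list[ImageRecord]:
    """Read a metadata CSV (paths relative to its directory) back into records."""
    meta_csv = Path(meta_csv)
    root = meta_csv.parent
    records = []
    with open(meta_csv, newline="") as fh:
        for row in csv.DictReader(fh):
            img = np.asarray(Image.open(root / row["image_path"]), dtype=float)
            img /= PNG_SCALE
            records.append(
                ImageRecord(
                    image=img,
                    roi=(
                        int(row["roi_row0"]),
                        int(row["roi_col0"]),
                        int(row["roi_height"]),
                        int(row["roi_width"]),
                    ),
                    label=row["label"],
                    patient_id=row["patient_id"],
                    path=row["image_path"],
                )
            )
    return records
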