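"""Seeded synthetic mammogram-mass ROIs with class-dependent structure.

The generator emulates the two morphological regimes a benign/malignant
classifier must separate: benign masses are smooth, round-to-oval, with a
long-correlation-length internal texture; malignant masses are irregular and
spiculated (star-convex boundaries with radial spikes), with sharper contrast
and a short-correlation-length texture. Clinical covariates (shape, margin,
breast composition, age, mass size) are drawn from class-conditional
distributions so they correlate with the label the way a clinical table does.

Everything is driven by one integer seed, so any pipeline stage can be tested
bit-reproducibly without downloading data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import ndimage

from .preprocess import MammogramROI

__all__ = [
    "ClassImagingParams",
    "ClassClinicalParams",
    "SyntheticSpec",
    "generate_mass_image",
    "generate_boundary",
    "generate_clinical",
    "generate_dataset",
    "write_dataset",
    "load_dataset",
]


@dataclass(frozen=True)
class ClassImagingParams:
    """Morphology and texture of one class's masses (pixel units)."""

    radius_mean: float
    radius_sd: float
    boundary_wobble: float  # low-frequency boundary perturbation amplitude (fraction of radius)
    n_spicules_base: int  # spicule count = base + Poisson(poisson_rate)
    n_spicules_poisson: float
    spicule_len_frac: float  # spike length as a fraction of the radius
    spicule_width: float  # angular width (radians) of each spike
    texture_corr_len: float  # Gaussian-random-field correlation length (px)
    texture_amp: float  # texture amplitude, 16-bit counts
    base_intensity: float  # mean mass intensity, 16-bit counts
    contrast: float  # multiplicative contrast boost on the texture


@dataclass(frozen=True)
class ClassClinicalParams:
    """Class-conditional clinical covariate distributions."""

    shape_probs: tuple[float, ...]  # codes 1..3
    margin_probs: tuple[float, ...]  # codes 1..5
    composition_probs: tuple[float, ...]  # codes 1..4
    age_mean: float
    age_sd: float


BENIGN_IMAGING = ClassImagingParams(
    radius_mean=70.0,
    radius_sd=12.0,
    boundary_wobble=0.04,
    n_spicules_base=0,
    n_spicules_poisson=0.0,
    spicule_len_frac=0.0,
    spicule_width=0.06,
    texture_corr_len=6.0,
    texture_amp=5000.0,
    base_intensity=26000.0,
    contrast=1.0,
)
MALIGNANT_IMAGING = ClassImagingParams(
    radius_mean=60.0,
    radius_sd=12.0,
    boundary_wobble=0.18,
    n_spicules_base=4,
    n_spicules_poisson=8.0,
    spicule_len_frac=0.55,
    spicule_width=0.06,
    texture_corr_len=1.5,
    texture_amp=5000.0,
    base_intensity=26000.0,
    contrast=1.4,
)
BENIGN_CLINICAL = ClassClinicalParams(
    shape_probs=(0.4, 0.4, 0.2),
    margin_probs=(0.5, 0.2, 0.15, 0.1, 0.05),
    composition_probs=(0.25, 0.35, 0.25, 0.15),
    age_mean=45.0,
    age_sd=10.0,
)
MALIGNANT_CLINICAL = ClassClinicalParams(
    shape_probs=(0.1, 0.2, 0.7),
    margin_probs=(0.05, 0.1, 0.1, 0.25, 0.5),
    composition_probs=(0.15, 0.25, 0.35, 0.25),
    age_mean=58.0,
    age_sd=10.0,
)


@dataclass(frozen=True)
class SyntheticSpec:
    n_benign: int = 20
    n_malignant: int = 20
    image_size: int = 320  # pre-crop canvas
    benign: ClassImagingParams = BENIGN_IMAGING
    malignant: ClassImagingParams = MALIGNANT_IMAGING
    benign_clinical: ClassClinicalParams = BENIGN_CLINICAL
    malignant_clinical: ClassClinicalParams = MALIGNANT_CLINICAL
    noise_sd: float = 400.0  # additive Gaussian noise inside the mass, 16-bit counts
    margin_px: tuple[int, int] = (4, 14)  # random zero margin around the mass bbox
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_benign < 1 or self.n_malignant < 1:
            raise ValueError("need at least one ROI per class")
        for probs in (
            self.benign_clinical.shape_probs,
            self.benign_clinical.margin_probs,
            self.benign_clinical.composition_probs,
            self.malignant_clinical.shape_probs,
            self.malignant_clinical.margin_probs,
            self.malignant_clinical.composition_probs,
        ):
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError("clinical covariate probabilities must sum to 1")

    def params_for(self, label: str) -> ClassImagingParams:
        return self.malignant if label == "malignant" else self.benign

    def clinical_for(self, label: str) -> ClassClinicalParams:
        return self.malignant_clinical if label == "malignant" else self.benign_clinical

    def null(self) -> "SyntheticSpec":
        """A no-signal variant: both classes share the benign distributions."""
        return replace(
            self,
            malignant=self.benign,
            malignant_clinical=self.benign_clinical,
        )


def generate_boundary(label: str, spec: SyntheticSpec, rng: np.random.Generator, n_angles: int = 720) -> np.ndarray:
    """Radius-versus-angle profile r(phi) of one mass boundary."""
    p = spec.params_for(label)
    R0 = max(12.0, rng.normal(p.radius_mean, p.radius_sd))
    phi = np.linspace(0, 2 * np.pi, n_angles, endpoint=False)
    # ellipse factor
    q = rng.uniform(0.6, 1.0)
    ang = rng.uniform(0, np.pi)
    ellipse = 1.0 / np.sqrt((np.cos(phi - ang)) ** 2 + (np.sin(phi - ang) / q) ** 2)
    # smooth low-frequency wobble
    wob = np.zeros_like(phi)
    for harmonic in (2, 3, 4, 5):
        wob += rng.normal(0, 1) * np.cos(harmonic * phi) + rng.normal(0, 1) * np.sin(harmonic * phi)
    wob *= p.boundary_wobble / 2.0
    r = R0 * ellipse * (1.0 + wob)
    # radial spicules
    n_sp = p.n_spicules_base + (rng.poisson(p.n_spicules_poisson) if p.n_spicules_poisson > 0 else 0)
    for _ in range(n_sp):
        center = rng.uniform(0, 2 * np.pi)
        length = p.spicule_len_frac * R0 * rng.uniform(0.5, 1.0)
        d = np.angle(np.exp(1j * (phi - center)))
        r += length * np.exp(-0.5 * (d / p.spicule_width) ** 2)
    return np.clip(r, 5.0, spec.image_size / 2.0 - 2.0)


def _texture_field(shape: tuple[int, int], corr_len: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian random field with the given correlation length."""
    noise = rng.standard_normal(shape)
    field = ndimage.gaussian_filter(noise, sigma=corr_len, mode="wrap")
    sd = field.std()
    return field / sd if sd > 0 else field


def generate_mass_image(label: str, spec: SyntheticSpec, rng: np.random.Generator) -> MammogramROI:
    """One 16-bit synthetic mass ROI: star-convex bright mass on black background."""
    if label not in {"benign", "malignant"}:
        raise ValueError(f"unknown class label: {label}")
    p = spec.params_for(label)
    n = spec.image_size
    r_profile = generate_boundary(label, spec, rng, n_angles=720)

    yy, xx = np.mgrid[0:n, 0:n].astype(np.float64)
    cy = cx = (n - 1) / 2.0
    rho = np.hypot(yy - cy, xx - cx)
    phi = np.arctan2(yy - cy, xx - cx) % (2 * np.pi)
    idx = np.floor(phi / (2 * np.pi) * r_profile.size).astype(int) % r_profile.size
    inside = rho <= r_profile[idx]

    tex = _texture_field((n, n), p.texture_corr_len, rng)
    falloff = 0.55 + 0.45 * np.clip(1.0 - rho / (r_profile[idx] + 1e-9), 0.0, 1.0)
    img = np.zeros((n, n), dtype=np.float64)
    img[inside] = (
        p.base_intensity * falloff[inside]
        + p.contrast * p.texture_amp * tex[inside]
        + rng.normal(0, spec.noise_sd, inside.sum())
    )
    img = np.clip(img, 0, 65535)

    # crop to the mass bounding box plus a random zero margin (the "raw ROI")
    rows = np.flatnonzero(inside.any(axis=1))
    cols = np.flatnonzero(inside.any(axis=0))
    m = rng.integers(spec.margin_px[0], spec.margin_px[1] + 1)
    r0, r1 = max(0, rows[0] - m), min(n, rows[-1] + 1 + m)
    c0, c1 = max(0, cols[0] - m), min(n, cols[-1] + 1 + m)
    patch = np.rint(img[r0:r1, c0:c1]).astype(np.int64)
    return MammogramROI(pixels=patch, label=label)


def generate_clinical(
    label: str,
    spec: SyntheticSpec,
    rng: np.random.Generator,
    roi_shape: tuple[int, int] | None = None,
) -> dict:
    """One clinical row with class-conditional covariates.

    ``mass_size`` is the diagonal length of the ROI rectangle when its shape is
    given, matching how mass size is read off a cropped ROI.
    """
    c = spec.clinical_for(label)
    shape_code = int(rng.choice(np.arange(1, 4), p=c.shape_probs))
    margin_code = int(rng.choice(np.arange(1, 6), p=c.margin_probs))
    composition_code = int(rng.choice(np.arange(1, 5), p=c.composition_probs))
    age = float(np.clip(rng.normal(c.age_mean, c.age_sd), 20.0, 80.0))
    if roi_shape is not None:
        mass_size = float(np.hypot(roi_shape[0], roi_shape[1]))
    else:
        mass_size = float(np.hypot(*(2 * [2.0 * spec.params_for(label).radius_mean])))
    return {
        "shape": shape_code,
        "margin": margin_code,
        "composition": composition_code,
        "age": age,
        "mass_size": mass_size,
        "label": label,
    }


@dataclass
class SyntheticDataset:
    rois: list[MammogramROI]
    clinical: pd.DataFrame  # indexed by roi_id; shape/margin/composition/age/mass_size + label
    labels: pd.Series  # roi_id -> "benign"/"malignant"


def _label_stream(spec: SyntheticSpec) -> Iterator[str]:
    for i in range(max(spec.n_benign, spec.n_malignant)):
        if i < spec.n_benign:
            yield "benign"
        if i < spec.n_malignant:
            yield "malignant"


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Paired images + clinical rows + labels, fully determined by spec.seed.

    ROIs are grouped two-per-patient (CC and MLO views of the same synthetic
    patient) so patient-level splitting is exercisable.
    """
    rng = np.random.default_rng(spec.seed)
    rois: list[MammogramROI] = []
    rows: list[dict] = []
    counters = {"benign": 0, "malignant": 0}
    for label in _label_stream(spec):
        i = counters[label]
        counters[label] += 1
        roi = generate_mass_image(label, spec, rng)
        roi.roi_id = f"{label[0]}{i:04d}"
        roi.patient_id = f"P{label[0]}{i // 2:04d}"
        roi.view = "CC" if i % 2 == 0 else "MLO"
        rec = generate_clinical(label, spec, rng, roi_shape=roi.pixels.shape)
        rec["roi_id"] = roi.roi_id
        rec["patient_id"] = roi.patient_id
        rec["view"] = roi.view
        rois.append(roi)
        rows.append(rec)
    clinical = pd.DataFrame(rows).set_index("roi_id")
    labels = clinical["label"]
    return SyntheticDataset(rois=rois, clinical=clinical, labels=labels)


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> None:
    """On-disk layout the real-data loader expects: 16-bit PNGs + clinical CSV."""
    from PIL import Image

    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    for roi in dataset.rois:
        img = Image.fromarray(roi.pixels.astype(np.uint16))
        img.save(out / "images" / f"{roi.roi_id}.png")
    dataset.clinical.to_csv(out / "clinical.csv")


def load_dataset(in_dir: str | Path) -> SyntheticDataset:
    """Read back a dataset written by :func:`write_dataset`."""
    from .preprocess import load_roi

    root = Path(in_dir)
    clinical = pd.read_csv(root / "clinical.csv").set_index("roi_id")
    rois = []
    for rid, row in clinical.iterrows():
        roi = load_roi(
            root / "images" / f"{rid}.png",
            metadata={
                "roi_id": rid,
                "patient_id": row.get("patient_id", ""),
                "view": row.get("view", "CC"),
                "label": row["label"],
            },
        )
        rois.append(roi)
    return SyntheticDataset(rois=rois, clinical=clinical, labels=clinical["label"])
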