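"""ROI loading and the five-step preprocessing chain.

A mammogram mass ROI arrives as a rectangular 16-bit grayscale patch cropped by a
radiologist. Before feature extraction it is (1) cropped to remove black
background, (2) min-max normalized to [0, 1], (3) rescaled without deformation
onto a 224x224 zero-padded canvas, (4) assigned to a training or test cohort by
a seeded random split, and (5) — training cohort only — expanded with the seven
non-identity flip/rotation symmetries of the square.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from skimage.transform import resize as _sk_resize

__all__ = [
    "MammogramROI",
    "PreprocessedROI",
    "CohortSplit",
    "DecodeError",
    "EmptyContentError",
    "load_roi",
    "crop_background",
    "min_max_normalize",
    "pad_resize",
    "dihedral_augment",
    "split_cohorts",
    "write_split_csv",
]

CANVAS_SIZE = 224
#: train fraction mirroring a 744/244 cohort split
DEFAULT_TRAIN_FRACTION = 744 / 988


class DecodeError(ValueError):
    """Raised when a file cannot be decoded as a grayscale image."""


class EmptyContentError(ValueError):
    """Raised when background cropping leaves no content."""


@dataclass
class MammogramROI:
    """Raw cropped mass patch with metadata.

    ``pixels`` is a 2-D nonnegative integer array on a 16-bit gray scale.
    """

    pixels: np.ndarray
    patient_id: str = ""
    view: str = "CC"
    label: str | None = None  # "benign" | "malignant" | None
    birads: int | None = None
    source_path: str = ""
    roi_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 2 or px.shape[1] < 2:
            raise ValueError("ROI pixels must be a 2-D array with >=2 rows and columns")
        if px.min() < 0 or px.max() > 65535:
            raise ValueError("ROI intensities must lie within [0, 65535]")
        self.pixels = px
        if not self.roi_id:
            self.roi_id = self.source_path or f"roi-{id(self):x}"


@dataclass
class PreprocessedROI:
    """A 224x224 canvas in [0, 1] with the content rectangle recorded."""

    pixels: np.ndarray
    scale_factor: float
    pad_offsets: tuple[int, int]  # (top, left)
    content_shape: tuple[int, int]  # (height, width) of the scaled content
    parent: MammogramROI | None = None

    @property
    def roi_id(self) -> str:
        return self.parent.roi_id if self.parent is not None else ""

    @property
    def label(self) -> str | None:
        return self.parent.label if self.parent is not None else None

    def content_slice(self) -> tuple[slice, slice]:
        t, l = self.pad_offsets
        h, w = self.content_shape
        return slice(t, t + h), slice(l, l + w)

    def content_mask(self) -> np.ndarray:
        m = np.zeros(self.pixels.shape, dtype=bool)
        m[self.content_slice()] = True
        return m

    def content(self) -> np.ndarray:
        return self.pixels[self.content_slice()]


@dataclass
class CohortSplit:
    train_ids: list[str]
    test_ids: list[str]
    seed: int
    mode: Literal["by_roi", "by_patient"]


def load_roi(path: str | Path, metadata: dict | None = None) -> MammogramROI:
    """Read a DICOM, PNG or TIFF grayscale ROI without rescaling intensities.

    DICOM RescaleSlope/RescaleIntercept are applied when present, and
    MONOCHROME1 images are inverted so that bright always means dense tissue.
    Color images are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise DecodeError(f"no such file: {path}")
    meta = dict(metadata or {})
    suffix = path.suffix.lower()
    if suffix in {".dcm", ".dicom"} or _looks_like_dicom(path):
        pixels = _read_dicom(path)
    else:
        pixels = _read_pil(path)
    return MammogramROI(
        pixels=pixels,
        patient_id=str(meta.get("patient_id", "")),
        view=str(meta.get("view", "CC")),
        label=meta.get("label"),
        birads=meta.get("birads"),
        source_path=str(path),
        roi_id=str(meta.get("roi_id", "")) or path.stem,
    )


def _looks_like_dicom(path: Path) -> bool:
    with open(path, "rb") as fh:
        head = fh.read(132)
    return len(head) >= 132 and head[128:132] == b"DICM"


def _read_dicom(path: Path) -> np.ndarray:
    import pydicom

    try:
        ds = pydicom.dcmread(path)
        arr = ds.pixel_array
    except Exception as exc:  # pragma: no cover - pydicom error variety
        raise DecodeError(f"cannot decode DICOM {path}: {exc}") from exc
    if arr.ndim != 2:
        raise DecodeError(f"unsupported DICOM layout (ndim={arr.ndim}); expected single-frame grayscale")
    arr = arr.astype(np.float64)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    arr = arr * slope + intercept
    if str(getattr(ds, "PhotometricInterpretation", "MONOCHROME2")) == "MONOCHROME1":
        arr = arr.max() - arr
    arr = np.clip(np.rint(arr), 0, 65535).astype(np.int64)
    return arr


def _read_pil(path: Path) -> np.ndarray:
    from PIL import Image

    try:
        img = Image.open(path)
        img.load()
    except Exception as exc:
        raise DecodeError(f"cannot decode image {path}: {exc}") from exc
    if img.mode in {"RGB", "RGBA", "P", "CMYK", "YCbCr"}:
        raise DecodeError(f"unsupported color image (mode={img.mode}); grayscale required")
    arr = np.asarray(img)
    if arr.ndim != 2:
        raise DecodeError(f"unsupported image layout with shape {arr.shape}")
    arr = np.clip(np.rint(arr.astype(np.float64)), 0, 65535).astype(np.int64)
    return arr


def crop_background(roi: MammogramROI, threshold: float = 0.0) -> MammogramROI:
    """Crop to the minimal bounding box of pixels above ``threshold * max``.

    ``threshold`` is a fraction of the image maximum; the default keeps every
    strictly positive pixel.
    """
    px = roi.pixels
    cut = threshold * float(px.max())
    mask = px > cut
    if not mask.any():
        raise EmptyContentError("no pixels above the background threshold")
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    cropped = px[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]
    return replace(roi, pixels=cropped)


def min_max_normalize(pixels: np.ndarray) -> np.ndarray:
    """Linear rescale of intensities onto [0, 1].

    A constant image has no dynamic range; it maps to all zeros with a warning
    rather than dividing by zero.
    """
    px = np.asarray(pixels, dtype=np.float64)
    if px.size == 0:
        raise ValueError("empty image")
    lo, hi = float(px.min()), float(px.max())
    if hi == lo:
        warnings.warn("constant image: min-max normalization returns all zeros", RuntimeWarning, stacklevel=2)
        return np.zeros_like(px)
    return (px - lo) / (hi - lo)


def pad_resize(
    pixels: np.ndarray,
    target: int = CANVAS_SIZE,
    parent: MammogramROI | None = None,
) -> PreprocessedROI:
    """Scale the longer side to ``target`` (bilinear, aspect preserved) and
    center the result on a ``target`` x ``target`` zero canvas."""
    if target < 2:
        raise ValueError("target canvas size must be >= 2")
    px = np.asarray(pixels, dtype=np.float64)
    if px.ndim != 2:
        raise ValueError("expected a 2-D image")
    h, w = px.shape
    scale = target / max(h, w)
    if h >= w:
        new_h, new_w = target, max(1, int(round(w * scale)))
    else:
        new_h, new_w = max(1, int(round(h * scale))), target
    if (new_h, new_w) == (h, w):
        content = px.copy()
    else:
        content = _sk_resize(px, (new_h, new_w), order=1, anti_aliasing=False, preserve_range=True)
    content = np.clip(content, 0.0, 1.0)
    top = (target - new_h) // 2
    left = (target - new_w) // 2
    canvas = np.zeros((target, target), dtype=np.float64)
    canvas[top : top + new_h, left : left + new_w] = content
    return PreprocessedROI(
        pixels=canvas,
        scale_factor=scale,
        pad_offsets=(top, left),
        content_shape=(new_h, new_w),
        parent=parent,
    )


# the 7 non-identity elements of the dihedral-4 group, as numpy index ops
_DIHEDRAL_OPS = (
    lambda a: np.rot90(a, 1),
    lambda a: np.rot90(a, 2),
    lambda a: np.rot90(a, 3),
    lambda a: np.fliplr(a),
    lambda a: np.rot90(np.fliplr(a), 1),
    lambda a: np.rot90(np.fliplr(a), 2),
    lambda a: np.rot90(np.fliplr(a), 3),
)


def dihedral_augment(roi: PreprocessedROI) -> list[PreprocessedROI]:
    """The 7 label-preserving flip/rotation variants of a square canvas.

    Together with the original these form the full 8-element orbit of the
    square's symmetry group.
    """
    n = roi.pixels.shape[0]
    if roi.pixels.shape[0] != roi.pixels.shape[1]:
        raise ValueError("dihedral augmentation requires a square canvas")
    out = []
    base_mask = roi.content_mask()
    for op in _DIHEDRAL_OPS:
        new_px = np.ascontiguousarray(op(roi.pixels))
        new_mask = op(base_mask)
        rows = np.flatnonzero(new_mask.any(axis=1))
        cols = np.flatnonzero(new_mask.any(axis=0))
        out.append(
            PreprocessedROI(
                pixels=new_px,
                scale_factor=roi.scale_factor,
                pad_offsets=(int(rows[0]), int(cols[0])),
                content_shape=(int(rows[-1] - rows[0] + 1), int(cols[-1] - cols[0] + 1)),
                parent=roi.parent,
            )
        )
    return out


def split_cohorts(
    dataset: Sequence[MammogramROI],
    train_fraction: float = DEFAULT_TRAIN_FRACTION,
    seed: int = 0,
    mode: Literal["by_roi", "by_patient"] = "by_roi",
    stratify: bool = True,
) -> CohortSplit:
    """Seeded random train/test split of a list of ROIs.

    ``by_roi`` splits ROIs independently (optionally stratified by label);
    ``by_patient`` keeps every ROI of a patient on the same side, so no patient
    leaks across cohorts.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    rng = np.random.default_rng(seed)
    ids = [r.roi_id for r in dataset]
    if len(set(ids)) != len(ids):
        raise ValueError("roi_id values must be unique for splitting")

    if mode == "by_patient":
        patients: dict[str, list[str]] = {}
        for r in dataset:
            patients.setdefault(r.patient_id, []).append(r.roi_id)
        order = sorted(patients)
        rng.shuffle(order)
        n_target = int(round(train_fraction * len(dataset)))
        train: list[str] = []
        test: list[str] = []
        for pid in order:
            bucket = train if len(train) < n_target else test
            bucket.extend(patients[pid])
        if not test:  # at least one patient held out
            test.extend(patients[order[-1]])
            train = [i for i in train if i not in set(test)]
    elif mode == "by_roi":
        if stratify and any(r.label is not None for r in dataset):
            train, test = [], []
            groups: dict[object, list[str]] = {}
            for r in dataset:
                groups.setdefault(r.label, []).append(r.roi_id)
            for _, members in sorted(groups.items(), key=lambda kv: str(kv[0])):
                members = list(members)
                rng.shuffle(members)
                k = int(round(train_fraction * len(members)))
                k = min(max(k, 1), len(members) - 1) if len(members) > 1 else k
                train.extend(members[:k])
                test.extend(members[k:])
        else:
            order = list(ids)
            rng.shuffle(order)
            k = int(round(train_fraction * len(order)))
            train, test = order[:k], order[k:]
    else:
        raise ValueError(f"unknown split mode: {mode}")
    return CohortSplit(train_ids=sorted(train), test_ids=sorted(test), seed=seed, mode=mode)


def write_split_csv(split: CohortSplit, path: str | Path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["roi_id", "cohort"])
        for rid in split.train_ids:
            w.writerow([rid, "train"])
        for rid in split.test_ids:
            w.writerow([rid, "test"])
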