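"""Hand-crafted radiomics features: 455 texture/shape/statistics values per ROI.

Nine families are concatenated in a fixed, named order:

==========  ====  =========================================================
family      dim   contents
==========  ====  =========================================================
hist           9  first-order intensity statistics
hu             7  Hu moment invariants (signed log10 magnitude)
glcm          56  14 Haralick descriptors x 4 directions (distance 1)
glgcm         15  gray-gradient co-occurrence descriptors
glds           4  gray-level difference statistics
glrlm         44  11 run-length descriptors x 4 directions
lbp          256  8-neighbor local binary pattern histogram
gmrf           4  second-order Gaussian Markov random field coefficients
gabor         60  20-filter Gabor bank (4 wavelengths x 5 orientations),
                  mean/std/energy of response magnitude
==========  ====  =========================================================

All statistics are computed on the content region only; the zero frame added
by padding is excluded so it cannot dominate co-occurrence counts. Entropies
are in bits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .preprocess import PreprocessedROI

__all__ = [
    "QuantizedImage",
    "HandcraftedFeatureVector",
    "FeatureExtractionError",
    "FAMILY_DIMS",
    "quantize_gray",
    "histogram_features",
    "glcm_features",
    "glgcm_features",
    "glds_features",
    "glrlm_features",
    "lbp_features",
    "gmrf_features",
    "hu_moments",
    "gabor_features",
    "extract_handcrafted",
    "feature_names",
    "extractor_config",
]

# contract: family order and dimensions; total must stay 455
FAMILY_DIMS = (
    ("hist", 9),
    ("hu", 7),
    ("glcm", 56),
    ("glgcm", 15),
    ("glds", 4),
    ("glrlm", 44),
    ("lbp", 256),
    ("gmrf", 4),
    ("gabor", 60),
)
TOTAL_FEATURES = sum(d for _, d in FAMILY_DIMS)

GLCM_LEVELS = 64
GLGCM_LEVELS = (16, 16)
GABOR_WAVELENGTHS = (4, 8, 16, 32)
GABOR_ORIENTATIONS_DEG = (0, 36, 72, 108, 144)

_DIRECTIONS = {"d0": (0, 1), "d45": (-1, 1), "d90": (1, 0), "d135": (1, 1)}

_HARALICK_NAMES = (
    "energy",
    "contrast",
    "correlation",
    "variance",
    "idm",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "difference_variance",
    "difference_entropy",
    "imc1",
    "imc2",
    "mcc",
)
_GLRLM_NAMES = ("sre", "lre", "gln", "rln", "rp", "lgre", "hgre", "srlge", "srhge", "lrlge", "lrhge")
_HIST_NAMES = ("mean", "variance", "skewness", "kurtosis", "energy", "entropy", "minimum", "maximum", "median")
_GLGCM_NAMES = (
    "small_gradient_dominance",
    "large_gradient_dominance",
    "gray_asymmetry",
    "gradient_asymmetry",
    "energy",
    "gray_mean",
    "gradient_mean",
    "gray_variance",
    "gradient_variance",
    "correlation",
    "gray_entropy",
    "gradient_entropy",
    "joint_entropy",
    "inertia",
    "idm",
)
_GLDS_NAMES = ("mean", "contrast", "asm", "entropy")


class FeatureExtractionError(RuntimeError):
    """A family-level failure, tagged with the family that raised it."""

    def __init__(self, family: str, message: str):
        super().__init__(f"{family}: {message}")
        self.family = family


@dataclass
class QuantizedImage:
    levels: int
    pixels: np.ndarray  # integer codes, full canvas; only content_mask cells meaningful
    content_mask: np.ndarray


@dataclass
class HandcraftedFeatureVector:
    values: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.names),):
            raise ValueError("values and names length mismatch")

    def family(self, name: str) -> np.ndarray:
        start = 0
        for fam, dim in FAMILY_DIMS:
            if fam == name:
                return self.values[start : start + dim]
            start += dim
        raise KeyError(name)


def feature_names() -> tuple[str, ...]:
    names: list[str] = []
    names += [f"hist.{s}" for s in _HIST_NAMES]
    names += [f"hu.h{i}" for i in range(1, 8)]
    for d in _DIRECTIONS:
        names += [f"glcm.{s}.{d}" for s in _HARALICK_NAMES]
    names += [f"glgcm.{s}" for s in _GLGCM_NAMES]
    names += [f"glds.{s}" for s in _GLDS_NAMES]
    for d in _DIRECTIONS:
        names += [f"glrlm.{s}.{d}" for s in _GLRLM_NAMES]
    names += [f"lbp.code{i:03d}" for i in range(256)]
    names += ["gmrf.horizontal", "gmrf.vertical", "gmrf.diagonal", "gmrf.antidiagonal"]
    for lam in GABOR_WAVELENGTHS:
        for ori in GABOR_ORIENTATIONS_DEG:
            for stat in ("mean", "std", "energy"):
                names.append(f"gabor.s{lam}_o{ori}_{stat}")
    assert len(names) == TOTAL_FEATURES
    return tuple(names)


FEATURE_NAMES = feature_names()


def _xlog2(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def _entropy(p: np.ndarray) -> float:
    return float(-_xlog2(p).sum())


# ---------------------------------------------------------------------------
# quantization


def quantize_gray(roi: PreprocessedROI, levels: int = GLCM_LEVELS) -> QuantizedImage:
    """Uniformly bin the content's [min, max] intensity range into ``levels``.

    Quantization is monotone in intensity; constant content maps to code 0.
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    mask = roi.content_mask()
    vals = roi.pixels[mask]
    if vals.size == 0:
        raise ValueError("empty content")
    codes = np.zeros(roi.pixels.shape, dtype=np.int64)
    lo, hi = float(vals.min()), float(vals.max())
    if hi > lo:
        q = np.floor((roi.pixels - lo) / (hi - lo) * levels).astype(np.int64)
        codes = np.clip(q, 0, levels - 1)
        codes[~mask] = 0
    return QuantizedImage(levels=levels, pixels=codes, content_mask=mask)


# ---------------------------------------------------------------------------
# first-order histogram


def histogram_features(roi: PreprocessedROI) -> np.ndarray:
    vals = roi.content().ravel().astype(np.float64)
    if vals.size == 0:
        raise ValueError("empty content")
    mean = vals.mean()
    var = vals.var()
    if var > 0:
        z = (vals - mean) / np.sqrt(var)
        skew = float((z**3).mean())
        kurt = float((z**4).mean() - 3.0)
    else:
        skew = kurt = 0.0
    hist, _ = np.histogram(vals, bins=256, range=(0.0, 1.0))
    p = hist / hist.sum()
    return np.array(
        [mean, var, skew, kurt, float((p**2).sum()), _entropy(p), vals.min(), vals.max(), float(np.median(vals))]
    )


# ---------------------------------------------------------------------------
# GLCM


def _pair_counts(q: QuantizedImage, offset: tuple[int, int]) -> np.ndarray:
    """Symmetric co-occurrence counts for one displacement, masked."""
    dr, dc = offset
    codes, mask = q.pixels, q.content_mask
    H, W = codes.shape
    r0, r1 = max(0, -dr), min(H, H - dr)
    c0, c1 = max(0, -dc), min(W, W - dc)
    a = codes[r0:r1, c0:c1]
    b = codes[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    valid = mask[r0:r1, c0:c1] & mask[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    av, bv = a[valid], b[valid]
    L = q.levels
    counts = np.bincount(av * L + bv, minlength=L * L).reshape(L, L).astype(np.float64)
    return counts + counts.T


def _haralick(P: np.ndarray) -> np.ndarray:
    L = P.shape[0]
    i = np.arange(L, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mx = float((i * px).sum())
    my = float((i * py).sum())
    sx = float(np.sqrt(((i - mx) ** 2 * px).sum()))
    sy = float(np.sqrt(((i - my) ** 2 * py).sum()))

    energy = float((P**2).sum())
    contrast = float(((ii - jj) ** 2 * P).sum())
    if sx > 0 and sy > 0:
        correlation = float(((ii - mx) * (jj - my) * P).sum() / (sx * sy))
    else:
        correlation = 0.0
    variance = float(((ii - mx) ** 2 * P).sum())
    idm = float((P / (1.0 + (ii - jj) ** 2)).sum())

    # i+j and |i-j| marginals
    psum = np.zeros(2 * L - 1)
    np.add.at(psum, (ii + jj).astype(int).ravel(), P.ravel())
    pdiff = np.zeros(L)
    np.add.at(pdiff, np.abs(ii - jj).astype(int).ravel(), P.ravel())
    k_sum = np.arange(2 * L - 1, dtype=np.float64)
    k_diff = np.arange(L, dtype=np.float64)
    sum_average = float((k_sum * psum).sum())
    sum_variance = float(((k_sum - sum_average) ** 2 * psum).sum())
    sum_entropy = _entropy(psum)
    entropy = _entropy(P.ravel())
    diff_mean = float((k_diff * pdiff).sum())
    difference_variance = float(((k_diff - diff_mean) ** 2 * pdiff).sum())
    difference_entropy = _entropy(pdiff)

    # information measures of correlation
    hx, hy = _entropy(px), _entropy(py)
    pxy = np.outer(px, py)
    nz = (P > 0) | (pxy > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        lp = np.where(pxy > 0, np.log2(np.where(pxy > 0, pxy, 1.0)), 0.0)
    hxy1 = float(-(P * lp).sum())
    hxy2 = float(-(pxy * lp).sum())
    denom = max(hx, hy)
    imc1 = (entropy - hxy1) / denom if denom > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy)))))

    # maximal correlation coefficient: sqrt of 2nd-largest eigenvalue of Q
    active = px > 0
    if active.sum() >= 2:
        Pa = P[np.ix_(active, active)]
        pxa, pya = px[active], py[active]
        Q = (Pa / pxa[:, None]) @ (Pa / pya[:, None]).T
        try:
            ev = np.linalg.eigvals(Q)
            ev = np.sort(np.real(ev))
            mcc = float(np.sqrt(max(0.0, min(1.0, ev[-2]))))
        except np.linalg.LinAlgError:  # pragma: no cover
            mcc = 0.0
    else:
        mcc = 0.0

    return np.array(
        [
            energy,
            contrast,
            correlation,
            variance,
            idm,
            sum_average,
            sum_variance,
            sum_entropy,
            entropy,
            difference_variance,
            difference_entropy,
            imc1,
            imc2,
            mcc,
        ]
    )


def glcm_features(q: QuantizedImage) -> np.ndarray:
    """14 Haralick descriptors per direction (0/45/90/135 deg, distance 1)."""
    if q.content_mask.sum() < 4:
        raise ValueError("insufficient content for co-occurrence statistics")
    out = []
    for offset in _DIRECTIONS.values():
        counts = _pair_counts(q, offset)
        total = counts.sum()
        if total == 0:
            raise ValueError("no valid pixel pairs in direction")
        out.append(_haralick(counts / total))
    return np.concatenate(out)


# ---------------------------------------------------------------------------
# GLGCM


def glgcm_features(
    roi: PreprocessedROI, q_levels: int = GLGCM_LEVELS[0], g_levels: int = GLGCM_LEVELS[1]
) -> np.ndarray:
    """Descriptors of the joint gray-value / Sobel-gradient-magnitude histogram."""
    content = roi.content().astype(np.float64)
    if content.shape[0] < 3 or content.shape[1] < 3:
        raise ValueError("content must be at least 3x3")
    gx = ndimage.sobel(content, axis=1, mode="reflect")
    gy = ndimage.sobel(content, axis=0, mode="reflect")
    grad = np.hypot(gx, gy)

    def _codes(a: np.ndarray, lo: float, hi: float, levels: int) -> np.ndarray:
        if hi <= lo:
            return np.zeros(a.shape, dtype=np.int64)
        return np.clip(np.floor((a - lo) / (hi - lo) * levels).astype(np.int64), 0, levels - 1)

    qc = _codes(content, float(content.min()), float(content.max()), q_levels)
    gc = _codes(grad, 0.0, float(grad.max()), g_levels)
    H = np.bincount((qc * g_levels + gc).ravel(), minlength=q_levels * g_levels)
    H = H.reshape(q_levels, g_levels).astype(np.float64)
    H /= H.sum()

    gi = np.arange(1, q_levels + 1, dtype=np.float64)  # gray index, 1-based
    sj = np.arange(1, g_levels + 1, dtype=np.float64)  # gradient index, 1-based
    pg = H.sum(axis=1)
    ps = H.sum(axis=0)
    small_grad = float((ps / sj**2).sum())
    large_grad = float((ps * sj**2).sum())
    gray_asym = float((pg**2).sum())
    grad_asym = float((ps**2).sum())
    energy = float((H**2).sum())
    mg = float((gi * pg).sum())
    ms = float((sj * ps).sum())
    vg = float(((gi - mg) ** 2 * pg).sum())
    vs = float(((sj - ms) ** 2 * ps).sum())
    if vg > 0 and vs > 0:
        corr = float(((gi[:, None] - mg) * (sj[None, :] - ms) * H).sum() / np.sqrt(vg * vs))
    else:
        corr = 0.0
    inertia = float(((gi[:, None] - sj[None, :]) ** 2 * H).sum())
    idm = float((H / (1.0 + (gi[:, None] - sj[None, :]) ** 2)).sum())
    return np.array(
        [
            small_grad,
            large_grad,
            gray_asym,
            grad_asym,
            energy,
            mg,
            ms,
            vg,
            vs,
            corr,
            _entropy(pg),
            _entropy(ps),
            _entropy(H.ravel()),
            inertia,
            idm,
        ]
    )


# ---------------------------------------------------------------------------
# GLDS


def glds_features(q: QuantizedImage) -> np.ndarray:
    """Mean/contrast/ASM/entropy of pooled absolute gray differences."""
    diffs = []
    codes, mask = q.pixels, q.content_mask
    H, W = codes.shape
    for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
        r0, r1 = max(0, -dr), min(H, H - dr)
        c0, c1 = max(0, -dc), min(W, W - dc)
        a = codes[r0:r1, c0:c1]
        b = codes[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        valid = mask[r0:r1, c0:c1] & mask[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        diffs.append(np.abs(a[valid] - b[valid]))
    d = np.concatenate(diffs)
    if d.size == 0:
        raise ValueError("insufficient content for difference statistics")
    p = np.bincount(d, minlength=q.levels).astype(np.float64)
    p /= p.sum()
    k = np.arange(q.levels, dtype=np.float64)
    return np.array([float((k * p).sum()), float((k**2 * p).sum()), float((p**2).sum()), _entropy(p)])


# ---------------------------------------------------------------------------
# GLRLM


def _lines_for_direction(codes: np.ndarray, mask: np.ndarray, direction: str) -> np.ndarray:
    """Stack the scan lines of one direction into rows, padded with -1."""
    a = np.where(mask, codes, -1)
    H, W = a.shape
    if direction == "d0":
        return a
    if direction == "d90":
        return a.T
    ii, jj = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
    if direction == "d135":  # down-right diagonals
        line = jj - ii + (H - 1)
        pos = ii
        canvas = np.full((H + W - 1, H), -1, dtype=np.int64)
    else:  # d45: up-right (anti-)diagonals
        line = ii + jj
        pos = ii
        canvas = np.full((H + W - 1, H), -1, dtype=np.int64)
    canvas[line.ravel(), pos.ravel()] = a.ravel()
    return canvas


def _run_length_matrix(lines: np.ndarray, levels: int, max_len: int) -> np.ndarray:
    """Count maximal constant runs per gray level; padding value -1 is skipped."""
    sep = np.full((lines.shape[0], 1), -1, dtype=np.int64)
    flat = np.concatenate([lines, sep], axis=1).ravel()
    change = np.flatnonzero(np.diff(flat) != 0)
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change, [flat.size - 1]])
    vals = flat[starts]
    lens = ends - starts + 1
    keep = vals >= 0
    vals, lens = vals[keep], np.minimum(lens[keep], max_len)
    R = np.bincount(vals * max_len + (lens - 1), minlength=levels * max_len).astype(np.float64)
    return R.reshape(levels, max_len)


def glrlm_features(q: QuantizedImage) -> np.ndarray:
    """11 run-length descriptors per direction (0/45/90/135 deg)."""
    if not q.content_mask.any():
        raise ValueError("empty content")
    max_len = max(q.pixels.shape)
    out = []
    for direction in _DIRECTIONS:
        lines = _lines_for_direction(q.pixels, q.content_mask, direction)
        R = _run_length_matrix(lines, q.levels, max_len)
        out.append(_glrlm_descriptors(R))
    return np.concatenate(out)


def _glrlm_descriptors(R: np.ndarray) -> np.ndarray:
    levels, max_len = R.shape
    g = np.arange(1, levels + 1, dtype=np.float64)[:, None]
    j = np.arange(1, max_len + 1, dtype=np.float64)[None, :]
    nr = R.sum()
    if nr == 0:
        raise ValueError("no runs counted")
    npx = float((R * j).sum())
    rg = R.sum(axis=1)
    rj = R.sum(axis=0)
    return np.array(
        [
            float((R / j**2).sum() / nr),
            float((R * j**2).sum() / nr),
            float((rg**2).sum() / nr),
            float((rj**2).sum() / nr),
            nr / npx,
            float((R / g**2).sum() / nr),
            float((R * g**2).sum() / nr),
            float((R / (g**2 * j**2)).sum() / nr),
            float((R * g**2 / j**2).sum() / nr),
            float((R * j**2 / g**2).sum() / nr),
            float((R * j**2 * g**2).sum() / nr),
        ]
    )


# ---------------------------------------------------------------------------
# LBP

# neighbor offsets clockwise from top-left; first offset -> most significant bit
_LBP_OFFSETS = ((-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1))


def lbp_features(roi: PreprocessedROI) -> np.ndarray:
    """Normalized 256-bin histogram of classic 8-neighbor LBP codes.

    Ties (neighbor equal to center) count as 1, so constant regions code 255.
    """
    content = roi.content().astype(np.float64)
    if content.shape[0] < 3 or content.shape[1] < 3:
        raise ValueError("content must be at least 3x3")
    center = content[1:-1, 1:-1]
    codes = np.zeros(center.shape, dtype=np.int64)
    for bit, (dr, dc) in enumerate(_LBP_OFFSETS):
        nb = content[1 + dr : content.shape[0] - 1 + dr, 1 + dc : content.shape[1] - 1 + dc]
        codes |= (nb >= center).astype(np.int64) << (7 - bit)
    hist = np.bincount(codes.ravel(), minlength=256).astype(np.float64)
    return hist / hist.sum()


# ---------------------------------------------------------------------------
# GMRF


def gmrf_features(roi: PreprocessedROI) -> np.ndarray:
    """Least-squares coefficients of a symmetric second-order GMRF.

    The conditional mean of each interior pixel is modelled as a linear
    combination of its four symmetric neighbor-pair sums (horizontal, vertical,
    diagonal, anti-diagonal); the fitted coefficients are the features.
    """
    x = roi.content().astype(np.float64)
    if x.shape[0] < 5 or x.shape[1] < 5:
        raise ValueError("content must be at least 5x5")
    x = x - x.mean()
    c = x[1:-1, 1:-1]
    pairs = np.stack(
        [
            x[1:-1, :-2] + x[1:-1, 2:],  # horizontal
            x[:-2, 1:-1] + x[2:, 1:-1],  # vertical
            x[:-2, :-2] + x[2:, 2:],  # diagonal (down-right)
            x[:-2, 2:] + x[2:, :-2],  # anti-diagonal
        ],
        axis=-1,
    ).reshape(-1, 4)
    y = c.ravel()
    A = pairs.T @ pairs
    b = pairs.T @ y
    cond = np.linalg.cond(A) if np.isfinite(A).all() else np.inf
    if not np.isfinite(cond) or cond > 1e10:
        warnings.warn("singular GMRF normal equations; using regularized solve", RuntimeWarning, stacklevel=2)
        A = A + 1e-8 * max(1.0, np.trace(A) / 4.0) * np.eye(4)
    theta = np.linalg.solve(A, b)
    return theta.astype(np.float64)


# ---------------------------------------------------------------------------
# Hu moments


def hu_moments(roi: PreprocessedROI) -> np.ndarray:
    """The 7 Hu invariants of the intensity distribution.

    Computed on the full canvas (padding is zero so it carries no mass) and
    passed through sign(h) * log10|h| for numeric stability.
    """
    from skimage import measure

    img = roi.pixels.astype(np.float64)
    if img.sum() <= 0:
        raise ValueError("zero total intensity")
    mu = measure.moments_central(img)
    nu = measure.moments_normalized(mu)
    h = measure.moments_hu(nu)
    out = np.zeros(7)
    nzi = h != 0
    out[nzi] = np.sign(h[nzi]) * np.log10(np.abs(h[nzi]))
    return out


# ---------------------------------------------------------------------------
# Gabor bank


def _sigma_x(wavelength: float, bandwidth: float = 1.0) -> float:
    b = 2.0**bandwidth
    return wavelength / np.pi * np.sqrt(np.log(2) / 2.0) * (b + 1) / (b - 1)


def _gabor_kernel(wavelength: float, theta: float, gamma: float = 0.5) -> np.ndarray:
    sx = _sigma_x(wavelength)
    sy = sx / gamma
    half = int(np.ceil(3.0 * max(sx, sy)))
    yy, xx = np.mgrid[-half : half + 1, -half : half + 1].astype(np.float64)
    xr = xx * np.cos(theta) + yy * np.sin(theta)
    yr = -xx * np.sin(theta) + yy * np.cos(theta)
    env = np.exp(-0.5 * (xr**2 / sx**2 + yr**2 / sy**2))
    return env * np.exp(2j * np.pi * xr / wavelength)


class GaborBank:
    """20 complex Gabor filters applied by circular FFT convolution.

    Kernel FFTs are cached per image shape, so batch extraction pays the
    kernel transform cost once.
    """

    def __init__(
        self,
        wavelengths: tuple[float, ...] = GABOR_WAVELENGTHS,
        orientations_deg: tuple[float, ...] = GABOR_ORIENTATIONS_DEG,
        gamma: float = 0.5,
    ):
        self.wavelengths = tuple(wavelengths)
        self.orientations_deg = tuple(orientations_deg)
        self.gamma = gamma
        self._fft_cache: dict[tuple[int, int], list[np.ndarray]] = {}

    def _kernels(self) -> list[np.ndarray]:
        return [
            _gabor_kernel(lam, np.deg2rad(ori), self.gamma)
            for lam in self.wavelengths
            for ori in self.orientations_deg
        ]

    def _kernel_ffts(self, shape: tuple[int, int]) -> list[np.ndarray]:
        if shape not in self._fft_cache:
            ffts = []
            for k in self._kernels():
                kh, kw = k.shape
                if kh > shape[0] or kw > shape[1]:
                    # truncate overlong kernels to the image support
                    th, tw = min(kh, shape[0]), min(kw, shape[1])
                    r0, c0 = (kh - th) // 2, (kw - tw) // 2
                    k = k[r0 : r0 + th, c0 : c0 + tw]
                    kh, kw = k.shape
                pad = np.zeros(shape, dtype=np.complex128)
                pad[:kh, :kw] = k
                pad = np.roll(pad, (-(kh // 2), -(kw // 2)), axis=(0, 1))
                ffts.append(np.fft.fft2(pad))
            self._fft_cache[shape] = ffts
        return self._fft_cache[shape]

    def responses(self, image: np.ndarray) -> list[np.ndarray]:
        F = np.fft.fft2(image.astype(np.float64))
        return [np.abs(np.fft.ifft2(F * KF)) for KF in self._kernel_ffts(image.shape)]


_DEFAULT_BANK = GaborBank()


def gabor_features(roi: PreprocessedROI, bank: GaborBank | None = None) -> np.ndarray:
    """Mean, std and energy of each filter's response magnitude over content."""
    bank = bank or _DEFAULT_BANK
    mask = roi.content_mask()
    out = np.empty(3 * len(bank.wavelengths) * len(bank.orientations_deg))
    for idx, resp in enumerate(bank.responses(roi.pixels)):
        v = resp[mask]
        out[3 * idx : 3 * idx + 3] = (v.mean(), v.std(), (v**2).mean())
    return out


# ---------------------------------------------------------------------------
# full extractor


def extract_handcrafted(roi: PreprocessedROI, bank: GaborBank | None = None) -> HandcraftedFeatureVector:
    """Concatenate all nine families into the 455-value named vector."""
    parts: list[np.ndarray] = []
    q64 = None
    for family, dim in FAMILY_DIMS:
        try:
            if family == "hist":
                vec = histogram_features(roi)
            elif family == "hu":
                vec = hu_moments(roi)
            elif family in {"glcm", "glds", "glrlm"}:
                if q64 is None:
                    q64 = quantize_gray(roi, GLCM_LEVELS)
                vec = {"glcm": glcm_features, "glds": glds_features, "glrlm": glrlm_features}[family](q64)
            elif family == "glgcm":
                vec = glgcm_features(roi)
            elif family == "lbp":
                vec = lbp_features(roi)
            elif family == "gmrf":
                vec = gmrf_features(roi)
            else:
                vec = gabor_features(roi, bank)
        except FeatureExtractionError:
            raise
        except Exception as exc:
            raise FeatureExtractionError(family, str(exc)) from exc
        if vec.shape != (dim,):
            raise FeatureExtractionError(family, f"expected {dim} values, got {vec.shape}")
        parts.append(vec)
    values = np.concatenate(parts)
    if not np.isfinite(values).all():
        bad = [FEATURE_NAMES[i] for i in np.flatnonzero(~np.isfinite(values))][:5]
        raise FeatureExtractionError("extract", f"non-finite features: {bad}")
    return HandcraftedFeatureVector(values=values, names=FEATURE_NAMES)


def extractor_config() -> dict:
    """The extractor settings written to the JSON sidecar of feature tables."""
    return {
        "total_features": TOTAL_FEATURES,
        "families": dict(FAMILY_DIMS),
        "glcm_levels": GLCM_LEVELS,
        "glgcm_levels": list(GLGCM_LEVELS),
        "gabor": {
            "wavelengths_px": list(GABOR_WAVELENGTHS),
            "orientations_deg": list(GABOR_ORIENTATIONS_DEG),
            "bandwidth_octaves": 1.0,
            "aspect_ratio": 0.5,
            "stats": ["mean", "std", "energy"],
        },
        "entropy_base": 2,
    }
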