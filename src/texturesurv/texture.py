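"""Histogram and GLCM texture features with multi-scale LoG filtering.

Eight features are computed inside the (refined) ROI of a lesion image:

first order, from the gray-level histogram
    ``average`` (mean), ``standard_deviation`` (population SD),
    ``skewness`` (third standardized moment) and ``kurtosis``
    (*excess* kurtosis, so a Gaussian histogram scores 0);

second order, from a grey-level co-occurrence matrix (GLCM)
    ``asm`` (angular second moment / energy, :math:`\\sum p^2`),
    ``entropy`` (:math:`-\\sum p \\log_2 p`, bits),
    ``contrast`` (:math:`\\sum (i-j)^2 p(i,j)`) and
    ``correlation`` (gray-level linear dependence, in [-1, 1]).

Each feature block is computed on the raw image (sigma = 0, the identity
transform) and on Laplacian-of-Gaussian (LoG) band-pass filtered versions
of it.  Small sigma isolates fine texture, large sigma coarse texture.
Pixels below 0 HU (stored value < 1024: air / fat) are excluded from the
ROI before any feature is computed; the refinement is derived once from the
unfiltered image and reused for every filter scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .lesion import HU_OFFSET, LesionImage

#: Filter scales used by the analysis; 0 denotes the unfiltered image.
ALLOWED_SIGMAS = (0.0, 1.0, 1.5, 2.0, 2.5)

#: Feature names in reporting order.
FEATURE_NAMES = (
    "average",
    "standard_deviation",
    "kurtosis",
    "skewness",
    "asm",
    "entropy",
    "contrast",
    "correlation",
)

#: Default co-occurrence offsets: E, S, SE, SW at distance 1, (row, col) steps.
DEFAULT_OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1))


class NoAnalyzablePixelsError(ValueError):
    """The ROI contains no pixels after the sub-0-HU exclusion."""


class DegenerateROIError(ValueError):
    """No valid pixel pair exists for the requested GLCM offsets."""


@dataclass(frozen=True)
class FilterSpec:
    """Laplacian-of-Gaussian filter configuration.

    ``sigma = 0`` is the identity transform regardless of ``mode``.
    ``mode = "response"`` returns the pure (zero-mean) LoG response;
    ``mode = "band-plus-dc"`` returns ``input + response`` so the DC level of
    the image is retained — under this mode the in-ROI average stays near its
    unfiltered value at every scale.  The kernel is truncated at
    ``kernel_truncation * sigma`` (default 4) and corrected to exactly zero
    DC gain, so a constant image always has zero response.
    """

    sigma: float
    mode: str = "band-plus-dc"
    kernel_truncation: float = 4.0

    def __post_init__(self) -> None:
        if self.mode not in ("response", "band-plus-dc"):
            raise ValueError(f"unknown filter mode: {self.mode!r}")
        if self.kernel_truncation <= 0:
            raise ValueError("kernel_truncation must be positive")


def apply_exclusion_rule(lesion: LesionImage) -> np.ndarray:
    """Remove sub-0-HU pixels (stored value < 1024) from the ROI mask.

    Air and fatty tissue have negative attenuation and are excluded from the
    texture analysis.  Returns a new boolean mask; the lesion is untouched.

    Raises
    ------
    NoAnalyzablePixelsError
        If no in-ROI pixel is at or above 0 HU.
    """
    refined = lesion.mask & (np.asarray(lesion.pixels) >= HU_OFFSET)
    if not refined.any():
        raise NoAnalyzablePixelsError("no analyzable pixels: ROI is entirely below 0 HU")
    return refined


def log_kernel(sigma: float, truncation: float = 4.0, zero_dc: bool = True) -> np.ndarray:
    """Discretized 2-D Laplacian-of-Gaussian kernel.

    The continuous kernel

    .. math:: \\nabla^2 G(x, y) = \\frac{x^2 + y^2 - 2\\sigma^2}{2\\pi\\sigma^6}
              e^{-(x^2+y^2)/2\\sigma^2}

    is sampled on the integer grid ``|x|, |y| <= ceil(truncation * sigma)``.
    With ``zero_dc=True`` (the default used by :func:`log_filter`) the small
    residual sum left by truncation and sampling is spread uniformly over the
    support so the kernel has exactly zero DC gain.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive for a LoG kernel")
    r = int(np.ceil(truncation * sigma))
    y, x = np.mgrid[-r : r + 1, -r : r + 1]
    q = (x * x + y * y) / (2.0 * sigma * sigma)
    k = (q - 1.0) / (np.pi * sigma**4) * np.exp(-q)
    if zero_dc:
        k = k - k.sum() / k.size
    return k


def log_filter(lesion_or_image: LesionImage | np.ndarray, spec: FilterSpec,
               allow_any_sigma: bool = False) -> np.ndarray:
    """Apply the LoG band-pass filter of ``spec`` to a lesion image.

    Returns a float array of the same shape.  ``sigma = 0`` returns the input
    values unchanged.  Border handling is reflect padding.

    Parameters
    ----------
    lesion_or_image
        A :class:`LesionImage` (its ``pixels`` are filtered) or a bare 2-D array.
    spec
        Filter scale and mode.
    allow_any_sigma
        Permit sigma values outside the standard set ``ALLOWED_SIGMAS``.
    """
    img = lesion_or_image.pixels if isinstance(lesion_or_image, LesionImage) else lesion_or_image
    img = np.asarray(img, dtype=float)
    if spec.sigma == 0:
        return img.copy()
    if not allow_any_sigma and spec.sigma not in ALLOWED_SIGMAS:
        raise ValueError(
            f"sigma {spec.sigma} not in {ALLOWED_SIGMAS}; pass allow_any_sigma=True to override"
        )
    kernel = log_kernel(spec.sigma, truncation=spec.kernel_truncation)
    response = ndimage.convolve(img, kernel, mode="reflect")
    if spec.mode == "response":
        return response
    return img + response


def histogram_features(values: np.ndarray) -> tuple[float, float, float, float]:
    """First-order features of an intensity sample.

    Returns ``(average, standard_deviation, skewness, kurtosis)`` using
    population (biased) moments; kurtosis is excess kurtosis.  For a constant
    sample the SD is 0 and skewness/kurtosis are returned as 0 by convention.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("histogram_features requires at least one value")
    mean = float(v.mean())
    centered = v - mean
    var = float(np.mean(centered**2))
    sd = float(np.sqrt(var))
    if sd == 0.0:
        return mean, 0.0, 0.0, 0.0
    z = centered / sd  # standardize before powering to avoid over/underflow
    skew = float(np.mean(z**3))
    kurt = float(np.mean(z**4)) - 3.0
    return mean, sd, skew, kurt


@dataclass
class CoocMatrix:
    """A normalized grey-level co-occurrence matrix.

    ``levels[i]`` is the gray level of row/column ``i`` of ``probabilities``.
    """

    levels: np.ndarray
    probabilities: np.ndarray
    offsets_used: tuple[tuple[int, int], ...]
    symmetric: bool

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=float)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        p = self.probabilities
        if p.ndim != 2 or p.shape[0] != p.shape[1] or p.shape[0] != self.levels.size:
            raise ValueError("probabilities must be square over the level list")
        if np.min(p) < -1e-12:
            raise ValueError("probabilities must be non-negative")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1")
        if self.symmetric and not np.allclose(p, p.T, atol=1e-12):
            raise ValueError("symmetric GLCM must equal its transpose")


def build_glcm(image: np.ndarray, mask: np.ndarray,
               offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS,
               symmetric: bool = True,
               quantization: str = "raw-integer",
               n_bins: int = 32) -> CoocMatrix:
    """Count co-occurring gray-level pairs inside a mask and normalize.

    Ordered pairs ``(p, p + offset)`` with both pixels in ``mask`` are counted
    over all offsets (pooled into a single matrix); with ``symmetric=True``
    the transposed counts are added.  ``quantization="raw-integer"`` uses
    rounded pixel values directly as gray levels (the matrix is stored densely
    over the *observed* levels only); ``"fixed-bins"`` rescales the in-mask
    range to ``n_bins`` levels 0..n_bins-1.

    Raises
    ------
    DegenerateROIError
        If no offset yields a valid in-mask pixel pair.
    """
    img = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if img.shape != mask.shape:
        raise ValueError("image and mask shapes differ")

    if quantization == "raw-integer":
        q = np.rint(img).astype(np.int64)
    elif quantization == "fixed-bins":
        vals = img[mask]
        lo, hi = float(vals.min()), float(vals.max())
        if hi == lo:
            q = np.zeros(img.shape, dtype=np.int64)
        else:
            q = np.floor((img - lo) / (hi - lo) * n_bins).astype(np.int64)
            q = np.clip(q, 0, n_bins - 1)
    else:
        raise ValueError(f"unknown quantization: {quantization!r}")

    i_list: list[np.ndarray] = []
    j_list: list[np.ndarray] = []
    nrow, ncol = img.shape
    for dr, dc in offsets:
        r0, r1 = max(0, -dr), min(nrow, nrow - dr)
        c0, c1 = max(0, -dc), min(ncol, ncol - dc)
        if r0 >= r1 or c0 >= c1:
            continue
        a = np.s_[r0:r1, c0:c1]
        b = np.s_[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        valid = mask[a] & mask[b]
        if valid.any():
            i_list.append(q[a][valid])
            j_list.append(q[b][valid])
    if not i_list:
        raise DegenerateROIError("degenerate ROI: no valid pixel pair for any offset")

    i_vals = np.concatenate(i_list)
    j_vals = np.concatenate(j_list)
    if symmetric:
        i_vals, j_vals = np.concatenate([i_vals, j_vals]), np.concatenate([j_vals, i_vals])

    levels, inv = np.unique(np.concatenate([i_vals, j_vals]), return_inverse=True)
    n = levels.size
    ii = inv[: i_vals.size]
    jj = inv[i_vals.size :]
    counts = np.zeros((n, n), dtype=np.float64)
    np.add.at(counts, (ii, jj), 1.0)
    return CoocMatrix(
        levels=levels.astype(float),
        probabilities=counts / counts.sum(),
        offsets_used=tuple(tuple(o) for o in offsets),
        symmetric=symmetric,
    )


def glcm_features(m: CoocMatrix, entropy_base: float = 2.0) -> tuple[float, float, float, float]:
    """Second-order features ``(asm, entropy, contrast, correlation)``.

    ``entropy`` uses log base 2 (bits) by default; pass ``entropy_base=np.e``
    for nats.  ``contrast`` and ``correlation`` weight cells by the actual
    gray-level values in ``m.levels``, so with raw-integer quantization the
    contrast is in squared stored-intensity units.  If either marginal SD is
    zero the correlation is returned as 0 by convention.
    """
    p = m.probabilities
    lv = m.levels
    asm = float(np.sum(p * p))
    nz = p[p > 0]
    entropy = float(-np.sum(nz * np.log(nz) / np.log(entropy_base)))
    diff = lv[:, None] - lv[None, :]
    contrast = float(np.sum(diff * diff * p))
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float(px @ lv)
    mu_y = float(py @ lv)
    var_x = float(px @ (lv - mu_x) ** 2)
    var_y = float(py @ (lv - mu_y) ** 2)
    denom = np.sqrt(var_x * var_y)
    if denom == 0.0:
        correlation = 0.0
    else:
        e_xy = float(lv @ p @ lv)
        correlation = float((e_xy - mu_x * mu_y) / denom)
    return asm, entropy, contrast, correlation


@dataclass
class FeatureVector:
    """The eight texture features of one lesion at one filter scale."""

    average: float
    standard_deviation: float
    kurtosis: float
    skewness: float
    asm: float
    entropy: float
    contrast: float
    correlation: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}


def extract_features(lesion: LesionImage,
                     sigmas: tuple[float, ...] = ALLOWED_SIGMAS,
                     mode: str = "band-plus-dc",
                     offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS,
                     symmetric: bool = True,
                     quantization: str = "raw-integer",
                     n_bins: int = 32,
                     entropy_base: float = 2.0) -> dict[float, FeatureVector]:
    """Compute all eight features at every filter scale.

    The sub-0-HU exclusion is applied once, on the unfiltered image, and the
    refined mask is reused for every scale.  Returns ``{sigma: FeatureVector}``.
    """
    refined = apply_exclusion_rule(lesion)
    out: dict[float, FeatureVector] = {}
    for sigma in sigmas:
        spec = FilterSpec(sigma=float(sigma), mode=mode)
        filtered = log_filter(lesion, spec)
        avg, sd, skew, kurt = histogram_features(filtered[refined])
        m = build_glcm(filtered, refined, offsets=offsets, symmetric=symmetric,
                       quantization=quantization, n_bins=n_bins)
        asm, ent, con, cor = glcm_features(m, entropy_base=entropy_base)
        out[float(sigma)] = FeatureVector(
            average=avg, standard_deviation=sd, kurtosis=kurt, skewness=skew,
            asm=asm, entropy=ent, contrast=con, correlation=cor,
        )
    return out
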