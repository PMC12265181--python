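"""Gradient Magnitude Similarity Deviation (GMSD).

GMSD scores the dissimilarity of two grayscale images from their gradient
magnitude maps.  For images ``A`` and ``B`` with gradient magnitudes
``G_A``, ``G_B`` the per-pixel gradient magnitude similarity is

    GMS(i,j) = (2 G_A G_B + C) / (G_A^2 + G_B^2 + C),      C > 0,

bounded in (0, 1] with 1 meaning identical local structure.  The map is
pooled by its mean (GMSM) and population standard deviation (GMSD):
identical images give GMSD = 0, and larger GMSD means greater
dissimilarity.  GMSD is robust to the noise types common in MRI
(Gaussian, salt-and-pepper, speckle), which is why it is used here to
compare a brain slice with its mirror image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "GRADIENT_KERNELS",
    "GmsdConfig",
    "GmsdResult",
    "as_gray_image",
    "gradient_magnitude",
    "gms_map",
    "gmsd",
    "foreground_mask",
]

# 3x3 horizontal-derivative kernels (x = column direction).  Each is
# normalized by the sum of its positive weights so a unit intensity step
# produces a unit response; the vertical kernel is the transpose.
GRADIENT_KERNELS: dict[str, np.ndarray] = {
    "prewitt": np.array([[1, 0, -1], [1, 0, -1], [1, 0, -1]], dtype=float) / 3.0,
    "sobel": np.array([[1, 0, -1], [2, 0, -2], [1, 0, -1]], dtype=float) / 4.0,
    "scharr": np.array([[3, 0, -3], [10, 0, -10], [3, 0, -3]], dtype=float) / 16.0,
}

#: Stability constant of the original GMSD literature, for images on a
#: 0-255 intensity scale (it is added to squared gradients).
C_REFERENCE = 170.0
_REFERENCE_RANGE = 255.0


class DimensionError(ValueError):
    """Image shapes incompatible with the requested operation."""


class ConfigurationError(ValueError):
    """Invalid option value (unknown kernel, non-positive C, ...)."""


def as_gray_image(pixels, *, name: str = "image") -> np.ndarray:
    """Validate and return a 2D grayscale image as a float array.

    Requires at least a 3x3 extent (the gradient kernels need a full
    neighborhood), finite values, and non-negative intensities.
    """
    img = np.asarray(pixels, dtype=float)
    if img.ndim != 2:
        raise DimensionError(f"{name} must be 2D, got shape {img.shape}")
    if img.shape[0] < 3 or img.shape[1] < 3:
        raise DimensionError(
            f"{name} must be at least 3x3 for 3x3 gradient kernels, got {img.shape}"
        )
    if not np.isfinite(img).all():
        raise ValueError(f"{name} contains non-finite values")
    if (img < 0).any():
        raise ValueError(f"{name} contains negative intensities")
    return img


@dataclass(frozen=True)
class GmsdConfig:
    """Options for GMSD computation.

    Parameters
    ----------
    kernel:
        Name of the 3x3 derivative kernel pair: ``prewitt`` (default,
        the operator of the original GMSD formulation), ``sobel`` or
        ``scharr``.
    c:
        Stability constant ``C`` of the GMS map.  ``None`` (default)
        rescales the reference value 170 to the images' dynamic range:
        ``C = 170 * (range / 255)**2`` (quadratic, because C is added to
        squared gradients).  A number fixes C explicitly.
    mask_background:
        If True, pool GMS only over foreground pixels (either image
        nonzero, dilated); default False pools over all N pixels.
    """

    kernel: str = "prewitt"
    c: float | None = None
    mask_background: bool = False

    def __post_init__(self) -> None:
        if self.kernel not in GRADIENT_KERNELS:
            raise ConfigurationError(
                f"unknown gradient operator {self.kernel!r}; "
                f"choose from {sorted(GRADIENT_KERNELS)}"
            )
        if self.c is not None and not self.c > 0:
            raise ConfigurationError(f"stability constant c must be > 0, got {self.c}")

    def resolve_c(self, *images: np.ndarray) -> float:
        if self.c is not None:
            return float(self.c)
        drange = max((float(img.max()) for img in images), default=0.0)
        if drange <= 0:
            return C_REFERENCE  # constant images: any C > 0 gives GMS = 1
        return C_REFERENCE * (drange / _REFERENCE_RANGE) ** 2


@dataclass(frozen=True)
class GmsdResult:
    """GMSD score with its mean pooling term and the underlying GMS map."""

    gmsd: float
    gmsm: float
    map: np.ndarray = field(repr=False)


def gradient_magnitude(img, operator: str = "prewitt") -> np.ndarray:
    """Per-pixel gradient magnitude ``sqrt(Gx^2 + Gy^2)``.

    ``Gx``/``Gy`` are the horizontal/vertical responses of the named 3x3
    kernel pair, convolved under symmetric (reflect) boundary padding so
    the output has the input's shape and mirror images give mirrored
    maps.
    """
    img = as_gray_image(img)
    if operator not in GRADIENT_KERNELS:
        raise ConfigurationError(
            f"unknown gradient operator {operator!r}; choose from {sorted(GRADIENT_KERNELS)}"
        )
    kx = GRADIENT_KERNELS[operator]
    gx = ndimage.convolve(img, kx, mode="reflect")
    gy = ndimage.convolve(img, kx.T, mode="reflect")
    return np.hypot(gx, gy)


def gms_map(g_a: np.ndarray, g_b: np.ndarray, c: float) -> np.ndarray:
    """Gradient magnitude similarity map of two gradient-magnitude maps."""
    g_a = np.asarray(g_a, dtype=float)
    g_b = np.asarray(g_b, dtype=float)
    if g_a.shape != g_b.shape:
        raise DimensionError(f"shape mismatch: {g_a.shape} vs {g_b.shape}")
    if not c > 0:
        raise ConfigurationError(f"stability constant c must be > 0, got {c}")
    return (2.0 * g_a * g_b + c) / (g_a**2 + g_b**2 + c)


def foreground_mask(img_a: np.ndarray, img_b: np.ndarray, dilate: int = 3) -> np.ndarray:
    """Boolean mask of pixels where either image is nonzero, dilated.

    Skull-stripped slices have large zero backgrounds where GMS is
    identically 1; this mask lets the pooling exclude them.
    """
    mask = (img_a > 0) | (img_b > 0)
    if dilate > 0:
        mask = ndimage.binary_dilation(mask, iterations=dilate)
    return mask


def gmsd(img_a, img_b, config: GmsdConfig | None = None) -> GmsdResult:
    """GMSD of two same-shape grayscale images.

    Returns the population standard deviation (divisor N) of the GMS map
    about its mean (GMSM).  ``gmsd(A, A)`` is exactly 0.
    """
    config = config or GmsdConfig()
    img_a = as_gray_image(img_a, name="imgA")
    img_b = as_gray_image(img_b, name="imgB")
    if img_a.shape != img_b.shape:
        raise DimensionError(f"shape mismatch: {img_a.shape} vs {img_b.shape}")
    c = config.resolve_c(img_a, img_b)
    g_a = gradient_magnitude(img_a, config.kernel)
    g_b = gradient_magnitude(img_b, config.kernel)
    gms = gms_map(g_a, g_b, c)
    if config.mask_background:
        pooled = gms[foreground_mask(img_a, img_b)]
        if pooled.size == 0:
            pooled = gms.ravel()
    else:
        pooled = gms.ravel()
    gmsm = float(pooled.mean())
    value = float(np.sqrt(np.mean((pooled - gmsm) ** 2)))
    return GmsdResult(gmsd=value, gmsm=gmsm, map=gms)
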