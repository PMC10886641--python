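"""Micrograph preprocessing and binarization.

The segmentation protocol is a fixed four-step chain: rolling-ball
background subtraction (implemented as grayscale opening with a disk),
median denoising, contrast-limited adaptive histogram equalization
(CLAHE), and Otsu thresholding.  Each step is a stateless
scikit-learn-style transformer over a 2-D intensity array; the
:class:`MicrographBinarizer` composes them in the fixed order, and the
module-level functions wrap the transformers for calibrated
:class:`~mitomorph.images.Micrograph` inputs.
"""

from __future__ import annotations

import numpy as np
from skimage import exposure
from skimage.filters import threshold_otsu
from skimage.morphology import disk, opening
from scipy.ndimage import median_filter
from sklearn.base import BaseEstimator, TransformerMixin

from .images import BinaryMask, Micrograph

__all__ = [
    "BackgroundSubtractor",
    "MedianDenoiser",
    "ClaheEnhancer",
    "OtsuBinarizer",
    "MicrographBinarizer",
    "subtract_background",
    "denoise_median",
    "enhance_clahe",
    "binarize_otsu",
    "preprocess_micrograph",
]


def _check_image(X) -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {X.shape}")
    if not np.all(np.isfinite(X)):
        raise ValueError("image contains non-finite values")
    return X


class _ImageTransformer(BaseEstimator, TransformerMixin):
    """Stateless image-to-image transformer base."""

    def fit(self, X, y=None):
        X = _check_image(X)
        self.n_features_in_ = X.shape[1]
        return self

    def fit_transform(self, X, y=None, **kwargs):
        return self.fit(X, y).transform(X)


class BackgroundSubtractor(_ImageTransformer):
    """Rolling-ball-style background removal.

    The background estimate is a grayscale opening with a disk of
    ``radius_px`` (50 px by default); the result is input minus
    background, clipped at zero, so a flat image maps to all zeros.  For
    radii above 10 px the disk footprint uses a sequence decomposition,
    a fast and close approximation of the exact disk.
    """

    def __init__(self, radius_px: int = 50):
        self.radius_px = radius_px

    def transform(self, X):
        X = _check_image(X)
        if self.radius_px < 1:
            raise ValueError("radius_px must be >= 1")
        if self.radius_px >= min(X.shape):
            raise ValueError(
                f"radius_px={self.radius_px} is larger than the image {X.shape}"
            )
        decomposition = "sequence" if self.radius_px > 10 else None
        footprint = disk(self.radius_px, decomposition=decomposition)
        background = opening(X, footprint)
        return np.clip(X - background, 0.0, None)


class MedianDenoiser(_ImageTransformer):
    """Median filter over a (2r+1)² neighborhood, reflected at edges."""

    def __init__(self, radius_px: int = 1):
        self.radius_px = radius_px

    def transform(self, X):
        X = _check_image(X)
        if self.radius_px < 1:
            raise ValueError("radius_px must be >= 1")
        size = 2 * self.radius_px + 1
        # "mirror" = reflection without duplicating the edge pixel,
        # matching np.pad(..., mode="reflect")
        return median_filter(X, size=size, mode="mirror")


class ClaheEnhancer(_ImageTransformer):
    """Contrast-limited adaptive histogram equalization.

    ``intensity_max`` sets the range used to normalize in and rescale
    out (full scale of the camera bit depth); the output spans that
    range and preserves rank order within each tile.
    """

    def __init__(self, tile_px: int = 64, clip_limit: float = 0.01,
                 intensity_max: float = 65535.0):
        self.tile_px = tile_px
        self.clip_limit = clip_limit
        self.intensity_max = intensity_max

    def transform(self, X):
        X = _check_image(X)
        if self.tile_px < 8:
            raise ValueError("tile_px must be >= 8")
        if not 0.0 < self.clip_limit <= 1.0:
            raise ValueError("clip_limit must be in (0, 1]")
        if np.ptp(X) == 0.0:
            return X.copy()  # no contrast to enhance
        # normalize by the image's own range so dim 16-bit data keeps its
        # full histogram resolution; output is rescaled to the bit-depth
        # range
        lo = X.min()
        scaled = (X - lo) / np.ptp(X)
        out = exposure.equalize_adapthist(
            scaled, kernel_size=self.tile_px, clip_limit=self.clip_limit
        )
        return out * self.intensity_max


class OtsuBinarizer(_ImageTransformer):
    """Otsu threshold over a 256-bin full-range histogram; strictly-above.

    The histogram uses 256 bins of integer-aligned width covering the
    data range (bin width ``ceil((max - min + 1) / 256)``): for an 8-bit
    image every integer value gets its own bin, so the threshold equals
    the exhaustive integer-search optimum; for 16-bit data spanning the
    full camera range the bins are 256 intensity units wide.

    Attributes
    ----------
    threshold_ : float
        Threshold of the most recent transform, on the input scale.
    """

    def __init__(self, nbins: int = 256):
        self.nbins = nbins

    def transform(self, X):
        X = _check_image(X)
        if np.ptp(X) == 0.0:
            raise ValueError("cannot threshold a constant image")
        lo = float(np.floor(X.min()))
        width = float(np.ceil((X.max() - lo + 1.0) / self.nbins))
        hi = lo + width * self.nbins
        counts, edges = np.histogram(X, bins=self.nbins, range=(lo, hi))
        centers = (edges[:-1] + edges[1:]) / 2.0
        thr_center = float(threshold_otsu(hist=(counts, centers)))
        # foreground = every bin above the optimal one: the threshold sits
        # just under that bin's upper edge (strictly-above convention)
        upper_edge = lo + (np.floor((thr_center - lo) / width) + 1.0) * width
        self.threshold_ = float(np.nextafter(upper_edge, lo))
        return X > self.threshold_


class MicrographBinarizer(_ImageTransformer):
    """The fixed preprocessing chain: background → median → CLAHE → Otsu.

    The step order is part of the protocol and cannot be reconfigured;
    only the step parameters are exposed.  ``transform`` maps a 2-D
    intensity array to a boolean foreground mask.
    """

    def __init__(
        self,
        rolling_ball_radius_px: int = 50,
        median_radius_px: int = 1,
        clahe_tile_px: int = 64,
        clahe_clip: float = 0.01,
        intensity_max: float = 65535.0,
    ):
        self.rolling_ball_radius_px = rolling_ball_radius_px
        self.median_radius_px = median_radius_px
        self.clahe_tile_px = clahe_tile_px
        self.clahe_clip = clahe_clip
        self.intensity_max = intensity_max

    def transform(self, X):
        X = _check_image(X)
        steps = [
            BackgroundSubtractor(self.rolling_ball_radius_px),
            MedianDenoiser(self.median_radius_px),
            ClaheEnhancer(self.clahe_tile_px, self.clahe_clip, self.intensity_max),
        ]
        for step in steps:
            X = step.transform(X)
        binarizer = OtsuBinarizer()
        mask = binarizer.transform(X)
        self.threshold_ = binarizer.threshold_
        return mask


def subtract_background(img: Micrograph, radius_px: int = 50) -> Micrograph:
    """Remove the morphological background estimate (rolling-ball style)."""
    return img.with_pixels(BackgroundSubtractor(radius_px).transform(img.pixels))


def denoise_median(img: Micrograph, radius_px: int = 1) -> Micrograph:
    """Median-filter the image with a (2r+1)² window."""
    return img.with_pixels(MedianDenoiser(radius_px).transform(img.pixels))


def enhance_clahe(img: Micrograph, tile_px: int = 64, clip_limit: float = 0.01) -> Micrograph:
    """Apply CLAHE scaled to the image's bit-depth range."""
    enhancer = ClaheEnhancer(tile_px, clip_limit, intensity_max=float(img.intensity_max))
    return img.with_pixels(enhancer.transform(img.pixels))


def binarize_otsu(img: Micrograph) -> BinaryMask:
    """Threshold with Otsu's method; pixels strictly above are foreground."""
    mask = OtsuBinarizer().transform(img.pixels)
    return BinaryMask(mask, pixels_per_micron=img.pixels_per_micron)


def preprocess_micrograph(
    img: Micrograph,
    rolling_ball_radius_px: int = 50,
    median_radius_px: int = 1,
    clahe_tile_px: int = 64,
    clahe_clip: float = 0.01,
) -> BinaryMask:
    """Run the full fixed chain and return the foreground mask."""
    binarizer = MicrographBinarizer(
        rolling_ball_radius_px=rolling_ball_radius_px,
        median_radius_px=median_radius_px,
        clahe_tile_px=clahe_tile_px,
        clahe_clip=clahe_clip,
        intensity_max=float(img.intensity_max),
    )
    mask = binarizer.transform(img.pixels)
    return BinaryMask(mask, pixels_per_micron=img.pixels_per_micron)
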