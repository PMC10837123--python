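"""Image containers and the pre-processing chain applied before morphometrics.

The chain mirrors a common FiJi workflow for mitochondrial network
imaging: outline the cell of interest and clear the outside, maximum
project the z-stack, subtract background, stretch contrast, then apply
median, unsharp and Hessian-based tubeness filters before binarisation.
Exact filter radii/sigmas are configuration, not inference: the defaults
are the customary FiJi values and every run can serialise the settings it
actually used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import tifffile
from skimage import filters, restoration
from skimage.draw import polygon2mask
from skimage.exposure import rescale_intensity
from skimage.morphology import disk

__all__ = [
    "ImageStack",
    "CellROI",
    "EnhanceConfig",
    "max_project",
    "enhance",
    "binarize",
    "clear_outside",
]


@dataclass
class ImageStack:
    """Multi-channel (optionally z / t) pixel data with pixel-size metadata.

    ``axes`` is a tifffile-style axis string over {C, Z, T, Y, X} matching
    ``pixels.ndim``; Y and X are always the trailing two axes.
    ``pixel_size_nm`` is the lateral pixel pitch.
    """

    pixels: np.ndarray
    axes: str = "CYX"
    pixel_size_nm: float = 1.0
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if len(self.axes) != self.pixels.ndim:
            raise ValueError(
                f"axes {self.axes!r} does not match ndim {self.pixels.ndim}")
        if not self.axes.endswith("YX"):
            raise ValueError("axes must end with 'YX'")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixel intensities must be finite")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")

    def channel(self, index_or_name) -> np.ndarray:
        """One channel's pixel data (identity if there is no C axis)."""
        if "C" not in self.axes:
            return self.pixels
        if isinstance(index_or_name, str):
            index_or_name = self.channel_names.index(index_or_name)
        return np.take(self.pixels, index_or_name, axis=self.axes.index("C"))

    def to_tiff(self, path) -> None:
        tifffile.imwrite(
            path, self.pixels, ome=True,
            metadata={"axes": self.axes,
                      "PhysicalSizeX": self.pixel_size_nm / 1000.0,
                      "PhysicalSizeXUnit": "µm"})

    @classmethod
    def from_tiff(cls, path, axes: str | None = None,
                  pixel_size_nm: float = 1.0) -> "ImageStack":
        with tifffile.TiffFile(path) as tif:
            pixels = tif.asarray()
            series_axes = tif.series[0].axes
        axes = axes or series_axes
        # tifffile may report a singleton sample axis etc.; keep known axes
        keep = [i for i, a in enumerate(axes) if a in "CZTYX"]
        pixels = pixels.reshape([pixels.shape[i] for i in keep])
        axes = "".join(axes[i] for i in keep)
        return cls(pixels=pixels, axes=axes, pixel_size_nm=pixel_size_nm)


@dataclass
class CellROI:
    """Region of interest outlining one cell.

    Either an explicit boolean ``mask`` or a ``polygon`` of (row, col)
    vertices; a polygon is rasterised on demand for a given image shape.
    """

    cell_id: str = "cell"
    mask: np.ndarray | None = None
    polygon: np.ndarray | None = None

    def __post_init__(self) -> None:
        if (self.mask is None) == (self.polygon is None):
            raise ValueError("provide exactly one of mask or polygon")
        if self.mask is not None and not self.mask.any():
            raise ValueError("ROI mask is empty")

    def to_mask(self, shape: tuple[int, int]) -> np.ndarray:
        if self.mask is not None:
            if self.mask.shape != tuple(shape):
                raise ValueError("ROI mask shape does not match image")
            return self.mask.astype(bool)
        poly = np.asarray(self.polygon, dtype=float)
        if (poly < 0).any() or (poly[:, 0] > shape[0]).any() \
                or (poly[:, 1] > shape[1]).any():
            raise ValueError("ROI polygon extends outside the image")
        mask = polygon2mask(shape, poly)
        if not mask.any():
            raise ValueError("ROI polygon rasterises to an empty mask")
        return mask


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def max_project(stack: ImageStack) -> np.ndarray:
    """Maximum-intensity projection over the z axis.

    A single-plane input (no Z axis) is returned unchanged with a warning,
    so 2-D acquisitions flow through the same pipeline.
    """
    if "Z" not in stack.axes:
        warnings.warn("max_project: input has no z axis; returning as-is",
                      stacklevel=2)
        return stack.pixels
    return stack.pixels.max(axis=stack.axes.index("Z"))


@dataclass(frozen=True)
class EnhanceConfig:
    """Stage settings for :func:`enhance`; set a stage to ``None``/0 to skip.

    Defaults mirror customary FiJi values: rolling-ball radius 50 px,
    contrast stretch with 0.35 % saturated pixels, 1-px median, unsharp
    radius 1 / weight 0.6, tubeness scale 1.5 px.
    """

    bg_radius: float | None = 50.0
    saturated: float | None = 0.0035
    median_radius: int | None = 1
    unsharp_radius: float | None = 1.0
    unsharp_weight: float = 0.6
    tubeness_sigma: float | None = 1.5


def enhance(image: np.ndarray, cfg: EnhanceConfig = EnhanceConfig()
            ) -> np.ndarray:
    """Pre-processing chain for tubular structures.

    Applied in a fixed order: rolling-ball background subtraction →
    saturated contrast stretch → median → unsharp mask → Sato (Hessian
    eigenvalue) tubeness.  Output is non-negative; with every stage
    disabled the function is the identity.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("enhance expects a 2-D image")
    if cfg.tubeness_sigma is not None and cfg.tubeness_sigma <= 0:
        raise ValueError("tubeness_sigma must be positive")

    if cfg.bg_radius:
        img = img - restoration.rolling_ball(img, radius=cfg.bg_radius)
    if cfg.saturated:
        lo, hi = np.percentile(img, [100 * cfg.saturated / 2,
                                     100 * (1 - cfg.saturated / 2)])
        if hi > lo:
            img = rescale_intensity(img, in_range=(lo, hi),
                                    out_range=(0.0, 1.0))
    if cfg.median_radius:
        img = filters.median(img, footprint=disk(cfg.median_radius))
    if cfg.unsharp_radius:
        img = filters.unsharp_mask(img, radius=cfg.unsharp_radius,
                                   amount=cfg.unsharp_weight,
                                   preserve_range=True)
    if cfg.tubeness_sigma:
        img = filters.sato(img, sigmas=[cfg.tubeness_sigma],
                           black_ridges=False)
    return np.clip(img, 0.0, None)


def binarize(image: np.ndarray, method: str | float = "otsu") -> np.ndarray:
    """Threshold to a boolean foreground mask.

    ``method`` is ``"otsu"`` or a fixed numeric threshold (foreground is
    strictly above it).  A constant image has no Otsu threshold: an empty
    mask is returned with a warning.
    """
    img = np.asarray(image)
    if isinstance(method, str):
        if method != "otsu":
            raise ValueError(f"unknown binarize method {method!r}")
        if img.max() == img.min():
            warnings.warn("binarize: constant image, returning empty mask",
                          stacklevel=2)
            return np.zeros(img.shape, dtype=bool)
        t = filters.threshold_otsu(img)
    else:
        t = float(method)
    return img > t


def clear_outside(image: np.ndarray, roi: CellROI) -> np.ndarray:
    """Zero every pixel outside the cell ROI."""
    img = np.asarray(image)
    mask = roi.to_mask(img.shape[-2:])
    return np.where(mask, img, 0)


def enhance_config_dict(cfg: EnhanceConfig) -> dict:
    """Serializable record of the settings actually used (for run logs)."""
    return asdict(cfg)
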