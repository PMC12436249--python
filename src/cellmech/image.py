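"""Raster container and the channel pre-correction chain.

Every quantitative arm of the package (nuclear/cytoplasmic ratio,
three-cube FRET index, traction microscopy) starts from the same
per-channel correction chain, applied in a fixed order:

1. illumination-gradient (flat-field) correction,
2. inter-channel translation registration,
3. background subtraction,
4. a light 3x3 mean smoothing ("three-point" smoothing).

All operations work on floating-point copies; raw integer camera data is
never mutated in place.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import tifffile
import yaml
from scipy import ndimage as ndi
from skimage.registration import phase_cross_correlation


class RegistrationWarning(UserWarning):
    """Raised when the correlation peak is indistinct or the shift implausibly large."""


@dataclass(frozen=True)
class IntensityImage:
    """A single-channel 2D micrograph with a physical pixel size.

    Parameters
    ----------
    pixels : ndarray
        2D intensity grid; converted to float64 on construction.
    pixel_size : float
        Physical size of one pixel, in micrometres.
    channel_name : str
        Free-text channel label (e.g. ``"dapi"``, ``"donor"``).
    """

    pixels: np.ndarray
    pixel_size: float
    channel_name: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ValueError(f"expected a 2D image, got shape {px.shape}")
        if not np.all(np.isfinite(px)):
            raise ValueError("image contains non-finite pixels")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray) -> "IntensityImage":
        return IntensityImage(pixels, self.pixel_size, self.channel_name)


@dataclass
class CorrectionRecord:
    """Provenance of the correction chain applied to one channel."""

    flatfield_applied: bool = False
    shift_xy: tuple[float, float] = (0.0, 0.0)
    background_level: float = 0.0
    smoothed: bool = False

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CorrectionRecord":
        d = json.loads(Path(path).read_text())
        d["shift_xy"] = tuple(d["shift_xy"])
        return cls(**d)


# ---------------------------------------------------------------------------
# corrections


def _polynomial_surface(img: np.ndarray, degree: int = 2) -> np.ndarray:
    """Least-squares fit of a low-order bivariate polynomial to an image."""
    ny, nx = img.shape
    y, x = np.mgrid[0:ny, 0:nx]
    # normalised coordinates keep the normal equations well conditioned
    xn = (x - nx / 2) / max(nx, 1)
    yn = (y - ny / 2) / max(ny, 1)
    cols = [np.ones_like(xn)]
    for d in range(1, degree + 1):
        for i in range(d + 1):
            cols.append(xn ** (d - i) * yn**i)
    A = np.stack([c.ravel() for c in cols], axis=1)
    coef, *_ = np.linalg.lstsq(A, img.ravel(), rcond=None)
    return (A @ coef).reshape(img.shape)


def correct_illumination(
    image: IntensityImage, flatfield: IntensityImage | None = None
) -> IntensityImage:
    """Remove a slowly varying illumination gradient.

    With a measured flat-field, the image is divided by the flat-field
    normalised to unit mean (so mean intensity is preserved). Without
    one, a 2nd-degree bivariate polynomial surface is fit to the image
    itself and divided out; higher orders would start absorbing cell
    signal.
    """
    px = image.pixels
    if flatfield is not None:
        ff = flatfield.pixels
        if ff.shape != px.shape:
            raise ValueError("flatfield shape does not match image")
        if np.any(ff <= 0):
            raise ValueError("flatfield must be strictly positive")
        surface = ff
    else:
        surface = _polynomial_surface(px, degree=2)
        floor = 1e-6 * max(abs(surface).max(), 1.0)
        surface = np.maximum(surface, floor)
    surface = surface / surface.mean()
    return image.with_pixels(px / surface)


def _phase_correlation_surface(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    fa = np.fft.fft2(a - a.mean())
    fb = np.fft.fft2(b - b.mean())
    cross = fa * np.conj(fb)
    mag = np.abs(cross)
    cross /= np.maximum(mag, 1e-15 * mag.max() + 1e-30)
    return np.real(np.fft.ifft2(cross))


def register_shift(
    reference: IntensityImage, moving: IntensityImage, upsample_factor: int = 100
) -> tuple[IntensityImage, tuple[float, float]]:
    """Estimate and undo the translation of ``moving`` relative to ``reference``.

    Translation is estimated by phase correlation with subpixel (upsampled
    DFT) refinement; only translation is modelled. Returns the moving
    image resampled onto the reference frame and the estimated shift
    ``(dy, dx)`` — the displacement of ``moving`` with respect to
    ``reference`` (so ``reference`` rolled by ``(3, -2)`` reports
    ``(3, -2)``).

    An indistinct correlation peak (peak / runner-up < 1.05) or a shift
    larger than a quarter of the image emits a warning and applies no
    shift.
    """
    ref, mov = reference.pixels, moving.pixels
    if ref.shape != mov.shape:
        raise ValueError("reference and moving images must share a shape")

    surf = _phase_correlation_surface(ref, mov)
    peak_idx = np.unravel_index(np.argmax(surf), surf.shape)
    peak = surf[peak_idx]
    # runner-up outside a 3x3 exclusion zone around the main peak
    masked = surf.copy()
    for dy in (-1, 0, 1):
        for dx in (-1, 0, 1):
            masked[(peak_idx[0] + dy) % surf.shape[0], (peak_idx[1] + dx) % surf.shape[1]] = -np.inf
    runner = masked.max()
    if peak <= 0 or (runner > 0 and peak / runner < 1.05):
        warnings.warn(
            "indistinct correlation peak; applying zero shift", RegistrationWarning
        )
        return moving.with_pixels(mov.copy()), (0.0, 0.0)

    applied, _, _ = phase_cross_correlation(ref, mov, upsample_factor=upsample_factor)
    shift_est = tuple(-float(s) for s in applied)  # displacement of moving vs reference

    if np.hypot(*shift_est) >= min(ref.shape) / 4:
        warnings.warn(
            f"estimated shift {shift_est} exceeds 1/4 of the image; "
            "registration failure suspected, applying zero shift",
            RegistrationWarning,
        )
        return moving.with_pixels(mov.copy()), (0.0, 0.0)

    shifted = ndi.shift(mov, applied, order=1, mode="nearest")
    return moving.with_pixels(shifted), shift_est


def background_level(
    image: IntensityImage, background_roi: np.ndarray | None = None
) -> float:
    """Background estimate: mean over a cell-free ROI, or the image's 5th percentile.

    The percentile fallback is robust to sparsely distributed bright cells.
    """
    if background_roi is not None:
        roi = np.asarray(background_roi, dtype=bool)
        if roi.shape != image.shape:
            raise ValueError("background ROI shape does not match image")
        n = int(roi.sum())
        if n == 0:
            raise ValueError("background ROI is empty")
        if n < 100:
            raise ValueError(f"background ROI has only {n} pixels (need >= 100)")
        return float(image.pixels[roi].mean())
    return float(np.percentile(image.pixels, 5))


def subtract_background(
    image: IntensityImage, background_roi: np.ndarray | None = None
) -> IntensityImage:
    """Subtract a scalar background level; negative results clip to zero."""
    level = background_level(image, background_roi)
    return image.with_pixels(np.clip(image.pixels - level, 0.0, None))


def smooth3(image: IntensityImage) -> IntensityImage:
    """One pass of a 3x3 uniform mean filter with replicate borders.

    The 2D analogue of a 3-point moving average; constants map to
    themselves and total intensity is preserved to well under 0.5% for
    images of 64x64 and up.
    """
    if min(image.shape) < 3:
        raise ValueError("image must be at least 3x3 to smooth")
    return image.with_pixels(ndi.uniform_filter(image.pixels, size=3, mode="nearest"))


def correct_channel(
    image: IntensityImage,
    flatfield: IntensityImage | None = None,
    reference: IntensityImage | None = None,
    background_roi: np.ndarray | None = None,
    smooth: bool = True,
    fit_illumination: bool = False,
) -> tuple[IntensityImage, CorrectionRecord]:
    """Apply the full chain: illumination -> shift -> background -> smoothing.

    Without a measured flat-field the illumination step is skipped unless
    ``fit_illumination`` is set: the self-fit polynomial surface is meant
    for slowly varying lamp gradients across a large field and will start
    absorbing cell signal on sparse scenes.
    """
    rec = CorrectionRecord()
    if flatfield is not None or fit_illumination:
        out = correct_illumination(image, flatfield)
    else:
        out = image.with_pixels(image.pixels.copy())
    rec.flatfield_applied = flatfield is not None
    if reference is not None:
        out, rec.shift_xy = register_shift(reference, out)
    rec.background_level = background_level(out, background_roi)
    out = out.with_pixels(np.clip(out.pixels - rec.background_level, 0.0, None))
    if smooth:
        out = smooth3(out)
        rec.smoothed = True
    return out, rec


# ---------------------------------------------------------------------------
# I/O


def read_tiff(
    path: str | Path, pixel_size: float, page: int = 0, channel_name: str = ""
) -> IntensityImage:
    """Read one page of a (possibly multi-page) 16-bit or float TIFF."""
    arr = tifffile.imread(str(path))
    if arr.ndim == 3:
        arr = arr[page]
    elif page != 0:
        raise IndexError(f"TIFF has a single page; page {page} requested")
    return IntensityImage(arr, pixel_size, channel_name)


def write_tiff(path: str | Path, image: IntensityImage) -> None:
    """Write an image as 32-bit float TIFF."""
    tifffile.imwrite(str(path), image.pixels.astype(np.float32))


def load_channels(
    tiff_path: str | Path, config_path: str | Path
) -> dict[str, IntensityImage]:
    """Load named channels from a multi-page TIFF using a YAML mapping.

    The YAML file must contain ``pixel_size`` (um/px) and ``channels``,
    a mapping of channel name to zero-based page index.
    """
    cfg = yaml.safe_load(Path(config_path).read_text())
    ps = float(cfg["pixel_size"])
    return {
        name: read_tiff(tiff_path, ps, page=int(page), channel_name=name)
        for name, page in cfg["channels"].items()
    }
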