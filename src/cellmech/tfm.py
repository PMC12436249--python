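"""Traction force microscopy by regularized Fourier-transform traction cytometry.

Cell-generated substrate stresses are inferred from the displacement of
fiducial beads between a loaded image (cell attached) and a relaxed
image (after lysis). Displacements are estimated by PIV-style windowed
cross-correlation with subpixel peak interpolation; the inverse elastic
problem is solved wavevector-by-wavevector under the Boussinesq
half-space model with zeroth-order Tikhonov regularization (FTTC).

The Fourier-domain Boussinesq kernel relating surface traction t(k) (Pa)
to surface displacement u(k) (um) of a semi-infinite incompressible
elastic half-space with Young's modulus E and Poisson ratio nu is

    G(k) = 2 (1 + nu) / (E k^3) * [ (1-nu) k^2 + nu ky^2,  -nu kx ky
                                    -nu kx ky,  (1-nu) k^2 + nu kx^2 ]

with k in rad/um; the k = 0 mode (rigid motion) is set to zero in both
directions. The regularized inverse is
t(k) = (G^T G + lambda^2 I)^-1 G^T u(k), with lambda applied to the
kernel in physical units (um/Pa), so a given lambda means the same
physical noise cut-off regardless of grid size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi

from .image import IntensityImage
from .segmentation import LabelMask


class TfmWarning(UserWarning):
    pass


@dataclass(frozen=True)
class SubstrateModel:
    """Linear-elastic half-space substrate.

    ``poisson_ratio`` defaults to 0.5 (incompressible silicone or
    polyacrylamide gel); ``pixel_size`` is the camera pixel size in um.
    """

    young_modulus: float  # Pa
    poisson_ratio: float = 0.5
    pixel_size: float = 0.103  # um/px

    def __post_init__(self) -> None:
        if not self.young_modulus > 0:
            raise ValueError("young_modulus must be positive")
        if not 0 <= self.poisson_ratio <= 0.5:
            raise ValueError("poisson_ratio must lie in [0, 0.5]")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")


@dataclass(frozen=True)
class DisplacementField:
    """Regular-grid displacement field in um.

    ``u`` is the x (column-direction) and ``v`` the y (row-direction)
    displacement; ``validity`` is False where a vector was replaced by
    interpolation. ``grid_spacing`` is the grid pitch in image pixels,
    ``origin`` the image-pixel coordinate (row, col) of grid node [0, 0]
    and ``pixel_size`` the um-per-image-pixel scale.
    """

    u: np.ndarray
    v: np.ndarray
    validity: np.ndarray
    grid_spacing: float
    pixel_size: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not (self.u.shape == self.v.shape == self.validity.shape):
            raise ValueError("u, v and validity must be congruent")
        if not self.grid_spacing > 0:
            raise ValueError("grid_spacing must be positive")

    @property
    def spacing_um(self) -> float:
        return self.grid_spacing * self.pixel_size


@dataclass(frozen=True)
class TractionField:
    """Regular-grid traction field in Pa, on the displacement grid."""

    tx: np.ndarray
    ty: np.ndarray
    regularization: float
    grid_spacing: float
    pixel_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    magnitude: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.tx.shape != self.ty.shape:
            raise ValueError("tx and ty must be congruent")
        object.__setattr__(self, "magnitude", np.hypot(self.tx, self.ty))

    @property
    def spacing_um(self) -> float:
        return self.grid_spacing * self.pixel_size


# ---------------------------------------------------------------------------
# Boussinesq kernel


def _kernel(
    shape: tuple[int, int], spacing_um: float, substrate: SubstrateModel
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fourier Boussinesq kernel components (Gxx, Gxy, Gyy) in um/Pa.

    The k = 0 entry is left at zero (handled by zeroing that mode).
    """
    ny, nx = shape
    kx = 2 * np.pi * np.fft.fftfreq(nx, d=spacing_um)
    ky = 2 * np.pi * np.fft.fftfreq(ny, d=spacing_um)
    KX, KY = np.meshgrid(kx, ky)
    K2 = KX**2 + KY**2
    K = np.sqrt(K2)
    K3 = np.where(K > 0, K**3, 1.0)  # guard; k=0 zeroed below
    E, nu = substrate.young_modulus, substrate.poisson_ratio
    pref = 2.0 * (1.0 + nu) / (E * K3)
    Gxx = pref * ((1.0 - nu) * K2 + nu * KY**2)
    Gyy = pref * ((1.0 - nu) * K2 + nu * KX**2)
    Gxy = -pref * nu * KX * KY
    Gxx[0, 0] = Gxy[0, 0] = Gyy[0, 0] = 0.0
    return Gxx, Gxy, Gyy


def boussinesq_forward(
    traction: TractionField, substrate: SubstrateModel
) -> DisplacementField:
    """Surface displacement of the elastic half-space under a traction field.

    Exact in the Fourier (periodic-continuation) sense; the zero
    wavevector is set to zero, so no rigid-body motion is produced.
    """
    if not (np.all(np.isfinite(traction.tx)) and np.all(np.isfinite(traction.ty))):
        raise ValueError("traction field contains non-finite values")
    Gxx, Gxy, Gyy = _kernel(traction.tx.shape, traction.spacing_um, substrate)
    tx_h = np.fft.fft2(traction.tx)
    ty_h = np.fft.fft2(traction.ty)
    ux_h = Gxx * tx_h + Gxy * ty_h
    uy_h = Gxy * tx_h + Gyy * ty_h
    ux_h[0, 0] = uy_h[0, 0] = 0.0
    u = np.real(np.fft.ifft2(ux_h))
    v = np.real(np.fft.ifft2(uy_h))
    return DisplacementField(
        u=u,
        v=v,
        validity=np.ones_like(u, dtype=bool),
        grid_spacing=traction.grid_spacing,
        pixel_size=traction.pixel_size,
        origin=traction.origin,
    )


def fill_invalid(field: DisplacementField) -> DisplacementField:
    """Replace invalid vectors with the nearest valid vector."""
    if field.validity.all():
        return field
    if not field.validity.any():
        raise ValueError("no valid vectors to interpolate from")
    _, (ir, ic) = ndi.distance_transform_edt(~field.validity, return_indices=True)
    return replace(field, u=field.u[ir, ic], v=field.v[ir, ic])


def fttc_inverse(
    field: DisplacementField, substrate: SubstrateModel, lam: float = 1e-4
) -> TractionField:
    """Tikhonov-regularized FTTC inversion of a displacement field.

    Solves (G^T G + lambda^2 I) t(k) = G^T u(k) per wavevector with the
    same kernel as the forward model; ``lam`` is in the kernel's
    physical units (um/Pa). The solution is linear in u for fixed
    lambda, and its L2 norm is non-increasing in lambda.
    """
    if lam < 0:
        raise ValueError("lam must be >= 0")
    field = fill_invalid(field)
    Gxx, Gxy, Gyy = _kernel(field.u.shape, field.spacing_um, substrate)
    ux_h = np.fft.fft2(field.u)
    uy_h = np.fft.fft2(field.v)
    # G is symmetric, so G^T G has entries in the same three components
    a = Gxx**2 + Gxy**2 + lam**2
    b = Gxy * (Gxx + Gyy)
    c = Gyy**2 + Gxy**2 + lam**2
    rx = Gxx * ux_h + Gxy * uy_h
    ry = Gxy * ux_h + Gyy * uy_h
    det = a * c - b**2
    det = np.where(det > 0, det, 1.0)
    tx_h = (c * rx - b * ry) / det
    ty_h = (a * ry - b * rx) / det
    tx_h[0, 0] = ty_h[0, 0] = 0.0
    tx = np.real(np.fft.ifft2(tx_h))
    ty = np.real(np.fft.ifft2(ty_h))
    return TractionField(
        tx=tx,
        ty=ty,
        regularization=lam,
        grid_spacing=field.grid_spacing,
        pixel_size=field.pixel_size,
        origin=field.origin,
    )


# ---------------------------------------------------------------------------
# displacement estimation (PIV)


def _subpixel_offset(c_minus: float, c0: float, c_plus: float) -> float:
    """Three-point Gaussian (log-parabolic) peak interpolation along one axis."""
    if c_minus > 0 and c0 > 0 and c_plus > 0:
        lm, l0, lp = np.log(c_minus), np.log(c0), np.log(c_plus)
    else:
        lm, l0, lp = c_minus, c0, c_plus
    denom = lm - 2 * l0 + lp
    if denom >= 0:
        return 0.0
    return float(np.clip(0.5 * (lm - lp) / denom, -1.0, 1.0))


def estimate_displacements(
    loaded: IntensityImage,
    relaxed: IntensityImage,
    window_px: int = 32,
    overlap: float = 0.5,
    taper: bool = False,
    median_threshold: float = 2.0,
) -> DisplacementField:
    """PIV-style bead displacement field, loaded relative to relaxed, in um.

    Each interrogation window of the loaded image is cross-correlated
    (FFT, mean-subtracted, optional Hann taper) against the same window
    of the relaxed image; the correlation peak is refined with a
    three-point Gaussian fit per axis. Vectors failing a peak-quality
    check or the normalized-median outlier test are replaced by the
    local median of valid neighbours and marked invalid in ``validity``.
    """
    a, b = loaded.pixels, relaxed.pixels
    if a.shape != b.shape:
        raise ValueError("loaded and relaxed images must share a shape")
    if a.std() < 1e-12 or b.std() < 1e-12:
        raise ValueError("image variance too low: no beads detected")
    if not 0 <= overlap < 1:
        raise ValueError("overlap must lie in [0, 1)")
    w = int(window_px)
    step = max(int(round(w * (1 - overlap))), 1)
    ny = (a.shape[0] - w) // step + 1
    nx = (a.shape[1] - w) // step + 1
    if ny < 2 or nx < 2:
        raise ValueError("image too small for the requested window/overlap")

    win = (
        np.hanning(w)[:, None] * np.hanning(w)[None, :] if taper else np.ones((w, w))
    )
    u_px = np.zeros((ny, nx))
    v_px = np.zeros((ny, nx))
    valid = np.ones((ny, nx), dtype=bool)
    half = w // 2

    def _correlate(wa: np.ndarray, wb: np.ndarray) -> np.ndarray:
        wa = (wa - wa.mean()) * win
        wb = (wb - wb.mean()) * win
        corr = np.real(np.fft.ifft2(np.fft.fft2(wa) * np.conj(np.fft.fft2(wb))))
        return np.fft.fftshift(corr)

    for i in range(ny):
        for j in range(nx):
            r0, c0 = i * step, j * step
            wa = a[r0 : r0 + w, c0 : c0 + w]
            corr = _correlate(wa, b[r0 : r0 + w, c0 : c0 + w])
            pk = np.unravel_index(np.argmax(corr), corr.shape)
            peak_val = corr[pk]
            if peak_val <= 0 or (peak_val - corr.mean()) < 3 * corr.std():
                valid[i, j] = False
                continue
            dy = pk[0] - half
            dx = pk[1] - half
            if max(abs(dy), abs(dx)) > w // 3:
                valid[i, j] = False
                continue
            # second pass: re-correlate against the relaxed window cropped at
            # the integer displacement, so the residual peak is symmetric
            # (removes the loss-of-pairs bias of one-pass correlation)
            ry, rx = r0 - dy, c0 - dx
            if 0 <= ry <= a.shape[0] - w and 0 <= rx <= a.shape[1] - w:
                corr = _correlate(wa, b[ry : ry + w, rx : rx + w])
                pk2 = np.unravel_index(np.argmax(corr), corr.shape)
                if max(abs(pk2[0] - half), abs(pk2[1] - half)) <= 2:
                    pk = pk2
                    peak_val = corr[pk]
                    dy += pk[0] - half
                    dx += pk[1] - half
            elif dy or dx:
                # matching relaxed content lies (partly) outside the frame;
                # the one-pass estimate is bias-prone, so hand the vector to
                # the neighbourhood-median replacement
                valid[i, j] = False
            # subpixel refinement, neighbours taken circularly
            cm = corr[(pk[0] - 1) % w, pk[1]]
            cp = corr[(pk[0] + 1) % w, pk[1]]
            dy += _subpixel_offset(cm, peak_val, cp)
            cm = corr[pk[0], (pk[1] - 1) % w]
            cp = corr[pk[0], (pk[1] + 1) % w]
            dx += _subpixel_offset(cm, peak_val, cp)
            v_px[i, j] = dy
            u_px[i, j] = dx

    if valid.sum() < 0.5 * valid.size:
        raise ValueError(
            f"{valid.size - int(valid.sum())}/{valid.size} windows invalid: "
            "images not comparable"
        )

    valid &= ~_normalized_median_outliers(u_px, v_px, valid, median_threshold)
    u_px, v_px = _replace_with_local_median(u_px, v_px, valid)

    ps = loaded.pixel_size
    return DisplacementField(
        u=u_px * ps,
        v=v_px * ps,
        validity=valid,
        grid_spacing=float(step),
        pixel_size=ps,
        origin=((w - 1) / 2.0, (w - 1) / 2.0),
    )


def _neighbour_stack(x: np.ndarray) -> np.ndarray:
    """3x3 neighbourhoods (excluding centre) as a stack, edge-padded with NaN."""
    p = np.pad(x.astype(float), 1, constant_values=np.nan)
    stack = []
    for dy in (-1, 0, 1):
        for dx in (-1, 0, 1):
            if dy == dx == 0:
                continue
            stack.append(p[1 + dy : 1 + dy + x.shape[0], 1 + dx : 1 + dx + x.shape[1]])
    return np.stack(stack)


def _normalized_median_outliers(
    u: np.ndarray, v: np.ndarray, valid: np.ndarray, threshold: float, eps: float = 0.1
) -> np.ndarray:
    """Universal normalized-median test over 3x3 neighbourhoods."""
    out = np.zeros(u.shape, dtype=bool)
    for comp in (u, v):
        masked = np.where(valid, comp, np.nan)
        neigh = _neighbour_stack(masked)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN neighbourhoods
            med = np.nanmedian(neigh, axis=0)
            res = np.nanmedian(np.abs(neigh - med), axis=0)
        r = np.abs(comp - med) / (res + eps)
        out |= np.isfinite(r) & (r > threshold)
    return out & valid  # only flag vectors that were considered valid


def _replace_with_local_median(
    u: np.ndarray, v: np.ndarray, valid: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Replace invalid vectors by the median of valid neighbours (then nearest)."""
    u, v = u.copy(), v.copy()
    for comp in (u, v):
        masked = np.where(valid, comp, np.nan)
        neigh = _neighbour_stack(masked)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            med = np.nanmedian(neigh, axis=0)
        fill = ~valid & np.isfinite(med)
        comp[fill] = med[fill]
        still = ~valid & ~np.isfinite(med)
        if still.any() and valid.any():
            _, (ir, ic) = ndi.distance_transform_edt(~valid, return_indices=True)
            comp[still] = comp[ir[still], ic[still]]
    return u, v


def drift_correct(
    field: DisplacementField,
    cell_mask: LabelMask | None,
    margin_px: float = 20.0,
    min_far_vectors: int = 20,
) -> DisplacementField:
    """Remove rigid stage drift using the far field.

    Subtracts the median displacement of grid nodes lying outside the
    cell mask dilated by ``margin_px`` (where true deformation is
    negligible) from every vector. With no mask, all valid vectors are
    treated as far field (appropriate for cell-free control pairs).
    """
    if cell_mask is None:
        far = field.validity.copy()
    else:
        dil = ndi.binary_dilation(
            cell_mask.foreground(), ndi.generate_binary_structure(2, 1), iterations=max(int(margin_px), 1)
        )
        rows = (field.origin[0] + np.arange(field.u.shape[0]) * field.grid_spacing).astype(int)
        cols = (field.origin[1] + np.arange(field.u.shape[1]) * field.grid_spacing).astype(int)
        rows = np.clip(rows, 0, dil.shape[0] - 1)
        cols = np.clip(cols, 0, dil.shape[1] - 1)
        far = ~dil[np.ix_(rows, cols)] & field.validity
    if far.sum() < min_far_vectors:
        warnings.warn(
            f"only {int(far.sum())} far-field vectors (< {min_far_vectors}); "
            "no drift correction applied",
            TfmWarning,
        )
        return field
    du = float(np.median(field.u[far]))
    dv = float(np.median(field.v[far]))
    return replace(field, u=field.u - du, v=field.v - dv)


def average_traction_stress(
    traction: TractionField, cell_mask: LabelMask
) -> "dict[int, float]":
    """Mean traction magnitude (Pa) over each cell's mask, per cell label.

    The pixel-resolution cell mask is sampled at the traction grid nodes
    (nearest pixel).
    """
    labels = cell_mask.label_values
    if len(labels) == 0:
        raise ValueError("cell mask is empty")
    rows = np.rint(
        traction.origin[0] + np.arange(traction.tx.shape[0]) * traction.grid_spacing
    ).astype(int)
    cols = np.rint(
        traction.origin[1] + np.arange(traction.tx.shape[1]) * traction.grid_spacing
    ).astype(int)
    rows = np.clip(rows, 0, cell_mask.shape[0] - 1)
    cols = np.clip(cols, 0, cell_mask.shape[1] - 1)
    sampled = cell_mask.labels[np.ix_(rows, cols)]
    out: dict[int, float] = {}
    for lab in labels:
        sel = sampled == lab
        if not sel.any():
            warnings.warn(f"cell {lab} covers no traction grid nodes", TfmWarning)
            continue
        out[int(lab)] = float(traction.magnitude[sel].mean())
    return out


def net_force_fraction(traction: TractionField) -> float:
    """|vector sum of forces| / sum of |forces|; ~0 for balanced fields."""
    fx = traction.tx.sum()
    fy = traction.ty.sum()
    total = traction.magnitude.sum()
    if total == 0:
        return 0.0
    return float(np.hypot(fx, fy) / total)
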