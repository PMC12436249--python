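"""Ground-truthed synthetic scenes for every pipeline stage.

Three generators emulate the three kinds of raw data the pipeline
consumes, each emitting the rendered images together with the exact
truth used to render them:

* ``make_cell_scene`` — DAPI / F-actin / YAP triples: anti-aliased
  elliptical nuclei inside elliptical cell silhouettes, with the YAP
  channel realising a configured nuclear-to-cytoplasmic ratio.
* ``make_fret_scene`` — donor / FRET / acceptor triples built from a
  per-pixel sensor concentration c and FRET efficiency E with known
  leakage fractions:  I_d = k_d c (1-E),  I_a = k_a c,
  I_f = k_f c E + dL I_d + aL I_a.  Under this minimal three-gain
  linear model the sensitized-emission index equation recovers
  exactly k_f E / k_a, which the truth map records.
* ``make_tfm_scene`` — bead image pairs: Gaussian-spot beads at random
  subpixel positions, displaced by the Boussinesq half-space response
  to a force-balanced traction patch set (plus optional uniform drift).

Noise is Poisson shot noise followed by additive Gaussian read noise,
both seeded; every generator is a pure function of its configuration
including the seed (same config, bit-identical scene).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .image import IntensityImage
from .segmentation import LabelMask
from .tfm import DisplacementField, SubstrateModel, TractionField, boussinesq_forward


class PlacementError(RuntimeError):
    """Requested objects could not be placed without overlap."""


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class NoiseParams:
    """Camera noise: Poisson shot noise then Gaussian read noise, plus offset."""

    gaussian_sd: float = 10.0
    poisson: bool = True
    background: float = 20.0  # additive offset applied before noise


@dataclass(frozen=True)
class CellSpec:
    """One rendered cell: ellipse geometry plus channel intensities."""

    center: tuple[float, float]  # (row, col) px
    cell_axes: tuple[float, float]  # semi-axes, px
    nucleus_axes: tuple[float, float]
    angle_deg: float = 0.0
    dapi_intensity: float = 3000.0
    factin_intensity: float = 1000.0
    yap_cyto_intensity: float = 150.0
    nc_ratio_true: float = 2.0


@dataclass(frozen=True)
class FretParams:
    """Generative parameters of a three-cube FRET scene."""

    E_cyto: float = 0.3
    E_puncta: float | None = None  # defaults to E_cyto
    c_cyto: float = 500.0
    c_puncta: float = 2000.0
    dL_true: float = 0.12
    aL_true: float = 0.08
    k_d: float = 1.0
    k_a: float = 1.0
    k_f: float = 1.0
    n_puncta: int = 12
    puncta_axes: tuple[float, float] = (6.0, 3.0)
    # smooth lognormal expression heterogeneity: sigma of log-concentration
    # and its correlation length in px (0 disables)
    c_texture_sigma: float = 0.4
    c_texture_length: float = 8.0
    mode: str = "fret"  # "fret" | "donor_only" | "acceptor_only"


@dataclass(frozen=True)
class TractionPatch:
    """A disk or Gaussian traction patch with a fixed direction."""

    center: tuple[float, float]  # (row, col) px
    radius_px: float  # disk radius, or Gaussian sigma
    magnitude: float  # Pa
    direction_deg: float = 0.0  # 0 = +x (columns)
    shape: str = "gaussian"  # "gaussian" | "disk"


@dataclass(frozen=True)
class TfmParams:
    patches: tuple[TractionPatch, ...] = ()
    young_modulus: float = 10_000.0  # Pa
    poisson_ratio: float = 0.5
    bead_density: float = 0.03  # beads per px^2
    bead_sigma: float = 1.2  # px, ~diffraction-limited 100 nm bead at 63x/1.4NA
    bead_amplitude: float = 1000.0
    drift_px: tuple[float, float] = (0.0, 0.0)  # (drow, dcol) added to loaded


@dataclass(frozen=True)
class SceneConfig:
    """Full specification of one synthetic scene; the seed fixes everything."""

    shape: tuple[int, int] = (256, 256)
    pixel_size: float = 0.325  # um/px
    seed: int = 0
    noise: NoiseParams = field(default_factory=NoiseParams)
    antialias: bool = True
    cells: tuple[CellSpec, ...] = ()
    fret: FretParams = field(default_factory=FretParams)
    tfm: TfmParams = field(default_factory=TfmParams)


@dataclass
class SyntheticTruth:
    """Per-scene ground truth emitted alongside the rendered images."""

    nucleus_mask: LabelMask | None = None
    cell_mask: LabelMask | None = None
    adhesion_mask: LabelMask | None = None
    nc_ratio_true: dict[int, float] | None = None
    fret_index_true: np.ndarray | None = None
    dL_true: float | None = None
    aL_true: float | None = None
    displacement_true: DisplacementField | None = None
    traction_true: TractionField | None = None


# ---------------------------------------------------------------------------
# rendering primitives


def ellipse_coverage(
    shape: tuple[int, int],
    center: tuple[float, float],
    axes: tuple[float, float],
    angle_deg: float = 0.0,
    supersample: int = 4,
    antialias: bool = True,
) -> np.ndarray:
    """Pixel coverage fraction of a filled, rotated ellipse.

    With ``antialias`` the fraction is estimated on a supersampled grid;
    without, the indicator at pixel centres (exact binary rendering used
    by the truth masks and by exactness tests).
    """
    cy, cx = center
    a, b = axes
    th = np.deg2rad(angle_deg)
    r0 = max(int(np.floor(cy - max(a, b) - 2)), 0)
    r1 = min(int(np.ceil(cy + max(a, b) + 2)) + 1, shape[0])
    c0 = max(int(np.floor(cx - max(a, b) - 2)), 0)
    c1 = min(int(np.ceil(cx + max(a, b) + 2)) + 1, shape[1])
    out = np.zeros(shape)
    if r1 <= r0 or c1 <= c0:
        return out
    s = supersample if antialias else 1
    offs = (np.arange(s) + 0.5) / s - 0.5
    rows = (np.arange(r0, r1)[:, None] + offs[None, :]).ravel()
    cols = (np.arange(c0, c1)[:, None] + offs[None, :]).ravel()
    Y = rows[:, None] - cy
    X = cols[None, :] - cx
    Xr = X * np.cos(th) + Y * np.sin(th)
    Yr = -X * np.sin(th) + Y * np.cos(th)
    inside = (Xr / max(b, 1e-9)) ** 2 + (Yr / max(a, 1e-9)) ** 2 <= 1.0
    cov = inside.reshape(r1 - r0, s, c1 - c0, s).mean(axis=(1, 3))
    out[r0:r1, c0:c1] = cov
    return out


def _smooth_field(
    shape: tuple[int, int], length: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance Gaussian random field with the given correlation length."""
    from scipy import ndimage as ndi

    g = ndi.gaussian_filter(rng.standard_normal(shape), length, mode="wrap")
    sd = g.std()
    return g / sd if sd > 0 else g


def _apply_noise(img: np.ndarray, noise: NoiseParams, rng: np.random.Generator) -> np.ndarray:
    out = img + noise.background
    if noise.poisson:
        out = rng.poisson(np.clip(out, 0, None)).astype(float)
    if noise.gaussian_sd > 0:
        out = out + rng.normal(0.0, noise.gaussian_sd, out.shape)
    return np.clip(out, 0.0, None)


def _label_from_coverages(
    coverages: list[np.ndarray], pixel_size: float, kind: str
) -> LabelMask:
    labels = np.zeros(coverages[0].shape if coverages else (0, 0), dtype=np.int32)
    for i, cov in enumerate(coverages, start=1):
        labels[cov > 0.5] = i
    return LabelMask(labels, pixel_size, kind)


# ---------------------------------------------------------------------------
# cell scenes


def random_cell_specs(
    shape: tuple[int, int],
    n_cells: int,
    rng: np.random.Generator,
    cell_axes: tuple[float, float] = (45.0, 35.0),
    nucleus_axes: tuple[float, float] = (20.0, 12.0),
    nc_ratio_true: float = 2.0,
    yap_cyto_intensity: float = 150.0,
    margin: float = 8.0,
    max_attempts: int = 1000,
) -> tuple[CellSpec, ...]:
    """Place ``n_cells`` non-overlapping cells uniformly at random.

    Raises :class:`PlacementError` if a non-overlapping layout cannot be
    found within ``max_attempts`` placement attempts.
    """
    placed: list[CellSpec] = []
    rmax = max(cell_axes)
    attempts = 0
    while len(placed) < n_cells:
        if attempts >= max_attempts:
            raise PlacementError(
                f"could not place {n_cells} cells in {max_attempts} attempts"
            )
        attempts += 1
        cy = rng.uniform(rmax + margin, shape[0] - rmax - margin)
        cx = rng.uniform(rmax + margin, shape[1] - rmax - margin)
        angle = rng.uniform(0, 180)
        if any(
            np.hypot(cy - p.center[0], cx - p.center[1]) < 2 * rmax + margin
            for p in placed
        ):
            continue
        placed.append(
            CellSpec(
                center=(cy, cx),
                cell_axes=cell_axes,
                nucleus_axes=nucleus_axes,
                angle_deg=angle,
                nc_ratio_true=nc_ratio_true,
                yap_cyto_intensity=yap_cyto_intensity,
            )
        )
    return tuple(placed)


def _check_no_overlap(config: SceneConfig) -> None:
    covs = [
        ellipse_coverage(config.shape, c.center, c.cell_axes, c.angle_deg, antialias=False)
        for c in config.cells
    ]
    total = np.zeros(config.shape)
    for cov in covs:
        total += cov > 0
    if (total > 1).any():
        raise PlacementError("cell silhouettes overlap; the generator rejects this")


def make_cell_scene(
    config: SceneConfig,
) -> tuple[IntensityImage, IntensityImage, IntensityImage, SyntheticTruth]:
    """Render (dapi, factin, yap) channels plus truth masks and ratios."""
    _check_no_overlap(config)
    rng = np.random.default_rng(config.seed)
    shape, ps, aa = config.shape, config.pixel_size, config.antialias
    dapi = np.zeros(shape)
    factin = np.zeros(shape)
    yap = np.zeros(shape)
    nuc_covs, cell_covs, ratios = [], [], {}
    for i, cell in enumerate(config.cells, start=1):
        ncov = ellipse_coverage(shape, cell.center, cell.nucleus_axes, cell.angle_deg, antialias=aa)
        ccov = ellipse_coverage(shape, cell.center, cell.cell_axes, cell.angle_deg, antialias=aa)
        dapi += cell.dapi_intensity * ncov
        factin += cell.factin_intensity * ccov
        yap += cell.yap_cyto_intensity * ccov
        yap += (cell.nc_ratio_true - 1.0) * cell.yap_cyto_intensity * ncov
        nuc_covs.append(ncov)
        cell_covs.append(ccov)
        ratios[i] = cell.nc_ratio_true

    truth = SyntheticTruth(
        nucleus_mask=_label_from_coverages(nuc_covs or [np.zeros(shape)], ps, "nucleus"),
        cell_mask=_label_from_coverages(cell_covs or [np.zeros(shape)], ps, "cell"),
        nc_ratio_true=ratios,
    )
    imgs = tuple(
        IntensityImage(_apply_noise(ch, config.noise, rng), ps, name)
        for ch, name in ((dapi, "dapi"), (factin, "factin"), (yap, "yap"))
    )
    return imgs[0], imgs[1], imgs[2], truth


# ---------------------------------------------------------------------------
# FRET scenes


def make_fret_scene(
    config: SceneConfig,
) -> tuple[IntensityImage, IntensityImage, IntensityImage, SyntheticTruth]:
    """Render (donor, fret, acceptor) channels plus the exact index truth.

    ``config.fret.mode`` selects the full-sensor scene or the donor-only
    / acceptor-only calibration scenes (E = 0 with the other fluorophore
    absent), used to fit dL and aL.
    """
    _check_no_overlap(config)
    rng = np.random.default_rng(config.seed)
    p = config.fret
    shape, ps, aa = config.shape, config.pixel_size, config.antialias
    k_d, k_a = p.k_d, p.k_a
    E_cyto = p.E_cyto
    E_puncta = p.E_cyto if p.E_puncta is None else p.E_puncta
    if p.mode == "donor_only":
        k_a, E_cyto, E_puncta = 0.0, 0.0, 0.0
    elif p.mode == "acceptor_only":
        k_d, E_cyto, E_puncta = 0.0, 0.0, 0.0
    elif p.mode != "fret":
        raise ValueError(f"unknown fret scene mode {p.mode!r}")
    if not (0 <= E_cyto < 1 and 0 <= E_puncta < 1):
        raise ValueError("FRET efficiency must lie in [0, 1)")

    conc = np.zeros(shape)
    E_map = np.zeros(shape)
    cell_covs, adh_covs = [], []
    for cell in config.cells:
        ccov = ellipse_coverage(shape, cell.center, cell.cell_axes, cell.angle_deg, antialias=aa)
        cell_covs.append(ccov)
        conc += p.c_cyto * ccov
        # puncta placed inside the nucleus-free periphery of the cell
        a_in, b_in = cell.cell_axes[0] * 0.85, cell.cell_axes[1] * 0.85
        a_out = max(cell.nucleus_axes) * 1.3
        th = np.deg2rad(cell.angle_deg)
        min_sep = 2.5 * max(p.puncta_axes)
        for _ in range(p.n_puncta):
            for _attempt in range(100):
                rho = np.sqrt(rng.uniform((a_out / a_in) ** 2, 1.0))
                phi = rng.uniform(0, 2 * np.pi)
                xr = rho * b_in * np.cos(phi)
                yr = rho * a_in * np.sin(phi)
                dy = xr * np.sin(th) + yr * np.cos(th)
                dx = xr * np.cos(th) - yr * np.sin(th)
                pc = (cell.center[0] + dy, cell.center[1] + dx)
                if all(
                    np.hypot(pc[0] - q.center[0], pc[1] - q.center[1]) > min_sep
                    for q in adh_covs
                ):
                    break
            acov = ellipse_coverage(
                shape, pc, p.puncta_axes, rng.uniform(0, 180), antialias=aa
            )
            adh_covs.append(_Punctum(pc, acov))
            conc += (p.c_puncta - p.c_cyto) * acov

    if p.c_texture_sigma > 0:
        g = _smooth_field(shape, p.c_texture_length, rng)
        conc = conc * np.exp(p.c_texture_sigma * g - p.c_texture_sigma**2 / 2)

    if adh_covs:
        pun_union = np.zeros(shape)
        for q in adh_covs:
            pun_union = np.maximum(pun_union, q.coverage)
        E_map = E_cyto + (E_puncta - E_cyto) * (pun_union > 0.5)
    else:
        E_map = np.full(shape, E_cyto)
    E_map = np.where(conc > 0, E_map, 0.0)

    donor = k_d * conc * (1.0 - E_map)
    acceptor = k_a * conc
    fret_ch = p.k_f * conc * E_map + p.dL_true * donor + p.aL_true * acceptor

    index_true = np.where(conc > 0, p.k_f * E_map / max(p.k_a, 1e-12), np.nan)
    truth = SyntheticTruth(
        cell_mask=_label_from_coverages(cell_covs or [np.zeros(shape)], ps, "cell"),
        adhesion_mask=_label_from_coverages(
            [q.coverage for q in adh_covs] or [np.zeros(shape)], ps, "adhesion"
        ),
        fret_index_true=index_true,
        dL_true=p.dL_true,
        aL_true=p.aL_true,
    )
    imgs = tuple(
        IntensityImage(_apply_noise(ch, config.noise, rng), ps, name)
        for ch, name in ((donor, "donor"), (fret_ch, "fret"), (acceptor, "acceptor"))
    )
    return imgs[0], imgs[1], imgs[2], truth


@dataclass(frozen=True)
class _Punctum:
    center: tuple[float, float]
    coverage: np.ndarray


# ---------------------------------------------------------------------------
# TFM scenes


def _paint_patches(
    shape: tuple[int, int], patches: tuple[TractionPatch, ...]
) -> tuple[np.ndarray, np.ndarray]:
    y, x = np.mgrid[0 : shape[0], 0 : shape[1]]
    tx = np.zeros(shape)
    ty = np.zeros(shape)
    for p in patches:
        r2 = (y - p.center[0]) ** 2 + (x - p.center[1]) ** 2
        if p.shape == "disk":
            w = (r2 <= p.radius_px**2).astype(float)
        elif p.shape == "gaussian":
            w = np.exp(-r2 / (2 * p.radius_px**2))
        else:
            raise ValueError(f"unknown patch shape {p.shape!r}")
        th = np.deg2rad(p.direction_deg)
        tx += p.magnitude * np.cos(th) * w
        ty += p.magnitude * np.sin(th) * w
    return tx, ty


def balanced_traction_truth(
    shape: tuple[int, int],
    patches: tuple[TractionPatch, ...],
    pixel_size: float,
    grid_spacing: float = 1.0,
) -> TractionField:
    """Paint traction patches and enforce exact force balance.

    If the configured patches carry a net force, a broad compensating
    Gaussian patch at the field centre absorbs it, so the vector sum of
    all forces is zero to machine precision.
    """
    tx, ty = _paint_patches(shape, patches)
    fx, fy = tx.sum(), ty.sum()
    if np.hypot(fx, fy) > 1e-9 * max(np.abs(tx).sum() + np.abs(ty).sum(), 1.0):
        sigma = min(shape) / 6.0
        y, x = np.mgrid[0 : shape[0], 0 : shape[1]]
        w = np.exp(
            -((y - shape[0] / 2) ** 2 + (x - shape[1] / 2) ** 2) / (2 * sigma**2)
        )
        w /= w.sum()
        tx -= fx * w
        ty -= fy * w
    # exact balance: spread any numerical residual uniformly
    tx -= tx.sum() / tx.size
    ty -= ty.sum() / ty.size
    return TractionField(
        tx=tx, ty=ty, regularization=0.0, grid_spacing=grid_spacing, pixel_size=pixel_size
    )


def make_tfm_scene(
    config: SceneConfig,
) -> tuple[IntensityImage, IntensityImage, SyntheticTruth]:
    """Render a (loaded, relaxed) bead image pair plus displacement truth.

    The relaxed image holds Gaussian spots at rest positions; in the
    loaded image each bead is shifted by the Boussinesq surface response
    to the truth traction, evaluated at its rest position, plus any
    configured uniform drift. Spots are evaluated analytically at
    subpixel positions (no rasterized shifting).
    """
    p = config.tfm
    if not 0.005 <= p.bead_density <= 0.1:
        raise ValueError("bead_density must lie in [0.005, 0.1] per px^2")
    rng = np.random.default_rng(config.seed)
    shape, ps = config.shape, config.pixel_size
    substrate = SubstrateModel(p.young_modulus, p.poisson_ratio, ps)

    traction = balanced_traction_truth(shape, p.patches, ps)
    disp = boussinesq_forward(traction, substrate)  # um, on the pixel grid

    n_beads = int(round(p.bead_density * shape[0] * shape[1]))
    pos = rng.uniform(0, 1, (n_beads, 2)) * np.array([shape[0] - 1, shape[1] - 1])

    from scipy.ndimage import map_coordinates

    u_at = map_coordinates(disp.u, pos.T, order=1) / ps  # px
    v_at = map_coordinates(disp.v, pos.T, order=1) / ps

    relaxed = _render_beads(shape, pos, p.bead_sigma, p.bead_amplitude)
    moved = pos + np.stack([v_at + p.drift_px[0], u_at + p.drift_px[1]], axis=1)
    loaded = _render_beads(shape, moved, p.bead_sigma, p.bead_amplitude)

    # cell footprint: union of patch supports, generously dilated
    y, x = np.mgrid[0 : shape[0], 0 : shape[1]]
    cell = np.zeros(shape, dtype=bool)
    for patch in p.patches:
        r = 3.0 * patch.radius_px
        cell |= (y - patch.center[0]) ** 2 + (x - patch.center[1]) ** 2 <= r**2
    truth = SyntheticTruth(
        cell_mask=LabelMask(cell.astype(np.int32), ps, "cell"),
        displacement_true=disp,
        traction_true=traction,
    )
    img_loaded = IntensityImage(_apply_noise(loaded, config.noise, rng), ps, "loaded")
    img_relaxed = IntensityImage(_apply_noise(relaxed, config.noise, rng), ps, "relaxed")
    return img_loaded, img_relaxed, truth


def _render_beads(
    shape: tuple[int, int], positions: np.ndarray, sigma: float, amplitude: float
) -> np.ndarray:
    """Sum of analytic 2D Gaussian spots at subpixel positions."""
    img = np.zeros(shape)
    half = int(np.ceil(4 * sigma))
    for py, px in positions:
        r0 = max(int(np.floor(py)) - half, 0)
        r1 = min(int(np.floor(py)) + half + 1, shape[0])
        c0 = max(int(np.floor(px)) - half, 0)
        c1 = min(int(np.floor(px)) + half + 1, shape[1])
        if r1 <= r0 or c1 <= c0:
            continue
        yy = np.arange(r0, r1)[:, None] - py
        xx = np.arange(c0, c1)[None, :] - px
        img[r0:r1, c0:c1] += amplitude * np.exp(-(yy**2 + xx**2) / (2 * sigma**2))
    return img
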