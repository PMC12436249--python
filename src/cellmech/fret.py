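"""Three-cube (sensitized-emission) FRET index with bleed-through calibration.

The FRET channel of a three-cube acquisition (donor excitation, acceptor
emission) contains, besides the sensitized emission of interest, donor
emission leaking through the acceptor filter and directly excited
acceptor emission. Both contaminations scale linearly with the pure
channels, so they are measured as regression slopes on single-fluorophore
samples: dL from donor-only cells (FRET vs donor channel) and aL from
acceptor-only cells (FRET vs acceptor channel).

The pixelwise index is then

    index = (I_f - dL * I_d - aL * I_a) / I_a = F_c / I_a

where I_f, I_d, I_a are the corrected FRET, donor and acceptor channel
intensities and F_c the corrected (bleed-through-free) FRET intensity.
The index is a relative proxy for FRET efficiency — no instrument
G-factor is applied — and for a molecular tension sensor it decreases
with force on the module. Per-cell values are averaged only over focal
adhesion pixels.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .image import IntensityImage
from .segmentation import LabelMask


class CalibrationError(ValueError):
    """The single-fluorophore calibration sample does not support a leakage fit."""


class FretWarning(UserWarning):
    pass


@dataclass(frozen=True)
class FretChannels:
    """The corrected donor / FRET / acceptor channel triple (I_d, I_f, I_a)."""

    donor: IntensityImage
    fret: IntensityImage
    acceptor: IntensityImage
    registered: bool = False

    def __post_init__(self) -> None:
        shapes = {self.donor.shape, self.fret.shape, self.acceptor.shape}
        if len(shapes) != 1:
            raise ValueError("donor, fret and acceptor must share a shape")
        sizes = {self.donor.pixel_size, self.fret.pixel_size, self.acceptor.pixel_size}
        if len(sizes) != 1:
            raise ValueError("channels must share a pixel size")


@dataclass
class FretCalibration:
    """Donor and acceptor leakage fractions with fit diagnostics."""

    dL: float
    aL: float
    dL_r2: float = 1.0
    aL_r2: float = 1.0
    n_pixels_d: int = 0
    n_pixels_a: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.dL < 1 and 0 <= self.aL < 1):
            raise ValueError("leakage fractions must lie in [0, 1)")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "FretCalibration":
        return cls(**json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class FretIndexMap:
    """Pixelwise FRET index with a validity mask.

    ``index`` holds F_c / I_a where ``valid`` is True and NaN elsewhere;
    pixels whose acceptor intensity falls below ``ia_floor`` are invalid
    (the ratio would blow up where the sensor is absent).
    """

    index: np.ndarray
    valid: np.ndarray
    ia_floor: float


def fit_leakage(
    fret: IntensityImage,
    single_channel: IntensityImage,
    cell_mask: np.ndarray,
    intensity_floor: float = 0.0,
) -> tuple[float, float, int]:
    """Leakage fraction: OLS slope of FRET vs single-fluorophore intensity.

    The regression includes an intercept (absorbing residual background)
    whose value is discarded; only the slope is the leakage fraction.
    Pixels are restricted to the cell mask and to single-channel
    intensities above ``intensity_floor`` so that empty pixels do not
    dominate the fit.

    Returns ``(slope, r_squared, n_pixels)``. A negative slope or an
    r-squared below 0.5 means the calibration sample is invalid.
    """
    mask = np.asarray(cell_mask, dtype=bool)
    if mask.shape != fret.shape or single_channel.shape != fret.shape:
        raise ValueError("mask and channels must share a shape")
    sel = mask & (single_channel.pixels > intensity_floor)
    n = int(sel.sum())
    if n < 500:
        raise CalibrationError(f"only {n} calibration pixels above floor (need >= 500)")
    x = single_channel.pixels[sel]
    y = fret.pixels[sel]
    if np.allclose(y, 0):
        return 0.0, 1.0, n
    if np.ptp(x) == 0:
        raise CalibrationError("single-fluorophore channel is constant; slope undefined")
    res = stats.linregress(x, y)
    r2 = float(res.rvalue**2)
    slope = float(res.slope)
    if slope < 0:
        raise CalibrationError(f"negative leakage slope ({slope:.4f})")
    if r2 < 0.5:
        raise CalibrationError(f"leakage fit r^2 = {r2:.3f} < 0.5")
    return slope, r2, n


def calibrate(
    donor_only: FretChannels,
    acceptor_only: FretChannels,
    donor_mask: np.ndarray,
    acceptor_mask: np.ndarray,
    intensity_floor: float = 0.0,
) -> FretCalibration:
    """Fit both leakage fractions from donor-only and acceptor-only samples."""
    dL, d_r2, n_d = fit_leakage(
        donor_only.fret, donor_only.donor, donor_mask, intensity_floor
    )
    aL, a_r2, n_a = fit_leakage(
        acceptor_only.fret, acceptor_only.acceptor, acceptor_mask, intensity_floor
    )
    return FretCalibration(dL, aL, d_r2, a_r2, n_d, n_a)


def fret_index(
    channels: FretChannels, calib: FretCalibration, ia_floor: float
) -> FretIndexMap:
    """Pixelwise index (I_f - dL*I_d - aL*I_a) / I_a on valid pixels."""
    if not channels.registered:
        raise ValueError("channels must be registered before index computation")
    if not ia_floor > 0:
        raise ValueError("ia_floor must be positive")
    ia = channels.acceptor.pixels
    valid = ia >= ia_floor
    fc = channels.fret.pixels - calib.dL * channels.donor.pixels - calib.aL * ia
    index = np.full(ia.shape, np.nan)
    np.divide(fc, ia, out=index, where=valid)
    return FretIndexMap(index=index, valid=valid, ia_floor=float(ia_floor))


def mean_fret_per_cell(
    index_map: FretIndexMap,
    adhesions: LabelMask,
    cell_assignment: dict[int, int],
    per_adhesion_mean: bool = False,
) -> pd.DataFrame:
    """Per-cell mean FRET index over that cell's focal-adhesion pixels.

    The default is the pixel-area-weighted mean over the union of the
    cell's valid adhesion pixels (adhesion-area normalisation); with
    ``per_adhesion_mean`` each adhesion contributes its own mean with
    equal weight instead. Invalid pixels are omitted from numerator and
    denominator alike. Cells with no valid adhesion pixels are excluded
    with a warning.
    """
    if index_map.index.shape != adhesions.shape:
        raise ValueError("index map and adhesion mask must share a shape")
    by_cell: dict[int, list[np.ndarray]] = {}
    for adh_label, cell in cell_assignment.items():
        sel = (adhesions.labels == adh_label) & index_map.valid
        by_cell.setdefault(cell, []).append(index_map.index[sel])

    rows = []
    for cell in sorted(by_cell):
        chunks = [c for c in by_cell[cell] if c.size > 0]
        n_px = int(sum(c.size for c in chunks))
        if n_px == 0:
            warnings.warn(f"cell {cell} has no valid adhesion pixels; excluded", FretWarning)
            continue
        if per_adhesion_mean:
            mean = float(np.mean([c.mean() for c in chunks]))
        else:
            mean = float(np.concatenate(chunks).mean())
        rows.append({"cell": cell, "mean_index": mean, "adhesion_area_px": n_px})
    return pd.DataFrame(rows, columns=["cell", "mean_index", "adhesion_area_px"])


def normalize_to_control(
    ts_values: "list[float] | np.ndarray", cts_values: "list[float] | np.ndarray"
) -> np.ndarray:
    """Divide tension-sensor per-cell means by the control-sensor group mean.

    The control construct carries the sensor module at the protein's
    C-terminus where it bears no force, so its group mean defines the
    zero-force index scale.
    """
    cts = np.asarray(cts_values, dtype=float)
    if cts.size == 0:
        raise ValueError("control group is empty")
    denom = cts.mean()
    if denom <= 0:
        raise ValueError(f"control group mean must be positive (got {denom})")
    return np.asarray(ts_values, dtype=float) / denom
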