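"""Per-cell nuclear/cytoplasmic (N/C) ratio and area measurements.

The N/C ratio is the mean signal (e.g. YAP immunofluorescence) inside
the nuclear mask divided by the mean signal in a thin cytoplasmic ring
just outside it. The ring does not average over the whole cytoplasm; it
samples a similar-thickness region of the cell next to the nucleus,
which is the quantity this pipeline is built to report.

Ratios are best computed on background-subtracted images: an additive
offset b biases the ratio toward 1, since (mu_n + b) / (mu_c + b) lies
between the true ratio and 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .image import IntensityImage
from .segmentation import LabelMask


class MeasurementWarning(UserWarning):
    pass


@dataclass(frozen=True)
class CellMeasurement:
    object_label: int
    nuclear_area: float  # um^2
    mean_nuclear_intensity: float
    mean_ring_intensity: float
    nc_ratio: float | None  # None when the ring mean is 0 or the ring is missing
    flagged: bool = False
    cell_area: float | None = None  # um^2, filled when a cell mask is matched


def measure_nc_ratio(
    signal: IntensityImage,
    nuclei: LabelMask,
    rings: LabelMask,
    nuclear_erosion_px: int = 0,
) -> list[CellMeasurement]:
    """Per-nucleus mean nuclear and ring intensity and their ratio.

    Labels in ``nuclei`` with no matching ring label, or whose ring mean
    is zero, are reported with ``nc_ratio`` of None and flagged rather
    than dropped.

    ``nuclear_erosion_px`` shrinks each nucleus by that many pixels for
    the intensity reading only (areas are still reported on the full
    mask), discounting blurred partial-volume pixels at the boundary.
    """
    if signal.shape != nuclei.shape or signal.shape != rings.shape:
        raise ValueError("signal, nuclei and rings must share a shape")
    out: list[CellMeasurement] = []
    px_area = nuclei.pixel_size**2
    labels = nuclei.label_values
    read_labels = nuclei.labels
    if nuclear_erosion_px > 0:
        eroded = ndi.grey_erosion(
            nuclei.labels, size=2 * nuclear_erosion_px + 1
        )
        # keep the full mask for any nucleus the erosion would delete
        keep = np.isin(labels, np.unique(eroded))
        read_labels = np.where(
            np.isin(nuclei.labels, labels[keep]), eroded, nuclei.labels
        )
    ring_labels = set(int(v) for v in rings.label_values)
    if len(labels) == 0:
        return out

    nuc_means = ndi.mean(signal.pixels, labels=read_labels, index=labels)
    nuc_areas = ndi.sum_labels(np.ones(nuclei.shape), labels=nuclei.labels, index=labels)
    for lab, mu_n, a_n in zip(labels, nuc_means, nuc_areas):
        lab = int(lab)
        if lab not in ring_labels:
            warnings.warn(f"nucleus {lab} has no ring; flagged", MeasurementWarning)
            out.append(
                CellMeasurement(lab, a_n * px_area, float(mu_n), float("nan"), None, True)
            )
            continue
        mu_r = float(ndi.mean(signal.pixels, labels=rings.labels, index=lab))
        if mu_r > 0:
            out.append(CellMeasurement(lab, a_n * px_area, float(mu_n), mu_r, float(mu_n) / mu_r))
        else:
            warnings.warn(f"nucleus {lab} ring mean is 0; flagged", MeasurementWarning)
            out.append(CellMeasurement(lab, a_n * px_area, float(mu_n), mu_r, None, True))
    return out


def nc_ratio_pipeline(
    dapi: IntensityImage,
    factin: IntensityImage,
    signal: IntensityImage,
    ring_width_px: int = 5,
    guard_px: float = 1.0,
    nuclear_erosion_px: int = 1,
    background_margin_px: int = 10,
) -> list[CellMeasurement]:
    """Full N/C analysis of one DAPI / F-actin / signal channel triple.

    Segments nuclei (Canny) and cells (Otsu on F-actin), subtracts the
    signal background measured on a cell-free ROI (complement of the
    dilated cell mask; falls back to the global 5th percentile when no
    such region exists), builds 5-px cytoplasmic rings with a 1-px
    partial-volume guard, and measures per-cell ratios.
    """
    from . import image as _image
    from . import segmentation as _seg

    cells = _seg.segment_cells(factin)
    roi = ~ndi.binary_dilation(cells.foreground(), iterations=background_margin_px)
    if roi.sum() >= 100:
        signal = _image.subtract_background(signal, roi)
    else:
        signal = _image.subtract_background(signal)
    nuclei = _seg.segment_nuclei(dapi)
    rings = _seg.make_cytoplasm_rings(nuclei, ring_width_px, guard_px=guard_px)
    measurements = measure_nc_ratio(
        signal, nuclei, rings, nuclear_erosion_px=nuclear_erosion_px
    )
    # attach cell areas by matching each nucleus to the cell under it
    areas = {
        int(lab): float(cnt) * cells.pixel_size**2
        for lab, cnt in zip(
            cells.label_values,
            ndi.sum_labels(np.ones(cells.shape), cells.labels, cells.label_values),
        )
    }
    out = []
    for m in measurements:
        sel = nuclei.labels == m.object_label
        under = cells.labels[sel]
        under = under[under > 0]
        cell_lab = int(np.bincount(under).argmax()) if under.size else None
        out.append(
            CellMeasurement(
                m.object_label,
                m.nuclear_area,
                m.mean_nuclear_intensity,
                m.mean_ring_intensity,
                m.nc_ratio,
                m.flagged,
                areas.get(cell_lab) if cell_lab else None,
            )
        )
    return out


def measure_areas(mask: LabelMask) -> pd.DataFrame:
    """Object areas in um^2 (pixel count times pixel_size squared)."""
    labels = mask.label_values
    if len(labels) == 0:
        return pd.DataFrame(columns=["label", "area_um2"])
    counts = ndi.sum_labels(np.ones(mask.shape), labels=mask.labels, index=labels)
    return pd.DataFrame(
        {"label": labels.astype(int), "area_um2": counts * mask.pixel_size**2}
    )


def measurements_to_frame(
    measurements: list[CellMeasurement],
    image_id: str = "",
    group: str = "",
) -> pd.DataFrame:
    """Flatten measurements to a table, tagging image and treatment group."""
    rows = [
        {
            "image_id": image_id,
            "group": group,
            "label": m.object_label,
            "nuclear_area_um2": m.nuclear_area,
            "cell_area_um2": m.cell_area,
            "mean_nuclear_intensity": m.mean_nuclear_intensity,
            "mean_ring_intensity": m.mean_ring_intensity,
            "nc_ratio": m.nc_ratio,
            "flagged": m.flagged,
        }
        for m in measurements
    ]
    return pd.DataFrame(rows)
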