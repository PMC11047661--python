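"""Per-cell quantification of micropattern chip images.

Implements the image-analysis stage of the screening assay: register the
predefined micropattern ROI grid against the DAPI channel by a random rigid
displacement search, segment nuclei by auto-threshold + connected components,
measure per-cell channel intensities over the nucleus mask dilated by 2 px,
and extract per-cell Fluo-4 traces from a time-lapse stack with the same
dilated masks.

Conventions: 0-based pixel coordinates, ``(x, y) = (column, row)``, origin
top-left; ROIs are closed discs; nuclei on a black (dark) background.
Touching nuclei are not split — the 80 µm pattern size is chosen precisely so
colonies are not over-clustered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import dilation, disk

from .errors import ValidationError
from .layout import ROI, ChipLayout


@dataclass
class CellRecord:
    """One segmented cell: identity, nucleus geometry, channel intensities."""

    pattern_id: int
    cell_id: int
    centroid_px: tuple[float, float]  # (x, y)
    nucleus_area_px: int
    intensity: dict[str, float] = field(default_factory=dict)
    component_label: int = 0  # label in the segmentation label image


@dataclass
class CalciumTrace:
    """One cell's Fluo-4 intensity per frame.

    The digitization window runs from one frame after ``induction_frame``
    through 20 frames after it, so the trace must hold at least
    ``induction_frame + 21`` frames.
    """

    cell_id: int
    pattern_id: int
    values: np.ndarray
    frame_rate_hz: float
    induction_frame: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValidationError(f"trace for cell {self.cell_id} has non-finite values")
        if len(self.values) < self.induction_frame + 21:
            raise ValidationError(
                f"trace for cell {self.cell_id} has {len(self.values)} frames; "
                f"needs at least {self.induction_frame + 21} to fit the "
                "20-frame post-induction window"
            )


@dataclass
class GridFit:
    """Result of the ROI-grid displacement search."""

    offset: tuple[int, int]  # (dx, dy) in px
    score: int  # foreground pixels inside all ROIs at the offset
    blank: bool  # True if the image had no foreground at all
    rois: list[ROI]


def autothreshold_binarize(image: np.ndarray) -> np.ndarray:
    """Otsu auto-threshold; foreground = pixels strictly above the threshold.

    Bright nuclei on a dark background.  A constant image yields an empty
    mask and a warning.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValidationError(f"expected a single-channel 2-D image, got shape {img.shape}")
    if not np.all(np.isfinite(img)):
        raise ValidationError("image contains non-finite values")
    if img.max() == img.min():
        warnings.warn("constant image: auto-threshold yields empty foreground",
                      stacklevel=2)
        return np.zeros(img.shape, dtype=bool)
    t = threshold_otsu(img)
    return img > t


def _roi_union_indices(
    rois: list[ROI], shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Pixel indices of the union of ROI discs (clipped to the image)."""
    h, w = shape
    mask = np.zeros(shape, dtype=bool)
    for roi in rois:
        x0 = max(int(np.floor(roi.cx - roi.radius)), 0)
        x1 = min(int(np.ceil(roi.cx + roi.radius)), w - 1)
        y0 = max(int(np.floor(roi.cy - roi.radius)), 0)
        y1 = min(int(np.ceil(roi.cy + roi.radius)), h - 1)
        if x1 < x0 or y1 < y0:
            continue
        yy, xx = np.mgrid[y0 : y1 + 1, x0 : x1 + 1]
        mask[y0 : y1 + 1, x0 : x1 + 1] |= (
            (xx - roi.cx) ** 2 + (yy - roi.cy) ** 2 <= roi.radius**2
        )
    return np.nonzero(mask)


def optimize_roi_grid(
    dapi_image: np.ndarray,
    layout: ChipLayout,
    iterations: int = 500,
    max_shift_px: int = 10,
    seed: int = 0,
) -> GridFit:
    """Rigid registration of the ROI grid by random integer displacements.

    Candidate global offsets are the origin (always evaluated first) followed
    by ``iterations`` distinct offsets sampled uniformly without replacement
    from the (2*max_shift_px+1)^2 integer lattice.  The offset maximizing the
    total auto-threshold foreground area inside all ROI discs wins; ties keep
    the first-encountered maximum.  When ``iterations`` covers the lattice
    (the default does) the search is exhaustive.

    A blank image (no foreground) returns offset (0, 0) with ``blank=True``.
    """
    if iterations < 0 or max_shift_px < 0:
        raise ValidationError("iterations and max_shift_px must be >= 0")
    img = np.asarray(dapi_image, dtype=float)
    h, w = img.shape
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fg = autothreshold_binarize(img)
    if not fg.any():
        warnings.warn("blank image: ROI grid left at the nominal origin",
                      stacklevel=2)
        return GridFit(offset=(0, 0), score=0, blank=True, rois=layout.rois())

    ys, xs = _roi_union_indices(layout.rois(), (h, w))
    ms = max_shift_px
    fg_pad = np.zeros((h + 2 * ms, w + 2 * ms), dtype=np.uint8)
    fg_pad[ms : ms + h, ms : ms + w] = fg

    span = np.arange(-ms, ms + 1)
    lattice = [(int(dx), int(dy)) for dy in span for dx in span]
    rng = np.random.default_rng(seed)
    others = [d for d in lattice if d != (0, 0)]
    order = rng.permutation(len(others))
    candidates = [(0, 0)] + [others[i] for i in order[: min(iterations, len(others))]]

    best_offset = (0, 0)
    best_score = -1
    for dx, dy in candidates:
        score = int(fg_pad[ys + ms + dy, xs + ms + dx].sum())
        if score > best_score:
            best_score = score
            best_offset = (dx, dy)
    return GridFit(
        offset=best_offset,
        score=best_score,
        blank=False,
        rois=layout.rois(offset=best_offset),
    )


def segment_nuclei(
    dapi_image: np.ndarray,
    rois: ROI | list[ROI],
    min_area_px: int = 20,
) -> tuple[list[CellRecord], np.ndarray]:
    """Segment nuclei and assign them to micropattern ROIs.

    The DAPI channel is auto-thresholded, connected components are labelled
    with 8-connectivity, components smaller than ``min_area_px`` are
    discarded, and each remaining component is assigned to the ROI circle
    containing its centroid (components outside every ROI are dropped).

    Returns the cell records (sorted by pattern then cell id) and the
    component label image, from which per-cell masks can be recovered as
    ``labels == record.component_label``.
    """
    roi_list = [rois] if isinstance(rois, ROI) else list(rois)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fg = autothreshold_binarize(dapi_image)
    labels = cc_label(fg, connectivity=2)
    records: list[CellRecord] = []
    cell_id = 0
    for region in regionprops(labels):
        if region.area < min_area_px:
            continue
        cy, cx = region.centroid
        owner = next((r for r in roi_list if r.contains(cx, cy)), None)
        if owner is None:
            continue
        records.append(
            CellRecord(
                pattern_id=owner.pattern_id,
                cell_id=cell_id,
                centroid_px=(float(cx), float(cy)),
                nucleus_area_px=int(region.area),
                component_label=int(region.label),
            )
        )
        cell_id += 1
    records.sort(key=lambda r: (r.pattern_id, r.cell_id))
    return records, labels


def dilated_mask(
    nucleus_mask: np.ndarray, dilation_px: int = 2
) -> np.ndarray:
    """Nucleus mask dilated by a disc structuring element (clipped at borders)."""
    mask = np.asarray(nucleus_mask, dtype=bool)
    if dilation_px < 0:
        raise ValidationError("dilation_px must be >= 0")
    if dilation_px == 0:
        return mask
    return dilation(mask, disk(dilation_px))


def measure_cell_intensity(
    channel_image: np.ndarray,
    nucleus_mask: np.ndarray,
    dilation_px: int = 2,
) -> float:
    """Mean channel intensity over the 2 px-dilated nucleus mask.

    The dilation captures the perinuclear stain (caspase-3/7 or Fluo-4)
    surrounding each nucleus.  An empty mask is an error.
    """
    mask = np.asarray(nucleus_mask, dtype=bool)
    if not mask.any():
        raise ValidationError("cannot measure intensity over an empty mask")
    if mask.shape != np.asarray(channel_image).shape:
        raise ValidationError("mask and image shapes differ")
    mask = dilated_mask(mask, dilation_px)
    return float(np.asarray(channel_image, dtype=float)[mask].mean())


def measure_cells(
    channel_image: np.ndarray,
    labels: np.ndarray,
    records: list[CellRecord],
    channel: str,
    dilation_px: int = 2,
) -> list[CellRecord]:
    """Fill ``record.intensity[channel]`` for every cell record in place."""
    for rec in records:
        rec.intensity[channel] = measure_cell_intensity(
            channel_image, labels == rec.component_label, dilation_px
        )
    return records


def extract_traces(
    stack: np.ndarray,
    labels: np.ndarray,
    records: list[CellRecord],
    induction_frame: int,
    frame_rate_hz: float = 5.0,
    dilation_px: int = 2,
) -> list[CalciumTrace]:
    """Per-cell Fluo-4 traces: mean over the dilated nucleus mask per frame.

    The stack is ``(n_frames, H, W)`` with every frame the same shape; the
    20-frame post-induction digitization window must fit, i.e.
    ``n_frames >= induction_frame + 21``.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValidationError(f"expected a (frames, H, W) stack, got shape {stack.shape}")
    n_frames = stack.shape[0]
    if n_frames < induction_frame + 21:
        raise ValidationError(
            f"stack has {n_frames} frames; the 20-frame post-induction window "
            f"requires at least {induction_frame + 21}"
        )
    if stack.shape[1:] != labels.shape:
        raise ValidationError("stack frame shape and label image shape differ")
    traces = []
    for rec in records:
        mask = dilated_mask(labels == rec.component_label, dilation_px)
        if not mask.any():
            raise ValidationError(f"empty mask for cell {rec.cell_id}")
        ys, xs = np.nonzero(mask)
        values = stack[:, ys, xs].mean(axis=1)
        traces.append(
            CalciumTrace(
                cell_id=rec.cell_id,
                pattern_id=rec.pattern_id,
                values=np.asarray(values, dtype=float),
                frame_rate_hz=frame_rate_hz,
                induction_frame=induction_frame,
            )
        )
    return traces


def cells_to_frame(records: list[CellRecord]) -> pd.DataFrame:
    """CellRecord list -> tidy table (one row per cell, one column per channel)."""
    channels = sorted({ch for r in records for ch in r.intensity})
    rows = []
    for r in records:
        row = {
            "pattern_id": r.pattern_id,
            "cell_id": r.cell_id,
            "x_px": r.centroid_px[0],
            "y_px": r.centroid_px[1],
            "area_px": r.nucleus_area_px,
        }
        for ch in channels:
            row[f"{ch}_mean"] = r.intensity.get(ch, np.nan)
        rows.append(row)
    cols = ["pattern_id", "cell_id", "x_px", "y_px", "area_px"] + [
        f"{ch}_mean" for ch in channels
    ]
    return pd.DataFrame(rows, columns=cols)
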