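"""Synthetic micropattern chips, calcium time-lapse stacks, and binary
dose-response tables with known ground truth.

The generator emulates the structure of the screening assay: arrays of 80 µm
circular micropatterns holding small colonies (about 4.5 ± 2 cells each),
an apoptosis readout in which caspase-3/7 intensity of responding cells is
elevated at least 1.2-fold over vehicle-control cells, and Fluo-4 calcium
traces with heterogeneous per-cell baselines and either a sharp (capsaicin-
like) or broad (surfactant-irritant-like) transient after the induction
frame.  Every output is fully determined by the config seed.

The statistical laws here are stand-ins: the source assay reports only the
mean ± sd of cells per micropattern and qualitative peak shapes, so the
cell-count law (rounded normal truncated at one cell) and intensity levels
are the package's own choices, documented in the methods note.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skimage.morphology import dilation, disk

from .errors import PlacementError, ValidationError
from .layout import ROI, ChipLayout, WellTreatment

#: extra radius (px) of the cytoplasmic stain footprint around each nucleus;
#: matches the 2 px mask dilation used at measurement time so noiseless
#: measured means equal the painted levels exactly.
STAIN_DILATION_PX = 2


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------


@dataclass
class SimChipConfig:
    """Geometry, population statistics and rendering levels for one chip.

    ``cells_mean``/``cells_sd`` default to the observed 4.5 ± 2 cells per
    80 µm micropattern.  ``grid_offset_px`` is the ground-truth rigid
    misalignment of the whole pattern array, which the ROI-grid optimizer
    must recover.
    """

    grid_rows: int = 4
    grid_cols: int = 4
    pattern_diameter_um: float = 80.0
    pixel_size_um: float = 1.0
    cells_mean: float = 4.5
    cells_sd: float = 2.0
    nucleus_radius_px: int = 5
    background_level: float = 10.0
    noise_sd: float = 2.0
    grid_offset_px: tuple[int, int] = (0, 0)
    seed: int = 0
    pitch_px: int | None = None
    dapi_amplitude: float = 200.0
    control_level: float = 100.0
    apoptotic_factor: float = 1.5

    def __post_init__(self) -> None:
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ValidationError("grid_rows and grid_cols must be >= 1")
        if self.cells_mean <= 0:
            raise ValidationError("cells_mean must be > 0")
        if self.cells_sd < 0:
            raise ValidationError("cells_sd must be >= 0")
        if self.pixel_size_um <= 0 or self.pattern_diameter_um <= 0:
            raise ValidationError("pattern diameter and pixel size must be > 0")
        if self.nucleus_radius_px < 1:
            raise ValidationError("nucleus_radius_px must be >= 1")
        if self.diameter_px < 2 * self.nucleus_radius_px:
            raise ValidationError(
                "pattern diameter in px must be at least twice the nucleus radius"
            )
        if self.apoptotic_factor < 1.2:
            raise ValidationError(
                "apoptotic_factor must be >= 1.2 so the 20% normalization "
                "threshold separates the classes"
            )
        if self.pitch_px is None:
            self.pitch_px = int(round(1.5 * self.diameter_px))
        if self.pitch_px <= self.diameter_px:
            raise ValidationError("pitch_px must exceed the pattern diameter")

    @property
    def diameter_px(self) -> float:
        return self.pattern_diameter_um / self.pixel_size_um

    @property
    def radius_px(self) -> float:
        return self.diameter_px / 2.0

    @property
    def margin_px(self) -> int:
        # room for the pattern itself plus up to ±12 px grid misalignment
        return int(math.ceil(self.radius_px)) + 16

    def layout(self, wells: dict[int, WellTreatment] | None = None) -> ChipLayout:
        """Nominal (un-shifted) layout describing where ROIs are expected."""
        m = self.margin_px
        return ChipLayout(
            grid_rows=self.grid_rows,
            grid_cols=self.grid_cols,
            pitch_px=float(self.pitch_px),
            pattern_diameter_px=self.diameter_px,
            origin_px=(float(m), float(m)),
            wells=wells or {},
        )

    def image_shape(self) -> tuple[int, int]:
        m = self.margin_px
        h = int(math.ceil(2 * m + (self.grid_rows - 1) * self.pitch_px)) + 1
        w = int(math.ceil(2 * m + (self.grid_cols - 1) * self.pitch_px)) + 1
        return (h, w)


@dataclass
class SimDoseConfig:
    """Ground-truth logistic law for Bernoulli micropattern outcomes.

    ``beta0``/``beta1`` are the logit intercept and per-nM slope of the
    positive-response probability p(C) = 1/(1+exp(-(beta0+beta1*C))).
    """

    beta0: float
    beta1: float
    concentrations: Sequence[float]
    n_patterns_per_conc: int
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.concentrations) == 0:
            raise ValidationError("concentrations must be non-empty")
        if any(c < 0 for c in self.concentrations):
            raise ValidationError("concentrations must be >= 0")
        if self.n_patterns_per_conc < 1:
            raise ValidationError("n_patterns_per_conc must be >= 1")


@dataclass
class SimTraceConfig:
    """Calcium time-lapse: 5 min at 5 frames/s with induction after 1 min.

    ``peak_shape``: ``"sharp"`` is a fast-rise transient decaying over ~5
    frames (agonist-like), ``"broad"`` a gamma-shaped transient decaying over
    ~50 frames (irritant-like), ``"none"`` leaves the baseline untouched.
    Baselines vary across cells (coefficient of variation ``baseline_cv``)
    to emulate heterogeneous resting intracellular Ca2+.
    """

    n_frames: int = 1500
    frame_rate_hz: float = 5.0
    induction_frame: int = 300
    baseline_mean: float = 100.0
    baseline_cv: float = 0.2
    peak_shape: str = "sharp"
    peak_amplitude: float = 50.0
    noise_sd: float = 1.0
    nucleus_radius_px: int = 5
    background_level: float = 5.0
    dapi_amplitude: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.induction_frame < self.n_frames - 20):
            raise ValidationError(
                "induction_frame must satisfy 0 < induction_frame < n_frames - 20"
            )
        if self.baseline_cv < 0:
            raise ValidationError("baseline_cv must be >= 0")
        if self.peak_shape not in ("sharp", "broad", "none"):
            raise ValidationError("peak_shape must be 'sharp', 'broad' or 'none'")
        if self.frame_rate_hz <= 0:
            raise ValidationError("frame_rate_hz must be > 0")
        if self.baseline_mean <= 0:
            raise ValidationError("baseline_mean must be > 0")


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------


@dataclass
class SimulatedChip:
    """Rendered two-channel chip plus ground truth.

    ``truth`` columns: pattern_id, cell_id, x_px, y_px, label (1 = apoptotic).
    """

    dapi: np.ndarray
    caspase: np.ndarray
    truth: pd.DataFrame
    layout: ChipLayout
    config: SimChipConfig

    def channels(self) -> list[np.ndarray]:
        return [self.dapi, self.caspase]


@dataclass
class SimulatedTimelapse:
    """Rendered Fluo-4 stack, DAPI reference frame and per-cell truth."""

    stack: np.ndarray  # (n_frames, H, W)
    dapi: np.ndarray  # (H, W)
    traces: np.ndarray  # (n_cells, n_frames) ground-truth cell traces
    truth: pd.DataFrame  # cell_id, x_px, y_px, baseline
    masks: list[np.ndarray]  # boolean nucleus mask per cell
    roi: ROI  # single ROI covering all rendered cells
    config: SimTraceConfig


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def simulate_pattern_counts(
    config: SimChipConfig, n_patterns: int | None = None
) -> np.ndarray:
    """Per-micropattern cell counts: rounded normal, truncated below at 1.

    Matches the printed colony-size moments (mean 4.5, sd 2 by default)
    while guaranteeing at least one cell so the 50%-of-cells rule is always
    defined.
    """
    n = config.grid_rows * config.grid_cols if n_patterns is None else int(n_patterns)
    if n < 1:
        raise ValidationError("n_patterns must be >= 1")
    rng = np.random.default_rng(config.seed)
    raw = rng.normal(config.cells_mean, config.cells_sd, size=n)
    return np.maximum(np.rint(raw).astype(int), 1)


def _place_cells(
    rng: np.random.Generator,
    center: tuple[float, float],
    n_cells: int,
    placement_radius: float,
    min_separation: float,
    pattern_id: int,
    max_retries: int = 100,
) -> list[tuple[float, float]]:
    """Rejection-sample non-overlapping cell centres inside a pattern circle.

    Each cell gets ``max_retries`` draws; if a crowded configuration dead-ends,
    the whole pattern is re-drawn, up to ``max_retries`` restarts, before
    giving up.
    """
    for _restart in range(max_retries):
        placed: list[tuple[float, float]] = []
        for _ in range(n_cells):
            ok = False
            for _attempt in range(max_retries):
                r = placement_radius * math.sqrt(rng.random())
                theta = rng.random() * 2 * math.pi
                x = center[0] + r * math.cos(theta)
                y = center[1] + r * math.sin(theta)
                if all(
                    (x - px) ** 2 + (y - py) ** 2 >= min_separation**2
                    for px, py in placed
                ):
                    placed.append((x, y))
                    ok = True
                    break
            if not ok:
                break
        else:
            return placed
    raise PlacementError(
        f"could not place {n_cells} non-overlapping cells in pattern "
        f"{pattern_id} after {max_retries} restarts"
    )


def _disc_indices(
    x: float, y: float, radius: float, shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pixel indices (ys, xs) of the rasterized closed disc, plus distances."""
    h, w = shape
    x0 = max(int(math.floor(x - radius)), 0)
    x1 = min(int(math.ceil(x + radius)), w - 1)
    y0 = max(int(math.floor(y - radius)), 0)
    y1 = min(int(math.ceil(y + radius)), h - 1)
    yy, xx = np.mgrid[y0 : y1 + 1, x0 : x1 + 1]
    d2 = (xx - x) ** 2 + (yy - y) ** 2
    inside = d2 <= radius**2
    return yy[inside], xx[inside], np.sqrt(d2[inside])


def _paint_nucleus(
    image: np.ndarray, x: float, y: float, radius: int, amplitude: float
) -> tuple[np.ndarray, np.ndarray]:
    """Add a Gaussian-profile nuclear blob; returns its pixel indices (ys, xs).

    The Gaussian sigma is 2x the radius so in-disc intensity stays within
    ~12% of the peak: bright flat-topped blobs that auto-threshold cleanly.
    """
    ys, xs, d = _disc_indices(x, y, radius, image.shape)
    sigma = 2.0 * radius
    image[ys, xs] += amplitude * np.exp(-(d**2) / (2 * sigma**2))
    return ys, xs


def _stain_indices(
    x: float, y: float, radius: int, shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Pixel indices of the stain footprint: the rasterized nucleus disc
    dilated by the measurement footprint (disk of STAIN_DILATION_PX).

    Computed on a local window so it matches exactly what a full-image
    morphological dilation of the segmented nucleus mask would produce.
    """
    pad = STAIN_DILATION_PX + 1
    half = radius + pad
    cx, cy = int(round(x)), int(round(y))
    y0, x0 = cy - half, cx - half
    side = 2 * half + 1
    yy, xx = np.mgrid[0:side, 0:side]
    local = ((xx + x0 - x) ** 2 + (yy + y0 - y) ** 2) <= radius**2
    stained = dilation(local, disk(STAIN_DILATION_PX))
    ys, xs = np.nonzero(stained)
    ys, xs = ys + y0, xs + x0
    keep = (ys >= 0) & (ys < shape[0]) & (xs >= 0) & (xs < shape[1])
    return ys[keep], xs[keep]


def simulate_chip_image(
    config: SimChipConfig,
    apoptotic_fraction_per_pattern: Mapping[int, float] | float = 0.0,
) -> SimulatedChip:
    """Render a two-channel chip (DAPI nuclei, caspase-3/7) with ground truth.

    Nuclei are non-overlapping Gaussian-profile discs confined to pattern
    circles placed on the nominal grid shifted by ``config.grid_offset_px``.
    The caspase channel paints each cell's stain footprint (nucleus dilated
    by 2 px) at the control level, or at ``apoptotic_factor`` times it for
    apoptotic cells; the ground-truth table records every cell's pattern,
    centroid and apoptosis label.

    ``apoptotic_fraction_per_pattern`` is either one fraction for all
    patterns or a map ``pattern_id -> fraction``; the number of apoptotic
    cells per pattern is ``round(fraction * n_cells)``.
    """
    layout = config.layout()
    n_pat = layout.n_patterns
    if isinstance(apoptotic_fraction_per_pattern, Mapping):
        fractions = {
            int(k): float(v) for k, v in apoptotic_fraction_per_pattern.items()
        }
        get_frac = lambda pid: fractions.get(pid, 0.0)  # noqa: E731
    else:
        f = float(apoptotic_fraction_per_pattern)
        get_frac = lambda pid: f  # noqa: E731
    for pid in range(n_pat):
        fr = get_frac(pid)
        if not (0.0 <= fr <= 1.0):
            raise ValidationError(
                f"apoptotic fraction for pattern {pid} must be in [0, 1], got {fr}"
            )

    rng = np.random.default_rng(config.seed)
    counts = np.maximum(
        np.rint(rng.normal(config.cells_mean, config.cells_sd, size=n_pat)).astype(
            int
        ),
        1,
    )

    shape = config.image_shape()
    dapi = np.full(shape, config.background_level, dtype=float)
    caspase = np.full(shape, config.background_level, dtype=float)

    r_nuc = config.nucleus_radius_px
    stain_r = r_nuc + STAIN_DILATION_PX
    # nuclei may reach the pattern boundary so the ROI-grid score is sharply
    # peaked at the true offset (misalignment clips boundary nuclei)
    placement_radius = config.radius_px - r_nuc - 1
    if placement_radius <= 0:
        raise ValidationError("pattern too small for the nucleus radius")
    min_sep = 2 * stain_r + 1.0
    dx, dy = config.grid_offset_px

    rows = []
    cell_id = 0
    for pid in range(n_pat):
        cx, cy = layout.pattern_center(pid)
        cx, cy = cx + dx, cy + dy
        n_cells = int(counts[pid])
        centers = _place_cells(
            rng, (cx, cy), n_cells, placement_radius, min_sep, pid
        )
        n_apop = int(round(get_frac(pid) * n_cells))
        labels = np.zeros(n_cells, dtype=int)
        labels[rng.permutation(n_cells)[:n_apop]] = 1
        for (x, y), lab in zip(centers, labels):
            _paint_nucleus(dapi, x, y, r_nuc, config.dapi_amplitude)
            sy, sx = _stain_indices(x, y, r_nuc, shape)
            level = config.control_level * (
                config.apoptotic_factor if lab else 1.0
            )
            caspase[sy, sx] = level
            rows.append(
                {
                    "pattern_id": pid,
                    "cell_id": cell_id,
                    "x_px": x,
                    "y_px": y,
                    "label": int(lab),
                }
            )
            cell_id += 1

    if config.noise_sd > 0:
        dapi += rng.normal(0.0, config.noise_sd, size=shape)
        caspase += rng.normal(0.0, config.noise_sd, size=shape)
        np.clip(dapi, 0.0, None, out=dapi)
        np.clip(caspase, 0.0, None, out=caspase)

    truth = pd.DataFrame(
        rows, columns=["pattern_id", "cell_id", "x_px", "y_px", "label"]
    )
    return SimulatedChip(
        dapi=dapi, caspase=caspase, truth=truth, layout=layout, config=config
    )


def peak_kernel(config: SimTraceConfig) -> np.ndarray:
    """Unit-peak transient added at the induction frame.

    ``sharp``: instantaneous rise, exponential decay with a 2-frame time
    constant (gone within ~5 frames).  ``broad``: gamma-shaped rise/decay
    (shape 2, scale 12.5 frames) peaking ~25 frames post-induction and
    decaying over ~50 frames.  ``none``: zeros.
    """
    t = np.arange(config.n_frames, dtype=float)
    dt = t - config.induction_frame
    k = np.zeros(config.n_frames)
    after = dt >= 0
    if config.peak_shape == "sharp":
        k[after] = np.exp(-dt[after] / 2.0)
    elif config.peak_shape == "broad":
        p, scale = 2.0, 12.5
        mode = p * scale
        k[after] = (dt[after] / mode) ** p * np.exp(p - dt[after] / scale)
    return k


def simulate_timelapse(config: SimTraceConfig, n_cells: int) -> SimulatedTimelapse:
    """Render a Fluo-4 time-lapse stack plus a DAPI reference frame.

    Each cell's ground-truth trace is ``baseline + peak_amplitude * kernel +
    noise``; the stack paints the trace value uniformly over the cell's
    stain footprint each frame, so re-measuring the stack over the masks
    reproduces the traces.
    """
    if n_cells < 1:
        raise ValidationError("n_cells must be >= 1")
    rng = np.random.default_rng(config.seed)

    r_nuc = config.nucleus_radius_px
    stain_r = r_nuc + STAIN_DILATION_PX
    spacing = 4 * stain_r + 2
    side = int(math.ceil(math.sqrt(n_cells)))
    margin = 2 * stain_r + 4
    size = 2 * margin + (side - 1) * spacing + 1
    shape = (size, size)

    baselines = rng.normal(
        config.baseline_mean, config.baseline_cv * config.baseline_mean, size=n_cells
    )
    baselines = np.maximum(baselines, 0.1 * config.baseline_mean)
    kernel = peak_kernel(config)

    traces = np.empty((n_cells, config.n_frames))
    for i in range(n_cells):
        noise = (
            rng.normal(0.0, config.noise_sd, size=config.n_frames)
            if config.noise_sd > 0
            else 0.0
        )
        traces[i] = baselines[i] + config.peak_amplitude * kernel + noise

    dapi = np.full(shape, config.background_level, dtype=float)
    masks: list[np.ndarray] = []
    stain_idx: list[tuple[np.ndarray, np.ndarray]] = []
    rows = []
    for i in range(n_cells):
        gr, gc = divmod(i, side)
        x = margin + gc * spacing
        y = margin + gr * spacing
        nys, nxs = _paint_nucleus(dapi, x, y, r_nuc, config.dapi_amplitude)
        nuc_mask = np.zeros(shape, dtype=bool)
        nuc_mask[nys, nxs] = True
        masks.append(nuc_mask)
        stain_idx.append(_stain_indices(x, y, r_nuc, shape))
        rows.append(
            {"cell_id": i, "x_px": float(x), "y_px": float(y), "baseline": baselines[i]}
        )

    stack = np.full(
        (config.n_frames,) + shape, config.background_level, dtype=np.float32
    )
    for i, (ys, xs) in enumerate(stain_idx):
        stack[:, ys, xs] = traces[i][:, None].astype(np.float32)

    center = (size - 1) / 2.0
    roi = ROI(pattern_id=0, cx=center, cy=center, radius=center * math.sqrt(2) + 1)
    truth = pd.DataFrame(rows, columns=["cell_id", "x_px", "y_px", "baseline"])
    return SimulatedTimelapse(
        stack=stack,
        dapi=dapi,
        traces=traces,
        truth=truth,
        masks=masks,
        roi=roi,
        config=config,
    )


def simulate_binary_dose_response(config: SimDoseConfig) -> pd.DataFrame:
    """Bernoulli micropattern outcomes from a ground-truth logistic law.

    Returns a long table (concentration_nM, pattern_id, outcome) with
    ``n_patterns_per_conc`` draws per concentration at success probability
    p(C) = 1/(1+exp(-(beta0 + beta1*C))).
    """
    from scipy.special import expit

    rng = np.random.default_rng(config.seed)
    rows = []
    for c in config.concentrations:
        p = float(expit(config.beta0 + config.beta1 * c))
        outcomes = (rng.random(config.n_patterns_per_conc) < p).astype(int)
        for i, y in enumerate(outcomes):
            rows.append(
                {"concentration_nM": float(c), "pattern_id": i, "outcome": int(y)}
            )
    return pd.DataFrame(rows, columns=["concentration_nM", "pattern_id", "outcome"])
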