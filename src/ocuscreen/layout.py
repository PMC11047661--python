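"""Micropattern chip layout: grid geometry and per-well treatment metadata.

A chip is a rectangular array of circular adhesive micropatterns on a
passivated glass substrate.  Each micropattern confines a small colony of
corneal epithelial cells and is the unit of binary readout.  A silicone
chamber partitions one chip into wells (typically four: three compound
concentrations plus one vehicle control), so treatment metadata is attached
per micropattern through a ``wells`` map.

Coordinates are 0-based pixel indices with ``(x, y) = (column, row)`` and the
origin at the top-left of the image.  A region of interest (ROI) is the
closed disc of one micropattern.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .errors import ValidationError


@dataclass(frozen=True)
class WellTreatment:
    """Treatment applied to one well: compound, concentration (nM), control flag."""

    compound: str
    concentration_nM: float
    is_vehicle_control: bool = False

    def __post_init__(self) -> None:
        if self.concentration_nM < 0:
            raise ValidationError(
                f"concentration_nM must be >= 0, got {self.concentration_nM}"
            )
        if self.is_vehicle_control and self.concentration_nM != 0:
            raise ValidationError(
                "a vehicle-control well carries concentration 0 of the test compound"
            )

    def to_dict(self) -> dict:
        return {
            "compound": self.compound,
            "concentration_nM": self.concentration_nM,
            "is_vehicle_control": self.is_vehicle_control,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "WellTreatment":
        return cls(
            compound=str(d["compound"]),
            concentration_nM=float(d["concentration_nM"]),
            is_vehicle_control=bool(d.get("is_vehicle_control", False)),
        )


@dataclass(frozen=True)
class ROI:
    """One micropattern's region of interest: a closed disc in pixel space."""

    pattern_id: int
    cx: float
    cy: float
    radius: float

    def contains(self, x: float, y: float) -> bool:
        return (x - self.cx) ** 2 + (y - self.cy) ** 2 <= self.radius**2


@dataclass
class ChipLayout:
    """Geometry of the micropattern array plus the per-pattern treatment map.

    Parameters
    ----------
    grid_rows, grid_cols
        Number of micropatterns along each axis.
    pitch_px
        Centre-to-centre spacing between adjacent micropatterns, pixels.
    pattern_diameter_px
        Diameter of each circular micropattern, pixels.
    origin_px
        ``(x, y)`` pixel position of the centre of pattern (row 0, col 0).
    wells
        Map ``pattern_id -> WellTreatment``.  Pattern ids run row-major:
        ``pattern_id = row * grid_cols + col``.
    """

    grid_rows: int
    grid_cols: int
    pitch_px: float
    pattern_diameter_px: float
    origin_px: tuple[float, float] = (0.0, 0.0)
    wells: dict[int, WellTreatment] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ValidationError("grid_rows and grid_cols must be >= 1")
        if self.pitch_px <= self.pattern_diameter_px:
            raise ValidationError(
                f"pitch_px ({self.pitch_px}) must exceed pattern_diameter_px "
                f"({self.pattern_diameter_px}); adjacent ROIs would overlap"
            )
        for pid in self.wells:
            if not (0 <= int(pid) < self.n_patterns):
                raise ValidationError(f"well map references unknown pattern id {pid}")

    @property
    def n_patterns(self) -> int:
        return self.grid_rows * self.grid_cols

    @property
    def pattern_radius_px(self) -> float:
        return self.pattern_diameter_px / 2.0

    def pattern_center(self, pattern_id: int) -> tuple[float, float]:
        row, col = divmod(int(pattern_id), self.grid_cols)
        return (
            self.origin_px[0] + col * self.pitch_px,
            self.origin_px[1] + row * self.pitch_px,
        )

    def rois(self, offset: tuple[float, float] = (0.0, 0.0)) -> list[ROI]:
        """ROIs for every pattern, optionally shifted by a global offset."""
        r = self.pattern_radius_px
        out = []
        for pid in range(self.n_patterns):
            cx, cy = self.pattern_center(pid)
            out.append(ROI(pid, cx + offset[0], cy + offset[1], r))
        return out

    def treatment_of(self, pattern_id: int) -> WellTreatment | None:
        return self.wells.get(int(pattern_id))

    def check_bounds(self, image_shape: tuple[int, int], margin: float = 0.0) -> None:
        """Raise if any ROI (padded by ``margin``) falls outside the image."""
        h, w = image_shape[:2]
        r = self.pattern_radius_px + margin
        for pid in range(self.n_patterns):
            cx, cy = self.pattern_center(pid)
            if cx - r < 0 or cy - r < 0 or cx + r > w - 1 or cy + r > h - 1:
                raise ValidationError(
                    f"pattern {pid} ROI at ({cx:.1f}, {cy:.1f}) exceeds image "
                    f"bounds {w}x{h} (margin {margin})"
                )

    # ---- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "grid_rows": self.grid_rows,
            "grid_cols": self.grid_cols,
            "pitch_px": self.pitch_px,
            "pattern_diameter_px": self.pattern_diameter_px,
            "origin_px": list(self.origin_px),
            "wells": {str(pid): t.to_dict() for pid, t in sorted(self.wells.items())},
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def from_dict(cls, d: Mapping) -> "ChipLayout":
        try:
            return cls(
                grid_rows=int(d["grid_rows"]),
                grid_cols=int(d["grid_cols"]),
                pitch_px=float(d["pitch_px"]),
                pattern_diameter_px=float(d["pattern_diameter_px"]),
                origin_px=tuple(float(v) for v in d.get("origin_px", (0.0, 0.0))),
                wells={
                    int(pid): WellTreatment.from_dict(t)
                    for pid, t in d.get("wells", {}).items()
                },
            )
        except (KeyError, TypeError) as exc:
            raise ValidationError(f"malformed layout: {exc}") from exc

    @classmethod
    def from_json(cls, path: str | Path) -> "ChipLayout":
        try:
            d = json.loads(Path(path).read_text())
        except json.JSONDecodeError as exc:
            raise ValidationError(f"layout file is not valid JSON: {exc}") from exc
        return cls.from_dict(d)


def four_well_layout(
    grid_rows: int,
    grid_cols: int,
    treatments: Sequence[WellTreatment],
    pitch_px: float,
    pattern_diameter_px: float,
    origin_px: tuple[float, float] = (0.0, 0.0),
) -> ChipLayout:
    """Partition a chip into four quadrant wells (three doses + one control).

    Quadrants are ordered top-left, top-right, bottom-left, bottom-right and
    take one treatment each, mirroring the chamber that splits a single
    micropatterned substrate into four wells.
    """
    if len(treatments) != 4:
        raise ValidationError("four_well_layout requires exactly 4 treatments")
    wells: dict[int, WellTreatment] = {}
    half_r = grid_rows / 2.0
    half_c = grid_cols / 2.0
    for pid in range(grid_rows * grid_cols):
        row, col = divmod(pid, grid_cols)
        quadrant = (2 if row >= half_r else 0) + (1 if col >= half_c else 0)
        wells[pid] = treatments[quadrant]
    return ChipLayout(
        grid_rows=grid_rows,
        grid_cols=grid_cols,
        pitch_px=pitch_px,
        pattern_diameter_px=pattern_diameter_px,
        origin_px=origin_px,
        wells=wells,
    )


def validate_layout(source: str | Path | Mapping | ChipLayout) -> ChipLayout:
    """Parse and validate a chip layout, warning on unusual control setups.

    Checks structural validity (grid, pitch vs diameter, well references) and
    the experimental design convention of exactly one vehicle-control well per
    chip.  Zero control wells triggers a warning (apoptosis normalization will
    be impossible downstream); more than one triggers a warning and the
    controls are pooled when computing the vehicle mean.
    """
    if isinstance(source, ChipLayout):
        layout = source
    elif isinstance(source, Mapping):
        layout = ChipLayout.from_dict(source)
    else:
        layout = ChipLayout.from_json(source)

    controls = {
        (t.compound, t.is_vehicle_control)
        for t in layout.wells.values()
        if t.is_vehicle_control
    }
    n_control_patterns = sum(
        1 for t in layout.wells.values() if t.is_vehicle_control
    )
    distinct_treatments = {
        (t.compound, t.concentration_nM, t.is_vehicle_control)
        for t in layout.wells.values()
    }
    n_control_wells = sum(1 for t in distinct_treatments if t[2])
    if layout.wells and n_control_wells == 0:
        warnings.warn(
            "layout has no vehicle-control well; apoptosis normalization "
            "requires one",
            stacklevel=2,
        )
    elif n_control_wells > 1:
        warnings.warn(
            f"layout has {n_control_wells} vehicle-control wells "
            f"({n_control_patterns} patterns); they will be pooled for the "
            "control mean",
            stacklevel=2,
        )
    _ = controls
    return layout
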