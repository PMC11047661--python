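"""Binary digitization of per-cell readouts and micropattern outcomes.

Apoptosis: a cell's caspase-3/7 intensity is normalized to the mean of the
matched vehicle-control cells, ``(I - mean_ctrl) / mean_ctrl``, and the cell
scores 1 when the relative excess is strictly above 20%.

Calcium (TRPV1 activation): the Fluo-4 trace is baseline-subtracted at the
initial frame and the integrated peak area is summed over the 20 frames
following induction (~4 s at 5 frames/s); a strictly positive area scores 1.

Either way, a micropattern scores 1 when at least 50% of its cells score 1
(the >50% variant is available via ``rule=">"``).  Patterns without any cell
are excluded with a logged exclusion record rather than silently dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .quantify import CalciumTrace

logger = logging.getLogger(__name__)

APOPTOSIS_ASSAY = "apoptosis"
TRPV1_ASSAY = "trpv1"

#: relative caspase excess over the vehicle-control mean above which a cell
#: is scored apoptotic
APOPTOSIS_THRESHOLD = 0.20

#: number of post-induction frames integrated for the calcium readout
CALCIUM_WINDOW_FRAMES = 20


@dataclass
class CellOutcome:
    """One cell's digitized readout: the normalized statistic and its 0/1 call."""

    cell_id: int
    pattern_id: int
    assay: str
    value: float  # normalized caspase ratio or integrated peak area
    outcome: int


@dataclass
class PatternOutcome:
    """One micropattern's binary response with its cell-level votes."""

    pattern_id: int
    assay: str
    n_cells: int
    n_positive: int
    outcome: int


def normalize_apoptosis(
    treated_intensity: float | np.ndarray, vehicle_control_mean: float
) -> float | np.ndarray:
    """Relative caspase excess over the vehicle-control mean.

    ``(I - mean_ctrl) / mean_ctrl``: 0 for a control-level cell, 0.2 for a
    cell at exactly 1.2x control.
    """
    if not np.isfinite(vehicle_control_mean) or vehicle_control_mean <= 0:
        raise ValidationError(
            "vehicle-control mean must be positive; is the control well "
            f"missing or blank? (got {vehicle_control_mean})"
        )
    result = (np.asarray(treated_intensity, dtype=float) - vehicle_control_mean) / (
        vehicle_control_mean
    )
    return float(result) if np.ndim(treated_intensity) == 0 else result


def binarize_cell_apoptosis(
    normalized: float, threshold: float = APOPTOSIS_THRESHOLD
) -> int:
    """1 iff the normalized ratio is strictly above the threshold.

    Exactly 20% excess scores 0 ("above 20%" is strict).
    """
    if not np.isfinite(normalized):
        raise ValidationError("normalized apoptosis value must be finite")
    return int(normalized > threshold)


def normalize_trace(trace: CalciumTrace | np.ndarray) -> np.ndarray:
    """Baseline-subtract a calcium trace at its initial frame (t0).

    Removes the heterogeneous resting Ca2+ baseline; output[0] is 0.
    """
    values = trace.values if isinstance(trace, CalciumTrace) else np.asarray(
        trace, dtype=float
    )
    if len(values) == 0:
        raise ValidationError("cannot normalize an empty trace")
    return values - values[0]


def integrated_peak_area(
    normalized_trace: np.ndarray,
    induction_frame: int,
    window_frames: int = CALCIUM_WINDOW_FRAMES,
) -> float:
    """Integrated peak area over the post-induction window.

    Rectangular-rule sum (dt = 1 frame) of the baseline-subtracted trace over
    frames ``induction_frame + 1`` through ``induction_frame + window_frames``.
    """
    values = np.asarray(normalized_trace, dtype=float)
    if induction_frame < 0 or window_frames < 1:
        raise ValidationError("induction_frame must be >= 0 and window_frames >= 1")
    if induction_frame + window_frames >= len(values):
        raise ValidationError(
            f"window [{induction_frame + 1}, {induction_frame + window_frames}] "
            f"overruns the {len(values)}-frame trace"
        )
    return float(values[induction_frame + 1 : induction_frame + window_frames + 1].sum())


def binarize_cell_calcium(area: float) -> int:
    """1 iff the integrated peak area is strictly positive (zero scores 0)."""
    if not np.isfinite(area):
        raise ValidationError("integrated peak area must be finite")
    return int(area > 0)


def binarize_pattern(
    cell_outcomes: Sequence[CellOutcome], rule: str = ">="
) -> PatternOutcome:
    """Micropattern call from its cells: 1 iff >=50% of cells are positive.

    ``rule=">"`` switches to the strict >50% variant.  All outcomes must
    belong to the same pattern and assay; an empty pattern is an error (the
    table-level drivers exclude and log such patterns instead).
    """
    if rule not in (">=", ">"):
        raise ValidationError("rule must be '>=' or '>'")
    if len(cell_outcomes) == 0:
        raise ValidationError("cannot binarize a pattern with no cell outcomes")
    pattern_ids = {c.pattern_id for c in cell_outcomes}
    assays = {c.assay for c in cell_outcomes}
    if len(pattern_ids) != 1 or len(assays) != 1:
        raise ValidationError(
            f"cell outcomes span patterns {sorted(pattern_ids)} / assays "
            f"{sorted(assays)}; binarize one pattern at a time"
        )
    n = len(cell_outcomes)
    n_pos = sum(c.outcome for c in cell_outcomes)
    frac = n_pos / n
    positive = frac >= 0.5 if rule == ">=" else frac > 0.5
    return PatternOutcome(
        pattern_id=pattern_ids.pop(),
        assay=assays.pop(),
        n_cells=n,
        n_positive=int(n_pos),
        outcome=int(positive),
    )


# ---------------------------------------------------------------------------
# table-level drivers
# ---------------------------------------------------------------------------


def _group_patterns(
    outcomes: Iterable[CellOutcome], rule: str
) -> tuple[list[PatternOutcome], list[int]]:
    by_pattern: dict[int, list[CellOutcome]] = {}
    for c in outcomes:
        by_pattern.setdefault(c.pattern_id, []).append(c)
    patterns = [
        binarize_pattern(cells, rule=rule) for _, cells in sorted(by_pattern.items())
    ]
    return patterns, []


def digitize_apoptosis(
    cells: pd.DataFrame,
    vehicle_control_mean: float,
    threshold: float = APOPTOSIS_THRESHOLD,
    rule: str = ">=",
    intensity_column: str = "caspase_mean",
    expected_patterns: Iterable[int] | None = None,
) -> tuple[list[CellOutcome], list[PatternOutcome], list[int]]:
    """Digitize a per-cell caspase intensity table into pattern outcomes.

    ``cells`` needs columns ``pattern_id``, ``cell_id`` and
    ``intensity_column``.  Returns cell outcomes, pattern outcomes, and the
    ids of expected patterns excluded because they held no cells (logged).
    """
    required = {"pattern_id", "cell_id", intensity_column}
    missing = required - set(cells.columns)
    if missing:
        raise ValidationError(f"cell table lacks columns: {sorted(missing)}")
    cell_outcomes = []
    for row in cells.itertuples(index=False):
        value = normalize_apoptosis(
            getattr(row, intensity_column), vehicle_control_mean
        )
        cell_outcomes.append(
            CellOutcome(
                cell_id=int(row.cell_id),
                pattern_id=int(row.pattern_id),
                assay=APOPTOSIS_ASSAY,
                value=float(value),
                outcome=binarize_cell_apoptosis(value, threshold),
            )
        )
    patterns, _ = _group_patterns(cell_outcomes, rule)
    excluded = _excluded_patterns(patterns, expected_patterns, APOPTOSIS_ASSAY)
    return cell_outcomes, patterns, excluded


def digitize_calcium(
    traces: Sequence[CalciumTrace],
    window_frames: int = CALCIUM_WINDOW_FRAMES,
    rule: str = ">=",
    expected_patterns: Iterable[int] | None = None,
) -> tuple[list[CellOutcome], list[PatternOutcome], list[int]]:
    """Digitize calcium traces into TRPV1-activation pattern outcomes."""
    cell_outcomes = []
    for trace in traces:
        area = integrated_peak_area(
            normalize_trace(trace), trace.induction_frame, window_frames
        )
        cell_outcomes.append(
            CellOutcome(
                cell_id=trace.cell_id,
                pattern_id=trace.pattern_id,
                assay=TRPV1_ASSAY,
                value=area,
                outcome=binarize_cell_calcium(area),
            )
        )
    patterns, _ = _group_patterns(cell_outcomes, rule)
    excluded = _excluded_patterns(patterns, expected_patterns, TRPV1_ASSAY)
    return cell_outcomes, patterns, excluded


def _excluded_patterns(
    patterns: list[PatternOutcome],
    expected: Iterable[int] | None,
    assay: str,
) -> list[int]:
    if expected is None:
        return []
    present = {p.pattern_id for p in patterns}
    excluded = sorted(set(int(p) for p in expected) - present)
    for pid in excluded:
        logger.warning("pattern %d excluded from %s digitization: no cells", pid, assay)
    return excluded


def pattern_outcomes_to_frame(
    patterns: Sequence[PatternOutcome],
    layout=None,
) -> pd.DataFrame:
    """PatternOutcome list -> tidy table, annotated with treatments if given."""
    rows = []
    for p in patterns:
        row = {
            "pattern_id": p.pattern_id,
            "assay": p.assay,
            "n_cells": p.n_cells,
            "n_positive": p.n_positive,
            "outcome": p.outcome,
        }
        if layout is not None:
            t = layout.treatment_of(p.pattern_id)
            row["compound"] = t.compound if t else ""
            row["concentration_nM"] = t.concentration_nM if t else np.nan
            row["is_vehicle_control"] = t.is_vehicle_control if t else False
        rows.append(row)
    cols = ["pattern_id", "assay", "n_cells", "n_positive", "outcome"]
    if layout is not None:
        cols += ["compound", "concentration_nM", "is_vehicle_control"]
    return pd.DataFrame(rows, columns=cols)


def vehicle_control_mean(
    cells: pd.DataFrame,
    layout,
    intensity_column: str = "caspase_mean",
) -> float:
    """Mean intensity over all cells in the chip's vehicle-control well(s).

    Multiple control wells are pooled.  A chip without a control well (or
    without any control cell) is an error that reports the well map, since
    the apoptosis normalization is undefined without it.
    """
    control_ids = {
        pid for pid, t in layout.wells.items() if t.is_vehicle_control
    }
    well_map = {
        pid: f"{t.compound}@{t.concentration_nM}nM"
        + (" [vehicle]" if t.is_vehicle_control else "")
        for pid, t in sorted(layout.wells.items())
    }
    if not control_ids:
        raise ValidationError(
            f"no vehicle-control well in layout; well map: {well_map}"
        )
    sel = cells[cells["pattern_id"].isin(control_ids)]
    if sel.empty:
        raise ValidationError(
            f"vehicle-control well(s) {sorted(control_ids)} contain no cells; "
            f"well map: {well_map}"
        )
    return float(sel[intensity_column].mean())
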