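"""384-well plate handling: serpentine fraction mapping, normalization,
bioactivity chromatograms and negative-peak calling.

At-line nanofractionation collects post-column eluate into a 384-well
plate at a fixed cadence (6 s per well by default), snaking row by row
(serpentine) through columns 1-23; the last column holds assay controls.
After a resazurin viability readout, each well's fluorescence maps back
to a retention-time slice, giving a "bioactivity chromatogram" in which
growth inhibition appears as a *negative* peak (a dip below the
normalized baseline of 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "PlateLayout",
    "PlateRead",
    "BioactivityTrace",
    "BioactivityPeak",
    "serpentine_order",
    "fraction_time",
    "normalize_plate",
    "build_trace",
    "detect_bioactivity_peaks",
]

ROW_LETTERS = "ABCDEFGHIJKLMNOP"


@dataclass(frozen=True)
class PlateLayout:
    """Geometry and timing of the nanofraction collection.

    Defaults mirror a 16x24 plate filled serpentine over columns 1-23
    (column 24 reserved for controls), 350 collected wells per sample,
    one well per 6 s of eluate.
    """

    rows: int = 16
    columns: int = 24
    control_column: int = 24
    wells_per_sample: int = 350
    fraction_seconds: float = 6.0
    collection_start: float = 0.0  # minutes on the LC axis
    start_left_to_right: bool = True

    def __post_init__(self) -> None:
        if self.fraction_seconds <= 0:
            raise ValueError("fraction_seconds must be positive")
        if self.wells_per_sample > self.n_usable:
            raise ValueError(
                f"wells_per_sample={self.wells_per_sample} exceeds usable "
                f"wells ({self.n_usable})"
            )

    @property
    def usable_columns(self) -> range:
        return range(1, self.columns)  # 1..23 when control is 24

    @property
    def n_usable(self) -> int:
        return self.rows * len(self.usable_columns)

    @property
    def fraction_minutes(self) -> float:
        return self.fraction_seconds / 60.0


@dataclass
class PlateRead:
    """One single-point fluorescence measurement of a whole plate.

    ``grid`` is rows x columns; NaN marks unmeasured wells.
    """

    grid: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2:
            raise ValueError("plate grid must be 2-D")
        if np.nanmin(self.grid, initial=0.0) < 0:
            raise ValueError("fluorescence values must be >= 0")


@dataclass
class BioactivityTrace:
    """Normalized assay response vs fraction collection time (minutes)."""

    times: np.ndarray
    response: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.times.shape != self.response.shape:
            raise ValueError("times and response must have equal length")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class BioactivityPeak:
    """A called negative maximum of the bioactivity chromatogram."""

    start_time: float
    apex_time: float
    end_time: float
    depth: float  # 1 - minimum normalized response
    n_fractions: int
    peak_id: int = 0

    def __post_init__(self) -> None:
        if not (self.start_time <= self.apex_time <= self.end_time):
            raise ValueError("peak times must satisfy start <= apex <= end")


def serpentine_order(layout: PlateLayout) -> list[tuple[int, int]]:
    """Well coordinates (row, column), both 1-based, in collection order.

    Row A runs columns 1→23, row B runs 23→1, alternating; the control
    column never appears.  Truncated to ``wells_per_sample`` entries.
    """
    cols = list(layout.usable_columns)
    order: list[tuple[int, int]] = []
    for r in range(1, layout.rows + 1):
        forward = (r % 2 == 1) == layout.start_left_to_right
        order.extend((r, c) for c in (cols if forward else cols[::-1]))
    return order[: layout.wells_per_sample]


def well_name(row: int, col: int) -> str:
    """Human-readable well label, e.g. ``(1, 1) -> "A1"``."""
    return f"{ROW_LETTERS[row - 1]}{col}"


def fraction_time(index: int, layout: PlateLayout) -> float:
    """Collection time (minutes) of fraction ``index`` (0-based).

    The fraction spans the half-open window ``[t, t + dt)``.
    """
    if not 0 <= index < layout.wells_per_sample:
        raise IndexError(
            f"fraction index {index} out of range 0..{layout.wells_per_sample - 1}"
        )
    return layout.collection_start + index * layout.fraction_minutes


def normalize_plate(
    read: PlateRead,
    layout: PlateLayout | None = None,
    include_controls_in_median: bool = False,
) -> PlateRead:
    """Divide every well by the median of the measured values.

    The median is taken over the sample wells of this single plate read
    (controls excluded by default; set ``include_controls_in_median`` to
    use every measured well).
    """
    grid = read.grid
    if layout is not None and not include_controls_in_median:
        mask = np.zeros_like(grid, dtype=bool)
        for r, c in serpentine_order(layout):
            mask[r - 1, c - 1] = True
        vals = grid[mask]
    else:
        vals = grid.ravel()
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no measured wells to normalize against")
    med = float(np.median(vals))
    if med <= 0:
        raise ValueError("plate median must be positive")
    return PlateRead(grid / med)


def build_trace(read: PlateRead, layout: PlateLayout) -> BioactivityTrace:
    """Unfold a (normalized) plate into a time-ordered bioactivity trace."""
    order = serpentine_order(layout)
    if not order:
        raise ValueError("layout has no usable wells")
    rows, cols = read.grid.shape
    if rows < layout.rows or cols < layout.columns:
        raise ValueError(
            f"plate grid {rows}x{cols} smaller than layout "
            f"{layout.rows}x{layout.columns}"
        )
    response = np.array([read.grid[r - 1, c - 1] for r, c in order])
    times = np.array([fraction_time(i, layout) for i in range(len(order))])
    return BioactivityTrace(times, response)


def detect_bioactivity_peaks(
    trace: BioactivityTrace,
    threshold: float = 0.8,
    min_width: int = 2,
) -> list[BioactivityPeak]:
    """Call negative maxima: runs of >= ``min_width`` fractions below
    ``threshold``.

    Contiguous sub-threshold fractions are merged into one peak whose
    apex is the response minimum; depth is ``1 - min(response)``.  The
    result is sorted by start time and deterministic.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    resp = trace.response
    below = resp < threshold
    peaks: list[BioactivityPeak] = []
    i = 0
    n = len(resp)
    while i < n:
        if not below[i]:
            i += 1
            continue
        j = i
        while j < n and below[j]:
            j += 1
        if j - i >= min_width:
            seg = resp[i:j]
            k = i + int(np.argmin(seg))
            peaks.append(
                BioactivityPeak(
                    start_time=float(trace.times[i]),
                    apex_time=float(trace.times[k]),
                    end_time=float(trace.times[j - 1]),
                    depth=float(1.0 - resp[k]),
                    n_fractions=j - i,
                    peak_id=len(peaks) + 1,
                )
            )
        i = j
    return peaks
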