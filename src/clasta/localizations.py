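"""Data model and CSV I/O for 2D localization tables.

Coordinates are continuous positions in nanometers, as produced by
single-molecule fitting software (e.g. ThunderSTORM exports).  A
:class:`LocalizationSet` bundles one color channel's localizations with the
rectangular region of interest (ROI) that defines the analysis area and the
torus used for randomization shifts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import EmptyInputError, FormatError

logger = logging.getLogger(__name__)

#: Column names per supported CSV dialect (x, y mandatory; frame optional).
DIALECTS = {
    "thunderstorm-csv": {"x": "x [nm]", "y": "y [nm]", "frame": "frame"},
    "plain-xy-csv": {"x": "x_nm", "y": "y_nm", "frame": "frame"},
}


@dataclass(frozen=True)
class RegionOfInterest:
    """Axis-aligned rectangle in nm; membership is half-open [min, max).

    The half-open convention makes the toroidal wrap bijective: a point
    shifted onto the maximum edge re-enters at the minimum edge.
    """

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        vals = (self.x_min, self.y_min, self.x_max, self.y_max)
        if not all(np.isfinite(vals)):
            raise ValueError("ROI bounds must be finite")
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError("ROI must have positive width and height")

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        """Area in nm^2."""
        return self.width * self.height

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside the half-open rectangle."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (
            (x >= self.x_min)
            & (x < self.x_max)
            & (y >= self.y_min)
            & (y < self.y_max)
        )

    @classmethod
    def square(cls, side_nm: float, origin: tuple[float, float] = (0.0, 0.0)) -> "RegionOfInterest":
        x0, y0 = origin
        return cls(x0, y0, x0 + side_nm, y0 + side_nm)


@dataclass
class LocalizationSet:
    """One channel's 2D localizations (nm) with acquisition-frame indices.

    ``frame`` is 1-based; records missing a frame column default to frame 1.
    Construction validates finiteness and shape but not ROI containment --
    simulated artifacts (drift, aberration, localization error) can push
    records slightly outside the ROI, and callers crop with :meth:`crop`
    before statistical analysis.
    """

    channel_id: str
    x: np.ndarray
    y: np.ndarray
    roi: RegionOfInterest
    frame: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float).ravel()
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.x.shape != self.y.shape:
            raise ValueError("x and y must have equal length")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError("coordinates must be finite")
        if self.frame is None:
            self.frame = np.ones(self.x.size, dtype=np.int64)
        else:
            self.frame = np.asarray(self.frame, dtype=np.int64).ravel()
            if self.frame.shape != self.x.shape:
                raise ValueError("frame must have the same length as x/y")
            if self.frame.size and self.frame.min() < 1:
                raise ValueError("frame indices are 1-based positive integers")

    def __len__(self) -> int:
        return self.x.size

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) coordinate array."""
        return np.column_stack([self.x, self.y])

    def all_in_roi(self) -> bool:
        return bool(np.all(self.roi.contains(self.x, self.y)))

    def crop(self, roi: RegionOfInterest | None = None) -> "LocalizationSet":
        """Return a copy restricted to ``roi`` (default: own ROI).

        Idempotent: cropping twice equals cropping once.
        """
        roi = roi if roi is not None else self.roi
        mask = roi.contains(self.x, self.y)
        return LocalizationSet(
            channel_id=self.channel_id,
            x=self.x[mask],
            y=self.y[mask],
            frame=self.frame[mask],
            roi=roi,
        )

    def with_coords(self, x: np.ndarray, y: np.ndarray) -> "LocalizationSet":
        return replace(self, x=np.asarray(x, float), y=np.asarray(y, float))


def read_localizations(
    path,
    dialect: str = "thunderstorm-csv",
    roi: RegionOfInterest | None = None,
    channel_id: str = "channel",
) -> LocalizationSet:
    """Read a localization table from CSV.

    Rows with non-finite coordinates are discarded.  If ``roi`` is given,
    rows outside it are dropped (the count is logged); otherwise the ROI is
    the bounding box of the data.

    Raises
    ------
    FormatError
        Unknown dialect or missing mandatory coordinate columns.
    EmptyInputError
        No rows remain after filtering.
    """
    if dialect not in DIALECTS:
        raise FormatError(f"unknown dialect {dialect!r}; choose from {sorted(DIALECTS)}")
    cols = DIALECTS[dialect]
    df = pd.read_csv(path)
    missing = [cols[c] for c in ("x", "y") if cols[c] not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {missing} for dialect {dialect!r}")
    x = pd.to_numeric(df[cols["x"]], errors="coerce").to_numpy(float)
    y = pd.to_numeric(df[cols["y"]], errors="coerce").to_numpy(float)
    finite = np.isfinite(x) & np.isfinite(y)
    if cols["frame"] in df.columns:
        frame = pd.to_numeric(df[cols["frame"]], errors="coerce").to_numpy()
        finite &= np.isfinite(frame)
        frame = frame[finite].astype(np.int64)
    else:
        frame = None
    x, y = x[finite], y[finite]
    if roi is not None:
        mask = roi.contains(x, y)
        n_dropped = int((~mask).sum())
        if n_dropped:
            logger.info("%s: dropped %d localization(s) outside the ROI", path, n_dropped)
        x, y = x[mask], y[mask]
        frame = frame[mask] if frame is not None else None
    if x.size == 0:
        raise EmptyInputError(f"{path}: no localizations after filtering")
    if roi is None:
        # bounding box of the data; the boundary points belong to the set
        roi = RegionOfInterest(
            float(x.min()), float(y.min()),
            float(max(x.max(), x.min() + 1e-9)), float(max(y.max(), y.min() + 1e-9)),
        )
    return LocalizationSet(channel_id=channel_id, x=x, y=y, frame=frame, roi=roi)


def write_localizations(ls: LocalizationSet, path, dialect: str = "thunderstorm-csv") -> None:
    """Write a localization table as CSV; round-trips coordinates exactly.

    Raises :class:`EmptyInputError` for an empty set and :class:`FormatError`
    for an unknown dialect.
    """
    if dialect not in DIALECTS:
        raise FormatError(f"unknown dialect {dialect!r}; choose from {sorted(DIALECTS)}")
    if len(ls) == 0:
        raise EmptyInputError("refusing to write an empty localization set")
    cols = DIALECTS[dialect]
    df = pd.DataFrame(
        {cols["x"]: ls.x, cols["y"]: ls.y, cols["frame"]: ls.frame}
    )
    df.to_csv(path, index=False)
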