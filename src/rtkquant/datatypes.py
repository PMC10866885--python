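"""Core containers shared across the analysis stages.

The containers are deliberately thin: they hold validated numbers plus the
flags the downstream fits need, and they serialise cleanly to table rows.
All intensities are in arbitrary fluorescence units ("arb. units"); only
ratios, slopes and rates carry meaning across acquisitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon

from .exceptions import ValidationError


@dataclass
class RoiPair:
    """Whole-cell (roi1) and interior/cytoplasmic (roi2) polygons for one cell.

    Polygon vertices are 0-based pixel coordinates ``(x, y)``. roi2 must lie
    strictly inside roi1 and both polygons must be simple; the membrane signal
    is the difference of the two integrated intensities.
    """

    cell_id: str
    roi1: np.ndarray  # (n, 2) vertex array
    roi2: np.ndarray

    def __post_init__(self) -> None:
        self.roi1 = np.asarray(self.roi1, dtype=float)
        self.roi2 = np.asarray(self.roi2, dtype=float)
        for name, arr in (("roi1", self.roi1), ("roi2", self.roi2)):
            if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
                raise ValidationError(
                    f"{self.cell_id}: {name} must be an (n>=3, 2) vertex array"
                )
        p1, p2 = self.polygon1, self.polygon2
        if not p1.is_valid or not p1.is_simple:
            raise ValidationError(f"{self.cell_id}: roi1 polygon is not simple")
        if not p2.is_valid or not p2.is_simple:
            raise ValidationError(f"{self.cell_id}: roi2 polygon is not simple")
        if p2.area <= 0 or p1.area <= p2.area:
            raise ValidationError(
                f"{self.cell_id}: require area(roi1) > area(roi2) > 0"
            )
        if not p1.contains(p2):
            raise ValidationError(
                f"{self.cell_id}: roi2 must be strictly contained in roi1"
            )

    @property
    def polygon1(self) -> Polygon:
        return Polygon(self.roi1)

    @property
    def polygon2(self) -> Polygon:
        return Polygon(self.roi2)


@dataclass
class CellMeasurement:
    """Per-cell membrane intensities for the expression and phospho channels.

    ``expr_im`` and ``phospho_im`` are the membrane intensities
    I_m = I_roi1 - I_roi2 for the mCherry (expression) and FITC (phospho)
    channels. Negative membrane intensities are retained and flagged rather
    than dropped: they occur when noise dominates a dim cell.
    """

    cell_id: str
    expr_roi1: float
    expr_roi2: float
    phospho_roi1: float
    phospho_roi2: float

    def __post_init__(self) -> None:
        vals = [self.expr_roi1, self.expr_roi2, self.phospho_roi1, self.phospho_roi2]
        if not np.all(np.isfinite(vals)):
            raise ValidationError(f"{self.cell_id}: non-finite ROI intensity")

    @property
    def expr_im(self) -> float:
        return self.expr_roi1 - self.expr_roi2

    @property
    def phospho_im(self) -> float:
        return self.phospho_roi1 - self.phospho_roi2

    @property
    def negative_flag(self) -> bool:
        """True when either membrane intensity is <= 0 (noise-dominated)."""
        return self.expr_im <= 0 or self.phospho_im <= 0


@dataclass
class FrapSeries:
    """Raw FRAP traces: bleach spot, whole cell (minus spot) and background.

    ``times`` are seconds from the first post-bleach frame; prebleach frames
    are stored separately and provide the normalisation reference.
    """

    times: np.ndarray
    f_roi: np.ndarray
    f_total: np.ndarray
    f_bg: np.ndarray
    pre_roi: np.ndarray
    pre_total: np.ndarray
    pre_bg: np.ndarray
    frame_interval: float = 0.5
    nominal_radius: float = 1.2  # um

    def __post_init__(self) -> None:
        for name in ("times", "f_roi", "f_total", "f_bg", "pre_roi", "pre_total", "pre_bg"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.times)
        if not (len(self.f_roi) == len(self.f_total) == len(self.f_bg) == n):
            raise ValidationError("post-bleach traces must all match len(times)")
        if n >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValidationError("times must be strictly increasing")
        if len(self.pre_roi) < 1:
            raise ValidationError("at least one prebleach frame is required")
        if not (len(self.pre_roi) == len(self.pre_total) == len(self.pre_bg)):
            raise ValidationError("prebleach traces must have equal length")

    @property
    def n_pre(self) -> int:
        return len(self.pre_roi)

    @property
    def n_post(self) -> int:
        return len(self.times)


@dataclass
class CorrectedSeries:
    """Background/photofade-corrected and prebleach-normalised FRAP trace."""

    times: np.ndarray
    f_corrected: np.ndarray     # ratio per frame, dimensionless
    f_normalized: np.ndarray    # f_corrected / prebleach reference
    prebleach_reference: float  # corrected prebleach value; normalises to 1


@dataclass
class RecoveryFit:
    """First-order recovery model f(t) = offset + A(1 - exp(-k t)).

    ``t_half`` follows the reporting convention k = 0.69 / t_half (the
    half-time of the fitted exponential above its floor). ``t_half_full``
    is the time at which the fitted curve crosses halfway between its floor
    and the full prebleach-normalised level 1; the two coincide whenever
    the fit recovers fully (offset + A = 1) and ``t_half_full`` is the
    robust reading on recoveries truncated by the acquisition window.
    """

    amplitude: float            # A
    rate: float                 # k, 1/time_unit
    t_half: float
    offset: float
    residual_sd: float
    converged: bool
    t_half_full: float = float("nan")
    time_unit: str = "s"
    no_recovery: bool = False


@dataclass
class DiffusionEstimate:
    """Effective bleach radius and the confocal diffusion coefficient."""

    effective_radius: float       # r_e, um
    t_half: float                 # s
    d_confocal: float             # um^2/s
    coefficient: float = 0.25     # fixed proportionality constant
    radius_below_nominal: bool = False


@dataclass
class TimeCourse:
    """Densitometric phospho intensity versus time for one construct.

    ``replicates`` maps replicate id -> (times_min, intensities) pairs; the
    single-series constructor stores one replicate named "1".
    """

    construct_id: str
    times: np.ndarray
    intensity: np.ndarray
    replicates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if len(self.times) != len(self.intensity):
            raise ValidationError("times and intensity must have equal length")
        if np.any(self.times < 0):
            raise ValidationError("times must be non-negative")
        if len(self.times) >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValidationError("times must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValidationError("intensities must be non-negative")
        if not self.replicates:
            self.replicates = {"1": (self.times, self.intensity)}


@dataclass
class KineticsSummary:
    """Fitted phospho kinetics: rise rate, decay half-life, persistence class."""

    construct_id: str
    rise_rate: float              # arb. units / min on the normalised curve
    rise_rate_se: float
    t_half_decay: float           # minutes; == window bound when censored
    censored: bool
    peak_time: float              # minutes
    persistence: str              # "transient" | "sustained"
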