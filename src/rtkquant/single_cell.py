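"""Single-cell membrane expression vs phosphorylation dose analysis.

A transiently transfected population expresses the receptor over a wide
concentration range. Per cell, the membrane intensity I_m of the expression
channel (mCherry) reports receptor density at the plasma membrane and the
phospho channel (FITC) reports C-terminal tyrosine phosphorylation. Cells are
binned by expression, bin means are fitted with a linear model
(ligand-dependent behaviour: phosphorylation proportional to receptor
density) against a quadratic model (ligand-independent, supra-linear
activation above a critical density), and the nested-model F-test selects
between them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .datatypes import CellMeasurement
from .exceptions import InsufficientDataError, ValidationError

__all__ = [
    "measure_population",
    "BinnedPopulation",
    "ActivationModelSelector",
    "bin_population",
    "fit_activation",
    "normalized_phospho",
    "fraction_phosphorylated",
    "ttest_unpaired",
]

DEFAULT_BIN_WIDTH = 2500.0          # arb. units, expression-channel binning
DEFAULT_RATIO_BIN_WIDTH = 10000.0   # arb. units, normalised-phospho binning
DEFAULT_MIN_CELLS = 3


@dataclass
class BinnedPopulation:
    """Expression-binned population summary.

    Bins are half-open intervals [k*w, (k+1)*w) anchored at zero on the
    expression axis; each retained bin has at least ``min_cells`` members.
    """

    bin_width: float
    table: pd.DataFrame  # bin_id, expr_mean, phospho_mean, n_cells, expr_sd, phospho_sd
    dropped: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_bins(self) -> int:
        return len(self.table)


def _cells_to_frame(cells: list[CellMeasurement]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_id": [c.cell_id for c in cells],
            "expr_im": [c.expr_im for c in cells],
            "phospho_im": [c.phospho_im for c in cells],
        }
    )


def measure_population(
    expr_image: np.ndarray,
    phospho_image: np.ndarray,
    rois,
    background_expr: float = 0.0,
    background_phospho: float = 0.0,
) -> list[CellMeasurement]:
    """Measure both channels over every ROI pair of a field of view.

    Backgrounds are mean per-pixel intensities of untransfected-cell or
    cell-free regions, applied as mean x ROI area inside the integration.
    """
    from .roi import measure_roi_intensity

    cells = []
    for pair in rois:
        cells.append(
            CellMeasurement(
                cell_id=pair.cell_id,
                expr_roi1=measure_roi_intensity(expr_image, pair.polygon1, background_expr),
                expr_roi2=measure_roi_intensity(expr_image, pair.polygon2, background_expr),
                phospho_roi1=measure_roi_intensity(phospho_image, pair.polygon1, background_phospho),
                phospho_roi2=measure_roi_intensity(phospho_image, pair.polygon2, background_phospho),
            )
        )
    return cells


def bin_population(
    cells: list[CellMeasurement],
    bin_width: float = DEFAULT_BIN_WIDTH,
    min_cells: int = DEFAULT_MIN_CELLS,
) -> BinnedPopulation:
    """Bin cells by expression I_m and average both channels per bin.

    Bins with fewer than ``min_cells`` members are dropped and reported in
    ``BinnedPopulation.dropped``. Raises if no bin survives.
    """
    if bin_width <= 0:
        raise ValidationError("bin_width must be positive")
    if not cells:
        raise ValidationError("cells must be non-empty")
    df = _cells_to_frame(cells)
    df["bin_id"] = np.floor(df["expr_im"] / bin_width).astype(int)
    g = df.groupby("bin_id")
    out = g.agg(
        expr_mean=("expr_im", "mean"),
        phospho_mean=("phospho_im", "mean"),
        n_cells=("expr_im", "size"),
        expr_sd=("expr_im", "std"),
        phospho_sd=("phospho_im", "std"),
    ).reset_index()
    keep = out["n_cells"] >= min_cells
    retained, dropped = out[keep].reset_index(drop=True), out[~keep].reset_index(drop=True)
    if retained.empty:
        raise InsufficientDataError(
            f"no bin reaches min_cells={min_cells} (max occupancy "
            f"{int(out['n_cells'].max())})"
        )
    return BinnedPopulation(bin_width=float(bin_width), table=retained, dropped=dropped)


class ActivationModelSelector(BaseEstimator, RegressorMixin):
    """Linear vs quadratic dose-response fit with nested-model selection.

    Fits phospho = a*x + b (ligand-dependent: phosphorylation tracks receptor
    density linearly) and phospho = c*x^2 + a*x + b (ligand-independent:
    supra-linear activation) to the expression/phospho bin means by ordinary
    least squares, and selects the quadratic model only when the nested
    F-test rejects the linear model at ``alpha`` and the curvature c is
    positive.

    Parameters
    ----------
    alpha : float, default 0.05
        Significance level of the nested-model F-test.
    weighting : {"cv", "n_cells", "none"}, default "cv"
        Weights for the bin-mean fit. "cv" uses n_cells / expr_mean^2,
        matching a constant-coefficient-of-variation (multiplicative)
        noise model for fluorescence with per-bin averaging; "n_cells"
        weights by occupancy only; "none" is ordinary least squares.
        Weighting matters because bins are unevenly occupied and the
        per-cell scatter grows with expression.

    Attributes
    ----------
    model_ : str
        Selected model, "linear" or "quadratic".
    slope_ : float
        Linear-model slope a (phospho per expression unit).
    slope_se_ : float
        Standard error of the linear slope.
    intercept_ : float
    coef_linear_ : ndarray, (intercept, a) of the linear fit.
    coef_quadratic_ : ndarray, (intercept, a, c) of the quadratic fit.
    coef_se_linear_, coef_se_quadratic_ : ndarray of standard errors.
    curvature_ : float
        Quadratic coefficient c.
    f_stat_, p_value_ : float
        Nested-model F statistic and p-value.
    """

    def __init__(self, alpha: float = 0.05, weighting: str = "cv"):
        self.alpha = alpha
        self.weighting = weighting

    def _weights(self, x, n_cells):
        if self.weighting == "none":
            return np.ones_like(x)
        if self.weighting == "n_cells":
            return n_cells.astype(float)
        if self.weighting == "cv":
            return n_cells / np.maximum(x, 1.0) ** 2
        raise ValidationError(f"unknown weighting {self.weighting!r}")

    def fit(self, X, y=None):
        """Fit both models to bin means.

        ``X`` may be a :class:`BinnedPopulation` (y ignored) or an (n, 1)
        array / 1-D sequence of expression means with ``y`` the phospho means
        (occupancy then defaults to 1 per bin).
        """
        if isinstance(X, BinnedPopulation):
            x = X.table["expr_mean"].to_numpy(dtype=float)
            y = X.table["phospho_mean"].to_numpy(dtype=float)
            n_cells = X.table["n_cells"].to_numpy(dtype=float)
        else:
            x = np.asarray(X, dtype=float).reshape(-1)
            y = np.asarray(y, dtype=float).reshape(-1)
            n_cells = np.ones_like(x)
        if len(x) < 4:
            raise InsufficientDataError(
                f"model comparison needs >= 4 bins, got {len(x)}"
            )
        if np.ptp(x) == 0:
            raise ValidationError("degenerate expression axis: all bins equal")

        w = self._weights(x, n_cells)
        lin = sm.WLS(y, sm.add_constant(x), weights=w).fit()
        quad = sm.WLS(y, sm.add_constant(np.column_stack([x, x**2])), weights=w).fit()
        f_stat, p_value, _ = quad.compare_f_test(lin)
        curvature = float(quad.params[2])

        self.coef_linear_ = np.asarray(lin.params, dtype=float)
        self.coef_se_linear_ = np.asarray(lin.bse, dtype=float)
        self.coef_quadratic_ = np.asarray(quad.params, dtype=float)
        self.coef_se_quadratic_ = np.asarray(quad.bse, dtype=float)
        self.slope_ = float(lin.params[1])
        self.slope_se_ = float(lin.bse[1])
        self.intercept_ = float(lin.params[0])
        self.curvature_ = curvature
        self.f_stat_ = float(f_stat)
        self.p_value_ = float(p_value)
        self.model_ = (
            "quadratic" if (p_value < self.alpha and curvature > 0) else "linear"
        )
        self.n_bins_ = len(x)
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float).reshape(-1)
        if self.model_ == "quadratic":
            b, a, c = self.coef_quadratic_
            return b + a * x + c * x**2
        b, a = self.coef_linear_
        return b + a * x


def fit_activation(binned: BinnedPopulation, alpha: float = 0.05) -> ActivationModelSelector:
    """Fit and select the activation model for a binned population."""
    return ActivationModelSelector(alpha=alpha).fit(binned)


def normalized_phospho(
    cells: list[CellMeasurement],
    bin_width: float = DEFAULT_RATIO_BIN_WIDTH,
) -> pd.DataFrame:
    """Per-bin mean +/- sd of the per-cell phospho/expression ratio.

    Cells with expression I_m <= 0 cannot be normalised; they are excluded
    with a warning (they remain in raw tables upstream). Bins follow the
    half-open [k*w, (k+1)*w) convention on the expression axis.
    """
    if bin_width <= 0:
        raise ValidationError("bin_width must be positive")
    df = _cells_to_frame(cells)
    bad = df["expr_im"] <= 0
    if bad.any():
        warnings.warn(
            f"excluding {int(bad.sum())} cell(s) with expression I_m <= 0 "
            "from ratio analysis",
            stacklevel=2,
        )
        df = df[~bad]
    if df.empty:
        raise InsufficientDataError("no cells with positive expression")
    df = df.copy()
    df["ratio"] = df["phospho_im"] / df["expr_im"]
    df["bin_id"] = np.floor(df["expr_im"] / bin_width).astype(int)
    out = (
        df.groupby("bin_id")
        .agg(
            expr_mean=("expr_im", "mean"),
            ratio_mean=("ratio", "mean"),
            ratio_sd=("ratio", "std"),
            n_cells=("ratio", "size"),
        )
        .reset_index()
    )
    return out


def fraction_phosphorylated(
    fit_construct: ActivationModelSelector, fit_wt: ActivationModelSelector
) -> float:
    """Slope ratio construct/wild-type: relative fraction phosphorylated.

    Both fits must be on the linear (ligand-dependent) branch with a positive
    wild-type slope; the ratio normalises a construct's dose-response slope
    against the wild-type receptor measured under the same stimulation.
    """
    for name, f in (("construct", fit_construct), ("wt", fit_wt)):
        if not hasattr(f, "slope_"):
            raise ValidationError(f"{name} fit is not fitted")
    if fit_wt.slope_ <= 0:
        raise ValidationError(
            f"wild-type slope must be positive, got {fit_wt.slope_:.3g}"
        )
    return float(fit_construct.slope_ / fit_wt.slope_)


def ttest_unpaired(
    group_a, group_b, two_tailed: bool = True, welch: bool = False
) -> tuple[float, float]:
    """Unpaired Student's t-test (equal variance by default; Welch optional).

    Returns ``(t, p)``; the one-tailed p is half the two-tailed p with the
    observed direction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("each group needs n >= 2")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    t, p = float(res.statistic), float(res.pvalue)
    if np.isnan(t):  # zero pooled variance, identical constant groups
        return 0.0, 1.0
    if not two_tailed:
        p = p / 2.0
    return t, p
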