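"""Phosphorylation rise/decay kinetics from densitometry time courses.

After ligand stimulation the receptor's phosphotyrosine signal rises to a
peak and then decays as phosphatases win out. Each series is normalised to
its highest observed intensity; the rise rate is the 0-to-peak linear slope
of the normalised curve (arb. units/min), and the decay half-life comes from
an exponential decay anchored at the observed peak. A decay that never
reaches half the peak inside the observation window (or whose rate is not
significantly positive) is censored and reported as a lower bound
"> window_end", which classifies the response as sustained rather than
transient.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator

from .datatypes import KineticsSummary, TimeCourse
from .exceptions import (
    FitError,
    InsufficientDataError,
    NoRiseError,
    ValidationError,
)

__all__ = [
    "normalize_timecourse",
    "KineticsFitter",
    "fit_rise_rate",
    "fit_decay_halflife",
    "classify_persistence",
    "summarize_timecourse",
]

DEFAULT_WINDOW_MIN = 60.0


def normalize_timecourse(tc: TimeCourse) -> TimeCourse:
    """Divide every intensity by the series maximum (per replicate).

    The highest intensity observed becomes exactly 1, matching the
    densitometry convention of normalising each data set against its own
    peak. Idempotent and invariant to rescaling the raw intensities.
    """
    replicates = {}
    for rep_id, (t, y) in tc.replicates.items():
        y = np.asarray(y, dtype=float)
        peak = y.max()
        if peak <= 0:
            raise ValidationError(
                f"{tc.construct_id}/{rep_id}: all-zero series cannot be normalised"
            )
        replicates[rep_id] = (np.asarray(t, dtype=float), y / peak)
    t0, y0 = replicates[next(iter(replicates))]
    if len(replicates) == 1:
        times, intensity = t0, y0
    else:
        # average replicates on the common grid when they share times
        times = t0
        same_grid = all(np.array_equal(times, t) for t, _ in replicates.values())
        if same_grid:
            intensity = np.mean([y for _, y in replicates.values()], axis=0)
        else:
            intensity = y0
    return TimeCourse(
        construct_id=tc.construct_id,
        times=times,
        intensity=intensity,
        replicates=replicates,
    )


def _peak_index(times: np.ndarray, intensity: np.ndarray, smooth: bool) -> int:
    y = intensity
    if smooth and len(y) >= 3:
        y = np.concatenate([[y[0]], np.median(
            np.column_stack([y[:-2], y[1:-1], y[2:]]), axis=1), [y[-1]]])
    return int(np.argmax(y))


class KineticsFitter(BaseEstimator):
    """Rise-slope and anchored exponential-decay fit of a phospho time course.

    Parameters
    ----------
    window_end : float, default 60.0
        End of the observation window (minutes); decay half-lives that the
        fitted curve cannot reach inside the window are censored at this
        bound, and the transient/sustained boundary sits at half of it.
    smooth_peak : bool, default False
        Locate the peak on a 3-point median-smoothed curve.
    alpha : float, default 0.05
        One-sided significance level required of the decay rate.

    Attributes
    ----------
    rise_rate_, rise_rate_se_ : float
    peak_time_, peak_value_ : float
    decay_rate_ : float
    t_half_decay_ : float (== window_end when censored)
    censored_ : bool
    persistence_ : str, "transient" or "sustained"
    summary_ : :class:`KineticsSummary`
    """

    def __init__(
        self,
        window_end: float = DEFAULT_WINDOW_MIN,
        smooth_peak: bool = False,
        alpha: float = 0.05,
    ):
        self.window_end = window_end
        self.smooth_peak = smooth_peak
        self.alpha = alpha

    def fit(self, X, y=None):
        """Fit a :class:`TimeCourse` (or ``(times, intensities)`` arrays)."""
        if isinstance(X, TimeCourse):
            tc = normalize_timecourse(X)
        else:
            tc = normalize_timecourse(
                TimeCourse("series", np.asarray(X, float), np.asarray(y, float))
            )
        t, f = tc.times, tc.intensity
        ipk = _peak_index(t, f, self.smooth_peak)
        self.peak_time_ = float(t[ipk])
        self.peak_value_ = float(f[ipk])

        self._fit_rise(t, f, ipk)
        self._fit_decay(t, f, ipk, pooled=tc.replicates)
        self.persistence_ = (
            "transient"
            if (not self.censored_ and self.t_half_decay_ < self.window_end / 2)
            else "sustained"
        )
        self.summary_ = KineticsSummary(
            construct_id=tc.construct_id,
            rise_rate=self.rise_rate_,
            rise_rate_se=self.rise_rate_se_,
            t_half_decay=self.t_half_decay_,
            censored=self.censored_,
            peak_time=self.peak_time_,
            persistence=self.persistence_,
        )
        return self

    def _fit_rise(self, t, f, ipk):
        if ipk == 0:
            if np.allclose(f, f[0]):  # flat series: no rise, slope is zero
                self.rise_rate_ = 0.0
                self.rise_rate_se_ = 0.0
                return
            raise NoRiseError("series peaks at the first time point")
        tr, fr = t[: ipk + 1], f[: ipk + 1]
        if len(tr) < 3:
            raise InsufficientDataError(
                "rise fit needs >= 3 points at or before the peak"
            )
        res = stats.linregress(tr, fr)
        self.rise_rate_ = float(res.slope)
        self.rise_rate_se_ = float(res.stderr)

    def _fit_decay(self, t, f, ipk, pooled=None):
        # pool post-peak points across replicates; peak amplitude is anchored
        td, fd = [], []
        for rep_t, rep_f in (pooled or {"1": (t, f)}).values():
            rep_t = np.asarray(rep_t, float)
            rep_f = np.asarray(rep_f, float)
            after = rep_t > self.peak_time_
            td.append(rep_t[after])
            fd.append(rep_f[after])
        td = np.concatenate(td)
        fd = np.concatenate(fd)
        if len(td) < 3:
            raise InsufficientDataError("decay fit needs >= 3 post-peak points")
        peak = self.peak_value_
        tpk = self.peak_time_

        def model(x, kd):
            return peak * np.exp(-kd * (x - tpk))

        try:
            popt, pcov = curve_fit(
                model, td, fd, p0=[0.05], bounds=(0.0, np.inf), maxfev=20000
            )
        except RuntimeError as exc:  # pragma: no cover
            raise FitError(f"decay fit did not converge: {exc}") from exc
        kd = float(popt[0])
        kd_se = float(np.sqrt(max(pcov[0, 0], 0.0)))
        self.decay_rate_ = kd

        # one-sided test that kd > 0 against its standard error
        dof = max(len(td) - 1, 1)
        significant = kd_se > 0 and stats.t.sf(kd / kd_se, dof) < self.alpha
        t_half = np.log(2.0) / kd if kd > 0 else np.inf
        reaches_half = tpk + t_half <= self.window_end
        if kd <= 0 or not significant or not reaches_half:
            self.censored_ = True
            self.t_half_decay_ = float(self.window_end)
        else:
            self.censored_ = False
            self.t_half_decay_ = float(t_half)


def fit_rise_rate(tc: TimeCourse) -> float:
    """0-to-peak linear slope of the max-normalised curve (arb. units/min)."""
    return KineticsFitter().fit(tc).rise_rate_


def fit_decay_halflife(
    tc: TimeCourse, window_end: float = DEFAULT_WINDOW_MIN
) -> tuple[float, bool]:
    """Decay half-life with censoring: ``(t_half, censored)``.

    A censored result means the half-life exceeds the observation window and
    the returned value is the window end (a lower bound, "> window_end").
    """
    fitter = KineticsFitter(window_end=window_end).fit(tc)
    return fitter.t_half_decay_, fitter.censored_


def classify_persistence(
    summary: KineticsSummary, window_end: float = DEFAULT_WINDOW_MIN
) -> str:
    """Transient if the uncensored half-life is below window_end/2, else sustained.

    The boundary value (t_half exactly window_end/2) classifies as sustained.
    """
    if summary.censored or summary.t_half_decay >= window_end / 2:
        return "sustained"
    return "transient"


def summarize_timecourse(
    tc: TimeCourse, window_end: float = DEFAULT_WINDOW_MIN, smooth_peak: bool = False
) -> KineticsSummary:
    """Full kinetics summary (rise, decay, censoring, persistence class)."""
    return KineticsFitter(window_end=window_end, smooth_peak=smooth_peak).fit(tc).summary_
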