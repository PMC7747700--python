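"""Binding and stability assay models.

Two fitted models:

* Competition fluorescence polarization.  The displacement curve is a
  fixed-Hill-slope logistic in log10 competitor concentration,

      Y = Bottom + (Top - Bottom) / (1 + 10^(X - logEC50)),

  and the inhibition constant corrects the midpoint for probe occupancy,

      logEC50 = logKi + log10(1 + [probe]/Kd_probe),

  with probe concentration and probe Kd in the same units (nM here).  The
  probe Kd is an input, measured separately; it is never re-fit.

* Differential scanning fluorimetry.  Melt curves are fitted with the
  Boltzmann sigmoid F(T) = f_min + (f_max - f_min)/(1 + exp((Tm - T)/slope)),
  after optional blank subtraction and truncation at the post-transition
  fluorescence maximum (SYPRO curves decay once the dye-bound state
  aggregates, so only the rising transition is informative).

Paired two-tailed t-tests compare log Ki (or Tm) values between matched
experiments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .errors import FitError, SpecificationError

__all__ = [
    "CompetitionDataset",
    "LogisticFit",
    "KiResult",
    "MeltCurve",
    "TmResult",
    "PairedTestResult",
    "logistic_competition",
    "fit_logistic_competition",
    "logec50_to_logki",
    "logki_to_logec50",
    "fit_ki",
    "compare_logki",
    "boltzmann",
    "fit_boltzmann",
    "delta_tm",
]


# ---------------------------------------------------------------------------
# Competition FP


@dataclass
class CompetitionDataset:
    """Dose-response table: X = log10 molar competitor, Y = mP replicates."""

    X: np.ndarray  # (n_points,)
    Y: np.ndarray  # (n_points, n_replicates)
    probe_conc: float  # nM
    probe_Kd: float  # nM
    label: str = ""

    def __post_init__(self):
        self.X = np.asarray(self.X, float)
        self.Y = np.atleast_2d(np.asarray(self.Y, float))
        if self.Y.shape[0] != self.X.shape[0]:
            self.Y = self.Y.T
        if self.Y.shape[0] != self.X.shape[0]:
            raise SpecificationError("X and Y lengths differ")
        if len(np.unique(self.X)) < 4:
            raise SpecificationError("need >= 4 distinct concentrations")
        if self.probe_conc <= 0 or self.probe_Kd <= 0:
            raise SpecificationError("probe concentration and Kd must be positive")


@dataclass
class LogisticFit:
    top: float
    bottom: float
    logec50: float
    residual_se: float
    converged: bool
    logec50_se: float = float("nan")


@dataclass
class KiResult:
    logki: float
    ci95: tuple[float, float]
    per_replicate_logki: list[float] = field(default_factory=list)

    @property
    def ki(self) -> float:
        return 10.0**self.logki


def logistic_competition(x, top, bottom, logec50, hill=1.0):
    """Displacement logistic, decreasing in x for top > bottom."""
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (x - logec50)))


def logec50_to_logki(logec50: float, probe_conc: float, probe_kd: float) -> float:
    """Exact inversion of the probe-occupancy correction (units: nM/nM)."""
    if probe_conc < 0 or probe_kd <= 0:
        raise SpecificationError("probe values must be positive")
    return float(logec50 - np.log10(1.0 + probe_conc / probe_kd))


def logki_to_logec50(logki: float, probe_conc: float, probe_kd: float) -> float:
    return float(logki + np.log10(1.0 + probe_conc / probe_kd))


def _fit_once(x, y, p0, variable_slope):
    if variable_slope:
        fun = lambda x, t, b, e, h: logistic_competition(x, t, b, e, h)
        p0 = (*p0, 1.0)
    else:
        fun = logistic_competition
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", optimize.OptimizeWarning)
        popt, pcov = optimize.curve_fit(fun, x, y, p0=p0, maxfev=20000)
    resid = y - fun(x, *popt)
    return popt, pcov, float(np.sum(resid**2))


def fit_logistic_competition(
    ds: CompetitionDataset, variable_slope: bool = False
) -> LogisticFit:
    """Least-squares fit of the displacement logistic on all replicate points.

    Multi-start over candidate midpoints across the dose range; the fit is
    flagged unconverged (never silently) if every start fails.
    """
    x = np.repeat(ds.X, ds.Y.shape[1])
    y = ds.Y.ravel()
    yrange = y.max() - y.min()
    if yrange <= 1e-12 or yrange < 0.02 * max(abs(y).max(), 1.0):
        raise FitError("flat data: no displacement transition to fit")
    starts = np.linspace(ds.X.min(), ds.X.max(), 7)
    best = None
    for e0 in starts:
        try:
            popt, pcov, sse = _fit_once(x, y, (y.max(), y.min(), e0), variable_slope)
        except (RuntimeError, ValueError):
            continue
        if best is None or sse < best[2]:
            best = (popt, pcov, sse)
    if best is None:
        raise FitError("logistic fit failed to converge from any start")
    popt, pcov, sse = best
    dof = max(len(y) - len(popt), 1)
    se = float(np.sqrt(sse / dof))
    logec50_se = float(np.sqrt(pcov[2, 2])) if np.isfinite(pcov[2, 2]) else float("nan")
    top, bottom, logec50 = popt[0], popt[1], popt[2]
    if top <= bottom:
        raise FitError("fit inverted: Top <= Bottom, not a displacement curve")
    return LogisticFit(
        top=float(top),
        bottom=float(bottom),
        logec50=float(logec50),
        residual_se=se,
        converged=True,
        logec50_se=logec50_se,
    )


def fit_ki(ds: CompetitionDataset, variable_slope: bool = False) -> KiResult:
    """Fit the competition curve and convert the midpoint to log Ki.

    The pooled fit gives the headline logKi and its normal-theory 95% CI;
    each replicate column is additionally fitted on its own to provide the
    per-experiment logKi sample used by paired tests.
    """
    fit = fit_logistic_competition(ds, variable_slope=variable_slope)
    logki = logec50_to_logki(fit.logec50, ds.probe_conc, ds.probe_Kd)
    half = 1.96 * fit.logec50_se if np.isfinite(fit.logec50_se) else float("nan")
    per_rep = []
    for r in range(ds.Y.shape[1]):
        sub = CompetitionDataset(
            X=ds.X, Y=ds.Y[:, [r]], probe_conc=ds.probe_conc, probe_Kd=ds.probe_Kd
        )
        try:
            f = fit_logistic_competition(sub, variable_slope=variable_slope)
            per_rep.append(logec50_to_logki(f.logec50, ds.probe_conc, ds.probe_Kd))
        except FitError:
            per_rep.append(float("nan"))
    return KiResult(
        logki=logki, ci95=(logki - half, logki + half), per_replicate_logki=per_rep
    )


@dataclass
class PairedTestResult:
    t: float
    p: float
    n_pairs: int
    degenerate: bool = False


def compare_logki(
    group_a: Sequence[float], group_b: Sequence[float]
) -> PairedTestResult:
    """Two-tailed paired t-test on matched per-experiment logKi values."""
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.shape != b.shape:
        raise SpecificationError("paired groups must have equal length")
    if len(a) < 2:
        raise SpecificationError("need >= 2 paired experiments")
    diff = a - b
    if np.allclose(diff, 0.0):
        return PairedTestResult(t=0.0, p=1.0, n_pairs=len(a))
    if np.var(diff, ddof=1) <= 1e-30:
        # constant non-zero shift: t is infinite, flag instead of fabricating p
        return PairedTestResult(t=float("inf"), p=0.0, n_pairs=len(a), degenerate=True)
    t, p = stats.ttest_rel(a, b)
    return PairedTestResult(t=float(t), p=float(p), n_pairs=len(a))


# ---------------------------------------------------------------------------
# DSF melt fitting


@dataclass
class MeltCurve:
    """One melt trace; temperatures strictly increasing, F same length."""

    T: np.ndarray  # degC
    F: np.ndarray
    background_subtracted: bool = False

    def __post_init__(self):
        self.T = np.asarray(self.T, float)
        self.F = np.asarray(self.F, float)
        if self.T.shape != self.F.shape:
            raise SpecificationError("T and F lengths differ")
        if np.any(np.diff(self.T) <= 0):
            raise SpecificationError("temperatures must be strictly increasing")

    def subtract_blank(self, blank: np.ndarray) -> "MeltCurve":
        blank = np.asarray(blank, float)
        if blank.shape != self.F.shape:
            raise SpecificationError("blank length differs from curve")
        return MeltCurve(T=self.T, F=self.F - blank, background_subtracted=True)


@dataclass
class TmResult:
    tm: float
    slope: float
    f_min: float
    f_max: float
    tm_se: float
    converged: bool


def boltzmann(t, tm, slope, f_min, f_max):
    return f_min + (f_max - f_min) / (1.0 + np.exp((tm - t) / slope))


def fit_boltzmann(curve: MeltCurve, truncate_at_peak: bool = True) -> TmResult:
    """Fit the Boltzmann sigmoid; Tm is the inflection temperature.

    With ``truncate_at_peak`` the fit window runs from the start of the
    trace to the global fluorescence maximum, discarding the post-peak
    decay.  Flat or monotone-decreasing traces raise a fit error.
    """
    T, F = curve.T, curve.F
    if truncate_at_peak:
        stop = int(np.argmax(F)) + 1
        if stop >= 4:
            T, F = T[:stop], F[:stop]
    rng = F.max() - F.min()
    if rng <= 1e-12:
        raise FitError("flat melt curve")
    if F[-1] <= F[0]:
        raise FitError("no rising transition: curve is non-increasing")
    # midpoint start: temperature where F crosses half-range
    half = F.min() + rng / 2.0
    tm0 = float(T[np.argmin(np.abs(F - half))])
    best = None
    for slope0 in (0.5, 1.5, 4.0):
        try:
            popt, pcov = optimize.curve_fit(
                boltzmann, T, F, p0=(tm0, slope0, F.min(), F.max()), maxfev=20000
            )
        except RuntimeError:
            continue
        sse = float(np.sum((F - boltzmann(T, *popt)) ** 2))
        if best is None or sse < best[2]:
            best = (popt, pcov, sse)
    if best is None:
        raise FitError("Boltzmann fit failed to converge")
    popt, pcov, _ = best
    tm, slope, fmin, fmax = popt
    if fmax <= fmin:
        # exploit the sign degeneracy F(tm,-s,fmax,fmin) = F(tm,s,fmin,fmax)
        fmin, fmax, slope = fmax, fmin, -slope
    if slope <= 0:
        raise FitError("fitted transition is not rising")
    tm_se = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else float("nan")
    return TmResult(
        tm=float(tm), slope=float(slope), f_min=float(fmin), f_max=float(fmax),
        tm_se=tm_se, converged=True,
    )


def delta_tm(sample: TmResult, reference: TmResult) -> float:
    """Tm shift of ``sample`` relative to ``reference`` (degC)."""
    if not (sample.converged and reference.converged):
        raise FitError("cannot take a Tm difference of unconverged fits")
    return float(sample.tm - reference.tm)
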