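"""Empirical treatment of release / ATPase time courses.

Mirrors the bench workflow: gel band intensities are converted to a released
fraction, the fraction-vs-time curve is fitted to an exponential-rise form
(no lag) and to a four-parameter sigmoid (lag-capable), and a small-sample
AIC comparison decides whether the curve carries a genuine lag phase.  The
lag itself is read off the sigmoid by the standard growth-curve convention:
the tangent at the inflection point extended down to the baseline.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.optimize import OptimizeWarning, curve_fit

from .kinetic_model import TimeCourse

__all__ = [
    "UndefinedFractionError",
    "FitError",
    "ReleaseMeasurement",
    "FitResult",
    "release_fraction",
    "timecourse_from_measurements",
    "fit_exponential_rise",
    "fit_sigmoid",
    "select_model_and_lag",
    "sigmoid_lag",
]

logger = logging.getLogger(__name__)

#: AICc margin by which the sigmoid must beat the best exponential form for a
#: lag to be declared.  The bench call was made by eye; Delta-AIC >= 2 is the
#: conventional "positive support" threshold.
LAG_AIC_MARGIN = 2.0


class UndefinedFractionError(ValueError):
    """Both band intensities are zero; the released fraction is undefined."""


class FitError(RuntimeError):
    """Nonlinear fit failed to converge from every start point."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass(frozen=True)
class ReleaseMeasurement:
    """One gel time point: half the supernatant (S) run next to the rest (S+P).

    ``s_half`` is the band intensity of half of the supernatant; ``s_plus_p``
    is the intensity of the remaining sample, i.e. the other supernatant half
    plus the pellet.  Intensities are arbitrary densitometry units.
    """

    time: float
    s_half: float
    s_plus_p: float

    def __post_init__(self) -> None:
        if self.s_half < 0 or self.s_plus_p < 0:
            raise ValueError("band intensities must be non-negative")


def release_fraction(m: ReleaseMeasurement,
                     denominator: Literal["s_plus_total", "twice_total"] = "s_plus_total") -> float:
    """Released fraction from the two gel bands: 2S / (S + (S+P)).

    Because the supernatant was split in half, doubling S recovers the full
    released signal while S + (S+P) is the total RNA.  The printed formula is
    typographically ambiguous; ``denominator="twice_total"`` selects the
    alternative reading 2S / (2*(S+P)).  Values outside [0, 1] (densitometry
    noise) are clipped and the clipping is logged.
    """
    if m.s_half == 0 and m.s_plus_p == 0:
        raise UndefinedFractionError("both band intensities are zero")
    if denominator == "s_plus_total":
        denom = m.s_half + m.s_plus_p
    elif denominator == "twice_total":
        denom = 2.0 * m.s_plus_p
    else:
        raise ValueError(f"unknown denominator rule {denominator!r}")
    if denom <= 0:
        raise UndefinedFractionError("denominator is zero")
    frac = 2.0 * m.s_half / denom
    if frac < 0.0 or frac > 1.0:
        logger.warning("release fraction %.4f at t=%s clipped to [0, 1]", frac, m.time)
        frac = min(max(frac, 0.0), 1.0)
    return frac


def timecourse_from_measurements(measurements: Iterable[ReleaseMeasurement],
                                 **kwargs) -> TimeCourse:
    """Convert a series of gel measurements into a release TimeCourse."""
    ms = sorted(measurements, key=lambda m: m.time)
    times = np.array([m.time for m in ms])
    values = np.array([release_fraction(m, **kwargs) for m in ms])
    return TimeCourse(times, values, kind="release")


@dataclass(frozen=True)
class FitResult:
    """Fitted empirical-curve parameters.

    ``form`` names the model: ``exp_rise`` y = a(1-exp(-b x)),
    ``exp_rise_offset`` y = y0 + a(1-exp(-b x)), or ``sigmoid``
    y = y0 + a / (1 + (x/x0)^b).  ``b`` is a rate (1/s) for the exponential
    forms and the dimensionless slope factor for the sigmoid (negative for
    rising curves under this parameterization).  ``aic`` is the
    small-sample-corrected AIC; ``lag`` is the tangent-intercept lag in
    seconds (0 unless a sigmoid lag was detected).
    """

    form: Literal["exp_rise", "exp_rise_offset", "sigmoid"]
    a: float
    b: float
    y0: float = 0.0
    x0: float | None = None
    rss: float = math.nan
    aic: float = math.nan
    lag: float = 0.0
    lag_detected: bool = False
    n_points: int = 0


# ---------------------------------------------------------------------------
# Model functions
# ---------------------------------------------------------------------------

def _exp_rise(x, a, b):
    return a * (1.0 - np.exp(-b * x))


def _exp_rise_offset(x, y0, a, b):
    return y0 + a * (1.0 - np.exp(-b * x))


def _sigmoid(x, y0, a, x0, b):
    # y = y0 + a / (1 + (x/x0)^b); at x=0 the b<0 limit is y0 and the b>0
    # limit is y0 + a -- evaluate the limit instead of 0**negative.
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    zero = x == 0.0
    with np.errstate(over="ignore"):
        out[~zero] = y0 + a / (1.0 + (x[~zero] / x0) ** b)
    out[zero] = y0 if b < 0 else y0 + a
    return out


def _aicc(rss: float, n: int, k_params: int) -> float:
    """Small-sample AIC for a Gaussian least-squares fit; k counts sigma too."""
    k = k_params + 1
    if n - k - 1 <= 0:
        return math.inf
    rss = max(rss, 1e-300)
    return n * math.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def _multi_start_fit(model, x, y, starts, bounds, n_params) -> tuple[np.ndarray, float, list]:
    best, best_rss, failures = None, math.inf, []
    for p0 in starts:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", OptimizeWarning)
                popt, _ = curve_fit(model, x, y, p0=p0, bounds=bounds,
                                    maxfev=20_000)
            rss = float(np.sum((model(x, *popt) - y) ** 2))
            if np.isfinite(rss) and rss < best_rss:
                best, best_rss = popt, rss
        except (RuntimeError, ValueError) as exc:
            failures.append((tuple(p0), str(exc)))
    if best is None:
        raise FitError(f"{model.__name__} failed from all {len(starts)} starts",
                       diagnostics={"failures": failures, "n": len(x)})
    return best, best_rss, failures


def _rate_guesses(t, y) -> list[float]:
    """Rate starts from the time at which the curve reaches half its span."""
    span = float(np.max(y) - np.min(y))
    if span <= 0:
        return [0.1, 1.0]
    half = np.min(y) + 0.5 * span
    above = np.nonzero(y >= half)[0]
    t_half = float(t[above[0]]) if above.size else float(t[-1])
    t_half = max(t_half, float(t[-1]) / len(t), 1e-9)
    b0 = math.log(2.0) / t_half
    return [b0 / 3.0, b0, 3.0 * b0]


def fit_exponential_rise(tc: TimeCourse, with_offset: bool = False) -> FitResult:
    """Least-squares fit of the exponential-rise release model.

    Fits y = a(1-exp(-b x)) or, ``with_offset``, y = y0 + a(1-exp(-b x)),
    using five deterministic data-derived start points.  Exponential rises
    have no lag phase by construction, so ``lag`` is 0.
    """
    t, y = tc.times, tc.values
    n_params = 3 if with_offset else 2
    if len(tc) < n_params + 2:
        raise ValueError(f"need >= {n_params + 2} points for the "
                         f"{n_params}-parameter exponential fit")
    a0 = max(float(np.max(y) - (np.min(y) if with_offset else 0.0)), 1e-6)
    rates = _rate_guesses(t, y)
    if with_offset:
        y00 = float(np.min(y))
        starts = [(y00, a0, b) for b in rates] + [(0.0, a0, rates[1]),
                                                  (y00, 1.2 * a0, rates[1])]
        bounds = ([-1.0, 1e-12, 1e-12], [2.0, 2.0, np.inf])
        model = _exp_rise_offset
    else:
        starts = [(a0, b) for b in rates] + [(1.2 * a0, rates[1]),
                                             (0.5 * a0, rates[1])]
        bounds = ([1e-12, 1e-12], [2.0, np.inf])
        model = _exp_rise
    popt, rss, _ = _multi_start_fit(model, t, y, starts, bounds, n_params)
    aic = _aicc(rss, len(tc), n_params)
    if with_offset:
        y0, a, b = popt
    else:
        (a, b), y0 = popt, 0.0
    form = "exp_rise_offset" if with_offset else "exp_rise"
    return FitResult(form=form, a=float(a), b=float(b), y0=float(y0),
                     rss=rss, aic=aic, lag=0.0, n_points=len(tc))


def fit_sigmoid(tc: TimeCourse) -> FitResult:
    """Least-squares fit of the four-parameter sigmoid y = y0 + a/(1+(x/x0)^b).

    Under this parameterization a *rising* curve has b < 0 (the curve then
    runs from y0 at x=0 up to y0 + a); b > 0 describes a decay.  Both signs
    are permitted; five deterministic starts cover rising shapes of varying
    steepness.
    """
    t, y = tc.times, tc.values
    if len(tc) < 6:
        raise ValueError("need >= 6 points for the 4-parameter sigmoid fit")
    y00 = float(np.min(y))
    a0 = max(float(np.max(y) - y00), 1e-6)
    span = float(np.max(y) - y00)
    half = y00 + 0.5 * span
    above = np.nonzero(y >= half)[0]
    x00 = float(t[above[0]]) if above.size and t[above[0]] > 0 else float(np.median(t[t > 0]))
    starts = [(y00, a0, x00, b0) for b0 in (-2.0, -4.0, -8.0)]
    starts += [(y00, a0, 0.6 * x00, -4.0), (y00, a0, 1.5 * x00, -4.0)]
    bounds = ([-1.0, 1e-12, 1e-9, -np.inf], [2.0, 2.0, np.inf, np.inf])
    popt, rss, _ = _multi_start_fit(_sigmoid, t, y, starts, bounds, 4)
    y0, a, x0, b = popt
    return FitResult(form="sigmoid", a=float(a), b=float(b), y0=float(y0),
                     x0=float(x0), rss=rss, aic=_aicc(rss, len(tc), 4),
                     n_points=len(tc))


def sigmoid_lag(fit: FitResult) -> float:
    """Tangent-intercept lag of a fitted sigmoid, clamped to >= 0.

    The tangent at the inflection point (x0, y0 + a/2) has slope
    -a*b/(4*x0); intersecting it with the baseline y = y0 gives
    lag = x0 * (1 + 2/b).  For a rising curve (b < 0) this sits left of x0.
    """
    if fit.form != "sigmoid" or fit.x0 is None:
        return 0.0
    if fit.b == 0:
        return 0.0
    return max(0.0, fit.x0 * (1.0 + 2.0 / fit.b))


def select_model_and_lag(tc: TimeCourse) -> FitResult:
    """Fit all candidate forms, select by small-sample AIC, extract the lag.

    Candidates: 2-parameter exponential rise, 3-parameter exponential rise
    with offset, 4-parameter sigmoid.  Models within ``LAG_AIC_MARGIN`` AICc
    units of the minimum are treated as statistically indistinguishable (the
    usual Delta-AIC < 2 convention) and the tie goes to the model with the
    fewest parameters; the sigmoid is therefore selected -- and a lag
    declared -- only when it beats every exponential form by at least that
    margin.  The returned ``lag`` is the tangent-intercept lag for a
    selected sigmoid and 0 otherwise: exponential rises have no lag phase.
    """
    candidates: list[tuple[FitResult, int]] = []
    errors: list[str] = []
    for fitter, nparams in ((lambda: fit_exponential_rise(tc, False), 2),
                            (lambda: fit_exponential_rise(tc, True), 3),
                            (lambda: fit_sigmoid(tc), 4)):
        try:
            candidates.append((fitter(), nparams))
        except (FitError, ValueError) as exc:
            errors.append(str(exc))
    if not candidates:
        raise FitError("all candidate fits failed", {"errors": errors})
    best_aic = min(f.aic for f, _ in candidates)
    plausible = [(f, n) for f, n in candidates if f.aic <= best_aic + LAG_AIC_MARGIN]
    plausible.sort(key=lambda c: (c[1], c[0].aic))
    best = plausible[0][0]
    if best.form == "sigmoid":
        lag = sigmoid_lag(best)
        return FitResult(**{**best.__dict__, "lag": lag,
                            "lag_detected": lag > 0.0})
    return best
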