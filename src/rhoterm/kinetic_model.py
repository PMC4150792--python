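"""Mechanistic model of Rho recruitment, activation and translocation.

The termination factor Rho loads onto a C-rich *rut* segment of the nascent
mRNA through its primary binding site, then undergoes a slow conformational
isomerization from the open-hexamer (OH) to the closed-hexamer (CH) form.
Only the closed, translocase-competent hexamer hydrolyses ATP, translocates
5'->3' along the mRNA and dislodges the elongation complex (EC).

The scheme is formalized as a linear continuous-time Markov chain

    Free  <-- k_off --  Bound(OH)
    Free  -- k_on  -->  Bound(OH)  -- k_iso -->  Committed(CH)
    Committed -- k_step --> ... (n_steps translocation steps) ... -- k_dislodge --> Released

with a single reversible stage (binding) and irreversibility from the
committed state onward.  NusG acts purely as a multiplier on the
isomerization rate (``nusg_factor``); ATP hydrolysis runs at a constant
``k_cat`` per committed Rho, reflecting assays on stalled (road-blocked)
complexes where translocation stoichiometry is not resolved.

No absolute rate constants are known for this system; the module defaults in
:data:`DEFAULT_PARAMS` are illustrative and every quantitative statement made
by the package is conditional on the caller's parameter choices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "InvalidParameterError",
    "NoCatchupError",
    "RateParameters",
    "ChainSpec",
    "TimeCourse",
    "TerminationPrediction",
    "DEFAULT_PARAMS",
    "mean_commitment_time",
    "commitment_cdf",
    "simulate_release_analytic",
    "simulate_release_gillespie",
    "sample_release_times",
    "sample_commitment_times",
    "simulate_atp_trace",
    "predict_termination_zone",
    "mean_release_time",
]

# Master-equation integration tolerance (relative); see docs/methods.md.
_ODE_RTOL = 1e-8
_ODE_ATOL = 1e-12


class InvalidParameterError(ValueError):
    """A rate constant or chain parameter violates its domain."""


class NoCatchupError(ValueError):
    """Rho cannot catch the polymerase (rho_speed <= rnap_speed)."""


@dataclass(frozen=True)
class RateParameters:
    """Rate constants of the recruitment/translocation scheme.

    Parameters
    ----------
    k_on : float
        Pseudo-first-order Rho binding rate at the rut site (1/s).
    k_off : float
        Unbinding rate of the open-hexamer complex (1/s); may be zero.
    k_iso : float
        OH -> CH isomerization rate, the k2 of the scheme (1/s).
    k_step : float
        Translocation stepping rate per nucleotide stage (1/s).
    k_dislodge : float
        EC dissociation rate once Rho has reached the polymerase (1/s).
    nusg_factor : float
        Multiplier applied to ``k_iso`` when NusG is present (> 0).
    k_cat : float
        ATP-hydrolysis rate per committed Rho (ATP/s, or pool-fraction/s
        when ``atp_pool`` is the normalized pool of 1.0).
    atp_pool : float
        Total ATP available (molecules, or 1.0 for a normalized pool).
    """

    k_on: float
    k_off: float
    k_iso: float
    k_step: float
    k_dislodge: float
    nusg_factor: float = 1.0
    k_cat: float = 0.01
    atp_pool: float = 1.0

    def __post_init__(self) -> None:
        for name in ("k_on", "k_iso", "k_step", "k_dislodge", "nusg_factor",
                     "k_cat", "atp_pool"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise InvalidParameterError(f"{name} must be finite and > 0, got {v!r}")
        if not (np.isfinite(self.k_off) and self.k_off >= 0):
            raise InvalidParameterError(f"k_off must be finite and >= 0, got {self.k_off!r}")

    def effective_k_iso(self, nusg: bool) -> float:
        """Isomerization rate, accelerated by NusG when the flag is set."""
        return self.k_iso * self.nusg_factor if nusg else self.k_iso

    def with_(self, **kwargs) -> "RateParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


#: Illustrative defaults -- the study system has no measured rate constants.
#: Order-of-magnitude choices: ~50 nM Rho at ~1e6 /M/s gives k_on ~ 0.05/s,
#: stable rut engagement k_off ~ 0.01/s, translocation ~60 nt/s, dislodging in
#: sub-second to seconds once Rho reaches the EC.
DEFAULT_PARAMS = RateParameters(k_on=0.05, k_off=0.01, k_iso=0.5, k_step=60.0,
                                k_dislodge=2.0, nusg_factor=100.0,
                                k_cat=0.01, atp_pool=1.0)


@dataclass(frozen=True)
class ChainSpec:
    """Geometry of the recruitment/translocation chain.

    ``n_steps`` is the number of nucleotide stages between the rut 3' end and
    the stalled elongation complex.  ``n_iso_stages`` resolves the OH -> CH
    isomerization into that many sequential sub-stages, each at rate
    ``n_iso_stages * k_eff`` so the mean isomerization time stays 1/k_eff:
    1 recovers a single exponential transition, larger values give the
    low-variance (Erlang) isomerization that large concerted conformational
    changes imply -- and that a lag phase in the release kinetics requires.
    Unbinding competes only with the first sub-stage; the chain is
    irreversible once isomerization has started, and strictly so from the
    committed (CH) state onward.
    """

    n_steps: int = 0
    n_iso_stages: int = 1

    def __post_init__(self) -> None:
        if not (isinstance(self.n_steps, (int, np.integer)) and self.n_steps >= 0):
            raise InvalidParameterError(f"n_steps must be a non-negative integer, got {self.n_steps!r}")
        if not (isinstance(self.n_iso_stages, (int, np.integer)) and self.n_iso_stages >= 1):
            raise InvalidParameterError(f"n_iso_stages must be a positive integer, got {self.n_iso_stages!r}")

    @property
    def state_labels(self) -> list[str]:
        return (["Free", "Bound(OH)"]
                + [f"Iso_{i}" for i in range(1, self.n_iso_stages)]
                + ["Committed(CH)"]
                + [f"Step_{i}" for i in range(1, self.n_steps + 1)]
                + ["Released"])


@dataclass(frozen=True)
class TimeCourse:
    """A sampled trajectory of a dimensionless fraction over time.

    ``kind`` is ``"release"`` (fraction of RNA released) or ``"atp"``
    (fraction of the ATP pool hydrolysed).
    """

    times: np.ndarray
    values: np.ndarray
    kind: str = "release"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or t.shape != v.shape:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.times.size


def _check_times(times: Sequence[float]) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("time grid must be a non-empty 1-D array")
    if np.any(t < 0):
        raise ValueError("time grid must be non-negative")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time grid must be strictly increasing")
    return t


# ---------------------------------------------------------------------------
# Commitment: Free <-> Bound -> Committed
# ---------------------------------------------------------------------------

def mean_commitment_time(params: RateParameters, nusg: bool = False,
                         n_iso_stages: int = 1) -> float:
    """Mean first-passage time from Free to the committed (CH) state.

    For the reversible-binding-then-isomerization chain the closed form is

        T = (k_off + k_eff) / (k_on * k_eff) + 1 / k_eff,

    with ``k_eff = k_iso * nusg_factor`` when NusG is present.  T decreases
    monotonically in both ``k_iso`` and ``nusg_factor``: a faster OH->CH
    transition wins the race against unbinding more often and wastes fewer
    binding attempts.  With isomerization resolved into n sub-stages
    (rate n*k_eff each, unbinding competing with the first) the mean becomes
    (k_off + n*k_eff)/(k_on*n*k_eff) + 1/k_eff, which reduces to the
    expression above at n = 1.
    """
    ke = params.effective_k_iso(nusg)
    lam = n_iso_stages * ke
    return (params.k_off + lam) / (params.k_on * lam) + 1.0 / ke


def _chain_rates(params: RateParameters, chain: ChainSpec, nusg: bool) -> np.ndarray:
    """Exit rates of the irreversible stages after commitment, ending in release."""
    return np.array([params.k_step] * chain.n_steps + [params.k_dislodge])


def _generator(params: RateParameters, chain: ChainSpec, nusg: bool) -> np.ndarray:
    """Full generator matrix.

    State order: Free, Bound, Iso_1..Iso_{m-1}, Committed, Step_1..Step_n,
    Released (m = n_iso_stages; for m = 1 the Bound -> Committed transition
    is direct).
    """
    ke = params.effective_k_iso(nusg)
    m = chain.n_iso_stages
    lam = m * ke
    irrev = list(np.full(m - 1, lam)) + list(_chain_rates(params, chain, nusg))
    n = 3 + len(irrev)
    Q = np.zeros((n, n))
    Q[0, 0], Q[0, 1] = -params.k_on, params.k_on
    Q[1, 0], Q[1, 2] = params.k_off, lam
    Q[1, 1] = -(params.k_off + lam)
    for i, r in enumerate(irrev):
        Q[2 + i, 2 + i] = -r
        Q[2 + i, 3 + i] = r
    return Q


def _commitment_generator(params: RateParameters, chain_or_stages, nusg: bool) -> np.ndarray:
    """Generator of the commitment sub-chain with Committed absorbing."""
    m = chain_or_stages.n_iso_stages if isinstance(chain_or_stages, ChainSpec) \
        else int(chain_or_stages)
    ke = params.effective_k_iso(nusg)
    lam = m * ke
    n = m + 2  # Free, Bound, Iso_1..Iso_{m-1}, Committed
    Q = np.zeros((n, n))
    Q[0, 0], Q[0, 1] = -params.k_on, params.k_on
    Q[1, 0], Q[1, 2] = params.k_off, lam
    Q[1, 1] = -(params.k_off + lam)
    for i in range(m - 1):
        Q[2 + i, 2 + i] = -lam
        Q[2 + i, 3 + i] = lam
    return Q


def _absorption_probability(Q: np.ndarray, times: np.ndarray,
                            absorbing: int) -> np.ndarray:
    """P(absorbed by t) for a chain started in state 0, via the master equation."""
    n = Q.shape[0]
    p0 = np.zeros(n)
    p0[0] = 1.0
    if times[-1] == 0.0:
        return np.zeros_like(times)
    QT = Q.T

    def rhs(t, p):
        return QT @ p

    sol = solve_ivp(rhs, (0.0, float(times[-1])), p0, t_eval=times,
                    method="LSODA", jac=lambda t, p: QT,
                    rtol=_ODE_RTOL, atol=_ODE_ATOL)
    if not sol.success:  # pragma: no cover - LSODA is robust for linear systems
        raise RuntimeError(f"master-equation integration failed: {sol.message}")
    return np.clip(sol.y[absorbing], 0.0, 1.0)


def commitment_cdf(params: RateParameters, times: Sequence[float],
                   nusg: bool = False, n_iso_stages: int = 1) -> TimeCourse:
    """P(Rho committed by t): first-passage CDF of the binding/isomerization chain."""
    t = _check_times(times)
    Q = _commitment_generator(params, n_iso_stages, nusg)
    return TimeCourse(t, _absorption_probability(Q, t, Q.shape[0] - 1),
                      kind="release")


# ---------------------------------------------------------------------------
# Release kinetics
# ---------------------------------------------------------------------------

def simulate_release_analytic(params: RateParameters, chain: ChainSpec,
                              times: Sequence[float],
                              nusg: bool = False) -> TimeCourse:
    """P(RNA released by t) from the master equation of the full chain.

    The fraction starts at 0, is monotone non-decreasing and tends to 1.
    With ``k_off = 0`` the release time is hypoexponential with mean
    ``sum(1/rate)`` over all chain stages.
    """
    t = _check_times(times)
    Q = _generator(params, chain, nusg)
    return TimeCourse(t, _absorption_probability(Q, t, Q.shape[0] - 1),
                      kind="release")


def mean_release_time(params: RateParameters, chain: ChainSpec,
                      nusg: bool = False) -> float:
    """Exact mean first-passage time Free -> Released."""
    post = _chain_rates(params, chain, nusg)
    return (mean_commitment_time(params, nusg, chain.n_iso_stages)
            + float(np.sum(1.0 / post)))


def sample_commitment_times(params: RateParameters, n_traj: int, seed,
                            nusg: bool = False,
                            n_iso_stages: int = 1) -> np.ndarray:
    """Draw exact first-passage times Free -> Committed.

    Exploits the renewal structure of the chain: each binding attempt is an
    Exp(k_on) wait plus an Exp(k_off + lam) sojourn in the bound state
    (lam = n_iso_stages * k_eff, the rate of entering isomerization), and the
    attempt succeeds with probability lam / (lam + k_off).  The number of
    attempts is geometric, so the passage time is a sum of two gamma variates
    plus the Erlang of the remaining isomerization sub-stages --
    distributionally identical to trajectory-level stochastic simulation of
    the chain, but vectorized.
    """
    if n_traj < 1:
        raise ValueError("n_traj must be >= 1")
    rng = np.random.default_rng(seed)
    ke = params.effective_k_iso(nusg)
    lam = n_iso_stages * ke
    p_commit = lam / (lam + params.k_off)
    attempts = rng.geometric(p_commit, size=n_traj)
    t_free = rng.gamma(shape=attempts, scale=1.0 / params.k_on)
    t_bound = rng.gamma(shape=attempts, scale=1.0 / (params.k_off + lam))
    t = t_free + t_bound
    if n_iso_stages > 1:
        t = t + rng.gamma(shape=n_iso_stages - 1, scale=1.0 / lam, size=n_traj)
    return t


def sample_release_times(params: RateParameters, chain: ChainSpec,
                         n_traj: int, seed, nusg: bool = False) -> np.ndarray:
    """Draw exact release times for the full chain (commitment + steps + dislodge)."""
    rng = np.random.default_rng(seed)
    t = sample_commitment_times(params, n_traj, rng, nusg=nusg,
                                n_iso_stages=chain.n_iso_stages)
    if chain.n_steps > 0:
        t = t + rng.gamma(shape=chain.n_steps, scale=1.0 / params.k_step,
                          size=n_traj)
    return t + rng.exponential(scale=1.0 / params.k_dislodge, size=n_traj)


def simulate_release_gillespie(params: RateParameters, chain: ChainSpec,
                               n_traj: int, seed,
                               times: Sequence[float] | None = None,
                               nusg: bool = False) -> tuple[TimeCourse, np.ndarray]:
    """Stochastic release kinetics: empirical CDF plus the release-time sample.

    Serves as the independent stochastic oracle for
    :func:`simulate_release_analytic`; the same seed always reproduces the
    identical sample.  If ``times`` is omitted a grid spanning the sample is
    chosen.
    """
    sample = sample_release_times(params, chain, n_traj, seed, nusg=nusg)
    if times is None:
        t = np.linspace(0.0, float(np.max(sample)) * 1.05 + 1e-9, 200)[1:]
    else:
        t = _check_times(times)
    ecdf = np.searchsorted(np.sort(sample), t, side="right") / n_traj
    return TimeCourse(t, ecdf, kind="release"), sample


# ---------------------------------------------------------------------------
# ATP hydrolysis
# ---------------------------------------------------------------------------

def simulate_atp_trace(params: RateParameters, chain: ChainSpec,
                       times: Sequence[float],
                       nusg: bool = False) -> TimeCourse:
    """Fraction of the ATP pool hydrolysed by t.

    Hydrolysis starts at commitment and runs at ``k_cat`` per committed Rho:

        f(t) = min(1, (k_cat / atp_pool) * integral_0^t P(committed by s) ds).

    A slow isomerization therefore shows up as a lag in the ATPase trace, the
    signature seen on weak-recruitment terminators; NusG removes the lag by
    accelerating the isomerization.  ``chain`` is accepted for interface
    symmetry but does not influence hydrolysis (the assay geometry is a
    stalled complex, not a moving one).
    """
    t = _check_times(times)
    rate = params.k_cat / params.atp_pool
    if t[-1] == 0.0:
        return TimeCourse(t, np.zeros_like(t), kind="atp")

    # master equation of the commitment sub-chain, augmented with the running
    # integral of the committed (absorbed) probability
    Q = _commitment_generator(params, chain, nusg)
    QT = Q.T
    n = Q.shape[0]

    def rhs(time, y):
        dp = QT @ y[:n]
        return np.append(dp, y[n - 1])

    y0 = np.zeros(n + 1)
    y0[0] = 1.0
    sol = solve_ivp(rhs, (0.0, float(t[-1])), y0, t_eval=t,
                    method="LSODA", rtol=_ODE_RTOL, atol=_ODE_ATOL)
    if not sol.success:  # pragma: no cover
        raise RuntimeError(f"ATP-trace integration failed: {sol.message}")
    f = np.minimum(1.0, rate * np.clip(sol.y[n], 0.0, None))
    return TimeCourse(t, f, kind="atp")


# ---------------------------------------------------------------------------
# Termination-zone prediction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TerminationPrediction:
    """Monte-Carlo termination-distance distribution and its analytic mean.

    Distances are measured in nucleotides from the rut 3' end.
    ``mean_analytic`` uses the closed-form mean commitment time;
    ``mean_mc`` is the sample mean of ``distances``.
    """

    distances: np.ndarray
    mean_analytic: float
    mean_mc: float


def _catchup_factor(rnap_speed: float, rho_speed: float) -> float:
    if not (rnap_speed > 0 and np.isfinite(rnap_speed)):
        raise InvalidParameterError(f"rnap_speed must be > 0, got {rnap_speed!r}")
    if not (rho_speed > rnap_speed):
        raise NoCatchupError(
            f"rho_speed ({rho_speed!r}) must exceed rnap_speed ({rnap_speed!r}) "
            "for Rho to reach the elongation complex")
    return rho_speed / (rho_speed - rnap_speed)


def predict_termination_zone(params: RateParameters, rnap_speed: float,
                             rho_speed: float, start_offset: float = 0.0,
                             n_traj: int = 10_000, seed=None,
                             nusg: bool = False,
                             n_iso_stages: int = 1) -> TerminationPrediction:
    """Predict the distance from the rut 3' end to the termination point.

    The polymerase is ``start_offset`` nt past the rut 3' end when the
    commitment clock starts and elongates at ``rnap_speed``; after a random
    commitment time T, Rho translocates at ``rho_speed`` and catches the
    polymerase at

        x = (start_offset + rnap_speed * T) * rho_speed / (rho_speed - rnap_speed),

    then dislodges it after an Exp(k_dislodge) wait during which the
    polymerase keeps moving.  The mean distance decomposes into the two terms
    the terminator-strength framework is built on: the time to form a
    translocase-competent Rho at the rut site, and the time to dislodge the
    EC.  Increasing ``k_iso`` (or adding NusG) shortens the first term and
    moves termination closer to the rut site -- early termination.
    """
    factor = _catchup_factor(rnap_speed, rho_speed)
    if start_offset < 0:
        raise InvalidParameterError("start_offset must be >= 0")
    rng = np.random.default_rng(seed)
    T = sample_commitment_times(params, n_traj, rng, nusg=nusg,
                                n_iso_stages=n_iso_stages)
    tau = rng.exponential(scale=1.0 / params.k_dislodge, size=n_traj)
    distances = (start_offset + rnap_speed * T) * factor + rnap_speed * tau
    mean_analytic = ((start_offset + rnap_speed
                      * mean_commitment_time(params, nusg, n_iso_stages))
                     * factor + rnap_speed / params.k_dislodge)
    return TerminationPrediction(distances=distances,
                                 mean_analytic=float(mean_analytic),
                                 mean_mc=float(np.mean(distances)))
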