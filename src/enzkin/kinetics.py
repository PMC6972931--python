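"""Michaelis–Menten kinetics with competitive product inhibition.

The reaction scheme is the classical one for an enzyme whose product binds
free enzyme and acts as a competitive inhibitor::

    S + E <-> ES -> E + P
        E + P <-> E_inh

Under the quasi-steady-state approximation (QSSA) the rate law is

    v = kcat * E0 * S / (Km * (1 + P/Ki) + S)

with the usual Michaelis constant ``Km``, turnover number ``kcat`` and
product-inhibition constant ``Ki``.  ``Ki = None`` means "no product
inhibition" (``Ki -> inf``), in which case the P-term drops out.

For a closed assay (no product present initially, ``P = S0 - S``) the rate
law integrates in closed form.  Substituting ``P = S0 - S`` gives

    dS/dt = -Vmax * S / (alpha + beta * S)

with ``alpha = Km * (1 + S0/Ki)``, ``beta = 1 - Km/Ki`` and
``Vmax = kcat * E0``, whose implicit solution is

    alpha * ln(S0/S) + beta * (S0 - S) = Vmax * t.

Solving for S yields the Lambert-W form
``S(t) = (alpha/beta) * W0(x)`` with
``x = (beta*S0/alpha) * exp((beta*S0 - Vmax*t)/alpha)`` (the Schnell–Mendoza
solution when ``beta = 1``, i.e. no inhibition), degenerating to exact
exponential decay ``S(t) = S0 * exp(-Vmax*t/(Km+S0))`` when ``Ki = Km``
(``beta = 0``).

The module provides the rate law, the integrated law and its closed-form /
numerical inverses, an adaptive-ODE trajectory, and a full mass-action
variant used to validate the QSSA reduction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq
from scipy.special import lambertw

__all__ = [
    "KineticsError",
    "BranchDomainError",
    "SolverError",
    "KineticParameters",
    "IntegratedLawCoefficients",
    "MicroscopicConstants",
    "ReactionState",
    "MassActionTrajectory",
    "rate_qssa",
    "integrated_time",
    "closed_form_substrate",
    "substrate_timecourse",
    "simulate_progress_qssa",
    "simulate_progress_mass_action",
]


class KineticsError(ValueError):
    """Invalid kinetic parameters or out-of-domain concentrations/times."""


class BranchDomainError(KineticsError):
    """Lambert-W argument left the principal-branch domain; use the numerical path."""


class SolverError(RuntimeError):
    """The ODE integrator failed to converge; carries the solver diagnostics."""


def _require_finite_positive(name: str, value: float) -> None:
    if not np.isfinite(value) or value <= 0:
        raise KineticsError(f"{name} must be finite and > 0, got {value!r}")


@dataclass(frozen=True)
class KineticParameters:
    """The (Km, kcat, Ki) triple describing one enzyme–substrate pair.

    Parameters
    ----------
    km : float
        Michaelis constant, M.
    kcat : float
        Turnover number, 1/s.
    ki : float or None
        Product-inhibition constant, M.  ``None`` means no product
        inhibition (Ki -> infinity).
    """

    km: float
    kcat: float
    ki: Optional[float] = None

    def __post_init__(self) -> None:
        _require_finite_positive("Km", self.km)
        _require_finite_positive("kcat", self.kcat)
        if self.ki is not None:
            _require_finite_positive("Ki", self.ki)

    @property
    def has_inhibition(self) -> bool:
        return self.ki is not None

    @property
    def specificity(self) -> float:
        """Specificity constant kcat/Km, M^-1 s^-1."""
        return self.kcat / self.km


@dataclass(frozen=True)
class IntegratedLawCoefficients:
    """Coefficients of the integrated rate law alpha*ln(S0/S) + beta*(S0-S) = Vmax*t.

    ``alpha = Km*(1 + S0/Ki)`` (M), ``beta = 1 - Km/Ki`` (dimensionless,
    exactly 1 without product inhibition), ``Vmax = kcat*E0`` (M/s).
    """

    alpha: float
    beta: float
    vmax: float

    def __post_init__(self) -> None:
        _require_finite_positive("alpha", self.alpha)
        _require_finite_positive("Vmax", self.vmax)
        if not np.isfinite(self.beta) or self.beta > 1:
            raise KineticsError(f"beta must be finite and <= 1, got {self.beta!r}")

    @classmethod
    def from_parameters(
        cls, params: KineticParameters, s0: float, e0: float
    ) -> "IntegratedLawCoefficients":
        _require_finite_positive("S0", s0)
        _require_finite_positive("E0", e0)
        if params.ki is None:
            alpha, beta = params.km, 1.0
        else:
            alpha = params.km * (1.0 + s0 / params.ki)
            beta = 1.0 - params.km / params.ki
        return cls(alpha=alpha, beta=beta, vmax=params.kcat * e0)


@dataclass(frozen=True)
class MicroscopicConstants:
    """Elementary rate constants of the full mass-action scheme.

    ``k1``/``k_minus1`` bind/release S to E, ``k2`` is the catalytic step,
    ``k3``/``k_minus3`` bind/release P to E.  Reduction to QSSA constants:
    ``Km = (k_minus1 + k2)/k1``, ``kcat = k2``, ``Ki = k_minus3/k3``.
    """

    k1: float
    k_minus1: float
    k2: float
    k3: float
    k_minus3: float

    def __post_init__(self) -> None:
        for name in ("k1", "k_minus1", "k2", "k3", "k_minus3"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise KineticsError(f"{name} must be finite and >= 0, got {v!r}")

    def reduced(self) -> KineticParameters:
        """Map to the macroscopic (Km, kcat, Ki) parameterization."""
        if self.k1 <= 0 or self.k2 <= 0:
            raise KineticsError("reduction requires k1 > 0 and k2 > 0")
        km = (self.k_minus1 + self.k2) / self.k1
        ki = self.k_minus3 / self.k3 if self.k3 > 0 else None
        return KineticParameters(km=km, kcat=self.k2, ki=ki)


@dataclass(frozen=True)
class ReactionState:
    """Concentrations (M) of every species in the mass-action scheme."""

    s: float
    p: float
    e: float
    es: float
    e_inh: float

    def __post_init__(self) -> None:
        for name in ("s", "p", "e", "es", "e_inh"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise KineticsError(f"{name} must be finite and >= 0, got {v!r}")

    @property
    def total_enzyme(self) -> float:
        return self.e + self.es + self.e_inh

    @property
    def total_substrate(self) -> float:
        """S + P + ES + E_inh: conserved along any mass-action trajectory.

        The inhibited complex carries one product molecule, so it belongs in
        the substrate-moiety balance; omitting it breaks conservation by up
        to the enzyme concentration once product binds enzyme.
        """
        return self.s + self.p + self.es + self.e_inh


@dataclass(frozen=True)
class MassActionTrajectory:
    """Time series of every species from the full mass-action simulation."""

    times: np.ndarray
    s: np.ndarray
    p: np.ndarray
    e: np.ndarray
    es: np.ndarray
    e_inh: np.ndarray

    def state_at(self, index: int) -> ReactionState:
        return ReactionState(
            s=max(float(self.s[index]), 0.0),
            p=max(float(self.p[index]), 0.0),
            e=max(float(self.e[index]), 0.0),
            es=max(float(self.es[index]), 0.0),
            e_inh=max(float(self.e_inh[index]), 0.0),
        )


# ---------------------------------------------------------------------------
# rate law and integrated law


def rate_qssa(s, p, params: KineticParameters, e0: float):
    """QSSA reaction rate v = kcat*E0*S / (Km*(1 + P/Ki) + S), M/s.

    Accepts scalars or arrays for ``s`` and ``p``.  Without product
    inhibition (``params.ki is None``) the P-term is dropped.
    """
    s = np.asarray(s, dtype=float)
    p = np.asarray(p, dtype=float)
    if np.any(s < 0) or np.any(p < 0):
        raise KineticsError("concentrations must be non-negative")
    _require_finite_positive("E0", e0)
    if params.ki is None:
        denom = params.km + s
    else:
        denom = params.km * (1.0 + p / params.ki) + s
    v = params.kcat * e0 * s / denom
    return v if v.ndim else float(v)


def integrated_time(s, coeffs: IntegratedLawCoefficients, s0: float):
    """Time at which the substrate concentration reaches ``s`` (exact inverse).

    t = [alpha*ln(S0/S) + beta*(S0 - S)] / Vmax, monotone decreasing in S.
    """
    _require_finite_positive("S0", s0)
    s = np.asarray(s, dtype=float)
    if np.any(s <= 0) or np.any(s > s0):
        raise KineticsError("integrated_time requires 0 < S <= S0")
    t = (coeffs.alpha * np.log(s0 / s) + coeffs.beta * (s0 - s)) / coeffs.vmax
    return t if t.ndim else float(t)


_BETA_ZERO_TOL = 1e-14


def _lambertw_principal_from_log(log_x: np.ndarray) -> np.ndarray:
    """W0(exp(log_x)) for log_x of any magnitude (log_x is real, x > 0).

    For moderate log_x the value is computed directly; for large log_x
    (where exp overflows) W0 solves w + ln w = log_x, obtained by Newton
    iteration from the asymptotic start w = log_x - ln(log_x).
    """
    log_x = np.asarray(log_x, dtype=float)
    out = np.empty_like(log_x)
    small = log_x <= 700.0
    if np.any(small):
        out[small] = lambertw(np.exp(log_x[small]), 0).real
    big = ~small
    if np.any(big):
        z = log_x[big]
        w = z - np.log(z)
        for _ in range(30):
            f = w + np.log(w) - z
            w = w - f / (1.0 + 1.0 / w)
            if np.all(np.abs(f) < 1e-14 * np.abs(z)):
                break
        out[big] = w
    return out


def closed_form_substrate(t, coeffs: IntegratedLawCoefficients, s0: float):
    """Closed-form S(t) for the integrated law, via the principal Lambert-W branch.

    ``S(t) = (alpha/beta) * W0((beta*S0/alpha) * exp((beta*S0 - Vmax*t)/alpha))``
    for ``beta != 0``; exponential decay ``S0*exp(-Vmax*t/alpha)`` for
    ``beta = 0``.  Raises :class:`BranchDomainError` if the W argument falls
    below -1/e (only possible through floating-point pathology with
    ``beta < 0``); callers should then fall back to root-finding on
    :func:`integrated_time`.
    """
    _require_finite_positive("S0", s0)
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    if np.any(t < 0) or not np.all(np.isfinite(t)):
        raise KineticsError("times must be finite and >= 0")
    alpha, beta, vmax = coeffs.alpha, coeffs.beta, coeffs.vmax

    if abs(beta) < _BETA_ZERO_TOL:
        s = s0 * np.exp(-vmax * t / alpha)
    elif beta > 0:
        log_x = np.log(beta * s0 / alpha) + (beta * s0 - vmax * t) / alpha
        s = (alpha / beta) * _lambertw_principal_from_log(log_x)
    else:
        # beta < 0: the argument is bounded in (-1/e, 0]; underflow to 0 is the
        # long-time limit S -> 0.
        x = (beta * s0 / alpha) * np.exp((beta * s0 - vmax * t) / alpha)
        floor = -np.exp(-1.0)
        if np.any(x < floor * (1.0 + 1e-9)):
            raise BranchDomainError(
                "Lambert-W argument below -1/e; use the numerical inversion path"
            )
        x = np.maximum(x, floor)
        s = (alpha / beta) * lambertw(x, 0).real
    s = np.clip(s, 0.0, s0)
    return float(s[0]) if scalar else s


def substrate_timecourse(
    params: KineticParameters, s0: float, e0: float, times
) -> np.ndarray:
    """S(t) on a time grid: closed form when valid, monotone bisection otherwise.

    This is the fast exact evaluation used by the synthetic-data generator
    and the fitting objective; it agrees with the adaptive-ODE path
    :func:`simulate_progress_qssa` to solver tolerance.
    """
    coeffs = IntegratedLawCoefficients.from_parameters(params, s0, e0)
    times = np.atleast_1d(np.asarray(times, dtype=float))
    try:
        return np.asarray(closed_form_substrate(times, coeffs, s0))
    except BranchDomainError:
        return _invert_integrated_law(times, coeffs, s0)


def _invert_integrated_law(
    times: np.ndarray, coeffs: IntegratedLawCoefficients, s0: float
) -> np.ndarray:
    """Bisection fallback: solve integrated_time(S) = t per grid point."""
    lo = s0 * 1e-300
    out = np.empty_like(times)
    for i, t in enumerate(times):
        if t <= 0.0:
            out[i] = s0
            continue
        f = lambda s, t=t: integrated_time(s, coeffs, s0) - t
        if f(lo) <= 0:  # grid time beyond numerical resolution: S ~ 0
            out[i] = 0.0
        else:
            out[i] = brentq(f, lo, s0, xtol=1e-300, rtol=8.9e-16)
    return out


# ---------------------------------------------------------------------------
# ODE trajectories


def simulate_progress_qssa(
    params: KineticParameters,
    s0: float,
    e0: float,
    times,
    rtol: float = 1e-10,
    atol_scale: float = 1e-14,
):
    """Numerical (S(t), P(t)) under the QSSA rate law, closed-assay mass balance.

    Integrates dS/dt = -v(S, S0-S) with an adaptive LSODA solver; P(t) is
    recovered from mass balance P = S0 - S.  Tight default tolerances
    (rtol 1e-10, atol 1e-14*S0) support the 1e-9 closed-form agreement the
    package's own tests demand.

    Raises
    ------
    SolverError
        If the integrator does not converge; the message carries the solver
        diagnostics.
    """
    _require_finite_positive("S0", s0)
    _require_finite_positive("E0", e0)
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 1:
        raise KineticsError("times must be a 1-D grid")
    if times[0] < 0 or np.any(np.diff(times) <= 0):
        raise KineticsError("times must start at t >= 0 and be strictly increasing")
    if e0 > 0.01 * s0:
        warnings.warn(
            f"E0 = {e0:g} M exceeds 1% of S0 = {s0:g} M; the QSSA free-substrate "
            "approximation may be inaccurate",
            stacklevel=2,
        )

    def rhs(_t, y):
        s = min(max(y[0], 0.0), s0)
        return [-rate_qssa(s, s0 - s, params, e0)]

    t_span = (0.0, float(times[-1]) if times[-1] > 0 else 1.0)
    sol = solve_ivp(
        rhs,
        t_span,
        [s0],
        method="LSODA",
        t_eval=times,
        rtol=rtol,
        atol=atol_scale * s0,
    )
    if not sol.success:
        raise SolverError(f"QSSA progress-curve integration failed: {sol.message}")
    s = np.clip(sol.y[0], 0.0, s0)
    return s, s0 - s


def simulate_progress_mass_action(
    micro: MicroscopicConstants,
    state0: ReactionState,
    times,
    rtol: float = 1e-9,
    atol_scale: float = 1e-12,
) -> MassActionTrajectory:
    """Full mass-action trajectory of (S, P, E, ES, E_inh).

    ODE system of the two-step scheme S+E<->ES->E+P, E+P<->E_inh.  Both
    conservation laws (total enzyme, total substrate counting ES) hold along
    the trajectory to solver tolerance.  In the limit E0/S0 -> 0 with fast
    binding the S(t) trajectory converges to the QSSA solution with the
    reduced constants.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 1:
        raise KineticsError("times must be a 1-D grid")
    if times[0] < 0 or np.any(np.diff(times) <= 0):
        raise KineticsError("times must start at t >= 0 and be strictly increasing")

    k1, km1, k2, k3, km3 = micro.k1, micro.k_minus1, micro.k2, micro.k3, micro.k_minus3
    scale = max(state0.total_substrate, state0.total_enzyme, 1e-300)

    def rhs(_t, y):
        s, e, es, p, e_inh = y
        bind = k1 * e * s
        unbind = km1 * es
        cat = k2 * es
        inh = k3 * e * p
        rel = km3 * e_inh
        return [
            -bind + unbind,
            -bind + unbind + cat - inh + rel,
            bind - unbind - cat,
            cat - inh + rel,
            inh - rel,
        ]

    y0 = [state0.s, state0.e, state0.es, state0.p, state0.e_inh]
    t_span = (0.0, float(times[-1]) if times[-1] > 0 else 1.0)
    sol = solve_ivp(
        rhs,
        t_span,
        y0,
        method="LSODA",
        t_eval=times,
        rtol=rtol,
        atol=atol_scale * scale,
    )
    if not sol.success:
        raise SolverError(f"mass-action integration failed: {sol.message}")
    s, e, es, p, e_inh = sol.y
    return MassActionTrajectory(
        times=times, s=s, p=p, e=e, es=es, e_inh=e_inh
    )
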