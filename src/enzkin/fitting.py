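"""Global progress-curve fitting: Km, kcat, Ki and kcat/Km with model selection.

The estimation problem is the one behind a substrate-panel kinetics table:
several progress curves per enzyme–substrate pair, recorded at >= 3 initial
substrate concentrations, fit *jointly* by unweighted nonlinear least
squares in the measured signal space (absorbance when optics are given),
sharing (Km, kcat[, Ki]) across curves.  Whether the product-inhibition
constant Ki is retained is decided by a nested F-test on the residual sum
of squares at significance level alpha = 0.05; a Ki that the data cannot
pin down is reported as absent ("N.D."), never clamped.

Optimization runs in log-parameter space (positivity for free, better
conditioning across the ~1e-6–1e3 dynamic range of the tables this
reproduces), with multi-start jittered restarts to guard against local
minima, starting from an initial-rate / Hanes–Woolf linearization guess.

The estimators follow the scikit-learn protocol (``fit``, ``predict``,
``get_params``/``set_params``, trailing-underscore fitted attributes), so
they compose with sklearn tooling; the module-level functions
(:func:`fit_global`, :func:`select_model`, :func:`estimate_specificity`,
:func:`bootstrap_uncertainty`) are thin wrappers over them.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

from .kinetics import KineticParameters, substrate_timecourse
from .spectro import ProgressCurve, absorbance_to_concentrations, concentration_to_absorbance

__all__ = [
    "FitError",
    "ConvergenceError",
    "FitResult",
    "ProgressCurveFitter",
    "PseudoFirstOrderRateFitter",
    "fit_global",
    "select_model",
    "estimate_specificity",
    "bootstrap_uncertainty",
    "initial_guess",
    "report_table",
    "format_sig",
]

MODEL_MM = "without_inhibition"
MODEL_MM_PI = "with_inhibition"

# log-space box for (Km, kcat, Ki): generous enough for every regime of a
# nucleoside-deacylase panel (Km ~ 1e-6..1e-2 M, kcat ~ 1e-2..1e3 /s).
_LOG_BOUNDS = {
    "km": (math.log(1e-10), math.log(1.0)),
    "kcat": (math.log(1e-8), math.log(1e8)),
    "ki": (math.log(1e-10), math.log(1e4)),
}


class FitError(ValueError):
    """Invalid fitting input."""


class ConvergenceError(RuntimeError):
    """Optimizer failed and no usable solution exists."""


@dataclass
class FitResult:
    """Estimates, uncertainties and model verdict for one enzyme–substrate set.

    ``params_hat`` is ``None`` for specificity-only results (the low-S0
    pseudo-first-order regime where Km and kcat are individually
    unidentifiable but kcat/Km is measurable).
    """

    params_hat: Optional[KineticParameters]
    specificity_hat: float
    model: str
    rss: float
    n_curves: int
    n_points: int
    se: dict = field(default_factory=dict)
    ci95: dict = field(default_factory=dict)
    p_value: Optional[float] = None
    rss_alternative: Optional[float] = None
    converged: bool = True
    message: str = ""
    warnings: list = field(default_factory=list)

    @property
    def km(self) -> Optional[float]:
        return self.params_hat.km if self.params_hat else None

    @property
    def kcat(self) -> Optional[float]:
        return self.params_hat.kcat if self.params_hat else None

    @property
    def ki(self) -> Optional[float]:
        return self.params_hat.ki if self.params_hat else None


# ---------------------------------------------------------------------------
# model evaluation


def _curve_concentrations(curve: ProgressCurve) -> np.ndarray:
    s, _ = absorbance_to_concentrations(curve)
    return s


def _predict_signal(params: KineticParameters, curve: ProgressCurve) -> np.ndarray:
    """Model trace in the curve's own signal space."""
    s = substrate_timecourse(params, curve.s0, curve.e0, curve.times)
    if curve.signal_units == "AU":
        return concentration_to_absorbance(s, curve.s0 - s, curve.optics)
    return s


def _residuals(params: KineticParameters, curves: Sequence[ProgressCurve]) -> np.ndarray:
    return np.concatenate(
        [curve.signal - _predict_signal(params, curve) for curve in curves]
    )


def _theta_to_params(theta: np.ndarray, with_ki: bool) -> KineticParameters:
    if with_ki:
        return KineticParameters(
            km=math.exp(theta[0]), kcat=math.exp(theta[1]), ki=math.exp(theta[2])
        )
    return KineticParameters(km=math.exp(theta[0]), kcat=math.exp(theta[1]))


# ---------------------------------------------------------------------------
# initial guess


def initial_guess(curves: Sequence[ProgressCurve]) -> KineticParameters:
    """Starting point from initial-rate estimates and a Hanes–Woolf line.

    Early-window slopes give per-curve initial rates v0; regressing
    S0/v0 on S0 (Hanes–Woolf: S0/v0 = S0/Vmax + Km/Vmax) yields (Km, Vmax)
    and hence kcat = Vmax/E0.  The Ki start equals Km.  Degenerate slopes
    fall back to documented defaults (Km = median S0, Vmax from the largest
    observed rate) with a warning.  Guaranteed inside the optimizer bounds.
    """
    if not curves:
        raise FitError("at least one curve is required")
    s0s, v0s = [], []
    for curve in curves:
        if len(curve) < 3:
            raise FitError(f"curve {curve.curve_id!r} has < 3 points")
        s = _curve_concentrations(curve)
        k = max(3, len(curve) // 10)
        slope = np.polyfit(curve.times[:k], s[:k], 1)[0]
        if slope < 0:
            s0s.append(curve.s0)
            v0s.append(-slope)
    e0 = float(np.mean([c.e0 for c in curves]))
    km = vmax = None
    if len(set(s0s)) >= 2:
        a, b = np.polyfit(np.asarray(s0s), np.asarray(s0s) / np.asarray(v0s), 1)
        if a > 0 and b > 0:
            vmax, km = 1.0 / a, b / a
    if km is None:
        if v0s:
            s0_ref = max(s0s)
            km = float(np.median([c.s0 for c in curves]))
            vmax = max(v0s) * (km + s0_ref) / s0_ref
        else:
            warnings.warn(
                "no usable initial slopes (flat or rising traces); falling back "
                "to default initial guess",
                stacklevel=2,
            )
            km = float(np.median([c.s0 for c in curves]))
            vmax = km / float(np.median([c.times[-1] for c in curves]))
    clip = lambda v, key: float(
        np.clip(v, math.exp(_LOG_BOUNDS[key][0]) * 10, math.exp(_LOG_BOUNDS[key][1]) / 10)
    )
    km = clip(km, "km")
    kcat = clip(vmax / e0, "kcat")
    return KineticParameters(km=km, kcat=kcat, ki=clip(km, "ki"))


# ---------------------------------------------------------------------------
# estimators


class ProgressCurveFitter(BaseEstimator):
    """Global nonlinear least-squares fit of (Km, kcat[, Ki]) to progress curves.

    Parameters
    ----------
    model : {"auto", "mm", "mm+pi"}
        ``"mm"`` fits plain Michaelis–Menten, ``"mm+pi"`` adds competitive
        product inhibition, ``"auto"`` fits both and keeps Ki only when the
        nested F-test on RSS is significant at ``alpha``.
    alpha : float
        Significance level of the model-selection F-test.
    n_restarts : int
        Multi-start count: the Hanes–Woolf guess plus ``n_restarts - 1``
        log-space jitters (sd 0.5) from ``random_state``.
    n_boot : int
        If > 0, run a residual-resampling bootstrap after the fit and
        replace the asymptotic 95% intervals by percentile intervals.
    random_state : int
        Seeds restart jitter and the bootstrap.

    Attributes
    ----------
    result_ : FitResult
    km_, kcat_, ki_, specificity_ : fitted parameter values (``ki_`` is
        ``None`` when product inhibition is absent or not selected).
    """

    def __init__(
        self,
        model: str = "auto",
        alpha: float = 0.05,
        n_restarts: int = 5,
        n_boot: int = 0,
        random_state: int = 0,
    ):
        self.model = model
        self.alpha = alpha
        self.n_restarts = n_restarts
        self.n_boot = n_boot
        self.random_state = random_state

    # -- internal machinery -------------------------------------------------

    def _validate_curves(self, curves: Sequence[ProgressCurve]) -> list:
        curves = list(curves)
        if not curves:
            raise FitError("at least one curve is required")
        notes = []
        if len({round(math.log(c.s0), 6) for c in curves}) < 3:
            msg = (
                "fewer than 3 distinct initial substrate concentrations; "
                "(Km, kcat, Ki) may be poorly identifiable"
            )
            warnings.warn(msg, stacklevel=3)
            notes.append(msg)
        return curves, notes

    def _fit_one_model(self, curves, with_ki: bool, guess: KineticParameters):
        keys = ("km", "kcat", "ki") if with_ki else ("km", "kcat")
        lo = np.array([_LOG_BOUNDS[k][0] for k in keys])
        hi = np.array([_LOG_BOUNDS[k][1] for k in keys])
        x0 = np.array(
            [math.log(guess.km), math.log(guess.kcat)]
            + ([math.log(guess.ki if guess.ki else guess.km)] if with_ki else [])
        )
        x0 = np.clip(x0, lo, hi)

        def obj(theta):
            return _residuals(_theta_to_params(theta, with_ki), curves)

        rng = np.random.default_rng(self.random_state)
        starts = [x0] + [
            np.clip(x0 + rng.normal(0.0, 0.5, size=x0.size), lo, hi)
            for _ in range(max(0, self.n_restarts - 1))
        ]
        best = None
        for start in starts:
            try:
                sol = least_squares(
                    obj, start, bounds=(lo, hi), method="trf",
                    xtol=1e-15, ftol=1e-15, gtol=1e-15,
                )
            except Exception:  # noqa: BLE001 - a bad restart must not kill the fit
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            raise ConvergenceError("all optimizer restarts failed")
        return best, with_ki

    @staticmethod
    def _uncertainty(sol, with_ki: bool, n: int) -> tuple[dict, dict]:
        """Asymptotic SEs and 95% CIs from the log-space Jacobian (delta method)."""
        keys = ("km", "kcat", "ki") if with_ki else ("km", "kcat")
        p = len(keys)
        dof = max(n - p, 1)
        rss = 2.0 * sol.cost
        jtj = sol.jac.T @ sol.jac
        try:
            cov_log = (rss / dof) * np.linalg.pinv(jtj)
        except np.linalg.LinAlgError:
            cov_log = np.full((p, p), np.inf)
        se_log = np.sqrt(np.clip(np.diag(cov_log), 0.0, np.inf))
        tcrit = stats.t.ppf(0.975, dof)
        values = np.exp(sol.x)
        se = {k: float(values[i] * se_log[i]) for i, k in enumerate(keys)}
        with np.errstate(over="ignore", under="ignore"):
            ci = {
                k: (
                    float(values[i] * np.exp(-tcrit * se_log[i])),
                    float(values[i] * np.exp(tcrit * se_log[i])),
                )
                for i, k in enumerate(keys)
            }
        # specificity kcat/Km via the log-space covariance of (log kcat - log Km)
        var_spec = cov_log[1, 1] + cov_log[0, 0] - 2.0 * cov_log[0, 1]
        spec = values[1] / values[0]
        se["specificity"] = float(spec * math.sqrt(max(var_spec, 0.0)))
        return se, ci

    def _ki_identifiable(self, sol, curves, se: dict) -> bool:
        ki = math.exp(sol.x[2])
        near_upper = sol.x[2] > _LOG_BOUNDS["ki"][1] - 1.0
        max_s0 = max(c.s0 for c in curves)
        se_ki = se.get("ki", math.inf)
        return not (near_upper or ki > 1e3 * max_s0 or not np.isfinite(se_ki))

    def _result_from_solution(self, sol, with_ki, curves, notes) -> FitResult:
        n = sum(len(c) for c in curves)
        params = _theta_to_params(sol.x, with_ki)
        se, ci = self._uncertainty(sol, with_ki, n)
        return FitResult(
            params_hat=params,
            specificity_hat=params.specificity,
            model=MODEL_MM_PI if with_ki else MODEL_MM,
            rss=2.0 * sol.cost,
            n_curves=len(curves),
            n_points=n,
            se=se,
            ci95=ci,
            converged=bool(sol.status > 0),
            message=sol.message,
            warnings=list(notes),
        )

    # -- sklearn API --------------------------------------------------------

    def fit(self, curves: Sequence[ProgressCurve], y=None) -> "ProgressCurveFitter":
        if self.model not in ("auto", "mm", "mm+pi"):
            raise FitError(f"unknown model {self.model!r}")
        curves, notes = self._validate_curves(curves)
        guess = initial_guess(curves)
        n = sum(len(c) for c in curves)

        if self.model == "mm":
            sol, with_ki = self._fit_one_model(curves, False, guess)
            result = self._result_from_solution(sol, False, curves, notes)
        elif self.model == "mm+pi":
            sol, with_ki = self._fit_one_model(curves, True, guess)
            result = self._result_from_solution(sol, True, curves, notes)
            if not self._ki_identifiable(sol, curves, result.se):
                msg = (
                    "Ki is unidentifiable from these curves (estimate at bound or "
                    "unbounded uncertainty); reporting it as absent"
                )
                warnings.warn(msg, stacklevel=2)
                result = self._drop_ki(result, curves, notes + [msg], guess)
        else:  # auto: nested F-test at alpha
            sol0, _ = self._fit_one_model(curves, False, guess)
            sol1, _ = self._fit_one_model(curves, True, guess)
            rss0, rss1 = 2.0 * sol0.cost, 2.0 * sol1.cost
            pval = _nested_f_pvalue(rss0, rss1, n, p_full=3, curves=curves)
            res1 = self._result_from_solution(sol1, True, curves, notes)
            keep_ki = pval < self.alpha and self._ki_identifiable(sol1, curves, res1.se)
            if keep_ki:
                result = res1
                result.rss_alternative = rss0
            else:
                result = self._result_from_solution(sol0, False, curves, notes)
                result.rss_alternative = rss1
            result.p_value = pval

        if self.n_boot:
            result = bootstrap_uncertainty(
                curves, result, n_boot=self.n_boot, seed=self.random_state
            )
        self.result_ = result
        self.km_ = result.km
        self.kcat_ = result.kcat
        self.ki_ = result.ki
        self.specificity_ = result.specificity_hat
        self.model_ = result.model
        return self

    def _drop_ki(self, result, curves, notes, guess) -> FitResult:
        sol, _ = self._fit_one_model(curves, False, guess)
        new = self._result_from_solution(sol, False, curves, notes)
        new.rss_alternative = result.rss
        return new

    def predict(self, curves: Sequence[ProgressCurve]) -> list[np.ndarray]:
        """Model signal (same units as each curve) at the fitted parameters."""
        if not hasattr(self, "result_"):
            raise FitError("fit the estimator before calling predict")
        return [_predict_signal(self.result_.params_hat, c) for c in curves]


def _nested_f_pvalue(rss0: float, rss1: float, n: int, p_full: int, curves) -> float:
    """Extra-sum-of-squares F-test p-value for adding the Ki parameter."""
    dof = max(n - p_full, 1)
    scale = sum(float(np.sum(np.square(c.signal))) for c in curves)
    floor = 1e-24 * max(scale, 1e-300)
    if rss0 - rss1 <= 0 or rss0 <= floor:
        return 1.0
    if rss1 <= floor:
        return 0.0
    f = (rss0 - rss1) / (rss1 / dof)
    return float(stats.f.sf(f, 1, dof))


class PseudoFirstOrderRateFitter(BaseEstimator):
    """Specificity constant kcat/Km from a low-substrate exponential trace.

    In the S0 << Km regime the progress curve is pseudo-first-order,
    S(t) = S0 * exp(-k_obs * t) with k_obs = (kcat/Km) * E0, so a single
    trace yields the specificity constant as k_obs / E0 — the only kinetic
    quantity measurable for substrates too poorly bound to saturate.

    A lack-of-fit check (nested F-test of the exponential against the full
    Michaelis–Menten model) warns when the trace shows saturation curvature,
    i.e. when S0 is in fact not << Km.
    """

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    def fit(self, curve: ProgressCurve, y=None) -> "PseudoFirstOrderRateFitter":
        s = _curve_concentrations(curve)
        t = curve.times
        if len(curve) < 3:
            raise FitError("need at least 3 points")

        # log-linear start where S > 0, robust to late-time zeros
        pos = s > 1e-12 * curve.s0
        if pos.sum() >= 2 and np.ptp(s[pos]) > 0:
            k0 = max(-np.polyfit(t[pos], np.log(s[pos] / curve.s0), 1)[0], 0.0)
        else:
            k0 = 0.0

        def resid(k):
            return s - curve.s0 * np.exp(-np.abs(k[0]) * t)

        sol = least_squares(resid, [k0], xtol=1e-15, ftol=1e-15, gtol=1e-15)
        k_obs = float(np.abs(sol.x[0]))
        rss_exp = 2.0 * sol.cost
        n = len(curve)

        notes = []
        if k_obs * t[-1] < 1e-6:
            msg = "trace is flat: no measurable turnover (k_obs ~ 0)"
            warnings.warn(msg, stacklevel=2)
            notes.append(msg)
        else:
            curvature = self._lack_of_fit(curve, s, rss_exp, n)
            if curvature is not None:
                warnings.warn(curvature, stacklevel=2)
                notes.append(curvature)

        self.k_obs_ = k_obs
        self.specificity_ = k_obs / curve.e0
        self.result_ = FitResult(
            params_hat=None,
            specificity_hat=self.specificity_,
            model="pseudo_first_order",
            rss=rss_exp,
            n_curves=1,
            n_points=n,
            se={"specificity": self._k_se(sol, n) / curve.e0},
            converged=bool(sol.status > 0),
            message=sol.message,
            warnings=notes,
        )
        return self

    @staticmethod
    def _k_se(sol, n: int) -> float:
        dof = max(n - 1, 1)
        jtj = float((sol.jac.T @ sol.jac).reshape(-1)[0])
        if jtj <= 0:
            return math.inf
        return math.sqrt((2.0 * sol.cost / dof) / jtj)

    def _lack_of_fit(self, curve, s, rss_exp, n) -> Optional[str]:
        """F-test the exponential against the saturating MM alternative."""
        conc_curve = ProgressCurve(
            curve_id=curve.curve_id, times=curve.times, signal=s,
            s0=curve.s0, e0=curve.e0, signal_units="M",
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mm = ProgressCurveFitter(model="mm", n_restarts=1).fit([conc_curve])
        except (FitError, ConvergenceError):
            return None
        dof = max(n - 2, 1)
        if rss_exp - mm.result_.rss <= 0 or mm.result_.rss <= 0:
            return None
        f = (rss_exp - mm.result_.rss) / (mm.result_.rss / dof)
        if stats.f.sf(f, 1, dof) < self.alpha and mm.km_ < 10.0 * curve.s0:
            return (
                "trace shows saturation curvature beyond first order; S0 does "
                "not satisfy S0 << Km and the specificity estimate is biased"
            )
        return None


# ---------------------------------------------------------------------------
# functional wrappers


def fit_global(
    curves: Sequence[ProgressCurve], model: str = "mm+pi", **fitter_kwargs
) -> FitResult:
    """Joint least-squares fit of all curves; see :class:`ProgressCurveFitter`."""
    return ProgressCurveFitter(model=model, **fitter_kwargs).fit(curves).result_


def select_model(
    curves: Sequence[ProgressCurve], alpha: float = 0.05, **fitter_kwargs
) -> FitResult:
    """Fit both nested models and keep Ki only if significant at ``alpha``."""
    return ProgressCurveFitter(model="auto", alpha=alpha, **fitter_kwargs).fit(curves).result_


def estimate_specificity(curve: ProgressCurve) -> float:
    """kcat/Km (M^-1 s^-1) from one pseudo-first-order trace."""
    return PseudoFirstOrderRateFitter().fit(curve).specificity_


def bootstrap_uncertainty(
    curves: Sequence[ProgressCurve],
    fit: FitResult,
    n_boot: int = 200,
    seed: int = 0,
) -> FitResult:
    """Residual-resampling bootstrap percentile intervals for a converged fit.

    Residuals at the fitted solution are resampled with replacement,
    added back to the fitted signal, and each replicate is refit from the
    original solution (single start).  Percentile 2.5/97.5 bounds replace
    the asymptotic intervals; bootstrap SDs replace the asymptotic SEs.
    Deterministic under ``seed``.
    """
    if n_boot < 50:
        raise FitError("n_boot must be >= 50 for stable percentile intervals")
    if fit.params_hat is None or not fit.converged:
        raise FitError("bootstrap requires a converged parametric fit")
    curves = list(curves)
    with_ki = fit.params_hat.ki is not None
    fitted = [_predict_signal(fit.params_hat, c) for c in curves]
    resid = np.concatenate([c.signal - f for c, f in zip(curves, fitted)])
    sizes = [len(c) for c in curves]
    rng = np.random.default_rng(seed)
    model = "mm+pi" if with_ki else "mm"
    samples = []
    for _ in range(n_boot):
        rstar = rng.choice(resid, size=resid.size, replace=True)
        pieces = np.split(rstar, np.cumsum(sizes)[:-1])
        boot_curves = [
            ProgressCurve(
                curve_id=c.curve_id, times=c.times, signal=f + piece,
                s0=c.s0, e0=c.e0, signal_units=c.signal_units,
                optics=c.optics, condition=c.condition,
            )
            for c, f, piece in zip(curves, fitted, pieces)
        ]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitter = ProgressCurveFitter(model=model, n_restarts=1)
            # start each replicate at the point estimate
            try:
                sol, _ = fitter._fit_one_model(boot_curves, with_ki, fit.params_hat)
            except ConvergenceError:
                continue
        samples.append(np.exp(sol.x))
    if not samples:
        raise ConvergenceError("every bootstrap replicate failed to refit")
    arr = np.asarray(samples)
    keys = ("km", "kcat", "ki") if with_ki else ("km", "kcat")
    out = replace(fit)
    out.se = dict(fit.se)
    out.ci95 = dict(fit.ci95)
    for i, key in enumerate(keys):
        lo, hi = np.percentile(arr[:, i], [2.5, 97.5])
        out.ci95[key] = (float(lo), float(hi))
        out.se[key] = float(np.std(arr[:, i], ddof=1))
    spec = arr[:, 1] / arr[:, 0]
    lo, hi = np.percentile(spec, [2.5, 97.5])
    out.ci95["specificity"] = (float(lo), float(hi))
    out.se["specificity"] = float(np.std(spec, ddof=1))
    out.warnings = fit.warnings + [f"bootstrap: {len(samples)}/{n_boot} replicates"]
    return out


# ---------------------------------------------------------------------------
# reporting


def format_sig(x: Optional[float], sig: int = 2) -> str:
    """Two-significant-figure table formatting; 'N.D.' for absent values."""
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return "N.D."
    if x == 0:
        return "0"
    exponent = math.floor(math.log10(abs(x)))
    if -3 <= exponent < 4:
        rounded = round(x, sig - 1 - exponent)
        if exponent >= sig - 1:
            return f"{rounded:.0f}"
        return f"{rounded:.{sig - 1 - exponent}f}"
    mant = x / 10**exponent
    mant = round(mant, sig - 1)
    if abs(mant) >= 10:  # rounding carried over a decade
        mant /= 10
        exponent += 1
    return f"{mant:.{sig - 1}f}e{exponent:+03d}"


def report_table(results: dict[str, FitResult]) -> tuple[pd.DataFrame, str]:
    """Substrate-panel kinetics table plus machine-readable records.

    One row per substrate with Km (M), kcat (1/s), Ki (M) and kcat/Km
    (M^-1 s^-1) at two significant figures; absent parameters render as
    "N.D.".  The specificity column is the ratio of the estimates, or the
    direct pseudo-first-order estimate when only that exists.  Returns the
    records as a DataFrame and the formatted text table.
    """
    records = []
    for label, res in results.items():
        records.append(
            {
                "substrate": label,
                "Km_M": res.km,
                "kcat_per_s": res.kcat,
                "Ki_M": res.ki,
                "kcat_over_Km_per_M_s": res.specificity_hat,
                "model": res.model,
                "rss": res.rss,
                "p_value": res.p_value,
                "n_curves": res.n_curves,
                "n_points": res.n_points,
                "converged": res.converged,
            }
        )
    df = pd.DataFrame.from_records(
        records,
        columns=[
            "substrate", "Km_M", "kcat_per_s", "Ki_M", "kcat_over_Km_per_M_s",
            "model", "rss", "p_value", "n_curves", "n_points", "converged",
        ],
    )
    header = f"{'Substrate':<14}{'Km (M)':<12}{'kcat (s^-1)':<14}{'Ki (M)':<12}{'kcat/Km (M^-1 s^-1)':<20}"
    lines = [header, "-" * len(header)]
    for rec in records:
        lines.append(
            f"{rec['substrate']:<14}"
            f"{format_sig(rec['Km_M']):<12}"
            f"{format_sig(rec['kcat_per_s']):<14}"
            f"{format_sig(rec['Ki_M']):<12}"
            f"{format_sig(rec['kcat_over_Km_per_M_s']):<20}"
        )
    return df, "\n".join(lines)
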