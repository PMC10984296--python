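"""MAP ("Bayesian feedback") estimation of individual PK parameters.

Given a subject's dosing history, sparse concentration observations and a
population prior, the individual random-effect vector eta is estimated by
minimising the -2 log-posterior

    OFV(eta) = sum_j [ (y_j - f_j)^2 / g_j^2 + ln(2 pi g_j^2) ]
             + eta' Omega^{-1} eta + ln|2 pi Omega|

where f_j is the model prediction at observation time j (via
:func:`neopk.prior.individualize` and superposed one-compartment closed
forms) and g_j^2 = sigma_add^2 + sigma_prop^2 f_j^2 is the combined
residual variance.  BLQ samples are discarded by default; an optional
censored-likelihood treatment replaces their contribution with
-2 ln Phi((LLOQ - f_j)/g_j).

The estimator is exposed in scikit-learn style as :class:`MAPRegressor`
(fit on observation times X and concentrations y, predict concentrations),
with :func:`map_objective` and :func:`fit_subject` as functional wrappers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize
from scipy.stats import norm
from sklearn.base import BaseEstimator, RegressorMixin

from .data import SubjectRecord
from .model import DosingEvent, concentration_profile
from .prior import IndividualParameters, PopulationPrior, individualize

__all__ = ["FitResult", "map_objective", "MAPRegressor", "fit_subject"]

_LOG_2PI = math.log(2.0 * math.pi)

#: BLQ handling policies: drop the sample, or censor the likelihood at LLOQ.
BLQ_METHODS = ("discard", "censor")


@dataclass(frozen=True)
class FitResult:
    """Outcome of a single-subject MAP fit."""

    individual: IndividualParameters
    objective_value: float
    converged: bool
    n_obs_used: int


def _residual_sd(prior: PopulationPrior, f: np.ndarray) -> np.ndarray:
    g2 = prior.sigma_add ** 2 + (prior.sigma_prop * f) ** 2
    if np.any(g2 <= 0):
        raise ZeroDivisionError(
            "degenerate residual variance: model prediction is 0 with no "
            "additive error component"
        )
    return np.sqrt(g2)


def _prior_term(prior: PopulationPrior, eta: np.ndarray) -> float:
    chol = prior._chol
    z = linalg.solve_triangular(chol, eta, lower=True)
    logdet = 2.0 * float(np.sum(np.log(np.diag(chol))))
    return float(z @ z) + prior.n_eta * _LOG_2PI + logdet


def _objective_arrays(prior: PopulationPrior, dosing: list[DosingEvent],
                      weight: float, times: np.ndarray, y: np.ndarray,
                      blq: np.ndarray, lloq: np.ndarray,
                      eta: np.ndarray, blq_method: str) -> float:
    params = individualize(prior, weight, eta)
    total = _prior_term(prior, eta)
    if times.size:
        f = concentration_profile(params, dosing, times)
        g = _residual_sd(prior, f)
        quant = ~blq
        if np.any(quant):
            r = (y[quant] - f[quant]) / g[quant]
            total += float(np.sum(r * r) + np.sum(np.log(2.0 * math.pi * g[quant] ** 2)))
        if blq_method == "censor" and np.any(blq):
            p = norm.cdf((lloq[blq] - f[blq]) / g[blq])
            total += float(-2.0 * np.sum(np.log(np.clip(p, 1e-300, None))))
    return total


def map_objective(prior: PopulationPrior, subject: SubjectRecord,
                  eta: np.ndarray, blq_method: str = "discard") -> float:
    """-2 log-posterior of eta for one subject (lower is better).

    With no usable observations the objective reduces to the prior term
    and is minimised at eta = 0.  The value is invariant to observation
    ordering.
    """
    if blq_method not in BLQ_METHODS:
        raise ValueError(f"blq_method must be one of {BLQ_METHODS}")
    eta = np.asarray(eta, dtype=float).ravel()
    if eta.shape[0] != prior.n_eta:
        raise ValueError(f"eta dimension {eta.shape[0]} != {prior.n_eta}")
    obs = subject.observations
    if blq_method == "discard":
        obs = [o for o in obs if not o.blq_flag]
    times = np.array([o.time for o in obs], dtype=float)
    y = np.array([o.value for o in obs], dtype=float)
    blq = np.array([o.blq_flag for o in obs], dtype=bool)
    lloq = np.array([o.lloq if o.lloq is not None else np.nan for o in obs],
                    dtype=float)
    return _objective_arrays(prior, subject.dosing, subject.weight,
                             times, y, blq, lloq, eta, blq_method)


class MAPRegressor(RegressorMixin, BaseEstimator):
    """Per-subject MAP estimator of individual PK parameters.

    Fits the random-effect vector eta of a one-compartment model to one
    subject's concentration-time data, penalised by the population prior
    ("Bayesian feedback").  Follows the scikit-learn estimator contract:
    ``fit(X, y)`` with X the observation times (hours, shape ``(n,)`` or
    ``(n, 1)``) and y the concentrations (mg/L); ``predict(X)`` returns
    model concentrations at arbitrary times.

    Parameters
    ----------
    prior : PopulationPrior
        Population typical values, IIV covariance and residual model.
    dosing : list of DosingEvent
        The subject's dosing history (non-empty).
    weight : float
        Subject body weight in kg, used for allometric scaling.
    blq_method : {"discard", "censor"}
        Below-limit sample handling (default drop).
    n_starts : int
        Extra jittered optimizer starts beyond eta=0 (0 = single start).
    random_state : int or None
        Seed for the jittered starts; the fit is otherwise deterministic.
    tol : float
        Relative convergence tolerance passed to the optimizer.

    Attributes
    ----------
    eta_ : ndarray
        MAP random effects.
    cl_, v_, ka_ : float
        Realized individual clearance (L/h), volume (L), absorption rate (1/h).
    objective_value_ : float
        -2 log-posterior at the optimum.
    converged_ : bool
    n_obs_used_ : int
    """

    def __init__(self, prior: PopulationPrior | None = None,
                 dosing: list[DosingEvent] | None = None,
                 weight: float | None = None,
                 blq_method: str = "discard",
                 n_starts: int = 0,
                 random_state: int | None = None,
                 tol: float = 1e-8):
        self.prior = prior
        self.dosing = dosing
        self.weight = weight
        self.blq_method = blq_method
        self.n_starts = n_starts
        self.random_state = random_state
        self.tol = tol

    def _validate(self):
        if self.prior is None:
            raise ValueError("MAPRegressor requires a PopulationPrior")
        if not self.dosing:
            raise ValueError("MAPRegressor requires a non-empty dosing history")
        if self.weight is None or not (self.weight > 0):
            raise ValueError("MAPRegressor requires a positive subject weight")
        if self.blq_method not in BLQ_METHODS:
            raise ValueError(f"blq_method must be one of {BLQ_METHODS}")

    def fit(self, X, y=None, blq_mask=None, lloq=None):
        """Estimate eta from observation times X and concentrations y.

        ``blq_mask`` marks below-limit samples (their y is ignored);
        ``lloq`` (scalar or array) is required when censoring them.
        Zero observations is allowed: the fit returns the prior mode.
        """
        self._validate()
        prior: PopulationPrior = self.prior
        if X is None or np.size(X) == 0:
            times = np.empty(0)
            yv = np.empty(0)
            blq = np.empty(0, dtype=bool)
            lloq_v = np.empty(0)
        else:
            times = np.asarray(X, dtype=float)
            if times.ndim == 2 and times.shape[1] == 1:
                times = times.ravel()
            if times.ndim != 1:
                raise ValueError("X must be 1-d times or a single-column matrix")
            yv = np.asarray(y, dtype=float).ravel()
            if yv.shape != times.shape:
                raise ValueError("X and y have mismatched lengths")
            blq = (np.zeros_like(times, dtype=bool) if blq_mask is None
                   else np.asarray(blq_mask, dtype=bool).ravel())
            lloq_v = np.broadcast_to(
                np.nan if lloq is None else np.asarray(lloq, dtype=float),
                times.shape).astype(float)
            if self.blq_method == "discard":
                keep = ~blq
                times, yv, blq, lloq_v = times[keep], yv[keep], blq[keep], lloq_v[keep]
            elif np.any(blq & ~np.isfinite(lloq_v)):
                raise ValueError("censored BLQ fitting requires lloq")
        self.n_features_in_ = 1

        dosing = list(self.dosing)

        def fun(eta: np.ndarray) -> float:
            try:
                return _objective_arrays(prior, dosing, float(self.weight),
                                         times, yv, blq, lloq_v, eta,
                                         self.blq_method)
            except ZeroDivisionError:
                # trial eta drove the prediction to underflow with a
                # proportional-only error model; infinitely bad, back off
                return np.inf

        starts = [np.zeros(prior.n_eta)]
        if self.n_starts:
            rng = np.random.default_rng(self.random_state)
            sd = np.sqrt(np.diag(prior.omega))
            starts += [rng.normal(0.0, sd) for _ in range(self.n_starts)]

        best = None
        for x0 in starts:
            # infinite objective values at absurd trial points make the
            # finite-difference gradient momentarily non-finite; harmless
            with np.errstate(invalid="ignore", over="ignore"):
                res = optimize.minimize(
                    fun, x0, method="L-BFGS-B", tol=self.tol,
                    options={"ftol": 1e-14, "gtol": 1e-9, "maxiter": 500})
            if not res.success:
                # polish with a simplex pass; sparse-data posteriors can have
                # nearly flat directions where quasi-Newton line searches stall
                res2 = optimize.minimize(
                    fun, res.x, method="Nelder-Mead",
                    options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000})
                if res2.fun <= res.fun:
                    res = res2
            if best is None or res.fun < best.fun:
                best = res
        assert best is not None

        self.eta_ = np.asarray(best.x, dtype=float)
        structural = individualize(prior, float(self.weight), self.eta_)
        self.individual_ = IndividualParameters(eta=self.eta_, structural=structural)
        self.cl_ = structural.cl
        self.v_ = structural.v
        self.ka_ = structural.ka
        self.objective_value_ = float(best.fun)
        self.converged_ = bool(best.success)
        self.n_obs_used_ = int(times.size)
        return self

    def predict(self, X):
        """Model concentrations (mg/L) at times X under the fitted parameters."""
        if not hasattr(self, "eta_"):
            raise AttributeError("MAPRegressor is not fitted yet; call fit first")
        times = np.asarray(X, dtype=float)
        if times.ndim == 2 and times.shape[1] == 1:
            times = times.ravel()
        return concentration_profile(self.individual_.structural,
                                     list(self.dosing), times)


def fit_subject(prior: PopulationPrior, subject: SubjectRecord,
                blq_method: str = "discard", n_starts: int = 0,
                random_state: int | None = None,
                tol: float = 1e-8) -> FitResult:
    """MAP-fit one subject record; thin wrapper over :class:`MAPRegressor`."""
    if not subject.dosing:
        raise ValueError(f"subject {subject.subject_id}: dosing history is empty")
    obs = subject.observations
    est = MAPRegressor(prior=prior, dosing=subject.dosing, weight=subject.weight,
                       blq_method=blq_method, n_starts=n_starts,
                       random_state=random_state, tol=tol)
    est.fit(np.array([o.time for o in obs]),
            np.array([o.value for o in obs]),
            blq_mask=np.array([o.blq_flag for o in obs], dtype=bool),
            lloq=np.array([o.lloq if o.lloq is not None else np.nan for o in obs]))
    return FitResult(individual=est.individual_,
                     objective_value=est.objective_value_,
                     converged=est.converged_,
                     n_obs_used=est.n_obs_used_)
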