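"""MAP estimation of agent parameters with a Laplace posterior approximation.

Parameters are estimated per subject-visit on the natural-log scale
(x = (ln du, ln ec)), which enforces positivity, under an independent Gaussian
prior on x.  The log-joint (choice log-likelihood plus log-prior) is maximized
by BFGS with central-difference gradients from a fixed set of deterministic
restarts; the posterior covariance is the inverse negative Hessian at the
optimum (Laplace approximation).  A brute-force lattice search over the same
log-joint (`fit_grid`) serves as an independent oracle.

Fit quality is summarized by the average action probability (mean model
probability of the chosen position) and accuracy (fraction of trials on which
the chosen position is a model argmax); chance accuracy on a nine-position
runway is 1/9.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .agent import AgentParams, choice_policy
from .task import N_POSITIONS, TRIAL_TYPES, TrialSpec

#: Floor applied to policy probabilities before taking logs, keeping the
#: likelihood finite for extreme parameter values.
POLICY_FLOOR = 1e-12

#: Clip on log-scale parameters inside the objective; beyond this range the
#: policy is numerically indistinguishable from its limit.
_LOG_CLIP = 12.0


@dataclass(frozen=True)
class PriorSpec:
    """Independent Gaussian prior on (ln du, ln ec)."""

    mean: tuple[float, float] = (0.0, 0.0)
    variance: tuple[float, float] = (4.0, 4.0)

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.variance):
            raise ValueError("prior variances must be > 0")


@dataclass
class FitResult:
    """MAP estimates with Laplace covariance and fit metrics."""

    du_hat: float
    ec_hat: float
    log_params: np.ndarray
    posterior_cov: np.ndarray | None
    log_joint: float
    avg_action_probability: float
    accuracy: float
    n_trials: int
    converged: bool

    def se_log_params(self) -> np.ndarray:
        if self.posterior_cov is None:
            return np.full(2, np.nan)
        return np.sqrt(np.clip(np.diag(self.posterior_cov), 0.0, None))

    def to_dict(self) -> dict:
        se = self.se_log_params()
        return {
            "du_hat": self.du_hat,
            "ec_hat": self.ec_hat,
            "log_du": float(self.log_params[0]),
            "log_ec": float(self.log_params[1]),
            "se_log_du": float(se[0]),
            "se_log_ec": float(se[1]),
            "log_joint": self.log_joint,
            "avg_action_prob": self.avg_action_probability,
            "accuracy": self.accuracy,
            "n_trials": self.n_trials,
            "converged": self.converged,
        }


def _as_trials(data) -> pd.DataFrame:
    """Accept a SubjectDataset or a bare trials DataFrame."""
    trials = getattr(data, "trials", data)
    if not isinstance(trials, pd.DataFrame):
        raise TypeError("expected a SubjectDataset or a trials DataFrame")
    if len(trials) == 0:
        raise ValueError("dataset has no trials")
    return trials


def choice_counts(data) -> np.ndarray:
    """(n_types, 9) matrix of choice counts by trial type and position."""
    trials = _as_trials(data)
    chosen = trials["chosen_position"].to_numpy()
    if not np.isin(chosen, np.arange(1, N_POSITIONS + 1)).all():
        raise ValueError("chosen positions must lie in 1..9")
    counts = np.zeros((len(TRIAL_TYPES), N_POSITIONS))
    for i, ttype in enumerate(TRIAL_TYPES):
        sel = trials["trial_type"] == ttype
        if sel.any():
            counts[i] = np.bincount(
                chosen[sel.to_numpy()] - 1, minlength=N_POSITIONS
            )
    return counts


def _policies_by_type(params: AgentParams, form: str) -> np.ndarray:
    return np.vstack(
        [choice_policy(params, TrialSpec(t), form=form).as_array() for t in TRIAL_TYPES]
    )


def _loglik_from_counts(params: AgentParams, counts: np.ndarray, form: str) -> float:
    pol = np.maximum(_policies_by_type(params, form), POLICY_FLOOR)
    return float((counts * np.log(pol)).sum())


def log_likelihood(params: AgentParams, data, form: str = "risk") -> float:
    """Sum over trials of ln p(chosen position | params); always <= ~0."""
    return _loglik_from_counts(params, choice_counts(data), form)


def _log_prior(x: np.ndarray, prior: PriorSpec) -> float:
    m = np.asarray(prior.mean)
    v = np.asarray(prior.variance)
    return float(
        -0.5 * (((x - m) ** 2) / v).sum() - 0.5 * np.log(2 * np.pi * v).sum()
    )


def _params_from_log(x: np.ndarray) -> AgentParams:
    xc = np.clip(x, -_LOG_CLIP, _LOG_CLIP)
    return AgentParams(du=float(np.exp(xc[0])), ec=float(np.exp(xc[1])))


def log_joint(x: np.ndarray, counts: np.ndarray, prior: PriorSpec, form: str) -> float:
    return _loglik_from_counts(_params_from_log(x), counts, form) + _log_prior(x, prior)


def _central_grad(f, x: np.ndarray, h: float = 1e-5) -> np.ndarray:
    g = np.empty_like(x)
    for i in range(len(x)):
        e = np.zeros_like(x)
        e[i] = h
        g[i] = (f(x + e) - f(x - e)) / (2 * h)
    return g


def _central_hessian(f, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    n = len(x)
    hess = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = h
        hess[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / h**2
        for j in range(i + 1, n):
            ej = np.zeros(n)
            ej[j] = h
            hess[i, j] = hess[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * h**2)
    return hess


class AgentParameterEstimator(BaseEstimator):
    """Scikit-learn-style MAP estimator of (du, ec) for one subject-visit.

    Parameters
    ----------
    prior_mean, prior_variance : tuple of float
        Gaussian prior on (ln du, ln ec).  The weakly informative default
        centers both parameters at 1 on the raw scale with log-scale SD 2.
    value_form : {"risk", "expected_log_preference"}
        Action-valuation form used by the agent.
    max_iter : int
        BFGS iteration cap per restart.
    tol : float
        Gradient-norm tolerance for convergence.

    After ``fit`` the estimates are exposed as ``du_``, ``ec_``,
    ``log_params_``, ``posterior_cov_``, ``log_joint_``,
    ``avg_action_probability_``, ``accuracy_`` and ``converged_``.
    """

    def __init__(
        self,
        prior_mean: tuple[float, float] = (0.0, 0.0),
        prior_variance: tuple[float, float] = (4.0, 4.0),
        value_form: str = "risk",
        max_iter: int = 64,
        tol: float = 1e-6,
    ):
        self.prior_mean = prior_mean
        self.prior_variance = prior_variance
        self.value_form = value_form
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y=None) -> "AgentParameterEstimator":
        """Fit to a SubjectDataset or trials DataFrame ``X``."""
        trials = _as_trials(X)
        counts = choice_counts(trials)
        prior = PriorSpec(tuple(self.prior_mean), tuple(self.prior_variance))

        def nlj(x: np.ndarray) -> float:
            return -log_joint(x, counts, prior, self.value_form)

        m = np.asarray(prior.mean, dtype=float)
        sd = np.sqrt(np.asarray(prior.variance))
        starts = [m] + [m + sd * np.array(c) for c in
                        itertools.product((-1.0, 1.0), repeat=2)]

        best = None
        any_success = False
        for x0 in starts:
            res = optimize.minimize(
                nlj,
                x0,
                jac=lambda x: _central_grad(nlj, x),
                method="BFGS",
                options={"maxiter": self.max_iter, "gtol": self.tol},
            )
            any_success = any_success or bool(res.success)
            if best is None or res.fun < best.fun:
                best = res

        x_hat = np.clip(best.x, -_LOG_CLIP, _LOG_CLIP)
        hess = _central_hessian(nlj, x_hat)
        cov_ok = True
        try:
            eigvals = np.linalg.eigvalsh(hess)
            if (eigvals > 0).all():
                cov = np.linalg.inv(hess)
            else:
                cov = np.linalg.pinv(hess)
                cov_ok = False
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(hess)
            cov_ok = False

        params = _params_from_log(x_hat)
        avg_p, acc = fit_metrics(params, trials, form=self.value_form)

        self.du_ = params.du
        self.ec_ = params.ec
        self.log_params_ = x_hat
        self.posterior_cov_ = cov
        self.log_joint_ = float(-best.fun)
        self.avg_action_probability_ = avg_p
        self.accuracy_ = acc
        self.n_trials_ = int(len(trials))
        self.converged_ = bool(any_success and cov_ok)
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Per-trial policy rows (n_trials, 9) under the fitted parameters."""
        trials = _as_trials(X)
        params = AgentParams(self.du_, self.ec_)
        pol = {t: choice_policy(params, TrialSpec(t), form=self.value_form).as_array()
               for t in TRIAL_TYPES}
        return np.vstack([pol[t] for t in trials["trial_type"]])

    def score(self, X, y=None) -> float:
        """Mean per-trial log-likelihood under the fitted parameters."""
        trials = _as_trials(X)
        return log_likelihood(
            AgentParams(self.du_, self.ec_), trials, form=self.value_form
        ) / len(trials)

    def result_(self) -> FitResult:
        return FitResult(
            du_hat=self.du_,
            ec_hat=self.ec_,
            log_params=self.log_params_,
            posterior_cov=self.posterior_cov_,
            log_joint=self.log_joint_,
            avg_action_probability=self.avg_action_probability_,
            accuracy=self.accuracy_,
            n_trials=self.n_trials_,
            converged=self.converged_,
        )


def fit_map(
    data,
    prior: PriorSpec | None = None,
    value_form: str = "risk",
    max_iter: int = 64,
    tol: float = 1e-6,
) -> FitResult:
    """MAP fit of (du, ec) with Laplace posterior covariance.

    Thin functional wrapper over :class:`AgentParameterEstimator`.
    """
    prior = prior or PriorSpec()
    est = AgentParameterEstimator(
        prior_mean=prior.mean,
        prior_variance=prior.variance,
        value_form=value_form,
        max_iter=max_iter,
        tol=tol,
    ).fit(data)
    return est.result_()


def fit_grid(
    data,
    log_du_grid: np.ndarray,
    log_ec_grid: np.ndarray,
    prior: PriorSpec | None = None,
    value_form: str = "risk",
) -> FitResult:
    """Exhaustive log-joint search over a log-space lattice (testing oracle)."""
    log_du_grid = np.atleast_1d(np.asarray(log_du_grid, dtype=float))
    log_ec_grid = np.atleast_1d(np.asarray(log_ec_grid, dtype=float))
    if log_du_grid.size == 0 or log_ec_grid.size == 0:
        raise ValueError("grid must be non-empty")
    prior = prior or PriorSpec()
    trials = _as_trials(data)
    counts = choice_counts(trials)
    best_x, best_lj = None, -np.inf
    for ldu in log_du_grid:
        for lec in log_ec_grid:
            x = np.array([ldu, lec])
            lj = log_joint(x, counts, prior, value_form)
            if lj > best_lj:
                best_lj, best_x = lj, x
    params = _params_from_log(best_x)
    avg_p, acc = fit_metrics(params, trials, form=value_form)
    return FitResult(
        du_hat=params.du,
        ec_hat=params.ec,
        log_params=best_x,
        posterior_cov=None,
        log_joint=best_lj,
        avg_action_probability=avg_p,
        accuracy=acc,
        n_trials=int(len(trials)),
        converged=True,
    )


def fit_metrics(params: AgentParams, data, form: str = "risk") -> tuple[float, float]:
    """(average action probability, accuracy) of a parameter set on data.

    Accuracy gives full credit whenever the chosen position belongs to the
    policy's argmax set (ties broken in the subject's favor).
    """
    trials = _as_trials(data)
    pol = {t: choice_policy(params, TrialSpec(t), form=form).as_array()
           for t in TRIAL_TYPES}
    p_chosen = np.empty(len(trials))
    hit = np.empty(len(trials))
    for i, (ttype, chosen) in enumerate(
        zip(trials["trial_type"], trials["chosen_position"])
    ):
        p = pol[ttype]
        p_chosen[i] = p[chosen - 1]
        hit[i] = p[chosen - 1] >= p.max() - 1e-12
    return float(p_chosen.mean()), float(hit.mean())


def optlog_transform(
    values, c_grid: np.ndarray | None = None
) -> tuple[np.ndarray, float]:
    """Skew-minimizing shifted log transform ln(values + c).

    The offset c is chosen from a geometric grid (0 plus 24 log-spaced points
    between 1e-3 and 1e2) to minimize the magnitude of the adjusted
    Fisher-Pearson sample skewness of the transformed values.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) == 0:
        raise ValueError("values must be a non-empty 1-d array")
    if c_grid is None:
        c_grid = np.concatenate([[0.0], np.logspace(-3, 2, 24)])
    valid = [c for c in c_grid if (v + c > 0).all()]
    if not valid:
        raise ValueError("no offset in the grid makes all values positive")

    def abs_skew(c: float) -> float:
        t = np.log(v + c)
        if np.std(t) == 0:
            return 0.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return abs(float(stats.skew(t, bias=False)))

    best_c = min(valid, key=abs_skew)
    return np.log(v + best_c), float(best_c)
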