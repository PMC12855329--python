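"""Observing-the-observer model fitting.

A perceptual filter (HGF variant, Rescorla-Wagner or Sutton K1) maps the
observed stimulus sequence ``u`` to trial-wise predictions; the unit-square
sigmoid response model maps predictions to the likelihood of the observed
binary gaze responses ``y``.  Free parameters carry Gaussian priors in an
unconstrained space (log / logit transforms for positive / bounded
quantities) and are estimated by MAP with seeded Nelder-Mead multistarts.
The log-model evidence is a Laplace approximation at the MAP:

    LME = log p(y, theta_MAP) + (d/2) log 2 pi - (1/2) log det(-H)

with the Hessian H of the log joint obtained by central finite differences.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.stats import norm

from .filters import (
    HGFInstabilityError,
    HGFParams,
    Trajectories,
    hgf_filter,
    response_loglik,
    rw_filter,
    sk1_filter,
)

__all__ = [
    "FreeParam",
    "ModelSpec",
    "FitResult",
    "default_model_specs",
    "model_predictions",
    "fit_map_laplace",
    "ideal_observer_priors",
    "extract_condition_parameters",
]

log = logging.getLogger(__name__)

MODEL_NAMES = ("rw", "sk1", "hgf2", "hgf3", "hgf4")


def _identity(x: float) -> float:
    return x


def _exp(x: float) -> float:
    return float(np.exp(x))


def _logistic(x: float) -> float:
    return float(1.0 / (1.0 + np.exp(-x)))


_TRANSFORMS: dict[str, Callable[[float], float]] = {
    "identity": _identity,
    "exp": _exp,
    "logistic": _logistic,
}


@dataclass(frozen=True)
class FreeParam:
    """One free parameter: Gaussian prior in the unconstrained space, plus the
    transform to its natural scale."""

    name: str
    prior_mean: float
    prior_sd: float
    transform: Literal["identity", "exp", "logistic"] = "identity"

    def to_natural(self, eta: float) -> float:
        return _TRANSFORMS[self.transform](eta)


@dataclass(frozen=True)
class ModelSpec:
    """A fittable perceptual model: name, free parameters, fixed settings."""

    name: str
    free: tuple[FreeParam, ...]
    fixed: dict = field(default_factory=dict)

    @property
    def n_free(self) -> int:
        return len(self.free)


def default_model_specs(zeta_prior: tuple[float, float] = (np.log(2.0), 1.5)) -> dict[str, ModelSpec]:
    """The five standard model specs compared in this toolkit.

    The coupling kappa is fixed at 1 (zero variance) in every HGF variant;
    value beliefs and learning rates start at neutral values in the
    associative models.  Response decisiveness zeta is free (log-normal) in
    all specs.
    """
    zeta = FreeParam("log_zeta", zeta_prior[0], zeta_prior[1], "exp")
    return {
        "rw": ModelSpec("rw", (FreeParam("logit_alpha", 0.0, 2.0, "logistic"), zeta)),
        "sk1": ModelSpec(
            "sk1",
            (
                FreeParam("beta0", -2.3, 1.5, "identity"),
                FreeParam("log_meta_rate", -2.3, 1.5, "exp"),
                zeta,
            ),
        ),
        "hgf2": ModelSpec("hgf2", (FreeParam("omega2", -3.0, 4.0, "identity"), zeta)),
        "hgf3": ModelSpec(
            "hgf3",
            (
                FreeParam("omega2", -3.0, 4.0, "identity"),
                FreeParam("omega3", -6.0, 3.0, "identity"),
                zeta,
            ),
        ),
        "hgf4": ModelSpec(
            "hgf4",
            (
                FreeParam("omega2", -3.0, 4.0, "identity"),
                FreeParam("omega3", -6.0, 3.0, "identity"),
                FreeParam("omega4", -6.0, 3.0, "identity"),
                zeta,
            ),
        ),
    }


def _natural_params(spec: ModelSpec, eta: np.ndarray) -> dict[str, float]:
    out = dict(spec.fixed)
    for fp, e in zip(spec.free, eta):
        key = fp.name
        for prefix in ("log_", "logit_"):
            if key.startswith(prefix):
                key = key[len(prefix):]
        out[key] = fp.to_natural(float(e))
    return out


def model_predictions(name: str, params: dict, u: np.ndarray) -> np.ndarray:
    """Trial-wise predictions p(u=1) for any of the five perceptual models.

    ``params`` holds natural-scale parameters (e.g. ``alpha``, ``omega2``,
    ...); response parameters such as ``zeta`` are ignored here.
    """
    if name == "rw":
        V = rw_filter(u, params["alpha"], params.get("v0", 0.5))
        return V[:-1]
    if name == "sk1":
        out = sk1_filter(u, params["beta0"], params["meta_rate"], params.get("v0", 0.5))
        return out["V"][:-1]
    if name in ("hgf2", "hgf3", "hgf4"):
        n_levels = int(name[-1])
        keys = ("kappa", "omega2", "omega3", "omega4", "mu2_0", "sigma2_0",
                "mu3_0", "sigma3_0", "mu4_0", "sigma4_0")
        hp = HGFParams(n_levels=n_levels, **{k: params[k] for k in keys if k in params})
        return hgf_filter(u, hp).muhat1
    raise ValueError(f"unknown model {name!r}")


@dataclass
class FitResult:
    """MAP fit of one model to one participant's (u, y) pair."""

    model: str
    map_params: dict
    map_eta: np.ndarray
    log_joint: float
    lme: float
    converged: bool
    n_restarts_used: int
    hessian_regularized: bool = False

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "map_params": {k: float(v) for k, v in self.map_params.items()},
            "map_eta": [float(e) for e in self.map_eta],
            "log_joint": float(self.log_joint),
            "lme": float(self.lme),
            "converged": bool(self.converged),
            "n_restarts_used": int(self.n_restarts_used),
            "hessian_regularized": bool(self.hessian_regularized),
        }


def _log_joint(spec: ModelSpec, eta: np.ndarray, u: np.ndarray, y: np.ndarray) -> float:
    try:
        params = _natural_params(spec, eta)
        muhat1 = model_predictions(spec.name, params, u)
        ll = response_loglik(muhat1, y, params.get("zeta", 1.0))
    except (HGFInstabilityError, FloatingPointError, OverflowError):
        return -np.inf
    if not np.isfinite(ll):
        return -np.inf
    lp = sum(
        norm.logpdf(e, fp.prior_mean, fp.prior_sd) for fp, e in zip(spec.free, eta)
    )
    return ll + lp


def fit_map_laplace(
    u: np.ndarray,
    y: np.ndarray,
    spec: ModelSpec,
    n_restarts: int = 10,
    seed: int = 0,
    xtol: float = 1e-6,
) -> FitResult:
    """MAP fit with seeded multistarts and a Laplace log-model evidence.

    Parameters
    ----------
    u, y
        Binary stimulus and response sequences of equal length.
    spec
        Model specification (free parameters with Gaussian priors).
    n_restarts
        Number of Nelder-Mead starts: the first at the prior means, the rest
        jittered by half a prior SD using ``seed``.
    """
    u = np.asarray(u)
    y = np.asarray(y)
    if len(u) != len(y):
        raise ValueError("u and y must have equal length")
    d = spec.n_free
    if d == 0:
        lj = _log_joint(spec, np.empty(0), u, y)
        return FitResult(spec.name, dict(spec.fixed), np.empty(0), lj, lj, np.isfinite(lj), 0)

    rng = np.random.default_rng(seed)
    mean = np.array([fp.prior_mean for fp in spec.free])
    sd = np.array([fp.prior_sd for fp in spec.free])

    def neg(eta: np.ndarray) -> float:
        lj = _log_joint(spec, eta, u, y)
        return -lj if np.isfinite(lj) else 1e12

    best = None
    used = 0
    for i in range(n_restarts):
        x0 = mean if i == 0 else mean + 0.5 * sd * rng.standard_normal(d)
        res = minimize(neg, x0, method="Nelder-Mead",
                       options={"xatol": xtol, "fatol": xtol, "maxiter": 400 * d})
        used += 1
        if best is None or res.fun < best.fun:
            best = res

    if best is None or best.fun >= 1e12:
        return FitResult(spec.name, {}, mean, -np.inf, -np.inf, False, used)

    eta = np.asarray(best.x, dtype=float)
    lj = -float(best.fun)

    # Laplace term: Hessian of the negative log joint by central differences
    step = 1e-4
    H = np.empty((d, d))
    for i in range(d):
        for j in range(i, d):
            ei = np.zeros(d); ei[i] = step
            ej = np.zeros(d); ej[j] = step
            fpp = _log_joint(spec, eta + ei + ej, u, y)
            fpm = _log_joint(spec, eta + ei - ej, u, y)
            fmp = _log_joint(spec, eta - ei + ej, u, y)
            fmm = _log_joint(spec, eta - ei - ej, u, y)
            H[i, j] = H[j, i] = -(fpp - fpm - fmp + fmm) / (4.0 * step**2)

    regularized = False
    if not np.all(np.isfinite(H)):
        H = np.eye(d)
        regularized = True
    evals, evecs = np.linalg.eigh(H)
    if np.any(evals < 1e-8):
        evals = np.maximum(evals, 1e-8)
        H = evecs @ np.diag(evals) @ evecs.T
        regularized = True
        log.debug("non-positive-definite Hessian regularized for model %s", spec.name)
    logdet = float(np.sum(np.log(evals)))
    lme = lj + 0.5 * d * np.log(2.0 * np.pi) - 0.5 * logdet

    return FitResult(
        model=spec.name,
        map_params=_natural_params(spec, eta),
        map_eta=eta,
        log_joint=lj,
        lme=float(lme),
        converged=bool(best.success),
        n_restarts_used=used,
        hessian_regularized=regularized,
    )


# ---------------------------------------------------------------------------
# Ideal-observer priors
# ---------------------------------------------------------------------------

def ideal_observer_priors(
    u_sequences: Sequence[np.ndarray],
    n_levels: int = 3,
    seed: int = 0,
) -> dict[str, float]:
    """Surprise-minimising HGF settings for the given stimulus sequences.

    Optimises the initial level-2 mean and the omegas so that an ideal
    Bayesian agent accumulates the least Shannon surprise about the inputs,
    then runs the filter at the optimum and returns the resulting posterior
    means as prior means for participant fits.  Falls back to neutral priors
    (mu2_0 = 0) if the optimiser fails.
    """
    seqs = [np.asarray(u) for u in u_sequences]
    if not seqs:
        raise ValueError("at least one input sequence is required")

    def surprise(x: np.ndarray) -> float:
        mu2_0, omega2 = x[0], x[1]
        omega3 = x[2] if n_levels >= 3 else -6.0
        try:
            total = 0.0
            for u in seqs:
                hp = HGFParams(n_levels=n_levels, mu2_0=mu2_0, omega2=omega2, omega3=omega3)
                m = np.clip(hgf_filter(u, hp).muhat1, 1e-9, 1 - 1e-9)
                total -= float(np.sum(np.where(u == 1, np.log(m), np.log1p(-m))))
            return total
        except (HGFInstabilityError, FloatingPointError):
            return 1e12

    x0 = np.array([0.0, -3.0, -6.0][: (3 if n_levels >= 3 else 2)])
    res = minimize(surprise, x0, method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-6, "maxiter": 2000})
    if not np.isfinite(res.fun) or res.fun >= 1e12:
        log.warning("ideal-observer optimisation failed; using neutral priors")
        return {"mu2_0": 0.0, "mu3_0": 1.0, "omega2": -3.0, "omega3": -6.0}

    mu2_0, omega2 = float(res.x[0]), float(res.x[1])
    omega3 = float(res.x[2]) if n_levels >= 3 else -6.0
    mu2_end, mu3_end = [], []
    for u in seqs:
        hp = HGFParams(n_levels=n_levels, mu2_0=mu2_0, omega2=omega2, omega3=omega3)
        traj = hgf_filter(u, hp)
        mu2_end.append(traj.mu2[-1])
        if traj.mu3 is not None:
            mu3_end.append(traj.mu3[-1])
    out = {"mu2_0": float(np.mean(mu2_end)), "omega2": omega2, "omega3": omega3}
    out["mu3_0"] = float(np.mean(mu3_end)) if mu3_end else 1.0
    return out


# ---------------------------------------------------------------------------
# Condition-wise parameter extraction
# ---------------------------------------------------------------------------

def extract_condition_parameters(traj: Trajectories, labels: Sequence[str]) -> dict:
    """Per-condition summaries of alpha2, |eps2| and |eps3|.

    ``labels`` aligns one expected/unexpected label with each trial of the
    trajectory.  Learning rates are reported as magnitudes: under the
    alpha2 = 1/pi2 convention alpha2 is positive by construction, so the
    sign-flip rule for negative learning rates is a no-op (flagged here).
    """
    labels = np.asarray(list(labels), dtype=object)
    if len(labels) != len(traj.alpha2):
        raise ValueError("labels must align one-to-one with trajectory trials")

    out: dict[str, dict] = {"sign_rule_applied": False}
    for cond in ("expected", "unexpected"):
        mask = labels == cond
        if not mask.any():
            out[cond] = {"alpha2": np.nan, "abs_eps2": np.nan, "abs_eps3": np.nan, "n": 0}
            continue
        summary = {
            "alpha2": float(np.mean(np.abs(traj.alpha2[mask]))),
            "abs_eps2": float(np.mean(np.abs(traj.eps2[mask]))),
            "abs_eps3": float(np.mean(np.abs(traj.eps3[mask]))) if traj.eps3 is not None else np.nan,
            "n": int(mask.sum()),
        }
        out[cond] = summary
    return out
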