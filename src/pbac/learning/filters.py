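"""Trial-by-trial learning filters: binary HGF (2/3/4 levels), Rescorla-Wagner,
Sutton K1, and the unit-square sigmoid response model.

All filters consume a binary input sequence ``u`` (ball side, coded 1 for the
counterbalanced "most probable" side) and produce per-trial predictions of
``p(u = 1)`` before each outcome is seen, plus model-specific belief states.

The hierarchical Gaussian filter treats the outcome tendency as a hierarchy of
Gaussian random walks: level 2 carries the logit tendency of the binary
outcome, level 3 its log-volatility, and (in the 4-level variant) level 4 the
log-volatility of the volatility.  Belief updates are variational one-step
updates in which each level's prediction error is weighted by a precision
ratio.  The level-coupling strength kappa is fixed at 1 (zero prior variance),
matching the low-trial-count regime this toolkit targets.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "HGFParams",
    "Trajectories",
    "HGFInstabilityError",
    "hgf_filter",
    "rw_filter",
    "sk1_filter",
    "unitsq_sigmoid",
    "response_loglik",
]

_EPS = 1e-9


class HGFInstabilityError(FloatingPointError):
    """A belief update produced a non-positive predicted or posterior precision.

    Raised when a parameter point renders the variational updates invalid; the
    fitting layer treats such points as having log-joint minus infinity.
    """


@dataclass(frozen=True)
class HGFParams:
    """Parameters of the binary hierarchical Gaussian filter.

    ``omega2``/``omega3``/``omega4`` are the tonic log-volatility offsets of
    levels 2-4 (only those up to ``n_levels`` are used).  ``kappa`` couples
    each level to the one above and is fixed at 1 by default.  Initial beliefs
    are wide and relatively uninformative.
    """

    n_levels: int = 3
    kappa: float = 1.0
    omega2: float = -3.0
    omega3: float = -6.0
    omega4: float = -6.0
    mu2_0: float = 0.0
    sigma2_0: float = 1.0
    mu3_0: float = 1.0
    sigma3_0: float = 1.0
    mu4_0: float = 1.0
    sigma4_0: float = 1.0

    def __post_init__(self) -> None:
        if self.n_levels not in (2, 3, 4):
            raise ValueError(f"n_levels must be 2, 3 or 4, got {self.n_levels}")
        for name in ("sigma2_0", "sigma3_0", "sigma4_0"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class Trajectories:
    """Per-trial belief states and prediction errors from an HGF pass.

    ``eps2``/``eps3`` are the precision-weighted prediction errors, realised
    as the belief increments mu_i - muhat_i; ``alpha2`` is the effective
    level-2 learning rate 1 / pi2 applied to the level-1 prediction error.
    """

    muhat1: np.ndarray
    muhat2: np.ndarray
    mu2: np.ndarray
    sigma2: np.ndarray
    delta1: np.ndarray
    delta2: np.ndarray
    eps2: np.ndarray
    alpha2: np.ndarray
    muhat3: np.ndarray | None = None
    mu3: np.ndarray | None = None
    sigma3: np.ndarray | None = None
    eps3: np.ndarray | None = None
    mu4: np.ndarray | None = None
    sigma4: np.ndarray | None = None

    def to_frame(self):
        import pandas as pd

        data = {
            "muhat1": self.muhat1,
            "muhat2": self.muhat2,
            "mu2": self.mu2,
            "sigma2": self.sigma2,
            "delta1": self.delta1,
            "delta2": self.delta2,
            "eps2": self.eps2,
            "alpha2": self.alpha2,
        }
        if self.mu3 is not None:
            data.update(muhat3=self.muhat3, mu3=self.mu3, sigma3=self.sigma3, eps3=self.eps3)
        if self.mu4 is not None:
            data.update(mu4=self.mu4, sigma4=self.sigma4)
        return pd.DataFrame(data)


def _logistic(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + np.exp(-x))
    e = np.exp(x)
    return e / (1.0 + e)


@dataclass
class HGFState:
    """Mutable belief state between trials (used by the closed-loop agents)."""

    params: HGFParams
    mu2: float = field(init=False)
    sigma2: float = field(init=False)
    mu3: float = field(init=False)
    sigma3: float = field(init=False)
    mu4: float = field(init=False)
    sigma4: float = field(init=False)

    def __post_init__(self) -> None:
        p = self.params
        self.mu2, self.sigma2 = p.mu2_0, p.sigma2_0
        self.mu3, self.sigma3 = p.mu3_0, p.sigma3_0
        self.mu4, self.sigma4 = p.mu4_0, p.sigma4_0

    @property
    def muhat1(self) -> float:
        """Predicted probability of u = 1 before the next outcome."""
        return _logistic(self.mu2)

    def update(self, u: int) -> dict[str, float]:
        """One variational update; returns the trial record."""
        with np.errstate(over="ignore"):
            return self._update(u)

    def _update(self, u: int) -> dict[str, float]:
        p = self.params
        k = p.kappa
        n = p.n_levels

        muhat2 = self.mu2
        if n >= 3:
            sigmahat2 = self.sigma2 + np.exp(k * self.mu3 + p.omega2)
        else:
            sigmahat2 = self.sigma2 + np.exp(p.omega2)
        if not sigmahat2 > 0 or not np.isfinite(sigmahat2):
            raise HGFInstabilityError("non-positive or non-finite predicted variance at level 2")

        muhat1 = _logistic(muhat2)
        delta1 = u - muhat1
        pi2 = 1.0 / sigmahat2 + muhat1 * (1.0 - muhat1)
        if not pi2 > 0:
            raise HGFInstabilityError("non-positive posterior precision at level 2")
        mu2 = muhat2 + delta1 / pi2
        sigma2 = 1.0 / pi2
        delta2 = (sigma2 + (mu2 - muhat2) ** 2) / sigmahat2 - 1.0

        rec = {
            "muhat1": muhat1,
            "muhat2": muhat2,
            "mu2": mu2,
            "sigma2": sigma2,
            "delta1": delta1,
            "delta2": delta2,
            "eps2": mu2 - muhat2,
            "alpha2": 1.0 / pi2,
        }

        if n >= 3:
            if n >= 4:
                sigmahat3 = self.sigma3 + np.exp(k * self.mu4 + p.omega3)
            else:
                sigmahat3 = self.sigma3 + np.exp(p.omega3)
            if not sigmahat3 > 0 or not np.isfinite(sigmahat3):
                raise HGFInstabilityError("non-positive predicted variance at level 3")
            w2 = np.exp(k * self.mu3 + p.omega2) / sigmahat2
            pi3 = 1.0 / sigmahat3 + (k**2 / 2.0) * w2 * (w2 + (2.0 * w2 - 1.0) * delta2)
            if not pi3 > 0 or not np.isfinite(pi3):
                raise HGFInstabilityError("non-positive posterior precision at level 3")
            muhat3 = self.mu3
            mu3 = muhat3 + (k / (2.0 * pi3)) * w2 * delta2
            sigma3 = 1.0 / pi3
            delta3 = (sigma3 + (mu3 - muhat3) ** 2) / sigmahat3 - 1.0
            rec.update(muhat3=muhat3, mu3=mu3, sigma3=sigma3, eps3=mu3 - muhat3)

            if n >= 4:
                sigmahat4 = self.sigma4 + np.exp(p.omega4)
                if not sigmahat4 > 0 or not np.isfinite(sigmahat4):
                    raise HGFInstabilityError("non-positive predicted variance at level 4")
                w3 = np.exp(k * self.mu4 + p.omega3) / sigmahat3
                pi4 = 1.0 / sigmahat4 + (k**2 / 2.0) * w3 * (w3 + (2.0 * w3 - 1.0) * delta3)
                if not pi4 > 0 or not np.isfinite(pi4):
                    raise HGFInstabilityError("non-positive posterior precision at level 4")
                mu4 = self.mu4 + (k / (2.0 * pi4)) * w3 * delta3
                sigma4 = 1.0 / pi4
                rec.update(mu4=mu4, sigma4=sigma4)
                self.mu4, self.sigma4 = mu4, sigma4

            self.mu3, self.sigma3 = mu3, sigma3

        self.mu2, self.sigma2 = mu2, sigma2
        return rec


def hgf_filter(u: np.ndarray, params: HGFParams) -> Trajectories:
    """Run the binary HGF over an input sequence.

    Parameters
    ----------
    u
        Binary outcome sequence (0/1), 1 coding the most probable side.
    params
        Filter parameters; ``params.n_levels`` selects the 2-, 3- or 4-level
        variant.

    Raises
    ------
    HGFInstabilityError
        If any trial produces a non-positive precision; the fitting layer
        converts this to a rejected parameter point.
    """
    u = np.asarray(u)
    if u.ndim != 1 or not np.isin(u, (0, 1)).all():
        raise ValueError("u must be a 1-D binary sequence")
    state = HGFState(params)
    records = [state.update(int(ui)) for ui in u]

    def col(key: str) -> np.ndarray:
        return np.array([r[key] for r in records])

    traj = Trajectories(
        muhat1=col("muhat1"),
        muhat2=col("muhat2"),
        mu2=col("mu2"),
        sigma2=col("sigma2"),
        delta1=col("delta1"),
        delta2=col("delta2"),
        eps2=col("eps2"),
        alpha2=col("alpha2"),
    )
    if params.n_levels >= 3:
        traj.muhat3 = col("muhat3")
        traj.mu3 = col("mu3")
        traj.sigma3 = col("sigma3")
        traj.eps3 = col("eps3")
    if params.n_levels >= 4:
        traj.mu4 = col("mu4")
        traj.sigma4 = col("sigma4")
    return traj


# ---------------------------------------------------------------------------
# Associative learning models
# ---------------------------------------------------------------------------

def rw_filter(u: np.ndarray, alpha: float, v0: float = 0.5) -> np.ndarray:
    """Rescorla-Wagner delta rule with a fixed learning rate.

    Returns the prediction trajectory ``V`` of length ``len(u) + 1``:
    ``V[t]`` is the prediction for trial ``t`` (before its outcome), updated
    as ``V[t+1] = V[t] + alpha * (u[t] - V[t])``.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    u = np.asarray(u, dtype=float)
    V = np.empty(len(u) + 1)
    V[0] = v0
    for t in range(len(u)):
        V[t + 1] = V[t] + alpha * (u[t] - V[t])
    return V


def sk1_filter(
    u: np.ndarray,
    beta0: float,
    meta_rate: float,
    v0: float = 0.5,
    clip_rate: float = 1.0,
) -> dict[str, np.ndarray]:
    """Sutton's K1 incremental-delta-bar-delta scheme for a single cue.

    The log learning rate adapts to the correlation between the current
    prediction error and a trace ``h`` of recent updates:

    * ``delta(t) = u(t) - V(t)``
    * ``beta(t+1) = beta(t) + meta_rate * delta(t) * h(t)``
    * ``alpha(t+1) = exp(beta(t+1))`` (clipped at ``clip_rate``, flagged)
    * ``V(t+1) = V(t) + alpha(t+1) * delta(t)``
    * ``h(t+1) = (h(t) + alpha(t+1) * delta(t)) * max(0, 1 - alpha(t+1))``

    With ``meta_rate = 0`` this reduces exactly to Rescorla-Wagner with
    ``alpha = exp(beta0)``.

    Returns a dict with ``V`` (length ``len(u) + 1``), per-trial rates
    ``alpha``, and a ``clipped`` flag array.
    """
    if not np.isfinite(beta0) or not np.isfinite(meta_rate):
        raise ValueError("beta0 and meta_rate must be finite")
    u = np.asarray(u, dtype=float)
    n = len(u)
    V = np.empty(n + 1)
    rates = np.empty(n)
    clipped = np.zeros(n, dtype=bool)
    V[0] = v0
    beta = beta0
    h = 0.0
    for t in range(n):
        delta = u[t] - V[t]
        beta = beta + meta_rate * delta * h
        alpha = np.exp(beta)
        if alpha > clip_rate:
            alpha = clip_rate
            clipped[t] = True
        V[t + 1] = V[t] + alpha * delta
        h = (h + alpha * delta) * max(0.0, 1.0 - alpha)
        rates[t] = alpha
    return {"V": V, "alpha": rates, "clipped": clipped}


# ---------------------------------------------------------------------------
# Response model
# ---------------------------------------------------------------------------

def unitsq_sigmoid(muhat1: np.ndarray, zeta: float) -> np.ndarray:
    """Unit-square sigmoid: p(y=1) = m^zeta / (m^zeta + (1-m)^zeta).

    zeta > 0 is the decisiveness of the side choice: zeta = 1 is probability
    matching; zeta -> infinity approaches a deterministic argmax.
    """
    if not zeta > 0:
        raise ValueError(f"zeta must be > 0, got {zeta}")
    m = np.clip(np.asarray(muhat1, dtype=float), _EPS, 1.0 - _EPS)
    logit = zeta * (np.log(m) - np.log1p(-m))
    out = np.where(logit >= 0, 1.0 / (1.0 + np.exp(-np.abs(logit))),
                   np.exp(-np.abs(logit)) / (1.0 + np.exp(-np.abs(logit))))
    return out


def response_loglik(muhat1: np.ndarray, y: np.ndarray, zeta: float) -> float:
    """Log-likelihood of binary gaze responses under the unit-square sigmoid.

    ``muhat1`` values outside (0, 1) are clamped to [1e-9, 1 - 1e-9].
    """
    y = np.asarray(y)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("y must be binary")
    p1 = unitsq_sigmoid(muhat1, zeta)
    p1 = np.clip(p1, _EPS, 1.0 - _EPS)
    return float(np.sum(np.where(y == 1, np.log(p1), np.log1p(-p1))))
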