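"""Random-effects Bayesian model selection.

Given a participants x models table of log-model evidences, a variational
Dirichlet scheme estimates the population frequencies of the candidate
models.  Exceedance probabilities (the probability that each model is the
most frequent) are computed by Monte-Carlo over the fitted Dirichlet (with an
analytic Beta shortcut for two models), and protected against the chance that
all models are equally frequent via the Bayes omnibus risk:

    PXP_k = EP_k * (1 - BOR) + BOR / K
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import betaln, digamma, gammaln, logsumexp
from scipy.stats import beta as beta_dist

__all__ = ["BMSResult", "bms_random_effects", "family_comparison", "group_bayes_factor", "GroupBF"]


@dataclass
class BMSResult:
    """Posterior of the random-effects model-selection scheme."""

    model_names: list[str]
    dirichlet_alpha: np.ndarray
    expected_frequencies: np.ndarray
    exceedance_probabilities: np.ndarray
    bor: float
    protected_exceedance: np.ndarray
    free_energy_rfx: float
    free_energy_null: float

    def to_dict(self) -> dict:
        return {
            "model_names": list(self.model_names),
            "dirichlet_alpha": self.dirichlet_alpha.tolist(),
            "expected_frequencies": self.expected_frequencies.tolist(),
            "exceedance_probabilities": self.exceedance_probabilities.tolist(),
            "bor": float(self.bor),
            "protected_exceedance": self.protected_exceedance.tolist(),
        }


def _dirichlet_neg_entropy_terms(alpha: np.ndarray, elog_r: np.ndarray) -> float:
    """log-normaliser + (alpha-1)'E[log r] of a Dirichlet density."""
    return float(
        gammaln(alpha.sum()) - gammaln(alpha).sum() + ((alpha - 1.0) * elog_r).sum()
    )


def bms_random_effects(
    lme: np.ndarray,
    model_names: list[str] | None = None,
    alpha0: float = 1.0,
    n_draws: int = 1_000_000,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> BMSResult:
    """Variational random-effects model selection over an LME table.

    Parameters
    ----------
    lme
        Array of shape (n_participants, n_models) of log-model evidences.
    alpha0
        Symmetric Dirichlet prior count (1 = uniform).
    n_draws
        Monte-Carlo draws for exceedance probabilities when K > 2 (the K = 2
        case uses the exact Beta tail probability).
    """
    lme = np.asarray(lme, dtype=float)
    if lme.ndim != 2 or lme.shape[1] < 2:
        raise ValueError("lme must be a 2-D table with at least two models")
    if not np.all(np.isfinite(lme)):
        raise ValueError("non-finite log-model evidences")
    n, K = lme.shape
    names = model_names if model_names is not None else [f"m{k}" for k in range(K)]
    if len(names) != K:
        raise ValueError("model_names length mismatch")

    alpha = np.full(K, alpha0, dtype=float)
    u = np.empty((n, K))
    for _ in range(max_iter):
        elog_r = digamma(alpha) - digamma(alpha.sum())
        logu = lme + elog_r
        logu -= logsumexp(logu, axis=1, keepdims=True)
        u = np.exp(logu)
        alpha_new = alpha0 + u.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new

    elog_r = digamma(alpha) - digamma(alpha.sum())
    ef = alpha / alpha.sum()

    # variational free energy of the random-effects model
    with np.errstate(divide="ignore", invalid="ignore"):
        ent_u = -np.where(u > 0, u * np.log(u), 0.0).sum()
    f_rfx = (
        float((u * (lme + elog_r)).sum())
        + ent_u
        + _dirichlet_neg_entropy_terms(np.full(K, alpha0), elog_r)
        - _dirichlet_neg_entropy_terms(alpha, elog_r)
    )
    # evidence of the null (all models equally frequent)
    f_null = float(logsumexp(lme - np.log(K), axis=1).sum())
    bor = float(1.0 / (1.0 + np.exp(f_rfx - f_null)))

    if K == 2:
        # P(r1 > r2) = P(x > 0.5), x ~ Beta(alpha1, alpha2)
        ep1 = float(beta_dist.sf(0.5, alpha[0], alpha[1]))
        ep = np.array([ep1, 1.0 - ep1])
    else:
        rng = np.random.default_rng(seed)
        draws = rng.dirichlet(alpha, size=n_draws)
        winners = np.argmax(draws, axis=1)
        ep = np.bincount(winners, minlength=K) / n_draws

    pxp = ep * (1.0 - bor) + bor / K
    return BMSResult(
        model_names=list(names),
        dirichlet_alpha=alpha,
        expected_frequencies=ef,
        exceedance_probabilities=ep,
        bor=bor,
        protected_exceedance=pxp,
        free_energy_rfx=f_rfx,
        free_energy_null=f_null,
    )


def family_comparison(
    result: BMSResult,
    families: dict[str, list[str]],
    n_draws: int = 200_000,
    seed: int = 0,
) -> dict[str, dict[str, float]]:
    """Family-level inference by pooling Dirichlet mass over model families.

    Exceedance of a family is the Monte-Carlo probability that its summed
    population frequency is the largest; the protected value applies the
    omnibus risk with the family's share of the uniform prior.
    """
    K = len(result.model_names)
    idx = {name: i for i, name in enumerate(result.model_names)}
    fam_names = list(families)
    fam_idx = [[idx[m] for m in families[f]] for f in fam_names]
    covered = sorted(i for ids in fam_idx for i in ids)
    if covered != list(range(K)):
        raise ValueError("families must partition the model set")

    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(result.dirichlet_alpha, size=n_draws)
    fam_mass = np.stack([draws[:, ids].sum(axis=1) for ids in fam_idx], axis=1)
    winners = np.argmax(fam_mass, axis=1)
    ep = np.bincount(winners, minlength=len(fam_names)) / n_draws

    out = {}
    for j, f in enumerate(fam_names):
        share = len(fam_idx[j]) / K
        out[f] = {
            "expected_frequency": float(result.expected_frequencies[fam_idx[j]].sum()),
            "exceedance": float(ep[j]),
            "protected_exceedance": float(ep[j] * (1.0 - result.bor) + result.bor * share),
        }
    return out


@dataclass
class GroupBF:
    """Group Bayes factor from summed per-participant LME differences."""

    log_value: float
    value: float
    overflowed: bool


def group_bayes_factor(lme_a: np.ndarray, lme_b: np.ndarray) -> GroupBF:
    """exp(sum(lme_a - lme_b)); overflow is flagged and the log value kept."""
    lme_a = np.asarray(lme_a, dtype=float)
    lme_b = np.asarray(lme_b, dtype=float)
    if lme_a.shape != lme_b.shape:
        raise ValueError("LME vectors must have equal length")
    s = float(np.sum(lme_a - lme_b))
    if s > 700.0:
        return GroupBF(log_value=s, value=np.inf, overflowed=True)
    return GroupBF(log_value=s, value=float(np.exp(s)), overflowed=False)
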