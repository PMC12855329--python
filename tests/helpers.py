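"""Independent oracles used by the test suite.

The HGF oracle below is a direct, stateless transcription of the one-step
variational update equations, kept deliberately separate from the package's
implementation (no shared code) so trajectory agreement is a genuine
cross-check.
"""
from __future__ import annotations

import math


def hgf3_oracle_step(mu2, sigma2, mu3, sigma3, u, kappa, omega2, omega3):
    """One hand-derived 3-level update; returns the new states and record."""
    sigmahat2 = sigma2 + math.exp(kappa * mu3 + omega2)
    muhat1 = 1.0 / (1.0 + math.exp(-mu2))
    delta1 = u - muhat1
    pi2 = 1.0 / sigmahat2 + muhat1 * (1.0 - muhat1)
    mu2_new = mu2 + delta1 / pi2
    sigma2_new = 1.0 / pi2
    delta2 = (sigma2_new + (mu2_new - mu2) ** 2) / sigmahat2 - 1.0

    sigmahat3 = sigma3 + math.exp(omega3)
    w2 = math.exp(kappa * mu3 + omega2) / sigmahat2
    pi3 = 1.0 / sigmahat3 + (kappa**2 / 2.0) * w2 * (w2 + (2.0 * w2 - 1.0) * delta2)
    mu3_new = mu3 + (kappa / (2.0 * pi3)) * w2 * delta2
    sigma3_new = 1.0 / pi3
    return {
        "mu2": mu2_new,
        "sigma2": sigma2_new,
        "mu3": mu3_new,
        "sigma3": sigma3_new,
        "muhat1": muhat1,
        "alpha2": 1.0 / pi2,
        "eps2": mu2_new - mu2,
        "eps3": mu3_new - mu3,
    }


def hgf2_oracle_step(mu2, sigma2, u, omega2):
    """One hand-derived 2-level update."""
    sigmahat2 = sigma2 + math.exp(omega2)
    muhat1 = 1.0 / (1.0 + math.exp(-mu2))
    delta1 = u - muhat1
    pi2 = 1.0 / sigmahat2 + muhat1 * (1.0 - muhat1)
    return {"mu2": mu2 + delta1 / pi2, "sigma2": 1.0 / pi2, "muhat1": muhat1}
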