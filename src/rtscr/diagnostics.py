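"""Convergence diagnostics and model comparison: R-hat, effective sample size, WAIC."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

__all__ = ["rhat", "ess", "waic", "ConvergenceReport"]


def rhat(chains: np.ndarray) -> float:
    """Split Gelman-Rubin statistic (plain, not rank-normalized).

    ``chains`` is (m, n): m >= 2 chains of equal length n.  Each chain is
    split in half, between/within variances are compared; values near 1
    indicate the chains sample the same distribution.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("rhat needs >= 2 chains of equal length (m, n array)")
    m, n = chains.shape
    if n < 4:
        raise ValueError("chains too short to split")
    half = n // 2
    split = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    k, h = split.shape
    means = split.mean(axis=1)
    W = split.var(axis=1, ddof=1).mean()
    B = h * means.var(ddof=1)
    if W <= 0:
        return 1.0
    var_plus = (h - 1) / h * W + B / h
    return float(np.sqrt(var_plus / W))


def ess(chains: np.ndarray) -> float:
    """Effective sample size via Geyer's initial positive sequence estimator."""
    chains = np.atleast_2d(np.asarray(chains, dtype=float))
    m, n = chains.shape
    if n < 4:
        return float(m * n)
    # mean autocorrelation across chains
    acs = []
    for c in chains:
        c = c - c.mean()
        v = c.var()
        if v == 0:
            continue
        f = np.fft.rfft(c, 2 * n)
        ac = np.fft.irfft(f * np.conj(f))[:n].real / (v * n)
        acs.append(ac)
    if not acs:
        return float(m * n)
    rho = np.mean(acs, axis=0)
    # sum of adjacent pairs, truncated at first negative pair
    tau = 1.0
    t = 1
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair < 0:
            break
        tau += 2 * pair
        t += 2
    return float(m * n / max(tau, 1.0))


def waic(ll_pointwise: np.ndarray) -> dict:
    """Widely applicable information criterion from pointwise log-likelihood draws.

    ``ll_pointwise`` is (n_draws, n_units); the pointwise unit here is the
    detector.  Returns WAIC = -2 (lppd - p_waic) with p_waic the summed
    posterior variance of the pointwise terms.  Lower is better.
    """
    ll = np.asarray(ll_pointwise, dtype=float)
    if ll.ndim == 3:                    # (chains, draws, units)
        ll = ll.reshape(-1, ll.shape[-1])
    if ll.ndim != 2 or ll.shape[0] < 2:
        raise ValueError("waic needs >= 2 draws of pointwise log-likelihood")
    ndraw = ll.shape[0]
    lppd = float(np.sum(logsumexp(ll, axis=0) - np.log(ndraw)))
    p_waic = float(np.sum(ll.var(axis=0, ddof=1)))
    return {"waic": -2.0 * (lppd - p_waic), "lppd": lppd, "p_waic": p_waic}


@dataclass
class ConvergenceReport:
    """Per-parameter split R-hat and effective sample sizes, with a pass flag
    (all R-hat < 1.1).  With a single chain R-hat cannot be computed and the
    report flags convergence as not assessed rather than passing silently."""

    rhat: dict = field(default_factory=dict)
    ess: dict = field(default_factory=dict)
    threshold: float = 1.1

    @property
    def assessed(self) -> bool:
        return any(v is not None for v in self.rhat.values())

    @property
    def passed(self) -> bool:
        vals = [v for v in self.rhat.values() if v is not None]
        if not vals:
            return False
        return all(v < self.threshold for v in vals)

    def worst(self) -> tuple[str, float] | None:
        vals = {k: v for k, v in self.rhat.items() if v is not None}
        if not vals:
            return None
        k = max(vals, key=vals.get)
        return k, vals[k]
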