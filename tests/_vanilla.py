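"""Independent plain Poisson SCR sampler used as a cross-check oracle.

Deliberately written differently from the package sampler: per-individual
Python loops, full row log-likelihood recomputation, Metropolis flips for the
inclusion indicators.  Covers the no-thinning special case only (all samples
identified), so the rt-SCR model with theta = 1 and nnid = 0 must agree with
it distributionally.
"""

import math

import numpy as np


def vanilla_scr(y, X, mask, M, iterations, burn, thin, seed, sigma_max):
    rng = np.random.default_rng(seed)
    n, J = y.shape
    yfull = np.zeros((M, J))
    yfull[:n] = y
    detected = yfull.sum(1) > 0
    s = mask.sample_uniform(rng, M)
    z = detected.copy()
    z[n:] = rng.random(M - n) < 0.5
    sigma = sigma_max / 4
    mu0 = math.log(max(y.sum(), 1) / (max(n, 1) * J) + 1e-9)
    psi = 0.5

    def row_ll(i, s_i, sig, m0):
        d2 = ((X - s_i) ** 2).sum(1)
        lam = np.exp(m0) * np.exp(-d2 / (2 * sig**2))
        lam = np.maximum(lam, 1e-300)
        return float((yfull[i] * np.log(lam) - lam).sum())

    keep = {"N": [], "sigma": [], "mu0": [], "psi": []}
    ps, psig, pmu = sigma_max / 10, sigma_max / 10, 0.25
    for it in range(iterations):
        for i in range(M):
            prop = s[i] + rng.normal(0, ps, 2)
            if not mask.contains(prop[None])[0]:
                continue
            if not z[i]:
                s[i] = prop
                continue
            if math.log(rng.random()) < row_ll(i, prop, sigma, mu0) - row_ll(i, s[i], sigma, mu0):
                s[i] = prop
        sp = sigma + rng.normal(0, psig)
        if 0 < sp < sigma_max:
            d = sum(
                row_ll(i, s[i], sp, mu0) - row_ll(i, s[i], sigma, mu0)
                for i in range(M) if z[i]
            )
            if math.log(rng.random()) < d:
                sigma = sp
        mp = mu0 + rng.normal(0, pmu)
        d = sum(
            row_ll(i, s[i], sigma, mp) - row_ll(i, s[i], sigma, mu0)
            for i in range(M) if z[i]
        ) - (mp**2 - mu0**2) / (2 * 100.0)
        if math.log(rng.random()) < d:
            mu0 = mp
        for i in range(M):
            if detected[i]:
                continue
            d2 = ((X - s[i]) ** 2).sum(1)
            Lam = float((np.exp(mu0) * np.exp(-d2 / (2 * sigma**2))).sum())
            cur = (math.log(psi) - Lam) if z[i] else math.log(1 - psi)
            new = math.log(1 - psi) if z[i] else (math.log(psi) - Lam)
            if math.log(rng.random()) < new - cur:
                z[i] = not z[i]
        psi = rng.beta(1 + z.sum(), 1 + M - z.sum())
        if it >= burn and (it - burn) % thin == 0:
            keep["N"].append(int(z.sum()))
            keep["sigma"].append(sigma)
            keep["mu0"].append(mu0)
            keep["psi"].append(psi)
    return {k: np.array(v) for k, v in keep.items()}
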