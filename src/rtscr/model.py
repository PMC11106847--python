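"""Random-thinning spatial capture-recapture (rt-SCR) model and MCMC sampler.

The model treats genotyped-but-unidentified samples as a random thinning of
the true encounter histories.  For individual i with activity center s_i and
detector j at x_j (single occasion, K = 1):

    y_true[i, j] ~ Poisson(z_i * lambda_ij)
    lambda_ij    = lambda0_j * exp(-d_ij^2 / (2 sigma^2))
    log lambda0_j = beta * L_j + eps_j,    eps_j ~ Normal(mu0, sigma_p^2)
    y_id[i, j]   ~ Binomial(y_true[i, j], theta)

with activity centers uniform over a habitat mask, data augmentation
(z_i ~ Bernoulli(psi), i = 1..M, N = sum z_i) and the identity-retention
probability theta.  Only the per-detector totals of unidentified samples,
nnid_j = sum_i (y_true - y_id)[i, j], are observed; the individual non-ID
counts are latent and are updated with a constrained Metropolis move that
shifts single units between active individuals, preserving the totals by
construction.

The sampler is a hand-written Metropolis-within-Gibbs scheme; see ``fit``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.special import gammaln

from .geometry import EncounterData, HabitatMask, SurveyDesign

__all__ = [
    "RandomThinningSCR",
    "Priors",
    "RtScrState",
    "detection_rate",
    "baseline_rate",
]


def detection_rate(d, lambda0, sigma):
    """Half-normal expected encounter rate at distance d from the activity center.

    lambda(d) = lambda0 * exp(-d^2 / (2 sigma^2)); lambda0 is the basal rate at
    d = 0 (activity center on the detector).
    """
    d = np.asarray(d, dtype=float)
    lambda0 = np.asarray(lambda0, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    if np.any(lambda0 < 0):
        raise ValueError("lambda0 must be non-negative")
    if not np.all(np.asarray(sigma) > 0):
        raise ValueError("sigma must be positive")
    return lambda0 * np.exp(-(d**2) / (2.0 * np.asarray(sigma, dtype=float) ** 2))


def baseline_rate(L_km, beta, epsilon):
    """Detector baseline rate: lambda0_j = exp(beta * L_j + eps_j), L_j in km."""
    return np.exp(beta * np.asarray(L_km, dtype=float) + np.asarray(epsilon, dtype=float))


@dataclass(frozen=True)
class Priors:
    """Prior hyperparameters (all configurable; defaults are weakly informative).

    psi, theta     : Beta(a, b)
    sigma          : Uniform(0, sigma_max) in meters; None -> half mask diagonal
    beta, mu0      : Normal(mean, sd)
    sigma_p        : Uniform(0, sigma_p_max)
    """

    psi: tuple[float, float] = (1.0, 1.0)
    theta: tuple[float, float] = (1.0, 1.0)
    sigma_max: float | None = None
    beta: tuple[float, float] = (0.0, 10.0)
    mu0: tuple[float, float] = (0.0, 10.0)
    sigma_p_max: float = 5.0


@dataclass
class RtScrState:
    """One full state of the rt-SCR Markov chain (internal units: meters)."""

    sigma: float
    theta: float
    psi: float
    beta: float
    mu0: float
    sigma_p: float
    eps: np.ndarray          # (J,)
    z: np.ndarray            # (M,) bool
    s: np.ndarray            # (M, 2)
    y_noid: np.ndarray       # (M, J) int

    def copy(self) -> "RtScrState":
        return RtScrState(
            self.sigma, self.theta, self.psi, self.beta, self.mu0, self.sigma_p,
            self.eps.copy(), self.z.copy(), self.s.copy(), self.y_noid.copy(),
        )


class RandomThinningSCR:
    """Random-thinning SCR model for single-occasion count data.

    Parameters
    ----------
    encounters : EncounterData
        Identified counts y_id (n x J) and unidentified per-detector totals nnid.
    design : SurveyDesign, optional
        Detector geometry; ``detectors``/``effort_km``/``mask`` may be given
        directly instead.
    M : int
        Data-augmentation size (default 4 * n detected individuals).
    effort_covariate, trap_random_effect : bool
        Switch the three nested detection models: null (both False), effort
        covariate only, or effort + per-trap normal random effect (default).

    Use ``fit`` to run the MCMC; it returns an :class:`~rtscr.results.RtScrResults`.
    """

    def __init__(
        self,
        encounters: EncounterData,
        design: SurveyDesign | None = None,
        *,
        detectors: np.ndarray | None = None,
        effort_km: np.ndarray | None = None,
        mask: HabitatMask | None = None,
        M: int | None = None,
        priors: Priors | None = None,
        effort_covariate: bool = True,
        trap_random_effect: bool = True,
    ):
        self.encounters = encounters
        if design is not None:
            detectors = design.detectors
            effort_km = design.detector_effort
            mask = design.mask
        if detectors is None or mask is None:
            raise ValueError("either a SurveyDesign or detectors+mask must be given")
        self.design = design
        self.X = np.asarray(detectors, dtype=float)
        self.J = len(self.X)
        if encounters.n_detectors != self.J:
            raise ValueError(
                f"encounter data has {encounters.n_detectors} detectors, design has {self.J}"
            )
        self.L = np.zeros(self.J) if effort_km is None else np.asarray(effort_km, float)
        self.mask = mask
        self.n = encounters.n_individuals
        self.M = int(M) if M is not None else max(4 * max(self.n, 1), self.n + 4)
        if self.M <= self.n:
            raise ValueError("augmentation size M must exceed the number detected")
        self.priors = priors or Priors()
        if self.priors.sigma_max is None:
            self.priors = replace(self.priors, sigma_max=mask.diagonal / 2.0)
        self.effort_covariate = effort_covariate
        self.trap_random_effect = trap_random_effect
        # full (M, J) identified counts: augmented rows are all zero
        self.y_id_full = np.zeros((self.M, self.J), dtype=int)
        self.y_id_full[: self.n] = encounters.y_id
        self.nnid = encounters.nnid.astype(int)
        self._sum_yid = int(self.y_id_full.sum())
        self._sum_nnid = int(self.nnid.sum())

    @classmethod
    def from_design(
        cls,
        design: SurveyDesign,
        encounters: EncounterData,
        prune_unsurveyed: bool = True,
        **kwargs,
    ) -> "RandomThinningSCR":
        """Build a model from a full-grid design + encounter data, optionally
        dropping detectors with zero effort (zero-count surveyed cells are kept)."""
        if prune_unsurveyed:
            design = design.retain_surveyed()
            if encounters.n_detectors != len(design.active):
                keep = design.active
                if encounters.y_id[:, np.setdiff1d(np.arange(encounters.n_detectors), keep)].sum() or \
                   encounters.nnid[np.setdiff1d(np.arange(encounters.n_detectors), keep)].sum():
                    raise ValueError("samples found in cells with zero effort; cannot prune")
                encounters = encounters.subset_detectors(keep)
        return cls(encounters, design, **kwargs)

    # ------------------------------------------------------------------
    # likelihood
    # ------------------------------------------------------------------
    def _loglam0(self, state: RtScrState) -> np.ndarray:
        out = state.beta * self.L + state.eps
        return out

    def _lam(self, state: RtScrState) -> np.ndarray:
        """(M, J) expected rates for *all* augmented individuals (ignoring z)."""
        d2 = ((state.s[:, None, :] - self.X[None, :, :]) ** 2).sum(-1)
        return np.exp(self._loglam0(state)[None, :] - d2 / (2.0 * state.sigma**2))

    def log_likelihood(self, state: RtScrState, pointwise: bool = False):
        """Log-likelihood of the data + latent counts at a given state.

        Returns the per-detector terms (Poisson for y_true of active
        individuals plus binomial thinning terms) if ``pointwise``; their sum
        otherwise.  Raises if the state violates the non-ID constraint
        sum_i y_noid[i, j] = nnid[j] or puts counts on inactive individuals.
        """
        y_noid = state.y_noid
        if not np.array_equal(y_noid.sum(axis=0), self.nnid):
            raise ValueError("state violates the constraint sum_i y_noid[:, j] = nnid[j]")
        if (y_noid < 0).any():
            raise ValueError("negative latent counts")
        y_true = self.y_id_full + y_noid
        if (y_true[~state.z] != 0).any():
            raise ValueError("inactive individuals must have zero encounters")
        lam = self._lam(state)
        z = state.z
        loglam = np.log(lam[z])
        pois = y_true[z] * loglam - lam[z] - gammaln(y_true[z] + 1)
        th = state.theta
        yt, yi = y_true[z], self.y_id_full[z]
        with np.errstate(divide="ignore", invalid="ignore"):
            binom = (
                gammaln(yt + 1) - gammaln(yi + 1) - gammaln(yt - yi + 1)
                + np.where(yi > 0, yi * np.log(th), 0.0)
                + np.where(yt - yi > 0, (yt - yi) * np.log1p(-th), 0.0)
            )
        per_detector = pois.sum(axis=0) + binom.sum(axis=0)
        return per_detector if pointwise else float(per_detector.sum())

    # ------------------------------------------------------------------
    # fitting
    # ------------------------------------------------------------------
    def fit(
        self,
        iterations: int = 20_000,
        burn_in: int = 5_000,
        thin: int = 5,
        chains: int = 3,
        seed: int | None = 0,
        *,
        full_settings: bool = False,
        fixed: dict | None = None,
        sigma_grid: Sequence[float] | None = None,
        theta_grid: Sequence[float] | None = None,
        allocation_moves: int = 2,
        progress: bool = False,
    ):
        """Run the Metropolis-within-Gibbs sampler and return an RtScrResults.

        Update blocks per sweep: (1) joint random-walk update of all activity
        centers with off-mask rejection; (2) inclusion indicators z by their
        exact Bernoulli full conditional and psi by a conjugate Beta draw;
        (3) random-walk updates of sigma (log scale), beta, mu0, sigma_p and a
        vectorized per-trap update of eps; (4) a conjugate Beta draw for theta;
        (5) the constrained single-unit reallocation move for the latent
        non-ID counts at every detector with nnid_j > 0.

        ``fixed`` may pin any of sigma/theta/psi/beta/mu0/sigma_p (scalars),
        ``s`` ((M, 2) array) or ``z`` ((M,) bool array); pinned blocks are
        skipped.  ``sigma_grid``/``theta_grid`` replace the continuous update
        by an exact Gibbs draw over a discrete grid (used for enumeration
        cross-checks).  ``full_settings`` switches to 3 chains of 250,000
        iterations, 10,000 burn-in, thinning by 5.
        """
        from .results import RtScrResults  # local import to avoid a cycle

        if full_settings:
            iterations, burn_in, thin, chains = 250_000, 10_000, 5, 3
        if iterations <= burn_in:
            raise ValueError("iterations must exceed burn_in")
        if thin < 1:
            raise ValueError("thin must be >= 1")
        fixed = dict(fixed or {})
        ss = np.random.SeedSequence(seed)
        chain_seeds = ss.spawn(chains)
        chain_draws = []
        for c in range(chains):
            rng = np.random.default_rng(chain_seeds[c])
            chain_draws.append(
                self._run_chain(
                    rng, iterations, burn_in, thin, fixed, sigma_grid, theta_grid,
                    allocation_moves, progress,
                )
            )
        draws = {
            k: np.stack([d[k] for d in chain_draws]) for k in chain_draws[0]
        }
        settings = dict(iterations=iterations, burn_in=burn_in, thin=thin,
                        chains=chains, seed=seed)
        res = RtScrResults(self, draws, settings)
        if res.max_N_fraction > 0.9 and res.prob_N_near_M > 0.01:
            warnings.warn(
                "posterior mass near the augmentation bound M: increase M",
                RuntimeWarning,
            )
        return res

    # -- initialization -------------------------------------------------
    def _initial_state(self, rng: np.random.Generator, fixed: dict) -> RtScrState:
        M, J, n = self.M, self.J, self.n
        z = np.zeros(M, dtype=bool)
        z[:n] = True
        z[n:] = rng.random(M - n) < 0.3
        if not z.any():
            z[0] = True
        s = self.mask.sample_uniform(rng, M)
        # detected individuals start at the (habitable pixel nearest to the)
        # effort-weighted centroid of their detections
        for i in range(n):
            w = self.y_id_full[i].astype(float)
            if w.sum() > 0:
                c = (self.X * w[:, None]).sum(0) / w.sum()
                if self.mask.contains(c[None])[0]:
                    s[i] = c
                else:
                    centers = self.mask.habitable_centers()
                    s[i] = centers[np.argmin(((centers - c) ** 2).sum(1))]
        sigma0 = fixed.get("sigma", max(self.mask.diagonal / 8.0, 1e-3))
        theta0 = fixed.get(
            "theta",
            (self._sum_yid + 1.0) / (self._sum_yid + self._sum_nnid + 2.0),
        )
        tot = self._sum_yid + self._sum_nnid
        mu0_0 = fixed.get("mu0", math.log(max(tot, 1) / max(z.sum() * J, 1) + 1e-12))
        beta0 = fixed.get("beta", 0.0)
        sp0 = fixed.get("sigma_p", 1.0)
        eps = np.full(J, mu0_0)
        psi0 = fixed.get("psi", max(z.mean(), 1.0 / M))
        state = RtScrState(
            float(sigma0), float(theta0), float(psi0), float(beta0),
            float(mu0_0), float(sp0), eps, z, s, np.zeros((M, J), dtype=int),
        )
        if "s" in fixed:
            state.s = np.array(fixed["s"], dtype=float)
        if "z" in fixed:
            state.z = np.array(fixed["z"], dtype=bool)
        # allocate the observed non-ID totals among active individuals
        lam = self._lam(state)
        act = np.nonzero(state.z)[0]
        for j in np.nonzero(self.nnid)[0]:
            w = lam[act, j]
            w = w / w.sum() if w.sum() > 0 else np.full(len(act), 1.0 / len(act))
            alloc = rng.multinomial(self.nnid[j], w)
            state.y_noid[act, j] = alloc
        return state

    # -- one chain -------------------------------------------------------
    def _run_chain(
        self, rng, iterations, burn_in, thin, fixed, sigma_grid, theta_grid,
        allocation_moves, progress,
    ) -> dict:
        M, J, n = self.M, self.J, self.n
        pri = self.priors
        st = self._initial_state(rng, fixed)
        X, L, yid = self.X, self.L, self.y_id_full
        self._Lbar = float(L.mean())
        re_model = self.trap_random_effect
        use_beta = self.effort_covariate and "beta" not in fixed

        # cached quantities
        D2 = ((st.s[:, None, :] - X[None, :, :]) ** 2).sum(-1)       # (M, J)
        loglam0 = st.beta * L + st.eps                               # (J,)
        G = np.exp(-D2 / (2 * st.sigma**2))                          # (M, J)
        lam0 = np.exp(loglam0)
        y_true = yid + st.y_noid

        # proposal scales, adapted during burn-in then frozen
        tune = {"s": self.mask.diagonal / 20, "sigma": 0.2, "beta": 0.3,
                "mu0": 0.3, "sigma_p": 0.3, "eps": 0.5}
        acc = {k: [0, 0] for k in tune}

        nkeep = (iterations - burn_in) // thin
        out = {
            "N": np.empty(nkeep), "psi": np.empty(nkeep), "sigma": np.empty(nkeep),
            "theta": np.empty(nkeep), "beta": np.empty(nkeep), "mu0": np.empty(nkeep),
            "sigma_p": np.empty(nkeep), "loglik": np.empty(nkeep),
            "expected_detections": np.empty(nkeep),
            "ll_pointwise": np.empty((nkeep, J)),
            "s": np.empty((nkeep, M, 2)), "z": np.empty((nkeep, M), dtype=bool),
            "eps": np.empty((nkeep, J)),
            "y_noid_draws": np.empty((nkeep, M, J), dtype=np.int32) if M * J <= 4000 else None,
        }
        if out["y_noid_draws"] is None:
            del out["y_noid_draws"]
        kept = 0

        theta_a, theta_b = pri.theta
        psi_a, psi_b = pri.psi
        log_theta_fixed = "theta" in fixed and theta_grid is None
        cols_nnid = np.nonzero(self.nnid)[0]

        for it in range(iterations):
            z = st.z
            zf = z[:, None]

            # ---- (1) activity centers, all rows at once -----------------
            if "s" not in fixed:
                prop = st.s + rng.normal(0, tune["s"], size=(M, 2))
                onmask = self.mask.contains(prop)
                d2p = ((prop[:, None, :] - X[None, :, :]) ** 2).sum(-1)
                Gp = np.exp(-d2p / (2 * st.sigma**2))
                dll = (
                    -(y_true * (d2p - D2)).sum(1) / (2 * st.sigma**2)
                    - (lam0[None, :] * (Gp - G)).sum(1)
                )
                accept = onmask & (np.log(rng.random(M)) < np.where(z, dll, 0.0))
                if accept.any():
                    st.s[accept] = prop[accept]
                    D2[accept] = d2p[accept]
                    G[accept] = Gp[accept]
                acc["s"][0] += int((accept & z).sum())
                acc["s"][1] += int(z.sum())

            # ---- (2) sigma ----------------------------------------------
            if sigma_grid is not None:
                lls = np.empty(len(sigma_grid))
                ytz = y_true[z]
                for g, sg in enumerate(sigma_grid):
                    Gg = np.exp(-D2[z] / (2 * sg**2))
                    lamg = lam0[None, :] * Gg
                    lls[g] = (ytz * np.log(lamg) - lamg).sum()
                p = np.exp(lls - lls.max())
                st.sigma = float(sigma_grid[rng.choice(len(sigma_grid), p=p / p.sum())])
                G = np.exp(-D2 / (2 * st.sigma**2))
            elif "sigma" not in fixed:
                lsp = math.log(st.sigma) + rng.normal(0, tune["sigma"])
                sp_ = math.exp(lsp)
                if sp_ < pri.sigma_max:
                    Gp = np.exp(-D2 / (2 * sp_**2))
                    dll = (
                        -(y_true[z] * D2[z]).sum() * (1 / (2 * sp_**2) - 1 / (2 * st.sigma**2))
                        - (lam0[None, :] * (Gp[z] - G[z])).sum()
                    )
                    # log-normal proposal Jacobian
                    if math.log(rng.random()) < dll + (lsp - math.log(st.sigma)):
                        st.sigma = sp_
                        G = Gp
                        acc["sigma"][0] += 1
                acc["sigma"][1] += 1

            colsum_yt = (y_true * zf).sum(0)      # (J,)
            colsum_G = (G * zf).sum(0)            # (J,)

            # ---- (3) beta -----------------------------------------------
            if use_beta:
                bp = st.beta + rng.normal(0, tune["beta"])
                lam0p = np.exp(bp * L + st.eps)
                dll = (colsum_yt * (bp - st.beta) * L).sum() - ((lam0p - lam0) * colsum_G).sum()
                dll += (
                    -((bp - pri.beta[0]) ** 2 - (st.beta - pri.beta[0]) ** 2)
                    / (2 * pri.beta[1] ** 2)
                )
                if math.log(rng.random()) < dll:
                    st.beta = bp
                    lam0 = lam0p
                    acc["beta"][0] += 1
                acc["beta"][1] += 1

            # ---- (3b) joint ridge move: beta and the trap effects are
            # nearly confounded (log lam0 = beta L + eps), so translate along
            # beta' = beta + delta, eps' = eps - delta * Lbar, mu0' likewise.
            if use_beta and re_model and "mu0" not in fixed:
                delta = rng.normal(0, tune["beta"])
                Lbar = self._Lbar
                bp = st.beta + delta
                ep = st.eps - delta * Lbar
                mp = st.mu0 - delta * Lbar
                lam0p = np.exp(bp * L + ep)
                dll = (colsum_yt * delta * (L - Lbar)).sum() - ((lam0p - lam0) * colsum_G).sum()
                dll += (
                    -((bp - pri.beta[0]) ** 2 - (st.beta - pri.beta[0]) ** 2)
                    / (2 * pri.beta[1] ** 2)
                    - ((mp - pri.mu0[0]) ** 2 - (st.mu0 - pri.mu0[0]) ** 2)
                    / (2 * pri.mu0[1] ** 2)
                )
                if math.log(rng.random()) < dll:
                    st.beta, st.eps, st.mu0 = bp, ep, mp
                    lam0 = lam0p

            # ---- (4) trap effects / intercept ---------------------------
            if re_model:
                # eps_j are conditionally independent given everything else
                ep = st.eps + rng.normal(0, tune["eps"], size=J)
                lam0p = np.exp(st.beta * L + ep)
                dll = (
                    colsum_yt * (ep - st.eps)
                    - (lam0p - lam0) * colsum_G
                    - ((ep - st.mu0) ** 2 - (st.eps - st.mu0) ** 2) / (2 * st.sigma_p**2)
                )
                accept = np.log(rng.random(J)) < dll
                st.eps[accept] = ep[accept]
                lam0 = np.exp(st.beta * L + st.eps)
                acc["eps"][0] += int(accept.sum())
                acc["eps"][1] += J
                if "mu0" not in fixed:
                    mp = st.mu0 + rng.normal(0, tune["mu0"])
                    dll = (
                        -((st.eps - mp) ** 2 - (st.eps - st.mu0) ** 2).sum()
                        / (2 * st.sigma_p**2)
                        - ((mp - pri.mu0[0]) ** 2 - (st.mu0 - pri.mu0[0]) ** 2)
                        / (2 * pri.mu0[1] ** 2)
                    )
                    if math.log(rng.random()) < dll:
                        st.mu0 = mp
                        acc["mu0"][0] += 1
                    acc["mu0"][1] += 1
                if "sigma_p" not in fixed:
                    spp = st.sigma_p + rng.normal(0, tune["sigma_p"])
                    if 0 < spp < pri.sigma_p_max:
                        dll = (
                            -J * (math.log(spp) - math.log(st.sigma_p))
                            - ((st.eps - st.mu0) ** 2).sum()
                            * (1 / (2 * spp**2) - 1 / (2 * st.sigma_p**2))
                        )
                        if math.log(rng.random()) < dll:
                            st.sigma_p = spp
                            acc["sigma_p"][0] += 1
                    acc["sigma_p"][1] += 1
            else:
                if "mu0" not in fixed:
                    mp = st.mu0 + rng.normal(0, tune["mu0"])
                    lam0p = np.exp(st.beta * L + mp)
                    dll = (colsum_yt * (mp - st.mu0)).sum() - ((lam0p - lam0) * colsum_G).sum()
                    dll += (
                        -((mp - pri.mu0[0]) ** 2 - (st.mu0 - pri.mu0[0]) ** 2)
                        / (2 * pri.mu0[1] ** 2)
                    )
                    if math.log(rng.random()) < dll:
                        st.mu0 = mp
                        st.eps[:] = mp
                        lam0 = lam0p
                        acc["mu0"][0] += 1
                    acc["mu0"][1] += 1

            # ---- (5) theta: conjugate Beta draw -------------------------
            if theta_grid is not None:
                lls = np.array(
                    [
                        self._sum_yid * math.log(tg) + self._sum_nnid * math.log1p(-tg)
                        if 0 < tg < 1
                        else (0.0 if (tg == 1 and self._sum_nnid == 0) else -np.inf)
                        for tg in theta_grid
                    ]
                )
                p = np.exp(lls - lls.max())
                st.theta = float(theta_grid[rng.choice(len(theta_grid), p=p / p.sum())])
            elif not log_theta_fixed:
                st.theta = rng.beta(theta_a + self._sum_yid, theta_b + self._sum_nnid)

            # ---- (6) constrained reallocation of latent non-ID counts ---
            lam_rows = lam0[None, :] * G
            act = np.nonzero(z)[0]
            if len(act) >= 2:
                for j in cols_nnid:
                    col = st.y_noid[:, j]
                    for _ in range(allocation_moves):
                        donors = act[col[act] > 0]
                        if len(donors) == 0:
                            break
                        a = donors[rng.integers(len(donors))]
                        b = act[rng.integers(len(act))]
                        if b == a:
                            continue
                        D = len(donors)
                        Dp = D - (col[a] == 1) + (col[b] == 0)
                        logr = (
                            math.log(lam_rows[b, j]) - math.log(lam_rows[a, j])
                            + math.log(col[a]) - math.log(col[b] + 1)
                            + math.log(D) - math.log(Dp)
                        )
                        if math.log(rng.random()) < logr:
                            col[a] -= 1
                            col[b] += 1
                            y_true[a, j] -= 1
                            y_true[b, j] += 1

            # ---- (7) z and psi ------------------------------------------
            if "z" not in fixed:
                eligible = y_true.sum(1) == 0
                eligible[:n] = False          # detected individuals stay in
                if eligible.any():
                    Lam = lam_rows[eligible].sum(1)
                    p1 = st.psi * np.exp(-Lam)
                    p1 = p1 / (p1 + (1 - st.psi))
                    st.z[eligible] = rng.random(eligible.sum()) < p1
                st.z[y_true.sum(1) > 0] = True
            if "psi" not in fixed:
                k = int(st.z.sum())
                st.psi = rng.beta(psi_a + k, psi_b + M - k)

            # ---- adaptation during burn-in ------------------------------
            if it < burn_in and (it + 1) % 100 == 0:
                for kname, (na, nt) in acc.items():
                    if nt > 0:
                        rate = na / nt
                        tune[kname] *= math.exp(1.5 * (rate - 0.38) / math.sqrt(1 + it / 100))
                    acc[kname] = [0, 0]

            # ---- record --------------------------------------------------
            if it >= burn_in and (it - burn_in) % thin == 0 and kept < nkeep:
                z = st.z
                lamz = lam_rows[z]
                out["N"][kept] = z.sum()
                out["psi"][kept] = st.psi
                out["sigma"][kept] = st.sigma / 1000.0          # report in km
                out["theta"][kept] = st.theta
                out["beta"][kept] = st.beta
                out["mu0"][kept] = st.mu0
                out["sigma_p"][kept] = st.sigma_p
                out["expected_detections"][kept] = lamz.sum()
                ll = self._pointwise_ll(st, y_true, lamz)
                out["ll_pointwise"][kept] = ll
                out["loglik"][kept] = ll.sum()
                out["s"][kept] = st.s
                out["z"][kept] = z
                out["eps"][kept] = st.eps
                if "y_noid_draws" in out:
                    out["y_noid_draws"][kept] = st.y_noid
                kept += 1

        return out

    def _pointwise_ll(self, st: RtScrState, y_true: np.ndarray, lamz: np.ndarray) -> np.ndarray:
        """Per-detector log-likelihood terms (Poisson + binomial thinning)."""
        z = st.z
        yt, yi = y_true[z], self.y_id_full[z]
        pois = yt * np.log(lamz) - lamz - gammaln(yt + 1)
        th = st.theta
        binom = gammaln(yt + 1) - gammaln(yi + 1) - gammaln(yt - yi + 1)
        if th >= 1.0:
            binom = np.where(yt == yi, binom, -np.inf)
        elif th <= 0.0:
            binom = np.where(yi == 0, binom, -np.inf)
        else:
            binom = binom + yi * math.log(th) + (yt - yi) * math.log1p(-th)
        return pois.sum(0) + binom.sum(0)
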