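"""Results container for fitted rt-SCR models: summaries, diagnostics, derived output."""

from __future__ import annotations

import json
from typing import Sequence

import numpy as np
import pandas as pd

from . import derived as _derived
from .diagnostics import ConvergenceReport, ess, rhat, waic as _waic

__all__ = ["RtScrResults"]

_SCALARS = ["N", "psi", "sigma", "theta", "beta", "mu0", "sigma_p"]


class RtScrResults:
    """Posterior draws and derived quantities from :meth:`RandomThinningSCR.fit`.

    ``draws[param]`` has shape (chains, n_retained) for scalar parameters;
    latent blocks keep their own trailing shape (``s`` is (chains, n, M, 2),
    ``eps`` is (chains, n, J), ``ll_pointwise`` is (chains, n, J)).  sigma is
    reported in km; the detector geometry stays in meters.
    """

    def __init__(self, model, draws: dict, settings: dict):
        self.model = model
        self.draws = draws
        self.settings = settings

    # -- basic access ---------------------------------------------------
    def get(self, param: str) -> np.ndarray:
        """Flattened draws (all chains concatenated) of a scalar parameter."""
        return self.draws[param].reshape(-1)

    @property
    def n_draws(self) -> int:
        return int(np.prod(self.draws["N"].shape))

    @property
    def max_N_fraction(self) -> float:
        return float(self.get("N").max() / self.model.M)

    @property
    def prob_N_near_M(self) -> float:
        return float(np.mean(self.get("N") > 0.9 * self.model.M))

    # -- summaries --------------------------------------------------------
    def summary(self, params: Sequence[str] | None = None) -> pd.DataFrame:
        """Posterior mean, SD and 2.5/50/97.5 percentiles per parameter."""
        params = list(params) if params is not None else [
            p for p in _SCALARS
            if p in self.draws and (p != "beta" or self.model.effort_covariate)
            and (p != "sigma_p" or self.model.trap_random_effect)
        ]
        rows = {}
        for p in params:
            x = self.get(p)
            rows[p] = {
                "mean": x.mean(),
                "sd": x.std(ddof=1),
                "q2.5": np.percentile(x, 2.5),
                "q50": np.percentile(x, 50),
                "q97.5": np.percentile(x, 97.5),
            }
        return pd.DataFrame(rows).T[["mean", "sd", "q2.5", "q50", "q97.5"]]

    def credible_interval(self, param: str, level: float = 0.95) -> tuple[float, float]:
        x = self.get(param)
        a = 100 * (1 - level) / 2
        return float(np.percentile(x, a)), float(np.percentile(x, 100 - a))

    # -- diagnostics ------------------------------------------------------
    def convergence(self, params: Sequence[str] | None = None) -> ConvergenceReport:
        params = list(params) if params is not None else [
            p for p in _SCALARS if p in self.draws
        ]
        rep = ConvergenceReport()
        multi = self.draws["N"].shape[0] >= 2
        for p in params:
            arr = self.draws[p]
            if arr.std() == 0:
                continue        # fixed parameter: nothing to assess
            rep.rhat[p] = rhat(arr) if multi else None
            rep.ess[p] = ess(arr)
        return rep

    def waic(self) -> dict:
        """WAIC with the detector as the pointwise unit."""
        return _waic(self.draws["ll_pointwise"])

    # -- derived quantities ------------------------------------------------
    def derived_density(self, area_km2: float, river_km: float):
        return _derived.derived_density(self.get("N"), area_km2, river_km)

    def movement_radius(self, quantile: float = 0.95) -> dict:
        r = _derived.movement_radius(self.get("sigma"), quantile)
        return {
            "mean": float(r.mean()),
            "sd": float(r.std(ddof=1)),
            "q2.5": float(np.percentile(r, 2.5)),
            "q97.5": float(np.percentile(r, 97.5)),
        }

    def ac_draws(self, individual: int | str) -> np.ndarray:
        """Posterior activity-center draws of one detected individual."""
        ids = self.model.encounters.individual_ids
        i = ids.index(individual) if isinstance(individual, str) else int(individual)
        return self.draws["s"][:, :, i, :].reshape(-1, 2)

    def ac_map(self, individual: int | str, **kwargs):
        return _derived.ac_map(self.ac_draws(individual), mask=self.model.mask, **kwargs)

    def ac_modes(self, **kwargs) -> np.ndarray:
        """(n, 2) highest-posterior-probability AC point estimates, all detected."""
        return np.array(
            [self.ac_map(i, **kwargs).mode for i in range(self.model.n)]
        )

    def gof(self, n_reps: int = 500, seed: int | None = 0, observed: dict | None = None):
        return _derived.gof_check(self, n_reps=n_reps, seed=seed, observed=observed)

    # -- persistence --------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Scalar draws as a tidy DataFrame (chain, draw, parameters)."""
        nchain, ndraw = self.draws["N"].shape
        data = {"chain": np.repeat(np.arange(nchain), ndraw),
                "draw": np.tile(np.arange(ndraw), nchain)}
        for p in _SCALARS:
            if p in self.draws:
                data[p] = self.draws[p].reshape(-1)
        return pd.DataFrame(data)

    def save(self, directory: str):
        """Write scalar draws as CSV plus a JSON run manifest."""
        import os

        os.makedirs(directory, exist_ok=True)
        self.to_frame().to_csv(os.path.join(directory, "posterior.csv"), index=False)
        rep = self.convergence()
        manifest = {
            "settings": self.settings,
            "M": self.model.M,
            "n_detected": self.model.n,
            "n_detectors": self.model.J,
            "rhat": {k: v for k, v in rep.rhat.items()},
            "converged": rep.passed if rep.assessed else None,
        }
        with open(os.path.join(directory, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2)
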