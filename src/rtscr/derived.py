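"""Derived quantities and diagnostics for fitted rt-SCR models.

Densities per km^2 of habitat and per km of river channel, the 95% movement
radius implied by the half-normal scale, empirical-Bayes activity-center maps,
the Clark-Evans average nearest-neighbor dispersion test, and posterior
predictive goodness-of-fit checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import chi2, norm

__all__ = [
    "DerivedDensity",
    "AcMap",
    "AnnResult",
    "GofReport",
    "derived_density",
    "movement_radius",
    "ac_map",
    "ann_test",
    "nn_summary",
    "gof_check",
]

# 95% quantile of a chi-square with 2 df: for a bivariate normal movement
# kernel, 95% of locations fall within sigma * sqrt(q) of the center.
_CHI2_95_2DF = chi2.ppf(0.95, df=2)


def _summaries(x: np.ndarray) -> dict:
    return {
        "mean": float(np.mean(x)),
        "sd": float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
        "q2.5": float(np.percentile(x, 2.5)),
        "q50": float(np.percentile(x, 50)),
        "q97.5": float(np.percentile(x, 97.5)),
    }


@dataclass
class DerivedDensity:
    """Posterior densities: D_s (individuals/km^2) and D_L (individuals/km river)."""

    D_s: dict
    D_L: dict
    area_km2: float
    river_km: float
    draws_D_s: np.ndarray
    draws_D_L: np.ndarray


def derived_density(N_draws: np.ndarray, area_km2: float, river_km: float) -> DerivedDensity:
    """Per-draw densities N/area and N/river-length, then posterior summaries.

    Division happens draw by draw *before* summarizing, so quantiles are
    quantiles of the density, not rescaled quantiles of N (for the mean the
    two coincide because the denominators are constants).
    """
    if area_km2 <= 0 or river_km <= 0:
        raise ValueError("area and river length must be positive")
    N = np.asarray(N_draws, dtype=float).ravel()
    ds = N / area_km2
    dl = N / river_km
    return DerivedDensity(_summaries(ds), _summaries(dl), area_km2, river_km, ds, dl)


def movement_radius(sigma, quantile: float = 0.95):
    """Radius containing ``quantile`` of movement outcomes for half-normal scale sigma.

    r = sigma * sqrt(chi2_2df^{-1}(quantile)); for the default 95% this is
    sigma * sqrt(5.991) ~= 2.4477 sigma.  Works element-wise on draw arrays.
    """
    q = chi2.ppf(quantile, df=2)
    return np.asarray(sigma, dtype=float) * np.sqrt(q)


@dataclass
class AcMap:
    """Kernel-density surface of one individual's activity-center posterior."""

    xs: np.ndarray              # (nx,) grid centers
    ys: np.ndarray              # (ny,)
    density: np.ndarray         # (ny, nx), integrates to 1 over the grid
    mode: tuple[float, float]   # argmax coordinates (the AC point estimate)
    bandwidth: tuple[float, float]

    @property
    def cell_area(self) -> float:
        return float((self.xs[1] - self.xs[0]) * (self.ys[1] - self.ys[0]))

    def integral(self) -> float:
        return float(self.density.sum() * self.cell_area)

    def plot(self, ax=None, levels: int = 8):
        """Contour plot of the AC posterior surface with the mode marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if self.density.size > 1:
            ax.contourf(self.xs, self.ys, self.density, levels=levels)
        ax.plot(*self.mode, "r+", markersize=10)
        ax.set_aspect("equal")
        ax.set_xlabel("x (m)")
        ax.set_ylabel("y (m)")
        return ax

    def to_csv(self, path: str):
        """Dump the surface as a long-form CSV grid (x, y, density)."""
        import pandas as pd

        X, Y = np.meshgrid(self.xs, self.ys)
        pd.DataFrame(
            {"x": X.ravel(), "y": Y.ravel(), "density": self.density.ravel()}
        ).to_csv(path, index=False)


def ac_map(
    s_draws: np.ndarray,
    mask=None,
    grid_shape: tuple[int, int] = (100, 100),
    bandwidth: tuple[float, float] | None = None,
    extent: tuple[float, float, float, float] | None = None,
) -> AcMap:
    """Gaussian-product KDE of posterior activity-center draws on a grid.

    The surface is clipped to the habitat mask (if given) and renormalized to
    integrate to one; the argmax is the activity-center point estimate.  The
    default bandwidth is the per-axis normal-reference rule h = sd * n^(-1/6).
    """
    s = np.asarray(s_draws, dtype=float)
    if s.ndim != 2 or s.shape[1] != 2:
        raise ValueError("s_draws must be (n, 2)")
    n = len(s)
    if n < 2 or (np.ptp(s[:, 0]) == 0 and np.ptp(s[:, 1]) == 0):
        warnings.warn("degenerate activity-center draws: returning the point itself")
        pt = tuple(s[0])
        xs = np.array([pt[0]])
        ys = np.array([pt[1]])
        return AcMap(xs, ys, np.array([[1.0]]), pt, (0.0, 0.0))
    if bandwidth is None:
        hx = max(s[:, 0].std(ddof=1), 1e-9) * n ** (-1 / 6)
        hy = max(s[:, 1].std(ddof=1), 1e-9) * n ** (-1 / 6)
    else:
        hx, hy = bandwidth
    if extent is None:
        if mask is not None:
            extent = mask.extent
        else:
            pad = 3 * max(hx, hy)
            extent = (s[:, 0].min() - pad, s[:, 1].min() - pad,
                      s[:, 0].max() + pad, s[:, 1].max() + pad)
    xmin, ymin, xmax, ymax = extent
    ny, nx = grid_shape
    xs = np.linspace(xmin, xmax, nx + 1)
    ys = np.linspace(ymin, ymax, ny + 1)
    xs = 0.5 * (xs[:-1] + xs[1:])
    ys = 0.5 * (ys[:-1] + ys[1:])
    # product-Gaussian kernel, evaluated separably
    kx = np.exp(-0.5 * ((xs[None, :] - s[:, 0, None]) / hx) ** 2)   # (n, nx)
    ky = np.exp(-0.5 * ((ys[None, :] - s[:, 1, None]) / hy) ** 2)   # (n, ny)
    dens = ky.T @ kx / (n * 2 * np.pi * hx * hy)                    # (ny, nx)
    if mask is not None:
        X, Y = np.meshgrid(xs, ys)
        on = mask.contains(np.column_stack([X.ravel(), Y.ravel()])).reshape(ny, nx)
        dens = np.where(on, dens, 0.0)
    cell = (xs[1] - xs[0]) * (ys[1] - ys[0])
    total = dens.sum() * cell
    if total <= 0:
        raise ValueError("density is zero everywhere on the grid (mask too small?)")
    dens = dens / total
    r, c = np.unravel_index(np.argmax(dens), dens.shape)
    return AcMap(xs, ys, dens, (float(xs[c]), float(ys[r])), (hx, hy))


@dataclass
class AnnResult:
    """Clark-Evans average nearest-neighbor test against complete spatial randomness."""

    observed_mean: float
    expected_mean: float
    ann: float
    z: float
    p_value: float
    verdict: str        # "clustered" | "random" | "dispersed"
    n_points: int
    area_km2: float


def _nn_distances(points: np.ndarray) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    tree = cKDTree(pts)
    d, _ = tree.query(pts, k=2)
    return d[:, 1]


def nn_summary(points: np.ndarray, subset: np.ndarray | None = None) -> float:
    """Mean nearest-neighbor distance among ``points`` (optionally a subset mask).

    With a subset, neighbors are searched within the subset only (e.g. the
    male-male nearest-neighbor mean)."""
    pts = np.asarray(points, dtype=float)
    if subset is not None:
        pts = pts[np.asarray(subset)]
    if len(pts) < 2:
        raise ValueError("need >= 2 points")
    return float(_nn_distances(pts).mean())


def ann_test(points: np.ndarray, area_km2: float, alpha: float = 0.05) -> AnnResult:
    """Average nearest-neighbor ratio with the CSR null (no edge correction).

    observed = mean NN distance; expected = 0.5 / sqrt(n / A);
    SE = 0.26136 / sqrt(n^2 / A); z = (obs - exp) / SE, two-sided normal p.
    ANN > 1 with small p -> dispersed, ANN < 1 -> clustered.  Points are in
    meters, the area in km^2.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        raise ValueError("need >= 3 points")
    if area_km2 <= 0:
        raise ValueError("area must be positive")
    A = area_km2 * 1e6
    n = len(pts)
    obs = float(_nn_distances(pts).mean())
    exp = 0.5 / np.sqrt(n / A)
    se = 0.26136 / np.sqrt(n**2 / A)
    zsc = (obs - exp) / se
    p = 2 * norm.sf(abs(zsc))
    if p < alpha:
        verdict = "dispersed" if obs > exp else "clustered"
    else:
        verdict = "random"
    return AnnResult(obs, float(exp), obs / exp, float(zsc), float(p), verdict, n, area_km2)


@dataclass
class GofReport:
    """Posterior-predictive goodness-of-fit for the three observation-model statistics:
    total detections, number of individuals detected (identified), detectors visited."""

    observed: dict
    replicates: dict          # statistic -> array over replicates
    p_values: dict            # Bayesian p = P(T_rep >= T_obs), ties count

    def adequate(self, lo: float = 0.05, hi: float = 0.95) -> bool:
        return all(lo < p < hi for p in self.p_values.values())

    def plot(self, axes=None):
        """Histogram of each replicate statistic with the observed value marked."""
        import matplotlib.pyplot as plt

        if axes is None:
            _, axes = plt.subplots(1, len(self.replicates), figsize=(4 * len(self.replicates), 3))
        for ax, (stat, reps) in zip(np.atleast_1d(axes), self.replicates.items()):
            ax.hist(reps, bins=30)
            ax.axvline(self.observed[stat], color="red")
            ax.set_title(f"{stat}\nBayesian p = {self.p_values[stat]:.2f}")
        return axes


def observed_statistics(encounters) -> dict:
    """The three GoF statistics evaluated on the observed data."""
    y_id, nnid = encounters.y_id, encounters.nnid
    return {
        "total_detections": int(y_id.sum() + nnid.sum()),
        "individuals_detected": int((y_id.sum(axis=1) > 0).sum()),
        "detectors_visited": int(((y_id.sum(axis=0) + nnid) > 0).sum()),
    }


def gof_check(
    results, n_reps: int = 500, seed: int | None = 0, observed: dict | None = None
) -> GofReport:
    """Simulate replicate surveys from retained posterior draws and compare.

    For each selected draw the full observation model is re-simulated for all
    M augmented individuals (y_true ~ Poisson, identities thinned with the
    draw's theta); the Bayesian p-value is the fraction of replicates whose
    statistic is >= the observed one.
    """
    if n_reps < 50:
        warnings.warn("n_reps < 50 gives unstable Bayesian p-values")
    model = results.model
    obs = observed if observed is not None else observed_statistics(model.encounters)
    rng = np.random.default_rng(seed)
    nchain, ndraw = results.draws["N"].shape
    total = nchain * ndraw
    reps = min(n_reps, total)
    pick = rng.choice(total, size=reps, replace=False)
    sig = results.draws["sigma"].reshape(-1) * 1000.0      # back to meters
    th = results.draws["theta"].reshape(-1)
    bet = results.draws["beta"].reshape(-1)
    eps = results.draws["eps"].reshape(total, -1)
    zs = results.draws["z"].reshape(total, -1)
    ss = results.draws["s"].reshape(total, -1, 2)
    X, L = model.X, model.L
    stats = {k: np.empty(reps) for k in obs}
    for r, t in enumerate(pick):
        z = zs[t]
        s = ss[t][z]
        d2 = ((s[:, None, :] - X[None, :, :]) ** 2).sum(-1)
        lam = np.exp(bet[t] * L + eps[t])[None, :] * np.exp(-d2 / (2 * sig[t] ** 2))
        y_true = rng.poisson(lam)
        y_id = rng.binomial(y_true, th[t])
        stats["total_detections"][r] = y_true.sum()
        stats["individuals_detected"][r] = (y_id.sum(axis=1) > 0).sum()
        stats["detectors_visited"][r] = (y_true.sum(axis=0) > 0).sum()
    p = {k: float(np.mean(stats[k] >= obs[k])) for k in obs}
    return GofReport(obs, stats, p)
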