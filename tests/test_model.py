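"""rt-SCR likelihood, sampler invariants, and diagnostics."""

import math
import warnings

import numpy as np
import pytest
from scipy.stats import binom, poisson
from shapely.geometry import Polygon

from rtscr.diagnostics import ess, rhat, waic
from rtscr.geometry import EncounterData, HabitatMask
from rtscr.model import Priors, RandomThinningSCR, RtScrState, baseline_rate, detection_rate
from rtscr.simulate import ScenarioConfig, generate_scenario


class TestDetectionRate:
    def test_basal_rate_at_distance_zero(self):
        assert detection_rate(0.0, 0.7, 500.0) == pytest.approx(0.7)

    def test_half_rate_distance(self):
        sigma = 800.0
        d_half = sigma * math.sqrt(2 * math.log(2))
        assert detection_rate(d_half, 1.0, sigma) == pytest.approx(0.5)

    def test_three_sigma(self):
        assert detection_rate(3 * 250.0, 1.0, 250.0) == pytest.approx(math.exp(-4.5))
        assert detection_rate(750.0, 1.0, 250.0) == pytest.approx(0.0111, abs=2e-4)

    def test_strictly_decreasing(self):
        d = np.linspace(0, 3000, 50)
        r = detection_rate(d, 1.0, 700.0)
        assert (np.diff(r) < 0).all()

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            detection_rate(-1.0, 1.0, 100.0)
        with pytest.raises(ValueError):
            detection_rate(1.0, 1.0, 0.0)
        with pytest.raises(ValueError):
            detection_rate(1.0, -0.5, 100.0)


class TestBaselineRate:
    def test_unit_rate(self):
        assert baseline_rate(0.0, 0.0, 0.0) == pytest.approx(1.0)

    def test_zero_effort_leaves_trap_effect(self):
        assert baseline_rate(0.0, 2.0, -1.3) == pytest.approx(math.exp(-1.3))

    def test_study_posterior_means_plug_in(self):
        # beta = 1.649, eps = -4.632, mean effort 439 m/ha = 0.439 km/cell
        lam0 = baseline_rate(0.439, 1.649, -4.632)
        assert lam0 == pytest.approx(math.exp(-3.908), rel=1e-3)
        assert lam0 == pytest.approx(0.0201, abs=2e-4)


def _tiny_model():
    X = np.array([[25.0, 25.0], [175.0, 25.0]])
    mask = HabitatMask(np.array([[True, True, True, True]]), 50.0, 0.0, 0.0)
    y_id = np.array([[2, 0], [0, 1]])
    nnid = np.array([2, 1])
    enc = EncounterData(y_id, nnid, ["A", "B"])
    m = RandomThinningSCR(enc, detectors=X, effort_km=np.array([0.2, 0.5]),
                          mask=mask, M=3)
    return m


class TestLogLikelihood:
    def _state(self, m, y_noid, theta=0.6, sigma=90.0):
        eps = np.array([-0.2, 0.4])
        return RtScrState(
            sigma=sigma, theta=theta, psi=0.5, beta=1.1, mu0=0.0, sigma_p=1.0,
            eps=eps, z=np.array([True, True, True]),
            s=np.array([[30.0, 20.0], [160.0, 30.0], [100.0, 25.0]]),
            y_noid=y_noid,
        )

    def test_matches_brute_force_pmf_product(self):
        m = _tiny_model()
        y_noid = np.array([[1, 0], [0, 1], [1, 0]])
        st = self._state(m, y_noid)
        y_true = m.y_id_full + y_noid
        lam0 = np.exp(st.beta * m.L + st.eps)
        d2 = ((st.s[:, None, :] - m.X[None, :, :]) ** 2).sum(-1)
        lam = lam0[None, :] * np.exp(-d2 / (2 * st.sigma**2))
        expect = (
            poisson.logpmf(y_true, lam).sum()
            + binom.logpmf(m.y_id_full, y_true, st.theta).sum()
        )
        assert m.log_likelihood(st) == pytest.approx(expect, rel=1e-12)
        pw = m.log_likelihood(st, pointwise=True)
        assert pw.shape == (2,)
        assert pw.sum() == pytest.approx(expect, rel=1e-12)

    def test_theta_one_with_full_identity_has_zero_thinning_term(self):
        m = _tiny_model()
        # force nnid = 0 by building a no-thinning dataset
        enc = EncounterData(m.encounters.y_id, np.zeros(2, int), ["A", "B"])
        m2 = RandomThinningSCR(enc, detectors=m.X, effort_km=m.L, mask=m.mask, M=3)
        st = self._state(m2, np.zeros((3, 2), int), theta=1.0)
        y_true = m2.y_id_full
        lam0 = np.exp(st.beta * m2.L + st.eps)
        d2 = ((st.s[:, None, :] - m2.X[None, :, :]) ** 2).sum(-1)
        lam = lam0[None, :] * np.exp(-d2 / (2 * st.sigma**2))
        assert m2.log_likelihood(st) == pytest.approx(poisson.logpmf(y_true, lam).sum())

    def test_all_zero_counts_reduce_to_minus_total_rate(self):
        X = np.array([[50.0, 50.0]])
        mask = HabitatMask(np.ones((2, 2), bool), 50.0, 0.0, 0.0)
        enc = EncounterData(np.zeros((1, 1), int), np.zeros(1, int), ["A"])
        m = RandomThinningSCR(enc, detectors=X, effort_km=np.zeros(1), mask=mask, M=2)
        st = RtScrState(100.0, 0.5, 0.5, 0.0, 0.0, 1.0, np.zeros(1),
                        np.array([True, True]),
                        np.array([[50.0, 50.0], [10.0, 90.0]]),
                        np.zeros((2, 1), int))
        d2 = ((st.s - X[0]) ** 2).sum(1)
        lam = np.exp(-d2 / (2 * st.sigma**2))
        assert m.log_likelihood(st) == pytest.approx(-lam.sum())

    def test_constraint_violation_raises(self):
        m = _tiny_model()
        bad = self._state(m, np.zeros((3, 2), int))     # sum y_noid != nnid
        with pytest.raises(ValueError, match="constraint"):
            m.log_likelihood(bad)

    def test_counts_on_inactive_individual_raise(self):
        m = _tiny_model()
        st = self._state(m, np.array([[2, 0], [0, 1], [0, 0]]))
        st.z[1] = False          # but individual 1 has identified samples
        with pytest.raises(ValueError, match="inactive"):
            m.log_likelihood(st)


@pytest.fixture(scope="module")
def small_fit():
    cfg = ScenarioConfig(
        n_individuals=5, sigma=250.0, lambda0_mean=-0.5, sigma_p=0.6,
        beta=1.0, seed=3,
        mask_spec=Polygon([(0, 0), (1600, 0), (1600, 700), (0, 700)]),
        pixel_size=30.0,
    )
    design, enc, truth = generate_scenario(cfg)
    model = RandomThinningSCR.from_design(design, enc, M=12)
    res = model.fit(iterations=2500, burn_in=500, thin=4, chains=2, seed=7)
    return model, res


class TestSamplerInvariants:
    def test_per_draw_noid_conservation(self, small_fit):
        model, res = small_fit
        yn = res.draws["y_noid_draws"]
        assert yn is not None
        flat = yn.reshape(-1, model.M, model.J)
        assert (flat.sum(axis=1) == model.nnid[None, :]).all()
        assert (flat >= 0).all()

    def test_latent_counts_only_on_active_individuals(self, small_fit):
        model, res = small_fit
        yn = res.draws["y_noid_draws"].reshape(-1, model.M, model.J)
        z = res.draws["z"].reshape(-1, model.M)
        assert (yn[~z] == 0).all()

    def test_N_equals_sum_z_and_activity_centers_on_mask(self, small_fit):
        model, res = small_fit
        z = res.draws["z"].reshape(-1, model.M)
        assert np.array_equal(z.sum(axis=1), res.get("N"))
        s = res.draws["s"].reshape(-1, 2)
        assert model.mask.contains(s).all()

    def test_theta_one_posterior_concentrates_at_n(self):
        # high basal rate: every individual is detected, no non-ID samples,
        # so N has essentially no posterior mass above the observed count
        cfg = ScenarioConfig(
            n_individuals=6, sigma=250.0, lambda0_mean=1.0, sigma_p=0.3,
            beta=0.5, theta=1.0, seed=12,
            mask_spec=Polygon([(0, 0), (1500, 0), (1500, 600), (0, 600)]),
            pixel_size=30.0,
        )
        design, enc, truth = generate_scenario(cfg)
        assert enc.n_individuals == 6 and enc.nnid.sum() == 0
        model = RandomThinningSCR.from_design(design, enc, M=18)
        res = model.fit(iterations=3000, burn_in=800, thin=4, chains=1, seed=1,
                        fixed={"theta": 1.0})
        N = res.get("N")
        assert np.mean(N == 6) > 0.9
        assert res.credible_interval("N") == (6.0, 6.0)

    def test_more_effort_means_more_expected_detections(self):
        # generative monotonicity, checked on the posterior of the fitted model
        base = dict(
            n_individuals=5, sigma=250.0, lambda0_mean=-0.8, sigma_p=0.4,
            beta=1.2, seed=8,
            mask_spec=Polygon([(0, 0), (1600, 0), (1600, 700), (0, 700)]),
            pixel_size=30.0,
        )
        out = {}
        for label, eff in [("low", 150.0), ("high", 900.0)]:
            cfg = ScenarioConfig(effort_mean=eff, effort_sd=0.0, **base)
            design, enc, truth = generate_scenario(cfg)
            model = RandomThinningSCR.from_design(design, enc, M=15)
            res = model.fit(iterations=2000, burn_in=500, thin=4, chains=1, seed=2)
            out[label] = res.get("expected_detections").mean()
        assert out["high"] > out["low"]

    def test_augmentation_bound_warning(self):
        cfg = ScenarioConfig(
            n_individuals=10, sigma=250.0, lambda0_mean=-1.5, sigma_p=0.4,
            beta=1.0, theta=0.25, seed=4,
            mask_spec=Polygon([(0, 0), (1600, 0), (1600, 700), (0, 700)]),
            pixel_size=30.0,
        )
        design, enc, truth = generate_scenario(cfg)
        model = RandomThinningSCR.from_design(design, enc, M=enc.n_individuals + 2)
        with pytest.warns(RuntimeWarning, match="augmentation"):
            model.fit(iterations=1200, burn_in=300, thin=3, chains=1, seed=1)

    def test_config_validation(self):
        m = _tiny_model()
        with pytest.raises(ValueError):
            m.fit(iterations=100, burn_in=200)
        with pytest.raises(ValueError):
            m.fit(thin=0)
        enc = m.encounters
        with pytest.raises(ValueError, match="M"):
            RandomThinningSCR(enc, detectors=m.X, effort_km=m.L, mask=m.mask, M=2)


class TestDiagnostics:
    def test_rhat_identical_chains_near_one(self, rng):
        c = rng.normal(size=5000)
        assert rhat(np.stack([c, c, c])) == pytest.approx(1.0, abs=0.01)

    def test_rhat_constant_chains(self):
        assert rhat(np.ones((3, 100))) == 1.0

    def test_rhat_disjoint_supports(self, rng):
        a = rng.normal(0, 1, 2000)
        b = rng.normal(50, 1, 2000)
        assert rhat(np.stack([a, b])) > 1.5

    def test_rhat_white_noise_calibration(self, rng):
        chains = rng.normal(size=(3, 10_000))
        r = rhat(chains)
        assert 1.0 - 1e-3 <= r <= 1.01

    def test_rhat_needs_multiple_chains(self, rng):
        with pytest.raises(ValueError):
            rhat(rng.normal(size=(1, 100)))

    def test_ess_white_noise_vs_autocorrelated(self, rng):
        w = rng.normal(size=(1, 4000))
        assert ess(w) == pytest.approx(4000, rel=0.25)
        x = np.empty(4000)
        x[0] = 0.0
        e = rng.normal(size=4000)
        for t in range(1, 4000):            # AR(1) with strong memory
            x[t] = 0.95 * x[t - 1] + e[t]
        assert ess(x[None, :]) < 1000

    def test_waic_properties(self, rng):
        ll = rng.normal(-2.0, 0.3, size=(200, 40))
        w1 = waic(ll)
        assert waic(ll)["waic"] == w1["waic"]           # deterministic
        shifted = ll + 0.5 / 40                          # adds c = 0.5 in total
        w2 = waic(shifted)
        assert w2["lppd"] == pytest.approx(w1["lppd"] + 0.5, abs=1e-9)
        assert w2["p_waic"] == pytest.approx(w1["p_waic"], abs=1e-9)
        assert w2["waic"] == pytest.approx(w1["waic"] - 1.0, abs=1e-8)

    def test_waic_degenerate_zero_variance(self):
        ll = np.tile(np.linspace(-3, -1, 10), (5, 1))
        out = waic(ll)
        assert out["p_waic"] == 0.0
        assert out["waic"] == pytest.approx(-2 * ll[0].sum())
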