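"""Circular KDE, Delta overlap estimators and the Watson-Wheeler test."""

import math
import warnings

import numpy as np
import pytest
from scipy import integrate
from scipy.stats import vonmises

from camoverlap import (
    ActivitySample,
    DensityEstimate,
    SpeciesSpec,
    delta1,
    delta4,
    estimate_overlap,
    sample_activity,
    true_delta,
    vm_kde,
    watson_wheeler,
)
from camoverlap.activity import DELTA4_THRESHOLD, density_grid

TWO_PI = 2 * math.pi

# shared area of vM(0, 2) and vM(pi, 2), adaptive quadrature to 1e-12
DELTA_VM0_VMPI_K2 = 0.15009376661359963


def analytic_density(mu: float, kappa: float, n_grid: int = 512,
                     n: int = 1000) -> DensityEstimate:
    grid = density_grid(n_grid)
    vals = vonmises.pdf(grid, kappa, loc=mu)
    vals = vals / (vals.sum() * TWO_PI / n_grid)
    return DensityEstimate(grid=grid, values=vals, kernel_concentration=kappa,
                           adjust=1.0, n=n)


class TestVmKde:
    def test_unit_mass(self, rng):
        s = ActivitySample("x", rng.uniform(0, TWO_PI, 200))
        est = vm_kde(s)
        assert est.integral() == pytest.approx(1.0, abs=1e-6)

    def test_uniform_sample_near_flat(self, rng):
        s = ActivitySample("x", rng.uniform(0, TWO_PI, 1000))
        est = vm_kde(s)
        assert np.all(np.abs(est.values - 1 / TWO_PI) < 0.15 / TWO_PI)

    def test_mode_recovery(self, rng):
        s = ActivitySample("x", rng.vonmises(math.pi, 4.0, 500) % TWO_PI)
        est = vm_kde(s)
        peak = est.grid[np.argmax(est.values)]
        assert abs(peak - math.pi) < 0.2

    def test_rejects_tiny_sample(self):
        with pytest.raises(ValueError):
            vm_kde(ActivitySample("x", np.array([1.0])))

    def test_identical_points_capped_with_warning(self):
        s = ActivitySample("x", np.full(20, 2.0))
        with pytest.warns(RuntimeWarning):
            est = vm_kde(s)
        assert est.integral() == pytest.approx(1.0, abs=1e-6)


class TestDelta1:
    def test_identity(self):
        f = analytic_density(0.0, 2.0)
        assert delta1(f, f) == pytest.approx(1.0, abs=1e-6)

    def test_disjoint_densities(self):
        f = analytic_density(0.0, 50.0)
        g = analytic_density(math.pi, 50.0)
        assert delta1(f, g) < 0.01

    def test_matches_quadrature_oracle(self):
        f = analytic_density(0.0, 2.0, n_grid=2048)
        g = analytic_density(math.pi, 2.0, n_grid=2048)
        assert delta1(f, g) == pytest.approx(DELTA_VM0_VMPI_K2, abs=1e-4)

    def test_grid_refinement_converges(self):
        err = []
        for ng in (128, 512):
            f = analytic_density(0.0, 2.0, n_grid=ng)
            g = analytic_density(math.pi, 2.0, n_grid=ng)
            err.append(abs(delta1(f, g) - DELTA_VM0_VMPI_K2))
        assert err[1] < 1e-3

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError):
            delta1(analytic_density(0, 2, 128), analytic_density(0, 2, 256))


class TestDelta4:
    def test_identical_samples_exactly_one(self, rng):
        t = rng.vonmises(1.0, 2.0, 100) % TWO_PI
        a = ActivitySample("a", t)
        b = ActivitySample("b", t.copy())
        assert delta4(a, b) == 1.0

    def test_same_distribution_near_one(self, rng):
        a = ActivitySample("a", rng.vonmises(math.pi, 2.0, 2000) % TWO_PI)
        b = ActivitySample("b", rng.vonmises(math.pi, 2.0, 2000) % TWO_PI)
        assert delta4(a, b) == pytest.approx(1.0, abs=0.05)

    def test_matches_analytic_overlap(self, rng):
        a = ActivitySample("a", rng.vonmises(0.0, 2.0, 500) % TWO_PI)
        b = ActivitySample("b", rng.vonmises(math.pi, 2.0, 500) % TWO_PI)
        assert delta4(a, b) == pytest.approx(DELTA_VM0_VMPI_K2, abs=0.05)

    def test_symmetry_and_rotation_invariance(self, rng):
        ta = rng.vonmises(0.5, 3.0, 300) % TWO_PI
        tb = rng.vonmises(2.5, 1.5, 300) % TWO_PI
        d = delta4(ActivitySample("a", ta), ActivitySample("b", tb))
        d_swap = delta4(ActivitySample("b", tb), ActivitySample("a", ta))
        rot = 1.234
        d_rot = delta4(ActivitySample("a", (ta + rot) % TWO_PI),
                       ActivitySample("b", (tb + rot) % TWO_PI))
        assert d == pytest.approx(d_swap, abs=1e-12)
        assert d == pytest.approx(d_rot, abs=0.02)


class TestEstimateOverlap:
    def test_estimator_selection_boundary(self, rng):
        t75 = rng.vonmises(0.0, 1.0, 75) % TWO_PI
        t74 = rng.vonmises(0.0, 1.0, 74) % TWO_PI
        t200 = rng.vonmises(0.0, 1.0, 200) % TWO_PI
        at_threshold = estimate_overlap(ActivitySample("a", t75),
                                        ActivitySample("b", t75.copy()),
                                        reps=2, seed=0)
        below = estimate_overlap(ActivitySample("a", t74),
                                 ActivitySample("b", t200), reps=2, seed=0)
        assert at_threshold.estimator == "Delta4"
        assert below.estimator == "Delta1"
        assert DELTA4_THRESHOLD == 75

    def test_identical_samples_ci_reaches_one(self, rng):
        t = rng.vonmises(2.0, 2.0, 120) % TWO_PI
        res = estimate_overlap(ActivitySample("a", t),
                               ActivitySample("b", t.copy()),
                               reps=100, seed=5)
        assert res.delta == 1.0
        assert res.ci_high == pytest.approx(1.0, abs=0.02)
        assert 0.0 <= res.ci_low <= res.ci_high <= 1.0

    def test_ci_brackets_point_and_is_seeded(self, rng):
        a = ActivitySample("a", rng.vonmises(0.0, 2.0, 90) % TWO_PI)
        b = ActivitySample("b", rng.vonmises(1.5, 2.0, 90) % TWO_PI)
        r1 = estimate_overlap(a, b, reps=200, seed=11)
        r2 = estimate_overlap(a, b, reps=200, seed=11)
        assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)
        assert r1.ci_low - 0.1 <= r1.delta <= r1.ci_high + 0.1

    def test_too_few_reps_omits_ci(self, rng):
        a = ActivitySample("a", rng.vonmises(0.0, 2.0, 50) % TWO_PI)
        with pytest.warns(RuntimeWarning):
            res = estimate_overlap(a, a, reps=0, seed=0)
        assert res.ci_low is None and res.ci_high is None


class TestParameterRecovery:
    """Delta4 recovers the quadrature-oracle overlap of known mixtures."""

    @pytest.mark.parametrize("spec_b, label", [
        (SpeciesSpec("b", ((1.7782158549525027, 4.0, 1.0),), 1.0), "low"),
        (SpeciesSpec("b", ((1.08855609006506, 2.0, 1.0),), 1.0), "mid"),
        (SpeciesSpec("b", ((0.1981281427224683, 2.0, 1.0),), 1.0), "high"),
    ])
    def test_delta4_within_tolerance_most_replicates(self, spec_b, label):
        kappa = spec_b.mixture[0][1]
        spec_a = SpeciesSpec("a", ((0.0, kappa, 1.0),), 1.0)
        truth = true_delta(spec_a, spec_b)
        hits = 0
        reps = 40
        for r in range(reps):
            rng = np.random.default_rng(1000 + r)
            a = ActivitySample("a", sample_activity(spec_a, 500, rng))
            b = ActivitySample("b", sample_activity(spec_b, 500, rng))
            hits += abs(delta4(a, b) - truth) <= 0.05
        assert hits / reps >= 0.9


def brute_force_watson_wheeler(ta, tb):
    """Independent rank-enumeration computation of W."""
    pooled = list(ta) + list(tb)
    order = sorted(range(len(pooled)), key=lambda i: pooled[i])
    ranks = [0] * len(pooled)
    for r, i in enumerate(order):
        ranks[i] = r + 1
    gam = [TWO_PI * r / len(pooled) for r in ranks]
    W = 0.0
    for idx, nk in ((range(len(ta)), len(ta)),
                    (range(len(ta), len(pooled)), len(tb))):
        C = sum(math.cos(gam[i]) for i in idx)
        S = sum(math.sin(gam[i]) for i in idx)
        W += (C * C + S * S) / nk
    return 2 * W


class TestWatsonWheeler:
    FIX_A = np.array([0.1, 0.5, 1.0, 1.4, 2.2, 3.0])
    FIX_B = np.array([2.8, 3.5, 4.2, 4.9, 5.5, 6.0])
    FIX_W = 7.464101615137755       # brute-force rank enumeration
    FIX_P_EXACT = 36 / 924          # exhaustive label assignments

    def test_statistic_matches_brute_force(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = watson_wheeler(ActivitySample("a", self.FIX_A),
                                 ActivitySample("b", self.FIX_B))
        assert res.W == pytest.approx(self.FIX_W, abs=1e-9)
        assert res.W == pytest.approx(
            brute_force_watson_wheeler(self.FIX_A, self.FIX_B), abs=1e-12)
        assert res.df == 2

    def test_permutation_p_matches_exhaustive(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = watson_wheeler(ActivitySample("a", self.FIX_A),
                                 ActivitySample("b", self.FIX_B),
                                 method="permutation", perm_reps=20000,
                                 seed=3)
        assert res.p_value == pytest.approx(self.FIX_P_EXACT, abs=0.01)

    def test_ties_warn_and_average(self, rng):
        ta = np.array([0.5, 0.5, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 1.5, 2.5])
        tb = (ta + 0.7) % TWO_PI
        with pytest.warns(RuntimeWarning):
            res = watson_wheeler(ActivitySample("a", ta),
                                 ActivitySample("b", tb))
        assert res.W >= 0

    def test_heavy_ties_need_permutation(self):
        ta = np.array([0.0, 1.0, 2.0, 3.0] * 5)
        tb = np.array([0.5, 1.0, 2.0, 3.5] * 5)
        with pytest.raises(ValueError, match="permutation"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                watson_wheeler(ActivitySample("a", ta),
                               ActivitySample("b", tb))

    def test_detects_shifted_distributions(self, rng):
        a = ActivitySample("a", rng.vonmises(0.0, 2.0, 150) % TWO_PI)
        b = ActivitySample("b", rng.vonmises(2.0, 2.0, 150) % TWO_PI)
        assert watson_wheeler(a, b).p_value < 1e-4
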