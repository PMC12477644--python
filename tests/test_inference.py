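"""Error functions, LHS screening, refinement, DRAM, K_D comparison."""

import numpy as np
import pandas as pd
import pytest

from emikin.inference import (
    ParameterSpace,
    chromogenic_objective,
    compare_kd_hypotheses,
    dram_sample,
    error_chromophore,
    error_fxa,
    fit_no_emicizumab,
    lhs_screen,
    local_refine,
    one_arm_objective,
)
from emikin.io import SCHEMA, TimecourseData
from emikin.params import default_params
from emikin.synthetic import NoiseModel, design_library, generate
from emikin.two_arm import ChromogenicConfig, build_two_arm


def _dataset(points, readout="total_FXa", replicate=1):
    """points: list of (condition_id, time, value)."""
    rows = [
        (cond, 0.0, 140.0, 1.0, 0.0, 80.0, replicate, t, readout, v)
        for cond, t, v in points
    ]
    return TimecourseData(pd.DataFrame(rows, columns=SCHEMA))


class TestErrorFunctions:
    def test_zero_when_sim_equals_exp(self):
        data = _dataset([("a", 60.0, 2.0), ("a", 120.0, 3.0)])
        sim = {"a": (np.array([60.0, 120.0]), np.array([2.0, 3.0]))}
        assert error_fxa(sim, data) == 0.0

    def test_single_point_relative_error(self):
        data = _dataset([("a", 60.0, 2.0)])
        sim = {"a": (np.array([60.0]), np.array([1.0]))}
        assert error_fxa(sim, data) == pytest.approx(1.0)

    def test_hand_summation_oracle(self):
        """Two conditions x two points: 1 + 0 + 1 + 0.0625 = 2.0625."""
        data = _dataset([("a", 60.0, 2.0), ("a", 120.0, 3.0),
                         ("b", 60.0, 4.0), ("b", 120.0, 5.0)])
        sim = {"a": (np.array([60.0, 120.0]), np.array([1.0, 3.0])),
               "b": (np.array([60.0, 120.0]), np.array([2.0, 4.0]))}
        assert error_fxa(sim, data) == pytest.approx(2.0625)

    def test_uniform_scaling_gives_n_eps_squared(self):
        eps = 0.01
        times = np.array([60.0, 120.0, 180.0])
        values = np.array([1.0, 2.0, 3.0])
        data = _dataset([("a", t, v * (1 + eps)) for t, v in zip(times, values)],
                        readout="chromophore")
        sim = {"a": (times, values)}
        assert error_chromophore(sim, data) == pytest.approx(3 * eps ** 2)

    def test_replicates_each_contribute(self):
        """Duplicate wells double the sum; matches a flat-indexed loop."""
        times = np.array([60.0, 120.0])
        sim_vals = np.array([1.0, 2.0])
        rows = []
        rng = np.random.default_rng(3)
        for rep in (1, 2):
            for t, sv in zip(times, sim_vals):
                rows.append(("a", 0.0, 140.0, 1.0, 0.0, 80.0, rep, t,
                             "chromophore", sv * (1 + 0.1 * rng.standard_normal())))
        frame = pd.DataFrame(rows, columns=SCHEMA)
        data = TimecourseData(frame)
        sim = {"a": (times, sim_vals)}
        flat = sum(
            ((row.value_nM - sim_vals[list(times).index(row.time_s)])
             / sim_vals[list(times).index(row.time_s)]) ** 2
            for row in frame.itertuples()
        )
        assert error_chromophore(sim, data) == pytest.approx(flat)

    def test_near_zero_sim_points_excluded(self):
        data = _dataset([("a", 0.0, 0.0), ("a", 60.0, 2.0)])
        sim = {"a": (np.array([0.0, 60.0]), np.array([0.0, 1.0]))}
        assert error_fxa(sim, data) == pytest.approx(1.0)


class TestParameterSpace:
    def test_bad_bounds_rejected(self):
        with pytest.raises(ValueError):
            ParameterSpace(names=("a",), lower=(1.0,), upper=(0.0,))
        with pytest.raises(ValueError):
            ParameterSpace(names=("a",), lower=(0.0,), upper=(1.0,),
                           fixed={"a": 2.0})

    def test_to_params_applies_powers_and_overlay(self):
        space = ParameterSpace(names=("kcat_noM",), lower=(-4.0,), upper=(0.0,),
                               fixed={"alpha": 0.5})
        p = space.to_params(np.array([-2.0]), default_params())
        assert p["kcat_noM"] == pytest.approx(1e-2)
        assert p["alpha"] == 0.5


class TestLhsScreen:
    def test_stratification_one_per_half(self):
        space = ParameterSpace(names=("x",), lower=(0.0,), upper=(1.0,))
        thetas = space.sample_lhs(2, seed=5)
        halves = sorted(int(v > 0.5) for v in thetas[:, 0])
        assert halves == [0, 1]

    def test_returns_sample_closest_to_target(self):
        space = ParameterSpace(names=("x", "y"), lower=(0.0, 0.0),
                               upper=(1.0, 1.0))
        target = np.array([0.3, 0.7])
        best, val, (thetas, vals) = lhs_screen(
            space, 50, lambda t: float(np.sum((t - target) ** 2)), seed=2)
        assert val == min(vals)
        assert np.all(best == thetas[np.argmin(vals)])

    def test_deterministic_given_seed(self):
        space = ParameterSpace(names=("x",), lower=(-1.0,), upper=(1.0,))
        obj = lambda t: float(t[0] ** 2)
        a = lhs_screen(space, 20, obj, seed=9)
        b = lhs_screen(space, 20, obj, seed=9)
        assert np.all(a[0] == b[0]) and a[1] == b[1]

    def test_all_nonfinite_errors(self):
        space = ParameterSpace(names=("x",), lower=(0.0,), upper=(1.0,))
        with pytest.raises(RuntimeError, match="non-finite"):
            lhs_screen(space, 5, lambda t: np.inf, seed=0)


class TestLocalRefine:
    SPACE = ParameterSpace(names=("x", "y"), lower=(-2.0, -2.0),
                           upper=(2.0, 2.0))

    def test_quadratic_interior_minimum(self):
        theta, val, _ = local_refine(
            np.array([1.5, -1.5]), self.SPACE,
            lambda t: float((t[0] - 0.3) ** 2 + (t[1] + 0.4) ** 2),
            fd_step=1e-8)  # noise-free objective: exact gradients are safe
        np.testing.assert_allclose(theta, [0.3, -0.4], atol=1e-6)

    def test_minimum_at_bound(self):
        theta, val, _ = local_refine(
            np.array([0.0, 0.0]), self.SPACE,
            lambda t: float((t[0] - 5.0) ** 2 + t[1] ** 2))
        assert theta[0] == pytest.approx(2.0)

    def test_never_worse_than_start(self):
        rough = lambda t: float(abs(t[0]) ** 0.3)  # nasty non-smooth objective
        start = np.array([0.5, 0.0])
        theta, val, _ = local_refine(start, self.SPACE, rough)
        assert val <= rough(start)

    def test_synthetic_chromogenic_recovery(self, params):
        """Starting 3x off the truth, refinement cuts the error >= 10-fold.

        The start is perturbed against the k_cat/K_D ridge (k_cat up,
        K_D down) so the initial misfit is genuine; noiseless data keeps
        the objective floor at the truth near zero.
        """
        lib = design_library()
        data = generate(lib["no_emicizumab_fx_titration"][:3], params,
                        NoiseModel(cv=0.0, floor_nM=0.0, replicates=1, seed=4))
        space = ParameterSpace(names=("kIXaX_off", "kcat_noM"),
                               lower=(-2.0, -4.0), upper=(3.0, 0.0))
        net = build_two_arm(chromo=ChromogenicConfig(), params=params)
        obj = chromogenic_objective(data, params, space, net)
        start = np.array([np.log10(params["kIXaX_off"] / 3),
                          np.log10(params["kcat_noM"] * 3)])
        theta, val, _ = local_refine(start, space, obj)
        assert val <= obj(start) / 10.0


class TestDram:
    def test_gaussian_target_moments(self):
        """1-D Gaussian target: mean and sd recovered within 5%."""
        space = ParameterSpace(names=("x",), lower=(-3.0, ), upper=(3.0,))
        mu, tau = 0.5, 0.2
        obj = lambda t: float(((t[0] - mu) / tau) ** 2)
        chain = dram_sample(np.array([0.0]), space, obj, n_draws=50000,
                            seed=12, sigma2=1.0)
        post = chain.samples[10000:, 0]
        assert post.mean() == pytest.approx(mu, abs=0.05 * tau / 0.2 * 0.2)
        assert post.std() == pytest.approx(tau, rel=0.05)
        assert 0.1 < chain.accept_rate < 0.9

    def test_bounds_respected(self):
        space = ParameterSpace(names=("x",), lower=(-0.5,), upper=(0.5,))
        chain = dram_sample(np.array([0.0]), space,
                            lambda t: float(t[0] ** 2), n_draws=2000, seed=3,
                            sigma2=10.0)
        assert chain.samples.min() >= -0.5
        assert chain.samples.max() <= 0.5

    def test_seed_exact_reproducibility(self):
        space = ParameterSpace(names=("x",), lower=(-1.0,), upper=(1.0,))
        obj = lambda t: float(t[0] ** 2)
        a = dram_sample(np.array([0.2]), space, obj, 500, seed=7)
        b = dram_sample(np.array([0.2]), space, obj, 500, seed=7)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_dissociation_scale_weakly_identified_above_threshold(self, params):
        """Fast antibody release from new FXa: the fit pins only a lower bound.

        The objective rises steeply when the M:FXa dissociation scale
        approaches 1 (the antibody would smother its product) but is
        nearly flat for further increases above the generating value, so
        the posterior for the scale is broad on the high side.
        """
        lib = design_library()
        data = generate([lib["emicizumab_titration"][2]], params,
                        NoiseModel(seed=6))
        space = ParameterSpace(names=("gamma_MXa",), lower=(0.0,), upper=(4.0,))
        net = build_two_arm(chromo=ChromogenicConfig(), params=params)
        obj = chromogenic_objective(data, params, space, net)
        base = obj(np.array([2.0]))  # the generating value, gamma = 100
        e1000 = obj(np.array([3.0]))
        e2 = obj(np.array([np.log10(2.0)]))
        assert e1000 < 3.0 * base
        assert e2 > 10.0 * base


class TestKdComparison:
    def test_alpha_beta_one_degenerate(self, params):
        """With alpha = beta = 1 the FX-arm K_D cannot affect the output."""
        lib = design_library()
        data = generate(lib["one_arm_emicizumab_titration"][:3], params,
                        NoiseModel(seed=8))
        errors = {}
        for kd in (56.0, 1560.0):
            p = params.with_updates(kMX_off=kd * params["kMX_on"])
            space = ParameterSpace(names=(), lower=(), upper=(),
                                   fixed={"alpha": 1.0, "beta": 1.0})
            obj = one_arm_objective(data, p, space)
            errors[kd] = obj(np.empty(0))
        assert errors[56.0] == pytest.approx(errors[1560.0], rel=1e-6)

    def test_data_generated_under_mak_kd_prefers_mak(self, params):
        """Self-consistency: the generating K_D wins the goodness-of-fit race."""
        lib = design_library()
        data = generate(lib["one_arm_emicizumab_titration"], params,
                        NoiseModel(seed=10))
        result = compare_kd_hypotheses(data, params, seed=10, n_lhs=15)
        assert result["best"] == "Mak"
        assert (result["options"]["Mak"]["error"]
                < result["options"]["Kitazawa"]["error"])


def test_pipeline_monotonicity(params):
    """screen -> refine never increases the objective."""
    lib = design_library()
    data = generate(lib["no_emicizumab_fx_titration"][:2], params,
                    NoiseModel(seed=13))
    fit = fit_no_emicizumab(data, params, seed=13, n_lhs=10)
    assert fit.error <= fit.error_start
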