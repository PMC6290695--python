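"""Sobol' sampling, Saltelli design construction and variance estimators.

The expensive oracles here are closed forms: the analytic variance
decomposition of additive models and of the Ishigami function, the CLT
standard error of a sample mean, and a brute-force double-loop Monte Carlo
estimate of the same indices.
"""

import numpy as np
import pandas as pd
import pytest

from isrsim.saltelli import (ParameterSpace, aleatory_variance,
                             bootstrap_estimate, build_design, default_space,
                             estimate_moments, first_order_index, run_seed,
                             scale_to_bounds, sobol_sequence, total_index)


def unit_space(n):
    return ParameterSpace(tuple((f"x{i + 1}", 0.0, 1.0) for i in range(n)))


def block_matrix(design, block, i=0):
    """(M, n) inputs of one block, ordered by j."""
    sub = design.block_rows(block, i)
    return sub[list(design.names)].to_numpy()


# ---------------------------------------------------------------------------
# Sobol sequence and scaling
# ---------------------------------------------------------------------------

class TestSobolSequence:
    def test_first_points_1d(self):
        assert np.allclose(sobol_sequence(1, 3).ravel(), [0.5, 0.75, 0.25])

    def test_deterministic(self):
        assert np.array_equal(sobol_sequence(4, 100), sobol_sequence(4, 100))

    def test_zero_point_skipped(self):
        assert not np.any(np.all(sobol_sequence(3, 64) == 0.0, axis=1))

    def test_unsupported_dimension(self):
        with pytest.raises(ValueError):
            sobol_sequence(100000, 4)

    def test_lower_star_discrepancy_than_pseudorandom(self):
        """256 Sobol' points cover the square more evenly than random ones."""

        def grid_star_discrepancy(pts, k=40):
            edges = (np.arange(1, k + 1)) / k
            disc = 0.0
            for ax in edges:
                for ay in edges:
                    frac = np.mean((pts[:, 0] < ax) & (pts[:, 1] < ay))
                    disc = max(disc, abs(frac - ax * ay))
            return disc

        d_sobol = grid_star_discrepancy(sobol_sequence(2, 256))
        for seed in range(10):
            pts = np.random.default_rng(seed).random((256, 2))
            assert d_sobol < grid_star_discrepancy(pts)

    def test_qmc_mean_converges_like_one_over_n(self):
        """On a smooth integrand the QMC error decays ~O(1/N), beating MC."""
        exact = 0.5 ** 3

        def f(u):
            return np.prod(u, axis=1)

        ns = 2 ** np.arange(4, 13)
        qmc_err = np.array([abs(f(sobol_sequence(3, n)).mean() - exact)
                            for n in ns])
        slope = np.polyfit(np.log(ns), np.log(qmc_err + 1e-16), 1)[0]
        assert slope < -0.85
        mc_err = np.array([
            np.sqrt(np.mean([
                (f(np.random.default_rng(s).random((n, 3))).mean() - exact) ** 2
                for s in range(10)])) for n in ns])
        assert qmc_err[-1] < mc_err[-1]


class TestScaleToBounds:
    def test_table_bounds(self):
        space = default_space()
        lo = scale_to_bounds(np.zeros(3), space)
        hi = scale_to_bounds(np.ones(3), space)
        assert np.allclose(lo, [0.432, 0.09, 15.0])
        assert np.allclose(hi, [0.528, 0.13, 23.0])

    def test_midpoint(self):
        mid = scale_to_bounds(np.full(3, 0.5), default_space())
        assert np.allclose(mid, [0.48, 0.11, 19.0])

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            scale_to_bounds(np.zeros(2), default_space())

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            ParameterSpace((("bad", 1.0, 1.0),))


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------

class TestSaltelliDesign:
    @pytest.mark.parametrize("M,n,expected", [(120, 3, 960), (1, 1, 4),
                                              (7, 2, 42)])
    def test_run_count(self, M, n, expected):
        design = build_design(unit_space(n), M, seed_root=0)
        assert design.n_runs == M * (2 * n + 2) == expected

    def test_block_structure(self):
        design = build_design(unit_space(3), 16, seed_root=5)
        xa = block_matrix(design, "A")
        xar = block_matrix(design, "A_RESEED")
        assert np.array_equal(xa, xar)
        for i in range(3):
            xfo = block_matrix(design, "FO", i)
            xto = block_matrix(design, "TO", i)
            # FO_i shares column i with A, all others with the complement
            assert np.array_equal(xfo[:, i], xa[:, i])
            others = [c for c in range(3) if c != i]
            for c in others:
                assert not np.array_equal(xfo[:, c], xa[:, c])
            # TO_i equals A except in column i
            assert np.array_equal(xto[:, others], xa[:, others])
            assert not np.array_equal(xto[:, i], xa[:, i])

    def test_seeds_distinct_and_reproducible(self):
        d1 = build_design(unit_space(2), 50, seed_root=9)
        d2 = build_design(unit_space(2), 50, seed_root=9)
        pd.testing.assert_frame_equal(d1.runs, d2.runs)
        assert d1.runs["seed"].nunique() == d1.n_runs
        assert (d1.runs["seed"] < 2 ** 31).all()
        assert run_seed(9, "A", 0, 0) != run_seed(9, "A_RESEED", 0, 0)


# ---------------------------------------------------------------------------
# Moments, aleatory variance
# ---------------------------------------------------------------------------

class TestMoments:
    def test_hand_arithmetic(self):
        mean, var, sd, cv = estimate_moments(np.array([1.0, 2.0, 3.0]))
        assert (mean, var, sd, cv) == (2.0, 1.0, 1.0, 50.0)

    def test_constant_samples(self):
        mean, var, sd, cv = estimate_moments(np.full(10, 7.0))
        assert var == 0.0 and cv == 0.0

    def test_zero_mean_flagged(self):
        _, _, _, cv = estimate_moments(np.array([-1.0, 1.0]))
        assert np.isnan(cv)

    def test_normal_cv(self, rng):
        x = rng.normal(10.0, 2.0, size=100_000)
        _, _, _, cv = estimate_moments(x)
        assert abs(cv - 20.0) < 0.5


class TestAleatoryVariance:
    def test_deterministic_model_zero(self):
        f = np.arange(10.0)
        var, sd = aleatory_variance(f, f)
        assert var == 0.0 and sd == 0.0

    def test_additive_noise_recovers_sigma2(self, rng):
        m = 100_000
        sigma = 0.7
        x = rng.random(m)
        fa = x + rng.normal(0, sigma, m)
        far = x + rng.normal(0, sigma, m)
        var, sd = aleatory_variance(fa, far)
        assert abs(var - sigma ** 2) < 0.05 * sigma ** 2
        assert sd == np.sqrt(var)

    def test_jensen_bound_vs_nested_monte_carlo(self, rng):
        """sqrt(Var^T_xi) bounds E_x[sd(f|x)]; equality for constant noise."""
        m = 40_000

        def model(x, noise):
            return x + (0.2 + x) * noise  # x-dependent noise amplitude

        x = rng.random(m)
        fa = model(x, rng.normal(size=m))
        far = model(x, rng.normal(size=m))
        _, bound = aleatory_variance(fa, far)
        # brute-force nested loop: E_x[sd_xi(f | x)] with sd(f|x) = 0.2 + x
        xs = rng.random(2000)
        inner_sd = np.array([np.std((0.2 + xi) * rng.normal(size=500))
                             for xi in xs])
        nested = inner_sd.mean()
        assert nested <= bound * 1.02
        # x-independent noise: the bound is tight
        fa2 = x + rng.normal(0, 0.5, m)
        far2 = x + rng.normal(0, 0.5, m)
        _, bound2 = aleatory_variance(fa2, far2)
        assert abs(bound2 - 0.5) < 0.02

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            aleatory_variance(np.zeros(3), np.zeros(4))


# ---------------------------------------------------------------------------
# Sobol indices
# ---------------------------------------------------------------------------

def design_outputs(f, space, M, seed_root=0, noise_sd=0.0):
    """Evaluate a vectorized deterministic model on every block."""
    design = build_design(space, M, seed_root)
    out = {}
    out["A"] = f(block_matrix(design, "A"))
    out["A_RESEED"] = f(block_matrix(design, "A_RESEED"))
    for i in range(space.n):
        out[f"FO{i}"] = f(block_matrix(design, "FO", i))
        out[f"TO{i}"] = f(block_matrix(design, "TO", i))
    if noise_sd:
        for key, block, i in [("A", "A", 0), ("A_RESEED", "A_RESEED", 0)] + \
                [(f"FO{i}", "FO", i) for i in range(space.n)] + \
                [(f"TO{i}", "TO", i) for i in range(space.n)]:
            seeds = build_design(space, M, seed_root).block_rows(
                block, i)["seed"].to_numpy()
            noise = np.array([np.random.default_rng(s).normal(0, noise_sd)
                              for s in seeds])
            out[key] = out[key] + noise
    return design, out


class TestSobolIndices:
    def test_additive_two_input_shares(self):
        """f = x1 + 2 x2 on U(0,1)^2: shares are 20% and 80%."""
        space = unit_space(2)
        _, out = design_outputs(lambda x: x[:, 0] + 2 * x[:, 1], space, 20_000)
        _, s1 = first_order_index(out["A"], out["FO0"])
        _, s2 = first_order_index(out["A"], out["FO1"])
        assert abs(s1 - 20.0) < 2.0
        assert abs(s2 - 80.0) < 2.0
        # additive model: totals equal first-order indices
        _, st1 = total_index(out["A"], out["TO0"])
        _, st2 = total_index(out["A"], out["TO1"])
        assert abs(st1 - 20.0) < 2.0
        assert abs(st2 - 80.0) < 2.0
        assert abs((s1 + s2) - 100.0) < 3.0

    def test_inert_input_index_zero(self):
        space = unit_space(2)
        _, out = design_outputs(lambda x: 3.0 * x[:, 0], space, 20_000)
        _, s2 = first_order_index(out["A"], out["FO1"])
        assert abs(s2) < 2.0

    def test_ishigami_closed_form(self):
        """Ishigami (a=7, b=0.1): S1=31.4%, S2=44.2%, S3=0, ST3=24.4%."""
        a, b = 7.0, 0.1
        space = ParameterSpace(tuple(
            (f"x{i}", -np.pi, np.pi) for i in (1, 2, 3)))

        def ishigami(x):
            return (np.sin(x[:, 0]) + a * np.sin(x[:, 1]) ** 2
                    + b * x[:, 2] ** 4 * np.sin(x[:, 0]))

        v1 = 0.5 * (1 + b * np.pi ** 4 / 5) ** 2
        v2 = a ** 2 / 8
        v13 = 8 * b ** 2 * np.pi ** 8 / 225
        v = v1 + v2 + v13
        _, out = design_outputs(ishigami, space, 50_000)
        _, s1 = first_order_index(out["A"], out["FO0"])
        _, s2 = first_order_index(out["A"], out["FO1"])
        _, s3 = first_order_index(out["A"], out["FO2"])
        _, st3 = total_index(out["A"], out["TO2"])
        assert abs(s1 - 100 * v1 / v) < 3.0
        assert abs(s2 - 100 * v2 / v) < 3.0
        assert abs(s3 - 0.0) < 3.0
        assert abs(st3 - 100 * v13 / v) < 3.0

    def test_pure_noise_total_indices_100(self, rng):
        """f depending only on the seed: every ST_i includes all the noise."""
        m = 50_000
        fa = rng.normal(size=m)
        st = [total_index(fa, rng.normal(size=m))[1] for _ in range(3)]
        assert np.allclose(st, 100.0, atol=3.0)

    def test_matches_double_loop_oracle(self, rng):
        """Saltelli estimates agree with brute-force double-loop MC."""
        space = unit_space(2)

        def f(x):
            return x[:, 0] ** 2 + x[:, 0] * x[:, 1]

        m = 40_000
        _, out = design_outputs(f, space, m)
        _, s1 = first_order_index(out["A"], out["FO0"])

        # double loop: Var_x1(E[f | x1]) via conditional means
        n_outer, n_inner = 400, 400
        x1 = rng.random(n_outer)
        cond = np.array([
            np.mean(f(np.column_stack([np.full(n_inner, xi),
                                       rng.random(n_inner)])))
            for xi in x1])
        var_tot = f(rng.random((200_000, 2))).var()
        s1_oracle = 100 * cond.var(ddof=1) / var_tot
        # combined SE dominated by the double-loop piece at these sizes
        assert abs(s1 - s1_oracle) < 5.0

    def test_zero_variance_flagged(self):
        f = np.full(10, 3.0)
        _, s = first_order_index(f, f)
        _, st = total_index(f, f)
        assert np.isnan(s) and np.isnan(st)


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

class TestBootstrap:
    def test_constant_outputs_zero_error(self, rng):
        blocks = {"A": np.full(50, 2.0)}
        mean, err = bootstrap_estimate(blocks, lambda b: b["A"].mean(),
                                       K=200, rng=rng)
        assert err == 0.0 and mean == 2.0

    def test_clt_standard_error_of_mean(self, rng):
        m = 1000
        blocks = {"A": rng.normal(size=m)}
        _, err = bootstrap_estimate(blocks, lambda b: b["A"].mean(),
                                    K=10_000, rng=rng)
        assert abs(err - 1 / np.sqrt(m)) < 0.1 / np.sqrt(m)

    def test_error_shrinks_with_m(self, rng):
        errs = []
        for m in (100, 400):
            blocks = {"A": rng.normal(size=m)}
            _, err = bootstrap_estimate(blocks, lambda b: b["A"].mean(),
                                        K=2000, rng=rng)
            errs.append(err)
        assert errs[1] < errs[0] / 1.5

    def test_pairing_preserved(self, rng):
        """Resampled rows stay aligned across blocks (paired estimators)."""
        m = 200
        fa = rng.normal(size=m)
        blocks = {"A": fa, "A_RESEED": fa.copy()}  # identical pairing

        def alea(b):
            return aleatory_variance(b["A"], b["A_RESEED"])[0]

        mean, err = bootstrap_estimate(blocks, alea, K=100, rng=rng)
        assert mean == 0.0 and err == 0.0

    def test_total_at_least_first_order_within_error(self, rng):
        """ST_i >= S_i within 2 bootstrap SDs on an interacting model."""
        space = unit_space(2)

        def f(x):
            return x[:, 0] + x[:, 0] * x[:, 1]

        _, out = design_outputs(f, space, 5000)
        blocks = {k: out[k] for k in ("A", "A_RESEED", "FO0", "TO0")}

        def diff(b):
            return (total_index(b["A"], b["TO0"])[1]
                    - first_order_index(b["A"], b["FO0"])[1])

        mean, err = bootstrap_estimate(blocks, diff, K=300, rng=rng)
        assert mean > -2 * err
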