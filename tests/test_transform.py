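"""Unit and property tests for the bounded-transform probability model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import gammaln, logsumexp
from scipy.stats import poisson

from conga.transform import (
    ConditionalConfig,
    CountMatrix,
    EdgeState,
    TransformSpec,
    conditional_logpmf,
    log_joint_unnormalized,
    normalizing_constant_bounds,
    transform,
    truncation_error_bound,
    tune_theta,
)


class TestTransform:
    @pytest.mark.parametrize(
        "x, theta, expected",
        [
            (0, 1.0, 0.0),
            (1, 1.0, math.pi / 4),
            (3, 2.0, math.atan(3.0) ** 2),
        ],
    )
    def test_known_values(self, x, theta, expected):
        assert transform(x, TransformSpec(theta)) == pytest.approx(expected, abs=1e-12)

    def test_rejects_negative_and_nonfinite(self):
        spec = TransformSpec(1.0)
        with pytest.raises(ValueError):
            transform(-1.0, spec)
        with pytest.raises(ValueError):
            transform(np.nan, spec)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        theta=st.floats(0.1, 10.0),
        x=st.integers(min_value=0, max_value=10_000),
    )
    def test_strictly_increasing_and_bounded(self, theta, x):
        spec = TransformSpec(theta)
        assert transform(x + 1, spec) > transform(x, spec)
        assert transform(x, spec) < spec.sup_value

    def test_invalid_theta(self):
        for bad in (0.0, -1.0, np.inf):
            with pytest.raises(ValueError):
                TransformSpec(bad)


class TestLogJoint:
    def test_zero_counts_unit_rates_no_edges(self):
        e = EdgeState.zeros(3)
        assert log_joint_unnormalized([0, 0, 0], [0.0, 0.0, 0.0], e, TransformSpec(1)) == 0.0

    def test_no_edges_is_sum_of_poisson_kernels(self, rng):
        e = EdgeState.zeros(4)
        x = rng.poisson(3, 4)
        ll = np.log(rng.uniform(0.5, 3, 4))
        expected = float(np.sum(x * ll - gammaln(x + 1.0)))
        got = log_joint_unnormalized(x, ll, e, TransformSpec(2.0))
        assert got == pytest.approx(expected, rel=1e-12)

    def test_two_node_hand_value(self):
        # x=(1,2), lambda=(1,1), beta12=0.5, theta=1:
        # -log(2) - 0.5 * arctan(1) * arctan(2)
        e = EdgeState.zeros(2)
        e.beta[0, 1] = e.beta[1, 0] = 0.5
        expected = -math.log(2.0) - 0.5 * (math.pi / 4) * math.atan(2.0)
        got = log_joint_unnormalized([1, 2], [0.0, 0.0], e, TransformSpec(1.0))
        assert got == pytest.approx(expected, abs=1e-12)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            log_joint_unnormalized([1, 2, 3], [0.0, 0.0], EdgeState.zeros(2), TransformSpec(1))


def brute_force_log_norm_const(alpha, edges, spec, support_max):
    """Enumeration oracle: log sum of the unnormalized pmf over a lattice."""
    P = len(alpha)
    k = np.arange(support_max + 1)
    grids = np.meshgrid(*([k] * P), indexing="ij")
    logp = np.zeros_like(grids[0], dtype=float)
    fk = transform(k, spec)
    for j in range(P):
        logp += grids[j] * alpha[j] - gammaln(grids[j] + 1.0)
    off = edges.offdiag()
    for j in range(P):
        for l in range(j + 1, P):
            logp -= off[j, l] * fk[grids[j]] * fk[grids[l]]
    return float(logsumexp(logp))


class TestNormalizingBounds:
    def test_collapse_without_edges(self):
        e = EdgeState.zeros(3)
        lo, hi = normalizing_constant_bounds([0.1, -0.2, 0.3], e, TransformSpec(1))
        expected = float(np.exp(0.1) + np.exp(-0.2) + np.exp(0.3))
        assert lo == pytest.approx(expected) and hi == pytest.approx(expected)

    def test_two_node_hand_value(self):
        e = EdgeState.zeros(2)
        e.beta[0, 1] = e.beta[1, 0] = 1.0
        lo, hi = normalizing_constant_bounds([0.0, 0.0], e, TransformSpec(1.0))
        u2 = (math.pi / 2) ** 2
        assert lo == pytest.approx(2.0 - u2, abs=1e-12)
        assert hi == pytest.approx(2.0 + u2, abs=1e-12)

    def test_brute_force_within_bounds(self, rng):
        spec = TransformSpec(1.0)
        for _ in range(10):
            alpha = rng.normal(0, 0.4, 2)
            e = EdgeState.zeros(2)
            w = rng.normal(0, 0.8)
            e.beta[0, 1] = e.beta[1, 0] = w
            lo, hi = normalizing_constant_bounds(alpha, e, spec)
            log_a = brute_force_log_norm_const(alpha, e, spec, 200)
            assert lo - 1e-9 <= log_a <= hi + 1e-9
            assert lo <= hi


class TestConditional:
    def test_no_edges_matches_truncated_poisson(self, cfg_small, spec1):
        e = EdgeState.zeros(2)
        lam = 2.5
        B = cfg_small.truncation_B
        k = np.arange(B + 1)
        logpmf = poisson.logpmf(k, lam) - np.log(poisson.cdf(B, lam))
        for x in (0, 1, 7, 30):
            got = conditional_logpmf(0, [x, 3], math.log(lam), e, spec1, cfg_small)
            assert got == pytest.approx(logpmf[x], abs=1e-10)

    def test_normalizes_to_one(self, rng, cfg_small, edges_factory):
        spec = TransformSpec(1.7)
        for _ in range(5):
            e = edges_factory(3, rng)
            x_row = rng.poisson(3, 3)
            a = rng.normal(0.5, 0.5)
            tot = logsumexp(
                [
                    conditional_logpmf(
                        1,
                        np.array([x_row[0], k, x_row[2]]),
                        a,
                        e,
                        spec,
                        cfg_small,
                    )
                    for k in range(cfg_small.truncation_B + 1)
                ]
            )
            assert tot == pytest.approx(0.0, abs=1e-10)

    def test_matches_enumerated_joint(self, rng):
        from conga.simulate import oracle_joint_table

        B = 20
        cfg = ConditionalConfig(truncation_B=B)
        spec = TransformSpec(1.3)
        log_lam = rng.normal(0.8, 0.3, 3)
        e = EdgeState.zeros(3)
        w01, w02, w12 = rng.normal(0, 0.7, 3)
        e.beta[0, 1] = e.beta[1, 0] = w01
        e.beta[0, 2] = e.beta[2, 0] = w02
        e.beta[1, 2] = e.beta[2, 1] = w12
        table = oracle_joint_table(log_lam, e, spec, B)
        x_rest = (3, 5)
        cond = table[:, x_rest[0], x_rest[1]]
        cond = np.log(cond / cond.sum())
        for xj in (0, 2, 9):
            got = conditional_logpmf(
                0, np.array([xj, *x_rest]), log_lam[0], e, spec, cfg
            )
            assert got == pytest.approx(cond[xj], abs=1e-10)

    def test_count_above_truncation_raises(self, cfg_small, spec1):
        with pytest.raises(ValueError, match="truncation_B"):
            conditional_logpmf(0, [31, 2], 0.0, EdgeState.zeros(2), spec1, cfg_small)


class TestTruncationErrorBound:
    def test_vanishes_as_B_grows(self, spec1):
        assert truncation_error_bound(400, 2.0, [1.0], [0.5], spec1) == 0.0

    def test_no_negative_edges_reduces_to_poisson_tail(self, spec1):
        lam = 3.0
        got = truncation_error_bound(25, lam, [2.0, 4.0], [0.3, 0.0], spec1)
        assert got == pytest.approx(math.exp(lam) * poisson.sf(25, lam), rel=1e-12)

    def test_monotone_nonincreasing_in_B(self, spec1, rng):
        beta = rng.normal(0, 1, 4)
        x = rng.poisson(3, 4).astype(float)
        vals = [truncation_error_bound(B, 2.0, x, beta, spec1) for B in range(0, 120)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_loose_variant_dominates(self, spec1, rng):
        beta = -np.abs(rng.normal(0, 1, 3))
        x = rng.poisson(2, 3).astype(float)
        tight = truncation_error_bound(10, 2.0, x, beta, spec1)
        loose = truncation_error_bound(10, 2.0, x, beta, spec1, loose=True)
        assert loose >= tight

    def test_dominates_true_truncation_error(self, spec1):
        # single-node conditional with one negative edge: the bound must
        # exceed the actual mass dropped from the normalizer
        lam, eta_partner, w = 2.0, 4.0, -0.8
        a = math.log(lam)
        fk_partner = transform(eta_partner, spec1)
        k = np.arange(400)
        terms = k * a - gammaln(k + 1.0) - transform(k, spec1) * (w * fk_partner)
        full = np.exp(terms)
        for B in (5, 10, 20, 40):
            true_err = full[B + 1 :].sum()
            bound = truncation_error_bound(B, lam, [eta_partner], [w], spec1)
            assert bound >= true_err


class TestTuneTheta:
    def test_constant_data_warns_and_returns_low(self):
        counts = CountMatrix(values=np.full((6, 2), 4))
        with pytest.warns(UserWarning):
            res = tune_theta(counts, (0.2, 5.0))
        assert res.theta == pytest.approx(0.2)

    def test_local_optimality_and_grid_agreement(self, rng):
        from conga.simulate import CopulaSimConfig, simulate_copula_poisson

        om = np.eye(4) * 1.2
        om[0, 1] = om[1, 0] = 0.4
        counts, _ = simulate_copula_poisson(
            CopulaSimConfig(n=150, P=4, precision=om, poisson_mean=4.0, seed=5)
        )
        res = tune_theta(counts)
        X = counts.values.astype(float)
        cov_x = np.cov(X, rowvar=False)

        def obj(t):
            return np.linalg.norm(
                np.cov(np.arctan(X) ** t, rowvar=False) - cov_x, ord="fro"
            )

        assert obj(res.theta) <= obj(res.theta + 0.1) + 1e-9
        assert obj(res.theta) <= obj(res.theta - 0.1) + 1e-9
        dense = np.arange(0.1, 10.0, 1e-3)
        best = dense[np.argmin([obj(t) for t in dense])]
        assert res.theta == pytest.approx(best, abs=2e-3)


class TestCountMatrix:
    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            CountMatrix(values=np.array([[1.5, 2.0], [0.0, 1.0]]))
        with pytest.raises(ValueError):
            CountMatrix(values=np.array([[-1, 2], [0, 1]]))
        with pytest.raises(ValueError):
            CountMatrix(values=np.array([[1, 2]]))  # n < 2

    def test_default_labels(self):
        cm = CountMatrix(values=np.zeros((3, 2), dtype=int))
        assert cm.node_names == ["V1", "V2"]
        assert len(cm.replicate_ids) == 3
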