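"""Bayes-factor checks against brute-force quadrature and pingouin.

The oracle evaluates the one-sided JZS Bayes factor by direct truncated-prior
integration on fixed Simpson grids: the noncentral-t likelihood is itself
computed by Simpson integration of the chi-square scale-mixture in log-v
space (independent of the package's peak-located Gauss-Legendre scheme), and
the prior integral runs over the Cauchy angle theta = arctan(delta / r).
"""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import integrate, special, stats

from multitrial.bayes import (
    DEFAULT_PRIOR_SCALE,
    bf_decision,
    jzs_bf_from_t,
    jzs_bf_one_sided,
    min_bf,
    pool_trials,
)
from multitrial.simulate import EffectModel, SimulationConfig, generate_dataset
from multitrial.ttests import one_sided_t_test

R = DEFAULT_PRIOR_SCALE


def oracle_log_nct(x: float, df: float, ncp: np.ndarray) -> np.ndarray:
    """Noncentral-t log-density by Simpson in w = log(v), v ~ chi2(df).

    f(x; df, mu) = Int phi(x sqrt(v/df) - mu) sqrt(v/df) chi2_df(v) dv.
    """
    w = np.linspace(math.log(df) - 6.0, math.log(df) + 6.0, 4001)
    v = np.exp(w)
    s = np.sqrt(v / df)
    log_chi2 = (
        (df / 2.0 - 1.0) * np.log(v) - v / 2.0
        - (df / 2.0) * math.log(2.0) - special.gammaln(df / 2.0)
    )
    base = log_chi2 + np.log(s) + w  # + w: Jacobian of v = exp(w)
    out = np.empty(ncp.size)
    for i in range(0, ncp.size, 500):
        mu = ncp[i:i + 500, None]
        z = x * s[None, :] - mu
        log_f = base[None, :] - 0.5 * z * z - 0.5 * math.log(2 * math.pi)
        m = log_f.max(axis=1, keepdims=True)
        out[i:i + 500] = (
            np.log(integrate.simpson(np.exp(log_f - m), x=w, axis=1))
            + m[:, 0]
        )
    return out


def oracle_one_sided_bf(t: float, n1: int, n2: int, r: float = R) -> float:
    nu = n1 + n2 - 2
    n_eff = n1 * n2 / (n1 + n2)
    theta = np.linspace(1e-9, math.pi / 2 - 1e-9, 4001)
    delta = r * np.tan(theta)
    log_f = oracle_log_nct(t, nu, delta * math.sqrt(n_eff))
    m = log_f.max()
    numer = integrate.simpson(np.exp(log_f - m), x=theta) * (2.0 / math.pi)
    log_numer = math.log(numer) + m
    return math.exp(log_numer - stats.t.logpdf(t, nu))


class TestJZSOracleEquivalence:
    @pytest.mark.parametrize("n", [20, 100, 400, 2000])
    @pytest.mark.parametrize("t", [-3.0, 0.0, 2.0, 5.0, 8.0])
    def test_one_sided_matches_bruteforce(self, t, n):
        ours = jzs_bf_from_t(t, n, n).bf_10
        ref = oracle_one_sided_bf(t, n, n)
        assert ours == pytest.approx(ref, rel=1e-4)

    def test_two_sided_matches_pingouin(self):
        import pingouin as pg

        for t, n in [(1.5, 20), (2.2, 15), (-2.0, 100), (4.0, 400)]:
            ours = jzs_bf_from_t(t, n, n, one_sided=False).bf_10
            ref = float(pg.bayesfactor_ttest(t, n, n, paired=False, r=R))
            assert ours == pytest.approx(ref, rel=1e-8)


class TestJZSProperties:
    def test_t_zero_one_sided_equals_two_sided_and_below_one(self):
        for n in (5, 20, 200):
            one = jzs_bf_from_t(0.0, n, n).bf_10
            two = jzs_bf_from_t(0.0, n, n, one_sided=False).bf_10
            assert one == pytest.approx(two, rel=1e-9)
            assert one < 1.0

    def test_positive_negative_mass_identity(self):
        # BF+(t) + BF+(-t) = 2 BF2(t): posterior masses sum to one
        for t, n in [(1.3, 25), (3.0, 100), (0.4, 400)]:
            plus = jzs_bf_from_t(t, n, n).bf_10
            minus = jzs_bf_from_t(-t, n, n).bf_10
            two = jzs_bf_from_t(t, n, n, one_sided=False).bf_10
            assert plus + minus == pytest.approx(2 * two, rel=1e-6)

    def test_monotone_in_t(self):
        bfs = [jzs_bf_from_t(t, 50, 50).bf_10
               for t in np.linspace(-2, 6, 17)]
        assert np.all(np.diff(bfs) > 0)

    def test_predictive_matching_limit(self):
        # as the effective sample size vanishes the data cannot discriminate
        # the models and the Bayes factor approaches 1
        from multitrial.bayes import _two_sided_log_bf
        assert _two_sided_log_bf(1.7, 10.0, 1e-12, R) == pytest.approx(
            0.0, abs=1e-6
        )

    def test_model_selection_consistency(self):
        # fixed true standardized effect 0.4: evidence accumulates with n;
        # at the null, the BF at t=0 vanishes as n grows
        alt = [
            jzs_bf_from_t(0.4 * math.sqrt(n / 2.0), n, n).bf_10
            for n in (20, 100, 400, 2000)
        ]
        assert np.all(np.diff(alt) > 0) and alt[-1] > 1e6
        null = [jzs_bf_from_t(0.0, n, n).bf_10 for n in (20, 200, 2000)]
        assert np.all(np.diff(null) < 0)

    def test_raw_data_route_matches_t_route(self, rng):
        c = rng.normal(0, 1, 40)
        e = rng.normal(0.5, 1, 40)
        res = jzs_bf_one_sided(c, e)
        t = one_sided_t_test(c, e).t_statistic
        assert res.bf_10 == pytest.approx(
            jzs_bf_from_t(t, 40, 40).bf_10, rel=1e-12
        )

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            jzs_bf_from_t(float("nan"), 10, 10)
        with pytest.raises(ValueError):
            jzs_bf_from_t(1.0, 1, 10)
        with pytest.raises(ValueError):
            jzs_bf_from_t(1.0, 10, 10, prior_scale=0.0)


class TestPoolTrials:
    def test_concatenation_preserves_values(self, rng):
        cfg = SimulationConfig(EffectModel(0.0), 20, 5)
        ds = generate_dataset(cfg, 0.4, rng)
        control, experimental = pool_trials(ds)
        assert control.shape == experimental.shape == (100,)
        assert np.array_equal(control, ds.control.ravel())
        assert experimental.mean() == pytest.approx(
            ds.experimental.mean(axis=1).mean()
        )

    def test_single_trial_identity(self, rng):
        cfg = SimulationConfig(EffectModel(0.0), 10, 1)
        ds = generate_dataset(cfg, 0.0, rng)
        control, _ = pool_trials(ds)
        assert np.array_equal(control, ds.control[0])


class TestMinBF:
    def test_calibration_boundary_is_exactly_one(self):
        assert min_bf(1.0 / math.e).bf_10 == 1.0
        assert min_bf(0.9).bf_10 == 1.0

    def test_printed_calibration_value(self):
        assert min_bf(0.05).bf_10 == pytest.approx(
            2.456023486604883, abs=1e-12
        )

    @given(st.floats(1e-6, 1 / math.e - 1e-6), st.floats(1e-4, 0.2))
    def test_monotone_decreasing_in_p(self, p1, gap):
        p2 = min(p1 + gap, 1 / math.e - 1e-9)
        if p2 > p1:
            assert min_bf(p1).bf_10 >= min_bf(p2).bf_10

    def test_bounds_jzs_evidence(self):
        # the minimum BF is an upper bound on the evidence of any specific
        # local alternative, hence above the JZS value at matched t
        for t, n in [(2.0, 20), (2.5, 100), (3.5, 400)]:
            p = stats.t.sf(t, 2 * n - 2)
            assert min_bf(p).bf_10 > jzs_bf_from_t(t, n, n).bf_10

    def test_domain_errors(self):
        for bad in (0.0, 1.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                min_bf(bad)


class TestBFDecision:
    @pytest.mark.parametrize("bf,thr,expected", [
        (50.0, 50.0, False),   # strict inequality at the boundary
        (10.5, 10.0, True),
        (2.0, 3.0, False),
    ])
    def test_strict_threshold(self, bf, thr, expected):
        res = min_bf(0.5)
        object.__setattr__(res, "bf_10", bf)
        assert bf_decision(res, thr) is expected

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            bf_decision(min_bf(0.5), 0.0)
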