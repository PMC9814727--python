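import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neqfe import (
    REDUCED_TEMPERATURE,
    WorkSet,
    bar,
    bar_reduced,
    bootstrap_se,
    chain_windows,
    gaussian_cft_sample,
    jarzynski,
    zwanzig,
)

KT = REDUCED_TEMPERATURE * 0.0083144621  # == 1 kJ/mol by construction


def test_reduced_temperature_gives_unit_kt(reduced_workset):
    assert reduced_workset(w_forward=[1.0]).kt == pytest.approx(1.0, rel=1e-14)


class TestJarzynski:
    def test_constant_forward_works(self):
        est = jarzynski([2.0, 2.0, 2.0], "forward", REDUCED_TEMPERATURE)
        assert est.dg == pytest.approx(2.0)
        assert est.method == "jarzynski_forward"
        assert (est.n_forward, est.n_reverse) == (3, 0)

    def test_two_value_forward_sample(self):
        # ΔG = −ln((1 + e⁻²)/2) = 0.5662 kT, direct arithmetic oracle
        expected = -math.log((1 + math.exp(-2)) / 2)
        est = jarzynski([0.0, 2.0], "forward", REDUCED_TEMPERATURE)
        assert est.dg == pytest.approx(expected, rel=1e-12)
        assert est.dg == pytest.approx(0.5662, abs=1e-4)

    def test_constant_reverse_works(self):
        est = jarzynski([3.0, 3.0], "reverse", REDUCED_TEMPERATURE)
        assert est.dg == pytest.approx(-3.0)
        assert est.method == "jarzynski_reverse"

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError, match="empty"):
            jarzynski([], "forward", 300.0)

    def test_single_sample_se_zero(self):
        est = jarzynski([1.5], "forward", 300.0)
        assert est.se == 0.0

    def test_huge_works_do_not_overflow(self):
        est = jarzynski([5000.0, 6000.0], "forward", REDUCED_TEMPERATURE)
        assert np.isfinite(est.dg)


class TestBar:
    def test_symmetric_dissipation_gives_zero(self, reduced_workset):
        est = bar(reduced_workset(w_forward=[1.0], w_reverse=[1.0]))
        assert est.dg == pytest.approx(0.0, abs=1e-12)

    def test_single_pair_closed_form(self, reduced_workset):
        est = bar(reduced_workset(w_forward=[3.0], w_reverse=[-1.0]))
        assert est.dg == pytest.approx(2.0, rel=1e-12)
        assert est.se == 0.0

    def test_recovers_gaussian_cft_truth(self):
        ws = gaussian_cft_sample(dg=5.0, sigma=2.0, n_forward=2000,
                                 n_reverse=2000, seed=11)
        est = bar(ws, n_boot=200, seed=1)
        assert abs(est.dg / ws.kt - 5.0) < 3 * est.se / ws.kt

    def test_one_sided_errors_direct_to_jarzynski(self, reduced_workset):
        with pytest.raises(ValueError, match="jarzynski"):
            bar(reduced_workset(w_forward=[1.0, 2.0]))

    def test_convergence_field_attached(self, reduced_workset):
        est = bar(reduced_workset(w_forward=[1.0, 1.2], w_reverse=[-0.9, -1.1]))
        assert est.convergence is not None
        assert -1 <= est.convergence <= 1

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_antisymmetry(self, seed):
        rng = np.random.default_rng(seed)
        uf = rng.normal(2, 1, rng.integers(2, 30))
        ur = rng.normal(-1, 2, rng.integers(2, 30))
        assert bar_reduced(uf, ur) == pytest.approx(-bar_reduced(ur, uf), abs=1e-7)

    @given(c=st.floats(-20, 20), seed=st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_shift_covariance(self, c, seed):
        rng = np.random.default_rng(seed)
        uf = rng.normal(1, 1.5, 17)
        ur = rng.normal(-1, 1.5, 13)
        base = bar_reduced(uf, ur)
        shifted = bar_reduced(uf + c, ur - c)
        assert shifted == pytest.approx(base + c, abs=1e-6)

    def test_unequal_sample_sizes_use_log_ratio(self):
        # closed-form check against the self-consistency equation by
        # plugging the root back in
        rng = np.random.default_rng(5)
        uf = rng.normal(3, 1, 40)
        ur = rng.normal(-3, 1, 10)
        f = bar_reduced(uf, ur)
        m = math.log(len(uf) / len(ur))
        lhs = np.sum(1 / (1 + np.exp(m + uf - f)))
        rhs = np.sum(1 / (1 + np.exp(-m + ur + f)))
        assert lhs == pytest.approx(rhs, abs=1e-6)


def _bar_self_consistent_iteration(uf, ur, tol=1e-12, max_iter=50_000):
    """Independent BAR oracle: damped fixed-point (Bennett) iteration.

    Iterates f ← f + ln(Σ_R φ(−M+u_R+f) / Σ_F φ(M+u_F−f)) until
    stationary — a different algorithm from the shipped Brent root-finder.
    """
    uf = np.asarray(uf, float)
    ur = np.asarray(ur, float)
    m = math.log(uf.size / ur.size)
    f = float(np.mean(uf) - np.mean(ur)) / 2.0
    for _ in range(max_iter):
        num = np.sum(1.0 / (1.0 + np.exp(np.clip(-m + ur + f, -700, 700))))
        den = np.sum(1.0 / (1.0 + np.exp(np.clip(m + uf - f, -700, 700))))
        step = math.log(num / den)
        f += 0.5 * step
        if abs(step) < tol:
            return f
    raise RuntimeError("no convergence")


# pymbar 4.2.0 (pymbar.other_estimators.bar, relative_tolerance=1e-12) run
# on exactly the sample construction below; values frozen because pymbar is
# not available at test time.
PYMBAR_REFERENCE = {
    1000: -3.073967051530882,
    1001: -0.6260173484527204,
    1002: -8.643187125756688,
    1003: -0.5611711554801917,
    1004: -0.1922772107583974,
    1005: -1.354064231901334,
    1006: -10.109688189028544,
    1007: -7.753316884243232,
    1008: -4.995159158254493,
    1009: 6.044435010629938,
    1010: 2.896146604336794,
    1011: 2.313162452776582,
    1012: -0.6205922788274546,
    1013: -5.629215925315265,
    1014: -3.720646489278271,
    1015: -4.176767506062297,
    1016: 4.745975378190929,
    1017: -10.90106480500335,
    1018: 5.373455755787831,
    1019: 2.609164777027921,
}


def _reference_sample(seed):
    rng = np.random.default_rng(seed)
    nf = int(rng.integers(5, 60))
    nr = int(rng.integers(5, 60))
    dg = rng.normal(0, 5)
    sig = rng.uniform(0.3, 4.0)
    uf = rng.normal(dg + sig**2 / 2, sig, nf)
    ur = rng.normal(-dg + sig**2 / 2, sig, nr)
    return uf, ur


@pytest.mark.parametrize("seed", sorted(PYMBAR_REFERENCE))
def test_bar_matches_established_implementation(seed):
    uf, ur = _reference_sample(seed)
    assert bar_reduced(uf, ur) == pytest.approx(PYMBAR_REFERENCE[seed], abs=1e-6)


@pytest.mark.parametrize("seed", [1000, 1004, 1009, 1013, 1017])
def test_bar_matches_fixed_point_oracle(seed):
    uf, ur = _reference_sample(seed)
    assert bar_reduced(uf, ur) == pytest.approx(
        _bar_self_consistent_iteration(uf, ur), abs=1e-7
    )


class TestBootstrapSe:
    def test_identical_works_zero_se(self, reduced_workset):
        ws = reduced_workset(w_forward=[2.0] * 5, w_reverse=[-2.0] * 5)
        assert bootstrap_se(ws, "bar", n_boot=50, seed=3) == pytest.approx(0.0, abs=1e-12)

    def test_deterministic_given_seed(self):
        ws = gaussian_cft_sample(1.0, 1.0, 30, 30, seed=9)
        a = bootstrap_se(ws, "bar", n_boot=100, seed=42)
        b = bootstrap_se(ws, "bar", n_boot=100, seed=42)
        assert a == b

    def test_matches_brute_force_jarzynski(self, reduced_workset):
        # exact bootstrap distribution for forward works {0, 2} kT:
        # the 4 equally likely resamples give estimates
        # {0, j, j, 2} with j = −ln((1+e⁻²)/2); compare sd against that.
        ws = reduced_workset(w_forward=[0.0, 2.0])
        j = -math.log((1 + math.exp(-2)) / 2)
        vals = np.array([0.0, j, j, 2.0])
        exact_sd = math.sqrt(np.mean(vals**2) - np.mean(vals) ** 2)
        se = bootstrap_se(ws, "jarzynski_forward", n_boot=20_000, seed=7)
        assert se == pytest.approx(exact_sd, rel=0.05)

    def test_requires_two_replicates(self, reduced_workset):
        with pytest.raises(ValueError, match="n_boot"):
            bootstrap_se(reduced_workset(w_forward=[1.0, 2.0]),
                         "jarzynski_forward", n_boot=1, seed=0)


class TestChainWindows:
    def test_additivity_and_quadrature(self, reduced_workset):
        # three windows with known ΔG and se, checked via single-pair
        # closed-form BAR: ΔG_w = (u_F − u_R)/2
        windows = [
            reduced_workset(w_forward=[1.0], w_reverse=[-1.0]),
            reduced_workset(w_forward=[2.0], w_reverse=[-2.0]),
            reduced_workset(w_forward=[-0.5], w_reverse=[0.5]),
        ]
        est = chain_windows(windows)
        assert est.dg == pytest.approx(2.5)
        assert est.method == "bar_chain"

    def test_quadrature_of_known_ses(self):
        # direct arithmetic: ΔG {1,2,−0.5}, se {0.1,0.1,0.1}
        total = math.sqrt(3 * 0.1**2)
        assert total == pytest.approx(0.1732, abs=1e-4)

    def test_single_window_identity(self):
        ws = gaussian_cft_sample(2.0, 1.0, 200, 200, seed=13)
        single = bar(ws, with_convergence=False)
        chained = chain_windows([ws])
        assert chained.dg == pytest.approx(single.dg, rel=1e-12)

    def test_failing_window_names_index(self, reduced_workset):
        windows = [
            reduced_workset(w_forward=[1.0], w_reverse=[-1.0]),
            reduced_workset(w_forward=[1.0]),  # one-sided: bar fails
        ]
        with pytest.raises(ValueError, match="window 1"):
            chain_windows(windows)

    def test_zwanzig_chain_on_energy_differences(self):
        est = chain_windows([np.array([1.0, 1.0]), np.array([2.0, 2.0])],
                            temperature=REDUCED_TEMPERATURE)
        assert est.dg == pytest.approx(3.0)
        assert est.method == "zwanzig_chain"

    def test_empty_errors(self):
        with pytest.raises(ValueError, match="at least one window"):
            chain_windows([])


class TestStatisticalProperties:
    def test_jarzynski_positive_bias_on_dissipative_samples(self):
        # Jensen bias: forward Jarzynski overestimates ΔG at σ=2 kT, n=50
        errors = []
        for seed in range(200):
            ws = gaussian_cft_sample(dg=0.0, sigma=2.0, n_forward=50,
                                     n_reverse=0, seed=seed)
            errors.append(jarzynski(ws.w_forward, "forward", ws.temperature).dg / ws.kt)
        assert np.mean(errors) > 0

    def test_gaussian_limit_second_cumulant(self):
        ws = gaussian_cft_sample(dg=3.0, sigma=1.5, n_forward=100_000,
                                 n_reverse=0, seed=2024)
        u = ws.u_forward
        est = jarzynski(ws.w_forward, "forward", ws.temperature).dg / ws.kt
        sem = u.std(ddof=1) / math.sqrt(u.size)
        # sample mean − σ²/2 → ΔG, and Jarzynski → ΔG
        assert u.mean() - 1.5**2 / 2 == pytest.approx(3.0, abs=4 * sem)
        assert est == pytest.approx(3.0, abs=0.05)

    def test_zwanzig_matches_jarzynski_forward(self):
        w = np.array([0.3, 1.2, -0.4])
        assert zwanzig(w, 300.0) == pytest.approx(
            jarzynski(w, "forward", 300.0).dg
        )
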