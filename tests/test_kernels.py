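"""Kinship probability kernels: closed-population identities and toy oracles."""

import numpy as np
import pytest

from sealkin.demography import LifeHistorySchedules, PopulationTrajectory
from sealkin.kernels import (
    KinKernelContext,
    SampleRecord,
    p_ggp,
    p_mhsp,
    p_phsp,
    p_pop,
    p_second_order,
    rel_prob_hsp,
)

from conftest import constant_trajectory, rec


def flat_context(nf_per_age=10.0, f=None, m=None, phi=None, pi=1.0, years=(1950, 2030)):
    """Fully controllable context with a constant age-flat population."""
    n = 40
    phi = np.full(n, 1.0) if phi is None else np.asarray(phi, float)
    phi = phi.copy()
    phi[-1] = 0.0
    f = np.asarray(f, float) if f is not None else np.r_[0.0, np.full(n - 1, 0.5)]
    m = np.asarray(m, float) if m is not None else np.r_[0.0, np.full(n - 1, 1.0)]
    sched = LifeHistorySchedules(phi=phi, fecundity=f, maturity=m)
    T = years[1] - years[0] + 1
    NF = np.full((T, n), nf_per_age)
    traj = PopulationTrajectory(start_year=years[0], NF=NF, NM=NF.copy(), lam=1.0)
    return KinKernelContext(traj, sched, pi=pi)


class TestPop:
    def test_mother_dead_before_birth_is_zero(self, toy_context):
        mother = rec("m", "F", 1990, 1999)
        pup = rec("p", "F", 2000, 2000)
        assert p_pop(mother, pup, toy_context) == 0.0

    def test_zero_fecundity_age_is_zero(self):
        ctx = flat_context(f=np.r_[0, 0, 0, np.full(37, 0.5)])
        mother = rec("m", "F", 1998, 2005)  # aged 2 at birth year 2000
        pup = rec("p", "F", 2000, 2001)
        assert p_pop(mother, pup, ctx) == 0.0

    def test_single_age_class_gives_one_over_k(self):
        # K females in the only reproducing age class: maternity is 1/K
        K = 25.0
        f = np.zeros(40)
        f[5] = 1.0
        ctx = flat_context(nf_per_age=K, f=f)
        mother = rec("m", "F", 1995, 2005)  # aged 5 in 2000
        pup = rec("p", "M", 2000, 2001)
        assert p_pop(mother, pup, ctx) == pytest.approx(1.0 / K)

    def test_conservation_of_motherhood(self, toy_context):
        # summing the kernel over every female alive in the birth year = 1
        b = 2000
        t = toy_context._t(b)
        NF = toy_context.trajectory.NF[t]
        total = 0.0
        for a in range(1, 40):
            mother = rec(f"m{a}", "F", b - a, b + 1)
            total += NF[a] * p_pop(mother, rec("p", "F", b, b), toy_context)
        assert total == pytest.approx(1.0, rel=1e-10)

    def test_pi_cancels_for_paternity(self):
        father = rec("f", "M", 1990, 2005)
        pup = rec("p", "F", 2000, 2001)
        p1 = p_pop(father, pup, flat_context(pi=1.0))
        p2 = p_pop(father, pup, flat_context(pi=0.3))
        assert p1 == pytest.approx(p2)

    def test_year_outside_trajectory_raises(self, toy_context):
        with pytest.raises(KeyError):
            p_pop(rec("m", "F", 1900, 1940), rec("p", "F", 1910, 1910), toy_context)


class TestHalfSiblings:
    def test_same_cohort_maternal_impossible(self, toy_context):
        a = rec("a", "F", 2000, 2003)
        b = rec("b", "F", 2000, 2004)
        assert p_mhsp(a, b, toy_context) == 0.0

    def test_dead_adults_cannot_share(self):
        ctx = flat_context(phi=np.zeros(40))
        assert p_mhsp(rec("a", "F", 2000, 2001), rec("b", "F", 2002, 2002), ctx) == 0.0

    def test_unordered_pair_rejected(self, toy_context):
        with pytest.raises(ValueError):
            p_mhsp(rec("a", "F", 2005, 2006), rec("b", "F", 2000, 2001), toy_context)

    def test_pi_one_reduces_paternal_to_maternal_mirror(self):
        # identical f and m schedules: the paternal kernel at pi=1 equals the
        # maternal kernel for delta >= 1
        f = np.r_[0.0, np.full(39, 0.5)]
        ctx = flat_context(f=f, m=f, pi=1.0)
        a, b = rec("a", "F", 2000, 2001), rec("b", "F", 2003, 2003)
        assert p_phsp(a, b, ctx) == pytest.approx(p_mhsp(a, b, ctx))

    def test_halving_pi_doubles_paternal(self):
        a, b = rec("a", "M", 2000, 2001), rec("b", "F", 2003, 2003)
        p1 = p_phsp(a, b, flat_context(pi=0.8))
        p2 = p_phsp(a, b, flat_context(pi=0.4))
        assert p2 == pytest.approx(2 * p1)

    def test_same_cohort_paternal_allowed(self, toy_context):
        a = rec("a", "F", 2000, 2003)
        b = rec("b", "M", 2000, 2004)
        assert p_phsp(a, b, toy_context) > 0.0

    def test_invalid_pi_rejected(self, toy_context):
        with pytest.raises(ValueError):
            KinKernelContext(toy_context.trajectory, toy_context.schedules, pi=0.0)


class TestGrandparent:
    def test_male_older_cannot_share_mtdna(self, toy_context):
        g = rec("g", "M", 1990, 2010)
        j = rec("j", "F", 2005, 2006)
        assert p_ggp(g, j, True, toy_context) == 0.0

    def test_small_birth_gap_infeasible(self):
        # knife-edge breeding at 5: a gap below 2 generations leaves no chain
        f = np.zeros(40)
        f[5:] = 0.5
        m = np.zeros(40)
        m[5:] = 1.0
        ctx = flat_context(f=f, m=m)
        g = rec("g", "F", 2000, 2015)
        j = rec("j", "F", 2009, 2010)  # gap 9 < 10
        assert p_ggp(g, j, True, ctx) + p_ggp(g, j, False, ctx) == 0.0

    def test_hand_enumerated_chain(self):
        # reproduction only at age 5 (females, f=0.5) and age 6 (males, m=1):
        # the only grandmother-daughter chain for a gap of 10 runs through a
        # daughter born b_i + 5:
        #   0.5 (daughter) * f_5 * [survive 5 yrs = 1] * f_5 / (10 ages... )
        f = np.zeros(40)
        f[5] = 0.5
        m = np.zeros(40)
        m[6] = 1.0
        K = 10.0
        ctx = flat_context(nf_per_age=K, f=f, m=m)
        g = rec("g", "F", 2000, 2006)
        j = rec("j", "F", 2010, 2011)
        expected = (0.5 * 0.5) * 1.0 * (0.5 / (K * 0.5))
        assert p_ggp(g, j, True, ctx) == pytest.approx(expected)
        assert p_ggp(g, j, False, ctx) == 0.0  # no feasible male-intermediate chain

    def test_grandparent_dead_before_chain_is_zero(self):
        f = np.zeros(40)
        f[5] = 0.5
        m = np.zeros(40)
        m[6] = 1.0
        ctx = flat_context(f=f, m=m)
        g = rec("g", "F", 2000, 2003)  # dead before the daughter could be born (2005)
        j = rec("j", "F", 2010, 2011)
        assert p_ggp(g, j, True, ctx) == 0.0


class TestSecondOrderAndScaling:
    def test_fn_rate_one_kills_probability(self, default_schedules):
        traj = constant_trajectory(default_schedules, 10_000, 1950, 2025)
        ctx = KinKernelContext(traj, default_schedules, pi=0.5, fn_rate=1.0 - 1e-12)
        p = p_second_order(rec("a", "F", 2000, 2001), rec("b", "F", 2004, 2004), False, ctx)
        assert p == pytest.approx(0.0, abs=1e-12)

    def test_pure_hsp_when_no_ggp(self, toy_context):
        # a one-year gap leaves no room for an intermediate generation
        a, b = rec("a", "F", 2000, 2001), rec("b", "F", 2001, 2002)
        assert p_ggp(a, b, True, toy_context) == 0.0
        assert p_second_order(a, b, True, toy_context) == pytest.approx(p_mhsp(a, b, toy_context))

    def test_unknown_stratum_pools_both(self, toy_context):
        a, b = rec("a", "F", 2000, 2005, "H1"), rec("b", "F", 2004, 2004, "H2")
        total = p_second_order(a, b, None, toy_context)
        assert total == pytest.approx(
            p_second_order(a, b, True, toy_context) + p_second_order(a, b, False, toy_context)
        )

    def test_kernels_scale_as_one_over_n(self, default_schedules):
        small = KinKernelContext(
            constant_trajectory(default_schedules, 10_000, 1950, 2025), default_schedules, pi=0.5
        )
        big = KinKernelContext(
            constant_trajectory(default_schedules, 20_000, 1950, 2025), default_schedules, pi=0.5
        )
        mother, pup = rec("m", "F", 1990, 2005), rec("p", "F", 2000, 2000)
        a, b = rec("a", "F", 2000, 2001), rec("b", "F", 2004, 2004)
        g, j = rec("g", "F", 1990, 2008), rec("j", "F", 2005, 2006)
        for fn, args in [
            (p_pop, (mother, pup)),
            (p_mhsp, (a, b)),
            (p_phsp, (a, b)),
            (p_ggp, (g, j, True)),
        ]:
            ps, pb = fn(*args, small), fn(*args, big)
            assert ps == pytest.approx(2 * pb, rel=1e-9)

    def test_kernels_bounded_random_records(self, toy_context):
        rng = np.random.default_rng(0)
        for _ in range(200):
            b1, b2 = sorted(rng.integers(1960, 2020, size=2))
            a = rec("a", rng.choice(["F", "M"]), b1, b1 + int(rng.integers(0, 20)))
            b = rec("b", rng.choice(["F", "M"]), b2, b2 + int(rng.integers(0, 5)))
            vals = [
                p_mhsp(a, b, toy_context),
                p_phsp(a, b, toy_context),
                p_ggp(a, b, a.sex == "F", toy_context),
                p_second_order(a, b, False, toy_context),
            ]
            for v in vals:
                assert 0.0 <= v <= 1.0


class TestRelProbHsp:
    def test_infeasible_ggp_gives_one(self, toy_context):
        a, b = rec("a", "F", 2008, 2008), rec("b", "F", 2011, 2011)  # gap 3
        assert rel_prob_hsp(a, b, True, toy_context) == pytest.approx(1.0)

    def test_equal_components_give_half(self):
        # construct p_hsp == p_ggp by direct computation, then check the ratio
        f = np.zeros(40)
        f[5] = 0.5
        m = np.zeros(40)
        m[6] = 1.0
        ctx = flat_context(nf_per_age=10.0, f=f, m=m)
        g, j = rec("g", "F", 2000, 2006), rec("j", "F", 2010, 2011)
        hsp = p_mhsp(g, j, ctx)
        ggp = p_ggp(g, j, True, ctx)
        expected = hsp / (hsp + ggp)
        assert rel_prob_hsp(g, j, True, ctx) == pytest.approx(expected)

    def test_both_zero_flagged(self):
        ctx = flat_context(phi=np.zeros(40))
        a, b = rec("a", "F", 2000, 2000), rec("b", "F", 2005, 2005)
        with pytest.warns(UserWarning):
            out = rel_prob_hsp(a, b, True, ctx)
        assert np.isnan(out)
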