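"""Competition dynamics: theta_in/theta_eq, ODE invariants, reaction yields."""

import math

import numpy as np
import pandas as pd
import pytest

from hybrikin import (
    MixtureSystem,
    TimeCourse,
    equilibration_halflife,
    equilibrium_accuracy,
    reaction_yields,
    simulate_mixture,
    theta_in,
)


def tgrid(tmax, n=400):
    return np.concatenate([[0.0], np.geomspace(max(tmax * 1e-9, 1e-9), tmax, n)])


class TestThetaIn:
    def test_equal_rates_give_half(self):
        assert theta_in(1.2e7, 1.2e7) == 0.5

    def test_nine_to_one(self):
        assert theta_in(9e6, 1e6) == pytest.approx(0.9)

    def test_vanishing_competitor_rate(self):
        assert theta_in(1e7, 0.0) == 1.0

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            theta_in(0.0, 1e6)


def cubic_theta_eq(kd_tp, kd_cp, t, c, p):
    """Closed-form oracle: the conservation equation as a cubic in free P."""
    # p*(K_T+p)*(K_C+p) + T*p*(K_C+p) + C*p*(K_T+p) - P*(K_T+p)*(K_C+p) = 0
    a3 = 1.0
    a2 = kd_tp + kd_cp + t + c - p
    a1 = kd_tp * kd_cp + t * kd_cp + c * kd_tp - p * (kd_tp + kd_cp)
    a0 = -p * kd_tp * kd_cp
    roots = np.roots([a3, a2, a1, a0])
    real = [r.real for r in roots if abs(r.imag) < 1e-18 * max(1.0, abs(r)) and 0 <= r.real <= p]
    pf = min(real)
    tp = t * pf / (kd_tp + pf)
    cp = c * pf / (kd_cp + pf)
    return tp / (tp + cp)


class TestEquilibriumAccuracy:
    def test_equal_kds_equimolar_is_half(self):
        th, _ = equilibrium_accuracy(1e-9, 1e-9, 2e-7, 2e-7, 2e-7)
        assert th == pytest.approx(0.5, abs=1e-12)

    def test_weak_competitor_limit_is_one(self):
        th, _ = equilibrium_accuracy(1e-12, 1.0, 1e-6, 1e-6, 5e-7)
        assert th == pytest.approx(1.0, abs=1e-6)

    def test_matches_cubic_closed_form(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            kd_tp = 10.0 ** rng.uniform(-14, -7)
            kd_cp = kd_tp * 10.0 ** rng.uniform(0, 6)
            t, c, p = (10.0 ** rng.uniform(-8, -5) for _ in range(3))
            th, _ = equilibrium_accuracy(kd_tp, kd_cp, t, c, p)
            assert th == pytest.approx(cubic_theta_eq(kd_tp, kd_cp, t, c, p), rel=1e-6)

    def test_species_conservation(self):
        th, sp = equilibrium_accuracy(1e-10, 1e-8, 2e-7, 3e-7, 1.5e-7)
        assert sp["P"] + sp["TP"] + sp["CP"] == pytest.approx(1.5e-7, rel=1e-9)
        assert sp["T"] + sp["TP"] == pytest.approx(2e-7, rel=1e-9)

    def test_rna_double_mismatch_panel_theta_eq_is_one(self, preset):
        """NN-derived K_Ds for the RNA m_4,9 mixture at 1 uM predict
        theta_eq = 1.00 to two decimals."""
        from hybrikin import kd_at

        kd_tp = kd_at(preset.duplex("perfect", rna=True))
        kd_cp = kd_at(preset.duplex("m_4,9", rna=True))
        th, _ = equilibrium_accuracy(kd_tp, kd_cp, 1e-6, 1e-6, 1e-6)
        assert round(th, 2) == 1.00


class TestSimulateMixture:
    def test_no_competitor_matches_closed_form(self):
        """Equal-concentration irreversible binding: x/c = kon*c*t/(1+kon*c*t)."""
        sys_ = MixtureSystem(1e-6, 0.0, 1e-6, 1e7, 0.0, 1e7, 0.0)
        t = tgrid(10.0)
        tc = simulate_mixture(sys_, t)
        expected = 1e-6 * (1e7 * 1e-6 * t) / (1.0 + 1e7 * 1e-6 * t)
        assert np.allclose(tc.species["TP"], expected, rtol=1e-6, atol=1e-15)

    def test_irreversible_theta_reaches_kinetic_partition(self):
        # no-depletion limit (P << T = C): the partition formula is exact
        sys_ = MixtureSystem(2e-7, 2e-7, 2e-9, 1.5e7, 0.0, 0.5e7, 0.0)
        tc = simulate_mixture(sys_, tgrid(1e5))
        assert tc.theta[-1] == pytest.approx(theta_in(1.5e7, 0.5e7), abs=1e-3)
        # at equal rates the partition is exact regardless of stoichiometry
        sys_eq = MixtureSystem(2e-7, 2e-7, 2e-7, 1.0e7, 0.0, 1.0e7, 0.0)
        tc_eq = simulate_mixture(sys_eq, tgrid(1e5))
        assert tc_eq.theta[-1] == pytest.approx(0.5, abs=1e-6)

    def test_mass_conservation(self):
        sys_ = MixtureSystem(2e-7, 2e-7, 2e-7, 1.5e7, 1e-4, 1.0e7, 1e-2, k_sd=1.0)
        tc = simulate_mixture(sys_, tgrid(1e5))
        for fam, cols in (("T", ["T", "TP", "TR"]), ("C", ["C", "CP", "CR"])):
            tot = tc.species[cols].sum(axis=1)
            assert np.max(np.abs(tot - tot.iloc[0])) <= 1e-9 * tot.iloc[0]

    @pytest.mark.parametrize("k_sd", [None, 1.0])
    def test_theta_converges_to_equilibrium_accuracy(self, k_sd):
        sys_ = MixtureSystem(2e-7, 2e-7, 2e-7, 1.5e7, 2e-4, 1.0e7, 2e-2, k_sd=k_sd)
        th_eq, _ = equilibrium_accuracy(
            sys_.kd_TP, sys_.kd_CP, 2e-7, 2e-7, 2e-7
        )
        # 20x the transient half-life
        tc_probe = simulate_mixture(sys_, tgrid(1e6))
        hl = equilibration_halflife(tc_probe)
        tc = simulate_mixture(sys_, tgrid(20 * hl))
        assert tc.theta[-1] == pytest.approx(th_eq, rel=0.01)

    def test_displacement_leaves_equilibrium_unchanged(self):
        base = dict(conc_T=2e-7, conc_C=2e-7, conc_P=2e-7,
                    kon_TP=1.5e7, koff_TP=2e-4, kon_CP=1.0e7, koff_CP=2e-2)
        t = tgrid(5e5)
        off = simulate_mixture(MixtureSystem(**base), t)
        on = simulate_mixture(MixtureSystem(**base, k_sd=5.0), t)
        assert off.theta[-1] == pytest.approx(on.theta[-1], rel=1e-3)

    def test_displacement_thermodynamic_consistency(self):
        sys_ = MixtureSystem(2e-7, 2e-7, 2e-7, 1.5e7, 1e-4, 1.0e7, 1e-2, k_sd=2.0)
        assert sys_.k_sd / sys_.k_sd_rev == pytest.approx(
            sys_.kd_CP / sys_.kd_TP, rel=1e-12
        )

    def test_early_theta_matches_kinetic_partition(self):
        """theta from the ODE at t = (10 kon c)^-1 is within 0.02 of the
        partition formula when koff << kon*c."""
        for ratio in (1.0, 3.0, 9.0):
            kon_cp = 1.5e7 / ratio
            sys_ = MixtureSystem(2e-7, 2e-7, 2e-7, 1.5e7, 1e-6, kon_cp, 1e-6)
            t_probe = 1.0 / (10 * 1.5e7 * 2e-7)
            tc = simulate_mixture(sys_, np.array([0.0, t_probe]))
            assert abs(tc.theta[-1] - theta_in(1.5e7, kon_cp)) < 0.02

    def test_bad_grid_rejected(self):
        sys_ = MixtureSystem(2e-7, 2e-7, 2e-7, 1e7, 0.0, 1e7, 0.0)
        with pytest.raises(ValueError):
            simulate_mixture(sys_, np.array([1.0, 2.0]))


class TestHalflife:
    def make_exponential_tc(self, lam, cp0=1e-7):
        t = tgrid(20.0 / lam, 600)
        cp = cp0 * np.exp(-lam * t)
        df = pd.DataFrame({"T": t * 0, "C": t * 0, "P": t * 0,
                           "TP": t * 0, "CP": cp, "TR": t * 0, "CR": t * 0})
        sys_ = MixtureSystem(1e-7, 1e-7, 1e-7, 1e7, 0.0, 1e7, lam)
        return TimeCourse(t, df, t * 0, t * 0, t * 0, sys_)

    def test_single_exponential_gives_ln2_over_lambda(self):
        for lam in (1e-3, 1.0):
            tc = self.make_exponential_tc(lam)
            assert equilibration_halflife(tc, cp_eq=0.0) == pytest.approx(
                math.log(2) / lam, rel=0.01
            )

    def test_system_at_equilibrium_rejected(self):
        sys_ = MixtureSystem(2e-7, 2e-7, 2e-7, 1.5e7, 1e-4, 1.0e7, 1e-2)
        t = tgrid(1e6)
        tc = simulate_mixture(sys_, t)
        eq = simulate_mixture(
            sys_, t, y0={"T": tc.species["T"].iloc[-1], "C": tc.species["C"].iloc[-1],
                         "P": tc.species["P"].iloc[-1], "TP": tc.species["TP"].iloc[-1],
                         "CP": tc.species["CP"].iloc[-1]},
        )
        with pytest.raises(ValueError, match="equilibri"):
            equilibration_halflife(eq)

    def test_tracks_competitor_off_rate(self):
        """Sub-stoichiometric probe, target out-competing: the equilibration
        half-life tracks ln2/koff_CP across a 100x off-rate sweep."""
        for koff in (1e-3, 1e-2, 1e-1):
            sys_ = MixtureSystem(2e-7, 2e-7, 5e-8, 1.5e7, 1e-6, 3e6, koff)
            tc = simulate_mixture(sys_, tgrid(1e6 / koff * 1e-0))
            ratio = equilibration_halflife(tc) / (math.log(2) / koff)
            assert 0.5 < ratio < 2.0


class TestReactionYields:
    BASE = dict(conc_T=2e-7, conc_C=2e-7, conc_P=2e-7,
                kon_TP=1.2e7, koff_TP=1e-5, kon_CP=1.2e7, koff_CP=5e-3)

    def test_requires_channel(self):
        with pytest.raises(ValueError):
            reaction_yields(MixtureSystem(**self.BASE), tgrid(10.0))

    def test_slow_reaction_yields_nothing(self):
        sys_ = MixtureSystem(**self.BASE, k_ext_TP=1e-6, k_ext_CP=1e-6,
                             substrate_conc=1e-4)
        tc = reaction_yields(sys_, tgrid(1e4))
        assert tc.reacted_C[-1] < 1e-3

    def test_fast_reaction_captures_initial_partition(self):
        """Reaction much faster than equilibration: every strand that binds
        gets extended, so competitor yield approaches its kinetic share of
        the probe."""
        sys_ = MixtureSystem(**self.BASE, k_ext_TP=1e4, k_ext_CP=1e4,
                             substrate_conc=1e-4)
        tc = reaction_yields(sys_, tgrid(1e5))
        share_c = (1 - theta_in(self.BASE["kon_TP"], self.BASE["kon_CP"]))
        expected = share_c * self.BASE["conc_P"] / self.BASE["conc_C"]
        assert tc.reacted_C[-1] == pytest.approx(expected, rel=0.1)
        assert np.all(np.diff(tc.reacted_C) >= -1e-15)

    def test_metastable_substrate_yield_despite_theta_eq_one(self):
        """Fast reaction + slow equilibration: tens-of-percent competitor
        yield even though theta_eq ~ 1, plateauing once C:P is depleted."""
        sys_ = MixtureSystem(**dict(self.BASE, koff_TP=1e-6, koff_CP=1e-2),
                             k_ext_TP=200.0, k_ext_CP=200.0,
                             substrate_conc=1e-4)
        th_eq, _ = equilibrium_accuracy(sys_.kd_TP, sys_.kd_CP, 2e-7, 2e-7, 2e-7)
        assert th_eq > 0.98
        tc = reaction_yields(sys_, tgrid(1e6))
        assert 0.10 < tc.reacted_C[-1] < 0.60
        # plateau: negligible growth over the last decade of time
        k = np.searchsorted(tc.time, tc.time[-1] / 10)
        assert tc.reacted_C[-1] - tc.reacted_C[k] < 0.01

    def test_yield_increases_with_reaction_rate(self):
        yields = []
        for k_ext in (1e1, 1e2, 1e3, 1e4):
            sys_ = MixtureSystem(**self.BASE, k_ext_TP=k_ext, k_ext_CP=k_ext,
                                 substrate_conc=1e-4)
            tc = reaction_yields(sys_, tgrid(1e6))
            yields.append(tc.reacted_C[-1])
        assert all(a <= b + 1e-9 for a, b in zip(yields, yields[1:]))
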