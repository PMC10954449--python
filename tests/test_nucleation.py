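"""Analytical association model: site enumeration, p_zip, k_on, fitting."""

import math

import numpy as np
import pytest

from hybrikin import (
    DefectSpec,
    KineticModelParams,
    RateRecord,
    annotate_duplex,
    defect_class,
    enumerate_sites,
    fit_model,
    koff_from_kd,
    log_koff_vs_dg,
    make_variant,
    p_zippering,
    parse_sequence,
    predict_kon,
)
from hybrikin.nn_thermo import R_KCAL, T0, nucleation_dg
from hybrikin.nucleation import Regression, in_register_site_count

RT25 = R_KCAL * (25.0 + T0)


def brute_force_sites(duplex, n):
    """Independent double-loop oracle over the full (i, j) grid."""
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    a, b = duplex.strand_a.bases, duplex.strand_b.bases
    out = []
    for i in range(1, len(a) - n + 2):
        for j in range(1, len(b) - n + 2):
            if all(comp[a[i - 1 + k]] == b[j + n - 2 - k] for k in range(n)):
                out.append((i, j))
    return out


class TestEnumerateSites:
    def test_perfect_pair_has_at_least_in_register_sites(self, perfect_duplex):
        sites = enumerate_sites(perfect_duplex, 3)
        assert len(sites) >= 10
        assert in_register_site_count(perfect_duplex, 3) == 10

    def test_matches_brute_force_oracle(self, preset, perfect_duplex):
        for duplex in (perfect_duplex, preset.duplex("m_6"), preset.duplex("b_4")):
            got = {(s.i, s.j) for s in enumerate_sites(duplex, 3)}
            assert got == set(brute_force_sites(duplex, 3))

    def test_site_dgs_match_nucleation_dg(self, perfect_duplex):
        for s in enumerate_sites(perfect_duplex, 3):
            assert s.dg == nucleation_dg(
                perfect_duplex.strand_a, s.i, perfect_duplex.strand_b, s.j, 3
            )

    def test_oversized_n_rejected(self, perfect_duplex):
        with pytest.raises(ValueError):
            enumerate_sites(perfect_duplex, 13)

    def test_dg_injection_hook(self, perfect_duplex):
        sites = enumerate_sites(perfect_duplex, 3)
        table = {(s.i, s.j): -6.45 for s in sites}
        injected = enumerate_sites(perfect_duplex, 3, dg_table=table)
        assert all(s.dg == -6.45 for s in injected)


class TestPZippering:
    def test_alpha_over_alpha_plus_one_at_zero_dg(self):
        assert p_zippering(0.0, 0.25) == pytest.approx(0.2)

    def test_infinite_dg_gives_zero(self):
        assert p_zippering(math.inf, 0.5) == 0.0

    def test_fitted_alpha_at_nupack_scale_dg(self):
        # alpha = 4.3e-5 with dG = -6.45 kcal/mol at 25 °C -> ~0.70
        assert p_zippering(-6.45, 4.3e-5) == pytest.approx(0.70, abs=0.01)

    def test_limits(self):
        assert p_zippering(-60.0, 1e-5) == pytest.approx(1.0, abs=1e-6)
        assert p_zippering(60.0, 1e5) == pytest.approx(0.0, abs=1e-6)

    def test_rate_ratio_form_equals_alpha_form(self):
        """The two-rate competition expression reduces to the alpha form."""
        rng = np.random.default_rng(0)
        for _ in range(50):
            k_zip = 10.0 ** rng.uniform(2, 9)
            k_diss = 10.0 ** rng.uniform(2, 9)
            dg = rng.uniform(-8, 8)
            direct = k_zip / (k_zip + k_diss * math.exp(dg / RT25))
            assert p_zippering(dg, k_zip / k_diss) == pytest.approx(direct, rel=1e-12)


class TestPredictKon:
    def test_equals_knuc_times_site_sum(self, perfect_duplex):
        model = KineticModelParams(2.2e6, 3, {"perfect": 0.1})
        sites = enumerate_sites(perfect_duplex, 3)
        expected = 2.2e6 * sum(p_zippering(s.dg, 0.1) for s in sites)
        assert predict_kon(perfect_duplex, model) == pytest.approx(expected, rel=1e-12)

    def test_saturating_alpha_gives_order_1e7(self, perfect_duplex):
        model = KineticModelParams(2.2e6, 3, {"perfect": 1e4})
        kon = predict_kon(perfect_duplex, model)
        assert 0.5e7 <= kon <= 5e7

    def test_vanishing_alpha_gives_zero(self, perfect_duplex):
        model = KineticModelParams(2.2e6, 3, {"perfect": 1e-300})
        assert predict_kon(perfect_duplex, model) == pytest.approx(0.0, abs=1e-3)

    def test_strand_swap_invariance(self, probe, target):
        d1 = annotate_duplex(target, probe)
        d2 = annotate_duplex(probe, target)
        model = KineticModelParams(2.2e6, 3, {"perfect": 0.05})
        assert predict_kon(d1, model) == pytest.approx(predict_kon(d2, model), rel=1e-12)

    def test_defect_inside_site_never_raises_kon(self, preset, perfect_duplex):
        alpha = {"perfect": 0.3, "single_mismatch": 0.3}
        m0 = KineticModelParams(2.2e6, 3, alpha)
        kon0 = predict_kon(perfect_duplex, m0)
        for name in ("m_5", "m_6", "m_7"):
            assert predict_kon(preset.duplex(name), m0) <= kon0 + 1e-9

    def test_missing_class_rejected(self, preset):
        model = KineticModelParams(2.2e6, 3, {"perfect": 1.0})
        with pytest.raises(ValueError):
            predict_kon(preset.duplex("m_6"), model)


class TestKoff:
    def test_examples(self):
        assert koff_from_kd(1e-9, 1e7) == pytest.approx(1e-2)
        assert koff_from_kd(1.0, 1.0) == 1.0

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            koff_from_kd(0.0, 1e7)

    def test_mismatch_koff_scales_with_kd_and_kon_ratios(self, preset, perfect_duplex):
        from hybrikin import kd_at

        model = KineticModelParams(2.2e6, 3, {"perfect": 0.3, "single_mismatch": 0.3})
        kon_p, kon_m = predict_kon(perfect_duplex, model), predict_kon(
            preset.duplex("m_6"), model
        )
        kd_p, kd_m = kd_at(perfect_duplex), kd_at(preset.duplex("m_6"))
        ratio = koff_from_kd(kd_m, kon_m) / koff_from_kd(kd_p, kon_p)
        assert ratio == pytest.approx((kd_m / kd_p) * (kon_m / kon_p), rel=1e-12)


def synthetic_records(preset, names, k_nuc, alpha_by_class, noise_frac, seed):
    rng = np.random.default_rng(seed)
    records = []
    for nm in names:
        duplex = preset.duplex(nm)
        cls = defect_class(duplex)
        model = KineticModelParams(k_nuc, 3, {cls: alpha_by_class[cls]})
        kon = predict_kon(duplex, model)
        noisy = kon * math.exp(rng.normal(0.0, noise_frac))
        records.append(RateRecord(nm, cls, noisy, duplex=duplex))
    return records


PANEL = [
    "perfect", "m_2", "m_3", "m_5", "m_8", "m_10", "m_4,9", "m_1,12",
    "b_3", "b_5", "b_6", "b_9",
]
TRUE_ALPHA = {"perfect": 5.0, "single_mismatch": 0.02,
              "double_mismatch": 0.01, "bulge": 3.0}


class TestFitModel:
    def test_parameter_recovery_with_noise(self, preset):
        records = synthetic_records(preset, PANEL, 2.2e6, TRUE_ALPHA, 0.05, seed=42)
        fit = fit_model(records, seed=1, n_bootstrap=0)
        assert abs(math.log10(fit.k_nuc / 2.2e6)) < 0.1
        for cls in ("single_mismatch", "double_mismatch"):
            if cls not in fit.alpha_lower_bound_classes:
                ratio = fit.alpha_by_class[cls] / TRUE_ALPHA[cls]
                assert 0.5 < ratio < 2.0, cls

    def test_bootstrap_intervals_cover_truth(self, preset):
        records = synthetic_records(preset, PANEL, 2.2e6, TRUE_ALPHA, 0.05, seed=7)
        fit = fit_model(records, seed=3, n_bootstrap=200)
        lo, hi = fit.conf_int["log10_k_nuc"]
        assert lo < math.log10(2.2e6) < hi

    def test_two_identical_records_closed_form(self, preset, perfect_duplex):
        model = KineticModelParams(3.3e6, 3, {"perfect": 0.2})
        kon = predict_kon(perfect_duplex, model)
        recs = [
            RateRecord("a", "perfect", kon, duplex=perfect_duplex),
            RateRecord("b", "perfect", kon, duplex=perfect_duplex),
        ]
        fit = fit_model(recs, fixed_alpha=0.2, n_bootstrap=0)
        assert math.log10(fit.k_nuc) == pytest.approx(math.log10(3.3e6), abs=1e-10)

    def test_single_class_rejected(self, preset, perfect_duplex):
        recs = [
            RateRecord(f"r{k}", "perfect", 1e7, duplex=perfect_duplex)
            for k in range(5)
        ]
        with pytest.raises(ValueError):
            fit_model(recs, n_bootstrap=0)

    def test_saturated_alpha_reported_as_lower_bound(self, preset):
        alpha = dict(TRUE_ALPHA, perfect=1e3, bulge=1e3)  # p ~ 1: unidentifiable
        records = synthetic_records(preset, PANEL, 2.2e6, alpha, 0.0, seed=0)
        fit = fit_model(records, seed=5, n_bootstrap=0)
        assert "perfect" in fit.alpha_lower_bound_classes


class TestLogKoffRegression:
    def test_exact_exponential_gives_r2_one(self, preset, perfect_duplex):
        from hybrikin import kd_at

        duplexes = {"perfect": perfect_duplex}
        duplexes.update({n: preset.duplex(n) for n in ("m_3", "m_6", "b_5", "m_4,9")})
        records = []
        for nm, d in duplexes.items():
            kon = 1e7
            # force k_off = A * exp(B * dG / RT): choose kd = koff/kon
            from hybrikin.nn_thermo import duplex_dh_ds, dg_from_dh_ds

            dh, ds = duplex_dh_ds(d)
            dg = dg_from_dh_ds(dh, ds, 25.0)
            koff = 1e-2 * math.exp(0.8 * dg / RT25)
            records.append(RateRecord(nm, defect_class(d), kon, kd=koff / kon, duplex=d))
        reg = log_koff_vs_dg(records)
        assert reg.r2 == pytest.approx(1.0, abs=1e-9)
        assert reg.slope == pytest.approx(0.8 / (RT25 * math.log(10)), rel=1e-9)

    def test_noisy_regression_r2_above_0p9(self, preset, perfect_duplex):
        rng = np.random.default_rng(11)
        pool = ["perfect"] + list(preset.variants)
        names = [pool[k % len(pool)] for k in range(30)]
        records = []
        for k, nm in enumerate(names):
            d = perfect_duplex if nm == "perfect" else preset.duplex(nm)
            from hybrikin.nn_thermo import duplex_dh_ds, dg_from_dh_ds

            dg = dg_from_dh_ds(*duplex_dh_ds(d), 25.0)
            koff = 1e-2 * math.exp(dg / RT25) * math.exp(rng.normal(0, 0.10))
            records.append(RateRecord(nm, defect_class(d), 1e7, kd=koff / 1e7, duplex=d))
        reg = log_koff_vs_dg(records)
        assert reg.n == 30 and reg.r2 > 0.9

    def test_too_few_records_rejected(self, perfect_duplex):
        recs = [RateRecord("a", "perfect", 1e7, kd=1e-9, duplex=perfect_duplex)]
        with pytest.raises(ValueError):
            log_koff_vs_dg(recs)
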