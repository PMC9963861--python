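"""Fitting engine: round trips, global sharing, model ranking, Arrhenius,
ratios and mono-exponential decays."""

import math

import numpy as np
import pytest

import nmrdfit as nf
from nmrdfit.constants import GAS_CONSTANT
from nmrdfit.fitting import UnderdeterminedError
from nmrdfit.parameters import params_to_natural
from nmrdfit.spectral import LorentzianComponent


def _noiseless(preset):
    return nf.simulate_profile(
        nf.SyntheticScenario(preset=preset, noise_cv=0.0, seed=0))


class TestProfileFit:
    @pytest.mark.parametrize("preset", [
        "table1_20wt_268K", "table2_20wt_268K",
        "table3_40wt_266K", "table4_20wt_268K"])
    def test_noiseless_round_trip_recovers_generators(self, preset):
        """Each family refits its own noiseless forward model to 1e-4
        relative (multi-start, fixed seed)."""
        spec, params, *_ = nf.get_preset(preset)
        prof = _noiseless(preset)
        res = nf.fit_profile(prof, spec, n_starts=8, seed=1234)
        truth = params_to_natural(spec, params)
        for name, val in truth.items():
            assert res.estimates[name] == pytest.approx(val, rel=1e-4), name

    def test_offset_only_model_recovers_constant(self):
        nu = np.geomspace(1e4, 2e7, 20)
        prof = nf.NMRDProfile(nu=nu, r1=np.full(20, 3.3), temperature=298.0)
        spec = nf.ModelSpec("lorentzian_sum", n_lorentzians=1)
        res = nf.fit_profile(prof, spec, fixed={"C1": 0.0, "tau1": 1e-9},
                             n_starts=6, seed=1)
        assert res.estimates["A"] == pytest.approx(3.3, rel=1e-6)

    def test_noisy_residence_model_tau_trans_recovery(self):
        """2%-noise residence-lifetime profile: tau_trans recovered near
        the generating 5.17e-8 s (median of a few seeds within 10%)."""
        spec, _, *_ = nf.get_preset("table4_20wt_268K")
        rec = []
        for seed in (1, 2, 3, 4, 5):
            prof = nf.simulate_profile(nf.SyntheticScenario(
                preset="table4_20wt_268K", noise_cv=0.02, seed=seed))
            res = nf.fit_profile(prof, spec, n_starts=12, seed=1234)
            rec.append(res.estimates["tau_trans"])
        assert np.median(rec) == pytest.approx(5.17e-8, rel=0.10)

    def test_underdetermined_refused_with_diagnostic(self):
        nu = np.array([1e4, 1e5, 1e6])
        prof = nf.NMRDProfile(nu=nu, r1=np.array([5.0, 4.0, 3.0]),
                              temperature=268.0)
        spec = nf.ModelSpec("surface2d_res", n_lorentzians=1)
        with pytest.raises(UnderdeterminedError, match="free parameters"):
            nf.fit_profile(prof, spec)

    def test_results_diagnostics_reported(self, residence_preset_20wt):
        spec, _ = residence_preset_20wt
        prof = _noiseless("table4_20wt_268K")
        res = nf.fit_profile(prof, spec, n_starts=4, seed=3)
        assert res.redchi >= 0
        assert res.nfev > 0
        assert np.isfinite(res.optimality)
        text = res.summary()
        assert "tau_trans" in text and "AICc" in text

    def test_bootstrap_uncertainties_match_curvature_scale(self):
        """Seeded parametric bootstrap agrees with the curvature-based
        errors within a factor of a few on a well-conditioned parameter."""
        spec, _, *_ = nf.get_preset("table4_20wt_268K")
        prof = nf.simulate_profile(nf.SyntheticScenario(
            preset="table4_20wt_268K", noise_cv=0.02, seed=4))
        res = nf.fit_profile(prof, spec, n_starts=8, seed=1)
        boot = nf.bootstrap_uncertainties(res, n_boot=20, seed=3)
        ratio = boot["tau_trans"] / res.stderr["tau_trans"]
        assert 0.3 < ratio < 3.0
        again = nf.bootstrap_uncertainties(res, n_boot=20, seed=3)
        assert again["tau_trans"] == boot["tau_trans"]

    def test_estimates_respect_bounds(self):
        spec, _, *_ = nf.get_preset("table4_20wt_268K")
        prof = nf.simulate_profile(nf.SyntheticScenario(
            preset="table4_20wt_268K", noise_cv=0.05, seed=9))
        res = nf.fit_profile(prof, spec, n_starts=6, seed=2)
        for name in ("C1", "C_trans"):
            assert 1e4 <= res.estimates[name] <= 1e10
        for name in ("tau1", "tau_trans"):
            assert 1e-12 <= res.estimates[name] <= 1e-4
        assert res.params.surface.tau_res > res.params.surface.tau_trans


class TestSeriesFit:
    def test_degenerate_sharing_matches_single_fit(self):
        """Two identical profiles with everything shared reproduce the
        single-profile estimates."""
        prof = _noiseless("table4_20wt_268K")
        spec, _, *_ = nf.get_preset("table4_20wt_268K")
        layout = {n: "shared" for n in
                  ("C1", "tau1", "C_trans", "tau_trans", "tau_res_ratio",
                   "A")}
        joint = nf.fit_series_global([prof, prof], spec, layout,
                                     n_starts=6, seed=5)
        single = nf.fit_profile(prof, spec, n_starts=6, seed=5)
        for name, val in single.estimates.items():
            if name in joint.shared_estimates:
                assert joint.shared_estimates[name] == pytest.approx(
                    val, rel=1e-6)

    def test_fully_free_layout_matches_independent_fits(self):
        """With no shared parameters the joint objective is block diagonal:
        estimates equal the independent per-profile fits."""
        profs = [_noiseless("table4_20wt_268K"),
                 _noiseless("table4_20wt_273K")]
        spec, _, *_ = nf.get_preset("table4_20wt_268K")
        joint = nf.fit_series_global(profs, spec, None, n_starts=6, seed=11)
        for prof, est in zip(profs, joint.per_temperature):
            single = nf.fit_profile(prof, spec, n_starts=6, seed=11)
            for name in ("tau_trans", "tau1", "A"):
                assert est[name] == pytest.approx(
                    single.estimates[name], rel=1e-5)

    def test_mixed_sample_labels_refused(self):
        p1 = _noiseless("table4_20wt_268K")
        p2 = nf.NMRDProfile(nu=p1.nu, r1=p1.r1, temperature=273.0,
                            sample="other")
        spec, _, *_ = nf.get_preset("table4_20wt_268K")
        with pytest.raises(ValueError, match="sample label"):
            nf.fit_series_global([p1, p2], spec)

    def test_recovered_tau_trans_monotone_in_temperature(self):
        """Round-trip of the four-temperature 20%wt residence-model series:
        per-temperature tau_trans decreases with temperature, matching the
        generating order."""
        profs = nf.simulate_temperature_series(
            preset_series="table4_20wt", noise_cv=0.0, seed=1)
        spec, _, *_ = nf.get_preset("table4_20wt_268K")
        layout = {"C1": "shared", "C_trans": "shared"}
        res = nf.fit_series_global(profs, spec, layout, n_starts=6, seed=21)
        taus = [est["tau_trans"] for est in res.per_temperature]
        assert all(a > b for a, b in zip(taus, taus[1:]))
        assert res.shared_estimates["C1"] == pytest.approx(4.31e7, rel=1e-3)
        assert res.shared_estimates["C_trans"] == pytest.approx(
            8.04e6, rel=1e-3)


class TestCompareModels:
    def _make_results(self, prof, specs_params, n_starts=6, seed=1):
        out = []
        for spec in specs_params:
            out.append(nf.fit_profile(prof, spec, n_starts=n_starts,
                                      seed=seed))
        return out

    def test_true_family_beats_nested_wrong_model(self):
        """The generating two-Lorentzian model outranks a one-Lorentzian
        reduction on AICc in nearly all noisy replicates."""
        spec2 = nf.ModelSpec("lorentzian_sum", n_lorentzians=2)
        spec1 = nf.ModelSpec("lorentzian_sum", n_lorentzians=1)
        params = nf.ModelParams(
            lorentzians=(LorentzianComponent(7.84e6, 1.97e-7),
                         LorentzianComponent(2.16e7, 2.28e-8)), A=2.52)
        wins = 0
        n_rep = 20
        for seed in range(n_rep):
            prof = nf.simulate_profile(nf.SyntheticScenario(
                spec=spec2, params=params, noise_cv=0.02, seed=seed))
            ranked = nf.compare_models(
                self._make_results(prof, [spec1, spec2]))
            if ranked.iloc[0]["family"] == "lorentzian_sum" and \
                    ranked.iloc[0]["n_free"] == 5:
                wins += 1
        assert wins >= round(0.95 * n_rep) - 1

    def test_duplicate_results_tie_keeps_input_order(self):
        prof = _noiseless("table1_20wt_268K")
        spec = nf.ModelSpec("lorentzian_sum", n_lorentzians=2)
        r = nf.fit_profile(prof, spec, n_starts=4, seed=1)
        df = nf.compare_models([r, r, r])
        assert list(df["index"]) == [0, 1, 2]
        assert df["delta_aicc"].abs().max() == 0

    def test_offset_only_ranks_last_on_dispersed_data(self):
        prof = _noiseless("table4_20wt_268K")
        spec_true, _, *_ = nf.get_preset("table4_20wt_268K")
        spec_flat = nf.ModelSpec("lorentzian_sum", n_lorentzians=1)
        rs = [nf.fit_profile(prof, spec_true, n_starts=4, seed=1),
              nf.fit_profile(prof, spec_flat, fixed={"C1": 1e4,
                                                     "tau1": 1e-9},
                             n_starts=4, seed=1)]
        df = nf.compare_models(rs)
        assert df.iloc[-1]["family"] == "lorentzian_sum"
        assert df.iloc[0]["family"] == "surface2d_res"

    def test_mixed_datasets_refused(self):
        r1 = nf.fit_profile(_noiseless("table1_20wt_268K"),
                            nf.ModelSpec("lorentzian_sum", 2),
                            n_starts=2, seed=1)
        r2 = nf.fit_profile(_noiseless("table1_20wt_273K"),
                            nf.ModelSpec("lorentzian_sum", 2),
                            n_starts=2, seed=1)
        with pytest.raises(ValueError, match="same profile"):
            nf.compare_models([r1, r2])


class TestArrhenius:
    def test_two_point_closed_form(self):
        """Two-point data reduce to Ea = R ln(t1/t2) / (1/T1 - 1/T2)."""
        data = [(268.0, 1.97e-7), (298.0, 8.33e-8)]
        res = nf.arrhenius_fit(data)
        closed = GAS_CONSTANT * math.log(1.97e-7 / 8.33e-8) \
            / (1 / 268.0 - 1 / 298.0)
        assert res.E_a == pytest.approx(closed, rel=1e-10)
        assert res.E_a == pytest.approx(1.90e4, rel=5e-3)
        assert res.r_squared == pytest.approx(1.0)

    def test_temperature_independent_tau_gives_zero_energy(self):
        res = nf.arrhenius_fit([(260.0, 1e-7), (280.0, 1e-7),
                                (300.0, 1e-7)])
        assert res.E_a == pytest.approx(0.0, abs=1e-8)

    def test_exact_recovery_of_known_law(self):
        law = nf.ArrheniusLaw(tau0=2.4e-11, E_a=1.9e4)
        data = [(T, law(T)) for T in (258, 268, 278, 288, 298)]
        res = nf.arrhenius_fit(data)
        assert res.E_a == pytest.approx(1.9e4, rel=1e-6)
        assert res.tau0 == pytest.approx(2.4e-11, rel=1e-6)

    def test_single_temperature_refused(self):
        with pytest.raises(ValueError):
            nf.arrhenius_fit([(268.0, 1e-7), (268.0, 2e-7)])


class TestProfileRatio:
    def test_self_ratio_is_one(self):
        p = _noiseless("table4_20wt_268K")
        rc = nf.profile_ratio(p, p)
        assert np.allclose(rc.ratio, 1.0, rtol=1e-12)

    def test_scale_multiplies_pointwise(self):
        p1 = _noiseless("table4_40wt_266K")
        p2 = _noiseless("table4_20wt_268K")
        base = nf.profile_ratio(p1, p2)
        scaled = nf.profile_ratio(p1, p2, scale=0.87)
        assert np.allclose(scaled.ratio, 0.87 * base.ratio, rtol=1e-12)

    def test_offset_only_profiles_give_constant_ratio(self):
        nu = np.geomspace(1e4, 2e7, 30)
        p1 = nf.NMRDProfile(nu=nu, r1=np.full(30, 4.0), temperature=268.0)
        p2 = nf.NMRDProfile(nu=nu, r1=np.full(30, 2.5), temperature=268.0)
        rc = nf.profile_ratio(p1, p2)
        assert np.allclose(rc.ratio, 1.6, rtol=1e-12)

    def test_disjoint_ranges_refused(self):
        nu1 = np.geomspace(1e4, 1e5, 10)
        nu2 = np.geomspace(1e6, 1e7, 10)
        p1 = nf.NMRDProfile(nu=nu1, r1=np.ones(10), temperature=268.0)
        p2 = nf.NMRDProfile(nu=nu2, r1=np.ones(10), temperature=268.0)
        with pytest.raises(ValueError, match="disjoint"):
            nf.profile_ratio(p1, p2)


class TestMonoexponentialDecay:
    def test_exact_round_trip(self):
        sim = nf.simulate_magnetization_decay(10.0, noise_cv=0.0)
        res = nf.fit_monoexponential_decay(sim.times, sim.magnetizations)
        assert res.R1 == pytest.approx(10.0, rel=1e-8)
        assert not res.flagged

    def test_inverted_amplitude_same_rate(self):
        sim = nf.simulate_magnetization_decay(4.5, noise_cv=0.0,
                                              M0=1.0, M_inf=-1.0)
        res = nf.fit_monoexponential_decay(sim.times, sim.magnetizations)
        assert res.R1 == pytest.approx(4.5, rel=1e-8)

    def test_noisy_recovery_mean_within_two_percent(self):
        """32 log-spaced points at 1% noise: mean recovered rate over many
        seeds within 2% of the generating 4.5 /s."""
        rates = []
        for seed in range(100):
            sim = nf.simulate_magnetization_decay(4.5, noise_cv=0.01,
                                                  seed=seed)
            rates.append(nf.fit_monoexponential_decay(
                sim.times, sim.magnetizations).R1)
        assert np.mean(rates) == pytest.approx(4.5, rel=0.02)

    def test_flat_data_flagged(self):
        t = np.geomspace(1e-3, 1.0, 16)
        m = np.ones(16) + 1e-3 * np.sin(np.arange(16.0))
        res = nf.fit_monoexponential_decay(t, m)
        assert res.flagged
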