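"""SID-MRM: ratios, dilution-curve calibration, LOQ/LOD, absolute amounts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from seroquant import (
    MRMSimConfig,
    absolute_concentration,
    cohort_stats,
    compute_ratios,
    determine_lod,
    determine_loq,
    fit_calibration,
    generate_mrm_dataset,
    interassay_cv,
    select_best_transition,
)
from seroquant.mrm import CalibrationCurve, records_to_frame


def series_frame(nominal_ratios, observed_ratios, spike=10.0, reps=1, cvs=None):
    """Build a dilution-series frame from per-point mean ratios (and optional
    per-point replicate spreads)."""
    rows = []
    for i, (nom, obs) in enumerate(zip(nominal_ratios, observed_ratios)):
        if cvs is None:
            reps_vals = [obs] * reps
        else:
            # symmetric two-replicate spread achieving the requested CV exactly
            d = cvs[i] * obs / np.sqrt(2)
            reps_vals = [obs - d, obs + d]
        for r, v in enumerate(reps_vals):
            rows.append(
                {"nominal_light_fmol": nom * spike, "spike_heavy_fmol": spike,
                 "replicate_id": r, "ratio": v}
            )
    return pd.DataFrame(rows)


class TestComputeRatios:
    def test_unit_ratio(self):
        df = pd.DataFrame(
            {"sample_id": ["s1"] * 2, "peptide": ["p"] * 2, "transition_id": ["t"] * 2,
             "label": ["light", "heavy"], "area": [500.0, 500.0]}
        )
        out = compute_ratios(df)
        assert out["ratio"].iloc[0] == 1.0 and not out["below_lod"].iloc[0]

    def test_zero_light_flags_below_lod(self):
        df = pd.DataFrame(
            {"sample_id": ["s1"] * 2, "peptide": ["p"] * 2, "transition_id": ["t"] * 2,
             "label": ["light", "heavy"], "area": [0.0, 400.0]}
        )
        out = compute_ratios(df)
        assert out["ratio"].iloc[0] == 0.0 and bool(out["below_lod"].iloc[0])

    def test_missing_or_zero_heavy_rejected(self):
        lonely = pd.DataFrame(
            {"sample_id": ["s1"], "peptide": ["p"], "transition_id": ["t"],
             "label": ["light"], "area": [5.0]}
        )
        with pytest.raises(ValueError):
            compute_ratios(lonely)
        zero = pd.DataFrame(
            {"sample_id": ["s1"] * 2, "peptide": ["p"] * 2, "transition_id": ["t"] * 2,
             "label": ["light", "heavy"], "area": [5.0, 0.0]}
        )
        with pytest.raises(ValueError):
            compute_ratios(zero)

    def test_qc_failed_pairs_excluded(self):
        df = pd.DataFrame(
            {"sample_id": ["s1"] * 2 + ["s2"] * 2, "peptide": ["p"] * 4,
             "transition_id": ["t"] * 4, "label": ["light", "heavy"] * 2,
             "area": [1.0, 2.0, 3.0, 4.0], "qc_pass": [True, True, False, False]}
        )
        assert list(compute_ratios(df)["sample_id"]) == ["s1"]

    def test_noiseless_cohort_reproduces_planted_ratios(self):
        cfg = MRMSimConfig(replicate_cv=0.0, biological_cv=0.0, group_fold=3.0,
                           cohort_sizes={"NSCLC": 3, "N": 2}, seed=0)
        sim = generate_mrm_dataset(cfg)
        out = compute_ratios(sim.cohort)
        expected = cfg.true_conc_fmol / cfg.spike_heavy_fmol
        by_group = out.groupby("group")["ratio"].unique()
        assert np.allclose(by_group["N"], expected)
        assert np.allclose(by_group["NSCLC"], expected * 3.0)


class TestFitCalibration:
    def test_noiseless_series_gives_exact_unit_line(self):
        sim = generate_mrm_dataset(MRMSimConfig(replicate_cv=0.0, seed=1))
        curve = fit_calibration(sim.dilution, "pep", "y8")
        assert curve.slope == pytest.approx(1.0, abs=1e-12)
        assert curve.intercept == pytest.approx(0.0, abs=1e-12)
        assert curve.pearson_r == pytest.approx(1.0, abs=1e-12)

    def test_anchor_at_ratio_closest_to_one(self):
        nominal = [1 / 9, 1 / 3, 1.0, 3.0, 9.0]
        observed = [0.12, 0.35, 1.029, 3.2, 9.5]
        curve = fit_calibration(series_frame(nominal, observed))
        assert curve.anchor_index == 2
        assert curve.points["mean_ratio"].iloc[curve.anchor_index] == pytest.approx(1.029)

    def test_parameter_recovery_under_noise(self):
        # slope ~1 and R>0.99 in at least 95% of seeded 5%-CV runs
        ok = 0
        runs = 200
        for seed in range(runs):
            sim = generate_mrm_dataset(MRMSimConfig(replicate_cv=0.05, seed=seed))
            c = fit_calibration(sim.dilution)
            ok += (0.97 <= c.slope <= 1.03) and c.pearson_r > 0.99
        assert ok / runs >= 0.95

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_calibration(series_frame([1.0, 3.0], [1.0, 3.0]))


class TestDetermineLoq:
    def test_clean_curve_quantifiable_from_lowest_point(self):
        sim = generate_mrm_dataset(MRMSimConfig(replicate_cv=0.02, seed=2))
        curve = fit_calibration(sim.dilution)
        loq = determine_loq(curve)
        assert loq == pytest.approx(sim.dilution["nominal_light_fmol"].min())
        assert curve.loq_fmol == loq

    def test_curvature_at_bottom_with_clean_cv_moves_loq_to_third_point(self):
        nominal = [3.0**k for k in range(-3, 4)]
        observed = list(nominal)
        observed[0] *= 6.0   # saturating bias at the two lowest points
        observed[1] *= 3.0
        curve = fit_calibration(
            series_frame(nominal, observed, cvs=[0.02] * len(nominal))
        )
        assert determine_loq(curve) == pytest.approx(nominal[2] * 10.0)

    def test_high_cv_points_are_skipped(self):
        nominal = [3.0**k for k in range(-3, 4)]
        curve = fit_calibration(
            series_frame(nominal, nominal, cvs=[0.5, 0.35] + [0.02] * 5)
        )
        assert determine_loq(curve) == pytest.approx(nominal[2] * 10.0)

    def test_not_quantifiable_returns_none(self):
        nominal = [1.0, 3.0, 9.0, 27.0]
        curve = fit_calibration(series_frame(nominal, nominal, cvs=[0.9] * 4))
        assert determine_loq(curve) is None
        assert curve.loq_fmol is None


class TestDetermineLod:
    def test_exact_measured_point(self):
        assert determine_lod([1.0, 2.0, 4.0], [1.5, 3.0, 6.0]) == 2.0

    def test_proportional_snr_extrapolates_tenfold(self):
        assert determine_lod([5.0], [30.0]) == pytest.approx(0.5)

    def test_loglog_interpolation_between_points(self):
        # S/N proportional to concentration between (1, 1.) and (100, 100.)
        assert determine_lod([1.0, 100.0], [1.0, 100.0]) == pytest.approx(3.0)

    def test_unreachable_target_rejected(self):
        with pytest.raises(ValueError):
            determine_lod([1.0, 2.0], [1.1, 2.5])


class TestInterassayCv:
    def test_hand_calculation(self):
        assert interassay_cv([9.0, 10.0, 11.0]) == pytest.approx(10.0)

    def test_identical_replicates(self):
        assert interassay_cv([7.7] * 5) == 0.0

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.floats(0.1, 1000.0))
    def test_scale_invariance(self, k):
        reps = np.array([9.0, 10.0, 11.5, 10.2])
        assert interassay_cv(reps * k) == pytest.approx(interassay_cv(reps), rel=1e-9)

    def test_generator_cv_centered_on_configured_value(self):
        # five-replicate assays at 2% CV, many runs: estimates center on 2%
        rng = np.random.default_rng(3)
        sigma = np.sqrt(np.log1p(0.02**2))
        cvs = [
            interassay_cv(10.0 * rng.lognormal(-sigma**2 / 2, sigma, 5))
            for _ in range(1000)
        ]
        assert np.mean(cvs) == pytest.approx(2.0, rel=0.1)

    def test_more_replicates_tighten_the_estimate(self):
        rng = np.random.default_rng(4)
        spread = []
        for n in (3, 10):
            cvs = [interassay_cv(rng.lognormal(0, 0.1, n)) for _ in range(800)]
            spread.append(np.std(cvs))
        assert spread[1] < spread[0]

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            interassay_cv([5.0])
        with pytest.raises(ValueError):
            interassay_cv([1.0, -1.0])


class TestSelectBestTransition:
    @staticmethod
    def _curve(tid, r, loq=None, heavy=1e5):
        pts = pd.DataFrame(
            {"nominal_light_fmol": [1.0, 3.0, 9.0], "nominal_ratio": [0.1, 0.3, 0.9],
             "mean_ratio": [0.1, 0.3, 0.9], "replicate_cv": [0.01] * 3,
             "n_replicates": [3] * 3}
        )
        return CalibrationCurve(
            peptide="p", transition_id=tid, points=pts, slope=1.0, intercept=0.0,
            pearson_r=r, anchor_index=2, spike_heavy_fmol=10.0, loq_fmol=loq,
            mean_heavy_area=heavy,
        )

    def test_single_candidate(self):
        assert select_best_transition([self._curve("y7", 0.98)]) == "y7"

    def test_highest_linearity_wins(self):
        curves = [self._curve("y7", 0.999), self._curve("y8", 0.98)]
        assert select_best_transition(curves) == "y7"

    def test_ties_break_by_loq_then_heavy_area(self):
        curves = [self._curve("a", 0.999, loq=2.0), self._curve("b", 0.999, loq=7.0)]
        assert select_best_transition(curves) == "a"
        curves = [self._curve("a", 0.999, loq=2.0, heavy=1e4),
                  self._curve("b", 0.999, loq=2.0, heavy=1e6)]
        assert select_best_transition(curves) == "b"


class TestAbsoluteConcentration:
    def test_anchor_identity_and_linear_response(self):
        curve = TestSelectBestTransition._curve("y8", 1.0)
        rec = absolute_concentration(1.0, curve, spike_fmol=10.0, protein="A1BG")
        assert rec.fmol_on_column == pytest.approx(10.0)
        rec3 = absolute_concentration(3.0, curve, spike_fmol=10.0, protein="A1BG")
        assert rec3.fmol_on_column == pytest.approx(30.0)

    def test_serum_concentration_arithmetic(self):
        curve = TestSelectBestTransition._curve("y8", 1.0)
        rec = absolute_concentration(
            1.0, curve, spike_fmol=10.0, serum_volume_ul=0.1,
            molar_mass_g_per_mol=50_000.0,
        )
        # 10 fmol * 50 kg/mol = 5e-10 g in 1e-4 mL -> 5 ug/mL
        assert rec.serum_conc_ug_per_ml == pytest.approx(5.0)

    def test_noiseless_round_trip_is_machine_precision(self):
        sim = generate_mrm_dataset(
            MRMSimConfig(replicate_cv=0.0, biological_cv=0.0, seed=5)
        )
        curve = fit_calibration(sim.dilution)
        ratios = compute_ratios(sim.cohort)
        control = ratios[ratios["sample_id"].str.startswith("N_")]
        rec = absolute_concentration(
            float(control["ratio"].iloc[0]), curve, protein="A1BG"
        )
        assert rec.fmol_on_column == pytest.approx(sim.truth["true_conc_fmol"], rel=1e-12)

    def test_extrapolation_flagged_and_bad_ratio_rejected(self):
        curve = TestSelectBestTransition._curve("y8", 1.0)
        assert absolute_concentration(50.0, curve, protein="A1BG").extrapolated
        assert not absolute_concentration(0.5, curve, protein="A1BG").extrapolated
        with pytest.raises(ValueError):
            absolute_concentration(0.0, curve, protein="A1BG")


class TestCohortStats:
    @staticmethod
    def _cohort_frame(seed, fold=3.0, n_cancer=50, n_control=25, informative=True):
        rng = np.random.default_rng(seed)
        rows = []
        for prot in ("A1BG", "LRG1"):
            base = 50.0 if prot == "A1BG" else 20.0
            for i in range(n_cancer + n_control):
                cancer = i < n_cancer
                mu = base * (fold if (cancer and informative) else 1.0)
                rows.append(
                    {"sample_id": f"s{i}", "protein": prot,
                     "group": "NSCLC" if cancer else "N",
                     "serum_conc_ug_per_ml": mu * rng.lognormal(0, 0.3)}
                )
        return pd.DataFrame(rows)

    def test_strong_fold_significant_null_demographics_not(self):
        runs, cancer_sig, demo_sig = 30, 0, []
        for seed in range(runs):
            conc = self._cohort_frame(seed)
            rng = np.random.default_rng(1000 + seed)
            demo = pd.DataFrame(
                {"sample_id": [f"s{i}" for i in range(75)],
                 "smoking": rng.choice(["Y", "N"], 75),
                 "age": rng.uniform(40, 75, 75)}
            )
            rep = cohort_stats(conc, demographics=demo)
            cancer_sig += (rep.per_protein["p_value"] < 0.01).all()
            demo_sig.extend(rep.demographics["p_value"].tolist())
        assert cancer_sig / runs >= 0.9
        # null demographic associations: roughly uniform p-values
        assert np.mean(np.array(demo_sig) < 0.05) < 0.15

    def test_panel_auc_at_least_each_single_auc(self):
        rep = cohort_stats(self._cohort_frame(7, fold=2.0))
        best_single = rep.per_protein["auc"].max()
        assert rep.panel_roc.auc >= best_single - 1e-12

    def test_single_class_rejected(self):
        conc = self._cohort_frame(0)
        conc["group"] = "NSCLC"
        with pytest.raises(ValueError):
            cohort_stats(conc)
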