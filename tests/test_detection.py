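import numpy as np
import pandas as pd
import pytest

import regenscan
from regenscan.allometry import AllometricFit, fit_all_limbs
from regenscan.config import LIMB_IDS, GeneratorConfig
from regenscan.detection import (
    CutoffSpec,
    assess_population,
    classify_limbs,
    corrected_body_mass,
    determine_cutoff,
    impute_missing_limb_mass,
    regeneration_index,
    summarize_injury,
)
from regenscan.synthetic import generate_population, limb_mass_col, limb_status_col

from conftest import detection_confusion, noiseless_config


def brute_force_gap_cutoff(residuals):
    """Exhaustive midpoint scan among detached negative residuals."""
    resid = np.sort(np.asarray(residuals, float))
    q1 = np.quantile(resid, 0.25)
    cand = resid[(resid < 0) & (resid < q1)]
    best_gap, best_mid = -np.inf, None
    for lo, hi in zip(cand[:-1], cand[1:]):
        if hi - lo > best_gap:
            best_gap, best_mid = hi - lo, (lo + hi) / 2.0
    return best_mid


class TestDetermineCutoff:
    def test_fixed_returns_value(self):
        resid = np.linspace(-0.05, 0.05, 40)
        assert determine_cutoff(resid, CutoffSpec(method="fixed", value=-0.01)) == -0.01

    def test_degenerate_input_falls_back_to_fixed(self):
        # tight cluster, no detached negatives
        resid = np.tile([-0.002, -0.001, 0.0, 0.001], 6)
        with pytest.warns(UserWarning, match="falling back"):
            out = determine_cutoff(resid, CutoffSpec(method="gap", value=-0.01))
        assert out == -0.01

    def test_gap_separates_mixture_clusters(self):
        rng = np.random.default_rng(12)
        resid = np.concatenate(
            [rng.normal(0, 0.002, 300), rng.normal(-0.05, 0.005, 40)]
        )
        cutoff = determine_cutoff(resid, CutoffSpec(method="gap", value=-0.01))
        assert -0.04 < cutoff < -0.01
        assert cutoff == pytest.approx(brute_force_gap_cutoff(resid))

    def test_quantile_method(self):
        rng = np.random.default_rng(3)
        resid = rng.normal(0, 0.01, 500)
        spec = CutoffSpec(method="quantile", value=-0.01, quantile=0.05)
        assert determine_cutoff(resid, spec) == pytest.approx(
            np.quantile(resid, 0.05)
        )

    def test_quantile_fallback_when_nonnegative(self):
        resid = np.linspace(0.0, 0.1, 50)
        spec = CutoffSpec(method="quantile", value=-0.01, quantile=0.05)
        with pytest.warns(UserWarning, match="falling back"):
            assert determine_cutoff(resid, spec) == -0.01

    def test_too_few_residuals_rejected(self):
        with pytest.raises(ValueError):
            determine_cutoff(np.zeros(5), CutoffSpec())

    def test_positive_fixed_value_rejected(self):
        with pytest.raises(ValueError):
            CutoffSpec(method="fixed", value=0.01)


class TestClassifyLimbs:
    def test_below_cutoff_flagged(self):
        flags = classify_limbs(pd.Series({"a": -0.02}), -0.01)
        assert bool(flags["a"])

    def test_tie_not_flagged(self):
        flags = classify_limbs(pd.Series({"a": -0.01}), -0.01)
        assert not bool(flags["a"])

    def test_monotone_in_cutoff(self):
        rng = np.random.default_rng(0)
        resid = pd.Series(rng.normal(0, 0.01, 200))
        n_flagged = [
            int(classify_limbs(resid, c).sum())
            for c in (-0.002, -0.005, -0.01, -0.02, -0.04)
        ]
        assert n_flagged == sorted(n_flagged, reverse=True)

    def test_sensitivity_specificity_regression_baseline(self):
        # frozen pre-build simulation values (default config, limb noise
        # SD 0.1, fixed -0.01 g cutoff, seed 1)
        cfg = GeneratorConfig(n_crabs=736, seed=1)
        crabs, truth = generate_population(cfg)
        fits = fit_all_limbs(crabs)
        _, flags, _ = assess_population(crabs, fits, CutoffSpec())
        sens, spec, _ = detection_confusion(crabs, truth, flags)
        assert sens == pytest.approx(0.9589, abs=0.02)
        assert spec == pytest.approx(0.9255, abs=0.02)


class TestRegenerationIndex:
    def test_no_flags_zero(self):
        assert regeneration_index({1: False, 2: False}, {1: 0.1, 2: 0.2}) == 0.0

    def test_sum_of_flagged_masses(self):
        flags = {1: True, 2: False, 3: True}
        masses = {1: 0.05, 2: 1.0, 3: 0.0391}
        assert regeneration_index(flags, masses) == pytest.approx(0.0891)

    def test_strictly_increasing_in_flagged_mass(self):
        flags = {1: True, 2: False}
        lo = regeneration_index(flags, {1: 0.05, 2: 0.2})
        hi = regeneration_index(flags, {1: 0.0501, 2: 0.2})
        assert hi > lo


def _fit(a, b, limb_id=1):
    # dummy residual pool so cutoff resolution has enough points
    resid = pd.Series(np.zeros(25), index=[f"Z{i}" for i in range(25)])
    return AllometricFit(limb_id, a=a, b=b, n_limbs_used=50, residuals=resid)


def _crab_row(cw=20.0, statuses=None, body_rest=2.0):
    statuses = statuses or {}
    row = {"crab_id": "C1", "carapace_width_mm": cw, "body_rest_mass_g": body_rest}
    for limb_id in LIMB_IDS:
        row[limb_status_col(limb_id)] = statuses.get(limb_id, "intact")
        row[limb_mass_col(limb_id)] = 0.1
    return pd.Series(row)


class TestImputeMissingLimbMass:
    def test_uninjured_crab_zero(self):
        fits = {l: _fit(2e-5, 3.0, l) for l in LIMB_IDS}
        assert impute_missing_limb_mass(fits, _crab_row()) == 0.0

    def test_single_missing_limb_direct_evaluation(self):
        fits = {l: _fit(2e-5, 3.0, l) for l in LIMB_IDS}
        crab = _crab_row(cw=20.0, statuses={4: "missing"})
        assert impute_missing_limb_mass(fits, crab) == pytest.approx(0.16)

    def test_bud_slots_contribute_full_predicted_mass(self):
        fits = {l: _fit(2e-5, 3.0, l) for l in LIMB_IDS}
        crab = _crab_row(cw=20.0, statuses={4: "missing", 7: "bud"})
        assert impute_missing_limb_mass(fits, crab) == pytest.approx(0.32)

    def test_matches_manual_summation_on_handcrafted_table(self):
        fits = {l: _fit(1e-5 * l, 2.5 + 0.05 * l, l) for l in LIMB_IDS}
        rng = np.random.default_rng(9)
        for _ in range(5):
            cw = rng.uniform(15, 30)
            lost = rng.choice(LIMB_IDS, size=3, replace=False)
            statuses = {int(l): rng.choice(["missing", "bud"]) for l in lost}
            crab = _crab_row(cw=cw, statuses=statuses)
            manual = sum(
                fits[l].a * cw ** fits[l].b for l in statuses
            )
            assert impute_missing_limb_mass(fits, crab) == pytest.approx(manual)

    def test_unconverged_fit_names_limb(self):
        fits = {l: _fit(2e-5, 3.0, l) for l in LIMB_IDS}
        fits[4].converged = False
        crab = _crab_row(statuses={4: "missing"})
        with pytest.raises(ValueError, match="limb 4"):
            impute_missing_limb_mass(fits, crab)


class TestCorrectedBodyMass:
    def test_uninjured_equals_body_rest(self):
        assert corrected_body_mass(_crab_row(body_rest=2.0), 0.0) == pytest.approx(2.0)

    def test_addition(self):
        assert corrected_body_mass(_crab_row(body_rest=2.0), 0.16) == pytest.approx(2.16)

    def test_negative_result_rejected(self):
        with pytest.raises(ValueError, match="units"):
            corrected_body_mass(_crab_row(body_rest=-3.0), 0.5)

    def test_generator_identity_no_injury_no_noise(self):
        cfg = GeneratorConfig(
            n_crabs=40, seed=6, p_loss=0.0, p_loss_sd=0.0,
            limb_noise_sd=0.0, organ_noise_sd=0.0, molt_stage_range=(1.0, 1.0),
            tradeoff_coeffs=((0, 0, 0),) * 4,
        )
        crabs, _ = generate_population(cfg)
        fits = fit_all_limbs(crabs)
        assessments, _, _ = assess_population(crabs, fits)
        alpha, beta = cfg.organ_allometry[3]
        season = regenscan.seasonal_effect(
            crabs["julian_day"].to_numpy(), cfg.season_amplitude, cfg.season_peak_day
        )
        expected = alpha * crabs["carapace_width_mm"] ** beta * season
        np.testing.assert_allclose(
            assessments["corrected_body_mass_g"], expected, rtol=1e-12
        )


class TestAssessPopulation:
    def test_limb_slot_conservation(self, default_assessment):
        assessments, _, _ = default_assessment
        total = (
            assessments["n_missing"] + assessments["n_buds"] + assessments["n_present"]
        )
        assert (total == 10).all()

    def test_flags_only_on_present_limbs(self, default_pop, default_assessment):
        _, crabs, _ = default_pop
        _, flags, _ = default_assessment
        wide = crabs.set_index("crab_id")
        for limb_id in LIMB_IDS:
            col = f"limb{limb_id:02d}"
            flagged_ids = flags.index[flags[col]]
            assert (wide.loc[flagged_ids, limb_status_col(limb_id)] == "intact").all()

    def test_regen_mass_invariant_to_row_order_and_site(self, default_pop, default_fits):
        _, crabs, _ = default_pop
        assessments, _, _ = assess_population(crabs, default_fits)
        shuffled = crabs.sample(frac=1.0, random_state=0).reset_index(drop=True)
        shuffled["site"] = "relabelled"
        assessments2, _, _ = assess_population(shuffled, default_fits)
        a = assessments.set_index("crab_id")["regen_mass_total_g"].sort_index()
        b = assessments2.set_index("crab_id")["regen_mass_total_g"].sort_index()
        pd.testing.assert_series_equal(a, b)

    def test_noiseless_truth_recovery_exact(self):
        cfg = noiseless_config(seed=2)
        crabs, truth = generate_population(cfg)
        fits = fit_all_limbs(crabs)
        _, flags, _ = assess_population(
            crabs, fits, CutoffSpec(method="fixed", value=-0.005)
        )
        _, _, exact = detection_confusion(crabs, truth, flags)
        assert exact

    def test_unconverged_fit_blocks_classification(self, default_pop, default_fits):
        _, crabs, _ = default_pop
        fits = dict(default_fits)
        bad = AllometricFit(
            5, a=1.0, b=2.0, n_limbs_used=10, residuals=pd.Series([]), converged=False
        )
        fits[5] = bad
        with pytest.raises(ValueError, match="unconverged"):
            assess_population(crabs, fits)


class TestSummarizeInjury:
    def _uninjured_crab_table(self):
        row = _crab_row()
        df = pd.DataFrame([row])
        return df

    def test_single_uninjured_crab_all_zero(self, default_fits):
        crabs = self._uninjured_crab_table()
        fits = {l: _fit(2e-5, 3.0, l) for l in LIMB_IDS}
        assessments, flags, _ = assess_population(
            crabs.assign(
                julian_day=100,
                site="X",
                ovary_mass_g=0.1,
                hepatopancreas_mass_g=0.2,
                stomach_mass_g=0.05,
            ),
            fits,
        )
        per_limb, pop = summarize_injury(crabs, assessments, flags)
        assert (per_limb[["n_missing_no_bud", "n_missing_with_bud"]] == 0).all().all()
        assert pop.at[0, "n_missing_incl_buds"] == 0

    def test_missing_percentage_of_all_limbs(self):
        # 721 absent slots among 736 crabs -> 9.8% of 7360
        n_crabs = 736
        rows = []
        absent_left = 721
        for i in range(n_crabs):
            k = min(absent_left, 10 if absent_left >= 10 else absent_left)
            statuses = {l: "missing" for l in range(1, k + 1)}
            absent_left -= k
            row = _crab_row(statuses=statuses)
            row["crab_id"] = f"C{i}"
            rows.append(row)
        assert absent_left == 0
        crabs = pd.DataFrame(rows)
        assessments = pd.DataFrame(
            {
                "crab_id": crabs["crab_id"],
                "regen_limb_count": 0,
                "regen_mass_total_g": 0.0,
            }
        )
        flags = pd.DataFrame(
            False,
            index=crabs["crab_id"],
            columns=[f"limb{l:02d}" for l in LIMB_IDS],
        )
        per_limb, pop = summarize_injury(crabs, assessments, flags)
        assert pop.at[0, "n_missing_incl_buds"] == 721
        assert pop.at[0, "pct_missing_of_all_limbs"] == pytest.approx(9.8, abs=0.05)

    def test_handcrafted_three_crab_tally(self):
        c1 = _crab_row(statuses={1: "missing", 2: "bud"})
        c2 = _crab_row(statuses={1: "bud"})
        c3 = _crab_row()
        for i, c in enumerate((c1, c2, c3)):
            c["crab_id"] = f"C{i}"
        crabs = pd.DataFrame([c1, c2, c3])
        assessments = pd.DataFrame(
            {
                "crab_id": crabs["crab_id"],
                "regen_limb_count": [1, 0, 0],
                "regen_mass_total_g": [0.05, 0.0, 0.0],
            }
        )
        flags = pd.DataFrame(
            False, index=crabs["crab_id"], columns=[f"limb{l:02d}" for l in LIMB_IDS]
        )
        flags.loc["C0", "limb03"] = True
        per_limb, pop = summarize_injury(crabs, assessments, flags)
        per_limb = per_limb.set_index("limb_id")
        assert per_limb.at[1, "n_missing_no_bud"] == 1
        assert per_limb.at[1, "n_missing_with_bud"] == 1
        assert per_limb.at[2, "n_missing_with_bud"] == 1
        assert per_limb.at[3, "n_historically_regenerating"] == 1
        assert pop.at[0, "n_missing_excl_buds"] == 1
        assert pop.at[0, "n_missing_incl_buds"] == 3
        assert pop.at[0, "mean_regen_mass_mg"] == pytest.approx(50.0 / 3)

    def test_empty_assessments_rejected(self):
        with pytest.raises(ValueError):
            summarize_injury(
                pd.DataFrame(), pd.DataFrame(), pd.DataFrame()
            )
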