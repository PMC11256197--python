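import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize

from flashtox import datasets
from flashtox.simulate import simulate_cohort
from flashtox.toxicity import (
    DoseResponseFit,
    InsufficientDataError,
    ToxicityRecord,
    build_report,
    dmf,
    fit_from_td50,
    fit_logistic,
    max_grade,
    mean_dmf,
    td50_ratio_across_studies,
    to_responders,
)

from conftest import grid_search_mle, make_responder_table


def record(grades, mouse_id="M1", arm="CONV", dose=30.0, assay="acute", days=None):
    days = days or range(8, 8 + len(grades))
    return ToxicityRecord(
        mouse_id=mouse_id, arm=arm, dose=dose, assay=assay,
        observations=tuple((float(d), float(g)) for d, g in zip(days, grades)),
    )


class TestMaxGrade:
    def test_maximum_over_window(self):
        assert max_grade(record([1.5, 2.0, 2.5, 2.0])) == 2.5

    def test_never_graded_is_zero(self):
        assert max_grade(record([0, 0, 0])) == 0.0

    def test_singleton(self):
        assert max_grade(record([3.5])) == 3.5

    def test_empty_observations_rejected(self):
        with pytest.raises(ValueError):
            max_grade(
                ToxicityRecord(mouse_id="M", arm="CONV", dose=30.0, assay="acute",
                               observations=())
            )


class TestToResponders:
    def test_nesting_for_one_mouse(self):
        r = record([1.5, 2.5, 2.0])
        for g, expect in [(1.5, 1), (2.0, 1), (2.5, 1), (3.0, 0), (3.5, 0)]:
            tab = to_responders([r], g).table
            assert tab["responders"].iloc[0] == expect

    def test_aggregation_by_group(self):
        recs = [record([2.5] if i < 3 else [1.5], mouse_id=f"M{i}") for i in range(8)]
        tab = to_responders(recs, 2.5).table
        assert tab.iloc[0][["n", "responders"]].tolist() == [8, 3]

    def test_unknown_grade_rejected(self):
        with pytest.raises(ValueError):
            to_responders([record([1.5])], 1.0)

    def test_excluded_records_dropped_with_warning(self):
        recs = [record([2.0], mouse_id="A"), record([2.0], mouse_id="B")]
        recs[1].excluded = True
        with pytest.warns(UserWarning, match="excluded"):
            tab = to_responders(recs, 2.0).table
        assert tab["n"].sum() == 1

    def test_reference_design_totals(self):
        """The analyzed-cohort design sums to 73/67 (skin) per arm."""
        cohort = simulate_cohort(seed=3)
        tab = to_responders(cohort.acute_records(), 1.5).table
        totals = tab.groupby("arm")["n"].sum()
        assert totals["FLASH"] == 73
        assert totals["CONV"] == 67


class TestFitLogistic:
    def test_symmetric_table_td50_exact(self):
        # responders (1, 4, 7) of 8 at doses (20, 30, 40): the likelihood is
        # symmetric about 30, so the MLE of TD50 is exactly 30.
        tab = make_responder_table([20, 30, 40], [8, 8, 8], [1, 4, 7])
        f = fit_logistic(tab, "CONV")
        assert f.converged
        assert f.td50 == pytest.approx(30.0, abs=1e-6)
        assert f.slope > 0
        lo, hi = f.td50_ci95
        assert lo <= f.td50 <= hi

    def test_matches_grid_search_oracle(self):
        tab = make_responder_table([20, 30, 40, 50], [8, 8, 8, 8], [0, 2, 6, 8])
        f = fit_logistic(tab, "CONV")
        t_or, b_or = grid_search_mle([20, 30, 40, 50], [8, 8, 8, 8], [0, 2, 6, 8])
        assert f.td50 == pytest.approx(t_or, abs=1e-3)
        assert f.slope == pytest.approx(b_or, abs=1e-3)

    def test_reparameterization_consistency(self):
        """GLM in (beta0, beta1) agrees with direct (td50, b) optimization."""
        dose = np.array([20.0, 30.0, 40.0, 50.0])
        n = np.full(4, 8.0)
        resp = np.array([0.0, 2.0, 6.0, 8.0])

        def nll(theta):
            td50, logb = theta
            b = np.exp(logb)
            p = 1.0 / (1.0 + np.exp(-(dose - td50) / b))
            p = np.clip(p, 1e-12, 1 - 1e-12)
            return -(resp * np.log(p) + (n - resp) * np.log1p(-p)).sum()

        direct = optimize.minimize(nll, x0=[35.0, np.log(3.0)], method="Nelder-Mead",
                                   options={"xatol": 1e-10, "fatol": 1e-12})
        tab = make_responder_table(dose, n.astype(int), resp.astype(int))
        f = fit_logistic(tab, "CONV")
        assert f.td50 == pytest.approx(direct.x[0], abs=1e-6)
        assert f.slope == pytest.approx(np.exp(direct.x[1]), abs=1e-6)

    def test_profile_ci_brackets_td50(self):
        tab = make_responder_table([20, 30, 40, 50], [8, 8, 8, 8], [0, 2, 6, 8])
        f = fit_logistic(tab, "CONV", ci="profile")
        lo, hi = f.td50_ci95
        assert lo < f.td50 < hi
        assert f.ci_method == "profile"

    def test_complete_separation_flagged_not_raised(self):
        tab = make_responder_table([20, 30, 40, 50], [8, 8, 8, 8], [0, 0, 8, 8])
        f = fit_logistic(tab, "CONV")
        assert not f.converged

    def test_single_dose_level_rejected(self):
        tab = make_responder_table([30, 30], [8, 8], [2, 3])
        with pytest.raises(InsufficientDataError):
            fit_logistic(tab, "CONV")


class TestDmf:
    def test_reference_acute_td50_pairs(self):
        t2 = datasets.TD50_ACUTE_SOBP
        e = dmf(fit_from_td50(t2["CONV"][1.5]), fit_from_td50(t2["FLASH"][1.5]), method="none")
        assert round(e.dmf, 2) == 1.42

    def test_reference_fibrosis_td50_pairs(self):
        t3 = datasets.TD50_FIBROSIS_SOBP
        e = dmf(fit_from_td50(t3["CONV"][2.0]), fit_from_td50(t3["FLASH"][2.0]), method="none")
        assert round(e.dmf, 2) == 1.17

    def test_identical_fits_give_unity_with_ci_containing_one(self):
        tab = make_responder_table([20, 30, 40], [8, 8, 8], [1, 4, 7])
        f = fit_logistic(tab, "CONV")
        e = dmf(f, f)
        assert e.dmf == pytest.approx(1.0, abs=1e-12)
        assert e.ci95[0] <= 1.0 <= e.ci95[1]

    def test_scale_equivariance(self):
        doses = [20, 30, 40, 50]
        resp_c, resp_f = [1, 4, 7, 8], [0, 2, 5, 7]
        for c in (1.0, 2.5):
            tc = make_responder_table([c * d for d in doses], [8] * 4, resp_c)
            tf = make_responder_table([c * d for d in doses], [8] * 4, resp_f, arm="FLASH")
            fc, ff = fit_logistic(tc, "CONV"), fit_logistic(tf, "FLASH")
            if c == 1.0:
                base = dmf(fc, ff).dmf
            else:
                assert dmf(fc, ff).dmf == pytest.approx(base, rel=1e-6)

    def test_non_converged_propagates_not_estimable(self):
        bad = DoseResponseFit(arm="CONV", grade=1.5, td50=np.nan, slope=np.nan, converged=False)
        good = fit_from_td50(38.4, "FLASH", 1.5)
        e = dmf(bad, good)
        assert not e.estimable

    def test_bootstrap_ci_contains_point_estimate(self):
        tc = make_responder_table([20, 30, 40, 50], [8] * 4, [1, 4, 7, 8])
        tf = make_responder_table([20, 30, 40, 50], [8] * 4, [0, 2, 5, 7], arm="FLASH")
        fc, ff = fit_logistic(tc, "CONV"), fit_logistic(tf, "FLASH")
        e = dmf(fc, ff, method="bootstrap",
                responder_tables=(tc.for_arm("CONV"), tf.for_arm("FLASH")),
                n_boot=200, seed=11)
        assert e.ci95[0] < e.dmf < e.ci95[1]


class TestSummaries:
    def test_mean_dmf_over_acute_reference_grades(self):
        t2 = datasets.TD50_ACUTE_SOBP
        ests = [
            dmf(fit_from_td50(t2["CONV"][g], grade=g), fit_from_td50(t2["FLASH"][g], grade=g),
                method="none")
            for g in datasets.ACUTE_GRADES
        ]
        m, (lo, hi) = mean_dmf(ests)
        assert round(m, 2) == 1.40
        assert round(lo, 2) == 1.35

    def test_single_estimate_degenerate_range(self):
        e = dmf(fit_from_td50(40.0), fit_from_td50(48.0), method="none")
        m, (lo, hi) = mean_dmf([e])
        assert m == lo == hi == pytest.approx(1.2)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            mean_dmf([])

    def test_cross_study_identity(self):
        t = datasets.TD50_ACUTE_SOBP["CONV"]
        m, (lo, hi) = td50_ratio_across_studies(t, t)
        assert m == 1.0 == lo == hi

    def test_cross_study_mismatched_grades_rejected(self):
        with pytest.raises(ValueError):
            td50_ratio_across_studies({1.5: 30.0}, {2.0: 30.0})


@pytest.fixture(scope="module")
def report():
    cohort = simulate_cohort(seed=7)
    return build_report(cohort.records, seed=7)


class TestBuildReport:
    def test_structure_has_all_grade_blocks(self, report):
        assert set(report["fits"]["acute"]) == {"1.5", "2", "2.5", "3", "3.5"}
        assert set(report["fits"]["fibrosis"]) == {"2", "3", "4"}

    def test_json_round_trip_lossless(self, report):
        assert json.loads(json.dumps(report)) == report

    def test_mean_dmf_blocks_present(self, report):
        for assay in ("acute", "fibrosis"):
            blk = report["mean_dmf"][assay]
            assert blk["mean"] is None or blk["mean"] > 0

    def test_not_estimable_grade_isolated(self):
        """One arm with zero responders at a grade flags only that grade."""
        cohort = simulate_cohort(seed=7)
        records = [r for r in cohort.records if r.assay == "acute"]
        # cripple CONV at grade 3.5 only: cap all CONV grades below 3.5
        for r in records:
            if r.arm == "CONV":
                r.observations = tuple((t, min(g, 3.0)) for t, g in r.observations)
        rep = build_report(records, grades={"acute": datasets.ACUTE_GRADES})
        assert not rep["dmf"]["acute"]["3.5"]["estimable"]
        assert rep["dmf"]["acute"]["1.5"]["estimable"]

    def test_fitted_td50_nondecreasing_in_grade(self, report):
        """Nested responder sets push TD50 up with grade severity."""
        for arm in ("CONV", "FLASH"):
            td50s = [
                report["fits"]["acute"][k][arm]["td50"]
                for k in ("1.5", "2", "2.5", "3", "3.5")
                if report["fits"]["acute"][k][arm]["converged"]
            ]
            assert all(b >= a - 1e-9 for a, b in zip(td50s, td50s[1:]))


@settings(deadline=None, max_examples=30)
@given(
    max_grades=st.lists(
        st.sampled_from([0.0, 1.5, 2.0, 2.5, 3.0, 3.5]), min_size=4, max_size=20
    )
)
def test_responder_nesting_property(max_grades):
    """Responder count is non-increasing as the grade threshold rises."""
    recs = [record([g] if g else [0.0], mouse_id=f"M{i}") for i, g in enumerate(max_grades)]
    counts = [
        to_responders(recs, g).table["responders"].sum() for g in datasets.ACUTE_GRADES
    ]
    assert all(b <= a for a, b in zip(counts, counts[1:]))
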