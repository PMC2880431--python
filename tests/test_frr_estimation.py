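"""Lexis expansion, expected counts, O/E estimation and hazard curves."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from famsubtype.cohort_model import (Exclusion, Family, FollowUpInterval,
                                     MarkerStatus, Proband, Relative, Role,
                                     derive_follow_up)
from famsubtype.frr_estimation import (EstimationError, ZERO_EVENT_UPPER,
                                       _expected_by_person, estimate_frr,
                                       expand_lexis, expected_count,
                                       frr_from_counts, nelson_aalen,
                                       run_subtype_analysis)
from famsubtype.frr_estimation import \
    test_frr_heterogeneity as frr_heterogeneity
from famsubtype.reference_rates import OutOfCoverageError
from famsubtype.synthetic_data import SimulationConfig, simulate_cohort


def _interval(entry_age, exit_age, birth, event=False, pid="R1", fid="F1"):
    return FollowUpInterval(fid, pid, entry_age, exit_age,
                            birth + entry_age, birth + exit_age, event)


class TestExpandLexis:
    def test_coincident_age_and_period_crossing(self, grid_table):
        # born 1940.0: the age-50 crossing happens exactly at the 1990
        # period break, so one life-line cut serves both axes -> 2 segments
        segs = expand_lexis(_interval(48, 52, 1940.0), grid_table)
        assert len(segs) == 2
        assert [round(s.person_years, 9) for s in segs] == [2.0, 2.0]
        assert segs[0].cell.age_lo == 45 and segs[0].cell.period_lo == 1985
        assert segs[1].cell.age_lo == 50 and segs[1].cell.period_lo == 1990

    def test_distinct_crossings_hand_enumeration(self, grid_table):
        # born 1940.5: cuts at 1990 (age 49.5) and at age 50 (1990.5)
        segs = expand_lexis(_interval(48, 52, 1940.5), grid_table)
        assert [round(s.person_years, 9) for s in segs] == [1.5, 0.5, 2.0]
        cells = [(s.cell.age_lo, s.cell.period_lo) for s in segs]
        assert cells == [(45, 1985), (45, 1990), (50, 1990)]

    def test_interval_inside_one_cell(self, grid_table):
        segs = expand_lexis(_interval(51, 54, 1940.0), grid_table)
        assert len(segs) == 1 and segs[0].person_years == 3.0

    def test_out_of_coverage_raises_by_default(self, grid_table):
        with pytest.raises(OutOfCoverageError):
            expand_lexis(_interval(40, 60, 1900.0), grid_table)  # pre-1960

    def test_truncate_clips_to_grid(self, grid_table):
        segs = expand_lexis(_interval(40, 60, 1900.0), grid_table,
                            coverage="truncate")
        total = sum(s.person_years for s in segs)
        assert abs(total - (1900.0 + 60 - 1960.0)) < 1e-9  # 1960 -> age 60

    def test_fully_outside_yields_empty(self, grid_table):
        segs = expand_lexis(_interval(30, 40, 1900.0), grid_table,
                            coverage="truncate")
        assert segs == []

    @given(birth=st.floats(1900, 1990), entry=st.floats(0, 84),
           length=st.floats(1e-6, 85))
    def test_person_years_conserved(self, grid_table, birth, entry, length):
        a0, a1 = grid_table.age_range
        p0, p1 = grid_table.period_range
        entry = max(entry, p0 - birth)
        exit_ = min(entry + length, a1, p1 - birth)
        if exit_ <= entry:
            return
        iv = _interval(entry, exit_, birth)
        segs = expand_lexis(iv, grid_table)
        assert abs(sum(s.person_years for s in segs) - iv.length) < 1e-9


class TestExpectedCount:
    def test_sums_rate_times_years(self, grid_table):
        segs = expand_lexis(_interval(48, 52, 1940.0), grid_table)
        by_hand = sum(s.person_years * s.cell.rate for s in segs)
        assert expected_count(segs) == by_hand

    def test_matches_fine_riemann_sum(self, grid_table):
        iv = _interval(47.3, 53.8, 1941.2)
        step = 1e-5
        ages = np.arange(iv.entry_age, iv.exit_age - step / 2, step) + step / 2
        i, j = grid_table.locate(ages, 1941.2 + ages)
        riemann = grid_table.rates[i, j].sum() * step
        e = expected_count(expand_lexis(iv, grid_table))
        assert abs(e - riemann) < 1e-6

    def test_vectorized_path_equals_segment_path(self, grid_table, rng):
        birth = rng.uniform(1910, 1985, 300)
        entry = np.maximum(1960.0 - birth, 0.0)
        exit_ = np.minimum(entry + rng.uniform(0.5, 60, 300),
                           np.minimum(85.0, 2009.999 - birth))
        keep = exit_ > entry
        birth, entry, exit_ = birth[keep], entry[keep], exit_[keep]
        vec = _expected_by_person(birth, entry, exit_, grid_table)
        for k in range(len(birth)):
            seg = expand_lexis(_interval(entry[k], exit_[k], birth[k]),
                               grid_table)
            assert abs(vec[k] - expected_count(seg)) < 1e-9


class TestEstimateFRR:
    def test_o_equals_e_gives_unity(self, grid_table, rng):
        ivs = [_interval(20, 60, 1940.0, pid=f"R{k}", fid=f"F{k}")
               for k in range(50)]
        e_each = _expected_by_person(np.array([1940.0]), np.array([20.0]),
                                     np.array([60.0]), grid_table)[0]
        n_events = round(50 * e_each)  # make O == round(E) artificially
        ivs = ([_interval(20, 60, 1940.0, event=True, pid=f"E{k}",
                          fid=f"G{k}") for k in range(n_events)]
               + ivs[n_events:])
        est = estimate_frr(ivs, grid_table)
        assert est.observed == n_events
        assert est.frr == pytest.approx(est.observed / est.expected)
        assert est.ci_lo <= est.frr <= est.ci_hi

    def test_pooling_mothers_and_sisters_is_exact(self, grid_table):
        fams, _ = simulate_cohort(SimulationConfig(n_families=400, seed=3,
                                                   frr=2.0), grid_table)
        ivs = {Role.MOTHER: [], Role.SISTER: []}
        for fam in fams:
            for rel in fam.relatives:
                res = derive_follow_up(rel)
                if not isinstance(res, Exclusion):
                    ivs[rel.role].append(res)
        em = estimate_frr(ivs[Role.MOTHER], grid_table)
        es = estimate_frr(ivs[Role.SISTER], grid_table)
        ea = estimate_frr(ivs[Role.MOTHER] + ivs[Role.SISTER], grid_table)
        assert em.observed + es.observed == ea.observed
        assert em.expected + es.expected == pytest.approx(ea.expected,
                                                          abs=1e-9)
        assert ea.frr == pytest.approx(
            (em.observed + es.observed) / (em.expected + es.expected))

    def test_zero_events_poisson_bound(self, grid_table):
        ivs = [_interval(20, 40, 1950.0, pid=f"R{k}", fid=f"F{k}")
               for k in range(5)]
        est = estimate_frr(ivs, grid_table)
        assert est.frr == 0.0
        assert est.ci_hi == pytest.approx(ZERO_EVENT_UPPER / est.expected)

    def test_from_counts_identity(self):
        est = frr_from_counts(100, 100.0)
        assert est.frr == 1.0

    def test_empty_stratum_is_an_error(self, grid_table):
        with pytest.raises(EstimationError):
            estimate_frr([], grid_table)


class TestHeterogeneity:
    def test_identical_estimates_p_one(self):
        a = frr_from_counts(100, 50.0, "a")
        assert frr_heterogeneity(a, a).p_value == pytest.approx(1.0)

    def test_type_i_error_near_nominal(self, grid_table):
        """Equal true FRRs in disjoint strata reject at ~5%."""
        rejections = 0
        reps = 60
        for i in range(reps):
            ests = []
            for j in (0, 1):
                fams, _ = simulate_cohort(
                    SimulationConfig(n_families=1500, seed=9000 + 2 * i + j,
                                     frr=1.8), grid_table)
                ivs = [r for f in fams for r in map(derive_follow_up,
                                                    f.relatives)
                       if not isinstance(r, Exclusion)]
                ests.append(estimate_frr(ivs, grid_table, label=str(j)))
            if frr_heterogeneity(*ests).p_value < 0.05:
                rejections += 1
        assert rejections / reps <= 0.15  # ~5% nominal, binomial slack

    def test_power_for_large_separation(self, grid_table):
        """FRR 1.5 vs 3.0 with 2000 families each is nearly always detected."""
        rejections = 0
        for i in range(10):
            ests = []
            for lam, off in ((1.5, 0), (3.0, 1)):
                fams, _ = simulate_cohort(
                    SimulationConfig(n_families=2000, seed=500 + 2 * i + off,
                                     frr=lam), grid_table)
                ivs = [r for f in fams for r in map(derive_follow_up,
                                                    f.relatives)
                       if not isinstance(r, Exclusion)]
                ests.append(estimate_frr(ivs, grid_table))
            if frr_heterogeneity(*ests).p_value < 0.05:
                rejections += 1
        assert rejections >= 9

    def test_zero_variance_rejected(self):
        a = frr_from_counts(100, 50.0)
        b = frr_from_counts(0, 10.0)
        with pytest.raises(EstimationError):
            frr_heterogeneity(a, b)


class TestNelsonAalen:
    def test_single_subject_event(self):
        curve = nelson_aalen([_interval(20, 55, 1940.0, event=True)])
        assert curve.ages.tolist() == [55]
        assert curve.cumhaz.tolist() == [1.0]

    def test_two_at_risk_one_event(self):
        ivs = [_interval(20, 55, 1940.0, event=True, pid="a"),
               _interval(20, 60, 1940.0, pid="b")]
        curve = nelson_aalen(ivs)
        assert curve.cumhaz.tolist() == [0.5]
        assert curve.variance.tolist() == [0.25]

    def test_staggered_entry_hand_risk_sets(self):
        # events at 40 (risk set {a,b}) and 50 (risk set {b,c}):
        # increments 1/2 + 1/2, variances 1/4 + 1/4
        ivs = [_interval(20, 40, 1940.0, event=True, pid="a"),
               _interval(30, 50, 1935.0, event=True, pid="b"),
               _interval(45, 70, 1930.0, pid="c")]
        curve = nelson_aalen(ivs)
        assert curve.ages.tolist() == [40, 50]
        assert np.allclose(curve.cumhaz, [0.5, 1.0])
        assert np.allclose(curve.variance, [0.25, 0.5])

    def test_no_events_zero_curve(self):
        curve = nelson_aalen([_interval(20, 60, 1940.0)])
        assert curve.ages.size == 0

    def test_matches_lifelines(self, grid_table):
        lifelines = pytest.importorskip("lifelines")
        fams, _ = simulate_cohort(SimulationConfig(n_families=150, seed=21,
                                                   frr=3.0), grid_table)
        ivs = [r for f in fams for r in map(derive_follow_up, f.relatives)
               if not isinstance(r, Exclusion)]
        curve = nelson_aalen(ivs)
        naf = lifelines.NelsonAalenFitter(nelson_aalen_smoothing=False)
        naf.fit(durations=[iv.exit_age for iv in ivs],
                event_observed=[iv.event for iv in ivs],
                entry=[iv.entry_age for iv in ivs])
        ours = dict(zip(curve.ages, curve.cumhaz))
        theirs = naf.cumulative_hazard_["NA_estimate"]
        for age, val in ours.items():
            assert val == pytest.approx(theirs.loc[age], abs=1e-10)


def _family(fid, er, relatives):
    p = Proband(fid, f"{fid}_P", 1950.0, 1995.0, er=er)
    return Family(fid, p, tuple(relatives))


class TestRunSubtypeAnalysis:
    def test_unknown_marker_relatives_only_in_all(self, grid_table):
        rels = lambda fid: [Relative(fid, f"{fid}_M", Role.MOTHER, 2000.0,
                                     birth_date=1925.0)]
        fams = [_family("F1", MarkerStatus.POSITIVE, rels("F1")),
                _family("F2", MarkerStatus.NEGATIVE, rels("F2")),
                _family("F3", MarkerStatus.UNKNOWN, rels("F3"))]
        rep = run_subtype_analysis(fams, grid_table, grouping="ER",
                                   by_role=False)
        by_label = rep.set_index("label")
        assert by_label.loc["all", "n_families"] == 3
        assert by_label.loc["ER-positive", "n_families"] == 1
        assert by_label.loc["ER-negative", "n_families"] == 1

    def test_er_grouping_shape(self, grid_table):
        fams, _ = simulate_cohort(SimulationConfig(n_families=300, seed=4),
                                  grid_table)
        rep = run_subtype_analysis(fams, grid_table, grouping="ER")
        assert set(rep["role"]) == {"all", "mother", "sister"}
        assert set(rep["label"]) == {"all", "ER-negative", "ER-positive"}
        assert (rep["window"] == "full").all()

    def test_windows_partition_expected_counts(self, grid_table):
        fams, _ = simulate_cohort(SimulationConfig(n_families=300, seed=4),
                                  grid_table)
        rep = run_subtype_analysis(fams, grid_table, grouping="ER",
                                   windows=("full", "under50", "from50"),
                                   by_role=False)
        pick = rep[rep.label == "all"].set_index("window")
        assert (pick.loc["under50", "expected"]
                + pick.loc["from50", "expected"]
                == pytest.approx(pick.loc["full", "expected"], rel=1e-9))
        assert (pick.loc["under50", "observed"]
                + pick.loc["from50", "observed"]
                == pick.loc["full", "observed"])
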