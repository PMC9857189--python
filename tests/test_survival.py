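import itertools

import numpy as np
import pytest

import giscan as g
from giscan.survival import DFS, OS, SurvivalOutcome


def outcomes(times, events, endpoint=DFS, prefix="P"):
    return [SurvivalOutcome(f"{prefix}{i}", t, e, endpoint)
            for i, (t, e) in enumerate(zip(times, events))]


def km_oracle(times, events):
    """Hand-rolled product-limit estimator (events before censoring at ties)."""
    pairs = sorted(zip(times, events))
    s = 1.0
    out = {}
    at_risk = len(pairs)
    i = 0
    while i < len(pairs):
        t = pairs[i][0]
        d = sum(1 for tt, ee in pairs if tt == t and ee == 1)
        n = sum(1 for tt, ee in pairs if tt >= t)
        if d:
            s *= 1 - d / n
            out[t] = s
        i += sum(1 for tt, _ in pairs if tt == t)
    return out


def logrank_oracle(times, events, groups):
    """Two-group observed-minus-expected chi-square over shared event times."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups, int)
    o_minus_e = 0.0
    var = 0.0
    for t in sorted(set(times[events == 1])):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (groups == 1)).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (groups == 1)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return None
    return o_minus_e ** 2 / var


class TestClassifyRecurrence:
    @pytest.mark.parametrize("months,expected", [
        (4, "progression"), (12, "relapse"), (6, "progression"), (6.5, "relapse"),
    ])
    def test_rule(self, months, expected):
        assert g.classify_recurrence(months) == expected

    def test_nonpositive_errors(self):
        with pytest.raises(ValueError):
            g.classify_recurrence(0)


class TestKmEstimate:
    def test_all_censored(self):
        curve = g.km_estimate(outcomes([5, 8, 12], [0, 0, 0]))
        assert (curve.survival == 1.0).all()

    def test_hand_computed_product_limit(self):
        # times {1 event, 2 censored, 3 event}: S(1)=2/3, S(3)=0
        curve = g.km_estimate(outcomes([1, 2, 3], [1, 0, 1]))
        assert curve.survival_at(1) == pytest.approx(2 / 3)
        assert curve.survival_at(3) == pytest.approx(0.0)

    def test_survival_at_zero_is_one(self):
        curve = g.km_estimate(outcomes([1, 2, 3], [1, 1, 1]))
        assert curve.survival_at(0) == 1.0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            g.km_estimate([])

    def test_monotone_nonincreasing(self):
        rng = np.random.default_rng(3)
        times = rng.exponential(10, 30).round(2) + 0.1
        events = rng.integers(0, 2, 30)
        curve = g.km_estimate(outcomes(times, events))
        assert (np.diff(curve.survival) <= 1e-12).all()

    def test_equals_one_minus_ecdf_without_censoring(self):
        times = [2.0, 5.0, 7.0, 9.0]
        curve = g.km_estimate(outcomes(times, [1, 1, 1, 1]))
        for i, t in enumerate(times):
            assert curve.survival_at(t) == pytest.approx(1 - (i + 1) / 4)

    def test_matches_oracle_random(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = rng.integers(3, 10)
            times = rng.integers(1, 6, n).astype(float)
            events = rng.integers(0, 2, n)
            curve = g.km_estimate(outcomes(times, events))
            for t, s in km_oracle(times, events).items():
                assert curve.survival_at(t) == pytest.approx(s)


class TestLogrankTest:
    def test_identical_groups(self):
        outs = outcomes([1, 2, 3, 1, 2, 3], [1, 1, 0, 1, 1, 0])
        res = g.logrank_test(outs, [0, 0, 0, 1, 1, 1])
        assert res.chi_square == pytest.approx(0.0, abs=1e-9)
        assert res.p == pytest.approx(1.0)
        assert res.df == 1

    def test_matches_brute_force_two_events(self):
        # group A events at {1,2}, group B censored at {3,3}
        times = [1, 2, 3, 3]
        events = [1, 1, 0, 0]
        groups = [0, 0, 1, 1]
        res = g.logrank_test(outcomes(times, events), groups)
        assert res.chi_square == pytest.approx(
            logrank_oracle(times, events, groups))

    def test_exhaustive_small_patterns_match_oracle(self):
        # all event/censor/group patterns at n=5, fixed distinct times
        times = [1.0, 2.0, 3.0, 4.0, 5.0]
        checked = 0
        for events in itertools.product([0, 1], repeat=5):
            for groups in itertools.product([0, 1], repeat=5):
                if len(set(groups)) < 2:
                    continue
                expected = logrank_oracle(times, events, groups)
                if expected is None:
                    continue
                res = g.logrank_test(outcomes(times, events), groups)
                assert res.chi_square == pytest.approx(expected, abs=1e-8), (
                    events, groups)
                checked += 1
        assert checked > 100

    def test_relabeling_invariant(self):
        times = [1, 2, 3, 4, 5, 6]
        events = [1, 0, 1, 1, 0, 1]
        a = g.logrank_test(outcomes(times, events), [0, 0, 0, 1, 1, 1])
        b = g.logrank_test(outcomes(times, events), ["x", "x", "x", "y", "y", "y"])
        assert a.chi_square == pytest.approx(b.chi_square)

    def test_time_shift_invariant(self):
        times = np.array([1, 2, 3, 4, 5, 6], float)
        events = [1, 0, 1, 1, 0, 1]
        groups = [0, 1, 0, 1, 0, 1]
        a = g.logrank_test(outcomes(times, events), groups)
        b = g.logrank_test(outcomes(times + 100, events), groups)
        assert a.chi_square == pytest.approx(b.chi_square)

    def test_single_group_errors(self):
        with pytest.raises(ValueError):
            g.logrank_test(outcomes([1, 2], [1, 1]), [0, 0])

    def test_power_hazard_ratio_4(self):
        # HR 4, n = 20 vs 20, exponential times, seed 37, 200 replicates
        hits = 0
        for rep in range(200):
            groups = {f"P{i}": int(i >= 20) for i in range(40)}
            outs = g.simulate_survival(groups, 4.0, seed=37 * 1000 + rep)
            res = g.logrank_test(outs, [groups[o.patient_id] for o in outs])
            hits += res.p < 0.05
        assert hits >= 160


class TestUnivariateGeneScreen:
    def _outs(self, n=10, seed=0):
        rng = np.random.default_rng(seed)
        return outcomes(rng.exponential(20, n) + 0.5, rng.integers(0, 2, n))

    def test_single_carrier_ineligible_dfs(self):
        outs = self._outs()
        groups = {o.patient_id: 0 for o in outs}
        groups["P0"] = 1
        res, eligible = g.univariate_gene_screen(groups, outs, DFS)
        assert not eligible
        assert res is not None  # test still runs, flag marks the exclusion

    def test_no_carrier_deaths_ineligible_os(self):
        outs = outcomes([10, 20, 5, 8, 30, 40], [0, 0, 1, 1, 1, 0],
                        endpoint=OS)
        groups = {"P0": 1, "P1": 1, "P2": 0, "P3": 0, "P4": 0, "P5": 0}
        res, eligible = g.univariate_gene_screen(groups, outs, OS)
        assert not eligible

    def test_two_carriers_eligible_dfs(self):
        outs = self._outs()
        groups = {o.patient_id: 0 for o in outs}
        groups["P0"] = groups["P1"] = 1
        _, eligible = g.univariate_gene_screen(groups, outs, DFS)
        assert eligible

    def test_endpoint_mismatch(self):
        outs = self._outs()
        with pytest.raises(ValueError, match="endpoint"):
            g.univariate_gene_screen({o.patient_id: 0 for o in outs}, outs, OS)

    def test_planted_hazard_detected(self):
        # carriers given hazard ratio 6; p < 0.05 in >= 80% of replicates, seed 41
        hits = 0
        for rep in range(200):
            groups = {f"P{i}": int(i < 6) for i in range(40)}
            outs = g.simulate_survival(groups, 6.0, seed=41 * 1000 + rep)
            res, eligible = g.univariate_gene_screen(groups, outs, DFS)
            assert eligible
            hits += res.p < 0.05
        assert hits >= 160


class TestCa125Subgroups:
    def _records(self):
        recs = []
        for i in range(8):
            recs.append(g.ClinicalRecord(
                patient_id=f"P{i}", ca125=float(100 * (i + 1)),
                figo_stage="III", histology="HGSC",
                dfs_months=float(5 + i), dfs_event=i % 2,
                os_months=float(20 + i), os_event=0))
        return recs

    def test_label_rules(self):
        recs = self._records()
        groups = {f"P{i}": int(i >= 4) for i in range(8)}
        labels, overall, pairwise = g.ca125_subgroups(groups, recs)
        med = labels["P0"].median_ca125
        assert med == pytest.approx(450.0)
        for pid, sub in labels.items():
            rec = next(r for r in recs if r.patient_id == pid)
            expected = {(1, 1): 1, (1, 0): 2, (0, 1): 3, (0, 0): 4}[
                (groups[pid], int(rec.ca125 > med))]
            assert sub.label == expected
        assert overall.df == len({s.label for s in labels.values()}) - 1

    def test_boundary_at_median_goes_low(self):
        recs = self._records()
        groups = {f"P{i}": 1 for i in range(8)}
        labels, _, _ = g.ca125_subgroups(groups, recs, median_ca125=400.0)
        assert labels["P3"].label == 2  # ca125 == 400 == median -> low arm

    def test_partition_covers_cohort(self):
        recs = self._records()
        groups = {f"P{i}": int(i % 3 == 0) for i in range(8)}
        labels, _, _ = g.ca125_subgroups(groups, recs)
        assert len(labels) == 8

    def test_explicit_example_labels(self):
        recs = [
            g.ClinicalRecord("A", 600.0, "III", "HGSC", 10.0, 1, 12.0, 0),
            g.ClinicalRecord("B", 575.5, "III", "HGSC", 11.0, 0, 12.0, 0),
            g.ClinicalRecord("C", 100.0, "III", "HGSC", 12.0, 1, 13.0, 0),
            g.ClinicalRecord("D", 800.0, "III", "HGSC", 13.0, 0, 14.0, 0),
        ]
        groups = {"A": 1, "B": 1, "C": 0, "D": 0}
        labels, _, _ = g.ca125_subgroups(groups, recs, median_ca125=575.5)
        assert labels["A"].label == 1
        assert labels["B"].label == 2   # == median -> low arm
        assert labels["C"].label == 4
        assert labels["D"].label == 3

    def test_too_few_arms(self):
        recs = self._records()[:2]
        groups = {"P0": 1, "P1": 1}
        with pytest.raises(ValueError, match="arms"):
            g.ca125_subgroups(groups, recs, median_ca125=1e9)


class TestOutcomesFromRecords:
    def test_os_lost_to_followup_dropped(self):
        recs = [
            g.ClinicalRecord("A", 100.0, "III", "HGSC", 10.0, 1, 12.0, 1),
            g.ClinicalRecord("B", 100.0, "III", "HGSC", 10.0, 1, float("nan"), 0),
        ]
        assert len(g.outcomes_from_records(recs, OS)) == 1
        assert len(g.outcomes_from_records(recs, DFS)) == 2


class TestScreenPanel:
    def test_fixture_screen_shape(self, panel):
        groups, records = g.make_fixture_cohort(panel, 40, seed=17)
        calls = groups.reset_index(names="sample_id").melt(
            id_vars="sample_id", var_name="gene", value_name="group")
        df = g.screen_panel(calls, records, DFS)
        assert len(df) == 33
        rab = df[df["gene"] == "RAB25"].iloc[0]
        assert rab["n_carriers"] == 3
        assert {"p", "p_bh", "eligible"}.issubset(df.columns)

    def test_all_censored_p_is_one(self, panel):
        recs = [g.ClinicalRecord(f"P{i}", 100.0, "III", "HGSC",
                                 10.0 + i, 0, 20.0 + i, 0) for i in range(10)]
        calls = []
        for i in range(10):
            calls.append({"sample_id": f"P{i}", "gene": "RAB25",
                          "group": int(i < 3)})
        import pandas as pd
        df = g.screen_panel(pd.DataFrame(calls), recs, DFS)
        assert df["p"].iloc[0] == pytest.approx(1.0)
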