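"""WHO bioassay analysis: pooled mortality, Abbott correction,
classification, synergist restoration and enzyme comparisons."""

import numpy as np
import pandas as pd
import pytest

from irtools import bioassay as ba
from irtools import simulate as sim
from conftest import exact_fisher_oracle


def _table(deaths, exposed=25, **cond):
    base = {"population": "P", "insecticide": "X", "synergist": "none"}
    base.update(cond)
    return pd.DataFrame([
        {**base, "tube_id": f"t{i}", "n_exposed": exposed, "n_dead_24h": d}
        for i, d in enumerate(deaths)
    ])


class TestPooledMortality:
    def test_all_dead(self):
        s = ba.pooled_mortality(_table([25, 25]), "P", "X")
        assert s.mortality == 100.0

    def test_none_dead(self):
        s = ba.pooled_mortality(_table([0, 0, 0], exposed=20), "P", "X")
        assert s.mortality == 0.0 and s.tube_sd == 0.0

    def test_worked_example(self):
        s = ba.pooled_mortality(_table([5, 6, 4, 7]), "P", "X")
        assert s.mortality == pytest.approx(22.0)
        # SD of tube-level mortalities {20, 24, 16, 28}
        assert s.tube_sd == pytest.approx(np.std([20, 24, 16, 28], ddof=1), abs=1e-9)
        assert s.n_total == 100 and not s.low_n

    def test_low_n_flag(self):
        s = ba.pooled_mortality(_table([5, 6], exposed=20), "P", "X")
        assert s.low_n

    def test_pooled_within_tube_range(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            deaths = rng.integers(0, 26, size=5)
            s = ba.pooled_mortality(_table(list(deaths)), "P", "X")
            per_tube = deaths / 25 * 100
            assert per_tube.min() - 1e-9 <= s.mortality <= per_tube.max() + 1e-9

    def test_missing_condition_errors(self):
        with pytest.raises(ValueError, match="no bioassay rows"):
            ba.pooled_mortality(_table([5]), "P", "Y")

    def test_odd_tube_size_warns(self):
        with pytest.warns(UserWarning, match="group size"):
            ba.pooled_mortality(_table([2, 3], exposed=10), "P", "X")


class TestAbbott:
    @pytest.mark.parametrize("obs,ctrl,expected", [
        (50.0, 0.0, 50.0),           # identity below the 5% band
        (50.0, 4.9, 50.0),
        (50.0, 10.0, 400 / 9),       # (50-10)/90*100
        (100.0, 20.0, 100.0),
    ])
    def test_correction(self, obs, ctrl, expected):
        assert ba.abbott_correct(obs, ctrl) == pytest.approx(expected)

    def test_invalid_run_above_20_percent_control(self):
        with pytest.raises(ValueError, match="invalid run"):
            ba.abbott_correct(30.0, 25.0)

    def test_monotone_in_observed(self):
        vals = [ba.abbott_correct(m, 10.0) for m in np.linspace(10, 100, 20)]
        assert all(b > a for a, b in zip(vals, vals[1:]))


class TestClassification:
    @pytest.mark.parametrize("mortality,expected", [
        (77.5, "resistant"),
        (100.0, "susceptible"),
        (90.0, "suspected"),   # boundary: strictly below 90 is resistant
        (89.999, "resistant"),
        (98.0, "susceptible"),
    ])
    def test_who_classes(self, mortality, expected):
        assert ba.classify_susceptibility(mortality) == expected

    def test_paper_mode_collapses_to_90_rule(self):
        assert ba.classify_susceptibility(90.0, paper_mode=True) == "not_resistant"
        assert ba.classify_susceptibility(89.9, paper_mode=True) == "resistant"

    def test_monotone_in_mortality(self):
        order = {"resistant": 0, "suspected": 1, "susceptible": 2}
        classes = [order[ba.classify_susceptibility(m)]
                   for m in np.linspace(0, 100, 101)]
        assert classes == sorted(classes)


class TestSynergistEffect:
    def test_identical_arms_p_one(self):
        t = pd.concat([
            _table([10, 10], exposed=20),
            _table([10, 10], exposed=20, synergist="PBO"),
        ])
        res, direction = ba.synergist_effect(t, "P", "X", "PBO")
        assert res.p_value == pytest.approx(1.0)
        assert direction == "unchanged"

    def test_restoration_detected_against_oracle(self):
        t = pd.concat([
            _table([2], exposed=20),
            _table([10], exposed=20, synergist="PBO"),
        ])
        res, direction = ba.synergist_effect(t, "P", "X", "PBO")
        expected = exact_fisher_oracle([[2, 18], [10, 10]])
        assert res.p_value == pytest.approx(expected, rel=1e-9)
        assert direction == "increased"
        assert (res.p_value < 0.05) == (expected < 0.05)

    def test_degenerate_all_dead_both_arms(self):
        t = pd.concat([
            _table([20, 20], exposed=20),
            _table([20, 20], exposed=20, synergist="DEM"),
        ])
        res, direction = ba.synergist_effect(t, "P", "X", "DEM")
        assert res.p_value == pytest.approx(1.0)

    def test_symmetric_up_to_direction(self):
        low = _table([3, 4], exposed=20)
        high = _table([15, 14], exposed=20, synergist="PBO")
        t = pd.concat([low, high])
        swapped = pd.concat([
            high.assign(synergist="none"), low.assign(synergist="PBO")])
        p1, d1 = ba.synergist_effect(t, "P", "X", "PBO")
        p2, d2 = ba.synergist_effect(swapped, "P", "X", "PBO")
        assert p1.p_value == pytest.approx(p2.p_value)
        assert {d1, d2} == {"increased", "decreased"}

    def test_missing_arm_errors(self):
        with pytest.raises(ValueError):
            ba.synergist_effect(_table([5]), "P", "X", "PBO")


class TestEnzymeComparison:
    def _enzyme_table(self, field, ref, family="GST"):
        rows = [("Funchal", family, f"f{i}", a) for i, a in enumerate(field)]
        rows += [("Rockefeller", family, f"r{i}", a) for i, a in enumerate(ref)]
        return pd.DataFrame(rows, columns=[
            "population", "enzyme_family", "individual_id", "activity"])

    def test_identical_groups_not_significant(self):
        vals = list(np.linspace(0.1, 2.0, 30))
        t = self._enzyme_table(vals, vals)
        res, _ = ba.compare_enzyme_activity(t, "Funchal", "Rockefeller", "GST")
        assert res.p_value > 0.9

    def test_full_separation_3v3(self):
        t = self._enzyme_table([1, 2, 3], [4, 5, 6])
        res, direction = ba.compare_enzyme_activity(
            t, "Funchal", "Rockefeller", "GST")
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1)
        assert res.p_value >= 0.05  # not significant at the 0.05 level
        assert direction == "reduced"

    def test_power_on_twofold_shift_at_n40(self):
        hits = 0
        runs = 200
        for seed in range(runs):
            df = sim.simulate_enzyme_activity(n_per_group=40, shift=2.0,
                                              enzyme_family="GST", seed=seed)
            res, direction = ba.compare_enzyme_activity(
                df, "Funchal", "Rockefeller", "GST")
            hits += (res.p_value < 0.05) and direction == "elevated"
        assert hits / runs >= 0.95

    def test_missing_group_errors(self):
        t = self._enzyme_table([1, 2, 3], [])
        with pytest.raises(ValueError):
            ba.compare_enzyme_activity(t, "Funchal", "Rockefeller", "GST")


class TestSummarize:
    def test_summary_covers_conditions_and_synergist_p(self, bioassay_table):
        out = ba.summarize_bioassay(bioassay_table)
        assert len(out) == 2  # permethrin none + PBO (controls excluded)
        pbo = out[out["synergist"] == "PBO"].iloc[0]
        assert pbo["synergist_significant"] == True  # noqa: E712
        assert pbo["synergist_direction"] == "increased"
        none = out[out["synergist"] == "none"].iloc[0]
        assert none["classification"] == "resistant"
        assert none["mortality_pct"] == pytest.approx(22.0)
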