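"""The replication-criterion differential-expression caller."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from irtools import simulate as sim
from irtools.diffexpr import (
    ABSENT,
    DETECTED,
    MARGINAL,
    DEConfig,
    ExpressionDataset,
    ReplicationDEModel,
    call_dataset,
    call_probe,
    expected_false_positives,
    filter_detectable,
    signed_fold_change,
)
from conftest import DETOX_CALL_TABLE

STATUS_ORDER = {"not_significant": 0, "potential": 1, "significant": 2}


def _dataset(matrices, flags=None):
    n = matrices[0].shape[0]
    labels = [f"c{i}" for i in range(len(matrices))]
    if flags is None:
        flags = [np.full(m.shape, DETECTED, dtype=object) for m in matrices]
    return ExpressionDataset(
        probe_ids=np.array([f"p{i}" for i in range(n)]),
        log2_ratios=dict(zip(labels, matrices)),
        flags=dict(zip(labels, flags)),
    )


class TestFilterDetectable:
    def test_all_detected_all_retained(self):
        m = np.zeros((5, 4))
        assert filter_detectable(_dataset([m, m])).all()

    def test_single_absent_flag_filters_the_probe(self):
        m = np.zeros((5, 4))
        fl = np.full((5, 4), DETECTED, dtype=object)
        fl[2, 1] = ABSENT
        fl2 = np.full((5, 4), MARGINAL, dtype=object)  # marginal is retained
        keep = filter_detectable(_dataset([m, m], [fl, fl2]))
        assert not keep[2] and keep.sum() == 4

    def test_retained_count_matches_binomial_expectation(self):
        cfg = sim.ExpressionSimConfig(n_probes=10000, n_contrasts=3, n_reps=4,
                                      dropout_prob=0.01, seed=20)
        ds, _ = sim.simulate_expression(cfg)
        keep = filter_detectable(ds)
        p = 0.99 ** 12  # survives 12 independent arrays
        expected = 10000 * p
        sd = np.sqrt(10000 * p * (1 - p))
        assert abs(keep.sum() - expected) < 3 * sd


class TestSignedFoldChange:
    @pytest.mark.parametrize("mean,expected", [(1.0, 2.0), (-1.0, -2.0), (0.0, 1.0)])
    def test_fixed_points(self, mean, expected):
        assert signed_fold_change([mean]) == pytest.approx(expected)

    @given(st.lists(st.floats(-8, 8), min_size=1, max_size=8))
    @settings(deadline=None, max_examples=80)
    def test_magnitude_at_least_one(self, values):
        assert abs(signed_fold_change(values)) >= 1.0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            signed_fold_change([])


class TestCallProbe:
    @pytest.mark.parametrize("gene", sorted(DETOX_CALL_TABLE))
    def test_published_detox_calls(self, gene):
        pairs, expected = DETOX_CALL_TABLE[gene]
        status, direction = call_probe(pairs)
        assert status == expected
        assert direction == "up"

    def test_null_probe_not_significant(self):
        assert call_probe([(1.0, 1.0)] * 3) == ("not_significant", None)

    def test_down_regulation_direction(self):
        status, direction = call_probe([(-5, 0.01), (-4, 0.02), (-3, 0.03)])
        assert (status, direction) == ("significant", "down")

    def test_sign_inconsistency_blocks_any_call(self):
        # two strong passes in opposite directions are never significant
        status, _ = call_probe([(30, 0.001), (-30, 0.001), (25, 0.001)])
        assert status == "not_significant"

    def test_rescue_requires_extreme_fc_in_passing_contrasts(self):
        # passes 2/3 but the passing FCs are below the rescue bound
        status, _ = call_probe([(5, 0.01), (6, 0.01), (4, 0.50)])
        assert status == "not_significant"
        # identical P pattern with extreme FCs is rescued
        status, _ = call_probe([(25, 0.01), (30, 0.01), (4, 0.50)])
        assert status == "potential"

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            call_probe([(np.nan, 0.01), (2, 0.02), (3, 0.03)])

    @given(
        st.lists(st.tuples(st.floats(1.1, 60), st.floats(1e-4, 0.99)),
                 min_size=3, max_size=3),
        st.integers(0, 2),
        st.floats(0.1, 0.99),
    )
    @settings(deadline=None, max_examples=100)
    def test_monotone_in_evidence(self, pairs, idx, shrink):
        before = STATUS_ORDER[call_probe(pairs)[0]]
        stronger = list(pairs)
        fc, p = stronger[idx]
        stronger[idx] = (fc * 1.5, p * shrink)  # more extreme FC, smaller P
        after = STATUS_ORDER[call_probe(stronger)[0]]
        assert after >= before


class TestExpectedFalsePositives:
    def test_published_expectations(self):
        assert round(expected_false_positives(9083, 0.05, 1), -1) == 450
        assert round(expected_false_positives(9083, 0.05, 3)) == 1

    def test_certain_alpha_returns_n(self):
        assert expected_false_positives(123, 0.999999, 1) == pytest.approx(
            123, rel=1e-5)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            expected_false_positives(0, 0.05, 3)
        with pytest.raises(ValueError):
            expected_false_positives(100, 1.5, 3)


class TestCallDataset:
    def test_all_up_dataset_has_only_up_directions(self):
        ds, _ = sim.simulate_expression(sim.ExpressionSimConfig(
            n_probes=300, de_fraction_up=1.0, de_log2fc=3.0, noise_sd=0.2,
            dropout_prob=0.0, seed=4))
        res = call_dataset(ds)
        called = res.records[res.records["status"] != "filtered"]
        assert set(called["direction"].dropna()) <= {"up"}

    def test_spiked_probes_recovered(self):
        ds, truth = sim.simulate_expression(sim.ExpressionSimConfig(
            n_probes=1000, de_fraction_up=0.05, de_fraction_down=0.05,
            de_log2fc=2.0, noise_sd=0.25, dropout_prob=0.0, seed=8))
        res = call_dataset(ds)
        merged = res.records.merge(truth, on="probe_id")
        spiked = merged[merged["label"] != "null"]
        assert (spiked["status"] == "significant").mean() >= 0.95
        null = merged[merged["label"] == "null"]
        assert (null["status"] == "significant").mean() < 0.01

    def test_records_sorted_by_combined_p(self):
        ds, _ = sim.simulate_expression(sim.ExpressionSimConfig(
            n_probes=100, de_fraction_up=0.2, noise_sd=0.3, seed=2))
        res = call_dataset(ds)
        cp = res.records["combined_p"].dropna().to_numpy()
        assert (np.diff(cp) >= 0).all()

    def test_mismatched_contrasts_rejected(self):
        m = np.zeros((5, 4))
        with pytest.raises(ValueError):
            ExpressionDataset(
                probe_ids=np.array([f"p{i}" for i in range(5)]),
                log2_ratios={"a": m},
                flags={"a": np.full((5, 4), DETECTED), "b": np.full((5, 4), DETECTED)},
            )

    def test_summary_reports_counts(self):
        ds, _ = sim.simulate_expression(sim.ExpressionSimConfig(
            n_probes=50, seed=3))
        text = ReplicationDEModel(ds).fit().summary()
        assert "retained" in text and "E[false +]" in text


class TestDEConfig:
    def test_invalid_thresholds(self):
        with pytest.raises(ValueError):
            DEConfig(alpha=0.0)
        with pytest.raises(ValueError):
            DEConfig(fc_threshold=0.5)
        with pytest.raises(ValueError):
            DEConfig(rescue_fc=1.5)

    def test_geometric_mean_fc_option(self):
        ds, _ = sim.simulate_expression(sim.ExpressionSimConfig(
            n_probes=80, de_fraction_up=0.2, de_log2fc=2.0, noise_sd=0.2, seed=6))
        arith = call_dataset(ds, DEConfig(mean_fc_method="arithmetic"))
        geom = call_dataset(ds, DEConfig(mean_fc_method="geometric"))
        # averaging convention must not change any call
        a = arith.records.sort_values("probe_id")["status"].to_numpy()
        g = geom.records.sort_values("probe_id")["status"].to_numpy()
        assert (a == g).all()
        # AM-GM: for probes positive in every contrast the geometric mean FC
        # is bounded above by the arithmetic mean FC
        ar = arith.records.set_index("probe_id")
        fc_cols = [c for c in ar.columns if c.startswith("fc_")]
        pos = (ar[fc_cols] > 0).all(axis=1)
        ga = geom.records.set_index("probe_id")["mean_fc"]
        assert (ga[pos] <= ar["mean_fc"][pos] + 1e-9).all()
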