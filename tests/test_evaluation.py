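"""Measurement calls, 2x2 agreement, improvement and pathway analysis."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from sgprflux.evaluation import (
    ComparisonResult,
    MetaboliteMeasurement,
    activity_difference,
    call_exchanges,
    compare_predictions,
    fisher_exact_2x2,
    improvement,
    pathway_overactivation,
    read_measurements,
    write_measurements,
)
from sgprflux.integration import ActivityState

from oracles import fisher_two_sided_oracle, mannwhitney_two_sided_oracle


class TestCallExchanges:
    def test_identical_samples_are_unchanged_with_p_one(self):
        calls = call_exchanges([MetaboliteMeasurement("m", [5, 5.1, 5.2], [5, 5.1, 5.2])])
        assert calls.calls["m"] == "unchanged"
        assert calls.p_value["m"] == pytest.approx(1.0)

    def test_three_vs_three_extreme_split_is_point_one(self):
        """Fully separated n=m=3 samples: exact two-sided p is 2/20 = 0.1."""
        calls = call_exchanges([MetaboliteMeasurement("m", [1, 2, 3], [10, 11, 12])], alpha=0.05)
        assert calls.p_value["m"] == pytest.approx(0.1)
        assert calls.calls["m"] == "unchanged"  # not significant at 0.05

    def test_direction_follows_median_change(self):
        ms = [
            MetaboliteMeasurement("down", [10, 11, 12, 13], [1, 2, 3, 4]),
            MetaboliteMeasurement("up", [1, 2, 3, 4], [10, 11, 12, 13]),
        ]
        calls = call_exchanges(ms, alpha=0.05)
        assert calls.calls["down"] == "consumed"
        assert calls.calls["up"] == "produced"

    def test_single_replicate_is_untestable(self):
        calls = call_exchanges([MetaboliteMeasurement("m", [5], [6, 7, 8])])
        assert calls.untestable == {"m"}
        assert "m" not in calls.calls

    @pytest.mark.parametrize("seed", range(4))
    def test_exact_p_matches_permutation_enumeration(self, seed):
        """Tie-free samples with n, m <= 6 against the full-enumeration oracle."""
        rng = np.random.default_rng(seed)
        n, m = rng.integers(2, 7), rng.integers(2, 7)
        pooled = rng.permutation(np.arange(1.0, 14.0))  # distinct values, no ties
        x, y = pooled[:n].tolist(), pooled[n : n + m].tolist()
        p = float(stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue)
        assert p == pytest.approx(float(mannwhitney_two_sided_oracle(x, y)), abs=1e-12)

    def test_measurement_table_round_trip(self, tmp_path):
        ms = [MetaboliteMeasurement("m1", [1, 2, 3], [4, 5, 6])]
        path = tmp_path / "meas.tsv"
        write_measurements(ms, path)
        again = read_measurements(path)
        assert again[0].metabolite_id == "m1"
        assert again[0].t0 == [1, 2, 3] and again[0].t5 == [4, 5, 6]

    def test_nonpositive_areas_rejected(self):
        with pytest.raises(ValueError):
            MetaboliteMeasurement("m", [0.0, 1.0], [1.0, 2.0])


class TestFisher:
    def test_hand_enumerated_table(self):
        """[[3,1],[1,3]]: tail sum over k = 0..4 gives 34/70."""
        assert fisher_exact_2x2(3, 1, 1, 3) == pytest.approx(34 / 70, abs=1e-15)

    def test_degenerate_margins_give_p_one(self):
        assert fisher_exact_2x2(0, 0, 0, 4) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exact_rational_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c, d = (int(x) for x in rng.integers(0, 11, size=4))
        if a + b + c + d == 0:
            a = 1
        assert fisher_exact_2x2(a, b, c, d) == pytest.approx(
            float(fisher_two_sided_oracle(a, b, c, d)), abs=1e-12
        )

    def test_matches_scipy_on_plain_tables(self):
        for table in [(5, 1, 2, 7), (3, 3, 4, 2), (0, 5, 5, 0), (8, 2, 1, 9)]:
            ours = fisher_exact_2x2(*table)
            ref = stats.fisher_exact([[table[0], table[1]], [table[2], table[3]]]).pvalue
            assert ours == pytest.approx(float(ref), abs=1e-10)


def state(labels: dict[str, str]) -> ActivityState:
    return ActivityState(states=labels)  # type: ignore[arg-type]


class TestComparePredictions:
    def test_table_orientation_and_right_proportion(self):
        pred = state({"EX_a": "active", "EX_b": "inactive", "EX_c": "active", "EX_d": "inactive"})
        from sgprflux.evaluation import ExchangeCall

        calls = ExchangeCall(
            calls={"a": "consumed", "b": "unchanged", "c": "unchanged", "d": "produced"},
            p_value={m: 0.01 for m in "abcd"},
        )
        mapping = {m: [f"EX_{m}"] for m in "abcd"}
        cmp = compare_predictions(pred, calls, mapping)
        assert (cmp.a, cmp.b, cmp.c, cmp.d) == (1, 1, 1, 1)
        assert cmp.right_proportion == pytest.approx(0.5)

    def test_either_direction_counts_as_predicted_active(self):
        pred = state({"EX_m_up": "inactive", "EX_m_sec": "active"})
        from sgprflux.evaluation import ExchangeCall

        calls = ExchangeCall(calls={"m": "produced"}, p_value={"m": 0.01})
        cmp = compare_predictions(pred, calls, {"m": ["EX_m_up", "EX_m_sec"]})
        assert (cmp.a, cmp.n) == (1, 1)

    def test_perfect_agreement(self):
        pred = state({"EX_a": "active", "EX_b": "inactive"})
        from sgprflux.evaluation import ExchangeCall

        calls = ExchangeCall(calls={"a": "consumed", "b": "unchanged"}, p_value={})
        cmp = compare_predictions(pred, calls, {"a": ["EX_a"], "b": ["EX_b"]})
        assert cmp.right_proportion == 1.0

    def test_no_overlap_is_an_error(self):
        from sgprflux.evaluation import ExchangeCall

        pred = state({"EX_a": "active"})
        calls = ExchangeCall(calls={"z": "consumed"}, p_value={})
        with pytest.raises(ValueError, match="evaluable"):
            compare_predictions(pred, calls, {"z": ["EX_z"]})


class TestImprovement:
    def r(self, a, b, c, d, mets):
        return ComparisonResult(a, b, c, d, fisher_p=1.0, metabolites=tuple(mets))

    def test_identity_gives_zero(self):
        x = self.r(3, 1, 1, 3, "abcdefgh")
        assert improvement(x, x) == 0.0

    def test_percentage_point_gain(self):
        mets = tuple(f"m{i}" for i in range(29))
        gpr = self.r(20, 4, 2, 3, mets)  # 23/29 right
        sgpr = self.r(21, 2, 2, 4, mets)  # 25/29 right
        assert improvement(gpr, sgpr) == pytest.approx(100 * 2 / 29, abs=5e-3)
        assert improvement(gpr, sgpr) == pytest.approx(6.90, abs=0.01)

    def test_sign_preserved_when_sgpr_worse(self):
        mets = tuple(f"m{i}" for i in range(20))
        gpr = self.r(10, 0, 0, 10, mets)
        sgpr = self.r(9, 1, 0, 10, mets)
        assert improvement(gpr, sgpr) == pytest.approx(-5.0)

    def test_mismatched_metabolite_sets_rejected(self):
        with pytest.raises(ValueError):
            improvement(self.r(1, 0, 0, 1, "ab"), self.r(1, 0, 0, 1, "ac"))


class TestActivityDifference:
    def test_identical_states(self):
        s = state({"r1": "active", "r2": "inactive"})
        assert activity_difference(s, s) == 0.0

    def test_two_of_hundred(self):
        a = state({f"r{i}": "active" for i in range(100)})
        flipped = dict(a.states)
        flipped["r0"] = flipped["r1"] = "inactive"
        assert activity_difference(a, state(flipped)) == pytest.approx(2.0)

    def test_complete_flip(self):
        a = state({"r1": "active", "r2": "active"})
        b = state({"r1": "inactive", "r2": "inactive"})
        assert activity_difference(a, b) == 100.0

    def test_mismatched_sets_rejected(self):
        with pytest.raises(ValueError):
            activity_difference(state({"r1": "active"}), state({"r2": "active"}))


class TestPathways:
    def two_states(self, n_ref_active, n_trt_active, n=10, pw="P"):
        rids = [f"{pw}_r{i}" for i in range(n)]
        ref = {r: "active" if i < n_ref_active else "inactive" for i, r in enumerate(rids)}
        trt = {r: "active" if i < n_trt_active else "inactive" for i, r in enumerate(rids)}
        pmap = {r: pw for r in rids}
        return state(ref), state(trt), pmap

    def test_relative_weight(self):
        ref, trt, pmap = self.two_states(4, 6)
        rep = pathway_overactivation({"ref": ref, "trt": trt}, pmap)
        assert rep.pathways["P"].relative_weight == pytest.approx(1.5)
        assert not rep.pathways["P"].exclusive

    def test_equal_counts_weight_one(self):
        ref, trt, pmap = self.two_states(4, 4)
        rep = pathway_overactivation({"ref": ref, "trt": trt}, pmap)
        assert rep.pathways["P"].relative_weight == pytest.approx(1.0)

    def test_exclusive_pathway_flagged(self):
        ref, trt, pmap = self.two_states(0, 3)
        rep = pathway_overactivation({"ref": ref, "trt": trt}, pmap)
        p = rep.pathways["P"]
        assert p.exclusive and p.relative_weight is None

    def test_identical_indicator_vectors_give_p_one(self):
        ref, trt, pmap = self.two_states(5, 5)
        rep = pathway_overactivation({"ref": ref, "trt": trt}, pmap)
        assert rep.pathways["P"].p_value == 1.0

    def test_requires_exactly_two_conditions(self):
        ref, trt, pmap = self.two_states(1, 2)
        with pytest.raises(ValueError):
            pathway_overactivation({"only": ref}, pmap)
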