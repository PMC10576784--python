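"""Assay matching, censoring, comparison scoring, and survey aggregation."""

import numpy as np
import pytest

from rbfekit.affinity import AffinityMeasurement, Qualifier
from rbfekit.exceptions import (
    InsufficientDataError,
    InsufficientOverlapError,
    RbfeError,
)
from rbfekit.metrics import weighted_rmse
from rbfekit.simulate import NoiseModel, SeriesSimConfig, simulate_assay_pair
from rbfekit.survey import (
    AssaySeries,
    censor_filter,
    compare_assays,
    comparison_category,
    match_compounds,
    repeatability_rms,
    survey_aggregate,
)


def series(values, assay_id="A", category="binding", mtype="Ki", quals=None):
    quals = quals or {}
    return AssaySeries(
        assay_id=assay_id,
        category=category,
        measurements=[
            AffinityMeasurement(cid, mtype, v, quals.get(cid, "eq"))
            for cid, v in values.items()
        ],
    )


class TestMatching:
    def test_inner_join_sorted(self):
        a = series({"x": 1e-8, "y": 2e-8, "z": 3e-8})
        b = series({"y": 1e-8, "z": 2e-8, "w": 3e-8}, assay_id="B")
        pairs = match_compounds(a, b)
        assert [p[0].compound_id for p in pairs] == ["y", "z"]

    def test_disjoint_sets_rejected(self):
        a = series({"x": 1e-8, "y": 2e-8})
        b = series({"u": 1e-8, "v": 2e-8}, assay_id="B")
        with pytest.raises(InsufficientOverlapError):
            match_compounds(a, b)

    def test_symmetric_up_to_pair_order(self):
        a = series({"x": 1e-8, "y": 2e-8, "z": 3e-8})
        b = series({"x": 3e-8, "y": 2e-8, "z": 1e-8}, assay_id="B")
        ab = match_compounds(a, b)
        ba = match_compounds(b, a)
        assert [(p[0].compound_id, p[1].value) for p in ab] == [
            (p[0].compound_id, p[0].value) for p in ba
        ]

    def test_duplicate_ids_in_one_series_rejected(self):
        with pytest.raises(RbfeError):
            AssaySeries(
                assay_id="A", category="binding",
                measurements=[
                    AffinityMeasurement("x", "Ki", 1e-8),
                    AffinityMeasurement("x", "Ki", 2e-8),
                ],
            )


class TestCensoring:
    def test_qualifier_drops_pair(self):
        a = series({"x": 1e-8, "y": 2e-8, "z": 3e-8}, quals={"y": "gt"})
        b = series({"x": 1e-8, "y": 2e-8, "z": 3e-8}, assay_id="B")
        kept, log = censor_filter(match_compounds(a, b))
        assert [p[0].compound_id for p in kept] == ["x", "z"]
        assert log == [{"compound_id": "y", "reason": "qualifier_gt_side_a"}]

    def test_plateau_rule_drops_shared_extreme(self):
        vals_a = {f"c{i}": 1e-5 for i in range(5)}  # all at A's max
        vals_a.update({"d1": 1e-8, "d2": 2e-8})
        vals_b = {k: (i + 1) * 1e-8 for i, k in enumerate(vals_a)}
        a, b = series(vals_a), series(vals_b, assay_id="B")
        kept, log = censor_filter(
            match_compounds(a, b), policy="qualifier_plus_plateau", plateau_k=3
        )
        assert sorted(p[0].compound_id for p in kept) == ["d1", "d2"]
        assert len(log) == 5
        assert all(e["reason"] == "plateau_side_a" for e in log)

    def test_plateau_rule_respects_k(self):
        vals_a = {"c1": 1e-5, "c2": 1e-5, "d1": 1e-8, "d2": 2e-8}
        vals_b = {k: (i + 1) * 1e-8 for i, k in enumerate(vals_a)}
        kept, log = censor_filter(
            match_compounds(series(vals_a), series(vals_b, assay_id="B")),
            policy="qualifier_plus_plateau", plateau_k=3,
        )
        assert len(kept) == 4 and not log  # only 2 share the extreme

    def test_censoring_never_adds_pairs(self):
        a = series({"x": 1e-8, "y": 2e-8, "z": 3e-8}, quals={"x": "lt"})
        b = series({"x": 1e-8, "y": 2e-8, "z": 3e-8}, assay_id="B")
        pairs = match_compounds(a, b)
        kept, _ = censor_filter(pairs)
        assert len(kept) <= len(pairs)

    def test_censoring_moves_rmse_toward_truth(self):
        # truncated measurements bias pairwise errors; dropping flagged
        # values brings the RMSE toward the uncensored-noise expectation
        sigma = 0.42
        cfg = SeriesSimConfig(
            n_compounds=120,
            noise=(NoiseModel(scale=sigma), NoiseModel(scale=sigma)),
            censor_limits=((2e-9, 3e-6), (2e-9, 3e-6)),
            seed=19,
        )
        _, a, b = simulate_assay_pair(cfg)
        raw = compare_assays(a, b, policy="qualifier_plus_plateau")
        n_flagged = sum(
            m.qualifier is not Qualifier.EQ for m in a.measurements + b.measurements
        )
        assert n_flagged > 0
        assert raw.metrics.n_compounds < cfg.n_compounds
        expected = 2 * sigma  # two independent noisy assays
        # censored-and-filtered RMSE close to the uncensored expectation
        assert raw.metrics.pairwise_rmse == pytest.approx(expected, rel=0.15)


class TestCompareAssays:
    def test_self_comparison_perfect(self):
        a = series({"x": 1e-8, "y": 5e-8, "z": 9e-7})
        comp = compare_assays(a, series({"x": 1e-8, "y": 5e-8, "z": 9e-7}, assay_id="B"))
        assert comp.metrics.pairwise_rmse == pytest.approx(0.0, abs=1e-12)
        assert comp.metrics.r_squared == pytest.approx(1.0)
        assert comp.metrics.kendall_tau == pytest.approx(1.0)

    def test_constant_fold_shift_gives_zero_rmse(self):
        vals = {"x": 1e-8, "y": 5e-8, "z": 9e-7}
        b = {k: 10 * v for k, v in vals.items()}
        comp = compare_assays(series(vals), series(b, assay_id="B"))
        assert comp.metrics.pairwise_rmse == pytest.approx(0.0, abs=1e-10)

    def test_order_invariance(self):
        _, a, b = simulate_assay_pair(SeriesSimConfig(n_compounds=25, seed=4))
        ab, ba = compare_assays(a, b).metrics, compare_assays(b, a).metrics
        assert ab.pairwise_rmse == pytest.approx(ba.pairwise_rmse, abs=1e-12)
        assert ab.pairwise_mue == pytest.approx(ba.pairwise_mue, abs=1e-12)
        assert ab.r_squared == pytest.approx(ba.r_squared, abs=1e-12)
        assert ab.kendall_tau == pytest.approx(ba.kendall_tau, abs=1e-12)

    def test_mixed_measure_types_allowed(self):
        a = series({"x": 1e-8, "y": 5e-8, "z": 9e-7}, mtype="Kd")
        b = series({"x": 2e-8, "y": 9e-8, "z": 2e-6}, assay_id="B", mtype="IC50")
        comp = compare_assays(a, b)
        assert comp.metrics.pairwise_rmse < 0.5  # consistent ratios, small error

    def test_category_label(self):
        assert comparison_category("binding", "functional") == "binding_vs_functional"
        assert comparison_category("functional", "binding") == "binding_vs_functional"
        assert comparison_category("binding", "binding") == "binding_vs_binding"
        with pytest.raises(RbfeError):
            comparison_category("binding", "cellular")

    def test_two_shared_compounds_skip_correlations(self):
        a = series({"x": 1e-8, "y": 5e-8})
        b = series({"x": 3e-8, "y": 2e-8}, assay_id="B")
        comp = compare_assays(a, b)
        assert comp.metrics.r_squared is None
        assert comp.metrics.kendall_tau is None
        assert comp.metrics.pairwise_rmse > 0


class TestAggregation:
    def _comparisons(self, n, seed0=0, category_b="functional"):
        comps = []
        for k in range(n):
            cfg = SeriesSimConfig(
                n_compounds=12 + k, seed=seed0 + k,
                categories=("binding", category_b),
            )
            _, a, b = simulate_assay_pair(cfg)
            comps.append(compare_assays(a, b))
        return comps

    def test_single_comparison_zero_width(self):
        comps = self._comparisons(1)
        agg = survey_aggregate(comps, n_boot=300, seed=0)
        block = agg["overall"]
        assert block["pairwise_rmse"].point == pytest.approx(
            comps[0].metrics.pairwise_rmse
        )
        assert block["pairwise_rmse"].ci_low == block["pairwise_rmse"].ci_high

    def test_per_category_equals_members(self):
        comps = self._comparisons(1, seed0=1, category_b="binding") + \
            self._comparisons(1, seed0=5, category_b="functional")
        agg = survey_aggregate(comps, n_boot=200, seed=0)
        cats = agg["by_category"]
        assert set(cats) == {"binding_vs_binding", "binding_vs_functional"}
        assert cats["binding_vs_binding"]["pairwise_rmse"].point == pytest.approx(
            comps[0].metrics.pairwise_rmse
        )

    def test_weighted_recomposition_over_categories(self):
        comps = self._comparisons(3, seed0=2, category_b="binding") + \
            self._comparisons(4, seed0=9, category_b="functional")
        agg = survey_aggregate(comps, n_boot=100, seed=0)
        parts = [
            (block["pairwise_rmse"].point,
             sum(c.metrics.n_compounds for c in comps
                 if c.comparison_category == cat))
            for cat, block in agg["by_category"].items()
        ]
        recomposed = weighted_rmse([p for p, _ in parts], [w for _, w in parts])
        assert recomposed == pytest.approx(agg["overall"]["pairwise_rmse"].point,
                                           abs=1e-12)

    def test_large_comparison_dominates_point_not_spread(self):
        small = self._comparisons(4, seed0=20)
        cfg = SeriesSimConfig(n_compounds=400, seed=99,
                              noise=(NoiseModel(scale=1.2), NoiseModel(scale=1.2)))
        _, a, b = simulate_assay_pair(cfg)
        big = compare_assays(a, b)
        agg = survey_aggregate(small + [big], n_boot=2000, seed=1)
        point = agg["overall"]["pairwise_rmse"].point
        # point estimate pulled toward the big noisy comparison...
        assert abs(point - big.metrics.pairwise_rmse) < abs(
            point - np.mean([c.metrics.pairwise_rmse for c in small])
        )
        # ...but the bootstrap interval still reflects the small comparisons
        assert agg["overall"]["pairwise_rmse"].ci_low < np.median(
            [c.metrics.pairwise_rmse for c in small]
        ) * 1.5

    def test_empty_rejected(self):
        with pytest.raises(InsufficientDataError):
            survey_aggregate([], n_boot=10, seed=0)


class TestRepeatability:
    def test_single_sd(self):
        agg = repeatability_rms({"A": [0.23]}, n_boot=100, seed=0)
        assert agg.point == pytest.approx(0.23)
        assert agg.ci_low == agg.ci_high == pytest.approx(0.23)

    def test_hand_value(self):
        agg = repeatability_rms({"A": [0.3, 0.4]}, n_boot=100, seed=0)
        assert agg.point == pytest.approx(np.sqrt(0.125), abs=1e-10)

    def test_composes_with_sqrt2_propagation(self):
        from rbfekit.affinity import abs_rmse_to_pairwise_rmse

        agg = repeatability_rms({"A": [0.23]}, n_boot=50, seed=0)
        assert round(abs_rmse_to_pairwise_rmse(agg.point), 2) == 0.33

    def test_negative_sd_rejected(self):
        with pytest.raises(RbfeError):
            repeatability_rms({"A": [0.2, -0.1]}, n_boot=10, seed=0)

    def test_bootstrap_over_groups(self):
        groups = {"A": [0.1, 0.12], "B": [0.5, 0.4], "C": [0.25]}
        agg = repeatability_rms(groups, n_boot=2000, seed=5)
        assert agg.ci_low < agg.point < agg.ci_high
        assert agg.m == 3
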