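"""Normalization, SP, rescue boundaries, PR, ranking and Hill fits."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import calscreen as cs
from calscreen.scoring import (
    compute_rescue_boundaries,
    fit_dose_response,
    normalize_features,
    parameter_recovery,
    radar_signature,
    rank_and_select,
    scalar_perturbation,
)


def make_annotations(rows):
    return pd.DataFrame(rows)


def symmetric_reference_setup(m=4.0, a=2.0, test_value=None, n_features=2):
    """Three reference wells at {m/a, m, m*a} per feature plus one test well.

    With a zero log offset the reference logs are symmetric about zero, so a
    test well at the median has z = 0 exactly and the reference log SD is
    ln(a) (sample SD of {-x, 0, x} is x).
    """
    cols = [f"f{i}" for i in range(n_features)]
    feats = pd.DataFrame(
        {
            "well_id": ["C1", "C2", "C3", "T1"],
            **{c: [m / a, m, m * a, m if test_value is None else test_value] for c in cols},
        }
    )
    ann = make_annotations(
        [
            dict(well_id="C1", plate_id="P1", genotype="CTRL", treatment="vehicle", vehicle="DMSO", replicate=1),
            dict(well_id="C2", plate_id="P1", genotype="CTRL", treatment="vehicle", vehicle="DMSO", replicate=2),
            dict(well_id="C3", plate_id="P1", genotype="CTRL", treatment="vehicle", vehicle="DMSO", replicate=3),
            dict(well_id="T1", plate_id="P1", genotype="CDD", treatment="CPD", vehicle="DMSO", replicate=1),
        ]
    )
    return feats, ann


class TestNormalizeFeatures:
    def test_well_at_reference_median_has_zero_z(self):
        feats, ann = symmetric_reference_setup()
        z, _ = normalize_features(feats, ann, log_offset=0.0)
        assert z.loc["T1"].abs().max() == pytest.approx(0.0, abs=1e-12)

    def test_double_the_median_gives_ln2_over_log_sd(self):
        # reference logs {-ln2, 0, ln2} -> sd = ln2, so z(2m) = ln2/ln2 = 1
        feats, ann = symmetric_reference_setup(m=4.0, a=2.0, test_value=8.0)
        z, stats = normalize_features(feats, ann, log_offset=0.0)
        assert z.loc["T1", "f0"] == pytest.approx(1.0)
        row = stats.table.set_index("feature").loc["f0"]
        assert row["control_log_sd"] == pytest.approx(np.log(2))
        assert row["reference_median"] == pytest.approx(4.0)

    def test_zero_spread_reference_is_capped_and_flagged(self):
        feats, ann = symmetric_reference_setup(a=1.0, test_value=8.0)  # refs identical
        z, stats = normalize_features(feats, ann, log_offset=0.0)
        assert z.loc["T1", "f0"] == 10.0  # above the reference mean, capped
        assert z.loc["C1", "f0"] == 0.0  # at the reference mean
        assert stats.table["zero_spread"].all()

    def test_missing_reference_wells_is_hard_error(self):
        feats, ann = symmetric_reference_setup()
        ann.loc[ann["well_id"] == "C3", "genotype"] = "CDD"  # only 2 refs left
        with pytest.raises(cs.MissingReferenceError):
            normalize_features(feats, ann)

    def test_scale_invariance_of_z(self):
        # multiplying a feature by a common factor cancels in median normalization
        feats, ann = symmetric_reference_setup(test_value=6.0)
        z1, _ = normalize_features(feats, ann, log_offset=0.0)
        scaled = feats.copy()
        scaled[["f0", "f1"]] *= 37.0
        z2, _ = normalize_features(scaled, ann, log_offset=0.0)
        pd.testing.assert_frame_equal(z1, z2)

    def test_vehicle_groups_normalized_separately(self):
        rows, data = [], {}
        for v, med in [("DMSO", 10.0), ("water", 100.0)]:
            for i, val in enumerate([med / 2, med, med * 2]):
                wid = f"{v}{i}"
                rows.append(
                    dict(well_id=wid, plate_id="P1", genotype="CTRL",
                         treatment="vehicle", vehicle=v, replicate=i + 1)
                )
                data[wid] = val
        feats = pd.DataFrame({"well_id": list(data), "f0": list(data.values())})
        z, stats = normalize_features(feats, make_annotations(rows), log_offset=0.0)
        # each group's median well sits at z = 0 against its own vehicle stats
        assert z.loc["DMSO1", "f0"] == pytest.approx(0.0)
        assert z.loc["water1", "f0"] == pytest.approx(0.0)
        meds = stats.table.set_index("vehicle")["reference_median"]
        assert meds["DMSO"] == 10.0 and meds["water"] == 100.0


class TestScalarPerturbation:
    def test_three_four_five_euclidean_norm(self):
        z = pd.DataFrame({"well_id": ["W1"], "f0": [3.0], "f1": [4.0]})
        ann = make_annotations(
            [dict(well_id="W1", plate_id="P1", genotype="CDD", treatment="CPD",
                  vehicle="DMSO", replicate=1)]
        )
        well_sp, table = scalar_perturbation(z, ann)
        assert well_sp["W1"] == pytest.approx(5.0)
        assert table.loc["CPD", "sp_mean"] == pytest.approx(5.0)

    def test_reference_center_replicate_has_zero_sp(self):
        feats, ann = symmetric_reference_setup()
        z, _ = normalize_features(feats, ann, log_offset=0.0)
        well_sp, _ = scalar_perturbation(z, ann)
        assert well_sp["T1"] == pytest.approx(0.0, abs=1e-12)

    def test_compound_sp_is_mean_of_replicates(self):
        z = pd.DataFrame({"well_id": ["W1", "W2"], "f0": [2.0, 4.0]})
        ann = make_annotations(
            [
                dict(well_id="W1", plate_id="P1", genotype="CDD", treatment="CPD",
                     vehicle="DMSO", replicate=1),
                dict(well_id="W2", plate_id="P1", genotype="CDD", treatment="CPD",
                     vehicle="DMSO", replicate=2),
            ]
        )
        _, table = scalar_perturbation(z, ann)
        assert table.loc["CPD", "sp_mean"] == pytest.approx(3.0)

    def test_feature_subset_selection(self):
        z = pd.DataFrame({"well_id": ["W1"], "f0": [3.0], "f1": [4.0]})
        ann = make_annotations(
            [dict(well_id="W1", plate_id="P1", genotype="CDD", treatment="CPD",
                  vehicle="DMSO", replicate=1)]
        )
        well_sp, _ = scalar_perturbation(z, ann, selected_features=["f0"])
        assert well_sp["W1"] == pytest.approx(3.0)
        with pytest.raises(cs.InvalidParameterError):
            scalar_perturbation(z, ann, selected_features=["nope"])


class TestRescueBoundaries:
    @staticmethod
    def ctrl_features(values):
        feats = pd.DataFrame(
            {"well_id": [f"C{i}" for i in range(len(values))], "f0": values}
        )
        ann = make_annotations(
            [
                dict(well_id=f"C{i}", plate_id="P1", genotype="CTRL",
                     treatment="vehicle", vehicle="DMSO", replicate=i + 1)
                for i in range(len(values))
            ]
        )
        return feats, ann

    def test_minmax_of_1_to_5(self):
        feats, ann = self.ctrl_features([1.0, 2.0, 3.0, 4.0, 5.0])
        b = compute_rescue_boundaries(feats, ann)
        assert b.table.loc["f0", "low"] == 1.0
        assert b.table.loc["f0", "high"] == 5.0

    def test_single_control_well_degenerates_with_warning(self):
        feats, ann = self.ctrl_features([3.0])
        with pytest.warns(UserWarning):
            b = compute_rescue_boundaries(feats, ann)
        assert b.table.loc["f0", "low"] == b.table.loc["f0", "high"] == 3.0

    def test_mean_plus_minus_two_sd(self):
        feats, ann = self.ctrl_features([2.0, 4.0, 6.0])  # mean 4, sd 2
        b = compute_rescue_boundaries(feats, ann, method="mean_sd", k_sd=2.0)
        assert b.table.loc["f0", "low"] == pytest.approx(0.0)
        assert b.table.loc["f0", "high"] == pytest.approx(8.0)

    def test_percentile_method_matches_quantiles(self):
        values = list(np.arange(1.0, 21.0))
        feats, ann = self.ctrl_features(values)
        b = compute_rescue_boundaries(feats, ann, method="percentile", percentiles=(10, 90))
        assert b.table.loc["f0", "low"] == pytest.approx(np.quantile(values, 0.10))
        assert b.table.loc["f0", "high"] == pytest.approx(np.quantile(values, 0.90))

    def test_unknown_method_and_no_controls_raise(self):
        feats, ann = self.ctrl_features([1.0, 2.0])
        with pytest.raises(cs.InvalidParameterError):
            compute_rescue_boundaries(feats, ann, method="magic")
        with pytest.raises(cs.MissingReferenceError):
            compute_rescue_boundaries(feats, ann, vehicle="water")


class TestParameterRecovery:
    @staticmethod
    def one_well(k_inside, n_features=17):
        """A replicate with k features inside [0, 1] boundaries, rest outside."""
        values = [0.5] * k_inside + [5.0] * (n_features - k_inside)
        feats = pd.DataFrame({"well_id": ["W1"], **{f"f{i}": [v] for i, v in enumerate(values)}})
        ann = make_annotations(
            [dict(well_id="W1", plate_id="P1", genotype="CDD", treatment="CPD",
                  vehicle="DMSO", replicate=1)]
        )
        table = pd.DataFrame(
            {"low": 0.0, "high": 1.0}, index=[f"f{i}" for i in range(n_features)]
        )
        boundaries = cs.RescueBoundaries(table, "minmax", "test")
        return feats, boundaries, ann

    @pytest.mark.parametrize("k", range(18))
    def test_k_of_17_inside_matches_bruteforce_count(self, k):
        feats, boundaries, ann = self.one_well(k)
        well_pr, table = parameter_recovery(feats, boundaries, ann)
        # independent brute-force count
        b = boundaries.table
        n_inside = sum(
            1
            for f in b.index
            if b.loc[f, "low"] <= feats.set_index("well_id").loc["W1", f] <= b.loc[f, "high"]
        )
        assert n_inside == k
        assert well_pr["W1"] == pytest.approx(100.0 * k / 17)
        assert table.loc["CPD", "pr_mean"] == pytest.approx(100.0 * k / 17)

    def test_eleven_of_17_is_64_71_percent(self):
        feats, boundaries, ann = self.one_well(11)
        well_pr, _ = parameter_recovery(feats, boundaries, ann)
        assert round(float(well_pr["W1"]), 2) == 64.71

    def test_boundary_endpoints_count_as_inside(self):
        feats, boundaries, ann = self.one_well(17)
        feats.loc[0, "f0"] = 0.0
        feats.loc[0, "f1"] = 1.0
        well_pr, _ = parameter_recovery(feats, boundaries, ann)
        assert well_pr["W1"] == 100.0

    def test_pr_monotone_as_boundaries_shrink(self):
        rng = np.random.default_rng(0)
        n = 17
        feats = pd.DataFrame(
            {"well_id": ["W1"], **{f"f{i}": [rng.uniform(0, 2)] for i in range(n)}}
        )
        ann = make_annotations(
            [dict(well_id="W1", plate_id="P1", genotype="CDD", treatment="CPD",
                  vehicle="DMSO", replicate=1)]
        )
        idx = [f"f{i}" for i in range(n)]
        wide = cs.RescueBoundaries(pd.DataFrame({"low": 0.0, "high": 2.0}, index=idx), "minmax", "t")
        narrow = cs.RescueBoundaries(pd.DataFrame({"low": 0.5, "high": 1.5}, index=idx), "minmax", "t")
        pr_wide, _ = parameter_recovery(feats, wide, ann)
        pr_narrow, _ = parameter_recovery(feats, narrow, ann)
        assert pr_narrow["W1"] <= pr_wide["W1"]

    def test_per_vehicle_boundary_mapping(self):
        feats, boundaries, ann = self.one_well(17)
        well_pr, _ = parameter_recovery(feats, {"DMSO": boundaries}, ann)
        assert well_pr["W1"] == 100.0
        with pytest.raises(cs.MissingReferenceError):
            parameter_recovery(feats, {"water": boundaries}, ann)


class TestRankAndSelect:
    @staticmethod
    def scores(sp, pr, ids=None):
        ids = ids or [f"C{i}" for i in range(len(sp))]
        return pd.DataFrame({"sp_mean": sp, "pr_mean": pr}, index=pd.Index(ids, name="compound_id"))

    def test_singleton_gets_rank_one(self):
        out = rank_and_select(self.scores([0.7], [80.0]))
        assert out["sp_rank"].iloc[0] == 1
        assert out["pr_rank"].iloc[0] == 1

    def test_sp_ranks_ascend_from_smallest(self):
        out = rank_and_select(self.scores([0.5, 1.2, 0.9], [70, 70, 70]))
        assert list(out["sp_rank"]) == [1, 3, 2]

    def test_pr_threshold_is_strict(self):
        out = rank_and_select(self.scores([0.1, 0.2], [60.0, 60.01]))
        assert not out["selected_pr"].iloc[0]
        assert out["selected_pr"].iloc[1]

    def test_ties_break_lexicographically(self):
        out = rank_and_select(self.scores([1.0, 1.0, 1.0], [50, 50, 50], ids=["B", "A", "C"]))
        assert out.loc["A", "sp_rank"] == 1
        assert out.loc["B", "sp_rank"] == 2
        assert out.loc["C", "sp_rank"] == 3

    def test_ranks_are_permutations(self):
        rng = np.random.default_rng(1)
        out = rank_and_select(self.scores(rng.uniform(0, 5, 30), rng.uniform(0, 100, 30)))
        assert sorted(out["sp_rank"]) == list(range(1, 31))
        assert sorted(out["pr_rank"]) == list(range(1, 31))

    def test_viability_rule_gates_leads(self):
        df = self.scores([0.1, 0.1], [90.0, 90.0])
        df["viability"] = [0.95, 0.5]
        df["vehicle"] = ["DMSO", "DMSO"]
        out = rank_and_select(df, vehicle_median_viability={"DMSO": 1.0})
        assert out["lead"].tolist() == [True, False]


class TestDoseResponse:
    def test_noiseless_curve_recovered_exactly(self):
        c = np.geomspace(1e-3, 10.0, 8)
        y = 0.0 + (80.0 - 0.0) * c / (c + 0.1)
        fit = fit_dose_response(c, y)
        assert fit.converged
        assert fit.ec50_uM == pytest.approx(0.1, abs=1e-4)
        assert fit.hill_slope == pytest.approx(1.0, abs=1e-3)
        assert fit.top_pct == pytest.approx(80.0, abs=1e-2)

    def test_steep_hill_slope_recovered(self):
        c = np.geomspace(0.3, 3.0, 12)
        y = 10.0 + 70.0 * c**6 / (c**6 + 1.0**6)
        fit = fit_dose_response(c, y)
        assert fit.converged
        assert fit.ec50_uM == pytest.approx(1.0, rel=1e-3)
        assert fit.hill_slope == pytest.approx(6.0, rel=1e-2)

    def test_flat_response_does_not_converge(self):
        fit = fit_dose_response([0.001, 0.01, 0.1, 1.0], [50.0, 50.0, 50.0, 50.0])
        assert not fit.converged
        assert fit.ec50_uM is None

    def test_too_few_concentrations_not_converged(self):
        fit = fit_dose_response([0.01, 0.1, 1.0], [10.0, 50.0, 90.0])
        assert not fit.converged

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(cs.InvalidParameterError):
            fit_dose_response([0.0, 0.1, 1.0, 10.0], [1, 2, 3, 4])


class TestRadarSignature:
    def test_group_medians_match_bruteforce(self):
        rng = np.random.default_rng(2)
        wells = [f"W{i}" for i in range(12)]
        values = pd.DataFrame(
            rng.normal(size=(12, 4)), index=pd.Index(wells, name="well_id"),
            columns=["f0", "f1", "f2", "f3"],
        )
        groups = pd.Series(["A"] * 6 + ["B"] * 6, index=values.index)
        out = radar_signature(values, groups)
        for g in ("A", "B"):
            sub = values[groups == g]
            for col in values.columns:
                assert out.loc[g, col] == pytest.approx(np.median(sub[col]))

    def test_identical_wells_summary_equals_well_values(self):
        values = pd.DataFrame(
            {"f0": [3.0, 3.0], "f1": [7.0, 7.0]},
            index=pd.Index(["W1", "W2"], name="well_id"),
        )
        out = radar_signature(values, pd.Series(["G", "G"], index=values.index))
        assert out.loc["G", "f0"] == 3.0
        assert out.loc["G", "f1"] == 7.0
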