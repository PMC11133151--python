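"""Registry composition and the individual filter operators against
hand-computed examples."""

import numpy as np
import pandas as pd
import pytest

from stroop_multiverse import (
    ParameterError,
    apply_specification,
    build_registry,
    clean_base,
    filter_rt_absolute,
    filter_rt_mad,
    filter_rt_sd,
    registry_table,
    remove_participants,
    trim_participants,
)
from stroop_multiverse.spec_registry import RemovalLog

from conftest import dataset_from_rts


def frame(rts, pid="p1"):
    return pd.DataFrame({"participant_id": pid, "condition": "alcohol",
                         "rt_ms": list(map(float, rts))})


class TestRegistry:
    def test_exactly_27_specifications(self):
        assert len(build_registry()) == 27

    def test_category_partition(self):
        counts = registry_table()["category"].value_counts().to_dict()
        assert counts == {
            "no_exclusion": 2, "sd_based": 6, "raw_rt_cutoff": 8,
            "participant_removal": 7, "mad_based": 2, "trimmed_mean": 2,
        }

    def test_spec_ids_pairwise_distinct(self):
        ids = [s.spec_id for s in build_registry()]
        assert len(set(ids)) == len(ids)

    def test_only_the_median_noexclusion_uses_the_median(self):
        centers = {s.spec_id: s.center for s in build_registry()}
        assert centers.pop("noexcl_median") == "median"
        assert set(centers.values()) == {"mean"}


class TestAbsoluteCutoff:
    def test_upper_cutoff(self):
        assert list(filter_rt_absolute([150, 900, 2500], upper=2000)) == [150, 900]

    def test_lower_cutoff(self):
        assert list(filter_rt_absolute([150, 900, 2500], lower=200)) == [900, 2500]

    def test_boundary_value_retained_removal_is_strict(self):
        assert list(filter_rt_absolute([2000], upper=2000)) == [2000]
        assert list(filter_rt_absolute([200], lower=200)) == [200]

    def test_no_bounds_rejected(self):
        with pytest.raises(ParameterError):
            filter_rt_absolute([500])

    def test_crossed_bounds_rejected(self):
        with pytest.raises(ParameterError):
            filter_rt_absolute([500], lower=1000, upper=100)


class TestSDFilter:
    def test_single_large_outlier_masks_itself_at_n5(self):
        # mean 847, sample SD ~1203.6, upper bound ~3254: nothing removed
        out = filter_rt_sd(frame([300, 305, 310, 320, 3000]),
                           k_upper=2, k_lower=2, mode="remove")
        assert sorted(out["rt_ms"]) == [300, 305, 310, 320, 3000]

    def test_zero_sd_removes_nothing(self):
        out = filter_rt_sd(frame([500] * 6), k_upper=2, k_lower=2, mode="remove")
        assert len(out) == 6

    def test_replace_with_mean_no_op_when_nothing_exceeds(self):
        # mean 500, SD 100, bound 800: all three inside
        out = filter_rt_sd(frame([400, 500, 600]), k_upper=3,
                           mode="replace_with_mean")
        assert sorted(out["rt_ms"]) == [400, 500, 600]

    def test_replace_with_mean_substitutes_participant_mean(self):
        rts = [400.0, 420.0, 440.0, 460.0, 480.0, 2000.0]
        m, s = np.mean(rts), np.std(rts, ddof=1)
        assert 2000.0 > m + 2 * s
        out = filter_rt_sd(frame(rts), k_upper=2, mode="replace_with_mean")
        assert len(out) == 6  # replacement conserves trial count
        assert pytest.approx(out["rt_ms"].max()) == m

    def test_replace_with_boundary_substitutes_bound(self):
        rts = [400.0, 420.0, 440.0, 460.0, 480.0, 2000.0]
        m, s = np.mean(rts), np.std(rts, ddof=1)
        out = filter_rt_sd(frame(rts), k_upper=2, mode="replace_with_boundary")
        assert pytest.approx(out["rt_ms"].max()) == m + 2 * s

    def test_singleton_participant_passes_through_and_is_logged(self):
        log = RemovalLog()
        out = filter_rt_sd(frame([3000]), k_upper=2, mode="remove", log=log)
        assert list(out["rt_ms"]) == [3000]
        assert log.unfiltered_participants == ["p1"]

    def test_statistics_pool_across_conditions(self):
        # 3000 in the alcohol cell is outlying only against the pooled spread
        df = pd.concat([
            frame([500, 510, 520, 3000], pid="p1"),
            frame([505, 515, 525, 495], pid="p1").assign(condition="neutral"),
        ], ignore_index=True)
        pooled = df["rt_ms"]
        bound = pooled.mean() + 2 * pooled.std(ddof=1)
        out = filter_rt_sd(df, k_upper=2, mode="remove")
        expected = sorted(pooled[pooled <= bound])
        assert sorted(out["rt_ms"]) == expected

    def test_no_k_rejected(self):
        with pytest.raises(ParameterError):
            filter_rt_sd(frame([1, 2, 3]))


class TestMADFilter:
    def test_upper_only_removes_the_extreme_point(self):
        # median 310, raw MAD 10, scaled 14.826, bound ~347.1
        out = filter_rt_mad(frame([300, 305, 310, 320, 3000]), 2.5,
                            two_sided=False)
        assert sorted(out["rt_ms"]) == [300, 305, 310, 320]

    def test_zero_mad_removes_nothing(self):
        out = filter_rt_mad(frame([500] * 5), 2.5)
        assert len(out) == 5

    def test_insensitive_to_outlier_magnitude(self):
        a = filter_rt_mad(frame([300, 305, 310, 320, 3000]), 2.5)
        b = filter_rt_mad(frame([300, 305, 310, 320, 30000]), 2.5)
        assert sorted(a["rt_ms"]) == sorted(b["rt_ms"])

    def test_two_sided_removes_low_tail_too(self):
        rts = [100, 300, 305, 310, 315, 320]
        out = filter_rt_mad(frame(rts), 2.5, two_sided=True)
        assert 100 not in set(out["rt_ms"])

    def test_nonpositive_multiplier_rejected(self):
        with pytest.raises(ParameterError):
            filter_rt_mad(frame([1, 2, 3]), 0)


class TestParticipantRules:
    def base_with_error_rates(self, rates, n_trials=10):
        data = {}
        rows = {}
        for i, rate in enumerate(rates):
            pid = f"p{i:02d}"
            n_err = int(round(rate * n_trials))
            rows[pid] = n_err
            data[pid] = {"alcohol": [500 + i] * ((n_trials - n_err + 1) // 2),
                         "neutral": [490 + i] * ((n_trials - n_err) // 2)}
        ds = dataset_from_rts(data)
        # append incorrect trials to reach the target error counts
        import pandas as pd
        extra = []
        for pid, n_err in rows.items():
            for j in range(n_err):
                extra.append(dict(participant_id=pid, trial_index=100 + j,
                                  phase="critical", condition="alcohol",
                                  colour="red", correct=False, rt_ms=600.0,
                                  block_id=None))
        trials = pd.concat([ds.trials, pd.DataFrame(extra)], ignore_index=True)
        from stroop_multiverse import Dataset
        return clean_base(Dataset(trials=trials))

    def test_error_rate_rule_is_strict_upper(self):
        base = self.base_with_error_rates([0] * 9 + [0.4])
        retained = remove_participants(base, "error_rate", {"threshold": 1 / 3})
        assert len(retained) == 9
        assert "p09" not in retained

    def test_identical_participants_all_retained_under_sd_rules(self):
        base = clean_base(dataset_from_rts({
            f"p{i}": {"alcohol": [500, 510], "neutral": [490, 505]}
            for i in range(5)
        }))
        for rule, params in [("mean_rt_sd", {"k": 2.0}),
                             ("error_count_sd", {"k": 3.0}),
                             ("interference_sd", {"k": 4.0})]:
            retained = remove_participants(base, rule, params)
            assert len(retained) == 5, rule

    def test_fast_rt_share_rule(self):
        base = clean_base(dataset_from_rts({
            "slow": {"alcohol": [500] * 5, "neutral": [490] * 5},
            "fast": {"alcohol": [150, 150, 150, 500, 510],
                     "neutral": [490] * 5},  # 30% of recorded RTs < 200
        }))
        retained = remove_participants(
            base, "fast_rt_share", {"rt_threshold": 200.0, "share": 0.25})
        assert retained == frozenset({"slow"})

    def test_interference_rule_is_two_sided(self):
        # one outlier among n can sit at most (n-1)/sqrt(n) SDs from the
        # sample mean, so crossing 4 SD needs n >= 18 scored participants
        data = {f"p{i:02d}": {"alcohol": [500 + i], "neutral": [500]}
                for i in range(25)}
        data["lo"] = {"alcohol": [100], "neutral": [500]}  # extreme negative
        base = clean_base(dataset_from_rts(data))
        retained = remove_participants(base, "interference_sd", {"k": 4.0})
        assert "lo" not in retained
        assert len(retained) == 25

    def test_unknown_rule_rejected(self, tiny_base):
        with pytest.raises(ParameterError):
            remove_participants(tiny_base, "no_such_rule", {})


class TestTrim:
    def test_hand_sorted_trim_20_percent(self):
        scores = pd.Series(
            [-50, 1, 2, 3, 4, 5, 6, 7, 8, 100],
            index=[f"p{i}" for i in range(10)],
        )
        retained = trim_participants(scores, 0.20)
        kept = sorted(scores[list(retained)])
        assert kept == [1, 2, 3, 4, 5, 6, 7, 8]
        assert np.mean(kept) == 4.5

    def test_floor_rule_trims_zero_at_10_percent_n10(self):
        scores = pd.Series(range(10), index=[f"p{i}" for i in range(10)])
        # floor(10 * 0.05) = 0 per tail: nobody is removed
        assert len(trim_participants(scores, 0.10)) == 10

    def test_equal_scores_leave_estimate_unchanged(self):
        scores = pd.Series([5.0] * 10, index=[f"p{i}" for i in range(10)])
        retained = trim_participants(scores, 0.20)
        assert np.mean(scores[list(retained)]) == 5.0

    def test_bad_proportion_rejected(self):
        scores = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        with pytest.raises(ParameterError):
            trim_participants(scores, 1.5)


class TestApplySpecification:
    def registry_by_id(self):
        return {s.spec_id: s for s in build_registry()}

    def test_no_exclusion_is_identity(self, tiny_base):
        ad = apply_specification(tiny_base, self.registry_by_id()["noexcl_mean"])
        pd.testing.assert_frame_equal(ad.rts, tiny_base.valid_rts)
        assert ad.removal_log.n_trials_removed == 0

    def test_each_spec_starts_from_base_never_chained(self, tiny_base):
        reg = self.registry_by_id()
        a1 = apply_specification(tiny_base, reg["cut_gt_2000"])
        a2 = apply_specification(tiny_base, reg["sd_remove_2s_3"])
        # base unchanged after both runs
        assert len(tiny_base.valid_rts) == 10
        assert len(a1.rts) == len(tiny_base.valid_rts)
        assert len(a2.rts) == len(tiny_base.valid_rts)

    def test_removal_log_counts_single_cutoff_removal(self):
        base = clean_base(dataset_from_rts({
            "p1": {"alcohol": [500, 2990], "neutral": [450, 460]},
            "p2": {"alcohol": [520, 530], "neutral": [455, 465]},
        }))
        ad = apply_specification(base, self.registry_by_id()["cut_gt_2000"])
        assert ad.removal_log.n_trials_removed == 1
        assert ad.removal_log.trials_removed_by_participant == {"p1": 1}
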