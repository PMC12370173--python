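import numpy as np
import pytest

from mpsprofiler import (
    ConditionLevel,
    SyntheticConfig,
    aggregate_importance,
    align_clusters,
    condition_levels,
    generate_dataset,
    intraphenotype_behaviors,
    planted_truth,
    profile_condition,
    run_all_conditions,
)
from mpsprofiler.profiling_pipeline import environments_at_level
from mpsprofiler.synthetic_data import HIGH_TIER, LOW_TIER


def _null_table(seed=0):
    return generate_dataset(
        SyntheticConfig(
            seed=seed, effect_size={"high": 0.0, "moderate": 0.0, "low": 0.0}
        )
    )


class TestConditionLevels:
    def test_twelve_levels_in_fixed_order(self):
        levels = condition_levels()
        assert len(levels) == 12
        assert [l.variable for l in levels[:4]] == [
            "pH", "pH", "perfusion", "perfusion",
        ]

    def test_levels_cover_plausible_environment_counts(self):
        counts = {l.name: len(environments_at_level(l)) for l in condition_levels()}
        assert counts["pH=7.4"] == 8 and counts["pH=6.5"] == 4
        assert counts["perfusion=static"] == 8 and counts["perfusion=dynamic"] == 4
        assert all(counts[f"hydrogel={h}"] == 3
                   for h in ("So-L", "So-H", "St-L", "St-H"))
        assert counts["gelatin_content=low"] == 6
        assert counts["alginate_content=high"] == 6

    def test_unknown_variable_rejected(self):
        with pytest.raises(ValueError):
            environments_at_level(ConditionLevel("temperature", 37))


class TestAlignClusters:
    def test_identity_when_assignments_match_truth(self):
        truth = np.repeat([0, 1], 5)
        mapping, cm = align_clusters(truth.copy(), truth)
        assert mapping == {0: 0, 1: 1}
        assert (cm.fp, cm.fn) == (0, 0)
        assert (cm.tp, cm.tn) == (5, 5)

    def test_swap_when_cluster_labels_are_complemented(self):
        truth = np.repeat([0, 1], 5)
        mapping, cm = align_clusters(1 - truth, truth)
        assert mapping == {0: 1, 1: 0}
        assert (cm.fp, cm.fn) == (0, 0)

    def test_random_assignments_give_chance_accuracy(self):
        """Aligned accuracy of label-independent clusters concentrates near
        0.5 (binomial null, folded by the max over two mappings)."""
        n_seeds, inside = 100, 0
        truth = np.repeat([0, 1], 36)
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            _, cm = align_clusters(rng.integers(0, 2, 72), truth)
            inside += 0.35 <= cm.accuracy <= 0.65
        assert inside >= 0.95 * n_seeds

    def test_alignment_never_below_chance(self, rng):
        truth = np.repeat([0, 1], 20)
        for _ in range(20):
            _, cm = align_clusters(rng.integers(0, 2, 40), truth)
            assert cm.accuracy >= 0.5

    def test_non_binary_inputs_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            align_clusters(np.array([0, 1, 2]), np.array([0, 1, 1]))


class TestProfileCondition:
    def test_acidic_level_separates_lines_without_error(self, default_table):
        profile = profile_condition(default_table, ConditionLevel("pH", 6.5), seed=0)
        assert profile.confusion_post.fp == 0
        assert profile.confusion_post.fn == 0
        assert profile.n_records == 24

    def test_retained_markers_come_from_planted_truth(
        self, default_table, default_config
    ):
        level = ConditionLevel("pH", 6.5)
        profile = profile_condition(default_table, level, seed=0)
        assert set(profile.ranking.retained) <= planted_truth(default_config, level)

    def test_single_cell_line_subset_rejected(self, default_table):
        invasive_only = default_table.subset(
            [r.cell_line == "invasive" for r in default_table.records]
        )
        with pytest.raises(ValueError, match="cell line"):
            profile_condition(invasive_only, ConditionLevel("pH", 6.5))

    def test_null_design_yields_flagged_profile(self):
        profile = profile_condition(_null_table(), ConditionLevel("pH", 6.5), seed=0)
        assert profile.no_features
        assert profile.ranking.retained == []
        assert profile.silhouette_post is None
        assert profile.confusion_post is None


class TestRunAllConditions:
    def test_one_profile_per_level(self, default_table):
        profiles = run_all_conditions(default_table, seed=0)
        assert [p.level.name for p in profiles] == [
            l.name for l in condition_levels()
        ]

    def test_empty_table_rejected(self, default_table):
        with pytest.raises(ValueError):
            run_all_conditions(default_table.subset([False] * 72))

    def test_failing_level_is_named(self, default_table):
        # drop every acidic record: the pH=6.5 level has no data
        keep = [
            env not in {e.env_id for e in
                        environments_at_level(ConditionLevel("pH", 6.5))}
            for env in default_table.env_ids()
        ]
        with pytest.raises(ValueError, match="pH=6.5"):
            run_all_conditions(default_table.subset(keep))

    def test_moderate_tier_recovered_only_under_stress(self):
        """The moderate tier is planted only under stress conditions, so
        moderate markers may clear the threshold at the acidic level but
        never at a neutral-pH static-only subset (per seed, the acidic
        moderate-retention count is >= the neutral-static one)."""
        from mpsprofiler.synthetic_data import MODERATE_TIER

        n_seeds, ok, acid_total, neutral_total = 25, 0, 0, 0
        for seed in range(n_seeds):
            table = generate_dataset(SyntheticConfig(seed=seed))
            acidic = profile_condition(table, ConditionLevel("pH", 6.5), seed=seed)
            static = table.subset(
                [r.env_id in {1, 4, 7, 10} for r in table.records]
            )
            neutral = profile_condition(static, ConditionLevel("pH", 7.4), seed=seed)
            ma = len(set(acidic.ranking.retained) & set(MODERATE_TIER))
            mn = len(set(neutral.ranking.retained) & set(MODERATE_TIER))
            ok += ma >= mn
            acid_total += ma
            neutral_total += mn
        assert ok >= 0.9 * n_seeds
        assert acid_total > neutral_total

    def test_feature_reduction_does_not_hurt_separation(self):
        """Over seeds and levels, silhouette does not drop and confusion
        errors do not grow after reduction (>= 90% of profiles)."""
        sil_ok = err_ok = total = 0
        for seed in range(10):
            table = generate_dataset(SyntheticConfig(seed=seed))
            for p in run_all_conditions(table, seed=seed):
                if p.no_features:
                    continue
                total += 1
                sil_ok += p.silhouette_post >= p.silhouette_pre - 1e-9
                err_ok += p.confusion_post.errors <= p.confusion_pre.errors
        assert sil_ok >= 0.9 * total
        assert err_ok >= 0.9 * total


class TestAggregateImportance:
    def test_dominant_marker_ranked_first(self, default_table):
        profiles = run_all_conditions(default_table, seed=0)
        agg = aggregate_importance(profiles)
        top = agg.order[0]
        assert all(
            agg.combined_score[top] >= agg.combined_score[m] for m in agg.order
        )
        assert top in HIGH_TIER

    def test_high_tier_outranks_low_tier(self, default_table):
        agg = aggregate_importance(run_all_conditions(default_table, seed=0))
        worst_high = max(agg.order.index(m) for m in HIGH_TIER)
        best_low = min(agg.order.index(m) for m in LOW_TIER)
        assert worst_high < best_low

    def test_profile_order_invariance(self, default_table):
        profiles = run_all_conditions(default_table, seed=0)
        a = aggregate_importance(profiles)
        b = aggregate_importance(list(reversed(profiles)))
        assert a.order == b.order
        assert a.combined_score == b.combined_score

    def test_single_profile_identity(self, default_table):
        profile = profile_condition(default_table, ConditionLevel("pH", 6.5), seed=0)
        agg = aggregate_importance([profile])
        assert agg.order == profile.ranking.order
        assert agg.times_retained["Vimentin MFI"] == (
            "Vimentin MFI" in profile.ranking.retained
        )

    def test_retained_counts_bounded_by_level_count(self, default_table):
        profiles = run_all_conditions(default_table, seed=0)
        agg = aggregate_importance(profiles)
        assert all(0 <= v <= len(profiles) for v in agg.times_retained.values())

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            aggregate_importance([])


class TestRetainedSetMonotonicity:
    def test_retained_size_monotone_in_effect_scale(self):
        """Scaling all planted effects by 0 / 0.5 / 1 produces a monotone
        non-decreasing total retained-set size (averaged over seeds)."""
        sizes = []
        for scale in (0.0, 0.5, 1.0):
            total = 0
            for seed in range(5):
                cfg = SyntheticConfig(
                    seed=seed,
                    effect_size={
                        "high": 4.0 * scale, "moderate": 2.5 * scale, "low": 0.0,
                    },
                )
                profiles = run_all_conditions(generate_dataset(cfg), seed=seed)
                total += sum(len(p.ranking.retained) for p in profiles)
            sizes.append(total)
        assert sizes[0] <= sizes[1] <= sizes[2]
        assert sizes[2] > sizes[0]


class TestIntraphenotype:
    def test_two_regimes_recovered_for_both_lines(self, default_table):
        for line in ("invasive", "noninvasive"):
            res = intraphenotype_behaviors(default_table, line, seed=0)
            assert res.k_star == 2

    def test_assignments_frame_joins_environment_metadata(self, default_table):
        res = intraphenotype_behaviors(default_table, "invasive", seed=0)
        assert len(res.assignments_frame) == 36
        assert {"env_id", "pH", "perfusion", "cluster"} <= set(
            res.assignments_frame.columns
        )

    def test_clusters_track_stress_environments(self, default_table):
        """The recovered bipartition should essentially separate stress
        (pH 6.5 or dynamic) from baseline environments."""
        res = intraphenotype_behaviors(default_table, "invasive", seed=0)
        frame = res.assignments_frame
        stress = (frame["pH"] == 6.5) | (frame["perfusion"] == "dynamic")
        _, cm = align_clusters(
            frame["cluster"].to_numpy(), stress.astype(int).to_numpy()
        )
        assert cm.accuracy >= 0.9

    def test_null_design_flagged_low_confidence(self):
        cfg = SyntheticConfig(
            seed=0,
            effect_size={"high": 0.0, "moderate": 0.0, "low": 0.0},
            env_response={},
        )
        res = intraphenotype_behaviors(generate_dataset(cfg), "invasive", seed=0)
        assert res.k_star == 2  # minimal-k rule on a flat profile
        assert res.low_confidence

    def test_k_max_two_is_trivial(self, default_table):
        res = intraphenotype_behaviors(default_table, "invasive", k_max=2, seed=0)
        assert res.k_star == 2

    def test_feature_elimination_path_returns_subset(self, default_table):
        res = intraphenotype_behaviors(
            default_table, "invasive", seed=0, eliminate_features=True, restarts=5
        )
        assert set(res.retained_features) <= set(default_table.marker_names)
        assert len(res.retained_features) >= 1
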