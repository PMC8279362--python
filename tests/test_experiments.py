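import numpy as np
import pytest

from ssp_homlab.experiments import (
    ExperimentResult,
    LevelResult,
    PredictorSettings,
    reference_size_interaction,
    run_ladder,
    strategy_check,
    trend_tests,
)
from ssp_homlab.layouts import LayoutSpec, RepeatResult
from ssp_homlab.predictor import EnsembleConfig


def _fabricate(design, ladder_field, levels, measures_per_level):
    """Assemble an ExperimentResult from hand-written per-repeat measures."""
    level_results = []
    for level, per_repeat in zip(levels, measures_per_level):
        keys = per_repeat[0].keys()
        mean = {k: float(np.mean([m[k] for m in per_repeat])) for k in keys}
        sd = {k: float(np.std([m[k] for m in per_repeat], ddof=1)) for k in keys}
        level_results.append(
            LevelResult(
                level=level,
                repeats=RepeatResult(per_repeat=per_repeat, mean=mean, sd=sd),
            )
        )
    return ExperimentResult(
        design=design, ladder_field=ladder_field, levels=levels,
        level_results=level_results,
    )


def _repeats(q3, jitter, n=5, seed=0, **extra):
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        row = {}
        for group in ("train", "test", "independent"):
            row[f"q3_{group}"] = q3[group] + rng.normal(0, jitter)
        row["gap"] = row["q3_train"] - row["q3_independent"]
        row.update(extra)
        out.append(row)
    return out


class TestTrendVerdicts:
    def test_flat_ladder_passes_no_effect_and_fails_trend(self):
        levels = [0.9, 0.6, 0.4, 0.2]
        flat = {"train": 0.62, "test": 0.55, "independent": 0.50}
        per_level = [
            _repeats(flat, jitter=0.004, seed=i) for i, _ in enumerate(levels)
        ]
        fig1 = _fabricate("fig1", "inter_cutoff_train_test", levels, per_level)
        verdicts = trend_tests(fig1)
        assert all(v.passed for v in verdicts.values())

        fig2 = _fabricate("fig2", "inner_cutoff_query", levels, per_level)
        assert not trend_tests(fig2)["inner_query_reduces_overfit"].passed

    def test_monotone_gap_ladder_passes_overfit_verdict(self):
        levels = [0.9, 0.6, 0.4, 0.2]
        per_level = [
            _repeats(
                {"train": 0.60 + g, "test": 0.55, "independent": 0.50},
                jitter=0.003,
                seed=i,
            )
            for i, g in enumerate([0.12, 0.08, 0.05, 0.02])
        ]
        fig2 = _fabricate("fig2", "inner_cutoff_query", levels, per_level)
        verdict = trend_tests(fig2)["inner_query_reduces_overfit"]
        assert verdict.passed
        assert verdict.details["rank_trend"] < 0

    def test_fig4_detects_apparent_accuracy_inflation(self):
        levels = ["All", 0.4, 0.2]
        per_level = [
            _repeats(
                {"train": t, "test": s, "independent": 0.50},
                jitter=0.004,
                seed=i,
            )
            for i, (t, s) in enumerate([(0.68, 0.60), (0.62, 0.55), (0.58, 0.52)])
        ]
        fig4 = _fabricate("fig4", "query_reference_cutoff", levels, per_level)
        verdicts = trend_tests(fig4)
        assert verdicts["query_reference_inflates_train"].passed
        assert verdicts["query_reference_inflates_test"].passed
        assert verdicts["query_reference_no_effect_independent"].passed

    def test_fig5_requires_monotone_entropy_and_positive_correlation(self):
        levels = [1.0, 0.9, 0.6, 0.3]
        entropies = [0.5, 0.7, 0.9, 1.1]
        accs = [0.50, 0.505, 0.51, 0.52]
        per_level = [
            _repeats(
                {"train": 0.6, "test": 0.55, "independent": a},
                jitter=0.003,
                seed=i,
                entropy_overall=e,
            )
            for i, (e, a) in enumerate(zip(entropies, accs))
        ]
        fig5 = _fabricate("fig5", "reference_inner_cutoff", levels, per_level)
        assert trend_tests(fig5)["reference_homology_entropy"].passed

        inverted = _fabricate(
            "fig5",
            "reference_inner_cutoff",
            levels,
            list(reversed(per_level)),
        )
        assert not trend_tests(inverted)["reference_homology_entropy"].passed

    def test_interaction_contrast_detects_faster_gap_growth(self):
        sizes = [250, 500, 1000]

        def ladder(gaps, seed):
            per_level = [
                _repeats(
                    {"train": 0.55 + g, "test": 0.55, "independent": 0.50},
                    jitter=0.002,
                    seed=seed + i,
                )
                for i, g in enumerate(gaps)
            ]
            return _fabricate("fig13", "reference_size", sizes, per_level)

        hi = ladder([0.05, 0.10, 0.16], seed=0)
        lo = ladder([0.02, 0.03, 0.04], seed=10)
        verdict = reference_size_interaction(hi, lo)
        assert verdict.passed
        assert verdict.details["mean_contrast"] > 0
        assert not reference_size_interaction(lo, hi).passed

    def test_insufficient_repeats_rejected(self):
        levels = [0.9, 0.2]
        per_level = [
            _repeats({"train": 0.6, "test": 0.55, "independent": 0.5}, 0.01, n=2)
            for _ in levels
        ]
        result = _fabricate("fig2", "inner_cutoff_query", levels, per_level)
        with pytest.raises(ValueError):
            trend_tests(result)


SMALL_SETTINGS = PredictorSettings(
    ensemble=EnsembleConfig(base_learner="decision-tree", n_members=3)
)


class TestRunLadder:
    def test_degenerate_single_level_is_reproducible(self, mini_universe, mini_pools):
        spec = LayoutSpec(
            reference_size=50, train_size=10, test_size=10, independent_size=5,
            n_repeats=2, seed=21,
        )
        kwargs = dict(
            base_spec=spec, ladder=[0.9], settings=SMALL_SETTINGS, pools=mini_pools
        )
        a = run_ladder("fig1", mini_universe, **kwargs)
        b = run_ladder("fig1", mini_universe, **kwargs)
        assert len(a.level_results) == 1
        assert a.level_results[0].repeats.n_repeats == 2
        assert a.level_results[0].repeats.mean == b.level_results[0].repeats.mean

    def test_result_table_is_plot_ready(self, mini_universe, mini_pools):
        spec = LayoutSpec(
            reference_size=50, train_size=10, test_size=10, independent_size=5,
            n_repeats=2, seed=22,
        )
        res = run_ladder(
            "fig2", mini_universe, base_spec=spec, ladder=[0.9, 0.5],
            settings=SMALL_SETTINGS, pools=mini_pools,
        )
        table = res.table()
        assert set(table.columns) == {
            "design", "level", "measure", "mean", "sd", "n_repeats"
        }
        assert set(table["level"]) == {0.9, 0.5}
        assert "q3_independent" in set(table["measure"])

    def test_unknown_design_rejected(self, mini_universe):
        with pytest.raises(ValueError):
            run_ladder("fig99", mini_universe)


class TestStrategyCheck:
    def test_report_contains_verified_cutoffs_and_is_reproducible(
        self, mini_universe, mini_pools
    ):
        sizes = dict(
            reference_size=25, train_size=6, test_size=6, independent_size=4
        )
        a = strategy_check(
            mini_universe, seed=31, n_repeats=2, settings=SMALL_SETTINGS,
            pools=mini_pools, sizes=sizes,
        )
        b = strategy_check(
            mini_universe, seed=31, n_repeats=2, settings=SMALL_SETTINGS,
            pools=mini_pools, sizes=sizes,
        )
        assert a["cutoffs"]["rigorous"] == 0.3
        assert a["rigorous_gap"] == b["rigorous_gap"]
        assert a["conventional_gap"] == b["conventional_gap"]
        assert len(a["paired_gap_reduction"]) == 2
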