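"""Multinomial downsampling and top-k retrieval evaluation."""

import numpy as np
import pandas as pd
import pytest

from studymatcher.errors import AnalysisError, ConfigError
from studymatcher.io import CountTable
from studymatcher.profiles import ProfileMatrix
from studymatcher.robustness import (
    NoiseConfig,
    compare_metrics,
    downsample_multinomial,
    inject_noise,
    run_noise_benchmark,
    topk_retrieval_eval,
)


class TestNoiseConfig:
    def test_defaults_match_analysis_settings(self):
        cfg = NoiseConfig()
        assert cfg.ratios == (0.1, 0.25, 0.75, 0.9)
        assert cfg.ks == (1, 3, 5, 10, 100)

    def test_bad_ratio_rejected(self):
        with pytest.raises(ConfigError):
            NoiseConfig(ratios=(0.0, 0.5))

    def test_bad_k_rejected(self):
        with pytest.raises(ConfigError):
            NoiseConfig(ks=(0, 3))


class TestDownsample:
    @pytest.mark.parametrize("ratio", [0.1, 0.25, 0.75, 0.9, 1.0])
    def test_total_is_rounded_fraction(self, ratio):
        counts = np.array([100, 250, 37, 613])
        out = downsample_multinomial(counts, ratio, seed=0)
        assert out.sum() == round(ratio * counts.sum())

    def test_vanishing_ratio_gives_zero_vector(self):
        out = downsample_multinomial(np.array([1, 1]), ratio=0.1, seed=0)
        assert out.sum() == 0

    def test_zero_total_rejected(self):
        with pytest.raises(AnalysisError):
            downsample_multinomial(np.array([0, 0]), 0.5, seed=0)

    def test_ratio_out_of_range_rejected(self):
        with pytest.raises(ConfigError):
            downsample_multinomial(np.array([5, 5]), 1.5, seed=0)

    def test_expected_counts_match_multinomial_mean(self):
        """(6,4) at ratio 0.5 over 10,000 replicates -> mean ~ (3,2)."""
        counts = np.array([6, 4])
        rng = np.random.default_rng(123)
        reps = np.stack(
            [downsample_multinomial(counts, 0.5, rng) for _ in range(10_000)]
        )
        mean = reps.mean(axis=0)
        # SE of a Binomial(5, p) mean over 10,000 replicates
        p = counts / counts.sum()
        se = np.sqrt(5 * p * (1 - p)) / np.sqrt(10_000)
        assert np.all(np.abs(mean - np.array([3.0, 2.0])) < 3 * se)

    def test_relative_abundances_preserved_in_expectation(self):
        counts = np.array([500, 300, 150, 50])
        p = counts / counts.sum()
        rng = np.random.default_rng(7)
        reps = np.stack(
            [downsample_multinomial(counts, 0.25, rng) for _ in range(10_000)]
        )
        rel = reps / reps.sum(axis=1, keepdims=True)
        se = np.sqrt(p * (1 - p) / 250) / np.sqrt(10_000)
        assert np.all(np.abs(rel.mean(axis=0) - p) < 3 * se + 1e-3)


def _count_table(n_samples=20, n_features=10, depth=1000, seed=0):
    rng = np.random.default_rng(seed)
    records = []
    for s in range(n_samples):
        p = rng.dirichlet(np.ones(n_features))
        counts = rng.multinomial(depth, p)
        records.extend(
            (f"f{f}", f"s{s:02d}", int(c)) for f, c in enumerate(counts) if c
        )
    return CountTable.from_records(records)


class TestInjectNoise:
    def test_ratio_controls_affected_fraction(self):
        table = _count_table(n_samples=40)
        cfg = NoiseConfig(subset_size=40, seed=5)
        noisy, affected = inject_noise(table, cfg, ratio=0.25)
        assert len(affected) == 10  # floor(0.25 * 40)
        totals = noisy.sample_totals()
        originals = table.sample_totals()
        for sid in affected:
            assert totals[sid] == round(0.25 * originals[sid])
        for sid in set(table.samples) - set(affected):
            assert totals[sid] == originals[sid]

    def test_tiny_ratio_leaves_input_unchanged(self):
        table = _count_table(n_samples=5)
        cfg = NoiseConfig(subset_size=5, seed=5)
        noisy, affected = inject_noise(table, cfg, ratio=0.1)  # floor(0.5)=0
        assert affected == []
        assert noisy == table

    def test_same_seed_reproduces_everything(self):
        table = _count_table()
        cfg = NoiseConfig(subset_size=10, seed=9)
        out1 = inject_noise(table, cfg, 0.5)
        out2 = inject_noise(table, cfg, 0.5)
        assert out1[1] == out2[1]
        assert out1[0] == out2[0]


class TestTopkRetrieval:
    def test_exact_copies_score_perfectly(self):
        table = _count_table(n_samples=12)
        profiles = ProfileMatrix.from_counts(table)
        for metric in ("cosine", "euclidean", "jsd"):
            report = topk_retrieval_eval(
                profiles, profiles, profiles.samples, metric, ks=(1, 3)
            )
            assert (report["percent"] == 100.0).all()

    def test_rank_bookkeeping_on_three_sample_fixture(self):
        # candidates: the query's true original is only the 2nd-best match
        originals = ProfileMatrix(
            pd.DataFrame(
                {"a": [1.0, 0.0], "b": [0.6, 0.4], "c": [0.0, 1.0]},
                index=["f1", "f2"],
            )
        )
        query = ProfileMatrix(
            pd.DataFrame({"b": [0.95, 0.05]}, index=["f1", "f2"])
        )
        report = topk_retrieval_eval(originals, query, ["b"], "cosine", ks=(1, 3))
        by_k = report.set_index("k")["percent"]
        assert by_k[1] == 0.0 and by_k[3] == 100.0

    def test_percentages_non_decreasing_in_k(self):
        table = _count_table(n_samples=30, depth=200, seed=3)
        cfg = NoiseConfig(subset_size=30, seed=3)
        noisy, affected = inject_noise(table, cfg, 0.5)
        original = ProfileMatrix.from_counts(table)
        noisy_p = ProfileMatrix.from_counts(noisy.restrict_samples(affected))
        for metric in ("cosine", "euclidean", "jsd"):
            report = topk_retrieval_eval(
                original, noisy_p, affected, metric, ks=(1, 2, 3, 5, 10)
            )
            assert report["percent"].is_monotonic_increasing

    def test_missing_query_rejected(self):
        profiles = ProfileMatrix.from_counts(_count_table(n_samples=3))
        with pytest.raises(AnalysisError, match="missing"):
            topk_retrieval_eval(profiles, profiles, ["ghost"], "cosine", (1,))


class TestCompareMetrics:
    def test_single_metric_wins(self):
        table = _count_table(n_samples=15)
        report = run_noise_benchmark(
            table, NoiseConfig(subset_size=15, seed=2, ratios=(0.5,)), metrics=("cosine",)
        )
        _ranked, winner, tie = compare_metrics(report)
        assert winner == "cosine" and not tie

    def test_all_tied_reports_lexicographic_winner_with_flag(self):
        report = pd.DataFrame(
            {
                "metric": ["cosine", "euclidean", "jsd"],
                "ratio": [0.5] * 3,
                "k": [3] * 3,
                "hits": [10] * 3,
                "queries": [10] * 3,
                "percent": [100.0] * 3,
            }
        )
        ranked, winner, tie = compare_metrics(report)
        assert winner == "cosine" and tie
        assert list(ranked.sort_values("rank")["metric"]) == [
            "cosine",
            "euclidean",
            "jsd",
        ]

    def test_benchmark_report_is_complete_grid(self):
        table = _count_table(n_samples=25, depth=400)
        cfg = NoiseConfig(subset_size=25, seed=4, ratios=(0.25, 0.75), ks=(1, 3))
        report = run_noise_benchmark(table, cfg)
        assert len(report) == 3 * 2 * 2  # metrics x ratios x ks
        assert set(report["metric"]) == {"cosine", "euclidean", "jsd"}
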