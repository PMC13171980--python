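"""Noise-injection robustness benchmark.

Noise emulates reduced sequencing depth: a seeded fraction of samples has
its counts resampled from a multinomial at a scaled-down total, with cell
probabilities equal to the original relative abundances.  The same ratio r
controls both the fraction of affected samples and the depth factor —
r = 0.25 downsamples 25% of the samples to 25% of their original depth.
Each noisy sample is then used as a query against all original profiles in
the evaluation subset, and a metric is scored by how often the true
original ranks within the top-k most similar candidates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AnalysisError, ConfigError
from .io import CountTable
from .profiles import ProfileMatrix
from .similarity import METRICS

DEFAULT_RATIOS = (0.1, 0.25, 0.75, 0.9)
DEFAULT_KS = (1, 3, 5, 10, 100)


@dataclass(frozen=True)
class NoiseConfig:
    """Benchmark configuration.

    ``ratios`` are the downsampling ratios (fraction affected = depth
    factor); ``subset_size`` caps how many samples form the evaluation
    subset; ``ks`` are the top-k levels reported.
    """

    ratios: tuple[float, ...] = DEFAULT_RATIOS
    subset_size: int = 200
    seed: int = 0
    ks: tuple[int, ...] = DEFAULT_KS

    def __post_init__(self):
        ratios = tuple(sorted(self.ratios))
        if any(not 0.0 < r <= 1.0 for r in ratios):
            raise ConfigError(f"ratios must lie in (0, 1]: {self.ratios}")
        object.__setattr__(self, "ratios", ratios)
        ks = tuple(sorted(self.ks))
        if any(k < 1 for k in ks):
            raise ConfigError(f"ks must be positive: {self.ks}")
        object.__setattr__(self, "ks", ks)
        if self.subset_size < 1:
            raise ConfigError("subset_size must be >= 1")


def downsample_multinomial(
    counts: np.ndarray, ratio: float, seed: int | np.random.Generator
) -> np.ndarray:
    """Resample a count vector at total' = round(ratio * total).

    Cell probabilities are the original relative abundances, so expected
    relative abundances are preserved while per-cell counts acquire
    realistic sampling noise.  ``round(ratio * total) == 0`` yields the
    all-zero vector (a degenerate but well-defined boundary).
    """
    if not 0.0 < ratio <= 1.0:
        raise ConfigError(f"ratio must lie in (0, 1], got {ratio}")
    counts = np.asarray(counts, dtype=np.int64)
    if (counts < 0).any():
        raise AnalysisError("counts must be nonnegative")
    total = int(counts.sum())
    if total == 0:
        raise AnalysisError("cannot downsample a zero-total count vector")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    new_total = int(round(ratio * total))
    if new_total == 0:
        return np.zeros_like(counts)
    return rng.multinomial(new_total, counts / total)


def inject_noise(
    table: CountTable, config: NoiseConfig, ratio: float
) -> tuple[CountTable, list[str]]:
    """Downsample a seeded random share of the evaluation subset.

    The evaluation subset is a uniform random choice of
    ``config.subset_size`` samples (or all samples when fewer exist); of
    those, floor(ratio x subset) are downsampled at depth factor = ratio
    and the rest are copied unchanged.  Returns the subset's noisy table
    and the sorted list of affected sample ids.
    """
    if not 0.0 < ratio <= 1.0:
        raise ConfigError(f"ratio must lie in (0, 1], got {ratio}")
    rng = np.random.default_rng(config.seed)
    samples = table.samples
    if config.subset_size > len(samples):
        subset = list(samples)
    else:
        subset = sorted(rng.choice(samples, size=config.subset_size, replace=False))
    n_affected = int(np.floor(ratio * len(subset)))
    affected = sorted(rng.choice(subset, size=n_affected, replace=False))
    sub_table = table.restrict_samples(subset)
    wide = sub_table.to_wide()
    for sid in affected:
        wide[sid] = downsample_multinomial(wide[sid].to_numpy(), ratio, rng)
    long = (
        wide.reset_index()
        .melt(id_vars="feature_id", var_name="sample_id", value_name="count")
    )
    long = long[long["count"] > 0]
    return CountTable(long, validate=False), affected


def _scores_vs_originals(
    original: ProfileMatrix, queries: ProfileMatrix, metric: str
) -> tuple[np.ndarray, bool]:
    """Score queries (rows) against all originals (columns).

    Returns the score grid and whether higher scores mean more similar
    (native metric orientation; rankings never depend on a transform).
    """
    aligned = queries.align_features(original.features)
    combined_ids = original.samples + [f"__q__{s}" for s in aligned.samples]
    X = np.vstack([original.matrix(), aligned.matrix()])
    n = original.n_samples
    if metric == "cosine":
        from sklearn.metrics.pairwise import cosine_similarity as _sk_cosine

        grid = _sk_cosine(X[n:], X[:n])
        return grid, True
    from scipy.spatial.distance import cdist

    if metric == "euclidean":
        return cdist(X[n:], X[:n], "euclidean"), False
    if metric == "jsd":
        return cdist(X[n:], X[:n], "jensenshannon") ** 2 / np.log(2), False
    raise AnalysisError(f"unknown metric {metric!r}")


def topk_retrieval_eval(
    original: ProfileMatrix,
    noisy: ProfileMatrix,
    affected: list[str],
    metric: str,
    ks: tuple[int, ...] = DEFAULT_KS,
) -> pd.DataFrame:
    """Rank each noisy query against all originals; report top-k hit rates.

    Rank of a query = 1 + number of candidate originals scoring strictly
    better than the true original (optimistic tie handling: ties share the
    better rank).  A query is a top-k hit iff its rank <= k.
    """
    missing = sorted(set(affected) - set(original.samples))
    if missing:
        raise AnalysisError(f"query id(s) missing from originals: {missing[:5]}")
    queries = noisy.subset_samples(affected)
    order = queries.samples
    grid, higher_better = _scores_vs_originals(original, queries, metric)
    orig_index = {s: i for i, s in enumerate(original.samples)}
    ranks = []
    for qi, sid in enumerate(order):
        scores = grid[qi]
        true_score = scores[orig_index[sid]]
        better = (
            (scores > true_score) if higher_better else (scores < true_score)
        )
        ranks.append(1 + int(better.sum()))
    ranks = np.asarray(ranks)
    rows = [
        {
            "metric": metric,
            "k": k,
            "hits": int((ranks <= k).sum()),
            "queries": len(ranks),
            "percent": 100.0 * float((ranks <= k).mean()) if len(ranks) else 0.0,
        }
        for k in ks
    ]
    return pd.DataFrame(rows)


def run_noise_benchmark(
    table: CountTable,
    config: NoiseConfig,
    metrics: tuple[str, ...] = METRICS,
) -> pd.DataFrame:
    """Full benchmark: per (metric, ratio, k), the top-k retrieval percent.

    All metrics are evaluated against the same noisy realization per ratio,
    so differences reflect the metrics rather than sampling luck.
    """
    rows = []
    for ratio in config.ratios:
        noisy_table, affected = inject_noise(table, config, ratio)
        if not affected:
            continue
        subset_ids = noisy_table.samples
        original = ProfileMatrix.from_counts(table.restrict_samples(subset_ids))
        nonzero_affected = [
            s for s in affected if s in noisy_table.samples
        ]  # drop degenerate zero-total downsamples
        noisy_profiles = ProfileMatrix.from_counts(
            noisy_table.restrict_samples(nonzero_affected)
        )
        for metric in metrics:
            report = topk_retrieval_eval(
                original, noisy_profiles, nonzero_affected, metric, config.ks
            )
            report.insert(1, "ratio", ratio)
            rows.append(report)
    if not rows:
        raise AnalysisError("no queries generated; increase subset or ratios")
    return pd.concat(rows, ignore_index=True)


def compare_metrics(report: pd.DataFrame) -> tuple[pd.DataFrame, str, bool]:
    """Rank metrics within every (ratio, k) cell and name an overall winner.

    Within a cell, metrics are ordered by descending top-k percent, ties
    broken lexicographically by metric name; the overall winner minimizes
    the mean rank.  Returns (per-cell ranking table, winner, tie flag).
    """
    if report.empty:
        raise AnalysisError("empty retrieval report")
    ranked = report.copy()
    if "ratio" not in ranked.columns:
        ranked["ratio"] = 1.0
    # competition ranking: equal percentages share the better rank
    ranked["rank"] = (
        ranked.groupby(["ratio", "k"])["percent"]
        .rank(ascending=False, method="min")
        .astype(int)
    )
    ranked = ranked.sort_values(
        ["ratio", "k", "rank", "metric"]
    ).reset_index(drop=True)
    means = ranked.groupby("metric")["rank"].mean().sort_index()
    best = means.min()
    winners = sorted(means[means == best].index)
    return ranked, winners[0], len(winners) > 1
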