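"""Group comparison of similarity distributions across relatedness levels.

Study-pair similarities (taxonomic and functional) are grouped by the
text-derived relatedness category of each pair.  A Kruskal–Wallis test
asks whether any of the four category distributions differs; three
one-vs-rest Mann–Whitney U tests per similarity type and run (high vs
medium&low, medium vs high&low, low vs high&medium — "none" excluded
because its far larger size would dominate pooled comparisons) localize
the differences; and all raw p-values are corrected jointly with the
Benjamini–Hochberg step-up FDR procedure.  A long-format export of
(pair, category, similarity) values backs violin-plot summaries,
optionally restricted to study pairs within one biome-lineage prefix.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .aggregate import StudySimilarityMatrix
from .errors import AnalysisError
from .io import StudyCatalog
from .relatedness import CATEGORIES, RelatednessVerdict

#: categories compared one-vs-rest (ordered); "none" is excluded
POSTHOC_CATEGORIES = ("high", "medium", "low")


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Rank-based H statistic (tie-corrected) and chi-square p-value."""
    if len(groups) < 2:
        raise AnalysisError("Kruskal-Wallis needs at least 2 groups")
    if any(len(g) == 0 for g in groups):
        raise AnalysisError("Kruskal-Wallis groups must be nonempty")
    if sum(len(g) for g in groups) < 5:
        raise AnalysisError("Kruskal-Wallis needs a total of at least 5 values")
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def mannwhitney_one_vs_rest(
    values_by_category: Mapping[str, Sequence[float]],
) -> list[dict]:
    """Two-sided Mann–Whitney U of each post-hoc category vs the pooled rest.

    Exactly three records are produced (high, medium, low), each comparing
    the category's values against the other two categories combined; the
    "none" category never enters.  scipy's exact method is used for small
    tie-free samples and the tie-corrected normal approximation otherwise.
    """
    for cat in POSTHOC_CATEGORIES:
        if not len(values_by_category.get(cat, [])):
            raise AnalysisError(f"category {cat!r} has no values")
    records = []
    for cat in POSTHOC_CATEGORIES:
        target = np.asarray(values_by_category[cat], dtype=float)
        rest = np.concatenate(
            [
                np.asarray(values_by_category[other], dtype=float)
                for other in POSTHOC_CATEGORIES
                if other != cat
            ]
        )
        u, p = sps.mannwhitneyu(target, rest, alternative="two-sided", method="auto")
        records.append(
            {
                "category": cat,
                "n_target": len(target),
                "n_rest": len(rest),
                "U": float(u),
                "p": float(p),
            }
        )
    return records


def benjamini_hochberg(pvalues: Sequence[float]) -> list[float]:
    """Step-up FDR adjustment, order-preserving, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if len(p) == 0:
        return []
    if ((p < 0) | (p > 1)).any():
        raise AnalysisError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def pairs_by_category(
    study_sims: StudySimilarityMatrix,
    verdicts: list[RelatednessVerdict],
    run: int | None = None,
) -> dict[str, list[float]]:
    """Similarity values grouped by relatedness category.

    ``run=None`` groups by the majority-vote final category; ``run=r``
    (1-based) groups by that run's raw category.  Verdict pairs missing
    from the matrix are skipped.
    """
    present = set(study_sims.ids)
    grouped: dict[str, list[float]] = {c: [] for c in CATEGORIES}
    for v in verdicts:
        if v.study_a not in present or v.study_b not in present:
            continue
        if run is None:
            cat = v.final
        else:
            cat = v.per_run[run - 1] if len(v.per_run) >= run else None
        if cat is None:
            continue
        grouped[cat].append(study_sims.value(v.study_a, v.study_b))
    return grouped


def full_stats_report(
    study_sims_by_type: Mapping[str, StudySimilarityMatrix],
    verdicts: list[RelatednessVerdict],
    runs: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Kruskal–Wallis + one-vs-rest tests per similarity type and run.

    Returns (kruskal table, post-hoc table).  The post-hoc table holds
    3 tests x ``runs`` x len(types) rows; Benjamini–Hochberg adjustment is
    applied jointly across all of them.
    """
    kw_rows = []
    mw_rows = []
    for sim_type, matrix in sorted(study_sims_by_type.items()):
        for run in range(1, runs + 1):
            grouped = pairs_by_category(matrix, verdicts, run=run)
            nonempty = [grouped[c] for c in CATEGORIES if grouped[c]]
            h, p = kruskal_wallis(nonempty)
            kw_rows.append(
                {
                    "similarity_type": sim_type,
                    "run": run,
                    "H": h,
                    "p": p,
                    "n_groups": len(nonempty),
                }
            )
            for rec in mannwhitney_one_vs_rest(grouped):
                mw_rows.append({"similarity_type": sim_type, "run": run, **rec})
    mw = pd.DataFrame(mw_rows)
    mw["p_adj"] = benjamini_hochberg(mw["p"].tolist())
    return pd.DataFrame(kw_rows), mw


def violin_export(
    study_sims_by_type: Mapping[str, StudySimilarityMatrix],
    verdicts: list[RelatednessVerdict],
    catalog: StudyCatalog | None = None,
    biome_prefix: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format similarity values by category, plus summary quartiles.

    When ``biome_prefix`` is given (colon-delimited lineage prefix), only
    pairs whose two studies both carry a lineage starting with the prefix
    are retained; this requires ``catalog`` for the lineage strings.
    Returns (long table, per-category summary with n/median/q1/q3).
    """
    if biome_prefix is not None and catalog is None:
        raise AnalysisError("biome stratification requires the study catalog")
    rows = []
    dropped = 0
    for sim_type, matrix in sorted(study_sims_by_type.items()):
        present = set(matrix.ids)
        for v in verdicts:
            if v.final is None:
                continue
            if v.study_a not in present or v.study_b not in present:
                dropped += 1
                continue
            if biome_prefix is not None:
                ok = all(
                    catalog[s].biome.startswith(biome_prefix)
                    for s in (v.study_a, v.study_b)
                )
                if not ok:
                    continue
            rows.append(
                {
                    "study_a": v.study_a,
                    "study_b": v.study_b,
                    "category": v.final,
                    "similarity": matrix.value(v.study_a, v.study_b),
                    "similarity_type": sim_type,
                }
            )
    long = pd.DataFrame(
        rows, columns=["study_a", "study_b", "category", "similarity", "similarity_type"]
    )
    if long.empty:
        raise AnalysisError("no verdict pair is present in the similarity matrices")
    long.attrs["dropped_pairs"] = dropped
    summary = (
        long.groupby(["similarity_type", "category"])["similarity"]
        .agg(
            n="count",
            median="median",
            q1=lambda s: float(np.quantile(s, 0.25)),
            q3=lambda s: float(np.quantile(s, 0.75)),
        )
        .reset_index()
    )
    return long, summary


def violin_plot(long: pd.DataFrame, path: str | Path) -> None:
    """Render violin plots of similarity by category (one panel per type).

    Thin presentation layer: purple violins for functional similarity,
    green for taxonomic, matching the palette conventions of the analysis.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import seaborn as sns

    types = sorted(long["similarity_type"].unique())
    palette = {"functional": "#7b4fa6", "taxonomic": "#3e8e5a"}
    order = [c for c in ("high", "medium", "low", "none") if c in set(long["category"])]
    fig, axes = plt.subplots(1, len(types), figsize=(5 * len(types), 4), squeeze=False)
    for ax, sim_type in zip(axes[0], types):
        sub = long[long["similarity_type"] == sim_type]
        sns.violinplot(
            data=sub,
            x="category",
            y="similarity",
            order=order,
            color=palette.get(sim_type, "#888888"),
            cut=0,
            inner="quartile",
            ax=ax,
        )
        ax.set_title(f"{sim_type} similarity")
        ax.set_ylim(0, 1)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
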