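"""Functional (GO term) profile pipeline.

Workflow: propagate raw term counts up the is-a hierarchy so every ancestor
accumulates the reads of its descendants ("backtracking", with set
semantics — a descendant's count reaches each distinct ancestor exactly
once regardless of how many paths connect them); compute local (within
sample) and global (across samples) term frequencies; remove ubiquitous
terms (global frequency > 0.75) and per-sample noise records (local
frequency < 0.01); rank the surviving terms by a TF-IDF score that favors
terms abundant where they occur yet rare across the dataset; greedily prune
the ranking so no retained term is a descendant of an earlier-retained one
(the curated "CCMRI Set-of-GO-terms"); and normalize the counts restricted
to that set into relative-abundance profiles.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd

from .errors import AnalysisError, ConfigError
from .io import CountTable, OntologyDAG
from .profiles import ProfileMatrix

logger = logging.getLogger(__name__)

DEFAULT_GLOBAL_MAX = 0.75
DEFAULT_LOCAL_MIN = 0.01


@dataclass(frozen=True)
class FrequencyTable:
    """Local and global term frequencies over one count table.

    ``local`` maps (feature_id, sample_id) records to the fraction of the
    sample's reads assigned to the term; ``global_freq`` maps each term to
    the fraction of samples in which it appears at all; ``n_samples`` is the
    denominator of the global frequency.
    """

    local: pd.DataFrame  # columns feature_id, sample_id, local_freq
    global_freq: pd.Series  # index feature_id
    n_samples: int


@dataclass(frozen=True)
class TfIdfScore:
    term_id: str
    tf: float
    idf: float

    @property
    def score(self) -> float:
        return self.tf * self.idf


def backtrack_counts(table: CountTable, dag: OntologyDAG) -> CountTable:
    """Propagate counts from each term to all of its distinct ancestors.

    Output count of (term t, sample s) = raw count of t in s plus the raw
    counts of every proper descendant of t in s.  Set semantics: in a
    diamond-shaped hierarchy a leaf's count reaches the shared ancestor
    once, not once per path.
    """
    unknown = sorted(set(table.df["feature_id"]) - set(dag.graph.nodes))
    if unknown:
        raise AnalysisError(f"terms not in the ontology: {unknown[:10]}")
    if len(table) == 0:
        return table
    rows = []
    for term in table.df["feature_id"].unique():
        targets = [term, *dag.ancestors(term)]
        rows.extend((term, target) for target in targets)
    expansion = pd.DataFrame(rows, columns=["feature_id", "target"])
    merged = table.df.merge(expansion, on="feature_id")
    out = (
        merged.groupby(["target", "sample_id"], as_index=False)["count"]
        .sum()
        .rename(columns={"target": "feature_id"})
    )
    return CountTable(out, validate=False)


def compute_frequencies(table: CountTable) -> FrequencyTable:
    """Local and global frequencies of every (term, sample) record."""
    if len(table) == 0:
        raise AnalysisError("cannot compute frequencies of an empty table")
    df = table.df
    totals = df.groupby("sample_id")["count"].transform("sum")
    if (totals == 0).any():
        raise AnalysisError("sample with zero total count")
    local = df.assign(local_freq=df["count"] / totals)[
        ["feature_id", "sample_id", "local_freq"]
    ]
    n_samples = df["sample_id"].nunique()
    global_freq = df.groupby("feature_id")["sample_id"].nunique() / n_samples
    return FrequencyTable(local=local, global_freq=global_freq, n_samples=n_samples)


def frequency_filter(
    table: CountTable,
    freqs: FrequencyTable,
    global_max: float = DEFAULT_GLOBAL_MAX,
    local_min: float = DEFAULT_LOCAL_MIN,
) -> CountTable:
    """Dual-threshold filter on term frequencies.

    Terms whose global frequency exceeds ``global_max`` are removed from
    every sample (overly generic, broadly distributed functions); remaining
    records whose local frequency falls below ``local_min`` are removed from
    that sample only (within-sample noise).  Both comparisons are strict, so
    boundary values survive.
    """
    for name, value in (("global_max", global_max), ("local_min", local_min)):
        if not 0.0 <= value <= 1.0:
            raise ConfigError(f"{name} must lie in [0, 1], got {value}")
    ubiquitous = set(freqs.global_freq[freqs.global_freq > global_max].index)
    df = table.df[~table.df["feature_id"].isin(ubiquitous)]
    df = df.merge(freqs.local, on=["feature_id", "sample_id"], how="left")
    df = df[df["local_freq"].fillna(0.0) >= local_min]
    return CountTable(df[["feature_id", "sample_id", "count"]], validate=False)


def tfidf_scores(table: CountTable, freqs: FrequencyTable) -> list[TfIdfScore]:
    """Score each term by mean local frequency x ln(N / n_term).

    TF is the term's local frequency averaged over the samples where it
    occurs in ``table``; IDF is the natural log of the total sample count
    over the number of samples containing the term.  The returned list is
    sorted by descending score, ties broken lexicographically by term id.
    """
    if freqs.n_samples == 0:
        raise AnalysisError("no samples to score")
    if len(table) == 0:
        return []
    df = table.df.merge(freqs.local, on=["feature_id", "sample_id"], how="left")
    if df["local_freq"].isna().any():
        raise AnalysisError("frequencies do not cover the table being scored")
    grouped = df.groupby("feature_id").agg(
        tf=("local_freq", "mean"), n_present=("sample_id", "nunique")
    )
    scores = [
        TfIdfScore(
            term_id=term,
            tf=float(row["tf"]),
            idf=math.log(freqs.n_samples / row["n_present"]),
        )
        for term, row in grouped.iterrows()
    ]
    return sorted(scores, key=lambda s: (-s.score, s.term_id))


def hierarchical_prune(
    ranked: list[TfIdfScore] | list[str], dag: OntologyDAG
) -> list[str]:
    """Greedy hierarchy-aware pruning over a ranked term list.

    Scanning in rank order, a term is retained iff it is hierarchically
    unrelated to every already-retained term: its descendants (more
    specific terms) are removed from further consideration, and a term
    that is itself an ancestor of a retained term is likewise redundant —
    it nests the same signal at a coarser level.  The result (the curated
    "CCMRI Set-of-GO-terms") therefore never contains a term together with
    one of its proper descendants.
    """
    kept: list[str] = []
    kept_set: set[str] = set()
    for item in ranked:
        term = item.term_id if isinstance(item, TfIdfScore) else item
        if kept_set & (dag.ancestors(term) | dag.descendants(term)):
            continue
        kept.append(term)
        kept_set.add(term)
    return kept


def build_functional_profiles(
    table: CountTable, ccmri: set[str] | list[str]
) -> ProfileMatrix:
    """Restrict counts to the curated term set and normalize per sample.

    Samples that retain no curated term are dropped with a logged warning
    rather than raising — they simply carry no usable functional signal.
    """
    ccmri = set(ccmri)
    if not ccmri:
        raise AnalysisError("curated term set is empty")
    restricted = table.restrict_features(ccmri)
    lost = sorted(set(table.samples) - set(restricted.samples))
    if lost:
        logger.warning(
            "%d sample(s) retain no curated term and were dropped: %s",
            len(lost),
            lost[:5],
        )
    return ProfileMatrix.from_counts(restricted)


def run_functional_pipeline(
    table: CountTable,
    dag: OntologyDAG,
    global_max: float = DEFAULT_GLOBAL_MAX,
    local_min: float = DEFAULT_LOCAL_MIN,
) -> tuple[ProfileMatrix, list[str], list[TfIdfScore]]:
    """Backtrack, filter, score, prune, normalize; returns
    (profiles, curated term list, full ranking)."""
    backtracked = backtrack_counts(table, dag)
    freqs = compute_frequencies(backtracked)
    filtered = frequency_filter(backtracked, freqs, global_max, local_min)
    ranking = tfidf_scores(filtered, freqs)
    ccmri = hierarchical_prune(ranking, dag)
    profiles = build_functional_profiles(filtered, ccmri)
    return profiles, ccmri, ranking


def threshold_grid_report(
    table: CountTable,
    dag: OntologyDAG,
    global_maxes: list[float],
    local_mins: list[float],
) -> pd.DataFrame:
    """Comparative accounting of candidate frequency-threshold pairs.

    For each (global_max, local_min) combination, reports how many terms are
    removed for being overly generic (high global frequency), how many
    records for being uninformative (low local frequency), and what remains.
    """
    backtracked = backtrack_counts(table, dag)
    freqs = compute_frequencies(backtracked)
    rows = []
    for gmax in global_maxes:
        for lmin in local_mins:
            filtered = frequency_filter(backtracked, freqs, gmax, lmin)
            n_generic = int((freqs.global_freq > gmax).sum())
            rows.append(
                {
                    "global_max": gmax,
                    "local_min": lmin,
                    "terms_removed_generic": n_generic,
                    "records_removed_low_local": len(backtracked)
                    - len(filtered)
                    - int(
                        backtracked.df["feature_id"]
                        .isin(freqs.global_freq[freqs.global_freq > gmax].index)
                        .sum()
                    ),
                    "remaining_terms": len(filtered.features),
                    "remaining_samples": len(filtered.samples),
                }
            )
    return pd.DataFrame(rows)
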