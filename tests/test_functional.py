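"""GO backtracking, frequency filtering, TF-IDF ranking and pruning."""

import math

import numpy as np
import pytest

from studymatcher.errors import AnalysisError, ConfigError
from studymatcher.functional import (
    backtrack_counts,
    build_functional_profiles,
    compute_frequencies,
    frequency_filter,
    hierarchical_prune,
    run_functional_pipeline,
    tfidf_scores,
)
from studymatcher.io import CountTable, OntologyDAG
from studymatcher.synthetic import generate_ontology


def naive_backtrack(table: CountTable, dag: OntologyDAG) -> dict:
    """Independent oracle: for every (term, sample), sum raw counts of the
    term and all its proper descendants."""
    raw = {
        (r.feature_id, r.sample_id): r.count for r in table.df.itertuples()
    }
    samples = set(table.df["sample_id"])
    out = {}
    for term in dag.terms:
        below = {term} | set(dag.descendants(term))
        for s in samples:
            total = sum(raw.get((d, s), 0) for d in below)
            if total:
                out[(term, s)] = total
    return out


class TestBacktrack:
    def test_chain_propagation(self, chain_dag):
        table = CountTable.from_records([("A", "s", 2), ("B", "s", 5)])
        out = backtrack_counts(table, chain_dag)
        got = {r.feature_id: r.count for r in out.df.itertuples()}
        assert got == {"B": 5, "A": 7, "R": 7}

    def test_diamond_counts_once(self, diamond_dag):
        table = CountTable.from_records([("D", "s", 4)])
        out = backtrack_counts(table, diamond_dag)
        got = {r.feature_id: r.count for r in out.df.itertuples()}
        assert got == {"D": 4, "B": 4, "C": 4, "R": 4}

    def test_root_only_is_identity(self, chain_dag):
        table = CountTable.from_records([("R", "s", 9)])
        assert backtrack_counts(table, chain_dag) == table

    def test_unknown_term_rejected(self, chain_dag):
        table = CountTable.from_records([("MYSTERY", "s", 1)])
        with pytest.raises(AnalysisError, match="MYSTERY"):
            backtrack_counts(table, chain_dag)

    def test_root_conserves_sample_total(self, chain_dag):
        table = CountTable.from_records(
            [("A", "s", 2), ("B", "s", 5), ("R", "s", 1)]
        )
        out = backtrack_counts(table, chain_dag)
        root = out.df[out.df.feature_id == "R"]["count"].iloc[0]
        assert root == table.sample_totals()["s"]

    def test_ancestor_at_least_descendant(self, diamond_dag):
        table = CountTable.from_records([("D", "s", 4), ("B", "s", 2)])
        out = backtrack_counts(table, diamond_dag)
        got = {r.feature_id: r.count for r in out.df.itertuples()}
        for term, count in got.items():
            for anc in diamond_dag.ancestors(term):
                assert got[anc] >= count

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_naive_oracle_on_random_dags(self, seed):
        rng = np.random.default_rng(seed)
        dag = generate_ontology(int(rng.integers(10, 51)), seed)
        terms = dag.terms
        records = []
        for s in range(3):
            chosen = rng.choice(terms, size=min(8, len(terms)), replace=False)
            for t in chosen:
                records.append((t, f"s{s}", int(rng.integers(1, 50))))
        table = CountTable.from_records(records)
        out = backtrack_counts(table, dag)
        got = {
            (r.feature_id, r.sample_id): r.count for r in out.df.itertuples()
        }
        assert got == naive_backtrack(table, dag)


class TestFrequencies:
    def test_global_is_presence_fraction(self):
        table = CountTable.from_records(
            [("t", "s1", 1), ("t", "s2", 1), ("u", "s1", 1), ("u", "s3", 1), ("u", "s4", 1)]
        )
        freqs = compute_frequencies(table)
        assert freqs.n_samples == 4
        assert freqs.global_freq["t"] == pytest.approx(0.5)
        assert freqs.global_freq["u"] == pytest.approx(0.75)

    def test_local_is_within_sample_share(self):
        table = CountTable.from_records([("t1", "s", 9), ("t2", "s", 1)])
        freqs = compute_frequencies(table)
        local = freqs.local.set_index("feature_id")["local_freq"]
        assert local["t1"] == pytest.approx(0.9)

    def test_ubiquitous_terms_have_global_one(self):
        table = CountTable.from_records(
            [(t, s, 1) for t in ("a", "b") for s in ("s1", "s2")]
        )
        freqs = compute_frequencies(table)
        assert (freqs.global_freq == 1.0).all()


class TestFrequencyFilter:
    def _fixture(self):
        # "common" in 4/4 samples; "niche" in 1; "tiny" has low local share
        records = []
        for s in ("s1", "s2", "s3", "s4"):
            records.append(("common", s, 500))
            records.append(("tiny", s, 1))  # local 1/501 < 0.01
        records.append(("niche", "s1", 400))
        table = CountTable.from_records(records)
        return table, compute_frequencies(table)

    def test_high_global_removed_everywhere(self):
        table, freqs = self._fixture()
        out = frequency_filter(table, freqs, global_max=0.75, local_min=0.0)
        assert "common" not in out.features
        assert "niche" in out.features

    def test_low_local_removed_per_sample(self):
        table, freqs = self._fixture()
        out = frequency_filter(table, freqs, global_max=1.0, local_min=0.01)
        assert "tiny" not in out.features  # below threshold in every sample
        assert "common" in out.features

    def test_neutral_thresholds_are_identity(self):
        table, freqs = self._fixture()
        assert frequency_filter(table, freqs, 1.0, 0.0) == table

    def test_thresholds_validated(self):
        table, freqs = self._fixture()
        with pytest.raises(ConfigError):
            frequency_filter(table, freqs, global_max=1.5)


class TestTfIdf:
    def test_direct_formula(self):
        # term in 2 of 10 samples, mean local frequency 0.2
        records = [("t", "s0", 20), ("other", "s0", 80), ("t", "s1", 20), ("other", "s1", 80)]
        records += [("other", f"s{i}", 100) for i in range(2, 10)]
        table = CountTable.from_records(records)
        freqs = compute_frequencies(table)
        scores = {s.term_id: s for s in tfidf_scores(table, freqs)}
        assert scores["t"].tf == pytest.approx(0.2)
        assert scores["t"].idf == pytest.approx(math.log(5))
        assert scores["t"].score == pytest.approx(0.2 * math.log(5))

    def test_everywhere_term_scores_zero(self):
        table = CountTable.from_records(
            [("t", s, 10) for s in ("s1", "s2", "s3")]
        )
        freqs = compute_frequencies(table)
        (score,) = tfidf_scores(table, freqs)
        assert score.idf == 0.0 and score.score == 0.0

    def test_ties_broken_by_term_id(self):
        table = CountTable.from_records(
            [("b", "s1", 5), ("a", "s1", 5), ("b", "s2", 5), ("a", "s2", 5)]
        )
        freqs = compute_frequencies(table)
        ranked = tfidf_scores(table, freqs)
        assert [s.term_id for s in ranked] == ["a", "b"]


def naive_prune(ranked_ids, dag):
    kept = []
    for term in ranked_ids:
        nested = any(
            dag.is_descendant(term, of=k) or dag.is_descendant(k, of=term)
            for k in kept
        )
        if not nested:
            kept.append(term)
    return kept


class TestPrune:
    def test_nested_terms_removed(self, chain_dag):
        # B is a descendant of kept A; R nests A from above; neither survives
        assert hierarchical_prune(["A", "B", "R"], chain_dag) == ["A"]

    def test_descendant_of_kept_removed_unrelated_kept(self):
        dag = OntologyDAG.from_edges(
            ["R", "X", "Y", "Z"], [("X", "R"), ("Y", "X"), ("Z", "R")]
        )
        # ranked X (.9), Y descendant of X (.8), Z unrelated (.7) -> {X, Z}
        assert hierarchical_prune(["X", "Y", "Z"], dag) == ["X", "Z"]

    def test_unrelated_terms_all_kept(self):
        dag = OntologyDAG.from_edges(
            ["R", "X", "Y", "Z"], [("X", "R"), ("Y", "R"), ("Z", "R")]
        )
        assert hierarchical_prune(["X", "Y", "Z"], dag) == ["X", "Y", "Z"]

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_and_is_antichain(self, seed):
        rng = np.random.default_rng(seed)
        dag = generate_ontology(30, seed)
        ranked = list(rng.permutation(dag.terms))[: int(rng.integers(5, 30))]
        kept = hierarchical_prune(ranked, dag)
        assert kept == naive_prune(ranked, dag)
        for a in kept:
            for b in kept:
                if a != b:
                    assert not dag.is_descendant(a, of=b)


class TestBuildProfiles:
    def test_full_term_set_equals_plain_normalization(self, chain_dag):
        table = CountTable.from_records([("A", "s", 1), ("B", "s", 3)])
        profiles = build_functional_profiles(table, {"A", "B"})
        np.testing.assert_allclose(
            profiles.df["s"].sort_index().to_numpy(), [0.25, 0.75]
        )

    def test_sample_without_curated_terms_dropped(self):
        table = CountTable.from_records([("A", "s1", 1), ("B", "s2", 1)])
        profiles = build_functional_profiles(table, {"A"})
        assert profiles.samples == ["s1"]

    def test_empty_curated_set_rejected(self):
        table = CountTable.from_records([("A", "s1", 1)])
        with pytest.raises(AnalysisError):
            build_functional_profiles(table, set())


class TestFullPipeline:
    def test_synthetic_run_produces_antichain(self, synthetic_run):
        dag, ccmri = synthetic_run["dag"], synthetic_run["ccmri"]
        assert len(ccmri) > 0
        for a in ccmri:
            for b in ccmri:
                if a != b:
                    assert not dag.is_descendant(a, of=b)

    def test_profiles_normalized(self, synthetic_run):
        sums = synthetic_run["functional_profiles"].df.sum(axis=0)
        np.testing.assert_allclose(sums.to_numpy(), 1.0, atol=1e-9)
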