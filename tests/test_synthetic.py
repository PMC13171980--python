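"""Synthetic data generator: structure, determinism, controlled relatedness."""

import numpy as np
import pytest

from studymatcher.errors import ConfigError
from studymatcher.io import read_go_table, read_obo, read_study_catalog, read_taxonomy_table
from studymatcher.profiles import ProfileMatrix
from studymatcher.similarity import cosine_similarity
from studymatcher.synthetic import (
    BIOME_LINEAGES,
    GroundTruth,
    SyntheticConfig,
    category_from_depth,
    domain_keywords,
    generate_ontology,
    generate_profiles,
    generate_study_texts,
    write_synthetic_dataset,
)


class TestGenerateOntology:
    def test_minimal_three_terms(self):
        dag = generate_ontology(3, seed=0)
        (root,) = dag.roots()
        assert len(dag) == 3
        assert all(dag.parents(t) == {root} for t in dag.terms if t != root)

    def test_too_few_terms_rejected(self):
        with pytest.raises(ConfigError):
            generate_ontology(2, seed=0)

    @pytest.mark.parametrize("seed", range(5))
    def test_single_root_and_every_node_reaches_it(self, seed):
        dag = generate_ontology(60, seed)
        (root,) = dag.roots()
        for term in dag.terms:
            if term != root:
                assert root in dag.ancestors(term)

    def test_some_terms_have_two_parents(self):
        dag = generate_ontology(120, 0)
        multi = [t for t in dag.terms if len(dag.parents(t)) == 2]
        assert multi  # diamonds exist to exercise set-ancestor semantics

    def test_identical_seed_identical_edges(self):
        e1 = sorted(generate_ontology(50, 1).graph.edges)
        e2 = sorted(generate_ontology(50, 1).graph.edges)
        assert e1 == e2


class TestGenerateProfiles:
    def _small(self, **kw):
        defaults = dict(
            n_biomes=4,
            studies_per_biome=2,
            samples_per_study=3,
            n_genera=40,
            n_go_terms=60,
            sequencing_depth=5000,
            seed=0,
        )
        defaults.update(kw)
        return SyntheticConfig(**defaults)

    def test_sample_totals_equal_depth_exactly(self):
        cfg = self._small()
        dag = generate_ontology(cfg.n_go_terms, cfg.seed)
        taxo, func, _cat, _truth = generate_profiles(cfg, dag)
        assert (taxo.sample_totals() == cfg.sequencing_depth).all()
        assert (func.sample_totals() == cfg.sequencing_depth).all()

    def test_fixed_seed_reproduces_tables(self):
        cfg = self._small()
        dag = generate_ontology(cfg.n_go_terms, cfg.seed)
        a = generate_profiles(cfg, dag)
        b = generate_profiles(cfg, dag)
        assert a[0] == b[0] and a[1] == b[1]

    def test_full_overlap_erases_biome_structure(self):
        cfg = self._small(cross_biome_overlap=1.0, dirichlet_concentration=500)
        dag = generate_ontology(cfg.n_go_terms, cfg.seed)
        taxo, _func, cat, truth = generate_profiles(cfg, dag)
        profiles = ProfileMatrix.from_counts(taxo)
        within, across = self._cosine_groups(profiles, cat, truth)
        # biomes share one base composition: no within/across gap
        assert abs(np.mean(within) - np.mean(across)) < 0.05

    def test_no_overlap_tight_studies_separate_biomes(self):
        cfg = self._small(cross_biome_overlap=0.0, dirichlet_concentration=5e4)
        dag = generate_ontology(cfg.n_go_terms, cfg.seed)
        taxo, _func, cat, truth = generate_profiles(cfg, dag)
        profiles = ProfileMatrix.from_counts(taxo)
        within, across = self._cosine_groups(profiles, cat, truth)
        assert np.mean(within) > np.mean(across)
        assert np.mean(within) > 0.99  # near-identical up to counting noise

    @staticmethod
    def _cosine_groups(profiles, catalog, truth, cap=200):
        rng = np.random.default_rng(0)
        samples = profiles.samples
        owner = {s: catalog.study_of_sample(s) for s in samples}
        within, across = [], []
        pairs = [
            (a, b)
            for i, a in enumerate(samples)
            for b in samples[i + 1 :]
        ]
        rng.shuffle(pairs)
        for a, b in pairs[:cap]:
            sim = cosine_similarity(profiles.vector(a), profiles.vector(b))
            if owner[a] == owner[b]:
                within.append(sim)
            elif truth.biome_of[owner[a]] != truth.biome_of[owner[b]]:
                across.append(sim)
        return within, across

    def test_functional_redundancy_raises_cross_biome_similarity(self):
        """Shared housekeeping core: raw functional profiles of unrelated
        biomes are more alike than their taxonomic profiles."""
        cfg = self._small()
        dag = generate_ontology(cfg.n_go_terms, cfg.seed)
        taxo, func, cat, truth = generate_profiles(cfg, dag)
        tp = ProfileMatrix.from_counts(taxo)
        fp = ProfileMatrix.from_counts(func)
        t_within, t_across = self._cosine_groups(tp, cat, truth)
        f_within, f_across = self._cosine_groups(fp, cat, truth)
        assert np.mean(f_across) > np.mean(t_across)

    def test_shallow_depth_warns(self):
        cfg = self._small(sequencing_depth=100)
        dag = generate_ontology(cfg.n_go_terms, cfg.seed)
        with pytest.warns(UserWarning, match="degenerate"):
            generate_profiles(cfg, dag)

    def test_undersized_dag_rejected(self):
        cfg = self._small()
        dag = generate_ontology(10, 0)
        with pytest.raises(ConfigError):
            generate_profiles(cfg, dag)


class TestGroundTruth:
    @pytest.mark.parametrize(
        "depth, category",
        [(0, "none"), (1, "low"), (2, "medium"), (3, "high"), (4, "high")],
    )
    def test_category_map(self, depth, category):
        assert category_from_depth(depth) == category

    def test_symmetric_and_monotone_in_shared_prefix(self):
        truth = GroundTruth(
            biome_of={
                "A": BIOME_LINEAGES[0],
                "B": BIOME_LINEAGES[1],
                "C": BIOME_LINEAGES[3],
            }
        )
        assert truth.category("A", "B") == truth.category("B", "A") == "medium"
        assert truth.category("A", "C") == "none"

    def test_self_pair_rejected(self):
        truth = GroundTruth(biome_of={"A": BIOME_LINEAGES[0]})
        with pytest.raises(ConfigError):
            truth.category("A", "A")


class TestStudyTexts:
    def _catalog_and_truth(self, seed=0):
        cfg = SyntheticConfig(
            n_biomes=6, studies_per_biome=2, samples_per_study=2,
            n_genera=30, n_go_terms=40, sequencing_depth=2000, seed=seed,
        )
        dag = generate_ontology(cfg.n_go_terms, seed)
        _t, _f, catalog, truth = generate_profiles(cfg, dag)
        return generate_study_texts(catalog, truth, seed), truth

    def test_same_biome_studies_share_keywords(self):
        catalog, truth = self._catalog_and_truth()
        same = [
            s for s in catalog.study_ids
            if truth.biome_of[s] == BIOME_LINEAGES[0]
        ]
        kw = [
            domain_keywords(catalog[s].title + " " + catalog[s].description)
            for s in same[:2]
        ]
        assert len(kw[0] & kw[1]) >= 3

    def test_unrelated_biomes_share_no_domain_keywords(self):
        catalog, truth = self._catalog_and_truth()
        host = next(
            s for s in catalog.study_ids
            if truth.biome_of[s].startswith("root:Host-associated")
        )
        env = next(
            s for s in catalog.study_ids
            if truth.biome_of[s].startswith("root:Environmental")
        )
        kw_host = domain_keywords(
            catalog[host].title + " " + catalog[host].description
        )
        kw_env = domain_keywords(
            catalog[env].title + " " + catalog[env].description
        )
        assert kw_host & kw_env == set()

    def test_fixed_seed_identical_texts(self):
        c1, _ = self._catalog_and_truth(seed=3)
        c2, _ = self._catalog_and_truth(seed=3)
        for sid in c1.study_ids:
            assert c1[sid].description == c2[sid].description


class TestDatasetWriter:
    def test_emitted_files_exercise_the_real_readers(self, tmp_path):
        cfg = SyntheticConfig(
            n_biomes=3, studies_per_biome=2, samples_per_study=2,
            n_genera=30, n_go_terms=40, sequencing_depth=2000, seed=5,
        )
        paths = write_synthetic_dataset(cfg, tmp_path)
        taxo = read_taxonomy_table(paths["taxonomy"])
        go, meta = read_go_table(paths["go"])
        dag = read_obo(paths["obo"])
        catalog = read_study_catalog(paths["catalog"])
        assert taxo.sample_totals().eq(2000).all()
        assert set(go.features) <= set(dag.terms)
        assert len(catalog) == 6
        assert all(meta[t][1] == "biological_process" for t in list(meta)[:5])

    def test_byte_identical_across_runs(self, tmp_path):
        cfg = SyntheticConfig(
            n_biomes=3, studies_per_biome=1, samples_per_study=2,
            n_genera=20, n_go_terms=30, sequencing_depth=1000, seed=9,
        )
        p1 = write_synthetic_dataset(cfg, tmp_path / "a")
        p2 = write_synthetic_dataset(cfg, tmp_path / "b")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes()
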