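"""Shared fixtures: toy ontologies and a full synthetic analysis run."""

from __future__ import annotations

import logging

import pytest

from studymatcher.aggregate import study_similarity
from studymatcher.functional import run_functional_pipeline
from studymatcher.io import OntologyDAG
from studymatcher.relatedness import MockBiomeBackend, classify_pairs
from studymatcher.similarity import all_vs_all, to_similarity
from studymatcher.synthetic import (
    SyntheticConfig,
    generate_ontology,
    generate_profiles,
    generate_study_texts,
)
from studymatcher.taxonomic import run_taxonomic_pipeline

logging.getLogger("studymatcher").setLevel(logging.ERROR)


@pytest.fixture
def chain_dag() -> OntologyDAG:
    """R <- A <- B: a three-term is-a chain."""
    return OntologyDAG.from_edges(["R", "A", "B"], [("B", "A"), ("A", "R")])


@pytest.fixture
def diamond_dag() -> OntologyDAG:
    """D is_a B, D is_a C, B/C is_a R: the classic diamond."""
    return OntologyDAG.from_edges(
        ["R", "B", "C", "D"],
        [("D", "B"), ("D", "C"), ("B", "R"), ("C", "R")],
    )


@pytest.fixture(scope="session")
def synthetic_run():
    """One full default-condition synthetic analysis, seed-pinned.

    Generates studies, runs both profile pipelines, cosine all-vs-all,
    study aggregation and mock-backend relatedness classification; shared
    across tests that interrogate different facets of the same run.
    """
    seed = 1
    config = SyntheticConfig(seed=seed)
    dag = generate_ontology(config.n_go_terms, seed)
    taxo, func, catalog, truth = generate_profiles(config, dag)
    catalog = generate_study_texts(catalog, truth, seed)
    taxo_profiles, accounting = run_taxonomic_pipeline(taxo)
    func_profiles, ccmri, ranking = run_functional_pipeline(func, dag)
    sims = {
        "taxonomic": to_similarity(all_vs_all(taxo_profiles, "cosine")),
        "functional": to_similarity(all_vs_all(func_profiles, "cosine")),
    }
    study_sims = {t: study_similarity(m, catalog) for t, m in sims.items()}
    verdicts = classify_pairs(catalog, MockBiomeBackend(), seed=seed)
    return {
        "config": config,
        "dag": dag,
        "taxonomic_counts": taxo,
        "functional_counts": func,
        "catalog": catalog,
        "truth": truth,
        "taxonomic_profiles": taxo_profiles,
        "functional_profiles": func_profiles,
        "ccmri": ccmri,
        "ranking": ranking,
        "sample_sims": sims,
        "study_sims": study_sims,
        "verdicts": verdicts,
        "accounting": accounting,
    }
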