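"""Synthetic microbiome studies with controlled ground-truth relatedness.

The generator emulates the statistical structure the analysis assumes,
without any download:

* studies are grouped into latent biomes arranged on a hierarchical
  lineage (``root:Environmental:Aquatic:Marine`` style), and genus
  compositions are drawn along that hierarchy, so communities from nearby
  biomes are compositionally closer than communities from distant ones;
* each sample is a Dirichlet-multinomial draw around its study's
  composition at a fixed sequencing depth, the same noise family used by
  the downsampling robustness benchmark;
* functional (GO leaf term) counts are derived from the genus counts
  through one global genus-to-term loading matrix that includes a shared
  housekeeping core, implementing functional redundancy: distinct taxa
  load onto overlapping term sets, so cross-biome functional similarity
  exceeds cross-biome taxonomic similarity by construction;
* study description texts are templated from a per-lineage-token keyword
  vocabulary, so studies of nearby biomes share wording that a
  deterministic mock classifier (and in principle a real language model)
  can pick up.

Ground-truth relatedness of a study pair is mapped from the number of
shared lineage components below the root: 3 or more -> high, 2 -> medium,
1 -> low, 0 -> none — mirroring the category definitions used in the
relatedness prompt.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import (
    CountTable,
    OntologyDAG,
    Study,
    StudyCatalog,
    write_obo,
    write_study_catalog,
)
from .relatedness import shared_lineage_depth

#: template biome lineages; a config uses the first ``n_biomes`` of these
BIOME_LINEAGES = (
    "root:Host-associated:Mammals:Digestive-system",
    "root:Host-associated:Mammals:Skin",
    "root:Host-associated:Birds:Digestive-system",
    "root:Environmental:Aquatic:Marine",
    "root:Environmental:Aquatic:Freshwater",
    "root:Environmental:Terrestrial:Soil",
    "root:Engineered:Wastewater:Activated-sludge",
    "root:Engineered:Food-production:Fermentation",
)

#: fraction of functional signal carried by the shared housekeeping core
_CORE_WEIGHT = 0.30

#: genus-specific leaf terms per genus
_TERMS_PER_GENUS = 2


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; identical seed implies identical outputs."""

    n_biomes: int = 6
    studies_per_biome: int = 2
    samples_per_study: int = 5
    n_genera: int = 60
    n_go_terms: int = 48
    sequencing_depth: int = 20_000
    dirichlet_concentration: float = 60.0
    cross_biome_overlap: float = 0.15
    seed: int = 0

    def __post_init__(self):
        for name in (
            "n_biomes",
            "studies_per_biome",
            "samples_per_study",
            "n_genera",
            "n_go_terms",
            "sequencing_depth",
        ):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if not 0.0 <= self.cross_biome_overlap <= 1.0:
            raise ConfigError("cross_biome_overlap must lie in [0, 1]")
        if self.dirichlet_concentration <= 0:
            raise ConfigError("dirichlet_concentration must be positive")
        if self.n_biomes > len(BIOME_LINEAGES):
            raise ConfigError(
                f"at most {len(BIOME_LINEAGES)} biomes supported"
            )


#: count-filter threshold paired with :func:`retrieval_benchmark_config`:
#: the default 30-read threshold at 20,000-read depth is a 0.15% relative
#: detection limit; 3 reads at the benchmark's 1,500-read depth keeps that
#: limit comparable
BENCHMARK_MIN_READS = 3


def retrieval_benchmark_config(seed: int) -> SyntheticConfig:
    """Study conditions for the noise-injection retrieval benchmark.

    Retrieval is only informative when a sample's nearest neighbors sit at
    distances comparable to downsampling noise, so this preset uses tight
    within-study replication (high Dirichlet concentration), a feature-rich
    genus axis, shallow sequencing depth (downsampled profiles become
    genuinely sparse, which is where metric behavior diverges), and enough
    samples (210) to fill the 200-sample evaluation subset.
    """
    return SyntheticConfig(
        studies_per_biome=5,
        samples_per_study=7,
        n_genera=150,
        dirichlet_concentration=5000.0,
        sequencing_depth=1500,
        seed=seed,
    )


def category_from_depth(depth: int) -> str:
    """Shared-lineage depth below root -> relatedness category."""
    return {0: "none", 1: "low", 2: "medium"}.get(depth, "high")


@dataclass
class GroundTruth:
    """Latent biome per study and derived pairwise relatedness."""

    biome_of: dict[str, str]

    def category(self, study_a: str, study_b: str) -> str:
        if study_a == study_b:
            raise ConfigError("self-pairs have no relatedness category")
        depth = shared_lineage_depth(self.biome_of[study_a], self.biome_of[study_b])
        return category_from_depth(depth)

    def pair_categories(self) -> dict[frozenset, str]:
        ids = sorted(self.biome_of)
        return {
            frozenset((a, b)): self.category(a, b)
            for i, a in enumerate(ids)
            for b in ids[i + 1 :]
        }


def generate_ontology(n_terms: int, seed: int) -> OntologyDAG:
    """Rooted acyclic is-a hierarchy with branch locality.

    The hierarchy is a shallow tree — root, a first level of broad
    branches, a second level of narrower branches, and leaves assigned to
    second-level branches in contiguous runs (so semantically "nearby"
    leaves share mid-level ancestors, as GO siblings do).  Roughly 10% of
    non-root terms receive a second parent from the adjacent branch,
    producing the diamond shapes that exercise set-semantics ancestor
    propagation.  Every non-root term has at least one parent; the result
    is acyclic by construction (edges always point to an earlier level).
    """
    if n_terms < 3:
        raise ConfigError("an ontology needs at least 3 terms")
    rng = np.random.default_rng(seed)
    terms = [f"GO:{i + 1:07d}" for i in range(n_terms)]
    nodes = {
        t: {"name": f"synthetic process {i + 1}", "namespace": "biological_process"}
        for i, t in enumerate(terms)
    }
    edges: list[tuple[str, str]] = []
    root = terms[0]
    rest = terms[1:]
    if len(rest) <= 4:
        level1, level2, leaves = rest, [], []
    else:
        b1 = max(2, round(n_terms / 40))
        b2 = max(2 * b1, round(n_terms / 12))
        if 1 + b1 + b2 >= n_terms:
            b2 = max(0, n_terms - 1 - b1 - 1)
        level1 = rest[:b1]
        level2 = rest[b1 : b1 + b2]
        leaves = rest[b1 + b2 :]
    for t in level1:
        edges.append((t, root))
    for i, t in enumerate(level2):
        primary = level1[i * len(level1) // max(1, len(level2))]
        edges.append((t, primary))
        if rng.random() < 0.10 and len(level1) > 1:
            others = [x for x in level1 if x != primary]
            edges.append((t, others[int(rng.integers(0, len(others)))]))
    for i, t in enumerate(leaves):
        primary = level2[i * len(level2) // max(1, len(leaves))]
        edges.append((t, primary))
        if rng.random() < 0.10 and len(level2) > 1:
            others = [x for x in level2 if x != primary]
            edges.append((t, others[int(rng.integers(0, len(others)))]))
    return OntologyDAG.from_edges(nodes, edges)


def _normalize(v: np.ndarray) -> np.ndarray:
    return v / v.sum()


#: composition weight of each lineage level's genus block in a leaf-biome
#: base composition: (root/cosmopolitan, first level, second level, leaf
#: endemics).  Comparable weights per level keep every level's signal well
#: above the detection thresholds of the downstream frequency filters.
_LEVEL_WEIGHTS = (0.20, 0.25, 0.25, 0.30)


def _path_weights(depth: int) -> np.ndarray:
    w = np.asarray(_LEVEL_WEIGHTS[: depth + 1], dtype=float)
    return w / w.sum()


def _lineage_compositions(
    lineages: tuple[str, ...], n_genera: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Draw a composition for every prefix of the biome lineage tree.

    The genus axis is partitioned into disjoint contiguous blocks, one per
    lineage-tree node (cosmopolitan genera at the root, branch endemics
    below); genera outside the allocated blocks stay absent everywhere,
    like the long rare tail of real profiles.  A node's composition is the
    ``_LEVEL_WEIGHTS``-weighted sum of the block compositions along its
    lineage path, so genus sharing between two biomes is exactly their
    shared lineage — no chance overlap — and compositional similarity is
    graded by lineage distance by construction.
    """
    nodes = ["root"]
    for lineage in lineages:
        parts = lineage.split(":")
        for depth in range(2, len(parts) + 1):
            prefix = ":".join(parts[:depth])
            if prefix not in nodes:
                nodes.append(prefix)
    if n_genera < len(nodes):
        raise ConfigError(
            f"n_genera={n_genera} cannot host {len(nodes)} lineage blocks"
        )
    block_size = n_genera // len(nodes)
    blocks: dict[str, np.ndarray] = {}
    for i, node in enumerate(nodes):
        v = np.zeros(n_genera)
        lo = i * block_size
        v[lo : lo + block_size] = rng.dirichlet(np.full(block_size, 0.7))
        blocks[node] = v
    comps: dict[str, np.ndarray] = {}
    for node in nodes:
        parts = node.split(":")
        path = [":".join(parts[:d]) for d in range(1, len(parts) + 1)]
        weights = _path_weights(len(path) - 1)
        comps[node] = _normalize(
            np.sum([w * blocks[p] for w, p in zip(weights, path)], axis=0)
        )
    return comps


def _genus_lineage(g: int) -> str:
    """Ranked MGnify-style lineage string for synthetic genus ``g``."""
    return (
        f"sk__Bacteria;k__;p__Phylum{g % 7:02d};c__Class{g % 13:02d};"
        f"o__Order{g % 17:02d};f__Family{g % 23:02d};g__Genus{g:03d}"
    )


def _loading_matrix(
    n_genera: int, leaf_terms: list[str], rng: np.random.Generator
) -> np.ndarray:
    """Genus x leaf-term loading with a shared housekeeping core.

    Every genus spends ``_CORE_WEIGHT`` of its functional output on the
    same core leaf terms (functional redundancy: different taxa,
    overlapping functions) and the rest on a few genus-specific terms
    taken from a window of the leaf axis that slides with the genus index.
    Because biome genus blocks are contiguous too, a specific term is
    carried by genera that co-occur, so term presence is biome-structured
    rather than universal — the sparsity the frequency filters act on.
    """
    n_leaf = len(leaf_terms)
    n_core = max(3, n_leaf // 8)
    n_specific = n_leaf - n_core
    k = min(_TERMS_PER_GENUS, max(1, n_specific))
    L = np.zeros((n_genera, n_leaf))
    core_profile = rng.dirichlet(np.ones(n_core))
    for g in range(n_genera):
        L[g, :n_core] = _CORE_WEIGHT * core_profile
        if n_specific <= 0:
            L[g, :n_core] /= L[g, :n_core].sum()
            continue
        start = n_core + (g * max(0, n_specific - k)) // max(1, n_genera - 1)
        idx = np.arange(start, min(start + k, n_leaf))
        L[g, idx] += (1 - _CORE_WEIGHT) * rng.dirichlet(np.ones(len(idx)))
    return L


def generate_profiles(
    config: SyntheticConfig, dag: OntologyDAG
) -> tuple[CountTable, CountTable, StudyCatalog, GroundTruth]:
    """Generate taxonomic and functional count tables plus the catalog.

    Returns (taxonomic CountTable with lineage-string features, functional
    CountTable with GO leaf-term features, StudyCatalog, GroundTruth).
    Every sample's total in both tables equals ``sequencing_depth`` exactly.
    """
    if len(dag) < config.n_go_terms:
        raise ConfigError(
            f"ontology has {len(dag)} terms; config expects >= {config.n_go_terms}"
        )
    if config.sequencing_depth < 10 * config.n_genera:
        warnings.warn(
            "sequencing_depth below 10x n_genera: profiles will be degenerate",
            stacklevel=2,
        )
    rng = np.random.default_rng(config.seed)
    lineages = BIOME_LINEAGES[: config.n_biomes]
    comps = _lineage_compositions(lineages, config.n_genera, rng)
    root_comp = comps["root"]
    ov = config.cross_biome_overlap
    conc = config.dirichlet_concentration

    leaf_terms = dag.leaves()
    L = _loading_matrix(config.n_genera, leaf_terms, rng)

    taxo_rows: list[tuple[str, str, int]] = []
    func_rows: list[tuple[str, str, int]] = []
    studies: list[Study] = []
    biome_of: dict[str, str] = {}

    for b, lineage in enumerate(lineages):
        base = _normalize((1 - ov) * comps[lineage] + ov * root_comp)
        for s in range(config.studies_per_biome):
            study_id = f"SYNSTUDY{b:02d}{s:02d}"
            study_comp = rng.dirichlet(np.maximum(3 * conc * base, 1e-8))
            sample_ids = [
                f"run_b{b:02d}s{s:02d}r{i:02d}"
                for i in range(config.samples_per_study)
            ]
            for sid in sample_ids:
                p = rng.dirichlet(np.maximum(conc * study_comp, 1e-8))
                genus_counts = rng.multinomial(config.sequencing_depth, p)
                for g, c in enumerate(genus_counts):
                    if c == 0:
                        continue
                    lineage_str = _genus_lineage(g)
                    if g % 5 == 0 and c >= 2:
                        # split into two species rows to exercise aggregation
                        taxo_rows.append(
                            (lineage_str + f";s__Genus{g:03d}_alpha", sid, c // 2)
                        )
                        taxo_rows.append(
                            (lineage_str + f";s__Genus{g:03d}_beta", sid, c - c // 2)
                        )
                    else:
                        taxo_rows.append((lineage_str, sid, int(c)))
                genus_rel = genus_counts / genus_counts.sum()
                p_func = _normalize(np.maximum(genus_rel @ L, 0))
                term_counts = rng.multinomial(config.sequencing_depth, p_func)
                func_rows.extend(
                    (leaf_terms[t], sid, int(c))
                    for t, c in enumerate(term_counts)
                    if c > 0
                )
            studies.append(
                Study(study_id=study_id, sample_ids=sample_ids, biome=lineage)
            )
            biome_of[study_id] = lineage

    taxonomic = CountTable.from_records(taxo_rows)
    functional = CountTable.from_records(func_rows)
    catalog = StudyCatalog(studies)
    return taxonomic, functional, catalog, GroundTruth(biome_of=biome_of)


# ---------------------------------------------------------------------------
# study texts
# ---------------------------------------------------------------------------

#: per-lineage-token domain keyword vocabulary; tokens of unrelated
#: branches never share keywords
TOKEN_KEYWORDS = {
    "Host-associated": ("host-associated", "symbiotic", "mucosal"),
    "Mammals": ("mammalian", "warm-blooded", "fur-bearing"),
    "Birds": ("avian", "feathered", "migratory"),
    "Digestive-system": ("gut", "digestive", "intestinal"),
    "Skin": ("skin", "epidermal", "sebaceous"),
    "Environmental": ("environmental", "free-living", "open-habitat"),
    "Aquatic": ("aquatic", "waterborne", "planktonic"),
    "Marine": ("marine", "seawater", "pelagic"),
    "Freshwater": ("freshwater", "lake", "riverine"),
    "Terrestrial": ("terrestrial", "land-based", "edaphic"),
    "Soil": ("soil", "rhizosphere", "loam"),
    "Engineered": ("engineered", "built-environment", "industrial"),
    "Wastewater": ("wastewater", "effluent", "sewage"),
    "Activated-sludge": ("activated-sludge", "aeration-basin", "flocculant"),
    "Food-production": ("food-production", "culinary", "starter-culture"),
    "Fermentation": ("fermentation", "brine", "fermented"),
}

_FILLER = (
    "amplicon sequencing",
    "shotgun metagenomics",
    "seasonal sampling",
    "longitudinal design",
    "replicated transects",
    "depth gradients",
)


def _keywords_for(lineage: str) -> list[str]:
    words: list[str] = []
    for token in lineage.split(":"):
        if token == "root":
            continue
        words.extend(TOKEN_KEYWORDS.get(token, (token.lower(),)))
    return words


def domain_keywords(text: str) -> set[str]:
    """Domain-vocabulary keywords present in a text block."""
    vocab = {w for words in TOKEN_KEYWORDS.values() for w in words}
    lowered = text.lower()
    return {w for w in vocab if w in lowered}


def generate_study_texts(
    catalog: StudyCatalog, truth: GroundTruth, seed: int
) -> StudyCatalog:
    """Fill titles, descriptions and abstracts from the keyword templates.

    Studies of the same biome leaf share their whole keyword vocabulary;
    studies from disjoint lineage branches share no domain keyword at all.
    Filler phrases (study-design wording) are drawn per study from a
    neutral pool, seeded for reproducibility.
    """
    rng = np.random.default_rng(seed)
    studies = []
    for study_id in catalog.study_ids:
        st = catalog[study_id]
        if not st.biome:
            raise ConfigError(f"study {study_id} lacks a biome lineage")
        words = _keywords_for(st.biome)
        leaf = st.biome.split(":")[-1]
        fillers = rng.choice(_FILLER, size=2, replace=False)
        title = f"{leaf} microbiome survey {study_id}: {words[0]} communities"
        description = (
            f"This study characterizes {words[0]} microbial communities in a "
            f"{leaf.lower()} setting using {fillers[0]}. Samples capture "
            f"{', '.join(words[1:5])} signatures; the design relies on "
            f"{fillers[1]}."
        )
        abstract = (
            f"We profiled {len(st.sample_ids)} samples of "
            f"{' and '.join(words[:3])} communities to resolve community "
            f"structure and function."
        )
        studies.append(
            Study(
                study_id=st.study_id,
                sample_ids=list(st.sample_ids),
                title=title,
                description=description,
                biome=st.biome,
                abstract=abstract,
                abstract_refs=1,
            )
        )
    return StudyCatalog(studies)


# ---------------------------------------------------------------------------
# dataset writer (emits the exact TSV dialects the readers consume)
# ---------------------------------------------------------------------------


def write_synthetic_dataset(
    config: SyntheticConfig, outdir: str | Path
) -> dict[str, Path]:
    """Generate a full dataset and write it in MGnify-style formats.

    Emits ``taxonomy_abundances_SSU.tsv`` (wide, lineage first column),
    ``GO_abundances.tsv`` (term/description/category + sample columns),
    ``ontology.obo`` and ``studies.tsv``, so synthetic data exercises the
    real readers end-to-end.  Returns the artifact paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dag = generate_ontology(config.n_go_terms, config.seed)
    taxonomic, functional, catalog, truth = generate_profiles(config, dag)
    catalog = generate_study_texts(catalog, truth, config.seed)

    paths = {
        "taxonomy": outdir / "taxonomy_abundances_SSU.tsv",
        "go": outdir / "GO_abundances.tsv",
        "obo": outdir / "ontology.obo",
        "catalog": outdir / "studies.tsv",
        "ground_truth": outdir / "ground_truth.tsv",
    }

    taxo_wide = taxonomic.to_wide().reset_index()
    taxo_wide = taxo_wide.rename(columns={"feature_id": "taxonomy"})
    taxo_wide.to_csv(paths["taxonomy"], sep="\t", index=False)

    go_wide = functional.to_wide().reset_index()
    go_wide.insert(1, "description", [dag.name(t) for t in go_wide["feature_id"]])
    go_wide.insert(
        2, "category", [dag.namespace(t) or "biological_process" for t in go_wide["feature_id"]]
    )
    go_wide = go_wide.rename(columns={"feature_id": "GO"})
    go_wide.to_csv(paths["go"], sep="\t", index=False)

    write_obo(dag, paths["obo"])
    write_study_catalog(catalog, paths["catalog"])

    pd.DataFrame(
        [(sid, biome) for sid, biome in sorted(truth.biome_of.items())],
        columns=["study_id", "biome"],
    ).to_csv(paths["ground_truth"], sep="\t", index=False)
    return paths
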