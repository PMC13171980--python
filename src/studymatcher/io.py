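"""Readers and writers for MGnify-style inputs.

Three standard artifacts are covered:

* abundance tables — tab-separated, features in the first column(s), one
  column of integer read counts per Run/Assembly ID (taxonomy tables carry a
  lineage column; GO tables carry term / description / category columns);
* the Gene Ontology hierarchy in OBO 1.2 format (is_a edges only);
* study catalogs mapping each study to its member samples and descriptive
  text (title, description, biome lineage, optional linked abstract).

Everything is parsed into three in-memory types — :class:`CountTable`
(sparse long-format counts, the "super table"), :class:`OntologyDAG` and
:class:`StudyCatalog` — that the rest of the package consumes.  Zero-count
cells are dropped at read time: the long format stores presence only, which
keeps "fraction of samples in which a term appears" computable directly
from record presence.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import obonet
import pandas as pd

from .errors import FormatError, OntologyError

COUNT_COLUMNS = ("feature_id", "sample_id", "count")

GO_NAMESPACES = frozenset(
    {"molecular_function", "biological_process", "cellular_component"}
)

#: Number of studies sharing one linked abstract at which that abstract is
#: considered non-study-specific and its text is blanked everywhere.
ABSTRACT_EXCLUSION_THRESHOLD = 16


class CountTable:
    """Long-format feature x sample integer read counts.

    Wraps a :class:`pandas.DataFrame` with columns ``feature_id``,
    ``sample_id`` and ``count``.  (feature, sample) pairs are unique and all
    counts are positive integers; zero cells are not stored.
    """

    def __init__(self, df: pd.DataFrame, *, validate: bool = True):
        df = df.loc[:, list(COUNT_COLUMNS)].copy()
        df["count"] = df["count"].astype("int64")
        df["feature_id"] = df["feature_id"].astype(str)
        df["sample_id"] = df["sample_id"].astype(str)
        if validate:
            if (df["count"] < 0).any():
                raise FormatError("negative counts are not allowed")
            if df.duplicated(["feature_id", "sample_id"]).any():
                dup = df[df.duplicated(["feature_id", "sample_id"], keep=False)]
                raise FormatError(
                    "duplicate (feature, sample) records: "
                    f"{dup[['feature_id', 'sample_id']].head().to_dict('records')}"
                )
        self._df = df.reset_index(drop=True)

    # -- accessors ---------------------------------------------------------
    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def features(self) -> list[str]:
        return sorted(self._df["feature_id"].unique())

    @property
    def samples(self) -> list[str]:
        return sorted(self._df["sample_id"].unique())

    def __len__(self) -> int:
        return len(self._df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, CountTable):
            return NotImplemented
        a = self._df.sort_values(["feature_id", "sample_id"]).reset_index(drop=True)
        b = other._df.sort_values(["feature_id", "sample_id"]).reset_index(drop=True)
        return a.equals(b)

    def sample_totals(self) -> pd.Series:
        """Total reads per sample (only samples with at least one record)."""
        return self._df.groupby("sample_id")["count"].sum()

    def total(self) -> int:
        return int(self._df["count"].sum())

    def restrict_features(self, keep: Iterable[str]) -> "CountTable":
        keep = set(keep)
        return CountTable(
            self._df[self._df["feature_id"].isin(keep)], validate=False
        )

    def restrict_samples(self, keep: Iterable[str]) -> "CountTable":
        keep = set(keep)
        return CountTable(
            self._df[self._df["sample_id"].isin(keep)], validate=False
        )

    def to_wide(self) -> pd.DataFrame:
        """Dense features x samples matrix of counts (zeros filled in)."""
        return (
            self._df.pivot(index="feature_id", columns="sample_id", values="count")
            .fillna(0)
            .astype("int64")
            .sort_index()
            .sort_index(axis=1)
        )

    # -- serialization -----------------------------------------------------
    def write_tsv(self, path: str | Path) -> None:
        out = self._df.sort_values(["feature_id", "sample_id"])
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "CountTable":
        df = pd.read_csv(path, sep="\t", dtype={"feature_id": str, "sample_id": str})
        missing = set(COUNT_COLUMNS) - set(df.columns)
        if missing:
            raise FormatError(f"super table {path} lacks columns {sorted(missing)}")
        return cls(df)

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str, int]]
    ) -> "CountTable":
        df = pd.DataFrame(records, columns=list(COUNT_COLUMNS))
        return cls(df)


class OntologyDAG:
    """Acyclic is-a hierarchy of functional terms.

    Edges run child -> parent, so the ancestors of a term are the nodes
    reachable from it.  Construction verifies acyclicity and that every edge
    endpoint is a declared node.
    """

    def __init__(self, graph: nx.DiGraph):
        if not nx.is_directed_acyclic_graph(graph):
            cycle = nx.find_cycle(graph)
            raise OntologyError(f"ontology contains a cycle: {cycle}")
        self._graph = graph
        self._ancestor_cache: dict[str, frozenset[str]] = {}
        self._descendant_cache: dict[str, frozenset[str]] = {}

    @classmethod
    def from_edges(
        cls,
        nodes: Mapping[str, Mapping[str, str]] | Iterable[str],
        edges: Iterable[tuple[str, str]],
    ) -> "OntologyDAG":
        """Build from explicit node metadata and child->parent edge pairs."""
        g = nx.DiGraph()
        if isinstance(nodes, Mapping):
            for term, attrs in nodes.items():
                g.add_node(term, **dict(attrs))
        else:
            g.add_nodes_from(nodes)
        declared = set(g.nodes)
        for child, parent in edges:
            for end in (child, parent):
                if end not in declared:
                    raise OntologyError(f"edge endpoint {end!r} is not a declared term")
            g.add_edge(child, parent)
        return cls(g)

    @property
    def graph(self) -> nx.DiGraph:
        return self._graph

    @property
    def terms(self) -> list[str]:
        return sorted(self._graph.nodes)

    def __contains__(self, term: str) -> bool:
        return term in self._graph

    def __len__(self) -> int:
        return self._graph.number_of_nodes()

    def name(self, term: str) -> str:
        return self._graph.nodes[term].get("name", term)

    def namespace(self, term: str) -> str | None:
        return self._graph.nodes[term].get("namespace")

    def parents(self, term: str) -> set[str]:
        return set(self._graph.successors(term))

    def children(self, term: str) -> set[str]:
        return set(self._graph.predecessors(term))

    def ancestors(self, term: str) -> frozenset[str]:
        """All proper ancestors of ``term`` (transitive is-a closure)."""
        cached = self._ancestor_cache.get(term)
        if cached is None:
            cached = frozenset(nx.descendants(self._graph, term))
            self._ancestor_cache[term] = cached
        return cached

    def descendants(self, term: str) -> frozenset[str]:
        """All proper descendants (more specific terms) of ``term``."""
        cached = self._descendant_cache.get(term)
        if cached is None:
            cached = frozenset(nx.ancestors(self._graph, term))
            self._descendant_cache[term] = cached
        return cached

    def is_descendant(self, term: str, of: str) -> bool:
        return of in self.ancestors(term)

    def roots(self) -> list[str]:
        return sorted(n for n in self._graph.nodes if self._graph.out_degree(n) == 0)

    def leaves(self) -> list[str]:
        return sorted(n for n in self._graph.nodes if self._graph.in_degree(n) == 0)


@dataclass
class Study:
    """One study: its member samples plus the text blocks used downstream."""

    study_id: str
    sample_ids: list[str]
    title: str = ""
    description: str = ""
    biome: str = ""
    abstract: str | None = None
    abstract_refs: int = 0

    def __post_init__(self):
        if not self.sample_ids:
            raise FormatError(f"study {self.study_id} has no samples")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError(f"study {self.study_id} lists duplicate samples")

    def text_block(self) -> str:
        """Human-readable block embedded into relatedness prompts."""
        lines = [
            f"Title: {self.title}",
            f"Description: {self.description}",
            f"Biome lineage: {self.biome}",
        ]
        if self.abstract:
            lines.append(f"Abstract: {self.abstract}")
        return "\n".join(lines)


class StudyCatalog:
    """Mapping of study_id -> :class:`Study`, with sample ownership checks."""

    def __init__(self, studies: Iterable[Study]):
        self._studies: dict[str, Study] = {}
        owner: dict[str, str] = {}
        for st in studies:
            if st.study_id in self._studies:
                raise FormatError(f"duplicate study id {st.study_id!r}")
            for sid in st.sample_ids:
                if sid in owner:
                    raise FormatError(
                        f"sample {sid!r} claimed by both {owner[sid]!r} and {st.study_id!r}"
                    )
                owner[sid] = st.study_id
            self._studies[st.study_id] = st
        self._sample_owner = owner

    @property
    def study_ids(self) -> list[str]:
        return sorted(self._studies)

    def __len__(self) -> int:
        return len(self._studies)

    def __contains__(self, study_id: str) -> bool:
        return study_id in self._studies

    def __getitem__(self, study_id: str) -> Study:
        return self._studies[study_id]

    def __iter__(self):
        return iter(self.study_ids)

    def samples_of(self, study_id: str) -> list[str]:
        return list(self._studies[study_id].sample_ids)

    def study_of_sample(self, sample_id: str) -> str | None:
        return self._sample_owner.get(sample_id)

    def all_samples(self) -> list[str]:
        return sorted(self._sample_owner)

    def apply_abstract_exclusion(
        self, threshold: int = ABSTRACT_EXCLUSION_THRESHOLD
    ) -> int:
        """Blank abstracts shared by ``threshold`` or more studies.

        Abstracts referenced that widely are boilerplate (e.g. resource
        announcements) rather than study-specific text and would skew
        text-based relatedness.  An abstract is blanked when either the
        explicit reference count reaches the threshold or the identical text
        occurs in that many studies of this catalog.  Returns the number of
        studies whose abstract was removed.
        """
        text_counts = Counter(
            st.abstract for st in self._studies.values() if st.abstract
        )
        blanked = 0
        for st in self._studies.values():
            if st.abstract is None:
                continue
            shared = text_counts[st.abstract]
            if st.abstract_refs >= threshold or shared >= threshold:
                st.abstract = None
                blanked += 1
        return blanked


# ---------------------------------------------------------------------------
# abundance table readers
# ---------------------------------------------------------------------------


def _melt_wide_counts(
    df: pd.DataFrame, feature_col: str, sample_cols: list[str], path: str | Path
) -> pd.DataFrame:
    """Wide abundance block -> long records, dropping zero cells."""
    records = df.melt(
        id_vars=[feature_col],
        value_vars=sample_cols,
        var_name="sample_id",
        value_name="count",
    )
    numeric = pd.to_numeric(records["count"], errors="coerce")
    bad = records[numeric.isna() & records["count"].notna()]
    if len(bad):
        row = bad.iloc[0]
        raise FormatError(
            f"{path}: non-numeric count {row['count']!r} for feature "
            f"{row[feature_col]!r}, sample column {row['sample_id']!r}"
        )
    records["count"] = numeric.fillna(0)
    if ((records["count"] % 1) != 0).any():
        row = records[(records["count"] % 1) != 0].iloc[0]
        raise FormatError(
            f"{path}: non-integer count {row['count']!r} for feature "
            f"{row[feature_col]!r}, sample column {row['sample_id']!r}"
        )
    records = records[records["count"] > 0]
    records = records.rename(columns={feature_col: "feature_id"})
    return records[list(COUNT_COLUMNS)].reset_index(drop=True)


def read_taxonomy_table(path: str | Path, marker: str = "SSU") -> CountTable:
    """Read an MGnify-style ``taxonomy_abundances_{LSU,SSU}.tsv`` file.

    First column holds the taxon lineage, the remaining column headers are
    Run/Assembly IDs, and each cell the read count.  The wide table is melted
    to long format; zero cells are dropped.
    """
    if marker not in ("LSU", "SSU"):
        raise FormatError(f"marker must be LSU or SSU, got {marker!r}")
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: missing header row") from exc
    if df.shape[1] < 1:
        raise FormatError(f"{path}: no columns found")
    feature_col = df.columns[0]
    sample_cols = list(df.columns[1:])
    if df.empty:
        return CountTable(pd.DataFrame(columns=list(COUNT_COLUMNS)))
    return CountTable(_melt_wide_counts(df, feature_col, sample_cols, path))


def read_go_table(
    path: str | Path,
) -> tuple[CountTable, dict[str, tuple[str, str]]]:
    """Read an MGnify-style ``GO_abundances.tsv`` / ``GO-slim_abundances.tsv``.

    The first three columns are the GO term accession, its description, and
    its category (one of the three GO namespaces); the remaining columns are
    Run/Assembly IDs.  Returns the long-format counts and a metadata map
    ``term_id -> (description, category)`` with the category preserved
    verbatim.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: missing header row") from exc
    if df.shape[1] < 3:
        raise FormatError(
            f"{path}: expected term/description/category as first three columns"
        )
    term_col, desc_col, cat_col = df.columns[:3]
    sample_cols = list(df.columns[3:])
    if df[term_col].duplicated().any():
        dup = df[term_col][df[term_col].duplicated()].iloc[0]
        raise FormatError(f"{path}: duplicate term row {dup!r}")
    normalized = (
        df[cat_col].fillna("").str.strip().str.lower().str.replace(" ", "_")
    )
    bad = df[~normalized.isin(GO_NAMESPACES)]
    if len(bad):
        raise FormatError(
            f"{path}: unknown category label {bad[cat_col].iloc[0]!r} "
            f"for term {bad[term_col].iloc[0]!r}"
        )
    metadata = {
        row[term_col]: (row[desc_col], row[cat_col]) for _, row in df.iterrows()
    }
    if not sample_cols or df.empty:
        return CountTable(pd.DataFrame(columns=list(COUNT_COLUMNS))), metadata
    table = CountTable(_melt_wide_counts(df, term_col, sample_cols, path))
    return table, metadata


# ---------------------------------------------------------------------------
# OBO ontology
# ---------------------------------------------------------------------------


def read_obo(path: str | Path) -> OntologyDAG:
    """Read an OBO 1.2 file into an :class:`OntologyDAG`.

    Only ``is_a`` edges are honored (``part_of`` and other relationship
    types are ignored); obsolete terms are skipped.  Raises
    :class:`OntologyError` on cycles or ``is_a`` references to undeclared
    terms.
    """
    multi = obonet.read_obo(str(path), ignore_obsolete=True)
    # obonet materializes referenced-but-undeclared terms as attribute-less
    # nodes; treat those as dangling-edge errors rather than silent terms.
    declared = {n for n, d in multi.nodes(data=True) if d}
    g = nx.DiGraph()
    for node in declared:
        data = multi.nodes[node]
        g.add_node(
            node, name=data.get("name", node), namespace=data.get("namespace")
        )
    for child, parent, key in multi.edges(keys=True):
        if key != "is_a":
            continue
        if parent not in declared:
            raise OntologyError(
                f"{path}: is_a target {parent!r} of {child!r} is not declared"
            )
        if child in declared:
            g.add_edge(child, parent)
    return OntologyDAG(g)


def write_obo(dag: OntologyDAG, path: str | Path) -> None:
    """Serialize a DAG as minimal OBO 1.2 term stanzas."""
    lines = ["format-version: 1.2", ""]
    for term in dag.terms:
        lines.append("[Term]")
        lines.append(f"id: {term}")
        lines.append(f"name: {dag.name(term)}")
        ns = dag.namespace(term)
        if ns:
            lines.append(f"namespace: {ns}")
        for parent in sorted(dag.parents(term)):
            lines.append(f"is_a: {parent} ! {dag.name(parent)}")
        lines.append("")
    Path(path).write_text("\n".join(lines))


# ---------------------------------------------------------------------------
# study catalog
# ---------------------------------------------------------------------------

_CATALOG_COLUMNS = [
    "study_id",
    "title",
    "description",
    "biome",
    "abstract",
    "abstract_refs",
    "sample_ids",
]


def read_study_catalog(path: str | Path) -> StudyCatalog:
    """Read a study catalog TSV (one row per study, JSON sample-id column).

    The abstract-exclusion rule is applied at load time: abstracts referenced
    by :data:`ABSTRACT_EXCLUSION_THRESHOLD` or more studies are blanked so
    that every downstream consumer sees the same curated text.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = set(_CATALOG_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: catalog lacks columns {sorted(missing)}")
    studies = []
    for _, row in df.iterrows():
        try:
            sample_ids = json.loads(row["sample_ids"])
        except json.JSONDecodeError as exc:
            raise FormatError(
                f"{path}: bad sample_ids JSON for study {row['study_id']!r}"
            ) from exc
        studies.append(
            Study(
                study_id=row["study_id"],
                sample_ids=list(sample_ids),
                title=row["title"],
                description=row["description"],
                biome=row["biome"],
                abstract=row["abstract"] or None,
                abstract_refs=int(row["abstract_refs"] or 0),
            )
        )
    catalog = StudyCatalog(studies)
    catalog.apply_abstract_exclusion()
    return catalog


def write_study_catalog(catalog: StudyCatalog, path: str | Path) -> None:
    rows = []
    for sid in catalog.study_ids:
        st = catalog[sid]
        rows.append(
            {
                "study_id": st.study_id,
                "title": st.title,
                "description": st.description,
                "biome": st.biome,
                "abstract": st.abstract or "",
                "abstract_refs": st.abstract_refs,
                "sample_ids": json.dumps(st.sample_ids),
            }
        )
    pd.DataFrame(rows, columns=_CATALOG_COLUMNS).to_csv(path, sep="\t", index=False)
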