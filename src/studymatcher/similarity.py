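"""Pairwise (dis)similarity metrics on abundance profiles.

Three complementary metrics are supported: cosine similarity (angle between
abundance vectors, in [0, 1] for nonnegative inputs), Euclidean distance,
and Jensen–Shannon divergence (log base 2, so the range is [0, 1] bits).
All-vs-all matrices compute the n(n-1)/2 unique off-diagonal pairs and
mirror them; distances can be mapped onto a common higher-is-more-similar
orientation for ranking, aggregation and plotting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, jensenshannon
from sklearn.metrics.pairwise import cosine_similarity as _sk_cosine

from .errors import AnalysisError
from .profiles import ProfileMatrix

METRICS = ("cosine", "euclidean", "jsd")

#: metrics whose native orientation is already higher-is-more-similar
_SIMILARITY_NATIVE = {"cosine"}


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """dot(u, v) / (|u| |v|); requires equal length and positive norms."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise AnalysisError(f"length mismatch: {u.shape} vs {v.shape}")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise AnalysisError("cosine similarity undefined for zero-norm vector")
    return float(np.dot(u, v) / (nu * nv))


def euclidean_distance(u: np.ndarray, v: np.ndarray) -> float:
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise AnalysisError(f"length mismatch: {u.shape} vs {v.shape}")
    return float(np.linalg.norm(u - v))


def jensen_shannon_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """JSD(p, q) in bits: 1/2 KL(p||m) + 1/2 KL(q||m), m = (p+q)/2, log2.

    Inputs must be probability vectors (nonnegative, summing to one within
    1e-9).  Disjoint supports give the base-2 maximum of 1.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise AnalysisError(f"length mismatch: {p.shape} vs {q.shape}")
    for name, vec in (("p", p), ("q", q)):
        if (vec < 0).any():
            raise AnalysisError(f"{name} has negative entries")
        if abs(vec.sum() - 1.0) > 1e-9:
            raise AnalysisError(f"{name} does not sum to 1 (sum={vec.sum()!r})")
    # scipy's jensenshannon returns the square root of the divergence
    return float(jensenshannon(p, q, base=2) ** 2)


@dataclass
class SimilarityMatrix:
    """Dense symmetric all-vs-all scores for one metric.

    ``similarity_oriented`` records whether higher values mean more similar
    (cosine natively; distances after :func:`to_similarity`).
    """

    ids: list[str]
    values: np.ndarray
    metric: str
    similarity_oriented: bool

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise AnalysisError(
                f"value grid shape {self.values.shape} does not match {n} ids"
            )
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise AnalysisError("similarity matrix is not symmetric")
        self._index = {sid: i for i, sid in enumerate(self.ids)}

    def value(self, a: str, b: str) -> float:
        try:
            return float(self.values[self._index[a], self._index[b]])
        except KeyError as exc:
            raise AnalysisError(f"id {exc.args[0]!r} not in matrix") from None

    def block(self, rows: list[str], cols: list[str]) -> np.ndarray:
        try:
            ri = [self._index[r] for r in rows]
            ci = [self._index[c] for c in cols]
        except KeyError as exc:
            raise AnalysisError(f"id {exc.args[0]!r} not in matrix") from None
        return self.values[np.ix_(ri, ci)]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def write_tsv(self, path: str | Path) -> None:
        """TSV grid plus a JSON sidecar recording metric and orientation."""
        self.to_dataframe().to_csv(path, sep="\t", index_label="id")
        meta = {
            "metric": self.metric,
            "similarity_oriented": self.similarity_oriented,
        }
        Path(str(path) + ".meta.json").write_text(json.dumps(meta))

    @classmethod
    def read_tsv(cls, path: str | Path) -> "SimilarityMatrix":
        df = pd.read_csv(path, sep="\t", index_col="id")
        meta = json.loads(Path(str(path) + ".meta.json").read_text())
        return cls(
            ids=[str(i) for i in df.index],
            values=df.to_numpy(),
            metric=meta["metric"],
            similarity_oriented=meta["similarity_oriented"],
        )


def pair_count(n: int) -> int:
    """Number of unique unordered pairs among n items: n(n-1)/2."""
    return n * (n - 1) // 2


def all_vs_all(profiles: ProfileMatrix, metric: str) -> SimilarityMatrix:
    """All-vs-all sample comparison under one metric.

    Exactly the n(n-1)/2 unique pairs are computed (vectorized) and
    mirrored; the diagonal is exact (1 for cosine, 0 for distances).
    """
    if metric not in METRICS:
        raise AnalysisError(f"unknown metric {metric!r}; choose from {METRICS}")
    if profiles.n_samples < 2:
        raise AnalysisError("all-vs-all needs at least 2 samples")
    X = profiles.matrix()
    if metric == "cosine":
        values = _sk_cosine(X)
        np.fill_diagonal(values, 1.0)
    elif metric == "euclidean":
        values = cdist(X, X, "euclidean")
        np.fill_diagonal(values, 0.0)
    else:  # jsd, in bits
        values = cdist(X, X, "jensenshannon") ** 2 / np.log(2)
        values = np.nan_to_num(values, nan=0.0)
        np.fill_diagonal(values, 0.0)
    values = (values + values.T) / 2.0  # enforce exact symmetry
    return SimilarityMatrix(
        ids=list(profiles.samples),
        values=values,
        metric=metric,
        similarity_oriented=metric in _SIMILARITY_NATIVE,
    )


def to_similarity(matrix: SimilarityMatrix) -> SimilarityMatrix:
    """Map any matrix onto the higher-is-more-similar orientation.

    Cosine is left unchanged; Jensen–Shannon divergence d maps to 1 - d
    (both live in [0, 1] bits); Euclidean distance d maps to 1 / (1 + d).
    All transforms are strictly monotone, so rankings are preserved.
    """
    if matrix.similarity_oriented:
        return matrix
    if matrix.metric == "jsd":
        values = 1.0 - matrix.values
    elif matrix.metric == "euclidean":
        values = 1.0 / (1.0 + matrix.values)
    else:
        raise AnalysisError(
            f"no similarity transform registered for metric {matrix.metric!r}"
        )
    return replace(matrix, values=values, similarity_oriented=True)
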