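"""Sample-to-study aggregation of similarities ("study matcher").

A study-level score for studies X and Y is built from the sample-level
similarity matrix by a directional nearest-neighbor rule: for each sample
in X take its maximum similarity to any sample of Y, average those maxima
to get the directional mean X->Y, do the same in the other direction, and
keep the larger of the two.  The rule emphasizes the strongest cross-study
correspondence — shared structure is retained even when other sample
groups differ — while the two directional means are kept as provenance
because their asymmetry is itself informative (partial overlap shows up as
unequal directions).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AnalysisError
from .io import StudyCatalog
from .similarity import SimilarityMatrix

logger = logging.getLogger(__name__)


def directional_mean_of_maxes(
    sim: SimilarityMatrix, from_samples: list[str], to_samples: list[str]
) -> float:
    """mean over x in ``from_samples`` of max over y in ``to_samples`` of sim(x, y)."""
    if not sim.similarity_oriented:
        raise AnalysisError(
            "aggregation requires a similarity-oriented matrix; apply "
            "to_similarity() first"
        )
    if not from_samples or not to_samples:
        raise AnalysisError("sample lists must be nonempty")
    block = sim.block(list(from_samples), list(to_samples))
    return float(block.max(axis=1).mean())


@dataclass
class StudySimilarityMatrix:
    """Symmetric study-level similarity grid with directional provenance."""

    ids: list[str]
    values: np.ndarray
    directional: dict[tuple[str, str], tuple[float, float]]
    metric: str

    def value(self, a: str, b: str) -> float:
        i = {s: k for k, s in enumerate(self.ids)}
        try:
            return float(self.values[i[a], i[b]])
        except KeyError as exc:
            raise AnalysisError(f"study {exc.args[0]!r} not in matrix") from None

    def pairs(self) -> list[tuple[str, str]]:
        return [
            (a, b)
            for ai, a in enumerate(self.ids)
            for b in self.ids[ai + 1 :]
        ]

    def to_dataframe(self) -> pd.DataFrame:
        """Long form: study_a, study_b, both directional means, final score."""
        rows = []
        for a, b in self.pairs():
            ab, ba = self.directional[(a, b)]
            rows.append(
                {
                    "study_a": a,
                    "study_b": b,
                    "sim_ab_mean": ab,
                    "sim_ba_mean": ba,
                    "study_similarity": self.value(a, b),
                }
            )
        return pd.DataFrame(rows)

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def study_similarity(
    sim: SimilarityMatrix, catalog: StudyCatalog
) -> StudySimilarityMatrix:
    """Condense the n x n sample matrix into the m x m study matrix.

    Catalog samples missing from the matrix (filtered out upstream) are
    dropped from their study with a warning; studies losing every sample
    are excluded from the output.  For each remaining unordered pair the
    value is max(mean-of-maxes X->Y, mean-of-maxes Y->X); the diagonal is
    the within-study X->X value (1 for cosine self-similarity).
    """
    if not sim.similarity_oriented:
        raise AnalysisError(
            "aggregation requires a similarity-oriented matrix; apply "
            "to_similarity() first"
        )
    available = set(sim.ids)
    members: dict[str, list[str]] = {}
    for study_id in catalog.study_ids:
        samples = [s for s in catalog.samples_of(study_id) if s in available]
        lost = len(catalog.samples_of(study_id)) - len(samples)
        if lost:
            logger.warning(
                "study %s: %d sample(s) absent from the similarity matrix",
                study_id,
                lost,
            )
        if not samples:
            logger.warning("study %s has no surviving samples; excluded", study_id)
            continue
        members[study_id] = samples
    ids = sorted(members)
    if len(ids) < 1:
        raise AnalysisError("no study has surviving samples")
    m = len(ids)
    values = np.zeros((m, m))
    directional: dict[tuple[str, str], tuple[float, float]] = {}
    for ai, a in enumerate(ids):
        values[ai, ai] = directional_mean_of_maxes(sim, members[a], members[a])
        for bi in range(ai + 1, m):
            b = ids[bi]
            ab = directional_mean_of_maxes(sim, members[a], members[b])
            ba = directional_mean_of_maxes(sim, members[b], members[a])
            final = max(ab, ba)
            values[ai, bi] = values[bi, ai] = final
            directional[(a, b)] = (ab, ba)
    return StudySimilarityMatrix(
        ids=ids, values=values, directional=directional, metric=sim.metric
    )
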