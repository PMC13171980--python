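"""Fixed-axis relative-abundance profile matrices.

A :class:`ProfileMatrix` projects every sample onto the same ordered feature
axis (genus names or GO term accessions) as a vector of relative abundances
summing to one — the fixed-length numerical encoding that all similarity
metrics operate on.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import AnalysisError
from .io import CountTable

_SUM_TOL = 1e-9


class ProfileMatrix:
    """Features x samples matrix of per-sample relative abundances."""

    def __init__(self, df: pd.DataFrame, *, validate: bool = True):
        df = df.astype(float)
        if validate:
            if (df.values < 0).any():
                raise AnalysisError("negative relative abundances")
            sums = df.sum(axis=0)
            bad = sums[(sums - 1.0).abs() > _SUM_TOL]
            if len(bad):
                raise AnalysisError(
                    f"sample vectors must sum to 1; offending samples: "
                    f"{list(bad.index[:5])}"
                )
        self._df = df

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def features(self) -> list[str]:
        return list(self._df.index)

    @property
    def samples(self) -> list[str]:
        return list(self._df.columns)

    @property
    def n_samples(self) -> int:
        return self._df.shape[1]

    def vector(self, sample_id: str) -> np.ndarray:
        return self._df[sample_id].to_numpy()

    def matrix(self) -> np.ndarray:
        """Samples x features array (rows in ``self.samples`` order)."""
        return self._df.to_numpy().T

    def subset_samples(self, keep: Iterable[str]) -> "ProfileMatrix":
        keep = [s for s in self.samples if s in set(keep)]
        return ProfileMatrix(self._df[keep], validate=False)

    def align_features(self, features: list[str]) -> "ProfileMatrix":
        """Reindex onto a given feature axis, filling absent features with 0.

        The vectors are *not* renormalized; callers aligning a noisy table to
        the original axis rely on abundances staying as computed.
        """
        return ProfileMatrix(
            self._df.reindex(features).fillna(0.0), validate=False
        )

    # -- serialization -----------------------------------------------------
    def write_tsv(self, path: str | Path) -> None:
        out = self._df.sort_index()
        out.to_csv(path, sep="\t", index_label="feature_id")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ProfileMatrix":
        df = pd.read_csv(path, sep="\t", index_col="feature_id")
        return cls(df)

    @classmethod
    def from_counts(cls, table: CountTable) -> "ProfileMatrix":
        """Normalize a count table: per-sample counts / per-sample total.

        The feature axis is the sorted union of features across all samples;
        features absent from a sample contribute zero.
        """
        if len(table) == 0:
            raise AnalysisError("cannot build profiles from an empty table")
        wide = table.to_wide().astype(float)
        totals = wide.sum(axis=0)
        zero = totals[totals == 0]
        if len(zero):
            raise AnalysisError(
                f"sample(s) with zero total count: {list(zero.index[:5])}"
            )
        return cls(wide / totals, validate=False)
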