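"""Taxonomic profile pipeline: lineage -> genus profiles.

Workflow: aggregate lineage-resolved counts to the genus rank, remove
low-abundance genus records (sequencing noise, index bleed), drop samples
with too few genera (failed libraries, insufficient depth), and normalize
each surviving sample to relative abundances.  Defaults: records with fewer
than 30 reads removed; samples with fewer than 10 distinct genera excluded.
"""

from __future__ import annotations

import re

import pandas as pd

from .errors import FormatError
from .io import CountTable
from .profiles import ProfileMatrix

DEFAULT_MIN_READS = 30
DEFAULT_MIN_GENERA = 10

_RANK_TOKEN = re.compile(r"^[a-z]{1,2}__")


def extract_genus(lineage: str) -> str | None:
    """Pull the genus name out of a ranked, semicolon-delimited lineage.

    MGnify lineages look like
    ``sk__Bacteria;k__;p__Proteobacteria;...;g__Vibrio;s__Vibrio_cholerae``.
    Returns the value of the ``g__`` token when present and non-empty,
    ``None`` otherwise (no genus rank, or an empty genus placeholder).
    """
    tokens = [t.strip() for t in str(lineage).split(";") if t.strip()]
    if not tokens or not any(_RANK_TOKEN.match(t) for t in tokens):
        raise FormatError(f"malformed lineage (no rank prefixes): {lineage!r}")
    for token in tokens:
        if token.startswith("g__"):
            value = token[3:].strip()
            return value or None
    return None


def aggregate_to_genus(table: CountTable) -> CountTable:
    """Sum lineage-level records into genus-level records per sample.

    Records whose lineage has no genus rank (or an empty one) are dropped —
    they cannot be attributed to a genus and would otherwise smear across
    the profile.
    """
    if len(table) == 0:
        return table
    df = table.df.copy()
    genus = df["feature_id"].map(extract_genus)
    df = df[genus.notna()]
    df["feature_id"] = genus[genus.notna()]
    agg = (
        df.groupby(["feature_id", "sample_id"], as_index=False)["count"].sum()
    )
    return CountTable(agg, validate=False)


def filter_taxa_counts(
    table: CountTable, min_reads: int = DEFAULT_MIN_READS
) -> CountTable:
    """Drop (genus, sample) records supported by fewer than ``min_reads``.

    Strict inequality: a record with exactly ``min_reads`` reads survives.
    """
    df = table.df
    return CountTable(df[df["count"] >= min_reads], validate=False)


def filter_low_richness_samples(
    table: CountTable, min_genera: int = DEFAULT_MIN_GENERA
) -> tuple[CountTable, list[str]]:
    """Exclude samples with fewer than ``min_genera`` distinct genera.

    Returns the filtered table and the sorted list of dropped sample ids.
    """
    if len(table) == 0:
        return table, []
    richness = table.df.groupby("sample_id")["feature_id"].nunique()
    dropped = sorted(richness[richness < min_genera].index)
    kept = table.df[~table.df["sample_id"].isin(dropped)]
    return CountTable(kept, validate=False), dropped


def normalize_relative_abundance(table: CountTable) -> ProfileMatrix:
    """Divide each count by its sample total; vectors sum to one."""
    return ProfileMatrix.from_counts(table)


def run_taxonomic_pipeline(
    table: CountTable,
    min_reads: int = DEFAULT_MIN_READS,
    min_genera: int = DEFAULT_MIN_GENERA,
) -> tuple[ProfileMatrix, dict]:
    """Full genus pipeline; returns profiles plus a filter-accounting dict."""
    genus = aggregate_to_genus(table)
    abundant = filter_taxa_counts(genus, min_reads)
    rich, dropped = filter_low_richness_samples(abundant, min_genera)
    profiles = normalize_relative_abundance(rich)
    accounting = {
        "input_records": len(table),
        "genus_records": len(genus),
        "records_after_count_filter": len(abundant),
        "samples_dropped_low_richness": dropped,
        "final_samples": profiles.n_samples,
        "final_genera": len(profiles.features),
    }
    return profiles, accounting
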