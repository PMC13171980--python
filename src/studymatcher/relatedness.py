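"""Text-based study-pair relatedness via a pluggable language-model backend.

For every unordered study pair a prompt embedding both studies' textual
metadata is sent to a backend (any callable ``prompt text -> response
text``); the structured JSON response is parsed into one of four ordinal
categories (none < low < medium < high), and the whole evaluation is
repeated three times with a majority vote deciding the final category.
When all three runs disagree the ordinal median is used, which respects
the category scale.  A deterministic mock backend that classifies from the
biome lineages embedded in the prompt ships for offline use; a real model
server is an optional adapter, never a test dependency.
"""

from __future__ import annotations

import json
import logging
import re
from collections import Counter
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Protocol

import pandas as pd

from .errors import AnalysisError, ResponseParseError
from .io import Study, StudyCatalog

logger = logging.getLogger(__name__)

#: ordinal relatedness scale, least to most related
CATEGORIES = ("none", "low", "medium", "high")

#: the prompt's own label for the lowest category, normalized to "none"
_LABEL_ALIASES = {"no": "none"}

_TEMPLATE = (
    resources.files("studymatcher.data")
    .joinpath("prompt_template.txt")
    .read_text()
)

#: the core question sentence presented verbatim to the model
CORE_QUESTION = (
    "How high similarity do you expect between these two microbiome studies?"
)


class Backend(Protocol):
    """Text-model contract: prompt text in, response text out."""

    def __call__(self, prompt: str) -> str: ...


@dataclass(frozen=True)
class RelatednessCall:
    """One backend response for one ordered study pair and run."""

    study_a: str
    study_b: str
    run: int
    category: str
    explanation: str
    raw: str


@dataclass(frozen=True)
class RelatednessVerdict:
    """Final category for a pair after voting across runs."""

    study_a: str
    study_b: str
    final: str | None
    per_run: tuple[str | None, ...]
    rule: str  # "majority", "ordinal_median", or "error"


def build_prompt(study_a: Study, study_b: Study) -> str:
    """Assemble the comparison prompt for one study pair.

    Each study contributes its title, description and biome lineage; the
    abstract section is present only when an abstract survived the
    shared-abstract exclusion rule.
    """
    for st in (study_a, study_b):
        if not (st.title or st.description or st.biome):
            raise AnalysisError(f"study {st.study_id} has no usable text")
    return _TEMPLATE.format(
        study_a=study_a.text_block(), study_b=study_b.text_block()
    )


def normalize_category(label: str) -> str:
    norm = label.strip().lower()
    norm = _LABEL_ALIASES.get(norm, norm)
    if norm not in CATEGORIES:
        raise ResponseParseError(f"unknown relatedness label {label!r}", raw=label)
    return norm


def parse_response(
    raw: str, study_a: str = "", study_b: str = "", run: int = 1
) -> RelatednessCall:
    """Parse a backend response into a :class:`RelatednessCall`.

    The response is expected to be (or contain) a JSON object with
    ``relatedness`` and ``explanation`` fields; the prompt's "no" label is
    normalized to "none".  Unparseable structures raise
    :class:`ResponseParseError` carrying the raw text.
    """
    if not raw or not raw.strip():
        raise ResponseParseError("empty response", raw=raw)
    try:
        payload = json.loads(raw)
    except json.JSONDecodeError:
        match = re.search(r"\{.*\}", raw, flags=re.DOTALL)
        if not match:
            raise ResponseParseError("no JSON object in response", raw=raw)
        try:
            payload = json.loads(match.group(0))
        except json.JSONDecodeError as exc:
            raise ResponseParseError(f"bad JSON: {exc}", raw=raw) from exc
    if not isinstance(payload, dict) or "relatedness" not in payload:
        raise ResponseParseError("response lacks a 'relatedness' field", raw=raw)
    category = normalize_category(str(payload["relatedness"]))
    return RelatednessCall(
        study_a=study_a,
        study_b=study_b,
        run=run,
        category=category,
        explanation=str(payload.get("explanation", "")),
        raw=raw,
    )


def majority_vote(calls: list[RelatednessCall]) -> RelatednessVerdict:
    """Modal category over exactly three runs; ordinal median on a 1/1/1 split."""
    if len(calls) != 3:
        raise AnalysisError(f"majority vote needs exactly 3 calls, got {len(calls)}")
    pairs = {(c.study_a, c.study_b) for c in calls}
    if len(pairs) != 1:
        raise AnalysisError(f"calls mix study pairs: {sorted(pairs)}")
    cats = [c.category for c in calls]
    counts = Counter(cats)
    top, n = counts.most_common(1)[0]
    if n >= 2:
        final, rule = top, "majority"
    else:
        ordered = sorted(cats, key=CATEGORIES.index)
        final, rule = ordered[1], "ordinal_median"
    a, b = calls[0].study_a, calls[0].study_b
    return RelatednessVerdict(
        study_a=a, study_b=b, final=final, per_run=tuple(cats), rule=rule
    )


def classify_pairs(
    catalog: StudyCatalog,
    backend: Backend,
    runs: int = 3,
    seed: int = 0,
    eligible: set[str] | None = None,
) -> list[RelatednessVerdict]:
    """Classify every unordered eligible study pair ``runs`` times.

    ``eligible`` restricts to studies for which profiles exist (defaults to
    the whole catalog).  A backend failure on a call is retried once; a
    second failure records an error verdict for the pair rather than
    aborting the batch.  ``seed`` is forwarded to backends that accept
    reseeding via a ``reseed`` method.
    """
    if runs != 3:
        raise AnalysisError("the voting scheme is defined for exactly 3 runs")
    if hasattr(backend, "reseed"):
        backend.reseed(seed)
    ids = sorted(eligible) if eligible is not None else catalog.study_ids
    ids = [s for s in ids if s in catalog]
    verdicts: list[RelatednessVerdict] = []
    for ai, a in enumerate(ids):
        for b in ids[ai + 1 :]:
            prompt = build_prompt(catalog[a], catalog[b])
            calls: list[RelatednessCall] = []
            failed = False
            for run in range(1, runs + 1):
                raw = None
                for attempt in range(2):
                    try:
                        raw = backend(prompt)
                        calls.append(parse_response(raw, a, b, run))
                        break
                    except (ResponseParseError, RuntimeError) as exc:
                        logger.warning(
                            "backend failure for (%s, %s) run %d attempt %d: %s",
                            a, b, run, attempt + 1, exc,
                        )
                else:
                    failed = True
                if failed:
                    break
            if failed:
                verdicts.append(
                    RelatednessVerdict(
                        study_a=a,
                        study_b=b,
                        final=None,
                        per_run=tuple(c.category for c in calls),
                        rule="error",
                    )
                )
            else:
                verdicts.append(majority_vote(calls))
    return verdicts


def run_histograms(verdicts: list[RelatednessVerdict]) -> pd.DataFrame:
    """Per-run category counts (categories x runs) across all verdicts."""
    runs = max((len(v.per_run) for v in verdicts), default=0)
    data = {
        f"run{r + 1}": Counter(
            v.per_run[r] for v in verdicts if len(v.per_run) > r
        )
        for r in range(runs)
    }
    return pd.DataFrame(
        {run: [counts.get(cat, 0) for cat in CATEGORIES] for run, counts in data.items()},
        index=list(CATEGORIES),
    )


def verdicts_to_dataframe(verdicts: list[RelatednessVerdict]) -> pd.DataFrame:
    rows = []
    for v in verdicts:
        row = {"study_a": v.study_a, "study_b": v.study_b}
        for r in range(3):
            row[f"run{r + 1}"] = v.per_run[r] if len(v.per_run) > r else ""
        row["final"] = v.final or ""
        row["rule"] = v.rule
        rows.append(row)
    return pd.DataFrame(rows)


def write_verdicts(verdicts: list[RelatednessVerdict], path: str | Path) -> None:
    verdicts_to_dataframe(verdicts).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# backends
# ---------------------------------------------------------------------------


class MockBiomeBackend:
    """Deterministic offline backend classifying from biome lineages.

    Reads the two "Biome lineage:" lines out of the prompt and maps the
    number of shared lineage components after the root (3+ -> high,
    2 -> medium, 1 -> low, 0 -> no) onto the prompt's categories.  Order
    of the two studies in the prompt does not affect the verdict.
    """

    def __init__(self, seed: int = 0):
        self.seed = seed

    def reseed(self, seed: int) -> None:
        self.seed = seed

    def __call__(self, prompt: str) -> str:
        lineages = re.findall(r"^Biome lineage:\s*(.+)$", prompt, flags=re.MULTILINE)
        if len(lineages) != 2:
            raise RuntimeError(
                f"expected 2 biome lineage lines in prompt, found {len(lineages)}"
            )
        depth = shared_lineage_depth(lineages[0], lineages[1])
        label = {0: "no", 1: "low", 2: "medium"}.get(depth, "high")
        explanation = (
            f"The studies sample biomes '{lineages[0]}' and '{lineages[1]}', "
            f"sharing {depth} lineage level(s) below the root."
        )
        return json.dumps({"explanation": explanation, "relatedness": label})


def shared_lineage_depth(a: str, b: str) -> int:
    """Number of common leading components of two colon-delimited lineages,
    not counting the shared root."""
    pa = [t.strip() for t in a.split(":") if t.strip()]
    pb = [t.strip() for t in b.split(":") if t.strip()]
    if pa and pb and pa[0].lower() == "root" and pb[0].lower() == "root":
        pa, pb = pa[1:], pb[1:]
    depth = 0
    for x, y in zip(pa, pb):
        if x != y:
            break
        depth += 1
    return depth
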