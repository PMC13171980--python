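"""End-to-end pipeline orchestration.

Runs the stages in order — data (synthetic generation or user files) ->
taxonomic profiles -> functional profiles -> all-vs-all similarity ->
noise-robustness benchmark -> study-level aggregation -> text relatedness
-> statistics — writing every intermediate artifact plus a manifest with
paths, checksums and per-stage seeds.  Per-stage seeds are split from the
master seed by a fixed hash derivation, so any stage can be re-run
independently yet reproducibly; re-running the whole pipeline with the
same config and seed reproduces all deterministic artifacts byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import functional, taxonomic
from .aggregate import study_similarity
from .errors import ConfigError, StudyMatcherError
from .io import (
    read_go_table,
    read_obo,
    read_study_catalog,
    read_taxonomy_table,
)
from .relatedness import (
    MockBiomeBackend,
    classify_pairs,
    run_histograms,
    write_verdicts,
)
from .robustness import NoiseConfig, compare_metrics, run_noise_benchmark
from .similarity import all_vs_all, to_similarity
from .stats import full_stats_report, violin_export, violin_plot
from .synthetic import SyntheticConfig, write_synthetic_dataset

logger = logging.getLogger(__name__)

_STAGES = (
    "data",
    "taxonomic",
    "functional",
    "similarity",
    "robustness",
    "matching",
    "relatedness",
    "stats",
)


def derive_seed(master: int, stage: str) -> int:
    """Stable per-stage seed below 2**31 derived from the master seed."""
    digest = hashlib.blake2b(f"{master}:{stage}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31)


@dataclass
class PipelineConfig:
    """Everything a full run needs; defaults are the analysis defaults."""

    outdir: str | Path = "studymatcher_run"
    seed: int = 0
    synthetic: SyntheticConfig | None = None
    taxonomy_path: str | Path | None = None
    go_path: str | Path | None = None
    obo_path: str | Path | None = None
    catalog_path: str | Path | None = None
    marker: str = "SSU"
    min_reads: int = taxonomic.DEFAULT_MIN_READS
    min_genera: int = taxonomic.DEFAULT_MIN_GENERA
    global_max: float = functional.DEFAULT_GLOBAL_MAX
    local_min: float = functional.DEFAULT_LOCAL_MIN
    metric: str = "cosine"
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    runs: int = 3

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        d["outdir"] = str(self.outdir)
        for key in ("taxonomy_path", "go_path", "obo_path", "catalog_path"):
            if d[key] is not None:
                d[key] = str(d[key])
        return d


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest.

    On a stage failure the manifest records partial completion and the
    failing stage before the exception propagates.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_jsonable(),
        "seeds": {stage: derive_seed(config.seed, stage) for stage in _STAGES},
        "stages": {},
        "status": "running",
    }
    (outdir / "config.json").write_text(json.dumps(config.to_jsonable(), indent=2))

    def record(stage: str, artifacts: dict[str, Path], **extra):
        manifest["stages"][stage] = {
            "artifacts": {
                name: {"path": str(p), "sha256": _checksum(Path(p))}
                for name, p in artifacts.items()
            },
            **extra,
        }

    current = "data"
    try:
        # ---- stage: data ------------------------------------------------
        datadir = outdir / "data"
        if config.synthetic is not None:
            synth = dataclasses.replace(
                config.synthetic, seed=derive_seed(config.seed, "data")
            )
            paths = write_synthetic_dataset(synth, datadir)
        else:
            needed = {
                "taxonomy_path": config.taxonomy_path,
                "go_path": config.go_path,
                "obo_path": config.obo_path,
                "catalog_path": config.catalog_path,
            }
            missing = [k for k, v in needed.items() if v is None]
            if missing:
                raise ConfigError(
                    f"no synthetic config and missing inputs: {missing}"
                )
            paths = {
                "taxonomy": Path(config.taxonomy_path),
                "go": Path(config.go_path),
                "obo": Path(config.obo_path),
                "catalog": Path(config.catalog_path),
            }
        record("data", paths)

        taxo_table = read_taxonomy_table(paths["taxonomy"], marker=config.marker)
        go_table, _go_meta = read_go_table(paths["go"])
        dag = read_obo(paths["obo"])
        catalog = read_study_catalog(paths["catalog"])

        # ---- stage: taxonomic profiles ---------------------------------
        current = "taxonomic"
        taxo_profiles, taxo_accounting = taxonomic.run_taxonomic_pipeline(
            taxo_table, config.min_reads, config.min_genera
        )
        p = outdir / "taxonomic_profiles.tsv"
        taxo_profiles.write_tsv(p)
        record("taxonomic", {"profiles": p}, accounting=taxo_accounting)
        logger.info("taxonomic accounting: %s", taxo_accounting)

        # ---- stage: functional profiles --------------------------------
        current = "functional"
        func_profiles, ccmri, _ranking = functional.run_functional_pipeline(
            go_table, dag, config.global_max, config.local_min
        )
        p = outdir / "functional_profiles.tsv"
        func_profiles.write_tsv(p)
        ccmri_path = outdir / "ccmri_terms.txt"
        ccmri_path.write_text("\n".join(ccmri) + "\n")
        record(
            "functional",
            {"profiles": p, "ccmri": ccmri_path},
            n_terms=len(ccmri),
            n_samples=func_profiles.n_samples,
        )

        # ---- stage: all-vs-all similarity ------------------------------
        current = "similarity"
        sims = {}
        artifacts = {}
        for sim_type, profiles in (
            ("taxonomic", taxo_profiles),
            ("functional", func_profiles),
        ):
            matrix = to_similarity(all_vs_all(profiles, config.metric))
            path = outdir / f"similarity_{sim_type}.tsv"
            matrix.write_tsv(path)
            sims[sim_type] = matrix
            artifacts[sim_type] = path
        record("similarity", artifacts, metric=config.metric)

        # ---- stage: robustness benchmark -------------------------------
        current = "robustness"
        noise = dataclasses.replace(
            config.noise, seed=derive_seed(config.seed, "robustness")
        )
        genus_table = taxonomic.filter_taxa_counts(
            taxonomic.aggregate_to_genus(taxo_table), config.min_reads
        )
        report = run_noise_benchmark(genus_table, noise)
        ranking, winner, tie = compare_metrics(report)
        p = outdir / "robustness_report.tsv"
        report.to_csv(p, sep="\t", index=False)
        record("robustness", {"report": p}, winner=winner, tie=tie)

        # ---- stage: study matching -------------------------------------
        current = "matching"
        study_sims = {}
        artifacts = {}
        for sim_type, matrix in sims.items():
            ssim = study_similarity(matrix, catalog)
            path = outdir / f"study_similarity_{sim_type}.tsv"
            ssim.write_tsv(path)
            study_sims[sim_type] = ssim
            artifacts[sim_type] = path
        record("matching", artifacts)

        # ---- stage: text relatedness -----------------------------------
        current = "relatedness"
        eligible = set()
        for matrix in study_sims.values():
            eligible.update(matrix.ids)
        backend = MockBiomeBackend()
        verdicts = classify_pairs(
            catalog,
            backend,
            runs=config.runs,
            seed=derive_seed(config.seed, "relatedness"),
            eligible=eligible,
        )
        p = outdir / "verdicts.tsv"
        write_verdicts(verdicts, p)
        hist_path = outdir / "run_histograms.tsv"
        run_histograms(verdicts).to_csv(hist_path, sep="\t", index_label="category")
        record("relatedness", {"verdicts": p, "histograms": hist_path})

        # ---- stage: statistics -----------------------------------------
        current = "stats"
        kw, mw = full_stats_report(study_sims, verdicts, runs=config.runs)
        long, summary = violin_export(study_sims, verdicts, catalog=catalog)
        artifacts = {}
        for name, frame in (
            ("kruskal", kw),
            ("mannwhitney", mw),
            ("values", long),
            ("summary", summary),
        ):
            path = outdir / f"stats_{name}.tsv"
            frame.to_csv(path, sep="\t", index=False)
            artifacts[name] = path
        fig_path = outdir / "violins.png"
        violin_plot(long, fig_path)
        record("stats", artifacts, figure=str(fig_path))

        manifest["status"] = "complete"
    except StudyMatcherError:
        manifest["status"] = f"failed at stage {current}"
        raise
    finally:
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
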