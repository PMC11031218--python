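"""End-to-end orchestration: simulate/load -> classify -> DE/DM -> enrichment
-> stability-LASSO -> integration -> clustering, behind one config.

Every stage writes its outputs as TSV under the run's output directory and
the run finishes with a JSON manifest listing each file's SHA-256 checksum,
so two runs with the same configuration and seeds can be compared
byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from responderomics.diff_analysis import (
    STANDARD_CONTRASTS,
    cluster_profiles,
    run_contrast,
    select_deg,
)
from responderomics.enrichment import enrichment_table, overlap_test, term_enrichment
from responderomics.errors import ConfigError, DataError
from responderomics.integration import flag_epigenetic_regulation, map_cpgs_to_genes, \
    marker_methylation_support
from responderomics.io_formats import (
    read_cpg_annotation,
    read_expression,
    read_gmt,
    read_methylation,
    read_samplesheet,
    write_gmt,
    write_matrix,
    write_table,
)
from responderomics.lasso_stability import stability_run, top_markers
from responderomics.phenotype import classify_cohort
from responderomics.synthetic import SimulationParams, simulate_all

logger = logging.getLogger(__name__)

_version = "0.1.0"


@dataclass
class RunConfig:
    """One pipeline run: inputs (or simulation), thresholds, and seeds."""

    outdir: str = "results"
    seed: int = 0
    # either simulate (params dict) or explicit input paths
    simulate: dict | None = None
    expression: str | None = None
    methylation: str | None = None
    samples: str | None = None
    cpg_annotation: str | None = None
    genesets: str | None = None
    # thresholds
    p_threshold: float = 0.05
    min_count: int = 5
    enrichment_mode: str = "standard"
    # stability-LASSO
    n_iter: int = 1000
    success_tol: float = 0.10
    success_min_frac: float = 0.5
    n_top: int = 20
    cv_folds: int = 5
    # integration
    integration_min_cpgs: int = 1
    integration_region: str = "all"
    integration_require_inverse: bool = False
    marker_min_cpgs: int = 2
    # clustering
    cluster_genes: list[str] | None = None
    cluster_k: int = 4

    def __post_init__(self) -> None:
        if self.simulate is None:
            needed = ("expression", "methylation", "samples", "cpg_annotation", "genesets")
            missing = [k for k in needed if getattr(self, k) is None]
            if missing:
                raise ConfigError(
                    f"config must either request simulation or provide paths for: {missing}"
                )
            for k in needed:
                path = Path(getattr(self, k))
                if not path.exists():
                    raise ConfigError(f"{k} file not found: {path}")
        if self.n_iter < 1:
            raise ConfigError(f"n_iter must be >= 1, got {self.n_iter}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with Path(path).open() as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record: config hash, per-file checksums, timings."""

    version: str
    config_hash: str
    files: dict[str, str] = field(default_factory=dict)  # relpath -> sha256
    stage_seconds: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def write(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_full_pipeline(config: RunConfig) -> RunManifest:
    """Execute every stage in order and write all outputs plus a manifest.

    A stage failure propagates with the stage name attached so the run can
    be replayed; outputs of completed stages are preserved.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(version=_version, config_hash=config.config_hash())
    written: list[Path] = []

    def emit(name: str, writer) -> Path:
        path = outdir / name
        writer(path)
        written.append(path)
        return path

    stage = "simulate_or_load"
    t0 = time.perf_counter()
    try:
        if config.simulate is not None:
            params = SimulationParams(**{**config.simulate, "seed": config.seed})
            sim = simulate_all(params)
            sheet, expression, methylation = sim["sheet"], sim["expression"], sim["methylation"]
            annotation, genesets, truth = sim["annotation"], sim["genesets"], sim["truth"]
            emit("samples.csv", lambda p: sheet.table.to_csv(p, index=False, float_format="%.10g"))
            emit("expression.tsv", lambda p: write_matrix(expression, p))
            emit("methylation.tsv", lambda p: write_matrix(methylation, p))
            emit("cpg_annotation.tsv",
                 lambda p: annotation.table.to_csv(p, sep="\t", index=False))
            emit("genesets.gmt", lambda p: write_gmt(genesets, p))
            emit("truth.tsv", lambda p: write_table(truth.to_frame(), p))
        else:
            sheet = read_samplesheet(config.samples)
            expression = read_expression(config.expression)
            methylation, _ = read_methylation(config.methylation)
            annotation = read_cpg_annotation(config.cpg_annotation)
            genesets = read_gmt(config.genesets)
        manifest.stage_seconds[stage] = time.perf_counter() - t0

        stage = "classify"
        t0 = time.perf_counter()
        phenotype = classify_cohort(sheet)
        emit("phenotype.tsv", lambda p: write_table(phenotype, p))
        manifest.stage_seconds[stage] = time.perf_counter() - t0

        stage = "differential"
        t0 = time.perf_counter()
        de_results, dm_results, deg_lists = {}, {}, {}
        for contrast in STANDARD_CONTRASTS:
            de = run_contrast(expression, sheet, contrast)
            de_results[contrast.name] = de
            deg_lists[contrast.name] = select_deg(de, config.p_threshold)
            emit(f"de_{contrast.name}.tsv", lambda p, de=de: write_table(de, p))
            dm = run_contrast(methylation, sheet, contrast)
            dm_results[contrast.name] = dm
            emit(f"dm_{contrast.name}.tsv", lambda p, dm=dm: write_table(dm, p))
        for name, degs in deg_lists.items():
            emit(f"deg_{name}.txt",
                 lambda p, degs=degs: p.write_text("".join(g + "\n" for g in degs)))
        manifest.stage_seconds[stage] = time.perf_counter() - t0

        stage = "enrichment"
        t0 = time.perf_counter()
        universe = list(expression.feature_ids)
        k, fold, p = overlap_test(
            deg_lists["LRE_w10_vs_w0"], deg_lists["RES_w10_vs_w0"], universe
        )
        overlap_df = pd.DataFrame(
            [{"list_a": "LRE_w10_vs_w0", "list_b": "RES_w10_vs_w0",
              "overlap_k": k, "fold_enrichment": fold, "p_value": p}]
        )
        emit("overlap.tsv", lambda p_: write_table(overlap_df, p_))
        for name, degs in deg_lists.items():
            rows = term_enrichment(
                degs, universe, genesets,
                min_count=config.min_count, p_threshold=config.p_threshold,
                mode=config.enrichment_mode,
            )
            emit(f"enrichment_{name}.tsv",
                 lambda p_, rows=rows: write_table(enrichment_table(rows), p_))
        manifest.stage_seconds[stage] = time.perf_counter() - t0

        stage = "stability_lasso"
        t0 = time.perf_counter()
        baseline_degs = deg_lists["RES_vs_LRE_w0"]
        if not baseline_degs:
            raise DataError("no baseline DEGs; stability-LASSO has no design")
        w0_samples = sheet.table[sheet.table["timepoint"] == "w0"]
        X = (
            expression.subset_features(baseline_degs)
            .subset_samples(w0_samples["sample_id"].tolist())
            .to_frame()
            .T
        )
        X.index = w0_samples["subject_id"].tolist()
        y = pd.Series(
            phenotype.set_index("subject_id")["fc"].reindex(X.index), name="matsuda_fc"
        )
        stability = stability_run(
            X, y, sheet, n_iter=config.n_iter, master_seed=config.seed,
            tol=config.success_tol, min_frac=config.success_min_frac,
            cv_folds=config.cv_folds,
        )
        emit("stability.tsv", lambda p: write_table(stability, p))
        emit("iterations.log",
             lambda p: write_table(stability.iterations, p))
        markers = top_markers(stability, config.n_top) if stability.n_successful else None
        if markers is not None:
            emit("top_markers.tsv", lambda p: write_table(markers, p))
        manifest.stage_seconds[stage] = time.perf_counter() - t0

        stage = "integration"
        t0 = time.perf_counter()
        mapping = map_cpgs_to_genes(annotation, config.integration_region)
        promoter_map = map_cpgs_to_genes(annotation, "promoter")
        fractions = []
        for name in ("RES_vs_LRE_w0", "LRE_w10_vs_w0", "RES_w10_vs_w0"):
            degs = deg_lists[name]
            if not degs:
                manifest.warnings.append(f"integration skipped for {name}: no DEGs")
                continue
            integ = flag_epigenetic_regulation(
                degs, dm_results[name], mapping,
                expression_effects=de_results[name].table["beta_hat"],
                min_cpgs=config.integration_min_cpgs,
                p_threshold=config.p_threshold,
                require_inverse_promoter=config.integration_require_inverse,
                promoter_cpgs=promoter_map,
            )
            emit(f"integration_{name}.tsv", lambda p, integ=integ: write_table(integ, p))
            fractions.append(
                {"contrast": name, "supported": integ.supported_count,
                 "degs": integ.deg_count, "fraction": integ.fraction}
            )
        emit("integration_summary.tsv",
             lambda p: write_table(pd.DataFrame(fractions), p))
        if markers is not None:
            support = marker_methylation_support(
                list(markers.index), dm_results["RES_vs_LRE_w0"], promoter_map,
                expression_effects=de_results["RES_vs_LRE_w0"].table["beta_hat"],
                min_cpgs=config.marker_min_cpgs, p_threshold=config.p_threshold,
            )
            emit("marker_promoter_support.tsv", lambda p: write_table(support, p))
        manifest.stage_seconds[stage] = time.perf_counter() - t0

        stage = "clustering"
        t0 = time.perf_counter()
        if config.cluster_genes:
            labels = cluster_profiles(expression, sheet, config.cluster_genes, config.cluster_k)
            emit("clusters.tsv",
                 lambda p: write_table(labels.to_frame().rename_axis("gene_id"), p))
        else:
            logger.info("no cluster gene subset supplied; clustering stage skipped")
            manifest.warnings.append("clustering skipped: no gene subset supplied")
        manifest.stage_seconds[stage] = time.perf_counter() - t0
    except Exception as exc:
        exc.args = (f"[stage {stage}, seed {config.seed}] {exc}",)
        raise

    for path in written:
        manifest.files[path.name] = _sha256(path)
    manifest.write(outdir / "manifest.json")
    return manifest
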