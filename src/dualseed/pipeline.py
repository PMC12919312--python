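"""End-to-end orchestration of the dual-seed targetome analysis.

Stages: load transcripts and miRNAs -> normalize mRNA (median-of-ratios,
FPKM, log2(1+FPKM)) and miRNA (RPM, log2(1+RPM)) counts -> abundance
filters (99% cumulative expression for the gene universe and the top-miRNA
panel) -> per-gene Spearman anticorrelation with the focal canonical miRNA
(BH-adjusted) -> seed-site scanning and target sets -> enrichment odds
ratios, canonical-vs-isomiR Jaccard tables, extension ratios and the
seed/no-seed correlation comparison. Outputs are TSV tables plus a JSON
manifest (config hash, seed, versions) that makes a run reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import time
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import (
    GroupComparison,
    compare_groups,
    significant_anticorrelated,
    spearman_table,
)
from .expression import (
    ExpressionMatrix,
    cumulative_abundance_filter,
    expressed_above,
    log2p1,
    normalize_counts,
    read_counts_tsv,
    read_sample_sheet,
    select_samples,
    size_factors,
    to_fpkm,
    to_rpm,
)
from .isomir import IsomiR, MatureMiRNA, make_extended_motif, read_mature_fasta
from .overlap import (
    OverlapResult,
    build_enrichment_table,
    extension_results_frame,
    jaccard_index,
    odds_ratio_fisher,
    overlap_profile,
    overlap_results_frame,
    percentile_rank,
)
from .scan import (
    POLICIES,
    REGIONS,
    build_target_set,
    collect_sites,
    extension_stats,
    gene_exon_lengths,
    load_transcripts,
    select_representative,
    sites_to_frame,
)

__all__ = ["ConfigError", "StageError", "PipelineConfig", "PipelineResult", "run_scan", "run_full"]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or incomplete pipeline configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed on valid configuration."""


_PATH_FIELDS = (
    "transcript_fasta",
    "gtf",
    "mature_fasta",
    "mrna_counts",
    "mirna_counts",
    "sample_sheet",
    "downregulated_list",
)


@dataclass(frozen=True)
class PipelineConfig:
    """All inputs, thresholds and knobs of one analysis run."""

    transcript_fasta: str
    gtf: str
    mature_fasta: str
    mrna_counts: str
    mirna_counts: str
    sample_sheet: str
    downregulated_list: str
    outdir: str = "results"
    focal_mirna: str = "hsa-miR-93-5p"
    isomir_shifts: tuple[int, ...] = (3, 4)
    extension_shift: int = 4
    region: str = "full_mrna"
    policy: str = "longest_spliced"
    abundance_fraction: float = 0.99
    expression_threshold: float = 1.0
    alpha: float = 0.05
    sample_type: str = "primary tumor"
    strip_versions: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: expected a mapping of configuration keys")
        unknown = set(raw) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ConfigError(f"{path}: unknown configuration keys {sorted(unknown)}")
        if "isomir_shifts" in raw:
            raw["isomir_shifts"] = tuple(raw["isomir_shifts"])
        return cls(**raw)

    def validate(self) -> None:
        for name in _PATH_FIELDS:
            path = Path(getattr(self, name))
            if not path.is_file():
                raise ConfigError(f"{name}: file not found: {path}")
        if self.region not in REGIONS:
            raise ConfigError(f"region must be one of {REGIONS}, got {self.region!r}")
        if self.policy not in POLICIES:
            raise ConfigError(f"policy must be one of {POLICIES}, got {self.policy!r}")
        if not (0 < self.abundance_fraction <= 1):
            raise ConfigError("abundance_fraction must be in (0, 1]")
        if not (0 < self.alpha < 1):
            raise ConfigError("alpha must be in (0, 1)")
        if self.extension_shift < 1:
            raise ConfigError("extension_shift must be >= 1")

    def sha256(self) -> str:
        blob = yaml.safe_dump(_jsonable(asdict(self)), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


@dataclass
class PipelineResult:
    """In-memory results of a full run (everything the TSV outputs contain)."""

    config: PipelineConfig
    n_universe: int
    n_top_mirnas: int
    association: pd.DataFrame
    target_table: pd.DataFrame  # downregulated-list genes, supplementary-style columns
    n_downregulated: int
    n_expressed: int
    n_expressed_with_6mer: int
    enrichment: pd.DataFrame
    jaccard_tables: dict[int, pd.DataFrame]
    focal_overlap: dict[int, OverlapResult]
    focal_percentile: dict[int, float]
    extension_table: pd.DataFrame
    seed_comparison: GroupComparison | None
    outputs: dict[str, Path] = field(default_factory=dict)


def _timed(stage: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", stage)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is None:
                logger.info("stage %s: done in %.1fs", stage, dt)
            else:
                logger.error("stage %s: failed after %.1fs: %s", stage, dt, exc)
            return False

    return _Timer()


def _load_inputs(config: PipelineConfig):
    mirnas = read_mature_fasta(config.mature_fasta)
    if config.focal_mirna not in mirnas:
        raise ConfigError(f"focal miRNA {config.focal_mirna!r} absent from {config.mature_fasta}")
    records = load_transcripts(config.transcript_fasta, config.gtf, config.strip_versions)
    reps = select_representative(records, config.policy)
    return mirnas, records, reps


def _normalized_matrices(config: PipelineConfig):
    sheet = read_sample_sheet(config.sample_sheet)
    lengths = gene_exon_lengths(config.gtf, config.strip_versions)

    mrna_raw = select_samples(read_counts_tsv(config.mrna_counts), sheet, config.sample_type)
    mrna_norm = normalize_counts(mrna_raw, size_factors(mrna_raw))
    mrna_fpkm = to_fpkm(mrna_norm, lengths)
    mrna_log = log2p1(mrna_fpkm)

    mirna_raw = select_samples(read_counts_tsv(config.mirna_counts), sheet, config.sample_type)
    mirna_norm = normalize_counts(mirna_raw, size_factors(mirna_raw))
    mirna_rpm = to_rpm(mirna_norm)
    mirna_log = log2p1(mirna_rpm)
    return mrna_fpkm, mrna_log, mirna_rpm, mirna_log


def _focal_motifs(config: PipelineConfig, mirnas: Mapping[str, MatureMiRNA]):
    focal = mirnas[config.focal_mirna]
    canonical = IsomiR(focal)
    motifs = {"canonical_6mer": canonical.seed_motif("6mer")}
    for shift in config.isomir_shifts:
        motifs[f"iso+{shift}_7mer-m8"] = IsomiR(focal, shift5=shift).seed_motif("7mer-m8")
    extended = make_extended_motif(focal, config.extension_shift)
    return focal, motifs, extended


def run_scan(config: PipelineConfig, outdir: str | Path | None = None) -> dict[str, Path]:
    """Scan the transcriptome for the focal miRNA's seed sites; write TSVs."""
    config.validate()
    outdir = Path(outdir or config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with _timed("scan"):
        mirnas, _, reps = _load_inputs(config)
        focal, motifs, extended = _focal_motifs(config, mirnas)
        motif_list = list(motifs.values())
        ext_map = {motifs["canonical_6mer"].motif_id: extended}
        sites = collect_sites(motif_list, reps, config.region, ext_map)
        sites_df = sites_to_frame(sites)
        target_rows = []
        for motif in motif_list:
            ts = build_target_set(focal.name, motif, reps, config.region)
            target_rows.extend(
                {"mirna_label": ts.mirna_label, "seed_type": ts.seed_type,
                 "region": ts.region, "gene_id": g}
                for g in sorted(ts.genes)
            )
        targets_df = pd.DataFrame(
            target_rows, columns=["mirna_label", "seed_type", "region", "gene_id"]
        )
    paths = {
        "sites": outdir / "sites.tsv",
        "target_sets": outdir / "target_sets.tsv",
    }
    sites_df.to_csv(paths["sites"], sep="\t", index=False, na_rep="NA")
    targets_df.to_csv(paths["target_sets"], sep="\t", index=False, na_rep="NA")
    return paths


def run_full(config: PipelineConfig, write: bool = True) -> PipelineResult:
    """Execute every stage and (optionally) write all output tables."""
    config.validate()

    with _timed("load"):
        mirnas, _, reps = _load_inputs(config)
        focal, _, extended = _focal_motifs(config, mirnas)
        downreg = [
            line.split("\t")[0].strip()
            for line in Path(config.downregulated_list).read_text().splitlines()[0:]
            if line.strip() and not line.lower().startswith("gene_id") and not line.startswith("#")
        ]
        if not downreg:
            raise StageError("downregulated gene list is empty")

    with _timed("normalize"):
        mrna_fpkm, mrna_log, mirna_rpm, mirna_log = _normalized_matrices(config)
        gene_filter = cumulative_abundance_filter(mrna_fpkm, config.abundance_fraction)
        universe = sorted(set(gene_filter.kept_ids) & set(reps))
        if not universe:
            raise StageError(
                "gene universe empty after the cumulative abundance filter "
                "intersected with annotated transcripts"
            )
        mirna_filter = cumulative_abundance_filter(mirna_rpm, config.abundance_fraction)
        top_mirnas = [m for m in mirna_filter.kept_ids if m in mirnas]
        if config.focal_mirna not in top_mirnas:
            top_mirnas.append(config.focal_mirna)

    with _timed("associate"):
        if config.focal_mirna not in mirna_log.row_ids:
            raise StageError(f"focal miRNA {config.focal_mirna!r} not in the miRNA count matrix")
        focal_vec = mirna_log.values.loc[config.focal_mirna]
        association = spearman_table(mrna_log, focal_vec, genes=universe)
        anticorrelated = significant_anticorrelated(association, config.alpha)

    with _timed("scan"):
        reps_universe = {g: reps[g] for g in universe}
        canonical_set = build_target_set(
            focal.name, IsomiR(focal).seed_motif("6mer"), reps_universe, config.region
        )
        iso_sets = {
            shift: build_target_set(
                f"{focal.name}|+{shift}",
                IsomiR(focal, shift5=shift).seed_motif("7mer-m8"),
                reps_universe,
                config.region,
            )
            for shift in config.isomir_shifts
        }

    with _timed("enrich"):
        expressed, not_expressed = expressed_above(
            mrna_log, downreg, config.expression_threshold
        )
        focal_set = sorted(set(expressed) & set(universe))
        assoc_universe = set(association.index[~association["excluded"]])
        enrich_rows = []
        if focal_set:
            t1 = build_enrichment_table(
                set(focal_set) & assoc_universe, anticorrelated, assoc_universe
            )
            or1, p1 = odds_ratio_fisher(t1)
            enrich_rows.append(
                {"comparison": "downregulated_vs_anticorrelated", "a": t1.a, "b": t1.b,
                 "c": t1.c, "d": t1.d, "odds_ratio": or1, "p_value": p1}
            )
            t2 = build_enrichment_table(set(focal_set), canonical_set.genes, set(universe))
            or2, p2 = odds_ratio_fisher(t2)
            enrich_rows.append(
                {"comparison": "downregulated_vs_canonical_6mer", "a": t2.a, "b": t2.b,
                 "c": t2.c, "d": t2.d, "odds_ratio": or2, "p_value": p2}
            )
        enrichment = pd.DataFrame(
            enrich_rows,
            columns=["comparison", "a", "b", "c", "d", "odds_ratio", "p_value"],
        )
        n_expressed_with_6mer = len(set(expressed) & canonical_set.genes)

        with_seed = canonical_set.genes & assoc_universe
        without_seed = assoc_universe - canonical_set.genes
        seed_comparison = None
        if with_seed and without_seed:
            seed_comparison = compare_groups(association, with_seed, without_seed)

    with _timed("overlap"):
        jaccard_tables: dict[int, pd.DataFrame] = {}
        focal_overlap: dict[int, OverlapResult] = {}
        focal_percentile: dict[int, float] = {}
        extension_results: list[OverlapResult] = []
        for shift in config.isomir_shifts:
            results = []
            for name in top_mirnas:
                mirna_obj = mirnas[name]
                if len(mirna_obj.sequence) < max(shift + 8, config.extension_shift + 8):
                    continue
                set6 = build_target_set(
                    name, IsomiR(mirna_obj).seed_motif("6mer"), reps_universe, config.region
                )
                set7 = build_target_set(
                    name,
                    IsomiR(mirna_obj, shift5=shift).seed_motif("7mer-m8"),
                    reps_universe,
                    config.region,
                )
                ext = None
                if shift == config.extension_shift:
                    ext = extension_stats(
                        IsomiR(mirna_obj).seed_motif("6mer"),
                        make_extended_motif(mirna_obj, config.extension_shift),
                        reps_universe,
                        config.region,
                    )
                result = overlap_profile(name, shift, set6.genes, set7.genes, ext)
                results.append(result)
                if name == config.focal_mirna:
                    focal_overlap[shift] = result
            jaccard_tables[shift] = overlap_results_frame(results)
            if shift == config.extension_shift:
                extension_results = results
            if config.focal_mirna in {r.mirna_label for r in results}:
                others = [
                    r.jaccard for r in results
                    if r.mirna_label != config.focal_mirna and not math.isnan(r.jaccard)
                ]
                if others:
                    focal_percentile[shift] = percentile_rank(
                        focal_overlap[shift].jaccard, others
                    )
        extension_table = extension_results_frame(extension_results)

    with _timed("report"):
        # seed flags are sequence properties: evaluate them on every annotated
        # transcript, not only the expression-filtered universe
        downreg_reps = {g: reps[g] for g in downreg if g in reps}
        iso_flags = {
            shift: build_target_set(
                f"{focal.name}|+{shift}",
                IsomiR(focal, shift5=shift).seed_motif("7mer-m8"),
                downreg_reps,
                config.region,
            ).genes
            if downreg_reps
            else set()
            for shift in config.isomir_shifts
        }
        canonical_flags = (
            build_target_set(
                focal.name, IsomiR(focal).seed_motif("6mer"), downreg_reps, config.region
            ).genes
            if downreg_reps
            else set()
        )
        medians = mrna_log.values.median(axis=1)
        target_table = pd.DataFrame(
            {
                "gene_id": downreg,
                "median_log2_fpkm": [float(medians.get(g, 0.0)) for g in downreg],
                "expressed": [g in set(expressed) for g in downreg],
                "Correlation_canonical": [
                    float(association["rho"].get(g, np.nan)) for g in downreg
                ],
                "Padj": [float(association["padj"].get(g, np.nan)) for g in downreg],
                "Seed_canonical": [g in canonical_flags for g in downreg],
                **{
                    f"Seed_iso_{shift}": [g in iso_flags[shift] for g in downreg]
                    for shift in sorted(config.isomir_shifts, reverse=True)
                },
            }
        )

    result = PipelineResult(
        config=config,
        n_universe=len(universe),
        n_top_mirnas=len(top_mirnas),
        association=association,
        target_table=target_table,
        n_downregulated=len(downreg),
        n_expressed=len(expressed),
        n_expressed_with_6mer=n_expressed_with_6mer,
        enrichment=enrichment,
        jaccard_tables=jaccard_tables,
        focal_overlap=focal_overlap,
        focal_percentile=focal_percentile,
        extension_table=extension_table,
        seed_comparison=seed_comparison,
    )
    if write:
        result.outputs = _write_outputs(result)
    return result


def _write_outputs(result: PipelineResult) -> dict[str, Path]:
    outdir = Path(result.config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def write(name: str, df: pd.DataFrame, index: bool = False) -> None:
        path = outdir / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=index, na_rep="NA")
        paths[name] = path

    write("association", result.association, index=True)
    write("target_genes", result.target_table)
    write("enrichment", result.enrichment)
    for shift, table in result.jaccard_tables.items():
        write(f"jaccard_plus{shift}", table)
    write("extension", result.extension_table)

    comparison = result.seed_comparison
    manifest = {
        "package": "dualseed",
        "version": __version__,
        "seed": result.config.seed,
        "config": _jsonable(asdict(result.config)),
        "config_sha256": result.config.sha256(),
        "n_universe": result.n_universe,
        "n_top_mirnas": result.n_top_mirnas,
        "n_downregulated": result.n_downregulated,
        "n_expressed": result.n_expressed,
        "n_expressed_with_6mer": result.n_expressed_with_6mer,
        "focal_jaccard": {
            str(k): _jsonable(v.jaccard) for k, v in result.focal_overlap.items()
        },
        "focal_percentile": _jsonable(result.focal_percentile),
        "seed_comparison_p": comparison.p_two_sided if comparison else None,
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    paths["manifest"] = manifest_path
    return paths
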