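"""End-to-end runs: phenotyping chain and genetics chain.

``run_phenotyping`` chains imaging -> diversity statistics -> clustering
over a manifest of scan files; ``run_genetics`` chains expression screening
and candidate-interval construction and intersects the two candidate lists
by gene coordinates (the convergence step that pins a trait-linked gene
inside an associated genomic window).

Every output CSV/TSV starts with provenance comment lines carrying the
package version, the seed, and a hash of the effective configuration, so a
rerun can be matched to its inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from . import __version__
from .clustering import cluster_accessions, cut_tree, summarize_groups
from .diversity import accession_means, stats_table
from .imaging import InputError, SegmentationConfig, extract_features, read_scan
from .intervals import (
    IntervalConfig,
    annotate_genes,
    build_intervals,
    candidate_snps,
    write_bed,
)
from .screening import ScreeningConfig, intersect_traits, screen_trait, zscore_matrix

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Stage parameters of a full run."""

    dpi: float = 600.0
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    cluster_linkage: str = "ward"
    cluster_standardize: bool = True
    cut_height: float | None = None
    cut_k: int | None = 4
    screening: ScreeningConfig = field(default_factory=ScreeningConfig)
    intervals: IntervalConfig = field(default_factory=IntervalConfig)
    seed: int = 0

    def hash(self) -> str:
        blob = json.dumps(_serializable(asdict(self)), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _serializable(obj: Any) -> Any:
    if isinstance(obj, Mapping):
        return {str(k): _serializable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_serializable(v) for v in obj]
    return obj if isinstance(obj, (str, int, float, bool, type(None))) else str(obj)


def write_table(df: pd.DataFrame, path: str | Path, cfg: RunConfig, index: bool = False) -> None:
    """Write a CSV/TSV with provenance header comments."""
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    with open(path, "w") as fh:
        fh.write(f"# budmetrics {__version__} | seed={cfg.seed} | config={cfg.hash()}\n")
        df.to_csv(fh, sep=sep, index=index)


def run_phenotyping(
    manifest: pd.DataFrame | str | Path,
    cfg: RunConfig,
    outdir: str | Path,
) -> dict[str, Any]:
    """Image batch -> feature table -> summary statistics -> clusters.

    ``manifest`` has columns ``path, accession_id`` and optionally ``dpi``
    (falling back to ``cfg.dpi``) and ``region``.  Per-file read failures
    are logged and skipped; the run continues and reports the failure count.
    """
    if not isinstance(manifest, pd.DataFrame):
        manifest = pd.read_csv(manifest, comment="#")
    if not {"path", "accession_id"}.issubset(manifest.columns):
        raise InputError("manifest needs columns: path, accession_id")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    images, n_failed = [], 0
    for _, row in manifest.iterrows():
        dpi = float(row["dpi"]) if "dpi" in manifest.columns and pd.notna(row.get("dpi")) else cfg.dpi
        try:
            images.append(read_scan(row["path"], dpi=dpi, accession_id=str(row["accession_id"])))
        except InputError:
            logger.exception("skipping unreadable scan %s", row["path"])
            n_failed += 1
    features = extract_features(images, cfg.segmentation)
    write_table(features, outdir / "features.csv", cfg)

    result: dict[str, Any] = {"features": features, "n_failed": n_failed}
    if len(features):
        long = features.melt(
            id_vars=["accession_id", "bud_index"],
            value_vars=["length_cm", "width_cm", "perimeter_cm", "area_cm2"],
            var_name="trait",
            value_name="value",
        )
        long["trait"] = long["trait"].str.replace(r"_cm2?$", "", regex=True)
        try:
            table = stats_table(long)
            write_table(table, outdir / "trait_stats.csv", cfg)
            result["stats"] = table
        except Exception:  # noqa: BLE001 - tiny batches may not support every stat
            logger.exception("summary statistics unavailable for this batch")
        means = accession_means(long)
        if len(means) >= 2 and not means.isna().any().any():
            tree = cluster_accessions(means, cfg.cluster_linkage, cfg.cluster_standardize)
            k = min(cfg.cut_k, len(means)) if cfg.cut_k else None
            assignment = cut_tree(tree, height=cfg.cut_height, k=k)
            regions = None
            if "region" in manifest.columns:
                regions = (
                    manifest.drop_duplicates("accession_id")
                    .set_index("accession_id")["region"]
                    .reindex(means.index)
                )
            summary = summarize_groups(assignment, means, regions)
            write_table(assignment.rename("group").to_frame(), outdir / "clusters.csv", cfg, index=True)
            write_table(summary["groups"], outdir / "cluster_summary.csv", cfg, index=True)
            result["clusters"] = assignment
            result["cluster_summary"] = summary
    return result


def run_genetics(
    tpm: pd.DataFrame,
    sample_traits: pd.DataFrame,
    groups: pd.Series,
    scans: Mapping[str, pd.DataFrame],
    genes: pd.DataFrame,
    cfg: RunConfig,
    outdir: str | Path,
) -> dict[str, Any]:
    """Expression screen + interval construction + gene-level convergence.

    ``sample_traits`` is a sample x trait table for the extreme panel;
    ``genes`` carries GFF3-derived gene coordinates (``gene_id, chrom,
    start, end``).  The joint report lists screened genes whose annotated
    span overlaps a candidate interval; screened genes absent from the
    annotation are excluded with a warning.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    per_trait: dict[str, list[str]] = {}
    for trait in sample_traits.columns:
        per_trait[trait] = screen_trait(tpm, sample_traits[trait], groups, cfg.screening)
    common, venn = intersect_traits(per_trait)
    write_table(venn, outdir / "venn_counts.csv", cfg)
    write_table(pd.DataFrame({"gene_id": common}), outdir / "screened_genes.csv", cfg)
    if common:
        write_table(zscore_matrix(tpm, common), outdir / "zscore_matrix.tsv", cfg, index=True)

    cands = candidate_snps(scans, cfg.intervals)
    ivs = build_intervals(cands, cfg.intervals)
    annotated, summary = annotate_genes(ivs, genes)
    write_bed(ivs, outdir / "intervals.bed")
    flat = annotated.copy()
    flat["snps"] = flat["snps"].map(lambda xs: ";".join(map(str, xs)))
    flat["traits"] = flat["traits"].map(";".join)
    flat["genes"] = flat["genes"].map(";".join)
    write_table(flat, outdir / "intervals_annotated.tsv", cfg)

    interval_genes = set().union(*annotated["genes"].map(set)) if len(annotated) else set()
    known = set(genes["gene_id"])
    unplaced = [g for g in common if g not in known]
    if unplaced:
        logger.warning("%d screened genes missing from the annotation: %s", len(unplaced), unplaced)
    joint = sorted((set(common) & known) & interval_genes)
    write_table(pd.DataFrame({"gene_id": joint}), outdir / "joint_candidates.csv", cfg)
    return {
        "per_trait": per_trait,
        "intersection": common,
        "venn": venn,
        "intervals": annotated,
        "interval_summary": summary,
        "joint_candidates": joint,
    }
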