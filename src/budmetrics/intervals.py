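"""GWAS post-processing: candidate intervals and genotype stratification.

Consumes per-trait SNP association scans (``chrom, pos, p``) produced by an
external mixed-model engine and applies the candidate-interval procedure:

1. keep SNPs significant (``p < alpha``) in at least ``min_traits`` traits;
2. flank each candidate SNP by ``F`` bp (clipped to the chromosome) and
   merge overlapping or book-ended intervals per chromosome;
3. annotate merged intervals with overlapping genes from a GFF3.

Coordinates are 1-based inclusive internally (GFF/VCF convention); BED
export is 0-based half-open.  A separate operation stratifies accession
phenotypes by genotype class at a lead SNP, with one-way ANOVA, Tukey's HSD
(Tukey-Kramer for unbalanced groups) and a compact letter display.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import gffutils
import networkx as nx
import numpy as np
import pandas as pd
from cyvcf2 import VCF
from scipy import stats

from .imaging import InputError, ValidationError

logger = logging.getLogger(__name__)

INTERVAL_COLUMNS = ["chrom", "start", "end", "n_snps", "snps", "traits"]


@dataclass
class IntervalConfig:
    """Candidate-interval construction parameters.

    ``alpha`` defaults to 1e-6 (a genome-wide -log10 P = 6 line);
    ``min_traits`` = 2 keeps only loci supported by at least two bud size
    traits; ``flank`` = 100 kb on each side of a candidate SNP.
    """

    alpha: float = 1e-6
    min_traits: int = 2
    flank: int = 100_000
    chrom_lengths: Mapping[str, int] = field(default_factory=dict)
    merge_bookended: bool = True

    def __post_init__(self) -> None:
        if self.flank < 0:
            raise ValidationError("flank must be >= 0")
        if self.min_traits < 1:
            raise ValidationError("min_traits must be >= 1")
        if not 0 < self.alpha <= 1:
            raise ValidationError("alpha must be in (0, 1]")


def candidate_snps(
    scans: Mapping[str, pd.DataFrame], cfg: IntervalConfig
) -> pd.DataFrame:
    """SNPs significant in at least ``cfg.min_traits`` traits.

    ``scans`` maps trait -> DataFrame with columns ``chrom, pos, p``.
    Missing p-values are treated as non-significant (with a warning).
    Returns columns ``chrom, pos, traits`` (sorted trait list per SNP).
    """
    if not scans:
        raise ValidationError("need at least one trait scan")
    support: dict[tuple[str, int], list[str]] = {}
    for trait, df in scans.items():
        need = {"chrom", "pos", "p"}
        if not need.issubset(df.columns):
            raise ValidationError(f"scan for {trait} must have columns {sorted(need)}")
        n_missing = df["p"].isna().sum()
        if n_missing:
            logger.warning("%d missing p-values in %s scan treated as non-significant", n_missing, trait)
        hits = df[df["p"] < cfg.alpha]
        for chrom, pos in zip(hits["chrom"], hits["pos"]):
            support.setdefault((str(chrom), int(pos)), []).append(trait)
    rows = [
        {"chrom": c, "pos": p, "traits": sorted(traits)}
        for (c, p), traits in support.items()
        if len(traits) >= cfg.min_traits
    ]
    out = pd.DataFrame(rows, columns=["chrom", "pos", "traits"])
    return out.sort_values(["chrom", "pos"], ignore_index=True)


def build_intervals(snps: pd.DataFrame, cfg: IntervalConfig) -> pd.DataFrame:
    """Flank candidate SNPs and merge overlapping/book-ended intervals.

    Each SNP contributes ``[max(1, pos-F), min(chrom_len, pos+F)]``; per
    chromosome, intervals are sorted and merged when the next start is at
    most one past the current end (or strictly overlapping if
    ``merge_bookended`` is off).  Source SNP positions and supporting traits
    are unioned into each merged record.
    """
    if not cfg.chrom_lengths:
        raise ValidationError("cfg.chrom_lengths is required")
    records: list[dict] = []
    for _, row in snps.iterrows():
        chrom, pos = str(row["chrom"]), int(row["pos"])
        if chrom not in cfg.chrom_lengths:
            raise ValidationError(f"no length for chromosome {chrom}")
        length = cfg.chrom_lengths[chrom]
        if not 1 <= pos <= length:
            raise ValidationError(f"SNP {chrom}:{pos} beyond chromosome length {length}")
        records.append(
            {
                "chrom": chrom,
                "start": max(1, pos - cfg.flank),
                "end": min(length, pos + cfg.flank),
                "snps": [pos],
                "traits": set(row.get("traits", []) or []),
            }
        )
    merged = merge_interval_records(records, bookended=cfg.merge_bookended)
    for rec in merged:
        rec["snps"] = sorted(set(rec["snps"]))
        rec["n_snps"] = len(rec["snps"])
        rec["traits"] = sorted(rec["traits"])
    return pd.DataFrame(merged, columns=INTERVAL_COLUMNS)


def merge_interval_records(records: list[dict], bookended: bool = True) -> list[dict]:
    """Merge interval records per chromosome; idempotent.

    Records need ``chrom, start, end`` and may carry ``snps``/``traits``
    payloads, which are unioned into the merged record.  Book-ended merging
    joins intervals whose next start is exactly one past the current end.
    """
    merged: list[dict] = []
    gap = 1 if bookended else 0
    for chrom in sorted({r["chrom"] for r in records}):
        chrom_recs = sorted(
            (dict(r) for r in records if r["chrom"] == chrom),
            key=lambda r: (r["start"], r["end"]),
        )
        current = None
        for rec in chrom_recs:
            if current is not None and rec["start"] <= current["end"] + gap:
                current["end"] = max(current["end"], rec["end"])
                current["snps"] = current.get("snps", []) + rec.get("snps", [])
                current["traits"] = set(current.get("traits", set())) | set(rec.get("traits", set()))
            else:
                if current is not None:
                    merged.append(current)
                current = rec
        if current is not None:
            merged.append(current)
    return merged


# ---------------------------------------------------------------------------
# GFF3 gene annotation


def read_gff_genes(source: str | Path) -> pd.DataFrame:
    """Parse gene features from a GFF3 file or text.

    Returns columns ``gene_id, chrom, start, end`` (1-based inclusive).
    Malformed feature lines raise :class:`InputError` naming the line.
    """
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source):
        text = Path(source).read_text()
    else:
        text = source
    for i, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        if len(line.split("\t")) != 9:
            raise InputError(f"malformed GFF3 line {i}: expected 9 tab-separated fields")
    try:
        db = gffutils.create_db(
            text,
            dbfn=":memory:",
            from_string=True,
            merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as exc:  # noqa: BLE001
        raise InputError(f"GFF3 parse failure: {exc}") from exc
    rows = [
        {
            "gene_id": feat.id,
            "chrom": feat.seqid,
            "start": int(feat.start),
            "end": int(feat.end),
        }
        for feat in db.features_of_type("gene")
    ]
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])


def annotate_genes(
    intervals: pd.DataFrame, genes: pd.DataFrame | str | Path
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Attach overlapping gene IDs to each interval, with a global summary.

    A gene overlaps an interval when their 1-based inclusive spans share at
    least one bp.  The summary counts each gene once across intervals and
    totals the merged span.
    """
    if not isinstance(genes, pd.DataFrame):
        genes = read_gff_genes(genes)
    annotated = intervals.copy()
    gene_lists: list[list[str]] = []
    all_genes: set[str] = set()
    for _, iv in intervals.iterrows():
        sub = genes[
            (genes["chrom"] == iv["chrom"])
            & (genes["start"] <= iv["end"])
            & (genes["end"] >= iv["start"])
        ]
        ids = sorted(sub["gene_id"])
        gene_lists.append(ids)
        all_genes.update(ids)
    annotated["genes"] = gene_lists
    summary = {
        "n_intervals": int(len(intervals)),
        "total_span_bp": int((intervals["end"] - intervals["start"] + 1).sum()) if len(intervals) else 0,
        "n_genes": len(all_genes),
    }
    return annotated, summary


def write_bed(intervals: pd.DataFrame, path: str | Path) -> None:
    """Write merged intervals as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for _, iv in intervals.iterrows():
            name = ",".join(iv["traits"]) if isinstance(iv.get("traits"), list) else "."
            fh.write(f"{iv['chrom']}\t{iv['start'] - 1}\t{iv['end']}\t{name or '.'}\n")


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED file back into 1-based inclusive interval coordinates."""
    rows = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise InputError(f"malformed BED line {i}")
        rows.append(
            {"chrom": parts[0], "start": int(parts[1]) + 1, "end": int(parts[2])}
        )
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


# ---------------------------------------------------------------------------
# lead-SNP genotype stratification


@dataclass
class TraitStratification:
    """Genotype-class comparison of one trait at one SNP."""

    trait: str
    group_values: dict[str, np.ndarray]  # genotype label -> phenotype values
    anova_f: float
    anova_p: float
    tukey: pd.DataFrame  # columns: group1, group2, p
    letters: dict[str, str]  # compact letter display at the 0.05 level


def _compact_letters(
    groups: Sequence[str], tukey: pd.DataFrame, alpha: float = 0.05
) -> dict[str, str]:
    """Compact letter display: groups share a letter iff no significant pair.

    Letters correspond to maximal cliques of the non-significance graph,
    ordered by first group appearance.
    """
    g = nx.Graph()
    g.add_nodes_from(groups)
    for _, row in tukey.iterrows():
        if row["p"] >= alpha:
            g.add_edge(row["group1"], row["group2"])
    order = {name: i for i, name in enumerate(groups)}
    cliques = sorted(
        (sorted(c, key=order.get) for c in nx.find_cliques(g)),
        key=lambda c: order[c[0]],
    )
    letters: dict[str, list[str]] = {name: [] for name in groups}
    for i, clique in enumerate(cliques):
        letter = chr(ord("a") + i)
        for name in clique:
            letters[name].append(letter)
    return {name: "".join(ls) for name, ls in letters.items()}


def _genotype_classes(vcf_path: str | Path, chrom: str, pos: int) -> pd.Series:
    """Genotype class label per sample at one VCF site, plus allele dosages.

    Missing genotypes are excluded; multi-allelic sites are restricted to the
    two most frequent alleles (others excluded with a warning).
    """
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    variant = None
    for v in vcf:
        if v.CHROM == chrom and v.POS == pos:
            variant = v
            break
    if variant is None:
        raise ValidationError(f"SNP {chrom}:{pos} not found in {vcf_path}")
    alleles = [variant.REF] + list(variant.ALT)
    calls = np.array([gt[:2] for gt in variant.genotypes])  # (n, 2), -1 missing
    counts = np.bincount(calls[calls >= 0], minlength=len(alleles))
    keep = np.argsort(counts)[::-1][:2]
    if len(alleles) > 2:
        logger.warning(
            "multi-allelic site %s:%d restricted to alleles %s",
            chrom,
            pos,
            [alleles[i] for i in keep],
        )
    labels = {}
    a0, a1 = sorted(keep)
    for sample, call in zip(samples, calls):
        if (call < 0).any() or not set(call).issubset({a0, a1}):
            continue
        n_alt = int((call == a1).sum())
        pair = sorted([alleles[call[0]], alleles[call[1]]])
        labels[sample] = (n_alt, "/".join(pair))
    if len({lab for _, lab in labels.values()}) < 2:
        raise ValidationError(f"SNP {chrom}:{pos} is monomorphic among usable samples")
    series = pd.Series({s: lab for s, (_, lab) in labels.items()}, name="genotype")
    # Class order follows alt-allele dosage: REF/REF < REF/ALT < ALT/ALT.
    dosage = {lab: dose for dose, lab in labels.values()}
    return series, dosage


def stratify_by_genotype(
    vcf_path: str | Path,
    site: str,
    phenotypes: pd.DataFrame,
    alpha: float = 0.05,
) -> dict[str, TraitStratification]:
    """Stratify accession trait means by genotype class at a lead SNP.

    ``site`` is ``"chrom:pos"``; ``phenotypes`` is an accession x trait
    table of means.  For each trait: one-way ANOVA across genotype classes,
    all-pairs Tukey HSD p-values (studentized range; Tukey-Kramer under
    imbalance), and a compact letter display at ``alpha``.
    """
    try:
        chrom, pos_s = site.rsplit(":", 1)
        pos = int(pos_s)
    except ValueError as exc:
        raise ValidationError(f"site must be 'chrom:pos', got {site!r}") from exc
    classes, dosage = _genotype_classes(vcf_path, chrom, pos)
    missing = classes.index.difference(phenotypes.index)
    if len(missing):
        raise ValidationError(f"phenotypes missing for samples: {missing.tolist()}")
    order = sorted(classes.unique(), key=lambda lab: dosage[lab])
    grouped = {lab: classes.index[classes == lab] for lab in order}
    small = [lab for lab, idx in grouped.items() if len(idx) < 2]
    if len(grouped) - len(small) < 2:
        raise ValidationError("need >= 2 genotype classes with >= 2 samples each")
    if small:
        logger.warning("genotype classes with < 2 samples dropped: %s", small)
        grouped = {lab: idx for lab, idx in grouped.items() if len(idx) >= 2}
        order = [lab for lab in order if lab in grouped]

    out: dict[str, TraitStratification] = {}
    for trait in phenotypes.columns:
        arrays = {lab: phenotypes.loc[idx, trait].to_numpy(dtype=float) for lab, idx in grouped.items()}
        f_stat, p_val = stats.f_oneway(*arrays.values())
        hsd = stats.tukey_hsd(*arrays.values())
        pairs = [
            {"group1": order[i], "group2": order[j], "p": float(hsd.pvalue[i, j])}
            for i in range(len(order))
            for j in range(i + 1, len(order))
        ]
        tukey = pd.DataFrame(pairs, columns=["group1", "group2", "p"])
        out[trait] = TraitStratification(
            trait=trait,
            group_values=arrays,
            anova_f=float(f_stat),
            anova_p=float(p_val),
            tukey=tukey,
            letters=_compact_letters(order, tukey, alpha),
        )
    return out


def stratification_table(strat: dict[str, TraitStratification]) -> pd.DataFrame:
    """Tidy per-trait, per-genotype summary of a stratification result."""
    rows = []
    for trait, res in strat.items():
        for lab, vals in res.group_values.items():
            rows.append(
                {
                    "trait": trait,
                    "genotype": lab,
                    "n": len(vals),
                    "mean": float(np.mean(vals)),
                    "sd": float(np.std(vals, ddof=1)),
                    "anova_p": res.anova_p,
                    "letters": res.letters[lab],
                }
            )
    return pd.DataFrame(rows)
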