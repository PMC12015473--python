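"""Synthetic inputs with known ground truth for every pipeline stage.

The generators here stand in for data that cannot be shipped: scanner images
of buds, replicate phenotype tables, expression matrices, and association
scans.  Each generator plants a known truth (closed-form shape geometry,
variance components, linked genes, multi-trait peaks) so downstream modules
can be validated quantitatively rather than by eyeball.

Rendered shapes are straight stadiums, ellipses, and circles: all four size
features (length, width, perimeter, area) then have exact closed forms, which
is what makes them usable as morphometric oracles.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .imaging import CM_PER_INCH, ScanImage, ValidationError
from .reference import DEFAULT_REGIONS, TRAIT_REFERENCE, TRAITS

# ---------------------------------------------------------------------------
# scanner scenes


@dataclass
class ShapeSpec:
    """A bud-like shape with closed-form size features.

    ``length_cm`` is the overall caliper length (tip to tip), ``width_cm``
    the caliper width.  A stadium is a rectangle of length ``L - W`` capped
    by two semicircles of diameter ``W``; a circle is specified with
    ``length_cm == width_cm``.
    """

    kind: str  # {"stadium", "ellipse", "circle"}
    length_cm: float
    width_cm: float
    center_px: tuple[float, float]  # (row, col)
    angle_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("stadium", "ellipse", "circle"):
            raise ValidationError(f"unknown shape kind {self.kind!r}")
        if self.kind == "circle":
            self.width_cm = self.length_cm
        if not (self.length_cm >= self.width_cm > 0):
            raise ValidationError("require length >= width > 0")

    @property
    def area_true(self) -> float:
        L, W = self.length_cm, self.width_cm
        if self.kind == "stadium":
            a = L - W
            return a * W + np.pi * (W / 2) ** 2
        return np.pi * (L / 2) * (W / 2)  # ellipse / circle

    @property
    def perimeter_true(self) -> float:
        L, W = self.length_cm, self.width_cm
        if self.kind == "stadium":
            return 2 * (L - W) + np.pi * W
        # Ramanujan's ellipse approximation (relative error < 1e-6 at these
        # aspect ratios); exact for the circle.
        a, b = L / 2, W / 2
        h3 = 3 * ((a - b) / (a + b)) ** 2
        return np.pi * (a + b) * (1 + h3 / (10 + np.sqrt(4 - h3)))

    def truth_row(self) -> dict:
        return {
            "kind": self.kind,
            "length_cm": self.length_cm,
            "width_cm": self.width_cm,
            "perimeter_cm": self.perimeter_true,
            "area_cm2": self.area_true,
            "center_row": self.center_px[0],
            "center_col": self.center_px[1],
            "angle_deg": self.angle_deg,
        }


def _coverage(shape: ShapeSpec, dpi: float, canvas: tuple[int, int], supersample: int):
    """Binary mask of the shape on the canvas (crisp, supersampled edges).

    Returns ``(mask, (r0, c0))`` where mask covers the shape's padded
    bounding box placed at canvas offset ``(r0, c0)``.
    """
    px_per_cm = dpi / CM_PER_INCH
    half_diag = (shape.length_cm / 2) * px_per_cm + 3
    r_c, c_c = shape.center_px
    r0 = max(0, int(np.floor(r_c - half_diag)))
    c0 = max(0, int(np.floor(c_c - half_diag)))
    r1 = min(canvas[0], int(np.ceil(r_c + half_diag)) + 1)
    c1 = min(canvas[1], int(np.ceil(c_c + half_diag)) + 1)
    if r1 <= r0 or c1 <= c0:
        return np.zeros((0, 0), dtype=bool), (0, 0)

    n = supersample
    # Supersampled pixel-center offsets within each pixel.
    sub = (np.arange(n) + 0.5) / n - 0.5
    rows = (np.arange(r0, r1)[:, None] + sub[None, :]).ravel()
    cols = (np.arange(c0, c1)[:, None] + sub[None, :]).ravel()
    rr = rows[:, None] - r_c
    cc = cols[None, :] - c_c

    theta = np.deg2rad(shape.angle_deg)
    # Rotate into the shape frame: x along the length axis, y across.
    x = cc * np.cos(theta) + rr * np.sin(theta)
    y = -cc * np.sin(theta) + rr * np.cos(theta)

    L = shape.length_cm * px_per_cm
    W = shape.width_cm * px_per_cm
    if shape.kind == "stadium":
        a_half = (L - W) / 2
        dx = np.maximum(np.abs(x) - a_half, 0.0)
        inside = dx**2 + y**2 <= (W / 2) ** 2
    else:
        inside = (x / (L / 2)) ** 2 + (y / (W / 2)) ** 2 <= 1.0

    h, w = r1 - r0, c1 - c0
    frac = inside.reshape(h, n, w, n).mean(axis=(1, 3))
    return frac > 0.5, (r0, c0)


FOREGROUND_RGB = (110, 125, 62)  # olive green-brown, typical of a fresh bud
BACKGROUND_RGB = (9, 8, 10)  # light-absorbing cloth


def render_scene(
    shapes: Sequence[ShapeSpec],
    dpi: float = 600.0,
    canvas_px: tuple[int, int] = (1200, 1200),
    noise_sd: float = 4.0,
    seed: int = 0,
    accession_id: str = "",
    supersample: int = 4,
    margin_px: int = 10,
) -> tuple[ScanImage, pd.DataFrame]:
    """Render bud-like shapes on a noisy near-black background.

    Each shape is rasterized analytically on a ``supersample``-times finer
    grid, averaged, and thresholded at half coverage, so the digitized
    boundary sits within half a fine-grid cell of the true curve.  The truth
    table carries the closed-form length, width, perimeter and area of every
    shape.

    Raises
    ------
    ValidationError
        If any shape extends within ``margin_px`` of the canvas edge or two
        shapes overlap.
    """
    rng = np.random.default_rng(seed)
    h, w = canvas_px
    occupancy = np.zeros((h, w), dtype=np.int16)
    masks = []
    for i, shape in enumerate(shapes):
        mask, (r0, c0) = _coverage(shape, dpi, canvas_px, supersample)
        rows, cols = np.nonzero(mask)
        if mask.size == 0 or len(rows) == 0:
            raise ValidationError(f"shape {i} falls outside the canvas")
        if (
            rows.min() + r0 < margin_px
            or cols.min() + c0 < margin_px
            or rows.max() + r0 >= h - margin_px
            or cols.max() + c0 >= w - margin_px
        ):
            raise ValidationError(f"shape {i} violates the {margin_px}-px canvas margin")
        occupancy[r0 : r0 + mask.shape[0], c0 : c0 + mask.shape[1]] += mask
        masks.append((mask, r0, c0))
    if (occupancy > 1).any():
        bad = [
            i
            for i, (m, r0, c0) in enumerate(masks)
            if (occupancy[r0 : r0 + m.shape[0], c0 : c0 + m.shape[1]][m] > 1).any()
        ]
        raise ValidationError(f"overlapping shapes: {bad}")

    img = np.empty((h, w, 3), dtype=float)
    img[:] = BACKGROUND_RGB
    fg = occupancy > 0
    img[fg] = FOREGROUND_RGB
    img += rng.normal(0.0, noise_sd, size=img.shape)
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    truth = pd.DataFrame([s.truth_row() for s in shapes])
    scan = ScanImage(
        pixels=pixels,
        dpi=dpi,
        source_id=f"synthetic-scene-seed{seed}",
        accession_id=accession_id,
    )
    return scan, truth


def random_bud_shapes(
    n: int,
    dpi: float = 600.0,
    canvas_px: tuple[int, int] = (2000, 2000),
    length_range_cm: tuple[float, float] = (1.5, 3.5),
    aspect_range: tuple[float, float] = (4.0, 9.0),
    seed: int = 0,
    margin_px: int = 16,
    min_gap_px: int = 12,
) -> list[ShapeSpec]:
    """Draw ``n`` non-overlapping random stadium/ellipse bud shapes.

    Placement is rejection-sampled on bounding circles separated by
    ``min_gap_px``, so rendered shapes are guaranteed disjoint and clear of
    the canvas border.  The default length range stops at mid-sized buds so
    several shapes pack onto one canvas; single-shape scenes can use the
    full size range.
    """
    rng = np.random.default_rng(seed)
    px_per_cm = dpi / CM_PER_INCH
    shapes: list[ShapeSpec] = []
    centers: list[tuple[float, float, float]] = []  # row, col, radius_px
    attempts = 0
    while len(shapes) < n:
        attempts += 1
        if attempts > 20000:
            raise ValidationError(
                f"cannot place {n} shapes on a {canvas_px} canvas; enlarge it"
            )
        L = rng.uniform(*length_range_cm)
        W = L / rng.uniform(*aspect_range)
        radius = (L / 2) * px_per_cm + min_gap_px
        lo_r, hi_r = margin_px + radius, canvas_px[0] - margin_px - radius
        lo_c, hi_c = margin_px + radius, canvas_px[1] - margin_px - radius
        if hi_r <= lo_r or hi_c <= lo_c:
            raise ValidationError("canvas too small for requested shape sizes")
        r_c, c_c = rng.uniform(lo_r, hi_r), rng.uniform(lo_c, hi_c)
        if any(
            np.hypot(r_c - r0, c_c - c0) < radius + rad0 for r0, c0, rad0 in centers
        ):
            continue
        shapes.append(
            ShapeSpec(
                kind=rng.choice(["stadium", "ellipse"]),
                length_cm=float(L),
                width_cm=float(W),
                center_px=(float(r_c), float(c_c)),
                angle_deg=float(rng.uniform(0, 180)),
            )
        )
        centers.append((r_c, c_c, radius))
    return shapes


# ---------------------------------------------------------------------------
# replicate phenotypes


def _default_trait_params() -> dict[str, tuple[float, float]]:
    return {t: (TRAIT_REFERENCE.loc[t, "mean"], TRAIT_REFERENCE.loc[t, "sd"]) for t in TRAITS}


@dataclass
class PhenotypeSimSpec:
    """Accession-replicate phenotype simulation.

    Each accession draws a genetic value ``g ~ N(0, sigma_g^2)`` per trait;
    each replicate bud adds environmental noise ``e ~ N(0, sigma_e^2)``.  The
    broad-sense heritability of the simulated trait is
    ``h2 = sigma_g^2 / (sigma_g^2 + sigma_e^2)``.  ``sigma_e`` may be given
    directly (per trait) or derived from ``target_h2``.

    Defaults mirror the published panel: 280 accessions, 15 replicate buds
    each, trait means/SDs on the published scale, and per-trait published
    heritabilities.
    """

    n_accessions: int = 280
    replicates_per_accession: int = 15
    trait_params: Mapping[str, tuple[float, float]] = field(
        default_factory=_default_trait_params
    )  # trait -> (mu, sigma_g)
    target_h2: Mapping[str, float] | float | None = None  # default: published h2
    sigma_e: Mapping[str, float] | float | None = None  # overrides target_h2
    regions: Sequence[str] = tuple(DEFAULT_REGIONS)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_accessions < 1 or self.replicates_per_accession < 1:
            raise ValidationError("need >= 1 accession and >= 1 replicate")
        for t, (mu, sg) in self.trait_params.items():
            if sg < 0:
                raise ValidationError(f"sigma_g < 0 for trait {t}")
        if self.target_h2 is not None:
            for t in self.trait_params:
                h2 = self._h2_for(t)
                if not 0 < h2 <= 1:
                    raise ValidationError(f"target_h2 for {t} must be in (0, 1]")

    def _h2_for(self, trait: str) -> float:
        if isinstance(self.target_h2, Mapping):
            return float(self.target_h2[trait])
        if self.target_h2 is not None:
            return float(self.target_h2)
        return float(TRAIT_REFERENCE.loc[trait, "h2"]) if trait in TRAIT_REFERENCE.index else 0.75

    def sigma_e_for(self, trait: str) -> float:
        if self.sigma_e is not None:
            if isinstance(self.sigma_e, Mapping):
                return float(self.sigma_e[trait])
            return float(self.sigma_e)
        h2 = self._h2_for(trait)
        sigma_g = self.trait_params[trait][1]
        return sigma_g * np.sqrt((1 - h2) / h2)


def simulate_phenotypes(spec: PhenotypeSimSpec) -> pd.DataFrame:
    """Simulate a long-format replicate phenotype table.

    Returns columns ``accession_id, region, replicate, trait, value``.
    """
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_accessions, spec.replicates_per_accession
    accessions = [f"ACC{i + 1:04d}" for i in range(n)]
    regions = rng.choice(list(spec.regions), size=n)
    frames = []
    for trait, (mu, sigma_g) in spec.trait_params.items():
        sigma_e = spec.sigma_e_for(trait)
        g = rng.normal(0.0, sigma_g, size=n)
        e = rng.normal(0.0, sigma_e, size=(n, m))
        values = mu + g[:, None] + e
        frames.append(
            pd.DataFrame(
                {
                    "accession_id": np.repeat(accessions, m),
                    "region": np.repeat(regions, m),
                    "replicate": np.tile(np.arange(1, m + 1), n),
                    "trait": trait,
                    "value": values.ravel(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_trait_blobs(
    n_per_group: Sequence[int] = (114, 89, 67, 10),
    centers: np.ndarray | None = None,
    sd: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Accession trait means drawn from well-separated phenotype groups.

    Emulates a germplasm panel whose accessions fall into discrete bud-size
    classes (e.g. small-, medium-, and large-bud resources).  Returns the
    accession x trait matrix and the planted group label per accession.
    Default group sizes follow the published four-group partition.
    """
    rng = np.random.default_rng(seed)
    k = len(n_per_group)
    if centers is None:
        # Spread groups along a small-to-large bud-size axis.
        base = TRAIT_REFERENCE["mean"].to_numpy()
        scales = np.linspace(0.7, 1.6, k)
        centers = np.outer(scales, base)
    centers = np.asarray(centers, dtype=float)
    if centers.shape != (k, len(TRAITS)):
        raise ValidationError(f"centers must be {(k, len(TRAITS))}, got {centers.shape}")
    rows, labels = [], []
    for gi, ng in enumerate(n_per_group):
        rows.append(centers[gi] + rng.normal(0.0, sd, size=(ng, len(TRAITS))))
        labels += [gi] * ng
    X = np.vstack(rows)
    order = rng.permutation(len(X))  # interleave groups in accession order
    accessions = [f"ACC{i + 1:04d}" for i in range(len(X))]
    df = pd.DataFrame(X[order], index=accessions, columns=TRAITS)
    df.index.name = "accession_id"
    return df, pd.Series(np.asarray(labels)[order], index=accessions, name="blob")


# ---------------------------------------------------------------------------
# expression


@dataclass
class ExpressionSimSpec:
    """TPM matrix simulation for a 4-vs-4 extreme-accession design.

    Linked genes follow ``log2(TPM + 1) = intercept + slope * z`` where ``z``
    is the standardized bud-size trait, plus Gaussian noise; null genes draw
    a log-normal baseline independent of the trait.  Modeling the linkage on
    the log2(TPM+1) scale keeps TPM positive while making the planted signal
    approximately linear for the Pearson screen.

    ``noise_sd`` (log2 units) applies to every gene; 0.25 corresponds to
    ~19% multiplicative scatter between samples.
    """

    n_genes: int = 1000
    n_linked_genes: int = 30
    n_small: int = 4
    n_large: int = 4
    slope: float = 2.0
    linked_signs: Sequence[int] | None = None  # default: random +/-1 per gene
    baseline_log2_range: tuple[float, float] = (1.0, 8.0)
    noise_sd: float = 0.25
    trait_small: tuple[float, float] = (2.0, 0.10)  # mean, SD of small-bud trait
    trait_large: tuple[float, float] = (3.4, 0.12)  # ~1.7x larger, as observed
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_linked_genes > self.n_genes:
            raise ValidationError("n_linked_genes must be <= n_genes")
        if self.n_small + self.n_large < 3:
            raise ValidationError("need >= 3 samples for a correlation")
        if self.linked_signs is not None and len(self.linked_signs) != self.n_linked_genes:
            raise ValidationError("linked_signs length must equal n_linked_genes")


def simulate_expression(
    spec: ExpressionSimSpec,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Simulate (tpm, trait, truth).

    Returns the gene x sample TPM matrix, the per-sample bud-size trait, and
    a truth table with columns ``linked`` (bool) and ``sign`` (+1/-1/0).
    Sample names carry their group: ``S1..S4`` small, ``L1..L4`` large.
    """
    rng = np.random.default_rng(spec.seed)
    samples = [f"S{i + 1}" for i in range(spec.n_small)] + [
        f"L{i + 1}" for i in range(spec.n_large)
    ]
    trait = np.concatenate(
        [
            rng.normal(*spec.trait_small, size=spec.n_small),
            rng.normal(*spec.trait_large, size=spec.n_large),
        ]
    )
    z = (trait - trait.mean()) / trait.std(ddof=0)

    genes = [f"GENE{i + 1:05d}" for i in range(spec.n_genes)]
    linked = np.zeros(spec.n_genes, dtype=bool)
    linked[: spec.n_linked_genes] = True
    signs = np.zeros(spec.n_genes, dtype=int)
    if spec.linked_signs is not None:
        signs[linked] = np.asarray(spec.linked_signs, dtype=int)
    else:
        signs[linked] = rng.choice([-1, 1], size=spec.n_linked_genes)

    lo, hi = spec.baseline_log2_range
    intercept = rng.uniform(lo, hi, size=spec.n_genes)
    # Linked genes must stay expressed across their full swing so the planted
    # log2(TPM+1) relation is exactly linear (never clipped at zero TPM).
    if linked.any():
        swing = spec.slope * np.abs(z).max()
        intercept[linked] = rng.uniform(swing, swing + (hi - lo), size=linked.sum())
    log2x = intercept[:, None] + np.where(linked, signs * spec.slope, 0.0)[:, None] * z[None, :]
    log2x += rng.normal(0.0, spec.noise_sd, size=log2x.shape)
    tpm = np.maximum(np.exp2(log2x) - 1.0, 0.0)

    tpm_df = pd.DataFrame(tpm, index=pd.Index(genes, name="gene_id"), columns=samples)
    trait_s = pd.Series(trait, index=samples, name="bud_size")
    truth = pd.DataFrame(
        {"linked": linked, "sign": signs}, index=pd.Index(genes, name="gene_id")
    )
    return tpm_df, trait_s, truth


def sample_groups(tpm: pd.DataFrame) -> pd.Series:
    """Group labels ('small'/'large') inferred from simulated sample names."""
    return pd.Series(
        ["small" if s.startswith("S") else "large" for s in tpm.columns],
        index=tpm.columns,
        name="group",
    )


# ---------------------------------------------------------------------------
# association scans, gene annotation, genotypes


@dataclass
class PlantedPeak:
    """A planted association signal at one SNP for a subset of traits."""

    chrom: str
    pos: int
    traits: Sequence[str]
    neglog10_p: float = 8.0
    lead: bool = True


@dataclass
class AssocSimSpec:
    """Per-trait association-scan simulation with planted multi-trait peaks."""

    chrom_lengths: Mapping[str, int] = field(
        default_factory=lambda: {"Chr1": 2_000_000, "Chr10": 20_000_000}
    )
    snp_spacing: int = 10_000
    traits: Sequence[str] = tuple(TRAITS)
    peaks: Sequence[PlantedPeak] = ()
    gene_length: int = 2_000
    gene_spacing: int = 5_000
    n_samples: int = 90
    alt_allele_freq: float = 0.4
    genotype_effect_sd: float = 1.0  # phenotype shift per alt allele, in SDs
    seed: int = 0

    def __post_init__(self) -> None:
        for pk in self.peaks:
            if pk.chrom not in self.chrom_lengths:
                raise ValidationError(f"peak chromosome {pk.chrom} not in chrom_lengths")
            if not 1 <= pk.pos <= self.chrom_lengths[pk.chrom]:
                raise ValidationError(f"peak at {pk.chrom}:{pk.pos} outside chromosome")
            for t in pk.traits:
                if t not in self.traits:
                    raise ValidationError(f"peak trait {t} not simulated")


def simulate_association(
    spec: AssocSimSpec,
) -> tuple[dict[str, pd.DataFrame], str, str, pd.DataFrame]:
    """Simulate (per-trait scans, GFF3 text, VCF text, sample phenotypes).

    Scans are ``chrom, pos, p`` tables on a regular SNP grid with uniform
    background p-values; planted peaks overwrite p at their position for
    their member traits.  The GFF3 tiles genes along each chromosome.  The
    VCF holds one biallelic record per lead peak; genotypes shift the sample
    phenotypes additively (hom-ref < het < hom-alt per alt allele), giving a
    monotone genotype-phenotype pattern for stratification tests.
    """
    rng = np.random.default_rng(spec.seed)
    grids = {
        c: np.arange(spec.snp_spacing, ln + 1, spec.snp_spacing)
        for c, ln in spec.chrom_lengths.items()
    }
    # Insert exact peak positions not on the grid.
    for pk in spec.peaks:
        if pk.pos not in grids[pk.chrom]:
            grids[pk.chrom] = np.sort(np.append(grids[pk.chrom], pk.pos))

    scans: dict[str, pd.DataFrame] = {}
    for trait in spec.traits:
        frames = []
        for chrom, pos in grids.items():
            p = rng.uniform(size=len(pos))
            frames.append(pd.DataFrame({"chrom": chrom, "pos": pos, "p": p}))
        scan = pd.concat(frames, ignore_index=True)
        for pk in spec.peaks:
            if trait in pk.traits:
                at = (scan["chrom"] == pk.chrom) & (scan["pos"] == pk.pos)
                scan.loc[at, "p"] = 10.0 ** (-pk.neglog10_p)
        scans[trait] = scan

    gff = io.StringIO()
    gff.write("##gff-version 3\n")
    for chrom, ln in spec.chrom_lengths.items():
        gff.write(f"##sequence-region {chrom} 1 {ln}\n")
    for chrom, ln in spec.chrom_lengths.items():
        start, i = 1, 1
        while start + spec.gene_length - 1 <= ln:
            end = start + spec.gene_length - 1
            gid = f"{chrom}g{i:05d}"
            gff.write(
                f"{chrom}\tsynthetic\tgene\t{start}\t{end}\t.\t+\t.\tID={gid};Name={gid}\n"
            )
            start += spec.gene_length + spec.gene_spacing
            i += 1

    samples = [f"ACC{i + 1:04d}" for i in range(spec.n_samples)]
    leads = [pk for pk in spec.peaks if pk.lead]
    genotypes = {}
    for pk in leads:
        genotypes[(pk.chrom, pk.pos)] = rng.binomial(2, spec.alt_allele_freq, size=spec.n_samples)

    pheno = pd.DataFrame(index=pd.Index(samples, name="accession_id"))
    for trait in spec.traits:
        mu = float(TRAIT_REFERENCE.loc[trait, "mean"]) if trait in TRAIT_REFERENCE.index else 0.0
        sd = float(TRAIT_REFERENCE.loc[trait, "sd"]) if trait in TRAIT_REFERENCE.index else 1.0
        vals = mu + rng.normal(0.0, sd, size=spec.n_samples)
        for pk in leads:
            if trait in pk.traits:
                vals = vals + genotypes[(pk.chrom, pk.pos)] * spec.genotype_effect_sd * sd
        pheno[trait] = vals

    vcf = io.StringIO()
    vcf.write("##fileformat=VCFv4.2\n")
    for chrom, ln in spec.chrom_lengths.items():
        vcf.write(f"##contig=<ID={chrom},length={ln}>\n")
    vcf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    vcf.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
    vcf.write("\t".join(samples) + "\n")
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1"}
    for pk in sorted(leads, key=lambda p: (p.chrom, p.pos)):
        g = genotypes[(pk.chrom, pk.pos)]
        fields = [
            pk.chrom,
            str(pk.pos),
            f"{pk.chrom}:{pk.pos}",
            "A",
            "G",
            ".",
            "PASS",
            ".",
            "GT",
        ] + [gt_str[int(x)] for x in g]
        vcf.write("\t".join(fields) + "\n")

    return scans, gff.getvalue(), vcf.getvalue(), pheno
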