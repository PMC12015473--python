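"""Descriptive and genetic-diversity statistics for germplasm traits.

Per trait this module computes max, min, mean, sample SD, coefficient of
variation, the Shannon-Wiener diversity index H' over grading classes, a
broad-sense heritability from replicate buds, and a Shapiro-Wilk normality
test — the classical summary table of a germplasm phenotyping study.

H' uses the common germplasm grading convention: 10 classes anchored at the
trait mean, with class 1 below mu - 2*sigma, classes 2-9 as successive
0.5*sigma bands, and class 10 above mu + 2*sigma; H' = -sum p_i ln(p_i) in
nats.  For a near-normal trait this construction yields H' a little above
2.0, independent of the trait's location and scale.

Broad-sense heritability is estimated from clonal replicates by a one-way
random-effects decomposition: accessions are groups, replicate buds are
within-group observations, sigma_g^2 = (MS_between - MS_within) / n0 with n0
the effective replicate number, and h2 = sigma_g^2 / (sigma_g^2 + MS_within),
truncating negative variance estimates at zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .imaging import ValidationError

logger = logging.getLogger(__name__)

STATS_COLUMNS = ["trait", "max", "min", "mean", "sd", "cv_pct", "h_prime", "h2", "shapiro_p"]


@dataclass
class DiversityBinning:
    """Grading classes anchored at (mu, sigma): mu +/- 2 sigma in 0.5-sigma steps."""

    n_classes: int = 10

    def edges(self, mu: float, sigma: float) -> np.ndarray:
        """Interior class edges; classes 1 and n are the open tails."""
        if self.n_classes != 10:
            half = (self.n_classes - 2) / 2
            return mu + sigma * 0.5 * np.arange(-half, half + 1)
        return mu + sigma * np.arange(-2.0, 2.5, 0.5)


@dataclass
class HeritabilityDecomposition:
    """One-way random-effects variance decomposition over clonal replicates."""

    ms_between: float
    ms_within: float
    n0: float  # effective replicate number (unbalanced designs)
    sigma2_g: float
    h2: float


@dataclass
class TraitStats:
    """One summary-table row for a single trait."""

    trait: str
    max: float
    min: float
    mean: float
    sd: float
    cv_pct: float
    h_prime: float
    h2: float
    shapiro_p: float


def describe_trait(values: np.ndarray | pd.Series) -> dict[str, float]:
    """Max, min, mean, sample SD (n-1) and CV (%) of accession-level values."""
    v = np.asarray(values, dtype=float)
    if v.size < 2 or not np.isfinite(v).all():
        raise ValidationError("need >= 2 finite values")
    mean = float(v.mean())
    if mean == 0:
        raise ValidationError("CV undefined for zero mean")
    sd = float(v.std(ddof=1))
    return {
        "max": float(v.max()),
        "min": float(v.min()),
        "mean": mean,
        "sd": sd,
        "cv_pct": sd / mean * 100.0,
    }


def shannon_index(
    values: np.ndarray | pd.Series, binning: DiversityBinning | None = None
) -> float:
    """Shannon-Wiener diversity index H' (nats) over grading classes.

    The binning is anchored at the sample mean and SD, so H' is invariant to
    affine rescaling of the trait.  A zero-variance sample occupies a single
    class and returns H' = 0.
    """
    binning = binning or DiversityBinning()
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValidationError("need >= 2 values")
    mu, sigma = v.mean(), v.std(ddof=1)
    if sigma == 0:
        logger.warning("zero trait variance: single occupied class, H' = 0")
        return 0.0
    counts = np.histogram(v, bins=np.r_[-np.inf, binning.edges(mu, sigma), np.inf])[0]
    p = counts[counts > 0] / v.size
    return float(-(p * np.log(p)).sum())


def broad_sense_heritability(
    replicates: pd.DataFrame,
    accession_col: str = "accession_id",
    value_col: str = "value",
) -> HeritabilityDecomposition:
    """Broad-sense heritability from an accession x replicate table.

    Uses the one-way ANOVA decomposition with Snedecor's effective replicate
    number ``n0 = (N - sum(n_i^2)/N) / (a - 1)`` for unbalanced designs.
    """
    groups = replicates.groupby(accession_col, observed=True)[value_col]
    sizes = groups.size()
    a, n_total = len(sizes), int(sizes.sum())
    if a < 2:
        raise ValidationError("need >= 2 accessions")
    if n_total - a < 1:
        raise ValidationError("no within-accession replication: h2 inestimable")
    values = replicates[value_col].to_numpy(dtype=float)
    grand = values.mean()
    means = groups.mean()
    ss_between = float((sizes * (means - grand) ** 2).sum())
    ss_within = float(((replicates[value_col] - replicates[accession_col].map(means)) ** 2).sum())
    ms_between = ss_between / (a - 1)
    ms_within = ss_within / (n_total - a)
    n0 = (n_total - float((sizes**2).sum()) / n_total) / (a - 1)
    sigma2_g = max(0.0, (ms_between - ms_within) / n0)
    denom = sigma2_g + ms_within
    h2 = float(np.clip(sigma2_g / denom, 0.0, 1.0)) if denom > 0 else 0.0
    return HeritabilityDecomposition(ms_between, ms_within, n0, sigma2_g, h2)


def normality_test(values: np.ndarray | pd.Series) -> dict[str, float]:
    """Shapiro-Wilk normality test (Royston algorithm via scipy)."""
    v = np.asarray(values, dtype=float)
    if not 3 <= v.size <= 5000:
        raise ValidationError(f"Shapiro-Wilk requires 3 <= n <= 5000, got {v.size}")
    if np.ptp(v) == 0:
        raise ValidationError("constant sample")
    w, p = stats.shapiro(v)
    return {"W": float(w), "p": float(p)}


def accession_means(
    phenotypes: pd.DataFrame,
    accession_col: str = "accession_id",
    trait_col: str = "trait",
    value_col: str = "value",
) -> pd.DataFrame:
    """Replicate -> accession aggregation: arithmetic mean per accession x trait."""
    wide = phenotypes.pivot_table(
        index=accession_col, columns=trait_col, values=value_col, aggfunc="mean"
    )
    wide.columns.name = None
    return wide


def stats_table(
    phenotypes: pd.DataFrame,
    binning: DiversityBinning | None = None,
) -> pd.DataFrame:
    """Full per-trait summary table from a long-format replicate table.

    Descriptives, H' and the normality test are computed on accession means;
    heritability is computed on the replicate-level table.
    """
    required = {"accession_id", "trait", "value"}
    if not required.issubset(phenotypes.columns):
        raise ValidationError(f"phenotype table must have columns {sorted(required)}")
    means = accession_means(phenotypes)
    rows = []
    for trait in means.columns:
        v = means[trait].dropna()
        desc = describe_trait(v)
        h2 = broad_sense_heritability(phenotypes[phenotypes["trait"] == trait]).h2
        rows.append(
            TraitStats(
                trait=trait,
                h_prime=shannon_index(v, binning),
                h2=h2,
                shapiro_p=normality_test(v)["p"],
                **desc,
            )
        )
    return pd.DataFrame([vars(r) for r in rows], columns=STATS_COLUMNS)
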