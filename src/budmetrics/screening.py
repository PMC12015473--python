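"""Trait-expression candidate-gene screening on extreme accessions.

Given a TPM matrix over a small panel of phenotypically extreme accessions
(four small-bud and four large-bud by default), each gene is screened per
trait by the Pearson correlation between its expression and the trait value,
combined with a group fold-change filter:

    pass  <=>  p < alpha  and  |log2 FC| > fc_min

where ``log2 FC = log2((mean TPM large + eps) / (mean TPM small + eps))``
with a pseudocount ``eps`` keeping the ratio finite for unexpressed genes.
P-values come from the t transform ``t = r * sqrt((n-2) / (1-r^2))`` with
n - 2 degrees of freedom.  No multiple-testing correction is applied: with
n = 8 samples this is a candidate screen, not inference, and is documented
as such.

Per-trait gene sets are intersected across traits (with full Venn region
counts), and selected genes can be row z-scored for heatmap export.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .imaging import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class ScreeningConfig:
    """Thresholds of the correlation + fold-change screen."""

    alpha: float = 0.01
    fc_min: float = 1.0
    epsilon: float = 0.1
    log_expression: bool = False  # correlate on log2(TPM+1) instead of TPM

    def __post_init__(self) -> None:
        if not 0 <= self.alpha < 1:
            raise ValidationError("alpha must be in [0, 1)")
        if self.epsilon <= 0:
            raise ValidationError("epsilon must be > 0")
        if self.fc_min < 0:
            raise ValidationError("fc_min must be >= 0")


def _check_samples(tpm: pd.DataFrame, labels: pd.Series, what: str) -> pd.Series:
    missing = tpm.columns.difference(labels.index)
    if len(missing):
        raise ValidationError(f"{what} missing for samples: {missing.tolist()}")
    return labels.reindex(tpm.columns)


def correlate_gene_trait(
    tpm: pd.DataFrame, trait: pd.Series
) -> pd.DataFrame:
    """Per-gene Pearson r and two-sided p against a per-sample trait.

    Zero-variance genes get ``r = p = NaN`` (they cannot carry signal and
    auto-fail the screen).  Vectorized over genes; identical to per-gene
    ``scipy.stats.pearsonr`` to floating-point accuracy.
    """
    trait = _check_samples(tpm, trait, "trait value")
    n = tpm.shape[1]
    if n < 3:
        raise ValidationError("need >= 3 samples")
    y = trait.to_numpy(dtype=float)
    if y.std(ddof=0) == 0:
        raise ValidationError("trait has zero variance")
    X = tpm.to_numpy(dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt((Xc**2).sum(axis=1))
    sy = np.sqrt((yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ yc) / (sx * sy)
        r = np.clip(r, -1.0, 1.0)
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) == 1.0, 0.0, p)
    zero_var = sx == 0
    if zero_var.any():
        logger.warning("%d zero-variance genes excluded from correlation", zero_var.sum())
    r[zero_var] = np.nan
    p[zero_var] = np.nan
    return pd.DataFrame({"r": r, "p": p}, index=tpm.index)


def fold_change(
    tpm: pd.DataFrame, groups: pd.Series, epsilon: float = 0.1
) -> pd.Series:
    """Per-gene log2 fold change, oriented large-bud over small-bud group.

    ``groups`` maps sample -> {"small", "large"}.  The pseudocount
    ``epsilon`` on each group-mean TPM keeps the ratio finite when a group
    is entirely unexpressed.
    """
    groups = _check_samples(tpm, groups, "group label")
    small = groups[groups == "small"].index
    large = groups[groups == "large"].index
    if len(small) == 0 or len(large) == 0:
        raise ValidationError("both 'small' and 'large' groups must be non-empty")
    mean_large = tpm[large].mean(axis=1)
    mean_small = tpm[small].mean(axis=1)
    lfc = np.log2((mean_large + epsilon) / (mean_small + epsilon))
    return lfc.rename("log2fc")


def associate(
    tpm: pd.DataFrame,
    trait: pd.Series,
    groups: pd.Series,
    cfg: ScreeningConfig | None = None,
) -> pd.DataFrame:
    """Full per-gene association table: r, p, log2fc and the pass flag."""
    cfg = cfg or ScreeningConfig()
    expr = np.log2(tpm + 1.0) if cfg.log_expression else tpm
    table = correlate_gene_trait(expr, trait)
    table["log2fc"] = fold_change(tpm, groups, cfg.epsilon)
    table["passes"] = (
        (table["p"] < cfg.alpha) & (table["log2fc"].abs() > cfg.fc_min)
    ).fillna(False)
    return table


def screen_trait(
    tpm: pd.DataFrame,
    trait: pd.Series,
    groups: pd.Series,
    cfg: ScreeningConfig | None = None,
) -> list[str]:
    """Sorted gene IDs passing the correlation + fold-change screen."""
    table = associate(tpm, trait, groups, cfg)
    return sorted(table.index[table["passes"]])


def intersect_traits(
    sets: dict[str, set[str] | list[str]],
) -> tuple[list[str], pd.DataFrame]:
    """Full intersection and all Venn region counts of per-trait gene sets.

    Returns the sorted genes common to every set and a table with one row
    per non-empty trait combination (2^k - 1 rows), counting genes whose
    membership is exactly that combination.
    """
    if not 2 <= len(sets) <= 4:
        raise ValidationError("need 2-4 gene sets")
    names = list(sets)
    as_sets = {t: set(s) for t, s in sets.items()}
    common = sorted(set.intersection(*as_sets.values()))
    rows = []
    for k in range(1, len(names) + 1):
        for combo in itertools.combinations(names, k):
            inside = set.intersection(*(as_sets[t] for t in combo))
            outside = set.union(set(), *(as_sets[t] for t in names if t not in combo))
            rows.append(
                {"traits": "&".join(combo), "n_traits": k, "count": len(inside - outside)}
            )
    return common, pd.DataFrame(rows)


def zscore_matrix(tpm: pd.DataFrame, genes: list[str] | None = None) -> pd.DataFrame:
    """Row-standardize selected genes: (x - row mean) / row SD (ddof=1).

    The standard transform behind expression heatmaps.  Constant rows are
    returned as zeros with a warning.
    """
    sub = tpm if genes is None else tpm.loc[list(genes)]
    X = sub.to_numpy(dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.any():
        logger.warning("%d constant rows z-scored to zeros", flat.sum())
        sd[sd == 0] = 1.0
    return pd.DataFrame((X - mu) / sd, index=sub.index, columns=sub.columns)
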