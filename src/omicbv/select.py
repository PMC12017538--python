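"""Feature-selection cascades for transcripts and SNPs.

Transcripts: batch one-way ANOVA with local-FDR adjustment (setA),
greedy collinearity pruning at |r| > 0.5, i.e. features explaining more
than 25% of another feature's variance (setB), and a training-set
phenotype correlation screen at |r| > 0.05 (setC).

SNPs: batch ANOVA at unadjusted p < 0.05 (the ALL set), relative variance
(dosage variance / mean dosage) > 1 (setA), the same collinearity pruning
(setB), and a training-set ANOVA of breeding values grouped by dosage
class at unadjusted p < 0.05 (setC).
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata

from .config import RunConfig
from .io import FamilyFeatureMatrix, PhenotypeTable, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "FilterReport",
    "PvalueSet",
    "one_way_anova",
    "anova_pvalues",
    "estimate_lfdr",
    "adjust_pvalues",
    "batch_filter_transcripts",
    "batch_filter_snps",
    "relative_variance_filter",
    "correlation_prune",
    "phenotype_screen_transcripts",
    "phenotype_screen_snps",
]


@dataclass
class FilterReport:
    stage: str
    features_in: int
    features_out: int
    removed: dict[str, str]  # feature ID -> reason
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.features_out > self.features_in:
            raise ValidationError("features_out cannot exceed features_in")
        if self.features_in - self.features_out != len(self.removed):
            raise ValidationError("removed + retained must equal input")


@dataclass
class PvalueSet:
    raw: pd.Series
    adjusted: pd.Series
    method: str  # "lfdr" | "BH" | "none"
    pi0: float | None = None  # null-proportion estimate (lfdr method only)

    def __post_init__(self) -> None:
        for s in (self.raw, self.adjusted):
            v = s.to_numpy(dtype=float)
            if ((v < 0) | (v > 1)).any() or np.isnan(v).any():
                raise ValidationError("p-values/adjusted values must lie in [0, 1]")


# ---------------------------------------------------------------------------
# one-way ANOVA
# ---------------------------------------------------------------------------

def one_way_anova(groups: list) -> tuple[float, float]:
    """Classical one-way ANOVA F statistic and p-value.

    Returns (F, p). Groups that are all identical (zero between- and
    within-group variance) give F = 0, p = 1 by convention.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 2:
        raise ValueError("need at least 2 groups")
    n = sum(g.size for g in groups)
    if n <= k:
        raise ValueError("total sample size must exceed the number of groups")
    grand = np.concatenate(groups).mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    if ssw == 0.0:
        if ssb == 0.0:
            return 0.0, 1.0
        return float("inf"), 0.0
    f = (ssb / (k - 1)) / (ssw / (n - k))
    p = float(stats.f.sf(f, k - 1, n - k))
    return float(f), p


def anova_pvalues(values: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Vectorized per-column one-way ANOVA p-values.

    ``values`` is observations x features, ``labels`` the group of each
    observation. Degenerate columns follow the same conventions as
    :func:`one_way_anova`.
    """
    labels = np.asarray(labels)
    groups = np.unique(labels)
    k = groups.size
    n = labels.size
    if k < 2 or n <= k:
        raise ValueError("need >=2 groups and n > k")
    grand = values.mean(axis=0)
    ssb = np.zeros(values.shape[1])
    ssw = np.zeros(values.shape[1])
    for g in groups:
        sub = values[labels == g]
        m = sub.mean(axis=0)
        ssb += sub.shape[0] * (m - grand) ** 2
        ssw += ((sub - m) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / (k - 1)) / (ssw / (n - k))
    p = stats.f.sf(f, k - 1, n - k)
    p = np.where(ssw == 0, np.where(ssb == 0, 1.0, 0.0), p)
    return np.asarray(p, dtype=float)


# ---------------------------------------------------------------------------
# local FDR
# ---------------------------------------------------------------------------

def estimate_lfdr(p: pd.Series | np.ndarray) -> PvalueSet:
    """Two-groups empirical-Bayes local FDR.

    pi0 is estimated on the grid lambda = 0.05..0.95 (step 0.05) with a
    cubic least-squares extrapolation toward lambda -> 1; the marginal
    density of probit-transformed p-values is estimated with a Gaussian
    kernel; lfdr_i = min(1, pi0 * f0(z_i) / f(z_i)) and is regularized to
    be monotone non-increasing in the p -> 0 direction.
    """
    if isinstance(p, pd.Series):
        index = p.index
        pv = p.to_numpy(dtype=float)
    else:
        pv = np.asarray(p, dtype=float)
        index = pd.RangeIndex(pv.size)
    if ((pv < 0) | (pv > 1)).any() or np.isnan(pv).any():
        raise ValidationError("p-values must lie in [0, 1]")
    if np.unique(pv).size < 2:
        raise ValidationError("need at least 2 distinct p-values for lfdr")
    if pv.size < 100:
        logger.warning("estimate_lfdr: only %d p-values; estimates will be noisy", pv.size)

    lam = np.arange(0.05, 0.951, 0.05)
    pi0_lam = np.array([(pv > l).mean() / (1.0 - l) for l in lam])
    coef = np.polyfit(lam, pi0_lam, deg=3)
    pi0 = float(np.clip(np.polyval(coef, 1.0), 1e-8, 1.0))

    eps = 1e-15
    z = stats.norm.ppf(np.clip(pv, eps, 1.0 - eps))
    kde = stats.gaussian_kde(z)
    f = np.maximum(kde(z), 1e-300)
    f0 = stats.norm.pdf(z)
    lfdr = np.clip(pi0 * f0 / f, 0.0, 1.0)

    order = np.argsort(pv, kind="stable")
    lfdr[order] = np.maximum.accumulate(lfdr[order])
    raw = pd.Series(pv, index=index)
    return PvalueSet(raw, pd.Series(lfdr, index=index), "lfdr", pi0=pi0)


def adjust_pvalues(p: pd.Series, method: str) -> PvalueSet:
    if method == "lfdr":
        return estimate_lfdr(p)
    if method == "BH":
        from statsmodels.stats.multitest import multipletests

        adj = multipletests(p.to_numpy(dtype=float), method="fdr_bh")[1]
        return PvalueSet(p.astype(float), pd.Series(adj, index=p.index), "BH")
    if method == "none":
        return PvalueSet(p.astype(float), p.astype(float), "none")
    raise ValueError(f"unknown adjustment method {method!r}")


# ---------------------------------------------------------------------------
# batch filters
# ---------------------------------------------------------------------------

def _single_batch_labels(fm: FamilyFeatureMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Mask of families in exactly one batch, plus that batch label."""
    fams = fm.family_ids
    nb = np.array([len(fm.family_to_batches[f]) for f in fams])
    labels = np.array([fm.family_to_batches[f][0] for f in fams])
    return nb == 1, labels


def _batch_anova_pvalues(fm: FamilyFeatureMatrix) -> pd.Series | None:
    single, labels = _single_batch_labels(fm)
    labels = labels[single]
    if np.unique(labels).size < 2:
        logger.warning("batch filter: fewer than 2 batches among single-batch families")
        return None
    values = fm.values.to_numpy(dtype=float)[single]
    p = anova_pvalues(values, labels)
    return pd.Series(p, index=fm.values.columns)


def batch_filter_transcripts(
    fm: FamilyFeatureMatrix, cfg: RunConfig | None = None
) -> tuple[FamilyFeatureMatrix, FilterReport]:
    """Remove transcripts whose family-mean log2 values show a batch effect.

    Families present in more than one batch are excluded from the ANOVA
    (their family means pool replicates from both batches, confounding the
    test) but are retained in the returned matrix. Adjusted values below
    the cutoff (local FDR by default) flag a transcript for removal.
    """
    cfg = cfg or RunConfig()
    p = _batch_anova_pvalues(fm)
    params = {"adjust": cfg.multiple_testing, "cutoff": cfg.lfdr_cutoff}
    if p is None:
        report = FilterReport("setA", len(fm.feature_ids), len(fm.feature_ids), {}, params)
        return fm, report
    ps = adjust_pvalues(p, cfg.multiple_testing)
    removed = ps.adjusted.index[ps.adjusted.to_numpy() < cfg.lfdr_cutoff]
    keep = [c for c in fm.feature_ids if c not in set(removed)]
    report = FilterReport(
        "setA",
        len(fm.feature_ids),
        len(keep),
        {c: "batch_effect" for c in removed},
        params,
    )
    return fm.subset_features(keep), report


def batch_filter_snps(
    fm: FamilyFeatureMatrix, alpha: float = 0.05
) -> tuple[FamilyFeatureMatrix, FilterReport]:
    """Remove SNPs with an unadjusted batch-ANOVA p-value below ``alpha``."""
    p = _batch_anova_pvalues(fm)
    params = {"adjust": "none", "alpha": alpha}
    if p is None:
        report = FilterReport("ALL", len(fm.feature_ids), len(fm.feature_ids), {}, params)
        return fm, report
    removed = p.index[p.to_numpy() < alpha]
    keep = [c for c in fm.feature_ids if c not in set(removed)]
    report = FilterReport(
        "ALL", len(fm.feature_ids), len(keep), {c: "batch_effect" for c in removed}, params
    )
    return fm.subset_features(keep), report


# ---------------------------------------------------------------------------
# variance / collinearity / phenotype screens
# ---------------------------------------------------------------------------

def relative_variance_filter(
    fm: FamilyFeatureMatrix, cutoff: float = 1.0
) -> tuple[FamilyFeatureMatrix, FilterReport]:
    """Keep SNPs whose sample variance / mean dosage exceeds ``cutoff``."""
    if fm.feature_kind != "snp_dosage":
        raise ValidationError("relative_variance_filter expects snp_dosage features")
    x = fm.values.to_numpy(dtype=float)
    mean = x.mean(axis=0)
    if (mean <= 0).any():
        raise ValidationError("SNPs with zero mean dosage must be excluded upstream")
    var = x.var(axis=0, ddof=1)
    ratio = var / mean
    keep_mask = ratio > cutoff
    keep = fm.values.columns[keep_mask]
    removed = {c: "relative_variance" for c in fm.values.columns[~keep_mask]}
    report = FilterReport("setA", len(fm.feature_ids), int(keep_mask.sum()), removed, {"cutoff": cutoff})
    return fm.subset_features(keep), report


def correlation_prune(
    fm: FamilyFeatureMatrix, r_cutoff: float = 0.5
) -> tuple[FamilyFeatureMatrix, FilterReport]:
    """Greedy collinearity pruning.

    While any feature pair has |Pearson r| > cutoff, take the pair with
    the largest |r| and remove the member with the larger mean absolute
    correlation to all remaining features (ties remove the later column).
    The rule is deterministic for a given column order.
    """
    cols = list(fm.values.columns)
    p = len(cols)
    if p < 2:
        raise ValidationError("correlation_prune needs at least 2 features")
    x = fm.values.to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.abs(np.corrcoef(x, rowvar=False))
    c = np.nan_to_num(c, nan=0.0)  # zero-variance features correlate with nothing
    np.fill_diagonal(c, 0.0)

    ii, jj = np.nonzero(np.triu(c > r_cutoff, k=1))
    heap = [(-c[i, j], int(i), int(j)) for i, j in zip(ii, jj)]
    heapq.heapify(heap)
    active = np.ones(p, dtype=bool)
    n_active = p
    rowsum = c.sum(axis=1)
    removed: dict[str, str] = {}
    while heap:
        negr, i, j = heapq.heappop(heap)
        if not (active[i] and active[j]):
            continue
        mean_i = rowsum[i] / (n_active - 1)
        mean_j = rowsum[j] / (n_active - 1)
        if mean_i > mean_j:
            drop = i
        elif mean_j > mean_i:
            drop = j
        else:
            drop = max(i, j)  # tie: remove the later column
        active[drop] = False
        n_active -= 1
        rowsum -= c[:, drop]
        removed[cols[drop]] = "collinear"
        if n_active == 0:
            raise ValidationError("correlation_prune removed every feature")
    keep = [cols[i] for i in range(p) if active[i]]
    report = FilterReport("setB", p, len(keep), removed, {"r_cutoff": r_cutoff})
    return fm.subset_features(keep), report


def phenotype_screen_transcripts(
    fm: FamilyFeatureMatrix, phen_train: PhenotypeTable, r_cutoff: float = 0.05
) -> tuple[FamilyFeatureMatrix, FilterReport]:
    """Keep transcripts with |Spearman r| > cutoff against training BVs.

    Only training families (those in ``phen_train``) enter the screen;
    constant features get r = 0 by the degenerate convention and are
    removed.
    """
    train = [f for f in phen_train.family_ids if f in set(fm.family_ids)]
    if len(train) < 3:
        raise ValidationError("phenotype screen needs at least 3 training families")
    x = fm.values.loc[train].to_numpy(dtype=float)
    y = phen_train.bv.loc[train].to_numpy()
    rx = np.apply_along_axis(rankdata, 0, x)
    ry = rankdata(y)
    sx = rx.std(axis=0)
    sy = ry.std()
    with np.errstate(invalid="ignore", divide="ignore"):
        r = ((rx - rx.mean(axis=0)) * (ry - ry.mean())[:, None]).mean(axis=0) / (sx * sy)
    r = np.nan_to_num(r, nan=0.0)
    keep_mask = np.abs(r) > r_cutoff
    keep = fm.values.columns[keep_mask]
    removed = {c: "phenotype_correlation" for c in fm.values.columns[~keep_mask]}
    report = FilterReport(
        "setC", len(fm.feature_ids), int(keep_mask.sum()), removed,
        {"r_cutoff": r_cutoff, "n_train": len(train)},
    )
    return fm.subset_features(keep), report


def phenotype_screen_snps(
    fm: FamilyFeatureMatrix, phen_train: PhenotypeTable, alpha: float = 0.05
) -> tuple[FamilyFeatureMatrix, FilterReport]:
    """Keep SNPs whose dosage classes separate training BVs (ANOVA p < alpha).

    Training-family breeding values are grouped by dosage class {0, 1, 2};
    empty classes are dropped, and SNPs with fewer than two occupied
    classes are removed as untestable.
    """
    train = [f for f in phen_train.family_ids if f in set(fm.family_ids)]
    if len(train) < 3:
        raise ValidationError("phenotype screen needs at least 3 training families")
    x = fm.values.loc[train].to_numpy(dtype=float)
    y = phen_train.bv.loc[train].to_numpy()
    keep: list[str] = []
    removed: dict[str, str] = {}
    for idx, col in enumerate(fm.values.columns):
        d = x[:, idx]
        groups = [y[d == lvl] for lvl in (0.0, 1.0, 2.0) if (d == lvl).any()]
        if len(groups) < 2 or sum(g.size for g in groups) <= len(groups):
            removed[col] = "untestable"
            continue
        _, p = one_way_anova(groups)
        if p < alpha:
            keep.append(col)
        else:
            removed[col] = "phenotype_anova"
    report = FilterReport(
        "setC", len(fm.feature_ids), len(keep), removed,
        {"alpha": alpha, "n_train": len(train)},
    )
    return fm.subset_features(keep), report
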