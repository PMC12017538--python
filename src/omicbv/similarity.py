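"""Family-by-family similarity matrices.

Two constructions are provided: the Pearson correlation matrix of
individuals across features (optionally feature-standardized first), used
as the similarity matrix for kriging, and the first-method VanRaden
genomic relationship matrix G = M M' / (2 * sum_k p_k (1 - p_k)) built
from allele-frequency-centered SNP dosages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import FamilyFeatureMatrix, ValidationError

logger = logging.getLogger(__name__)

__all__ = ["SimilarityMatrix", "GRM", "pearson_similarity", "vanraden_grm", "grm_histogram"]


@dataclass
class SimilarityMatrix:
    entries: pd.DataFrame  # symmetric, diagonal 1
    source_feature_kind: str
    n_features: int

    def __post_init__(self) -> None:
        a = self.entries.to_numpy()
        if not np.allclose(a, a.T, atol=1e-12):
            raise ValidationError("similarity matrix must be symmetric")

    @property
    def family_ids(self) -> list[str]:
        return list(self.entries.index)


@dataclass
class GRM:
    """VanRaden genomic relationship matrix with its scaling metadata."""

    entries: pd.DataFrame
    allele_freqs: pd.Series  # alternate-allele frequency per retained SNP
    denominator: float       # 2 * sum_k p_k (1 - p_k)

    def __post_init__(self) -> None:
        a = self.entries.to_numpy()
        if not np.allclose(a, a.T, atol=1e-10):
            raise ValidationError("GRM must be symmetric")
        if not np.isfinite(a).all():
            raise ValidationError("GRM entries must be finite")
        if self.denominator <= 0:
            raise ValidationError("GRM denominator must be > 0")

    @property
    def family_ids(self) -> list[str]:
        return list(self.entries.index)


def pearson_similarity(fm: FamilyFeatureMatrix, *, standardize: bool = True) -> SimilarityMatrix:
    """Pearson correlation matrix of families across features.

    With ``standardize`` (the default) each feature is centered and scaled
    to unit variance across families before the family-by-family
    correlation is taken; zero-variance features carry no similarity
    information and are dropped with a warning.
    """
    x = fm.values.to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=0)
    usable = sd > 0
    n_dropped = int((~usable).sum())
    if n_dropped:
        logger.warning("pearson_similarity: dropping %d zero-variance features", n_dropped)
    x = x[:, usable]
    if x.shape[1] < 2:
        raise ValidationError("need at least 2 features with nonzero variance")
    if standardize:
        x = (x - x.mean(axis=0)) / x.std(axis=0, ddof=0)
    c = np.corrcoef(x)
    c = np.clip((c + c.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    entries = pd.DataFrame(c, index=fm.values.index, columns=fm.values.index)
    return SimilarityMatrix(entries, fm.feature_kind, int(x.shape[1]))


def vanraden_grm(fm: FamilyFeatureMatrix) -> GRM:
    """First-method VanRaden GRM from a family dosage matrix.

    Column j is centered by twice its alternate-allele frequency p_j
    estimated from the input families; monomorphic SNPs (p = 0 or 1) are
    excluded with a warning. G = M M' / (2 sum_j p_j (1 - p_j)).
    """
    if fm.feature_kind != "snp_dosage":
        raise ValidationError("vanraden_grm expects snp_dosage features")
    g = fm.values.to_numpy(dtype=float)
    p = g.mean(axis=0) / 2.0
    poly = (p > 0.0) & (p < 1.0)
    n_mono = int((~poly).sum())
    if n_mono:
        logger.warning("vanraden_grm: excluding %d monomorphic SNPs", n_mono)
    if not poly.any():
        raise ValidationError("all SNPs are monomorphic; GRM undefined")
    g = g[:, poly]
    p = p[poly]
    m = g - 2.0 * p
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    grm = m @ m.T / denom
    grm = (grm + grm.T) / 2.0
    entries = pd.DataFrame(grm, index=fm.values.index, columns=fm.values.index)
    freqs = pd.Series(p, index=fm.values.columns[poly])
    return GRM(entries, freqs, denom)


def grm_histogram(g: GRM, train_ids, test_ids) -> dict:
    """Flat list of train-vs-test relationship entries with summary quantiles."""
    train_ids = list(train_ids)
    test_ids = list(test_ids)
    overlap = set(train_ids) & set(test_ids)
    if overlap:
        raise ValidationError(f"train/test IDs overlap: {sorted(overlap)[:5]}")
    block = g.entries.loc[train_ids, test_ids].to_numpy().ravel()
    qs = np.quantile(block, [0.0, 0.25, 0.5, 0.75, 1.0]) if block.size else np.full(5, np.nan)
    return {
        "values": block,
        "n": int(block.size),
        "quantiles": {"min": qs[0], "q25": qs[1], "median": qs[2], "q75": qs[3], "max": qs[4]},
        "mean": float(block.mean()) if block.size else float("nan"),
    }
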