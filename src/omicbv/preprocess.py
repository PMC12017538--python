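"""Replicate aggregation, log2 transform, low-expression filter, and
replicate-reproducibility summaries.

Family means are taken over raw replicate counts first, then one is added
(to eliminate zeros) and the result log2-transformed. Spearman rank
correlation is computed as the Pearson correlation of average-rank
transforms, so ties receive average ranks.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import FamilyFeatureMatrix, ReplicateCountMatrix, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "family_mean_log2",
    "low_expression_filter",
    "spearman",
    "spearman_with_flag",
    "reproducibility_report",
]


def family_mean_log2(rc: ReplicateCountMatrix) -> FamilyFeatureMatrix:
    """Aggregate replicate counts to log2(family mean + 1) per transcript."""
    fams = rc.families()
    fam_of = pd.Series({r: rc.replicate_to_family[r] for r in rc.counts.index})
    means = rc.counts.groupby(fam_of).mean().loc[fams]
    values = np.log2(means + 1.0)
    f2b: dict[str, tuple[str, ...]] = {}
    for r in rc.counts.index:
        f = rc.replicate_to_family[r]
        b = rc.replicate_to_batch[r]
        f2b.setdefault(f, ())
        if b not in f2b[f]:
            f2b[f] = tuple(sorted((*f2b[f], b)))
    return FamilyFeatureMatrix(values, "transcript_log2", f2b)


def low_expression_filter(fm: FamilyFeatureMatrix, min_mean_log2: float = 3.0) -> FamilyFeatureMatrix:
    """Keep transcripts whose mean log2 value across families is >= threshold."""
    if fm.feature_kind != "transcript_log2":
        raise ValidationError("low_expression_filter expects transcript_log2 features")
    keep = fm.values.columns[fm.values.mean(axis=0).to_numpy() >= min_mean_log2]
    if len(keep) == 0:
        logger.warning("low_expression_filter removed every transcript")
    return fm.subset_features(keep)


def spearman_with_flag(x, y) -> tuple[float, bool]:
    """Spearman r plus a flag marking the degenerate constant-vector case."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    rx = rankdata(x)
    ry = rankdata(y)
    sx = rx.std()
    sy = ry.std()
    if sx == 0 or sy == 0:
        return 0.0, True
    r = float(np.dot(rx - rx.mean(), ry - ry.mean()) / (x.size * sx * sy))
    return float(np.clip(r, -1.0, 1.0)), False


def spearman(x, y) -> float:
    """Spearman rank correlation (0.0 for a constant vector)."""
    return spearman_with_flag(x, y)[0]


def _pairwise_spearman(log2_counts: np.ndarray) -> np.ndarray:
    """All-pairs Spearman over rows via rank transform + correlation matrix."""
    ranks = np.apply_along_axis(rankdata, 1, log2_counts)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(ranks)
    # constant rows produce NaN; report 0 by the degenerate-vector convention
    c = np.nan_to_num(c, nan=0.0)
    return np.clip(c, -1.0, 1.0)


def reproducibility_report(rc: ReplicateCountMatrix) -> pd.DataFrame:
    """Pairwise Spearman correlations of log2(count+1) grouped into categories.

    Categories follow the reproducibility analysis of the study:

    * ``within_family`` — replicate pairs from the same family and batch;
    * ``cross_batch``  — replicate pairs from the same family grown in
      different batches;
    * ``among_family`` — replicate pairs from different families;
    * ``family_mean``  — pairs of family-mean log2 expression profiles.

    All transcripts are used, unfiltered. Returns a tidy frame with
    columns (a, b, category, r).
    """
    reps = rc.replicate_ids
    log2c = np.log2(rc.counts.to_numpy(dtype=float) + 1.0)
    rows: list[dict] = []
    if len(reps) >= 2:
        c = _pairwise_spearman(log2c)
        for i, j in combinations(range(len(reps)), 2):
            fi, fj = rc.replicate_to_family[reps[i]], rc.replicate_to_family[reps[j]]
            bi, bj = rc.replicate_to_batch[reps[i]], rc.replicate_to_batch[reps[j]]
            if fi == fj:
                cat = "within_family" if bi == bj else "cross_batch"
            else:
                cat = "among_family"
            rows.append({"a": reps[i], "b": reps[j], "category": cat, "r": c[i, j]})

    fam_log2 = family_mean_log2(rc)
    fams = fam_log2.family_ids
    if len(fams) >= 2:
        c = _pairwise_spearman(fam_log2.values.to_numpy())
        for i, j in combinations(range(len(fams)), 2):
            rows.append({"a": fams[i], "b": fams[j], "category": "family_mean", "r": c[i, j]})

    df = pd.DataFrame(rows, columns=["a", "b", "category", "r"])
    for cat in ("within_family", "cross_batch", "among_family", "family_mean"):
        if (df["category"] == cat).sum() == 0:
            logger.warning("reproducibility_report: no pairs in category %s", cat)
    return df
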