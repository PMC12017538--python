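"""Cross-batch experiment runner and accuracy metrics.

Train/test splits follow the batch rule of the emulated study: families
present in more than one batch always go to training. Accuracy is the
Pearson correlation of predicted versus observed breeding values with the
two-sided p-value of the simple-regression t-test (n-2 df). Whether
combining data types adds information is judged by a nested linear-model
F-test (obs ~ single vs obs ~ single + combined); a Hotelling-Williams
dependent-correlation test is available as an alternative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .config import RunConfig
from .io import (
    FamilyFeatureMatrix,
    OmicbvError,
    PhenotypeTable,
    ReplicateCountMatrix,
    ValidationError,
)
from .predict import (
    PredictionResult,
    combine_predictions,
    elasticnet_fit,
    elasticnet_predict_families,
    kriging_fit,
    kriging_predict_families,
    tune_elasticnet,
)
from .preprocess import family_mean_log2, low_expression_filter
from .select import (
    FilterReport,
    batch_filter_snps,
    batch_filter_transcripts,
    correlation_prune,
    phenotype_screen_snps,
    phenotype_screen_transcripts,
    relative_variance_filter,
)
from .similarity import pearson_similarity

logger = logging.getLogger(__name__)

__all__ = [
    "DataBundle",
    "AccuracyResult",
    "ComparisonResult",
    "EvaluationReport",
    "make_split",
    "accuracy",
    "compare_models",
    "build_stage_sets",
    "run_experiment",
    "STAGES",
]

STAGES = ("ALL", "setA", "setB", "setC")
MODELS = ("kriging", "elasticnet")
DATATYPES = ("snps", "transcripts", "combined")


@dataclass
class DataBundle:
    counts: ReplicateCountMatrix
    snps: FamilyFeatureMatrix
    phen: PhenotypeTable


class AccuracyResult(NamedTuple):
    r: float
    p: float
    n: int
    degenerate: bool


class ComparisonResult(NamedTuple):
    p: float
    statistic: float
    degenerate: bool


@dataclass
class EvaluationReport:
    records: pd.DataFrame       # model, datatype, stage, r, p, n_test, degenerate, error
    comparisons: pd.DataFrame   # model, stage, baseline, p, statistic, degenerate
    split: dict
    predictions: dict = field(default_factory=dict)
    filter_reports: dict = field(default_factory=dict)


def make_split(phen: PhenotypeTable, train_batches, test_batches) -> tuple[list[str], list[str]]:
    """Assign families to train/test by batch; multi-batch families train."""
    train_b = {str(b) for b in train_batches}
    test_b = {str(b) for b in test_batches}
    train, test = [], []
    for f in phen.family_ids:
        batches = set(phen.family_to_batches[f])
        if batches & train_b:
            train.append(f)
        elif batches & test_b:
            test.append(f)
    if not test:
        raise ValidationError("empty test set")
    return train, test


def accuracy(pred: PredictionResult, phen: PhenotypeTable) -> AccuracyResult:
    """Pearson r of predicted vs observed BVs with the regression t-test p."""
    ids = list(pred.predictions.index)
    if len(ids) < 3:
        raise ValidationError("accuracy needs at least 3 test families")
    yhat = pred.predictions.to_numpy(dtype=float)
    yobs = phen.bv.loc[ids].to_numpy()
    if yhat.std() == 0 or yobs.std() == 0:
        return AccuracyResult(0.0, 1.0, len(ids), True)
    r, p = stats.pearsonr(yhat, yobs)
    return AccuracyResult(float(r), float(p), len(ids), False)


def _nested_f(obs: np.ndarray, single: np.ndarray, combined: np.ndarray) -> ComparisonResult:
    n = obs.size
    x_r = np.column_stack([np.ones(n), single])
    x_f = np.column_stack([np.ones(n), single, combined])
    rss_r = float(((obs - x_r @ np.linalg.lstsq(x_r, obs, rcond=None)[0]) ** 2).sum())
    rss_f = float(((obs - x_f @ np.linalg.lstsq(x_f, obs, rcond=None)[0]) ** 2).sum())
    df2 = n - 3
    if df2 <= 0 or rss_f <= 0:
        return ComparisonResult(0.0 if rss_r > rss_f else 1.0, float("inf"), True)
    f = max(0.0, (rss_r - rss_f)) / (rss_f / df2)
    return ComparisonResult(float(stats.f.sf(f, 1, df2)), float(f), False)


def _williams(obs: np.ndarray, single: np.ndarray, combined: np.ndarray) -> ComparisonResult:
    n = obs.size
    r13 = np.corrcoef(combined, obs)[0, 1]
    r23 = np.corrcoef(single, obs)[0, 1]
    r12 = np.corrcoef(combined, single)[0, 1]
    det = 1 - r13**2 - r23**2 - r12**2 + 2 * r13 * r23 * r12
    rbar = (r13 + r23) / 2
    denom = 2 * det * (n - 1) / (n - 3) + rbar**2 * (1 - r12) ** 3
    if denom <= 0:
        return ComparisonResult(1.0, 0.0, True)
    t = (r13 - r23) * np.sqrt((n - 1) * (1 + r12) / denom)
    p = 2 * stats.t.sf(abs(t), n - 3)
    return ComparisonResult(float(p), float(t), False)


def compare_models(
    obs: pd.Series,
    pred_single: PredictionResult,
    pred_combined: PredictionResult,
    method: str = "nested_f",
) -> ComparisonResult:
    """Does the combined prediction add information beyond the single one?"""
    ids = list(pred_single.predictions.index)
    if set(ids) != set(pred_combined.predictions.index):
        raise ValidationError("compare_models: family sets differ")
    o = obs.loc[ids].to_numpy(dtype=float)
    s = pred_single.predictions.loc[ids].to_numpy(dtype=float)
    c = pred_combined.predictions.loc[ids].to_numpy(dtype=float)
    if s.std() == 0 or c.std() == 0:
        return ComparisonResult(1.0, 0.0, True)
    if abs(np.corrcoef(s, c)[0, 1]) > 0.9999:
        return ComparisonResult(1.0, 0.0, True)
    if method == "nested_f":
        return _nested_f(o, s, c)
    if method == "williams":
        return _williams(o, s, c)
    raise ValueError(f"unknown comparison method {method!r}")


# ---------------------------------------------------------------------------
# stage construction and the full grid
# ---------------------------------------------------------------------------

def build_stage_sets(
    fam_log2: FamilyFeatureMatrix,
    snps: FamilyFeatureMatrix,
    phen_train: PhenotypeTable,
    cfg: RunConfig,
) -> tuple[dict[str, dict[str, FamilyFeatureMatrix]], dict[str, FilterReport]]:
    """Run both filter cascades; returns {datatype: {stage: matrix}} + reports.

    All phenotype-dependent screens see only the training phenotypes.
    """
    reports: dict[str, FilterReport] = {}

    def _step(stage_key, op, fm, *args):
        # a cascade stage left with too few features passes through unchanged;
        # the affected grid cells are reported as degenerate downstream
        if len(fm.feature_ids) < 2:
            logger.warning("stage %s skipped: fewer than 2 features remain", stage_key)
            stage = stage_key.split("_", 1)[1]
            return fm, FilterReport(stage, len(fm.feature_ids), len(fm.feature_ids), {})
        return op(fm, *args)

    tr_all = low_expression_filter(fam_log2, cfg.min_mean_log2)
    tr_seta, reports["transcripts_setA"] = _step(
        "transcripts_setA", batch_filter_transcripts, tr_all, cfg
    )
    tr_setb, reports["transcripts_setB"] = _step(
        "transcripts_setB", correlation_prune, tr_seta, cfg.prune_r_cutoff
    )
    tr_setc, reports["transcripts_setC"] = _step(
        "transcripts_setC", phenotype_screen_transcripts, tr_setb,
        phen_train, cfg.transcript_phen_r_cutoff,
    )

    snp_all, reports["snps_ALL"] = _step("snps_ALL", batch_filter_snps, snps, cfg.snp_batch_alpha)
    # monomorphic-zero SNPs have undefined relative variance; drop them first
    means = snp_all.values.mean(axis=0)
    poly = means.index[means.to_numpy() > 0]
    snp_all_poly = snp_all.subset_features(poly)
    snp_seta, reports["snps_setA"] = _step(
        "snps_setA", relative_variance_filter, snp_all_poly, cfg.relative_variance_cutoff
    )
    snp_setb, reports["snps_setB"] = _step(
        "snps_setB", correlation_prune, snp_seta, cfg.prune_r_cutoff
    )
    snp_setc, reports["snps_setC"] = _step(
        "snps_setC", phenotype_screen_snps, snp_setb, phen_train, cfg.snp_phen_alpha
    )

    matrices = {
        "transcripts": {"ALL": tr_all, "setA": tr_seta, "setB": tr_setb, "setC": tr_setc},
        "snps": {"ALL": snp_all, "setA": snp_seta, "setB": snp_setb, "setC": snp_setc},
    }
    return matrices, reports


def _predict_cell(
    model: str,
    fm: FamilyFeatureMatrix,
    datatype: str,
    stage: str,
    phen_train: PhenotypeTable,
    test_ids: list[str],
    cfg: RunConfig,
    seed: int,
) -> PredictionResult:
    if model == "kriging":
        s = pearson_similarity(fm, standardize=cfg.standardize_similarity)
        km = kriging_fit(s, phen_train, cfg.theta, raw_weights=cfg.raw_kriging_weights)
        res = kriging_predict_families(km, s, test_ids)
    else:
        x_train = fm.subset_families(phen_train.family_ids)
        rng = np.random.default_rng(seed)
        a, l = tune_elasticnet(x_train, phen_train, cfg, rng)
        en = elasticnet_fit(x_train, phen_train, a, l)
        res = elasticnet_predict_families(en, fm, test_ids, datatype)
        res.model = "elasticnet"
    res.datatype = datatype
    res.stage = stage
    return res


def run_experiment(
    bundle: DataBundle,
    cfg: RunConfig | None = None,
    train_batches=("1",),
    test_batches=("2", "3"),
) -> EvaluationReport:
    """Run the {kriging, elastic net} x {snps, transcripts, combined} x
    {ALL, setA, setB, setC} grid for one cross-batch split.

    Feature screens and elastic-net tuning are computed on training
    families only. Per-cell failures are recorded and the grid continues.
    """
    cfg = cfg or RunConfig()
    phen = bundle.phen
    train_ids, test_ids = make_split(phen, train_batches, test_batches)
    phen_train = phen.subset(train_ids)

    fam_log2 = family_mean_log2(bundle.counts)
    matrices, reports = build_stage_sets(fam_log2, bundle.snps, phen_train, cfg)

    predictions: dict[tuple[str, str, str], PredictionResult] = {}
    records: list[dict] = []
    seed_rng = np.random.default_rng([cfg.seed, 97])
    for stage in STAGES:
        for model in MODELS:
            for datatype in ("snps", "transcripts"):
                cell_seed = int(seed_rng.integers(0, 2**31 - 1))
                key = (model, datatype, stage)
                try:
                    predictions[key] = _predict_cell(
                        model, matrices[datatype][stage], datatype, stage,
                        phen_train, test_ids, cfg, cell_seed,
                    )
                except (OmicbvError, np.linalg.LinAlgError) as exc:
                    logger.warning("cell %s failed: %s", key, exc)
                    records.append({
                        "model": model, "datatype": datatype, "stage": stage,
                        "r": np.nan, "p": np.nan, "n_test": len(test_ids),
                        "degenerate": True, "error": str(exc),
                    })
            key_s = (model, "snps", stage)
            key_t = (model, "transcripts", stage)
            if key_s in predictions and key_t in predictions:
                predictions[(model, "combined", stage)] = combine_predictions(
                    predictions[key_s], predictions[key_t]
                )
            else:
                records.append({
                    "model": model, "datatype": "combined", "stage": stage,
                    "r": np.nan, "p": np.nan, "n_test": len(test_ids),
                    "degenerate": True,
                    "error": "missing single-datatype predictions",
                })
        for model in MODELS:
            for datatype in DATATYPES:
                key = (model, datatype, stage)
                if key not in predictions:
                    continue
                acc = accuracy(predictions[key], phen)
                records.append({
                    "model": model, "datatype": datatype, "stage": stage,
                    "r": acc.r, "p": acc.p, "n_test": acc.n,
                    "degenerate": acc.degenerate, "error": "",
                })

    comparisons: list[dict] = []
    obs = phen.bv
    for stage in STAGES:
        for model in MODELS:
            comb = predictions.get((model, "combined", stage))
            if comb is None:
                continue
            for baseline in ("snps", "transcripts"):
                single = predictions.get((model, baseline, stage))
                if single is None:
                    continue
                cmp_res = compare_models(obs, single, comb, cfg.model_comparison)
                comparisons.append({
                    "model": model, "stage": stage, "baseline": baseline,
                    "p": cmp_res.p, "statistic": cmp_res.statistic,
                    "degenerate": cmp_res.degenerate,
                })

    rec_df = pd.DataFrame(
        records,
        columns=["model", "datatype", "stage", "r", "p", "n_test", "degenerate", "error"],
    )
    cmp_df = pd.DataFrame(
        comparisons, columns=["model", "stage", "baseline", "p", "statistic", "degenerate"]
    )
    split = {
        "train_batches": [str(b) for b in train_batches],
        "test_batches": [str(b) for b in test_batches],
        "n_train": len(train_ids),
        "n_test": len(test_ids),
        "overlap_to_train": True,
    }
    return EvaluationReport(rec_df, cmp_df, split, predictions, reports)
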