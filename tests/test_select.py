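import numpy as np
import pandas as pd
import pytest
from scipy import stats

from omicbv.config import RunConfig
from omicbv.io import FamilyFeatureMatrix, PhenotypeTable, ValidationError
from omicbv.select import (
    FilterReport,
    adjust_pvalues,
    anova_pvalues,
    batch_filter_snps,
    batch_filter_transcripts,
    correlation_prune,
    estimate_lfdr,
    one_way_anova,
    phenotype_screen_snps,
    phenotype_screen_transcripts,
    relative_variance_filter,
)


def _fm(values, kind, batches=None):
    fams = [f"F{i}" for i in range(values.shape[0])]
    df = pd.DataFrame(values, index=fams,
                      columns=[f"x{j:03d}" for j in range(values.shape[1])])
    if batches is None:
        batches = {f: ("1",) for f in fams}
    else:
        batches = {f: b for f, b in zip(fams, batches)}
    return FamilyFeatureMatrix(df, kind, batches)


class TestOneWayAnova:
    def test_identical_groups_give_p_one(self):
        f, p = one_way_anova([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert f == 0.0 and p == 1.0

    def test_separated_groups_give_tiny_p(self):
        f, p = one_way_anova([[0.0, 0.001, -0.001], [10.0, 10.001, 9.999]])
        assert p < 1e-10

    def test_matches_hand_sums_of_squares(self):
        groups = [[1.0, 2.0], [2.0, 4.0]]
        f, p = one_way_anova(groups)
        # hand ANOVA table: grand mean 2.25; SSB = 2*(1.5-2.25)^2 + 2*(3-2.25)^2
        ssb = 2 * (1.5 - 2.25) ** 2 + 2 * (3.0 - 2.25) ** 2
        ssw = (1 - 1.5) ** 2 + (2 - 1.5) ** 2 + (2 - 3) ** 2 + (4 - 3) ** 2
        f_oracle = (ssb / 1) / (ssw / 2)
        assert f == pytest.approx(f_oracle)
        assert p == pytest.approx(float(stats.f.sf(f_oracle, 1, 2)))

    def test_matches_scipy(self):
        rng = np.random.default_rng(0)
        groups = [rng.normal(size=7), rng.normal(0.5, 1, size=5), rng.normal(size=6)]
        f, p = one_way_anova(groups)
        sf, sp = stats.f_oneway(*groups)
        assert f == pytest.approx(sf) and p == pytest.approx(sp)

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=(12, 8))
        labels = np.array(["a"] * 5 + ["b"] * 4 + ["c"] * 3)
        ps = anova_pvalues(values, labels)
        for j in range(8):
            groups = [values[labels == g, j] for g in ("a", "b", "c")]
            assert ps[j] == pytest.approx(one_way_anova(groups)[1], abs=1e-12)


class TestLfdr:
    def test_uniform_null_pi0_near_one(self):
        rng = np.random.default_rng(0)
        pi0s, mean_lfdrs = [], []
        for _ in range(20):
            ps = estimate_lfdr(rng.uniform(size=2000))
            # pi0 recoverable from lfdr at large p-values (null region)
            mean_lfdrs.append(ps.adjusted.mean())
            pi0s.append(ps.adjusted[ps.raw > 0.8].mean())
        assert np.mean(pi0s) >= 0.9
        assert np.mean(mean_lfdrs) >= 0.9

    def test_strong_signal_small_lfdr_in_bottom_decile(self):
        rng = np.random.default_rng(3)
        p = np.concatenate([rng.beta(0.1, 1.0, size=1000), rng.uniform(size=1000)])
        ps = estimate_lfdr(p)
        order = np.argsort(p)
        bottom = ps.adjusted.to_numpy()[order[:200]]
        assert bottom.mean() < 0.2

    def test_outputs_clamped_to_unit_interval(self):
        rng = np.random.default_rng(5)
        ps = estimate_lfdr(rng.beta(0.3, 1.0, size=500))
        adj = ps.adjusted.to_numpy()
        assert (adj >= 0).all() and (adj <= 1).all()

    def test_monotone_in_p(self):
        rng = np.random.default_rng(7)
        ps = estimate_lfdr(rng.uniform(size=800))
        df = pd.DataFrame({"p": ps.raw, "lfdr": ps.adjusted}).sort_values("p")
        assert (np.diff(df.lfdr.to_numpy()) >= -1e-12).all()

    def test_fewer_than_two_distinct_errors(self):
        with pytest.raises(ValidationError):
            estimate_lfdr(np.full(50, 0.5))

    def test_bh_alternative(self):
        from statsmodels.stats.multitest import multipletests

        p = pd.Series([0.001, 0.02, 0.5, 0.9])
        ps = adjust_pvalues(p, "BH")
        np.testing.assert_allclose(
            ps.adjusted.to_numpy(), multipletests(p, method="fdr_bh")[1]
        )


class TestBatchFilters:
    def _transcript_fixture(self, seed=0, n_fam=60, n_feat=120, shift_first=20):
        rng = np.random.default_rng(seed)
        batches = [("1",)] * (n_fam // 2) + [("2",)] * (n_fam // 2)
        x = rng.normal(5.0, 1.0, size=(n_fam, n_feat))
        # inject +2 log2 shift in batch 2 for the first features
        x[n_fam // 2:, :shift_first] += 2.0
        return _fm(x, "transcript_log2", batches), shift_first

    def test_shifted_transcripts_removed_null_retained(self):
        fm, shift_first = self._transcript_fixture()
        out, report = batch_filter_transcripts(fm, RunConfig())
        removed = set(report.removed)
        shifted = set(fm.feature_ids[:shift_first])
        assert shifted <= removed
        # the bulk of unshifted transcripts survives
        assert len(out.feature_ids) >= (len(fm.feature_ids) - shift_first) * 0.8

    def test_multibatch_families_excluded_but_retained(self):
        fm, _ = self._transcript_fixture()
        # make one family span both batches; it must not influence the ANOVA
        b = dict(fm.family_to_batches)
        b["F0"] = ("1", "2")
        fm2 = FamilyFeatureMatrix(fm.values, "transcript_log2", b)
        out, _ = batch_filter_transcripts(fm2, RunConfig())
        assert "F0" in out.family_ids

    def test_removal_set_matches_brute_force(self):
        fm, _ = self._transcript_fixture(seed=3)
        cfg = RunConfig()
        _, report = batch_filter_transcripts(fm, cfg)
        # independent recomputation: scipy ANOVA per transcript + lfdr
        labels = np.array([fm.family_to_batches[f][0] for f in fm.family_ids])
        pvals = []
        for c in fm.feature_ids:
            groups = [fm.values.loc[labels == b, c] for b in ("1", "2")]
            pvals.append(stats.f_oneway(*groups).pvalue)
        adj = estimate_lfdr(pd.Series(pvals, index=fm.feature_ids)).adjusted
        expected = set(adj.index[adj < cfg.lfdr_cutoff])
        assert set(report.removed) == expected

    def test_snp_filter_unadjusted_alpha(self):
        rng = np.random.default_rng(4)
        n_fam = 60
        batches = [("1",)] * 30 + [("2",)] * 30
        g = rng.binomial(2, 0.3, size=(n_fam, 80)).astype(float)
        g[30:, :10] = rng.binomial(2, 0.9, size=(30, 10))  # batch-biased calls
        fm = _fm(g, "snp_dosage", batches)
        out, report = batch_filter_snps(fm, alpha=0.05)
        assert set(fm.feature_ids[:10]) <= set(report.removed)
        # brute-force identity on the whole removal set
        expected = set()
        for c in fm.feature_ids:
            groups = [fm.values.loc[[b == ("1",) for b in batches], c],
                      fm.values.loc[[b == ("2",) for b in batches], c]]
            if stats.f_oneway(*groups).pvalue < 0.05:
                expected.add(c)
        assert set(report.removed) == expected


class TestRelativeVariance:
    def test_hand_examples(self):
        # (0,0,2,2): mean 1, sample var 4/3 -> kept
        # (1,1,1,1): var 0 -> removed; (0,1,1,2): mean 1, var 2/3 -> removed
        values = np.array([[0.0, 1.0, 0.0],
                           [0.0, 1.0, 1.0],
                           [2.0, 1.0, 1.0],
                           [2.0, 1.0, 2.0]])
        fm = _fm(values, "snp_dosage")
        out, report = relative_variance_filter(fm, cutoff=1.0)
        assert out.feature_ids == ["x000"]
        assert set(report.removed) == {"x001", "x002"}

    def test_strict_inequality_at_cutoff(self):
        # (0,2): mean 1, sample var 2 -> ratio 2 kept at cutoff 1, removed at 2
        fm = _fm(np.array([[0.0], [2.0]]), "snp_dosage")
        assert relative_variance_filter(fm, 1.0)[0].feature_ids == ["x000"]
        assert relative_variance_filter(fm, 2.0)[0].feature_ids == []


def brute_force_prune(values, r_cutoff):
    """Independent implementation of the greedy pruning rule."""
    cols = list(values.columns)
    active = set(range(len(cols)))
    c = np.abs(np.corrcoef(values.to_numpy(), rowvar=False))
    c = np.nan_to_num(c, nan=0.0)
    np.fill_diagonal(c, 0.0)
    while True:
        best = None
        for i in sorted(active):
            for j in sorted(active):
                if i < j and c[i, j] > r_cutoff:
                    if best is None or c[i, j] > c[best[0], best[1]]:
                        best = (i, j)
        if best is None:
            break
        i, j = best
        others_i = [c[i, k] for k in active if k != i]
        others_j = [c[j, k] for k in active if k != j]
        mi, mj = np.mean(others_i), np.mean(others_j)
        drop = i if mi > mj else j if mj > mi else max(i, j)
        active.discard(drop)
    return [cols[i] for i in sorted(active)]


class TestCorrelationPrune:
    def test_duplicated_feature_removed_once(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=8)
        values = np.column_stack([base, base, rng.normal(size=8)])
        fm = _fm(values, "transcript_log2")
        out, report = correlation_prune(fm, 0.5)
        assert len(out.feature_ids) == 2
        assert len(report.removed) == 1

    def test_orthogonal_features_untouched(self):
        values = np.array([[1.0, 0.0, 0.0],
                           [-1.0, 0.0, 0.0],
                           [0.0, 1.0, 0.0],
                           [0.0, -1.0, 0.0],
                           [0.0, 0.0, 1.0],
                           [0.0, 0.0, -1.0]])
        fm = _fm(values, "transcript_log2")
        out, _ = correlation_prune(fm, 0.1)
        assert out.feature_ids == fm.feature_ids

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_independent_greedy_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, blocks = 20, 2
        cols = []
        for _ in range(blocks):  # planted correlated blocks
            base = rng.normal(size=n)
            for _ in range(3):
                cols.append(base + rng.normal(0, 0.4, size=n))
        cols += [rng.normal(size=n) for _ in range(2)]
        values = np.column_stack(cols)
        fm = _fm(values, "transcript_log2")
        out, _ = correlation_prune(fm, 0.5)
        assert out.feature_ids == brute_force_prune(fm.values, 0.5)


class TestPhenotypeScreens:
    def _phen(self, bv, fams):
        return PhenotypeTable(pd.Series(bv, index=fams), {f: ("1",) for f in fams})

    def test_perfect_feature_kept_constant_removed(self):
        rng = np.random.default_rng(0)
        bv = rng.normal(size=10)
        values = np.column_stack([bv, np.full(10, 2.0), rng.normal(size=10)])
        fm = _fm(values, "transcript_log2")
        phen = self._phen(bv, fm.family_ids)
        out, report = phenotype_screen_transcripts(fm, phen, 0.05)
        assert "x000" in out.feature_ids
        assert report.removed.get("x001") == "phenotype_correlation"

    def test_matches_brute_force_spearman_screen(self):
        rng = np.random.default_rng(6)
        values = rng.normal(size=(15, 40))
        fm = _fm(values, "transcript_log2")
        phen = self._phen(rng.normal(size=15), fm.family_ids)
        out, _ = phenotype_screen_transcripts(fm, phen, 0.05)
        expected = [
            c for c in fm.feature_ids
            if abs(stats.spearmanr(fm.values[c], phen.bv).statistic) > 0.05
        ]
        assert out.feature_ids == expected

    def test_screen_uses_training_families_only(self):
        rng = np.random.default_rng(8)
        values = rng.normal(size=(20, 30))
        fm = _fm(values, "transcript_log2")
        train = fm.family_ids[:12]
        phen = self._phen(rng.normal(size=12), train)
        out1, _ = phenotype_screen_transcripts(fm, phen, 0.05)
        # perturbing non-training rows must not change the retained set
        values2 = values.copy()
        values2[12:] += rng.normal(size=(8, 30))
        out2, _ = phenotype_screen_transcripts(_fm(values2, "transcript_log2"), phen, 0.05)
        assert out1.feature_ids == out2.feature_ids

    def test_snp_screen_single_class_untestable(self):
        rng = np.random.default_rng(1)
        g = np.column_stack([np.full(12, 1.0), rng.binomial(2, 0.5, 12)]).astype(float)
        fm = _fm(g, "snp_dosage")
        phen = self._phen(rng.normal(size=12), fm.family_ids)
        out, report = phenotype_screen_snps(fm, phen, 0.05)
        assert report.removed.get("x000") == "untestable"

    def test_snp_screen_partitioning_snp_kept(self):
        rng = np.random.default_rng(2)
        n = 30
        dosage = np.repeat([0.0, 2.0], n // 2)
        bv = dosage * 2.0 + rng.normal(0, 0.3, size=n)
        g = np.column_stack([dosage, rng.binomial(2, 0.4, n)]).astype(float)
        fm = _fm(g, "snp_dosage")
        phen = self._phen(bv, fm.family_ids)
        out, _ = phenotype_screen_snps(fm, phen, 0.05)
        assert "x000" in out.feature_ids

    def test_snp_screen_null_type_i_rate(self):
        # null SNPs should pass at roughly the alpha rate
        rng = np.random.default_rng(3)
        kept = total = 0
        for _ in range(30):
            g = rng.binomial(2, 0.4, size=(40, 40)).astype(float)
            fm = _fm(g, "snp_dosage")
            phen = self._phen(rng.normal(size=40), fm.family_ids)
            out, report = phenotype_screen_snps(fm, phen, 0.05)
            testable = [c for c, why in report.removed.items() if why != "untestable"]
            kept += len(out.feature_ids)
            total += len(out.feature_ids) + len(testable)
        assert 0.02 <= kept / total <= 0.09


class TestIdempotenceAndReports:
    def test_filters_idempotent(self, dosage_matrix, phenotypes):
        out1, _ = relative_variance_filter(dosage_matrix, 0.5)
        out2, rep2 = relative_variance_filter(out1, 0.5)
        assert out2.feature_ids == out1.feature_ids

        rng = np.random.default_rng(0)
        base = rng.normal(size=12)
        vals = np.column_stack([base, base + rng.normal(0, 0.2, 12),
                                rng.normal(size=(12, 4))])
        fm = _fm(vals, "transcript_log2")
        p1, _ = correlation_prune(fm, 0.5)
        p2, rep = correlation_prune(p1, 0.5)
        assert p2.feature_ids == p1.feature_ids and not rep.removed

        s1, _ = phenotype_screen_transcripts(fm, phenotypes, 0.05)
        s2, _ = phenotype_screen_transcripts(s1, phenotypes, 0.05)
        assert s2.feature_ids == s1.feature_ids

    def test_batch_filter_snps_idempotent(self):
        rng = np.random.default_rng(9)
        batches = [("1",)] * 25 + [("2",)] * 25
        g = rng.binomial(2, 0.3, size=(50, 60)).astype(float)
        fm = _fm(g, "snp_dosage", batches)
        out1, _ = batch_filter_snps(fm, 0.05)
        out2, rep2 = batch_filter_snps(out1, 0.05)
        assert out2.feature_ids == out1.feature_ids and not rep2.removed

    def test_report_counts_consistent(self):
        fm = _fm(np.random.default_rng(0).binomial(2, 0.3, (10, 20)).astype(float),
                 "snp_dosage")
        out, report = relative_variance_filter(fm, 1.0)
        assert report.features_in == 20
        assert report.features_out == len(out.feature_ids)
        assert report.features_in - report.features_out == len(report.removed)

    def test_report_invariant_violation_raises(self):
        with pytest.raises(ValidationError):
            FilterReport("setA", 5, 6, {}, {})
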