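"""Replicate reproducibility: rank correlations of expression profiles.

Computes pairwise Spearman correlations of log2(count+1) profiles across
all transcripts, grouped the way reproducibility is usually summarized in
family trials: replicate pairs within a family, replicate pairs of the
same family grown in different batches, pairs from different families,
and pairs of family-mean profiles. Within-family similarity exceeding
among-family similarity is what makes family-level prediction possible
at all.
"""

from omicbv import SyntheticConfig, simulate_study, reproducibility_report

cfg = SyntheticConfig.scaled(n_transcripts=1500, n_snps=50, seed=7)
counts, _, _, _ = simulate_study(cfg)

report = reproducibility_report(counts)
summary = report.groupby("category").r.agg(["mean", "min", "max", "count"])
print(summary.round(3))
# within_family should sit highest (shared biology and batch), cross_batch
# a little lower (same family, different year/platform), among_family
# lower still; family_mean pairs show how similar family-level expression
# programs are overall.
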