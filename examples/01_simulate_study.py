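"""Generate a synthetic three-batch family study and look at its pieces.

Builds replicate-level transcript counts, family SNP dosages and breeding
values with the 45/11/22 batch layout (five families repeated in batches
one and two), then prints the shapes and a few ground-truth facts the
downstream analyses will try to recover.
"""

import numpy as np

from omicbv import SyntheticConfig, simulate_study

cfg = SyntheticConfig.scaled(n_transcripts=1000, n_snps=2000, seed=42)
counts, snps, phen, truth = simulate_study(cfg)

print(f"replicates x transcripts: {counts.counts.shape}")
print(f"families x SNPs:          {snps.values.shape}")
print(f"families with phenotypes: {len(phen.family_ids)}")
n_multi = sum(len(b) > 1 for b in phen.family_to_batches.values())
print(f"families grown in two batches: {n_multi}")
print(f"breeding value sd: {phen.bv.std():.3f}")
print(f"causal SNPs: {len(truth.causal_snp_ids)}, "
      f"signal transcripts: {len(truth.signal_transcript_ids)}")
r = np.corrcoef(truth.true_bv, truth.structure_axis)[0, 1]
print(f"corr(BV, latent family-structure axis): {r:.2f}")
# The structure axis is the provenance-like gradient that shifts allele
# frequencies at a subset of SNPs; its correlation with the breeding value
# is what similarity-based prediction can exploit.
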