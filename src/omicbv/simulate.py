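"""Synthetic study generator: families, SNP dosages, phenotypes, RNA counts.

The generator emulates the structure of a three-batch family trial:
78 families grown in batches of 45/11/22 across different years, five of
the batch-one families repeated in batch two, one to three pooled-seedling
biological replicates per family per batch, negative-binomial replicate
counts over ~10^4 transcripts, and family genotypes as alternate-allele
dosages at ~10^4 transcriptome-aligned SNPs.

Phenotypes are additive breeding values driven by a subset of causal SNPs
plus a residual polygenic term. A minority of transcripts carries a
heritable expression signal proportional to the standardized breeding
value. Technical batch effects are injected into both data types: log2
expression shifts for a fraction of transcripts, and dosage-call bias
(batch-shifted resampling frequency) for a fraction of SNPs.

Two structures give the downstream filters something real to act on:

* co-expression modules — groups of null transcripts sharing a per-family
  latent factor, i.e. redundant correlated noise that collinearity pruning
  can remove;
* a latent family-structure axis that shifts per-family allele frequencies
  at a subset of SNPs (including the causal ones). Pure Binomial(2, p)
  dosages have variance/mean = 1 - p < 1 at every locus, so without such
  structure a relative-variance > 1 screen would keep only sampling noise;
  with it, the screen enriches for loci whose frequencies genuinely differ
  among families, as intended in the original analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import FamilyFeatureMatrix, PhenotypeTable, ReplicateCountMatrix

__all__ = ["SyntheticConfig", "SyntheticTruth", "simulate_families", "simulate_expression", "simulate_study"]


class ConfigError(ValueError):
    pass


@dataclass
class SyntheticConfig:
    """Generator settings. Defaults mirror the emulated study design."""

    # family / batch layout
    n_families_per_batch: tuple[int, int, int] = (45, 11, 22)
    n_overlap: int = 5  # batch-one families repeated in batch two
    replicate_probs: tuple[float, float, float] = (0.15, 0.25, 0.60)  # P(1), P(2), P(3) replicates

    # feature counts
    n_transcripts: int = 10_000
    n_snps: int = 10_000
    n_causal_snps: int = 200
    n_signal_transcripts: int = 1000

    # genetic architecture
    snp_effect_scale: float = 1.0      # total causal-effect scale (BV units)
    residual_bv_var: float = 0.25      # polygenic/residual BV variance
    maf_range: tuple[float, float] = (0.15, 0.5)
    structured_snp_fraction: float = 0.08
    structured_maf_range: tuple[float, float] = (0.05, 0.2)
    structure_loading_range: tuple[float, float] = (0.14, 0.2)
    n_structure_axes: int = 4          # independent family-structure axes; only axis 0 tracks BV
    causal_alignment: float = 0.5      # fraction of causal effects signed with the axis-0 loading
    ld_block_size: int = 5
    ld_copy_prob: float = 0.995

    # expression model (log2 scale)
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 2.2
    expression_signal_slope: float = 0.18  # log2 units per expression-state standard deviation
    expression_state_noise: float = 1.0    # family expression state = z(BV) + N(0, this); caps the transcript channel
    family_noise_sd: float = 0.3
    coexpr_fraction: float = 0.35
    coexpr_module_size: int = 5
    coexpr_loading: float = 1.0
    signal_coexpr_loading: float = 0.7     # shared factor within co-regulated signal modules

    # batch effects
    batch_affected_fraction_transcripts: float = 0.60
    batch_effect_sd_transcripts: float = 2.0
    batch_family_noise_sd: float = 1.0     # extra family-level technical noise on affected transcripts outside batch one
    batch_affected_fraction_snps: float = 0.05
    snp_batch_freq_shift: float = 0.35

    # counts
    nb_dispersion: float = 10.0            # NB size; larger -> closer to Poisson
    library_size_range: tuple[float, float] = (0.5, 1.5)  # replicate size factors

    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_families_per_batch) < 1 or self.n_transcripts < 1 or self.n_snps < 1:
            raise ConfigError("counts must be positive")
        if self.n_causal_snps > self.n_snps:
            raise ConfigError("n_causal_snps cannot exceed n_snps")
        if self.n_signal_transcripts > self.n_transcripts:
            raise ConfigError("n_signal_transcripts cannot exceed n_transcripts")
        if self.n_overlap > min(self.n_families_per_batch[0], 10**9):
            raise ConfigError("n_overlap cannot exceed the batch-one family count")
        for name in (
            "structured_snp_fraction",
            "coexpr_fraction",
            "batch_affected_fraction_transcripts",
            "batch_affected_fraction_snps",
            "ld_copy_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        if not 0.0 <= self.causal_alignment <= 1.0:
            raise ConfigError("causal_alignment must be in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be > 0")
        if self.residual_bv_var < 0:
            raise ConfigError("residual_bv_var must be >= 0")
        if abs(sum(self.replicate_probs) - 1.0) > 1e-9:
            raise ConfigError("replicate_probs must sum to 1")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        for k, v in list(d.items()):
            if isinstance(v, list):
                d[k] = tuple(v)
        return cls(**d)

    @classmethod
    def scaled(cls, n_transcripts: int, n_snps: int, **kwargs) -> "SyntheticConfig":
        """Config with reduced feature counts but default signal *fractions*.

        Causal-SNP and signal-transcript counts are scaled proportionally
        so the statistical regime (signal dilution, batch-effect fractions)
        matches the full-size default configuration.
        """
        base = cls()
        kwargs.setdefault(
            "n_causal_snps", max(2, round(base.n_causal_snps * n_snps / base.n_snps))
        )
        kwargs.setdefault(
            "n_signal_transcripts",
            max(2, round(base.n_signal_transcripts * n_transcripts / base.n_transcripts)),
        )
        return cls(n_transcripts=n_transcripts, n_snps=n_snps, **kwargs)


@dataclass
class SyntheticTruth:
    """Hidden generator state for recovery tests."""

    true_bv: pd.Series
    causal_snp_ids: list[str]
    batch_affected_snp_ids: list[str]
    snp_effects: dict[str, float]
    structure_axis: pd.Series
    signal_transcript_ids: list[str] = field(default_factory=list)
    batch_affected_transcript_ids: list[str] = field(default_factory=list)
    transcript_slopes: dict[str, float] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "true_bv": {k: float(v) for k, v in self.true_bv.items()},
            "causal_snp_ids": list(self.causal_snp_ids),
            "batch_affected_snp_ids": list(self.batch_affected_snp_ids),
            "snp_effects": {k: float(v) for k, v in self.snp_effects.items()},
            "structure_axis": {k: float(v) for k, v in self.structure_axis.items()},
            "signal_transcript_ids": list(self.signal_transcript_ids),
            "batch_affected_transcript_ids": list(self.batch_affected_transcript_ids),
            "transcript_slopes": {k: float(v) for k, v in self.transcript_slopes.items()},
        }


def _family_layout(cfg: SyntheticConfig) -> dict[str, tuple[str, ...]]:
    n1, n2, n3 = cfg.n_families_per_batch
    total = n1 + n2 + n3
    width = max(3, len(str(total)))
    fam_ids = [f"F{i + 1:0{width}d}" for i in range(total)]
    f2b: dict[str, tuple[str, ...]] = {}
    for i, f in enumerate(fam_ids):
        if i < n1:
            # the last n_overlap batch-one families repeat in batch two
            f2b[f] = ("1", "2") if i >= n1 - cfg.n_overlap else ("1",)
        elif i < n1 + n2:
            f2b[f] = ("2",)
        else:
            f2b[f] = ("3",)
    return f2b


def simulate_families(
    cfg: SyntheticConfig,
) -> tuple[FamilyFeatureMatrix, PhenotypeTable, SyntheticTruth]:
    """Simulate family SNP dosages and additive breeding values.

    Per SNP j an allele frequency p_j ~ U(maf_range) is drawn (shared
    within an LD block) and family dosages g_ij ~ Binomial(2, f_ij), where
    f_ij = p_j for unstructured SNPs and p_j shifted along the latent
    family-structure axis for structured ones. Breeding values are
    BV_i = sum_{j in causal} a_j (g_ij - 2 p_j) + e_i with
    e_i ~ N(0, residual_bv_var), computed from the true dosages before any
    batch-dependent call bias is injected into the observed matrix.
    """
    rng = np.random.default_rng([cfg.seed, 11])
    f2b = _family_layout(cfg)
    fam_ids = list(f2b)
    n_fam = len(fam_ids)
    primary_batch = np.array([f2b[f][0] for f in fam_ids])

    # latent family-structure axes (provenance-like); axis 0 tracks the BV
    n_axes = max(1, cfg.n_structure_axes)
    u = rng.normal(size=(n_axes, n_fam))

    m = cfg.n_snps
    block = max(1, cfg.ld_block_size)
    n_blocks = int(np.ceil(m / block))
    block_of = np.repeat(np.arange(n_blocks), block)[:m]
    p_block = rng.uniform(*cfg.maf_range, size=n_blocks)

    # structured blocks: latent-axis loading on allele frequency; drawn at
    # lower MAF so their variance/mean ratio separates from unstructured loci
    n_structured_blocks = int(round(cfg.structured_snp_fraction * n_blocks))
    structured_blocks = rng.choice(n_blocks, size=n_structured_blocks, replace=False)
    p_block[structured_blocks] = rng.uniform(*cfg.structured_maf_range, size=n_structured_blocks)
    p = p_block[block_of]
    gamma_block = np.zeros(n_blocks)
    gamma_block[structured_blocks] = rng.uniform(
        *cfg.structure_loading_range, size=n_structured_blocks
    ) * rng.choice([-1.0, 1.0], size=n_structured_blocks)
    axis_block = np.full(n_blocks, -1)
    axis_block[structured_blocks] = rng.integers(0, n_axes, size=n_structured_blocks)

    # per-family per-SNP sampling frequencies
    axis_term = np.where(
        axis_block[block_of] >= 0, u[np.maximum(axis_block[block_of], 0)].T, 0.0
    )
    freq = np.clip(p[None, :] + gamma_block[block_of][None, :] * axis_term, 0.02, 0.98)

    g = np.empty((n_fam, m), dtype=np.int64)
    for j in range(m):
        draw = rng.binomial(2, freq[:, j])
        if j > 0 and block_of[j] == block_of[j - 1]:
            keep_prev = rng.random(n_fam) < cfg.ld_copy_prob
            draw = np.where(keep_prev, g[:, j - 1], draw)
        g[:, j] = draw

    width = max(5, len(str(m)))
    snp_ids = [f"S{j + 1:0{width}d}" for j in range(m)]

    # causal SNPs drawn from axis-0 structured blocks when available
    axis0_members = np.flatnonzero(axis_block[block_of] == 0)
    if axis0_members.size >= cfg.n_causal_snps:
        causal_idx = rng.choice(axis0_members, size=cfg.n_causal_snps, replace=False)
    else:
        extra = rng.choice(
            np.setdiff1d(np.arange(m), axis0_members),
            size=cfg.n_causal_snps - axis0_members.size,
            replace=False,
        )
        causal_idx = np.concatenate([axis0_members, extra])
    causal_idx = np.sort(causal_idx)
    a = rng.normal(0.0, cfg.snp_effect_scale / np.sqrt(max(1, cfg.n_causal_snps)), size=causal_idx.size)
    # directional selection: a fraction of causal effects is signed with the
    # structure axis, so families shifted along it carry genuinely better BVs
    gamma_causal = gamma_block[block_of[causal_idx]]
    align = rng.random(causal_idx.size) < cfg.causal_alignment
    align &= gamma_causal != 0.0
    a[align] = np.abs(a[align]) * np.sign(gamma_causal[align])

    centered = g[:, causal_idx] - 2.0 * p[causal_idx]
    e = rng.normal(0.0, np.sqrt(cfg.residual_bv_var), size=n_fam)
    bv = centered @ a + e

    # batch-dependent dosage-call bias in the *observed* matrix
    g_obs = g.copy()
    n_biased = int(round(cfg.batch_affected_fraction_snps * m))
    biased_idx = np.sort(rng.choice(m, size=n_biased, replace=False))
    batches = np.array(["1", "2", "3"])
    target_batch = rng.choice(batches, size=n_biased)
    shift = rng.choice([-1.0, 1.0], size=n_biased) * cfg.snp_batch_freq_shift
    for k, j in enumerate(biased_idx):
        mask = primary_batch == target_batch[k]
        if not mask.any():
            continue
        fb = np.clip(freq[mask, j] + shift[k], 0.01, 0.99)
        g_obs[mask, j] = rng.binomial(2, fb)

    values = pd.DataFrame(g_obs.astype(float), index=fam_ids, columns=snp_ids)
    fm = FamilyFeatureMatrix(values, "snp_dosage", dict(f2b))
    phen = PhenotypeTable(pd.Series(bv, index=fam_ids), dict(f2b))
    truth = SyntheticTruth(
        true_bv=pd.Series(bv, index=fam_ids),
        causal_snp_ids=[snp_ids[j] for j in causal_idx],
        batch_affected_snp_ids=[snp_ids[j] for j in biased_idx],
        snp_effects={snp_ids[j]: float(a_k) for j, a_k in zip(causal_idx, a)},
        structure_axis=pd.Series(u[0], index=fam_ids),
    )
    return fm, phen, truth


def simulate_expression(
    cfg: SyntheticConfig, truth: SyntheticTruth, phen: PhenotypeTable
) -> ReplicateCountMatrix:
    """Simulate replicate-level negative-binomial transcript counts.

    The log2 mean of transcript t in family i is
    baseline_t + b_t * z(BV_i) * 1[t signal] + module contribution
    + family noise, and each replicate adds the batch effect of the batch
    it was grown in. Replicate counts are drawn
    NB(mean = size_factor * 2^log2mean, dispersion = nb_dispersion).
    ``truth`` is updated in place with the transcript-side ground truth.
    """
    rng = np.random.default_rng([cfg.seed, 23])
    fam_ids = phen.family_ids
    n_fam = len(fam_ids)
    t = cfg.n_transcripts
    width = max(5, len(str(t)))
    tr_ids = [f"T{i + 1:0{width}d}" for i in range(t)]

    baseline = np.clip(
        rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, size=t), 0.0, 14.0
    )

    signal_idx = np.sort(rng.choice(t, size=cfg.n_signal_transcripts, replace=False))
    slopes = np.zeros(t)
    slopes[signal_idx] = (
        cfg.expression_signal_slope
        * rng.uniform(0.7, 1.3, size=signal_idx.size)
        * rng.choice([-1.0, 1.0], size=signal_idx.size)
    )

    n_batch_aff = int(round(cfg.batch_affected_fraction_transcripts * t))
    batch_aff_idx = np.sort(rng.choice(t, size=n_batch_aff, replace=False))
    # batch one is the reference; affected transcripts shift in batches 2 and 3
    delta = np.zeros((t, 3))
    for col in (1, 2):
        mag = cfg.batch_effect_sd_transcripts * (
            0.75 + np.abs(rng.normal(0.0, 0.5, size=n_batch_aff))
        )
        delta[batch_aff_idx, col] = rng.choice([-1.0, 1.0], size=n_batch_aff) * mag

    # co-expression modules among transcripts that are neither signal nor batch-affected
    free = np.setdiff1d(np.arange(t), np.union1d(signal_idx, batch_aff_idx))
    n_module_members = int(round(cfg.coexpr_fraction * t))
    n_module_members = min(n_module_members, free.size)
    msize = max(2, cfg.coexpr_module_size)
    n_modules = n_module_members // msize
    module_members = rng.choice(free, size=n_modules * msize, replace=False)
    module_of = np.full(t, -1)
    for k in range(n_modules):
        module_of[module_members[k * msize : (k + 1) * msize]] = k

    bv = truth.true_bv.loc[fam_ids].to_numpy()
    z = (bv - bv.mean()) / bv.std() if bv.std() > 0 else np.zeros_like(bv)
    # juvenile expression tracks the breeding value only through a noisy
    # family-level expression state; this caps how much of the BV the
    # transcript channel can ever recover
    z = z + rng.normal(0.0, cfg.expression_state_noise, size=n_fam)

    module_factor = rng.normal(size=(max(1, n_modules), n_fam))
    fam_noise = rng.normal(0.0, cfg.family_noise_sd, size=(n_fam, t))
    bio = baseline[None, :] + np.outer(z, slopes) + fam_noise
    if n_modules:
        loadings = np.where(module_of >= 0, cfg.coexpr_loading, 0.0)
        bio += module_factor[np.maximum(module_of, 0)].T * loadings[None, :]

    # signal transcripts are co-regulated: groups of them share a module
    # factor, so collinearity pruning later collapses each group to one
    # representative without losing the underlying signal
    n_sig_modules = signal_idx.size // msize
    if n_sig_modules:
        sig_members = rng.permutation(signal_idx)[: n_sig_modules * msize]
        sig_factor = rng.normal(size=(n_sig_modules, n_fam))
        sig_module_of = np.full(t, -1)
        for k in range(n_sig_modules):
            sig_module_of[sig_members[k * msize : (k + 1) * msize]] = k
        sig_loadings = np.where(sig_module_of >= 0, cfg.signal_coexpr_loading, 0.0)
        bio += sig_factor[np.maximum(sig_module_of, 0)].T * sig_loadings[None, :]

    # family-level technical noise on affected transcripts outside the
    # reference batch (platform/facility artifacts are family-dependent)
    tech = np.zeros((n_fam, t, 2))
    tech[:, batch_aff_idx, :] = rng.normal(
        0.0, cfg.batch_family_noise_sd, size=(n_fam, n_batch_aff, 2)
    )

    batch_col = {"1": 0, "2": 1, "3": 2}
    rep_ids: list[str] = []
    rep_family: dict[str, str] = {}
    rep_batch: dict[str, str] = {}
    rows: list[np.ndarray] = []
    d = cfg.nb_dispersion
    for i, f in enumerate(fam_ids):
        for b in phen.family_to_batches[f]:
            n_rep = int(rng.choice([1, 2, 3], p=cfg.replicate_probs))
            bc = batch_col.get(b, 0)
            mu_log2 = bio[i] + delta[:, bc]
            if bc > 0:
                mu_log2 = mu_log2 + tech[i, :, bc - 1]
            for r in range(n_rep):
                sf = rng.uniform(*cfg.library_size_range)
                mu = sf * np.exp2(mu_log2)
                counts = rng.negative_binomial(d, d / (d + mu))
                rid = f"{f}_b{b}_r{r + 1}"
                rep_ids.append(rid)
                rep_family[rid] = f
                rep_batch[rid] = b
                rows.append(counts)

    counts = pd.DataFrame(
        np.vstack(rows).astype(np.int64), index=rep_ids, columns=tr_ids
    )
    truth.signal_transcript_ids = [tr_ids[i] for i in signal_idx]
    truth.batch_affected_transcript_ids = [tr_ids[i] for i in batch_aff_idx]
    truth.transcript_slopes = {tr_ids[i]: float(slopes[i]) for i in signal_idx}
    return ReplicateCountMatrix(counts, rep_family, rep_batch)


def simulate_study(
    cfg: SyntheticConfig,
) -> tuple[ReplicateCountMatrix, FamilyFeatureMatrix, PhenotypeTable, SyntheticTruth]:
    """Full synthetic study: counts, SNP dosages, phenotypes and truth."""
    snps, phen, truth = simulate_families(cfg)
    rc = simulate_expression(cfg, truth, phen)
    return rc, snps, phen, truth
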