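"""Domain types and plain-text readers/writers.

Matrices travel as UTF-8 TSV with a header row and the row ID in the first
column. Genotypes may also come from a VCF with one diploid sample per
family; sites are reduced to alternate-allele dosages (0/1/2) after the
three hard filters applied in the study: QUAL > 30, minor allele frequency
> 0.05 across families, and no missing genotypes. Only biallelic SNVs are
considered; multi-allelic records and indels are skipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "OmicbvError",
    "FormatError",
    "ValidationError",
    "MappingError",
    "ReplicateCountMatrix",
    "FamilyFeatureMatrix",
    "PhenotypeTable",
    "read_count_matrix",
    "write_count_matrix",
    "read_feature_matrix",
    "write_feature_matrix",
    "read_phenotypes",
    "write_phenotypes",
    "read_genotypes_vcf",
]


class OmicbvError(Exception):
    """Base class for pipeline errors."""


class FormatError(OmicbvError):
    """A file does not conform to the expected dialect."""


class ValidationError(OmicbvError):
    """Values violate a domain-type invariant."""


class MappingError(OmicbvError):
    """A replicate or family is missing from a required map."""


_BATCH_SEP = ";"


def _as_batch_tuple(value) -> tuple[str, ...]:
    if isinstance(value, tuple):
        return tuple(str(b) for b in value)
    if isinstance(value, (list, set, frozenset)):
        return tuple(sorted(str(b) for b in value))
    return (str(value),)


@dataclass
class ReplicateCountMatrix:
    """Raw transcript counts per biological replicate.

    ``counts`` is replicates x transcripts with non-negative integer
    entries; every replicate maps to exactly one family and one batch.
    """

    counts: pd.DataFrame
    replicate_to_family: dict[str, str]
    replicate_to_batch: dict[str, str]

    def __post_init__(self) -> None:
        if self.counts.columns.duplicated().any():
            raise ValidationError("duplicate transcript IDs")
        if self.counts.index.duplicated().any():
            raise ValidationError("duplicate replicate IDs")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.asarray(arr, dtype=float) == np.floor(np.asarray(arr, dtype=float))):
                raise ValidationError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValidationError("counts must be non-negative")
        missing = [r for r in self.counts.index if r not in self.replicate_to_family]
        if missing:
            raise MappingError(f"replicates missing from family map: {missing[:5]}")
        missing = [r for r in self.counts.index if r not in self.replicate_to_batch]
        if missing:
            raise MappingError(f"replicates missing from batch map: {missing[:5]}")

    @property
    def replicate_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.counts.columns)

    def families(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.counts.index:
            seen.setdefault(self.replicate_to_family[r], None)
        return list(seen)


@dataclass
class FamilyFeatureMatrix:
    """Families x features, either log2 expression means or SNP dosages.

    ``family_to_batches`` maps each family to the tuple of batches it was
    grown in; a handful of families legitimately occur in two batches.
    """

    values: pd.DataFrame
    feature_kind: str  # "transcript_log2" | "snp_dosage"
    family_to_batches: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        if self.feature_kind not in ("transcript_log2", "snp_dosage"):
            raise ValidationError(f"unknown feature_kind {self.feature_kind!r}")
        if self.values.index.duplicated().any():
            raise ValidationError("duplicate family IDs")
        if self.values.columns.duplicated().any():
            raise ValidationError("duplicate feature IDs")
        arr = self.values.to_numpy(dtype=float)
        if np.isnan(arr).any():
            raise ValidationError("missing entries are not allowed")
        if self.feature_kind == "snp_dosage" and not np.isin(arr, (0.0, 1.0, 2.0)).all():
            raise ValidationError("snp_dosage values must be in {0, 1, 2}")
        self.family_to_batches = {
            f: _as_batch_tuple(b) for f, b in self.family_to_batches.items()
        }
        missing = [f for f in self.values.index if f not in self.family_to_batches]
        if missing:
            raise MappingError(f"families missing from batch map: {missing[:5]}")

    @property
    def family_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset_features(self, feature_ids) -> "FamilyFeatureMatrix":
        return FamilyFeatureMatrix(
            values=self.values.loc[:, list(feature_ids)],
            feature_kind=self.feature_kind,
            family_to_batches=dict(self.family_to_batches),
        )

    def subset_families(self, family_ids) -> "FamilyFeatureMatrix":
        return FamilyFeatureMatrix(
            values=self.values.loc[list(family_ids), :],
            feature_kind=self.feature_kind,
            family_to_batches={f: self.family_to_batches[f] for f in family_ids},
        )


@dataclass
class PhenotypeTable:
    """Breeding value per family plus the batch(es) each family was grown in."""

    bv: pd.Series
    family_to_batches: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        if self.bv.index.duplicated().any():
            raise ValidationError("duplicate family IDs in phenotype table")
        vals = self.bv.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise ValidationError("breeding values must be finite")
        self.bv = self.bv.astype(float)
        self.family_to_batches = {
            f: _as_batch_tuple(b) for f, b in self.family_to_batches.items()
        }
        missing = [f for f in self.bv.index if f not in self.family_to_batches]
        if missing:
            raise MappingError(f"families missing from batch map: {missing[:5]}")

    @property
    def family_ids(self) -> list[str]:
        return list(self.bv.index)

    def subset(self, family_ids) -> "PhenotypeTable":
        ids = list(family_ids)
        return PhenotypeTable(
            bv=self.bv.loc[ids],
            family_to_batches={f: self.family_to_batches[f] for f in ids},
        )


# ---------------------------------------------------------------------------
# TSV readers / writers
# ---------------------------------------------------------------------------

def _read_tsv_matrix(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - passthrough detail
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if df.columns.size == 0:
        raise FormatError(f"{path}: no feature columns (missing header row?)")
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    return df


def read_count_matrix(path: str | Path, family_map_path: str | Path) -> ReplicateCountMatrix:
    """Read a replicate x transcript count TSV plus a replicate/family/batch map."""
    df = _read_tsv_matrix(path)
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise FormatError(f"{path}: non-numeric counts")
    fl = arr.astype(float)
    if not np.all(fl == np.floor(fl)):
        raise ValidationError(f"{path}: counts must be integers")
    if (fl < 0).any():
        raise ValidationError(f"{path}: negative count")
    m = pd.read_csv(family_map_path, sep="\t", dtype=str)
    required = {"replicate", "family", "batch"}
    if not required.issubset(m.columns):
        raise FormatError(f"{family_map_path}: needs columns {sorted(required)}")
    fam = dict(zip(m["replicate"], m["family"]))
    bat = dict(zip(m["replicate"], m["batch"]))
    return ReplicateCountMatrix(df.astype(np.int64), fam, bat)


def write_count_matrix(rc: ReplicateCountMatrix, path: str | Path, family_map_path: str | Path) -> None:
    rc.counts.to_csv(path, sep="\t", index_label="replicate")
    rows = [
        {"replicate": r, "family": rc.replicate_to_family[r], "batch": rc.replicate_to_batch[r]}
        for r in rc.counts.index
    ]
    pd.DataFrame(rows).to_csv(family_map_path, sep="\t", index=False)


def read_feature_matrix(path: str | Path, feature_kind: str, batch_map_path: str | Path) -> FamilyFeatureMatrix:
    df = _read_tsv_matrix(path).astype(float)
    m = pd.read_csv(batch_map_path, sep="\t", dtype=str)
    if not {"family", "batches"}.issubset(m.columns):
        raise FormatError(f"{batch_map_path}: needs columns ['family', 'batches']")
    f2b = {
        f: tuple(str(b).split(_BATCH_SEP)) for f, b in zip(m["family"], m["batches"])
    }
    return FamilyFeatureMatrix(df, feature_kind, f2b)


def write_feature_matrix(fm: FamilyFeatureMatrix, path: str | Path, batch_map_path: str | Path) -> None:
    if fm.feature_kind == "snp_dosage":
        fm.values.astype(np.int64).to_csv(path, sep="\t", index_label="family")
    else:
        fm.values.to_csv(path, sep="\t", index_label="family", float_format="%.12g")
    rows = [
        {"family": f, "batches": _BATCH_SEP.join(fm.family_to_batches[f])}
        for f in fm.values.index
    ]
    pd.DataFrame(rows).to_csv(batch_map_path, sep="\t", index=False)


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", dtype={"family": str, "batches": str})
    if not {"family", "bv", "batches"}.issubset(df.columns):
        raise FormatError(f"{path}: needs columns ['family', 'bv', 'batches']")
    bv = pd.Series(df["bv"].to_numpy(dtype=float), index=df["family"])
    f2b = {f: tuple(str(b).split(_BATCH_SEP)) for f, b in zip(df["family"], df["batches"])}
    return PhenotypeTable(bv, f2b)


def write_phenotypes(phen: PhenotypeTable, path: str | Path) -> None:
    rows = [
        {"family": f, "bv": phen.bv[f], "batches": _BATCH_SEP.join(phen.family_to_batches[f])}
        for f in phen.bv.index
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF genotypes
# ---------------------------------------------------------------------------

def read_genotypes_vcf(
    path: str | Path,
    family_to_batches: Mapping[str, tuple[str, ...]] | None = None,
    *,
    min_qual: float = 30.0,
    min_maf: float = 0.05,
) -> FamilyFeatureMatrix:
    """Read diploid per-family genotypes from a VCF into a dosage matrix.

    Retains biallelic SNVs with QUAL > ``min_qual``, minor allele frequency
    > ``min_maf`` computed across the families present, and no missing
    genotypes. Non-diploid genotypes cause the record to be skipped with a
    warning. The filters are per-site, so record order never changes the
    retained set.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    n = len(samples)
    if n == 0:
        raise FormatError(f"{path}: VCF has no samples")
    ids: list[str] = []
    rows: list[np.ndarray] = []
    for var in vcf:
        if len(var.ALT) != 1:
            continue  # multi-allelic or missing ALT
        if not var.is_snp:
            continue
        if var.QUAL is None or var.QUAL <= min_qual:
            continue
        gts = var.genotypes  # [[a0, a1, phased], ...]
        alleles = np.full((n, 2), -1, dtype=int)
        bad_ploidy = False
        for i, g in enumerate(gts):
            calls = g[:-1]
            if len(calls) != 2:
                bad_ploidy = True
                break
            alleles[i] = calls
        if bad_ploidy:
            logger.warning("skipping non-diploid record %s:%s", var.CHROM, var.POS)
            continue
        if (alleles < 0).any():
            continue  # missing genotype -> site dropped
        dosage = (alleles == 1).sum(axis=1)
        p_alt = dosage.sum() / (2 * n)
        maf = min(p_alt, 1 - p_alt)
        if maf <= min_maf:
            continue
        site_id = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        ids.append(site_id)
        rows.append(dosage)
    vcf.close()
    if not rows:
        raise ValidationError(f"{path}: all sites removed by filters")
    values = pd.DataFrame(
        np.column_stack(rows).astype(float), index=samples, columns=ids
    )
    if family_to_batches is None:
        family_to_batches = {s: ("1",) for s in samples}
    return FamilyFeatureMatrix(values, "snp_dosage", dict(family_to_batches))
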