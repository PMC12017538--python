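import numpy as np
import pandas as pd
import pytest

from omicbv.io import FamilyFeatureMatrix, PhenotypeTable, ReplicateCountMatrix


@pytest.fixture
def tiny_counts():
    """2 replicates x 3 transcripts, one family each."""
    counts = pd.DataFrame(
        [[0, 5, 8], [2, 0, 1]],
        index=["r1", "r2"],
        columns=["tA", "tB", "tC"],
    )
    return ReplicateCountMatrix(
        counts,
        {"r1": "F1", "r2": "F2"},
        {"r1": "1", "r2": "1"},
    )


@pytest.fixture
def small_counts():
    """Two families with two replicates each across two batches."""
    rng = np.random.default_rng(7)
    counts = pd.DataFrame(
        rng.poisson(20, size=(4, 50)),
        index=["F1_a", "F1_b", "F2_a", "F2_b"],
        columns=[f"t{i}" for i in range(50)],
    )
    fam = {"F1_a": "F1", "F1_b": "F1", "F2_a": "F2", "F2_b": "F2"}
    bat = {"F1_a": "1", "F1_b": "1", "F2_a": "1", "F2_b": "2"}
    return ReplicateCountMatrix(counts, fam, bat)


@pytest.fixture
def dosage_matrix():
    rng = np.random.default_rng(3)
    g = rng.binomial(2, 0.3, size=(12, 30)).astype(float)
    fams = [f"F{i}" for i in range(12)]
    values = pd.DataFrame(g, index=fams, columns=[f"s{j}" for j in range(30)])
    batches = {f: ("1",) if i < 6 else ("2",) for i, f in enumerate(fams)}
    return FamilyFeatureMatrix(values, "snp_dosage", batches)


@pytest.fixture
def phenotypes(dosage_matrix):
    rng = np.random.default_rng(5)
    bv = pd.Series(rng.normal(size=12), index=dosage_matrix.family_ids)
    return PhenotypeTable(bv, dict(dosage_matrix.family_to_batches))


def make_vcf(path, records, samples=("FamA", "FamB", "FamC", "FamD")):
    """Write a minimal VCF v4.2 text file. ``records`` are dicts with keys
    chrom, pos, ref, alt, qual, gts (list of GT strings)."""
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "##contig=<ID=tig1,length=10000>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    for r in records:
        row = [
            r.get("chrom", "tig1"), str(r["pos"]), r.get("id", "."),
            r.get("ref", "A"), r.get("alt", "G"), str(r.get("qual", 50)),
            ".", ".", "GT", *r["gts"],
        ]
        lines.append("\t".join(row))
    path.write_text("\n".join(lines) + "\n")
    return path
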