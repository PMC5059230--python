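"""Shared fixtures: tiny hand-built genotype matrices and simulated panels."""

import numpy as np
import pandas as pd
import pytest

from orscpop.io_meta import MISSING, GenotypeMatrix


def make_genotypes(calls, chrom=None, pos=None, ids=None, acc=None) -> GenotypeMatrix:
    """Build a GenotypeMatrix from a (n_snps, n_acc) list of dosages
    (None -> missing)."""
    calls = np.array(
        [[MISSING if v is None else v for v in row] for row in calls], dtype=np.int8
    )
    n_snps, n_acc = calls.shape
    if chrom is None:
        chrom = ["1"] * n_snps
    if pos is None:
        pos = {}
        out = []
        for c in chrom:
            pos.setdefault(c, 0)
            pos[c] += 100
            out.append(pos[c])
        pos = out
    if ids is None:
        ids = [f"snp{i}" for i in range(n_snps)]
    if acc is None:
        acc = [f"acc{j}" for j in range(n_acc)]
    return GenotypeMatrix(
        snp_ids=np.array(ids, dtype=object),
        chrom=np.array(chrom, dtype=object),
        pos_bp=np.array(pos),
        ref_allele=np.array(["A"] * n_snps, dtype=object),
        alt_allele=np.array(["G"] * n_snps, dtype=object),
        calls=calls,
        accession_ids=np.array(acc, dtype=object),
    )


@pytest.fixture
def tiny_vcf(tmp_path):
    """3 biallelic SNPs x 2 samples, plus helpers for dosage assertions."""
    text = """##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=1>
##contig=<ID=2>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2
1\t100\tv1\tA\tG\t.\t.\t.\tGT\t0/0\t0/1
1\t200\tv2\tC\tT\t.\t.\t.\tGT\t1/1\t./.
2\t150\tv3\tG\tA\t.\t.\t.\tGT\t0/1\t1/1
"""
    p = tmp_path / "tiny.vcf"
    p.write_text(text)
    return p


@pytest.fixture
def multiallelic_vcf(tmp_path):
    """5 sites, one tri-allelic."""
    rows = [
        ("1", 100, "v1", "A", "G", "0/0", "0/1"),
        ("1", 200, "v2", "C", "T", "1/1", "0/0"),
        ("1", 300, "v3", "G", "A,T", "0/1", "0/0"),
        ("1", 400, "v4", "T", "C", "0/1", "0/1"),
        ("2", 100, "v5", "A", "C", "0/0", "1/1"),
    ]
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "##contig=<ID=1>",
        "##contig=<ID=2>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2",
    ]
    for c, p, i, r, a, g1, g2 in rows:
        lines.append(f"{c}\t{p}\t{i}\t{r}\t{a}\t.\t.\t.\tGT\t{g1}\t{g2}")
    p = tmp_path / "multi.vcf"
    p.write_text("\n".join(lines) + "\n")
    return p


@pytest.fixture
def metadata_frame():
    from orscpop.io_meta import METADATA_COLUMNS

    df = pd.DataFrame(
        {c: pd.Series([np.nan, np.nan], dtype=object) for c in METADATA_COLUMNS}
    )
    df["accession_id"] = ["a1", "a2"]
    df["species_label"] = ["O. rufipogon", "O. nivara"]
    df["country"] = ["Laos", "India"]
    df["latitude"] = [18.2, np.nan]
    df["longitude"] = [102.5, np.nan]
    return df
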