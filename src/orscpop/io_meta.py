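"""Genotype, metadata, and ancestry (Q-matrix) containers and file formats.

The central container is :class:`GenotypeMatrix`, a SNP-major matrix of
unphased diploid dosages (count of the alternate allele, 0/1/2, with ``-1``
for a missing call).  Genotypes arrive either as VCF 4.x or as a
tab-separated "hapmap-like" dosage table; both loaders drop multi-allelic
sites, sort by (chromosome, position), and enforce unique SNP and accession
identifiers.

SNP filtering implements the GBS quality rules used throughout the
analyses: per-SNP call rate strictly above a threshold (default 0.5) and a
minor allele count of at least ``min_mac`` (default 4, i.e. MAC > 3),
counted over called alleles only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("orscpop")

MISSING = -1  # dosage sentinel

#: metadata TSV column schema, in file order
METADATA_COLUMNS = [
    "accession_id",
    "species_label",
    "country",
    "latitude",
    "longitude",
    "subpop",
    "cp_group",
    "hull_color",
    "pericarp_score",
    "rc_indel",
    "bh4_indel",
]


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Diploid SNP dosages with genomic coordinates.

    Attributes
    ----------
    snp_ids : (n_snps,) array of str
        Unique SNP identifiers.
    chrom : (n_snps,) array of str
        Chromosome label per SNP.
    pos_bp : (n_snps,) array of int
        1-based physical position, strictly increasing within a chromosome.
    ref_allele, alt_allele : (n_snps,) array of str
    calls : (n_snps, n_accessions) int8 array
        Alternate-allele dosage in {0, 1, 2}; ``-1`` marks a missing call.
    accession_ids : (n_accessions,) array of str
    """

    snp_ids: np.ndarray
    chrom: np.ndarray
    pos_bp: np.ndarray
    ref_allele: np.ndarray
    alt_allele: np.ndarray
    calls: np.ndarray
    accession_ids: np.ndarray

    def __post_init__(self) -> None:
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos_bp = np.asarray(self.pos_bp, dtype=np.int64)
        self.ref_allele = np.asarray(self.ref_allele, dtype=object)
        self.alt_allele = np.asarray(self.alt_allele, dtype=object)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.accession_ids = np.asarray(self.accession_ids, dtype=object)
        self._validate()

    def _validate(self) -> None:
        n_snps = len(self.snp_ids)
        if self.calls.shape != (n_snps, len(self.accession_ids)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{n_snps} SNPs x {len(self.accession_ids)} accessions"
            )
        if len(set(self.snp_ids)) != n_snps:
            raise ParseError("duplicate SNP ids")
        if len(set(self.accession_ids)) != len(self.accession_ids):
            raise ParseError("duplicate accession ids")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError(f"invalid dosage values: {np.unique(self.calls[bad])}")
        for c in pd.unique(self.chrom):
            pos = self.pos_bp[self.chrom == c]
            if not np.all(np.diff(pos) > 0):
                raise ParseError(f"positions not strictly increasing on {c}")

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    def accession_indices(self, ids) -> np.ndarray:
        """Column indices for a sequence of accession ids (order preserved)."""
        lookup = {a: i for i, a in enumerate(self.accession_ids)}
        try:
            return np.array([lookup[a] for a in ids], dtype=np.intp)
        except KeyError as e:
            raise KeyError(f"unknown accession id {e.args[0]!r}") from None

    def take_snps(self, index: np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to the given SNP row indices (order kept)."""
        return GenotypeMatrix(
            snp_ids=self.snp_ids[index],
            chrom=self.chrom[index],
            pos_bp=self.pos_bp[index],
            ref_allele=self.ref_allele[index],
            alt_allele=self.alt_allele[index],
            calls=self.calls[index],
            accession_ids=self.accession_ids,
        )

    def take_accessions(self, ids) -> "GenotypeMatrix":
        idx = self.accession_indices(ids)
        return GenotypeMatrix(
            snp_ids=self.snp_ids,
            chrom=self.chrom,
            pos_bp=self.pos_bp,
            ref_allele=self.ref_allele,
            alt_allele=self.alt_allele,
            calls=self.calls[:, idx],
            accession_ids=self.accession_ids[idx],
        )

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            np.array_equal(self.snp_ids, other.snp_ids)
            and np.array_equal(self.chrom, other.chrom)
            and np.array_equal(self.pos_bp, other.pos_bp)
            and np.array_equal(self.ref_allele, other.ref_allele)
            and np.array_equal(self.alt_allele, other.alt_allele)
            and np.array_equal(self.calls, other.calls)
            and np.array_equal(self.accession_ids, other.accession_ids)
        )


@dataclass
class AncestryMatrix:
    """Per-accession ancestry proportions over K groups (fastStructure meanQ)."""

    accession_ids: np.ndarray
    q: np.ndarray  # (n_accessions, K), rows sum to 1

    def __post_init__(self) -> None:
        self.accession_ids = np.asarray(self.accession_ids, dtype=object)
        self.q = np.asarray(self.q, dtype=float)
        if self.q.ndim != 2 or self.q.shape[0] != len(self.accession_ids):
            raise ValueError("q must be (n_accessions, K)")
        if (self.q < 0).any() or (self.q > 1).any():
            raise ValueError("ancestry proportions must lie in [0, 1]")
        if not np.allclose(self.q.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("ancestry rows must sum to 1 within 1e-6")

    @property
    def K(self) -> int:
        return self.q.shape[1]


@dataclass
class FilterReport:
    """Counts of SNPs removed by each quality rule."""

    n_input: int = 0
    n_removed_call_rate: int = 0
    n_removed_mac: int = 0
    n_retained: int = 0


# ---------------------------------------------------------------------------
# genotype I/O
# ---------------------------------------------------------------------------


def read_genotypes(path, format: str = "vcf") -> GenotypeMatrix:
    """Load a genotype matrix from ``vcf`` or a ``hapmap-table`` TSV.

    Multi-allelic sites are dropped (count logged).  The result is sorted by
    (chromosome, position); duplicate SNP ids or duplicate positions within
    a chromosome raise :class:`ParseError`.
    """
    if format == "vcf":
        g = _read_vcf(str(path))
    elif format == "hapmap-table":
        g = _read_hapmap_table(str(path))
    else:
        raise ValueError(f"unknown genotype format {format!r}")
    return _sort_matrix(g)


def _sort_matrix(g: GenotypeMatrix) -> GenotypeMatrix:
    order = np.lexsort((g.pos_bp, g.chrom.astype(str)))
    return g.take_snps(order)


def _read_vcf(path: str) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=True)
    samples = list(vcf.samples)
    snp_ids, chroms, poss, refs, alts, rows = [], [], [], [], [], []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        snp_ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        gt = np.asarray(var.gt_types, dtype=np.int8)  # 0=hom-ref 1=het 2=hom-alt 3=missing
        gt[gt == 3] = MISSING
        rows.append(gt)
    vcf.close()
    if n_multi:
        logger.info("read_genotypes: dropped %d multi-allelic site(s)", n_multi)
    if not rows:
        raise ParseError(f"{path}: no biallelic variants")
    return GenotypeMatrix(
        snp_ids=np.array(snp_ids, dtype=object),
        chrom=np.array(chroms, dtype=object),
        pos_bp=np.array(poss),
        ref_allele=np.array(refs, dtype=object),
        alt_allele=np.array(alts, dtype=object),
        calls=np.vstack(rows),
        accession_ids=np.array(samples, dtype=object),
    )


def _read_hapmap_table(path: str) -> GenotypeMatrix:
    fixed = ["snp_id", "chrom", "pos", "ref", "alt"]
    try:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    except Exception as e:  # pandas raises several types; unify
        raise ParseError(f"{path}: {e}") from e
    if list(df.columns[: len(fixed)]) != fixed:
        raise ParseError(f"{path}: header must start with {fixed}")
    acc = list(df.columns[len(fixed):])
    calls = np.full((len(df), len(acc)), MISSING, dtype=np.int8)
    for j, a in enumerate(acc):
        col = df[a]
        called = col.notna() & (col.astype(str) != "NA")
        vals = pd.to_numeric(col[called], errors="coerce")
        if vals.isna().any():
            row = int(vals.index[vals.isna()][0]) + 2  # header + 1-based
            raise ParseError(f"{path}: non-numeric dosage at line {row}, column {a}")
        calls[called.to_numpy(), j] = vals.astype(np.int8)
    # multi-allelic rows: comma-separated alt
    multi = df["alt"].astype(str).str.contains(",")
    if multi.any():
        logger.info("read_genotypes: dropped %d multi-allelic site(s)", int(multi.sum()))
        df = df[~multi]
        calls = calls[~multi.to_numpy()]
    return GenotypeMatrix(
        snp_ids=df["snp_id"].to_numpy(dtype=object),
        chrom=df["chrom"].to_numpy(dtype=object),
        pos_bp=df["pos"].to_numpy(),
        ref_allele=df["ref"].to_numpy(dtype=object),
        alt_allele=df["alt"].to_numpy(dtype=object),
        calls=calls,
        accession_ids=np.array(acc, dtype=object),
    )


def write_genotypes(g: GenotypeMatrix, path, format: str = "vcf") -> None:
    """Write a genotype matrix as plain-text VCF 4.2 or a hapmap-style TSV."""
    path = str(path)
    if format == "vcf":
        _write_vcf(g, path)
    elif format == "hapmap-table":
        _write_hapmap_table(g, path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")


_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def _write_vcf(g: GenotypeMatrix, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in pd.unique(g.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, g.accession_ids))
            + "\n"
        )
        for i in range(g.n_snps):
            gts = "\t".join(_GT_CODE[int(d)] for d in g.calls[i])
            fh.write(
                f"{g.chrom[i]}\t{g.pos_bp[i]}\t{g.snp_ids[i]}\t"
                f"{g.ref_allele[i]}\t{g.alt_allele[i]}\t.\t.\t.\tGT\t{gts}\n"
            )


def _write_hapmap_table(g: GenotypeMatrix, path: str) -> None:
    df = pd.DataFrame(
        {
            "snp_id": g.snp_ids,
            "chrom": g.chrom,
            "pos": g.pos_bp,
            "ref": g.ref_allele,
            "alt": g.alt_allele,
        }
    )
    calls = g.calls.astype(object)
    calls[calls == MISSING] = "NA"
    for j, a in enumerate(g.accession_ids):
        df[str(a)] = calls[:, j]
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# SNP filtering
# ---------------------------------------------------------------------------


def filter_snps(
    g: GenotypeMatrix,
    min_call_rate: float = 0.5,
    min_mac: int = 4,
    return_report: bool = False,
):
    """Apply the GBS quality filters: call rate and minor allele count.

    A SNP is retained when its call rate is *strictly* greater than
    ``min_call_rate`` and its minor allele count over called alleles is at
    least ``min_mac`` (so the defaults encode call rate > 50 % and
    MAC > 3).  Retained SNPs keep their order.  An empty result is a
    warning, not an error.
    """
    if not 0 <= min_call_rate <= 1:
        raise ValueError("min_call_rate must lie in [0, 1]")
    if min_mac < 0:
        raise ValueError("min_mac must be non-negative")
    called = g.calls != MISSING
    n_called = called.sum(axis=1)
    call_rate = n_called / g.n_accessions
    pass_rate = call_rate > min_call_rate
    alt = np.where(called, g.calls, 0).sum(axis=1)
    mac = np.minimum(alt, 2 * n_called - alt)
    pass_mac = mac >= min_mac
    keep = pass_rate & pass_mac
    report = FilterReport(
        n_input=g.n_snps,
        n_removed_call_rate=int((~pass_rate).sum()),
        n_removed_mac=int((pass_rate & ~pass_mac).sum()),
        n_retained=int(keep.sum()),
    )
    logger.info(
        "filter_snps: %d in, %d removed by call rate, %d by MAC, %d retained",
        report.n_input,
        report.n_removed_call_rate,
        report.n_removed_mac,
        report.n_retained,
    )
    if report.n_retained == 0:
        logger.warning("filter_snps: no SNPs passed the filters")
    out = g.take_snps(np.flatnonzero(keep))
    return (out, report) if return_report else out


# ---------------------------------------------------------------------------
# Q-matrix
# ---------------------------------------------------------------------------


def read_qmatrix(path, labels) -> AncestryMatrix:
    """Read a fastStructure meanQ file (whitespace-separated floats).

    ``labels`` supplies accession ids in file row order; rows whose sum is
    within 1e-3 of 1 are renormalized, anything further off is an error.
    """
    labels = list(labels)
    try:
        q = np.loadtxt(str(path), ndmin=2)
    except ValueError as e:
        raise ParseError(f"{path}: non-numeric Q-matrix entry ({e})") from e
    if q.shape[0] != len(labels):
        raise ParseError(
            f"{path}: {q.shape[0]} rows but {len(labels)} accession labels"
        )
    if q.shape[1] < 2:
        raise ParseError(f"{path}: Q-matrix needs at least 2 columns")
    sums = q.sum(axis=1)
    bad = np.abs(sums - 1.0) > 1e-3
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise ParseError(f"{path}: row {i + 1} sums to {sums[i]:.6f}, not 1")
    return AncestryMatrix(accession_ids=np.array(labels, dtype=object), q=q / sums[:, None])


def write_qmatrix(am: AncestryMatrix, path) -> None:
    np.savetxt(str(path), am.q, fmt="%.6f")


# ---------------------------------------------------------------------------
# accession metadata
# ---------------------------------------------------------------------------


def read_metadata(path) -> pd.DataFrame:
    """Read the accession metadata TSV (AccessionTable).

    Returns a DataFrame with :data:`METADATA_COLUMNS`, indexed by row order.
    Unknown species labels are kept verbatim; coordinates and pericarp
    scores are range-checked, naming the offending row on failure.
    """
    df = pd.read_csv(str(path), sep="\t", dtype={"accession_id": str})
    missing_cols = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ParseError(f"{path}: missing metadata columns {missing_cols}")
    df = df[METADATA_COLUMNS].copy()
    return validate_metadata(df, name=str(path))


def validate_metadata(df: pd.DataFrame, name: str = "metadata") -> pd.DataFrame:
    if df["accession_id"].duplicated().any():
        dup = df.loc[df["accession_id"].duplicated(), "accession_id"].iloc[0]
        raise ParseError(f"{name}: duplicate accession_id {dup!r}")
    for col, lo, hi in [("latitude", -90, 90), ("longitude", -180, 180), ("pericarp_score", 0, 1)]:
        vals = pd.to_numeric(df[col], errors="coerce")
        out_of_range = vals.notna() & ((vals < lo) | (vals > hi))
        if out_of_range.any():
            i = int(out_of_range.idxmax())
            raise ParseError(
                f"{name}: {col}={vals[i]} out of [{lo}, {hi}] for accession "
                f"{df.loc[i, 'accession_id']!r}"
            )
        df[col] = vals
    return df


def write_metadata(df: pd.DataFrame, path) -> None:
    df[METADATA_COLUMNS].to_csv(str(path), sep="\t", index=False)
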