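"""Windowed Fst, nucleotide diversity, Jukes-Cantor distances, and NJ trees.

Statistics follow the windowed design used for GBS panels: SNPs are cut
into non-overlapping windows of a fixed SNP count (default 100) within each
chromosome, and each statistic is reported per window together with a
per-kb normalization over the window's physical span.

Fst is the Weir & Cockerham (1984) theta, computed per SNP from the
variance components a (among populations), b (among individuals within
populations) and c (within individuals), with missing genotypes excluded
per SNP.  A window's value is the ratio of sums sum(a)/sum(a+b+c) over its
SNPs; the genome-wide estimate is the mean of window values with an
empirical 95 % CI from the window-value percentiles.

Genetic distances between accessions use unphased allele-sharing (0, 0.5
or 1 per co-called site) corrected with the Jukes-Cantor model; group
distances average the corrected values over inter-group accession pairs.
Neighbor-joining trees are built with scikit-bio, with SNP-bootstrap
bipartition support.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_meta import MISSING, GenotypeMatrix

logger = logging.getLogger("orscpop")

WINDOW_COLUMNS = ["chrom", "window_index", "start_bp", "end_bp", "n_snps", "value", "per_kb"]


@dataclass
class Window:
    chrom: str
    window_index: int
    snp_rows: np.ndarray  # row indices into the genotype matrix


@dataclass
class PairwiseMatrix:
    """Symmetric non-negative matrix with a zero diagonal."""

    labels: list
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("matrix must be symmetric")
        if not np.all(np.diag(self.values) == 0):
            raise ValueError("diagonal must be exactly 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass
class FstResult:
    """Per-SNP theta plus windowed and genome-wide summaries."""

    per_snp: pd.DataFrame       # snp_id, chrom, pos_bp, a, bc_total, theta
    windows: pd.DataFrame       # WINDOW_COLUMNS, value = ratio-of-sums theta
    genome_mean: float          # mean of window values
    ci_low: float               # 2.5 percentile of window values
    ci_high: float              # 97.5 percentile
    overall_ratio: float        # sum(a)/sum(a+b+c) over every usable SNP


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------


def make_windows(g: GenotypeMatrix, snps_per_window: int = 100) -> list[Window]:
    """Cut each chromosome into consecutive blocks of exactly
    ``snps_per_window`` SNPs; a trailing partial block is dropped (logged).
    """
    if snps_per_window < 1:
        raise ValueError("snps_per_window must be positive")
    windows: list[Window] = []
    n_dropped = 0
    for c in pd.unique(g.chrom):
        rows = np.flatnonzero(g.chrom == c)
        n_full = len(rows) // snps_per_window
        if n_full == 0:
            logger.warning("make_windows: %s has %d SNPs (< %d), no windows",
                           c, len(rows), snps_per_window)
        for w in range(n_full):
            windows.append(Window(str(c), w, rows[w * snps_per_window:(w + 1) * snps_per_window]))
        n_dropped += len(rows) - n_full * snps_per_window
    if n_dropped:
        logger.info("make_windows: dropped %d trailing SNP(s) in partial windows", n_dropped)
    return windows


def _window_frame(g: GenotypeMatrix, windows, values, n_snps_used) -> pd.DataFrame:
    rows = []
    for w, val, n_used in zip(windows, values, n_snps_used):
        start = int(g.pos_bp[w.snp_rows[0]])
        end = int(g.pos_bp[w.snp_rows[-1]])
        span_kb = (end - start) / 1000.0
        per_kb = val / span_kb if span_kb > 0 and np.isfinite(val) else np.nan
        rows.append((w.chrom, w.window_index, start, end, n_used, val, per_kb))
    return pd.DataFrame(rows, columns=WINDOW_COLUMNS)


# ---------------------------------------------------------------------------
# Weir-Cockerham Fst
# ---------------------------------------------------------------------------


def wc_variance_components(g: GenotypeMatrix, pops: dict[str, list]) -> pd.DataFrame:
    """Per-SNP Weir-Cockerham variance components for two or more groups.

    ``pops`` maps a group name to its accession ids.  Missing genotypes are
    excluded per SNP (pairwise deletion); a SNP where any group has no
    called accession, or that is monomorphic over all groups, gets NaN
    components and is excluded from window sums downstream.

    Returns a DataFrame with columns a, bc_total (= a+b+c), theta.
    """
    if len(pops) < 2:
        raise ValueError("need at least two groups")
    groups = [g.accession_indices(ids) for ids in pops.values()]
    r = len(groups)

    n_i = np.empty((g.n_snps, r))      # called individuals per group
    p_i = np.empty((g.n_snps, r))      # alt-allele frequency per group
    h_i = np.empty((g.n_snps, r))      # observed het frequency per group
    for k, idx in enumerate(groups):
        sub = g.calls[:, idx]
        called = sub != MISSING
        n = called.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            alt = np.where(called, sub, 0).sum(axis=1)
            n_i[:, k] = n
            p_i[:, k] = np.where(n > 0, alt / (2 * n), np.nan)
            h_i[:, k] = np.where(n > 0, (sub == 1).sum(axis=1) / n, np.nan)

    ok = (n_i >= 1).all(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        n_bar = n_i.mean(axis=1)
        n_c = (r * n_bar - (n_i**2).sum(axis=1) / (r * n_bar)) / (r - 1)
        p_bar = (n_i * p_i).sum(axis=1) / (r * n_bar)
        s2 = (n_i * (p_i - p_bar[:, None]) ** 2).sum(axis=1) / ((r - 1) * n_bar)
        h_bar = (n_i * h_i).sum(axis=1) / (r * n_bar)

        inner = p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4
        a = n_bar / n_c * (s2 - inner / (n_bar - 1))
        b = n_bar / (n_bar - 1) * (
            p_bar * (1 - p_bar) - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
        )
        c = h_bar / 2
        total = a + b + c

    # monomorphic across all groups, or any group uncallable, or n_bar <= 1
    usable = ok & (n_bar > 1) & np.isfinite(total) & (total != 0)
    poly = (p_bar > 0) & (p_bar < 1)
    usable &= poly
    a = np.where(usable, a, np.nan)
    total = np.where(usable, total, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = a / total
    return pd.DataFrame(
        {
            "snp_id": g.snp_ids,
            "chrom": g.chrom,
            "pos_bp": g.pos_bp,
            "a": a,
            "bc_total": total,
            "theta": theta,
        }
    )


def wc_fst(
    g: GenotypeMatrix,
    pops: dict[str, list],
    windows: list[Window] | None = None,
    snps_per_window: int = 100,
) -> FstResult:
    """Windowed Weir-Cockerham Fst between two or more accession groups."""
    per_snp = wc_variance_components(g, pops)
    if windows is None:
        windows = make_windows(g, snps_per_window)
    a = per_snp["a"].to_numpy()
    tot = per_snp["bc_total"].to_numpy()
    values, n_used = [], []
    for w in windows:
        wa, wt = a[w.snp_rows], tot[w.snp_rows]
        use = np.isfinite(wt)
        denom = wt[use].sum()
        values.append(wa[use].sum() / denom if use.any() and denom != 0 else np.nan)
        n_used.append(int(use.sum()))
    wdf = _window_frame(g, windows, values, n_used)
    vals = wdf["value"].dropna().to_numpy()
    if len(vals) == 0:
        genome, lo, hi = np.nan, np.nan, np.nan
    else:
        genome = float(vals.mean())
        lo, hi = (float(x) for x in np.percentile(vals, [2.5, 97.5]))
    use = np.isfinite(tot)
    overall = float(a[use].sum() / tot[use].sum()) if use.any() else np.nan
    return FstResult(per_snp=per_snp, windows=wdf, genome_mean=genome,
                     ci_low=lo, ci_high=hi, overall_ratio=overall)


def pairwise_fst(g: GenotypeMatrix, pops: dict[str, list],
                 snps_per_window: int = 100) -> PairwiseMatrix:
    """Genome-wide Fst (mean of windows) for every pair of groups."""
    names = list(pops)
    m = np.zeros((len(names), len(names)))
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            res = wc_fst(g, {names[i]: pops[names[i]], names[j]: pops[names[j]]},
                         snps_per_window=snps_per_window)
            m[i, j] = m[j, i] = res.genome_mean
    return PairwiseMatrix(labels=names, values=m)


# ---------------------------------------------------------------------------
# nucleotide diversity
# ---------------------------------------------------------------------------


def pi_per_snp(g: GenotypeMatrix, pop) -> np.ndarray:
    """Unbiased per-SNP diversity (n/(n-1)) * 2p(1-p) over called alleles."""
    idx = g.accession_indices(pop)
    sub = g.calls[:, idx]
    called = sub != MISSING
    n = 2 * called.sum(axis=1)  # called alleles
    alt = np.where(called, sub, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / n, np.nan)
        pi = np.where(n > 1, n / (n - 1) * 2 * p * (1 - p), np.nan)
    return pi


def pi_within(
    g: GenotypeMatrix,
    pop,
    windows: list[Window] | None = None,
    snps_per_window: int = 100,
) -> pd.DataFrame:
    """Windowed nucleotide diversity within one population.

    The window value is the sum of per-SNP diversities; ``per_kb`` divides
    by the window's physical span in kb (NaN when the span is zero).
    """
    if len(pop) < 2:
        raise ValueError("population needs at least 2 accessions")
    if windows is None:
        windows = make_windows(g, snps_per_window)
    pi = pi_per_snp(g, pop)
    values, n_used = [], []
    for w in windows:
        v = pi[w.snp_rows]
        use = np.isfinite(v)
        values.append(float(v[use].sum()))
        n_used.append(int(use.sum()))
    return _window_frame(g, windows, values, n_used)


# ---------------------------------------------------------------------------
# Jukes-Cantor distance
# ---------------------------------------------------------------------------


def jc_correct(p):
    """Jukes-Cantor correction d = -(3/4) ln(1 - 4p/3), valid for p < 0.75."""
    p_arr = np.asarray(p, dtype=float)
    if np.any((p_arr < 0) | (p_arr >= 0.75)):
        raise ValueError("Jukes-Cantor correction requires 0 <= p < 0.75")
    d = -0.75 * np.log1p(-4.0 * p_arr / 3.0)
    return float(d) if np.isscalar(p) or p_arr.ndim == 0 else d


def _allele_sharing_p(calls: np.ndarray, i: int, j: int, rows: np.ndarray) -> float:
    """Mean per-site allele-sharing distance between two accessions.

    Site distance is |dosage_i - dosage_j| / 2 (0, 0.5 or 1), over
    co-called SNPs in ``rows``.  NaN when no SNP is co-called.
    """
    a, b = calls[rows, i], calls[rows, j]
    ok = (a != MISSING) & (b != MISSING)
    if not ok.any():
        return np.nan
    return float(np.abs(a[ok] - b[ok]).mean() / 2.0)


def individual_distances(g: GenotypeMatrix, ids=None, polymorphic_only: bool = True) -> PairwiseMatrix:
    """JC-corrected allele-sharing distance matrix between accessions."""
    ids = list(g.accession_ids if ids is None else ids)
    idx = g.accession_indices(ids)
    sub = g.calls[:, idx]
    if polymorphic_only:
        rows = np.flatnonzero(_polymorphic_rows(sub))
    else:
        rows = np.arange(g.n_snps)
    n = len(ids)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p = _allele_sharing_p(sub, i, j, rows)
            if np.isnan(p):
                logger.warning("individual_distances: %s vs %s share no co-called SNP",
                               ids[i], ids[j])
                m[i, j] = m[j, i] = np.nan
            else:
                m[i, j] = m[j, i] = jc_correct(min(p, 0.7499999))
    return PairwiseMatrix(labels=ids, values=m)


def _polymorphic_rows(sub: np.ndarray) -> np.ndarray:
    called = sub != MISSING
    n = 2 * called.sum(axis=1)
    alt = np.where(called, sub, 0).sum(axis=1)
    return (alt > 0) & (alt < n)


def pairwise_distance(g: GenotypeMatrix, groups: dict[str, list]) -> PairwiseMatrix:
    """Mean JC-corrected distance between accession groups.

    For each group pair the SNP set is restricted to SNPs polymorphic in
    the union of the two groups; the entry is the mean corrected distance
    over all inter-group accession pairs.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    m = np.zeros((len(names), len(names)))
    for gi in range(len(names)):
        for gj in range(gi + 1, len(names)):
            ids_i, ids_j = list(groups[names[gi]]), list(groups[names[gj]])
            union = ids_i + ids_j
            idx = g.accession_indices(union)
            sub = g.calls[:, idx]
            rows = np.flatnonzero(_polymorphic_rows(sub))
            ds = []
            for a in range(len(ids_i)):
                for b in range(len(ids_i), len(union)):
                    p = _allele_sharing_p(sub, a, b, rows)
                    if not np.isnan(p):
                        ds.append(jc_correct(min(p, 0.7499999)))
            m[gi, gj] = m[gj, gi] = float(np.mean(ds)) if ds else np.nan
    return PairwiseMatrix(labels=names, values=m)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------


def nj_tree(m: PairwiseMatrix):
    """Saitou-Nei neighbor joining on a distance matrix (scikit-bio TreeNode)."""
    from skbio import DistanceMatrix
    from skbio.tree import nj

    if len(m.labels) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if not np.all(np.isfinite(m.values)):
        raise ValueError("distance matrix has missing entries")
    return nj(DistanceMatrix(m.values, [str(x) for x in m.labels]))


def _bipartitions(tree, taxa: frozenset) -> set[frozenset]:
    splits = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(taxa) - 1:
            splits.add(min(side, taxa - side, key=sorted))
    return splits


def bootstrap_support(
    g: GenotypeMatrix,
    groups: dict[str, list] | None,
    n_reps: int = 100,
    seed: int = 0,
    ids=None,
) -> tuple[object, dict[frozenset, float]]:
    """NJ tree with SNP-bootstrap bipartition support.

    Resamples SNPs with replacement ``n_reps`` times, rebuilds the distance
    matrix and tree, and reports for each internal bipartition of the
    reference tree the fraction of replicate trees containing it.
    """
    rng = np.random.default_rng(seed)

    def distances(matrix: GenotypeMatrix) -> PairwiseMatrix:
        if groups is not None:
            return pairwise_distance(matrix, groups)
        return individual_distances(matrix, ids=ids)

    ref_m = distances(g)
    ref_tree = nj_tree(ref_m)
    taxa = frozenset(str(x) for x in ref_m.labels)
    ref_splits = _bipartitions(ref_tree, taxa)
    counts = {s: 0 for s in ref_splits}
    for _ in range(n_reps):
        rows = rng.integers(0, g.n_snps, size=g.n_snps)
        rows = np.sort(rows)
        boot = GenotypeMatrix(
            snp_ids=np.array([f"b{k}" for k in range(g.n_snps)], dtype=object),
            chrom=g.chrom[rows],
            pos_bp=np.arange(1, g.n_snps + 1) * 10,  # placeholder coords
            ref_allele=g.ref_allele[rows],
            alt_allele=g.alt_allele[rows],
            calls=g.calls[rows],
            accession_ids=g.accession_ids,
        )
        for s in _bipartitions(nj_tree(distances(boot)), taxa):
            if s in counts:
                counts[s] += 1
    support = {s: 100.0 * c / n_reps for s, c in counts.items()}
    return ref_tree, support


def write_newick(tree, path) -> None:
    buf = io.StringIO()
    tree.write(buf)
    with open(str(path), "w") as fh:
        fh.write(buf.getvalue())
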