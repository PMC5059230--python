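"""Linkage-disequilibrium decay: pairwise r2, distance binning, sub-sampling CIs.

r2 is the composite (genotype-dosage) measure: the squared Pearson
correlation of the two SNPs' dosage vectors over co-called accessions.
It is computed within populations for same-chromosome SNP pairs up to a
maximum distance (default 10 Mb), after a per-population SNP filter
(missing fraction <= 30 %, minor allele carried by >= 2 accessions).

Because mean r2 is biased upward in small samples, populations of unequal
size are compared by repeatedly sub-sampling a fixed number of accessions
(default 12, the size of the smallest group in the study design) and
re-running the full filter + r2 + binning pipeline per draw, yielding a
per-bin mean and empirical 95 % band.  A population already at the target
size is analysed once, without a band.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_meta import MISSING, GenotypeMatrix

logger = logging.getLogger("orscpop")

LDBIN_COLUMNS = ["dist_lo_bp", "dist_hi_bp", "mean_r2", "n_pairs", "ci_lo", "ci_hi"]


def default_bin_edges(max_dist_bp: int = 10_000_000, step_bp: int = 100_000) -> np.ndarray:
    """0..max in fixed steps; bins are half-open [lo, hi)."""
    return np.arange(0, max_dist_bp + step_bp, step_bp)


# ---------------------------------------------------------------------------
# per-population SNP filter
# ---------------------------------------------------------------------------


def ld_filter(g: GenotypeMatrix, pop) -> GenotypeMatrix:
    """Keep SNPs with <= 30 % missing data in ``pop`` and a minor allele
    carried by at least two accessions of ``pop``."""
    if len(pop) == 0:
        raise ValueError("population is empty")
    idx = g.accession_indices(pop)
    sub = g.calls[:, idx]
    called = sub != MISSING
    n = called.sum(axis=1)
    missing_frac = 1 - n / len(idx)
    alt = np.where(called, sub, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        minor_is_alt = alt <= 2 * n - alt
    minor_dosage_present = np.where(
        minor_is_alt[:, None], (sub > 0) & called, (sub < 2) & called
    )
    n_carriers = minor_dosage_present.sum(axis=1)
    keep = (missing_frac <= 0.30 + 1e-9) & (n_carriers >= 2)
    return g.take_snps(np.flatnonzero(keep))


# ---------------------------------------------------------------------------
# pairwise r2
# ---------------------------------------------------------------------------


def pairwise_r2(
    g: GenotypeMatrix,
    pop,
    max_dist_bp: int = 10_000_000,
    min_called: int = 4,
) -> pd.DataFrame:
    """(distance, r2) for same-chromosome SNP pairs within ``max_dist_bp``.

    r2 is the squared Pearson correlation of dosages over co-called
    accessions; pairs with fewer than ``min_called`` co-called accessions
    or zero variance in either vector are skipped.
    """
    idx = g.accession_indices(pop)
    dists, r2s = [], []
    for c in pd.unique(g.chrom):
        rows = np.flatnonzero(g.chrom == c)
        if len(rows) < 2:
            continue
        X = g.calls[rows][:, idx].astype(float)
        M = (X != MISSING).astype(float)
        Xz = np.where(M > 0, X, 0.0)
        # pairwise sufficient statistics over co-called accessions
        N = M @ M.T
        Sx = Xz @ M.T          # sum of x over co-called, per (x-row, y-row)
        Sy = Sx.T
        Sxy = Xz @ Xz.T
        Sxx = (Xz**2) @ M.T
        Syy = Sxx.T
        with np.errstate(invalid="ignore", divide="ignore"):
            cov = Sxy - Sx * Sy / N
            varx = Sxx - Sx**2 / N
            vary = Syy - Sy**2 / N
            r2 = cov**2 / (varx * vary)
        pos = g.pos_bp[rows]
        iu, ju = np.triu_indices(len(rows), k=1)
        d = np.abs(pos[ju] - pos[iu])
        ok = (
            (d <= max_dist_bp)
            & (N[iu, ju] >= min_called)
            & (varx[iu, ju] > 0)
            & (vary[iu, ju] > 0)
        )
        dists.append(d[ok])
        r2s.append(r2[iu, ju][ok])
    if not dists:
        return pd.DataFrame({"dist_bp": [], "r2": []})
    return pd.DataFrame(
        {"dist_bp": np.concatenate(dists), "r2": np.concatenate(r2s)}
    )


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------


def bin_ld(pairs: pd.DataFrame, bin_edges_bp) -> pd.DataFrame:
    """Mean r2 within half-open distance bins [lo, hi).

    A pair landing exactly on an edge belongs to the bin starting at that
    edge.  Empty bins report NaN with n_pairs = 0.
    """
    edges = np.asarray(bin_edges_bp, dtype=float)
    if len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be increasing with >= 2 values")
    d = pairs["dist_bp"].to_numpy(dtype=float)
    r2 = pairs["r2"].to_numpy(dtype=float)
    which = np.digitize(d, edges, right=False) - 1  # [lo, hi)
    in_range = (which >= 0) & (which < len(edges) - 1)
    means = np.full(len(edges) - 1, np.nan)
    counts = np.zeros(len(edges) - 1, dtype=int)
    for b in range(len(edges) - 1):
        sel = in_range & (which == b)
        counts[b] = int(sel.sum())
        if counts[b]:
            means[b] = r2[sel].mean()
    return pd.DataFrame(
        {
            "dist_lo_bp": edges[:-1].astype(int),
            "dist_hi_bp": edges[1:].astype(int),
            "mean_r2": means,
            "n_pairs": counts,
            "ci_lo": np.nan,
            "ci_hi": np.nan,
        }
    )


def ld_decay_bins(
    g: GenotypeMatrix, pop, bin_edges_bp=None, max_dist_bp: int = 10_000_000
) -> pd.DataFrame:
    """Filter, compute pairwise r2, and bin — the single-population pipeline."""
    if bin_edges_bp is None:
        bin_edges_bp = default_bin_edges(max_dist_bp)
    filtered = ld_filter(g, pop)
    pairs = pairwise_r2(filtered, pop, max_dist_bp=max_dist_bp)
    return bin_ld(pairs, bin_edges_bp)


# ---------------------------------------------------------------------------
# equal-sample-size sub-sampling
# ---------------------------------------------------------------------------


def subsample_ld(
    g: GenotypeMatrix,
    pops: dict[str, list],
    n_sub: int = 12,
    n_reps: int = 100,
    seed: int = 0,
    bin_edges_bp=None,
    max_dist_bp: int = 10_000_000,
) -> dict[str, pd.DataFrame]:
    """Per-population binned LD with equal-sample-size CIs.

    A population of exactly ``n_sub`` accessions is the reference: analysed
    once, no CI.  Larger populations are sub-sampled without replacement
    ``n_reps`` times, the whole filter + r2 + binning pipeline re-run per
    draw, and each bin reports the replicate mean with 2.5/97.5 percentile
    bounds.  A population smaller than ``n_sub`` is an error.
    """
    if bin_edges_bp is None:
        bin_edges_bp = default_bin_edges(max_dist_bp)
    rng = np.random.default_rng(seed)
    out: dict[str, pd.DataFrame] = {}
    for name, ids in pops.items():
        ids = list(ids)
        if len(ids) < n_sub:
            raise ValueError(
                f"population {name!r} has {len(ids)} accessions, fewer than n_sub={n_sub}"
            )
        if len(ids) == n_sub:
            out[name] = ld_decay_bins(g, ids, bin_edges_bp, max_dist_bp)
            continue
        reps = np.full((n_reps, len(bin_edges_bp) - 1), np.nan)
        for r in range(n_reps):
            draw = [ids[k] for k in rng.choice(len(ids), size=n_sub, replace=False)]
            reps[r] = ld_decay_bins(g, draw, bin_edges_bp, max_dist_bp)["mean_r2"].to_numpy()
        with np.errstate(invalid="ignore"):
            mean = np.nanmean(reps, axis=0)
            lo = np.nanpercentile(reps, 2.5, axis=0)
            hi = np.nanpercentile(reps, 97.5, axis=0)
        df = bin_ld(pd.DataFrame({"dist_bp": [], "r2": []}), bin_edges_bp)
        df["mean_r2"], df["ci_lo"], df["ci_hi"] = mean, lo, hi
        df["n_pairs"] = np.sum(~np.isnan(reps), axis=0)  # replicates contributing
        out[name] = df
    return out


def write_ld_bins(bins: dict[str, pd.DataFrame], path) -> None:
    frames = []
    for pop, df in bins.items():
        d = df.copy()
        d.insert(0, "pop", pop)
        frames.append(d)
    pd.concat(frames, ignore_index=True).to_csv(str(path), sep="\t", index=False)
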