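"""Synthetic structured-panel generators for end-to-end testing.

Every analysis stage in this package can be exercised on data produced
here, with known ground truth:

* Nuclear genotypes follow the Balding-Nichols model: each SNP draws an
  ancestral frequency p ~ Uniform(0.05, 0.95); each subpopulation k with
  differentiation F_k draws its frequency from
  Beta(p(1-F_k)/F_k, (1-p)(1-F_k)/F_k); pure accessions are
  Binomial(2, p_k).  Admixed accessions draw a Dirichlet(1,...,1) ancestry
  vector and sample each allele copy from an ancestry-weighted group.
  F_k is exactly the Weir-Cockerham estimand, so estimator recovery can be
  checked directly.  Setting ``recomb_block_bp`` switches allele copies to
  mosaics of a small group-specific haplotype pool with exponential
  segment lengths, which induces monotonically decaying LD without a full
  recombination model; left unset, SNPs are independent.
* Geography places one centroid per subpopulation and scatters members
  around it, with admixed accessions at ancestry-weighted positions, so
  genetic and geographic distances correlate (isolation by distance).
* Chloroplast haplotypes perform a stepwise mutation walk from a root:
  each subpopulation founder derives ``theta_cp`` group-private sites;
  members add 0-2 further steps; outgroups sit >= 6 shared steps from the
  root.  One site is a deletion analog with a nested SNP at the next site
  (deriving in different groups, as for the classic 69-bp chloroplast
  deletion and the SNP inside it).
* The domestication panel plants a focal deletion locus plus a block of
  cultivated-differentiated SNPs around it in a known set of introgressed
  accessions, alongside red-pericarp wild and white-pericarp cultivated
  reference accessions.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .haplonet import CP_MISSING, HaplotypeAlignment
from .io_meta import MISSING, AncestryMatrix, GenotypeMatrix, METADATA_COLUMNS

logger = logging.getLogger("orscpop")

#: 12 rice-like chromosome lengths in bp (23-45 Mb)
RICE_CHROM_LENGTHS = (
    45_000_000, 36_000_000, 38_000_000, 35_000_000, 30_000_000, 32_000_000,
    30_000_000, 28_000_000, 24_000_000, 24_000_000, 30_000_000, 23_000_000,
)

OUTGROUP_LABEL = "outgroup"
ROOT_RELATIVE_LABEL = "AA-relative"


@dataclass
class SimConfig:
    """Parameters of the synthetic study panel.

    Defaults emulate the study design this package targets: 6 wild
    subpopulations (the smallest with 12 members), ~25 % admixed
    accessions, ~28 % missing genotype calls, 25 chloroplast sites.
    ``n_snps`` defaults to a desk-scale 5000.
    """

    K: int = 6
    fst_targets: tuple = (0.15, 0.20, 0.25, 0.20, 0.30, 0.25)
    n_per_group: tuple = (60, 35, 20, 40, 12, 47)
    n_admixed: int = 72
    n_snps: int = 5000
    chrom_lengths: tuple = RICE_CHROM_LENGTHS
    missing_rate: float = 0.28
    seed: int = 0
    theta_cp: int = 3
    n_cp_sites: int = 25
    recomb_block_bp: int | None = None
    n_hap_pool: int = 8
    n_outgroups: int = 3
    n_root_relatives: int = 2
    species_label_noise: float = 0.10
    # domestication panel
    n_dom_wild: int = 70
    n_dom_introgressed: int = 10
    n_dom_cultivated: int = 30
    n_dom_block_snps: int = 40
    n_dom_background_snps: int = 60
    dom_block_halfwidth_bp: int = 290_000
    dom_focal_pos: int = 2_000_000
    dom_chrom: str = "7"
    n_dom_discordant: int = 0

    def __post_init__(self) -> None:
        if self.K < 1 or self.n_snps < 1 or self.n_cp_sites < 5:
            raise ValueError("counts must be positive (n_cp_sites >= 5)")
        if len(self.fst_targets) != self.K or len(self.n_per_group) != self.K:
            raise ValueError("fst_targets and n_per_group must have length K")
        if any(not 0 <= f < 1 for f in self.fst_targets):
            raise ValueError("fst_targets must lie in [0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if len(self.chrom_lengths) != 12:
            raise ValueError("chrom_lengths must list 12 chromosomes")

    @property
    def group_names(self) -> list:
        return [f"W{k + 1}" for k in range(self.K)]


@dataclass
class TruthSet:
    """Ground truth emitted alongside each simulated panel."""

    true_q: AncestryMatrix
    true_fst: tuple
    group_names: list
    centroids: dict = field(default_factory=dict)           # group -> (lat, lon)
    founder_haplotypes: dict = field(default_factory=dict)  # group -> sequence str
    founder_walks: dict = field(default_factory=dict)       # group -> [seq, ...] root->founder
    root_haplotype: str = ""
    introgressed_ids: list = field(default_factory=list)
    dom_block_snp_ids: list = field(default_factory=list)
    dom_ingene_snp_ids: list = field(default_factory=list)
    dom_region: tuple | None = None
    dom_discordant_ids: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _snp_positions(cfg: SimConfig, rng, n_snps: int):
    """Uniform SNP placement over the 12 chromosomes; unique, sorted."""
    lengths = np.asarray(cfg.chrom_lengths, dtype=float)
    probs = lengths / lengths.sum()
    counts = rng.multinomial(n_snps, probs)
    chroms, poss = [], []
    for c, (n_c, L) in enumerate(zip(counts, lengths), start=1):
        pos = np.unique(rng.integers(1, int(L), size=n_c))
        while len(pos) < n_c:  # top up collisions
            extra = rng.integers(1, int(L), size=n_c - len(pos))
            pos = np.unique(np.concatenate([pos, extra]))
        chroms.extend([str(c)] * n_c)
        poss.extend(pos.tolist())
    chroms = np.array(chroms, dtype=object)
    poss = np.array(poss, dtype=np.int64)
    # canonical (lexicographic chromosome, position) order, matching the
    # genotype loaders so emitted files round-trip exactly
    order = np.lexsort((poss, chroms.astype(str)))
    return chroms[order], poss[order]


def _group_frequencies(cfg: SimConfig, rng, n_snps: int) -> np.ndarray:
    """(K, n_snps) Balding-Nichols group allele frequencies."""
    p = rng.uniform(0.05, 0.95, size=n_snps)
    P = np.empty((cfg.K, n_snps))
    for k, F in enumerate(cfg.fst_targets):
        if F == 0:
            P[k] = p
        else:
            shape = (1 - F) / F
            P[k] = rng.beta(p * shape, (1 - p) * shape)
    return P


def _mosaic_gamete(rng, pool: np.ndarray, chrom_arr, pos_arr, chrom_lengths,
                   block_bp: float) -> np.ndarray:
    """One allele copy as a mosaic of pool haplotypes with Exp(block_bp) segments."""
    S = pool.shape[1]
    out = np.empty(S, dtype=np.int8)
    for c_idx, L in enumerate(chrom_lengths, start=1):
        sel = chrom_arr == str(c_idx)
        if not sel.any():
            continue
        pos = pos_arr[sel]
        cuts = [0.0]
        while cuts[-1] < L:
            cuts.append(cuts[-1] + rng.exponential(block_bp))
        seg = np.searchsorted(np.array(cuts[1:]), pos, side="right")
        hap_per_seg = rng.integers(0, pool.shape[0], size=len(cuts))
        out[sel] = pool[hap_per_seg[seg], np.flatnonzero(sel)]
    return out


# ---------------------------------------------------------------------------
# nuclear panel
# ---------------------------------------------------------------------------


def simulate_structured_genotypes(cfg: SimConfig):
    """Simulate the structured nuclear panel.

    Returns (GenotypeMatrix, metadata DataFrame, TruthSet).  Deterministic
    under ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    chrom, pos = _snp_positions(cfg, rng, cfg.n_snps)
    P = _group_frequencies(cfg, rng, cfg.n_snps)
    n_pure = int(sum(cfg.n_per_group))
    n_total = n_pure + cfg.n_admixed
    acc_ids = [f"A{i + 1:04d}" for i in range(n_total)]

    # true ancestry: one-hot for pure, Dirichlet(1) for admixed
    q = np.zeros((n_total, cfg.K))
    memberships = []
    i = 0
    for k, n_k in enumerate(cfg.n_per_group):
        for _ in range(n_k):
            q[i, k] = 1.0
            memberships.append(cfg.group_names[k])
            i += 1
    if cfg.n_admixed:
        q[n_pure:] = rng.dirichlet(np.ones(cfg.K), size=cfg.n_admixed)
        memberships.extend(["admixed"] * cfg.n_admixed)

    pools = None
    if cfg.recomb_block_bp:
        pools = [
            (rng.random((cfg.n_hap_pool, cfg.n_snps)) < P[k]).astype(np.int8)
            for k in range(cfg.K)
        ]

    calls = np.empty((cfg.n_snps, n_total), dtype=np.int8)
    for i in range(n_total):
        qi = q[i]
        if pools is None:
            if qi.max() == 1.0:
                k = int(qi.argmax())
                calls[:, i] = rng.binomial(2, P[k])
            else:
                dosage = np.zeros(cfg.n_snps, dtype=np.int8)
                for _ in range(2):
                    grp = rng.choice(cfg.K, size=cfg.n_snps, p=qi)
                    dosage += (rng.random(cfg.n_snps) < P[grp, np.arange(cfg.n_snps)])
                calls[:, i] = dosage
        else:
            dosage = np.zeros(cfg.n_snps, dtype=np.int8)
            for _ in range(2):
                k = int(rng.choice(cfg.K, p=qi))
                dosage += _mosaic_gamete(rng, pools[k], chrom, pos,
                                         cfg.chrom_lengths, cfg.recomb_block_bp)
            calls[:, i] = dosage

    if cfg.missing_rate > 0:
        mask = rng.random(calls.shape) < cfg.missing_rate
        calls[mask] = MISSING

    g = GenotypeMatrix(
        snp_ids=np.array([f"S{chrom[j]}_{pos[j]}" for j in range(cfg.n_snps)], dtype=object),
        chrom=chrom,
        pos_bp=pos,
        ref_allele=np.array(["A"] * cfg.n_snps, dtype=object),
        alt_allele=np.array(["G"] * cfg.n_snps, dtype=object),
        calls=calls,
        accession_ids=np.array(acc_ids, dtype=object),
    )

    # species labels: odd groups perennial-like, even groups annual-like,
    # flipped with probability species_label_noise
    base_label = {
        name: ("O. rufipogon" if k % 2 == 0 else "O. nivara")
        for k, name in enumerate(cfg.group_names)
    }
    labels = []
    for i in range(n_total):
        k = int(q[i].argmax())
        lab = base_label[cfg.group_names[k]]
        if rng.random() < cfg.species_label_noise:
            lab = "O. nivara" if lab == "O. rufipogon" else "O. rufipogon"
        labels.append(lab)

    meta = pd.DataFrame(
        {c: pd.Series([np.nan] * n_total, dtype=object) for c in METADATA_COLUMNS}
    )
    meta["accession_id"] = acc_ids
    meta["species_label"] = labels
    meta["country"] = "synthetic"
    meta["subpop"] = memberships
    truth = TruthSet(
        true_q=AncestryMatrix(np.array(acc_ids, dtype=object), q),
        true_fst=tuple(cfg.fst_targets),
        group_names=cfg.group_names,
    )
    return g, meta, truth


# ---------------------------------------------------------------------------
# geography
# ---------------------------------------------------------------------------

_BASE_LAT, _BASE_LON = 15.0, 100.0
_KM_PER_DEG = 111.0


def simulate_geography(
    table: pd.DataFrame,
    truth: TruthSet,
    centroid_spread_km: float = 2000.0,
    jitter_km: float = 100.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Place accessions on the map with ancestry-correlated coordinates.

    Each subpopulation receives a centroid scattered around a common base
    point with SD ``centroid_spread_km``; members are jittered around it
    with SD ``jitter_km``.  Admixed accessions sit at the ancestry-weighted
    average of the centroids.  Coordinates are clipped to valid ranges.
    """
    rng = np.random.default_rng(seed)
    if table["subpop"].isna().all():
        raise ValueError("subpop assignments are required before geography")
    names = truth.group_names
    cent = {}
    for name in names:
        dlat = rng.normal(0, centroid_spread_km) / _KM_PER_DEG
        dlon = rng.normal(0, centroid_spread_km) / (_KM_PER_DEG * np.cos(np.radians(_BASE_LAT)))
        cent[name] = (_BASE_LAT + dlat, _BASE_LON + dlon)
    truth.centroids = cent
    qmap = {a: truth.true_q.q[i] for i, a in enumerate(truth.true_q.accession_ids)}
    out = table.copy()
    lats, lons = [], []
    for _, row in out.iterrows():
        sp = row["subpop"]
        if sp in cent:
            base = cent[sp]
        else:  # admixed: ancestry-weighted centroid
            qi = qmap[row["accession_id"]]
            base = (
                float(sum(qi[k] * cent[names[k]][0] for k in range(len(names)))),
                float(sum(qi[k] * cent[names[k]][1] for k in range(len(names)))),
            )
        lat = base[0] + rng.normal(0, jitter_km) / _KM_PER_DEG
        lon = base[1] + rng.normal(0, jitter_km) / (_KM_PER_DEG * np.cos(np.radians(_BASE_LAT)))
        lats.append(float(np.clip(lat, -89.0, 89.0)))
        lons.append(float(np.clip(lon, -179.0, 179.0)))
    out["latitude"] = lats
    out["longitude"] = lons
    return out


# ---------------------------------------------------------------------------
# chloroplast haplotypes
# ---------------------------------------------------------------------------

# site 0: deletion analog (I = insertion/ancestral, D = deletion/derived)
# site 1: SNP nested inside the deletion (A ancestral, G derived)
_CP_ANC = ["I", "A"]
_CP_DER = ["D", "G"]
_OUTGROUP_STEPS = 6


def simulate_chloroplast(cfg: SimConfig, truth: TruthSet, seed: int | None = None) -> HaplotypeAlignment:
    """Stepwise-mutation chloroplast haplotypes with group-private founders.

    Site 0 is a deletion analog and site 1 its nested SNP; they derive in
    different subpopulations.  Outgroups share a 6-step divergence path on
    outgroup-private sites.
    """
    S = cfg.n_cp_sites
    need = cfg.K * cfg.theta_cp + _OUTGROUP_STEPS
    if need > S:
        raise ValueError(
            f"requested mutation steps ({need}) exceed available sites ({S})"
        )
    rng = np.random.default_rng(cfg.seed + 101 if seed is None else seed)
    anc = np.array(
        _CP_ANC + [rng.choice(list("ACGT")) for _ in range(S - 2)], dtype=object
    )
    der = np.empty(S, dtype=object)
    der[0], der[1] = _CP_DER
    for s in range(2, S):
        der[s] = rng.choice([c for c in "ACGT" if c != anc[s]])
    site_kind = ["indel"] + ["SNP"] * (S - 1)
    site_ids = [f"cp{s + 1}" for s in range(S)]
    root = anc.copy()

    # partition sites: group-private walks, outgroup path, reserve; the two
    # special sites derive in different groups (when K >= 2)
    free = list(range(2, S))
    rng.shuffle(free)
    ptr = 0

    def take(n: int) -> list[int]:
        nonlocal ptr
        got = free[ptr:ptr + n]
        ptr += n
        return got

    walks_sites: list[list[int]] = []
    for k in range(cfg.K):
        if cfg.theta_cp >= 1 and cfg.K >= 2 and k == 1 % cfg.K:
            sites = [0] + take(cfg.theta_cp - 1)   # deletion derives here
        elif cfg.theta_cp >= 1 and cfg.K >= 2 and k == 2 % cfg.K:
            sites = [1] + take(cfg.theta_cp - 1)   # nested SNP derives here
        else:
            sites = take(cfg.theta_cp)
        walks_sites.append(sites)
    out_sites = take(_OUTGROUP_STEPS)
    reserve = free[ptr:]

    founders, walks = {}, {}
    for k, name in enumerate(truth.group_names):
        h = root.copy()
        walk = ["".join(h)]
        for s in walks_sites[k]:
            h = h.copy()
            h[s] = der[s]
            walk.append("".join(h))
        founders[name] = "".join(h)
        walks[name] = walk
    truth.root_haplotype = "".join(root)
    truth.founder_haplotypes = founders
    truth.founder_walks = walks

    founder_vec = {name: np.array(list(seq), dtype=object) for name, seq in founders.items()}
    acc_ids, groups, rows = [], [], []
    qmap = {a: truth.true_q.q[i] for i, a in enumerate(truth.true_q.accession_ids)}
    extra_max = min(2, cfg.theta_cp, len(reserve))
    seen_groups: set[str] = set()
    for a in truth.true_q.accession_ids:
        qi = qmap[a]
        k = int(np.argmax(qi))
        name = truth.group_names[k]
        h = founder_vec[name].copy()
        # the first member of each group carries the founder haplotype
        # exactly, so every founder is a sampled network node
        if name in seen_groups and extra_max:
            n_extra = int(rng.integers(0, extra_max + 1))
            if n_extra:
                for s in rng.choice(reserve, size=n_extra, replace=False):
                    h[s] = der[s]
        seen_groups.add(name)
        acc_ids.append(str(a))
        groups.append(name if qi.max() >= 0.75 else "admixed")
        rows.append(h)
    for j in range(cfg.n_root_relatives):
        acc_ids.append(f"REL{j + 1}")
        groups.append(ROOT_RELATIVE_LABEL)
        rows.append(root.copy())
    out_base = root.copy()
    for s in out_sites:
        out_base[s] = der[s]
    for j in range(cfg.n_outgroups):
        h = out_base.copy()
        if j and reserve:  # one private extra step per additional outgroup
            s = reserve[(j - 1) % len(reserve)]
            h[s] = der[s]
        acc_ids.append(f"OUT{j + 1}")
        groups.append(OUTGROUP_LABEL)
        rows.append(h)
    return HaplotypeAlignment(
        site_ids=site_ids,
        site_kind=site_kind,
        accession_ids=acc_ids,
        alleles=np.array(rows, dtype=object),
        group_labels=groups,
    )


# ---------------------------------------------------------------------------
# domestication panel
# ---------------------------------------------------------------------------


def simulate_domestication_panel(cfg: SimConfig, truth: TruthSet, seed: int | None = None):
    """Simulate the focal-locus introgression panel.

    Returns (GenotypeMatrix, metadata DataFrame).  The matrix holds the
    red-pericarp wild panel, the planted introgressed accessions and the
    white-pericarp cultivated reference; the truth set records the planted
    block SNPs, the two in-gene SNPs, the introgressed accession ids and
    any planted phenotype/genotype discordants.
    """
    rng = np.random.default_rng(cfg.seed + 202 if seed is None else seed)
    chrom = cfg.dom_chrom
    focal = cfg.dom_focal_pos
    half = cfg.dom_block_halfwidth_bp
    region = (chrom, focal - half, focal + half) if half > 0 else (chrom, focal, focal)

    n_block = cfg.n_dom_block_snps if half > 0 else 0
    block_pos: list[int] = []
    if n_block:
        # two in-gene SNPs flank the focal indel; the rest spread over the block
        block_pos = [focal - 1000, focal + 1000]
        lo, hi = focal - half, focal + half
        while len(block_pos) < n_block:
            cand = int(rng.integers(lo, hi + 1))
            if cand not in block_pos:
                block_pos.append(cand)
    bg_lo, bg_hi = focal - 2 * max(half, 100_000), focal + 2 * max(half, 100_000)
    bg_pos: list[int] = []
    while len(bg_pos) < cfg.n_dom_background_snps:
        cand = int(rng.integers(bg_lo, max(bg_hi, bg_lo + 1)))
        if cand not in bg_pos and cand not in block_pos:
            bg_pos.append(cand)

    all_pos = sorted(block_pos + bg_pos)
    is_block = np.array([p in set(block_pos) for p in all_pos])
    snp_ids = np.array([f"D{chrom}_{p}" for p in all_pos], dtype=object)
    n_snps = len(all_pos)

    n_w, n_i, n_c = cfg.n_dom_wild, cfg.n_dom_introgressed, cfg.n_dom_cultivated
    wild_ids = [f"WR{i + 1:03d}" for i in range(n_w)]
    intro_ids = [f"WI{i + 1:03d}" for i in range(n_i)]
    cult_ids = [f"CS{i + 1:03d}" for i in range(n_c)]
    acc_ids = wild_ids + intro_ids + cult_ids

    # allele frequencies: block SNPs near-fixed for opposite alleles;
    # background SNPs share one common frequency across panels
    f_cult = np.where(is_block, 0.98, 0.0)
    f_wild = np.where(is_block, 0.02, 0.0)
    bg_f = rng.uniform(0.2, 0.8, size=n_snps)
    f_cult = np.where(is_block, f_cult, bg_f)
    f_wild = np.where(is_block, f_wild, bg_f)

    calls = np.empty((n_snps, len(acc_ids)), dtype=np.int8)
    for j, acc in enumerate(acc_ids):
        if acc in cult_ids:
            calls[:, j] = rng.binomial(2, f_cult)
        elif acc in intro_ids:
            base = rng.binomial(2, f_wild)
            base[is_block] = 2  # homozygous cultivated introgression block
            calls[:, j] = base
        else:
            base = rng.binomial(2, f_wild)
            base[is_block] = 0  # guaranteed wild haplotype across the block
            calls[:, j] = base

    g = GenotypeMatrix(
        snp_ids=snp_ids,
        chrom=np.array([chrom] * n_snps, dtype=object),
        pos_bp=np.array(all_pos, dtype=np.int64),
        ref_allele=np.array(["A"] * n_snps, dtype=object),
        alt_allele=np.array(["G"] * n_snps, dtype=object),
        calls=calls,
        accession_ids=np.array(acc_ids, dtype=object),
    )

    meta = pd.DataFrame(
        {c: pd.Series([np.nan] * len(acc_ids), dtype=object) for c in METADATA_COLUMNS}
    )
    meta["accession_id"] = acc_ids
    meta["country"] = "synthetic"
    meta.loc[: n_w - 1, "species_label"] = "O. rufipogon"
    meta.loc[n_w: n_w + n_i - 1, "species_label"] = "O. rufipogon"
    meta.loc[n_w + n_i:, "species_label"] = "O. sativa-subpop"
    meta["pericarp_score"] = [1.0] * n_w + [0.0] * n_i + [0.0] * n_c
    meta["rc_indel"] = ["wild"] * n_w + ["deletion"] * n_i + ["deletion"] * n_c
    meta["hull_color"] = ["black"] * n_w + ["light"] * n_i + ["light"] * n_c
    meta["bh4_indel"] = ["wild"] * n_w + ["deletion"] * n_i + ["deletion"] * n_c

    discordant = []
    if cfg.n_dom_discordant:
        picks = rng.choice(n_w, size=min(cfg.n_dom_discordant, n_w), replace=False)
        for p in sorted(picks):
            # seed-stock heterogeneity analog: black hull but deletion genotype
            meta.loc[p, "bh4_indel"] = "deletion"
            discordant.append(wild_ids[p])

    ingene = [f"D{chrom}_{focal - 1000}", f"D{chrom}_{focal + 1000}"] if n_block else []
    truth.introgressed_ids = intro_ids
    truth.dom_block_snp_ids = sorted(f"D{chrom}_{p}" for p in block_pos)
    truth.dom_ingene_snp_ids = ingene
    truth.dom_region = region
    truth.dom_discordant_ids = discordant
    return g, meta
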