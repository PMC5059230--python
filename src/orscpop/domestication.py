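"""Domestication-locus indel scoring and extended-haplotype introgression calls.

Two rice domestication genes are modelled: *RC* (red pericarp; a 14-bp
coding deletion yields white pericarp) and *Bh4* (black hull; a 22-bp
deletion yields light hull).  PCR amplicons of 236 bp (*RC*) and 227 bp
(*Bh4*) spanning the indels are scored from observed band lengths.

Introgression of the cultivated *RC* region into wild accessions is
detected from extended haplotypes: SNPs in a window around the locus are
screened (MAF > 0.05, < 3 % missing) and kept only when their allele
frequencies differ between white-pericarp cultivated and red-pericarp wild
panels (two-sided Fisher exact, p < 1e-5); each accession is then painted
cultivated / wild / heterozygous / missing per SNP relative to the
majority allele of the cultivated reference.  An accession carrying a
cultivated (or heterozygous) state at all three in-gene focal markers (two
SNPs and the 14-bp indel) is classified introgressed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_meta import MISSING, GenotypeMatrix

logger = logging.getLogger("orscpop")

STATES = ("cultivated", "wild", "heterozygous", "missing")


@dataclass(frozen=True)
class IndelAssay:
    locus: str
    amplicon_wild_bp: int
    deletion_bp: int

    def __post_init__(self) -> None:
        if self.deletion_bp >= self.amplicon_wild_bp:
            raise ValueError("deletion larger than amplicon")

    @property
    def deletion_product_bp(self) -> int:
        return self.amplicon_wild_bp - self.deletion_bp


RC_ASSAY = IndelAssay("RC", amplicon_wild_bp=236, deletion_bp=14)
BH4_ASSAY = IndelAssay("BH4", amplicon_wild_bp=227, deletion_bp=22)


def score_indel(assay: IndelAssay, band_lengths_bp, tolerance_bp: int = 3) -> str:
    """Score a gel lane: wild band only -> 'wild', deletion band only ->
    'deletion', both -> 'het'.  Bands are matched within +/- tolerance."""
    bands = list(band_lengths_bp)
    if not bands:
        raise ValueError(f"{assay.locus}: no bands observed")
    has_wild = has_del = False
    for b in bands:
        if abs(b - assay.amplicon_wild_bp) <= tolerance_bp:
            has_wild = True
        elif abs(b - assay.deletion_product_bp) <= tolerance_bp:
            has_del = True
        else:
            raise ValueError(
                f"{assay.locus}: band of {b} bp matches neither "
                f"{assay.amplicon_wild_bp} nor {assay.deletion_product_bp} bp"
            )
    if has_wild and has_del:
        return "het"
    return "wild" if has_wild else "deletion"


# ---------------------------------------------------------------------------
# SNP selection around the focal locus
# ---------------------------------------------------------------------------


def _allele_counts(g: GenotypeMatrix, rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    called = g.calls[rows] != MISSING
    n = 2 * called.sum(axis=1)
    alt = np.where(called, g.calls[rows], 0).sum(axis=1)
    return alt, n


def select_region_snps(
    sativa_white: GenotypeMatrix,
    orsc_red: GenotypeMatrix,
    region: tuple[str, int, int],
    maf_min: float = 0.05,
    missing_max: float = 0.03,
    p_cutoff: float = 1e-5,
    test: str = "fisher",
) -> list:
    """Select ancestry-informative SNPs in a genomic region.

    ``region`` is (chrom, start_bp, end_bp), closed.  Both panels must be
    genotyped over the region with matching SNP ids.  Filters are applied
    in order: MAF > maf_min and missing fraction < missing_max, both over
    the two panels combined; then a per-SNP two-sided test of allele-count
    difference between the panels (Fisher exact by default, chi-square
    with ``test='chi2'``), keeping SNPs with p < p_cutoff.  Heterozygotes
    contribute one allele to each class of the 2x2 table.
    """
    chrom, start, end = region
    in_region = lambda g: np.flatnonzero(
        (g.chrom == chrom) & (g.pos_bp >= start) & (g.pos_bp <= end)
    )
    rows_s, rows_o = in_region(sativa_white), in_region(orsc_red)
    ids_s = list(sativa_white.snp_ids[rows_s])
    common = [sid for sid in ids_s if sid in set(orsc_red.snp_ids[rows_o])]
    if not common:
        logger.warning("select_region_snps: no SNPs in region %s:%d-%d", chrom, start, end)
        return []
    pos_s = {sid: r for sid, r in zip(sativa_white.snp_ids, range(sativa_white.n_snps))}
    pos_o = {sid: r for sid, r in zip(orsc_red.snp_ids, range(orsc_red.n_snps))}
    rs = np.array([pos_s[sid] for sid in common])
    ro = np.array([pos_o[sid] for sid in common])

    alt_s, n_s = _allele_counts(sativa_white, rs)
    alt_o, n_o = _allele_counts(orsc_red, ro)
    n_tot = n_s + n_o
    alt_tot = alt_s + alt_o
    with np.errstate(invalid="ignore", divide="ignore"):
        p_all = np.where(n_tot > 0, alt_tot / n_tot, np.nan)
        maf = np.minimum(p_all, 1 - p_all)
    n_acc = sativa_white.n_accessions + orsc_red.n_accessions
    missing_frac = 1 - (n_tot / 2) / n_acc
    pass_initial = (maf > maf_min) & (missing_frac < missing_max)

    selected = []
    for k in np.flatnonzero(pass_initial):
        table = np.array(
            [[alt_s[k], n_s[k] - alt_s[k]], [alt_o[k], n_o[k] - alt_o[k]]]
        )
        if test == "fisher":
            p = stats.fisher_exact(table, alternative="two-sided")[1]
        elif test == "chi2":
            p = stats.chi2_contingency(table, correction=False)[1]
        else:
            raise ValueError("test must be 'fisher' or 'chi2'")
        if p < p_cutoff:
            selected.append(common[k])
    return selected


# ---------------------------------------------------------------------------
# extended haplotypes
# ---------------------------------------------------------------------------


@dataclass
class ExtendedHaplotype:
    accession_id: str
    snp_ids: list
    states: list                      # per selected SNP, one of STATES
    focal_states: dict                # marker name -> state ('deletion' maps to cultivated)


def build_extended_haplotypes(
    panel: GenotypeMatrix,
    selected_snps,
    cultivated_reference,
    focal_markers: dict[str, dict] | None = None,
) -> list[ExtendedHaplotype]:
    """Paint each accession cultivated/wild/het/missing at the selected SNPs.

    The cultivated allele at each SNP is the majority allele among the
    ``cultivated_reference`` accession ids (a tied SNP is dropped with a
    warning).  ``focal_markers`` maps a marker name to per-accession states
    (e.g. the two in-gene SNPs taken from the panel plus the 14-bp indel
    assay results); when omitted, focal states are left empty.
    """
    selected_snps = [s for s in selected_snps]
    if not selected_snps:
        raise ValueError("no selected SNPs")
    ref_idx = panel.accession_indices(cultivated_reference)
    id_to_row = {sid: r for r, sid in enumerate(panel.snp_ids)}
    rows, cult_is_alt = [], []
    for sid in selected_snps:
        r = id_to_row[sid]
        sub = panel.calls[r, ref_idx]
        called = sub != MISSING
        alt = int(sub[called].sum())
        total = int(2 * called.sum())
        if total == 0 or alt * 2 == total:
            logger.warning("build_extended_haplotypes: reference tied at %s, dropped", sid)
            continue
        rows.append(r)
        cult_is_alt.append(alt * 2 > total)
    out = []
    for j, acc in enumerate(panel.accession_ids):
        states = []
        for r, is_alt in zip(rows, cult_is_alt):
            d = int(panel.calls[r, j])
            if d == MISSING:
                states.append("missing")
            elif d == 1:
                states.append("heterozygous")
            else:
                cultivated = (d == 2) == is_alt
                states.append("cultivated" if cultivated else "wild")
        focal = {}
        if focal_markers:
            for name, per_acc in focal_markers.items():
                focal[name] = per_acc.get(acc, "missing")
        out.append(
            ExtendedHaplotype(
                accession_id=str(acc),
                snp_ids=[panel.snp_ids[r] for r in rows],
                states=states,
                focal_states=focal,
            )
        )
    return out


def assemble_focal_markers(
    ext_haps: list[ExtendedHaplotype],
    ingene_snp_ids,
    indel_calls: dict,
    indel_name: str = "rc_14bp_indel",
) -> list[ExtendedHaplotype]:
    """Attach the three in-gene focal marker states to each haplotype.

    The two in-gene SNP states are read off the painted extended haplotype
    (``missing`` when a SNP was not selected); the indel state comes from
    ``indel_calls`` (accession id -> wild/deletion/het).  Modifies the
    haplotypes in place and returns them.
    """
    ingene_snp_ids = list(ingene_snp_ids)
    if len(ingene_snp_ids) != 2:
        raise ValueError("expected exactly two in-gene SNP ids")
    for h in ext_haps:
        pos = {sid: k for k, sid in enumerate(h.snp_ids)}
        focal = {}
        for sid in ingene_snp_ids:
            focal[f"snp_{sid}"] = h.states[pos[sid]] if sid in pos else "missing"
        call = indel_calls.get(h.accession_id, "missing")
        focal[indel_name] = call if call in ("wild", "deletion", "het") else "missing"
        h.focal_states = focal
    return ext_haps


_FOCAL_CULTIVATED = {"cultivated", "heterozygous", "het", "deletion"}
_FOCAL_WILD = {"wild"}


def classify_introgression(h: ExtendedHaplotype) -> str:
    """Classify an accession from its three in-gene focal markers.

    Cultivated or heterozygous state at all three markers (the functional
    deletion counts as the cultivated allele) -> ``introgressed``; wild at
    all three -> ``wild``; anything else, including a missing marker,
    -> ``inconsistent``.
    """
    if len(h.focal_states) != 3:
        raise ValueError("three focal marker states are required")
    vals = list(h.focal_states.values())
    if any(v == "missing" for v in vals):
        logger.warning("classify_introgression: %s has a missing focal marker",
                       h.accession_id)
        return "inconsistent"
    if all(v in _FOCAL_CULTIVATED for v in vals):
        return "introgressed"
    if all(v in _FOCAL_WILD for v in vals):
        return "wild"
    return "inconsistent"


# ---------------------------------------------------------------------------
# phenotype / genotype concordance
# ---------------------------------------------------------------------------


def phenotype_genotype_concordance(table: pd.DataFrame) -> pd.DataFrame:
    """Check seed phenotypes against functional indel genotypes.

    Expected pairings (functional alleles are dominant): white pericarp
    (score < 0.5) with homozygous *RC* deletion, red pericarp with at
    least one wild *RC* allele; light hull with homozygous *Bh4* deletion,
    black hull with at least one wild *Bh4* allele.  Returns one row per
    scoreable accession x locus with a ``concordant`` flag.
    """
    rows = []
    for _, acc in table.iterrows():
        score = acc.get("pericarp_score")
        rc = acc.get("rc_indel")
        if pd.notna(score) and isinstance(rc, str) and rc in ("wild", "deletion", "het"):
            white = score < 0.5
            expected_white = rc == "deletion"
            rows.append(
                {
                    "accession_id": acc["accession_id"],
                    "locus": "RC",
                    "phenotype": "white" if white else "red",
                    "genotype": rc,
                    "concordant": white == expected_white,
                }
            )
        hull = acc.get("hull_color")
        bh4 = acc.get("bh4_indel")
        if isinstance(hull, str) and hull in ("black", "light") and isinstance(bh4, str) \
                and bh4 in ("wild", "deletion", "het"):
            light = hull == "light"
            expected_light = bh4 == "deletion"
            rows.append(
                {
                    "accession_id": acc["accession_id"],
                    "locus": "BH4",
                    "phenotype": hull,
                    "genotype": bh4,
                    "concordant": light == expected_light,
                }
            )
    df = pd.DataFrame(rows, columns=["accession_id", "locus", "phenotype", "genotype", "concordant"])
    n_disc = int((~df["concordant"]).sum()) if len(df) else 0
    logger.info("phenotype_genotype_concordance: %d scoreable, %d discordant",
                len(df), n_disc)
    return df
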