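"""Indel assay scoring, region SNP selection, extended haplotypes,
introgression calls, and phenotype/genotype concordance."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from orscpop import domestication
from orscpop.domestication import (
    BH4_ASSAY,
    RC_ASSAY,
    ExtendedHaplotype,
    classify_introgression,
    score_indel,
    select_region_snps,
)
from orscpop.synthetic_data import SimConfig, simulate_domestication_panel, simulate_structured_genotypes

from conftest import make_genotypes


def fisher_exact_oracle(table):
    """Two-sided Fisher exact p by exhaustive hypergeometric enumeration."""
    a, b = table[0]
    c, d = table[1]
    n = a + b + c + d
    row1, col1 = a + b, a + c
    rv = hypergeom(n, row1, col1)
    support = range(max(0, row1 + col1 - n), min(row1, col1) + 1)
    p_obs = rv.pmf(a)
    return sum(rv.pmf(k) for k in support if rv.pmf(k) <= p_obs * (1 + 1e-9))


class TestScoreIndel:
    def test_rc_wild_band(self):
        assert score_indel(RC_ASSAY, [236]) == "wild"

    def test_rc_deletion_band(self):
        assert score_indel(RC_ASSAY, [222]) == "deletion"

    def test_bh4_het_bands(self):
        assert score_indel(BH4_ASSAY, [227, 205]) == "het"

    def test_tolerance_window(self):
        assert score_indel(RC_ASSAY, [233]) == "wild"   # within +/- 3 bp
        with pytest.raises(ValueError, match="RC"):
            score_indel(RC_ASSAY, [229])               # matches neither

    def test_no_bands_rejected(self):
        with pytest.raises(ValueError):
            score_indel(RC_ASSAY, [])

    def test_product_lengths_consistent(self):
        assert RC_ASSAY.deletion_product_bp == 222
        assert BH4_ASSAY.deletion_product_bp == 205


class TestSelectRegionSnps:
    def _panels(self, rows_s, rows_o, pos=None):
        n_s = len(rows_s[0])
        gs = make_genotypes(rows_s, pos=pos)
        go = make_genotypes(rows_o, pos=pos,
                            acc=[f"o{j}" for j in range(len(rows_o[0]))])
        return gs, go

    def test_low_maf_excluded_before_testing(self):
        # MAF 0.04 in the combined panel: excluded even though differentiated
        rows_s = [[1] + [0] * 24]   # 1/50 alt
        rows_o = [[1] + [0] * 24]   # 1/50 alt -> combined MAF 0.02
        gs, go = self._panels(rows_s, rows_o)
        sel = select_region_snps(gs, go, ("1", 1, 1000))
        assert sel == []

    def test_high_missing_excluded(self):
        rows_s = [[2] * 19 + [None]]   # 1 of 40 calls missing -> 2.5 % ok
        rows_o = [[0] * 18 + [None, None]]  # total 3/40 = 7.5 % -> excluded
        gs, go = self._panels(rows_s, rows_o)
        sel = select_region_snps(gs, go, ("1", 1, 1000))
        assert sel == []

    def test_differentiated_snp_selected(self):
        rows_s = [[2] * 20]
        rows_o = [[0] * 20]
        gs, go = self._panels(rows_s, rows_o)
        sel = select_region_snps(gs, go, ("1", 1, 1000))
        assert sel == ["snp0"]

    def test_region_restriction(self):
        rows = [[2] * 20, [2] * 20]
        rows_o = [[0] * 20, [0] * 20]
        gs, go = self._panels(rows, rows_o, pos=[100, 5000])
        sel = select_region_snps(gs, go, ("1", 1, 1000))
        assert sel == ["snp0"]

    def test_accession_order_and_allele_label_invariance(self):
        rng = np.random.default_rng(0)
        rows_s = rng.integers(0, 3, size=(5, 20)).tolist()
        rows_o = rng.integers(0, 3, size=(5, 20)).tolist()
        gs, go = self._panels(rows_s, rows_o)
        sel1 = select_region_snps(gs, go, ("1", 1, 1000), p_cutoff=0.5)
        # permute accessions
        perm = rng.permutation(20)
        gs2 = gs.take_accessions([gs.accession_ids[i] for i in perm])
        sel2 = select_region_snps(gs2, go, ("1", 1, 1000), p_cutoff=0.5)
        assert sel1 == sel2
        # relabel alleles (dosage x -> 2-x) in both panels
        gs3 = make_genotypes((2 - np.array(rows_s)).tolist())
        go3 = make_genotypes((2 - np.array(rows_o)).tolist(),
                             acc=[f"o{j}" for j in range(20)])
        sel3 = select_region_snps(gs3, go3, ("1", 1, 1000), p_cutoff=0.5)
        assert sel1 == sel3

    @pytest.mark.parametrize(
        "table",
        [
            [[5, 5], [1, 9]],
            [[12, 0], [3, 9]],
            [[2, 8], [8, 2]],
            [[0, 10], [10, 0]],
            [[7, 3], [6, 4]],
        ],
    )
    def test_fisher_matches_hypergeometric_oracle(self, table):
        from scipy.stats import fisher_exact

        p = fisher_exact(np.array(table), alternative="two-sided")[1]
        assert p == pytest.approx(fisher_exact_oracle(table), rel=1e-6)


class TestExtendedHaplotypes:
    def _panel(self):
        # 3 SNPs; cultivated reference (c0,c1) homozygous alt everywhere
        calls = [
            [2, 2, 2, 0, 1],
            [2, 2, 0, 0, 2],
            [2, 2, 2, 2, None],
        ]
        acc = ["c0", "c1", "w0", "w1", "w2"]
        return make_genotypes(calls, acc=acc)

    def test_states_assigned_relative_to_cultivated_majority(self):
        g = self._panel()
        haps = domestication.build_extended_haplotypes(
            g, ["snp0", "snp1", "snp2"], ["c0", "c1"]
        )
        by_id = {h.accession_id: h for h in haps}
        assert by_id["w0"].states == ["cultivated", "wild", "cultivated"]
        assert by_id["w1"].states == ["wild", "wild", "cultivated"]
        assert by_id["w2"].states == ["heterozygous", "cultivated", "missing"]

    def test_tied_reference_snp_dropped(self):
        calls = [[2, 0, 1], [2, 2, 0]]
        g = make_genotypes(calls, acc=["c0", "c1", "w0"])
        haps = domestication.build_extended_haplotypes(g, ["snp0", "snp1"], ["c0", "c1"])
        assert haps[0].snp_ids == ["snp1"]  # snp0 tied 2 vs 2 alleles


class TestClassifyIntrogression:
    def _h(self, states):
        return ExtendedHaplotype(
            accession_id="x", snp_ids=[], states=[],
            focal_states=dict(zip(["m1", "m2", "m3"], states)),
        )

    @pytest.mark.parametrize(
        "states,expected",
        [
            (("cultivated", "cultivated", "deletion"), "introgressed"),
            (("heterozygous", "cultivated", "het"), "introgressed"),
            (("wild", "wild", "wild"), "wild"),
            (("cultivated", "wild", "wild"), "inconsistent"),
            (("cultivated", "cultivated", "missing"), "inconsistent"),
        ],
    )
    def test_rule(self, states, expected):
        assert classify_introgression(self._h(states)) == expected

    def test_wrong_marker_count_rejected(self):
        h = ExtendedHaplotype("x", [], [], {"m1": "wild"})
        with pytest.raises(ValueError):
            classify_introgression(h)


class TestPanelRecovery:
    def test_planted_block_and_introgressed_recovered(self):
        cfg = SimConfig(seed=12)
        _, _, truth = simulate_structured_genotypes(
            SimConfig(K=1, fst_targets=(0.1,), n_per_group=(2,), n_admixed=0,
                      n_snps=10, seed=12)
        )
        g, meta = simulate_domestication_panel(cfg, truth, seed=77)
        cult = [a for a in g.accession_ids if a.startswith("CS")]
        red = [a for a in g.accession_ids if a.startswith("WR")]
        sel = select_region_snps(
            g.take_accessions(cult), g.take_accessions(red), truth.dom_region
        )
        assert sorted(sel) == truth.dom_block_snp_ids
        haps = domestication.build_extended_haplotypes(g, sel, cult)
        indel = dict(zip(meta["accession_id"], meta["rc_indel"]))
        domestication.assemble_focal_markers(haps, truth.dom_ingene_snp_ids, indel)
        calls = {
            h.accession_id: classify_introgression(h)
            for h in haps if not h.accession_id.startswith("CS")
        }
        found = sorted(a for a, c in calls.items() if c == "introgressed")
        assert found == sorted(truth.introgressed_ids)

    def test_zero_introgressed_flags_nobody(self):
        cfg = SimConfig(n_dom_introgressed=0, seed=4)
        _, _, truth = simulate_structured_genotypes(
            SimConfig(K=1, fst_targets=(0.1,), n_per_group=(2,), n_admixed=0,
                      n_snps=10, seed=4)
        )
        g, meta = simulate_domestication_panel(cfg, truth, seed=5)
        cult = [a for a in g.accession_ids if a.startswith("CS")]
        red = [a for a in g.accession_ids if a.startswith("WR")]
        sel = select_region_snps(
            g.take_accessions(cult), g.take_accessions(red), truth.dom_region
        )
        haps = domestication.build_extended_haplotypes(g, sel, cult)
        indel = dict(zip(meta["accession_id"], meta["rc_indel"]))
        domestication.assemble_focal_markers(haps, truth.dom_ingene_snp_ids, indel)
        wild_calls = [
            classify_introgression(h) for h in haps
            if h.accession_id.startswith("WR")
        ]
        assert all(c == "wild" for c in wild_calls)

    def test_block_width_zero_selects_nothing(self):
        cfg = SimConfig(dom_block_halfwidth_bp=0, seed=9)
        _, _, truth = simulate_structured_genotypes(
            SimConfig(K=1, fst_targets=(0.1,), n_per_group=(2,), n_admixed=0,
                      n_snps=10, seed=9)
        )
        g, meta = simulate_domestication_panel(cfg, truth, seed=10)
        cult = [a for a in g.accession_ids if a.startswith("CS")]
        red = [a for a in g.accession_ids if a.startswith("WR")]
        sel = select_region_snps(
            g.take_accessions(cult), g.take_accessions(red), truth.dom_region
        )
        assert sel == []


class TestPhenotypeConcordance:
    def test_expected_pairings(self):
        df = pd.DataFrame(
            {
                "accession_id": ["a", "b", "c", "d"],
                "pericarp_score": [0.0, 1.0, 0.0, np.nan],
                "rc_indel": ["deletion", "wild", "wild", "deletion"],
                "hull_color": ["light", "black", "black", "black"],
                "bh4_indel": ["deletion", "wild", "deletion", "wild"],
            }
        )
        rep = domestication.phenotype_genotype_concordance(df)
        rc = rep[rep["locus"] == "RC"].set_index("accession_id")
        bh = rep[rep["locus"] == "BH4"].set_index("accession_id")
        assert rc.loc["a", "concordant"] and rc.loc["b", "concordant"]
        assert not rc.loc["c", "concordant"]       # white pericarp, wild allele
        assert "d" not in rc.index                 # missing phenotype skipped
        assert not bh.loc["c", "concordant"]       # black hull, deletion allele

    def test_planted_discordants_recovered(self):
        cfg = SimConfig(n_dom_discordant=2, seed=21)
        _, _, truth = simulate_structured_genotypes(
            SimConfig(K=1, fst_targets=(0.1,), n_per_group=(2,), n_admixed=0,
                      n_snps=10, seed=21)
        )
        g, meta = simulate_domestication_panel(cfg, truth, seed=22)
        rep = domestication.phenotype_genotype_concordance(meta)
        disc = sorted(rep.loc[~rep["concordant"], "accession_id"].unique())
        assert disc == sorted(truth.dom_discordant_ids)
        assert len(disc) == 2
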