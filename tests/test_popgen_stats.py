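"""Windowed Fst / pi / Jukes-Cantor distances / NJ trees.

The Weir-Cockerham theta implementation is checked against an independent
ANOVA-mean-squares oracle (sums of squares over allele indicators, a
different computational route from the closed-form variance components),
and pi against exhaustive pairwise allele comparison.
"""

import itertools

import numpy as np
import pytest

from orscpop import popgen_stats
from orscpop.io_meta import MISSING
from orscpop.popgen_stats import (
    PairwiseMatrix,
    jc_correct,
    make_windows,
    pairwise_distance,
    pi_per_snp,
    pi_within,
    wc_fst,
    wc_variance_components,
)

from conftest import make_genotypes


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def wc_theta_anova_oracle(pops):
    """Weir-Cockerham theta for one SNP via ANOVA mean squares.

    ``pops`` is a list of per-population dosage lists (no missing).  Uses
    the among-population / among-individual / within-individual sums of
    squares over per-individual allele frequencies, a different route from
    the closed-form a/b/c components.
    """
    r = len(pops)
    n_i = [len(p) for p in pops]
    n_tot = sum(n_i)
    p_ind = [[d / 2 for d in pop] for pop in pops]
    p_i = [sum(pi) / len(pi) for pi in p_ind]
    p_bar = sum(ni * pi for ni, pi in zip(n_i, p_i)) / n_tot
    ms1 = sum(2 * ni * (pi - p_bar) ** 2 for ni, pi in zip(n_i, p_i)) / (r - 1)
    ms2 = sum(
        2 * (pij - p_i[k]) ** 2 for k, pop in enumerate(p_ind) for pij in pop
    ) / (n_tot - r)
    ms3 = sum(
        2 * pij * (1 - pij) for pop in p_ind for pij in pop
    ) / n_tot
    n_c = (n_tot - sum(ni**2 for ni in n_i) / n_tot) / (r - 1)
    s_a = (ms1 - ms2) / (2 * n_c)
    s_b = (ms2 - ms3) / 2
    s_c = ms3
    return s_a / (s_a + s_b + s_c)


def pi_pairwise_oracle(dosages):
    """Per-SNP diversity by exhaustive comparison of all allele pairs."""
    alleles = []
    for d in dosages:
        if d != MISSING:
            alleles += [1] * d + [0] * (2 - d)
    pairs = list(itertools.combinations(alleles, 2))
    return sum(a != b for a, b in pairs) / len(pairs)


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------


class TestMakeWindows:
    def test_trailing_partial_dropped(self):
        g = make_genotypes([[0, 1]] * 250)
        w = make_windows(g, 100)
        assert len(w) == 2
        assert all(len(x.snp_rows) == 100 for x in w)

    def test_exact_window(self):
        g = make_genotypes([[0, 1]] * 100)
        assert len(make_windows(g, 100)) == 1

    def test_windows_never_span_chromosomes(self):
        g = make_genotypes([[0, 1]] * 300, chrom=["1"] * 150 + ["2"] * 150)
        w = make_windows(g, 100)
        assert len(w) == 2
        assert {x.chrom for x in w} == {"1", "2"}


# ---------------------------------------------------------------------------
# Weir-Cockerham theta
# ---------------------------------------------------------------------------


class TestWcFst:
    def _two_pop_matrix(self, pop1, pop2):
        calls = [list(pop1) + list(pop2)]
        g = make_genotypes(calls)
        pops = {
            "p1": [f"acc{j}" for j in range(len(pop1))],
            "p2": [f"acc{j}" for j in range(len(pop1), len(pop1) + len(pop2))],
        }
        return g, pops

    @pytest.mark.parametrize(
        "pop1,pop2",
        [
            ([2, 1, 0, 0, 0], [2, 2, 2, 1, 0]),   # 3/10 vs 7/10 alt alleles
            ([1, 1, 1, 1, 1], [0, 0, 2, 2, 1]),   # het-heavy vs mixed
            ([0, 0, 1], [2, 2, 1]),
            ([2, 2, 2, 0], [1, 1, 0, 0]),
        ],
    )
    def test_theta_matches_anova_oracle(self, pop1, pop2):
        g, pops = self._two_pop_matrix(pop1, pop2)
        theta = wc_variance_components(g, pops)["theta"].iloc[0]
        assert theta == pytest.approx(wc_theta_anova_oracle([pop1, pop2]), abs=1e-12)

    def test_three_populations_match_oracle(self):
        pops_d = [[0, 1, 2, 0], [2, 2, 1, 1], [0, 0, 0, 1]]
        calls = [sum(pops_d, [])]
        g = make_genotypes(calls)
        pops = {
            "a": [f"acc{j}" for j in range(4)],
            "b": [f"acc{j}" for j in range(4, 8)],
            "c": [f"acc{j}" for j in range(8, 12)],
        }
        theta = wc_variance_components(g, pops)["theta"].iloc[0]
        assert theta == pytest.approx(wc_theta_anova_oracle(pops_d), abs=1e-12)

    def test_fixed_difference_gives_one(self):
        calls = [[0] * 10 + [2] * 10] * 100
        g = make_genotypes(calls)
        pops = {"a": [f"acc{j}" for j in range(10)],
                "b": [f"acc{j}" for j in range(10, 20)]}
        res = wc_fst(g, pops, snps_per_window=100)
        assert res.windows["value"].iloc[0] == pytest.approx(1.0)
        assert res.genome_mean == pytest.approx(1.0)

    def test_monomorphic_snps_excluded(self):
        calls = [[0, 0, 2, 2], [0, 0, 0, 0], [1, 1, 1, 1]]
        g = make_genotypes(calls)
        pops = {"a": ["acc0", "acc1"], "b": ["acc2", "acc3"]}
        df = wc_variance_components(g, pops)
        assert np.isfinite(df["theta"].iloc[0])
        assert np.isnan(df["theta"].iloc[1])   # monomorphic
        assert np.isfinite(df["theta"].iloc[2])  # all-het is polymorphic

    def test_missing_excluded_per_snp(self):
        g, pops = self._two_pop_matrix([2, 1, 0, None, None], [2, 2, 2, 1, 0])
        theta = wc_variance_components(g, pops)["theta"].iloc[0]
        assert theta == pytest.approx(
            wc_theta_anova_oracle([[2, 1, 0], [2, 2, 2, 1, 0]]), abs=1e-12
        )

    def test_window_values_in_estimator_range(self):
        rng = np.random.default_rng(42)
        calls = rng.integers(0, 3, size=(200, 30)).tolist()
        g = make_genotypes(calls)
        pops = {"a": [f"acc{j}" for j in range(15)],
                "b": [f"acc{j}" for j in range(15, 30)]}
        res = wc_fst(g, pops, snps_per_window=100)
        vals = res.windows["value"].dropna()
        assert ((vals >= -0.05) & (vals <= 1.0)).all()


# ---------------------------------------------------------------------------
# nucleotide diversity
# ---------------------------------------------------------------------------


class TestPi:
    def test_monomorphic_window_is_zero(self):
        g = make_genotypes([[0, 0, 0, 0]] * 10)
        df = pi_within(g, [f"acc{j}" for j in range(4)], snps_per_window=10)
        assert df["value"].iloc[0] == 0.0

    def test_closed_form_single_snp(self):
        # p = 0.5 over n = 20 alleles -> (20/19) * 2 * 0.25 = 0.5263...
        g = make_genotypes([[1] * 10])
        pi = pi_per_snp(g, [f"acc{j}" for j in range(10)])
        assert pi[0] == pytest.approx(20 / 19 * 0.5, abs=1e-12)

    def test_per_kb_normalization(self):
        # 100 SNPs at p=0.5 spanning exactly 100 kb
        pos = [1000 + i * 1010 for i in range(100)]  # span 99,990 ~ not exact
        pos = [1000 + i * (100_000 // 99) for i in range(100)]
        g = make_genotypes([[1] * 10] * 100, pos=pos)
        df = pi_within(g, [f"acc{j}" for j in range(10)], snps_per_window=100)
        span_kb = (pos[-1] - pos[0]) / 1000
        expected = 100 * (20 / 19 * 0.5) / span_kb
        assert df["per_kb"].iloc[0] == pytest.approx(expected, rel=1e-9)

    @pytest.mark.parametrize(
        "dosages",
        [[0, 1, 2, 1], [2, 2, 0, None, 1], [1, 1, 1, 1, 1, 1], [0, 2]],
    )
    def test_matches_exhaustive_pairwise_oracle(self, dosages):
        g = make_genotypes([dosages])
        called = [d for d in dosages if d is not None]
        pi = pi_per_snp(g, [f"acc{j}" for j in range(len(dosages))])
        assert pi[0] == pytest.approx(pi_pairwise_oracle(
            [MISSING if d is None else d for d in dosages]), abs=1e-12)


# ---------------------------------------------------------------------------
# Jukes-Cantor
# ---------------------------------------------------------------------------


class TestJukesCantor:
    def test_zero(self):
        assert jc_correct(0.0) == 0.0

    def test_known_value(self):
        assert jc_correct(0.1) == pytest.approx(0.10732, abs=1e-5)

    @pytest.mark.parametrize("p", [0.75, 0.8, -0.01])
    def test_domain_errors(self, p):
        with pytest.raises(ValueError):
            jc_correct(p)

    def test_strictly_increasing_and_at_least_p(self):
        p = np.linspace(0, 0.74, 200)
        d = jc_correct(p)
        assert np.all(np.diff(d) > 0)
        assert np.all(d >= p)


# ---------------------------------------------------------------------------
# pairwise distances
# ---------------------------------------------------------------------------


class TestPairwiseDistance:
    def test_self_distance_zero(self):
        g = make_genotypes([[0, 2], [1, 1], [2, 0]])
        m = popgen_stats.individual_distances(g)
        assert m.values[0, 0] == 0.0 and m.values[1, 1] == 0.0

    def test_enumerated_pair(self):
        # (0,0,2) vs (2,2,2): sites differ 1,1,0 -> p = 2/3 -> jc(2/3)
        g = make_genotypes([[0, 2], [0, 2], [2, 2]])
        m = popgen_stats.individual_distances(g, polymorphic_only=False)
        assert m.values[0, 1] == pytest.approx(jc_correct(2 / 3), abs=1e-12)

    def test_group_distance_symmetric_nonnegative(self):
        rng = np.random.default_rng(3)
        calls = rng.integers(0, 3, size=(60, 12)).tolist()
        g = make_genotypes(calls)
        groups = {"a": [f"acc{j}" for j in range(6)],
                  "b": [f"acc{j}" for j in range(6, 12)]}
        m = pairwise_distance(g, groups)
        assert m.values[0, 1] == m.values[1, 0] >= 0

    def test_polymorphic_restriction(self):
        # SNP fixed in the union must not contribute to the group distance
        calls = [[2, 2, 2, 2], [0, 0, 2, 2]]
        g = make_genotypes(calls)
        groups = {"a": ["acc0", "acc1"], "b": ["acc2", "acc3"]}
        m = pairwise_distance(g, groups)
        assert m.values[0, 1] == pytest.approx(jc_correct(0.7499999), abs=1e-6)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------


def _patristic(tree, a, b):
    return tree.find(a).distance(tree.find(b))


class TestNJ:
    def test_three_taxa_closed_form(self):
        d_ab, d_ac, d_bc = 3.0, 4.0, 5.0
        m = PairwiseMatrix(
            labels=["A", "B", "C"],
            values=np.array([[0, d_ab, d_ac], [d_ab, 0, d_bc], [d_ac, d_bc, 0]]),
        )
        tree = popgen_stats.nj_tree(m)
        assert _patristic(tree, "A", "B") == pytest.approx(d_ab)
        assert _patristic(tree, "A", "C") == pytest.approx(d_ac)
        assert _patristic(tree, "B", "C") == pytest.approx(d_bc)

    def test_four_taxa_additive_recovery(self):
        # tree ((A:1,B:2):1,C:3,D:4) with internal edge 1
        d = {
            ("A", "B"): 3, ("A", "C"): 5, ("A", "D"): 6,
            ("B", "C"): 6, ("B", "D"): 7, ("C", "D"): 7,
        }
        labels = ["A", "B", "C", "D"]
        vals = np.zeros((4, 4))
        for (x, y), v in d.items():
            i, j = labels.index(x), labels.index(y)
            vals[i, j] = vals[j, i] = v
        tree = popgen_stats.nj_tree(PairwiseMatrix(labels=labels, values=vals))
        for (x, y), v in d.items():
            assert _patristic(tree, x, y) == pytest.approx(v, abs=1e-9)

    def test_ultrametric_hierarchy_recovered(self):
        # ((A,B),(C,D)): within-pair distance 2, between-pair 4
        labels = ["A", "B", "C", "D"]
        vals = np.full((4, 4), 4.0)
        vals[0, 1] = vals[1, 0] = 2.0
        vals[2, 3] = vals[3, 2] = 2.0
        np.fill_diagonal(vals, 0.0)
        tree = popgen_stats.nj_tree(PairwiseMatrix(labels=labels, values=vals))
        splits = popgen_stats._bipartitions(tree, frozenset(labels))
        assert frozenset({"A", "B"}) in splits or frozenset({"C", "D"}) in splits

    def test_missing_entries_rejected(self):
        vals = np.zeros((3, 3))
        vals[0, 1] = vals[1, 0] = np.nan
        m = PairwiseMatrix(labels=list("ABC"), values=vals)
        with pytest.raises(ValueError, match="missing"):
            popgen_stats.nj_tree(m)

    def test_bootstrap_identical_data_full_support(self):
        # three clear pairs; every SNP carries the same pattern, so every
        # bootstrap resample yields the same tree
        calls = [[0, 0, 1, 1, 2, 2]] * 30
        g = make_genotypes(calls)
        tree, support = popgen_stats.bootstrap_support(
            g, groups=None, n_reps=25, seed=0
        )
        assert support  # at least one internal split
        assert all(v == 100.0 for v in support.values())
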