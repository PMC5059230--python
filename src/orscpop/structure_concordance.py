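"""Admixture classification from Q-matrices and species-label concordance.

An accession is assigned to the subpopulation carrying its maximum
ancestry proportion when that proportion reaches the threshold (default
0.75); below the threshold it is ``admixed`` (strictly less than 75 %
shared ancestry; exactly 0.75 is assigned).  Concordance between genetic
subpopulations and taxonomic species labels is a Pearson chi-square on
the group x label contingency table (admixed accessions excluded by
default), with effect size reported as Cramer's V squared,
chi2 / (n * min(rows-1, cols-1)), which lies in [0, 1] and reduces to
phi-squared for two-column tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_meta import AncestryMatrix

logger = logging.getLogger("orscpop")

ADMIXED = "admixed"


@dataclass
class ConcordanceResult:
    contingency: pd.DataFrame
    chi2: float
    df: int
    p: float
    effect_r2: float
    n: int


def assign_subpop(
    q: AncestryMatrix,
    group_names=None,
    threshold: float = 0.75,
) -> pd.Series:
    """Label each accession with its majority-ancestry group or 'admixed'."""
    if not 0.5 < threshold <= 1:
        raise ValueError("threshold must lie in (0.5, 1]")
    if group_names is None:
        group_names = [f"W{k + 1}" for k in range(q.K)]
    group_names = list(group_names)
    if len(group_names) != q.K:
        raise ValueError("group_names length must equal K")
    best = q.q.argmax(axis=1)
    maxq = q.q.max(axis=1)
    labels = [
        group_names[b] if m >= threshold else ADMIXED for b, m in zip(best, maxq)
    ]
    return pd.Series(labels, index=list(q.accession_ids), name="subpop")


def concordance(
    assignments: pd.Series,
    species_labels: pd.Series,
    exclude_admixed: bool = True,
) -> ConcordanceResult:
    """Chi-square association between subpopulations and species labels.

    Both inputs are indexed by accession id.  With ``exclude_admixed``
    (default) admixed accessions are dropped before the table is formed.
    Pearson chi-square without continuity correction; any empty label class
    after exclusion is an error.
    """
    df = pd.DataFrame({"subpop": assignments, "species": species_labels}).dropna()
    if exclude_admixed:
        df = df[df["subpop"] != ADMIXED]
    table = pd.crosstab(df["subpop"], df["species"])
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need at least 2 groups and 2 labels after exclusion")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("empty label class after exclusion")
    chi2, p, dof, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
    n = int(table.to_numpy().sum())
    k = min(table.shape[0] - 1, table.shape[1] - 1)
    effect = float(chi2 / (n * k))
    return ConcordanceResult(contingency=table, chi2=float(chi2), df=int(dof),
                             p=float(p), effect_r2=effect, n=n)


def species_composition(assignments: pd.Series, species_labels: pd.Series) -> pd.DataFrame:
    """Per-subpopulation percentage of each species label (rows sum to 100)."""
    df = pd.DataFrame({"subpop": assignments, "species": species_labels}).dropna()
    if df.empty:
        raise ValueError("no labelled accessions")
    counts = pd.crosstab(df["subpop"], df["species"])
    return counts.div(counts.sum(axis=1), axis=0) * 100.0
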