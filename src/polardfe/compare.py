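"""Category comparisons, divergence and the BLOSUM62 conservation
correlation.

The BLOSUM62 diagonal identity scores are embedded as constants (standard
matrix of Henikoff & Henikoff, half-bit log-odds of an amino acid aligning
to itself in >62%-identity blocks); tryptophan and cysteine carry the two
largest scores.
"""

from __future__ import annotations

from itertools import combinations
from math import comb
from typing import Callable, Sequence

import numpy as np
from scipy import stats as sps

from .alignment_io import FOCAL, NUCLEOTIDES, OUTGROUP1, Alignment

__all__ = [
    "BLOSUM62_DIAGONAL", "AMINO_ACIDS",
    "wilcoxon_category_test", "chi_square_table", "pairwise_divergence",
    "blosum_identity_correlation", "deleterious_proportion",
]

#: diagonal of the standard BLOSUM62 substitution matrix
BLOSUM62_DIAGONAL: dict[str, int] = {
    "A": 4, "R": 5, "N": 6, "D": 6, "C": 9, "Q": 5, "E": 5, "G": 6,
    "H": 8, "I": 4, "L": 4, "K": 5, "M": 5, "F": 6, "P": 7, "S": 4,
    "T": 5, "W": 11, "Y": 7, "V": 4,
}

AMINO_ACIDS = tuple(sorted(BLOSUM62_DIAGONAL))


def _rank_sum_exact_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact permutation p-value for the rank-sum statistic
    (enumerates group assignments; ties handled by midranks)."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n1 = len(x)
    obs = ranks[:n1].sum()
    mean = ranks.sum() * n1 / len(pooled)
    total = comb(len(pooled), n1)
    extreme = sum(
        1
        for idx in combinations(range(len(pooled)), n1)
        if abs(ranks[list(idx)].sum() - mean) >= abs(obs - mean) - 1e-9
    )
    return extreme / total


def wilcoxon_category_test(
    groups: Sequence[np.ndarray | Sequence[float]],
    method: str = "asymptotic",
) -> float:
    """Nonparametric test for differences among category means.

    Two groups: Wilcoxon rank-sum (normal approximation with tie
    correction, or exact enumeration for small samples with
    ``method="exact"``).  More than two groups: Kruskal-Wallis.  Returns a
    two-sided p-value; identical data across groups give p = 1.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(len(a) == 0 for a in arrays):
        raise ValueError("groups must be non-empty")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 1.0
    if len(arrays) == 2:
        if method == "exact":
            return _rank_sum_exact_p(arrays[0], arrays[1])
        return float(
            sps.mannwhitneyu(arrays[0], arrays[1], alternative="two-sided",
                             method="asymptotic").pvalue
        )
    return float(sps.kruskal(*arrays).pvalue)


def chi_square_table(contingency) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on a category x outcome
    count table; returns (statistic, df, p)."""
    table = np.asarray(contingency, dtype=float)
    if table.ndim != 2:
        raise ValueError("contingency table must be 2-dimensional")
    if np.any(table < 0) or not np.allclose(table, np.round(table)):
        raise ValueError("contingency table must hold non-negative counts")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("contingency table has a zero margin")
    stat, p, df, _ = sps.chi2_contingency(table, correction=False)
    return float(stat), int(df), float(p)


def pairwise_divergence(
    aln: Alignment,
    predicate: Callable[[int], bool] | None = None,
) -> float:
    """Per-site divergence between the focal and first-outgroup consensus.

    Counts selected, fully observed sites (every focal and first-outgroup
    strain called) at which the two population consensus (majority) alleles
    differ.  Consensus ties break to the lexicographically smallest
    nucleotide, deterministically.
    """
    focal = aln.rows(FOCAL)
    og1 = aln.rows(OUTGROUP1)
    nuc = np.array(NUCLEOTIDES)
    complete = np.isin(focal, nuc).all(axis=0) & np.isin(og1, nuc).all(axis=0)

    def consensus(block: np.ndarray, pos: int) -> bytes:
        col = block[:, pos]
        vals, counts = np.unique(col, return_counts=True)
        return bytes(vals[np.lexsort((vals, -counts))][0])

    eligible = 0
    diffs = 0
    for pos in range(aln.length):
        if not complete[pos]:
            continue
        if predicate is not None and not predicate(pos):
            continue
        eligible += 1
        if consensus(focal, pos) != consensus(og1, pos):
            diffs += 1
    if eligible == 0:
        raise ValueError("no eligible sites for divergence")
    return diffs / eligible


def deleterious_proportion(mean: float, shape: float,
                           threshold: float = 1.0) -> float:
    """P(NeSd >= threshold) under a gamma DFE with the given mean and shape.

    An infinite mean denotes a boundary fit (the estimate is a lower bound
    far above the threshold); its deleterious mass lies entirely above any
    finite threshold.
    """
    if not np.isfinite(mean):
        return 1.0
    if mean <= 0 or shape <= 0:
        raise ValueError("gamma mean and shape must be positive")
    return float(sps.gamma.sf(threshold, a=shape, scale=mean / shape))


def blosum_identity_correlation(
    per_aa_deleterious_proportion: dict[str, float],
) -> tuple[float, float]:
    """Squared Pearson correlation between per-amino-acid deleterious
    proportions and the BLOSUM62 diagonal identity score.

    Requires all 20 amino acids; returns (r_squared, two-sided p) with the
    standard df = n - 2 test.
    """
    missing = [a for a in AMINO_ACIDS if a not in per_aa_deleterious_proportion]
    if missing:
        raise ValueError(f"missing amino acids: {missing}")
    props = np.array([per_aa_deleterious_proportion[a] for a in AMINO_ACIDS],
                     dtype=float)
    if np.any(~np.isfinite(props)) or np.any((props < 0) | (props > 1)):
        raise ValueError("proportions must be finite and in [0, 1]")
    scores = np.array([BLOSUM62_DIAGONAL[a] for a in AMINO_ACIDS], dtype=float)
    r, p = sps.pearsonr(props, scores)
    return float(r * r), float(p)
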