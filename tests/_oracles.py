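"""Independent oracles used by the test suite.

Everything here is deliberately written from first principles (brute-force
enumeration, dense linear algebra on small state spaces, direct formula
transcriptions) and never calls the code paths it checks.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy import linalg
from scipy import stats as sps

STANDARD_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

SENSE_CODONS = sorted(c for c, aa in STANDARD_CODE.items() if aa != "*")


def degeneracy_brute(codon: str, offset: int) -> int:
    """Degeneracy by exhaustive substitution over the genetic-code table."""
    aa = STANDARD_CODE[codon]
    syn = 0
    for b in "ACGT":
        if b == codon[offset]:
            continue
        alt = codon[:offset] + b + codon[offset + 1:]
        if STANDARD_CODE[alt] == aa:  # stops never equal a sense amino acid
            syn += 1
    return {3: 4, 0: 0}.get(syn, 2)


def wf_stationary_density(two_n: int, S: float) -> np.ndarray:
    """Stationary segregating density v_j (j = 1..2N-1) for unit influx,
    built from a dense Wright-Fisher matrix (independent of the package)."""
    M = two_n
    s = S / (2.0 * M)
    p = np.arange(M + 1) / M
    p_sel = p * (1.0 + s) / (1.0 + p * s)
    P = sps.binom.pmf(np.arange(M + 1)[None, :], M, p_sel[:, None])
    Q = P[1:M, 1:M]
    rhs = np.zeros(M - 1)
    rhs[0] = 1.0
    return linalg.solve(np.eye(M - 1) - Q.T, rhs)


def wf_expected_sfs(n: int, S: float, two_n: int = 200) -> np.ndarray:
    """Expected segregating SFS shape (classes 1..n-1, normalized to sum 1)
    from a dense Wright-Fisher transition matrix.

    Haploid pool of ``two_n`` copies, genic selection s = S / (2 * two_n),
    unit mutation influx at one copy per generation; the stationary
    segregating density solves (I - Q^T) v = e_1.
    """
    M = two_n
    s = S / (2.0 * M)
    p = np.arange(M + 1) / M
    p_sel = p * (1.0 + s) / (1.0 + p * s)
    P = sps.binom.pmf(np.arange(M + 1)[None, :], M, p_sel[:, None])
    Q = P[1:M, 1:M]
    rhs = np.zeros(M - 1)
    rhs[0] = 1.0
    v = linalg.solve(np.eye(M - 1) - Q.T, rhs)
    pj = np.arange(1, M) / M
    e = np.array([np.sum(sps.binom.pmf(i, n, pj) * v) for i in range(1, n)])
    return e / e.sum()


def rank_sum_exact_p(x, y) -> float:
    """Two-sided exact p for the rank-sum statistic by full enumeration of
    group assignments (midranks for ties)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n1 = len(x)
    obs = ranks[:n1].sum()
    mean = ranks.sum() * n1 / len(pooled)
    hits = 0
    total = 0
    for idx in combinations(range(len(pooled)), n1):
        total += 1
        if abs(ranks[list(idx)].sum() - mean) >= abs(obs - mean) - 1e-9:
            hits += 1
    return hits / total


def pearson_r2_direct(x, y) -> float:
    """r^2 straight from the product-moment formula."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc = x - x.mean()
    yc = y - y.mean()
    r = (xc * yc).sum() / np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
    return r * r


def pearson_chi2_direct(table) -> float:
    """Pearson statistic by direct summation of (o - e)^2 / e."""
    t = np.asarray(table, float)
    e = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    return float(((t - e) ** 2 / e).sum())
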