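"""Ancestral/derived polarization and unfolded site-frequency spectra.

The focal population's alleles are polarized with a two-outgroup parsimony
ladder: the first outgroup population settles polymorphic sites; when the
focal and first-outgroup populations are fixed for different alleles, the
single second-outgroup sequence casts the deciding vote.  A site enters the
analysis only if every focal strain is called (no gaps or missing data),
at least one first-outgroup strain is called, and the second-outgroup
sequence is called — the conservative "no missing values" filter.  The
third outgroup plays no role in polarization (it is reserved for the
conservation classification).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np

from .alignment_io import (
    FOCAL, GAP, MISSING, NUCLEOTIDES, OUTGROUP1, OUTGROUP2,
    Alignment, SiteColumn, StrainMap,
)

__all__ = [
    "RESOLVED", "EXCLUDED_MISSING", "EXCLUDED_AMBIGUOUS",
    "PolarizedSite", "SFS",
    "polarize_site", "polarize_alignment", "build_sfs", "mean_da_frequency",
]

RESOLVED = "RESOLVED"
EXCLUDED_MISSING = "EXCLUDED_MISSING"
EXCLUDED_AMBIGUOUS = "EXCLUDED_AMBIGUOUS"

_NUC_SET = set(NUCLEOTIDES)


@dataclass(frozen=True)
class PolarizedSite:
    position: int
    n: int
    derived_count: int | None
    ancestral_nt: bytes | None
    derived_nt: bytes | None
    status: str

    @property
    def resolved(self) -> bool:
        return self.status == RESOLVED


@dataclass
class SFS:
    """Unfolded site-frequency spectrum: counts of sites with i derived
    copies out of n, i = 0..n, for one site category."""

    n: int
    counts: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if len(self.counts) != self.n + 1:
            raise ValueError(f"SFS needs n+1 = {self.n + 1} classes")
        if np.any(self.counts < 0):
            raise ValueError("SFS counts must be non-negative")

    @property
    def n_sites(self) -> int:
        return int(self.counts.sum())

    def __add__(self, other: "SFS") -> "SFS":
        if other.n != self.n:
            raise ValueError("cannot add SFS with different n")
        return SFS(self.n, self.counts + other.counts,
                   label=f"{self.label}+{other.label}")


def _alleles(values: Iterable[bytes]) -> tuple[set[bytes], bool]:
    """Distinct nucleotide states and whether any gap/missing was seen."""
    seen: set[bytes] = set()
    incomplete = False
    for v in values:
        if v in _NUC_SET:
            seen.add(v)
        else:
            incomplete = True
    return seen, incomplete


def polarize_site(column: SiteColumn, strain_map: StrainMap) -> PolarizedSite:
    """Assign ancestral/derived states at one alignment column.

    Decision ladder: (1) any focal gap/missing, no first-outgroup call, or
    no second-outgroup call -> excluded as missing; (2) focal biallelic
    {x, y}: resolved if the first outgroup is fixed for x or for y, else
    ambiguous; (3) focal monomorphic x: first outgroup fixed for x gives
    i = 0; fixed for y != x defers to the second outgroup (y -> fixed
    derived, x -> i = 0, anything else -> ambiguous); a polymorphic first
    outgroup at a monomorphic focal site is ambiguous; (4) three or more
    focal alleles -> ambiguous.
    """
    pops = strain_map.populations
    focal = [column.allele_by_strain[s] for s in pops if pops[s] == FOCAL]
    og1 = [column.allele_by_strain[s] for s in pops if pops[s] == OUTGROUP1]
    og2 = [column.allele_by_strain[s] for s in pops if pops[s] == OUTGROUP2][0]
    n = len(focal)
    pos = column.position

    def excluded(status: str) -> PolarizedSite:
        return PolarizedSite(pos, n, None, None, None, status)

    focal_set, focal_incomplete = _alleles(focal)
    if focal_incomplete:
        return excluded(EXCLUDED_MISSING)
    og1_set, _ = _alleles(og1)
    if not og1_set or og2 not in _NUC_SET:
        return excluded(EXCLUDED_MISSING)

    if len(focal_set) == 1:
        (x,) = focal_set
        if len(og1_set) > 1:
            return excluded(EXCLUDED_AMBIGUOUS)
        (y,) = og1_set
        if y == x:
            return PolarizedSite(pos, n, 0, x, None, RESOLVED)
        if og2 == y:
            return PolarizedSite(pos, n, n, y, x, RESOLVED)
        if og2 == x:
            return PolarizedSite(pos, n, 0, x, None, RESOLVED)
        return excluded(EXCLUDED_AMBIGUOUS)

    if len(focal_set) == 2:
        x, y = sorted(focal_set)
        if og1_set == {x}:
            anc, der = x, y
        elif og1_set == {y}:
            anc, der = y, x
        else:
            return excluded(EXCLUDED_AMBIGUOUS)
        i = sum(1 for v in focal if v == der)
        return PolarizedSite(pos, n, i, anc, der, RESOLVED)

    return excluded(EXCLUDED_AMBIGUOUS)


def polarize_alignment(aln: Alignment) -> list[PolarizedSite]:
    """Polarize every column of an alignment (vectorized filters, per-site
    ladder)."""
    pops = aln.strain_map.populations
    focal_ids = aln.strain_map.by_population(FOCAL)
    og1_ids = aln.strain_map.by_population(OUTGROUP1)
    og2_id = aln.strain_map.by_population(OUTGROUP2)[0]
    focal = np.vstack([aln.row(s) for s in focal_ids])
    og1 = np.vstack([aln.row(s) for s in og1_ids]) if og1_ids else np.empty((0, aln.length), "S1")
    og2 = aln.row(og2_id)
    n = len(focal_ids)
    nuc = np.array(NUCLEOTIDES)

    focal_ok = np.isin(focal, nuc).all(axis=0)
    og1_any = np.isin(og1, nuc).any(axis=0) if len(og1) else np.zeros(aln.length, bool)
    og2_ok = np.isin(og2, nuc)

    out: list[PolarizedSite] = []
    for pos in range(aln.length):
        if not (focal_ok[pos] and og1_any[pos] and og2_ok[pos]):
            out.append(PolarizedSite(pos, n, None, None, None, EXCLUDED_MISSING))
            continue
        col_f = focal[:, pos]
        focal_set = set(col_f.tolist())
        og1_set = {v for v in og1[:, pos].tolist() if v in _NUC_SET}
        o2 = bytes(og2[pos])

        if len(focal_set) == 1:
            (x,) = focal_set
            if len(og1_set) > 1:
                out.append(PolarizedSite(pos, n, None, None, None, EXCLUDED_AMBIGUOUS))
                continue
            (y,) = og1_set
            if y == x:
                out.append(PolarizedSite(pos, n, 0, x, None, RESOLVED))
            elif o2 == y:
                out.append(PolarizedSite(pos, n, n, y, x, RESOLVED))
            elif o2 == x:
                out.append(PolarizedSite(pos, n, 0, x, None, RESOLVED))
            else:
                out.append(PolarizedSite(pos, n, None, None, None, EXCLUDED_AMBIGUOUS))
        elif len(focal_set) == 2:
            x, y = sorted(focal_set)
            if og1_set == {x}:
                anc, der = x, y
            elif og1_set == {y}:
                anc, der = y, x
            else:
                out.append(PolarizedSite(pos, n, None, None, None, EXCLUDED_AMBIGUOUS))
                continue
            i = int(np.count_nonzero(col_f == der))
            out.append(PolarizedSite(pos, n, i, anc, der, RESOLVED))
        else:
            out.append(PolarizedSite(pos, n, None, None, None, EXCLUDED_AMBIGUOUS))
    return out


def build_sfs(
    polarized: Sequence[PolarizedSite],
    predicate: Callable[[int], bool] | None = None,
    label: str = "",
    n: int | None = None,
) -> SFS:
    """Count resolved sites into an unfolded SFS.

    ``predicate`` selects positions (a category membership test); excluded
    sites never contribute.  An empty category yields an all-zero spectrum.
    """
    if n is None:
        if not polarized:
            raise ValueError("cannot infer n from an empty site list")
        n = polarized[0].n
    counts = np.zeros(n + 1, dtype=np.int64)
    for site in polarized:
        if not site.resolved:
            continue
        if predicate is not None and not predicate(site.position):
            continue
        counts[site.derived_count] += 1
    return SFS(n=n, counts=counts, label=label)


def mean_da_frequency(sfs: SFS) -> float:
    """Mean derived-allele frequency per site, sum_i (i/n) c_i / sum_i c_i."""
    total = sfs.counts.sum()
    if total == 0:
        raise ValueError(f"empty SFS for category {sfs.label!r}")
    i = np.arange(sfs.n + 1)
    return float(np.dot(i / sfs.n, sfs.counts) / total)
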