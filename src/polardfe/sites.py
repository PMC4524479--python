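"""Site classification: region, codon degeneracy, outgroup conservation,
ancestral amino acid.

Degeneracy follows the standard nuclear genetic code and the 0/2/4-fold
trichotomy: a codon position is 4-fold if all three possible substitutions
are synonymous, 0-fold if none is, and 2-fold otherwise (which folds the
rare 3-fold isoleucine position into the 2-fold class).  Conservation is
assessed at the amino-acid level between the two distant outgroup
sequences: a coding site is outgroup-conserved if both outgroup codons
translate to the same amino acid, regardless of synonymous differences.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .alignment_io import (
    FOCAL, NUCLEOTIDES, OUTGROUP2, OUTGROUP3,
    Alignment, GenomeAnnotation, Interval,
)
from .polarize import PolarizedSite

__all__ = [
    "CONSERVED", "NONCONSERVED", "UNCLASSIFIED",
    "SiteRecord",
    "degeneracy_of", "conservation_status", "classify_sites",
    "site_table",
]

CONSERVED = "CONSERVED"
NONCONSERVED = "NONCONSERVED"
UNCLASSIFIED = "UNCLASSIFIED"

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_CODON_TO_AA = dict(_TABLE.forward_table)
_STOPS = set(_TABLE.stop_codons)
_BASES = "ACGT"


def degeneracy_of(codon: str, offset: int) -> int | None:
    """Degeneracy class (0, 2 or 4) of position ``offset`` of a sense codon.

    Counts the synonymous fraction of the three possible substitutions at
    that position: 3 synonymous -> 4-fold, 0 -> 0-fold, otherwise 2-fold.
    Returns None for stop codons or codons with ambiguous bases.
    """
    codon = codon.upper()
    if offset not in (0, 1, 2):
        raise ValueError("offset must be 0, 1 or 2")
    if len(codon) != 3 or any(b not in _BASES for b in codon):
        return None
    if codon in _STOPS:
        return None
    aa = _CODON_TO_AA[codon]
    k = 0
    for b in _BASES:
        if b == codon[offset]:
            continue
        alt = codon[:offset] + b + codon[offset + 1:]
        if alt not in _STOPS and _CODON_TO_AA[alt] == aa:
            k += 1
    return 4 if k == 3 else (0 if k == 0 else 2)


def _translate(codon: str) -> str | None:
    codon = codon.upper()
    if len(codon) != 3 or any(b not in _BASES for b in codon):
        return None
    if codon in _STOPS:
        return None
    return _CODON_TO_AA[codon]


def conservation_status(codon_outgroup2: str, codon_outgroup3: str) -> str:
    """Amino-acid conservation between the two outgroup codons.

    Conserved means both codons translate to the same amino acid
    (synonymous differences still count as conserved); any gap, ambiguity
    or stop leaves the site unclassified.
    """
    aa2 = _translate(codon_outgroup2)
    aa3 = _translate(codon_outgroup3)
    if aa2 is None or aa3 is None:
        return UNCLASSIFIED
    return CONSERVED if aa2 == aa3 else NONCONSERVED


@dataclass
class SiteRecord:
    """Per-site classification plus polarization outcome."""

    position: int
    region: str
    degeneracy: int | None = None
    conserved: str = UNCLASSIFIED
    ancestral_aa: str | None = None
    ancestral_nt: str | None = None
    derived_count: int | None = None
    derived_nt: str | None = None
    status: str = ""
    gene_id: str = ""
    essential: bool | None = None


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _focal_majority(aln_focal: np.ndarray, pos: int) -> str | None:
    """Majority focal allele at a column; None on tie or no calls."""
    col = [v for v in aln_focal[:, pos].tolist() if v in set(NUCLEOTIDES)]
    if not col:
        return None
    counts = Counter(col).most_common()
    if len(counts) > 1 and counts[0][1] == counts[1][1]:
        return None
    return counts[0][0].decode()


def classify_sites(
    aln: Alignment,
    annotation: GenomeAnnotation,
    polarized: list[PolarizedSite],
) -> list[SiteRecord]:
    """Populate a SiteRecord for every alignment position.

    Coding codons are read on the coding strand (reverse complement for
    minus-strand genes).  The ancestral codon uses the polarizer's ancestral
    nucleotide where resolved, falling back on the focal-population majority
    allele; if any codon position stays uncalled, or the ancestral codon is
    a stop, degeneracy and ancestral amino acid are left undefined for the
    whole codon.  Outgroup conservation uses the realized outgroup codons.
    """
    if len(polarized) != aln.length:
        raise ValueError("polarized site list does not match alignment length")
    regions = annotation.region_codes()
    records = [
        SiteRecord(
            position=p,
            region=str(regions[p]),
            derived_count=polarized[p].derived_count,
            derived_nt=(polarized[p].derived_nt or b"").decode() or None,
            ancestral_nt=(polarized[p].ancestral_nt or b"").decode() or None,
            status=polarized[p].status,
        )
        for p in range(aln.length)
    ]

    focal = aln.rows(FOCAL)
    og2 = aln.row(aln.strain_map.by_population(OUTGROUP2)[0])
    og3 = aln.row(aln.strain_map.by_population(OUTGROUP3)[0])

    def outgroup_codon(row: np.ndarray, positions: list[int], strand: str) -> str:
        s = "".join(bytes(row[p]).decode() if bytes(row[p]) in set(NUCLEOTIDES) else "?"
                    for p in positions)
        return _revcomp(s) if strand == "-" else s

    for iv in annotation.coding_intervals():
        coding_positions = list(range(iv.start, iv.end))
        if iv.strand == "-":
            coding_positions = coding_positions[::-1]
        coding_positions = coding_positions[iv.frame_offset:]
        for c0 in range(0, len(coding_positions) - 2, 3):
            codon_pos = coding_positions[c0:c0 + 3]
            # ancestral codon in coding-strand orientation
            anc = []
            for p in codon_pos:
                nt = records[p].ancestral_nt
                if nt is None:
                    nt = _focal_majority(focal, p)
                if nt is not None and iv.strand == "-":
                    nt = _revcomp(nt)
                anc.append(nt)
            anc_codon = None if any(a is None for a in anc) else "".join(anc)
            aa = _translate(anc_codon) if anc_codon else None
            # outgroup codons read in alignment order then oriented
            aln_order = sorted(codon_pos)
            c2 = outgroup_codon(og2, aln_order, iv.strand)
            c3 = outgroup_codon(og3, aln_order, iv.strand)
            cons = conservation_status(c2, c3)
            for off, p in enumerate(codon_pos):
                rec = records[p]
                rec.gene_id = iv.gene_id
                rec.essential = iv.essential
                rec.conserved = cons
                if anc_codon is not None and aa is not None:
                    rec.degeneracy = degeneracy_of(anc_codon, off)
                    rec.ancestral_aa = aa
    return records


def site_table(records: list[SiteRecord]):
    """Records as a pandas DataFrame (the canonical site-table TSV layout)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "position": [r.position for r in records],
            "region": [r.region for r in records],
            "degeneracy": [r.degeneracy if r.degeneracy is not None else "NA"
                           for r in records],
            "conserved": [r.conserved for r in records],
            "ancestral_aa": [r.ancestral_aa or "NA" for r in records],
            "ancestral_nt": [r.ancestral_nt or "NA" for r in records],
            "derived_count": [r.derived_count if r.derived_count is not None
                              else "NA" for r in records],
            "status": [r.status for r in records],
            "gene_id": [r.gene_id for r in records],
            "essential": ["NA" if r.essential is None else int(r.essential)
                          for r in records],
        }
    )
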