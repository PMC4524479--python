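"""Reading and writing multi-strain alignments, strain maps and annotations.

Coordinates are 0-based, half-open, in alignment space throughout.  The
alignment is a rectangular matrix of single-byte states per strain and
column: ``A C G T`` (uppercased), ``-`` for an alignment gap, and ``N`` for
any other/unknown character (missing data).  Gap and missing are distinct
states, but any column gapped in a focal strain is unusable for allele
counting and is excluded by the polarizer's missing-data filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "FOCAL", "OUTGROUP1", "OUTGROUP2", "OUTGROUP3", "POPULATIONS",
    "GAP", "MISSING", "NUCLEOTIDES",
    "StrainMap", "SiteColumn", "Interval", "GenomeAnnotation", "Alignment",
    "read_strain_map", "write_strain_map",
    "read_alignment", "write_alignment",
    "read_annotation", "write_annotation",
]

FOCAL = "FOCAL"
OUTGROUP1 = "OUTGROUP1"
OUTGROUP2 = "OUTGROUP2"
OUTGROUP3 = "OUTGROUP3"
POPULATIONS = (FOCAL, OUTGROUP1, OUTGROUP2, OUTGROUP3)

GAP = b"-"
MISSING = b"N"
NUCLEOTIDES = (b"A", b"C", b"G", b"T")

REGION_KINDS = ("CODING", "LTR", "INTERGENIC")


@dataclass(frozen=True)
class StrainMap:
    """Assignment of strain ids to populations.

    The focal population needs at least two sequences for frequencies to be
    meaningful; the second and third outgroups are single representatives.
    """

    populations: dict[str, str]

    def __post_init__(self) -> None:
        for sid, pop in self.populations.items():
            if pop not in POPULATIONS:
                raise ValueError(f"strain {sid!r}: unknown population {pop!r}")
        if len(self.by_population(FOCAL)) < 2:
            raise ValueError("strain map needs >= 2 FOCAL strains")
        for pop in (OUTGROUP2, OUTGROUP3):
            if len(self.by_population(pop)) != 1:
                raise ValueError(f"strain map needs exactly one {pop} sequence")

    def by_population(self, pop: str) -> list[str]:
        return [s for s, p in self.populations.items() if p == pop]

    def __len__(self) -> int:
        return len(self.populations)


@dataclass(frozen=True)
class SiteColumn:
    """One alignment column: byte state per strain."""

    position: int
    allele_by_strain: dict[str, bytes]


@dataclass(frozen=True)
class Interval:
    start: int
    end: int
    kind: str
    strand: str = "+"
    frame_offset: int = 0
    gene_id: str = ""
    essential: bool | None = None
    ltr_fixed: bool | None = None

    def __post_init__(self) -> None:
        if self.kind not in REGION_KINDS:
            raise ValueError(f"unknown interval kind {self.kind!r}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.frame_offset not in (0, 1, 2):
            raise ValueError("frame_offset must be 0, 1 or 2")
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad interval coordinates {self.start}..{self.end}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class GenomeAnnotation:
    """Non-overlapping region intervals over the alignment; positions not
    covered by any interval are implicitly intergenic."""

    intervals: list[Interval]
    length: int

    def __post_init__(self) -> None:
        ivs = sorted(self.intervals, key=lambda iv: iv.start)
        for a, b in zip(ivs, ivs[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"overlapping intervals: {a.gene_id or a.kind} "
                    f"[{a.start},{a.end}) and {b.gene_id or b.kind} "
                    f"[{b.start},{b.end})"
                )
        for iv in ivs:
            if iv.end > self.length:
                raise ValueError(f"interval {iv.gene_id or iv.kind} ends at "
                                 f"{iv.end} beyond alignment length {self.length}")
            if iv.kind == "CODING" and (len(iv) - iv.frame_offset) % 3 != 0:
                raise ValueError(
                    f"coding interval {iv.gene_id!r} has length {len(iv)} "
                    f"(frame offset {iv.frame_offset}) not divisible by 3"
                )
        self.intervals = ivs

    def region_codes(self) -> np.ndarray:
        """Per-position region label array ('CODING'/'LTR'/'INTERGENIC')."""
        out = np.full(self.length, "INTERGENIC", dtype="U10")
        for iv in self.intervals:
            out[iv.start:iv.end] = iv.kind
        return out

    def coding_intervals(self) -> list[Interval]:
        return [iv for iv in self.intervals if iv.kind == "CODING"]


@dataclass
class Alignment:
    """Rectangular alignment: byte matrix (strains x columns) plus ids."""

    ids: list[str]
    matrix: np.ndarray  # dtype S1, shape (n_strains, length)
    strain_map: StrainMap
    _row: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.ids):
            raise ValueError("matrix shape does not match ids")
        self._row = {sid: k for k, sid in enumerate(self.ids)}

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def rows(self, population: str) -> np.ndarray:
        idx = [self._row[s] for s in self.strain_map.by_population(population)]
        return self.matrix[idx]

    def row(self, strain_id: str) -> np.ndarray:
        return self.matrix[self._row[strain_id]]

    def column(self, pos: int) -> SiteColumn:
        return SiteColumn(pos, {sid: bytes(self.matrix[k, pos])
                                for sid, k in self._row.items()})

    def columns(self) -> Iterator[SiteColumn]:
        for pos in range(self.length):
            yield self.column(pos)


# ---------------------------------------------------------------------------
# readers / writers


def _normalize(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype="S1").copy()
    bad = ~np.isin(arr, list(NUCLEOTIDES) + [GAP])
    arr[bad] = MISSING
    return arr


def read_strain_map(path: str | Path) -> StrainMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("strain_id", "population"):
        if col not in df.columns:
            raise ValueError(f"strain map is missing column {col!r}")
    if df["strain_id"].duplicated().any():
        dup = df.loc[df["strain_id"].duplicated(), "strain_id"].iloc[0]
        raise ValueError(f"duplicate strain id {dup!r} in strain map")
    return StrainMap(dict(zip(df["strain_id"], df["population"])))


def write_strain_map(smap: StrainMap, path: str | Path) -> None:
    pd.DataFrame(
        {"strain_id": list(smap.populations), "population": list(smap.populations.values())}
    ).to_csv(path, sep="\t", index=False)


def read_alignment(fasta_path: str | Path, strain_map_path: str | Path) -> Alignment:
    """Read an aligned FASTA plus its strain map into an Alignment.

    All records must have equal length and appear in the strain map;
    characters outside ``ACGT-`` (case-insensitive) become missing data.
    """
    smap = read_strain_map(strain_map_path)
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {fasta_path}")
    length = len(records[0].seq)
    ids, rows = [], []
    for rec in records:
        if len(rec.seq) != length:
            raise ValueError(
                f"record {rec.id!r} has length {len(rec.seq)}, expected {length}"
            )
        if rec.id not in smap.populations:
            raise ValueError(f"record {rec.id!r} not present in strain map")
        ids.append(rec.id)
        rows.append(_normalize(str(rec.seq)))
    missing = set(smap.populations) - set(ids)
    if missing:
        raise ValueError(f"strains in map but not in FASTA: {sorted(missing)}")
    return Alignment(ids=ids, matrix=np.vstack(rows), strain_map=smap)


def write_alignment(aln: Alignment, fasta_path: str | Path) -> None:
    records = [
        SeqRecord(Seq(aln.row(sid).tobytes().decode()), id=sid, description="")
        for sid in aln.ids
    ]
    SeqIO.write(records, str(fasta_path), "fasta")


_ANNOT_COLS = ["start", "end", "kind", "strand", "frame_offset",
               "gene_id", "essential", "ltr_fixed"]


def _parse_flag(v) -> bool | None:
    if pd.isna(v) or v in ("", "NA", "unknown"):
        return None
    if isinstance(v, str):
        return v.strip().lower() in ("1", "true", "yes")
    return bool(v)


def read_annotation(tsv_path: str | Path, alignment_length: int) -> GenomeAnnotation:
    df = pd.read_csv(tsv_path, sep="\t", dtype={"gene_id": str},
                     keep_default_na=False, na_values=["NA"])
    for col in _ANNOT_COLS:
        if col not in df.columns:
            raise ValueError(f"annotation is missing column {col!r}")
    intervals = [
        Interval(
            start=int(r.start), end=int(r.end), kind=str(r.kind),
            strand=str(r.strand), frame_offset=int(r.frame_offset),
            gene_id="" if pd.isna(r.gene_id) else str(r.gene_id),
            essential=_parse_flag(r.essential),
            ltr_fixed=_parse_flag(r.ltr_fixed),
        )
        for r in df.itertuples()
    ]
    return GenomeAnnotation(intervals=intervals, length=alignment_length)


def write_annotation(annot: GenomeAnnotation, path: str | Path) -> None:
    def flag(v):
        return "NA" if v is None else int(v)

    pd.DataFrame(
        [
            {
                "start": iv.start, "end": iv.end, "kind": iv.kind,
                "strand": iv.strand, "frame_offset": iv.frame_offset,
                "gene_id": iv.gene_id, "essential": flag(iv.essential),
                "ltr_fixed": flag(iv.ltr_fixed),
            }
            for iv in annot.intervals
        ],
        columns=_ANNOT_COLS,
    ).to_csv(path, sep="\t", index=False)
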