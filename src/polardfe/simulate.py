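"""Synthetic data generation: SFS-level simulation straight from the
selection model, and toy multi-strain alignments with full truth tables.

The alignment generator emulates the structure of the real data this
pipeline targets: 12 European (focal) strains, 8 Far East (first outgroup)
strains, one *S. cariocanus* (second outgroup) and one *S. cerevisiae*
(third outgroup) sequence over a chromosome segment of coding genes
(both strands), LTR remnants and intergenic tracts.  Mutation is single-hit
Jukes-Cantor per site; outgroup branches evolve neutrally; within each
population the per-site derived-allele count is drawn from the exact
expected unfolded-SFS class probabilities for that site's scaled selection
coefficient, so selection thins polymorphism exactly as the inference model
assumes.  Default rates target ~1.4% EU-FE nucleotide divergence with
per-site polymorphism about ten times lower.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment_io import (
    FOCAL, OUTGROUP1, OUTGROUP2, OUTGROUP3,
    Alignment, GenomeAnnotation, Interval, StrainMap,
    write_alignment, write_annotation, write_strain_map,
)
from .dfe import (
    DFEParams, binomial_sojourn, dfe_mixture, expected_sfs,
    fixation_rate, fixed_class_segregating_integral, DemographyModel,
)
from .polarize import SFS
from .sites import degeneracy_of

__all__ = ["SimulationConfig", "SfsSimulation", "AlignmentSimulation",
           "simulate_sfs", "simulate_alignment", "DEFAULT_CLASS_DFES"]

_BASES = np.array([b"A", b"C", b"G", b"T"])
_STOPS = {"TAA", "TAG", "TGA"}

#: site-class selection models used by default: LTRs neutral, intergenic
#: weakly constrained, synonymous classes neutral-to-mild, zero-fold sites
#: under the leptokurtic gamma DFE estimated for this population
DEFAULT_CLASS_DFES: dict[str, DFEParams] = {
    "ltr": DFEParams(deleterious_kind="none"),
    "intergenic": DFEParams(deleterious_kind="equal", NeSd_mean=1.0),
    "fourfold": DFEParams(deleterious_kind="none"),
    "twofold": DFEParams(deleterious_kind="equal", NeSd_mean=5.0),
    "zerofold": DFEParams(deleterious_kind="gamma", NeSd_mean=140.3,
                          beta_d=0.28),
}


@dataclass
class SimulationConfig:
    """Study conditions for the generators.

    ``theta`` is the per-site scaled mutation rate (the neutral expectation
    of nucleotide diversity); ``T_div_focal``/``T_div_outgroup1`` are the
    scaled lengths of the focal and first-outgroup branches governing fixed
    derived alleles.  The defaults anchor the neutral classes on the
    fastest-evolving regions: theta * T ~ 2.3% fixed derived per branch
    (~4.6% EU-FE divergence at LTRs, polymorphism ten times lower), which
    yields ~0.5% divergence at zero-fold sites under the default gamma DFE
    and an overall EU-FE divergence near the observed ~1.4% once selection
    and sequence composition are taken into account.
    ``div_outgroup2``/``div_outgroup3`` are per-site substitution
    probabilities on the deeper neutral outgroup branches.
    """

    seed: int
    n_focal: int = 12
    n_outgroup1: int = 8
    theta: float = 0.0046
    T_div_focal: float = 5.0
    T_div_outgroup1: float = 5.0
    div_outgroup2: float = 0.04
    div_outgroup3: float = 0.12
    class_dfes: dict[str, DFEParams] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_DFES))
    class_sizes: dict[str, int] = field(
        default_factory=lambda: {"ltr": 3000, "intergenic": 15000,
                                 "fourfold": 45000, "twofold": 45000,
                                 "zerofold": 90000})
    # alignment-level knobs
    n_genes: int = 25
    gene_length_range: tuple[int, int] = (300, 1500)
    n_ltrs: int = 6
    ltr_length: int = 330
    intergenic_length_range: tuple[int, int] = (150, 500)
    missing_rate: float = 0.0005
    essential_fraction: float = 0.1
    demography: DemographyModel = field(default_factory=DemographyModel)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducibility")
        if self.n_focal < 2 or self.n_outgroup1 < 1:
            raise ValueError("need >= 2 focal and >= 1 first-outgroup strains")
        if any(v <= 0 for v in self.class_sizes.values()):
            raise ValueError("class sizes must be positive")


@dataclass
class SfsSimulation:
    sfs_by_class: dict[str, SFS]
    truth: dict[str, DFEParams]
    config: SimulationConfig


def _site_class_probs(n: int, S: np.ndarray, theta: float, T_div: float,
                      demography: DemographyModel | None = None) -> np.ndarray:
    """Exact class probabilities p_0..p_n per site for an array of scaled
    effects."""
    if demography is not None and demography.kind == "two_epoch":
        rows = [expected_sfs(n, (np.array([s]), np.array([1.0])), theta,
                             T_div, 1.0, demography=demography) for s in S]
        return np.vstack(rows)
    b = binomial_sojourn(n, S) * theta
    en = theta * (T_div * np.atleast_1d(fixation_rate(S))
                  + fixed_class_segregating_integral(n, S))
    seg = np.concatenate([b, en[:, None]], axis=1)
    p0 = 1.0 - seg.sum(axis=1)
    if np.any(p0 <= 0):
        raise ValueError("theta/T_div too large: negative invariant probability")
    return np.concatenate([p0[:, None], seg], axis=1)


def _draw_effects(params: DFEParams, size: int, rng: np.random.Generator) -> np.ndarray:
    """Per-site scaled effects drawn from a DFE (continuous gamma for the
    deleterious component)."""
    S = np.zeros(size)
    adv = rng.random(size) < params.p_a
    S[adv] = params.S_a
    rest = ~adv
    if params.deleterious_kind == "equal":
        S[rest] = -params.NeSd_mean
    elif params.deleterious_kind == "gamma":
        S[rest] = -rng.gamma(params.beta_d,
                             params.NeSd_mean / params.beta_d,
                             rest.sum())
    np.clip(S, -5000.0, 5000.0, out=S)
    return S


def _draw_counts(probs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One categorical draw per row of a probability matrix."""
    cum = np.cumsum(probs, axis=1)
    u = rng.random(probs.shape[0])
    return (u[:, None] > cum).sum(axis=1)


def simulate_sfs(config: SimulationConfig) -> SfsSimulation:
    """Simulate unfolded SFS per site class directly from the model.

    Every site draws its scaled effect from the class DFE, its SFS class
    from the exact expected class probabilities, independently across
    sites; deterministic under a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_focal
    demog = config.demography if config.demography.kind == "two_epoch" else None
    out: dict[str, SFS] = {}
    for label in sorted(config.class_sizes):
        L = config.class_sizes[label]
        params = config.class_dfes[label]
        S = _draw_effects(params, L, rng)
        probs = _site_class_probs(n, S, config.theta, config.T_div_focal,
                                  demography=demog)
        counts = np.bincount(_draw_counts(probs, rng), minlength=n + 1)
        out[label] = SFS(n=n, counts=counts, label=label)
    return SfsSimulation(sfs_by_class=out,
                         truth=dict(config.class_dfes), config=config)


# ---------------------------------------------------------------------------
# alignment-level simulation


@dataclass
class AlignmentSimulation:
    alignment: Alignment
    annotation: GenomeAnnotation
    truth: pd.DataFrame
    config: SimulationConfig

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "alignment.fa",
            "strains": outdir / "strains.tsv",
            "annotation": outdir / "annotation.tsv",
            "truth": outdir / "truth.tsv",
        }
        write_alignment(self.alignment, paths["fasta"])
        write_strain_map(self.alignment.strain_map, paths["strains"])
        write_annotation(self.annotation, paths["annotation"])
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


def _random_gene(length: int, rng: np.random.Generator) -> str:
    """Random coding sequence of sense codons (ATG start, no stops)."""
    codons = []
    while len(codons) < length // 3:
        c = "".join(rng.choice(list("ACGT"), 3))
        if c not in _STOPS:
            codons.append(c)
    codons[0] = "ATG"
    return "".join(codons)


def _layout(config: SimulationConfig, rng: np.random.Generator):
    """Alternating intergenic / gene / LTR layout along the segment."""
    intervals: list[Interval] = []
    pieces: list[str] = []
    pos = 0
    n_ess = max(1, int(round(config.essential_fraction * config.n_genes)))
    essential_ids = set(rng.choice(config.n_genes, size=n_ess, replace=False))
    ltr_slots = set(rng.choice(config.n_genes, size=min(config.n_ltrs,
                                                        config.n_genes),
                               replace=False))
    for g in range(config.n_genes):
        ig_len = int(rng.integers(*config.intergenic_length_range))
        pieces.append("".join(rng.choice(list("ACGT"), ig_len)))
        pos += ig_len
        if g in ltr_slots:
            intervals.append(Interval(pos, pos + config.ltr_length, "LTR",
                                      ltr_fixed=True))
            pieces.append("".join(rng.choice(list("ACGT"), config.ltr_length)))
            pos += config.ltr_length
        lo, hi = config.gene_length_range
        glen = int(rng.integers(lo // 3, hi // 3 + 1)) * 3
        strand = "+" if rng.random() < 0.5 else "-"
        gene = _random_gene(glen, rng)
        from Bio.Seq import Seq
        placed = gene if strand == "+" else str(Seq(gene).reverse_complement())
        intervals.append(Interval(pos, pos + glen, "CODING", strand=strand,
                                  gene_id=f"G{g + 1:03d}",
                                  essential=(g in essential_ids)))
        pieces.append(placed)
        pos += glen
    tail = int(rng.integers(*config.intergenic_length_range))
    pieces.append("".join(rng.choice(list("ACGT"), tail)))
    pos += tail
    ancestral = "".join(pieces)
    assert len(ancestral) == pos
    return ancestral, GenomeAnnotation(intervals=intervals, length=pos)


def _true_site_classes(ancestral: str, annot: GenomeAnnotation):
    """Per-position truth: region and, for coding, degeneracy from the
    ancestral codon."""
    from Bio.Seq import Seq

    L = len(ancestral)
    region = annot.region_codes()
    degen = np.full(L, -1, dtype=int)
    for iv in annot.coding_intervals():
        positions = list(range(iv.start, iv.end))
        if iv.strand == "-":
            positions = positions[::-1]
        positions = positions[iv.frame_offset:]
        for c0 in range(0, len(positions) - 2, 3):
            codon_pos = positions[c0:c0 + 3]
            codon = "".join(ancestral[p] for p in sorted(codon_pos))
            if iv.strand == "-":
                codon = str(Seq(codon).reverse_complement())
            for off, p in enumerate(codon_pos):
                d = degeneracy_of(codon, off)
                degen[p] = -1 if d is None else d
    return region, degen


def _mutate_neutral(seq: np.ndarray, prob: float, rng: np.random.Generator) -> np.ndarray:
    """Jukes-Cantor substitutions: each site changes to a random different
    base with the given probability."""
    out = seq.copy()
    hit = np.nonzero(rng.random(len(seq)) < prob)[0]
    for p in hit:
        choices = _BASES[_BASES != out[p]]
        out[p] = rng.choice(choices)
    return out


def simulate_alignment(config: SimulationConfig) -> AlignmentSimulation:
    """Generate a toy multi-strain alignment with a full truth table.

    The ancestral (EU-FE common ancestor) sequence carries genes, LTRs and
    intergenic tracts; each population receives per-site derived-allele
    counts drawn from the expected-SFS class probabilities for the site's
    effect; the two deep outgroups accumulate neutral substitutions.
    """
    rng = np.random.default_rng(config.seed)
    ancestral_str, annot = _layout(config, rng)
    L = len(ancestral_str)
    ancestral = np.frombuffer(ancestral_str.encode(), dtype="S1").copy()
    region, degen = _true_site_classes(ancestral_str, annot)

    # per-site scaled effects by class
    S = np.zeros(L)
    class_of = np.where(
        region == "LTR", "ltr",
        np.where(region == "INTERGENIC", "intergenic", ""))
    class_of = class_of.astype(object)
    coding = region == "CODING"
    class_of[coding & (degen == 4)] = "fourfold"
    class_of[coding & (degen == 2)] = "twofold"
    class_of[coding & (degen == 0)] = "zerofold"
    class_of[coding & (degen == -1)] = "intergenic"  # unclassifiable codon edge
    for label in ("ltr", "intergenic", "fourfold", "twofold", "zerofold"):
        mask = class_of == label
        S[mask] = _draw_effects(config.class_dfes[label], int(mask.sum()), rng)

    def population_haplotypes(n_seq: int, T_div: float):
        probs = _site_class_probs(n_seq, S, config.theta, T_div)
        counts = _draw_counts(probs, rng)
        hap = np.tile(ancestral, (n_seq, 1))
        derived = np.full(L, b"", dtype="S1")
        poly = np.nonzero(counts > 0)[0]
        for p in poly:
            d = rng.choice(_BASES[_BASES != ancestral[p]])
            derived[p] = d
            carriers = rng.choice(n_seq, size=counts[p], replace=False)
            hap[carriers, p] = d
        return hap, counts, derived

    focal_hap, focal_counts, _ = population_haplotypes(
        config.n_focal, config.T_div_focal)
    og1_hap, _, _ = population_haplotypes(
        config.n_outgroup1, config.T_div_outgroup1)
    og2 = _mutate_neutral(ancestral, config.div_outgroup2, rng)
    og3 = _mutate_neutral(ancestral, config.div_outgroup3, rng)

    # sprinkle missing data outside the focal truth comparison set
    ids = ([f"EU_{k + 1:02d}" for k in range(config.n_focal)]
           + [f"FE_{k + 1:02d}" for k in range(config.n_outgroup1)]
           + ["CARIOCANUS", "CEREVISIAE"])
    matrix = np.vstack([focal_hap, og1_hap, og2[None, :], og3[None, :]])
    if config.missing_rate > 0:
        mask = rng.random(matrix.shape) < config.missing_rate
        matrix[mask] = b"N"
    pops = {sid: FOCAL for sid in ids[: config.n_focal]}
    pops.update({sid: OUTGROUP1
                 for sid in ids[config.n_focal:config.n_focal + config.n_outgroup1]})
    pops["CARIOCANUS"] = OUTGROUP2
    pops["CEREVISIAE"] = OUTGROUP3
    aln = Alignment(ids=ids, matrix=matrix, strain_map=StrainMap(pops))

    truth = pd.DataFrame({
        "position": np.arange(L),
        "ancestral": [b.decode() for b in ancestral],
        "S": S,
        "region": region,
        "degeneracy": degen,
        "derived_count": focal_counts,
    })
    return AlignmentSimulation(alignment=aln, annotation=annot,
                               truth=truth, config=config)
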