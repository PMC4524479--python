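import numpy as np
import pytest

from polardfe.alignment_io import (
    FOCAL, OUTGROUP1, OUTGROUP2, OUTGROUP3, Alignment, SiteColumn, StrainMap,
)
from polardfe.simulate import SimulationConfig, simulate_alignment


def make_strain_map(n_focal=12, n_og1=8) -> StrainMap:
    pops = {f"EU_{k + 1:02d}": FOCAL for k in range(n_focal)}
    pops.update({f"FE_{k + 1:02d}": OUTGROUP1 for k in range(n_og1)})
    pops["CARIOCANUS"] = OUTGROUP2
    pops["CEREVISIAE"] = OUTGROUP3
    return StrainMap(pops)


def make_column(focal, og1, og2, og3="A", position=0,
                strain_map=None) -> tuple[SiteColumn, StrainMap]:
    """Column from per-population allele strings, e.g. focal='A'*10+'G'*2."""
    smap = strain_map or make_strain_map(len(focal), len(og1))
    alleles = {}
    fids = smap.by_population(FOCAL)
    oids = smap.by_population(OUTGROUP1)
    for sid, a in zip(fids, focal):
        alleles[sid] = a.encode()
    for sid, a in zip(oids, og1):
        alleles[sid] = a.encode()
    alleles[smap.by_population(OUTGROUP2)[0]] = og2.encode()
    alleles[smap.by_population(OUTGROUP3)[0]] = og3.encode()
    return SiteColumn(position, alleles), smap


@pytest.fixture(scope="session")
def short_branch_sim():
    """Synthetic alignment in the homoplasy-free (short outgroup branch)
    regime, with truth table."""
    config = SimulationConfig(seed=20260930, n_genes=12,
                              T_div_focal=1.0, T_div_outgroup1=1.0,
                              div_outgroup2=0.003, div_outgroup3=0.01)
    return simulate_alignment(config)


@pytest.fixture(scope="session")
def default_sim():
    """Synthetic alignment at the default (realistic-divergence) settings."""
    return simulate_alignment(SimulationConfig(seed=7, n_genes=10))
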