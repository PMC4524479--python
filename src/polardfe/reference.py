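"""Reference DFE estimates for the European *Saccharomyces paradoxus*
population (chromosome III survey).

These constants are the published maximum-likelihood estimates that the
worked examples and the conservation-correlation analysis operate on:
per-category and per-ancestral-amino-acid fits of the equal-effects model
(model 1) and the gamma model (model 2) to zero-fold degenerate coding
sites, and the log-likelihoods of the seven-model family.  Effects are on
the NeSd scale.

Gamma means printed as lower bounds ("> 2.9e10") are degenerate boundary
fits: the likelihood is maximized with the mean running to infinity at a
tiny shape, so only a bound is reported.  Such entries carry
``boundary=True`` and are treated as mean -> infinity (all deleterious
mass above any finite NeSd threshold) in downstream proportions.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import inf

__all__ = [
    "AAGammaFit", "PER_AA_FITS", "CATEGORY_GAMMA", "NONCONSERVED_EQUAL_NESD",
    "CATEGORY_MODEL_LOGL", "MODEL_N_PARAMS_TABLE", "BY_AA_SUM_LOGL",
    "per_aa_deleterious_proportions",
]


@dataclass(frozen=True)
class AAGammaFit:
    n_sites: int
    model1_NeSd: float          # equal-effects estimate
    model2_mean: float          # gamma mean (inf if boundary)
    model2_shape: float
    boundary: bool = False


#: per ancestral amino acid, outgroup-conserved zero-fold sites
PER_AA_FITS: dict[str, AAGammaFit] = {
    "A": AAGammaFit(4792, 1.34, 36.29, 0.29),
    "C": AAGammaFit(1190, 21394.0, 25207.0, 54.1),
    "D": AAGammaFit(5171, 6.28, 6.78, 7.85),
    "E": AAGammaFit(5712, 2.35, 59928.0, 0.20),
    "F": AAGammaFit(4381, 3.64, 593.04, 0.50),
    "G": AAGammaFit(4621, 2.31, 34.46, 0.64),
    "H": AAGammaFit(1952, 3.27, 91.21, 0.68),
    "I": AAGammaFit(5744, 1.94, 22952.0, 0.17),
    "K": AAGammaFit(6283, 2.24, 26.39, 0.65),
    "L": AAGammaFit(5319, 2.04, inf, 0.05, boundary=True),
    "M": AAGammaFit(2723, 2.03, 570.30, 0.28),
    "N": AAGammaFit(5085, 31.76, 22.73, 0.39),
    "P": AAGammaFit(4073, 2.12, 66.77, 0.46),
    "Q": AAGammaFit(3677, 1.99, 4928.0, 0.23),
    "R": AAGammaFit(2299, 2.45, 12.47, 1.03),
    "S": AAGammaFit(7480, 1.75, 7.01, 0.82),
    "T": AAGammaFit(4949, 1.65, 3353.0, 0.18),
    "V": AAGammaFit(4860, 1.31, 1501.0, 0.15),
    "W": AAGammaFit(1706, 2.83, inf, 0.05, boundary=True),
    "Y": AAGammaFit(3035, 2.96, 10.65, 1.52),
}

#: gamma (mean, shape) for pooled categories of zero-fold sites
CATEGORY_GAMMA: dict[str, tuple[float, float]] = {
    "total": (140.3, 0.28),
    "conserved": (158.68, 0.33),
}

#: nonconserved sites: no significant variation, equal-effects estimate
NONCONSERVED_EQUAL_NESD = 0.53

#: log-likelihoods of the seven-model family per zero-fold site category
CATEGORY_MODEL_LOGL: dict[str, dict[int, float]] = {
    "total": {1: -2666.78, 2: -2603.30, 3: -2606.95, 4: -2603.30,
              5: -3329.98, 6: -2606.95, 7: -2603.30},
    "conserved": {1: -1995.85, 2: -1926.67, 3: -1929.54, 4: -1926.67,
                  5: -2691.10, 6: -1929.54, 7: -1926.67},
    "nonconserved": {1: -590.47, 2: -590.47, 3: -590.47, 4: -590.47,
                     5: -600.29, 6: -590.47, 7: -590.47},
}

#: free selection parameters per model id
MODEL_N_PARAMS_TABLE: dict[int, int] = {1: 1, 2: 2, 3: 2, 4: 3, 5: 2, 6: 3, 7: 4}

#: summed log-likelihoods of per-amino-acid fits (conserved sites), for the
#: pooled-vs-partitioned likelihood-ratio tests
BY_AA_SUM_LOGL: dict[str, float] = {"model1": -1956.07, "model2": -1884.57}


def per_aa_deleterious_proportions(threshold: float = 1.0) -> dict[str, float]:
    """Proportion of deleterious mutations (NeSd >= threshold) per ancestral
    amino acid, from the gamma (model 2) reference fits.

    Boundary rows (mean reported only as a lower bound) contribute
    proportion 1: in the mean -> infinity limit all deleterious mass
    exceeds any finite threshold.
    """
    from .compare import deleterious_proportion

    return {
        aa: deleterious_proportion(fit.model2_mean, fit.model2_shape, threshold)
        for aa, fit in PER_AA_FITS.items()
    }
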