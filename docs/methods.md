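# Methods

## Model

The inference engine is a Poisson-random-field description of new
mutations in a panmictic population. Sites are independent; each site of a
class of `L` sites receives new mutations at scaled per-site rate `theta`
(the neutral expectation of nucleotide diversity). A mutation with scaled
selection coefficient `S = N_e s` (negative deleterious, positive
advantageous) contributes an expected density of segregating copies

    tau(x; S) = 2 (1 - e^{-S(1-x)}) / [ x (1-x) (1 - e^{-S}) ],

which reduces to `2/x` as `S -> 0`. Sampling `n` haploid sequences turns
this into expected unfolded-SFS class counts

    e_i = L * theta * Int C(n,i) x^i (1-x)^{n-i} tau(x; S) dx ,  0 < i < n.

These integrals are evaluated in closed form: with
`M = 1F1(i; n; S)` (Kummer's function) the bracketed integral equals
`2 C(n,i) B(i, n-i) * (1 - e^{-S} M) / (1 - e^{-S})`, rearranged per sign
of `S` so that every factor stays in (0, 1) — no quadrature, no overflow,
for |S| up to the working cap of 5000. The neutral limit recovers
Watterson's `e_i = L theta * 2/i` exactly.

The fixed-derived class `i = n` is the sum of a fixation flux
`L * theta * T_div * u(S)`, with `u(S) = S/(1 - e^{-S})` the fixation
probability relative to neutral and `T_div` a free scaled divergence
nuisance, plus the segregating mass that binomial sampling places at
`i = n` (one smooth Gauss–Legendre integral, 240 nodes). The invariant
class is the remainder `e_0 = L - sum_{i>0} e_i`, which makes the Poisson
likelihood over classes multinomial-like with a fixed total.

### DFE and model family

Deleterious effects are either a point mass (`equal`) or gamma distributed
with mean `NeSd` and shape `beta`; an optional advantageous point mass
puts weight `p_a` at `+S_a`. The seven fitted configurations follow the
standard family: (1) equal, no advantage; (2) gamma, no advantage;
(3, 4) equal/gamma with `p_a` free but `S_a` pinned at 1e-6 (≈0);
(5) advantage only, deleterious effects removed; (6, 7) equal/gamma with
`p_a` and `S_a` free. Reported parameter counts cover only the selection
parameters (1, 2, 2, 3, 2, 3, 4).

The gamma is discretized into `K = 200` equal-probability slabs, each
represented by its conditional mean (computed from the shape `beta + 1`
CDF), with magnitudes clamped at 5000 — mutations that strong are
effectively absent from all observable classes, so the clamp only protects
the numerics. Effect-bin proportions (NeSd <1, 1–10, 10–100, >100) come
from the gamma CDF directly and are therefore independent of `K`.

### Shared nuisances and fitting

`theta` and `T_div` are shared between the neutral (4-fold degenerate)
and selected site classes: the neutral-to-selected contrast is what
identifies the absolute scale of selection, and with an independent
selected-class `theta` the gamma mean is unidentified (it runs to the
boundary while `theta` compensates — verified empirically). Fitting is
joint maximum likelihood: a closed-form neutral-only fit seeds the
nuisances, the selection parameters are optimized alone (Nelder–Mead,
10 seeded random starts plus one default start), and the best candidates
are refined jointly over all parameters, with a final restart of the
winner. Transforms: log for `theta`, `T_div`, `NeSd`, `beta`, `S_a`
(bounds 1e-4..1e7 for the mean, 0.02..60 for the shape); logit for `p_a`.
Fits on exact expected counts recover the generating parameters to four
decimals, and over simulated replicates the fitted maximum never falls
below the likelihood at truth, so the optimizer introduces no systematic
shortfall. Boundary estimates (mean at 1e6+, shape at 0.02) are flagged on
the returned fit rather than hidden.

### Demography

Population size change is assessed on the neutral class only, with a
discrete Wright–Fisher grid: a haploid pool of `grid_size` copies (genic
selection `s = S / (2M)`, matching the diffusion convention above), at
mutation–drift equilibrium for unit influx, instantaneously resized by a
factor `r` at scaled time `t` (units of 2N generations of the new size)
and stepped forward generation by generation with influx proportional to
the new size. At `r = 1` the grid equilibrium is exactly invariant, so the
constant-size model is exactly nested inside the two-epoch model and the
LRT (df = 2, `r` and `t`) cannot go negative. `theta` and the fixed-class
mean profile out of the grid likelihood in closed form, leaving a
two-dimensional outer optimization. Fixations during the post-change epoch
are absorbed into the free divergence term rather than tracked on the
grid. The default grid is 200 states; the calibration tests use 100 (their
stated problem size), where the grid spectrum still matches the diffusion
spectrum to ~2% per class and converges as the grid is refined.
Simulations confirm the test is conservative under the null (empirical
type-I error ≈ 0.01–0.03 at alpha = 0.05) and has overwhelming power
against a five-fold recent expansion at realistic site counts.

## Polarization rules

A column enters the analysis only if every focal strain is called (no gap
or missing base), at least one first-outgroup strain is called, and the
second-outgroup sequence is called. The ladder: focal biallelic {x, y}
resolves iff the first outgroup is fixed for x or for y (a polymorphic
first outgroup containing the focal minor allele, or any third allele, is
excluded as ambiguous — the conservative reading of "unambiguous"
assignment); focal monomorphic x with the first outgroup fixed for y ≠ x
defers to the second outgroup (y → fixed derived, x → substitution on the
outgroup branch, anything else → ambiguous). The third outgroup never
participates in polarization; it only scores conservation. Sites with any
missing focal strain are dropped rather than projected to a smaller n.

Degeneracy (0/2/4-fold, with the 3-fold isoleucine position folded into
the 2-fold class) is computed from the ancestral codon, reconstructed from
per-site ancestral alleles with a focal-majority fallback; codons with an
unresolvable position or an ancestral stop are left unclassified.
Conservation is the amino-acid identity of the two outgroup codons
(synonymous differences conserved; gaps, ambiguity or stops →
unclassified, exposed as a third bucket rather than forced into the
conserved/nonconserved partition).

## Synthetic data

The generator emulates the study's structure, not its full biology:
a chromosome segment of random sense-codon genes (both strands), LTR
tracts and intergenic spacers; single-hit Jukes–Cantor mutation (no
indels, no context effects, no rate heterogeneity beyond the DFE); free
recombination between sites (derived alleles assigned to random strain
subsets, no linkage disequilibrium or haplotype structure); neutral
evolution on the outgroup branches; essentiality flags assigned at random
(the study found no essentiality effect, so none is built in). Passing
tests therefore demonstrate correctness of the pipeline's logic and
calibration of its statistics under the model's own assumptions — not
robustness to linkage, alignment error, or mutation-spectrum biases that
real data would add.

Default study conditions (chosen once, from the published anchors): 12
focal + 8 first-outgroup strains; neutral `theta = 0.0046` and branch
lengths `T_div = 5` per branch, anchored on the fastest (LTR) class —
~4.6% EU–FE divergence at LTRs with polymorphism ten times lower. Under
the default class DFEs (LTR neutral; intergenic equal `NeSd = 1`; 4-fold
neutral; 2-fold equal `NeSd = 5`; 0-fold gamma mean 140.3, shape 0.28)
this yields ~0.55% divergence at 0-fold sites and an overall EU–FE
divergence on the observed ~1.4–2.5% scale, emerging from composition.
Consensus-based divergence runs above the fixed-difference rate because
mid-frequency polymorphism flips the eight-strain outgroup consensus; this
is a property of the measure, not of the calibration. Deeper outgroups use
per-site substitution probabilities 0.04 (*S. cariocanus*) and 0.12
(*S. cerevisiae*); exactness fixtures shorten all branches
(`T_div = 1`, outgroup probabilities 0.003/0.01) to suppress homoplasy and
parallel fixations, the regime in which parsimony polarization is provably
correct.

## Reference estimates and the conservation correlation

The package bundles the published per-category and per-amino-acid DFE
estimates for the European *S. paradoxus* population (chromosome III,
0-fold degenerate sites) as constants, used by the worked examples and the
BLOSUM62 analysis. Two amino acids (L, W) have gamma means printed only as
lower bounds (">2.9e10") at the minimal shape — degenerate boundary fits.
These are treated as mean → infinity: their deleterious mass lies above
any finite NeSd threshold, so their deleterious proportion is 1. With that
rule the 20-amino-acid correlation between the proportion of deleterious
mutations (NeSd ≥ 1) and the BLOSUM62 diagonal gives r² = 0.330
(p = 0.0081, df = 18); taking the printed boundary values at face value
instead would place ~26% of L and W mutations below NeSd = 1 purely as an
artifact of the unconverged shape, and the correlation collapses. The
Pearson p-value uses the standard df = n − 2 = 18.

Problem sizes used by the heavier checks (all chosen for statistical
meaning at single-CPU scale): estimator recovery at L = 90,000 selected +
90,000 neutral sites over five replicate fits, assessed on the median
across replicates (individual ML estimates scatter along the gamma
(mean, shape) likelihood ridge at this information level; the median
measures central recovery, and a worst-of-five criterion would reject even
an exact estimator about half the time); demography calibration over 200
null simulations of 20,000 sites at grid 100.

## Known limitations

- The scaled-effect convention (`S` entering `tau` is the reported
  `N_e S_d` directly) is internally consistent but the historical
  program's 2Ns/4Ns convention is not recoverable from the source study;
  quantities that depend only on reported gamma parameters (bins,
  correlations, LRT arithmetic) are convention-free.
- Absolute log-likelihoods are not comparable across implementations
  (fixed-class and invariant-class handling differ); only likelihood
  differences and test statistics are meaningful.
- No SFS projection for missing data, no probabilistic polarization, no
  linkage modeling, no confidence intervals — matching the scope of the
  original analysis.
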