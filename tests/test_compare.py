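import numpy as np
import pytest

from polardfe.compare import (
    AMINO_ACIDS, BLOSUM62_DIAGONAL, blosum_identity_correlation,
    chi_square_table, deleterious_proportion, pairwise_divergence,
    wilcoxon_category_test,
)
from polardfe.reference import PER_AA_FITS, per_aa_deleterious_proportions

from _oracles import pearson_chi2_direct, pearson_r2_direct, rank_sum_exact_p


class TestBlosumConstants:
    def test_twenty_positive_entries(self):
        assert len(BLOSUM62_DIAGONAL) == 20
        assert all(v > 0 for v in BLOSUM62_DIAGONAL.values())

    def test_tryptophan_and_cysteine_largest(self):
        top2 = sorted(BLOSUM62_DIAGONAL, key=BLOSUM62_DIAGONAL.get)[-2:]
        assert set(top2) == {"W", "C"}

    def test_matches_biopython_matrix(self):
        """Embedded constants agree with the independently shipped
        BLOSUM62."""
        from Bio.Align import substitution_matrices

        m = substitution_matrices.load("BLOSUM62")
        for aa, score in BLOSUM62_DIAGONAL.items():
            assert m[aa, aa] == score


class TestWilcoxon:
    def test_identical_groups(self):
        assert wilcoxon_category_test([[1, 1, 1], [1, 1, 1]]) == 1.0

    def test_exact_matches_enumeration_oracle(self):
        x, y = [0, 0, 0, 0], [1, 1, 1, 1]
        p = wilcoxon_category_test([x, y], method="exact")
        assert p == pytest.approx(rank_sum_exact_p(x, y))
        assert p == pytest.approx(2 / 70)  # the two extreme assignments

    def test_asymptotic_close_to_exact_on_moderate_samples(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 9)
        y = rng.normal(1.0, 1, 9)
        p_a = wilcoxon_category_test([x, y])
        p_e = wilcoxon_category_test([x, y], method="exact")
        assert p_a == pytest.approx(p_e, abs=0.02)

    def test_three_groups_kruskal(self):
        p = wilcoxon_category_test([[1, 2, 3], [1.1, 2.1, 3.1], [5, 6, 7]])
        assert 0 < p < 1

    def test_power_on_separated_site_classes(self):
        """Derived-allele frequencies drawn with LTR >> coding means are
        told apart decisively at 10,000 sites."""
        rng = np.random.default_rng(4)
        ltr = rng.binomial(12, 0.28, 2_000) / 12
        coding = rng.binomial(12, 0.06, 8_000) / 12
        assert wilcoxon_category_test([ltr, coding]) < 1e-3

    def test_validation(self):
        with pytest.raises(ValueError):
            wilcoxon_category_test([[1, 2]])
        with pytest.raises(ValueError):
            wilcoxon_category_test([[1, 2], []])


class TestChiSquare:
    def test_no_association(self):
        stat, df, p = chi_square_table([[10, 10], [10, 10]])
        assert stat == 0.0 and p == 1.0

    def test_direct_summation_oracle(self):
        table = [[20, 10], [10, 20]]
        stat, df, p = chi_square_table(table)
        assert stat == pytest.approx(pearson_chi2_direct(table))
        assert df == 1

    def test_df_formula(self):
        rng = np.random.default_rng(0)
        table = rng.integers(1, 50, size=(4, 13))
        _, df, _ = chi_square_table(table)
        assert df == 36

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square_table([[0, 0], [5, 5]])


class TestDivergence:
    def test_identical_sequences(self):
        from polardfe.alignment_io import Alignment
        from conftest import make_strain_map

        smap = make_strain_map(2, 2)
        matrix = np.vstack([np.frombuffer(b"ACGT" * 25, "S1")] * len(smap))
        aln = Alignment(ids=list(smap.populations), matrix=matrix.copy(),
                        strain_map=smap)
        assert pairwise_divergence(aln) == 0.0

    def test_counting(self):
        from polardfe.alignment_io import Alignment
        from conftest import make_strain_map

        smap = make_strain_map(2, 2)
        seqs = {sid: bytearray(b"A" * 100) for sid in smap.populations}
        for sid in smap.by_population("OUTGROUP1"):
            seqs[sid][7] = ord("G")  # one fixed difference
        matrix = np.vstack([np.frombuffer(bytes(seqs[sid]), "S1")
                            for sid in smap.populations])
        aln = Alignment(ids=list(smap.populations), matrix=matrix.copy(),
                        strain_map=smap)
        assert pairwise_divergence(aln) == pytest.approx(0.01)

    def test_matches_independent_recount(self, default_sim):
        """Package divergence equals a from-scratch consensus recount."""
        from collections import Counter
        from polardfe.alignment_io import FOCAL, NUCLEOTIDES, OUTGROUP1

        aln = default_sim.alignment
        focal, og1 = aln.rows(FOCAL), aln.rows(OUTGROUP1)
        nuc = set(NUCLEOTIDES)
        elig = diff = 0
        for p in range(aln.length):
            cf, co = focal[:, p], og1[:, p]
            if not (all(v in nuc for v in cf) and all(v in nuc for v in co)):
                continue
            elig += 1

            def consensus(col):
                counts = Counter(col)
                top = max(counts.values())
                return min(b for b, c in counts.items() if c == top)

            diff += consensus(cf) != consensus(co)
        assert pairwise_divergence(aln) == pytest.approx(diff / elig)

    def test_generator_divergence_targets(self, default_sim):
        """The default fixture reproduces the divergence structure: LTR
        (neutral) EU-FE divergence on the observed ~4.6% scale (consensus
        divergence runs somewhat above the fixed-difference rate because
        mid-frequency polymorphism flips the eight-strain outgroup
        consensus), coding below intergenic below LTR, and overall
        divergence on the observed ~1.4% scale."""
        aln = default_sim.alignment
        regions = default_sim.truth["region"].to_numpy()
        div = {r: pairwise_divergence(
                   aln, predicate=lambda p, r=r: regions[p] == r)
               for r in ("LTR", "INTERGENIC", "CODING")}
        assert 0.03 < div["LTR"] < 0.07
        assert div["CODING"] < div["INTERGENIC"] < div["LTR"]
        overall = pairwise_divergence(aln)
        assert 0.008 < overall < 0.035

    def test_no_eligible_sites(self, default_sim):
        with pytest.raises(ValueError):
            pairwise_divergence(default_sim.alignment,
                                predicate=lambda p: False)


class TestBlosumCorrelation:
    def test_affine_proportions_give_r2_one(self):
        scores = np.array([BLOSUM62_DIAGONAL[a] for a in AMINO_ACIDS], float)
        props = (scores - scores.min()) / (scores.max() - scores.min())
        r2, p = blosum_identity_correlation(dict(zip(AMINO_ACIDS, props)))
        assert r2 == pytest.approx(1.0)
        assert p < 1e-12

    def test_direct_formula_oracle(self):
        """Five-point hand example with one perturbed value matches the
        product-moment formula."""
        x = np.array([1, 2, 3, 4, 5], float)
        y = np.array([2, 4, 6, 8, 11], float)
        from scipy.stats import pearsonr

        r, _ = pearsonr(x, y)
        assert r * r == pytest.approx(pearson_r2_direct(x, y))

    def test_rescaling_invariance(self):
        props = per_aa_deleterious_proportions()
        r2a, _ = blosum_identity_correlation(props)
        scaled = {a: 0.25 + 0.5 * v for a, v in props.items()}
        r2b, _ = blosum_identity_correlation(scaled)
        assert r2a == pytest.approx(r2b)

    def test_missing_amino_acid_named(self):
        props = per_aa_deleterious_proportions()
        props.pop("W")
        with pytest.raises(ValueError, match="W"):
            blosum_identity_correlation(props)


class TestDeleteriousProportion:
    def test_boundary_fits_are_fully_deleterious(self):
        assert deleterious_proportion(np.inf, 0.05) == 1.0
        for aa in ("L", "W"):
            assert PER_AA_FITS[aa].boundary
            fit = PER_AA_FITS[aa]
            assert deleterious_proportion(fit.model2_mean, fit.model2_shape) == 1.0

    def test_point_values(self):
        # nonconserved category: equal effects at 0.53, all below NeSd = 1
        assert deleterious_proportion(0.53, 100.0) < 0.01
        assert 0.8 < deleterious_proportion(158.68, 0.33) < 0.9
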