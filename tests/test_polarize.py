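import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from polardfe.polarize import (
    EXCLUDED_AMBIGUOUS, EXCLUDED_MISSING, RESOLVED, SFS,
    build_sfs, mean_da_frequency, polarize_alignment, polarize_site,
)

from conftest import make_column, make_strain_map


class TestPolarizeSite:
    @pytest.mark.parametrize("focal,og1,og2,i,anc", [
        ("A" * 10 + "G" * 2, "A" * 8, "A", 2, b"A"),   # outgroup settles
        ("G" * 12, "A" * 8, "A", 12, b"A"),             # fixed derived
        ("A" * 12, "A" * 8, "A", 0, b"A"),              # invariant
        ("G" * 12, "A" * 8, "G", 0, b"G"),              # change on outgroup1 branch
        ("A" * 6 + "G" * 6, "G" * 8, "C", 6, b"G"),     # og1 fixed for minor
    ])
    def test_resolved_ladder(self, focal, og1, og2, i, anc):
        col, smap = make_column(focal, og1, og2)
        site = polarize_site(col, smap)
        assert site.status == RESOLVED
        assert site.derived_count == i
        assert site.ancestral_nt == anc

    @pytest.mark.parametrize("focal,og1,og2,status", [
        ("A" * 11 + "N", "A" * 8, "A", EXCLUDED_MISSING),    # focal missing
        ("A" * 11 + "-", "A" * 8, "A", EXCLUDED_MISSING),    # focal gap
        ("A" * 10 + "G" * 2, "N" * 8, "A", EXCLUDED_MISSING),  # no og1 data
        ("A" * 10 + "G" * 2, "A" * 8, "-", EXCLUDED_MISSING),  # no og2 datum
        ("A" * 10 + "G" * 2, "A" * 4 + "G" * 4, "A", EXCLUDED_AMBIGUOUS),
        ("A" * 10 + "G" * 2, "C" * 8, "A", EXCLUDED_AMBIGUOUS),  # third allele
        ("A" * 12, "G" * 8, "C", EXCLUDED_AMBIGUOUS),  # og2 third allele
        ("A" * 12, "A" * 4 + "G" * 4, "A", EXCLUDED_AMBIGUOUS),  # og1 polymorphic
        ("A" * 5 + "G" * 5 + "C" * 2, "A" * 8, "A", EXCLUDED_AMBIGUOUS),
    ])
    def test_exclusion_ladder(self, focal, og1, og2, status):
        col, smap = make_column(focal, og1, og2)
        assert polarize_site(col, smap).status == status

    def test_partial_outgroup1_data_suffices(self):
        """The filter demands at least one first-outgroup strain, not all."""
        col, smap = make_column("A" * 10 + "G" * 2, "A" + "N" * 7, "A")
        site = polarize_site(col, smap)
        assert site.status == RESOLVED and site.derived_count == 2

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from("ACGT-N"), min_size=22, max_size=22),
           st.permutations("ACGT"))
    def test_nucleotide_relabeling_invariance(self, alleles, perm):
        """Permuting the nucleotide alphabet permutes ancestral/derived
        identities but preserves the derived count and status."""
        mapping = dict(zip("ACGT", perm))
        smap = make_strain_map(12, 8)
        focal, og1, og2 = "".join(alleles[:12]), "".join(alleles[12:20]), alleles[20]
        col, _ = make_column(focal, og1, og2, alleles[21], strain_map=smap)
        relab = ["".join(mapping.get(a, a) for a in s)
                 for s in (focal, og1, og2, alleles[21])]
        col2, _ = make_column(*relab, strain_map=smap)
        s1, s2 = polarize_site(col, smap), polarize_site(col2, smap)
        assert s1.status == s2.status
        assert s1.derived_count == s2.derived_count
        if s1.status == RESOLVED and s1.ancestral_nt is not None:
            assert s2.ancestral_nt == mapping[s1.ancestral_nt.decode()].encode()

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from("ACGT-N"), min_size=22, max_size=22),
           st.randoms(use_true_random=False))
    def test_strain_order_invariance(self, alleles, rnd):
        """Shuffling strains within populations changes nothing."""
        smap = make_strain_map(12, 8)
        focal = list(alleles[:12])
        og1 = list(alleles[12:20])
        col, _ = make_column("".join(focal), "".join(og1), alleles[20],
                             alleles[21], strain_map=smap)
        rnd.shuffle(focal)
        rnd.shuffle(og1)
        col2, _ = make_column("".join(focal), "".join(og1), alleles[20],
                              alleles[21], strain_map=smap)
        s1, s2 = polarize_site(col, smap), polarize_site(col2, smap)
        assert (s1.status, s1.derived_count) == (s2.status, s2.derived_count)


class TestSFS:
    def test_counts_and_mean(self):
        sfs = SFS(n=12, counts=[3] + [0] * 11 + [1])
        assert sfs.n_sites == 4
        assert mean_da_frequency(sfs) == pytest.approx(0.25)

    def test_mean_boundaries(self):
        assert mean_da_frequency(SFS(12, [0] * 12 + [5])) == 1.0
        with pytest.raises(ValueError):
            mean_da_frequency(SFS(12, [0] * 13))

    def test_build_sfs_conservation_and_partition(self, short_branch_sim):
        """Sum of category spectra equals the spectrum of the union, and
        totals count exactly the resolved sites."""
        sim = short_branch_sim
        pol = polarize_alignment(sim.alignment)
        n_resolved = sum(1 for p in pol if p.resolved)
        regions = sim.truth["region"].to_numpy()
        total = build_sfs(pol, label="all")
        assert total.n_sites == n_resolved
        parts = [build_sfs(pol, predicate=lambda p, r=r: regions[p] == r,
                           label=r)
                 for r in ("CODING", "LTR", "INTERGENIC")]
        assert np.array_equal(sum(parts[1:], parts[0]).counts, total.counts)

    def test_sfs_matches_brute_force_recount(self, short_branch_sim):
        pol = polarize_alignment(short_branch_sim.alignment)
        sfs = build_sfs(pol, label="all")
        want = np.zeros(13, dtype=int)
        for p in pol:
            if p.status == "RESOLVED":
                want[p.derived_count] += 1
        assert np.array_equal(sfs.counts, want)

    def test_mean_frequency_two_routes(self, short_branch_sim):
        """SFS-based mean equals the direct per-site average."""
        pol = polarize_alignment(short_branch_sim.alignment)
        sfs = build_sfs(pol, label="all")
        direct = np.mean([p.derived_count / p.n for p in pol if p.resolved])
        assert mean_da_frequency(sfs) == pytest.approx(direct)


class TestPolarizerAccuracy:
    def test_short_branch_truth_recovery(self, short_branch_sim):
        """Resolved derived counts match the generator truth at >= 99% of
        sites when outgroup branches are short (homoplasy-free regime)."""
        sim = short_branch_sim
        pol = polarize_alignment(sim.alignment)
        truth = sim.truth["derived_count"].to_numpy()
        resolved = [(p.derived_count, truth[p.position])
                    for p in pol if p.resolved]
        agree = np.mean([a == b for a, b in resolved])
        assert len(resolved) > 5000
        assert agree >= 0.99

    def test_bulk_agrees_with_per_site(self, default_sim):
        aln = default_sim.alignment
        bulk = polarize_alignment(aln)
        for pos in range(0, aln.length, 997):
            single = polarize_site(aln.column(pos), aln.strain_map)
            assert (single.status, single.derived_count) == \
                   (bulk[pos].status, bulk[pos].derived_count)
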