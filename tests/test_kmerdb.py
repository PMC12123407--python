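"""Database construction: filter cascade, invariants, brute-force oracle."""

from collections import Counter

import pytest

from kivcn.kmerdb import (
    DatabaseBuildError,
    KmerDatabase,
    build_database,
    exclude_background,
    extract_region_kmers,
    filter_by_multiplicity,
    remove_shared,
)
from kivcn.regions import GenomicRegion

from oracle import brute_build, window_tally


def region(chrom, start, end, label="repeat"):
    return GenomicRegion(chrom, start, end, label)


class TestExtractRegionKmers:
    def test_small_example_by_hand(self):
        ref = {"c": "ACGTACGTAC"}
        got = extract_region_kmers(ref, [region("c", 0, 10)], 4)
        assert got == Counter({"ACGT": 2, "CGTA": 3, "GTAC": 2})

    def test_k_larger_than_region_is_empty(self):
        ref = {"c": "ACGTACGTAC"}
        assert extract_region_kmers(ref, [region("c", 0, 5)], 8) == Counter()

    def test_ambiguous_run_contributes_nothing(self):
        ref = {"c": "ACGTNNNNACGT"}
        got = extract_region_kmers(ref, [region("c", 4, 8)], 4)
        assert got == Counter()

    def test_out_of_bounds_region_names_it(self):
        ref = {"c": "ACGTACGT"}
        with pytest.raises(ValueError, match="c:0-99"):
            extract_region_kmers(ref, [region("c", 0, 99)], 4)

    def test_counts_sum_over_regions_and_match_oracle(self):
        ref = {"c": "ACGTACGTACGTTTTGGGACGT"}
        regions = [region("c", 0, 12), region("c", 8, 22)]
        got = extract_region_kmers(ref, regions, 5)
        expected = window_tally(ref["c"][0:12], 5) + window_tally(ref["c"][8:22], 5)
        assert got == expected


class TestMultiplicityFilter:
    def test_strict_equality(self):
        counts = {"AAAA": 6, "CCCC": 5, "GGGG": 6, "TTTT": 7}
        assert filter_by_multiplicity(counts, 6) == {"AAAA", "GGGG"}

    def test_empty_input(self):
        assert filter_by_multiplicity({}, 3) == set()

    def test_tandem_repeat_retained_kmers_recount_to_expected(self):
        # 6 identical copies of a 50 bp unit; every retained k-mer must
        # re-count to exactly 6 under a brute-force rescan
        import numpy as np

        rng = np.random.default_rng(5)
        unit = "".join(rng.choice(list("ACGT"), size=50))
        array = unit * 6
        counts = extract_region_kmers({"c": array}, [region("c", 0, len(array))], 11)
        kept = filter_by_multiplicity(counts, 6)
        assert kept
        rescan = window_tally(array, 11)
        assert all(rescan[km] == 6 for km in kept)


class TestExcludeBackground:
    def test_flanking_occurrence_removes_kmer(self):
        # kmer ACGTA occurs in the region and once in the right flank
        ref = {"c": "ACGTAGGGGGGACGTA"}
        regions = [region("c", 0, 5)]
        kept = exclude_background({"ACGTA"}, ref, regions, 5)
        assert kept == set()

    def test_kmer_absent_outside_is_retained(self):
        ref = {"c": "ACGTAGGGGGG"}
        kept = exclude_background({"ACGTA"}, ref, [region("c", 0, 5)], 5)
        assert kept == {"ACGTA"}

    def test_decoy_contig_removes_exactly_its_kmers(self):
        import numpy as np

        rng = np.random.default_rng(11)
        locus = "".join(rng.choice(list("ACGT"), size=200))
        regions = [region("locus", 0, 200)]
        counts = extract_region_kmers({"locus": locus}, regions, 13)
        kmers = set(counts)
        # decoy contig carries 3 of the locus k-mers (verified by brute scan)
        chosen = sorted(kmers)[:3]
        decoy = "T".join(chosen)
        ref = {"locus": locus, "decoy": decoy}
        kept = exclude_background(kmers, ref, regions, 13)
        removed = kmers - kept
        decoy_hits = {km for km in kmers if window_tally(decoy, 13).get(km, 0) > 0}
        assert removed == decoy_hits
        assert set(chosen) <= removed


class TestRemoveShared:
    @pytest.mark.parametrize(
        "a,b,expect_a,expect_b",
        [
            ({"x", "y"}, {"y", "z"}, {"x"}, {"z"}),
            ({"x"}, {"z"}, {"x"}, {"z"}),  # disjoint -> unchanged
            ({"x"}, {"x"}, set(), set()),  # degenerate
        ],
    )
    def test_intersection_removed(self, a, b, expect_a, expect_b):
        out_a, out_b = remove_shared(a, b)
        assert (out_a, out_b) == (expect_a, expect_b)
        assert not out_a & out_b


def toy_reference(rng, duplicate_norm_in_flank=False):
    """6x tandem copies of a 60 bp unit + 600 bp norm + unrelated flank."""
    unit = "".join(rng.choice(list("ACGT"), size=60))
    norm = "".join(rng.choice(list("ACGT"), size=600))
    # duplicating the whole norm region in the flank voids its specificity
    flank = norm if duplicate_norm_in_flank else "".join(
        rng.choice(list("ACGT"), size=300)
    )
    seq = unit * 6 + norm + flank
    rep = region("c", 0, 360, "repeat")
    nrm = region("c", 360, 960, "normalization")
    return {"c": seq}, [rep], [nrm]


class TestBuildDatabase:
    def test_matches_brute_force_pipeline(self):
        import numpy as np

        ref, rep, nrm = toy_reference(np.random.default_rng(3))
        db = build_database(ref, rep, nrm, k=15)
        expected = brute_build(ref, rep, nrm, 15)
        assert set(db.repeat_kmers) == expected["repeat"]
        assert set(db.norm_kmers) == expected["norm"]
        assert not db.repeat_kmers & db.norm_kmers

    def test_specificity_invariant_on_small_locus(self, small_template, small_db):
        """Every retained k-mer recounts to exactly its multiplicity, all
        inside its declared regions, across the whole reference."""
        ref = small_template.reference
        genome = window_tally(next(iter(ref.values())), small_db.k)
        rep_region = small_template.repeat_regions[0]
        seq = ref[rep_region.chrom]
        in_repeat = window_tally(seq[rep_region.start : rep_region.end], small_db.k)
        for km in sorted(small_db.repeat_kmers)[:200]:
            assert genome[km] == small_db.repeat_multiplicity
            assert in_repeat[km] == small_db.repeat_multiplicity
        nr = small_template.norm_regions[0]
        in_norm = window_tally(seq[nr.start : nr.end], small_db.k)
        for km in sorted(small_db.norm_kmers)[:200]:
            assert genome[km] == small_db.norm_multiplicity
            assert in_norm[km] == small_db.norm_multiplicity

    def test_duplicated_norm_region_is_hard_error(self):
        import numpy as np

        ref, rep, nrm = toy_reference(np.random.default_rng(3), True)
        with pytest.raises(DatabaseBuildError, match="stage"):
            build_database(ref, rep, nrm, k=15)

    def test_save_load_roundtrip_and_deterministic_output(self, tmp_path):
        import numpy as np

        ref, rep, nrm = toy_reference(np.random.default_rng(9))
        d1, d2 = tmp_path / "a", tmp_path / "b"
        db = build_database(ref, rep, nrm, k=15, outdir=d1)
        build_database(ref, rep, nrm, k=15, outdir=d2)
        for name in ("repeat_kmers.fasta", "repeat_kmers.tsv",
                     "norm_kmers.fasta", "norm_kmers.tsv"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()
        loaded = KmerDatabase.load(d1)
        assert loaded.k == db.k
        assert loaded.repeat_kmers == db.repeat_kmers
        assert loaded.norm_kmers == db.norm_kmers

    def test_database_invariant_enforced_on_construction(self):
        with pytest.raises(ValueError, match="shared"):
            KmerDatabase(k=4, repeat_kmers=frozenset({"ACGT"}),
                         norm_kmers=frozenset({"ACGT"}))
        with pytest.raises(ValueError, match="canonical"):
            # TTTT is the reverse complement of AAAA, hence non-canonical
            KmerDatabase(k=4, repeat_kmers=frozenset({"TTTT"}),
                         norm_kmers=frozenset({"CCGG"}))
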