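"""Unit and property tests for isomiR alignment, classification and calling."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isomirkit import catalog, synthetic
from isomirkit._seq import normalize_rna, revcomp_rna

from conftest import MIR140_3P1, MIR140_3P2

rna = st.text(alphabet="ACGU", min_size=8, max_size=30)


class TestSeqHelpers:
    def test_normalize_converts_dna_and_uppercases(self):
        assert normalize_rna("acgt") == "ACGU"

    def test_normalize_rejects_non_nucleotides(self):
        with pytest.raises(ValueError):
            normalize_rna("ACGN")

    @given(rna)
    @settings(max_examples=50, deadline=None)
    def test_revcomp_is_an_involution(self, seq):
        assert revcomp_rna(revcomp_rna(seq)) == seq


class TestExtractSeed:
    @pytest.mark.parametrize(
        "sequence, seed",
        [
            (MIR140_3P1, "CCACAGG"),
            (MIR140_3P2, "ACCACAG"),
            ("ACCACAGGGTAGAACCACGGAC", "CCACAGG"),  # DNA input normalised
            ("AUGCAUGC", "UGCAUGC"),
        ],
    )
    def test_seed_is_positions_2_to_8(self, sequence, seed):
        assert catalog.extract_seed(sequence) == seed

    def test_short_sequence_is_an_error(self):
        with pytest.raises(ValueError):
            catalog.extract_seed("ACGUACG")

    def test_the_two_registers_have_distinct_seeds(self):
        assert catalog.extract_seed(MIR140_3P1) != catalog.extract_seed(MIR140_3P2)


class TestAlignRead:
    def test_identity_read_aligns_canonically(self, mir140_context):
        ctx, ref, ms = mir140_context
        aln = catalog.align_read(ref.sequence, ref, ctx, ms)
        assert (aln.five_prime_offset, aln.three_prime_offset, aln.nontemplated_tail) == (0, 0, "")

    def test_shifted_register_gets_minus_one_offset(self, mir140_context):
        """The -1-shifted seed register (one nt downstream, one templated nt
        longer at the 3' end) is the relationship between the two miR-140-3p
        isomiRs."""
        ctx, ref, ms = mir140_context
        aln = catalog.align_read(MIR140_3P1, ref, ctx, ms)
        assert aln.five_prime_offset == -1
        assert aln.three_prime_offset == 1
        assert aln.nontemplated_tail == ""

    def test_nontemplated_tail_is_minimal_suffix(self, locus_refs):
        """A 3' addition that does not match the genomic continuation is a
        tail; one that does is consumed as a templated extension first
        (checked against a brute-force longest-extension oracle)."""
        ref, hairpins = locus_refs
        hp = hairpins[ref.hairpin_name]
        ctx = hp.context
        me = ref.start + len(ref.sequence)
        next_base = ctx[me]
        other = next(b for b in "ACGU" if b != next_base)

        aln = catalog.align_read(ref.sequence + other, ref, ctx, ref.start)
        assert (aln.three_prime_offset, aln.nontemplated_tail) == (0, other)

        aln2 = catalog.align_read(ref.sequence + next_base, ref, ctx, ref.start)
        assert (aln2.three_prime_offset, aln2.nontemplated_tail) == (1, "")

        # oracle: longest l such that the extension matches the genome
        ext = next_base + other
        l = 0
        while l < len(ext) and ctx[me + l] == ext[l]:
            l += 1
        aln3 = catalog.align_read(ref.sequence + ext, ref, ctx, ref.start)
        assert aln3.three_prime_offset == l
        assert aln3.nontemplated_tail == ext[l:]

    def test_unanchorable_read_is_rejected_not_raised(self, locus_refs):
        ref, hairpins = locus_refs
        hp = hairpins[ref.hairpin_name]
        junk = "ACGU" * 6  # periodic, will not match the random hairpin
        assert catalog.align_read(junk, ref, hp.context, ref.start) is None


class TestClassify:
    @pytest.mark.parametrize(
        "five, three, tail, category, templated",
        [
            (0, 0, "", "canonical", True),
            (0, 2, "", "3prime_only", True),
            (0, 0, "A", "3prime_only", False),
            (2, 0, "", "5prime_only", True),
            (-1, 1, "A", "mixed", False),
            (-1, 1, "", "mixed", True),
        ],
    )
    def test_category_follows_offsets_and_tail(self, five, three, tail, category, templated):
        got = catalog.classify_isomir(catalog.Alignment(five, three, tail))
        assert got == (category, templated)


def _record(seq="A" * 22, count=10, offset=0, ref="m"):
    return catalog.IsomiRRecord(
        sequence=seq, count=count, ref=ref,
        five_prime_offset=offset, three_prime_offset=0, nontemplated_tail="",
        templated=True, seed=seq[1:8], category="canonical" if offset == 0 else "5prime_only",
    )


class TestFivePrimeCalls:
    def test_thresholds_are_strict(self):
        """Boundary records (count exactly 100, fraction exactly 0.05) and a
        99-count record never pass; a clear case does."""
        # fractions are computed against the arm total
        records = [
            _record("A" * 22, count=700, offset=0),
            _record("C" + "A" * 21, count=100, offset=1),   # count boundary
            _record("G" + "A" * 21, count=99, offset=-4),   # just under threshold
            _record("U" + "A" * 21, count=101, offset=-1),  # fraction 101/2000 > 0.05? no
            _record("AG" + "A" * 20, count=1000, offset=-1),
        ]
        total = sum(r.count for r in records)
        calls = {c.sequence: c for c in catalog.call_5p_isomirs(records)}
        assert not calls["A" * 22].passes                  # offset 0
        assert not calls["C" + "A" * 21].passes            # count == 100
        assert not calls["G" + "A" * 21].passes            # count 99
        assert calls["AG" + "A" * 20].passes               # 1000 reads, 50%
        assert calls["AG" + "A" * 20].fraction == 1000 / total

    def test_fraction_boundary_fails(self):
        records = [
            _record("A" * 22, count=1900, offset=0),
            _record("C" + "A" * 21, count=200, offset=-1),  # fraction per arm: 200/4000
            _record("G" + "A" * 21, count=1900, offset=2),
        ]
        calls = {c.sequence: c for c in catalog.call_5p_isomirs(records)}
        assert calls["C" + "A" * 21].fraction == pytest.approx(0.05)
        assert not calls["C" + "A" * 21].passes

    def test_canonical_only_denominator_switch(self):
        records = [
            _record("A" * 22, count=1000, offset=0),
            _record("C" + "A" * 21, count=200, offset=-1),
        ]
        arm = {c.sequence: c for c in catalog.call_5p_isomirs(records)}
        canon = {
            c.sequence: c
            for c in catalog.call_5p_isomirs(records, fraction_denominator="canonical_only")
        }
        assert arm["C" + "A" * 21].fraction == pytest.approx(200 / 1200)
        assert canon["C" + "A" * 21].fraction == pytest.approx(200 / 1000)

    def test_empty_catalog_gives_empty_calls(self):
        assert catalog.call_5p_isomirs([]) == []


class TestSeedGroups:
    def test_mir140_registers_form_two_groups(self, mir140_context):
        ctx, ref, ms = mir140_context
        records = []
        for seq, count in ((MIR140_3P1, 600), (MIR140_3P2, 400)):
            aln = catalog.align_read(seq, ref, ctx, ms)
            cat, templ = catalog.classify_isomir(aln)
            records.append(
                catalog.IsomiRRecord(
                    sequence=seq, count=count, ref=ref.name,
                    five_prime_offset=aln.five_prime_offset,
                    three_prime_offset=aln.three_prime_offset,
                    nontemplated_tail=aln.nontemplated_tail,
                    templated=templ, seed=catalog.extract_seed(seq), category=cat,
                )
            )
        groups = catalog.group_by_seed(records)
        assert [g.seed for g in groups] == ["CCACAGG", "ACCACAG"]
        assert [g.suffix_name for g in groups] == [".1", ".2"]
        assert sum(g.total_count for g in groups) == 1000
        assert sum(g.fraction_of_mirna for g in groups) == pytest.approx(1.0)
        # the two registers' 5' offsets differ by exactly one nucleotide
        offs = [g.members[0].five_prime_offset for g in groups]
        assert offs[0] - offs[1] == -1

    def test_identical_seeds_merge(self):
        records = [_record("A" * 22, 5), _record("A" * 21 + "C", 7)]
        groups = catalog.group_by_seed(records)
        assert len(groups) == 1
        assert groups[0].total_count == 12
        assert groups[0].representative == "A" * 21 + "C"

    def test_empty_input(self):
        assert catalog.group_by_seed([]) == []

    def test_name_override_reassigns_suffix(self):
        records = [_record("A" * 22, 5), _record("CG" + "A" * 20, 7, offset=-1)]
        groups = catalog.group_by_seed(
            records, name_overrides={records[0].seed: ".2"}
        )
        by_seed = {g.seed: g.suffix_name for g in groups}
        assert by_seed[records[0].seed] == ".2"


class TestTailComposition:
    def test_counts_weighted_by_reads(self):
        recs = [
            catalog.IsomiRRecord("A" * 22, 2, "m", 0, 0, "A", False, "A" * 7, "3prime_only"),
            catalog.IsomiRRecord("C" + "A" * 21, 1, "m", 0, 0, "U", False, "A" * 7, "3prime_only"),
        ]
        assert catalog.tail_composition(recs) == {"A": 2, "C": 0, "G": 0, "U": 1}

    def test_all_templated_gives_zeros(self):
        assert catalog.tail_composition([_record()]) == {"A": 0, "C": 0, "G": 0, "U": 0}

    def test_tail_a_rate_recovered_from_pool(self, locus, locus_refs):
        """Reads gaining an extra nontemplated A at rate 0.3 are recovered
        within 3 binomial standard errors."""
        ref, hairpins = locus_refs
        spec = synthetic.ReadCompositionSpec(
            entries=[synthetic.IsomiRComposition(0, 0, "C", 1.0)],
            total_depth=100_000,
            tail_A_rate=0.3,
        )
        pool, _ = synthetic.gen_read_pool(locus, spec, rng_seed=11)
        records, rejects = catalog.build_catalog(
            pool.itertuples(index=False), [ref], hairpins
        )
        assert not rejects
        total = sum(r.count for r in records)
        with_a = sum(r.count for r in records if r.nontemplated_tail.endswith("A"))
        se = (0.3 * 0.7 / total) ** 0.5
        assert abs(with_a / total - 0.3) < 3 * se


class TestRoundTrip:
    def test_noiseless_pool_is_fully_recovered(self, locus, locus_refs):
        """Every read in a synthetic pool gets back its true offsets, tail,
        templated flag and category."""
        import pandas as pd

        ref, hairpins = locus_refs
        pool, truth = synthetic.gen_read_pool(
            locus, synthetic.default_read_composition(50_000), rng_seed=3
        )
        records, rejects = catalog.build_catalog(
            pool.itertuples(index=False), [ref], hairpins
        )
        assert not rejects
        got = (
            pd.DataFrame(
                {
                    "sequence": [r.sequence for r in records],
                    "five_prime_offset": [r.five_prime_offset for r in records],
                    "three_prime_offset": [r.three_prime_offset for r in records],
                    "nontemplated_tail": [r.nontemplated_tail for r in records],
                    "templated": [r.templated for r in records],
                    "category": [r.category for r in records],
                }
            )
            .sort_values("sequence")
            .reset_index(drop=True)
        )
        want = (
            truth[got.columns].sort_values("sequence").reset_index(drop=True)
        )
        pd.testing.assert_frame_equal(got, want)

    def test_category_fractions_sum_to_one(self, locus, locus_refs):
        ref, hairpins = locus_refs
        pool, _ = synthetic.gen_read_pool(
            locus, synthetic.default_read_composition(20_000), rng_seed=5
        )
        records, _ = catalog.build_catalog(pool.itertuples(index=False), [ref], hairpins)
        total = sum(r.count for r in records)
        by_cat = {}
        for r in records:
            by_cat[r.category] = by_cat.get(r.category, 0) + r.count
        assert sum(by_cat.values()) == total == 20_000
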