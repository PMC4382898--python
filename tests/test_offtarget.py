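"""Mismatch/gap-tolerant search against the windowed DP oracle."""
import numpy as np
import pytest

from conftest import random_dna, random_protospacer
from oracles import dp_oracle_ends

from crisprdesign import (
    AlignmentBudget,
    DesignParams,
    GenomeCollection,
    NucleotideSequence,
    PlantSpec,
    count_consistency_check,
    make_synthetic_genome,
    offtargets_to_bed,
    offtargets_to_tsv,
    reverse_complement,
    search_approximate,
)
from crisprdesign.offtarget import _scan_ends


def _genome_from(seq, rid="g"):
    return GenomeCollection(records=(NucleotideSequence(rid, seq),))


def _embed(rng, background_len, *sites):
    """Plant site strings at well-separated positions in random background."""
    bg = list(random_dna(rng, background_len))
    gap = background_len // (len(sites) + 1)
    positions = []
    for i, site in enumerate(sites, start=1):
        pos = i * gap
        bg[pos : pos + len(site)] = list(site)
        positions.append(pos)
    return "".join(bg), positions


class TestExamples:
    def test_exact_planting_is_a_perfect_hit(self, rng):
        proto = random_protospacer(rng)
        seq, (pos,) = _embed(rng, 3000, proto + "AGG")
        hits = search_approximate(
            proto, _genome_from(seq), AlignmentBudget(0, 0)
        )
        plus = [h for h in hits if h.strand == "+"]
        assert len(plus) == 1
        (h,) = plus
        assert (h.start, h.end) == (pos + 1, pos + 20)
        assert h.n_mismatch == 0 and h.n_gap == 0
        assert h.marker_line == "|" * 20
        assert h.pam_at_site == "AGG" and h.pam_ok

    def test_single_substitution_marks_x_at_the_edit(self, rng):
        proto = random_protospacer(rng)
        sub = "A" if proto[11] != "A" else "C"
        variant = proto[:11] + sub + proto[12:]
        seq, (pos,) = _embed(rng, 3000, variant + "TGG")
        hits = [
            h
            for h in search_approximate(
                proto, _genome_from(seq), AlignmentBudget(1, 0)
            )
            if h.strand == "+" and h.start == pos + 1
        ]
        (h,) = hits
        assert h.n_mismatch == 1 and h.n_gap == 0
        assert h.marker_line[11] == "X"
        assert h.marker_line.count("X") == 1

    def test_deleted_base_appears_as_subject_gap(self, rng):
        proto = random_protospacer(rng)
        deleted = proto[:10] + proto[11:]  # one base missing
        seq, (pos,) = _embed(rng, 3000, deleted + "CGG")
        hits = [
            h
            for h in search_approximate(
                proto, _genome_from(seq), AlignmentBudget(0, 1)
            )
            if h.strand == "+" and abs(h.start - (pos + 1)) <= 1
        ]
        assert hits, "deletion variant should be found with one gap"
        h = hits[0]
        assert h.n_gap == 1 and h.n_mismatch == 0
        assert "-" in h.aligned_subject
        assert h.aligned_query.replace("-", "") == proto

    def test_wrong_query_length_is_an_error(self, rng):
        with pytest.raises(ValueError, match="length"):
            search_approximate(
                "ACGT", _genome_from(random_dna(rng, 100)), AlignmentBudget()
            )

    def test_empty_genome_yields_no_hits(self, rng):
        empty = GenomeCollection(records=())
        assert search_approximate(
            random_protospacer(rng), empty, AlignmentBudget()
        ) == []


class TestOracleEquivalence:
    @pytest.mark.parametrize("budget", [(0, 0), (1, 0), (2, 1), (3, 1)])
    def test_per_end_agreement_on_planted_genome(self, rng, budget):
        """Every feasible end position and its (gaps, mismatches) must match
        the exhaustive windowed DP oracle, on both strands."""
        mm, gaps = budget
        proto = random_protospacer(rng)
        sub = "G" if proto[4] != "G" else "T"
        variant = proto[:4] + sub + proto[5:]
        ins = proto[:7] + "A" + proto[7:]
        seq, _ = _embed(rng, 2500, proto + "AGG", variant + "TGG", ins + "AGG")
        qa = np.frombuffer(proto.encode(), dtype=np.uint8)
        for strand_seq in (seq, reverse_complement(seq)):
            sa = np.frombuffer(strand_seq.encode(), dtype=np.uint8)
            impl = {
                j: (g, m)
                for j, g, m in _scan_ends(
                    qa, sa, AlignmentBudget(mm, gaps)
                )
            }
            oracle = dp_oracle_ends(proto, strand_seq, mm, gaps)
            assert impl == oracle

    def test_reported_hits_are_a_subset_of_feasible_ends(self, rng):
        proto = random_protospacer(rng)
        seq = random_dna(rng, 4000)
        budget = AlignmentBudget(3, 1)
        hits = search_approximate(proto, _genome_from(seq), budget)
        for h in hits:
            strand_seq = seq if h.strand == "+" else reverse_complement(seq)
            end_local = h.end if h.strand == "+" else len(seq) - h.start + 1
            best = dp_oracle_ends(
                proto,
                strand_seq[max(0, end_local - 25) : end_local],
                3,
                1,
            )
            assert best, h


class TestProperties:
    def test_budget_monotonicity(self, rng):
        """Growing either budget component never loses a reported locus
        (up to the 50%-overlap collapse of nearby alignments)."""
        proto = random_protospacer(rng)
        sub = "C" if proto[2] != "C" else "A"
        seq, _ = _embed(
            rng, 3000, proto + "AGG", proto[:2] + sub + proto[3:] + "GGG"
        )
        genome = _genome_from(seq)
        budgets = [(0, 0), (1, 0), (2, 0), (3, 0), (3, 1)]
        prev = None
        for mm, gaps in budgets:
            hits = search_approximate(proto, genome, AlignmentBudget(mm, gaps))
            if prev is not None:
                for ph in prev:
                    assert any(
                        h.strand == ph.strand
                        and min(h.end, ph.end) - max(h.start, ph.start) + 1
                        >= 0.5 * (min(h.end - h.start, ph.end - ph.start) + 1)
                        for h in hits
                    ), (mm, gaps, ph)
            prev = hits

    def test_strand_symmetry_under_genome_reverse_complement(self, rng):
        proto = random_protospacer(rng)
        sub = "T" if proto[9] != "T" else "G"
        seq, _ = _embed(rng, 3000, proto + "AGG", proto[:9] + sub + proto[10:] + "CGG")
        budget = AlignmentBudget(2, 1)
        fwd = search_approximate(proto, _genome_from(seq), budget)
        rev = search_approximate(
            proto, _genome_from(reverse_complement(seq)), budget
        )
        L = len(seq)
        mirrored = sorted(
            (L - h.end + 1, L - h.start + 1, "-" if h.strand == "+" else "+",
             h.n_mismatch, h.n_gap)
            for h in rev
        )
        assert mirrored == sorted(
            (h.start, h.end, h.strand, h.n_mismatch, h.n_gap) for h in fwd
        )

    def test_gap_stripped_query_reproduces_input(self, rng):
        proto = random_protospacer(rng)
        seq = random_dna(rng, 5000)
        for h in search_approximate(proto, _genome_from(seq), AlignmentBudget(3, 1)):
            assert h.aligned_query.replace("-", "") == proto
            assert len(h.aligned_query) == len(h.aligned_subject)
            assert len(h.marker_line) == len(h.aligned_query)
            assert h.n_mismatch == h.marker_line.count("X")
            assert h.n_gap == h.marker_line.count(" ")

    def test_require_pam_filters_non_pam_sites(self, rng):
        proto = random_protospacer(rng)
        seq, _ = _embed(rng, 3000, proto + "AGG", proto + "ATT")
        genome = _genome_from(seq)
        free = search_approximate(proto, genome, AlignmentBudget(0, 0))
        gated = search_approximate(
            proto, genome, AlignmentBudget(0, 0, require_pam=True)
        )
        assert len(gated) < len(free)
        assert all(h.pam_ok for h in gated)


class TestConsistencyAndExport:
    def test_zero_budget_search_equals_exact_count(self, planted_fixture):
        proto, _, genome, _ = planted_fixture
        assert count_consistency_check(proto, genome, DesignParams())

    def test_absent_target_consistency(self, rng):
        genome = _genome_from(random_dna(rng, 2000))
        assert count_consistency_check(
            random_protospacer(rng), genome, DesignParams()
        )

    def test_many_planted_copies_consistency(self, rng):
        proto = random_protospacer(rng)
        spec = PlantSpec(protospacer=proto, pam="AGG", copies_full=4)
        genome, _ = make_synthetic_genome(8000, [spec], seed=31)
        assert count_consistency_check(proto, genome, DesignParams())

    def test_tsv_and_bed_exports(self, rng):
        proto = random_protospacer(rng)
        seq, _ = _embed(rng, 2000, proto + "AGG")
        hits = search_approximate(proto, _genome_from(seq), AlignmentBudget(1, 0))
        tsv = offtargets_to_tsv(hits)
        lines = tsv.strip().split("\n")
        assert lines[0].startswith("record\tstart")
        assert len(lines) == len(hits) + 1
        assert all(len(l.split("\t")) == 11 for l in lines)
        bed = offtargets_to_bed(hits)
        for h, line in zip(hits, bed.strip().split("\n")):
            chrom, start, end, _name, _score, strand = line.split("\t")
            assert int(start) == h.start - 1 and int(end) == h.end
            assert strand == h.strand
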