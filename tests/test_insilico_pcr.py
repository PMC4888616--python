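import numpy as np
import pytest

from conftest import random_sequence
from oracles import primer_sites_fullscan, rc
from unilocus.insilico_pcr import (EPCRParams, classify_copy_number,
                                   develop_markers, epcr_amplimers,
                                   find_primer_sites)
from unilocus.primer_design import PrimerPair
from unilocus.seqio import SequenceRecord


def make_pair(left, right, expected):
    return PrimerPair(left=left, right=right, left_tm=60, right_tm=60,
                      left_gc=50, right_gc=50, expected_product=expected,
                      left_start=0, right_end=0)


def sites_key(sites):
    return {(s.three_prime_end, s.mismatches, s.gaps) for s in sites}


class TestFindPrimerSites:
    PRIMER = "ACGGTTCAGCATGACCGTAT"   # 20-mer, unique-ish

    def test_planted_primer_found_once_exact(self, rng, make_record):
        seq = random_sequence(rng, 3000)
        pos = 1200
        seq = seq[:pos] + self.PRIMER + seq[pos + 20:]
        sites = find_primer_sites(self.PRIMER, make_record(seq))
        exact = [s for s in sites if s.mismatches == 0 and s.gaps == 0]
        assert len(exact) == 1
        assert exact[0].three_prime_end == pos + 20
        assert exact[0].start == pos + 1

    def test_three_substitutions_exceed_budget(self, rng, make_record):
        seq = random_sequence(rng, 1000)
        mutated = "TGTCTTCTGC" + self.PRIMER[10:]   # 3+ subs in 5' half
        assert sum(a != b for a, b in zip(mutated, self.PRIMER)) >= 3
        seq = seq[:400] + mutated + seq[420:]
        assert find_primer_sites(self.PRIMER, make_record(seq)) == []

    def test_two_substitutions_within_budget(self, rng, make_record):
        seq = random_sequence(rng, 1000)
        mutated = "GG" + self.PRIMER[2:]
        assert sum(a != b for a, b in zip(mutated, self.PRIMER)) == 2
        seq = seq[:400] + mutated + seq[420:]
        sites = find_primer_sites(self.PRIMER, make_record(seq))
        # the planted site is recovered within the 2-mismatch budget
        # (a 1-gap alignment may report an even lower mismatch count)
        assert any(s.three_prime_end == 420 and s.mismatches <= 2
                   for s in sites)

    def test_seed_region_mismatch_abolishes_site(self, rng, make_record):
        seq = random_sequence(rng, 1000)
        mutated = self.PRIMER[:-1] + ("A" if self.PRIMER[-1] != "A" else "C")
        seq = seq[:400] + mutated + seq[420:]
        assert all(s.three_prime_end != 420
                   for s in find_primer_sites(self.PRIMER, make_record(seq)))

    def test_single_gap_tolerated(self, rng, make_record):
        seq = random_sequence(rng, 1000)
        gapped = self.PRIMER[:5] + self.PRIMER[6:]   # one primer base deleted
        seq = seq[:400] + gapped + seq[400 + len(gapped):]
        sites = find_primer_sites(self.PRIMER, make_record(seq))
        assert any(s.gaps == 1 for s in sites)

    def test_minus_strand_maps_coordinates(self, rng, make_record):
        seq = random_sequence(rng, 800)
        pos = 300
        seq = seq[:pos] + rc(self.PRIMER) + seq[pos + 20:]
        sites = find_primer_sites(self.PRIMER, make_record(seq), strand="-")
        exact = [s for s in sites if s.mismatches == 0]
        assert len(exact) == 1
        assert exact[0].three_prime_end == pos + 1   # 3' end points left
        assert exact[0].end == pos + 20

    def test_primer_shorter_than_seed_rejected(self, make_record):
        with pytest.raises(ValueError):
            find_primer_sites("ACGTACGT", make_record("ACGT" * 50))

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_fullscan_dp_oracle(self, seed, make_record):
        """Seeded search equals an exhaustive every-position DP scan,
        including mutated/gapped planted copies."""
        rng = np.random.default_rng(seed)
        seq = random_sequence(rng, 2000)
        primer = random_sequence(rng, 22, gc=0.5)
        # plant exact, substituted and gapped copies
        copies = [primer,
                  "T" + primer[1:],
                  primer[:4] + primer[5:],               # deletion
                  primer[:7] + "A" + primer[7:],          # insertion
                  rc(primer)]
        pos = 100
        for cpy in copies:
            seq = seq[:pos] + cpy + seq[pos + len(cpy):]
            pos += 300
        rec = make_record(seq)
        params = EPCRParams()
        for strand in "+-":
            got = sites_key(find_primer_sites(primer, rec, params, strand))
            if strand == "+":
                want = primer_sites_fullscan(primer, seq, params.seed_word,
                                             params.max_mismatch_per_primer,
                                             params.max_gaps_per_primer)
            else:
                n = len(seq)
                want = {(n - t + 1, mm, g) for t, mm, g in
                        primer_sites_fullscan(primer, rc(seq),
                                              params.seed_word,
                                              params.max_mismatch_per_primer,
                                              params.max_gaps_per_primer)}
            assert got == want


class TestEpcrAmplimers:
    LEFT = "ACGGTTCAGCATGACCGTAT"
    RIGHT = "TGACCAGTTGCACTGCAGTA"

    def _template(self, rng, spacer_len):
        inner = random_sequence(rng, spacer_len - 40)
        return self.LEFT + inner + rc(self.RIGHT)

    def test_exact_pair_single_hit_with_expected_product(self, rng,
                                                         make_record):
        amplicon = self._template(rng, 200)
        seq = random_sequence(rng, 500) + amplicon + random_sequence(rng, 500)
        pair = make_pair(self.LEFT, self.RIGHT, 200)
        hits = epcr_amplimers(pair, [make_record(seq)],
                              expected_product=200)
        assert len(hits) == 1
        assert hits[0].product_length == 200
        assert hits[0].orientation == "plus"
        assert hits[0].start == 501 and hits[0].end == 700

    def test_duplicated_amplicon_two_hits(self, rng, make_record):
        amplicon = self._template(rng, 180)
        seq = (random_sequence(rng, 300) + amplicon +
               random_sequence(rng, 300) + amplicon +
               random_sequence(rng, 300))
        pair = make_pair(self.LEFT, self.RIGHT, 180)
        hits = epcr_amplimers(pair, [make_record(seq)], expected_product=180)
        assert len(hits) == 2

    def test_product_outside_margin_rejected(self, rng, make_record):
        amplicon = self._template(rng, 260)
        seq = random_sequence(rng, 300) + amplicon + random_sequence(rng, 300)
        pair = make_pair(self.LEFT, self.RIGHT, 180)
        # margin 50: 260 > 180 + 50 -> no hit
        assert epcr_amplimers(pair, [make_record(seq)],
                              expected_product=180) == []
        # without an expected size the absolute bounds still admit it
        assert len(epcr_amplimers(pair, [make_record(seq)])) == 1

    def test_minus_orientation_found_on_revcomp(self, rng, make_record):
        amplicon = self._template(rng, 200)
        seq = random_sequence(rng, 400) + rc(amplicon) + random_sequence(rng, 400)
        pair = make_pair(self.LEFT, self.RIGHT, 200)
        hits = epcr_amplimers(pair, [make_record(seq)], expected_product=200)
        assert len(hits) == 1 and hits[0].orientation == "minus"


class TestClassifyCopyNumber:
    def test_verdicts(self, rng, make_record):
        amplicon = ("ACGGTTCAGCATGACCGTAT" + random_sequence(rng, 100) +
                    rc("TGACCAGTTGCACTGCAGTA"))
        hit_seq = random_sequence(rng, 200) + amplicon + random_sequence(rng, 200)
        pair = make_pair("ACGGTTCAGCATGACCGTAT", "TGACCAGTTGCACTGCAGTA", 140)
        hits1 = epcr_amplimers(pair, [make_record(hit_seq)],
                               expected_product=140)
        hits2 = epcr_amplimers(pair, [make_record(hit_seq + amplicon)],
                               expected_product=140)
        assert classify_copy_number([]).verdict == "none"
        assert classify_copy_number(hits1).verdict == "single_locus"
        assert classify_copy_number(hits2).verdict == "multi_locus"
        assert classify_copy_number(hits2).n_hits == 2


class TestDevelopMarkers:
    def test_truth_table_verdicts_recovered(self, small_genome):
        records, truth = small_genome
        catalog = develop_markers(records)
        got = {(m.locus.seq_id, m.locus.start, m.locus.end):
               m.classification.verdict for m in catalog.markers}
        assert len(got) == len(truth)
        for row in truth.itertuples(index=False):
            assert got[(row.seq_id, row.start, row.end)] == \
                row.expected_verdict

    def test_partition_conserves_designed_count(self, small_genome):
        records, _ = small_genome
        catalog = develop_markers(records)
        part = catalog.partition()
        assert sum(part.values()) == len(catalog.markers)
        assert catalog.n_loci == len(catalog.markers) + len(catalog.undesigned)

    def test_marker_ids_serial_in_genome_order(self, small_genome):
        records, _ = small_genome
        catalog = develop_markers(records)
        ids = [m.marker_id for m in catalog.markers]
        assert ids == [f"AHGA{i + 1:05d}" for i in range(len(ids))]
        order = [(m.locus.seq_id, m.locus.start) for m in catalog.markers]
        assert order == sorted(order)

    def test_designed_pair_recovers_its_own_locus(self, small_genome):
        records, _ = small_genome
        catalog = develop_markers(records)
        for m in catalog.markers:
            containing = [h for h in m.hits
                          if h.seq_id == m.locus.seq_id
                          and h.start <= m.locus.start
                          and h.end >= m.locus.end]
            assert containing, f"{m.marker_id} does not recover its source"

    def test_planted_copy_flips_single_to_multi(self, small_genome):
        records, _ = small_genome
        catalog = develop_markers(records)
        marker = catalog.single_locus_markers()[0]
        (hit,) = marker.hits
        src = next(r for r in records if r.id == hit.seq_id)
        amplicon = src.residues[hit.start - 1:hit.end]
        other = next(r for r in records if r.id != hit.seq_id)
        modified = [SequenceRecord(r.id, r.residues + amplicon)
                    if r.id == other.id else r for r in records]
        hits2 = epcr_amplimers(marker.pair, modified,
                               expected_product=marker.pair.expected_product)
        assert classify_copy_number(hits2).verdict == "multi_locus"

    def test_strand_symmetry_of_hit_counts(self, small_genome):
        records, _ = small_genome
        catalog = develop_markers(records)
        flipped = [SequenceRecord(r.id, rc(r.residues)) for r in records]
        for m in catalog.markers[:4]:
            hits = epcr_amplimers(m.pair, flipped,
                                  expected_product=m.pair.expected_product)
            assert len(hits) == m.classification.n_hits

    def test_genome_without_ssrs_yields_empty_catalog(self, rng, make_record):
        seq = random_sequence(rng, 3000, gc=0.5)
        from unilocus.ssr_scan import scan_perfect_ssrs
        rec = make_record(seq)
        if scan_perfect_ssrs(rec):   # rare: re-roll deterministically
            seq = random_sequence(np.random.default_rng(999), 3000, gc=0.5)
            rec = make_record(seq)
        catalog = develop_markers([rec])
        assert catalog.n_loci == len(scan_perfect_ssrs(rec))
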