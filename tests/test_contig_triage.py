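"""Host subtraction, translated search, and the five-criterion filter."""


import numpy as np
import pytest

from vectorvirome.contig_triage import (cross_assembler_confirm, decide,
                                        hit_frame, host_subtract,
                                        mean_coverage, orf_completeness,
                                        translated_search, triage)
from vectorvirome.io_formats import HitRecord, PipelineConfig, SeqRecord
from vectorvirome.species_assign import revcomp
from vectorvirome.synthetic_data import gen_coding_genome

from conftest import random_dna

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def make_hit(query="c", evalue=1e-30, q_start=1, q_end=300, subject="p"):
    length = (abs(q_end - q_start) + 1) // 3
    return HitRecord(query, subject, 100.0, length, 0, 0, q_start, q_end,
                     1, length, evalue, 100.0)


class TestHostSubtract:
    def test_exact_host_substring_removed(self):
        rng = np.random.default_rng(0)
        host = SeqRecord("h", random_dna(10000, rng))
        read = SeqRecord("r", host.seq[500:600])
        assert host_subtract([read], [host]) == []

    def test_reverse_complement_removed(self):
        rng = np.random.default_rng(1)
        host = SeqRecord("h", random_dna(10000, rng))
        read = SeqRecord("r", revcomp(host.seq[500:600]))
        assert host_subtract([read], [host]) == []

    def test_unrelated_read_retained_zero_shared_kmers(self):
        rng = np.random.default_rng(2)
        host = SeqRecord("h", random_dna(10000, rng))
        read = SeqRecord("r", random_dna(100, rng))
        # brute-force: the random read shares no 21-mer with the host
        host_kmers = {host.seq[i:i + 21] for i in range(len(host.seq) - 20)}
        for probe in (read.seq, revcomp(read.seq)):
            assert all(probe[i:i + 21] not in host_kmers
                       for i in range(len(probe) - 20))
        assert host_subtract([read], [host]) == [read]

    def test_empty_host_set_warns_and_keeps(self, caplog):
        read = SeqRecord("r", "ACGT" * 10)
        with caplog.at_level("WARNING"):
            assert host_subtract([read], []) == [read]
        assert "empty host" in caplog.text


class TestTranslatedSearch:
    def _planted(self, seed=0, minus=False):
        """Contig with an exact 60-aa in-frame segment of a 200-aa reference."""
        rng = np.random.default_rng(seed)
        prot = "".join(rng.choice(list(AA20), size=200))
        from Bio.Data.CodonTable import standard_dna_table
        codon_for = {}
        for codon, aa in standard_dna_table.forward_table.items():
            codon_for.setdefault(aa, codon)
        insert = "".join(codon_for[a] for a in prot[50:110])
        contig_seq = random_dna(90, rng) + insert + random_dna(90, rng)
        if minus:
            contig_seq = revcomp(contig_seq)
        return (SeqRecord("c", contig_seq),
                SeqRecord("ref_virus", prot, alphabet="aa"))

    def test_planted_homology_found(self):
        contig, ref = self._planted()
        hits = translated_search(contig, [ref])
        top = hits[0]
        assert top.pct_identity == 100.0
        assert top.aln_length >= 60
        assert top.evalue < 1e-20
        assert not top.is_minus

    def test_minus_strand_hit(self):
        contig, ref = self._planted(seed=3, minus=True)
        hits = translated_search(contig, [ref])
        top = hits[0]
        # the planted 60-aa segment is recovered (extension may add a few
        # net-positive near-matches beyond it)
        assert top.pct_identity >= 90.0 and top.aln_length >= 60
        assert top.evalue < 1e-20
        assert top.is_minus
        assert hit_frame(top, len(contig.seq)) <= -1

    def test_hit_coordinates_translate_back(self):
        contig, ref = self._planted(seed=4)
        top = translated_search(contig, [ref])[0]
        lo, hi = top.q_span
        from Bio.Seq import Seq
        assert str(Seq(contig.seq[lo:hi]).translate()) \
            == ref.seq[top.s_start - 1:top.s_end]

    def test_random_contig_no_significant_hit(self):
        rng = np.random.default_rng(5)
        contig = SeqRecord("c", random_dna(1000, rng))
        ref = SeqRecord("p", "".join(rng.choice(list(AA20), size=200)),
                        alphabet="aa")
        hits = translated_search(contig, [ref], evalue_max=float("inf"))
        assert all(h.evalue > 1e-20 for h in hits)

    def test_evalue_monotone_in_score_within_frame(self):
        # E = K*m*n*exp(-lambda*S): decreasing in S for fixed frame length m
        contig, ref = self._planted(seed=6)
        hits = translated_search(contig, [ref], evalue_max=float("inf"))
        by_frame: dict[int, list] = {}
        for h in hits:
            by_frame.setdefault(hit_frame(h, len(contig.seq)), []).append(h)
        checked = 0
        for group in by_frame.values():
            group.sort(key=lambda h: h.bitscore)
            evs = [h.evalue for h in group]
            assert evs == sorted(evs, reverse=True)
            checked += len(group)
        assert checked == len(hits) and len(hits) > 3

    def test_too_short_contig(self):
        with pytest.raises(ValueError):
            translated_search(SeqRecord("c", "ACGTAC"),
                              [SeqRecord("p", "MKV", alphabet="aa")])


class TestMeanCoverage:
    def test_arithmetic_identity(self):
        assert mean_coverage(1000, [100] * 10) == 1.0

    def test_boundary_twenty_fold(self):
        assert mean_coverage(1000, [100] * 200) == 20.0

    def test_no_reads(self):
        assert mean_coverage(1000, []) == 0.0

    def test_zero_length(self):
        with pytest.raises(ValueError):
            mean_coverage(0, [10])


class TestOrfCompleteness:
    def test_complete_orf_passes(self):
        genome, (o0, o1) = gen_coding_genome(1000, seed=1, seq_id="c")
        hit = make_hit(q_start=o0 + 1, q_end=o1)
        orf, ok = orf_completeness(genome, hit)
        assert ok and orf.has_stop_codon and orf.has_start_codon
        # the run covers the planted ORF and ends at its stop codon (it may
        # extend left if the random prefix is stop-free in this frame)
        assert orf.start <= o0 and orf.end == o1

    def test_internal_midpoint_stop_fails(self):
        # a stop at the midpoint splits the frame into two ~50% runs, so the
        # longest ORF covers < 80% of the hit span
        rng = np.random.default_rng(2)
        from vectorvirome.synthetic_data import _NONSTOP_CODONS
        codons = list(rng.choice(_NONSTOP_CODONS, size=100))
        codons[50] = "TAA"
        seq = "ATG" + "".join(codons) + "TAA"
        contig = SeqRecord("c", seq)
        hit = make_hit(q_start=1, q_end=len(seq))
        orf, ok = orf_completeness(contig, hit)
        assert not ok
        assert orf.aa_length <= 51  # enumerated: both runs about half the span

    def test_zero_span_frac_always_passes(self):
        rng = np.random.default_rng(3)
        contig = SeqRecord("c", random_dna(600, rng))
        hit = make_hit(q_start=1, q_end=600)
        orf, ok = orf_completeness(contig, hit, min_span_frac=0.0)
        assert ok and orf is not None

    def test_minus_frame_orf(self):
        genome, (o0, o1) = gen_coding_genome(900, seed=4, seq_id="c")
        flipped = SeqRecord("c", revcomp(genome.seq))
        L = len(flipped.seq)
        # hit footprint mirrored onto the minus strand, blastx-style coords
        hit = make_hit(q_start=L - o0, q_end=L - o1 + 1)
        assert hit.is_minus
        orf, ok = orf_completeness(flipped, hit)
        assert ok and orf.frame < 0
        # the ORF covers the mirrored planted span on the plus strand
        assert orf.start <= L - o1 + 3 and orf.end >= L - o0 - 3
        assert orf.has_stop_codon

    def test_out_of_bounds_hit(self):
        contig = SeqRecord("c", "ACG" * 100)
        with pytest.raises(ValueError):
            orf_completeness(contig, make_hit(q_start=1, q_end=5000))


class TestCrossAssembler:
    def test_identical_confirmed(self):
        rng = np.random.default_rng(0)
        c = SeqRecord("a1", random_dna(1000, rng))
        flags = cross_assembler_confirm([c], [SeqRecord("b1", c.seq)])
        assert flags == {"a1": True}

    def test_only_in_one_set_unconfirmed(self):
        rng = np.random.default_rng(1)
        c = SeqRecord("a1", random_dna(1000, rng))
        other = SeqRecord("b1", random_dna(1000, rng))
        assert cross_assembler_confirm([c], [other]) == {"a1": False}

    def test_containment_confirmed(self):
        rng = np.random.default_rng(2)
        long_seq = random_dna(2000, rng)
        a = SeqRecord("a1", long_seq[400:1400])
        assert long_seq.find(a.seq) == 400  # genuine substring containment
        flags = cross_assembler_confirm([a], [SeqRecord("b1", long_seq)])
        assert flags == {"a1": True}

    def test_reverse_complement_confirmed(self):
        rng = np.random.default_rng(3)
        c = SeqRecord("a1", random_dna(1000, rng))
        flags = cross_assembler_confirm([c], [SeqRecord("b1", revcomp(c.seq))])
        assert flags == {"a1": True}


class TestTriage:
    def test_unknown_contig_in_hits_is_hard_error(self):
        contig = SeqRecord("c1", "ACG" * 200)
        hit = make_hit(query="ghost")
        with pytest.raises(KeyError):
            triage([contig], [hit], {}, [], PipelineConfig())

    def test_boundary_candidate_passes_all_inclusive(self):
        genome, (o0, o1) = gen_coding_genome(500, seed=9, seq_id="c1")
        hit = make_hit(query="c1", evalue=1e-20, q_start=o0 + 1, q_end=o1)
        reads = {"c1": [100.0] * 100}  # exactly 20.0x on 500 nt
        decisions = triage([genome], [hit], reads, [SeqRecord("b", genome.seq)],
                           PipelineConfig())
        (d,) = decisions
        assert d.mean_coverage == 20.0
        assert d.overall and all([d.pass_evalue, d.pass_length,
                                  d.pass_coverage, d.pass_orf,
                                  d.pass_cross_assembler])

    def test_length_499_fails_only_length(self):
        genome, (o0, o1) = gen_coding_genome(499, seed=10, seq_id="c1")
        hit = make_hit(query="c1", evalue=1e-30, q_start=o0 + 1, q_end=o1)
        reads = {"c1": [100.0] * 150}
        (d,) = triage([genome], [hit], reads, [SeqRecord("b", genome.seq)],
                      PipelineConfig())
        assert not d.pass_length and not d.overall
        assert d.pass_evalue and d.pass_coverage and d.pass_orf

    def test_recheck_hook_drops_nonviral(self):
        genome, (o0, o1) = gen_coding_genome(600, seed=11, seq_id="c1")
        hit = make_hit(query="c1", evalue=1e-30, q_start=o0 + 1, q_end=o1)
        reads = {"c1": [100.0] * 200}
        recheck = [make_hit(query="c1", subject="host_ribosomal_protein")]
        (d,) = triage([genome], [hit], reads, [SeqRecord("b", genome.seq)],
                      PipelineConfig(), recheck_hits=recheck)
        assert not d.pass_recheck and not d.overall
        recheck_viral = [make_hit(query="c1", subject="toti_like_virus_rdrp")]
        (d2,) = triage([genome], [hit], reads, [SeqRecord("b", genome.seq)],
                       PipelineConfig(), recheck_hits=recheck_viral)
        assert d2.pass_recheck and d2.overall

    def test_relaxing_thresholds_is_monotone(self):
        """Loosening any single threshold never turns a pass into a fail."""
        rng = np.random.default_rng(12)
        cases = []
        for i in range(200):
            cases.append(dict(
                length=int(rng.integers(300, 700)),
                evalue=10.0 ** rng.uniform(-40, -5),
                coverage=float(rng.uniform(0, 40)),
                orf=bool(rng.integers(2)), cross=bool(rng.integers(2))))
        base = PipelineConfig()
        relaxed = [PipelineConfig(evalue_max=1e-15),
                   PipelineConfig(min_coverage=10.0),
                   PipelineConfig(min_contig_len=300)]
        for case in cases:
            hit = make_hit(evalue=case["evalue"], q_end=300)
            d0 = decide("c", case["length"], hit, case["coverage"], None,
                        case["orf"], case["cross"], base)
            for cfg in relaxed:
                d1 = decide("c", case["length"], hit, case["coverage"], None,
                            case["orf"], case["cross"], cfg)
                assert d1.overall or not d0.overall
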