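"""Generators: determinism, exact divergence, distributional fidelity."""

import numpy as np
import pytest
from scipy import stats

from vectorvirome.io_formats import SeqRecord
from vectorvirome.species_assign import revcomp
from vectorvirome.synthetic_data import (SrnaPoolSpec, default_study_spec,
                                         gen_coding_genome, gen_mtcoi_variant,
                                         gen_rnaseq_reads, gen_srna_pool,
                                         gen_study, gen_viral_genome)


class TestGenViralGenome:
    def test_seed_determinism(self):
        a = gen_viral_genome(1000, 0.5, 1, 7)
        b = gen_viral_genome(1000, 0.5, 1, 7)
        assert [r.seq for r in a] == [r.seq for r in b]

    def test_five_segments_with_suffixed_ids(self):
        segs = gen_viral_genome(500, 0.45, 5, 1)
        assert [r.id for r in segs] == [f"virus_s{i}" for i in range(1, 6)]
        assert len({r.seq for r in segs}) == 5

    def test_gc_one_boundary(self):
        (rec,) = gen_viral_genome(500, 1.0, 1, 2)
        assert set(rec.seq) <= {"G", "C"}

    def test_gc_within_three_sd(self):
        n, gc = 5000, 0.4
        (rec,) = gen_viral_genome(n, gc, 1, 3)
        realized = sum(c in "GC" for c in rec.seq)
        sd = np.sqrt(n * gc * (1 - gc))
        assert abs(realized - n * gc) < 3 * sd

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            gen_viral_genome(50)


class TestGenMtcoiVariant:
    def test_zero_divergence_identical(self):
        ref = gen_viral_genome(600, seed=1)[0]
        assert gen_mtcoi_variant(ref, 0.0, 1).seq == ref.seq

    def test_exact_substitution_count(self):
        ref = gen_viral_genome(1000, seed=2)[0]
        var = gen_mtcoi_variant(ref, 0.035, 3)
        diffs = sum(a != b for a, b in zip(ref.seq, var.seq))
        assert diffs == 35
        assert len(var.seq) == len(ref.seq)

    def test_seed_determinism(self):
        ref = gen_viral_genome(400, seed=4)[0]
        assert gen_mtcoi_variant(ref, 0.05, 9).seq \
            == gen_mtcoi_variant(ref, 0.05, 9).seq

    def test_out_of_range_rejected(self):
        ref = gen_viral_genome(400, seed=5)[0]
        with pytest.raises(ValueError):
            gen_mtcoi_variant(ref, 0.3, 1)


class TestGenRnaseqReads:
    def test_reads_are_substrings_either_strand(self):
        (g,) = gen_viral_genome(2000, seed=1)
        reads, truth = gen_rnaseq_reads([(g, 1.0)], 100, 100, 2)
        assert len(reads) == 100
        for read in reads:
            assert read.seq in g.seq or revcomp(read.seq) in g.seq
        # truth table records the exact origin
        for read, row in zip(reads, truth.itertuples()):
            frag = g.seq[row.pos:row.pos + 100]
            expect = frag if row.strand == "+" else revcomp(frag)
            assert read.seq == expect

    def test_zero_weight_genome_gets_no_reads(self):
        g1 = gen_viral_genome(1000, seed=1)[0]
        g2 = SeqRecord("other", gen_viral_genome(1000, seed=2)[0].seq)
        _, truth = gen_rnaseq_reads([(g1, 1.0), (g2, 0.0)], 50, 500, 3)
        assert (truth.genome_id == "other").sum() == 0

    def test_multinomial_counts_within_three_sd(self):
        g1 = gen_viral_genome(1000, seed=1)[0]
        g2 = SeqRecord("other", gen_viral_genome(1000, seed=2)[0].seq)
        _, truth = gen_rnaseq_reads([(g1, 0.5), (g2, 0.5)], 50, 10000, 4)
        n1 = (truth.genome_id == g1.id).sum()
        assert abs(n1 - 5000) < 3 * np.sqrt(10000 * 0.25)

    def test_bad_weights_rejected(self):
        g = gen_viral_genome(500, seed=1)[0]
        with pytest.raises(ValueError):
            gen_rnaseq_reads([(g, 0.0)], 50, 10, 1)


class TestGenSrnaPool:
    def test_pure_22mer_plus_pool(self):
        g, _ = gen_coding_genome(900, seed=1, seq_id="v")
        spec = SrnaPoolSpec(n_reads=300, size_dist={22: 1.0},
                            plus_fraction=1.0, seed=2)
        reads, truth = gen_srna_pool(g, spec)
        assert all(len(r.seq) == 22 for r in reads)
        assert all(r.seq in g.seq for r in reads)
        assert (truth.strand == "+").all()

    def test_forced_u_start_condition_mode(self):
        g, _ = gen_coding_genome(900, seed=3, seq_id="v")
        spec = SrnaPoolSpec(n_reads=300, size_dist={22: 1.0},
                            five_prime_dist={"U": 1.0}, seed=4)
        reads, truth = gen_srna_pool(g, spec)
        assert all(r.seq[0] == "T" for r in reads)  # U emitted as DNA T
        assert not truth.forced.any()  # conditioning keeps perfect matches

    def test_substitute_mode_flags_forced_reads(self):
        g, _ = gen_coding_genome(900, seed=5, seq_id="v")
        spec = SrnaPoolSpec(n_reads=300, size_dist={22: 1.0},
                            five_prime_dist={"U": 1.0},
                            five_prime_mode="substitute", seed=6)
        reads, truth = gen_srna_pool(g, spec)
        assert all(r.seq[0] == "T" for r in reads)
        for read, row in zip(reads, truth.itertuples()):
            frag = g.seq[row.pos:row.pos + row.length]
            emitted = frag if row.strand == "+" else revcomp(frag)
            if row.forced:
                assert emitted[0] != "T" and read.seq[1:] == emitted[1:]
            else:
                assert read.seq == emitted

    def test_truth_positions_verify_by_mapping_back(self):
        g, _ = gen_coding_genome(1200, seed=7, seq_id="v")
        spec = SrnaPoolSpec(n_reads=500,
                            size_dist={21: 0.3, 22: 0.4, 23: 0.3},
                            plus_fraction=0.5, seed=8)
        reads, truth = gen_srna_pool(g, spec)
        for read, row in zip(reads, truth.itertuples()):
            frag = g.seq[row.pos:row.pos + row.length]
            expect = frag if row.strand == "+" else revcomp(frag)
            assert read.seq == expect

    def test_strand_count_within_three_sd(self):
        g, _ = gen_coding_genome(1500, seed=9, seq_id="v")
        spec = SrnaPoolSpec(n_reads=20000, size_dist={22: 1.0},
                            plus_fraction=0.5, seed=10)
        _, truth = gen_srna_pool(g, spec)
        plus = (truth.strand == "+").sum()
        assert abs(plus - 10000) < 3 * np.sqrt(20000 * 0.25)  # 3 SD ~ 212

    def test_size_and_fiveprime_chisquare_fidelity(self):
        # realized categorical frequencies converge to the spec distributions
        g, _ = gen_coding_genome(3000, seed=11, seq_id="v")
        size_dist = {21: 0.2, 22: 0.6, 23: 0.2}
        fp_dist = {"A": 0.25, "C": 0.25, "G": 0.25, "U": 0.25}
        spec = SrnaPoolSpec(n_reads=50000, size_dist=size_dist,
                            five_prime_dist=fp_dist, seed=12)
        reads, truth = gen_srna_pool(g, spec)
        obs = truth.length.value_counts()
        counts = [obs.get(k, 0) for k in sorted(size_dist)]
        expected = [size_dist[k] * 50000 for k in sorted(size_dist)]
        assert stats.chisquare(counts, expected).pvalue > 0.001
        fp_obs = truth.five_prime.map({"T": "U"}.get, na_action=None) \
            .fillna(truth.five_prime).value_counts()
        counts = [fp_obs.get(k, 0) for k in "ACGU"]
        expected = [fp_dist[k] * 50000 for k in "ACGU"]
        assert stats.chisquare(counts, expected).pvalue > 0.001

    def test_hotspot_weighting_enriches_region(self):
        g, _ = gen_coding_genome(2000, seed=13, seq_id="v")
        spec = SrnaPoolSpec(n_reads=5000, size_dist={22: 1.0},
                            hotspot_regions=((500, 600, 20.0),), seed=14)
        _, truth = gen_srna_pool(g, spec)
        in_spot = ((truth.pos >= 500) & (truth.pos < 600)).mean()
        # 100/1979 of starts at weight 20 vs background 1
        assert in_spot > 0.3

    def test_genome_too_short_rejected(self):
        g = SeqRecord("v", "ACGT" * 10)
        with pytest.raises(ValueError):
            gen_srna_pool(g, SrnaPoolSpec(n_reads=10, size_dist={30: 1.0}))


class TestGenStudy:
    def test_cardinality_and_truth(self, study_bundle):
        spec = study_bundle.spec
        n_expected = sum(s.n_datasets for s in spec.species)
        assert len(study_bundle.datasets) == n_expected == 6
        assert len(study_bundle.truth_datasets) == n_expected

    def test_core_virus_dominates_truth_composition(self, study_bundle):
        tr = study_bundle.truth_reads
        for ds in study_bundle.datasets:
            sub = tr[tr.dataset_id == ds.dataset_id].set_index("virus_id")
            core = study_bundle.truth_datasets.set_index("dataset_id") \
                .loc[ds.dataset_id, "dominant_virus"]
            share = sub.loc[core, "reads"] / sub.reads.sum()
            assert share > 0.95

    def test_same_seed_reproduces_bundle(self, study_bundle):
        other = gen_study(seed=1)
        assert [d.dataset_id for d in other.datasets] \
            == [d.dataset_id for d in study_bundle.datasets]
        for d1, d2 in zip(other.datasets, study_bundle.datasets):
            assert [c.seq for c in d1.contigs_a] == [c.seq for c in d2.contigs_a]
            assert [r.seq for r in d1.reads] == [r.seq for r in d2.reads]
            assert [r.seq for r in d1.srna] == [r.seq for r in d2.srna]
            assert d1.hits == d2.hits

    def test_bundle_writes_plain_text_files(self, study_bundle, tmp_path):
        study_bundle.write(tmp_path)
        first = study_bundle.datasets[0].dataset_id
        assert (tmp_path / "mtcoi_references.fasta").exists()
        assert (tmp_path / first / "contigs_trinity.fasta").exists()
        assert (tmp_path / first / "hits.tsv").exists()
        assert (tmp_path / "truth_datasets.tsv").exists()

    def test_too_few_species_rejected(self):
        spec = default_study_spec(n_species=1)
        with pytest.raises(ValueError):
            gen_study(spec, seed=0)
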