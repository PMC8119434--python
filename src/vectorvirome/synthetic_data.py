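"""Synthetic study generator with ground truth.

Emulates the statistical structure the analysis assumes — several host
datasets per cryptic species with mtCOI contigs at controlled divergence from
labelled references, viral genomes seeded at controlled read abundance
(a dominant "core" virus per species plus a low-abundance virus shared across
species), host decoy contigs with no viral homology, and small-RNA pools with
controlled size distribution, strand polarity, 5'-terminal nucleotide bias
and positional hotspots — so every downstream stage can be exercised and
scored against a truth table without any sequencing data.

All generators are pure functions of (parameters, seed). sRNA reads are
emitted in DNA alphabet (T, not U); 5'-nt reporting maps T to U downstream.
The 5' bias is realised by *conditioning the start position* on the sampled
5' base, so every read still maps back perfectly; a substitution mode
(overwrite position 0, breaking the perfect match there) is available and
flagged in the truth table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .io_formats import SeqRecord, write_fasta, write_hits_tab
from .species_assign import revcomp

logger = logging.getLogger("vectorvirome")

_BASES = np.array(list("ACGT"))
_NONSTOP_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
                   if a + b + c not in ("TAA", "TAG", "TGA")]
_U2T = {"A": "A", "C": "C", "G": "G", "U": "T", "T": "T"}


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def stage_seed(seed: int, stage: str) -> np.random.SeedSequence:
    """Deterministic per-stage child seed fanned out from one global seed."""
    import zlib
    return np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())])


# ---------------------------------------------------------------------------
# Genomes

def gen_viral_genome(length: int, gc_fraction: float = 0.5,
                     n_segments: int = 1, seed=0) -> list[SeqRecord]:
    """Random viral genome segments with a target GC content.

    Segment ids get ``_s<i>`` suffixes, mirroring segmented genomes such as
    the quaranjavirus five-segment layout.
    """
    if length < 100:
        raise ValueError("segment length must be >= 100")
    rng = _rng(seed)
    p = np.array([(1 - gc_fraction) / 2, gc_fraction / 2,
                  gc_fraction / 2, (1 - gc_fraction) / 2])
    out = []
    for i in range(n_segments):
        seq = "".join(rng.choice(_BASES, size=length, p=p))
        out.append(SeqRecord(f"virus_s{i + 1}", seq))
    return out


def gen_coding_genome(length: int, seed=0, orf_frac: float = 0.85,
                      seq_id: str = "virus") -> tuple[SeqRecord, tuple[int, int]]:
    """Random genome carrying one long clean ORF (ATG...stop-free...TAA).

    Returns the record and the ORF's 0-based half-open nt span. The ORF
    occupies about ``orf_frac`` of the genome, starts in frame +1 relative to
    its own start, and is the longest ORF by construction.
    """
    if length < 300:
        raise ValueError("coding genome length must be >= 300")
    rng = _rng(seed)
    n_codons = max(int(length * orf_frac) // 3 - 2, 30)
    orf = "ATG" + "".join(rng.choice(_NONSTOP_CODONS, size=n_codons)) + "TAA"
    rest = length - len(orf)
    pre = rest // 2
    prefix = "".join(rng.choice(_BASES, size=pre)) if pre else ""
    suffix = "".join(rng.choice(_BASES, size=rest - pre)) if rest - pre else ""
    seq = prefix + orf + suffix
    return SeqRecord(seq_id, seq), (pre, pre + len(orf))


def gen_mtcoi_variant(reference: SeqRecord, divergence: float, seed=0,
                      seq_id: str | None = None) -> SeqRecord:
    """Substitution-only variant at an exact divergence from the reference.

    Exactly ``round(divergence * length)`` positions (sampled without
    replacement) are substituted to a different base.
    """
    if not 0 <= divergence <= 0.2:
        raise ValueError("divergence must lie in [0, 0.2]")
    rng = _rng(seed)
    seq = list(reference.seq)
    n_sub = round(divergence * len(seq))
    for pos in rng.choice(len(seq), size=n_sub, replace=False):
        alternatives = [b for b in "ACGT" if b != seq[pos]]
        seq[pos] = alternatives[rng.integers(len(alternatives))]
    return SeqRecord(seq_id or f"{reference.id}_var", "".join(seq),
                     reference.description)


# ---------------------------------------------------------------------------
# RNA-seq reads

def gen_rnaseq_reads(genomes_with_weights: list[tuple[SeqRecord, float]],
                     read_len: int, n_reads: int, seed=0,
                     id_prefix: str = "read",
                     ) -> tuple[list[SeqRecord], pd.DataFrame]:
    """Uniform-start stranded reads, multinomial across genomes.

    Returns the reads and a truth table (read_id, genome_id, pos, strand).
    """
    weights = np.array([w for _, w in genomes_with_weights], dtype=float)
    if weights.sum() <= 0 or np.any(weights < 0):
        raise ValueError("weights must be non-negative with positive sum")
    for g, _ in genomes_with_weights:
        if read_len > len(g.seq):
            raise ValueError(f"read_len {read_len} exceeds genome {g.id}")
    rng = _rng(seed)
    counts = rng.multinomial(n_reads, weights / weights.sum())
    reads: list[SeqRecord] = []
    rows = []
    idx = 0
    for (genome, _), count in zip(genomes_with_weights, counts):
        if count == 0:
            continue
        starts = rng.integers(0, len(genome.seq) - read_len + 1, size=count)
        strands = rng.integers(0, 2, size=count)  # 0 plus, 1 minus
        for pos, minus in zip(starts, strands):
            frag = genome.seq[pos:pos + read_len]
            seq = revcomp(frag) if minus else frag
            rid = f"{id_prefix}{idx:06d}"
            reads.append(SeqRecord(rid, seq))
            rows.append((rid, genome.id, int(pos), "-" if minus else "+"))
            idx += 1
    truth = pd.DataFrame(rows, columns=["read_id", "genome_id", "pos", "strand"])
    return reads, truth


# ---------------------------------------------------------------------------
# Small-RNA pools

@dataclass(frozen=True)
class SrnaPoolSpec:
    """Controls the observables of a simulated vsiRNA pool."""

    n_reads: int
    size_dist: dict[int, float]                 # read length -> probability
    plus_fraction: float = 0.5
    five_prime_dist: dict[str, float] | None = None  # RNA alphabet {A,C,G,U}
    five_prime_mode: str = "condition"          # "condition" | "substitute"
    hotspot_regions: tuple[tuple[int, int, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.size_dist:
            raise ValueError("size_dist must be non-empty")
        if abs(sum(self.size_dist.values()) - 1.0) > 1e-9:
            raise ValueError("size_dist must sum to 1")
        if not 0.0 <= self.plus_fraction <= 1.0:
            raise ValueError("plus_fraction must lie in [0, 1]")
        if self.five_prime_dist is not None:
            if abs(sum(self.five_prime_dist.values()) - 1.0) > 1e-9:
                raise ValueError("five_prime_dist must sum to 1")
        if self.five_prime_mode not in ("condition", "substitute"):
            raise ValueError("five_prime_mode must be condition or substitute")


def gen_srna_pool(genome: SeqRecord, spec: SrnaPoolSpec,
                  id_prefix: str = "srna",
                  ) -> tuple[list[SeqRecord], pd.DataFrame]:
    """Simulate a vsiRNA pool from one genome under an SrnaPoolSpec.

    Each read is an exact substring of the plus strand or of the reverse
    complement; length, strand and (optionally) the 5'-terminal base follow
    the spec's distributions, and hotspot weights multiply the start-position
    probability. In the default "condition" mode the 5' bias is achieved by
    sampling starts whose genome base equals the sampled 5' base, so every
    read maps back with zero mismatches; in "substitute" mode position 0 is
    overwritten (flagged ``forced`` in the truth table).
    """
    L_max = max(spec.size_dist)
    if len(genome.seq) < 2 * L_max:
        raise ValueError("genome must be at least twice the max read length")
    rng = _rng(spec.seed)
    glen = len(genome.seq)
    base_w = np.ones(glen)
    for start, end, weight in spec.hotspot_regions:
        base_w[start:end] *= weight
    sizes = np.array(sorted(spec.size_dist))
    size_p = np.array([spec.size_dist[s] for s in sizes])
    lengths = rng.choice(sizes, size=spec.n_reads, p=size_p)
    minus = rng.random(spec.n_reads) >= spec.plus_fraction
    if spec.five_prime_dist is not None:
        fp_bases = np.array(sorted(spec.five_prime_dist))
        fp_p = np.array([spec.five_prime_dist[b] for b in fp_bases])
        bases5 = rng.choice(fp_bases, size=spec.n_reads, p=fp_p)
    else:
        bases5 = np.array([""] * spec.n_reads)
    garr = np.frombuffer(genome.seq.encode(), dtype="S1").astype("U1")
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    reads: list[SeqRecord] = []
    rows = []
    # group by (length, strand, sampled 5' base) and draw starts vectorised
    order = np.arange(spec.n_reads)
    for L in sizes:
        for is_minus in (False, True):
            valid = base_w[:glen - L + 1].copy()
            # 5' base of a read starting at p: genome[p] on plus,
            # complement(genome[p+L-1]) on minus
            if is_minus:
                fp_at = np.array([comp[b] for b in garr[L - 1:]])[:glen - L + 1]
            else:
                fp_at = garr[:glen - L + 1]
            for b5 in (np.unique(bases5) if spec.five_prime_dist is not None
                       else [""]):
                sel = order[(lengths == L) & (minus == is_minus)
                            & (bases5 == b5)]
                if sel.size == 0:
                    continue
                w = valid.copy()
                forced = np.zeros(sel.size, dtype=bool)
                if b5 and spec.five_prime_mode == "condition":
                    w = w * (fp_at == _U2T[b5])
                    if w.sum() == 0:  # no eligible start: fall back, unforced
                        w = valid.copy()
                starts = rng.choice(len(w), size=sel.size, p=w / w.sum())
                for ridx, pos in zip(sel, starts):
                    frag = genome.seq[pos:pos + L]
                    seq = revcomp(frag) if is_minus else frag
                    was_forced = False
                    if b5 and spec.five_prime_mode == "substitute":
                        want = _U2T[b5]
                        if seq[0] != want:
                            seq = want + seq[1:]
                            was_forced = True
                    rid = f"{id_prefix}{ridx:06d}"
                    rows.append((rid, genome.id, int(pos),
                                 "-" if is_minus else "+", int(L), seq[0],
                                 was_forced))
                    reads.append((rid, seq))
    reads.sort(key=lambda t: t[0])
    rows.sort(key=lambda t: t[0])
    records = [SeqRecord(rid, seq) for rid, seq in reads]
    truth = pd.DataFrame(
        rows, columns=["read_id", "genome_id", "pos", "strand", "length",
                       "five_prime", "forced"])
    return records, truth


# ---------------------------------------------------------------------------
# Whole-study bundles

@dataclass(frozen=True)
class SpeciesSpec:
    label: str
    n_datasets: int = 2
    core_virus: str = ""
    core_segments: tuple[int, ...] = (1500,)   # segment lengths, nt
    mtcoi_divergence: float = 0.01             # dataset contig vs its reference


@dataclass(frozen=True)
class StudySpec:
    """The simulated study design (the desk-scale stand-in for the SRA sets)."""

    species: tuple[SpeciesSpec, ...]
    minor_virus_len: int = 600
    core_weight: float = 0.96
    minor_weight: float = 0.04
    n_viral_reads: int = 12000
    n_host_reads: int = 600
    read_len: int = 100
    n_decoys: int = 3
    decoy_len: int = 800
    mtcoi_len: int = 700
    srna_n_reads: int = 5000
    srna_peak: int = 22
    srna_plus_fraction: float = 0.5


def default_study_spec(n_species: int = 3, n_datasets: int = 2) -> StudySpec:
    """3 species x 2 datasets, one core virus per species (>=95% of viral
    reads), a shared low-abundance virus, host decoys and sRNA pools.

    Core genome lengths and segment counts differ across species so that the
    abundance clusters are asymmetric (first species' core is segmented,
    quaranjavirus-style).
    """
    labels = ["MEAM1", "MED", "SSA1", "NW1", "AsiaII1"][:n_species]
    seglens = [(1200, 900), (1500,), (1900,), (1100,), (1700,)]
    species = tuple(
        SpeciesSpec(label=lab, n_datasets=n_datasets,
                    core_virus=f"core_{lab}", core_segments=seglens[i],
                    mtcoi_divergence=0.01)
        for i, lab in enumerate(labels))
    return StudySpec(species=species)


@dataclass
class DatasetBundle:
    dataset_id: str
    species_label: str
    contigs_a: list[SeqRecord]
    contigs_b: list[SeqRecord]
    reads: list[SeqRecord]
    srna: list[SeqRecord]
    hits: list
    mtcoi_divergence: float


@dataclass
class StudyBundle:
    spec: StudySpec
    references: list[SeqRecord]           # mtCOI refs with species= tags
    protein_refs: list[SeqRecord]         # toy viral-protein reference (aa)
    viruses: dict[str, list[SeqRecord]]   # virus id -> segments
    contig_to_virus: dict[str, str]
    datasets: list[DatasetBundle]
    truth_datasets: pd.DataFrame          # dataset_id, species, divergence, dominant
    truth_reads: pd.DataFrame             # dataset_id, virus_id, reads

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(self.references, out / "mtcoi_references.fasta")
        write_fasta(self.protein_refs, out / "viral_proteins.fasta")
        for ds in self.datasets:
            d = out / ds.dataset_id
            d.mkdir(exist_ok=True)
            write_fasta(ds.contigs_a, d / "contigs_trinity.fasta")
            write_fasta(ds.contigs_b, d / "contigs_metaviral.fasta")
            write_fasta(ds.reads, d / "rnaseq.fasta")
            write_fasta(ds.srna, d / "srna.fasta")
            write_hits_tab(ds.hits, d / "hits.tsv")
        self.truth_datasets.to_csv(out / "truth_datasets.tsv", sep="\t",
                                   index=False, lineterminator="\n")
        self.truth_reads.to_csv(out / "truth_reads.tsv", sep="\t",
                                index=False, lineterminator="\n")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def gen_study(spec: StudySpec | None = None, seed: int = 0) -> StudyBundle:
    """Generate a full study bundle with truth tables.

    Per dataset: contig sets from two pseudo-assemblers (the species' core
    virus segments and the shared minor virus, host decoys, and an mtCOI
    contig at the configured divergence), RNA-seq reads with the configured
    viral composition, an sRNA pool from the core virus, and a hit table from
    the built-in translated search against the bundled protein reference.
    """
    from .contig_triage import translated_search

    if spec is None:
        spec = default_study_spec()
    if len(spec.species) < 2:
        raise ValueError("need at least 2 species")
    rng = _rng(stage_seed(seed, "study"))

    # mtCOI references: mutate a common ancestor heavily so labels are far apart
    ancestor = SeqRecord("mtCOI_ancestor", _random_seq(rng, spec.mtcoi_len))
    references = []
    ref_seqs = set()
    for i, sp in enumerate(spec.species):
        ref = gen_mtcoi_variant(ancestor, 0.1,
                                seed=stage_seed(seed, f"ref_{sp.label}"),
                                seq_id=f"mtCOI_{sp.label}")
        ref = SeqRecord(ref.id, ref.seq, f"species={sp.label}")
        if ref.seq in ref_seqs:
            raise ValueError("species share identical mtCOI references")
        ref_seqs.add(ref.seq)
        references.append(ref)

    # viral genomes: one core per species (+ clean ORF per segment), one minor
    viruses: dict[str, list[SeqRecord]] = {}
    contig_to_virus: dict[str, str] = {}
    protein_refs: list[SeqRecord] = []
    for sp in spec.species:
        segs = []
        for si, slen in enumerate(sp.core_segments):
            rec, (o0, o1) = gen_coding_genome(
                slen, seed=stage_seed(seed, f"{sp.core_virus}_s{si}"),
                seq_id=f"{sp.core_virus}_s{si + 1}")
            segs.append(rec)
            contig_to_virus[rec.id] = sp.core_virus
            prot = str(Seq(rec.seq[o0:o1]).translate()).rstrip("*")
            protein_refs.append(SeqRecord(f"{rec.id}_viral_protein", prot,
                                          "toy viral reference",
                                          alphabet="aa"))
        viruses[sp.core_virus] = segs
    minor_rec, (m0, m1) = gen_coding_genome(
        spec.minor_virus_len, seed=stage_seed(seed, "minor_virus"),
        seq_id="minor_virus_s1")
    mprot = str(Seq(minor_rec.seq[m0:m1]).translate()).rstrip("*")
    protein_refs.append(SeqRecord("minor_virus_s1_viral_protein",
                                  mprot, "toy viral reference", alphabet="aa"))
    viruses["minor_virus"] = [minor_rec]
    contig_to_virus[minor_rec.id] = "minor_virus"
    host_genome = SeqRecord(
        "host_genome", _random_seq(_rng(stage_seed(seed, "host")), 10000))

    datasets: list[DatasetBundle] = []
    ds_rows = []
    read_rows = []
    for sp in spec.species:
        ref = next(r for r in references if r.description == f"species={sp.label}")
        for di in range(sp.n_datasets):
            ds_id = f"{sp.label}_d{di + 1}"
            ds_ss = stage_seed(seed, f"dataset_{ds_id}")
            ds_rng = _rng(ds_ss)
            mtcoi = gen_mtcoi_variant(
                ref, sp.mtcoi_divergence,
                seed=stage_seed(seed, f"mtcoi_{ds_id}"),
                seq_id=f"{ds_id}_mtcoi")
            mtcoi = SeqRecord(mtcoi.id, mtcoi.seq)  # strip species tag
            decoys_a = [SeqRecord(f"{ds_id}_decoyA{i}",
                                  _random_seq(ds_rng, spec.decoy_len))
                        for i in range(spec.n_decoys)]
            decoys_b = [SeqRecord(f"{ds_id}_decoyB{i}",
                                  _random_seq(ds_rng, spec.decoy_len))
                        for i in range(spec.n_decoys)]
            viral_contigs = list(viruses[sp.core_virus]) + [minor_rec]
            contigs_a = viral_contigs + decoys_a + [mtcoi]
            # second assembler recovers the viral contigs slightly trimmed
            contigs_b = [SeqRecord(c.id + "_b", c.seq[: int(len(c.seq) * 0.99)])
                         for c in viral_contigs] + decoys_b
            # RNA-seq reads: core weight split across segments by length
            core_segs = viruses[sp.core_virus]
            seg_lens = np.array([len(s.seq) for s in core_segs], dtype=float)
            gw = [(s, spec.core_weight * l / seg_lens.sum())
                  for s, l in zip(core_segs, seg_lens)]
            gw.append((minor_rec, spec.minor_weight))
            host_w = (spec.n_host_reads / spec.n_viral_reads
                      * (spec.core_weight + spec.minor_weight))
            gw.append((host_genome, host_w))
            reads, read_truth = gen_rnaseq_reads(
                gw, spec.read_len, spec.n_viral_reads + spec.n_host_reads,
                seed=stage_seed(seed, f"reads_{ds_id}"),
                id_prefix=f"{ds_id}_r")
            per_genome = read_truth.groupby("genome_id").size()
            for virus_id, segs in viruses.items():
                n = int(sum(per_genome.get(s.id, 0) for s in segs))
                read_rows.append((ds_id, virus_id, n))
            # sRNA pool from the largest core segment, canonical regime
            srna_genome = max(core_segs, key=lambda s: len(s.seq))
            pool_spec = SrnaPoolSpec(
                n_reads=spec.srna_n_reads,
                size_dist=_peaked_size_dist(spec.srna_peak),
                plus_fraction=spec.srna_plus_fraction,
                five_prime_dist=None,
                seed=int(_rng(stage_seed(seed, f"srna_{ds_id}")).integers(2**31)),
            )
            srna, _ = gen_srna_pool(srna_genome, pool_spec,
                                    id_prefix=f"{ds_id}_s")
            hits = []
            for contig in contigs_a:
                hits.extend(translated_search(contig, protein_refs,
                                              evalue_max=1e-5))
            datasets.append(DatasetBundle(ds_id, sp.label, contigs_a,
                                          contigs_b, reads, srna, hits,
                                          sp.mtcoi_divergence))
            ds_rows.append((ds_id, sp.label, sp.mtcoi_divergence,
                            sp.core_virus))
    truth_datasets = pd.DataFrame(
        ds_rows, columns=["dataset_id", "species", "mtcoi_divergence",
                          "dominant_virus"])
    truth_reads = pd.DataFrame(
        read_rows, columns=["dataset_id", "virus_id", "reads"])
    return StudyBundle(spec, references, protein_refs, viruses,
                       contig_to_virus, datasets, truth_datasets, truth_reads)


def _peaked_size_dist(peak: int, spread: float = 0.08) -> dict[int, float]:
    """Size distribution concentrated at ``peak`` with light shoulders."""
    dist = {peak: 1.0 - 2 * spread}
    for d in (-1, 1):
        if peak + d in SIZE_RANGE_SET:
            dist[peak + d] = spread
        else:
            dist[peak] += spread
    total = sum(dist.values())
    return {k: v / total for k, v in dist.items()}


SIZE_RANGE_SET = set(range(18, 31))
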