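"""Virus-derived small-RNA (vsiRNA) profiling and origin classification.

Cleaned 18-30 nt reads are mapped to viral genomes requiring a perfect match
(zero mismatches) on either strand, with redundant counting: every read copy
contributes. A read matching k positions contributes weight 1/k to the depth
at each matched 5' start, and is assigned to a strand only when all its
matches agree (otherwise it is strand-ambiguous: counted in depth, excluded
from the size/strand and 5'-nt histograms).

The resulting profile (read-length x strand histogram, 5'-terminal nucleotide
matrix reported in RNA alphabet with T read as U, strand-resolved positional
depth, hotspot regions) is classified as the product of the host antiviral
RNAi pathway (canonical: a 21-22 nt size peak with reads drawn roughly
equally from both genomic strands, the signature of Dicer processing a dsRNA
replication intermediate) or as non-canonical (23 nt peak and/or strong
strand bias together with a strong 5' U bias), which suggests the small RNAs
derive from another organism's silencing machinery rather than the insect's.
Cutoffs quantifying "strong" and "balanced" are configurable; defaults are
stated in the docs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import SeqRecord
from .species_assign import revcomp

logger = logging.getLogger("vectorvirome")

SIZE_RANGE = range(18, 31)
_T2U = {"A": "A", "C": "C", "G": "G", "T": "U", "N": "N"}


def clean_srna(reads: Sequence[SeqRecord], len_min: int = 18,
               len_max: int = 30, adapter: str | None = None,
               ) -> list[SeqRecord]:
    """Adapter-clip, drop N-containing reads, keep lengths in [len_min, len_max].

    Adapter clipping removes everything from the first exact occurrence of
    ``adapter`` in the read onward. Length bounds are inclusive.
    """
    if len_min > len_max:
        raise ValueError("len_min must be <= len_max")
    out = []
    for read in reads:
        seq = read.seq
        if adapter:
            cut = seq.find(adapter)
            if cut >= 0:
                seq = seq[:cut]
        if not seq or "N" in seq:
            continue
        if len_min <= len(seq) <= len_max:
            out.append(read if seq == read.seq
                       else SeqRecord(read.id, seq, read.description, "nt"))
    return out


@dataclass(frozen=True)
class SrnaPlacement:
    genome_id: str
    pos: int      # 0-based window start on the genome plus strand
    strand: str   # "+" or "-"


@dataclass
class SrnaMapping:
    """Per-read perfect-match placements across all virus genomes/segments."""

    placements: dict[str, list[SrnaPlacement]]
    reads: dict[str, SeqRecord]

    def strand_of(self, read_id: str) -> str | None:
        """Consensus strand, or None if unmapped or strand-ambiguous."""
        places = self.placements.get(read_id, ())
        strands = {p.strand for p in places}
        return strands.pop() if len(strands) == 1 else None


def map_srna(reads: Sequence[SeqRecord], genomes: Sequence[SeqRecord],
             ) -> SrnaMapping:
    """Zero-mismatch mapping of (redundant) sRNA reads to virus genomes."""
    lengths = {len(r.seq) for r in reads}
    index: dict[str, list[tuple[str, int]]] = {}
    for g in genomes:
        for L in lengths:
            for i in range(len(g.seq) - L + 1):
                index.setdefault(g.seq[i:i + L], []).append((g.id, i))
    placements: dict[str, list[SrnaPlacement]] = {}
    read_map: dict[str, SeqRecord] = {}
    for read in reads:
        read_map[read.id] = read
        places = [SrnaPlacement(gid, pos, "+")
                  for gid, pos in index.get(read.seq, ())]
        rc = revcomp(read.seq)
        if rc == read.seq:
            # reverse-complement palindrome: every occurrence matches both
            # strands at the same locus
            places += [SrnaPlacement(p.genome_id, p.pos, "-") for p in places]
        else:
            places += [SrnaPlacement(gid, pos, "-")
                       for gid, pos in index.get(rc, ())]
        placements[read.id] = places
    return SrnaMapping(placements, read_map)


@dataclass
class VsiRNAProfile:
    """Size/strand/5'-nt/positional summary of vsiRNAs for one genome."""

    virus_id: str
    size_strand: pd.DataFrame   # sizes 18..30 x {plus, minus}, counts
    five_prime: pd.DataFrame    # sizes x {A, C, G, U}, counts
    depth_plus: np.ndarray      # per-position 5'-start weight
    depth_minus: np.ndarray
    total_mapped: int           # reads with >=1 placement on this genome
    strand_assigned: int
    plus_fraction: float


def build_profile(mapping: SrnaMapping, genome: SeqRecord) -> VsiRNAProfile:
    """Histogram the placements of one genome (or one segment).

    Depth is recorded at the read's 5' start: the window start for plus reads
    and the window end for minus reads (their 5' end sits at the right edge
    in plus-strand coordinates).
    """
    sizes = list(SIZE_RANGE)
    ss = np.zeros((len(sizes), 2), dtype=int)       # sizes x (plus, minus)
    fp = np.zeros((len(sizes), 4), dtype=int)       # sizes x A,C,G,U
    base_col = {"A": 0, "C": 1, "G": 2, "T": 3}     # T reported as U
    depth_plus = np.zeros(len(genome.seq))
    depth_minus = np.zeros(len(genome.seq))
    total = 0
    assigned = 0
    for rid, places in mapping.placements.items():
        here = [p for p in places if p.genome_id == genome.id]
        if not here:
            continue
        total += 1
        read = mapping.reads[rid]
        L = len(read.seq)
        w = 1.0 / len(places)  # k counts matches across all genomes
        for p in here:
            if p.strand == "+":
                depth_plus[p.pos] += w
            else:
                depth_minus[p.pos + L - 1] += w
        strand = mapping.strand_of(rid)
        if strand is None or not 18 <= L <= 30:
            continue
        assigned += 1
        ss[L - 18, 0 if strand == "+" else 1] += 1
        fp[L - 18, base_col.get(read.seq[0], 3)] += 1
    size_strand = pd.DataFrame(ss, index=sizes, columns=["plus", "minus"])
    five_prime = pd.DataFrame(fp, index=sizes, columns=list("ACGU"))
    plus = int(size_strand["plus"].sum())
    minus = int(size_strand["minus"].sum())
    frac = plus / (plus + minus) if (plus + minus) else float("nan")
    return VsiRNAProfile(genome.id, size_strand, five_prime, depth_plus,
                         depth_minus, total, assigned, frac)


def pool_profiles(profiles: Sequence[VsiRNAProfile], virus_id: str,
                  ) -> VsiRNAProfile:
    """Pool per-segment profiles of one virus (depths concatenated)."""
    if not profiles:
        raise ValueError("no profiles to pool")
    size_strand = sum(p.size_strand for p in profiles)
    five_prime = sum(p.five_prime for p in profiles)
    depth_plus = np.concatenate([p.depth_plus for p in profiles])
    depth_minus = np.concatenate([p.depth_minus for p in profiles])
    total = sum(p.total_mapped for p in profiles)
    assigned = sum(p.strand_assigned for p in profiles)
    plus = int(size_strand["plus"].sum())
    minus = int(size_strand["minus"].sum())
    frac = plus / (plus + minus) if (plus + minus) else float("nan")
    return VsiRNAProfile(virus_id, size_strand, five_prime, depth_plus,
                         depth_minus, total, assigned, frac)


def detect_hotspots(depth: np.ndarray, z: float = 3.0, max_gap: int = 5,
                    ) -> list[tuple[int, int]]:
    """Regions of unusually deep vsiRNA accumulation.

    Positions whose depth exceeds mean + z*SD (statistics over positions with
    nonzero support) are merged into maximal runs allowing gaps of up to
    ``max_gap`` nt. Returns 0-based half-open (start, end) regions.
    """
    depth = np.asarray(depth, dtype=float)
    if len(depth) < 10:
        raise ValueError("depth array too short")
    support = depth[depth > 0]
    if support.size == 0:
        return []
    cutoff = support.mean() + z * support.std()
    idx = np.flatnonzero(depth > cutoff)
    if idx.size == 0:
        return []
    regions = []
    start = prev = int(idx[0])
    for i in idx[1:]:
        if i - prev <= max_gap + 1:
            prev = int(i)
        else:
            regions.append((start, prev + 1))
            start = prev = int(i)
    regions.append((start, prev + 1))
    return regions


# ---------------------------------------------------------------------------
# Classification

@dataclass(frozen=True)
class ClassifyThresholds:
    min_reads: int = 100
    canonical_peaks: tuple[int, ...] = (21, 22)
    noncanonical_peak: int = 23
    plus_band: tuple[float, float] = (0.35, 0.65)
    u_strong: float = 0.5


@dataclass(frozen=True)
class ProfileClassification:
    virus_id: str
    peak_size: int | None
    plus_fraction: float
    fiveprime_U_fraction: float
    fiveprime_AU_fraction: float
    label: str  # canonical_host_RNAi | non_canonical | insufficient_data
    rule_trace: tuple[str, ...]


def classify_profile(profile: VsiRNAProfile,
                     thresholds: ClassifyThresholds = ClassifyThresholds(),
                     ) -> ProfileClassification:
    """Host-RNAi-canonical vs non-canonical call for one vsiRNA profile.

    Canonical: size peak at 21-22 nt and a plus-strand fraction inside the
    balanced band. Non-canonical: a 23 nt peak or strand bias, reinforced by
    a strong 5' U bias when present. Profiles below ``min_reads`` mapped
    strand-assigned reads are labelled insufficient_data.
    """
    t = thresholds
    totals = profile.size_strand.sum(axis=1)
    n = int(totals.sum())
    if n < t.min_reads:
        return ProfileClassification(profile.virus_id, None, float("nan"),
                                     float("nan"), float("nan"),
                                     "insufficient_data",
                                     (f"mapped reads {n} < {t.min_reads}",))
    peak = int(totals.idxmax())
    plus_frac = profile.plus_fraction
    fp = profile.five_prime.sum(axis=0)
    u_frac = float(fp["U"] / n)
    au_frac = float((fp["A"] + fp["U"]) / n)
    lo, hi = t.plus_band
    balanced = lo <= plus_frac <= hi
    trace: list[str] = []
    trace.append(f"peak_size={peak}")
    trace.append(f"plus_fraction={plus_frac:.3f} "
                 f"({'balanced' if balanced else 'biased'})")
    trace.append(f"5'U={u_frac:.3f} "
                 f"({'strong' if u_frac >= t.u_strong else 'weak'})")
    if peak in t.canonical_peaks and balanced:
        label = "canonical_host_RNAi"
        trace.append("canonical: 21-22 nt peak with balanced strands")
    elif (peak == t.noncanonical_peak or not balanced) and u_frac >= t.u_strong:
        label = "non_canonical"
        trace.append("non-canonical: 23 nt peak / strand bias with strong 5'U")
    else:
        label = "non_canonical"
        trace.append("non-canonical: canonical conditions not met")
    return ProfileClassification(profile.virus_id, peak, plus_frac, u_frac,
                                 au_frac, label, tuple(trace))
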