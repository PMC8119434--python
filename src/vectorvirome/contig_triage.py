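"""Multi-criterion triage of candidate viral contigs.

A contig is accepted as a putative virus only when all five criteria hold:

1. best protein-homology E-value <= 1e-20,
2. assembled length >= 500 bp,
3. mean remapped read depth >= 20x,
4. a nearly complete ORF of the predicted viral protein (the longest ORF in
   the hit frame must span >= 80% of the hit footprint and end in a stop
   codon; a start codon is not required because viral contigs are often
   5'-truncated),
5. confirmation by an independent assembly (near-identical containment in the
   second assembler's contig set).

All thresholds are inclusive ("no less than" reads as >=). Host-derived reads
can be removed beforehand with a k-mer subtraction. A pluggable re-check hit
table (mirroring a nucleotide/protein database false-positive screen) can
drop candidates whose best re-check subject is non-viral.

The built-in translated search is a deliberately small blastx-like tool for
self-contained runs: six-frame translation, exact amino-acid word seeding,
ungapped X-drop extension under BLOSUM62, and Karlin-Altschul E-values with
fixed ungapped constants (lambda=0.318, K=0.13). External hit tables take
precedence when provided.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .io_formats import HitRecord, PipelineConfig, SeqRecord
from .species_assign import revcomp

logger = logging.getLogger("vectorvirome")

# Ungapped Karlin-Altschul constants for BLOSUM62.
LAMBDA_UNGAPPED = 0.318
K_UNGAPPED = 0.13

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_STOP_SCORE = -4  # alignment through a stop codon is heavily penalised


def _aa_score(x: str, y: str) -> int:
    if x == "*" or y == "*":
        return _STOP_SCORE
    try:
        return int(_BLOSUM62[x, y])
    except (KeyError, IndexError):
        return -1


@dataclass(frozen=True)
class OrfStats:
    """The longest open reading frame found in a hit's frame."""

    frame: int  # one of +1,+2,+3,-1,-2,-3
    start: int  # 0-based half-open nt coords on the contig plus strand
    end: int
    has_start_codon: bool
    has_stop_codon: bool
    aa_length: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("ORF end must exceed start")


@dataclass(frozen=True)
class TriageDecision:
    contig_id: str
    pass_evalue: bool
    pass_length: bool
    pass_coverage: bool
    pass_orf: bool
    pass_cross_assembler: bool
    pass_recheck: bool
    overall: bool
    best_hit: HitRecord | None
    mean_coverage: float
    orf: OrfStats | None

    def __post_init__(self) -> None:
        expected = (self.pass_evalue and self.pass_length and
                    self.pass_coverage and self.pass_orf and
                    self.pass_cross_assembler and self.pass_recheck)
        if self.overall != expected:
            raise ValueError("overall must equal the AND of all flags")


# ---------------------------------------------------------------------------
# Host read subtraction

def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def host_subtract(reads: Sequence[SeqRecord], host_genomes: Sequence[SeqRecord],
                  k: int = 21, min_frac: float = 0.8) -> list[SeqRecord]:
    """Drop reads sharing >= ``min_frac`` of their k-mers with the host.

    Either orientation of the read may match. Reads shorter than ``k`` carry
    no k-mers and are retained. An empty host set retains everything with a
    warning.
    """
    if not host_genomes:
        logger.warning("host_subtract: empty host genome set; all reads kept")
        return list(reads)
    host: set[str] = set()
    for g in host_genomes:
        host |= _kmers(g.seq, k)
    kept = []
    for read in reads:
        nk = len(read.seq) - k + 1
        if nk <= 0:
            kept.append(read)
            continue
        fwd = sum(read.seq[i:i + k] in host for i in range(nk))
        rc = revcomp(read.seq)
        rev = sum(rc[i:i + k] in host for i in range(nk))
        if max(fwd, rev) / nk >= min_frac:
            logger.debug("host_subtract: removed %s (%d/%d host k-mers)",
                         read.id, max(fwd, rev), nk)
            continue
        kept.append(read)
    return kept


# ---------------------------------------------------------------------------
# Translated homology search (blastx-like)

def _six_frames(seq: str) -> list[tuple[int, str]]:
    """(frame, protein) for frames +1..+3 and -1..-3."""
    rc = revcomp(seq)
    frames = []
    for sign, s in ((1, seq), (-1, rc)):
        for off in range(3):
            sub = s[off:]
            sub = sub[:len(sub) - len(sub) % 3]
            if not sub:
                continue
            frames.append((sign * (off + 1), str(Seq(sub).translate())))
    return frames


def _aa_to_nt_coords(frame: int, qa_start: int, qa_end: int, nt_len: int,
                     ) -> tuple[int, int]:
    """Map aa alignment [qa_start, qa_end) in a frame to 1-based nt coords.

    Returns (q_start, q_end) with q_start > q_end for negative frames,
    following blastx convention.
    """
    off = abs(frame) - 1
    if frame > 0:
        nt0, nt1 = off + 3 * qa_start, off + 3 * qa_end  # plus strand, half-open
        return nt0 + 1, nt1
    rc0, rc1 = off + 3 * qa_start, off + 3 * qa_end      # revcomp coords
    return nt_len - rc0, nt_len - rc1 + 1


def translated_search(contig: SeqRecord, protein_refs: Sequence[SeqRecord],
                      word_size: int = 3, x_drop: int = 20,
                      evalue_max: float = 10.0) -> list[HitRecord]:
    """Six-frame translated search of a contig against protein references.

    Exact ``word_size``-aa seeds are extended ungapped in both directions
    with an X-drop of ``x_drop``; the best alignment per (reference, frame,
    diagonal) is kept and scored with ungapped Karlin-Altschul statistics
    (E = K*m*n*exp(-lambda*S), m the frame's query length in aa, n the total
    reference residues). Hits are sorted by E-value.
    """
    if len(contig.seq) < 3 * word_size:
        raise ValueError(f"contig {contig.id} shorter than one seed word")
    index: dict[str, list[tuple[int, int]]] = {}
    for ri, ref in enumerate(protein_refs):
        for p in range(len(ref.seq) - word_size + 1):
            word = ref.seq[p:p + word_size]
            if "*" in word or "X" in word:
                continue
            index.setdefault(word, []).append((ri, p))
    n_total = sum(len(r.seq) for r in protein_refs)
    frames = dict(_six_frames(contig.seq))
    hits: dict[tuple[int, int, int], tuple[int, int, int, int]] = {}
    # key (ref, frame, diagonal) -> (score, qa_start, sa_start, length)
    for frame, prot in frames.items():
        for q in range(len(prot) - word_size + 1):
            word = prot[q:q + word_size]
            for ri, s in index.get(word, ()):
                ref_seq = protein_refs[ri].seq
                score = sum(_aa_score(prot[q + t], ref_seq[s + t])
                            for t in range(word_size))
                # extend right
                best, best_r = score, word_size
                cur, t = score, word_size
                while q + t < len(prot) and s + t < len(ref_seq):
                    cur += _aa_score(prot[q + t], ref_seq[s + t])
                    t += 1
                    if cur > best:
                        best, best_r = cur, t
                    elif best - cur > x_drop:
                        break
                # extend left
                score2, best_l = best, 0
                cur, t = best, 1
                while q - t >= 0 and s - t >= 0:
                    cur += _aa_score(prot[q - t], ref_seq[s - t])
                    if cur > score2:
                        score2, best_l = cur, t
                    elif score2 - cur > x_drop:
                        break
                    t += 1
                key = (ri, frame, q - s)
                val = (score2, q - best_l, s - best_l, best_l + best_r)
                if key not in hits or val[0] > hits[key][0]:
                    hits[key] = val
    out: list[HitRecord] = []
    for (ri, frame, _diag), (score, qa, sa, length) in hits.items():
        prot = frames[frame]
        m = len(prot)
        with np.errstate(over="ignore"):
            evalue = float(K_UNGAPPED * m * n_total *
                           math.exp(-LAMBDA_UNGAPPED * score))
        if evalue > evalue_max:
            continue
        ref = protein_refs[ri]
        matches = sum(prot[qa + t] == ref.seq[sa + t] for t in range(length))
        q_start, q_end = _aa_to_nt_coords(frame, qa, qa + length,
                                          len(contig.seq))
        bitscore = (LAMBDA_UNGAPPED * score - math.log(K_UNGAPPED)) / math.log(2)
        out.append(HitRecord(
            query_id=contig.id, subject_id=ref.id,
            pct_identity=100.0 * matches / length, aln_length=length,
            mismatches=length - matches, gap_opens=0,
            q_start=q_start, q_end=q_end, s_start=sa + 1, s_end=sa + length,
            evalue=evalue, bitscore=bitscore,
        ))
    out.sort(key=lambda h: (h.evalue, -h.bitscore, h.subject_id))
    return out


def hit_frame(hit: HitRecord, contig_len: int) -> int:
    """Reading frame (+1..+3 / -1..-3) implied by a hit's nt coordinates."""
    if not hit.is_minus:
        return (hit.q_start - 1) % 3 + 1
    return -((contig_len - hit.q_start) % 3 + 1)


# ---------------------------------------------------------------------------
# Coverage, ORF completeness, cross-assembler confirmation

def mean_coverage(contig: SeqRecord | int,
                  mapped_read_lengths: Iterable[float]) -> float:
    """Mean fold depth: total mapped read bases / contig length."""
    length = contig if isinstance(contig, int) else len(contig.seq)
    if length <= 0:
        raise ValueError("zero-length contig")
    return sum(mapped_read_lengths) / length


def _orfs_in_frame(contig: SeqRecord, frame: int) -> list[OrfStats]:
    """All maximal stop-free codon runs in one frame, as plus-strand coords."""
    L = len(contig.seq)
    seq = contig.seq if frame > 0 else revcomp(contig.seq)
    off = abs(frame) - 1
    sub = seq[off:]
    sub = sub[:len(sub) - len(sub) % 3]
    codons = [sub[i:i + 3] for i in range(0, len(sub), 3)]
    orfs: list[OrfStats] = []
    run_start = 0
    for ci in range(len(codons) + 1):
        at_stop = ci < len(codons) and codons[ci] in ("TAA", "TAG", "TGA")
        at_end = ci == len(codons)
        if not (at_stop or at_end):
            continue
        if ci > run_start:
            has_stop = at_stop
            nt0 = off + 3 * run_start
            nt1 = off + 3 * (ci + (1 if has_stop else 0))
            if frame < 0:  # map from revcomp coords back to plus strand
                nt0, nt1 = L - nt1, L - nt0
            has_start = any(c == "ATG" for c in codons[run_start:ci])
            orfs.append(OrfStats(frame, nt0, nt1, has_start, has_stop,
                                 ci - run_start))
        run_start = ci + 1
    return orfs


def orf_completeness(contig: SeqRecord, hit: HitRecord,
                     min_span_frac: float = 0.8) -> tuple[OrfStats | None, bool]:
    """Longest ORF in the hit's frame and whether it is "almost complete".

    Pass iff that ORF covers >= ``min_span_frac`` of the hit's query footprint
    and carries a stop codon (start codon optional: viral contigs are often
    5'-truncated).
    """
    lo, hi = hit.q_span
    if lo < 0 or hi > len(contig.seq):
        raise ValueError(f"hit coordinates outside contig {contig.id}")
    frame = hit_frame(hit, len(contig.seq))
    orfs = _orfs_in_frame(contig, frame)
    if not orfs:
        return None, False
    orf = max(orfs, key=lambda o: (o.aa_length, -o.start))
    span = hi - lo
    overlap = max(0, min(orf.end, hi) - max(orf.start, lo))
    ok = (overlap >= min_span_frac * span) and orf.has_stop_codon
    if min_span_frac == 0:
        ok = True
    return orf, ok


def cross_assembler_confirm(set_a: Sequence[SeqRecord],
                            set_b: Sequence[SeqRecord],
                            min_ident: float = 0.98,
                            min_frac: float = 0.90) -> dict[str, bool]:
    """Confirm contigs of A by near-identity containment in some contig of B.

    A contig is confirmed iff some contig of the other set aligns locally
    (either orientation) at identity >= ``min_ident`` over >= ``min_frac`` of
    the shorter contig's length. Returns flags keyed by contig id of A.
    """
    from Bio import Align

    aligner = Align.PairwiseAligner(mode="local", match_score=1,
                                    mismatch_score=-2, open_gap_score=-3,
                                    extend_gap_score=-2)
    flags: dict[str, bool] = {}
    for a in set_a:
        confirmed = False
        for b in set_b:
            short, long_ = (a.seq, b.seq) if len(a.seq) <= len(b.seq) \
                else (b.seq, a.seq)
            for query in (short, revcomp(short)):
                aln = aligner.align(long_, query)
                if len(aln) == 0:
                    continue
                best = aln[0]
                t_seg, q_seg = best.aligned
                matches = 0
                cols = 0
                for (ts, te), (qs, qe) in zip(t_seg, q_seg):
                    cols += te - ts
                    matches += sum(long_[ts + t] == query[qs + t]
                                   for t in range(te - ts))
                if cols == 0:
                    continue
                span = q_seg[-1][1] - q_seg[0][0]
                if (matches / cols >= min_ident
                        and span >= min_frac * len(short)):
                    confirmed = True
                    break
            if confirmed:
                break
        flags[a.id] = confirmed
    return flags


# ---------------------------------------------------------------------------
# Triage

def decide(contig_id: str, contig_len: int, best_hit: HitRecord | None,
           coverage: float, orf: OrfStats | None, orf_pass: bool,
           cross_pass: bool, config: PipelineConfig,
           recheck_pass: bool = True) -> TriageDecision:
    """Combine per-criterion measurements into a decision (pure function)."""
    p_e = best_hit is not None and best_hit.evalue <= config.evalue_max
    p_len = contig_len >= config.min_contig_len
    p_cov = coverage >= config.min_coverage
    overall = p_e and p_len and p_cov and orf_pass and cross_pass and recheck_pass
    for name, flag in (("evalue", p_e), ("length", p_len), ("coverage", p_cov),
                       ("orf", orf_pass), ("cross_assembler", cross_pass),
                       ("recheck", recheck_pass)):
        if not flag:
            logger.debug("triage %s: fails %s", contig_id, name)
    return TriageDecision(contig_id, p_e, p_len, p_cov, orf_pass, cross_pass,
                          recheck_pass, overall, best_hit, coverage, orf)


def triage(candidates: Sequence[SeqRecord], hits: Sequence[HitRecord],
           mapped_read_lengths: Mapping[str, Sequence[float]],
           set_b: Sequence[SeqRecord], config: PipelineConfig,
           recheck_hits: Sequence[HitRecord] | None = None,
           is_viral_subject: Callable[[str], bool] | None = None,
           ) -> list[TriageDecision]:
    """Apply the five-criterion filter to every candidate contig.

    ``mapped_read_lengths`` maps contig id to the lengths of reads remapped to
    it (weights allowed). ``recheck_hits`` is the optional false-positive
    re-screen: a candidate is dropped when its best re-check subject is
    non-viral according to ``is_viral_subject`` (default: the subject id
    contains "virus" or "viral", case-insensitive).
    """
    by_id = {c.id: c for c in candidates}
    hits_by_query: dict[str, list[HitRecord]] = {}
    for h in hits:
        if h.query_id not in by_id:
            raise KeyError(f"hit references unknown contig {h.query_id!r}")
        hits_by_query.setdefault(h.query_id, []).append(h)
    if is_viral_subject is None:
        def is_viral_subject(s: str) -> bool:
            return "virus" in s.lower() or "viral" in s.lower()
    recheck_best: dict[str, HitRecord] = {}
    if recheck_hits is not None:
        for h in recheck_hits:
            cur = recheck_best.get(h.query_id)
            if cur is None or h.evalue < cur.evalue:
                recheck_best[h.query_id] = h
    cross = cross_assembler_confirm(candidates, set_b,
                                    config.cross_min_ident,
                                    config.cross_min_frac)
    decisions = []
    for contig in candidates:
        chits = sorted(hits_by_query.get(contig.id, []),
                       key=lambda h: (h.evalue, -h.bitscore, h.subject_id))
        best = chits[0] if chits else None
        cov = mean_coverage(contig, mapped_read_lengths.get(contig.id, ()))
        orf, orf_ok = (None, False)
        if best is not None:
            orf, orf_ok = orf_completeness(contig, best,
                                           config.min_orf_span_frac)
        recheck_ok = True
        if recheck_hits is not None and contig.id in recheck_best:
            recheck_ok = is_viral_subject(recheck_best[contig.id].subject_id)
        decisions.append(decide(contig.id, len(contig.seq), best, cov, orf,
                                orf_ok, cross.get(contig.id, False),
                                config, recheck_ok))
    return decisions
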