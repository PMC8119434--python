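"""Cryptic-species assignment from mtCOI-like contigs.

A whitefly dataset is assigned to the cryptic species of its nearest labelled
mtCOI reference, where "nearest" means smallest uncorrected p-distance on the
optimal global alignment, and the assignment is accepted only when that
divergence does not exceed the species-delimitation threshold (3.5% by
convention in the Bemisia tabaci literature; the boundary is inclusive).
Datasets whose best contig is within threshold of references from two or more
species are reported with all in-threshold labels (mixed-species samples do
occur). No substitution-model correction is applied: the 3.5% convention is
identity-based.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass

import numpy as np

from .io_formats import SeqRecord

logger = logging.getLogger("vectorvirome")

UNASSIGNED = "UNASSIGNED"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Alignment:
    """A scored global alignment; aligned strings contain '-' gaps."""

    aligned_a: str
    aligned_b: str
    score: float


@dataclass(frozen=True)
class MtcoiReference:
    species_label: str
    record: SeqRecord

    def __post_init__(self) -> None:
        if not self.species_label:
            raise ValueError("species label must be non-empty")


@dataclass(frozen=True)
class SpeciesCall:
    dataset_id: str
    contig_id: str | None
    best_reference_id: str | None
    species_label: str
    divergence: float | None
    within_threshold_labels: tuple[str, ...] = ()


def references_from_fasta(records: list[SeqRecord]) -> list[MtcoiReference]:
    """Build references from FASTA records carrying a ``species=`` tag."""
    refs = []
    for rec in records:
        label = None
        for token in rec.description.split():
            if token.startswith("species="):
                label = token.split("=", 1)[1]
        if label is None:
            raise ValueError(f"reference {rec.id!r} lacks a species= tag")
        refs.append(MtcoiReference(label, rec))
    return refs


# ---------------------------------------------------------------------------
# Needleman-Wunsch global alignment (linear gap penalty)

def _as_seq(x) -> str:
    return x.seq if isinstance(x, SeqRecord) else str(x)


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _nw_matrix(a: str, b: str, match: int, mismatch: int, gap: int) -> np.ndarray:
    """Full DP score matrix, shape (len(a)+1, len(b)+1), int32.

    Rows are vectorised: the in-row left-gap recurrence
    ``H[i,j] = max(cand[j], max_{k<j} cand[k] + gap*(j-k))`` is solved with a
    running maximum of ``cand - gap*j``.
    """
    ea, eb = _encode(a), _encode(b)
    n, m = len(ea), len(eb)
    H = np.empty((n + 1, m + 1), dtype=np.int32)
    H[0] = gap * np.arange(m + 1, dtype=np.int32)
    js = np.arange(m + 1, dtype=np.int64)
    for i in range(1, n + 1):
        sub = np.where(eb == ea[i - 1], match, mismatch).astype(np.int64)
        cand = np.empty(m + 1, dtype=np.int64)
        cand[0] = gap * i
        cand[1:] = np.maximum(H[i - 1, :-1] + sub, H[i - 1, 1:] + gap)
        H[i] = np.maximum.accumulate(cand - gap * js) + gap * js
    return H


def nw_score(a, b, match: int = 1, mismatch: int = -1, gap: int = -2) -> int:
    """Optimal global alignment score only (no traceback)."""
    sa, sb = _as_seq(a), _as_seq(b)
    if not sa or not sb:
        raise ValueError("cannot align empty sequences")
    return int(_nw_matrix(sa, sb, match, mismatch, gap)[-1, -1])


def global_align(a, b, match: int = 1, mismatch: int = -1, gap: int = -2,
                 ) -> Alignment:
    """Optimal Needleman-Wunsch global alignment under a linear gap penalty.

    Tie-breaking during traceback is deterministic: diagonal is preferred,
    then the gap consuming ``a`` (up), then the gap consuming ``b`` (left).
    """
    sa, sb = _as_seq(a), _as_seq(b)
    if not sa or not sb:
        raise ValueError("cannot align empty sequences")
    H = _nw_matrix(sa, sb, match, mismatch, gap)
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = len(sa), len(sb)
    while i > 0 or j > 0:
        here = H[i, j]
        if i > 0 and j > 0:
            s = match if sa[i - 1] == sb[j - 1] else mismatch
            if here == H[i - 1, j - 1] + s:
                out_a.append(sa[i - 1]); out_b.append(sb[j - 1])
                i -= 1; j -= 1
                continue
        if i > 0 and here == H[i - 1, j] + gap:
            out_a.append(sa[i - 1]); out_b.append("-")
            i -= 1
            continue
        out_a.append("-"); out_b.append(sb[j - 1])
        j -= 1
    return Alignment("".join(reversed(out_a)), "".join(reversed(out_b)),
                     int(H[-1, -1]))


def p_distance(aligned_a, aligned_b=None) -> float:
    """Uncorrected p-distance with pairwise deletion of gap and N columns.

    mismatches / compared columns, where any column containing '-' or 'N' in
    either string is excluded from both counts. Accepts an
    :class:`Alignment` or two equal-length aligned strings.
    """
    if aligned_b is None:
        aligned_a, aligned_b = aligned_a.aligned_a, aligned_a.aligned_b
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned strings must have equal length")
    compared = 0
    mismatches = 0
    for x, y in zip(aligned_a, aligned_b):
        if x in "-N" or y in "-N":
            continue
        compared += 1
        if x != y:
            mismatches += 1
    if compared == 0:
        raise ValueError("no comparable columns (all gap/N)")
    return mismatches / compared


# ---------------------------------------------------------------------------
# mtCOI contig search and species call

@dataclass(frozen=True)
class MtcoiCandidate:
    contig_id: str
    reference: MtcoiReference
    orientation: str  # "+" or "-"
    divergence: float
    identity: float
    alignment: Alignment


def find_mtcoi_contig(contigs: list[SeqRecord],
                      references: list[MtcoiReference],
                      min_identity: float = 0.75,
                      match: int = 1, mismatch: int = -1, gap: int = -2,
                      ) -> MtcoiCandidate | None:
    """Best (contig, reference) pair by global alignment score.

    Both contig orientations are scanned against every reference; the argmax
    by score is returned, ties broken by (contig_id, reference_id, '+').
    Returns None when the best pair's identity (1 - p-distance) falls below
    ``min_identity``: no credible mtCOI contig in the assembly. The default
    0.75 sits between the apparent identity of optimally aligned random DNA
    (about 0.6 — optimal alignment inflates chance identity well above 25%)
    and the weakest genuine congeneric mtCOI match (>= 0.8).
    """
    if not contigs or not references:
        raise ValueError("need at least one contig and one reference")
    best = None  # (score, contig_id, ref_id, orientation, contig_seq, ref)
    for contig in sorted(contigs, key=lambda r: r.id):
        for ref in sorted(references, key=lambda r: r.record.id):
            for orient, seq in (("+", contig.seq), ("-", revcomp(contig.seq))):
                score = nw_score(seq, ref.record.seq, match, mismatch, gap)
                if best is None or score > best[0]:
                    best = (score, contig.id, ref.record.id, orient, seq, ref)
    score, contig_id, ref_id, orient, seq, ref = best
    aln = global_align(seq, ref.record.seq, match, mismatch, gap)
    try:
        div = p_distance(aln)
    except ValueError:
        return None
    identity = 1.0 - div
    if identity < min_identity:
        logger.debug("best mtCOI candidate %s vs %s identity %.3f < %.3f; "
                     "no candidate", contig_id, ref_id, identity, min_identity)
        return None
    return MtcoiCandidate(contig_id, ref, orient, div, identity, aln)


def assign_species(contigs: list[SeqRecord],
                   references: list[MtcoiReference],
                   threshold: float = 0.035,
                   dataset_id: str = "dataset",
                   ) -> SpeciesCall:
    """Assign a dataset to the species of its nearest mtCOI reference.

    The call is the nearest reference's label iff divergence <= threshold
    (inclusive boundary), else UNASSIGNED. All species labels whose nearest
    reference is within threshold are reported in
    ``within_threshold_labels`` so mixed-species datasets are visible.
    """
    if not 0 < threshold < 0.2:
        raise ValueError("threshold must lie in (0, 0.2)")
    cand = find_mtcoi_contig(contigs, references)
    if cand is None:
        return SpeciesCall(dataset_id, None, None, UNASSIGNED, None)
    if cand.divergence > threshold:
        logger.debug("%s: divergence %.4f exceeds threshold %.4f",
                     dataset_id, cand.divergence, threshold)
        return SpeciesCall(dataset_id, cand.contig_id, cand.reference.record.id,
                           UNASSIGNED, cand.divergence)
    # secondary scan: which other species are also within threshold?
    contig = next(c for c in contigs if c.id == cand.contig_id)
    seq = contig.seq if cand.orientation == "+" else revcomp(contig.seq)
    labels: dict[str, float] = {}
    for ref in references:
        aln = global_align(seq, ref.record.seq)
        try:
            d = p_distance(aln)
        except ValueError:
            continue
        if d <= threshold:
            prev = labels.get(ref.species_label)
            if prev is None or d < prev:
                labels[ref.species_label] = d
    within = tuple(sorted(labels, key=lambda s: (labels[s], s)))
    return SpeciesCall(dataset_id, cand.contig_id, cand.reference.record.id,
                       cand.reference.species_label, cand.divergence, within)


# ---------------------------------------------------------------------------
# Distance tree of datasets

def mtcoi_distance_matrix(seqs: list[SeqRecord]) -> np.ndarray:
    """Pairwise p-distance matrix from global alignments of mtCOI sequences."""
    n = len(seqs)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dm[i, j] = dm[j, i] = p_distance(global_align(seqs[i], seqs[j]))
    return dm


def dataset_tree(ids: list[str], distances: np.ndarray) -> str:
    """Neighbor-joining tree on a p-distance matrix, as a newick string."""
    if len(ids) < 3:
        raise ValueError("need at least 3 datasets for a tree")
    from skbio import DistanceMatrix
    from skbio.tree import nj

    dm = DistanceMatrix(np.asarray(distances, dtype=float), ids)
    tree = nj(dm)
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()
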