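"""Per-dataset virus quantification and host-lineage association.

Relative abundance of viral contig *j* is its TPM
``a_j = (b_j/c_j) / sum_j(b_j/c_j) * 1e6`` where *b_j* is the number of
uniquely mapped fragments (single-end reads with exactly one best location
across the whole viral contig set; multi-mappers are dropped) and *c_j* the
contig length in nt. TPM sums to one million per dataset whenever any read
maps, and is invariant to uniform scaling of the counts.

Composition shares are raw-count fractions by default (TPM shares are an
option); the dominant ("core") virus of a dataset is the argmax share with a
flagged lexicographic tie-break. The association matrix counts, per virus and
species, the datasets where the virus is present (TPM above a detection
floor, default 0), and labels each virus species-specific (present in
exactly one species) or shared (present in two or more).

The built-in mapper is exact-match (zero mismatches) over both strands via a
substring index; tabular counts from an external aligner may be supplied
instead.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import SeqRecord
from .species_assign import SpeciesCall, revcomp

logger = logging.getLogger("vectorvirome")


@dataclass(frozen=True)
class Placement:
    contig_id: str
    pos: int  # 0-based start on the contig plus strand
    strand: str  # "+" or "-"


@dataclass
class MappingResult:
    """All exact-match placements per read across a contig set."""

    placements: dict[str, list[Placement]]  # read_id -> occurrences
    read_lengths: dict[str, int]

    def is_unique(self, read_id: str) -> bool:
        return len(self.placements.get(read_id, ())) == 1

    def unique_counts(self) -> dict[str, int]:
        """b_j: uniquely mapped fragment count per contig."""
        counts: dict[str, int] = {}
        for rid, places in self.placements.items():
            if len(places) == 1:
                counts[places[0].contig_id] = counts.get(places[0].contig_id, 0) + 1
        return counts

    def mapped_lengths(self) -> dict[str, list[float]]:
        """Per-contig mapped read lengths (1/k weighted for multi-mappers)."""
        out: dict[str, list[float]] = {}
        for rid, places in self.placements.items():
            if not places:
                continue
            w = 1.0 / len(places)
            for p in places:
                out.setdefault(p.contig_id, []).append(w * self.read_lengths[rid])
        return out


def build_substring_index(contigs: Sequence[SeqRecord], lengths: set[int],
                          ) -> dict[str, list[tuple[str, int]]]:
    """Index every window of the given lengths across all contig plus strands."""
    index: dict[str, list[tuple[str, int]]] = {}
    for contig in contigs:
        seq = contig.seq
        for L in lengths:
            for i in range(len(seq) - L + 1):
                index.setdefault(seq[i:i + L], []).append((contig.id, i))
    return index


def map_reads_exact(reads: Sequence[SeqRecord], contigs: Sequence[SeqRecord],
                    ) -> MappingResult:
    """Enumerate all exact occurrences of each read on either strand.

    A read placed at one location exactly is unique; reads with zero or
    multiple occurrences are excluded from unique counts.
    """
    lengths = {len(r.seq) for r in reads}
    index = build_substring_index(contigs, lengths)
    placements: dict[str, list[Placement]] = {}
    read_lengths: dict[str, int] = {}
    for read in reads:
        read_lengths[read.id] = len(read.seq)
        places = [Placement(cid, pos, "+") for cid, pos in index.get(read.seq, ())]
        rc = revcomp(read.seq)
        places += [Placement(cid, pos, "-") for cid, pos in index.get(rc, ())]
        if read.seq == rc:  # palindromic: same occurrence found twice
            places = sorted(set(places), key=lambda p: (p.contig_id, p.pos, p.strand))
        placements[read.id] = places
    return MappingResult(placements, read_lengths)


# ---------------------------------------------------------------------------
# TPM and composition

def tpm(b: Sequence[float], c: Sequence[float]) -> np.ndarray:
    """Transcripts per million: a_j = (b_j/c_j) / sum(b_j/c_j) * 1e6."""
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    if np.any(c <= 0):
        raise ValueError("all contig lengths must be positive")
    rate = b / c
    total = rate.sum()
    if total == 0:
        warnings.warn("all-zero counts: TPM defined as all-zero", stacklevel=2)
        return np.zeros_like(rate)
    return rate / total * 1e6


@dataclass(frozen=True)
class CompositionResult:
    shares: dict[str, float]
    dominant: str | None
    tie: bool
    no_reads: bool


def composition(counts: Mapping[str, float]) -> CompositionResult:
    """Percentage shares and the dominant (core) virus of one dataset."""
    total = float(sum(counts.values()))
    if total == 0:
        return CompositionResult({k: 0.0 for k in counts}, None, False, True)
    shares = {k: v / total for k, v in counts.items()}
    best = max(shares.values())
    leaders = sorted(k for k, v in shares.items() if v == best)
    return CompositionResult(shares, leaders[0], len(leaders) > 1, False)


# ---------------------------------------------------------------------------
# Association with host species

@dataclass
class AssociationMatrix:
    presence: pd.DataFrame       # viruses x species: dataset presence counts
    virus_class: dict[str, str]  # virus -> "species_specific:<label>"|"shared"|"absent"
    dominant: dict[str, tuple[str | None, float]]  # dataset -> (virus, share)


def associate(species_calls: Mapping[str, SpeciesCall | str],
              tpm_table: pd.DataFrame,
              counts_table: pd.DataFrame | None = None,
              detection_floor_tpm: float = 0.0) -> AssociationMatrix:
    """Presence-by-species matrix plus per-dataset dominant virus.

    ``tpm_table`` is datasets x viruses (TPM). Presence means TPM strictly
    above the detection floor. ``counts_table`` (same shape, raw counts) feeds
    the dominant-virus call; TPM is used when absent.
    """
    labels: dict[str, str] = {}
    for ds in tpm_table.index:
        if ds not in species_calls:
            raise KeyError(f"dataset {ds!r} missing from species calls")
        call = species_calls[ds]
        labels[ds] = call.species_label if isinstance(call, SpeciesCall) else call
    species = sorted(set(labels.values()))
    viruses = list(tpm_table.columns)
    presence = pd.DataFrame(0, index=viruses, columns=species, dtype=int)
    for ds in tpm_table.index:
        for v in viruses:
            if tpm_table.loc[ds, v] > detection_floor_tpm:
                presence.loc[v, labels[ds]] += 1
    virus_class: dict[str, str] = {}
    for v in viruses:
        present_in = [s for s in species if presence.loc[v, s] > 0]
        if not present_in:
            virus_class[v] = "absent"
        elif len(present_in) == 1:
            virus_class[v] = f"species_specific:{present_in[0]}"
        else:
            virus_class[v] = "shared"
    basis = counts_table if counts_table is not None else tpm_table
    dominant: dict[str, tuple[str | None, float]] = {}
    for ds in basis.index:
        comp = composition(basis.loc[ds].to_dict())
        share = comp.shares.get(comp.dominant, 0.0) if comp.dominant else 0.0
        dominant[ds] = (comp.dominant, share)
    return AssociationMatrix(presence, virus_class, dominant)


# ---------------------------------------------------------------------------
# PCA

@dataclass
class PcaResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_fractions: np.ndarray


def pca(abundance: pd.DataFrame, log_transform: bool = True,
        center: bool = True, n_components: int | None = None) -> PcaResult:
    """PCA of the (log10(TPM+1)-transformed, column-centered) abundance matrix.

    Computed by SVD; sign convention: the largest-magnitude loading of each
    component is positive. A constant matrix yields all-zero scores with a
    warning.
    """
    if abundance.shape[0] < 2 or abundance.shape[1] < 2:
        raise ValueError("PCA needs at least 2 datasets and 2 viruses")
    X = abundance.to_numpy(dtype=float)
    if log_transform:
        X = np.log10(X + 1.0)
    if center:
        X = X - X.mean(axis=0)
    if n_components is None:
        # full rank of the (centered) matrix so variance fractions sum to 1
        n_components = min(X.shape[0] - (1 if center else 0), X.shape[1])
        n_components = max(n_components, 1)
    if not np.any(np.abs(X) > 1e-12):
        warnings.warn("constant abundance matrix: zero variance", stacklevel=2)
        comps = [f"PC{i+1}" for i in range(n_components)]
        return PcaResult(
            pd.DataFrame(0.0, index=abundance.index, columns=comps),
            pd.DataFrame(0.0, index=abundance.columns, columns=comps),
            np.zeros(n_components))
    from sklearn.decomposition import PCA as SkPCA

    model = SkPCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(X)
    loadings = model.components_.T  # viruses x components
    for k in range(loadings.shape[1]):
        imax = int(np.argmax(np.abs(loadings[:, k])))
        if loadings[imax, k] < 0:
            loadings[:, k] *= -1
            scores[:, k] *= -1
    comps = [f"PC{i+1}" for i in range(n_components)]
    frac = model.explained_variance_ratio_
    return PcaResult(pd.DataFrame(scores, index=abundance.index, columns=comps),
                     pd.DataFrame(loadings, index=abundance.columns,
                                  columns=comps),
                     frac)


# ---------------------------------------------------------------------------
# qPCR helper

def ddct(ct_target_case: float, ct_ref_case: float,
         ct_target_ctrl: float, ct_ref_ctrl: float) -> float:
    """Relative expression by the 2^-ddCt method.

    ddCt = (Ct_target,case - Ct_ref,case) - (Ct_target,ctrl - Ct_ref,ctrl).
    """
    delta_delta = (ct_target_case - ct_ref_case) - (ct_target_ctrl - ct_ref_ctrl)
    return float(2.0 ** (-delta_delta))
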