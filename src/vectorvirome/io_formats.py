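"""Readers/writers for the external formats the pipeline touches.

FASTA, FASTQ, 12-column BLAST tabular (outfmt 6), TSV reports, newick and a
TOML run configuration. Parsers are strict: they fail fast with the offending
line number, reject duplicate ids (duplicate contig ids would corrupt count
tables downstream) and accept CRLF line endings and trailing blank lines.

No science lives here.
"""

from __future__ import annotations

import dataclasses
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd

logger = logging.getLogger("vectorvirome")

_NT_CHARS = set("ACGTN")
# Permissive amino-acid set: 20 standard + ambiguity codes + stop.
_AA_CHARS = set("ACDEFGHIKLMNPQRSTVWYBZJXUO*")

HITS_COLUMNS = [
    "query_id", "subject_id", "pct_identity", "aln_length", "mismatches",
    "gap_opens", "q_start", "q_end", "s_start", "s_end", "evalue", "bitscore",
]


class ParseError(ValueError):
    """Raised on malformed input files; message names the file and line."""


@dataclass(frozen=True)
class SeqRecord:
    """An identified sequence, the universal currency of all stages.

    ``alphabet`` is ``"nt"`` (A/C/G/T/N) or ``"aa"``.
    """

    id: str
    seq: str
    description: str = ""
    alphabet: Literal["nt", "aa"] = "nt"

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"sequence id must be a non-empty token: {self.id!r}")
        if not self.seq:
            raise ValueError(f"empty sequence for record {self.id!r}")
        allowed = _NT_CHARS if self.alphabet == "nt" else _AA_CHARS
        bad = set(self.seq) - allowed
        if bad:
            raise ValueError(
                f"record {self.id!r}: characters {sorted(bad)} invalid for "
                f"alphabet {self.alphabet!r}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class HitRecord:
    """One translated-homology alignment row (BLAST outfmt 6 semantics).

    Query coordinates are 1-based inclusive nucleotide positions on the query
    plus strand; ``q_start > q_end`` signals a minus-strand (negative frame)
    hit, as in blastx output. Subject coordinates are 1-based amino-acid
    positions.
    """

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.q_start < 1 or self.q_end < 1:
            raise ValueError("query coordinates are 1-based and must be >= 1")
        if self.evalue < 0:
            raise ValueError("evalue must be non-negative")
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError("pct_identity must lie in [0, 100]")

    @property
    def is_minus(self) -> bool:
        return self.q_start > self.q_end

    @property
    def q_span(self) -> tuple[int, int]:
        """Hit footprint on the query plus strand, 0-based half-open."""
        lo, hi = sorted((self.q_start, self.q_end))
        return lo - 1, hi


@dataclass
class PipelineConfig:
    """Thresholds and knobs for a full run; defaults are the published ones."""

    evalue_max: float = 1e-20
    min_coverage: float = 20.0
    min_contig_len: int = 500
    species_divergence_max: float = 0.035
    srna_len_min: int = 18
    srna_len_max: int = 30
    min_orf_span_frac: float = 0.8
    cross_min_ident: float = 0.98
    cross_min_frac: float = 0.90
    detection_floor_tpm: float = 0.0
    srna_min_reads: int = 100
    rng_seed: int = 0
    input_dir: str = ""
    output_dir: str = ""

    def __post_init__(self) -> None:
        for name in ("evalue_max", "min_coverage", "min_contig_len",
                     "species_divergence_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.srna_len_min > self.srna_len_max:
            raise ValueError("srna_len_min must be <= srna_len_max")


def load_config(path: str | Path) -> PipelineConfig:
    """Load a TOML config; unknown keys are rejected."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ParseError(f"{path}: unknown config keys {sorted(unknown)}")
    return PipelineConfig(**data)


# ---------------------------------------------------------------------------
# FASTA / FASTQ

def _infer_alphabet(seq: str) -> Literal["nt", "aa"]:
    return "nt" if set(seq) <= _NT_CHARS else "aa"


def read_fasta(path: str | Path, alphabet: Literal["nt", "aa", "auto"] = "auto",
               ) -> list[SeqRecord]:
    """Parse a FASTA file into SeqRecords, order preserved.

    Sequences are uppercased with whitespace stripped. Malformed headers,
    empty records and duplicate ids raise :class:`ParseError` naming the line.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        seq = "".join(chunks).upper()
        if not seq:
            raise ParseError(f"{path}:{header_line}: record {header!r} has an "
                             "empty sequence")
        rid = header.split()[0]
        desc = header[len(rid):].strip()
        if rid in seen:
            raise ParseError(f"{path}:{header_line}: duplicate id {rid!r}")
        seen.add(rid)
        alpha = _infer_alphabet(seq) if alphabet == "auto" else alphabet
        try:
            records.append(SeqRecord(rid, seq, desc, alpha))
        except ValueError as exc:
            raise ParseError(f"{path}:{header_line}: {exc}") from exc

    with open(path, encoding="ascii") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\r\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                header_line = lineno
                chunks = []
                if not header:
                    raise ParseError(f"{path}:{lineno}: empty FASTA header")
            else:
                if header is None:
                    raise ParseError(f"{path}:{lineno}: sequence data before "
                                     "first header")
                chunks.append("".join(line.split()))
    flush()
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path,
                width: int = 70) -> None:
    with open(path, "w", encoding="ascii", newline="\n") as fh:
        for rec in records:
            head = f">{rec.id} {rec.description}".rstrip()
            fh.write(head + "\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i:i + width] + "\n")


def read_fastq(path: str | Path) -> list[tuple[SeqRecord, str]]:
    """Parse 4-line-block FASTQ into (SeqRecord, quality string) pairs."""
    out: list[tuple[SeqRecord, str]] = []
    seen: set[str] = set()
    with open(path, encoding="ascii") as fh:
        lines = [ln.rstrip("\r\n") for ln in fh]
    while lines and not lines[-1].strip():
        lines.pop()
    if len(lines) % 4 != 0:
        raise ParseError(f"{path}: truncated FASTQ (line count {len(lines)} "
                         "not a multiple of 4)")
    for i in range(0, len(lines), 4):
        head, seq, plus, qual = lines[i:i + 4]
        lineno = i + 1
        if not head.startswith("@"):
            raise ParseError(f"{path}:{lineno}: expected '@' header")
        if not plus.startswith("+"):
            raise ParseError(f"{path}:{lineno + 2}: expected '+' separator")
        if len(seq) != len(qual):
            raise ParseError(f"{path}:{lineno + 3}: quality length "
                             f"{len(qual)} != sequence length {len(seq)}")
        rid = head[1:].split()[0] if head[1:].strip() else ""
        if not rid:
            raise ParseError(f"{path}:{lineno}: empty read id")
        if rid in seen:
            raise ParseError(f"{path}:{lineno}: duplicate id {rid!r}")
        seen.add(rid)
        try:
            rec = SeqRecord(rid, seq.upper(), head[1 + len(rid):].strip(), "nt")
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
        out.append((rec, qual))
    return out


def write_fastq(reads: Iterable[tuple[SeqRecord, str]], path: str | Path) -> None:
    with open(path, "w", encoding="ascii", newline="\n") as fh:
        for rec, qual in reads:
            if len(qual) != len(rec.seq):
                raise ValueError(f"read {rec.id}: quality/sequence length mismatch")
            fh.write(f"@{rec.id}\n{rec.seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# BLAST tabular (outfmt 6)

def read_hits_tab(path: str | Path) -> list[HitRecord]:
    """Parse a 12-column tab-separated hit table (BLAST outfmt 6 order)."""
    hits: list[HitRecord] = []
    with open(path, encoding="ascii") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\r\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 12:
                raise ParseError(f"{path}:{lineno}: expected 12 columns, "
                                 f"got {len(cols)}")
            try:
                hits.append(HitRecord(
                    query_id=cols[0], subject_id=cols[1],
                    pct_identity=float(cols[2]), aln_length=int(cols[3]),
                    mismatches=int(cols[4]), gap_opens=int(cols[5]),
                    q_start=int(cols[6]), q_end=int(cols[7]),
                    s_start=int(cols[8]), s_end=int(cols[9]),
                    evalue=float(cols[10]), bitscore=float(cols[11]),
                ))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return hits


def write_hits_tab(hits: Iterable[HitRecord], path: str | Path) -> None:
    with open(path, "w", encoding="ascii", newline="\n") as fh:
        for h in hits:
            fh.write("\t".join([
                h.query_id, h.subject_id, f"{h.pct_identity:.1f}",
                str(h.aln_length), str(h.mismatches), str(h.gap_opens),
                str(h.q_start), str(h.q_end), str(h.s_start), str(h.s_end),
                f"{h.evalue:.6g}", f"{h.bitscore:.6g}",
            ]) + "\n")


# ---------------------------------------------------------------------------
# Result tables

_TABLE_FILES = {
    "species_calls": "species_calls.tsv",
    "triage": "triage_report.tsv",
    "abundance": "abundance.tsv",
    "composition": "composition.tsv",
    "association": "association_matrix.tsv",
    "pca_scores": "pca_scores.tsv",
    "srna_profile": "profile.tsv",
    "five_prime": "five_prime.tsv",
    "depth": "depth.tsv",
    "hotspots": "hotspots.tsv",
    "classification": "classification.tsv",
}


def write_tables(results: dict, out_dir: str | Path) -> list[Path]:
    """Write every recognised result to ``out_dir``; byte-stable.

    ``results`` maps result names to pandas DataFrames (written as TSV with
    ``%.6g`` floats), plus the special keys ``passing_contigs`` (SeqRecords,
    written as FASTA) and ``tree_newick`` (a newick string).
    Empty DataFrames yield headers-only TSVs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for key, fname in _TABLE_FILES.items():
        if key not in results:
            continue
        df: pd.DataFrame = results[key]
        path = out_dir / fname
        df.to_csv(path, sep="\t", index=False, float_format="%.6g",
                  lineterminator="\n")
        written.append(path)
    if "passing_contigs" in results:
        path = out_dir / "passing_contigs.fasta"
        write_fasta(results["passing_contigs"], path)
        written.append(path)
    if "tree_newick" in results:
        path = out_dir / "mtcoi_tree.nwk"
        with open(path, "w", encoding="ascii", newline="\n") as fh:
            fh.write(results["tree_newick"].rstrip() + "\n")
        written.append(path)
    for path in written:
        logger.debug("wrote %s", path)
    return written
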