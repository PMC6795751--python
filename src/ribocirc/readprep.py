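"""Ribo-seq read cleaning and contaminant removal.

Ribosome-protected fragments (RPFs) arrive as short (~25-35 nt) single-end
reads carrying the usual library artifacts: 3' adapter read-through and
degraded base qualities.  This module (1) trims adapters and low-quality
tails, (2) removes reads that align to an rRNA reference, and (3) removes
reads perfectly explained by the linear genome.  What survives is the set of
"final unique" Ribo-seq reads: the only reads that can plausibly testify to
translation across a back-splice junction, since a junction-spanning read
has no contiguous match in the linear genome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, TextIO

log = logging.getLogger(__name__)

PHRED_OFFSET = 33  # Sanger encoding; other dialects are rejected at parse time
_VALID_BASES = frozenset("ACGTN")


class ReadError(ValueError):
    """Raised for malformed reads or FASTQ records."""


@dataclass(frozen=True)
class Read:
    """A single-end read: identifier, bases over {A,C,G,T,N}, Phred scores."""

    id: str
    seq: str
    qual: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.qual) != len(self.seq):
            raise ReadError(
                f"read {self.id!r}: quality length {len(self.qual)} != "
                f"sequence length {len(self.seq)}"
            )
        if not self.seq:
            raise ReadError(f"read {self.id!r}: empty sequence")
        if not _VALID_BASES.issuperset(self.seq):
            bad = set(self.seq) - _VALID_BASES
            raise ReadError(f"read {self.id!r}: invalid bases {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class TrimParams:
    """Adapter/quality trimming thresholds (single-end defaults).

    The sliding-window rule scans ``window_len``-base windows from the 5'
    end and truncates the read at the start of the first window whose mean
    Phred quality falls below ``window_minq``.
    """

    adapters: tuple[str, ...] = ("AGATCGGAAGAGC",)  # TruSeq universal
    window_len: int = 4
    window_minq: float = 15.0
    leading_q: int = 3
    trailing_q: int = 3
    min_len: int = 20
    min_adapter_overlap: int = 7
    max_adapter_mismatch: int = 1

    def __post_init__(self) -> None:
        if self.min_len < 1:
            raise ValueError("min_len must be >= 1")
        for name in ("window_len", "window_minq", "leading_q", "trailing_q"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


# ---------------------------------------------------------------------------
# trimming
# ---------------------------------------------------------------------------

def _adapter_clip_pos(seq: str, params: TrimParams) -> int:
    """Leftmost position where an adapter prefix overlaps the read suffix.

    A hit requires overlap length >= min_adapter_overlap and at most
    max_adapter_mismatch mismatches; returns len(seq) when no hit.
    """
    n = len(seq)
    for pos in range(0, n - params.min_adapter_overlap + 1):
        suffix_len = n - pos
        for adapter in params.adapters:
            ov = min(suffix_len, len(adapter))
            if ov < params.min_adapter_overlap:
                continue
            mm = 0
            for a, b in zip(seq[pos:pos + ov], adapter[:ov]):
                if a != b:
                    mm += 1
                    if mm > params.max_adapter_mismatch:
                        break
            else:
                return pos
    return n


def _trim_pass(seq: str, qual: list[int], params: TrimParams) -> tuple[str, list[int]]:
    """One application of adapter clip + quality trims."""
    # 1. adapter clip
    cut = _adapter_clip_pos(seq, params)
    seq, qual = seq[:cut], qual[:cut]

    # 2. leading / trailing low-quality bases
    lo = 0
    while lo < len(qual) and qual[lo] < params.leading_q:
        lo += 1
    hi = len(qual)
    while hi > lo and qual[hi - 1] < params.trailing_q:
        hi -= 1
    seq, qual = seq[lo:hi], qual[lo:hi]

    # 3. sliding window from the 5' end: truncate at first failing window
    w = params.window_len
    if w > 0:
        for start in range(0, len(qual) - w + 1):
            if sum(qual[start:start + w]) / w < params.window_minq:
                seq, qual = seq[:start], qual[:start]
                break
    return seq, qual


def trim_read(read: Read, params: TrimParams | None = None) -> Read | None:
    """Adapter-clip and quality-trim one read; None if it falls below min_len.

    Steps, in order: adapter clip; leading/trailing per-base quality trim;
    5'-to-3' sliding-window mean-quality truncation; length filter.
    Sequence and qualities are trimmed in lockstep.  The step sequence is
    repeated until it reaches a fixpoint (truncation can expose a new,
    shorter adapter overlap), which makes trimming idempotent.
    """
    params = params or TrimParams()
    seq, qual = read.seq, list(read.qual)
    while seq:
        new_seq, new_qual = _trim_pass(seq, qual, params)
        if new_seq == seq:
            break
        seq, qual = new_seq, new_qual

    # 4. length filter
    if len(seq) < params.min_len:
        return None
    return Read(read.id, seq, tuple(qual))


def trim_reads(reads: Iterable[Read], params: TrimParams | None = None) -> list[Read]:
    """Trim a batch of reads, dropping those below the length floor."""
    params = params or TrimParams()
    out = []
    n_in = 0
    for read in reads:
        n_in += 1
        trimmed = trim_read(read, params)
        if trimmed is not None:
            out.append(trimmed)
    log.info("trim: %d reads in, %d surviving", n_in, len(out))
    return out


# ---------------------------------------------------------------------------
# reference-based filtering
# ---------------------------------------------------------------------------

def filter_by_reference(
    reads: list[Read],
    index,
    max_mismatch: int,
    keep_matching: bool = False,
    label: str = "reference",
) -> list[Read]:
    """Keep or drop reads that have a full-length alignment to a reference.

    ``index`` is a :class:`ribocirc.junctionmap.RefIndex`.  Both strands are
    searched; an alignment is any gap-free full-length placement with at
    most ``max_mismatch`` substitutions.  With ``keep_matching=False``
    (depletion mode, the default) every read with such an alignment is
    dropped: used with max_mismatch=2 against rRNA, and with max_mismatch=0
    against the linear genome so that only reads the genome cannot
    perfectly explain remain.  Order and multiplicity of survivors mirror
    the input.
    """
    from . import junctionmap  # local import: modules are peers

    if len(index.ref) == 0:
        raise ValueError("empty reference")
    out = []
    for read in reads:
        hits = junctionmap.align_read(
            read, index, max_mismatch=max_mismatch, first_only=True
        )
        matched = bool(hits)
        if matched == keep_matching:
            out.append(read)
    log.info(
        "filter[%s, mm<=%d, keep_matching=%s]: %d reads in, %d surviving",
        label, max_mismatch, keep_matching, len(reads), len(out),
    )
    return out


# ---------------------------------------------------------------------------
# FASTQ I/O (4-line records, Sanger +33 qualities)
# ---------------------------------------------------------------------------

def parse_fastq(handle: TextIO) -> Iterator[Read]:
    """Parse 4-line FASTQ records into Read objects; +33 qualities only."""
    from Bio import SeqIO

    for rec in SeqIO.parse(handle, "fastq"):  # Biopython enforces Sanger +33
        qual = tuple(rec.letter_annotations["phred_quality"])
        yield Read(rec.id, str(rec.seq).upper(), qual)


def read_fastq(path) -> list[Read]:
    with open(path) as fh:
        return list(parse_fastq(fh))


def write_fastq(reads: Iterable[Read], handle: TextIO) -> int:
    n = 0
    for read in reads:
        qline = "".join(chr(q + PHRED_OFFSET) for q in read.qual)
        handle.write(f"@{read.id}\n{read.seq}\n+\n{qline}\n")
        n += 1
    return n
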