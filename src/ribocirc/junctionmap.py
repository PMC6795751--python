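"""Gap-free read alignment to the virtual genome and RMRJ extraction.

The aligner is a deliberately simple seed-and-verify scheme with a full
sensitivity guarantee.  A read placed with at most m substitutions must,
by the pigeonhole principle, contain at least one of m+1 disjoint chunks
matching the reference exactly; each chunk's leading k-mer is looked up in
an exact-location table and every candidate offset is verified end to end.
Alignments are strictly gap-free and may not touch an N base, which
confines every placement to a single doubled circRNA unit (the N spacers
are longer than any read).

A read whose placement spans a unit's junction — at least ``min_overhang``
bases on each side — is junction-spanning evidence of translation across
the back-splice.  Per circRNA, the junction-spanning placements are
counted (NMJ, number of mapped reads on the junction); when NMJ exceeds
the threshold (default: strictly greater than 3) their union interval is
emitted as the RMRJ (read-mapped region on the junction), the sequence
segment that is subsequently classified for coding potential.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .pseudoref import VirtualGenome, Unit
from .readprep import Read

log = logging.getLogger(__name__)

DEFAULT_SEED_LEN = 12
DEFAULT_MAX_MISMATCH = 2
DEFAULT_NMJ_MIN = 3      # an RMRJ requires NMJ strictly greater than this
DEFAULT_MIN_OVERHANG = 1

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# indexing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RefIndex:
    """Exact k-mer location table over a reference sequence.

    Every k-mer of the reference that is free of N is retrievable with all
    of its start positions.
    """

    ref: str
    k: int
    table: dict

    def positions(self, kmer: str) -> Sequence[int]:
        return self.table.get(kmer, ())


def build_index(ref: str, k: int = DEFAULT_SEED_LEN) -> RefIndex:
    if not 1 <= k <= 32:
        raise ValueError(f"seed length k={k} outside [1, 32]")
    if k > len(ref):
        raise ValueError(f"seed length k={k} exceeds reference length {len(ref)}")
    table: dict[str, list[int]] = {}
    ref = ref.upper()
    for i in range(len(ref) - k + 1):
        kmer = ref[i:i + k]
        if "N" in kmer:
            continue
        table.setdefault(kmer, []).append(i)
    return RefIndex(ref, k, {km: tuple(pos) for km, pos in table.items()})


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class Alignment:
    """A gap-free full-length placement of a read on the reference."""

    start: int
    strand: str  # '+' sorts before '-'
    end: int
    mismatches: int
    read_id: str = ""

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


def _verify(ref: str, seq: str, s: int, max_mismatch: int) -> int | None:
    """Mismatch count of seq laid at ref[s:s+len(seq)], or None on reject.

    Any N in the overlapped reference window invalidates the placement;
    an N in the read never matches anything.
    """
    window = ref[s:s + len(seq)]
    if "N" in window:
        return None
    mm = 0
    for a, b in zip(window, seq):
        if a != b or b == "N":
            mm += 1
            if mm > max_mismatch:
                return None
    return mm


def _scan_offsets(ref: str, seq: str, max_mismatch: int) -> list[tuple[int, int]]:
    """Brute sliding comparison of seq against every offset (one strand).

    Fallback path for reads too short to carry max_mismatch+1 seed chunks;
    vectorised so depletion filtering against small references stays fast.
    """
    n, m = len(ref), len(seq)
    if m > n:
        return []
    ref_a = np.frombuffer(ref.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(ref_a, m)
    seq_a = np.frombuffer(seq.encode(), dtype=np.uint8)
    mism = (windows != seq_a).sum(axis=1) + (windows == ord("N")).sum(axis=1) \
        + ((seq_a == ord("N")) & (windows == seq_a)).sum(axis=1)
    hits = np.nonzero(mism <= max_mismatch)[0]
    out = []
    for s in hits:
        mm = _verify(ref, seq, int(s), max_mismatch)
        if mm is not None:
            out.append((int(s), mm))
    return out


def _pigeonhole_offsets(index: RefIndex, seq: str, max_mismatch: int) -> list[tuple[int, int]]:
    """Seed-and-verify on one strand; requires len(seq) >= (m+1) * k."""
    ref, k = index.ref, index.k
    n_chunks = max_mismatch + 1
    m = len(seq)
    # chunk starts partition the read into n_chunks pieces, each >= k long
    bounds = [round(i * m / n_chunks) for i in range(n_chunks + 1)]
    candidates: set[int] = set()
    for i in range(n_chunks):
        chunk_start = bounds[i]
        for pos in index.positions(seq[chunk_start:chunk_start + k]):
            s = pos - chunk_start
            if 0 <= s <= len(ref) - m:
                candidates.add(s)
    out = []
    for s in sorted(candidates):
        mm = _verify(ref, seq, s, max_mismatch)
        if mm is not None:
            out.append((s, mm))
    return out


def align_read(
    read: Read | str,
    index: RefIndex,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    first_only: bool = False,
) -> list[Alignment]:
    """All gap-free full-length placements of a read, both strands.

    Placements have at most ``max_mismatch`` substitutions and never
    overlap an N base of the reference.  Sensitivity is complete: when the
    read is long enough to carry max_mismatch+1 disjoint seed chunks of
    the index's k, pigeonhole seeding finds every placement; shorter reads
    fall back to a full scan.  Output is deduplicated and sorted by
    (start, strand); with ``first_only`` the search stops at the first hit
    (existence queries for depletion filtering).
    """
    seq = read.seq if isinstance(read, Read) else read
    read_id = read.id if isinstance(read, Read) else ""
    if len(seq) < index.k:
        log.warning("read %r shorter than seed length %d: skipped", read_id, index.k)
        return []
    use_pigeonhole = len(seq) >= (max_mismatch + 1) * index.k
    results: list[Alignment] = []
    for strand, oriented in (("+", seq), ("-", revcomp(seq))):
        if use_pigeonhole:
            hits = _pigeonhole_offsets(index, oriented, max_mismatch)
        else:
            hits = _scan_offsets(index.ref, oriented, max_mismatch)
        for s, mm in hits:
            results.append(Alignment(s, strand, s + len(seq), mm, read_id))
            if first_only:
                return sorted(set(results))
    return sorted(set(results))


# ---------------------------------------------------------------------------
# unit assignment and junction logic
# ---------------------------------------------------------------------------

def spans_junction(aln: Alignment, junction: int,
                   min_overhang: int = DEFAULT_MIN_OVERHANG) -> bool:
    """True iff the placement has >= min_overhang bases on each side of J."""
    return aln.start <= junction - min_overhang and aln.end >= junction + min_overhang


@dataclass(frozen=True)
class Placement:
    """A read's single resolved placement inside one doubled unit."""

    read_id: str
    unit: Unit
    alignment: Alignment
    spanning: bool


def assign_to_units(
    alns_by_read: dict[str, list[Alignment]],
    vg: VirtualGenome,
    min_overhang: int = DEFAULT_MIN_OVERHANG,
) -> list[Placement]:
    """Resolve each read to at most one placement in one unit.

    Reads hitting two or more distinct circRNA units are ambiguous and
    discarded.  Within a single doubled unit the tandem duplication gives
    every non-junction placement a shadow at s +/- L; such duplicates are
    collapsed to the junction-spanning placement when one exists, else to
    the leftmost (ties on start broken toward the + strand).
    """
    placements: list[Placement] = []
    for read_id in alns_by_read:
        alns = alns_by_read[read_id]
        by_unit: dict[str, list[Alignment]] = {}
        for aln in alns:
            unit = vg.unit_of(aln.start)
            if unit is None or aln.end > unit.end:
                # cannot happen for N-free alignments with spacer >= read len
                continue
            by_unit.setdefault(unit.circ_id, []).append(aln)
        if len(by_unit) != 1:
            continue  # unplaced or ambiguous across units
        (circ_id, unit_alns), = by_unit.items()
        unit = vg.by_id(circ_id)
        spanning = sorted(a for a in unit_alns
                          if spans_junction(a, unit.junction, min_overhang))
        # a spanning placement's shadow lies outside the unit, so no two
        # spanning placements can be shadows of each other
        starts = [a.start for a in spanning]
        assert not any(b - a == unit.length for a in starts for b in starts), \
            "junction-spanning shadow pair inside one unit"
        if spanning:
            chosen, is_span = spanning[0], True
        else:
            chosen, is_span = min(unit_alns), False
        placements.append(Placement(read_id, unit, chosen, is_span))
    return placements


@dataclass(frozen=True)
class RMRJ:
    """Read-mapped region on a junction: merged junction-spanning interval."""

    circ_id: str
    start: int
    end: int
    nmj: int
    seq: str
    junction_offset: int  # junction position within seq

    def __post_init__(self) -> None:
        assert self.seq and "N" not in self.seq, "RMRJ sequence contains N"
        assert 0 < self.junction_offset < len(self.seq)


def compute_rmrjs(
    placements: Iterable[Placement],
    vg: VirtualGenome,
    nmj_min: int = DEFAULT_NMJ_MIN,
    min_overhang: int = DEFAULT_MIN_OVERHANG,
    plus_strand_only: bool = False,
    deduplicate: bool = False,
) -> list[RMRJ]:
    """Merge junction-spanning placements per circRNA into RMRJs.

    NMJ counts the junction-spanning placements (both strands by default;
    ``deduplicate`` collapses identical intervals, e.g. PCR duplicates).
    An RMRJ is emitted only when NMJ > nmj_min; its interval is the union
    [min start, max end) of the spanning placements — these all contain
    the junction, so the union is one contiguous junction-covering
    interval.  Output sorted by circ_id.
    """
    spanning: dict[str, list[Alignment]] = {}
    for p in placements:
        if not p.spanning:
            continue
        if plus_strand_only and p.alignment.strand == "-":
            continue
        spanning.setdefault(p.unit.circ_id, []).append(p.alignment)
    out: list[RMRJ] = []
    for circ_id in sorted(spanning):
        alns = spanning[circ_id]
        if deduplicate:
            seen = {(a.start, a.end, a.strand) for a in alns}
            nmj = len(seen)
        else:
            nmj = len(alns)
        if nmj <= nmj_min:
            continue
        unit = vg.by_id(circ_id)
        s = min(a.start for a in alns)
        e = max(a.end for a in alns)
        seq = vg.layout[s:e]
        out.append(RMRJ(circ_id, s, e, nmj, seq, unit.junction - s))
    return out


# ---------------------------------------------------------------------------
# convenience driver and I/O
# ---------------------------------------------------------------------------

def effective_seed_len(read_lengths: Iterable[int], k: int, max_mismatch: int) -> int:
    """Largest seed length <= k for which pigeonhole seeding covers all reads."""
    min_len = min(read_lengths, default=k * (max_mismatch + 1))
    return max(4, min(k, min_len // (max_mismatch + 1)))


def map_reads(
    reads: Iterable[Read],
    vg: VirtualGenome,
    k: int = DEFAULT_SEED_LEN,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    min_overhang: int = DEFAULT_MIN_OVERHANG,
) -> tuple[dict[str, list[Alignment]], list[Placement]]:
    """Align reads to the virtual genome and resolve unit placements.

    The seed length is capped so that even the shortest read can be split
    into max_mismatch+1 seed chunks, keeping the sensitivity guarantee
    without falling back to full scans.
    """
    reads = list(reads)
    k = effective_seed_len((len(r) for r in reads), k, max_mismatch)
    index = build_index(vg.layout, k)
    alns_by_read: dict[str, list[Alignment]] = {}
    n = 0
    for read in reads:
        n += 1
        alns = align_read(read, index, max_mismatch)
        if alns:
            alns_by_read[read.id] = alns
    placements = assign_to_units(alns_by_read, vg, min_overhang)
    log.info("map: %d reads in, %d aligned, %d placed",
             n, len(alns_by_read), len(placements))
    return alns_by_read, placements


def write_sam(placements: Iterable[Placement], vg: VirtualGenome, handle,
              reads_by_id: dict[str, Read] | None = None,
              record_id: str = "virtual_genome") -> None:
    """Emit resolved placements as SAM (1-based POS, NM mismatch tag)."""
    handle.write("@HD\tVN:1.6\tSO:unsorted\n")
    handle.write(f"@SQ\tSN:{record_id}\tLN:{len(vg.layout)}\n")
    for p in sorted(placements, key=lambda p: (p.alignment.start, p.read_id)):
        a = p.alignment
        length = a.end - a.start
        flag = 16 if a.strand == "-" else 0
        read = reads_by_id.get(p.read_id) if reads_by_id else None
        if read is not None:
            seq = read.seq if a.strand == "+" else revcomp(read.seq)
            qual = "".join(chr(q + 33) for q in
                           (read.qual if a.strand == "+" else read.qual[::-1]))
        else:
            seq, qual = vg.layout[a.start:a.end], "*"
        handle.write(
            f"{p.read_id}\t{flag}\t{record_id}\t{a.start + 1}\t255\t{length}M\t"
            f"*\t0\t0\t{seq}\t{qual}\tNM:i:{a.mismatches}\n"
        )


def placements_from_sam(path, vg: VirtualGenome,
                        min_overhang: int = DEFAULT_MIN_OVERHANG) -> list[Placement]:
    """Adopt externally produced SAM/BAM alignments against the layout.

    Only gap-free (single M cigar) records are accepted; downstream
    contracts (unit confinement, junction spanning) are re-derived here.
    """
    import pysam

    alns_by_read: dict[str, list[Alignment]] = {}
    with pysam.AlignmentFile(str(path), check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.cigartuples is None:
                continue
            if len(rec.cigartuples) != 1 or rec.cigartuples[0][0] != 0:
                continue  # not gap-free full-length
            strand = "-" if rec.is_reverse else "+"
            nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            aln = Alignment(rec.reference_start, strand,
                            rec.reference_end, int(nm), rec.query_name)
            alns_by_read.setdefault(rec.query_name, []).append(aln)
    return assign_to_units(alns_by_read, vg, min_overhang)


def write_rmrj_fasta(rmrjs: Iterable[RMRJ], handle) -> None:
    for r in rmrjs:
        handle.write(f">{r.circ_id}\n{r.seq}\n")


def write_rmrj_table(rmrjs: Iterable[RMRJ], handle) -> None:
    handle.write("circ_id\tstart\tend\tnmj\tjunction_offset\n")
    for r in rmrjs:
        handle.write(f"{r.circ_id}\t{r.start}\t{r.end}\t{r.nmj}\t{r.junction_offset}\n")
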