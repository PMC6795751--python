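"""Junction-centered pseudo-reference ("virtual genome") construction.

A circRNA is covalently closed, so reads produced from the ribosome
transiting its back-splice junction have no contiguous match in the linear
transcriptome.  To make those reads mappable with an ordinary gap-free
aligner, each candidate circRNA sequence is duplicated in tandem — the
back-splice junction then sits exactly at the midpoint of the doubled unit
— and units are concatenated with runs of N so that no short read can
align across two different circRNAs.  The unit table keeps the inverse
coordinate map from the layout back to circRNA (monomer) space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, TextIO

log = logging.getLogger(__name__)

DEFAULT_SPACER = 100  # N bases between units; must exceed the read length

SPACER = "spacer"  # sentinel returned by locate() for positions inside N runs


@dataclass(frozen=True)
class CircRNA:
    """A candidate circRNA: full monomer sequence on its transcribed strand.

    The sequence is given in linear form; position 0 is the first base
    after the back-splice, so the junction lies between base L-1 and base 0
    of the circle.
    """

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"circRNA {self.id!r}: empty sequence")

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Unit:
    """One doubled circRNA inside the layout.

    offset: 0-based start of the unit; the unit occupies [offset, offset+2L).
    junction: layout index J with the back-splice between layout[J-1] and
    layout[J]; always offset + L (the unit midpoint).
    """

    circ_id: str
    offset: int
    length: int

    @property
    def junction(self) -> int:
        return self.offset + self.length

    @property
    def end(self) -> int:
        return self.offset + 2 * self.length


@dataclass(frozen=True)
class VirtualGenome:
    layout: str
    spacer: int
    units: tuple[Unit, ...]

    def unit_of(self, pos: int) -> Unit | None:
        """The unit containing layout position pos, or None (spacer)."""
        if not 0 <= pos < len(self.layout):
            raise ValueError(f"position {pos} outside layout of length {len(self.layout)}")
        import bisect
        offsets = [u.offset for u in self.units]
        i = bisect.bisect_right(offsets, pos) - 1
        if i >= 0 and pos < self.units[i].end:
            return self.units[i]
        return None

    def by_id(self, circ_id: str) -> Unit:
        for u in self.units:
            if u.circ_id == circ_id:
                return u
        raise KeyError(circ_id)


def build_virtual_genome(
    circs: Iterable[CircRNA], spacer: int = DEFAULT_SPACER,
    max_read_len: int = 50,
) -> VirtualGenome:
    """Concatenate doubled circRNA sequences with N-spacers.

    layout = seq_1 seq_1 N^spacer seq_2 seq_2 N^spacer ... (no leading or
    trailing padding).  A spacer shorter than the longest expected read
    would let one alignment bridge two circRNAs, so a warning is logged
    when spacer < max_read_len.
    """
    circs = list(circs)
    if not circs:
        raise ValueError("empty circRNA list")
    ids = [c.id for c in circs]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate circRNA ids: {dup}")
    if spacer < max_read_len:
        log.warning(
            "spacer %d is shorter than the expected read-length bound %d; "
            "reads may align across units", spacer, max_read_len,
        )
    parts: list[str] = []
    units: list[Unit] = []
    offset = 0
    for i, circ in enumerate(circs):
        if i > 0:
            parts.append("N" * spacer)
            offset += spacer
        parts.append(circ.seq * 2)
        units.append(Unit(circ.id, offset, circ.length))
        offset += 2 * circ.length
    return VirtualGenome("".join(parts), spacer, tuple(units))


def locate(vg: VirtualGenome, pos: int):
    """Map a layout position to (circ_id, monomer position) or the spacer marker.

    Positions in the second copy of a unit fold back onto the monomer via
    (pos - offset) mod L.
    """
    unit = vg.unit_of(pos)  # raises on out-of-range
    if unit is None:
        return SPACER
    return unit.circ_id, (pos - unit.offset) % unit.length


# ---------------------------------------------------------------------------
# output (FASTA layout, BED junction table, TSV unit map)
# ---------------------------------------------------------------------------

def write_fasta(vg: VirtualGenome, handle: TextIO, per_unit: bool = False,
                record_id: str = "virtual_genome", width: int = 70) -> None:
    """Write the layout as FASTA: one record for the whole layout (default)
    or one doubled-unit record per circRNA."""
    def emit(name: str, seq: str) -> None:
        handle.write(f">{name}\n")
        for i in range(0, len(seq), width):
            handle.write(seq[i:i + width] + "\n")

    if per_unit:
        for u in vg.units:
            emit(u.circ_id, vg.layout[u.offset:u.end])
    else:
        emit(record_id, vg.layout)


def write_junction_bed(vg: VirtualGenome, handle: TextIO,
                       record_id: str = "virtual_genome") -> None:
    """Junctions as 1-bp BED features [J-1, J) on the whole-layout record."""
    for u in vg.units:
        handle.write(f"{record_id}\t{u.junction - 1}\t{u.junction}\t{u.circ_id}\n")


def write_unit_table(vg: VirtualGenome, handle: TextIO) -> None:
    handle.write("circ_id\toffset\tlength\tjunction\tend\n")
    for u in vg.units:
        handle.write(f"{u.circ_id}\t{u.offset}\t{u.length}\t{u.junction}\t{u.end}\n")


def read_circ_fasta(path) -> list[CircRNA]:
    """Load candidate circRNA monomer sequences from FASTA."""
    from Bio import SeqIO

    return [CircRNA(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
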