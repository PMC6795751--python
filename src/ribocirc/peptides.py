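"""Start-codon-independent peptide prediction on coding RMRJs.

Ribosome-profiling coverage of circRNAs is too sparse for reliable 3-nt
periodicity or initiation-site calling, and circRNA translation can start
at non-AUG codons, so ORF calling anchored on a start codon is the wrong
tool here.  Instead, each coding-labelled RMRJ is scanned in all three
reading frames for maximal stop-free amino-acid runs; the longest run
that covers the back-splice junction and reaches the minimum length is
reported as the translated peptide.  No start codon is required anywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

from Bio.Data.CodonTable import standard_dna_table

from .junctionmap import RMRJ

log = logging.getLogger(__name__)

DEFAULT_MIN_AA = 10

_CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
_CODON_TABLE.update({codon: "*" for codon in standard_dna_table.stop_codons})


@dataclass(frozen=True)
class PeptideCall:
    """A predicted translated segment covering the back-splice junction.

    The nucleotide interval is half-open within the RMRJ sequence and has
    length 3 * len(aa_seq); it always contains the junction offset.
    """

    circ_id: str
    frame: int
    start: int
    end: int
    aa_seq: str
    strand: str = "+"
    spans_junction: bool = True

    def __post_init__(self) -> None:
        assert "*" not in self.aa_seq
        assert self.end - self.start == 3 * len(self.aa_seq)


def translate(seq: str, frame: int) -> str:
    """Standard-code translation of seq[frame:]; trailing partial codon dropped.

    Codons containing N translate to 'X'; stop codons render as '*'.
    """
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
    seq = seq.upper()
    aa = []
    for i in range(frame, len(seq) - 2, 3):
        codon = seq[i:i + 3]
        aa.append("X" if "N" in codon else _CODON_TABLE[codon])
    return "".join(aa)


def _stop_free_runs(aa: str) -> Iterable[tuple[int, int]]:
    """Maximal '*'-free runs of an amino-acid string as (start, end) pairs."""
    start = None
    for i, c in enumerate(aa):
        if c == "*":
            if start is not None:
                yield start, i
                start = None
        elif start is None:
            start = i
    if start is not None:
        yield start, len(aa)


def predict_peptide(rmrj: RMRJ, min_aa: int = DEFAULT_MIN_AA) -> PeptideCall | None:
    """The longest junction-covering stop-free run over the three frames.

    A run covers the junction when its nucleotide interval has at least
    one base on each side of the RMRJ's junction offset.  Runs shorter
    than ``min_aa`` amino acids are ignored.  Ties go to the lowest frame,
    then the leftmost run.  Returns None when no qualifying run exists.
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    j = rmrj.junction_offset
    best: PeptideCall | None = None
    for frame in (0, 1, 2):
        aa = translate(rmrj.seq, frame)
        for a_start, a_end in _stop_free_runs(aa):
            nt_start = frame + 3 * a_start
            nt_end = frame + 3 * a_end
            if a_end - a_start < min_aa:
                continue
            if not (nt_start < j and nt_end > j):
                continue  # must cover the junction with a base on each side
            if best is None or (a_end - a_start) > len(best.aa_seq):
                best = PeptideCall(rmrj.circ_id, frame, nt_start, nt_end,
                                   aa[a_start:a_end])
    return best


def predict_peptides(rmrjs: Iterable[RMRJ], min_aa: int = DEFAULT_MIN_AA) -> list[PeptideCall]:
    out = []
    n = 0
    for rmrj in rmrjs:
        n += 1
        call = predict_peptide(rmrj, min_aa)
        if call is not None:
            out.append(call)
    log.info("peptides: %d RMRJs in, %d peptide calls", n, len(out))
    return out


def write_peptide_fasta(calls: Iterable[PeptideCall], nmj_by_circ: dict[str, int],
                        handle) -> None:
    """FASTA of predicted peptides; header circ_id|frame|interval|NMJ."""
    for c in calls:
        nmj = nmj_by_circ.get(c.circ_id, 0)
        handle.write(f">{c.circ_id}|frame={c.frame}|{c.start}-{c.end}|NMJ={nmj}\n")
        handle.write(c.aa_seq + "\n")


def write_peptide_table(calls: Iterable[PeptideCall], handle) -> None:
    handle.write("circ_id\tframe\tstart\tend\tlength_aa\taa_seq\n")
    for c in calls:
        handle.write(f"{c.circ_id}\t{c.frame}\t{c.start}\t{c.end}\t"
                     f"{len(c.aa_seq)}\t{c.aa_seq}\n")
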