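"""Synthetic fixtures: circRNAs with planted translated regions, RPF reads,
contaminants, training sets, and a Markov-chain null-sequence generator.

Everything the detection pipeline consumes can be generated here with a
known ground truth: a small linear genome and rRNA reference, candidate
circRNA sequences — some carrying a junction-crossing, codon-biased,
stop-free coding region — ribosome-protected-fragment reads (25-35 nt)
with adapter read-through, quality decay and rRNA/genome contamination,
coding/noncoding training sets for the classifier, and order-k Markov
null sequences that preserve the nucleotide/di-nucleotide composition of
a training set while destroying its codon structure (the null model for
false-discovery estimation).

Translated circRNAs are planted so that recovery is decidable: the coding
run crosses the back-splice junction, is flanked by in-frame stop codons,
and is built from guard cycles of the coding model whose shifted reading
frames hit a stop codon within every 12 nt — so the planted frame is the
unique junction-covering stop-free frame at junction-window scale.
Junction coverage is sampled with a configurable anchor (default 7 nt) on
each side of the back-splice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

from .pseudoref import CircRNA
from .readprep import Read, write_fastq

log = logging.getLogger(__name__)

BASES = "ACGT"
STOP_CODONS = tuple(standard_dna_table.stop_codons)  # TAA TAG TGA

# --------------------------------------------------------------------------
# codon usage model (coding-like synthesis)
# --------------------------------------------------------------------------

# The coding-like model has two fixed layers, both shipped with the
# package: (1) codon usage — amino-acid composition typical of globular
# proteins with one strongly preferred codon per amino acid (80% of its
# amino acid's mass), mimicking highly expressed genes; (2) codon-pair
# bias — a first-order chain over sense codons in which each codon has
# one favored successor carrying most of the transition mass.  The pair
# layer is a deliberately sharp caricature of natural codon-pair bias: it
# concentrates word-adjacency weight enough that even a ~30-70 nt
# junction window carries a classifiable coding signature, while an
# order-1 nucleotide Markov null fitted to such sequences reproduces
# their composition but not the pair structure.
_AA_WEIGHT = {
    "A": 7.4, "R": 4.2, "N": 4.4, "D": 5.9, "C": 3.3, "E": 5.8, "Q": 3.7,
    "G": 7.4, "H": 2.9, "I": 3.8, "L": 7.6, "K": 7.2, "M": 1.8, "F": 4.0,
    "P": 5.0, "S": 8.1, "T": 6.2, "W": 1.3, "Y": 3.3, "V": 6.8,
}
_PREFERRED = {
    "A": "GCC", "R": "CGC", "N": "AAC", "D": "GAC", "C": "TGC", "E": "GAG",
    "Q": "CAG", "G": "GGC", "H": "CAC", "I": "ATC", "L": "CTG", "K": "AAG",
    "M": "ATG", "F": "TTC", "P": "CCC", "S": "AGC", "T": "ACC", "W": "TGG",
    "Y": "TAC", "V": "GTG",
}
_PREF_SHARE = 0.8


def _codon_usage() -> tuple[list[str], np.ndarray]:
    by_aa: dict[str, list[str]] = {}
    for codon, aa in standard_dna_table.forward_table.items():
        by_aa.setdefault(aa, []).append(codon)
    codons, probs = [], []
    total = sum(_AA_WEIGHT.values())
    for aa, weight in _AA_WEIGHT.items():
        syn = sorted(by_aa[aa])
        pref = _PREFERRED[aa]
        rest = [c for c in syn if c != pref]
        codons.append(pref)
        probs.append(weight / total * (_PREF_SHARE if rest else 1.0))
        for c in rest:
            codons.append(c)
            probs.append(weight / total * (1.0 - _PREF_SHARE) / len(rest))
    return codons, np.array(probs) / sum(probs)

CODON_LIST, CODON_PROBS = _codon_usage()
_N_CODONS = len(CODON_LIST)
_CODON_IDX = {c: i for i, c in enumerate(CODON_LIST)}

FAVORED_MASS = 0.9   # transition mass on each codon's favored successor
N_GUARD_CASSETTES = 8  # structural maximum of disjoint shift-stop cycles
_TABLE_BUILD_SEED = 20240915  # fixes the shipped successor map


def _shift_stop_pairs(shift: int) -> list[tuple[str, str]]:
    """Sense-codon pairs whose concatenation reads a stop in frame +shift."""
    stops = set(STOP_CODONS)
    out = []
    for c1 in CODON_LIST:
        for c2 in CODON_LIST:
            if (c1 + c2)[shift:shift + 3] in stops:
                out.append((c1, c2))
    return out


GUARD_CYCLE_LEN = 4  # codons per guard cycle (12 nt period)


def _build_pair_model():
    """Fixed favored-successor map, transition matrix and guard cycles.

    A guard cycle is a closed loop A-B-C-D-A of the successor map in
    which the pair (A,B) reads a stop codon in frame +1 and (C,D) a stop
    in frame +2.  Codon chains are attracted into these cycles, so coding
    sequences are locally near-periodic with a 12-nt period — short
    enough that even a ~30-70 nt junction window repeats its motifs — and,
    crucially for frame-unambiguous peptide calls, every 12-nt stretch of
    a cycle-repeat region contains a stop in both shifted frames while
    frame 0 stays stop-free.
    """
    rng = np.random.default_rng(_TABLE_BUILD_SEED)
    shift1 = _shift_stop_pairs(1)
    shift2 = _shift_stop_pairs(2)
    cycles: list[tuple[str, ...]] = []
    used: set[str] = set()
    order1 = rng.permutation(len(shift1))
    order2 = rng.permutation(len(shift2))
    free = [c for c in sorted(CODON_LIST, key=lambda c: -CODON_PROBS[_CODON_IDX[c]])]
    for i1 in order1:
        if len(cycles) == N_GUARD_CASSETTES:
            break
        a, b = shift1[i1]
        if a in used or b in used or a == b:
            continue
        for i2 in order2:
            c, d = shift2[i2]
            if used.isdisjoint({c, d}) and len({a, b, c, d}) == 4:
                extras = [x for x in free
                          if x not in used | {a, b, c, d}][:GUARD_CYCLE_LEN - 4]
                cycle = (a, b, c, d, *extras)
                cycles.append(cycle)
                used.update(cycle)
                break
    assert len(cycles) == N_GUARD_CASSETTES
    favored = [int(rng.choice(_N_CODONS, p=CODON_PROBS)) for _ in range(_N_CODONS)]
    for cycle in cycles:
        for i, codon in enumerate(cycle):
            favored[_CODON_IDX[codon]] = _CODON_IDX[cycle[(i + 1) % len(cycle)]]
    trans = np.tile(CODON_PROBS * (1.0 - FAVORED_MASS), (_N_CODONS, 1))
    for i, j in enumerate(favored):
        trans[i, j] += FAVORED_MASS
    trans /= trans.sum(axis=1, keepdims=True)
    return favored, np.cumsum(trans, axis=1), tuple(cycles)

CODON_SUCCESSOR, _TRANS_CUM, GUARD_CYCLES = _build_pair_model()


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(BASES), size=length))


def _codon_chain(rng: np.random.Generator, n_codons: int,
                 start: int | None = None) -> list[int]:
    if n_codons <= 0:
        return []
    idx = [int(rng.choice(_N_CODONS, p=CODON_PROBS)) if start is None else start]
    while len(idx) < n_codons:
        idx.append(int(np.searchsorted(_TRANS_CUM[idx[-1]], rng.random())))
    return idx


def coding_sequence(rng: np.random.Generator, length: int,
                    random_phase: bool = True) -> str:
    """A stop-free sequence from the codon-usage + codon-pair model.

    With ``random_phase`` the sequence is cut at a random codon phase so
    fragments do not all start in frame 0 (as RMRJ windows do not).
    """
    shift = int(rng.integers(0, 3)) if random_phase else 0
    n_codons = (length + shift + 2) // 3
    seq = "".join(CODON_LIST[i] for i in _codon_chain(rng, n_codons))
    return seq[shift:shift + length]


def _cycle_repeat(rng: np.random.Generator, cycle: tuple[str, ...],
                  length: int) -> str:
    """An arbitrary-phase stretch of a guard-cycle repeat."""
    period = "".join(cycle)
    reps = period * (length // len(period) + 2)
    start = int(rng.integers(0, len(period)))
    return reps[start:start + length]


def _junction_cut(rng: np.random.Generator, length: int,
                  anchor: int = 7) -> int:
    """Left-arm length of a junction window: uniform with >= anchor nt on
    each side where the window allows it (mirrors read-anchor geometry)."""
    a = max(1, min(anchor, (length - 1) // 2))
    return int(rng.integers(a, length - a + 1))


def coding_junction_fragment(
    rng: np.random.Generator,
    length: int,
    circ_len_range: tuple[int, int] = (200, 800),
    orf_len_range: tuple[int, int] = (60, 300),
) -> str:
    """Coding sequence as seen across a back-splice junction.

    A junction window cut from a translated circRNA model: a planted
    junction-crossing coding run with whatever flanking sequence falls
    inside the window when the run's arms are shorter than the window's.
    This is the shape of the material the classifier must recognise when
    it labels an RMRJ, and it is the default positive training set.
    """
    if length < 4:
        return coding_sequence(rng, length)
    circ_len = int(rng.integers(max(circ_len_range[0], orf_len_range[0] + 6,
                                    length + 2),
                                circ_len_range[1] + 1))
    orf_hi = min(orf_len_range[1], circ_len - 6)
    orf_len = int(rng.integers(orf_len_range[0] // 3, orf_hi // 3 + 1)) * 3
    monomer, _ = plant_translated_circ(rng, circ_len, orf_len)
    left = min(_junction_cut(rng, length), circ_len - 1)
    L = len(monomer)
    doubled = monomer * 2
    return doubled[L - left:L - left + length]


def noncoding_junction_fragment(rng: np.random.Generator, source: str,
                                length: int) -> str:
    """A junction window cut from a doubled noncoding (null) sequence.

    Mirrors the geometry of :func:`coding_junction_fragment` for the
    negative class.  When the source is shorter than the window, the
    window wraps around the circle — the same tandem self-repetition a
    real RMRJ on a very short circRNA would show — so the classifier
    learns that wrap repetition alone is not a coding signature.
    """
    L = len(source)
    length = min(length, 2 * L - 2)
    left = min(_junction_cut(rng, length), L - 1)
    doubled = source * 2
    return doubled[L - left:L - left + length]


# --------------------------------------------------------------------------
# Markov-chain null-sequence emulator
# --------------------------------------------------------------------------

def markov_emulate(
    train: Sequence[str],
    order: int = 1,
    n: int = 1,
    length_model: Sequence[int] | Callable | None = None,
    seed: int = 0,
) -> list[str]:
    """Generate sequences from an order-k Markov chain fitted to ``train``.

    Transition counts are estimated with pseudo-count-1 smoothing over
    {A,C,G,T}; initial states follow the empirical distribution of
    training-sequence prefixes, and output lengths are drawn from the
    empirical training length distribution unless ``length_model`` is
    given (a list of lengths to sample from, or a callable(rng) -> int).
    The emitted ensemble reproduces the training mono- and k+1-mer
    composition but none of its frame structure.  Deterministic per seed.
    """
    if not train:
        raise ValueError("empty training set")
    if order < 0:
        raise ValueError("order must be >= 0")
    rng = np.random.default_rng(seed)
    base_idx = {b: i for i, b in enumerate(BASES)}

    if order == 0:
        counts = np.ones(4)
        for seq in train:
            for b in seq:
                if b in base_idx:
                    counts[base_idx[b]] += 1
        probs = counts / counts.sum()
        trans = None
        starts = None
    else:
        trans_counts: dict[str, np.ndarray] = {}
        starts = []
        for seq in train:
            seq = seq.upper()
            if len(seq) >= order:
                starts.append(seq[:order])
            for i in range(len(seq) - order):
                ctx, nxt = seq[i:i + order], seq[i + order]
                if nxt not in base_idx or any(b not in base_idx for b in ctx):
                    continue
                if ctx not in trans_counts:
                    trans_counts[ctx] = np.ones(4)  # pseudo-count smoothing
                trans_counts[ctx][base_idx[nxt]] += 1
        trans = {ctx: np.cumsum(c / c.sum()) for ctx, c in trans_counts.items()}
        if not starts:
            raise ValueError("training sequences shorter than the model order")

    lengths = [len(s) for s in train]
    def draw_length() -> int:
        if callable(length_model):
            return int(length_model(rng))
        pool = list(length_model) if length_model is not None else lengths
        return int(pool[rng.integers(0, len(pool))])

    uniform_cum = np.cumsum(np.ones(4) / 4)
    out = []
    for _ in range(n):
        length = draw_length()
        if order == 0:
            idx = rng.choice(4, size=length, p=probs)
            out.append("".join(BASES[i] for i in idx))
            continue
        state = starts[rng.integers(0, len(starts))]
        chars = list(state[:length])
        while len(chars) < length:
            ctx = "".join(chars[-order:]) if len(chars) >= order else state
            cum = trans.get(ctx, uniform_cum)
            chars.append(BASES[int(np.searchsorted(cum, rng.random(), side="right"))])
        out.append("".join(chars[:length]))
    return out


# --------------------------------------------------------------------------
# circRNA planting
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedORF:
    """Ground truth for one translated circRNA, in doubled-unit coordinates.

    The circRNA's junction sits between monomer positions L-1 and 0; in
    the doubled unit (seq+seq) the junction index is L and the planted
    coding run occupies [start, end) with start < L < end.
    """

    start: int
    end: int
    frame: int  # start % 3 in doubled-unit coordinates
    aa_seq: str


def junction_combo_count() -> int:
    """Distinct (left cycle, right cycle, phases) junction configurations."""
    n = len(GUARD_CYCLES)
    return n * (n - 1) * GUARD_CYCLE_LEN * GUARD_CYCLE_LEN


def _decode_combo(combo: int) -> tuple[int, int, int, int]:
    n = len(GUARD_CYCLES)
    combo, phase_r = divmod(combo, GUARD_CYCLE_LEN)
    combo, phase_l = divmod(combo, GUARD_CYCLE_LEN)
    xi, yoff = divmod(combo, n - 1)
    yi = (xi + 1 + yoff) % n
    return xi, yi, phase_l, phase_r


def plant_translated_circ(
    rng: np.random.Generator,
    circ_len: int,
    orf_len: int,
    combo: int | None = None,
) -> tuple[str, PlantedORF]:
    """A circRNA monomer carrying a junction-crossing planted coding run.

    The run is flanked by in-frame stop codons and crosses the junction
    with at least 18 nt on each side.  Each side is a repeat of one guard
    cycle of the coding model (two different cycles, random phases), so
    the junction region has the model's periodic pair structure while
    both shifted reading frames hit a stop codon within every 18 nt on
    either side of the junction — the planted frame is the unique
    junction-covering stop-free frame at RMRJ scale.
    """
    from .peptides import translate

    if orf_len % 3 or orf_len < 12 * GUARD_CYCLE_LEN // 2:
        raise ValueError(f"ORF length {orf_len} infeasible")
    if orf_len + 6 > circ_len:
        raise ValueError(f"ORF length {orf_len} does not fit in circRNA of {circ_len} nt")
    # split across the junction: a nt before, b nt after, both >= 18
    a_choices = np.arange(18, orf_len - 18 + 1, 3)
    a = int(rng.choice(a_choices))
    n_codons = orf_len // 3
    jc = a // 3  # codon index at which the junction falls
    if combo is None:
        combo = int(rng.integers(0, junction_combo_count()))
    xi, yi, phase_l, phase_r = _decode_combo(combo)
    cyc_l, cyc_r = GUARD_CYCLES[xi], GUARD_CYCLES[yi]  # distinct cycles
    codons = [cyc_l[(phase_l + i) % GUARD_CYCLE_LEN] for i in range(jc)]
    codons += [cyc_r[(phase_r + i) % GUARD_CYCLE_LEN] for i in range(n_codons - jc)]
    orf = "".join(codons)
    assert len(orf) == orf_len

    seq = list(random_seq(rng, circ_len))
    L = circ_len
    for i, b in enumerate(orf):  # ORF occupies circular [L-a, L) U [0, orf_len-a)
        seq[(L - a + i) % L] = b
    stop_before = STOP_CODONS[rng.integers(0, len(STOP_CODONS))]
    stop_after = STOP_CODONS[rng.integers(0, len(STOP_CODONS))]
    for i, b in enumerate(stop_before):
        seq[(L - a - 3 + i) % L] = b
    for i, b in enumerate(stop_after):
        seq[(orf_len - a + i) % L] = b
    monomer = "".join(seq)
    doubled = monomer * 2
    start, end = L - a, L - a + orf_len
    aa = translate(doubled[start:end], 0)
    assert "*" not in aa
    return monomer, PlantedORF(start, end, start % 3, aa)


# --------------------------------------------------------------------------
# read sampling
# --------------------------------------------------------------------------

def _qualities(rng: np.random.Generator, length: int,
               mean: float, decay: float) -> tuple[int, ...]:
    q = rng.normal(mean - decay * np.arange(length), 2.0)
    return tuple(int(v) for v in np.clip(np.round(q), 2, 40))


def _with_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    hits = np.nonzero(rng.random(len(chars)) < rate)[0]
    for i in hits:
        alternatives = [b for b in BASES if b != chars[i]]
        chars[i] = alternatives[rng.integers(0, 3)]
    return "".join(chars)


def spanning_read_seq(rng: np.random.Generator, monomer: str,
                      read_len: int, insert_len: int | None = None,
                      min_overhang: int = 1) -> str:
    """A read crossing the back-splice with >= min_overhang nt each side."""
    L = len(monomer)
    eff = insert_len if insert_len is not None else read_len
    mo = max(1, min(min_overhang, (eff - 1) // 2))
    u = int(rng.integers(mo, eff - mo + 1))  # left overhang
    doubled = monomer * 2
    return doubled[L - u:L - u + eff]


def spanning_reads(monomer: str, n: int, rng: np.random.Generator,
                   read_len_range: tuple[int, int] = (25, 35),
                   circ_id: str = "circ", qual: int = 35,
                   min_overhang: int = 7) -> list[Read]:
    """Error-free junction-spanning reads for one circRNA (helper for
    null-model experiments that need passing junction coverage)."""
    out = []
    for i in range(n):
        length = int(rng.integers(read_len_range[0], read_len_range[1] + 1))
        length = min(length, 2 * len(monomer) - 2)
        seq = spanning_read_seq(rng, monomer, length, min_overhang=min_overhang)
        out.append(Read(f"{circ_id}_span_{i}", seq, (qual,) * len(seq)))
    return out


# --------------------------------------------------------------------------
# dataset simulation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic dataset."""

    seed: int = 0
    n_circ_translated: int = 5
    n_circ_untranslated: int = 5
    circ_len_range: tuple[int, int] = (200, 800)
    orf_len_range: tuple[int, int] = (60, 300)
    reads_per_translated_junction: int = 8
    spanning_reads_untranslated: int = 2   # sub-threshold by construction
    nonspanning_reads_per_circ: int = 3
    read_len_range: tuple[int, int] = (25, 35)
    spanning_min_overhang: int = 7  # junction anchor on each side of a read
    rrna_read_fraction: float = 0.1
    linear_read_fraction: float = 0.1
    adapter_fraction: float = 0.1
    subst_error_rate: float = 0.002
    qual_mean: float = 35.0
    qual_decay: float = 0.1
    genome_len: int = 5000
    rrna_len: int = 1500
    adapter: str = "AGATCGGAAGAGC"
    n_train_coding: int = 300
    n_train_noncoding: int = 300
    train_len_range: tuple[int, int] = (30, 60)
    markov_order: int = 1

    def __post_init__(self) -> None:
        for name in ("rrna_read_fraction", "linear_read_fraction", "adapter_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.rrna_read_fraction + self.linear_read_fraction > 1.0:
            raise ValueError("contaminant fractions sum above 1")
        for name in ("n_circ_translated", "n_circ_untranslated",
                     "reads_per_translated_junction", "nonspanning_reads_per_circ",
                     "spanning_reads_untranslated", "n_train_coding",
                     "n_train_noncoding"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.orf_len_range[0] + 6 > self.circ_len_range[1]:
            raise ValueError("shortest ORF cannot fit in the longest circRNA")


@dataclass(frozen=True)
class TruthRow:
    circ_id: str
    translated: bool
    orf_start: int      # doubled-unit coordinates; -1 when untranslated
    orf_end: int
    frame: int
    aa_seq: str
    n_spanning_reads: int
    n_other_reads: int
    recoverable: bool   # translated and spanning depth above the NMJ cut


@dataclass
class SimBundle:
    config: SimConfig
    genome: str
    rrna: str
    circs: list[CircRNA]
    reads: list[Read]
    train_coding: list[str]
    train_noncoding: list[str]
    truth: list[TruthRow]

    def truth_by_id(self) -> dict[str, TruthRow]:
        return {row.circ_id: row for row in self.truth}


def _maybe_adapterize(rng, cfg: SimConfig, seq: str) -> str:
    """Emulate 3' adapter read-through: shorten the insert and pad with
    adapter bases, keeping the raw read length."""
    total = len(seq)
    min_insert = 20
    if total - 7 < min_insert:
        return seq
    insert_len = int(rng.integers(min_insert, total - 7 + 1))
    pad = cfg.adapter * (1 + (total - insert_len) // len(cfg.adapter))
    return seq[:insert_len] + pad[:total - insert_len]


def simulate_dataset(cfg: SimConfig, nmj_min: int = 3) -> SimBundle:
    """Generate a complete, truth-annotated synthetic input bundle.

    Translated circRNAs receive ``reads_per_translated_junction``
    junction-spanning reads; untranslated circRNAs receive only
    non-spanning and sub-threshold spanning reads.  Contaminant reads are
    drawn from the rRNA and linear genome references at the configured
    fractions (relative to total reads), and a fraction of all reads carry
    3' adapter read-through.  Byte-deterministic for a fixed config.
    """
    rng = np.random.default_rng(cfg.seed)
    genome = random_seq(rng, cfg.genome_len)
    rrna = random_seq(rng, cfg.rrna_len)

    circs: list[CircRNA] = []
    truth: list[TruthRow] = []
    reads: list[Read] = []

    def add_read(name: str, seq: str, adapterizable: bool = True) -> None:
        if adapterizable and rng.random() < cfg.adapter_fraction:
            seq = _maybe_adapterize(rng, cfg, seq)
        seq = _with_errors(rng, seq, cfg.subst_error_rate)
        reads.append(Read(name, seq, _qualities(rng, len(seq), cfg.qual_mean,
                                                cfg.qual_decay)))

    lo, hi = cfg.orf_len_range
    # junction configurations dealt without replacement: no two planted
    # circRNAs share both guard cycles and phases at the junction
    combos = rng.choice(junction_combo_count(),
                        size=min(cfg.n_circ_translated, junction_combo_count()),
                        replace=False)
    for i in range(cfg.n_circ_translated):
        cid = f"circ_t{i:03d}"
        min_len = max(cfg.circ_len_range[0], lo + 6)
        circ_len = int(rng.integers(min_len, cfg.circ_len_range[1] + 1))
        orf_hi = min(hi, circ_len - 6)
        orf_len = int(rng.integers(lo // 3, orf_hi // 3 + 1)) * 3
        monomer, planted = plant_translated_circ(
            rng, circ_len, orf_len, combo=int(combos[i % len(combos)]))
        circs.append(CircRNA(cid, monomer))
        n_span = cfg.reads_per_translated_junction
        for r in range(n_span):
            length = int(rng.integers(*cfg.read_len_range, endpoint=True))
            if rng.random() < cfg.adapter_fraction and length >= 28:
                insert = int(rng.integers(20, length - 7 + 1))
                seq = spanning_read_seq(rng, monomer, length, insert_len=insert,
                                        min_overhang=cfg.spanning_min_overhang)
                pad = cfg.adapter * 4
                seq = seq + pad[:length - len(seq)]
                add_read(f"{cid}_span{r}", seq, adapterizable=False)
            else:
                add_read(f"{cid}_span{r}",
                         spanning_read_seq(rng, monomer, length,
                                           min_overhang=cfg.spanning_min_overhang),
                         adapterizable=False)
        for r in range(cfg.nonspanning_reads_per_circ):
            length = int(rng.integers(*cfg.read_len_range, endpoint=True))
            s = int(rng.integers(0, circ_len - length + 1))
            add_read(f"{cid}_body{r}", monomer[s:s + length])
        truth.append(TruthRow(cid, True, planted.start, planted.end,
                              planted.frame, planted.aa_seq, n_span,
                              cfg.nonspanning_reads_per_circ,
                              n_span > nmj_min))

    for i in range(cfg.n_circ_untranslated):
        cid = f"circ_u{i:03d}"
        circ_len = int(rng.integers(*cfg.circ_len_range, endpoint=True))
        monomer = random_seq(rng, circ_len)
        circs.append(CircRNA(cid, monomer))
        n_span = cfg.spanning_reads_untranslated
        assert n_span <= nmj_min, "untranslated spanning depth must stay sub-threshold"
        for r in range(n_span):
            length = int(rng.integers(*cfg.read_len_range, endpoint=True))
            add_read(f"{cid}_span{r}", spanning_read_seq(rng, monomer, length),
                     adapterizable=False)
        for r in range(cfg.nonspanning_reads_per_circ):
            length = int(rng.integers(*cfg.read_len_range, endpoint=True))
            s = int(rng.integers(0, circ_len - length + 1))
            add_read(f"{cid}_body{r}", monomer[s:s + length])
        truth.append(TruthRow(cid, False, -1, -1, -1, "", n_span,
                              cfg.nonspanning_reads_per_circ, False))

    # contaminants, sized so the configured fractions refer to total reads
    n_signal = len(reads)
    signal_frac = 1.0 - cfg.rrna_read_fraction - cfg.linear_read_fraction
    total = n_signal / signal_frac if signal_frac > 0 else n_signal
    n_rrna = int(round(total * cfg.rrna_read_fraction))
    n_linear = int(round(total * cfg.linear_read_fraction))
    for i in range(n_rrna):
        length = int(rng.integers(*cfg.read_len_range, endpoint=True))
        s = int(rng.integers(0, cfg.rrna_len - length + 1))
        seq = rrna[s:s + length]
        if rng.random() < 0.5:
            from .junctionmap import revcomp
            seq = revcomp(seq)
        add_read(f"rrna{i}", seq)
    for i in range(n_linear):
        length = int(rng.integers(*cfg.read_len_range, endpoint=True))
        s = int(rng.integers(0, cfg.genome_len - length + 1))
        seq = genome[s:s + length]
        if rng.random() < 0.5:
            from .junctionmap import revcomp
            seq = revcomp(seq)
        add_read(f"lin{i}", seq, adapterizable=False)

    order = rng.permutation(len(reads))
    reads = [reads[int(i)] for i in order]

    train_coding = [
        coding_junction_fragment(
            rng, int(rng.integers(*cfg.train_len_range, endpoint=True)))
        for _ in range(cfg.n_train_coding)
    ]
    # null sources have candidate-circRNA lengths, so negative windows show
    # the composition of coding material without its pair structure
    null_lengths = [int(rng.integers(*cfg.circ_len_range, endpoint=True))
                    for _ in range(cfg.n_train_noncoding)]
    null_sources = markov_emulate(
        train_coding or [coding_sequence(rng, 300)],
        order=cfg.markov_order,
        n=cfg.n_train_noncoding,
        length_model=null_lengths,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    train_noncoding = [
        noncoding_junction_fragment(
            rng, src, int(rng.integers(*cfg.train_len_range, endpoint=True)))
        for src in null_sources
    ]
    log.info("simulate: %d circRNAs (%d translated), %d reads, %d+%d training",
             len(circs), cfg.n_circ_translated, len(reads),
             len(train_coding), len(train_noncoding))
    return SimBundle(cfg, genome, rrna, circs, reads,
                     train_coding, train_noncoding, truth)


# --------------------------------------------------------------------------
# serialisation
# --------------------------------------------------------------------------

def write_bundle(bundle: SimBundle, outdir) -> dict[str, Path]:
    """Write the bundle as standard FASTA/FASTQ/TSV files plus a config YAML."""
    import yaml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {name: outdir / fname for name, fname in [
        ("genome", "genome.fasta"), ("rrna", "rrna.fasta"),
        ("circs", "circrnas.fasta"), ("reads", "reads.fastq"),
        ("train_coding", "train_coding.fasta"),
        ("train_noncoding", "train_noncoding.fasta"),
        ("truth", "truth.tsv"), ("config", "sim_config.yaml"),
    ]}
    _write_fasta(paths["genome"], [("genome", bundle.genome)])
    _write_fasta(paths["rrna"], [("rRNA", bundle.rrna)])
    _write_fasta(paths["circs"], [(c.id, c.seq) for c in bundle.circs])
    with open(paths["reads"], "w") as fh:
        write_fastq(bundle.reads, fh)
    _write_fasta(paths["train_coding"],
                 [(f"coding{i}", s) for i, s in enumerate(bundle.train_coding)])
    _write_fasta(paths["train_noncoding"],
                 [(f"noncoding{i}", s) for i, s in enumerate(bundle.train_noncoding)])
    with open(paths["truth"], "w") as fh:
        fh.write("circ_id\ttranslated\torf_start\torf_end\tframe\taa_seq\t"
                 "n_spanning_reads\tn_other_reads\trecoverable\n")
        for row in bundle.truth:
            fh.write(f"{row.circ_id}\t{int(row.translated)}\t{row.orf_start}\t"
                     f"{row.orf_end}\t{row.frame}\t{row.aa_seq}\t"
                     f"{row.n_spanning_reads}\t{row.n_other_reads}\t"
                     f"{int(row.recoverable)}\n")
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(asdict(bundle.config), fh, sort_keys=True)
    return paths


def _write_fasta(path, records: Iterable[tuple[str, str]], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta_seqs(path) -> list[str]:
    from Bio import SeqIO

    return [str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")]
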