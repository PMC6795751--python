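"""Validation experiments: null-model false-discovery rate and depth
sensitivity.

Two study designs used to characterise the detector on synthetic data:

* :func:`fdr_experiment` — the null-model control.  The classifier is
  trained on synthetic coding junction fragments versus Markov-random
  negatives; an order-1 Markov emulator is then fitted to the positive
  training sequences and used to emit null candidate sequences that share
  their composition but not their codon-pair structure.  Every null is
  treated as a candidate circRNA, given junction-spanning read coverage
  above the NMJ threshold through the real mapping machinery, and
  classified.  The fraction of nulls labelled translated estimates the
  false-discovery rate of the classification stage.

* :func:`depth_sensitivity` — junction-read depth titration.  One
  synthetic cohort is generated at the deepest coverage; shallower
  conditions reuse the identical circRNAs and reads with junction reads
  subsampled per circRNA, so sensitivity is compared across depths on
  coupled data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import junctionmap, netclassify, pipeline, pseudoref, readprep, simdata

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# false-discovery rate on Markov nulls
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FdrResult:
    n_null: int
    n_with_rmrj: int
    n_called_translated: int
    cv_accuracy: float

    @property
    def fdr(self) -> float:
        return self.n_called_translated / self.n_null if self.n_null else 0.0


def fdr_experiment(
    seed: int,
    n_train: int = 500,
    n_null: int = 10_000,
    reads_per_null: int = 6,
    n_trees: int = 100,
    batch_size: int = 400,
    sim_cfg: simdata.SimConfig | None = None,
) -> FdrResult:
    """False-discovery rate of the classification stage on Markov nulls.

    Trains on ``n_train`` coding junction fragments vs ``n_train``
    Markov-random negatives (the synthetic generator's defaults), fits an
    order-1 Markov emulator to the positives, emits ``n_null`` null
    candidate sequences with candidate-circRNA lengths, gives each
    junction coverage that passes the NMJ cut (``reads_per_null`` > 3
    spanning reads, mapped with the standard aligner), classifies the
    resulting RMRJs, and reports the fraction labelled translated.
    """
    cfg = sim_cfg or simdata.SimConfig(seed=seed, n_train_coding=n_train,
                                       n_train_noncoding=n_train)
    rng = np.random.default_rng(seed)
    bundle = simdata.simulate_dataset(cfg)
    model = netclassify.train_classifier(
        bundle.train_coding, bundle.train_noncoding,
        seed=seed % (2**31 - 1), n_trees=n_trees)

    null_lengths = [int(rng.integers(*cfg.circ_len_range, endpoint=True))
                    for _ in range(n_null)]
    nulls = simdata.markov_emulate(
        bundle.train_coding, order=cfg.markov_order, n=n_null,
        length_model=null_lengths, seed=int(rng.integers(0, 2**31 - 1)))

    n_with_rmrj = 0
    n_coding = 0
    for lo in range(0, n_null, batch_size):
        chunk = nulls[lo:lo + batch_size]
        circs = [pseudoref.CircRNA(f"null{lo + i}", s)
                 for i, s in enumerate(chunk)]
        vg = pseudoref.build_virtual_genome(circs)
        reads = []
        for c in circs:
            reads.extend(simdata.spanning_reads(
                c.seq, reads_per_null, rng,
                read_len_range=cfg.read_len_range, circ_id=c.id))
        for i, r in enumerate(reads):  # unique ids within the batch
            reads[i] = readprep.Read(f"{r.id}_{i}", r.seq, r.qual)
        _, placements = junctionmap.map_reads(reads, vg)
        rmrjs = junctionmap.compute_rmrjs(placements, vg)
        n_with_rmrj += len(rmrjs)
        _, translated = netclassify.classify_rmrjs(rmrjs, model)
        n_coding += len(translated)
    log.info("FDR experiment: %d nulls, %d with RMRJ, %d called translated",
             n_null, n_with_rmrj, n_coding)
    return FdrResult(n_null, n_with_rmrj, n_coding, model.cv_accuracy)


# ---------------------------------------------------------------------------
# sensitivity vs junction-read depth
# ---------------------------------------------------------------------------

def _subsample_junction_reads(bundle: simdata.SimBundle, depth: int) -> list:
    """Keep only the first ``depth`` junction-spanning reads per translated
    circRNA; all other reads pass through unchanged."""
    keep = []
    for read in bundle.reads:
        if "_span" in read.id and read.id.startswith("circ_t"):
            idx = int(read.id.rsplit("_span", 1)[1])
            if idx >= depth:
                continue
        keep.append(read)
    return keep


def depth_sensitivity(
    seed: int,
    depths: tuple[int, ...] = (2, 4, 8, 16),
    n_translated: int = 20,
    n_untranslated: int = 10,
    sim_cfg: simdata.SimConfig | None = None,
) -> dict[int, float]:
    """Sensitivity (recovered / planted translated circRNAs) per depth.

    The cohort is generated once at max(depths) junction reads per
    translated circRNA; each shallower condition subsamples junction
    reads from the same FASTQ, so all depths share circRNAs, contaminants
    and training data.  Classification uses one model trained on the
    bundle's training sets.
    """
    max_depth = max(depths)
    cfg = sim_cfg or simdata.SimConfig(
        seed=seed, n_circ_translated=n_translated,
        n_circ_untranslated=n_untranslated,
        reads_per_translated_junction=max_depth)
    bundle = simdata.simulate_dataset(cfg)
    model = netclassify.train_classifier(
        bundle.train_coding, bundle.train_noncoding,
        seed=seed % (2**31 - 1), n_trees=100)
    vg = pseudoref.build_virtual_genome([c for c in bundle.circs])
    trim = readprep.TrimParams(adapters=(cfg.adapter,))
    out: dict[int, float] = {}
    for depth in sorted(depths):
        reads = _subsample_junction_reads(bundle, depth)
        reads = readprep.trim_reads(reads, trim)
        _, placements = junctionmap.map_reads(reads, vg)
        rmrjs = junctionmap.compute_rmrjs(placements, vg)
        _, translated = netclassify.classify_rmrjs(rmrjs, model)
        truth = bundle.truth_by_id()
        tp = sum(1 for cid in translated if truth[cid].translated)
        out[depth] = tp / n_translated if n_translated else 0.0
        log.info("depth %d: sensitivity %.3f", depth, out[depth])
    return out
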