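"""End-to-end orchestration: read prep -> virtual genome -> junction
mapping -> coding classification -> peptide prediction.

Each stage reads and writes plain files in the output directory, so the
whole chain can run in one call or stage by stage with the intermediate
files as contracts.  A run report collects input/output counts for every
stage together with the full parameter set and seed, and identical
configurations reproduce every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import junctionmap, netclassify, peptides, pseudoref, readprep, simdata

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are left in place."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """All inputs, outputs and tunables of the five-stage pipeline."""

    outdir: str = "ribocirc_out"
    # inputs (empty string = stage input not available)
    reads_fastq: str = ""
    circ_fasta: str = ""
    rrna_fasta: str = ""
    genome_fasta: str = ""
    train_coding_fasta: str = ""
    train_noncoding_fasta: str = ""
    model_path: str = ""          # pre-trained model; skips the train stage
    # read preparation
    adapters: tuple[str, ...] = ("AGATCGGAAGAGC",)
    window_len: int = 4
    window_minq: float = 15.0
    leading_q: int = 3
    trailing_q: int = 3
    min_read_len: int = 20
    rrna_max_mismatch: int = 2
    # virtual genome
    spacer: int = 100
    fasta_per_unit: bool = False
    # mapping
    seed_len: int = 12
    max_mismatch: int = 2
    nmj_min: int = 3
    min_overhang: int = 1
    plus_strand_only: bool = False
    dedup_junction_reads: bool = False
    emit_sam: bool = False
    # classification
    word_len: int = 3
    thresholds: int = 10
    cv_folds: int = 5
    n_trees: int = 100
    classify_full_sequence: bool = False
    # peptides
    min_aa: int = 10
    # misc
    seed: int = 0
    threads: int = 1
    # stage toggles
    stages: tuple[str, ...] = ("prep", "buildref", "map", "train",
                               "classify", "peptides")

    def path(self, name: str) -> Path:
        return Path(self.outdir) / name

    def trim_params(self) -> readprep.TrimParams:
        return readprep.TrimParams(
            adapters=tuple(self.adapters), window_len=self.window_len,
            window_minq=self.window_minq, leading_q=self.leading_q,
            trailing_q=self.trailing_q, min_len=self.min_read_len)


def load_config(path, **overrides) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    data.update(overrides)
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("adapters", "stages"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    return PipelineConfig(**data)


def save_config(cfg: PipelineConfig, path) -> None:
    data = dataclasses.asdict(cfg)
    data["adapters"] = list(data["adapters"])
    data["stages"] = list(data["stages"])
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_prep(cfg: PipelineConfig) -> dict:
    """Trim reads, deplete rRNA, drop reads perfectly matching the genome."""
    reads = readprep.read_fastq(cfg.reads_fastq)
    counts = {"raw": len(reads)}
    reads = readprep.trim_reads(reads, cfg.trim_params())
    counts["trimmed"] = len(reads)
    if cfg.rrna_fasta:
        rrna = "".join(simdata.read_fasta_seqs(cfg.rrna_fasta))
        k = junctionmap.effective_seed_len(
            (len(r) for r in reads), cfg.seed_len, cfg.rrna_max_mismatch)
        index = junctionmap.build_index(rrna, k)
        reads = readprep.filter_by_reference(
            reads, index, max_mismatch=cfg.rrna_max_mismatch, label="rRNA")
    counts["rrna_depleted"] = len(reads)
    if cfg.genome_fasta:
        genome = "".join(simdata.read_fasta_seqs(cfg.genome_fasta))
        index = junctionmap.build_index(genome, cfg.seed_len)
        reads = readprep.filter_by_reference(
            reads, index, max_mismatch=0, label="genome")
    counts["final_unique"] = len(reads)
    with open(cfg.path("final_reads.fastq"), "w") as fh:
        readprep.write_fastq(reads, fh)
    return counts


def _build_vg(cfg: PipelineConfig) -> pseudoref.VirtualGenome:
    circs = pseudoref.read_circ_fasta(cfg.circ_fasta)
    return pseudoref.build_virtual_genome(circs, cfg.spacer)


def stage_buildref(cfg: PipelineConfig) -> dict:
    vg = _build_vg(cfg)
    with open(cfg.path("virtual_genome.fasta"), "w") as fh:
        pseudoref.write_fasta(vg, fh, per_unit=cfg.fasta_per_unit)
    with open(cfg.path("junctions.bed"), "w") as fh:
        pseudoref.write_junction_bed(vg, fh)
    with open(cfg.path("units.tsv"), "w") as fh:
        pseudoref.write_unit_table(vg, fh)
    return {"circRNAs": len(vg.units), "layout_len": len(vg.layout)}


def stage_map(cfg: PipelineConfig) -> dict:
    vg = _build_vg(cfg)
    reads = readprep.read_fastq(cfg.path("final_reads.fastq"))
    alns, placements = junctionmap.map_reads(
        reads, vg, k=cfg.seed_len, max_mismatch=cfg.max_mismatch,
        min_overhang=cfg.min_overhang)
    rmrjs = junctionmap.compute_rmrjs(
        placements, vg, nmj_min=cfg.nmj_min, min_overhang=cfg.min_overhang,
        plus_strand_only=cfg.plus_strand_only,
        deduplicate=cfg.dedup_junction_reads)
    if cfg.emit_sam:
        reads_by_id = {r.id: r for r in reads}
        with open(cfg.path("alignments.sam"), "w") as fh:
            junctionmap.write_sam(placements, vg, fh, reads_by_id)
    with open(cfg.path("rmrjs.fasta"), "w") as fh:
        junctionmap.write_rmrj_fasta(rmrjs, fh)
    with open(cfg.path("rmrjs.tsv"), "w") as fh:
        junctionmap.write_rmrj_table(rmrjs, fh)
    return {"reads": len(reads), "aligned": len(alns),
            "placed": len(placements),
            "junction_spanning": sum(p.spanning for p in placements),
            "rmrjs": len(rmrjs)}


def stage_train(cfg: PipelineConfig) -> dict:
    if cfg.model_path:
        return {"model": cfg.model_path, "trained": 0}
    pos = simdata.read_fasta_seqs(cfg.train_coding_fasta)
    neg = simdata.read_fasta_seqs(cfg.train_noncoding_fasta)
    model = netclassify.train_classifier(
        pos, neg, w=cfg.word_len, thresholds=cfg.thresholds,
        cv_folds=cfg.cv_folds, seed=cfg.seed, n_trees=cfg.n_trees)
    model.save(cfg.path("model.pkl"))
    return {"positives": len(pos), "negatives": len(neg),
            "cv_accuracy": round(model.cv_accuracy, 4), "trained": 1}


def _load_rmrjs(cfg: PipelineConfig) -> list[junctionmap.RMRJ]:
    import csv

    seqs = {}
    name = None
    with open(cfg.path("rmrjs.fasta")) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = ""
            elif name:
                seqs[name] += line
    out = []
    with open(cfg.path("rmrjs.tsv")) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(junctionmap.RMRJ(
                row["circ_id"], int(row["start"]), int(row["end"]),
                int(row["nmj"]), seqs[row["circ_id"]],
                int(row["junction_offset"])))
    return out


def stage_classify(cfg: PipelineConfig) -> dict:
    model_path = cfg.model_path or cfg.path("model.pkl")
    model = netclassify.CodingModel.load(model_path)
    rmrjs = _load_rmrjs(cfg)
    full = None
    if cfg.classify_full_sequence:
        circs = pseudoref.read_circ_fasta(cfg.circ_fasta)
        full = {c.id: c.seq for c in circs}
    records, translated = netclassify.classify_rmrjs(rmrjs, model, full)
    with open(cfg.path("predictions.tsv"), "w") as fh:
        fh.write("circ_id\tlabel\tscore\n")
        for cid, label, score in records:
            fh.write(f"{cid}\t{label}\t{score:.4f}\n")
    with open(cfg.path("translated_circrnas.tsv"), "w") as fh:
        fh.write("circ_id\n")
        for cid in translated:
            fh.write(cid + "\n")
    return {"rmrjs": len(records), "translated": len(translated)}


def stage_peptides(cfg: PipelineConfig) -> dict:
    import csv

    rmrjs = _load_rmrjs(cfg)
    coding_ids = set()
    with open(cfg.path("predictions.tsv")) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            if row["label"] == netclassify.LABEL_CODING:
                coding_ids.add(row["circ_id"])
    coding_rmrjs = [r for r in rmrjs if r.circ_id in coding_ids]
    calls = peptides.predict_peptides(coding_rmrjs, min_aa=cfg.min_aa)
    nmj = {r.circ_id: r.nmj for r in rmrjs}
    with open(cfg.path("peptides.fasta"), "w") as fh:
        peptides.write_peptide_fasta(calls, nmj, fh)
    with open(cfg.path("peptides.tsv"), "w") as fh:
        peptides.write_peptide_table(calls, fh)
    return {"coding_rmrjs": len(coding_rmrjs), "peptides": len(calls)}


_STAGE_FUNCS = {
    "prep": stage_prep,
    "buildref": stage_buildref,
    "map": stage_map,
    "train": stage_train,
    "classify": stage_classify,
    "peptides": stage_peptides,
}


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the enabled stages in order and write the run report.

    Any stage failure raises :class:`StageError` tagged with the stage
    name; outputs of completed stages are preserved.  The translated set
    in the report is, by construction, the circRNAs that both have an
    RMRJ and whose RMRJ is labelled coding.
    """
    Path(cfg.outdir).mkdir(parents=True, exist_ok=True)
    report: dict = {"parameters": dataclasses.asdict(cfg), "stages": {}}
    report["parameters"]["adapters"] = list(cfg.adapters)
    report["parameters"]["stages"] = list(cfg.stages)
    for stage in cfg.stages:
        func = _STAGE_FUNCS[stage]
        try:
            counts = func(cfg)
        except Exception as exc:  # noqa: BLE001 - re-tag with stage name
            _write_report(cfg, report)
            raise StageError(stage, exc) from exc
        log.info("stage %s: %s", stage, counts)
        report["stages"][stage] = counts
    if "classify" in report["stages"]:
        with open(cfg.path("translated_circrnas.tsv")) as fh:
            report["translated_circrnas"] = fh.read().splitlines()[1:]
    _write_report(cfg, report)
    return report


def _write_report(cfg: PipelineConfig, report: dict) -> None:
    with open(cfg.path("report.yaml"), "w") as fh:
        yaml.safe_dump(report, fh, sort_keys=True)


def simulate_to_dir(cfg: simdata.SimConfig, outdir) -> PipelineConfig:
    """Generate a synthetic bundle and a pipeline config pointing at it."""
    bundle = simdata.simulate_dataset(cfg)
    paths = simdata.write_bundle(bundle, outdir)
    return PipelineConfig(
        outdir=str(Path(outdir) / "out"),
        reads_fastq=str(paths["reads"]),
        circ_fasta=str(paths["circs"]),
        rrna_fasta=str(paths["rrna"]),
        genome_fasta=str(paths["genome"]),
        train_coding_fasta=str(paths["train_coding"]),
        train_noncoding_fasta=str(paths["train_noncoding"]),
        adapters=(cfg.adapter,),
        seed=cfg.seed,
    )
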