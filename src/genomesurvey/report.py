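"""End-to-end survey orchestration: qc -> kmer -> estimate -> assembly ->
gc-depth -> ssr, with file-based stage outputs and one consolidated report.

Stages communicate through files and plain data structures so any stage
can be re-run or inspected on its own. Rerunning with the same config and
inputs reproduces byte-identical numeric outputs; provenance (version,
config hash, timestamps) lives in a separate block that callers may strip
when diffing reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .assembly import compute_stats
from .gcdepth import summarize_gc, window_gc_depth, write_records_tsv as write_gc_tsv
from .io import read_fasta, read_fastq
from .kmer import analyze_spectrum, count_kmer_table
from .qc import run_qc
from .ssr import find_ssrs, summarize_ssrs, write_records_tsv as write_ssr_tsv

logger = logging.getLogger("genomesurvey")

__all__ = ["SurveyConfig", "StageError", "run_survey"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass
class SurveyConfig:
    """Inputs and knobs for a full survey run.

    Reads (``reads1``/``reads2``) drive QC and the k-mer spectrum; the
    assembly FASTAs drive assembly statistics, the GC-depth profile and
    SSR mining. Any missing input marks its sections as skipped.
    """

    reads1: str | None = None
    reads2: str | None = None
    contigs_fasta: str | None = None
    scaffolds_fasta: str | None = None
    adapters: list[str] = field(default_factory=list)
    k: int = 17
    window: int = 500
    ssr_min_len: int = 12
    max_n_frac: float = 0.1
    min_q: int = 5
    max_lowq_frac: float = 0.5
    seed: int = 0
    out_dir: str = "survey_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SurveyConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write_tsv_row(path: Path, header: list[str], row: list) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        fh.write("\t".join(str(x) for x in row) + "\n")


def run_survey(config: SurveyConfig) -> dict:
    """Run every configured stage; return the consolidated report dict.

    Writes per-stage files plus ``survey_report.json`` into
    ``config.out_dir``. While a run is in progress a ``run.partial``
    marker sits in the output directory; it is removed on success, so its
    presence flags outputs from an aborted run.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    marker = out / "run.partial"
    marker.touch()
    config.to_yaml(out / "config.yaml")

    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    report: dict = {
        "qc": "skipped",
        "spectrum": "skipped",
        "assembly": "skipped",
        "gc": "skipped",
        "ssr": "skipped",
        "provenance": {
            "version": __version__,
            "config_hash": config.config_hash(),
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        },
    }
    try:
        clean = None
        if config.reads1 and config.reads2:
            stage = "qc"
            try:
                logger.info("stage qc: filtering reads")
                raw1 = read_fastq(config.reads1)
                raw2 = read_fastq(config.reads2)
                c1, c2, stats = run_qc(
                    raw1,
                    raw2,
                    adapter_seqs=config.adapters,
                    max_n_frac=config.max_n_frac,
                    min_q=config.min_q,
                    max_lowq_frac=config.max_lowq_frac,
                )
                clean = (c1, c2)
                report["qc"] = stats.as_dict()
                _write_tsv_row(
                    out / "qc_stats.tsv",
                    ["raw_bases", "effective_rate", "clean_bases", "error_rate", "q20", "q30", "gc_content"],
                    [
                        stats.raw_bases,
                        f"{stats.effective_rate:.2f}",
                        stats.clean_bases,
                        f"{stats.error_rate:.2f}",
                        f"{stats.q20:.2f}",
                        f"{stats.q30:.2f}",
                        f"{stats.gc_content:.2f}",
                    ],
                )
            except Exception as exc:  # noqa: BLE001
                raise StageError(stage, exc) from exc

            stage = "kmer"
            try:
                logger.info("stage kmer: counting %d-mers", config.k)
                table = count_kmer_table([clean[0], clean[1]], k=config.k)
                hist = table.histogram()
                hist.to_tsv(out / "kmer_histogram.tsv")
                est = analyze_spectrum(hist)
                report["spectrum"] = est.as_dict()
                with open(out / "spectrum.json", "w") as fh:
                    json.dump(est.as_dict(), fh, indent=2)
                    fh.write("\n")
            except Exception as exc:  # noqa: BLE001
                raise StageError(stage, exc) from exc
        else:
            table = None

        asm_rows = []
        for label, path in (("contig", config.contigs_fasta), ("scaffold", config.scaffolds_fasta)):
            if not path:
                continue
            stage = "asm-stats"
            try:
                logger.info("stage asm-stats: %s", label)
                recs = read_fasta(path)
                st = compute_stats(recs)
                asm_rows.append((label, st))
            except Exception as exc:  # noqa: BLE001
                raise StageError(stage, exc) from exc
        if asm_rows:
            report["assembly"] = {label: st.as_dict() for label, st in asm_rows}
            with open(out / "assembly_stats.tsv", "w") as fh:
                fh.write("set\ttotal_length\ttotal_number\tmax_length\tn50\tn90\n")
                for label, st in asm_rows:
                    fh.write(
                        f"{label}\t{st.total_length}\t{st.total_number}"
                        f"\t{st.max_length}\t{st.n50}\t{st.n90}\n"
                    )

        scaff_path = config.scaffolds_fasta or config.contigs_fasta
        if scaff_path:
            scaff = read_fasta(scaff_path)
            if table is not None:
                stage = "gc-depth"
                try:
                    logger.info("stage gc-depth: window=%d", config.window)
                    gc_records = window_gc_depth(scaff, table, window=config.window)
                    write_gc_tsv(gc_records, out / "gc_depth.tsv")
                    summ = summarize_gc(gc_records)
                    report["gc"] = {
                        "mean_gc": summ.mean_gc,
                        "gc_low": summ.gc_low,
                        "gc_high": summ.gc_high,
                        "depth_quartiles": list(summ.depth_quartiles),
                        "n_windows": summ.n_windows,
                    }
                except Exception as exc:  # noqa: BLE001
                    raise StageError(stage, exc) from exc

            stage = "ssr"
            try:
                logger.info("stage ssr: min span %d", config.ssr_min_len)
                ssr_records = []
                for rec in scaff:
                    ssr_records.extend(find_ssrs(rec, min_total_len=config.ssr_min_len))
                write_ssr_tsv(ssr_records, out / "ssr_loci.tsv")
                summary = summarize_ssrs(ssr_records)
                report["ssr"] = summary.as_dict()
                with open(out / "ssr_summary.tsv", "w") as fh:
                    classes = list(summary.counts)
                    fh.write("statistic\t" + "\t".join(classes) + "\ttotal\n")
                    fh.write(
                        "count\t" + "\t".join(str(summary.counts[c]) for c in classes)
                        + f"\t{summary.total}\n"
                    )
                    fh.write(
                        "percent\t"
                        + "\t".join(f"{summary.percentages[c]:.2f}" for c in classes)
                        + "\t100.00\n"
                    )
            except Exception as exc:  # noqa: BLE001
                raise StageError(stage, exc) from exc

        with open(out / "survey_report.json", "w") as fh:
            json.dump(report, fh, indent=2)
            fh.write("\n")
        marker.unlink(missing_ok=True)
        return report
    finally:
        logger.removeHandler(handler)
        handler.close()
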