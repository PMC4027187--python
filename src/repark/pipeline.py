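"""End-to-end pipeline: count -> threshold -> extract -> assemble -> stats
[-> evaluate], with persisted intermediates and a provenance record.

Intermediate files use the open per-stage formats, so any stage can be
substituted externally (e.g. a histogram produced by another k-mer
counter can be fed to the threshold stage, or the abundant k-mer FASTA
to another de Bruijn assembler).
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field, asdict

from . import __version__
from .assembly import (
    DEFAULT_K_ASM, DEFAULT_MIN_LEN, RepeatLibrary, assemble_unitigs,
    build_graph, write_library,
)
from .errors import ParameterError
from .evaluate import (
    DEFAULT_REPEAT_IDENTITY, EvaluationReport, classify_repetitive,
    family_completeness, map_consensuses, mask_reference, hits_to_tsv,
)
from .io_seq import SequenceRecord, read_sequences, write_sequences
from .kmer import (
    DEFAULT_K, count_kmers, histogram, write_histogram, write_spectrum,
)
from .metrics import LibraryMetrics, summarize
from .threshold import ThresholdEstimate, estimate_threshold, extract_abundant

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Parameters of one pipeline run."""

    reads: str
    outdir: str
    k_count: int = DEFAULT_K
    k_asm: int = DEFAULT_K_ASM
    safety_factor: float = 2.0
    manual_T: int | None = None
    min_len: int = DEFAULT_MIN_LEN
    min_identity: float = DEFAULT_REPEAT_IDENTITY
    seed: int | None = None
    reference: str | None = None
    families: str | None = None

    def validate(self) -> None:
        if self.k_asm > self.k_count:
            raise ParameterError(
                f"k_asm ({self.k_asm}) must not exceed k_count ({self.k_count})"
            )
        if self.safety_factor <= 0:
            raise ParameterError("safety_factor must be > 0")
        if not 0 < self.min_identity <= 1:
            raise ParameterError("min_identity must be in (0, 1]")
        if self.min_len < 1:
            raise ParameterError("min_len must be >= 1")


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(
    config: RunConfig,
) -> tuple[RepeatLibrary, LibraryMetrics, EvaluationReport | None]:
    """Execute all stages; intermediates and a provenance record are
    written under config.outdir. Output bytes are a pure function of the
    inputs and parameters."""
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    out = lambda name: os.path.join(config.outdir, name)

    t0 = time.monotonic()
    reads = list(read_sequences(config.reads))
    logger.info("stage read: %d reads (%.1fs)", len(reads), time.monotonic() - t0)

    t0 = time.monotonic()
    spectrum = count_kmers(reads, k=config.k_count)
    hist = histogram(spectrum)
    write_histogram(hist, out("spectrum.histo.tsv"))
    logger.info(
        "stage count: %d distinct %d-mers (%.1fs)",
        len(spectrum), config.k_count, time.monotonic() - t0,
    )

    estimate: ThresholdEstimate | None = None
    if config.manual_T is not None:
        T = config.manual_T
        threshold_report: dict = {"T": T, "manual": True}
    else:
        estimate = estimate_threshold(hist, safety_factor=config.safety_factor)
        T = estimate.T
        threshold_report = {**estimate.as_dict(), "manual": False}
    with open(out("threshold.json"), "wt") as fh:
        json.dump(threshold_report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("stage threshold: T=%d", T)

    abundant = extract_abundant(spectrum, T)
    write_sequences(
        (SequenceRecord(id=f"kmer_{i}", seq=s) for i, s in enumerate(abundant)),
        out("abundant.fa"),
        wrap=0,
    )
    if not abundant:
        logger.warning("no abundant k-mers at T=%d: library will be empty", T)
    logger.info("stage extract: %d abundant k-mers", len(abundant))

    t0 = time.monotonic()
    graph = build_graph(abundant, k_asm=config.k_asm)
    library = assemble_unitigs(graph, min_len=config.min_len)
    library.params.update(
        {"k_count": config.k_count, "T": T, "k_asm": config.k_asm,
         "min_len": config.min_len}
    )
    write_library(library, out("repark_lib.fa"))
    logger.info(
        "stage assemble: %d consensuses (%.1fs)",
        len(library), time.monotonic() - t0,
    )

    stats = summarize(library)
    with open(out("metrics.json"), "wt") as fh:
        json.dump(stats.as_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")

    report: EvaluationReport | None = None
    if config.reference is not None and len(library) > 0:
        t0 = time.monotonic()
        reference = list(read_sequences(config.reference))
        hits = map_consensuses(library, reference)
        hits_to_tsv(hits, out("hits.tsv"))
        report = classify_repetitive(hits, library, config.min_identity)
        report.masked_fraction = mask_reference(
            hits, reference, config.min_identity
        )
        if config.families is not None:
            fams = list(read_sequences(config.families))
            report.family_completeness = family_completeness(
                fams, library, config.min_identity
            )
        with open(out("evaluation.json"), "wt") as fh:
            json.dump(report.as_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        logger.info("stage evaluate: done (%.1fs)", time.monotonic() - t0)

    provenance = {
        "tool": "repark",
        "version": __version__,
        "config": asdict(config),
        "inputs": {
            "reads_sha256": _sha256(config.reads),
            **(
                {"reference_sha256": _sha256(config.reference)}
                if config.reference else {}
            ),
        },
        "threshold": threshold_report,
        "metrics": stats.as_dict(),
    }
    with open(out("provenance.json"), "wt") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return library, stats, report
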