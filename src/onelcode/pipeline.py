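"""End-to-end pipeline: transcribe → scan motifs → search → classify.

Each peptide record is expanded into its four variants; each variant is
scanned for motifs and searched against the transcriptome independently;
hits are pooled and classified into strand-based regulation calls.  Every
output file re-parses under this package's own readers, and identical
config + inputs give byte-identical outputs.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, List

from . import classify as classify_mod
from . import io as io_mod
from .code import builtin_code
from .motifs import MotifHit, scan_all
from .search import (
    AlignmentHit,
    build_word_index,
    format_blast_tabular,
    seed_extend_search,
)
from .transcribe import TranscriptVariant, enumerate_variants

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: io_mod.PipelineConfig) -> Dict[str, Path]:
    """Run the full pipeline per config; returns the written file paths."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    code = builtin_code()

    try:
        peptides = io_mod.read_fasta(config.peptide_fasta)
    except Exception as exc:
        raise PipelineError("read-peptides", exc) from exc

    variants: List[TranscriptVariant] = []
    for pid, seq in peptides.items():
        all_four = enumerate_variants(seq, code, peptide_id=pid)
        variants.extend(
            v
            for v in all_four
            if v.direction in config.directions and v.serine_policy in config.serine_policies
        )
    logger.info("transcribe: %d peptides -> %d variants", len(peptides), len(variants))

    motif_hits: List[MotifHit] = []
    for v in variants:
        motif_hits.extend(
            scan_all(v, window=config.are3_window, t_fraction=config.are3_t_fraction)
        )
    logger.info("motifs: %d hits", len(motif_hits))

    try:
        transcriptome = io_mod.read_fasta(config.transcriptome_fasta)
        index = build_word_index(transcriptome, config.search.word_size)
        hits: List[AlignmentHit] = []
        for v in variants:
            hits.extend(seed_extend_search(v, index, transcriptome, config.search))
    except Exception as exc:
        raise PipelineError("search", exc) from exc
    logger.info("search: %d hits on %d transcripts", len(hits),
                len({h.subject_id for h in hits}))

    gene_map = io_mod.read_gene_map(config.gene_map) if config.gene_map else None
    calls = classify_mod.classify_hits(hits, gene_map=gene_map)
    logger.info("classify: %d calls (%d repressive, %d promotive)", len(calls),
                sum(c.mode == "repressive" for c in calls),
                sum(c.mode == "promotive" for c in calls))

    paths = {
        "variants_fasta": out_dir / "variants.fasta",
        "motifs_tsv": out_dir / "motifs.tsv",
        "hits_tsv": out_dir / "hits.tsv",
        "calls_tsv": out_dir / "calls.tsv",
        "calls_json": out_dir / "calls.json",
    }
    io_mod.write_variants_fasta(variants, paths["variants_fasta"], alphabet=config.alphabet)
    io_mod.write_motif_tsv(motif_hits, paths["motifs_tsv"])
    paths["hits_tsv"].write_text(format_blast_tabular(hits))
    paths["calls_tsv"].write_text(classify_mod.render_report(calls, "tsv"))
    paths["calls_json"].write_text(classify_mod.render_report(calls, "json"))
    return paths
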