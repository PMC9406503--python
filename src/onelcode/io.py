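"""FASTA / TSV / config readers and writers.

FASTA goes through Bio.SeqIO; sequences are upper-cased on read and ids
must be unique.  Motif and hit tables are plain TSV so they re-parse with
pandas or this module's own readers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Tuple, Union

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .motifs import DEFAULT_ARE3_T_FRACTION, DEFAULT_ARE3_WINDOW, MotifHit
from .search import SearchParams
from .transcribe import TranscriptVariant

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


def read_fasta(path: PathLike) -> Dict[str, str]:
    """Read FASTA into an ordered {id: SEQUENCE} map.

    Sequence case is normalized to upper.  Duplicate ids and empty files
    are errors.
    """
    records: Dict[str, str] = {}
    dupes: List[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            dupes.append(rec.id)
        records[rec.id] = str(rec.seq).upper()
    if dupes:
        raise ValueError(f"duplicate FASTA ids in {path}: {sorted(set(dupes))}")
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Mapping[str, str], path: PathLike, width: int = 70) -> None:
    seqs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


def write_variants_fasta(
    variants: Iterable[TranscriptVariant], path: PathLike, alphabet: str = "dna"
) -> None:
    """Variant FASTA keyed by the deterministic variant ids; usable directly
    as BLASTn query input (alphabet "rna" renders T as U for display)."""
    if alphabet not in ("dna", "rna"):
        raise ValueError(f"alphabet must be 'dna' or 'rna', got {alphabet!r}")
    out = {
        v.variant_id: (v.sequence if alphabet == "dna" else v.rna()) for v in variants
    }
    write_fasta(out, path)


def write_motif_tsv(hits: Iterable[MotifHit], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("variant_id\tmotif_class\tstart\tend\tmatched\n")
        for h in hits:
            fh.write(f"{h.variant_id}\t{h.motif_class}\t{h.start}\t{h.end}\t{h.matched}\n")


def read_gene_map(path: PathLike) -> Dict[str, str]:
    """Two-column transcript→gene TSV (header optional)."""
    mapping: Dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 2:
            raise ValueError(f"gene map rows need 2 columns, got {len(cols)}: {line!r}")
        if cols[0].lower() in ("transcript", "transcript_id"):
            continue
        mapping[cols[0]] = cols[1]
    return mapping


@dataclass
class PipelineConfig:
    """Full-pipeline configuration; unspecified fields keep the documented
    defaults (the standard search settings: word 7, +2/−3, E ≤ 100, 500
    targets)."""

    peptide_fasta: Optional[str] = None
    transcriptome_fasta: Optional[str] = None
    out_dir: str = "onelcode_out"
    directions: Tuple[str, ...] = ("forward", "reverse")
    serine_policies: Tuple[str, ...] = ("C", "G")
    alphabet: str = "dna"
    are3_window: int = DEFAULT_ARE3_WINDOW
    are3_t_fraction: float = DEFAULT_ARE3_T_FRACTION
    search: SearchParams = field(default_factory=SearchParams)
    gene_map: Optional[str] = None
    report_format: str = "tsv"
    log_level: str = "INFO"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: PathLike) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "PipelineConfig":
        raw = dict(raw)
        search_raw = raw.pop("search", {}) or {}
        if isinstance(search_raw.get("lambda_k"), list):
            search_raw["lambda_k"] = tuple(search_raw["lambda_k"])
        known = {f.name for f in dc_fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("directions", "serine_policies"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(search=SearchParams(**search_raw), **raw)
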