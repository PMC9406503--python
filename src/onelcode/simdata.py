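"""Synthetic transcriptomes with planted ground truth.

Backgrounds are i.i.d. nucleotide sequences with a configurable GC
fraction (no higher-order composition, UTR structure or splicing — a
documented limitation).  Queries are planted by *substitution* at a
recorded offset, on the plus strand verbatim or on the minus strand as
the reverse complement, so transcript lengths never change and the
manifest's coordinates are exact.  All randomness flows through a single
integer seed: regeneration is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .search import reverse_complement

_ALPHABET = np.array(list("ACGT"))


@dataclass(frozen=True)
class PlantRecord:
    subject_id: str
    planted_query_id: str
    strand: str  # "plus" | "minus"
    offset: int  # 0-based start of the planted window on the transcript
    planted_sequence: str  # the sequence as it appears on the plus strand


@dataclass
class PlantManifest:
    """Ground truth for planted occurrences, with generation parameters."""

    records: List[PlantRecord] = field(default_factory=list)
    seed: Optional[int] = None
    gc_fraction: Optional[float] = None
    length_range: Optional[Tuple[int, int]] = None

    def verify(self, transcriptome: Dict[str, str]) -> None:
        """Assert every planted window is present where the manifest says."""
        for r in self.records:
            seq = transcriptome[r.subject_id]
            window = seq[r.offset : r.offset + len(r.planted_sequence)]
            if window != r.planted_sequence:
                raise AssertionError(
                    f"manifest mismatch on {r.subject_id}@{r.offset}: "
                    f"expected {r.planted_sequence}, found {window}"
                )

    def to_tsv(self) -> str:
        lines = ["subject_id\tplanted_query_id\tstrand\toffset\tplanted_sequence"]
        for r in self.records:
            lines.append(
                f"{r.subject_id}\t{r.planted_query_id}\t{r.strand}"
                f"\t{r.offset}\t{r.planted_sequence}"
            )
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "gc_fraction": self.gc_fraction,
                "length_range": list(self.length_range) if self.length_range else None,
                "records": [r.__dict__ for r in self.records],
            },
            indent=2,
        )

    @classmethod
    def from_tsv(cls, text: str) -> "PlantManifest":
        records = []
        for line in text.splitlines()[1:]:
            if not line.strip():
                continue
            sid, qid, strand, offset, seq = line.split("\t")
            records.append(PlantRecord(sid, qid, strand, int(offset), seq))
        return cls(records=records)


def random_transcriptome(
    n_transcripts: int,
    length_range: Tuple[int, int],
    gc_fraction: float = 0.5,
    seed: int = 0,
) -> Dict[str, str]:
    """Reproducible i.i.d. background transcripts, headers ``synth_0001``…"""
    lo, hi = length_range
    if n_transcripts < 1:
        raise ValueError("n_transcripts must be >= 1")
    if lo < 50 or hi < lo:
        raise ValueError(f"lengths must satisfy 50 <= lo <= hi, got ({lo}, {hi})")
    if not (0 < gc_fraction < 1):
        raise ValueError(f"gc_fraction must be in (0, 1), got {gc_fraction}")
    rng = np.random.default_rng(seed)
    p = np.array(
        [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    )  # A C G T
    out: Dict[str, str] = {}
    for i in range(1, n_transcripts + 1):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(_ALPHABET[rng.choice(4, size=length, p=p)])
        out[f"synth_{i:04d}"] = seq
    return out


def plant(
    transcriptome: Dict[str, str],
    query: str,
    strand: str = "plus",
    query_id: str = "query",
    seed: int = 0,
    subjects: Optional[Sequence[str]] = None,
) -> Tuple[Dict[str, str], PlantManifest]:
    """Plant the query into transcripts by substitution.

    On strand "plus" the query is planted verbatim; on "minus" its reverse
    complement is.  One plant per chosen subject (default: one random
    subject).  Returns a modified copy of the transcriptome plus the
    manifest recording (subject, offset, planted sequence).
    """
    if strand not in ("plus", "minus"):
        raise ValueError(f"strand must be plus/minus, got {strand!r}")
    query = query.upper()
    rng = np.random.default_rng(seed)
    ids = list(transcriptome)
    chosen = list(subjects) if subjects is not None else [ids[int(rng.integers(len(ids)))]]
    out = dict(transcriptome)
    manifest = PlantManifest(seed=seed)
    planted = query if strand == "plus" else reverse_complement(query)
    for sid in chosen:
        seq = out[sid]
        if len(query) > len(seq):
            raise ValueError(
                f"query ({len(query)} nt) longer than transcript {sid} ({len(seq)} nt)"
            )
        offset = int(rng.integers(len(seq) - len(planted) + 1))
        out[sid] = seq[:offset] + planted + seq[offset + len(planted) :]
        manifest.records.append(
            PlantRecord(sid, query_id, strand, offset, planted)
        )
    manifest.verify(out)
    return out, manifest


def planted_transcriptome(
    query: str,
    n_plants: int = 20,
    n_background: int = 20,
    length_range: Tuple[int, int] = (200, 400),
    gc_fraction: float = 0.5,
    seed: int = 0,
    query_id: str = "query",
) -> Tuple[Dict[str, str], PlantManifest]:
    """Background + n_plants transcripts with the query planted, strands
    alternating plus/minus deterministically from the seed."""
    total = n_plants + n_background
    txome = random_transcriptome(total, length_range, gc_fraction, seed)
    rng = np.random.default_rng(seed + 1)
    ids = list(txome)
    chosen = [ids[i] for i in rng.permutation(total)[:n_plants]]
    manifest = PlantManifest(
        seed=seed, gc_fraction=gc_fraction, length_range=length_range
    )
    out = dict(txome)
    for k, sid in enumerate(chosen):
        strand = "plus" if k % 2 == 0 else "minus"
        out, sub = plant(out, query, strand=strand, query_id=query_id,
                         seed=seed + 2 + k, subjects=[sid])
        manifest.records.extend(sub.records)
    manifest.verify(out)
    return out, manifest
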