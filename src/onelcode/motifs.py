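"""Regulatory motif scanners for transcribed variants.

Scans the "imaginary RNA" (DNA spelling) produced by transcription for:

* PAS — the polyadenylation signal hexamer AAUAAA (DNA ``AATAAA``);
* ARE class I — the pentamer AUUUA (``ATTTA``), every occurrence;
* ARE class II — maximal runs of two or more overlapping AUUUA copies
  offset 4 apart (``ATTTATTTA…``), one hit per run;
* ARE class III — U-rich stretches: every literal ``TTTC`` plus every
  maximal window of length ≥ w whose T fraction is ≥ f.

Scanning is literal and strand-naive: no complementing is performed, and
all overlapping occurrences are reported (class II merges by definition).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Union

from .transcribe import TranscriptVariant

MOTIF_CLASSES = ("PAS", "ARE_I", "ARE_II", "ARE_III")

PAS_MOTIF = "AATAAA"
ARE_PENTAMER = "ATTTA"
ARE3_LITERAL = "TTTC"

#: Default U-rich window length and T-fraction threshold for ARE class III.
DEFAULT_ARE3_WINDOW = 8
DEFAULT_ARE3_T_FRACTION = 0.75


@dataclass(frozen=True)
class MotifHit:
    """A motif occurrence on a variant, 0-based half-open coordinates."""

    variant_id: str
    motif_class: str
    start: int
    end: int
    matched: str

    def __post_init__(self) -> None:
        if self.motif_class not in MOTIF_CLASSES:
            raise ValueError(f"unknown motif class {self.motif_class!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad coordinates [{self.start}, {self.end})")
        if self.end - self.start != len(self.matched):
            raise ValueError("matched text length disagrees with coordinates")


def _seq_and_id(variant: Union[TranscriptVariant, str], variant_id: str) -> tuple[str, str]:
    if isinstance(variant, TranscriptVariant):
        return variant.sequence, variant.variant_id
    return variant.upper(), variant_id


def _find_all(seq: str, motif: str) -> List[int]:
    """All (overlapping) start offsets of motif in seq, left to right."""
    hits, i = [], seq.find(motif)
    while i != -1:
        hits.append(i)
        i = seq.find(motif, i + 1)
    return hits


def scan_pas(variant: Union[TranscriptVariant, str], variant_id: str = "seq") -> List[MotifHit]:
    """One hit per exact AATAAA occurrence, overlapping ones included."""
    seq, vid = _seq_and_id(variant, variant_id)
    return [
        MotifHit(vid, "PAS", i, i + len(PAS_MOTIF), seq[i : i + len(PAS_MOTIF)])
        for i in _find_all(seq, PAS_MOTIF)
    ]


def _scan_are_i(seq: str, vid: str) -> List[MotifHit]:
    return [
        MotifHit(vid, "ARE_I", i, i + 5, seq[i : i + 5])
        for i in _find_all(seq, ARE_PENTAMER)
    ]


def _scan_are_ii(seq: str, vid: str) -> List[MotifHit]:
    # Chain ATTTA occurrences offset exactly 4 apart; runs of >=2 copies
    # merge into a single hit spanning the run (ATTTATTTA -> [0, 9)).
    starts = _find_all(seq, ARE_PENTAMER)
    hits: List[MotifHit] = []
    i = 0
    pos = set(starts)
    while i < len(starts):
        run_start = starts[i]
        copies = 1
        nxt = run_start + 4
        while nxt in pos:
            copies += 1
            nxt += 4
        if copies >= 2:
            end = run_start + 4 * copies + 1
            hits.append(MotifHit(vid, "ARE_II", run_start, end, seq[run_start:end]))
        # skip the occurrences consumed by this chain
        while i < len(starts) and starts[i] < run_start + 4 * copies:
            i += 1
    return hits


def _scan_are_iii(seq: str, vid: str, window: int, t_fraction: float) -> List[MotifHit]:
    hits = [
        MotifHit(vid, "ARE_III", i, i + 4, seq[i : i + 4])
        for i in _find_all(seq, ARE3_LITERAL)
    ]
    n = len(seq)
    # prefix T counts for O(1) window fractions
    pref = [0] * (n + 1)
    for i, ch in enumerate(seq):
        pref[i + 1] = pref[i] + (ch == "T")

    def frac_ok(i: int, j: int) -> bool:
        return pref[j] - pref[i] >= t_fraction * (j - i)

    # longest qualifying window per start, then drop contained candidates
    candidates: List[tuple[int, int]] = []
    for i in range(n - window + 1):
        best = -1
        for j in range(n, i + window - 1, -1):
            if frac_ok(i, j):
                best = j
                break
        if best > 0:
            candidates.append((i, best))
    maximal = [
        (i, j)
        for i, j in candidates
        if not any(
            (i2 <= i and j2 >= j and (i2, j2) != (i, j)) for i2, j2 in candidates
        )
    ]
    hits.extend(MotifHit(vid, "ARE_III", i, j, seq[i:j]) for i, j in maximal)
    hits.sort(key=lambda h: (h.start, h.end))
    return hits


def scan_are(
    variant: Union[TranscriptVariant, str],
    are_class: str,
    window: int = DEFAULT_ARE3_WINDOW,
    t_fraction: float = DEFAULT_ARE3_T_FRACTION,
    variant_id: str = "seq",
) -> List[MotifHit]:
    """Scan one ARE class; see the module docstring for class semantics.

    ``window`` and ``t_fraction`` apply to class III only (window length
    ≥ 4, fraction in (0, 1]).
    """
    if are_class not in ("ARE_I", "ARE_II", "ARE_III"):
        raise ValueError(f"are_class must be ARE_I/ARE_II/ARE_III, got {are_class!r}")
    if window < 4:
        raise ValueError(f"class-III window must be >= 4, got {window}")
    if not (0 < t_fraction <= 1):
        raise ValueError(f"t_fraction must be in (0, 1], got {t_fraction}")
    seq, vid = _seq_and_id(variant, variant_id)
    if are_class == "ARE_I":
        return _scan_are_i(seq, vid)
    if are_class == "ARE_II":
        return _scan_are_ii(seq, vid)
    return _scan_are_iii(seq, vid, window, t_fraction)


def scan_all(
    variant: Union[TranscriptVariant, str],
    window: int = DEFAULT_ARE3_WINDOW,
    t_fraction: float = DEFAULT_ARE3_T_FRACTION,
    variant_id: str = "seq",
) -> List[MotifHit]:
    """PAS plus all three ARE classes, concatenated in class order."""
    hits = scan_pas(variant, variant_id=variant_id)
    for cls in ("ARE_I", "ARE_II", "ARE_III"):
        hits.extend(scan_are(variant, cls, window, t_fraction, variant_id=variant_id))
    return hits
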