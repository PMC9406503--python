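"""Word-seeded local alignment of variants against a transcriptome.

The search mirrors short-query BLASTn mechanics: exact words of length
``word_size`` (default 7) shared between query and subject nominate
candidate (subject, strand) pairs; each candidate is then scored by an
exact affine-gap Smith–Waterman alignment.  Because 1-L queries are short
(tens of nucleotides), running the full dynamic program on every seeded
candidate is cheap and makes the reported best score per (subject, strand)
exactly the local-alignment optimum — seeding acts purely as a candidate
filter, never as a band constraint.

The minus strand is handled by reverse-complementing the query and
searching the plus-strand index; coordinates are emitted 1-based inclusive
with the BLAST convention (``s_start > s_end`` signals a minus-strand hit).

Expectation values follow Karlin–Altschul statistics,
``E = K·m·n·exp(−λS)``, with (λ, K) from a precomputed table for the
default +2/−3 scheme; custom schemes must supply their own (λ, K).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, TextIO, Tuple, Union

from .transcribe import TranscriptVariant

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# (λ, K) for supported scoring schemes, natural-log scale.
# Keys: (match, mismatch, gap_open, gap_extend); (0, 0) gap costs mean ungapped.
_KA_TABLE: Dict[Tuple[int, int, int, int], Tuple[float, float]] = {
    (2, -3, 0, 0): (0.634, 0.408),
    (2, -3, 5, 2): (0.625, 0.410),
    (1, -2, 0, 0): (1.33, 0.621),
}

BLAST_TABULAR_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SearchParams:
    """Alignment and reporting parameters (defaults mirror short-query blastn)."""

    word_size: int = 7
    match: int = 2
    mismatch: int = -3
    gap_open: int = 5   # penalty, applied once per gap
    gap_extend: int = 2  # penalty per gapped column (first included)
    evalue_max: float = 100.0
    max_targets: int = 500
    lambda_k: Optional[Tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.word_size < 4:
            raise ValueError(f"word_size must be >= 4, got {self.word_size}")
        if not (self.match > 0 > self.mismatch):
            raise ValueError("require match > 0 > mismatch")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be >= 0")
        if self.evalue_max <= 0:
            raise ValueError("evalue_max must be > 0")
        if self.max_targets < 1:
            raise ValueError("max_targets must be >= 1")

    def resolve_lambda_k(self) -> Tuple[float, float]:
        """(λ, K) for this scheme, from the table or the user override."""
        if self.lambda_k is not None:
            return self.lambda_k
        key = (self.match, self.mismatch, self.gap_open, self.gap_extend)
        if key in _KA_TABLE:
            return _KA_TABLE[key]
        raise ValueError(
            f"no precomputed Karlin–Altschul (λ, K) for scoring scheme "
            f"match={self.match} mismatch={self.mismatch} "
            f"gap_open={self.gap_open} gap_extend={self.gap_extend}; "
            f"supply lambda_k=(λ, K) explicitly"
        )


@dataclass(frozen=True)
class AlignmentHit:
    """A local alignment between a query variant and a transcript.

    Coordinates are 1-based inclusive.  ``strand == "minus"`` iff
    ``s_start > s_end`` (subject coordinates are always plus-strand
    positions, per the BLAST tabular convention).
    """

    query_id: str
    subject_id: str
    strand: str  # "plus" | "minus"
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    score: float  # raw alignment score
    identity_pct: float
    align_len: int
    mismatches: int
    gap_opens: int
    evalue: float
    bit_score: float

    def __post_init__(self) -> None:
        if self.strand not in ("plus", "minus"):
            raise ValueError(f"strand must be plus/minus, got {self.strand!r}")
        if not (1 <= self.q_start <= self.q_end):
            raise ValueError("query coordinates must satisfy 1 <= q_start <= q_end")
        if (self.strand == "minus") != (self.s_start > self.s_end):
            raise ValueError("strand label inconsistent with subject coordinates")
        if not (0 < self.identity_pct <= 100):
            raise ValueError("identity_pct must be in (0, 100]")
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")


def evalue(score: float, query_len: int, db_len: int,
           lambda_k: Tuple[float, float]) -> float:
    """Karlin–Altschul expectation E = K·m·n·exp(−λS)."""
    if score <= 0:
        raise ValueError(f"score must be > 0, got {score}")
    if query_len <= 0 or db_len <= 0:
        raise ValueError("sequence lengths must be > 0")
    lam, k = lambda_k
    return k * query_len * db_len * math.exp(-lam * score)


def bit_score(score: float, lambda_k: Tuple[float, float]) -> float:
    """Normalized bit score S' = (λS − ln K) / ln 2."""
    lam, k = lambda_k
    return (lam * score - math.log(k)) / math.log(2.0)


def raw_score_from_bits(bits: float, lambda_k: Tuple[float, float]) -> float:
    lam, k = lambda_k
    return (bits * math.log(2.0) + math.log(k)) / lam


# ---------------------------------------------------------------------------
# Word index


@dataclass
class WordIndex:
    word_size: int
    postings: Dict[str, List[Tuple[str, int]]] = field(default_factory=dict)

    def lookup(self, word: str) -> List[Tuple[str, int]]:
        return self.postings.get(word, [])

    def __len__(self) -> int:
        return sum(len(v) for v in self.postings.values())


def build_word_index(transcriptome: Mapping[str, str], word_size: int = 7) -> WordIndex:
    """Index every plus-strand word of each transcript.

    Words containing N are not indexed.  The minus strand is never indexed;
    minus-strand search reverse-complements the query instead.
    """
    if not transcriptome:
        raise ValueError("empty transcriptome: nothing to index")
    if word_size < 4:
        raise ValueError(f"word_size must be >= 4, got {word_size}")
    index = WordIndex(word_size=word_size)
    for sid, seq in transcriptome.items():
        seq = seq.upper()
        for off in range(len(seq) - word_size + 1):
            word = seq[off : off + word_size]
            if "N" in word:
                continue
            index.postings.setdefault(word, []).append((sid, off))
    return index


# ---------------------------------------------------------------------------
# Affine-gap Smith–Waterman with traceback


@dataclass(frozen=True)
class _Local:
    score: int
    q_start: int  # 0-based inclusive
    q_end: int    # 0-based exclusive
    s_start: int
    s_end: int
    matches: int
    mismatches: int
    gap_opens: int
    align_len: int


def smith_waterman(query: str, subject: str, params: SearchParams) -> Optional[_Local]:
    """Best local alignment under affine gaps (gap cost open + len·extend).

    N matches nothing (scores as a mismatch against any letter).  Returns
    None when no alignment scores above zero.  Ties in the optimum are
    broken toward the smallest (subject end, query end) to keep output
    deterministic.
    """
    m, n = len(query), len(subject)
    ma, mi = params.match, params.mismatch
    go, ge = params.gap_open, params.gap_extend
    open_cost = go + ge
    NEG = -(10 ** 9)

    H = [[0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in query (move along subject)
    F = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in subject (move along query)

    best, best_i, best_j = 0, 0, 0
    for i in range(1, m + 1):
        qi = query[i - 1]
        Hi, Hp, Ei, Fi, Fp = H[i], H[i - 1], E[i], F[i], F[i - 1]
        for j in range(1, n + 1):
            s = ma if (qi == subject[j - 1] and qi != "N") else mi
            e = max(Hi[j - 1] - open_cost, Ei[j - 1] - ge)
            f = max(Hp[j] - open_cost, Fp[j] - ge)
            h = max(0, Hp[j - 1] + s, e, f)
            Ei[j], Fi[j], Hi[j] = e, f, h
            if h > best:
                best, best_i, best_j = h, i, j
    if best <= 0:
        return None

    # traceback from the first (smallest i, then j) occurrence of the optimum
    i, j, state = best_i, best_j, "H"
    matches = mismatches = gap_opens = align_len = 0
    end_i, end_j = best_i, best_j
    while i > 0 and j > 0:
        if state == "H":
            h = H[i][j]
            if h == 0:
                break
            s = params.match if (query[i - 1] == subject[j - 1] and query[i - 1] != "N") else params.mismatch
            if h == H[i - 1][j - 1] + s:
                align_len += 1
                if s == params.match:
                    matches += 1
                else:
                    mismatches += 1
                i, j = i - 1, j - 1
            elif h == E[i][j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            align_len += 1
            if E[i][j] == H[i][j - 1] - open_cost:
                gap_opens += 1
                state = "H"
            j -= 1
        else:  # F
            align_len += 1
            if F[i][j] == H[i - 1][j] - open_cost:
                gap_opens += 1
                state = "H"
            i -= 1
    return _Local(
        score=best, q_start=i, q_end=end_i, s_start=j, s_end=end_j,
        matches=matches, mismatches=mismatches, gap_opens=gap_opens,
        align_len=align_len,
    )


# ---------------------------------------------------------------------------
# Seed + extend search


def _query_of(variant: Union[TranscriptVariant, Tuple[str, str], str]) -> Tuple[str, str]:
    if isinstance(variant, TranscriptVariant):
        return variant.variant_id, variant.sequence
    if isinstance(variant, tuple):
        return variant
    return "query", variant.upper()


def _seeded_subjects(qseq: str, index: WordIndex) -> set:
    w = index.word_size
    subjects = set()
    for off in range(len(qseq) - w + 1):
        word = qseq[off : off + w]
        if "N" in word:
            continue
        for sid, _ in index.lookup(word):
            subjects.add(sid)
    return subjects


def seed_extend_search(
    variant: Union[TranscriptVariant, Tuple[str, str], str],
    index: WordIndex,
    transcriptome: Mapping[str, str],
    params: Optional[SearchParams] = None,
) -> List[AlignmentHit]:
    """Search one variant against the transcriptome on both strands.

    Every (subject, strand) sharing at least one exact ``word_size``-mer
    with the query is scored by full local alignment; the optimal alignment
    per (subject, strand) is reported if its E-value passes ``evalue_max``.
    Hits are sorted by ascending E-value (ties: subject id, then subject
    start) and at most ``max_targets`` distinct subjects are retained.
    """
    params = params or SearchParams()
    query_id, qseq = _query_of(variant)
    if len(qseq) < params.word_size:
        raise ValueError(
            f"query {query_id!r} ({len(qseq)} nt) is shorter than "
            f"word_size ({params.word_size} nt)"
        )
    if index.word_size != params.word_size:
        raise ValueError(
            f"index word size {index.word_size} != params word_size {params.word_size}"
        )
    lam_k = params.resolve_lambda_k()
    db_len = sum(len(s) for s in transcriptome.values())
    m = len(qseq)

    hits: List[AlignmentHit] = []
    for strand, sseq_query in (("plus", qseq), ("minus", reverse_complement(qseq))):
        for sid in sorted(_seeded_subjects(sseq_query, index)):
            aln = smith_waterman(sseq_query, transcriptome[sid].upper(), params)
            if aln is None:
                continue
            e = evalue(aln.score, m, db_len, lam_k)
            if e > params.evalue_max:
                continue
            if strand == "plus":
                q_start, q_end = aln.q_start + 1, aln.q_end
                s_start, s_end = aln.s_start + 1, aln.s_end
            else:
                # alignment used revcomp(query): map back to query coords,
                # swap subject ends so s_start > s_end flags the strand
                q_start, q_end = m - aln.q_end + 1, m - aln.q_start
                s_start, s_end = aln.s_end, aln.s_start + 1
            hits.append(
                AlignmentHit(
                    query_id=query_id, subject_id=sid, strand=strand,
                    q_start=q_start, q_end=q_end, s_start=s_start, s_end=s_end,
                    score=float(aln.score),
                    identity_pct=round(100.0 * aln.matches / aln.align_len, 3),
                    align_len=aln.align_len, mismatches=aln.mismatches,
                    gap_opens=aln.gap_opens, evalue=e,
                    bit_score=round(bit_score(aln.score, lam_k), 1),
                )
            )
    hits.sort(key=lambda h: (h.evalue, h.subject_id, min(h.s_start, h.s_end)))
    kept_subjects: List[str] = []
    kept: List[AlignmentHit] = []
    for h in hits:
        if h.subject_id not in kept_subjects:
            if len(kept_subjects) >= params.max_targets:
                continue
            kept_subjects.append(h.subject_id)
        kept.append(h)
    return kept


def search_all_variants(
    variants: Sequence[TranscriptVariant],
    transcriptome: Mapping[str, str],
    params: Optional[SearchParams] = None,
) -> List[AlignmentHit]:
    """Search each variant independently and pool the hits."""
    params = params or SearchParams()
    index = build_word_index(transcriptome, params.word_size)
    hits: List[AlignmentHit] = []
    for v in variants:
        hits.extend(seed_extend_search(v, index, transcriptome, params))
    return hits


# ---------------------------------------------------------------------------
# BLAST tabular (outfmt 6) interop


def format_blast_tabular(hits: Iterable[AlignmentHit]) -> str:
    """Render hits as 12-column outfmt-6 TSV (no header)."""
    rows = []
    for h in hits:
        rows.append(
            "\t".join(
                [
                    h.query_id, h.subject_id, f"{h.identity_pct:.3f}",
                    str(h.align_len), str(h.mismatches), str(h.gap_opens),
                    str(h.q_start), str(h.q_end), str(h.s_start), str(h.s_end),
                    f"{h.evalue:.3g}", f"{h.bit_score:.1f}",
                ]
            )
        )
    return "\n".join(rows) + ("\n" if rows else "")


def parse_blast_tabular(
    source: Union[str, TextIO],
    lambda_k: Optional[Tuple[float, float]] = None,
) -> List[AlignmentHit]:
    """Parse NCBI BLAST tabular output (-outfmt 6) into AlignmentHits.

    Strand is inferred from ``sstart > send``.  The raw score is
    reconstructed from the bit score under (λ, K) — the default +2/−3
    gapped scheme unless ``lambda_k`` is given.  Malformed rows raise
    ValueError naming the 1-based line number.
    """
    lam_k = lambda_k or _KA_TABLE[(2, -3, 5, 2)]
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source) as fh:
            text = fh.read()
    hits: List[AlignmentHit] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 12:
            raise ValueError(
                f"line {lineno}: expected 12 tab-separated columns, got {len(fields)}"
            )
        try:
            (qseqid, sseqid, pident, length, mism, gapo,
             qstart, qend, sstart, send, ev, bits) = fields
            pident_f = float(pident)
            length_i, mism_i, gapo_i = int(length), int(mism), int(gapo)
            qs, qe, ss, se = int(qstart), int(qend), int(sstart), int(send)
            ev_f, bits_f = float(ev), float(bits)
        except ValueError as exc:
            raise ValueError(f"line {lineno}: non-numeric field ({exc})") from None
        hits.append(
            AlignmentHit(
                query_id=qseqid, subject_id=sseqid,
                strand="minus" if ss > se else "plus",
                q_start=qs, q_end=qe, s_start=ss, s_end=se,
                score=round(raw_score_from_bits(bits_f, lam_k)),
                identity_pct=pident_f, align_len=length_i,
                mismatches=mism_i, gap_opens=gapo_i,
                evalue=ev_f, bit_score=bits_f,
            )
        )
    return hits
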