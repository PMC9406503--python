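"""Strand-aware regulatory classification of alignment hits.

The rule: a query variant aligning to the transcript sequence itself
(plus strand) marks the gene as post-transcriptionally *repressive*
(green); an alignment to the reverse complement (minus strand) marks it
*promotive* (yellow).  A subject hit on both strands yields two calls,
one per mode.

Interpretive caveat (carried into report headers): the repressive /
promotive reading is a modelling hypothesis about RBP–RNA interference —
the direction of effect may differ per RNA, per life-cycle stage and per
binding site; only the strand assignment itself is computed here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

from .search import AlignmentHit

MODE_BY_STRAND = {"plus": "repressive", "minus": "promotive"}
COLOR_BY_MODE = {"repressive": "green", "promotive": "yellow"}

REPORT_CAVEAT = (
    "# mode semantics: plus-strand (sense) alignment => repressive (green); "
    "minus-strand (antisense) => promotive (yellow). The direction of the "
    "biological effect is hypothesis-dependent and may be reversed for "
    "individual RNAs."
)


@dataclass(frozen=True)
class RegulationCall:
    """Per-(subject, mode) verdict aggregated over supporting hits."""

    subject_id: str
    mode: str  # "repressive" | "promotive"
    best_evalue: float
    best_score: float
    n_hits: int
    supporting_variants: Tuple[str, ...]

    def __post_init__(self) -> None:
        if self.mode not in COLOR_BY_MODE:
            raise ValueError(f"mode must be repressive/promotive, got {self.mode!r}")
        if self.n_hits < 1:
            raise ValueError("a call needs at least one supporting hit")

    @property
    def color(self) -> str:
        return COLOR_BY_MODE[self.mode]


def classify_hits(
    hits: Iterable[AlignmentHit],
    gene_map: Optional[Mapping[str, str]] = None,
) -> List[RegulationCall]:
    """Group hits by (subject, strand) and call one mode per group.

    ``gene_map`` optionally collapses transcript ids to gene ids before
    grouping (isoforms merge; the best E-value wins per gene per mode).
    Output is sorted by ascending best E-value, then subject id, then mode.
    """
    groups: Dict[Tuple[str, str], List[AlignmentHit]] = {}
    for h in hits:
        subject = gene_map.get(h.subject_id, h.subject_id) if gene_map else h.subject_id
        groups.setdefault((subject, h.strand), []).append(h)
    calls = []
    for (subject, strand), group in groups.items():
        variants = tuple(sorted({h.query_id for h in group}))
        calls.append(
            RegulationCall(
                subject_id=subject,
                mode=MODE_BY_STRAND[strand],
                best_evalue=min(h.evalue for h in group),
                best_score=max(h.score for h in group),
                n_hits=len(group),
                supporting_variants=variants,
            )
        )
    calls.sort(key=lambda c: (c.best_evalue, c.subject_id, c.mode))
    return calls


def render_report(calls: List[RegulationCall], fmt: str = "tsv") -> str:
    """Render calls as ``tsv`` or ``json`` with the color column."""
    if fmt == "tsv":
        lines = [
            REPORT_CAVEAT,
            "subject_id\tmode\tcolor\tbest_evalue\tbest_score\tn_hits\tsupporting_variants",
        ]
        for c in calls:
            lines.append(
                f"{c.subject_id}\t{c.mode}\t{c.color}\t{c.best_evalue:.3g}"
                f"\t{c.best_score:g}\t{c.n_hits}\t{','.join(c.supporting_variants)}"
            )
        return "\n".join(lines) + "\n"
    if fmt == "json":
        return json.dumps(
            {
                "caveat": REPORT_CAVEAT.lstrip("# "),
                "calls": [
                    {
                        "subject_id": c.subject_id,
                        "mode": c.mode,
                        "color": c.color,
                        "best_evalue": c.best_evalue,
                        "best_score": c.best_score,
                        "n_hits": c.n_hits,
                        "supporting_variants": list(c.supporting_variants),
                    }
                    for c in calls
                ],
            },
            indent=2,
        )
    raise ValueError(f"unknown report format {fmt!r} (expected 'tsv' or 'json')")
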