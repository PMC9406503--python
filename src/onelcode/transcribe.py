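"""Transcribe a peptide into its four candidate nucleotide sequences.

A peptide is read either N→C ("forward") or C→N ("reverse"), and serine is
rendered globally as C or as G, giving the four labeled variants
{forward, reverse} × {S-C, S-G}.  The reverse-mode transcript is the plain
character reversal of the forward transcript under the same serine policy
(no complementing).  Output length always equals peptide length: one
nucleotide per residue.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

from .code import OneLCode, builtin_code

DIRECTIONS = ("forward", "reverse")
SERINE_POLICIES = ("C", "G")

_DIR_TAG = {"forward": "fwd", "reverse": "rev"}

_DNA_TO_RNA = str.maketrans("Tt", "Uu")


@dataclass(frozen=True)
class TranscriptVariant:
    """One of the four candidate nucleotide sequences for a peptide."""

    peptide_id: str
    direction: str  # "forward" (N→C) | "reverse" (C→N)
    serine_policy: str  # "C" | "G"
    sequence: str  # DNA alphabet {A,C,G,T,N}

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")
        if self.serine_policy not in SERINE_POLICIES:
            raise ValueError(f"serine_policy must be one of {SERINE_POLICIES}")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"variant sequence contains non-DNA letters: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def variant_id(self) -> str:
        """Deterministic ID: ``<peptide_id>|fwd|S-C`` etc."""
        return f"{self.peptide_id}|{_DIR_TAG[self.direction]}|S-{self.serine_policy}"

    def rna(self) -> str:
        """RNA rendering (T→U) of the sequence, for display."""
        return self.sequence.translate(_DNA_TO_RNA)


def transcribe(
    peptide: str,
    code: Optional[OneLCode] = None,
    direction: str = "forward",
    serine_policy: str = "C",
    peptide_id: str = "peptide",
    strict: bool = False,
) -> TranscriptVariant:
    """Map each residue to its second-codon-position nucleotide.

    The i-th output letter is the code lookup of the i-th residue of the
    peptide read in the stated direction.  Whitespace is stripped; an empty
    peptide yields an empty variant.  Unknown residues follow the code
    module's policy (placeholder N, or an error when ``strict``).
    """
    if code is None:
        code = builtin_code()
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}, got {direction!r}")
    residues = "".join(peptide.split())
    forward = "".join(
        code.lookup(aa, serine_policy=serine_policy, strict=strict) for aa in residues
    )
    seq = forward if direction == "forward" else forward[::-1]
    return TranscriptVariant(
        peptide_id=peptide_id,
        direction=direction,
        serine_policy=serine_policy,
        sequence=seq,
    )


def enumerate_variants(
    peptide: str,
    code: Optional[OneLCode] = None,
    peptide_id: str = "peptide",
    strict: bool = False,
    dedupe: bool = False,
) -> List[TranscriptVariant]:
    """Return the four labeled variants in deterministic order.

    Order: (forward, S-C), (forward, S-G), (reverse, S-C), (reverse, S-G).
    With ``dedupe`` variants with identical sequences are collapsed (always
    possible when the peptide contains no serine), keeping the first label.
    """
    variants = [
        transcribe(peptide, code, direction=d, serine_policy=sp,
                   peptide_id=peptide_id, strict=strict)
        for d in DIRECTIONS
        for sp in SERINE_POLICIES
    ]
    if dedupe:
        seen: dict[str, TranscriptVariant] = {}
        for v in variants:
            seen.setdefault(v.sequence, v)
        variants = list(seen.values())
    return variants
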