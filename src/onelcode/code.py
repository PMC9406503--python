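"""The 1-L protein→nucleotide recognition code.

Each of the 20 standard amino acids is mapped to the nucleotide found at
the second position of its codons in the standard genetic code.  For 19
amino acids this letter is unique; serine (S) is the single ambiguous
residue, because its six codons (TCN, AGC, AGT) place either C or G at
position two.  The mapping is therefore a function residue → {A,C,G,T}
with ``|mapping['S']| == 2`` and singletons everywhere else.

The internal alphabet is DNA (T, not U); RNA is a display rendering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Mapping

from Bio.Data import CodonTable

logger = logging.getLogger(__name__)

STANDARD_AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
DNA_LETTERS = frozenset("ACGT")

#: Unknown/ambiguous residue placeholder emitted under the lenient policy.
#: N never seeds a word and scores as a mismatch in alignment.
UNKNOWN_NUCLEOTIDE = "N"

# Second-codon-position table for the standard genetic code.  S is the only
# residue with two admissible letters (TCN → C, AGC/AGT → G).
_BUILTIN: Dict[str, FrozenSet[str]] = {
    "F": frozenset("T"), "L": frozenset("T"), "I": frozenset("T"),
    "M": frozenset("T"), "V": frozenset("T"),
    "P": frozenset("C"), "T": frozenset("C"), "A": frozenset("C"),
    "S": frozenset("CG"),
    "Y": frozenset("A"), "H": frozenset("A"), "Q": frozenset("A"),
    "N": frozenset("A"), "K": frozenset("A"), "D": frozenset("A"),
    "E": frozenset("A"),
    "C": frozenset("G"), "W": frozenset("G"), "R": frozenset("G"),
    "G": frozenset("G"),
}


class UnknownResidueError(ValueError):
    """Raised for a non-standard residue under the strict policy."""


@dataclass(frozen=True)
class OneLCode:
    """Amino-acid → nucleotide-set mapping.

    Parameters
    ----------
    mapping
        Residue letter (uppercase, 20 standard amino acids) to the set of
        DNA letters occurring at codon position 2.
    source
        Provenance tag: ``"builtin"`` or ``"derived-from-codon-table"``.
    """

    mapping: Mapping[str, FrozenSet[str]]
    source: str = "builtin"

    def __post_init__(self) -> None:
        keys = set(self.mapping)
        if keys != set(STANDARD_AMINO_ACIDS):
            missing = sorted(STANDARD_AMINO_ACIDS - keys)
            extra = sorted(keys - STANDARD_AMINO_ACIDS)
            raise ValueError(
                f"code table must cover exactly the 20 standard amino acids; "
                f"missing={missing} extra={extra}"
            )
        for aa, letters in self.mapping.items():
            if not letters or not set(letters) <= DNA_LETTERS:
                raise ValueError(f"invalid nucleotide set for {aa}: {set(letters)}")
            want = 2 if aa == "S" else 1
            if len(letters) != want:
                raise ValueError(
                    f"{aa} must map to exactly {want} nucleotide(s), got {sorted(letters)}"
                )

    def lookup(self, residue: str, serine_policy: str = "C", strict: bool = False) -> str:
        """Return the single mapped DNA letter for one residue.

        Serine is disambiguated by ``serine_policy`` ("C" or "G").  A
        non-standard residue (B, J, O, U, X, Z, ``*`` …) raises
        :class:`UnknownResidueError` when ``strict`` is true, otherwise it
        maps to ``N`` with a logged warning.  Input case is ignored.
        """
        if serine_policy not in ("C", "G"):
            raise ValueError(f"serine_policy must be 'C' or 'G', got {serine_policy!r}")
        aa = residue.upper()
        if aa not in self.mapping:
            if strict:
                raise UnknownResidueError(f"non-standard residue {residue!r}")
            logger.warning("non-standard residue %r mapped to placeholder N", residue)
            return UNKNOWN_NUCLEOTIDE
        letters = self.mapping[aa]
        if len(letters) == 1:
            return next(iter(letters))
        return serine_policy

    def to_tsv(self) -> str:
        """Render the table as two-column TSV (residue, comma-joined set)."""
        lines = ["residue\tnucleotides"]
        for aa in sorted(self.mapping):
            lines.append(f"{aa}\t{','.join(sorted(self.mapping[aa]))}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str, source: str = "builtin") -> "OneLCode":
        """Parse the TSV produced by :meth:`to_tsv` (round-trip safe)."""
        mapping: Dict[str, FrozenSet[str]] = {}
        lines = [ln for ln in text.splitlines() if ln.strip()]
        for ln in lines[1:]:  # skip header
            try:
                aa, nts = ln.split("\t")
            except ValueError as exc:
                raise ValueError(f"malformed code-table line: {ln!r}") from exc
            mapping[aa.strip().upper()] = frozenset(nts.strip().upper().split(","))
        return cls(mapping=mapping, source=source)


def builtin_code() -> OneLCode:
    """The shipped 1-L code table."""
    return OneLCode(mapping=dict(_BUILTIN), source="builtin")


def derive_code(codon_table: Mapping[str, str] | None = None) -> OneLCode:
    """Derive the 1-L code from a codon table.

    Parameters
    ----------
    codon_table
        Map from DNA codon (e.g. ``"CAA"``) to one-letter amino acid.
        Defaults to the standard genetic code (NCBI table 1, 61 sense
        codons; stop codons are not part of the map).

    Returns
    -------
    OneLCode
        For every amino acid, the set of distinct letters at codon
        position 2 (1-based) over all its codons.

    Raises
    ------
    ValueError
        If the table does not cover all 20 standard amino acids.
    """
    if codon_table is None:
        codon_table = CodonTable.unambiguous_dna_by_id[1].forward_table
    mapping: Dict[str, set] = {}
    for codon, aa in codon_table.items():
        aa = aa.upper()
        if aa not in STANDARD_AMINO_ACIDS:
            continue
        mapping.setdefault(aa, set()).add(codon[1].upper())
    missing = sorted(STANDARD_AMINO_ACIDS - set(mapping))
    if missing:
        raise ValueError(f"codon table is missing amino acids: {missing}")
    return OneLCode(
        mapping={aa: frozenset(v) for aa, v in mapping.items()},
        source="derived-from-codon-table",
    )


def lookup(code: OneLCode, residue: str, serine_policy: str = "C", strict: bool = False) -> str:
    """Module-level convenience wrapper around :meth:`OneLCode.lookup`."""
    return code.lookup(residue, serine_policy=serine_policy, strict=strict)
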