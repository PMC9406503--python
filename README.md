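# onelcode

Sequence-space tools for the **1-L protein–RNA recognition code**: the
hypothesis that an RNA-binding protein (RBP) can carry an amino-acid
sequence directly compatible with the RNA it recognizes, one residue per
nucleotide, where each amino acid stands for the nucleotide found at the
**second position of its codons**. Under the standard genetic code this
mapping is unambiguous for 19 amino acids and two-valued only for serine
(TCN → C, AGC/AGT → G):

| second-position letter | amino acids |
|---|---|
| U (T) | F L I M V |
| C | P T A (+S) |
| A | Y H Q N K D E |
| G | C W R G (+S) |

Reading a peptide N→C or C→N, with serine rendered globally as C or as G,
gives **four candidate nucleotide sequences** per peptide. The package

1. **transcribes** peptides into these four variants (`onelcode.transcribe`),
2. **scans** them for regulatory motifs — the poly(A) signal AAUAAA and
   AU-rich elements of classes I (scattered AUUUA), II (overlapping AUUUA
   runs) and III (U-rich, including the literal UUUC) (`onelcode.motifs`),
3. **searches** them against a transcriptome on both strands with a
   word-seeded local aligner (word size 7, match +2 / mismatch −3, gaps
   5/2, Karlin–Altschul E-values, E ≤ 100, ≤ 500 targets — the settings of
   a short-query BLASTn run) and imports/exports NCBI BLAST `-outfmt 6`
   tables for interop with real BLAST runs (`onelcode.search`),
4. **classifies** hit transcripts by strand: a sense (plus-strand) hit is
   called *repressive* (green), an antisense (minus-strand) hit
   *promotive* (yellow) (`onelcode.classify`), and
5. **simulates** transcriptomes with planted, manifest-verified ground
   truth so the whole chain is testable without downloads
   (`onelcode.simdata`).

It is aimed at people exploring peptide–RNA recognition hypotheses (for
instance treating the amyloid-β peptide as a candidate small RBP) who
want the mechanics — transcription, motif content, strand-aware search,
classification — reproducible on the desk, with real transcriptome-scale
screening delegated to NCBI BLASTn via the tabular bridge.

## Worked example

```python
from onelcode import builtin_code, transcribe, scan_pas, scan_are, ABETA42

code = builtin_code()

# A WDR33 N-terminal fragment read C->N spells the poly(A) signal:
v = transcribe("QNQIQQ", code, direction="reverse")
print(v.sequence, v.rna())          # AATAAA AAUAAA

# The HUR RRM1 fragment read N->C spells an ARE pentamer + spaced PAS:
w = transcribe("NLIVNYLPQNMTQDE", code, direction="forward")
print(w.sequence)                   # ATTTAATCAATCAAA
print(scan_are(w, "ARE_I")[0].start)   # 0   (ATTTA at the start)
print(len(scan_pas(w)))                # 0   (AATcAAA is not an exact PAS)

# Amyloid-beta 42 carries both a PAS and a class-III ARE word:
ab = transcribe(ABETA42, code)
print(ab.sequence)
# ACATGAACGAATAAAATTTTCAATGCAAGCTTGTTTGGTTTC
print([(h.start, h.matched) for h in scan_pas(ab)])
# [(9, 'AATAAA')]
print([(h.start, h.matched) for h in scan_are(ab, "ARE_III") if h.matched == "TTTC"])
# [(17, 'TTTC'), (38, 'TTTC')]
```

The full pipeline (transcribe → scan → search → classify) runs from the
shell; here against a synthetic transcriptome with four planted copies:

```bash
onelcode simdata -o tx.fasta -n 20 --seed 4
onelcode run --peptides peptides.fasta --transcriptome tx.fasta --out-dir out/
cat out/calls.tsv
```

`calls.tsv` lists one row per (transcript, mode): subject id, mode
(`repressive`/`promotive`), color (`green`/`yellow`), best E-value, best
raw score, hit count and the supporting variant ids. The mode is the
strand rule above; the header notes that the direction of the biological
effect is a modelling hypothesis, not a computed fact.

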