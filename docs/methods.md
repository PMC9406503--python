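# Methods

## The recognition code and its transcription

The 1-L code maps each standard amino acid to the nucleotide at the
second position of its codons in the standard genetic code. The shipped
table is validated on construction (20 keys; serine and only serine maps
to two letters, {C, G}) and is reproduced exactly by `derive_code`, which
re-derives it from any codon→amino-acid map covering the 20 amino acids.
The internal alphabet is DNA; `TranscriptVariant.rna()` renders U for
display. This matches FASTA/BLASTn conventions and avoids carrying two
alphabets through the pipeline.

A peptide of length n yields four variants of length n: the reading
direction (N→C "forward", C→N "reverse") times the global serine
rendering (all S→C or all S→G). Serine policy is global, not
per-residue — per-residue mixing would produce 2^k candidates instead of
four and would no longer describe a single consistent recognition string.
The reverse variant is computed as the character reversal of the forward
transcript; a property test confirms this equals transcribing the
reversed peptide. Variant ids are deterministic
(`<peptide_id>|fwd|S-C` …) so every downstream table joins on them.

Non-standard residues (B, J, O, U, X, Z, `*`) map to the placeholder N
with a logged warning; a `strict` flag turns this into an error. N never
enters a seed word and scores as a mismatch in alignment, so placeholder
positions cannot create hits. Input case is ignored (protein FASTA is
frequently mixed-case; case carries no meaning here).

## Motif scanning

Scanning operates on the transcribed variant, literally and without
complementing — the variant is the hypothesized recognition string, not a
genomic strand. All overlapping occurrences are reported.

* **PAS**: every exact AATAAA.
* **ARE I**: every exact ATTTA.
* **ARE II**: maximal chains of ATTTA copies offset exactly 4 apart
  (ATTTATTTA…), at least two copies, one hit per chain spanning it.
* **ARE III**: every literal TTTC, always reported; plus every maximal
  window of length ≥ w with T fraction ≥ f. "U-rich" has no canonical
  quantitative definition, so the window parameters are explicit and
  conservative: **w = 8, f = 0.75** by default, both configurable. A
  window hit is maximal by containment — it is the longest qualifying
  window at its start and is not contained in any other qualifying
  window. Only the literal motifs (AATAAA, ATTTA, TTTC) are relied on by
  the package's own validation; the windowed scanner is a convenience
  whose thresholds callers should set for their application.

## Search

The search engine mirrors short-query BLASTn mechanics at desk scale.

* **Seeding.** All plus-strand words of length `word_size` (default 7) of
  every transcript are indexed exactly; words containing N are skipped.
  The minus strand is covered by reverse-complementing the query, never
  by indexing the complement.
* **Extension.** Every (subject, strand) pair sharing at least one exact
  word with the query is scored by a full affine-gap Smith–Waterman
  alignment with traceback (match +2, mismatch −3, gap cost
  open 5 + 2 per column). Queries here are tens of nucleotides, so the
  full O(mn) dynamic program per seeded candidate is cheap; in exchange
  the reported best hit per (subject, strand) is the exact local-alignment
  optimum, not an X-drop approximation — the test suite asserts equality
  with an independent brute-force aligner over hundreds of random seeded
  instances. Seeding therefore acts purely as a candidate filter, as in
  BLAST, and alignments on a (subject, strand) with no shared word are by
  design invisible.
* **Statistics.** E = K·m·n·exp(−λS) with m the query length and n the
  total database length. (λ, K) pairs ship precomputed for the default
  schemes (+2/−3 ungapped: 0.634/0.408; +2/−3 with gaps 5/2: 0.625/0.410;
  +1/−2 ungapped: 1.33/0.621); any other scheme requires the caller to
  supply (λ, K) explicitly rather than silently reusing wrong constants.
  NCBI BLAST additionally length-adjusts m and n, so NCBI E-values for the
  same alignment are smaller by a modest constant factor; scores, bit
  scores, coordinates and strand conventions agree.
* **Reporting.** Hits with E > `evalue_max` (default 100) are dropped;
  hits are sorted by ascending E, ties broken by subject id then subject
  start, and at most `max_targets` (default 500) distinct subjects are
  kept. Coordinates are 1-based inclusive; a minus-strand hit has
  s_start > s_end (the BLAST tabular convention). Low-complexity
  filtering is deliberately off: the queries are short and A/T-rich, and
  DUST-style masking would erase exactly the signal under study.
* **Interop.** Hit tables serialize to 12-column `-outfmt 6` TSV and
  external BLASTn tables parse back into the same hit type, with strand
  inferred from the subject coordinates. Raw score is not an outfmt-6
  column, so on import it is reconstructed from the bit score under the
  active (λ, K).

## Classification

Hits are grouped by (subject, strand): plus → *repressive* (green),
minus → *promotive* (yellow). A subject hit on both strands yields two
calls — no figure-style resolution of dual-strand genes is attempted, the
caller decides. Per group the call carries the minimum E-value, maximum
raw score, hit count and the sorted supporting variant ids; hit counts
are conserved (every input hit supports exactly one call). An optional
transcript→gene TSV collapses isoforms before grouping (best E-value wins
per gene per mode). Report headers carry the interpretive caveat that
repression/promotion is a hypothesis about RBP–RNA interference whose
direction may be reversed for individual RNAs; the package computes the
strand assignment only.

## Synthetic data

`random_transcriptome` draws i.i.d. sequences with a configurable GC
fraction (A and T equiprobable at (1−gc)/2, G and C at gc/2) and lengths
uniform in a range; defaults used throughout the tests are 20 planted +
20 background transcripts of 200–400 nt at GC 0.5 — comfortably larger
than the 42-nt queries and dense enough that chance 7-mer seeds occur,
exercising the E-value filter. Planting substitutes the query (plus) or
its reverse complement (minus) at a recorded offset, keeping lengths
fixed so manifest coordinates stay exact; `PlantManifest.verify`
re-checks every record against the emitted FASTA. All randomness flows
through integer seeds and regeneration is byte-identical.

What the generator does **not** emulate: real transcript structure (UTRs,
splicing, isoforms), compositional heterogeneity, repeats, or any
higher-order sequence model. Passing the planted-recovery tests shows the
mechanics (seeding, strand handling, classification) are correct; it says
nothing about the biological prevalence or meaning of such matches in a
real transcriptome.

## Numerical and design choices

* Alignment tie-breaks: the optimum cell with the smallest (query end,
  subject end) wins traceback; equal-E hits order by subject id then
  subject start. Output is byte-deterministic for fixed inputs.
* The gap model is open + extend·length (the first gapped column pays
  both), matching the +2/−3/5/2 scheme the (λ, K) table is keyed on.
* `evalue` refuses non-positive scores and lengths rather than returning
  degenerate values.
* Empty peptides transcribe to empty variants; empty hit lists classify
  to empty (but well-formed) reports; an empty transcriptome is an error
  at indexing time, surfaced by the pipeline with the failing stage name.
* Problem sizes in the tests and the acceptance script (200 oracle pairs
  of 20–60 nt queries vs 100–500 nt subjects; 40-transcript synthetic
  transcriptomes) were chosen as the smallest sizes that exercise both
  strands, gapped alignments and the E-value filter with comfortable
  margins.

## Limitations

* The aligner is desk-scale: a Python dynamic program over seeded
  candidates. Transcriptome- or genome-scale screening should run in NCBI
  BLASTn and come back through the outfmt-6 importer.
* E-values use the raw m·n search space, not NCBI's length-adjusted
  effective space; with the default E ≤ 100 threshold this is
  inconsequential for filtering but the absolute E-values are mildly
  conservative.
* Which genes a full-transcriptome screen would report, and with what
  final selection thresholds, is out of scope; only the mechanics are
  reproduced and property-tested here.
* The repressive/promotive call is a strand label with a hypothesis
  attached, not a prediction of in-vivo regulation.
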