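# Methods

## The assay, as modeled

A genetically encoded peptide library is displayed on the *E. coli*
surface (eCPX scaffold), phosphorylated by a purified tyrosine kinase
domain, labeled with a biotinylated pan-phosphotyrosine antibody, and
the phosphorylated cells are pulled down on avidin beads. Deep
sequencing of the peptide-coding amplicons from the bead-enriched
(sorted) and input (unsorted) populations yields per-peptide read
counts; enrichment of a peptide in the sorted sample relative to the
unsorted sample is a proxy for its relative phosphorylation
efficiency.

Every amplicon shares one layout:

```
NNNNNN ACCGCAGGTACTTCCGTA GCTGGCCAGTCTGGCCAG [coding, 3L nt]
       GGAGGGCAGTCTGGGCAGTCTG GTGACTACAACAAAA NNNNNN
```

The two randomized 6-mers come from the sequencing primers; the inner
18/22-nt constants are the library-oligo flanks. Insert extraction
anchors on the full constant regions (36 nt upstream, 37 nt
downstream). For an 11-residue peptide the amplicon is 118 nt, so
75+75-nt paired reads overlap by 32 nt across the insert.

## Library architectures

- **Defined pools**: explicit peptide lists, reverse-translated with a
  fixed per-amino-acid codon table. The default table uses, for each
  amino acid, the most common *E. coli* codon whose third base is G or
  C (NNS-compatible), because no reverse-translation rule is intrinsic
  to the assay; explicit codons can be supplied per member.
- **Degenerate X₅-Y-X₅**: NNS codons (N = any base, S = G/C) at ten
  positions around a fixed central `tat` tyrosine. NNS encodes all 20
  amino acids plus the amber stop codon TAG and cannot produce
  TAA/TGA; canonical diversity is 20¹⁰, and 21¹⁰ with amber
  suppression.
- **Scanning mutagenesis**: one oligo per position of a reference
  peptide, NNS at that position and the reference codons elsewhere;
  the peptide-level support is the reference, 19 substitutions per
  position, and one amber variant per position (210 canonical peptides
  for an 11-mer).

Emitted oligos follow the uppercase-flank / lowercase-coding
convention; all sequence comparisons are case-insensitive.

## Read processing

**Merging.** The reverse read is reverse-complemented and the best
suffix–prefix overlap with the forward read is chosen by score
(matches − mismatches), requiring overlap ≥ `min_overlap` (default 10)
and mismatch fraction ≤ `max_mismatch_fraction` (default 0.25); ties
go to the longer overlap. At mismatched overlap positions the
higher-quality base wins (forward wins ties). This replaces an
external merger so the pipeline has no binary dependencies; it is
validated against a brute-force best-overlap search.

**Extraction.** The leftmost 5′-anchor match and the nearest
subsequent 3′-anchor match bound the insert. Each anchor tolerates
`max_flank_mismatches` substitutions (default 1 — at 36/37-nt anchor
lengths one mismatch absorbs typical sequencing error with negligible
off-target risk; indels are not tolerated). If both anchors fail, the
reverse-complement orientation is tried and recorded in QC.

**Translation.** Frame 0, standard genetic code. TAG → `*` (candidate
non-canonical site under amber suppression). TAA/TGA cannot encode a
displayed peptide (the cell would truncate the scaffold), so such
reads are rejected as `terminator_fail` by default; a `mask` policy
maps them to `X` for diagnostics. Length mismatches against the design
are `length_fail`; non-multiple-of-3 inserts are `frame_fail`. Status
counts always sum to the number of input pairs.

## Counting and filter modes

Counting is at the peptide level after translation, so synonymous
codons collapse (the assay reads out displayed peptides, not codons).
Residue×position matrices use a fixed row order (20 canonical residues
alphabetically, `*` last) so serialized outputs are byte-stable.
Filter modes for amber analysis: `full` (all reads), `nostop` (no
amber), `onestop` (exactly one amber; multi-amber reads are excluded,
not truncated). Under `full`, every column of the matrix sums to the
number of retained reads.

The scanning counts matrix writes the exact-reference count into the
reference-residue cell of every column, mirroring how such matrices
are tabulated; the matrix sum therefore over-counts the wild type
(L−1) times, and all totals downstream subtract `wt_count × (L−1)`
(multiplier 10 for an 11-mer). Peptides differing from the reference
at ≥2 positions are excluded and reported.

## Scoring

All three schemes compute frequency ratios sorted/unsorted:

- **Discrete**: per-peptide counts → frequencies → ratio, with log₂
  and log₁₀ transforms. Logo input selection takes single-tyrosine
  peptides above an enrichment cutoff (default 3) as foreground
  against all single-tyrosine peptides as background, emitting
  position-frequency tables for external logo tools.
- **Positional** (degenerate): per-position column totals →
  frequencies → ratio. The fixed central column is masked: the design
  encodes essentially nothing but Tyr there, so ratios in that column
  are meaningless. Default display transform is log₂.
- **Scanning**: repeat-corrected totals → frequencies → ratio → log →
  subtract the reference's log score, so reference cells are exactly 0
  in every column; central-Tyr stop mutants act as the internal
  negative control. Default display transform is log₁₀.

**Zeros.** The assay gives no information about peptides absent from
the unsorted sample, so their scores default to NaN (flagged, never
infinite). An optional additive pseudocount (0.5 when enabled) applied
to both samples makes all scores finite; it is off by default because
the frequency-ratio definition has no pseudocount.

**Replicates.** Each sorted sample is compared only to its matched
unsorted sample; cross-replicate averaging is an explicit post-step
(element-wise mean of log scores), never implicit pooling.

## The screen simulator

The simulator exists so that every downstream stage can be tested with
known ground truth; its defaults define the study conditions for those
tests.

- **Specificity model**: log position weights $w(j, a)$ over the 21
  residue symbols (incl. `*`), acting multiplicatively on a
  first-order rate. The phosphorylation extent of peptide $p$ after
  exposure $t$ is
  $1 - \exp\!\big(-k_0\, t\, e^{\sum_j w(j, p_j)}\big)$.
  `calibrate_exposure` root-finds the exposure at which the
  population-mean extent hits a target (the protocol aims for 25–50%
  before selection), to ±0.5% absolute.
- **Library sampling**: defined pools enumerate their members;
  scanning pools cover reference + single mutants weighted by NNS
  codon multiplicity; degenerate pools draw iid NNS codons per
  randomized position (so residue abundances follow NNS codon usage,
  including amber at 1/32). Optional log-normal abundance skew models
  cloning bottlenecks; it defaults to 0 in tests.
- **Selection**: per cell, Bernoulli phosphorylation at the peptide's
  extent, then Bernoulli capture at `capture_efficiency` (0.9) if
  phosphorylated, else `background_capture` (0.01). These two rates
  are simulation parameters with no claimed biological value. The
  sorted population is the captured cells; the unsorted population is
  the input.
- **Read emission**: reads are drawn multinomially from the
  population; each read's amplicon gets fresh random 6-mers and a
  fresh design-consistent codon assignment (random NNS codon per
  randomized residue), and R1/R2 are the two 75-nt ends with
  independent substitution errors at the configured rate (indels are
  not modeled, matching the substitution-only anchor tolerance). A
  truth table of sampled read counts per peptide accompanies every
  sample. All randomness flows from one seed through spawned generator
  streams, so identical configs yield byte-identical FASTQ.

**What the simulator does not capture**: PCR amplification bias
(exposed only as an optional per-peptide weight, not defaulted),
antibody/bead binding kinetics and saturation, display-level variation
between cells, cluster-density artifacts, and quality-score structure
(simulated qualities are uniform). Passing the recovery tests
therefore shows the *analysis* is correct and unbiased under the
generative model, not that real screens are free of these effects.

## Problem sizes and numerical choices

The test suite and acceptance script run simulated screens at
4,000–200,000 reads per sample; the position-weight recovery study
uses 200,000 reads per sample and 300,000 cells, a scale at which
per-cell Poisson noise leaves Pearson r ≈ 0.95–0.96 between planted
weights and recovered log₂ enrichments (the check requires ≥ 0.9).
Log₂ enrichment is only approximately linear in the planted log rate
weights — the kinetics saturate and capture adds a background floor —
which bounds the attainable correlation slightly below 1 even at
infinite depth.

Root finding uses Brent's method on the monotone mean-extent function
with a doubling bracket. Frequency tables are validated to sum to 1
within 1e−9. Reference cells in scanning output are pinned to exactly
0.0 after normalization to avoid ±1-ulp noise in downstream
comparisons.

## Known limitations

- Flank matching tolerates substitutions only; an indel inside an
  anchor loses the read.
- Counting is exact-match; no fuzzy whitelist matching for defined
  pools.
- The mapping from enrichment to kinetic constants is intentionally
  out of scope; both log transforms are exposed because either may be
  preferred for visualization.
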