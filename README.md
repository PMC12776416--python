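# pepdisplay

Analysis toolkit for profiling tyrosine kinase substrate specificity by
**bacterial peptide display and deep sequencing**. Peptide libraries are
displayed on the *E. coli* surface via the eCPX scaffold, phosphorylated
by a purified kinase domain, and the phosphorylated cells are enriched
with a biotinylated pan-phosphotyrosine antibody and avidin beads.
Paired-end sequencing of the sorted and unsorted populations then
quantifies, for every peptide, how efficiently the kinase phosphorylated
it.

`pepdisplay` implements the complete computational side of that assay:

- **Library design** — oligo pools for the three architectures: defined
  phosphosite pools, the degenerate X₅-Y-X₅ library (NNS codons around a
  fixed central Tyr), and scanning-mutagenesis pools of a reference
  peptide, all with the display vector's constant flanks.
- **Read processing** — paired-end merge (quality-weighted overlap
  consensus), flank-anchored insert extraction, and translation with
  amber (`TAG → *`) handling and full QC accounting.
- **Counting & scoring** — per-peptide counts, residue×position
  matrices with `full`/`nostop`/`onestop` stop-codon filtering, and the
  three enrichment schemes (see below).
- **Screen simulator** — a generative model of the whole experiment
  (finite library sampling, first-order phosphorylation kinetics under a
  position-weight specificity model, Bernoulli capture, amplicon read
  emission) so every stage is testable against known ground truth.
- **Planning arithmetic** — DNA molarity conversion, serial dilutions,
  sequencing depth/multiplexing, and loading-mix composition.

## The enrichment statistic

For peptide *i* with read counts $c_i^{s}$ (sorted) and $c_i^{u}$
(matched unsorted sample),

$$E_i = \frac{c_i^{s} / \sum_j c_j^{s}}{c_i^{u} / \sum_j c_j^{u}}$$

the ratio of relative frequencies, reported alongside its log₂/log₁₀
transforms. Degenerate libraries are scored per (residue, position)
using per-position column totals, with the fixed central-Tyr column
masked. Scanning libraries correct the totals for the wild type
repeating in every matrix column (subtract $c_{wt}\,(n-1)$ for an
*n*-mer), then normalize log scores so the reference peptide scores
exactly 0. Amber-suppression screens are scored on the subset of reads
with exactly one amber codon, so the non-canonical residue (the `*`
row) is compared on a fair display-efficiency baseline.

## Worked example

`examples/02_simulate_and_score_degenerate.py` simulates a degenerate
screen with a kinase that prefers Ile at −2 and Glu at +1 (and dislikes
Pro at +2), processes the simulated FASTQ pair end to end, and recovers
the profile:

```
sorted sample:   50000/50000 reads ok
unsorted sample: 50000/50000 reads ok

recovered log2 enrichment at the planted preferences
(positive = favored by the simulated kinase, negative = disfavored):
  I at -2: log2 = +1.33  (ground-truth weight +1.2)
  E at +1: log2 = +0.96  (ground-truth weight +0.9)
  P at +2: log2 = -0.88  (ground-truth weight -0.8)

column at -2, top three residues by enrichment:
I    2.52
Y    1.05
D    1.04
```

The recovered log₂ scores track the planted position weights: favored
residues come out positive and top their column, disfavored ones come
out negative. The other examples cover oligo-pool design
(`01_design_oligo_pools.py`), scanning mutagenesis with the wild-type
repeat correction (`03_scanning_mutagenesis.py`), amber-suppression
profiling of a non-canonical residue (`04_amber_suppression.py`), and
the sequencing-prep planning numbers
(`05_sequencing_prep_planning.py`).

A thin CLI wraps the same functions:

```bash
pepdisplay design --design design.yaml --out-prefix pool
pepdisplay process --r1 R1.fastq.gz --r2 R2.fastq.gz --design design.yaml --out peptides.tsv
pepdisplay simulate --design design.yaml --model model.json --out-dir sim/
pepdisplay run --config run.yaml --out-dir results/
pepdisplay plan depth --library-size 10000 --kit-yield 30000000
```

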