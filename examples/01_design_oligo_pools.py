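"""Build the three library oligo-pool architectures.

Constructs the degenerate X5-Y-X5 oligo, the 11 scanning-mutagenesis
oligos for the Src consensus peptide, and a small defined pool, and
prints the templates with their theoretical diversities.
"""

from pepdisplay import (
    LibraryDesign,
    build_defined_oligos,
    build_degenerate_oligo,
    build_scanning_oligos,
    theoretical_diversity,
    validate_oligo,
)

# Degenerate library: five random residues (NNS codons) on each side of
# a fixed central phospho-acceptor tyrosine.
x5 = LibraryDesign.x5_y_x5()
oligo = build_degenerate_oligo(x5)
print("X5-Y-X5 oligo:")
print(" ", oligo.sequence)
print("  canonical diversity:", f"{theoretical_diversity(x5):,}")          # 20^10
print("  with amber suppression:", f"{theoretical_diversity(x5, True):,}")  # 21^10
print("  validation:", validate_oligo(oligo, x5)["passed"])

# Scanning mutagenesis: one oligo per position, NNS at that position and
# the reference codons elsewhere.
scan = LibraryDesign.src_consensus_scanning()
print(f"\nScanning pool for {scan.reference_peptide} "
      f"({theoretical_diversity(scan)} distinct peptides):")
for o in build_scanning_oligos(scan):
    print(f"  position {o.varied_position:2d}: {o.sequence}")

# Defined pool: explicit members reverse-translated with the default
# NNS-compatible codon table.
defined = LibraryDesign(kind="defined", peptide_length=11,
                        members=("PDECIYDMFPF", "EDAIYAAPFAK"))
print("\nDefined pool:")
for o in build_defined_oligos(defined):
    print(f"  {o.design_id}: {o.sequence}")
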