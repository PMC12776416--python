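"""Peptide-library oligo design for eCPX bacterial display.

Three library architectures share a single amplicon layout: a constant
5' flank, a peptide-coding cassette, and a constant 3' flank, cloned
in-frame onto the N-terminus of the eCPX display scaffold.

* **defined** — an explicit list of peptides (e.g. a phosphosite
  library) reverse-translated with a fixed codon table.
* **degenerate** — NNS codons at every randomized position, optionally
  with a fixed central residue (the X5-Y-X5 design: five random
  residues on each side of a fixed phospho-acceptor tyrosine). NNS
  encodes all 20 canonical amino acids plus the amber stop codon (TAG),
  and cannot encode ochre (TAA) or opal (TGA).
* **scanning** — single-position mutagenesis of a reference peptide:
  one oligo per position, with NNS at that position and the reference
  codons everywhere else.

Emitted oligos follow the convention of uppercase flanks and degenerate
codons with lowercase fixed coding sequence; all comparisons are
case-insensitive.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio.Data.IUPACData import ambiguous_dna_values

# Constant flanks of the library oligos (the display-vector junctions).
FIVE_FLANK = "GCTGGCCAGTCTGGCCAG"
THREE_FLANK = "GGAGGGCAGTCTGGGCAGTCTG"

# Constant amplicon sequence outside the oligo flanks, up to the
# randomized 6-N stretches introduced by the sequencing primers.
UPSTREAM_CONST = "ACCGCAGGTACTTCCGTA"
DOWNSTREAM_CONST = "GTGACTACAACAAAA"

# Anchors used for insert extraction: the full non-N constant regions
# flanking the peptide-coding cassette in a merged read (36 and 37 nt).
FIVE_ANCHOR = UPSTREAM_CONST + FIVE_FLANK
THREE_ANCHOR = THREE_FLANK + DOWNSTREAM_CONST

# Canonical residue ordering used for all matrices; amber (`*`) last.
CANONICAL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
AMBER = "*"
ROW_ORDER = tuple(CANONICAL_RESIDUES) + (AMBER,)

CENTRAL_TYR_CODON = "tat"

#: Default reverse-translation codon per amino acid: the most common
#: E. coli codon among those with G or C in the third position, so that
#: defined-library members remain NNS-compatible.
DEFAULT_CODON_TABLE = {
    "A": "gcg", "C": "tgc", "D": "gac", "E": "gag", "F": "ttc",
    "G": "ggc", "H": "cac", "I": "atc", "K": "aag", "L": "ctg",
    "M": "atg", "N": "aac", "P": "ccg", "Q": "cag", "R": "cgc",
    "S": "agc", "T": "acc", "V": "gtg", "W": "tgg", "Y": "tac",
    AMBER: "tag",
}

_STANDARD_CODE = {}


def _build_standard_code() -> dict:
    from Bio.Data.CodonTable import unambiguous_dna_by_id

    table = unambiguous_dna_by_id[1]
    code = {c.upper(): aa for c, aa in table.forward_table.items()}
    for stop in table.stop_codons:
        code[stop.upper()] = "*" if stop.upper() == "TAG" else "#"
    return code


def translate_codon(codon: str) -> str:
    """Translate one codon. TAG -> ``*`` (amber), TAA/TGA -> ``#``
    (terminator sentinel), anything non-ACGT -> ``X``."""
    global _STANDARD_CODE
    if not _STANDARD_CODE:
        _STANDARD_CODE = _build_standard_code()
    return _STANDARD_CODE.get(codon.upper(), "X")


def expand_degenerate_codon(pattern: str) -> list[str]:
    """All concrete codons matched by an IUPAC degenerate codon."""
    pools = [ambiguous_dna_values[b.upper()] for b in pattern]
    out = [""]
    for pool in pools:
        out = [prefix + b for prefix in out for b in pool]
    return out


def nns_codons() -> list[str]:
    return expand_degenerate_codon("NNS")


def nns_residue_multiplicities() -> dict:
    """Residue -> number of NNS codons encoding it (amber ``*`` = 1)."""
    mult: dict = {}
    for codon in nns_codons():
        aa = translate_codon(codon)
        mult[aa] = mult.get(aa, 0) + 1
    return mult


def is_dna(seq: str) -> bool:
    return len(seq) > 0 and set(seq.upper()) <= set("ACGT")


@dataclass
class LibraryDesign:
    """Declarative description of one library architecture.

    Parameters
    ----------
    kind
        ``defined``, ``degenerate`` or ``scanning``.
    peptide_length
        Number of displayed residues (default 11, the X5-Y-X5 and
        Src-consensus layout).
    central_fixed
        Optional ``(position, residue)`` pair held constant in a
        degenerate design, e.g. ``(5, "Y")`` for a centered
        phospho-acceptor tyrosine.
    reference_peptide, reference_codons
        Scanning designs: the wild-type peptide and its exact codons.
    members
        Defined designs: the peptide list.
    """

    kind: str
    peptide_length: int = 11
    five_flank: str = FIVE_FLANK
    three_flank: str = THREE_FLANK
    degenerate_codon: str = "NNS"
    central_fixed: Optional[tuple[int, str]] = None
    central_codon: str = CENTRAL_TYR_CODON
    reference_peptide: Optional[str] = None
    reference_codons: Optional[tuple[str, ...]] = None
    members: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        if self.kind not in ("defined", "degenerate", "scanning"):
            raise ValueError(f"unknown library kind: {self.kind!r}")
        self.five_flank = self.five_flank.upper()
        self.three_flank = self.three_flank.upper()
        if not (is_dna(self.five_flank) and is_dna(self.three_flank)):
            raise ValueError("flanks must be nonempty DNA over ACGT")
        if self.peptide_length < 1:
            raise ValueError("peptide_length must be >= 1")
        for base in self.degenerate_codon:
            if base.upper() not in ambiguous_dna_values:
                raise ValueError(f"non-IUPAC symbol in codon pattern: {base!r}")
        if self.reference_codons is not None:
            self.reference_codons = tuple(c.lower() for c in self.reference_codons)
        if self.members is not None:
            self.members = tuple(m.upper() for m in self.members)
        if self.kind == "scanning":
            if self.reference_peptide is None or self.reference_codons is None:
                raise ValueError("scanning design needs reference_peptide and reference_codons")
            self.reference_peptide = self.reference_peptide.upper()
            if not (len(self.reference_peptide) == self.peptide_length == len(self.reference_codons)):
                raise ValueError("reference peptide/codons length must equal peptide_length")
        if self.central_fixed is not None:
            pos, res = self.central_fixed
            if not (0 <= pos < self.peptide_length):
                raise ValueError("central_fixed position outside the peptide")
            self.central_fixed = (pos, res.upper())

    # -- convenience -----------------------------------------------------
    @classmethod
    def x5_y_x5(cls) -> "LibraryDesign":
        """The degenerate X5-Y-X5 design: 11-mer, central Tyr fixed."""
        return cls(kind="degenerate", peptide_length=11, central_fixed=(5, "Y"))

    @classmethod
    def src_consensus_scanning(cls) -> "LibraryDesign":
        """Scanning mutagenesis of the Src consensus peptide."""
        codons = "ccg gat gaa tgc att tat gat atg ttt ccg ttt".split()
        return cls(
            kind="scanning",
            peptide_length=11,
            reference_peptide="PDECIYDMFPF",
            reference_codons=tuple(codons),
        )

    def position_labels(self) -> list[int]:
        """Column labels for matrices: centered (-k..+k) when a central
        residue is fixed, else 0-based indices."""
        if self.central_fixed is not None:
            c = self.central_fixed[0]
            return [i - c for i in range(self.peptide_length)]
        return list(range(self.peptide_length))

    def masked_positions(self) -> set:
        """Columns masked in positional enrichment output (the fixed
        central column is not informative)."""
        if self.central_fixed is not None:
            return {self.position_labels()[self.central_fixed[0]]}
        return set()

    def to_dict(self) -> dict:
        d = {"kind": self.kind, "peptide_length": self.peptide_length}
        if self.central_fixed is not None:
            d["central_fixed"] = list(self.central_fixed)
            d["central_codon"] = self.central_codon
        if self.reference_peptide is not None:
            d["reference_peptide"] = self.reference_peptide
            d["reference_codons"] = list(self.reference_codons)
        if self.members is not None:
            d["members"] = list(self.members)
        if self.degenerate_codon != "NNS":
            d["degenerate_codon"] = self.degenerate_codon
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "LibraryDesign":
        kw = dict(d)
        if "central_fixed" in kw:
            kw["central_fixed"] = tuple(kw["central_fixed"])
        if "reference_codons" in kw:
            kw["reference_codons"] = tuple(kw["reference_codons"])
        if "members" in kw:
            kw["members"] = tuple(kw["members"])
        return cls(**kw)


@dataclass
class OligoTemplate:
    """One flanked oligo, possibly containing IUPAC-degenerate codons."""

    sequence: str
    design_id: str
    varied_position: Optional[int] = None

    def coding_region(self, design: LibraryDesign) -> str:
        seq = self.sequence
        return seq[len(design.five_flank):len(seq) - len(design.three_flank)]


def build_degenerate_oligo(design: LibraryDesign) -> OligoTemplate:
    """Assemble the degenerate-library oligo (e.g. the X5-Y-X5 oligo:
    five NNS codons, ``tat``, five NNS codons, flanked)."""
    if design.kind != "degenerate":
        raise ValueError("design.kind must be 'degenerate'")
    if design.central_fixed is not None:
        pos = design.central_fixed[0]
        # a *centered* fixed residue requires an odd length
        if pos == design.peptide_length // 2 and design.peptide_length % 2 == 0:
            raise ValueError("centered fixed residue requires odd peptide_length")
    codons = []
    for i in range(design.peptide_length):
        if design.central_fixed is not None and i == design.central_fixed[0]:
            codons.append(design.central_codon.lower())
        else:
            codons.append(design.degenerate_codon.upper())
    seq = design.five_flank + "".join(codons) + design.three_flank
    return OligoTemplate(sequence=seq, design_id="degenerate")


def build_scanning_oligos(design: LibraryDesign) -> list[OligoTemplate]:
    """One oligo per position: NNS at position *i*, reference codons
    elsewhere, ordered by position."""
    if design.kind != "scanning":
        raise ValueError("design.kind must be 'scanning'")
    ref_translation = "".join(translate_codon(c) for c in design.reference_codons)
    if ref_translation != design.reference_peptide:
        raise ValueError(
            f"reference_codons translate to {ref_translation!r}, "
            f"not reference_peptide {design.reference_peptide!r}"
        )
    oligos = []
    for i in range(design.peptide_length):
        codons = list(design.reference_codons)
        codons[i] = design.degenerate_codon.upper()
        seq = design.five_flank + "".join(codons) + design.three_flank
        oligos.append(OligoTemplate(sequence=seq, design_id=f"scan_{i}", varied_position=i))
    return oligos


def build_defined_oligos(
    design: LibraryDesign,
    codon_choice: Optional[dict] = None,
    member_codons: Optional[dict] = None,
) -> list[OligoTemplate]:
    """One fully fixed oligo per member peptide.

    ``codon_choice`` overrides the per-amino-acid codon table;
    ``member_codons`` maps a peptide to an explicit codon list.
    """
    if design.kind != "defined":
        raise ValueError("design.kind must be 'defined'")
    if not design.members:
        raise ValueError("defined design has no members")
    table = dict(DEFAULT_CODON_TABLE)
    if codon_choice:
        table.update({k.upper(): v.lower() for k, v in codon_choice.items()})
    oligos = []
    for idx, member in enumerate(design.members):
        bad = set(member) - set(CANONICAL_RESIDUES)
        if bad:
            raise ValueError(f"member {member!r} contains non-canonical letters {sorted(bad)}")
        if member_codons and member in member_codons:
            codons = [c.lower() for c in member_codons[member]]
        else:
            codons = [table[aa] for aa in member]
        seq = design.five_flank + "".join(codons) + design.three_flank
        oligos.append(OligoTemplate(sequence=seq, design_id=f"defined_{idx}_{member}"))
    return oligos


def theoretical_diversity(design: LibraryDesign, include_amber: bool = False) -> int:
    """Number of distinct peptides a design can encode.

    Degenerate: ``alphabet ** n_randomized`` with alphabet 20 (canonical)
    or 21 (amber included). Scanning: reference + 19 substitutions per
    position (+1 amber variant per position when included).
    """
    if design.kind == "defined":
        raise ValueError(
            "theoretical_diversity is defined for degenerate/scanning designs; "
            "for a defined library use len(design.members)"
        )
    alphabet = 21 if include_amber else 20
    if design.kind == "degenerate":
        n_random = design.peptide_length - (1 if design.central_fixed is not None else 0)
        return alphabet ** n_random
    # scanning: reference plus (alphabet - 1) substitutions per position
    return design.peptide_length * (alphabet - 1) + 1


def validate_oligo(oligo: OligoTemplate, design: LibraryDesign) -> dict:
    """Structural checks on a template; failures are reported, not raised."""
    seq = oligo.sequence.upper()
    report: dict = {}
    report["five_flank_ok"] = seq.startswith(design.five_flank)
    report["three_flank_ok"] = seq.endswith(design.three_flank)
    coding_len = len(seq) - len(design.five_flank) - len(design.three_flank)
    report["frame_ok"] = coding_len >= 0 and coding_len % 3 == 0
    report["length_ok"] = coding_len == 3 * design.peptide_length
    pattern_ok = True
    if report["five_flank_ok"] and report["three_flank_ok"] and report["frame_ok"]:
        coding = oligo.coding_region(design)
        for base in coding:
            if base.upper() not in ambiguous_dna_values:
                pattern_ok = False
    else:
        pattern_ok = False
    report["pattern_ok"] = pattern_ok
    if design.kind == "scanning" and pattern_ok and report["length_ok"]:
        coding = oligo.coding_region(design)
        codons = [coding[i:i + 3] for i in range(0, len(coding), 3)]
        ok = True
        for i, codon in enumerate(codons):
            if oligo.varied_position is not None and i == oligo.varied_position:
                continue
            if translate_codon(codon) != design.reference_peptide[i]:
                ok = False
        report["reference_ok"] = ok
    report["passed"] = all(v for v in report.values())
    return report


def build_oligos(design: LibraryDesign) -> list[OligoTemplate]:
    """Dispatch on design kind."""
    if design.kind == "degenerate":
        return [build_degenerate_oligo(design)]
    if design.kind == "scanning":
        return build_scanning_oligos(design)
    return build_defined_oligos(design)


def write_oligos_fasta(oligos: Iterable[OligoTemplate], path) -> None:
    with open(path, "w") as fh:
        for o in oligos:
            fh.write(f">{o.design_id}\n{o.sequence}\n")


def write_oligos_csv(oligos: Iterable[OligoTemplate], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["design_id", "varied_position", "sequence"])
        for o in oligos:
            writer.writerow([o.design_id, "" if o.varied_position is None else o.varied_position, o.sequence])
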