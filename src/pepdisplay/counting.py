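"""Aggregate translated peptides into the count structures scoring uses.

Three structures:

* :class:`CountsTable` — per-peptide read counts (defined libraries).
* :class:`ResiduePositionMatrix` — residue x position counts for
  degenerate libraries, with stop-codon filter modes: ``full`` (all
  reads), ``nostop`` (no amber), ``onestop`` (exactly one amber — the
  subset carrying exactly one non-canonical residue under suppression).
* :class:`ScanningCountsMatrix` — single-mutant counts around a
  reference peptide, in which the exact reference count is repeated in
  the wild-type cell of every column; downstream totals must correct
  for this repetition (subtract wt_count x (L-1)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .design import ROW_ORDER
from .reads import PeptideRecord

FILTER_MODES = ("full", "nostop", "onestop")


def _as_peptides(records: Iterable[Union[PeptideRecord, str]]):
    for r in records:
        if isinstance(r, PeptideRecord):
            if r.status == "ok":
                yield r.peptide
        else:
            yield r


@dataclass
class CountsTable:
    entries: dict
    sample_id: str = ""
    sorted_flag: bool = False
    excluded: dict = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.entries.values())

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# sample_id={self.sample_id}\tsorted={self.sorted_flag}\n")
            fh.write("peptide\tcount\n")
            for pep in sorted(self.entries):
                fh.write(f"{pep}\t{self.entries[pep]}\n")

    @classmethod
    def from_tsv(cls, path, sample_id: str = "", sorted_flag: bool = False) -> "CountsTable":
        entries = {}
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or line.startswith("peptide\t"):
                    continue
                pep, n = line.rstrip("\n").split("\t")
                entries[pep] = int(n)
        return cls(entries, sample_id, sorted_flag)


@dataclass
class ResiduePositionMatrix:
    """21 x L matrix (rows: canonical residues then ``*``)."""

    matrix: pd.DataFrame
    mask: set = field(default_factory=set)
    filter_mode: str = "full"
    sample_id: str = ""
    excluded: int = 0

    @property
    def positions(self) -> list:
        return list(self.matrix.columns)

    def column_totals(self) -> pd.Series:
        return self.matrix.sum(axis=0)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# sample_id={self.sample_id}\tfilter_mode={self.filter_mode}\tmask={sorted(self.mask)}\n")
            self.matrix.to_csv(fh, sep="\t")


@dataclass
class ScanningCountsMatrix:
    matrix: ResiduePositionMatrix
    reference_peptide: str
    wt_count: int
    excluded_reads: int = 0

    def corrected_total(self) -> int:
        """Total contributing reads: matrix sum minus the wild-type
        repetition, wt_count x (L-1)."""
        L = len(self.reference_peptide)
        return int(self.matrix.matrix.to_numpy().sum()) - self.wt_count * (L - 1)


def count_peptides(
    records: Iterable[Union[PeptideRecord, str]],
    whitelist: Optional[set] = None,
    sample_id: str = "",
    sorted_flag: bool = False,
) -> CountsTable:
    """Exact-match tally of ok peptides; with a whitelist, non-members
    are excluded and reported in ``excluded``."""
    entries: dict = {}
    excluded: dict = {}
    for pep in _as_peptides(records):
        if whitelist is not None and pep not in whitelist:
            excluded[pep] = excluded.get(pep, 0) + 1
            continue
        entries[pep] = entries.get(pep, 0) + 1
    return CountsTable(entries, sample_id, sorted_flag, excluded)


def _passes_filter(peptide: str, mode: str) -> bool:
    n_amber = peptide.count("*")
    if mode == "full":
        return True
    if mode == "nostop":
        return n_amber == 0
    if mode == "onestop":
        return n_amber == 1
    raise ValueError(f"unknown filter_mode {mode!r}")


def position_residue_counts(
    records: Iterable[Union[PeptideRecord, str]],
    length: int,
    filter_mode: str = "full",
    positions: Optional[Sequence] = None,
    sample_id: str = "",
) -> ResiduePositionMatrix:
    """Residue-by-position count matrix over fixed-length peptides.

    Records of the wrong length are excluded and tallied in
    ``excluded``. Under ``full`` every column sums to the number of
    retained records.
    """
    if filter_mode not in FILTER_MODES:
        raise ValueError(f"unknown filter_mode {filter_mode!r}")
    cols = list(positions) if positions is not None else list(range(length))
    if len(cols) != length:
        raise ValueError("positions labels must match peptide length")
    row_index = {aa: i for i, aa in enumerate(ROW_ORDER)}
    counts = np.zeros((len(ROW_ORDER), length), dtype=np.int64)
    excluded = 0
    for pep in _as_peptides(records):
        if len(pep) != length:
            excluded += 1
            continue
        if not _passes_filter(pep, filter_mode):
            continue
        ok = True
        idx = []
        for aa in pep:
            i = row_index.get(aa)
            if i is None:  # e.g. masked terminator 'X'
                ok = False
                break
            idx.append(i)
        if not ok:
            excluded += 1
            continue
        for j, i in enumerate(idx):
            counts[i, j] += 1
    df = pd.DataFrame(counts, index=list(ROW_ORDER), columns=cols)
    return ResiduePositionMatrix(df, filter_mode=filter_mode, sample_id=sample_id, excluded=excluded)


def scanning_matrix_counts(
    table: CountsTable,
    reference: str,
    positions: Optional[Sequence] = None,
) -> ScanningCountsMatrix:
    """Fold per-peptide counts into the scanning-mutagenesis matrix.

    Single mutants land in (mutant residue, position); the exact
    reference's count is written into the reference-residue cell of
    *every* column (the wild-type repetition); multi-mutants are
    excluded and their reads reported.
    """
    reference = reference.upper()
    L = len(reference)
    cols = list(positions) if positions is not None else list(range(L))
    df = pd.DataFrame(
        np.zeros((len(ROW_ORDER), L), dtype=np.int64),
        index=list(ROW_ORDER),
        columns=cols,
    )
    wt_count = 0
    excluded_reads = 0
    for pep, n in table.entries.items():
        if len(pep) != L:
            excluded_reads += n
            continue
        diffs = [j for j in range(L) if pep[j] != reference[j]]
        if not diffs:
            wt_count = n
        elif len(diffs) == 1:
            j = diffs[0]
            if pep[j] in df.index:
                df.loc[pep[j], cols[j]] += n
            else:
                excluded_reads += n
        else:
            excluded_reads += n
    for j, ref_aa in enumerate(reference):
        df.loc[ref_aa, cols[j]] = wt_count
    matrix = ResiduePositionMatrix(df, filter_mode="full", sample_id=table.sample_id)
    return ScanningCountsMatrix(matrix, reference, wt_count, excluded_reads)
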