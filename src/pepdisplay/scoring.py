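"""Enrichment scoring for sorted vs matched unsorted display samples.

Three schemes, all built on the same frequency-ratio statistic
(frequency of a peptide/residue in the bead-selected sample divided by
its frequency in the matched unselected sample):

* **discrete** — per-peptide enrichment scores for defined libraries.
* **positional** — residue x position enrichment for degenerate
  libraries, computed from per-position column totals, with the fixed
  central column masked (it carries essentially no variation).
* **scanning** — per-mutant enrichment with the wild-type-repetition
  correction applied to totals, log-transformed and normalized so the
  reference peptide scores exactly zero.

Zeros policy: by default cells/peptides with zero unsorted counts get
NaN scores (flagged, not infinite); an optional additive pseudocount
applied to both samples makes every score finite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd

from .counting import (
    CountsTable,
    ResiduePositionMatrix,
    ScanningCountsMatrix,
    position_residue_counts,
)
from .design import LibraryDesign
from .reads import PeptideRecord

DEFAULT_PSEUDOCOUNT = 0.5  # used only when pseudocounts are enabled


def frequencies(table: CountsTable) -> dict:
    """Per-peptide relative frequency (counts / total); sums to 1."""
    total = table.total
    if total <= 0:
        raise ValueError("counts table is empty")
    return {pep: n / total for pep, n in table.entries.items()}


def enrichment_scores(
    sorted_table: CountsTable,
    unsorted_table: CountsTable,
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """Per-peptide enrichment table (discrete scheme).

    Rows indexed by peptide, over the union of both samples, with
    counts, frequencies, the sorted/unsorted frequency ratio, and its
    log2/log10 transforms. With ``pseudocount == 0`` peptides absent
    from the unsorted sample get NaN enrichment.
    """
    if sorted_table.total <= 0 or unsorted_table.total <= 0:
        raise ValueError("both samples must have positive totals")
    peptides = sorted(set(sorted_table.entries) | set(unsorted_table.entries))
    cs = np.array([sorted_table.entries.get(p, 0) for p in peptides], dtype=float)
    cu = np.array([unsorted_table.entries.get(p, 0) for p in peptides], dtype=float)
    if pseudocount:
        cs = cs + pseudocount
        cu = cu + pseudocount
    fs = cs / cs.sum()
    fu = cu / cu.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        enr = np.where(fu > 0, fs / fu, np.nan)
        log2 = np.where(enr > 0, np.log2(np.where(enr > 0, enr, 1.0)), np.nan)
        log10 = np.where(enr > 0, np.log10(np.where(enr > 0, enr, 1.0)), np.nan)
    df = pd.DataFrame(
        {
            "count_sorted": cs if pseudocount else cs.astype(int),
            "count_unsorted": cu if pseudocount else cu.astype(int),
            "freq_sorted": fs,
            "freq_unsorted": fu,
            "enrichment": enr,
            "log2_enrichment": log2,
            "log10_enrichment": log10,
        },
        index=pd.Index(peptides, name="peptide"),
    )
    df.attrs["pseudocount"] = pseudocount
    df.attrs["samples"] = (sorted_table.sample_id, unsorted_table.sample_id)
    return df


@dataclass
class PositionEnrichmentMatrix:
    """Residue x position enrichment ratios with log transforms."""

    enrichment: pd.DataFrame
    log2: pd.DataFrame
    log10: pd.DataFrame
    mask: set = field(default_factory=set)
    filter_mode: str = "full"

    def to_tsv(self, path, which: str = "log2") -> None:
        df = getattr(self, which)
        with open(path, "w") as fh:
            fh.write(f"# filter_mode={self.filter_mode}\tmask={sorted(self.mask)}\tvalues={which}\n")
            df.to_csv(fh, sep="\t")


def position_enrichment(
    sorted_matrix: ResiduePositionMatrix,
    unsorted_matrix: ResiduePositionMatrix,
    mask: Optional[set] = None,
    pseudocount: float = 0.0,
) -> PositionEnrichmentMatrix:
    """Positional enrichment for degenerate libraries.

    Column totals -> per-cell frequencies -> sorted/unsorted ratio;
    masked columns (e.g. the fixed central tyrosine) are set to NaN.
    """
    if list(sorted_matrix.matrix.columns) != list(unsorted_matrix.matrix.columns) or list(
        sorted_matrix.matrix.index
    ) != list(unsorted_matrix.matrix.index):
        raise ValueError("sorted and unsorted matrices have different shapes/labels")
    if sorted_matrix.filter_mode != unsorted_matrix.filter_mode:
        raise ValueError("filter modes differ between samples")
    cs = sorted_matrix.matrix.astype(float) + pseudocount
    cu = unsorted_matrix.matrix.astype(float) + pseudocount
    fs = cs / cs.sum(axis=0)
    fu = cu / cu.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        enr = fs / fu
    enr = enr.where(fu > 0)
    mask = set(mask) if mask is not None else set()
    for col in mask:
        enr[col] = np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        log2 = np.log2(enr.where(enr > 0))
        log10 = np.log10(enr.where(enr > 0))
    return PositionEnrichmentMatrix(enr, log2, log10, mask, sorted_matrix.filter_mode)


@dataclass
class ScanningEnrichmentMatrix:
    """Log enrichment per (mutant residue, position), wild type = 0."""

    enrichment: pd.DataFrame
    log_normalized: pd.DataFrame
    log_base: int
    reference_peptide: str
    reference_log_enrichment: float


def scanning_enrichment(
    sorted_counts: ScanningCountsMatrix,
    unsorted_counts: ScanningCountsMatrix,
    log_base: int = 10,
    pseudocount: float = 0.0,
) -> ScanningEnrichmentMatrix:
    """Scanning-mutagenesis enrichment, normalized to the wild type.

    Sample totals use the wild-type repeat correction (matrix sum minus
    wt_count x (L-1)); frequencies are cell counts over that total;
    log-ratio scores have the reference's log score subtracted, so
    reference cells are exactly 0 in every column.
    """
    if sorted_counts.reference_peptide != unsorted_counts.reference_peptide:
        raise ValueError("reference peptides differ between samples")
    ref = sorted_counts.reference_peptide
    tot_s = sorted_counts.corrected_total()
    tot_u = unsorted_counts.corrected_total()
    if tot_s <= 0 or tot_u <= 0:
        raise ValueError("corrected total must be positive in both samples")
    cs = sorted_counts.matrix.matrix.astype(float) + pseudocount
    cu = unsorted_counts.matrix.matrix.astype(float) + pseudocount
    fs = cs / tot_s
    fu = cu / tot_u
    with np.errstate(divide="ignore", invalid="ignore"):
        enr = (fs / fu).where(cu > 0)
        log = np.log2(enr.where(enr > 0)) if log_base == 2 else np.log10(enr.where(enr > 0))
    cols = list(enr.columns)
    ref_ratio = (sorted_counts.wt_count / tot_s) / (unsorted_counts.wt_count / tot_u)
    ref_log = math.log2(ref_ratio) if log_base == 2 else math.log10(ref_ratio)
    norm = log - ref_log
    # pin reference cells to exactly zero (they are the baseline)
    for j, aa in enumerate(ref):
        norm.loc[aa, cols[j]] = 0.0
    return ScanningEnrichmentMatrix(enr, norm, log_base, ref, ref_log)


def amber_position_enrichment(
    sorted_records: Iterable[Union[PeptideRecord, str]],
    unsorted_records: Iterable[Union[PeptideRecord, str]],
    design: LibraryDesign,
    pseudocount: float = 0.0,
) -> PositionEnrichmentMatrix:
    """Positional enrichment restricted to one-amber peptides.

    Amber-containing sequences are systematically depleted relative to
    amber-free ones (lower display efficiency even under suppression),
    so the non-canonical residue's preference is read out only within
    the exactly-one-amber subset; the ``*`` row then reports its
    positional enrichment on a fair baseline.
    """
    labels = design.position_labels()
    ms = position_residue_counts(
        sorted_records, design.peptide_length, filter_mode="onestop", positions=labels
    )
    mu = position_residue_counts(
        unsorted_records, design.peptide_length, filter_mode="onestop", positions=labels
    )
    if ms.matrix.to_numpy().sum() == 0 or mu.matrix.to_numpy().sum() == 0:
        raise ValueError("no one-amber records in at least one sample")
    return position_enrichment(ms, mu, mask=design.masked_positions(), pseudocount=pseudocount)


def select_for_logo(
    table: pd.DataFrame,
    cutoff: float = 3.0,
    single_tyrosine_only: bool = True,
) -> tuple[list, list, pd.DataFrame, pd.DataFrame]:
    """Foreground/background peptide sets for probability-logo tools.

    Foreground: peptides above the enrichment cutoff (default 3);
    background: all scored peptides — both restricted to peptides with
    exactly one tyrosine when ``single_tyrosine_only``. Also returns
    position-frequency tables for each set.
    """
    peptides = list(table.index)
    scored = table["enrichment"].notna()
    if single_tyrosine_only:
        one_tyr = pd.Series([p.count("Y") == 1 for p in peptides], index=table.index)
    else:
        one_tyr = pd.Series(True, index=table.index)
    background = [p for p in table.index[one_tyr & scored]]
    foreground = [p for p in table.index[one_tyr & scored & (table["enrichment"] > cutoff)]]
    return foreground, background, _position_frequencies(foreground), _position_frequencies(background)


def _position_frequencies(peptides: list) -> pd.DataFrame:
    from .design import ROW_ORDER

    if not peptides:
        return pd.DataFrame(index=list(ROW_ORDER))
    L = len(peptides[0])
    counts = position_residue_counts(peptides, L)
    totals = counts.matrix.sum(axis=0)
    return counts.matrix / totals.replace(0, np.nan)


def mean_log_scores(matrices: list, which: str = "log2") -> pd.DataFrame:
    """Cross-replicate averaging: element-wise mean of log scores from
    per-pair comparisons (each sorted sample scored only against its
    matched unsorted sample)."""
    if not matrices:
        raise ValueError("no matrices to average")
    stacked = np.stack([getattr(m, which).to_numpy(dtype=float) for m in matrices])
    import warnings

    with warnings.catch_warnings():
        # cells NaN in every replicate (masked columns) stay NaN
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean = np.nanmean(stacked, axis=0)
    template = getattr(matrices[0], which)
    return pd.DataFrame(mean, index=template.index, columns=template.columns)


def plot_heatmap(df: pd.DataFrame, path, title: str = "", vlim: Optional[float] = None) -> None:
    """Diverging blue-white-red heatmap of log enrichment scores."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = df.to_numpy(dtype=float)
    if vlim is None:
        finite = data[np.isfinite(data)]
        vlim = float(np.abs(finite).max()) if finite.size else 1.0
    fig, ax = plt.subplots(figsize=(0.45 * data.shape[1] + 2, 0.3 * data.shape[0] + 1.5))
    im = ax.imshow(data, cmap="bwr", vmin=-vlim, vmax=vlim, aspect="auto")
    ax.set_xticks(range(data.shape[1]), [str(c) for c in df.columns])
    ax.set_yticks(range(data.shape[0]), list(df.index))
    ax.set_xlabel("position")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.8, label="log enrichment")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
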