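"""Raw paired-end amplicon reads -> translated peptide records.

Processing follows merge -> flank-anchored insert extraction ->
translation. The merger builds a consensus over the best suffix-prefix
overlap between the forward read and the reverse-complemented reverse
read, resolving mismatches by base quality. Insert extraction anchors
on the constant regions flanking the peptide-coding cassette
(36 nt upstream, 37 nt downstream), tolerating a configurable number of
substitutions per anchor. Translation maps TAG to ``*`` (the amber
codon, a candidate non-canonical-residue site under suppression) and
rejects reads containing the terminators TAA/TGA, which cannot encode a
displayed peptide.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from typing import Iterable, Optional

from Bio.Seq import reverse_complement
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .design import FIVE_ANCHOR, THREE_ANCHOR, LibraryDesign, translate_codon

STATUSES = ("ok", "merge_fail", "flank_fail", "frame_fail", "length_fail", "terminator_fail")


@dataclass
class PeptideRecord:
    """One processed read."""

    insert_dna: str
    peptide: str
    n_amber: int
    n_terminator: int
    status: str
    read_id: str = ""
    orientation: str = "forward"


@dataclass
class QCStats:
    """Per-sample processing tallies; status counts sum to input reads."""

    sample_id: str = ""
    counts: dict = field(default_factory=lambda: {s: 0 for s in STATUSES})
    reads_in: int = 0
    reverse_orientation: int = 0

    @property
    def reads_ok(self) -> int:
        return self.counts["ok"]

    def record(self, status: str) -> None:
        self.reads_in += 1
        self.counts[status] += 1

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "sample_id": self.sample_id,
                    "reads_in": self.reads_in,
                    "reads_ok": self.reads_ok,
                    "status_counts": self.counts,
                    "reverse_orientation": self.reverse_orientation,
                },
                fh,
                indent=2,
            )


def merge_pair(
    forward: str,
    reverse: str,
    forward_qual: Optional[str] = None,
    reverse_qual: Optional[str] = None,
    min_overlap: int = 10,
    max_mismatch_fraction: float = 0.25,
) -> Optional[str]:
    """Merge a read pair via its best suffix-prefix overlap.

    The reverse read is reverse-complemented; every overlap length from
    ``min_overlap`` up to the shorter read is scored as
    matches - mismatches, keeping overlaps whose mismatch fraction is at
    most ``max_mismatch_fraction``. At mismatched overlap positions the
    base with the higher quality wins (forward wins ties). Returns the
    merged sequence, or None when no admissible overlap exists.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    if not (0 <= max_mismatch_fraction < 0.5):
        raise ValueError("max_mismatch_fraction must be in [0, 0.5)")
    fwd = forward.upper()
    rev = reverse_complement(reverse.upper())
    rq = reverse_qual[::-1] if reverse_qual is not None else None

    best = None  # (score, overlap_len, mismatch_positions)
    max_len = min(len(fwd), len(rev))
    for ov in range(min_overlap, max_len + 1):
        f_tail = fwd[len(fwd) - ov:]
        r_head = rev[:ov]
        if f_tail == r_head:
            mism: list[int] = []
        else:
            mism = [i for i in range(ov) if f_tail[i] != r_head[i]]
            if len(mism) > max_mismatch_fraction * ov:
                continue
        score = ov - 2 * len(mism)
        if best is None or score > best[0] or (score == best[0] and ov > best[1]):
            best = (score, ov, mism)
    if best is None:
        return None
    _, ov, mism = best
    start = len(fwd) - ov
    consensus = list(fwd[start:])
    for i in mism:
        fq = forward_qual[start + i] if forward_qual is not None else "!"
        rqc = rq[i] if rq is not None else "!"
        if rqc > fq:
            consensus[i] = rev[i]
    return fwd[:start] + "".join(consensus) + rev[ov:]


def _find_approx(seq: str, anchor: str, max_mismatches: int, start: int = 0) -> int:
    """Leftmost occurrence of ``anchor`` in ``seq`` with at most
    ``max_mismatches`` substitutions, or -1."""
    exact = seq.find(anchor, start)
    if exact != -1 or max_mismatches == 0:
        return exact
    n, m = len(seq), len(anchor)
    for i in range(start, n - m + 1):
        mism = 0
        window = seq[i:i + m]
        for a, b in zip(window, anchor):
            if a != b:
                mism += 1
                if mism > max_mismatches:
                    break
        else:
            return i
    return -1


def extract_insert(
    merged: str,
    design: Optional[LibraryDesign] = None,
    max_flank_mismatches: int = 1,
) -> Optional[str]:
    """Extract the peptide-coding insert between the two flank anchors.

    Uses the leftmost 5' anchor match and the nearest subsequent 3'
    anchor match; returns None when either anchor is missing or the
    insert length is negative.
    """
    seq = merged.upper()
    i5 = _find_approx(seq, FIVE_ANCHOR, max_flank_mismatches)
    if i5 == -1:
        return None
    insert_start = i5 + len(FIVE_ANCHOR)
    i3 = _find_approx(seq, THREE_ANCHOR, max_flank_mismatches, start=insert_start)
    if i3 == -1:
        return None
    return seq[insert_start:i3]


def translate_insert(
    insert_dna: str,
    design: Optional[LibraryDesign] = None,
    terminator_policy: str = "fail",
    read_id: str = "",
) -> PeptideRecord:
    """Translate an insert in frame 0 into a PeptideRecord.

    TAG -> ``*``; TAA/TGA -> ``terminator_fail`` (or ``X`` under
    ``terminator_policy="mask"``); untranslatable codons -> ``X``.
    Length checks against the design populate frame/length failures.
    """
    seq = insert_dna.upper()
    if len(seq) % 3 != 0:
        return PeptideRecord(insert_dna, "", 0, 0, "frame_fail", read_id)
    residues = []
    n_amber = 0
    n_term = 0
    for i in range(0, len(seq), 3):
        aa = translate_codon(seq[i:i + 3])
        if aa == "*":
            n_amber += 1
        elif aa == "#":
            n_term += 1
            aa = "X"
        residues.append(aa)
    peptide = "".join(residues)
    if n_term > 0 and terminator_policy == "fail":
        return PeptideRecord(insert_dna, peptide, n_amber, n_term, "terminator_fail", read_id)
    if design is not None and len(peptide) != design.peptide_length:
        return PeptideRecord(insert_dna, peptide, n_amber, n_term, "length_fail", read_id)
    return PeptideRecord(insert_dna, peptide, n_amber, n_term, "ok", read_id)


def _open_maybe_gzip(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def _iter_fastq(path):
    with _open_maybe_gzip(path) as fh:
        yield from FastqGeneralIterator(fh)


@dataclass
class ProcessingParams:
    min_overlap: int = 10
    max_mismatch_fraction: float = 0.25
    max_flank_mismatches: int = 1
    terminator_policy: str = "fail"
    try_reverse_orientation: bool = True


def process_pair(
    forward: str,
    reverse: Optional[str],
    design: LibraryDesign,
    params: ProcessingParams,
    forward_qual: Optional[str] = None,
    reverse_qual: Optional[str] = None,
    read_id: str = "",
) -> PeptideRecord:
    """Merge (if paired) -> extract -> translate for one read (pair)."""
    if reverse is None:
        merged = forward.upper()
    else:
        merged = merge_pair(
            forward, reverse, forward_qual, reverse_qual,
            min_overlap=params.min_overlap,
            max_mismatch_fraction=params.max_mismatch_fraction,
        )
        if merged is None:
            return PeptideRecord("", "", 0, 0, "merge_fail", read_id)
    insert = extract_insert(merged, design, params.max_flank_mismatches)
    orientation = "forward"
    if insert is None and params.try_reverse_orientation:
        insert = extract_insert(reverse_complement(merged), design, params.max_flank_mismatches)
        orientation = "reverse"
    if insert is None:
        return PeptideRecord("", "", 0, 0, "flank_fail", read_id)
    rec = translate_insert(insert, design, params.terminator_policy, read_id)
    rec.orientation = orientation
    return rec


def process_sample(
    fastq_forward,
    fastq_reverse=None,
    design: Optional[LibraryDesign] = None,
    params: Optional[ProcessingParams] = None,
    sample_id: str = "",
) -> tuple[list[PeptideRecord], QCStats]:
    """Stream a FASTQ sample (paired or pre-merged) into peptide records.

    Returns all records (including failures, with their status set) and
    the QC tallies. Paired files must list mates in the same order.
    """
    if design is None:
        raise ValueError("a LibraryDesign is required")
    params = params or ProcessingParams()
    stats = QCStats(sample_id=sample_id)
    records: list[PeptideRecord] = []

    if fastq_reverse is None:
        for rid, seq, qual in _iter_fastq(fastq_forward):
            rec = process_pair(seq, None, design, params, qual, None, rid.split()[0])
            stats.record(rec.status)
            if rec.orientation == "reverse":
                stats.reverse_orientation += 1
            records.append(rec)
        return records, stats

    fwd_iter = _iter_fastq(fastq_forward)
    rev_iter = _iter_fastq(fastq_reverse)
    while True:
        f = next(fwd_iter, None)
        r = next(rev_iter, None)
        if f is None and r is None:
            break
        if f is None or r is None:
            raise IOError("paired FASTQ files have unequal read counts")
        fid, fseq, fqual = f
        rid, rseq, rqual = r
        rec = process_pair(fseq, rseq, design, params, fqual, rqual, fid.split()[0])
        stats.record(rec.status)
        if rec.orientation == "reverse":
            stats.reverse_orientation += 1
        records.append(rec)
    return records, stats


def write_peptide_table(records: Iterable[PeptideRecord], path) -> None:
    """Per-sample TSV of processed reads (peptide, insert, amber count, status)."""
    with open(path, "w") as fh:
        fh.write("peptide\tinsert_dna\tn_amber\tstatus\n")
        for rec in records:
            fh.write(f"{rec.peptide}\t{rec.insert_dna}\t{rec.n_amber}\t{rec.status}\n")
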