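"""Read processing: merging, flank-anchored extraction, translation."""

import pytest
from Bio.Seq import reverse_complement
from hypothesis import given, settings, strategies as st

from pepdisplay.design import FIVE_ANCHOR, THREE_ANCHOR, LibraryDesign
from pepdisplay.reads import (
    ProcessingParams,
    extract_insert,
    merge_pair,
    process_pair,
    process_sample,
    translate_insert,
)

DNA = st.text(alphabet="ACGT", min_size=1)


class TestMergePair:
    def test_hand_constructed_overlap(self):
        # forward and reverse share the 9-nt overlap TACGTACGT
        forward = "ACGTACGTACGT"
        reverse = reverse_complement("TACGTACGTTTT")
        assert merge_pair(forward, reverse, min_overlap=5) == "ACGTACGTACGTTTT"

    def test_full_overlap_identity(self):
        forward = "ACGTTGCAACGGTTAA"
        assert merge_pair(forward, reverse_complement(forward), min_overlap=5) == forward

    def test_disjoint_reads_fail(self):
        assert merge_pair("AAAAAAAAAAAA", "CCCCCCCCCCCC", min_overlap=10) is None

    def test_quality_resolves_mismatch(self):
        # one mismatch in the overlap; the base with higher quality wins
        template = "ACGTACGTACGTTTTT"
        forward = template[:12]
        reverse_sense = template[4:]
        corrupted = reverse_sense[:2] + "G" + reverse_sense[3:]  # overlap pos 6
        reverse = reverse_complement(corrupted)
        merged_fwd_wins = merge_pair(
            forward, reverse, "I" * 12, "!" * 12,
            min_overlap=6, max_mismatch_fraction=0.3,
        )
        assert merged_fwd_wins == template
        merged_rev_wins = merge_pair(
            forward, reverse, "!" * 12, "I" * 12,
            min_overlap=6, max_mismatch_fraction=0.3,
        )
        assert merged_rev_wins == template[:6] + "G" + template[7:]

    def test_agrees_with_brute_force_best_overlap(self):
        """Merge oracle: on random constructed pairs the merger agrees
        with an independent brute-force search over all overlap
        offsets (score = matches - mismatches, ties to the longer
        overlap)."""
        import numpy as np

        def brute_force(fwd, rev_read, min_overlap=10, max_mm_frac=0.25):
            rev = reverse_complement(rev_read)
            best = None
            for ov in range(min_overlap, min(len(fwd), len(rev)) + 1):
                pairs = list(zip(fwd[-ov:], rev[:ov]))
                mm = sum(a != b for a, b in pairs)
                if mm > max_mm_frac * ov:
                    continue
                score = ov - 2 * mm
                if best is None or score > best[0] or (score == best[0] and ov > best[1]):
                    best = (score, ov, mm)
            if best is None:
                return None
            _, ov, _ = best
            # equal qualities: the forward base wins every conflict
            return fwd + rev[ov:]

        rng = np.random.default_rng(2024)
        bases = "ACGT"
        for _ in range(1000):
            n = int(rng.integers(40, 120))
            template = "".join(bases[i] for i in rng.integers(0, 4, size=n))
            read_len = int(rng.integers(n // 2 + 8, n + 1))
            forward = template[:read_len]
            reverse = reverse_complement(template[n - read_len:])
            merged = merge_pair(forward, reverse, min_overlap=10)
            assert merged == brute_force(forward, reverse)

    def test_reconstructs_template_from_overlapping_reads(self):
        """Error-free reads cut from a random high-entropy template
        merge back into it."""
        import numpy as np

        rng = np.random.default_rng(7)
        bases = "ACGT"
        for _ in range(200):
            n = int(rng.integers(60, 120))
            template = "".join(bases[i] for i in rng.integers(0, 4, size=n))
            read_len = int(rng.integers(n // 2 + 10, n + 1))
            forward = template[:read_len]
            reverse = reverse_complement(template[n - read_len:])
            assert merge_pair(forward, reverse, min_overlap=10) == template

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            merge_pair("ACGT", "ACGT", min_overlap=0)
        with pytest.raises(ValueError):
            merge_pair("ACGT", "ACGT", max_mismatch_fraction=0.6)


def _assemble(insert, n5="AACCGT", n3="TTGCAT"):
    return n5 + FIVE_ANCHOR + insert + THREE_ANCHOR + n3


class TestExtractInsert:
    INSERT = "tatgatatgtttccgtttgatgaatgcat".upper()[:33].ljust(33, "A")

    def test_round_trip(self):
        assert extract_insert(_assemble(self.INSERT), max_flank_mismatches=0) == self.INSERT

    def test_tolerates_one_anchor_mismatch(self):
        merged = _assemble(self.INSERT)
        i = merged.index(FIVE_ANCHOR) + 5
        base = "G" if merged[i] != "G" else "T"
        corrupted = merged[:i] + base + merged[i + 1:]
        assert extract_insert(corrupted, max_flank_mismatches=1) == self.INSERT
        assert extract_insert(corrupted, max_flank_mismatches=0) is None

    def test_missing_three_anchor_fails(self):
        merged = "AACCGT" + FIVE_ANCHOR + self.INSERT
        assert extract_insert(merged) is None


class TestTranslateInsert:
    def test_single_tyrosine_codon(self):
        rec = translate_insert("tat")
        assert rec.peptide == "Y" and rec.n_amber == 0 and rec.status == "ok"

    def test_src_consensus_coding_sequence(self):
        rec = translate_insert("ccggatgaatgcatttatgatatgtttccgttt")
        assert rec.peptide == "PDECIYDMFPF"
        assert rec.status == "ok"

    def test_amber_codon_maps_to_star(self):
        rec = translate_insert("tagtat")
        assert rec.peptide == "*Y" and rec.n_amber == 1 and rec.status == "ok"

    def test_terminator_rejected_by_default(self):
        rec = translate_insert("taatat")
        assert rec.status == "terminator_fail" and rec.n_terminator == 1

    def test_terminator_masked_under_mask_policy(self):
        rec = translate_insert("taatat", terminator_policy="mask")
        assert rec.status == "ok" and rec.peptide == "XY"

    def test_frame_failure(self):
        assert translate_insert("tatg").status == "frame_fail"

    def test_length_failure_against_design(self, x5_design):
        assert translate_insert("tat", x5_design).status == "length_fail"


class TestProcessSample:
    def test_zero_error_round_trip_is_lossless(self, small_screen):
        stats = small_screen["stats_unsorted"]
        assert stats.reads_in == 4000
        assert stats.counts["ok"] == 4000
        assert sum(stats.counts.values()) == stats.reads_in

    def test_status_counts_conserve_reads(self, small_screen):
        for key in ("stats_sorted", "stats_unsorted"):
            stats = small_screen[key]
            assert sum(stats.counts.values()) == stats.reads_in

    def test_broken_anchors_are_tallied(self, tmp_path, x5_design):
        """Pairs whose 3' anchor is destroyed must be flank_fail."""
        insert = "NNStat".replace("NNS", "gcg") * 0 + "gcggcggcggcggcgtatgcggcggcggcggcg"
        good = _assemble(insert.upper())
        bad = good.replace(THREE_ANCHOR, "T" * len(THREE_ANCHOR))
        r1 = tmp_path / "r1.fastq"
        r2 = tmp_path / "r2.fastq"
        with open(r1, "w") as f1, open(r2, "w") as f2:
            for i in range(20):
                amp = bad if i < 3 else good
                fwd, rev = amp[:75], reverse_complement(amp)[:75]
                f1.write(f"@r{i}/1\n{fwd}\n+\n{'I' * len(fwd)}\n")
                f2.write(f"@r{i}/2\n{rev}\n+\n{'I' * len(rev)}\n")
        records, stats = process_sample(r1, r2, x5_design)
        assert stats.counts["ok"] == 17
        assert stats.counts["flank_fail"] == 3

    def test_empty_fastq(self, tmp_path, x5_design):
        r1 = tmp_path / "e1.fastq"
        r2 = tmp_path / "e2.fastq"
        r1.write_text("")
        r2.write_text("")
        records, stats = process_sample(r1, r2, x5_design)
        assert records == [] and stats.reads_in == 0

    def test_unpaired_files_rejected(self, tmp_path, x5_design):
        r1 = tmp_path / "u1.fastq"
        r2 = tmp_path / "u2.fastq"
        r1.write_text("@a\nACGT\n+\nIIII\n")
        r2.write_text("")
        with pytest.raises(IOError):
            process_sample(r1, r2, x5_design)

    def test_reverse_orientation_fallback(self, x5_design):
        insert = "gcggcggcggcggcgtatgcggcggcggcggcg".upper()
        amp = _assemble(insert)
        # swap R1 and R2 of a normal pair: the merged consensus is the
        # reverse complement of the amplicon
        rec = process_pair(
            reverse_complement(amp)[:75], amp[:75],
            x5_design, ProcessingParams(),
        )
        assert rec.status == "ok"
        assert rec.orientation == "reverse"
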