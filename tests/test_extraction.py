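"""Read-level call extraction: phasing rule, strand handling, stats accounting."""

import numpy as np
import pysam
import pytest

from editphase.extraction import (
    CALL_EDITED,
    CALL_OTHER,
    CALL_REF,
    CALL_UNCOVERED,
    extract_calls,
    group_by_cell,
)
from editphase.simulate import SimConfig, build_reference, simulate_cohort
from editphase.sites import EditSite, EditSiteSet

from conftest import make_header, make_read

# genomic 0-based site positions of the shipped cpx7A config
CPX = [374, 387, 388]


@pytest.fixture(scope="module")
def cpx_ref(cpx_sites):
    contigs = build_reference([cpx_sites], read_length=150)
    return contigs["cpx7A_synth"]


@pytest.fixture()
def cpx_header(cpx_ref):
    return make_header({"cpx7A_synth": len(cpx_ref)})


def ref_read(cpx_ref, header, name, start, length, edits=(), mutate=None, **kw):
    """Read copied from the reference with G substituted at edited site indices."""
    seq = list(cpx_ref[start : start + length])
    for idx in edits:
        seq[CPX[idx] - start] = "G"
    for pos, base in (mutate or {}).items():
        seq[pos - start] = base
    return make_read(header, name, "cpx7A_synth", start, "".join(seq), **kw)


class TestPhasedExtraction:
    def test_fully_spanning_reads_called_per_state(self, cpx_sites, cpx_ref, cpx_header):
        reads = [
            ref_read(cpx_ref, cpx_header, "unedited", 350, 60),
            ref_read(cpx_ref, cpx_header, "triple", 350, 60, edits=(0, 1, 2)),
            ref_read(cpx_ref, cpx_header, "first_only", 350, 60, edits=(0,)),
        ]
        calls, stats = extract_calls(reads, cpx_sites, "c1")
        assert stats.total == stats.passing == 3
        by_name = {c.read_id: c.calls for c in calls}
        assert by_name["unedited"] == (CALL_REF,) * 3
        assert by_name["triple"] == (CALL_EDITED,) * 3
        assert by_name["first_only"] == (CALL_EDITED, CALL_REF, CALL_REF)

    def test_read_ending_before_last_site_fails_coverage(
        self, cpx_sites, cpx_ref, cpx_header
    ):
        # covers 375 and 388 but ends before 389: not a continuous span of all sites
        read = ref_read(cpx_ref, cpx_header, "short", 360, 28)
        assert read.reference_end == 388  # half-open: site 388 not included
        calls, stats = extract_calls([read], cpx_sites, "c1")
        assert calls == []
        assert stats.fail_coverage == 1 and stats.total == 1

    def test_low_base_quality_at_one_site_drops_read(self, cpx_sites, cpx_ref, cpx_header):
        quals = [40] * 60
        quals[CPX[1] - 350] = 5
        read = ref_read(cpx_ref, cpx_header, "lowq", 350, 60, quals=quals)
        calls, stats = extract_calls([read], cpx_sites, "c1")
        assert calls == []
        assert stats.fail_quality == 1

    def test_low_mapping_quality_drops_read(self, cpx_sites, cpx_ref, cpx_header):
        read = ref_read(cpx_ref, cpx_header, "lowmapq", 350, 60, mapq=3)
        calls, stats = extract_calls([read], cpx_sites, "c1")
        assert calls == []
        assert stats.fail_quality == 1

    def test_other_base_emitted_but_flagged(self, cpx_sites, cpx_ref, cpx_header):
        read = ref_read(cpx_ref, cpx_header, "snv", 350, 60, mutate={CPX[2]: "C"})
        calls, stats = extract_calls([read], cpx_sites, "c1")
        assert stats.other_base == 1 and stats.passing == 0
        assert calls[0].calls == (CALL_REF, CALL_REF, CALL_OTHER)
        assert not calls[0].is_evaluable()

    def test_deletion_over_a_site_fails_coverage(self, cpx_sites, cpx_ref, cpx_header):
        # 19M spans 355..373, 2D deletes the site at 374, then 39M resumes at 376
        seq = cpx_ref[355:374] + cpx_ref[376:415]
        read = make_read(
            cpx_header, "del", "cpx7A_synth", 355, seq, cigar="19M2D39M"
        )
        calls, stats = extract_calls([read], cpx_sites, "c1")
        assert calls == []
        assert stats.fail_coverage == 1

    def test_stats_partition_on_mixed_bag(self, cpx_sites, cpx_ref, cpx_header):
        reads = [
            ref_read(cpx_ref, cpx_header, "ok", 350, 60),
            ref_read(cpx_ref, cpx_header, "short", 360, 28),
            ref_read(cpx_ref, cpx_header, "lowmapq", 350, 60, mapq=0),
            ref_read(cpx_ref, cpx_header, "snv", 350, 60, mutate={CPX[0]: "T"}),
        ]
        calls, stats = extract_calls(reads, cpx_sites, "c1")
        stats.check_partition()
        assert (stats.passing, stats.fail_coverage, stats.fail_quality, stats.other_base) == (
            1,
            1,
            1,
            1,
        )


class TestIndependentExtraction:
    def test_partial_coverage_emitted_with_uncovered(self, syx_sites, syn_sites):
        contigs = build_reference([syn_sites], read_length=60)
        header = make_header({"syn_synth": len(contigs["syn_synth"])})
        # covers the sites at 42 and 54 but ends before the one at 57
        seq = contigs["syn_synth"][30:55]
        read = make_read(header, "partial", "syn_synth", 30, seq)
        calls, stats = extract_calls([read], syn_sites, "c1")
        assert stats.total == 1 and stats.passing == 1
        assert calls[0].calls == (CALL_REF, CALL_REF, CALL_UNCOVERED)


class TestStrandHandling:
    def _mirrored_sets(self):
        plus_sites = tuple(
            EditSite(
                site_id=f"p{i}",
                gene="mini",
                transcript_pos=tp,
                codon_index=ci,
                codon_offset=co,
                strand="+",
                contig="P",
                genomic_start=g,
            )
            for i, (tp, ci, co, g) in enumerate(
                [(375, 125, 3, 10), (388, 130, 1, 20), (389, 130, 2, 21)]
            )
        )
        minus_sites = tuple(
            EditSite(
                site_id=f"m{i}",
                gene="mini",
                transcript_pos=tp,
                codon_index=ci,
                codon_offset=co,
                strand="-",
                contig="M",
                genomic_start=g,
            )
            for i, (tp, ci, co, g) in enumerate(
                [(375, 125, 3, 90), (388, 130, 1, 80), (389, 130, 2, 79)]
            )
        )
        codons = {125: "ATA", 130: "AAT"}
        return (
            EditSiteSet(gene="mini", sites=plus_sites, ref_codons=codons),
            EditSiteSet(gene="mini", sites=minus_sites, ref_codons=codons),
        )

    @pytest.mark.parametrize(
        "state",
        [(False, False, False), (True, False, True), (True, True, True), (False, True, False)],
    )
    def test_plus_and_minus_encodings_agree(self, state):
        """One biological molecule encoded on either genomic strand calls identically."""
        plus_set, minus_set = self._mirrored_sets()
        header = make_header({"P": 120, "M": 120})

        plus_seq = list("A" * 30)  # covers 5..35
        for (g, e) in zip([10, 20, 21], state):
            plus_seq[g - 5] = "G" if e else "A"
        plus_read = make_read(header, "p", "P", 5, "".join(plus_seq))

        minus_seq = list("T" * 30)  # covers 70..100 on the opposite strand
        for (g, e) in zip([90, 80, 79], state):
            minus_seq[g - 70] = "C" if e else "T"
        minus_read = make_read(header, "m", "M", 70, "".join(minus_seq))

        plus_calls, _ = extract_calls([plus_read], plus_set, "c1")
        minus_calls, _ = extract_calls([minus_read], minus_set, "c1")
        assert plus_calls[0].calls == minus_calls[0].calls
        assert plus_calls[0].edit_state() == state

    def test_minus_strand_other_base(self):
        _, minus_set = self._mirrored_sets()
        header = make_header({"M": 120})
        seq = list("T" * 30)
        seq[90 - 70] = "A"  # genomic A = sense T: neither ref nor edited
        read = make_read(header, "m", "M", 70, "".join(seq))
        calls, stats = extract_calls([read], minus_set, "c1")
        assert calls[0].calls[0] == CALL_OTHER
        assert stats.other_base == 1


class TestGrouping:
    def _write_sam(self, path, header, reads):
        with pysam.AlignmentFile(str(path), "w", header=header) as fh:
            for read in reads:
                fh.write(read)

    def test_per_file_mode_uses_filename_stems(self, tmp_path, cpx_ref, cpx_header):
        for cell in ("b", "a"):
            self._write_sam(
                tmp_path / f"{cell}.sam",
                cpx_header,
                [ref_read(cpx_ref, cpx_header, f"{cell}_r0", 350, 60)],
            )
        groups = group_by_cell([tmp_path / "b.sam", tmp_path / "a.sam"])
        assert [g[0] for g in groups] == ["a", "b"]  # lexicographic cell order

    def test_duplicate_cell_files_rejected(self, tmp_path, cpx_ref, cpx_header):
        (tmp_path / "x").mkdir()
        for sub in (tmp_path, tmp_path / "x"):
            self._write_sam(
                sub / "a.sam",
                cpx_header,
                [ref_read(cpx_ref, cpx_header, "r0", 350, 60)],
            )
        with pytest.raises(ValueError, match="duplicated cell_id"):
            group_by_cell([tmp_path / "a.sam", tmp_path / "x" / "a.sam"])

    def test_tag_mode_buckets_and_excludes_untagged(self, tmp_path, cpx_ref, cpx_header):
        reads = [
            ref_read(cpx_ref, cpx_header, "r0", 350, 60, tags={"CB": "cellB"}),
            ref_read(cpx_ref, cpx_header, "r1", 350, 60, tags={"CB": "cellA"}),
            ref_read(cpx_ref, cpx_header, "r2", 350, 60),  # untagged
        ]
        path = tmp_path / "all.sam"
        self._write_sam(path, cpx_header, reads)
        groups = group_by_cell(path)
        assert [g[0] for g in groups] == ["cellA", "cellB"]
        assert sum(len(g[1]) for g in groups) == 2


class TestSimulatorRoundTrip:
    def test_error_free_reads_reproduce_intended_states(self, tmp_path, cpx_sites):
        """With zero sequencing error, extraction recovers the simulator's
        per-read edit states exactly, and phasing-failing reads are dropped."""
        cfg = SimConfig(
            n_cells={"Ib": 4},
            reads_per_cell_mean=60,
            seq_error=0.0,
            seed=11,
            write_read_truth=True,
        )
        res = simulate_cohort(cfg, tmp_path)
        import pandas as pd

        read_truth = pd.read_csv(res.read_truth_path, sep="\t").set_index("read_id")
        for cell, reads in group_by_cell(res.alignment_path):
            calls, stats = extract_calls(reads, cpx_sites, cell)
            stats.check_partition()
            emitted = {c.read_id for c in calls}
            for c in calls:
                row = read_truth.loc[c.read_id]
                assert bool(row["spans_all_sites"])
                assert c.edit_state() == (
                    bool(row["e375"]),
                    bool(row["e388"]),
                    bool(row["e389"]),
                )
            truants = read_truth[
                (read_truth["cell_id"] == cell) & ~read_truth["spans_all_sites"]
            ]
            assert emitted.isdisjoint(set(truants.index))
            assert stats.fail_coverage == len(truants)
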