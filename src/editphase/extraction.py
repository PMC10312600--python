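"""Per-read base calls at configured edit sites, with read-level phasing.

For a *phased* site set a read contributes only if one contiguous aligned
segment covers every site — the rule that lets a single read classify a
transcript's combinatorial edit haplotype.  Paired mates are deliberately
not merged: one :class:`ReadCall` corresponds to one aligned segment of one
sequencing read.  Calls are reported on the mRNA sense strand, so for a
minus-strand gene a genomic T→C mismatch is an edited (G) call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
import pysam

from .sites import EditSiteSet, PHASED

logger = logging.getLogger(__name__)

__all__ = [
    "CALL_REF",
    "CALL_EDITED",
    "CALL_OTHER",
    "CALL_UNCOVERED",
    "ReadCall",
    "ExtractionStats",
    "extract_calls",
    "group_by_cell",
    "calls_to_frame",
]

CALL_REF = "ref"            # A on the sense strand
CALL_EDITED = "edited"      # G on the sense strand (inosine read as G)
CALL_OTHER = "other"        # any base not in {A, G}: sequencing error / SNV
CALL_UNCOVERED = "uncovered"

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass(frozen=True)
class ReadCall:
    """One read's sense-strand base call at each site of a phasing group."""

    cell_id: str
    read_id: str
    calls: tuple[str, ...]
    mapq: int
    min_baseq_at_sites: int

    def is_evaluable(self) -> bool:
        """True when every site call is ref or edited (contributes to haplotypes)."""
        return all(c in (CALL_REF, CALL_EDITED) for c in self.calls)

    def edit_state(self) -> tuple[bool, ...]:
        if not self.is_evaluable():
            raise ValueError(f"read {self.read_id!r} has non-evaluable site calls")
        return tuple(c == CALL_EDITED for c in self.calls)


@dataclass
class ExtractionStats:
    """Per-cell accounting of every primary alignment on the gene's contig.

    The four outcome counters partition ``total``: a read either passes
    (emitted, all covered-site calls in {A, G}), fails coverage (cannot be
    evaluated at the required sites), fails quality (mapping or base quality
    below threshold), or carries an off-model base at a site (emitted but
    flagged ``other``).
    """

    cell_id: str
    total: int = 0
    passing: int = 0
    fail_coverage: int = 0
    fail_quality: int = 0
    other_base: int = 0

    def check_partition(self) -> None:
        parts = self.passing + self.fail_coverage + self.fail_quality + self.other_base
        if parts != self.total:
            raise AssertionError(
                f"cell {self.cell_id}: outcome counts {parts} != total {self.total}"
            )


def _site_positions(sites: EditSiteSet) -> tuple[str, list[int]]:
    contigs = {s.contig for s in sites.sites}
    if None in contigs:
        raise ValueError(
            f"gene {sites.gene!r}: sites need contig + genomic coordinates for extraction"
        )
    if len(contigs) != 1:
        raise ValueError(f"gene {sites.gene!r}: sites span multiple contigs {contigs}")
    return contigs.pop(), [s.genomic_start for s in sites.sites]


def _iter_alignments(
    alignments, contig: str, start: int, stop: int
) -> Iterator[pysam.AlignedSegment]:
    if isinstance(alignments, (str, Path)):
        with pysam.AlignmentFile(str(alignments)) as fh:
            yield from _iter_alignments(fh, contig, start, stop)
        return
    if isinstance(alignments, pysam.AlignmentFile):
        if contig not in alignments.references:
            raise ValueError(f"contig {contig!r} missing from alignment header")
        if alignments.has_index():
            yield from alignments.fetch(contig, start, stop)
        else:
            for read in alignments.fetch(until_eof=True):
                if read.reference_name == contig:
                    yield read
        return
    # plain iterable of AlignedSegment (e.g. a per-cell view from group_by_cell)
    for read in alignments:
        if read.reference_name == contig:
            yield read


def extract_calls(
    alignments,
    sites: EditSiteSet,
    cell_id: str,
    *,
    min_mapq: int = 20,
    min_baseq: int = 20,
) -> tuple[list[ReadCall], ExtractionStats]:
    """Walk one cell's alignments and call each read at the configured sites.

    ``alignments`` may be a SAM/BAM path, an open ``pysam.AlignmentFile``
    (indexed files use random access, otherwise the stream is filtered by
    contig), or an iterable of aligned segments.  Secondary and supplementary
    records are ignored; unmapped and off-contig reads never enter the stats.

    For phased site sets a :class:`ReadCall` is emitted only when one
    contiguous aligned segment covers *all* sites with base quality at least
    ``min_baseq`` at each; an indel or reference skip over any site drops the
    read as failing coverage.  For independent site sets a read is emitted
    with per-site ``uncovered`` entries as long as at least one site is
    callable.
    """
    contig, positions = _site_positions(sites)
    strands = [s.strand for s in sites.sites]
    phased = sites.phasing == PHASED
    lo, hi = min(positions), max(positions) + 1

    calls_out: list[ReadCall] = []
    stats = ExtractionStats(cell_id=cell_id)

    for read in _iter_alignments(alignments, contig, lo, hi):
        if read.is_secondary or read.is_supplementary or read.is_unmapped:
            continue
        if read.reference_end is None or read.reference_end <= lo or read.reference_start >= hi:
            continue  # does not overlap the site window at all
        stats.total += 1

        if read.mapping_quality < min_mapq:
            stats.fail_quality += 1
            continue

        ref_to_query = {
            rpos: qpos
            for qpos, rpos in read.get_aligned_pairs(matches_only=False)
            if rpos is not None
        }
        seq = read.query_sequence or ""
        quals = read.query_qualities  # may be None for '*' records

        site_calls: list[str] = []
        site_quals: list[int] = []
        low_qual = False
        for pos, strand in zip(positions, strands):
            qpos = ref_to_query.get(pos)
            if qpos is None or qpos >= len(seq):
                site_calls.append(CALL_UNCOVERED)
                continue
            q = 255 if quals is None else int(quals[qpos])
            if q < min_baseq:
                low_qual = True
                site_calls.append(CALL_UNCOVERED)
                continue
            base = seq[qpos].upper()
            if strand == "-":
                base = _COMPLEMENT.get(base, "N")
            if base == "A":
                site_calls.append(CALL_REF)
            elif base == "G":
                site_calls.append(CALL_EDITED)
            else:
                site_calls.append(CALL_OTHER)
            site_quals.append(q)

        covered = [c for c in site_calls if c != CALL_UNCOVERED]
        if phased and len(covered) < sites.k:
            if low_qual:
                stats.fail_quality += 1
            else:
                stats.fail_coverage += 1
            continue
        if not covered:
            if low_qual:
                stats.fail_quality += 1
            else:
                stats.fail_coverage += 1
            continue

        rc = ReadCall(
            cell_id=cell_id,
            read_id=read.query_name or "",
            calls=tuple(site_calls),
            mapq=read.mapping_quality,
            min_baseq_at_sites=min(site_quals) if site_quals else 255,
        )
        calls_out.append(rc)
        if any(c == CALL_OTHER for c in site_calls):
            stats.other_base += 1
        else:
            stats.passing += 1

    stats.check_partition()
    return calls_out, stats


def group_by_cell(
    source,
    cell_tag: str = "CB",
) -> list[tuple[str, list[pysam.AlignedSegment]]]:
    """Partition alignments into per-cell views, in lexicographic cell order.

    ``source`` is either a sequence of per-cell SAM/BAM paths (cell id taken
    from the file name stem) or a single path / open file whose reads carry a
    per-read cell tag (default ``CB``).  Reads lacking the tag are excluded
    and counted in an ``untagged`` bin reported via logging.
    """
    if isinstance(source, (list, tuple)):
        by_cell: dict[str, list[pysam.AlignedSegment]] = {}
        for path in source:
            cell = Path(path).stem
            if cell in by_cell:
                raise ValueError(f"duplicated cell_id {cell!r} across input files")
            with pysam.AlignmentFile(str(path)) as fh:
                by_cell[cell] = list(fh.fetch(until_eof=True))
        return sorted(by_cell.items())

    if isinstance(source, (str, Path)):
        with pysam.AlignmentFile(str(source)) as fh:
            return group_by_cell(fh, cell_tag=cell_tag)

    by_cell = {}
    untagged = 0
    for read in source.fetch(until_eof=True):
        try:
            cell = read.get_tag(cell_tag)
        except KeyError:
            untagged += 1
            continue
        by_cell.setdefault(str(cell), []).append(read)
    if untagged:
        logger.info("excluded %d reads lacking the %s cell tag", untagged, cell_tag)
    return sorted(by_cell.items())


def calls_to_frame(calls: Sequence[ReadCall], sites: EditSiteSet) -> pd.DataFrame:
    """Tabulate read calls (one row per read, one column per site) for TSV dumps."""
    rows = []
    for rc in calls:
        row = {"cell_id": rc.cell_id, "read_id": rc.read_id, "mapq": rc.mapq,
               "min_baseq_at_sites": rc.min_baseq_at_sites}
        row.update(dict(zip(sites.site_ids, rc.calls)))
        rows.append(row)
    cols = ["cell_id", "read_id", "mapq", "min_baseq_at_sites", *sites.site_ids]
    return pd.DataFrame(rows, columns=cols)
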