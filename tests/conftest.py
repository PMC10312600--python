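"""Shared fixtures: site sets, in-memory SAM builders, and a naive profiler oracle."""

from __future__ import annotations

from collections import Counter

import numpy as np
import pysam
import pytest

from editphase import load_builtin_config
from editphase.extraction import (
    CALL_EDITED,
    CALL_OTHER,
    CALL_REF,
    CALL_UNCOVERED,
    ReadCall,
)
from editphase.profiles import QC_EXCLUDED, QC_PASS
from editphase.sites import EditSiteSet, recode


@pytest.fixture(scope="session")
def cpx_sites() -> EditSiteSet:
    return load_builtin_config("cpx7A")


@pytest.fixture(scope="session")
def syn_sites() -> EditSiteSet:
    return load_builtin_config("syn")


@pytest.fixture(scope="session")
def syx_sites() -> EditSiteSet:
    return load_builtin_config("syx1a")


def make_header(contigs: dict[str, int]) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": n, "LN": ln} for n, ln in contigs.items()],
        }
    )


def make_read(
    header: pysam.AlignmentHeader,
    name: str,
    contig: str,
    start: int,
    seq: str,
    mapq: int = 60,
    quals: list[int] | None = None,
    cigar: str | None = None,
    tags: dict | None = None,
) -> pysam.AlignedSegment:
    a = pysam.AlignedSegment(header)
    a.query_name = name
    a.query_sequence = seq
    a.flag = 0
    a.reference_id = list(header.references).index(contig)
    a.reference_start = start
    a.mapping_quality = mapq
    a.cigarstring = cigar or f"{len(seq)}M"
    a.query_qualities = pysam.qualitystring_to_array("I" * len(seq)) if quals is None else quals
    for tag, value in (tags or {}).items():
        a.set_tag(tag, value)
    return a


def make_call(
    sites: EditSiteSet,
    calls: tuple[str, ...],
    cell_id: str = "c1",
    read_id: str = "r",
) -> ReadCall:
    return ReadCall(
        cell_id=cell_id, read_id=read_id, calls=calls, mapq=60, min_baseq_at_sites=40
    )


def state_calls(sites: EditSiteSet, state, cell_id="c1", read_id="r") -> ReadCall:
    """ReadCall for a fully evaluable read with the given edit state."""
    return make_call(
        sites,
        tuple(CALL_EDITED if e else CALL_REF for e in state),
        cell_id=cell_id,
        read_id=read_id,
    )


def naive_profile(calls, sites: EditSiteSet, min_reads: int = 10):
    """Brute-force re-count of a cell profile, independent of the library path.

    Walks the reads one by one with explicit string comparisons and returns
    (n_phased, haplotype Counter, variant percent dict, coverage dict, qc).
    """
    good = (CALL_REF, CALL_EDITED)
    counter: Counter = Counter()
    coverage = dict.fromkeys(sites.site_ids, 0)
    n_phased = 0
    for rc in calls:
        for sid, c in zip(sites.site_ids, rc.calls):
            if c == CALL_REF or c == CALL_EDITED:
                coverage[sid] += 1
        if all(c in good for c in rc.calls):
            n_phased += 1
            counter[tuple(c == CALL_EDITED for c in rc.calls)] += 1
    percent: dict[str, float] = {}
    for state, n in counter.items():
        name = recode(state, sites)
        percent[name] = percent.get(name, 0.0) + 100.0 * n / n_phased
    qc = QC_PASS
    for sid in sites.site_ids:
        if coverage[sid] < min_reads:
            qc = QC_EXCLUDED
    return n_phased, counter, percent, coverage, qc


def random_calls(rng: np.random.Generator, sites: EditSiteSet, n_reads: int, cell="c1"):
    """Randomized read-call fixtures mixing all four call categories."""
    cats = np.array([CALL_REF, CALL_EDITED, CALL_OTHER, CALL_UNCOVERED], dtype=object)
    probs = np.array([0.45, 0.35, 0.1, 0.1])
    out = []
    for j in range(n_reads):
        picks = tuple(cats[rng.choice(4, size=sites.k, p=probs)])
        out.append(make_call(sites, picks, cell_id=cell, read_id=f"r{j}"))
    return out
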