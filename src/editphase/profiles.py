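"""Per-cell editing profiles with coverage-based inclusion filters.

A cell's *haplotype profile* counts phased reads over the ``2^k`` edit
states and expresses each protein variant as a percent of the phased reads
(variant reads divided by total evaluable reads for that cell).  A cell is
excluded from downstream summaries when any site of interest has fewer than
``min_reads`` evaluable reads (default 10).  Site-level profiles report the
per-site edit fraction with per-site denominators, which also serves
independent (non-phased) site sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .extraction import CALL_EDITED, CALL_REF, ReadCall
from .sites import EditSiteSet, EditState

__all__ = [
    "QC_PASS",
    "QC_EXCLUDED",
    "CellProfile",
    "SiteLevelProfile",
    "profile_cell",
    "site_profile_cell",
    "fully_edited_fraction",
    "profiles_to_frame",
    "site_profiles_to_frame",
]

QC_PASS = "pass"
QC_EXCLUDED = "excluded_low_coverage"


@dataclass(frozen=True)
class CellProfile:
    """Haplotype counts and variant percentages for one cell.

    ``variant_percent`` covers every enumerated variant (zeros included) and
    sums to 100 whenever ``n_phased_reads > 0``.  ``per_site_coverage``
    counts reads evaluable (A or G call) at each site, the quantity the
    ``min_reads`` filter is applied to.
    """

    cell_id: str
    site_ids: tuple[str, ...]
    n_phased_reads: int
    haplotype_counts: Mapping[EditState, int]
    variant_percent: Mapping[str, float]
    per_site_coverage: Mapping[str, int]
    qc: str

    def site_edit_percent(self, site_id: str) -> float:
        """Marginal edit percent at one site, over the phased reads."""
        if self.n_phased_reads == 0:
            return math.nan
        idx = self.site_ids.index(site_id)
        edited = sum(n for state, n in self.haplotype_counts.items() if state[idx])
        return 100.0 * edited / self.n_phased_reads


@dataclass(frozen=True)
class SiteLevelProfile:
    """Per-site edit percentages for one cell, with per-site denominators."""

    cell_id: str
    site_ids: tuple[str, ...]
    edit_percent: Mapping[str, float]      # NaN when no evaluable reads
    n_evaluable: Mapping[str, int]         # ref + edited calls at the site
    site_qc: Mapping[str, str]             # QC_PASS / QC_EXCLUDED per site

    @property
    def qc(self) -> str:
        return QC_PASS if all(v == QC_PASS for v in self.site_qc.values()) else QC_EXCLUDED


def _single_cell_id(calls: Sequence[ReadCall], cell_id: str | None) -> str:
    ids = {c.cell_id for c in calls}
    if len(ids) > 1:
        raise ValueError(f"calls span multiple cells: {sorted(ids)}")
    if ids:
        found = ids.pop()
        if cell_id is not None and cell_id != found:
            raise ValueError(f"cell_id {cell_id!r} does not match calls ({found!r})")
        return found
    if cell_id is None:
        raise ValueError("empty call list needs an explicit cell_id")
    return cell_id


def profile_cell(
    calls: Sequence[ReadCall],
    sites: EditSiteSet,
    min_reads: int = 10,
    cell_id: str | None = None,
) -> CellProfile:
    """Build one cell's haplotype profile from its read calls.

    Only reads whose every site call is ref or edited enter the haplotype
    counts and the percentage denominator; reads carrying an off-model base
    at any site are removed entirely so sequencing errors cannot create
    phantom haplotypes.  The cell is flagged ``excluded_low_coverage`` when
    any site has fewer than ``min_reads`` evaluable reads.
    """
    cell = _single_cell_id(calls, cell_id)
    states = sites.states()
    recoding = sites.recoding()
    variants = sites.variant_names()

    counts: dict[EditState, int] = {s: 0 for s in states}
    coverage = {sid: 0 for sid in sites.site_ids}
    n_phased = 0
    for rc in calls:
        if len(rc.calls) != sites.k:
            raise ValueError(
                f"read {rc.read_id!r}: {len(rc.calls)} calls for {sites.k} sites"
            )
        for sid, c in zip(sites.site_ids, rc.calls):
            if c in (CALL_REF, CALL_EDITED):
                coverage[sid] += 1
        if rc.is_evaluable():
            counts[rc.edit_state()] += 1
            n_phased += 1

    percent = {v: 0.0 for v in variants}
    if n_phased > 0:
        for state, n in counts.items():
            percent[recoding[state]] += 100.0 * n / n_phased

    qc = QC_PASS if all(coverage[sid] >= min_reads for sid in sites.site_ids) else QC_EXCLUDED
    return CellProfile(
        cell_id=cell,
        site_ids=sites.site_ids,
        n_phased_reads=n_phased,
        haplotype_counts=counts,
        variant_percent=percent,
        per_site_coverage=coverage,
        qc=qc,
    )


def site_profile_cell(
    calls: Sequence[ReadCall],
    sites: EditSiteSet,
    min_reads: int = 10,
    cell_id: str | None = None,
) -> SiteLevelProfile:
    """Per-site edit fractions for one cell.

    Each site's denominator is its own evaluable-read count (ref + edited
    calls); ``other`` and ``uncovered`` calls are excluded.  Sites with fewer
    than ``min_reads`` evaluable reads are flagged excluded individually.
    """
    cell = _single_cell_id(calls, cell_id)
    edited = {sid: 0 for sid in sites.site_ids}
    evaluable = {sid: 0 for sid in sites.site_ids}
    for rc in calls:
        if len(rc.calls) != sites.k:
            raise ValueError(
                f"read {rc.read_id!r}: {len(rc.calls)} calls for {sites.k} sites"
            )
        for sid, c in zip(sites.site_ids, rc.calls):
            if c == CALL_EDITED:
                edited[sid] += 1
                evaluable[sid] += 1
            elif c == CALL_REF:
                evaluable[sid] += 1

    percent = {
        sid: (100.0 * edited[sid] / evaluable[sid]) if evaluable[sid] else math.nan
        for sid in sites.site_ids
    }
    qc = {
        sid: (QC_PASS if evaluable[sid] >= min_reads else QC_EXCLUDED)
        for sid in sites.site_ids
    }
    return SiteLevelProfile(
        cell_id=cell,
        site_ids=sites.site_ids,
        edit_percent=percent,
        n_evaluable=evaluable,
        site_qc=qc,
    )


def fully_edited_fraction(profiles: Sequence[CellProfile], site_id: str) -> float:
    """Percent of cells whose marginal edit fraction at ``site_id`` is 100%.

    Expects QC-pass profiles; raises on empty input (the fraction is
    undefined with no cells).
    """
    if not profiles:
        raise ValueError("fully_edited_fraction is undefined for zero cells")
    full = sum(1 for p in profiles if p.site_edit_percent(site_id) == 100.0)
    return 100.0 * full / len(profiles)


def profiles_to_frame(profiles: Sequence[CellProfile]) -> pd.DataFrame:
    """One row per cell: qc, phased-read count, one column per variant percent."""
    rows = []
    for p in profiles:
        row = {"cell_id": p.cell_id, "qc": p.qc, "n_phased_reads": p.n_phased_reads}
        row.update(p.variant_percent)
        rows.append(row)
    return pd.DataFrame(rows)


def site_profiles_to_frame(profiles: Sequence[SiteLevelProfile]) -> pd.DataFrame:
    """One row per cell with per-site edit percent and evaluable-read columns."""
    rows = []
    for p in profiles:
        row: dict = {"cell_id": p.cell_id, "qc": p.qc}
        for sid in p.site_ids:
            row[f"{sid}_percent"] = p.edit_percent[sid]
            row[f"{sid}_n"] = p.n_evaluable[sid]
        rows.append(row)
    return pd.DataFrame(rows)
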