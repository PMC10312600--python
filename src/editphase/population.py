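"""Population-level summaries of single-cell editing profiles.

Aggregates per-cell variant percentages into per-group means ± SEM,
expressing-cell fractions (cells with any reads of a variant), conditional
means among expressing cells, and the sorted stacked-profile matrix used to
display one bar per neuron.  Also provides the cross-gene single-base
comparison with its joint coverage filter.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .profiles import QC_PASS, CellProfile, SiteLevelProfile
from .sites import EditSiteSet

__all__ = [
    "PopulationSummary",
    "summarize",
    "build_profile_matrix",
    "crossgene_compare",
    "summary_to_frame",
]


@dataclass(frozen=True)
class PopulationSummary:
    """Per-variant statistics for one cell group (e.g. Ib or Is motoneurons)."""

    group: str
    n_pass: int
    n_excluded: int
    variant_mean: Mapping[str, float]          # mean percent across pass cells
    variant_sem: Mapping[str, float]           # sample SD / sqrt(n); NaN if n < 2
    expressing_fraction: Mapping[str, float]   # cells with percent > threshold, in [0, 1]
    conditional_mean: Mapping[str, float]      # mean percent among expressing cells
    any_editing_fraction: float                # cells with unedited percent < 100, in [0, 1]


def _sem(values: np.ndarray) -> float:
    if len(values) < 2:
        return math.nan
    return float(np.std(values, ddof=1) / math.sqrt(len(values)))


def summarize(
    profiles: Sequence[CellProfile],
    groups: Mapping[str, str],
    sites: EditSiteSet,
    expressing_threshold: float = 0.0,
) -> dict[str, PopulationSummary]:
    """Aggregate QC-pass profiles into per-group population summaries.

    ``groups`` maps cell_id to a group label (from cell metadata, never
    inferred).  A variant counts as *expressed* in a cell when its percent is
    strictly above ``expressing_threshold`` (default 0: one phased read
    suffices).  Groups with no passing cells are omitted with a warning.
    """
    variants = sites.variant_names()
    unedited = sites.unedited_variant()
    by_group: dict[str, list[CellProfile]] = {}
    excluded: dict[str, int] = {}
    for p in profiles:
        try:
            g = groups[p.cell_id]
        except KeyError:
            raise KeyError(f"cell {p.cell_id!r} missing from group metadata") from None
        if p.qc == QC_PASS:
            by_group.setdefault(g, []).append(p)
        else:
            excluded[g] = excluded.get(g, 0) + 1

    out: dict[str, PopulationSummary] = {}
    for g in sorted(set(by_group) | set(excluded)):
        cells = by_group.get(g, [])
        if not cells:
            warnings.warn(f"group {g!r}: no QC-pass cells, omitted from summary")
            continue
        mat = np.array([[p.variant_percent[v] for v in variants] for p in cells])
        mean = {v: float(mat[:, j].mean()) for j, v in enumerate(variants)}
        sem = {v: _sem(mat[:, j]) for j, v in enumerate(variants)}
        expressing = {
            v: float((mat[:, j] > expressing_threshold).mean())
            for j, v in enumerate(variants)
        }
        conditional = {}
        for j, v in enumerate(variants):
            expr = mat[:, j][mat[:, j] > expressing_threshold]
            conditional[v] = float(expr.mean()) if len(expr) else math.nan
        any_edit = float(
            np.mean([p.variant_percent[unedited] < 100.0 for p in cells])
        )
        out[g] = PopulationSummary(
            group=g,
            n_pass=len(cells),
            n_excluded=excluded.get(g, 0),
            variant_mean=mean,
            variant_sem=sem,
            expressing_fraction=expressing,
            conditional_mean=conditional,
            any_editing_fraction=any_edit,
        )
    return out


def build_profile_matrix(
    profiles: Sequence[CellProfile],
    groups: Mapping[str, str],
    sites: EditSiteSet,
) -> pd.DataFrame:
    """Cells × variants percent matrix for stacked-bar display.

    Rows are QC-pass cells, indexed by (group, cell_id); groups are
    concatenated in sorted label order and, within each group, cells are
    sorted by descending unedited percent with ties broken by cell_id.  Every
    row sums to 100.
    """
    unedited = sites.unedited_variant()
    variants = sites.variant_names()
    rows = []
    for p in profiles:
        if p.qc != QC_PASS:
            continue
        rows.append(
            {
                "group": groups[p.cell_id],
                "cell_id": p.cell_id,
                **{v: p.variant_percent[v] for v in variants},
            }
        )
    frame = pd.DataFrame(rows, columns=["group", "cell_id", *variants])
    frame = frame.sort_values(
        by=["group", unedited, "cell_id"], ascending=[True, False, True]
    )
    return frame.set_index(["group", "cell_id"])


def crossgene_compare(
    site_profiles: Mapping[str, Sequence[SiteLevelProfile]],
    min_reads: int = 10,
) -> pd.DataFrame:
    """Per-cell edit percentages at every configured base across genes.

    ``site_profiles`` maps gene name to that gene's per-cell site-level
    profiles.  A cell is included only when *every* base of interest, across
    all genes, has at least ``min_reads`` evaluable reads (the joint filter);
    cells missing a gene entirely are excluded.  Columns are site ids in the
    given gene order; values are edit percents.
    """
    per_gene: dict[str, dict[str, SiteLevelProfile]] = {}
    columns: list[str] = []
    for gene, profs in site_profiles.items():
        indexed: dict[str, SiteLevelProfile] = {}
        for p in profs:
            if p.cell_id in indexed:
                raise ValueError(f"gene {gene!r}: duplicate profile for cell {p.cell_id!r}")
            indexed[p.cell_id] = p
        per_gene[gene] = indexed
        first = next(iter(indexed.values()), None)
        if first is not None:
            columns.extend(first.site_ids)

    shared = set.intersection(*(set(d) for d in per_gene.values())) if per_gene else set()
    rows = []
    for cell in sorted(shared):
        values: dict[str, float] = {}
        ok = True
        for gene, indexed in per_gene.items():
            prof = indexed[cell]
            for sid in prof.site_ids:
                if prof.n_evaluable[sid] < min_reads:
                    ok = False
                values[sid] = prof.edit_percent[sid]
        if ok:
            rows.append({"cell_id": cell, **values})

    frame = pd.DataFrame(rows, columns=["cell_id", *columns])
    if frame.empty:
        warnings.warn("no cell passes the joint cross-gene coverage filter")
    return frame.set_index("cell_id")


def summary_to_frame(summaries: Mapping[str, PopulationSummary]) -> pd.DataFrame:
    """Long-format table of per-group, per-variant summary statistics."""
    rows = []
    for g, s in summaries.items():
        for v in s.variant_mean:
            rows.append(
                {
                    "group": g,
                    "variant": v,
                    "n_pass": s.n_pass,
                    "mean_percent": s.variant_mean[v],
                    "sem_percent": s.variant_sem[v],
                    "expressing_fraction": s.expressing_fraction[v],
                    "conditional_mean_percent": s.conditional_mean[v],
                }
            )
    return pd.DataFrame(rows)
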