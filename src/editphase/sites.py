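"""Edit-site models and combinatorial codon recoding.

A-to-I editing deaminates adenosines in double-stranded RNA; the resulting
inosine pairs like guanosine, so an edited site appears as an A→G change on
the mRNA sense strand.  This module describes a gene's editable adenosines
(an :class:`EditSiteSet`), the joint edited/unedited state of those sites on
one transcript (an edit state, or haplotype), and the deterministic mapping
from each of the ``2^k`` states to a protein-variant name such as
``"I125M,N130S"``.

Site sets are *phased* when all sites must be observed together on one
continuous read (e.g. the three complexin exon-7A adenosines at transcript
positions 375/388/389), or *independent* when each site is quantified on its
own (e.g. the syntaxin-1A M244V site).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml
from Bio.Seq import Seq

__all__ = [
    "EditSite",
    "EditSiteSet",
    "EditState",
    "SiteConfigError",
    "load_site_config",
    "builtin_config_path",
    "load_builtin_config",
    "recode",
    "enumerate_variants",
]

#: Edit state of a phasing group: one boolean per site, True = edited (read as G).
EditState = tuple[bool, ...]

PHASED = "phased"
INDEPENDENT = "independent"


class SiteConfigError(ValueError):
    """Raised for malformed or internally inconsistent site configurations."""


@dataclass(frozen=True)
class EditSite:
    """One editable adenosine on the mRNA sense strand.

    ``transcript_pos`` is 1-based in the coding mRNA; ``genomic_start`` is
    the 0-based position of the base on ``contig`` (half-open convention:
    the site occupies ``[genomic_start, genomic_start + 1)``).
    """

    site_id: str
    gene: str
    transcript_pos: int
    codon_index: int
    codon_offset: int
    strand: str = "+"
    contig: str | None = None
    genomic_start: int | None = None
    ref_base: str = "A"

    def __post_init__(self) -> None:
        if self.ref_base != "A":
            raise SiteConfigError(
                f"site {self.site_id!r}: ref_base must be 'A' for A-to-I sites, "
                f"got {self.ref_base!r}"
            )
        if self.strand not in ("+", "-"):
            raise SiteConfigError(f"site {self.site_id!r}: strand must be '+' or '-'")
        if self.codon_offset not in (1, 2, 3):
            raise SiteConfigError(
                f"site {self.site_id!r}: codon_offset must be 1, 2 or 3"
            )
        expected = (self.codon_index - 1) * 3 + self.codon_offset
        if self.transcript_pos != expected:
            raise SiteConfigError(
                f"site {self.site_id!r}: transcript_pos {self.transcript_pos} "
                f"contradicts codon {self.codon_index} offset {self.codon_offset} "
                f"(expected {expected})"
            )


@dataclass(frozen=True)
class EditSiteSet:
    """Ordered editable adenosines of one gene with their codon context.

    ``ref_codons`` maps codon index (1-based amino-acid number) to the
    reference codon string; every codon containing a site must be present
    and must carry an ``A`` at each site's offset.
    """

    gene: str
    sites: tuple[EditSite, ...]
    ref_codons: Mapping[int, str]
    phasing: str = PHASED

    def __post_init__(self) -> None:
        if not self.sites:
            raise SiteConfigError(f"gene {self.gene!r}: empty site set")
        if self.phasing not in (PHASED, INDEPENDENT):
            raise SiteConfigError(
                f"gene {self.gene!r}: phasing must be {PHASED!r} or {INDEPENDENT!r}"
            )
        pos = [s.transcript_pos for s in self.sites]
        if pos != sorted(pos) or len(set(pos)) != len(pos):
            raise SiteConfigError(
                f"gene {self.gene!r}: sites must be sorted by transcript_pos "
                "with no duplicates"
            )
        for s in self.sites:
            if s.gene != self.gene:
                raise SiteConfigError(
                    f"site {s.site_id!r} belongs to {s.gene!r}, not {self.gene!r}"
                )
            codon = self.ref_codons.get(s.codon_index)
            if codon is None:
                raise SiteConfigError(
                    f"site {s.site_id!r}: no reference codon for index {s.codon_index}"
                )
            if len(codon) != 3 or set(codon) - set("ACGT"):
                raise SiteConfigError(
                    f"codon {s.codon_index}: invalid reference codon {codon!r}"
                )
            if codon[s.codon_offset - 1] != "A":
                raise SiteConfigError(
                    f"site {s.site_id!r}: reference codon {codon} has "
                    f"{codon[s.codon_offset - 1]!r}, not 'A', at offset {s.codon_offset}"
                )

    # -- derived structure -------------------------------------------------

    @property
    def k(self) -> int:
        """Number of sites."""
        return len(self.sites)

    @property
    def site_ids(self) -> tuple[str, ...]:
        return tuple(s.site_id for s in self.sites)

    def states(self) -> list[EditState]:
        """All ``2^k`` edit states in binary order (first site most significant)."""
        return list(itertools.product((False, True), repeat=self.k))

    def recode(self, state: EditState) -> str:
        """Protein-variant name for one edit state (see :func:`recode`)."""
        return recode(state, self)

    def recoding(self) -> dict[EditState, str]:
        """Map every edit state to its variant name."""
        return {state: self.recode(state) for state in self.states()}

    def variant_names(self) -> list[str]:
        """Distinct variant names in binary state order (see :func:`enumerate_variants`)."""
        return enumerate_variants(self)

    def unedited_variant(self) -> str:
        """Name of the fully unedited variant."""
        return self.recode((False,) * self.k)

    def index_of(self, site_id: str) -> int:
        for i, s in enumerate(self.sites):
            if s.site_id == site_id:
                return i
        raise KeyError(f"no site {site_id!r} in gene {self.gene!r}")


def recode(state: Sequence[bool], sites: EditSiteSet) -> str:
    """Translate one edit state into a protein-variant name.

    Each edited position substitutes G into its reference codon; codons are
    translated with the standard nuclear genetic code.  Residues touched by
    the site set are rendered as ``<ref><index>`` when unchanged (``"N130"``)
    and ``<ref><index><new>`` when recoded (``"N130S"``); codon labels are
    joined in codon order, e.g. ``"I125M,N130S"``.
    """
    state = tuple(bool(b) for b in state)
    if len(state) != sites.k:
        raise ValueError(
            f"edit state has length {len(state)}, site set has {sites.k} sites"
        )
    by_codon: dict[int, list[tuple[int, bool]]] = {}
    for site, edited in zip(sites.sites, state):
        by_codon.setdefault(site.codon_index, []).append((site.codon_offset, edited))

    labels = []
    for codon_index in sorted(by_codon):
        ref = sites.ref_codons[codon_index]
        bases = list(ref)
        for offset, edited in by_codon[codon_index]:
            if edited:
                bases[offset - 1] = "G"
        aa_ref = str(Seq(ref).translate())
        aa_new = str(Seq("".join(bases)).translate())
        label = f"{aa_ref}{codon_index}"
        if aa_new != aa_ref:
            label += aa_new
        labels.append(label)
    return ",".join(labels)


def enumerate_variants(sites: EditSiteSet) -> list[str]:
    """All distinct protein variants reachable by editing, in binary state order.

    States that translate to the same protein (synonymous edits) collapse to
    one name, so the result can be shorter than ``2^k``.
    """
    seen: list[str] = []
    for state in sites.states():
        name = recode(state, sites)
        if name not in seen:
            seen.append(name)
    return seen


# -- configuration files ---------------------------------------------------

_TSV_REQUIRED = [
    "site_id",
    "gene",
    "transcript_pos",
    "strand",
    "codon_index",
    "codon_offset",
    "ref_codon",
]


def load_site_config(path: str | Path) -> EditSiteSet:
    """Load a per-gene site configuration from TSV, JSON or YAML.

    The TSV layout has one row per site with columns ``site_id, gene,
    transcript_pos, contig, genomic_start, strand, codon_index, codon_offset,
    ref_codon, phasing``.  ``genomic_start`` (0-based) defaults to
    ``transcript_pos - 1``, i.e. transcript coordinates on a synthetic
    transcript-as-contig reference.  JSON/YAML files carry the equivalent
    mapping ``{gene, phasing, sites: [...]}``.
    """
    path = Path(path)
    if not path.exists():
        raise SiteConfigError(f"site config not found: {path}")
    if path.suffix.lower() in (".json", ".yaml", ".yml"):
        with open(path) as fh:
            doc = json.load(fh) if path.suffix.lower() == ".json" else yaml.safe_load(fh)
        return _siteset_from_mapping(doc, source=str(path))
    return _siteset_from_table(pd.read_csv(path, sep="\t", dtype=str), source=str(path))


def _siteset_from_mapping(doc: Mapping, source: str) -> EditSiteSet:
    try:
        rows = doc["sites"]
        gene = doc["gene"]
    except (TypeError, KeyError) as exc:
        raise SiteConfigError(f"{source}: expected keys 'gene' and 'sites'") from exc
    frame = pd.DataFrame(rows).astype(str)
    frame["gene"] = gene
    frame["phasing"] = str(doc.get("phasing", PHASED))
    return _siteset_from_table(frame, source=source)


def _siteset_from_table(frame: pd.DataFrame, source: str) -> EditSiteSet:
    missing = [c for c in _TSV_REQUIRED if c not in frame.columns]
    if missing:
        raise SiteConfigError(f"{source}: missing required columns {missing}")
    genes = frame["gene"].unique()
    if len(genes) != 1:
        raise SiteConfigError(
            f"{source}: configs are per-gene, found genes {sorted(genes)}"
        )
    phasing_vals = (
        frame["phasing"].unique() if "phasing" in frame.columns else [PHASED]
    )
    if len(phasing_vals) != 1:
        raise SiteConfigError(f"{source}: inconsistent phasing flags {list(phasing_vals)}")

    sites: list[EditSite] = []
    ref_codons: dict[int, str] = {}
    for i, row in frame.iterrows():
        try:
            codon_index = int(row["codon_index"])
            codon = str(row["ref_codon"]).upper()
            contig = row.get("contig")
            contig = None if pd.isna(contig) or contig == "" else str(contig)
            gstart = row.get("genomic_start")
            if pd.isna(gstart) or gstart == "":
                gstart = int(row["transcript_pos"]) - 1
            site = EditSite(
                site_id=str(row["site_id"]),
                gene=str(row["gene"]),
                transcript_pos=int(row["transcript_pos"]),
                codon_index=codon_index,
                codon_offset=int(row["codon_offset"]),
                strand=str(row["strand"]),
                contig=contig,
                genomic_start=int(gstart),
            )
        except (ValueError, SiteConfigError) as exc:
            raise SiteConfigError(f"{source}, row {i} ({row.get('site_id')}): {exc}") from exc
        if codon_index in ref_codons and ref_codons[codon_index] != codon:
            raise SiteConfigError(
                f"{source}, row {i}: conflicting reference codons for index {codon_index}"
            )
        ref_codons[codon_index] = codon
        sites.append(site)

    sites.sort(key=lambda s: s.transcript_pos)
    try:
        return EditSiteSet(
            gene=str(genes[0]),
            sites=tuple(sites),
            ref_codons=ref_codons,
            phasing=str(phasing_vals[0]),
        )
    except SiteConfigError as exc:
        raise SiteConfigError(f"{source}: {exc}") from exc


def builtin_config_path(name: str) -> Path:
    """Path to a shipped site configuration (``"cpx7A"``, ``"syn"`` or ``"syx1a"``)."""
    ref = resources.files("editphase.data").joinpath(f"{name}.tsv")
    with resources.as_file(ref) as p:
        path = Path(p)
    if not path.exists():
        raise SiteConfigError(f"no builtin site config named {name!r}")
    return path


def load_builtin_config(name: str) -> EditSiteSet:
    """Load a shipped site configuration by name."""
    return load_site_config(builtin_config_path(name))
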