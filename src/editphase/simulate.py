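"""Synthetic Patch-seq-like read generator with full ground truth.

Emulates deep full-length single-cell RNA sequencing of motoneurons over the
complexin exon-7A editing region: each cell draws an editing propensity for
the upstream adenosine (transcript position 375) from a mixture spanning 0
to 100% (including fully unedited and fully edited cells), and per-read
editing of the two downstream adenosines (388/389) is conditional on the
375 state — editing 375 strongly enables the downstream edits, the linkage
that makes double-edit variants far more common than lone N130 changes.
ADAR abundance (TPM) is drawn log-normally and, by default, independently
of editing.

Reads are emitted pre-aligned over a synthetic reference in which transcript
coordinates equal contig coordinates, as one coordinate-sorted SAM with a
per-read cell tag, alongside the reference FASTA, a per-cell expression
table and a truth table carrying every generative parameter and the expected
and realized haplotype fractions, so each downstream estimate can be scored
exactly.
"""

from __future__ import annotations

import dataclasses
import json
import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .sites import EditSiteSet, SiteConfigError, load_builtin_config

__all__ = [
    "BetaSpec",
    "MixtureSpec",
    "SimConfig",
    "CrossGeneConfig",
    "SimResult",
    "build_reference",
    "simulate_cohort",
    "simulate_crossgene",
    "sample_editing_expression_pairs",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class BetaSpec:
    """Beta(a, b) distribution for a per-cell probability."""

    a: float
    b: float

    def draw(self, rng: np.random.Generator, size=None):
        return rng.beta(self.a, self.b, size=size)

    @property
    def mean(self) -> float:
        return self.a / (self.a + self.b)


@dataclass(frozen=True)
class MixtureSpec:
    """Point masses at 0 and 1 plus a Beta body for a per-cell probability.

    Spans the full 0–100% range, including fully unedited cells (weight
    ``w_zero``) and cells that edit every transcript (weight ``w_one``).
    """

    w_zero: float = 0.05
    w_one: float = 0.03
    a: float = 1.2
    b: float = 2.6

    def __post_init__(self) -> None:
        if not (0 <= self.w_zero <= 1 and 0 <= self.w_one <= 1):
            raise ValueError("mixture weights must lie in [0, 1]")
        if self.w_zero + self.w_one > 1:
            raise ValueError("mixture weights sum above 1")

    def draw(self, rng: np.random.Generator) -> float:
        u = rng.random()
        if u < self.w_zero:
            return 0.0
        if u < self.w_zero + self.w_one:
            return 1.0
        return float(rng.beta(self.a, self.b))

    @property
    def mean(self) -> float:
        body = 1.0 - self.w_zero - self.w_one
        return self.w_one + body * self.a / (self.a + self.b)


@dataclass
class SimConfig:
    """Study conditions for a simulated editing cohort.

    Defaults emulate the observed cohort structure: two motoneuron classes
    of ~100 cells, deep per-cell coverage of the edited exon, a 375-editing
    propensity averaging ≈ 30% with both fully unedited and fully edited
    cells, and conditional downstream edit rates an order of magnitude
    higher on 375-edited transcripts than on unedited ones.
    """

    n_cells: Mapping[str, int] = field(default_factory=lambda: {"Ib": 100, "Is": 100})
    reads_per_cell_mean: float = 500.0
    reads_per_cell_shape: float = 10.0   # negative-binomial shape; larger = tighter
    p375: MixtureSpec = field(default_factory=MixtureSpec)
    q388_edited: BetaSpec = field(default_factory=lambda: BetaSpec(1.0, 10.0))
    q389_edited: BetaSpec = field(default_factory=lambda: BetaSpec(1.5, 3.7))
    q388_unedited: float = 0.005
    q389_unedited: float = 0.03
    seq_error: float = 0.001
    read_length: int = 150
    truncated_fraction: float = 0.1      # reads placed to fail the phasing rule
    tpm_log_mean: float = math.log(50.0)
    tpm_log_sd: float = 0.6
    tpm_coupling: float = 0.0            # 0 = editing independent of ADAR TPM
    adar_gene: str = "Adar"
    seed: int = 0
    write_read_truth: bool = False

    def __post_init__(self) -> None:
        for name in ("q388_unedited", "q389_unedited", "seq_error", "truncated_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.reads_per_cell_mean <= 0 or self.reads_per_cell_shape <= 0:
            raise ValueError("read-count parameters must be positive")
        if self.read_length < 1:
            raise ValueError("read_length must be positive")


@dataclass
class CrossGeneConfig:
    """Conditions for the cross-gene single-base comparison cohort.

    Each gene's sites are edited independently per read, with heterogeneous
    per-cell rates spanning 0–100%; defaults give synapsin sites a broad
    high-variance rate distribution and the syntaxin-1A site a low one.
    """

    n_cells: Mapping[str, int] = field(default_factory=lambda: {"Ib": 20, "Is": 20})
    reads_per_cell_mean: float = 100.0
    reads_per_cell_shape: float = 5.0
    site_rates: Mapping[str, BetaSpec] = field(
        default_factory=lambda: {
            "syn_43": BetaSpec(0.7, 0.7),
            "syn_55": BetaSpec(0.7, 0.7),
            "syn_58": BetaSpec(0.7, 0.7),
            "syx1a_730": BetaSpec(0.25, 4.75),
        }
    )
    seq_error: float = 0.001
    read_length: int = 150
    seed: int = 0


@dataclass
class SimResult:
    """File paths and in-memory truth for one simulated cohort."""

    alignment_path: Path
    reference_path: Path
    truth_path: Path
    truth: pd.DataFrame
    expression_path: Path | None = None
    config_path: Path | None = None
    read_truth_path: Path | None = None


# -- reference construction -------------------------------------------------


def _contig_length(sites: EditSiteSet, read_length: int) -> int:
    return max(s.genomic_start for s in sites.sites) + read_length + 60


def build_reference(
    site_sets: Sequence[EditSiteSet], read_length: int = 150
) -> dict[str, str]:
    """Synthetic contig sequences carrying each gene's codon context.

    Background sequence is deterministic per contig name; the reference
    codons are written in at the coordinates implied by each site, so the
    sense strand carries an A at every editable position.
    """
    contigs: dict[str, np.ndarray] = {}
    for sites in site_sets:
        contig = sites.sites[0].contig
        if contig is None:
            raise SiteConfigError(f"gene {sites.gene!r}: sites carry no contig")
        length = _contig_length(sites, read_length)
        rng = np.random.default_rng(zlib.crc32(contig.encode()))
        seq = _BASES[rng.integers(0, 4, size=length)].copy()
        for site in sites.sites:
            codon = sites.ref_codons[site.codon_index]
            start = site.genomic_start - (site.codon_offset - 1)
            for j, base in enumerate(codon):
                b = base.encode()
                if site.strand == "-":
                    b = {b"A": b"T", b"C": b"G", b"G": b"C", b"T": b"A"}[b]
                seq[start + j] = np.frombuffer(b, dtype="S1")[0]
        prev = contigs.get(contig)
        if prev is not None and len(prev) >= len(seq):
            continue
        contigs[contig] = seq
    return {name: arr.tobytes().decode() for name, arr in contigs.items()}


def _write_fasta(contigs: Mapping[str, str], path: Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(contigs):
            fh.write(f">{name}\n")
            seq = contigs[name]
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


# -- read emission ----------------------------------------------------------


def _read_windows(sites: EditSiteSet, read_length: int, contig_len: int):
    """Start windows (inclusive) for phasing-passing and phasing-failing reads."""
    pos = [s.genomic_start for s in sites.sites]
    lo, hi = min(pos), max(pos)
    full = (max(0, hi - read_length + 1), lo)
    if full[0] > full[1]:
        raise SiteConfigError(
            f"gene {sites.gene!r}: read_length {read_length} cannot span sites "
            f"{lo}..{hi}"
        )
    # cover the first site but end before the last one
    trunc = (max(0, lo - read_length + 1), hi - read_length)
    if trunc[0] > trunc[1]:
        # fall back to reads that miss every site
        trunc = (hi + 1, contig_len - read_length)
        if trunc[0] > trunc[1]:
            trunc = None
    return full, trunc


def _emit_cell_reads(
    rng: np.random.Generator,
    ref: np.ndarray,
    sites: EditSiteSet,
    edit_matrix: np.ndarray,   # (n_reads, k) booleans, intended edit states
    full_mask: np.ndarray,     # (n_reads,) True = spans all sites
    windows,
    read_length: int,
    seq_error: float,
    cell_id: str,
):
    """Materialise one cell's reads as (start, name, seq) records."""
    full_win, trunc_win = windows
    n = len(edit_matrix)
    starts = np.empty(n, dtype=int)
    n_full = int(full_mask.sum())
    starts[full_mask] = rng.integers(full_win[0], full_win[1] + 1, size=n_full)
    if n - n_full:
        if trunc_win is None:
            raise SiteConfigError(
                f"gene {sites.gene!r}: no placement exists for phasing-failing reads"
            )
        starts[~full_mask] = rng.integers(
            trunc_win[0], trunc_win[1] + 1, size=n - n_full
        )

    site_pos = np.array([s.genomic_start for s in sites.sites])
    minus = np.array([s.strand == "-" for s in sites.sites])
    records = []
    for j in range(n):
        start = int(starts[j])
        seq = ref[start : start + read_length].copy()
        for idx in np.nonzero(edit_matrix[j])[0]:
            p = site_pos[idx] - start
            if 0 <= p < read_length:
                seq[p] = b"C" if minus[idx] else b"G"
        if seq_error > 0:
            err = np.nonzero(rng.random(read_length) < seq_error)[0]
            if len(err):
                shift = rng.integers(1, 4, size=len(err))
                codes = np.searchsorted(_BASES, seq[err])
                seq[err] = _BASES[(codes + shift) % 4]
        records.append((start, f"{cell_id}_r{j:05d}", seq.tobytes().decode()))
    return records


def _write_sam(
    records: list[tuple[int, str, str, str, str]],
    contigs: Mapping[str, str],
    path: Path,
    read_length: int,
    cell_tag: str = "CB",
) -> None:
    """Write coordinate-sorted SAM; records are (start, name, seq, contig, cell)."""
    names = sorted(contigs)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": n, "LN": len(contigs[n])} for n in names],
    }
    tid = {n: i for i, n in enumerate(names)}
    records = sorted(records, key=lambda r: (tid[r[3]], r[0], r[1]))
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for start, name, seq, contig, cell in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = name
            a.query_sequence = seq
            a.flag = 0
            a.reference_id = tid[contig]
            a.reference_start = start
            a.mapping_quality = 60
            a.cigarstring = f"{len(seq)}M"
            a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            a.set_tag(cell_tag, cell)
            out.write(a)


# -- cohort simulation ------------------------------------------------------


def _expected_fractions(p: float, q388e: float, q389e: float,
                        q388u: float, q389u: float) -> dict[tuple[bool, bool, bool], float]:
    out = {}
    for e1 in (False, True):
        p1 = p if e1 else 1 - p
        q2 = q388e if e1 else q388u
        q3 = q389e if e1 else q389u
        for e2 in (False, True):
            p2 = q2 if e2 else 1 - q2
            for e3 in (False, True):
                p3 = q3 if e3 else 1 - q3
                out[(e1, e2, e3)] = p1 * p2 * p3
    return out


def _logit_shift(p: float, shift: float) -> float:
    if p <= 0.0 or p >= 1.0 or shift == 0.0:
        return p
    logit = math.log(p / (1 - p)) + shift
    return 1.0 / (1.0 + math.exp(-logit))


def simulate_cohort(
    config: SimConfig,
    outdir: str | Path,
    sites: EditSiteSet | None = None,
) -> SimResult:
    """Simulate a two-group editing cohort and write all pipeline inputs.

    Produces a coordinate-sorted SAM (cell tag ``CB``), the synthetic
    reference FASTA, an expression TSV (per-cell ADAR TPM), a JSON echo of
    the configuration, and a per-cell truth TSV with the generative
    parameters, the expected fractions of all eight edit haplotypes under
    the factorized linkage model, and the realized haplotype counts of the
    phasing-passing reads.  Identical seed and configuration give
    byte-identical outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sites = sites if sites is not None else load_builtin_config("cpx7A")
    if sites.k != 3:
        raise SiteConfigError("cohort simulation expects a 3-site phased group")

    contigs = build_reference([sites], config.read_length)
    contig = sites.sites[0].contig
    ref = np.frombuffer(contigs[contig].encode(), dtype="S1")
    windows = _read_windows(sites, config.read_length, len(ref))

    rng = np.random.default_rng(config.seed)
    nb_p = config.reads_per_cell_shape / (
        config.reads_per_cell_shape + config.reads_per_cell_mean
    )
    state_names = [sites.recode(s) for s in sites.states()]

    sam_records: list[tuple[int, str, str, str, str]] = []
    truth_rows = []
    expr_rows = []
    read_truth_rows = []
    for group in sorted(config.n_cells):
        for i in range(config.n_cells[group]):
            cell = f"{group}_{i:03d}"
            p = config.p375.draw(rng)
            q388e = max(float(config.q388_edited.draw(rng)), config.q388_unedited)
            q389e = max(float(config.q389_edited.draw(rng)), config.q389_unedited)
            tpm = float(rng.lognormal(config.tpm_log_mean, config.tpm_log_sd))
            if config.tpm_coupling != 0.0:
                z = (math.log(tpm) - config.tpm_log_mean) / config.tpm_log_sd
                p = _logit_shift(p, config.tpm_coupling * z)
            n_reads = int(rng.negative_binomial(config.reads_per_cell_shape, nb_p))

            e375 = rng.random(n_reads) < p
            q388 = np.where(e375, q388e, config.q388_unedited)
            q389 = np.where(e375, q389e, config.q389_unedited)
            e388 = rng.random(n_reads) < q388
            e389 = rng.random(n_reads) < q389
            edit_matrix = np.column_stack([e375, e388, e389]) if n_reads else np.zeros((0, 3), bool)
            full_mask = rng.random(n_reads) >= config.truncated_fraction

            recs = _emit_cell_reads(
                rng, ref, sites, edit_matrix, full_mask, windows,
                config.read_length, config.seq_error, cell,
            )
            sam_records.extend((s, n, q, contig, cell) for s, n, q in recs)

            expected = _expected_fractions(
                p, q388e, q389e, config.q388_unedited, config.q389_unedited
            )
            realized = {name: 0 for name in state_names}
            for j in np.nonzero(full_mask)[0]:
                realized[sites.recode(tuple(edit_matrix[j]))] += 1
            row = {
                "cell_id": cell,
                "group": group,
                "n_reads": n_reads,
                "n_full_reads": int(full_mask.sum()),
                "p375": p,
                "q388_edited": q388e,
                "q389_edited": q389e,
                "q388_unedited": config.q388_unedited,
                "q389_unedited": config.q389_unedited,
                "adar_tpm": tpm,
            }
            for state, name in zip(sites.states(), state_names):
                row[f"frac_{name}"] = expected[state]
            for name in dict.fromkeys(state_names):
                row[f"n_{name}"] = realized[name]
            truth_rows.append(row)
            expr_rows.append({"cell_id": cell, "gene": config.adar_gene, "tpm": tpm})
            if config.write_read_truth:
                for j, (_, rname, _) in enumerate(recs):
                    read_truth_rows.append(
                        {
                            "cell_id": cell,
                            "read_id": rname,
                            "e375": bool(edit_matrix[j, 0]),
                            "e388": bool(edit_matrix[j, 1]),
                            "e389": bool(edit_matrix[j, 2]),
                            "spans_all_sites": bool(full_mask[j]),
                        }
                    )

    fasta_path = outdir / "reference.fa"
    sam_path = outdir / "cohort.sam"
    truth_path = outdir / "truth.tsv"
    expr_path = outdir / "expression.tsv"
    config_path = outdir / "sim_config.json"
    _write_fasta(contigs, fasta_path)
    _write_sam(sam_records, contigs, sam_path, config.read_length)
    truth = pd.DataFrame(truth_rows)
    truth.to_csv(truth_path, sep="\t", index=False, float_format="%.10g")
    pd.DataFrame(expr_rows).to_csv(expr_path, sep="\t", index=False, float_format="%.10g")
    with open(config_path, "w") as fh:
        json.dump(dataclasses.asdict(config), fh, indent=2, default=str)

    read_truth_path = None
    if config.write_read_truth:
        read_truth_path = outdir / "read_truth.tsv"
        pd.DataFrame(read_truth_rows).to_csv(read_truth_path, sep="\t", index=False)

    return SimResult(
        alignment_path=sam_path,
        reference_path=fasta_path,
        truth_path=truth_path,
        truth=truth,
        expression_path=expr_path,
        config_path=config_path,
        read_truth_path=read_truth_path,
    )


def simulate_crossgene(
    config: CrossGeneConfig,
    outdir: str | Path,
    site_sets: Sequence[EditSiteSet] | None = None,
) -> SimResult:
    """Simulate independent-site editing for the cross-gene comparison.

    Default genes are synapsin (three independent sites) and syntaxin-1A
    (one site), written into one SAM over both synthetic contigs with the
    same cells covered for every gene.  Per-read site states are independent
    Bernoulli draws at each cell's per-site rate; the truth table records
    those rates and the realized per-site edited/covered read counts.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if site_sets is None:
        site_sets = [load_builtin_config("syn"), load_builtin_config("syx1a")]
    for ss in site_sets:
        for sid in ss.site_ids:
            if sid not in config.site_rates:
                raise ValueError(f"no rate distribution configured for site {sid!r}")

    contigs = build_reference(site_sets, config.read_length)
    refs = {
        name: np.frombuffer(seq.encode(), dtype="S1") for name, seq in contigs.items()
    }
    rng = np.random.default_rng(config.seed)
    nb_p = config.reads_per_cell_shape / (
        config.reads_per_cell_shape + config.reads_per_cell_mean
    )

    sam_records: list[tuple[int, str, str, str, str]] = []
    truth_rows = []
    for group in sorted(config.n_cells):
        for i in range(config.n_cells[group]):
            cell = f"{group}_{i:03d}"
            row: dict = {"cell_id": cell, "group": group}
            for ss in site_sets:
                contig = ss.sites[0].contig
                windows = _read_windows(ss, config.read_length, len(refs[contig]))
                rates = np.array(
                    [float(config.site_rates[sid].draw(rng)) for sid in ss.site_ids]
                )
                n_reads = int(rng.negative_binomial(config.reads_per_cell_shape, nb_p))
                edit_matrix = rng.random((n_reads, ss.k)) < rates
                full_mask = np.ones(n_reads, dtype=bool)
                recs = _emit_cell_reads(
                    rng, refs[contig], ss, edit_matrix, full_mask, windows,
                    config.read_length, config.seq_error, f"{cell}_{ss.gene}",
                )
                sam_records.extend((s, n, q, contig, cell) for s, n, q in recs)
                row[f"n_reads_{ss.gene}"] = n_reads
                for j, sid in enumerate(ss.site_ids):
                    row[f"rate_{sid}"] = rates[j]
                    row[f"n_edited_{sid}"] = int(edit_matrix[:, j].sum())
            truth_rows.append(row)

    fasta_path = outdir / "reference.fa"
    sam_path = outdir / "crossgene.sam"
    truth_path = outdir / "crossgene_truth.tsv"
    _write_fasta(contigs, fasta_path)
    _write_sam(sam_records, contigs, sam_path, config.read_length)
    truth = pd.DataFrame(truth_rows)
    truth.to_csv(truth_path, sep="\t", index=False, float_format="%.10g")
    return SimResult(
        alignment_path=sam_path,
        reference_path=fasta_path,
        truth_path=truth_path,
        truth=truth,
    )


def sample_editing_expression_pairs(
    config: SimConfig,
    n_cells: int,
    rng: np.random.Generator | int,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (ADAR TPM, site-375 edit percent) pairs without materialising reads.

    Uses the same per-cell generative model as :func:`simulate_cohort` —
    mixture-distributed editing propensity, negative-binomial read depth,
    binomial read sampling — but skips sequence emission, which makes
    replicate studies of the regression stage (e.g. confidence-interval
    calibration under the default independence of editing and TPM) cheap.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    nb_p = config.reads_per_cell_shape / (
        config.reads_per_cell_shape + config.reads_per_cell_mean
    )
    tpm = np.empty(n_cells)
    percent = np.empty(n_cells)
    for i in range(n_cells):
        p = config.p375.draw(rng)
        t = float(rng.lognormal(config.tpm_log_mean, config.tpm_log_sd))
        if config.tpm_coupling != 0.0:
            z = (math.log(t) - config.tpm_log_mean) / config.tpm_log_sd
            p = _logit_shift(p, config.tpm_coupling * z)
        n = max(int(rng.negative_binomial(config.reads_per_cell_shape, nb_p)), 1)
        percent[i] = 100.0 * rng.binomial(n, p) / n
        tpm[i] = t
    return tpm, percent
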