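"""Synthetic genomes with planted transcriptome architecture.

The generator emulates the data shapes of a growth-phase-dependent,
strand-specific bacterial RNA-seq experiment: genes tiled on both strands and
grouped into transcription units (operons), per-unit log-normal transcript
abundances, sharp 5' coverage steps at planted TSSs, covered intragenic gaps
within operons, leaderless genes (TSS exactly at the start codon),
deliberately mis-annotated start codons offset upstream by multiples of 3, a
TANNNT element planted 7-12 nt upstream of a configurable fraction of TSSs,
and multi-library coverage (three phases x two replicates by default) with
negative-binomial per-base noise over a small Poisson background.

Internal (sub-operon) TSSs are condition-dependent: a unit given an internal
TSS is transcribed from its primary TSS in all phases but the last, and only
from the internal TSS (a suffix transcript) in the last phase. This mirrors
stimulus-dependent independent transcription of internal genes and keeps the
planted structure self-consistent: the full unit is recoverable as one operon
(union of joins across phases) while the internal step is cleanly visible in
the phase where the upstream half is silent.

All randomness flows from a single integer seed through a spawned
``numpy.random.SeedSequence`` per consumer (layout, per-phase abundances, one
stream per library), so every artifact is reproducible byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .io_formats import (
    CoverageTrack,
    GeneModel,
    write_bedgraph,
    write_fasta,
    write_gff3,
    write_tsv,
)

#: Lower bound on per-unit mean depth (reads/base). Keeps every planted TSS
#: comfortably above the default calling threshold so that noiseless recovery
#: is a property of the method, not of lucky draws.
MIN_UNIT_DEPTH = 30.0

DEFAULT_LIBRARIES: tuple[tuple[str, int], ...] = (
    ("16h", 1),
    ("16h", 2),
    ("26h", 1),
    ("26h", 2),
    ("39h", 1),
    ("39h", 2),
)


@dataclass(frozen=True)
class GenomeParams:
    """Layout and architecture of the planted genome.

    Lengths/gaps in nt; fractions in [0, 1]. ``fraction_misannotated`` is a
    fraction of all genes (realized count is round(fraction * n_genes), drawn
    from unit-first genes, which carry the TSS evidence). Leaded 5'-UTRs are
    uniform over ``leaded_utr``; leaderless genes have UTR exactly 0.
    Mis-annotation offsets are 3k nt for k uniform over ``misannotation_k``.
    """

    gene_length: tuple[int, int] = (300, 900)
    intra_gap: tuple[int, int] = (5, 40)  # within a unit: covered by transcript
    inter_gap: tuple[int, int] = (150, 400)  # between units: background only
    operon_sizes: tuple[int, ...] = (1, 2, 3, 4)
    operon_size_probs: tuple[float, ...] = (0.55, 0.20, 0.15, 0.10)
    fraction_leaderless: float = 0.45
    fraction_misannotated: float = 0.07
    fraction_internal_tss: float = 0.30
    fraction_motif: float = 0.70
    leaded_utr: tuple[int, int] = (15, 80)
    misannotation_k: tuple[int, int] = (1, 8)
    start_codon_probs: tuple[float, float] = (0.7, 0.3)  # ATG, GTG
    abundance_mu: float = 4.0  # lognormal location of per-unit mean depth
    abundance_sigma: float = 0.6
    margin: int = 600
    genome_length: int | None = None  # error if the tiling does not fit


@dataclass(frozen=True)
class NoiseConfig:
    """Library-level stochasticity of the simulated coverage.

    ``noiseless`` replaces every random component with its mean and zeroes the
    background. Per-base noise is negative binomial with dispersion ``nb_size``
    (variance m + m^2/size) over a Poisson background of ``background_mean``.
    ``phase_sigma`` is the lognormal sigma of per-(unit, phase) abundance
    multipliers; ``taper`` linearly attenuates depth 5'->3' across a
    transcript (0 disables).
    """

    noiseless: bool = False
    background_mean: float = 0.1
    nb_size: float = 10.0
    phase_sigma: float = 0.4
    taper: float = 0.0
    read_length: int = 100


@dataclass
class SyntheticTruth:
    """Planted ground truth for every downstream stage."""

    genes: list[GeneModel]  # annotated models (mis-annotations included)
    true_tss: dict[str, int]  # gene_id -> planted TSS (primary + internal)
    operons: list[tuple[str, ...]]  # genomic order, one tuple per unit
    sub_operon_tss: dict[str, int]  # internal TSSs only
    leaderless_flags: dict[str, bool]  # over TSS-bearing genes
    misannotated: dict[str, tuple[int, int]]  # gene -> (annotated, true) cds_start
    abundance: dict[str, float]  # unit_id -> base mean depth (reads/base)
    unit_of_gene: dict[str, str]
    unit_strand: dict[str, str]
    unit_ids: list[str]
    true_cds_start: dict[str, int]
    genome_length: int
    seed: int


def _check_fraction(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {value}")


def generate_genome(
    n_genes: int, params: GenomeParams | None = None, seed: int = 0
) -> tuple[str, SyntheticTruth]:
    """Build a genome sequence and its planted truth. Deterministic per seed."""
    params = params or GenomeParams()
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    for name in ("fraction_leaderless", "fraction_misannotated", "fraction_internal_tss", "fraction_motif"):
        _check_fraction(name, getattr(params, name))

    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])

    # --- unit sizes (trimmed so the gene total is exact) ---
    sizes: list[int] = []
    while sum(sizes) < n_genes:
        sizes.append(int(rng.choice(params.operon_sizes, p=params.operon_size_probs)))
    sizes[-1] -= sum(sizes) - n_genes
    if sizes[-1] == 0:
        sizes.pop()

    unit_ids = [f"U{i + 1:04d}" for i in range(len(sizes))]
    unit_strands = {uid: ("+" if rng.random() < 0.5 else "-") for uid in unit_ids}

    # --- tile genes left to right ---
    gene_counter = 0
    cursor = params.margin + 1
    true_bounds: dict[str, tuple[int, int]] = {}
    unit_genes: dict[str, list[str]] = {}
    unit_of_gene: dict[str, str] = {}
    for uid, size in zip(unit_ids, sizes):
        members = []
        for j in range(size):
            gene_counter += 1
            gid = f"g{gene_counter:04d}"
            length = int(rng.integers(params.gene_length[0], params.gene_length[1] + 1))
            start, end = cursor, cursor + length - 1
            true_bounds[gid] = (start, end)
            members.append(gid)
            unit_of_gene[gid] = uid
            gap_rng = params.intra_gap if j < size - 1 else params.inter_gap
            cursor = end + 1 + int(rng.integers(gap_rng[0], gap_rng[1] + 1))
        unit_genes[uid] = members
    genome_length = cursor + params.margin
    if params.genome_length is not None:
        if params.genome_length < genome_length:
            raise ValueError(
                f"genome_length {params.genome_length} too short for the tiling "
                f"({genome_length} nt needed)"
            )
        genome_length = params.genome_length

    true_cds_start = {
        gid: (true_bounds[gid][0] if unit_strands[unit_of_gene[gid]] == "+" else true_bounds[gid][1])
        for gid in true_bounds
    }

    # --- TSS-bearing genes: unit-first genes plus internal-TSS genes ---
    firsts = {
        uid: (unit_genes[uid][0] if unit_strands[uid] == "+" else unit_genes[uid][-1])
        for uid in unit_ids
    }
    multi_units = [uid for uid in unit_ids if len(unit_genes[uid]) > 1]
    n_internal = int(round(params.fraction_internal_tss * len(multi_units)))
    internal_units = (
        list(rng.choice(multi_units, size=n_internal, replace=False)) if n_internal else []
    )
    internal_gene_of_unit: dict[str, str] = {}
    for uid in internal_units:
        non_first = [g for g in unit_genes[uid] if g != firsts[uid]]
        internal_gene_of_unit[uid] = str(rng.choice(non_first))

    tss_bearing = sorted(set(firsts.values()) | set(internal_gene_of_unit.values()))

    # --- mis-annotations: drawn from unit-first genes, exact count ---
    n_mis = int(round(params.fraction_misannotated * n_genes))
    first_pool = sorted(set(firsts.values()))
    if n_mis > len(first_pool):
        raise ValueError(
            f"fraction_misannotated={params.fraction_misannotated} asks for {n_mis} "
            f"mis-annotated genes but only {len(first_pool)} unit-first genes exist"
        )
    mis_genes = sorted(rng.choice(first_pool, size=n_mis, replace=False)) if n_mis else []

    # --- leaderless flags (mis-annotated genes are leaderless post-correction) ---
    n_lead = max(int(round(params.fraction_leaderless * len(tss_bearing))), len(mis_genes))
    leaderless = set(mis_genes)
    remaining = [g for g in tss_bearing if g not in leaderless]
    extra = n_lead - len(leaderless)
    if extra > 0 and remaining:
        leaderless |= set(rng.choice(remaining, size=min(extra, len(remaining)), replace=False))
    leaderless_flags = {g: (g in leaderless) for g in tss_bearing}

    # --- TSS positions ---
    true_tss: dict[str, int] = {}
    for gid in tss_bearing:
        strand = unit_strands[unit_of_gene[gid]]
        utr = 0 if leaderless_flags[gid] else int(
            rng.integers(params.leaded_utr[0], params.leaded_utr[1] + 1)
        )
        cds = true_cds_start[gid]
        true_tss[gid] = cds - utr if strand == "+" else cds + utr
    sub_operon_tss = {
        internal_gene_of_unit[uid]: true_tss[internal_gene_of_unit[uid]]
        for uid in internal_units
    }

    # --- annotated gene models, with mis-annotation offsets ---
    misannotated: dict[str, tuple[int, int]] = {}
    ann_bounds = dict(true_bounds)
    for gid in mis_genes:
        strand = unit_strands[unit_of_gene[gid]]
        k = int(rng.integers(params.misannotation_k[0], params.misannotation_k[1] + 1))
        offset = 3 * k
        s, e = true_bounds[gid]
        if strand == "+":
            ann_bounds[gid] = (s - offset, e)
            misannotated[gid] = (s - offset, s)
        else:
            ann_bounds[gid] = (s, e + offset)
            misannotated[gid] = (e + offset, e)

    genes = [
        GeneModel(
            gene_id=gid,
            strand=unit_strands[unit_of_gene[gid]],
            start=ann_bounds[gid][0],
            end=ann_bounds[gid][1],
        )
        for gid in sorted(ann_bounds, key=lambda g: ann_bounds[g][0])
    ]
    genes = [
        GeneModel(g.gene_id, g.strand, g.start, g.end, order_index=i)
        for i, g in enumerate(genes)
    ]

    # --- abundances ---
    abundance = {
        uid: float(max(MIN_UNIT_DEPTH, rng.lognormal(params.abundance_mu, params.abundance_sigma)))
        for uid in unit_ids
    }

    # --- sequence: random background, planted start codons and motifs ---
    seq = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=genome_length)
    for gid in true_bounds:
        strand = unit_strands[unit_of_gene[gid]]
        codon = "ATG" if rng.random() < params.start_codon_probs[0] else "GTG"
        _plant(seq, true_cds_start[gid], strand, codon)
    n_motif = int(round(params.fraction_motif * len(tss_bearing)))
    motif_genes = (
        sorted(rng.choice(tss_bearing, size=n_motif, replace=False)) if n_motif else []
    )
    for gid in motif_genes:
        strand = unit_strands[unit_of_gene[gid]]
        d = int(rng.integers(7, 13))
        motif = "TA" + "".join(rng.choice(list("ACGT"), size=3)) + "T"
        p = true_tss[gid]
        if strand == "+":
            _plant(seq, p - d - 6, "+", motif)
        else:
            _plant(seq, p + d + 1, "-", motif, anchor="left")
    sequence = seq.tobytes().decode()

    truth = SyntheticTruth(
        genes=genes,
        true_tss=true_tss,
        operons=[tuple(unit_genes[uid]) for uid in unit_ids],
        sub_operon_tss=sub_operon_tss,
        leaderless_flags=leaderless_flags,
        misannotated=misannotated,
        abundance=abundance,
        unit_of_gene=unit_of_gene,
        unit_strand=dict(unit_strands),
        unit_ids=unit_ids,
        true_cds_start=true_cds_start,
        genome_length=genome_length,
        seed=seed,
    )
    return sequence, truth


def _plant(seq: np.ndarray, pos: int, strand: str, fragment: str, anchor: str = "cds") -> None:
    """Write ``fragment`` (given 5'->3' on ``strand``) into the sequence array.

    ``anchor='cds'``: on +, the fragment starts at ``pos``; on -, it ends at
    ``pos`` reading leftwards (i.e. occupies pos-len+1..pos reverse-
    complemented). ``anchor='left'`` places the reverse complement starting at
    ``pos`` regardless of reading direction.
    """
    frag = fragment if strand == "+" else str(Seq(fragment).reverse_complement())
    if strand == "+":
        i = pos - 1
    elif anchor == "cds":
        i = pos - len(fragment)
    else:
        i = pos - 1
    seq[i : i + len(frag)] = np.frombuffer(frag.encode(), dtype="S1")


# ---------------------------------------------------------------------------
# coverage simulation
# ---------------------------------------------------------------------------

def simulate_coverage(
    truth: SyntheticTruth,
    libraries: Sequence[tuple[str, int]] | None = None,
    noise: NoiseConfig | None = None,
    seed: int = 0,
) -> list[CoverageTrack]:
    """Simulate strand-specific per-base coverage for each library.

    Returns two tracks (one per strand) per (phase, replicate) library. Units
    carrying an internal TSS are transcribed from it alone in the last phase
    (suffix transcript) and from the primary TSS in all earlier phases.
    """
    noise = noise or NoiseConfig()
    libraries = list(libraries or DEFAULT_LIBRARIES)
    phases = list(dict.fromkeys(phase for phase, _ in libraries))
    subop_phase = phases[-1]

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(libraries) + 1)
    phase_rng = np.random.default_rng(children[0])

    units_with_internal = {
        truth.unit_of_gene[g] for g in truth.sub_operon_tss
    }
    # per-(unit, phase) abundance; drawn in a fixed order for determinism
    phase_abundance: dict[tuple[str, str], float] = {}
    for uid in truth.unit_ids:
        for phase in phases:
            factor = float(phase_rng.lognormal(0.0, noise.phase_sigma))
            phase_abundance[(uid, phase)] = max(MIN_UNIT_DEPTH, truth.abundance[uid] * factor)

    # mean depth per (phase, strand)
    n = truth.genome_length
    means: dict[tuple[str, str], np.ndarray] = {
        (phase, strand): np.zeros(n) for phase in phases for strand in "+-"
    }
    gene_end_cache = {g.gene_id: (g.start, g.end) for g in truth.genes}
    for uid, members in zip(truth.unit_ids, truth.operons):
        strand = truth.unit_strand[uid]
        first = members[0] if strand == "+" else members[-1]
        for phase in phases:
            suffix_only = uid in units_with_internal and phase == subop_phase
            if suffix_only:
                internal = next(g for g in members if g in truth.sub_operon_tss)
                tss = truth.true_tss[internal]
            else:
                tss = truth.true_tss[first]
            if strand == "+":
                lo = tss
                hi = max(gene_end_cache[g][1] for g in members)
            else:
                lo = min(gene_end_cache[g][0] for g in members)
                hi = tss
            a = phase_abundance[(uid, phase)]
            seg = np.full(hi - lo + 1, a)
            if noise.taper > 0:
                ramp = np.linspace(1.0, 1.0 - noise.taper, seg.size)
                seg *= ramp if strand == "+" else ramp[::-1]
            means[(phase, strand)][lo - 1 : hi] += seg

    tracks: list[CoverageTrack] = []
    for (phase, replicate), child in zip(libraries, children[1:]):
        rng = np.random.default_rng(child)
        lib_id = f"{phase}_{replicate}"
        depths = {}
        for strand in "+-":
            m = means[(phase, strand)]
            if noise.noiseless:
                depth = np.rint(m).astype(np.int64)
            else:
                depth = np.zeros(n, dtype=np.int64)
                on = m > 0
                if on.any():
                    mm = m[on]
                    p = noise.nb_size / (noise.nb_size + mm)
                    depth[on] = rng.negative_binomial(noise.nb_size, p)
                depth += rng.poisson(noise.background_mean, size=n)
            depths[strand] = depth
        total = max(1, int(round((depths["+"].sum() + depths["-"].sum()) / noise.read_length)))
        for strand in "+-":
            tracks.append(
                CoverageTrack(
                    library_id=lib_id,
                    phase_label=phase,
                    replicate=replicate,
                    strand=strand,
                    depth=depths[strand],
                    total_mapped=total,
                    read_length=noise.read_length,
                )
            )
    return tracks


# ---------------------------------------------------------------------------
# dataset export
# ---------------------------------------------------------------------------

def write_dataset(
    outdir: str | Path,
    sequence: str,
    truth: SyntheticTruth,
    tracks: Sequence[CoverageTrack],
    chrom: str = "chr",
) -> None:
    """Write FASTA + GFF3 + per-library bedGraph pairs + truth TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(sequence, outdir / "genome.fasta", name=chrom)
    write_gff3(truth.genes, outdir / "annotation.gff3", chrom=chrom)
    by_lib: dict[str, dict[str, CoverageTrack]] = {}
    for t in tracks:
        by_lib.setdefault(t.library_id, {})[t.strand] = t
    for lib_id, pair in by_lib.items():
        write_bedgraph(pair["+"], outdir / f"{lib_id}.plus.bedgraph", chrom=chrom)
        write_bedgraph(pair["-"], outdir / f"{lib_id}.minus.bedgraph", chrom=chrom)

    write_tsv(
        pd.DataFrame(
            [
                {
                    "gene_id": gid,
                    "tss_position": pos,
                    "strand": truth.unit_strand[truth.unit_of_gene[gid]],
                    "leaderless": truth.leaderless_flags[gid],
                    "internal": gid in truth.sub_operon_tss,
                }
                for gid, pos in sorted(truth.true_tss.items())
            ]
        ),
        outdir / "tss_truth.tsv",
    )
    write_tsv(
        pd.DataFrame(
            [
                {
                    "unit_id": uid,
                    "strand": truth.unit_strand[uid],
                    "genes": ",".join(members),
                    "abundance": truth.abundance[uid],
                }
                for uid, members in zip(truth.unit_ids, truth.operons)
            ]
        ),
        outdir / "operon_truth.tsv",
    )
    write_tsv(
        pd.DataFrame(
            [
                {
                    "gene_id": gid,
                    "annotated_cds_start": ann,
                    "true_cds_start": true,
                    "offset_nt": abs(ann - true),
                }
                for gid, (ann, true) in sorted(truth.misannotated.items())
            ]
        ),
        outdir / "misannotation_truth.tsv",
    )
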