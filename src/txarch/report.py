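"""Pipeline orchestration, summary statistics and provenance-stamped outputs.

``run_pipeline`` chains the stages: simulate (or ingest files) -> quantify ->
TSS calling -> 5'-UTR architecture -> operons -> summary. Every tabular output
carries a ``#``-prefixed provenance header (tool version, config hash, input
checksums, seed) and re-running an identical config reproduces identical
bytes for all deterministic stages.

The leaderless tally is reported twice: pre-correction (transcripts whose
5'-UTR is already below the leaderless bound) and post-correction (adding the
negative-UTR genes, whose corrected starts make them leaderless). Both are
printed side by side; the pipeline never silently picks one.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .architecture import (
    ReannotationProposal,
    UtrRecord,
    apply_reannotations,
    compute_utr,
    propose_reannotation,
    utr_distribution,
)
from .io_formats import (
    CoverageTrack,
    GeneModel,
    parse_gff3,
    read_coverage_bedgraph,
    read_fasta,
    sha256_file,
    write_gff3,
    write_tss_bed,
    write_tsv,
)
from .operons import (
    OperonCall,
    OperonComparison,
    OperonParams,
    call_operons,
    compare_to_reference,
    detect_suboperons,
    group_counts,
)
from .quantify import (
    DegRecord,
    ExpressionRecord,
    call_degs,
    enrich,
    library_counts,
    phase_pooled_counts,
    phase_rpkm,
    rpkm,
)
from .rounding import percentage
from .synthetic_data import (
    DEFAULT_LIBRARIES,
    GenomeParams,
    NoiseConfig,
    SyntheticTruth,
    generate_genome,
    simulate_coverage,
    write_dataset,
)
from .tss import TssParams, detect_tss, scan_minus10

logger = logging.getLogger("txarch")


@dataclass
class SummaryReport:
    n_genes: int
    n_tss: int
    n_orphans: int
    n_leaderless_pre: int
    n_negative_utr: int
    n_corrected: int
    n_leaderless_post: int
    n_units: int
    n_polycistronic: int
    utr_bins: dict[str, int] = field(default_factory=dict)
    operon_group_counts: dict[str, int] = field(default_factory=dict)
    pct_leaderless_pre_1dp: float = 0.0
    pct_leaderless_pre_2dp: float = 0.0
    pct_leaderless_post_1dp: float = 0.0
    pct_leaderless_post_2dp: float = 0.0
    pct_negative_utr_1dp: float = 0.0
    pct_motif_1dp: float = 0.0
    n_deg: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


@dataclass
class PipelineResult:
    sequence: str
    genes: list[GeneModel]
    tracks: list[CoverageTrack]
    truth: SyntheticTruth | None
    expression: list[ExpressionRecord]
    degs: dict[str, list[DegRecord]]
    enrichment: dict[str, list]
    tss_calls: list
    motif_hits: list
    motif_fraction: float
    utr_records: list[UtrRecord]
    utr_table: pd.DataFrame
    proposals: list[ReannotationProposal]
    units: list[OperonCall]
    comparisons: list[OperonComparison]
    summary: SummaryReport


def select_promoter_candidates(
    expression: Sequence[ExpressionRecord],
    top_n: int,
    exclude: frozenset[str] | set[str] = frozenset(),
) -> list[str]:
    """Rank genes by mean RPKM across libraries, descending, and take the top.

    Candidate promoters for overexpression work are simply the most highly
    transcribed genes; ``exclude`` removes ids (e.g. rRNA/tRNA genes) before
    ranking. Ties break lexicographically by gene id.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    means: dict[str, list[float]] = {}
    for rec in expression:
        if rec.gene_id in exclude:
            continue
        means.setdefault(rec.gene_id, []).append(rec.rpkm)
    ranked = sorted(means, key=lambda g: (-float(np.mean(means[g])), g))
    if top_n > len(ranked):
        logger.warning("top_n=%d exceeds %d available genes; returning all", top_n, len(ranked))
    return ranked[:top_n]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

class ConfigError(ValueError):
    """Missing or inconsistent pipeline configuration."""


def load_config(config: str | Path | Mapping[str, Any]) -> dict[str, Any]:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = dict(config)
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    return cfg


def _config_hash(cfg: Mapping[str, Any]) -> str:
    canon = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()


def _validate_config(cfg: Mapping[str, Any]) -> None:
    if ("simulate" in cfg) == ("inputs" in cfg):
        raise ConfigError("config must name exactly one of 'simulate' or 'inputs'")
    if "inputs" in cfg:
        inputs = cfg["inputs"]
        for key in ("fasta", "gff3", "coverage"):
            if key not in inputs:
                raise ConfigError(f"config missing required key inputs.{key}")
        for path in [inputs["fasta"], inputs["gff3"]] + [
            p for lib in inputs["coverage"] for p in (lib.get("plus"), lib.get("minus"))
        ]:
            if path is None or not Path(path).exists():
                raise ConfigError(f"input file not found: {path}")


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def run_pipeline(
    config: str | Path | Mapping[str, Any], outdir: str | Path | None = None
) -> PipelineResult:
    """Run every stage per the config; optionally write all outputs to outdir.

    The config names either a ``simulate`` block (synthetic dataset) or an
    ``inputs`` block (FASTA + GFF3 + per-library bedGraph pairs), plus
    optional ``params`` overrides per stage, ``reference_operons`` (TSV path,
    or planted truth when simulating), ``category_map`` (TSV path) and
    ``contrasts`` (phase pairs; default: first phase against each later one).
    """
    cfg = load_config(config)
    _validate_config(cfg)
    seed = int(cfg.get("seed", 0))
    params = cfg.get("params", {}) or {}
    checksums: dict[str, str] = {}
    truth: SyntheticTruth | None = None

    logger.info("txarch %s starting; seed=%d", __version__, seed)
    for stage, block in sorted(params.items()):
        logger.info("params.%s = %s", stage, block)

    # --- ingest / simulate ---
    if "simulate" in cfg:
        sim = cfg["simulate"] or {}
        n_genes = int(sim.get("n_genes", 60))
        gparams = GenomeParams(**(sim.get("genome", {}) or {}))
        noise_block = dict(sim.get("noise", {}) or {})
        if sim.get("noiseless"):
            noise_block["noiseless"] = True
        noise = NoiseConfig(**noise_block)
        sequence, truth = generate_genome(n_genes, gparams, seed=seed)
        libraries = [tuple(x) for x in sim.get("libraries", DEFAULT_LIBRARIES)]
        tracks = simulate_coverage(truth, libraries, noise, seed=seed)
        genes = truth.genes
    else:
        inputs = cfg["inputs"]
        sequence = read_fasta(inputs["fasta"])
        genes = parse_gff3(inputs["gff3"])
        checksums["fasta"] = sha256_file(inputs["fasta"])
        checksums["gff3"] = sha256_file(inputs["gff3"])
        tracks = []
        for lib in inputs["coverage"]:
            plus, minus = read_coverage_bedgraph(
                lib["plus"],
                lib["minus"],
                genome_length=len(sequence),
                library_id=lib["library_id"],
                phase_label=lib.get("phase", ""),
                replicate=int(lib.get("replicate", 1)),
                total_mapped=lib.get("total_mapped"),
                read_length=int(lib.get("read_length", 100)),
            )
            tracks.extend([plus, minus])

    # --- quantify ---
    qparams = params.get("quantify", {}) or {}
    counts_by_lib = library_counts(tracks, genes)
    totals_by_lib = {t.library_id: t.total_mapped for t in tracks}
    expression = []
    for lib, counts in sorted(counts_by_lib.items()):
        lib_rpkm = rpkm(counts, genes, totals_by_lib[lib])
        for gid in sorted(counts):
            expression.append(ExpressionRecord(gid, lib, counts[gid], lib_rpkm[gid]))
    phase_counts, phase_totals = phase_pooled_counts(tracks, genes)
    rpkm_phase = phase_rpkm(tracks, genes)
    phases = list(dict.fromkeys(t.phase_label for t in tracks))
    contrasts = [tuple(c) for c in cfg.get("contrasts", [])] or [
        (phases[0], p) for p in phases[1:]
    ]
    degs = {
        f"{a}_vs_{b}": call_degs(
            phase_counts[a],
            phase_counts[b],
            phase_totals[a],
            phase_totals[b],
            min_fold=float(qparams.get("min_fold", 2.0)),
            fdr_max=float(qparams.get("fdr_max", 0.001)),
            contrast=(a, b),
        )
        for a, b in contrasts
    }
    enrichment: dict[str, list] = {}
    if cfg.get("category_map"):
        cat_df = pd.read_csv(cfg["category_map"], sep="\t", comment="#")
        checksums["category_map"] = sha256_file(cfg["category_map"])
        cat_map: dict[str, set[str]] = {}
        for gid, cat in zip(cat_df.iloc[:, 0], cat_df.iloc[:, 1]):
            cat_map.setdefault(str(gid), set()).add(str(cat))
        background = {g.gene_id for g in genes}
        for name, recs in degs.items():
            deg_ids = {r.gene_id for r in recs if r.is_deg}
            enrichment[name] = enrich(deg_ids, background, cat_map)

    # --- TSS ---
    tparams = TssParams(**(params.get("tss", {}) or {}))
    tss_calls = detect_tss(tracks, genes, tparams)
    assigned = [c for c in tss_calls if c.gene_id is not None]
    orphans = [c for c in tss_calls if c.gene_id is None]
    motif_hits, motif_fraction = scan_minus10(sequence, assigned)

    # --- architecture ---
    leaderless_max = int((params.get("architecture", {}) or {}).get("leaderless_max", 9))
    by_gene = {g.gene_id: g for g in genes}
    utr_records = [
        compute_utr(c, by_gene[c.gene_id], leaderless_max) for c in assigned
    ]
    utr_table = utr_distribution(utr_records) if utr_records else pd.DataFrame()
    proposals = [
        propose_reannotation(r, by_gene[r.gene_id], sequence)
        for r in utr_records
        if r.utr_class == "negative"
    ]

    # --- operons ---
    oparams = OperonParams(**(params.get("operons", {}) or {}))
    pooled = _pool_by_phase(tracks)
    units = call_operons(sorted(genes, key=lambda g: g.start), pooled, rpkm_phase, oparams)
    units = detect_suboperons(units, assigned)
    reference, reference_ids = _load_reference(cfg, truth)
    comparisons = (
        compare_to_reference(units, reference, reference_ids) if reference is not None else []
    )

    # --- summary ---
    n_tss = len(assigned)
    bins = {row["utr_class"]: int(row["count"]) for _, row in utr_table.iterrows()}
    n_lead_pre = bins.get("leaderless", 0)
    n_neg = bins.get("negative", 0)
    n_corrected = sum(p.status == "corrected" for p in proposals)
    summary = SummaryReport(
        n_genes=len(genes),
        n_tss=n_tss,
        n_orphans=len(orphans),
        n_leaderless_pre=n_lead_pre,
        n_negative_utr=n_neg,
        n_corrected=n_corrected,
        n_leaderless_post=n_lead_pre + n_neg,
        n_units=len(units),
        n_polycistronic=sum(len(u.genes) > 1 for u in units),
        utr_bins=bins,
        operon_group_counts=group_counts(comparisons) if comparisons else {},
        pct_leaderless_pre_1dp=percentage(n_lead_pre, n_tss, 1) if n_tss else 0.0,
        pct_leaderless_pre_2dp=percentage(n_lead_pre, n_tss, 2) if n_tss else 0.0,
        pct_leaderless_post_1dp=percentage(n_lead_pre + n_neg, n_tss, 1) if n_tss else 0.0,
        pct_leaderless_post_2dp=percentage(n_lead_pre + n_neg, n_tss, 2) if n_tss else 0.0,
        pct_negative_utr_1dp=percentage(n_neg, n_tss, 1) if n_tss else 0.0,
        pct_motif_1dp=percentage(
            round(motif_fraction * n_tss), n_tss, 1
        ) if n_tss else 0.0,
        n_deg={name: sum(r.is_deg for r in recs) for name, recs in degs.items()},
    )

    result = PipelineResult(
        sequence=sequence,
        genes=list(genes),
        tracks=tracks,
        truth=truth,
        expression=expression,
        degs=degs,
        enrichment=enrichment,
        tss_calls=tss_calls,
        motif_hits=motif_hits,
        motif_fraction=motif_fraction,
        utr_records=utr_records,
        utr_table=utr_table,
        proposals=proposals,
        units=units,
        comparisons=comparisons,
        summary=summary,
    )
    if outdir is not None or cfg.get("outdir"):
        _write_outputs(Path(outdir or cfg["outdir"]), cfg, checksums, seed, result)
    return result


def _pool_by_phase(tracks: Sequence[CoverageTrack]) -> dict[str, dict[str, CoverageTrack]]:
    pooled: dict[str, dict[str, CoverageTrack]] = {}
    for t in tracks:
        slot = pooled.setdefault(t.phase_label, {})
        if t.strand in slot:
            prev = slot[t.strand]
            slot[t.strand] = CoverageTrack(
                library_id=f"{t.phase_label}_pooled",
                phase_label=t.phase_label,
                replicate=0,
                strand=t.strand,
                depth=prev.depth + t.depth,
                total_mapped=prev.total_mapped + t.total_mapped,
                read_length=t.read_length,
            )
        else:
            slot[t.strand] = CoverageTrack(
                library_id=f"{t.phase_label}_pooled",
                phase_label=t.phase_label,
                replicate=0,
                strand=t.strand,
                depth=t.depth.copy(),
                total_mapped=t.total_mapped,
                read_length=t.read_length,
            )
    return pooled


def _load_reference(
    cfg: Mapping[str, Any], truth: SyntheticTruth | None
) -> tuple[list[tuple[str, ...]] | None, list[str] | None]:
    ref = cfg.get("reference_operons")
    if ref is None:
        if truth is not None:
            multi = [(uid, m) for uid, m in zip(truth.unit_ids, truth.operons) if len(m) > 1]
            return [m for _, m in multi], [uid for uid, _ in multi]
        return None, None
    df = pd.read_csv(ref, sep="\t", comment="#")
    operons = [tuple(str(x).split(",")) for x in df.iloc[:, 1]]
    return operons, [str(x) for x in df.iloc[:, 0]]


def _write_outputs(
    outdir: Path,
    cfg: Mapping[str, Any],
    checksums: Mapping[str, str],
    seed: int,
    result: PipelineResult,
) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    header = [
        f"txarch={__version__}",
        f"config_sha256={_config_hash(cfg)}",
        f"seed={seed}",
    ] + [f"checksum_{k}={v}" for k, v in sorted(checksums.items())]

    if result.truth is not None:
        write_dataset(outdir / "simulated", result.sequence, result.truth, result.tracks)

    write_tsv(
        pd.DataFrame([asdict(e) for e in result.expression]),
        outdir / "expression.tsv",
        header,
    )
    for name, recs in result.degs.items():
        df = pd.DataFrame([asdict(r) for r in recs])
        df["contrast"] = [f"{a}:{b}" for a, b in df["contrast"]]
        write_tsv(df, outdir / f"deg_{name}.tsv", header)
    for name, recs in result.enrichment.items():
        write_tsv(
            pd.DataFrame([asdict(r) for r in recs]),
            outdir / f"enrichment_{name}.tsv",
            header,
        )
    write_tsv(
        pd.DataFrame(
            [
                {
                    "gene_id": c.gene_id or "",
                    "position": c.position,
                    "strand": c.strand,
                    "step_score": c.step_score,
                    "n_libraries": len(c.supporting_libraries),
                }
                for c in result.tss_calls
            ]
        ),
        outdir / "tss_calls.tsv",
        header + ["spacer_anchor=end_exclusive"],
    )
    write_tss_bed(result.tss_calls, outdir / "tss.bed")
    write_tsv(
        pd.DataFrame([asdict(h) for h in result.motif_hits]),
        outdir / "motif_hits.tsv",
        header + ["spacer_anchor=end_exclusive", f"fraction_with_motif={result.motif_fraction:.6f}"],
    )
    write_tsv(
        pd.DataFrame([asdict(r) for r in result.utr_records]),
        outdir / "utr_records.tsv",
        header,
    )
    if not result.utr_table.empty:
        write_tsv(result.utr_table, outdir / "utr_distribution.tsv", header)
    write_tsv(
        pd.DataFrame([asdict(p) for p in result.proposals]),
        outdir / "reannotations.tsv",
        header,
    )
    corrected = apply_reannotations(result.genes, result.proposals)
    write_gff3(corrected, outdir / "reannotations.gff3", header_lines=header)
    write_tsv(
        pd.DataFrame(
            [
                {
                    "unit_id": u.unit_id,
                    "genes": ",".join(u.genes),
                    "strand": u.strand,
                    "phases_supported": ",".join(sorted(u.phases_supported)),
                    "primary_tss": u.primary_tss if u.primary_tss is not None else "",
                    "internal_tss": ";".join(f"{g}:{p}" for g, p in sorted(u.internal_tss.items())),
                }
                for u in result.units
            ]
        ),
        outdir / "operons.tsv",
        header,
    )
    if result.comparisons:
        summary_block = [
            f"group_{label}={count}" for label, count in group_counts(result.comparisons).items()
        ]
        write_tsv(
            pd.DataFrame([asdict(c) for c in result.comparisons]),
            outdir / "operon_comparison.tsv",
            header + summary_block,
        )
    with open(outdir / "summary.json", "w") as fh:
        json.dump(result.summary.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
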