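"""Transcription start site calling and -10 promoter motif scanning.

A TSS shows up in single-nucleotide coverage as a sharp upward step: depth at
the first transcribed base is much higher than the few bases immediately
upstream. The caller formalizes this as a depth/upstream-mean ratio rule with
replicate concordance: a candidate position must carry depth >= ``d_min`` and a
pseudocounted ratio >= ``r_min`` against the mean of the ``w`` bases upstream,
independently in at least ``m_min`` libraries at the identical coordinate.
Each retained candidate is assigned to the gene whose search window contains
it; per gene, the single call with the highest pooled step score wins.

The -10 element recognized by bacterial sigma-A factors is scanned as the fixed
degenerate pattern TANNNT within a short spacer window upstream of each call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

from .io_formats import CoverageTrack, GeneModel, STRANDS


@dataclass(frozen=True)
class TssParams:
    """Tunables of the step-calling rule.

    d_min: minimum depth at the candidate base.
    r_min: minimum (depth + psi) / (upstream mean + psi) step ratio.
    w: width (nt) of the upstream window used for the local baseline.
    pseudocount: psi, stabilizes the ratio over silent upstream regions.
    m_min: libraries that must carry the candidate at the identical coordinate.
    u_max / d_max: gene search window, from u_max nt upstream of the annotated
        start codon to d_max nt into the gene (capped at d_max_frac of the gene
        length) so that mis-annotated starts (negative 5'-UTRs) stay visible.
    """

    d_min: float = 10.0
    r_min: float = 5.0
    w: int = 5
    pseudocount: float = 1.0
    m_min: int = 2
    u_max: int = 500
    d_max: int = 300
    d_max_frac: float = 0.5


@dataclass
class TssCall:
    position: int  # 1-based
    strand: str
    gene_id: str | None
    step_score: float
    supporting_libraries: list[str] = field(default_factory=list)
    downstream_mean_depth: float = 0.0


@dataclass(frozen=True)
class MotifHit:
    tss_position: int
    strand: str
    motif_start: int  # genomic 1-based leftmost coordinate of the 6-mer
    spacer: int  # bases strictly between the motif's 3' end and the TSS
    matched_sequence: str  # on the TSS's strand


def _upstream_mean(depth: np.ndarray, w: int, strand: str) -> np.ndarray:
    """Mean depth over the w bases 5' of each position (truncated at edges)."""
    n = depth.size
    cs = np.concatenate(([0.0], np.cumsum(depth, dtype=np.float64)))
    idx = np.arange(n)
    if strand == "+":
        lo, hi = np.maximum(idx - w, 0), idx
    else:
        lo, hi = idx + 1, np.minimum(idx + 1 + w, n)
    width = hi - lo
    out = np.zeros(n)
    nz = width > 0
    out[nz] = (cs[hi] - cs[lo])[nz] / width[nz]
    return out


def _downstream_mean(depth: np.ndarray, i: int, w: int, strand: str) -> float:
    n = depth.size
    if strand == "+":
        seg = depth[i : min(i + w, n)]
    else:
        seg = depth[max(i - w + 1, 0) : i + 1]
    return float(seg.mean()) if seg.size else 0.0


def _gene_window(gene: GeneModel, params: TssParams) -> tuple[int, int]:
    into = min(params.d_max, int(gene.length * params.d_max_frac))
    if gene.strand == "+":
        return gene.cds_start - params.u_max, gene.cds_start + into
    return gene.cds_start - into, gene.cds_start + params.u_max


def _signed_utr(position: int, gene: GeneModel) -> int:
    if gene.strand == "+":
        return gene.cds_start - position
    return position - gene.cds_start


def detect_tss(
    tracks: list[CoverageTrack],
    genes: list[GeneModel],
    params: TssParams | None = None,
) -> list[TssCall]:
    """Call at most one TSS per gene from strand-specific coverage tracks.

    Returns gene-assigned calls plus orphan candidates (``gene_id is None``)
    that fell in no gene's search window. Candidates assigned to a gene but
    beaten by a stronger call in the same window are dropped.
    """
    params = params or TssParams()
    if not tracks:
        raise ValueError("at least one coverage track is required")
    lengths = {t.genome_length for t in tracks}
    if len(lengths) != 1:
        raise ValueError(f"inconsistent genome lengths across tracks: {sorted(lengths)}")

    psi = params.pseudocount
    best_by_gene: dict[str, TssCall] = {}
    orphans: list[TssCall] = []

    for strand in STRANDS:
        strand_tracks = [t for t in tracks if t.strand == strand]
        if not strand_tracks:
            continue
        upmeans = [_upstream_mean(t.depth, params.w, strand) for t in strand_tracks]
        masks = [
            (t.depth >= params.d_min) & ((t.depth + psi) / (u + psi) >= params.r_min)
            for t, u in zip(strand_tracks, upmeans)
        ]
        support_count = np.sum(masks, axis=0)
        candidates = np.flatnonzero(support_count >= params.m_min)

        strand_genes = [g for g in genes if g.strand == strand]
        windows = [_gene_window(g, params) for g in strand_genes]

        for i in candidates:
            sup = [
                (t, u) for t, u, m in zip(strand_tracks, upmeans, masks) if m[i]
            ]
            # Pooled score: mean depth / mean upstream baseline across the
            # supporting libraries, each pseudocounted once.
            d_mean = float(np.mean([t.depth[i] for t, _ in sup]))
            u_mean = float(np.mean([u[i] for _, u in sup]))
            score = (d_mean + psi) / (u_mean + psi)
            call = TssCall(
                position=int(i) + 1,
                strand=strand,
                gene_id=None,
                step_score=score,
                supporting_libraries=[t.library_id for t, _ in sup],
                downstream_mean_depth=float(
                    np.mean([_downstream_mean(t.depth, int(i), params.w, strand) for t, _ in sup])
                ),
            )
            pos = call.position
            hits = [
                g
                for g, (lo, hi) in zip(strand_genes, windows)
                if lo <= pos <= hi
            ]
            if not hits:
                orphans.append(call)
                continue
            # A coordinate can sit in overlapping windows of adjacent genes;
            # it belongs to the gene whose start codon it is nearest to.
            gene = min(hits, key=lambda g: (abs(_signed_utr(pos, g)), g.gene_id))
            call.gene_id = gene.gene_id
            cur = best_by_gene.get(gene.gene_id)
            if cur is None or _beats(call, cur, gene.strand):
                best_by_gene[gene.gene_id] = call

    calls = list(best_by_gene.values()) + orphans
    calls.sort(key=lambda c: (c.position, c.strand))
    return calls


def _beats(new: TssCall, cur: TssCall, strand: str) -> bool:
    if new.step_score != cur.step_score:
        return new.step_score > cur.step_score
    # tie: most upstream in gene sense
    return new.position < cur.position if strand == "+" else new.position > cur.position


# ---------------------------------------------------------------------------
# -10 motif scan
# ---------------------------------------------------------------------------

def _is_tannnt(s: str) -> bool:
    return len(s) == 6 and s[0] == "T" and s[1] == "A" and s[5] == "T"


def scan_minus10(
    sequence: str,
    calls: list[TssCall],
    spacer_range: tuple[int, int] = (7, 12),
) -> tuple[list[MotifHit], float]:
    """Scan for TANNNT with its 3' end a short spacer upstream of each TSS.

    The spacer counts the bases strictly between the motif's last base and the
    TSS. On the - strand the pattern is matched on the reverse complement.
    Calls too close to the genome edge are scanned over the truncated window.
    Returns all hits and the fraction of calls with at least one hit.
    """
    lo, hi = spacer_range
    n = len(sequence)
    hits: list[MotifHit] = []
    with_hit: set[tuple[int, str]] = set()
    for call in calls:
        p = call.position
        for d in range(lo, hi + 1):
            if call.strand == "+":
                ms, me = p - d - 6, p - d - 1
                if ms < 1:
                    continue
                sub = sequence[ms - 1 : me]
            else:
                ms, me = p + d + 1, p + d + 6
                if me > n:
                    continue
                sub = str(Seq(sequence[ms - 1 : me]).reverse_complement())
            if _is_tannnt(sub):
                hits.append(
                    MotifHit(
                        tss_position=p,
                        strand=call.strand,
                        motif_start=ms,
                        spacer=d,
                        matched_sequence=sub,
                    )
                )
                with_hit.add((p, call.strand))
    fraction = len({(c.position, c.strand) for c in calls} & with_hit) / len(calls) if calls else 0.0
    return hits, fraction
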