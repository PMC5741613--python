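"""Expression quantification: counts, RPKM, phase comparison, DEGs, enrichment.

Per-gene read counts are recovered from per-base coverage as summed depth over
the gene body divided by the read length. RPKM = count * 1e9 / (gene length in
nt * total mapped reads). Differential expression between two libraries is
tested with an exact binomial two-library test (the observed count of one
library against the pooled count, success probability proportional to the
library totals) with Benjamini-Hochberg FDR control; a gene is a DEG at
>= ``min_fold`` fold change and FDR < ``fdr_max`` (defaults 2-fold, 0.001).
Category enrichment of DEGs uses the hypergeometric upper tail with the rich
factor (DEGs in category / category size in background) as effect size.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import CoverageTrack, GeneModel


@dataclass(frozen=True)
class ExpressionRecord:
    gene_id: str
    library_id: str
    raw_count: float
    rpkm: float


@dataclass(frozen=True)
class DegRecord:
    gene_id: str
    contrast: tuple[str, str]  # (phase_A, phase_B); fold change is B over A
    log2fc: float
    p_value: float
    fdr: float
    is_deg: bool


@dataclass(frozen=True)
class EnrichmentRecord:
    category_id: str
    n_deg_in_cat: int
    n_cat_in_background: int
    rich_factor: float
    p_value: float
    q_value: float


# ---------------------------------------------------------------------------
# counting and normalization
# ---------------------------------------------------------------------------

def count_reads(track: CoverageTrack, genes: Sequence[GeneModel]) -> dict[str, int]:
    """Per-gene read counts from coverage, for genes on the track's strand.

    count = round_half_up(sum of depth over [start, end] / read_length).
    """
    n = track.genome_length
    cs = np.concatenate(([0], np.cumsum(track.depth)))
    out: dict[str, int] = {}
    for g in genes:
        if g.strand != track.strand:
            continue
        if g.end > n:
            raise ValueError(f"gene {g.gene_id} extends beyond genome length {n}")
        total = int(cs[g.end] - cs[g.start - 1])
        out[g.gene_id] = int(math.floor(total / track.read_length + 0.5))
    return out


def rpkm(
    counts: Mapping[str, float], genes: Sequence[GeneModel], total_mapped: int
) -> dict[str, float]:
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    lengths = {g.gene_id: g.length for g in genes}
    out = {}
    for gene_id, c in counts.items():
        length = lengths[gene_id]
        if length <= 0:
            raise ValueError(f"gene {gene_id} has non-positive length")
        out[gene_id] = c * 1e9 / (length * total_mapped)
    return out


def library_counts(
    tracks: Sequence[CoverageTrack], genes: Sequence[GeneModel]
) -> dict[str, dict[str, int]]:
    """Counts per library, merging the library's two strand tracks."""
    out: dict[str, dict[str, int]] = {}
    for t in tracks:
        out.setdefault(t.library_id, {}).update(count_reads(t, genes))
    return out


def phase_pooled_counts(
    tracks: Sequence[CoverageTrack], genes: Sequence[GeneModel]
) -> tuple[dict[str, dict[str, int]], dict[str, int]]:
    """Replicate-pooled counts and total_mapped per phase.

    Replicates within a growth phase are summed before any contrast, mirroring
    phase-level comparison of pooled libraries.
    """
    counts: dict[str, dict[str, int]] = {}
    totals: dict[str, int] = {}
    seen_libs: dict[str, set[str]] = {}
    for t in tracks:
        phase = t.phase_label
        c = counts.setdefault(phase, {g.gene_id: 0 for g in genes})
        for gid, v in count_reads(t, genes).items():
            c[gid] += v
        if t.library_id not in seen_libs.setdefault(phase, set()):
            totals[phase] = totals.get(phase, 0) + t.total_mapped
            seen_libs[phase].add(t.library_id)
    return counts, totals


def phase_rpkm(
    tracks: Sequence[CoverageTrack], genes: Sequence[GeneModel]
) -> dict[str, dict[str, float]]:
    counts, totals = phase_pooled_counts(tracks, genes)
    return {phase: rpkm(c, genes, totals[phase]) for phase, c in counts.items()}


# ---------------------------------------------------------------------------
# rank-sum test
# ---------------------------------------------------------------------------

def wilcoxon_rank_sum(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Mann-Whitney U (midranks for ties) with a two-sided p-value.

    Exact p by full enumeration of labelings when n_a + n_b <= 12 and the
    pooled sample is tie-free; otherwise the normal approximation with tie and
    continuity corrections. Returns (U for sample a, p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    u = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    m = n1 * n2
    has_ties = np.unique(pooled).size < pooled.size

    if n1 + n2 <= 12 and not has_ties:
        order = np.argsort(pooled)
        key_obs = min(u, m - u)
        count = total = 0
        idx = range(n1 + n2)
        rank_of = np.empty(n1 + n2)
        rank_of[order] = np.arange(1, n1 + n2 + 1)
        for comb in combinations(idx, n1):
            u_star = rank_of[list(comb)].sum() - n1 * (n1 + 1) / 2
            if min(u_star, m - u_star) <= key_obs + 1e-12:
                count += 1
            total += 1
        return u, count / total

    mu = m / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    sigma2 = m / 12.0 * (n + 1 - tie_term)
    if sigma2 <= 0:
        return u, 1.0
    z = (u - mu - 0.5 * np.sign(u - mu)) / math.sqrt(sigma2)
    return u, float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    if len(p_values) == 0:
        return np.array([])
    return multipletests(p_values, method="fdr_bh")[1]


def call_degs(
    counts_a: Mapping[str, int],
    counts_b: Mapping[str, int],
    total_a: int,
    total_b: int,
    min_fold: float = 2.0,
    fdr_max: float = 0.001,
    pseudocount: float = 0.5,
    contrast: tuple[str, str] = ("A", "B"),
) -> list[DegRecord]:
    """Exact binomial two-library DEG test over a shared gene universe.

    For each gene, count_B is tested against n = count_A + count_B with
    success probability total_B / (total_A + total_B); fold change is
    log2((count_B + eps)/total_B) - log2((count_A + eps)/total_A).
    """
    if set(counts_a) != set(counts_b):
        raise ValueError("count maps must share the same gene universe")
    if total_a <= 0 or total_b <= 0:
        raise ValueError("library totals must be positive")
    genes = sorted(counts_a)
    p0 = total_b / (total_a + total_b)
    log2fc = []
    pvals = []
    for gid in genes:
        ca, cb = counts_a[gid], counts_b[gid]
        if ca < 0 or cb < 0:
            raise ValueError(f"negative count for gene {gid}")
        log2fc.append(
            math.log2((cb + pseudocount) / total_b) - math.log2((ca + pseudocount) / total_a)
        )
        n = ca + cb
        pvals.append(1.0 if n == 0 else stats.binomtest(cb, n, p0).pvalue)
    fdr = benjamini_hochberg(pvals)
    thr = math.log2(min_fold)
    return [
        DegRecord(
            gene_id=gid,
            contrast=contrast,
            log2fc=lfc,
            p_value=p,
            fdr=float(q),
            is_deg=bool(abs(lfc) >= thr and q < fdr_max),
        )
        for gid, lfc, p, q in zip(genes, log2fc, pvals, fdr)
    ]


# ---------------------------------------------------------------------------
# category enrichment
# ---------------------------------------------------------------------------

def enrich(
    deg_ids: Iterable[str],
    background_ids: Iterable[str],
    category_map: Mapping[str, Iterable[str]],
) -> list[EnrichmentRecord]:
    """Hypergeometric enrichment of DEGs per category, BH-corrected.

    ``category_map`` maps gene_id -> categories. Records are sorted by
    q-value ascending (ties by category id). Categories with no background
    members are skipped with a warning.
    """
    deg = set(deg_ids)
    background = set(background_ids)
    if not deg <= background:
        raise ValueError("deg_ids must be a subset of background_ids")
    cat_members: dict[str, set[str]] = {}
    for gid, cats in category_map.items():
        if gid not in background:
            continue
        for cat in cats:
            cat_members.setdefault(cat, set()).add(gid)
    for cat in set(category_map_values(category_map)) - set(cat_members):
        warnings.warn(f"category {cat} has no background members; skipped", stacklevel=2)

    M, N = len(background), len(deg)
    rows = []
    for cat in sorted(cat_members):
        members = cat_members[cat]
        k = len(members & deg)
        K = len(members)
        p = float(stats.hypergeom.sf(k - 1, M, K, N))
        rows.append((cat, k, K, k / K, p))
    qvals = benjamini_hochberg([r[4] for r in rows])
    records = [
        EnrichmentRecord(cat, k, K, rf, p, float(q))
        for (cat, k, K, rf, p), q in zip(rows, qvals)
    ]
    records.sort(key=lambda r: (r.q_value, r.category_id))
    return records


def category_map_values(category_map: Mapping[str, Iterable[str]]) -> set[str]:
    out: set[str] = set()
    for cats in category_map.values():
        out.update(cats)
    return out
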