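"""Operon and sub-operon inference, and comparison against a reference map.

Two adjacent genes are co-transcribed into one unit when (a) they share a
strand, (b) the transcript demonstrably covers the intergenic gap (every gap
base at depth >= ``c_min`` on the pooled strand track of some growth phase;
abutting or overlapping genes join trivially), and (c) their expression levels
are comparable: max/min RPKM ratio strictly below ``ratio_max`` (default 2),
with ``epsilon`` clamping the denominator. Joins are evaluated per phase on replicate-pooled
coverage and the final units are the union of joins across phases, since
condition-dependent operon structure is expected. Maximal runs of joined pairs
form polycistronic units; unjoined genes are monocistrons.

A gene inside a unit that carries its own called TSS marks a sub-operon.
Multi-gene units are compared to a reference operon prediction set (DOOR-style
ordered gene lists) and classified into five groups: confirmed (equal gene
set), extended (reference nested in call), dismissed (call nested in
reference), new (no reference overlap) and alternative (internal TSS present;
takes precedence). Non-nested partial overlaps are labeled dismissed with an
explicit crossing flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .io_formats import CoverageTrack, GeneModel
from .tss import TssCall


@dataclass(frozen=True)
class OperonParams:
    c_min: float = 1.0  # min per-base depth over the intergenic gap
    ratio_max: float = 2.0  # strict upper bound on the max/min RPKM ratio
    epsilon: float = 0.1  # RPKM pseudocount; both genes below it => no join


@dataclass
class OperonCall:
    unit_id: str
    genes: tuple[str, ...]  # genomic order
    strand: str
    phases_supported: set[str] = field(default_factory=set)
    primary_tss: int | None = None
    internal_tss: dict[str, int] = field(default_factory=dict)

    def first_gene(self) -> str:
        """5'-most member in transcription sense."""
        return self.genes[0] if self.strand == "+" else self.genes[-1]


@dataclass(frozen=True)
class OperonComparison:
    unit_id: str
    label: str  # confirmed | extended | dismissed | new | alternative | unlabeled
    matched_reference_ids: tuple[str, ...] = ()
    crossing_flag: bool = False


FIVE_GROUPS = ("confirmed", "extended", "dismissed", "new", "alternative")


def _pair_joined(
    a: GeneModel,
    b: GeneModel,
    track: CoverageTrack,
    rpkm_phase: Mapping[str, float],
    params: OperonParams,
) -> bool:
    if a.strand != b.strand:
        return False
    gap = track.depth[a.end : b.start - 1]  # 1-based positions a.end+1 .. b.start-1
    if gap.size and gap.min() < params.c_min:
        return False
    ra, rb = rpkm_phase[a.gene_id], rpkm_phase[b.gene_id]
    eps = params.epsilon
    if ra < eps and rb < eps:
        return False  # covered gap with both genes silent is no evidence
    # epsilon clamps the denominator only, so the 2-fold boundary stays exact
    lo, hi = min(ra, rb), max(ra, rb)
    return hi / max(lo, eps) < params.ratio_max


def call_operons(
    genes: Sequence[GeneModel],
    pooled_tracks: Mapping[str, Mapping[str, CoverageTrack]],
    rpkm_by_phase: Mapping[str, Mapping[str, float]],
    params: OperonParams | None = None,
) -> list[OperonCall]:
    """Join adjacent genes into transcription units.

    ``pooled_tracks[phase][strand]`` is the replicate-pooled coverage track of
    that phase and strand; ``rpkm_by_phase[phase][gene_id]`` the phase RPKM.
    """
    params = params or OperonParams()
    genes = list(genes)
    if any(genes[i].start > genes[i + 1].start for i in range(len(genes) - 1)):
        raise ValueError("genes must be sorted by start coordinate")
    phases = list(rpkm_by_phase)
    for phase in phases:
        missing = {g.gene_id for g in genes} - set(rpkm_by_phase[phase])
        if missing:
            raise ValueError(f"phase {phase} lacks RPKM for genes {sorted(missing)[:3]}...")

    n = len(genes)
    joined_any = np.zeros(max(n - 1, 0), dtype=bool)
    joined_by_phase: dict[str, np.ndarray] = {}
    for phase in phases:
        j = np.zeros(max(n - 1, 0), dtype=bool)
        for i in range(n - 1):
            a, b = genes[i], genes[i + 1]
            if a.strand != b.strand:
                continue
            j[i] = _pair_joined(a, b, pooled_tracks[phase][a.strand], rpkm_by_phase[phase], params)
        joined_by_phase[phase] = j
        joined_any |= j

    units: list[OperonCall] = []
    i = 0
    while i < n:
        j = i
        while j < n - 1 and joined_any[j]:
            j += 1
        members = tuple(g.gene_id for g in genes[i : j + 1])
        strand = genes[i].strand
        if len(members) == 1:
            supported = {
                ph for ph in phases if rpkm_by_phase[ph][members[0]] >= params.epsilon
            }
        else:
            supported = {
                ph for ph in phases if joined_by_phase[ph][i:j].all()
            }
        units.append(
            OperonCall(
                unit_id=f"TU{len(units) + 1:04d}",
                genes=members,
                strand=strand,
                phases_supported=supported,
            )
        )
        i = j + 1
    return units


def detect_suboperons(
    units: Sequence[OperonCall], tss_calls: Sequence[TssCall]
) -> list[OperonCall]:
    """Populate primary and internal TSSs of each unit from gene-assigned calls."""
    tss_by_gene = {c.gene_id: c.position for c in tss_calls if c.gene_id is not None}
    out = []
    for u in units:
        first = u.first_gene()
        internal = {
            g: tss_by_gene[g] for g in u.genes if g != first and g in tss_by_gene
        }
        out.append(
            replace(u, primary_tss=tss_by_gene.get(first), internal_tss=internal)
        )
    return out


def compare_to_reference(
    units: Sequence[OperonCall],
    reference: Sequence[Sequence[str]],
    reference_ids: Sequence[str] | None = None,
) -> list[OperonComparison]:
    """Classify each unit against reference operon predictions.

    Multi-gene units with an internal TSS are ``alternative`` regardless of
    set relations. Otherwise the reference operon with maximal Jaccard overlap
    decides: equal sets -> confirmed; reference nested in call -> extended;
    call nested in reference -> dismissed; no overlap -> new; non-nested
    overlap -> dismissed with ``crossing_flag``. Monocistrons are labeled
    dismissed when the reference places the gene inside a multi-gene operon,
    else reported as ``unlabeled``.
    """
    if reference_ids is None:
        reference_ids = [f"REF{i + 1:04d}" for i in range(len(reference))]
    ref_sets = [frozenset(r) for r in reference]
    seen: set[str] = set()
    for rs in ref_sets:
        dup = seen & rs
        if dup:
            raise ValueError(f"gene(s) {sorted(dup)} appear in multiple reference operons")
        seen |= rs

    out = []
    for u in units:
        uset = frozenset(u.genes)
        overlapping = [
            (rid, rs) for rid, rs in zip(reference_ids, ref_sets) if uset & rs
        ]
        if len(u.genes) == 1:
            multi = [(rid, rs) for rid, rs in overlapping if len(rs) > 1]
            if multi:
                out.append(
                    OperonComparison(u.unit_id, "dismissed", tuple(r for r, _ in multi))
                )
            else:
                out.append(OperonComparison(u.unit_id, "unlabeled"))
            continue
        if u.internal_tss:
            out.append(
                OperonComparison(u.unit_id, "alternative", tuple(r for r, _ in overlapping))
            )
            continue
        if not overlapping:
            out.append(OperonComparison(u.unit_id, "new"))
            continue
        rid, rs = max(
            overlapping, key=lambda item: len(uset & item[1]) / len(uset | item[1])
        )
        if rs == uset:
            label, crossing = "confirmed", False
        elif rs < uset:
            label, crossing = "extended", False
        elif uset < rs:
            label, crossing = "dismissed", False
        else:
            label, crossing = "dismissed", True
        out.append(OperonComparison(u.unit_id, label, (rid,), crossing))
    return out


def group_counts(comparisons: Sequence[OperonComparison]) -> dict[str, int]:
    """Per-label totals over the five groups (unlabeled monocistrons excluded)."""
    counts = {label: 0 for label in FIVE_GROUPS}
    for c in comparisons:
        if c.label in counts:
            counts[c.label] += 1
    return counts
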