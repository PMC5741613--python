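"""5'-UTR geometry, leaderless classification and start-codon re-annotation.

The signed 5'-UTR length is the gene-sense distance from the TSS to the first
base of the annotated start codon. A negative value means the TSS lies inside
the annotated CDS - a strong sign the start codon was mis-annotated by the
genome's automated annotation. When the three bases at such a TSS read ATG or
GTG and the offset is a multiple of 3 (so the reading frame is preserved), the
TSS itself is proposed as the corrected start codon and the transcript becomes
leaderless.

Class boundaries: leaderless mRNAs carry essentially no 5'-UTR (< 10 nt by the
working definition here, boundary configurable); "short" covers 10-50 nt,
"mid" 51-100 nt, "long" > 100 nt.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from Bio.Seq import Seq

from .io_formats import GeneModel
from .rounding import percentage
from .tss import TssCall

UTR_CLASSES = ("negative", "leaderless", "short", "mid", "long")

ACCEPTED_START_CODONS = ("ATG", "GTG")


@dataclass(frozen=True)
class UtrRecord:
    gene_id: str
    tss_position: int
    utr_length: int  # signed, nt
    utr_class: str


@dataclass(frozen=True)
class ReannotationProposal:
    gene_id: str
    annotated_cds_start: int
    proposed_cds_start: int
    start_codon: str  # the 3 nt observed at the TSS (gene strand)
    offset_nt: int
    status: str  # "corrected" | "unresolved"
    reason: str = ""


def classify_utr(utr_length: int, leaderless_max: int = 9) -> str:
    if utr_length < 0:
        return "negative"
    if utr_length <= leaderless_max:
        return "leaderless"
    if utr_length <= 50:
        return "short"
    if utr_length <= 100:
        return "mid"
    return "long"


def compute_utr(call: TssCall, gene: GeneModel, leaderless_max: int = 9) -> UtrRecord:
    """Signed 5'-UTR length of a gene given its assigned TSS call."""
    if call.strand != gene.strand:
        raise ValueError(
            f"strand mismatch: call on {call.strand}, gene {gene.gene_id} on {gene.strand}"
        )
    if gene.strand == "+":
        utr = gene.cds_start - call.position
    else:
        utr = call.position - gene.cds_start
    return UtrRecord(
        gene_id=gene.gene_id,
        tss_position=call.position,
        utr_length=utr,
        utr_class=classify_utr(utr, leaderless_max),
    )


def utr_distribution(records: Sequence[UtrRecord]) -> pd.DataFrame:
    """Count/fraction table over UTR classes (all classes present, zeros kept).

    Percentages are reported rounded half-up at both 1 and 2 decimals.
    """
    if not records:
        raise ValueError("utr_distribution requires at least one record")
    counts = {cls: 0 for cls in UTR_CLASSES}
    for r in records:
        counts[r.utr_class] += 1
    total = len(records)
    rows = [
        {
            "utr_class": cls,
            "count": n,
            "fraction": n / total,
            "pct_1dp": percentage(n, total, 1),
            "pct_2dp": percentage(n, total, 2),
        }
        for cls, n in counts.items()
    ]
    return pd.DataFrame(rows)


def propose_reannotation(
    record: UtrRecord, gene: GeneModel, sequence: str
) -> ReannotationProposal:
    """Propose the TSS as the corrected start codon of a negative-UTR gene.

    Corrected iff the codon read at the TSS (reverse-complemented on -) is ATG
    or GTG and the annotated-to-proposed offset is a multiple of 3; otherwise
    the annotation is retained and the failing condition recorded. TTG, though
    a known bacterial start codon, is deliberately not auto-corrected.
    """
    if record.utr_class != "negative":
        raise ValueError(f"{gene.gene_id}: re-annotation applies to negative-UTR genes only")
    p = record.tss_position
    offset = -record.utr_length
    n = len(sequence)

    if gene.strand == "+":
        edge_ok = p + 2 <= n
        codon = sequence[p - 1 : p + 2] if edge_ok else ""
    else:
        edge_ok = p - 2 >= 1
        codon = str(Seq(sequence[p - 3 : p]).reverse_complement()) if edge_ok else ""

    if not edge_ok:
        return ReannotationProposal(
            gene_id=gene.gene_id,
            annotated_cds_start=gene.cds_start,
            proposed_cds_start=gene.cds_start,
            start_codon=codon,
            offset_nt=offset,
            status="unresolved",
            reason="edge",
        )

    codon_ok = codon in ACCEPTED_START_CODONS
    frame_ok = offset % 3 == 0
    if codon_ok and frame_ok:
        return ReannotationProposal(
            gene_id=gene.gene_id,
            annotated_cds_start=gene.cds_start,
            proposed_cds_start=p,
            start_codon=codon,
            offset_nt=offset,
            status="corrected",
        )
    reasons = []
    if not codon_ok:
        reasons.append("codon:TTG" if codon == "TTG" else "codon")
    if not frame_ok:
        reasons.append("frame")
    return ReannotationProposal(
        gene_id=gene.gene_id,
        annotated_cds_start=gene.cds_start,
        proposed_cds_start=gene.cds_start,
        start_codon=codon,
        offset_nt=offset,
        status="unresolved",
        reason=",".join(reasons),
    )


def apply_reannotations(
    genes: Sequence[GeneModel], proposals: Sequence[ReannotationProposal]
) -> list[GeneModel]:
    """Return gene models with corrected proposals applied (others unchanged).

    A corrected start moves the gene's 5' boundary to the proposed position;
    the remaining ORF is an in-frame suffix of the annotated one, so no stop
    codon can be introduced.
    """
    corrected = {p.gene_id: p for p in proposals if p.status == "corrected"}
    out = []
    for g in genes:
        p = corrected.get(g.gene_id)
        if p is None:
            out.append(g)
        elif g.strand == "+":
            out.append(GeneModel(g.gene_id, "+", p.proposed_cds_start, g.end, order_index=g.order_index))
        else:
            out.append(GeneModel(g.gene_id, "-", g.start, p.proposed_cds_start, order_index=g.order_index))
    return out
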