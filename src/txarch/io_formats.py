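"""File formats and coordinate conventions.

All in-memory coordinates are 1-based inclusive, matching GFF3 and the genome
annotation frame. Conversions to/from 0-based half-open systems (bedGraph, BED)
happen only in this module, at the file boundary. Per-base depth is held in a
numpy vector where index ``i - 1`` stores genome position ``i``.

Only single-contig genomes are supported: the organisms this pipeline targets
(e.g. *Mycobacterium smegmatis* mc\\ :sup:`2`\\ 155) carry one chromosome.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

STRANDS = ("+", "-")
_IUPAC_OK = set("ACGTN")


class GffParseError(ValueError):
    """Malformed GFF3 content (carries the offending line number)."""


class FastaError(ValueError):
    """Unusable FASTA input (multi-record, empty, or non-IUPAC characters)."""


class BedGraphError(ValueError):
    """Malformed bedGraph content."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """One annotated gene.

    ``cds_start`` is the genome coordinate of the first base of the annotated
    start codon: equal to ``start`` on the + strand and to ``end`` on the
    - strand. If omitted it is derived from the strand.
    """

    gene_id: str
    strand: str
    start: int
    end: int
    cds_start: int | None = None
    order_index: int = 0

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"{self.gene_id}: strand must be + or -, got {self.strand!r}")
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")
        if self.start < 1:
            raise ValueError(f"{self.gene_id}: coordinates are 1-based, got start {self.start}")
        expected = self.start if self.strand == "+" else self.end
        if self.cds_start is None:
            object.__setattr__(self, "cds_start", expected)
        elif self.cds_start != expected:
            raise ValueError(
                f"{self.gene_id}: cds_start {self.cds_start} inconsistent with "
                f"strand {self.strand} (expected {expected})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class CoverageTrack:
    """Per-library, per-strand integer depth over the whole genome."""

    library_id: str
    phase_label: str
    replicate: int
    strand: str
    depth: np.ndarray
    total_mapped: int
    read_length: int = 100

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        self.depth = np.asarray(self.depth, dtype=np.int64)
        if self.depth.ndim != 1:
            raise ValueError("depth must be a 1-D vector")
        if (self.depth < 0).any():
            raise ValueError("depth values must be non-negative")
        if self.total_mapped <= 0:
            raise ValueError("total_mapped must be positive")
        if self.read_length <= 0:
            raise ValueError("read_length must be positive")

    @property
    def genome_length(self) -> int:
        return int(self.depth.shape[0])


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def _parse_attributes(col: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for item in col.strip().split(";"):
        item = item.strip()
        if not item or "=" not in item:
            continue
        key, _, value = item.partition("=")
        out[key.strip()] = value.strip()
    return out


def parse_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene models from a GFF3 file.

    Records of type ``gene`` are used; if the file carries none, ``CDS``
    records are used instead. Records with start > end are rejected with a
    warning and parsing continues; a duplicated identifier is an error.
    Returns genes sorted by start coordinate with ``order_index`` assigned.
    """
    by_type: dict[str, list[tuple[str, str, int, int]]] = {"gene": [], "CDS": []}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise GffParseError(f"line {lineno}: expected 9 tab-separated columns, got {len(parts)}")
            ftype = parts[2]
            if ftype not in by_type:
                continue
            try:
                start, end = int(parts[3]), int(parts[4])
            except ValueError as exc:
                raise GffParseError(f"line {lineno}: non-integer coordinates") from exc
            strand = parts[6]
            if strand not in STRANDS:
                raise GffParseError(f"line {lineno}: strand must be + or -, got {strand!r}")
            attrs = _parse_attributes(parts[8])
            gene_id = attrs.get("ID") or attrs.get("locus_tag")
            if not gene_id:
                raise GffParseError(f"line {lineno}: record carries neither ID nor locus_tag")
            if start > end:
                warnings.warn(
                    f"line {lineno}: rejected record {gene_id} with start {start} > end {end}",
                    stacklevel=2,
                )
                continue
            by_type[ftype].append((gene_id, strand, start, end))

    records = by_type["gene"] or by_type["CDS"]
    seen: set[str] = set()
    for gene_id, *_ in records:
        if gene_id in seen:
            raise GffParseError(f"duplicate gene_id {gene_id!r}")
        seen.add(gene_id)
    records.sort(key=lambda r: (r[2], r[3], r[0]))
    return [
        GeneModel(gene_id=g, strand=s, start=a, end=b, order_index=i)
        for i, (g, s, a, b) in enumerate(records)
    ]


def write_gff3(
    genes: Sequence[GeneModel],
    path: str | Path,
    chrom: str = "chr",
    source: str = "txarch",
    header_lines: Iterable[str] = (),
) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for line in header_lines:
            fh.write(f"#{line}\n")
        for g in sorted(genes, key=lambda g: (g.start, g.end)):
            fh.write(
                f"{chrom}\t{source}\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> str:
    """Read a single-contig genome; returns the uppercased sequence string."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) == 0:
        raise FastaError(f"{path}: no FASTA records found")
    if len(records) > 1:
        raise FastaError(f"{path}: expected a single contig, found {len(records)} records")
    seq = str(records[0].seq).upper()
    bad = set(seq) - _IUPAC_OK
    if bad:
        raise FastaError(f"{path}: non-IUPAC characters {sorted(bad)}")
    return seq


def write_fasta(sequence: str, path: str | Path, name: str = "chr", width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(sequence), width):
            fh.write(sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------

def read_bedgraph_vector(path: str | Path, genome_length: int) -> np.ndarray:
    """Read one bedGraph file into a 1-based depth vector (index i-1 = pos i).

    bedGraph intervals are 0-based half-open: ``[s, e)`` with value ``v`` sets
    1-based positions ``s+1 .. e``. Unspecified positions are 0. Overlapping
    intervals resolve last-writer-wins with a warning.
    """
    depth = np.zeros(genome_length, dtype=np.int64)
    written = np.zeros(genome_length, dtype=bool)
    warned = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise BedGraphError(f"{path} line {lineno}: expected 4 columns")
            try:
                s, e, v = int(parts[1]), int(parts[2]), float(parts[3])
            except ValueError as exc:
                raise BedGraphError(f"{path} line {lineno}: non-numeric field") from exc
            if e > genome_length:
                raise BedGraphError(
                    f"{path} line {lineno}: interval end {e} beyond genome length {genome_length}"
                )
            if s < 0 or s > e:
                raise BedGraphError(f"{path} line {lineno}: bad interval [{s}, {e})")
            if v < 0:
                raise BedGraphError(f"{path} line {lineno}: negative depth {v}")
            if s == e:
                continue
            if not warned and written[s:e].any():
                warnings.warn(f"{path} line {lineno}: overlapping intervals, last writer wins", stacklevel=2)
                warned = True
            depth[s:e] = int(round(v))
            written[s:e] = True
    return depth


def read_coverage_bedgraph(
    path_plus: str | Path,
    path_minus: str | Path,
    genome_length: int,
    library_id: str,
    phase_label: str = "",
    replicate: int = 1,
    total_mapped: int | None = None,
    read_length: int = 100,
) -> tuple[CoverageTrack, CoverageTrack]:
    """Read one library's strand pair of bedGraph files into CoverageTracks.

    When ``total_mapped`` is not given it is estimated from the summed depth of
    both strands divided by the read length.
    """
    plus = read_bedgraph_vector(path_plus, genome_length)
    minus = read_bedgraph_vector(path_minus, genome_length)
    if total_mapped is None:
        total_mapped = max(1, int(round((plus.sum() + minus.sum()) / read_length)))
    make = lambda strand, depth: CoverageTrack(  # noqa: E731
        library_id=library_id,
        phase_label=phase_label,
        replicate=replicate,
        strand=strand,
        depth=depth,
        total_mapped=total_mapped,
        read_length=read_length,
    )
    return make("+", plus), make("-", minus)


def write_bedgraph(track: CoverageTrack, path: str | Path, chrom: str = "chr") -> None:
    """Write a depth vector as run-length-encoded bedGraph (zero runs omitted)."""
    d = track.depth
    with open(path, "w") as fh:
        if d.size == 0:
            return
        boundaries = np.flatnonzero(np.diff(d)) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [d.size]))
        for s, e in zip(starts, ends):
            v = int(d[s])
            if v:
                fh.write(f"{chrom}\t{s}\t{e}\t{v}\n")


# ---------------------------------------------------------------------------
# BED6 for TSS calls
# ---------------------------------------------------------------------------

def write_tss_bed(calls: Sequence, path: str | Path, chrom: str = "chr") -> None:
    """Write TSS calls as BED6. A 1-based TSS at p becomes chromStart p-1, chromEnd p."""
    with open(path, "w") as fh:
        for c in calls:
            name = c.gene_id if c.gene_id is not None else "orphan"
            score = int(min(1000, max(0, round(c.step_score))))
            fh.write(f"{chrom}\t{c.position - 1}\t{c.position}\t{name}\t{score}\t{c.strand}\n")


def read_tss_bed(path: str | Path) -> list[tuple[int, str, str, int]]:
    """Read a TSS BED6 file back to 1-based (position, strand, name, score) tuples."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            out.append((int(parts[1]) + 1, parts[5], parts[3], int(parts[4])))
    return out


# ---------------------------------------------------------------------------
# provenance-stamped TSVs
# ---------------------------------------------------------------------------

def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_tsv(df: pd.DataFrame, path: str | Path, header_lines: Iterable[str] = ()) -> None:
    """Write a DataFrame as TSV with ``#``-prefixed provenance header lines."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"#{line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
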