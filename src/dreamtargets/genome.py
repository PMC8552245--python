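"""Genomic data model and text-format I/O.

All internal coordinates are 0-based half-open on every type and operation;
GFF3's 1-based closed coordinates are converted at the parse boundary and
restored on write.  This single convention is deliberate: every downstream
stage (peak calling, windowing, assignment) does interval arithmetic, and
mixing conventions is the classic source of off-by-one bugs.

Supported formats: BED3/BED6 (verbatim coordinates), GFF3 gene/mRNA models
with an auxiliary promoter BED, bedGraph coverage (expanded to per-base
arrays), and FASTA (Biopython).  Readers tolerate comment and ``track``
header lines.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GenomicInterval",
    "PeakSet",
    "GeneModel",
    "CoverageTrack",
    "load_intervals",
    "write_intervals",
    "load_gene_models",
    "write_gene_models",
    "load_promoters",
    "load_coverage",
    "write_coverage",
    "load_fasta",
    "write_fasta",
    "merge_intervals",
    "rescale_to_midpoint",
    "overlap_fraction",
    "overlap_any",
]

_STRANDS = {"+", "-", "."}


@dataclass(frozen=True)
class GenomicInterval:
    """A strand-aware half-open interval [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(f"require 0 <= start < end, got [{self.start}, {self.end})")
        if self.strand not in _STRANDS:
            raise ValueError(f"strand must be one of {_STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        # left-biased for even lengths; fixed convention
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """>= 1 bp overlap under half-open semantics."""
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


class PeakSet:
    """An ordered collection of intervals; the unit of all peak arithmetic."""

    def __init__(self, intervals=()):
        self.intervals: list[GenomicInterval] = list(intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def __getitem__(self, i):
        return self.intervals[i]

    def __eq__(self, other) -> bool:
        return isinstance(other, PeakSet) and self.intervals == other.intervals

    def __repr__(self) -> str:
        return f"PeakSet({len(self)} intervals)"

    def sorted(self) -> "PeakSet":
        return PeakSet(sorted(self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)))

    def chroms(self) -> list[str]:
        return sorted({iv.chrom for iv in self.intervals})

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [iv.chrom for iv in self.intervals],
                "start": [iv.start for iv in self.intervals],
                "end": [iv.end for iv in self.intervals],
                "name": [iv.name for iv in self.intervals],
                "score": [iv.score for iv in self.intervals],
                "strand": [iv.strand for iv in self.intervals],
            }
        )


@dataclass
class GeneModel:
    """Gene span with transcript TSS/TTS lists and optional promoters.

    TSS/TTS are strand-aware single positions (0-based): the TSS of a minus
    strand transcript is its larger coordinate.
    """

    gene_id: str
    span: GenomicInterval
    strand: str
    tss_list: list[int] = field(default_factory=list)
    tts_list: list[int] = field(default_factory=list)
    promoters: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene strand must be + or -, got {self.strand!r}")

    @property
    def tss_5prime(self) -> int:
        """The 5'-most (most upstream in transcription direction) TSS."""
        if not self.tss_list:
            raise ValueError(f"gene {self.gene_id} has no TSS")
        return min(self.tss_list) if self.strand == "+" else max(self.tss_list)

    @property
    def tts_3prime(self) -> int:
        """The 3'-most (most downstream) TTS."""
        if not self.tts_list:
            raise ValueError(f"gene {self.gene_id} has no TTS")
        return max(self.tts_list) if self.strand == "+" else min(self.tts_list)


@dataclass
class CoverageTrack:
    """Per-base (or per-bin) non-negative signal over [0, span) of a chromosome."""

    chrom: str
    values: np.ndarray
    resolution: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("coverage values must be 1-D")
        if self.values.size and (not np.all(np.isfinite(self.values)) or np.any(self.values < 0)):
            raise ValueError("coverage values must be finite and >= 0")
        if self.resolution < 1:
            raise ValueError("resolution must be >= 1 bp per bin")

    @property
    def span(self) -> int:
        return self.values.size * self.resolution


# ---------------------------------------------------------------------------
# BED


def _fmt_score(score: float | None) -> str:
    if score is None:
        return "0"
    if float(score).is_integer():
        return str(int(score))
    return format(float(score), "g")


def load_intervals(path) -> PeakSet:
    """Read a BED3/BED6 file (0-based half-open, kept verbatim)."""
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED line needs >= 3 columns: {line!r}")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            name = fields[3] if len(fields) > 3 and fields[3] != "." else (fields[3] if len(fields) > 3 else None)
            score = float(fields[4]) if len(fields) > 4 else None
            strand = fields[5] if len(fields) > 5 else "."
            intervals.append(GenomicInterval(fields[0], start, end, strand, name, score))
    return PeakSet(intervals)


def write_intervals(peaks: PeakSet, path) -> None:
    """Write canonical 6-column BED (name '.', score 0 when absent)."""
    with open(path, "w") as fh:
        for iv in peaks:
            name = iv.name if iv.name is not None else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{_fmt_score(iv.score)}\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# GFF3 + promoters


def load_gene_models(path, promoter_bed=None) -> list[GeneModel]:
    """Read gene/mRNA features from GFF3 into GeneModels.

    GFF3 1-based closed coordinates are converted to 0-based half-open.
    TSS/TTS are derived strand-aware from each mRNA; mRNAs without a parent
    gene are skipped with a warning.  An optional promoter BED (name column
    = gene id) attaches promoter intervals.
    """
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True, force=True
    )
    genes: dict[str, GeneModel] = {}
    for g in db.features_of_type("gene"):
        gid = g.id
        span = GenomicInterval(g.seqid, g.start - 1, g.end, g.strand)
        genes[gid] = GeneModel(gene_id=gid, span=span, strand=g.strand)
    for m in db.features_of_type("mRNA"):
        parents = m.attributes.get("Parent", [])
        parent = next((p for p in parents if p in genes), None)
        if parent is None:
            warnings.warn(f"mRNA {m.id} has no parent gene; skipped")
            continue
        gm = genes[parent]
        start0, end0 = m.start - 1, m.end  # half-open
        if gm.strand == "+":
            gm.tss_list.append(start0)
            gm.tts_list.append(end0 - 1)
        else:
            gm.tss_list.append(end0 - 1)
            gm.tts_list.append(start0)
    out = list(genes.values())
    if promoter_bed is not None:
        proms = load_intervals(promoter_bed)
        by_gene: dict[str, list[GenomicInterval]] = {}
        for iv in proms:
            if iv.name:
                by_gene.setdefault(iv.name, []).append(iv)
        for gm in out:
            gm.promoters = by_gene.get(gm.gene_id, [])
    return out


def write_gene_models(genes: list[GeneModel], path) -> None:
    """Write GeneModels back to GFF3 (one gene + one mRNA per TSS/TTS pair)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gm in genes:
            s = gm.span
            fh.write(
                f"{s.chrom}\tdreamtargets\tgene\t{s.start + 1}\t{s.end}\t.\t{gm.strand}\t.\tID={gm.gene_id}\n"
            )
            for i, (tss, tts) in enumerate(zip(gm.tss_list, gm.tts_list), 1):
                lo, hi = (tss, tts) if gm.strand == "+" else (tts, tss)
                fh.write(
                    f"{s.chrom}\tdreamtargets\tmRNA\t{lo + 1}\t{hi + 1}\t.\t{gm.strand}\t.\t"
                    f"ID={gm.gene_id}.t{i};Parent={gm.gene_id}\n"
                )


def load_promoters(path) -> PeakSet:
    """Promoter BED; identical to load_intervals, named for clarity."""
    return load_intervals(path)


# ---------------------------------------------------------------------------
# bedGraph


def load_coverage(path, chrom: str, length: int | None = None) -> CoverageTrack:
    """Expand a bedGraph into a per-base CoverageTrack for one chromosome.

    Records must be non-overlapping; uncovered bases are 0.  With no
    records for the chromosome an all-zero track of the declared length is
    returned.
    """
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: bedGraph line needs 4 columns")
            if fields[0] != chrom:
                continue
            rows.append((int(fields[1]), int(fields[2]), float(fields[3])))
    if not rows:
        if length is None:
            raise ValueError(f"no records for {chrom} and no declared length")
        return CoverageTrack(chrom, np.zeros(length))
    rows.sort()
    maxend = max(e for _, e, _ in rows)
    n = length if length is not None else maxend
    if maxend > n:
        raise ValueError(f"bedGraph extends past declared length ({maxend} > {n})")
    values = np.zeros(n)
    prev_end = -1
    for start, end, val in rows:
        if val < 0:
            raise ValueError(f"negative bedGraph value {val} at {chrom}:{start}-{end}")
        if start < prev_end:
            raise ValueError(f"overlapping bedGraph records near {chrom}:{start}")
        values[start:end] = val
        prev_end = end
    return CoverageTrack(chrom, values)


def write_coverage(track: CoverageTrack, path, precision: int = 6) -> None:
    """Write a CoverageTrack as run-length-encoded bedGraph (zero runs skipped)."""
    v = track.values
    with open(path, "w") as fh:
        if v.size == 0:
            return
        change = np.flatnonzero(np.diff(v)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [v.size]])
        r = track.resolution
        for s, e in zip(starts, ends):
            val = v[s]
            if val == 0:
                continue
            txt = format(val, f".{precision}g")
            fh.write(f"{track.chrom}\t{s * r}\t{e * r}\t{txt}\n")


# ---------------------------------------------------------------------------
# FASTA


def load_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# interval algebra


def merge_intervals(peaks: PeakSet) -> PeakSet:
    """Merge overlapping (and book-ended) intervals; sorted, disjoint output.

    Covered bases are conserved exactly; names/scores/strands are dropped
    from merged output (a merged region no longer belongs to one source).
    """
    if len(peaks) == 0:
        return PeakSet()
    merged: list[GenomicInterval] = []
    for iv in sorted(peaks, key=lambda p: (p.chrom, p.start, p.end)):
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return PeakSet(merged)


def rescale_to_midpoint(peaks: PeakSet, halfwidth: int = 100) -> PeakSet:
    """Standardize peaks to [mid - halfwidth, mid + halfwidth), clipped at 0.

    The midpoint is floor((start + end) / 2).  The default half-width of
    100 bp gives the fixed 200 bp windows used before counting/comparison.
    """
    if halfwidth <= 0:
        raise ValueError("halfwidth must be positive")
    out = []
    for iv in peaks:
        mid = iv.midpoint
        out.append(replace(iv, start=max(0, mid - halfwidth), end=mid + halfwidth))
    return PeakSet(out)


def _reference_index(reference: PeakSet):
    """Per-chromosome sorted merged arrays for fast any-overlap queries."""
    merged = merge_intervals(reference)
    idx: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for iv in merged:
        idx.setdefault(iv.chrom, ([], []))  # type: ignore[arg-type]
    bych: dict[str, list[GenomicInterval]] = {}
    for iv in merged:
        bych.setdefault(iv.chrom, []).append(iv)
    return {
        ch: (np.array([iv.start for iv in ivs]), np.array([iv.end for iv in ivs]))
        for ch, ivs in bych.items()
    }


def overlap_any(query: PeakSet, reference: PeakSet) -> np.ndarray:
    """Boolean array: does each query interval overlap >= 1 bp of reference?"""
    idx = _reference_index(reference)
    out = np.zeros(len(query), dtype=bool)
    for i, iv in enumerate(query):
        if iv.chrom not in idx:
            continue
        starts, ends = idx[iv.chrom]
        j = np.searchsorted(starts, iv.end)  # candidates with start < iv.end
        out[i] = j > 0 and ends[j - 1] > iv.start
    return out


def overlap_fraction(query: PeakSet, reference: PeakSet) -> float:
    """Fraction of query intervals overlapping >= 1 bp of any reference interval."""
    if len(query) == 0:
        warnings.warn("overlap_fraction: empty query; returning 0.0")
        return 0.0
    return float(overlap_any(query, reference).mean())
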