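"""Standard-format I/O and the genome <-> transcript coordinate bridge.

All internal coordinates are 0-based half-open (BED convention). GFF3 rows
(1-based closed) are shifted at the format boundary only, so a GFF ``start``
of 10 becomes internal start 9. Dense per-chromosome arrays back the coverage
and score tracks; the synthetic genomes this package analyses are small
enough that positional random access into a plain ``numpy`` array is the
simplest correct contract.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd

#: Araport-style long-noncoding feature types collapsed into one group for
#: all lncRNA analyses.
LNCRNA_TYPES = frozenset({"lncRNA", "antisense_lncRNA", "antisense_RNA", "ncRNA"})

MRNA_BIOTYPE = "mRNA"
LNCRNA_BIOTYPE = "lncRNA-like"


class ParseError(ValueError):
    """Malformed record in an input file."""


class AnnotationError(ValueError):
    """Structurally invalid gene model (e.g. CDS outside exons)."""


# ---------------------------------------------------------------------------
# Intervals
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Interval:
    """Strand-aware genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ParseError(
                f"interval {self.chrom}:{self.start}-{self.end} has start >= end"
            )
        if self.strand not in ("+", "-", "."):
            raise ParseError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def strands_compatible(self, other: "Interval") -> bool:
        return self.strand == "." or other.strand == "." or self.strand == other.strand

    def overlaps(self, other: "Interval") -> bool:
        """True if the two intervals share >= 1 nucleotide."""
        return (
            self.chrom == other.chrom
            and self.strands_compatible(other)
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class IntervalSet:
    """Ordered collection of :class:`Interval` with a provenance label."""

    intervals: list[Interval] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[Interval]:
        return iter(self.intervals)

    def __getitem__(self, i) -> Interval:
        return self.intervals[i]

    def total_nucleotides(self) -> int:
        return sum(iv.length for iv in self.intervals)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (iv.chrom, iv.start, iv.end, iv.name, iv.score, iv.strand)
                for iv in self.intervals
            ],
            columns=["chrom", "start", "end", "name", "score", "strand"],
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, provenance: dict | None = None) -> "IntervalSet":
        ivs = [
            Interval(str(r.chrom), int(r.start), int(r.end), str(r.name), float(r.score), str(r.strand))
            for r in df.itertuples(index=False)
        ]
        return cls(ivs, provenance or {})


# ---------------------------------------------------------------------------
# Transcript models
# ---------------------------------------------------------------------------


@dataclass
class TranscriptModel:
    """Spliced gene model with UTR/CDS/intron segmentation.

    ``exons`` are genomic intervals sorted by genomic start; ``cds_span`` is
    the genomic (start, end) of the coding region for mRNAs and ``None`` for
    lncRNA-like models. Transcript space is spliced, 5'->3' (reversed for
    minus-strand models).
    """

    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_span: tuple[int, int] | None = None
    biotype: str = MRNA_BIOTYPE

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"{self.transcript_id}: strand must be + or -")
        self.exons = sorted((int(s), int(e)) for s, e in self.exons)
        for (s, e) in self.exons:
            if s >= e:
                raise AnnotationError(f"{self.transcript_id}: empty exon {s}-{e}")
        for (_, e0), (s1, _) in zip(self.exons, self.exons[1:]):
            if s1 < e0:
                raise AnnotationError(f"{self.transcript_id}: overlapping exons")
        if self.biotype == LNCRNA_BIOTYPE and self.cds_span is not None:
            raise AnnotationError(f"{self.transcript_id}: lncRNA-like model has a CDS")
        if self.cds_span is not None:
            cs, ce = self.cds_span
            if (
                self._exonic_overlap(cs, ce) == 0
                or cs < self.exons[0][0]
                or ce > self.exons[-1][1]
            ):
                raise AnnotationError(f"{self.transcript_id}: CDS outside exons")

    def _exonic_overlap(self, start: int, end: int) -> int:
        return sum(max(0, min(e, end) - max(s, start)) for s, e in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def spliced_positions(self) -> np.ndarray:
        """Genomic coordinates of spliced nucleotides in 5'->3' order."""
        pos = np.concatenate([np.arange(s, e) for s, e in self.exons])
        return pos[::-1] if self.strand == "-" else pos

    # -- region lengths ----------------------------------------------------

    def _cds_mask(self) -> np.ndarray:
        pos = self.spliced_positions()
        cs, ce = self.cds_span  # type: ignore[misc]
        return (pos >= cs) & (pos < ce)

    @property
    def cds_len(self) -> int:
        if self.cds_span is None:
            return 0
        return int(self._cds_mask().sum())

    @property
    def utr5_len(self) -> int:
        if self.cds_span is None:
            return 0
        return int(np.argmax(self._cds_mask()))

    @property
    def utr3_len(self) -> int:
        if self.cds_span is None:
            return 0
        return self.spliced_length - self.utr5_len - self.cds_len

    # -- coordinate bridges ------------------------------------------------

    def genomic_to_transcript(self, track) -> np.ndarray:
        """Project a genomic track onto the spliced transcript, 5'->3'.

        ``track`` may be a per-chromosome array mapping, a LibraryTrack or a
        ScoreTrack. Introns are dropped; minus-strand output is reversed.
        """
        data = getattr(track, "data", track)
        arr = np.asarray(data[self.chrom])
        vals = np.concatenate([arr[s:e] for s, e in self.exons])
        return vals[::-1] if self.strand == "-" else vals

    def transcript_to_genomic(self, t_start: int, t_end: int) -> list[tuple[int, int]]:
        """Map a transcript-space interval back to genomic exonic blocks."""
        pos = self.spliced_positions()[t_start:t_end]
        if pos.size == 0:
            return []
        pos = np.sort(pos)
        breaks = np.where(np.diff(pos) != 1)[0]
        starts = np.concatenate([[pos[0]], pos[breaks + 1]])
        ends = np.concatenate([pos[breaks] + 1, [pos[-1] + 1]])
        return [(int(s), int(e)) for s, e in zip(starts, ends)]

    # -- segmentation ------------------------------------------------------

    def segments(self) -> list[tuple[str, int, int]]:
        """Genomic (label, start, end) feature segments.

        mRNAs yield 5'UTR / CDS / 3'UTR exonic blocks plus introns; lncRNA-like
        models yield 'lncRNA' exon blocks plus introns.
        """
        out: list[tuple[str, int, int]] = []
        for (_, e0), (s1, _) in zip(self.exons, self.exons[1:]):
            out.append(("intron", e0, s1))
        if self.cds_span is None:
            out.extend(("lncRNA", s, e) for s, e in self.exons)
            return out
        cs, ce = self.cds_span
        left, right = ("5UTR", "3UTR") if self.strand == "+" else ("3UTR", "5UTR")
        for s, e in self.exons:
            if e <= cs:
                out.append((left, s, e))
            elif s >= ce:
                out.append((right, s, e))
            else:
                if s < cs:
                    out.append((left, s, cs))
                out.append(("CDS", max(s, cs), min(e, ce)))
                if e > ce:
                    out.append((right, ce, e))
        return out


def chrom_sizes(annotation: Sequence[TranscriptModel], margin: int = 200) -> dict[str, int]:
    """Chromosome lengths implied by an annotation (max end + margin)."""
    sizes: dict[str, int] = {}
    for m in annotation:
        sizes[m.chrom] = max(sizes.get(m.chrom, 0), m.span[1] + margin)
    return sizes


# ---------------------------------------------------------------------------
# Tracks
# ---------------------------------------------------------------------------


@dataclass
class LibraryTrack:
    """Per-nucleotide read coverage for one sequencing library.

    ``rnase`` is the nuclease applied ('ds' or 'ss'); ``sample_type`` is
    'footprint' (protein present during digestion) or 'structure_only'
    (proteinase K first). Note that the ssRNase-treated library reads out
    double-stranded RNA (dsRNA-seq) and vice versa.
    """

    data: dict[str, np.ndarray]
    condition: str = ""
    replicate: int = 0
    rnase: str = ""
    sample_type: str = ""

    def __post_init__(self) -> None:
        for chrom, arr in self.data.items():
            if np.any(np.asarray(arr) < 0):
                raise ValueError(f"negative coverage on {chrom}")

    def total(self) -> int:
        return int(sum(int(np.sum(a)) for a in self.data.values()))


@dataclass
class ScoreTrack:
    """Per-nucleotide real-valued track; NaN marks undefined positions."""

    data: dict[str, np.ndarray]
    kind: str = "score"

    def defined_fraction(self) -> float:
        tot = sum(a.size for a in self.data.values())
        ok = sum(int(np.sum(~np.isnan(a))) for a in self.data.values())
        return ok / tot if tot else 0.0


def coverage_from_reads(reads: IntervalSet, sizes: Mapping[str, int]) -> dict[str, np.ndarray]:
    """Per-nucleotide coverage arrays from aligned-read intervals."""
    cov = {c: np.zeros(n, dtype=np.int64) for c, n in sizes.items()}
    for r in reads:
        a = cov[r.chrom]
        a[max(0, r.start) : min(len(a), r.end)] += 1
    return cov


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------


def _open(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_intervals(path, provenance: dict | None = None) -> IntervalSet:
    """Read a BED6 (or BED3/4/5) file into an IntervalSet."""
    ivs: list[Interval] = []
    with _open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 BED fields")
            try:
                ivs.append(
                    Interval(
                        f[0],
                        int(f[1]),
                        int(f[2]),
                        f[3] if len(f) > 3 else ".",
                        float(f[4]) if len(f) > 4 else 0.0,
                        f[5] if len(f) > 5 else ".",
                    )
                )
            except (ValueError, ParseError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return IntervalSet(ivs, provenance or {"path": str(path)})


def write_intervals(intervals: IntervalSet | Iterable[Interval], path) -> None:
    with _open(path, "wt") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{iv.score:g}\t{iv.strand}\n"
            )


def read_bedgraph(path, sizes: Mapping[str, int] | None = None) -> dict[str, np.ndarray]:
    """Read a bedGraph into dense per-chromosome arrays.

    If ``sizes`` is omitted, chromosome lengths are inferred from the maximum
    end coordinate present.
    """
    rows: list[tuple[str, int, int, float]] = []
    with _open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 bedGraph fields")
            try:
                start, end, value = int(f[1]), int(f[2]), float(f[3])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if start >= end:
                raise ParseError(f"{path}:{lineno}: start >= end")
            rows.append((f[0], start, end, value))
    if sizes is None:
        sizes = {}
        for chrom, _, end, _ in rows:
            sizes[chrom] = max(sizes.get(chrom, 0), end)
    out = {c: np.zeros(n, dtype=float) for c, n in sizes.items()}
    for chrom, start, end, value in rows:
        out[chrom][start:end] = value
    return out


def write_bedgraph(data: Mapping[str, np.ndarray], path) -> None:
    """Write dense arrays as run-length-encoded bedGraph (zero runs skipped)."""
    with _open(path, "wt") as fh:
        for chrom in sorted(data):
            arr = np.asarray(data[chrom])
            if arr.size == 0:
                continue
            change = np.where(np.diff(arr) != 0)[0]
            starts = np.concatenate([[0], change + 1])
            ends = np.concatenate([change + 1, [arr.size]])
            for s, e in zip(starts, ends):
                v = arr[s]
                if v == 0 or np.isnan(v):
                    continue
                fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def read_table(path, **kwargs) -> pd.DataFrame:
    """Read a TSV table (first column becomes the index by default)."""
    kwargs.setdefault("sep", "\t")
    kwargs.setdefault("index_col", 0)
    return pd.read_csv(path, **kwargs)


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_TRANSCRIPT_TYPES = frozenset({"mRNA"}) | LNCRNA_TYPES


def read_annotation(path) -> list[TranscriptModel]:
    """Parse GFF3/GTF transcript models (via gffutils).

    Araport-style noncoding types (lncRNA, antisense_lncRNA, antisense_RNA,
    ncRNA) are collapsed to the single lncRNA-like biotype.
    """
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # gffutils raises assorted types on bad input
        raise ParseError(f"{path}: {exc}") from exc

    models: list[TranscriptModel] = []
    for ftype in sorted(_TRANSCRIPT_TYPES):
        for feat in db.features_of_type(ftype):
            exons = [
                (c.start - 1, c.end)
                for c in db.children(feat, featuretype="exon")
            ]
            if not exons:
                exons = [(feat.start - 1, feat.end)]
            cds = [(c.start - 1, c.end) for c in db.children(feat, featuretype="CDS")]
            cds_span = (min(s for s, _ in cds), max(e for _, e in cds)) if cds else None
            biotype = MRNA_BIOTYPE if ftype == "mRNA" else LNCRNA_BIOTYPE
            if biotype == LNCRNA_BIOTYPE:
                cds_span = None
            models.append(
                TranscriptModel(
                    transcript_id=feat.id,
                    chrom=feat.seqid,
                    strand=feat.strand,
                    exons=exons,
                    cds_span=cds_span,
                    biotype=biotype,
                )
            )
    models.sort(key=lambda m: (m.chrom, m.span[0], m.transcript_id))
    return models


def write_annotation(annotation: Sequence[TranscriptModel], path) -> None:
    """Write transcript models as GFF3 (1-based closed at the boundary)."""
    with _open(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for m in sorted(annotation, key=lambda m: (m.chrom, m.span[0], m.transcript_id)):
            ftype = "mRNA" if m.biotype == MRNA_BIOTYPE else "lncRNA"
            s, e = m.span
            fh.write(
                f"{m.chrom}\tpipseq\t{ftype}\t{s + 1}\t{e}\t.\t{m.strand}\t.\t"
                f"ID={m.transcript_id}\n"
            )
            for i, (xs, xe) in enumerate(m.exons, 1):
                fh.write(
                    f"{m.chrom}\tpipseq\texon\t{xs + 1}\t{xe}\t.\t{m.strand}\t.\t"
                    f"ID={m.transcript_id}.exon{i};Parent={m.transcript_id}\n"
                )
            if m.cds_span is not None:
                cs, ce = m.cds_span
                for i, (xs, xe) in enumerate(m.exons, 1):
                    os_, oe = max(xs, cs), min(xe, ce)
                    if os_ < oe:
                        fh.write(
                            f"{m.chrom}\tpipseq\tCDS\t{os_ + 1}\t{oe}\t.\t{m.strand}\t0\t"
                            f"ID={m.transcript_id}.cds{i};Parent={m.transcript_id}\n"
                        )


def write_json(obj, path) -> None:
    with _open(path, "wt") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")
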