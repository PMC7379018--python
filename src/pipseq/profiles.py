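"""Metagene and peak-centered profile construction.

A profile is a transcripts x positions matrix of occupancy (0/1) or score
values, aligned on a common anchor (start/stop codon), binned to a fixed
number of bins per region, or centered on peaks with equal-length flanks.
Windows extending past a transcript end contribute undefined entries (NaN),
never genomic intronic/intergenic signal. Occupancy profiles are plotted
with the most-bound position normalized to 1.0 within each declared window;
the same machinery serves PPS occupancy and m6A density.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .genome_io import (
    Interval,
    IntervalSet,
    LibraryTrack,
    LNCRNA_BIOTYPE,
    MRNA_BIOTYPE,
    ScoreTrack,
    TranscriptModel,
)

logger = logging.getLogger(__name__)

#: expression filters: minimum total reads per library, per biotype
MIN_READS_MRNA = 50
MIN_READS_LNCRNA = 5
MIN_UTR5 = 45
MIN_UTR3 = 140


class ShuffleError(RuntimeError):
    """Shuffling could not place all peaks under the constraints."""


@dataclass
class ProfileMatrix:
    """Rows = transcripts/peaks, columns = positions or bins; NaN = undefined."""

    matrix: np.ndarray
    anchor: str
    row_ids: list[str] = field(default_factory=list)
    normalization: str | None = None

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    def n(self) -> np.ndarray:
        """Defined entries per column."""
        return np.sum(~np.isnan(self.matrix), axis=0)

    def mean(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            n = self.n()
            s = np.nansum(self.matrix, axis=0)
            return np.where(n > 0, s / np.maximum(n, 1), np.nan)

    def sem(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            n = self.n().astype(float)
            sd = np.nanstd(self.matrix, axis=0, ddof=0)
            return np.where(n > 0, sd / np.sqrt(np.maximum(n, 1.0)), np.nan)

    def max_normalized(self, window: slice | None = None) -> "ProfileMatrix":
        """Scale so the max of the mean profile within the window is 1.0."""
        mean = self.mean()
        sub = mean[window] if window is not None else mean
        peak = np.nanmax(sub) if np.any(~np.isnan(sub)) else np.nan
        if not np.isfinite(peak) or peak == 0:
            return ProfileMatrix(self.matrix.copy(), self.anchor, list(self.row_ids),
                                 self.normalization)
        return ProfileMatrix(self.matrix / peak, self.anchor, list(self.row_ids),
                             "max-1.0")


# ---------------------------------------------------------------------------
# Expression filtering and occupancy
# ---------------------------------------------------------------------------


def filter_expressed(
    annotation: Sequence[TranscriptModel],
    libraries: Sequence[LibraryTrack],
    biotype: str = MRNA_BIOTYPE,
) -> list[TranscriptModel]:
    """Transcripts passing the metagene expression filters.

    mRNAs need >= 50 reads in every library plus a >= 45 nt 5'UTR and
    >= 140 nt 3'UTR; lncRNA-like transcripts need >= 5 reads in every
    library. Both bounds are inclusive.
    """
    min_reads = MIN_READS_MRNA if biotype == MRNA_BIOTYPE else MIN_READS_LNCRNA
    out = []
    for m in annotation:
        if m.biotype != biotype:
            continue
        if biotype == MRNA_BIOTYPE and (m.utr5_len < MIN_UTR5 or m.utr3_len < MIN_UTR3):
            continue
        totals = (int(np.sum(m.genomic_to_transcript(lib))) for lib in libraries)
        if all(t >= min_reads for t in totals):
            out.append(m)
    return out


def occupancy_track(
    intervals: IntervalSet | Sequence[Interval], sizes: Mapping[str, int]
) -> ScoreTrack:
    """0/1 per-nucleotide occupancy: 1 wherever >= 1 interval covers the base."""
    data = {c: np.zeros(n, dtype=float) for c, n in sizes.items()}
    for iv in intervals:
        data[iv.chrom][iv.start : iv.end] = 1.0
    return ScoreTrack(data, kind="occupancy")


# ---------------------------------------------------------------------------
# Anchored and binned profiles
# ---------------------------------------------------------------------------


def anchored_profile(
    track: ScoreTrack,
    transcripts: Sequence[TranscriptModel],
    anchor: str = "start",
    flank: int = 100,
    max_normalize: bool = False,
) -> ProfileMatrix:
    """Transcript-space rows aligned on the first nucleotide of the start
    (or stop) codon, spanning +/- ``flank`` nt.

    Positions beyond a transcript end are NaN. With ``max_normalize`` the
    window's most-occupied position is scaled to 1.0 (occupancy profiles).
    """
    if anchor not in ("start", "stop"):
        raise ValueError("anchor must be 'start' or 'stop'")
    width = 2 * flank + 1
    rows = np.full((len(transcripts), width), np.nan)
    ids = []
    for i, m in enumerate(transcripts):
        if m.cds_span is None:
            raise ValueError(f"{m.transcript_id}: anchored profiles need a CDS")
        vals = m.genomic_to_transcript(track)
        a = m.utr5_len if anchor == "start" else m.utr5_len + m.cds_len - 3
        lo, hi = a - flank, a + flank + 1
        src_lo, src_hi = max(lo, 0), min(hi, vals.size)
        rows[i, src_lo - lo : src_hi - lo] = vals[src_lo:src_hi]
        ids.append(m.transcript_id)
    pm = ProfileMatrix(rows, anchor, ids)
    return pm.max_normalized() if max_normalize else pm


def bin_array(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Floor-partition binning: bin b averages [floor(bL/n), floor((b+1)L/n)).

    Regions shorter than the bin count repeat single positions so the output
    always has ``n_bins`` entries; all-undefined bins stay NaN.
    """
    values = np.asarray(values, dtype=float)
    L = values.size
    if L == 0:
        return np.full(n_bins, np.nan)
    out = np.empty(n_bins)
    for b in range(n_bins):
        lo = (b * L) // n_bins
        hi = ((b + 1) * L) // n_bins
        if hi > lo:
            chunk = values[lo:hi]
            out[b] = np.nanmean(chunk) if np.any(~np.isnan(chunk)) else np.nan
        else:
            out[b] = values[min(lo, L - 1)]
    return out


def binned_profile(
    values_per_row: Sequence,
    scheme: str = "whole-100",
    n_bins: int = 100,
    row_ids: Sequence[str] | None = None,
    max_normalize: bool = False,
) -> ProfileMatrix:
    """Fixed-bin profile rows.

    ``scheme='whole-100'`` takes one array per row and bins it; the
    ``'utr5-cds-utr3-100-each'`` scheme takes (utr5, cds, utr3) array triples
    and concatenates the three binned regions.
    """
    rows = []
    for item in values_per_row:
        if scheme == "whole-100":
            rows.append(bin_array(np.asarray(item, dtype=float), n_bins))
        elif scheme == "utr5-cds-utr3-100-each":
            rows.append(np.concatenate([bin_array(np.asarray(part, dtype=float), n_bins)
                                        for part in item]))
        else:
            raise ValueError(f"unknown scheme {scheme!r}")
    mat = np.vstack(rows) if rows else np.empty((0, n_bins))
    pm = ProfileMatrix(mat, "binned", list(row_ids or []))
    return pm.max_normalized() if max_normalize else pm


def zscore_window(values: np.ndarray, window: slice | None = None) -> np.ndarray:
    """Z-score a mean profile with respect to the graphed window.

    Statistics (population convention) come from the window's defined
    entries and are applied to the whole array; zero spread maps to zeros.
    """
    values = np.asarray(values, dtype=float)
    sub = values[window] if window is not None else values
    ok = ~np.isnan(sub)
    if not ok.any():
        return np.full_like(values, np.nan)
    mu = sub[ok].mean()
    sd = sub[ok].std(ddof=0)
    if sd == 0:
        return np.where(np.isnan(values), np.nan, 0.0)
    return (values - mu) / sd


# ---------------------------------------------------------------------------
# Peak-centered profiles and shuffled controls
# ---------------------------------------------------------------------------


def peak_centered_profile(
    peaks: IntervalSet | Sequence[Interval],
    track: ScoreTrack,
    n_bins: int = 20,
    max_normalize: bool = False,
) -> ProfileMatrix:
    """[5' flank | peak | 3' flank] rows, flanks of the peak's own length,
    each third binned to ``n_bins``.

    Peaks whose flanks cross a chromosome edge are dropped with a log record.
    Minus-strand peaks are reported 5'->3'.
    """
    rows, ids = [], []
    for iv in peaks:
        arr = track.data[iv.chrom]
        L = iv.length
        if iv.start - L < 0 or iv.end + L > arr.size:
            logger.warning("dropping peak %s at %s:%d-%d (chromosome edge)",
                           iv.name, iv.chrom, iv.start, iv.end)
            continue
        seg = np.array(arr[iv.start - L : iv.end + L], dtype=float)
        if iv.strand == "-":
            seg = seg[::-1]
        rows.append(np.concatenate([bin_array(seg[:L], n_bins),
                                    bin_array(seg[L : 2 * L], n_bins),
                                    bin_array(seg[2 * L :], n_bins)]))
        ids.append(iv.name)
    mat = np.vstack(rows) if rows else np.empty((0, 3 * n_bins))
    pm = ProfileMatrix(mat, "peak-centered", ids)
    return pm.max_normalized() if max_normalize else pm


def shuffle_peaks(
    peaks: IntervalSet | Sequence[Interval],
    genes: IntervalSet | Sequence[Interval],
    seed: int,
    max_attempts: int = 1000,
) -> IntervalSet:
    """Random non-overlapping relocation of peaks within genes.

    Each shuffled peak keeps its length and chromosome, lands wholly inside a
    gene interval (uniform over feasible placements by rejection sampling),
    and overlaps no other shuffled peak. Raises :class:`ShuffleError` naming
    the chromosome when a peak cannot be placed.
    """
    rng = np.random.default_rng(seed)
    genes_by_chrom: dict[str, list[Interval]] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.chrom, []).append(g)
    placed: dict[str, list[tuple[int, int]]] = {}
    out: list[Interval] = []
    for iv in peaks:
        L = iv.length
        cands = [g for g in genes_by_chrom.get(iv.chrom, []) if g.length >= L]
        if not cands:
            raise ShuffleError(f"no gene on {iv.chrom} can hold a {L} nt peak")
        weights = np.array([g.length - L + 1 for g in cands], dtype=float)
        weights /= weights.sum()
        taken = placed.setdefault(iv.chrom, [])
        for _ in range(max_attempts):
            g = cands[int(rng.choice(len(cands), p=weights))]
            s = int(rng.integers(g.start, g.end - L + 1))
            e = s + L
            if all(e <= ts or s >= te for ts, te in taken):
                taken.append((s, e))
                out.append(Interval(iv.chrom, s, e, iv.name, iv.score, iv.strand))
                break
        else:
            raise ShuffleError(f"could not place peak {iv.name} on {iv.chrom} "
                               f"after {max_attempts} attempts")
    return IntervalSet(out, {"type": "shuffled"})
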