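"""Per-nucleotide RNA secondary-structure scores from paired nuclease libraries.

The structure score at nucleotide i is the generalized-log ratio of coverage
in the dsRNA-seq library (ssRNase-treated, reads out paired RNA) to the
ssRNA-seq library (dsRNase-treated, reads out unpaired RNA):

    S_i = glog(ds_i) - glog(ss_i),    glog(x) = log2(x + sqrt(1 + x^2))

where ds_i = n_ds,i * max(L_ds, L_ss) / L_ds (and symmetrically for ss),
L being the total genome-wide covered length (positions with >= 1 read) of
each library. Positive S means likely double-stranded. Positions with zero
coverage in both libraries carry the undefined marker (NaN) and are excluded
from every mean downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .genome_io import LibraryTrack, ScoreTrack, TranscriptModel

REGIONS = ("utr5", "cds", "utr3", "transcript")


def glog(x):
    """Generalized log2: glog(x) = log2(x + sqrt(1 + x^2)); glog(0) = 0."""
    x = np.asarray(x, dtype=float)
    return np.log2(x + np.sqrt(1.0 + x * x))


@dataclass
class StructureScoreSet:
    """Raw and (optionally) standardized structure scores plus coverage stats."""

    raw: dict[str, np.ndarray]
    l_ds: int
    l_ss: int
    standardized: dict[str, np.ndarray] | None = None
    condition: str = ""

    def raw_track(self) -> ScoreTrack:
        return ScoreTrack(self.raw, kind="structure_score")

    def standardized_track(self) -> ScoreTrack:
        if self.standardized is None:
            raise ValueError("scores have not been standardized")
        return ScoreTrack(self.standardized, kind="structure_score_std")


def structure_score(ds: LibraryTrack, ss: LibraryTrack) -> StructureScoreSet:
    """Raw glog-ratio structure scores from a dsRNA-seq / ssRNA-seq pair.

    ``ds`` must be the ssRNase-treated (dsRNA-seq) library and ``ss`` the
    dsRNase-treated (ssRNA-seq) one; positions uncovered in both are NaN.
    """
    l_ds = sum(int(np.count_nonzero(a)) for a in ds.data.values())
    l_ss = sum(int(np.count_nonzero(a)) for a in ss.data.values())
    if l_ds == 0 and l_ss == 0:
        raise ValueError("both libraries are empty")
    l_max = max(l_ds, l_ss)
    raw: dict[str, np.ndarray] = {}
    for chrom, nds in ds.data.items():
        nds = np.asarray(nds, dtype=float)
        nss = np.asarray(ss.data[chrom], dtype=float)
        if nds.shape != nss.shape:
            raise ValueError(f"track length mismatch on {chrom}")
        ds_i = nds * (l_max / l_ds) if l_ds else np.zeros_like(nds)
        ss_i = nss * (l_max / l_ss) if l_ss else np.zeros_like(nss)
        s = glog(ds_i) - glog(ss_i)
        s[(nds + nss) == 0] = np.nan
        raw[chrom] = s
    return StructureScoreSet(raw, l_ds, l_ss, condition=ds.condition)


def _zscore(values: np.ndarray) -> np.ndarray:
    """Population z-score over defined entries; zero-sd windows map to 0."""
    out = np.full(values.shape, np.nan)
    ok = ~np.isnan(values)
    if not ok.any():
        return out
    mu = values[ok].mean()
    sd = values[ok].std(ddof=0)
    out[ok] = 0.0 if sd == 0 else (values[ok] - mu) / sd
    return out


def standardize(
    scores: StructureScoreSet,
    annotation: Sequence[TranscriptModel],
    scope: str = "transcript",
) -> StructureScoreSet:
    """Standardize raw scores to normalize by read coverage.

    ``scope='transcript'`` z-scores within each spliced transcript (the
    default); ``scope='global'`` z-scores over all defined positions at once.
    Positions outside any transcript remain undefined under transcript scope.
    """
    if scope not in ("transcript", "global"):
        raise ValueError("scope must be 'transcript' or 'global'")
    std = {c: np.full(a.shape, np.nan) for c, a in scores.raw.items()}
    if scope == "global":
        flat = np.concatenate([scores.raw[c] for c in sorted(scores.raw)])
        z = _zscore(flat)
        i = 0
        for c in sorted(scores.raw):
            n = scores.raw[c].size
            std[c] = z[i : i + n]
            i += n
    else:
        for m in annotation:
            pos = m.spliced_positions()
            vals = scores.raw[m.chrom][pos]
            scores_z = _zscore(vals)
            std[m.chrom][pos] = scores_z
    return StructureScoreSet(
        scores.raw, scores.l_ds, scores.l_ss, standardized=std,
        condition=scores.condition,
    )


def normalize_by_transcript_mean(
    scores: ScoreTrack | Mapping[str, np.ndarray],
    model: TranscriptModel,
    mode: str = "subtract",
) -> np.ndarray:
    """Transcript-space profile values normalized by the transcript mean.

    Scores are log-scale, so the default removes the mean by subtraction;
    ``mode='divide'`` is available for the ratio reading. Undefined positions
    stay NaN and are ignored in the mean.
    """
    vals = model.genomic_to_transcript(scores)
    mu = np.nanmean(vals) if np.any(~np.isnan(vals)) else np.nan
    if mode == "subtract":
        return vals - mu
    if mode == "divide":
        return vals / mu if mu != 0 else np.full_like(vals, np.nan)
    raise ValueError("mode must be 'subtract' or 'divide'")


@dataclass
class RegionStructure:
    """Per-transcript mean structure score by region for one condition."""

    transcript_id: str
    condition: str
    means: dict[str, float] = field(default_factory=dict)


@dataclass
class RegionFoldChange:
    """Salt-minus-control change of region-mean structure scores."""

    transcript_id: str
    fold_change: dict[str, float] = field(default_factory=dict)
    classes: dict[str, str] = field(default_factory=dict)


def region_average(
    scores: StructureScoreSet | ScoreTrack,
    model: TranscriptModel,
    condition: str | None = None,
) -> RegionStructure:
    """Mean score over 5'UTR / CDS / 3'UTR / whole spliced transcript.

    Uses standardized scores when a StructureScoreSet with them is given.
    Regions with no defined position get NaN.
    """
    if isinstance(scores, StructureScoreSet):
        track = scores.standardized_track() if scores.standardized is not None else scores.raw_track()
        condition = condition or scores.condition
    else:
        track = scores
    vals = model.genomic_to_transcript(track)
    u5, cds = model.utr5_len, model.cds_len

    def mean_of(a: np.ndarray) -> float:
        return float(np.nanmean(a)) if np.any(~np.isnan(a)) else math.nan

    means = {"transcript": mean_of(vals)}
    if model.cds_span is not None:
        means["utr5"] = mean_of(vals[:u5])
        means["cds"] = mean_of(vals[u5 : u5 + cds])
        means["utr3"] = mean_of(vals[u5 + cds :])
    return RegionStructure(model.transcript_id, condition or "", means)


def structure_fold_change(
    control: RegionStructure, salt: RegionStructure
) -> RegionFoldChange:
    """Region-wise structure change, salt minus control.

    Scores are already log-scale, so the log2 ratio of region averages is the
    difference of means. FC > 0 is classed 'greater-in-salt', < 0
    'lower-in-salt', exactly 0 'unchanged'; NaN propagates.
    """
    if control.transcript_id != salt.transcript_id:
        raise ValueError("transcript mismatch")
    fc: dict[str, float] = {}
    cls: dict[str, str] = {}
    for region in control.means:
        d = salt.means.get(region, math.nan) - control.means[region]
        fc[region] = d
        if math.isnan(d):
            cls[region] = "undefined"
        elif d > 0:
            cls[region] = "greater-in-salt"
        elif d < 0:
            cls[region] = "lower-in-salt"
        else:
            cls[region] = "unchanged"
    return RegionFoldChange(control.transcript_id, fc, cls)


def fold_constraints(
    scores: np.ndarray, paired_above: float = 2.0, unpaired_below: float = -0.5
) -> str:
    """Folding-constraint string from per-nucleotide structure scores.

    Strictly above ``paired_above`` -> '|' (force double-stranded), strictly
    below ``unpaired_below`` -> 'x' (force single-stranded), anything else
    (boundaries and undefined included) -> '.'. The dialect matches RNAfold's
    constraint notation.
    """
    out = []
    for v in np.asarray(scores, dtype=float):
        if np.isnan(v):
            out.append(".")
        elif v > paired_above:
            out.append("|")
        elif v < unpaired_below:
            out.append("x")
        else:
            out.append(".")
    return "".join(out)
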