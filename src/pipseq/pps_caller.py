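"""Protein-protected site (PPS) calling and interval classification.

The caller compares per-nucleotide coverage of a footprint library (nuclease
digestion with proteins present) to its matched structure-only library
(proteins removed first). Each position gets an enrichment score
-log10 P(Poisson(structure-only + pseudocount) >= footprint); a label-swap
permutation of the pair provides the null score distribution, and the call
threshold is the smallest score at which the estimated false discovery rate
(#null >= t) / (#observed >= t) drops to the requested level (5% by default).
Runs of above-threshold positions become PPS intervals; intervals sharing at
least one nucleotide are merged, required in both replicates for
high-confidence status, and classified as condition-specific or shared by
>= 1-nt overlap across conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

from .genome_io import (
    Interval,
    IntervalSet,
    LibraryTrack,
    ScoreTrack,
    TranscriptModel,
)

_LN10 = math.log(10.0)


@dataclass
class EnrichmentTrack:
    """Per-nucleotide -log10 upper-tail Poisson p-values (0 where coverage 0)."""

    data: dict[str, np.ndarray]
    footprint_meta: dict = field(default_factory=dict)
    structure_meta: dict = field(default_factory=dict)

    def flat(self) -> np.ndarray:
        return np.concatenate([self.data[c] for c in sorted(self.data)])


@dataclass
class PPSCallSet:
    intervals: IntervalSet
    fdr_threshold: float | None = None
    label: str = "replicate-level"

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)


# ---------------------------------------------------------------------------
# Depth equalization
# ---------------------------------------------------------------------------


def equalize_depth(
    lib_a: IntervalSet, lib_b: IntervalSet, seed: int
) -> tuple[IntervalSet, IntervalSet]:
    """Randomly downsample the larger read set to the size of the smaller.

    Simple random sampling without replacement, seeded; read order within the
    kept subset is preserved.
    """
    if len(lib_a) == 0 or len(lib_b) == 0:
        raise ValueError("cannot equalize an empty library")
    n = min(len(lib_a), len(lib_b))
    rng = np.random.default_rng(seed)

    def sub(lib: IntervalSet) -> IntervalSet:
        if len(lib) == n:
            return lib
        keep = np.sort(rng.choice(len(lib), size=n, replace=False))
        return IntervalSet([lib[i] for i in keep], dict(lib.provenance, downsampled=True))

    return sub(lib_a), sub(lib_b)


# ---------------------------------------------------------------------------
# Poisson enrichment + permutation FDR
# ---------------------------------------------------------------------------


def poisson_enrichment(
    footprint: LibraryTrack,
    structure_only: LibraryTrack,
    pseudocount: float = 1.0,
) -> EnrichmentTrack:
    """Per-nucleotide enrichment of footprint over structure-only coverage.

    score_i = -log10 P(Poisson(s_i + pseudocount) >= f_i); positions with
    zero footprint coverage score 0 (P(X >= 0) = 1).
    """
    data: dict[str, np.ndarray] = {}
    for chrom, f in footprint.data.items():
        f = np.asarray(f)
        s = np.asarray(structure_only.data[chrom])
        if f.shape != s.shape:
            raise ValueError(f"track length mismatch on {chrom}")
        if np.any(f < 0) or np.any(s < 0):
            raise ValueError("negative coverage")
        score = np.zeros(f.shape, dtype=float)
        nz = f > 0
        if np.any(nz):
            # sf(f-1) = P(X >= f); logsf avoids underflow at extreme scores
            score[nz] = -stats.poisson.logsf(f[nz] - 1, s[nz] + pseudocount) / _LN10
        data[chrom] = score
    meta_f = {"condition": footprint.condition, "replicate": footprint.replicate,
              "rnase": footprint.rnase}
    meta_s = {"condition": structure_only.condition,
              "replicate": structure_only.replicate, "rnase": structure_only.rnase}
    return EnrichmentTrack(data, meta_f, meta_s)


def fdr_threshold(
    observed: EnrichmentTrack, null: EnrichmentTrack, q: float = 0.05
) -> float:
    """Smallest score threshold with estimated FDR <= q (inclusive, >= t).

    The estimate at threshold t is (#null positions >= t) / (#observed
    positions >= t); returns +inf if no threshold achieves it.
    """
    if not 0.0 < q < 1.0:
        raise ValueError("q must lie in (0, 1)")
    obs = np.sort(observed.flat())
    nul = np.sort(null.flat())
    candidates = np.unique(obs[obs > 0])
    if candidates.size == 0:
        return math.inf
    n_obs_ge = obs.size - np.searchsorted(obs, candidates, side="left")
    n_null_ge = nul.size - np.searchsorted(nul, candidates, side="left")
    ok = n_null_ge <= q * n_obs_ge
    if not np.any(ok):
        return math.inf
    return float(candidates[np.argmax(ok)])


# ---------------------------------------------------------------------------
# Interval machinery
# ---------------------------------------------------------------------------


def merge_intervals(intervals: Sequence[Interval]) -> list[Interval]:
    """Merge intervals sharing >= 1 nucleotide (book-ended ones stay apart).

    Merging is per (chrom, strand); the merged score is the max of the
    members' scores.
    """
    by_key: dict[tuple[str, str], list[Interval]] = {}
    for iv in intervals:
        by_key.setdefault((iv.chrom, iv.strand), []).append(iv)
    out: list[Interval] = []
    for (chrom, strand), ivs in sorted(by_key.items()):
        ivs = sorted(ivs, key=lambda x: (x.start, x.end))
        cur = ivs[0]
        for nxt in ivs[1:]:
            if nxt.start < cur.end:  # strict: adjacency does not merge
                cur = Interval(
                    chrom, cur.start, max(cur.end, nxt.end), cur.name,
                    max(cur.score, nxt.score), strand,
                )
            else:
                out.append(cur)
                cur = nxt
        out.append(cur)
    return out


def _trees(intervals: Sequence[Interval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
    return trees


def overlap_mask(a: Sequence[Interval], b: Sequence[Interval]) -> np.ndarray:
    """Boolean per interval of ``a``: does it share >= 1 nt with any of ``b``."""
    trees = _trees(b)
    mask = np.zeros(len(a), dtype=bool)
    for i, iv in enumerate(a):
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        mask[i] = any(iv.strands_compatible(h.data) for h in tree.overlap(iv.start, iv.end))
    return mask


def call_pps(track: EnrichmentTrack, threshold: float) -> PPSCallSet:
    """Maximal runs of positions scoring >= threshold, merged, with max score."""
    if not math.isfinite(threshold):
        raise ValueError("threshold must be finite")
    intervals: list[Interval] = []
    for chrom in sorted(track.data):
        score = track.data[chrom]
        mask = score >= threshold
        if not mask.any():
            continue
        d = np.diff(mask.astype(np.int8))
        starts = np.where(d == 1)[0] + 1
        ends = np.where(d == -1)[0] + 1
        if mask[0]:
            starts = np.concatenate([[0], starts])
        if mask[-1]:
            ends = np.concatenate([ends, [mask.size]])
        for s, e in zip(starts, ends):
            intervals.append(
                Interval(chrom, int(s), int(e), f"pps_{chrom}_{s}",
                         float(np.max(score[s:e])), ".")
            )
    merged = merge_intervals(intervals)
    cond = track.footprint_meta.get("condition")
    rep = track.footprint_meta.get("replicate")
    return PPSCallSet(
        IntervalSet(merged, {"condition": cond, "replicate": rep}),
        fdr_threshold=threshold,
        label="replicate-level",
    )


def call_pps_pair(
    footprint: LibraryTrack,
    structure_only: LibraryTrack,
    q: float = 0.05,
    pseudocount: float = 1.0,
) -> tuple[PPSCallSet, float]:
    """Score a footprint/structure-only pair, set the permutation-FDR
    threshold from the label-swapped null, and call PPSs.

    Returns an empty call set (threshold +inf) when no threshold reaches q.
    """
    observed = poisson_enrichment(footprint, structure_only, pseudocount)
    null = poisson_enrichment(structure_only, footprint, pseudocount)
    t = fdr_threshold(observed, null, q)
    if not math.isfinite(t):
        empty = PPSCallSet(IntervalSet([], dict(observed.footprint_meta)), t)
        return empty, t
    return call_pps(observed, t), t


# ---------------------------------------------------------------------------
# Replicate intersection and condition classification
# ---------------------------------------------------------------------------


def high_confidence(rep1: PPSCallSet, rep2: PPSCallSet) -> PPSCallSet:
    """Replicate-1 PPSs sharing >= 1 nt with some replicate-2 PPS.

    Anchors on the replicate-1 geometry (the returned intervals are rep1's).
    """
    mask = overlap_mask(rep1.intervals.intervals, rep2.intervals.intervals)
    kept = [iv for iv, m in zip(rep1.intervals, mask) if m]
    prov = dict(rep1.intervals.provenance, replicate="both")
    return PPSCallSet(IntervalSet(kept, prov), rep1.fdr_threshold, "high-confidence")


def _as_intervals(x) -> list[Interval]:
    if isinstance(x, PPSCallSet):
        return list(x.intervals)
    return list(x)


def classify_condition(control_hc, salt_hc) -> dict[str, PPSCallSet]:
    """Split high-confidence PPSs into control-specific / salt-specific / shared.

    Shared PPSs overlap (>= 1 nt) an interval of the other condition and are
    reported in the control anchor geometry; the specific sets are the
    non-overlapping remainders of each condition.
    """
    control = _as_intervals(control_hc)
    salt = _as_intervals(salt_hc)
    c_mask = overlap_mask(control, salt)
    s_mask = overlap_mask(salt, control)
    mk = lambda ivs, lab: PPSCallSet(IntervalSet(ivs, {"class": lab}), None, lab)
    return {
        "shared": mk([iv for iv, m in zip(control, c_mask) if m], "shared"),
        "control_specific": mk([iv for iv, m in zip(control, c_mask) if not m],
                               "control-specific"),
        "salt_specific": mk([iv for iv, m in zip(salt, s_mask) if not m],
                            "salt-specific"),
    }


# ---------------------------------------------------------------------------
# Annotation, enrichment and conservation of called intervals
# ---------------------------------------------------------------------------


def _segment_trees(annotation: Sequence[TranscriptModel]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for m in annotation:
        for label, s, e in m.segments():
            trees.setdefault(m.chrom, IntervalTree()).addi(s, e, label)
    return trees


def annotate_features(pps, annotation: Sequence[TranscriptModel]) -> list[set[str]]:
    """Greedy per-interval feature labels: every overlapping feature counts.

    Intervals in unannotated space are labelled 'intergenic'.
    """
    trees = _segment_trees(annotation)
    out: list[set[str]] = []
    for iv in _as_intervals(pps):
        tree = trees.get(iv.chrom)
        labels = {h.data for h in tree.overlap(iv.start, iv.end)} if tree else set()
        out.append(labels or {"intergenic"})
    return out


def feature_distribution(labels: Sequence[set[str]]) -> dict[str, float]:
    """Label-occurrence distribution with equal weight per occurrence."""
    counts: dict[str, int] = {}
    for s in labels:
        for lab in s:
            counts[lab] = counts.get(lab, 0) + 1
    total = sum(counts.values())
    return {k: v / total for k, v in sorted(counts.items())} if total else {}


def feature_enrichment(pps, annotation: Sequence[TranscriptModel]) -> dict[str, float]:
    """log2(observed / expected) nucleotide share per annotated feature.

    Observed: fraction of PPS-covered nucleotides falling in the feature
    (a nucleotide under two feature labels counts once for each, matching the
    greedy annotation rule). Expected: the feature's share of annotated
    transcriptome nucleotides. Features with zero annotated nucleotides get
    NaN.
    """
    ivs = _as_intervals(pps)
    if not ivs:
        raise ValueError("empty PPS set")
    ann_nt: dict[str, int] = {}
    obs_nt: dict[str, int] = {}
    trees = _segment_trees(annotation)
    for m in annotation:
        for label, s, e in m.segments():
            ann_nt[label] = ann_nt.get(label, 0) + (e - s)
    for iv in ivs:
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        for h in tree.overlap(iv.start, iv.end):
            ov = min(iv.end, h.end) - max(iv.start, h.begin)
            obs_nt[h.data] = obs_nt.get(h.data, 0) + ov
    tot_ann = sum(ann_nt.values())
    tot_obs = sum(obs_nt.values())
    out: dict[str, float] = {}
    for label, n_ann in sorted(ann_nt.items()):
        if n_ann == 0 or tot_obs == 0:
            out[label] = math.nan
            continue
        obs = obs_nt.get(label, 0) / tot_obs
        exp = n_ann / tot_ann
        out[label] = math.log2(obs / exp) if obs > 0 else -math.inf
    return out


@dataclass
class ConservationComparison:
    pps_means: np.ndarray
    flank5_means: np.ndarray
    flank3_means: np.ndarray
    ks_statistic: float
    p_value: float
    n_dropped: int


def conservation_compare(pps, cons: ScoreTrack) -> ConservationComparison:
    """Mean conservation over each PPS vs equal-length 5'/3' flanks.

    Intervals whose flanks would run past a chromosome edge are dropped (and
    counted in ``n_dropped``). The two-sample KS test compares the PPS-mean
    distribution to the pooled flank-mean distribution.
    """
    pm, f5, f3 = [], [], []
    dropped = 0
    for iv in _as_intervals(pps):
        arr = cons.data[iv.chrom]
        L = iv.length
        if iv.start - L < 0 or iv.end + L > arr.size:
            dropped += 1
            continue
        pm.append(float(np.nanmean(arr[iv.start : iv.end])))
        f5.append(float(np.nanmean(arr[iv.start - L : iv.start])))
        f3.append(float(np.nanmean(arr[iv.end : iv.end + L])))
    pm_a, f5_a, f3_a = map(np.asarray, (pm, f5, f3))
    flanks = np.concatenate([f5_a, f3_a]) if pm else np.array([])
    if pm_a.size and flanks.size:
        ks = stats.ks_2samp(pm_a, flanks)
        stat, p = float(ks.statistic), float(ks.pvalue)
    else:
        stat, p = math.nan, math.nan
    return ConservationComparison(pm_a, f5_a, f3_a, stat, p, dropped)
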