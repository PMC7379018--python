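"""Cross-assay layer: abundance, stability, protein and m6A statistics.

Transcript stability is summarized by the proportion-uncapped metric, the
log2 ratio of degradome (GMUCT) RPM to mRNA-seq RPM for the same transcript;
higher values mean more degradation intermediates per message, i.e. a less
stable transcript. Because the metric already lives on a log scale, its
salt-vs-control fold change is the difference PU_salt - PU_control (the log2
of the RPM-ratio ratio), positive for transcripts destabilized in salt.
Protein output comes from per-run-normalized iBAQ intensities filtered to
proteins detected in at least two replicates of each condition. The module
also classifies condition-specific m6A peak dynamics and runs the stratified
protein-abundance comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import Interval, IntervalSet, TranscriptModel
from .pps_caller import classify_condition, overlap_mask

STABILIZED = "stabilized-in-salt"
DESTABILIZED = "destabilized-in-salt"
UNCHANGED = "unchanged"

M6A_CLASSES = ("control-specific", "salt-specific", "both-shifted", "both-same", "none")


# ---------------------------------------------------------------------------
# RPM, abundance, stability
# ---------------------------------------------------------------------------


def rpm(counts, library_total: float):
    """Reads per million: counts * 1e6 / library total."""
    if library_total <= 0:
        raise ValueError("library total must be > 0")
    return np.asarray(counts, dtype=float) * 1e6 / library_total


def abundance_fold_change(rpm_control, rpm_salt):
    """log2(RPM_salt / RPM_control)."""
    return np.log2(np.asarray(rpm_salt, dtype=float) / np.asarray(rpm_control, dtype=float))


def proportion_uncapped(gmuct_rpm, mrna_rpm):
    """PU = log2(RPM_GMUCT / RPM_mRNA-seq); scale-invariant in library size."""
    return np.log2(np.asarray(gmuct_rpm, dtype=float) / np.asarray(mrna_rpm, dtype=float))


def pu_fold_change(pu_control, pu_salt):
    """PU_salt - PU_control (log-domain difference; > 0 = destabilized)."""
    return np.asarray(pu_salt, dtype=float) - np.asarray(pu_control, dtype=float)


def stability_class(fc: float) -> str:
    if math.isnan(fc):
        return "undefined"
    if fc > 0:
        return DESTABILIZED
    if fc < 0:
        return STABILIZED
    return UNCHANGED


# ---------------------------------------------------------------------------
# Proteins
# ---------------------------------------------------------------------------


def protein_fold_change(
    intensity: pd.DataFrame,
    condition_of: Mapping[str, str] | None = None,
    normalization: str = "total",
    min_replicates: int = 2,
) -> pd.DataFrame:
    """Per-protein log2(salt/control) from a runs x proteins intensity table.

    Each run (column) is normalized to its own total (or median of nonzero
    values); proteins must be detected (nonzero) in at least
    ``min_replicates`` runs of *each* condition to be retained. Columns are
    mapped to conditions by ``condition_of`` or, by default, by their
    ``<condition>_<run>`` prefix.
    """
    if condition_of is None:
        condition_of = {c: c.rsplit("_", 1)[0] for c in intensity.columns}
    norm = intensity.astype(float).copy()
    for col in norm.columns:
        v = norm[col]
        if normalization == "total":
            denom = v.sum()
        elif normalization == "median":
            nz = v[v > 0]
            denom = nz.median() if len(nz) else 0.0
        else:
            raise ValueError("normalization must be 'total' or 'median'")
        norm[col] = v / denom if denom > 0 else 0.0
    ctrl_cols = [c for c in norm.columns if condition_of[c] == "control"]
    salt_cols = [c for c in norm.columns if condition_of[c] == "salt"]
    detected = ((norm[ctrl_cols] > 0).sum(axis=1) >= min_replicates) & (
        (norm[salt_cols] > 0).sum(axis=1) >= min_replicates
    )
    kept = norm[detected]
    fc = np.log2(kept[salt_cols].mean(axis=1) / kept[ctrl_cols].mean(axis=1))
    return pd.DataFrame({"protein_fc": fc})


# ---------------------------------------------------------------------------
# m6A dynamics
# ---------------------------------------------------------------------------


def m6a_dynamics(
    ctrl_peaks: IntervalSet,
    salt_peaks: IntervalSet,
    annotation: Sequence[TranscriptModel],
) -> tuple[dict[str, str], dict[str, IntervalSet]]:
    """Classify m6A peaks and transcripts by condition specificity.

    Peak classes (control-specific / salt-specific / shared) follow the
    >= 1-nt overlap rule across conditions. Transcript classes: lost all m6A
    in salt ('control-specific'), gained it only in salt ('salt-specific'),
    modified in both conditions at independent locations ('both-shifted') or
    with at least one overlapping peak pair ('both-same'), or 'none'.
    """
    peak_sets = classify_condition(ctrl_peaks, salt_peaks)
    peak_classes = {k: v.intervals for k, v in peak_sets.items()}

    tx_class: dict[str, str] = {}
    for m in annotation:
        exon_ivs = [Interval(m.chrom, s, e, m.transcript_id, 0.0, m.strand)
                    for s, e in m.exons]
        c_hits = [iv for iv, hit in zip(ctrl_peaks, overlap_mask(list(ctrl_peaks), exon_ivs)) if hit]
        s_hits = [iv for iv, hit in zip(salt_peaks, overlap_mask(list(salt_peaks), exon_ivs)) if hit]
        if not c_hits and not s_hits:
            tx_class[m.transcript_id] = "none"
        elif c_hits and not s_hits:
            tx_class[m.transcript_id] = "control-specific"
        elif s_hits and not c_hits:
            tx_class[m.transcript_id] = "salt-specific"
        else:
            shared = overlap_mask(c_hits, s_hits).any()
            tx_class[m.transcript_id] = "both-same" if shared else "both-shifted"
    return tx_class, peak_classes


# ---------------------------------------------------------------------------
# Correlations and rank tests
# ---------------------------------------------------------------------------


def window_correlation(
    profile_a: np.ndarray, profile_b: np.ndarray, window: slice | None = None
) -> tuple[float, float]:
    """Spearman rho between two mean profiles within a window.

    p-value from the asymptotic t approximation
    t = rho * sqrt((n - 2) / (1 - rho^2)); ties get average ranks.
    """
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    if window is not None:
        a, b = a[window], b[window]
    ok = ~(np.isnan(a) | np.isnan(b))
    res = stats.spearmanr(a[ok], b[ok])
    return float(res.statistic), float(res.pvalue)


def paired_score_correlation(x, y) -> tuple[float, float]:
    """Pearson correlation on per-transcript paired scores."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    res = stats.pearsonr(x[ok], y[ok])
    return float(res.statistic), float(res.pvalue)


def group_compare(values_a, values_b, paired: bool = False) -> tuple[float, float]:
    """Wilcoxon comparison of two samples.

    Unpaired (default): Mann-Whitney rank-sum with the tie-corrected normal
    approximation, two-sided. Paired mode uses the signed-rank test for
    aligned rows.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if paired:
        res = stats.wilcoxon(np.asarray(values_a, dtype=float),
                             np.asarray(values_b, dtype=float))
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Transcript-level table and strata
# ---------------------------------------------------------------------------


def build_transcript_stats(
    mrna_counts: pd.DataFrame,
    gmuct_counts: pd.DataFrame,
    protein_fc: pd.DataFrame | None = None,
    m6a_class: Mapping[str, str] | None = None,
    pseudo_reads: float = 0.5,
) -> pd.DataFrame:
    """Assemble the per-transcript statistics table.

    Count tables have ``<condition>_<replicate>`` columns; RPMs are averaged
    across replicates per condition, with ``pseudo_reads`` added before the
    log to keep zero-count transcripts finite.
    """

    def cond_rpm(df: pd.DataFrame, cond: str) -> pd.Series:
        cols = [c for c in df.columns if c.startswith(cond + "_")]
        vals = []
        for c in cols:
            total = df[c].sum()
            vals.append((df[c] + pseudo_reads) * 1e6 / total)
        return pd.concat(vals, axis=1).mean(axis=1)

    out = pd.DataFrame(index=mrna_counts.index)
    for cond in ("control", "salt"):
        out[f"rpm_mrna_{cond}"] = cond_rpm(mrna_counts, cond)
        out[f"rpm_gmuct_{cond}"] = cond_rpm(gmuct_counts.reindex(mrna_counts.index), cond)
        out[f"pu_{cond}"] = proportion_uncapped(
            out[f"rpm_gmuct_{cond}"], out[f"rpm_mrna_{cond}"]
        )
    out["abundance_fc"] = abundance_fold_change(out["rpm_mrna_control"], out["rpm_mrna_salt"])
    out["pu_fold_change"] = pu_fold_change(out["pu_control"], out["pu_salt"])
    out["stability_class"] = [stability_class(v) for v in out["pu_fold_change"]]
    if protein_fc is not None:
        out["protein_fc"] = protein_fc["protein_fc"].reindex(out.index)
    if m6a_class is not None:
        out["m6a_class"] = pd.Series(m6a_class).reindex(out.index).fillna("none")
    return out


@dataclass
class StratumSummary:
    n: int
    values: np.ndarray

    @property
    def median(self) -> float:
        return float(np.median(self.values)) if self.n else math.nan


def strata_report(
    table: pd.DataFrame,
    value_col: str = "protein_fc",
    m6a_flag_class: str = "salt-specific",
) -> dict:
    """2x2 stratified comparison: (salt-specific m6A yes/no) x (stabilized /
    destabilized), with rank-sum tests of m6A-vs-no-m6A within each stability
    class.

    Returns stratum summaries keyed (m6a, stability) plus a ``tests`` mapping
    with (statistic, p) per stability class; tests on an empty stratum are
    skipped (reported as None).
    """
    df = table.dropna(subset=[value_col])
    has_m6a = df["m6a_class"] == m6a_flag_class
    strata: dict[tuple[bool, str], StratumSummary] = {}
    tests: dict[str, tuple[float, float] | None] = {}
    for stab in (STABILIZED, DESTABILIZED):
        in_class = df["stability_class"] == stab
        with_m6a = df.loc[in_class & has_m6a, value_col].to_numpy()
        without = df.loc[in_class & ~has_m6a, value_col].to_numpy()
        strata[(True, stab)] = StratumSummary(with_m6a.size, with_m6a)
        strata[(False, stab)] = StratumSummary(without.size, without)
        if with_m6a.size and without.size:
            tests[stab] = group_compare(with_m6a, without)
        else:
            tests[stab] = None
    return {"strata": strata, "tests": tests, "n_total": len(df)}
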