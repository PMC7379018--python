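"""Synthetic PIP-seq study generator with known ground truth.

Emulates the full data model of a paired-nuclease protein-occupancy /
RNA-structure experiment under two conditions (control and salt) with two
biological replicates: a virtual annotated genome, 16 per-nucleotide
coverage libraries (2 conditions x 2 replicates x {footprint, structure-only}
x {dsRNase, ssRNase}), condition-specific m6A peak sets, GMUCT / mRNA-seq
count tables with planted stability shifts, and per-run protein intensity
tables with planted fold changes.

Coverage is simulated directly as per-nucleotide counts (Poisson around a
per-library mean), not as reads; a thin 50-nt read-interval emitter is
provided for exercising the depth-equalization path. Everything is
deterministic given ``SimulationConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_io import (
    Interval,
    IntervalSet,
    LibraryTrack,
    LNCRNA_BIOTYPE,
    MRNA_BIOTYPE,
    TranscriptModel,
    chrom_sizes,
    write_annotation,
    write_bedgraph,
    write_intervals,
    write_json,
)

CONDITIONS = ("control", "salt")
REPLICATES = (1, 2)
RNASES = ("ds", "ss")
SAMPLE_TYPES = ("footprint", "structure_only")


class ConfigurationError(ValueError):
    """Infeasible or inconsistent simulation parameters."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic experiment.

    Defaults describe a desk-scale version of a nuclear PIP-seq experiment:
    ~1 kb transcripts at 30x mean coverage, protein footprints enriched 4x in
    the footprint libraries, and 4x dsRNase/ssRNase coverage asymmetry over
    planted double-stranded regions.
    """

    n_transcripts: int = 200
    transcript_length_range: tuple[int, int] = (800, 1200)
    utr5_length_range: tuple[int, int] = (20, 120)
    utr3_length_range: tuple[int, int] = (60, 250)
    n_introns_range: tuple[int, int] = (0, 2)
    intron_length_range: tuple[int, int] = (60, 200)
    intergenic_gap_range: tuple[int, int] = (100, 300)
    n_chromosomes: int = 2
    frac_lncrna: float = 0.1
    #: fraction of mRNAs drawn to satisfy the metagene expression filters
    #: (>=45 nt 5'UTR and >=140 nt 3'UTR)
    frac_profile_eligible: float = 0.8
    mean_depth: float = 30.0
    footprint_density: float = 1.0  # expected planted PPSs per kb
    footprint_length_range: tuple[int, int] = (20, 50)
    footprint_enrichment: float = 4.0
    #: probability a planted footprint appears in both replicates of its
    #: condition (partial replicate concordance)
    replicate_concordance: float = 0.6
    paired_region_density: float = 1.0  # planted ds/ss regions per kb
    paired_region_length_range: tuple[int, int] = (30, 80)
    ds_ss_contrast: float = 4.0
    m6a_peak_rate_by_condition: Mapping[str, float] = field(
        default_factory=lambda: {"control": 0.6, "salt": 1.0}
    )
    m6a_peak_length_range: tuple[int, int] = (50, 120)
    stability_shift_sd: float = 0.5
    protein_log2fc_sd: float = 0.5
    protein_noise_sd: float = 0.3  # log2-scale run-to-run noise
    protein_dropout: float = 0.1  # per-run probability of a missed protein
    nb_dispersion: float = 0.1
    n_count_replicates: int = 2
    n_protein_runs: int = 3
    mean_expression: float = 200.0
    expression_log_sd: float = 1.0
    pu_base_log2: float = -1.0  # baseline log2 GMUCT/mRNA ratio
    read_length: int = 50
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "transcript_length_range",
            "utr5_length_range",
            "utr3_length_range",
            "n_introns_range",
            "intron_length_range",
            "intergenic_gap_range",
            "footprint_length_range",
            "paired_region_length_range",
            "m6a_peak_length_range",
        ):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise ConfigurationError(f"{name}={lo, hi} must satisfy 0 <= low <= high")
        if self.n_transcripts < 0:
            raise ConfigurationError("n_transcripts must be >= 0")
        for name in ("frac_lncrna", "frac_profile_eligible", "replicate_concordance",
                     "protein_dropout"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} must lie in [0, 1]")
        if self.mean_depth <= 0:
            raise ConfigurationError("mean_depth must be > 0")
        if self.footprint_enrichment < 1 or self.ds_ss_contrast < 1:
            raise ConfigurationError("enrichment and contrast factors must be >= 1")
        for name in ("footprint_density", "paired_region_density",
                     "stability_shift_sd", "protein_log2fc_sd", "nb_dispersion"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for rate in self.m6a_peak_rate_by_condition.values():
            if rate < 0:
                raise ConfigurationError("m6a peak rates must be >= 0")
        # every UTR draw must leave room for a >=63 nt CDS
        min_len = self.transcript_length_range[0]
        if self.utr5_length_range[1] + self.utr3_length_range[1] + 63 > min_len:
            raise ConfigurationError(
                "UTR ranges leave no room for a CDS in the shortest transcript"
            )


@dataclass
class GroundTruth:
    """Planted signal locations and effect sizes."""

    planted_footprints: dict[tuple[str, int], IntervalSet] = field(default_factory=dict)
    planted_paired_regions: IntervalSet = field(default_factory=IntervalSet)
    planted_m6a: dict[str, IntervalSet] = field(default_factory=dict)
    planted_stability_shift: dict[str, float] = field(default_factory=dict)
    planted_protein_log2fc: dict[str, float] = field(default_factory=dict)


def _rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    # independent, reproducible streams per stage
    return np.random.default_rng(np.random.SeedSequence([int(cfg.seed), stream]))


def _rand_len(rng: np.random.Generator, lohi: tuple[int, int]) -> int:
    return int(rng.integers(lohi[0], lohi[1] + 1))


# ---------------------------------------------------------------------------
# Annotation + ground truth
# ---------------------------------------------------------------------------


def _plant_in_exon(
    rng: np.random.Generator, model: TranscriptModel, length_range: tuple[int, int]
) -> tuple[int, int]:
    """One contiguous interval inside a single exon, length-weighted."""
    lens = np.array([e - s for s, e in model.exons], dtype=float)
    exon = model.exons[int(rng.choice(len(model.exons), p=lens / lens.sum()))]
    length = min(_rand_len(rng, length_range), exon[1] - exon[0])
    start = int(rng.integers(exon[0], exon[1] - length + 1))
    return start, start + length


def simulate_annotation(
    cfg: SimulationConfig,
) -> tuple[list[TranscriptModel], GroundTruth]:
    """Tile a virtual genome with non-overlapping transcripts and plant truth."""
    cfg.validate()
    rng = _rng(cfg, 0)
    truth = GroundTruth(
        planted_footprints={(c, r): IntervalSet(provenance={"condition": c, "replicate": r})
                            for c in CONDITIONS for r in REPLICATES},
        planted_paired_regions=IntervalSet(provenance={"type": "paired_regions"}),
        planted_m6a={c: IntervalSet(provenance={"condition": c}) for c in CONDITIONS},
    )
    models: list[TranscriptModel] = []
    cursors = {f"chr{i + 1}": 0 for i in range(cfg.n_chromosomes)}
    chroms = list(cursors)

    for i in range(cfg.n_transcripts):
        chrom = chroms[i % len(chroms)]
        length = _rand_len(rng, cfg.transcript_length_range)
        is_lnc = rng.random() < cfg.frac_lncrna
        strand = "+" if rng.random() < 0.5 else "-"
        start = cursors[chrom] + _rand_len(rng, cfg.intergenic_gap_range)

        # intron placement in transcript space
        n_introns = _rand_len(rng, cfg.n_introns_range)
        cut_pool = np.arange(1, length)
        n_introns = min(n_introns, cut_pool.size)
        cuts = np.sort(rng.choice(cut_pool, size=n_introns, replace=False))
        intron_lens = [_rand_len(rng, cfg.intron_length_range) for _ in range(n_introns)]
        exons: list[tuple[int, int]] = []
        g = start
        prev = 0
        for cut, ilen in zip(cuts, intron_lens):
            exons.append((g, g + (cut - prev)))
            g += (cut - prev) + ilen
            prev = cut
        exons.append((g, g + (length - prev)))
        end = exons[-1][1]
        cursors[chrom] = end

        tid = f"TX{i + 1:05d}"
        if is_lnc:
            model = TranscriptModel(tid, chrom, strand, exons, None, LNCRNA_BIOTYPE)
        else:
            eligible = rng.random() < cfg.frac_profile_eligible
            lo5, hi5 = cfg.utr5_length_range
            lo3, hi3 = cfg.utr3_length_range
            if eligible:
                u5 = int(rng.integers(max(lo5, 45), hi5 + 1))
                u3 = int(rng.integers(max(lo3, 140), hi3 + 1))
            else:
                u5 = int(rng.integers(lo5, max(lo5 + 1, min(hi5 + 1, 45))))
                u3 = int(rng.integers(lo3, max(lo3 + 1, min(hi3 + 1, 140))))
            cds = length - u5 - u3
            u3 += cds % 3  # keep CDS length divisible by 3
            cds -= cds % 3
            pos = np.concatenate([np.arange(s, e) for s, e in exons])
            if strand == "+":
                cs, ce = int(pos[u5]), int(pos[u5 + cds - 1]) + 1
            else:
                rpos = pos[::-1]
                cs, ce = int(rpos[u5 + cds - 1]), int(rpos[u5]) + 1
            model = TranscriptModel(tid, chrom, strand, exons, (cs, ce), MRNA_BIOTYPE)
        models.append(model)

        kb = model.spliced_length / 1000.0

        # footprints, shared across replicates with probability
        # replicate_concordance
        for cond in CONDITIONS:
            for j in range(rng.poisson(cfg.footprint_density * kb)):
                s, e = _plant_in_exon(rng, model, cfg.footprint_length_range)
                name = f"fp_{cond}_{tid}_{j}"
                reps = (
                    REPLICATES
                    if rng.random() < cfg.replicate_concordance
                    else (int(rng.choice(REPLICATES)),)
                )
                for rep in reps:
                    truth.planted_footprints[(cond, rep)].intervals.append(
                        Interval(chrom, s, e, name, 0.0, strand)
                    )

        # non-overlapping paired/unpaired structure regions
        placed: list[tuple[int, int]] = []
        for j in range(rng.poisson(cfg.paired_region_density * kb)):
            for _ in range(20):
                s, e = _plant_in_exon(rng, model, cfg.paired_region_length_range)
                if all(e <= ps or s >= pe for ps, pe in placed):
                    placed.append((s, e))
                    label = "paired" if rng.random() < 0.5 else "unpaired"
                    truth.planted_paired_regions.intervals.append(
                        Interval(chrom, s, e, label, 0.0, strand)
                    )
                    break

        for cond in CONDITIONS:
            rate = cfg.m6a_peak_rate_by_condition.get(cond, 0.0)
            for j in range(rng.poisson(rate)):
                s, e = _plant_in_exon(rng, model, cfg.m6a_peak_length_range)
                truth.planted_m6a[cond].intervals.append(
                    Interval(chrom, s, e, f"m6a_{cond}_{tid}_{j}", 0.0, strand)
                )

        if model.biotype == MRNA_BIOTYPE:
            truth.planted_stability_shift[tid] = float(
                rng.normal(0.0, cfg.stability_shift_sd)
            )
            truth.planted_protein_log2fc[tid] = float(
                rng.normal(0.0, cfg.protein_log2fc_sd)
            )
        else:
            truth.planted_stability_shift[tid] = float(
                rng.normal(0.0, cfg.stability_shift_sd)
            )

    return models, truth


# ---------------------------------------------------------------------------
# Coverage libraries
# ---------------------------------------------------------------------------


def _masks(
    annotation: Sequence[TranscriptModel],
    truth: GroundTruth,
    sizes: Mapping[str, int],
):
    exonic = {c: np.zeros(n, dtype=bool) for c, n in sizes.items()}
    for m in annotation:
        for s, e in m.exons:
            exonic[m.chrom][s:e] = True
    paired = {c: np.zeros(n, dtype=bool) for c, n in sizes.items()}
    unpaired = {c: np.zeros(n, dtype=bool) for c, n in sizes.items()}
    for iv in truth.planted_paired_regions:
        (paired if iv.name == "paired" else unpaired)[iv.chrom][iv.start : iv.end] = True
    fp = {
        key: {c: np.zeros(n, dtype=bool) for c, n in sizes.items()}
        for key in truth.planted_footprints
    }
    for key, ivs in truth.planted_footprints.items():
        for iv in ivs:
            fp[key][iv.chrom][iv.start : iv.end] = True
    return exonic, paired, unpaired, fp


def simulate_libraries(
    annotation: Sequence[TranscriptModel],
    truth: GroundTruth,
    cfg: SimulationConfig,
) -> dict[tuple[str, int, str, str], LibraryTrack]:
    """Draw the 16 coverage libraries, keyed (condition, replicate, sample_type, rnase).

    Base coverage is Poisson(mean_depth) on exonic positions. Planted paired
    regions multiply the ssRNase-treated (dsRNA-seq) mean by ``ds_ss_contrast``
    and divide the dsRNase-treated mean by it (reversed in unpaired regions);
    planted footprints multiply both footprint-sample means by
    ``footprint_enrichment`` in the replicates carrying the footprint.
    """
    if not annotation:
        raise ValueError("annotation is empty")
    cfg.validate()
    rng = _rng(cfg, 1)
    sizes = chrom_sizes(annotation)
    exonic, paired, unpaired, fp = _masks(annotation, truth, sizes)

    libs: dict[tuple[str, int, str, str], LibraryTrack] = {}
    for cond in CONDITIONS:
        for rep in REPLICATES:
            for stype in SAMPLE_TYPES:
                for rnase in RNASES:
                    data: dict[str, np.ndarray] = {}
                    for chrom, n in sizes.items():
                        lam = np.where(exonic[chrom], cfg.mean_depth, 0.0)
                        if rnase == "ss":  # ssRNase-treated => dsRNA-seq readout
                            lam[paired[chrom]] *= cfg.ds_ss_contrast
                            lam[unpaired[chrom]] /= cfg.ds_ss_contrast
                        else:
                            lam[paired[chrom]] /= cfg.ds_ss_contrast
                            lam[unpaired[chrom]] *= cfg.ds_ss_contrast
                        if stype == "footprint":
                            lam[fp[(cond, rep)][chrom]] *= cfg.footprint_enrichment
                        data[chrom] = rng.poisson(lam).astype(np.int64)
                    libs[(cond, rep, stype, rnase)] = LibraryTrack(
                        data, condition=cond, replicate=rep, rnase=rnase, sample_type=stype
                    )
    return libs


def merge_replicates(a: LibraryTrack, b: LibraryTrack) -> LibraryTrack:
    """Pool two replicate libraries by summing coverage."""
    data = {c: a.data[c] + b.data[c] for c in a.data}
    return LibraryTrack(data, a.condition, 0, a.rnase, a.sample_type)


def simulate_reads(
    annotation: Sequence[TranscriptModel],
    cfg: SimulationConfig,
    n_reads: int,
    stream: int = 7,
) -> IntervalSet:
    """Uniform fixed-length read intervals over exons (for downsampling tests)."""
    if not annotation:
        raise ValueError("annotation is empty")
    rng = _rng(cfg, stream)
    lens = np.array([m.spliced_length for m in annotation], dtype=float)
    picks = rng.choice(len(annotation), size=n_reads, p=lens / lens.sum())
    reads: list[Interval] = []
    for k, idx in enumerate(picks):
        m = annotation[int(idx)]
        lens_m = np.array([e - s for s, e in m.exons], dtype=float)
        s_exon, e_exon = m.exons[int(rng.choice(len(m.exons), p=lens_m / lens_m.sum()))]
        rl = min(cfg.read_length, e_exon - s_exon)
        start = int(rng.integers(s_exon, e_exon - rl + 1))
        reads.append(Interval(m.chrom, start, start + rl, f"read{k}", 0.0, m.strand))
    return IntervalSet(reads, {"type": "reads"})


# ---------------------------------------------------------------------------
# Counts and proteins
# ---------------------------------------------------------------------------


def _nb(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mean))


def simulate_counts_and_proteins(
    annotation: Sequence[TranscriptModel],
    truth: GroundTruth,
    cfg: SimulationConfig,
    protein_effects: Mapping[str, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Per-transcript mRNA-seq / GMUCT count tables and a protein run table.

    GMUCT means are constructed so the log2 proportion-uncapped difference
    (salt minus control) equals the planted stability shift in expectation.
    Protein intensities get ``n_protein_runs`` runs per condition with
    log-normal noise around the planted log2 fold change; per-run dropout
    yields proteins seen in fewer than two replicates, exercising the
    detection filter downstream. ``protein_effects`` overrides the planted
    per-protein effects when supplied.
    """
    if not annotation:
        raise ValueError("annotation is empty")
    cfg.validate()
    rng = _rng(cfg, 2)
    tids = [m.transcript_id for m in annotation]
    expr = rng.lognormal(np.log(cfg.mean_expression), cfg.expression_log_sd, len(tids))
    shift = np.array([truth.planted_stability_shift.get(t, 0.0) for t in tids])

    cols = [f"{c}_{r}" for c in CONDITIONS for r in range(1, cfg.n_count_replicates + 1)]
    mrna = pd.DataFrame(index=pd.Index(tids, name="transcript_id"), columns=cols, dtype=np.int64)
    gmuct = mrna.copy()
    pu0 = 2.0 ** cfg.pu_base_log2
    for cond in CONDITIONS:
        g_mean = expr * pu0 * (2.0 ** shift if cond == "salt" else 1.0)
        for r in range(1, cfg.n_count_replicates + 1):
            mrna[f"{cond}_{r}"] = _nb(rng, expr, cfg.nb_dispersion)
            gmuct[f"{cond}_{r}"] = _nb(rng, g_mean, cfg.nb_dispersion)

    if protein_effects is None:
        protein_effects = truth.planted_protein_log2fc
    prot_ids = [m.transcript_id for m in annotation if m.biotype == MRNA_BIOTYPE]
    run_cols = [f"{c}_{r}" for c in CONDITIONS for r in range(1, cfg.n_protein_runs + 1)]
    base = rng.lognormal(np.log(1e6), 1.0, len(prot_ids))
    prot = pd.DataFrame(
        0.0, index=pd.Index(prot_ids, name="protein_id"), columns=run_cols
    )
    for j, tid in enumerate(prot_ids):
        fc = float(protein_effects.get(tid, 0.0))
        for cond in CONDITIONS:
            mean = base[j] * (2.0 ** fc if cond == "salt" else 1.0)
            for r in range(1, cfg.n_protein_runs + 1):
                if rng.random() < cfg.protein_dropout:
                    continue
                prot.loc[tid, f"{cond}_{r}"] = mean * 2.0 ** rng.normal(
                    0.0, cfg.protein_noise_sd
                )
    return mrna, gmuct, prot


# ---------------------------------------------------------------------------
# On-disk emission
# ---------------------------------------------------------------------------


def write_simulation(outdir, cfg: SimulationConfig) -> None:
    """Run the full generator and emit GFF3/bedGraph/BED/TSV/JSON artifacts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    annotation, truth = simulate_annotation(cfg)
    write_annotation(annotation, outdir / "annotation.gff3")
    summary = {
        "n_transcripts": len(annotation),
        "seed": cfg.seed,
        "planted_paired_regions": len(truth.planted_paired_regions),
    }
    if annotation:
        libs = simulate_libraries(annotation, truth, cfg)
        for (cond, rep, stype, rnase), lib in libs.items():
            write_bedgraph(lib.data, outdir / f"{cond}_rep{rep}_{stype}_{rnase}.bedGraph")
        mrna, gmuct, prot = simulate_counts_and_proteins(annotation, truth, cfg)
        mrna.to_csv(outdir / "mrna_counts.tsv", sep="\t")
        gmuct.to_csv(outdir / "gmuct_counts.tsv", sep="\t")
        prot.to_csv(outdir / "protein_intensity.tsv", sep="\t")
    for (cond, rep), ivs in truth.planted_footprints.items():
        write_intervals(ivs, outdir / f"truth_footprints_{cond}_rep{rep}.bed")
    write_intervals(truth.planted_paired_regions, outdir / "truth_paired_regions.bed")
    for cond, ivs in truth.planted_m6a.items():
        write_intervals(ivs, outdir / f"truth_m6a_{cond}.bed")
        summary[f"n_m6a_{cond}"] = len(ivs)
    for (cond, rep), ivs in truth.planted_footprints.items():
        summary[f"n_footprints_{cond}_rep{rep}"] = len(ivs)
    write_json(summary, outdir / "ground_truth_summary.json")
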