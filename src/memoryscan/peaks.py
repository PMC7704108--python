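"""Scoring of p65 peaks as candidate transcriptional-memory modules.

A transcriptional-memory module, in this analysis, is an NF-κB binding site
embedded in a CpG-dense, initially methylated region: methylation around the
κB site disfavors p65 binding, sustained stimulation demethylates it, and the
inherited hypomethylated state enables a stronger response to a later
stimulus. This module implements the peak-level accounting:

* best κB motif hit per peak (log-odds PWM scan, both strands);
* CpG positions within a ±250 bp flank of the motif center;
* mean methylation level and total methylation M (sum of per-CpG levels,
  "methylated-CpG equivalents") per peak and time point;
* initial-state classification (methylated ≥ 50 %, unmethylated < 20 %);
* grouping by total demethylation (top quartile vs. rest; quantile bins);
* peak-to-nearest-gene linking with a distance cap;
* responsive-element definition (induced p65 peaks co-occupied by H3K27ac),
  consensus peak merging with blacklist removal;
* motif-anchored demethylation profiles with lowess smoothing;
* signal-track normalization anchored on unmethylated peaks, averaged
  profiles, eRNA RPKM, and occupancy-change classification.

Coordinates are 0-based half-open (BED semantics) throughout.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

from .config import (
    DEFAULT_FLANK,
    DEFAULT_LINK_CAP,
    DEFAULT_LOWESS_FRAC,
    DEFAULT_MIN_COV,
    DEFAULT_NEAR_TSS,
    DEFAULT_OCCUPANCY_SPLIT,
)

# ---------------------------------------------------------------------------
# Core interval and record types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    name: str = ""
    strand: str = "."

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class KappaBHit:
    """Best-scoring κB motif hit within a peak."""

    offset: int          # motif start relative to peak start
    length: int
    score: float         # log2 odds vs. uniform background
    strand: str          # "+" or "-"

    def center_in(self, peak: GenomicInterval) -> int:
        """Genomic coordinate of the motif center (floor for even lengths)."""
        return peak.start + self.offset + self.length // 2


@dataclass
class PeakMethylation:
    """Methylation summary of the CpGs in a peak's motif flank."""

    mean_level: float | None
    total: float | None   # M, methylated-CpG equivalents
    n_used: int

    @property
    def has_data(self) -> bool:
        return self.n_used > 0


NO_DATA = PeakMethylation(mean_level=None, total=None, n_used=0)

STATE_METHYLATED = "methylated"
STATE_UNMETHYLATED = "unmethylated"
STATE_INTERMEDIATE = "intermediate"
STATE_NO_DATA = "no_data"


@dataclass
class ModuleScore:
    """Per-peak memory-module score combining CpG density and demethylation."""

    peak: GenomicInterval
    hit: KappaBHit
    cpg_positions: tuple[int, ...]
    level_t0: float | None
    level_t12: float | None
    m_t0: float | None
    m_t12: float | None
    n_used: int
    initial_state: str = STATE_NO_DATA
    demethylation_group: str = ""
    quantile_bin: int = -1

    @property
    def n_cpg_flank(self) -> int:
        return len(self.cpg_positions)

    @property
    def delta_m(self) -> float | None:
        if self.m_t0 is None or self.m_t12 is None:
            return None
        return self.m_t0 - self.m_t12

    @property
    def has_data(self) -> bool:
        return self.n_used > 0


@dataclass(frozen=True)
class PeakGeneLink:
    peak_id: str
    gene_id: str
    distance: int        # signed: TSS − motif center
    within_10kb: bool


# ---------------------------------------------------------------------------
# Motif scanning
# ---------------------------------------------------------------------------

_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def pwm_from_consensus(consensus: str, pseudo: float = 0.01) -> np.ndarray:
    """Near-deterministic PWM (positions × ACGT) from a consensus sequence."""
    pwm = np.full((len(consensus), 4), pseudo / 3)
    for i, base in enumerate(consensus.upper()):
        pwm[i, _BASES.index(base)] = 1.0 - pseudo
    return pwm


def _log_odds(pwm: np.ndarray, background: float = 0.25, eps: float = 1e-9) -> np.ndarray:
    sums = pwm.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=1e-6):
        raise ValueError("PWM rows must each sum to 1 before log-odds transform")
    return np.log2(np.maximum(pwm, eps) / background)


def _scan_strand(seq: str, lod: np.ndarray) -> np.ndarray:
    """Log-odds score at each start position of one strand."""
    k = lod.shape[0]
    n = len(seq) - k + 1
    idx = np.array([_BASES.find(b) for b in seq.upper()])
    scores = np.full(n, -np.inf)
    min_lod = lod.min() - 1.0  # ambiguous base scores below any real base
    for pos in range(n):
        window = idx[pos : pos + k]
        s = 0.0
        for j, b in enumerate(window):
            s += lod[j, b] if b >= 0 else min_lod
        scores[pos] = s
    return scores


def scan_kb_motif(sequence: str, pwm: np.ndarray) -> KappaBHit:
    """Best κB motif hit over both strands of ``sequence``.

    Ties are broken by the leftmost start position, then the + strand. The
    reverse-strand score at start ``p`` scores the reverse complement of the
    window beginning at ``p`` on the forward sequence.
    """
    k = pwm.shape[0]
    if len(sequence) < k:
        raise ValueError(
            f"sequence length {len(sequence)} shorter than motif length {k}"
        )
    lod = _log_odds(pwm)
    fwd = _scan_strand(sequence, lod)
    rev_scores_on_rc = _scan_strand(reverse_complement(sequence), lod)
    # map reverse-strand start back to forward coordinates
    rev = rev_scores_on_rc[::-1]

    best = None
    for pos in range(len(fwd)):
        for strand, score in (("+", fwd[pos]), ("-", rev[pos])):
            if best is None or score > best[0] + 1e-12:
                best = (score, pos, strand)
    score, pos, strand = best
    return KappaBHit(offset=pos, length=k, score=float(score), strand=strand)


# ---------------------------------------------------------------------------
# CpG accounting and methylation scoring
# ---------------------------------------------------------------------------


def cpgs_in_flank(
    genome_seq: str,
    peak: GenomicInterval,
    hit: KappaBHit,
    flank: int = DEFAULT_FLANK,
) -> list[int]:
    """Genomic positions of CpG cytosines within ±``flank`` bp of the motif center.

    The boundary is inclusive: a CpG exactly ``flank`` bp from the center
    counts. Positions are clipped to the genome and returned sorted.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    center = hit.center_in(peak)
    lo = max(0, center - flank)
    hi = min(len(genome_seq) - 2, center + flank)
    seq = genome_seq.upper()
    return [
        pos
        for pos in range(lo, hi + 1)
        if seq[pos] == "C" and seq[pos + 1] == "G"
    ]


def _meth_lookup(meth: pd.DataFrame) -> dict[tuple[str, int], tuple[float, int]]:
    out = {}
    for row in meth.itertuples(index=False):
        cov = int(row.count_meth) + int(row.count_unmeth)
        level = row.count_meth / cov if cov > 0 else float("nan")
        out[(row.chrom, int(row.pos))] = (level, cov)
    return out


def peak_methylation(
    meth: pd.DataFrame,
    cpg_positions: Sequence[int],
    chrom: str,
    min_cov: int = DEFAULT_MIN_COV,
) -> PeakMethylation:
    """Mean level and total methylation M over covered flank CpGs.

    CpGs absent from the table or below ``min_cov`` coverage are excluded.
    With zero usable CpGs a no-data sentinel is returned, never a silent 0.
    """
    if len(cpg_positions) == 0:
        raise ValueError("cpg_positions must be non-empty")
    lookup = _meth_lookup(meth)
    levels = []
    for pos in cpg_positions:
        rec = lookup.get((chrom, int(pos)))
        if rec is None:
            continue
        level, cov = rec
        if cov >= min_cov:
            levels.append(level)
    if not levels:
        return NO_DATA
    arr = np.asarray(levels)
    return PeakMethylation(
        mean_level=float(arr.mean()), total=float(arr.sum()), n_used=len(arr)
    )


def classify_initial_state(summary: PeakMethylation | float | None) -> str:
    """Classify a peak by its initial mean methylation level.

    ≥ 0.50 methylated, < 0.20 unmethylated, otherwise intermediate; a no-data
    sentinel propagates.
    """
    if isinstance(summary, PeakMethylation):
        if not summary.has_data:
            return STATE_NO_DATA
        level = summary.mean_level
    else:
        level = summary
    if level is None or (isinstance(level, float) and math.isnan(level)):
        return STATE_NO_DATA
    if not 0.0 <= level <= 1.0:
        raise ValueError(f"methylation level must be in [0, 1], got {level}")
    if level >= 0.50:
        return STATE_METHYLATED
    if level < 0.20:
        return STATE_UNMETHYLATED
    return STATE_INTERMEDIATE


def score_peak(
    genome_seq: str,
    peak: GenomicInterval,
    pwm: np.ndarray,
    meth_t0: pd.DataFrame,
    meth_t12: pd.DataFrame,
    flank: int = DEFAULT_FLANK,
    min_cov: int = DEFAULT_MIN_COV,
) -> ModuleScore:
    """Full per-peak module score: motif, flank CpGs, M at both time points."""
    hit = scan_kb_motif(genome_seq[peak.start : peak.end], pwm)
    cpgs = cpgs_in_flank(genome_seq, peak, hit, flank=flank)
    if cpgs:
        s0 = peak_methylation(meth_t0, cpgs, peak.chrom, min_cov=min_cov)
        s12 = peak_methylation(meth_t12, cpgs, peak.chrom, min_cov=min_cov)
    else:
        s0 = s12 = NO_DATA
    n_used = min(s0.n_used, s12.n_used)
    score = ModuleScore(
        peak=peak,
        hit=hit,
        cpg_positions=tuple(cpgs),
        level_t0=s0.mean_level,
        level_t12=s12.mean_level,
        m_t0=s0.total,
        m_t12=s12.total,
        n_used=n_used,
        initial_state=classify_initial_state(s0),
    )
    return score


# ---------------------------------------------------------------------------
# Grouping
# ---------------------------------------------------------------------------

GROUP_TOP_Q = "topQ"
GROUP_REST = "rest"


def demethylation_grouping(
    scores: Sequence[ModuleScore],
    mode: str = "topQ",
    n_bins: int = 5,
    statistic: str = "delta_m",
) -> dict:
    """Group peaks by total demethylation (or another statistic).

    ``topQ`` mode labels peaks whose delta_M is strictly greater than the
    upper quartile Q3 (linear-interpolation quantile) as ``topQ`` and the rest
    as ``rest`` — the split between highly demethylated candidate memory
    modules and other methylated peaks. Quantile modes cut the peaks into
    ``n_bins`` equal-count bins of the statistic (bin 0 = lowest).
    """
    usable = [s for s in scores if s.has_data]
    if not usable:
        raise ValueError("no peaks with methylation data to group")

    def stat(s: ModuleScore) -> float:
        if statistic == "delta_m":
            return s.delta_m
        if statistic == "m_t0":
            return s.m_t0
        if statistic == "n_cpg":
            return float(s.n_cpg_flank)
        raise ValueError(f"unknown statistic {statistic!r}")

    values = np.array([stat(s) for s in usable])

    if mode == "topQ":
        q3 = float(np.quantile(values, 0.75))  # type-7 linear interpolation
        if np.all(values == values[0]):
            warnings.warn("all demethylation values identical; topQ group is empty")
        for s, v in zip(usable, values):
            s.demethylation_group = GROUP_TOP_Q if v > q3 else GROUP_REST
        return {
            "mode": "topQ",
            "q3": q3,
            GROUP_TOP_Q: [s for s in usable if s.demethylation_group == GROUP_TOP_Q],
            GROUP_REST: [s for s in usable if s.demethylation_group == GROUP_REST],
        }

    if mode in ("quantile", "quartile", "quintile"):
        if mode == "quartile":
            n_bins = 4
        elif mode == "quintile":
            n_bins = 5
        if len(usable) < n_bins:
            raise ValueError(
                f"{len(usable)} peaks cannot be cut into {n_bins} quantile bins"
            )
        order = np.argsort(values, kind="stable")
        bins: list[list[ModuleScore]] = [list() for _ in range(n_bins)]
        for rank, idx in enumerate(np.array_split(order, n_bins) , start=0):
            for i in idx:
                usable[i].quantile_bin = rank
                bins[rank].append(usable[i])
        edges = [float(np.quantile(values, k / n_bins)) for k in range(n_bins + 1)]
        return {"mode": mode, "n_bins": n_bins, "bins": bins, "edges": edges}

    raise ValueError(f"unknown grouping mode {mode!r}")


# ---------------------------------------------------------------------------
# Peak → gene linking
# ---------------------------------------------------------------------------


def link_peaks_to_genes(
    scores: Sequence[ModuleScore],
    tss_table: pd.DataFrame,
    max_dist: int = DEFAULT_LINK_CAP,
    near_tss: int = DEFAULT_NEAR_TSS,
) -> list[PeakGeneLink]:
    """Link each peak to the nearest TSS within ``max_dist`` bp (inclusive).

    Distance is |motif center − TSS| on the same chromosome; ties are broken
    by the lexicographically smaller gene id. ``tss_table`` needs columns
    chrom, pos, gene_id (strand optional).
    """
    if tss_table.empty:
        raise ValueError("empty TSS table")
    links = []
    by_chrom = {
        chrom: grp.sort_values(["pos", "gene_id"]).reset_index(drop=True)
        for chrom, grp in tss_table.groupby("chrom")
    }
    for s in scores:
        grp = by_chrom.get(s.peak.chrom)
        if grp is None:
            continue
        center = s.hit.center_in(s.peak)
        pos = grp["pos"].to_numpy()
        dist = np.abs(pos - center)
        best = dist.min()
        if best > max_dist:
            continue
        cand = grp.loc[dist == best]
        gene = sorted(cand["gene_id"])[0]
        tss = int(cand.loc[cand["gene_id"] == gene, "pos"].iloc[0])
        links.append(
            PeakGeneLink(
                peak_id=s.peak.name or f"{s.peak.chrom}:{s.peak.start}-{s.peak.end}",
                gene_id=gene,
                distance=int(tss - center),
                within_10kb=abs(tss - center) <= near_tss,
            )
        )
    return links


# ---------------------------------------------------------------------------
# Interval algebra: induced peaks, responsive elements, consensus merging
# ---------------------------------------------------------------------------


def _any_overlap(iv: GenomicInterval, others: Iterable[GenomicInterval]) -> bool:
    return any(iv.overlaps(o) for o in others)


def induced_peaks(
    peaks_12h: Sequence[GenomicInterval], peaks_0h: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Stimulus-induced peaks: present at 12 h with no ≥1 bp overlap at 0 h."""
    return [p for p in peaks_12h if not _any_overlap(p, peaks_0h)]


def define_responsive_elements(
    p65_induced: Sequence[GenomicInterval],
    h3k27ac: Sequence[GenomicInterval],
) -> list[GenomicInterval]:
    """Induced p65 peaks co-occupied (≥1 bp overlap) by H3K27ac."""
    return [p for p in p65_induced if _any_overlap(p, h3k27ac)]


def merge_intervals(
    intervals: Sequence[GenomicInterval], bookended: bool = True
) -> list[GenomicInterval]:
    """Merge overlapping (and, by default, bookended) intervals per chromosome."""
    merged: list[GenomicInterval] = []
    for iv in sorted(intervals, key=lambda x: (x.chrom, x.start, x.end)):
        if merged:
            last = merged[-1]
            joined = iv.start <= last.end if bookended else iv.start < last.end
            if last.chrom == iv.chrom and joined:
                if iv.end > last.end:
                    merged[-1] = GenomicInterval(
                        last.chrom, last.start, iv.end, name=last.name
                    )
                continue
        merged.append(iv)
    return merged


def merge_consensus_peaks(
    peaks_first: Sequence[GenomicInterval],
    peaks_second: Sequence[GenomicInterval],
    blacklist: Sequence[GenomicInterval] = (),
) -> list[GenomicInterval]:
    """Consensus peak set: merge both inductions, drop blacklist overlaps."""
    merged = merge_intervals(list(peaks_first) + list(peaks_second))
    return [m for m in merged if not _any_overlap(m, blacklist)]


# ---------------------------------------------------------------------------
# Motif-anchored demethylation profile
# ---------------------------------------------------------------------------


def demethylation_profile(
    scores: Sequence[ModuleScore],
    meth_t0: pd.DataFrame,
    meth_t12: pd.DataFrame,
    window: int = 500,
    lowess_frac: float = DEFAULT_LOWESS_FRAC,
    grid_step: int = 10,
    min_cov: int = DEFAULT_MIN_COV,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-CpG methylation by signed distance to the κB motif, lowess-smoothed.

    Returns ``(scatter, curves)``. ``scatter`` has one row per covered CpG per
    peak: signed distance (motif strand orients the axis), level_t0, level_t12
    and their difference. ``curves`` tabulates lowess fits of level_t0,
    level_t12 and of the per-CpG difference (t0 − t12) on a fixed grid; the
    difference is smoothed after subtraction, not as a difference of fits.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    lut0 = _meth_lookup(meth_t0)
    lut12 = _meth_lookup(meth_t12)
    rows = []
    for s in scores:
        center = s.hit.center_in(s.peak)
        sign = 1 if s.hit.strand == "+" else -1
        for pos in s.cpg_positions:
            dist = (pos - center) * sign
            if abs(dist) > window:
                continue
            r0 = lut0.get((s.peak.chrom, pos))
            r12 = lut12.get((s.peak.chrom, pos))
            if r0 is None or r12 is None or r0[1] < min_cov or r12[1] < min_cov:
                continue
            rows.append((dist, r0[0], r12[0], r0[0] - r12[0]))
    scatter = pd.DataFrame(rows, columns=["distance", "level_t0", "level_t12", "diff"])
    if len(scatter) < 10:
        raise ValueError(
            f"only {len(scatter)} covered CpGs in ±{window} bp; "
            "need at least 10 for lowess smoothing"
        )
    grid = np.arange(-window, window + 1, grid_step, dtype=float)
    x = scatter["distance"].to_numpy(dtype=float)
    curves = {"distance": grid}
    for col in ("level_t0", "level_t12", "diff"):
        fitted = sm_lowess(
            scatter[col].to_numpy(), x, frac=lowess_frac, xvals=grid, is_sorted=False
        )
        curves[f"{col}_smooth"] = fitted
    return scatter, pd.DataFrame(curves)


# ---------------------------------------------------------------------------
# Signal tracks: normalization, profiles, eRNA, occupancy change
# ---------------------------------------------------------------------------


def _track_to_array(track: pd.DataFrame, length: int) -> np.ndarray:
    """Expand a bedGraph-style frame (chrom, start, end, value) to per-base."""
    arr = np.zeros(length)
    for row in track.itertuples(index=False):
        arr[int(row.start) : int(row.end)] = row.value
    return arr


def _mean_at_peaks(arr: np.ndarray, peaks: Sequence[GenomicInterval]) -> float:
    vals = np.concatenate([arr[p.start : p.end] for p in peaks])
    return float(vals.mean())


def normalize_signal(
    tracks: Mapping[str, pd.DataFrame],
    unmethylated_peaks: Sequence[GenomicInterval],
    genome_length: int,
) -> dict[str, pd.DataFrame]:
    """Depth-normalize tracks, then anchor them on unmethylated peaks.

    Each sample is first scaled to counts per million (total signal mass of
    one million), then multiplied by ``s_j`` = (grand mean across samples of
    the mean signal at initially unmethylated peaks) / (sample j's mean signal
    there). After scaling every sample has the same mean signal at the
    unmethylated anchor peaks — regions whose occupancy the methylation state
    cannot have changed.
    """
    if not unmethylated_peaks:
        raise ValueError("need at least one initially unmethylated anchor peak")
    cpm_arrays = {}
    for sample, track in tracks.items():
        arr = _track_to_array(track, genome_length)
        total = arr.sum()
        if total <= 0:
            raise ValueError(f"sample {sample!r} has zero total signal")
        cpm_arrays[sample] = arr * (1e6 / total)
    anchor_means = {
        sample: _mean_at_peaks(arr, unmethylated_peaks)
        for sample, arr in cpm_arrays.items()
    }
    for sample, mean in anchor_means.items():
        if mean <= 0:
            raise ValueError(
                f"sample {sample!r} has zero signal at unmethylated anchor peaks"
            )
    grand = float(np.mean(list(anchor_means.values())))
    out = {}
    for sample, track in tracks.items():
        arr = _track_to_array(track, genome_length)
        total = arr.sum()
        scale = (1e6 / total) * (grand / anchor_means[sample])
        scaled = track.copy()
        scaled["value"] = scaled["value"] * scale
        out[sample] = scaled
    return out


def aggregate_profile(
    track: pd.DataFrame,
    scores: Sequence[ModuleScore],
    genome_length: int,
    half_window: int = 500,
    bin_size: int = 25,
) -> pd.DataFrame:
    """Mean binned signal across peaks, centered on the motif, strand-oriented."""
    if (2 * half_window) % bin_size != 0:
        raise ValueError("bin size must divide the window evenly")
    arr = _track_to_array(track, genome_length)
    n_bins = 2 * half_window // bin_size
    profiles = []
    for s in scores:
        center = s.hit.center_in(s.peak)
        lo, hi = center - half_window, center + half_window
        if lo < 0 or hi > genome_length:
            continue
        segment = arr[lo:hi]
        if s.hit.strand == "-":
            segment = segment[::-1]
        profiles.append(segment.reshape(n_bins, bin_size).mean(axis=1))
    if not profiles:
        raise ValueError("no peaks fit inside the genome for profiling")
    mean_profile = np.mean(profiles, axis=0)
    offsets = np.arange(-half_window, half_window, bin_size) + bin_size // 2
    return pd.DataFrame({"offset": offsets, "signal": mean_profile})


def erna_rpkm(
    counts: pd.DataFrame, peak_lengths: Mapping[str, int], library_sizes: Mapping[str, float]
) -> pd.DataFrame:
    """eRNA RPKM per peak per sample: count / (length_kb × library_millions).

    ``counts`` is peaks × samples of raw read counts over p65-bound regions.
    """
    out = counts.astype(float).copy()
    lengths = np.array([peak_lengths[p] for p in counts.index], dtype=float)
    if (lengths <= 0).any():
        raise ValueError("peak lengths must be positive")
    if (out.to_numpy() < 0).any():
        raise ValueError("read counts must be non-negative")
    for sample in out.columns:
        lib = library_sizes[sample]
        if lib <= 0:
            raise ValueError(f"library size for {sample!r} must be positive")
        out[sample] = out[sample] / (lengths / 1e3) / (lib / 1e6)
    return out


def occupancy_change(
    signal_first: Mapping[str, float],
    signal_second: Mapping[str, float],
    fold_split: float = DEFAULT_OCCUPANCY_SPLIT,
) -> pd.DataFrame:
    """Classify peaks by occupancy change between inductions.

    The log2 ratio second/first at each peak is split at ±log2(``fold_split``)
    (inclusive) into higher_in_second / lower_in_second / unchanged.
    """
    if fold_split <= 1:
        raise ValueError("fold_split must exceed 1")
    cut = math.log2(fold_split)
    rows = []
    for peak_id in signal_first:
        a, b = signal_first[peak_id], signal_second[peak_id]
        if a <= 0 or b <= 0:
            raise ValueError(f"non-positive signal at peak {peak_id!r}")
        ratio = math.log2(b / a)
        if ratio >= cut:
            cls = "higher_in_second"
        elif ratio <= -cut:
            cls = "lower_in_second"
        else:
            cls = "unchanged"
        rows.append((peak_id, ratio, cls))
    return pd.DataFrame(rows, columns=["peak_id", "log2_ratio", "class"])


def scores_to_frame(scores: Sequence[ModuleScore]) -> pd.DataFrame:
    """Flatten ModuleScores into a tidy frame for reporting."""
    rows = []
    for s in scores:
        rows.append(
            {
                "peak_id": s.peak.name or f"{s.peak.chrom}:{s.peak.start}-{s.peak.end}",
                "chrom": s.peak.chrom,
                "start": s.peak.start,
                "end": s.peak.end,
                "motif_start": s.peak.start + s.hit.offset,
                "motif_strand": s.hit.strand,
                "motif_score": s.hit.score,
                "n_cpg_flank": s.n_cpg_flank,
                "n_used": s.n_used,
                "level_t0": s.level_t0,
                "level_t12": s.level_t12,
                "m_t0": s.m_t0,
                "m_t12": s.m_t12,
                "delta_m": s.delta_m,
                "initial_state": s.initial_state,
                "demethylation_group": s.demethylation_group,
                "quantile_bin": s.quantile_bin,
            }
        )
    return pd.DataFrame(rows)
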