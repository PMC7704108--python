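"""Synthetic data with the statistical structure the analysis assumes.

Generates every input the pipeline consumes, so all stages run offline:

* bisulfite clone sets for a CMV-promoter-like locus (17 CpGs) and two
  MER11B-like retroviral elements (7 CpGs each, κB site in the middle);
* a toy chromosome with p65 peaks that embed one κB consensus each, CpG
  landscapes of planted density and initial methylation, and genes whose TSS
  distances to peaks span the <10 kb, 10–100 kb and >100 kb strata;
* per-CpG methylation count tables at baseline (t0) and after 12 days of
  sustained stimulation (t12), with motif-anchored exponential demethylation
  whose amplitude depends on genotype (WT vs. RELA/TET knockouts);
* per-peak occupancy signal decaying exponentially with total methylation;
* a five-condition expression table with planted memory genes, a reporter,
  responsive-only controls and an IL32-like elevated-baseline non-memory gene.

Every generator is deterministic given its :class:`SimulationConfig` seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .clones import CloneSet, Locus, call_clones
from .config import SimulationConfig
from .io import METH_COLUMNS
from .peaks import GenomicInterval

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# Sequence helpers
# ---------------------------------------------------------------------------


def _random_sequence_no_cpg(rng: np.random.Generator, length: int) -> list[str]:
    seq = list(rng.choice(_BASES, size=length))
    for i in range(length - 1):
        if seq[i] == "C" and seq[i + 1] == "G":
            seq[i + 1] = "T"
    return seq


def _scrub_stray_cpgs(
    seq: list[str], planted_cpgs: set[int], motif_footprints: set[int]
) -> None:
    """Remove CpG dinucleotides that were not planted deliberately."""
    for i in range(len(seq) - 1):
        if seq[i] == "C" and seq[i + 1] == "G" and i not in planted_cpgs:
            if i in motif_footprints:       # C inside a motif: mutate the G outside
                seq[i + 1] = "T"
            else:                            # otherwise mutate the C
                seq[i] = "A"


def _plant(seq: list[str], start: int, text: str) -> None:
    seq[start : start + len(text)] = list(text)


# ---------------------------------------------------------------------------
# Bisulfite clone simulation
# ---------------------------------------------------------------------------


@dataclass
class SimulatedClones:
    """A locus plus raw simulated clone sequences (bisulfite images)."""

    locus: Locus
    sequences: list[str]
    per_cpg_prob: np.ndarray

    def clone_records(self) -> list[tuple[str, str]]:
        return [(f"clone_{i:03d}", s) for i, s in enumerate(self.sequences)]

    def to_clone_set(self) -> CloneSet:
        return call_clones(self.locus, self.clone_records())


def simulate_bisulfite_clones(
    reference: str | Locus,
    per_cpg_prob: Sequence[float],
    n_clones: int,
    config: SimulationConfig,
) -> SimulatedClones:
    """Simulate Sanger clones of a bisulfite-converted locus (top strand).

    Each clone is the bisulfite image of the reference: non-CpG cytosines are
    converted C→T with probability ``conversion_efficiency``; each CpG
    cytosine is retained (methylated) with its per-site probability, otherwise
    read as T; finally every base suffers a random substitution at
    ``sequencing_error_rate``. Clone order is deterministic given the seed.
    """
    locus = reference if isinstance(reference, Locus) else Locus("locus", reference)
    probs = np.asarray(per_cpg_prob, dtype=float)
    if len(probs) != locus.n_cpgs:
        raise ValueError(
            f"per_cpg_prob has length {len(probs)} but the locus has "
            f"{locus.n_cpgs} CpGs"
        )
    if ((probs < 0) | (probs > 1)).any():
        raise ValueError("per-CpG probabilities must be in [0, 1]")
    if n_clones <= 0:
        raise ValueError("n_clones must be positive")

    rng = np.random.default_rng(config.seed)
    ref = np.array(list(locus.reference))
    cpg_pos = np.array(locus.cpg_positions)
    cpg_set = set(locus.cpg_positions)
    non_cpg_c = np.array(
        [i for i, b in enumerate(locus.reference) if b == "C" and i not in cpg_set],
        dtype=int,
    )

    sequences = []
    for _ in range(n_clones):
        clone = ref.copy()
        meth = rng.random(len(cpg_pos)) < probs
        clone[cpg_pos[~meth]] = "T"
        converted = rng.random(len(non_cpg_c)) < config.conversion_efficiency
        clone[non_cpg_c[converted]] = "T"
        if config.sequencing_error_rate > 0:
            err = rng.random(len(clone)) < config.sequencing_error_rate
            for i in np.flatnonzero(err):
                clone[i] = rng.choice([b for b in "ACGT" if b != clone[i]])
        sequences.append("".join(clone))
    return SimulatedClones(locus=locus, sequences=sequences, per_cpg_prob=probs)


# ---------------------------------------------------------------------------
# Reference-like loci
# ---------------------------------------------------------------------------


def _build_locus(
    locus_id: str,
    region: str,
    length: int,
    n_cpgs: int,
    motif_starts: Sequence[int],
    consensus: str,
    seed: int,
) -> Locus:
    rng = np.random.default_rng(seed)
    seq = _random_sequence_no_cpg(rng, length)
    footprints: set[int] = set()
    for start in motif_starts:
        _plant(seq, start, consensus)
        footprints.update(range(start, start + len(consensus)))
    blocked = set(footprints) | {f - 1 for f in footprints}
    candidates = [
        p for p in range(2, length - 2, 4) if p not in blocked and (p + 1) not in blocked
    ]
    positions = sorted(rng.choice(candidates, size=n_cpgs, replace=False))
    for p in positions:
        _plant(seq, p, "CG")
    _scrub_stray_cpgs(seq, set(positions), footprints)
    return Locus(locus_id, "".join(seq), tuple(positions), region=region)


def cmv_like_locus(consensus: str = "GGGACTTTCC") -> Locus:
    """A CMV-promoter-like amplicon: 17 CpGs, several κB sites, ~400 bp."""
    return _build_locus(
        "CMVp", "CMV", length=400, n_cpgs=17,
        motif_starts=[60, 180, 300], consensus=consensus, seed=20201106,
    )


def mer11b_like_loci(consensus: str = "GGGACTTTCC") -> tuple[Locus, Locus]:
    """Two MER11B-like LTR elements: 7 CpGs flanking one central κB site.

    The left element is 209 bp and the right 166 bp, mirroring the paired
    retroviral enhancers upstream of a memory gene.
    """
    left = _build_locus(
        "MER11B_left", "MER11B-left", length=209, n_cpgs=7,
        motif_starts=[100], consensus=consensus, seed=11,
    )
    right = _build_locus(
        "MER11B_right", "MER11B-right", length=166, n_cpgs=7,
        motif_starts=[78], consensus=consensus, seed=12,
    )
    return left, right


# ---------------------------------------------------------------------------
# Toy genome
# ---------------------------------------------------------------------------

PEAK_HALF_WIDTH = 300

# (CpG density class, initial methylation class) cycled over peaks
_PEAK_CLASSES = (
    ("low", "unmethylated"),
    ("low", "methylated"),
    ("high", "unmethylated"),
    ("high", "methylated"),
)


@dataclass
class ToyPeak:
    interval: GenomicInterval
    motif_start: int                 # genomic coordinate
    motif_strand: str
    cpg_positions: tuple[int, ...]   # genomic coordinates, strictly increasing
    initial_prob: np.ndarray         # per-CpG initial methylation probability
    density_class: str
    methylation_class: str

    @property
    def motif_center(self) -> int:
        return self.motif_start + len("GGGACTTTCC") // 2


@dataclass
class ToyGenome:
    chrom: str
    sequence: str
    genes: list[tuple[str, int, str]]     # (gene_id, TSS, strand)
    peaks: list[ToyPeak]
    config: SimulationConfig = field(repr=False, default=None)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def tss_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(self.chrom, tss, strand, gid) for gid, tss, strand in self.genes],
            columns=["chrom", "pos", "strand", "gene_id"],
        )

    def peak_intervals(self) -> list[GenomicInterval]:
        return [p.interval for p in self.peaks]


def simulate_toy_genome(config: SimulationConfig) -> ToyGenome:
    """Build the toy chromosome with planted peaks, CpG landscapes and genes.

    Peaks cycle through four classes crossing CpG density (low: 0–5 CpGs in
    the ±250 bp motif flank; high: 10–25) with initial methylation
    (unmethylated < 20 %; methylated ≥ 50 %, drawn in 0.70–0.95). Genes are
    placed so nearest-peak TSS distances span < 10 kb, 10–100 kb and > 100 kb.
    """
    if config.n_peaks < 2 or config.n_genes < 2:
        raise ValueError("need at least 2 peaks and 2 genes")
    rng = np.random.default_rng(config.seed)
    length = config.genome_length
    consensus = config.kappa_b_consensus
    flank = 250

    peak_lo, peak_hi = int(0.05 * length), int(0.65 * length)
    spacing = (peak_hi - peak_lo) // config.n_peaks
    if spacing < 2 * PEAK_HALF_WIDTH + 200 or length - peak_hi < 130_000:
        raise ValueError(
            f"genome of {length} bp is too short to place {config.n_peaks} peaks "
            "and the full gene-distance strata"
        )

    seq = _random_sequence_no_cpg(rng, length)
    peaks: list[ToyPeak] = []
    footprints: set[int] = set()
    planted: set[int] = set()

    for k in range(config.n_peaks):
        center = peak_lo + k * spacing + spacing // 2
        density, meth_class = _PEAK_CLASSES[k % len(_PEAK_CLASSES)]
        motif_start = center - len(consensus) // 2
        _plant(seq, motif_start, consensus)
        footprints.update(range(motif_start, motif_start + len(consensus)))

        n_cpg = (
            int(rng.integers(0, 6)) if density == "low" else int(rng.integers(10, 26))
        )
        blocked = set(range(motif_start - 1, motif_start + len(consensus) + 1))
        candidates = [
            p
            for p in range(center - flank + 2, center + flank - 2, 4)
            if p not in blocked and (p + 1) not in blocked
        ]
        positions = sorted(rng.choice(candidates, size=n_cpg, replace=False)) if n_cpg else []
        for p in positions:
            _plant(seq, p, "CG")
        planted.update(positions)
        if meth_class == "unmethylated":
            probs = rng.uniform(0.02, 0.15, size=n_cpg)
        else:
            probs = rng.uniform(0.70, 0.95, size=n_cpg)
        interval = GenomicInterval(
            config.chrom, center - PEAK_HALF_WIDTH, center + PEAK_HALF_WIDTH,
            name=f"peak_{k:03d}",
        )
        peaks.append(
            ToyPeak(
                interval=interval,
                motif_start=motif_start,
                motif_strand="+",
                cpg_positions=tuple(int(p) for p in positions),
                initial_prob=probs,
                density_class=density,
                methylation_class=meth_class,
            )
        )

    _scrub_stray_cpgs(seq, planted, footprints)

    # Genes: cycle near (<10 kb of a peak), mid (10–100 kb past the last
    # peak) and far (>100 kb past the last peak) strata.
    last_center = peaks[-1].motif_center
    genes = []
    strands = ("+", "-")
    for g in range(config.n_genes):
        stratum = g % 3
        if stratum == 0:
            anchor = peaks[int(rng.integers(0, config.n_peaks))].motif_center
            offset = int(rng.integers(500, 9_500)) * (1 if rng.random() < 0.5 else -1)
            tss = int(np.clip(anchor + offset, 0, length - 1))
        elif stratum == 1:
            tss = last_center + int(rng.integers(12_000, 95_000))
        else:
            tss = last_center + int(rng.integers(110_000, length - last_center - 1_000))
        genes.append((f"G{g:04d}", tss, strands[g % 2]))

    return ToyGenome(
        chrom=config.chrom, sequence="".join(seq), genes=genes, peaks=peaks,
        config=config,
    )


# ---------------------------------------------------------------------------
# Methylation dynamics
# ---------------------------------------------------------------------------


def demethylation_amount(
    distance_bp: np.ndarray, config: SimulationConfig
) -> np.ndarray:
    """g·δ·exp(−|d|/λ): methylation loss at distance d from the motif center."""
    return (
        config.genotype_multiplier
        * config.demethylation_scale
        * np.exp(-np.abs(distance_bp) / config.decay_length)
    )


def simulate_methylation_dynamics(
    genome: ToyGenome, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-CpG methylation count tables at t0 and after sustained stimulation.

    The underlying level at t12 is t0 minus a motif-anchored exponential
    demethylation, scaled by the genotype multiplier and clipped to [0, 1];
    methylated/unmethylated counts are binomial draws at the configured
    coverage.
    """
    rng = np.random.default_rng(config.seed + 1)
    rows0, rows12 = [], []
    for peak in genome.peaks:
        if not peak.cpg_positions:
            continue
        pos = np.asarray(peak.cpg_positions)
        p0 = peak.initial_prob
        loss = demethylation_amount(pos - peak.motif_center, config)
        p12 = np.clip(p0 - loss, 0.0, 1.0)
        for p, a, b in zip(pos, p0, p12):
            n = config.coverage
            m0 = int(rng.binomial(n, a))
            m12 = int(rng.binomial(n, b))
            rows0.append((genome.chrom, int(p), m0 / n, m0, n - m0))
            rows12.append((genome.chrom, int(p), m12 / n, m12, n - m12))
    t0 = pd.DataFrame(rows0, columns=METH_COLUMNS)
    t12 = pd.DataFrame(rows12, columns=METH_COLUMNS)
    return t0, t12


# ---------------------------------------------------------------------------
# Occupancy
# ---------------------------------------------------------------------------


def simulate_occupancy(
    genome: ToyGenome, meth: pd.DataFrame, config: SimulationConfig
) -> pd.DataFrame:
    """Per-peak summit occupancy decaying exponentially with total methylation.

    Summit signal = amplitude · exp(−β·M) · ε with mean-one lognormal noise ε,
    where M is the sum of per-CpG methylation levels over the peak's flank
    CpGs in ``meth``. Multiplicative noise keeps the signal strictly positive
    and its group means ordered. Returns peak_id, m_total, signal.
    """
    lookup = {
        (r.chrom, int(r.pos)): (r.count_meth, r.count_meth + r.count_unmeth)
        for r in meth.itertuples(index=False)
    }
    rng = np.random.default_rng(config.seed + 2)
    sd = config.occupancy_noise_sd
    rows = []
    for peak in genome.peaks:
        m = 0.0
        for p in peak.cpg_positions:
            rec = lookup.get((genome.chrom, p))
            if rec is None:
                raise ValueError(
                    f"methylation table does not cover CpG at {genome.chrom}:{p}"
                )
            cm, cov = rec
            m += cm / cov if cov > 0 else 0.0
        noise = float(np.exp(rng.normal(-sd * sd / 2.0, sd))) if sd > 0 else 1.0
        signal = config.occupancy_amplitude * np.exp(-config.occupancy_decay * m) * noise
        rows.append((peak.interval.name, m, signal))
    return pd.DataFrame(rows, columns=["peak_id", "m_total", "signal"])


def occupancy_track(
    genome: ToyGenome, occupancy: pd.DataFrame, bin_size: int = 25, shape_sd: float = 100.0
) -> pd.DataFrame:
    """Render per-peak summit signals as a binned bedGraph-style track.

    Each peak contributes a Gaussian-shaped bump of width ``shape_sd`` bp
    centered on its motif.
    """
    summit = dict(zip(occupancy["peak_id"], occupancy["signal"]))
    n_bins = genome.length // bin_size
    values = np.zeros(n_bins)
    centers = (np.arange(n_bins) + 0.5) * bin_size
    for peak in genome.peaks:
        s = summit[peak.interval.name]
        values += s * np.exp(-((centers - peak.motif_center) ** 2) / (2 * shape_sd**2))
    keep = values > 1e-9
    return pd.DataFrame(
        {
            "chrom": genome.chrom,
            "start": (np.arange(n_bins) * bin_size)[keep],
            "end": (np.arange(n_bins) * bin_size + bin_size)[keep],
            "value": values[keep],
        }
    )


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

from .expression import CONDITIONS, ExpressionMatrix  # noqa: E402


@dataclass
class MemoryGenePlan:
    """Planted condition means and expected classifications.

    ``means`` is a gene × condition table of true FPKM means. The three gene
    lists name which planted genes are full memory genes, which are responsive
    without memory, and which are IL32-like (elevated recovery baseline but no
    stronger second induction).
    """

    means: pd.DataFrame
    memory_genes: tuple[str, ...]
    responsive_only: tuple[str, ...]
    il32_like: tuple[str, ...]

    def __post_init__(self):
        listed = set(self.memory_genes) | set(self.responsive_only) | set(self.il32_like)
        unknown = listed - set(self.means.index)
        if unknown:
            raise ValueError(f"plan references unknown genes: {sorted(unknown)}")
        missing = [c for c in CONDITIONS if c not in self.means.columns]
        if missing:
            raise ValueError(f"plan means lack condition(s): {missing}")


#: Planted FPKM means (naive, first 12 h, sustained 12 d, recovery, second 12 h)
#: for the named genes. Memory genes satisfy all classifier criteria by
#: construction; IL32-like has an elevated recovery baseline but a flat
#: second/first ratio; NFKB-pathway controls respond without memory.
_PLANTED_MEANS = {
    # gene:        (naive, first, sustained, recovery, second)
    "CALCB":       (2.0, 173.0, 699.0, 30.0, 347.0),
    "EGFP":        (1.0, 80.0, 400.0, 25.0, 242.0),
    "PTGES":       (3.0, 60.0, 300.0, 20.0, 150.0),
    "CCL2":        (5.0, 90.0, 200.0, 10.0, 131.0),
    "TNF":         (4.0, 70.0, 150.0, 8.0, 98.0),
    "LHX2":        (2.0, 30.0, 80.0, 5.0, 45.0),
    "IL32":        (4.0, 40.0, 120.0, 20.0, 40.0),
    "NFKB2":       (10.0, 100.0, 120.0, 12.0, 100.0),
    "NFKBIA":      (20.0, 160.0, 180.0, 22.0, 160.0),
}

PLANTED_MEMORY = ("CALCB", "CCL2", "EGFP", "LHX2", "PTGES", "TNF")
PLANTED_RESPONSIVE_ONLY = ("NFKB2", "NFKBIA")
PLANTED_IL32_LIKE = ("IL32",)


def default_memory_plan(config: SimulationConfig) -> MemoryGenePlan:
    """The default planted design plus lognormal background genes.

    Background genes have a constant mean across all five conditions, drawn
    lognormally around 10 FPKM, so none is responsive.
    """
    rng = np.random.default_rng(config.seed + 3)
    rows = {g: list(v) for g, v in _PLANTED_MEANS.items()}
    for i in range(config.n_genes):
        base = float(np.exp(rng.normal(np.log(10.0), 1.0)))
        rows[f"BG{i:04d}"] = [base] * 5
    means = pd.DataFrame.from_dict(rows, orient="index", columns=list(CONDITIONS))
    means.index.name = "gene"
    return MemoryGenePlan(
        means=means,
        memory_genes=PLANTED_MEMORY,
        responsive_only=PLANTED_RESPONSIVE_ONLY,
        il32_like=PLANTED_IL32_LIKE,
    )


def simulate_expression(
    config: SimulationConfig, plan: MemoryGenePlan | None = None
) -> ExpressionMatrix:
    """Five-condition FPKM table with replicate noise around planted means.

    Replicate values are lognormal around the planted condition means with
    ``noise_sd`` in log2 units; at zero noise they equal the means exactly.
    """
    if plan is None:
        plan = default_memory_plan(config)
    rng = np.random.default_rng(config.seed + 4)
    genes = plan.means.index
    columns = pd.MultiIndex.from_tuples(
        [(c, f"rep{r + 1}") for c in CONDITIONS for r in range(config.n_replicates)],
        names=["condition", "replicate"],
    )
    values = np.empty((len(genes), len(columns)))
    for j, (cond, _rep) in enumerate(columns):
        mean = plan.means[cond].to_numpy(dtype=float)
        if config.noise_sd > 0:
            values[:, j] = mean * np.exp2(rng.normal(0.0, config.noise_sd, size=len(genes)))
        else:
            values[:, j] = mean
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=columns))


# ---------------------------------------------------------------------------
# Bundle emission
# ---------------------------------------------------------------------------


def emit_all(outdir: str | Path, config: SimulationConfig, n_clones: int = 30) -> dict:
    """Write the full synthetic fixture bundle to ``outdir``; return the paths."""
    from . import io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    locus = cmv_like_locus(config.kappa_b_consensus)
    sim = simulate_bisulfite_clones(
        locus, np.full(locus.n_cpgs, 0.906), n_clones, config
    )
    io.write_fasta(outdir / "cmv_locus.fa", {locus.id: locus.reference})
    io.write_fasta(outdir / "cmv_clones.fa", dict(sim.clone_records()))

    genome = simulate_toy_genome(config)
    io.write_fasta(outdir / "genome.fa", {genome.chrom: genome.sequence})
    io.write_bed(outdir / "peaks.bed", genome.peak_intervals())
    io.write_tss_table(outdir / "tss.tsv", genome.tss_table())

    t0, t12 = simulate_methylation_dynamics(genome, config)
    io.write_bismark_cov(outdir / "meth_t0.cov", t0)
    io.write_bismark_cov(outdir / "meth_t12.cov", t12)

    occ = simulate_occupancy(genome, t0, config)
    io.write_bedgraph(outdir / "occupancy_t0.bedgraph", occupancy_track(genome, occ))

    expr = simulate_expression(config)
    expr.to_tsv(outdir / "expression.tsv")

    from .peaks import pwm_from_consensus

    io.write_pwm(outdir / "kb_motif.pwm", pwm_from_consensus(config.kappa_b_consensus))
    config.to_yaml(outdir / "config.yaml")
    return {p.name: p for p in sorted(outdir.iterdir())}
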