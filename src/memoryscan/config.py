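"""Simulation and run configuration.

All tunable knobs of the synthetic-data generator and the analysis live in
:class:`SimulationConfig`. Defaults encode the study conditions the generators
emulate: a 12-hour acute NF-κB response followed by 12 days of sustained
TNF-α exposure, with active demethylation around κB sites that depends on the
genotype (wild type vs. RELA or TET knockouts).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

#: Classic NF-κB (p65/p50) consensus binding site planted into simulated peaks.
KAPPA_B_CONSENSUS = "GGGACTTTCC"

#: Genotype multipliers on the demethylation amplitude. Wild type demethylates
#: fully; TET2 loss removes most of the activity, TET3 loss some, TET1 loss
#: almost none; RELA loss (no p65 binding) or triple TET loss abolishes it.
GENOTYPE_DEMETHYLATION = {
    "WT": 1.0,
    "TET1_KO": 0.95,
    "TET2_KO": 0.3,
    "TET3_KO": 0.7,
    "RELA_KO": 0.05,
    "TET_TKO": 0.05,
}

GENOTYPES = tuple(GENOTYPE_DEMETHYLATION)


@dataclass
class SimulationConfig:
    """Knobs for the synthetic-data generators.

    Parameters
    ----------
    seed
        Seed for all randomness; identical configs give bit-identical output.
    n_genes
        Number of background genes in the toy genome / expression table.
    n_peaks
        Number of p65 peaks planted in the toy genome.
    genome_length
        Toy chromosome length in bp.
    conversion_efficiency
        Probability that a non-CpG cytosine is bisulfite-converted to T.
    sequencing_error_rate
        Per-base probability of a random substitution in a Sanger clone read.
    genotype
        One of ``WT, TET1_KO, TET2_KO, TET3_KO, RELA_KO, TET_TKO``.
    demethylation_scale
        δ — maximal per-CpG methylation loss at the motif center (fraction).
    decay_length
        λ — exponential decay length (bp) of demethylation away from the motif.
    occupancy_decay
        β — occupancy loss per methylated-CpG equivalent; the summit signal is
        proportional to exp(−β·M) where M is total methylation.
    occupancy_amplitude
        Summit signal of a fully unmethylated peak (arbitrary units).
    occupancy_noise_sd
        SD of the mean-one lognormal noise on simulated summit signals
        (natural-log scale).
    coverage
        Per-CpG sequencing coverage for simulated methylation count tables.
    noise_sd
        Replicate noise of simulated expression, in log2-FPKM units.
    n_replicates
        Replicates per expression condition.
    """

    seed: int = 0
    n_genes: int = 500
    n_peaks: int = 40
    genome_length: int = 1_000_000
    conversion_efficiency: float = 0.99
    sequencing_error_rate: float = 0.001
    genotype: str = "WT"
    demethylation_scale: float = 0.6
    decay_length: float = 300.0
    occupancy_decay: float = math.log(2)
    occupancy_amplitude: float = 100.0
    occupancy_noise_sd: float = 0.2
    coverage: int = 30
    noise_sd: float = 0.1
    n_replicates: int = 3
    chrom: str = "chrSim"
    kappa_b_consensus: str = field(default=KAPPA_B_CONSENSUS)

    def __post_init__(self) -> None:
        for name in ("conversion_efficiency", "sequencing_error_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if not 0.0 <= self.demethylation_scale <= 1.0:
            raise ValueError(
                f"demethylation_scale must be in [0, 1], got {self.demethylation_scale}"
            )
        for name in ("n_genes", "n_peaks", "genome_length", "coverage", "n_replicates"):
            value = getattr(self, name)
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if self.genotype not in GENOTYPE_DEMETHYLATION:
            raise ValueError(
                f"unknown genotype {self.genotype!r}; expected one of {GENOTYPES}"
            )
        if self.decay_length <= 0:
            raise ValueError("decay_length must be positive")
        if self.noise_sd < 0 or self.occupancy_noise_sd < 0:
            raise ValueError("noise SDs must be non-negative")

    @property
    def genotype_multiplier(self) -> float:
        return GENOTYPE_DEMETHYLATION[self.genotype]

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)


# Analysis-side default thresholds (echoed by the CLI).
DEFAULT_FC_MIN = 2.0          # responsiveness fold change, strict >
DEFAULT_ALPHA = 0.01          # responsiveness p-value cutoff
DEFAULT_MEMORY_RATIO = 1.3    # second/first induction ratio, inclusive ≥
DEFAULT_FPKM_MIN = 5.0        # expression floor in the second induction, strict >
DEFAULT_FLANK = 250           # bp around the κB motif center for CpG accounting
DEFAULT_MIN_COV = 5           # per-CpG coverage filter
DEFAULT_LINK_CAP = 100_000    # peak-to-gene distance cap in bp
DEFAULT_NEAR_TSS = 10_000     # "near TSS" stratification distance in bp
DEFAULT_LOWESS_FRAC = 0.3     # lowess span for demethylation profiles
DEFAULT_OCCUPANCY_SPLIT = 1.5 # fold change splitting higher/lower occupancy
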