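"""Locus-specific bisulfite clone analysis.

Quantifies DNA methylation of a PCR-amplified locus from Sanger-sequenced
clones of bisulfite-converted DNA — the analysis behind classic "lollipop"
plots in which each horizontal line is one clone, filled circles are
methylated CpGs and open circles are unmethylated CpGs.

Clones are compared gaplessly to the unconverted reference (amplicons of a
fixed locus; indel-bearing clones fail the length check). Top strand only:
at each CpG cytosine, a retained C is called methylated and a converted T
unmethylated. Conversion efficiency is estimated from non-CpG cytosines and
used for BiQ-style quality filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

DEFAULT_MIN_CONVERSION = 0.95
DEFAULT_MAX_MISMATCH = 0.10

GLYPHS = {"METH": "*", "UNMETH": "o", "MISSING": "."}
GLYPH_TO_CALL = {v: k for k, v in GLYPHS.items()}


class Call(str, Enum):
    """Methylation call at one CpG of one clone."""

    METH = "METH"
    UNMETH = "UNMETH"
    MISSING = "MISSING"


def find_cpg_positions(sequence: str) -> list[int]:
    """0-based offsets of the C of every CpG dinucleotide in ``sequence``."""
    seq = sequence.upper()
    return [i for i in range(len(seq) - 1) if seq[i] == "C" and seq[i + 1] == "G"]


@dataclass(frozen=True)
class Locus:
    """A bisulfite amplicon: unconverted genomic reference plus CpG positions."""

    id: str
    reference: str
    cpg_positions: tuple[int, ...] = ()
    region: str = ""

    def __post_init__(self):
        ref = self.reference.upper()
        object.__setattr__(self, "reference", ref)
        positions = tuple(self.cpg_positions) or tuple(find_cpg_positions(ref))
        object.__setattr__(self, "cpg_positions", positions)
        if not positions:
            raise ValueError(f"locus {self.id!r} contains no CpG")
        if list(positions) != sorted(set(positions)):
            raise ValueError("CpG positions must be strictly increasing")
        for p in positions:
            if p < 0 or p + 1 >= len(ref) or ref[p] != "C" or ref[p + 1] != "G":
                raise ValueError(f"position {p} does not index a CpG in the reference")

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_positions)


@dataclass(frozen=True)
class CloneMethylationPattern:
    clone_id: str
    calls: tuple[Call, ...]
    conversion_rate: float
    mismatch_rate: float


@dataclass
class CloneSet:
    """All clone patterns of one locus, plus the QC thresholds applied."""

    locus: Locus
    patterns: list[CloneMethylationPattern] = field(default_factory=list)
    min_conversion: float | None = None
    max_mismatch: float | None = None
    n_removed: int = 0

    def __post_init__(self):
        n = self.locus.n_cpgs
        for p in self.patterns:
            if len(p.calls) != n:
                raise ValueError(
                    f"clone {p.clone_id!r} has {len(p.calls)} calls for a "
                    f"{n}-CpG locus"
                )

    def __len__(self) -> int:
        return len(self.patterns)


def call_clone(locus: Locus, clone_seq: str, clone_id: str = "clone") -> CloneMethylationPattern:
    """Call per-CpG methylation of one Sanger clone against the reference.

    At each CpG cytosine an observed C is METH, T is UNMETH, anything else
    (including N) is MISSING. The conversion rate is the fraction of non-CpG
    reference cytosines read as T; the mismatch rate is the fraction of
    non-cytosine reference positions that disagree with the clone.
    """
    if not clone_seq:
        raise ValueError("empty clone sequence")
    ref = locus.reference
    seq = clone_seq.upper()
    if len(seq) != len(ref):
        raise ValueError(
            f"clone length {len(seq)} != reference length {len(ref)} "
            "(gapless comparison; indel-bearing clones are rejected)"
        )
    cpg_set = set(locus.cpg_positions)

    calls = []
    for p in locus.cpg_positions:
        base = seq[p]
        calls.append(Call.METH if base == "C" else Call.UNMETH if base == "T" else Call.MISSING)

    non_cpg_c = [i for i, b in enumerate(ref) if b == "C" and i not in cpg_set]
    converted = sum(1 for i in non_cpg_c if seq[i] == "T")
    conversion_rate = converted / len(non_cpg_c) if non_cpg_c else 1.0

    non_c = [i for i, b in enumerate(ref) if b != "C"]
    mismatched = sum(1 for i in non_c if seq[i] != ref[i])
    mismatch_rate = mismatched / len(non_c) if non_c else 0.0

    return CloneMethylationPattern(clone_id, tuple(calls), conversion_rate, mismatch_rate)


def call_clones(locus: Locus, clone_seqs: Iterable[tuple[str, str]]) -> CloneSet:
    """Call a whole set of ``(clone_id, sequence)`` pairs into a CloneSet."""
    patterns = [call_clone(locus, seq, cid) for cid, seq in clone_seqs]
    return CloneSet(locus, patterns)


def qc_filter(
    clones: CloneSet,
    min_conversion: float = DEFAULT_MIN_CONVERSION,
    max_mismatch: float = DEFAULT_MAX_MISMATCH,
) -> CloneSet:
    """Drop clones with poor bisulfite conversion or too many mismatches."""
    for name, value in (("min_conversion", min_conversion), ("max_mismatch", max_mismatch)):
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {value}")
    kept = [
        p
        for p in clones.patterns
        if p.conversion_rate >= min_conversion and p.mismatch_rate <= max_mismatch
    ]
    return CloneSet(
        locus=clones.locus,
        patterns=kept,
        min_conversion=min_conversion,
        max_mismatch=max_mismatch,
        n_removed=clones.n_removed + len(clones.patterns) - len(kept),
    )


def _call_matrix(clones: CloneSet) -> np.ndarray:
    """Clone × CpG matrix with 1=METH, 0=UNMETH, nan=MISSING."""
    mat = np.full((len(clones), clones.locus.n_cpgs), np.nan)
    for i, pattern in enumerate(clones.patterns):
        for j, call in enumerate(pattern.calls):
            if call == Call.METH:
                mat[i, j] = 1.0
            elif call == Call.UNMETH:
                mat[i, j] = 0.0
    return mat


def locus_level(clones: CloneSet) -> tuple[float, np.ndarray]:
    """Pooled locus methylation level and per-CpG levels.

    The locus level is (# methylated calls) / (# methylated + unmethylated
    calls) pooled over all clones; MISSING calls enter neither numerator nor
    denominator. Per-CpG levels are the same statistic per column (nan where
    a CpG has no informative call).
    """
    mat = _call_matrix(clones)
    if mat.size == 0 or np.all(np.isnan(mat)):
        raise ValueError("no informative methylation calls in clone set")
    with np.errstate(invalid="ignore"):
        per_cpg = np.nanmean(mat, axis=0)
    level = float(np.nanmean(mat))
    return level, per_cpg


def lollipop_matrix(clones: CloneSet) -> str:
    """Render the clone set as a text lollipop matrix (one row per clone)."""
    if not clones.patterns:
        raise ValueError("empty clone set")
    lines = [f"# locus={clones.locus.id} n_cpgs={clones.locus.n_cpgs}"]
    for p in clones.patterns:
        row = "".join(GLYPHS[c.value] for c in p.calls)
        lines.append(f"{p.clone_id}\t{row}")
    return "\n".join(lines) + "\n"


def parse_lollipop_matrix(text: str, locus: Locus) -> CloneSet:
    """Read a text lollipop matrix back into a CloneSet (calls only)."""
    patterns = []
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        clone_id, row = line.split("\t")
        calls = tuple(Call(GLYPH_TO_CALL[g]) for g in row)
        patterns.append(CloneMethylationPattern(clone_id, calls, np.nan, np.nan))
    return CloneSet(locus, patterns)


def clone_report(clones_raw: CloneSet, clones_pass: CloneSet) -> dict:
    """Summary statistics for one locus after QC, as a flat record."""
    level, per_cpg = locus_level(clones_pass)
    return {
        "locus": clones_pass.locus.id,
        "region": clones_pass.locus.region,
        "n_clones_pass": len(clones_pass),
        "n_clones_fail": len(clones_raw) - len(clones_pass),
        "locus_level": level,
        "per_cpg_levels": ",".join(f"{x:.4f}" for x in per_cpg),
    }
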