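"""Shared readers and writers.

Centralizes coordinate conventions so no analysis module sees mixed ones:
BED and all internal coordinates are 0-based half-open; Bismark-style
coverage files are 1-based and converted on read/write. All readers reject
malformed input loudly with line numbers.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .peaks import GenomicInterval

__version__ = "0.1.0"

METH_COLUMNS = ["chrom", "pos", "level", "count_meth", "count_unmeth"]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` mapping."""
    records = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(path, records: Mapping[str, str]) -> None:
    SeqIO.write(
        [SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()],
        str(path),
        "fasta",
    )


# ---------------------------------------------------------------------------
# BED / bedGraph
# ---------------------------------------------------------------------------


def read_bed(path) -> list[GenomicInterval]:
    """Read a BED file as 0-based half-open intervals.

    ``track``/``browser``/comment lines are skipped; malformed rows raise
    with their line number.
    """
    intervals = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            chrom, start_s, end_s = fields[:3]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 0 or start >= end:
                raise ValueError(
                    f"{path}:{lineno}: invalid interval {chrom}:{start}-{end}"
                )
            name = fields[3] if len(fields) > 3 else ""
            strand = fields[5] if len(fields) > 5 else "."
            intervals.append(GenomicInterval(chrom, start, end, name=name, strand=strand))
    return intervals


def write_bed(path, intervals: Sequence[GenomicInterval]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            name = iv.name or "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def read_bedgraph(path) -> pd.DataFrame:
    """Read a bedGraph into a (chrom, start, end, value) frame."""
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 bedGraph columns")
            try:
                rows.append(
                    (fields[0], int(fields[1]), int(fields[2]), float(fields[3]))
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed bedGraph row") from exc
            if rows[-1][1] < 0 or rows[-1][1] >= rows[-1][2]:
                raise ValueError(f"{path}:{lineno}: invalid interval")
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def write_bedgraph(path, track: pd.DataFrame) -> None:
    track.to_csv(path, sep="\t", header=False, index=False,
                 columns=["chrom", "start", "end", "value"])


# ---------------------------------------------------------------------------
# Bismark-coverage methylation tables
# ---------------------------------------------------------------------------


def read_bismark_cov(path, warn_tolerance_pp: float = 0.5) -> pd.DataFrame:
    """Read a Bismark-coverage-dialect TSV into the internal CpG table.

    Input columns: chrom, start (1-based), end, methylation %, count
    methylated, count unmethylated. Positions are converted to 0-based and the
    level is recomputed from the counts — the percentage column is advisory;
    a disagreement above ``warn_tolerance_pp`` percentage points warns.
    """
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise ValueError(f"{path}:{lineno}: expected 6 coverage columns")
            chrom, start_s, _end_s, pct_s, m_s, u_s = fields
            try:
                start1, pct = int(start_s), float(pct_s)
                count_m, count_u = int(m_s), int(u_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed coverage row") from exc
            if count_m < 0 or count_u < 0:
                raise ValueError(f"{path}:{lineno}: negative counts")
            cov = count_m + count_u
            level = count_m / cov if cov > 0 else float("nan")
            if cov > 0 and abs(level * 100 - pct) > warn_tolerance_pp:
                warnings.warn(
                    f"{path}:{lineno}: stated level {pct}% disagrees with counts "
                    f"({level * 100:.2f}%) by more than {warn_tolerance_pp} points"
                )
            rows.append((chrom, start1 - 1, level, count_m, count_u))
    return pd.DataFrame(rows, columns=METH_COLUMNS)


def write_bismark_cov(path, meth: pd.DataFrame) -> None:
    """Write the internal CpG table in Bismark-coverage dialect (1-based)."""
    with open(path, "w") as fh:
        for row in meth.itertuples(index=False):
            cov = row.count_meth + row.count_unmeth
            pct = 100.0 * row.count_meth / cov if cov > 0 else 0.0
            pos1 = int(row.pos) + 1
            fh.write(
                f"{row.chrom}\t{pos1}\t{pos1}\t{pct:.6g}\t"
                f"{int(row.count_meth)}\t{int(row.count_unmeth)}\n"
            )


# ---------------------------------------------------------------------------
# PWM and TSS tables
# ---------------------------------------------------------------------------


def read_pwm(path) -> np.ndarray:
    """Read a tab-separated position × {A,C,G,T} probability matrix."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [b for b in "ACGT" if b not in df.columns]
    if missing:
        raise ValueError(f"PWM file {path} lacks column(s) {missing}")
    pwm = df[list("ACGT")].to_numpy(dtype=float)
    if not np.allclose(pwm.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError(f"PWM rows in {path} must each sum to 1")
    return pwm


def write_pwm(path, pwm: np.ndarray) -> None:
    pd.DataFrame(pwm, columns=list("ACGT")).to_csv(path, sep="\t", index=False)


def read_tss_table(path) -> pd.DataFrame:
    """Read a TSS TSV with columns chrom, pos, strand, gene_id."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"chrom", "pos", "gene_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"TSS table {path} lacks column(s) {sorted(missing)}")
    if (df["pos"] < 0).any():
        raise ValueError(f"TSS table {path} has negative positions")
    return df


def write_tss_table(path, tss: pd.DataFrame) -> None:
    cols = [c for c in ("chrom", "pos", "strand", "gene_id") if c in tss.columns]
    tss.to_csv(path, sep="\t", index=False, columns=cols)


# ---------------------------------------------------------------------------
# Report writing with provenance
# ---------------------------------------------------------------------------


def config_hash(config: Mapping) -> str:
    payload = json.dumps(dict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def write_report(
    path,
    frame: pd.DataFrame,
    config: Mapping | None = None,
    seed: int | None = None,
    force: bool = False,
    sort_by: Sequence[str] | None = None,
) -> None:
    """Write a TSV report with a provenance header, deterministically ordered.

    Refuses to overwrite an existing file unless ``force`` is set.
    """
    path = Path(path)
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists; pass force=True to overwrite")
    out = frame.copy()
    if sort_by:
        out = out.sort_values(list(sort_by), kind="stable")
    header = [
        f"# memoryscan v{__version__}",
        f"# config_hash={config_hash(config or {})}",
        f"# seed={seed if seed is not None else 'NA'}",
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        out.to_csv(fh, sep="\t", index=False)


def read_report(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
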