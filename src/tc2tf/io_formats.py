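"""Readers and writers for the pipeline's on-disk formats.

Three external representations are handled here: tab-separated tables
(expression matrix, design table, probe->gene map, result tables), FASTA
promoter sequences, and TRANSFAC-dialect position count matrices. Readers
reject malformed input rather than silently repairing it, and every
writer/reader pair is an exact inverse on valid data.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GENOTYPES = ("wt", "ko")
BASES = "ACGT"
_VALID_SEQ = re.compile(r"^[ACGTN]*$")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def _is_number(x) -> bool:
    try:
        float(x)
        return True
    except (TypeError, ValueError):
        return False


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def _comment_header(params: Mapping[str, object] | None) -> str:
    from tc2tf import __version__

    lines = [f"# tc2tf {__version__}"]
    if params:
        kv = " ".join(f"{k}={v}" for k, v in params.items())
        lines.append(f"# params: {kv}")
    return "\n".join(lines) + "\n"


def write_table_tsv(df: pd.DataFrame, path: str | Path,
                    params: Mapping[str, object] | None = None,
                    index: bool = False) -> None:
    """Write a result table as TSV with a commented provenance header."""
    with open(path, "w") as fh:
        fh.write(_comment_header(params))
        df.to_csv(fh, sep="\t", index=index)


def read_expression_tsv(path: str | Path, linear_scale: bool = False) -> pd.DataFrame:
    """Read a probe x sample expression matrix.

    First column holds probe ids, the header row sample ids, the body is
    numeric. With ``linear_scale=True`` intensities are log2-transformed on
    load so the in-memory scale is always log2.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
    if df.shape[0] == 0:
        raise FormatError(f"{path}: no probes")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate probe_id {dup!r}")
    if df.columns.duplicated().any():
        raise FormatError(f"{path}: duplicate sample ids in header")
    out = pd.DataFrame(index=df.index.astype(str), columns=df.columns.astype(str),
                       dtype=float)
    for col in df.columns:
        try:
            # float() is a correctly-rounded parse, so written matrices
            # round-trip bit-exactly
            out[col] = np.array([float(x) for x in df[col]])
        except (TypeError, ValueError):
            bad = next(r for r, x in zip(df.index, df[col])
                       if not _is_number(x))
            raise FormatError(
                f"{path}: non-numeric value at probe {bad!r}, sample {col!r}")
        if not np.isfinite(out[col].to_numpy()).all():
            bad = df.index[~np.isfinite(out[col].to_numpy())][0]
            raise FormatError(
                f"{path}: non-finite value at probe {bad!r}, sample {col!r}")
    out.index.name = "probe_id"
    if linear_scale:
        if (out.to_numpy() <= 0).any():
            raise FormatError(f"{path}: non-positive intensity on linear scale")
        out = np.log2(out)
    return out


def write_expression_tsv(matrix: pd.DataFrame, path: str | Path,
                         params: Mapping[str, object] | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_comment_header(params))
        matrix.to_csv(fh, sep="\t", index_label="probe_id")


def read_design_tsv(path: str | Path, time_grid: Iterable[float] | None = None
                    ) -> pd.DataFrame:
    """Read the sample design table (sample_id, genotype, time_h, replicate).

    Validates uniqueness of sample ids, genotype levels, and that every
    (genotype, replicate) group carries exactly one t=0 control.
    """
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"sample_id": str, "genotype": str})
    required = {"sample_id", "genotype", "time_h", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing design columns {sorted(missing)}")
    return validate_design(df, time_grid=time_grid, source=str(path))


def validate_design(df: pd.DataFrame, time_grid: Iterable[float] | None = None,
                    source: str = "design") -> pd.DataFrame:
    df = df.copy()
    if df["sample_id"].duplicated().any():
        raise FormatError(f"{source}: duplicate sample_id")
    bad = set(df["genotype"]) - set(GENOTYPES)
    if bad:
        raise FormatError(f"{source}: unknown genotype values {sorted(bad)}")
    df["time_h"] = pd.to_numeric(df["time_h"])
    if (df["time_h"] < 0).any():
        raise FormatError(f"{source}: negative time_h")
    if time_grid is not None:
        off = set(df["time_h"]) - set(float(t) for t in time_grid)
        if off:
            raise FormatError(f"{source}: time points {sorted(off)} not on grid")
    df["replicate"] = pd.to_numeric(df["replicate"], downcast="integer")
    if (df["replicate"] < 1).any():
        raise FormatError(f"{source}: replicate must be a positive integer")
    for (gt, rep), grp in df.groupby(["genotype", "replicate"]):
        n0 = int((grp["time_h"] == 0).sum())
        if n0 != 1:
            raise FormatError(
                f"{source}: group (genotype={gt}, replicate={rep}) has {n0} "
                f"t=0 control samples, expected exactly 1")
    return df.reset_index(drop=True)


def write_design_tsv(df: pd.DataFrame, path: str | Path,
                     params: Mapping[str, object] | None = None) -> None:
    write_table_tsv(df, path, params=params, index=False)


def read_probe_map_tsv(path: str | Path) -> pd.DataFrame:
    """Read the probe->gene map (probe_id, gene_id, ambiguous)."""
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"probe_id": str, "gene_id": str})
    required = {"probe_id", "gene_id", "ambiguous"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing probe map columns {sorted(missing)}")
    if df["probe_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate probe_id")
    df["gene_id"] = df["gene_id"].fillna("")
    df["ambiguous"] = df["ambiguous"].astype(bool)
    return df.reset_index(drop=True)


def write_probe_map_tsv(df: pd.DataFrame, path: str | Path,
                        params: Mapping[str, object] | None = None) -> None:
    write_table_tsv(df, path, params=params, index=False)


# ---------------------------------------------------------------------------
# TRANSFAC position count matrices
# ---------------------------------------------------------------------------

@dataclass
class PwmRecord:
    """A position count matrix over A,C,G,T.

    ``counts`` is a 4 x L array, rows in A,C,G,T order, one column per motif
    position. Fractional counts are permitted (frequency-normalized matrices
    occur in the wild). Every position must have a strictly positive count
    sum.
    """

    motif_id: str
    name: str = ""
    counts: np.ndarray = field(default_factory=lambda: np.zeros((4, 0)))

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise FormatError(f"{self.motif_id}: counts must be 4 x L")
        if self.counts.shape[1] < 1:
            raise FormatError(f"{self.motif_id}: motif length must be >= 1")
        if (self.counts < 0).any():
            raise FormatError(f"{self.motif_id}: negative count")
        sums = self.counts.sum(axis=0)
        if (sums <= 0).any():
            pos = int(np.argmax(sums <= 0))
            raise FormatError(
                f"{self.motif_id}: zero count sum at position {pos + 1}")

    @property
    def length(self) -> int:
        return self.counts.shape[1]


def _parse_count_row(tokens: list[str], lineno: int) -> list[float]:
    # TRANSFAC rows may append a consensus letter after the four counts.
    body = tokens[1:]
    if body and re.fullmatch(r"[A-Za-z]", body[-1]):
        body = body[:-1]
    if len(body) != 4:
        raise FormatError(
            f"line {lineno}: expected 4 numeric count fields, got {len(body)}")
    try:
        return [float(x) for x in body]
    except ValueError as exc:
        raise FormatError(f"line {lineno}: non-numeric count field") from exc


def read_transfac(path: str | Path) -> list[PwmRecord]:
    """Parse a TRANSFAC-dialect matrix file into PwmRecords.

    Accepts optional AC/ID/NA annotation lines, a ``P0  A  C  G  T`` header,
    numbered count rows (tab- or space-delimited), ``XX`` separators, and
    ``//`` record terminators.
    """
    records: list[PwmRecord] = []
    ac = ""
    ident = ""
    name = ""
    rows: list[list[float]] = []
    saw_p0 = False
    saw_block = False

    def flush(lineno: int) -> None:
        nonlocal ac, ident, name, rows, saw_p0, saw_block
        if not saw_block:
            return
        if not saw_p0:
            raise FormatError(f"line {lineno}: matrix block lacks a P0 header")
        if not rows:
            raise FormatError(f"line {lineno}: matrix block has no count rows")
        motif_id = ident or ac or f"matrix_{len(records) + 1}"
        counts = np.asarray(rows, dtype=float).T  # rows A,C,G,T x positions
        records.append(PwmRecord(motif_id=motif_id, name=name, counts=counts))
        ac = ident = name = ""
        rows = []
        saw_p0 = False
        saw_block = False

    with open(path) as fh:
        lineno = 0
        for raw in fh:
            lineno += 1
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("XX"):
                continue
            tokens = line.split()
            tag = tokens[0]
            if tag == "//":
                flush(lineno)
                continue
            saw_block = True
            if tag == "AC":
                ac = tokens[1] if len(tokens) > 1 else ""
            elif tag == "ID":
                ident = tokens[1] if len(tokens) > 1 else ""
            elif tag == "NA":
                name = " ".join(tokens[1:])
            elif tag == "P0" or tag == "PO":
                saw_p0 = True
            elif re.fullmatch(r"\d+", tag):
                if not saw_p0:
                    raise FormatError(
                        f"line {lineno}: count row before P0 header")
                rows.append(_parse_count_row(tokens, lineno))
            # other annotation tags (DE, BF, ...) are ignored
        flush(lineno)
    return records


def write_transfac(records: Iterable[PwmRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"ID {rec.motif_id}\n")
            if rec.name:
                fh.write(f"NA {rec.name}\n")
            fh.write("P0      A      C      G      T\n")
            for j in range(rec.length):
                a, c, g, t = rec.counts[:, j]
                fh.write(f"{j + 1:02d} {a:6g} {c:6g} {g:6g} {t:6g}\n")
            fh.write("XX\n//\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read promoters as an id -> uppercase DNA mapping.

    The id is the header token up to the first whitespace. Only A,C,G,T,N are
    accepted (after uppercasing); the first illegal character is reported with
    its 1-based position.
    """
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if rec.id in out:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        if not _VALID_SEQ.fullmatch(seq):
            pos = next(i for i, ch in enumerate(seq) if ch not in "ACGTN")
            raise FormatError(
                f"{path}: illegal character {seq[pos]!r} in {rec.id!r} "
                f"at position {pos + 1}")
        out[rec.id] = seq
    return out


def extract_promoters(genome: Mapping[str, str], gene_table: pd.DataFrame,
                      flank: int = 2000) -> dict[str, str]:
    """Cut TSS-centered promoter windows from genome sequences.

    ``gene_table`` needs columns gene_id, chrom, tss (0-based), strand. The
    window is [tss - flank, tss + flank) in chromosome coordinates, reported
    on the gene strand (reverse-complemented for minus-strand genes) and
    padded with N where it overhangs a chromosome end. Supplied promoter
    FASTA is the pipeline's canonical input; this is a convenience for users
    starting from a genome.
    """
    required = {"gene_id", "chrom", "tss", "strand"}
    missing = required - set(gene_table.columns)
    if missing:
        raise FormatError(f"gene table missing columns {sorted(missing)}")
    out: dict[str, str] = {}
    for row in gene_table.itertuples(index=False):
        if row.chrom not in genome:
            raise FormatError(f"unknown chromosome {row.chrom!r} "
                              f"for gene {row.gene_id!r}")
        if row.strand not in "+-":
            raise FormatError(f"bad strand {row.strand!r} "
                              f"for gene {row.gene_id!r}")
        chrom = genome[row.chrom]
        tss = int(row.tss)
        lo, hi = tss - flank, tss + flank
        seq = ("N" * max(0, -lo)
               + chrom[max(0, lo):min(len(chrom), hi)].upper()
               + "N" * max(0, hi - len(chrom)))
        if row.strand == "-":
            seq = seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]
        if row.gene_id in out:
            raise FormatError(f"duplicate gene_id {row.gene_id!r}")
        out[row.gene_id] = seq
    return out


def write_fasta(sequences: Mapping[str, str], path: str | Path,
                width: int = 70) -> None:
    records = [SeqRecord(Seq(seq), id=gid, description="")
               for gid, seq in sequences.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)
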