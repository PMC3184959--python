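"""Readers and writers for the plain-text formats the pipeline touches.

FASTA goes through Biopython; tables are TSV via pandas. All genomic and
residue coordinates in these files are 1-based inclusive.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import (
    CoordinateError,
    ExpressionMatrix,
    FormatError,
    GeneLocus,
    ProteinRecord,
    SegmentBlockPair,
    STANDARD_AA,
)

logger = logging.getLogger("phytocyanin")

PathLike = Union[str, Path]


def to_zero_based(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return start - 1, end


def to_one_based(start: int, end: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    return start + 1, end


def read_fasta(path: PathLike, nonstandard: str = "reject") -> list[ProteinRecord]:
    """Read protein FASTA into :class:`ProteinRecord` objects.

    Sequences are uppercased. Letters outside the 20 standard residues + X
    are rejected (``nonstandard="reject"``, default) or mapped to X
    (``nonstandard="mask"``).
    """
    if nonstandard not in ("reject", "mask"):
        raise ValueError("nonstandard must be 'reject' or 'mask'")
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if nonstandard == "mask":
            seq = "".join(c if c in STANDARD_AA else "X" for c in seq)
        records.append(ProteinRecord(id=rec.id, seq=seq))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: PathLike) -> None:
    seqs = [SeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    SeqIO.write(seqs, str(path), "fasta")


def read_alignment(path: PathLike) -> tuple[list[str], list[str]]:
    """Read an aligned FASTA; returns (ids, rows). Rows must share a length;
    gaps are '-'."""
    ids, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        rows.append(str(rec.seq).upper())
    if len(rows) < 2:
        raise FormatError("alignment needs >= 2 sequences")
    if len({len(r) for r in rows}) != 1:
        raise FormatError("alignment rows differ in length")
    return ids, rows


def assign_ordinals(loci: list[GeneLocus]) -> list[GeneLocus]:
    """Assign per-chromosome 1-based ordinals by ascending start (ties by
    end, then gene_id). Input order is preserved in the returned list."""
    by_chrom: dict[str, list[GeneLocus]] = {}
    for loc in loci:
        by_chrom.setdefault(loc.chrom, []).append(loc)
    rank: dict[str, int] = {}
    for chrom_loci in by_chrom.values():
        ordered = sorted(chrom_loci, key=lambda g: (g.start, g.end, g.gene_id))
        for i, g in enumerate(ordered, start=1):
            rank[g.gene_id] = i
    return [
        GeneLocus(g.gene_id, g.chrom, g.start, g.end, g.strand, rank[g.gene_id])
        for g in loci
    ]


def read_gene_table(path: PathLike) -> list[GeneLocus]:
    """Read a TSV with columns gene_id, chrom, start, end, strand and assign
    per-chromosome ordinals."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    need = {"gene_id", "chrom", "start", "end", "strand"}
    if not need <= set(df.columns):
        raise FormatError(f"gene table needs columns {sorted(need)}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise FormatError(f"duplicate gene id {dup!r}")
    loci = [
        GeneLocus(r.gene_id, r.chrom, int(r.start), int(r.end), str(r.strand))
        for r in df.itertuples()
    ]
    return assign_ordinals(loci)


def write_gene_table(loci: Iterable[GeneLocus], path: PathLike) -> None:
    pd.DataFrame(
        [
            {
                "gene_id": g.gene_id,
                "chrom": g.chrom,
                "start": g.start,
                "end": g.end,
                "strand": g.strand,
                "ordinal": g.ordinal,
            }
            for g in loci
        ]
    ).to_csv(path, sep="\t", index=False)


def _parse_interval(text: str) -> tuple[int, int]:
    try:
        start_s, end_s = text.split("-")
        start, end = int(start_s), int(end_s)
    except ValueError as exc:
        raise FormatError(f"malformed interval {text!r}") from exc
    if start > end:
        raise CoordinateError(f"interval {text!r}: start > end")
    return start, end


def _parse_bool(text) -> Optional[bool]:
    s = str(text).strip().upper()
    if s in ("TRUE", "T", "1", "YES"):
        return True
    if s in ("FALSE", "F", "0", "NO"):
        return False
    if s in ("", "NA", "NAN", "NONE"):
        return None
    raise FormatError(f"bad boolean {text!r}")


def read_annotation_table(path: PathLike, records: list[ProteinRecord]) -> list[ProteinRecord]:
    """Attach external predictor flags (sp, gas, pcld intervals, nglyc sites)
    to protein records, keyed by id. Proteins absent from the table keep their
    flags unset; table rows naming unknown proteins are skipped with a
    warning."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "id" not in df.columns:
        raise FormatError("annotation table needs an 'id' column")
    by_id = {r.id: r for r in records}
    for row in df.itertuples():
        rec = by_id.get(row.id)
        if rec is None:
            logger.warning("annotation row for unknown protein %r skipped", row.id)
            continue
        if "sp" in df.columns and row.sp != "":
            rec.sp_flag = _parse_bool(row.sp)
        if "gas" in df.columns and row.gas != "":
            rec.gas_flag = _parse_bool(row.gas)
        if "pcld" in df.columns and row.pcld != "":
            rec.pcld_intervals = [
                _parse_interval(part) for part in str(row.pcld).split(";")
            ]
        if "nglyc" in df.columns and row.nglyc != "":
            rec.nglyc_sites = [int(p) for p in str(row.nglyc).split(";")]
        ProteinRecord(rec.id, rec.seq, rec.sp_flag, rec.gas_flag,
                      rec.pcld_intervals, rec.nglyc_sites)  # re-validate
    return records


def read_expression_matrix(values_path: PathLike, meta_path: PathLike) -> ExpressionMatrix:
    """Read a TSV signal matrix (first column gene id, header = sample ids)
    plus a sample-metadata sheet (sample_id, tissue, condition, replicate)."""
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0, dtype=str)
    need = {"tissue", "condition", "replicate"}
    if not need <= set(meta.columns):
        raise FormatError(f"sample metadata needs columns {sorted(need)}")
    return ExpressionMatrix(values=values, sample_meta=meta)


def write_expression_matrix(matrix: ExpressionMatrix, values_path: PathLike,
                            meta_path: PathLike) -> None:
    matrix.values.to_csv(values_path, sep="\t")
    matrix.sample_meta.to_csv(meta_path, sep="\t")


def read_block_table(path: PathLike) -> list[SegmentBlockPair]:
    """Read duplicated-segment block pairs (pair_id, chromA, startA, endA,
    chromB, startB, endB)."""
    df = pd.read_csv(path, sep="\t", dtype={"pair_id": str, "chromA": str, "chromB": str})
    need = {"pair_id", "chromA", "startA", "endA", "chromB", "startB", "endB"}
    if not need <= set(df.columns):
        raise FormatError(f"block table needs columns {sorted(need)}")
    return [
        SegmentBlockPair(r.pair_id, r.chromA, int(r.startA), int(r.endA),
                         r.chromB, int(r.startB), int(r.endB))
        for r in df.itertuples()
    ]


def write_newick(newick: str, path: PathLike) -> None:
    Path(path).write_text(newick if newick.endswith("\n") else newick + "\n")
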