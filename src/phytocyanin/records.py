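"""Core domain types shared across the package.

Coordinates are 1-based inclusive everywhere (the convention of biology
annotation tables); :mod:`phytocyanin.io` provides converters to and from
0-based half-open at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")
#: sentinel for a ligand column that aligns to a gap
ABSENT = "-"

SUBFAMILIES = ("UCL", "SCL", "ENODL")
ARCH_TYPES = ("I", "II", "III", "IV", "V", "VI")


class FormatError(ValueError):
    """Malformed input file or record."""


class CoordinateError(ValueError):
    """Invalid genomic or residue coordinates."""


@dataclass
class ProteinRecord:
    """A protein with optional externally supplied feature annotations.

    ``sp_flag``/``gas_flag`` carry signal-peptide and GPI-anchor-signal
    predictions made by external tools; ``pcld_intervals`` are 1-based
    inclusive residue intervals of plastocyanin-like domains. Unset flags
    (``None``) mean "not annotated" and downstream code falls back to the
    built-in heuristics.
    """

    id: str
    seq: str
    sp_flag: Optional[bool] = None
    gas_flag: Optional[bool] = None
    pcld_intervals: Optional[list[tuple[int, int]]] = None
    nglyc_sites: Optional[list[int]] = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise FormatError(f"protein {self.id!r}: empty sequence")
        bad = set(self.seq) - STANDARD_AA - {"X"}
        if bad:
            raise FormatError(
                f"protein {self.id!r}: non-standard residues {sorted(bad)}"
            )
        if self.pcld_intervals:
            prev_end = 0
            for start, end in sorted(self.pcld_intervals):
                if not (1 <= start <= end <= len(self.seq)):
                    raise CoordinateError(
                        f"protein {self.id!r}: PCLD interval ({start},{end}) "
                        f"outside [1,{len(self.seq)}]"
                    )
                if start <= prev_end:
                    raise CoordinateError(
                        f"protein {self.id!r}: overlapping PCLD intervals"
                    )
                prev_end = end

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class GeneLocus:
    """A gene position on a chromosome; ``ordinal`` is the 1-based rank of
    the gene among all genes on its chromosome sorted by start."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    ordinal: int = 0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise CoordinateError(
                f"gene {self.gene_id!r}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.gene_id!r}: bad strand {self.strand!r}")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of nonnegative signals with sample metadata.

    ``sample_meta`` is indexed by sample id with columns ``tissue``,
    ``condition`` and ``replicate``.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("expression values must be finite")
        if (vals < 0).any():
            raise ValueError("expression values must be nonnegative")
        missing = set(self.values.columns) - set(self.sample_meta.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class LigandTuple:
    """The four copper-binding positions of a plastocyanin-like domain,
    as the residues found at the conserved His/Cys/His/Met(Gln) columns;
    a column aligned to a gap is ``ABSENT``."""

    l1: str
    l2: str
    l3: str
    l4: str

    def __post_init__(self) -> None:
        for letter in (self.l1, self.l2, self.l3, self.l4):
            if letter != ABSENT and letter not in STANDARD_AA and letter != "X":
                raise ValueError(f"bad ligand letter {letter!r}")

    def __iter__(self):
        return iter((self.l1, self.l2, self.l3, self.l4))


@dataclass
class FamilyAssignment:
    """Subfamily + architecture call for one protein."""

    protein_id: str
    subfamily: str
    arch_type: str  # I..VI or UNCLASSIFIED
    chimeric_agp: bool
    ligands: Optional[LigandTuple] = None
    disulfide_ok: Optional[bool] = None
    has_sp: Optional[bool] = None
    has_gas: Optional[bool] = None
    has_alr: Optional[bool] = None
    n_pcld: Optional[int] = None

    def __post_init__(self) -> None:
        if self.subfamily not in SUBFAMILIES:
            raise ValueError(f"bad subfamily {self.subfamily!r}")
        if self.arch_type not in ARCH_TYPES + ("UNCLASSIFIED",):
            raise ValueError(f"bad architecture type {self.arch_type!r}")
        if self.chimeric_agp != (self.arch_type in ("I", "II")):
            raise ValueError("chimeric_agp must hold exactly for types I and II")


@dataclass(frozen=True)
class SegmentBlockPair:
    """A pair of collinear (segmentally duplicated) chromosome blocks."""

    pair_id: str
    chrom_a: str
    start_a: int
    end_a: int
    chrom_b: str
    start_b: int
    end_b: int

    def __post_init__(self) -> None:
        if self.start_a > self.end_a or self.start_b > self.end_b:
            raise CoordinateError(f"block pair {self.pair_id!r}: start > end")


@dataclass(frozen=True)
class TandemGroup:
    """Tandemly duplicated family genes on one chromosome, ordered by
    ordinal; any two consecutive members are separated by at most five
    intervening genes."""

    chrom: str
    gene_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.gene_ids) < 2:
            raise ValueError("tandem group needs >= 2 members")


@dataclass(frozen=True)
class StressCall:
    """Differential-expression call of one gene under one stress."""

    gene_id: str
    condition: str
    fold_change: float
    p_value: float
    call: str  # UP | DOWN | NONE

    def __post_init__(self) -> None:
        if self.call not in ("UP", "DOWN", "NONE"):
            raise ValueError(f"bad call {self.call!r}")


@dataclass
class QpcrPlate:
    """Ct measurements plus the per-gene standard-curve dilution series.

    ``ct`` has columns gene, sample, bio_rep, tech_rep, ct (NaN = undetected);
    ``dilution`` has columns gene, amount, ct.
    """

    ct: pd.DataFrame
    dilution: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"gene", "sample", "bio_rep", "tech_rep", "ct"}
        if not need <= set(self.ct.columns):
            raise FormatError(f"qPCR table needs columns {sorted(need)}")
        if ((self.ct["ct"].dropna()) <= 0).any():
            raise ValueError("Ct values must be positive or NaN (undetected)")
        need_d = {"gene", "amount", "ct"}
        if not need_d <= set(self.dilution.columns):
            raise FormatError(f"dilution table needs columns {sorted(need_d)}")
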