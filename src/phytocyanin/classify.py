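"""Copper-ligand subfamily calling and six-type architecture classification.

Phytocyanins share a plastocyanin-like domain (PCLD) that binds a single
copper atom through four conserved residues: His, Cys, His and an axial
Met or Gln. Proteins with the complete ligand set are uclacyanin-like
(UCL, axial Met) or stellacyanin-like (SCL, axial Gln); proteins whose
PCLD lacks any key ligand are early-nodulin-like (ENODL). Independent of
the ligand set, domain architecture falls into six types built from four
elements — N-terminal signal peptide (SP), PCLD count, AGP-like region
(ALR) and C-terminal GPI-anchor signal (GAS):

    I   SP + PCLD + ALR + GAS      IV  SP + PCLD
    II  SP + PCLD + ALR            V   PCLD only
    III SP + PCLD + GAS            VI  SP + 2 PCLDs

Types I and II are chimeric AGPs: a secreted protein carrying AG
glycomodules is a substrate for arabinogalactosylation.

Ligand sites are read off a global pairwise alignment of the query PCLD to
a bundled annotated reference domain (BLOSUM62, affine gaps); a ligand
column aligned to a gap is reported ABSENT.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .features import call_alr, heuristic_gas, heuristic_sp
from .records import ABSENT, FamilyAssignment, LigandTuple, ProteinRecord

logger = logging.getLogger("phytocyanin")

#: residues excluded at each terminus when SP / GAS is present: the signal
#: peptide occupies roughly the first 25 residues, the GPI omega-region
#: roughly the last 25
SP_REGION_LEN = 25
GAS_REGION_LEN = 25


class LowConfidenceAlignment(ValueError):
    """Query aligns to the reference PCLD below the score floor."""


class NoPcldError(ValueError):
    """No plastocyanin-like domain could be located in a protein."""


@dataclass(frozen=True)
class ReferencePcld:
    """An annotated reference PCLD: the canonical sequence plus the 1-based
    columns of the four copper ligands (H, C, H, M) and of the two
    disulfide-forming cysteines."""

    seq: str
    ligand_columns: tuple[int, int, int, int]
    disulfide_columns: tuple[int, int]

    def __post_init__(self) -> None:
        for col in self.ligand_columns + self.disulfide_columns:
            if not 1 <= col <= len(self.seq):
                raise ValueError(f"annotated column {col} outside reference")
        letters = tuple(self.seq[c - 1] for c in self.ligand_columns)
        if letters != ("H", "C", "H", "M"):
            raise ValueError(f"reference ligand residues must be H,C,H,M, got {letters}")
        for col in self.disulfide_columns:
            if self.seq[col - 1] != "C":
                raise ValueError("disulfide columns must hold Cys")


# Canonical uclacyanin-type PCLD assembled for this package (synthetic,
# Pro-free so the domain can never contribute glycomodules): H24/C38/H52
# coordinate the copper with the axial M57; C13/C46 form the disulfide.
REFERENCE_PCLD = ReferencePcld(
    seq=(
        "ATYKVGDESG"  #  1-10
        "WTCNGKTFRV"  # 11-20  C13 = disulfide 1
        "GDEHFNYESG"  # 21-30  H24 = ligand 1
        "AKDVAEVCKS"  # 31-40  C38 = ligand 2
        "GYDSTCTDNA"  # 41-50  C46 = disulfide 2
        "THDSGKMATV"  # 51-60  H52 = ligand 3, M57 = ligand 4
    ),
    ligand_columns=(24, 38, 52, 57),
    disulfide_columns=(13, 46),
)


def _make_aligner(mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def _self_score(ref: ReferencePcld) -> float:
    aligner = _make_aligner("global")
    return aligner.score(ref.seq, ref.seq)


def extract_ligand_sites(
    query_pcld: str,
    ref: ReferencePcld = REFERENCE_PCLD,
    min_score_fraction: float = 0.3,
) -> tuple[LigandTuple, bool]:
    """Map the reference's ligand columns onto a query PCLD through a global
    pairwise alignment; returns the ligand tuple and whether both disulfide
    columns map to Cys. Ties between equal-scoring alignments are broken by
    the leftmost (first enumerated) alignment.

    Raises :class:`LowConfidenceAlignment` when the alignment score falls
    below ``min_score_fraction`` of the reference self-score.
    """
    if len(query_pcld) < 30:
        raise ValueError("query PCLD shorter than 30 residues")
    aligner = _make_aligner("global")
    alignments = aligner.align(ref.seq, query_pcld)
    aln = alignments[0]
    if aln.score < min_score_fraction * _self_score(ref):
        raise LowConfidenceAlignment(
            f"alignment score {aln.score:.1f} below floor"
        )
    ref_blocks, query_blocks = aln.aligned

    def mapped(col: int) -> str:
        c = col - 1
        for (ts, te), (qs, _qe) in zip(ref_blocks, query_blocks):
            if ts <= c < te:
                return query_pcld[qs + (c - ts)]
        return ABSENT

    letters = [mapped(c) for c in ref.ligand_columns]
    disulfide_ok = all(mapped(c) == "C" for c in ref.disulfide_columns)
    return LigandTuple(*letters), disulfide_ok


def classify_subfamily(lig: LigandTuple) -> str:
    """(H,C,H,M) -> UCL; (H,C,H,Q) -> SCL; anything lacking a key residue ->
    ENODL."""
    letters = tuple(lig)
    if letters == ("H", "C", "H", "M"):
        return "UCL"
    if letters == ("H", "C", "H", "Q"):
        return "SCL"
    return "ENODL"


def classify_architecture(has_sp: bool, n_pcld: int, has_alr: bool,
                          has_gas: bool) -> str:
    """Map the four architecture elements to one of the six types;
    combinations outside the six are UNCLASSIFIED."""
    if n_pcld < 1:
        raise NoPcldError("architecture typing requires >= 1 PCLD")
    table = {
        (True, 1, True, True): "I",
        (True, 1, True, False): "II",
        (True, 1, False, True): "III",
        (True, 1, False, False): "IV",
        (False, 1, False, False): "V",
        (True, 2, False, False): "VI",
    }
    return table.get((has_sp, n_pcld, has_alr, has_gas), "UNCLASSIFIED")


def locate_pclds(
    seq: str,
    ref: ReferencePcld = REFERENCE_PCLD,
    min_score_fraction: float = 0.5,
    max_domains: int = 2,
) -> list[tuple[int, int]]:
    """Locate PCLDs by local alignment of the reference against the
    sequence; after each hit the matched segment is masked and the scan
    repeats, keeping hits scoring at least ``min_score_fraction`` of the
    reference self-score. Returns 1-based inclusive intervals, N- to
    C-terminal."""
    floor = min_score_fraction * _self_score(ref)
    aligner = _make_aligner("local")
    working = seq
    hits: list[tuple[int, int]] = []
    for _ in range(max_domains):
        alignments = aligner.align(working, ref.seq)
        if len(alignments) == 0:
            break
        aln = alignments[0]
        if aln.score < floor:
            break
        blocks = aln.aligned[0]
        start, end = int(blocks[0][0]) + 1, int(blocks[-1][1])
        hits.append((start, end))
        working = working[: start - 1] + "X" * (end - start + 1) + working[end:]
    return sorted(hits)


def classify_protein(
    protein: ProteinRecord,
    ref: ReferencePcld = REFERENCE_PCLD,
) -> FamilyAssignment:
    """Full per-protein call: locate PCLD(s) (annotated intervals win over
    the alignment scan), read SP/GAS from annotations or the heuristics,
    call the ALR outside the PCLD/SP/GAS intervals, then assign subfamily
    from the first (N-terminal) PCLD and the architecture type."""
    intervals = protein.pcld_intervals or locate_pclds(protein.seq, ref)
    if not intervals:
        raise NoPcldError(f"no PCLD detected in protein {protein.id!r}")
    has_sp = protein.sp_flag if protein.sp_flag is not None else heuristic_sp(protein.seq)
    has_gas = (
        protein.gas_flag if protein.gas_flag is not None else heuristic_gas(protein.seq)
    )
    n = len(protein.seq)
    excluded = list(intervals)
    if has_sp:
        excluded.append((1, min(SP_REGION_LEN, n)))
    if has_gas:
        excluded.append((max(1, n - GAS_REGION_LEN + 1), n))
    alr = call_alr(protein, excluded)

    first = intervals[0]
    ligands, disulfide_ok = extract_ligand_sites(
        protein.seq[first[0] - 1 : first[1]], ref
    )
    arch = classify_architecture(has_sp, len(intervals), alr.present, has_gas)
    return FamilyAssignment(
        protein_id=protein.id,
        subfamily=classify_subfamily(ligands),
        arch_type=arch,
        chimeric_agp=arch in ("I", "II"),
        ligands=ligands,
        disulfide_ok=disulfide_ok,
        has_sp=has_sp,
        has_gas=has_gas,
        has_alr=alr.present,
        n_pcld=len(intervals),
    )


def classify_family(
    proteins: Sequence[ProteinRecord],
    ref: ReferencePcld = REFERENCE_PCLD,
) -> list[FamilyAssignment]:
    """classify_protein over a family; proteins without a detectable PCLD
    are skipped with a warning (they are not phytocyanins)."""
    out = []
    for rec in proteins:
        try:
            out.append(classify_protein(rec, ref))
        except NoPcldError:
            logger.warning("protein %r has no detectable PCLD; skipped", rec.id)
    return out


def summarize_types(assignments: Sequence[FamilyAssignment]) -> pd.DataFrame:
    """Subfamily x architecture-type count table with row totals and a
    grand total (mirrors the family classification tables of genome-wide
    surveys)."""
    types = ["I", "II", "III", "IV", "V", "VI", "UNCLASSIFIED"]
    subfams = ["UCL", "SCL", "ENODL"]
    table = pd.DataFrame(0, index=types, columns=subfams, dtype=int)
    for a in assignments:
        table.loc[a.arch_type, a.subfamily] += 1
    table["total"] = table.sum(axis=1)
    table.loc["total"] = table.sum(axis=0)
    return table


def assignment_report(assignments: Sequence[FamilyAssignment]) -> pd.DataFrame:
    rows = []
    for a in assignments:
        lig = tuple(a.ligands) if a.ligands else (None,) * 4
        rows.append(
            {
                "id": a.protein_id,
                "subfamily": a.subfamily,
                "arch_type": a.arch_type,
                "chimeric_agp": a.chimeric_agp,
                "l1": lig[0],
                "l2": lig[1],
                "l3": lig[2],
                "l4": lig[3],
                "disulfide_ok": a.disulfide_ok,
            }
        )
    return pd.DataFrame(rows)
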