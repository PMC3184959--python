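"""Amino-acid bias and arabinogalactan (AG) glycomodule detection.

Arabinogalactan proteins (AGPs) are recognised from the protein backbone by
composition and motif rules: a high fraction of Pro+Ala+Ser+Thr (PAST, >35%
is characteristic), Pro-rich regions in which consecutive prolines are at
most 11 residues apart (such prolines are presumed hydroxylated), and AG
glycomodules — clusters of 2–4+ (Ala/Ser/Thr)-Pro dipeptides whose prolines
are noncontiguous (not adjacent to another Pro, which would instead suggest
an extensin-like SP2-4 block).

Positions in this module are 1-based inclusive, matching the rest of the
package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .records import ProteinRecord

#: maximum number of non-Pro residues between consecutive hydroxylation-
#: context prolines within one Pro-rich region
MAX_PRO_GAP = 11
#: maximum spacing between consecutive glycomodule dipeptide starts
#: (the Pro-gap rule plus the 2-residue dipeptide)
MAX_DIPEPTIDE_SPACING = 13
#: minimum number of qualifying dipeptides for an AGP-like region call
MIN_ALR_DIPEPTIDES = 3

GLYCOMODULE_HEADS = set("AST")
HYDROPHOBIC = set("AILVFMW")
SMALL = set("SAGNC")


@dataclass(frozen=True)
class ProRichRegion:
    """Maximal run of prolines in hydroxylation context: >= 2 Pro, each at
    most ``MAX_PRO_GAP`` non-Pro residues from the next."""

    start: int
    end: int
    pro_count: int
    past_fraction: float


@dataclass(frozen=True)
class Glycomodule:
    """Cluster of noncontiguous [AST]P dipeptides (1-based start positions)."""

    dipeptide_starts: tuple[int, ...]

    @property
    def size(self) -> int:
        return len(self.dipeptide_starts)


@dataclass
class AlrCall:
    """Result of the AGP-like-region decision for one protein."""

    present: bool
    glycomodules: list[Glycomodule] = field(default_factory=list)
    regions: list[ProRichRegion] = field(default_factory=list)
    region_past: float = 0.0


def past_fraction(seq: str, interval: Optional[tuple[int, int]] = None) -> float:
    """Fraction of Pro/Ala/Ser/Thr residues over ``interval`` (1-based
    inclusive; whole sequence if omitted)."""
    if interval is None:
        interval = (1, len(seq))
    start, end = interval
    if not (1 <= start <= end <= len(seq)):
        raise ValueError(f"interval ({start},{end}) invalid for length {len(seq)}")
    window = seq[start - 1 : end]
    return sum(c in "PAST" for c in window) / len(window)


def find_pro_rich_regions(seq: str) -> list[ProRichRegion]:
    """Maximal chains of prolines with <= 11 non-Pro residues between
    consecutive Pro; chains of fewer than 2 Pro are dropped. Region bounds
    run from the first to the last Pro of the chain."""
    pros = [i + 1 for i, c in enumerate(seq) if c == "P"]
    regions: list[ProRichRegion] = []
    run: list[int] = []
    for pos in pros:
        if run and pos - run[-1] - 1 > MAX_PRO_GAP:
            if len(run) >= 2:
                regions.append(_make_region(seq, run))
            run = []
        run.append(pos)
    if len(run) >= 2:
        regions.append(_make_region(seq, run))
    return regions


def _make_region(seq: str, pros: list[int]) -> ProRichRegion:
    start, end = pros[0], pros[-1]
    return ProRichRegion(
        start=start,
        end=end,
        pro_count=len(pros),
        past_fraction=past_fraction(seq, (start, end)),
    )


def _kept_dipeptide_starts(seq: str, start: int, end: int) -> list[int]:
    """[AST]P dipeptide starts within [start,end] whose Pro is noncontiguous
    (neither neighbour in the full sequence is a Pro)."""
    kept = []
    for i in range(start, end):  # dipeptide start i, Pro at i+1 (1-based)
        if seq[i - 1] in GLYCOMODULE_HEADS and seq[i] == "P":
            p = i + 1
            left = seq[p - 2] if p >= 2 else ""
            right = seq[p] if p < len(seq) else ""
            if left != "P" and right != "P":
                kept.append(i)
    return kept


def find_glycomodules(seq: str, region: ProRichRegion) -> list[Glycomodule]:
    """AG glycomodules inside a Pro-rich region: noncontiguous [AST]P
    dipeptides grouped into clusters whose consecutive starts are at most
    ``MAX_DIPEPTIDE_SPACING`` apart; clusters of >= 2 dipeptides are
    reported."""
    if not (1 <= region.start <= region.end <= len(seq)):
        raise ValueError("region outside sequence")
    kept = _kept_dipeptide_starts(seq, region.start, region.end)
    modules: list[Glycomodule] = []
    cluster: list[int] = []
    for pos in kept:
        if cluster and pos - cluster[-1] > MAX_DIPEPTIDE_SPACING:
            if len(cluster) >= 2:
                modules.append(Glycomodule(tuple(cluster)))
            cluster = []
        cluster.append(pos)
    if len(cluster) >= 2:
        modules.append(Glycomodule(tuple(cluster)))
    return modules


def _mask_intervals(seq: str, intervals: Sequence[tuple[int, int]]) -> str:
    chars = list(seq)
    for start, end in intervals:
        if not (1 <= start <= end <= len(seq)):
            raise ValueError(f"excluded interval ({start},{end}) out of bounds")
        for i in range(start - 1, end):
            chars[i] = "X"
    return "".join(chars)


def call_alr(protein: ProteinRecord,
             excluded: Sequence[tuple[int, int]] = ()) -> AlrCall:
    """Decide whether a protein carries an AGP-like region (ALR) outside the
    ``excluded`` intervals (the folded domain, signal peptide and GPI
    omega-region, which are not O-glycosylation substrates).

    The ALR is called present when the qualifying glycomodules found in
    Pro-rich regions outside the exclusions carry at least
    ``MIN_ALR_DIPEPTIDES`` dipeptides in total. ``region_past`` is the PAST
    fraction over the union of regions that contain a glycomodule (0 when
    none do).
    """
    masked = _mask_intervals(protein.seq, excluded)
    regions = find_pro_rich_regions(masked)
    qualifying: list[tuple[ProRichRegion, list[Glycomodule]]] = []
    for region in regions:
        mods = find_glycomodules(masked, region)
        if mods:
            qualifying.append((region, mods))
    all_mods = [m for _, mods in qualifying for m in mods]
    total = sum(m.size for m in all_mods)
    if qualifying:
        residues = [
            c
            for region, _ in qualifying
            for c in masked[region.start - 1 : region.end]
        ]
        region_past = sum(c in "PAST" for c in residues) / len(residues)
    else:
        region_past = 0.0
    return AlrCall(
        present=total >= MIN_ALR_DIPEPTIDES,
        glycomodules=all_mods,
        regions=[r for r, _ in qualifying],
        region_past=region_past,
    )


def _longest_stretch(window: str, alphabet: set[str]) -> tuple[int, int]:
    """(best length, 0-based end-exclusive index of best run) within window;
    leftmost longest run wins."""
    best_len, best_end = 0, 0
    run = 0
    for i, c in enumerate(window):
        run = run + 1 if c in alphabet else 0
        if run > best_len:
            best_len, best_end = run, i + 1
    return best_len, best_end


def heuristic_sp(seq: str) -> bool:
    """Toy signal-peptide rule for synthetic data (stands in for SignalP):
    true iff the first 25 residues contain a hydrophobic stretch of >= 8
    residues starting within the first 6 positions."""
    if len(seq) < 40:
        raise ValueError("sequence too short for SP/GAS heuristics (< 40)")
    window = seq[:25]
    run = 0
    for i, c in enumerate(window):
        run = run + 1 if c in HYDROPHOBIC else 0
        if run >= 8 and (i + 1) - run + 1 <= 6:  # 1-based start of the run
            return True
    return False


def heuristic_gas(seq: str) -> bool:
    """Toy GPI-anchor-signal rule for synthetic data (stands in for Big-PI):
    true iff the last 25 residues contain a hydrophobic stretch of >= 10
    residues ending within 3 of the C-terminus, with a small residue
    (S/A/G/N/C — the omega-site candidates) 10–20 positions upstream of the
    stretch end and strictly before the stretch start."""
    if len(seq) < 40:
        raise ValueError("sequence too short for SP/GAS heuristics (< 40)")
    n = len(seq)
    window = seq[n - 25 :]
    # enumerate runs; accept any satisfying all constraints
    run = 0
    for i, c in enumerate(window):
        run = run + 1 if c in HYDROPHOBIC else 0
        if run < 10:
            continue
        end_1b = n - 25 + i + 1  # 1-based position of run end in full seq
        if n - end_1b > 3:
            continue
        start_1b = end_1b - run + 1
        for dist in range(10, 21):
            p = end_1b - dist
            if 1 <= p < start_1b and seq[p - 1] in SMALL:
                return True
    return False


def feature_report(records: Sequence[ProteinRecord]) -> "pd.DataFrame":
    """Per-protein TSV-ready feature summary."""
    import pandas as pd

    rows = []
    for rec in records:
        regions = find_pro_rich_regions(rec.seq)
        call = call_alr(rec, rec.pcld_intervals or ())
        rows.append(
            {
                "id": rec.id,
                "past_fraction": round(past_fraction(rec.seq), 4),
                "n_pro_rich_regions": len(regions),
                "n_glycomodules": len(call.glycomodules),
                "alr_present": call.present,
            }
        )
    return pd.DataFrame(rows)
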