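"""Tandem and segmental (collinear-block) gene-duplication detection.

Tandem duplicates are family genes on one chromosome separated by at most
five intervening genes (counting genes of any family between the two
ordinals); chains of such pairs merge transitively into one group.
Segmental duplicates are family genes lying in paired collinear chromosome
blocks whose offsets from their respective block starts differ by at most
500 kb.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from .records import FamilyAssignment, GeneLocus, SegmentBlockPair, TandemGroup

#: "separated by five or fewer genes"
MAX_INTERVENING = 5
#: "maximal distance between collinear gene pairs of 500 kb"
MAX_COLLINEAR_OFFSET = 500_000


def find_tandem_groups(
    loci: Sequence[GeneLocus],
    family_ids: Sequence[str],
    max_intervening: int = MAX_INTERVENING,
) -> list[TandemGroup]:
    """Group family genes into tandem-duplicate clusters.

    ``loci`` must carry per-chromosome ordinals over ALL genes (family and
    background); two family genes chain when ``ordinal gap - 1 <=
    max_intervening``, and groups are the transitive closure of that
    relation. Singletons are dropped.
    """
    by_id = {g.gene_id: g for g in loci}
    missing = [fid for fid in family_ids if fid not in by_id]
    if missing:
        raise KeyError(f"family ids missing from loci: {missing}")
    by_chrom: dict[str, list[GeneLocus]] = {}
    for fid in family_ids:
        g = by_id[fid]
        by_chrom.setdefault(g.chrom, []).append(g)
    groups: list[TandemGroup] = []
    for chrom in sorted(by_chrom):
        members = sorted(by_chrom[chrom], key=lambda g: g.ordinal)
        chain: list[GeneLocus] = []
        for g in members:
            if chain and g.ordinal - chain[-1].ordinal - 1 > max_intervening:
                if len(chain) >= 2:
                    groups.append(TandemGroup(chrom, tuple(x.gene_id for x in chain)))
                chain = []
            chain.append(g)
        if len(chain) >= 2:
            groups.append(TandemGroup(chrom, tuple(x.gene_id for x in chain)))
    return groups


@dataclass(frozen=True)
class SegmentalPair:
    """Two family genes related through a collinear block pair."""

    pair_id: str
    gene_a: str
    gene_b: str
    offset_diff: float


def _genes_in_block(loci: Sequence[GeneLocus], family: set[str], chrom: str,
                    start: int, end: int) -> list[GeneLocus]:
    return [
        g
        for g in loci
        if g.gene_id in family and g.chrom == chrom and start <= g.midpoint <= end
    ]


def find_segmental_pairs(
    loci: Sequence[GeneLocus],
    blocks: Sequence[SegmentBlockPair],
    family_ids: Sequence[str],
    max_offset: int = MAX_COLLINEAR_OFFSET,
) -> list[SegmentalPair]:
    """Pair family genes across duplicated-segment blocks.

    A gene belongs to a block when its midpoint lies inside it; genes from
    the two sides of a block pair are paired when their offsets from the
    respective block starts differ by at most ``max_offset`` (the
    collinearity stand-in). A gene may appear in pairs from several blocks.
    """
    family = set(family_ids)
    pairs: list[SegmentalPair] = []
    for blk in blocks:
        in_a = _genes_in_block(loci, family, blk.chrom_a, blk.start_a, blk.end_a)
        in_b = _genes_in_block(loci, family, blk.chrom_b, blk.start_b, blk.end_b)
        for ga in in_a:
            for gb in in_b:
                if ga.gene_id == gb.gene_id:
                    continue
                diff = abs(
                    (ga.midpoint - blk.start_a) - (gb.midpoint - blk.start_b)
                )
                if diff <= max_offset:
                    pairs.append(
                        SegmentalPair(blk.pair_id, ga.gene_id, gb.gene_id, diff)
                    )
    return pairs


@dataclass
class DuplicationReport:
    n_duplicated_genes: int
    n_tandem_genes: int
    n_segmental_genes: int
    tandem_per_chrom: dict[str, int] = field(default_factory=dict)
    tandem_concordance: Optional[float] = None
    segmental_concordance: Optional[float] = None


def duplication_report(
    tandem: Sequence[TandemGroup],
    segmental: Sequence[SegmentalPair],
    assignments: Optional[Mapping[str, FamilyAssignment]] = None,
) -> DuplicationReport:
    """Summarise duplication: gene counts (union over both mechanisms),
    per-chromosome tandem counts, and — when subfamily assignments are
    supplied — the fraction of groups/pairs whose members share a
    subfamily."""
    tandem_genes = {gid for grp in tandem for gid in grp.gene_ids}
    seg_genes = {g for p in segmental for g in (p.gene_a, p.gene_b)}
    per_chrom: dict[str, int] = {}
    for grp in tandem:
        per_chrom[grp.chrom] = per_chrom.get(grp.chrom, 0) + len(grp.gene_ids)

    tandem_conc = seg_conc = None
    if assignments is not None:
        def subfam(gid: str) -> str:
            return assignments[gid].subfamily

        if tandem:
            same = sum(
                len({subfam(g) for g in grp.gene_ids}) == 1 for grp in tandem
            )
            tandem_conc = same / len(tandem)
        if segmental:
            same = sum(subfam(p.gene_a) == subfam(p.gene_b) for p in segmental)
            seg_conc = same / len(segmental)

    return DuplicationReport(
        n_duplicated_genes=len(tandem_genes | seg_genes),
        n_tandem_genes=len(tandem_genes),
        n_segmental_genes=len(seg_genes),
        tandem_per_chrom=per_chrom,
        tandem_concordance=tandem_conc,
        segmental_concordance=seg_conc,
    )


def tandem_table(groups: Sequence[TandemGroup]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"group": i + 1, "chrom": g.chrom, "genes": ";".join(g.gene_ids)}
            for i, g in enumerate(groups)
        ]
    )


def segmental_table(pairs: Sequence[SegmentalPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pair_id": p.pair_id,
                "gene_a": p.gene_a,
                "gene_b": p.gene_b,
                "offset_diff": p.offset_diff,
            }
            for p in pairs
        ]
    )
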