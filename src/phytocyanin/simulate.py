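"""Seeded generators for synthetic inputs with known ground truth.

Every generator is deterministic in (spec, seed). Sequence backgrounds are
proline-free outside planted cassettes so no accidental glycomodule can
arise, and planted features sit strictly inside or outside the decision
rules' bounds (never on a boundary) so downstream calls are insensitive to
the package's documented threshold choices.

The default family fixture reproduces the rice phytocyanin census: 62
proteins distributed over subfamily x architecture-type cells as
19/1/18 (type I), 3/1/4 (III), 11/1/2 (IV) and 2/0/0 (V) for
UCL/SCL/ENODL respectively.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .classify import REFERENCE_PCLD, ReferencePcld
from .duplication import SegmentalPair, MAX_COLLINEAR_OFFSET, MAX_INTERVENING
from .io import assign_ordinals
from .records import (
    ABSENT,
    ExpressionMatrix,
    FamilyAssignment,
    GeneLocus,
    LigandTuple,
    ProteinRecord,
    QpcrPlate,
    SegmentBlockPair,
    TandemGroup,
)

# residues safe for linkers/fillers: no Pro (would seed glycomodules), no
# hydrophobics (would trip the SP/GAS heuristics)
LINKER_ALPHABET = "GSTNQDEKRHY"
GAS_FILLER_ALPHABET = "DEKQRT"
# glycomodule units: [AST]P dipeptide + a 3-residue spacer; unit length 5
# keeps Pro gaps at 4 (<= 11) and dipeptide spacing at 5 (<= 13)
ALR_UNITS = ("APSGE", "SPTGE", "TPAGE")

#: rice census used as the default family fixture (subfamily, type) -> count
RICE_TABLE1 = {
    ("UCL", "I"): 19, ("SCL", "I"): 1, ("ENODL", "I"): 18,
    ("UCL", "III"): 3, ("SCL", "III"): 1, ("ENODL", "III"): 4,
    ("UCL", "IV"): 11, ("SCL", "IV"): 1, ("ENODL", "IV"): 2,
    ("UCL", "V"): 2,
}

_ARCH_ELEMENTS = {  # type -> (sp, n_pcld, alr, gas)
    "I": (True, 1, True, True),
    "II": (True, 1, True, False),
    "III": (True, 1, False, True),
    "IV": (True, 1, False, False),
    "V": (False, 1, False, False),
    "VI": (True, 2, False, False),
}


@dataclass(frozen=True)
class ProteinSpec:
    """Recipe for one synthetic phytocyanin."""

    subfamily: str  # UCL | SCL | ENODL
    arch_type: str  # I..VI
    n_glycomodule_dipeptides: Optional[int] = None  # default 8 when ALR present
    seed: int = 0

    def __post_init__(self) -> None:
        if self.arch_type not in _ARCH_ELEMENTS:
            raise ValueError(f"unknown architecture type {self.arch_type!r}")
        if self.subfamily not in ("UCL", "SCL", "ENODL"):
            raise ValueError(f"unknown subfamily {self.subfamily!r}")
        has_alr = _ARCH_ELEMENTS[self.arch_type][2]
        n = self.n_glycomodule_dipeptides
        if n is not None:
            if has_alr and n < 6:
                raise ValueError("ALR-bearing types need >= 6 planted dipeptides")
            if not has_alr and n != 0:
                raise ValueError(
                    f"type {self.arch_type} carries no ALR; dipeptide count must be 0"
                )


def _linker(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(LINKER_ALPHABET), size=length))


def _sp_cassette(rng: np.random.Generator) -> str:
    # 25 residues: Met-Lys start, a 10-residue Leu stretch (begins at
    # position 3 <= 6), then neutral filler
    return "MK" + "L" * 10 + _linker(rng, 13)


def _gas_cassette(rng: np.random.Generator) -> str:
    # 25 residues: filler, omega-site Asn 14 upstream of the stretch end,
    # two spacers, then a 12-residue Leu tail ending at the C-terminus
    filler = "".join(rng.choice(list(GAS_FILLER_ALPHABET), size=10))
    return filler + "N" + "QQ" + "L" * 12


def _alr_cassette(rng: np.random.Generator, n_dipeptides: int) -> str:
    units = rng.choice(ALR_UNITS, size=n_dipeptides)
    return "".join(units)


def _mutate_pcld(subfamily: str, rng: np.random.Generator,
                 ref: ReferencePcld) -> tuple[str, LigandTuple]:
    seq = list(ref.seq)
    cols = ref.ligand_columns
    if subfamily == "UCL":
        letters = ["H", "C", "H", "M"]
    elif subfamily == "SCL":
        seq[cols[3] - 1] = "Q"
        letters = ["H", "C", "H", "Q"]
    else:  # ENODL: break a random key site by substitution or deletion
        site = int(rng.integers(0, 4))
        letters = ["H", "C", "H", "M"]
        if rng.random() < 0.5:
            sub = str(rng.choice(list("SGND")))
            seq[cols[site] - 1] = sub
            letters[site] = sub
        else:
            del seq[cols[site] - 1]
            letters[site] = ABSENT
    return "".join(seq), LigandTuple(*letters)


def gen_pc_protein(
    spec: ProteinSpec,
    protein_id: str = "synthetic",
    ref: ReferencePcld = REFERENCE_PCLD,
) -> tuple[ProteinRecord, FamilyAssignment]:
    """Assemble one protein from cassettes (SP, linkers, PCLD(s), ALR, GAS
    tail) and return it with its intended truth assignment."""
    rng = np.random.default_rng(spec.seed)
    has_sp, n_pcld, has_alr, has_gas = _ARCH_ELEMENTS[spec.arch_type]
    n_dip = spec.n_glycomodule_dipeptides
    if n_dip is None:
        n_dip = 8 if has_alr else 0

    pcld_seq, ligands = _mutate_pcld(spec.subfamily, rng, ref)
    parts: list[str] = []
    if has_sp:
        parts.append(_sp_cassette(rng))
        parts.append(_linker(rng, int(rng.integers(8, 16))))
    parts.append(pcld_seq)
    if n_pcld == 2:
        parts.append(_linker(rng, int(rng.integers(10, 18))))
        parts.append(pcld_seq)
    if has_alr:
        parts.append(_linker(rng, int(rng.integers(8, 16))))
        parts.append(_alr_cassette(rng, n_dip))
    if has_gas:
        parts.append(_linker(rng, int(rng.integers(4, 9))))
        parts.append(_gas_cassette(rng))
    elif spec.arch_type in ("IV", "VI"):
        parts.append(_linker(rng, int(rng.integers(6, 12))))

    record = ProteinRecord(id=protein_id, seq="".join(parts))
    truth = FamilyAssignment(
        protein_id=protein_id,
        subfamily=spec.subfamily,
        arch_type=spec.arch_type,
        chimeric_agp=spec.arch_type in ("I", "II"),
        ligands=ligands,
        has_sp=has_sp,
        has_gas=has_gas,
        has_alr=has_alr,
        n_pcld=n_pcld,
    )
    return record, truth


def gen_family_fixture(
    table: Optional[Mapping[tuple[str, str], int]] = None,
    seed: int = 0,
) -> tuple[list[ProteinRecord], list[FamilyAssignment]]:
    """One protein per occupant of each (subfamily, type) cell; the default
    table is the rice census (62 proteins)."""
    if table is None:
        table = RICE_TABLE1
    rng = np.random.default_rng(seed)
    proteins: list[ProteinRecord] = []
    truths: list[FamilyAssignment] = []
    i = 0
    for (subfam, arch), count in sorted(table.items()):
        if count < 0:
            raise ValueError("cell counts must be nonnegative")
        for _ in range(count):
            i += 1
            sub_seed = int(rng.integers(0, 2**31 - 1))
            rec, truth = gen_pc_protein(
                ProteinSpec(subfam, arch, seed=sub_seed),
                protein_id=f"PC{i:03d}",
            )
            proteins.append(rec)
            truths.append(truth)
    return proteins, truths


# ---------------------------------------------------------------------------
# genome layouts


@dataclass(frozen=True)
class TandemClusterSpec:
    chrom_index: int
    size: int
    intervening: int  # background genes between consecutive members


@dataclass(frozen=True)
class BlockPairSpec:
    chrom_a_index: int
    chrom_b_index: int
    offset_diff: int  # bp difference of the two genes' offsets from block starts


@dataclass(frozen=True)
class LayoutSpec:
    n_chromosomes: int = 3
    background_per_chrom: int = 60
    gene_length: int = 3_000
    spacing: int = 50_000
    tandem_clusters: tuple[TandemClusterSpec, ...] = (
        TandemClusterSpec(0, 3, 2),
        TandemClusterSpec(1, 2, 4),
    )
    n_scattered: int = 2
    block_pairs: tuple[BlockPairSpec, ...] = (BlockPairSpec(1, 2, 100_000),)
    seed: int = 0


@dataclass
class LayoutTruth:
    tandem_groups: list[TandemGroup]
    segmental_pairs: list[SegmentalPair]


def gen_genome_layout(
    spec: LayoutSpec = LayoutSpec(),
) -> tuple[list[GeneLocus], list[str], list[SegmentBlockPair], LayoutTruth]:
    """Deterministic genome layout with planted tandem clusters, scattered
    family singletons and collinear block pairs.

    Returns (all loci with ordinals, family gene ids, block pairs, truth).
    Planted features are spaced >= 16 gene slots apart so no accidental
    tandem chaining or block capture can occur.
    """
    slots_needed = 20  # initial offset per chromosome
    chrom_names = [f"chr{i + 1}" for i in range(spec.n_chromosomes)]
    # slot -> family marker per chromosome
    family_slots: dict[int, list[tuple[int, str]]] = {i: [] for i in range(spec.n_chromosomes)}
    cursor = {i: 18 for i in range(spec.n_chromosomes)}
    fam_counter = 0

    def next_slots(chrom: int, offsets: Sequence[int]) -> list[int]:
        nonlocal fam_counter
        base = cursor[chrom]
        slots = [base + off for off in offsets]
        cursor[chrom] = slots[-1] + 16
        if cursor[chrom] - 16 >= spec.background_per_chrom:
            raise ValueError("layout too dense: raise background_per_chrom")
        return slots

    truth_groups: list[TandemGroup] = []
    for cl in spec.tandem_clusters:
        offsets = [k * (cl.intervening + 1) for k in range(cl.size)]
        slots = next_slots(cl.chrom_index, offsets)
        ids = []
        for s in slots:
            fam_counter += 1
            gid = f"fam{fam_counter:03d}"
            family_slots[cl.chrom_index].append((s, gid))
            ids.append(gid)
        if cl.intervening <= MAX_INTERVENING and cl.size >= 2:
            truth_groups.append(
                TandemGroup(chrom_names[cl.chrom_index], tuple(ids))
            )

    rng = np.random.default_rng(spec.seed)
    for k in range(spec.n_scattered):
        chrom = int(rng.integers(0, spec.n_chromosomes))
        (slot,) = next_slots(chrom, [0])
        fam_counter += 1
        family_slots[chrom].append((slot, f"fam{fam_counter:03d}"))

    blocks: list[SegmentBlockPair] = []
    truth_pairs: list[SegmentalPair] = []
    offset_base = 100_000
    for bi, bp in enumerate(spec.block_pairs):
        (slot_a,) = next_slots(bp.chrom_a_index, [0])
        (slot_b,) = next_slots(bp.chrom_b_index, [0])
        fam_counter += 1
        gid_a = f"fam{fam_counter:03d}"
        fam_counter += 1
        gid_b = f"fam{fam_counter:03d}"
        family_slots[bp.chrom_a_index].append((slot_a, gid_a))
        family_slots[bp.chrom_b_index].append((slot_b, gid_b))
        mid_a = _slot_mid(slot_a, spec)
        mid_b = _slot_mid(slot_b, spec)
        block_len = bp.offset_diff + 2 * offset_base
        start_a = int(mid_a - offset_base)
        start_b = int(mid_b - offset_base - bp.offset_diff)
        if start_a < 1 or start_b < 1:
            raise ValueError("block extends before chromosome start")
        pair_id = f"block{bi + 1}"
        blocks.append(
            SegmentBlockPair(
                pair_id,
                chrom_names[bp.chrom_a_index], start_a, start_a + block_len,
                chrom_names[bp.chrom_b_index], start_b, start_b + block_len,
            )
        )
        if bp.offset_diff <= MAX_COLLINEAR_OFFSET:
            truth_pairs.append(
                SegmentalPair(pair_id, gid_a, gid_b,
                              float(abs((mid_a - start_a) - (mid_b - start_b))))
            )

    loci: list[GeneLocus] = []
    family_ids: list[str] = []
    for ci, chrom in enumerate(chrom_names):
        fam_by_slot = dict(family_slots[ci])
        for s in range(spec.background_per_chrom):
            start = 10_000 + s * spec.spacing
            gid = fam_by_slot.get(s, f"bg_{chrom}_{s:03d}")
            if s in fam_by_slot:
                family_ids.append(gid)
            loci.append(GeneLocus(gid, chrom, start, start + spec.gene_length - 1))
    loci = assign_ordinals(loci)
    return loci, family_ids, blocks, LayoutTruth(truth_groups, truth_pairs)


def _slot_mid(slot: int, spec: LayoutSpec) -> float:
    start = 10_000 + slot * spec.spacing
    return start + (spec.gene_length - 1) / 2.0


# ---------------------------------------------------------------------------
# expression data


@dataclass(frozen=True)
class ExprSpec:
    n_genes: int = 40
    tissues: tuple[str, ...] = ("root", "leaf", "stem", "panicle")
    conditions: tuple[str, ...] = ("drought", "salt", "cold")
    n_replicates: int = 4
    n_specific: int = 4  # EST tissue-specific genes
    n_up: int = 3  # planted fold 4.0 under the first condition
    n_down: int = 3  # planted fold 0.25 under the first condition
    fold_up: float = 4.0
    fold_down: float = 0.25
    noise_sd: float = 0.2  # log2 units
    baseline_log2_mean: float = 6.0
    baseline_log2_sd: float = 1.0
    est_total: int = 12
    efficiency: float = 2.0
    ct_intercept: float = 34.0
    seed: int = 0


@dataclass
class ExprTruth:
    specific: dict[str, str]
    up: set[str]
    down: set[str]
    mpss_tiers: dict[str, str]
    qpcr_relative: pd.DataFrame  # genes x samples, planted relative levels
    slope: float


def gen_expression_data(
    spec: ExprSpec = ExprSpec(),
) -> tuple[ExpressionMatrix, pd.DataFrame, pd.DataFrame, QpcrPlate, ExprTruth]:
    """Synthetic expression bundle: a stress microarray matrix (control +
    conditions, log-normal noise, planted multiplicative folds), an EST
    count table with planted tissue-specific genes, an MPSS tpm table with
    planted abundance tiers, and a qPCR plate whose Ct values follow the
    stated amplification efficiency exactly.
    """
    rng = np.random.default_rng(spec.seed)
    genes = [f"g{i + 1:03d}" for i in range(spec.n_genes)]

    # --- microarray stress matrix
    arms = ("control",) + spec.conditions
    samples = [f"{cond}_r{r + 1}" for cond in arms for r in range(spec.n_replicates)]
    meta = pd.DataFrame(
        {
            "tissue": "seedling",
            "condition": [s.rsplit("_", 1)[0] for s in samples],
            "replicate": [int(s.rsplit("_r", 1)[1]) for s in samples],
        },
        index=pd.Index(samples, name="sample_id"),
    )
    base = 2.0 ** rng.normal(spec.baseline_log2_mean, spec.baseline_log2_sd, spec.n_genes)
    picks = rng.choice(spec.n_genes, size=spec.n_up + spec.n_down, replace=False)
    up_genes = {genes[i] for i in picks[: spec.n_up]}
    down_genes = {genes[i] for i in picks[spec.n_up :]}
    stress_cond = spec.conditions[0]
    values = np.empty((spec.n_genes, len(samples)))
    for gi, gene in enumerate(genes):
        for si, sample in enumerate(samples):
            cond = meta.loc[sample, "condition"]
            fold = 1.0
            if cond == stress_cond and gene in up_genes:
                fold = spec.fold_up
            elif cond == stress_cond and gene in down_genes:
                fold = spec.fold_down
            values[gi, si] = base[gi] * fold * 2.0 ** rng.normal(0.0, spec.noise_sd)
    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples),
        sample_meta=meta,
    )

    # --- EST counts: balanced round-robin for background genes (no strict
    # majority possible with >= 3 tissues), dominant tissue for planted ones
    n_t = len(spec.tissues)
    spec_picks = rng.choice(spec.n_genes, size=spec.n_specific, replace=False)
    specific = {
        genes[i]: str(rng.choice(list(spec.tissues))) for i in spec_picks
    }
    est_rows = []
    for gene in genes:
        counts = {t: spec.est_total // n_t for t in spec.tissues}
        rem = spec.est_total - sum(counts.values())
        order = list(rng.permutation(list(spec.tissues)))
        for t in order[:rem]:
            counts[t] += 1
        if gene in specific:
            # dominant tissue takes all but one EST per other tissue:
            # a strict majority with margin for est_total >= 2*n_tissues
            dom = specific[gene]
            counts = {t: 1 for t in spec.tissues}
            counts[dom] = spec.est_total - (n_t - 1)
        est_rows.append({"gene_id": gene, **counts})
    est = pd.DataFrame(est_rows).set_index("gene_id")

    # --- MPSS tpm with planted tiers (values kept away from 50/500 bounds)
    tiers = ("LOW", "MODERATE", "STRONG")
    tier_rng = {"LOW": (0.0, 40.0), "MODERATE": (60.0, 450.0), "STRONG": (600.0, 5000.0)}
    mpss_tiers = {g: tiers[int(rng.integers(0, 3))] for g in genes}
    mpss = pd.DataFrame(
        {
            "gene_id": genes,
            "tpm": [float(rng.uniform(*tier_rng[mpss_tiers[g]])) for g in genes],
        }
    ).set_index("gene_id")

    # --- qPCR: 4 reference genes at a common per-sample quantity; targets
    # at planted relative levels; Ct from the stated efficiency
    slope = -1.0 / np.log10(spec.efficiency)
    ref_genes = [f"ref{i + 1}" for i in range(4)]
    target_genes = genes[: min(4, spec.n_genes)]
    qpcr_samples = ["root", "leaf", "panicle"]
    rel = pd.DataFrame(
        2.0 ** rng.normal(0.0, 1.5, (len(target_genes), len(qpcr_samples))),
        index=target_genes,
        columns=qpcr_samples,
    )
    ct_rows = []
    for sample in qpcr_samples:
        ref_level = float(rng.uniform(50, 500))
        for bio in (1, 2):
            for gene in ref_genes + target_genes:
                q = ref_level * (rel.loc[gene, sample] if gene in target_genes else 1.0)
                ct = spec.ct_intercept + slope * np.log10(q)
                for tech in (1, 2, 3):
                    ct_rows.append(
                        {"gene": gene, "sample": sample, "bio_rep": bio,
                         "tech_rep": tech, "ct": ct}
                    )
    dil_rows = []
    amounts = (10.0, 30.0, 90.0, 270.0, 810.0, 2430.0)
    for gene in ref_genes + target_genes:
        for amount in amounts:
            dil_rows.append(
                {"gene": gene, "amount": amount,
                 "ct": spec.ct_intercept + slope * np.log10(amount)}
            )
    plate = QpcrPlate(ct=pd.DataFrame(ct_rows), dilution=pd.DataFrame(dil_rows))

    truth = ExprTruth(
        specific=specific,
        up=up_genes,
        down=down_genes,
        mpss_tiers=mpss_tiers,
        qpcr_relative=rel,
        slope=float(slope),
    )
    return matrix, est, mpss, plate, truth
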