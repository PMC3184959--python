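"""Digital expression rules (EST, MPSS, microarray) and qRT-PCR
quantification.

The digital-expression conventions implemented here:

* EST tissue specificity — a gene is specifically expressed in the unique
  tissue contributing strictly more than half of its total EST count.
* MPSS abundance tiers — tags-per-million below 50 is LOW, 50–500
  (inclusive) MODERATE, above 500 STRONG.
* Microarray display normalisation — each signal is divided by the grand
  mean of the matrix and log2-transformed; genes are then hierarchically
  clustered with centred-correlation distance and average linkage.
* Stress differential calls — fold change on the linear scale with a Welch
  t-test on log2 signals; UP requires fold > 2 and p < 0.05, DOWN fold
  < 0.5 and p < 0.05.
* qRT-PCR — per-gene standard curves fitted as Ct vs log10(template
  amount) on a 3-fold dilution series (amounts 10..2430); quantities are
  normalised by the geometric mean of four housekeeping reference genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .records import ExpressionMatrix, QpcrPlate, StressCall

MPSS_LOW_BOUND = 50.0
MPSS_STRONG_BOUND = 500.0
FC_UP = 2.0
FC_DOWN = 0.5
ALPHA = 0.05
DILUTION_AMOUNTS = (10.0, 30.0, 90.0, 270.0, 810.0, 2430.0)


def est_specific_tissue(counts: Mapping[str, int]) -> Optional[str]:
    """The unique tissue holding a strict majority of the gene's EST counts,
    or None. A zero total yields None."""
    vals = list(counts.values())
    if any(v < 0 for v in vals):
        raise ValueError("EST counts must be nonnegative")
    total = sum(vals)
    if total == 0:
        return None
    for tissue, n in counts.items():
        if n * 2 > total:
            return tissue
    return None


def est_coverage_percent(n_with_evidence: int, n_total: int) -> float:
    """Percentage of family genes with EST/FL-cDNA support."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return 100.0 * n_with_evidence / n_total


def mpss_tier(tpm: float) -> str:
    """<50 tpm LOW, 50–500 inclusive MODERATE, >500 STRONG."""
    if not np.isfinite(tpm) or tpm < 0:
        raise ValueError(f"tpm must be finite and nonnegative, got {tpm}")
    if tpm < MPSS_LOW_BOUND:
        return "LOW"
    if tpm <= MPSS_STRONG_BOUND:
        return "MODERATE"
    return "STRONG"


def normalize_microarray(
    matrix: ExpressionMatrix | pd.DataFrame,
    pseudo: Optional[float] = None,
) -> pd.DataFrame:
    """Divide every signal by the grand mean of the matrix and take log2.

    Zeros are floored at ``pseudo`` before division (default: half the
    smallest positive value in the matrix). An all-zero matrix is an error.
    """
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    arr = values.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("signals must be nonnegative")
    positive = arr[arr > 0]
    if positive.size == 0:
        raise ValueError("all-zero matrix cannot be normalized")
    if pseudo is None:
        pseudo = 0.5 * positive.min()
    arr = np.where(arr == 0, pseudo, arr)
    ratios = arr / arr.mean()
    return pd.DataFrame(np.log2(ratios), index=values.index, columns=values.columns)


def cluster_genes(normalized: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Agglomerative clustering of genes with centred-correlation distance
    (1 - Pearson r between rows) and average linkage.

    A zero-variance gene is undefined under correlation and is assigned the
    maximal distance (2.0) to every other gene. Returns the scipy linkage
    matrix and the deterministic leaf order (gene ids); ties follow input
    order through scipy's deterministic agglomeration.
    """
    if normalized.shape[0] < 2:
        raise ValueError("clustering needs >= 2 genes")
    arr = normalized.to_numpy(dtype=float)
    sd = arr.std(axis=1)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(arr)
    dist = 1.0 - corr
    degenerate = sd == 0
    dist[degenerate, :] = 2.0
    dist[:, degenerate] = 2.0
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    linkage = hierarchy.linkage(squareform(dist, checks=False), method="average")
    order = hierarchy.leaves_list(linkage)
    return linkage, [normalized.index[i] for i in order]


def call_stress_de(
    matrix: ExpressionMatrix,
    condition: str,
    control: str = "control",
    fc_hi: float = FC_UP,
    fc_lo: float = FC_DOWN,
    alpha: float = ALPHA,
    pseudo: Optional[float] = None,
) -> list[StressCall]:
    """Per-gene stress call: fold change = mean(condition)/mean(control) on
    the linear scale; p from a two-sided Welch t-test on log2 signals.

    UP iff fold > ``fc_hi`` and p < ``alpha``; DOWN iff fold < ``fc_lo``
    and p < ``alpha``; otherwise NONE. Requires >= 2 replicates per arm.
    """
    meta = matrix.sample_meta
    cond_samples = meta.index[meta["condition"] == condition]
    ctrl_samples = meta.index[meta["condition"] == control]
    if len(cond_samples) < 2 or len(ctrl_samples) < 2:
        raise ValueError("need >= 2 replicates per arm")
    vals = matrix.values
    arr = vals.to_numpy(dtype=float)
    positive = arr[arr > 0]
    if pseudo is None:
        pseudo = 0.5 * positive.min() if positive.size else 1e-6
    floored = vals.where(vals > 0, pseudo)
    log2v = np.log2(floored)

    calls: list[StressCall] = []
    for gene in vals.index:
        cond_lin = floored.loc[gene, cond_samples].to_numpy(dtype=float)
        ctrl_lin = floored.loc[gene, ctrl_samples].to_numpy(dtype=float)
        fold = cond_lin.mean() / ctrl_lin.mean()
        t_res = stats.ttest_ind(
            log2v.loc[gene, cond_samples],
            log2v.loc[gene, ctrl_samples],
            equal_var=False,
        )
        p = float(t_res.pvalue)
        if np.isnan(p):  # identical constant arms
            p = 1.0
        if fold > fc_hi and p < alpha:
            call = "UP"
        elif fold < fc_lo and p < alpha:
            call = "DOWN"
        else:
            call = "NONE"
        calls.append(StressCall(gene, condition, float(fold), p, call))
    return calls


@dataclass(frozen=True)
class StandardCurve:
    slope: float
    intercept: float
    r_squared: float

    def quantity(self, ct: float) -> float:
        """Template amount for an observed Ct (inverse of the fit)."""
        return float(10.0 ** ((ct - self.intercept) / self.slope))


def qpcr_standard_curve(
    cts: Sequence[float],
    amounts: Sequence[float] = DILUTION_AMOUNTS,
) -> StandardCurve:
    """Least-squares fit of Ct against log10(template amount) over a
    dilution series. Warns when Ct does not decrease monotonically with
    amount (pipetting/efficiency trouble)."""
    cts = np.asarray(cts, dtype=float)
    amounts = np.asarray(amounts, dtype=float)
    ok = np.isfinite(cts)
    cts, amounts = cts[ok], amounts[ok]
    if len(cts) < 3:
        raise ValueError("standard curve needs >= 3 dilution points")
    order = np.argsort(amounts)
    if np.any(np.diff(cts[order]) >= 0):
        warnings.warn("non-monotone Ct across the dilution series", stacklevel=2)
    if np.allclose(cts, cts[0]):
        return StandardCurve(0.0, float(cts[0]), float("nan"))
    fit = stats.linregress(np.log10(amounts), cts)
    return StandardCurve(float(fit.slope), float(fit.intercept), float(fit.rvalue) ** 2)


def fit_standard_curves(plate: QpcrPlate) -> dict[str, StandardCurve]:
    curves = {}
    for gene, sub in plate.dilution.groupby("gene"):
        curves[gene] = qpcr_standard_curve(sub["ct"].to_numpy(), sub["amount"].to_numpy())
    return curves


def qpcr_relative_expression(
    plate: QpcrPlate,
    reference_genes: Sequence[str],
    curves: Optional[Mapping[str, StandardCurve]] = None,
) -> pd.DataFrame:
    """Standard-curve relative quantification.

    Technical replicates are averaged on the Ct scale; each Ct is converted
    to a template quantity through its gene's standard curve; the quantity
    is divided by the geometric mean of the reference-gene quantities of
    the same (sample, biological replicate). Biological replicates are then
    summarised as mean +/- sd. Samples in which any reference gene is
    undetected are flagged and excluded.

    Returns a tidy frame: gene, sample, mean, sd, n_bio_reps, flagged.
    """
    if len(reference_genes) < 1:
        raise ValueError("at least one reference gene required")
    if curves is None:
        curves = fit_standard_curves(plate)
    missing = [g for g in set(plate.ct["gene"]) if g not in curves]
    if missing:
        raise KeyError(f"no standard curve for genes: {sorted(missing)}")

    mean_ct = (
        plate.ct.groupby(["gene", "sample", "bio_rep"])["ct"]
        .mean()  # NaN-aware: missing technical replicates are dropped
        .reset_index()
    )
    mean_ct["quantity"] = [
        curves[g].quantity(c) if np.isfinite(c) else np.nan
        for g, c in zip(mean_ct["gene"], mean_ct["ct"])
    ]

    refs = set(reference_genes)
    rows = []
    flagged: set[tuple[str, str]] = set()
    for (sample, bio_rep), sub in mean_ct.groupby(["sample", "bio_rep"]):
        ref_q = sub.loc[sub["gene"].isin(refs), "quantity"]
        if len(ref_q) < len(refs) or ref_q.isna().any():
            for g in sub.loc[~sub["gene"].isin(refs), "gene"]:
                flagged.add((g, sample))
            continue
        norm = float(stats.gmean(ref_q))
        for r in sub.itertuples():
            if r.gene in refs or not np.isfinite(r.quantity):
                continue
            rows.append(
                {
                    "gene": r.gene,
                    "sample": sample,
                    "bio_rep": bio_rep,
                    "relative": r.quantity / norm,
                }
            )
    tidy = pd.DataFrame(rows)
    if tidy.empty:
        out = pd.DataFrame(columns=["gene", "sample", "mean", "sd", "n_bio_reps", "flagged"])
    else:
        out = (
            tidy.groupby(["gene", "sample"])["relative"]
            .agg(mean="mean", sd=lambda x: x.std(ddof=1) if len(x) > 1 else 0.0,
                 n_bio_reps="count")
            .reset_index()
        )
        out["flagged"] = [
            (g, s) in flagged for g, s in zip(out["gene"], out["sample"])
        ]
    return out
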