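"""Digital-expression rules (EST, MPSS, microarray) and qRT-PCR."""

import numpy as np
import pandas as pd
import pytest

from phytocyanin import (
    ExpressionMatrix,
    QpcrPlate,
    call_stress_de,
    cluster_genes,
    est_coverage_percent,
    est_specific_tissue,
    fit_standard_curves,
    gen_expression_data,
    mpss_tier,
    normalize_microarray,
    qpcr_relative_expression,
    qpcr_standard_curve,
)
from phytocyanin.simulate import ExprSpec


@pytest.mark.parametrize(
    "counts,expected",
    [
        ({"root": 6, "leaf": 2, "stem": 2}, "root"),
        ({"root": 5, "leaf": 5}, None),  # exactly half fails the strict rule
        ({"root": 1}, "root"),
        ({"root": 0, "leaf": 0}, None),
    ],
)
def test_est_specific_tissue(counts, expected):
    assert est_specific_tissue(counts) == expected


def test_est_negative_counts_error():
    with pytest.raises(ValueError):
        est_specific_tissue({"root": -1})


@pytest.mark.parametrize(
    "tpm,tier",
    [(0, "LOW"), (49.9, "LOW"), (50, "MODERATE"), (500, "MODERATE"),
     (500.1, "STRONG"), (1e6, "STRONG")],
)
def test_mpss_tier(tpm, tier):
    assert mpss_tier(tpm) == tier


def test_mpss_tier_partitions_and_rejects_negative():
    rng = np.random.default_rng(1)
    for tpm in rng.uniform(0, 2000, 200):
        assert mpss_tier(tpm) in ("LOW", "MODERATE", "STRONG")
    with pytest.raises(ValueError):
        mpss_tier(-0.1)


def _matrix(values, n_rep=1, conditions=None):
    df = pd.DataFrame(values)
    df.index = [f"g{i}" for i in range(df.shape[0])]
    df.columns = [f"s{i}" for i in range(df.shape[1])]
    meta = pd.DataFrame(
        {
            "tissue": "seedling",
            "condition": conditions or ["none"] * df.shape[1],
            "replicate": range(df.shape[1]),
        },
        index=df.columns,
    )
    return ExpressionMatrix(df, meta)


def test_normalize_constant_matrix_gives_zeros():
    out = normalize_microarray(_matrix([[3.0, 3.0], [3.0, 3.0]]))
    assert np.allclose(out.to_numpy(), 0.0)


def test_normalize_grand_mean_example():
    out = normalize_microarray(_matrix([[1.0], [3.0]]))
    assert out.to_numpy().flatten() == pytest.approx([np.log2(0.5), np.log2(1.5)])


def test_normalize_zero_floor_and_conservation():
    out = normalize_microarray(_matrix([[0.0, 2.0], [4.0, 6.0]]))
    assert np.isfinite(out.to_numpy()).all()
    with pytest.raises(ValueError):
        normalize_microarray(_matrix([[0.0], [0.0]]))
    # conservation: grand mean of 2^values is 1 when no zeros
    clean = normalize_microarray(_matrix([[1.0, 2.0], [4.0, 9.0]]))
    assert (2.0 ** clean.to_numpy()).mean() == pytest.approx(1.0, abs=1e-9)


def test_cluster_identical_rows_merge_first():
    df = pd.DataFrame(
        [[1.0, 2.0, 3.0, 1.0], [1.0, 2.0, 3.0, 1.0], [3.0, 2.0, 1.0, 3.0]],
        index=["a", "b", "c"],
        columns=list("wxyz"),
    )
    linkage, order = cluster_genes(df)
    # first merge joins the identical pair at distance ~0
    assert set(linkage[0, :2].astype(int)) == {0, 1}
    assert linkage[0, 2] == pytest.approx(0.0, abs=1e-12)
    assert set(order) == {"a", "b", "c"}


def test_cluster_permutation_preserves_heights():
    rng = np.random.default_rng(0)
    df = pd.DataFrame(rng.normal(size=(6, 5)), index=list("abcdef"))
    z1, _ = cluster_genes(df)
    perm = [3, 1, 5, 0, 2, 4]
    z2, _ = cluster_genes(df.iloc[perm])
    assert np.allclose(sorted(z1[:, 2]), sorted(z2[:, 2]))


def test_cluster_zero_variance_gene_is_outcast():
    df = pd.DataFrame(
        [[1.0, 1.0, 1.0], [0.0, 1.0, 2.0], [0.1, 1.0, 2.1]],
        index=["flat", "a", "b"],
    )
    linkage, _ = cluster_genes(df)
    assert set(linkage[0, :2].astype(int)) == {1, 2}  # flat gene joins last


def test_stress_calls_null_duplicated_arms():
    rng = np.random.default_rng(2)
    base = rng.uniform(10, 100, size=(20, 2))
    values = np.hstack([base, base])  # condition arrays duplicate the controls
    m = _matrix(values, conditions=["control", "control", "salt", "salt"])
    calls = call_stress_de(m, "salt")
    assert all(c.call == "NONE" for c in calls)
    assert all(c.fold_change == pytest.approx(1.0) for c in calls)


def test_stress_call_gates():
    # planted 4-fold gene is UP; strong p with weak fold stays NONE
    rng = np.random.default_rng(3)
    n = 4
    ctrl = 50.0 * 2 ** rng.normal(0, 0.1, size=(2, n))
    cond = ctrl.copy()
    cond[0] *= 4.0   # fold gate + significance -> UP
    cond[1] *= 1.5   # significant but below the fold gate -> NONE
    m = _matrix(
        np.hstack([ctrl, cond]),
        conditions=["control"] * n + ["drought"] * n,
    )
    calls = {c.gene_id: c for c in call_stress_de(m, "drought")}
    assert calls["g0"].call == "UP"
    assert calls["g1"].call == "NONE" and calls["g1"].p_value < 0.05


def test_stress_requires_replicates():
    m = _matrix([[1.0, 2.0]], conditions=["control", "salt"])
    with pytest.raises(ValueError):
        call_stress_de(m, "salt")


def test_qpcr_standard_curve_closed_form():
    amounts = np.array([10.0, 30.0, 90.0, 270.0, 810.0, 2430.0])
    # perfect efficiency 2: Ct drops by log2(3) per 3-fold dilution step
    cts = 30.0 - np.log2(amounts / amounts[0])
    curve = qpcr_standard_curve(cts, amounts)
    assert curve.slope == pytest.approx(-np.log2(3) / np.log10(3), abs=1e-9)
    assert curve.r_squared == pytest.approx(1.0)


def test_qpcr_standard_curve_edge_cases():
    with pytest.raises(ValueError):
        qpcr_standard_curve([30.0, 29.0], [10.0, 30.0])
    with pytest.warns(UserWarning):
        curve = qpcr_standard_curve([25.0] * 6)
    assert curve.slope == 0.0 and np.isnan(curve.r_squared)


def _toy_plate(target_factor=8.0, ref_factor=2.0):
    slope, intercept = -np.log2(10.0) / 1.0, 34.0  # efficiency 2

    def ct(q):
        return intercept + slope * np.log10(q)

    rows = []
    for gene, q in [("tgt", 10.0 * target_factor)] + [
        (f"ref{i}", 10.0 * ref_factor) for i in range(1, 5)
    ]:
        for tech in (1, 2, 3):
            rows.append(
                {"gene": gene, "sample": "s1", "bio_rep": 1, "tech_rep": tech,
                 "ct": ct(q)}
            )
    dil = [
        {"gene": g, "amount": a, "ct": ct(a)}
        for g in ("tgt", "ref1", "ref2", "ref3", "ref4")
        for a in (10.0, 30.0, 90.0, 270.0, 810.0, 2430.0)
    ]
    return QpcrPlate(pd.DataFrame(rows), pd.DataFrame(dil))


def test_qpcr_relative_identity_and_ratio():
    refs = ["ref1", "ref2", "ref3", "ref4"]
    equal = qpcr_relative_expression(_toy_plate(1.0, 1.0), refs)
    assert equal["mean"].iloc[0] == pytest.approx(1.0)
    ratio = qpcr_relative_expression(_toy_plate(8.0, 2.0), refs)
    assert ratio["mean"].iloc[0] == pytest.approx(4.0)


def test_qpcr_missing_tech_rep_and_undetected_reference():
    plate = _toy_plate()
    plate.ct.loc[plate.ct["tech_rep"] == 3, "ct"] = np.nan  # drop one tech rep
    refs = ["ref1", "ref2", "ref3", "ref4"]
    out = qpcr_relative_expression(plate, refs)
    assert out["mean"].iloc[0] == pytest.approx(4.0)

    plate.ct.loc[plate.ct["gene"] == "ref1", "ct"] = np.nan  # reference lost
    out = qpcr_relative_expression(plate, refs)
    assert out.empty  # the only sample is flagged and excluded


def test_generator_qpcr_round_trip():
    matrix, est, mpss, plate, truth = gen_expression_data(ExprSpec(seed=8))
    curves = fit_standard_curves(plate)
    assert curves["ref1"].slope == pytest.approx(truth.slope, abs=1e-6)
    out = qpcr_relative_expression(plate, ["ref1", "ref2", "ref3", "ref4"], curves)
    got = out.pivot(index="gene", columns="sample", values="mean")
    want = truth.qpcr_relative.loc[got.index, got.columns]
    assert np.allclose(got.to_numpy(), want.to_numpy(), rtol=1e-9)


def test_generator_est_and_mpss_truth():
    matrix, est, mpss, plate, truth = gen_expression_data(ExprSpec(seed=8))
    for gene in est.index:
        assert est_specific_tissue(est.loc[gene].to_dict()) == truth.specific.get(gene)
    for gene in mpss.index:
        assert mpss_tier(float(mpss.loc[gene, "tpm"])) == truth.mpss_tiers[gene]


def test_est_coverage_percent():
    assert est_coverage_percent(38, 62) == pytest.approx(61.29, abs=0.005)
    with pytest.raises(ValueError):
        est_coverage_percent(1, 0)
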