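"""Differential-expression machinery tests: size factors, Wald GLM behavior,
TE contrast, classification rule and enrichment filter."""
import itertools

import numpy as np
import pandas as pd
import pytest

from ribolite.difftrans import (
    EnrichFilter,
    bh_adjust,
    classify_flags,
    classify_regulation,
    filter_enriched,
    nb_fit_test,
    size_factors,
    te_from_results,
    te_test,
)


def two_group_design(n=3, assay="riboseq", prefix="s"):
    rows = []
    for cond in "AB":
        for i in range(1, n + 1):
            rows.append({"sample_id": f"{prefix}_{cond}{i}", "assay": assay,
                         "condition": cond, "replicate": i})
    return pd.DataFrame(rows)


def nb_counts(rng, G, mean, disp, design, lfc=None):
    mu = np.full((G, len(design)), float(mean))
    if lfc is not None:
        mu[:, (design["condition"] == "B").to_numpy()] *= 2.0 ** np.asarray(lfc)[:, None]
    r = 1 / disp
    Y = rng.negative_binomial(r, r / (r + mu))
    return pd.DataFrame(Y, index=[f"g{i:04d}" for i in range(G)], columns=design["sample_id"])


# ---------------------------------------------------------------------------
# Size factors
# ---------------------------------------------------------------------------


def test_size_factors_identical_columns_are_unity():
    counts = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
    f = size_factors(counts)
    assert np.allclose(f, [1.0, 1.0])


def test_size_factors_doubled_column_ratio():
    counts = pd.DataFrame({"a": [10, 20, 30], "b": [20, 40, 60]})
    f = size_factors(counts)
    assert f["b"] / f["a"] == pytest.approx(2.0)
    assert np.prod(f) == pytest.approx(1.0)  # geometric mean 1


def test_size_factors_match_hand_computation():
    """3-gene x 2-sample fixture, median-of-ratios computed longhand."""
    counts = pd.DataFrame({"a": [100, 50, 8], "b": [200, 40, 16]})
    geo = np.sqrt(counts["a"] * counts["b"])
    ratios_a = np.sort(counts["a"] / geo)
    ratios_b = np.sort(counts["b"] / geo)
    expected_a, expected_b = ratios_a[1], ratios_b[1]
    norm = np.sqrt(expected_a * expected_b)
    f = size_factors(counts)
    assert f["a"] == pytest.approx(expected_a / norm)
    assert f["b"] == pytest.approx(expected_b / norm)


def test_size_factors_require_a_fully_positive_gene():
    counts = pd.DataFrame({"a": [0, 5], "b": [7, 0]})
    with pytest.raises(ValueError, match="pseudo-reference"):
        size_factors(counts)


def test_scaling_one_sample_moves_its_factor_and_not_log2fc(rng):
    design = two_group_design(3)
    counts = nb_counts(rng, 80, 150, 0.05, design)
    res = nb_fit_test(counts, design, "riboseq")
    scaled = counts.copy()
    scaled.iloc[:, 0] = scaled.iloc[:, 0] * 7
    f0 = size_factors(counts)
    f1 = size_factors(scaled)
    ratio = (f1 / f0).to_numpy()
    assert ratio[0] / ratio[1] == pytest.approx(7.0, rel=1e-9)
    res_scaled = nb_fit_test(scaled, design, "riboseq")
    assert np.allclose(res["log2fc"], res_scaled["log2fc"], atol=1e-6)


# ---------------------------------------------------------------------------
# BH oracle
# ---------------------------------------------------------------------------


def brute_force_bh(p):
    """Step-up procedure by direct enumeration."""
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def test_bh_matches_brute_force_step_up(rng):
    for n in range(1, 13):
        for _ in range(40):
            p = rng.random(n)
            assert np.allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)
    # padj is monotone in p and >= p
    p = rng.random(100)
    adj = bh_adjust(p)
    assert (adj >= p - 1e-15).all()
    order = np.argsort(p)
    assert (np.diff(adj[order]) >= -1e-15).all()


# ---------------------------------------------------------------------------
# NB Wald test
# ---------------------------------------------------------------------------


def test_gene_with_identical_counts_everywhere_is_exact_null(rng):
    design = two_group_design(3)
    counts = nb_counts(rng, 30, 100, 0.05, design)
    counts.iloc[0] = 123
    res = nb_fit_test(counts, design, "riboseq", factors=pd.Series(1.0, index=design["sample_id"]))
    assert res.iloc[0]["log2fc"] == 0.0
    assert res.iloc[0]["p"] == 1.0


def test_all_zero_gene_flagged_untestable(rng):
    design = two_group_design(3)
    counts = nb_counts(rng, 20, 100, 0.05, design)
    counts.iloc[3] = 0
    res = nb_fit_test(counts, design, "riboseq")
    row = res.iloc[3]
    assert row["untestable"] and row["log2fc"] == 0.0 and row["p"] == 1.0


def test_planted_effect_recovered_in_mean(rng):
    """200 genes with a planted 4-fold change, embedded sparsely in a null
    background so that median-of-ratios normalization stays valid."""
    design = two_group_design(3)
    lfc = np.zeros(4000)
    lfc[:200] = 2.0
    counts = nb_counts(rng, 4000, 200, 0.05, design, lfc=lfc)
    res = nb_fit_test(counts, design, "riboseq")
    assert abs(res["log2fc"][:200].mean() - 2.0) <= 0.15
    # affected genes overwhelmingly significant, background mostly not
    assert (res["padj"][:200] < 0.05).mean() > 0.9
    assert (res["p"][200:] < 0.05).mean() < 0.12


def test_design_validation_errors(rng):
    design = two_group_design(3)
    counts = nb_counts(rng, 10, 50, 0.05, design)
    with pytest.raises(ValueError, match="no samples"):
        nb_fit_test(counts, design, "rnaseq")
    lone = design.drop(index=[1, 2])  # condition A left with one replicate
    with pytest.raises(ValueError, match="replicates"):
        nb_fit_test(counts, lone, "riboseq")


# ---------------------------------------------------------------------------
# TE contrast
# ---------------------------------------------------------------------------


def full_design(n=3):
    return pd.concat(
        [two_group_design(n, "riboseq", "ribo"), two_group_design(n, "rnaseq", "rna")],
        ignore_index=True,
    )


def test_te_statistic_zero_for_identical_fits(rng):
    design = full_design()
    counts_r = nb_counts(rng, 20, 150, 0.05, design[design.assay == "riboseq"])
    counts = pd.concat(
        [counts_r, counts_r.set_axis(design[design.assay == "rnaseq"]["sample_id"], axis=1)],
        axis=1,
    )
    te = te_test(counts, design)
    assert np.allclose(te["delta_log2fc"], 0.0, atol=1e-9)
    assert np.allclose(te["p"], 1.0)


def test_te_null_when_both_assays_share_the_effect(rng):
    design = full_design()
    lfc = np.zeros(300)
    lfc[:60] = 1.5
    counts = pd.concat(
        [
            nb_counts(rng, 300, 200, 0.05, design[design.assay == a].reset_index(drop=True), lfc=lfc)
            .set_axis(design[design.assay == a]["sample_id"], axis=1)
            for a in ("riboseq", "rnaseq")
        ],
        axis=1,
    )
    te = te_test(counts, design)
    assert (te["p"] < 0.05).mean() < 0.12


def test_te_power_for_ribo_only_effect(rng):
    design = full_design()
    lfc_ribo = np.zeros(300)
    lfc_ribo[:60] = 2.0
    ribo = nb_counts(rng, 300, 200, 0.05, design[design.assay == "riboseq"].reset_index(drop=True), lfc=lfc_ribo)
    rna = nb_counts(rng, 300, 200, 0.05, design[design.assay == "rnaseq"].reset_index(drop=True))
    counts = pd.concat(
        [ribo.set_axis(design[design.assay == "riboseq"]["sample_id"], axis=1),
         rna.set_axis(design[design.assay == "rnaseq"]["sample_id"], axis=1)],
        axis=1,
    )
    te = te_test(counts, design)
    assert (te["padj"][:60] < 0.05).mean() >= 0.9


def test_te_requires_both_assays(rng):
    design = two_group_design(3)
    counts = nb_counts(rng, 10, 50, 0.05, design)
    with pytest.raises(ValueError, match="rnaseq"):
        te_test(counts, design)


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "ribo_sig,rna_sig,te_sig,signs,expected",
    [
        (True, True, False, (1, 1), "transcription"),
        (True, False, True, (1, 0), "translation"),
        (False, True, True, (0, 1), "buffering"),
        (True, True, True, (1, 1), "concordant"),
        (True, True, True, (-1, -1), "concordant"),
        (True, True, True, (1, -1), "none"),
        (False, False, False, (0, 0), "none"),
        (False, False, True, (0, 0), "none"),
        (True, False, False, (1, 0), "none"),
    ],
)
def test_classification_rule(ribo_sig, rna_sig, te_sig, signs, expected):
    assert classify_flags(ribo_sig, rna_sig, te_sig, *signs) == expected


def test_classify_regulation_table():
    def de(gene, lfc, padj, assay):
        return {"gene_id": gene, "assay": assay, "log2fc": lfc, "se": 0.1,
                "p": padj, "padj": padj, "untestable": False}

    ribo = pd.DataFrame([de("g1", 2.0, 1e-4, "riboseq"), de("g2", 1.0, 0.5, "riboseq")])
    rna = pd.DataFrame([de("g1", 1.0, 1e-3, "rnaseq"), de("g2", 0.1, 0.9, "rnaseq")])
    te = pd.DataFrame([
        {"gene_id": "g1", "delta_log2fc": 1.0, "se": 0.1, "p": 1e-3, "padj": 1e-3, "untestable": False},
        {"gene_id": "g2", "delta_log2fc": 0.9, "se": 0.5, "p": 0.4, "padj": 0.6, "untestable": False},
    ])
    out = classify_regulation(ribo, rna, te, alpha=0.05)
    assert list(out["class"]) == ["concordant", "none"]
    assert list(out["color"]) == ["violet", "grey"]
    with pytest.raises(ValueError, match="different gene sets"):
        classify_regulation(ribo, rna.iloc[:1], te)


# ---------------------------------------------------------------------------
# Enrichment filter
# ---------------------------------------------------------------------------


def test_filter_enriched_strict_inequalities():
    res = pd.DataFrame(
        {
            "gene_id": ["boundary_fc", "passes", "boundary_p"],
            "log2fc": [2.0, 2.1, 3.0],
            "padj": [1e-200, 1e-200, 1e-150],
        }
    )
    out = filter_enriched(res, EnrichFilter(min_fold_change=4.0, max_padj=1e-150, direction="up"))
    assert out == {"passes"}


def test_filter_enriched_directions():
    res = pd.DataFrame(
        {"gene_id": ["up", "down"], "log2fc": [3.0, -3.0], "padj": [1e-10, 1e-10]}
    )
    filt = lambda d: EnrichFilter(min_fold_change=4.0, max_padj=1e-5, direction=d)
    assert filter_enriched(res, filt("up")) == {"up"}
    assert filter_enriched(res, filt("down")) == {"down"}
    assert filter_enriched(res, filt("both")) == {"up", "down"}


def test_enrich_filter_validation():
    with pytest.raises(ValueError):
        EnrichFilter(min_fold_change=0.5)
    with pytest.raises(ValueError):
        EnrichFilter(max_padj=0.0)
    with pytest.raises(ValueError):
        EnrichFilter(direction="sideways")
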