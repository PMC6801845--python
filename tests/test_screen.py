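"""Five-step screen: step logic, conversion arithmetic, funnel, recovery."""

import numpy as np
import pandas as pd
import pytest

import gravscreen as gs
from gravscreen.design import build_design
from gravscreen.screen import (
    ScreenConfig,
    relative_expression,
    step1_panel_filter,
    step2_expression_filter,
    step5_convert_and_classify,
)


def _toy_normalized():
    """Two genes x 36 samples with exact condition-wise values."""
    design = build_design()
    vals = {}
    for row in design.itertuples(index=False):
        base = {
            "ST": 2000.0, "RO": 1000.0,
            "ST-C3": 3200.0, "RO-C3": 800.0,
        }.get(row.condition, 500.0)
        vals[row.sample_id] = [base, 100.0]
    norm = pd.DataFrame(vals, index=pd.Index(["gA", "gB"], name="gene_id"))
    return norm, design


def test_step1_intersects_detected_panel(default_fixture):
    counts, design, truth, _ = default_fixture
    panel = truth.index[truth["in_panel"]].tolist()
    kept = step1_panel_filter(counts, panel)
    assert len(kept) == 82
    assert set(kept) <= set(panel)


def test_step1_disjoint_panel_warns_empty(default_fixture):
    counts, *_ = default_fixture
    with pytest.warns(UserWarning):
        assert step1_panel_filter(counts, ["NOT_A_GENE"]) == []


def test_step1_full_panel_when_all_detected():
    counts = pd.DataFrame({"s0": [5, 1], "s1": [2, 3]}, index=["a", "b"])
    assert step1_panel_filter(counts, ["a", "b"]) == ["a", "b"]


def test_step2_boundary():
    norm = pd.DataFrame(
        {"s0": [1500.0, 999.9, 1000.0], "s1": [10.0, 20.0, 30.0]},
        index=["hi", "lo", "edge"],
    )
    kept = step2_expression_filter(norm, ["s0", "s1"], threshold=1000.0)
    assert kept == ["hi", "edge"]  # >= threshold retained, 999.9 dropped


def test_step2_planted_high_genes(default_fixture, normalized_fixture):
    counts, design, truth, _ = default_fixture
    norm, *_ = normalized_fixture
    standing = design.loc[design["gravity"] == "ST", "sample_id"].tolist()
    panel = step1_panel_filter(counts, truth.index[truth["in_panel"]].tolist())
    kept = step2_expression_filter(norm, standing, threshold=1000.0, genes=panel)
    assert len(kept) == 13


def test_step5_arithmetic_from_definition():
    """ST 2000 / RO 1000 -> r=2; converted RO-C3 = 1600; adjusted fc 0.5."""
    norm, design = _toy_normalized()
    out = step5_convert_and_classify(norm, design, ["gA"])
    row = out.loc["gA"]
    assert row["ratio_r"] == pytest.approx(2.0)
    assert row["converted_C3"] == pytest.approx(1600.0)
    assert row["adjusted_fc_C3"] == pytest.approx(0.5)
    assert row["class_C3"] == "enhanced_decrease"


def test_step5_identity_when_r_one_and_equal_means():
    norm, design = _toy_normalized()
    out = step5_convert_and_classify(norm, design, ["gB"])  # flat gene
    row = out.loc["gB"]
    assert row["ratio_r"] == pytest.approx(1.0)
    for arm in ("X3", "X24", "C3", "C24"):
        assert row[f"adjusted_fc_{arm}"] == pytest.approx(1.0)
        assert row[f"class_{arm}"] == "none"


def test_step5_conversion_consistency():
    """With r = 1 the adjusted fold change equals the plain RO/ST ratio."""
    design = build_design()
    rng = np.random.default_rng(8)
    vals = {
        row.sample_id: [1000.0 * (1.5 if row.condition == "RO-X24" else 1.0)]
        for row in design.itertuples(index=False)
    }
    norm = pd.DataFrame(vals, index=pd.Index(["g"], name="gene_id"))
    out = step5_convert_and_classify(norm, design, ["g"])
    assert out.loc["g", "adjusted_fc_X24"] == pytest.approx(1.5)
    assert out.loc["g", "class_X24"] == "enhanced_increase"


def test_step5_zero_ro_mean_unclassifiable():
    norm, design = _toy_normalized()
    norm.loc["gA", design.loc[design["condition"] == "RO", "sample_id"]] = 0.0
    out = step5_convert_and_classify(norm, design, ["gA"])
    assert bool(out.loc["gA", "unclassifiable"])


def test_funnel_monotonicity(screen_result):
    s = screen_result.step_sets
    entered = set(s["step3_pass"]) | set(s["step4_pass"])
    assert set(s["step2"]) <= set(s["step1"])
    assert entered <= set(s["step2"])
    assert set(s["selected"]) <= entered


def test_no_microgravity_effect_genes_fail_step4(screen_result, default_fixture):
    """The four high-expression genes without any gravity sensitivity
    (modeled on ATM/CDC20/CDK6/TFDP1) do not pass the microgravity-alone
    comparison on the default fixture."""
    _, _, truth, _ = default_fixture
    rec = screen_result.records.set_index("gene_id")
    four = ["ATM", "CDC20", "CDK6", "TFDP1"]
    step4 = rec.loc[four, "step4_pass"]
    assert not step4.fillna(False).any()


def test_recovery_on_default_fixture(screen_result, default_fixture):
    _, _, truth, _ = default_fixture
    truth_syn = set(truth.index[truth["synergy_class_truth"] != "none"])
    sel = set(screen_result.selected)
    assert len(sel & truth_syn) >= 8
    rec = screen_result.records.set_index("gene_id")
    correct = sum(
        rec.loc[g, "synergy_class"] == truth.loc[g, "synergy_class_truth"]
        for g in sel & truth_syn
    )
    assert correct >= 8


def test_screen_scale_invariance(default_fixture, normalized_fixture):
    """A global rescaling of the normalized matrix leaves r, adjusted fold
    changes, classes and relative expression unchanged."""
    counts, design, truth, _ = default_fixture
    norm, *_ = normalized_fixture
    genes = truth.index[truth["synergy_class_truth"] != "none"].tolist()
    a = step5_convert_and_classify(norm, design, genes)
    b = step5_convert_and_classify(norm * 7.5, design, genes)
    for arm in ("X3", "C24"):
        np.testing.assert_allclose(a[f"adjusted_fc_{arm}"], b[f"adjusted_fc_{arm}"])
        assert (a[f"class_{arm}"] == b[f"class_{arm}"]).all()
    ra = relative_expression(norm, design, genes)
    rb = relative_expression(norm * 7.5, design, genes)
    rel_cols = [c for c in ra.columns if c.startswith("rel_")]
    np.testing.assert_allclose(ra[rel_cols], rb[rel_cols], rtol=1e-12)


def test_relative_expression_identities(default_fixture, normalized_fixture):
    counts, design, truth, _ = default_fixture
    norm, *_ = normalized_fixture
    genes = truth.index[truth["synergy_class_truth"] != "none"].tolist()
    rel = relative_expression(norm, design, genes)
    rel_cols = [c for c in rel.columns if c.startswith("rel_")]
    # per-gene max over condition means is exactly 1
    assert np.allclose(rel[rel_cols].max(axis=1), 1.0)
    se_cols = [c for c in rel.columns if c.startswith("se_")]
    assert (rel[se_cols] >= 0).all().all()


def test_relative_expression_all_equal_conditions():
    norm, design = _toy_normalized()
    rel = relative_expression(norm, design, ["gB"])
    rel_cols = [c for c in rel.columns if c.startswith("rel_")]
    assert np.allclose(rel.loc["gB", rel_cols].astype(float), 1.0)


def test_relative_expression_direction_calls(
    default_fixture, normalized_fixture
):
    """Planted enhanced-increase genes show a significant upward call for
    RO-C3 relative to ST-C3."""
    counts, design, truth, _ = default_fixture
    norm, factors, lib, phi = normalized_fixture
    genes = truth.index[truth["synergy_class_truth"] == "enhanced_increase"].tolist()
    rel = relative_expression(
        norm, design, genes, counts=counts, phi=phi,
        pairs=[("ST-C3", "RO-C3")], lib_sizes=lib,
    )
    assert (rel["dir_RO-C3_vs_ST-C3"] == "up").mean() >= 0.8
    assert (rel["rel_RO-C3"] > rel["rel_ST-C3"]).all()


def test_screen_config_validation():
    with pytest.raises(ValueError):
        ScreenConfig(alpha=1.5)
    with pytest.raises(ValueError):
        ScreenConfig(step2_threshold=-1)
    with pytest.raises(ValueError):
        ScreenConfig(step2_scope="everything")
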