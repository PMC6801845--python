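"""Exact NB test and dispersion estimation: oracles, limits, properties."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import gravscreen as gs
from gravscreen.detest import (
    Contrast,
    equalize_library_sizes,
    estimate_common_dispersion,
    exact_nb_test,
    run_contrast,
)

from conftest import nb_counts


def enumeration_p(sum_a, sum_b, n_a, n_b, phi):
    """Independent brute-force oracle: full enumeration of the conditional
    split using plain pmf products (no log-space, no truncation)."""
    s = int(sum_a) + int(sum_b)
    if s == 0:
        return 1.0
    k = np.arange(s + 1)
    if phi == 0:
        lam = 7.3  # arbitrary: cancels in the conditional ratio
        joint = stats.poisson(n_a * lam).pmf(k) * stats.poisson(n_b * lam).pmf(s - k)
    else:
        p = 0.37  # arbitrary shared NB success probability: cancels
        joint = stats.nbinom(n_a / phi, p).pmf(k) * stats.nbinom(n_b / phi, p).pmf(s - k)
    obs = joint[int(sum_a)]
    return float(joint[joint <= obs * (1 + 1e-12)].sum() / joint.sum())


def test_equal_split_equal_sizes_p_is_one():
    assert exact_nb_test(10, 10, 3, 3, phi=0.1) == 1.0
    assert exact_nb_test(0, 0, 3, 3, phi=0.2) == 1.0  # untestable convention


@pytest.mark.parametrize("phi", [0.0, 0.1, 0.5])
@pytest.mark.parametrize("n_a,n_b", [(1, 1), (3, 3), (2, 5), (6, 4)])
def test_matches_enumeration_oracle(phi, n_a, n_b):
    for s in (1, 7, 23, 50):
        for sum_a in range(0, s + 1, max(1, s // 5)):
            ours = exact_nb_test(sum_a, s - sum_a, n_a, n_b, phi=phi)
            oracle = enumeration_p(sum_a, s - sum_a, n_a, n_b, phi)
            assert ours == pytest.approx(oracle, abs=1e-9)


def test_poisson_limit_is_binomial_test():
    """phi -> 0: the conditional split is binomial with p = n_a/(n_a+n_b)."""
    s, k, n_a, n_b = 40, 9, 2, 3
    expected = stats.binomtest(k, s, n_a / (n_a + n_b)).pvalue
    assert exact_nb_test(k, s - k, n_a, n_b, phi=0.0) == pytest.approx(expected, rel=1e-12)
    # and small phi converges to it
    small = exact_nb_test(k, s - k, n_a, n_b, phi=1e-8)
    assert small == pytest.approx(expected, rel=1e-4)


def test_truncated_path_matches_full_enumeration():
    """Large totals trigger support truncation; the excluded mass must be
    irrelevant at 1e-9."""
    sum_a, sum_b = 12000, 13500
    ours = exact_nb_test(sum_a, sum_b, 3, 3, phi=0.1)
    s = sum_a + sum_b
    k = np.arange(s + 1)
    logp = stats.betabinom(s, 3 / 0.1, 3 / 0.1).logpmf(k)
    obs = logp[sum_a]
    full = np.exp(logp[logp <= obs + 1e-10]).sum() / np.exp(logp).sum()
    assert ours == pytest.approx(full, abs=1e-9)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    s=st.integers(1, 60),
    k=st.integers(0, 60),
    n_a=st.integers(1, 6),
    n_b=st.integers(1, 6),
    phi=st.sampled_from([0.0, 0.05, 0.3, 1.0]),
)
def test_group_swap_symmetry(s, k, n_a, n_b, phi):
    k = min(k, s)
    p_ab = exact_nb_test(k, s - k, n_a, n_b, phi=phi)
    p_ba = exact_nb_test(s - k, k, n_b, n_a, phi=phi)
    assert p_ab == pytest.approx(p_ba, rel=1e-9)
    assert 0.0 <= p_ab <= 1.0


@pytest.mark.parametrize("phi", [0.0, 0.1, 0.5])
@pytest.mark.parametrize("n_a,n_b", [(3, 3), (6, 6)])
def test_balanced_monotonicity(phi, n_a, n_b):
    """With equal group sizes, p is non-increasing as the split moves away
    from balance."""
    s = 40
    ps = [exact_nb_test(k, s - k, n_a, n_b, phi=phi) for k in range(s // 2, s + 1)]
    assert all(a >= b - 1e-12 for a, b in zip(ps, ps[1:]))


@pytest.mark.parametrize("n_a,n_b,phi", [(2, 5, 0.1), (4, 3, 0.5)])
def test_unbalanced_p_is_unimodal(n_a, n_b, phi):
    s = 30
    ps = np.array([exact_nb_test(k, s - k, n_a, n_b, phi=phi) for k in range(s + 1)])
    peak = int(np.argmax(ps))
    assert all(ps[i] <= ps[i + 1] + 1e-12 for i in range(peak))
    assert all(ps[i] >= ps[i + 1] - 1e-12 for i in range(peak, s))


def test_agrees_with_edger_exact_test(tmp_path):
    """Independent oracle: edgeR's classic exact test (smallp rejection
    region) on a small matrix with a fixed common dispersion."""
    if shutil.which("Rscript") is None:
        pytest.fail("Rscript not available: edgeR oracle cannot run")
    rng = np.random.default_rng(11)
    mu = np.array([20, 50, 100, 300, 800, 40, 60, 5, 1000, 150], dtype=float)
    phi = 0.15
    y = nb_counts(rng, mu, phi, 6)
    y[3, 3:] *= 3
    counts = pd.DataFrame(
        y, index=[f"g{i}" for i in range(10)], columns=[f"s{j}" for j in range(6)]
    )
    counts_path = tmp_path / "counts.tsv"
    counts.to_csv(counts_path, sep="\t")
    script = tmp_path / "oracle.R"
    script.write_text(
        "suppressMessages(library(edgeR))\n"
        "args <- commandArgs(trailingOnly=TRUE)\n"
        "counts <- as.matrix(read.delim(args[1], row.names=1))\n"
        "d <- DGEList(counts=counts, group=factor(rep(c('a','b'), each=3)))\n"
        f"et <- exactTest(d, dispersion={phi}, rejection.region='smallp')\n"
        "write.table(data.frame(gene=rownames(et$table), p=et$table$PValue),\n"
        "            args[2], sep='\\t', quote=FALSE, row.names=FALSE)\n"
    )
    out = tmp_path / "p.tsv"
    subprocess.run(
        ["Rscript", str(script), str(counts_path), str(out)],
        check=True,
        capture_output=True,
    )
    edger = pd.read_csv(out, sep="\t", index_col=0)["p"]
    pseudo, _ = equalize_library_sizes(counts, phi)
    ours = pd.Series(
        [
            exact_nb_test(a, b, 3, 3, phi=phi)
            for a, b in zip(pseudo.iloc[:, :3].sum(axis=1), pseudo.iloc[:, 3:].sum(axis=1))
        ],
        index=counts.index,
    )
    # pseudo-count rounding may differ by one unit between implementations
    assert np.abs(np.log(ours / edger)).max() < 0.05


def test_constant_identical_columns_phi_zero():
    counts = pd.DataFrame(np.full((50, 6), 40), columns=[f"s{i}" for i in range(6)])
    groups = pd.Series(["a"] * 3 + ["b"] * 3, index=counts.columns)
    est = estimate_common_dispersion(counts, groups)
    assert est.phi == 0.0


def test_poisson_data_low_phi():
    rng = np.random.default_rng(2)
    mu = 100 * np.exp(rng.normal(0, 1, 2000))
    counts = pd.DataFrame(nb_counts(rng, mu, 0.0, 6), columns=[f"s{i}" for i in range(6)])
    groups = pd.Series(["a"] * 3 + ["b"] * 3, index=counts.columns)
    est = estimate_common_dispersion(counts, groups)
    assert est.phi < 0.02


def test_dispersion_recovery():
    rng = np.random.default_rng(3)
    mu = 150 * np.exp(rng.normal(0, 1, 2000))
    counts = pd.DataFrame(nb_counts(rng, mu, 0.2, 12), columns=[f"s{i}" for i in range(12)])
    groups = pd.Series(["a"] * 6 + ["b"] * 6, index=counts.columns)
    est = estimate_common_dispersion(counts, groups)
    assert est.phi == pytest.approx(0.2, rel=0.25)


def test_single_replicate_everywhere_rejected():
    counts = pd.DataFrame({"a": [1, 2], "b": [3, 4]})
    groups = pd.Series(["g1", "g2"], index=["a", "b"])
    with pytest.raises(ValueError, match="supply phi"):
        estimate_common_dispersion(counts, groups)


def test_run_contrast_fields_and_null_fc():
    rng = np.random.default_rng(4)
    mu = np.full(50, 200.0)
    y = nb_counts(rng, mu, 0.05, 6)
    counts = pd.DataFrame(y, columns=[f"s{i}" for i in range(6)])
    norm = counts / counts.sum() * 1e6
    contrast = Contrast("t", ("s0", "s1", "s2"), ("s3", "s4", "s5"))
    table = run_contrast(counts, norm, contrast, phi=0.05)
    assert set(
        ["gene_id", "mean_a", "mean_b", "fold_change", "log2_fc", "p_value", "significant"]
    ) <= set(table.columns)
    assert table["p_value"].between(0, 1).all()
    # equal means => log2 fc = 0 exactly
    norm_eq = norm.copy()
    norm_eq[:] = 100.0
    table_eq = run_contrast(counts, norm_eq, contrast, phi=0.05)
    assert (table_eq["log2_fc"] == 0).all()
    assert not table_eq["significant"].any()


def test_contrast_validation():
    with pytest.raises(ValueError, match="overlap"):
        Contrast("bad", ("a", "b"), ("b", "c"))
    with pytest.raises(ValueError, match="nonempty"):
        Contrast("bad", (), ("a",))


def test_run_contrast_bh_flag():
    rng = np.random.default_rng(5)
    counts = pd.DataFrame(nb_counts(rng, np.full(20, 100.0), 0.1, 6),
                          columns=[f"s{i}" for i in range(6)])
    norm = counts / counts.sum() * 1e6
    contrast = Contrast("t", ("s0", "s1", "s2"), ("s3", "s4", "s5"))
    table = run_contrast(counts, norm, contrast, phi=0.1, bh=True)
    assert "fdr" in table.columns
    assert (table["fdr"] >= table["p_value"] - 1e-12).all()
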