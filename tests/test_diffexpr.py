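"""Moderated-t differential expression, CPM normalization and BH adjustment."""

import subprocess
import sys

import numpy as np
import pandas as pd
import pytest

from brmmode.diffexpr import (
    bh_adjust,
    call_de,
    cpm_normalize,
    estimate_variance_prior,
    moderated_test,
    run_contrast,
)
from tests.conftest import make_count_matrix


def test_cpm_definition():
    counts = np.zeros((3, 2), dtype=int)
    counts[0, 0] = 100
    counts[1, 0] = 1_000_000 - 100
    counts[:, 1] = [10, 10, 10]
    cm = make_count_matrix(counts, ["control", "dsBRM"])
    cpm, logcpm = cpm_normalize(cm)
    assert cpm.iloc[0, 0] == pytest.approx(100.0)
    assert logcpm.iloc[0, 0] == pytest.approx(np.log2(100.5))


def test_cpm_scale_invariance_and_toy_oracle():
    counts = np.array([[10, 1], [30, 2], [60, 7]])
    cm = make_count_matrix(counts, ["control", "dsBRM"])
    cpm, _ = cpm_normalize(cm)
    # brute-force: column sums 100 and 10
    np.testing.assert_allclose(cpm.to_numpy()[:, 0], [1e5, 3e5, 6e5])
    np.testing.assert_allclose(cpm.to_numpy()[:, 1], [1e5, 2e5, 7e5])
    cm2 = make_count_matrix(counts * np.array([2, 1]), ["control", "dsBRM"])
    np.testing.assert_allclose(cpm_normalize(cm2)[0].to_numpy(), cpm.to_numpy())


def test_cpm_all_zero_sample_errors():
    counts = np.array([[1, 0], [2, 0]])
    cm = make_count_matrix(counts, ["control", "dsBRM"])
    with pytest.raises(ValueError, match="all-zero"):
        cpm_normalize(cm)


def _toy_logcpm(seed=0, n=200):
    rng = np.random.default_rng(seed)
    mat = rng.normal(5, 1, (n, 6)) * rng.gamma(3, 0.4, (n, 1))
    return pd.DataFrame(
        mat, index=[f"g{i}" for i in range(n)], columns=[f"s{j}" for j in range(6)]
    )


def test_constant_gene_has_zero_statistic():
    logcpm = _toy_logcpm()
    logcpm.iloc[0, :] = 7.0
    res = moderated_test(logcpm, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
    assert res["t"].iloc[0] == 0.0
    assert res["p"].iloc[0] == 1.0


def test_infinite_prior_df_limit_gives_common_variance_z():
    """Forced d0 -> inf: identical within-group scatter for every gene drives the
    log-variance spread to zero, and every gene shares the prior variance."""
    n = 50
    rows = []
    for g in range(n):
        rows.append([0.0, 1.0, 2.0, g + 0.0, g + 1.0, g + 2.0])
    logcpm = pd.DataFrame(rows, columns=[f"s{j}" for j in range(6)])
    res = moderated_test(logcpm, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
    assert np.isinf(res["df"].iloc[0])
    assert res["s2_post"].nunique() == 1
    # z-like statistic: mean difference over the common s0 * sqrt(2/3)
    s0 = res["s2_post"].iloc[0]
    expected_t = 5.0 / np.sqrt(s0 * (2 / 3))  # gene 5: means 6 vs 1
    assert res["t"].iloc[5] == pytest.approx(expected_t)


def test_group_swap_negates_statistics():
    logcpm = _toy_logcpm(1)
    a, b = ["s0", "s1", "s2"], ["s3", "s4", "s5"]
    r1 = moderated_test(logcpm, a, b)
    r2 = moderated_test(logcpm, b, a)
    np.testing.assert_allclose(r1["log2fc"], -r2["log2fc"])
    np.testing.assert_allclose(r1["t"], -r2["t"])
    np.testing.assert_allclose(r1["p"], r2["p"])


def test_within_group_permutation_invariance():
    logcpm = _toy_logcpm(2)
    r1 = moderated_test(logcpm, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
    r2 = moderated_test(logcpm, ["s2", "s0", "s1"], ["s5", "s3", "s4"])
    np.testing.assert_allclose(r1["t"], r2["t"])
    np.testing.assert_allclose(r1["p"], r2["p"])


def test_moderated_t_matches_limma_ebayes(tmp_path):
    """Independent oracle: limma's eBayes on the same matrix (via Rscript)."""
    logcpm = _toy_logcpm(5, n=300)
    logcpm.to_csv(tmp_path / "logcpm.tsv", sep="\t")
    script = tmp_path / "limma.R"
    script.write_text(
        'suppressMessages(library(limma))\n'
        'm <- as.matrix(read.table("logcpm.tsv", header=TRUE, row.names=1, sep="\\t"))\n'
        "design <- model.matrix(~ factor(c(0,0,0,1,1,1)))\n"
        "fit <- eBayes(lmFit(m, design))\n"
        'out <- data.frame(t=fit$t[,2], p=fit$p.value[,2], d0=fit$df.prior)\n'
        'write.table(out, "limma_out.tsv", sep="\\t", quote=FALSE)\n'
    )
    subprocess.run(["Rscript", "limma.R"], cwd=tmp_path, check=True, capture_output=True)
    ref = pd.read_csv(tmp_path / "limma_out.tsv", sep="\t")
    mine = moderated_test(logcpm, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
    np.testing.assert_allclose(mine["t"].to_numpy(), ref["t"].to_numpy(), atol=1e-8)
    np.testing.assert_allclose(mine["p"].to_numpy(), ref["p"].to_numpy(), atol=1e-8)
    assert mine["df"].iloc[0] - 4 == pytest.approx(ref["d0"].iloc[0])


def test_prior_estimation_consistency():
    """Moment-matching recovers a known (s0^2, d0) prior within 10% at 5000 genes."""
    rng = np.random.default_rng(7)
    n, d, d0_true, s0_true = 5000, 4, 6.0, 0.8
    sigma2 = d0_true * s0_true / rng.chisquare(d0_true, n)
    s2 = sigma2 * rng.chisquare(d, n) / d
    s0_hat, d0_hat = estimate_variance_prior(s2, d)
    assert s0_hat == pytest.approx(s0_true, rel=0.10)
    assert d0_hat == pytest.approx(d0_true, rel=0.10)


def test_prior_estimation_error_guidance():
    with pytest.raises(ValueError, match="variance prior"):
        estimate_variance_prior(np.zeros(10), 4)


def test_bh_step_up_brute_force_example():
    q = bh_adjust([0.01, 0.02, 0.03, 0.04])
    np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])
    assert bh_adjust([0.2]).tolist() == [0.2]


def test_bh_matches_brute_force_definition_and_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(11)
    p = rng.uniform(size=97)

    def brute(pv):
        m = len(pv)
        order = np.argsort(pv)
        q = np.empty(m)
        for rank_pos, idx in enumerate(order):
            j_ge = [pv[order[jj]] * m / (jj + 1) for jj in range(rank_pos, m)]
            q[idx] = min(1.0, min(j_ge))
        return q

    q = bh_adjust(p)
    np.testing.assert_allclose(q, brute(p))
    np.testing.assert_allclose(q, multipletests(p, method="fdr_bh")[1])


def test_bh_preserves_ranking_and_validates_input():
    rng = np.random.default_rng(12)
    p = rng.uniform(size=50)
    q = bh_adjust(p)
    # monotone transform: q ordered by p never decreases (ties allowed)
    assert np.all(np.diff(q[np.argsort(p)]) >= 0)
    with pytest.raises(ValueError, match=r"\[0, 1\]"):
        bh_adjust([0.5, 1.5])


def test_call_de_threshold_strict():
    res = pd.DataFrame({"log2fc": [1.0, -1.0], "p": [0.01, 0.02]})
    out = call_de(res, q_threshold=0.05)
    # q = (0.02, 0.02): both strictly below 0.05
    assert out["significant"].all()
    res2 = pd.DataFrame({"log2fc": [1.0], "p": [0.05]})
    out2 = call_de(res2, q_threshold=0.05)
    assert not out2["significant"].iloc[0] and out2["direction"].iloc[0] == "none"


def test_run_contrast_drops_all_zero_genes(small_study):
    from brmmode.genome_model import CountMatrix

    counts = CountMatrix(
        counts=small_study.counts.counts.copy(), samples=small_study.counts.samples
    )
    counts.counts.iloc[0, :] = 0
    res = run_contrast(counts, "dsBRM_WT")
    assert counts.counts.index[0] not in res.index
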