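"""Empirical-Bayes moderated two-group differential expression on counts.

The test statistic is a moderated t: per-gene pooled variances of log2-CPM are
shrunk toward an inverse-gamma prior whose parameters (s0^2, d0) are estimated
by moment-matching the distribution of log sample variances via trigamma
inversion. The moderated statistic is referred to a Student t distribution
with d0 + d_g degrees of freedom. Multiple testing is controlled with the
Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats

from .genome_model import CountMatrix

__all__ = [
    "cpm_normalize",
    "estimate_variance_prior",
    "moderated_test",
    "bh_adjust",
    "call_de",
    "run_contrast",
]


def cpm_normalize(cm: CountMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Counts-per-million and log2(CPM + 0.5) matrices.

    CPM_gs = counts_gs / libsize_s * 1e6. Raises if any library is empty.
    """
    libsize = cm.counts.sum(axis=0)
    if (libsize == 0).any():
        empty = list(libsize.index[libsize == 0])
        raise ValueError(f"all-zero sample(s): {empty}")
    cpm = cm.counts / libsize * 1e6
    logcpm = np.log2(cpm + 0.5)
    return cpm, logcpm


def estimate_variance_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Moment-match (s0^2, d0) to observed log sample variances.

    With s^2_g ~ s_g0^2 * chi^2_d / d, e_g = log s^2_g - digamma(d/2) + log(d/2)
    has mean log s0^2 + digamma(d0/2) - log(d0/2) and variance
    trigamma(d/2) + trigamma(d0/2); d0 follows by inverting the trigamma
    function on the excess variance of e_g. Returns (s0^2, d0) with
    d0 = inf when the observed spread is at or below the chi-square floor
    (all genes then share one variance).
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if s2.size == 0:
        raise ValueError(
            "no gene has positive within-group variance; the variance prior "
            "cannot be estimated (check for constant or duplicated samples)"
        )
    e = np.log(s2) - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) if e.size > 1 else 0.0
    excess = evar - float(special.polygamma(1, df / 2.0))
    if excess <= 1e-8:
        return float(np.exp(emean)), np.inf
    half_d0 = _trigamma_inverse(excess)
    d0 = 2.0 * half_d0
    s0_sq = float(np.exp(emean + special.digamma(half_d0) - np.log(half_d0)))
    return s0_sq, d0


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on the reciprocal scale)."""
    if y <= 0:
        raise ValueError("trigamma inverse requires y > 0")
    x = 0.5 + 1.0 / y  # good starting value: trigamma(x) ~ 1/x + 1/(2x^2)
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def moderated_test(
    logcpm: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
) -> pd.DataFrame:
    """Moderated t test of group B vs group A per gene.

    Returns a DataFrame indexed by gene with columns log2fc (mean B - mean A),
    t, df, p, s2 (raw pooled variance) and s2_post (moderated variance).
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need >= 2 samples per group")
    a = logcpm[group_a].to_numpy()
    b = logcpm[group_b].to_numpy()
    na, nb = a.shape[1], b.shape[1]
    d = na + nb - 2
    ssa = ((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ssb = ((b - b.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    s2 = (ssa + ssb) / d
    s0_sq, d0 = estimate_variance_prior(s2, d)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + d * s2) / (d0 + d)
        df_total = d0 + d
    log2fc = b.mean(axis=1) - a.mean(axis=1)
    se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, log2fc / se, 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "t": t,
            "df": df_total,
            "p": p,
            "s2": s2,
            "s2_post": s2_post,
        },
        index=logcpm.index,
    )


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} p_(j) * m / j, clipped to 1, in the input order.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-d vector")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def call_de(result: pd.DataFrame, q_threshold: float = 0.05) -> pd.DataFrame:
    """Attach q, significance (q < threshold, strict) and direction flags."""
    out = result.copy()
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["q"] < q_threshold
    out["direction"] = np.where(
        out["significant"], np.where(out["log2fc"] > 0, "up", "down"), "none"
    )
    return out


def run_contrast(
    cm: CountMatrix,
    condition: str,
    control: str = "control",
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Full DE pipeline for one condition-vs-control contrast.

    Genes with zero counts in every sample of the contrast are dropped before
    prior estimation (they carry no information and would distort it).
    """
    group_a = cm.samples_for(control)
    group_b = cm.samples_for(condition)
    if not group_b:
        raise ValueError(f"no samples for condition {condition!r}")
    sub = cm.counts[group_a + group_b]
    keep = sub.sum(axis=1) > 0
    cm_sub = CountMatrix(
        counts=sub.loc[keep], samples=cm.samples.loc[group_a + group_b]
    )
    _, logcpm = cpm_normalize(cm_sub)
    res = moderated_test(logcpm, group_a, group_b)
    return call_de(res, q_threshold=q_threshold)
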