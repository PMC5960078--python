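"""Scaled gene-body metagene profiles with fixed flanks, and K-S comparisons.

Each gene body is rescaled to B bins (near-equal bp, remainder spread over the
leading bins); fixed-width 5' and 3' flanks contribute F bins each, so every
gene maps onto a common axis of 2F + B bins running 5'->3' of the gene.
Group profiles are averaged after a robustness filter that drops the most
extreme 0.5% of genes by expression. Group-versus-group significance uses a
two-sample Kolmogorov-Smirnov test on per-gene mean signal over a named
window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import distributions

from .genome_model import CoverageTrack, GeneModel

__all__ = [
    "MetageneProfile",
    "gene_profile",
    "group_metagene",
    "gene_window_mean",
    "ks_two_sample",
]

logger = logging.getLogger(__name__)

DEFAULT_BODY_BINS = 100
DEFAULT_FLANK_BINS = 50
DEFAULT_FLANK_BP = 1000


@dataclass
class MetageneProfile:
    """Per-gene binned signal and the group mean over a common bin axis."""

    matrix: pd.DataFrame  # genes x (2F + B)
    mean: np.ndarray
    body_bins: int
    flank_bins: int
    flank_bp: int
    n_genes: int

    @property
    def n_bins(self) -> int:
        return 2 * self.flank_bins + self.body_bins

    def body_slice(self) -> slice:
        return slice(self.flank_bins, self.flank_bins + self.body_bins)


def _bin_edges(start: int, end: int, nbins: int) -> np.ndarray:
    """Integer edges splitting [start, end) into nbins near-equal intervals.

    The remainder of (end - start) / nbins is spread one bp at a time over the
    leading bins.
    """
    length = end - start
    base, rem = divmod(length, nbins)
    widths = np.full(nbins, base, dtype=int)
    widths[:rem] += 1
    return start + np.concatenate(([0], np.cumsum(widths)))


def _binned_means(vec: np.ndarray, edges: np.ndarray, chrom_len: int) -> np.ndarray:
    out = np.zeros(len(edges) - 1)
    for i in range(len(edges) - 1):
        lo, hi = max(0, edges[i]), min(chrom_len, edges[i + 1])
        if hi > lo:
            out[i] = vec[lo:hi].mean()
    return out


def gene_profile(
    track: CoverageTrack,
    gene: GeneModel,
    body_bins: int = DEFAULT_BODY_BINS,
    flank_bins: int = DEFAULT_FLANK_BINS,
    flank_bp: int = DEFAULT_FLANK_BP,
) -> np.ndarray:
    """Binned signal vector (flank5, body, flank3) oriented 5'->3' of the gene.

    Flank bins falling off the chromosome end are zero. Raises for genes
    shorter than ``body_bins`` bp (callers are expected to skip them).
    """
    if flank_bp < flank_bins:
        raise ValueError("flank_bp must be >= flank_bins (at least 1 bp per bin)")
    if gene.length < body_bins:
        raise ValueError(f"gene {gene.gene_id} shorter than {body_bins} bp")
    vec = track[gene.chrom]
    chrom_len = track.chrom_sizes[gene.chrom]
    left = _binned_means(vec, _bin_edges(gene.start - flank_bp, gene.start, flank_bins), chrom_len)
    body = _binned_means(vec, _bin_edges(gene.start, gene.end, body_bins), chrom_len)
    right = _binned_means(vec, _bin_edges(gene.end, gene.end + flank_bp, flank_bins), chrom_len)
    profile = np.concatenate([left, body, right])
    if gene.strand == "-":
        profile = profile[::-1]
    return profile


def profile_matrix(
    track: CoverageTrack,
    genes: list[GeneModel],
    body_bins: int = DEFAULT_BODY_BINS,
    flank_bins: int = DEFAULT_FLANK_BINS,
    flank_bp: int = DEFAULT_FLANK_BP,
) -> pd.DataFrame:
    """Stack per-gene profiles; genes shorter than body_bins bp are skipped."""
    rows, ids, skipped = [], [], []
    for g in genes:
        if g.length < body_bins:
            skipped.append(g.gene_id)
            continue
        rows.append(gene_profile(track, g, body_bins, flank_bins, flank_bp))
        ids.append(g.gene_id)
    if skipped:
        logger.info("skipped %d genes shorter than %d bp: %s%s",
                    len(skipped), body_bins, ",".join(skipped[:5]),
                    "..." if len(skipped) > 5 else "")
    return pd.DataFrame(rows, index=ids)


def group_metagene(
    track: CoverageTrack,
    genes: list[GeneModel],
    expression: pd.Series | None = None,
    robust_pct: float = 0.5,
    two_sided: bool = False,
    body_bins: int = DEFAULT_BODY_BINS,
    flank_bins: int = DEFAULT_FLANK_BINS,
    flank_bp: int = DEFAULT_FLANK_BP,
) -> MetageneProfile:
    """Average profile of a gene group after the expression robustness filter.

    With ``robust_pct`` = 0.5, genes above the 99.5th expression percentile
    are removed before averaging (``two_sided`` also trims the bottom tail).
    ``expression`` (e.g. CPM) is required whenever robust_pct > 0.
    """
    matrix = profile_matrix(track, genes, body_bins, flank_bins, flank_bp)
    if robust_pct > 0:
        if expression is None:
            raise ValueError("expression values required when robust_pct > 0")
        expr = expression.reindex(matrix.index)
        hi = np.nanpercentile(expr, 100.0 - robust_pct)
        keep = expr <= hi
        if two_sided:
            lo = np.nanpercentile(expr, robust_pct)
            keep &= expr >= lo
        matrix = matrix.loc[keep.fillna(False)]
    if matrix.empty:
        raise ValueError("no genes left after length and robustness filtering")
    return MetageneProfile(
        matrix=matrix,
        mean=matrix.to_numpy().mean(axis=0),
        body_bins=body_bins,
        flank_bins=flank_bins,
        flank_bp=flank_bp,
        n_genes=len(matrix),
    )


def gene_window_mean(
    track: CoverageTrack, gene: GeneModel, window: str = "body"
) -> float:
    """Per-gene mean signal over a named window: body, tss200 or tes200."""
    if window == "body":
        lo, hi = gene.start, gene.end
    elif window == "tss200":
        lo, hi = gene.tss - 200, gene.tss + 201
    elif window == "tes200":
        lo, hi = gene.tes - 200, gene.tes + 201
    else:
        raise ValueError(f"unknown window {window!r}")
    return track.region_mean(gene.chrom, lo, hi, clip=True)


def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test.

    D = sup |ECDF_x - ECDF_y|; the p-value comes from the asymptotic
    Kolmogorov distribution evaluated at D * sqrt(n_eff) with
    n_eff = nx * ny / (nx + ny).
    """
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    nx, ny = x.size, y.size
    if nx == 0 or ny == 0:
        raise ValueError("both samples must be non-empty")
    grid = np.concatenate([x, y])
    cdf_x = np.searchsorted(x, grid, side="right") / nx
    cdf_y = np.searchsorted(y, grid, side="right") / ny
    d = float(np.max(np.abs(cdf_x - cdf_y)))
    n_eff = nx * ny / (nx + ny)
    p = float(distributions.kstwobign.sf(d * np.sqrt(n_eff)))
    return d, min(1.0, p)
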