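"""Promoter hexamer strand-bias and TATA-box frequency analysis.

All 4096 hexamers are counted exhaustively over strand-oriented promoter
windows (overlapping occurrences allowed, step 1). A hexamer's antisense
count is the count of its reverse complement on the sense sequence, so the
log2 sense/antisense ratio measures strand asymmetry — the signature of
directional promoter elements such as the TATA box. The fraction of genes
whose window carries a canonical TATAAA is compared against a genome-average
baseline with an exact binomial test.
"""

from __future__ import annotations

import itertools
import logging
from typing import Iterable

import pandas as pd
from scipy.stats import binomtest

from .genome_model import PromoterWindow, reverse_complement

__all__ = [
    "ALL_HEXAMERS",
    "ALT_TATA_MOTIFS",
    "hexamer_strand_bias",
    "tata_fraction",
    "binom_vs_baseline",
]

logger = logging.getLogger(__name__)

ALL_HEXAMERS: list[str] = ["".join(h) for h in itertools.product("ACGT", repeat=6)]

# canonical TATAAA plus the A->T single substitutions in its 3' half
ALT_TATA_MOTIFS: frozenset[str] = frozenset({"TATAAA", "TATTAA", "TATATA", "TATAAT"})

ALT_TSS_SEPARATOR = "@"

GENOME_TATA_BASELINE = 0.19


def _count_kmers(seq: str, counts: dict[str, int]) -> None:
    for i in range(len(seq) - 5):
        kmer = seq[i : i + 6]
        if kmer in counts:  # hexamers containing N never match
            counts[kmer] += 1


def hexamer_strand_bias(windows: Iterable[PromoterWindow]) -> pd.DataFrame:
    """Sense/antisense occurrence counts and log2 ratio for all 4096 hexamers.

    Returns a DataFrame indexed by hexamer with columns ``sense``,
    ``antisense`` and ``log2_ratio`` = log2((S+1)/(A+1)). Windows shorter than
    6 bp are skipped. By construction r(h) = -r(revcomp(h)).
    """
    import numpy as np

    sense = dict.fromkeys(ALL_HEXAMERS, 0)
    n_skipped = 0
    for w in windows:
        if len(w.sequence) < 6:
            n_skipped += 1
            continue
        _count_kmers(w.sequence.upper(), sense)
    if n_skipped:
        logger.info("skipped %d windows shorter than 6 bp", n_skipped)
    table = pd.DataFrame(
        {"sense": pd.Series(sense)}, index=pd.Index(ALL_HEXAMERS, name="hexamer")
    )
    rc = [reverse_complement(h) for h in ALL_HEXAMERS]
    table["antisense"] = table["sense"].reindex(rc).to_numpy()
    table["log2_ratio"] = np.log2((table["sense"] + 1) / (table["antisense"] + 1))
    return table


def _base_gene_id(window_id: str) -> str:
    """Alternative-TSS windows are named gene@k; they count as one gene."""
    return window_id.split(ALT_TSS_SEPARATOR, 1)[0]


def tata_fraction(
    windows: Iterable[PromoterWindow],
    motifs: Iterable[str] = ("TATAAA",),
) -> tuple[int, int, float]:
    """(k, n, k/n): genes whose promoter window contains any of the motifs.

    A gene counts once regardless of the number of hits or of alternative-TSS
    windows carrying them.
    """
    motifs = set(m.upper() for m in motifs)
    hit_genes: set[str] = set()
    all_genes: set[str] = set()
    for w in windows:
        gid = _base_gene_id(w.gene_id)
        all_genes.add(gid)
        seq = w.sequence.upper()
        if any(m in seq for m in motifs):
            hit_genes.add(gid)
    n = len(all_genes)
    k = len(hit_genes)
    return k, n, (k / n if n else 0.0)


def binom_vs_baseline(k: int, n: int, p0: float = GENOME_TATA_BASELINE) -> float:
    """Exact two-sided binomial p for k successes in n trials vs rate p0.

    Two-sided in the minimum-likelihood sense: the p-value sums the
    probabilities of all outcomes no more likely than the observed k.
    """
    if not (0 <= k <= n) or n <= 0:
        raise ValueError(f"require 0 <= k <= n with n > 0, got k={k}, n={n}")
    if not (0.0 < p0 < 1.0):
        raise ValueError("baseline rate must lie in (0, 1)")
    return float(binomtest(k, n, p0, alternative="two-sided").pvalue)
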