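"""Nucleosome-change profiles and Cluster 1 / Cluster 2 partitioning."""

import numpy as np
import pandas as pd
import pytest

from brmmode.genome_model import CoverageTrack, GeneModel
from brmmode.nucleosome import DeltaProfileSet, cluster_delta, delta_profiles


def make_track(values):
    t = CoverageTrack({"chr1": len(values)})
    t.data["chr1"] = np.asarray(values, dtype=float)
    return t


GENES = [
    GeneModel("ga", "chr1", 2000, 3000, "+"),
    GeneModel("gb", "chr1", 6000, 7500, "-"),
]


def test_identical_tracks_give_zero_delta():
    t = make_track(np.random.default_rng(0).uniform(0.5, 2, 10000))
    d = delta_profiles(t, t, GENES, body_bins=10, flank_bins=2, flank_bp=100)
    np.testing.assert_allclose(d.matrix.to_numpy(), 0.0, atol=1e-12)
    np.testing.assert_allclose(d.body_mean, 0.0, atol=1e-12)


def test_uniform_shift_appears_in_every_bin():
    ctrl = make_track(np.full(10000, 2.0))
    depl = make_track(np.full(10000, 3.0))
    d = delta_profiles(ctrl, depl, GENES, body_bins=10, flank_bins=2, flank_bp=100,
                       normalize=False)
    np.testing.assert_allclose(d.matrix.to_numpy(), 1.0)


def test_normalization_cancels_depth_differences():
    rng = np.random.default_rng(1)
    base = rng.uniform(0.5, 2, 10000)
    ctrl = make_track(base)
    depl = make_track(base * 3.0)  # pure depth difference
    d = delta_profiles(ctrl, depl, GENES, body_bins=10, flank_bins=2, flank_bp=100)
    np.testing.assert_allclose(d.matrix.to_numpy(), 0.0, atol=1e-12)


def test_toy_two_gene_hand_binned_difference():
    ctrl = make_track(np.zeros(10000))
    depl_vals = np.zeros(10000)
    depl_vals[2000:3000] = 2.0  # whole body of ga
    depl = make_track(depl_vals)
    d = delta_profiles(ctrl, depl, GENES, body_bins=5, flank_bins=1, flank_bp=100,
                       normalize=False)
    np.testing.assert_allclose(d.matrix.loc["ga"].to_numpy()[1:6], 2.0)
    np.testing.assert_allclose(d.matrix.loc["gb"].to_numpy(), 0.0)
    assert d.body_mean["ga"] == pytest.approx(2.0)


def test_chromosome_mismatch_errors():
    t1 = make_track(np.ones(10000))
    t2 = CoverageTrack({"chr2": 10000})
    with pytest.raises(ValueError, match="different chromosomes"):
        delta_profiles(t1, t2, GENES)
    g_bad = [GeneModel("g", "chrX", 0, 1000, "+")]
    with pytest.raises(ValueError, match="absent"):
        delta_profiles(t1, t1, g_bad)


def _planted_delta_set(rng, delta=1.5, sd=0.3, n_hi=20, n_lo=60, bins=30):
    ids = [f"g{i:03d}" for i in range(n_hi + n_lo)]
    shift = np.concatenate([np.full(n_hi, delta), np.zeros(n_lo)])
    mat = rng.normal(shift[:, None], sd, (n_hi + n_lo, bins))
    df = pd.DataFrame(mat, index=ids)
    return (
        DeltaProfileSet(matrix=df, body_mean=df.mean(axis=1), body_bins=bins, flank_bins=0),
        np.concatenate([np.ones(n_hi, dtype=int), np.full(n_lo, 2, dtype=int)]),
    )


def test_cluster_recovers_planted_partition():
    rng = np.random.default_rng(30)
    profiles, truth = _planted_delta_set(rng, delta=2.0, sd=0.1)
    labeled = cluster_delta(profiles, seed=7)
    assert (labeled.labels.to_numpy() == truth).all()
    # high-gain group carries label 1 by the labeling rule
    assert labeled.matrix.loc[labeled.labels == 1].to_numpy().mean() > (
        labeled.matrix.loc[labeled.labels == 2].to_numpy().mean()
    )


def test_cluster_agreement_at_stated_separation():
    """Planted body gain +1.5, noise sd 0.3: near-perfect recovery."""
    rng = np.random.default_rng(31)
    profiles, truth = _planted_delta_set(rng, delta=1.5, sd=0.3)
    labeled = cluster_delta(profiles, seed=1)
    agreement = (labeled.labels.to_numpy() == truth).mean()
    assert agreement >= 0.95


def test_negating_deltas_swaps_cluster_labels():
    rng = np.random.default_rng(32)
    profiles, truth = _planted_delta_set(rng, delta=2.0, sd=0.1)
    neg = DeltaProfileSet(
        matrix=-profiles.matrix,
        body_mean=-profiles.body_mean,
        body_bins=profiles.body_bins,
        flank_bins=0,
    )
    labeled = cluster_delta(neg, seed=7)
    swapped = np.where(truth == 1, 2, 1)
    assert (labeled.labels.to_numpy() == swapped).all()


def test_identical_profiles_deterministic_under_seed():
    mat = pd.DataFrame(np.ones((8, 10)), index=[f"g{i}" for i in range(8)])
    profiles = DeltaProfileSet(matrix=mat, body_mean=mat.mean(axis=1), body_bins=10,
                               flank_bins=0)
    l1 = cluster_delta(profiles, seed=3)
    l2 = cluster_delta(profiles, seed=3)
    pd.testing.assert_series_equal(l1.labels, l2.labels)
    assert set(l1.labels) <= {1, 2}


def test_gene_order_invariance():
    rng = np.random.default_rng(33)
    profiles, _ = _planted_delta_set(rng)
    shuffled = DeltaProfileSet(
        matrix=profiles.matrix.sample(frac=1.0, random_state=4),
        body_mean=profiles.body_mean.sample(frac=1.0, random_state=4),
        body_bins=profiles.body_bins,
        flank_bins=0,
    )
    l1 = cluster_delta(profiles, seed=5)
    l2 = cluster_delta(shuffled, seed=5)
    pd.testing.assert_series_equal(l1.labels.sort_index(), l2.labels.sort_index())


def test_overall_mean_is_size_weighted_cluster_mean():
    rng = np.random.default_rng(34)
    profiles, _ = _planted_delta_set(rng)
    labeled = cluster_delta(profiles, seed=2)
    body = labeled.matrix
    total = body.to_numpy().mean()
    parts = 0.0
    for lab in (1, 2):
        members = body.loc[labeled.labels == lab]
        parts += members.to_numpy().mean() * len(members)
    assert total == pytest.approx(parts / len(body))


def test_too_few_genes_errors():
    mat = pd.DataFrame(np.ones((1, 5)), index=["only"])
    profiles = DeltaProfileSet(matrix=mat, body_mean=mat.mean(axis=1), body_bins=5,
                               flank_bins=0)
    with pytest.raises(ValueError, match="at least k"):
        cluster_delta(profiles)
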