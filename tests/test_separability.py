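"""Band-limiting, embedding, and pairwise KS testing."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import ks_2samp

from silentspeech import (
    SynthConfig, bandlimit, embed, extract_epochs, filter_stage1,
    filter_stage2, generate_recording, ks_pairwise, spectral_features,
)
from silentspeech.separability import EmbeddingPoints


def ecdf_ks_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Exhaustive sup|F1−F2| over the pooled order statistics."""
    pooled = np.concatenate([x, y])
    d = 0.0
    for v in pooled:
        f1 = np.mean(x <= v)
        f2 = np.mean(y <= v)
        d = max(d, abs(f1 - f2))
    return d


def test_stopband_sinusoid_is_annihilated():
    t = np.arange(2048) / 500.0
    f_stop = 8 * 500.0 / 2048  # bin-aligned ≈ 1.95 Hz, below the 5 Hz edge
    x = np.sin(2 * np.pi * f_stop * t)
    y = bandlimit(x[None, :], 500.0, return_time=True)
    assert np.abs(y).max() < 1e-6 * np.abs(x).max()


def test_passband_sinusoid_is_preserved():
    t = np.arange(2048) / 500.0
    f_pass = 41 * 500.0 / 2048  # bin-aligned ≈ 10 Hz
    x = np.sin(2 * np.pi * f_pass * t)
    y = bandlimit(x[None, :], 500.0, return_time=True)
    assert np.sum(y ** 2) == pytest.approx(np.sum(x ** 2), rel=1e-9)


def test_band_energy_matches_parseval_oracle():
    rng = np.random.default_rng(0)
    x = rng.standard_normal(2048)
    mag = bandlimit(x[None, :], 500.0)[0]
    freqs = np.fft.rfftfreq(2048, 1 / 500.0)
    spec = np.fft.rfft(x)
    keep = (freqs >= 5.0) & (freqs <= 49.0)
    assert np.sum(mag ** 2) == pytest.approx(np.sum(np.abs(spec[keep]) ** 2))
    assert np.all(mag[~keep] == 0.0)


def test_bandlimit_requires_adequate_rate():
    with pytest.raises(ValueError, match="rate"):
        bandlimit(np.zeros((1, 100)), 80.0)


def test_embedding_has_three_columns_and_duplicate_invariance():
    rng = np.random.default_rng(1)
    X = rng.standard_normal((120, 40))
    X[60] = X[0]  # exact duplicate row
    emb = embed(X, ["a"] * 60 + ["b"] * 60, seed=0, max_iter=500)
    assert emb.coords.shape == (120, 3)
    diameter = np.linalg.norm(emb.coords.max(0) - emb.coords.min(0))
    assert np.linalg.norm(emb.coords[0] - emb.coords[60]) < 0.01 * diameter


def test_small_sample_reduces_pca_with_warning(caplog):
    rng = np.random.default_rng(2)
    X = rng.standard_normal((30, 100))
    emb = embed(X, ["a"] * 15 + ["b"] * 15, seed=0, max_iter=250)
    assert emb.coords.shape == (30, 3)


def test_separable_classes_cluster_in_embedding():
    """Distinct oscillatory signatures produce a clustered 3-D embedding."""
    from sklearn.metrics import silhouette_score

    cfg = SynthConfig(n_subjects=1, sessions_per_subject=12, words_per_session=10,
                      words=("forward", "stop"), class_effect=3.0, seed=5)
    rec, _ = generate_recording(cfg)
    es = filter_stage2(filter_stage1(extract_epochs(rec)))
    emb = embed(spectral_features(es), es.labels(), seed=0, max_iter=500)
    assert silhouette_score(emb.coords, emb.labels) > 0.2


def test_ks_identical_samples_give_zero_statistic():
    x = np.arange(50, dtype=float)
    coords = np.stack([np.concatenate([x, x])] * 3, axis=1)
    emb = EmbeddingPoints(coords=coords, labels=["a"] * 50 + ["b"] * 50)
    rep = ks_pairwise(emb)
    assert np.all(rep.table.statistic == 0.0)
    assert np.all(rep.table.pvalue == 1.0)


def test_ks_disjoint_supports_give_statistic_one():
    coords = np.stack([np.concatenate([[1, 2, 3, 2, 1], [5, 6, 7, 6, 5.0]])] * 3, axis=1)
    emb = EmbeddingPoints(coords=coords, labels=["a"] * 5 + ["b"] * 5)
    rep = ks_pairwise(emb)
    assert np.all(rep.table.statistic == 1.0)


@given(st.integers(0, 2 ** 31 - 1), st.integers(5, 200), st.integers(5, 200))
def test_ks_statistic_equals_ecdf_oracle(seed, na, nb):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(na)
    y = rng.standard_normal(nb) + rng.uniform(-1, 1)
    assert ks_2samp(x, y, method="asymp").statistic == pytest.approx(
        ecdf_ks_oracle(x, y), abs=1e-12
    )


def test_small_groups_excluded_with_36_pairs_for_9_words():
    rng = np.random.default_rng(3)
    labels = sum([[w] * 20 for w in
                  ("forward", "backward", "up", "down", "help", "take", "stop",
                   "release", "pseudo")], []) + ["forward"] * 0
    coords = rng.standard_normal((len(labels), 3))
    emb = EmbeddingPoints(coords=coords, labels=labels)
    rep = ks_pairwise(emb)
    assert len(rep.best_component) == 36
    assert len(rep.table) == 108
    assert set(rep.best_component.values()) <= {1, 2, 3}
    # now starve one word below the minimum group size
    labels2 = [l for l in labels if l != "pseudo"] + ["pseudo"] * 4
    coords2 = rng.standard_normal((len(labels2), 3))
    rep2 = ks_pairwise(EmbeddingPoints(coords=coords2, labels=labels2))
    assert len(rep2.best_component) == 28  # 8 words remain


def test_all_word_pairs_significant_with_distinct_signatures():
    """With distinct class signatures every pair separates at n≈200/class.

    Statistical mirror of the full-scale finding that all 36 word pairs are
    distinguishable; run at 9 words × ~200 epochs per word.
    """
    cfg = SynthConfig(n_subjects=4, sessions_per_subject=50, words_per_session=10,
                      class_effect=2.5, subject_effect=0.3, seed=100)
    rec, _ = generate_recording(cfg)
    es = filter_stage2(filter_stage1(extract_epochs(rec)))
    del rec
    feats = spectral_features(es)
    emb = embed(feats, es.labels(), seed=0, max_iter=500)
    rep = ks_pairwise(emb)
    worst = max(rep.pair(a, b).pvalue.min() for a, b in rep.best_component)
    assert len(rep.best_component) == 36
    assert worst < 0.01
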