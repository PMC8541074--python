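"""Statistical separability of per-word EEG distributions.

The question this module answers: before any classifier is trained, do the
words already occupy distinguishable regions of signal space?  The route:
take the left-temporal channels (nearest the speech areas), band-limit
their spectra to 5–49 Hz, reduce with PCA to 50 components and t-SNE to 3,
then compare every pair of word groups component-by-component with the
two-sample Kolmogorov–Smirnov test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .epoching import EpochSet
from .layout import ChannelLayout, default_layout

__all__ = [
    "EmbeddingPoints",
    "KSReport",
    "bandlimit",
    "spectral_features",
    "embed",
    "ks_pairwise",
]

log = logging.getLogger(__name__)

BAND_LO_HZ = 5.0
BAND_HI_HZ = 49.0
PCA_COMPONENTS = 50
TSNE_COMPONENTS = 3
TSNE_PERPLEXITY = 30.0
TSNE_LEARNING_RATE = 10.0
TSNE_MAX_ITER = 5000
MIN_GROUP_SIZE = 5


@dataclass(eq=False)
class EmbeddingPoints:
    """3-component embedding coordinates, one row per epoch."""

    coords: np.ndarray  # [n × 3]
    labels: list[str]

    def __post_init__(self) -> None:
        if self.coords.shape != (len(self.labels), TSNE_COMPONENTS):
            raise ValueError(
                f"coords must be n×{TSNE_COMPONENTS} with one label per row"
            )

    def group(self, label: str) -> np.ndarray:
        idx = [i for i, l in enumerate(self.labels) if l == label]
        return self.coords[idx]


@dataclass(eq=False)
class KSReport:
    """Pairwise per-component KS statistics over word groups.

    ``table`` is long-format: word_a, word_b, component (1-based), statistic,
    pvalue.  ``best_component`` maps each pair to the component where the
    test is most convincing (smallest p-value).
    """

    table: pd.DataFrame
    best_component: dict[tuple[str, str], int]

    def pair(self, a: str, b: str) -> pd.DataFrame:
        a, b = sorted((a, b))
        return self.table[(self.table.word_a == a) & (self.table.word_b == b)]

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def bandlimit(
    epoch_data: np.ndarray,
    rate: float,
    lo: float = BAND_LO_HZ,
    hi: float = BAND_HI_HZ,
    return_time: bool = False,
) -> np.ndarray:
    """Zero spectral content outside [lo, hi] Hz, per channel.

    Returns the magnitude spectrum with the stop band zeroed (the feature
    representation; phase-invariant), or with ``return_time`` the
    band-limited time series via the inverse transform.
    """
    if rate <= 2 * hi:
        raise ValueError(f"rate {rate} must exceed twice the upper edge {hi}")
    x = np.asarray(epoch_data, dtype=float)
    spec = np.fft.rfft(x, axis=-1)
    freqs = np.fft.rfftfreq(x.shape[-1], 1.0 / rate)
    stop = (freqs < lo) | (freqs > hi)
    spec[..., stop] = 0.0
    if return_time:
        return np.fft.irfft(spec, n=x.shape[-1], axis=-1)
    return np.abs(spec)


def spectral_features(es: EpochSet, layout: ChannelLayout | None = None) -> np.ndarray:
    """Per-epoch feature vectors: left-temporal in-band spectral magnitudes.

    For each epoch the left-temporal channels are band-limited to 5–49 Hz
    and the retained-bin magnitudes concatenated across channels.
    """
    if layout is None:
        layout = default_layout()
    idx = layout.indices(layout.temporal_left)
    freqs = np.fft.rfftfreq(es[0].data.shape[-1], 1.0 / es.rate)
    keep = (freqs >= BAND_LO_HZ) & (freqs <= BAND_HI_HZ)
    feats = []
    for ep in es:
        mag = bandlimit(ep.data[idx], es.rate)
        feats.append(mag[:, keep].ravel())
    return np.stack(feats)


def embed(
    features: np.ndarray,
    labels: list[str],
    seed: int = 0,
    max_iter: int = TSNE_MAX_ITER,
) -> EmbeddingPoints:
    """PCA to 50 dimensions, then t-SNE to 3.

    t-SNE runs with perplexity 30 and learning rate 10 (reduced when the
    sample is too small for them) and a fixed seed; the exact gradient is
    used since the embedding is 3-D.
    """
    n = features.shape[0]
    n_pca = min(PCA_COMPONENTS, features.shape[1])
    if n <= PCA_COMPONENTS:
        n_pca = max(1, min(n - 1, n_pca))
        log.warning("only %d samples; reducing PCA to %d components", n, n_pca)
    reduced = PCA(n_components=n_pca, random_state=seed).fit_transform(features)
    perplexity = min(TSNE_PERPLEXITY, (n - 1) / 3.0)
    tsne = TSNE(
        n_components=TSNE_COMPONENTS,
        perplexity=perplexity,
        learning_rate=TSNE_LEARNING_RATE,
        max_iter=max_iter,
        method="exact",
        init="pca",
        random_state=seed,
    )
    coords = tsne.fit_transform(reduced)
    return EmbeddingPoints(coords=np.asarray(coords, dtype=float), labels=list(labels))


def ks_pairwise(emb: EmbeddingPoints) -> KSReport:
    """Two-sample KS test for every word pair, per embedding component.

    D = sup|F₁ − F₂| with the asymptotic two-sample p-value.  Words with
    fewer than 5 points are excluded with a warning; at least two groups
    must remain.
    """
    sizes = {l: emb.labels.count(l) for l in dict.fromkeys(emb.labels)}
    usable = sorted(l for l, n in sizes.items() if n >= MIN_GROUP_SIZE)
    for l, n in sizes.items():
        if n < MIN_GROUP_SIZE:
            log.warning("excluding word %r: only %d points (< %d)", l, n, MIN_GROUP_SIZE)
    if len(usable) < 2:
        raise ValueError("need at least two word groups with >= 5 points")

    rows = []
    best: dict[tuple[str, str], int] = {}
    for a, b in combinations(usable, 2):
        xa, xb = emb.group(a), emb.group(b)
        pvals = []
        for c in range(TSNE_COMPONENTS):
            res = ks_2samp(xa[:, c], xb[:, c], method="asymp")
            # the asymptotic formula underflows to 0 for very large D;
            # clamp so p stays strictly positive
            p = max(float(res.pvalue), np.finfo(float).tiny)
            rows.append(
                dict(word_a=a, word_b=b, component=c + 1,
                     statistic=float(res.statistic), pvalue=p)
            )
            pvals.append(p)
        best[(a, b)] = int(np.argmin(pvals)) + 1
    return KSReport(table=pd.DataFrame(rows), best_component=best)
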