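"""Eye-noise extraction from frontal electrode triads.

Blinks and eye movements dominate the frontal channels as a high-amplitude,
low-frequency transient.  Rather than cleaning the EEG, this module *keeps*
the ocular signal as an explicit feature: for each configured frontal triad
it unmixes two independent components, detrends them by zeroing the lowest
FFT bins, smooths with a Savitzky–Golay filter, and selects the component
whose maximum stands furthest above its median — the signature shape of a
blink bump against a flat background.  The input segment is never modified.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter
from sklearn.decomposition import FastICA

from .layout import ChannelLayout

__all__ = ["EyeComponents", "extract_eye_noise", "detrend_lowest_bins"]

log = logging.getLogger(__name__)

SAVGOL_WINDOW = 21
SAVGOL_POLYORDER = 5
ICA_SEED = 42


@dataclass(eq=False)
class EyeComponents:
    """One extracted eye-noise series per frontal triad.

    ``series`` is [n_groups × T]; ``chosen_index`` records which of the two
    unmixed components was selected per group (−1 for a degenerate group
    where the triad carried no signal and zeros were returned).
    """

    series: np.ndarray
    chosen_index: list[int]
    groups: tuple[tuple[str, ...], ...]

    @property
    def n_groups(self) -> int:
        return self.series.shape[0]


def detrend_lowest_bins(x: np.ndarray, k: int = 3) -> np.ndarray:
    """Zero the ``k`` lowest nonnegative-frequency FFT bins (incl. DC).

    Equivalent to subtracting the signal's projection onto the k lowest
    Fourier basis functions; removes slow trends while leaving the pass
    band untouched.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < 2 * k:
        raise ValueError(f"need at least {2 * k} samples, got {x.shape[-1]}")
    spec = np.fft.rfft(x, axis=-1)
    spec[..., :k] = 0.0
    return np.fft.irfft(spec, n=x.shape[-1], axis=-1)


def _oriented(component: np.ndarray) -> tuple[np.ndarray, float]:
    """Resolve ICA's sign ambiguity for the max−median rule.

    A blink is an upward bump after unmixing only up to sign; evaluate the
    rule on both orientations and keep the better one.
    """
    score_pos = float(np.max(component) - np.median(component))
    score_neg = float(np.max(-component) - np.median(-component))
    if score_neg > score_pos:
        return -component, score_neg
    return component, score_pos


def _extract_group(segment: np.ndarray) -> tuple[np.ndarray, int]:
    """Run the three-step extraction on one triad (3 × T)."""
    T = segment.shape[1]
    if not np.any(np.std(segment, axis=1) > 1e-12):
        log.warning("degenerate (constant) triad segment; returning zeros")
        return np.zeros(T), -1
    ica = FastICA(n_components=2, algorithm="deflation", random_state=ICA_SEED)
    try:
        comps = ica.fit_transform(segment.T).T  # [2 × T]
    except Exception as e:
        log.warning("ICA failed on triad (%s); returning zeros", e)
        return np.zeros(T), -1
    best_series, best_score, best_idx = None, -np.inf, -1
    for i in range(comps.shape[0]):
        c = detrend_lowest_bins(comps[i], k=3)
        c = savgol_filter(c, SAVGOL_WINDOW, polyorder=SAVGOL_POLYORDER)
        c, score = _oriented(c)
        if score > best_score:
            best_series, best_score, best_idx = c, score, i
    return best_series, best_idx


def extract_eye_noise(
    segment: np.ndarray, layout: ChannelLayout, groups=None
) -> EyeComponents:
    """Extract one eye-noise series per frontal triad from ``segment``.

    ``segment`` is [n_channels × T] in the layout's channel order, with
    T ≥ 21 (the smoother window).  Per triad: 2-component deflation ICA
    (fixed seed), zero the 3 lowest FFT bins of each component, smooth
    (Savitzky–Golay, window 21, order 5), and keep the component with the
    largest max − median.  The input array is not modified.
    """
    if groups is None:
        groups = layout.frontal_groups
    if segment.shape[0] != layout.n_channels:
        raise ValueError(
            f"segment has {segment.shape[0]} rows, layout has {layout.n_channels} channels"
        )
    if segment.shape[1] < SAVGOL_WINDOW:
        raise ValueError(f"segment too short: need T >= {SAVGOL_WINDOW}")
    for g in groups:
        for ch in g:
            if ch not in layout.names:
                raise ValueError(f"triad channel {ch!r} missing from layout")

    series, chosen = [], []
    for g in groups:
        triad = segment[layout.indices(g), :]
        s, idx = _extract_group(np.array(triad, dtype=float))
        series.append(s)
        chosen.append(idx)
    return EyeComponents(
        series=np.stack(series), chosen_index=chosen, groups=tuple(tuple(g) for g in groups)
    )
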