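"""Synthetic multi-subject silent-speech EEG.

The generator emulates the structure the analysis pipeline assumes: trials
of 3 s word presentation followed by 2 s of blank screen, a closed 9-word
vocabulary, several sessions per subject, 40 channels at 500 Hz.  Each
channel carries 1/f background noise plus a small spatially common
component; each word adds a signature of three narrowband oscillations
(centre frequencies drawn once per vocabulary from 5–49 Hz, random phase
per trial) weighted towards the temporal electrodes; each subject applies a
fixed random linear mixing to the neural part of the signal; blink
transients land on the frontal electrodes.

The class signal is a spatio-spectral pattern, not a trivial amplitude
offset, so downstream separability and classification are earned rather
than baked in.  See ``docs/methods.md`` for what this emulation does and
does not capture about real EEG.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import WORDS, EventMark, Recording
from .layout import ChannelLayout, default_layout

__all__ = ["SynthConfig", "GroundTruth", "generate_recording", "generate_blink"]

#: Trial timing: word on screen for 3 s, blank for 2 s.
PRESENTATION_S = 3.0
BLANK_S = 2.0


@dataclass(frozen=True)
class SynthConfig:
    """Study-shaped simulation parameters.

    Parameters
    ----------
    n_subjects, sessions_per_subject, words_per_session
        Cohort shape; a session is 10 words read in random order, an
        experiment runs 5–14 sessions, so 5 is the modest default.
    rate
        Sampling rate in Hz.
    class_effect
        Amplitude scale (dimensionless, 1.0 ≈ oscillation amplitude of
        4 µV against ~10 µV background) of the per-word oscillatory
        signatures; 0 removes all class information.
    subject_effect
        Scale of the subject-specific random channel mixing; 0 makes all
        subjects identical.
    blink_rate
        Expected blink events per second on the frontal channels.
    words
        Vocabulary to draw from (subset of the canonical nine for binary
        experiments).
    seed
        Single seed from which every random draw flows.
    """

    n_subjects: int = 1
    sessions_per_subject: int = 5
    words_per_session: int = 10
    rate: float = 500.0
    class_effect: float = 1.0
    subject_effect: float = 0.5
    blink_rate: float = 0.2
    words: tuple[str, ...] = WORDS
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_subjects, self.sessions_per_subject, self.words_per_session) < 1:
            raise ValueError("counts must be >= 1")
        if min(self.class_effect, self.subject_effect, self.blink_rate) < 0:
            raise ValueError("effect scales must be >= 0")
        unknown = set(self.words) - set(WORDS)
        if unknown:
            raise ValueError(f"unknown words: {sorted(unknown)}")


@dataclass(eq=False)
class GroundTruth:
    """What was actually injected: trials, and blink onsets/topographies."""

    trials: pd.DataFrame  # onset_sample, label, subject_id, session_id
    blinks: pd.DataFrame  # onset_sample, amplitude_uV, subject_id
    blink_weights: np.ndarray  # [n_blinks × n_channels], frontal support only
    signature_freqs: dict[str, np.ndarray]  # word -> 3 centre frequencies (Hz)


def generate_blink(
    duration_s: float, amplitude: float, rate: float = 500.0
) -> np.ndarray:
    """A smooth unimodal blink transient (squared-sine bump).

    The waveform peaks at exactly ``amplitude`` µV and concentrates its
    spectral energy below ~3 Hz for physiological durations (0.2–0.5 s).
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    n = max(3, int(round(duration_s * rate)))
    t = (np.arange(n) + 0.5) / n
    w = np.sin(np.pi * t) ** 2
    peak = w.max()
    if amplitude == 0 or peak == 0:
        return np.zeros(n)
    return w * (amplitude / peak)


def _pink_noise(rng: np.random.Generator, n_ch: int, n_samp: int, rate: float) -> np.ndarray:
    """1/f^α noise with α=1, unit-ish std, one independent series per row."""
    nf = n_samp // 2 + 1
    freqs = np.fft.rfftfreq(n_samp, 1 / rate)
    shaping = np.zeros(nf)
    shaping[1:] = 1.0 / np.sqrt(freqs[1:])
    spec = (
        rng.standard_normal((n_ch, nf)) + 1j * rng.standard_normal((n_ch, nf))
    ) * shaping
    x = np.fft.irfft(spec, n=n_samp, axis=1)
    x /= x.std(axis=1, keepdims=True) + 1e-30
    return x


def _signature_frequencies(cfg: SynthConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Three narrowband centre frequencies per word, drawn once, 5–49 Hz.

    Drawn for the full vocabulary (in canonical order) regardless of the
    words actually used, so a word keeps its signature across configs.
    """
    return {w: np.sort(rng.uniform(5.0, 49.0, size=3)) for w in WORDS}


def _word_topography(
    rng: np.random.Generator, layout: ChannelLayout
) -> np.ndarray:
    """Per-word channel weights, emphasized over the temporal electrodes."""
    w = rng.uniform(0.0, 0.4, size=layout.n_channels)
    temporal = set(layout.temporal_left) | set(layout.temporal_right)
    for i, name in enumerate(layout.names):
        if name in temporal:
            w[i] = rng.uniform(0.8, 1.2)
    return w


_FRONTAL_BASE = {"Fp1": 1.0, "Fpz": 1.0, "Fp2": 1.0, "F7": 0.4, "F3": 0.5, "Fz": 0.5, "F4": 0.5, "F8": 0.4}


def generate_recording(
    cfg: SynthConfig, layout: ChannelLayout | None = None
) -> tuple[Recording, GroundTruth]:
    """Simulate one continuous multi-subject recording with ground truth.

    Subjects' sessions are concatenated into a single recording; every
    trial contributes 5 s of signal (3 s presentation + 2 s blank) with a
    mark at presentation onset carrying label, subject and session ids.
    All randomness flows from ``cfg.seed``.
    """
    if layout is None:
        layout = default_layout()
    rng = np.random.default_rng(cfg.seed)
    rate = cfg.rate
    trial_len = int(round((PRESENTATION_S + BLANK_S) * rate))
    pres_len = int(round(PRESENTATION_S * rate))
    n_trials_per_session = cfg.words_per_session
    trials_per_subject = cfg.sessions_per_subject * n_trials_per_session
    n_trials = cfg.n_subjects * trials_per_subject
    n_samples = n_trials * trial_len
    nch = layout.n_channels

    sig_freqs = _signature_frequencies(cfg, rng)
    topo = {w: _word_topography(rng, layout) for w in WORDS}
    # per-subject mixing: identity plus a small random matrix, drawn once
    mixers = [
        np.eye(nch) + cfg.subject_effect * rng.standard_normal((nch, nch)) / np.sqrt(nch)
        for _ in range(cfg.n_subjects)
    ]

    data = np.zeros((nch, n_samples))
    trial_rows: list[dict] = []
    blink_rows: list[dict] = []
    blink_weight_rows: list[np.ndarray] = []

    frontal_idx = {layout.index_of(n): a for n, a in _FRONTAL_BASE.items() if n in layout.names}
    t_pres = np.arange(pres_len) / rate
    envelope = np.ones(pres_len)
    ramp = int(round(0.1 * rate))
    envelope[:ramp] = np.linspace(0, 1, ramp)
    envelope[-ramp:] = np.linspace(1, 0, ramp)

    marks: list[EventMark] = []
    pos = 0
    for s in range(cfg.n_subjects):
        subject_id = f"s{s:02d}"
        mix = mixers[s]
        sub_start = pos
        sub_len = trials_per_subject * trial_len
        background = 10.0 * _pink_noise(rng, nch, sub_len, rate)
        common = 3.0 * _pink_noise(rng, 1, sub_len, rate)
        common_weights = 0.5 + 0.5 * rng.random(nch)
        neural = background + common_weights[:, None] * common
        for sess in range(cfg.sessions_per_subject):
            session_id = f"sess{sess:02d}"
            labels = rng.choice(len(cfg.words), size=n_trials_per_session)
            for li in labels:
                word = cfg.words[li]
                onset = pos - sub_start
                osc = np.zeros(pres_len)
                for f0 in sig_freqs[word]:
                    phase = rng.uniform(0, 2 * np.pi)
                    osc += np.sin(2 * np.pi * f0 * t_pres + phase)
                osc *= envelope * cfg.class_effect * 4.0
                neural[:, onset:onset + pres_len] += topo[word][:, None] * osc
                marks.append(EventMark(pos, word, subject_id, session_id))
                trial_rows.append(
                    dict(onset_sample=pos, label=word,
                         subject_id=subject_id, session_id=session_id)
                )
                pos += trial_len
        mixed = mix @ neural
        # blinks ride on top of the mixed signal: frontal topography only
        n_blinks = rng.poisson(cfg.blink_rate * sub_len / rate)
        for _ in range(n_blinks):
            onset = int(rng.integers(0, max(1, sub_len - int(0.5 * rate))))
            amp = rng.uniform(60.0, 120.0)
            wave = generate_blink(rng.uniform(0.25, 0.45), amp, rate)
            weights = np.zeros(nch)
            for idx, base in frontal_idx.items():
                weights[idx] = base * rng.uniform(0.8, 1.2)
            end = min(sub_len, onset + wave.size)
            mixed[:, onset:end] += weights[:, None] * wave[: end - onset]
            blink_rows.append(
                dict(onset_sample=sub_start + onset, amplitude_uV=amp, subject_id=subject_id)
            )
            blink_weight_rows.append(weights)
        data[:, sub_start:sub_start + sub_len] = mixed

    truth = GroundTruth(
        trials=pd.DataFrame(trial_rows),
        blinks=pd.DataFrame(blink_rows, columns=["onset_sample", "amplitude_uV", "subject_id"]),
        blink_weights=(
            np.array(blink_weight_rows) if blink_weight_rows else np.zeros((0, nch))
        ),
        signature_freqs=sig_freqs,
    )
    rec = Recording(data=data, rate=rate, layout=layout, marks=marks)
    return rec, truth
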