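"""Shared fixtures and cached heavy computations.

Training runs and large simulations are memoized at module scope so the
same trained model can back several independent checks without repeating
minutes of work.
"""

from __future__ import annotations

import functools

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from silentspeech import (
    ModelConfig, SynthConfig, TrainConfig, build_model, evaluate,
    extract_epochs, filter_stage1, filter_stage2, generate_recording,
    split_dataset, tensorize_epochs, train,
)

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_recording():
    """One subject, 3 sessions × 10 words: the standard small fixture."""
    cfg = SynthConfig(n_subjects=1, sessions_per_subject=3, words_per_session=10, seed=1)
    return generate_recording(cfg)


@functools.lru_cache(maxsize=None)
def two_class_run(class_effect: float, max_iter: int = 300, seed: int = 7):
    """Full pipeline + lite training on a binary vocabulary.

    Returns (EvalReport, history).  Cached: several tests interrogate the
    same run (accuracy level, chance behaviour, monotonicity in the class
    effect).
    """
    cfg = SynthConfig(
        n_subjects=1, sessions_per_subject=12, words_per_session=10,
        words=("forward", "stop"), class_effect=class_effect,
        subject_effect=0.3, seed=seed,
    )
    rec, _ = generate_recording(cfg)
    es = filter_stage2(filter_stage1(extract_epochs(rec)))
    tensors = tensorize_epochs(es)
    tcfg = TrainConfig(max_iter=max_iter, seed=3)
    splits = split_dataset(tensors, tcfg)
    model = build_model(ModelConfig.lite(n_classes=2), seed=5)
    model, history = train(model, splits, tcfg)
    return evaluate(model, splits), history


@functools.lru_cache(maxsize=None)
def out_of_sample_run(seed: int):
    """Two subjects, one held out entirely; binary vocabulary.

    class_effect 2.5 with subject_effect 4.0: the word signal is learnable
    within a subject, but the subject-specific channel mixing dominates it,
    so the learned decision rule does not transfer.
    """
    cfg = SynthConfig(
        n_subjects=2, sessions_per_subject=8, words_per_session=10,
        words=("forward", "stop"), class_effect=2.5, subject_effect=4.0,
        seed=seed,
    )
    rec, _ = generate_recording(cfg)
    es = filter_stage2(filter_stage1(extract_epochs(rec)))
    tensors = tensorize_epochs(es)
    tcfg = TrainConfig(max_iter=150, seed=seed, out_of_sample_subjects=("s01",))
    splits = split_dataset(tensors, tcfg)
    model = build_model(ModelConfig.lite(n_classes=2), seed=seed)
    model, _ = train(model, splits, tcfg)
    return evaluate(model, splits)
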