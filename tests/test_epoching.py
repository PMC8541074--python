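"""Epoch extraction and the two amplitude-modulus filters."""

import math

import numpy as np
import pytest

from silentspeech import (
    Epoch, EpochSet, EventMark, Recording, extract_epochs, filter_stage1,
    filter_stage2, load_epochs, save_epochs,
)


def _epoch_with_total(total: float, rng=None, label="forward") -> Epoch:
    """An epoch whose Σ|x| equals ``total`` exactly (flat positive data)."""
    value = total / (40 * 2048)
    return Epoch(data=np.full((40, 2048), value, dtype=np.float32), label=label,
                 subject_id="s00", session_id="sess00")


def test_extraction_yields_one_full_epoch_per_mark(small_recording):
    rec, truth = small_recording
    es = extract_epochs(rec)
    assert len(es) == len(truth.trials) == 30
    for ep in es:
        assert ep.data.shape == (40, 2048)
    assert es.labels() == list(truth.trials.label)


def test_epoch_data_is_exact_recording_slice(small_recording):
    rec, _ = small_recording
    es = extract_epochs(rec)
    m = rec.marks[3]
    assert np.array_equal(es[3].data, rec.data[:, m.onset:m.onset + 2048])


def test_mark_too_close_to_end_is_skipped():
    rng = np.random.default_rng(0)
    data = rng.normal(size=(40, 25_000))
    marks = [EventMark(onset=i * 2500, label="up") for i in range(9)]
    marks.append(EventMark(onset=25_000 - 100, label="down"))
    rec = Recording(data=data, marks=marks)
    es = extract_epochs(rec)
    assert len(es) == 9
    assert es.provenance["skipped_boundary"] == 1


def test_stage1_removes_nonfinite_zero_channel_and_saturated():
    rng = np.random.default_rng(1)
    epochs = [Epoch(rng.normal(size=(40, 2048)), "up", "s00", "sess00") for _ in range(20)]
    epochs[3].data[5, 100] = np.nan
    epochs[7].data[2, :] = 0.0  # dead channel
    epochs[11].data *= 1e4  # saturated
    out = filter_stage1(EpochSet(epochs=epochs))
    assert len(out) == 17
    s = out.provenance["stage1"]
    assert (s["removed_nonfinite"], s["removed_zero_channel"], s["removed_over_cap"]) == (1, 1, 1)


def test_stage1_with_generous_cap_is_identity():
    rng = np.random.default_rng(2)
    epochs = [Epoch(rng.normal(size=(40, 2048)), "up", "s00", "sess00") for _ in range(10)]
    out = filter_stage1(EpochSet(epochs=epochs), abs_cap=1e12)
    assert out.epochs == epochs


def test_stage1_seeded_corruption_count():
    rng = np.random.default_rng(3)
    epochs = [Epoch(rng.normal(size=(40, 2048)).astype(np.float32), "up", "s00", "sess00")
              for _ in range(100)]
    corrupted = rng.choice(100, size=7, replace=False)
    for i in corrupted:
        epochs[i].data[0, :] = 5e3  # one saturated channel
    out = filter_stage1(EpochSet(epochs=epochs))
    assert len(out) == 93
    assert all(i not in corrupted for i, e in enumerate(epochs) if e in out.epochs)


@pytest.mark.parametrize("n", [20, 100, 1000])
def test_stage2_retains_ceil_95_percent_of_distinct_totals(n):
    rng = np.random.default_rng(n)
    totals = rng.permutation(n) + 1.0
    es = EpochSet(epochs=[_epoch_with_total(t * 1e4) for t in totals])
    out = filter_stage2(es)
    # brute-force oracle: count totals at or below the interpolated percentile
    cutoff = np.percentile([e.total_abs_amplitude for e in es], 95.0)
    expected = int(np.sum([e.total_abs_amplitude <= cutoff for e in es]))
    assert len(out) == expected
    assert abs(len(out) - math.ceil(0.95 * n)) <= 1


def test_stage2_identical_epochs_all_retained():
    es = EpochSet(epochs=[_epoch_with_total(1e5) for _ in range(8)])
    assert len(filter_stage2(es)) == 8


def test_stage2_single_epoch_retained_and_empty_rejected():
    assert len(filter_stage2(EpochSet(epochs=[_epoch_with_total(1.0)]))) == 1
    with pytest.raises(ValueError, match="nonempty"):
        filter_stage2(EpochSet(epochs=[]))


def test_filters_preserve_relative_order():
    rng = np.random.default_rng(4)
    epochs = []
    for i in range(50):
        e = Epoch(rng.normal(size=(40, 2048)).astype(np.float32), "up", "s00", f"sess{i:02d}")
        epochs.append(e)
    out = filter_stage2(filter_stage1(EpochSet(epochs=epochs)))
    surviving_sessions = [e.session_id for e in out]
    original_order = [e.session_id for e in epochs if e in out.epochs]
    assert surviving_sessions == original_order


def test_epochset_hdf5_round_trip(tmp_path, small_recording):
    rec, _ = small_recording
    es = filter_stage1(extract_epochs(rec))
    path = tmp_path / "epochs.h5"
    save_epochs(es, path)
    back = load_epochs(path)
    assert len(back) == len(es)
    assert back.labels() == es.labels()
    assert np.array_equal(back.stack(), es.stack())
    assert back.provenance == es.provenance
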