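"""Index-mask downsampling and 256×256 tensor assembly."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from silentspeech import (
    Epoch, assemble_tensor, default_layout, make_masks, median_rows,
    split_samples, tensorize_epochs,
)
from silentspeech.epoching import EpochSet
from silentspeech.tensorize import load_tensors, save_tensors


def test_factor2_masks_are_even_and_odd_indices():
    dm = make_masks(250.0, 2, length=1024)
    assert dm.rate_out == 125.0
    assert np.array_equal(dm.masks[0], np.arange(0, 1024, 2))
    assert np.array_equal(dm.masks[1], np.arange(1, 1024, 2))


def test_factor4_masks_are_residue_classes():
    dm = make_masks(250.0, 4, length=1024)
    assert dm.rate_out == 62.5
    for r in range(4):
        assert np.array_equal(dm.masks[r], np.arange(r, 1024, 4))


def test_unsupported_factor_rejected():
    with pytest.raises(ValueError, match="factor"):
        make_masks(250.0, 3)


@given(st.integers(0, 2 ** 31 - 1), st.sampled_from([2, 4]))
def test_masks_partition_and_reconstruct_exactly(seed, factor):
    x = np.random.default_rng(seed).standard_normal(64)
    dm = make_masks(500.0, factor, length=64)
    phases = dm.apply(x)
    rebuilt = np.empty_like(x)
    for mask, phase in zip(dm.masks, phases):
        rebuilt[mask] = phase
    assert np.array_equal(rebuilt, x)
    assert sum(p.size for p in phases) == x.size


def _ramp_epoch() -> Epoch:
    data = np.arange(40 * 2048, dtype=float).reshape(40, 2048)
    return Epoch(data=data, label="up", subject_id="s00", session_id="sess00")


def test_split_samples_takes_even_then_odd_columns():
    ep = _ramp_epoch()
    s01, s02 = split_samples(ep)
    assert s01.shape == (40, 1024) and s02.shape == (40, 1024)
    assert np.array_equal(s01, ep.data[:, 0::2])
    assert np.array_equal(s02, ep.data[:, 1::2])
    rebuilt = np.empty_like(ep.data)
    rebuilt[:, 0::2], rebuilt[:, 1::2] = s01, s02
    assert np.array_equal(rebuilt, ep.data)


def test_split_samples_rejects_wrong_shape():
    bad = Epoch(data=np.zeros((40, 1000)), label="up", subject_id="s", session_id="s")
    with pytest.raises(ValueError, match="2048"):
        split_samples(bad)


def test_median_rows_match_elementwise_oracle():
    rng = np.random.default_rng(0)
    layout = default_layout()
    sample = rng.normal(size=(40, 1024))
    rows = median_rows(sample, "Ft7", "T3", layout)
    oracle = np.median(
        np.stack([sample[layout.index_of("Ft7")], sample[layout.index_of("T3")]]), axis=0
    )
    assert rows.shape == (5, 256)
    assert np.array_equal(rows[0], oracle[0::2][:256])
    for p in range(4):
        assert np.array_equal(rows[1 + p], oracle[p::4])


def test_median_of_identical_and_opposite_channels():
    layout = default_layout()
    sample = np.zeros((40, 1024))
    sample[layout.index_of("Ft7")] = 3.5
    sample[layout.index_of("T3")] = 3.5
    assert np.all(median_rows(sample, "Ft7", "T3", layout) == 3.5)
    sample[layout.index_of("T3")] = -3.5
    assert np.all(median_rows(sample, "Ft7", "T3", layout) == 0.0)


def test_median_rows_missing_channel_rejected():
    with pytest.raises(ValueError, match="missing"):
        median_rows(np.zeros((40, 1024)), "Ft7", "Nope", default_layout())


def test_assembled_tensor_shape_and_gapless_row_map():
    rng = np.random.default_rng(1)
    t = assemble_tensor(rng.normal(size=(40, 1024)), label="up")
    assert t.data.shape == (256, 256)
    pos = 0
    for _, start, stop in t.row_map:
        assert start == pos
        pos = stop
    assert pos == 256


def test_62hz_block_is_160_rows_and_125hz_blocks_40_each():
    rng = np.random.default_rng(2)
    t = assemble_tensor(rng.normal(size=(40, 1024)))
    blocks = {name: (stop - start) for name, start, stop in t.row_map}
    assert blocks["ds62_all"] == 160
    assert blocks["ds125_left"] == 40 and blocks["ds125_right"] == 40
    assert blocks["eye_left"] == 3 and blocks["eye_right"] == 3
    assert blocks["median_ft7_t3"] == 5 and blocks["median_ft8_t4"] == 5


def test_downsampled_blocks_contain_exact_phase_data():
    """Lossless phases: the 62.5 Hz block rows are exact sample slices."""
    rng = np.random.default_rng(3)
    sample = rng.normal(size=(40, 1024))
    layout = default_layout()
    t = assemble_tensor(sample, layout)
    ds62 = t.block("ds62_all")
    for ch in range(40):
        for p in range(4):
            assert np.array_equal(ds62[4 * ch + p], sample[ch, p::4])
    left = layout.hemisphere_channels("left")
    ds125 = t.block("ds125_left")
    for i, ch in enumerate(left):
        row = sample[layout.index_of(ch)]
        assert np.array_equal(ds125[2 * i], row[0::2][:256])
        assert np.array_equal(ds125[2 * i + 1], row[1::2][:256])


def test_zero_sample_gives_zero_tensor_with_flagged_eye_rows():
    t = assemble_tensor(np.zeros((40, 1024)))
    assert np.all(t.data == 0.0)


def test_assembly_is_deterministic():
    rng = np.random.default_rng(4)
    sample = rng.normal(size=(40, 1024))
    a = assemble_tensor(sample.copy())
    b = assemble_tensor(sample.copy())
    assert np.array_equal(a.data, b.data)


def test_both_samples_share_label_and_provenance():
    rng = np.random.default_rng(5)
    ep = Epoch(rng.normal(size=(40, 2048)), "help", "s03", "sess01")
    tensors = tensorize_epochs(EpochSet(epochs=[ep]))
    assert len(tensors) == 2
    assert {t.sample_tag for t in tensors} == {"Sample01", "Sample02"}
    for t in tensors:
        assert (t.label, t.subject_id, t.session_id, t.epoch_id) == ("help", "s03", "sess01", 0)


def test_tensor_hdf5_round_trip(tmp_path):
    rng = np.random.default_rng(6)
    ep = Epoch(rng.normal(size=(40, 2048)), "take", "s00", "sess00")
    tensors = tensorize_epochs(EpochSet(epochs=[ep]))
    path = tmp_path / "tensors.h5"
    save_tensors(tensors, path)
    back = load_tensors(path)
    assert len(back) == 2
    assert np.array_equal(back[0].data, tensors[0].data)
    assert back[1].sample_tag == "Sample02"
    assert back[0].row_map == [tuple(b) for b in tensors[0].row_map]
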