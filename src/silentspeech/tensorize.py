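"""Index-mask downsampling and assembly of 256 × 256 input tensors.

Downsampling never discards samples: lowering the rate by a factor f turns
one series into f phase sub-series (indices congruent to 0..f−1 mod f),
which together reconstruct the original exactly.  Each 40 × 2048 epoch is
first split into two 40 × 1024 samples (even/odd columns, 250 Hz); each
sample is then packed into one 256 × 256 tensor:

    eye noise, left triads                      3 rows
    125 Hz phases (first half), left hemisphere 40 rows (20 ch × 2 phases)
    median of Ft7/T3 (125 Hz half + 62.5 Hz)     5 rows
    62.5 Hz phases, all 40 channels            160 rows (40 ch × 4 phases)
    median of Ft8/T4                             5 rows
    125 Hz phases (first half), right hemisphere 40 rows
    eye noise, right triads                      3 rows

The ``row_map`` on every tensor records this block layout explicitly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from .epoching import Epoch, EpochSet
from .layout import ChannelLayout, default_layout
from .ocular import extract_eye_noise

__all__ = [
    "DownsampleMasks",
    "InputTensor",
    "make_masks",
    "split_samples",
    "median_rows",
    "assemble_tensor",
    "tensorize_epochs",
    "save_tensors",
    "load_tensors",
]

TENSOR_SIZE = 256


@dataclass(frozen=True)
class DownsampleMasks:
    """Index masks realizing a lossless rate reduction by an integer factor.

    Mask ``m`` holds the indices congruent to ``m`` modulo the factor; the
    masks are disjoint and cover ``0..length−1``.
    """

    rate_in: float
    rate_out: float
    masks: tuple[np.ndarray, ...]

    @property
    def factor(self) -> int:
        return len(self.masks)

    def apply(self, x: np.ndarray) -> list[np.ndarray]:
        """Select each phase sub-series along the last axis."""
        return [x[..., m] for m in self.masks]


def make_masks(rate_in: float, factor: int, length: int = 1024) -> DownsampleMasks:
    """Build the residue-class index masks for a factor-2 or factor-4 drop."""
    if factor not in (2, 4):
        raise ValueError(f"unsupported downsampling factor {factor} (use 2 or 4)")
    masks = tuple(np.arange(m, length, factor) for m in range(factor))
    return DownsampleMasks(rate_in=rate_in, rate_out=rate_in / factor, masks=masks)


def split_samples(epoch: Epoch) -> tuple[np.ndarray, np.ndarray]:
    """Split a 40 × 2048 epoch into two 40 × 1024 samples at 250 Hz.

    Sample 01 takes the even-index columns, Sample 02 the odd ones;
    interleaving them recovers the epoch exactly.
    """
    d = epoch.data
    if d.ndim != 2 or d.shape[1] != 2048:
        raise ValueError(f"expected channels × 2048 epoch data, got {d.shape}")
    return d[:, 0::2].copy(), d[:, 1::2].copy()


def median_rows(sample: np.ndarray, ch_a: str, ch_b: str, layout: ChannelLayout) -> np.ndarray:
    """Median (= mean, for two channels) series packed into 5 tensor rows.

    Row 0 is the first half of the 125 Hz phase-0 series; rows 1–4 are the
    four 62.5 Hz phase series.
    """
    for ch in (ch_a, ch_b):
        if ch not in layout.names:
            raise ValueError(f"channel {ch!r} missing from layout")
    m = np.median(
        np.stack([sample[layout.index_of(ch_a)], sample[layout.index_of(ch_b)]]), axis=0
    )
    half = TENSOR_SIZE
    rows = [m[0::2][:half]]
    rows += [m[p::4] for p in range(4)]
    return np.stack(rows)


@dataclass(eq=False)
class InputTensor:
    """One assembled 256 × 256 classifier input with its block layout."""

    data: np.ndarray
    label: str
    subject_id: str
    session_id: str
    sample_tag: str  # "Sample01" | "Sample02"
    epoch_id: int
    row_map: list = field(default_factory=list)  # [(block, start, stop), ...]

    def __post_init__(self) -> None:
        if self.data.shape != (TENSOR_SIZE, TENSOR_SIZE):
            raise ValueError(f"tensor must be {TENSOR_SIZE}×{TENSOR_SIZE}, got {self.data.shape}")

    def block(self, name: str) -> np.ndarray:
        for bname, start, stop in self.row_map:
            if bname == name:
                return self.data[start:stop]
        raise KeyError(name)


def _first_half_phases(x: np.ndarray) -> np.ndarray:
    """125 Hz phase rows for one 1024-sample channel: 2 phases, first 256 cols."""
    return np.stack([x[0::2][:TENSOR_SIZE], x[1::2][:TENSOR_SIZE]])


def assemble_tensor(
    sample: np.ndarray,
    layout: ChannelLayout | None = None,
    *,
    label: str = "",
    subject_id: str = "",
    session_id: str = "",
    sample_tag: str = "Sample01",
    epoch_id: int = 0,
) -> InputTensor:
    """Pack one 40 × 1024 sample (250 Hz) into a 256 × 256 input tensor.

    See the module docstring for the block order; ``row_map`` records it on
    the result.  Eye-noise rows are extracted from the 62.5 Hz phase-0
    series of the configured frontal triads, three per hemisphere.
    """
    if layout is None:
        layout = default_layout()
    if sample.shape != (layout.n_channels, 1024):
        raise ValueError(f"expected {layout.n_channels}×1024 sample, got {sample.shape}")
    left, right = layout.hemisphere_channels("left"), layout.hemisphere_channels("right")

    eye_basis = sample[:, 0::4]  # 62.5 Hz phase-0 series, length 256
    eye = extract_eye_noise(eye_basis, layout)
    sides = [layout.frontal_group_side(g) for g in eye.groups]
    eye_left = eye.series[[i for i, s in enumerate(sides) if s == "left"]]
    eye_right = eye.series[[i for i, s in enumerate(sides) if s == "right"]]

    ds125 = {
        side: np.concatenate(
            [_first_half_phases(sample[layout.index_of(ch)]) for ch in chans]
        )
        for side, chans in (("left", left), ("right", right))
    }
    ds62 = np.concatenate(
        [np.stack([sample[i, p::4] for p in range(4)]) for i in range(layout.n_channels)]
    )

    blocks = [
        ("eye_left", eye_left),
        ("ds125_left", ds125["left"]),
        ("median_ft7_t3", median_rows(sample, "Ft7", "T3", layout)),
        ("ds62_all", ds62),
        ("median_ft8_t4", median_rows(sample, "Ft8", "T4", layout)),
        ("ds125_right", ds125["right"]),
        ("eye_right", eye_right),
    ]
    row_map, rows, pos = [], [], 0
    for name, arr in blocks:
        row_map.append((name, pos, pos + arr.shape[0]))
        rows.append(arr)
        pos += arr.shape[0]
    data = np.concatenate(rows)
    if data.shape != (TENSOR_SIZE, TENSOR_SIZE):
        raise ValueError(
            f"assembled tensor is {data.shape}; layout block sizes are inconsistent"
        )
    return InputTensor(
        data=data, label=label, subject_id=subject_id, session_id=session_id,
        sample_tag=sample_tag, epoch_id=epoch_id, row_map=row_map,
    )


def tensorize_epochs(es: EpochSet, layout: ChannelLayout | None = None) -> list[InputTensor]:
    """Build both Sample 01 and Sample 02 tensors for every epoch."""
    if layout is None:
        layout = default_layout()
    tensors = []
    for i, ep in enumerate(es):
        s01, s02 = split_samples(ep)
        for tag, s in (("Sample01", s01), ("Sample02", s02)):
            tensors.append(
                assemble_tensor(
                    s, layout, label=ep.label, subject_id=ep.subject_id,
                    session_id=ep.session_id, sample_tag=tag, epoch_id=i,
                )
            )
    return tensors


# --- HDF5 container ---------------------------------------------------------

def save_tensors(tensors: list[InputTensor], path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=np.stack([t.data for t in tensors]))
        str_dt = h5py.string_dtype()
        for key in ("label", "subject_id", "session_id", "sample_tag"):
            f.create_dataset(key, data=[getattr(t, key) for t in tensors], dtype=str_dt)
        f.create_dataset("epoch_id", data=[t.epoch_id for t in tensors])
        f.attrs["row_map"] = json.dumps(tensors[0].row_map if tensors else [])


def load_tensors(path: str | Path) -> list[InputTensor]:
    with h5py.File(path, "r") as f:
        data = f["data"][...]
        meta = {
            key: [s.decode() for s in f[key][...]]
            for key in ("label", "subject_id", "session_id", "sample_tag")
        }
        epoch_ids = f["epoch_id"][...]
        row_map = [tuple(b) for b in json.loads(f.attrs["row_map"])]
    return [
        InputTensor(
            data=data[i], label=meta["label"][i], subject_id=meta["subject_id"][i],
            session_id=meta["session_id"][i], sample_tag=meta["sample_tag"][i],
            epoch_id=int(epoch_ids[i]), row_map=row_map,
        )
        for i in range(data.shape[0])
    ]
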