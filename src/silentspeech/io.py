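"""Reading and writing multichannel EEG recordings with event marks.

Recordings are stored as EDF+ files (16-bit, one-second data records, TAL
annotation track).  Reading goes through :func:`mne.io.read_raw_edf`, so any
EDF/BDF-family file mne can parse is accepted; event marks are decoded from
the annotation track, or from an optional sidecar CSV
(``<stem>.events.csv`` with columns onset_sample, label, subject_id,
session_id) for files lacking text annotations.  Writing uses a small EDF+
serializer so round-trips stay lossless for channel names and marks and
within 16-bit quantization for the signal.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .layout import ChannelLayout, default_layout

__all__ = [
    "WORDS",
    "EventMark",
    "Recording",
    "FormatError",
    "LayoutMismatchError",
    "read_recording",
    "write_recording",
]

#: Closed nine-word vocabulary: eight command words plus one pseudoword.
WORDS: tuple[str, ...] = (
    "forward", "backward", "up", "down", "help", "take", "stop", "release", "pseudo",
)


class FormatError(ValueError):
    """The file is not a parseable EDF/BDF-family recording."""


class LayoutMismatchError(ValueError):
    """Channel count in the file disagrees with the expected layout."""

    def __init__(self, found: int, expected: int):
        super().__init__(
            f"recording has {found} channels but the layout defines {expected}"
        )
        self.found = found
        self.expected = expected


@dataclass(frozen=True, order=True)
class EventMark:
    """A word-presentation event: onset sample plus trial metadata."""

    onset: int
    label: str
    subject_id: str = "s00"
    session_id: str = "sess00"

    def __post_init__(self) -> None:
        if self.label not in WORDS:
            raise ValueError(f"label {self.label!r} not in the 9-word vocabulary")


@dataclass(eq=False)
class Recording:
    """A channels × samples EEG matrix with rate, layout, and event marks.

    ``data`` is in microvolts, one row per channel in ``layout`` order.
    Marks are kept sorted by onset; onsets are 0-based sample indices in
    ``[0, n_samples)``.
    """

    data: np.ndarray
    rate: float = 500.0
    layout: ChannelLayout = field(default_factory=default_layout)
    marks: list[EventMark] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels × samples)")
        if self.data.shape[0] != self.layout.n_channels:
            raise LayoutMismatchError(self.data.shape[0], self.layout.n_channels)
        self.marks = sorted(self.marks)
        for m in self.marks:
            if not (0 <= m.onset < self.n_samples):
                raise ValueError(f"mark onset {m.onset} outside [0, {self.n_samples})")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate


# --- EDF+ serialization -----------------------------------------------------

_ANN_LABEL = "EDF Annotations"


def _fmt8(value: float) -> bytes:
    """Format a physical min/max into at most 8 ASCII chars, value-exact."""
    s = f"{value:.4g}"
    if len(s) > 8:
        s = f"{value:.2g}"
    return s.encode("ascii")


def _mark_description(m: EventMark) -> str:
    return f"{m.label}|{m.subject_id}|{m.session_id}"


def _parse_description(desc: str) -> tuple[str, str, str] | None:
    parts = desc.split("|")
    if len(parts) == 3 and parts[0] in WORDS:
        return parts[0], parts[1], parts[2]
    if len(parts) == 1 and parts[0] in WORDS:
        return parts[0], "s00", "sess00"
    return None


def write_recording(rec: Recording, path: str | Path) -> None:
    """Serialize ``rec`` to an EDF+ file (plus a sidecar events CSV).

    The signal is quantized to 16 bits against a per-channel symmetric
    physical range, in one-second records; marks go into the EDF+ TAL
    annotation track and, redundantly, into ``<stem>.events.csv``.  The
    trailing partial second, if any, is zero-padded (EDF stores an integer
    number of records).
    """
    path = Path(path)
    rate = int(round(rec.rate))
    nch, ns = rec.data.shape
    n_rec = max(1, int(np.ceil(ns / rate)))
    data = rec.data
    if ns < n_rec * rate:
        data = np.pad(data, ((0, 0), (0, n_rec * rate - ns)))

    pmaxs = []
    for i in range(nch):
        m = float(np.max(np.abs(data[i])))
        pm = float(_fmt8((m if m > 0 else 1.0) * 1.01))
        pmaxs.append(pm)

    # One TAL block per record: the mandatory record-onset stamp followed by
    # the events whose onset falls inside that second.
    events = sorted(rec.marks)
    tals = []
    for r in range(n_rec):
        tal = f"+{r}\x14\x14\x00".encode("ascii")
        for m in events:
            onset_s = m.onset / rec.rate
            if r <= onset_s < r + 1:
                tal += f"+{onset_s:.6f}\x14{_mark_description(m)}\x14\x00".encode("ascii")
        tals.append(tal)
    ann_spr = max(len(t) for t in tals) // 2 + 8  # annotation samples (2 bytes each)

    tot = nch + 1
    hdr = b"0".ljust(8)
    hdr += b"X X X X".ljust(80)
    hdr += b"Startdate 01-JAN-2001 X X X".ljust(80)
    hdr += b"01.01.01" + b"00.00.00"
    hdr += str(256 * (tot + 1)).encode().ljust(8)
    hdr += b"EDF+C".ljust(44)
    hdr += str(n_rec).encode().ljust(8)
    hdr += b"1".ljust(8)
    hdr += str(tot).encode().ljust(4)
    hdr += b"".join([n.encode("ascii").ljust(16) for n in rec.layout.names])
    hdr += _ANN_LABEL.encode().ljust(16)
    hdr += b" " * 80 * tot
    hdr += b"uV".ljust(8) * nch + b" " * 8
    hdr += b"".join(_fmt8(-p).ljust(8) for p in pmaxs) + b"-1".ljust(8)
    hdr += b"".join(_fmt8(p).ljust(8) for p in pmaxs) + b"1".ljust(8)
    hdr += b"-32768".ljust(8) * tot
    hdr += b"32767".ljust(8) * tot
    hdr += b" " * 80 * tot
    hdr += str(rate).encode().ljust(8) * nch + str(ann_spr).encode().ljust(8)
    hdr += b" " * 32 * tot
    assert len(hdr) == 256 * (tot + 1)

    try:
        with open(path, "wb") as f:
            f.write(hdr)
            for r in range(n_rec):
                for i in range(nch):
                    seg = data[i, r * rate:(r + 1) * rate]
                    # inverse of the EDF decode affine:
                    # physical = (dig - dmin) * (pmax - pmin)/(dmax - dmin) + pmin
                    cal = 2 * pmaxs[i] / 65535.0
                    dig = np.clip(np.round((seg + pmaxs[i]) / cal) - 32768, -32768, 32767)
                    f.write(dig.astype("<i2").tobytes())
                f.write(tals[r].ljust(2 * ann_spr, b"\x00"))
    except OSError as e:
        raise OSError(f"cannot write recording to {path}: {e}") from e

    _write_sidecar(rec, path)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".events.csv")


def _write_sidecar(rec: Recording, path: Path) -> None:
    with open(_sidecar_path(path), "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["onset_sample", "label", "subject_id", "session_id"])
        for m in rec.marks:
            w.writerow([m.onset, m.label, m.subject_id, m.session_id])


def _read_sidecar(path: Path) -> list[EventMark] | None:
    sp = _sidecar_path(path)
    if not sp.exists():
        return None
    marks = []
    with open(sp, newline="") as f:
        for row in csv.DictReader(f):
            marks.append(
                EventMark(
                    onset=int(row["onset_sample"]),
                    label=row["label"],
                    subject_id=row.get("subject_id", "s00"),
                    session_id=row.get("session_id", "sess00"),
                )
            )
    return marks


def read_recording(path: str | Path, layout: ChannelLayout | None = None) -> Recording:
    """Read an EDF/BDF-family file into a :class:`Recording`.

    Marks come from the sidecar events CSV when present, otherwise from the
    file's annotation track.  Raises :class:`FormatError` for unparseable
    files and :class:`LayoutMismatchError` when the channel count disagrees
    with ``layout`` (default: the canonical 40-channel layout).
    """
    import mne

    path = Path(path)
    if layout is None:
        layout = default_layout()
    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as e:  # mne raises various concrete types
        raise FormatError(f"cannot parse {path} as an EDF/BDF-family file: {e}") from e

    names = tuple(raw.ch_names)
    if len(names) != layout.n_channels:
        raise LayoutMismatchError(len(names), layout.n_channels)
    if names != layout.names:
        layout = replace(layout, names=names, hemisphere_of={})

    data = raw.get_data(units="uV")
    rate = float(raw.info["sfreq"])

    marks = _read_sidecar(path)
    if marks is None:
        marks = []
        for onset, desc in zip(raw.annotations.onset, raw.annotations.description):
            parsed = _parse_description(str(desc))
            if parsed is None:
                continue
            label, subj, sess = parsed
            marks.append(
                EventMark(int(round(onset * rate)), label, subj, sess)
            )
    return Recording(data=data, rate=rate, layout=layout, marks=marks)
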