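"""Trial windowing and amplitude-based epoch rejection.

An epoch is the 40 × 2048 window starting at a word-presentation mark
(≈4.1 s at 500 Hz, covering the 3 s presentation and part of the blank).
Two amplitude filters follow: the first rejects clearly broken epochs
(non-finite values, all-zero channels, or an absolute-amplitude total above
a hard cap); the second trims the upper tail by dropping epochs whose total
absolute amplitude exceeds the 95th percentile of the survivors.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from .io import Recording

__all__ = [
    "Epoch",
    "EpochSet",
    "extract_epochs",
    "filter_stage1",
    "filter_stage2",
    "save_epochs",
    "load_epochs",
]

log = logging.getLogger(__name__)

EPOCH_LENGTH = 2048


@dataclass(eq=False)
class Epoch:
    """One labeled trial window (channels × samples, microvolts)."""

    data: np.ndarray
    label: str
    subject_id: str
    session_id: str
    rate: float = 500.0

    @property
    def total_abs_amplitude(self) -> float:
        """Σ|x| over all channels and samples — the rejection statistic."""
        return float(np.sum(np.abs(self.data)))


@dataclass(eq=False)
class EpochSet:
    """An ordered collection of epochs plus a log of filter removals."""

    epochs: list[Epoch]
    rate: float = 500.0
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.epochs)

    def __iter__(self):
        return iter(self.epochs)

    def __getitem__(self, i) -> Epoch:
        return self.epochs[i]

    def stack(self) -> np.ndarray:
        return np.stack([e.data for e in self.epochs])

    def labels(self) -> list[str]:
        return [e.label for e in self.epochs]


def extract_epochs(rec: Recording, length: int = EPOCH_LENGTH, offset: int = 0) -> EpochSet:
    """Cut one fixed-length window per mark.

    The window is ``[onset + offset, onset + offset + length)``; marks too
    close to the end of the recording are skipped with a warning rather than
    zero-padded.
    """
    epochs = []
    skipped = 0
    for m in rec.marks:
        start = m.onset + offset
        stop = start + length
        if start < 0 or stop > rec.n_samples:
            log.warning(
                "skipping mark at sample %d (%s): window [%d, %d) outside recording",
                m.onset, m.label, start, stop,
            )
            skipped += 1
            continue
        epochs.append(
            Epoch(
                data=rec.data[:, start:stop].copy(),
                label=m.label,
                subject_id=m.subject_id,
                session_id=m.session_id,
                rate=rec.rate,
            )
        )
    return EpochSet(
        epochs=epochs,
        rate=rec.rate,
        provenance={"n_marks": len(rec.marks), "skipped_boundary": skipped},
    )


def filter_stage1(es: EpochSet, abs_cap: float | None = None) -> EpochSet:
    """First amplitude filter: drop broken or grossly noisy epochs.

    Removes epochs containing non-finite samples, epochs with an all-zero
    channel (missing data), and epochs whose total absolute amplitude
    exceeds ``abs_cap``.  When ``abs_cap`` is None it defaults to 10× the
    median epoch total, a scale-free cap that needs no dataset constant.
    """
    if abs_cap is not None and abs_cap <= 0:
        raise ValueError("abs_cap must be positive")
    totals = np.array([e.total_abs_amplitude for e in es.epochs])
    if abs_cap is None:
        finite = totals[np.isfinite(totals)]
        abs_cap = 10.0 * float(np.median(finite)) if finite.size else np.inf
    kept, n_nonfinite, n_zero_channel, n_over_cap = [], 0, 0, 0
    for e, t in zip(es.epochs, totals):
        if not np.all(np.isfinite(e.data)):
            n_nonfinite += 1
            continue
        if np.any(np.all(e.data == 0.0, axis=1)):
            n_zero_channel += 1
            continue
        if t > abs_cap:
            n_over_cap += 1
            continue
        kept.append(e)
    prov = dict(es.provenance)
    prov["stage1"] = {
        "input": len(es.epochs),
        "removed_nonfinite": n_nonfinite,
        "removed_zero_channel": n_zero_channel,
        "removed_over_cap": n_over_cap,
        "abs_cap": float(abs_cap),
        "output": len(kept),
    }
    return EpochSet(epochs=kept, rate=es.rate, provenance=prov)


def filter_stage2(es: EpochSet, percentile: float = 95.0) -> EpochSet:
    """Second amplitude filter: trim the upper tail of the total-amplitude
    distribution.

    The cutoff is the given percentile (linear interpolation) of the total
    absolute amplitudes of the epochs surviving stage 1; epochs strictly
    above it are removed.  With n distinct totals this retains ⌈0.95·n⌉ ± 1.
    """
    if len(es.epochs) == 0:
        raise ValueError("filter_stage2 requires a nonempty epoch set")
    totals = np.array([e.total_abs_amplitude for e in es.epochs])
    cutoff = float(np.percentile(totals, percentile))
    kept = [e for e, t in zip(es.epochs, totals) if t <= cutoff]
    prov = dict(es.provenance)
    prov["stage2"] = {
        "input": len(es.epochs),
        "percentile": percentile,
        "cutoff": cutoff,
        "removed": len(es.epochs) - len(kept),
        "output": len(kept),
    }
    return EpochSet(epochs=kept, rate=es.rate, provenance=prov)


# --- HDF5 container ---------------------------------------------------------

def save_epochs(es: EpochSet, path: str | Path) -> None:
    """Store an EpochSet as an HDF5 cube with a label table."""
    with h5py.File(path, "w") as f:
        if len(es):
            f.create_dataset("data", data=es.stack())
        else:
            f.create_dataset("data", shape=(0, 0, 0))
        str_dt = h5py.string_dtype()
        f.create_dataset("label", data=[e.label for e in es], dtype=str_dt)
        f.create_dataset("subject_id", data=[e.subject_id for e in es], dtype=str_dt)
        f.create_dataset("session_id", data=[e.session_id for e in es], dtype=str_dt)
        f.attrs["rate"] = es.rate
        f.attrs["provenance"] = json.dumps(es.provenance)


def load_epochs(path: str | Path) -> EpochSet:
    with h5py.File(path, "r") as f:
        data = f["data"][...]
        labels = [s.decode() for s in f["label"][...]]
        subjects = [s.decode() for s in f["subject_id"][...]]
        sessions = [s.decode() for s in f["session_id"][...]]
        rate = float(f.attrs["rate"])
        prov = json.loads(f.attrs["provenance"])
    epochs = [
        Epoch(data=data[i], label=labels[i], subject_id=subjects[i],
              session_id=sessions[i], rate=rate)
        for i in range(len(labels))
    ]
    return EpochSet(epochs=epochs, rate=rate, provenance=prov)
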