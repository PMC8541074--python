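"""Canonical 40-channel montage and hemisphere bookkeeping.

The decoding pipeline is tied to a 40-electrode 10–20-style montage
referenced to Afz, with extra electrodes over the temporal areas.  All
spatial structure the pipeline relies on — the left/right hemisphere
partition, the frontal electrode triads used for ocular-noise extraction
and the temporal groups near the speech areas — lives here.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "ChannelLayout",
    "DEFAULT_CHANNEL_NAMES",
    "default_layout",
    "split_hemispheres",
]

#: The canonical 40-channel montage, in recording order.
DEFAULT_CHANNEL_NAMES: tuple[str, ...] = (
    "Fp1", "Fpz", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "Ft7", "Fc3", "Fcz", "Fc4", "Ft8", "T3", "C3", "Cz",
    "C4", "T4", "Tp7", "Cp3", "Cpz", "Cp4", "Tp8", "C5",
    "Tp9", "P3", "Pz", "P4", "Tp10", "C6", "P5", "Po3",
    "Poz", "Po4", "P6", "Po7", "O1", "Oz", "O2", "Po8",
)

#: Midline electrodes carry a 'z' suffix and belong to neither hemisphere
#: anatomically; the default assignment alternates them front-to-back so the
#: partition stays spatially balanced at 20/20.
_MIDLINE_TO_SIDE: dict[str, str] = {
    "Fpz": "left", "Fz": "right",
    "Fcz": "left", "Cz": "right",
    "Cpz": "left", "Pz": "right",
    "Poz": "left", "Oz": "right",
}

#: Frontal triads used for eye-noise extraction: the four classical groups
#: around the reference plus two symmetric fronto-polar completions, so that
#: three triads sit over each hemisphere.
DEFAULT_FRONTAL_GROUPS: tuple[tuple[str, str, str], ...] = (
    ("Fpz", "Fz", "F3"),
    ("Fp1", "F3", "F7"),
    ("Fpz", "Fz", "F4"),
    ("Fp2", "F4", "F8"),
    ("Fp1", "Fpz", "F3"),
    ("Fp2", "Fpz", "F4"),
)

DEFAULT_TEMPORAL_LEFT: tuple[str, ...] = ("T3", "Ft7", "C5", "Tp7")
DEFAULT_TEMPORAL_RIGHT: tuple[str, ...] = ("T4", "Ft8", "C6", "Tp8")

_TRAILING_DIGITS = re.compile(r"(\d+)$")


def _lateral_side(name: str) -> str | None:
    """Side implied by 10–20 numbering: odd = left, even = right, z = midline."""
    m = _TRAILING_DIGITS.search(name)
    if m is None:
        return None
    return "left" if int(m.group(1)) % 2 == 1 else "right"


def _default_hemisphere_map(names: tuple[str, ...]) -> dict[str, str]:
    out: dict[str, str] = {}
    for name in names:
        side = _lateral_side(name)
        if side is None:
            side = _MIDLINE_TO_SIDE.get(name)
        if side is None:
            raise ValueError(f"cannot infer hemisphere for channel {name!r}")
        out[name] = side
    return out


@dataclass(frozen=True)
class ChannelLayout:
    """Electrode montage with hemisphere and functional-group annotations.

    Parameters
    ----------
    names
        Channel labels in recording order.
    reference
        Label of the reference electrode (not part of ``names``).
    hemisphere_of
        Map from channel label to ``"left"`` or ``"right"``; a total
        partition of ``names``.
    frontal_groups
        Electrode triads over the frontal region used for ocular-noise
        extraction.
    temporal_left, temporal_right
        Electrode groups over the temporal areas (near the speech centres
        on the left).
    """

    names: tuple[str, ...] = DEFAULT_CHANNEL_NAMES
    reference: str = "Afz"
    hemisphere_of: dict[str, str] = field(default_factory=dict)
    frontal_groups: tuple[tuple[str, ...], ...] = DEFAULT_FRONTAL_GROUPS
    temporal_left: tuple[str, ...] = DEFAULT_TEMPORAL_LEFT
    temporal_right: tuple[str, ...] = DEFAULT_TEMPORAL_RIGHT

    def __post_init__(self) -> None:
        if not self.hemisphere_of:
            object.__setattr__(
                self, "hemisphere_of", _default_hemisphere_map(self.names)
            )
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate channel names in layout")
        missing = set(self.names) - set(self.hemisphere_of)
        if missing:
            raise ValueError(f"channels without hemisphere assignment: {sorted(missing)}")
        bad = {v for v in self.hemisphere_of.values()} - {"left", "right"}
        if bad:
            raise ValueError(f"invalid hemisphere values: {sorted(bad)}")
        for group in list(self.frontal_groups) + [self.temporal_left, self.temporal_right]:
            for ch in group:
                if ch not in self.names:
                    raise ValueError(f"group channel {ch!r} not in layout")

    @property
    def n_channels(self) -> int:
        return len(self.names)

    def index_of(self, name: str) -> int:
        return self.names.index(name)

    def indices(self, names) -> list[int]:
        return [self.names.index(n) for n in names]

    def hemisphere_channels(self, side: str) -> tuple[str, ...]:
        """Channels assigned to ``side``, in recording order."""
        return tuple(n for n in self.names if self.hemisphere_of[n] == side)

    def frontal_group_side(self, group: tuple[str, ...]) -> str:
        """Hemisphere a frontal triad sits over (majority of lateral members)."""
        votes = [s for s in (_lateral_side(ch) for ch in group) if s is not None]
        if not votes:
            raise ValueError(f"triad {group} has no lateral channel to lateralize by")
        return "left" if votes.count("left") >= votes.count("right") else "right"

    def frontal_groups_for(self, side: str) -> tuple[tuple[str, ...], ...]:
        return tuple(g for g in self.frontal_groups if self.frontal_group_side(g) == side)


def default_layout() -> ChannelLayout:
    """The canonical 40-channel layout used throughout the pipeline."""
    return ChannelLayout()


def split_hemispheres(layout: ChannelLayout) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Partition the layout's channels into (left, right) label tuples.

    The default montage yields a balanced 20/20 split: lateral electrodes
    follow 10–20 numbering (odd left, even right) and the eight midline
    electrodes alternate sides front-to-back.
    """
    left = layout.hemisphere_channels("left")
    right = layout.hemisphere_channels("right")
    return left, right
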