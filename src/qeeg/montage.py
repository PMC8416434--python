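"""Scalp montage definition for the 19-channel international 10-20 layout.

The analysis montage is the classic 19-site eyes-closed clinical layout.
Channel-name matching is case-insensitive and accepts the legacy
T3/T4/T5/T6 labels for the modern T7/T8/P7/P8 sites, since exported 10-20
datasets vary in which convention they use.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .errors import ChannelMismatchError

#: The 19 channels of the 10-20 system, in canonical analysis order.
DEFAULT_CHANNELS: tuple[str, ...] = (
    "FP1", "FP2", "F7", "F3", "Fz", "F4", "F8",
    "T7", "C3", "Cz", "C4", "T8",
    "P7", "P3", "Pz", "P4", "P8", "O1", "O2",
)

#: Legacy 10-20 aliases (old label -> modern label), upper-cased keys.
LEGACY_ALIASES: dict[str, str] = {"T3": "T7", "T4": "T8", "T5": "P7", "T6": "P8"}


@dataclass(frozen=True)
class ChannelMontage:
    """An ordered set of channel labels plus a free-text reference descriptor."""

    labels: tuple[str, ...] = DEFAULT_CHANNELS
    reference: str = "linked mastoid"

    def __post_init__(self):
        labels = tuple(self.labels)
        if len(set(l.upper() for l in labels)) != len(labels):
            raise ValueError("montage labels must be unique")
        object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        """Index of ``label`` (case-insensitive, legacy aliases accepted)."""
        canon = canonical_label(label)
        lookup = {l.upper(): i for i, l in enumerate(self.labels)}
        try:
            return lookup[canon.upper()]
        except KeyError:
            raise ChannelMismatchError(extra=[label]) from None

    def pairs(self) -> list[tuple[str, str]]:
        """All unordered channel pairs, lexicographic by montage index.

        For the default 19-channel montage this enumerates the 171
        coherence pairs in a stable order.
        """
        labels = self.labels
        return [
            (labels[i], labels[j])
            for i in range(len(labels))
            for j in range(i + 1, len(labels))
        ]


DEFAULT_MONTAGE = ChannelMontage()


def canonical_label(label: str) -> str:
    """Map a raw channel name onto the montage's modern label.

    Case-insensitive; strips the EDF-style "EEG " prefix and reference
    suffixes ("-REF", "-A1A2", ...), and resolves T3/T4/T5/T6 aliases.
    """
    up = label.strip().upper()
    if up.startswith("EEG "):
        up = up[4:].strip()
    up = up.split("-")[0].strip()
    up = LEGACY_ALIASES.get(up, up)
    for canon in DEFAULT_CHANNELS:
        if canon.upper() == up:
            return canon
    return label.strip()


def match_channels(found: Iterable[str], montage: ChannelMontage = DEFAULT_MONTAGE) -> list[int]:
    """Map found channel names onto montage order.

    Returns, for each montage position, the index into ``found`` holding
    that channel. Extra channels (e.g. a 64-channel file) are ignored;
    missing montage channels raise :class:`ChannelMismatchError`.
    """
    found = list(found)
    by_name: dict[str, int] = {}
    for i, name in enumerate(found):
        canon = canonical_label(name).upper()
        if canon not in by_name:  # first occurrence wins
            by_name[canon] = i
    order, missing = [], []
    for label in montage.labels:
        idx = by_name.get(label.upper())
        if idx is None:
            missing.append(label)
        else:
            order.append(idx)
    if missing:
        raise ChannelMismatchError(missing=missing)
    return order
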