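"""Scalp electrode montages.

The analysis montage is a 30-channel subset of the 10/10 placement system
(a 32-electrode cap recorded against CPz with AFz ground leaves 30 scalp
channels for analysis).  Positions are 2-D projections of the standard
spherical layout onto the axial plane: ``x`` increases to the subject's
right, ``y`` toward the nasion, head radius 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ChannelMontage",
    "default_montage",
    "generic_montage",
    "ANTERIOR_CHANNELS",
    "POSTERIOR_CHANNELS",
]

#: Prefrontal electrode group used for anterior regional complexity.
ANTERIOR_CHANNELS = ("Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8")

#: Parieto-occipital electrode group used for posterior regional complexity.
POSTERIOR_CHANNELS = ("T5", "T6", "P3", "P4", "Pz", "O1", "O2")

# Approximate axial-plane projections of the 10/10 positions.
_POSITIONS_1010: dict[str, tuple[float, float]] = {
    "Fp1": (-0.31, 0.95), "Fp2": (0.31, 0.95),
    "F7": (-0.81, 0.59), "F3": (-0.45, 0.55), "Fz": (0.0, 0.50),
    "F4": (0.45, 0.55), "F8": (0.81, 0.59),
    "FT7": (-0.95, 0.31), "FC3": (-0.55, 0.28), "FCz": (0.0, 0.25),
    "FC4": (0.55, 0.28), "FT8": (0.95, 0.31),
    "T3": (-1.00, 0.0), "C3": (-0.50, 0.0), "Cz": (0.0, 0.0),
    "C4": (0.50, 0.0), "T4": (1.00, 0.0),
    "TP7": (-0.95, -0.31), "CP3": (-0.55, -0.28), "CP4": (0.55, -0.28),
    "TP8": (0.95, -0.31),
    "T5": (-0.81, -0.59), "P3": (-0.45, -0.55), "Pz": (0.0, -0.50),
    "P4": (0.45, -0.55), "T6": (0.81, -0.59),
    "POz": (0.0, -0.75),
    "O1": (-0.31, -0.95), "Oz": (0.0, -1.00), "O2": (0.31, -0.95),
}

#: Channel order of the default 30-channel analysis montage.
DEFAULT_CHANNELS: tuple[str, ...] = tuple(_POSITIONS_1010)


@dataclass(frozen=True)
class ChannelMontage:
    """An ordered set of scalp channels with 2-D positions.

    Parameters
    ----------
    names
        Ordered, unique channel labels (10/10 nomenclature).
    positions
        ``(n_channels, 2)`` array of axial-plane coordinates.
    anterior_set, posterior_set
        Disjoint 7-channel regional groups, each a subset of ``names``.
    """

    names: tuple[str, ...]
    positions: np.ndarray
    anterior_set: tuple[str, ...] = ANTERIOR_CHANNELS
    posterior_set: tuple[str, ...] = POSTERIOR_CHANNELS
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        names = tuple(self.names)
        if len(set(names)) != len(names):
            raise ValueError("channel names must be unique")
        pos = np.asarray(self.positions, dtype=float)
        if pos.shape != (len(names), 2):
            raise ValueError(
                f"positions must have shape ({len(names)}, 2), got {pos.shape}"
            )
        for region, label in ((self.anterior_set, "anterior"), (self.posterior_set, "posterior")):
            missing = set(region) - set(names)
            if missing:
                raise ValueError(f"{label} channels missing from montage: {sorted(missing)}")
        if set(self.anterior_set) & set(self.posterior_set):
            raise ValueError("anterior and posterior sets must be disjoint")
        object.__setattr__(self, "names", names)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "_index", {n: i for i, n in enumerate(names)})

    @property
    def n_channels(self) -> int:
        return len(self.names)

    def __len__(self) -> int:
        return len(self.names)

    def indices(self, channels) -> np.ndarray:
        """Integer indices of ``channels`` in montage order."""
        try:
            return np.array([self._index[c] for c in channels], dtype=int)
        except KeyError as err:
            raise KeyError(f"channel {err.args[0]!r} not in montage") from None

    def scope_indices(self, scope: str) -> np.ndarray:
        """Channel indices for a named scope: 'global', 'anterior' or 'posterior'."""
        if scope == "global":
            return np.arange(self.n_channels)
        if scope == "anterior":
            if not self.anterior_set:
                raise ValueError("montage defines no anterior channel set")
            return self.indices(self.anterior_set)
        if scope == "posterior":
            if not self.posterior_set:
                raise ValueError("montage defines no posterior channel set")
            return self.indices(self.posterior_set)
        raise ValueError(f"unknown scope {scope!r}")


def default_montage() -> ChannelMontage:
    """The 30-channel 10/10 analysis montage."""
    pos = np.array([_POSITIONS_1010[c] for c in DEFAULT_CHANNELS])
    return ChannelMontage(names=DEFAULT_CHANNELS, positions=pos)


def generic_montage(n_channels: int) -> ChannelMontage:
    """An abstract montage of ``n_channels`` points on a circle.

    Useful for signal-level simulations (e.g. synchronization studies)
    where electrode identity is irrelevant; it defines no regional sets.
    """
    if n_channels < 1:
        raise ValueError("need at least one channel")
    theta = 2 * np.pi * np.arange(n_channels) / n_channels
    pos = np.column_stack([np.sin(theta), np.cos(theta)])
    names = tuple(f"ch{i:02d}" for i in range(n_channels))
    return ChannelMontage(names=names, positions=pos, anterior_set=(),
                          posterior_set=())
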