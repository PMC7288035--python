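"""Electrode montage: the 16-channel 10-20 layout used throughout the package.

Channel names follow the international 10-20 system; 2D coordinates are the
standard polar projection of the scalp onto the unit head disk (vertex Cz at
the origin, nose towards +y, outer electrode ring at radius 0.9).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The 16 recorded channels, in acquisition order.
CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F4", "Fz", "F3", "T7", "C3", "Cz",
    "C4", "T8", "P4", "Pz", "P3", "O1", "Oz", "O2",
)

# Classic 10-20 polar projection: outer ring (Fp, T, O) at r = 0.9,
# F3/F4/P3/P4 at r = 0.587 (39 deg off the midline), Fz/Pz/C3/C4 at r = 0.451.
_COORDS: dict[str, tuple[float, float]] = {
    "Fp1": (-0.2781, 0.8560),
    "Fp2": (0.2781, 0.8560),
    "F3": (-0.3694, 0.4562),
    "Fz": (0.0, 0.4510),
    "F4": (0.3694, 0.4562),
    "T7": (-0.9, 0.0),
    "C3": (-0.4510, 0.0),
    "Cz": (0.0, 0.0),
    "C4": (0.4510, 0.0),
    "T8": (0.9, 0.0),
    "P3": (-0.3694, -0.4562),
    "Pz": (0.0, -0.4510),
    "P4": (0.3694, -0.4562),
    "O1": (-0.2781, -0.8560),
    "Oz": (0.0, -0.9),
    "O2": (0.2781, -0.8560),
}

#: The four behaviour categories, in the fixed reporting order.
CATEGORIES: tuple[str, ...] = ("HKT_PO", "HKT_Leader", "BSC_PO", "BSC_Leader")

#: Named sensor groups used by the correlation hypotheses.  The frontal group
#: proxies the prefrontal cortex; temporal and parietal together proxy the
#: temporoparietal junction.
SENSOR_GROUPS: dict[str, tuple[str, ...]] = {
    "frontal": ("Fp1", "Fp2", "F3", "Fz", "F4"),
    "occipital": ("O1", "Oz", "O2"),
    "temporal": ("T7", "T8"),
    "parietal": ("P3", "P4"),
}


class MontageError(ValueError):
    """Raised for invalid montage definitions or unknown channel names."""


@dataclass(frozen=True)
class Montage:
    """An ordered set of named electrodes with unit-disk coordinates.

    The channel order is fixed and shared by every matrix and image produced
    from it, so positional indices are meaningful across the whole pipeline.
    """

    names: tuple[str, ...]
    coords: np.ndarray = field(repr=False)  # (n, 2), within the unit disk

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        if len(set(self.names)) != len(self.names):
            raise MontageError("channel names must be unique")
        if coords.shape != (len(self.names), 2):
            raise MontageError(
                f"coords shape {coords.shape} does not match {len(self.names)} channels"
            )
        radii = np.hypot(coords[:, 0], coords[:, 1])
        if np.any(radii > 1.0 + 1e-9):
            bad = self.names[int(np.argmax(radii))]
            raise MontageError(f"electrode {bad} lies outside the unit head disk")

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise MontageError(f"unknown channel {name!r}") from None

    def indices(self, names) -> list[int]:
        return [self.index(n) for n in names]

    def group(self, name: str) -> tuple[str, ...]:
        """Member channels of a named sensor group."""
        try:
            return SENSOR_GROUPS[name]
        except KeyError:
            raise MontageError(
                f"unknown sensor group {name!r}; known: {sorted(SENSOR_GROUPS)}"
            ) from None

    def group_indices(self, name: str) -> list[int]:
        return self.indices(self.group(name))


def default_montage() -> Montage:
    """The 16-channel montage of the study, in acquisition order."""
    return Montage(CHANNELS, np.array([_COORDS[c] for c in CHANNELS]))
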