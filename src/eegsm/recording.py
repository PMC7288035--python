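"""In-memory containers for recordings and whole studies."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .montage import CATEGORIES, Montage, default_montage

ROLES = ("process_owner", "leader")
SYSTEMS = ("HKT", "BSC")

#: Map (system, role) -> category label, in the fixed reporting order.
_ROLE_SHORT = {"process_owner": "PO", "leader": "Leader"}


def category_label(system: str, role: str) -> str:
    if system not in SYSTEMS:
        raise ValueError(f"unknown system {system!r}; expected one of {SYSTEMS}")
    if role not in ROLES:
        raise ValueError(f"unknown role {role!r}; expected one of {ROLES}")
    return f"{system}_{_ROLE_SHORT[role]}"


@dataclass
class Recording:
    """One 60 s multichannel EEG recording with its study labels.

    ``data`` is channels x samples, in microvolt scale before amplitude
    normalization and unitless afterwards.  ``phase_boundary_s`` marks the
    point where the leader stops talking and the process owner takes over
    (metadata only; the signal itself is not phase dependent).
    """

    data: np.ndarray
    rate: float
    montage: Montage = field(default_factory=default_montage)
    pair_id: int = 0
    role: str = "process_owner"
    system: str = "HKT"
    phase_boundary_s: float = 10.0
    normalized: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a channels x samples matrix")
        if self.data.shape[0] != len(self.montage):
            raise ValueError(
                f"{self.data.shape[0]} channels but montage has {len(self.montage)}"
            )
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if self.system not in SYSTEMS:
            raise ValueError(f"unknown system {self.system!r}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate

    @property
    def category(self) -> str:
        return category_label(self.system, self.role)

    def with_data(self, data: np.ndarray, *, normalized: bool | None = None) -> "Recording":
        """Copy of this recording with new samples (labels preserved)."""
        out = replace(self, data=data)
        if normalized is not None:
            out.normalized = normalized
        return out


@dataclass
class Dataset:
    """A full study: ``n_pairs`` subject pairs x 4 recordings each."""

    recordings: list[Recording]
    n_pairs: int
    seed: int | None = None

    def __post_init__(self) -> None:
        by_pair: dict[int, set[str]] = {}
        for rec in self.recordings:
            by_pair.setdefault(rec.pair_id, set()).add(rec.category)
        if len(by_pair) != self.n_pairs:
            raise ValueError(
                f"expected {self.n_pairs} pairs, found {len(by_pair)} pair ids"
            )
        for pid, cats in sorted(by_pair.items()):
            if cats != set(CATEGORIES):
                raise ValueError(
                    f"pair {pid} has categories {sorted(cats)}; "
                    f"expected exactly one recording per category"
                )
        rates = {rec.rate for rec in self.recordings}
        durs = {rec.n_samples for rec in self.recordings}
        if len(rates) > 1 or len(durs) > 1:
            raise ValueError("all recordings must share rate and duration")

    def __len__(self) -> int:
        return len(self.recordings)

    def __iter__(self):
        return iter(self.recordings)

    @property
    def pair_ids(self) -> list[int]:
        return sorted({rec.pair_id for rec in self.recordings})

    def by_category(self, category: str) -> list[Recording]:
        return [r for r in self.recordings if r.category == category]

    def map(self, fn) -> "Dataset":
        """Apply ``fn`` to every recording, keeping the study structure."""
        return Dataset([fn(r) for r in self.recordings], self.n_pairs, self.seed)
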