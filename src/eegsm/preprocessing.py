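"""Signal conditioning: drift-removing high-pass, 50 Hz low-pass, and
amplitude normalisation to [-10, 10].

The chain order is fixed (high-pass, then low-pass, then normalise) and all
filters are applied zero-phase (forward-backward), so no stage introduces a
time shift.  Normalisation is one affine map per recording over all channels
jointly: per-channel scaling would destroy the inter-channel amplitude
relationships that the topographic maps display.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .recording import Recording

#: Default high-pass cutoff (Hz); matches the sensor's lower bandwidth edge.
DEFAULT_HP_CUTOFF = 0.2
#: Default low-pass cutoff (Hz).
DEFAULT_LP_CUTOFF = 50.0
#: Default amplitude bound after normalisation (unitless).
DEFAULT_BOUND = 10.0


class FilterError(ValueError):
    """Raised for invalid filter specifications."""


@dataclass(frozen=True)
class FilterSpec:
    """A one-sided recursive filter design.

    The low-pass default order (8) is chosen so that the zero-phase
    (twice-applied) Butterworth response attenuates power by at least 20 dB
    at 1.2x the cutoff; order 4 suffices for the drift-removing high-pass.
    """

    kind: str  # "high-pass" | "low-pass"
    cutoff_hz: float
    order: int = 4
    family: str = "butterworth"

    def __post_init__(self) -> None:
        if self.kind not in ("high-pass", "low-pass"):
            raise FilterError(f"unknown filter kind {self.kind!r}")
        if self.cutoff_hz <= 0:
            raise FilterError("cutoff must be positive")
        if self.order < 1:
            raise FilterError("order must be at least 1")
        if self.family != "butterworth":
            raise FilterError(f"unsupported design family {self.family!r}")

    def sos(self, rate: float) -> np.ndarray:
        if self.cutoff_hz >= rate / 2:
            raise FilterError(
                f"cutoff {self.cutoff_hz} Hz is at or above Nyquist ({rate / 2} Hz)"
            )
        btype = "highpass" if self.kind == "high-pass" else "lowpass"
        return signal.butter(self.order, self.cutoff_hz, btype=btype,
                             fs=rate, output="sos")


def _apply_zero_phase(rec: Recording, spec: FilterSpec) -> Recording:
    sos = spec.sos(rec.rate)
    # reflect padding, 3x the effective filter length, as in standard
    # zero-phase practice; keeps edge transients off the analysed span
    padlen = min(rec.n_samples - 1, 3 * (2 * spec.order + 1))
    out = signal.sosfiltfilt(sos, rec.data, axis=1, padtype="even", padlen=padlen)
    if not np.all(np.isfinite(out)):
        raise FilterError("filtering produced non-finite values")
    return rec.with_data(out)


def remove_drift(rec: Recording, spec: FilterSpec | None = None) -> Recording:
    """High-pass the recording to remove DC offset and slow drift."""
    spec = spec or FilterSpec("high-pass", DEFAULT_HP_CUTOFF, order=4)
    if spec.kind != "high-pass":
        raise FilterError("remove_drift requires a high-pass FilterSpec")
    return _apply_zero_phase(rec, spec)


def band_limit(rec: Recording, spec: FilterSpec | None = None) -> Recording:
    """Low-pass the recording to remove power above the cutoff."""
    spec = spec or FilterSpec("low-pass", DEFAULT_LP_CUTOFF, order=8)
    if spec.kind != "low-pass":
        raise FilterError("band_limit requires a low-pass FilterSpec")
    return _apply_zero_phase(rec, spec)


def normalize_amplitude(rec: Recording, bound: float = DEFAULT_BOUND) -> Recording:
    """Affinely map the whole recording onto [-bound, +bound].

    One map for all channels jointly: the global minimum lands on -bound and
    the global maximum on +bound, preserving relative structure across
    channels.  Pearson correlations between channels are invariant under
    this map.  Idempotent (re-normalising changes nothing).
    """
    lo, hi = float(rec.data.min()), float(rec.data.max())
    if hi == lo:
        raise ValueError("cannot normalise a constant recording (zero range)")
    out = 2.0 * bound * (rec.data - lo) / (hi - lo) - bound
    return rec.with_data(out, normalized=True)


def preprocess(rec: Recording, hp_cutoff: float = DEFAULT_HP_CUTOFF,
               lp_cutoff: float = DEFAULT_LP_CUTOFF,
               bound: float = DEFAULT_BOUND) -> Recording:
    """The full conditioning chain: high-pass -> low-pass -> normalise."""
    out = remove_drift(rec, FilterSpec("high-pass", hp_cutoff, order=4))
    out = band_limit(out, FilterSpec("low-pass", lp_cutoff, order=8))
    return normalize_amplitude(out, bound)
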