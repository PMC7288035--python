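"""Synthetic correlated-EEG generator.

The study's real recordings are not publicly deposited, so every downstream
stage is exercised on surrogate data whose *cross-channel correlation
structure* encodes the condition being simulated.  Each of the four
behaviour categories gets a :class:`ConditionProfile`: a list of directives
that pin the Pearson correlation between (or within) named sensor groups to
a target level.  Signals are band-limited Gaussian noise mixed through a
factor of the target correlation matrix, so the zero-lag correlations of the
output converge to the target; optional slow drift and 50 Hz line components
emulate the acquisition artifacts the preprocessing stage must remove.

Two ready-made profile sets are provided:

* :func:`default_profiles` encodes the five sensor-group hypotheses
  (strong couplings at 0.65, weak at 0.20, baseline 0.15) and is the set
  used by the correlation analysis.
* :func:`separable_profiles` couples sensor groups with opposite polarity
  (+0.9 within / -0.9 between over a distinct group bipartition per
  category).  Because topographic images are min-max colour-scaled per
  segment, only polarity contrasts of this kind survive into the rendered
  image; this is the set used to validate the image classifier (see
  docs/methods.md for the information-ceiling analysis behind this).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .correlation import CorrelationMatrix
from .montage import CATEGORIES, Montage, default_montage
from .recording import Dataset, Recording

#: Default directive levels for the hypothesis-encoding profiles.
STRONG = 0.65
WEAK = 0.20
BASELINE = 0.15

#: Passband of the simulated band-limited noise (Hz).  Chosen inside the
#: sensor bandwidth of 0.2-43 Hz; a common linear band-pass applied to all
#: channels preserves the zero-lag correlation structure of the mixture.
NOISE_BAND = (1.0, 40.0)

#: RMS amplitude of the simulated brain signal, microvolts.
SIGNAL_SCALE_UV = 20.0


class ProfileError(ValueError):
    """Raised for directives that do not resolve against the montage."""


@dataclass(frozen=True)
class Directive:
    """Pin the correlation between two sensor groups to ``level``.

    ``relation`` is ``"within"`` (off-diagonal entries inside one group;
    requires ``group_a == group_b``) or ``"between"`` (all cross entries of
    two disjoint groups).
    """

    group_a: str
    group_b: str
    relation: str
    level: float

    def __post_init__(self) -> None:
        if self.relation not in ("within", "between"):
            raise ProfileError(f"unknown relation {self.relation!r}")
        if not -1.0 <= self.level <= 1.0:
            raise ProfileError(f"target level {self.level} outside [-1, 1]")
        if self.relation == "within" and self.group_a != self.group_b:
            raise ProfileError("within-directive requires a single group")


@dataclass(frozen=True)
class ArtifactSettings:
    """Acquisition artifacts added on top of the brain-signal mixture.

    ``drift_amplitude_uv`` scales a slow (< 0.1 Hz) sinusoidal drift per
    channel, emulating the DC drifts seen in AC-coupled recordings;
    ``line_amplitude_uv`` adds a 50 Hz mains component (zero by default:
    the simulated sensor applies a hardware notch).
    """

    drift_amplitude_uv: float = 40.0
    line_amplitude_uv: float = 0.0


@dataclass(frozen=True)
class ConditionProfile:
    """Generative description of one behaviour category."""

    category: str
    directives: tuple[Directive, ...] = ()
    baseline: float = BASELINE
    artifacts: ArtifactSettings = field(default_factory=ArtifactSettings)

    def __post_init__(self) -> None:
        if not -1.0 <= self.baseline <= 1.0:
            raise ProfileError("baseline outside [-1, 1]")
        strong_levels = [abs(d.level) for d in self.directives if abs(d.level) > 0.5]
        if strong_levels and abs(self.baseline) >= min(strong_levels):
            raise ProfileError("baseline must stay below any strong directive level")

    def validate(self, montage: Montage) -> None:
        for d in self.directives:
            montage.group(d.group_a)
            montage.group(d.group_b)


def nearest_correlation_matrix(a: np.ndarray, tol: float = 1e-8,
                               max_iter: int = 100) -> tuple[np.ndarray, float]:
    """Project a symmetric matrix to the nearest valid correlation matrix.

    Alternates eigenvalue clipping with diagonal renormalisation until the
    smallest eigenvalue clears ``-tol``.  Returns the repaired matrix and
    the largest absolute change made to any entry.
    """
    x = np.asarray(a, dtype=float).copy()
    for _ in range(max_iter):
        w, v = np.linalg.eigh(x)
        if w.min() >= -tol:
            break
        w = np.clip(w, 0.0, None)
        x = (v * w) @ v.T
        d = np.sqrt(np.diag(x))
        x = x / np.outer(d, d)
        x = (x + x.T) / 2.0
        np.fill_diagonal(x, 1.0)
    x = np.clip(x, -1.0, 1.0)
    np.fill_diagonal(x, 1.0)
    return x, float(np.max(np.abs(x - a)))


def directive_matrix(profile: ConditionProfile, montage: Montage) -> np.ndarray:
    """The raw blockwise target before the positive-semidefinite repair."""
    profile.validate(montage)
    n = len(montage)
    m = np.full((n, n), float(profile.baseline))
    np.fill_diagonal(m, 1.0)
    for d in profile.directives:
        ia = montage.group_indices(d.group_a)
        ib = montage.group_indices(d.group_b)
        for i in ia:
            for j in ib:
                if i != j:
                    m[i, j] = m[j, i] = d.level
    return m


def build_target_correlation(profile: ConditionProfile, montage: Montage | None = None,
                             *, delta_tolerance: float = 0.05) -> CorrelationMatrix:
    """Build the generative target correlation matrix for one condition.

    Entries are set blockwise from the profile's directives (baseline
    elsewhere), then projected to the nearest valid correlation matrix.  If
    the projection moves any entry by more than ``delta_tolerance`` the
    directive set is infeasible as stated and a warning reports the maximum
    change; the projected (valid) matrix is returned either way, with the
    change recorded in ``projection_delta``.
    """
    montage = montage or default_montage()
    raw = directive_matrix(profile, montage)
    repaired, delta = nearest_correlation_matrix(raw)
    if delta > delta_tolerance:
        warnings.warn(
            f"directive set for {profile.category!r} is not jointly feasible; "
            f"nearest-correlation projection changed entries by up to {delta:.3f}",
            stacklevel=2,
        )
    out = CorrelationMatrix(repaired, montage, provenance="target",
                            category=profile.category)
    out.projection_delta = delta
    return out


def _band_limited_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                        rate_hz: float, band: tuple[float, float]) -> np.ndarray:
    lo, hi = band
    hi = min(hi, 0.499 * rate_hz)
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=rate_hz, output="sos")
    white = rng.standard_normal((n_channels, n_samples))
    x = signal.sosfiltfilt(sos, white, axis=1)
    # common per-channel standardisation keeps the mixing algebra exact
    return x / x.std(axis=1, keepdims=True)


def simulate_recording(target: CorrelationMatrix | np.ndarray, duration_s: float = 60.0,
                       rate_hz: float = 128.0, artifacts: ArtifactSettings | None = None,
                       seed: int = 0, *, montage: Montage | None = None,
                       pair_id: int = 0, role: str = "process_owner",
                       system: str = "HKT") -> Recording:
    """Simulate one recording with the given target correlation structure.

    Independent band-limited Gaussian channels are mixed through a square
    root of the target matrix, so the empirical zero-lag Pearson matrix of
    the output converges to ``target`` as the recording grows.  Deterministic
    for a fixed ``seed``.
    """
    if isinstance(target, CorrelationMatrix):
        montage = montage or target.montage
        tvals = target.values
    else:
        montage = montage or default_montage()
        tvals = np.asarray(target, dtype=float)
    n = len(montage)
    n_samples = int(round(duration_s * rate_hz))
    if n_samples < 2:
        raise ValueError("duration_s x rate_hz must be at least 2 samples")
    w, v = np.linalg.eigh(tvals)
    if w.min() < -1e-8:
        raise ValueError(
            f"target is not positive semidefinite (eigenvalue {w.min():.3e})"
        )
    factor = v * np.sqrt(np.clip(w, 0.0, None))

    rng = np.random.default_rng(seed)
    noise = _band_limited_noise(rng, n, n_samples, rate_hz, NOISE_BAND)
    data = SIGNAL_SCALE_UV * (factor @ noise)

    art = artifacts or ArtifactSettings()
    t = np.arange(n_samples) / rate_hz
    if art.drift_amplitude_uv:
        freqs = rng.uniform(0.02, 0.1, size=n)
        phases = rng.uniform(0, 2 * np.pi, size=n)
        data += art.drift_amplitude_uv * np.sin(
            2 * np.pi * freqs[:, None] * t[None, :] + phases[:, None])
    if art.line_amplitude_uv:
        phases = rng.uniform(0, 2 * np.pi, size=n)
        data += art.line_amplitude_uv * np.sin(
            2 * np.pi * 50.0 * t[None, :] + phases[:, None])
    return Recording(data, rate_hz, montage, pair_id=pair_id, role=role,
                     system=system, phase_boundary_s=10.0)


def _recording_seed(global_seed: int, pair: int, cond: int) -> int:
    """Counter-based per-recording seed: stable under pair-count changes."""
    ss = np.random.SeedSequence((int(global_seed), int(pair), int(cond)))
    return int(ss.generate_state(1)[0] % (2**31))


_CATEGORY_LABELS = {
    "HKT_PO": ("HKT", "process_owner"),
    "HKT_Leader": ("HKT", "leader"),
    "BSC_PO": ("BSC", "process_owner"),
    "BSC_Leader": ("BSC", "leader"),
}


def generate_study(n_pairs: int, profiles: dict[str, ConditionProfile] | list[ConditionProfile],
                   seed: int = 0, *, duration_s: float = 60.0, rate_hz: float = 128.0,
                   montage: Montage | None = None) -> Dataset:
    """Generate a study-shaped dataset: ``n_pairs`` x 4 condition recordings.

    One recording per pair per category, each with an independent seed
    derived from the global seed and the (pair, condition) counters, so
    changing the pair count never reshuffles earlier pairs.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be at least 1")
    if isinstance(profiles, (list, tuple)):
        profiles = {p.category: p for p in profiles}
    missing = set(CATEGORIES) - set(profiles)
    if missing:
        raise ValueError(f"need one profile per category; missing {sorted(missing)}")
    montage = montage or default_montage()
    targets = {c: build_target_correlation(profiles[c], montage) for c in CATEGORIES}
    recs = []
    for pair in range(n_pairs):
        for ci, cat in enumerate(CATEGORIES):
            system, role = _CATEGORY_LABELS[cat]
            recs.append(simulate_recording(
                targets[cat], duration_s, rate_hz, profiles[cat].artifacts,
                seed=_recording_seed(seed, pair, ci), montage=montage,
                pair_id=pair, role=role, system=system))
    return Dataset(recs, n_pairs, seed)


def default_profiles(strong: float = STRONG, weak: float = WEAK,
                     baseline: float = BASELINE) -> dict[str, ConditionProfile]:
    """Hypothesis-encoding profiles for the four behaviour categories.

    Every category couples the frontal group internally (H3) and the
    occipital group internally; leaders additionally couple frontal to
    occipital (H1) while process owners leave that link weak (H2); HKT
    categories couple frontal to the temporal and parietal groups (H4)
    while BSC categories leave those links weak (H5).

    Each category's strongly coupled groups form one *coherent set*: every
    within- and between-group link inside the set is pinned to ``strong``.
    Pinning only the hypothesis-named links and leaving the transitively
    implied ones (e.g. occipital-temporal when both couple to frontal) at
    baseline yields an infeasible matrix whose positive-semidefinite repair
    drags the named links well below their target; the coherent-set form is
    feasible essentially as stated, so the generated data carries the
    hypothesised structure at the nominal levels.
    """
    def prof(cat, coherent, weak_links, solo=()):
        ds = []
        for i, ga in enumerate(coherent):
            ds.append(Directive(ga, ga, "within", strong))
            for gb in coherent[i + 1:]:
                ds.append(Directive(ga, gb, "between", strong))
        for ga in solo:  # internally coherent but outside the coupled set
            ds.append(Directive(ga, ga, "within", strong))
        for ga, gb in weak_links:
            ds.append(Directive(ga, gb, "between", weak))
        return ConditionProfile(cat, tuple(ds), baseline)

    return {
        # PO speaks: frontal+TPJ cohere; occipital coheres internally but
        # ties to frontal only weakly (H2, H3, H4)
        "HKT_PO": prof("HKT_PO", ("frontal", "temporal", "parietal"),
                       [("frontal", "occipital")], solo=("occipital",)),
        # leader listens: everything coheres (H1, H3, H4)
        "HKT_Leader": prof("HKT_Leader",
                           ("frontal", "occipital", "temporal", "parietal"), []),
        # PO speaks, BSC: frontal and occipital each internally coherent,
        # all frontal links outward weak (H2, H3, H5)
        "BSC_PO": prof("BSC_PO", ("frontal",),
                       [("frontal", "occipital"), ("frontal", "temporal"),
                        ("frontal", "parietal")], solo=("occipital",)),
        # leader listens, BSC: frontal+occipital cohere, TPJ stays weak
        # (H1, H3, H5)
        "BSC_Leader": prof("BSC_Leader", ("frontal", "occipital"),
                           [("frontal", "temporal"), ("frontal", "parietal")]),
    }


def identity_profiles() -> dict[str, ConditionProfile]:
    """Null profiles: no directives, zero baseline (uncorrelated channels)."""
    return {c: ConditionProfile(c, (), 0.0) for c in CATEGORIES}


def profile_set(name: str) -> dict[str, ConditionProfile]:
    """Look up a named profile set: default | separable | identity."""
    sets = {"default": default_profiles, "separable": separable_profiles,
            "identity": identity_profiles}
    try:
        return sets[name]()
    except KeyError:
        raise ValueError(
            f"unknown profile set {name!r}; known: {sorted(sets)}"
        ) from None


def separable_profiles(level: float = 0.9) -> dict[str, ConditionProfile]:
    """Profiles whose rendered topographic maps are class-separable.

    Each category couples a different bipartition of the sensor groups with
    opposite polarity (+level within each side, -level across), producing a
    distinct two-block colour template in every min-max scaled map:

    * HKT_PO      - frontal vs occipital in antiphase
    * HKT_Leader  - frontal+occipital vs temporal+parietal in antiphase
    * BSC_PO      - frontal vs temporal+parietal in antiphase
    * BSC_Leader  - occipital vs temporal+parietal in antiphase
    """
    def block(groups_pos, groups_neg):
        ds = []
        for gs in (groups_pos, groups_neg):
            for i, ga in enumerate(gs):
                ds.append(Directive(ga, ga, "within", level))
                for gb in gs[i + 1:]:
                    ds.append(Directive(ga, gb, "between", level))
        for ga in groups_pos:
            for gb in groups_neg:
                ds.append(Directive(ga, gb, "between", -level))
        return tuple(ds)

    tpj = ("temporal", "parietal")
    return {
        "HKT_PO": ConditionProfile("HKT_PO", block(("frontal",), ("occipital",)), 0.0),
        "HKT_Leader": ConditionProfile(
            "HKT_Leader", block(("frontal", "occipital"), tpj), 0.0),
        "BSC_PO": ConditionProfile("BSC_PO", block(("frontal",), tpj), 0.0),
        "BSC_Leader": ConditionProfile("BSC_Leader", block(("occipital",), tpj), 0.0),
    }
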