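"""Channel-correlation analysis: per-recording Pearson matrices, category
averages, difference maps, and the evaluation of the five sensor-group
hypotheses.

The five hypotheses relate the two behaviour roles (process owner / leader)
and the two management systems (HKT / BSC) to coupling between named sensor
groups:

* H1 - leaders show strong frontal <-> occipital coupling (they listen).
* H2 - process owners show strong coupling *within* the frontal and within
  the occipital group (they speak), but not between the two groups.
* H3 - everyone shows strong coupling within the frontal group
  (goal-directed executive behaviour).
* H4 - HKT practitioners show strong frontal <-> temporal/parietal coupling.
* H5 - BSC practitioners show only weak frontal <-> temporal/parietal
  coupling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .montage import Montage, SENSOR_GROUPS, default_montage
from .recording import Recording


class CorrelationError(ValueError):
    """Raised for invalid correlation-matrix operations."""


@dataclass
class SensorGroup:
    """A named subset of montage channels."""

    name: str
    members: tuple[str, ...]

    def indices(self, montage: Montage) -> list[int]:
        return montage.indices(self.members)


def named_group(name: str) -> SensorGroup:
    if name not in SENSOR_GROUPS:
        raise CorrelationError(
            f"unknown sensor group {name!r}; known: {sorted(SENSOR_GROUPS)}"
        )
    return SensorGroup(name, SENSOR_GROUPS[name])


@dataclass
class CorrelationMatrix:
    """A symmetric 16x16 matrix in montage order.

    ``provenance`` records what the entries are: a single recording, a
    category average, a generator target, or a difference of two matrices
    (only a difference may have a non-unit diagonal and entries in [-2, 2]).
    """

    values: np.ndarray
    montage: Montage = field(default_factory=default_montage)
    provenance: str = "single_recording"
    category: str | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.montage)
        if v.shape != (n, n):
            raise CorrelationError(f"expected a {n}x{n} matrix, got {v.shape}")
        if not np.allclose(v, v.T, atol=1e-10):
            raise CorrelationError("matrix must be symmetric")
        bound = 2.0 if self.provenance == "difference" else 1.0
        if np.any(np.abs(v) > bound + 1e-9):
            raise CorrelationError(f"entries must lie in [-{bound}, {bound}]")
        if self.provenance != "difference" and not np.allclose(np.diag(v), 1.0, atol=1e-9):
            raise CorrelationError("non-difference matrices must have unit diagonal")
        self.values = (v + v.T) / 2.0

    def entry(self, a: str, b: str) -> float:
        return float(self.values[self.montage.index(a), self.montage.index(b)])

    @property
    def colorscale_bound(self) -> float:
        """Symmetric colour bound: max |entry| for differences, else 1."""
        if self.provenance == "difference":
            return float(np.max(np.abs(self.values)))
        return 1.0


def correlation_matrix(rec: Recording, span: str = "full") -> CorrelationMatrix:
    """Zero-lag Pearson correlation between all channel pairs.

    ``span`` selects the analysed stretch: ``"full"`` uses the whole
    recording, ``"exclude_first_10s"`` drops the leader-talks phase.
    """
    if span == "full":
        data = rec.data
    elif span == "exclude_first_10s":
        start = int(round(rec.phase_boundary_s * rec.rate))
        data = rec.data[:, start:]
    else:
        raise CorrelationError(f"unknown span {span!r}")
    if data.shape[1] < 2:
        raise CorrelationError("need at least 2 samples")
    sd = data.std(axis=1)
    if np.any(sd == 0):
        bad = rec.montage.names[int(np.argmin(sd))]
        raise CorrelationError(f"channel {bad} has zero variance")
    r = np.corrcoef(data)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(np.clip(r, -1.0, 1.0), rec.montage,
                             provenance="single_recording", category=rec.category)


def average_correlation(mats: list[CorrelationMatrix],
                        method: str = "fisher_z") -> CorrelationMatrix:
    """Elementwise average of correlation matrices across recordings.

    ``fisher_z`` (default) averages on the variance-stabilised atanh scale
    and transforms back; ``arithmetic`` averages the raw coefficients.
    """
    if not mats:
        raise CorrelationError("cannot average an empty list of matrices")
    montage = mats[0].montage
    for m in mats:
        if m.montage.names != montage.names:
            raise CorrelationError("matrices use different montages")
    stack = np.stack([m.values for m in mats])
    if method == "fisher_z":
        z = np.arctanh(np.clip(stack, -1 + 1e-15, 1 - 1e-15))
        avg = np.tanh(z.mean(axis=0))
    elif method == "arithmetic":
        avg = stack.mean(axis=0)
    else:
        raise CorrelationError(f"unknown averaging method {method!r}")
    np.fill_diagonal(avg, 1.0)
    cats = {m.category for m in mats}
    return CorrelationMatrix(avg, montage, provenance="category_average",
                             category=cats.pop() if len(cats) == 1 else None)


def difference(ma: CorrelationMatrix, mb: CorrelationMatrix) -> CorrelationMatrix:
    """Elementwise ``ma - mb`` (antisymmetric under operand swap)."""
    if ma.montage.names != mb.montage.names:
        raise CorrelationError("matrices use different montages")
    return CorrelationMatrix(ma.values - mb.values, ma.montage, provenance="difference")


@dataclass
class GroupStats:
    """Aggregate over the correlation entries linking two sensor groups."""

    minimum: float
    maximum: float
    mean: float
    entries: list[tuple[str, str, float]]

    @property
    def n(self) -> int:
        return len(self.entries)


def group_summary(m: CorrelationMatrix, a: SensorGroup, b: SensorGroup,
                  relation: str) -> GroupStats:
    """Min/max/mean over the entries linking groups ``a`` and ``b``.

    ``between`` uses all |a| x |b| cross entries (groups must be disjoint);
    ``within`` requires ``a == b`` and uses the off-diagonal entries inside
    the group.
    """
    names = m.montage.names
    if relation == "within":
        if set(a.members) != set(b.members):
            raise CorrelationError("within-relation requires a single group")
        idx = a.indices(m.montage)
        entries = [(names[i], names[j], float(m.values[i, j]))
                   for k, i in enumerate(idx) for j in idx[k + 1:]]
    elif relation == "between":
        if set(a.members) & set(b.members):
            raise CorrelationError(
                f"groups {a.name!r} and {b.name!r} overlap under 'between'"
            )
        ia, ib = a.indices(m.montage), b.indices(m.montage)
        entries = [(names[i], names[j], float(m.values[i, j]))
                   for i in ia for j in ib]
    else:
        raise CorrelationError(f"unknown relation {relation!r}")
    vals = np.array([e[2] for e in entries])
    return GroupStats(float(vals.min()), float(vals.max()), float(vals.mean()), entries)


@dataclass
class HypothesisSpec:
    """One testable coupling expectation over sensor groups.

    ``pairs`` lists (group_a, group_b, relation) triples whose entries are
    pooled; ``expectation`` is ``"strong"`` (entries should exceed
    ``theta_strong``) or ``"weak"`` (entries should stay below
    ``theta_weak``).
    """

    id: str
    categories: tuple[str, ...]
    pairs: tuple[tuple[str, str, str], ...]
    expectation: str
    theta_strong: float = 0.5
    theta_weak: float = 0.4

    def __post_init__(self) -> None:
        if self.expectation not in ("strong", "weak"):
            raise CorrelationError(f"unknown expectation {self.expectation!r}")
        if not self.theta_weak < self.theta_strong:
            raise CorrelationError("theta_weak must be below theta_strong")


def default_hypotheses(theta_strong: float = 0.5,
                       theta_weak: float = 0.4) -> list[HypothesisSpec]:
    """The five sensor-group hypotheses at the default thresholds.

    ``theta_strong`` = 0.5 sits just below the 0.52-0.71 range reported for
    clearly strong couplings; ``theta_weak`` = 0.4 sits above the <= 0.23
    range reported for clearly weak ones.
    """
    return [
        HypothesisSpec("H1", ("HKT_Leader", "BSC_Leader"),
                       (("frontal", "occipital", "between"),),
                       "strong", theta_strong, theta_weak),
        HypothesisSpec("H2", ("HKT_PO", "BSC_PO"),
                       (("frontal", "frontal", "within"),
                        ("occipital", "occipital", "within")),
                       "strong", theta_strong, theta_weak),
        HypothesisSpec("H3", ("HKT_PO", "HKT_Leader", "BSC_PO", "BSC_Leader"),
                       (("frontal", "frontal", "within"),),
                       "strong", theta_strong, theta_weak),
        HypothesisSpec("H4", ("HKT_PO", "HKT_Leader"),
                       (("frontal", "temporal", "between"),
                        ("frontal", "parietal", "between")),
                       "strong", theta_strong, theta_weak),
        HypothesisSpec("H5", ("BSC_PO", "BSC_Leader"),
                       (("frontal", "temporal", "between"),
                        ("frontal", "parietal", "between")),
                       "weak", theta_strong, theta_weak),
    ]


@dataclass
class HypothesisResult:
    """Verdict for one hypothesis in one category, with its evidence."""

    hypothesis_id: str
    category: str
    expectation: str
    verdict: str  # supported | mixed | not_supported
    stats: GroupStats
    theta_strong: float
    theta_weak: float


@dataclass
class HypothesisReport:
    """All hypothesis x category verdicts for one set of category averages."""

    results: list[HypothesisResult]

    def result(self, hypothesis_id: str, category: str) -> HypothesisResult:
        for r in self.results:
            if r.hypothesis_id == hypothesis_id and r.category == category:
                return r
        raise KeyError((hypothesis_id, category))

    def supported(self, hypothesis_id: str) -> bool:
        """True if the hypothesis is supported in every applicable category."""
        rs = [r for r in self.results if r.hypothesis_id == hypothesis_id]
        if not rs:
            raise KeyError(hypothesis_id)
        return all(r.verdict == "supported" for r in rs)

    def to_dict(self) -> dict:
        return {
            "results": [
                {
                    "hypothesis": r.hypothesis_id,
                    "category": r.category,
                    "expectation": r.expectation,
                    "verdict": r.verdict,
                    "theta_strong": r.theta_strong,
                    "theta_weak": r.theta_weak,
                    "min": r.stats.minimum,
                    "max": r.stats.maximum,
                    "mean": r.stats.mean,
                    "entries": [list(e) for e in r.stats.entries],
                }
                for r in self.results
            ]
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _verdict(stats: GroupStats, expectation: str,
             theta_strong: float, theta_weak: float) -> str:
    if expectation == "strong":
        if stats.minimum >= theta_strong:
            return "supported"
        if stats.mean >= theta_strong:
            return "mixed"
        return "not_supported"
    if stats.maximum <= theta_weak:
        return "supported"
    if stats.mean <= theta_weak:
        return "mixed"
    return "not_supported"


def evaluate_hypotheses(category_matrices: dict[str, CorrelationMatrix],
                        specs: list[HypothesisSpec] | None = None) -> HypothesisReport:
    """Evaluate each hypothesis on the average matrix of each category.

    A hypothesis is *supported* in a category when every pooled entry meets
    the expectation (min >= theta_strong for strong, max <= theta_weak for
    weak), *mixed* when the mean meets it but the extremum does not, and
    *not supported* otherwise.
    """
    if specs is None:
        specs = default_hypotheses()
    results = []
    for spec in specs:
        for cat in spec.categories:
            if cat not in category_matrices:
                raise CorrelationError(
                    f"hypothesis {spec.id} needs category {cat!r}, not provided"
                )
            m = category_matrices[cat]
            pooled: list[tuple[str, str, float]] = []
            for ga, gb, relation in spec.pairs:
                st = group_summary(m, named_group(ga), named_group(gb), relation)
                pooled.extend(st.entries)
            vals = np.array([e[2] for e in pooled])
            stats = GroupStats(float(vals.min()), float(vals.max()),
                               float(vals.mean()), pooled)
            results.append(HypothesisResult(
                spec.id, cat, spec.expectation,
                _verdict(stats, spec.expectation, spec.theta_strong, spec.theta_weak),
                stats, spec.theta_strong, spec.theta_weak))
    return HypothesisReport(results)
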