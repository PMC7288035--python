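import numpy as np
import pytest

from eegsm import (CorrelationMatrix, Recording, average_correlation,
                   correlation_matrix, default_hypotheses, difference,
                   evaluate_hypotheses, group_summary, named_group)
from eegsm.correlation import CorrelationError, HypothesisSpec


def _brute_force_pearson(x, y):
    """Textbook formula, written independently of numpy.corrcoef."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = (sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y)) ** 0.5
    return num / den


def _matrix(montage, values, provenance="single_recording"):
    return CorrelationMatrix(values, montage, provenance=provenance)


class TestCorrelationMatrix:
    def test_identical_and_negated_channels(self, montage, rng):
        data = rng.standard_normal((16, 200))
        data[1] = data[0]
        data[2] = -data[0]
        m = correlation_matrix(Recording(data, 128.0, montage))
        assert m.entry("Fp1", "Fp2") == pytest.approx(1.0)
        assert m.entry("Fp1", "F4") == pytest.approx(-1.0)
        assert np.allclose(np.diag(m.values), 1.0)
        assert np.allclose(m.values, m.values.T)

    def test_matches_brute_force_formula(self, montage):
        data = np.random.default_rng(3).standard_normal((16, 100))
        data[0, :4] = [1, 2, 3, 4]
        m = correlation_matrix(Recording(data, 128.0, montage))
        for i in range(4):
            for j in range(i + 1, 4):
                expected = _brute_force_pearson(list(data[i]), list(data[j]))
                assert m.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_four_sample_textbook_example(self, montage, rng):
        data = rng.standard_normal((16, 4))
        data[0] = [1, 2, 3, 4]
        data[1] = [2, 4, 5, 9]
        m = correlation_matrix(Recording(data, 128.0, montage))
        assert m.values[0, 1] == pytest.approx(
            _brute_force_pearson([1, 2, 3, 4], [2, 4, 5, 9]), abs=1e-12)

    def test_zero_variance_channel_is_named(self, montage, rng):
        data = rng.standard_normal((16, 50))
        data[montage.index("Cz")] = 2.0
        with pytest.raises(CorrelationError, match="Cz"):
            correlation_matrix(Recording(data, 128.0, montage))

    def test_span_excludes_the_leader_phase(self, montage, rng):
        data = rng.standard_normal((16, 60 * 128))
        rec = Recording(data, 128.0, montage)
        full = correlation_matrix(rec, "full")
        tail = correlation_matrix(rec, "exclude_first_10s")
        expected = np.corrcoef(data[:, 10 * 128:])
        assert np.allclose(tail.values, expected, atol=1e-12)
        assert not np.allclose(full.values, tail.values)

    def test_affine_transform_of_all_channels_is_invariant(self, montage, rng):
        data = rng.standard_normal((16, 300))
        a = correlation_matrix(Recording(data, 128.0, montage))
        b = correlation_matrix(Recording(5.0 * data - 3.0, 128.0, montage))
        assert np.allclose(a.values, b.values, atol=1e-12)


class TestAveraging:
    def test_single_matrix_averages_to_itself(self, montage, rng):
        data = rng.standard_normal((16, 100))
        m = correlation_matrix(Recording(data, 128.0, montage))
        for method in ("fisher_z", "arithmetic"):
            avg = average_correlation([m], method)
            assert np.allclose(avg.values, m.values, atol=1e-12)

    def test_equal_entries_average_to_themselves(self, montage):
        v = np.eye(16)
        v[0, 1] = v[1, 0] = 0.5
        m = _matrix(montage, v)
        for method in ("fisher_z", "arithmetic"):
            avg = average_correlation([m, m], method)
            assert avg.values[0, 1] == pytest.approx(0.5)

    def test_fisher_vs_arithmetic_closed_form(self, montage):
        va, vb = np.eye(16), np.eye(16)
        va[0, 1] = va[1, 0] = 0.2
        vb[0, 1] = vb[1, 0] = 0.8
        ma, mb = _matrix(montage, va), _matrix(montage, vb)
        arith = average_correlation([ma, mb], "arithmetic")
        fish = average_correlation([ma, mb], "fisher_z")
        assert arith.values[0, 1] == pytest.approx(0.5)
        expected = np.tanh((np.arctanh(0.2) + np.arctanh(0.8)) / 2)
        assert fish.values[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_perfect_correlations_average_cleanly_under_fisher(self, montage):
        v = np.eye(16)
        v[0, 1] = v[1, 0] = 1.0
        avg = average_correlation([_matrix(montage, v)] * 3, "fisher_z")
        assert avg.values[0, 1] == pytest.approx(1.0)

    def test_empty_list_is_an_error(self):
        with pytest.raises(CorrelationError, match="empty"):
            average_correlation([])


class TestGroupSummary:
    def test_group_entry_counts_are_exact_combinatorics(self, montage):
        m = _matrix(montage, np.eye(16))
        frontal, occipital = named_group("frontal"), named_group("occipital")
        temporal, parietal = named_group("temporal"), named_group("parietal")
        assert group_summary(m, frontal, frontal, "within").n == 10
        assert group_summary(m, occipital, occipital, "within").n == 3
        assert group_summary(m, frontal, occipital, "between").n == 15
        n_tp = (group_summary(m, frontal, temporal, "between").n
                + group_summary(m, frontal, parietal, "between").n)
        assert n_tp == 20

    def test_identity_matrix_within_stats_are_zero(self, montage):
        m = _matrix(montage, np.eye(16))
        st = group_summary(m, named_group("frontal"), named_group("frontal"), "within")
        assert st.minimum == st.maximum == st.mean == 0.0

    def test_hand_built_matrix_stats(self, montage):
        """Enumeration oracle: 15 frontal x occipital entries, 14 at 0.6 and
        one at 0.3 -> min 0.3, max 0.6, mean 0.58."""
        v = np.eye(16)
        fi = montage.group_indices("frontal")
        oi = montage.group_indices("occipital")
        for i in fi:
            for j in oi:
                v[i, j] = v[j, i] = 0.6
        v[fi[0], oi[0]] = v[oi[0], fi[0]] = 0.3
        st = group_summary(_matrix(montage, v), named_group("frontal"),
                           named_group("occipital"), "between")
        assert st.minimum == pytest.approx(0.3)
        assert st.maximum == pytest.approx(0.6)
        assert st.mean == pytest.approx((14 * 0.6 + 0.3) / 15)

    def test_overlapping_groups_under_between_are_rejected(self, montage):
        m = _matrix(montage, np.eye(16))
        with pytest.raises(CorrelationError, match="overlap"):
            group_summary(m, named_group("frontal"), named_group("frontal"), "between")


class TestDifference:
    def test_difference_properties(self, montage, rng):
        data = rng.standard_normal((16, 200))
        a = correlation_matrix(Recording(data, 128.0, montage))
        b = correlation_matrix(Recording(rng.standard_normal((16, 200)), 128.0, montage))
        d = difference(a, b)
        assert np.allclose(d.values, a.values - b.values)
        assert np.allclose(difference(b, a).values, -d.values)
        assert np.allclose(difference(a, a).values, 0.0)
        assert d.provenance == "difference"
        assert d.colorscale_bound == pytest.approx(np.max(np.abs(d.values)))

    def test_scalar_example(self, montage):
        va, vb = np.eye(16), np.eye(16)
        va[0, 1] = va[1, 0] = 0.7
        vb[0, 1] = vb[1, 0] = 0.5
        d = difference(_matrix(montage, va), _matrix(montage, vb))
        assert d.values[0, 1] == pytest.approx(0.2)


class TestHypotheses:
    def _with_block(self, montage, groups_a, groups_b, value, base=0.0):
        v = np.full((16, 16), base)
        np.fill_diagonal(v, 1.0)
        ia = [i for g in groups_a for i in montage.group_indices(g)]
        ib = [i for g in groups_b for i in montage.group_indices(g)]
        for i in ia:
            for j in ib:
                if i != j:
                    v[i, j] = v[j, i] = value
        return _matrix(montage, v, provenance="category_average")

    def test_strong_within_frontal_is_supported(self, montage):
        m = self._with_block(montage, ["frontal"], ["frontal"], 0.7)
        cats = {c: m for c in ("HKT_PO", "HKT_Leader", "BSC_PO", "BSC_Leader")}
        spec = [h for h in default_hypotheses() if h.id == "H3"]
        report = evaluate_hypotheses(cats, spec)
        assert report.supported("H3")

    def test_mixed_verdict_when_extremum_violates_but_mean_satisfies(self, montage):
        # frontal x TPJ entries mostly weak with one clear outlier
        v = np.eye(16)
        fi = montage.group_indices("frontal")
        tp = montage.group_indices("temporal") + montage.group_indices("parietal")
        vals = np.linspace(0.28, 0.38, len(fi) * len(tp))
        for k, (i, j) in enumerate([(i, j) for i in fi for j in tp]):
            v[i, j] = v[j, i] = vals[k]
        v[fi[0], tp[-1]] = v[tp[-1], fi[0]] = 0.65  # the outlier
        m = _matrix(montage, v, provenance="category_average")
        spec = [h for h in default_hypotheses() if h.id == "H5"]
        report = evaluate_hypotheses({"BSC_PO": m, "BSC_Leader": m}, spec)
        r = report.result("H5", "BSC_PO")
        assert r.stats.maximum > r.theta_weak
        assert r.stats.mean <= r.theta_weak
        assert r.verdict == "mixed"

    def test_identity_matrix_supports_no_strong_hypothesis(self, montage):
        m = _matrix(montage, np.eye(16), provenance="category_average")
        cats = {c: m for c in ("HKT_PO", "HKT_Leader", "BSC_PO", "BSC_Leader")}
        report = evaluate_hypotheses(cats)
        for r in report.results:
            if r.expectation == "strong":
                assert r.verdict == "not_supported"
            else:  # identity has zero couplings: weak expectations hold
                assert r.verdict == "supported"

    def test_every_verdict_is_traceable_to_its_entries(self, montage):
        m = _matrix(montage, np.eye(16), provenance="category_average")
        cats = {c: m for c in ("HKT_PO", "HKT_Leader", "BSC_PO", "BSC_Leader")}
        for r in evaluate_hypotheses(cats).results:
            vals = [e[2] for e in r.stats.entries]
            assert r.stats.minimum == min(vals)
            assert r.stats.maximum == max(vals)
            assert r.stats.mean == pytest.approx(sum(vals) / len(vals))

    def test_missing_category_is_an_error(self, montage):
        m = _matrix(montage, np.eye(16), provenance="category_average")
        with pytest.raises(CorrelationError, match="BSC_Leader"):
            evaluate_hypotheses({"HKT_PO": m, "HKT_Leader": m, "BSC_PO": m})

    def test_threshold_ordering_is_validated(self):
        with pytest.raises(CorrelationError):
            HypothesisSpec("HX", ("HKT_PO",), (("frontal", "frontal", "within"),),
                           "strong", theta_strong=0.3, theta_weak=0.4)
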