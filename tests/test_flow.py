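"""Channel-of-interest pipeline: TE matrices, contrasts, bootstrap selection."""

import numpy as np
import pytest

from teflow.flow import (
    TEMatrix,
    bootstrap_upper_threshold,
    common_channels,
    grand_average,
    lag_to_ms,
    neutral_contrast,
    pairwise_te,
    select_channels,
)
from teflow.synthetic import CouplingSpec, SyntheticDesign, generate_recording
from teflow.te import TEConfig


def mat(values, labels=None, condition="EM", subject="S00", **kw):
    values = np.asarray(values, dtype=float)
    labels = labels or tuple(f"c{i}" for i in range(values.shape[0]))
    return TEMatrix(values=values, labels=labels, condition=condition,
                    subject=subject, **kw)


def const_offdiag(c, size=4):
    v = np.full((size, size), float(c))
    np.fill_diagonal(v, 0.0)
    return v


class TestPairwiseTE:
    def test_ground_truth_edge_is_matrix_maximum(self):
        d = SyntheticDesign(
            n_channels=4, channel_labels=("A", "B", "C", "D"), rate=100.0,
            duration_samples=1500, ar_coeff=0.5, noise_sd=1.0, seed=21,
            couplings=(CouplingSpec("A", "B", delay=5, strength=0.6,
                                    conditions=frozenset({"EM"})),),
        )
        rec = generate_recording(d, "S00", "EM")
        m = pairwise_te(rec, TEConfig(), (0, 6))
        i, j = m.labels.index("A"), m.labels.index("B")
        assert m.values[i, j] == m.values.max()
        assert m.lags[i, j] == 5
        assert np.all(np.diag(m.values) == 0.0)

    def test_independent_channels_stay_small(self):
        d = SyntheticDesign(n_channels=3, rate=100.0, duration_samples=1200,
                            ar_coeff=0.3, noise_sd=1.0, seed=22)
        m = pairwise_te(generate_recording(d, "S00", "NF"), TEConfig(), (0, 4))
        off = m.values[~np.eye(3, dtype=bool)]
        assert np.all(off < 0.06)

    def test_two_channels_two_entries(self):
        d = SyntheticDesign(n_channels=2, rate=100.0, duration_samples=800,
                            ar_coeff=0.3, noise_sd=1.0, seed=23)
        m = pairwise_te(generate_recording(d, "S00", "NF"), TEConfig(), (0, 2))
        assert np.count_nonzero(m.values) == 2

    def test_single_channel_rejected(self):
        d = SyntheticDesign(n_channels=1, rate=100.0, duration_samples=800,
                            ar_coeff=0.3, noise_sd=1.0, seed=24)
        with pytest.raises(ValueError, match="2 channels"):
            pairwise_te(generate_recording(d, "S00", "NF"))


class TestLagToMs:
    @pytest.mark.parametrize("lag,rate,ms", [(50, 100.0, 500.0), (0, 100.0, 0.0),
                                             (5, 100.0, 50.0), (10, 1000.0, 10.0)])
    def test_conversion(self, lag, rate, ms):
        assert lag_to_ms(lag, rate) == pytest.approx(ms)

    def test_negative_lag_rejected(self):
        with pytest.raises(ValueError):
            lag_to_ms(-1, 100.0)


class TestContrastAndAverage:
    def test_identical_matrices_zero_contrast(self):
        a = mat(const_offdiag(0.3))
        b = mat(const_offdiag(0.3), condition="NM")
        assert np.all(neutral_contrast(a, b).values == 0.0)

    def test_uniform_offset(self):
        a = mat(const_offdiag(0.11))
        b = mat(const_offdiag(0.10), condition="NM")
        diff = neutral_contrast(a, b).values
        off = ~np.eye(4, dtype=bool)
        assert np.allclose(diff[off], 0.01)

    def test_negative_residuals_retained(self):
        a = mat(const_offdiag(0.1))
        b = mat(const_offdiag(0.2), condition="NM")
        assert np.all(neutral_contrast(a, b).values[~np.eye(4, dtype=bool)] < 0)

    def test_label_mismatch_rejected(self):
        a = mat(const_offdiag(0.1), labels=("a", "b", "c", "d"))
        b = mat(const_offdiag(0.1), labels=("a", "b", "c", "e"), condition="NM")
        with pytest.raises(ValueError, match="label"):
            neutral_contrast(a, b)

    def test_subject_mismatch_rejected(self):
        a = mat(const_offdiag(0.1), subject="S00")
        b = mat(const_offdiag(0.1), subject="S01", condition="NM")
        with pytest.raises(ValueError, match="subject"):
            neutral_contrast(a, b)

    def test_grand_average_identity_and_mean(self):
        m0 = mat(const_offdiag(0.0))
        m2 = mat(const_offdiag(0.2))
        assert np.allclose(grand_average([m2]).values, m2.values)
        avg = grand_average([m0, m2]).values
        assert np.allclose(avg[~np.eye(4, dtype=bool)], 0.1)

    def test_grand_average_order_invariant(self):
        rng = np.random.default_rng(0)
        mats = [mat(np.triu(rng.normal(size=(4, 4)), 1)) for _ in range(5)]
        fwd = grand_average(mats).values
        rev = grand_average(mats[::-1]).values
        assert np.allclose(fwd, rev, atol=1e-12)

    def test_empty_average_rejected(self):
        with pytest.raises(ValueError):
            grand_average([])


class TestBootstrapThreshold:
    def test_constant_matrix_all_survive(self):
        flow = bootstrap_upper_threshold(mat(const_offdiag(0.5)), B=500, seed=0)
        assert flow.threshold == pytest.approx(0.5)
        assert np.all(flow.out_degree == 3)

    def test_single_large_entry_survives_alone(self):
        v = np.zeros((10, 10))
        v[0, 1] = 1.0
        flow = bootstrap_upper_threshold(mat(v, condition="EM"), B=500, seed=1)
        assert flow.threshold > 0
        assert np.count_nonzero(flow.surviving) == 1
        assert flow.surviving[0, 1] == 1.0
        assert flow.out_degree[0] == 1

    def test_seeded_determinism(self):
        rng = np.random.default_rng(3)
        m = mat(np.abs(np.triu(rng.normal(size=(6, 6)), 1)))
        t1 = bootstrap_upper_threshold(m, B=1000, seed=7).threshold
        t2 = bootstrap_upper_threshold(m, B=1000, seed=7).threshold
        assert t1 == t2

    def test_level_monotonicity(self):
        rng = np.random.default_rng(4)
        m = mat(np.abs(np.triu(rng.normal(size=(8, 8)), 1)))
        lo = bootstrap_upper_threshold(m, B=2000, level=90.0, seed=5)
        hi = bootstrap_upper_threshold(m, B=2000, level=99.0, seed=5)
        assert np.count_nonzero(hi.surviving) <= np.count_nonzero(lo.surviving)

    def test_small_b_rejected(self):
        with pytest.raises(ValueError, match="B"):
            bootstrap_upper_threshold(mat(const_offdiag(0.1)), B=10)


class TestSelection:
    def flow_with_degrees(self, degrees):
        C = len(degrees)
        v = np.zeros((C, C))
        for i, d in enumerate(degrees):
            cols = [c for c in range(C) if c != i][:d]
            v[i, cols] = 1.0
        labels = tuple(f"c{i}" for i in range(C))
        return bootstrap_upper_threshold(
            mat(v, labels=labels), B=500, seed=9
        )

    def test_equal_degrees_select_nothing(self):
        flow = self.flow_with_degrees([2, 2, 2, 2])
        # constant thresholds keep everything; degrees equal -> none exceed
        assert select_channels(flow, B=500, seed=0) == frozenset()

    def test_dominant_channel_selected(self):
        v = np.zeros((4, 4))
        v[0, 1:] = 5.0  # degree 3 vs 0 elsewhere, entries far above threshold
        flow = bootstrap_upper_threshold(mat(v), B=500, seed=2)
        assert flow.out_degree.tolist() == [3, 0, 0, 0]
        assert select_channels(flow, B=2000, seed=3) == {"c0"}

    def test_all_zero_degrees_empty_selection(self):
        from teflow.flow import ThresholdedFlow
        flow = ThresholdedFlow(
            contrast_mean=np.zeros((3, 3)), threshold=1.0,
            surviving=np.zeros((3, 3)), out_degree=np.zeros(3, dtype=int),
            labels=("a", "b", "c"),
        )
        assert select_channels(flow, B=500, seed=0) == frozenset()


class TestCommonChannels:
    def test_identical_sets(self):
        sel = {"AM": {"F3", "C2"}, "EM": {"F3", "C2"}}
        common, dropped = common_channels(sel)
        assert common == {"F3", "C2"}
        assert dropped == ()

    def test_disjoint_sets(self):
        common, dropped = common_channels({"AM": {"F3"}, "EM": {"C2"}})
        assert common == frozenset()
        assert dropped == ()

    def test_empty_setting_dropped_from_intersection(self):
        sel = {"AF": {"A", "B", "C"}, "AM": {"B", "C", "D"}, "EF": set()}
        common, dropped = common_channels(sel)
        assert common == {"B", "C"}
        assert dropped == ("EF",)

    def test_all_empty(self):
        common, dropped = common_channels({"AF": set(), "EM": set()})
        assert common == frozenset()
        assert set(dropped) == {"AF", "EM"}

    def test_single_setting_rejected(self):
        with pytest.raises(ValueError):
            common_channels({"AM": {"F3"}})


class TestMatrixInvariants:
    def test_nonzero_diagonal_rejected(self):
        v = const_offdiag(0.1)
        v[0, 0] = 0.5
        with pytest.raises(ValueError, match="diagonal"):
            mat(v)

    def test_nonfinite_rejected(self):
        v = const_offdiag(0.1)
        v[0, 1] = np.inf
        with pytest.raises(ValueError, match="finite"):
            mat(v)
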