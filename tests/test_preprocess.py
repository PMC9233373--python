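import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nactmeth import preprocess as pp
from nactmeth.io_model import (
    BetaMatrix,
    CpGAnnotation,
    DetectionPMatrix,
    MValueMatrix,
    ValidationError,
)


def _beta(arr, cols=None):
    arr = np.atleast_2d(np.asarray(arr, float))
    cols = cols or [f"s{j}" for j in range(arr.shape[1])]
    return BetaMatrix(
        pd.DataFrame(arr, index=[f"cg{i}" for i in range(arr.shape[0])], columns=cols)
    )


class TestTransforms:
    @pytest.mark.parametrize(
        "beta,expected_m",
        [(0.5, 0.0), (0.8, 2.0), (0.2, -2.0)],
    )
    def test_beta_to_m_reference_points(self, beta, expected_m):
        m = pp.beta_to_m(_beta([[beta]]))
        assert m.values.iat[0, 0] == pytest.approx(expected_m, abs=1e-12)

    def test_m_to_beta_reference_points(self):
        m = MValueMatrix(pd.DataFrame([[0.0, 2.0]], index=["cg0"], columns=["a", "b"]))
        b = pp.m_to_beta(m)
        assert b.values.iat[0, 0] == pytest.approx(0.5, abs=1e-12)
        assert b.values.iat[0, 1] == pytest.approx(0.8, abs=1e-12)

    def test_round_trip(self):
        x = _beta([[0.37, 0.001, 0.999, 0.5]])
        back = pp.m_to_beta(pp.beta_to_m(x))
        np.testing.assert_allclose(back.values.to_numpy(), x.values.to_numpy(), atol=1e-12)

    @pytest.mark.parametrize("eps", [0.0, -0.1, 0.5, 0.7])
    def test_bad_epsilon_rejected(self, eps):
        with pytest.raises(ValueError, match="epsilon"):
            pp.beta_to_m(_beta([[0.5]]), epsilon=eps)

    def test_missing_stays_missing(self):
        m = pp.beta_to_m(_beta([[0.5, np.nan]]))
        assert np.isnan(m.values.iat[0, 1])

    @given(
        st.lists(
            # grid spacing 1e-5 keeps strict monotonicity representable in floats
            st.integers(min_value=1000, max_value=99000).map(lambda i: i / 1e5),
            min_size=2, max_size=20, unique=True,
        )
    )
    @settings(max_examples=25, deadline=None)
    def test_monotonicity(self, betas):
        m = pp.beta_to_m(_beta([betas])).values.to_numpy().ravel()
        order_b = np.argsort(betas)
        assert (np.diff(m[order_b]) > 0).all()


class TestDetectionFilter:
    def _pair(self, fail_count, n=10):
        beta = _beta([np.full(n, 0.5)])
        detp = np.full(n, 0.001)
        detp[:fail_count] = 0.2
        dp = DetectionPMatrix(
            pd.DataFrame([detp], index=["cg0"], columns=beta.sample_ids)
        )
        return beta, dp

    def test_80pct_failing_removed(self):
        beta, dp = self._pair(8)
        out, rep = pp.detection_filter(beta, dp)
        assert out.shape[0] == 0
        assert rep.n_sites_removed_detection == 1

    def test_70pct_failing_kept(self):
        beta, dp = self._pair(7)
        out, _ = pp.detection_filter(beta, dp)
        assert out.shape[0] == 1

    def test_all_good_nothing_removed(self):
        beta, dp = self._pair(0)
        out, rep = pp.detection_filter(beta, dp)
        assert out.shape[0] == 1 and rep.n_sites_removed_detection == 0

    def test_shape_mismatch_rejected(self):
        beta, _ = self._pair(0, n=10)
        _, dp = self._pair(0, n=9)
        with pytest.raises(ValidationError, match="aligned"):
            pp.detection_filter(beta, dp)


class TestQuantileNormalize:
    def test_two_column_worked_example(self):
        b = _beta(np.array([[0.1, 0.3], [0.2, 0.4], [0.3, 0.5]]))
        out = pp.quantile_normalize(b).values.to_numpy()
        np.testing.assert_allclose(out[:, 0], [0.2, 0.3, 0.4], atol=1e-12)
        np.testing.assert_allclose(out[:, 1], [0.2, 0.3, 0.4], atol=1e-12)

    def test_identical_columns_unchanged(self):
        col = np.array([0.1, 0.5, 0.9])
        b = _beta(np.column_stack([col, col]))
        out = pp.quantile_normalize(b).values.to_numpy()
        np.testing.assert_allclose(out, np.column_stack([col, col]), atol=1e-12)

    def test_columns_share_sorted_values(self):
        rng = np.random.default_rng(4)
        b = _beta(rng.uniform(0, 1, size=(50, 4)))
        out = pp.quantile_normalize(b).values.to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(1, 4):
            np.testing.assert_allclose(np.sort(out[:, j]), ref, atol=1e-12)

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        b = _beta(rng.uniform(0, 1, size=(60, 3)))
        once = pp.quantile_normalize(b)
        twice = pp.quantile_normalize(once)
        np.testing.assert_allclose(
            twice.values.to_numpy(), once.values.to_numpy(), atol=1e-12
        )

    def test_single_sample_warns(self):
        b = _beta([[0.1], [0.2]])
        with pytest.warns(UserWarning, match="single sample"):
            out = pp.quantile_normalize(b)
        np.testing.assert_array_equal(out.values.to_numpy(), b.values.to_numpy())

    def test_preserves_order_within_column(self):
        rng = np.random.default_rng(6)
        arr = rng.uniform(0, 1, size=(40, 3))
        out = pp.quantile_normalize(_beta(arr)).values.to_numpy()
        for j in range(3):
            assert (np.argsort(arr[:, j]) == np.argsort(out[:, j])).all()


def _bimodal_sample(rng, n, lo, hi, sd):
    half = n // 2
    return np.concatenate([rng.normal(lo, sd, half), rng.normal(hi, sd, n - half)])


class TestPeakCorrection:
    def _matrix(self, m1, m2):
        vals = np.concatenate([m1, m2])
        ids = [f"cg{i}" for i in range(len(vals))]
        m = MValueMatrix(pd.DataFrame({"s1": vals}, index=ids))
        ann = CpGAnnotation(
            pd.DataFrame(
                {
                    "cpg_id": ids,
                    "gene": "G1",
                    "genomic_context": "promoter",
                    "island": "CGI",
                    "probe_type": ["I"] * len(m1) + ["II"] * len(m2),
                }
            )
        )
        return m, ann

    def test_identity_when_distributions_match(self):
        rng = np.random.default_rng(0)
        m1 = _bimodal_sample(rng, 500, -2, 2, 0.3)
        m2 = _bimodal_sample(rng, 1500, -2, 2, 0.3)
        m, ann = self._matrix(m1, m2)
        out, rep = pp.peak_correct_type2(m, ann)
        peaks = rep.peak_positions["s1"]
        assert peaks["typeII_after"]["unmeth"] == pytest.approx(
            peaks["typeI"]["unmeth"], abs=0.15
        )

    def test_compressed_modes_rescaled(self):
        rng = np.random.default_rng(1)
        m1 = _bimodal_sample(rng, 500, -2, 2, 0.3)
        m2 = _bimodal_sample(rng, 1500, -1.5, 1.5, 0.3)
        m, ann = self._matrix(m1, m2)
        out, rep = pp.peak_correct_type2(m, ann)
        after = rep.peak_positions["s1"]["typeII_after"]
        assert after["unmeth"] == pytest.approx(-2.0, abs=0.1)
        assert after["meth"] == pytest.approx(2.0, abs=0.1)

    def test_type1_probes_bit_identical(self):
        rng = np.random.default_rng(2)
        m1 = _bimodal_sample(rng, 400, -2, 2, 0.3)
        m2 = _bimodal_sample(rng, 1200, -1.5, 1.5, 0.3)
        m, ann = self._matrix(m1, m2)
        out, _ = pp.peak_correct_type2(m, ann)
        np.testing.assert_array_equal(out.values.to_numpy()[:400], m1[:, None])

    def test_zero_is_fixed_point(self):
        rng = np.random.default_rng(3)
        m1 = _bimodal_sample(rng, 400, -2, 2, 0.3)
        m2 = np.append(_bimodal_sample(rng, 1200, -1.5, 1.5, 0.3), 0.0)
        m, ann = self._matrix(m1, m2)
        out, _ = pp.peak_correct_type2(m, ann)
        assert out.values.to_numpy()[-1, 0] == 0.0

    def test_single_probe_type_rejected(self):
        rng = np.random.default_rng(4)
        m2 = _bimodal_sample(rng, 100, -1.5, 1.5, 0.3)
        m, ann = self._matrix(np.array([]), m2)
        with pytest.raises(ValidationError, match="both probe types"):
            pp.peak_correct_type2(m, ann)
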