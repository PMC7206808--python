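"""Observer-agreement statistics against hand-computed oracles."""

import numpy as np
import pytest

from nervetrace.agreement import (
    ReaderMatrix,
    bland_altman,
    build_agreement_report,
    coefficient_of_determination,
    hinkle_band,
    icc_two_way,
)


def icc_anova_oracle(values, variant="absolute_agreement"):
    """Independent ICC computation written out in elementary steps."""
    values = np.asarray(values, dtype=float)
    n, k = values.shape
    grand = sum(values[i, j] for i in range(n) for j in range(k)) / (n * k)
    row_means = [sum(values[i, :]) / k for i in range(n)]
    col_means = [sum(values[:, j]) / n for j in range(k)]
    ss_rows = k * sum((m - grand) ** 2 for m in row_means)
    ss_cols = n * sum((m - grand) ** 2 for m in col_means)
    ss_total = sum(
        (values[i, j] - grand) ** 2 for i in range(n) for j in range(k)
    )
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = (ss_total - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    if variant == "absolute_agreement":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    else:
        denom = msr + (k - 1) * mse
    return (msr - mse) / denom


# a fixed 6 images x 3 readers CNFL table with visible reader offsets
TABLE_6x3 = np.array(
    [
        [12.1, 13.0, 11.5],
        [15.4, 16.2, 14.9],
        [9.8, 10.9, 9.1],
        [18.3, 19.5, 17.2],
        [14.0, 14.6, 13.1],
        [11.2, 12.4, 10.8],
    ]
)


def _matrix(values):
    n, k = np.asarray(values).shape
    return ReaderMatrix(
        np.asarray(values, float),
        [f"R{j}" for j in range(k)],
        [f"img{i}" for i in range(n)],
    )


class TestR2:
    def test_perfect_linear_relation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert coefficient_of_determination(x, 2 * x + 1) == pytest.approx(1.0)

    def test_hand_computed_value(self):
        # x=[1,2,3], y=[1,2,4]: r = 9/sqrt(84), r^2 = 27/28
        r2 = coefficient_of_determination([1, 2, 3], [1, 2, 4])
        assert r2 == pytest.approx(27 / 28, abs=1e-12)

    def test_sign_insensitive(self):
        x = np.array([1.0, 2.0, 3.0, 5.0])
        assert coefficient_of_determination(x, -x) == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            coefficient_of_determination([1, 1, 1], [1, 2, 3])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            coefficient_of_determination([1, 2, 3], [1, 2])


class TestICC:
    def test_matches_anova_oracle_6x3(self):
        overall, _ = icc_two_way(_matrix(TABLE_6x3))
        assert overall == pytest.approx(icc_anova_oracle(TABLE_6x3), abs=1e-10)

    def test_consistency_variant_matches_oracle(self):
        overall, _ = icc_two_way(_matrix(TABLE_6x3), variant="consistency")
        assert overall == pytest.approx(
            icc_anova_oracle(TABLE_6x3, "consistency"), abs=1e-10
        )

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        n, k = TABLE_6x3.shape
        long = pd.DataFrame(
            {
                "targets": np.repeat(np.arange(n), k),
                "raters": np.tile(np.arange(k), n),
                "ratings": TABLE_6x3.ravel(),
            }
        )
        ref = pingouin.intraclass_corr(
            long, targets="targets", raters="raters", ratings="ratings"
        )
        icc2 = float(ref.loc[ref["Type"] == "ICC(A,1)", "ICC"].iloc[0])
        icc3 = float(ref.loc[ref["Type"] == "ICC(C,1)", "ICC"].iloc[0])
        overall_abs, _ = icc_two_way(_matrix(TABLE_6x3))
        overall_con, _ = icc_two_way(_matrix(TABLE_6x3), variant="consistency")
        assert overall_abs == pytest.approx(icc2, abs=1e-8)
        assert overall_con == pytest.approx(icc3, abs=1e-8)

    def test_identical_readers_give_one(self):
        col = np.array([1.0, 2.0, 3.0, 4.0])
        overall, pairwise = icc_two_way(_matrix(np.stack([col, col], axis=1)))
        assert overall == pytest.approx(1.0)
        assert np.allclose(pairwise.values, 1.0)

    def test_pure_noise_near_zero(self):
        rng = np.random.default_rng(0)
        overall, _ = icc_two_way(_matrix(rng.normal(size=(300, 3))))
        assert abs(overall) < 0.2

    def test_constant_offset_separates_variants(self):
        col = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        table = np.stack([col, col + 2.0], axis=1)
        absolute, _ = icc_two_way(_matrix(table))
        consistency, _ = icc_two_way(_matrix(table), variant="consistency")
        assert consistency == pytest.approx(1.0)
        assert absolute < consistency  # the offset counts against agreement

    def test_pairwise_table_symmetric_unit_diagonal(self):
        _, pairwise = icc_two_way(_matrix(TABLE_6x3))
        assert np.allclose(pairwise.values, pairwise.values.T)
        assert np.allclose(np.diag(pairwise.values), 1.0)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            icc_two_way(_matrix(TABLE_6x3), variant="nope")


class TestBlandAltman:
    def test_unit_triplet_rpc(self):
        # d = [-1, 0, 1]: mean 0, SD 1 (ddof=1), RPC exactly 1.96
        ba = bland_altman([0.0, 0.0, 0.0], [1.0, 0.0, -1.0])
        assert ba.mean_diff == pytest.approx(0.0)
        assert ba.sd_diff == pytest.approx(1.0)
        assert ba.rpc == pytest.approx(1.96)
        assert ba.loa_low == pytest.approx(-1.96)
        assert ba.loa_high == pytest.approx(1.96)

    def test_mean_diff_antisymmetric(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=10), rng.normal(size=10)
        assert bland_altman(x, y).mean_diff == pytest.approx(-bland_altman(y, x).mean_diff)
        assert bland_altman(x, y).rpc == pytest.approx(bland_altman(y, x).rpc)

    def test_constant_offset(self):
        x = np.array([1.0, 2.0, 3.0])
        ba = bland_altman(x + 0.5, x)
        assert ba.mean_diff == pytest.approx(0.5)
        assert ba.rpc == pytest.approx(0.0)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1.0, 2.0], [1.0, 2.0])


class TestHinkle:
    @pytest.mark.parametrize(
        "r,band",
        [
            (0.95, "very_high"),
            (0.9, "very_high"),
            (0.89, "high"),
            (0.7, "high"),
            (0.69, "moderate"),
            (0.5, "moderate"),
            (0.49, "low"),
            (0.0, "low"),
        ],
    )
    def test_band_boundaries(self, r, band):
        assert hinkle_band(r) == band

    @pytest.mark.parametrize("r", [-0.1, 1.1])
    def test_out_of_range_rejected(self, r):
        with pytest.raises(ValueError):
            hinkle_band(r)


class TestReport:
    def test_report_shapes_and_consistency(self):
        report = build_agreement_report(_matrix(TABLE_6x3))
        assert report.pairwise_r2.shape == (3, 3)
        assert report.pairwise_icc.shape == (3, 3)
        assert len(report.bland_altman) == 3  # C(3,2) pairs
        overall, _ = icc_two_way(_matrix(TABLE_6x3))
        assert report.overall_icc == pytest.approx(overall)

    def test_negative_correlation_labelled_low(self):
        col = np.array([1.0, 2.0, 3.0, 4.0])
        report = build_agreement_report(_matrix(np.stack([col, -col], axis=1)))
        assert report.hinkle_labels.iloc[0, 1] == "low"
        # ... even though r^2 itself is 1
        assert report.pairwise_r2.iloc[0, 1] == pytest.approx(1.0)

    def test_matrix_validation(self):
        with pytest.raises(ValueError):  # too few images
            ReaderMatrix(np.ones((2, 2)), ["a", "b"], ["i", "j"])
        with pytest.raises(ValueError):  # one reader
            ReaderMatrix(np.ones((5, 1)), ["a"], list("abcde"))
        with pytest.raises(ValueError):  # NaN cell
            bad = TABLE_6x3.copy()
            bad[0, 0] = np.nan
            _matrix(bad)


class TestSimulatedRecovery:
    def test_two_way_random_effects_recovery(self):
        # y_ij = mu + r_i + c_j + e_ij with known variance components; the
        # population ICC(2,1) is var_r / (var_r + var_c + var_e)
        var_r, var_c, var_e = 4.0, 0.5, 1.0
        true_icc = var_r / (var_r + var_c + var_e)
        rng = np.random.default_rng(12345)
        n, k, reps = 200, 3, 100
        estimates = []
        for _ in range(reps):
            r = rng.normal(0, np.sqrt(var_r), size=(n, 1))
            c = rng.normal(0, np.sqrt(var_c), size=(1, k))
            e = rng.normal(0, np.sqrt(var_e), size=(n, k))
            overall, _ = icc_two_way(_matrix(10.0 + r + c + e))
            estimates.append(overall)
        assert np.mean(estimates) == pytest.approx(true_icc, abs=0.05)
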