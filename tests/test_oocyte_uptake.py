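"""Uptake calling: normalization, outlier QC, t-test oracle, direction logic."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as st

from deorphan.oocyte_uptake import (
    OocyteMeasurement,
    call_direction,
    call_uptake,
    compare_to_control,
    detect_control_background,
    normalize_per_oocyte,
    remove_outliers_iqr,
)
from deorphan.synthetic_data import (
    OocyteSimParams,
    TransporterTruth,
    importer_for_fold_change,
    simulate_oocyte_assay,
)


class TestNormalization:
    def test_per_oocyte_amount(self):
        m = OocyteMeasurement("T", "c", "p1", 10, 500.0)
        assert normalize_per_oocyte(m) == 50.0
        assert normalize_per_oocyte(OocyteMeasurement("T", "c", "p2", 10, 0.0)) == 0.0

    def test_zero_oocytes_rejected(self):
        with pytest.raises(ValueError):
            normalize_per_oocyte(OocyteMeasurement("T", "c", "p1", 0, 1.0))

    def test_mixed_pool_sizes_share_a_common_scale(self):
        # pools of 7 and 10 from the same condition: the condition mean is the
        # mean of per-oocyte values, not of raw responses
        df = pd.DataFrame({
            "transporter": ["T"] * 2, "compound": ["c"] * 2,
            "pool_id": ["p1", "p2"], "n_oocytes": [7, 10],
            "response": [70.0, 120.0],
        })
        out = normalize_per_oocyte(df)
        assert out["per_oocyte"].tolist() == [10.0, 12.0]
        assert out["per_oocyte"].mean() == pytest.approx(11.0)
        assert (df["response"].sum() / df["n_oocytes"].sum()) != 11.0


class TestOutliers:
    def test_constant_values_unflagged(self):
        kept, flagged = remove_outliers_iqr([5, 5, 5, 5])
        assert len(kept) == 4 and len(flagged) == 0

    def test_obvious_outlier_flagged(self):
        kept, flagged = remove_outliers_iqr([10, 11, 12, 13, 50])
        assert flagged.tolist() == [50.0]
        assert sorted(kept) == [10, 11, 12, 13]

    def test_small_n_guard(self):
        kept, flagged = remove_outliers_iqr([1, 2, 3])
        assert len(flagged) == 0

    def test_idempotence_properties(self, rng):
        """Single-pass removal is exactly idempotent below n=4 and whenever
        the first pass flags nothing; assay-sized triplicate pools are
        therefore never re-trimmed."""
        sigma = np.sqrt(np.log1p(0.2 ** 2))
        for _ in range(300):
            n = int(rng.integers(1, 11))
            vals = rng.lognormal(0, sigma, n)
            kept, flagged = remove_outliers_iqr(vals)
            _, again = remove_outliers_iqr(kept)
            if n < 4 or flagged.size == 0:
                assert again.size == 0
            # triplicates (the assay default) are always below the guard
            _, f3 = remove_outliers_iqr(vals[:3]) if n >= 3 else (None, np.array([]))
            assert f3.size == 0


class TestCompareToControl:
    def test_identical_groups(self):
        log2fc, p = compare_to_control([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert log2fc == 0.0 and p == 1.0

    def test_tenfold_shift_matches_pooled_t_oracle(self):
        tvals, cvals = [8.0, 10.0, 12.0], [0.9, 1.0, 1.1]
        log2fc, p = compare_to_control(tvals, cvals)
        assert log2fc == pytest.approx(np.log2(10.0))
        assert p < 0.01
        x, y = np.asarray(tvals), np.asarray(cvals)
        sp2 = (x.var(ddof=1) + y.var(ddof=1)) / 2
        t0 = (x.mean() - y.mean()) / np.sqrt(sp2 * (2 / 3))
        assert abs(p - 2 * st.t.sf(abs(t0), 4)) < 1e-10

    def test_common_scale_invariance(self):
        a = compare_to_control([2.0, 3.0, 4.0], [1.0, 1.5, 2.0])
        b = compare_to_control([20.0, 30.0, 40.0], [10.0, 15.0, 20.0])
        assert a[0] == pytest.approx(b[0])
        assert a[1] == pytest.approx(b[1])

    def test_insufficient_replicates(self):
        with pytest.raises(ValueError):
            compare_to_control([1.0], [1.0, 2.0])


class TestDirection:
    @pytest.mark.parametrize(
        "log2fc,p,background,expected",
        [
            (2.0, 0.01, True, "import"),
            (2.0, 0.01, False, "import"),
            (-1.5, 0.03, True, "export"),
            (-1.5, 0.03, False, "indeterminate"),
            (0.9, 0.2, True, "none"),
            (-0.9, 0.2, False, "none"),
        ],
    )
    def test_rule(self, log2fc, p, background, expected):
        assert call_direction(log2fc, p, 0.05, background) == expected


class TestBackgroundDetection:
    def test_all_zero_controls(self):
        assert detect_control_background([0.0, 0.0, 0.0]) is False

    def test_consistent_positive_signal(self):
        assert detect_control_background([1.9, 2.1, 2.0]) is True
        assert detect_control_background([2.0, 2.0, 2.0]) is True  # zero variance

    def test_single_value_treated_as_absent_with_warning(self):
        with pytest.warns(UserWarning):
            assert detect_control_background([0.01]) is False


def test_call_uptake_recovers_truth_without_sign_errors():
    """4x importers and 0.25x exporters over background are called with the
    right sign; inactive conditions mostly stay quiet."""
    params = OocyteSimParams(background_ratio=0.5, noise_cv=0.2, seed=0)
    truths = []
    for i in range(40):
        truths.append(importer_for_fold_change(f"I{i}", f"cmp{i}", 4.0, params))
        truths.append(TransporterTruth(f"E{i}", f"cmp{i}", "exporter",
                                       exporter_factor_beta=0.25))
        truths.append(TransporterTruth(f"N{i}", f"cmp{i}", "none"))
    meas, truth = simulate_oocyte_assay(truths, params)
    calls = call_uptake(meas).merge(truth.table, on=["transporter", "compound"])
    imp = calls[calls["activity"] == "importer"]
    exp = calls[calls["activity"] == "exporter"]
    nul = calls[calls["activity"] == "none"]
    assert (imp["direction"] == "import").mean() >= 0.85
    assert (exp["direction"] == "export").mean() >= 0.85
    assert (imp["direction"] == "export").sum() == 0
    assert (exp["direction"] == "import").sum() == 0
    assert (nul["direction"] != "none").mean() <= 0.15


def test_bh_flag_is_more_conservative():
    params = OocyteSimParams(background_ratio=0.5, noise_cv=0.2, seed=1)
    truths = [TransporterTruth(f"N{i}", f"cmp{i}", "none") for i in range(30)]
    truths.append(importer_for_fold_change("I0", "cmpX", 6.0, params))
    meas, _ = simulate_oocyte_assay(truths, params)
    plain = call_uptake(meas)
    adjusted = call_uptake(meas, bh=True)
    n_sig_plain = (plain["direction"] != "none").sum()
    n_sig_bh = (adjusted["direction"] != "none").sum()
    assert n_sig_bh <= n_sig_plain
    assert (adjusted["p_adjusted"] >= adjusted["p_value"]).all()
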