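"""Generators: seeded determinism, closed-form limits, label conservation."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from deorphan.growth_phenotype import GrowthCurve
from deorphan.synthetic_data import (
    GrowthSimParams,
    OocyteSimParams,
    SerumSimParams,
    TransporterTruth,
    expected_intracellular_mM,
    logistic_od,
    simulate_growth_curves,
    simulate_oocyte_assay,
    simulate_serum_screen,
)


class TestSerumScreen:
    def test_seeded_determinism(self):
        p = SerumSimParams(n_compounds=50, seed=7)
        t1, tr1 = simulate_serum_screen(p)
        t2, tr2 = simulate_serum_screen(p)
        pd.testing.assert_frame_equal(t1.values, t2.values)
        pd.testing.assert_frame_equal(tr1.table, tr2.table)
        t3, _ = simulate_serum_screen(SerumSimParams(n_compounds=50, seed=8))
        assert not t1.values.equals(t3.values)

    def test_exact_label_counts(self):
        _, truth = simulate_serum_screen(
            SerumSimParams(n_compounds=1000, frac_consumed=0.2, frac_secreted=0.15))
        counts = truth.table["true_class"].value_counts()
        assert counts["consumed"] == 200
        assert counts["secreted"] == 150
        assert counts["unchanged"] == 650

    def test_no_effect_no_noise_groups_identical(self):
        p = SerumSimParams(n_compounds=20, frac_consumed=0.0, frac_secreted=0.0,
                           replicate_cv=0.0, seed=1)
        table, truth = simulate_serum_screen(p)
        ctrl = table.values[table.group_columns("control")].to_numpy()
        trt = table.values[table.group_columns("treated")].to_numpy()
        np.testing.assert_allclose(ctrl, trt, rtol=1e-12)
        assert (truth.table["true_log2fc"] == 0).all()

    def test_invalid_fractions_raise(self):
        with pytest.raises(ValueError):
            simulate_serum_screen(SerumSimParams(frac_consumed=0.7, frac_secreted=0.5))
        with pytest.raises(ValueError):
            simulate_serum_screen(SerumSimParams(n_replicates_per_group=1))


class TestOocyteAssay:
    def test_saturated_equilibrative_limit(self):
        p = OocyteSimParams(background_ratio=0.0, noise_cv=0.0, seed=0)
        truth = TransporterTruth("T1", "cmp", "importer",
                                 accumulation_ratio_A=1.0, rate_k=1e6)
        meas, _ = simulate_oocyte_assay([truth], p)
        cond = meas[meas["transporter"] == "T1"]
        per_oocyte = cond["response"] / cond["n_oocytes"]
        # amount per oocyte = volume * C_in; unity volume => concentration
        np.testing.assert_allclose(per_oocyte, p.c_medium, rtol=1e-9)

    def test_exporter_depletes_background(self):
        p = OocyteSimParams(background_ratio=0.5, noise_cv=0.0)
        truth = TransporterTruth("E", "cmp", "exporter", exporter_factor_beta=0.3)
        assert expected_intracellular_mM(truth, p) == pytest.approx(0.3)

    def test_gfp_control_always_emitted(self):
        p = OocyteSimParams(seed=3)
        meas, truth = simulate_oocyte_assay(
            [TransporterTruth("T1", "a", "none"), TransporterTruth("T1", "b", "none")], p)
        gfp = meas[meas["transporter"] == "GFP_control"]
        assert set(gfp["compound"]) == {"a", "b"}

    def test_monte_carlo_mean_matches_closed_form(self):
        p = OocyteSimParams(background_ratio=0.0, noise_cv=0.2, n_pools=1000, seed=42)
        truth = TransporterTruth("T", "cmp", "importer", accumulation_ratio_A=4.0, rate_k=2.0)
        meas, _ = simulate_oocyte_assay([truth], p)
        cond = meas[meas["transporter"] == "T"]
        c_in = (cond["response"] / cond["n_oocytes"]).to_numpy() / p.oocyte_volume_uL
        expected = expected_intracellular_mM(truth, p)
        se = c_in.std(ddof=1) / np.sqrt(len(c_in))
        assert abs(c_in.mean() - expected) < 3 * se

    def test_accumulation_monotone_in_A(self):
        p = OocyteSimParams(background_ratio=0.1)
        cs = [expected_intracellular_mM(
            TransporterTruth("T", "c", "importer", A, 1.0), p) for A in (1, 2, 4, 8)]
        assert np.all(np.diff(cs) > 0)

    def test_duplicate_condition_rejected(self):
        p = OocyteSimParams()
        truths = [TransporterTruth("T", "c", "none"), TransporterTruth("T", "c", "none")]
        with pytest.raises(ValueError, match="duplicate"):
            simulate_oocyte_assay(truths, p)

    def test_seeded_determinism(self):
        p = OocyteSimParams(noise_cv=0.2, background_ratio=0.3, seed=9)
        truths = [TransporterTruth("T", "c", "importer", 2.0, 1.0)]
        m1, _ = simulate_oocyte_assay(truths, p)
        m2, _ = simulate_oocyte_assay(truths, p)
        pd.testing.assert_frame_equal(m1, m2)


class TestGrowthCurves:
    def test_noiseless_passthrough_matches_closed_form(self):
        p = GrowthSimParams(concentrations=(0.0,), od_noise_sd=0.0, n_replicates=1, seed=0)
        curves, _ = simulate_growth_curves(p)
        expected = logistic_od(np.asarray(p.t_grid), p.mu0, p.K0, p.od0)
        np.testing.assert_allclose(curves[0].od, expected, rtol=1e-9)

    def test_hill_midpoint_halves_rate_and_capacity(self):
        p = GrowthSimParams(hill_h=3.7, concentrations=(0.0, 2.45), od_noise_sd=0.0,
                            n_replicates=1)
        _, truth = simulate_growth_curves(p)
        row = truth.table.set_index("conc_mM").loc[2.45]
        assert row["mu"] == pytest.approx(p.mu0 / 2)
        assert row["K"] == pytest.approx(p.K0 / 2)

    def test_rate_monotone_decreasing_in_concentration(self):
        p = GrowthSimParams(concentrations=(0.0, 1.0, 2.45, 5.0, 10.0),
                            od_noise_sd=0.0, n_replicates=1)
        _, truth = simulate_growth_curves(p)
        mus = truth.table.sort_values("conc_mM")["mu"].to_numpy()
        assert np.all(np.diff(mus) < 0)

    def test_replicate_mean_within_gaussian_noise_bound(self):
        p = GrowthSimParams(concentrations=(0.0,), od_noise_sd=0.02, n_replicates=3,
                            seed=21)
        curves, _ = simulate_growth_curves(p)
        clean = logistic_od(np.asarray(p.t_grid), p.mu0, p.K0, p.od0)
        mean_od = np.mean([c.od for c in curves], axis=0)
        bound = 3 * 0.02 / np.sqrt(3)
        frac_within = np.mean(np.abs(mean_od - clean) <= bound)
        assert frac_within >= 0.99

    def test_seeded_determinism(self):
        p = GrowthSimParams(seed=4, concentrations=(0.0, 2.0), n_replicates=2)
        c1, _ = simulate_growth_curves(p)
        c2, _ = simulate_growth_curves(p)
        for a, b in zip(c1, c2):
            np.testing.assert_array_equal(a.od, b.od)

    def test_invalid_params_raise(self):
        with pytest.raises(ValueError):
            simulate_growth_curves(GrowthSimParams(od0=2.0, K0=1.0))
        with pytest.raises(ValueError):
            simulate_growth_curves(GrowthSimParams(t_grid=(1.0, 0.5)))
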