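"""Experiment I/O, synthetic data, objective arithmetic, Sobol machinery."""

import numpy as np
import pandas as pd
import pytest

from emimech.calibrate import (DEFAULT_BOUNDS, ExperimentSample,
                               generate_synthetic_experiment, mode_magnitude,
                               objective, read_experiment, saltelli_design,
                               simulate_loads, sobol_sensitivity,
                               write_experiment, MODES)
from emimech.materials import PARAM_NAMES, MaterialParams


@pytest.fixture(scope="module")
def sim_setup(cal_setup):
    return cal_setup


@pytest.fixture(scope="module")
def synthetic_sample(cal_sample):
    return cal_sample


class TestExperimentIO:
    def test_round_trip(self, synthetic_sample, tmp_path):
        write_experiment(synthetic_sample, tmp_path / "s1")
        back = read_experiment(tmp_path / "s1")
        assert back.sample_id == synthetic_sample.sample_id
        assert set(back.modes) == set(synthetic_sample.modes)
        for mode in back.modes:
            lam0, load0 = synthetic_sample.modes[mode]
            lam1, load1 = back.modes[mode]
            assert np.array_equal(lam0, lam1)
            # the load <-> force area conversion costs the last ulp
            assert np.allclose(load0, load1, rtol=1e-12, atol=1e-15)

    def test_toy_table_starts_at_unit_stretch(self, tmp_path):
        d = tmp_path / "toy"
        d.mkdir()
        (d / "dimensions.json").write_text(
            '{"sample_id": "toy", "length_mm": 10, "width_mm": 10, '
            '"height_mm": 10}')
        pd.DataFrame({"displacement_mm": [0.0, 1.0],
                      "force_N": [0.0, 0.5]}).to_csv(d / "FF.csv",
                                                     index=False)
        with pytest.warns(UserWarning):
            sample = read_experiment(d)
        lam, load = sample.modes["FF"]
        assert lam[0] == 1.0 and load[0] == 0.0
        assert lam[1] == pytest.approx(1.1)
        assert load[1] == pytest.approx(0.5 / 100.0 * 1e3)  # N/mm^2 -> kPa

    def test_negative_displacements_dropped(self, tmp_path):
        d = tmp_path / "neg"
        d.mkdir()
        (d / "dimensions.json").write_text(
            '{"length_mm": 10, "width_mm": 10, "height_mm": 10}')
        pd.DataFrame({"displacement_mm": [-0.5, 0.0, 0.5],
                      "force_N": [-0.1, 0.0, 0.2]}).to_csv(d / "SS.csv",
                                                           index=False)
        with pytest.warns(UserWarning):
            sample = read_experiment(d)
        lam, _ = sample.modes["SS"]
        assert len(lam) == 2
        assert lam.min() >= 1.0

    def test_malformed_row_reported(self, tmp_path):
        d = tmp_path / "bad"
        d.mkdir()
        (d / "dimensions.json").write_text(
            '{"length_mm": 10, "width_mm": 10, "height_mm": 10}')
        (d / "FF.csv").write_text(
            "displacement_mm,force_N\n0.0,0.0\n0.5,\n")
        with pytest.raises(ValueError, match="line 3"):
            read_experiment(d)


class TestSyntheticGenerator:
    def test_noiseless_matches_simulator(self, synthetic_sample, sim_setup,
                                         table3_params):
        sim = simulate_loads(table3_params, modes=MODES, **sim_setup)
        for mode in MODES:
            _, load_sample = synthetic_sample.modes[mode]
            _, load_sim = sim[mode]
            assert np.allclose(load_sample, load_sim, rtol=1e-9, atol=1e-9)

    def test_same_seed_is_deterministic(self, sim_setup, table3_params):
        kw = dict(noise_sd=0.3, **sim_setup)
        a = generate_synthetic_experiment(table3_params, seed=5, **kw)
        b = generate_synthetic_experiment(table3_params, seed=5, **kw)
        for mode in MODES:
            assert np.array_equal(a.modes[mode][1], b.modes[mode][1])

    def test_noise_magnitude(self, sim_setup, table3_params,
                             synthetic_sample):
        """Mean absolute deviation of the added noise ~ sd * sqrt(2/pi)."""
        sd = 0.5
        devs = []
        for seed in range(8):
            noisy = generate_synthetic_experiment(
                table3_params, noise_sd=sd, seed=seed, **sim_setup)
            for mode in MODES:
                clean = synthetic_sample.modes[mode][1]
                dirty = noisy.modes[mode][1]
                devs.extend(np.abs(dirty - clean)[clean != 0.0])
        mad = np.mean(devs)
        assert mad == pytest.approx(sd * np.sqrt(2 / np.pi), rel=0.25)


class TestObjective:
    def test_zero_for_matching_data(self, synthetic_sample, sim_setup,
                                    table3_params):
        val = objective(table3_params, synthetic_sample,
                        sim_config=sim_setup)
        assert val < 1e-6

    def test_perturbation_increases_objective(self, synthetic_sample,
                                              sim_setup, table3_params):
        worse = MaterialParams.from_array(
            table3_params.as_array() * [1, 1, 2.0, 1, 1, 1])
        val = objective(worse, synthetic_sample, sim_config=sim_setup)
        assert val > 0.01

    def test_l2_arithmetic(self, synthetic_sample, sim_setup,
                           table3_params):
        """A hand-built discrepancy of 3 and 4 kPa must give exactly 5."""
        shifted = ExperimentSample(
            sample_id="shifted", length_mm=10, width_mm=10, height_mm=10)
        lamF, loadF = synthetic_sample.modes["FF"]
        lamS, loadS = synthetic_sample.modes["SS"]
        shifted.modes["FF"] = (lamF[-1:], loadF[-1:] + 3.0)
        shifted.modes["SS"] = (lamS[-1:], loadS[-1:] + 4.0)
        val = objective(table3_params, shifted, sim_config=sim_setup)
        assert val == pytest.approx(5.0, abs=1e-5)


class TestSobol:
    def test_design_size(self):
        X = saltelli_design(512, 6, seed=0)
        assert X.shape == (512 * 8, 6)
        assert X.min() >= 0.1 and X.max() <= 30.0

    def test_full_scale_evaluation_count(self):
        calls = [0]

        def f(x):
            calls[0] += 1
            return float(np.sum(x))

        sobol_sensitivity(f, n_base=512, dim=6, seed=1, n_boot=0)
        assert calls[0] == 4096

    def test_additive_linear_closed_form(self):
        c = np.array([3.0, 1.0, 0.5, 0.0, 2.0, 0.1])

        def f(x):
            return float(c @ x)

        res = sobol_sensitivity(f, n_base=1024, dim=6, seed=2, n_boot=50)
        expected = c ** 2 / np.sum(c ** 2)   # identical uniform ranges
        assert np.allclose(res.S1, expected, atol=0.05)
        assert np.allclose(res.ST, expected, atol=0.05)

    def test_single_parameter_dependence(self):
        def f(x):
            return float(np.sin(x[2]))

        res = sobol_sensitivity(f, n_base=256, dim=6, seed=3, n_boot=0)
        assert res.ST[2] > 0.9
        assert np.all(np.abs(np.delete(res.ST, 2)) < 0.05)

    def test_seeded_reproducibility(self):
        def f(x):
            return float(x[0] * x[1] + x[3] ** 2)

        a = sobol_sensitivity(f, n_base=128, dim=6, seed=9)
        b = sobol_sensitivity(f, n_base=128, dim=6, seed=9)
        assert np.array_equal(a.S1, b.S1)
        assert np.array_equal(a.ST, b.ST)
        assert np.array_equal(a.S1_conf, b.S1_conf)

    def test_degenerate_output_flagged(self):
        res = sobol_sensitivity(lambda x: 1.0, n_base=64, dim=6, seed=4)
        assert res.degenerate
        assert np.allclose(res.S1, 0.0) and np.allclose(res.ST, 0.0)


def test_mode_magnitudes():
    assert mode_magnitude("FF") == 0.10
    assert mode_magnitude("NS") == 0.40


def test_bounds_constant():
    assert DEFAULT_BOUNDS == (0.01, 40.0)
    assert len(PARAM_NAMES) == 6
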