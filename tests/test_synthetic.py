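"""Synthetic-data generator: catalog fidelity, noise structure, censoring."""

import numpy as np
import pytest

import nmrdfit as nf
from nmrdfit.synthetic import VIDAL_298_TAU_SCALE, ParameterCatalog

# Published parameter values, frozen as the decimal strings the tables print.
# Keyed by (jelly-kind row, temperature): (tau_s, c_i_dd, tau_i, a); the
# slow/fast dipolar constants and tau_f are global except where noted.
TABLE_ROWS = {
    ("bear|phantasia", 298): ("2.43e-6", "1.00e9", "4.83e-7", "27.0"),
    ("bear|phantasia", 323): ("2.43e-6", "8.02e8", "3.49e-7", "27.0"),
    ("balla-apple", 298): ("1.64e-6", "5.20e8", "3.97e-7", "40.6"),
    ("balla-apple", 323): ("1.50e-6", "4.12e8", "3.00e-7", "40.6"),
    ("balla-raspberry", 298): ("1.76e-6", "7.86e8", "4.34e-7", "37.8"),
    ("balla-raspberry", 323): ("1.37e-6", "1.78e8", "2.74e-7", "37.8"),
    ("tropifruity|color-rado", 298): ("1.92e-6", "7.08e8", "4.17e-7", "33.1"),
    ("tropifruity|color-rado", 323): ("1.20e-6", "3.61e8", "3.66e-7", "33.1"),
}
VIDAL_ROWS = {
    "coke|fish|pizza": ("1.46e8", "1.53e-6", "6.98e8", "2.53e-7",
                        "1.25e9", "3.55e-8", "25.6"),
    "cherry": ("1.16e7", "2.55e-6", "1.38e8", "3.45e-7",
               "9.11e8", "5.61e-8", "38.4"),
    "roll": ("1.46e8", "1.26e-6", "4.90e8", "9.32e-8",
             "1.25e9", "9.68e-9", "15.1"),
    "watermelon": ("2.94e7", "2.44e-6", "1.64e8", "4.27e-7",
                   "8.79e8", "4.39e-8", "35.0"),
}


class TestCatalogFidelity:
    def test_haribo_rows_match_published_strings(self, catalog):
        for row in catalog.rows:
            if row.brand != "Haribo":
                continue
            key = ("|".join(row.kinds), int(row.temperature_k))
            tau_s, c_i, tau_i, a = TABLE_ROWS[key]
            assert row.params["tau_s"].text == tau_s
            assert row.params["c_i_dd"].text == c_i
            assert row.params["tau_i"].text == tau_i
            assert row.params["a"].text == a
            # global slow/fast parameters, with the raspberry-323 exception
            assert row.params["c_s_dd"].text == "1.46e8"
            assert row.params["tau_f"].text == "5.21e-8"
            expected_cf = ("1.02e9" if key == ("balla-raspberry", 323)
                           else "1.25e9")
            assert row.params["c_f_dd"].text == expected_cf

    def test_vidal_rows_match_published_strings(self, catalog):
        seen = set()
        for row in catalog.rows:
            if row.brand != "Vidal":
                continue
            assert row.temperature_k == 323.0
            key = "|".join(row.kinds)
            values = VIDAL_ROWS[key]
            for name, text in zip(nf.PARAM_NAMES, values):
                assert row.params[name].text == text, (key, name)
            seen.add(key)
        assert seen == set(VIDAL_ROWS)

    def test_fixed_flags_follow_missing_uncertainties(self, catalog):
        bear323 = catalog.row_for("bear", 323)
        assert set(bear323.fixed_names()) == {"tau_s", "a"}
        coke = catalog.row_for("coke", 323)
        assert set(coke.fixed_names()) == {"c_s_dd", "c_f_dd"}
        cherry = catalog.row_for("cherry", 323)
        assert cherry.fixed_names() == ()

    def test_csv_and_json_forms_agree(self, catalog, tmp_path):
        catalog.to_json(tmp_path / "cat.json")
        from_json = ParameterCatalog.from_json(tmp_path / "cat.json")
        assert from_json.to_dict() == catalog.to_dict()
        catalog.to_csv(tmp_path / "cat.csv")
        from_csv = ParameterCatalog.from_csv(tmp_path / "cat.csv")
        assert from_csv.to_dict() == catalog.to_dict()

    def test_packaged_json_matches_packaged_csv(self, catalog):
        from importlib import resources
        path = resources.files("nmrdfit").joinpath("data/catalog.json")
        with resources.as_file(path) as p:
            from_json = ParameterCatalog.from_json(p)
        assert from_json.to_dict() == catalog.to_dict()


class TestMakeProfile:
    def test_zero_noise_equals_model(self, bear298, grid32):
        prof = nf.make_profile(bear298, grid32, nf.NoiseSpec(0.0, 0))
        assert np.array_equal(prof.r1, nf.evaluate_r1(bear298, grid32))
        assert not prof.censored.any()

    def test_seed_determinism(self, bear298, grid32):
        a = nf.make_profile(bear298, grid32, nf.NoiseSpec(0.02, 123))
        b = nf.make_profile(bear298, grid32, nf.NoiseSpec(0.02, 123))
        assert np.array_equal(a.r1, b.r1)
        c = nf.make_profile(bear298, grid32, nf.NoiseSpec(0.02, 124))
        assert not np.array_equal(a.r1, c.r1)

    def test_noise_level_calibrated(self, grid32):
        model = nf.RelaxationModel.from_components([1e9], [1e-7], 10.0)
        freqs = np.logspace(4, 7, 1000)
        prof = nf.make_profile(model, freqs, nf.NoiseSpec(0.02, 5))
        rel = prof.r1 / nf.evaluate_r1(model, freqs) - 1
        assert 0.017 < np.std(rel) < 0.023

    def test_noise_uncorrelated_across_frequencies(self):
        model = nf.RelaxationModel.from_components([1e9], [1e-7], 10.0)
        freqs = np.logspace(4, 7, 1000)
        prof = nf.make_profile(model, freqs, nf.NoiseSpec(0.02, 9))
        rel = prof.r1 / nf.evaluate_r1(model, freqs) - 1
        rho = np.corrcoef(rel[:-1], rel[1:])[0, 1]
        assert abs(rho) < 0.1

    def test_censoring_consistent_with_measurability(self, bear298, grid32):
        prof = nf.make_profile(bear298, grid32, nf.NoiseSpec(0.0, 0),
                               dead_time=3e-3)
        expected = ~nf.assess_measurability(nf.evaluate_r1(bear298, grid32),
                                            3e-3)
        assert np.array_equal(prof.censored, expected)
        assert prof.censored.any()  # the slowest rates exceed the 3 ms limit


class TestMakeRecovery:
    def test_exact_values_without_noise(self):
        t = np.linspace(0.0, 0.1, 20)
        curve = nf.make_recovery(50.0, 0.0, 1.0, t, nf.NoiseSpec(0.0, 0))
        assert curve.magnetization[0] == 0.0  # M(0) = m_init exactly
        at_5_t1 = nf.make_recovery(50.0, 0.0, 1.0, np.array([0.0, 0.1]),
                                   nf.NoiseSpec(0.0, 0))
        assert abs(at_5_t1.magnetization[-1] - 1.0) < 0.007  # e^-5 ≈ 0.0067

    def test_roundtrip_with_recovery_fitter(self):
        errors = []
        for seed in range(20):
            curve = nf.make_recovery(80.0, 0.0, 1.0,
                                     noise=nf.NoiseSpec(0.01, seed))
            fit = nf.fit_recovery(curve, dead_time=0.0)
            errors.append(abs(fit.r1 / 80.0 - 1))
        assert np.median(errors) < 0.03


class TestMakeDataset:
    def test_row_coverage_and_metadata(self, catalog):
        profiles = nf.make_dataset(catalog, noise=nf.NoiseSpec(0.0, 0))
        keys = {(p.meta["brand"], p.sample_id, p.temperature_k)
                for p in profiles}
        assert len(profiles) == 24  # 6 Haribo × 2 T + 6 Vidal + 6 emulated
        assert ("Haribo", "bear", 298.0) in keys
        assert ("Vidal", "coke", 298.0) in keys
        emulated = [p for p in profiles if p.meta.get("synthetic_emulation")]
        assert {p.temperature_k for p in emulated} == {298.0}
        assert all(p.censored.sum() >= 1 for p in emulated)
        real = [p for p in profiles if not p.meta.get("synthetic_emulation")]
        assert all(not p.censored.any() for p in real)

    def test_byte_determinism(self, catalog):
        a = nf.make_dataset(catalog, noise=nf.NoiseSpec(0.02, 77))
        b = nf.make_dataset(catalog, noise=nf.NoiseSpec(0.02, 77))
        for pa, pb in zip(a, b):
            assert pa.sample_id == pb.sample_id
            assert pa.r1.tobytes() == pb.r1.tobytes()

    def test_emulated_vidal_uses_scaled_correlation_times(self, catalog):
        profiles = nf.make_dataset(catalog, noise=nf.NoiseSpec(0.0, 0))
        cherry_emulated = next(p for p in profiles
                               if p.sample_id == "cherry"
                               and p.temperature_k == 298.0)
        scaled = catalog.row_for("cherry", 323).model(
            tau_scale=VIDAL_298_TAU_SCALE)
        mask = cherry_emulated.uncensored
        assert np.allclose(cherry_emulated.r1[mask],
                           nf.evaluate_r1(scaled, cherry_emulated.freqs_hz)[mask],
                           rtol=1e-12)

    def test_clean_profiles_refit_to_their_rows(self, catalog, grid32):
        """Noise-free generated profiles round-trip through the fitter."""
        profiles = nf.make_dataset(catalog, grid=grid32,
                                   noise=nf.NoiseSpec(0.0, 0),
                                   emulate_vidal_298=False)
        import warnings
        for prof in profiles[::3]:  # one representative per parameter row
            truth = catalog.model_for(prof.sample_id,
                                      prof.temperature_k).to_params()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                result = nf.fit_single(prof, 3, seed=0)
            fitted = result.models[0].to_params()
            for name in nf.PARAM_NAMES:
                assert fitted[name] == pytest.approx(truth[name], rel=1e-3)
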