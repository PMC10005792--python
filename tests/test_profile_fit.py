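"""Single, constrained-global and parsimony fitting of dispersion profiles."""

import warnings

import numpy as np
import pytest

import nmrdfit as nf
from nmrdfit.constraints import fixed, free, shared
from nmrdfit.fitting import DEFAULT_BLOCKS, write_fit_report
from nmrdfit.recovery import InsufficientDataError


def profile_from(model, grid, cv, seed, **kw):
    return nf.make_profile(model, grid, nf.NoiseSpec(cv, seed), **kw)


class TestFitSingle:
    def test_noise_free_roundtrip_all_catalog_rows(self, catalog, grid32):
        """Every published parameter row is recovered to ≤ 0.1% from clean data."""
        for row in catalog.rows:
            model = row.model()
            prof = profile_from(model, grid32, 0.0, 0)
            result = nf.fit_single(prof, 3, seed=0)
            truth = model.to_params()
            fitted = result.models[0].to_params()
            for name in nf.PARAM_NAMES:
                assert fitted[name] == pytest.approx(truth[name], rel=1e-3), \
                    f"{row.kinds[0]}@{row.temperature_k:g}: {name}"

    def test_offset_only_profile(self, grid32):
        model = nf.RelaxationModel((nf.SpectralComponent(0.0, 1e-7, "other"),),
                                   offset_a=27.0)
        prof = profile_from(model, grid32, 0.02, 3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = nf.fit_single(prof, 1, seed=0)
        fitted = result.models[0]
        # the spurious Lorentzian amplitude stays below the noise floor
        assert 5 * fitted.c_dd[0] * fitted.tau[0] < 3 * 0.02 * 27.0
        assert fitted.offset_a == pytest.approx(27.0, rel=0.02)

    def test_fixed_parameter_is_exact(self, bear323, grid32):
        prof = profile_from(bear323, grid32, 0.02, 5)
        result = nf.fit_single(prof, 3, fixed={"tau_s": 2.43e-6, "a": 27.0},
                               seed=1)
        fitted = result.models[0].to_params()
        assert fitted["tau_s"] == 2.43e-6
        assert fitted["a"] == 27.0
        assert result.uncertainties[0]["tau_s"] is None
        assert result.statuses[0]["tau_s"].startswith("fixed")

    def test_noisy_recovery_bear(self, bear298, grid32):
        """2% noise, 20 seeds: every parameter's median error stays modest."""
        truth = bear298.to_params()
        errs = {k: [] for k in nf.PARAM_NAMES}
        for seed in range(20):
            prof = profile_from(bear298, grid32, 0.02, seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                result = nf.fit_single(prof, 3, seed=seed)
            fitted = result.models[0].to_params()
            for k in nf.PARAM_NAMES:
                errs[k].append(abs(fitted[k] / truth[k] - 1))
        # intermediate/fast dynamics and the offset are tightly determined;
        # the slow pair carries the large C_s-τ_s anticorrelation
        for name in ("c_i_dd", "tau_i", "c_f_dd", "tau_f", "a"):
            assert np.median(errs[name]) < 0.05, name
        for name in ("c_s_dd", "tau_s"):
            assert np.median(errs[name]) < 0.25, name

    def test_insufficient_points_rejected(self, bear298):
        prof = profile_from(bear298, nf.FrequencyGrid.log_spaced(1e4, 1e7, 6),
                            0.0, 0)
        with pytest.raises(InsufficientDataError):
            nf.fit_single(prof, 3)

    def test_confidence_intervals_cover_truth(self, bear323, grid32, catalog):
        """Nominal 90% intervals cover the generating values most of the time."""
        row = catalog.row_for("bear", 323)
        truth = bear323.to_params()
        clamp = {n: truth[n] for n in row.fixed_names()}
        covered = {k: 0 for k in row.free_names()}
        n_seeds = 30
        for seed in range(n_seeds):
            prof = profile_from(bear323, grid32, 0.02, seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                result = nf.fit_single(prof, 3, fixed=clamp, seed=seed)
            fitted = result.models[0].to_params()
            unc = result.uncertainties[0]
            for k in covered:
                if abs(fitted[k] - truth[k]) <= 1.645 * unc[k]:
                    covered[k] += 1
        for k, n_cov in covered.items():
            assert n_cov >= 0.7 * n_seeds, k


class TestOptimizerOracle:
    def test_matches_exhaustive_grid_search(self, bear298, grid32):
        """On a 2-parameter sub-problem the optimizer lands on the grid-search
        minimum of the weighted SSE surface, within one 200×200 grid cell."""
        truth = bear298.to_params()
        prof = profile_from(bear298, grid32, 0.02, 11)
        clamp = {k: truth[k] for k in nf.PARAM_NAMES
                 if k not in ("c_i_dd", "tau_i")}
        result = nf.fit_single(prof, 3, fixed=clamp, seed=0)
        fitted = result.models[0].to_params()

        log_c = np.linspace(8.0, 10.0, 200)
        log_t = np.linspace(-7.5, -6.0, 200)
        omega = 2 * np.pi * prof.freqs_hz
        sigma = prof.r1_err
        base = (truth["c_s_dd"] * nf.lorentzian_bracket(truth["tau_s"], omega)
                + truth["c_f_dd"] * nf.lorentzian_bracket(truth["tau_f"], omega)
                + truth["a"])
        tau_grid = 10.0 ** log_t
        bracket = (tau_grid[:, None] / (1 + (omega[None, :] * tau_grid[:, None]) ** 2)
                   + 4 * tau_grid[:, None] / (1 + (2 * omega[None, :] * tau_grid[:, None]) ** 2))
        c_grid = 10.0 ** log_c
        # SSE over the (τ, C) grid, vectorized: residual (τ,C,ν)
        model_cube = base[None, None, :] + c_grid[None, :, None] * bracket[:, None, :]
        sse = np.sum(((model_cube - prof.r1[None, None, :]) / sigma) ** 2, axis=2)
        i_t, i_c = np.unravel_index(np.argmin(sse), sse.shape)
        step_c = log_c[1] - log_c[0]
        step_t = log_t[1] - log_t[0]
        assert abs(np.log10(fitted["c_i_dd"]) - log_c[i_c]) <= step_c
        assert abs(np.log10(fitted["tau_i"]) - log_t[i_t]) <= step_t


class TestGlobalFit:
    def test_identical_profiles_fully_shared(self, bear298, grid32):
        p1 = profile_from(bear298, grid32, 0.02, 21, sample_id="a",
                          temperature_k=298)
        p2 = profile_from(bear298, grid32, 0.02, 22, sample_id="b",
                          temperature_k=298)
        result = nf.global_fit([p1, p2], nf.ConstraintMap.fully_shared(2),
                               seed=0)
        m1, m2 = (m.to_params() for m in result.models)
        for name in nf.PARAM_NAMES:
            assert m1[name] == m2[name]  # bit-identical across the group
        truth = bear298.to_params()
        for name in ("c_i_dd", "tau_i", "c_f_dd", "tau_f", "a"):
            assert m1[name] == pytest.approx(truth[name], rel=0.1)

    def test_temperature_pair_with_table_constraints(self, bear298, bear323,
                                                     grid32):
        """Freeing only (C_i, τ_i) per temperature reproduces both rows."""
        p1 = profile_from(bear298, grid32, 0.02, 31, sample_id="bear",
                          temperature_k=298)
        p2 = profile_from(bear323, grid32, 0.02, 32, sample_id="bear",
                          temperature_k=323)
        entry = {
            "c_s_dd": shared("cs"), "tau_s": fixed(2.43e-6),
            "c_f_dd": shared("cf"), "tau_f": shared("tf"),
            "a": shared("a"), "c_i_dd": free(), "tau_i": free(),
        }
        cmap = nf.ConstraintMap([dict(entry), dict(entry)])
        result = nf.global_fit([p1, p2], cmap, seed=0)
        for i, truth_model in enumerate((bear298, bear323)):
            truth = truth_model.to_params()
            fitted = result.models[i].to_params()
            assert fitted["tau_s"] == 2.43e-6
            assert result.uncertainties[i]["tau_s"] is None
            for name in ("c_i_dd", "tau_i"):
                assert fitted[name] == pytest.approx(truth[name], rel=0.15), \
                    (i, name)

    def test_all_fixed_is_evaluate_only(self, bear298, grid32):
        truth = bear298.to_params()
        entry = {name: fixed(truth[name]) for name in nf.PARAM_NAMES}
        prof = profile_from(bear298, grid32, 0.02, 41)
        with pytest.warns(UserWarning, match="evaluat"):
            result = nf.global_fit([prof], nf.ConstraintMap([entry]))
        assert result.n_free == 0
        assert result.models[0].to_params() == truth

    def test_report_table_layout(self, bear298, grid32, tmp_path):
        prof = profile_from(bear298, grid32, 0.02, 51, sample_id="bear",
                            temperature_k=298)
        result = nf.fit_single(prof, 3, seed=0)
        frame = write_fit_report([result], tmp_path / "report.csv")
        assert (tmp_path / "report.csv").exists()
        assert frame.loc[0, "sample_id"] == "bear"
        for name in nf.PARAM_NAMES:
            assert name in frame.columns
            assert f"{name}_status" in frame.columns
        assert frame.loc[0, "aic"] == pytest.approx(result.aic)


class TestParsimonySearch:
    def test_identical_generators_free_nothing(self, bear298, grid32):
        p1 = profile_from(bear298, grid32, 0.02, 61, sample_id="x",
                          temperature_k=298)
        p2 = profile_from(bear298, grid32, 0.02, 62, sample_id="x",
                          temperature_k=298)
        out = nf.parsimony_search([p1, p2], seed=0)
        assert out.freed_blocks == []

    def test_intermediate_block_found_for_temperature_pair(self, bear298,
                                                           bear323, grid32):
        p1 = profile_from(bear298, grid32, 0.02, 71, sample_id="bear",
                          temperature_k=298)
        p2 = profile_from(bear323, grid32, 0.02, 72, sample_id="bear",
                          temperature_k=323)
        out = nf.parsimony_search([p1, p2], seed=0)
        assert out.freed_blocks == [("c_i_dd", "tau_i")]

    def test_raspberry_pair_frees_slow_time_too(self, catalog, grid32):
        m298 = catalog.model_for("balla-raspberry", 298)
        m323 = catalog.model_for("balla-raspberry", 323)
        p1 = profile_from(m298, grid32, 0.02, 81, sample_id="rasp",
                          temperature_k=298)
        p2 = profile_from(m323, grid32, 0.02, 82, sample_id="rasp",
                          temperature_k=323)
        out = nf.parsimony_search([p1, p2], seed=0)
        assert ("c_i_dd", "tau_i") in out.freed_blocks
        assert ("tau_s",) in out.freed_blocks

    def test_chisquare_never_increases_when_freeing(self, bear298, bear323,
                                                    grid32):
        p1 = profile_from(bear298, grid32, 0.02, 91, temperature_k=298)
        p2 = profile_from(bear323, grid32, 0.02, 92, temperature_k=323)
        base = nf.global_fit([p1, p2], nf.ConstraintMap.fully_shared(2), seed=0)
        current_map = nf.ConstraintMap.fully_shared(2)
        current = base
        for block in DEFAULT_BLOCKS:
            trial_map = current_map.with_free_block(block)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                trial = nf.global_fit([p1, p2], trial_map,
                                      init=current.models, seed=0)
            assert trial.chisqr <= current.chisqr * (1 + 1e-9)
            current_map, current = trial_map, trial


class TestSelectComponents:
    def test_three_components_noise_free(self, bear298, grid32):
        prof = profile_from(bear298, grid32, 0.0, 0)
        k, per_k = nf.select_components(prof, k_max=4, seed=0)
        assert k == 3
        assert per_k[3].aic < per_k[2].aic
        assert per_k[2].aic < per_k[1].aic

    def test_single_lorentzian_generator(self, grid32):
        model = nf.RelaxationModel.from_components([5e8], [1e-7], 20.0)
        prof = profile_from(model, grid32, 0.02, 7)
        k, _ = nf.select_components(prof, k_max=3, seed=0)
        assert k == 1

    def test_estimator_api(self, bear298, grid32):
        prof = profile_from(bear298, grid32, 0.02, 8)
        sel = nf.ComponentSelector(k_max=4, random_state=0).fit(prof)
        assert sel.k_ == 3
        assert sel.predict(grid32.freqs_hz).shape == (32,)


class TestConstraintMap:
    def test_json_roundtrip(self, tmp_path):
        entry = {"c_s_dd": shared("cs"), "tau_s": fixed(2.43e-6),
                 "c_i_dd": free()}
        cmap = nf.ConstraintMap([dict(entry), dict(entry)])
        cmap.to_json(tmp_path / "c.json")
        back = nf.ConstraintMap.from_json(tmp_path / "c.json")
        assert back == cmap
        assert back.constraint(0, "tau_s").value == 2.43e-6

    def test_shared_group_needs_two_members(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            nf.ConstraintMap([{"c_s_dd": shared("solo")}])

    def test_free_slot_counting(self):
        cmap = nf.ConstraintMap.fully_shared(3)
        assert cmap.n_free_slots == 7
        freed = cmap.with_free_block(("c_i_dd", "tau_i"))
        assert freed.n_free_slots == 5 + 2 * 3
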