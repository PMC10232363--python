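import filecmp

import numpy as np
import pandas as pd
import pytest

from nutriscreen import (
    ConfigError,
    KineticTrace,
    MID,
    SyntheticConfig,
    correct_natural_abundance,
    fit_curve_params,
    km_estimate,
    logistic_signal,
    simulate_expression,
    simulate_plates,
    simulate_spectra,
    simulate_standards,
    simulate_survival,
    spearman,
    write_campaign,
)
from nutriscreen.synthetic import spectra_frame

from conftest import small_config


class TestConfigValidation:
    def test_non_positive_duration_rejected(self):
        with pytest.raises(ConfigError):
            SyntheticConfig(duration_h=-1.0)
        with pytest.raises(ConfigError):
            SyntheticConfig(interval_h=0.0)

    def test_non_integer_grid_rejected(self):
        with pytest.raises(ConfigError):
            SyntheticConfig(duration_h=74.5, interval_h=0.4)

    def test_effect_size_out_of_range_rejected(self):
        with pytest.raises(ConfigError):
            SyntheticConfig(planted_pairs=(("uridine", "UPP1", 1.5),))

    def test_planted_gene_outside_range_rejected(self):
        with pytest.raises(ConfigError):
            SyntheticConfig(planted_pairs=(("uridine", "NOSUCH", 0.5),))

    def test_default_grid_is_paper_shape(self):
        cfg = SyntheticConfig()
        assert cfg.time_grid.size == 299  # 74.5 h at 15-min intervals, inclusive
        assert cfg.time_grid[-1] == pytest.approx(74.5)


class TestPlates:
    def test_noise_free_amplitude_identity(self):
        """A saturated noise-free logistic peaks at baseline + A and kinetics recovers A."""
        t = np.arange(0, 74.5 + 1e-9, 0.25)
        y = logistic_signal(t, lambda_h=10.0, mu=0.15, A=1.0, baseline=0.1)
        assert y.max() == pytest.approx(1.1, abs=1e-9)
        p = fit_curve_params(KineticTrace("P", "W", t, y), 5)
        assert p.A == pytest.approx(1.1, abs=1e-6)  # baseline included; A - baseline = 1

    def test_deterministic_output_bytes(self, tmp_path):
        cfg = small_config(seed=7)
        a = write_campaign(cfg, tmp_path / "a")
        b = write_campaign(cfg, tmp_path / "b")
        for name in a:
            assert filecmp.cmp(a[name], b[name], shallow=False), name

    def test_negative_control_max_matches_order_statistic_oracle(self):
        """SD of blank-well maxima matches a Monte-Carlo of max of i.i.d. normals."""
        cfg = SyntheticConfig(
            seed=5,
            n_cell_lines=12,
            n_substrates=8,
            n_neg_controls=85,
            n_pos_controls=3,
            noise_sd=0.01,
        )
        platemap, traces = simulate_plates(cfg)
        neg = platemap[platemap["role"] == "negative_control"]
        assert len(neg) == 1020
        merged = traces.merge(neg[["plate_id", "well"]], on=["plate_id", "well"])
        maxima = merged.groupby(["plate_id", "well"])["signal"].max()
        rng = np.random.default_rng(0)
        oracle = (0.01 * rng.standard_normal((4000, cfg.time_grid.size))).max(axis=1)
        assert abs(maxima.std() - oracle.std()) / oracle.std() < 0.30

    def test_outlier_line_shifted_uniformly(self):
        cfg = small_config(seed=2, outlier_cell_lines=("CL03",))
        _, _, truth = simulate_plates(cfg, return_truth=True)
        base = truth[truth["cell_line"] == "CL01"]["baseline"].unique()
        shifted = truth[truth["cell_line"] == "CL03"]["baseline"].unique()
        assert shifted == pytest.approx(base + cfg.outlier_shift)


class TestExpression:
    @staticmethod
    def random_rma(rng, cfg):
        return pd.DataFrame(
            rng.normal(0.5, 0.3, (cfg.n_substrates, cfg.n_cell_lines)),
            index=cfg.substrates,
            columns=cfg.cell_lines,
        )

    def test_effect_one_gives_perfect_spearman(self):
        cfg = small_config(planted_pairs=(("uridine", "UPP1", 1.0),))
        rma = self.random_rma(np.random.default_rng(1), cfg)
        expr = simulate_expression(cfg, rma)
        rho, _ = spearman(rma.loc["uridine"], expr.loc["UPP1"])
        assert rho == pytest.approx(1.0)

    def test_effect_zero_is_null_on_average(self):
        cfg = small_config(planted_pairs=(("uridine", "UPP1", 0.0),))
        rhos = []
        for seed in range(200):
            c = small_config(seed=seed, planted_pairs=(("uridine", "UPP1", 0.0),))
            rma = self.random_rma(np.random.default_rng(seed + 10_000), c)
            expr = simulate_expression(c, rma)
            rhos.append(spearman(rma.loc["uridine"], expr.loc["UPP1"])[0])
        assert abs(np.mean(rhos)) < 0.1

    def test_missing_cell_line_rejected(self):
        cfg = small_config()
        rma = self.random_rma(np.random.default_rng(0), cfg).drop(columns=["CL05"])
        with pytest.raises(ConfigError):
            simulate_expression(cfg, rma)


class TestSpectra:
    def test_p_zero_spectrum_proportional_to_mid(self):
        cfg = small_config(natural_abundance_p=0.0, spectra_noise_frac=0.0)
        mid = MID("met", np.array([1.0, 0.0, 0.0, 0.0]))
        (spec,) = simulate_spectra(cfg, [mid])
        np.testing.assert_allclose(
            spec.areas / spec.areas.sum(), [1.0, 0.0, 0.0, 0.0], atol=1e-12
        )

    def test_unlabelled_m1_fraction_is_binomial(self):
        """M+0-only input at p convolves to an M+1 share of n·p·(1−p)^(n−1)."""
        p = 0.0107
        cfg = small_config(natural_abundance_p=p, spectra_noise_frac=0.0)
        mid = MID("met", np.array([1.0, 0, 0, 0, 0, 0.0]))
        (spec,) = simulate_spectra(cfg, [mid])
        frac = spec.areas / spec.areas.sum()
        assert frac[1] == pytest.approx(5 * p * (1 - p) ** 4, abs=1e-12)

    def test_noise_free_round_trip(self):
        cfg = small_config(spectra_noise_frac=0.0)
        rng = np.random.default_rng(3)
        f = rng.dirichlet(np.ones(6))
        mid = MID("met", f / f.sum())
        (spec,) = simulate_spectra(cfg, [mid])
        recovered = correct_natural_abundance(spec, cfg.natural_abundance_p)
        np.testing.assert_allclose(recovered.fractions, mid.fractions, atol=1e-8)

    def test_unnormalized_mid_rejected(self):
        with pytest.raises(Exception):
            MID("met", np.array([0.5, 0.4]))  # sums to 0.9


class TestSurvival:
    def test_all_censored_km_is_flat_one(self):
        cfg = small_config(censor_max=1e-9, n_survival_samples=30)
        scores = pd.Series(
            np.random.default_rng(0).standard_normal(30),
            index=[f"T{i}" for i in range(30)],
        )
        surv = simulate_survival(cfg, scores)
        assert surv["event"].sum() == 0
        km = km_estimate(surv["time"], surv["event"])
        np.testing.assert_allclose(km.survival, 1.0)

    def test_invalid_hazard_ratio_rejected(self):
        with pytest.raises(ConfigError):
            small_config(hazard_ratio=0.0)


class TestStandards:
    def test_noise_free_series_is_exact_line(self):
        cfg = small_config(response_noise_frac=0.0)
        standards, samples = simulate_standards(cfg, [24.1, 50.0])
        slope, intercept = cfg.standard_slope, cfg.standard_intercept
        np.testing.assert_allclose(
            standards["response"], slope * standards["conc"] + intercept, atol=1e-12
        )
        np.testing.assert_allclose(
            samples["response"], slope * samples["true_conc"] + intercept, atol=1e-12
        )

    def test_dilution_series_spans_5mM_to_1uM(self):
        standards, _ = simulate_standards(small_config(), [10.0])
        assert standards["conc"].max() == pytest.approx(5000.0)
        assert standards["conc"].min() == pytest.approx(5000.0 * 0.5**12)  # ~1.2 μM


class TestSpectraFrame:
    def test_frame_round_trips_areas(self):
        cfg = small_config(spectra_noise_frac=0.0)
        mid = MID("met", np.array([0.2, 0.8]))
        specs = simulate_spectra(cfg, [mid], n_replicates=2, group="ctrl")
        frame = spectra_frame(specs)
        assert set(frame.columns) == {
            "metabolite", "n_carbons", "iso_index", "area", "sample", "group",
        }
        assert len(frame) == 2 * 2  # 2 replicates x (n_carbons + 1)
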