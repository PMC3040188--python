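import numpy as np
import pandas as pd
import pytest

from poolscan import (
    PipelineConfig,
    RasMatrix,
    ValidationError,
    filter_samples_by_cv,
    pca_stratification_check,
    probe_qc,
    replicate_correlation,
    variance_profile,
)
from poolscan.simulate import SimulationConfig, simulate_dataset

from conftest import make_design


def ras_from_rows(rows: dict, design) -> RasMatrix:
    return RasMatrix(
        pd.DataFrame.from_dict(rows, orient="index", columns=design.array_ids)
    )


class TestSampleCv:
    def test_constant_triplicate_kept(self):
        out = filter_samples_by_cv(pd.DataFrame({"a": [10], "b": [10], "c": [10]}))
        assert out["cv"].iloc[0] == 0.0 and out["kept"].iloc[0]

    def test_variable_triplicate_excluded(self):
        out = filter_samples_by_cv(pd.DataFrame({"a": [10], "b": [20], "c": [30]}))
        assert out["cv"].iloc[0] == pytest.approx(0.5)
        assert not out["kept"].iloc[0]

    def test_infinite_threshold_keeps_all(self):
        conc = pd.DataFrame(np.abs(np.random.default_rng(0).normal(10, 5, (20, 3))) + 1)
        assert filter_samples_by_cv(conc, cv_max=np.inf)["kept"].all()

    def test_non_positive_concentration_rejected(self):
        with pytest.raises(ValidationError, match="non-positive"):
            filter_samples_by_cv(pd.DataFrame({"a": [0.0], "b": [1.0], "c": [1.0]}))


class TestProbeQc:
    def test_band_and_aad_rules(self, design24):
        n = len(design24.array_ids)
        alternating = [0.1, 0.9] * (n // 2)
        ras = ras_from_rows(
            {"const": [0.5] * n, "rare": [0.05] * n, "noisy": alternating}, design24
        )
        qc = probe_qc(ras)
        assert qc.loc["const", "pass_flag"]
        assert qc.loc["const", "aad"] == 0.0
        assert not qc.loc["rare", "pass_flag"]
        assert qc.loc["rare", "reason"] == "mean RAS outside band"
        assert qc.loc["noisy", "mean_ras"] == pytest.approx(0.5)
        assert qc.loc["noisy", "aad"] == pytest.approx(0.4)
        assert not qc.loc["noisy", "pass_flag"]

    def test_boundary_is_strict(self, design24):
        n = len(design24.array_ids)
        ras = ras_from_rows({"edge": [0.9] * n}, design24)
        assert not probe_qc(ras)["pass_flag"].iloc[0]

    def test_insufficient_data(self, design24):
        n = len(design24.array_ids)
        row = [np.nan] * n
        row[0] = 0.5
        qc = probe_qc(ras_from_rows({"p": row}, design24))
        assert not qc["pass_flag"].iloc[0]
        assert qc["reason"].iloc[0] == "insufficient data"

    def test_order_independence(self, design24, rng):
        from conftest import random_ras

        ras = random_ras(design24, 50, rng)
        shuffled = RasMatrix(ras.values.sample(frac=1, axis=1, random_state=1))
        a = probe_qc(ras)
        b = probe_qc(shuffled)
        pd.testing.assert_frame_equal(a, b)


class TestReplicateCorrelation:
    def test_identical_and_negated_arrays(self, rng):
        design = make_design(n_pools=1, n_replicates=2)
        x = rng.random(30)
        vals = pd.DataFrame(
            {
                "case_p1_r1": x,
                "case_p1_r2": x,
                "control_p1_r1": 1 - x,
                "control_p1_r2": rng.random(30),
            },
            index=[f"p{i}" for i in range(30)],
        )
        corr, summary = replicate_correlation(RasMatrix(vals), design)
        assert corr.loc["case_p1_r1", "case_p1_r2"] == pytest.approx(1.0)
        assert corr.loc["case_p1_r1", "control_p1_r1"] == pytest.approx(-1.0)
        assert np.allclose(np.diag(corr), 1.0)
        assert np.allclose(corr, corr.T)

    def test_zero_variance_array_reported_missing(self, design24, rng):
        from conftest import random_ras

        ras = random_ras(design24, 30, rng)
        vals = ras.values.copy()
        vals.iloc[:, 0] = 0.5
        corr, summary = replicate_correlation(RasMatrix(vals), design24)
        assert corr.iloc[0, 1:].isna().all()
        assert summary["warning"]

    def test_triplicates_more_correlated_than_between_groups(self):
        ds = simulate_dataset(
            SimulationConfig(
                n_probes=300, n_chromosomes=1, n_effect_blocks=0,
                effect_delta=0.0, tau=0.02, sigma=0.02, seed=11,
            )
        )
        _, summary = replicate_correlation(ds.ras, ds.design)
        assert summary["within_triplicate_mean"] > summary["between_group_mean"]


class TestVarianceProfile:
    def test_constant_matrix_gives_zero_means(self, design24):
        n = len(design24.array_ids)
        ras = ras_from_rows({f"p{i}": [0.4] * n for i in range(5)}, design24)
        profile = variance_profile(ras, design24)
        for mu in (profile.mu_replicate, profile.mu_group, profile.mu_overall):
            assert mu == pytest.approx(0.0, abs=1e-15)

    def test_measurement_noise_only_is_homogeneous(self):
        # tau=0 and no effect: the three nesting levels agree closely
        ds = simulate_dataset(
            SimulationConfig(
                n_probes=400, n_chromosomes=1, n_effect_blocks=0,
                effect_delta=0.0, tau=0.0, sigma=0.04, seed=5,
            )
        )
        # keep only the measurement layer: divide out pool-frequency spread
        resid = ds.ras.values.to_numpy() - ds.pool_freqs.reindex(
            columns=[(r["group"], r["pool"]) for _, r in ds.design.table.iterrows()]
        ).to_numpy()
        ras = RasMatrix(
            pd.DataFrame(
                np.clip(resid + 0.5, 0, 1),
                index=ds.ras.probe_ids, columns=ds.ras.array_ids,
            )
        )
        profile = variance_profile(ras, ds.design)
        assert profile.mu_group == pytest.approx(profile.mu_replicate, rel=0.1)
        assert profile.mu_overall == pytest.approx(profile.mu_replicate, rel=0.1)

    def test_planted_group_difference_inflates_overall_level(self):
        ds = simulate_dataset(
            SimulationConfig(
                n_probes=200, n_chromosomes=1, n_effect_blocks=12,
                effect_delta=0.3, tau=0.02, sigma=0.02, seed=6,
            )
        )
        profile = variance_profile(ds.ras, ds.design)
        assert profile.mu_overall > profile.mu_group


class TestStratificationCheck:
    def _markers(self, ras):
        return list(ras.probe_ids[:40])

    def test_single_population_groups_are_mixed(self):
        scores = []
        for seed in range(6):
            ds = simulate_dataset(
                SimulationConfig(
                    n_probes=150, n_chromosomes=1, n_effect_blocks=0,
                    effect_delta=0.0, tau=0.02, sigma=0.02, seed=seed,
                )
            )
            res = pca_stratification_check(ds.ras, ds.design, self._markers(ds.ras))
            scores.append(abs(res.mixing_score))
        assert np.mean(scores) < 0.2

    def test_stratified_groups_are_flagged(self, design24, rng):
        # the two groups drawn around different marker frequencies
        labels = design24.table["group"].to_numpy()
        base = rng.uniform(0.2, 0.8, 60)
        shift = np.where(rng.random(60) < 0.5, 0.15, -0.15)
        vals = np.empty((60, len(labels)))
        for j, g in enumerate(labels):
            centre = base + (shift if g == "case" else 0.0)
            vals[:, j] = np.clip(centre + rng.normal(0, 0.02, 60), 0, 1)
        ras = RasMatrix(
            pd.DataFrame(vals, index=[f"p{i}" for i in range(60)], columns=design24.array_ids)
        )
        res = pca_stratification_check(ras, design24, [f"p{i}" for i in range(60)])
        assert res.mixing_score > 0.5 and res.alarm

    def test_constant_matrix_is_degenerate(self, design24):
        n = len(design24.array_ids)
        ras = ras_from_rows({f"p{i}": [0.5] * n for i in range(10)}, design24)
        res = pca_stratification_check(ras, design24, [f"p{i}" for i in range(10)])
        assert res.degenerate and res.mixing_score == 0.0

    def test_missing_marker_ids_rejected(self, design24, rng):
        from conftest import random_ras

        ras = random_ras(design24, 10, rng)
        with pytest.raises(ValidationError, match="ghost"):
            pca_stratification_check(ras, design24, ["p0000", "ghost"])
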