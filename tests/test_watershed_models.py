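import numpy as np
import pytest

from watershed_sem.estimation import DataInput, fit, standardize_solution
from watershed_sem.fit_compare import fit_baseline, fit_indices, lrt_nested
from watershed_sem.model_spec import degrees_of_freedom
from watershed_sem.synthetic_data import CohortConfig, generate_cohort
from watershed_sem.watershed_models import (
    CALM_BATTERY,
    NKI_BATTERY,
    TRACTS,
    CohortBattery,
    build_cognitive_regression,
    build_measurement_model,
    build_single_path_model,
    build_watershed,
    build_wm_single_factor,
    run_full_analysis,
    single_path_probe,
)

# hand-enumerated free-parameter counts for every watershed variant (CALM):
# loadings + task residuals + latent (residual) variances + regressions +
# residual covariances + tract variances + tract covariances
CALM_WATERSHED_FREE = {
    "original": 93,            # 5+7+3+22+1+10+45
    "zero_paths_to_speed": 83,
    "zero_paths_to_memory": 83,
    "equal_tract_paths": 75,   # 20 tract paths collapse to 2
    "altA": 82,                # 5+7+3+12+0+10+45
    "altC": 83,                # 5+7+3+12+1+10+45
    "altD": 103,               # 5+7+3+12+21 exo covs+10+45
}


class TestBattery:
    def test_calm_counts(self):
        assert len(CALM_BATTERY.wm_tasks) == 4
        assert len(CALM_BATTERY.gf_tasks) == 1
        assert len(CALM_BATTERY.speed_tasks) == 3
        assert len(CALM_BATTERY.tract_names) == 10

    def test_nki_counts(self):
        assert len(NKI_BATTERY.wm_tasks) == 3
        assert len(NKI_BATTERY.gf_tasks) == 4
        assert len(NKI_BATTERY.speed_tasks) == 3

    def test_disjoint_tasks_enforced(self):
        with pytest.raises(ValueError, match="disjoint"):
            CohortBattery(label="x", wm_tasks=("a", "b"), gf_tasks=("a",),
                          speed_tasks=("c",))

    def test_ten_tracts_enforced(self):
        with pytest.raises(ValueError, match="10 tract"):
            CohortBattery(label="x", wm_tasks=("a",), gf_tasks=("b",),
                          speed_tasks=("c",), tract_names=("UF", "SLF"))

    def test_roundtrip(self):
        assert CohortBattery.from_dict(CALM_BATTERY.to_dict()) == CALM_BATTERY


class TestBuilders:
    def test_unknown_variants(self):
        with pytest.raises(ValueError):
            build_measurement_model(CALM_BATTERY, "four")
        with pytest.raises(ValueError):
            build_watershed(CALM_BATTERY, "altE")
        with pytest.raises(ValueError):
            build_cognitive_regression(CALM_BATTERY, "both_zero")

    def test_wm_single_factor_df(self):
        assert degrees_of_freedom(build_wm_single_factor(TRACTS)) == 35

    def test_watershed_df(self):
        assert degrees_of_freedom(build_watershed(CALM_BATTERY, "original")) == 78
        assert degrees_of_freedom(build_watershed(NKI_BATTERY, "original")) == 112

    @pytest.mark.parametrize("variant,expected_q", sorted(CALM_WATERSHED_FREE.items()))
    def test_variant_free_parameter_bookkeeping(self, variant, expected_q):
        from watershed_sem.model_spec import build_ram
        spec = build_watershed(CALM_BATTERY, variant)
        assert build_ram(spec).n_free == expected_q

    def test_zero_paths_df_increment(self):
        base = degrees_of_freedom(build_watershed(CALM_BATTERY, "original"))
        for variant in ("zero_paths_to_speed", "zero_paths_to_memory"):
            assert degrees_of_freedom(build_watershed(CALM_BATTERY, variant)) \
                == base + 10
        assert degrees_of_freedom(
            build_watershed(CALM_BATTERY, "equal_tract_paths")) == base + 18

    def test_equal_paths_df_increment(self):
        free = degrees_of_freedom(build_cognitive_regression(CALM_BATTERY, "free"))
        eq = degrees_of_freedom(
            build_cognitive_regression(CALM_BATTERY, "equal_paths"))
        assert eq == free + 1


class TestRegressionComparisons:
    def test_zero_speed_negligible_when_speed_irrelevant(self, calm_cov_5k):
        # generator truth has a near-zero speed -> fluid path
        free = fit(build_cognitive_regression(CALM_BATTERY, "free"), calm_cov_5k)
        zero = fit(build_cognitive_regression(CALM_BATTERY, "zero_speed"),
                   calm_cov_5k)
        d, ddf, p = lrt_nested(zero, free)
        assert ddf == 1
        assert p > 0.01

    def test_zero_memory_rejected(self, calm_cov_5k):
        free = fit(build_cognitive_regression(CALM_BATTERY, "free"), calm_cov_5k)
        zero = fit(build_cognitive_regression(CALM_BATTERY, "zero_memory"),
                   calm_cov_5k)
        d, ddf, p = lrt_nested(zero, free)
        assert ddf == 1
        assert p < 1e-6


class TestWmSingleFactor:
    def test_misfit_detectable_under_three_cluster_truth(self, rng):
        n = 5000
        clusters = [TRACTS[:4], TRACTS[4:7], TRACTS[7:]]
        f = rng.multivariate_normal(np.zeros(3),
                                    0.3 * np.ones((3, 3)) + 0.7 * np.eye(3),
                                    size=n)
        cols = {}
        for k, cl in enumerate(clusters):
            for t in cl:
                cols[t] = 0.85 * f[:, k] + rng.standard_normal(n) * 0.55
        raw = np.column_stack([cols[t] for t in TRACTS])
        data = DataInput.from_covariance(np.cov(raw, rowvar=False), n=n,
                                         names=TRACTS)
        result = fit(build_wm_single_factor(TRACTS), data)
        ix = fit_indices(result, fit_baseline(data))
        assert ix.cfi < 0.95

    def test_good_fit_under_one_factor_truth(self, rng):
        n = 5000
        f = rng.standard_normal(n)
        raw = np.column_stack([0.7 * f + rng.standard_normal(n) * 0.71
                               for _ in TRACTS])
        data = DataInput.from_covariance(np.cov(raw, rowvar=False), n=n,
                                         names=TRACTS)
        result = fit(build_wm_single_factor(TRACTS), data)
        ix = fit_indices(result, fit_baseline(data))
        assert ix.rmsea < 0.05


class TestSinglePathProbe:
    def test_recovers_single_true_path(self, rng):
        config = CohortConfig(
            n_subjects=10_000, imaging_fraction=1.0, emit_raw_speed=False,
            seed=77,
            tract_paths_wm=(0, 0, 0, 0, 0, 0, 0.5, 0, 0, 0),  # FMin only
            tract_paths_speed=tuple([0.0] * 10), r2_wm=0.25, r2_speed=0.0)
        df = generate_cohort(config)
        cols = list(CALM_BATTERY.all_columns)
        data = DataInput.from_covariance(df[cols].cov().to_numpy(),
                                         n=len(df), names=cols)
        rec = single_path_probe(CALM_BATTERY, "FMin", "wm", data)
        assert rec["converged"]
        assert rec["standardized"] == pytest.approx(0.5, abs=0.05)

    def test_probe_model_df(self):
        spec = build_single_path_model(CALM_BATTERY, "FMin", "wm")
        # removing 19 tract paths from the original watershed frees 19 moments
        assert degrees_of_freedom(spec) == 78 + 19

    def test_bad_tract_errors(self, calm_cov_5k):
        with pytest.raises(ValueError, match="tract"):
            single_path_probe(CALM_BATTERY, "XYZ", "wm", calm_cov_5k)
        with pytest.raises(ValueError, match="endophenotype"):
            single_path_probe(CALM_BATTERY, "FMin", "gf", calm_cov_5k)


@pytest.fixture(scope="module")
def report(calm_cov_5k):
    return run_full_analysis({"calm": calm_cov_5k},
                             {"calm": CALM_BATTERY},
                             probes={"calm": [("FMin", "wm")]})


class TestModelSelection:
    def test_original_wins_five_model_contest(self):
        """Data generated under the watershed truth: the original model
        attains the largest Akaike weight among {original, altA-D} in at
        least 90% of replicates (30 replicates at n = 2,000)."""
        from watershed_sem.fit_compare import akaike_weights
        cols = list(CALM_BATTERY.all_columns)
        specs = {v: build_watershed(CALM_BATTERY, v)
                 for v in ("original", "altA", "altB", "altC", "altD")}
        wins = 0
        n_reps = 30
        for rep in range(n_reps):
            config = CohortConfig(n_subjects=2000, imaging_fraction=1.0,
                                  emit_raw_speed=False, seed=9000 + rep)
            df = generate_cohort(config)
            data = DataInput.from_covariance(df[cols].cov().to_numpy(),
                                             n=2000, names=cols)
            aics = []
            for spec in specs.values():
                f = fit(spec, data)
                aics.append(-2 * f.loglik + 2 * f.n_free)
            wins += int(np.argmax(akaike_weights(aics))) == 0
        assert wins / n_reps >= 0.90


class TestFullAnalysis:
    def test_structure(self, report):
        section = report.cohorts["calm"]
        assert set(section) == {"measurement", "cognitive_regression",
                                "white_matter", "watershed", "probes"}
        assert len(section["probes"]) == 1
        for model, f in report.fits["calm"].items():
            assert f.converged, model

    def test_r_squared_near_truth(self, report):
        r2 = report.cohorts["calm"]["watershed"]["r_squared"]
        assert r2["wm"] == pytest.approx(0.323, abs=0.05)
        assert r2["speed"] == pytest.approx(0.382, abs=0.05)
        assert r2["gf"] == pytest.approx(0.51, abs=0.05)

    def test_original_watershed_preferred(self, report):
        weights = report.cohorts["calm"]["watershed"]["table"]["akaike_weights"]
        assert max(weights, key=weights.get) == "original"

    def test_report_is_pure(self, report, calm_cov_5k):
        again = run_full_analysis({"calm": calm_cov_5k},
                                  {"calm": CALM_BATTERY},
                                  probes={"calm": [("FMin", "wm")]})
        assert report.to_json() == again.to_json()

    def test_markdown_renders(self, report):
        md = report.to_markdown()
        assert "Measurement models" in md and "R^2" in md

    def test_empty_inputs_error(self):
        with pytest.raises(ValueError, match="empty"):
            run_full_analysis({}, {})
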