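"""Cascade tests: FDR, selection, paired tests, phase wiring, invariants."""

import numpy as np
import pandas as pd
import pytest

from twinmet import (
    SimulationConfig, CascadeConfig, simulate_dataset, bh_adjust, residualize,
    within_pair_test, select_top_fraction, select_for_validation,
    run_discovery, run_replication, run_validation, sensitivity_rerun,
    run_cascade, CascadeAnalysis,
)
from twinmet.preprocess import run_preprocessing


def brute_force_bh(p):
    """Independent step-up oracle: p_(i) * m / i, cumulative min from the top."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


class TestBH:
    def test_hand_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_test_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            m = rng.integers(1, 101)
            p = rng.uniform(size=m)
            np.testing.assert_allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)


class TestSelection:
    def records(self, panels, ps, betas):
        return pd.DataFrame({"panel": panels, "p": ps, "beta": betas},
                            index=pd.Index([f"m{i}" for i in range(len(ps))],
                                           name="id"))

    def test_per_panel_counts_forward_23(self):
        rng = np.random.default_rng(1)
        panels = ["amines"] * 64 + ["organic_acids"] * 20 + ["other"] * 5
        rec = self.records(panels, rng.uniform(size=89), rng.normal(size=89))
        selected = select_top_fraction(rec, CascadeConfig())
        assert len(selected) == 23

    def test_global_fraction_ceiling(self):
        rec = self.records(["amines"] * 8, np.linspace(0.01, 0.8, 8),
                           np.ones(8))
        cfg = CascadeConfig(per_panel_counts=None)
        assert len(select_top_fraction(rec, cfg)) == 2  # ceil(0.25 * 8)

    def test_tie_break_by_abs_beta(self):
        rec = self.records(["amines"] * 3, [0.5, 0.01, 0.01], [9.0, 0.1, 0.5])
        cfg = CascadeConfig(per_panel_counts=None, top_fraction=0.3)
        assert select_top_fraction(rec, cfg) == ["m2"]  # p tie -> larger |beta|

    def test_count_exceeding_panel_errors(self):
        rec = self.records(["amines"] * 2, [0.1, 0.2], [1.0, 1.0])
        cfg = CascadeConfig(per_panel_counts={"amines": 5})
        with pytest.raises(ValueError, match="exceeds panel"):
            select_top_fraction(rec, cfg)


class TestResidualize:
    def test_orthogonal_to_covariates(self):
        rng = np.random.default_rng(2)
        sex = rng.integers(0, 2, 50).astype(float)
        age = rng.uniform(6, 13, 50)
        y = rng.normal(size=50)
        r = residualize(y, sex, age)
        assert abs(r.mean()) < 1e-10
        assert abs(r @ sex) < 1e-8
        assert abs(r @ (age - age.mean())) < 1e-7

    def test_pure_age_outcome_vanishes(self):
        age = np.linspace(6, 13, 20)
        sex = np.r_[np.zeros(10), np.ones(10)]
        r = residualize(2.0 * age, sex, age)
        np.testing.assert_allclose(r, 0.0, atol=1e-10)

    def test_collinear_covariates_error(self):
        age = np.ones(10)
        with pytest.raises(ValueError, match="collinear"):
            residualize(np.arange(10.0), np.ones(10), age)


def discordant_cohort(n_pairs):
    rows = []
    for i in range(n_pairs):
        for role, grp in (("twin1", "discordant_high"), ("twin2", "discordant_low")):
            rows.append({"subject_id": f"F{i}_{role[-1]}", "family_id": f"F{i}",
                         "zygosity": "MZ", "role": role,
                         "sex": "F" if i % 2 else "M",
                         "age": 6.0 + (i % 7), "aggression_score": 5.0,
                         "t_score": 50.0, "group": grp, "density": 1.02,
                         "excl_chronic": False, "excl_medication": False,
                         "excl_vitamins": False})
    return pd.DataFrame(rows)


class TestWithinPairTest:
    def residuals_for(self, diffs):
        cohort = discordant_cohort(len(diffs))
        resid = {}
        for i, d in enumerate(diffs):
            resid[f"F{i}_1"] = float(d)
            resid[f"F{i}_2"] = 0.0
        return pd.Series(resid), cohort

    def test_hand_t_statistic(self):
        resid, cohort = self.residuals_for([1.0, 2.0, 3.0])
        rec = within_pair_test(resid, cohort)
        assert rec["mean_diff"] == pytest.approx(2.0)
        assert rec["t"] == pytest.approx(2.0 / (1.0 / np.sqrt(3)), abs=1e-9)
        assert rec["t"] == pytest.approx(3.464, abs=1e-3)
        assert rec["df"] == 2

    def test_zero_variance_guard(self):
        resid, cohort = self.residuals_for([0.0, 0.0, 0.0])
        rec = within_pair_test(resid, cohort)
        assert rec["mean_diff"] == 0.0 and rec["p"] == 1.0

    def test_df_bookkeeping_at_design_scale(self):
        rng = np.random.default_rng(3)
        resid, cohort = self.residuals_for(rng.normal(size=189))
        assert within_pair_test(resid, cohort)["df"] == 188

    def test_incomplete_pair_dropped(self):
        resid, cohort = self.residuals_for([1.0, 2.0, 3.0])
        resid[resid.index[0]] = np.nan
        assert within_pair_test(resid, cohort)["n_pairs"] == 2

    def test_family_level_confounder_invariance(self):
        # adding a per-family constant leaves all differences bit-identical
        rng = np.random.default_rng(4)
        diffs = rng.normal(size=30)
        resid, cohort = self.residuals_for(diffs)
        shifted = resid.copy()
        for i in range(30):
            shift = rng.normal()
            shifted[f"F{i}_1"] += shift
            shifted[f"F{i}_2"] += shift
        a = within_pair_test(resid, cohort)
        b = within_pair_test(shifted, cohort)
        assert a["df"] == b["df"] and a["n_pairs"] == b["n_pairs"]
        # identical up to float cancellation of the added constants
        assert a["mean_diff"] == pytest.approx(b["mean_diff"], rel=1e-12)
        assert a["t"] == pytest.approx(b["t"], rel=1e-12)


class TestCongruenceSelection:
    def frames(self, betas, diffs, ps=None):
        idx = pd.Index([f"m{i}" for i in range(len(betas))], name="id")
        disc = pd.DataFrame({"beta": betas,
                             "p": ps if ps is not None else np.linspace(0.01, 0.2, len(betas))},
                            index=idx)
        rep = pd.DataFrame({"mean_diff": diffs}, index=idx)
        return disc, rep

    def test_incongruent_excluded(self):
        disc, rep = self.frames([0.2, -0.3], [-0.1, -0.2])
        selected, book = select_for_validation(disc, rep, CascadeConfig(), k=2)
        assert selected == ["m1"]
        assert not book.loc["m0", "congruent"]

    def test_all_incongruent_warns_empty(self):
        disc, rep = self.frames([0.2, 0.3], [-0.1, -0.2])
        with pytest.warns(UserWarning, match="congruent"):
            selected, _ = select_for_validation(disc, rep, CascadeConfig(), k=2)
        assert selected == []

    def test_best_by_discovery_p(self):
        disc, rep = self.frames([0.2, 0.3, 0.4], [0.1, 0.2, 0.3],
                                ps=[0.5, 0.001, 0.01])
        selected, _ = select_for_validation(disc, rep, CascadeConfig(), k=2)
        assert selected == ["m1", "m2"]


@pytest.fixture(scope="module")
def small_report(small_dataset, small_config):
    cohort, matrix, _ = small_dataset
    return run_cascade(cohort, matrix, CascadeConfig(), seed=small_config.seed)


class TestCascadeEndToEnd:
    def test_nesting_invariant(self, small_report):
        r = small_report
        assert set(r.candidate_features) <= set(r.selected_features)
        assert set(r.selected_features) <= set(r.discovery_features.index)
        assert set(r.replication_features.index) == set(r.selected_features)

    def test_forwards_five_biomarkers_and_one_ratio(self, default_dataset):
        cohort, matrix, _ = default_dataset
        report = run_cascade(cohort, matrix, CascadeConfig(), seed=0)
        assert len(report.selected_features) == 23
        assert len(report.selected_ratios) == 3
        assert len(report.candidate_features) == 5
        assert report.candidate_ratio in report.selected_ratios
        assert len(report.validation_features) == 5
        # candidates are congruent across discovery and replication
        book = report.candidate_book
        assert book.loc[report.candidate_features, "congruent"].all()

    def test_validation_n_bookkeeping(self, default_dataset):
        cohort, matrix, _ = default_dataset
        report = run_cascade(cohort, matrix, CascadeConfig(), seed=0)
        n_val = int((cohort["group"].isin(["case", "control"])).sum())
        assert (report.validation_features["n"] == n_val).all()
        assert n_val == 183 + 184

    def test_fdr_p_never_below_p(self, small_report):
        for df in (small_report.discovery_features, small_report.discovery_ratios,
                   small_report.replication_features):
            assert (df["fdr_p"] >= df["p"] - 1e-15).all()

    def test_estimator_wrapper(self, small_dataset):
        cohort, matrix, _ = small_dataset
        est = CascadeAnalysis().fit(cohort, matrix)
        assert est.report_.report_hash() == est.report_.report_hash()
        assert list(est.discovery_.index) == list(
            est.report_.discovery_features.index)
        assert "config" in est.get_params()

    def test_empty_discovery_set_errors(self, small_dataset):
        cohort, matrix, _ = small_dataset
        disc_only = cohort[cohort["group"].isin(["case", "control"])]
        with pytest.raises(ValueError, match="empty discovery"):
            run_discovery(pd.DataFrame(index=disc_only["subject_id"]),
                          pd.DataFrame(index=disc_only["subject_id"]),
                          disc_only, CascadeConfig())

    def test_overlapping_phases_rejected(self, small_dataset):
        cohort, matrix, _ = small_dataset
        bad = cohort.copy()
        # move one case into a discovery family
        fam = bad.loc[bad["group"] == "concordant_low", "family_id"].iloc[0]
        case_idx = bad.index[bad["group"] == "case"][0]
        bad.loc[case_idx, "family_id"] = fam
        with pytest.raises(ValueError, match="independent"):
            run_cascade(bad, matrix, CascadeConfig())

    def test_absent_candidate_errors(self, small_dataset):
        cohort, _, _ = small_dataset
        feats = pd.DataFrame({"x": np.zeros(len(cohort))},
                             index=cohort["subject_id"])
        with pytest.raises(ValueError, match="absent"):
            run_validation(feats, feats, cohort, ["nope"], None, CascadeConfig())


class TestSensitivity:
    def test_no_exclusions_identity(self, small_dataset):
        cohort, matrix, _ = small_dataset
        clean = cohort.copy()
        for flag in ("excl_chronic", "excl_medication", "excl_vitamins"):
            clean[flag] = False
        report = run_cascade(clean, matrix, CascadeConfig())
        sens = report.sensitivity_features
        rep = report.replication_features.loc[report.candidate_features]
        for flag in ("excl_chronic", "excl_medication", "excl_vitamins"):
            sub = sens[sens["scenario"] == flag]
            np.testing.assert_allclose(sub["mean_diff"].to_numpy(),
                                       rep["mean_diff"].to_numpy())
            np.testing.assert_allclose(sub["t"].to_numpy(), rep["t"].to_numpy())

    def test_flagged_twin_drops_whole_pair(self):
        cohort = discordant_cohort(5)
        cohort.loc[cohort["subject_id"] == "F0_1", "excl_medication"] = True
        rng = np.random.default_rng(5)
        feats = pd.DataFrame({"x": rng.normal(size=len(cohort))},
                             index=cohort["subject_id"])
        sens, _ = sensitivity_rerun(feats, feats.iloc[:, :0], cohort, ["x"],
                                    None, CascadeConfig(),
                                    flags=("excl_medication",))
        assert sens["n_pairs"].iloc[0] == 4

    def test_exclusion_removes_planted_confounder_bias(self):
        # medication-linked shift biases within-pair differences; excluding
        # medicated twins' pairs restores the null
        full, excl = [], []
        for seed in range(15):
            cfg = SimulationConfig(
                n_amines=8, n_organic_acids=2, n_other=1, n_true_assoc=0,
                exclusion_shift=1.0, n_concordant_low_pairs=20,
                n_concordant_high_pairs=15, n_discordant_pairs=45,
                n_control_pairs=8, n_clinical=5, seed=100 + seed,
            )
            cohort, matrix, _ = simulate_dataset(cfg)
            dens = pd.Series(cohort["density"].to_numpy(),
                             index=cohort["subject_id"].to_numpy())
            mask = pd.Series(
                cohort["group"].isin(["concordant_low", "control"]).to_numpy(),
                index=cohort["subject_id"].to_numpy())
            feats = run_preprocessing(matrix, dens, mask)["int"].values
            names = list(feats.columns)
            empty = feats.iloc[:, :0]
            rep, _ = run_replication(feats, empty, cohort, names, [],
                                     CascadeConfig())
            sens, _ = sensitivity_rerun(feats, empty, cohort, names, None,
                                        CascadeConfig(),
                                        flags=("excl_medication",))
            full.extend(rep["mean_diff"].tolist())
            excl.extend(sens["mean_diff"].tolist())
        assert np.mean(full) > 0.1              # planted bias visible
        assert abs(np.mean(excl)) < np.mean(full) / 2


class TestMonotonicity:
    def test_effect_size_monotone_in_discovery_evidence(self):
        # larger planted effects never reduce average discovery evidence
        mean_logp = []
        for effect in (0.0, 0.4, 0.9):
            logs = []
            for seed in range(4):
                cfg = SimulationConfig(
                    n_amines=10, n_organic_acids=2, n_other=1, n_true_assoc=3,
                    effect_size_sd=effect, n_concordant_low_pairs=40,
                    n_concordant_high_pairs=40, n_discordant_pairs=10,
                    n_control_pairs=8, n_clinical=5, seed=50 + seed,
                )
                cohort, matrix, truth = simulate_dataset(cfg)
                dens = pd.Series(cohort["density"].to_numpy(),
                                 index=cohort["subject_id"].to_numpy())
                mask = pd.Series(
                    cohort["group"].isin(["concordant_low", "control"]).to_numpy(),
                    index=cohort["subject_id"].to_numpy())
                feats = run_preprocessing(matrix, dens, mask)["int"].values
                disc, _ = run_discovery(feats, feats.iloc[:, :0], cohort,
                                        CascadeConfig())
                planted = [f for f in truth["associated_features"]
                           if f in disc.index]
                logs.append(-np.log10(disc.loc[planted, "p"]).mean())
            mean_logp.append(np.mean(logs))
        assert mean_logp[0] <= mean_logp[1] + 0.2 <= mean_logp[2] + 0.4


class TestNullCascade:
    def test_null_validation_rarely_significant(self):
        hits = 0
        for seed in range(8):
            cfg = SimulationConfig(
                n_true_assoc=0, n_concordant_low_pairs=30,
                n_concordant_high_pairs=25, n_discordant_pairs=20,
                n_control_pairs=15, n_clinical=30, seed=300 + seed,
            )
            cohort, matrix, _ = simulate_dataset(cfg)
            report = run_cascade(cohort, matrix, CascadeConfig())
            sig = (report.validation_features["fdr_p"] <= 0.05).any()
            hits += bool(sig)
        assert hits <= 2


class TestPower:
    def test_planted_effects_reach_candidacy(self, default_dataset):
        reached = 0
        n_seeds = 4
        for seed in range(n_seeds):
            cfg = SimulationConfig(effect_size_sd=0.4, seed=700 + seed)
            cohort, matrix, truth = simulate_dataset(cfg)
            report = run_cascade(cohort, matrix, CascadeConfig())
            planted = set(truth["associated_features"])
            reached += bool(planted & set(report.candidate_features))
        assert reached >= 3
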