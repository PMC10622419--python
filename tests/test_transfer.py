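"""Centroid classifier: training, assignment, transfer to the NAC-style
cohort, response association and outcome models."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oracles import fisher_2x2_enumeration
from subtyper.consensus import SubtypeAssignment
from subtyper.io import CohortMatrix
from subtyper.synthetic import SynthConfig, generate_nac_cohort, generate_profile_cohort
from subtyper.transfer import (
    assign,
    assign_cohort,
    fit_classifier,
    nac_outcome_models,
    response_association,
)


@pytest.fixture
def trained(small_cohort):
    cohort, truth = small_cohort
    assignment = SubtypeAssignment(
        labels=truth.tumor_subtype.map(lambda v: f"T{v}"),
        compartment="tumor")
    clf = fit_classifier(cohort, assignment, panel_size=20)
    return cohort, assignment, clf


class TestFitClassifier:
    def test_resubstitution_agreement(self, trained):
        cohort, assignment, clf = trained
        relabeled = assign_cohort(clf, cohort)
        agree = (relabeled.labels == assignment.labels.loc[
            relabeled.labels.index]).mean()
        assert agree >= 0.95

    def test_identical_subtypes_rejected(self):
        X = np.tile(np.linspace(1, 2, 10), (12, 1))
        df = pd.DataFrame(X, index=[f"s{i}" for i in range(12)],
                          columns=[f"m{i}" for i in range(10)])
        cohort = CohortMatrix(data=df, compartment="tumor")
        labels = pd.Series(["T1"] * 6 + ["T2"] * 6, index=df.index)
        assignment = SubtypeAssignment(labels=labels, compartment="tumor")
        with pytest.raises(ValueError, match="coincide"):
            fit_classifier(cohort, assignment, panel_size=5)

    def test_deterministic_panel(self, trained):
        cohort, assignment, clf = trained
        clf2 = fit_classifier(cohort, assignment, panel_size=20)
        assert clf.panel == clf2.panel
        pd.testing.assert_frame_equal(clf.centroids, clf2.centroids)

    def test_panel_capped_with_warning(self, trained, caplog):
        cohort, assignment, _ = trained
        clf = fit_classifier(cohort, assignment, panel_size=10_000)
        assert len(clf.panel) == cohort.data.shape[1]

    def test_json_round_trip(self, trained, tmp_path):
        from subtyper.transfer import CentroidClassifier
        _, _, clf = trained
        p = clf.to_json(tmp_path / "clf.json")
        back = CentroidClassifier.from_json(p)
        assert back.panel == clf.panel
        pd.testing.assert_frame_equal(back.centroids, clf.centroids,
                                      check_exact=False)


class TestAssign:
    def test_centroid_itself_distance_zero(self, trained):
        _, _, clf = trained
        s = clf.subtypes[0]
        raw = (clf.centroids.loc[s] * clf.feature_sds + clf.feature_means)
        label, dists = assign(clf, raw)
        assert label == s
        assert dists[s] == pytest.approx(0.0, abs=1e-10)

    def test_tie_breaks_to_lower_index(self, trained):
        _, _, clf = trained
        a, b = clf.subtypes[0], clf.subtypes[1]
        mid_z = (clf.centroids.loc[a] + clf.centroids.loc[b]) / 2
        raw = mid_z * clf.feature_sds + clf.feature_means
        label, dists = assign(clf, raw)
        assert dists[a] == pytest.approx(dists[b])
        assert label == a

    def test_low_coverage_rejected(self, trained):
        _, _, clf = trained
        partial = pd.Series(1.0, index=clf.panel[: len(clf.panel) // 2])
        with pytest.raises(ValueError, match="covers"):
            assign(clf, partial)

    def test_missing_features_imputed(self, trained):
        _, _, clf = trained
        s = clf.subtypes[0]
        raw = clf.centroids.loc[s] * clf.feature_sds + clf.feature_means
        raw = raw.drop(clf.panel[-2:])  # 10% missing, above coverage floor
        label, _ = assign(clf, raw)
        assert label == s

    def test_affine_consistent_rescaling_invariance(self, trained):
        """Assignment only depends on the z-scored position: feeding raw
        features consistent with the stored z-parameters of a scaled space
        gives the same labels (no hidden re-standardization)."""
        cohort, _, clf = trained
        import copy
        clf2 = copy.deepcopy(clf)
        clf2.feature_means = clf.feature_means * 2 + 5
        clf2.feature_sds = clf.feature_sds * 2
        clf2.feature_medians = clf.feature_medians * 2 + 5
        for sid in cohort.data.index[:10]:
            orig, _ = assign(clf, cohort.data.loc[sid])
            scaled, _ = assign(clf2, cohort.data.loc[sid] * 2 + 5)
            assert orig == scaled

    def test_nac_recovery_at_low_noise(self, trained):
        _, _, clf = trained
        cfg = SynthConfig(n_patients=100, n_metabolites=40, noise_sd=0.5,
                          seed=41)
        nac, _, truth = generate_nac_cohort(cfg, clf, clf.subtypes[1])
        assigned = assign_cohort(clf, nac)
        correct = (assigned.labels ==
                   truth.tumor_subtype.map(lambda v: f"T{v}")).mean()
        assert correct >= 0.9


class TestNoLeakage:
    def test_nac_scoring_uses_training_parameters(self, trained):
        """Mutating the stored scaling changes NAC assignments: proof that
        assignment reads the training z-parameters, not cohort statistics."""
        _, _, clf = trained
        cfg = SynthConfig(n_patients=30, n_metabolites=40, noise_sd=0.5,
                          seed=43)
        nac, _, _ = generate_nac_cohort(cfg, clf, clf.subtypes[0])
        baseline = assign_cohort(clf, nac).labels
        import copy
        mutated = copy.deepcopy(clf)
        mutated.feature_means = clf.feature_means + 10 * clf.feature_sds
        shifted = assign_cohort(mutated, nac).labels
        assert not baseline.equals(shifted)


class TestResponseAssociation:
    def test_fisher_against_enumeration(self):
        labels = pd.Series(["S1"] * 12 + ["S2"] * 9,
                           index=[f"N{i}" for i in range(21)])
        assignment = SubtypeAssignment(labels=labels, compartment="stroma")
        response = pd.Series(["resistant"] * 11 + ["sensitive"]
                             + ["resistant"] * 4 + ["sensitive"] * 5,
                             index=labels.index)
        res = response_association(assignment, response)
        p = res["pairwise"]["p"].iloc[0]
        assert p == pytest.approx(
            fisher_2x2_enumeration([[11, 1], [4, 5]]), abs=1e-10)

    def test_balanced_table_p_one(self):
        labels = pd.Series(["S1"] * 10 + ["S2"] * 10,
                           index=[f"N{i}" for i in range(20)])
        assignment = SubtypeAssignment(labels=labels, compartment="stroma")
        response = pd.Series((["resistant"] * 5 + ["sensitive"] * 5) * 2,
                             index=labels.index)
        res = response_association(assignment, response)
        assert res["pairwise"]["p"].iloc[0] == 1.0

    def test_planted_enrichment_detected_majority_of_seeds(self, trained):
        """0.9-vs-0.3 resistance at n=40: a significant pairwise Fisher test
        against the resistant subtype in >= 3/5 seeds."""
        _, _, clf = trained
        resistant = clf.subtypes[1]
        hits = 0
        for seed in range(5):
            cfg = SynthConfig(n_patients=40, n_metabolites=40, noise_sd=0.5,
                              seed=100 + seed)
            nac, clinical, _ = generate_nac_cohort(
                cfg, clf, resistant, resistant_enrichment=0.9,
                baseline_resistance=0.3)
            assigned = assign_cohort(clf, nac)
            res = response_association(
                assigned, clinical.set_index("patient_id")["response"])
            pw = res["pairwise"]
            vs_resistant = pw[(pw.group1 == resistant) | (pw.group2 == resistant)]
            hits += (vs_resistant["p"] < 0.05).any()
        assert hits >= 3

    def test_null_fisher_p_superuniform(self):
        """Equal resistance across subtypes: the exact test's p-values are
        valid, i.e. P(p <= alpha) <= alpha (discrete exact tests are
        conservative, so uniformity holds only as an upper bound)."""
        rng = np.random.default_rng(1)
        ps = []
        for _ in range(200):
            sub = rng.integers(0, 2, size=40)
            resist = rng.random(40) < 0.3
            table = [[int(resist[sub == g].sum()),
                      int((~resist[sub == g]).sum())] for g in (0, 1)]
            ps.append(stats.fisher_exact(table)[1])
        ps = np.asarray(ps)
        for alpha in (0.01, 0.05, 0.1, 0.2):
            # 3-sigma Monte Carlo slack on the binomial proportion
            slack = 3 * np.sqrt(alpha * (1 - alpha) / 200)
            assert (ps <= alpha).mean() <= alpha + slack


class TestOutcomeModels:
    def test_protective_subtype_recovered(self, trained):
        _, _, clf = trained
        cfg = SynthConfig(n_patients=2000, n_metabolites=40, noise_sd=0.5,
                          censor_rate=0.2, seed=51)
        resistant = clf.subtypes[1]
        nac, clinical, _ = generate_nac_cohort(
            cfg, clf, resistant, resistant_enrichment=0.9,
            baseline_resistance=0.1, resistant_hr=3.0)
        assigned = assign_cohort(clf, nac)
        out = nac_outcome_models(assigned, clinical, reference=clf.subtypes[0])
        hr = out["cox"].hr(f"subtype_{resistant}")
        # the resistant-enriched subtype must carry an elevated hazard
        assert hr > 1.0
        assert out["cox"].table.loc[f"subtype_{resistant}", "ci_low"] > 1.0

    def test_missing_mpr_omitted_with_warning(self, trained, caplog):
        _, _, clf = trained
        cfg = SynthConfig(n_patients=120, n_metabolites=40, noise_sd=0.5,
                          seed=53)
        nac, clinical, _ = generate_nac_cohort(cfg, clf, clf.subtypes[0])
        clinical = clinical.drop(columns=["MPR"])
        assigned = assign_cohort(clf, nac)
        out = nac_outcome_models(assigned, clinical)
        assert "MPR" not in out["cox"].table.index
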