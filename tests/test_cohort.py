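import numpy as np
import pytest

from cvmstage import cohort as coh
from cvmstage.agreement import consensus_partition, weighted_kappa
from cvmstage.datamodel import LandmarkSet, Subject
from cvmstage.morphometry import chord_height, extract_features, point_distance


def perfect_raters():
    return [coh.RaterProfile(f"R{i}", p_exact=1.0, p_far=0.0)
            for i in (1, 2, 3)]


class TestRate:
    def test_perfect_rater_reproduces_truth(self, rng):
        prof = coh.RaterProfile("R", p_exact=1.0, p_far=0.0)
        assert all(coh.rate(s, prof, rng) == s for s in range(1, 7))

    def test_boundary_truncation_renormalizes(self, rng):
        # all error mass aimed below stage 1 flips to the valid side
        prof = coh.RaterProfile("R", p_exact=0.5, adjacent_bias=1.0, p_far=0.0)
        draws = coh.rate_many(np.ones(2000, dtype=int), prof, rng)
        assert set(draws) == {1, 2}

    def test_error_frequencies_match_profile(self, rng):
        # binomial SE oracle on 1e5 draws at an interior stage
        prof = coh.RaterProfile("R", p_exact=0.8, adjacent_bias=0.5, p_far=0.0)
        n = 100_000
        draws = coh.rate_many(np.full(n, 3), prof, rng)
        for stage, p in ((2, 0.1), (3, 0.8), (4, 0.1)):
            freq = (draws == stage).mean()
            se = np.sqrt(p * (1 - p) / n)
            assert abs(freq - p) < 3 * se

    def test_transition_rows_sum_to_one(self):
        prof = coh.RaterProfile("R", p_exact=0.6, adjacent_bias=0.3, p_far=0.1)
        np.testing.assert_allclose(prof.transition_matrix().sum(axis=1), 1.0)
        np.testing.assert_allclose(prof.repeat_matrix().sum(axis=1), 1.0)


class TestGenerateVertebra:
    def test_stage1_flat_border_at_zero_jitter(self, rng):
        morph = coh.default_morphology()[0]
        pts = coh.generate_vertebra(1, "C2", morph, jitter_sd=0.0, rng=rng)
        for p in pts[1:4]:
            assert chord_height(p + 500, pts[0] + 500, pts[4] + 500) < 1e-9

    def test_stage6_c4_vertically_rectangular(self):
        morph = coh.default_morphology()[5]
        rng = np.random.default_rng(42)
        pts = coh.generate_vertebra(6, "C4", morph, jitter_sd=0.0, rng=rng)
        width = point_distance(pts[0], pts[4])
        height = point_distance(pts[0], pts[5])
        assert width / height < 1.0

    def test_same_seed_identical(self):
        morph = coh.default_morphology()[3]
        a = coh.generate_vertebra(4, "C3", morph, 1.0, np.random.default_rng(9))
        b = coh.generate_vertebra(4, "C3", morph, 1.0, np.random.default_rng(9))
        np.testing.assert_array_equal(a, b)

    def test_morphology_row_must_match_stage(self, rng):
        with pytest.raises(ValueError, match="does not match"):
            coh.generate_vertebra(2, "C2", coh.default_morphology()[0], 0, rng)


class TestCohort:
    def test_default_counts_sum_to_study_size(self):
        spec = coh.CohortSpec(seed=0)
        assert spec.n == 1380
        cohort = coh.generate_cohort(spec, profiles=perfect_raters())
        assert len(cohort) == 1380

    def test_scaled_spec_keeps_composition(self):
        spec = coh.CohortSpec().scaled(0.3)
        assert spec.n == round(0.3 * 1380)

    def test_ages_within_range_and_sex_ratio(self):
        cohort = coh.generate_cohort(coh.CohortSpec(seed=3))
        ages = [s.age for s in cohort.subjects.values()]
        assert min(ages) >= 4.0 and max(ages) <= 21.0
        frac_f = np.mean([s.sex == "female" for s in cohort.subjects.values()])
        assert abs(frac_f - 1.12 / 2.12) < 0.05

    def test_seed_reproducibility(self):
        a = coh.generate_cohort(coh.CohortSpec(seed=5).scaled(0.1),
                                profiles=perfect_raters())
        b = coh.generate_cohort(coh.CohortSpec(seed=5).scaled(0.1),
                                profiles=perfect_raters())
        for sid in a.subject_ids:
            np.testing.assert_array_equal(a.landmark_sets[sid].to_array(),
                                          b.landmark_sets[sid].to_array())
            assert a.panels[sid].ratings == b.panels[sid].ratings

    def test_perfect_raters_give_complete_agreement(self):
        cohort = coh.generate_cohort(coh.CohortSpec(seed=1).scaled(0.1),
                                     profiles=perfect_raters())
        panels = [cohort.panels[s] for s in sorted(cohort.panels)]
        part = consensus_partition(panels)
        assert part.counts()["Complete"] == len(panels)
        # and consensus equals the generating stage
        assert all(part.consensus[s] == cohort.true_stage[s]
                   for s in cohort.true_stage)

    def test_empty_spec_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            coh.CohortSpec(stage_counts=(0, 0, 0, 0, 0, 0))

    def test_concavity_monotone_in_stage(self):
        # summed concavity height and AUC strictly increase with stage
        spec = coh.CohortSpec(stage_counts=(40,) * 6, jitter_sd=0.0, seed=11)
        cohort = coh.generate_cohort(spec)
        heights = {s: [] for s in range(1, 7)}
        aucs = {s: [] for s in range(1, 7)}
        for sid, stage in cohort.true_stage.items():
            f = extract_features(cohort.landmark_sets[sid],
                                 cohort.subjects[sid])
            heights[stage].append(f["C2_height_1_3_5"]
                                  + f["C3_height_6_8_10"]
                                  + f["C4_height_13_15_17"])
            aucs[stage].append(f["C2_AUC"] + f["C3_AUC"] + f["C4_AUC"])
        mh = [np.mean(heights[s]) for s in range(1, 7)]
        ma = [np.mean(aucs[s]) for s in range(1, 7)]
        assert all(a < b for a, b in zip(mh, mh[1:]))
        assert all(a < b for a, b in zip(ma, ma[1:]))

    def test_stage_signal_recoverable(self):
        # a plain classifier on the geometry recovers stage far above chance
        from sklearn.linear_model import LogisticRegression
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler
        from cvmstage.morphometry import extract_feature_table
        cohort = coh.generate_cohort(
            coh.CohortSpec(stage_counts=(60,) * 6, jitter_sd=0.5, seed=2))
        ids = cohort.subject_ids
        X = extract_feature_table([cohort.landmark_sets[s] for s in ids],
                                  [cohort.subjects[s] for s in ids])
        y = np.array([cohort.true_stage[s] for s in ids])
        perm = np.random.default_rng(0).permutation(len(ids))
        half = len(ids) // 2
        clf = make_pipeline(StandardScaler(), LogisticRegression(max_iter=2000))
        clf.fit(X.iloc[perm[:half]], y[perm[:half]])
        acc = clf.score(X.iloc[perm[half:]], y[perm[half:]])
        assert acc > 0.5  # chance is 1/6


class TestCalibration:
    def test_near_perfect_targets_give_near_perfect_raters(self):
        profiles, ach = coh.calibrate_profiles(
            (0.985, 1.0), (0.985, 1.0), n_sim=2000, rng=0,
            family="categorical")
        assert ach["inter_kappa_mean"] > 0.95
        assert all(p.p_exact > 0.95 for p in profiles)

    def test_perceptual_ceiling_reported_when_unattainable(self):
        # blunders and personal boundary shifts cap perceptual agreement
        with pytest.raises(ValueError, match="achievable range"):
            coh.calibrate_profiles((0.99, 1.0), (0.86, 0.92),
                                   n_sim=1000, rng=0)

    def test_negative_target_unattainable(self):
        with pytest.raises(ValueError, match="unattainable"):
            coh.calibrate_profiles((-1.0, -0.5), (0.86, 0.92),
                                   n_sim=500, rng=0)

    def test_categorical_family_hits_targets(self):
        profiles, ach = coh.calibrate_profiles(
            (0.62, 0.78), (0.86, 0.92), n_sim=2000, rng=4,
            family="categorical")
        assert 0.62 <= ach["inter_kappa_mean"] <= 0.78
        assert 0.86 <= ach["intra_kappa"] <= 0.92
        assert all(p.sigma is None for p in profiles)

    def test_repeat_session_correlation(self, rng):
        # perceptual repeats agree with the primary session far more than
        # an independent rater would
        profiles, _ = coh.calibrate_profiles((0.62, 0.78), (0.86, 0.92),
                                             n_sim=2000, rng=6)
        cohort = coh.generate_cohort(
            coh.CohortSpec(seed=8, n_repeat=300), profiles=profiles)
        rid = profiles[0].rater_id
        both = [p for p in cohort.panels.values()
                if rid in p.repeat_ratings]
        assert len(both) == 300
        a = [p.ratings[rid] for p in both]
        b = [p.repeat_ratings[rid] for p in both]
        intra = weighted_kappa(a, b)
        assert intra > 0.8
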