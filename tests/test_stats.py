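"""Welch machinery, random-model filtering, and group comparisons."""

import numpy as np
import pytest

import eigenalign as ea
from eigenalign.stats import DegenerateSampleError, _welch_grid

from conftest import welch_oracle


class TestWelchTTest:
    def test_identical_samples_give_t0_p1(self):
        r = ea.welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.t == 0.0
        assert r.p == pytest.approx(1.0)

    def test_matches_formula_oracle(self):
        r = ea.welch_t_test([1, 2, 3, 4], [2, 3, 4, 5, 6])
        t, df, p = welch_oracle([1, 2, 3, 4], [2, 3, 4, 5, 6])
        assert r.t == pytest.approx(t, abs=1e-10)
        assert r.df == pytest.approx(df, abs=1e-10)
        assert r.p == pytest.approx(p, abs=1e-10)

    def test_oracle_agreement_on_many_random_samples(self):
        rng = np.random.default_rng(1)
        for _ in range(300):
            a = rng.normal(rng.uniform(-1, 1), rng.uniform(0.5, 2), rng.integers(2, 30))
            b = rng.normal(rng.uniform(-1, 1), rng.uniform(0.5, 2), rng.integers(2, 30))
            r = ea.welch_t_test(a, b)
            t, df, p = welch_oracle(a, b)
            assert r.t == pytest.approx(t, abs=1e-10)
            assert r.df == pytest.approx(df, abs=1e-10)
            assert r.p == pytest.approx(p, abs=1e-10)

    def test_swap_negates_t_keeps_p(self):
        a, b = [1.0, 2.0, 4.0], [2.0, 5.0, 6.0, 7.0]
        r1, r2 = ea.welch_t_test(a, b), ea.welch_t_test(b, a)
        assert r1.t == pytest.approx(-r2.t)
        assert r1.p == pytest.approx(r2.p)
        assert np.sign(r1.t) == np.sign(r1.mean_diff)

    def test_degenerate_and_short_samples_rejected(self):
        with pytest.raises(DegenerateSampleError):
            ea.welch_t_test([1.0, 1.0], [2.0, 2.0])
        with pytest.raises(ValueError):
            ea.welch_t_test([1.0], [1.0, 2.0])

    def test_vectorized_grid_matches_scalar(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(6, 4, 4))
        b = rng.normal(size=(9, 4, 4))
        t, df, p = _welch_grid(a, b)
        for i in range(4):
            for j in range(4):
                r = ea.welch_t_test(a[:, i, j], b[:, i, j])
                assert t[i, j] == pytest.approx(r.t, abs=1e-10)
                assert df[i, j] == pytest.approx(r.df, abs=1e-10)
                assert p[i, j] == pytest.approx(r.p, abs=1e-10)


class TestRandomModelNull:
    def test_seeded_determinism(self):
        cfg = ea.PipelineConfig()
        a = ea.random_model_null(8, 5, n_sets=2, seed=4, config=cfg)
        b = ea.random_model_null(8, 5, n_sets=2, seed=4, config=cfg)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_sets_differ_and_angles_valid(self):
        sets = ea.random_model_null(8, 6, n_sets=3, seed=9)
        assert len(sets) == 3
        assert not np.array_equal(sets[0], sets[1])
        for s in sets:
            assert s.shape == (6, 8, 8)
            assert s.min() >= 0 and s.max() <= np.pi

    def test_generator_contract(self):
        m = ea.random_uniform_matrix(10, seed=3)
        iu = np.triu_indices(10, 1)
        vals = m.weights[iu]
        assert vals.min() > 0 and vals.max() < 1
        assert not np.diag(m.weights).any()


class TestEligiblePairs:
    def test_alpha_one_keeps_all_offdiagonal(self, study_results):
        s1 = ea.angle_stack(study_results[0])
        s2 = ea.angle_stack(study_results[1])
        nulls = ea.random_model_null(20, 5, n_sets=1, seed=0)
        mask = ea.eligible_pairs(s1, s2, nulls, alpha=1.0)
        assert mask.n_eligible_pairs == 20 * 19 // 2

    def test_alpha_zero_empty(self, study_results):
        s1 = ea.angle_stack(study_results[0])
        s2 = ea.angle_stack(study_results[1])
        nulls = ea.random_model_null(20, 5, n_sets=1, seed=0)
        assert ea.eligible_pairs(s1, s2, nulls, alpha=0.0).n_eligible_pairs == 0

    def test_intersection_shrinks_with_more_sets(self, study_results):
        s1 = ea.angle_stack(study_results[0])
        s2 = ea.angle_stack(study_results[1])
        nulls = ea.random_model_null(20, 30, n_sets=3, seed=1)
        m1 = ea.eligible_pairs(s1, s2, nulls[:1], alpha=0.05)
        m3 = ea.eligible_pairs(s1, s2, nulls, alpha=0.05)
        assert m3.n_eligible_pairs <= m1.n_eligible_pairs
        assert not m3.mask[np.eye(20, dtype=bool)].any()
        np.testing.assert_array_equal(m3.mask, m3.mask.T)

    def test_planted_tight_pair_survives_every_set(self):
        # a pair aligned at ~0 in every subject is un-null-like by design
        rng = np.random.default_rng(6)
        n, m = 10, 8
        stack = rng.uniform(0.5, np.pi / 2, size=(m, n, n))
        stack = (stack + stack.transpose(0, 2, 1)) / 2
        stack[:, 2, 7] = stack[:, 7, 2] = rng.uniform(0, 0.02, m)
        for s in range(m):
            np.fill_diagonal(stack[s], 0)
        nulls = ea.random_model_null(n, 50, n_sets=3, seed=2)
        mask = ea.eligible_pairs(stack, stack, nulls, alpha=0.05)
        assert mask.mask[2, 7]


class TestCompareAlignment:
    def test_identical_groups_never_significant(self, study_results):
        s = ea.angle_stack(study_results[0])
        res = ea.compare_alignment(s, s, alpha=0.05)
        assert not res.significant.any()

    def test_direction_vocabulary(self, study_results):
        s1 = ea.angle_stack(study_results[1])  # degraded first
        s2 = ea.angle_stack(study_results[0])
        res = ea.compare_alignment(s1, s2, alpha=0.05)
        i, j = 0, 10  # degraded homotopic pair: angle grew, alignment fell
        assert res.mean_a[i, j] > res.mean_b[i, j]
        assert res.direction_label(i, j) == "decrease"

    def test_roi_counts_sum_to_twice_pairs(self, study_results):
        s1 = ea.angle_stack(study_results[1])
        s2 = ea.angle_stack(study_results[0])
        res = ea.compare_alignment(s1, s2, alpha=0.05)
        n_sig_pairs = res.significant[np.triu_indices(20, 1)].sum()
        assert res.roi_change_counts().sum() == 2 * n_sig_pairs

    def test_significance_monotone_in_alpha(self, study_results):
        s1 = ea.angle_stack(study_results[1])
        s2 = ea.angle_stack(study_results[0])
        lo = ea.compare_alignment(s1, s2, alpha=0.01).significant
        hi = ea.compare_alignment(s1, s2, alpha=0.10).significant
        assert (~lo | hi).all()  # lo subset of hi

    def test_significant_subset_of_eligible(self, study_results):
        s1 = ea.angle_stack(study_results[1])
        s2 = ea.angle_stack(study_results[0])
        nulls = ea.random_model_null(20, 30, n_sets=3, seed=3)
        mask = ea.eligible_pairs(s1, s2, nulls, alpha=0.05)
        res = ea.compare_alignment(s1, s2, mask, alpha=0.05)
        assert (~res.significant | res.eligible).all()

    def test_empty_mask_gives_empty_result(self, study_results):
        s1 = ea.angle_stack(study_results[0])
        s2 = ea.angle_stack(study_results[1])
        nulls = ea.random_model_null(20, 5, n_sets=1, seed=0)
        mask = ea.eligible_pairs(s1, s2, nulls, alpha=0.0)
        res = ea.compare_alignment(s1, s2, mask, alpha=0.05)
        assert not res.significant.any()
        assert list(res.tested_pairs()) == []


class TestTypeICalibration:
    def test_same_generator_flag_rate_near_alpha(self):
        """Cohorts drawn from one generator are flagged at ~alpha."""
        cfg = ea.PipelineConfig()

        def spec(seed):
            return ea.CohortSpec(
                n_roi=10, n_subjects=10,
                homotopic_pairs=((0, 5), (1, 6)),
                community_blocks=((0, 5, 2, 3), (1, 6, 7, 8)),
                seed=seed,
            )

        iu = np.triu_indices(10, 1)
        rates = []
        for rep in range(200):
            g1 = ea.generate_cohort(spec(2 * rep))
            g2 = ea.generate_cohort(spec(2 * rep + 1))
            s1 = ea.angle_stack(ea.run_group(g1, cfg))
            s2 = ea.angle_stack(ea.run_group(g2, cfg))
            res = ea.compare_alignment(s1, s2, alpha=0.05)
            rates.append(res.significant[iu].mean())
        assert abs(np.mean(rates) - 0.05) <= 0.02


class TestCompareCentrality:
    def test_identical_groups_not_flagged(self, study_results):
        e = ea.ec_stack(study_results[0])
        assert not ea.compare_centrality(e, e).significant.any()

    def test_label_swap_flips_directions(self, study_results):
        e1, e2 = ea.ec_stack(study_results[0]), ea.ec_stack(study_results[1])
        a = ea.compare_centrality(e1, e2)
        b = ea.compare_centrality(e2, e1)
        np.testing.assert_array_equal(a.increased(), ~b.increased() | (a.mean_a == a.mean_b))

    def test_planted_hub_boost_detected(self):
        rng = np.random.default_rng(12)
        base = rng.uniform(0, 0.3, (12, 12))
        base = (base + base.T) / 2
        np.fill_diagonal(base, 0)

        def group(boost, seed):
            r = np.random.default_rng(seed)
            ms = []
            for s in range(10):
                w = base + r.normal(0, 0.03, base.shape)
                w = (w + w.T) / 2
                w[3, :] += boost
                w[:, 3] += boost
                np.fill_diagonal(w, 0)
                ms.append(ea.ConnectivityMatrix(f"s{s}", np.clip(w, 0, 1)))
            return ea.run_group(ea.SubjectGroup("g", tuple(ms)), ea.PipelineConfig())

        plain = ea.ec_stack(group(0.0, 1))
        boosted = ea.ec_stack(group(0.25, 2))
        res = ea.compare_centrality(boosted, plain, alpha=0.05)
        assert res.significant[3]
        assert res.direction_label(3) == "increase"


class TestCompareConnectivity:
    def test_identical_groups_zero_counts(self, study_cohorts):
        g = study_cohorts[0]
        res = ea.compare_connectivity(g, g)
        assert res.roi_change_counts().sum() == 0

    def test_planted_edge_shift_flagged(self, study_cohorts):
        healthy, degraded = study_cohorts
        res = ea.compare_connectivity(degraded, healthy, alpha=0.05)
        # the degraded coupling is the gross weight change
        from eigenalign.synthetic import STUDY_DEGRADED

        for i, j in STUDY_DEGRADED:
            assert res.significant[i, j]
            assert res.direction_label(i, j) == "decrease"
        sig_pairs = res.significant[np.triu_indices(20, 1)].sum()
        assert sig_pairs < 25  # weight tests stay local: no mass flagging

    def test_uses_pre_threshold_weights(self, study_cohorts):
        healthy, _ = study_cohorts
        res = ea.compare_connectivity(healthy, healthy)
        np.testing.assert_array_equal(res.mean_a, healthy.weight_stack().mean(axis=0))


class TestCompareCommunitySizes:
    def test_identical_groups_t_zero(self, study_results):
        out = ea.compare_community_sizes(study_results[0], study_results[0])
        assert set(out) == {
            "most_influential", "least_influential", "mean_two_most", "mean_two_least"
        }
        for r in out.values():
            assert r.t == 0.0

    def test_planted_dominant_community_difference(self):
        def group(block, seed):
            spec = ea.CohortSpec(
                n_roi=12,
                n_subjects=8,
                community_blocks=(block,),
                mu_in=0.7,
                mu_out=0.1,
                background_jitter=0.05,
                noise_sd=0.05,
                seed=seed,
            )
            return ea.run_group(ea.generate_cohort(spec), ea.PipelineConfig())

        big = group(tuple(range(8)), 1)
        small = group(tuple(range(4)), 2)
        out = ea.compare_community_sizes(big, small)
        assert out["most_influential"].p < 0.05


class TestSubstituteRoi:
    def test_identity_substitution(self, study_cohorts):
        g = study_cohorts[0]
        out = ea.substitute_roi(g, g, roi_id=5)
        for orig, sub in zip(g, out):
            np.testing.assert_array_equal(orig.weights, sub.weights)

    def test_row_and_column_replaced_rest_untouched(self, study_cohorts):
        healthy, degraded = study_cohorts
        roi_id = 1  # internal index 0
        out = ea.substitute_roi(healthy, degraded, roi_id=roi_id)
        idx = roi_id - 1
        keep = np.ones(20, dtype=bool)
        keep[idx] = False
        for host, donor, sub in zip(healthy, degraded, out):
            np.testing.assert_array_equal(sub.weights[idx, keep], donor.weights[idx, keep])
            np.testing.assert_array_equal(sub.weights[keep][:, keep],
                                          host.weights[keep][:, keep])
            np.testing.assert_array_equal(sub.weights, sub.weights.T)
            assert sub.weights[idx, idx] == 0

    def test_pairing_truncates_to_smaller_group(self, study_cohorts):
        healthy, degraded = study_cohorts
        short = ea.SubjectGroup("short", degraded.members[:4])
        out = ea.substitute_roi(healthy, short, roi_id=3)
        assert len(out) == 4

    def test_bad_roi_rejected(self, study_cohorts):
        with pytest.raises(ValueError):
            ea.substitute_roi(study_cohorts[0], study_cohorts[1], roi_id=99)

    def test_substitution_moves_target_alignments(self, study_cohorts, study_results):
        # transplant a scrambled version of one region's couplings: that
        # region's alignments must shift beyond the noise floor while the
        # rest of the network stays at it
        healthy, _ = study_cohorts
        idx = 5  # an unpaired block member
        rest = [j for j in range(20) if j != idx]
        rng = np.random.default_rng(42)
        perm = rng.permutation(rest)
        donors = []
        for m in healthy:
            w = m.weights.copy()
            row = np.zeros(20)
            row[rest] = w[idx, perm]  # same weights, scrambled partners
            w[idx, :] = row
            w[:, idx] = row
            w[idx, idx] = 0.0
            donors.append(ea.ConnectivityMatrix(m.subject_id + "-d", w))
        donor = ea.SubjectGroup("donor", tuple(donors))
        altered = ea.substitute_roi(healthy, donor, roi_id=idx + 1)
        cfg = ea.PipelineConfig()
        a_host = ea.angle_stack(study_results[0])
        a_alt = ea.angle_stack(ea.run_group(altered, cfg))
        shift = np.abs(a_alt.mean(axis=0) - a_host.mean(axis=0))
        # noise floor: the same statistic between two healthy reruns
        other_cohort = ea.generate_cohort(ea.synthetic.bilateral_study_spec(0.0, seed=33))
        a_other = ea.angle_stack(ea.run_group(other_cohort, cfg))
        noise = np.abs(a_other.mean(axis=0) - a_host.mean(axis=0))
        iu = np.triu_indices(20, 1)
        row_shift = shift[idx, rest].mean()
        distant_pairs = [(i, j) for i, j in zip(*iu) if idx not in (i, j)]
        distant_shift = np.mean([shift[i, j] for i, j in distant_pairs])
        assert row_shift > 2.0 * noise[iu].mean()
        assert distant_shift < 0.8 * row_shift  # effect centred on the target
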