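"""The synthetic family-structured cohort generator."""

import numpy as np
import pytest

from conncca.cohort import (
    CohortSpec,
    generate_cohort,
    generate_confound_base,
    generate_family_structure,
    generate_motion_table,
    generate_node_timeseries,
    generate_scores,
    generate_sm_matrix,
)
from conncca.netmats import group_average, partial_netmat_ridge
from conncca.qc import run_is_good


def tiny_spec(**kw):
    defaults = dict(
        n_mz_families=2, n_dz_families=1, n_sib_families=1, sibs_per_family=3,
        n_singles=2, n_nodes=10, n_timepoints=100, n_sms=6, seed=0,
    )
    defaults.update(kw)
    return CohortSpec(**defaults)


class TestSpecValidation:
    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            tiny_spec(n_singles=-1)

    def test_rho_ordering_enforced(self):
        with pytest.raises(ValueError, match="rho_mz >= rho_dz"):
            tiny_spec(rho_mz=0.3, rho_dz=0.5)

    def test_rho_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            tiny_spec(rho_mz=1.2)

    def test_asymmetric_edge_loadings_rejected(self):
        lam = np.zeros((10, 10))
        lam[0, 1] = 0.1  # not symmetrized
        with pytest.raises(ValueError, match="symmetric"):
            tiny_spec(edge_loadings=[lam])


class TestFamilyStructure:
    def test_singles_only(self):
        spec = CohortSpec(
            n_mz_families=0, n_dz_families=0, n_sib_families=0, n_singles=5,
            n_modes=0, n_sms=3, n_nodes=5,
        )
        fams = generate_family_structure(spec)
        assert len(fams) == 5
        assert (fams["member_type"] == "SINGLE").all()
        assert fams["family_id"].nunique() == 5

    def test_mixed_counts_arithmetic(self):
        # 2 MZ fams (4) + 1 DZ fam (2) + 1 sib fam x3 (3) + 2 singles = 11 in 6 families
        fams = generate_family_structure(tiny_spec())
        assert len(fams) == 2 * 2 + 1 * 2 + 3 + 2 == 11
        assert fams["family_id"].nunique() == 6
        assert fams["member_type"].value_counts().to_dict() == {
            "MZ": 4, "SIB": 3, "DZ": 2, "SINGLE": 2,
        }

    def test_all_four_member_types_emitted(self):
        fams = generate_family_structure(tiny_spec())
        assert set(fams["member_type"]) == {"MZ", "DZ", "SIB", "SINGLE"}

    def test_twins_come_in_same_family_pairs(self):
        fams = generate_family_structure(tiny_spec())
        for _, grp in fams[fams["member_type"].isin(["MZ", "DZ"])].groupby("family_id"):
            assert len(grp) == 2


class TestScores:
    def test_perfect_sharing_gives_identical_cotwins(self):
        spec = tiny_spec(rho_mz=1.0, rho_dz=0.5)
        fams = generate_family_structure(spec)
        truth = generate_scores(spec, fams, np.random.default_rng(0))
        mz = fams.index[fams["member_type"] == "MZ"]
        np.testing.assert_allclose(
            truth.subject_scores[mz[0]], truth.subject_scores[mz[1]]
        )

    def test_zero_rho_gives_independence(self):
        spec = CohortSpec(
            n_mz_families=500, n_dz_families=0, n_sib_families=0, n_singles=0,
            rho_mz=0.0, rho_dz=0.0, rho_sib=0.0, n_sms=3, n_nodes=5,
        )
        fams = generate_family_structure(spec)
        truth = generate_scores(spec, fams, np.random.default_rng(1))
        s = truth.subject_scores[:, 0].reshape(-1, 2)
        assert abs(np.corrcoef(s[:, 0], s[:, 1])[0, 1]) < 0.1

    def test_cotwin_correlation_hits_target(self):
        # Monte-Carlo check of the shared-component construction
        spec = CohortSpec(
            n_mz_families=1000, n_dz_families=0, n_sib_families=0, n_singles=0,
            rho_mz=0.8, rho_dz=0.5, n_sms=3, n_nodes=5,
        )
        fams = generate_family_structure(spec)
        truth = generate_scores(spec, fams, np.random.default_rng(2))
        s = truth.subject_scores[:, 0].reshape(-1, 2)
        assert np.corrcoef(s[:, 0], s[:, 1])[0, 1] == pytest.approx(0.8, abs=0.05)

    def test_marginals_standard_normal(self):
        spec = CohortSpec(n_singles=2000, n_mz_families=0, n_dz_families=0,
                          n_sib_families=0, n_sms=3, n_nodes=5)
        fams = generate_family_structure(spec)
        truth = generate_scores(spec, fams, np.random.default_rng(3))
        s = truth.subject_scores[:, 0]
        assert abs(s.mean()) < 0.08 and abs(s.std() - 1) < 0.06


class TestSMMatrix:
    def test_noiseless_sm_is_perfectly_correlated(self):
        spec = tiny_spec(sm_noise_sd=0.0, missing_rate=0.0,
                         confound_effects=np.zeros(5), add_pathological=False)
        fams = generate_family_structure(spec)
        rng = np.random.default_rng(0)
        truth = generate_scores(spec, fams, rng)
        base = generate_confound_base(spec, rng)
        sm, _ = generate_sm_matrix(truth, spec, base, rng)
        load = truth.true_sm_loadings[0]
        for j in np.flatnonzero(load):
            r = np.corrcoef(sm.iloc[:, j], truth.subject_scores[:, 0])[0, 1]
            assert abs(r) == pytest.approx(1.0, abs=1e-12)
            assert np.sign(r) == np.sign(load[j])

    def test_zero_missing_rate(self):
        spec = tiny_spec(missing_rate=0.0, add_pathological=False)
        cohort = generate_cohort(spec)
        assert not cohort.sm.isna().any().any()

    def test_attenuation_formula(self):
        # loading 1, noise sd 1 => corr = 1/sqrt(2)
        spec = CohortSpec(
            n_singles=2000, n_mz_families=0, n_dz_families=0, n_sib_families=0,
            n_sms=4, n_nodes=5, sm_noise_sd=1.0, missing_rate=0.0,
            sm_loadings=np.array([[1.0, 1.0, 0.0, 0.0]]),
            confound_effects=np.zeros(5), add_pathological=False,
        )
        fams = generate_family_structure(spec)
        rng = np.random.default_rng(5)
        truth = generate_scores(spec, fams, rng)
        base = generate_confound_base(spec, rng)
        sm, _ = generate_sm_matrix(truth, spec, base, rng)
        r = np.corrcoef(sm["sm000"], truth.subject_scores[:, 0])[0, 1]
        assert r == pytest.approx(1 / np.sqrt(2), abs=0.03)

    def test_pathological_columns_caught_by_filter(self):
        from conncca.sm_prep import quantitative_filter

        # the outlier rule max(Y) > 100 mean(Y) is bounded by the subject
        # count, so it needs a cohort of more than 100 subjects to fire
        spec = tiny_spec(n_singles=150, n_nodes=5, n_timepoints=30)
        ledger = quantitative_filter(generate_cohort(spec).sm)
        assert ledger.loc["path_constant", "status"] == "dropped_c2"
        assert ledger.loc["path_missing", "status"] == "dropped_c1"
        assert ledger.loc["path_identical", "status"] == "dropped_c2"
        assert ledger.loc["path_outlier", "status"] == "dropped_c3"


class TestNodeTimeseries:
    def test_output_shape(self, small_cohort):
        spec = small_cohort.spec
        assert small_cohort.timeseries.shape == (
            spec.n_subjects, spec.n_timepoints, spec.n_nodes,
        )

    def test_zero_scores_recover_base_partial_correlations(self):
        # group-mean partial netmat vs the closed-form partials of Omega_base
        from conncca.cohort import _base_precision
        from conncca.cohort import GroundTruth

        spec = CohortSpec(
            n_singles=200, n_mz_families=0, n_dz_families=0, n_sib_families=0,
            n_nodes=20, n_timepoints=750, n_sms=3, n_modes=1,
        )
        truth = GroundTruth(
            subject_scores=np.zeros((200, 1)),
            true_sm_loadings=np.zeros((1, 3)),
            true_edge_loadings=[np.zeros((20, 20))],
        )
        ts = generate_node_timeseries(truth, spec, np.random.default_rng(6))
        nms = [partial_netmat_ridge(ts[i], rho=1e-6) for i in range(200)]
        est = np.tanh(group_average(nms).z)
        p = _base_precision(20)
        dd = np.sqrt(np.diag(p))
        expected = -p / np.outer(dd, dd)
        np.fill_diagonal(expected, 0)
        assert np.max(np.abs(est - expected)) < 0.05

    def test_no_edge_signal_is_a_negative_control(self):
        # with Lambda = 0 the edges carry no score information
        spec = tiny_spec(n_singles=60, n_mz_families=0, n_dz_families=0,
                         n_sib_families=0, edge_loadings=[np.zeros((10, 10))],
                         n_timepoints=200)
        fams = generate_family_structure(spec)
        rng = np.random.default_rng(7)
        truth = generate_scores(spec, fams, rng)
        ts = generate_node_timeseries(truth, spec, rng)
        edges = np.array([partial_netmat_ridge(ts[i]).z[0, 1] for i in range(60)])
        r = np.corrcoef(edges, truth.subject_scores[:, 0])[0, 1]
        assert abs(r) < 0.35  # no systematic association

    def test_planted_edges_track_the_score(self, small_cohort):
        lam = small_cohort.truth.true_edge_loadings[0]
        i, j = np.argwhere(np.triu(lam) != 0)[0]
        edges = np.array(
            [
                partial_netmat_ridge(small_cohort.timeseries[s]).z[i, j]
                for s in range(small_cohort.spec.n_subjects)
            ]
        )
        r = np.corrcoef(edges, small_cohort.truth.subject_scores[:, 0])[0, 1]
        assert np.sign(r) == np.sign(lam[i, j])
        assert abs(r) > 0.5


class TestMotion:
    def test_quiet_baseline_passes_run_filter(self):
        spec = tiny_spec()
        fams = generate_family_structure(spec)
        runs, _ = generate_motion_table(
            spec, np.random.default_rng(0), fams,
            baseline_median=0.1, spike_prob=0.0,
        )
        assert all(run_is_good(r) for r in runs)

    def test_bad_runs_fail_the_filter(self):
        spec = tiny_spec()
        fams = generate_family_structure(spec)
        runs, _ = generate_motion_table(
            spec, np.random.default_rng(1), fams, bad_run_frac=1.0,
        )
        assert not any(run_is_good(r) for r in runs)

    def test_spike_exceedances_match_binomial_expectation(self):
        # near-constant low baseline; exceedance prob is spike_prob * P(mag > gap)
        spec = CohortSpec(n_singles=50, n_mz_families=0, n_dz_families=0,
                          n_sib_families=0, n_sms=3, n_nodes=5)
        fams = generate_family_structure(spec)
        runs, _ = generate_motion_table(
            spec, np.random.default_rng(2), fams,
            baseline_median=0.05, baseline_sigma=1e-6,
            spike_prob=0.05, spike_scale=0.5,
        )
        fd = np.concatenate([r.fd for r in runs])
        p_true = 0.05 * np.exp(-0.25 / 0.5)  # exponential tail beyond the gap
        n = fd.size
        se = np.sqrt(p_true * (1 - p_true) / n)
        assert np.mean(fd > 0.3) == pytest.approx(p_true, abs=2 * se)


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        spec = tiny_spec(seed=42)
        a = generate_cohort(spec, with_motion=True)
        b = generate_cohort(spec, with_motion=True)
        assert a.families.equals(b.families)
        assert a.sm.equals(b.sm)
        assert a.confound_base.equals(b.confound_base)
        np.testing.assert_array_equal(a.timeseries, b.timeseries)
        np.testing.assert_array_equal(
            a.truth.subject_scores, b.truth.subject_scores
        )
        for ra, rb in zip(a.motion_runs, b.motion_runs):
            np.testing.assert_array_equal(ra.fd, rb.fd)

    def test_different_seeds_differ(self):
        a = generate_cohort(tiny_spec(seed=1))
        b = generate_cohort(tiny_spec(seed=2))
        assert not np.array_equal(a.timeseries, b.timeseries)
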