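"""Copy-state model, purity, clustering and clone fractions."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from clonedeconv import clonal


class TestExpectedBaf:
    @pytest.mark.parametrize(
        "state,rho,f,expected",
        [
            ("AB", 1.0, 1.0, 0.5),
            ("B", 1.0, 1.0, 1.0),
            ("ABB", 1.0, 1.0, 2 / 3),
            ("BB", 1.0, 1.0, 1.0),
            ("AB", 0.5, 1.0, 0.25),  # rho*f*m / (rho*2 + 2(1-rho)) = 0.5/2
            ("AB", 0.5, 0.5, 0.125),
            ("B", 0.5, 1.0, 0.5 / 1.5),
        ],
    )
    def test_reference_points(self, state, rho, f, expected):
        assert clonal.expected_baf(state, rho, f) == pytest.approx(expected)

    @given(
        rho=st.floats(0.05, 1.0),
        f1=st.floats(0.0, 1.0),
        f2=st.floats(0.0, 1.0),
        state=st.sampled_from(["AB", "B", "BB", "ABB"]),
    )
    def test_monotone_in_fraction_and_bounded(self, rho, f1, f2, state):
        lo, hi = sorted([f1, f2])
        b_lo, b_hi = clonal.expected_baf(state, rho, lo), clonal.expected_baf(state, rho, hi)
        assert 0.0 <= b_lo <= b_hi <= 1.0

    @given(
        r1=st.floats(0.05, 1.0),
        r2=st.floats(0.05, 1.0),
        f=st.floats(0.0, 1.0),
        state=st.sampled_from(["AB", "B", "BB", "ABB"]),
    )
    def test_monotone_in_purity(self, r1, r2, f, state):
        lo, hi = sorted([r1, r2])
        assert clonal.expected_baf(state, lo, f) <= clonal.expected_baf(state, hi, f) + 1e-12

    def test_expected_logr_reference_points(self):
        assert clonal.expected_logr("AB", 1.0, 1.0) == pytest.approx(0.0)
        assert clonal.expected_logr("B", 1.0, 1.0) == pytest.approx(-1.0)
        assert clonal.expected_logr("ABB", 1.0, 1.0) == pytest.approx(np.log2(1.5))
        assert clonal.expected_logr("BB", 0.5, 1.0) == pytest.approx(0.0)


class TestEstimatePurity:
    def test_mode_at_quarter_gives_half(self):
        rng = np.random.default_rng(0)
        bafs = rng.normal(0.25, 0.01, size=50)
        est = clonal.estimate_purity(bafs, "b1")
        assert est.rho == pytest.approx(0.5, abs=0.02)
        assert est.source == "max_clonal_baf"

    def test_mode_at_half_caps_at_one(self):
        rng = np.random.default_rng(0)
        rho = clonal.estimate_purity(rng.normal(0.5, 0.01, size=50)).rho
        assert rho == pytest.approx(1.0, abs=0.02) and rho <= 1.0
        # noise-free peak above 0.5 hits the cap exactly
        assert clonal.estimate_purity(np.full(10, 0.52)).rho == 1.0

    def test_too_few_mutations_is_an_error(self):
        with pytest.raises(ValueError, match="provided"):
            clonal.estimate_purity([0.25, 0.26])


class TestAssignState:
    @pytest.mark.parametrize("rho", [0.3, 0.5, 1.0])
    @pytest.mark.parametrize("f", [0.5, 1.0])
    @pytest.mark.parametrize("state", ["AB", "B", "BB", "ABB"])
    def test_noise_free_points_recover_their_state(self, state, rho, f):
        baf = clonal.expected_baf(state, rho, f)
        logr = clonal.expected_logr(state, rho, f)
        label, f_hat, sub = clonal.assign_state(baf, logr, rho, candidate_fractions=[f])
        assert label == state
        assert f_hat == pytest.approx(f)
        assert sub == (f < 0.95)

    def test_subclonal_bb_degenerate_with_clonal_ab_resolves_simpler(self):
        # BB carried by half the cells sits exactly on AB carried by all of
        # them: (rho*f, 0) == (rho/2, 0); with both fractions on offer the
        # point is unidentifiable and the simpler AB interpretation wins
        rho = 0.5
        baf = clonal.expected_baf("BB", rho, 0.5)
        assert baf == pytest.approx(clonal.expected_baf("AB", rho, 1.0))
        label, f_hat, _ = clonal.assign_state(baf, 0.0, rho, candidate_fractions=[0.5, 1.0])
        assert label == "AB" and f_hat == 1.0

    def test_far_point_is_unassigned_not_forced(self):
        label, f_hat, _ = clonal.assign_state(0.95, 2.5, 0.3, candidate_fractions=[1.0])
        assert label == "unassigned" and np.isnan(f_hat)

    def test_tie_breaks_toward_simpler_state(self):
        # at rho=1, f=1 both B and BB predict (1.0, ...); B (one change) wins
        label, _, _ = clonal.assign_state(1.0, -1.0, 1.0, candidate_fractions=[1.0])
        assert label == "B"


class TestClusterMutations:
    def _draw(self, theta, n_per, depth, seed):
        rng = np.random.default_rng(seed)
        alts, deps, labels = [], [], []
        for k, th in enumerate(theta):
            d = rng.poisson(depth, size=(n_per, len(th)))
            a = rng.binomial(d, np.asarray(th)[None, :])
            alts.append(a)
            deps.append(d)
            labels += [k] * n_per
        return np.vstack(alts), np.vstack(deps), np.array(labels)

    def test_single_profile_yields_one_cluster(self):
        alt, dep, _ = self._draw([[0.25, 0.25]], 60, 1500, seed=0)
        assert clonal.cluster_mutations(alt, dep, k_max=5, seed=0).k == 1

    def test_two_separated_profiles_fully_recovered(self):
        alt, dep, truth = self._draw([[0.25, 0.25], [0.10, 0.10]], 50, 1500, seed=1)
        fit = clonal.cluster_mutations(alt, dep, k_max=5, seed=0)
        assert fit.k == 2
        # perfect assignment up to label permutation
        same = (fit.labels == truth).mean()
        assert max(same, 1 - same) == 1.0

    def test_fixed_seed_is_deterministic(self):
        alt, dep, _ = self._draw([[0.3, 0.1], [0.1, 0.3], [0.3, 0.3]], 30, 1693, seed=2)
        f1 = clonal.cluster_mutations(alt, dep, k_max=6, seed=0)
        f2 = clonal.cluster_mutations(alt, dep, k_max=6, seed=0)
        assert f1.k == f2.k
        assert np.array_equal(f1.labels, f2.labels)
        assert np.allclose(f1.theta, f2.theta)

    def test_alt_exceeding_depth_rejected(self):
        with pytest.raises(ValueError):
            clonal.cluster_mutations(np.array([[5]]), np.array([[3]]))


class TestCloneFractions:
    def test_ratio_half(self):
        mean_baf = np.array([[0.25, 0.25], [0.125, 0.10]])
        phi = clonal.clone_fractions(mean_baf, clonal_index=0)
        assert phi[1] == pytest.approx([0.5, 0.4])

    def test_absent_cluster_is_zero_and_self_is_one(self):
        mean_baf = np.array([[0.25, 0.2], [0.0, 0.0]])
        phi = clonal.clone_fractions(mean_baf, 0)
        assert phi[0] == pytest.approx([1.0, 1.0])
        assert phi[1] == pytest.approx([0.0, 0.0])

    def test_zero_clonal_baf_is_undefined(self):
        phi = clonal.clone_fractions(np.array([[0.25, 0.0], [0.1, 0.0]]), 0)
        assert np.isnan(phi[1, 1])

    def test_identify_clonal_cluster_requires_dominance_everywhere(self):
        mean_baf = np.array([[0.3, 0.05], [0.05, 0.3], [0.3, 0.3]])
        idx, unambiguous = clonal.identify_clonal_cluster(mean_baf)
        assert idx == 2 and unambiguous
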