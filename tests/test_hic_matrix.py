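"""Contact-map statistics: binning, separation scores, misassembly score."""

import math

import numpy as np
import pytest

from hicphase import hic_matrix as hm
from hicphase.assembly_model import AssemblyError

from conftest import random_symmetric, separation_oracle


class TestBuildMatrix:
    def test_direct_binning_example(self):
        contacts = [("s", 50_000, "s", 150_000), ("s", 50_000, "s", 250_000)]
        mat = hm.build_matrix([("s", 300_000)], contacts, 100_000)
        expected = np.zeros((3, 3))
        expected[0, 1] = expected[1, 0] = 1
        expected[0, 2] = expected[2, 0] = 1
        assert np.array_equal(mat.M, expected)

    def test_no_contacts_zero_matrix(self):
        mat = hm.build_matrix([("s", 250_000)], [], 100_000)
        assert mat.n_bins == 2 and not mat.M.any()

    def test_trailing_partial_bin_dropped(self):
        mat = hm.build_matrix([("s", 250_000)], [("s", 10_000, "s", 210_000)], 100_000)
        assert mat.n_bins == 2
        assert not mat.M.any()  # second end falls in the dropped bin

    def test_column_sums_match_independent_count(self):
        rng = np.random.default_rng(11)
        n = 10_000
        pa = rng.integers(0, 400_000, n)
        pb = rng.integers(0, 400_000, n)
        contacts = [("s", int(a), "s", int(b)) for a, b in zip(pa, pb)]
        mat = hm.build_matrix([("s", 400_000)], contacts, 100_000)
        # independent counting oracle: per-bin contact-end counts
        ends = np.concatenate([pa // 100_000, pb // 100_000])
        expected = np.bincount(ends, minlength=4).astype(float)
        col = mat.M.sum(axis=0) + np.diagonal(mat.M)  # self-bin ends count twice
        assert np.array_equal(col, expected)

    def test_symmetry_and_position_bounds(self):
        with pytest.raises(AssemblyError, match="beyond"):
            hm.build_matrix([("s", 100_000)], [("s", 100_000, "s", 0)], 50_000)
        rng = np.random.default_rng(1)
        contacts = [("s", int(a), "s", int(b))
                    for a, b in rng.integers(0, 90_000, (200, 2))]
        mat = hm.build_matrix([("s", 90_000)], contacts, 10_000)
        assert np.array_equal(mat.M, mat.M.T)
        assert (mat.M >= 0).all()


class TestSeparationScores:
    def test_uniform_matrix_gives_zero_s(self):
        M = np.full((8, 8), 10.0)
        sc = hm.separation_scores(hm.HiCMatrix(("s",), 1, M, junction_bin=4), k_max=3)
        assert sc.S_upper == 0 and sc.S_lower == 0

    def test_zero_outer_forces_s_equals_s0_and_r_one(self):
        # block-diagonal: all cross-junction pixels zero, inner pixels positive
        M = np.zeros((8, 8))
        M[:4, :4] = 7.0
        M[4:, 4:] = 7.0
        sc = hm.separation_scores(hm.HiCMatrix(("s",), 1, M, junction_bin=4), k_max=3)
        assert sc.S_upper == pytest.approx(sc.S_upper_0)
        assert sc.S_lower == pytest.approx(sc.S_lower_0)
        assert sc.R_upper == 1.0 and sc.R_lower == 1.0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 13))
        M = random_symmetric(rng, n)
        b = int(rng.integers(1, n))
        k_max = int(rng.integers(1, 5))
        sc = hm.separation_scores(hm.HiCMatrix(("s",), 1, M, junction_bin=b), k_max)
        su, sl, ru, rl, su0, sl0 = separation_oracle(M, b, k_max)
        assert sc.S_upper == pytest.approx(su, abs=1e-12)
        assert sc.S_lower == pytest.approx(sl, abs=1e-12)
        assert sc.R_upper == pytest.approx(ru, abs=1e-12)
        assert sc.R_lower == pytest.approx(rl, abs=1e-12)
        assert sc.S_upper_0 == pytest.approx(su0, abs=1e-12)
        assert sc.S_lower_0 == pytest.approx(sl0, abs=1e-12)

    def test_s_scales_quadratically_with_matrix(self):
        rng = np.random.default_rng(42)
        M = random_symmetric(rng, 10)
        mat = hm.HiCMatrix(("s",), 1, M, junction_bin=5)
        sc1 = hm.separation_scores(mat, 4)
        sc3 = hm.separation_scores(hm.HiCMatrix(("s",), 1, 3 * M, junction_bin=5), 4)
        assert sc3.S_upper == pytest.approx(9 * sc1.S_upper)
        assert sc3.S_lower == pytest.approx(9 * sc1.S_lower)

    def test_junction_requires_a_bin_each_side(self):
        M = np.zeros((4, 4))
        with pytest.raises(AssemblyError):
            hm.separation_scores(hm.HiCMatrix(("s",), 1, M, junction_bin=0), 2)
        with pytest.raises(AssemblyError):
            hm.separation_scores(hm.HiCMatrix(("s",), 1, M, junction_bin=None), 2)


class TestErroneousEdge:
    def _scores(self, s_up, s_lo, r_up, r_lo):
        return hm.SeparationScores(s_up, s_lo, r_up, r_lo, 1.0, 1.0)

    def test_both_conditions_hold(self):
        assert hm.is_erroneous_edge_hic(self._scores(0.6, 0.6, 0.9, 0.9))

    def test_r_condition_fails(self):
        assert not hm.is_erroneous_edge_hic(self._scores(0.6, 0.6, 0.8, 0.7))

    def test_s_condition_fails(self):
        assert not hm.is_erroneous_edge_hic(self._scores(0.4, 0.5, 0.9, 0.9))

    def test_zero_normalizer_counts_as_zero_ratio(self):
        sc = hm.SeparationScores(0.6, 0.6, 0.9, 0.9, 0.0, 1.0)
        assert sc.s_ratio_sum == pytest.approx(0.6)
        assert not hm.is_erroneous_edge_hic(sc)


class TestGlobalProfile:
    def test_constant_off_diagonal(self):
        M = np.full((12, 12), 3.0)
        mu = hm.global_distance_profile([hm.HiCMatrix(("s",), 1, M)], 5)
        assert np.allclose(mu[1:], 3.0)

    def test_pooled_pixels_not_mean_of_means(self):
        M1 = np.full((4, 4), 2.0)
        M2 = np.full((10, 10), 8.0)
        mu = hm.global_distance_profile(
            [hm.HiCMatrix(("a",), 1, M1), hm.HiCMatrix(("b",), 1, M2)], 2
        )
        # k=1: 3 pixels of 2 and 9 pixels of 8 pooled
        assert mu[1] == pytest.approx((3 * 2 + 9 * 8) / 12)
        assert mu[1] != pytest.approx((2 + 8) / 2)

    def test_simulated_decay_is_monotone(self):
        from conftest import desk_contact_maps

        intra, _, _ = desk_contact_maps(seed=3)
        mu = hm.global_distance_profile([intra], 10)
        assert all(mu[k] >= mu[k + 1] for k in range(1, 10))


class TestMisassemblyScore:
    def _decay_matrix(self, n, value=40.0):
        M = np.zeros((n, n))
        for k in range(1, 11):
            idx = np.arange(n - k)
            M[idx, idx + k] = value / k
            M[idx + k, idx] = value / k
        return M

    def test_zero_when_decay_matches_global(self):
        M = self._decay_matrix(40)
        mat = hm.HiCMatrix(("s",), 1, M)
        mu = hm.global_distance_profile([mat], 10)
        prof = hm.misassembly_score_profile(mat, mu, 10)
        # interior bins see exactly the global band means
        assert np.allclose(prof.scores[10:30], 0.0, atol=1e-9)

    def test_halved_band_means_closed_form(self):
        M = self._decay_matrix(60)
        mat = hm.HiCMatrix(("s",), 1, M)
        mu_all = 2 * hm.global_distance_profile([mat], 10)
        prof = hm.misassembly_score_profile(mat, mu_all, 10)
        expected = sum(mu_all[k] / 2 for k in range(1, 11))
        assert prof.scores[20] == pytest.approx(expected)

    def test_matrix_too_small(self):
        with pytest.raises(AssemblyError):
            hm.misassembly_score_profile(hm.HiCMatrix(("s",), 1, np.zeros((5, 5))),
                                         np.ones(11), 10)


class TestPeaks:
    def test_flat_profile_has_no_peaks(self):
        assert hm.detect_peaks(np.zeros(10), 2) == []
        assert hm.detect_peaks(np.full(10, 4.0), 2) == []

    def test_local_max_example(self):
        prof = np.array([0, 1, 5, 1, 0, 2, 7, 2, 0], dtype=float)
        assert hm.detect_peaks(prof, 1) == [2, 6]

    def test_plateau_keeps_leftmost_bin(self):
        prof = np.array([0, 1, 5, 5, 1, 0, 0], dtype=float)
        assert hm.detect_peaks(prof, 1) == [2]

    def test_incomplete_window_excluded(self):
        prof = np.array([9, 1, 0, 0, 0, 1, 9], dtype=float)
        assert hm.detect_peaks(prof, 2) == []

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_windowed_max_oracle(self, seed):
        rng = np.random.default_rng(seed)
        prof = rng.integers(0, 6, 40).astype(float)
        w = 2
        oracle = [
            b
            for b in range(w, len(prof) - w)
            if prof[b] > 0
            and all(prof[b] > prof[b - d] for d in range(1, w + 1))
            and all(prof[b] >= prof[b + d] for d in range(1, w + 1))
        ]
        assert hm.detect_peaks(prof, w) == oracle


class TestThresholdP:
    def test_no_peaks_returns_infinite_p(self):
        M = np.zeros((15, 15))
        mat = hm.HiCMatrix(("s",), 1, M)
        prof = hm.misassembly_score_profile(mat, np.zeros(11), 10)
        P, cands = hm.select_threshold_P(prof, mat, 10)
        assert math.isinf(P) and cands == []

    def test_two_junction_chimera_flags_both(self):
        # three intact blocks joined at bins 15 and 30: both cuts maximise S
        n = 45
        M = np.zeros((n, n))
        for k in range(1, 11):
            for i in range(n - k):
                if (i // 15) == ((i + k) // 15):
                    M[i, i + k] = M[i + k, i] = 50.0 / k
        mat = hm.HiCMatrix(("s",), 1, M)
        mu_all = np.array([0.0] + [50.0 / k for k in range(1, 11)])
        prof = hm.misassembly_score_profile(mat, mu_all, 10)
        P, cands = hm.select_threshold_P(prof, mat, 10)
        near = {b for b in cands for j in (15, 30) if abs(b - j) <= 1}
        assert len(near) == 2
        # exhaustive P-sweep oracle over the same peak set
        peaks = prof.peaks
        scores_at = {
            b: (lambda sc: sc.S_upper + sc.S_lower)(
                hm.separation_scores(hm.HiCMatrix(("s",), 1, M, junction_bin=b), 10)
            )
            for b in peaks
        }
        best, bp = -1.0, math.inf
        for trial in sorted({0.0} | {float(prof.scores[b]) for b in peaks}):
            cuts = [b for b in peaks if prof.scores[b] > trial]
            if not cuts:
                continue
            m = float(np.mean([scores_at[b] for b in cuts]))
            if m > best or (m == best and trial > bp):
                best, bp = m, trial
        assert P == pytest.approx(bp)
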