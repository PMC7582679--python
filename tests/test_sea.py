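"""Similarity-ensemble scoring: Tanimoto, raw scores, background, E-values."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from targetfish.sea import (
    EULER_GAMMA,
    BackgroundFitError,
    TargetLigandSet,
    e_value,
    fit_background,
    gumbel_tail,
    predict_targets,
    raw_score,
    sample_background_z,
    tanimoto,
    tanimoto_matrix,
    z_score,
)


def _bv(bits, n=128):
    v = np.zeros(n, dtype=np.uint8)
    v[list(bits)] = 1
    return v


class TestTanimoto:
    def test_identical_nonempty_is_one(self):
        assert tanimoto(_bv([1, 5, 9]), _bv([1, 5, 9])) == 1.0

    def test_disjoint_nonempty_is_zero(self):
        assert tanimoto(_bv([1, 2]), _bv([3, 4])) == 0.0

    def test_hand_counted_intersection_over_union(self):
        assert tanimoto(_bv([1, 2, 3]), _bv([2, 3, 4])) == pytest.approx(2 / 4)

    def test_both_empty_defined_as_zero(self):
        assert tanimoto(_bv([]), _bv([])) == 0.0

    def test_length_mismatch_fatal(self):
        with pytest.raises(ValueError):
            tanimoto(_bv([1], n=64), _bv([1], n=128))

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        a=st.sets(st.integers(0, 63), max_size=30),
        b=st.sets(st.integers(0, 63), max_size=30),
    )
    def test_matches_set_arithmetic_and_is_symmetric(self, a, b):
        va, vb = _bv(a, 64), _bv(b, 64)
        expected = len(a & b) / len(a | b) if a | b else 0.0
        assert tanimoto(va, vb) == pytest.approx(expected)
        assert tanimoto(va, vb) == tanimoto(vb, va)


class TestRawScore:
    # crafted vectors with exact pairwise Tanimotos {0.8, 0.3, 0.6, 0.1}
    Q1 = _bv(range(10))  # {0..9}
    Q2 = _bv([0, 1, 2, 3, 4, 5, 20, 21])
    L1 = _bv(range(8))  # subset of Q1
    L2 = _bv([0, 6, 7])

    def _target(self):
        return TargetLigandSet("T", np.stack([self.L1, self.L2]))

    def test_crafted_pairwise_values(self):
        tc = tanimoto_matrix(np.stack([self.Q1, self.Q2]), np.stack([self.L1, self.L2]))
        assert tc[0, 0] == pytest.approx(0.8)
        assert tc[0, 1] == pytest.approx(0.3)
        assert tc[1, 0] == pytest.approx(0.6)
        assert tc[1, 1] == pytest.approx(0.1)

    def test_threshold_truncation_sums_only_qualifying_pairs(self):
        raw, max_tc = raw_score(np.stack([self.Q1, self.Q2]), self._target(), threshold=0.57)
        assert raw == pytest.approx(0.8 + 0.6)
        assert max_tc == pytest.approx(0.8)

    def test_zero_threshold_sums_all_pairs(self):
        raw, _ = raw_score(np.stack([self.Q1, self.Q2]), self._target(), threshold=0.0)
        assert raw == pytest.approx(0.8 + 0.3 + 0.6 + 0.1)

    def test_threshold_one_without_identical_pair_gives_zero(self):
        raw, max_tc = raw_score(np.stack([self.Q1, self.Q2]), self._target(), threshold=1.0)
        assert raw == 0.0
        assert max_tc < 1.0

    def test_symmetry_between_query_and_target_roles(self, decoy_pool_fps):
        rng = np.random.default_rng(5)
        idx = rng.choice(len(decoy_pool_fps), size=7, replace=False)
        A, B = decoy_pool_fps[idx[:3]], decoy_pool_fps[idx[3:]]
        ra, _ = raw_score(A, TargetLigandSet("b", B), threshold=0.3)
        rb, _ = raw_score(B, TargetLigandSet("a", A), threshold=0.3)
        assert ra == pytest.approx(rb)

    def test_brute_force_oracle_on_random_small_sets(self, decoy_pool_fps):
        rng = np.random.default_rng(17)
        for _ in range(50):
            n, m = rng.integers(1, 6), rng.integers(1, 6)
            idx = rng.choice(len(decoy_pool_fps), size=n + m, replace=False)
            q, t = decoy_pool_fps[idx[:n]], decoy_pool_fps[idx[n:]]
            thr = float(rng.uniform(0, 1))
            raw, max_tc = raw_score(q, TargetLigandSet("t", t), threshold=thr)
            # independent double loop
            pairs = [tanimoto(qi, tj) for qi in q for tj in t]
            assert raw == pytest.approx(sum(v for v in pairs if v >= thr))
            assert max_tc == pytest.approx(max(pairs))

    def test_empty_query_fatal(self):
        with pytest.raises(ValueError):
            raw_score(np.zeros((0, 128), dtype=np.uint8), self._target())


class TestBackground:
    SIZES = [(1, 2), (2, 2), (2, 4), (4, 4), (4, 8)]

    def test_same_seed_reproduces_identical_coefficients(self, decoy_pool_fps):
        a = fit_background(decoy_pool_fps, self.SIZES, threshold=0.4, n_samples=60, seed=3)
        b = fit_background(decoy_pool_fps, self.SIZES, threshold=0.4, n_samples=60, seed=3)
        assert a.mean_coeffs == b.mean_coeffs
        assert a.sd_coeffs == b.sd_coeffs

    def test_degenerate_all_zero_scores_fatal(self, decoy_pool_fps):
        # threshold 1.0 and distinct decoys: no pair can ever score
        with pytest.raises(BackgroundFitError):
            fit_background(decoy_pool_fps, self.SIZES, threshold=1.0, n_samples=60, seed=3)

    def test_mean_function_matches_monte_carlo_oracle(self, decoy_pool_fps):
        sizes = [(2, 2), (2, 4), (4, 4), (4, 8), (8, 8), (8, 12), (10, 10)]
        bg = fit_background(decoy_pool_fps, sizes, threshold=0.4, n_samples=150, seed=9)
        # fresh (10,10) draws as the independent oracle for product 100
        from targetfish.sea import _sample_raw_scores

        rng = np.random.default_rng(1234)
        raws = _sample_raw_scores(rng, decoy_pool_fps, 10, 10, 0.4, 600)
        se = raws.std(ddof=1) / np.sqrt(len(raws))
        assert abs(bg.mean(100) - raws.mean()) < 3 * max(se, 1e-9) + 0.05 * raws.mean()

    def test_sd_prediction_positive_over_fitted_range(self, decoy_pool_fps):
        bg = fit_background(decoy_pool_fps, self.SIZES, threshold=0.4, n_samples=60, seed=3)
        lo, hi = bg.fitted_product_range
        assert all(bg.sd(x) > 0 for x in np.linspace(lo, hi, 100))

    def test_json_round_trip(self, decoy_pool_fps, tmp_path):
        bg = fit_background(decoy_pool_fps, self.SIZES, threshold=0.4, n_samples=60, seed=3)
        bg.to_json(tmp_path / "bg.json")
        from targetfish.sea import BackgroundModel

        back = BackgroundModel.from_json(tmp_path / "bg.json")
        assert back == bg


class TestZAndEValues:
    def _bg(self, decoy_pool_fps):
        return fit_background(
            decoy_pool_fps, [(1, 2), (2, 2), (2, 4), (4, 4)], threshold=0.4, n_samples=60, seed=3
        )

    def test_raw_equal_to_mean_gives_zero(self, decoy_pool_fps):
        bg = self._bg(decoy_pool_fps)
        assert z_score(bg.mean(8), 2, 4, bg) == pytest.approx(0.0)

    def test_raw_one_sd_above_mean_gives_one(self, decoy_pool_fps):
        bg = self._bg(decoy_pool_fps)
        assert z_score(bg.mean(8) + bg.sd(8), 2, 4, bg) == pytest.approx(1.0)

    def test_calibration_of_fresh_random_ensembles(self, decoy_pool_fps):
        sizes = [(1, 2), (2, 2), (2, 4), (4, 4), (4, 8)]
        bg = fit_background(decoy_pool_fps, sizes, threshold=0.4, n_samples=150, seed=3)
        zs = sample_background_z(decoy_pool_fps, sizes, bg, n_draws=500, seed=99)
        assert abs(zs.mean()) < 0.15
        assert 0.8 < zs.std(ddof=1) < 1.2

    def test_e_value_closed_form_at_zero(self):
        expected = 10 * (1 - np.exp(-np.exp(-EULER_GAMMA)))
        assert e_value(0.0, 10) == pytest.approx(expected, abs=1e-12)
        assert e_value(0.0, 10) == pytest.approx(4.296, abs=5e-4)

    def test_tail_limits(self):
        assert e_value(60.0, 10) == pytest.approx(0.0, abs=1e-12)
        assert e_value(-60.0, 10) == pytest.approx(10.0)

    def test_monotone_non_increasing_in_z(self):
        zs = np.linspace(-8, 8, 161)
        es = [e_value(z, 25) for z in zs]
        assert all(a >= b for a, b in zip(es, es[1:]))

    def test_gumbel_tail_probability_bounds(self):
        for z in (-5, -1, 0, 1, 5):
            assert 0.0 <= gumbel_tail(z) <= 1.0


class TestPredictTargets:
    def _refs_and_bg(self, decoy_pool_fps):
        rng = np.random.default_rng(21)
        refs = []
        for i in range(6):
            idx = rng.choice(len(decoy_pool_fps), size=4, replace=False)
            refs.append(TargetLigandSet(f"T{i}", decoy_pool_fps[idx]))
        bg = fit_background(
            decoy_pool_fps, [(1, 2), (2, 2), (2, 4), (4, 4), (4, 8)], threshold=0.4, n_samples=60, seed=3
        )
        return refs, bg

    def test_self_identical_reference_ranks_first(self, decoy_pool_fps):
        refs, bg = self._refs_and_bg(decoy_pool_fps)
        query = refs[2].ligand_fps
        scores = predict_targets(query, refs, bg)
        assert scores[0].target_id == "T2"
        assert scores[0].e_value == min(s.e_value for s in scores)

    def test_zero_cutoff_flags_nothing(self, decoy_pool_fps):
        refs, bg = self._refs_and_bg(decoy_pool_fps)
        scores = predict_targets(refs[0].ligand_fps, refs, bg, e_cutoff=0.0)
        assert not any(s.predicted for s in scores)

    def test_e_value_ordering_reverses_z_ordering(self, decoy_pool_fps):
        refs, bg = self._refs_and_bg(decoy_pool_fps)
        scores = predict_targets(refs[1].ligand_fps, refs, bg)
        zs = [s.z_score for s in scores]
        assert zs == sorted(zs, reverse=True)

    def test_raw_zero_implies_max_tc_below_threshold(self, decoy_pool_fps):
        refs, bg = self._refs_and_bg(decoy_pool_fps)
        for s in predict_targets(refs[0].ligand_fps, refs, bg):
            if s.raw_score == 0.0:
                assert s.max_tc < bg.tanimoto_threshold

    def test_fingerprint_length_mismatch_fatal(self, decoy_pool_fps):
        refs, bg = self._refs_and_bg(decoy_pool_fps)
        with pytest.raises(ValueError):
            predict_targets(np.zeros((1, 64), dtype=np.uint8), refs, bg)
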