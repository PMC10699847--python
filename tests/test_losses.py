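"""Loss components: torsion recursion, FAPE, cross-entropies, aggregation."""

import numpy as np
import pytest
from helpers import random_rigid
from hypothesis import given, settings
from hypothesis import strategies as st

from foldeval import (FapeConfig, LossWeights, RigidFrame, TorsionSet,
                      ValidationError, angle_loss, angle_unit_vector,
                      apply_rigid, backbone_frames, bin_confidence, chi_error,
                      chi_error_table, combined_loss, fape, fape_weight,
                      make_peptide, perturb_rigid, pre_torsion_errors,
                      sc_confidence_loss, secondary_structure_loss,
                      side_chain_confidence, weighted_fape)
from foldeval.losses import DSSP8_ALPHABET


def torsion_set(chis_deg, masks, symmetric=None):
    chi = np.deg2rad(np.asarray(chis_deg, dtype=float))
    mask = np.asarray(masks, dtype=bool)
    sym = np.zeros_like(mask) if symmetric is None else np.asarray(symmetric, bool)
    return TorsionSet(chi, mask, sym)


class TestChiError:
    def test_unit_vector(self):
        assert np.allclose(angle_unit_vector(0.0), [1, 0])
        assert np.allclose(angle_unit_vector(np.pi / 2), [0, 1], atol=1e-12)

    @pytest.mark.parametrize("delta,expected", [
        (0.0, 0.0), (np.pi, 2.0), (np.pi / 2, np.sqrt(2))])
    def test_known_chords(self, delta, expected):
        e = chi_error(angle_unit_vector(0.0), angle_unit_vector(delta))
        assert e == pytest.approx(expected, abs=1e-12)

    @settings(derandomize=True, max_examples=200)
    @given(a=st.floats(-np.pi, np.pi), b=st.floats(-np.pi, np.pi))
    def test_equals_chord_length(self, a, b):
        e = chi_error(angle_unit_vector(a), angle_unit_vector(b))
        assert e == pytest.approx(2 * abs(np.sin((a - b) / 2)), abs=1e-9)
        assert 0.0 <= e <= 2.0 + 1e-12


class TestPreTorsionErrors:
    all_on = np.ones(4, dtype=bool)

    def test_zero_fixed_point(self):
        assert np.allclose(pre_torsion_errors(np.zeros(4), self.all_on), 0.0)

    def test_maximal_error_absorbs(self):
        out = pre_torsion_errors(np.array([2.0, 0, 0, 0]), self.all_on)
        assert np.allclose(out, 2.0)

    def test_upstream_error_propagates_to_correct_chi2(self):
        # chi2 predicted perfectly, chi1 wrong by E=0.5: the conditioned
        # chi2 error inherits the upstream 0.5
        mask = np.array([True, True, False, False])
        out = pre_torsion_errors(np.array([0.5, 0.0, 0.0, 0.0]), mask)
        assert out[1] == pytest.approx(0.5)
        assert np.allclose(out[2:], 0.0)

    def test_non_prefix_mask_rejected(self):
        with pytest.raises(ValidationError):
            pre_torsion_errors(np.zeros(4), np.array([True, False, True, False]))

    def test_out_of_range_errors_rejected(self):
        with pytest.raises(ValidationError):
            pre_torsion_errors(np.array([2.5, 0, 0, 0]), self.all_on)

    @settings(derandomize=True, max_examples=300)
    @given(e=st.lists(st.floats(0, 2), min_size=4, max_size=4),
           bump=st.floats(0, 0.5), k=st.integers(0, 3))
    def test_bounded_monotone_dominating(self, e, bump, k):
        e = np.array(e)
        out = pre_torsion_errors(e, self.all_on)
        assert np.all(out >= -1e-12) and np.all(out <= 2 + 1e-12)
        # dominates the raw error and the previous conditioned error
        assert np.all(out >= e - 1e-12)
        assert np.all(np.diff(out) >= -1e-12)
        # monotone in every input
        e2 = e.copy()
        e2[k] = min(2.0, e2[k] + bump)
        out2 = pre_torsion_errors(e2, self.all_on)
        assert np.all(out2 >= out - 1e-12)


class TestAngleLoss:
    def test_identical_torsions_zero(self, mixed_torsions):
        assert angle_loss(mixed_torsions, mixed_torsions) == 0.0

    def test_single_arginine_all_pi_off(self):
        t_true = torsion_set([[10, 40, -60, 170]], [[1, 1, 1, 1]])
        chi_pred = np.rad2deg(np.deg2rad([[10, 40, -60, 170]]) + np.pi)
        t_pred = torsion_set(np.vectorize(lambda x: ((x + 180) % 360) - 180)(chi_pred),
                             [[1, 1, 1, 1]])
        assert angle_loss(t_true, t_pred) == pytest.approx(8.0, abs=1e-9)

    def test_masked_sums_divide_by_total_residues(self):
        # GLY (no chi) + SER with chi1 off by 90 deg, N = 2
        t_true = torsion_set([[0, 0, 0, 0], [30, 0, 0, 0]],
                             [[0, 0, 0, 0], [1, 0, 0, 0]])
        t_pred = torsion_set([[0, 0, 0, 0], [120, 0, 0, 0]],
                             [[0, 0, 0, 0], [1, 0, 0, 0]])
        assert angle_loss(t_true, t_pred) == pytest.approx(np.sqrt(2) / 2)

    def test_mask_mismatch_rejected(self):
        a = torsion_set([[0, 0, 0, 0]], [[1, 0, 0, 0]])
        b = torsion_set([[0, 0, 0, 0]], [[1, 1, 0, 0]])
        with pytest.raises(ValidationError):
            angle_loss(a, b)

    def test_symmetry_correction_halves_aspartate_flip(self):
        # ASP chi2 off by exactly pi: raw error 2, symmetry-corrected 0
        sym = [[False, True, False, False]]
        t_true = torsion_set([[10, 20, 0, 0]], [[1, 1, 0, 0]], sym)
        t_pred = torsion_set([[10, -160, 0, 0]], [[1, 1, 0, 0]], sym)
        raw = angle_loss(t_true, t_pred, symmetry_correct=False)
        corrected = angle_loss(t_true, t_pred, symmetry_correct=True)
        assert raw == pytest.approx(2.0)
        assert corrected == pytest.approx(0.0, abs=1e-9)

    def test_error_table_chi1_unconditioned(self, mixed_torsions, rng):
        pred = TorsionSet(
            np.where(mixed_torsions.mask,
                     np.arctan2(np.sin(mixed_torsions.chi + 0.3),
                                np.cos(mixed_torsions.chi + 0.3)), 0.0),
            mixed_torsions.mask, mixed_torsions.symmetric)
        e, e_tilde, mask = chi_error_table(mixed_torsions, pred)
        has_chi1 = mask[:, 0]
        assert np.allclose(e_tilde[has_chi1, 0], e[has_chi1, 0])
        assert np.all(e_tilde[mask] >= e[mask] - 1e-12)


class TestFape:
    def test_perfect_prediction_zero(self, mixed_peptide, mixed_frames):
        pts = mixed_peptide.coordinates(("N", "CA", "C"))
        mat, scalar = fape(mixed_frames, pts, mixed_frames, pts)
        assert scalar == 0.0 and np.all(mat == 0.0)

    def test_clamp_saturates_large_errors(self):
        frames = [RigidFrame.identity()]
        mat, scalar = fape(frames, [[100.0, 0, 0]], frames, [[0.0, 0, 0]])
        assert mat[0, 0] == 10.0 and scalar == 10.0

    def test_global_rigid_invariance(self, mixed_peptide, mixed_frames, rng):
        pts = mixed_peptide.coordinates(("N", "CA", "C"))
        pert = perturb_rigid(mixed_peptide, 1.5, seed=8)
        frames_p = backbone_frames(pert)
        pts_p = pert.coordinates(("N", "CA", "C"))
        _, ref = fape(frames_p, pts_p, mixed_frames, pts)
        for _ in range(20):
            g = RigidFrame(*random_rigid(rng))
            moved_frames = [g.compose(f) for f in frames_p]
            moved_pts = apply_rigid(g, pts_p)
            _, got = fape(moved_frames, moved_pts, mixed_frames, pts)
            assert abs(got - ref) < 1e-9

    def test_count_mismatch_rejected(self, mixed_frames, mixed_peptide):
        pts = mixed_peptide.coordinates(("N", "CA", "C"))
        with pytest.raises(ValidationError):
            fape(mixed_frames, pts, mixed_frames[:-1], pts)


class TestFapeWeight:
    def test_inflection_value(self):
        assert fape_weight(12.0) == pytest.approx(2.0, abs=1e-12)

    def test_asymptotes(self):
        cfg = FapeConfig()
        assert fape_weight(1e4, cfg) == pytest.approx(cfg.h, abs=1e-12)
        assert fape_weight(0.0, cfg) == pytest.approx(
            1.0 / (1.0 + np.exp(-24.0)) + 1.5, abs=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(d=st.floats(0, 100), step=st.floats(1e-6, 10))
    def test_nonincreasing_and_bounded(self, d, step):
        cfg = FapeConfig()
        w1, w2 = fape_weight(d, cfg), fape_weight(d + step, cfg)
        assert w1 >= w2
        # mathematically (h, 1+h) open; the lower bound saturates in float
        assert cfg.h <= w1 <= 1.0 + cfg.h

    @settings(derandomize=True, max_examples=100)
    @given(d=st.floats(5, 19), step=st.floats(0.5, 10))
    def test_strictly_decreasing_away_from_saturation(self, d, step):
        # in the float-resolvable range around the inflection the decrease
        # is strict, not just weak
        assert fape_weight(d) > fape_weight(d + step)


class TestWeightedFape:
    def test_perfect_prediction_zero(self, mixed_peptide, mixed_frames):
        n = len(mixed_peptide)
        pts = mixed_peptide.coordinates(("CA",))
        d = np.full((n, n), 12.0)
        np.fill_diagonal(d, 0.0)
        assert weighted_fape(mixed_frames, pts, mixed_frames, pts, d) == 0.0

    def test_saturated_errors_at_inflection_weight(self):
        # two residues far apart in truth vs prediction: all per-pair
        # errors clamp at 10; all weights at d = v equal 2.0 -> 20 per pair
        frames = [RigidFrame.identity(), RigidFrame(np.eye(3), [3.8, 0, 0])]
        pts_true = np.array([[0.0, 0, 0], [3.8, 0, 0]])
        pts_pred = pts_true + np.array([500.0, 0, 0])
        d = np.full((2, 2), 12.0)  # including the diagonal, deliberately
        val = weighted_fape(frames, pts_pred, frames, pts_true, d)
        assert val == pytest.approx(20.0, abs=1e-9)

    def test_unit_weights_reduce_to_fape(self, mixed_peptide, mixed_frames):
        n = len(mixed_peptide)
        pert = perturb_rigid(mixed_peptide, 1.0, seed=2)
        frames_p = backbone_frames(pert)
        pts_p = pert.coordinates(("CA",))
        pts = mixed_peptide.coordinates(("CA",))
        cfg = FapeConfig(h=0.5)
        d = np.full((n, n), cfg.v)
        np.fill_diagonal(d, 0.0)
        wf = weighted_fape(frames_p, pts_p, mixed_frames, pts, d, cfg=cfg)
        mat, plain = fape(frames_p, pts_p, mixed_frames, pts, cfg)
        # off-diagonal weights are exactly 1; diagonal (d=0) weights ~1.5
        expected = np.mean(np.where(np.eye(n, dtype=bool),
                                    fape_weight(0.0, cfg) * mat, mat))
        assert wf == pytest.approx(expected, abs=1e-12)

    def test_weight_sum_normalization_option(self, mixed_peptide, mixed_frames):
        n = len(mixed_peptide)
        pert = perturb_rigid(mixed_peptide, 1.0, seed=2)
        frames_p = backbone_frames(pert)
        pts_p = pert.coordinates(("CA",))
        pts = mixed_peptide.coordinates(("CA",))
        d = np.abs(np.subtract.outer(np.arange(n), np.arange(n))) * 3.8
        cfg = FapeConfig(normalize_by_weight_sum=True)
        mat, _ = fape(frames_p, pts_p, mixed_frames, pts, cfg)
        w = fape_weight(d.astype(float), cfg)
        expected = np.sum(w * mat) / np.sum(w)
        got = weighted_fape(frames_p, pts_p, mixed_frames, pts,
                            d.astype(float), cfg=cfg)
        assert got == pytest.approx(expected, abs=1e-12)


class TestSecondaryStructureLoss:
    def test_one_hot_match_is_tiny(self):
        labels = "HHEE"
        probs = np.zeros((4, 8))
        for i, c in enumerate(labels):
            probs[i, DSSP8_ALPHABET.index(c)] = 1.0
        assert secondary_structure_loss(labels, probs) <= 1e-7

    def test_uniform_prediction_is_ln8(self):
        probs = np.full((5, 8), 1 / 8)
        assert secondary_structure_loss("HGIEB", probs) == pytest.approx(
            np.log(8), abs=1e-9)

    def test_mean_over_rows(self):
        probs = np.vstack([np.eye(8)[0], np.full(8, 1 / 8)])
        assert secondary_structure_loss("H-", probs) == pytest.approx(
            np.log(8) / 2, abs=1e-9)

    def test_invalid_label_rejected(self):
        with pytest.raises(ValidationError, match="label"):
            secondary_structure_loss("HX", np.full((2, 8), 1 / 8))

    def test_off_simplex_rejected(self):
        with pytest.raises(ValidationError):
            secondary_structure_loss("HH", np.full((2, 8), 0.2))


class TestSideChainConfidence:
    delta0 = np.deg2rad(12.0)

    @pytest.mark.parametrize("mult,expected", [(0, 1.0), (1, 0.5), (2, 0.2)])
    def test_reference_points(self, mult, expected):
        s = side_chain_confidence(mult * self.delta0, self.delta0)
        assert s == pytest.approx(expected, abs=1e-12)

    def test_even_and_decreasing(self):
        deltas = np.deg2rad(np.array([1.0, 5.0, 20.0, 90.0, 179.0]))
        s_pos = side_chain_confidence(deltas, self.delta0)
        s_neg = side_chain_confidence(-deltas, self.delta0)
        assert np.allclose(s_pos, s_neg)
        assert np.all(np.diff(s_pos) < 0)

    def test_wraps_circularly(self):
        # 350 deg difference is really -10 deg
        a = side_chain_confidence(np.deg2rad(350.0), self.delta0)
        b = side_chain_confidence(np.deg2rad(-10.0), self.delta0)
        assert a == pytest.approx(b, abs=1e-12)

    def test_bad_delta0_rejected(self):
        with pytest.raises(ValidationError):
            side_chain_confidence(0.1, 0.0)


class TestBinConfidence:
    @pytest.mark.parametrize("s,expected_bin", [(0.0, 0), (1.0, 49), (0.5, 25)])
    def test_bin_indices(self, s, expected_bin):
        idx, one_hot = bin_confidence(s)
        assert idx == expected_bin
        assert one_hot.shape == (50,) and one_hot[idx] == 1.0
        assert one_hot.sum() == 1.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bin_confidence(1.2)


class TestScConfidenceLoss:
    def test_one_hot_match_is_tiny(self, rng):
        s = rng.uniform(size=6)
        probs = np.zeros((6, 50))
        for i, x in enumerate(s):
            probs[i, bin_confidence(x)[0]] = 1.0
        assert sc_confidence_loss(s, probs) <= 1e-7

    def test_uniform_prediction_is_ln50(self, rng):
        s = rng.uniform(size=6)
        probs = np.full((6, 50), 1 / 50)
        assert sc_confidence_loss(s, probs) == pytest.approx(np.log(50), abs=1e-9)

    def test_glycine_only_input_rejected(self):
        probs = np.full((3, 50), 1 / 50)
        with pytest.raises(ValidationError, match="chi1"):
            sc_confidence_loss(np.ones(3), probs, mask=np.zeros(3, dtype=bool))

    def test_mask_restricts_the_mean(self):
        s = np.array([0.1, 0.9])
        probs = np.full((2, 50), 1 / 50)
        probs[1] = 0.0
        probs[1, bin_confidence(0.9)[0]] = 1.0
        mask = np.array([False, True])
        assert sc_confidence_loss(s, probs, mask=mask) <= 1e-7


class TestCombinedLoss:
    def test_all_zero(self):
        assert combined_loss(0, 0, 0, 0) == 0.0

    def test_default_other_weights_sum(self):
        w = LossWeights(c1=0, c2=0, c3=0, c4=0)
        assert combined_loss(1, 1, 1, 1, l_others=np.ones(6), weights=w) == \
            pytest.approx(3.82)

    def test_single_term_reduction(self):
        w = LossWeights(c1=1, c2=0, c3=0, c4=0, c_others=(0,) * 6)
        assert combined_loss(8.0, 5.0, 5.0, 5.0, weights=w) == 8.0

    def test_linear_in_each_component(self):
        w = LossWeights(c1=0.5, c2=0.3, c3=2.0, c4=0.01)
        base = combined_loss(1, 1, 1, 1, weights=w)
        bumped = combined_loss(3, 1, 1, 1, weights=w)
        assert bumped - base == pytest.approx(2 * 0.5)

    def test_negative_component_rejected(self):
        with pytest.raises(ValidationError):
            combined_loss(-1.0, 0, 0, 0)
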