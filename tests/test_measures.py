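import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from restmvpa import (Bold4D, DcParams, MaskVolume, alff_falff_map,
                      build_feature_matrix, degree_centrality_map, kcc,
                      read_bold4d, reho_map, seed_fc_map)
from restmvpa.measures import MeasureMap

from oracles import degree_centrality_brute, kendall_w

AFFINE = np.diag([3.0, 3.0, 3.0, 1.0])


class TestKcc:
    def test_identical_monotone_series_give_one(self):
        base = np.array([1.0, 3.0, 4.0, 7.0, 9.0, 12.0])
        block = np.tile(base, (5, 1))
        assert kcc(block) == pytest.approx(1.0)

    def test_two_reversed_orderings_give_zero(self):
        up = np.arange(10.0)
        assert kcc(np.stack([up, up[::-1]])) == pytest.approx(0.0)

    def test_matches_rank_definition_oracle(self, rng):
        for _ in range(200):
            K = rng.integers(2, 8)
            T = rng.integers(3, 15)
            block = rng.standard_normal((K, T))
            if rng.random() < 0.3:  # exercise mid-rank ties
                block = np.round(block)
            assert kcc(block) == pytest.approx(kendall_w(block), abs=1e-12)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            kcc(np.zeros((1, 10)))
        with pytest.raises(ValueError):
            kcc(np.zeros((3, 1)))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(arrays(np.float64, (4, 12),
                  elements=st.floats(-50, 50, allow_nan=False)))
    def test_bounded_in_unit_interval(self, block):
        assert 0.0 <= kcc(block) <= 1.0 + 1e-12

    def test_invariant_to_monotone_transform(self, rng):
        block = rng.standard_normal((5, 12))
        assert kcc(np.exp(block)) == pytest.approx(kcc(block), abs=1e-12)


class TestReho:
    def test_common_series_gives_one_everywhere(self, rng, small_mask):
        series = rng.standard_normal(30)
        data = np.broadcast_to(series, (8, 8, 8, 30)).copy()
        bold = Bold4D(data=data, affine=AFFINE, tr_s=3.0)
        out = reho_map(bold, small_mask)
        assert np.allclose(out.data[small_mask.data], 1.0)

    def test_interior_voxel_matches_direct_kcc(self, rng, small_mask):
        bold = Bold4D(data=rng.standard_normal((8, 8, 8, 20)),
                      affine=AFFINE, tr_s=3.0)
        out = reho_map(bold, small_mask, neighborhood=27)
        block = bold.data[3:6, 4:7, 2:5].reshape(27, 20)
        assert out.data[4, 5, 3] == pytest.approx(kcc(block), abs=1e-10)

    @pytest.mark.parametrize("nb,expected_k", [(7, 7), (19, 19), (27, 27)])
    def test_neighborhood_sizes(self, rng, small_mask, nb, expected_k):
        bold = Bold4D(data=rng.standard_normal((8, 8, 8, 15)),
                      affine=AFFINE, tr_s=3.0)
        out = reho_map(bold, small_mask, neighborhood=nb)
        offsets = np.abs(np.indices((3, 3, 3)) - 1).sum(axis=0)
        sel = offsets <= {7: 1, 19: 2, 27: 3}[nb]
        block = bold.data[3:6, 3:6, 3:6][sel]
        assert block.shape[0] == expected_k
        assert out.data[4, 4, 4] == pytest.approx(kcc(block), abs=1e-10)

    def test_invalid_neighborhood(self, random_bold, small_mask):
        with pytest.raises(ValueError):
            reho_map(random_bold, small_mask, neighborhood=9)

    def test_planted_coherent_sphere_raises_reho(self, effect_cohort):
        import json
        truth = json.loads(
            (effect_cohort["dir"] / "ground_truth.json").read_text())
        vox = truth["effect0_coherence"]
        manifest = effect_cohort["manifest"]
        bold = read_bold4d(manifest[manifest.label == 1].iloc[0]["path"])
        mask = MaskVolume(data=np.ones((16, 16, 16), bool), affine=AFFINE)
        out = reho_map(bold, mask)
        inside = out.data.ravel()[vox].mean()
        outside_idx = np.setdiff1d(np.arange(16**3), vox)
        assert inside > out.data.ravel()[outside_idx].mean()

    def test_strict_mode_zeroes_incomplete_edges(self, random_bold, small_mask):
        out = reho_map(random_bold, small_mask, strict=True)
        assert out.data[0, 0, 0] == 0.0
        assert out.data[4, 4, 4] > 0.0


class TestAlffFalff:
    def _bold(self, series):
        data = np.zeros((4, 4, 4, len(series)))
        data[:] = series
        return Bold4D(data=data, affine=AFFINE, tr_s=3.0)

    def test_pure_inband_sinusoid_has_falff_one(self):
        t = np.arange(128) * 3.0
        f = 16 / (128 * 3.0)  # exactly on an FFT bin, inside 0.01-0.08 Hz
        x = np.sin(2 * np.pi * f * t)
        mask = MaskVolume(data=np.ones((4, 4, 4), bool), affine=AFFINE)
        alff, falff = alff_falff_map(self._bold(x), mask)
        assert falff.data[0, 0, 0] == pytest.approx(1.0, abs=1e-6)
        assert alff.data[0, 0, 0] > 0

    def test_zero_series_flagged_as_zero(self):
        mask = MaskVolume(data=np.ones((4, 4, 4), bool), affine=AFFINE)
        alff, falff = alff_falff_map(self._bold(np.zeros(64)), mask)
        assert alff.data[0, 0, 0] == 0.0
        assert falff.data[0, 0, 0] == 0.0

    def test_white_noise_falff_matches_bin_fraction(self, rng):
        T = 1024
        mask = MaskVolume(data=np.ones((4, 4, 4), bool), affine=AFFINE)
        data = rng.standard_normal((4, 4, 4, T))
        bold = Bold4D(data=data, affine=AFFINE, tr_s=3.0)
        _, falff = alff_falff_map(bold, mask)
        freqs = np.fft.rfftfreq(T, d=3.0)
        n_band = int(((freqs >= 0.01) & (freqs <= 0.08)).sum())
        n_full = int((freqs > 0).sum())
        expected = n_band / n_full
        assert falff.data[mask.data].mean() == pytest.approx(expected, rel=0.05)

    def test_full_band_cap_override(self, rng):
        mask = MaskVolume(data=np.ones((4, 4, 4), bool), affine=AFFINE)
        bold = Bold4D(data=rng.standard_normal((4, 4, 4, 120)),
                      affine=AFFINE, tr_s=3.0)
        _, f_nyq = alff_falff_map(bold, mask)
        _, f_cap = alff_falff_map(bold, mask, full_band_hz=(0.0, 0.1))
        assert np.all(f_cap.data[mask.data] >= f_nyq.data[mask.data] - 1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_falff_bounded_and_scale_invariant(self, seed):
        g = np.random.default_rng(seed)
        mask = MaskVolume(data=np.ones((2, 2, 2), bool), affine=AFFINE)
        data = g.standard_normal((2, 2, 2, 64))
        bold = Bold4D(data=data, affine=AFFINE, tr_s=3.0)
        _, falff = alff_falff_map(bold, mask)
        vals = falff.data[mask.data]
        assert np.all((vals >= 0) & (vals <= 1 + 1e-12))
        bold2 = Bold4D(data=7.5 * data, affine=AFFINE, tr_s=3.0)
        _, falff2 = alff_falff_map(bold2, mask)
        np.testing.assert_allclose(falff2.data, falff.data, atol=1e-10)


class TestDegreeCentrality:
    def test_zscored_map_has_zero_mean_unit_sd(self, random_bold, small_mask):
        out = degree_centrality_map(random_bold, small_mask)
        vals = out.data[small_mask.data]
        assert abs(vals.mean()) < 1e-9
        assert vals.std() == pytest.approx(1.0, abs=1e-9)

    def test_three_voxel_hand_case(self):
        # v1 = v2 (r=1), v3 = -v1: pre-z degrees (1, 1, 0) at threshold 0.25
        base = np.array([1.0, -2.0, 0.5, 3.0, -1.0, 2.0])
        data = np.zeros((3, 1, 1, 6))
        data[0, 0, 0] = base
        data[1, 0, 0] = base
        data[2, 0, 0] = -base
        bold = Bold4D(data=data, affine=AFFINE, tr_s=3.0)
        mask = MaskVolume(data=np.ones((3, 1, 1), bool), affine=AFFINE)
        out = degree_centrality_map(bold, mask)
        raw = np.array([1.0, 1.0, 0.0])
        expected = (raw - raw.mean()) / raw.std()
        np.testing.assert_allclose(out.data[:, 0, 0], expected, atol=1e-9)

    def test_matches_brute_force_on_small_mask(self, rng):
        shape = (4, 4, 3)
        data = rng.standard_normal((*shape, 30))
        bold = Bold4D(data=data, affine=AFFINE, tr_s=3.0)
        mask = MaskVolume(data=np.ones(shape, bool), affine=AFFINE)
        out = degree_centrality_map(bold, mask, block_size=7)
        series = data.reshape(-1, 30)
        brute = degree_centrality_brute(series, 0.25)
        expected = (brute - brute.mean()) / brute.std()
        np.testing.assert_allclose(out.data[mask.data], expected, atol=1e-8)

    def test_keep_all_threshold_equals_row_sums(self, rng):
        shape = (3, 3, 3)
        data = rng.standard_normal((*shape, 25))
        bold = Bold4D(data=data, affine=AFFINE, tr_s=3.0)
        mask = MaskVolume(data=np.ones(shape, bool), affine=AFFINE)
        out = degree_centrality_map(
            bold, mask, DcParams(r_threshold=-0.999999))
        corr = np.corrcoef(data.reshape(-1, 25))
        expected_raw = corr.sum(axis=1) - 1.0
        expected = (expected_raw - expected_raw.mean()) / expected_raw.std()
        np.testing.assert_allclose(out.data[mask.data], expected, atol=1e-7)

    def test_too_few_voxels(self, rng):
        data = rng.standard_normal((2, 1, 1, 20))
        bold = Bold4D(data=data, affine=AFFINE, tr_s=3.0)
        mask = MaskVolume(data=np.ones((2, 1, 1), bool), affine=AFFINE)
        with pytest.raises(ValueError):
            degree_centrality_map(bold, mask)


class TestSeedFc:
    def test_known_correlations_map_through_atanh(self, rng, small_mask):
        data = rng.standard_normal((8, 8, 8, 200))
        seed = np.zeros((8, 8, 8), bool)
        seed[0, 0, 0] = True
        bold = Bold4D(data=data, affine=AFFINE, tr_s=3.0)
        out = seed_fc_map(bold, small_mask, MaskVolume(seed, AFFINE))
        s = data[0, 0, 0]
        v = data[5, 5, 5]
        r = np.corrcoef(s, v)[0, 1]
        assert out.data[5, 5, 5] == pytest.approx(np.arctanh(r), abs=1e-10)

    def test_atanh_of_half(self):
        assert np.arctanh(0.5) == pytest.approx(0.5493, abs=1e-4)

    def test_seed_voxel_itself_is_clipped_finite(self, rng, small_mask):
        data = rng.standard_normal((8, 8, 8, 50))
        seed = np.zeros((8, 8, 8), bool)
        seed[2, 2, 2] = True
        bold = Bold4D(data=data, affine=AFFINE, tr_s=3.0)
        out = seed_fc_map(bold, small_mask, MaskVolume(seed, AFFINE))
        expected = np.arctanh(1 - 1e-7)
        assert out.data[2, 2, 2] == pytest.approx(expected)
        assert np.all(np.isfinite(out.data))

    def test_z_strictly_increasing_in_r(self):
        r = np.linspace(-0.99, 0.99, 50)
        z = np.arctanh(r)
        assert np.all(np.diff(z) > 0)

    def test_invariant_to_positive_scaling(self, rng, small_mask):
        data = rng.standard_normal((8, 8, 8, 40))
        seed = np.zeros((8, 8, 8), bool)
        seed[1, 1, 1] = True
        b1 = Bold4D(data=data, affine=AFFINE, tr_s=3.0)
        b2 = Bold4D(data=3.7 * data, affine=AFFINE, tr_s=3.0)
        m = MaskVolume(seed, AFFINE)
        np.testing.assert_allclose(
            seed_fc_map(b1, small_mask, m).data,
            seed_fc_map(b2, small_mask, m).data, atol=1e-9)

    def test_seed_outside_mask_rejected(self, rng):
        brain = np.zeros((8, 8, 8), bool)
        brain[:4] = True
        seed = np.zeros((8, 8, 8), bool)
        seed[6, 6, 6] = True
        data = rng.standard_normal((8, 8, 8, 30))
        bold = Bold4D(data=data, affine=AFFINE, tr_s=3.0)
        with pytest.raises(ValueError, match="outside"):
            seed_fc_map(bold, MaskVolume(brain, AFFINE),
                        MaskVolume(seed, AFFINE))


class TestFeatureMatrix:
    def _maps(self, rng, n_subj, measures, shape=(4, 4, 4)):
        out = []
        for i in range(n_subj):
            out.append({
                m: MeasureMap(data=rng.standard_normal(shape),
                              measure_name=m, subject_id=f"s{i}")
                for m in measures
            })
        return out

    def test_counting_and_provenance(self, rng):
        maps = self._maps(rng, 2, ["ReHo", "ALFF"])
        sel = np.zeros((4, 4, 4), bool)
        sel.ravel()[[3, 10, 20, 40, 60]] = True
        mask = MaskVolume(data=sel, affine=AFFINE)
        fm = build_feature_matrix(maps, mask, labels=[0, 1])
        assert fm.values.shape == (2, 10)
        assert fm.columns[0] == ("ReHo", 3)
        assert {c[0] for c in fm.columns} == {"ReHo", "ALFF"}
        # canonical order: ReHo block before ALFF block
        assert [c[0] for c in fm.columns[:5]] == ["ReHo"] * 5

    def test_single_measure_equals_masked_flatten(self, rng):
        maps = self._maps(rng, 3, ["ReHo"])
        mask = MaskVolume(data=np.ones((4, 4, 4), bool), affine=AFFINE)
        fm = build_feature_matrix(maps, mask, labels=[0, 0, 1])
        for i in range(3):
            np.testing.assert_array_equal(fm.values[i],
                                          maps[i]["ReHo"].data.ravel())

    def test_shuffling_subjects_permutes_rows_only(self, rng):
        maps = self._maps(rng, 4, ["ReHo", "DC"])
        mask = MaskVolume(data=np.ones((4, 4, 4), bool), affine=AFFINE)
        fm = build_feature_matrix(maps, mask, labels=[0, 0, 1, 1])
        perm = [2, 0, 3, 1]
        fm2 = build_feature_matrix([maps[i] for i in perm], mask,
                                   labels=[1, 0, 1, 0])
        assert fm.columns == fm2.columns
        np.testing.assert_array_equal(fm2.values, fm.values[perm])

    def test_missing_measure_errors(self, rng):
        maps = self._maps(rng, 2, ["ReHo", "ALFF"])
        del maps[1]["ALFF"]
        mask = MaskVolume(data=np.ones((4, 4, 4), bool), affine=AFFINE)
        with pytest.raises(ValueError, match="missing"):
            build_feature_matrix(maps, mask, labels=[0, 1])
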