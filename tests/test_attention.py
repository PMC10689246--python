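"""Context templates against a brute-force oracle; AS and permutation
contracts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from speechenc import attention, synthetic
from speechenc.datatypes import Segmentation, TEMPLATE_CONTEXTS


def brute_force_templates(seg: Segmentation) -> dict[str, np.ndarray]:
    """Literal per-entry evaluation of the six indicator definitions."""
    T = seg.n_frames

    def seg_of(bounds, i):
        ks = [k for k, b in enumerate(bounds) if b <= i]
        return ks[-1] if ks else None

    def build(bounds, offset):
        A = np.zeros((T, T), dtype=int)
        for i in range(T):
            for j in range(T):
                ki, kj = seg_of(bounds, i), seg_of(bounds, j)
                if ki is None or kj is None:
                    continue
                if kj == ki + offset and kj >= 0:
                    A[i, j] = 1
        return A

    ph0 = build(seg.phoneme_bounds, 0)
    sy0 = build(seg.syllable_bounds, 0)
    return {
        "phoneme(0)": ph0,
        "phoneme(-1)": build(seg.phoneme_bounds, -1),
        "phoneme(-2)": build(seg.phoneme_bounds, -2),
        "syllable(0)'": sy0 - ph0,
        "syllable(-1)": build(seg.syllable_bounds, -1),
        "syllable(-2)": build(seg.syllable_bounds, -2),
    }


class TestTemplates:
    def test_worked_enumeration(self):
        # bounds {0,2,4}, T=6: 12 / 8 / 4 ones in the three phoneme templates
        seg = Segmentation([0, 2, 4], [0, 2, 4], ["aa", "b", "s"], 6)
        t = attention.build_templates(seg)
        assert t["phoneme(0)"].matrix.sum() == 12
        assert t["phoneme(-1)"].matrix.sum() == 8
        assert t["phoneme(-2)"].matrix.sum() == 4

    def test_matches_brute_force_on_random_segmentations(self, random_segmentations):
        for seg in random_segmentations:
            if seg.n_frames > 120:
                continue
            fast = attention.build_templates(seg)
            slow = brute_force_templates(seg)
            for c in TEMPLATE_CONTEXTS:
                np.testing.assert_array_equal(fast[c].matrix, slow[c],
                                              err_msg=f"context {c}")

    def test_phoneme_templates_pairwise_disjoint(self, random_segmentations):
        for seg in random_segmentations:
            t = attention.build_templates(seg)
            p0 = t["phoneme(0)"].matrix
            p1 = t["phoneme(-1)"].matrix
            p2 = t["phoneme(-2)"].matrix
            assert not np.any(p0 & p1)
            assert not np.any(p0 & p2)
            assert not np.any(p1 & p2)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.sets(st.integers(1, 39), min_size=0, max_size=8), st.data())
    def test_disjointness_property_on_arbitrary_bounds(self, extra, data):
        # phoneme templates stay pairwise disjoint for any valid segmentation
        ph_bounds = np.array(sorted({0} | extra))
        n_sy = data.draw(st.integers(1, len(ph_bounds)))
        sy_bounds = np.array(sorted(
            data.draw(st.sets(st.sampled_from(list(ph_bounds[1:])) if len(ph_bounds) > 1
                              else st.just(0), min_size=0, max_size=n_sy)) | {0}))
        seg = Segmentation(ph_bounds, sy_bounds,
                           ["aa"] * len(ph_bounds), n_frames=40)
        t = attention.build_templates(seg)
        for a, b in (("phoneme(0)", "phoneme(-1)"), ("phoneme(0)", "phoneme(-2)"),
                     ("phoneme(-1)", "phoneme(-2)")):
            assert not np.any(t[a].matrix & t[b].matrix)
        # the syllable(0)' template never overlaps the current phoneme
        assert not np.any(t["syllable(0)'"].matrix & t["phoneme(0)"].matrix)

    def test_single_phoneme_degenerate(self):
        seg = Segmentation([0], [0], ["aa"], 8)
        t = attention.build_templates(seg)
        assert t["phoneme(0)"].matrix.all()
        assert t["phoneme(-1)"].matrix.sum() == 0
        assert t["phoneme(-2)"].matrix.sum() == 0

    def test_one_phoneme_per_syllable_coincidence(self):
        seg = Segmentation([0, 3, 6], [0, 3, 6], ["aa", "b", "s"], 9)
        t = attention.build_templates(seg)
        assert t["syllable(0)'"].matrix.sum() == 0
        np.testing.assert_array_equal(t["syllable(-1)"].matrix,
                                      t["phoneme(-1)"].matrix)


class TestAttentionScore:
    def _setup(self, seg):
        return attention.build_templates(seg)

    def test_exact_template_scores_one(self, small_segmentation):
        t = self._setup(small_segmentation)
        A = t["phoneme(0)"].matrix.astype(float)
        scores = attention.attention_score([A[None, None]], [t], "phoneme(0)")
        assert scores[0].as_value == pytest.approx(1.0)

    def test_complement_scores_minus_one(self, small_segmentation):
        t = self._setup(small_segmentation)
        A = t["phoneme(0)"].matrix.astype(float)
        scores = attention.attention_score([(1 - A)[None, None]], [t], "phoneme(0)")
        assert scores[0].as_value == pytest.approx(-1.0)

    def test_head_averaging_contract(self, small_segmentation):
        # one exact-template head + one uncorrelated head -> layer AS ~ 0.5
        t = self._setup(small_segmentation)
        A = t["phoneme(0)"].matrix.astype(float)
        rng = np.random.default_rng(0)
        rs = []
        for _ in range(20):
            noise = rng.random(A.shape)
            W = np.stack([A, noise])[None]  # (1 layer, 2 heads, T, T)
            rs.append(attention.attention_score([W], [t], "phoneme(0)")[0].as_value)
        assert np.mean(rs) == pytest.approx(0.5, abs=0.05)

    def test_zero_variance_template_skipped(self):
        seg = Segmentation([0], [0], ["aa"], 6)  # phoneme(-1) is all-zero
        t = attention.build_templates(seg)
        W = np.random.default_rng(1).random((1, 1, 6, 6))
        scores = attention.attention_score([W], [t], "phoneme(-1)")
        assert scores[0].n_skipped == 1
        assert np.isnan(scores[0].as_value)

    def test_reindexing_invariance(self, small_segmentation):
        t = self._setup(small_segmentation)
        A = t["phoneme(0)"].matrix.astype(float)
        rng = np.random.default_rng(2)
        W = rng.random(A.shape)
        perm = rng.permutation(A.shape[0])
        r1 = attention.template_correlation(W, A)
        r2 = attention.template_correlation(W[np.ix_(perm, perm)], A[np.ix_(perm, perm)])
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_as_monotone_in_mixture_weight(self, small_segmentation):
        tmpl = attention.build_templates(small_segmentation)
        values = []
        for w in (0.0, 0.25, 0.5, 0.75, 1.0):
            mix = np.zeros((1, 6))
            mix[0, 0] = w
            rs = []
            for seed in range(10):
                W = synthetic.gen_attention_matrices(
                    small_segmentation, mix, noise_sd=0.5, n_heads=2, seed=seed)
                rs.append(attention.attention_score([W], [tmpl], "phoneme(0)")[0].as_value)
            values.append(np.mean(rs))
        assert np.all(np.diff(values) > 0)


class TestASBPSCorrelation:
    def test_identity_and_reversal(self):
        v = np.linspace(0.2, 1.5, 12)
        assert attention.as_bps_correlation(v, v) == pytest.approx(1.0)
        assert attention.as_bps_correlation(v, -v) == pytest.approx(-1.0)

    def test_matches_textbook_pearson(self, rng):
        a, b = rng.standard_normal((2, 12))
        r = attention.as_bps_correlation(a, b)
        num = np.sum((a - a.mean()) * (b - b.mean()))
        den = np.sqrt(np.sum((a - a.mean()) ** 2) * np.sum((b - b.mean()) ** 2))
        assert r == pytest.approx(num / den, abs=1e-12)

    def test_too_few_layers_rejected(self):
        with pytest.raises(ValueError):
            attention.as_bps_correlation([1, 2], [1, 2])

    def test_constant_profile_flagged(self):
        with pytest.warns(UserWarning, match="constant"):
            r = attention.as_bps_correlation(np.ones(5), np.arange(5.0))
        assert np.isnan(r)


def _null_setup(seed, n_sent=6, T=60, n_layers=5):
    rng = np.random.default_rng(seed)
    base = [synthetic.gen_feature_stream(T, {"spectrogram": 6}, seed=int(rng.integers(2**31 - 1)))
            for _ in range(n_sent)]
    layers = {
        f"layer{l}": [synthetic.gen_feature_stream(
            T, {"embedding": 4}, seed=int(rng.integers(2**31 - 1)))
            for _ in range(n_sent)]
        for l in range(n_layers)
    }
    y = rng.standard_normal(n_sent * T)
    sid = np.repeat(np.arange(n_sent), T)
    as_vec = rng.random(n_layers)
    return layers, base, y, sid, as_vec


class TestPermutationNull:
    def test_identity_permutation_bounds_p(self):
        layers, base, y, sid, as_vec = _null_setup(1)
        r, p, null = attention.permutation_null(layers, base, y, sid, as_vec,
                                                n_perm=50, seed=2)
        assert p >= 1.0 / 51.0
        assert len(null) == 50

    def test_extreme_low_rank_gives_p_one(self, small_segmentation):
        # an observed statistic below every permuted one must give p = 1
        layers, base, y, sid, as_vec = _null_setup(3)
        r, p, null = attention.permutation_null(layers, base, y, sid, as_vec,
                                                n_perm=30, seed=4)
        manual = (1 + np.sum(null >= r)) / 31.0
        assert p == pytest.approx(manual)

    def test_excessive_permutations_warn(self):
        layers, base, y, sid, as_vec = _null_setup(5, n_sent=3)
        with pytest.warns(UserWarning, match="replacement"):
            attention.permutation_null(layers, base, y, sid, as_vec,
                                       n_perm=10, seed=6)

    def test_unequal_sentence_lengths_rejected(self):
        layers, base, y, sid, as_vec = _null_setup(7)
        sid = sid.copy()
        sid[0] = 1  # sentence 0 loses a frame
        with pytest.raises(ValueError, match="equal-length"):
            attention.permutation_null(layers, base, y, sid, as_vec, n_perm=5)


class TestLabelPermutationP:
    def test_matches_manual_count(self, rng):
        x = rng.standard_normal(10)
        y = x + 0.1 * rng.standard_normal(10)
        r, p = attention.pearson_permutation_p(x, y, n_perm=99, seed=8)
        assert r == pytest.approx(stats.pearsonr(x, y)[0])
        assert 0 < p <= 0.05  # strong positive dependence
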