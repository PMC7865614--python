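"""Statistical and bag-of-features descriptors of asymmetry maps."""

import numpy as np
import pytest

from hemiasym import (
    FeatureRecord,
    PhantomSpec,
    STAT_NAMES,
    StatFeatureVector,
    asymmetry_map,
    bof_encode,
    bof_fit,
    class_feature_means,
    dwt_approx,
    extract_descriptors,
    generate_phantom,
    mirror_mse,
    mse_pareto,
    normalize_features,
    stat_features,
)
from hemiasym.features import bof_fit_descriptors, encode_descriptors, records_to_frame, frame_to_records


def _record(label, vec):
    return FeatureRecord(source_id=f"{label}-{id(vec)}", label=label,
                         stats=StatFeatureVector.from_array(vec))


class TestMirrorMSE:
    def test_identical_zero(self):
        arr = np.random.default_rng(0).uniform(0, 255, (8, 8))
        assert mirror_mse(arr, arr) == 0.0

    def test_constants(self):
        assert mirror_mse(np.full((4, 4), 10.0), np.full((4, 4), 20.0)) == 100.0

    def test_matches_double_loop(self):
        rng = np.random.default_rng(1)
        a, b = rng.uniform(0, 255, (7, 9)), rng.uniform(0, 255, (7, 9))
        acc = 0.0
        for i in range(7):
            for j in range(9):
                acc += (a[i, j] - b[i, j]) ** 2
        assert mirror_mse(a, b) == pytest.approx(acc / 63, rel=1e-12)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            mirror_mse(np.zeros((4, 4)), np.zeros((4, 5)))


class TestDWT:
    def test_haar_constant_gain(self):
        sub = dwt_approx(np.full((8, 8), 7.0), "db1", 1)
        assert sub.shape == (4, 4)
        assert np.allclose(sub, 14.0)  # separable low-pass gain sqrt(2)^2

    def test_2x2_single_coefficient(self):
        sub = dwt_approx(np.full((2, 2), 5.0), "db1", 1)
        assert sub.shape == (1, 1) and sub[0, 0] == pytest.approx(10.0)

    def test_orthogonal_energy_preserved(self):
        import pywt

        rng = np.random.default_rng(2)
        arr = rng.uniform(0, 255, (16, 16))
        cA, (cH, cV, cD) = pywt.dwt2(arr, "db1")
        energy = sum((c**2).sum() for c in (cA, cH, cV, cD))
        assert energy == pytest.approx((arr**2).sum(), rel=1e-6)

    def test_too_small_raises(self):
        with pytest.raises(ValueError, match="smaller"):
            dwt_approx(np.ones((1, 1)), "db2", 1)


@pytest.fixture(scope="module")
def lesion_stats():
    b = generate_phantom(PhantomSpec(label="AD", seed=9, noise_sigma=2.0))
    amap = asymmetry_map(b.image.pixels)
    return stat_features(amap, b.image)


@pytest.fixture(scope="module")
def map_corpus():
    maps = []
    for i in range(5):
        b = generate_phantom(PhantomSpec(label="AD", seed=60 + i, noise_sigma=2.0))
        maps.append(asymmetry_map(b.image.pixels))
    return maps


class TestStatFeatures:
    def test_order_is_fixed(self):
        vec = StatFeatureVector.from_array(np.arange(10.0))
        assert vec.mse == 0.0 and vec.idm == 9.0
        assert tuple(STAT_NAMES) == ("mse", "mean", "std", "entropy", "rms",
                                     "variance", "smoothness", "kurtosis", "skewness", "idm")

    def test_moment_identities(self, lesion_stats):
        s = lesion_stats
        assert s.variance == pytest.approx(s.std**2, rel=1e-9)
        assert s.rms**2 == pytest.approx(s.mean**2 + s.variance, rel=1e-9)

    def test_ranges(self, lesion_stats):
        s = lesion_stats
        assert 0.0 <= s.entropy <= 8.0
        assert 0.0 < s.idm <= 1.0
        assert 0.0 <= s.smoothness < 1.0

    def test_degenerate_zero_map_contract(self, symmetric_bundle):
        amap = asymmetry_map(symmetric_bundle.image.pixels)
        assert np.all(amap.pixels == 0)
        with pytest.warns(RuntimeWarning, match="undefined"):
            s = stat_features(amap, symmetric_bundle.image)
        assert (s.mean, s.std, s.entropy, s.rms, s.variance, s.smoothness,
                s.kurtosis, s.skewness) == (0.0,) * 8
        assert s.idm == 1.0
        assert s.mse == 0.0  # a symmetric original mirrors onto itself

    def test_entropy_matches_hand_histogram(self):
        amap = np.zeros((16, 16))
        amap[:, 8:] = 255.0
        sub = dwt_approx(amap).ravel()
        lo, hi = sub.min(), sub.max()
        scaled = (sub - lo) * 255.0 / (hi - lo)
        counts, _ = np.histogram(scaled, bins=256, range=(0, 256))
        p = counts[counts > 0] / sub.size
        expected = -(p * np.log2(p)).sum()
        s = stat_features(amap, np.zeros((16, 16)))
        assert s.entropy == pytest.approx(expected, rel=1e-12)
        assert s.entropy == pytest.approx(1.0)  # two equally likely levels

    def test_invariant_under_map_mirror(self):
        rng = np.random.default_rng(7)
        amap = rng.uniform(0, 120, (32, 32))
        orig = rng.uniform(0, 255, (32, 32))
        a = stat_features(amap, orig).as_array()
        b = stat_features(amap[:, ::-1], orig).as_array()
        assert np.allclose(a, b, rtol=1e-9)

    def test_example_vector_shape_and_order(self):
        # published example vector: used only as an ordering/shape fixture
        example = [849.477703, 10.47024065, 90.10031233, 0.764676239, 51.73779963,
                   7260.005288, 0.999995013, 52.78224277, 5.661092548, 9052.865381]
        vec = StatFeatureVector.from_array(example)
        assert vec.as_array().shape == (10,)
        assert vec.mse == example[0] and vec.idm == example[-1]


class TestDatasetSummaries:
    def test_normalize_column(self):
        recs = [_record("NC", [v] + [0.0] * 9) for v in (2.0, 4.0, 6.0)]
        out = normalize_features(recs)
        assert [r.stats.mse for r in out] == [0.0, 0.5, 1.0]
        assert all(r.stats.mean == 0.0 for r in out)  # constant column -> 0

    def test_normalize_roundtrip(self):
        rng = np.random.default_rng(8)
        recs = [_record("AD", rng.uniform(-5, 5, 10)) for _ in range(6)]
        out, (lo, hi) = normalize_features(recs, return_bounds=True)
        X = np.stack([r.stats.as_array() for r in out])
        back = X * (hi - lo) + lo
        orig = np.stack([r.stats.as_array() for r in recs])
        assert np.allclose(back, orig, atol=1e-12)

    def test_class_means(self):
        recs = [_record("NC", np.full(10, 1.0)), _record("AD", np.full(10, 2.0)),
                _record("AD", np.full(10, 4.0))]
        means = class_feature_means(recs)
        assert means.loc["NC", "mse"] == 1.0
        assert means.loc["AD", "mse"] == 3.0  # midpoint of the two records

    def test_class_means_match_brute_force(self):
        rng = np.random.default_rng(9)
        recs = [_record(lab, rng.uniform(0, 1, 10))
                for lab in ("NC", "NC", "EMCI", "AD", "AD", "AD")]
        means = class_feature_means(recs)
        for lab in ("NC", "EMCI", "AD"):
            manual = np.mean([r.stats.as_array() for r in recs if r.label == lab], axis=0)
            assert np.allclose(means.loc[lab].to_numpy(), manual)

    def test_pareto_ordering_and_cumulative(self):
        recs = [_record("AD", [60.0] + [0] * 9), _record("NC", [30.0] + [0] * 9),
                _record("EMCI", [10.0] + [0] * 9)]
        df = mse_pareto(recs)
        assert list(df.index) == ["AD", "NC", "EMCI"]
        assert np.allclose(df["cumulative_pct"], [60.0, 90.0, 100.0])

    def test_pareto_single_class(self):
        df = mse_pareto([_record("AD", [5.0] + [0] * 9)])
        assert list(df["cumulative_pct"]) == [100.0]

    def test_empty_inputs_raise(self):
        with pytest.raises(ValueError):
            mse_pareto([])
        with pytest.raises(ValueError):
            class_feature_means([])


class TestMonotonicity:
    def test_lesion_amplitude_increases_mse(self):
        """Stronger unilateral lesions -> strictly larger mirror MSE."""
        mses = []
        for amp in (2.0, 8.0, 16.0):
            b = generate_phantom(PhantomSpec(label="AD", seed=44, asymmetry_amplitude=amp))
            mses.append(mirror_mse(b.image.pixels, b.image.pixels[:, ::-1]))
        assert mses[0] < mses[1] < mses[2]


class TestBOF:
    def test_same_seed_identical_codebook(self, map_corpus):
        cb1 = bof_fit(map_corpus, k=8, seed=5)
        cb2 = bof_fit(map_corpus, k=8, seed=5)
        assert np.array_equal(cb1.centers, cb2.centers)

    def test_histogram_normalized(self, map_corpus):
        cb = bof_fit(map_corpus, k=8, seed=5)
        for m in map_corpus:
            h = bof_encode(m, cb)
            assert h.shape == (8,)
            assert h.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.all(h >= 0)

    def test_assignment_matches_exhaustive_nearest_neighbor(self, map_corpus):
        cb = bof_fit(map_corpus, k=8, seed=5)
        desc = extract_descriptors(map_corpus[0])
        hist = encode_descriptors(desc, cb)
        manual = np.zeros(8)
        for d in desc:
            dists = [np.sum((d - c) ** 2) for c in cb.centers]
            manual[int(np.argmin(dists))] += 1
        assert np.allclose(hist, manual / manual.sum(), atol=1e-12)

    def test_two_blob_populations_separate(self):
        # construct two descriptor clouds far apart; k=2 must split them
        rng = np.random.default_rng(10)
        a = rng.normal(0.0, 0.01, (40, 64))
        b = rng.normal(1.0, 0.01, (40, 64)) / np.sqrt(64)
        cb = bof_fit_descriptors([a, b], k=2, seed=0)
        ha = encode_descriptors(a, cb)
        hb = encode_descriptors(b, cb)
        assert ha.max() == 1.0 and hb.max() == 1.0
        assert ha.argmax() != hb.argmax()

    def test_too_few_descriptors_raises(self, map_corpus):
        with pytest.raises(ValueError, match="descriptors"):
            bof_fit(map_corpus[:1], k=100000, seed=0)

    def test_uniform_histogram_when_no_descriptors(self, map_corpus):
        cb = bof_fit(map_corpus, k=8, seed=5)
        with pytest.warns(RuntimeWarning, match="uniform"):
            h = encode_descriptors(np.zeros((0, 64)), cb)
        assert np.allclose(h, 1 / 8)

    def test_dim_mismatch_raises(self, map_corpus):
        cb = bof_fit(map_corpus, k=8, seed=5)
        with pytest.raises(ValueError, match="dim"):
            encode_descriptors(np.zeros((3, 32)), cb)


class TestTabularRoundtrip:
    def test_records_frame_roundtrip(self):
        rng = np.random.default_rng(11)
        recs = [FeatureRecord(source_id=f"s{i}", label="NC",
                              stats=StatFeatureVector.from_array(rng.uniform(0, 1, 10)),
                              bof_hist=rng.dirichlet(np.ones(4)))
                for i in range(3)]
        df = records_to_frame(recs)
        back = frame_to_records(df)
        for r, b in zip(recs, back):
            assert r.source_id == b.source_id and r.label == b.label
            assert np.allclose(r.stats.as_array(), b.stats.as_array())
            assert np.allclose(r.bof_hist, b.bof_hist)
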