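"""Similarity compression, descriptor assembly and negative sampling."""

import numpy as np
import pandas as pd
import pytest

from mdlink import (
    ATTR_DIM,
    BLOCK_BOUNDS,
    DESCRIPTOR_LEN,
    CompressConfig,
    LabeledPairSet,
    build_dataset,
    build_descriptor,
    compress_similarity,
)


@pytest.fixture(scope="module")
def sim100():
    rng = np.random.default_rng(0)
    base = rng.random((100, 8))
    mat = np.corrcoef(base)
    ids = [f"e{i:03d}" for i in range(100)]
    return pd.DataFrame(mat, index=ids, columns=ids)


class TestCompress:
    def test_output_dim_64(self, sim100):
        out = compress_similarity(sim100, CompressConfig(epochs=3, seed=0))
        assert set(out) == set(sim100.index)
        assert all(v.shape == (ATTR_DIM,) for v in out.values())

    def test_identical_rows_identical_codes(self):
        rng = np.random.default_rng(1)
        M = rng.random((10, 10))
        M[3] = M[7]  # duplicate rows -> identical encoder output
        df = pd.DataFrame(M, index=[f"r{i}" for i in range(10)],
                          columns=[f"r{i}" for i in range(10)])
        out = compress_similarity(df, CompressConfig(epochs=2, seed=0))
        assert np.array_equal(out["r3"], out["r7"])

    def test_training_reduces_reconstruction_error(self, sim100):
        """Reconstruction MSE after training beats the untrained state."""
        from mdlink import _autoencoder as ae

        X = sim100.values.astype(float)
        mu, sd = X.mean(0), X.std(0) + 1e-8
        Xz = (X - mu) / sd
        rng = np.random.default_rng(4)
        state = ae.init_state([100, 256, 64], rng, activation="sigmoid",
                              output_activation="identity")
        _, before = ae.reconstruct(Xz, state)
        mse_before = np.mean((before - Xz) ** 2)
        ae.train(Xz, None, state, alpha=0, beta=1, nu=0, learning_rate=0.01,
                 epochs=30, batch_size=64, rng=rng)
        _, after = ae.reconstruct(Xz, state)
        assert np.mean((after - Xz) ** 2) < mse_before

    def test_seed_determinism(self, sim100):
        a = compress_similarity(sim100, CompressConfig(epochs=3, seed=9))
        b = compress_similarity(sim100, CompressConfig(epochs=3, seed=9))
        assert all(np.array_equal(a[k], b[k]) for k in a)

    def test_non_square_rejected(self):
        df = pd.DataFrame(np.ones((3, 4)))
        with pytest.raises(ValueError):
            compress_similarity(df, CompressConfig(epochs=1))

    def test_fit_ids_subset(self, sim100):
        ids = list(sim100.index)[:40]
        out = compress_similarity(
            sim100, CompressConfig(epochs=2, seed=0), fit_ids=ids
        )
        assert set(out) == set(sim100.index)  # applied to all rows


class TestDescriptor:
    @pytest.fixture()
    def components(self, rng):
        behavior = {
            ("miRNA", "m1"): rng.random(128),
            ("disease", "d1"): rng.random(128),
        }
        attr_m = {"m1": rng.random(64)}
        attr_d = {"d1": rng.random(64)}
        return behavior, attr_m, attr_d

    def test_block_boundaries(self):
        assert BLOCK_BOUNDS == (0, 128, 192, 320, 384)
        assert DESCRIPTOR_LEN == 384

    def test_concatenation_order(self, components):
        behavior, attr_m, attr_d = components
        fd = build_descriptor("m1", "d1", behavior, attr_m, attr_d)
        assert fd.shape == (384,)
        assert np.array_equal(fd[0:128], behavior[("miRNA", "m1")])
        assert np.array_equal(fd[128:192], attr_m["m1"])
        assert np.array_equal(fd[192:320], behavior[("disease", "d1")])
        assert np.array_equal(fd[320:384], attr_d["d1"])

    def test_missing_component_names_entity(self, components):
        behavior, attr_m, attr_d = components
        with pytest.raises(KeyError, match="m2"):
            build_descriptor("m2", "d1", behavior, attr_m, attr_d)
        with pytest.raises(KeyError, match="d9"):
            build_descriptor("m1", "d9", behavior, {"m1": attr_m["m1"]}, attr_d)


class TestBuildDataset:
    @pytest.fixture()
    def world(self, rng):
        mirnas = [f"m{i}" for i in range(8)]
        diseases = [f"d{i}" for i in range(6)]
        behavior = {("miRNA", m): rng.random(128) for m in mirnas}
        behavior |= {("disease", d): rng.random(128) for d in diseases}
        attr_m = {m: rng.random(64) for m in mirnas}
        attr_d = {d: rng.random(64) for d in diseases}
        pos = LabeledPairSet(
            tuple((f"m{i}", f"d{i % 6}", 1) for i in range(8))
        )
        return mirnas, diseases, behavior, attr_m, attr_d, pos

    def test_counts_and_balance(self, world):
        mirnas, diseases, behavior, am, ad, pos = world
        X, y, rows = build_dataset(pos, mirnas, diseases, behavior, am, ad,
                                   ratio=1.0, seed=0)
        assert X.shape == (16, 384)
        assert y.sum() == 8 and len(y) == 16

    def test_negatives_disjoint_from_positives(self, world):
        mirnas, diseases, behavior, am, ad, pos = world
        _, y, rows = build_dataset(pos, mirnas, diseases, behavior, am, ad,
                                   ratio=1.0, seed=1)
        positives = {(m, d) for m, d, lab in pos.pairs}
        negatives = {r for r, lab in zip(rows, y) if lab == 0}
        assert not negatives & positives

    def test_seed_determinism(self, world):
        mirnas, diseases, behavior, am, ad, pos = world
        X1, y1, r1 = build_dataset(pos, mirnas, diseases, behavior, am, ad, seed=5)
        X2, y2, r2 = build_dataset(pos, mirnas, diseases, behavior, am, ad, seed=5)
        assert np.array_equal(X1, X2) and np.array_equal(y1, y2) and r1 == r2

    def test_insufficient_universe(self, world):
        mirnas, diseases, behavior, am, ad, pos = world
        with pytest.raises(ValueError):
            build_dataset(pos, mirnas, diseases, behavior, am, ad,
                          ratio=10.0, seed=0)

    def test_exclusion_respected(self, world):
        mirnas, diseases, behavior, am, ad, pos = world
        banned = {("m0", "d1"), ("m1", "d0")}
        _, y, rows = build_dataset(pos, mirnas, diseases, behavior, am, ad,
                                   seed=2, exclude=banned)
        negatives = {r for r, lab in zip(rows, y) if lab == 0}
        assert not negatives & banned
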