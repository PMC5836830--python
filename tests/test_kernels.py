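import numpy as np
import pytest

from conftest import small_instance
from heterokern.data_model_io import ProfileTable, ValidationError
from heterokern.feature_maps import psi
from heterokern.kernels import (
    BASE_KERNELS,
    GramMatrix,
    KernelSpec,
    combined_kernel,
    domain_composition_kernel,
    gram,
    min_kernel,
    minmax_kernel,
    mlpk,
    scale_normalize,
    tppk,
)

X = np.array([2, 0, 1, 1, 0], dtype=float)
Y = np.array([0, 1, 1, 0, 0], dtype=float)


class TestMinKernel:
    def test_self_value_is_sum(self):
        assert min_kernel(X, X) == 4.0

    def test_cross_value_by_hand(self):
        # elementwise minima: (0, 0, 1, 0, 0)
        assert min_kernel(X, Y) == 1.0

    def test_zero_vector(self):
        assert min_kernel(X, np.zeros(5)) == 0.0

    def test_negative_entry_rejected(self):
        with pytest.raises(ValidationError):
            min_kernel(np.array([-1.0, 0.0]), np.array([0.0, 0.0]))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            min_kernel(X, np.zeros(3))


class TestScaleNormalize:
    def test_diagonal_is_one(self):
        norm = scale_normalize(min_kernel)
        assert norm(X, X) == pytest.approx(1.0)

    def test_hand_value(self):
        # min(X, Y) sums to 1; self-kernels 4 and 2
        norm = scale_normalize(min_kernel)
        assert norm(X, Y) == pytest.approx(1.0 / np.sqrt(8.0))

    def test_zero_vector_convention(self):
        norm = scale_normalize(min_kernel)
        assert norm(np.zeros(5), X) == 0.0
        assert norm(np.zeros(5), np.zeros(5)) == 0.0


class TestMinMax:
    def test_identity_is_one(self):
        assert minmax_kernel(X, X) == 1.0

    def test_disjoint_supports_zero(self):
        assert minmax_kernel(np.array([1.0, 0.0]), np.array([0.0, 2.0])) == 0.0

    def test_hand_value(self):
        y = np.array([1, 1, 1, 0, 0], dtype=float)
        assert minmax_kernel(X, y) == pytest.approx(2.0 / 5.0)

    def test_both_zero_convention(self):
        assert minmax_kernel(np.zeros(3), np.zeros(3)) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            minmax_kernel(np.array([-1.0]), np.array([1.0]))

    def test_equals_min_over_summax(self, rng):
        # dual-route check: independent numerator and denominator
        for _ in range(50):
            x = rng.integers(0, 4, size=8).astype(float)
            y = rng.integers(0, 4, size=8).astype(float)
            summax = float(sum(max(a, b) for a, b in zip(x, y)))
            expected = 0.0 if summax == 0 else min_kernel(x, y) / summax
            assert minmax_kernel(x, y) == pytest.approx(expected, rel=1e-12)

    def test_range_and_one_iff_equal(self, rng):
        for _ in range(50):
            x = rng.integers(0, 4, size=6).astype(float)
            y = rng.integers(0, 4, size=6).astype(float)
            v = minmax_kernel(x, y)
            assert 0.0 <= v <= 1.0
            if not np.array_equal(x, y):
                if np.any(np.minimum(x, y) != np.maximum(x, y)):
                    assert v < 1.0


class TestMLPK:
    def test_self_form(self):
        lifted = mlpk(min_kernel)
        expected = (min_kernel(X, X) + min_kernel(Y, Y) - 2 * min_kernel(X, Y)) ** 2
        assert lifted((X, Y), (X, Y)) == pytest.approx(expected)

    def test_identical_members_give_zero(self):
        lifted = mlpk(min_kernel)
        assert lifted((X, X), (Y, np.zeros(5))) == 0.0

    def test_hand_substitution(self):
        x1, x2 = np.array([1.0, 0.0]), np.array([0.0, 1.0])
        x3, x4 = np.array([1.0, 1.0]), np.array([0.0, 0.0])
        # (K13 - K14 - K23 + K24)^2 = (1 - 0 - 1 + 0)^2 = 0
        assert mlpk(min_kernel)((x1, x2), (x3, x4)) == 0.0

    def test_nonnegative_and_swap_invariant(self, rng):
        lifted = mlpk(min_kernel)
        for _ in range(25):
            v = [rng.integers(0, 4, size=5).astype(float) for _ in range(4)]
            k = lifted((v[0], v[1]), (v[2], v[3]))
            assert k >= 0.0
            assert k == pytest.approx(lifted((v[1], v[0]), (v[2], v[3])))
            assert k == pytest.approx(lifted((v[0], v[1]), (v[3], v[2])))
            assert k == pytest.approx(lifted((v[2], v[3]), (v[0], v[1])))


class TestTPPK:
    def test_self_form(self):
        lifted = tppk(min_kernel)
        expected = min_kernel(X, X) * min_kernel(Y, Y) + min_kernel(X, Y) ** 2
        assert lifted((X, Y), (X, Y)) == pytest.approx(expected)

    def test_hand_substitution(self):
        x1, x2 = np.array([1.0, 0.0]), np.array([0.0, 1.0])
        x3, x4 = np.array([1.0, 1.0]), np.array([0.0, 0.0])
        # K13*K24 + K14*K23 = 1*0 + 0*1 = 0
        assert tppk(min_kernel)((x1, x2), (x3, x4)) == 0.0

    def test_swap_invariance(self, rng):
        lifted = tppk(min_kernel)
        for _ in range(25):
            v = [rng.integers(0, 4, size=5).astype(float) for _ in range(4)]
            k = lifted((v[0], v[1]), (v[2], v[3]))
            assert k == pytest.approx(lifted((v[1], v[0]), (v[2], v[3])))
            assert k == pytest.approx(lifted((v[0], v[1]), (v[3], v[2])))
            assert k == pytest.approx(lifted((v[2], v[3]), (v[0], v[1])))


class TestDomainComposition:
    def table(self):
        return ProfileTable(
            "domain-count",
            ["D1", "D2"],
            {
                "A": np.array([1, 0]),
                "B": np.array([0, 2]),
                "C": np.array([0, 2]),  # same composition as B
                "D": np.array([1, 0]),  # same composition as A
                "E": np.array([2, 2]),
            },
        )

    def test_identity(self):
        k = domain_composition_kernel(self.table())
        assert k(("A", "B"), ("A", "B")) == 1.0

    def test_crossed_match(self):
        k = domain_composition_kernel(self.table())
        # phi(A) == phi(D), phi(B) == phi(C): crossed assignment fires
        assert k(("A", "B"), ("C", "D")) == 1.0

    def test_all_distinct(self):
        k = domain_composition_kernel(self.table())
        assert k(("A", "B"), ("E", "A")) == 0.0

    def test_missing_protein_is_zero_vector(self):
        k = domain_composition_kernel(self.table())
        assert k(("Z1", "Z2"), ("Z3", "Z4")) == 1.0  # all zero vectors match


ALL_SPECS = [
    KernelSpec(base, pw, "dom", 0.7)
    for base in BASE_KERNELS
    for pw in ("mlpk", "tppk")
] + [
    KernelSpec("min", "mlpk+tppk", "dom", 0.7),
    KernelSpec("min", "domain-composition", "dom", 0.7),
    KernelSpec("min", "none", "dom", 0.0),
]


class TestKernelSpec:
    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            KernelSpec(base="bogus")
        with pytest.raises(ValueError):
            KernelSpec(pairwise="bogus")
        with pytest.raises(ValueError):
            KernelSpec(feature_source="bogus")
        with pytest.raises(ValueError):
            KernelSpec(alpha=-0.1)


class TestCombinedKernel:
    def test_alpha_zero_is_psi_inner_product(self, default_instance):
        inputs, pairset = default_instance
        a, b = pairset.pairs[0], pairset.pairs[1]
        spec = KernelSpec("min", "mlpk", "dom", 0.0)
        expected = float(
            psi(inputs.network, inputs.dom_table, a)
            @ psi(inputs.network, inputs.dom_table, b)
        )
        assert combined_kernel(spec, inputs, a, b) == pytest.approx(expected, rel=1e-12)

    def test_sum_lift_is_termwise_sum(self, default_instance):
        inputs, pairset = default_instance
        a, b = pairset.pairs[0], pairset.pairs[5]
        base_val = combined_kernel(KernelSpec("min", "none", "dom", 0.0), inputs, a, b)
        m = combined_kernel(KernelSpec("min", "mlpk", "dom", 1.0), inputs, a, b) - base_val
        t = combined_kernel(KernelSpec("min", "tppk", "dom", 1.0), inputs, a, b) - base_val
        s = combined_kernel(KernelSpec("min", "mlpk+tppk", "dom", 1.0), inputs, a, b)
        assert s == pytest.approx(base_val + m + t, rel=1e-10)

    def test_affine_in_alpha(self, default_instance):
        inputs, pairset = default_instance
        a, b = pairset.pairs[2], pairset.pairs[7]
        k0 = combined_kernel(KernelSpec("minmax", "mlpk", "dom", 0.0), inputs, a, b)
        k1 = combined_kernel(KernelSpec("minmax", "mlpk", "dom", 1.0), inputs, a, b)
        k2 = combined_kernel(KernelSpec("minmax", "mlpk", "dom", 2.0), inputs, a, b)
        assert k2 - k0 == pytest.approx(2 * (k1 - k0), rel=1e-10)


def naive_gram(spec, pairs_a, pairs_b, inputs):
    """Independent oracle: evaluate the scalar kernel in a double loop."""
    out = np.zeros((len(pairs_a), len(pairs_b)))
    for i, pa in enumerate(pairs_a):
        for j, pb in enumerate(pairs_b):
            out[i, j] = combined_kernel(spec, inputs, pa, pb)
    return out


class TestGram:
    def test_one_by_one_alpha_zero(self, default_instance):
        inputs, pairset = default_instance
        pair = pairset.pairs[0]
        G = gram(KernelSpec("min", "mlpk", "dom", 0.0), [pair], [pair], inputs)
        v = psi(inputs.network, inputs.dom_table, pair)
        assert G.entries[0, 0] == pytest.approx(float(v @ v), rel=1e-12)

    @pytest.mark.parametrize("spec", ALL_SPECS, ids=lambda s: f"{s.base}-{s.pairwise}")
    def test_matches_naive_double_loop(self, spec):
        inputs, pairset = small_instance(seed=3)
        pairs = pairset.pairs[:20]
        G = gram(spec, pairs, pairs, inputs)
        expected = naive_gram(spec, pairs, pairs, inputs)
        np.testing.assert_allclose(G.entries, expected, rtol=1e-10, atol=1e-12)

    def test_rectangular_matches_naive(self):
        inputs, pairset = small_instance(seed=5)
        rows, cols = pairset.pairs[:6], pairset.pairs[6:15]
        spec = KernelSpec("scale-normalized-min", "tppk", "dom", 0.4)
        G = gram(spec, rows, cols, inputs)
        np.testing.assert_allclose(
            G.entries, naive_gram(spec, rows, cols, inputs), rtol=1e-10, atol=1e-12
        )

    def test_square_is_symmetric(self, default_instance):
        inputs, pairset = default_instance
        pairs = pairset.pairs[:25]
        G = gram(KernelSpec("minmax", "mlpk", "dom", 0.5), pairs, pairs, inputs)
        np.testing.assert_allclose(G.entries, G.entries.T, rtol=1e-12)

    def test_permutation_permutes_entries(self):
        inputs, pairset = small_instance(seed=9)
        pairs = pairset.pairs[:10]
        spec = KernelSpec("min", "tppk", "dom", 0.3)
        G = gram(spec, pairs, pairs, inputs)
        perm = [3, 1, 4, 0, 2, 9, 8, 5, 7, 6]
        Gp = gram(spec, [pairs[i] for i in perm], [pairs[j] for j in perm], inputs)
        np.testing.assert_allclose(Gp.entries, G.entries[np.ix_(perm, perm)], rtol=1e-12)

    def test_other_feature_sources(self):
        inputs, pairset = small_instance(seed=11)
        pairs = pairset.pairs[:12]
        for source in ("phylo", "local"):
            spec = KernelSpec("minmax", "mlpk", source, 0.8)
            G = gram(spec, pairs, pairs, inputs)
            np.testing.assert_allclose(
                G.entries, naive_gram(spec, pairs, pairs, inputs), rtol=1e-10, atol=1e-12
            )

    def test_psd_over_random_instances(self):
        specs = ALL_SPECS
        for seed in range(10):
            inputs, pairset = small_instance(seed=seed)
            pairs = pairset.pairs[:40]
            for spec in specs:
                G = gram(spec, pairs, pairs, inputs).entries
                eig = np.linalg.eigvalsh((G + G.T) / 2)
                assert eig.min() >= -1e-8 * max(eig.max(), 1.0), (seed, spec)


def test_gram_tsv_roundtrip_shape(tmp_path, default_instance):
    inputs, pairset = default_instance
    pairs = pairset.pairs[:5]
    spec = KernelSpec("min", "mlpk", "dom", 0.5)
    G = gram(spec, pairs, pairs, inputs)
    out = tmp_path / "gram.tsv"
    G.write_tsv(out, spec=spec)
    lines = out.read_text().splitlines()
    assert len(lines) == 6
    assert out.with_suffix(".tsv.json").exists()


def test_gram_matrix_shape_validation():
    with pytest.raises(ValueError):
        GramMatrix([("A", "B")], [("A", "B")], np.zeros((2, 2)))
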