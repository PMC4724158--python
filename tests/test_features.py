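import numpy as np
import pytest

from mpminer.features import (
    SparseDescriptorMatrix,
    qnpr_descriptors,
    sparseness,
    unsupervised_filter,
)


def _as_dict(X, row):
    dense = X.toarray()
    return {name: dense[row, j] for j, name in enumerate(X.column_names)
            if dense[row, j] != 0}


class TestQNPR:
    def test_hand_enumerated_substrings_of_cco(self):
        X = qnpr_descriptors(["CCO"], min_freq=1)
        assert _as_dict(X, 0) == {"C": 2, "O": 1, "CC": 1, "CO": 1, "CCO": 1}

    def test_identical_molecules_give_identical_rows(self):
        X = qnpr_descriptors(["CCO"] * 10, min_freq=5)
        dense = X.toarray()
        assert sorted(X.column_names) == ["C", "CC", "CCO", "CO", "O"]
        assert (dense == dense[0]).all()

    def test_min_freq_counts_molecules_not_occurrences(self):
        # "N" occurs in 4 molecules (twice in one) -> below min_freq=5
        smiles = ["NCN", "NC", "CN", "NO"] + ["CC"] * 6
        X = qnpr_descriptors(smiles, min_freq=5)
        assert "N" not in X.column_names
        X4 = qnpr_descriptors(smiles, min_freq=4)
        assert "N" in X4.column_names

    def test_row_order_follows_input_and_columns_are_stable(self):
        a = qnpr_descriptors(["CCO", "CCN", "CCC", "CCO", "CCN"], min_freq=2)
        b = qnpr_descriptors(["CCN", "CCC", "CCO", "CCN", "CCO"], min_freq=2)
        assert a.column_names == b.column_names
        assert sorted(map(tuple, a.toarray())) == sorted(map(tuple,
                                                             b.toarray()))

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            qnpr_descriptors([])


class TestSparseness:
    def test_dense_matrix_has_zero_sparseness(self):
        X = qnpr_descriptors(["CC", "CC"], min_freq=1)
        # columns C and CC, both non-zero everywhere
        assert sparseness(X) == 0.0

    def test_counts_zeros_per_nonzero(self):
        import scipy.sparse as sp
        X = SparseDescriptorMatrix(
            matrix=sp.csr_matrix(np.array([[1.0, 0.0], [0.0, 0.0]])),
            column_names=["a", "b"])
        assert sparseness(X) == 3.0

    def test_matches_brute_force_on_random_fixture(self):
        rng = np.random.default_rng(5)
        import scipy.sparse as sp
        dense = rng.random((20, 15)) * (rng.random((20, 15)) < 0.2)
        X = SparseDescriptorMatrix(matrix=sp.csr_matrix(dense),
                                   column_names=[str(j) for j in range(15)])
        nz = np.count_nonzero(dense)
        assert sparseness(X) == pytest.approx((dense.size - nz) / nz)

    def test_all_zero_matrix_rejected(self):
        import scipy.sparse as sp
        X = SparseDescriptorMatrix(matrix=sp.csr_matrix((3, 3)),
                                   column_names=["a", "b", "c"])
        with pytest.raises(ValueError):
            sparseness(X)


def _named(dense, names=None):
    import scipy.sparse as sp
    dense = np.asarray(dense, dtype=float)
    names = names or [f"c{j}" for j in range(dense.shape[1])]
    return SparseDescriptorMatrix(matrix=sp.csr_matrix(dense),
                                  column_names=list(names))


class TestUnsupervisedFilter:
    def test_near_empty_columns_eliminated(self):
        dense = np.zeros((6, 3))
        dense[:, 0] = [1, 2, 3, 4, 5, 6]
        dense[0:2, 1] = 1.0          # exactly 2 non-zeros: dropped
        dense[0:3, 2] = [5, 6, 7]    # 3 non-zeros: kept
        Xf, gmap = unsupervised_filter(_named(dense))
        assert Xf.column_names == ["c0", "c2"]
        assert "c1" not in gmap  # dropped for emptiness, not correlation

    def test_identical_columns_keep_first(self):
        col = np.array([1.0, 2, 3, 4, 5, 6])
        Xf, gmap = unsupervised_filter(_named(np.column_stack([col, col])))
        assert Xf.column_names == ["c0"]
        assert gmap == {"c1": "c0"}

    def test_affine_related_column_grouped(self):
        col = np.array([1.0, 2, 3, 4, 5, 6])
        dense = np.column_stack([col, 2 * col + 3.0])
        Xf, gmap = unsupervised_filter(_named(dense))
        assert Xf.column_names == ["c0"]
        assert gmap == {"c1": "c0"}

    def test_uncorrelated_columns_all_kept(self):
        rng = np.random.default_rng(0)
        dense = rng.random((50, 4)) + 0.1  # dense, independent
        Xf, gmap = unsupervised_filter(_named(dense))
        assert Xf.n_cols == 4 and gmap == {}

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        base = rng.random((40, 5)) + 0.1
        dense = np.column_stack([base, base[:, 0] * 3 + 1])
        Xf, _ = unsupervised_filter(_named(dense))
        Xff, gmap2 = unsupervised_filter(Xf)
        assert Xff.column_names == Xf.column_names
        assert gmap2 == {}

    def test_matches_brute_force_greedy_oracle(self):
        rng = np.random.default_rng(2)
        n, p = 30, 20
        base = rng.random((n, 6)) + 0.05
        cols = [base[:, rng.integers(6)] * rng.uniform(0.5, 2.0)
                + (rng.uniform(-1, 1) if rng.random() < 0.5 else 0.0)
                if rng.random() < 0.5 else rng.random(n)
                for _ in range(p)]
        dense = np.column_stack(cols)
        X = _named(dense)
        Xf, gmap = unsupervised_filter(X)

        # independent O(p^2) oracle: greedy grouping in column order
        keep, mapping = [], {}
        for j in range(p):
            if np.count_nonzero(dense[:, j]) <= 2:
                continue
            for k in keep:
                r = np.corrcoef(dense[:, j], dense[:, k])[0, 1]
                if r * r > 0.95:
                    mapping[f"c{j}"] = f"c{k}"
                    break
            else:
                keep.append(j)
        assert Xf.column_names == [f"c{k}" for k in keep]
        assert gmap == mapping

    def test_never_inspects_a_target(self):
        # pure API property: the filter takes no target argument and the
        # result depends only on the matrix
        rng = np.random.default_rng(3)
        dense = rng.random((30, 6)) + 0.1
        a, _ = unsupervised_filter(_named(dense))
        b, _ = unsupervised_filter(_named(dense.copy()))
        assert a.column_names == b.column_names
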