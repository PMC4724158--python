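"""Sparse QNPR descriptors and unsupervised descriptor filtering.

QNPR descriptors count every contiguous character substring (length 1–3 by
default) of a molecule's SMILES string; substrings occurring in fewer than
five molecules of the dataset are dropped.  The SMILES is split character
by character — two-letter element symbols are not tokenized — so canonical
SMILES should be fixed upstream for reproducible descriptors.

The unsupervised filter removes near-empty columns (two or fewer non-zero
values across the dataset) and collapses groups of inter-correlated columns
(pairwise R² > 0.95) to a single representative.  It never consults the
target property, so it introduces no selection bias.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import scipy.sparse as sp

__all__ = [
    "SparseDescriptorMatrix",
    "qnpr_descriptors",
    "unsupervised_filter",
    "sparseness",
]


@dataclass
class SparseDescriptorMatrix:
    """A named molecule × descriptor matrix stored sparsely (CSR)."""

    matrix: sp.csr_matrix
    column_names: List[str]

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_cols(self) -> int:
        return self.matrix.shape[1]

    @property
    def nnz(self) -> int:
        return int(self.matrix.nnz)

    def toarray(self) -> np.ndarray:
        return self.matrix.toarray()


def _substrings(s: str, min_len: int, max_len: int) -> Dict[str, int]:
    counts: Dict[str, int] = {}
    for length in range(min_len, max_len + 1):
        for i in range(len(s) - length + 1):
            sub = s[i:i + length]
            counts[sub] = counts.get(sub, 0) + 1
    return counts


def qnpr_descriptors(
    smiles_list: Sequence[str],
    min_len: int = 1,
    max_len: int = 3,
    min_freq: int = 5,
) -> SparseDescriptorMatrix:
    """QNPR substring-count descriptors over a set of SMILES strings.

    One column per substring of length ``min_len``..``max_len`` present in
    at least ``min_freq`` molecules; the cell value is the occurrence count
    of the substring in that molecule's SMILES.  Columns are ordered
    lexicographically so the matrix depends only on the multiset of SMILES.
    """
    if len(smiles_list) == 0:
        raise ValueError("empty dataset")
    per_mol = [_substrings(s, min_len, max_len) for s in smiles_list]
    mol_freq: Dict[str, int] = {}
    for counts in per_mol:
        for sub in counts:
            mol_freq[sub] = mol_freq.get(sub, 0) + 1
    columns = sorted(sub for sub, f in mol_freq.items() if f >= min_freq)
    col_index = {c: j for j, c in enumerate(columns)}

    rows, cols, data = [], [], []
    for i, counts in enumerate(per_mol):
        for sub, v in counts.items():
            j = col_index.get(sub)
            if j is not None:
                rows.append(i)
                cols.append(j)
                data.append(v)
    matrix = sp.csr_matrix(
        (data, (rows, cols)), shape=(len(smiles_list), len(columns)),
        dtype=np.float64)
    return SparseDescriptorMatrix(matrix=matrix, column_names=columns)


def sparseness(X: SparseDescriptorMatrix) -> float:
    """Zero entries per non-zero entry of the matrix."""
    nnz = X.nnz
    if nnz == 0:
        raise ValueError("all-zero matrix")
    total = X.n_rows * X.n_cols
    return (total - nnz) / nnz


def _pairwise_r2(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0.0 and sb == 0.0:
        return 1.0
    if sa == 0.0 or sb == 0.0:
        return 0.0
    r = float(np.corrcoef(a, b)[0, 1])
    return r * r


def unsupervised_filter(
    X: SparseDescriptorMatrix,
    max_nonzero_drop: int = 2,
    r2_threshold: float = 0.95,
) -> Tuple[SparseDescriptorMatrix, Dict[str, str]]:
    """Drop near-empty columns and collapse inter-correlated ones.

    Columns with at most ``max_nonzero_drop`` non-zero values are removed.
    Remaining columns are grouped greedily in column order: a column joins
    the first kept column whose squared Pearson correlation with it exceeds
    ``r2_threshold``, otherwise it is kept itself.  ``group_map`` maps each
    dropped column name to the kept representative it correlates with.
    """
    if X.n_rows < 2:
        raise ValueError("need at least two rows to correlate descriptors")
    dense = X.toarray()
    nonzero_counts = (dense != 0).sum(axis=0)
    candidate_idx = [j for j in range(X.n_cols)
                     if nonzero_counts[j] > max_nonzero_drop]

    kept: List[int] = []
    group_map: Dict[str, str] = {}
    reps: List[np.ndarray] = []
    rep_means: List[float] = []
    rep_stds: List[float] = []
    for j in candidate_idx:
        col = dense[:, j]
        mu, sd = col.mean(), col.std()
        assigned = False
        for k, rep in enumerate(reps):
            if sd == 0.0 and rep_stds[k] == 0.0:
                r2 = 1.0
            elif sd == 0.0 or rep_stds[k] == 0.0:
                r2 = 0.0
            else:
                cov = float(np.dot(col - mu, rep - rep_means[k])) / len(col)
                r = cov / (sd * rep_stds[k])
                r2 = r * r
            if r2 > r2_threshold:
                group_map[X.column_names[j]] = X.column_names[kept[k]]
                assigned = True
                break
        if not assigned:
            kept.append(j)
            reps.append(col)
            rep_means.append(mu)
            rep_stds.append(sd)

    filtered = SparseDescriptorMatrix(
        matrix=sp.csr_matrix(X.matrix[:, kept]),
        column_names=[X.column_names[j] for j in kept],
    )
    return filtered, group_map
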