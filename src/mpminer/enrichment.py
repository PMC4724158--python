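"""Hypergeometric over/under-representation of structural features.

Given binary feature incidence over a population of molecules and a subset
of interest (e.g. the compounds that decompose on heating rather than
melt), each feature's upper-tail hypergeometric probability measures how
surprising its subset count is under random draws, and the fold change
(k/n)/(K/N) measures the direction and size of the effect.  Features are
pluggable SMARTS predicates; a starter set covers groups known to favor
thermal decomposition (acids, primary amines, tetrazoles, nitroso).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
from rdkit import Chem
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EnrichmentResult",
    "set_compare",
    "FUNCTIONAL_GROUP_SMARTS",
    "feature_incidence",
]


@dataclass(frozen=True)
class EnrichmentResult:
    feature: str
    k: int  # feature count in the subset
    n: int  # subset size
    K: int  # feature count in the population
    N: int  # population size
    fold: float  # (k/n) / (K/N)
    p_value: float  # upper-tail hypergeometric probability of >= k
    q_value: float = float("nan")  # Benjamini-Hochberg adjusted


# Groups the decomposition analysis names; SMARTS via the structure library.
FUNCTIONAL_GROUP_SMARTS: Dict[str, str] = {
    "carboxylic_acid": "[CX3](=O)[OX2H1]",
    "phosphonic_acid": "[PX4](=O)([OX2H1])[OX2H1]",
    "alpha_amino_acid": "[NX3;H2][CX4][CX3](=O)[OX2H1]",
    "primary_amine": "[NX3;H2;!$(NC=O)]",
    "tetrazole": "c1nnnn1",
    "nitroso": "[NX2]=O",
}


def feature_incidence(
    smiles_list: Sequence[str],
    patterns: Optional[Mapping[str, str]] = None,
) -> Dict[str, np.ndarray]:
    """Binary presence of each SMARTS-defined group per molecule.

    Incidence is presence, not count — the hypergeometric model requires
    binary features.  Unparsable SMILES count as lacking every feature.
    """
    patterns = dict(patterns or FUNCTIONAL_GROUP_SMARTS)
    queries = {name: Chem.MolFromSmarts(s) for name, s in patterns.items()}
    mols = [Chem.MolFromSmiles(s) for s in smiles_list]
    return {
        name: np.array([m is not None and m.HasSubstructMatch(q)
                        for m in mols])
        for name, q in queries.items()
    }


def set_compare(
    features_by_record: Mapping[str, Sequence[bool]],
    subset_mask: Sequence[bool],
) -> List[EnrichmentResult]:
    """Hypergeometric enrichment of each feature in a subset of records.

    ``features_by_record`` maps feature name to a per-record boolean
    incidence vector; ``subset_mask`` selects the subset.  For each feature
    the upper-tail probability P(X >= k) of drawing k feature carriers in n
    draws from a population of N with K carriers is computed, the fold
    change reported, Benjamini–Hochberg q-values attached, and results
    returned sorted by p-value.
    """
    mask = np.asarray(subset_mask, dtype=bool)
    N = mask.size
    n = int(mask.sum())
    if n > N:
        raise ValueError("subset larger than population")
    raw: List[EnrichmentResult] = []
    for name, incidence in features_by_record.items():
        inc = np.asarray(incidence, dtype=bool)
        if inc.size != N:
            raise ValueError(f"incidence length mismatch for {name!r}")
        K = int(inc.sum())
        k = int((inc & mask).sum())
        fold = ((k / n) / (K / N)) if (n > 0 and K > 0) else float("nan")
        p = float(hypergeom.sf(k - 1, N, K, n))
        raw.append(EnrichmentResult(feature=name, k=k, n=n, K=K, N=N,
                                    fold=fold, p_value=p))
    if not raw:
        return []
    qvals = multipletests([r.p_value for r in raw], method="fdr_bh")[1]
    results = [EnrichmentResult(feature=r.feature, k=r.k, n=r.n, K=r.K,
                                N=r.N, fold=r.fold, p_value=r.p_value,
                                q_value=float(q))
               for r, q in zip(raw, qvals)]
    results.sort(key=lambda r: (r.p_value, r.feature))
    return results
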