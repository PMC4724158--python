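"""Curation of extracted compound/melting-point records.

Mirrors the cleaning applied to patent-mined melting points before QSPR
modeling: suspicious-value and mixture exclusion, transitive elimination of
near-duplicate measurements (|ΔT| <= 1 °C), selection of one representative
record per molecule (nearest the median of its distinct measurements, so
the link to the originating patent is preserved), the all-pairs ΔT stream
feeding the experimental-accuracy estimate, and the drug-like
[50, 250] °C subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from rdkit import Chem

from .association import CompoundMPRecord

__all__ = [
    "CuratedDataset",
    "canonical_key",
    "exclude_suspicious_and_mixtures",
    "deduplicate",
    "pairwise_differences",
    "pairwise_difference_pairs",
    "drug_like_subset",
    "curate",
]


@dataclass
class CuratedDataset:
    """One representative record per molecule plus its measurement group."""

    records: List[CompoundMPRecord]
    groups: Dict[str, List[CompoundMPRecord]]
    counts: Dict[str, int] = field(default_factory=dict)


def canonical_key(smiles: str) -> Optional[str]:
    """Canonical SMILES of the standardized structure, or None if unparsable.

    No salt stripping is performed: multi-component records are excluded
    outright rather than desalted.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    return Chem.MolToSmiles(mol)


def exclude_suspicious_and_mixtures(
    records: Iterable[CompoundMPRecord],
) -> Tuple[List[CompoundMPRecord], Dict[str, int]]:
    """Drop flagged records, mixtures and unparsable structures.

    A mixture is a structure with more than one connected component.
    Returns the retained records and exclusion counts by class.
    """
    kept: List[CompoundMPRecord] = []
    counts = {"input": 0, "suspicious_excluded": 0,
              "mixtures_excluded": 0, "unparsable_excluded": 0}
    for rec in records:
        counts["input"] += 1
        if rec.mp.suspicious:
            counts["suspicious_excluded"] += 1
            continue
        mol = Chem.MolFromSmiles(rec.smiles)
        if mol is None:
            counts["unparsable_excluded"] += 1
            continue
        if len(Chem.GetMolFrags(mol)) > 1:
            counts["mixtures_excluded"] += 1
            continue
        kept.append(rec)
    counts["retained"] = len(kept)
    return kept, counts


def _merge_clusters(
    group: Sequence[CompoundMPRecord], delta_t: float
) -> List[CompoundMPRecord]:
    """Single-linkage merge of measurements within |ΔT| <= delta_t.

    Each merged cluster keeps its first-seen record, so chains like
    100, 100.8, 101.5 collapse to one measurement.
    """
    order = sorted(range(len(group)), key=lambda i: group[i].mp.midpoint)
    clusters: List[List[int]] = []
    for idx in order:
        v = group[idx].mp.midpoint
        if clusters and v - group[clusters[-1][-1]].mp.midpoint <= delta_t:
            clusters[-1].append(idx)
        else:
            clusters.append([idx])
    # first-seen = smallest original index within the cluster
    return [group[min(c)] for c in clusters]


def _median(values: Sequence[float]) -> float:
    s = sorted(values)
    n = len(s)
    mid = n // 2
    return s[mid] if n % 2 else 0.5 * (s[mid - 1] + s[mid])


def deduplicate(
    records: Iterable[CompoundMPRecord], delta_t: float = 1.0
) -> CuratedDataset:
    """Collapse repeated measurements and pick a per-molecule representative.

    Measurements of one molecule are merged transitively whenever their
    midpoints differ by at most ``delta_t``; the survivors are that
    molecule's distinct measurement values.  The representative is the
    retained record whose midpoint lies nearest the median of the distinct
    values; ties resolve to the lower temperature, then the earlier patent
    id — deterministic and provenance-preserving.
    """
    by_key: Dict[str, List[CompoundMPRecord]] = {}
    counts = {"input": 0, "unparsable_excluded": 0}
    for rec in records:
        counts["input"] += 1
        key = canonical_key(rec.smiles)
        if key is None:
            counts["unparsable_excluded"] += 1
            continue
        by_key.setdefault(key, []).append(rec)

    groups: Dict[str, List[CompoundMPRecord]] = {}
    representatives: List[CompoundMPRecord] = []
    eliminated = 0
    for key, group in by_key.items():
        retained = _merge_clusters(group, delta_t)
        eliminated += len(group) - len(retained)
        groups[key] = retained
        med = _median([r.mp.midpoint for r in retained])
        rep = min(retained,
                  key=lambda r: (abs(r.mp.midpoint - med), r.mp.midpoint,
                                 r.doc_id))
        representatives.append(rep)
    counts["duplicates_eliminated"] = eliminated
    counts["molecules"] = len(groups)
    return CuratedDataset(records=representatives, groups=groups,
                          counts=counts)


def _group_values(group) -> List[float]:
    return [r.mp.midpoint if isinstance(r, CompoundMPRecord) else float(r)
            for r in group]


def pairwise_differences(groups: Mapping[str, Sequence]) -> List[float]:
    """|ΔT| for every pair of distinct measurements of the same molecule."""
    diffs: List[float] = []
    for group in groups.values():
        values = _group_values(group)
        diffs.extend(abs(a - b) for a, b in combinations(values, 2))
    return diffs


def pairwise_difference_pairs(
    groups: Mapping[str, Sequence],
) -> List[Tuple[float, float]]:
    """(mean MP, |ΔT|) per measurement pair, for the binned accuracy curve."""
    pairs: List[Tuple[float, float]] = []
    for group in groups.values():
        values = _group_values(group)
        pairs.extend((0.5 * (a + b), abs(a - b))
                     for a, b in combinations(values, 2))
    return pairs


def drug_like_subset(
    records: Iterable[CompoundMPRecord], low: float = 50.0, high: float = 250.0
) -> List[CompoundMPRecord]:
    """Records whose interval midpoint lies in the closed [low, high] °C."""
    return [r for r in records if low <= r.mp.midpoint <= high]


def curate(
    records: Iterable[CompoundMPRecord], delta_t: float = 1.0
) -> CuratedDataset:
    """Full curation chain: exclusion, deduplication, representative pick."""
    kept, excl_counts = exclude_suspicious_and_mixtures(records)
    dataset = deduplicate(kept, delta_t=delta_t)
    merged = dict(excl_counts)
    merged["duplicates_eliminated"] = dataset.counts["duplicates_eliminated"]
    merged["molecules"] = dataset.counts["molecules"]
    merged["input"] = excl_counts["input"]
    dataset.counts = merged
    return dataset
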