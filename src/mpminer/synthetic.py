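"""Synthetic fixtures: patent-style corpora and structure–property tables.

Every downstream module is testable without any external download:

* :func:`generate_corpus` emits annotated experimental sections in the
  shape of patent text — a heading naming the synthesized product, a
  synthesis paragraph, and a characterization tail carrying a
  melting-point declaration — together with the ground-truth normalized
  record for each declaration.  The generator can inject the error
  patterns real patent text exhibits (missing decimal points, decimal
  commas, truncated or inverted ranges, grossly misprinted values) and
  records in the truth stream what it injected.

* :func:`generate_qspr` emits a structure–property table over an
  enumerable family of substituted aromatics and alkanes.  The latent
  melting point is a deterministic, descriptor-visible function of simple
  structural counts centered near 155 °C; observations add Gaussian noise
  of known σ, duplicates re-observe with fresh noise, gross outliers are
  offset by a known multiple of σ, and a minority decomposing class is
  drawn with its median shifted upward (210 vs 155 °C in the real data)
  and biased toward acid/amine-bearing structures so that both the
  classifier and the enrichment analysis have signal to find.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from rdkit import Chem

from .association import AnnotatedDocument, Block, CompoundMPRecord, Entity
from .grammar import NormalizedMP, Outcome, Qualifier, SuspiciousReason

__all__ = [
    "CorpusConfig",
    "QSPRConfig",
    "TruthRecord",
    "molecule_family",
    "generate_corpus",
    "generate_qspr",
]

TYPO_CLASSES = ("missing_decimal", "comma_decimal", "truncated_range",
                "inverted_range", "huge_value")


@dataclass
class CorpusConfig:
    n_sections: int = 100
    seed: int = 0
    typo_rates: Dict[str, float] = field(
        default_factory=lambda: {c: 0.0 for c in TYPO_CLASSES})
    unit_mix: float = 0.10          # fraction of single values in °F
    spelled_out_fraction: float = 0.05
    range_fraction: float = 0.55
    measurement_error_fraction: float = 0.05
    qualifier_rate: float = 0.05
    from_literature_rate: float = 0.05
    decompose_fraction: float = 0.055
    sublime_fraction: float = 0.01
    explicit_fraction: float = 0.5  # bracket-after-entity vs end-of-section


@dataclass
class QSPRConfig:
    n_molecules: int = 2000
    sigma_noise: float = 35.0       # °C, experimental reproducibility
    duplicate_rate: float = 0.3     # probability of a repeat measurement
    outlier_rate: float = 0.0
    outlier_offset_sigma: float = 5.0
    decomp_fraction: float = 0.055  # minority decomposing class
    decomp_median_shift: float = 55.0  # 210 °C vs 155 °C medians
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.decomp_fraction < 1.0:
            raise ValueError("decomp_fraction must be in [0, 1)")
        if self.sigma_noise <= 0:
            raise ValueError("sigma_noise must be positive")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one generated declaration, plus production tags."""

    record: CompoundMPRecord
    tags: Dict[str, str]


# ---------------------------------------------------------------------------
# Molecule family
# ---------------------------------------------------------------------------

_SUBS = ["", "C", "CC", "CCC", "CCCC", "C(C)C", "O", "OC", "OCC", "N", "NC",
         "F", "Cl", "Br", "C#N", "C=O", "C(=O)O", "C(=O)N"]
_NONEMPTY = [s for s in _SUBS if s]


@lru_cache(maxsize=1)
def molecule_family() -> List[str]:
    """Deterministic, enumerable family of valid single-component SMILES."""
    raw: List[str] = []
    # mono/di-substituted aromatics over several cores
    for r1 in _SUBS:
        raw.append(r1 + "c1ccccc1" if r1 else "c1ccccc1")
        for r2 in _NONEMPTY:
            raw.append(r1 + f"c1ccc({r2})cc1")   # para
            raw.append(r1 + f"c1cccc({r2})c1")   # meta
            raw.append(r1 + f"c1ccc({r2})nc1")   # pyridine
            raw.append(r1 + f"c1ccc({r2})s1")    # thiophene
    # tri-substituted benzenes and pyridines
    for r1 in _NONEMPTY:
        for r2 in _NONEMPTY:
            for r3 in _NONEMPTY:
                raw.append(r1 + f"c1cc({r2})cc({r3})c1")
                raw.append(r1 + f"c1nc({r2})cc({r3})c1")
    # alkanes / simple aliphatics
    for k in range(1, 11):
        for tail in ["", "O", "N", "Cl", "C(=O)O", "OC"]:
            raw.append("C" * k + tail)
    seen = {}
    for s in raw:
        mol = Chem.MolFromSmiles(s)
        if mol is None:
            continue
        can = Chem.MolToSmiles(mol)
        if can not in seen:
            seen[can] = True
    return sorted(seen)


def _latent_features(smiles: str) -> np.ndarray:
    mol = Chem.MolFromSmiles(smiles)
    nring = mol.GetRingInfo().NumRings()
    symbols = [a.GetSymbol() for a in mol.GetAtoms()]
    n_n = symbols.count("N")
    n_o = symbols.count("O")
    n_hal = sum(symbols.count(x) for x in ("F", "Cl", "Br"))
    heavy = mol.GetNumHeavyAtoms()
    return np.array([nring, n_n, n_o, n_hal, heavy], dtype=float)


def _latent_mp_raw(feats: np.ndarray) -> float:
    nring, n_n, n_o, n_hal, heavy = feats
    # linear in a handful of counts plus a mild interaction, so kernel
    # learners beat a purely linear stack detectably
    return (44.0 * nring + 22.0 * n_n + 14.0 * n_o + 10.0 * n_hal
            + 4.0 * (heavy - 6.0) + 6.0 * n_n * nring)


@lru_cache(maxsize=1)
def _family_center() -> float:
    vals = [_latent_mp_raw(_latent_features(s)) for s in molecule_family()]
    return float(np.mean(vals))


def latent_mp(smiles: str) -> float:
    """Deterministic true melting point, centered near 155 °C."""
    return 155.0 + _latent_mp_raw(_latent_features(smiles)) - _family_center()


# ---------------------------------------------------------------------------
# Corpus generation
# ---------------------------------------------------------------------------

_ONES_W = ["zero", "one", "two", "three", "four", "five", "six", "seven",
           "eight", "nine", "ten", "eleven", "twelve", "thirteen",
           "fourteen", "fifteen", "sixteen", "seventeen", "eighteen",
           "nineteen"]
_TENS_W = {20: "twenty", 30: "thirty", 40: "forty", 50: "fifty",
           60: "sixty", 70: "seventy", 80: "eighty", 90: "ninety"}


def _spell(n: int) -> str:
    if not 0 <= n <= 999:
        raise ValueError("spelled-out numbers limited to 0..999")
    parts: List[str] = []
    if n >= 100:
        parts.append(_ONES_W[n // 100] + " hundred")
        n %= 100
        if n:
            parts.append("and")
    if n >= 20:
        tens, ones = 10 * (n // 10), n % 10
        parts.append(_TENS_W[tens] + ("-" + _ONES_W[ones] if ones else ""))
    elif n > 0 or not parts:
        parts.append(_ONES_W[n])
    return " ".join(parts)


def _fmt(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else f"{v:g}"


_PREFIXES = ["m.p.", "mp", "mpt", "melting point"]
_QUAL_TOKENS = [(">", Qualifier.GREATER), ("<", Qualifier.LESS),
                ("about", Qualifier.APPROX), ("ca.", Qualifier.APPROX)]


def _suspicious_reasons(low: float, high: float) -> frozenset:
    reasons = set()
    if max(low, high) > 500.0:
        reasons.add(SuspiciousReason.ABOVE_500)
    if abs(high - low) > 50.0:
        reasons.add(SuspiciousReason.RANGE_OVER_50)
    if high < low:
        reasons.add(SuspiciousReason.INVERTED_RANGE)
    if min(low, high) < -273.15:
        reasons.add(SuspiciousReason.BELOW_ABSOLUTE_ZERO)
    return frozenset(reasons)


def _render_declaration(rng: np.random.Generator, cfg: CorpusConfig):
    """Build one declaration: (text, truth low, truth high, qualifier,
    outcome, tags)."""
    tags: Dict[str, str] = {}

    typo = None
    for cls in TYPO_CLASSES:
        if rng.random() < cfg.typo_rates.get(cls, 0.0):
            typo = cls
            break
    tags["typo"] = typo or "none"

    base = int(rng.integers(55, 296))
    qualifier = Qualifier.NONE
    outcome = Outcome.MELT
    u = rng.random()
    if u < cfg.decompose_fraction:
        outcome = Outcome.DECOMPOSE
    elif u < cfg.decompose_fraction + cfg.sublime_fraction:
        outcome = Outcome.SUBLIME

    if typo in ("missing_decimal", "comma_decimal", "truncated_range",
                "inverted_range"):
        kind = "range"
    elif typo == "huge_value":
        kind = "single"
    else:
        r = rng.random()
        if r < cfg.range_fraction:
            kind = "range"
        elif r < cfg.range_fraction + cfg.measurement_error_fraction:
            kind = "error"
        else:
            kind = "single"
    tags["value_kind"] = kind
    tags["unit"] = "celsius"
    tags["spelled"] = "no"

    if kind == "range":
        width = int(rng.integers(1, 4))
        if typo is not None:
            # typo'd ranges stay within one tens block of three-digit values
            # so truncation is unambiguously repairable (and an inverted
            # print has equal digit counts, hence is unrepairable)
            base = int(rng.integers(100, 291))
            if (base + width) // 10 != base // 10:
                base -= width
        low, high = float(base), float(base + width)
        sep = rng.choice(["-", "–", "—", " to "])
        if typo == "comma_decimal":
            high = low + 0.5
            value_text = f"{_fmt(low)}{sep}{int(low)},5"
        elif typo == "truncated_range":
            hs, ls = _fmt(high), _fmt(low)
            cut = int(rng.integers(1, len(hs)))  # digits kept at the tail
            value_text = f"{ls}{sep}{hs[len(hs) - cut:]}"
        elif typo == "missing_decimal":
            # "235-236.0" printed as "235-2360"
            value_text = f"{_fmt(low)}{sep}{int(high * 10)}"
            high = high * 10
        elif typo == "inverted_range":
            low, high = high, low  # printed inverted, same digit count
            value_text = f"{_fmt(low)}{sep}{_fmt(high)}"
        else:
            value_text = f"{_fmt(low)}{sep}{_fmt(high)}"
        if rng.random() < 0.5:
            value_text += " °C"
    elif kind == "error":
        err = int(rng.integers(1, 4))
        low, high = float(base - err), float(base + err)
        value_text = f"{base} ± {err} °C"
    else:  # single
        if typo == "huge_value":
            shown = base * 10  # misprint: an extra digit
            low = high = float(shown)
            value_text = f"{shown} °C"
        elif rng.random() < cfg.spelled_out_fraction:
            tags["spelled"] = "yes"
            low = high = float(base)
            value_text = _spell(base) + " degrees Celsius"
        elif rng.random() < cfg.unit_mix:
            tags["unit"] = "fahrenheit"
            f_shown = int(round(base * 9 / 5 + 32))
            low = high = (f_shown - 32.0) * 5.0 / 9.0
            value_text = f"{f_shown} °F"
        else:
            low = high = float(base)
            value_text = f"{base} °C"
            if rng.random() < cfg.qualifier_rate:
                tok, qualifier = _QUAL_TOKENS[rng.integers(len(_QUAL_TOKENS))]
                value_text = f"{tok}{'' if tok in '<>' else ' '}{value_text}"

    prefix = _PREFIXES[rng.integers(len(_PREFIXES))]
    tags["prefix"] = "mp_phrase" if prefix == "melting point" else "mp_abbrev"
    text = f"{prefix} {value_text}"
    from_lit = rng.random() < cfg.from_literature_rate
    if from_lit:
        text = "lit. " + text
    tags["from_literature"] = "yes" if from_lit else "no"

    if outcome is Outcome.DECOMPOSE:
        text += " " + rng.choice(["decomp.", "with decomposition", "dec."])
    elif outcome is Outcome.SUBLIME:
        text += " subl."
    tags["outcome"] = outcome.value
    tags["qualifier"] = qualifier.value

    truth = NormalizedMP(
        low_c=low, high_c=high, qualifier=qualifier, outcome=outcome,
        suspicious=bool(_suspicious_reasons(low, high)),
        suspicious_reasons=_suspicious_reasons(low, high),
        raw_text=text,
    )
    return text, truth, tags


def generate_corpus(
    cfg: CorpusConfig,
) -> Tuple[List[AnnotatedDocument], List[TruthRecord]]:
    """Patent-style experimental sections with ground-truth MP associations.

    One document per section: a heading naming the product (entity with
    SMILES), a synthesis paragraph mentioning a reagent (distractor
    entity), and a characterization paragraph carrying the declaration
    either explicitly in a bracket after the product name or implicitly at
    the end of the section.
    """
    rng = np.random.default_rng(cfg.seed)
    family = molecule_family()
    docs: List[AnnotatedDocument] = []
    truths: List[TruthRecord] = []
    for i in range(cfg.n_sections):
        doc_id = f"US-SYN-{cfg.seed}-{i:05d}"
        product = family[int(rng.integers(len(family)))]
        reagent = family[int(rng.integers(len(family)))]
        name = f"compound {i + 1}"
        mp_text, truth_mp, tags = _render_declaration(rng, cfg)
        explicit = rng.random() < cfg.explicit_fraction
        tags["association"] = "explicit" if explicit else "implicit"

        heading_text = f"Example {i + 1}. Synthesis of {name}"
        h_start = heading_text.index(name)
        heading = Block(kind="heading", text=heading_text)

        p1_text = (f"A solution of the starting material ({reagent}, 2.0 g) "
                   "in tetrahydrofuran was treated with base and heated "
                   "under reflux for 3 h.")
        r_start = p1_text.index(reagent)
        p1 = Block(kind="paragraph", text=p1_text, paragraph_number=1)

        if explicit:
            p2_text = (f"Recrystallization from ethanol afforded {name} "
                       f"({mp_text}) as a colorless solid.")
            e_start = p2_text.index(name)
            entity2 = Entity(block_index=2, char_span=(e_start,
                             e_start + len(name)), label=name, smiles=product)
        else:
            p2_text = ("The residue was purified by column chromatography "
                       f"to afford the title compound. {mp_text}.")
            entity2 = None
        p2 = Block(kind="paragraph", text=p2_text, paragraph_number=2)

        entities = [
            Entity(block_index=0, char_span=(h_start, h_start + len(name)),
                   label=name, smiles=product),
            Entity(block_index=1, char_span=(r_start, r_start + len(reagent)),
                   label="starting material", smiles=reagent),
        ]
        if entity2 is not None:
            entities.append(entity2)

        docs.append(AnnotatedDocument(doc_id=doc_id,
                                      blocks=[heading, p1, p2],
                                      entities=entities))
        truths.append(TruthRecord(
            record=CompoundMPRecord(
                smiles=product, mp=truth_mp, doc_id=doc_id,
                paragraph_number=2,
                association_kind=tags["association"]),
            tags=tags,
        ))
    return docs, truths


# ---------------------------------------------------------------------------
# QSPR table generation
# ---------------------------------------------------------------------------

def _decomp_weight(smiles: str) -> float:
    # acids and amines decompose preferentially (they do in the real data)
    w = 1.0
    if "C(=O)O" in smiles or "OC(=O)" in smiles:
        w += 6.0
    if "N" in smiles.replace("#N", ""):
        w += 3.0
    return w


def generate_qspr(cfg: QSPRConfig) -> pd.DataFrame:
    """Structure–property table with truth columns.

    One row per measurement; columns: ``molecule_id``, ``smiles``,
    ``mp_true``, ``mp_observed``, ``outcome`` (melt/decompose),
    ``is_outlier``, ``measurement_index``.  Duplicates re-observe the same
    latent value with fresh noise; outliers are offset by
    ``outlier_offset_sigma * sigma_noise`` with random sign; decomposing
    molecules have their latent value shifted by ``decomp_median_shift``
    and are sampled preferentially among acid/amine structures.
    """
    rng = np.random.default_rng(cfg.seed)
    family = molecule_family()
    if cfg.n_molecules > len(family):
        raise ValueError(
            f"family holds {len(family)} distinct molecules; "
            f"requested {cfg.n_molecules}")
    chosen = rng.choice(len(family), size=cfg.n_molecules, replace=False)
    smiles = [family[j] for j in sorted(chosen)]

    n_decomp = int(round(cfg.decomp_fraction * cfg.n_molecules))
    weights = np.array([_decomp_weight(s) for s in smiles])
    decomp_idx = set(rng.choice(cfg.n_molecules, size=n_decomp,
                                replace=False,
                                p=weights / weights.sum()).tolist())

    rows = []
    for i, smi in enumerate(smiles):
        true = latent_mp(smi)
        outcome = "melt"
        if i in decomp_idx:
            outcome = "decompose"
            true += cfg.decomp_median_shift
        n_meas = 1 + int(rng.random() < cfg.duplicate_rate)
        for j in range(n_meas):
            obs = true + rng.normal(0.0, cfg.sigma_noise)
            is_outlier = rng.random() < cfg.outlier_rate
            if is_outlier:
                obs += (cfg.outlier_offset_sigma * cfg.sigma_noise
                        * rng.choice([-1.0, 1.0]))
            rows.append({"molecule_id": i, "smiles": smi, "mp_true": true,
                         "mp_observed": obs, "outcome": outcome,
                         "is_outlier": is_outlier, "measurement_index": j})
    return pd.DataFrame(rows)
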