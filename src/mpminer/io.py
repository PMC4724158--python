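"""Serialization of compound/melting-point records.

Associations are serialized to SDF with one record per association and a
fixed set of property fields; curated datasets round-trip through the same
fields.  JSON-lines output mirrors the parser's view of a document.
"""

from __future__ import annotations

import json
from typing import Iterable, List, Optional

from rdkit import Chem
from rdkit import RDLogger

from .association import CompoundMPRecord
from .grammar import NormalizedMP, Outcome, Qualifier, SuspiciousReason

RDLogger.DisableLog("rdApp.*")

__all__ = ["write_sdf", "read_sdf", "mention_to_jsonl", "write_jsonl"]

SDF_FIELDS = ("MP_RAW", "MP_LOW_C", "MP_HIGH_C", "OUTCOME", "QUALIFIER",
              "SUSPICIOUS", "PATENT_ID", "PARAGRAPH_NUM")


def write_sdf(records: Iterable[CompoundMPRecord], path: str) -> int:
    """Write one SDF entry per association; returns the number written.

    Records whose SMILES does not parse are skipped (they cannot carry a
    connection table).
    """
    n = 0
    with Chem.SDWriter(path) as writer:
        for rec in records:
            mol = Chem.MolFromSmiles(rec.smiles)
            if mol is None:
                continue
            mol.SetProp("MP_RAW", rec.mp.raw_text)
            mol.SetProp("MP_LOW_C", repr(rec.mp.low_c))
            mol.SetProp("MP_HIGH_C", repr(rec.mp.high_c))
            mol.SetProp("OUTCOME", rec.mp.outcome.value)
            mol.SetProp("QUALIFIER", rec.mp.qualifier.value)
            mol.SetProp("SUSPICIOUS", "1" if rec.mp.suspicious else "0")
            if rec.mp.suspicious:
                mol.SetProp("SUSPICIOUS_REASONS", ",".join(
                    sorted(r.value for r in rec.mp.suspicious_reasons)))
            mol.SetProp("PATENT_ID", rec.doc_id)
            if rec.paragraph_number is not None:
                mol.SetProp("PARAGRAPH_NUM", str(rec.paragraph_number))
            mol.SetProp("ASSOCIATION", rec.association_kind)
            writer.write(mol)
            n += 1
    return n


def read_sdf(path: str) -> List[CompoundMPRecord]:
    """Read associations back from SDF written by :func:`write_sdf`."""
    records: List[CompoundMPRecord] = []
    for mol in Chem.SDMolSupplier(path, sanitize=True):
        if mol is None:
            continue
        reasons = frozenset(
            SuspiciousReason(r)
            for r in mol.GetProp("SUSPICIOUS_REASONS").split(",")
        ) if mol.HasProp("SUSPICIOUS_REASONS") else frozenset()
        mp = NormalizedMP(
            low_c=float(mol.GetProp("MP_LOW_C")),
            high_c=float(mol.GetProp("MP_HIGH_C")),
            qualifier=Qualifier(mol.GetProp("QUALIFIER")),
            outcome=Outcome(mol.GetProp("OUTCOME")),
            suspicious=mol.GetProp("SUSPICIOUS") == "1",
            suspicious_reasons=reasons,
            raw_text=mol.GetProp("MP_RAW") if mol.HasProp("MP_RAW") else "",
        )
        para: Optional[int] = (int(mol.GetProp("PARAGRAPH_NUM"))
                               if mol.HasProp("PARAGRAPH_NUM") else None)
        records.append(CompoundMPRecord(
            smiles=Chem.MolToSmiles(mol),
            mp=mp,
            doc_id=mol.GetProp("PATENT_ID") if mol.HasProp("PATENT_ID") else "",
            paragraph_number=para,
            association_kind=(mol.GetProp("ASSOCIATION")
                              if mol.HasProp("ASSOCIATION") else "explicit"),
        ))
    return records


def mention_to_jsonl(n: NormalizedMP, span) -> str:
    return json.dumps({
        "raw_text": n.raw_text,
        "span": list(span),
        "low_c": n.low_c,
        "high_c": n.high_c,
        "qualifier": n.qualifier.value,
        "outcome": n.outcome.value,
        "suspicious": n.suspicious,
        "suspicious_reasons": sorted(r.value for r in n.suspicious_reasons),
    })


def write_jsonl(lines: Iterable[str], path: str) -> None:
    with open(path, "w") as fh:
        for line in lines:
            fh.write(line + "\n")
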