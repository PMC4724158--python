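import math

import numpy as np
import pytest
from rdkit import Chem

from mpminer.accuracy import estimate_sigma
from mpminer.association import extract_records
from mpminer.curation import deduplicate, pairwise_differences
from mpminer.grammar import SuspiciousReason
from mpminer.synthetic import (
    CorpusConfig,
    QSPRConfig,
    generate_corpus,
    generate_qspr,
    molecule_family,
)


def _records_match(rec, truth):
    t = truth.record
    return (rec.smiles == t.smiles
            and rec.mp.low_c == t.mp.low_c
            and rec.mp.high_c == t.mp.high_c
            and rec.mp.qualifier == t.mp.qualifier
            and rec.mp.outcome == t.mp.outcome
            and rec.mp.suspicious == t.mp.suspicious
            and rec.mp.suspicious_reasons == t.mp.suspicious_reasons
            and rec.doc_id == t.doc_id
            and rec.paragraph_number == t.paragraph_number
            and rec.association_kind == t.association_kind)


class TestMoleculeFamily:
    def test_all_members_parse_as_single_components(self):
        fam = molecule_family()
        assert len(fam) > 5000
        sample = fam[:: max(1, len(fam) // 300)]
        for s in sample:
            mol = Chem.MolFromSmiles(s)
            assert mol is not None
            assert len(Chem.GetMolFrags(mol)) == 1

    def test_family_is_deterministic(self):
        assert molecule_family() == molecule_family()


class TestCorpus:
    def test_deterministic_given_seed(self):
        a_docs, a_truth = generate_corpus(CorpusConfig(n_sections=20, seed=5))
        b_docs, b_truth = generate_corpus(CorpusConfig(n_sections=20, seed=5))
        assert [d.to_json() for d in a_docs] == [d.to_json() for d in b_docs]
        assert [t.record for t in a_truth] == [t.record for t in b_truth]

    def test_canonical_corpus_recovered_exactly(self):
        docs, truths = generate_corpus(CorpusConfig(n_sections=150, seed=1))
        for doc, truth in zip(docs, truths):
            records, left = extract_records(doc)
            assert len(records) == 1 and not left, doc.doc_id
            assert _records_match(records[0], truth), (
                doc.blocks[2].text, records[0], truth.record)

    def test_grammar_production_coverage(self):
        _, truths = generate_corpus(CorpusConfig(n_sections=400, seed=2))
        tags = [t.tags for t in truths]
        assert {t["value_kind"] for t in tags} == {"single", "range", "error"}
        assert {t["prefix"] for t in tags} == {"mp_abbrev", "mp_phrase"}
        assert {t["unit"] for t in tags} == {"celsius", "fahrenheit"}
        assert "yes" in {t["spelled"] for t in tags}
        assert "yes" in {t["from_literature"] for t in tags}
        assert {t["outcome"] for t in tags} >= {"melt", "decompose"}
        assert {t["association"] for t in tags} == {"explicit", "implicit"}
        assert len({t["qualifier"] for t in tags}) > 1

    @pytest.mark.parametrize("typo", ["comma_decimal", "truncated_range"])
    def test_repairable_typos_still_recover_truth(self, typo):
        cfg = CorpusConfig(n_sections=60, seed=3, typo_rates={typo: 1.0})
        docs, truths = generate_corpus(cfg)
        assert all(t.tags["typo"] == typo for t in truths)
        for doc, truth in zip(docs, truths):
            records, _ = extract_records(doc)
            assert len(records) == 1
            assert _records_match(records[0], truth)
            assert not records[0].mp.suspicious

    @pytest.mark.parametrize("typo, reason", [
        ("inverted_range", SuspiciousReason.INVERTED_RANGE),
        ("huge_value", SuspiciousReason.ABOVE_500),
        ("missing_decimal", SuspiciousReason.ABOVE_500),
    ])
    def test_unrepairable_typos_are_flagged(self, typo, reason):
        cfg = CorpusConfig(n_sections=60, seed=4, typo_rates={typo: 1.0})
        docs, truths = generate_corpus(cfg)
        for doc, truth in zip(docs, truths):
            records, _ = extract_records(doc)
            assert len(records) == 1
            rec = records[0]
            assert rec.mp.suspicious
            assert reason in rec.mp.suspicious_reasons
            assert _records_match(rec, truth)


class TestQSPR:
    def test_deterministic_given_seed(self):
        a = generate_qspr(QSPRConfig(n_molecules=100, seed=6))
        b = generate_qspr(QSPRConfig(n_molecules=100, seed=6))
        assert a.equals(b)

    def test_requested_sizes_and_truth_columns(self):
        df = generate_qspr(QSPRConfig(n_molecules=500, duplicate_rate=0.0,
                                      outlier_rate=0.1, seed=7))
        assert df.molecule_id.nunique() == 500
        assert set(df.columns) >= {"smiles", "mp_true", "mp_observed",
                                   "outcome", "is_outlier"}
        # outliers are offset by ~5 sigma from truth
        out = df[df.is_outlier]
        assert len(out) > 20
        assert (abs(out.mp_observed - out.mp_true) > 2 * 35.0).all()

    def test_decomposing_minority_with_shifted_median(self):
        df = generate_qspr(QSPRConfig(n_molecules=2000, seed=8))
        per_mol = df.drop_duplicates("molecule_id")
        frac = (per_mol.outcome == "decompose").mean()
        assert frac == pytest.approx(0.055, abs=0.005)
        shift = (per_mol[per_mol.outcome == "decompose"].mp_true.median()
                 - per_mol[per_mol.outcome == "melt"].mp_true.median())
        assert 40.0 <= shift <= 80.0

    def test_accuracy_module_recovers_generating_sigma(self):
        from mpminer.association import CompoundMPRecord
        from mpminer.grammar import NormalizedMP

        df = generate_qspr(QSPRConfig(n_molecules=5000, sigma_noise=35.0,
                                      duplicate_rate=0.5, outlier_rate=0.0,
                                      seed=9))
        records = [
            CompoundMPRecord(smiles=r.smiles,
                             mp=NormalizedMP(low_c=r.mp_observed,
                                             high_c=r.mp_observed),
                             doc_id=str(i), paragraph_number=None,
                             association_kind="explicit")
            for i, r in enumerate(df.itertuples())]
        ds = deduplicate(records, delta_t=0.0)
        diffs = pairwise_differences(ds.groups)
        assert len(diffs) > 1000
        assert estimate_sigma(diffs) == pytest.approx(35.0, abs=2.0)

    def test_oversized_request_rejected(self):
        with pytest.raises(ValueError):
            generate_qspr(QSPRConfig(n_molecules=10 ** 6))
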