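import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from rdkit import Chem

from orthopred.curation import (
    CurationConfig,
    UnitError,
    compound_record,
    from_pchembl,
    resolve_conflicting_labels,
    select_actives,
    standardize_structure,
    structure_filter,
    to_pchembl,
)


class TestToPchembl:
    @pytest.mark.parametrize(
        "value, units, expected",
        [
            (10, "uM", 5.0),           # the 10 µM activity cutoff
            (1, "nM", 9.0),
            (50, "nM", -math.log10(5e-8)),
            (1, "M", 0.0) if False else (1000, "uM", 3.0),
        ],
    )
    def test_examples(self, value, units, expected):
        assert to_pchembl(value, units) == pytest.approx(expected, abs=1e-9)

    def test_rejects_nonpositive_and_unknown_units(self):
        with pytest.raises(ValueError):
            to_pchembl(0, "nM")
        with pytest.raises(UnitError, match="percent"):
            to_pchembl(50, "percent")

    @given(st.floats(min_value=1e-3, max_value=1e6),
           st.sampled_from(["nM", "uM", "M", "mM", "pM"]))
    def test_roundtrip_identity(self, value, units):
        back = from_pchembl(to_pchembl(value, units), units)
        assert back == pytest.approx(value, rel=1e-9)


class TestStandardize:
    def test_salt_keeps_largest_fragment_and_neutralizes(self):
        std, reason = standardize_structure("c1ccccc1C(=O)[O-].[Na+]")
        assert reason is None
        assert std == Chem.CanonSmiles("OC(=O)c1ccccc1")

    def test_unparseable_rejected_with_reason(self):
        std, reason = standardize_structure("not_a_smiles")
        assert std is None and "unparseable" in reason

    def test_idempotent_on_library(self, library):
        for smi in library["smiles"].head(60):
            once, _ = standardize_structure(smi)
            twice, _ = standardize_structure(once)
            assert twice == once


def _oracle_filter(smiles: str, config: CurationConfig) -> bool:
    """Independent atom-scan: explicit loops over atoms and masses."""
    mol = Chem.MolFromSmiles(smiles)
    zs = [a.GetAtomicNum() for a in mol.GetAtoms()]
    if config.require_carbon and 6 not in zs:
        return False
    for z in zs:
        if 21 <= z <= 32 or 36 <= z <= 52 or z >= 54:
            return False
    mw = sum(a.GetMass() for a in mol.GetAtoms()) + 1.008 * sum(
        a.GetTotalNumHs() for a in mol.GetAtoms()
    )
    return config.mw_min <= mw <= config.mw_max


class TestStructureFilter:
    def test_weight_rule_rejects_ethanol(self):
        passed, reason = structure_filter(compound_record("x", "CCO"))
        assert not passed and "weight" in reason

    def test_element_rule_forbids_first_transition_row(self):
        # ferrocene-like organometallic: iron (Z=26) is in the 21-32 window
        passed, reason = structure_filter(
            compound_record("fe", "[Fe].c1ccccc1CCCCCC")
        )
        assert passed is False and "Z=26" in reason

    def test_iodine_allowed(self):
        # iodobenzene: Z=53 sits between the forbidden windows, MW ≈ 204
        passed, reason = structure_filter(compound_record("i", "Ic1ccccc1"))
        assert passed and reason is None

    def test_matches_bruteforce_oracle_on_library(self, library):
        config = CurationConfig()
        extra = ["CCO", "Ic1ccccc1", "O=S(=O)(O)O", "[Fe]", "C" * 80]
        for smi in list(library["smiles"]) + extra:
            rec = compound_record("x", smi)
            got, _ = structure_filter(rec, config)
            assert got == _oracle_filter(smi, config), smi


def _record(**kw):
    base = dict(compound_id="c1", smiles="CCO", target_accession="P1",
                species="human", pchembl=6.0, standard_type="IC50",
                standard_units="nM", assay_type="binding", confidence=8,
                activity_comment=None, label="unknown", record_date="2010-01-01",
                source="chembl-like")
    base.update(kw)
    return base


class TestSelectActives:
    def test_threshold_and_comment_rules(self):
        df = pd.DataFrame([
            _record(compound_id="a", smiles="C1", pchembl=5.0, confidence=6),
            _record(compound_id="b", smiles="C2", pchembl=4.99, confidence=9),
            _record(compound_id="c", smiles="C3", pchembl=None, confidence=7,
                    activity_comment="active"),
            _record(compound_id="d", smiles="C4", pchembl=7.0, confidence=5),
            _record(compound_id="e", smiles="C5", pchembl=7.0, assay_type="other"),
            _record(compound_id="f", smiles="C6", pchembl=7.0,
                    target_accession=""),
        ])
        kept, rejected = select_actives(df)
        assert sorted(kept["compound_id"]) == ["a", "c"]
        reasons = dict(zip(rejected["compound_id"], rejected["reason"]))
        assert "pchembl" in reasons["b"]
        assert "confidence" in reasons["d"]
        assert "assay" in reasons["e"]
        assert "target" in reasons["f"]

    def test_duplicates_collapse_to_earliest_date(self):
        df = pd.DataFrame([
            _record(compound_id="late", record_date="2014-05-01"),
            _record(compound_id="early", record_date="2006-02-01"),
            _record(compound_id="undated", record_date=None),
        ])
        kept, _ = select_actives(df)
        assert list(kept["compound_id"]) == ["early"]

    def test_row_order_invariance(self, rng):
        rows = [
            _record(compound_id=f"c{i}", smiles=f"S{i % 7}",
                    record_date=f"20{10 + i % 5}-01-0{1 + i % 9}")
            for i in range(30)
        ]
        df = pd.DataFrame(rows)
        kept1, _ = select_actives(df)
        shuffled = df.iloc[rng.permutation(len(df))].reset_index(drop=True)
        kept2, _ = select_actives(shuffled)
        key = ["smiles", "compound_id"]
        assert kept1.sort_values(key)[key].values.tolist() == \
            kept2.sort_values(key)[key].values.tolist()


class TestResolveConflicts:
    def test_active_wins_and_counts(self):
        act = pd.DataFrame([_record(compound_id="a", smiles="CC", label="active")])
        inact = pd.DataFrame([
            _record(compound_id="p1", smiles="CC", label="inactive",
                    source="pubchem-like"),
            _record(compound_id="p2", smiles="CCC", label="inactive",
                    source="pubchem-like"),
        ])
        merged, n = resolve_conflicting_labels(act, inact)
        assert n == 1
        assert sorted(merged["compound_id"]) == ["a", "p2"]

    def test_disjoint_union_zero_conflicts(self):
        act = pd.DataFrame([_record(compound_id="a", smiles="CC")])
        inact = pd.DataFrame([_record(compound_id="b", smiles="CCC",
                                      label="inactive")])
        merged, n = resolve_conflicting_labels(act, inact)
        assert n == 0 and len(merged) == 2

    def test_planted_conflicts_match_bruteforce(self, rng):
        smiles = [f"S{i}" for i in range(40)]
        act = pd.DataFrame([_record(compound_id=f"a{i}", smiles=s,
                                    target_accession=f"T{i % 5}")
                            for i, s in enumerate(smiles[:25])])
        inact = pd.DataFrame([_record(compound_id=f"i{i}", smiles=s,
                                      target_accession=f"T{i % 5}",
                                      label="inactive")
                              for i, s in enumerate(smiles[10:])])
        expected = len(
            {(r.smiles, r.target_accession) for r in act.itertuples()}
            & {(r.smiles, r.target_accession) for r in inact.itertuples()}
        )
        _, n = resolve_conflicting_labels(act, inact)
        assert n == expected
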