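import numpy as np
import pandas as pd
import pytest

from orthopred.orthomap import (
    ConflictReport,
    OrthologueMapping,
    TrainingSet,
    apply_min_actives,
    concordance_analysis,
    conflict_analysis,
    coverage_summary,
    merge_orthologue_actives,
    prot_change_binning,
)


def _members(ids_smiles, provenance="human"):
    return pd.DataFrame({
        "compound_id": [i for i, _ in ids_smiles],
        "smiles": [s for _, s in ids_smiles],
        "provenance": provenance,
    })


def _ortho_records(rows):
    return pd.DataFrame([
        {"compound_id": c, "smiles": s, "target_accession": acc,
         "species": sp, "label": "active"}
        for c, s, acc, sp in rows
    ])


MAP = OrthologueMapping("G1", "P1", "Q1", "rat", prot_change=0.1)


class TestMapping:
    def test_rejects_self_mapping_and_bad_ratio(self):
        with pytest.raises(ValueError):
            OrthologueMapping("G", "P1", "P1", "rat")
        with pytest.raises(ValueError):
            OrthologueMapping("G", "P1", "Q1", "rat", prot_change=1.5)

    def test_training_set_invariants(self):
        with pytest.raises(ValueError, match="duplicate"):
            TrainingSet("P1", _members([("a", "CC"), ("b", "CC")]))
        with pytest.raises(ValueError, match="active and inactive"):
            TrainingSet("P1", _members([("a", "CC")]),
                        _members([("b", "CC")], "measured"))


class TestMerge:
    def test_empty_orthologue_table_is_identity(self):
        sets = {"P1": TrainingSet("P1", _members([("a", "CC")]))}
        merged, log = merge_orthologue_actives(sets, _ortho_records([]), [MAP])
        assert merged["P1"].n_actives == 1
        assert len(log) == 0

    def test_duplicate_smiles_keeps_human_copy(self):
        sets = {"P1": TrainingSet("P1", _members([("h1", "CC")]))}
        ortho = _ortho_records([
            ("o1", "CC", "Q1", "rat"),      # duplicate of human structure
            ("o2", "CCC", "Q1", "rat"),
            ("o3", "CCCC", "Q1", "rat"),
        ])
        merged, log = merge_orthologue_actives(sets, ortho, [MAP])
        ts = merged["P1"]
        assert ts.n_actives == 3
        assert ts.n_orthologue_actives == 2
        prov = dict(zip(ts.actives["smiles"], ts.actives["provenance"]))
        assert prov["CC"] == "human"
        assert log.set_index("target_accession").loc["P1", "duplicates"] == 1

    def test_orphan_accession_skipped_and_logged(self):
        sets = {"P1": TrainingSet("P1", _members([("a", "CC")]))}
        ortho = _ortho_records([("o1", "CCC", "QX", "rat")])
        merged, log = merge_orthologue_actives(sets, ortho, [MAP])
        assert merged["P1"].n_actives == 1
        assert log.attrs["n_orphans"] == 1

    def test_set_difference_oracle(self, rng):
        human_smiles = [f"H{i}" for i in range(10)]
        ortho_smiles = [f"H{i}" for i in range(4)] + [f"O{i}" for i in range(7)]
        sets = {"P1": TrainingSet(
            "P1", _members([(f"h{i}", s) for i, s in enumerate(human_smiles)]))}
        ortho = _ortho_records([(f"o{i}", s, "Q1", "rat")
                                for i, s in enumerate(ortho_smiles)])
        merged, _ = merge_orthologue_actives(sets, ortho, [MAP])
        expected = len(set(human_smiles) | set(ortho_smiles))
        assert merged["P1"].n_actives == expected


class TestMinActives:
    @pytest.mark.parametrize("n, kept", [(9, False), (10, True)])
    def test_threshold(self, n, kept):
        sets = {"P1": TrainingSet(
            "P1", _members([(f"a{i}", f"S{i}") for i in range(n)]))}
        retained, _ = apply_min_actives(sets, 10)
        assert ("P1" in retained) is kept

    def test_newly_enabled_flag(self):
        mixed = _members([(f"h{i}", f"S{i}") for i in range(6)])
        mixed = pd.concat([mixed, _members(
            [(f"o{i}", f"T{i}") for i in range(4)], "orthologue:rat")],
            ignore_index=True)
        all_human = _members([(f"h{i}", f"S{i}") for i in range(10)])
        sets = {"P1": TrainingSet("P1", mixed),
                "P2": TrainingSet("P2", all_human)}
        retained, enabled = apply_min_actives(sets, 10)
        assert set(retained) == {"P1", "P2"}
        assert enabled == ["P1"]


class TestCoverage:
    def test_identity_gives_zero_change(self):
        sets = {f"P{i}": TrainingSet(
            f"P{i}", _members([(f"a{i}", f"S{i}")])) for i in range(5)}
        out = coverage_summary(sets, sets, {f"P{i}": "kinase" for i in range(5)})
        assert (out["pct_change"] == 0.0).all()

    def test_toy_arithmetic(self):
        def mk(accs):
            return {a: TrainingSet(a, _members([(a, a)])) for a in accs}
        before = mk([f"A{i}" for i in range(10)] + [f"B{i}" for i in range(5)])
        after = mk([f"A{i}" for i in range(11)] + [f"B{i}" for i in range(5)])
        classes = {a: a[0] for a in after}
        out = coverage_summary(before, after, classes).set_index("target_class")
        assert out.loc["A", "pct_change"] == pytest.approx(10.0)
        assert out.loc["B", "pct_change"] == pytest.approx(0.0)

    def test_share_with_orthologue_additions(self):
        sets = {}
        for i in range(100):
            prov = "orthologue:rat" if i < 56 else "human"
            sets[f"P{i}"] = TrainingSet(f"P{i}", _members([(f"a{i}", f"S{i}")], prov))
        out = coverage_summary(sets, sets, {})
        assert out.attrs["share_with_orthologues"] == pytest.approx(56.0)


def _mk_mappings(n):
    return [OrthologueMapping(f"G{i}", f"P{i}", f"Q{i}", "rat") for i in range(n)]


class TestConflicts:
    def test_disjoint_sets_fully_compatible(self):
        maps = _mk_mappings(2)
        act = _ortho_records([("o1", "A", "Q0", "rat"), ("o2", "B", "Q1", "rat")])
        inact = pd.DataFrame([{"compound_id": "i1", "smiles": "C",
                               "target_accession": "P0", "label": "inactive"}])
        rep = conflict_analysis(act, inact, maps)
        assert rep.n_conflicting == 0
        assert rep.compatibility_pct == 100.0
        assert rep.pair_conflict_free_pct == 100.0

    def test_planted_conflicts_match_bruteforce_join(self, rng):
        maps = _mk_mappings(5)
        act_rows, inact_rows = [], []
        for m in range(5):
            for i in range(40):
                act_rows.append((f"o{m}_{i}", f"S{m}_{i}", f"Q{m}", "rat"))
            for i in rng.choice(40, size=rng.integers(0, 10), replace=False):
                inact_rows.append({"compound_id": f"i{m}_{i}",
                                   "smiles": f"S{m}_{i}",
                                   "target_accession": f"P{m}",
                                   "label": "inactive"})
        act = _ortho_records(act_rows)
        inact = pd.DataFrame(inact_rows)
        rep = conflict_analysis(act, inact, maps)
        # brute-force pairwise smiles join
        expected = 0
        for m in maps:
            a = {r["smiles"] for _, r in act.iterrows()
                 if r["target_accession"] == m.orthologue_accession}
            b = {r["smiles"] for _, r in inact.iterrows()
                 if r["target_accession"] == m.human_accession}
            expected += len(a & b)
        assert rep.n_conflicting == expected
        assert rep.n_mapped == 200

    def test_row_permutation_invariance(self, rng):
        maps = _mk_mappings(3)
        act = _ortho_records([(f"o{i}", f"S{i % 10}", f"Q{i % 3}", "rat")
                              for i in range(30)])
        inact = pd.DataFrame([{"compound_id": f"i{i}", "smiles": f"S{i}",
                               "target_accession": f"P{i % 3}",
                               "label": "inactive"} for i in range(10)])
        rep1 = conflict_analysis(act, inact, maps)
        act2 = act.iloc[rng.permutation(len(act))].reset_index(drop=True)
        rep2 = conflict_analysis(act2, inact, maps)
        assert rep1.n_conflicting == rep2.n_conflicting
        assert rep1.compatibility_pct == rep2.compatibility_pct

    def test_summary_from_printed_counts(self):
        rep = ConflictReport.from_counts(2291, 85)
        assert rep.conflict_pct == pytest.approx(100 * 85 / 2291)

    def test_report_validates_counts(self):
        with pytest.raises(ValueError):
            ConflictReport.from_counts(10, 11)


class TestConcordance:
    def test_identical_values(self):
        paired = pd.DataFrame({
            "human_pchembl": [5.5, 6.5, 7.5, 8.0],
            "ortho_pchembl": [5.5, 6.5, 7.5, 8.0],
            "standard_units": "nM", "standard_type": "Ki",
            "assay_type": "binding",
        })
        rep = concordance_analysis(paired)
        assert rep.r_squared == pytest.approx(1.0)
        assert rep.median_abs_discordance == 0.0
        assert rep.frac_both_active == 1.0

    def test_closed_form_pearson(self):
        paired = pd.DataFrame({"human_pchembl": [5.0, 6.0, 7.0],
                               "ortho_pchembl": [7.0, 6.0, 5.0]})
        rep = concordance_analysis(paired)
        x, y = np.array([5.0, 6.0, 7.0]), np.array([7.0, 6.0, 5.0])
        r = (np.mean(x * y) - x.mean() * y.mean()) / (x.std() * y.std())
        assert rep.r_squared == pytest.approx(r ** 2)
        assert rep.r_squared == pytest.approx(1.0)  # perfectly anti-correlated

    def test_small_groups_undefined_not_zero(self):
        paired = pd.DataFrame({
            "human_pchembl": [5.0, 6.0], "ortho_pchembl": [5.1, 6.1],
            "standard_units": "nM", "standard_type": "Ki",
            "assay_type": "binding",
        })
        rep = concordance_analysis(paired)
        assert np.isnan(rep.per_group["r_squared"]).all()

    def test_frac_both_active_monotone_in_cutoff(self, rng):
        paired = pd.DataFrame({
            "human_pchembl": rng.normal(6.5, 1.0, 200),
            "ortho_pchembl": rng.normal(6.5, 1.0, 200),
        })
        fracs = [concordance_analysis(paired, c).frac_both_active
                 for c in (4.0, 5.0, 6.0, 7.0)]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))

    def test_printed_count_summary(self):
        frac = concordance_analysis.__globals__["ConcordanceReport"]
        assert frac.both_active_fraction(20608, 21446) * 100 == pytest.approx(
            96.09, abs=0.005)


class TestProtChangeBinning:
    def _paired(self, pcs, discs):
        return pd.DataFrame({
            "human_accession": [f"P{i}" for i in range(len(pcs))],
            "orthologue_accession": [f"Q{i}" for i in range(len(pcs))],
            "human_pchembl": [6.0] * len(pcs),
            "ortho_pchembl": [6.0 + d for d in discs],
        }), [OrthologueMapping(f"G{i}", f"P{i}", f"Q{i}", "rat", prot_change=pc)
             for i, pc in enumerate(pcs)]

    def test_single_zero_bin(self):
        paired, maps = self._paired([0.0, 0.0, 0.0], [0.0, 0.0, 0.0])
        bins, r2, n_exc = prot_change_binning(paired, maps)
        assert len(bins) == 1 and bins["median_abs_discordance"].iloc[0] == 0.0
        assert n_exc == 0

    def test_planted_bin_medians_recovered(self):
        pcs = [0.05] * 3 + [0.15] * 3
        discs = [0.5, 0.5, 0.5, 1.0, 1.0, 1.0]
        paired, maps = self._paired(pcs, discs)
        bins, _, _ = prot_change_binning(paired, maps)
        assert list(bins["median_abs_discordance"]) == [0.5, 1.0]
        assert list(bins["bin_lo"]) == [0.0, pytest.approx(0.1)]

    def test_constant_discordance_zero_trend(self):
        paired, maps = self._paired([0.05, 0.15, 0.25, 0.35], [0.7] * 4)
        _, r2, _ = prot_change_binning(paired, maps)
        assert r2 == 0.0

    def test_missing_prot_change_excluded_and_counted(self):
        paired, maps = self._paired([0.05, 0.15], [0.5, 0.5])
        maps[1] = OrthologueMapping("G1", "P1", "Q1", "rat", prot_change=None)
        bins, _, n_exc = prot_change_binning(paired, maps)
        assert n_exc == 1 and bins["n_pairs"].sum() == 1
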