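"""Reconciliation: LCA mapping, pair labels, xenologs, Dollo gains/losses."""

import dendropy
import numpy as np
import pandas as pd
import pytest

import m6aevo as m
from m6aevo import (
    EvolParams,
    ProteinRecord,
    build_presence_absence,
    classify_pairs,
    detect_xenologs,
    infer_gains_losses,
    lca_reconcile,
    simulate_family,
    simulate_species_panel,
)
from m6aevo.genetree import set_supports
from m6aevo.trees import node_tipsets, tip_label

from conftest import make_species_tree


def gene_tree(newick: str, support: float = 1.0) -> dendropy.Tree:
    t = dendropy.Tree.get(data=newick, schema="newick")
    set_supports(t, support)
    return t


class TestLcaReconcile:
    def test_congruent_tree_all_speciations(self, abcd_tree):
        gt = gene_tree("((a1,b1),(c1,d1));")
        tip_map = {"a1": "A", "b1": "B", "c1": "C", "d1": "D"}
        recon = lca_reconcile(gt, abcd_tree, tip_map)
        assert recon.duplication_count == 0
        assert recon.speciation_count == 3

    def test_root_duplication_two_copies(self):
        sp = make_species_tree("(A:1,B:1)r;", {"A": "Amorphea", "B": "SAR"})
        gt = gene_tree("((a1,b1),(a2,b2));")
        tip_map = {"a1": "A", "b1": "B", "a2": "A", "b2": "B"}
        recon = lca_reconcile(gt, sp, tip_map)
        assert recon.duplication_count == 1
        assert recon.speciation_count == 2
        assert recon.node_events[gt.seed_node] == "duplication"

    def test_unmapped_tip_errors(self, abcd_tree):
        gt = gene_tree("((a1,b1),c1);")
        with pytest.raises(ValueError):
            lca_reconcile(gt, abcd_tree, {"a1": "A", "b1": "B"})

    def test_invariant_to_tip_order(self, abcd_tree):
        tip_map = {"a1": "A", "b1": "B", "c1": "C", "d1": "D"}
        r1 = lca_reconcile(gene_tree("((a1,b1),(c1,d1));"), abcd_tree, tip_map)
        r2 = lca_reconcile(gene_tree("((d1,c1),(b1,a1));"), abcd_tree, tip_map)
        assert r1.duplication_count == r2.duplication_count
        assert r1.speciation_count == r2.speciation_count


class TestClassifyPairs:
    def test_congruent_tree_all_orthologs(self, abcd_tree):
        gt = gene_tree("((a1,b1),(c1,d1));")
        recon = lca_reconcile(gt, abcd_tree, {"a1": "A", "b1": "B", "c1": "C", "d1": "D"})
        pairs = classify_pairs(recon)
        assert set(pairs["relation"]) == {"ortholog"}
        assert len(pairs) == 6  # C(4,2)

    def test_duplication_separates_paralogs(self):
        sp = make_species_tree("(A:1,B:1)r;", {"A": "Amorphea", "B": "SAR"})
        gt = gene_tree("((a1,b1),(a2,b2));")
        recon = lca_reconcile(gt, sp, {"a1": "A", "b1": "B", "a2": "A", "b2": "B"})
        pairs = classify_pairs(recon).set_index(["tip1", "tip2"])["relation"]
        assert pairs.get(("a1", "b1")) == "ortholog"
        assert pairs.get(("a1", "a2")) == "paralog"

    def test_xenolog_flag_propagates_to_pairs(self, abcd_tree):
        gt = gene_tree("((a1,b1),(c1,d1));")
        recon = lca_reconcile(gt, abcd_tree, {"a1": "A", "b1": "B", "c1": "C", "d1": "D"})
        pairs = classify_pairs(recon, xenolog_tips=["d1"])
        with_d = pairs[(pairs["tip1"] == "d1") | (pairs["tip2"] == "d1")]
        assert set(with_d["relation"]) == {"xenolog"}


class TestDetectXenologs:
    @pytest.fixture
    def mixed_panel(self):
        # Bacteria clade and Amorphea clade are non-sisters (SAR between)
        return make_species_tree(
            "((B1:1,B2:1)n2:1,((S1:1,S2:1)n4:1,(M1:1,(M2:0.5,M3:0.5)n6:0.5)n5:1)n3:1)n1;",
            {
                "B1": "Bacteria", "B2": "Bacteria",
                "S1": "SAR", "S2": "SAR",
                "M1": "Amorphea", "M2": "Amorphea", "M3": "Amorphea",
            },
        )

    def test_foreign_tip_in_supported_clade_called(self, mixed_panel):
        # one Bacteria sequence nested among Amorphea sequences
        gt = gene_tree("(((b1,m2),(m1,m3)),((s1,s2),b2));", support=0.95)
        tip_map = {"b1": "B1", "b2": "B2", "m1": "M1", "m2": "M2", "m3": "M3",
                   "s1": "S1", "s2": "S2"}
        calls = detect_xenologs(gt, mixed_panel, tip_map, support_threshold=0.8)
        assert [c.tip for c in calls] == ["b1"]
        assert calls[0].donor_supergroup == "Amorphea"

    def test_low_support_gates_call(self, mixed_panel):
        gt = gene_tree("(((b1,m2),(m1,m3)),((s1,s2),b2));", support=0.5)
        tip_map = {"b1": "B1", "b2": "B2", "m1": "M1", "m2": "M2", "m3": "M3",
                   "s1": "S1", "s2": "S2"}
        assert detect_xenologs(gt, mixed_panel, tip_map, support_threshold=0.8) == []

    def test_missing_supports_error(self, mixed_panel):
        gt = dendropy.Tree.get(data="(((b1,m2),(m1,m3)),((s1,s2),b2));", schema="newick")
        tip_map = {"b1": "B1", "b2": "B2", "m1": "M1", "m2": "M2", "m3": "M3",
                   "s1": "S1", "s2": "S2"}
        with pytest.raises(ValueError):
            detect_xenologs(gt, mixed_panel, tip_map)

    def test_simulated_transfers_recovered_without_false_positives(self):
        """Noise-free true gene trees: every between-supergroup (non-sister)
        transfer recipient flagged, nothing else."""
        sp = simulate_species_panel(
            {"Bacteria": 4, "Archaea": 4, "SAR": 4, "Amorphea": 4}, seed=3
        )
        clade_parents = sp.supergroup_clade_parents()

        def nonsister(a, b):
            pa, pb = clade_parents[a], clade_parents[b]
            return not (pa is not None and pa is pb)

        def branch_supergroup(label):
            if label in sp.supergroup_of:
                return sp.supergroup_of[label]
            for n in sp.tree.preorder_node_iter():
                if tip_label(n) == label:
                    sgs = {sp.supergroup_of[tip_label(x)] for x in n.leaf_iter()}
                    return sgs.pop() if len(sgs) == 1 else None
            return None

        params = EvolParams(dup_rate=0.1, loss_rate=0.1, transfer_rate=0.05)
        rng = np.random.default_rng(11)
        n_transfers = fp = fn = 0
        for i in range(60):
            fam = simulate_family(sp, params, seed=int(rng.integers(2**31)))
            if fam.gene_tree is None or len(fam.tip_map) < 2:
                continue
            set_supports(fam.gene_tree, 1.0)
            called = {c.tip for c in detect_xenologs(fam.gene_tree, sp, fam.tip_map)}
            expected = set()
            for ev, desc in zip(fam.history.transfers, fam.transfer_descendants):
                dsg = branch_supergroup(ev.branch)
                rsg = branch_supergroup(ev.recipient)
                if dsg and rsg and dsg != rsg and nonsister(dsg, rsg) and desc:
                    expected |= set(desc)
                    n_transfers += 1
            all_desc = (
                set().union(*fam.transfer_descendants)
                if fam.transfer_descendants
                else set()
            )
            fn += len(expected - called)
            fp += len((called - expected) - all_desc)
        assert n_transfers > 0
        assert fn == 0
        assert fp == 0


class TestPresenceAbsence:
    def test_matrix_values(self, abcd_tree):
        retained = {
            "fam1": [ProteinRecord("x1", "A", "MK"), ProteinRecord("x2", "C", "MK")],
            "fam2": [],
        }
        pam = build_presence_absence(retained, abcd_tree, {"fam1": {"C"}})
        assert list(pam.index) == abcd_tree.taxa
        assert pam.loc["A", "fam1"] == 1
        assert pam.loc["C", "fam1"] == 2  # xenolog-present
        assert pam.loc["B", "fam1"] == 0
        assert (pam["fam2"] == 0).all()

    def test_unknown_taxon_errors(self, abcd_tree):
        with pytest.raises(ValueError):
            build_presence_absence(
                {"f": [ProteinRecord("x", "Zzz", "MK")]}, abcd_tree
            )


class TestGainsLosses:
    def test_all_present_gain_at_root(self, abcd_tree):
        pam = pd.DataFrame({"f": [1, 1, 1, 1]}, index=abcd_tree.taxa)
        s = infer_gains_losses(pam, abcd_tree)["f"]
        assert s.gain_branch == "n1"
        assert s.losses == []

    def test_single_absent_tip_is_lineage_specific_loss(self, abcd_tree):
        pam = pd.DataFrame(
            {"f": [1 if t != "D" else 0 for t in abcd_tree.taxa]},
            index=abcd_tree.taxa,
        )
        s = infer_gains_losses(pam, abcd_tree)["f"]
        assert s.gain_branch == "n1"
        assert s.losses == ["D"]

    def test_alternate_absences_two_terminal_losses(self, abcd_tree):
        pam = pd.DataFrame(
            {"f": [1 if t in ("A", "C") else 0 for t in abcd_tree.taxa]},
            index=abcd_tree.taxa,
        )
        s = infer_gains_losses(pam, abcd_tree)["f"]
        assert s.gain_branch == "n1"
        assert sorted(s.losses) == ["B", "D"]

    def test_empty_family_no_gain(self, abcd_tree):
        pam = pd.DataFrame({"f": [0, 0, 0, 0]}, index=abcd_tree.taxa)
        s = infer_gains_losses(pam, abcd_tree)["f"]
        assert s.gain_branch is None
        assert s.losses == []

    def test_xenolog_cells_do_not_drag_gain(self, abcd_tree):
        # native presence only in the (A,B) cherry; a transferred copy in D
        values = {"A": 1, "B": 1, "C": 0, "D": 2}
        pam = pd.DataFrame(
            {"f": [values[t] for t in abcd_tree.taxa]}, index=abcd_tree.taxa
        )
        s = infer_gains_losses(pam, abcd_tree)["f"]
        assert s.gain_branch == "n2"
        assert s.losses == []

    def test_matches_independent_dollo_oracle(self):
        sp = simulate_species_panel({"A": 4, "B": 4, "C": 4}, seed=17)
        tipsets = node_tipsets(sp.tree)
        rng = np.random.default_rng(5)
        for _ in range(100):
            present = {t for t in sp.taxa if rng.random() < 0.5}
            pam = pd.DataFrame(
                {"f": [1 if t in present else 0 for t in sp.taxa]}, index=sp.taxa
            )
            s = infer_gains_losses(pam, sp, max_loss_internal_nodes=10**6)["f"]
            if not present:
                assert s.gain_branch is None
                continue
            gain = min(
                (n for n, ts in tipsets.items() if present <= ts),
                key=lambda n: len(tipsets[n]),
            )
            assert s.gain_branch == (tip_label(gain) or "root")
            # oracle losses: maximal absent subtrees below the gain node
            expected = []
            for node in sp.tree.preorder_node_iter():
                par = node.parent_node
                if par is None or not (tipsets[node] <= tipsets[gain]):
                    continue
                if node is gain:
                    continue
                under_gain = False
                anc = node
                while anc is not None:
                    if anc is gain:
                        under_gain = True
                        break
                    anc = anc.parent_node
                if not under_gain:
                    continue
                if not (tipsets[node] & present) and (tipsets[par] & present):
                    expected.append(tip_label(node))
            assert sorted(s.candidate_losses) == sorted(expected)
            assert set(s.losses) <= set(s.candidate_losses)
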