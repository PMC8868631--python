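"""Ground-truth generators: panels, gene histories, sequences, structures."""

import math

import numpy as np
import pytest

from m6aevo import (
    DEFAULT_PANEL_COUNTS,
    EvolParams,
    default_panel,
    evolve_sequences,
    simulate_family,
    simulate_species_panel,
    simulate_structure_pair,
)
from m6aevo.trees import node_tipsets, splits, tip_label


class TestSpeciesPanel:
    def test_default_panel_composition(self):
        sp = default_panel()
        assert len(sp.taxa) == 88
        counts = {}
        for t, g in sp.supergroup_of.items():
            counts[g] = counts.get(g, 0) + 1
        assert counts == DEFAULT_PANEL_COUNTS

    def test_supergroups_are_clades(self):
        sp = simulate_species_panel({"A": 3, "B": 4, "C": 2}, seed=11)
        tipsets = set(node_tipsets(sp.tree).values())
        for g, n in (("A", 3), ("B", 4), ("C", 2)):
            members = frozenset(t for t, sg in sp.supergroup_of.items() if sg == g)
            assert members in tipsets

    def test_minimal_two_tip_tree(self):
        sp = simulate_species_panel({"A": 1, "B": 1}, seed=0)
        assert sorted(sp.taxa) == ["A_01", "B_01"]

    def test_deterministic_for_seed(self):
        counts = {"A": 3, "B": 5}
        assert (
            simulate_species_panel(counts, seed=4).newick()
            == simulate_species_panel(counts, seed=4).newick()
        )

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            simulate_species_panel({}, seed=1)

    def test_ultrametric(self):
        sp = simulate_species_panel({"A": 4, "B": 4}, seed=3)
        depths = []
        for leaf in sp.tree.leaf_node_iter():
            d, node = 0.0, leaf
            while node.parent_node is not None:
                d += node.edge.length or 0.0
                node = node.parent_node
            depths.append(d)
        assert np.allclose(depths, 1.0)


class TestSimulateFamily:
    def test_no_events_mirrors_species_tree(self):
        sp = simulate_species_panel({"A": 4, "B": 4}, seed=9)
        fam = simulate_family(sp, EvolParams(), seed=1)
        assert len(fam.tip_map) == 8
        gene_splits = {
            frozenset(fam.tip_map[t] for t in s) for s in splits(fam.gene_tree)
        }
        assert gene_splits == splits(sp.tree)
        assert fam.history.count("gain") == 1
        assert fam.history.count("duplication") == 0

    def test_extinction_under_heavy_loss(self):
        sp = simulate_species_panel({"A": 2, "B": 2}, seed=9)
        fam = simulate_family(sp, EvolParams(loss_rate=200.0), seed=2)
        assert fam.gene_tree is None
        assert fam.records == []
        assert fam.history.count("gain") == 1
        assert fam.history.count("loss") >= 1

    def test_exactly_one_gain_always(self):
        sp = simulate_species_panel({"A": 3, "B": 3}, seed=9)
        for seed in range(20):
            fam = simulate_family(
                sp, EvolParams(dup_rate=0.3, loss_rate=0.3, transfer_rate=0.1), seed=seed
            )
            assert fam.history.count("gain") == 1

    def test_birth_death_balance_keeps_mean_copy_number_one(self):
        """With duplication rate = loss rate the expected tip copy number is 1."""
        sp = simulate_species_panel({"A": 4, "B": 4, "C": 4, "D": 4}, seed=16)
        n_tips = 16
        total = 0
        reps = 400
        params = EvolParams(dup_rate=0.1, loss_rate=0.1)
        for seed in range(reps):
            fam = simulate_family(sp, params, seed=seed)
            total += len(fam.tip_map)
        mean = total / (reps * n_tips)
        assert mean == pytest.approx(1.0, abs=0.05)

    def test_copy_number_bookkeeping(self):
        """Copies at a tip = root copies + duplications + incoming transfers
        - losses along its root path."""
        sp = simulate_species_panel({"A": 4, "B": 4, "C": 4, "D": 4}, seed=23)
        # branch label -> path membership
        paths = {}
        for leaf in sp.tree.leaf_node_iter():
            labels = set()
            node = leaf
            while node.parent_node is not None:
                labels.add(tip_label(node))
                node = node.parent_node
            paths[tip_label(leaf)] = labels
        params = EvolParams(dup_rate=0.2, loss_rate=0.2, transfer_rate=0.1)
        for seed in range(30):
            fam = simulate_family(sp, params, seed=seed)
            counts = {t: 0 for t in sp.taxa}
            for taxon in fam.tip_map.values():
                counts[taxon] += 1
            for taxon, path in paths.items():
                expected = 1  # the root gain
                for e in fam.history.events:
                    if e.kind == "duplication" and e.branch in path:
                        expected += 1
                    elif e.kind == "loss" and e.branch in path:
                        expected -= 1
                    elif e.kind == "transfer" and e.recipient in path:
                        expected += 1
                assert counts[taxon] == expected, (taxon, seed)


class TestEvolveSequences:
    def test_rate_zero_identical_sequences(self):
        sp = simulate_species_panel({"A": 3, "B": 3}, seed=1)
        params = EvolParams(subst_rate=0.0, seq_length=100)
        fam = evolve_sequences(simulate_family(sp, params, seed=2), params, seed=3)
        seqs = {r.sequence for r in fam.records}
        assert len(seqs) == 1

    def test_uniform_replacement_closed_form(self):
        """Two tips at path length t: expected differing-site proportion is
        (19/20)(1 - exp(-(20/19) t))."""
        sp = simulate_species_panel({"A": 1, "B": 1}, seed=5)  # path length 2.0
        rate = 0.15
        params = EvolParams(subst_rate=rate, seq_length=6000)
        fam = evolve_sequences(simulate_family(sp, params, seed=6), params, seed=7)
        s1, s2 = (r.sequence for r in fam.records)
        p_hat = sum(a != b for a, b in zip(s1, s2)) / len(s1)
        t = 2.0 * rate
        p_expected = (19 / 20) * (1 - math.exp(-(20 / 19) * t))
        # 3 binomial standard errors at n = 6000
        se = math.sqrt(p_expected * (1 - p_expected) / 6000)
        assert abs(p_hat - p_expected) < 3 * se + 1e-9

    def test_motif_columns_invariant(self):
        sp = simulate_species_panel({"A": 4, "B": 4}, seed=2)
        params = EvolParams(subst_rate=1.0, seq_length=120, motifs=[("DPPW", 50)])
        fam = evolve_sequences(simulate_family(sp, params, seed=3), params, seed=4)
        for r in fam.records:
            assert r.sequence[50:54] == "DPPW"

    def test_length_and_alphabet_conserved(self):
        sp = simulate_species_panel({"A": 3, "B": 2}, seed=8)
        params = EvolParams(subst_rate=0.5, seq_length=80)
        fam = evolve_sequences(simulate_family(sp, params, seed=9), params, seed=10)
        for r in fam.records:
            assert len(r.sequence) == 80
            assert set(r.sequence) <= set("ACDEFGHIKLMNPQRSTVWY")

    def test_motif_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            EvolParams(seq_length=40, motifs=[("DPPW", 38)])


class TestStructurePair:
    def test_rigid_motion_only_superposes_exactly(self):
        from m6aevo import superpose

        a, b = simulate_structure_pair(50, (0.3, 0.8, -0.4), (1, 2, 3), 0.0, seed=1)
        assert superpose(a, b).rmsd == pytest.approx(0.0, abs=1e-9)

    def test_noise_gives_sqrt3_sigma_rmsd(self):
        """Isotropic sigma=1 noise on every coordinate gives RMSD near sqrt(3)."""
        from m6aevo import superpose

        rmsds = []
        for seed in range(20):
            a, b = simulate_structure_pair(500, (0.2, 0.1, 0.5), (0, 0, 0), 1.0, seed=seed)
            rmsds.append(superpose(a, b, reject_sigma=1e9).rmsd)
        assert np.mean(rmsds) == pytest.approx(math.sqrt(3), abs=0.05)

    def test_deterministic_for_seed(self):
        a1, b1 = simulate_structure_pair(30, (0.1, 0.2, 0.3), (1, 1, 1), 0.5, seed=4)
        a2, b2 = simulate_structure_pair(30, (0.1, 0.2, 0.3), (1, 1, 1), 0.5, seed=4)
        assert np.array_equal(a1.coords, a2.coords)
        assert np.array_equal(b1.coords, b2.coords)

    def test_too_few_atoms_rejected(self):
        with pytest.raises(ValueError):
            simulate_structure_pair(2, (0, 0, 0), (0, 0, 0), 0.0, seed=1)
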