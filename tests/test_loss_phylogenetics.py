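"""Dollo loss counting, lesion matching and event dating."""

import itertools

import numpy as np
import pytest

from genedecay.loss_phylogenetics import (
    Chronogram,
    SharedLesionGroup,
    date_events,
    dollo_min_losses,
    match_lesions,
    scenario_totals,
)
from genedecay.synthetic_data import yule_tree


def brute_force_min_losses(chronogram, tip_states):
    """Exhaustive enumeration over all irreversible-loss scenarios.

    Every assignment of retained/lost to the internal nodes is checked
    for irreversibility (no lost parent with a retained child, with a
    retained super-root above the real root) and tip consistency; the
    minimum number of retained->lost edges over valid assignments is the
    Dollo minimum.
    """
    tree = chronogram.tree
    internals = list(tree.preorder_internal_node_iter())
    leaves = list(tree.leaf_node_iter())
    best = None
    for bits in itertools.product([True, False], repeat=len(internals)):
        retained = {id(n): b for n, b in zip(internals, bits)}
        for leaf in leaves:
            retained[id(leaf)] = tip_states[leaf.taxon.label] == "retained"
        ok = True
        losses = 0
        # virtual retained super-root above the real root
        if not retained[id(tree.seed_node)]:
            losses += 1
        for node in tree.preorder_node_iter():
            parent = node.parent_node
            if parent is None:
                continue
            if not retained[id(parent)] and retained[id(node)]:
                ok = False  # regain: forbidden
                break
            if retained[id(parent)] and not retained[id(node)]:
                losses += 1
        if ok and (best is None or losses < best):
            best = losses
    return best


class TestDolloOracle:
    def test_matches_exhaustive_enumeration_on_random_trees(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            n = int(rng.integers(4, 13))
            tree = yule_tree(n, 10.0, rng)
            chrono = Chronogram(tree)
            states = {
                t: ("lost" if rng.random() < 0.5 else "retained")
                for t in chrono.tips()
            }
            got, branches = dollo_min_losses(chrono, states)
            expected = brute_force_min_losses(chrono, states)
            assert got == expected
            assert len(branches) == got

    def test_all_retained_zero_losses(self):
        c = Chronogram.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        n, _ = dollo_min_losses(
            c, {t: "retained" for t in "ABCD"}
        )
        assert n == 0

    def test_all_lost_single_stem_event(self):
        c = Chronogram.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        n, branches = dollo_min_losses(c, {t: "lost" for t in "ABCD"})
        assert n == 1
        assert branches[0].clade == frozenset("ABCD")

    def test_uncertain_tips_excluded_by_default(self):
        c = Chronogram.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        states = {"A": "lost", "B": "uncertain", "C": "retained",
                  "D": "retained"}
        n, branches = dollo_min_losses(c, states)
        assert n == 1
        assert branches[0].clade == frozenset("A")
        # forcing the uncertain tip lost merges the event upward
        n_forced, branches_forced = dollo_min_losses(
            c, states, uncertain="lost"
        )
        assert n_forced == 1
        assert branches_forced[0].clade == frozenset("AB")

    def test_adding_lost_tip_inside_lost_clade_never_increases_count(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            tree = yule_tree(8, 10.0, rng)
            chrono = Chronogram(tree)
            states = {t: "retained" for t in chrono.tips()}
            # lose one full cherry
            node = next(
                n
                for n in tree.postorder_internal_node_iter()
                if len(n.leaf_nodes()) == 2
            )
            pair = [l.taxon.label for l in node.leaf_iter()]
            states[pair[0]] = "lost"
            n_before, _ = dollo_min_losses(chrono, states)
            states[pair[1]] = "lost"
            n_after, _ = dollo_min_losses(chrono, states)
            assert n_after <= n_before

    def test_missing_tip_state_rejected(self):
        c = Chronogram.from_newick("((A:1,B:1):1,C:2);")
        with pytest.raises(ValueError):
            dollo_min_losses(c, {"A": "lost"})


class TestChronogram:
    def test_ages_from_ultrametric_lengths(self):
        c = Chronogram.from_newick("((A:10,B:10):20,C:30);")
        assert c.age(c.mrca({"A", "B"})) == pytest.approx(10.0)
        assert c.age(c.tree.seed_node) == pytest.approx(30.0)

    def test_age_table_overrides(self):
        c = Chronogram.from_newick(
            "((A,B),C);",
            node_ages={
                frozenset({"A", "B"}): 52.0,
                frozenset({"A", "B", "C"}): 70.0,
            },
        )
        assert c.age(c.mrca({"A", "B"})) == 52.0

    def test_child_older_than_parent_rejected(self):
        with pytest.raises(ValueError):
            Chronogram.from_newick(
                "((A,B),C);",
                node_ages={
                    frozenset({"A", "B"}): 80.0,
                    frozenset({"A", "B", "C"}): 70.0,
                },
            )


class TestMatchLesions:
    def test_shared_insertion_grouped_across_clades(self):
        rows = [
            {"species": s, "kind": "frameshift_indel",
             "ref_bp_start": p, "ref_bp_end": p, "allele": "insAATCG"}
            for s, p in [("Canidae", 2000), ("Felidae", 2001),
                         ("Hyaenidae", 1999)]
        ]
        groups = match_lesions(rows)
        assert len(groups) == 1
        assert groups[0].members == ["Canidae", "Felidae", "Hyaenidae"]

    def test_disjoint_coordinates_stay_separate(self):
        rows = [
            {"species": "X", "kind": "inframe_indel",
             "ref_bp_start": 100, "ref_bp_end": 102, "allele": "del3"},
            {"species": "Y", "kind": "inframe_indel",
             "ref_bp_start": 300, "ref_bp_end": 302, "allele": "del3"},
        ]
        groups = match_lesions(rows)
        assert len(groups) == 2
        assert all(g.size == 1 for g in groups)

    def test_different_allele_never_grouped(self):
        rows = [
            {"species": "X", "kind": "frameshift_indel",
             "ref_bp_start": 100, "ref_bp_end": 100, "allele": "insA"},
            {"species": "Y", "kind": "frameshift_indel",
             "ref_bp_start": 100, "ref_bp_end": 100, "allele": "insG"},
        ]
        assert len(match_lesions(rows)) == 2

    def test_synthetic_cohort_grouping_equals_truth(self, rng):
        """Planted shared + private lesions are grouped exactly."""
        shared = {"kind": "frameshift_indel", "ref_bp_start": 500,
                  "ref_bp_end": 500, "allele": "del1"}
        rows = [
            {"species": f"S{i}", **shared} for i in range(4)
        ]
        privates = []
        for i, pos in enumerate(rng.choice(
            np.arange(600, 2000, 10), 6, replace=False
        )):
            row = {"species": f"P{i}", "kind": "premature_stop",
                   "ref_bp_start": int(pos), "ref_bp_end": int(pos) + 2,
                   "allele": f"TAA@{int(pos) // 3}"}
            privates.append(row)
        groups = match_lesions(rows + privates)
        sizes = sorted(g.size for g in groups)
        assert sizes == [1, 1, 1, 1, 1, 1, 4]


class TestDating:
    def _cetartiodactyla(self):
        return Chronogram.from_newick(
            "(((Hippopotamidae:55,Cetacea:55):15,"
            "(Pecora:52,Tragulidae:52):18):10,Suidae:80);"
        )

    def test_ruminantia_window_52_to_70(self):
        c = self._cetartiodactyla()
        states = {"Hippopotamidae": "retained", "Cetacea": "retained",
                  "Pecora": "lost", "Tragulidae": "lost",
                  "Suidae": "retained"}
        n, branches = dollo_min_losses(c, states)
        assert n == 1
        (event,) = date_events(c, dollo_branches=branches)
        assert event.min_age == pytest.approx(52.0)
        assert event.max_age == pytest.approx(70.0)

    def test_singleton_lesion_dates_from_zero(self):
        c = self._cetartiodactyla()
        group = SharedLesionGroup(
            kind="premature_stop", allele="TAA@100",
            ref_bp_start=298, ref_bp_end=300, members=["Pecora"],
        )
        (event,) = date_events(c, groups=[group])
        assert event.min_age == 0.0
        assert event.max_age == pytest.approx(52.0)

    def test_group_spanning_retained_tip_rejected(self):
        c = self._cetartiodactyla()
        group = SharedLesionGroup(
            kind="frameshift_indel", allele="del1",
            ref_bp_start=10, ref_bp_end=10,
            members=["Pecora", "Cetacea"],
        )
        states = {"Hippopotamidae": "retained", "Cetacea": "retained",
                  "Pecora": "lost", "Tragulidae": "lost",
                  "Suidae": "retained"}
        (event,) = date_events(c, groups=[group], tip_states=states)
        assert event.rejected
        assert "homoplasy" in event.diagnostic

    def test_simulated_loss_time_falls_in_interval(self):
        """On simulations the true loss time lies inside [min, max]."""
        from genedecay.synthetic_data import SimulationConfig, simulate

        nwk = "((A:30,B:30):20,(C:30,D:30):20);"
        cfg = SimulationConfig(
            seed=99, newick=nwk, n_codons=150,
            loss_branches=("A|B",), nonsense_rate=1e-3,
        )
        res = simulate(cfg)
        chrono = Chronogram(res.tree)
        n, branches = dollo_min_losses(chrono, res.tip_states())
        assert n == 1
        (event,) = date_events(chrono, dollo_branches=branches)
        loss_row = res.branch_regimes.query("regime == 'loss'").iloc[0]
        # branch A|B runs from age 50 down to age 30
        true_age = 50.0 - loss_row["loss_time_from_branch_start"]
        assert event.min_age <= true_age <= event.max_age

    def test_intervals_always_ordered(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            tree = yule_tree(8, 40.0, rng)
            chrono = Chronogram(tree)
            states = {
                t: ("lost" if rng.random() < 0.4 else "retained")
                for t in chrono.tips()
            }
            _, branches = dollo_min_losses(chrono, states)
            for event in date_events(chrono, dollo_branches=branches):
                assert event.min_age <= event.max_age + 1e-9


class TestScenarioTotals:
    def test_all_clades_fixed_at_one(self):
        assert scenario_totals({c: (1, 1) for c in "abcde"}) == (5, 5)

    def test_sum_equals_exhaustive_enumeration(self, rng):
        for _ in range(20):
            table = {
                f"c{i}": tuple(sorted(rng.integers(0, 4, size=2)))
                for i in range(int(rng.integers(1, 6)))
            }
            lo, hi = scenario_totals(table)
            combos = itertools.product(
                *[range(a, b + 1) for a, b in table.values()]
            )
            sums = [sum(c) for c in combos]
            assert lo == min(sums)
            assert hi == max(sums)

    def test_inverted_range_rejected(self):
        with pytest.raises(ValueError):
            scenario_totals({"a": (2, 1)})
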