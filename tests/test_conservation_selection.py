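"""Conservation profiling, NG86 counting and the selection-intensity test."""

import itertools

import dendropy
import numpy as np
import pytest
from scipy import optimize

from genedecay.codon_model import (
    CodonRateModel,
    SENSE_CODONS,
    codons_to_indices,
    f3x4_frequencies,
    tree_loglik,
)
from genedecay.conservation_selection import (
    build_msa,
    complete_codon_columns,
    identity_profile,
    ng86_omega,
    relax_test,
)
from genedecay.reference_model import DomainPartition, DomainRegion
from genedecay.synthetic_data import SimulationConfig, simulate


def toy_partition(n: int) -> DomainPartition:
    return DomainPartition(
        regions=(DomainRegion("all", 1, n),), analysis_start=1
    )


class TestBuildMSA:
    def test_identical_pair_trivial(self, ref_cds):
        msa = build_msa({"a": ref_cds, "b": ref_cds}, ref_cds)
        assert msa.n_species == 2
        assert msa.n_residues == 692
        assert msa.removed_insertions == []
        assert (msa.codon_columns[0] == msa.codon_columns[1]).all()

    def test_private_insertion_removed_and_logged(self, ref_cds):
        withins = ref_cds[:600] + "GCTGCA" + ref_cds[600:]
        cohort = {"ins": withins, "b": ref_cds, "c": ref_cds,
                  "d": ref_cds, "e": ref_cds, "f": ref_cds,
                  "g": ref_cds, "h": ref_cds, "i": ref_cds,
                  "j": ref_cds, "k": ref_cds}
        msa = build_msa(cohort, ref_cds)
        assert msa.insertion_columns == []
        assert len(msa.removed_insertions) == 2  # two inserted codons
        assert msa.removed_insertions[0]["carriers"] == ["ins"]
        assert msa.n_residues == 692

    def test_shared_deletion_columns_retained(self, ref_cds):
        """In-frame deletions shared by the whole cohort stay visible as
        gap columns in canonical numbering."""
        deleted = ref_cds[:900] + ref_cds[903:]
        cohort = {f"s{i}": deleted for i in range(4)}
        msa = build_msa(cohort, ref_cds)
        gap_cols = (msa.codon_columns == "---").all(axis=0)
        # a 3-bp deletion hits one codon, or two when the aligner places
        # the gap across a codon boundary; either way every species shows
        # the same shared gap columns
        assert 1 <= gap_cols.sum() <= 2
        per_species_gaps = (msa.codon_columns == "---").sum(axis=1)
        assert len(set(per_species_gaps)) == 1
        assert msa.n_residues == 692

    def test_widely_shared_insertion_becomes_column(self, ref_cds):
        withins = ref_cds[:600] + "GCTGCA" + ref_cds[600:]
        cohort = {"a": withins, "b": withins, "c": ref_cds}
        msa = build_msa(cohort, ref_cds)
        assert len(msa.insertion_columns) == 2
        assert msa.removed_insertions == []


class TestIdentityProfile:
    def test_identical_pair_all_100(self, ref_cds, bundle):
        msa = build_msa({"a": ref_cds, "b": ref_cds}, ref_cds)
        profile = identity_profile(msa, bundle.domains)
        valid = ~np.isnan(profile.column_identity)
        assert (profile.column_identity[valid] == 100.0).all()
        assert profile.analysis_conserved_fraction == 1.0
        for name, mean in profile.domain_mean.items():
            assert mean == pytest.approx(100.0)

    def test_hand_computed_three_sequences(self):
        """Three 10-residue sequences checked against pair-by-pair
        enumeration done independently below."""
        seqs = {
            "a": "ATGGCTGCTGCAGCAGCTGCAGCTGCAGCA",
            "b": "ATGGCTTCTGCAGCAGCTGCAGCTGCAGCA",
            "c": "ATGTCTTCTGCAGCAGCTGCAGCTGCAGCA",
        }
        ref = seqs["a"] + "TAA"
        msa = build_msa(
            {k: v + "TAA" for k, v in seqs.items()}, ref
        )
        profile = identity_profile(msa, toy_partition(10))
        aa = msa.aa_matrix()
        for col in range(10):
            pairs = list(itertools.combinations(range(3), 2))
            expected = 100.0 * np.mean(
                [aa[i, col] == aa[j, col] for i, j in pairs]
            )
            assert profile.column_identity[col] == pytest.approx(expected)
        # columns 2 and 3 (0-based 1, 2) carry the substitutions
        assert profile.column_identity[1] == pytest.approx(100 / 3)
        assert profile.column_identity[2] == pytest.approx(100 / 3)
        assert profile.domain_mean["all"] == pytest.approx(
            (8 * 100 + 2 * 100 / 3) / 10
        )
        assert profile.domain_conserved_fraction["all"] == pytest.approx(0.8)

    def test_permutation_invariance(self, ref_cds, bundle, rng):
        cohort = {}
        for i in range(5):
            seq = list(ref_cds)
            for codon in rng.choice(600, 30, replace=False):
                seq[3 * codon: 3 * codon + 3] = list("GCA")
            cohort[f"s{i}"] = "".join(seq)
        p1 = identity_profile(
            build_msa(cohort, ref_cds), bundle.domains
        )
        shuffled = dict(reversed(list(cohort.items())))
        p2 = identity_profile(
            build_msa(shuffled, ref_cds), bundle.domains
        )
        np.testing.assert_allclose(
            p1.column_identity, p2.column_identity
        )


class TestNG86:
    def test_identical_sequences_no_substitutions(self):
        r = ng86_omega({"a": "ATGAAA", "b": "ATGAAA"})
        assert r.omega is None
        assert r.note == "no substitutions"

    def test_single_synonymous_difference_gives_omega_zero(self):
        # one GCT -> GCC change (synonymous, Ala) over 21 codons
        a = "ATG" + "GCT" * 20
        b = "ATG" + "GCT" * 19 + "GCC"
        r = ng86_omega({"a": a, "b": b})
        assert r.dn == 0.0
        assert r.ds > 0
        assert r.omega == 0.0

    def test_single_nonsynonymous_difference_ds_zero(self):
        # GCT -> GTT is Ala -> Val
        r = ng86_omega({"a": "ATGGCT", "b": "ATGGTT"})
        assert r.ds == 0.0
        assert r.omega is None
        assert r.note == "dS = 0"

    def test_neutral_simulation_recovers_omega_near_one(self):
        cfg = SimulationConfig(
            seed=31, newick="(A:25,B:25);", n_codons=400,
            background_omega=1.0, branch_scale=0.006,
        )
        res = simulate(cfg)
        r = ng86_omega(res.tip_cds)
        assert r.omega == pytest.approx(1.0, rel=0.35)

    def test_purifying_simulation_gives_low_omega(self):
        cfg = SimulationConfig(
            seed=32, newick="(A:25,B:25);", n_codons=400,
            background_omega=0.1, branch_scale=0.006,
        )
        res = simulate(cfg)
        r = ng86_omega(res.tip_cds)
        assert r.omega < 0.4


def exhaustive_loglik_4tip(tree, tips, pi, kappa, omega):
    """Likelihood by explicit summation over all internal-state
    assignments of a 4-tip tree ((A,B),(C,D)) — the brute-force oracle
    for the pruning implementation."""
    m = CodonRateModel(kappa, omega, pi)
    root = tree.seed_node
    X, Y = root.child_nodes()
    PX = m.transition_matrix(X.edge.length)
    PY = m.transition_matrix(Y.edge.length)
    Pt = {
        leaf.taxon.label: m.transition_matrix(leaf.edge.length)
        for leaf in tree.leaf_node_iter()
    }
    A, B = [c.taxon.label for c in X.child_nodes()]
    C, D = [c.taxon.label for c in Y.child_nodes()]
    n61 = len(SENSE_CODONS)
    total = 0.0
    n_sites = len(next(iter(tips.values())))
    for s in range(n_sites):
        a, b = tips[A][s], tips[B][s]
        c, d = tips[C][s], tips[D][s]
        # joint probability tensor over (root, x, y) internal states
        joint = (
            pi[:, None, None]
            * PX[:, :, None]
            * PY[:, None, :]
            * (Pt[A][:, a] * Pt[B][:, b])[None, :, None]
            * (Pt[C][:, c] * Pt[D][:, d])[None, None, :]
        )
        assert joint.shape == (n61, n61, n61)
        total += np.log(joint.sum())
    return total


class TestCodonLikelihood:
    def test_transition_matrix_matches_scipy_expm(self, rng):
        """The spectral P(t) equals the matrix exponential computed by
        an independent dense algorithm."""
        from scipy.linalg import expm

        pi = f3x4_frequencies(rng.integers(0, 61, 300))
        for kappa, omega in [(2.0, 0.3), (1.0, 1.0)]:
            m = CodonRateModel(kappa, omega, pi)
            for t in (0.05, 0.5, 2.0):
                err = np.abs(
                    m.transition_matrix(t) - expm(m.Q * t)
                ).max()
                assert err < 1e-9

    def test_pruning_equals_exhaustive_summation(self, rng):
        tree = dendropy.Tree.get(
            data="((A:0.12,B:0.25):0.1,(C:0.3,D:0.07):0.18);",
            schema="newick",
        )
        pi = f3x4_frequencies(rng.integers(0, 61, 300))
        tips = {l: rng.integers(0, 61, size=15) for l in "ABCD"}
        for kappa, omega in [(2.0, 0.2), (1.0, 1.0), (4.0, 0.05)]:
            ll = tree_loglik(tree, tips, pi, kappa, omega)
            oracle = exhaustive_loglik_4tip(tree, tips, pi, kappa, omega)
            assert ll == pytest.approx(oracle, abs=1e-8)

    def test_missing_data_tip_is_marginalized(self, rng):
        tree = dendropy.Tree.get(
            data="((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1);",
            schema="newick",
        )
        pi = f3x4_frequencies(rng.integers(0, 61, 300))
        tips = {l: rng.integers(0, 61, size=10) for l in "ABCD"}
        tips_missing = dict(tips)
        tips_missing["D"] = np.full(10, -1)
        ll = tree_loglik(tree, tips_missing, pi, 2.0, 0.3)
        # equals the likelihood of the 3-tip tree without D
        tree3 = dendropy.Tree.get(
            data="((A:0.1,B:0.1):0.1,C:0.2);", schema="newick"
        )
        ll3 = tree_loglik(
            tree3, {l: tips[l] for l in "ABC"}, pi, 2.0, 0.3
        )
        assert ll == pytest.approx(ll3, abs=1e-8)

    def test_ml_pairwise_omega_agrees_with_ng86(self):
        """Model-free NG86 and the ML fit agree within 20% at moderate
        divergence on pairwise data."""
        cfg = SimulationConfig(
            seed=77, newick="(A:20,B:20);", n_codons=600,
            background_omega=0.3, branch_scale=0.005,
        )
        res = simulate(cfg)
        tips = {
            k: codons_to_indices(v[:-3]) for k, v in res.tip_cds.items()
        }
        pi = f3x4_frequencies(np.concatenate(list(tips.values())))
        tree = dendropy.Tree.get(
            data="(A:20,B:20);", schema="newick", rooting="force-rooted"
        )

        def nll(x):
            return -tree_loglik(
                tree, tips, pi, np.exp(x[0]), np.exp(x[1]),
                branch_scale=np.exp(x[2]),
            )

        fit = optimize.minimize(
            nll, [np.log(2.0), np.log(0.3), np.log(0.005)],
            method="L-BFGS-B",
        )
        ml_omega = float(np.exp(fit.x[1]))
        ng = ng86_omega(res.tip_cds)
        assert ng.omega == pytest.approx(ml_omega, rel=0.20)


class TestRelaxTest:
    def _cohort(self, seed, post_loss_omega=1.0, loss=("T1|T2",)):
        nwk = "((T1:15,T2:15):20,((T3:15,T4:15):10,(T5:20,T6:20):5):10);"
        cfg = SimulationConfig(
            seed=seed, newick=nwk, n_codons=400,
            background_omega=0.1, post_loss_omega=post_loss_omega,
            branch_scale=0.01, loss_branches=loss,
            frameshift_rate=0.0, nonsense_rate=0.0,
        )
        res = simulate(cfg)
        tips = complete_codon_columns(
            {k: codons_to_indices(v[:-3]) for k, v in res.tip_cds.items()}
        )
        return tips, res.tree

    def test_relaxed_clade_detected(self):
        tips, tree = self._cohort(5)
        r = relax_test(tips, tree, {"T1", "T2"}, n_starts=1)
        assert r.K < 1.0
        assert r.pvalue < 0.05
        assert r.omega_test > r.omega_reference
        assert r.lrt >= 0.0
        assert r.lnl_alt >= r.lnl_null

    def test_null_not_significant_under_equal_omega(self):
        tips, tree = self._cohort(6, loss=())
        r = relax_test(tips, tree, {"T1", "T2"}, n_starts=1)
        assert r.pvalue > 0.01
        assert r.lnl_alt >= r.lnl_null

    def test_k_one_implies_equal_omegas(self):
        from genedecay.conservation_selection import SelectionResult

        tips, tree = self._cohort(8, loss=())
        r = relax_test(tips, tree, {"T3", "T4"}, n_starts=1)
        implied = r.omega_reference ** r.K
        assert r.omega_test == pytest.approx(implied, rel=1e-6)

    def test_species_tree_mismatch_rejected(self):
        tips, tree = self._cohort(9, loss=())
        del tips["T6"]
        with pytest.raises(ValueError):
            relax_test(tips, tree, {"T1", "T2"})

    def test_test_set_must_be_proper_subset(self):
        tips, tree = self._cohort(10, loss=())
        with pytest.raises(ValueError):
            relax_test(tips, tree, set(tips))
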