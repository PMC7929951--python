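"""Synthetic cohorts with full truth tables for end-to-end validation.

The generator emulates the inferred decay process of a pseudogenizing
gene: codon evolution under purifying selection (ω < 1) on functional
branches and, on every lineage descending from a loss event, a switch to
neutral evolution (ω = 1) accompanied by frameshifting indels, nonsense
substitutions and exon-scale deletions.  Every planted alteration is
recorded in a truth table so that lesion calling, loss mapping, dating
and selection testing can each be scored against ground truth.

All randomness flows through one :class:`numpy.random.Generator` seeded
from the configuration; identical seeds give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd

from .codon_model import (
    SENSE_CODONS,
    CodonRateModel,
    codons_to_indices,
    evolve_codons,
    f3x4_frequencies,
    indices_to_codons,
)
from .reference_model import GeneModel

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "simulate",
    "yule_tree",
    "inject_deletion",
    "mutate_sequence",
    "surviving_truth",
]

STOPS = ("TAA", "TAG", "TGA")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated cohort.

    Rates are per-branch-length unit; branch lengths are read from the
    tree, in My for a chronogram (substitution rates then being per My)
    or in expected substitutions per codon for a phylogram with
    ``branch_scale`` = 1.
    """

    seed: int
    newick: str | None = None  # explicit tree; otherwise Yule
    n_tips: int = 8
    tree_age: float = 50.0  # root age (My) for generated Yule trees
    n_codons: int = 500
    root_cds: str | None = None  # defaults to a stationary draw
    background_omega: float = 0.1
    post_loss_omega: float = 1.0  # neutrality after loss; <1 emulates
    # partial relaxation (omega_test = background_omega**K)
    kappa: float = 2.0
    branch_scale: float = 0.005  # substitutions/codon per My on the tree
    loss_branches: tuple[str, ...] = ()  # named by their subtended tip sets,
    # e.g. "A|B" = branch above MRCA of {A, B}; () means no losses
    frameshift_rate: float = 2e-5  # events per coding bp per My, post-loss
    nonsense_rate: float = 2e-4  # events per codon per My, post-loss
    exon_deletion_rate: float = 0.0  # events per exon per My, post-loss
    indel_frameshift_prob: float = 0.8  # else in-frame (3n) indel

    def __post_init__(self) -> None:
        for name in (
            "background_omega",
            "post_loss_omega",
            "kappa",
            "branch_scale",
            "frameshift_rate",
            "nonsense_rate",
            "exon_deletion_rate",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.indel_frameshift_prob <= 1:
            raise ValueError("indel_frameshift_prob outside [0, 1]")


@dataclass
class SimulationResult:
    tree: dendropy.Tree
    root_cds: str  # ancestral CDS: the reference for scanning the tips
    tip_cds: dict[str, str]
    truth: pd.DataFrame  # planted lesions: tip, kind, ref_bp_start/end, ...
    branch_regimes: pd.DataFrame  # per-branch: clade, regime, loss_time
    config: SimulationConfig

    def tip_states(self) -> dict[str, str]:
        """True retained/lost state per tip, from the branch regimes."""
        regime = dict(
            zip(self.branch_regimes["branch"], self.branch_regimes["regime"])
        )
        return {
            tip: (
                "lost"
                if regime.get(tip) in ("loss", "neutral")
                else "retained"
            )
            for tip in self.tip_cds
        }


def yule_tree(
    n_tips: int, age: float, rng: np.random.Generator
) -> dendropy.Tree:
    """Ultrametric pure-birth tree with ``n_tips`` tips and root age ``age``.

    Standard backward construction: exponential coalescence-style merge
    times rescaled so the root sits at ``age``.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    taxa = dendropy.TaxonNamespace(
        [f"T{i + 1}" for i in range(n_tips)]
    )
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = []
    for taxon in taxa:
        node = dendropy.Node(taxon=taxon)
        node.age_tmp = 0.0
        nodes.append(node)
    t = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        t += rng.exponential(1.0 / k)
        i, j = sorted(rng.choice(k, size=2, replace=False))
        parent = dendropy.Node()
        parent.age_tmp = t
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent.add_child(a)
        parent.add_child(b)
        nodes.append(parent)
    root = nodes[0]
    scale = age / root.age_tmp
    tree.seed_node = root
    for node in tree.preorder_node_iter():
        node.age_tmp *= scale
        if node.parent_node is not None:
            node.edge.length = (
                node.parent_node.age_tmp - node.age_tmp
            )
    return tree


def _branch_key(node: dendropy.Node) -> str:
    tips = sorted(
        leaf.taxon.label for leaf in node.leaf_iter()
    )
    return "|".join(tips)


def _random_root_cds(
    n_codons: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform random sense codons with an ATG start, no stops."""
    idx = rng.integers(0, len(SENSE_CODONS), size=n_codons)
    idx[0] = _ATG
    return idx


_ATG = SENSE_CODONS.index("ATG")


@dataclass
class _Lesion:
    kind: str
    ref_bp_start: int
    ref_bp_end: int
    allele: str
    branch: str


def _plant_lesions(
    cfg: SimulationConfig,
    model: GeneModel | None,
    duration: float,
    n_codons: int,
    branch: str,
    rng: np.random.Generator,
) -> list[_Lesion]:
    """Draw the decay lesions accrued on one neutral branch segment."""
    lesions: list[_Lesion] = []
    cds_bp = 3 * n_codons
    n_fs = rng.poisson(cfg.frameshift_rate * cds_bp * duration)
    for _ in range(n_fs):
        pos = int(rng.integers(1, cds_bp - 6))
        if rng.random() < cfg.indel_frameshift_prob:
            length = int(rng.integers(1, 3))  # 1 or 2 bp
            kind = "frameshift_indel"
        else:
            length = int(rng.choice([3, 6]))
            kind = "inframe_indel"
        if rng.random() < 0.5:
            lesions.append(
                _Lesion(kind, pos, pos + length - 1, f"del{length}", branch)
            )
        else:
            ins = "".join(
                "ACGT"[i] for i in rng.integers(0, 4, size=length)
            )
            lesions.append(_Lesion(kind, pos, pos, f"ins{ins}", branch))
    n_stop = rng.poisson(cfg.nonsense_rate * n_codons * duration)
    # keep nonsense well before the reference stop so calls are unambiguous
    for _ in range(n_stop):
        codon = int(rng.integers(2, max(3, n_codons - 10)))
        stop = STOPS[rng.integers(0, 3)]
        bp = 3 * (codon - 1) + 1
        lesions.append(
            _Lesion("premature_stop", bp, bp + 2, f"{stop}@{codon}", branch)
        )
    if model is not None and cfg.exon_deletion_rate > 0:
        offsets = model.exon_cds_offsets()
        n_del = rng.poisson(
            cfg.exon_deletion_rate * len(offsets) * duration
        )
        for _ in range(n_del):
            k = int(rng.integers(0, len(offsets)))
            lo, hi = offsets[k]
            lesions.append(
                _Lesion(
                    "exon_deletion",
                    lo + 1,
                    hi,
                    f"del{hi - lo}",
                    branch,
                )
            )
    return lesions


def _apply_lesions(cds: str, lesions: list[_Lesion]) -> str:
    """Apply planted lesions to a tip CDS by reference coordinates.

    Deletions mask reference positions; insertions attach after their
    anchor base; premature stops overwrite the codon in place.  Larger
    deletions silently swallow smaller lesions inside them, matching the
    truth-table convention that a lesion survives at a tip unless
    overwritten by a larger deletion.
    """
    n = len(cds)
    keep = np.ones(n, dtype=bool)
    bases = list(cds)
    inserts: dict[int, str] = {}
    for les in lesions:
        if les.allele.startswith("del"):
            keep[les.ref_bp_start - 1:les.ref_bp_end] = False
        elif les.allele.startswith("ins"):
            inserts[les.ref_bp_start - 1] = (
                inserts.get(les.ref_bp_start - 1, "") + les.allele[3:]
            )
        elif les.kind == "premature_stop":
            stop = les.allele.split("@")[0]
            bases[les.ref_bp_start - 1:les.ref_bp_start + 2] = list(stop)
    out = []
    for i in range(n):
        if keep[i]:
            out.append(bases[i])
        if i in inserts and keep[i]:
            out.append(inserts[i])
    return "".join(out)


def simulate(
    cfg: SimulationConfig, model: GeneModel | None = None
) -> SimulationResult:
    """Run one cohort simulation.

    Codon states evolve by sampling from matrix-exponential transition
    probabilities of the same generator used in fitting.  A loss branch
    switches from the background model to the neutral (ω = 1) model at a
    loss time drawn uniformly along the branch; all descendant branches
    are then fully neutral and accrue decay lesions, which are applied to
    the evolved tip sequences and recorded in the truth table.
    """
    rng = np.random.default_rng(cfg.seed)
    if cfg.newick is not None:
        tree = dendropy.Tree.get(
            data=cfg.newick, schema="newick", rooting="force-rooted"
        )
    else:
        tree = yule_tree(cfg.n_tips, cfg.tree_age, rng)

    if cfg.root_cds is not None:
        root_idx = codons_to_indices(cfg.root_cds)
        if (root_idx < 0).any():
            raise ValueError("root CDS contains stops/ambiguity")
    else:
        root_idx = _random_root_cds(cfg.n_codons, rng)
    n_codons = root_idx.size
    pi = f3x4_frequencies(root_idx)
    bg = CodonRateModel(cfg.kappa, cfg.background_omega, pi)
    neutral = CodonRateModel(cfg.kappa, cfg.post_loss_omega, pi)

    keys = {}
    for node in tree.postorder_node_iter():
        keys[id(node)] = _branch_key(node)
    known = {keys[id(n)] for n in tree.preorder_node_iter()}
    bad = set(cfg.loss_branches) - known
    if bad:
        raise ValueError(f"loss branches not in tree: {sorted(bad)}")

    states: dict[int, np.ndarray] = {id(tree.seed_node): root_idx}
    lost_below: dict[int, bool] = {id(tree.seed_node): False}
    lesion_store: dict[int, list[_Lesion]] = {id(tree.seed_node): []}
    regime_rows = []
    truth_rows = []

    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        parent = node.parent_node
        t = (node.edge.length or 0.0)
        key = keys[id(node)]
        parent_lost = lost_below[id(parent)]
        is_loss_branch = key in cfg.loss_branches and not parent_lost
        lost = parent_lost or is_loss_branch
        lost_below[id(node)] = lost
        lesions = list(lesion_store[id(parent)])

        sub_t = t * cfg.branch_scale
        if not lost:
            child = evolve_codons(states[id(parent)], bg, sub_t, rng)
            neutral_span = 0.0
        elif is_loss_branch:
            loss_at = float(rng.uniform(0.0, t))  # time from branch start
            pre = evolve_codons(
                states[id(parent)], bg, loss_at * cfg.branch_scale, rng
            )
            child = evolve_codons(
                pre, neutral, (t - loss_at) * cfg.branch_scale, rng
            )
            neutral_span = t - loss_at
            regime_rows.append(
                {
                    "branch": key,
                    "regime": "loss",
                    "loss_time_from_branch_start": loss_at,
                    "branch_length": t,
                }
            )
        else:
            child = evolve_codons(states[id(parent)], neutral, sub_t, rng)
            neutral_span = t
        child[0] = states[id(parent)][0]  # start codon treated as invariant
        if not (lost and not is_loss_branch):
            if not lost:
                regime_rows.append(
                    {
                        "branch": key,
                        "regime": "selected",
                        "loss_time_from_branch_start": np.nan,
                        "branch_length": t,
                    }
                )
        else:
            regime_rows.append(
                {
                    "branch": key,
                    "regime": "neutral",
                    "loss_time_from_branch_start": np.nan,
                    "branch_length": t,
                }
            )
        if neutral_span > 0:
            lesions.extend(
                _plant_lesions(
                    cfg, model, neutral_span, n_codons, key, rng
                )
            )
        states[id(node)] = child
        lesion_store[id(node)] = lesions

        if node.is_leaf():
            tip = node.taxon.label
            for les in lesions:
                truth_rows.append(
                    {
                        "tip": tip,
                        "kind": les.kind,
                        "ref_bp_start": les.ref_bp_start,
                        "ref_bp_end": les.ref_bp_end,
                        "allele": les.allele,
                        "branch": les.branch,
                    }
                )

    tip_cds = {}
    for leaf in tree.leaf_node_iter():
        seq = indices_to_codons(states[id(leaf)]) + "TAA"
        lesions = lesion_store[id(leaf)]
        tip_cds[leaf.taxon.label] = (
            _apply_lesions(seq, lesions) if lesions else seq
        )

    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "tip", "kind", "ref_bp_start", "ref_bp_end", "allele", "branch",
        ],
    )
    regimes = pd.DataFrame(
        regime_rows,
        columns=[
            "branch", "regime", "loss_time_from_branch_start",
            "branch_length",
        ],
    )
    return SimulationResult(
        tree=tree,
        root_cds=indices_to_codons(root_idx) + "TAA",
        tip_cds=tip_cds,
        truth=truth,
        branch_regimes=regimes,
        config=cfg,
    )


def surviving_truth(truth: pd.DataFrame) -> pd.DataFrame:
    """Planted lesions that survive at their tip.

    A lesion whose reference span is contained inside a *deletion*
    planted on the same lineage is overwritten (its bases are gone at
    the tip) and is not expected to be recoverable.
    """
    if len(truth) == 0:
        return truth
    keep = []
    for tip, grp in truth.groupby("tip"):
        dels = grp[grp["allele"].str.startswith("del")]
        for idx, row in grp.iterrows():
            covered = (
                (dels.index != idx)
                & (dels["ref_bp_start"] <= row["ref_bp_start"])
                & (dels["ref_bp_end"] >= row["ref_bp_end"])
            )
            if not covered.any():
                keep.append(idx)
    return truth.loc[sorted(keep)]


# ---------------------------------------------------------------------------
# locus-level helpers
# ---------------------------------------------------------------------------


def inject_deletion(
    locus: str, start: int, end: int
) -> tuple[str, dict]:
    """Excise locus[start:end) (0-based half-open) and record the truth.

    Returns the mutated locus and a record with the 1-based breakpoint
    anchors as :mod:`genedecay.locus_archaeology` reports them: the last
    retained base before the deletion and the first after it.
    """
    if not 0 <= start <= end <= len(locus):
        raise ValueError(
            f"span [{start}, {end}) outside locus of {len(locus)} bp"
        )
    mutated = locus[:start] + locus[end:]
    record = {
        "left_ref": start,  # 1-based last base kept == 0-based start
        "right_ref": end + 1,  # 1-based first base kept after the cut
        "span": end + 1 - start,
        "deleted_bp": end - start,
    }
    return mutated, record


def mutate_sequence(
    seq: str, rate: float, rng: np.random.Generator
) -> str:
    """Independent substitutions at the given per-base rate (locus noise)."""
    seq = list(seq)
    n_mut = rng.binomial(len(seq), rate)
    for pos in rng.choice(len(seq), size=n_mut, replace=False):
        current = seq[pos]
        options = [b for b in "ACGT" if b != current]
        seq[pos] = options[rng.integers(0, 3)]
    return "".join(seq)
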