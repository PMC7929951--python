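"""Counting and dating independent gene-loss events on a species tree.

Gene loss is modelled as a Dollo character: a functional gene can be lost
any number of times but never regained.  Under that assumption the
minimum number of independent losses explaining a set of tip states is
determined exactly by marking every internal node *retained* iff any
descendant tip retained the gene; each edge from a retained parent to a
lost child is one loss event.

Event ages are bracketed from a dated tree: the crown age of the losing
clade (all members already share the loss, so it happened no later) is
the minimum, and the age of the split from the nearest gene-retaining
lineage is the maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy

from .locus_archaeology import Breakpoint

__all__ = [
    "Chronogram",
    "SharedLesionGroup",
    "LossEvent",
    "dollo_min_losses",
    "match_lesions",
    "match_breakpoints",
    "date_events",
    "scenario_totals",
    "RETAINED",
    "LOST",
    "UNCERTAIN",
]

RETAINED, LOST, UNCERTAIN = "retained", "lost", "uncertain"


class Chronogram:
    """A rooted, dated species tree (ages in My before present).

    Wraps a :class:`dendropy.Tree`.  Ages are taken from branch lengths
    assuming an ultrametric tree (tips at age 0); alternatively, ages for
    named clades can be imposed with ``node_ages`` — a mapping from a
    frozenset of tip labels to the age of their MRCA — in which case
    branch lengths are optional.
    """

    def __init__(
        self,
        tree: dendropy.Tree,
        node_ages: dict[frozenset[str], float] | None = None,
    ):
        self.tree = tree
        self.tree.encode_bipartitions(suppress_unifurcations=False)
        self._ages: dict[int, float] = {}
        if node_ages:
            self._apply_age_table(node_ages)
        else:
            self._ages_from_lengths()
        for node in self.tree.preorder_node_iter():
            if node.parent_node is not None:
                if self.age(node) > self.age(node.parent_node) + 1e-9:
                    raise ValueError(
                        "child older than parent: tree is not a valid "
                        "chronogram"
                    )

    @classmethod
    def from_newick(
        cls,
        newick: str,
        node_ages: dict[frozenset[str], float] | None = None,
    ) -> "Chronogram":
        tree = dendropy.Tree.get(
            data=newick, schema="newick", rooting="force-rooted"
        )
        return cls(tree, node_ages=node_ages)

    def _ages_from_lengths(self) -> None:
        depths = {}
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None:
                depths[id(node)] = 0.0
            else:
                depths[id(node)] = depths[id(node.parent_node)] + (
                    node.edge.length or 0.0
                )
        max_depth = max(
            depths[id(leaf)] for leaf in self.tree.leaf_node_iter()
        )
        self._ages = {k: max_depth - v for k, v in depths.items()}

    def _apply_age_table(
        self, node_ages: dict[frozenset[str], float]
    ) -> None:
        self._ages = {
            id(leaf): 0.0 for leaf in self.tree.leaf_node_iter()
        }
        for tips, age in node_ages.items():
            node = self.mrca(tips)
            self._ages[id(node)] = float(age)
        # interpolate any unaged internal node between dated neighbours
        for node in self.tree.postorder_internal_node_iter():
            if id(node) not in self._ages:
                self._ages[id(node)] = max(
                    self._ages[id(c)] for c in node.child_nodes()
                )

    def age(self, node: dendropy.Node) -> float:
        return self._ages[id(node)]

    def tips(self) -> list[str]:
        return [
            leaf.taxon.label for leaf in self.tree.leaf_node_iter()
        ]

    def mrca(self, tip_labels) -> dendropy.Node:
        labels = set(tip_labels)
        node = self.tree.mrca(
            taxa=[
                t
                for t in self.tree.taxon_namespace
                if t.label in labels
            ]
        )
        if node is None:
            raise ValueError(f"no MRCA for {sorted(labels)}")
        return node

    def tip_set(self, node: dendropy.Node) -> frozenset[str]:
        return frozenset(
            leaf.taxon.label for leaf in node.leaf_iter()
        )


# ---------------------------------------------------------------------------
# Dollo parsimony
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LossBranch:
    """An edge on which a loss event is placed, named by the losing clade."""

    clade: frozenset[str]
    child_age: float
    parent_age: float


def dollo_min_losses(
    chronogram: Chronogram,
    tip_states: dict[str, str],
    uncertain: str = "exclude",
) -> tuple[int, list[LossBranch]]:
    """Minimum number of irreversible losses and their branches.

    ``tip_states`` maps every tip label to ``retained``/``lost``/
    ``uncertain``.  Uncertain tips are excluded by default (they carry no
    information either way); ``uncertain='retained'`` or ``'lost'``
    forces them into a state.  If every considered tip is lost, the
    single event is placed on the stem above the root (ages equal to the
    root age: the data cannot see further back).
    """
    if uncertain not in ("exclude", RETAINED, LOST):
        raise ValueError(f"bad uncertain policy {uncertain!r}")
    tips = set(chronogram.tips())
    missing = tips - tip_states.keys()
    if missing:
        raise ValueError(f"tips without state: {sorted(missing)}")
    state = {}
    for label in tips:
        s = tip_states[label]
        if s == UNCERTAIN:
            if uncertain == "exclude":
                continue
            s = uncertain
        if s not in (RETAINED, LOST):
            raise ValueError(f"bad state {s!r} for tip {label}")
        state[label] = s
    if not state:
        return 0, []

    retained: dict[int, bool] = {}
    considered: dict[int, bool] = {}  # subtree has any considered tip
    for node in chronogram.tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            considered[id(node)] = label in state
            retained[id(node)] = state.get(label) == RETAINED
        else:
            kids = node.child_nodes()
            considered[id(node)] = any(considered[id(c)] for c in kids)
            retained[id(node)] = any(
                retained[id(c)] for c in kids
            )

    losses: list[LossBranch] = []
    root = chronogram.tree.seed_node
    if not retained[id(root)]:
        age = chronogram.age(root)
        losses.append(
            LossBranch(
                clade=chronogram.tip_set(root) & state.keys(),
                child_age=age,
                parent_age=age,
            )
        )
        return 1, losses
    for node in chronogram.tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            continue
        if (
            considered[id(node)]
            and retained[id(parent)]
            and not retained[id(node)]
        ):
            losses.append(
                LossBranch(
                    clade=chronogram.tip_set(node) & state.keys(),
                    child_age=chronogram.age(node),
                    parent_age=chronogram.age(parent),
                )
            )
    return len(losses), losses


# ---------------------------------------------------------------------------
# lesion matching across species
# ---------------------------------------------------------------------------


@dataclass
class SharedLesionGroup:
    """Species sharing one lesion signature (same kind, allele and
    coordinates within tolerance)."""

    kind: str
    allele: str
    ref_bp_start: int
    ref_bp_end: int
    members: list[str]

    @property
    def size(self) -> int:
        return len(self.members)


def match_lesions(
    lesion_table,
    tolerance: int = 2,
) -> list[SharedLesionGroup]:
    """Group per-species lesions into shared-signature groups.

    ``lesion_table`` is an iterable of mappings (or a DataFrame) with
    columns ``species, kind, ref_bp_start, ref_bp_end, allele``.
    Matching is exact on kind and allele with a +/-``tolerance`` bp slack
    on coordinates (alignment jitter at homopolymers); each lesion joins
    at most one group, anchored to the group's first member.
    """
    if hasattr(lesion_table, "to_dict"):
        rows = lesion_table.to_dict("records")
    else:
        rows = [dict(r) for r in lesion_table]
    rows.sort(
        key=lambda r: (
            r["kind"],
            r["allele"],
            int(r["ref_bp_start"]),
            int(r["ref_bp_end"]),
            r["species"],
        )
    )
    groups: list[SharedLesionGroup] = []
    for row in rows:
        g = groups[-1] if groups else None
        if (
            g is not None
            and g.kind == row["kind"]
            and g.allele == row["allele"]
            and abs(int(row["ref_bp_start"]) - g.ref_bp_start) <= tolerance
            and abs(int(row["ref_bp_end"]) - g.ref_bp_end) <= tolerance
        ):
            g.members.append(row["species"])
        else:
            groups.append(
                SharedLesionGroup(
                    kind=row["kind"],
                    allele=row["allele"],
                    ref_bp_start=int(row["ref_bp_start"]),
                    ref_bp_end=int(row["ref_bp_end"]),
                    members=[row["species"]],
                )
            )
    for g in groups:
        g.members = sorted(set(g.members))
    return groups


def match_breakpoints(
    per_species: dict[str, list[Breakpoint]],
) -> list[tuple[Breakpoint, list[str]]]:
    """Group breakpoints across species by ambiguity-interval overlap."""
    groups: list[tuple[Breakpoint, list[str]]] = []
    for species in sorted(per_species):
        for bp in per_species[species]:
            for anchor, members in groups:
                if anchor.matches(bp):
                    members.append(species)
                    break
            else:
                groups.append((bp, [species]))
    return [(a, sorted(set(m))) for a, m in groups]


# ---------------------------------------------------------------------------
# dating
# ---------------------------------------------------------------------------


@dataclass
class LossEvent:
    clade: frozenset[str]
    min_age: float  # crown age of the losing clade
    max_age: float  # stem age: split from the nearest retaining lineage
    evidence: str
    rejected: bool = False
    diagnostic: str = ""

    def to_dict(self) -> dict:
        return {
            "clade": ",".join(sorted(self.clade)),
            "min_age": self.min_age,
            "max_age": self.max_age,
            "evidence": self.evidence,
            "rejected": self.rejected,
            "diagnostic": self.diagnostic,
        }


def date_events(
    chronogram: Chronogram,
    groups: list[SharedLesionGroup] | None = None,
    dollo_branches: list[LossBranch] | None = None,
    tip_states: dict[str, str] | None = None,
) -> list[LossEvent]:
    """Bound the age of each loss event from the dated tree.

    Shared-lesion groups date the event to [crown age of the members'
    MRCA, age of that node's parent].  A group whose MRCA subtends a
    gene-retaining tip is rejected (the signature is likely homoplasy,
    not a single ancestral lesion).  Dollo-assigned branches (no shared
    molecular evidence needed) are dated the same way from their own
    endpoints.
    """
    events: list[LossEvent] = []
    for group in groups or []:
        label = f"{group.kind} {group.allele} @{group.ref_bp_start}"
        members = set(group.members)
        missing = members - set(chronogram.tips())
        if missing:
            raise ValueError(f"group members not in tree: {sorted(missing)}")
        if len(members) == 1:
            tip = chronogram.mrca(members)
            events.append(
                LossEvent(
                    clade=frozenset(members),
                    min_age=0.0,
                    max_age=chronogram.age(tip.parent_node)
                    if tip.parent_node
                    else chronogram.age(tip),
                    evidence=label,
                )
            )
            continue
        node = chronogram.mrca(members)
        below = chronogram.tip_set(node)
        retaining = {
            t
            for t in below
            if tip_states is not None and tip_states.get(t) == RETAINED
        }
        if retaining:
            events.append(
                LossEvent(
                    clade=frozenset(members),
                    min_age=chronogram.age(node),
                    max_age=chronogram.age(node.parent_node)
                    if node.parent_node
                    else chronogram.age(node),
                    evidence=label,
                    rejected=True,
                    diagnostic=(
                        "MRCA subtends gene-retaining tip(s) "
                        f"{sorted(retaining)}: signature likely homoplasy"
                    ),
                )
            )
            continue
        events.append(
            LossEvent(
                clade=frozenset(members),
                min_age=chronogram.age(node),
                max_age=chronogram.age(node.parent_node)
                if node.parent_node
                else chronogram.age(node),
                evidence=label,
            )
        )
    for branch in dollo_branches or []:
        events.append(
            LossEvent(
                clade=branch.clade,
                min_age=branch.child_age,
                max_age=branch.parent_age,
                evidence="dollo",
            )
        )
    return events


def scenario_totals(
    per_clade_ranges: dict[str, tuple[int, int]]
) -> tuple[int, int]:
    """Total loss-count range: sum of per-clade minima and maxima."""
    lo = sum(v[0] for v in per_clade_ranges.values())
    hi = sum(v[1] for v in per_clade_ranges.values())
    if lo > hi:
        raise ValueError("per-clade minima exceed maxima")
    return lo, hi
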