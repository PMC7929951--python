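"""Lesion calling and gene-status classification for a query CDS.

A *lesion* is any alteration relevant to gene status, localized in
reference CDS coordinates.  Severity encodes how it bears on
functionality:

* ``hard`` — inactivating on its own: premature stops before the
  late-truncation threshold, frameshifting indels, exon-scale or
  whole-gene deletions, splice disruptions, start-codon loss, and
  substitution of the residues required for autocatalytic maturation
  (catalytic triad + oxyanion-hole asparagine), without which the protein
  is not secreted.
* ``soft`` — suspicious but tolerated in known lineages: substitution of
  a conserved structural cysteine.
* ``neutral`` — in-frame indels and truncations at or after the
  late-truncation threshold (residue 681 by default), which leave the
  protein functional.

Indels by themselves are deliberately not treated as evidence of
inactivation when in frame: shared ancient in-frame indels occur in
lineages with fully functional genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from Bio.Seq import Seq

from .alignment import AlignmentParams, CodonAwareAlignment, align_cds
from .reference_model import GeneModel, KeyResidueSet, cds_to_protein

__all__ = [
    "Lesion",
    "GeneStatusCall",
    "StatusThresholds",
    "call_lesions",
    "classify_status",
    "scan_query",
    "HARD",
    "SOFT",
    "NEUTRAL",
]

HARD, SOFT, NEUTRAL = "hard", "soft", "neutral"
STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class Lesion:
    """One detected alteration, in 1-based reference CDS coordinates."""

    kind: str
    ref_bp_start: int
    ref_bp_end: int
    allele: str
    severity: str
    note: str = ""

    @property
    def ref_codon_start(self) -> int:
        return cds_to_protein(self.ref_bp_start)

    @property
    def ref_codon_end(self) -> int:
        return cds_to_protein(self.ref_bp_end)

    def signature(self) -> tuple[str, int, int, str]:
        """Identity used when matching lesions across species."""
        return (self.kind, self.ref_bp_start, self.ref_bp_end, self.allele)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "ref_bp_start": self.ref_bp_start,
            "ref_bp_end": self.ref_bp_end,
            "ref_codon_start": self.ref_codon_start,
            "ref_codon_end": self.ref_codon_end,
            "allele": self.allele,
            "severity": self.severity,
            "note": self.note,
        }


@dataclass(frozen=True)
class StatusThresholds:
    """Coverage cut-offs for status calling.

    Queries covering less than ``exclusion`` of the reference CDS are not
    classifiable; ``completeness`` is the bar for calling a lesion-free
    query functional outright.
    """

    exclusion: float = 0.40
    completeness: float = 0.85


@dataclass
class GeneStatusCall:
    status: str  # functional | pseudogene | uncertain
    evidence: list[Lesion]
    coverage_fraction: float
    reason: str = ""

    def hard_lesions(self) -> list[Lesion]:
        return [l for l in self.evidence if l.severity == HARD]

    def soft_lesions(self) -> list[Lesion]:
        return [l for l in self.evidence if l.severity == SOFT]


# ---------------------------------------------------------------------------
# lesion calling
# ---------------------------------------------------------------------------


def _indel_runs(aln: CodonAwareAlignment):
    """Maximal gap runs as (type, col_start, col_end_exclusive)."""
    q, r = aln.aligned_query, aln.aligned_ref
    runs = []
    i = 0
    while i < len(q):
        if q[i] == "-" and r[i] != "-":
            j = i
            while j < len(q) and q[j] == "-" and r[j] != "-":
                j += 1
            runs.append(("del", i, j))
            i = j
        elif q[i] != "-" and r[i] == "-":
            j = i
            while j < len(q) and q[j] != "-" and r[j] == "-":
                j += 1
            runs.append(("ins", i, j))
            i = j
        else:
            i += 1
    return runs


def _ref_pos_of_col(aln: CodonAwareAlignment):
    """Per-column 1-based reference bp (0 before the first ref base)."""
    pos, out = 0, []
    for rc in aln.aligned_ref:
        if rc != "-":
            pos += 1
        out.append(pos)
    return out


def _exons_fully_deleted(model: GeneModel, bp_start: int, bp_end: int):
    """Model exon indices whose whole coding span lies in [bp_start, bp_end]."""
    hit = []
    for exon, (lo, hi) in zip(model.exons, model.exon_cds_offsets()):
        if bp_start <= lo + 1 and hi <= bp_end:
            hit.append(exon.index)
    return hit


def _indel_lesions(
    aln: CodonAwareAlignment, model: GeneModel | None
) -> list[Lesion]:
    refpos = _ref_pos_of_col(aln)
    cds_len = len(aln.reference)
    ncols = len(aln.aligned_ref)
    lesions = []
    for kind, i, j in _indel_runs(aln):
        if kind == "del" and (i == 0 or j == ncols):
            # terminal query gap: incomplete sequence, not a deletion call
            continue
        length = j - i
        if kind == "del":
            bp_start, bp_end = refpos[i], refpos[j - 1]
            allele = f"del{length}"
            if length == cds_len:
                lesions.append(
                    Lesion(
                        "whole_gene_deletion", 1, cds_len, allele, HARD
                    )
                )
                continue
            exons = (
                _exons_fully_deleted(model, bp_start, bp_end)
                if model is not None
                else []
            )
            if exons:
                lesions.append(
                    Lesion(
                        "exon_deletion",
                        bp_start,
                        bp_end,
                        allele,
                        HARD,
                        note="exons " + ",".join(map(str, exons)),
                    )
                )
                continue
        else:
            # insertion anchored after the preceding reference base
            anchor = max(1, refpos[i])
            bp_start = bp_end = anchor
            inserted = aln.aligned_query[i:j]
            allele = f"ins{inserted}"
        if length % 3:
            kind_name = "frameshift_indel"
            severity = HARD
        else:
            kind_name = "inframe_indel"
            severity = NEUTRAL
        lesions.append(
            Lesion(kind_name, bp_start, bp_end, allele, severity)
        )
    return lesions


def _annotate_frame_restoration(lesions: list[Lesion]) -> list[Lesion]:
    """Mark frameshift pairs whose lengths cancel back into frame.

    Compensated pairs remain hard: lineages with overlapping 1-bp and 2-bp
    deletions restoring the frame are still pseudogenes, but the derived
    annotation is useful when auditing calls.
    """
    out = list(lesions)
    shift = 0
    open_group: list[int] = []
    for idx, les in enumerate(out):
        if les.kind != "frameshift_indel":
            continue
        length = (
            int(les.allele[3:])
            if les.allele.startswith("del")
            else len(les.allele[3:])
        )
        delta = length if les.allele.startswith("ins") else -length
        shift = (shift + delta) % 3
        open_group.append(idx)
        if shift == 0:
            for g in open_group:
                out[g] = replace(out[g], note="frame_restored")
            open_group = []
    return out


def _aligned_query_codon(aln: CodonAwareAlignment, codon: int) -> str | None:
    """Query triplet aligned to the three bases of reference codon ``codon``.

    Homologous-triplet semantics: downstream of a frameshift the triplet
    is still read off the alignment columns (stop codons and residue
    substitutions are called as they appear in the alignment, the way
    pseudogene alignments are read in practice).  Returns None when any
    of the three columns is gapped or incomplete.
    """
    cols = []
    ref_base = 0
    lo, hi = 3 * (codon - 1), 3 * codon
    for i, rc in enumerate(aln.aligned_ref):
        if rc != "-":
            if lo <= ref_base < hi:
                cols.append(i)
            ref_base += 1
            if ref_base >= hi:
                break
    if len(cols) != 3:
        return None
    bases = [aln.aligned_query[c] for c in cols]
    if "-" in bases:
        return None
    return "".join(bases)


def call_lesions(
    aln: CodonAwareAlignment,
    model: GeneModel | None = None,
    keyres: KeyResidueSet | None = None,
) -> list[Lesion]:
    """Call all lesions on a codon-aware alignment.

    ``model`` enables exon-scale deletion classification; ``keyres``
    enables key-residue substitution calls and sets the late-truncation
    threshold (default 681 without a key-residue set).
    """
    n_ref_codons = len(aln.reference) // 3  # includes the stop codon
    threshold = keyres.late_truncation_threshold if keyres else 681

    lesions = _annotate_frame_restoration(_indel_lesions(aln, model))
    if any(l.kind == "whole_gene_deletion" for l in lesions):
        return sorted(lesions, key=lambda l: (l.ref_bp_start, l.kind))

    stop_codon_sites = set()
    # reference codon n_ref_codons is the stop; scan coding codons only
    for codon in range(1, n_ref_codons):
        qcodon = _aligned_query_codon(aln, codon)
        if qcodon is None or "N" in qcodon:
            continue
        if qcodon in STOP_CODONS:
            stop_codon_sites.add(codon)
            bp = 3 * (codon - 1) + 1
            if codon < threshold:
                lesions.append(
                    Lesion(
                        "premature_stop", bp, bp + 2, f"{qcodon}@{codon}", HARD
                    )
                )
            else:
                lesions.append(
                    Lesion(
                        "late_truncation",
                        bp,
                        bp + 2,
                        f"{qcodon}@{codon}",
                        NEUTRAL,
                    )
                )

    first_codon = _aligned_query_codon(aln, 1)
    if first_codon is not None and "N" not in first_codon:
        if first_codon != "ATG":
            lesions.append(
                Lesion("start_loss", 1, 3, f"ATG>{first_codon}", HARD)
            )

    if keyres is not None:
        for res in keyres.all_residues():
            codon = res.position
            if codon >= n_ref_codons or codon in stop_codon_sites:
                continue
            qcodon = _aligned_query_codon(aln, codon)
            if qcodon is None or "N" in qcodon:
                continue
            observed = str(Seq(qcodon).translate())
            if observed == res.expected_aa:
                continue
            severity = HARD if res.position in keyres.hard_positions else SOFT
            bp = 3 * (codon - 1) + 1
            lesions.append(
                Lesion(
                    "key_residue_substitution",
                    bp,
                    bp + 2,
                    f"{res.expected_aa}{res.position}{observed}",
                    severity,
                    note=res.role,
                )
            )

    return sorted(lesions, key=lambda l: (l.ref_bp_start, l.kind))


# ---------------------------------------------------------------------------
# status classification
# ---------------------------------------------------------------------------


def classify_status(
    lesions: list[Lesion],
    coverage: float,
    thresholds: StatusThresholds | None = None,
) -> GeneStatusCall:
    """Apply the functionality criteria to a lesion list plus coverage."""
    if not 0.0 <= coverage <= 1.0:
        raise ValueError(f"coverage {coverage} outside [0, 1]")
    thresholds = thresholds or StatusThresholds()
    if coverage < thresholds.exclusion:
        return GeneStatusCall(
            "uncertain", list(lesions), coverage, reason="insufficient coverage"
        )
    hard = [l for l in lesions if l.severity == HARD]
    soft = [l for l in lesions if l.severity == SOFT]
    if hard:
        return GeneStatusCall(
            "pseudogene",
            list(lesions),
            coverage,
            reason=f"{len(hard)} inactivating lesion(s)",
        )
    if soft:
        return GeneStatusCall(
            "uncertain",
            list(lesions),
            coverage,
            reason="conserved-cysteine substitution(s) only",
        )
    if coverage < thresholds.completeness:
        return GeneStatusCall(
            "uncertain", list(lesions), coverage, reason="incomplete sequence"
        )
    return GeneStatusCall("functional", list(lesions), coverage)


def scan_query(
    query: str,
    reference: str,
    model: GeneModel | None = None,
    keyres: KeyResidueSet | None = None,
    params: AlignmentParams | None = None,
    thresholds: StatusThresholds | None = None,
) -> GeneStatusCall:
    """Align, call lesions and classify in one step."""
    aln = align_cds(query, reference, params)
    lesions = call_lesions(aln, model, keyres)
    return classify_status(lesions, aln.coverage_fraction(), thresholds)
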