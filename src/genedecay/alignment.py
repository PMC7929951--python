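"""Frame-aware global pairwise alignment of a query CDS to the reference CDS.

The aligner itself is a standard global affine-gap aligner
(:class:`Bio.Align.PairwiseAligner`); what this module adds is the codon
bookkeeping layered on top: per-column reference codon indices and a frame
state track that records where insertions/deletions of length not divisible
by three knock the query out of the reference reading frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align

__all__ = ["AlignmentParams", "CodonAwareAlignment", "align_cds"]

_VALID = set("ACGTN")


@dataclass(frozen=True)
class AlignmentParams:
    """Affine-gap scoring; defaults favour long clean gaps over scatter."""

    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -8.0
    gap_extend: float = -1.0


@dataclass
class CodonAwareAlignment:
    """Column-indexed global alignment of query against the reference CDS.

    Attributes
    ----------
    aligned_query, aligned_ref:
        Equal-length strings with ``-`` for gaps.
    ref_codon:
        Per-column 1-based reference codon index (codon of the reference
        base in that column; for reference-gap columns, the codon of the
        last preceding reference base, 0 before any).
    frame_state:
        Per-column frame offset of the query relative to the reference
        reading frame: 0 in frame, 1 or 2 shifted.  Changes only at indel
        columns whose cumulative length mod 3 is nonzero.
    score:
        Alignment score under the declared parameters.
    """

    aligned_query: str
    aligned_ref: str
    score: float
    params: AlignmentParams
    ref_codon: np.ndarray = field(init=False)
    frame_state: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        q, r = self.aligned_query, self.aligned_ref
        if len(q) != len(r):
            raise ValueError("aligned strings differ in length")
        ref_codon = np.zeros(len(q), dtype=int)
        frame = np.zeros(len(q), dtype=int)
        ref_pos = 0  # reference bases consumed
        shift = 0  # (query bases - ref bases) consumed, mod 3
        for i, (qc, rc) in enumerate(zip(q, r)):
            if rc != "-":
                ref_pos += 1
            if qc != "-" and rc == "-":
                shift = (shift + 1) % 3
            elif qc == "-" and rc != "-":
                shift = (shift - 1) % 3
            ref_codon[i] = (ref_pos - 1) // 3 + 1 if ref_pos else 0
            frame[i] = shift
        self.ref_codon = ref_codon
        self.frame_state = frame

    @property
    def query(self) -> str:
        return self.aligned_query.replace("-", "")

    @property
    def reference(self) -> str:
        return self.aligned_ref.replace("-", "")

    def coverage_fraction(self) -> float:
        """Fraction of reference bases aligned to a non-N query base."""
        covered = sum(
            1
            for qc, rc in zip(self.aligned_query, self.aligned_ref)
            if rc != "-" and qc not in ("-", "N")
        )
        return covered / max(1, len(self.reference))

    def query_codon_at(self, ref_codon_index: int) -> str:
        """Query bases aligned to the three reference bases of a codon.

        Returns a 3-character string (may contain ``-``); only meaningful
        where the query is in frame.
        """
        cols = np.nonzero(
            (self.ref_codon == ref_codon_index)
            & (np.frombuffer(self.aligned_ref.encode(), dtype=np.uint8) != 45)
        )[0]
        return "".join(self.aligned_query[c] for c in cols)


def _collapse_slip_pairs(
    query_aln: str, ref_aln: str, max_sep: int = 15, max_len: int = 3
) -> tuple[str, str]:
    """Rewrite nearby equal-length del/ins gap pairs as substitutions.

    In homopolymer-rich regions an affine-gap aligner can explain a run
    of substitutions as a short deletion plus a nearby equal-length
    insertion ("slip").  Such pairs are less parsimonious than the
    substitutions they mimic and would fabricate frameshift calls, so
    windows containing exactly one deletion run and one insertion run of
    equal length (each <= ``max_len``, separated by <= ``max_sep``
    gap-free columns) are re-paired base to base.
    """
    def gap_kind(i: int) -> str | None:
        if query_aln[i] == "-" and ref_aln[i] != "-":
            return "del"
        if query_aln[i] != "-" and ref_aln[i] == "-":
            return "ins"
        return None

    while True:
        runs = []
        i = 0
        while i < len(query_aln):
            kind = gap_kind(i)
            if kind is None:
                i += 1
                continue
            j = i
            while j < len(query_aln) and gap_kind(j) == kind:
                j += 1
            runs.append((kind, i, j))
            i = j
        changed = False
        for (k1, a1, b1), (k2, a2, b2) in zip(runs, runs[1:]):
            if (
                k1 != k2
                and (b1 - a1) == (b2 - a2) <= max_len
                and a2 - b1 <= max_sep
            ):
                window_q = query_aln[a1:b2].replace("-", "")
                window_r = ref_aln[a1:b2].replace("-", "")
                if len(window_q) != len(window_r):
                    continue
                query_aln = query_aln[:a1] + window_q + query_aln[b2:]
                ref_aln = ref_aln[:a1] + window_r + ref_aln[b2:]
                changed = True
                break
        if not changed:
            return query_aln, ref_aln


def align_cds(
    query: str,
    reference: str,
    params: AlignmentParams | None = None,
) -> CodonAwareAlignment:
    """Globally align ``query`` to ``reference`` with affine gap costs.

    Tie-breaking is deterministic: the first alignment in the aligner's
    canonical enumeration order is used, which places gaps as far left as
    the scoring allows, so lesion coordinates are reproducible.
    """
    params = params or AlignmentParams()
    for name, seq in (("query", query), ("reference", reference)):
        if not seq:
            raise ValueError(f"{name} sequence is empty")
        bad = set(seq.upper()) - _VALID
        if bad:
            raise ValueError(f"{name} has invalid characters {sorted(bad)}")
    query, reference = query.upper(), reference.upper()
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    # N never rewards a match nor pays a mismatch
    aligner.wildcard = "N"
    # a query shorter than the reference is missing data, not a deletion:
    # terminal query gaps are free (semi-global alignment)
    try:
        aligner.end_deletion_score = 0.0
    except AttributeError:  # older biopython naming
        aligner.query_end_gap_score = 0.0
    alignment = aligner.align(reference, query)[0]
    ref_aln, query_aln = str(alignment[0]), str(alignment[1])
    query_aln, ref_aln = _collapse_slip_pairs(query_aln, ref_aln)
    return CodonAwareAlignment(
        aligned_query=query_aln,
        aligned_ref=ref_aln,
        score=float(alignment.score),
        params=params,
    )
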